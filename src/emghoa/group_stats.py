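"""Group-comparison statistics.

Two-group tests per parameter x sensor (overall or per task) are gated by a
Shapiro-Wilk normality check in each group: one-way ANOVA when both groups
look normal, Kruskal-Wallis otherwise.  No multiplicity correction is applied
across the sensor x task x parameter grid by default (Benjamini-Hochberg is
available via a flag).

The normalization values (MAX/MVC/GRASP per sensor) are compared with a mixed
repeated-measures ANOVA — group between subjects, sensor and method within —
followed by Tukey's-B homogeneous subsets on the sensor means.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import StatisticsError

__all__ = [
    "GroupComparisonResult",
    "normality_gate",
    "compare_groups",
    "compare_table",
    "mixed_rm_anova",
    "tukeys_b_subsets",
    "build_sign_table",
    "render_sign_table",
]

logger = logging.getLogger(__name__)

ALPHA = 0.05
ALPHA_NORM = 0.05


@dataclass(frozen=True)
class GroupComparisonResult:
    parameter: str
    sensor: int
    task_id: object  # int or "ALL"
    test_used: str  # "anova" | "kruskal_wallis"
    statistic: float
    p_value: float
    direction: str  # "patient_higher" | "patient_lower" | "none"


def normality_gate(
    healthy: np.ndarray,
    patients: np.ndarray,
    alpha_norm: float = ALPHA_NORM,
) -> str:
    """Choose the two-group test: ANOVA if both groups pass Shapiro-Wilk.

    Constant data (Shapiro-Wilk undefined) is treated as non-normal.
    """
    for name, vals in (("healthy", healthy), ("patients", patients)):
        v = np.asarray(vals, dtype=float)
        if len(v) < 3:
            raise StatisticsError(f"normality gate needs n >= 3 per group ({name} has {len(v)})")
        if np.ptp(v) == 0:
            logger.warning("constant data in %s group; treating as non-normal", name)
            return "kruskal_wallis"
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            _, p = stats.shapiro(v)
        if p < alpha_norm:
            return "kruskal_wallis"
    return "anova"


def compare_groups(
    healthy: np.ndarray,
    patients: np.ndarray,
    parameter: str,
    sensor: int,
    task_id: object = "ALL",
    alpha: float = ALPHA,
    alpha_norm: float = ALPHA_NORM,
) -> GroupComparisonResult:
    """Normality-gated two-group comparison of one feature cell.

    Direction (reported only when p < alpha) comes from group means for the
    ANOVA branch and from mean ranks for the Kruskal-Wallis branch.
    """
    h = np.asarray(healthy, dtype=float)
    p_ = np.asarray(patients, dtype=float)
    if len(h) == 0 or len(p_) == 0:
        raise StatisticsError(f"empty group in comparison of {parameter} sensor {sensor}")
    test = normality_gate(h, p_, alpha_norm=alpha_norm)
    if test == "anova":
        stat, pval = stats.f_oneway(h, p_)
        patient_higher = np.mean(p_) > np.mean(h)
    else:
        if np.ptp(np.concatenate([h, p_])) == 0:
            stat, pval = 0.0, 1.0
            patient_higher = False
        else:
            stat, pval = stats.kruskal(h, p_)
            ranks = stats.rankdata(np.concatenate([h, p_]))
            patient_higher = np.mean(ranks[len(h):]) > np.mean(ranks[: len(h)])
    if pval < alpha:
        direction = "patient_higher" if patient_higher else "patient_lower"
    else:
        direction = "none"
    return GroupComparisonResult(
        parameter=parameter,
        sensor=int(sensor),
        task_id=task_id,
        test_used=test,
        statistic=float(stat),
        p_value=float(pval),
        direction=direction,
    )


def compare_table(
    table: pd.DataFrame,
    value_column: str,
    parameter: str,
    per_task: bool = False,
    alpha: float = ALPHA,
    alpha_norm: float = ALPHA_NORM,
    bh_correction: bool = False,
) -> pd.DataFrame:
    """Run :func:`compare_groups` over every sensor (x task) cell of a table.

    ``table`` needs ``participant_id``, ``group``, ``sensor``, ``task_id`` (if
    ``per_task``) and the value column.  With ``bh_correction`` the p-values
    of the whole grid are Benjamini-Hochberg adjusted before thresholding.
    """
    rows = []
    keys = ["sensor", "task_id"] if per_task else ["sensor"]
    for key_vals, sub in table.groupby(keys, sort=True):
        if not per_task:
            key_vals = (key_vals,) if not isinstance(key_vals, tuple) else key_vals
        sensor = key_vals[0]
        task = key_vals[1] if per_task else "ALL"
        h = sub.loc[sub["group"] == "healthy", value_column].to_numpy(float)
        p_ = sub.loc[sub["group"] == "patient", value_column].to_numpy(float)
        res = compare_groups(
            h, p_, parameter, sensor, task, alpha=alpha, alpha_norm=alpha_norm
        )
        rows.append(res.__dict__ | {"parameter": parameter})
    out = pd.DataFrame(rows)
    if bh_correction and len(out):
        from statsmodels.stats.multitest import multipletests

        reject, p_adj, _, _ = multipletests(out["p_value"], alpha=alpha, method="fdr_bh")
        out["p_adjusted"] = p_adj
        # keep a cell's direction only if it survives the adjusted decision
        out["direction"] = [
            d if (rej and d != "none") else "none"
            for rej, d in zip(reject, out["direction"])
        ]
    return out


# ---------------------------------------------------------------------------
# Mixed repeated-measures ANOVA (group between; sensor and method within)
# ---------------------------------------------------------------------------

def mixed_rm_anova(table: pd.DataFrame, value_column: str = "value") -> pd.DataFrame:
    """Mixed-design ANOVA: group (between) x sensor x method (both within).

    ``table`` columns: ``participant_id``, ``group``, ``sensor``, ``method``
    and the value column; every participant must have a complete sensor x
    method grid.  Sums of squares use unweighted marginal means with the
    harmonic mean of the group sizes for within-subject strata (exact
    textbook values for balanced groups); each effect is tested against its
    own error stratum.  Returns one row per effect with SS, df, F and p.
    """
    df = table.copy()
    required = {"participant_id", "group", "sensor", "method", value_column}
    missing_cols = required - set(df.columns)
    if missing_cols:
        raise StatisticsError(f"mixed_rm_anova: missing columns {sorted(missing_cols)}")
    sensors = np.sort(df["sensor"].unique())
    methods = np.sort(df["method"].unique())
    a, b = len(sensors), len(methods)
    cube = df.pivot_table(
        index=["group", "participant_id"],
        columns=["sensor", "method"],
        values=value_column,
    )
    if cube.isna().any().any() or cube.shape[1] != a * b:
        raise StatisticsError("mixed_rm_anova: incomplete sensor x method grid")
    groups = cube.index.get_level_values("group")
    group_levels = list(pd.unique(groups))
    g = len(group_levels)
    n_g = np.array([(groups == gl).sum() for gl in group_levels])
    n_s = int(n_g.sum())
    n_h = g / np.sum(1.0 / n_g)  # harmonic mean of group sizes

    y = cube.to_numpy(float).reshape(n_s, a, b)
    gi = np.array([group_levels.index(gl) for gl in groups])

    subj_mean = y.mean(axis=(1, 2))
    grand_w = subj_mean.mean()
    gmeans = np.array([subj_mean[gi == j].mean() for j in range(g)])

    # between-subjects stratum
    ss_g = a * b * float(np.sum(n_g * (gmeans - grand_w) ** 2))
    ss_subj = a * b * float(sum(np.sum((subj_mean[gi == j] - gmeans[j]) ** 2) for j in range(g)))
    df_g, df_subj = g - 1, n_s - g

    def _stratum(profiles: np.ndarray, levels: int, mult: float):
        """SS for a within effect, its group interaction, and the error.

        ``profiles``: subject x levels, centered per subject (rows sum to 0).
        """
        cell = np.stack([profiles[gi == j].mean(axis=0) for j in range(g)])  # g x levels
        marg = cell.mean(axis=0)  # unweighted over groups
        ss_eff = mult * n_h * g * float(np.sum(marg**2))
        ss_int = mult * n_h * float(np.sum((cell - marg) ** 2))
        ss_err = mult * float(
            sum(np.sum((profiles[gi == j] - cell[j]) ** 2) for j in range(g))
        )
        return ss_eff, ss_int, ss_err

    sensor_prof = y.mean(axis=2) - subj_mean[:, None]  # n_s x a
    ss_s, ss_gs, ss_err_s = _stratum(sensor_prof, a, mult=b)
    method_prof = y.mean(axis=1) - subj_mean[:, None]  # n_s x b
    ss_m, ss_gm, ss_err_m = _stratum(method_prof, b, mult=a)
    inter = (
        y
        - y.mean(axis=2, keepdims=True)
        - y.mean(axis=1, keepdims=True)
        + subj_mean[:, None, None]
    ).reshape(n_s, a * b)
    ss_sm, ss_gsm, ss_err_sm = _stratum(inter, a * b, mult=1.0)

    rows = [
        ("group", ss_g, df_g, ss_subj, df_subj),
        ("sensor", ss_s, a - 1, ss_err_s, (a - 1) * df_subj),
        ("group:sensor", ss_gs, (g - 1) * (a - 1), ss_err_s, (a - 1) * df_subj),
        ("method", ss_m, b - 1, ss_err_m, (b - 1) * df_subj),
        ("group:method", ss_gm, (g - 1) * (b - 1), ss_err_m, (b - 1) * df_subj),
        ("sensor:method", ss_sm, (a - 1) * (b - 1), ss_err_sm, (a - 1) * (b - 1) * df_subj),
        (
            "group:sensor:method",
            ss_gsm,
            (g - 1) * (a - 1) * (b - 1),
            ss_err_sm,
            (a - 1) * (b - 1) * df_subj,
        ),
    ]
    records = []
    for name, ss, dfe, ss_err, df_err in rows:
        if df_err <= 0:
            raise StatisticsError(f"mixed_rm_anova: no error degrees of freedom for {name}")
        ms_err = ss_err / df_err
        ms = ss / dfe if dfe > 0 else 0.0
        if ms_err == 0.0:
            f = 0.0 if ss == 0.0 else np.inf
            p = 1.0 if ss == 0.0 else 0.0
        else:
            f = ms / ms_err
            p = float(stats.f.sf(f, dfe, df_err))
        records.append(
            {
                "effect": name,
                "ss": ss,
                "df": dfe,
                "ss_error": ss_err,
                "df_error": df_err,
                "F": f,
                "p_value": p,
            }
        )
    return pd.DataFrame(records)


def tukeys_b_subsets(
    means: Mapping[object, float],
    ms_error: float,
    df_error: float,
    n_per_level: float,
    alpha: float = ALPHA,
) -> list[list[object]]:
    """Tukey's-B homogeneous subsets of level means.

    The critical value for a span of r means averages the Tukey HSD
    studentized-range quantile q(alpha, k, df) and the Student-Newman-Keuls
    quantile q(alpha, r, df).  A contiguous run of sorted means forms a
    homogeneous subset when its range does not exceed the critical range for
    its span; maximal such runs are reported in ascending mean order.
    """
    if df_error <= 0:
        raise StatisticsError(f"tukeys_b_subsets: df_error must be > 0, got {df_error}")
    levels = sorted(means, key=lambda k: means[k])
    k = len(levels)
    if k < 2:
        return [list(levels)]
    se = np.sqrt(ms_error / n_per_level)
    q_full = stats.studentized_range.ppf(1 - alpha, k, df_error)

    def crit(span: int) -> float:
        if span < 2:
            return 0.0
        q_snk = stats.studentized_range.ppf(1 - alpha, span, df_error)
        return 0.5 * (q_full + q_snk) * se

    m = np.array([means[lv] for lv in levels])
    intervals = []
    for i in range(k):
        j = i
        while j + 1 < k and (m[j + 1] - m[i]) <= crit(j + 1 - i + 1):
            j += 1
        intervals.append((i, j))
    # keep maximal intervals only
    subsets = []
    for i, j in intervals:
        if not any(oi <= i and j <= oj and (oi, oj) != (i, j) for oi, oj in intervals):
            if (i, j) not in [(s[0], s[1]) for s in subsets]:
                subsets.append((i, j))
    return [levels[i : j + 1] for i, j in subsets]


def build_sign_table(results: Sequence[GroupComparisonResult] | pd.DataFrame) -> pd.DataFrame:
    """Per-task sign matrix: '+' patients higher, '-' lower, '' not significant.

    Rows are (parameter, sensor); columns are task ids.
    """
    if isinstance(results, pd.DataFrame):
        df = results
    else:
        df = pd.DataFrame([r.__dict__ for r in results])
    if len(df) == 0:
        return pd.DataFrame()
    sign = df["direction"].map({"patient_higher": "+", "patient_lower": "-", "none": ""})
    out = df.assign(sign=sign).pivot_table(
        index=["parameter", "sensor"],
        columns="task_id",
        values="sign",
        aggfunc="first",
    )
    return out.fillna("")


def render_sign_table(sign_table: pd.DataFrame) -> str:
    """Plain-text rendering of a sign matrix (rows sensor x parameter)."""
    if sign_table.empty:
        return "(no comparisons)"
    return sign_table.to_string()
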