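"""End-to-end orchestration: simulate -> preprocess -> features -> stats ->
discriminant, with CSV/JSON outputs and a reproducibility manifest."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

from . import discriminant as disc
from . import features as feat
from . import group_stats as gs
from . import normalization as norm
from . import preprocessing as prep
from .errors import ConfigurationError, StatisticsError
from .synthetic_data import CohortConfig, GroupEffect, RawRecording, generate_cohort

__all__ = [
    "RunConfig",
    "extract_tables",
    "overall_comparisons",
    "per_task_comparisons",
    "normalization_anova",
    "fit_study_classifiers",
    "run_full_analysis",
]

logger = logging.getLogger(__name__)

#: candidate-variable prefixes per study classifier family
FAMILY_PREFIXES = {
    "F_MAX": ("M_MAX", "R_MAX"),
    "F_MVC": ("M_MVC", "R_MVC"),
    "F_GRASP": ("M_GRASP", "R_GRASP"),
    "F_Waveform": ("NZC", "EWL"),
    "F_NoMVC": ("M_MAX", "R_MAX", "NZC", "EWL"),
}

_ID_COLUMNS = ("participant_id", "group")


@dataclass
class RunConfig:
    """Full pipeline configuration; serialized verbatim into the manifest."""

    cohort: CohortConfig = field(default_factory=CohortConfig)
    sigma_ms: float = prep.DEFAULT_SIGMA_MS
    n_frames: int = prep.N_FRAMES
    notch_on_waveform: bool = False
    alpha: float = gs.ALPHA
    alpha_norm: float = gs.ALPHA_NORM
    bh_correction: bool = False
    p_enter: float = 0.05
    p_remove: float = 0.10
    strict_loocv: bool = False

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        eff = d["cohort"]["effect"]
        if eff.get("affected_sensors") is not None:
            eff["affected_sensors"] = sorted(eff["affected_sensors"])
        return d

    @staticmethod
    def from_dict(d: dict) -> "RunConfig":
        d = dict(d)
        cohort = d.pop("cohort", {})
        if isinstance(cohort, dict):
            cohort = dict(cohort)
            eff = cohort.pop("effect", {})
            if isinstance(eff, dict):
                eff = dict(eff)
                if eff.get("affected_sensors") is not None:
                    eff["affected_sensors"] = frozenset(eff["affected_sensors"])
                eff = GroupEffect(**eff)
            if "noise_band" in cohort and cohort["noise_band"] is not None:
                cohort["noise_band"] = tuple(cohort["noise_band"])
            cohort = CohortConfig(effect=eff, **cohort)
        return RunConfig(cohort=cohort, **d)

    @staticmethod
    def from_yaml(path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ConfigurationError(f"config file {path} must hold a mapping")
        return RunConfig.from_dict(data)


# ---------------------------------------------------------------------------
# feature extraction
# ---------------------------------------------------------------------------

def extract_tables(
    recordings: Iterable[RawRecording],
    sigma_ms: float = prep.DEFAULT_SIGMA_MS,
    n_frames: int = prep.N_FRAMES,
    notch_on_waveform: bool = False,
) -> dict[str, pd.DataFrame]:
    """Run both processing paths and build all feature tables.

    Returns ``normalization``, ``amplitude`` (per-task median/range per
    method), ``waveform`` (per-task NZC/EWL raw rates and rescaled values) and
    the wide participant ``summary``.
    """
    recs = list(recordings)
    by_ps: dict[tuple[str, int], list[RawRecording]] = {}
    group_of: dict[str, str] = {}
    for rec in recs:
        by_ps.setdefault((rec.participant_id, rec.sensor), []).append(rec)
        group_of[rec.participant_id] = rec.group

    norm_rows, amp_rows, wave_rows = [], [], []
    notch = prep.DEFAULT_NOTCH if notch_on_waveform else None
    for (pid, sensor), rec_list in sorted(by_ps.items()):
        envelopes = [
            prep.amplitude_envelope(r, sigma_ms=sigma_ms) for r in rec_list
        ]
        ns = norm.compute_normalization_values(envelopes, pid, sensor)
        norm_rows.append(ns)
        shft = [
            (r, e) for r, e in zip(rec_list, envelopes) if r.task_family == "shft"
        ]
        shft.sort(key=lambda t: t[0].task_id)
        nzc_rates, ewl_rates, task_ids = [], [], []
        for rec, env in shft:
            resampled = prep.resample_frames(env.samples, n_frames)
            for method in norm.METHODS:
                denom = ns.denominator(method)
                normalized = norm.normalize_envelope(
                    resampled, denom, context=f"{pid}/sensor{sensor}/{method}"
                )
                med, rng = feat.amplitude_params(normalized, n_frames)
                amp_rows.append(
                    {
                        "participant_id": pid,
                        "group": group_of[pid],
                        "sensor": sensor,
                        "task_id": rec.task_id,
                        "method": method,
                        "median": med,
                        "range": rng,
                    }
                )
            wf = prep.preprocess_waveform(rec, notch=notch)
            nzc_rates.append(feat.compute_nzc(wf.samples))
            ewl_rates.append(feat.compute_ewl(wf.samples))
            task_ids.append(rec.task_id)
        nzc_scaled = feat.rescale_minmax(nzc_rates, context=f"{pid}/sensor{sensor}/NZC")
        ewl_scaled = feat.rescale_minmax(ewl_rates, context=f"{pid}/sensor{sensor}/EWL")
        for tid, nr, er, nsc, esc in zip(task_ids, nzc_rates, ewl_rates, nzc_scaled, ewl_scaled):
            wave_rows.append(
                {
                    "participant_id": pid,
                    "group": group_of[pid],
                    "sensor": sensor,
                    "task_id": tid,
                    "nzc_rate": nr,
                    "ewl_rate": er,
                    "nzc_rescaled": nsc,
                    "ewl_rescaled": esc,
                }
            )
    amplitude = pd.DataFrame(amp_rows)
    waveform = pd.DataFrame(wave_rows)
    summary = feat.summarize_participants(amplitude, waveform)
    return {
        "normalization": norm.normalization_table(norm_rows),
        "normalization_sets": norm_rows,
        "amplitude": amplitude,
        "waveform": waveform,
        "summary": summary,
    }


def _parse_feature_column(col: str) -> tuple[str, int] | None:
    import re

    m = re.fullmatch(r"(M_MAX|R_MAX|M_MVC|R_MVC|M_GRASP|R_GRASP|NZC|EWL)(\d+)", col)
    return (m.group(1), int(m.group(2))) if m else None


# ---------------------------------------------------------------------------
# statistics
# ---------------------------------------------------------------------------

def overall_comparisons(
    summary: pd.DataFrame,
    alpha: float = gs.ALPHA,
    alpha_norm: float = gs.ALPHA_NORM,
) -> pd.DataFrame:
    """Group comparison of every task-averaged feature column."""
    rows = []
    h_mask = summary["group"] == "healthy"
    for col in summary.columns:
        parsed = _parse_feature_column(str(col))
        if parsed is None:
            continue
        param, sensor = parsed
        res = gs.compare_groups(
            summary.loc[h_mask, col].to_numpy(float),
            summary.loc[~h_mask, col].to_numpy(float),
            param,
            sensor,
            alpha=alpha,
            alpha_norm=alpha_norm,
        )
        rows.append(res.__dict__ | {"column": col})
    return pd.DataFrame(rows)


def per_task_comparisons(
    amplitude: pd.DataFrame,
    waveform: pd.DataFrame,
    alpha: float = gs.ALPHA,
    alpha_norm: float = gs.ALPHA_NORM,
    bh_correction: bool = False,
) -> pd.DataFrame:
    """Per-task group comparisons for every parameter x sensor cell."""
    parts = []
    for method in norm.METHODS:
        sub = amplitude[amplitude["method"] == method]
        for stat, prefix in (("median", "M"), ("range", "R")):
            parts.append(
                gs.compare_table(
                    sub,
                    stat,
                    f"{prefix}_{method}",
                    per_task=True,
                    alpha=alpha,
                    alpha_norm=alpha_norm,
                    bh_correction=bh_correction,
                )
            )
    for col, name in (("nzc_rescaled", "NZC"), ("ewl_rescaled", "EWL")):
        parts.append(
            gs.compare_table(
                waveform,
                col,
                name,
                per_task=True,
                alpha=alpha,
                alpha_norm=alpha_norm,
                bh_correction=bh_correction,
            )
        )
    return pd.concat(parts, ignore_index=True)


def normalization_anova(
    normalization: pd.DataFrame,
    groups: pd.Series | dict,
    alpha: float = gs.ALPHA,
) -> dict:
    """Mixed RM-ANOVA of the normalization values plus Tukey's-B sensor subsets."""
    long = normalization.melt(
        id_vars=["participant_id", "sensor"],
        value_vars=["max_mV", "mvc_mV", "grasp_mV"],
        var_name="method",
        value_name="value",
    )
    long["method"] = long["method"].str.replace("_mV", "", regex=False).str.upper()
    if isinstance(groups, dict):
        long["group"] = long["participant_id"].map(groups)
    else:
        long["group"] = long["participant_id"].map(dict(groups))
    table = gs.mixed_rm_anova(long)
    sensor_row = table[table["effect"] == "sensor"].iloc[0]
    means = long.groupby("sensor")["value"].mean().to_dict()
    n_subj = long["participant_id"].nunique()
    n_methods = long["method"].nunique()
    subsets = gs.tukeys_b_subsets(
        means,
        ms_error=sensor_row["ss_error"] / sensor_row["df_error"],
        df_error=sensor_row["df_error"],
        n_per_level=n_subj * n_methods,
        alpha=alpha,
    )
    return {"anova": table, "sensor_means": means, "tukey_b_subsets": subsets}


# ---------------------------------------------------------------------------
# discriminant stage
# ---------------------------------------------------------------------------

def fit_study_classifiers(
    summary: pd.DataFrame,
    overall: pd.DataFrame,
    alpha: float = gs.ALPHA,
    p_enter: float = 0.05,
    p_remove: float = 0.10,
    strict_loocv: bool = False,
    families: Sequence[str] = tuple(FAMILY_PREFIXES),
) -> dict[str, dict]:
    """Stepwise LDA + LOOCV per classifier family.

    Candidates are restricted to the feature columns that differed
    significantly between groups in the overall comparisons.  Box's M is run
    on each family's candidate set; a violation (p < 0.05) is logged and the
    analysis proceeds.
    """
    sig_cols = [
        f"{row.parameter}{row.sensor}"
        for row in overall.itertuples()
        if row.direction != "none"
    ]
    results: dict[str, dict] = {}
    y = summary["group"].to_numpy()
    for family in families:
        prefixes = FAMILY_PREFIXES[family]
        candidates = [
            c
            for c in sig_cols
            if any(
                c.startswith(p) and _parse_feature_column(c)[0] == p for p in prefixes
            )
        ]
        entry: dict = {"family": family, "candidates": candidates}
        if not candidates:
            entry["model"] = None
            entry["note"] = "no significant candidate variables"
            results[family] = entry
            continue
        try:
            X = summary[candidates].to_numpy(float)
            m_stat, m_p = disc.boxs_m_test(X, y)
            entry["boxs_m"] = {"M": m_stat, "p": m_p}
            if m_p < alpha:
                logger.warning(
                    "%s: Box's M violated (p=%.3g); proceeding with LDA", family, m_p
                )
        except StatisticsError as exc:
            entry["boxs_m"] = {"error": str(exc)}
        model = disc.stepwise_lda(
            summary, candidates, p_enter=p_enter, p_remove=p_remove
        )
        entry["model"] = model
        if model is not None:
            entry["cv"] = disc.loocv(
                summary,
                model.variables if not strict_loocv else candidates,
                strict=strict_loocv,
                p_enter=p_enter,
                p_remove=p_remove,
            )
        results[family] = entry
    return results


# ---------------------------------------------------------------------------
# full run
# ---------------------------------------------------------------------------

def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_full_analysis(config: RunConfig, outdir: str | Path) -> dict:
    """Simulate a cohort and run the complete analysis, writing all outputs.

    Writes feature tables, comparison tables, sign matrices, the RM-ANOVA of
    normalization values, fitted discriminant models with CV reports, and a
    manifest (config + content hashes).  Identical config => identical hashes.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    logger.info("simulating cohort (seed=%s)", config.cohort.seed)
    recordings, truth = generate_cohort(config.cohort)
    logger.info("extracting features from %d recordings", len(recordings))
    tables = extract_tables(
        recordings,
        sigma_ms=config.sigma_ms,
        n_frames=config.n_frames,
        notch_on_waveform=config.notch_on_waveform,
    )
    overall = overall_comparisons(tables["summary"], config.alpha, config.alpha_norm)
    per_task = per_task_comparisons(
        tables["amplitude"],
        tables["waveform"],
        config.alpha,
        config.alpha_norm,
        config.bh_correction,
    )
    sign_table = gs.build_sign_table(per_task)
    norm_groups = dict(zip(tables["summary"]["participant_id"], tables["summary"]["group"]))
    rm = normalization_anova(tables["normalization"], norm_groups, config.alpha)
    models = fit_study_classifiers(
        tables["summary"],
        overall,
        alpha=config.alpha,
        p_enter=config.p_enter,
        p_remove=config.p_remove,
        strict_loocv=config.strict_loocv,
    )

    files: dict[str, Path] = {}

    def _write_csv(name: str, df: pd.DataFrame) -> None:
        path = outdir / name
        df.to_csv(path, index=False)
        files[name] = path

    _write_csv("ground_truth.csv", truth)
    _write_csv("normalization_values.csv", tables["normalization"])
    _write_csv("amplitude_features.csv", tables["amplitude"])
    _write_csv("waveform_features.csv", tables["waveform"])
    _write_csv("participant_summary.csv", tables["summary"])
    _write_csv("comparisons_overall.csv", overall)
    _write_csv("comparisons_per_task.csv", per_task)
    _write_csv("rm_anova_normalization.csv", rm["anova"])
    sign_path = outdir / "sign_matrix.txt"
    sign_path.write_text(gs.render_sign_table(sign_table) + "\n")
    files["sign_matrix.txt"] = sign_path

    model_payload = {}
    for family, entry in models.items():
        model = entry.get("model")
        model_payload[family] = {
            "candidates": entry.get("candidates", []),
            "boxs_m": entry.get("boxs_m"),
            "model": model.to_dict() if model is not None else None,
            "cv": entry["cv"].to_dict() if entry.get("cv") is not None else None,
            "note": entry.get("note"),
        }
    models_path = outdir / "discriminant_models.json"
    models_path.write_text(json.dumps(model_payload, indent=2, sort_keys=True) + "\n")
    files["discriminant_models.json"] = models_path

    manifest = {
        "config": config.to_dict(),
        "seed": config.cohort.seed,
        "n_recordings": len(recordings),
        "tukey_b_subsets": [[int(s) for s in sub] for sub in rm["tukey_b_subsets"]],
        "files": {name: _sha256(path) for name, path in sorted(files.items())},
    }
    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return {
        "tables": tables,
        "overall": overall,
        "per_task": per_task,
        "sign_table": sign_table,
        "rm_anova": rm,
        "models": models,
        "manifest": manifest,
    }
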