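"""Box's M, stepwise Wilks'-lambda LDA, LOOCV and the published formulas."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from emghoa.discriminant import (
    PUBLISHED_CLASSIFIERS,
    DiscriminantModel,
    boxs_m_test,
    evaluate_published_classifier,
    fit_lda,
    loocv,
    stepwise_lda,
    wilks_lambda,
)
from emghoa.errors import MissingInputError, StatisticsError


def _table(X, y, columns=None):
    columns = columns or [f"x{i}" for i in range(X.shape[1])]
    df = pd.DataFrame(X, columns=columns)
    df["group"] = y
    df["participant_id"] = [f"S{i:03d}" for i in range(len(df))]
    return df


# ---------------------------------------------------------------------------
# Box's M
# ---------------------------------------------------------------------------

def test_boxs_m_zero_for_duplicated_groups(rng):
    X0 = rng.standard_normal((12, 3))
    X = np.vstack([X0, X0])
    labels = ["healthy"] * 12 + ["patient"] * 12
    M, p = boxs_m_test(X, labels)
    assert M == pytest.approx(0.0, abs=1e-10)
    assert p == pytest.approx(1.0)


def test_boxs_m_matches_log_determinant_formula(rng):
    Xh = rng.standard_normal((8, 2))
    Xp = rng.standard_normal((9, 2)) * 1.5
    X = np.vstack([Xh, Xp])
    labels = np.array(["healthy"] * 8 + ["patient"] * 9)
    M, p = boxs_m_test(X, labels)
    # independent textbook computation
    S1 = np.cov(Xh, rowvar=False)
    S2 = np.cov(Xp, rowvar=False)
    n1, n2, g, k = 8, 9, 2, 2
    Sp = ((n1 - 1) * S1 + (n2 - 1) * S2) / (n1 + n2 - g)
    M_oracle = (n1 + n2 - g) * np.log(np.linalg.det(Sp)) - (
        (n1 - 1) * np.log(np.linalg.det(S1)) + (n2 - 1) * np.log(np.linalg.det(S2))
    )
    c1 = (
        (2 * k**2 + 3 * k - 1)
        / (6.0 * (k + 1) * (g - 1))
        * (1.0 / (n1 - 1) + 1.0 / (n2 - 1) - 1.0 / (n1 + n2 - g))
    )
    chi2 = M_oracle * (1 - c1)
    p_oracle = stats.chi2.sf(chi2, k * (k + 1) * (g - 1) / 2)
    assert M == pytest.approx(M_oracle, rel=1e-10)
    assert p == pytest.approx(p_oracle, rel=1e-10)


def test_boxs_m_detects_inflated_variance():
    rng = np.random.default_rng(0)
    hits = 0
    for _ in range(20):
        Xh = rng.standard_normal((40, 3))
        Xp = rng.standard_normal((40, 3)) * np.sqrt(10.0)
        _, p = boxs_m_test(np.vstack([Xh, Xp]), ["h"] * 40 + ["p"] * 40)
        hits += p < 0.05
    assert hits >= 18


def test_boxs_m_singularity_error(rng):
    x = rng.standard_normal(10)
    X = np.column_stack([x, x])  # perfectly collinear
    with pytest.raises(StatisticsError, match="singular"):
        boxs_m_test(X, ["h"] * 5 + ["p"] * 5)


# ---------------------------------------------------------------------------
# stepwise selection
# ---------------------------------------------------------------------------

def test_single_separating_variable_gives_perfect_training_accuracy(rng):
    x = np.concatenate([rng.normal(0, 0.1, 10), rng.normal(5, 0.1, 10)])
    y = ["healthy"] * 10 + ["patient"] * 10
    table = _table(x[:, None], y)
    model = stepwise_lda(table, ["x0"])
    assert model.variables == ["x0"]
    assert (model.classify(table) == np.array(y)).all()


def test_noise_variable_rarely_selected():
    rng = np.random.default_rng(42)
    noise_in = 0
    for _ in range(100):
        signal = np.concatenate([rng.normal(0, 1, 12), rng.normal(3, 1, 12)])
        noise = rng.standard_normal(24)
        y = ["healthy"] * 12 + ["patient"] * 12
        table = _table(np.column_stack([signal, noise]), y, ["sig", "noise"])
        model = stepwise_lda(table, ["sig", "noise"])
        assert model is not None and "sig" in model.variables
        noise_in += "noise" in model.variables
    assert noise_in <= 10


def test_duplicated_candidates_enter_once(rng):
    x = np.concatenate([rng.normal(0, 1, 10), rng.normal(4, 1, 10)])
    y = ["healthy"] * 10 + ["patient"] * 10
    table = _table(np.column_stack([x, x]), y, ["a", "b"])
    model = stepwise_lda(table, ["a", "b"])
    assert len(model.variables) == 1


def test_no_model_when_nothing_discriminates(rng):
    x = rng.standard_normal(30)
    y = ["healthy"] * 15 + ["patient"] * 15
    assert stepwise_lda(_table(x[:, None], y), ["x0"]) is None


def test_lambda_non_increasing_over_entry_steps(rng):
    n = 40
    base = np.concatenate([np.zeros(20), np.ones(20)])
    X = np.column_stack(
        [base * 2 + rng.standard_normal(n) for _ in range(4)]
    )
    y = ["healthy"] * 20 + ["patient"] * 20
    model = stepwise_lda(_table(X, y), [f"x{i}" for i in range(4)])
    entry_lams = [
        lam
        for lam, step in zip(model.lambda_path, model.step_log)
        if step.startswith("enter")
    ]
    assert all(b <= a + 1e-12 for a, b in zip(entry_lams, entry_lams[1:]))
    assert model.wilks_lambda == pytest.approx(
        wilks_lambda(
            np.column_stack([_table(X, y)[v] for v in model.variables]), np.array(y)
        )
    )


def test_single_variable_lambda_matches_anova_identity(rng):
    """For one variable, lambda = SSW/SST, so F-to-enter is the ANOVA F."""
    x = np.concatenate([rng.normal(0, 1, 8), rng.normal(2, 1, 8)])
    y = np.array(["h"] * 8 + ["p"] * 8)
    lam = wilks_lambda(x[:, None], y)
    ssw = sum(np.sum((x[y == gl] - x[y == gl].mean()) ** 2) for gl in ("h", "p"))
    sst = np.sum((x - x.mean()) ** 2)
    assert lam == pytest.approx(ssw / sst, rel=1e-12)


def test_fit_lda_matches_sklearn_direction(rng):
    """Cross-check the Fisher raw-score fit against scikit-learn's LDA."""
    from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

    X = np.vstack([rng.normal(0, 1, (15, 2)), rng.normal(1.2, 1, (15, 2))])
    y = np.array(["healthy"] * 15 + ["patient"] * 15)
    w, c = fit_lda(X, y)
    clf = LinearDiscriminantAnalysis(priors=[0.5, 0.5]).fit(X, y)
    ours = np.where(X @ w + c < 0, "patient", "healthy")
    assert (ours == clf.predict(X)).mean() == 1.0


# ---------------------------------------------------------------------------
# LOOCV
# ---------------------------------------------------------------------------

def test_loocv_perfect_for_separated_groups(rng):
    x = np.concatenate([rng.normal(0, 0.2, 10), rng.normal(10, 0.2, 10)])
    y = ["healthy"] * 10 + ["patient"] * 10
    report = loocv(_table(x[:, None], y), ["x0"])
    assert report.accuracy == 100.0
    assert report.sensitivity == 100.0 and report.specificity == 100.0


def test_loocv_accuracy_is_weighted_mean_of_sens_spec(rng):
    x = np.concatenate([rng.normal(0, 1.5, 12), rng.normal(1, 1.5, 8)])
    y = ["healthy"] * 12 + ["patient"] * 8
    rep = loocv(_table(x[:, None], y), ["x0"])
    weighted = (rep.specificity * 12 + rep.sensitivity * 8) / 20
    assert rep.accuracy == pytest.approx(weighted)


def test_loocv_chance_level_under_permuted_labels():
    rng = np.random.default_rng(7)
    accs = []
    for _ in range(20):
        x = rng.standard_normal(20)
        y = np.array(["healthy"] * 10 + ["patient"] * 10)
        rng.shuffle(y)
        if len(set(y[:-1])) < 2:  # pragma: no cover - guard unlikely degenerate shuffle
            continue
        accs.append(loocv(_table(x[:, None], y), ["x0"]).accuracy)
    assert 30.0 < np.mean(accs) < 65.0


def test_loocv_matches_hand_computation_on_six_points():
    """Exhaustive hand oracle on a 1-D six-participant dataset."""
    x = np.array([1.0, 2.0, 3.0, 6.0, 7.0, 11.0])
    y = np.array(["healthy"] * 3 + ["patient"] * 3)
    rep = loocv(_table(x[:, None], y), ["x0"])
    expected = []
    for i in range(6):
        mask = np.ones(6, bool)
        mask[i] = False
        xh = x[mask & (y == "healthy")]
        xp = x[mask & (y == "patient")]
        s2 = (np.sum((xh - xh.mean()) ** 2) + np.sum((xp - xp.mean()) ** 2)) / 3.0  # n - 2 pooled df
        w = (xh.mean() - xp.mean()) / s2
        c = -0.5 * w * (xh.mean() + xp.mean())
        score = w * x[i] + c
        if xp.mean() * w + c > 0:
            score = -score
        expected.append("patient" if score < 0 else "healthy")
    assert list(rep.predictions["predicted"]) == expected


def test_loocv_approaches_bayes_rate(rng):
    """With 1-D Gaussian groups at delta=2 sigma, LOOCV accuracy at n=200
    approaches the generating model's Bayes rate Phi(delta/2) ~ 84.1%."""
    n = 100
    x = np.concatenate([rng.normal(-1, 1, n), rng.normal(1, 1, n)])
    y = ["healthy"] * n + ["patient"] * n
    rep = loocv(_table(x[:, None], y), ["x0"])
    bayes = 100 * stats.norm.cdf(1.0)
    assert abs(rep.accuracy - bayes) <= 5.0


def test_loocv_strict_mode_runs(rng):
    x = np.concatenate([rng.normal(0, 1, 12), rng.normal(3, 1, 12)])
    noise = rng.standard_normal(24)
    y = ["healthy"] * 12 + ["patient"] * 12
    table = _table(np.column_stack([x, noise]), y, ["sig", "noise"])
    rep = loocv(table, ["sig", "noise"], strict=True)
    assert rep.accuracy > 80.0


# ---------------------------------------------------------------------------
# published classifiers
# ---------------------------------------------------------------------------

ZEROED_CONSTANTS = {
    "F_MAX": -0.586,
    "F_MVC": -2.931,
    "F_GRASP": -3.27,
    "F_Waveform": -1.481,
    "F_NoMVC": 1.109,
}


@pytest.mark.parametrize("name, constant", sorted(ZEROED_CONSTANTS.items()))
def test_published_constant_at_zero_inputs(name, constant):
    clf = PUBLISHED_CLASSIFIERS[name]
    zeros = {v: 0.0 for v in clf.variables}
    score, label = evaluate_published_classifier(name, zeros)
    assert score == constant
    assert label == ("patient" if constant < 0 else "healthy")


@pytest.mark.parametrize("name", sorted(PUBLISHED_CLASSIFIERS))
def test_published_unit_input_recovers_each_coefficient(name):
    clf = PUBLISHED_CLASSIFIERS[name]
    zeros = {v: 0.0 for v in clf.variables}
    base, _ = evaluate_published_classifier(name, zeros)
    for coef, var in clf.terms:
        bumped = dict(zeros, **{var: 1.0})
        score, _ = evaluate_published_classifier(name, bumped)
        assert score - base == pytest.approx(coef, abs=1e-12)


def test_published_waveform_example():
    score, label = evaluate_published_classifier("F_Waveform", {"EWL1": 0.0, "NZC4": 0.0})
    assert score == -1.481 and label == "patient"
    score, label = evaluate_published_classifier("F_MAX", {"R_MAX2": 0.0, "M_MAX4": 0.0})
    assert score == -0.586 and label == "patient"


def test_published_missing_input_names_variable():
    with pytest.raises(MissingInputError, match="NZC4"):
        evaluate_published_classifier("F_Waveform", {"EWL1": 0.0})
    with pytest.raises(MissingInputError):
        evaluate_published_classifier("F_Bogus", {})


def test_score_exactly_zero_classifies_healthy():
    model = DiscriminantModel(["x"], np.array([1.0]), 0.0, 1.0)
    assert model.classify({"x": 0.0})[0] == "healthy"
    assert model.classify({"x": -1e-12})[0] == "patient"


def test_published_score_is_exact_affine_map(rng):
    clf = PUBLISHED_CLASSIFIERS["F_GRASP"]
    a = {v: float(rng.uniform(-2, 2)) for v in clf.variables}
    b = {v: float(rng.uniform(-2, 2)) for v in clf.variables}
    sa, _ = evaluate_published_classifier("F_GRASP", a)
    sb, _ = evaluate_published_classifier("F_GRASP", b)
    expected = sum(coef * (a[v] - b[v]) for coef, v in clf.terms)
    assert sa - sb == pytest.approx(expected, abs=1e-12)


def test_orientation_invariance(rng):
    X = np.vstack([rng.normal(0, 1, (10, 2)), rng.normal(2, 1, (10, 2))])
    y = ["healthy"] * 10 + ["patient"] * 10
    table = _table(X, y)
    model = stepwise_lda(table, ["x0", "x1"])
    flipped_scores = -model.score(table)
    flipped_labels = np.where(flipped_scores > 0, "patient", "healthy")
    assert (model.classify(table) == flipped_labels).all()


def test_nomvc_carries_incompleteness_caveat():
    assert PUBLISHED_CLASSIFIERS["F_NoMVC"].incomplete
    assert not PUBLISHED_CLASSIFIERS["F_MAX"].incomplete
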