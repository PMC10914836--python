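import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

import slidemil as sm


# ---------------------------------------------------------------------------
# evaluate / QWK
# ---------------------------------------------------------------------------


def test_perfect_predictions():
    rep = sm.evaluate([1, 2, 3, 2, 3], [1, 2, 3, 2, 3])
    assert rep.accuracy.value == 1.0
    assert rep.qwk == pytest.approx(1.0)
    assert rep.sensitivity.value == 1.0
    assert np.array_equal(np.diag(rep.confusion), rep.confusion.sum(axis=1))


def _qwk_direct(cm):
    """Independent oracle: observed/expected weighted agreement from the
    confusion matrix with weights (i-j)^2/(K-1)^2."""
    cm = np.asarray(cm, dtype=float)
    K = cm.shape[0]
    w = np.array([[(i - j) ** 2 for j in range(K)] for i in range(K)]) / (K - 1) ** 2
    row = cm.sum(axis=1)
    col = cm.sum(axis=0)
    expected = np.outer(row, col) / cm.sum()
    return 1.0 - (w * cm).sum() / (w * expected).sum()


def test_reversed_ordinal_predictions():
    rep = sm.evaluate([3, 2, 1], [1, 2, 3])
    assert rep.accuracy.value == pytest.approx(1 / 3)
    assert rep.qwk == pytest.approx(_qwk_direct(rep.confusion))


def test_qwk_matches_direct_formula_on_random_inputs():
    rng = np.random.default_rng(0)
    for _ in range(50):
        truth = rng.integers(1, 4, size=60)
        preds = rng.integers(1, 4, size=60)
        if len(np.unique(truth)) < 2 or len(np.unique(preds)) < 2:
            continue
        cm = np.zeros((3, 3))
        for t, p in zip(truth, preds):
            cm[t - 1, p - 1] += 1
        assert sm.quadratic_weighted_kappa(truth, preds) == pytest.approx(
            _qwk_direct(cm)
        )


def test_qwk_is_one_iff_diagonal():
    assert sm.quadratic_weighted_kappa([1, 2, 3, 3], [1, 2, 3, 3]) == 1.0
    assert sm.quadratic_weighted_kappa([1, 2, 3, 3], [1, 2, 3, 2]) < 1.0


def test_binary_collapse_semantics():
    """Positives predicted positive with the wrong grade: sensitivity and
    binary accuracy are unaffected by the grade confusion."""
    rep = sm.evaluate([3, 2, 1], [2, 3, 1])
    assert rep.sensitivity.value == 1.0
    assert rep.binary_accuracy.value == 1.0
    assert rep.accuracy.value == pytest.approx(1 / 3)


def test_single_class_truth_flags_qwk():
    rep = sm.evaluate([1, 1, 1], [1, 1, 1])
    assert np.isnan(rep.qwk)
    assert "undefined" in rep.qwk_flag


def test_evaluate_rejects_bad_input():
    with pytest.raises(ValueError):
        sm.evaluate([], [])
    with pytest.raises(ValueError):
        sm.evaluate([1, 2], [1, 2, 3])


# ---------------------------------------------------------------------------
# binomial confidence interval
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "m,n,expected_pp",
    [
        (0.9344, 900, 1.62),  # 93.44% +/- 1.62 on a 900-slide test set
        (0.89, 100, 6.13),  # 89.00% +/- 6.13 on a 100-slide set
        (0.9778, 900, 0.96),
        (0.8491, 232, 4.61),
    ],
)
def test_ci_half_width_reproduces_reported_values(m, n, expected_pp):
    ci = sm.binomial_ci(m, n, 0.95)
    assert ci.half_width * 100 == pytest.approx(expected_pp, abs=0.005)


def test_ci_degenerate_proportions():
    assert sm.binomial_ci(1.0, 37).half_width == 0.0
    assert sm.binomial_ci(0.0, 37).half_width == 0.0


def test_ci_width_scales_inverse_sqrt_n():
    a = sm.binomial_ci(0.8, 100)
    b = sm.binomial_ci(0.8, 400)
    assert a.half_width == pytest.approx(2 * b.half_width)


def test_ci_maximal_at_half():
    widths = [sm.binomial_ci(m, 50).half_width for m in (0.1, 0.3, 0.5, 0.7, 0.9)]
    assert max(widths) == widths[2]


def test_ci_validates_inputs():
    with pytest.raises(ValueError):
        sm.binomial_ci(1.2, 10)
    with pytest.raises(ValueError):
        sm.binomial_ci(0.5, 0)
    with pytest.raises(ValueError):
        sm.binomial_ci(0.5, 10, c=1.0)


# ---------------------------------------------------------------------------
# McNemar
# ---------------------------------------------------------------------------


def _flags_with_cells(a, b, c, d):
    """Paired correctness flags tallying to the given contingency cells."""
    fa = [False] * a + [True] * b + [False] * c + [True] * d
    fb = [False] * a + [False] * b + [True] * c + [True] * d
    return fa, fb


def test_mcnemar_direct_substitution():
    fa, fb = _flags_with_cells(0, 10, 0, 5)
    res = sm.mcnemar_test(fa, fb)
    assert res.b == 10 and res.c == 0
    assert res.chi2 == pytest.approx((10 - 1) ** 2 / 10)  # 8.1
    assert res.significant


def test_mcnemar_equal_discordance_never_significant():
    for k in (1, 2, 5):
        fa, fb = _flags_with_cells(0, k, k, 3)
        res = sm.mcnemar_test(fa, fb)
        assert res.chi2 == pytest.approx(1 / (2 * k))
        assert not res.significant


def test_mcnemar_reported_p_value():
    assert sm.mcnemar_p_from_chi2(6.94) == pytest.approx(0.008, abs=5e-4)


def test_mcnemar_symmetry():
    fa, fb = _flags_with_cells(2, 7, 3, 8)
    r1 = sm.mcnemar_test(fa, fb)
    r2 = sm.mcnemar_test(fb, fa)
    assert (r1.b, r1.c) == (r2.c, r2.b)
    assert r1.chi2 == r2.chi2 and r1.p_value == r2.p_value


def test_mcnemar_degenerate_no_discordance():
    res = sm.mcnemar_test([True, False], [True, False])
    assert res.chi2 == 0.0 and res.p_value == 1.0


def test_mcnemar_matches_statsmodels():
    from statsmodels.stats.contingency_tables import mcnemar as sm_mcnemar

    rng = np.random.default_rng(1)
    fa = rng.random(200) < 0.8
    fb = rng.random(200) < 0.7
    ours = sm.mcnemar_test(fa, fb)
    table = [[ours.d, ours.c], [ours.b, ours.a]]  # both-right / discordant / both-wrong
    ref = sm_mcnemar(table, exact=False, correction=True)
    assert ours.chi2 == pytest.approx(ref.statistic)
    assert ours.p_value == pytest.approx(ref.pvalue)


def test_p_value_quantile_consistency():
    assert sps.chi2.sf(sps.chi2.ppf(0.95, 1), 1) == pytest.approx(0.05, abs=1e-6)
    assert sm.CHI2_CRITICAL_95 == pytest.approx(sps.chi2.ppf(0.95, 1), abs=5e-4)


# ---------------------------------------------------------------------------
# PR curve
# ---------------------------------------------------------------------------


def _pr_brute_force(scores, truth):
    points = []
    for t in sorted(set(scores)):
        pred = np.asarray(scores) >= t
        tp = (pred & truth).sum()
        fp = (pred & ~truth).sum()
        fn = (~pred & truth).sum()
        if tp + fp:
            points.append((tp / (tp + fp), tp / (tp + fn)))
    return points


def test_pr_curve_separable():
    curve = sm.pr_curve([0.9, 0.8, 0.2, 0.1], [True, True, False, False])
    assert curve.f1 == pytest.approx(1.0)
    pairs = set(zip(np.round(curve.precision, 9), np.round(curve.recall, 9)))
    assert (1.0, 1.0) in pairs


def test_pr_curve_constant_scores():
    truth = np.array([True, False, True, False])
    curve = sm.pr_curve([0.5] * 4, truth)
    assert curve.precision[0] == pytest.approx(0.5)  # prevalence at recall 1
    assert curve.recall[0] == 1.0


def test_pr_curve_matches_threshold_enumeration():
    scores = [0.9, 0.7, 0.6, 0.55, 0.3, 0.1]
    truth = np.array([True, False, True, True, False, True])
    curve = sm.pr_curve(scores, truth)
    ours = set(zip(np.round(curve.precision[:-1], 9), np.round(curve.recall[:-1], 9)))
    brute = {(round(p, 9), round(r, 9)) for p, r in _pr_brute_force(scores, truth)}
    assert brute <= ours


def test_pr_curve_operating_point_f1():
    curve = sm.pr_curve(
        [0.9, 0.8, 0.4, 0.1], [True, True, True, False],
        predicted_positive=[True, True, False, False],
    )
    # tp=2 fp=0 fn=1 -> F1 = 4/5
    assert curve.f1 == pytest.approx(0.8)
    assert curve.f1_source == "operating_point"


def test_pr_curve_requires_both_classes():
    with pytest.raises(ValueError):
        sm.pr_curve([0.1, 0.2], [True, True])


# ---------------------------------------------------------------------------
# confidence densities
# ---------------------------------------------------------------------------


def test_confidence_density_point_mass():
    dens = sm.confidence_density([0.7, 0.7, 0.7], [True, True, True])
    assert dens.mean_correct == pytest.approx(0.7)
    assert "incorrect" in dens.skipped
    peak = dens.grid[np.argmax(dens.density_correct)]
    assert peak == pytest.approx(0.7, abs=0.01)


def test_confidence_density_normalised():
    rng = np.random.default_rng(2)
    conf = np.clip(rng.normal(0.55, 0.05, 400), 0, 1)
    correct = rng.random(400) < 0.5
    dens = sm.confidence_density(conf, correct)
    for d in (dens.density_correct, dens.density_incorrect):
        assert np.trapezoid(d, dens.grid) == pytest.approx(1.0, abs=1e-3)


def test_confidence_density_group_mean_gap():
    conf = [0.9, 0.9, 0.9, 0.6, 0.6, 0.6]
    correct = [True, True, True, False, False, False]
    dens = sm.confidence_density(conf, correct)
    assert dens.mean_correct - dens.mean_incorrect == pytest.approx(0.3)


def test_confidence_density_needs_samples():
    with pytest.raises(ValueError):
        sm.confidence_density([], [])
    with pytest.raises(ValueError):
        sm.confidence_density([0.5, 0.6], [True, False])  # both groups < 2


# ---------------------------------------------------------------------------
# disagreement export and label correction
# ---------------------------------------------------------------------------


def test_export_no_disagreements(tmp_path):
    out = tmp_path / "review.tsv"
    table = sm.export_disagreements(
        ["a", "b"], [1, 2], [1, 2], [0.9, 0.8], out=out
    )
    assert table.empty
    assert out.read_text().startswith("slide_id\t")


def test_label_correction_rectifies_metrics():
    """A second labelling round flipping 2 of 8 disputed labels counts those
    slides as correct on re-evaluation."""
    ids = [f"s{i}" for i in range(20)]
    truth = np.array([1] * 10 + [2] * 5 + [3] * 5)
    preds = truth.copy()
    preds[[0, 1, 2, 3, 11, 12, 16, 17]] = [2, 2, 3, 3, 3, 1, 2, 1]  # 8 mismatches
    conf = np.linspace(0.5, 0.99, 20)
    table = sm.export_disagreements(ids, preds, truth, conf)
    assert len(table) == 8
    review = pd.DataFrame(
        {"slide_id": ["s0", "s11"], "corrected_label": [2, 3]}
    )
    corrected = sm.apply_label_corrections(ids, truth, review)
    before = sm.evaluate(preds, truth).accuracy.value
    after = sm.evaluate(preds, corrected).accuracy.value
    assert after == pytest.approx(before + 2 / 20)


def test_label_correction_unknown_slide_errors():
    review = pd.DataFrame({"slide_id": ["nope"], "corrected_label": [2]})
    with pytest.raises(KeyError, match="nope"):
        sm.apply_label_corrections(["a"], [1], review)
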