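"""Site-wise metric suite vs independent arithmetic and pair-counting oracles."""

import math

import numpy as np
import pytest

from featkit.evaluate import (MetricReport, aggregate, auprc, auroc, confusion,
                              evaluate_sites, metrics, plot_conservation,
                              plot_metrics)


def test_confusion_basic_and_all_positive():
    assert confusion([1, 0], [0.9, 0.1]) == (1, 0, 0, 1)
    tp, fp, fn, tn = confusion([1, 0, 1], [0.9, 0.8, 0.7])
    assert (fn, tn) == (0, 0) and (tp, fp) == (2, 1)


def test_confusion_threshold_is_closed_on_the_left():
    assert confusion([1], [0.5], threshold=0.5) == (1, 0, 0, 0)


def test_confusion_counts_match_counting_loop():
    rng = np.random.default_rng(0)
    y = rng.integers(0, 2, size=1000)
    s = rng.random(1000)
    tp, fp, fn, tn = confusion(y, s, threshold=0.4)
    otp = ofp = ofn = otn = 0
    for yi, si in zip(y, s):
        pred = si >= 0.4
        if pred and yi:
            otp += 1
        elif pred:
            ofp += 1
        elif yi:
            ofn += 1
        else:
            otn += 1
    assert (tp, fp, fn, tn) == (otp, ofp, ofn, otn)
    assert tp + fp + fn + tn == 1000


def test_confusion_error_paths():
    with pytest.raises(ValueError):
        confusion([], [])
    with pytest.raises(ValueError):
        confusion([1, 0], [0.5])
    with pytest.raises(ValueError):
        confusion([2, 0], [0.5, 0.5])


def test_metrics_direct_arithmetic():
    rep = metrics((8, 2, 4, 86))
    assert rep.precision == pytest.approx(8 / 10)
    assert rep.recall == pytest.approx(8 / 12)
    assert rep.specificity == pytest.approx(86 / 88)
    assert rep.accuracy == pytest.approx(94 / 100)
    assert rep.f1 == pytest.approx(2 * 0.8 * (8 / 12) / (0.8 + 8 / 12))
    expected_mcc = (8 * 86 - 2 * 4) / math.sqrt(10 * 12 * 88 * 90)
    assert rep.mcc == pytest.approx(expected_mcc)


def test_perfect_prediction_all_ones():
    rep = metrics((10, 0, 0, 10))
    assert (rep.accuracy, rep.precision, rep.recall, rep.specificity,
            rep.f1, rep.mcc) == (1.0, 1.0, 1.0, 1.0, 1.0, 1.0)


def test_zero_denominators_reported_as_none():
    rep = metrics((0, 0, 5, 5))  # nothing predicted positive
    assert rep.precision is None
    assert rep.recall == 0.0
    assert rep.mcc == 0.0  # zero factor convention
    only_neg = metrics((0, 0, 0, 5))
    assert only_neg.recall is None and only_neg.f1 is None


def test_label_swap_leaves_mcc_and_accuracy_unchanged():
    rng = np.random.default_rng(1)
    y = rng.integers(0, 2, size=300)
    s = rng.random(300)
    rep = metrics(confusion(y, s))
    swapped = metrics(confusion(1 - y, 1 - s + 1e-12))
    assert swapped.accuracy == pytest.approx(rep.accuracy)
    assert swapped.mcc == pytest.approx(rep.mcc, abs=1e-9)
    # precision of the swapped problem plays the NPV role of the original
    npv = rep.tn / (rep.tn + rep.fn)
    assert swapped.precision == pytest.approx(npv)


def test_auroc_separation_and_ties():
    assert auroc([0, 0, 1, 1], [0.1, 0.2, 0.8, 0.9]) == 1.0
    assert auroc([0, 1, 0, 1], [0.5, 0.5, 0.5, 0.5]) == 0.5
    with pytest.warns(UserWarning):
        assert auroc([1, 1], [0.2, 0.4]) is None


def test_auroc_matches_pair_counting_oracle():
    rng = np.random.default_rng(7)
    y = rng.integers(0, 2, size=200)
    s = np.round(rng.random(200), 2)  # coarse scores force ties
    got = auroc(y, s)
    wins = ties = 0
    pos = s[y == 1]
    neg = s[y == 0]
    for sp in pos:
        for sn in neg:
            if sp > sn:
                wins += 1
            elif sp == sn:
                ties += 1
    expected = (wins + 0.5 * ties) / (len(pos) * len(neg))
    assert got == pytest.approx(expected, abs=1e-12)


def test_auroc_score_negation_identity():
    rng = np.random.default_rng(3)
    y = rng.integers(0, 2, size=150)
    s = rng.random(150)  # continuous, ties almost surely absent
    assert auroc(y, s) + auroc(y, -s) == pytest.approx(1.0)


def test_auprc_bounds_and_perfect_case():
    assert auprc([0, 1], [0.1, 0.9]) == pytest.approx(1.0)
    rng = np.random.default_rng(9)
    y = rng.integers(0, 2, size=100)
    s = rng.random(100)
    val = auprc(y, s)
    assert 0.0 <= val <= 1.0
    # random scores should land near the positive prevalence
    assert val > y.mean() / 3


def test_aggregate_pooled_equals_concatenation():
    rng = np.random.default_rng(5)
    ys = [rng.integers(0, 2, size=50) for _ in range(3)]
    ss = [rng.random(50) for _ in range(3)]
    reports = [metrics(confusion(y, s)) for y, s in zip(ys, ss)]
    pooled = aggregate(reports, mode="pooled")
    concat = metrics(confusion(np.concatenate(ys), np.concatenate(ss)))
    assert pooled.as_dict() == concat.as_dict()
    single = aggregate([reports[0]], mode="pooled")
    assert single.as_dict() == reports[0].as_dict()
    two = aggregate([metrics((1, 0, 0, 1))] * 2, mode="pooled")
    assert (two.tp, two.fp, two.fn, two.tn) == (2, 0, 0, 2)


def test_macro_vs_pooled_diverge_on_imbalance():
    """A tiny perfect protein and a large poor one: macro weights them
    equally, pooling is dominated by the large one."""
    small = metrics((5, 0, 0, 5))        # precision 1.0
    large = metrics((10, 90, 0, 900))    # precision 0.1
    macro = aggregate([small, large], mode="macro")
    pooled = aggregate([small, large], mode="pooled")
    assert macro["precision"] == pytest.approx(0.55)
    assert pooled.precision == pytest.approx(15 / 105)
    assert macro["precision"] > pooled.precision


def test_macro_skips_none_and_reports_count():
    defined = metrics((5, 5, 5, 5))
    undefined = metrics((0, 0, 5, 5))  # precision None
    macro = aggregate([defined, undefined], mode="macro")
    assert macro["precision"] == pytest.approx(defined.precision)
    assert macro["skipped"]["precision"] == 1


def test_metric_suite_agrees_with_sklearn():
    """Cross-check against an independent reference implementation."""
    from sklearn.metrics import (accuracy_score, matthews_corrcoef,
                                 precision_score, recall_score, roc_auc_score)
    rng = np.random.default_rng(11)
    y = rng.integers(0, 2, size=400)
    s = rng.random(400)
    pred = (s >= 0.5).astype(int)
    rep = metrics(confusion(y, s))
    assert rep.accuracy == pytest.approx(accuracy_score(y, pred))
    assert rep.precision == pytest.approx(precision_score(y, pred))
    assert rep.recall == pytest.approx(recall_score(y, pred))
    assert rep.mcc == pytest.approx(matthews_corrcoef(y, pred), abs=1e-12)
    assert auroc(y, s) == pytest.approx(roc_auc_score(y, s), abs=1e-12)


def test_evaluate_sites_attaches_ranking_metrics():
    rep = evaluate_sites([1, 0, 1, 0], [0.9, 0.2, 0.8, 0.4])
    assert isinstance(rep, MetricReport)
    assert rep.auroc == 1.0 and rep.auprc == pytest.approx(1.0)
    assert rep.n == 4


def test_plots_are_smoke_tested(tmp_path, msa_fixture):
    from featkit.features import jsd_conservation
    prof = jsd_conservation(msa_fixture.alignment)
    out = tmp_path / "jsd.png"
    plot_conservation(prof, out)
    assert out.exists() and out.stat().st_size > 0
    rep = metrics((8, 2, 4, 86))
    out2 = tmp_path / "metrics.png"
    plot_metrics({"model": rep}, out2)
    assert out2.exists() and out2.stat().st_size > 0
    with pytest.raises(ValueError):
        plot_conservation(np.array([]), tmp_path / "never.png")
    assert not (tmp_path / "never.png").exists()
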