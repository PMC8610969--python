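"""ROC, Youden and DeLong tests against brute-force and bootstrap oracles."""

import warnings

import numpy as np
import pytest

from ivimroi import (
    BENIGN_HIGH,
    BENIGN_LOW,
    accuracy,
    auc_confidence_interval,
    choose_direction,
    compare_modes,
    delong_covariance,
    delong_test,
    delong_variance,
    empirical_auc,
    evaluate_roc,
    youden_cutoff,
)


def brute_force_auc(benign, malignant, direction=BENIGN_HIGH):
    total = 0.0
    for b in benign:
        for m in malignant:
            hit = b > m if direction == BENIGN_HIGH else b < m
            total += 1.0 if hit else (0.5 if b == m else 0.0)
    return total / (len(benign) * len(malignant))


def exhaustive_youden(benign, malignant, direction):
    """Independent cut-off search over a dense threshold set."""
    pts = np.unique(np.concatenate([benign, malignant]))
    cands = np.concatenate([[-np.inf, np.inf], pts - 1e-9, pts + 1e-9, pts])
    best = -np.inf
    for t in cands:
        if direction == BENIGN_HIGH:
            sens = np.mean(np.asarray(malignant) < t)
            spec = np.mean(np.asarray(benign) > t)
        else:
            sens = np.mean(np.asarray(malignant) > t)
            spec = np.mean(np.asarray(benign) < t)
        best = max(best, sens + spec - 1.0)
    return best


class TestAUC:
    def test_perfect_separation(self):
        assert empirical_auc([5, 6, 7], [1, 2, 3], BENIGN_HIGH) == 1.0

    def test_complete_overlap_with_ties(self):
        # pairs (1,1)=.5 (1,2)=0 (2,1)=1 (2,2)=.5 → 2/4
        assert empirical_auc([1, 2], [1, 2], BENIGN_HIGH) == 0.5

    def test_direction_flip_symmetry(self):
        rng = np.random.default_rng(0)
        b, m = rng.normal(1, 1, 13), rng.normal(0, 1, 17)
        a_hi = empirical_auc(b, m, BENIGN_HIGH)
        a_lo = empirical_auc(b, m, BENIGN_LOW)
        assert a_hi + a_lo == pytest.approx(1.0)

    def test_matches_brute_force_and_sklearn(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(1)
        for _ in range(30):
            nb, nm = rng.integers(2, 30, 2)
            b = rng.integers(0, 10, nb).astype(float)  # integer draws force ties
            m = rng.integers(0, 10, nm).astype(float)
            auc = empirical_auc(b, m, BENIGN_HIGH)
            assert auc == pytest.approx(brute_force_auc(b, m))
            y = np.r_[np.ones(nb), np.zeros(nm)]
            assert auc == pytest.approx(roc_auc_score(y, np.r_[b, m]))

    def test_empty_group_raises(self):
        with pytest.raises(ValueError):
            empirical_auc([], [1.0])


class TestDirection:
    def test_benign_high_when_benign_larger(self):
        assert choose_direction([10, 11], [1, 2]) == BENIGN_HIGH

    def test_swap_flips(self):
        assert choose_direction([1, 2], [10, 11]) == BENIGN_LOW

    def test_tie_defaults_benign_high(self):
        assert choose_direction([1, 2], [1, 2]) == BENIGN_HIGH


class TestDeLongVariance:
    def test_hand_computed_small_case(self):
        # benign [1,3], malignant [2,4]: V_b = (0, .5), V_m = (.5, 0)
        # var = 0.125/2 + 0.125/2 = 0.125
        var = delong_variance([1, 3], [2, 4], BENIGN_HIGH)
        assert var == pytest.approx(0.125)

    def test_perfect_separation_zero_variance_warns(self):
        with pytest.warns(UserWarning, match="degenerate"):
            var = delong_variance([5, 6, 7], [1, 2, 3], BENIGN_HIGH)
        assert var == 0.0

    def test_covariance_of_self_is_variance(self):
        rng = np.random.default_rng(2)
        b, m = rng.normal(1, 1, 9), rng.normal(0, 1, 12)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            assert delong_covariance(b, m, b, m) == pytest.approx(delong_variance(b, m))


class TestConfidenceInterval:
    def test_zero_variance_degenerate(self):
        assert auc_confidence_interval(0.8, 0.0) == (0.8, 0.8)

    def test_upper_clipped_to_one(self):
        lo, hi = auc_confidence_interval(0.98, 0.01)
        assert hi == 1.0 and 0.0 <= lo < 0.98

    def test_zero_level_degenerate(self):
        lo, hi = auc_confidence_interval(0.7, 0.1, level=0.0)
        assert lo == pytest.approx(0.7) and hi == pytest.approx(0.7)


class TestYouden:
    def test_separable_midpoint(self):
        cut, sens, spec = youden_cutoff([8, 9, 10], [1, 2, 3], BENIGN_HIGH)
        assert cut == 5.5 and sens == 1.0 and spec == 1.0

    def test_matches_exhaustive_search(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            nb, nm = rng.integers(3, 40, 2)
            b = rng.integers(0, 15, nb).astype(float)
            m = rng.integers(0, 15, nm).astype(float)
            direction = choose_direction(b, m)
            cut, sens, spec = youden_cutoff(b, m, direction)
            assert sens + spec - 1 == pytest.approx(exhaustive_youden(b, m, direction))
            # reported operating point reproduces the confusion counts at cut
            if direction == BENIGN_HIGH:
                assert sens == pytest.approx(np.mean(m < cut))
                assert spec == pytest.approx(np.mean(b > cut))

    def test_tie_breaks_to_smallest_cutoff(self):
        # both midpoints achieve J = 1 only at 2.5; force a J tie instead:
        # benign [4,5], malignant [1,2] → J=1 anywhere in (2,4); midpoint 3.0
        cut, _, _ = youden_cutoff([4, 5], [1, 2], BENIGN_HIGH)
        assert cut == 3.0
        # identical groups: every cutoff gives J=0 → smallest candidate (−inf)
        cut, sens, spec = youden_cutoff([1, 2], [1, 2], BENIGN_HIGH)
        assert cut == -np.inf
        assert sens + spec - 1 == pytest.approx(0.0)


class TestAccuracy:
    @pytest.mark.parametrize(
        "sens,spec,n_mal,n_ben,expected",
        [
            (0.797, 0.914, 74, 35, 0.835),  # printed 1.5 T 2D ADC row
            (0.963, 0.789, 54, 19, 0.918),  # printed 3.0 T 2D ADC row
        ],
    )
    def test_reproduces_printed_cells(self, sens, spec, n_mal, n_ben, expected):
        assert accuracy(sens, spec, n_mal, n_ben) == pytest.approx(expected, abs=5.1e-4)

    def test_prevalence_independence_at_equality(self):
        for s in (0.3, 0.85):
            assert accuracy(s, s, 7, 93) == pytest.approx(s)

    def test_positive_counts_required(self):
        with pytest.raises(ValueError):
            accuracy(0.9, 0.9, 0, 5)


class TestDeLongTest:
    def test_self_comparison_null(self):
        rng = np.random.default_rng(4)
        b, m = rng.normal(1, 1, 10), rng.normal(0, 1, 10)
        cmp = delong_test(b, m, b, m)
        assert cmp.z == 0.0 and cmp.p == 1.0

    def test_antisymmetry(self):
        rng = np.random.default_rng(5)
        b1, m1 = rng.normal(1, 1, 12), rng.normal(0, 1, 15)
        b2, m2 = b1 + rng.normal(0, 0.6, 12), m1 + rng.normal(0, 0.6, 15)
        ab = delong_test(b1, m1, b2, m2, BENIGN_HIGH, BENIGN_HIGH)
        ba = delong_test(b2, m2, b1, m1, BENIGN_HIGH, BENIGN_HIGH)
        assert ab.z == pytest.approx(-ba.z)
        assert ab.p == pytest.approx(ba.p)

    def test_agrees_with_lesion_bootstrap(self):
        """DeLong p vs a 2000-resample lesion-level bootstrap of the AUC
        difference on a few toy paired instances (full-size check in the
        acceptance suite)."""
        rng = np.random.default_rng(6)
        for _ in range(4):
            nb = nm = 14
            b1, m1 = rng.normal(0.9, 1, nb), rng.normal(0, 1, nm)
            b2 = 0.7 * b1 + rng.normal(0, 0.7, nb)
            m2 = 0.7 * m1 + rng.normal(0, 0.7, nm)
            cmp = delong_test(b1, m1, b2, m2, BENIGN_HIGH, BENIGN_HIGH)
            p_boot = bootstrap_p(b1, m1, b2, m2, 2000, rng)
            assert cmp.p == pytest.approx(p_boot, abs=0.05)


def bootstrap_p(b1, m1, b2, m2, n_boot, rng):
    """Two-sided p from a lesion-level bootstrap of AUC_a − AUC_b.

    Benign and malignant lesions are resampled with replacement (paired
    markers travel together); the bootstrap SD of the AUC difference is
    plugged into a normal two-sided test of the observed difference.
    """
    from scipy.stats import norm

    nb, nm = len(b1), len(m1)
    ib = rng.integers(0, nb, (n_boot, nb))
    im = rng.integers(0, nm, (n_boot, nm))
    bb1, mm1 = np.asarray(b1)[ib], np.asarray(m1)[im]
    bb2, mm2 = np.asarray(b2)[ib], np.asarray(m2)[im]

    def auc(bb, mm):
        s = (bb[:, :, None] > mm[:, None, :]) + 0.5 * (bb[:, :, None] == mm[:, None, :])
        return s.mean(axis=(1, 2))

    diff = auc(bb1, mm1) - auc(bb2, mm2)
    sd = np.std(diff, ddof=1)
    observed = empirical_auc(b1, m1) - empirical_auc(b2, m2)
    if sd == 0:
        return 1.0 if observed == 0 else 0.0
    return min(2.0 * norm.sf(abs(observed) / sd), 1.0)


class TestEvaluateROC:
    def test_full_result_consistency(self):
        rng = np.random.default_rng(7)
        b, m = rng.normal(1500, 300, 35), rng.normal(1100, 200, 74)
        res = evaluate_roc(b, m)
        assert res.direction == BENIGN_HIGH
        assert 0 <= res.ci_low <= res.auc <= res.ci_high <= 1
        assert res.accuracy == pytest.approx(
            accuracy(res.sensitivity, res.specificity, 74, 35)
        )
        assert res.summary()["AUC"] == res.auc


class TestCompareModes:
    @pytest.fixture
    def summaries(self):
        import pandas as pd

        rng = np.random.default_rng(8)
        rows = []
        for i in range(24):
            cls = "benign" if i < 8 else "malignant"
            base = rng.normal(1600 if cls == "benign" else 1100, 200)
            for parameter in ("adc", "d2"):
                for extent in ("2D", "3DG", "3DA"):
                    for tissue in ("inclCDA", "exclCDA"):
                        rows.append(
                            {
                                "lesion": f"L{i}",
                                "class": cls,
                                "parameter": parameter,
                                "extent": extent,
                                "tissue": tissue,
                                "mean": base + rng.normal(0, 30),
                                "median": base + rng.normal(0, 30),
                                "sd": abs(rng.normal(100, 10)),
                                "p5": base - 200,
                                "p10": base - 150,
                                "p25": base - 80,
                                "p75": base + 80,
                                "p90": base + 150,
                                "p95": base + 200,
                                "skewness": rng.normal(0, 0.5),
                                "kurtosis": rng.normal(0, 1),
                            }
                        )
        return pd.DataFrame(rows)

    def test_structural_row_counts(self, summaries):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fam = compare_modes(summaries)
        # family (i): parameters x 3 extent pairings, per tissue mode
        assert len(fam["extent"][fam["extent"].tissue == "inclCDA"]) == 2 * 3
        # family (ii): parameters x 3 extents
        assert len(fam["tissue"]) == 2 * 3
        # family (iii): parameters x 10 histogram metrics x 3 pairings
        assert len(fam["metric"]) == 2 * 10 * 3

    def test_identical_arms_give_p_one(self, summaries):
        s = summaries.copy()
        for col in ("median", "p10"):
            s[col] = s["mean"]
        incl = s[s.tissue == "exclCDA"].copy()
        incl["tissue"] = "inclCDA"
        s = __import__("pandas").concat([s[s.tissue == "exclCDA"], incl])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fam = compare_modes(s)
        tissue = fam["tissue"]
        assert (tissue["p"] == 1.0).all()
        med = fam["metric"]
        assert (med[med.metric == "median"]["p"] == 1.0).all()
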