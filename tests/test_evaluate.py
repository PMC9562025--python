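"""Consensus rule, detection matching, kappa, t-test and two-way ANOVA."""

import numpy as np
import pandas as pd
import pytest

import tntdetect as td
from tntdetect import detect, evaluate
from tntdetect.config import MatchCriterion
from tntdetect.phantom import rasterize_polylines
from tntdetect.types import TNTLine, ValidationError

#: TCR x 100 values for the four image sets (true, predicted)
TCR100_TRUE = [4.79, 2.32, 4.38, 4.68]
TCR100_PRED = [5.02, 3.73, 3.58, 3.01]


def _line(r0, c0, r1, c1, w=2.0):
    return TNTLine(np.array([[r0, c0], [r1, c1]], float), width_px=w)


class TestConsensus:
    def _marks(self, votes_per_structure):
        """Four experts; structure i is marked by the first ``votes`` experts."""
        experts = [[], [], [], []]
        for i, votes in enumerate(votes_per_structure):
            base = 40.0 * i
            for e in range(votes):
                experts[e].append(_line(base, 10 + e, base, 40 + e))
        return experts

    def test_four_expert_rule(self):
        res = td.consensus(self._marks([4, 3, 2, 1]))
        assert res.accepted == {0, 1}
        assert res.flagged_for_review == {2}
        assert res.rejected == {3}
        assert res.votes == {0: 4, 1: 3, 2: 2, 3: 1}

    def test_partition_property(self):
        res = td.consensus(self._marks([4, 2, 2, 1, 3]))
        all_ids = res.accepted | res.flagged_for_review | res.rejected
        assert all_ids == set(res.votes)
        assert not (res.accepted & res.flagged_for_review)
        assert not (res.accepted & res.rejected)
        assert not (res.flagged_for_review & res.rejected)

    def test_generalized_panel_sizes(self):
        marks = self._marks([4, 3, 2, 1])[:3]  # 3 experts
        res = td.consensus(marks, n_experts=3)
        # majority (>=2 of 3) accepted; 1 rejected; no exact half for odd n
        assert res.accepted == {0, 1, 2}
        assert res.flagged_for_review == set()
        assert res.rejected == {3}

    def test_mismatched_panel_size_rejected(self):
        with pytest.raises(ValidationError):
            td.consensus(self._marks([1]), n_experts=2)


class TestMatchDetections:
    def _detections_for(self, lines, shape=(300, 300)):
        mask = rasterize_polylines(shape, lines, taper_px=0.0)
        params = td.DetectParams(area_min_px=1.0, area_max_px=1e9)
        return td.count_tnts(mask, params)

    def test_no_predictions_all_false_negative(self):
        truth = [_line(20 * i + 10, 10, 20 * i + 10, 60) for i in range(5)]
        tp, fp, fn, assignment = td.match_detections([], truth)
        assert (tp, fp, fn) == (0, 0, 5)
        assert assignment == {}

    def test_exact_predictions_no_errors(self):
        truth = [_line(50, 20, 50, 150), _line(150, 30, 220, 200)]
        preds = self._detections_for(truth)
        tp, fp, fn, _ = td.match_detections(preds, truth)
        assert fp == 0 and fn == 0 and tp == len(preds)

    def test_partition_identity_on_random_phantoms(self):
        spec = td.PhantomSpec(image_height_px=256, image_width_px=256,
                              n_cells=8, tnt_probability_per_cell_pair=0.4,
                              noise_sd=0.02, seed=21)
        _, truth = td.generate_phantom(spec)
        # predictions: detections from a partly wrong mask (some lines
        # missing, one spurious)
        lines = truth.tnt_lines[:-1] + [_line(10, 10, 10, 80)]
        preds = self._detections_for(lines, shape=(256, 256))
        tp, fp, fn, assignment = td.match_detections(preds, truth.tnt_lines)
        assert tp + fp == len(preds)
        assert tp + fn == len(truth.tnt_lines)
        assert len(assignment) == tp
        assert len(set(assignment.values())) == tp  # one-to-one

    def test_distance_criterion_excludes_distant_prediction(self):
        truth = [_line(50, 20, 50, 150)]
        preds = self._detections_for([_line(200, 20, 200, 150)])
        tp, fp, fn, _ = td.match_detections(
            preds, truth, MatchCriterion(min_fraction=0.3, distance_px=5.0))
        assert (tp, fp, fn) == (0, 1, 1)


class TestDetectionMetrics:
    def test_counts_to_metrics(self):
        m = td.detection_metrics(tp=14, fp=6, fn=20)
        assert m.precision == pytest.approx(0.7)
        assert m.recall == pytest.approx(14 / 34)
        assert m.f1 == pytest.approx(2 * 0.7 * (14 / 34) / (0.7 + 14 / 34))

    def test_published_f1_arithmetic(self):
        assert evaluate.f1_from_pr(0.41, 0.26) == pytest.approx(0.32, abs=0.005)
        assert evaluate.f1_from_pr(0.67, 0.70) == pytest.approx(0.68, abs=0.005)
        assert evaluate.f1_from_pr(0.38, 0.61) == pytest.approx(0.47, abs=0.005)

    def test_all_zero_counts_flagged(self):
        m = td.detection_metrics(0, 0, 0)
        assert (m.precision, m.recall, m.f1) == (0.0, 0.0, 0.0)
        assert m.undefined

    def test_monotone_in_errors(self):
        base = td.detection_metrics(10, 5, 5)
        assert td.detection_metrics(10, 6, 5).precision < base.precision
        assert td.detection_metrics(10, 5, 6).recall < base.recall

    def test_negative_counts_rejected(self):
        with pytest.raises(ValidationError):
            td.detection_metrics(-1, 0, 0)


class TestCohensKappa:
    def test_identical_vectors(self, rng):
        a = rng.integers(0, 2, 50)
        assert td.cohens_kappa(a, a) == 1.0

    def test_perfectly_opposite_balanced(self):
        a = np.array([0, 0, 1, 1])
        assert td.cohens_kappa(a, 1 - a) == pytest.approx(-1.0)

    def test_independent_raters_near_zero(self, rng):
        a = rng.integers(0, 2, 1000)
        b = rng.integers(0, 2, 1000)
        assert abs(td.cohens_kappa(a, b)) <= 0.07

    def test_symmetric_and_label_swap_invariant(self, rng):
        a = rng.integers(0, 2, 60)
        b = rng.integers(0, 2, 60)
        k = td.cohens_kappa(a, b)
        assert td.cohens_kappa(b, a) == pytest.approx(k)
        assert td.cohens_kappa(1 - a, 1 - b) == pytest.approx(k)

    def test_agrees_with_reference_implementation(self, rng):
        from sklearn.metrics import cohen_kappa_score
        for _ in range(20):
            n = int(rng.integers(10, 200))
            a = rng.integers(0, 2, n)
            b = rng.integers(0, 2, n)
            if len(np.unique(np.concatenate([a, b]))) < 2:
                continue
            assert td.cohens_kappa(a, b) == pytest.approx(
                cohen_kappa_score(a, b), abs=1e-6)

    def test_constant_identical_raters(self):
        assert td.cohens_kappa([1, 1, 1], [1, 1, 1]) == 1.0

    def test_pairwise_matrix(self, rng):
        vecs = [rng.integers(0, 2, 40) for _ in range(4)]
        m = evaluate.pairwise_kappa_matrix(vecs)
        assert m.shape == (4, 4)
        assert np.allclose(m, m.T)
        assert np.allclose(np.diag(m), 1.0)


class TestTcrTtest:
    def test_published_tcr_comparison(self):
        t, df, p = td.tcr_ttest(TCR100_TRUE, TCR100_PRED)
        assert df == 6
        assert round(p, 2) == 0.78

    def test_identical_samples(self):
        t, _, p = td.tcr_ttest([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == 0.0
        assert p == 1.0

    def test_large_shift_is_significant(self, rng):
        x = rng.normal(0, 1, 10)
        _, _, p = td.tcr_ttest(x, x + 10.0)
        assert p < 0.001

    def test_agrees_with_reference_implementation(self, rng):
        from scipy import stats
        for _ in range(20):
            x = rng.normal(0, 1, int(rng.integers(3, 30)))
            y = rng.normal(0.5, 2, int(rng.integers(3, 30)))
            t, df, p = td.tcr_ttest(x, y)
            ref = stats.ttest_ind(x, y, equal_var=True)
            assert t == pytest.approx(ref.statistic, abs=1e-6)
            assert p == pytest.approx(ref.pvalue, abs=1e-6)
            tw, _, pw = td.tcr_ttest(x, y, equal_var=False)
            refw = stats.ttest_ind(x, y, equal_var=False)
            assert tw == pytest.approx(refw.statistic, abs=1e-6)
            assert pw == pytest.approx(refw.pvalue, abs=1e-6)

    def test_shift_invariance(self):
        t1, _, p1 = td.tcr_ttest(TCR100_TRUE, TCR100_PRED)
        shifted_true = [v + 100.0 for v in TCR100_TRUE]
        shifted_pred = [v + 100.0 for v in TCR100_PRED]
        t2, _, p2 = td.tcr_ttest(shifted_true, shifted_pred)
        assert t1 == pytest.approx(t2, abs=1e-9)
        assert p1 == pytest.approx(p2, abs=1e-9)

    def test_too_short_samples_rejected(self):
        with pytest.raises(ValidationError):
            td.tcr_ttest([1.0], [1.0, 2.0])


def _counts_frame(values):
    rows = []
    for (source, image_set), v in values.items():
        rows.append({"source": source, "image_set": image_set, "count": v})
    return pd.DataFrame(rows)


class TestCountsAnova:
    def test_identical_sources_no_source_effect(self):
        vals = {}
        for s in ("human", "model"):
            for i, v in enumerate([43, 18, 33, 42]):
                vals[(s, f"set{i}")] = v
        f_source, f_set, p_source, p_set = td.counts_anova(_counts_frame(vals))
        assert f_source == 0.0
        assert p_source == 1.0

    def test_agrees_with_reference_implementation(self, rng):
        import statsmodels.api as sm
        import statsmodels.formula.api as smf
        from statsmodels.stats.anova import anova_lm
        for _ in range(10):
            vals = {}
            for s in ("human", "model"):
                for i in range(4):
                    vals[(s, f"set{i}")] = float(rng.integers(5, 60))
            df = _counts_frame(vals)
            f_source, f_set, p_source, p_set = td.counts_anova(df)
            fit = smf.ols("count ~ C(source) + C(image_set)", data=df).fit()
            table = anova_lm(fit, typ=2)
            assert f_source == pytest.approx(table.loc["C(source)", "F"],
                                             abs=1e-6)
            assert f_set == pytest.approx(table.loc["C(image_set)", "F"],
                                          abs=1e-6)
            assert p_source == pytest.approx(table.loc["C(source)", "PR(>F)"],
                                             abs=1e-6)
            assert p_set == pytest.approx(table.loc["C(image_set)", "PR(>F)"],
                                          abs=1e-6)

    def test_injected_effect_ordering(self):
        # a much larger source effect than set effect must give F_source > F_set
        vals = {}
        noise = iter([0.3, -0.2, 0.1, -0.1, 0.2, -0.3, 0.15, -0.15])
        for s_idx, s in enumerate(("human", "model")):
            for i in range(4):
                vals[(s, f"set{i}")] = 10.0 + 20.0 * s_idx + 0.5 * i + next(noise)
        f_source, f_set, _, _ = td.counts_anova(_counts_frame(vals))
        assert f_source > f_set

    def test_missing_cells_rejected(self):
        df = _counts_frame({("human", "a"): 1, ("human", "b"): 2,
                            ("model", "a"): 3})
        with pytest.raises(ValidationError):
            td.counts_anova(df)

    def test_published_counts_show_no_source_effect(self):
        # human vs model TNT counts across the four image sets
        vals = {("human", f"set{i}"): v
                for i, v in enumerate([43, 18, 33, 42])}
        vals.update({("model", f"set{i}"): v
                     for i, v in enumerate([45, 29, 27, 27])})
        _, _, p_source, _ = td.counts_anova(_counts_frame(vals))
        assert p_source > 0.05
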