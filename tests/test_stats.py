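import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from statsmodels.stats.multitest import multipletests

from plastotrans.plastome import StudyDesign
from plastotrans.stats import (
    classify_cold_responsive,
    estimate_pi0,
    fold_changes,
    percentile_thresholds,
    polysome_monosome_ratio,
    relative_translation_activity,
    splicing_efficiency,
    storey_qvalues,
    ttest_one_sample,
    ttest_two_sided,
)


class TestTTest:
    def test_identical_groups_p_one(self):
        assert ttest_two_sided([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == pytest.approx(1.0)

    def test_separated_groups_tiny_p(self):
        p = ttest_two_sided([0.0, 0.0, 0.0], [10.0, 10.0, 10.0001])
        assert p < 1e-6

    def test_zero_variance_conventions(self):
        assert ttest_two_sided([5.0, 5.0], [5.0, 5.0]) == 1.0
        assert ttest_two_sided([5.0, 5.0], [6.0, 6.0]) == 0.0

    def test_matches_exhaustive_permutation_oracle(self):
        """Parametric p tracks the exhaustive two-sample permutation p at n=3+3."""
        rng = np.random.default_rng(0)
        for _ in range(5):
            pooled = rng.normal(0, 1, 6)
            a, b = pooled[:3], pooled[3:]
            t_obs = abs(_tstat(a, b))
            count = 0
            perms = list(itertools.combinations(range(6), 3))
            for idx in perms:
                ia = np.array(idx)
                ib = np.array([i for i in range(6) if i not in idx])
                if abs(_tstat(pooled[ia], pooled[ib])) >= t_obs - 1e-12:
                    count += 1
            p_perm = count / len(perms)
            p_param = ttest_two_sided(a, b)
            assert abs(p_param - p_perm) < 0.25  # 20 permutations: coarse grid

    def test_one_sample_conventions(self):
        assert ttest_one_sample([0.0, 0.0, 0.0]) == 1.0
        assert ttest_one_sample([1.0, 1.0]) == 0.0
        assert ttest_one_sample([1.0, 1.1, 0.9]) < 0.01


def _tstat(a, b):
    na, nb = len(a), len(b)
    sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    return (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / na + 1 / nb))


class TestStoreyQ:
    def test_pi0_one_equals_bh_exactly(self):
        rng = np.random.default_rng(42)
        for _ in range(50):
            m = rng.integers(5, 300)
            p = rng.beta(0.5, rng.uniform(0.5, 4), m)
            q = storey_qvalues(p, pi0_method="fixed_1")
            bh = multipletests(p, method="fdr_bh")[1]
            # identical up to the last-bit rounding of (m*p)/k vs p/(k/m)
            np.testing.assert_allclose(q, bh, rtol=0, atol=1e-12)

    def test_single_p(self):
        assert storey_qvalues([0.01], pi0_method="fixed_1")[0] == pytest.approx(0.01)

    def test_uniform_pi0_near_one(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            p = rng.uniform(0, 1, 2000)
            assert 0.9 <= estimate_pi0(p, method="smoother") <= 1.0

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            storey_qvalues([0.5, 1.5])

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=200))
    def test_q_monotone_in_p_and_bounded(self, pvals):
        q = storey_qvalues(pvals, pi0_method="fixed_1")
        assert np.all((q >= 0) & (q <= 1))
        order = np.argsort(pvals, kind="mergesort")
        assert np.all(np.diff(q[order]) >= -1e-12)


def _abundance_frame(design, entries):
    """entries: {(orf, layer, condition, timepoint, replicate): value}"""
    rows = [
        dict(orf=o, layer=l, condition=c, timepoint=t, replicate=r, abundance=v,
             n_valid=3, low_support=False)
        for (o, l, c, t, r), v in entries.items()
    ]
    return pd.DataFrame(rows)


def _fill_design(design, fn):
    entries = {}
    for layer in design.layers:
        for cond in design.conditions:
            for tp in [design.baseline_label] + design.timepoint_labels:
                for rep in design.replicates:
                    entries[("g", layer, cond, tp, rep)] = fn(layer, cond, tp, rep)
    return entries


class TestFoldChanges:
    def test_hand_example(self, design):
        # A(t)=4, A(0)=2, C(t)=1, C(0)=1 -> log2FC = 1 at every timepoint
        def fn(layer, cond, tp, rep):
            if tp == design.baseline_label:
                return 2.0 if cond == "acclimating" else 1.0
            return 4.0 if cond == "acclimating" else 1.0

        fc = fold_changes(_abundance_frame(design, _fill_design(design, fn)), design)
        assert np.allclose(fc["log2fc_output"], 1.0)
        assert np.allclose(fc["log2fc_te"], 0.0)  # same change on both layers

    def test_all_equal_gives_zero(self, design):
        fc = fold_changes(
            _abundance_frame(design, _fill_design(design, lambda *a: 3.0)), design
        )
        assert np.allclose(fc["log2fc_output"], 0.0)
        assert np.allclose(fc["p_output"], 1.0)

    def test_replicate_mean(self, design):
        # per-replicate acclim/control log2 ratios 1.0, 1.2, 0.8 -> mean 1.0
        ratios = {1: 1.0, 2: 1.2, 3: 0.8}

        def fn(layer, cond, tp, rep):
            if tp == design.baseline_label or cond == "control":
                return 1.0
            return float(2.0 ** ratios[rep])

        fc = fold_changes(_abundance_frame(design, _fill_design(design, fn)), design)
        assert np.allclose(fc["log2fc_output"], 1.0)

    def test_te_identity_on_simulated_study(self, normalized, design):
        fc = fold_changes(normalized["abundances"], design)
        ok = fc[["log2fc_output", "log2fc_rna", "log2fc_te"]].dropna()
        np.testing.assert_allclose(
            ok["log2fc_te"], ok["log2fc_output"] - ok["log2fc_rna"], atol=1e-12
        )

    def test_missing_baseline_propagates(self, design):
        entries = _fill_design(design, lambda *a: 2.0)
        entries = {k: v for k, v in entries.items() if k[3] != design.baseline_label}
        fc = fold_changes(_abundance_frame(design, entries), design)
        assert fc["log2fc_output"].isna().all()


def _fc_frame(design, q_by_tp, fc_by_tp, gene="g"):
    rows = []
    for tp in design.timepoint_labels:
        rows.append(
            dict(orf=gene, timepoint=tp,
                 log2fc_output=fc_by_tp.get(tp, 0.0), log2fc_rna=0.0, log2fc_te=0.0,
                 p_output=0.5, p_rna=0.5, p_te=0.5,
                 q_output=q_by_tp.get(tp, 1.0), q_rna=1.0, q_te=1.0)
        )
    return pd.DataFrame(rows)


class TestClassifier:
    def test_two_consecutive_rule(self, design):
        fc = _fc_frame(design, {"1h": 0.01, "5h": 0.01}, {"1h": 1.0, "5h": 1.0})
        calls = classify_cold_responsive(fc, design)
        assert len(calls) == 1 and calls[0].qualifying_rule == "consecutive2"
        assert calls[0].direction == "up"

    def test_three_total_rule(self, design):
        fc = _fc_frame(
            design,
            {"0.5min": 0.01, "20min": 0.01, "1d": 0.01},
            {"0.5min": -1.0, "20min": -1.0, "1d": -1.0},
        )
        calls = classify_cold_responsive(fc, design)
        assert len(calls) == 1 and calls[0].qualifying_rule == "total3"
        assert calls[0].direction == "down"

    def test_single_timepoint_not_called(self, design):
        fc = _fc_frame(design, {"2d": 0.001}, {"2d": 2.0})
        assert classify_cold_responsive(fc, design) == []

    def test_large_fc_without_significance_not_called(self, design):
        fc = _fc_frame(design, {}, {tp: 3.0 for tp in design.timepoint_labels})
        assert classify_cold_responsive(fc, design) == []

    def test_mixed_direction_ambiguous(self, design):
        fc = _fc_frame(design, {"1h": 0.01, "5h": 0.01}, {"1h": 1.0, "5h": -1.0})
        calls = classify_cold_responsive(fc, design)
        assert calls[0].direction == "ambiguous"

    def test_invariant_to_gene_order_and_rescaling(self, normalized, design):
        ab = normalized["abundances"]
        fc1 = fold_changes(ab, design)
        shuffled = ab.sample(frac=1.0, random_state=1)
        scaled = shuffled.assign(abundance=shuffled["abundance"] * 37.5)
        fc2 = fold_changes(scaled, design)
        c1 = [(c.gene, c.direction) for c in classify_cold_responsive(fc1, design)]
        c2 = [(c.gene, c.direction) for c in classify_cold_responsive(fc2, design)]
        assert c1 == c2


class TestPercentileThresholds:
    def test_hand_computed_quantiles(self):
        # sorted -5..5 (11 values); linear interpolation lands on index 0.2*10=2
        cuts = percentile_thresholds(list(range(-5, 6)), top_frac=0.2)
        assert cuts.low_cut == pytest.approx(-3.0)
        assert cuts.high_cut == pytest.approx(3.0)

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError, match=">= 10"):
            percentile_thresholds([-2, -1, 0, 1, 2], top_frac=0.2)

    def test_symmetric_input_symmetric_cuts(self):
        v = np.concatenate([np.arange(-50, 51)]) / 10
        cuts = percentile_thresholds(v)
        assert cuts.low_cut == pytest.approx(-cuts.high_cut)

    def test_degenerate_all_equal(self):
        cuts = percentile_thresholds([1.0] * 20)
        assert cuts.degenerate and cuts.low_cut == cuts.high_cut


class TestSplicing:
    def _exon_frame(self, design, fn):
        rows = []
        for gene, exons in [("ndhA", (1, 2))]:
            for e in exons:
                for cond in design.conditions:
                    for tp in design.timepoint_labels:
                        for rep in design.replicates:
                            rows.append(
                                dict(orf=gene, exon_index=e, layer="footprint",
                                     condition=cond, timepoint=tp, replicate=rep,
                                     abundance=fn(e, cond, tp, rep), n_valid=3,
                                     low_support=False)
                            )
        return pd.DataFrame(rows)

    def test_equal_abundances_zero(self, design, annotation):
        tab, _ = splicing_efficiency(
            self._exon_frame(design, lambda *a: 2.0), annotation, design
        )
        assert np.allclose(tab["log2_ratio"], 0.0)

    def test_twofold_downstream_gain_is_plus_one(self, design, annotation):
        def fn(exon, cond, tp, rep):
            if cond == "acclimating" and exon == 2:
                return 2.0
            return 1.0

        tab, _ = splicing_efficiency(self._exon_frame(design, fn), annotation, design)
        assert np.allclose(tab["log2_ratio"], 1.0)

    def test_short_first_exon_trio_excluded(self, normalized, annotation, design):
        tab, excluded = splicing_efficiency(
            normalized["exon_abundances"], annotation, design
        )
        bad = {g for g, _ in excluded}
        assert {"petB", "petD", "rpl16"} <= bad
        assert not set(tab["gene"]) & bad

    def test_injected_ndhA_shift_recovered(self, normalized, annotation, design):
        truth = normalized["truth"]
        tab, _ = splicing_efficiency(normalized["exon_abundances"], annotation, design)
        got = tab[(tab.gene == "ndhA") & (tab.timepoint == "1d")]["log2_ratio"].iloc[0]
        want = truth.splicing.query("gene=='ndhA' and timepoint=='1d'")["true_log2_shift"].iloc[0]
        assert got == pytest.approx(want, abs=0.35)


class TestPolysomeRatio:
    def test_uniform_fractions(self):
        sig = np.ones(11)
        assert polysome_monosome_ratio(sig, range(4), range(4, 10)) == pytest.approx(1.5)

    def test_identical_profiles_unit_activity(self):
        sig = np.arange(1.0, 12.0)
        assert relative_translation_activity(sig, sig, range(4), range(4, 10)) == pytest.approx(1.0)

    def test_scaled_polysomes(self):
        sig = np.ones(11)
        acc = sig.copy()
        acc[4:10] *= 0.7
        assert relative_translation_activity(acc, sig, range(4), range(4, 10)) == pytest.approx(0.7)

    def test_overlapping_sets_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            polysome_monosome_ratio(np.ones(5), [0, 1], [1, 2])

    def test_zero_monosome_rejected(self):
        sig = np.array([0.0, 0.0, 1.0, 1.0])
        with pytest.raises(ValueError, match="monosome"):
            polysome_monosome_ratio(sig, [0, 1], [2, 3])
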