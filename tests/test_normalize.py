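import numpy as np
import pandas as pd
import pytest

from plastotrans.normalize import (
    STATUS_BACKGROUND,
    STATUS_OK,
    STATUS_SATURATED,
    build_signal_table,
    global_scale,
    net_signal,
    normalize_scans,
    orf_abundance,
    within_orf_sd_normalize,
)
from plastotrans.plastome import assign_probes
from plastotrans.simulate import ArrayScan

from oracles import brute_force_cascade, small_instance


class TestNetSignal:
    @pytest.mark.parametrize(
        "f,b,value,status",
        [
            (612, 100, 512.0, STATUS_OK),
            (150, 100, 0.0, STATUS_BACKGROUND),   # below the 100-count floor
            (199, 100, 0.0, STATUS_BACKGROUND),
            (200, 100, 100.0, STATUS_OK),
            (50, 100, 0.0, STATUS_BACKGROUND),    # negative net clamps to 0
        ],
    )
    def test_floor_and_subtraction(self, f, b, value, status):
        v, s = net_signal(np.array([f]), np.array([b]))
        assert (v[0], s[0]) == (value, status)

    def test_saturated_excluded(self):
        v, s = net_signal(np.array([65535.0]), np.array([0.0]))
        assert s[0] == STATUS_SATURATED and np.isnan(v[0])


def _table(values_by_array, orf="g", coding=True):
    """Minimal signal table: {array_key: [probe values]} single channel."""
    rows = []
    for (layer, tp, rep), vals in values_by_array.items():
        for i, v in enumerate(vals):
            rows.append(
                dict(probe_id=f"p{i}", orf=orf if coding else None, exon_index=1 if coding else None,
                     coding=coding, layer=layer, condition="acclimating", timepoint=tp,
                     replicate=rep, value=float(v), status=STATUS_OK)
            )
    return pd.DataFrame(rows)


class TestGlobalScale:
    def test_two_arrays_meet_at_grand_mean(self):
        t = _table({("fp", "a", 1): [100, 100], ("fp", "b", 1): [200, 200]})
        out = global_scale(t)
        means = out.groupby("timepoint")["value"].mean()
        assert means["a"] == pytest.approx(150.0)
        assert means["b"] == pytest.approx(150.0)
        assert out["value"].mean() == pytest.approx(t["value"].mean())

    def test_single_array_identity(self):
        t = _table({("fp", "a", 1): [10, 20, 30]})
        out = global_scale(t)
        np.testing.assert_allclose(out["value"], t["value"])

    def test_constant_signals_unchanged(self):
        t = _table({("fp", "a", 1): [7, 7], ("fp", "b", 1): [7, 7]})
        np.testing.assert_allclose(global_scale(t)["value"], 7.0)

    def test_array_without_valid_probes_rejected(self):
        t = _table({("fp", "a", 1): [10, 20]})
        t2 = _table({("fp", "b", 1): [5, 6]})
        t2["status"] = STATUS_SATURATED
        with pytest.raises(ValueError, match="fp"):
            global_scale(pd.concat([t, t2], ignore_index=True))


class TestWithinOrfSdNormalize:
    def test_pooled_sd_division(self):
        t = _table({("fp", "a", 1): [2, 4, 6]})
        out = within_orf_sd_normalize(t)
        np.testing.assert_allclose(out["value"], [1.0, 2.0, 3.0])

    def test_post_sd_is_one(self):
        t = _table({("fp", "a", 1): [3, 9, 17, 4]})
        out = within_orf_sd_normalize(t)
        assert out["value"].std(ddof=1) == pytest.approx(1.0)

    def test_scale_invariance_across_replicates(self):
        t1 = _table({("fp", "a", 1): [1, 2, 5]})
        t3 = _table({("fp", "a", 1): [3, 6, 15]})  # x3 proportional replicate
        v1 = within_orf_sd_normalize(t1)["value"].to_numpy()
        v3 = within_orf_sd_normalize(t3)["value"].to_numpy()
        np.testing.assert_allclose(v1, v3)

    def test_constant_orf_passes_through_flagged(self):
        from plastotrans.normalize import NormalizationManifest

        t = _table({("fp", "a", 1): [5, 5, 5]})
        m = NormalizationManifest()
        out = within_orf_sd_normalize(t, manifest=m)
        np.testing.assert_allclose(out["value"], 5.0)
        assert len(m.constant_orfs) == 1


class TestOrfAbundance:
    def test_simple_mean(self):
        t = _table({("fp", "a", 1): [1, 2, 3]})
        out = orf_abundance(t)
        assert out["abundance"].iloc[0] == pytest.approx(2.0)
        assert out["n_valid"].iloc[0] == 3

    def test_background_zeros_included_in_mean(self):
        t = _table({("fp", "a", 1): [0, 0, 6]})
        t.loc[t["value"] == 0, "status"] = STATUS_BACKGROUND
        assert orf_abundance(t)["abundance"].iloc[0] == pytest.approx(2.0)

    def test_all_saturated_orf_missing(self):
        t = _table({("fp", "a", 1): [1, 2]})
        t["status"] = STATUS_SATURATED
        t["value"] = np.nan
        assert orf_abundance(t).empty

    def test_low_support_flagged(self):
        t = _table({("fp", "a", 1): [4.0]})
        out = orf_abundance(t, min_probes=2)
        assert bool(out["low_support"].iloc[0])


def test_channel_swap_exactly_swaps_conditions(preset_study, probes):
    scans, _ = preset_study
    swapped = []
    for scan in scans[:6]:
        d = scan.data.rename(
            columns={"f635": "f532", "f532": "f635", "b635": "b532", "b532": "b635"}
        )[scan.data.columns]
        swapped.append(ArrayScan(scan.layer, scan.timepoint, scan.replicate, d))
    ab_orig, _, _, _ = normalize_scans(scans[:6], probes)
    ab_swap, _, _, _ = normalize_scans(swapped, probes)
    key = ["orf", "layer", "timepoint", "replicate"]
    a = ab_orig[ab_orig.condition == "acclimating"].set_index(key)["abundance"]
    c = ab_swap[ab_swap.condition == "control"].set_index(key)["abundance"]
    pd.testing.assert_series_equal(a, c.reindex(a.index), check_names=False)


def test_cascade_matches_straight_line_brute_force():
    annotation, layout, scans = small_instance(seed=3)
    probes = assign_probes(layout, annotation)
    probe_orf = {p.probe_id: p.orf for p in probes}
    oracle = brute_force_cascade(scans, probe_orf)
    abundances, _, _, _ = normalize_scans(scans, probes)
    assert len(oracle) > 0
    for row in abundances.itertuples(index=False):
        k = (row.orf, (row.layer, row.timepoint, row.replicate), row.condition)
        assert row.abundance == pytest.approx(oracle[k], rel=1e-12, abs=1e-12)
    assert len(abundances) == len(oracle)


def test_manifest_counts_exclusions(preset_study, probes):
    scans, _ = preset_study
    _, _, table, manifest = normalize_scans(scans, probes)
    d = manifest.as_dict()
    assert d["n_entries"] == len(table)
    assert d["n_saturated"] == (table["status"] == STATUS_SATURATED).sum()
    assert d["n_background"] == (table["status"] == STATUS_BACKGROUND).sum()
    assert d["n_arrays_scaled"] == 16 * 3  # 2 layers x (7 tp + baseline) x 3 reps
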