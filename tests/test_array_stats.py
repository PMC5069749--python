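"""Spot signal extraction, aggregation and Q/D comparisons."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from metalhomeo import (ArraySimConfig, GeneSignal, SpotMeasurement,
                        SpotSignal, aggregate_gene, compare_signals,
                        compare_table, compute_spot_signal, gene_signal_table,
                        separation_d, simulate_spot_table, spot_signal_table,
                        summarize_replicates)

from conftest import TINY_CV, naive_compare, naive_gene_table


def spot(spot_mean, spot_dev, bg_mean, bg_dev, **kw):
    defaults = dict(gene_id="g", probe_id="p", replicate=1, strain="s",
                    condition="c")
    defaults.update(kw)
    return SpotMeasurement(spot_mean=spot_mean, spot_dev=spot_dev,
                           bg_mean=bg_mean, bg_dev=bg_dev, **defaults)


class TestSpotSignal:
    @pytest.mark.parametrize(
        "m, signal, deviation, d, passes",
        [(spot(10, 1, 4, 1), 6.0, 1.0, 3.0, True),     # hand: |10-4|/(1+1)
         (spot(5, 2, 5, 2), 0.0, 2.0, 0.0, False),     # identical spot/bg
         (spot(6, 2, 4, 2), 2.0, 2.0, 0.5, False)])    # bars overlap
    def test_hand_computed_examples(self, m, signal, deviation, d, passes):
        s = compute_spot_signal(m)
        assert s == SpotSignal(signal, deviation, d, passes)

    def test_zero_deviation_limits(self):
        assert compute_spot_signal(spot(10, 0, 4, 0)).d_value == math.inf
        assert compute_spot_signal(spot(5, 0, 5, 0)).d_value == 0.0

    def test_negative_deviation_rejected(self):
        with pytest.raises(ValueError):
            compute_spot_signal(spot(10, -1, 4, 1))

    def test_table_form_matches_scalar_form(self, small_array):
        table = spot_signal_table(small_array.spots)
        row = small_array.spots.iloc[17]
        scalar = compute_spot_signal(SpotMeasurement(**row.to_dict()))
        assert np.isclose(table["signal"].iloc[17], scalar.signal)
        assert np.isclose(table["d_value"].iloc[17], scalar.d_value)


class TestSeparationD:
    @given(st.tuples(
        st.floats(-1e6, 1e6), st.floats(0, 1e6),
        st.floats(-1e6, 1e6), st.floats(0, 1e6)))
    @settings(max_examples=300, deadline=None)
    def test_d_gt_1_iff_error_bars_do_not_touch(self, vals):
        ma, da, mb, db = vals
        d = separation_d(ma, da, mb, db)
        assert (d > 1) == (abs(ma - mb) > da + db)

    @given(st.floats(-1e6, 1e6), st.floats(0, 1e6),
           st.floats(-1e6, 1e6), st.floats(0, 1e6))
    @settings(max_examples=100, deadline=None)
    def test_symmetry(self, ma, da, mb, db):
        assert separation_d(ma, da, mb, db) == separation_d(mb, db, ma, da)


class TestReplicateSummary:
    def test_identical_signals_have_zero_deviation(self):
        sigs = [SpotSignal(6.0, 0.5, 3.0, True)] * 3
        assert summarize_replicates(sigs) == (6.0, 0.0, 3.0, 3)

    def test_hand_computed_mean_sd_dmin(self):
        sigs = [SpotSignal(4.0, 0.1, 2.0, True),
                SpotSignal(6.0, 0.1, 3.0, True),
                SpotSignal(8.0, 0.1, 4.0, True)]
        mean, dev, d_min, n = summarize_replicates(sigs)
        assert (mean, d_min, n) == (6.0, 2.0, 3)
        assert dev == pytest.approx(2.0)   # sample SD of {4,6,8}

    def test_filtered_spots_are_excluded(self):
        sigs = [SpotSignal(6.0, 0.5, 3.0, True),
                SpotSignal(100.0, 0.5, 0.9, False)]
        assert summarize_replicates(sigs) == (6.0, 0.0, 3.0, 1)

    def test_empty_input_is_flagged_missing(self):
        assert summarize_replicates([]) is None
        assert summarize_replicates(
            [SpotSignal(1.0, 1.0, 0.5, False)]) is None


class TestGeneAggregation:
    def test_single_probe_is_identity(self):
        g = aggregate_gene("g1", "s", "c", [(10.0, 1.0, 1.5, 3)])
        assert (g.mean_signal, g.deviation, g.d_min, g.n_spots_used) == \
            (10.0, 1.0, 1.5, 3)

    def test_probe_means_and_dmin_combine(self):
        g = aggregate_gene("g1", "s", "c",
                           [(10.0, 1.0, 1.5, 3), (20.0, 3.0, 2.5, 3)])
        assert g.mean_signal == 15.0
        assert g.deviation == 2.0          # unweighted mean of probe devs
        assert g.d_min == 1.5
        assert g.n_spots_used == 6

    def test_no_surviving_probe_gives_nf_status(self):
        g = aggregate_gene("g1", "s", "c", [None, None])
        assert g.status == "NF" and g.n_spots_used == 0
        assert math.isnan(g.mean_signal)


def gs(mean, dev, gene="g1", status="OK"):
    return GeneSignal(gene, "s", "c", mean, dev, 2.0, 3, status)


class TestCompare:
    def test_fourfold_with_tight_bars_is_significant_up(self):
        r = compare_signals(gs(4.0, 0.5), gs(1.0, 0.5))
        assert (r.q_value, r.d_comparison) == (4.0, 3.0)
        assert r.direction == "U" and r.significant and r.status == "OK"

    def test_identical_signals_are_null(self):
        r = compare_signals(gs(4.0, 0.5), gs(4.0, 0.5))
        assert (r.q_value, r.d_comparison) == (1.0, 0.0)
        assert r.direction == "N" and not r.significant

    def test_wide_bars_make_fourfold_nonsignificant(self):
        r = compare_signals(gs(4.0, 2.0), gs(1.0, 2.0))
        assert r.q_value == 4.0 and r.d_comparison == 0.75
        assert r.direction == "U" and not r.significant

    @pytest.mark.parametrize("a, b", [
        (None, gs(1.0, 0.5)), (gs(4.0, 0.5), None),
        (gs(-1.0, 0.5), gs(1.0, 0.5)), (gs(4.0, 0.5), gs(0.0, 0.5)),
        (gs(4.0, 0.5, status="NF"), gs(1.0, 0.5))])
    def test_missing_or_nonpositive_operand_is_nq(self, a, b):
        r = compare_signals(a, b)
        assert r.status == "NQ" and not r.significant
        assert math.isnan(r.q_value)

    @given(st.floats(0.1, 1e5), st.floats(0, 1e4),
           st.floats(0.1, 1e5), st.floats(0, 1e4))
    @settings(max_examples=200, deadline=None)
    def test_reciprocity_and_symmetric_d(self, ma, da, mb, db):
        ab = compare_signals(gs(ma, da), gs(mb, db))
        ba = compare_signals(gs(mb, db), gs(ma, da))
        assert ab.q_value * ba.q_value == pytest.approx(1.0)
        assert ab.d_comparison == ba.d_comparison


class TestNoiseFreeRecovery:
    def test_planted_fold_recovered_and_nulls_unregulated(self, small_array):
        genes = gene_signal_table(spot_signal_table(small_array.spots))
        cmp = compare_table(genes, ("d7", "EDTA"), ("d7", "Zn"))
        planted = cmp.set_index("gene_id").loc["g00003"]
        assert planted["q_value"] == pytest.approx(4.0, rel=1e-6)
        assert planted["direction"] == "U" and planted["significant"]
        others = cmp[cmp["gene_id"] != "g00003"]
        assert (others["direction"] == "N").all()


class TestOracleEquivalence:
    """The vectorised pipeline must match a straight-line loop reference."""

    @pytest.mark.parametrize("seed", [0, 1])
    def test_gene_and_comparison_tables_identical(self, seed):
        cfg = ArraySimConfig(
            n_genes=30, probes_per_gene=2, n_replicates=3,
            strains=["a", "b"], conditions=["x"],
            planted_effects={"g00002": {("a", "x"): 4.0},
                             "g00005": {("a", "x"): 0.2}},
            pixel_cv=0.6, rng_seed=seed)   # high noise: exercises NF/NQ paths
        sim = simulate_spot_table(cfg)
        genes = gene_signal_table(spot_signal_table(sim.spots))
        ref = pd.DataFrame(naive_gene_table(sim.spots))
        merged = genes.merge(ref, on=["gene_id", "strain", "condition"],
                             suffixes=("", "_ref"))
        assert len(merged) == len(genes) == len(ref)
        assert (merged["status"] == merged["status_ref"]).all()
        for col in ("mean_signal", "deviation", "d_min"):
            ok = merged["status"] == "OK"
            np.testing.assert_allclose(merged.loc[ok, col],
                                       merged.loc[ok, f"{col}_ref"],
                                       rtol=1e-12)
        assert (merged["n_spots_used"] == merged["n_spots_used_ref"]).all()

        cmp = compare_table(genes, ("a", "x"), ("b", "x"))
        ref_cmp = naive_compare(naive_gene_table(sim.spots), ("a", "x"),
                                ("b", "x"))
        assert set(cmp["gene_id"]) == set(ref_cmp)
        for _, row in cmp.iterrows():
            exp = ref_cmp[row["gene_id"]]
            assert row["status"] == exp["status"]
            assert row["direction"] == exp["direction"]
            assert bool(row["significant"]) == exp["significant"]
            if exp["status"] == "OK":
                assert row["q_value"] == pytest.approx(exp["q_value"],
                                                       rel=1e-12)


def test_missing_columns_raise_named_error():
    with pytest.raises(ValueError, match="bg_dev"):
        spot_signal_table(pd.DataFrame({"gene_id": ["g"]}))
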