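"""Filter cascade, independence rule, VAF aggregation, tier assignment."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from clonesift.config import FilterConfig
from clonesift.prioritize import (
    aggregate_vaf,
    assign_tier,
    count_validated,
    filter_calls,
    merge_tandem,
    prioritize,
    require_independent,
)
from clonesift.types import ALLELES, PileupMatrix, SampleMeta, SampleSheet


def _call(sample="S01", amp="AMP_X", pos=50, alt="C", alt_count=30,
          depth=15000, p=50.0, chrom="chr1", ref="A"):
    return {
        "sample_id": sample, "amplicon_id": amp, "chrom": chrom, "pos": pos,
        "ref": ref, "alt": alt, "alt_count": alt_count, "depth": depth,
        "vaf": alt_count / depth, "neg_log10_p": p,
    }


def _calls(rows):
    return pd.DataFrame(rows)


def _uniform_pileup(samples, amplicons, positions, depth=15000):
    rows = []
    for s in samples:
        for a in amplicons:
            for p in positions:
                rows.append(
                    {"sample_id": s, "amplicon_id": a, "chrom": "chr1",
                     "pos": p, "ref": "A", "A": depth, "C": 0, "G": 0, "T": 0,
                     "mean_bq": 35.0}
                )
    return PileupMatrix(pd.DataFrame(rows))


def _sheet(n, biopsies=None):
    samples = []
    for i in range(n):
        bid = biopsies[i] if biopsies else f"B{i:02d}"
        samples.append(
            SampleMeta(
                sample_id=f"S{i:02d}", biopsy_id=bid, testis_id="T1",
                slice_id="T1S1", slice_position=i, flow_cell="FC1", lane="FC1L1",
                mean_base_quality=35.0,
            )
        )
    return SampleSheet(samples)


@pytest.fixture
def simple_panel(tiny_panel):
    return tiny_panel


class TestFilterCalls:
    def test_max_vaf_cap_removes_whole_variant(self, simple_panel):
        calls = _calls([
            _call("S01", "AMP_T", alt_count=480, depth=15000),  # 3.2%
            _call("S02", "AMP_T", alt_count=30, depth=15000),
        ])
        pu = _uniform_pileup(["S01", "S02"], ["AMP_T"], [50])
        out, _ = filter_calls(calls, pu, simple_panel, FilterConfig())
        assert out.empty  # both calls of the >=3% variant removed

    def test_vaf_just_under_cap_retained(self, simple_panel):
        calls = _calls([_call("S01", "AMP_T", alt_count=442, depth=15000)])  # 2.95%
        pu = _uniform_pileup(["S01"], ["AMP_T"], [50])
        out, _ = filter_calls(calls, pu, simple_panel, FilterConfig())
        assert len(out) == 1

    def test_primer_proximal_removed(self, simple_panel):
        amp = simple_panel.amplicons[0]
        edge_pos = amp.callable_start  # 1 base from the fwd primer 3' end
        inner_pos = amp.callable_start + 10
        calls = _calls([
            _call("S01", "AMP_T", pos=edge_pos),
            _call("S01", "AMP_T", pos=inner_pos),
        ])
        pu = _uniform_pileup(["S01"], ["AMP_T"], [edge_pos, inner_pos])
        out, _ = filter_calls(calls, pu, simple_panel, FilterConfig())
        assert list(out["pos"]) == [inner_pos]

    def test_low_median_depth_position_removed(self, simple_panel):
        calls = _calls([_call("S01", "AMP_T", pos=50)])
        pu = _uniform_pileup(["S01", "S02", "S03"], ["AMP_T"], [50], depth=4000)
        out, _ = filter_calls(calls, pu, simple_panel, FilterConfig())
        assert out.empty

    def test_excess_call_sample_removed(self, simple_panel):
        amp = simple_panel.amplicons[0]
        rows = []
        # S00 piles up 60 calls; 30 other samples have one call each
        for j in range(60):
            rows.append(_call("S00", "AMP_T", pos=amp.callable_start + 5 + j,
                              alt=("C" if amp.sequence[25 + 5 + j] != "C" else "G")))
        for i in range(1, 31):
            rows.append(_call(f"S{i:02d}", "AMP_T", pos=amp.callable_start + 5))
        positions = sorted({r["pos"] for r in rows})
        pu = _uniform_pileup([f"S{i:02d}" for i in range(31)], ["AMP_T"], positions)
        out, _ = filter_calls(_calls(rows), pu, simple_panel, FilterConfig())
        assert "S00" not in set(out["sample_id"])
        assert set(out["sample_id"]) == {f"S{i:02d}" for i in range(1, 31)}

    def test_stage_counts_non_increasing(self, simple_panel):
        calls = _calls([
            _call("S01", "AMP_T", pos=50),
            _call("S02", "AMP_T", pos=50),
            _call("S03", "AMP_T", pos=20, alt_count=5),
        ])
        pu = _uniform_pileup(["S01", "S02", "S03"], ["AMP_T"], [20, 50])
        _, stages = filter_calls(calls, pu, simple_panel, FilterConfig())
        order = ["raw", "min_alt_reads", "excess_calls", "primer_proximal",
                 "min_median_depth", "max_vaf_cap"]
        values = [stages[k] for k in order]
        assert values == sorted(values, reverse=True)

    def test_threshold_monotonicity_grid(self, simple_panel):
        # raising any strictness knob never enlarges the surviving set
        rng = np.random.default_rng(7)
        amp = simple_panel.amplicons[0]
        positions = list(range(amp.callable_start, amp.callable_end, 3))
        rows = []
        for i in range(12):
            for pos in rng.choice(positions, size=6, replace=False):
                rows.append(
                    _call(f"S{i:02d}", "AMP_T", pos=int(pos),
                          alt_count=int(rng.integers(5, 500)))
                )
        calls = _calls(rows)
        pu = _uniform_pileup(
            [f"S{i:02d}" for i in range(12)], ["AMP_T"], positions,
            depth=int(rng.integers(5500, 9000)),
        )

        def survivors(cfg):
            out, _ = filter_calls(calls, pu, simple_panel, cfg)
            return set(map(tuple, out[["sample_id", "pos", "alt"]].values))

        base = FilterConfig()
        base_set = survivors(base)
        stricter = [
            FilterConfig(min_alt_reads=40),
            FilterConfig(min_median_depth=8000),
            FilterConfig(max_vaf_cap=0.01),
            FilterConfig(primer_proximal_bp=10),
            FilterConfig(excess_min_calls=4),
        ]
        for cfg in stricter:
            assert survivors(cfg) <= base_set


class TestRequireIndependent:
    def test_singleton_dropped(self):
        calls = _calls([_call("S01")])
        out = require_independent(calls, _sheet(2))
        assert out.empty

    def test_two_samples_kept(self):
        calls = _calls([_call("S01"), _call("S02")])
        out = require_independent(calls, _sheet(2))
        assert len(out) == 2

    def test_overlapping_amplicons_one_sample_kept(self):
        calls = _calls([_call("S01", "AMP_A"), _call("S01", "AMP_B")])
        out = require_independent(calls, _sheet(2))
        assert len(out) == 2

    def test_replicate_pair_kept(self):
        sheet = _sheet(2, biopsies=["B01", "B01"])
        calls = _calls([_call("S00"), _call("S01")])
        out = require_independent(calls, sheet)
        assert len(out) == 2


class TestAggregateVaf:
    def test_mean_over_overlapping_amplicons(self):
        calls = require_independent(
            _calls([
                _call("S01", "AMP_A", alt_count=20, depth=10000),  # 0.2%
                _call("S01", "AMP_B", alt_count=40, depth=10000),  # 0.4%
            ]),
            _sheet(2),
        )
        agg = aggregate_vaf(calls)
        assert agg.iloc[0]["vaf"] == pytest.approx(0.003)

    def test_single_call_identity(self):
        calls = require_independent(
            _calls([_call("S01", "AMP_A", alt_count=50, depth=10000),
                    _call("S02", "AMP_A", alt_count=50, depth=10000)]),
            _sheet(3),
        )
        agg = aggregate_vaf(calls)
        assert np.allclose(agg["vaf"], 0.005)

    def test_replicate_pair_mean(self):
        # 1.0% and 1.2% replicates aggregate to 1.1% at biopsy level
        sheet = _sheet(2, biopsies=["B01", "B01"])
        calls = require_independent(
            _calls([
                _call("S00", alt_count=100, depth=10000),
                _call("S01", alt_count=120, depth=10000),
            ]),
            sheet,
        )
        res_cands = prioritize(
            calls.drop(columns="variant_id"),
            _uniform_pileup(["S00", "S01"], ["AMP_X"], [50]),
            _panel_with("AMP_X"),
            sheet,
        )
        assert res_cands.candidates.iloc[0]["max_vaf"] == pytest.approx(0.011)


def _panel_with(amp_id):
    from clonesift.types import Amplicon, AmpliconPanel
    return AmpliconPanel([
        Amplicon(
            amplicon_id=amp_id, gene="G", pathway="OTHER", chrom="chr1",
            start=0, end=100, fwd_primer_len=20, rev_primer_len=20,
            sequence="A" * 100,
        )
    ])


class TestAssignTier:
    def test_overlap_support_is_tier1_even_at_low_vaf(self):
        assert assign_tier(True, False, 0.0012) == 1

    def test_replicate_support_is_tier1(self):
        assert assign_tier(False, True, 0.0006) == 1

    def test_tier2_at_boundary(self):
        assert assign_tier(False, False, 0.002) == 2

    def test_tier2_above(self):
        assert assign_tier(False, False, 0.0025) == 2

    def test_tier3_at_boundary(self):
        assert assign_tier(False, False, 0.001) == 3

    def test_tier4_below(self):
        assert assign_tier(False, False, 0.0006) == 4

    @given(
        overlap=st.booleans(),
        replicate=st.booleans(),
        vaf=st.floats(min_value=1e-6, max_value=0.0299),
    )
    @settings(max_examples=200, deadline=None)
    def test_tier_partition_exhaustive_and_exclusive(self, overlap, replicate, vaf):
        tier = assign_tier(overlap, replicate, vaf)
        assert tier in (1, 2, 3, 4)
        if overlap or replicate:
            assert tier == 1


class TestMergeTandem:
    def _candidates(self, vafs_a, vafs_b, pos_b=51):
        cands = pd.DataFrame([
            {"variant_id": "chr1:50:A>C", "chrom": "chr1", "pos": 50, "ref": "A",
             "alt": "C", "is_tandem": False, "n_samples": len(vafs_a),
             "n_biopsies": len(vafs_a), "n_amplicons": 1,
             "overlap_support": False, "replicate_support": False,
             "max_vaf": max(vafs_a.values())},
            {"variant_id": f"chr1:{pos_b}:G>T", "chrom": "chr1", "pos": pos_b,
             "ref": "G", "alt": "T", "is_tandem": False, "n_samples": len(vafs_b),
             "n_biopsies": len(vafs_b), "n_amplicons": 1,
             "overlap_support": False, "replicate_support": False,
             "max_vaf": max(vafs_b.values())},
        ])
        rows = []
        for vid, vafs in (("chr1:50:A>C", vafs_a), (f"chr1:{pos_b}:G>T", vafs_b)):
            for s, v in vafs.items():
                rows.append({"variant_id": vid, "sample_id": s, "biopsy_id": s,
                             "testis_id": "T1", "vaf": v, "n_amplicons": 1})
        return cands, pd.DataFrame(rows)

    def test_adjacent_correlated_merged(self):
        vafs = {"S01": 0.004, "S02": 0.002, "S03": 0.001}
        cands, cs = self._candidates(vafs, vafs)
        merged, merged_cs = merge_tandem(cands, cs)
        assert len(merged) == 1
        row = merged.iloc[0]
        assert bool(row["is_tandem"])
        assert row["ref"] == "AG" and row["alt"] == "CT"
        assert set(merged_cs["sample_id"]) == set(vafs)

    def test_non_adjacent_not_merged(self):
        vafs = {"S01": 0.004, "S02": 0.002}
        cands, cs = self._candidates(vafs, vafs, pos_b=52)
        merged, _ = merge_tandem(cands, cs)
        assert len(merged) == 2
        assert not merged["is_tandem"].any()

    def test_uncorrelated_not_merged(self):
        a = {"S01": 0.004, "S02": 0.002, "S03": 0.001, "S04": 0.0035}
        b = {"S01": 0.001, "S02": 0.004, "S03": 0.0035, "S04": 0.001}
        cands, cs = self._candidates(a, b)
        merged, _ = merge_tandem(cands, cs)
        assert len(merged) == 2

    def test_disjoint_samples_not_merged(self):
        a = {"S01": 0.004, "S02": 0.002}
        b = {"S03": 0.004, "S04": 0.002}
        cands, cs = self._candidates(a, b)
        merged, _ = merge_tandem(cands, cs)
        assert len(merged) == 2


class TestCountValidated:
    def test_reconstructs_distinct_variant_total(self):
        tiers = [
            {"candidates": 40, "rescreened": 18, "validated": 17,
             "assume_unrescreened_true": True},
            {"candidates": 26, "rescreened": 26, "validated": 18},
            {"candidates": 29, "rescreened": 22, "validated": 4},
        ]
        assert count_validated(tiers) == 61

    def test_inconsistent_counts_rejected(self):
        with pytest.raises(ValueError):
            count_validated([{"candidates": 5, "rescreened": 2, "validated": 3}])
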