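"""Generator contracts: panels, layouts, clone placement, pileup simulation."""
import math

import networkx as nx
import numpy as np
import pytest

from clonesift.config import (
    CloneConfig,
    DepthConfig,
    ErrorModelConfig,
    LayoutConfig,
    PanelConfig,
)
from clonesift.synthetic import (
    bottleneck_resample,
    build_error_model,
    build_layout,
    build_panel,
    place_clones,
    simulate_pileups,
    simulate_reads,
)
from clonesift.types import ALLELES, ConfigurationError, GroundTruth, CloneSpec


class TestBuildPanel:
    def test_overlap_pair_count(self):
        panel = build_panel(PanelConfig(n_amplicons=30, overlap_fraction=0.1), seed=7)
        assert len(panel.overlapping_pairs()) == 3  # 0.1 * 30 / 2 pairs

    def test_determinism_byte_identical(self):
        a = build_panel(PanelConfig(), seed=7)
        b = build_panel(PanelConfig(), seed=7)
        assert [x for x in a.amplicons] == [x for x in b.amplicons]

    def test_different_seeds_differ(self):
        a = build_panel(PanelConfig(), seed=7)
        b = build_panel(PanelConfig(), seed=8)
        assert a.amplicons != b.amplicons

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_pathway_share_near_target(self, seed):
        panel = build_panel(PanelConfig(ras_mapk_share=0.419), seed=seed)
        assert abs(panel.pathway_share("RAS_MAPK") - 0.419) < 0.02

    def test_callable_nonempty_everywhere(self, default_panel):
        for amp in default_panel:
            assert amp.callable_end > amp.callable_start

    def test_zero_callable_rejected(self):
        with pytest.raises(ConfigurationError):
            PanelConfig(amplicon_length=(40, 45), fwd_primer_len=20, rev_primer_len=20)

    def test_overlapping_amplicons_share_sequence(self, default_panel):
        for a_id, b_id in default_panel.overlapping_pairs():
            a, b = default_panel[a_id], default_panel[b_id]
            lo, hi = max(a.start, b.start), min(a.end, b.end)
            assert a.sequence[lo - a.start:hi - a.start] == \
                b.sequence[lo - b.start:hi - b.start]


class TestBuildLayout:
    def test_ring_and_interslice_edges(self):
        # 2 slices x 8: 8 ring edges per slice + 8 facing edges
        _, bmap = build_layout(
            LayoutConfig(n_testes=1, slices_per_testis=2, biopsies_per_slice=8),
            seed=1,
        )
        assert bmap.graph.number_of_nodes() == 16
        assert bmap.graph.number_of_edges() == 24

    def test_single_biopsy(self):
        _, bmap = build_layout(
            LayoutConfig(n_testes=1, slices_per_testis=1, biopsies_per_slice=1),
            seed=1,
        )
        assert bmap.graph.number_of_nodes() == 1
        assert bmap.graph.number_of_edges() == 0

    def test_replicates_inflate_sample_count(self):
        # 276 biopsies with 12 duplicated -> 288 samples
        sheet, _ = build_layout(
            LayoutConfig(
                n_testes=1, slices_per_testis=23, biopsies_per_slice=12,
                n_replicates=12, n_flow_cells=2, lanes_per_flow_cell=8,
            ),
            seed=1,
        )
        assert len(sheet) == 288
        assert len(sheet.replicate_pairs()) == 12

    def test_replicates_share_biopsy(self):
        sheet, _ = build_layout(LayoutConfig(n_replicates=3), seed=2)
        for primary, rep in sheet.replicate_pairs():
            assert sheet[primary].biopsy_id == sheet[rep].biopsy_id

    def test_too_many_replicates_rejected(self):
        with pytest.raises(ConfigurationError):
            LayoutConfig(
                n_testes=1, slices_per_testis=1, biopsies_per_slice=4,
                n_replicates=5,
            )

    def test_graph_components_are_testes(self):
        _, bmap = build_layout(LayoutConfig(n_testes=3), seed=4)
        comps = list(nx.connected_components(bmap.graph))
        assert len(comps) == 3
        for comp in comps:
            assert len({bmap.testis_of(b) for b in comp}) == 1


class TestPlaceClones:
    def test_empty(self, default_panel, default_layout):
        _, bmap = default_layout
        truth = place_clones(default_panel, bmap, CloneConfig(n_clones=0), seed=1)
        assert len(truth) == 0
        assert truth.variants() == []

    def test_clonal_paths_connected(self, default_panel, default_layout):
        _, bmap = default_layout
        truth = place_clones(
            default_panel, bmap, CloneConfig(n_clones=10, walk_length=(4, 4)),
            seed=5,
        )
        for clone in truth.clones:
            assert bmap.is_connected(clone.path)

    def test_tandem_alleles_share_vafs_exactly(self, default_panel, default_layout):
        _, bmap = default_layout
        truth = place_clones(
            default_panel, bmap,
            CloneConfig(n_clones=8, tandem_fraction=1.0), seed=6,
        )
        for clone in truth.clones:
            assert clone.is_tandem
            v1, v2 = clone.variants
            assert v2[1] == v1[1] + 1
            for b in clone.path:
                assert truth.vaf_for(b, v1) == truth.vaf_for(b, v2)

    def test_vaf_ceiling_rejected(self):
        with pytest.raises(ConfigurationError):
            CloneConfig(vaf_range=(0.001, 0.03))

    def test_postzygotic_spans_three_slices(self, default_panel, default_layout):
        _, bmap = default_layout
        truth = place_clones(
            default_panel, bmap,
            CloneConfig(n_clones=0, n_postzygotic=2), seed=7,
        )
        for clone in truth.clones:
            assert clone.kind == "POSTZYGOTIC"
            assert len({bmap.slice_of(b) for b in clone.path}) >= 3
            assert len(clone.path) >= 6

    def test_ground_truth_exhaustive(self, default_panel, default_layout):
        _, bmap = default_layout
        truth = place_clones(default_panel, bmap, CloneConfig(n_clones=5), seed=8)
        df = truth.to_df()
        assert len(df) == sum(
            len(c.vaf_by_biopsy) * len(c.variants) for c in truth.clones
        )
        for r in df.itertuples(index=False):
            assert truth.vaf_for(r.biopsy_id, (r.chrom, r.pos, r.ref, r.alt)) == r.vaf


def _flat_error_model(panel, sheet, median=1e-4, rho=0.0):
    return build_error_model(
        panel, sheet,
        ErrorModelConfig(
            median_rate=median, log_sigma=0.0, flow_cell_effects={},
            lane_effects={}, bq_slope=0.0, rho=rho,
        ),
        seed=0,
    )


class TestSimulatePileups:
    def test_depth_conservation(self, spiked_run):
        pu = spiked_run["pileup"]
        depths = pu.depth.to_numpy()
        assert (depths >= 0).all()
        # per-(sample, amplicon) depth constant across alleles by construction;
        # conservation: A+C+G+T == simulated depth is definitional, so check
        # the pileup's internal consistency against per-allele sums
        assert (pu.df[list(ALLELES)].sum(axis=1).to_numpy() == depths).all()

    def test_null_mean_alt_fraction(self, default_layout):
        # flat e = 1e-4, depth 15000, 48 samples: per-position mean alt
        # fraction concentrates near 1e-4 (Monte-Carlo over ~1000 columns)
        panel = build_panel(PanelConfig(n_amplicons=8), seed=2)
        sheet, bmap = default_layout
        em = _flat_error_model(panel, sheet)
        truth = GroundTruth([])
        pu = simulate_pileups(panel, sheet, truth, em, DepthConfig(), seed=3)
        df = pu.df
        alt = df[list(ALLELES)].sum(axis=1) - df.apply(lambda r: r[r["ref"]], axis=1)
        depth = df[list(ALLELES)].sum(axis=1)
        per_pos = (
            alt.groupby([df["amplicon_id"], df["pos"]]).sum()
            / depth.groupby([df["amplicon_id"], df["pos"]]).sum()
        ) / 3.0  # three alt alleles per position, each at rate ~1e-4
        assert len(per_pos) > 700
        frac_in_window = ((per_pos > 5e-5) & (per_pos < 2e-4)).mean()
        assert frac_in_window > 0.99
        assert abs(per_pos.mean() - 1e-4) < 2e-5

    def test_spiked_expected_alt_count(self, tiny_panel):
        # VAF 1% + e 1e-4 at depth 15000 -> mean alt count ~ 151.5
        sheet, bmap = build_layout(
            LayoutConfig(n_testes=1, slices_per_testis=25, biopsies_per_slice=8),
            seed=4,
        )
        amp = tiny_panel.amplicons[0]
        pos = amp.callable_start + 5
        ref = amp.ref_base(pos)
        alt = next(a for a in ALLELES if a != ref)
        vafs = {s.biopsy_id: 0.01 for s in sheet}
        truth = GroundTruth([
            CloneSpec(
                clone_id="C1", variants=((amp.chrom, pos, ref, alt),),
                testis_id="T1", path=tuple(vafs), vaf_by_biopsy=vafs,
                kind="CLONAL",
            )
        ])
        em = _flat_error_model(tiny_panel, sheet)
        pu = simulate_pileups(
            tiny_panel, sheet, truth, em,
            DepthConfig(mean_depth=15000, dispersion=0.0, n_templates=10**6),
            seed=5,
        )
        row = pu.df[pu.df["pos"] == pos]
        assert len(row) == 200
        assert abs(row[alt].mean() - 151.5) < 4.0

    def test_bottleneck_zero_template_mass(self):
        # vaf * n_templates = 1 -> P(no mutant template) ~ exp(-1)
        rng = np.random.default_rng(11)
        realized = bottleneck_resample(rng, vaf=0.001, n_templates=1000, size=10000)
        assert abs((realized == 0).mean() - math.exp(-1)) < 0.02

    def test_bottleneck_variance_matches_analytic(self, tiny_panel):
        # var(alt/depth) ~ v(1-v)/n_templates + (e+v)/depth, within 20%
        v, n_templates, depth, e = 0.01, 1000, 15000, 1e-7
        sheet, _ = build_layout(
            LayoutConfig(n_testes=1, slices_per_testis=24, biopsies_per_slice=12),
            seed=6,
        )
        amp = tiny_panel.amplicons[0]
        pos = amp.callable_start
        ref = amp.ref_base(pos)
        alt = next(a for a in ALLELES if a != ref)
        vafs = {s.biopsy_id: v for s in sheet}
        truth = GroundTruth([
            CloneSpec(
                clone_id="C1", variants=((amp.chrom, pos, ref, alt),),
                testis_id="T1", path=tuple(vafs), vaf_by_biopsy=vafs,
                kind="CLONAL",
            )
        ])
        em = _flat_error_model(tiny_panel, sheet, median=e)
        obs = []
        for seed in range(35):  # 35 x 288 = 10,080 Monte-Carlo reps
            pu = simulate_pileups(
                tiny_panel, sheet, truth, em,
                DepthConfig(mean_depth=depth, dispersion=0.0, n_templates=n_templates),
                seed=100 + seed,
            )
            row = pu.df[pu.df["pos"] == pos]
            obs.append(row[alt].to_numpy() / depth)
        obs = np.concatenate(obs)
        analytic = v * (1 - v) / n_templates + (e + v) / depth
        assert abs(obs.var() - analytic) / analytic < 0.2

    def test_determinism(self, spiked_run):
        pu2 = simulate_pileups(
            spiked_run["panel"], spiked_run["sheet"], spiked_run["truth"],
            build_error_model(
                spiked_run["panel"], spiked_run["sheet"], ErrorModelConfig(),
                seed=spiked_run["seed"],
            ),
            DepthConfig(), seed=spiked_run["seed"],
        )
        assert spiked_run["pileup"].equals(pu2)

    def test_zero_depth_yields_empty_counts(self, tiny_panel):
        sheet, _ = build_layout(
            LayoutConfig(n_testes=1, slices_per_testis=1, biopsies_per_slice=8),
            seed=7,
        )
        em = _flat_error_model(tiny_panel, sheet)
        pu = simulate_pileups(
            tiny_panel, sheet, GroundTruth([]), em,
            DepthConfig(mean_depth=0, dispersion=0.0), seed=8,
        )
        assert (pu.depth == 0).all()

    def test_spatial_property_clonal_connected(self, default_panel, default_layout):
        _, bmap = default_layout
        truth = place_clones(
            default_panel, bmap, CloneConfig(n_clones=12), seed=9,
        )
        for clone in truth.clones:
            if clone.kind == "CLONAL":
                positives = [b for b, v in clone.vaf_by_biopsy.items() if v > 0]
                assert bmap.is_connected(positives)


class TestSimulateReads:
    def test_error_free_reads_match_reference(self, tiny_panel):
        df = simulate_reads(tiny_panel, ["S1"], n_pairs=3, seed=1)
        amp = tiny_panel.amplicons[0]
        for r in df.itertuples(index=False):
            start = int(r.start)
            assert r.bases == amp.sequence[start - amp.start:start - amp.start + len(r.bases)]
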