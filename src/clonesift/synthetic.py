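"""Synthetic testis/biopsy/panel generator with known ground truth.

Emulates the structure of a multi-biopsy deep amplicon screen: a panel of
(partly overlapping) amplicons with pathway labels, testes dissected into
slices of radially arranged biopsies, clonal variants spiked along connected
biopsy walks, and per-position background error with heavy-tailed rates and
flow-cell/lane/base-quality batch effects. Everything is deterministic under
a fixed (config, seed) pair.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .config import (
    CloneConfig,
    DepthConfig,
    ErrorModelConfig,
    LayoutConfig,
    PanelConfig,
)
from .types import (
    ALLELES,
    Amplicon,
    AmpliconPanel,
    BiopsyMap,
    CloneSpec,
    ConfigurationError,
    GroundTruth,
    PileupMatrix,
    SampleMeta,
    SampleSheet,
    Variant,
)
from .util import expit, logit, substream

_BASES = np.array(list("ACGT"))


# ---------------------------------------------------------------------------
# panel


def build_panel(config: PanelConfig, seed: int) -> AmpliconPanel:
    """Generate a deterministic amplicon panel.

    ``round(overlap_fraction * n_amplicons)`` overlapping pairs are created
    (each pair shares a gene and roughly half its span). Pathway labels are
    assigned per gene so that the unique callable share of RAS_MAPK bases
    approaches ``ras_mapk_share``; the last RAS_MAPK amplicon's length is
    nudged to land the share within rounding error.
    """
    rng = substream(seed, "panel")
    n = config.n_amplicons
    n_pairs = int(round(config.overlap_fraction * n))
    n_genes_total = config.n_genes or max(4, n // 3)

    # gene -> number of amplicons; overlap pairs sit inside one gene
    gene_sizes: list[int] = []
    remaining = n
    for _ in range(n_pairs):
        gene_sizes.append(2)
        remaining -= 2
    n_single_genes = max(1, n_genes_total - n_pairs)
    base = remaining // n_single_genes
    extra = remaining % n_single_genes
    for i in range(n_single_genes):
        size = base + (1 if i < extra else 0)
        if size > 0:
            gene_sizes.append(size)
    rng.shuffle(gene_sizes)

    lo, hi = config.amplicon_length
    gap = 600  # leaves room for the share-adjustment nudge below
    chrom_cursor = {f"chr{i + 1}": 1000 for i in range(config.n_chroms)}
    chrom_names = list(chrom_cursor)

    amp_rows = []  # (gene, chrom, start, end, overlapping: bool)
    genes: list[str] = []
    for gi, size in enumerate(gene_sizes):
        gene = f"GENE{gi + 1:03d}"
        genes.append(gene)
        chrom = chrom_names[gi % len(chrom_names)]
        cursor = chrom_cursor[chrom]
        prev = None
        for ai in range(size):
            length = int(rng.integers(lo, hi + 1))
            if size == 2 and ai == 1 and prev is not None:
                # overlapping mate: start midway through its partner
                start = prev[0] + (prev[1] - prev[0]) // 2
            else:
                start = cursor
            end = start + length
            amp_rows.append([gene, chrom, start, end, size == 2])
            cursor = max(cursor, end) + gap
            prev = (start, end)
        chrom_cursor[chrom] = cursor

    fwd, rev = config.fwd_primer_len, config.rev_primer_len

    def callable_len(row) -> int:
        return (row[3] - row[2]) - fwd - rev

    gene_rows: dict[str, list[list]] = {}
    for row in amp_rows:
        gene_rows.setdefault(row[0], []).append(row)

    def union_bp(rows: list[list]) -> int:
        """Unique callable bp of a gene (interval merge)."""
        ivs = sorted((r[2] + fwd, r[3] - rev) for r in rows)
        total, cur_s, cur_e = 0, *ivs[0]
        for s, e in ivs[1:]:
            if s > cur_e:
                total += cur_e - cur_s
                cur_s, cur_e = s, e
            else:
                cur_e = max(cur_e, e)
        return total + (cur_e - cur_s)

    gene_bp = {g: union_bp(rows) for g, rows in gene_rows.items()}
    total_bp = sum(gene_bp.values())
    target = config.ras_mapk_share

    order = list(genes)
    rng.shuffle(order)
    ras_genes: set[str] = set()
    acc = 0
    for gene in order:
        if target <= 0.0:
            break
        nxt = acc + gene_bp[gene]
        if abs(nxt / total_bp - target) <= abs(acc / total_bp - target):
            ras_genes.add(gene)
            acc = nxt
        if acc / total_bp >= target:
            break

    # land the share on target by extending amplicon ends (never trimming):
    # under target, grow RAS bases:  (acc+d)/(total+d) = s  =>  d = (s*T-R)/(1-s)
    # over target, grow non-RAS bases (denominator only):  R/(T+d) = s
    if ras_genes and 0.0 < target < 1.0:

        def extend(pool_genes: list[str], need: int) -> int:
            # grow each gene's rightmost amplicon, <=500 each to respect the
            # inter-amplicon gaps left at placement time
            for g in sorted(pool_genes):
                if need <= 0:
                    break
                row = max(gene_rows[g], key=lambda r: r[3])
                step = min(500, need)
                row[3] += step
                need -= step
            return need

        if acc / total_bp < target:
            delta = int(round((target * total_bp - acc) / (1.0 - target)))
            extend(list(ras_genes), delta)
        else:
            delta = int(round(acc / target - total_bp))
            extend([g for g in genes if g not in ras_genes], delta)

    non_ras = [g for g in order if g not in ras_genes]
    neutral_genes = set(non_ras[: config.n_neutral_genes])

    # reference sequence: one random chromosome string per chrom, shared by
    # overlapping amplicons so their bases agree
    span_hi = {c: 0 for c in chrom_names}
    for _, chrom, _, end, _ in amp_rows:
        span_hi[chrom] = max(span_hi[chrom], end)
    chrom_seq = {
        c: "".join(rng.choice(_BASES, size=span_hi[c])) for c in chrom_names
    }

    amplicons = []
    for i, (gene, chrom, start, end, _) in enumerate(amp_rows):
        pathway = (
            "RAS_MAPK" if gene in ras_genes
            else "NEUTRAL" if gene in neutral_genes
            else "OTHER"
        )
        amplicons.append(
            Amplicon(
                amplicon_id=f"AMP{i + 1:04d}",
                gene=gene,
                pathway=pathway,
                chrom=chrom,
                start=start,
                end=end,
                fwd_primer_len=fwd,
                rev_primer_len=rev,
                sequence=chrom_seq[chrom][start:end],
            )
        )
    return AmpliconPanel(amplicons)


# ---------------------------------------------------------------------------
# layout


def build_layout(config: LayoutConfig, seed: int) -> tuple[SampleSheet, BiopsyMap]:
    """Samples with batch covariates plus the biopsy adjacency graph.

    Each slice is a ring of biopsies; same-index biopsies of adjacent slices
    of one testis are connected. Replicated biopsies yield a second sample
    flagged via ``replicate_of``.
    """
    rng = substream(seed, "layout")
    g = nx.Graph()
    biopsies: list[tuple[str, str, str, int]] = []  # id, testis, slice, position
    for t in range(config.n_testes):
        testis = f"T{t + 1}"
        for s in range(config.slices_per_testis):
            slice_id = f"{testis}S{s + 1}"
            nb = config.biopsies_per_slice
            for b in range(nb):
                bid = f"{slice_id}B{b + 1:02d}"
                g.add_node(
                    bid, testis_id=testis, slice_id=slice_id, slice_position=b
                )
                biopsies.append((bid, testis, slice_id, b))
            # ring neighbours within the slice
            if nb == 2:
                g.add_edge(f"{slice_id}B01", f"{slice_id}B02")
            elif nb > 2:
                for b in range(nb):
                    g.add_edge(
                        f"{slice_id}B{b + 1:02d}",
                        f"{slice_id}B{(b + 1) % nb + 1:02d}",
                    )
            # facing segments of the previous slice
            if s > 0:
                prev = f"{testis}S{s}"
                for b in range(nb):
                    g.add_edge(f"{prev}B{b + 1:02d}", f"{slice_id}B{b + 1:02d}")

    replicated = set(
        rng.choice(len(biopsies), size=config.n_replicates, replace=False).tolist()
    )

    n_samples = len(biopsies) + config.n_replicates
    n_cells = config.n_flow_cells * config.lanes_per_flow_cell
    per_cell = math.ceil(n_samples / n_cells)

    samples: list[SampleMeta] = []

    def batch(idx: int) -> tuple[str, str]:
        cell = min(idx // per_cell, n_cells - 1)
        fc = cell // config.lanes_per_flow_cell + 1
        lane = cell % config.lanes_per_flow_cell + 1
        # lane labels are globally unique: lanes are nested in flow cells, so
        # lane dummies absorb the flow-cell effect in downstream models
        return f"FC{fc}", f"FC{fc}L{lane}"

    idx = 0
    pending_replicates = []
    for i, (bid, testis, slice_id, pos) in enumerate(biopsies):
        fc, lane = batch(idx)
        samples.append(
            SampleMeta(
                sample_id=bid,
                biopsy_id=bid,
                testis_id=testis,
                slice_id=slice_id,
                slice_position=pos,
                flow_cell=fc,
                lane=lane,
                mean_base_quality=round(float(
                    rng.normal(config.mean_base_quality, config.base_quality_sd)
                ), 4),
                replicate_of=None,
            )
        )
        idx += 1
        if i in replicated:
            pending_replicates.append((bid, testis, slice_id, pos))
    for bid, testis, slice_id, pos in pending_replicates:
        fc, lane = batch(idx)
        samples.append(
            SampleMeta(
                sample_id=f"{bid}R",
                biopsy_id=bid,
                testis_id=testis,
                slice_id=slice_id,
                slice_position=pos,
                flow_cell=fc,
                lane=lane,
                mean_base_quality=round(float(
                    rng.normal(config.mean_base_quality, config.base_quality_sd)
                ), 4),
                replicate_of=bid,
            )
        )
        idx += 1

    return SampleSheet(samples), BiopsyMap(g)


# ---------------------------------------------------------------------------
# clones


def _random_walk(rng: np.random.Generator, g: nx.Graph, start: str, length: int) -> list[str]:
    """Self-avoiding random walk; stops early if boxed in."""
    path = [start]
    while len(path) < length:
        options = [n for n in g.neighbors(path[-1]) if n not in path]
        if not options:
            break
        path.append(options[int(rng.integers(len(options)))])
    return path


def _pick_site(
    rng: np.random.Generator,
    panel: AmpliconPanel,
    used: set[tuple[str, int]],
    tandem: bool,
) -> tuple[Variant, ...]:
    for _ in range(1000):
        amp = panel.amplicons[int(rng.integers(len(panel)))]
        hi = amp.callable_end - (2 if tandem else 1)
        if hi <= amp.callable_start:
            continue
        pos = int(rng.integers(amp.callable_start, hi + 1))
        span = 2 if tandem else 1
        if any((amp.chrom, pos + k) in used for k in range(span)):
            continue
        variants = []
        for k in range(span):
            ref = amp.ref_base(pos + k)
            alt = str(rng.choice([b for b in ALLELES if b != ref]))
            variants.append((amp.chrom, pos + k, ref, alt))
            used.add((amp.chrom, pos + k))
        return tuple(variants)
    raise ConfigurationError("could not place clone variant: panel exhausted")


def place_clones(
    panel: AmpliconPanel,
    bmap: BiopsyMap,
    config: CloneConfig,
    seed: int,
) -> GroundTruth:
    """Spike clonal (and optionally post-zygotic) variants with known VAFs.

    CLONAL paths are connected walks in the biopsy graph; the VAF decays
    geometrically from a peak biopsy along the walk. Tandem clones mutate two
    adjacent positions with identical per-biopsy VAFs. POSTZYGOTIC clones
    scatter across >= 3 slices of one testis.
    """
    rng = substream(seed, "clones")
    g = bmap.graph
    testes: dict[str, list[str]] = {}
    for b in g.nodes:
        testes.setdefault(g.nodes[b]["testis_id"], []).append(b)
    for bs in testes.values():
        bs.sort()
    testis_ids = sorted(testes)

    clones: list[CloneSpec] = []
    used_sites: set[tuple[str, int]] = set()

    for ci in range(config.n_clones):
        testis = testis_ids[int(rng.integers(len(testis_ids)))]
        start = testes[testis][int(rng.integers(len(testes[testis])))]
        lo, hi = config.walk_length
        path = _random_walk(rng, g, start, int(rng.integers(lo, hi + 1)))
        peak_vaf = float(
            np.exp(rng.uniform(np.log(config.vaf_range[0]), np.log(config.vaf_range[1])))
        )
        peak = int(rng.integers(len(path)))
        vafs = {
            b: peak_vaf * config.vaf_decay ** abs(i - peak)
            for i, b in enumerate(path)
        }
        tandem = bool(rng.random() < config.tandem_fraction)
        variants = _pick_site(rng, panel, used_sites, tandem)
        clones.append(
            CloneSpec(
                clone_id=f"CL{ci + 1:03d}",
                variants=variants,
                testis_id=testis,
                path=tuple(path),
                vaf_by_biopsy=vafs,
                kind="CLONAL",
            )
        )

    for pi in range(config.n_postzygotic):
        # needs a testis with >= 3 slices
        eligible = [
            t for t in testis_ids
            if len({g.nodes[b]["slice_id"] for b in testes[t]}) >= 3
        ]
        if not eligible:
            raise ConfigurationError(
                "postzygotic clone requires a testis with >= 3 slices"
            )
        testis = eligible[int(rng.integers(len(eligible)))]
        slices: dict[str, list[str]] = {}
        for b in testes[testis]:
            slices.setdefault(g.nodes[b]["slice_id"], []).append(b)
        slice_ids = sorted(slices)
        lo, hi = config.postzygotic_biopsies
        n_b = int(rng.integers(lo, min(hi, len(testes[testis])) + 1))
        chosen_slices = list(
            rng.choice(slice_ids, size=min(max(3, n_b // 2), len(slice_ids)), replace=False)
        )
        members: list[str] = []
        # one biopsy per chosen slice first (guarantees >= 3 slices), then fill
        for s in chosen_slices:
            members.append(slices[s][int(rng.integers(len(slices[s])))])
        pool = [b for b in testes[testis] if b not in members]
        while len(members) < n_b and pool:
            members.append(pool.pop(int(rng.integers(len(pool)))))
        vaf = config.postzygotic_vaf
        vafs = {
            b: float(np.clip(vaf * rng.lognormal(0.0, 0.25), 1e-4, 0.029))
            for b in members
        }
        variants = _pick_site(rng, panel, used_sites, tandem=False)
        clones.append(
            CloneSpec(
                clone_id=f"PZ{pi + 1:03d}",
                variants=variants,
                testis_id=testis,
                path=tuple(members),
                vaf_by_biopsy=vafs,
                kind="POSTZYGOTIC",
            )
        )

    return GroundTruth(clones)


# ---------------------------------------------------------------------------
# error model


@dataclass
class ErrorModel:
    """Per-(amplicon, position, alt) background rates plus batch effects.

    ``rates[amplicon_id]`` is an (L, 4) array over callable positions and
    alleles; the reference allele's own column is NaN. Covariate effects act
    additively on the logit of the rate.
    """

    rates: dict[str, np.ndarray]
    flow_cell_effects: dict[str, float]
    lane_effects: dict[str, float]
    bq_slope: float
    bq_reference: float
    rho: float


def build_error_model(
    panel: AmpliconPanel,
    sheet: SampleSheet,
    config: ErrorModelConfig,
    seed: int,
) -> ErrorModel:
    """Draw heavy-tailed per-position error rates and batch effect sizes.

    Rates are log-normal around ``median_rate`` and clipped below 0.01 so
    every background position stays in (0, 0.01).
    """
    rng = substream(seed, "error_model")
    rates: dict[str, np.ndarray] = {}
    for amp in panel:
        pos = amp.callable_positions
        e = np.exp(rng.normal(np.log(config.median_rate), config.log_sigma,
                              size=(len(pos), 4)))
        e = np.clip(e, 1e-7, 0.0099)
        refs = np.array([ALLELES.index(amp.ref_base(p)) for p in pos])
        e[np.arange(len(pos)), refs] = np.nan
        rates[amp.amplicon_id] = e

    flow_cells = sorted({s.flow_cell for s in sheet})
    lanes = sorted({s.lane for s in sheet})
    if config.flow_cell_effects is not None:
        fc_eff = {fc: float(config.flow_cell_effects.get(fc, 0.0)) for fc in flow_cells}
    else:
        fc_eff = {fc: float(rng.normal(0.0, config.flow_cell_sd)) for fc in flow_cells}
    if config.lane_effects is not None:
        lane_eff = {ln: float(config.lane_effects.get(ln, 0.0)) for ln in lanes}
    else:
        lane_eff = {ln: float(rng.normal(0.0, config.lane_sd)) for ln in lanes}

    bq_ref = float(np.mean([s.mean_base_quality for s in sheet]))
    return ErrorModel(
        rates=rates,
        flow_cell_effects=fc_eff,
        lane_effects=lane_eff,
        bq_slope=config.bq_slope,
        bq_reference=bq_ref,
        rho=config.rho,
    )


# ---------------------------------------------------------------------------
# pileup simulation


def bottleneck_resample(
    rng: np.random.Generator, vaf: float, n_templates: int, size: int
) -> np.ndarray:
    """Resample a true VAF through a finite pool of input template molecules.

    Returns realized fractions ``Binomial(n_templates, vaf) / n_templates`` —
    the template-sampling noise of droplet PCR: at vaf*n_templates ≈ 1, about
    ``exp(-1)`` of draws carry zero mutant templates.
    """
    return rng.binomial(n_templates, vaf, size=size) / float(n_templates)


def simulate_pileups(
    panel: AmpliconPanel,
    sheet: SampleSheet,
    truth: GroundTruth,
    error_model: ErrorModel,
    depth_config: DepthConfig,
    seed: int,
) -> PileupMatrix:
    """Overdispersed counts for every (sample, amplicon, callable position).

    Per position, each non-reference allele draws
    ``BetaBinomial(depth, e_eff + realized_vaf, rho)`` where ``e_eff`` is the
    batch-shifted background rate and any spiked VAF is first pushed through
    the template bottleneck. Reference counts absorb the remainder, so
    allele counts always sum to the simulated depth.
    """
    rng = substream(seed, "pileups")
    n = len(sheet)
    sample_ids = sheet.sample_ids
    fc_eff = np.array([error_model.flow_cell_effects[s.flow_cell] for s in sheet])
    lane_eff = np.array([error_model.lane_effects[s.lane] for s in sheet])
    sample_bq = np.array([s.mean_base_quality for s in sheet])
    biopsy_ids = [s.biopsy_id for s in sheet]
    rho = error_model.rho

    # variants indexed by (amplicon_id) for the spike overlay; a variant may
    # fall in several overlapping amplicons and is bottlenecked per amplicon
    variants_by_amp: dict[str, list[Variant]] = {a.amplicon_id: [] for a in panel}
    for v in truth.variants():
        for a in panel.amplicons_covering(v[0], v[1]):
            variants_by_amp[a.amplicon_id].append(v)

    frames = []
    for amp in panel:
        pos = amp.callable_positions
        L = len(pos)
        if L == 0:
            continue
        refs = np.array([amp.ref_base(p) for p in pos])
        ref_idx = np.array([ALLELES.index(b) for b in refs])

        if depth_config.mean_depth == 0:
            depth = np.zeros(n, dtype=np.int64)
        elif depth_config.dispersion > 0:
            lam = rng.gamma(
                1.0 / depth_config.dispersion,
                depth_config.mean_depth * depth_config.dispersion,
                size=n,
            )
            depth = rng.poisson(lam)
        else:
            depth = np.full(n, depth_config.mean_depth, dtype=np.int64)

        bq = sample_bq[:, None] + rng.normal(0.0, depth_config.bq_position_sd, (n, L))

        e = error_model.rates[amp.amplicon_id]  # (L, 4), NaN on ref
        alt_mask = ~np.isnan(e)  # (L, 4)
        logit_p = np.where(alt_mask, logit(np.where(alt_mask, e, 0.5)), np.nan)
        shift = (
            fc_eff[:, None, None]
            + lane_eff[:, None, None]
            + error_model.bq_slope * (bq - error_model.bq_reference)[:, :, None]
        )
        p = expit(logit_p[None, :, :] + shift)  # (n, L, 4)

        for v in variants_by_amp[amp.amplicon_id]:
            li = int(v[1] - amp.callable_start)
            ai = ALLELES.index(v[3])
            true_vaf = np.array([truth.vaf_for(b, v) for b in biopsy_ids])
            hit = true_vaf > 0
            if not hit.any():
                continue
            realized = np.zeros(n)
            realized[hit] = (
                rng.binomial(depth_config.n_templates, true_vaf[hit])
                / float(depth_config.n_templates)
            )
            p[:, li, ai] = np.clip(p[:, li, ai] + realized, 0.0, 0.999)

        p_alt = np.where(alt_mask[None, :, :], p, 0.0)
        if rho > 0:
            shape_a = np.where(alt_mask[None, :, :], p_alt * (1 - rho) / rho, 1.0)
            shape_b = np.where(alt_mask[None, :, :], (1 - p_alt) * (1 - rho) / rho, 1.0)
            q = rng.beta(shape_a, shape_b)
        else:
            q = p_alt
        q = np.where(alt_mask[None, :, :], q, 0.0)
        counts = rng.binomial(depth[:, None, None], q)

        # reference allele takes the remainder; cap pathological jackpots
        alt_sum = counts.sum(axis=2)
        over = alt_sum > depth[:, None]
        if over.any():
            si, pi = np.nonzero(over)
            for s_i, p_i in zip(si, pi):
                excess = int(alt_sum[s_i, p_i] - depth[s_i])
                top = int(np.argmax(counts[s_i, p_i]))
                counts[s_i, p_i, top] -= excess
            alt_sum = counts.sum(axis=2)
        counts[np.arange(n)[:, None], np.arange(L)[None, :], ref_idx[None, :]] = (
            depth[:, None] - alt_sum
        )

        frames.append(
            pd.DataFrame(
                {
                    "sample_id": np.repeat(sample_ids, L),
                    "amplicon_id": amp.amplicon_id,
                    "chrom": amp.chrom,
                    "pos": np.tile(pos, n),
                    "ref": np.tile(refs, n),
                    "A": counts[:, :, 0].ravel(),
                    "C": counts[:, :, 1].ravel(),
                    "G": counts[:, :, 2].ravel(),
                    "T": counts[:, :, 3].ravel(),
                    "mean_bq": np.round(bq.ravel(), 2),
                }
            )
        )

    if not frames:
        return PileupMatrix(
            pd.DataFrame(
                columns=["sample_id", "amplicon_id", "chrom", "pos", "ref",
                         "A", "C", "G", "T", "mean_bq"]
            )
        )
    return PileupMatrix(pd.concat(frames, ignore_index=True))


# ---------------------------------------------------------------------------
# synthetic reads (exercises the pileup builder without external data)


def simulate_reads(
    panel: AmpliconPanel,
    sample_ids: Sequence[str],
    n_pairs: int,
    seed: int,
    read_len: int = 100,
    mismatch_rate: float = 0.0,
) -> pd.DataFrame:
    """Error-free (or uniformly-mismatched) paired read records per amplicon.

    R1 starts at the amplicon start, R2 ends at the amplicon end; with short
    amplicons the mates overlap. Output schema matches the reads TSV.
    """
    rng = substream(seed, "reads")
    rows = []
    for amp in panel:
        length = amp.end - amp.start
        rl = min(read_len, length)
        for sid in sample_ids:
            for k in range(n_pairs):
                pair = f"{sid}:{amp.amplicon_id}:{k}"
                for mate, start in (("R1", amp.start), ("R2", amp.end - rl)):
                    bases = list(amp.sequence[start - amp.start: start - amp.start + rl])
                    if mismatch_rate > 0:
                        flips = rng.random(rl) < mismatch_rate
                        for i in np.nonzero(flips)[0]:
                            bases[i] = str(
                                rng.choice([b for b in ALLELES if b != bases[i]])
                            )
                    quals = rng.integers(25, 41, size=rl)
                    rows.append(
                        {
                            "sample_id": sid,
                            "amplicon_id": amp.amplicon_id,
                            "pair_id": pair,
                            "mate": mate,
                            "start": start,
                            "bases": "".join(bases),
                            "quals": ",".join(str(int(q)) for q in quals),
                        }
                    )
    return pd.DataFrame(rows)
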