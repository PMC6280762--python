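"""Seeded end-to-end orchestration.

Each stage reads its inputs from and writes its outputs to one run
directory; ``run_pipeline`` chains the stages, so running the CLI
subcommands one by one produces byte-identical artifacts to ``run-all``.
All randomness derives from the single root seed via named substreams.
"""
from __future__ import annotations

import dataclasses
import logging
from pathlib import Path

import pandas as pd

from . import io
from .background import amplicon_qc, call_outliers
from .config import RunConfig
from .enrichment import enrichment_report
from .geography import count_independent_events, events_table, occurrences_from_candidates, plot_slice_map
from .prioritize import prioritize
from .synthetic import (
    build_error_model,
    build_layout,
    build_panel,
    place_clones,
    simulate_pileups,
)
from .types import PileupMatrix

logger = logging.getLogger(__name__)

ARTIFACTS = {
    "panel_bed": "panel.bed",
    "panel_meta": "panel_meta.tsv",
    "samples": "samples.tsv",
    "biopsy_nodes": "biopsy_nodes.tsv",
    "biopsy_edges": "biopsy_edges.tsv",
    "truth": "truth.tsv",
    "pileup": "pileup.tsv",
    "qc": "amplicon_qc.json",
    "calls": "calls.tsv",
    "stage_counts": "stage_counts.json",
    "candidates": "candidates.tsv",
    "candidate_samples": "candidate_samples.tsv",
    "vcf": "candidates.vcf",
    "events": "events.tsv",
    "enrichment": "enrichment.json",
    "manifest": "manifest.json",
}


def _path(outdir: Path, key: str) -> Path:
    return outdir / ARTIFACTS[key]


def stage_simulate(config: RunConfig, outdir: Path) -> list[Path]:
    """Panel, layout, clones and simulated pileups with ground truth."""
    outdir.mkdir(parents=True, exist_ok=True)
    panel = build_panel(config.panel, config.seed)
    sheet, bmap = build_layout(config.layout, config.seed)
    truth = place_clones(panel, bmap, config.clones, config.seed)
    error_model = build_error_model(panel, sheet, config.error_model, config.seed)
    pileup = simulate_pileups(
        panel, sheet, truth, error_model, config.depth, config.seed
    )
    written = []
    io.write_panel(panel, _path(outdir, "panel_bed"), _path(outdir, "panel_meta"))
    written += [_path(outdir, "panel_bed"), _path(outdir, "panel_meta")]
    io.write_sample_sheet(sheet, _path(outdir, "samples"))
    written.append(_path(outdir, "samples"))
    io.write_biopsy_map(bmap, _path(outdir, "biopsy_nodes"), _path(outdir, "biopsy_edges"))
    written += [_path(outdir, "biopsy_nodes"), _path(outdir, "biopsy_edges")]
    io.write_ground_truth(truth, _path(outdir, "truth"))
    written.append(_path(outdir, "truth"))
    io.write_pileup(pileup, _path(outdir, "pileup"))
    written.append(_path(outdir, "pileup"))
    return written


def stage_call(config: RunConfig, outdir: Path) -> list[Path]:
    """Amplicon QC plus outlier calling on the passing amplicons."""
    pileup = io.read_pileup(_path(outdir, "pileup"))
    sheet = io.read_sample_sheet(_path(outdir, "samples"))
    qc = amplicon_qc(pileup, config.calling)
    passing = {a for a, ok in qc.items() if ok}
    sub = PileupMatrix(pileup.df[pileup.df["amplicon_id"].isin(passing)])
    calls = call_outliers(sub, sheet, config.calling)
    io.write_json({"pass": sorted(passing), "fail": sorted(set(qc) - passing)},
                  _path(outdir, "qc"))
    io.write_calls(calls, _path(outdir, "calls"))
    return [_path(outdir, "qc"), _path(outdir, "calls")]


def stage_prioritize(config: RunConfig, outdir: Path) -> list[Path]:
    """Filter cascade, candidate merging and tier assignment."""
    calls = io.read_calls(_path(outdir, "calls"))
    pileup = io.read_pileup(_path(outdir, "pileup"))
    panel = io.read_panel(_path(outdir, "panel_bed"), _path(outdir, "panel_meta"))
    sheet = io.read_sample_sheet(_path(outdir, "samples"))
    result = prioritize(calls, pileup, panel, sheet, config.filters)
    io.write_candidates(result.candidates, _path(outdir, "candidates"))
    io.write_candidate_samples(result.candidate_samples, _path(outdir, "candidate_samples"))
    io.write_vcf(result.candidates, _path(outdir, "vcf"))
    io.write_json(result.stage_counts, _path(outdir, "stage_counts"))
    return [
        _path(outdir, "candidates"), _path(outdir, "candidate_samples"),
        _path(outdir, "vcf"), _path(outdir, "stage_counts"),
    ]


def stage_clones(config: RunConfig, outdir: Path) -> list[Path]:
    """Spatial clonal events and post-zygotic flags."""
    cs = io.read_candidate_samples(_path(outdir, "candidate_samples"))
    bmap = io.read_biopsy_map(_path(outdir, "biopsy_nodes"), _path(outdir, "biopsy_edges"))
    events = events_table(cs, bmap, config.postzygotic)
    io.write_events(events, _path(outdir, "events"))
    written = [_path(outdir, "events")]
    if config.make_plots and not cs.empty:
        sheet = io.read_sample_sheet(_path(outdir, "samples"))
        for testis in sorted({s.testis_id for s in sheet}):
            p = outdir / f"slice_map_{testis}.png"
            plot_slice_map(cs, bmap, testis, str(p))
            written.append(p)
    return written


def stage_enrich(config: RunConfig, outdir: Path) -> list[Path]:
    """Pathway and tandem statistics over the candidate set."""
    candidates = pd.read_csv(_path(outdir, "candidates"), sep="\t")
    panel = io.read_panel(_path(outdir, "panel_bed"), _path(outdir, "panel_meta"))
    res = enrichment_report(
        candidates, panel, config.enrichment.tandem_background_rate
    )
    payload = (
        {
            "fisher_p": res.fisher_p,
            "log_odds": res.log_odds,
            "wald_p": res.wald_p,
            "tandem_fold": res.tandem_fold,
            "table": [list(row) for row in res.table],
        }
        if res is not None
        else {"fisher_p": None, "log_odds": None, "wald_p": None,
              "tandem_fold": None, "table": None}
    )
    io.write_json(payload, _path(outdir, "enrichment"))
    return [_path(outdir, "enrichment")]


def write_manifest(config: RunConfig, outdir: Path) -> dict:
    from . import __version__

    calls = io.read_calls(_path(outdir, "calls"))
    stage_counts = io.read_json(_path(outdir, "stage_counts"))
    candidates = pd.read_csv(_path(outdir, "candidates"), sep="\t")
    cs = io.read_candidate_samples(_path(outdir, "candidate_samples"))
    events = io.read_events(_path(outdir, "events"))
    sheet = io.read_sample_sheet(_path(outdir, "samples"))
    qc = io.read_json(_path(outdir, "qc"))
    tier_counts = (
        candidates["tier"].value_counts().to_dict() if not candidates.empty else {}
    )
    manifest = {
        "version": __version__,
        "seed": config.seed,
        "n_samples": len(sheet),
        "amplicons_pass_qc": len(qc["pass"]),
        "amplicons_fail_qc": len(qc["fail"]),
        "positions_called": int(
            calls.drop_duplicates(["chrom", "pos"]).shape[0]
        ),
        "stage_counts": stage_counts,
        "tier_counts": {str(k): int(v) for k, v in sorted(tier_counts.items())},
        "n_independent_events": (
            count_independent_events(occurrences_from_candidates(cs, sheet))
            if not cs.empty else 0
        ),
        "n_postzygotic_flagged": (
            int(events.drop_duplicates(["variant_id", "testis_id"])["postzygotic_flag"].sum())
            if not events.empty else 0
        ),
    }
    io.write_json(manifest, _path(outdir, "manifest"))
    return manifest


def run_pipeline(config: RunConfig, outdir: str | Path | None = None) -> dict:
    """All stages in order; partial outputs are removed on failure."""
    outdir = Path(outdir if outdir is not None else config.outdir)
    written: list[Path] = []
    try:
        written += stage_simulate(config, outdir)
        written += stage_call(config, outdir)
        written += stage_prioritize(config, outdir)
        written += stage_clones(config, outdir)
        written += stage_enrich(config, outdir)
        manifest = write_manifest(config, outdir)
    except Exception:
        for p in written:
            try:
                p.unlink(missing_ok=True)
            except OSError:  # pragma: no cover
                pass
        raise
    return manifest
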