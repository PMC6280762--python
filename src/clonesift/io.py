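"""Readers and writers for every on-disk artifact.

All tabular artifacts are long-format TSV; the panel additionally gets a BED
(0-based half-open, matching the internal convention) and candidates a
VCF-like file (1-based POS). Every writer round-trips through its reader.
"""
from __future__ import annotations

import json
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd

from .types import (
    Amplicon,
    AmpliconPanel,
    BiopsyMap,
    GroundTruth,
    PileupMatrix,
    SampleMeta,
    SampleSheet,
    SchemaError,
    parse_variant_id,
)

PathLike = Union[str, Path]

PANEL_META_COLUMNS = [
    "amplicon_id", "gene", "pathway", "chrom", "start", "end",
    "fwd_primer_len", "rev_primer_len", "sequence",
]
SHEET_COLUMNS = [
    "sample_id", "biopsy_id", "testis_id", "slice_id", "slice_position",
    "flow_cell", "lane", "mean_base_quality", "replicate_of",
]
CALL_COLUMNS = [
    "sample_id", "amplicon_id", "chrom", "pos", "ref", "alt",
    "alt_count", "depth", "vaf", "neg_log10_p",
]


def _require_columns(df: pd.DataFrame, columns: list[str], path: PathLike) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")


def _read_tsv(path: PathLike, columns: list[str], **kwargs) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t", **kwargs)
    except Exception as exc:  # pragma: no cover - delegated message
        raise SchemaError(f"{path}: unreadable TSV ({exc})") from exc
    _require_columns(df, columns, path)
    return df


# ---------------------------------------------------------------------------
# panel


def write_panel(panel: AmpliconPanel, bed_path: PathLike, meta_path: PathLike) -> None:
    with open(bed_path, "w") as fh:
        for a in panel:
            fh.write(f"{a.chrom}\t{a.start}\t{a.end}\t{a.amplicon_id}\n")
    pd.DataFrame(
        [
            {
                "amplicon_id": a.amplicon_id,
                "gene": a.gene,
                "pathway": a.pathway,
                "chrom": a.chrom,
                "start": a.start,
                "end": a.end,
                "fwd_primer_len": a.fwd_primer_len,
                "rev_primer_len": a.rev_primer_len,
                "sequence": a.sequence,
            }
            for a in panel
        ]
    ).to_csv(meta_path, sep="\t", index=False)


def read_panel(bed_path: PathLike, meta_path: PathLike) -> AmpliconPanel:
    meta = _read_tsv(meta_path, PANEL_META_COLUMNS, dtype={"sequence": str})
    bed_rows = {}
    with open(bed_path) as fh:
        for lineno, line in enumerate(fh, 1):
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 4:
                raise SchemaError(f"{bed_path}: line {lineno}: expected 4 BED fields")
            bed_rows[fields[3]] = (fields[0], int(fields[1]), int(fields[2]))
    amplicons = []
    for r in meta.itertuples(index=False):
        if r.amplicon_id not in bed_rows:
            raise SchemaError(f"{bed_path}: amplicon {r.amplicon_id} absent from BED")
        chrom, start, end = bed_rows[r.amplicon_id]
        if (chrom, start, end) != (r.chrom, int(r.start), int(r.end)):
            raise SchemaError(
                f"{meta_path}: amplicon {r.amplicon_id}: BED/metadata interval mismatch"
            )
        amplicons.append(
            Amplicon(
                amplicon_id=str(r.amplicon_id),
                gene=str(r.gene),
                pathway=str(r.pathway),
                chrom=chrom,
                start=start,
                end=end,
                fwd_primer_len=int(r.fwd_primer_len),
                rev_primer_len=int(r.rev_primer_len),
                sequence="" if pd.isna(r.sequence) else str(r.sequence),
            )
        )
    return AmpliconPanel(amplicons)


# ---------------------------------------------------------------------------
# layout


def write_sample_sheet(sheet: SampleSheet, path: PathLike) -> None:
    sheet.to_df().to_csv(path, sep="\t", index=False)


def read_sample_sheet(path: PathLike) -> SampleSheet:
    df = _read_tsv(path, SHEET_COLUMNS, dtype={"replicate_of": str}, keep_default_na=False)
    samples = [
        SampleMeta(
            sample_id=str(r.sample_id),
            biopsy_id=str(r.biopsy_id),
            testis_id=str(r.testis_id),
            slice_id=str(r.slice_id),
            slice_position=int(r.slice_position),
            flow_cell=str(r.flow_cell),
            lane=str(r.lane),
            mean_base_quality=float(r.mean_base_quality),
            replicate_of=str(r.replicate_of) or None,
        )
        for r in df.itertuples(index=False)
    ]
    return SampleSheet(samples)


def write_biopsy_map(bmap: BiopsyMap, nodes_path: PathLike, edges_path: PathLike) -> None:
    bmap.nodes_df().to_csv(nodes_path, sep="\t", index=False)
    bmap.edges_df().to_csv(edges_path, sep="\t", index=False)


def read_biopsy_map(nodes_path: PathLike, edges_path: PathLike) -> BiopsyMap:
    nodes = _read_tsv(nodes_path, ["biopsy_id", "testis_id", "slice_id", "slice_position"])
    edges = _read_tsv(edges_path, ["biopsy_a", "biopsy_b"])
    return BiopsyMap.from_tables(nodes, edges)


# ---------------------------------------------------------------------------
# ground truth, pileups, reads, calls, candidates, events


def write_ground_truth(truth: GroundTruth, path: PathLike) -> None:
    truth.to_df().to_csv(path, sep="\t", index=False)


def read_ground_truth(path: PathLike) -> GroundTruth:
    df = _read_tsv(
        path,
        ["clone_id", "kind", "testis_id", "biopsy_id", "chrom", "pos", "ref", "alt", "vaf"],
    )
    if df.empty:
        return GroundTruth([])
    return GroundTruth.from_df(df)


def write_pileup(pileup: PileupMatrix, path: PathLike) -> None:
    pileup.df.to_csv(path, sep="\t", index=False)


def read_pileup(path: PathLike) -> PileupMatrix:
    df = _read_tsv(
        path,
        ["sample_id", "amplicon_id", "chrom", "pos", "ref", "A", "C", "G", "T", "mean_bq"],
    )
    return PileupMatrix(df)


def write_reads(reads_df: pd.DataFrame, path: PathLike) -> None:
    reads_df.to_csv(path, sep="\t", index=False)


def read_reads(path: PathLike) -> pd.DataFrame:
    return _read_tsv(
        path,
        ["sample_id", "amplicon_id", "pair_id", "mate", "start", "bases", "quals"],
        dtype={"bases": str, "quals": str},
        keep_default_na=False,
    )


def write_calls(calls: pd.DataFrame, path: PathLike) -> None:
    calls.to_csv(path, sep="\t", index=False)


def read_calls(path: PathLike) -> pd.DataFrame:
    df = _read_tsv(path, CALL_COLUMNS)
    df["pos"] = df["pos"].astype(int)
    return df


def write_candidates(candidates: pd.DataFrame, path: PathLike) -> None:
    candidates.to_csv(path, sep="\t", index=False)


def read_candidates(path: PathLike) -> pd.DataFrame:
    return _read_tsv(path, ["variant_id", "chrom", "pos", "ref", "alt", "tier"])


def write_candidate_samples(df: pd.DataFrame, path: PathLike) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_candidate_samples(path: PathLike) -> pd.DataFrame:
    return _read_tsv(path, ["variant_id", "sample_id", "biopsy_id", "vaf", "tier"])


def write_events(events: pd.DataFrame, path: PathLike) -> None:
    events.to_csv(path, sep="\t", index=False)


def read_events(path: PathLike) -> pd.DataFrame:
    return _read_tsv(
        path,
        ["variant_id", "testis_id", "component_index", "members",
         "span_slices", "n_components", "postzygotic_flag"],
    )


# ---------------------------------------------------------------------------
# VCF-like candidate export (1-based POS)

_VCF_HEADER = """\
##fileformat=VCFv4.2
##INFO=<ID=TIER,Number=1,Type=Integer,Description="Candidate confidence tier">
##INFO=<ID=NBIOPSY,Number=1,Type=Integer,Description="Positive biopsy count">
##INFO=<ID=MAXVAF,Number=1,Type=Float,Description="Maximum per-biopsy mean VAF">
##INFO=<ID=TANDEM,Number=0,Type=Flag,Description="Dinucleotide substitution">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO
"""


def write_vcf(candidates: pd.DataFrame, path: PathLike) -> None:
    with open(path, "w") as fh:
        fh.write(_VCF_HEADER)
        df = candidates.sort_values(["chrom", "pos"]) if not candidates.empty else candidates
        for r in df.itertuples(index=False):
            info = f"TIER={int(r.tier)};NBIOPSY={int(r.n_biopsies)};MAXVAF={r.max_vaf:.6g}"
            if bool(r.is_tandem):
                info += ";TANDEM"
            fh.write(
                f"{r.chrom}\t{int(r.pos) + 1}\t{r.variant_id}\t{r.ref}\t{r.alt}"
                f"\t.\tPASS\t{info}\n"
            )


def read_vcf(path: PathLike) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 8:
                raise SchemaError(f"{path}: line {lineno}: expected 8 VCF columns")
            chrom, pos1, vid, ref, alt, _qual, _filt, info = fields
            info_map: dict[str, str] = {}
            flags = set()
            for item in info.split(";"):
                if "=" in item:
                    k, v = item.split("=", 1)
                    info_map[k] = v
                else:
                    flags.add(item)
            rows.append(
                {
                    "variant_id": vid,
                    "chrom": chrom,
                    "pos": int(pos1) - 1,
                    "ref": ref,
                    "alt": alt,
                    "is_tandem": "TANDEM" in flags,
                    "tier": int(info_map["TIER"]),
                    "n_biopsies": int(info_map["NBIOPSY"]),
                    "max_vaf": float(info_map["MAXVAF"]),
                }
            )
    return pd.DataFrame(
        rows,
        columns=["variant_id", "chrom", "pos", "ref", "alt", "is_tandem",
                 "tier", "n_biopsies", "max_vaf"],
    )


# ---------------------------------------------------------------------------
# JSON reports


def write_json(data: dict, path: PathLike) -> None:
    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serializable: {type(o)}")

    with open(path, "w") as fh:
        json.dump(data, fh, indent=2, sort_keys=True, default=_default)
        fh.write("\n")


def read_json(path: PathLike) -> dict:
    with open(path) as fh:
        return json.load(fh)
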