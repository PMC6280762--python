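"""Core domain objects shared by every pipeline stage.

Coordinates are 0-based half-open everywhere inside the package; BED export
keeps that convention and VCF export converts to 1-based positions.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Optional, Sequence

import networkx as nx
import numpy as np
import pandas as pd

ALLELES = ("A", "C", "G", "T")
ALLELE_INDEX = {a: i for i, a in enumerate(ALLELES)}
PATHWAYS = ("RAS_MAPK", "OTHER", "NEUTRAL")

#: (chrom, pos, ref, alt) — the atomic variant key used across the pipeline.
Variant = tuple[str, int, str, str]


class ConfigurationError(ValueError):
    """A config asked for something impossible (e.g. empty callable region)."""


class InputError(ValueError):
    """User-supplied data refers to unknown entities or violates a contract."""


class SchemaError(ValueError):
    """An on-disk artifact does not match its expected schema."""


def variant_id(v: Variant) -> str:
    return f"{v[0]}:{v[1]}:{v[2]}>{v[3]}"


def parse_variant_id(s: str) -> Variant:
    chrom, pos, change = s.split(":")
    ref, alt = change.split(">")
    return (chrom, int(pos), ref, alt)


@dataclass(frozen=True)
class Amplicon:
    """A PCR target with primer geometry and a pathway label.

    The callable interval excludes primer-binding sequence:
    ``[start + fwd_primer_len, end - rev_primer_len)``.
    """

    amplicon_id: str
    gene: str
    pathway: str
    chrom: str
    start: int
    end: int
    fwd_primer_len: int
    rev_primer_len: int
    sequence: str = ""

    def __post_init__(self) -> None:
        if self.pathway not in PATHWAYS:
            raise ConfigurationError(
                f"amplicon {self.amplicon_id}: unknown pathway {self.pathway!r}"
            )
        if self.end <= self.start:
            raise ConfigurationError(
                f"amplicon {self.amplicon_id}: empty interval [{self.start}, {self.end})"
            )
        if self.callable_end <= self.callable_start:
            raise ConfigurationError(
                f"amplicon {self.amplicon_id}: primers leave no callable sequence"
            )
        if self.sequence and len(self.sequence) != self.end - self.start:
            raise ConfigurationError(
                f"amplicon {self.amplicon_id}: sequence length != interval length"
            )

    @property
    def callable_start(self) -> int:
        return self.start + self.fwd_primer_len

    @property
    def callable_end(self) -> int:
        return self.end - self.rev_primer_len

    @property
    def callable_positions(self) -> np.ndarray:
        return np.arange(self.callable_start, self.callable_end)

    def covers(self, chrom: str, pos: int) -> bool:
        """True iff ``pos`` lies in this amplicon's callable interval."""
        return chrom == self.chrom and self.callable_start <= pos < self.callable_end

    def ref_base(self, pos: int) -> str:
        if not self.start <= pos < self.end:
            raise InputError(
                f"position {pos} outside amplicon {self.amplicon_id} "
                f"[{self.start}, {self.end})"
            )
        if not self.sequence:
            raise InputError(f"amplicon {self.amplicon_id} carries no sequence")
        return self.sequence[pos - self.start]


class AmpliconPanel:
    """An ordered collection of amplicons defining the callable space."""

    def __init__(self, amplicons: Sequence[Amplicon]):
        self.amplicons = list(amplicons)
        self._by_id = {a.amplicon_id: a for a in self.amplicons}
        if len(self._by_id) != len(self.amplicons):
            raise ConfigurationError("duplicate amplicon_id in panel")

    def __len__(self) -> int:
        return len(self.amplicons)

    def __iter__(self) -> Iterator[Amplicon]:
        return iter(self.amplicons)

    def __getitem__(self, amplicon_id: str) -> Amplicon:
        try:
            return self._by_id[amplicon_id]
        except KeyError:
            raise InputError(f"unknown amplicon_id {amplicon_id!r}") from None

    def __contains__(self, amplicon_id: str) -> bool:
        return amplicon_id in self._by_id

    def amplicons_covering(self, chrom: str, pos: int) -> list[Amplicon]:
        return [a for a in self.amplicons if a.covers(chrom, pos)]

    def overlapping_pairs(self) -> list[tuple[str, str]]:
        """Unordered pairs of amplicons whose genomic intervals overlap."""
        pairs = []
        by_chrom: dict[str, list[Amplicon]] = {}
        for a in self.amplicons:
            by_chrom.setdefault(a.chrom, []).append(a)
        for amps in by_chrom.values():
            amps = sorted(amps, key=lambda a: a.start)
            for i, a in enumerate(amps):
                for b in amps[i + 1:]:
                    if b.start >= a.end:
                        break
                    pairs.append((a.amplicon_id, b.amplicon_id))
        return pairs

    def callable_union(self, pathway: Optional[str] = None) -> int:
        """Unique callable base pairs, optionally restricted to one pathway."""
        intervals: dict[str, list[tuple[int, int]]] = {}
        for a in self.amplicons:
            if pathway is not None and a.pathway != pathway:
                continue
            intervals.setdefault(a.chrom, []).append(
                (a.callable_start, a.callable_end)
            )
        total = 0
        for ivs in intervals.values():
            ivs.sort()
            cur_s, cur_e = ivs[0]
            for s, e in ivs[1:]:
                if s > cur_e:
                    total += cur_e - cur_s
                    cur_s, cur_e = s, e
                else:
                    cur_e = max(cur_e, e)
            total += cur_e - cur_s
        return total

    def pathway_share(self, pathway: str = "RAS_MAPK") -> float:
        return self.callable_union(pathway) / self.callable_union()

    def ref_base(self, chrom: str, pos: int) -> str:
        for a in self.amplicons:
            if a.chrom == chrom and a.start <= pos < a.end and a.sequence:
                return a.ref_base(pos)
        raise InputError(f"no amplicon sequence covers {chrom}:{pos}")


@dataclass(frozen=True)
class SampleMeta:
    """One sequenced library with its batch covariates and biopsy of origin."""

    sample_id: str
    biopsy_id: str
    testis_id: str
    slice_id: str
    slice_position: int
    flow_cell: str
    lane: str
    mean_base_quality: float
    replicate_of: Optional[str] = None


class SampleSheet:
    def __init__(self, samples: Sequence[SampleMeta]):
        self.samples = list(samples)
        self._by_id = {s.sample_id: s for s in self.samples}
        if len(self._by_id) != len(self.samples):
            raise ConfigurationError("duplicate sample_id in sample sheet")

    def __len__(self) -> int:
        return len(self.samples)

    def __iter__(self) -> Iterator[SampleMeta]:
        return iter(self.samples)

    def __getitem__(self, sample_id: str) -> SampleMeta:
        try:
            return self._by_id[sample_id]
        except KeyError:
            raise InputError(f"unknown sample_id {sample_id!r}") from None

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    def to_df(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "sample_id": s.sample_id,
                    "biopsy_id": s.biopsy_id,
                    "testis_id": s.testis_id,
                    "slice_id": s.slice_id,
                    "slice_position": s.slice_position,
                    "flow_cell": s.flow_cell,
                    "lane": s.lane,
                    "mean_base_quality": s.mean_base_quality,
                    "replicate_of": s.replicate_of if s.replicate_of else "",
                }
                for s in self.samples
            ]
        )

    def replicate_pairs(self) -> list[tuple[str, str]]:
        """(primary, replicate) sample-id pairs sharing a biopsy."""
        pairs = []
        for s in self.samples:
            if s.replicate_of:
                primary = self._by_id.get(s.replicate_of)
                if primary is None or primary.biopsy_id != s.biopsy_id:
                    raise InputError(
                        f"replicate {s.sample_id} does not share a biopsy "
                        f"with {s.replicate_of}"
                    )
                pairs.append((s.replicate_of, s.sample_id))
        return pairs

    def samples_of_biopsy(self, biopsy_id: str) -> list[str]:
        return [s.sample_id for s in self.samples if s.biopsy_id == biopsy_id]


class BiopsyMap:
    """Undirected adjacency over biopsies: ring neighbours within a slice plus
    facing segments of adjacent slices of the same testis."""

    def __init__(self, graph: nx.Graph):
        self.graph = graph

    @classmethod
    def from_tables(
        cls, nodes: pd.DataFrame, edges: pd.DataFrame
    ) -> "BiopsyMap":
        g = nx.Graph()
        for row in nodes.itertuples(index=False):
            g.add_node(
                row.biopsy_id,
                testis_id=row.testis_id,
                slice_id=row.slice_id,
                slice_position=int(row.slice_position),
            )
        for row in edges.itertuples(index=False):
            g.add_edge(row.biopsy_a, row.biopsy_b)
        return cls(g)

    @property
    def biopsy_ids(self) -> list[str]:
        return list(self.graph.nodes)

    def testis_of(self, biopsy_id: str) -> str:
        self._check(biopsy_id)
        return self.graph.nodes[biopsy_id]["testis_id"]

    def slice_of(self, biopsy_id: str) -> str:
        self._check(biopsy_id)
        return self.graph.nodes[biopsy_id]["slice_id"]

    def _check(self, biopsy_id: str) -> None:
        if biopsy_id not in self.graph:
            raise InputError(f"biopsy {biopsy_id!r} missing from biopsy map")

    def components(self, biopsies: Iterable[str]) -> list[set[str]]:
        """Connected components of the subgraph induced by ``biopsies``."""
        biopsies = list(biopsies)
        for b in biopsies:
            self._check(b)
        sub = self.graph.subgraph(biopsies)
        return [set(c) for c in nx.connected_components(sub)]

    def is_connected(self, biopsies: Iterable[str]) -> bool:
        return len(self.components(biopsies)) <= 1

    def nodes_df(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "biopsy_id": b,
                    "testis_id": d["testis_id"],
                    "slice_id": d["slice_id"],
                    "slice_position": d["slice_position"],
                }
                for b, d in self.graph.nodes(data=True)
            ]
        )

    def edges_df(self) -> pd.DataFrame:
        return pd.DataFrame(
            sorted((min(u, v), max(u, v)) for u, v in self.graph.edges),
            columns=["biopsy_a", "biopsy_b"],
        )


@dataclass(frozen=True)
class CloneSpec:
    """A spiked mutational event with its spatial footprint.

    ``variants`` holds one substitution, or two adjacent ones for a tandem
    (dinucleotide) event that shares per-biopsy VAFs exactly.
    """

    clone_id: str
    variants: tuple[Variant, ...]
    testis_id: str
    path: tuple[str, ...]
    vaf_by_biopsy: Mapping[str, float]
    kind: str  # CLONAL | POSTZYGOTIC

    def __post_init__(self) -> None:
        if self.kind not in ("CLONAL", "POSTZYGOTIC"):
            raise ConfigurationError(f"unknown clone kind {self.kind!r}")
        if not self.path:
            raise ConfigurationError("clone with empty biopsy path")
        for v in self.vaf_by_biopsy.values():
            if not 0.0 < v < 0.03:
                raise ConfigurationError(
                    f"clone {self.clone_id}: VAF {v} outside (0, 0.03)"
                )

    @property
    def is_tandem(self) -> bool:
        return len(self.variants) == 2


class GroundTruth:
    """Exhaustive record of spiked signal: every nonzero (biopsy, variant) VAF."""

    def __init__(self, clones: Sequence[CloneSpec]):
        self.clones = list(clones)
        self._vaf: dict[tuple[str, Variant], float] = {}
        for c in self.clones:
            for v in c.variants:
                for b, vaf in c.vaf_by_biopsy.items():
                    key = (b, v)
                    if key in self._vaf:
                        raise ConfigurationError(
                            f"two clones spike {variant_id(v)} in biopsy {b}"
                        )
                    self._vaf[key] = vaf

    def __len__(self) -> int:
        return len(self.clones)

    def variants(self) -> list[Variant]:
        seen: dict[Variant, None] = {}
        for c in self.clones:
            for v in c.variants:
                seen.setdefault(v, None)
        return list(seen)

    def vaf_for(self, biopsy_id: str, variant: Variant) -> float:
        return self._vaf.get((biopsy_id, variant), 0.0)

    def to_df(self) -> pd.DataFrame:
        rows = []
        for c in self.clones:
            for v in c.variants:
                for b in c.path:
                    if b not in c.vaf_by_biopsy:
                        continue
                    rows.append(
                        {
                            "clone_id": c.clone_id,
                            "kind": c.kind,
                            "testis_id": c.testis_id,
                            "biopsy_id": b,
                            "chrom": v[0],
                            "pos": v[1],
                            "ref": v[2],
                            "alt": v[3],
                            "vaf": c.vaf_by_biopsy[b],
                        }
                    )
        return pd.DataFrame(
            rows,
            columns=[
                "clone_id", "kind", "testis_id", "biopsy_id",
                "chrom", "pos", "ref", "alt", "vaf",
            ],
        )

    @classmethod
    def from_df(cls, df: pd.DataFrame) -> "GroundTruth":
        clones = []
        for clone_id, grp in df.groupby("clone_id", sort=False):
            variants = tuple(
                sorted(
                    {
                        (r.chrom, int(r.pos), r.ref, r.alt)
                        for r in grp.itertuples(index=False)
                    },
                    key=lambda v: (v[0], v[1]),
                )
            )
            vafs = {}
            path = []
            for r in grp.itertuples(index=False):
                if r.biopsy_id not in vafs:
                    path.append(r.biopsy_id)
                vafs[r.biopsy_id] = float(r.vaf)
            clones.append(
                CloneSpec(
                    clone_id=str(clone_id),
                    variants=variants,
                    testis_id=grp["testis_id"].iloc[0],
                    path=tuple(path),
                    vaf_by_biopsy=vafs,
                    kind=grp["kind"].iloc[0],
                )
            )
        return cls(clones)


PILEUP_COLUMNS = [
    "sample_id", "amplicon_id", "chrom", "pos", "ref",
    "A", "C", "G", "T", "mean_bq",
]


class PileupMatrix:
    """Long-format per-(sample, amplicon, position) nucleotide counts.

    The wrapped frame has one row per (sample_id, amplicon_id, pos) with
    integer columns A/C/G/T and the per-position mean base quality used as a
    normalization covariate downstream.
    """

    def __init__(self, df: pd.DataFrame):
        missing = [c for c in PILEUP_COLUMNS if c not in df.columns]
        if missing:
            raise SchemaError(f"pileup frame missing columns {missing}")
        df = df[PILEUP_COLUMNS].copy()
        for c in ALLELES:
            df[c] = df[c].astype(np.int64)
            if (df[c] < 0).any():
                raise SchemaError(f"negative counts in allele column {c}")
        df["pos"] = df["pos"].astype(np.int64)
        self.df = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def depth(self) -> pd.Series:
        return self.df[list(ALLELES)].sum(axis=1)

    @property
    def sample_ids(self) -> list[str]:
        return list(pd.unique(self.df["sample_id"]))

    @property
    def amplicon_ids(self) -> list[str]:
        return list(pd.unique(self.df["amplicon_id"]))

    def for_amplicon(self, amplicon_id: str) -> pd.DataFrame:
        return self.df[self.df["amplicon_id"] == amplicon_id]

    def equals(self, other: "PileupMatrix") -> bool:
        a = self.df.sort_values(["sample_id", "amplicon_id", "pos"]).reset_index(drop=True)
        b = other.df.sort_values(["sample_id", "amplicon_id", "pos"]).reset_index(drop=True)
        if len(a) != len(b):
            return False
        num_ok = np.allclose(a["mean_bq"], b["mean_bq"], atol=1e-9)
        rest = [c for c in PILEUP_COLUMNS if c != "mean_bq"]
        return num_ok and a[rest].equals(b[rest])
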