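"""Spatial clonal-event analysis over the biopsy adjacency graph.

Groups each candidate variant's positive biopsies into connected components
per testis, counts independent mutational events with the conservative
one-event-per-(variant, testis) convention, and flags broad scattered
patterns consistent with an early post-zygotic origin rather than a clonal
expansion along a single tubule.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Union

import pandas as pd

from .config import PostzygoticConfig
from .types import BiopsyMap, InputError, SampleSheet


@dataclass(frozen=True)
class ClonalEvent:
    """One connected component of a variant's positive biopsies in one testis."""

    variant_id: str
    testis_id: str
    component_index: int
    members: tuple[str, ...]
    span_slices: int
    n_components: int  # upper bound on events for this (variant, testis)
    lower_bound: int = 1  # the conservative per-(variant, testis) count


def count_independent_events(
    occurrences: Union[pd.DataFrame, Iterable[tuple[str, str]]],
) -> int:
    """Sum over variants of the number of distinct testes carrying them.

    ``occurrences`` is any iterable (or frame with columns ``variant_id``,
    ``testis_id``) of per-observation (variant, testis) pairs; duplicates
    collapse. This is the minimum-event convention: a variant seen in k
    testes counts as k independent mutational events.
    """
    if isinstance(occurrences, pd.DataFrame):
        pairs = set(
            zip(occurrences["variant_id"], occurrences["testis_id"])
        )
    else:
        pairs = set((str(v), str(t)) for v, t in occurrences)
    return len(pairs)


def occurrences_from_candidates(
    candidate_samples: pd.DataFrame, sheet: SampleSheet
) -> pd.DataFrame:
    """(variant, testis) incidence pairs from the per-sample candidate table."""
    df = candidate_samples.copy()
    if "testis_id" not in df.columns:
        meta = {s.sample_id: s.testis_id for s in sheet}
        df["testis_id"] = df["sample_id"].map(meta)
    return df[["variant_id", "testis_id"]].drop_duplicates().reset_index(drop=True)


def build_events(
    variant_id: str,
    biopsies: Iterable[str],
    bmap: BiopsyMap,
) -> list[ClonalEvent]:
    """Connected components of a variant's positive biopsies, per testis.

    The component count is an upper bound on the number of mutational events;
    the experiment's resolving power cannot exclude a single tubule linking
    distant components, hence ``lower_bound`` stays 1 per testis.
    """
    biopsies = list(dict.fromkeys(biopsies))
    if not biopsies:
        raise InputError(f"variant {variant_id}: no positive biopsies")
    per_testis: dict[str, list[str]] = {}
    for b in biopsies:
        per_testis.setdefault(bmap.testis_of(b), []).append(b)

    events: list[ClonalEvent] = []
    for testis, members in sorted(per_testis.items()):
        comps = sorted(bmap.components(members), key=lambda c: sorted(c)[0])
        for i, comp in enumerate(comps):
            events.append(
                ClonalEvent(
                    variant_id=variant_id,
                    testis_id=testis,
                    component_index=i,
                    members=tuple(sorted(comp)),
                    span_slices=len({bmap.slice_of(b) for b in comp}),
                    n_components=len(comps),
                )
            )
    return events


def flag_postzygotic(
    biopsies: Iterable[str],
    bmap: BiopsyMap,
    cfg: Optional[PostzygoticConfig] = None,
) -> bool:
    """True iff the occurrence pattern looks early post-zygotic.

    A broadly scattered variant — spanning at least ``min_slices`` slices,
    split into at least ``min_components`` disconnected pieces, across at
    least ``min_biopsies`` biopsies — is incompatible with an expansion
    confined to one seminiferous tubule.
    """
    cfg = cfg or PostzygoticConfig()
    biopsies = list(dict.fromkeys(biopsies))
    if not biopsies:
        return False
    slices = {bmap.slice_of(b) for b in biopsies}
    comps = bmap.components(biopsies)
    return (
        len(slices) >= cfg.min_slices
        and len(comps) >= cfg.min_components
        and len(biopsies) >= cfg.min_biopsies
    )


def events_table(
    candidate_samples: pd.DataFrame,
    bmap: BiopsyMap,
    cfg: Optional[PostzygoticConfig] = None,
) -> pd.DataFrame:
    """Per-(variant, testis, component) event table with post-zygotic flags."""
    cfg = cfg or PostzygoticConfig()
    rows = []
    for vid, grp in candidate_samples.groupby("variant_id", sort=False):
        biopsies = list(dict.fromkeys(grp["biopsy_id"]))
        per_testis: dict[str, list[str]] = {}
        for b in biopsies:
            per_testis.setdefault(bmap.testis_of(b), []).append(b)
        for ev in build_events(vid, biopsies, bmap):
            rows.append(
                {
                    "variant_id": ev.variant_id,
                    "testis_id": ev.testis_id,
                    "component_index": ev.component_index,
                    "members": ";".join(ev.members),
                    "span_slices": ev.span_slices,
                    "n_components": ev.n_components,
                    "postzygotic_flag": flag_postzygotic(
                        per_testis[ev.testis_id], bmap, cfg
                    ),
                }
            )
    return pd.DataFrame(
        rows,
        columns=["variant_id", "testis_id", "component_index", "members",
                 "span_slices", "n_components", "postzygotic_flag"],
    )


def plot_slice_map(
    candidate_samples: pd.DataFrame,
    bmap: BiopsyMap,
    testis_id: str,
    path: str,
) -> None:
    """Ring diagram of one testis' slices with VAF-scaled variant markers."""
    import math

    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    g = bmap.graph
    slices: dict[str, list[str]] = {}
    for b, d in g.nodes(data=True):
        if d["testis_id"] == testis_id:
            slices.setdefault(d["slice_id"], []).append(b)
    slice_ids = sorted(slices)
    fig, axes = plt.subplots(
        1, max(1, len(slice_ids)), figsize=(3 * max(1, len(slice_ids)), 3.2)
    )
    if len(slice_ids) <= 1:
        axes = [axes]
    variant_ids = sorted(candidate_samples["variant_id"].unique())
    cmap = plt.get_cmap("tab20")
    coords = {}
    for ax, sid in zip(axes, slice_ids):
        members = sorted(slices[sid], key=lambda b: g.nodes[b]["slice_position"])
        n = len(members)
        for b in members:
            k = g.nodes[b]["slice_position"]
            ang = 2 * math.pi * k / max(n, 1)
            coords[b] = (math.cos(ang), math.sin(ang))
            ax.plot(*coords[b], "o", ms=14, mfc="white", mec="0.7")
        ax.set_title(sid, fontsize=9)
        ax.set_xlim(-1.5, 1.5)
        ax.set_ylim(-1.5, 1.5)
        ax.set_aspect("equal")
        ax.axis("off")
        for vi, vid in enumerate(variant_ids):
            pos = candidate_samples[
                (candidate_samples["variant_id"] == vid)
                & (candidate_samples["biopsy_id"].isin(members))
            ]
            for r in pos.itertuples(index=False):
                x, y = coords[r.biopsy_id]
                ax.plot(
                    x, y, "o",
                    ms=4 + 400 * float(r.vaf),
                    color=cmap(vi % 20), alpha=0.75,
                )
    fig.suptitle(f"Testis {testis_id}", fontsize=11)
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)
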