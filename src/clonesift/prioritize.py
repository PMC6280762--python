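"""Post-call filtering, the two-independent-calls rule, and tier assignment.

Raw outlier calls are filtered for artifact signatures (excess-call samples
and amplicons, primer-proximal positions, near-germline VAFs, low-coverage
positions), merged into cross-sample candidate variants, VAF-aggregated, and
assigned confidence tiers 1-4.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .config import FilterConfig
from .types import AmpliconPanel, PileupMatrix, SampleSheet, variant_id

logger = logging.getLogger(__name__)

CANDIDATE_COLUMNS = [
    "variant_id", "chrom", "pos", "ref", "alt", "is_tandem", "tier",
    "n_samples", "n_biopsies", "n_amplicons",
    "overlap_support", "replicate_support", "max_vaf",
]
CANDIDATE_SAMPLE_COLUMNS = [
    "variant_id", "sample_id", "biopsy_id", "testis_id", "vaf", "tier",
]


def _excess_threshold(counts: pd.Series, cfg: FilterConfig) -> float:
    """Scale-free outlier trim: Q3 + k*IQR, floored so sparse call sets
    (where the IQR degenerates to zero) never exclude everything."""
    if counts.empty:
        return float(cfg.excess_min_calls)
    q1, q3 = counts.quantile(0.25), counts.quantile(0.75)
    return max(q3 + cfg.excess_iqr_factor * (q3 - q1), float(cfg.excess_min_calls))


def filter_calls(
    calls: pd.DataFrame,
    pileup: PileupMatrix,
    panel: AmpliconPanel,
    cfg: Optional[FilterConfig] = None,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Apply the artifact filter cascade; returns (filtered calls, stage counts).

    Removes, in order: calls below the read floor; calls in samples or
    amplicons with an excessive call count; calls within
    ``primer_proximal_bp`` of a primer 3'-end; calls at positions whose
    median depth across samples is below ``min_median_depth``; and every call
    of any variant whose maximum VAF reaches ``max_vaf_cap`` (such variants
    read as constitutional, not mosaic, so the whole variant goes).
    """
    cfg = cfg or FilterConfig()
    stages = {"raw": len(calls)}
    out = calls.copy()

    out = out[out["alt_count"] >= cfg.min_alt_reads]
    stages["min_alt_reads"] = len(out)

    if not out.empty:
        per_sample = out.groupby("sample_id").size()
        bad_samples = set(
            per_sample[per_sample > _excess_threshold(per_sample, cfg)].index
        )
        per_amp = out.groupby("amplicon_id").size()
        bad_amps = set(per_amp[per_amp > _excess_threshold(per_amp, cfg)].index)
        if bad_samples or bad_amps:
            logger.info(
                "filter_calls: excess-call exclusion of %d samples, %d amplicons",
                len(bad_samples), len(bad_amps),
            )
        out = out[
            ~out["sample_id"].isin(bad_samples)
            & ~out["amplicon_id"].isin(bad_amps)
        ]
    stages["excess_calls"] = len(out)

    if not out.empty:
        keep = np.ones(len(out), dtype=bool)
        for i, r in enumerate(out.itertuples(index=False)):
            amp = panel[r.amplicon_id]
            keep[i] = (
                amp.callable_start + cfg.primer_proximal_bp
                <= r.pos
                < amp.callable_end - cfg.primer_proximal_bp
            )
        out = out[keep]
    stages["primer_proximal"] = len(out)

    if not out.empty:
        depth = pileup.df.assign(_depth=pileup.depth)
        med_depth = depth.groupby(["amplicon_id", "pos"])["_depth"].median()
        key = pd.MultiIndex.from_frame(out[["amplicon_id", "pos"]])
        out = out[med_depth.reindex(key).to_numpy() >= cfg.min_median_depth]
    stages["min_median_depth"] = len(out)

    if not out.empty:
        vkey = out["chrom"] + ":" + out["pos"].astype(str) + ":" + out["ref"] + ">" + out["alt"]
        max_vaf = out.groupby(vkey.values)["vaf"].transform("max")
        out = out[max_vaf < cfg.max_vaf_cap]
    stages["max_vaf_cap"] = len(out)

    return out.reset_index(drop=True), stages


def require_independent(calls: pd.DataFrame, sheet: SampleSheet) -> pd.DataFrame:
    """Keep only variants with two or more independent calls.

    Independence means calls in >= 2 samples, calls in >= 2 (overlapping)
    amplicons of one sample, or calls in both members of a replicate pair —
    the last is a special case of the first, kept explicit for tiering.
    """
    if calls.empty:
        return calls.copy()
    df = calls.copy()
    df["variant_id"] = [
        variant_id((r.chrom, r.pos, r.ref, r.alt))
        for r in df.itertuples(index=False)
    ]
    keep_ids = []
    for vid, grp in df.groupby("variant_id", sort=False):
        n_samples = grp["sample_id"].nunique()
        overlap = (grp.groupby("sample_id")["amplicon_id"].nunique() >= 2).any()
        if n_samples >= 2 or overlap:
            keep_ids.append(vid)
    return df[df["variant_id"].isin(keep_ids)].reset_index(drop=True)


def aggregate_vaf(calls: pd.DataFrame) -> pd.DataFrame:
    """Per-sample mean VAF over the amplicons calling a variant."""
    return (
        calls.groupby(["variant_id", "sample_id"], sort=False)
        .agg(vaf=("vaf", "mean"), n_amplicons=("amplicon_id", "nunique"))
        .reset_index()
    )


def assign_tier(
    overlap_support: bool,
    replicate_support: bool,
    max_vaf: float,
    cfg: Optional[FilterConfig] = None,
) -> int:
    """Confidence tier: 1 = multiply-supported; 2/3/4 by descending max VAF.

    The 0.2% boundary belongs to Tier 2 and the 0.1% boundary to Tier 3.
    """
    cfg = cfg or FilterConfig()
    if overlap_support or replicate_support:
        return 1
    if max_vaf >= cfg.tier2_min_vaf:
        return 2
    if max_vaf >= cfg.tier3_min_vaf:
        return 3
    return 4


@dataclass
class PrioritizeResult:
    candidates: pd.DataFrame  # one row per candidate variant
    candidate_samples: pd.DataFrame  # one row per (candidate, sample)
    stage_counts: dict[str, int]


def _build_candidates(
    calls: pd.DataFrame, sheet: SampleSheet, cfg: FilterConfig
) -> tuple[pd.DataFrame, pd.DataFrame]:
    per_sample = aggregate_vaf(calls)
    meta = {s.sample_id: s for s in sheet}
    per_sample["biopsy_id"] = per_sample["sample_id"].map(
        lambda s: meta[s].biopsy_id
    )
    per_sample["testis_id"] = per_sample["sample_id"].map(
        lambda s: meta[s].testis_id
    )

    cand_rows = []
    for vid, grp in calls.groupby("variant_id", sort=False):
        ps = per_sample[per_sample["variant_id"] == vid]
        biopsy_vaf = ps.groupby("biopsy_id")["vaf"].mean()
        overlap = (grp.groupby("sample_id")["amplicon_id"].nunique() >= 2).any()
        replicate = (ps.groupby("biopsy_id")["sample_id"].nunique() >= 2).any()
        first = grp.iloc[0]
        cand_rows.append(
            {
                "variant_id": vid,
                "chrom": first["chrom"],
                "pos": int(first["pos"]),
                "ref": first["ref"],
                "alt": first["alt"],
                "is_tandem": False,
                "n_samples": grp["sample_id"].nunique(),
                "n_biopsies": int(biopsy_vaf.size),
                "n_amplicons": grp["amplicon_id"].nunique(),
                "overlap_support": bool(overlap),
                "replicate_support": bool(replicate),
                "max_vaf": float(biopsy_vaf.max()),
            }
        )
    candidates = pd.DataFrame(cand_rows)
    return candidates, per_sample


def merge_tandem(
    candidates: pd.DataFrame,
    candidate_samples: pd.DataFrame,
    cfg: Optional[FilterConfig] = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Merge adjacent candidates with correlated per-sample VAFs into one
    dinucleotide (tandem) candidate.

    Two candidates at (pos, pos+1) sharing >= 2 called samples whose VAFs
    correlate above ``tandem_r_threshold`` are treated as a single mutational
    event; the merged per-sample VAF is the mean of the two components.
    """
    cfg = cfg or FilterConfig()
    if candidates.empty:
        return candidates.copy(), candidate_samples.copy()
    cands = candidates.sort_values(["chrom", "pos"]).reset_index(drop=True)
    by_pos = {(r.chrom, r.pos): i for i, r in enumerate(cands.itertuples(index=False))}
    merged_away: set[str] = set()
    merges: list[tuple[str, str]] = []
    for i, r in enumerate(cands.itertuples(index=False)):
        j = by_pos.get((r.chrom, r.pos + 1))
        if j is None or r.variant_id in merged_away:
            continue
        other = cands.iloc[j]
        if other["variant_id"] in merged_away:
            continue
        a = candidate_samples[candidate_samples["variant_id"] == r.variant_id]
        b = candidate_samples[candidate_samples["variant_id"] == other["variant_id"]]
        shared = a.merge(b, on="sample_id", suffixes=("_a", "_b"))
        if len(shared) < 2:
            continue
        va, vb = shared["vaf_a"].to_numpy(), shared["vaf_b"].to_numpy()
        if np.std(va) == 0 or np.std(vb) == 0:
            corr = 1.0 if len(shared) >= 2 else 0.0
        else:
            corr = float(np.corrcoef(va, vb)[0, 1])
        if corr > cfg.tandem_r_threshold:
            merges.append((r.variant_id, other["variant_id"]))
            merged_away.update([r.variant_id, other["variant_id"]])

    if not merges:
        return cands, candidate_samples.copy()

    cs = candidate_samples.copy()
    rows = cands.set_index("variant_id", drop=False)
    new_rows, new_cs = [], []
    for vid_a, vid_b in merges:
        a, b = rows.loc[vid_a], rows.loc[vid_b]
        tandem_vid = f"{a['chrom']}:{a['pos']}:{a['ref']}{b['ref']}>{a['alt']}{b['alt']}"
        sa = cs[cs["variant_id"] == vid_a]
        sb = cs[cs["variant_id"] == vid_b]
        both = pd.concat([sa, sb])
        agg = (
            both.groupby(["sample_id", "biopsy_id", "testis_id"], sort=False)["vaf"]
            .mean()
            .reset_index()
        )
        agg.insert(0, "variant_id", tandem_vid)
        new_cs.append(agg)
        biopsy_vaf = agg.groupby("biopsy_id")["vaf"].mean()
        new_rows.append(
            {
                "variant_id": tandem_vid,
                "chrom": a["chrom"],
                "pos": int(a["pos"]),
                "ref": a["ref"] + b["ref"],
                "alt": a["alt"] + b["alt"],
                "is_tandem": True,
                "n_samples": agg["sample_id"].nunique(),
                "n_biopsies": int(biopsy_vaf.size),
                "n_amplicons": max(int(a["n_amplicons"]), int(b["n_amplicons"])),
                "overlap_support": bool(a["overlap_support"] or b["overlap_support"]),
                "replicate_support": bool(a["replicate_support"] or b["replicate_support"]),
                "max_vaf": float(biopsy_vaf.max()),
            }
        )
    keep = ~cands["variant_id"].isin(merged_away)
    cands_out = pd.concat(
        [cands[keep], pd.DataFrame(new_rows)], ignore_index=True
    ).sort_values(["chrom", "pos"]).reset_index(drop=True)
    cs_out = pd.concat(
        [cs[~cs["variant_id"].isin(merged_away)]] + new_cs, ignore_index=True
    )
    return cands_out, cs_out


def prioritize(
    calls: pd.DataFrame,
    pileup: PileupMatrix,
    panel: AmpliconPanel,
    sheet: SampleSheet,
    cfg: Optional[FilterConfig] = None,
) -> PrioritizeResult:
    """Full cascade: filter -> independence -> aggregate -> tandem merge -> tier."""
    cfg = cfg or FilterConfig()
    filtered, stages = filter_calls(calls, pileup, panel, cfg)
    independent = require_independent(filtered, sheet)
    stages["independent_calls"] = len(independent)

    if independent.empty:
        candidates = pd.DataFrame(columns=CANDIDATE_COLUMNS)
        cs = pd.DataFrame(columns=CANDIDATE_SAMPLE_COLUMNS)
        stages["candidates"] = 0
        return PrioritizeResult(candidates, cs, stages)

    candidates, candidate_samples = _build_candidates(independent, sheet, cfg)
    candidates, candidate_samples = merge_tandem(candidates, candidate_samples, cfg)
    candidates["tier"] = [
        assign_tier(r.overlap_support, r.replicate_support, r.max_vaf, cfg)
        for r in candidates.itertuples(index=False)
    ]
    candidates = candidates[CANDIDATE_COLUMNS]
    candidate_samples = candidate_samples.merge(
        candidates[["variant_id", "tier"]], on="variant_id"
    )[CANDIDATE_SAMPLE_COLUMNS]
    stages["candidates"] = len(candidates)
    return PrioritizeResult(candidates, candidate_samples, stages)


def count_validated(tier_stats: list[dict]) -> int:
    """Distinct validated variants from per-tier screening tallies.

    Each entry carries ``candidates``, ``rescreened``, ``validated`` and
    ``assume_unrescreened_true``. Tiers whose unrescreened candidates are
    trusted contribute ``candidates - (rescreened - validated)``; otherwise
    only the directly validated count is credited.
    """
    total = 0
    for t in tier_stats:
        failed = int(t["rescreened"]) - int(t["validated"])
        if failed < 0 or int(t["validated"]) > int(t["rescreened"]):
            raise ValueError("validated count exceeds rescreened count")
        if t.get("assume_unrescreened_true", False):
            total += int(t["candidates"]) - failed
        else:
            total += int(t["validated"])
    return total
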