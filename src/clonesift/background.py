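"""Background error modeling and per-sample outlier calling.

At every (amplicon, position, alt allele) the vector of per-sample allele
fractions is transformed to ``logit((alt + 0.5) / (depth + 1))``, adjusted
for batch covariates with a linear model (lane dummies — lanes are labeled
globally and nested in flow cells, so they absorb the flow-cell effect — plus
per-position mean base quality), and the per-lane median of the residuals is
removed. Outliers are then scored one-sided against the remaining samples,
either by a leave-one-out robust z (normal tail) or by the exact upper tail
of a beta-binomial null fitted to the other samples' counts.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import betaln, gammaln, logsumexp

from .config import CallConfig
from .types import ALLELES, AmpliconPanel, PileupMatrix, SampleSheet, SchemaError
from .util import count_logit

logger = logging.getLogger(__name__)

LN10 = math.log(10.0)


# ---------------------------------------------------------------------------
# per-amplicon array assembly


@dataclass
class AlleleFractionMatrix:
    """Sample-by-(position, alt) arrays for one amplicon.

    Columns enumerate (position, alt allele) pairs; ``t`` is the transformed
    fraction, defined only where depth > 0 (NaN elsewhere).
    """

    amplicon_id: str
    chrom: str
    sample_ids: list[str]
    lanes: np.ndarray  # (n,) lane label per sample
    positions: np.ndarray  # (P,) genomic position per column
    alts: np.ndarray  # (P,) alt allele per column
    refs: np.ndarray  # (P,) reference allele per column
    counts: np.ndarray  # (n, P) alt counts
    depth: np.ndarray  # (n, P)
    bq: np.ndarray  # (n, P) mean base quality covariate
    t: np.ndarray  # (n, P) transformed fraction


def allele_fraction_matrix(
    amplicon_df: pd.DataFrame, sheet: SampleSheet
) -> AlleleFractionMatrix:
    """Pivot one amplicon's long pileup rows into dense arrays."""
    if amplicon_df.empty:
        raise SchemaError("empty amplicon pileup")
    amplicon_id = amplicon_df["amplicon_id"].iloc[0]
    chrom = amplicon_df["chrom"].iloc[0]
    present = set(amplicon_df["sample_id"])
    sample_ids = [s for s in sheet.sample_ids if s in present]
    positions = np.sort(amplicon_df["pos"].unique())
    n, L = len(sample_ids), len(positions)

    s_idx = {s: i for i, s in enumerate(sample_ids)}
    p_idx = {p: j for j, p in enumerate(positions)}
    si = amplicon_df["sample_id"].map(s_idx).to_numpy()
    pi = amplicon_df["pos"].map(p_idx).to_numpy()

    counts4 = np.zeros((n, L, 4), dtype=np.int64)
    counts4[si, pi, :] = amplicon_df[list(ALLELES)].to_numpy()
    bq_pos = np.zeros((n, L))
    bq_pos[si, pi] = amplicon_df["mean_bq"].to_numpy()

    refs_by_pos = np.empty(L, dtype="<U1")
    refs_by_pos[pi] = amplicon_df["ref"].to_numpy()

    depth_pos = counts4.sum(axis=2)

    # columns: the three non-reference alleles at each position
    cols_pos, cols_alt = [], []
    for j in range(L):
        for a in ALLELES:
            if a != refs_by_pos[j]:
                cols_pos.append(j)
                cols_alt.append(a)
    cols_pos = np.array(cols_pos)
    alt_idx = np.array([ALLELES.index(a) for a in cols_alt])

    counts = counts4[:, cols_pos, alt_idx]
    depth = depth_pos[:, cols_pos]
    bq = bq_pos[:, cols_pos]
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(depth > 0, count_logit(counts, depth), np.nan)

    lanes = np.array([sheet[s].lane for s in sample_ids])
    return AlleleFractionMatrix(
        amplicon_id=amplicon_id,
        chrom=chrom,
        sample_ids=sample_ids,
        lanes=lanes,
        positions=positions[cols_pos],
        alts=np.array(cols_alt),
        refs=refs_by_pos[cols_pos],
        counts=counts,
        depth=depth,
        bq=bq,
        t=t,
    )


# ---------------------------------------------------------------------------
# normalization


@dataclass
class NormalizationResult:
    residuals: np.ndarray  # (n, P); NaN where depth == 0
    lane_levels: list[str]  # first level is the dummy-coding baseline
    lane_coefs: np.ndarray  # (n_levels, P); baseline row is zero
    bq_slope: np.ndarray  # (P,)


def normalize(
    t: np.ndarray,
    lanes: np.ndarray,
    bq: Optional[np.ndarray] = None,
) -> NormalizationResult:
    """Remove batch structure from transformed fractions.

    Fits ``t ~ intercept + lane + bq`` per column (Frisch–Waugh: the
    categorical projection is shared across columns, the base-quality slope
    is column-specific), then subtracts the per-lane median of the residuals.
    A single-lane design degrades to intercept + bq with a logged warning.
    """
    t = np.asarray(t, dtype=float)
    n, P = t.shape
    lane_levels = sorted(set(lanes))
    if len(lane_levels) == 1:
        logger.warning("normalize: single lane — dropping lane covariate")

    X1 = np.ones((n, 1 + max(0, len(lane_levels) - 1)))
    for k, lv in enumerate(lane_levels[1:]):
        X1[:, 1 + k] = (lanes == lv).astype(float)

    valid = ~np.isnan(t)
    if valid.all():
        resid, coefs, slope = _normalize_block(t, X1, bq)
    else:
        resid = np.full_like(t, np.nan)
        coefs = np.zeros((X1.shape[1], P))
        slope = np.zeros(P)
        for j in range(P):
            rows = valid[:, j]
            if rows.sum() < 2:
                continue
            bq_j = bq[rows, j:j + 1] if bq is not None else None
            r, c, s = _normalize_block(t[rows, j:j + 1], X1[rows], bq_j)
            resid[rows, j] = r[:, 0]
            coefs[:, j] = c[:, 0]
            slope[j] = s[0]

    # per-lane median removal
    for lv in lane_levels:
        rows = lanes == lv
        med = np.nanmedian(np.where(valid[rows], resid[rows], np.nan), axis=0)
        resid[rows] -= np.where(np.isnan(med), 0.0, med)
    resid[~valid] = np.nan

    full_coefs = np.zeros((len(lane_levels), P))
    full_coefs[1:, :] = coefs[1:, :] if coefs.shape[0] > 1 else 0.0
    return NormalizationResult(
        residuals=resid,
        lane_levels=lane_levels,
        lane_coefs=full_coefs,
        bq_slope=slope,
    )


def _normalize_block(t, X1, bq):
    """OLS residuals + coefficients for fully-observed columns."""
    pinv1 = np.linalg.pinv(X1)
    H = X1 @ pinv1
    t_res = t - H @ t
    if bq is not None:
        b_res = bq - H @ bq
        denom = (b_res ** 2).sum(axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            slope = np.where(denom > 1e-12, (b_res * t_res).sum(axis=0) / denom, 0.0)
        resid = t_res - b_res * slope
        coefs = pinv1 @ (t - bq * slope)
    else:
        slope = np.zeros(t.shape[1])
        resid = t_res
        coefs = pinv1 @ t
    return resid, coefs, slope


@dataclass
class BackgroundFit:
    """Per-amplicon normalization results with information weights."""

    lane_levels: list[str]
    results: dict[str, NormalizationResult] = field(default_factory=dict)
    weights: dict[str, np.ndarray] = field(default_factory=dict)

    def lane_effect(self, lane: str, ref_lane: Optional[str] = None) -> float:
        """Recover a lane's batch effect relative to a reference lane.

        Count-weighted (w = mean alt count squared) average of the fitted
        per-column lane contrasts: low-count columns attenuate the logit-scale
        coefficient, so the weighting leans on the well-measured columns.
        """
        if ref_lane is None:
            ref_lane = self.lane_levels[0]
        li = self.lane_levels.index(lane)
        ri = self.lane_levels.index(ref_lane)
        num = den = 0.0
        for amp, res in self.results.items():
            w = self.weights[amp] ** 2
            contrast = res.lane_coefs[li] - res.lane_coefs[ri]
            num += float((w * contrast).sum())
            den += float(w.sum())
        return num / den if den > 0 else 0.0


def fit_background(
    pileup: PileupMatrix, sheet: SampleSheet, config: Optional[CallConfig] = None
) -> BackgroundFit:
    """Normalize every amplicon and keep the fitted covariate structure."""
    config = config or CallConfig()
    lane_levels: list[str] = sorted({s.lane for s in sheet})
    fit = BackgroundFit(lane_levels=lane_levels)
    for amp_id in pileup.amplicon_ids:
        afm = allele_fraction_matrix(pileup.for_amplicon(amp_id), sheet)
        if len(afm.sample_ids) < config.min_samples:
            continue
        res = normalize(afm.t, afm.lanes, afm.bq)
        if res.lane_levels != lane_levels:
            # amplicon missing some lanes entirely; align coefficient rows
            aligned = np.zeros((len(lane_levels), res.lane_coefs.shape[1]))
            for i, lv in enumerate(res.lane_levels):
                aligned[lane_levels.index(lv)] = res.lane_coefs[i]
            res.lane_coefs = aligned
            res.lane_levels = lane_levels
        fit.results[amp_id] = res
        fit.weights[amp_id] = afm.counts.mean(axis=0)
    return fit


# ---------------------------------------------------------------------------
# beta-binomial null


def betabinom_logpmf(x, n, a, b):
    """Log pmf of BetaBinomial(n, a, b) from log-gamma identities."""
    x = np.asarray(x, dtype=float)
    n = np.asarray(n, dtype=float)
    return (
        gammaln(n + 1) - gammaln(x + 1) - gammaln(n - x + 1)
        + betaln(x + a, n - x + b) - betaln(a, b)
    )


def _betabinom_log_tail(k, n, a, b) -> np.ndarray:
    """log P(X >= k) for BetaBinomial(n, a, b), summed in log space.

    Accumulates from ``k`` upward until the terms fall 45 nats below the
    running sum, so the result is accurate arbitrarily deep in the tail.
    (The library survival function loses all precision out there, and the
    calling cutoff of 1e-20 lives exactly there.)
    """
    k, n, a, b = np.broadcast_arrays(
        *(np.asarray(v, dtype=float) for v in (k, n, a, b))
    )
    shape = k.shape
    k, n, a, b = (v.ravel().copy() for v in (k, n, a, b))
    out_log = np.full(k.shape, -np.inf)
    out_log[k <= 0] = 0.0  # whole support
    active = np.nonzero((k > 0) & (k <= n))[0]
    x0 = k.copy()
    chunk = 256
    offsets = np.arange(chunk)
    while active.size:
        X = x0[active, None] + offsets[None, :]
        in_support = X <= n[active, None]
        lp = betabinom_logpmf(
            np.where(in_support, X, 0.0), n[active, None],
            a[active, None], b[active, None],
        )
        lp = np.where(in_support, lp, -np.inf)
        out_log[active] = np.logaddexp(out_log[active], logsumexp(lp, axis=1))
        tail_term = lp[:, -1]
        exhausted = x0[active] + chunk > n[active]
        converged = exhausted | (tail_term < out_log[active] - 45.0)
        x0[active] += chunk
        active = active[~converged]
    return np.minimum(out_log, 0.0).reshape(shape)


def betabinom_tail(k, n, a, b) -> np.ndarray:
    """Exact upper tail P(X >= k) of BetaBinomial(n, a, b)."""
    return np.exp(_betabinom_log_tail(k, n, a, b))


def betabinom_neg_log10_sf(k, n, a, b) -> np.ndarray:
    """-log10 P(X >= k); finite even where the tail underflows a double."""
    return -_betabinom_log_tail(k, n, a, b) / LN10


def fit_betabinom_moments(ks: np.ndarray, ds: np.ndarray) -> tuple[float, float]:
    """Method-of-moments beta-binomial fit to counts ``ks`` at depths ``ds``.

    Returns (a, b) of the Beta mixing distribution. Pools with half-count
    smoothing so an all-zero vector still yields a proper null.
    """
    ks = np.asarray(ks, dtype=float)
    ds = np.asarray(ds, dtype=float)
    n = len(ks)
    sk, sd = ks.sum(), ds.sum()
    sk2d = float((ks ** 2 / np.where(ds > 0, ds, 1.0)).sum())
    mu, rho = _moments_from_sums(sk, sd, sk2d, n)
    return _beta_params(mu, rho)


def _moments_from_sums(sk, sd, sk2d, n):
    mu = (sk + 0.5) / (sd + 1.0)
    s = sk2d - 2.0 * mu * sk + mu ** 2 * sd
    denom = sd - n
    with np.errstate(divide="ignore", invalid="ignore"):
        rho = np.where(
            denom > 0, (s / (mu * (1.0 - mu)) - n) / denom, 1e-9
        )
    rho = np.clip(rho, 1e-9, 0.5)
    return mu, rho


def _beta_params(mu, rho):
    scale = 1.0 / rho - 1.0
    return mu * scale, (1.0 - mu) * scale


# ---------------------------------------------------------------------------
# outlier calling


def call_outliers(
    pileup: PileupMatrix,
    sheet: SampleSheet,
    config: Optional[CallConfig] = None,
) -> pd.DataFrame:
    """Score every candidate (sample, amplicon, position, alt) one-sided.

    Emits a call iff ``-log10 P > p_cutoff`` and ``alt_count >=
    min_alt_reads``. Candidate scoring is restricted to entries already
    meeting the read floor — sub-threshold entries can never be emitted, and
    skipping them keeps the scan fast. Calling is invariant to sample order.
    """
    config = config or CallConfig()
    rows: list[dict] = []
    for amp_id in pileup.amplicon_ids:
        adf = pileup.for_amplicon(amp_id)
        afm = allele_fraction_matrix(adf, sheet)
        n = len(afm.sample_ids)
        valid = afm.depth > 0
        n_valid = valid.sum(axis=0)
        testable = n_valid >= config.min_samples

        cand = (afm.counts >= config.min_alt_reads) & valid & testable[None, :]
        if not cand.any():
            continue
        ci, cj = np.nonzero(cand)

        if config.mode == "robust_z":
            res = normalize(afm.t, afm.lanes, afm.bq).residuals
            neg_log10_p = np.empty(len(ci))
            for k, (s, j) in enumerate(zip(ci, cj)):
                col = res[:, j]
                others = np.delete(col, s)
                others = others[~np.isnan(others)]
                med = np.median(others)
                mad = np.median(np.abs(others - med))
                scale = max(1.4826 * mad, config.mad_floor)
                z = (res[s, j] - med) / scale
                neg_log10_p[k] = -stats.norm.logsf(z) / LN10
        else:
            neg_log10_p = _betabinom_neglog10p(afm, ci, cj, valid, config)

        keep = neg_log10_p > config.p_cutoff
        for k in np.nonzero(keep)[0]:
            s, j = ci[k], cj[k]
            rows.append(
                {
                    "sample_id": afm.sample_ids[s],
                    "amplicon_id": amp_id,
                    "chrom": afm.chrom,
                    "pos": int(afm.positions[j]),
                    "ref": afm.refs[j],
                    "alt": afm.alts[j],
                    "alt_count": int(afm.counts[s, j]),
                    "depth": int(afm.depth[s, j]),
                    "vaf": float(afm.counts[s, j] / afm.depth[s, j]),
                    "neg_log10_p": float(neg_log10_p[k]),
                }
            )
    calls = pd.DataFrame(
        rows,
        columns=["sample_id", "amplicon_id", "chrom", "pos", "ref", "alt",
                 "alt_count", "depth", "vaf", "neg_log10_p"],
    )
    return calls.sort_values(
        ["chrom", "pos", "alt", "sample_id", "amplicon_id"]
    ).reset_index(drop=True)


def _betabinom_neglog10p(afm, ci, cj, valid, config: CallConfig) -> np.ndarray:
    """Vectorized leave-one-out beta-binomial tail for candidate entries.

    The null at each column is fitted on the other samples after excluding
    the top ``trim_fraction`` of fractions — a contaminated-normal guard so
    that a clone present in several biopsies does not inflate its own null.
    """
    counts, depth = afm.counts.astype(float), afm.depth.astype(float)
    n, P = counts.shape
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = np.where(valid, counts / np.where(depth > 0, depth, 1.0), -1.0)

    n_valid = valid.sum(axis=0)
    n_trim = np.ceil(config.trim_fraction * n_valid).astype(int)
    order = np.argsort(frac, axis=0)  # invalid rows (-1) sort first
    untrimmed = valid.copy()
    for j in range(P):
        if n_trim[j] > 0:
            untrimmed[order[n - n_trim[j]:, j], j] = False

    k2d = np.where(untrimmed, counts ** 2 / np.where(depth > 0, depth, 1.0), 0.0)
    sk = np.where(untrimmed, counts, 0.0).sum(axis=0)
    sd = np.where(untrimmed, depth, 0.0).sum(axis=0)
    sk2d = k2d.sum(axis=0)
    n_u = untrimmed.sum(axis=0)

    in_null = untrimmed[ci, cj]
    k_s, d_s = counts[ci, cj], depth[ci, cj]
    sk_o = sk[cj] - np.where(in_null, k_s, 0.0)
    sd_o = sd[cj] - np.where(in_null, d_s, 0.0)
    sk2d_o = sk2d[cj] - np.where(in_null, k_s ** 2 / d_s, 0.0)
    n_o = n_u[cj] - in_null.astype(int)

    mu, rho = _moments_from_sums(sk_o, sd_o, sk2d_o, n_o)
    a, b = _beta_params(mu, rho)

    # screen: sf >= pmf(k), so -log10 sf <= -log10 pmf(k); a candidate whose
    # single-term bound misses the cutoff can never be emitted, and the bound
    # costs one logpmf instead of a tail summation
    bound = -betabinom_logpmf(k_s, d_s, a, b) / LN10
    out = np.minimum(bound, config.p_cutoff)
    hot = bound > config.p_cutoff
    if hot.any():
        out[hot] = betabinom_neg_log10_sf(k_s[hot], d_s[hot], a[hot], b[hot])
    return out


# ---------------------------------------------------------------------------
# amplicon QC


def amplicon_qc(
    pileup: PileupMatrix,
    config: Optional[CallConfig] = None,
    panel: Optional[AmpliconPanel] = None,
) -> dict[str, bool]:
    """Coverage-based amplicon pass/fail.

    An amplicon passes iff the median across samples of its per-sample mean
    depth reaches ``min_amplicon_depth``. Panel amplicons absent from the
    pileup fail.
    """
    config = config or CallConfig()
    verdict: dict[str, bool] = {}
    depth = pileup.depth
    df = pileup.df.assign(_depth=depth)
    for amp_id, adf in df.groupby("amplicon_id", sort=False):
        per_sample_mean = adf.groupby("sample_id")["_depth"].mean()
        verdict[str(amp_id)] = bool(
            per_sample_mean.median() >= config.min_amplicon_depth
        )
    if panel is not None:
        for amp in panel:
            verdict.setdefault(amp.amplicon_id, False)
    return verdict
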