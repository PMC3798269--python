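"""Gene and interval scoring on enrichment tracks.

TSS scores use a symmetric 1 kb window (-500..+500 bp around the 5' end of
the gene model); binding intervals are maximal runs of probes above a log2
threshold; metagene profiles accumulate strand-oriented probe offsets into
50 bp bins.
"""
from __future__ import annotations

import numpy as np
import pandas as pd

from .core import (
    EnrichmentTrack,
    GeneModels,
    GeneSet,
    MetageneProfile,
    PeakSet,
    ProbeMap,
    ValidationError,
)


def _window_mean(
    track: EnrichmentTrack, chrom: str, center: int, half_width: int, min_probes: int
) -> float:
    """Mean of defined scores at probe midpoints in [center-hw, center+hw)."""
    sl = track.probe_map.chrom_slice(chrom)
    mids = track.probe_map.midpoints[sl]
    lo = np.searchsorted(mids, center - half_width, side="left")
    hi = np.searchsorted(mids, center + half_width, side="left")
    window = track.scores[sl][lo:hi]
    window = window[np.isfinite(window)]
    if len(window) < min_probes:
        return np.nan
    return float(window.mean())


def tss_window_score(
    track: EnrichmentTrack,
    gene: pd.Series,
    half_width: int = 500,
    min_probes: int = 4,
) -> float:
    """Mean log2 enrichment over the 1 kb TSS window of one gene
    (NaN if fewer than ``min_probes`` defined scores fall in the window)."""
    if half_width <= 0:
        raise ValidationError("half_width must be positive")
    return _window_mean(track, gene["chrom"], int(gene["tss"]), half_width, min_probes)


def interval_window_score(
    track: EnrichmentTrack,
    chrom: str,
    start: int,
    end: int,
    half_width: int = 500,
    min_probes: int = 4,
) -> float:
    """Mean log2 enrichment over a 1 kb window centred on the interval
    midpoint, ``floor((start+end)/2)``."""
    if half_width <= 0:
        raise ValidationError("half_width must be positive")
    return _window_mean(track, chrom, (int(start) + int(end)) // 2, half_width, min_probes)


def call_intervals(
    track: EnrichmentTrack,
    threshold: float = 1.0,
    max_gap: int = 250,
    min_probes: int = 2,
    score_half_width: int = 500,
) -> PeakSet:
    """Call binding intervals as maximal runs of probes with score > threshold.

    Qualifying runs separated by <= ``max_gap`` bp (end of one qualifying
    probe to start of the next) are merged; merged runs with fewer than
    ``min_probes`` qualifying probes are dropped.  Each interval spans the
    first to last qualifying probe and carries a midpoint-window score.
    """
    if max_gap < 0 or min_probes < 1:
        raise ValidationError("max_gap must be >= 0 and min_probes >= 1")
    pm = track.probe_map
    starts = pm.df["start"].to_numpy()
    ends = pm.df["end"].to_numpy()
    rows = []
    for chrom in pm.chroms:
        sl = pm.chrom_slice(chrom)
        with np.errstate(invalid="ignore"):
            qual = np.flatnonzero(track.scores[sl] > threshold)
        if len(qual) == 0:
            continue
        s = starts[sl][qual]
        e = ends[sl][qual]
        # split where the gap between consecutive qualifying probes exceeds max_gap
        gap = s[1:] - e[:-1]
        breaks = np.flatnonzero(gap > max_gap)
        run_bounds = np.r_[0, breaks + 1, len(qual)]
        for i in range(len(run_bounds) - 1):
            a, b = run_bounds[i], run_bounds[i + 1]
            if b - a < min_probes:
                continue
            rows.append((chrom, int(s[a]), int(e[b - 1]), int(b - a)))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "n_probes"])
    df["midpoint_score"] = [
        interval_window_score(track, r.chrom, r.start, r.end, score_half_width)
        for r in df.itertuples()
    ]
    return PeakSet(
        df,
        params={"threshold": threshold, "max_gap": max_gap, "min_probes": min_probes},
    )


def score_gene_table(
    tracks: dict[str, EnrichmentTrack],
    genes: GeneModels,
    half_width: int = 500,
    min_probes: int = 4,
) -> pd.DataFrame:
    """TSS-window score of every gene under every condition.

    Returns a genes x conditions DataFrame (NaN where the window holds too
    few defined probes).
    """
    out = pd.DataFrame(index=genes.gene_ids.copy(), dtype=float)
    tss = genes.df["tss"].to_numpy()
    for condition, track in tracks.items():
        scores = np.full(len(genes), np.nan)
        for chrom in np.unique(genes.df["chrom"]):
            gmask = (genes.df["chrom"] == chrom).to_numpy()
            sl = track.probe_map.chrom_slice(chrom)
            mids = track.probe_map.midpoints[sl]
            vals = track.scores[sl]
            finite = np.isfinite(vals)
            csum = np.concatenate([[0.0], np.cumsum(np.where(finite, vals, 0.0))])
            ccnt = np.concatenate([[0], np.cumsum(finite.astype(np.int64))])
            lo = np.searchsorted(mids, tss[gmask] - half_width, side="left")
            hi = np.searchsorted(mids, tss[gmask] + half_width, side="left")
            cnt = ccnt[hi] - ccnt[lo]
            with np.errstate(invalid="ignore"):
                mean = (csum[hi] - csum[lo]) / cnt
            mean[cnt < min_probes] = np.nan
            scores[gmask] = mean
        out[condition] = scores
    return out


def metagene_profile(
    track: EnrichmentTrack,
    genes: GeneModels,
    gene_set: GeneSet | None = None,
    span: int = 2000,
    bin_bp: int = 50,
) -> MetageneProfile:
    """Accumulated strand-oriented profile around the TSS.

    Probe offsets are computed relative to each gene's TSS and negated for
    minus-strand genes, so negative offsets are upstream for both strands.
    Defined probe scores are pooled per bin across genes; each bin reports
    the pooled mean and the number of genes contributing at least one probe.
    """
    if span <= 0 or bin_bp <= 0 or span % bin_bp:
        raise ValidationError("span must be a positive multiple of bin_bp")
    gdf = genes.df if gene_set is None else genes.subset(gene_set.members)
    if len(gdf) == 0:
        raise ValidationError("empty gene set")
    n_bins = 2 * span // bin_bp
    sums = np.zeros(n_bins)
    counts = np.zeros(n_bins, dtype=np.int64)
    gene_hits = np.zeros(n_bins, dtype=np.int64)
    pm = track.probe_map
    for r in gdf.itertuples():
        sl = pm.chrom_slice(r.chrom)
        mids = pm.midpoints[sl]
        lo = np.searchsorted(mids, r.tss - span, side="left")
        hi = np.searchsorted(mids, r.tss + span, side="left")
        if hi == lo:
            continue
        off = mids[lo:hi] - r.tss
        if r.strand == "-":
            off = -off
        vals = track.scores[sl][lo:hi]
        keep = np.isfinite(vals) & (off >= -span) & (off < span)
        if not keep.any():
            continue
        bins = ((off[keep] + span) // bin_bp).astype(np.int64)
        np.add.at(sums, bins, vals[keep])
        np.add.at(counts, bins, 1)
        gene_hits[np.unique(bins)] += 1
    with np.errstate(invalid="ignore"):
        mean = sums / counts
    mean[counts == 0] = np.nan
    offsets = -span + bin_bp / 2.0 + bin_bp * np.arange(n_bins)
    return MetageneProfile(offsets, mean, gene_hits, bin_bp, span)


def random_background_profile(
    track: EnrichmentTrack,
    genes: GeneModels,
    universe: list[str] | None = None,
    n_genes: int = 942,
    n_samplings: int = 10,
    span: int = 2000,
    bin_bp: int = 50,
    seed: int | np.random.Generator = 0,
) -> MetageneProfile:
    """Average metagene profile over random gene samples.

    Draws ``n_samplings`` subsets of ``n_genes`` genes uniformly without
    replacement (within each sampling) from the universe and averages their
    profiles bin-wise.  Deterministic for a fixed seed.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    pool = list(universe) if universe is not None else list(genes.gene_ids)
    if n_genes > len(pool):
        raise ValidationError(f"n_genes={n_genes} exceeds universe size {len(pool)}")
    profiles = []
    for _ in range(n_samplings):
        picked = rng.choice(len(pool), size=n_genes, replace=False)
        subset = GeneSet.from_ids("random", [pool[i] for i in picked])
        profiles.append(metagene_profile(track, genes, subset, span, bin_bp))
    mean = np.nanmean(np.vstack([p.mean for p in profiles]), axis=0)
    n_g = np.vstack([p.n_genes for p in profiles]).mean(axis=0).round().astype(np.int64)
    return MetageneProfile(profiles[0].offsets, mean, n_g, bin_bp, span)
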