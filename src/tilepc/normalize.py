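"""Raw two-channel intensities -> smoothed log2 ChIP/input enrichment tracks.

The processing chain is: median-scale each sample to 500, quantile-normalize
all ChIP and input columns together, form per-pair log2 ChIP/input ratios,
smooth in 500 bp windows requiring at least 4 oligos, then average
biological replicates.  Dye swaps need no special handling here: channel
roles come from sample metadata, so a swapped replicate enters identically.
"""
from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .core import EnrichmentTrack, IntensityMatrix, ProbeMap, ValidationError


def median_scale(values: np.ndarray, target: float = 500.0) -> np.ndarray:
    """Multiplicatively rescale a positive intensity vector so its median
    equals ``target``.  Rank order is preserved."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValidationError("cannot median-scale an empty vector")
    if target <= 0:
        raise ValidationError("median-scale target must be positive")
    if not np.isfinite(v).all() or (v <= 0).any():
        raise ValidationError("intensities must be positive and finite")
    return v * (target / np.median(v))


def quantile_normalize(columns: np.ndarray | pd.DataFrame) -> np.ndarray:
    """Force every column onto the common rank-mean reference distribution.

    The reference is the across-column mean of sorted values at each rank.
    Ties within a column receive the mean of the reference values over the
    tied rank span (mid-rank interpolation), so the result is deterministic
    and invariant to input row order.
    """
    x = np.asarray(columns, dtype=float)
    if x.ndim != 2 or x.shape[1] < 2:
        raise ValidationError("quantile normalization needs a matrix of >= 2 columns")
    if not np.isfinite(x).all():
        raise ValidationError("quantile normalization requires finite values")
    n = x.shape[0]
    reference = np.sort(x, axis=0).mean(axis=1)
    out = np.empty_like(x)
    grid = np.arange(1, n + 1, dtype=float)
    for j in range(x.shape[1]):
        ranks = rankdata(x[:, j], method="average")  # mid-ranks for ties
        out[:, j] = np.interp(ranks, grid, reference)
    return out


def log_ratio(chip: np.ndarray, input_: np.ndarray) -> np.ndarray:
    """Elementwise log2(ChIP/input)."""
    chip = np.asarray(chip, dtype=float)
    input_ = np.asarray(input_, dtype=float)
    if chip.shape != input_.shape:
        raise ValidationError("chip and input vectors must have matching lengths")
    if (chip <= 0).any() or (input_ <= 0).any():
        raise ValidationError("intensities must be positive")
    return np.log2(chip / input_)


def window_smooth(
    ratios: np.ndarray,
    probe_map: ProbeMap,
    window_bp: int = 500,
    min_oligos: int = 4,
    condition: str = "",
) -> EnrichmentTrack:
    """Sliding-window mean of per-probe scores, evaluated at probe midpoints.

    At each probe position ``p`` the score is the mean of ratios of probes
    whose midpoints lie in ``[p - window_bp/2, p + window_bp/2)``; windows
    never cross chromosome boundaries.  If fewer than ``min_oligos`` defined
    ratios fall in the window the score is missing.
    """
    if window_bp <= 0:
        raise ValidationError("window_bp must be positive")
    if min_oligos < 1:
        raise ValidationError("min_oligos must be >= 1")
    ratios = np.asarray(ratios, dtype=float)
    if ratios.shape != (len(probe_map),):
        raise ValidationError("ratios misaligned to probe map")
    half = window_bp / 2.0
    out = np.full(len(probe_map), np.nan)
    mids = probe_map.midpoints
    for chrom in probe_map.chroms:
        sl = probe_map.chrom_slice(chrom)
        m = mids[sl].astype(float)
        r = ratios[sl]
        finite = np.isfinite(r)
        csum = np.concatenate([[0.0], np.cumsum(np.where(finite, r, 0.0))])
        ccnt = np.concatenate([[0], np.cumsum(finite.astype(np.int64))])
        lo = np.searchsorted(m, m - half, side="left")
        hi = np.searchsorted(m, m + half, side="left")
        cnt = ccnt[hi] - ccnt[lo]
        with np.errstate(invalid="ignore"):
            mean = (csum[hi] - csum[lo]) / cnt
        mean[cnt < min_oligos] = np.nan
        out[sl] = mean
    return EnrichmentTrack(
        probe_map, out, condition=condition,
        params={"window_bp": window_bp, "min_oligos": min_oligos},
    )


def combine_replicates(tracks: list[EnrichmentTrack]) -> EnrichmentTrack:
    """Per-probe mean over replicate tracks, ignoring missing scores.

    All tracks must share one ProbeMap and one condition label; a probe is
    missing in the result only where every replicate is missing.
    """
    if not tracks:
        raise ValidationError("no tracks to combine")
    pm = tracks[0].probe_map
    cond = tracks[0].condition
    for t in tracks[1:]:
        if t.probe_map is not pm and t.probe_map != pm:
            raise ValidationError("tracks do not share a probe map")
        if t.condition != cond:
            raise ValidationError(
                f"cannot combine tracks of different conditions: {cond!r} vs {t.condition!r}"
            )
    stack = np.vstack([t.scores for t in tracks])
    with np.errstate(invalid="ignore"):
        mean = np.nanmean(stack, axis=0)
    return EnrichmentTrack(pm, mean, condition=cond, params=dict(tracks[0].params, n_replicates=len(tracks)))


def normalize_experiment(
    intensities: IntensityMatrix,
    median_target: float = 500.0,
    window_bp: int = 500,
    min_oligos: int = 4,
) -> dict[str, EnrichmentTrack]:
    """Run the full normalization chain; one combined track per condition."""
    scaled = np.column_stack(
        [median_scale(intensities.column(s.sample_id), median_target) for s in intensities.samples]
    )
    normed = quantile_normalize(scaled)
    cols = {s.sample_id: normed[:, i] for i, s in enumerate(intensities.samples)}
    out: dict[str, EnrichmentTrack] = {}
    for condition in intensities.conditions():
        reps = []
        for chip, inp in intensities.chip_input_pairs(condition):
            ratios = log_ratio(cols[chip.sample_id], cols[inp.sample_id])
            reps.append(
                window_smooth(ratios, intensities.probe_map, window_bp, min_oligos, condition)
            )
        if reps:
            out[condition] = combine_replicates(reps)
    return out
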