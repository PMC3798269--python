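import numpy as np
import pandas as pd
import pytest

import tilepc as tp


def make_probe_map(midpoints, chrom="chr1", length=50):
    """ProbeMap with probes centred on the given midpoints."""
    mids = np.asarray(midpoints)
    return tp.ProbeMap(
        pd.DataFrame(
            {
                "chrom": chrom,
                "start": mids - length // 2,
                "end": mids + length - length // 2,
                "probe_id": [f"{chrom}_p{i}" for i in range(len(mids))],
            }
        )
    )


def random_instance(rng, n_max=400, missing_frac=0.1):
    """Random multi-chromosome probe map + scores with missing values."""
    n_chrom = rng.integers(1, 3)
    frames = []
    for c in range(n_chrom):
        n = int(rng.integers(10, n_max // n_chrom + 10))
        starts = np.sort(rng.choice(np.arange(0, 60_000, 25), size=n, replace=False))
        frames.append(
            pd.DataFrame(
                {
                    "chrom": f"chr{c + 1}",
                    "start": starts,
                    "end": starts + 50,
                    "probe_id": [f"c{c}_p{i}" for i in range(n)],
                }
            )
        )
    pm = tp.ProbeMap(pd.concat(frames, ignore_index=True))
    scores = rng.normal(0, 1, size=len(pm))
    scores[rng.random(len(pm)) < missing_frac] = np.nan
    return pm, scores


def assert_scores_close(actual, desired):
    """Equality up to floating rounding (summation order); NaN patterns exact."""
    np.testing.assert_allclose(actual, desired, rtol=1e-9, atol=1e-12, equal_nan=True)


# ---------------------------------------------------------------------------
# independent brute-force oracles (deliberately naive O(n^2) implementations)


def brute_window_mean(pm, scores, chrom, center, half_width, min_probes):
    sl = pm.chrom_slice(chrom)
    vals = []
    for mid, s in zip(pm.midpoints[sl], scores[sl]):
        if center - half_width <= mid < center + half_width and np.isfinite(s):
            vals.append(s)
    return float(np.mean(vals)) if len(vals) >= min_probes else np.nan


def brute_window_smooth(pm, scores, window_bp, min_oligos):
    out = np.full(len(pm), np.nan)
    half = window_bp / 2
    chroms = pm.df["chrom"].tolist()
    mids = pm.midpoints.tolist()
    vals_in = [float(s) for s in scores]
    for i in range(len(pm)):
        chrom, p = chroms[i], mids[i]
        vals = [
            vals_in[j]
            for j in range(len(pm))
            if chroms[j] == chrom
            and p - half <= mids[j] < p + half
            and np.isfinite(vals_in[j])
        ]
        if len(vals) >= min_oligos:
            out[i] = np.mean(vals)
    return out


def brute_call_intervals(pm, scores, threshold, max_gap, min_probes):
    df = pm.df
    qual = [
        i for i in range(len(pm)) if np.isfinite(scores[i]) and scores[i] > threshold
    ]
    runs, current = [], []
    for i in qual:
        if current and (
            df.at[i, "chrom"] != df.at[current[-1], "chrom"]
            or df.at[i, "start"] - df.at[current[-1], "end"] > max_gap
        ):
            runs.append(current)
            current = []
        current.append(i)
    if current:
        runs.append(current)
    return [
        (df.at[r[0], "chrom"], int(df.at[r[0], "start"]), int(df.at[r[-1], "end"]), len(r))
        for r in runs
        if len(r) >= min_probes
    ]


# ---------------------------------------------------------------------------
# shared simulation (expensive; computed once per session)


@pytest.fixture(scope="session")
def default_sim():
    cfg = tp.SimConfig(seed=101)
    genes, probes, matrix, truth = tp.simulate_dataset(cfg)
    tracks = tp.normalize_experiment(matrix)
    table = tp.score_gene_table(tracks, genes)
    return {
        "config": cfg,
        "genes": genes,
        "probes": probes,
        "matrix": matrix,
        "truth": truth,
        "tracks": tracks,
        "table": table,
    }


@pytest.fixture(scope="session")
def small_sim():
    cfg = tp.SimConfig(
        n_chroms=1, chrom_length=2_000_000, n_genes=200, target_fraction=0.2, seed=7
    )
    genes, probes, matrix, truth = tp.simulate_dataset(cfg)
    return cfg, genes, probes, matrix, truth
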