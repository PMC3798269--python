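"""Synthetic tiling-array datasets with known ground truth.

Emulates a NimbleGen-style dense two-colour design: probes tiled at fixed
spacing, ChIP/input channel pairs per replicate with an optional dye swap,
lognormal probe-affinity background, per-sample scale factors, multiplicative
log2-scale noise, and log2-enrichment domains planted at target-gene TSSs.

Condition-specific amplitude multipliers let one dataset mirror a biological
contrast: "regulated" targets scale with the condition multiplier while
"canonical" targets keep full amplitude in every condition (the shape of a
constitutive Polycomb target versus a stage-regulated one).
"""
from __future__ import annotations

import os
from dataclasses import dataclass, field, asdict
from typing import Mapping

import numpy as np
import pandas as pd

from .core import (
    GeneModels,
    GeneSet,
    IntensityMatrix,
    PeakSet,
    ProbeMap,
    SampleMeta,
    ValidationError,
)
from . import io as tio


@dataclass
class SimConfig:
    """Study-condition parameters for one simulated dataset.

    Lengths in bp, amplitudes and noise in log2 units.  ``target_fraction``
    of genes carry a planted domain centred on their TSS; of those,
    ``canonical_fraction`` keep full amplitude in every condition while the
    rest are scaled by the per-condition multiplier.  Gaussian domains use
    sd = domain_width / 5.
    """

    n_chroms: int = 2
    chrom_length: int = 9_000_000
    probe_spacing: int = 75
    probe_length: int = 50
    n_genes: int = 2000
    target_fraction: float = 0.1
    canonical_fraction: float = 0.0
    amplitude: float = 1.5
    domain_shape: str = "boxcar"
    domain_width: int = 1500
    noise_sd: float = 0.3
    background_median: float = 500.0
    background_log2_sd: float = 1.2
    sample_scale_log2_range: float = 0.5
    conditions: Mapping[str, float] = field(default_factory=lambda: {"wildtype": 1.0})
    replicates: int = 2
    dye_swap: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.probe_spacing < 1:
            raise ValidationError("probe_spacing must be >= 1")
        if not 0.0 <= self.target_fraction <= 1.0:
            raise ValidationError("target_fraction must be in [0, 1]")
        if not 0.0 <= self.canonical_fraction <= 1.0:
            raise ValidationError("canonical_fraction must be in [0, 1]")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")
        if self.domain_shape not in ("boxcar", "gaussian"):
            raise ValidationError(f"unknown domain_shape {self.domain_shape!r}")


@dataclass
class SimulationTruth:
    """Planted signal bookkeeping serialized alongside every dataset."""

    genes: pd.DataFrame  # index gene_id; columns cls, amplitude, chrom, tss
    sample_scales: pd.Series  # sample_id -> linear scale factor
    config: SimConfig

    def target_set(self, name: str = "target") -> GeneSet:
        return GeneSet.from_ids(name, self.genes.index[self.genes["cls"] != "background"])

    def nontarget_set(self, name: str = "nontarget") -> GeneSet:
        return GeneSet.from_ids(name, self.genes.index[self.genes["cls"] == "background"])

    def domains(self) -> pd.DataFrame:
        """Planted domain intervals (chrom, start, end, gene_id, amplitude)."""
        t = self.genes[self.genes["cls"] != "background"]
        half = self.config.domain_width // 2
        return pd.DataFrame(
            {
                "chrom": t["chrom"].to_numpy(),
                "start": t["tss"].to_numpy() - half,
                "end": t["tss"].to_numpy() + half,
                "gene_id": t.index.to_numpy(),
                "amplitude": t["amplitude"].to_numpy(),
            }
        ).sort_values(["chrom", "start"]).reset_index(drop=True)


def simulate_genome(
    config: SimConfig, rng: np.random.Generator | None = None
) -> tuple[GeneModels, ProbeMap]:
    """Tile probes at fixed spacing and place non-overlapping genes.

    Each chromosome is divided into equal slots, one gene per slot, placed
    with enough margin that a planted domain stays inside the slot (so
    planted domains never overlap).
    """
    rng = rng or np.random.default_rng(config.seed)
    # probes
    rows = []
    for c in range(config.n_chroms):
        chrom = f"chr{c + 1}"
        starts = np.arange(0, config.chrom_length - config.probe_length + 1, config.probe_spacing)
        rows.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "start": starts,
                    "end": starts + config.probe_length,
                    "probe_id": [f"{chrom}_p{i:06d}" for i in range(len(starts))],
                }
            )
        )
    probes = ProbeMap(pd.concat(rows, ignore_index=True))
    # genes
    grow: list[tuple] = []
    if config.n_genes:
        per = np.full(config.n_chroms, config.n_genes // config.n_chroms)
        per[: config.n_genes % config.n_chroms] += 1
        gid = 0
        margin = config.domain_width // 2 + config.probe_length
        for c in range(config.n_chroms):
            if per[c] == 0:
                continue
            chrom = f"chr{c + 1}"
            slot = config.chrom_length // per[c]
            for k in range(per[c]):
                length = int(rng.integers(800, 2501))
                avail = slot - length - 2 * margin
                if avail < 0:
                    raise ValidationError(
                        f"genes do not fit: slot {slot} bp cannot hold a {length} bp "
                        f"gene with {margin} bp margins; reduce n_genes or enlarge chroms"
                    )
                start = k * slot + margin + int(rng.integers(0, avail + 1))
                strand = "+" if rng.random() < 0.5 else "-"
                gid += 1
                grow.append((f"g{gid:05d}", chrom, start, start + length, strand))
    genes = GeneModels(
        pd.DataFrame(grow, columns=["gene_id", "chrom", "start", "end", "strand"])
    )
    return genes, probes


def _domain_profile(offsets: np.ndarray, config: SimConfig) -> np.ndarray:
    """Planted log2-enrichment shape (unit amplitude) at bp offsets from a TSS."""
    half = config.domain_width / 2.0
    if config.domain_shape == "boxcar":
        return (np.abs(offsets) < half).astype(float)
    sd = config.domain_width / 5.0
    return np.exp(-0.5 * (offsets / sd) ** 2)


def simulate_intensities(
    genes: GeneModels,
    probes: ProbeMap,
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> tuple[IntensityMatrix, SimulationTruth]:
    """Generate two-channel intensities with planted TSS-centred domains.

    Per probe: a lognormal affinity shared by all channels; per sample: a
    global scale factor and independent N(0, noise_sd) log2 noise per probe.
    ChIP channels additionally carry 2**signal, the sum of planted domain
    profiles for that condition.
    """
    rng = rng or np.random.default_rng(config.seed + 1)
    n_targets = int(round(config.n_genes * config.target_fraction))
    order = rng.permutation(len(genes))
    target_idx = order[:n_targets]
    n_canon = int(round(n_targets * config.canonical_fraction))
    cls = np.full(len(genes), "background", dtype=object)
    cls[target_idx[n_canon:]] = "target"
    cls[target_idx[:n_canon]] = "canonical"
    amp = np.where(cls == "background", 0.0, config.amplitude)
    truth_genes = pd.DataFrame(
        {
            "cls": cls,
            "amplitude": amp,
            "chrom": genes.df["chrom"].to_numpy(),
            "tss": genes.df["tss"].to_numpy(),
        },
        index=genes.gene_ids.copy(),
    )

    # per-condition per-probe signal, assembled chromosome by chromosome
    mids = probes.midpoints
    signal = {cond: np.zeros(len(probes)) for cond in config.conditions}
    reach = config.domain_width if config.domain_shape == "boxcar" else config.domain_width * 2
    for g, row in truth_genes[truth_genes["cls"] != "background"].iterrows():
        sl = probes.chrom_slice(row["chrom"])
        m = mids[sl]
        lo = np.searchsorted(m, row["tss"] - reach)
        hi = np.searchsorted(m, row["tss"] + reach)
        prof = row["amplitude"] * _domain_profile(m[lo:hi] - row["tss"], config)
        for cond, mult in config.conditions.items():
            factor = 1.0 if row["cls"] == "canonical" else mult
            signal[cond][sl.start + lo : sl.start + hi] += factor * prof

    affinity = config.background_median * np.exp2(
        rng.normal(0.0, config.background_log2_sd, size=len(probes))
    )
    samples: list[SampleMeta] = []
    columns: dict[str, np.ndarray] = {}
    scales: dict[str, float] = {}
    for cond in config.conditions:
        for rep in range(1, config.replicates + 1):
            swap = config.dye_swap and rep % 2 == 0
            for role in ("chip", "input"):
                sid = f"{cond}_rep{rep}_{role}"
                dye = ("cy3" if role == "chip" else "cy5") if swap else (
                    "cy5" if role == "chip" else "cy3"
                )
                samples.append(SampleMeta(sid, role, cond, rep, dye))
                scale = float(np.exp2(rng.uniform(
                    -config.sample_scale_log2_range, config.sample_scale_log2_range
                )))
                scales[sid] = scale
                noise = rng.normal(0.0, config.noise_sd, size=len(probes)) if config.noise_sd else 0.0
                sig = signal[cond] if role == "chip" else 0.0
                columns[sid] = affinity * scale * np.exp2(sig + noise)
    matrix = IntensityMatrix(probes, pd.DataFrame(columns), samples)
    truth = SimulationTruth(truth_genes, pd.Series(scales, name="scale"), config)
    return matrix, truth


def simulate_dataset(
    config: SimConfig,
) -> tuple[GeneModels, ProbeMap, IntensityMatrix, SimulationTruth]:
    """Genome + intensities from one seed."""
    rng = np.random.default_rng(config.seed)
    genes, probes = simulate_genome(config, rng)
    matrix, truth = simulate_intensities(genes, probes, config, rng)
    return genes, probes, matrix, truth


# ---------------------------------------------------------------------------
# fixture export / import


def export_fixture(
    genes: GeneModels,
    probes: ProbeMap,
    matrix: IntensityMatrix,
    truth: SimulationTruth,
    out_dir: str,
) -> dict[str, str]:
    """Write probes.bed, genes.gff3, intensities.tsv, samples.tsv, truth.tsv.

    The files use the same formats as real-data inputs; re-reading them
    reproduces the dataset exactly, and the same seed yields byte-identical
    files.
    """
    os.makedirs(out_dir, exist_ok=True)
    paths = {k: os.path.join(out_dir, f) for k, f in {
        "probes": "probes.bed", "genes": "genes.gff3",
        "intensities": "intensities.tsv", "samples": "samples.tsv",
        "truth": "truth.tsv",
    }.items()}
    tio.write_probe_map(probes, paths["probes"])
    tio.write_gene_models_gff3(genes, paths["genes"])
    tio.write_intensity_table(matrix, paths["intensities"])
    tio.write_sample_sheet(matrix.samples, paths["samples"])
    with open(paths["truth"], "w") as fh:
        cfg = asdict(truth.config)
        cfg["conditions"] = dict(cfg["conditions"])
        fh.write(f"# config: {cfg!r}\n")
        for sid, sc in truth.sample_scales.items():
            fh.write(f"# scale: {sid}={sc:.17g}\n")
        out = truth.genes.reset_index(names="gene_id")
        out.to_csv(fh, sep="\t", index=False, float_format="%.17g")
    return paths


def load_fixture(out_dir: str) -> tuple[GeneModels, ProbeMap, IntensityMatrix, pd.DataFrame]:
    """Read a fixture directory back into in-memory objects (truth as a frame)."""
    probes = tio.read_probe_map(os.path.join(out_dir, "probes.bed"))
    genes = tio.read_gene_models(os.path.join(out_dir, "genes.gff3"), format="gff3")
    samples = tio.read_sample_sheet(os.path.join(out_dir, "samples.tsv"))
    matrix = tio.read_intensity_table(os.path.join(out_dir, "intensities.tsv"), probes, samples)
    truth = pd.read_csv(
        os.path.join(out_dir, "truth.tsv"), sep="\t", comment="#", dtype={"gene_id": str}
    ).set_index("gene_id")
    return genes, probes, matrix, truth


# ---------------------------------------------------------------------------
# recovery evaluation


def domain_recovery(peaks: PeakSet, planted: pd.DataFrame) -> pd.DataFrame:
    """Best-overlap Jaccard of each planted domain against called intervals.

    ``planted`` needs chrom/start/end columns (as from
    :meth:`SimulationTruth.domains`).  Returns one row per planted domain
    with its best Jaccard index (0 when nothing overlaps).
    """
    out = []
    for r in planted.itertuples():
        cand = peaks.df[peaks.df["chrom"] == r.chrom]
        best = 0.0
        for p in cand.itertuples():
            inter = min(r.end, p.end) - max(r.start, p.start)
            if inter <= 0:
                continue
            union = max(r.end, p.end) - min(r.start, p.start)
            best = max(best, inter / union)
        out.append((r.chrom, r.start, r.end, r.gene_id, best))
    return pd.DataFrame(out, columns=["chrom", "start", "end", "gene_id", "jaccard"])
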