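"""Shared genomic data model for the tiling-array pipeline.

All coordinates are 0-based half-open throughout the package; GFF3 input is
converted on read.  Probe "position" for all window arithmetic is the probe
interval midpoint, ``floor((start + end) / 2)``.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

CHROMATIN_STATES = ("BLACK", "BLUE", "RED", "YELLOW", "GREEN")
UNASSIGNED = "unassigned"


class ValidationError(ValueError):
    """Raised when an input table violates a data-model invariant."""


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise ValidationError(msg)


class ProbeMap:
    """Genomic coordinates and identities of tiling-array probes.

    Sorted by (chrom, start); probe ids unique; every probe has positive
    length.  Rows are stored in a DataFrame with columns
    ``chrom, start, end, probe_id``.
    """

    def __init__(self, df: pd.DataFrame):
        df = df.loc[:, ["chrom", "start", "end", "probe_id"]].copy()
        df["chrom"] = df["chrom"].astype(str)
        df["start"] = df["start"].astype(np.int64)
        df["end"] = df["end"].astype(np.int64)
        df["probe_id"] = df["probe_id"].astype(str)
        bad = df.index[df["end"] <= df["start"]]
        if len(bad):
            i = bad[0]
            raise ValidationError(
                f"probe {df.at[i, 'probe_id']!r} at input row {i} has "
                f"end <= start ({df.at[i, 'start']}..{df.at[i, 'end']}): "
                "zero- or negative-length probes are not allowed"
            )
        dup = df["probe_id"][df["probe_id"].duplicated()]
        if len(dup):
            raise ValidationError(f"duplicate probe_id {dup.iloc[0]!r}")
        df = df.sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True)
        self.df = df
        self._midpoints = ((df["start"].to_numpy() + df["end"].to_numpy()) // 2).astype(np.int64)
        # contiguous row slice per chromosome (df is sorted)
        self._chrom_slices: dict[str, slice] = {}
        chroms = df["chrom"].to_numpy()
        if len(chroms):
            starts = np.flatnonzero(np.r_[True, chroms[1:] != chroms[:-1]])
            bounds = np.r_[starts, len(chroms)]
            for i, s in enumerate(starts):
                self._chrom_slices[chroms[s]] = slice(int(s), int(bounds[i + 1]))

    def __len__(self) -> int:
        return len(self.df)

    def __eq__(self, other) -> bool:
        return isinstance(other, ProbeMap) and self.df.equals(other.df)

    @property
    def midpoints(self) -> np.ndarray:
        """Probe midpoints, the anchor for all window arithmetic."""
        return self._midpoints

    @property
    def probe_ids(self) -> pd.Index:
        return pd.Index(self.df["probe_id"])

    @property
    def chroms(self) -> list[str]:
        return list(self._chrom_slices)

    def chrom_slice(self, chrom: str) -> slice:
        """Row slice of this chromosome's probes (empty slice if absent)."""
        return self._chrom_slices.get(chrom, slice(0, 0))


@dataclass(frozen=True)
class SampleMeta:
    """One hybridized channel: ChIP or input, with condition/replicate/dye."""

    sample_id: str
    role: str  # "chip" | "input"
    condition: str
    replicate: int
    dye: str  # "cy3" | "cy5"

    def __post_init__(self):
        _require(self.role in ("chip", "input"), f"bad role {self.role!r}")
        _require(self.dye in ("cy3", "cy5"), f"bad dye {self.dye!r}")
        _require(self.replicate >= 1, "replicate must be >= 1")


def validate_sample_sheet(samples: list[SampleMeta]) -> None:
    """Every chip sample must have a matched input of the same condition/replicate."""
    ids = [s.sample_id for s in samples]
    dup = {i for i in ids if ids.count(i) > 1}
    _require(not dup, f"duplicate sample_id(s): {sorted(dup)}")
    inputs = {(s.condition, s.replicate) for s in samples if s.role == "input"}
    for s in samples:
        if s.role == "chip" and (s.condition, s.replicate) not in inputs:
            raise ValidationError(
                f"chip sample {s.sample_id!r} ({s.condition}, rep {s.replicate}) "
                "has no matched input sample"
            )


class IntensityMatrix:
    """Raw per-probe channel intensities, rows aligned to a ProbeMap."""

    def __init__(self, probe_map: ProbeMap, values: pd.DataFrame, samples: list[SampleMeta]):
        _require(len(values) == len(probe_map), "row count must equal probe count")
        order = [s.sample_id for s in samples]
        missing = [c for c in order if c not in values.columns]
        _require(not missing, f"intensity columns missing for samples: {missing}")
        values = values.loc[:, order].astype(float).reset_index(drop=True)
        arr = values.to_numpy()
        if not np.isfinite(arr).all() or (arr <= 0).any():
            r, c = np.argwhere(~(np.isfinite(arr) & (arr > 0)))[0]
            probe = probe_map.df.iloc[r]
            raise ValidationError(
                f"non-positive or non-finite intensity {arr[r, c]!r} for probe "
                f"{probe['probe_id']} ({probe['chrom']}:{probe['start']}-{probe['end']}) "
                f"in sample {order[c]!r}"
            )
        self.probe_map = probe_map
        self.values = values
        self.samples = list(samples)
        validate_sample_sheet(self.samples)

    def column(self, sample_id: str) -> np.ndarray:
        return self.values[sample_id].to_numpy()

    def conditions(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.samples:
            seen.setdefault(s.condition, None)
        return list(seen)

    def chip_input_pairs(self, condition: str) -> list[tuple[SampleMeta, SampleMeta]]:
        """(chip, input) sample pairs for one condition, ordered by replicate."""
        chips = sorted(
            (s for s in self.samples if s.condition == condition and s.role == "chip"),
            key=lambda s: s.replicate,
        )
        by_rep = {
            s.replicate: s
            for s in self.samples
            if s.condition == condition and s.role == "input"
        }
        return [(c, by_rep[c.replicate]) for c in chips]


@dataclass
class EnrichmentTrack:
    """Per-probe log2 ChIP/input enrichment aligned to a ProbeMap.

    ``scores`` is float with NaN marking probes where the signal is
    undefined (e.g. windows failing the minimum-oligo rule).
    """

    probe_map: ProbeMap
    scores: np.ndarray
    condition: str = ""
    params: dict = field(default_factory=dict)

    def __post_init__(self):
        self.scores = np.asarray(self.scores, dtype=float)
        _require(self.scores.shape == (len(self.probe_map),), "scores misaligned to probe map")
        defined = self.scores[~np.isnan(self.scores)]
        _require(np.isfinite(defined).all(), "scores must be finite where defined")

    @property
    def defined(self) -> np.ndarray:
        return ~np.isnan(self.scores)


class GeneModels:
    """Gene coordinates with strand; TSS is the 5' end of the model
    (= start on '+', = end - 1 on '-')."""

    def __init__(self, df: pd.DataFrame):
        df = df.loc[:, ["gene_id", "chrom", "start", "end", "strand"]].copy()
        df["gene_id"] = df["gene_id"].astype(str)
        df["chrom"] = df["chrom"].astype(str)
        df["start"] = df["start"].astype(np.int64)
        df["end"] = df["end"].astype(np.int64)
        dup = df["gene_id"][df["gene_id"].duplicated()]
        if len(dup):
            raise ValidationError(f"duplicate gene_id {dup.iloc[0]!r}")
        bad_strand = ~df["strand"].isin(["+", "-"])
        if bad_strand.any():
            g = df.loc[bad_strand, "gene_id"].iloc[0]
            raise ValidationError(f"gene {g!r} has missing or invalid strand")
        _require((df["end"] > df["start"]).all(), "gene end must exceed start")
        df["tss"] = np.where(df["strand"] == "+", df["start"], df["end"] - 1)
        df = df.sort_values(["chrom", "start", "gene_id"], kind="mergesort")
        self.df = df.set_index("gene_id", drop=False)

    def __len__(self) -> int:
        return len(self.df)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self.df.index

    @property
    def gene_ids(self) -> pd.Index:
        return self.df.index

    def subset(self, gene_ids: Iterable[str]) -> pd.DataFrame:
        return self.df.loc[[g for g in gene_ids if g in self.df.index]]


@dataclass(frozen=True)
class GeneSet:
    """A named collection of gene identifiers."""

    name: str
    members: frozenset[str]

    @classmethod
    def from_ids(cls, name: str, ids: Iterable[str]) -> "GeneSet":
        return cls(name, frozenset(str(i) for i in ids))

    def __len__(self) -> int:
        return len(self.members)

    def restrict_to(self, genes: GeneModels) -> tuple["GeneSet", list[str]]:
        """Drop members outside the gene-model universe; return (set, dropped)."""
        dropped = sorted(m for m in self.members if m not in genes)
        kept = self.members - set(dropped)
        return GeneSet(self.name, frozenset(kept)), dropped


class DomainAnnotation:
    """Five-state chromatin-domain intervals (BLACK/BLUE/RED/YELLOW/GREEN),
    non-overlapping within each chromosome."""

    def __init__(self, df: pd.DataFrame):
        df = df.loc[:, ["chrom", "start", "end", "state"]].copy()
        df["chrom"] = df["chrom"].astype(str)
        df["start"] = df["start"].astype(np.int64)
        df["end"] = df["end"].astype(np.int64)
        df["state"] = df["state"].astype(str)
        bad = ~df["state"].isin(CHROMATIN_STATES)
        if bad.any():
            raise ValidationError(
                f"unknown chromatin state {df.loc[bad, 'state'].iloc[0]!r}; "
                f"expected one of {CHROMATIN_STATES}"
            )
        _require((df["end"] > df["start"]).all(), "domain end must exceed start")
        df = df.sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True)
        same = df["chrom"].shift() == df["chrom"]
        overlap = same & (df["start"] < df["end"].shift())
        if overlap.any():
            i = int(np.flatnonzero(overlap.to_numpy())[0])
            raise ValidationError(
                f"overlapping domain intervals on {df.at[i, 'chrom']} near {df.at[i, 'start']}"
            )
        self.df = df

    def __len__(self) -> int:
        return len(self.df)


@dataclass
class PeakSet:
    """Above-threshold binding intervals with 1 kb midpoint-window scores."""

    df: pd.DataFrame  # chrom, start, end, n_probes, midpoint_score
    params: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.df)


@dataclass
class MetageneProfile:
    """Accumulated (average) signal profile around the TSS, strand-oriented.

    ``offsets`` are bin centers in bp relative to the TSS (negative =
    upstream); ``mean`` is the mean of pooled probe scores per bin;
    ``n_genes`` counts genes contributing at least one defined probe.
    """

    offsets: np.ndarray
    mean: np.ndarray
    n_genes: np.ndarray
    bin_bp: int
    span: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"offset": self.offsets, "mean": self.mean, "n_genes": self.n_genes}
        )


EnrichmentTable = pd.DataFrame
"""Genes x conditions table of mean log2 TSS-window enrichment (NaN = missing)."""
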