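"""Readers and writers for the external formats the pipeline touches.

BED is native (0-based half-open).  GFF3 is converted on read via pyranges.
Tabular files are TSV with a header row and ``.`` for missing values.
"""
from __future__ import annotations

import os
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import pyranges as pr

from .core import (
    DomainAnnotation,
    EnrichmentTrack,
    GeneModels,
    GeneSet,
    IntensityMatrix,
    ProbeMap,
    SampleMeta,
    ValidationError,
)

MISSING = "."


# ---------------------------------------------------------------------------
# probes


def read_probe_map(path: str, format: str = "bed") -> ProbeMap:
    """Read a probe layout from BED4 (``format='bed'``) or headered TSV
    with columns chrom/start/end/probe_id (``format='tsv'``).

    Input row order is irrelevant; the returned map is sorted.
    """
    if format == "bed":
        df = pd.read_csv(
            path, sep="\t", header=None, comment="#",
            names=["chrom", "start", "end", "probe_id"], usecols=range(4),
            dtype={"chrom": str, "probe_id": str},
        )
    elif format == "tsv":
        df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "probe_id": str})
        need = {"chrom", "start", "end", "probe_id"}
        if not need.issubset(df.columns):
            raise ValidationError(f"{path}: missing columns {sorted(need - set(df.columns))}")
    else:
        raise ValueError(f"unknown probe map format {format!r}")
    try:
        return ProbeMap(df)
    except ValidationError as e:
        raise ValidationError(f"{path}: {e}") from e


def write_probe_map(probe_map: ProbeMap, path: str) -> None:
    probe_map.df.to_csv(path, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# samples and intensities


def read_sample_sheet(path: str) -> list[SampleMeta]:
    """TSV with columns sample_id, role, condition, replicate, dye."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    need = {"sample_id", "role", "condition", "replicate", "dye"}
    if not need.issubset(df.columns):
        raise ValidationError(f"{path}: missing columns {sorted(need - set(df.columns))}")
    return [
        SampleMeta(r.sample_id, r.role, r.condition, int(r.replicate), r.dye)
        for r in df.itertuples()
    ]


def write_sample_sheet(samples: Sequence[SampleMeta], path: str) -> None:
    pd.DataFrame(
        [(s.sample_id, s.role, s.condition, s.replicate, s.dye) for s in samples],
        columns=["sample_id", "role", "condition", "replicate", "dye"],
    ).to_csv(path, sep="\t", index=False)


def read_intensity_table(
    path: str, probe_map: ProbeMap, samples: Sequence[SampleMeta]
) -> IntensityMatrix:
    """Read a probe x sample TSV of raw intensities (first column probe_id).

    Rows are reordered to ProbeMap order; every probe must be present and
    every value positive and finite.
    """
    df = pd.read_csv(path, sep="\t", dtype={"probe_id": str})
    if "probe_id" not in df.columns:
        raise ValidationError(f"{path}: first column must be 'probe_id'")
    df = df.set_index("probe_id")
    missing = probe_map.probe_ids.difference(df.index)
    if len(missing):
        raise ValidationError(
            f"{path}: missing intensity rows for {len(missing)} probe(s), "
            f"e.g. {list(missing[:5])}"
        )
    df = df.loc[probe_map.probe_ids].reset_index(drop=True)
    return IntensityMatrix(probe_map, df, list(samples))


def write_intensity_table(matrix: IntensityMatrix, path: str) -> None:
    out = matrix.values.copy()
    out.insert(0, "probe_id", matrix.probe_map.df["probe_id"].to_numpy())
    out.to_csv(path, sep="\t", index=False, float_format="%.17g")


# ---------------------------------------------------------------------------
# gene models and gene sets


def read_gene_models(path: str, format: str = "gff3") -> GeneModels:
    """Read gene models from GFF3 (``gene`` features; ID attribute) or BED
    (name + strand columns).  TSS is derived from strand on load."""
    if format == "gff3":
        g = pr.read_gff3(path).df
        if "Feature" in g.columns:
            g = g[g["Feature"] == "gene"]
        if "Strand" not in g.columns or g["Strand"].isin([".", ""]).any():
            raise ValidationError(f"{path}: gene records lack a strand field")
        name_col = "ID" if "ID" in g.columns else "Name"
        df = pd.DataFrame(
            {
                "gene_id": g[name_col].astype(str),
                "chrom": g["Chromosome"].astype(str),
                "start": g["Start"],
                "end": g["End"],
                "strand": g["Strand"].astype(str),
            }
        )
    elif format == "bed":
        g = pr.read_bed(path).df
        if "Strand" not in g.columns:
            raise ValidationError(f"{path}: BED gene file needs a strand column (BED6+)")
        df = pd.DataFrame(
            {
                "gene_id": g["Name"].astype(str),
                "chrom": g["Chromosome"].astype(str),
                "start": g["Start"],
                "end": g["End"],
                "strand": g["Strand"].astype(str),
            }
        )
    else:
        raise ValueError(f"unknown gene model format {format!r}")
    try:
        return GeneModels(df.reset_index(drop=True))
    except ValidationError as e:
        raise ValidationError(f"{path}: {e}") from e


def write_gene_models_gff3(genes: GeneModels, path: str, source: str = "tilepc") -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for r in genes.df.itertuples():
            fh.write(
                f"{r.chrom}\t{source}\tgene\t{r.start + 1}\t{r.end}\t.\t{r.strand}\t.\t"
                f"ID={r.gene_id}\n"
            )


def read_gene_set(path: str, name: str | None = None) -> GeneSet:
    """One gene_id per line; blank lines and '#' comments ignored."""
    with open(path) as fh:
        ids = [ln.strip() for ln in fh if ln.strip() and not ln.startswith("#")]
    return GeneSet.from_ids(name or os.path.splitext(os.path.basename(path))[0], ids)


def write_gene_set(gene_set: GeneSet, path: str) -> None:
    with open(path, "w") as fh:
        for g in sorted(gene_set.members):
            fh.write(g + "\n")


def read_domains(path: str) -> DomainAnnotation:
    """BED4 with the chromatin state label in the name column."""
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        names=["chrom", "start", "end", "state"], usecols=range(4),
        dtype={"chrom": str, "state": str},
    )
    try:
        return DomainAnnotation(df)
    except ValidationError as e:
        raise ValidationError(f"{path}: {e}") from e


# ---------------------------------------------------------------------------
# enrichment tracks


def write_track(track: EnrichmentTrack, path: str, format: str = "bedgraph") -> None:
    """Write a track as bedGraph (probe intervals) or fixedStep wiggle.

    Probes with missing scores are omitted.  Wiggle output requires uniform
    probe spacing within each chromosome.
    """
    pm = track.probe_map.df
    ok = track.defined
    if format == "bedgraph":
        with open(path, "w") as fh:
            name = track.condition or "track"
            fh.write(f'track type=bedGraph name="{name}"\n')
            for chrom, start, end, score in zip(
                pm["chrom"].to_numpy()[ok], pm["start"].to_numpy()[ok],
                pm["end"].to_numpy()[ok], track.scores[ok],
            ):
                fh.write(f"{chrom}\t{start}\t{end}\t{score:.17g}\n")
    elif format == "wig":
        with open(path, "w") as fh:
            name = track.condition or "track"
            fh.write(f'track type=wiggle_0 name="{name}"\n')
            for chrom in track.probe_map.chroms:
                sl = track.probe_map.chrom_slice(chrom)
                keep = ok[sl]
                starts = pm["start"].to_numpy()[sl][keep]
                if len(starts) == 0:
                    continue
                steps = np.unique(np.diff(starts))
                if len(steps) > 1:
                    raise ValidationError(
                        f"non-uniform probe spacing on {chrom}; use bedgraph format"
                    )
                step = int(steps[0]) if len(steps) else 1
                span = int((pm["end"].to_numpy()[sl][keep] - starts)[0])
                fh.write(f"fixedStep chrom={chrom} start={starts[0] + 1} step={step} span={span}\n")
                for score in track.scores[sl][keep]:
                    fh.write(f"{score:.17g}\n")
    else:
        raise ValueError(f"unknown track format {format!r}")


def read_track(path: str, probe_map: ProbeMap, condition: str = "") -> EnrichmentTrack:
    """Read a bedGraph written by :func:`write_track` back onto a ProbeMap.

    Records are matched to probes by (chrom, start); probes without a record
    get a missing score.
    """
    df = pd.read_csv(
        path, sep="\t", header=None, comment="t",  # skips the 'track ...' line
        names=["chrom", "start", "end", "score"],
        dtype={"chrom": str},
    )
    scores = np.full(len(probe_map), np.nan)
    key = pd.MultiIndex.from_frame(probe_map.df[["chrom", "start"]])
    rec = pd.Series(df["score"].to_numpy(), index=pd.MultiIndex.from_frame(df[["chrom", "start"]]))
    aligned = rec.reindex(key)
    scores[:] = aligned.to_numpy()
    return EnrichmentTrack(probe_map, scores, condition=condition)


# ---------------------------------------------------------------------------
# tabular results


def write_table(df: pd.DataFrame, path: str, index_label: str | None = None) -> None:
    """TSV with '.' for missing values."""
    df.to_csv(path, sep="\t", na_rep=MISSING, index=index_label is not None,
              index_label=index_label, float_format="%.6g")


def read_enrichment_table(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", na_values=[MISSING], dtype={"gene_id": str})
    return df.set_index("gene_id")


def write_peaks_bed(peaks, path: str) -> None:
    """Peaks as BED5-like TSV: chrom start end name midpoint_score."""
    with open(path, "w") as fh:
        for i, r in enumerate(peaks.df.itertuples(), start=1):
            score = MISSING if pd.isna(r.midpoint_score) else f"{r.midpoint_score:.6g}"
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\tpeak_{i}\t{score}\n")
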