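"""Gene assignment to five-state chromatin domains and per-state fold
enrichment of a gene set relative to a gene universe."""
from __future__ import annotations

import numpy as np
import pandas as pd
import pyranges as pr

from .core import (
    CHROMATIN_STATES,
    UNASSIGNED,
    DomainAnnotation,
    GeneModels,
    GeneSet,
    ValidationError,
)


def assign_gene_domains(
    genes: GeneModels, domains: DomainAnnotation, rule: str = "tss"
) -> pd.Series:
    """Map each gene to a chromatin state or to ``unassigned``.

    rule='tss': the state whose interval contains the TSS.
    rule='majority': the state covering the largest fraction of the gene
    body; ties and zero coverage give ``unassigned``.
    """
    if rule not in ("tss", "majority"):
        raise ValidationError(f"rule must be 'tss' or 'majority', got {rule!r}")
    dom = pr.PyRanges(
        domains.df.rename(
            columns={"chrom": "Chromosome", "start": "Start", "end": "End", "state": "state"}
        )
    )
    out = pd.Series(UNASSIGNED, index=genes.gene_ids.copy(), name="state")
    if rule == "tss":
        pts = pr.PyRanges(
            pd.DataFrame(
                {
                    "Chromosome": genes.df["chrom"].to_numpy(),
                    "Start": genes.df["tss"].to_numpy(),
                    "End": genes.df["tss"].to_numpy() + 1,
                    "gene_id": genes.df["gene_id"].to_numpy(),
                }
            )
        )
        hit = pts.join(dom).df
        if len(hit):
            out.loc[hit["gene_id"].to_numpy()] = hit["state"].to_numpy()
        return out
    bodies = pr.PyRanges(
        pd.DataFrame(
            {
                "Chromosome": genes.df["chrom"].to_numpy(),
                "Start": genes.df["start"].to_numpy(),
                "End": genes.df["end"].to_numpy(),
                "gene_id": genes.df["gene_id"].to_numpy(),
            }
        )
    )
    ov = bodies.join(dom).df
    if len(ov):
        ov["cov"] = np.minimum(ov["End"], ov["End_b"]) - np.maximum(ov["Start"], ov["Start_b"])
        cov = ov.groupby(["gene_id", "state"])["cov"].sum().unstack(fill_value=0)
        best = cov.idxmax(axis=1)
        top = cov.max(axis=1)
        tied = (cov.eq(top, axis=0)).sum(axis=1) > 1
        best[tied] = UNASSIGNED
        out.loc[best.index] = best
    return out


def domain_fold_enrichment(
    gene_set: GeneSet, assignment: pd.Series, universe: GeneSet
) -> pd.DataFrame:
    """Per-state percentages and fold enrichment of a set over a universe.

    For each state s, fold(s) = (fraction of set assigned s) / (fraction of
    universe assigned s), with unassigned genes excluded from both
    denominators; a state present in the set but absent from the universe
    gets fold = +inf.
    """
    if not gene_set.members <= universe.members:
        extra = sorted(gene_set.members - universe.members)[:5]
        raise ValidationError(f"set is not a subset of the universe (e.g. {extra})")
    missing = universe.members - set(assignment.index)
    if missing:
        raise ValidationError(
            f"assignment does not cover the universe ({len(missing)} genes missing)"
        )

    def fractions(ids: frozenset[str]) -> pd.Series:
        states = assignment.loc[sorted(ids)]
        assigned = states[states != UNASSIGNED]
        counts = assigned.value_counts().reindex(CHROMATIN_STATES, fill_value=0)
        total = counts.sum()
        if total == 0:
            raise ValidationError("no assigned genes in group")
        return counts / total

    f_set = fractions(gene_set.members)
    f_uni = fractions(universe.members)
    with np.errstate(divide="ignore", invalid="ignore"):
        fold = (f_set / f_uni).to_numpy()
    fold = np.where((f_uni.to_numpy() == 0) & (f_set.to_numpy() > 0), np.inf, fold)
    fold = np.where((f_uni.to_numpy() == 0) & (f_set.to_numpy() == 0), np.nan, fold)
    return pd.DataFrame(
        {
            "state": CHROMATIN_STATES,
            "set_pct": 100 * f_set.to_numpy(),
            "universe_pct": 100 * f_uni.to_numpy(),
            "fold": fold,
        }
    )
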