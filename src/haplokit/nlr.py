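"""Consensus cataloguing of NLR disease-resistance gene loci.

NLRs (nucleotide-binding leucine-rich repeat proteins) are the main class of
plant disease-resistance gene products.  Two independent lines of evidence
locate them in an assembly: a de-novo motif-based locus predictor run on the
genome sequence, and the functional descriptions of annotated gene models
(selected by resistance-associated keywords).  Either source alone
over-calls; the catalogue kept here is their positional consensus — the
annotated gene models that overlap a de-novo locus by at least one base
(half-open coordinates, so mere adjacency is not overlap).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd
from intervaltree import IntervalTree

from .alignment_io import GenomeInterval

__all__ = [
    "DEFAULT_KEYWORDS",
    "NlrLocus",
    "select_functional_genes",
    "consensus_nlrs",
    "nlr_census",
]

#: functional-description keywords marking resistance gene analogs
DEFAULT_KEYWORDS = ("Disease", "NBS-LRR", "NB-ARC")

SOURCES = ("denovo", "annotation")


@dataclass
class NlrLocus(GenomeInterval):
    """An NLR locus: a genomic interval tagged with its evidence source
    (de-novo predictor vs annotation keyword) and, for de-novo loci, an
    optional completeness flag from the predictor."""

    source: str = "annotation"
    complete: Optional[bool] = None

    def __post_init__(self) -> None:
        super().__post_init__()
        if self.source not in SOURCES:
            raise ValueError(f"unknown source {self.source!r} (expected {SOURCES})")


def select_functional_genes(
    genes: Iterable[GenomeInterval],
    keywords: Sequence[str] = DEFAULT_KEYWORDS,
    function_key: str = "function",
) -> list[NlrLocus]:
    """Select genes whose functional description contains any keyword as a
    case-insensitive substring; duplicates removed by gene id (first wins)."""
    kws = [k.lower() for k in keywords]
    seen: set[str] = set()
    out: list[NlrLocus] = []
    for g in genes:
        func = str(g.attributes.get(function_key, "")).lower()
        if not any(k in func for k in kws):
            continue
        if g.id in seen:
            continue
        seen.add(g.id)
        out.append(
            NlrLocus(
                chrom=g.chrom,
                start=g.start,
                end=g.end,
                id=g.id,
                strand=g.strand,
                attributes=dict(g.attributes),
                source="annotation",
            )
        )
    return out


def consensus_nlrs(
    denovo: Sequence[NlrLocus],
    annotated: Sequence[NlrLocus],
    min_overlap: int = 1,
    same_strand: bool = False,
    emit: str = "annotation",
) -> list[NlrLocus]:
    """Loci found by both methods: by default the annotated gene models that
    overlap >= ``min_overlap`` bases with at least one de-novo locus on the
    same chromosome (strand-agnostic unless ``same_strand``).  Each locus is
    reported once, sorted by (chrom, start).  ``emit='denovo'`` mirrors the
    call, reporting the supported de-novo loci instead.
    """
    if min_overlap < 1:
        raise ValueError("min_overlap must be >= 1")
    if emit not in ("annotation", "denovo"):
        raise ValueError(f"unknown emit mode {emit!r}")
    if emit == "denovo":
        keep, against = denovo, annotated
    else:
        keep, against = annotated, denovo

    if keep and against:
        shared = {l.chrom for l in keep} & {l.chrom for l in against}
        if not shared:
            warnings.warn(
                "no chromosome names shared between the two NLR tracks; "
                "possible naming-scheme mismatch",
                stacklevel=2,
            )

    trees: dict[str, IntervalTree] = {}
    for l in against:
        trees.setdefault(l.chrom, IntervalTree()).addi(l.start, l.end, l)

    out = []
    for l in keep:
        tree = trees.get(l.chrom)
        if tree is None:
            continue
        for iv in tree[l.start:l.end]:
            if same_strand and iv.data.strand != l.strand:
                continue
            if min(iv.end, l.end) - max(iv.begin, l.start) >= min_overlap:
                out.append(l)
                break
    return sorted(out, key=lambda l: (l.chrom, l.start, l.end, l.id))


def nlr_census(consensus_by_genome: Mapping[str, Sequence[NlrLocus]]) -> pd.DataFrame:
    """Per-genome, per-chromosome counts of consensus NLR loci (tidy table:
    genome, chrom, count, plus a per-genome ``total`` row; unplaced-scaffold
    bins such as chrUn appear as their own chromosome rows)."""
    rows = []
    for genome in sorted(consensus_by_genome):
        loci = consensus_by_genome[genome]
        per_chrom: dict[str, int] = {}
        for l in loci:
            per_chrom[l.chrom] = per_chrom.get(l.chrom, 0) + 1
        for chrom in sorted(per_chrom):
            rows.append({"genome": genome, "chrom": chrom, "count": per_chrom[chrom]})
        rows.append({"genome": genome, "chrom": "total", "count": len(loci)})
    return pd.DataFrame(rows, columns=["genome", "chrom", "count"])
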