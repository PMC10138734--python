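"""Readers and writers for alignment coordinate files and genomic intervals.

Whole-genome aligners emit pairwise local alignments in one of two tabular
dialects handled here: the MUMmer ``show-coords -T`` format (1-based,
inclusive coordinates; reverse-strand query alignments have start > end) and
minimap2's PAF (0-based, half-open; query coordinates always on the forward
strand, orientation in the strand column).  Both are normalised on read to a
single internal convention — 0-based half-open coordinates, forward-normalised
query intervals, explicit strand flag — so downstream binning and interval
arithmetic never see dialect differences.  BED output is therefore a direct
serialisation.

Also provided: BED6 and GFF3 interval reading, BED6 writing, and the
two-column chromosome-length TSV used to anchor bin grids and coverage
denominators.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

import gffutils

__all__ = [
    "AlignmentRecord",
    "GenomeInterval",
    "ParseError",
    "read_alignments",
    "write_alignments",
    "filter_alignments",
    "read_bed",
    "write_bed",
    "read_gff3",
    "read_chrom_lengths",
    "write_chrom_lengths",
    "round_half_up",
]

#: chromosome name -> length in bases
ChromLengths = Mapping[str, int]

DIALECTS = ("showcoords_tab", "paf")


class ParseError(ValueError):
    """Raised for malformed input lines; message names the offending line."""


def round_half_up(x: float, decimals: int = 0) -> float:
    """Round with ties away from zero (the convention used for medians and
    BED scores), unlike builtin/numpy banker's rounding."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class AlignmentRecord:
    """One pairwise local alignment between a reference and a query chromosome.

    Coordinates are 0-based half-open.  Query coordinates are stored on the
    forward strand regardless of alignment orientation; ``strand`` records the
    orientation.  ``pct_identity`` is 100 x matching bases / aligned bases.
    ``mapq`` is present only for dialects that carry it (PAF).
    """

    ref_chrom: str
    ref_start: int
    ref_end: int
    query_chrom: str
    query_start: int
    query_end: int
    strand: str = "+"
    pct_identity: float = 100.0
    mapq: Optional[int] = None

    def __post_init__(self) -> None:
        if self.ref_start < 0 or self.ref_start >= self.ref_end:
            raise ValueError(
                f"invalid reference interval {self.ref_chrom}:"
                f"{self.ref_start}-{self.ref_end}"
            )
        if not 0.0 <= self.pct_identity <= 100.0:
            raise ValueError(f"pct_identity out of range: {self.pct_identity}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"invalid strand: {self.strand!r}")

    @property
    def ref_span(self) -> int:
        """Aligned bases on the reference (ref_end - ref_start)."""
        return self.ref_end - self.ref_start

    @property
    def ref_midpoint(self) -> int:
        return (self.ref_start + self.ref_end) // 2


@dataclass
class GenomeInterval:
    """A located feature (gene, NLR locus, intersection segment) in 0-based
    half-open coordinates."""

    chrom: str
    start: int
    end: int
    id: str = "."
    strand: str = "."
    attributes: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}"
            )

    def __len__(self) -> int:
        return self.end - self.start

    def overlap(self, other: "GenomeInterval") -> int:
        """Overlap in bases with another interval (0 if different chromosome;
        half-open adjacency counts as 0)."""
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


# ---------------------------------------------------------------------------
# alignment dialects
# ---------------------------------------------------------------------------

def read_alignments(path, dialect: str) -> list[AlignmentRecord]:
    """Read pairwise alignments from *path* in the given dialect.

    ``showcoords_tab``: tab dialect of ``show-coords -T`` with columns
    S1 E1 S2 E2 LEN1 LEN2 %IDY REFNAME QRYNAME (1-based inclusive; S2 > E2
    marks a reverse-strand alignment).  Header lines are skipped.

    ``paf``: standard 12+-column PAF; percent identity is computed as
    matches / alignment-block-length x 100 and the target is taken as the
    reference.

    File order is preserved.  Malformed lines raise :class:`ParseError`
    naming the line number.
    """
    if dialect == "showcoords_tab":
        return _read_showcoords(path)
    if dialect == "paf":
        return _read_paf(path)
    raise ValueError(f"unknown dialect: {dialect!r} (expected one of {DIALECTS})")


_NUMERIC = re.compile(r"^-?\d+(\.\d+)?$")


def _looks_like_coords_data(fields: Sequence[str]) -> bool:
    return len(fields) >= 9 and all(_NUMERIC.match(f) for f in fields[:7])


def _read_showcoords(path) -> list[AlignmentRecord]:
    records: list[AlignmentRecord] = []
    data_started = False
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if not data_started:
                if not _looks_like_coords_data(fields):
                    continue  # header block (file names, NUCMER, column tags)
                data_started = True
            if not _looks_like_coords_data(fields):
                raise ParseError(f"{path}: malformed show-coords line {lineno}")
            s1, e1, s2, e2 = (int(f) for f in fields[:4])
            idy = float(fields[6])
            ref_name, qry_name = fields[7], fields[8]
            if s1 <= 0 or e1 <= 0 or s1 > e1:
                raise ParseError(
                    f"{path}: line {lineno}: negative or inverted reference "
                    f"coordinates {s1}..{e1}"
                )
            if s2 <= e2:
                strand, q_start, q_end = "+", s2 - 1, e2
            else:
                strand, q_start, q_end = "-", e2 - 1, s2
            try:
                records.append(
                    AlignmentRecord(
                        ref_chrom=ref_name,
                        ref_start=s1 - 1,
                        ref_end=e1,
                        query_chrom=qry_name,
                        query_start=q_start,
                        query_end=q_end,
                        strand=strand,
                        pct_identity=idy,
                    )
                )
            except ValueError as exc:
                raise ParseError(f"{path}: line {lineno}: {exc}") from exc
    return records


def _read_paf(path) -> list[AlignmentRecord]:
    records: list[AlignmentRecord] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 12:
                raise ParseError(
                    f"{path}: malformed PAF line {lineno} "
                    f"({len(fields)} columns, expected >= 12)"
                )
            try:
                q_start, q_end = int(fields[2]), int(fields[3])
                strand = fields[4]
                t_start, t_end = int(fields[7]), int(fields[8])
                matches, block_len = int(fields[9]), int(fields[10])
                mapq = int(fields[11])
            except ValueError as exc:
                raise ParseError(f"{path}: malformed PAF line {lineno}: {exc}") from exc
            if t_start < 0 or t_start >= t_end:
                raise ParseError(
                    f"{path}: line {lineno}: negative or inverted reference "
                    f"coordinates {t_start}..{t_end}"
                )
            if block_len <= 0:
                raise ParseError(f"{path}: line {lineno}: non-positive block length")
            try:
                records.append(
                    AlignmentRecord(
                        ref_chrom=fields[5],
                        ref_start=t_start,
                        ref_end=t_end,
                        query_chrom=fields[0],
                        query_start=q_start,
                        query_end=q_end,
                        strand=strand,
                        pct_identity=100.0 * matches / block_len,
                        mapq=mapq,
                    )
                )
            except ValueError as exc:
                raise ParseError(f"{path}: line {lineno}: {exc}") from exc
    return records


def write_alignments(records: Iterable[AlignmentRecord], path, dialect: str) -> None:
    """Write alignments in the given dialect, inverting the read-time
    normalisation so coordinate fields reproduce the source convention.

    The show-coords dialect round-trips every field exactly (identity is
    written at full float precision).  PAF requires an integer matches
    column, so percent identity is quantised to matches/block_len on write.
    """
    records = list(records)
    if dialect == "showcoords_tab":
        with open(path, "w") as fh:
            fh.write("/dev/null /dev/null\nNUCMER\n\n")
            fh.write("[S1]\t[E1]\t[S2]\t[E2]\t[LEN 1]\t[LEN 2]\t[% IDY]\t[TAGS]\n")
            for r in records:
                if r.strand == "+":
                    s2, e2 = r.query_start + 1, r.query_end
                else:
                    s2, e2 = r.query_end, r.query_start + 1
                fh.write(
                    f"{r.ref_start + 1}\t{r.ref_end}\t{s2}\t{e2}\t"
                    f"{r.ref_span}\t{r.query_end - r.query_start}\t"
                    f"{r.pct_identity!r}\t{r.ref_chrom}\t{r.query_chrom}\n"
                )
    elif dialect == "paf":
        with open(path, "w") as fh:
            for r in records:
                block_len = max(r.ref_span, r.query_end - r.query_start)
                matches = int(round(r.pct_identity * block_len / 100.0))
                mapq = 255 if r.mapq is None else r.mapq
                fh.write(
                    f"{r.query_chrom}\t{r.query_end}\t{r.query_start}\t"
                    f"{r.query_end}\t{r.strand}\t{r.ref_chrom}\t{r.ref_end}\t"
                    f"{r.ref_start}\t{r.ref_end}\t{matches}\t{block_len}\t{mapq}\n"
                )
    else:
        raise ValueError(f"unknown dialect: {dialect!r} (expected one of {DIALECTS})")


def filter_alignments(
    records: Sequence[AlignmentRecord],
    min_ref_span: int = 0,
    min_mapq: Optional[int] = None,
    chrom_pairing: Optional[Mapping[str, str]] = None,
) -> list[AlignmentRecord]:
    """Keep alignments with ``ref_span >= min_ref_span`` and, if requested,
    ``mapq >= min_mapq``; order preserved, input untouched.

    ``chrom_pairing`` optionally maps reference chromosome -> homologous query
    chromosome; records aligning off the homologous pair are dropped (a
    conservative screen against spurious repeat-driven alignments between
    non-homologous chromosomes; off by default).

    Requesting a MAPQ filter on records without MAPQ (show-coords input) is a
    dialect mismatch and raises ``ValueError``.
    """
    if min_ref_span < 0:
        raise ValueError("min_ref_span must be >= 0")
    out = []
    for r in records:
        if r.ref_span < min_ref_span:
            continue
        if min_mapq is not None:
            if r.mapq is None:
                raise ValueError(
                    "MAPQ filter requested but record lacks mapq "
                    "(dialect mismatch: show-coords carries no MAPQ)"
                )
            if r.mapq < min_mapq:
                continue
        if chrom_pairing is not None and chrom_pairing.get(r.ref_chrom) != r.query_chrom:
            continue
        out.append(r)
    return out


# ---------------------------------------------------------------------------
# intervals and chromosome lengths
# ---------------------------------------------------------------------------

def write_bed(items: Iterable, path) -> None:
    """Write intervals or haploblocks as BED6 (0-based half-open), sorted by
    (chrom, start).  For haploblocks the score column carries the median
    identity x 10, rounded half-up; plain intervals score 0."""
    rows = []
    for it in items:
        median = getattr(it, "median_identity", None)
        if median is not None:
            score = int(round_half_up(median * 10))
            name = getattr(it, "id", ".") or "."
        else:
            score = int(it.attributes.get("score", 0)) if it.attributes else 0
            name = it.id or "."
        strand = getattr(it, "strand", ".") or "."
        rows.append((it.chrom, it.start, it.end, name, score, strand))
    rows.sort(key=lambda r: (r[0], r[1], r[2]))
    with open(path, "w") as fh:
        for row in rows:
            fh.write("\t".join(str(x) for x in row) + "\n")


def read_bed(path) -> list[GenomeInterval]:
    """Read BED3/BED6 into :class:`GenomeInterval` (score kept in
    ``attributes['score']`` when present)."""
    out = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}: malformed BED line {lineno}")
            try:
                chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ParseError(f"{path}: malformed BED line {lineno}: {exc}") from exc
            name = fields[3] if len(fields) > 3 else "."
            attrs = {}
            if len(fields) > 4:
                attrs["score"] = fields[4]
            strand = fields[5] if len(fields) > 5 else "."
            try:
                out.append(GenomeInterval(chrom, start, end, name, strand, attrs))
            except ValueError as exc:
                raise ParseError(f"{path}: line {lineno}: {exc}") from exc
    return out


def read_gff3(path, feature_types: Optional[set[str]] = None) -> list[GenomeInterval]:
    """Read GFF3 features into :class:`GenomeInterval` (coordinates converted
    to 0-based half-open; all attributes kept as strings).

    ``feature_types`` restricts to the given column-3 types (e.g. {"gene"}).
    The feature id is the ``ID`` attribute when present.
    """
    out = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            try:
                feat = gffutils.feature.feature_from_line(line)
            except Exception as exc:  # gffutils raises bare exceptions
                raise ParseError(f"{path}: malformed GFF3 line {lineno}: {exc}") from exc
            if feature_types is not None and feat.featuretype not in feature_types:
                continue
            attrs = {k: ",".join(v) for k, v in feat.attributes.items()}
            fid = attrs.get("ID", ".")
            out.append(
                GenomeInterval(
                    chrom=feat.seqid,
                    start=feat.start - 1,
                    end=feat.end,
                    id=fid,
                    strand=feat.strand or ".",
                    attributes=attrs,
                )
            )
    return out


def read_chrom_lengths(path) -> dict[str, int]:
    """Read a two-column TSV of chromosome name and length in bases."""
    lengths: dict[str, int] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ParseError(f"{path}: malformed length line {lineno}")
            try:
                length = int(fields[1])
            except ValueError as exc:
                raise ParseError(f"{path}: malformed length line {lineno}: {exc}") from exc
            if length <= 0:
                raise ParseError(f"{path}: line {lineno}: non-positive length")
            lengths[fields[0]] = length
    return lengths


def write_chrom_lengths(lengths: ChromLengths, path) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(lengths):
            fh.write(f"{chrom}\t{lengths[chrom]}\n")
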