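"""Haploblock construction from binned whole-genome alignment identities.

A haploblock is a contiguous chromosomal region over which two genomes share
near-identical sequence.  The operational definition implemented here: take
all pairwise local alignments between a reference and a query genome, discard
short ones, assign each surviving alignment's percent identity to the fixed
5-Mb reference bin containing its midpoint, compute the per-bin median
identity, and merge adjacent bins into maximal runs — either runs sharing an
identical rounded median (``identical_median`` mode) or runs whose medians
all clear a similarity cutoff (``threshold`` mode).  Runs whose median fails
the per-pair cutoff (strictly greater by default, matching ">99%"/">95%"
conventions) are discarded.  Bins with no alignments carry no evidence of
shared ancestry and always terminate a run.

The module also provides the downstream interval arithmetic used on block
sets: multi-genome intersection, genome coverage, summary statistics, and
association of point features (e.g. NLR genes) with blocks.
"""

from __future__ import annotations

import hashlib
import json
import statistics
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional, Sequence

from intervaltree import IntervalTree

from .alignment_io import (
    AlignmentRecord,
    ChromLengths,
    GenomeInterval,
    filter_alignments,
    round_half_up,
)

__all__ = [
    "Bin",
    "Haploblock",
    "HaploblockSet",
    "HaploblockParams",
    "bin_alignments",
    "bin_median",
    "call_haploblocks",
    "genome_coverage",
    "block_summary",
    "intersect_haploblock_sets",
    "associate_intervals",
    "write_haploblocks_tsv",
    "read_haploblocks_tsv",
]

MERGE_MODES = ("identical_median", "threshold")


@dataclass
class HaploblockParams:
    """Tunable parameters of the haploblock caller.

    bin_size
        Width of the fixed reference bin grid, bases.  Default 5 Mb.
    min_aln_len
        Minimum reference span of an alignment to be used, bases.  Default
        20 kb (a 10-kb variant is in circulation for the same analysis; set
        explicitly to taste).
    identity_cutoff
        Per-pair similarity cutoff in percent: blocks whose median does not
        clear it are discarded.  95 for distant pairs, 99 for very close ones.
    merge_mode
        ``identical_median`` merges adjacent bins sharing the same rounded
        median; ``threshold`` merges adjacent bins whose medians all clear
        the cutoff.
    median_rounding
        Decimal places at which medians are rounded (half-up) before the
        identical-median comparison.  Float medians are almost never bitwise
        equal, so equality must be taken at finite precision.
    min_bins
        Minimum number of constituent bins for a block to be reported.
    strict_cutoff
        If true (default) the cutoff comparison is strictly greater.
    """

    bin_size: int = 5_000_000
    min_aln_len: int = 20_000
    identity_cutoff: float = 95.0
    merge_mode: str = "identical_median"
    median_rounding: int = 2
    min_bins: int = 1
    strict_cutoff: bool = True

    def __post_init__(self) -> None:
        if self.bin_size <= 0:
            raise ValueError("bin_size must be > 0")
        if not 0.0 <= self.identity_cutoff <= 100.0:
            raise ValueError("identity_cutoff must be in [0, 100]")
        if self.merge_mode not in MERGE_MODES:
            raise ValueError(
                f"unknown merge_mode {self.merge_mode!r} (expected one of {MERGE_MODES})"
            )
        if self.min_bins < 1:
            raise ValueError("min_bins must be >= 1")

    def passes_cutoff(self, median: float) -> bool:
        if self.strict_cutoff:
            return median > self.identity_cutoff
        return median >= self.identity_cutoff

    def digest(self) -> str:
        """Stable 8-hex digest of the parameter values, for output headers."""
        blob = json.dumps(self.__dict__, sort_keys=True).encode()
        return hashlib.sha1(blob).hexdigest()[:8]


@dataclass
class Bin:
    """One cell of the fixed bin grid on a reference chromosome, holding the
    percent identities of the alignments whose midpoints fall inside it."""

    chrom: str
    index: int
    start: int
    end: int
    identities: list[float] = field(default_factory=list)

    @property
    def n_alignments(self) -> int:
        return len(self.identities)


def bin_median(b: Bin, rounding: int = 2) -> Optional[float]:
    """Unweighted median of the bin's identities (mean of the central pair
    for even counts), rounded half-up to ``rounding`` decimals; ``None`` for
    an empty bin."""
    if not b.identities:
        return None
    return round_half_up(statistics.median(b.identities), rounding)


@dataclass
class Haploblock:
    """A maximal run of adjacent non-empty bins merged into one block.

    Boundaries are multiples of ``bin_size`` except a terminal truncation at
    the chromosome end.
    """

    chrom: str
    start: int
    end: int
    median_identity: float
    n_bins: int
    n_alignments: int
    id: str = "."

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise ValueError(f"invalid block {self.chrom}:{self.start}-{self.end}")
        if self.n_bins < 1 or self.n_alignments < 1:
            raise ValueError("haploblock must contain >= 1 bin and >= 1 alignment")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class HaploblockSet:
    """All haploblocks called for one (reference, query) genome pair, sorted
    by (chrom, start) and pairwise disjoint."""

    reference_genome: str
    query_genome: str
    params: HaploblockParams
    blocks: list[Haploblock] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.blocks = sorted(self.blocks, key=lambda b: (b.chrom, b.start))
        prev: Optional[Haploblock] = None
        for b in self.blocks:
            if prev is not None and prev.chrom == b.chrom and b.start < prev.end:
                raise ValueError(
                    f"overlapping haploblocks on {b.chrom}: "
                    f"{prev.start}-{prev.end} and {b.start}-{b.end}"
                )
            prev = b

    def __len__(self) -> int:
        return len(self.blocks)

    def __iter__(self):
        return iter(self.blocks)


# ---------------------------------------------------------------------------
# construction
# ---------------------------------------------------------------------------

def bin_alignments(
    records: Sequence[AlignmentRecord],
    bin_size: int,
    chrom_lengths: ChromLengths,
) -> list[Bin]:
    """Assign each alignment's identity to the bin containing its reference
    midpoint.  Returns every bin of every chromosome in the length table,
    empty ones included, ordered by (chrom, index)."""
    if bin_size <= 0:
        raise ValueError("bin_size must be > 0")
    grid: dict[str, list[Bin]] = {}
    for chrom in sorted(chrom_lengths):
        length = chrom_lengths[chrom]
        n_bins = (length + bin_size - 1) // bin_size
        grid[chrom] = [
            Bin(chrom, i, i * bin_size, min((i + 1) * bin_size, length))
            for i in range(n_bins)
        ]
    for r in records:
        if r.ref_chrom not in grid:
            raise ValueError(
                f"alignment on unknown chromosome {r.ref_chrom!r} "
                "(length table inconsistent with alignments)"
            )
        mid = r.ref_midpoint
        if mid >= chrom_lengths[r.ref_chrom]:
            raise ValueError(
                f"alignment midpoint {mid} beyond {r.ref_chrom} length "
                f"{chrom_lengths[r.ref_chrom]}"
            )
        grid[r.ref_chrom][mid // bin_size].identities.append(r.pct_identity)
    return [b for chrom in sorted(grid) for b in grid[chrom]]


def _runs(bins: Sequence[Bin], params: HaploblockParams):
    """Split one chromosome's bins into maximal mergeable runs, yielding
    (bins, medians) pairs.  Empty bins always terminate a run."""
    run: list[Bin] = []
    meds: list[float] = []
    for b in bins:
        m = bin_median(b, params.median_rounding)
        # empty bins (no evidence) and, in threshold mode, failing bins
        # can neither join nor start a run
        if m is None or (
            params.merge_mode == "threshold" and not params.passes_cutoff(m)
        ):
            if run:
                yield run, meds
            run, meds = [], []
            continue
        if params.merge_mode == "identical_median" and run and m != meds[-1]:
            yield run, meds
            run, meds = [], []
        run.append(b)
        meds.append(m)
    if run:
        yield run, meds


def call_haploblocks(
    records: Sequence[AlignmentRecord],
    params: HaploblockParams,
    chrom_lengths: ChromLengths,
    reference_genome: str = "reference",
    query_genome: str = "query",
) -> HaploblockSet:
    """Full haploblock pipeline for one genome pair: length filter, midpoint
    binning, per-bin medians, adjacent-bin merging, cutoff filter.

    An empty record list yields a valid empty set.
    """
    kept = filter_alignments(records, min_ref_span=params.min_aln_len)
    bins = bin_alignments(kept, params.bin_size, chrom_lengths)
    by_chrom: dict[str, list[Bin]] = {}
    for b in bins:
        by_chrom.setdefault(b.chrom, []).append(b)

    blocks: list[Haploblock] = []
    for chrom in sorted(by_chrom):
        for run, meds in _runs(by_chrom[chrom], params):
            if params.merge_mode == "identical_median":
                block_median = meds[0]
            else:
                block_median = round_half_up(
                    statistics.median(meds), params.median_rounding
                )
            if len(run) < params.min_bins or not params.passes_cutoff(block_median):
                continue
            blocks.append(
                Haploblock(
                    chrom=chrom,
                    start=run[0].start,
                    end=min(run[-1].end, chrom_lengths[chrom]),
                    median_identity=block_median,
                    n_bins=len(run),
                    n_alignments=sum(b.n_alignments for b in run),
                )
            )
    for i, b in enumerate(blocks):
        blocks[i] = replace(b, id=f"hb{i + 1:04d}")
    return HaploblockSet(reference_genome, query_genome, params, blocks)


# ---------------------------------------------------------------------------
# statistics and interval arithmetic
# ---------------------------------------------------------------------------

def genome_coverage(hset: HaploblockSet, chrom_lengths: ChromLengths) -> float:
    """Percent of the genome (sum of chromosome lengths) covered by the
    set's blocks."""
    covered = 0
    for b in hset:
        if b.chrom not in chrom_lengths or b.end > chrom_lengths[b.chrom]:
            raise ValueError(
                f"block {b.chrom}:{b.start}-{b.end} beyond chromosome length"
            )
        covered += len(b)
    total = sum(chrom_lengths.values())
    return 100.0 * covered / total


def block_summary(hset: HaploblockSet) -> dict:
    """Count, mean/min/max block length, and per-chromosome counts."""
    lengths = [len(b) for b in hset]
    per_chrom: dict[str, int] = {}
    for b in hset:
        per_chrom[b.chrom] = per_chrom.get(b.chrom, 0) + 1
    return {
        "count": len(lengths),
        "mean_length": (sum(lengths) / len(lengths)) if lengths else None,
        "min_length": min(lengths) if lengths else None,
        "max_length": max(lengths) if lengths else None,
        "per_chrom": per_chrom,
    }


def _coverage_intervals(hset: HaploblockSet) -> dict[str, list[tuple[int, int]]]:
    """Per-chromosome disjoint coverage intervals, merging abutting blocks."""
    cov: dict[str, list[tuple[int, int]]] = {}
    for b in hset:  # blocks already sorted
        ivs = cov.setdefault(b.chrom, [])
        if ivs and ivs[-1][1] >= b.start:
            ivs[-1] = (ivs[-1][0], max(ivs[-1][1], b.end))
        else:
            ivs.append((b.start, b.end))
    return cov


def _intersect_two(
    a: list[tuple[int, int]], b: list[tuple[int, int]]
) -> list[tuple[int, int]]:
    out, i, j = [], 0, 0
    while i < len(a) and j < len(b):
        lo = max(a[i][0], b[j][0])
        hi = min(a[i][1], b[j][1])
        if lo < hi:
            out.append((lo, hi))
        if a[i][1] < b[j][1]:
            i += 1
        else:
            j += 1
    return out


def intersect_haploblock_sets(sets: Sequence[HaploblockSet]) -> list[GenomeInterval]:
    """Maximal reference intervals covered by at least one block in EVERY
    input set (all sets must share the reference genome).  Output is disjoint
    and sorted; each interval's attributes record the medians of the blocks
    of each set overlapping it."""
    if len(sets) < 2:
        raise ValueError("need at least two haploblock sets to intersect")
    ref = sets[0].reference_genome
    for s in sets[1:]:
        if s.reference_genome != ref:
            raise ValueError(
                f"mismatched reference genomes: {ref!r} vs {s.reference_genome!r}"
            )
    coverages = [_coverage_intervals(s) for s in sets]
    chroms = set(coverages[0])
    for cov in coverages[1:]:
        chroms &= set(cov)

    trees = []
    for s in sets:
        t: dict[str, IntervalTree] = {}
        for b in s:
            t.setdefault(b.chrom, IntervalTree()).addi(b.start, b.end, b)
        trees.append(t)

    out: list[GenomeInterval] = []
    for chrom in sorted(chroms):
        common = coverages[0][chrom]
        for cov in coverages[1:]:
            common = _intersect_two(common, cov[chrom])
        for start, end in common:
            attrs = {}
            for i, (s, tree) in enumerate(zip(sets, trees)):
                hits = sorted(tree[chrom][start:end], key=lambda iv: iv.begin)
                attrs[f"median_{i}_{s.query_genome}"] = ",".join(
                    repr(iv.data.median_identity) for iv in hits
                )
            out.append(
                GenomeInterval(
                    chrom, start, end, id=f"isect{len(out) + 1:04d}", attributes=attrs
                )
            )
    return out


def associate_intervals(
    hset: HaploblockSet, features: Iterable[GenomeInterval]
) -> dict[str, Optional[Haploblock]]:
    """Map each feature id to the haploblock it overlaps by >= 1 bp, or
    ``None``.  A feature spanning several blocks goes to the block with the
    larger overlap, ties to the leftmost."""
    trees: dict[str, IntervalTree] = {}
    for b in hset:
        trees.setdefault(b.chrom, IntervalTree()).addi(b.start, b.end, b)
    out: dict[str, Optional[Haploblock]] = {}
    for f in features:
        best: Optional[Haploblock] = None
        best_ov = 0
        tree = trees.get(f.chrom)
        if tree is not None:
            for iv in tree[f.start:f.end]:
                ov = min(iv.end, f.end) - max(iv.begin, f.start)
                if ov > best_ov or (ov == best_ov and ov > 0 and iv.begin < best.start):
                    best, best_ov = iv.data, ov
        out[f.id] = best
    return out


# ---------------------------------------------------------------------------
# TSV serialisation
# ---------------------------------------------------------------------------

_TSV_COLUMNS = (
    "reference",
    "query",
    "chrom",
    "start",
    "end",
    "n_bins",
    "n_alignments",
    "median_identity",
)


def write_haploblocks_tsv(hset: HaploblockSet, path, version: str = "") -> None:
    """Write a block table with a header comment carrying the tool version
    and a digest of the calling parameters (no timestamps: reruns are
    byte-identical)."""
    with open(path, "w") as fh:
        fh.write(f"#haplokit{(' ' + version) if version else ''} params={hset.params.digest()}\n")
        fh.write("\t".join(_TSV_COLUMNS) + "\n")
        for b in hset:
            fh.write(
                f"{hset.reference_genome}\t{hset.query_genome}\t{b.chrom}\t"
                f"{b.start}\t{b.end}\t{b.n_bins}\t{b.n_alignments}\t"
                f"{b.median_identity!r}\n"
            )


def read_haploblocks_tsv(path, params: Optional[HaploblockParams] = None) -> HaploblockSet:
    """Read a block table written by :func:`write_haploblocks_tsv`."""
    blocks = []
    ref = query = None
    with open(path) as fh:
        header_seen = False
        for raw in fh:
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            if not header_seen:
                header_seen = True  # column header
                continue
            f = line.split("\t")
            ref, query = f[0], f[1]
            blocks.append(
                Haploblock(
                    chrom=f[2],
                    start=int(f[3]),
                    end=int(f[4]),
                    median_identity=float(f[7]),
                    n_bins=int(f[5]),
                    n_alignments=int(f[6]),
                )
            )
    return HaploblockSet(
        ref or "reference", query or "query", params or HaploblockParams(), blocks
    )
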