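"""Shared fixtures and independent brute-force oracles.

The oracles here are deliberately naive re-derivations (sort-based medians,
explicit run enumeration, per-base bitmaps, quadratic overlap scans) kept
independent of the library code paths they check.
"""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pytest
from hypothesis import settings

from haplokit.alignment_io import AlignmentRecord

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


def dec_round(x: float, nd: int = 2) -> float:
    """Independent half-up rounding via Decimal."""
    return float(
        Decimal(repr(float(x))).quantize(Decimal(1).scaleb(-nd), rounding=ROUND_HALF_UP)
    )


def sort_median(values, nd=None):
    """Sort-based median: middle element, or mean of the central pair."""
    s = sorted(values)
    k = len(s)
    m = s[k // 2] if k % 2 else (s[k // 2 - 1] + s[k // 2]) / 2.0
    return dec_round(m, nd) if nd is not None else m


def records_from_bins(bin_lists, bin_size=5_000_000, chrom="chr1S", span=30_000):
    """Alignment records whose midpoints land in prescribed bins, one record
    per identity value, all passing a 20-kb length filter."""
    records = []
    for i, identities in enumerate(bin_lists):
        for k, ident in enumerate(identities):
            start = i * bin_size + k * (span + 10_000)
            records.append(
                AlignmentRecord(
                    ref_chrom=chrom,
                    ref_start=start,
                    ref_end=start + span,
                    query_chrom=chrom,
                    query_start=start,
                    query_end=start + span,
                    strand="+",
                    pct_identity=ident,
                )
            )
    return records


def oracle_call(bin_lists, bin_size, chrom_len, cutoff, mode, nd=2, min_bins=1):
    """Explicit run-enumeration oracle for haploblock calling on one
    chromosome.  Returns (start, end, median, n_bins, n_alignments) tuples."""
    meds = [sort_median(ids, nd) if ids else None for ids in bin_lists]
    n = len(meds)
    blocks = []
    i = 0
    while i < n:
        if meds[i] is None or (mode == "threshold" and not meds[i] > cutoff):
            i += 1
            continue
        j = i
        if mode == "identical_median":
            while j + 1 < n and meds[j + 1] == meds[i]:
                j += 1
            block_median = meds[i]
        else:
            while j + 1 < n and meds[j + 1] is not None and meds[j + 1] > cutoff:
                j += 1
            block_median = dec_round(sort_median(meds[i : j + 1]), nd)
        n_bins = j - i + 1
        if n_bins >= min_bins and block_median > cutoff:
            blocks.append(
                (
                    i * bin_size,
                    min((j + 1) * bin_size, chrom_len),
                    block_median,
                    n_bins,
                    sum(len(x) for x in bin_lists[i : j + 1]),
                )
            )
        i = j + 1
    return blocks


def random_bin_instance(rng, max_bins=20, p_empty=0.3, lo=90.0, hi=100.0):
    """Random per-bin identity lists for oracle-equivalence checks."""
    n_bins = int(rng.integers(1, max_bins + 1))
    return [
        []
        if rng.random() < p_empty
        else list(rng.uniform(lo, hi, size=int(rng.integers(1, 5))))
        for _ in range(n_bins)
    ]


def bitmap_coverage(intervals, length):
    """Per-base boolean coverage mask of [0, length)."""
    mask = np.zeros(length, dtype=bool)
    for start, end in intervals:
        mask[start:end] = True
    return mask


def quadratic_overlaps(features, blocks):
    """O(n*m) overlap scan: feature id -> (best overlap, block index) with
    ties to the leftmost block, or None."""
    out = {}
    for f in features:
        best = None
        best_ov = 0
        for bi, b in enumerate(blocks):
            if b.chrom != f.chrom:
                continue
            ov = min(b.end, f.end) - max(b.start, f.start)
            if ov <= 0:
                continue
            if ov > best_ov or (
                ov == best_ov and best is not None and b.start < blocks[best].start
            ):
                best, best_ov = bi, ov
        out[f.id] = best
    return out


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
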