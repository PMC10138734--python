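"""Rule-based confidence classification of predicted protein sequences.

Annotation pipelines for large Triticeae genomes over-predict: transcript
evidence and ab-initio callers emit fragments, pseudogenes and transposon
open reading frames alongside real genes.  The screen implemented here
classifies every predicted protein from its completeness (start and stop
codon present) and its best homology hit against three databases:

* ``UniMag`` — reviewed Magnoliophyta proteins (Swiss-Prot subset), the
  trusted reference set;
* ``UniPoa`` — Poaceae proteins (UniProt), a broader but less curated set;
* ``PTREP`` — hypothetical transposon proteins (TREP), used as a negative
  screen for mobile-element ORFs.

A hit qualifies when its E-value is below ``evalue_max`` (default 1e-10) and
its coverage exceeds ``cov_min`` (default 95%): subject coverage for the two
protein databases, query coverage for the transposon database.  Both
comparisons are strict, so boundary values (E-value exactly 1e-10, coverage
exactly 95) do not qualify.  Labels, with C/M/P/T = complete / qualified
UniMag / UniPoa / PTREP hit, evaluated in precedence order:

* ``HC``  (high confidence): C and a UniMag hit qualifying on BOTH subject
  and query coverage; or C with no UniMag hit, a UniPoa hit and no PTREP hit.
* ``REP`` (transposon): no UniMag hit, complete, PTREP hit.
* ``LC``  (low confidence): incomplete with a UniMag or UniPoa hit and no
  PTREP hit; or complete with no hit in any database.
* ``UNCLASSIFIED`` otherwise (the screen assigns such proteins no tag).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

__all__ = [
    "DATABASES",
    "LABELS",
    "HitEvidence",
    "ProteinEvidence",
    "ClassifierParams",
    "qualify_hit",
    "classify_protein",
    "classify_all",
    "read_hits_table",
    "read_completeness",
    "build_evidence",
    "write_labels_tsv",
]

DATABASES = ("UniMag", "UniPoa", "PTREP")
LABELS = ("HC", "LC", "REP", "UNCLASSIFIED")

# the transposon database appears in the wild under both names
_DB_ALIASES = {"TREP": "PTREP"}


def _norm_db(db: str) -> str:
    db = _DB_ALIASES.get(db, db)
    if db not in DATABASES:
        raise ValueError(f"unknown database {db!r} (expected one of {DATABASES})")
    return db


@dataclass
class HitEvidence:
    """Best hit of one protein against one database."""

    db: str
    evalue: float
    subject_coverage: float
    query_coverage: float

    def __post_init__(self) -> None:
        self.db = _norm_db(self.db)
        if self.evalue < 0:
            raise ValueError("evalue must be >= 0")
        for v in (self.subject_coverage, self.query_coverage):
            if not 0.0 <= v <= 100.0:
                raise ValueError(f"coverage out of range: {v}")


@dataclass
class ProteinEvidence:
    """Completeness flag plus at most one best hit per database."""

    protein_id: str
    complete: bool
    hits: dict[str, HitEvidence] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.hits = {_norm_db(k): v for k, v in self.hits.items()}


@dataclass
class ClassifierParams:
    """Thresholds and rule variants of the confidence screen.

    ``hc2_requires_complete`` controls whether the second high-confidence
    clause (UniPoa hit, no UniMag, no PTREP) also demands a complete protein;
    the conservative reading (default) requires it.
    """

    evalue_max: float = 1e-10
    cov_min: float = 95.0
    hc2_requires_complete: bool = True


def qualify_hit(
    hit: Optional[HitEvidence],
    evalue_max: float = 1e-10,
    cov_min: float = 95.0,
    strict: bool = False,
) -> bool:
    """Whether a best hit counts as evidence.

    E-value must be strictly below ``evalue_max`` and the db-appropriate
    coverage strictly above ``cov_min``: subject coverage for the protein
    references (UniMag, UniPoa), query coverage for the transposon database
    (PTREP).  With ``strict=True`` (the first high-confidence clause on
    UniMag) BOTH subject and query coverage must exceed the threshold.
    ``None`` (no hit) never qualifies.
    """
    if hit is None:
        return False
    if not hit.evalue < evalue_max:
        return False
    if hit.db == "PTREP":
        return hit.query_coverage > cov_min
    if strict:
        return hit.subject_coverage > cov_min and hit.query_coverage > cov_min
    return hit.subject_coverage > cov_min


def classify_protein(
    ev: ProteinEvidence, params: Optional[ClassifierParams] = None
) -> str:
    """Assign one of ``HC``/``LC``/``REP``/``UNCLASSIFIED`` to a protein
    (unqualified hits count as no hit)."""
    p = params or ClassifierParams()
    c = ev.complete
    m = qualify_hit(ev.hits.get("UniMag"), p.evalue_max, p.cov_min)
    m_strict = qualify_hit(ev.hits.get("UniMag"), p.evalue_max, p.cov_min, strict=True)
    pq = qualify_hit(ev.hits.get("UniPoa"), p.evalue_max, p.cov_min)
    t = qualify_hit(ev.hits.get("PTREP"), p.evalue_max, p.cov_min)

    hc2_complete_ok = c if p.hc2_requires_complete else True
    if (c and m_strict) or (hc2_complete_ok and not m and pq and not t):
        return "HC"
    if not m and c and t:
        return "REP"
    if (not c and (m or pq) and not t) or (c and not m and not pq and not t):
        return "LC"
    return "UNCLASSIFIED"


def classify_all(
    evidence: Sequence[ProteinEvidence], params: Optional[ClassifierParams] = None
) -> tuple[dict[str, str], Counter]:
    """Classify a batch; returns (protein_id -> label, label counts).

    Labels are order-independent; duplicate protein ids are an input error.
    """
    seen = set()
    labels: dict[str, str] = {}
    for ev in evidence:
        if ev.protein_id in seen:
            raise ValueError(f"duplicate protein id {ev.protein_id!r}")
        seen.add(ev.protein_id)
        labels[ev.protein_id] = classify_protein(ev, params)
    counts = Counter(labels.values())
    for lab in LABELS:
        counts.setdefault(lab, 0)
    return labels, counts


# ---------------------------------------------------------------------------
# tabular input / output
# ---------------------------------------------------------------------------

#: 12-column tabular homology-search layout plus a database name column
HITS_COLUMNS = [
    "qseqid",
    "sseqid",
    "pident",
    "length",
    "mismatch",
    "gapopen",
    "qstart",
    "qend",
    "sstart",
    "send",
    "evalue",
    "bitscore",
    "db",
    "subject_coverage",
    "query_coverage",
]


def read_hits_table(path) -> pd.DataFrame:
    """Read a best-hit table: the standard 12 tabular homology-search columns
    plus ``db``, ``subject_coverage`` and ``query_coverage``.  No header."""
    df = pd.read_csv(path, sep="\t", names=HITS_COLUMNS, comment="#")
    df["db"] = df["db"].map(lambda d: _norm_db(str(d)))
    return df


def read_completeness(path) -> dict[str, bool]:
    """Read a two-column TSV protein_id <tab> complete (1/0, true/false)."""
    df = pd.read_csv(path, sep="\t", names=["protein_id", "complete"], comment="#")
    truthy = {"1", "true", "yes", "complete"}
    return {
        str(r.protein_id): str(r.complete).strip().lower() in truthy
        for r in df.itertuples()
    }


def build_evidence(
    hits: pd.DataFrame, completeness: Mapping[str, bool]
) -> list[ProteinEvidence]:
    """Assemble per-protein evidence, keeping the best (lowest E-value) hit
    per database.  Proteins present only in the completeness table get an
    empty hit set."""
    by_protein: dict[str, dict[str, HitEvidence]] = {
        pid: {} for pid in completeness
    }
    for row in hits.itertuples():
        pid = str(row.qseqid)
        if pid not in completeness:
            raise ValueError(f"hit for protein {pid!r} missing from completeness table")
        hit = HitEvidence(
            db=row.db,
            evalue=float(row.evalue),
            subject_coverage=float(row.subject_coverage),
            query_coverage=float(row.query_coverage),
        )
        current = by_protein[pid].get(hit.db)
        if current is None or hit.evalue < current.evalue:
            by_protein[pid][hit.db] = hit
    return [
        ProteinEvidence(pid, completeness[pid], hits=by_protein[pid])
        for pid in completeness
    ]


def write_labels_tsv(labels: Mapping[str, str], counts: Counter, prefix) -> None:
    """Write per-protein labels and a per-label count summary."""
    with open(f"{prefix}.labels.tsv", "w") as fh:
        fh.write("protein_id\tlabel\n")
        for pid in sorted(labels):
            fh.write(f"{pid}\t{labels[pid]}\n")
    with open(f"{prefix}.summary.tsv", "w") as fh:
        fh.write("label\tcount\n")
        for lab in LABELS:
            fh.write(f"{lab}\t{counts.get(lab, 0)}\n")
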