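"""Seeded synthetic inputs with known truth for every pipeline stage.

Real inputs to this pipeline are multi-gigabase genome assemblies and the
outputs of external aligner/orthology/locus-prediction runs.  The generators
here emulate the *statistical structure* those tools hand the pipeline, at
desk scale and with the ground truth attached:

* chromosome-scale alignment tilings whose percent identities are drawn from
  planted haplotype tracts plus Gaussian noise (with sub-threshold decoy
  alignments mixed in);
* genome pairs as FASTA, the query differing from the reference by a
  per-tract substitution rate;
* orthogroup tables with exact planted exclusive-sharing structure;
* protein hit-evidence covering every branch of the confidence classifier;
* paired de-novo/annotated NLR tracks with planted overlap.

Every generator draws from its own named pseudo-random stream derived from a
single integer seed, so outputs are byte-identical across reruns and adding
one generator call never perturbs another's stream.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .alignment_io import AlignmentRecord, GenomeInterval, write_bed
from .confidence import ClassifierParams, HitEvidence, ProteinEvidence
from .nlr import NlrLocus
from .orthogroups import OrthogroupTable

__all__ = [
    "TractSpec",
    "SimConfig",
    "NlrTrackConfig",
    "TRUTH_TABLE",
    "stream_rng",
    "simulate_alignments",
    "simulate_genome_pair",
    "simulate_orthogroup_table",
    "simulate_protein_evidence",
    "simulate_nlr_tracks",
]


def stream_rng(seed: int, stream: str) -> np.random.Generator:
    """Independent generator for a named stream under one master seed."""
    return np.random.default_rng([int(seed), zlib.crc32(stream.encode())])


@dataclass
class TractSpec:
    """A planted tract of known target identity on a reference chromosome
    (0-based half-open)."""

    chrom: str
    start: int
    end: int
    target_identity: float
    label: str = ""

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise ValueError(f"invalid tract {self.chrom}:{self.start}-{self.end}")
        if not 0.0 <= self.target_identity <= 100.0:
            raise ValueError("target_identity must be in [0, 100]")


@dataclass
class SimConfig:
    """Conditions of an alignment-tiling simulation.

    Alignments tile each chromosome left to right with mean length
    ``aln_mean_len`` (uniform jitter ``aln_len_jitter``) and uniform gaps up
    to ``aln_gap_max``; each alignment's identity is its midpoint tract's
    target plus N(0, ``noise_sd``) noise, clipped to [0, 100].  Regions not
    covered by a tract use ``background_identity``.  ``decoy_frac`` of tiling
    steps additionally emit a short sub-threshold alignment (shorter than
    ``decoy_max_len``), emulating the spurious short hits a length filter is
    there to remove.
    """

    chrom_lengths: dict[str, int]
    tracts: list[TractSpec] = field(default_factory=list)
    aln_mean_len: int = 30_000
    aln_len_jitter: int = 5_000
    aln_gap_max: int = 5_000
    noise_sd: float = 0.1
    background_identity: float = 90.0
    decoy_frac: float = 0.05
    decoy_max_len: int = 10_000
    seed: int = 0

    def __post_init__(self) -> None:
        by_chrom: dict[str, list[TractSpec]] = {}
        for t in self.tracts:
            if t.chrom not in self.chrom_lengths:
                raise ValueError(f"tract on unknown chromosome {t.chrom!r}")
            if t.end > self.chrom_lengths[t.chrom]:
                raise ValueError(f"tract {t.chrom}:{t.start}-{t.end} beyond chromosome")
            by_chrom.setdefault(t.chrom, []).append(t)
        for chrom, ts in by_chrom.items():
            ts.sort(key=lambda t: t.start)
            for a, b in zip(ts, ts[1:]):
                if b.start < a.end:
                    raise ValueError(
                        f"overlapping tracts on {chrom}: "
                        f"{a.start}-{a.end} and {b.start}-{b.end}"
                    )


def _tract_identity(config: SimConfig, chrom: str, pos: int) -> float:
    for t in config.tracts:
        if t.chrom == chrom and t.start <= pos < t.end:
            return t.target_identity
    return config.background_identity


def simulate_alignments(
    config: SimConfig,
) -> tuple[list[AlignmentRecord], list[TractSpec]]:
    """Generate an alignment tiling per the config; returns (records, truth
    tracts).  Deterministic under (config, seed)."""
    rng = stream_rng(config.seed, "alignments")
    records: list[AlignmentRecord] = []
    for chrom in sorted(config.chrom_lengths):
        length = config.chrom_lengths[chrom]
        pos = 0
        while True:
            aln_len = config.aln_mean_len + int(
                rng.integers(-config.aln_len_jitter, config.aln_len_jitter + 1)
            )
            aln_len = max(aln_len, 1)
            if pos + aln_len > length:
                break
            mid = pos + aln_len // 2
            ident = _tract_identity(config, chrom, mid)
            ident = float(np.clip(ident + rng.normal(0.0, config.noise_sd), 0.0, 100.0))
            records.append(
                AlignmentRecord(
                    ref_chrom=chrom,
                    ref_start=pos,
                    ref_end=pos + aln_len,
                    query_chrom=chrom,
                    query_start=pos,
                    query_end=pos + aln_len,
                    strand="+",
                    pct_identity=ident,
                )
            )
            if config.decoy_frac > 0 and rng.random() < config.decoy_frac:
                d_len = int(rng.integers(500, config.decoy_max_len))
                d_start = pos + aln_len // 4
                d_mid = d_start + d_len // 2
                if d_start + d_len <= length and d_mid < length:
                    d_ident = _tract_identity(config, chrom, d_mid)
                    d_ident = float(
                        np.clip(d_ident + rng.normal(0.0, 5.0), 0.0, 100.0)
                    )
                    records.append(
                        AlignmentRecord(
                            ref_chrom=chrom,
                            ref_start=d_start,
                            ref_end=d_start + d_len,
                            query_chrom=chrom,
                            query_start=d_start,
                            query_end=d_start + d_len,
                            strand="+",
                            pct_identity=d_ident,
                        )
                    )
            pos += aln_len + int(rng.integers(0, config.aln_gap_max + 1))
    return records, list(config.tracts)


_BASES = np.frombuffer(b"ACGT", dtype="S1")


def simulate_genome_pair(
    config: SimConfig, out_dir: Optional[Path] = None
) -> tuple[list[SeqRecord], list[SeqRecord], list[GenomeInterval]]:
    """Generate a (reference, query) genome pair: the query is the reference
    with substitutions at rate (100 - target_identity)/100 at uniformly
    random positions inside each tract (background rate elsewhere).

    Intended for desk-scale chromosomes (<= 10 Mb) so an external aligner can
    be slotted into the pipeline end to end.  If ``out_dir`` is given, writes
    ``reference.fasta``, ``query.fasta`` and ``truth.bed``.
    """
    for length in config.chrom_lengths.values():
        if length > 10_000_000:
            raise ValueError("genome-pair simulation is desk-scale: chromosomes <= 10 Mb")
    rng = stream_rng(config.seed, "genome_pair")
    ref_records, qry_records = [], []
    truth = [
        GenomeInterval(t.chrom, t.start, t.end, id=t.label or f"tract{i + 1}")
        for i, t in enumerate(config.tracts)
    ]
    for chrom in sorted(config.chrom_lengths):
        n = config.chrom_lengths[chrom]
        ref = _BASES[rng.integers(0, 4, size=n)]
        qry = ref.copy()
        rates = np.full(n, (100.0 - config.background_identity) / 100.0)
        for t in config.tracts:
            if t.chrom == chrom:
                rates[t.start:t.end] = (100.0 - t.target_identity) / 100.0
        hit = rng.random(n) < rates
        idx = np.flatnonzero(hit)
        if idx.size:
            # replace with a uniformly chosen *different* base
            shift = rng.integers(1, 4, size=idx.size)
            codes = np.searchsorted(_BASES, qry[idx])
            qry[idx] = _BASES[(codes + shift) % 4]
        ref_records.append(SeqRecord(Seq(ref.tobytes().decode()), id=chrom, description=""))
        qry_records.append(SeqRecord(Seq(qry.tobytes().decode()), id=chrom, description=""))
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        SeqIO.write(ref_records, out_dir / "reference.fasta", "fasta")
        SeqIO.write(qry_records, out_dir / "query.fasta", "fasta")
        write_bed(truth, out_dir / "truth.bed")
    return ref_records, qry_records, truth


def simulate_orthogroup_table(
    panel: Sequence[str],
    combination_counts: Mapping[Sequence[str], int],
    copy_model: str = "single",
    seed: int = 0,
) -> tuple[OrthogroupTable, dict[tuple[str, ...], int]]:
    """Generate an orthogroup table whose exclusive-sharing counts equal
    ``combination_counts`` exactly.

    ``copy_model='single'`` puts one gene per member genome per group;
    ``'random'`` puts 1-3.  Returns (table, truth counts keyed by tuple in
    panel order).
    """
    if copy_model not in ("single", "random"):
        raise ValueError(f"unknown copy_model {copy_model!r}")
    rng = stream_rng(seed, "orthogroups")
    order = {g: i for i, g in enumerate(panel)}
    truth: dict[tuple[str, ...], int] = {}
    groups: dict[str, dict[str, list[str]]] = {}
    serial = gene_serial = 0
    for combo, count in sorted(
        combination_counts.items(), key=lambda kv: tuple(sorted(kv[0]))
    ):
        combo_t = tuple(sorted(set(combo), key=order.__getitem__))
        if not combo_t:
            raise ValueError("empty genome combination")
        unknown = set(combo_t) - set(panel)
        if unknown:
            raise ValueError(f"combination uses unknown genomes: {sorted(unknown)}")
        truth[combo_t] = truth.get(combo_t, 0) + count
        for _ in range(count):
            serial += 1
            gid = f"OG{serial:07d}"
            members: dict[str, list[str]] = {}
            for genome in combo_t:
                n_copies = 1 if copy_model == "single" else int(rng.integers(1, 4))
                genes = []
                for _ in range(n_copies):
                    gene_serial += 1
                    genes.append(f"{genome}|g{gene_serial:06d}")
                members[genome] = genes
            groups[gid] = members
    return OrthogroupTable(list(panel), groups), truth


# (complete, UniMag, UniPoa, PTREP) qualified-hit combination -> label.
# Written out clause by clause from the documented decision rules; the
# classifier must reproduce this table exactly.
TRUTH_TABLE: dict[tuple[bool, bool, bool, bool], str] = {
    # complete with a qualified UniMag hit: high confidence regardless of rest
    (True, True, False, False): "HC",
    (True, True, True, False): "HC",
    (True, True, False, True): "HC",
    (True, True, True, True): "HC",
    # complete, no UniMag, UniPoa and no transposon hit: high confidence
    (True, False, True, False): "HC",
    # complete, no UniMag, transposon hit: repeat-associated
    (True, False, True, True): "REP",
    (True, False, False, True): "REP",
    # complete with no hit anywhere: low confidence
    (True, False, False, False): "LC",
    # incomplete with protein-db support and no transposon hit: low confidence
    (False, True, False, False): "LC",
    (False, True, True, False): "LC",
    (False, False, True, False): "LC",
    # everything else is left untagged
    (False, True, False, True): "UNCLASSIFIED",
    (False, True, True, True): "UNCLASSIFIED",
    (False, False, True, True): "UNCLASSIFIED",
    (False, False, False, True): "UNCLASSIFIED",
    (False, False, False, False): "UNCLASSIFIED",
}


def _make_hit(
    rng: np.random.Generator,
    db: str,
    qualified: bool,
    params: ClassifierParams,
) -> Optional[HitEvidence]:
    """Draw a best hit on the requested side of the thresholds (qualified
    hits clear every relevant coverage so strict and plain qualification
    agree); unqualified evidence is no hit, a weak E-value, or low coverage."""
    lo, hi = params.cov_min, 100.0
    if qualified:
        return HitEvidence(
            db=db,
            evalue=float(10.0 ** -rng.uniform(12, 30)),
            subject_coverage=float(rng.uniform(lo + 0.5, hi)),
            query_coverage=float(rng.uniform(lo + 0.5, hi)),
        )
    mode = rng.integers(0, 3)
    if mode == 0:
        return None
    if mode == 1:  # strong coverage but E-value at/above the cutoff
        return HitEvidence(
            db=db,
            evalue=float(params.evalue_max * rng.uniform(1.0, 1e4)),
            subject_coverage=float(rng.uniform(lo + 0.5, hi)),
            query_coverage=float(rng.uniform(lo + 0.5, hi)),
        )
    return HitEvidence(  # strong E-value but coverage at/below the cutoff
        db=db,
        evalue=float(10.0 ** -rng.uniform(12, 30)),
        subject_coverage=float(rng.uniform(0.0, lo - 0.5)),
        query_coverage=float(rng.uniform(0.0, lo - 0.5)),
    )


def simulate_protein_evidence(
    n: int,
    label_mix: Optional[Mapping[str, float]] = None,
    seed: int = 0,
    params: Optional[ClassifierParams] = None,
) -> tuple[list[ProteinEvidence], dict[str, str]]:
    """Generate ``n`` proteins with evidence sampled per truth label.

    ``label_mix`` weights the four labels (default: uniform over the labels
    with a non-empty preimage).  Returns (evidence list, protein_id -> truth
    label).
    """
    p = params or ClassifierParams()
    rng = stream_rng(seed, "protein_evidence")
    by_label: dict[str, list[tuple[bool, bool, bool, bool]]] = {}
    for combo, label in TRUTH_TABLE.items():
        by_label.setdefault(label, []).append(combo)
    mix = dict(label_mix) if label_mix else {lab: 1.0 for lab in by_label}
    for lab in mix:
        if lab not in by_label:
            raise ValueError(f"unknown label {lab!r}")
    labels = sorted(mix)
    weights = np.array([mix[lab] for lab in labels], dtype=float)
    weights /= weights.sum()

    evidence: list[ProteinEvidence] = []
    truth: dict[str, str] = {}
    for i in range(n):
        label = labels[int(rng.choice(len(labels), p=weights))]
        combos = by_label[label]
        c, m, pq, t = combos[int(rng.integers(0, len(combos)))]
        pid = f"prot{i + 1:06d}"
        hits = {}
        for db, want in (("UniMag", m), ("UniPoa", pq), ("PTREP", t)):
            hit = _make_hit(rng, db, want, p)
            if hit is not None:
                hits[db] = hit
        evidence.append(ProteinEvidence(pid, complete=c, hits=hits))
        truth[pid] = label
    return evidence, truth


@dataclass
class NlrTrackConfig:
    """Conditions for paired de-novo/annotated NLR tracks.

    Each chromosome is divided into ``n_per_chrom`` slots; one annotated
    locus sits in the left part of each slot and, with probability
    ``overlap_frac``, a de-novo locus is planted overlapping it.  Extra
    unsupported de-novo loci go into the right part of slots, guaranteed
    clear of every annotated locus.
    """

    chrom_lengths: dict[str, int]
    n_per_chrom: int = 30
    overlap_frac: float = 0.5
    extra_denovo_frac: float = 0.3
    seed: int = 0


def simulate_nlr_tracks(
    config: NlrTrackConfig,
) -> tuple[list[NlrLocus], list[NlrLocus], set[str]]:
    """Generate (de-novo loci, annotated loci, truth) where truth is the set
    of annotated locus ids with a planted >= 1 bp de-novo overlap."""
    rng = stream_rng(config.seed, "nlr_tracks")
    denovo: list[NlrLocus] = []
    annotated: list[NlrLocus] = []
    truth: set[str] = set()
    serial = 0
    for chrom in sorted(config.chrom_lengths):
        length = config.chrom_lengths[chrom]
        slot = length // config.n_per_chrom
        if slot < 100:
            raise ValueError(f"chromosome {chrom} too short for {config.n_per_chrom} slots")
        for k in range(config.n_per_chrom):
            serial += 1
            base = k * slot
            gene_len = int(rng.integers(slot // 20 + 2, max(slot // 10, slot // 20 + 3)))
            gene = NlrLocus(
                chrom=chrom,
                start=base,
                end=base + gene_len,
                id=f"{chrom}_nlr{serial:05d}",
                strand="+" if rng.random() < 0.5 else "-",
                source="annotation",
                attributes={"function": "Disease resistance protein"},
            )
            annotated.append(gene)
            if rng.random() < config.overlap_frac:
                off = gene_len // 2  # overlap = gene_len - off >= 1
                denovo.append(
                    NlrLocus(
                        chrom=chrom,
                        start=base + off,
                        end=base + off + gene_len,
                        id=f"dn{serial:05d}",
                        strand="+",
                        source="denovo",
                        complete=bool(rng.random() < 0.7),
                    )
                )
                truth.add(gene.id)
            if rng.random() < config.extra_denovo_frac:
                # right 30% of the slot: disjoint from every annotated locus
                d_start = base + int(0.65 * slot)
                d_len = int(rng.integers(50, max(int(0.3 * slot), 51)))
                d_end = min(d_start + d_len, base + slot - 1)
                if d_end > d_start:
                    denovo.append(
                        NlrLocus(
                            chrom=chrom,
                            start=d_start,
                            end=d_end,
                            id=f"dnx{serial:05d}",
                            strand="+",
                            source="denovo",
                            complete=False,
                        )
                    )
    return denovo, annotated, truth
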