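"""Set algebra over orthogroup membership tables.

An orthogroup clusters the genes across a panel of genomes that descend from
one ancestral gene.  Orthology inference tools emit the clustering as a
tab-separated table — one row per group, one column per genome, gene ids
joined by ", " — which this module reads, post-processes and summarises:

* splitting polyploid annotations into their diploid subgenomes by gene-id
  pattern (a hexaploid wheat column becomes three diploid panel members);
* exclusive sharing counts — groups with genes in every member of a genome
  set and none outside it — the quantities behind upset plots;
* species-specific groups (exclusive to one genome);
* single-copy groups (exactly one gene in every panel member), the natural
  anchors for cross-genome comparison of gene families.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

__all__ = [
    "OrthogroupTable",
    "split_subgenomes",
    "exclusive_shared_count",
    "upset_counts",
    "single_copy_groups",
    "species_specific_groups",
    "read_orthogroups_tsv",
    "write_orthogroups_tsv",
]


@dataclass
class OrthogroupTable:
    """Ordered genome panel plus group_id -> genome -> gene-id list.

    Absent genomes may simply be missing from a group's mapping (equivalent
    to an empty list).  A gene id must not occur in more than one group.
    """

    panel: list[str]
    groups: dict[str, dict[str, list[str]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        panel_set = set(self.panel)
        if len(panel_set) != len(self.panel):
            raise ValueError("duplicate genome labels in panel")
        seen: dict[str, str] = {}
        for gid, members in self.groups.items():
            for genome, genes in members.items():
                if genome not in panel_set:
                    raise ValueError(
                        f"group {gid!r} references genome {genome!r} not in panel"
                    )
                for gene in genes:
                    if gene in seen:
                        raise ValueError(
                            f"gene {gene!r} appears in groups {seen[gene]!r} and {gid!r}"
                        )
                    seen[gene] = gid

    def __len__(self) -> int:
        return len(self.groups)

    def genomes_of(self, gid: str) -> frozenset[str]:
        """Panel members with at least one gene in the group."""
        return frozenset(
            g for g, genes in self.groups[gid].items() if genes
        )

    def gene_count(self) -> int:
        return sum(
            len(genes) for m in self.groups.values() for genes in m.values()
        )


def split_subgenomes(
    table: OrthogroupTable,
    rules: Mapping[str, Sequence[tuple[str, str]]],
) -> OrthogroupTable:
    """Split polyploid panel members into subgenomes by gene-id pattern.

    ``rules`` maps a genome label to (regular expression, subgenome label)
    pairs, e.g. ``{"CS": [(r"TraesCS\\d+A", "CS_A"), ...]}``.  Every gene of a
    split genome must match exactly one pattern; unmatched or ambiguous ids
    raise an error listing the offenders.  Genomes without rules pass
    through.  Gene counts are conserved.
    """
    compiled = {
        genome: [(re.compile(pat), label) for pat, label in rs]
        for genome, rs in rules.items()
    }
    new_panel: list[str] = []
    for g in table.panel:
        if g in compiled:
            new_panel.extend(label for _, label in compiled[g])
        else:
            new_panel.append(g)

    offenders: list[str] = []
    new_groups: dict[str, dict[str, list[str]]] = {}
    for gid, members in table.groups.items():
        new_members: dict[str, list[str]] = {}
        for genome, genes in members.items():
            if genome not in compiled:
                new_members.setdefault(genome, []).extend(genes)
                continue
            for gene in genes:
                matches = [lab for rx, lab in compiled[genome] if rx.search(gene)]
                if len(matches) != 1:
                    offenders.append(gene)
                    continue
                new_members.setdefault(matches[0], []).append(gene)
        new_groups[gid] = new_members
    if offenders:
        raise ValueError(
            "gene ids not matched by exactly one subgenome rule: "
            + ", ".join(sorted(offenders)[:20])
            + ("..." if len(offenders) > 20 else "")
        )
    return OrthogroupTable(new_panel, new_groups)


def exclusive_shared_count(table: OrthogroupTable, genome_set: Iterable[str]) -> int:
    """Groups with >= 1 gene in EVERY member of ``genome_set`` and none in
    any other panel genome."""
    gs = frozenset(genome_set)
    unknown = gs - set(table.panel)
    if unknown:
        raise ValueError(f"unknown genome labels: {sorted(unknown)}")
    return sum(1 for gid in table.groups if table.genomes_of(gid) == gs)


def upset_counts(table: OrthogroupTable) -> dict[tuple[str, ...], int]:
    """Exclusive sharing counts for every genome combination realised in the
    table (zero-count combinations omitted; keys are tuples in panel order).
    Counts sum to the number of groups."""
    order = {g: i for i, g in enumerate(table.panel)}
    counts: dict[tuple[str, ...], int] = {}
    for gid in table.groups:
        combo = tuple(sorted(table.genomes_of(gid), key=order.__getitem__))
        if not combo:
            continue
        counts[combo] = counts.get(combo, 0) + 1
    return counts


def single_copy_groups(
    table: OrthogroupTable,
    panel: Optional[Iterable[str]] = None,
    strict: bool = True,
) -> list[str]:
    """Groups with EXACTLY one gene in every genome of ``panel`` (default:
    the table's full panel).  With ``strict`` (default) a gene in any
    non-panel genome disqualifies the group; otherwise non-panel membership
    is ignored."""
    sel = list(panel) if panel is not None else list(table.panel)
    unknown = set(sel) - set(table.panel)
    if unknown:
        raise ValueError(f"unknown genome labels: {sorted(unknown)}")
    sel_set = set(sel)
    out = []
    for gid, members in table.groups.items():
        if any(len(members.get(g, [])) != 1 for g in sel):
            continue
        if strict and any(
            genes for g, genes in members.items() if g not in sel_set
        ):
            continue
        out.append(gid)
    return out


def species_specific_groups(table: OrthogroupTable) -> dict[str, int]:
    """Per genome, the number of groups exclusive to it."""
    counts = upset_counts(table)
    return {g: counts.get((g,), 0) for g in table.panel}


# ---------------------------------------------------------------------------
# TSV layout (orthology-tool standard: group id column + one column/genome)
# ---------------------------------------------------------------------------

def read_orthogroups_tsv(path) -> OrthogroupTable:
    """Read the de-facto standard orthogroup table: first column the group
    id, one column per genome, gene lists joined by ", "."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    panel = list(df.columns[1:])
    groups: dict[str, dict[str, list[str]]] = {}
    for row in df.itertuples(index=False):
        gid = row[0]
        members: dict[str, list[str]] = {}
        for genome, cell in zip(panel, row[1:]):
            genes = [g for g in (s.strip() for s in cell.split(",")) if g]
            if genes:
                members[genome] = genes
        groups[gid] = members
    return OrthogroupTable(panel, groups)


def write_orthogroups_tsv(table: OrthogroupTable, path) -> None:
    with open(path, "w") as fh:
        fh.write("Orthogroup\t" + "\t".join(table.panel) + "\n")
        for gid in sorted(table.groups):
            cells = [
                ", ".join(table.groups[gid].get(g, [])) for g in table.panel
            ]
            fh.write(gid + "\t" + "\t".join(cells) + "\n")
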