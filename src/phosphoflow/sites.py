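"""Localization filtering and aggregation of peptides into phosphosites,
phosphoislands and unphosphorylated counter groups.

A *phosphorylation site* is the set of phosphorylated residues on one
protein; peptide variants (missed cleavages, oxidation) carrying the same
residue set are merged.  Its log2 ratio is a two-level unweighted mean:
evidence entries are averaged within each replicate, then replicate means are
averaged for the final ratio.

A *phosphoisland* is a connected component of phosphopeptides that share at
least one phosphorylated residue; its *unphosphorylated counter group* (UCG)
pools all unphosphorylated peptides overlapping at least one of the island's
phosphorylated positions and is averaged the same way.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np

from .errors import AssemblyError
from .evidence_io import EvidenceRecord

PHOSPHO_ACCEPTORS = "STY"


@dataclass
class PhosphoSite:
    """A set of phosphorylated residues on one protein, one setup."""

    protein_id: str
    positions: tuple[int, ...]
    residues: str
    setup: str
    per_replicate_log2: dict[str, float]
    final_log2: float
    n_evidence: int

    @property
    def identity(self) -> tuple[str, tuple[int, ...]]:
        return (self.protein_id, self.positions)


@dataclass
class PhosphoIsland:
    """Connected component of phosphopeptides sharing phosphorylated
    residues, with its unphosphorylated counter group."""

    protein_id: str
    positions: tuple[int, ...]
    span: tuple[int, int]
    member_sites: list[PhosphoSite] = field(default_factory=list)
    ucg_log2: float | None = None
    ucg_n: int = 0


def isoform_probability(record: EvidenceRecord) -> float:
    """Product of the highest individual localization probabilities, one per
    phosphate group on the peptide."""
    k = len(record.phospho_positions)
    if k == 0:
        raise AssemblyError("isoform probability is undefined without phospho")
    probs = sorted(record.per_position_probability.values(), reverse=True)
    if not probs:
        return 1.0
    return math.prod(probs[:k])


def filter_localization(
    records: Iterable[EvidenceRecord], threshold: float = 0.70
) -> list[EvidenceRecord]:
    """Discard phosphopeptides with isoform probability strictly below the
    threshold (exactly 0.70 is retained); unphosphorylated records pass."""
    return [
        r
        for r in records
        if not r.is_phosphorylated or isoform_probability(r) >= threshold
    ]


def _site_residues(
    protein_id: str,
    positions: Sequence[int],
    records: Sequence[EvidenceRecord],
    proteome: Mapping[str, str] | None,
) -> str:
    letters = []
    for p in positions:
        letter = None
        for r in records:
            if r.peptide_start <= p <= r.peptide_end:
                letter = r.bare_sequence[p - r.peptide_start]
                break
        if proteome is not None:
            seq = proteome.get(protein_id)
            if seq is None or p > len(seq):
                raise AssemblyError(f"position {p} beyond protein {protein_id}")
            fasta_letter = seq[p - 1]
            if letter is not None and fasta_letter != letter:
                raise AssemblyError(
                    f"residue mismatch at {protein_id}:{p}: evidence says "
                    f"{letter}, FASTA says {fasta_letter}"
                )
            letter = fasta_letter
        if letter is None or letter not in PHOSPHO_ACCEPTORS:
            raise AssemblyError(
                f"{protein_id}:{p} is {letter!r}, not a phospho-acceptor"
            )
        letters.append(letter)
    return "".join(letters)


def _two_level_mean(records: Sequence[EvidenceRecord]) -> tuple[dict[str, float], float]:
    by_rep: dict[str, list[float]] = {}
    for r in records:
        if r.log2_corrected is None:
            raise AssemblyError("records must be normalized before assembly")
        by_rep.setdefault(r.replicate_id, []).append(r.log2_corrected)
    rep_means = {rep: float(np.mean(v)) for rep, v in sorted(by_rep.items())}
    return rep_means, float(np.mean(list(rep_means.values())))


def assemble_sites(
    records: Iterable[EvidenceRecord],
    proteome: Mapping[str, str] | None = None,
) -> list[PhosphoSite]:
    """Group normalized, localization-filtered phosphopeptides into sites.

    One site per (setup, protein, exact phosphorylated-position set);
    evidence entries are averaged per replicate, replicate means averaged for
    the final ratio.  When a proteome is given, the residue letter at every
    position is validated against it (mismatch is a hard error).
    """
    groups: dict[tuple[str, str, tuple[int, ...]], list[EvidenceRecord]] = {}
    for r in records:
        if not r.is_phosphorylated:
            continue
        groups.setdefault((r.setup_id, r.protein_id, r.phospho_positions), []).append(r)
    sites = []
    for (setup, pid, positions), grp in sorted(groups.items()):
        rep_means, final = _two_level_mean(grp)
        sites.append(
            PhosphoSite(
                protein_id=pid,
                positions=positions,
                residues=_site_residues(pid, positions, grp, proteome),
                setup=setup,
                per_replicate_log2=rep_means,
                final_log2=final,
                n_evidence=len(grp),
            )
        )
    return sites


def build_phosphoislands(
    records: Sequence[EvidenceRecord],
    proteome: Mapping[str, str] | None = None,
    attach_ucgs: bool = True,
) -> list[PhosphoIsland]:
    """Partition phosphopeptides into islands: connected components of the
    graph joining peptides that share >= 1 phosphorylated position.

    Records should come from one experiment run; pass ``attach_ucgs=False``
    to skip counter-group aggregation.
    """
    phospho = [r for r in records if r.is_phosphorylated]
    graph: nx.Graph = nx.Graph()
    graph.add_nodes_from(range(len(phospho)))
    pos_index: dict[tuple[str, int], list[int]] = {}
    for i, r in enumerate(phospho):
        for p in r.phospho_positions:
            pos_index.setdefault((r.protein_id, p), []).append(i)
    for members in pos_index.values():
        for j in members[1:]:
            graph.add_edge(members[0], j)
    islands = []
    for component in nx.connected_components(graph):
        member_records = [phospho[i] for i in sorted(component)]
        pid = member_records[0].protein_id
        positions = tuple(
            sorted({p for r in member_records for p in r.phospho_positions})
        )
        island = PhosphoIsland(
            protein_id=pid,
            positions=positions,
            span=(positions[0], positions[-1]),
            member_sites=assemble_sites(member_records, proteome),
        )
        if attach_ucgs:
            attach_ucg(island, records)
        islands.append(island)
    islands.sort(key=lambda isl: (isl.protein_id, isl.positions))
    return islands


def attach_ucg(
    island: PhosphoIsland, records: Iterable[EvidenceRecord]
) -> PhosphoIsland:
    """Attach the unphosphorylated counter group: all unphosphorylated
    peptides of the island's protein whose span covers at least one of the
    island's phosphorylated positions, averaged like a site.  The UCG ratio
    stays undefined (None) when no such peptide exists."""
    members = [
        r
        for r in records
        if not r.is_phosphorylated
        and r.protein_id == island.protein_id
        and any(r.peptide_start <= p <= r.peptide_end for p in island.positions)
    ]
    if members:
        _, island.ucg_log2 = _two_level_mean(members)
        island.ucg_n = len(members)
    else:
        island.ucg_log2 = None
        island.ucg_n = 0
    return island
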