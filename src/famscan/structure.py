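"""Exon/intron structure, splice phases, chromosome distribution and
motif presence/absence matrices."""

from __future__ import annotations

import pandas as pd

from .identify import scan_protein
from .models import GeneModel, MotifDefinition, ProteinRecord


def intron_count(gene: GeneModel) -> int:
    if not gene.exons:
        raise ValueError(f"gene {gene.id}: no exons")
    return len(gene.exons) - 1


def coding_exon_lengths(gene: GeneModel) -> list[int]:
    """Exon lengths in coding (5'->3') order; minus-strand genes reverse
    the genomic exon order first."""
    exons = sorted(gene.exons)
    if gene.strand == "-":
        exons = exons[::-1]
    return [e - s + 1 for s, e in exons]


def splice_phases(gene: GeneModel) -> list[int]:
    """Intron phases in the GSDS convention: cumulative upstream coding
    length mod 3 (0 = intron between codons).

    Note this differs from the GFF3 CDS ``phase`` column, which counts
    bases to skip to reach the next codon start; see
    :func:`gsds_phase_to_gff3`.
    """
    lengths = coding_exon_lengths(gene)
    if sum(lengths) % 3 != 0:
        raise ValueError(f"gene {gene.id}: CDS length not divisible by 3")
    phases = []
    cumulative = 0
    for length in lengths[:-1]:
        cumulative += length
        phases.append(cumulative % 3)
    return phases


def gsds_phase_to_gff3(phase: int) -> int:
    """Convert a GSDS intron phase to the GFF3 CDS phase of the next exon."""
    return (3 - phase) % 3


def structure_report(genes: list[GeneModel]) -> pd.DataFrame:
    rows = []
    for gene in genes:
        rows.append(
            {
                "id": gene.id,
                "chromosome": gene.chromosome,
                "intron_count": intron_count(gene),
                "exon_lengths": ",".join(map(str, coding_exon_lengths(gene))),
                "phases": ",".join(map(str, splice_phases(gene))),
            }
        )
    return pd.DataFrame(rows)


def chromosome_distribution(
    genes: list[GeneModel], chromosomes: tuple[str, ...] = tuple(str(i) for i in range(1, 13))
) -> pd.Series:
    """Gene counts per chromosome (all named chromosomes, zeros included)."""
    counts = pd.Series(0, index=list(chromosomes), dtype=int)
    for gene in genes:
        if gene.chromosome not in counts.index:
            raise ValueError(f"gene {gene.id}: unknown chromosome {gene.chromosome!r}")
        counts[gene.chromosome] += 1
    return counts


def occupied_chromosomes(counts: pd.Series) -> int:
    return int((counts > 0).sum())


def motif_presence_matrix(
    proteins: list[ProteinRecord],
    motifs: tuple[MotifDefinition, ...],
    threshold: float = 0.8,
) -> pd.DataFrame:
    """Boolean gene x motif presence matrix: present iff the best window's
    match fraction reaches ``threshold``."""
    data = {}
    for protein in proteins:
        hits = scan_protein(protein, motifs, presence_threshold=threshold)
        data[protein.id] = {f"Motif{h.motif_index}": h.fraction >= threshold for h in hits}
    frame = pd.DataFrame.from_dict(data, orient="index")
    return frame[[f"Motif{m.index}" for m in motifs]]


def subfamily_motif_summary(
    presence: pd.DataFrame, subfamily_of: dict[str, str]
) -> pd.DataFrame:
    """Per-subfamily fraction of members carrying each motif."""
    grouped = presence.groupby(presence.index.map(subfamily_of))
    return grouped.mean().sort_index()
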