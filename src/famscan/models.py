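"""Shared domain types for the famscan pipeline.

These are deliberately small, dumb containers: every analysis module takes
and returns these types so that the pipeline stages compose without any
stage knowing how its inputs were produced (simulated or read from disk).
"""

from __future__ import annotations

from dataclasses import dataclass, field


AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: Ambiguity letters allowed in motif consensus strings and the residues
#: each one is compatible with.  ``X`` matches any standard residue.
AMBIGUITY = {
    "B": frozenset("DN"),
    "Z": frozenset("EQ"),
    "J": frozenset("IL"),
    "X": frozenset(AMINO_ACIDS),
}


@dataclass(frozen=True)
class MotifDefinition:
    """A conserved protein motif given as a consensus string.

    The consensus is written over the 20 standard residues plus the
    ambiguity letters B (D/N), Z (E/Q), J (I/L) and X (any).
    """

    index: int
    consensus: str

    @property
    def width(self) -> int:
        return len(self.consensus)

    def __post_init__(self) -> None:
        if not 6 <= self.width <= 200:
            raise ValueError(
                f"motif {self.index}: width {self.width} outside [6, 200]"
            )
        bad = set(self.consensus) - set(AMINO_ACIDS) - set(AMBIGUITY)
        if bad:
            raise ValueError(f"motif {self.index}: invalid letters {sorted(bad)}")


@dataclass(frozen=True)
class ProteinRecord:
    """An amino-acid sequence with identity metadata."""

    id: str
    sequence: str
    description: str = ""

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class GeneModel:
    """A located gene with exon structure: the unit for structure and
    duplication analyses.

    Coordinates are 1-based inclusive (GFF3 convention); ``exons`` are CDS
    exons ordered 5'->3' on the coding strand.
    """

    id: str
    chromosome: str
    start: int
    end: int
    strand: str = "+"
    exons: list[tuple[int, int]] = field(default_factory=list)
    utrs: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        ex = sorted(self.exons)
        for (s1, e1), (s2, e2) in zip(ex, ex[1:]):
            if s2 <= e1:
                raise ValueError(f"gene {self.id}: overlapping exons")
        for s, e in ex:
            if s > e:
                raise ValueError(f"gene {self.id}: exon start > end")

    @property
    def cds_length(self) -> int:
        return sum(e - s + 1 for s, e in self.exons)


@dataclass(frozen=True)
class ScanHit:
    """Best-scoring window of one motif on one protein."""

    protein_id: str
    motif_index: int
    start: int  # 1-based position on the protein
    fraction: float  # fraction of consensus-compatible positions, in [0, 1]
    present: bool


@dataclass
class CandidateReport:
    """Per-protein outcome of the family-identification scan."""

    protein_id: str
    hits: dict[int, ScanHit]
    score: float
    evalue: float
    redundant: bool = False
    incomplete: bool = False
    verdict: str = "reject"


@dataclass
class ParalogPair:
    """A sister gene pair with alignment identity and duplication class."""

    gene_a: str
    gene_b: str
    identity: float
    distance_bp: int | None = None  # start-to-start, same chromosome only
    intervening_genes: int | None = None
    duplication_class: str = "unclassified"


@dataclass(frozen=True)
class CtRecord:
    """One qRT-PCR well pair: target and reference CT for a gene in one
    biological/technical replicate of one treatment."""

    gene_id: str
    treatment: str
    biological_replicate: int
    technical_replicate: int
    ct_target: float
    ct_reference: float


@dataclass
class CtTable:
    """Replicate CT measurements across genes and treatments."""

    records: list[CtRecord]
    reference_gene: str = "EF1a"
    control_label: str = "control"

    def genes(self) -> list[str]:
        return sorted({r.gene_id for r in self.records})

    def treatments(self) -> list[str]:
        return sorted({r.treatment for r in self.records})


@dataclass
class RegulationCall:
    """Relative-quantification verdict for one gene under one treatment."""

    gene_id: str
    treatment: str
    fold_change: float
    p_value: float
    call: str  # up | down | unchanged


@dataclass
class PlantedTruth:
    """Ground truth planted by the synthetic generator, used by tests and
    by the run report to audit recovery."""

    family_members: set[str]
    subfamily_of: dict[str, str]
    decoy_kind: dict[str, str]
    planted_pairs: list[tuple[str, str, str]]
    expression_pattern: dict[str, str]
    regulation_pattern: dict[str, dict[str, str]]


@dataclass
class GenomeBundle:
    """A complete synthetic dataset: chromosomes, gene models, proteins and
    the planted truth behind them."""

    chromosomes: list[tuple[str, int]]
    genes: list[GeneModel]
    proteins: list[ProteinRecord]
    cds: dict[str, str]
    truth: PlantedTruth

    def gene(self, gene_id: str) -> GeneModel:
        for g in self.genes:
            if g.id == gene_id:
                return g
        raise KeyError(gene_id)

    def protein(self, protein_id: str) -> ProteinRecord:
        for p in self.proteins:
            if p.id == protein_id:
                return p
        raise KeyError(protein_id)
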