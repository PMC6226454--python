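"""Curated reference data for the potato Hsp70 (StHsp70) gene family.

This module freezes the published characteristics of the 20 StHsp70 genes
of *Solanum tuberosum* — chromosome coordinates (printed as chromosome:kb
spans), ORF length, intron count, protein length, molecular weight and pI —
together with the ten conserved Hsp70 motifs (consensus strings with
ambiguity letters) and the subfamily structure of the family.  The
synthetic-data generator treats these values as the conditions to emulate;
the analysis modules never read them.

Two narrative-vs-table discrepancies in the source data are handled
explicitly:

* StHsp70-10 and StHsp70-11 are intron-less in the running text while the
  printed intron column reads 1; the generator follows the text by default
  (``table_intron_counts`` restores the printed column).
* The printed per-chromosome counts (chr8 carries one gene) are taken as
  authoritative over the text's "six chromosomes with two genes each".
"""

from __future__ import annotations

from dataclasses import dataclass

from .models import MotifDefinition

#: Hsp70 domain-architecture order used to assemble scaffold proteins:
#: N-terminal ATPase (NBD) motifs first, then substrate-binding domain and
#: C-terminal lid.  The published motif numbering is not positional, hence
#: this explicit order (configurable in the generator).
SCAFFOLD_MOTIF_ORDER = (7, 9, 1, 4, 2, 3, 5, 10, 6, 8)

#: The ten conserved Hsp70 motifs (index -> consensus).  Widths are implied
#: by the consensus strings (50,50,50,50,50,29,24,50,41,41; total 435).
MOTIFS: tuple[MotifDefinition, ...] = tuple(
    MotifDefinition(i, c)
    for i, c in [
        (1, "VKNAVVTVPAYFNDSQRQATKDAGVIAGLNVMRIINEPTAAAJAYGLDKK"),
        (2, "PLSLGJETAGGVMTVLIPRNTTIPTKKEQVFSTYSDNQPGVLIQVYEGER"),
        (3, "FDLGGGTFDVSJLTIEEGIFEVKATAGDTHLGGEDFDNRLVNHFVQEFKR"),
        (4, "TRARFEELNMDLFRKCMEPVEKCLRDAKLDKSDIHEVVLVGGSTRIPKVQ"),
        (5, "LGKFELSGIPPAPRGVPQIEVCFDIDANGILNVSAEDKTTGQKNKITITN"),
        (6, "FNGKELCKSINPDEAVAYGAAVQAAILSG"),
        (7, "VEIIANDQGNRTTPSYVAFTDTER"),
        (8, "KHKKDISGBPRALRRLRTACERAKRTLSSTAQTTIEIDSLYEGIDFYSTI"),
        (9, "GDAAKNQVAMNPENTVFDAKRLIGRRFSDPSVQSDMKLWPF"),
        (10, "AVDZAIEWLDSNQLAEADEFEDKMKELESICNPIIAKMYQG"),
    ]
)

#: Core motifs present in every family member; their joint presence is the
#: domain-completeness requirement of the identification filter.
CORE_MOTIFS = (1, 3, 4)


@dataclass(frozen=True)
class FamilyGene:
    """One curated family member: published locus and protein characteristics."""

    name: str
    chromosome: int
    start_kb: float
    end_kb: float
    orf_bp: int
    introns: int  # printed intron column
    length_aa: int
    mw_kda: float
    pi: float

    @property
    def start_bp(self) -> int:
        return round(self.start_kb * 1000)

    @property
    def end_bp(self) -> int:
        return round(self.end_kb * 1000)


FAMILY_TABLE: tuple[FamilyGene, ...] = tuple(
    FamilyGene(*row)
    for row in [
        ("StHsp70-1", 1, 80158.5, 80162.9, 2121, 7, 706, 75.15, 5.16),
        ("StHsp70-2", 12, 50389.4, 50395.4, 2613, 9, 870, 95.99, 5.34),
        ("StHsp70-3", 12, 50378.3, 50384.1, 2550, 8, 849, 93.57, 5.23),
        ("StHsp70-4", 1, 82924.1, 82928.6, 2025, 5, 674, 72.41, 5.95),
        ("StHsp70-5", 1, 82849.8, 82853.6, 2034, 5, 677, 72.78, 5.82),
        ("StHsp70-6", 7, 42050.3, 42058.2, 2673, 12, 890, 98.96, 5.83),
        ("StHsp70-7", 11, 38747.6, 38749.9, 1959, 1, 652, 71.31, 5.14),
        ("StHsp70-8", 6, 56528.0, 56531.0, 1947, 1, 648, 71.02, 5.04),
        ("StHsp70-9", 10, 51360.2, 51363.5, 1944, 1, 647, 70.89, 5.03),
        ("StHsp70-10", 3, 57412.2, 57414.4, 1965, 1, 654, 71.89, 5.21),
        ("StHsp70-11", 12, 49581.3, 49583.7, 1920, 1, 639, 70.80, 5.42),
        ("StHsp70-12", 9, 1958.6, 1962.0, 1950, 1, 649, 71.24, 5.13),
        ("StHsp70-13", 11, 38717.6, 38720.3, 1950, 1, 649, 71.20, 5.09),
        ("StHsp70-14", 9, 53571.5, 53573.5, 1722, 0, 573, 62.41, 5.53),
        ("StHsp70-15", 7, 1089.7, 1092.7, 1845, 1, 614, 67.47, 5.11),
        ("StHsp70-16", 6, 5489.7, 5492.1, 1461, 1, 486, 53.27, 5.48),
        ("StHsp70-17", 4, 7035.0, 7037.9, 1950, 1, 649, 71.23, 5.07),
        ("StHsp70-18", 8, 56395.4, 56399.8, 2004, 7, 667, 73.46, 5.04),
        ("StHsp70-19", 3, 45718.2, 45722.3, 2007, 7, 668, 73.61, 5.10),
        ("StHsp70-20", 1, 77390.8, 77394.2, 2010, 6, 669, 74.68, 5.32),
    ]
)

#: Genes that are intron-less per the narrative despite a printed count of 1.
NARRATIVE_INTRONLESS = ("StHsp70-10", "StHsp70-11")

#: Subfamily membership (sizes 10/3/3/1/3 for A..E).  A groups the
#: single/zero-intron cytosolic-like members, B and C the 5-7-intron
#: members, D the intron-less singleton, E the long >7-intron members.
SUBFAMILY_OF: dict[str, str] = {
    **{f"StHsp70-{i}": "A" for i in (7, 8, 9, 10, 11, 12, 13, 15, 16, 17)},
    **{f"StHsp70-{i}": "B" for i in (1, 18, 19)},
    **{f"StHsp70-{i}": "C" for i in (4, 5, 20)},
    "StHsp70-14": "D",
    **{f"StHsp70-{i}": "E" for i in (2, 3, 6)},
}

#: Per-member motif losses: StHsp70-6 lacks Motif 7, StHsp70-14 lacks
#: Motif 8; subfamily E lacks Motifs 2 and 5; Motif 10 is restricted to
#: subfamilies A and B.
MOTIF_LOSSES: dict[str, tuple[int, ...]] = {
    "StHsp70-6": (7, 2, 5, 10),
    "StHsp70-2": (2, 5, 10),
    "StHsp70-3": (2, 5, 10),
    "StHsp70-14": (8, 10),
    "StHsp70-4": (10,),
    "StHsp70-5": (10,),
    "StHsp70-20": (10,),
}

#: The five sister (cherry) pairs with their duplication class.
SISTER_PAIRS: tuple[tuple[str, str, str], ...] = (
    ("StHsp70-4", "StHsp70-5", "tandem"),
    ("StHsp70-7", "StHsp70-13", "tandem"),
    ("StHsp70-2", "StHsp70-3", "tandem"),
    ("StHsp70-18", "StHsp70-19", "segmental"),
    ("StHsp70-9", "StHsp70-12", "segmental"),
)

#: The eleven tissues of the expression atlas, in display order.
TISSUES = (
    "root",
    "leaf",
    "tuber",
    "stolon",
    "stamen",
    "petiole",
    "flower",
    "petal",
    "sepal",
    "carpel",
    "stem",
)

#: Tissue-expression pattern class per gene.  Classes:
#: broad        — expressed in every tissue
#: silent       — lowly expressed or not expressed anywhere
#: root_tuber   — expressed only in root and tuber
#: root_tuber_stolon — expressed only in root, tuber and stolon
#: not_stamen   — every tissue except stamen
#: vegetative   — high in root/tuber/stolon/leaf, low in stamen/stem/flower/sepal
EXPRESSION_PATTERN: dict[str, str] = {
    **{
        f"StHsp70-{i}": "broad"
        for i in (1, 2, 3, 5, 6, 7, 8, 9, 12, 13, 17, 18, 19)
    },
    "StHsp70-15": "silent",
    "StHsp70-16": "silent",
    "StHsp70-11": "root_tuber",
    "StHsp70-20": "root_tuber_stolon",
    "StHsp70-4": "not_stamen",
    "StHsp70-10": "vegetative",
    "StHsp70-14": "vegetative",
}

#: Tissues in which each pattern class is "on" (at the high mean);
#: ``vegetative`` genes additionally sit at an intermediate mean in the
#: tissues not listed as off.
PATTERN_ON_TISSUES: dict[str, tuple[str, ...]] = {
    "broad": TISSUES,
    "silent": (),
    "root_tuber": ("root", "tuber"),
    "root_tuber_stolon": ("root", "tuber", "stolon"),
    "not_stamen": tuple(t for t in TISSUES if t != "stamen"),
    "vegetative": ("root", "tuber", "stolon", "leaf"),
}

ABIOTIC_TREATMENTS = ("salt", "drought", "heat", "cold")
HORMONE_TREATMENTS = ("IAA", "ABA", "GA3", "SA")
BIOTIC_TREATMENTS = ("P.infestans", "BAP", "BABA", "BTH")
ALL_TREATMENTS = ABIOTIC_TREATMENTS + HORMONE_TREATMENTS + BIOTIC_TREATMENTS


def _regulation_pattern() -> dict[str, dict[str, str]]:
    """Planted regulation truth (gene -> treatment -> up/down/unchanged).

    Abiotic and the named hormone responses follow the published per-gene
    account; the hormone pattern is one fixed assignment consistent with
    the published marginal counts (6/8/8/4 genes changed under
    IAA/ABA/GA3/SA, down-calls dominating, StHsp70-8 up under all four,
    StHsp70-7 up under ABA+GA3, StHsp70-17 up under ABA/GA3/SA).
    """
    pat: dict[str, dict[str, str]] = {
        g.name: {t: "unchanged" for t in ALL_TREATMENTS} for g in FAMILY_TABLE
    }

    def mark(genes: tuple[int, ...], treatments: tuple[str, ...], call: str) -> None:
        for i in genes:
            for t in treatments:
                pat[f"StHsp70-{i}"][t] = call

    # abiotic stresses
    mark((1, 8, 9, 10, 17), ABIOTIC_TREATMENTS, "up")
    mark((2, 4, 13, 18), ABIOTIC_TREATMENTS, "down")
    mark((7,), ("drought",), "up")
    mark((7,), ("salt", "heat", "cold"), "down")
    mark((11,), ("salt", "drought"), "up")
    mark((16,), ("drought", "cold"), "up")
    mark((20,), ("drought", "heat", "cold"), "up")
    mark((19,), ("heat", "cold"), "down")
    # hormones
    mark((8,), HORMONE_TREATMENTS, "up")
    mark((7,), ("ABA", "GA3"), "up")
    mark((17,), ("ABA", "GA3", "SA"), "up")
    mark((2, 4, 13, 18, 3), ("IAA",), "down")
    mark((2, 4, 13, 18, 12), ("ABA",), "down")
    mark((2, 4, 13, 18, 5), ("GA3",), "down")
    mark((2, 13), ("SA",), "down")
    # biotic / induced-resistance chemicals
    mark((12,), ("P.infestans",), "up")
    mark((1, 8, 9, 10, 17), ("BABA",), "up")
    mark((2, 3, 4, 5, 6, 12, 13, 18, 19), ("BABA",), "down")
    mark(
        tuple(i for i in range(1, 21) if i not in (15, 16, 20)),
        ("BAP",),
        "down",
    )
    mark((1, 2, 3, 4, 5, 6, 8, 9, 10, 12, 13, 17, 18, 19), ("BTH",), "down")
    return pat


REGULATION_PATTERN: dict[str, dict[str, str]] = _regulation_pattern()

#: 12 chromosomes; lengths chosen so that every curated locus fits with
#: room for background genes (potato chromosomes are tens of Mb).
CHROMOSOME_LENGTHS: tuple[tuple[str, int], ...] = tuple(
    (str(i), 90_000_000) for i in range(1, 13)
)
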