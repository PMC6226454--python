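"""Synthetic potato-like dataset generator.

Builds a fully self-contained toy genome carrying a planted Hsp70-like
gene family with the statistical and positional structure the analysis
stages assume: 20 true members assembled from the ten published motifs
and evolved along a five-subfamily topology, placed at the published
chromosome:kb coordinates with the published intron counts; decoy
candidates (redundant isoform records and truncated fragments) plus
background genes; a tissue-expression matrix; and replicate qRT-PCR CT
tables with planted stress/hormone effects.

Everything is driven by a single integer seed; identical configurations
produce identical outputs.

Design notes
------------
* Motif positions evolve at a strongly attenuated substitution rate
  relative to linkers and tails (conserved domains vs spacers), so family
  membership stays detectable by motif scanning while the phylogenetic
  signal lives mostly in the spacers.
* Member lengths are matched to the published per-gene protein lengths by
  giving each subfamily ancestor an evolving C-terminal tail and trimming
  each leaf to its target (linker edits only; no general indel model).
"""

from __future__ import annotations

import itertools
import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .models import (
    AMBIGUITY,
    AMINO_ACIDS,
    CtRecord,
    CtTable,
    GeneModel,
    GenomeBundle,
    MotifDefinition,
    PlantedTruth,
    ProteinRecord,
)
from .reference import (
    ALL_TREATMENTS,
    CHROMOSOME_LENGTHS,
    CORE_MOTIFS,
    EXPRESSION_PATTERN,
    FAMILY_TABLE,
    MOTIF_LOSSES,
    MOTIFS,
    NARRATIVE_INTRONLESS,
    PATTERN_ON_TISSUES,
    REGULATION_PATTERN,
    SCAFFOLD_MOTIF_ORDER,
    SISTER_PAIRS,
    SUBFAMILY_OF,
    TISSUES,
)

#: Attenuation of the substitution rate inside motif segments relative to
#: linkers/tails (conserved domains evolve slowly).  The core motifs
#: shared by every member are the most constrained.
MOTIF_RATE_ATTENUATION = 0.12
CORE_MOTIF_RATE_ATTENUATION = 0.04

#: Codon table used for reverse translation (one codon per residue chosen
#: uniformly at random among synonymous codons).
_CODONS: dict[str, tuple[str, ...]] = {
    "A": ("GCT", "GCC", "GCA", "GCG"),
    "C": ("TGT", "TGC"),
    "D": ("GAT", "GAC"),
    "E": ("GAA", "GAG"),
    "F": ("TTT", "TTC"),
    "G": ("GGT", "GGC", "GGA", "GGG"),
    "H": ("CAT", "CAC"),
    "I": ("ATT", "ATC", "ATA"),
    "K": ("AAA", "AAG"),
    "L": ("TTA", "TTG", "CTT", "CTC", "CTA", "CTG"),
    "M": ("ATG",),
    "N": ("AAT", "AAC"),
    "P": ("CCT", "CCC", "CCA", "CCG"),
    "Q": ("CAA", "CAG"),
    "R": ("CGT", "CGC", "CGA", "CGG", "AGA", "AGG"),
    "S": ("TCT", "TCC", "TCA", "TCG", "AGT", "AGC"),
    "T": ("ACT", "ACC", "ACA", "ACG"),
    "V": ("GTT", "GTC", "GTA", "GTG"),
    "W": ("TGG",),
    "Y": ("TAT", "TAC"),
}
_STOPS = ("TAA", "TAG", "TGA")
_CODON_TO_AA = {c: aa for aa, cs in _CODONS.items() for c in cs}


def derive_seed(seed: int, stage: str) -> int:
    """Stage-specific seed derived from the top-level seed, so toggling
    one stage never shifts another stage's random stream."""
    return (seed * 1_000_003 + zlib.crc32(stage.encode())) % (2**31)


@dataclass(frozen=True)
class GeneratorConfig:
    """Knobs of the synthetic generator.  Defaults are the study
    conditions the downstream analyses are exercised under."""

    seed: int = 42
    n_true: int = 20
    n_decoys: int = 5
    n_background: int = 30
    substitution_rate_within: float = 0.05
    substitution_rate_between: float = 0.25
    linker_length_range: tuple[int, int] = (8, 18)
    fpkm_high: float = 100.0
    fpkm_low: float = 0.2
    expression_noise_sd: float = 0.25
    ct_effect: float = 2.0  # planted |ddCT| in cycles (2 -> 4-fold)
    ct_noise_sd: float = 0.2
    replicates: int = 3
    technical_replicates: int = 3
    table_intron_counts: bool = False
    motif_order: tuple[int, ...] = SCAFFOLD_MOTIF_ORDER

    def __post_init__(self) -> None:
        for rate in (self.substitution_rate_within, self.substitution_rate_between):
            if not 0.0 <= rate <= 0.9:
                raise ValueError(f"substitution rate {rate} outside [0, 0.9]")
        if self.replicates < 2:
            raise ValueError("need >= 2 biological replicates (t-test impossible)")
        lo, hi = self.linker_length_range
        if lo < 0 or hi < lo:
            raise ValueError("invalid linker length range")


# ---------------------------------------------------------------------------
# scaffold assembly and family evolution

@dataclass
class Segment:
    kind: str  # "motif" | "linker" | "tail"
    motif_index: int | None
    residues: list[str]


@dataclass
class _Member:
    """A leaf protein kept in segment form so motif regions stay
    addressable for deletions and truncations."""

    name: str
    segments: list[Segment]

    @property
    def sequence(self) -> str:
        return "".join("".join(s.residues) for s in self.segments)


def resolve_consensus(consensus: str, rng: np.random.Generator) -> list[str]:
    """Resolve ambiguity letters uniformly at random among their residues."""
    out = []
    for c in consensus:
        if c in AMBIGUITY:
            allowed = sorted(AMBIGUITY[c])
            out.append(allowed[rng.integers(len(allowed))])
        else:
            out.append(c)
    return out


def build_scaffold(
    motifs: tuple[MotifDefinition, ...] = MOTIFS,
    seed: int = 42,
    linker_length_range: tuple[int, int] = (8, 18),
    order: tuple[int, ...] = SCAFFOLD_MOTIF_ORDER,
) -> ProteinRecord:
    """One resolved instance of each motif in architecture order, joined
    by random linkers."""
    segments = _scaffold_segments(motifs, seed, linker_length_range, order)
    return ProteinRecord(
        "scaffold", "".join("".join(s.residues) for s in segments), "synthetic scaffold"
    )


def _scaffold_segments(
    motifs: tuple[MotifDefinition, ...],
    seed: int,
    linker_length_range: tuple[int, int],
    order: tuple[int, ...],
) -> list[Segment]:
    by_index = {m.index: m for m in motifs}
    missing = [i for i in order if i not in by_index]
    if missing:
        raise ValueError(f"motif list incomplete: missing indices {missing}")
    rng = np.random.default_rng(derive_seed(seed, "scaffold"))
    lo, hi = linker_length_range
    segments: list[Segment] = []
    for pos, index in enumerate(order):
        if pos > 0:
            length = int(rng.integers(lo, hi + 1)) if hi > 0 else 0
            linker = [AMINO_ACIDS[i] for i in rng.integers(0, 20, length)]
            segments.append(Segment("linker", None, linker))
        segments.append(Segment("motif", index, resolve_consensus(by_index[index].consensus, rng)))
    segments.append(Segment("tail", None, []))
    return segments


def _mutate(segments: list[Segment], rate: float, rng: np.random.Generator) -> list[Segment]:
    """Apply i.i.d. per-site substitutions; motif segments evolve at an
    attenuated rate."""
    out = []
    for seg in segments:
        if seg.kind == "motif":
            atten = (
                CORE_MOTIF_RATE_ATTENUATION
                if seg.motif_index in CORE_MOTIFS
                else MOTIF_RATE_ATTENUATION
            )
            seg_rate = rate * atten
        else:
            seg_rate = rate
        residues = list(seg.residues)
        if seg_rate > 0 and residues:
            hits = np.flatnonzero(rng.random(len(residues)) < seg_rate)
            for i in hits:
                choices = [aa for aa in AMINO_ACIDS if aa != residues[i]]
                residues[i] = choices[rng.integers(len(choices))]
        out.append(Segment(seg.kind, seg.motif_index, residues))
    return out


def _cherry(x: int, y: int):
    return ((x, "cherry_leaf"), (y, "cherry_leaf"))


def _build_topology():
    """Planted unrooted topology as nested (child, rate-kind) pairs.

    Subfamily A is a caterpillar with cherries (7,13) and (9,12) at its
    ends and the six remaining members attached along the spine, so the
    family's only cherries are the five planted sister pairs.  Sister
    pairs are recent duplicates, hence their leaves sit on short
    ``cherry_leaf`` branches.  Each subfamily ancestor is wrapped in an
    ``("extend", ...)`` marker where the shared C-terminal tail is grown
    before within-clade divergence.
    """
    node = _cherry(9, 12)
    for leaf in (17, 11, 10, 16, 15, 8):
        node = ((node, "spine"), (leaf, "terminal"))
    a_clade = ((node, "spine"), (_cherry(7, 13), "cherry_stem"))
    b_clade = ((_cherry(18, 19), "cherry_stem"), (1, "terminal"))
    c_clade = ((_cherry(4, 5), "cherry_stem"), (20, "terminal"))
    e_clade = ((_cherry(2, 3), "cherry_stem"), (6, "terminal"))
    ab = ((("extend", a_clade), "stemA"), (("extend", b_clade), "stem"))
    ce = ((("extend", c_clade), "stem"), (("extend", e_clade), "stem"))
    # root trifurcation: (A,B) | (C,E) | D
    return ((ab, "backbone"), (ce, "backbone"), (("extend", 14), "stem"))


_TOPOLOGY = _build_topology()

#: Spine edges are longer than terminal edges so the caterpillar backbone
#: of subfamily A is recovered reliably from finite sequences.
_SPINE_FACTOR = 1.8

#: The stem of the largest subfamily is longer than the other stems: the
#: big cytosolic-like clade is the most diverged from the rest of the
#: family, and its internal depth would otherwise mask its stem.
_STEM_A_FACTOR = 2.4

#: Sister-pair leaves are recent duplicates and sit on branches this much
#: shorter than singleton terminal branches.
_CHERRY_LEAF_FACTOR = 0.4


def _topology_leaves(spec) -> list[str]:
    if isinstance(spec, int):
        return [f"StHsp70-{spec}"]
    if spec and spec[0] == "extend":
        return _topology_leaves(spec[1])
    return [name for child, _rate in spec for name in _topology_leaves(child)]


def evolve_family(
    scaffold_segments: list[Segment],
    config: GeneratorConfig,
    motifs: tuple[MotifDefinition, ...] = MOTIFS,
) -> list[_Member]:
    """Evolve the 20 family members along the planted five-subfamily
    topology, applying the per-member motif losses and matching each
    member's length to its published protein length."""
    rng = np.random.default_rng(derive_seed(config.seed, "evolve"))
    width_of = {m.index: m.width for m in motifs}
    target_len = {g.name: g.length_aa for g in FAMILY_TABLE}
    rates = {
        "terminal": config.substitution_rate_within,
        "cherry_leaf": _CHERRY_LEAF_FACTOR * config.substitution_rate_within,
        "cherry_stem": config.substitution_rate_within,
        "spine": min(0.9, _SPINE_FACTOR * config.substitution_rate_within),
        "stem": config.substitution_rate_between,
        "stemA": min(0.9, _STEM_A_FACTOR * config.substitution_rate_between),
        "backbone": config.substitution_rate_between / 3.0,
    }
    members: list[_Member] = []

    def extend_tail(segments: list[Segment], leaves: list[str]) -> list[Segment]:
        current = sum(len(s.residues) for s in segments)
        needed = max(
            target_len[name] + sum(width_of[i] for i in MOTIF_LOSSES.get(name, ()))
            for name in leaves
        )
        add = max(0, needed - current)
        out = [Segment(s.kind, s.motif_index, list(s.residues)) for s in segments]
        out[-1].residues.extend(AMINO_ACIDS[i] for i in rng.integers(0, 20, add))
        return out

    def finalize_leaf(name: str, segments: list[Segment]) -> _Member:
        segs = [Segment(s.kind, s.motif_index, list(s.residues)) for s in segments]
        losses = MOTIF_LOSSES.get(name, ())
        segs = [s for s in segs if not (s.kind == "motif" and s.motif_index in losses)]
        member = _Member(name, segs)
        excess = len(member.sequence) - target_len[name]
        # length matching by linker edits: trim the tail, then linker ends
        for seg in reversed(segs):
            if excess <= 0:
                break
            if seg.kind in ("tail", "linker") and seg.residues:
                take = min(excess, len(seg.residues))
                del seg.residues[len(seg.residues) - take :]
                excess -= take
        if excess > 0:
            raise ValueError(f"{name}: cannot trim to target length {target_len[name]}")
        deficit = target_len[name] - len(member.sequence)
        if deficit > 0:
            segs[-1].residues.extend(AMINO_ACIDS[i] for i in rng.integers(0, 20, deficit))
        return member

    def walk(spec, segments: list[Segment]) -> None:
        if isinstance(spec, int):
            members.append(finalize_leaf(f"StHsp70-{spec}", segments))
            return
        if spec and spec[0] == "extend":
            walk(spec[1], extend_tail(segments, _topology_leaves(spec[1])))
            return
        for child, rate_kind in spec:
            walk(child, _mutate(segments, rates[rate_kind], rng))

    walk(_TOPOLOGY, scaffold_segments)
    order = {g.name: i for i, g in enumerate(FAMILY_TABLE)}
    members.sort(key=lambda m: order[m.name])
    if len(members) != len(FAMILY_TABLE):
        raise AssertionError("topology does not cover the family")
    return members


# ---------------------------------------------------------------------------
# genome placement

def translate(cds: str) -> str:
    """Translate a CDS (with terminal stop codon) to protein."""
    if len(cds) % 3 != 0:
        raise ValueError("CDS length not divisible by 3")
    codons = [cds[i : i + 3] for i in range(0, len(cds), 3)]
    if codons and codons[-1] in _STOPS:
        codons = codons[:-1]
    try:
        return "".join(_CODON_TO_AA[c] for c in codons)
    except KeyError as exc:
        raise ValueError(f"unknown codon {exc.args[0]!r}") from exc


def _reverse_translate(protein: str, rng: np.random.Generator) -> str:
    codons = []
    for aa in protein:
        options = _CODONS[aa]
        codons.append(options[rng.integers(len(options))])
    codons.append(_STOPS[rng.integers(len(_STOPS))])
    return "".join(codons)


def _make_exons(
    gene_start: int,
    gene_end: int,
    orf_bp: int,
    n_introns: int,
    rng: np.random.Generator,
    intron_range: tuple[int, int] = (100, 500),
) -> list[tuple[int, int]]:
    """Exon coordinates filling the locus from its start: introns placed
    uniformly at random inside the CDS, lengths uniform in
    ``intron_range`` (capped so everything fits the locus span)."""
    span = gene_end - gene_start + 1
    slack = span - orf_bp
    if n_introns == 0:
        return [(gene_start, gene_start + orf_bp - 1)]
    lo, hi = intron_range
    cap = max(lo, min(hi, slack // n_introns))
    lengths = [int(rng.integers(lo, cap + 1)) for _ in range(n_introns)]
    cuts = sorted(rng.choice(np.arange(1, orf_bp), size=n_introns, replace=False))
    exons = []
    prev_cut = 0
    genome_pos = gene_start
    for cut, ilen in zip(cuts, lengths):
        exon_len = cut - prev_cut
        exons.append((genome_pos, genome_pos + exon_len - 1))
        genome_pos += exon_len + ilen
        prev_cut = cut
    exons.append((genome_pos, genome_pos + (orf_bp - prev_cut) - 1))
    if exons[-1][1] > gene_end:
        raise ValueError("exons exceed locus span")
    return exons


def _excise_motif(member: _Member, motif_index: int, new_name: str) -> _Member:
    segs = [
        Segment(s.kind, s.motif_index, list(s.residues))
        for s in member.segments
        if not (s.kind == "motif" and s.motif_index == motif_index)
    ]
    return _Member(new_name, segs)


#: Truncated-fragment decoys: (source member number, excised core motif,
#: chromosome, start bp).  Loci sit on otherwise free chromosome arms.
_TRUNCATED_DECOYS = (
    (17, 1, "2", 12_000_000),
    (12, 3, "5", 30_000_000),
    (9, 4, "4", 30_000_000),
)

#: Redundant decoys: duplicate isoform records of these members, sharing
#: the member's locus.
_REDUNDANT_DECOYS = (1, 8)

#: Background genes planted between tandem-pair members so the
#: intervening-gene rule is exercised (chromosome, start bp): two genes
#: between StHsp70-5 and StHsp70-4, one between StHsp70-13 and StHsp70-7.
_PLANTED_BACKGROUND = (("1", 82_870_000), ("1", 82_890_000), ("11", 38_730_000))


def place_genes(members: list[_Member], config: GeneratorConfig) -> GenomeBundle:
    """Assemble the genome bundle: true members at the published loci,
    decoys, and background genes."""
    rng = np.random.default_rng(derive_seed(config.seed, "genome"))
    genes: list[GeneModel] = []
    proteins: list[ProteinRecord] = []
    cds_of: dict[str, str] = {}
    decoy_kind: dict[str, str] = {}
    by_name = {m.name: m for m in members}

    def add_gene(
        name: str,
        protein_seq: str,
        chromosome: str,
        start: int,
        end: int | None,
        n_introns: int,
        description: str = "",
    ) -> GeneModel:
        cds = _reverse_translate(protein_seq, rng)
        if end is None:
            end = start + len(cds) + n_introns * 500 + int(rng.integers(200, 800))
        exons = _make_exons(start, end, len(cds), n_introns, rng)
        utrs = []
        if exons[-1][1] < end:
            utrs.append((exons[-1][1] + 1, end))
        gene = GeneModel(name, chromosome, start, end, "+", exons, utrs)
        genes.append(gene)
        proteins.append(ProteinRecord(name, protein_seq, description))
        cds_of[name] = cds
        return gene

    table = {g.name: g for g in FAMILY_TABLE}
    for member in members:
        row = table[member.name]
        n_introns = row.introns
        if not config.table_intron_counts and member.name in NARRATIVE_INTRONLESS:
            n_introns = 0
        add_gene(
            member.name,
            member.sequence,
            str(row.chromosome),
            row.start_bp,
            row.end_bp,
            n_introns,
            description="family member",
        )

    if config.n_decoys > 0:
        for num in _REDUNDANT_DECOYS:
            row = table[f"StHsp70-{num}"]
            name = f"StHsp70-{num}_iso2"
            add_gene(
                name,
                by_name[f"StHsp70-{num}"].sequence,
                str(row.chromosome),
                row.start_bp,
                row.end_bp,
                0,
                description="redundant isoform record",
            )
            decoy_kind[name] = "redundant"
        for num, motif_index, chrom, start in _TRUNCATED_DECOYS:
            name = f"StHsp70-{num}_frag"
            fragment = _excise_motif(by_name[f"StHsp70-{num}"], motif_index, name)
            add_gene(
                name, fragment.sequence, chrom, start, None, 0,
                description="truncated fragment",
            )
            decoy_kind[name] = "truncated"

    n_planted = min(len(_PLANTED_BACKGROUND), config.n_background)
    chrom_cycle = itertools.cycle(str(i) for i in range(1, 13))
    placed = 0
    bg_index = 0
    while placed < config.n_background:
        name = f"BG-{placed + 1}"
        length = int(rng.integers(200, 501))
        protein_seq = "".join(AMINO_ACIDS[i] for i in rng.integers(0, 20, length))
        if placed < n_planted:
            chrom, start = _PLANTED_BACKGROUND[placed]
        else:
            chrom = next(chrom_cycle)
            start = int(rng.integers(1_000_000, 85_000_000))
            span_guess = length * 3 + 3 + 2000
            if any(
                g.chromosome == chrom and g.start <= start + span_guess and start <= g.end
                for g in genes
            ):
                bg_index += 1
                continue
        add_gene(name, protein_seq, chrom, start, None, int(rng.integers(0, 3)),
                 description="background gene")
        decoy_kind[name] = "background"
        placed += 1

    truth = PlantedTruth(
        family_members={m.name for m in members},
        subfamily_of=dict(SUBFAMILY_OF),
        decoy_kind=decoy_kind,
        planted_pairs=[tuple(p) for p in SISTER_PAIRS],
        expression_pattern=dict(EXPRESSION_PATTERN),
        regulation_pattern={g: dict(t) for g, t in REGULATION_PATTERN.items()},
    )
    return GenomeBundle(
        chromosomes=list(CHROMOSOME_LENGTHS),
        genes=genes,
        proteins=proteins,
        cds=cds_of,
        truth=truth,
    )


# ---------------------------------------------------------------------------
# expression and CT simulation

def simulate_expression(
    bundle: GenomeBundle,
    config: GeneratorConfig,
    tissues: tuple[str, ...] = TISSUES,
) -> pd.DataFrame:
    """FPKM matrix (family genes x tissues) honoring the planted
    tissue-pattern classes, with multiplicative log-normal noise."""
    if not tissues:
        raise ValueError("tissue list must be non-empty")
    rng = np.random.default_rng(derive_seed(config.seed, "expression"))
    names = [g.name for g in FAMILY_TABLE if g.name in bundle.truth.family_members]
    rows = []
    for name in names:
        pattern = bundle.truth.expression_pattern[name]
        on = set(PATTERN_ON_TISSUES[pattern])
        means = []
        for tissue in tissues:
            if pattern == "silent":
                means.append(config.fpkm_low)
            elif tissue in on:
                means.append(config.fpkm_high)
            elif pattern == "vegetative":
                means.append(config.fpkm_low)
            else:
                means.append(0.0)
        rows.append(means)
    values = np.asarray(rows, dtype=float)
    if config.expression_noise_sd > 0:
        noise = rng.lognormal(0.0, config.expression_noise_sd, values.shape)
        values = values * noise
    return pd.DataFrame(np.maximum(values, 0.0), index=names, columns=list(tissues))


def simulate_ct(
    bundle: GenomeBundle,
    config: GeneratorConfig,
    treatments: tuple[str, ...] = ALL_TREATMENTS,
    control_label: str = "control",
) -> CtTable:
    """Replicate CT tables with planted up/down shifts of magnitude
    ``ct_effect`` cycles (reference-gene CT constant in expectation)."""
    if config.replicates < 2:
        raise ValueError("need >= 2 biological replicates")
    rng = np.random.default_rng(derive_seed(config.seed, "ct"))
    names = [g.name for g in FAMILY_TABLE if g.name in bundle.truth.family_members]
    baseline = {name: 22.0 + 4.0 * rng.random() for name in names}
    records: list[CtRecord] = []
    tech_sd = config.ct_noise_sd / 2.0
    for name in names:
        pattern = bundle.truth.regulation_pattern[name]
        for treatment in (control_label, *treatments):
            if treatment == control_label:
                shift = 0.0
            else:
                direction = pattern.get(treatment, "unchanged")
                shift = {"up": -config.ct_effect, "down": config.ct_effect}.get(direction, 0.0)
            for bio in range(1, config.replicates + 1):
                bio_noise = rng.normal(0.0, config.ct_noise_sd) if config.ct_noise_sd else 0.0
                for tech in range(1, config.technical_replicates + 1):
                    eps_t = rng.normal(0.0, tech_sd) if tech_sd else 0.0
                    eps_r = rng.normal(0.0, tech_sd) if tech_sd else 0.0
                    records.append(
                        CtRecord(
                            gene_id=name,
                            treatment=treatment,
                            biological_replicate=bio,
                            technical_replicate=tech,
                            ct_target=baseline[name] + shift + bio_noise + eps_t,
                            ct_reference=20.0 + eps_r,
                        )
                    )
    return CtTable(records, reference_gene="EF1a", control_label=control_label)


def generate(config: GeneratorConfig | None = None) -> GenomeBundle:
    """Convenience: scaffold -> family -> genome bundle."""
    config = config or GeneratorConfig()
    segments = _scaffold_segments(
        MOTIFS, config.seed, config.linker_length_range, config.motif_order
    )
    members = evolve_family(segments, config)
    return place_genes(members, config)
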