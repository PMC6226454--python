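"""Family-member identification by consensus-motif scoring.

A profile-HMM search over a proteome is replaced here by a transparent
equivalent: each of the published consensus motifs is slid along every
protein, the best-matching window per motif is recorded as a match
fraction (ambiguity letters B/Z/J/X expanded), the family score is the
mean best fraction over the core motifs present in all members, and
significance is assessed with a permutation E-value computed from
residue-shuffled proteins.  Candidates passing the E-value threshold are
then subjected to redundancy and domain-completeness filters.
"""

from __future__ import annotations

import numpy as np

from .models import AMBIGUITY, AMINO_ACIDS, CandidateReport, GeneModel, MotifDefinition, ProteinRecord, ScanHit
from .reference import CORE_MOTIFS

#: Minimum best-window match fraction for a motif to count as present.
PRESENCE_THRESHOLD = 0.8

#: Default empirical E-value acceptance threshold.  The permutation
#: E-value has a floor of N_db/(n_shuffles+1), so at the default 999
#: shuffles a candidate passes only by outscoring every null replicate.
EVALUE_THRESHOLD = 0.1

DEFAULT_SHUFFLES = 999

_AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}


def encode_sequence(sequence: str) -> np.ndarray:
    """Encode a protein sequence as an int array over the 20 residues."""
    try:
        return np.fromiter(
            (_AA_INDEX[c] for c in sequence), dtype=np.int8, count=len(sequence)
        )
    except KeyError as exc:
        raise ValueError(f"non-standard residue {exc.args[0]!r} in sequence") from exc


def compatibility_matrix(motif: MotifDefinition) -> np.ndarray:
    """(width, 20) boolean matrix: which residues satisfy each consensus
    position (exact match, or within the ambiguity class)."""
    mat = np.zeros((motif.width, len(AMINO_ACIDS)), dtype=bool)
    for j, c in enumerate(motif.consensus):
        allowed = AMBIGUITY.get(c, frozenset((c,)))
        for aa in allowed:
            mat[j, _AA_INDEX[aa]] = True
    return mat


def match_fraction(window: str, motif: MotifDefinition) -> float:
    """Fraction of window positions compatible with the motif consensus."""
    if len(window) != motif.width:
        raise ValueError(
            f"window length {len(window)} != motif {motif.index} width {motif.width}"
        )
    compat = compatibility_matrix(motif)
    enc = encode_sequence(window)
    return float(compat[np.arange(motif.width), enc].mean())


def _best_windows(encoded: np.ndarray, compat: np.ndarray) -> tuple[int, float]:
    """Best (leftmost on ties) window start (0-based) and match fraction."""
    w = compat.shape[0]
    windows = np.lib.stride_tricks.sliding_window_view(encoded, w)
    fracs = compat[np.arange(w)[None, :], windows].mean(axis=1)
    best = int(np.argmax(fracs))  # argmax takes the leftmost maximum
    return best, float(fracs[best])


def scan_protein(
    protein: ProteinRecord,
    motifs: list[MotifDefinition] | tuple[MotifDefinition, ...],
    presence_threshold: float = PRESENCE_THRESHOLD,
) -> list[ScanHit]:
    """Best-scoring window per motif; hits below the presence threshold are
    reported with ``present=False`` rather than dropped."""
    if not protein.sequence:
        raise ValueError(f"protein {protein.id}: empty sequence")
    encoded = encode_sequence(protein.sequence)
    hits = []
    for motif in motifs:
        if motif.width > len(encoded):
            hits.append(ScanHit(protein.id, motif.index, 1, 0.0, False))
            continue
        start0, frac = _best_windows(encoded, compatibility_matrix(motif))
        hits.append(
            ScanHit(protein.id, motif.index, start0 + 1, frac, frac >= presence_threshold)
        )
    return hits


def family_score(hits: list[ScanHit], core_motifs: tuple[int, ...] = CORE_MOTIFS) -> float:
    """Mean best-match fraction over the core motifs."""
    by_index = {h.motif_index: h for h in hits}
    missing = [i for i in core_motifs if i not in by_index]
    if missing:
        raise ValueError(f"scan incomplete: no hits for core motifs {missing}")
    return float(np.mean([by_index[i].fraction for i in core_motifs]))


def null_score_distribution(
    proteome: list[ProteinRecord],
    motifs: list[MotifDefinition] | tuple[MotifDefinition, ...],
    n_shuffles: int = DEFAULT_SHUFFLES,
    seed: int = 0,
    core_motifs: tuple[int, ...] = CORE_MOTIFS,
) -> np.ndarray:
    """Family scores of residue-permuted proteins drawn round-robin from
    the proteome; the shared null sample behind every E-value."""
    if n_shuffles < 1:
        raise ValueError("n_shuffles must be >= 1")
    rng = np.random.default_rng(seed)
    core = [m for m in motifs if m.index in core_motifs]
    compats = [compatibility_matrix(m) for m in core]
    encoded = [encode_sequence(p.sequence) for p in proteome]
    scores = np.empty(n_shuffles)
    for k in range(n_shuffles):
        shuffled = rng.permutation(encoded[k % len(encoded)])
        fracs = []
        for m, compat in zip(core, compats):
            if m.width > len(shuffled):
                fracs.append(0.0)
            else:
                fracs.append(_best_windows(shuffled, compat)[1])
        scores[k] = np.mean(fracs)
    return scores


def empirical_evalue(
    score: float,
    proteome: list[ProteinRecord],
    motifs: list[MotifDefinition] | tuple[MotifDefinition, ...],
    n_shuffles: int = DEFAULT_SHUFFLES,
    seed: int = 0,
    null_scores: np.ndarray | None = None,
) -> float:
    """Permutation E-value: E = N_db * (1 + #{null >= score}) / (1 + n_shuffles).

    ``null_scores`` may be passed to reuse one null sample across a whole
    proteome scan (the default when calling :func:`scan_proteome`).
    """
    if null_scores is None:
        null_scores = null_score_distribution(proteome, motifs, n_shuffles, seed)
    n = len(null_scores)
    exceed = int(np.sum(null_scores >= score))
    return len(proteome) * (1 + exceed) / (1 + n)


def scan_proteome(
    proteome: list[ProteinRecord],
    motifs: list[MotifDefinition] | tuple[MotifDefinition, ...],
    n_shuffles: int = DEFAULT_SHUFFLES,
    seed: int = 0,
    presence_threshold: float = PRESENCE_THRESHOLD,
) -> list[CandidateReport]:
    """Scan every protein, score it, and attach a permutation E-value
    computed against one shared null sample."""
    null = null_score_distribution(proteome, motifs, n_shuffles, seed)
    reports = []
    for protein in proteome:
        hits = scan_protein(protein, motifs, presence_threshold)
        score = family_score(hits)
        ev = empirical_evalue(score, proteome, motifs, null_scores=null)
        reports.append(CandidateReport(protein.id, {h.motif_index: h for h in hits}, score, ev))
    return reports


def _locus_overlap(a: GeneModel, b: GeneModel) -> float:
    if a.chromosome != b.chromosome:
        return 0.0
    inter = min(a.end, b.end) - max(a.start, b.start) + 1
    if inter <= 0:
        return 0.0
    return inter / min(a.end - a.start + 1, b.end - b.start + 1)


def filter_candidates(
    reports: list[CandidateReport],
    proteome: list[ProteinRecord],
    gene_index: dict[str, GeneModel] | None = None,
    evalue_threshold: float = EVALUE_THRESHOLD,
    core_motifs: tuple[int, ...] = CORE_MOTIFS,
) -> list[CandidateReport]:
    """Apply the redundancy and domain-completeness filters.

    A candidate is *incomplete* if any core motif is absent; *redundant*
    if its sequence is byte-identical to an already-accepted candidate or
    its locus overlaps an accepted candidate's locus by >= 50% (the
    higher-scoring candidate is kept, ties broken by smaller id).
    Decisions are order-invariant: candidates are processed by decreasing
    score, then id.  Returns the accepted reports; flags and verdicts are
    set on every report.
    """
    seq_of = {p.id: p.sequence for p in proteome}
    accepted: list[CandidateReport] = []
    accepted_seqs: set[str] = set()
    for report in sorted(reports, key=lambda r: (-r.score, r.protein_id)):
        report.incomplete = any(
            i not in report.hits or not report.hits[i].present for i in core_motifs
        )
        report.redundant = False
        if report.evalue < evalue_threshold and not report.incomplete:
            if seq_of[report.protein_id] in accepted_seqs:
                report.redundant = True
            elif gene_index is not None and report.protein_id in gene_index:
                mine = gene_index[report.protein_id]
                for other in accepted:
                    if other.protein_id in gene_index and _locus_overlap(
                        mine, gene_index[other.protein_id]
                    ) >= 0.5:
                        report.redundant = True
                        break
        ok = (
            report.evalue < evalue_threshold
            and not report.redundant
            and not report.incomplete
        )
        report.verdict = "accept" if ok else "reject"
        if ok:
            accepted.append(report)
            accepted_seqs.add(seq_of[report.protein_id])
    accepted.sort(key=lambda r: r.protein_id)
    return accepted
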