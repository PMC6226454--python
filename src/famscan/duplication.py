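"""Smith-Waterman local alignment and duplication-class assignment.

The aligner is an affine-gap local dynamic program (scores floored at 0,
traceback from the global maximum cell) with EMBOSS ``water`` defaults:
BLOSUM62, gap open 10, gap extend 0.5 — the first gap residue costs the
open penalty, each further residue the extension penalty.

Classification of a sister pair follows the positional rule: *tandem* if
the two genes sit on the same chromosome within 100 kb (start-to-start)
with at most five annotated genes between them; *segmental* if they lie
on different chromosomes; same-chromosome pairs failing the tandem rule
are *ambiguous* (duplicated-block detection is not attempted, but a
user-supplied block list can be injected).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from Bio.Align import substitution_matrices

from .models import AMINO_ACIDS, GeneModel, ParalogPair

TANDEM_WINDOW_BP = 100_000
TANDEM_MAX_INTERVENING = 5

_NEG_INF = -1e30


def blosum62_matrix() -> np.ndarray:
    """BLOSUM62 as a (20, 20) float array over the standard residue order."""
    blosum = substitution_matrices.load("BLOSUM62")
    n = len(AMINO_ACIDS)
    mat = np.empty((n, n))
    for i, a in enumerate(AMINO_ACIDS):
        for j, b in enumerate(AMINO_ACIDS):
            mat[i, j] = blosum[a][b]
    return mat


_BLOSUM62 = None


def _default_matrix() -> np.ndarray:
    global _BLOSUM62
    if _BLOSUM62 is None:
        _BLOSUM62 = blosum62_matrix()
    return _BLOSUM62


@dataclass(frozen=True)
class LocalAlignment:
    score: float
    aligned_a: str
    aligned_b: str

    @property
    def identity(self) -> float:
        """Exact matches over aligned columns (0 for an empty alignment)."""
        if not self.aligned_a:
            return 0.0
        matches = sum(
            x == y and x != "-" for x, y in zip(self.aligned_a, self.aligned_b)
        )
        return matches / len(self.aligned_a)


def _encode(seq: str) -> np.ndarray:
    index = {aa: i for i, aa in enumerate(AMINO_ACIDS)}
    try:
        return np.fromiter((index[c] for c in seq), dtype=np.int64, count=len(seq))
    except KeyError as exc:
        raise ValueError(f"non-standard residue {exc.args[0]!r}") from exc


def smith_waterman(
    a: str,
    b: str,
    matrix: np.ndarray | None = None,
    gap_open: float = 10.0,
    gap_extend: float = 0.5,
) -> LocalAlignment:
    """Best local alignment of ``a`` and ``b`` under affine gap costs.

    Ties for the maximum cell are broken toward the smallest row, then
    column; traceback prefers diagonal over a gap in ``a`` over a gap in
    ``b``.
    """
    if not a or not b:
        raise ValueError("empty input sequence")
    if gap_open <= 0 or gap_extend <= 0:
        raise ValueError("gap penalties must be positive")
    if gap_open < gap_extend:
        raise ValueError("gap_open must be >= gap_extend")
    S = _default_matrix() if matrix is None else matrix
    ea, eb = _encode(a), _encode(b)
    m, n = len(ea), len(eb)

    H = np.zeros((m + 1, n + 1))
    E = np.full((m + 1, n + 1), _NEG_INF)  # gap in a (consumes b)
    F = np.full((m + 1, n + 1), _NEG_INF)  # gap in b (consumes a)
    j_idx = np.arange(n + 1)
    for i in range(1, m + 1):
        F[i, 1:] = np.maximum(H[i - 1, 1:] - gap_open, F[i - 1, 1:] - gap_extend)
        diag = H[i - 1, :-1] + S[ea[i - 1], eb]
        h_ne = np.zeros(n + 1)
        h_ne[1:] = np.maximum.reduce([np.zeros(n), diag, F[i, 1:]])
        # E[j] = max_{k<j} h_ne[k] - open - (j-1-k)*ext, via a running max;
        # chains through E itself are dominated because open >= extend.
        c = h_ne + (j_idx + 1) * gap_extend - gap_open
        E[i, 1:] = np.maximum.accumulate(c[:-1]) - j_idx[1:] * gap_extend
        H[i] = np.maximum(h_ne, E[i])

    best = float(H.max())
    if best <= 0:
        return LocalAlignment(0.0, "", "")
    i, j = np.unravel_index(int(np.argmax(H)), H.shape)  # smallest row, then col

    out_a: list[str] = []
    out_b: list[str] = []
    state = "H"
    while True:
        if state == "H":
            if H[i, j] == 0:
                break
            if i > 0 and j > 0 and H[i, j] == H[i - 1, j - 1] + S[ea[i - 1], eb[j - 1]]:
                out_a.append(a[i - 1])
                out_b.append(b[j - 1])
                i, j = i - 1, j - 1
            elif H[i, j] == E[i, j]:
                state = "E"
            else:
                state = "F"
        elif state == "E":
            out_a.append("-")
            out_b.append(b[j - 1])
            if E[i, j] == H[i, j - 1] - gap_open:
                state = "H"
            j -= 1
        else:
            out_a.append(a[i - 1])
            out_b.append("-")
            if F[i, j] == H[i - 1, j] - gap_open:
                state = "H"
            i -= 1
    return LocalAlignment(best, "".join(reversed(out_a)), "".join(reversed(out_b)))


def classify_pair(
    pair: ParalogPair,
    genes: list[GeneModel],
    tandem_window_bp: int = TANDEM_WINDOW_BP,
    max_intervening: int = TANDEM_MAX_INTERVENING,
    segmental_blocks: list[tuple[str, str]] | None = None,
) -> ParalogPair:
    """Assign a duplication class to a sister pair against the gene index.

    ``segmental_blocks`` optionally lists (chromosome, chromosome) pairs
    known to be duplicated blocks; without it, different-chromosome
    coparalogs are classified segmental.
    """
    index = {g.id: g for g in genes}
    try:
        ga, gb = index[pair.gene_a], index[pair.gene_b]
    except KeyError as exc:
        raise KeyError(f"gene {exc.args[0]} not in index") from exc
    if ga.chromosome != gb.chromosome:
        if segmental_blocks is None or any(
            {ga.chromosome, gb.chromosome} == set(block) for block in segmental_blocks
        ):
            pair.duplication_class = "segmental"
        else:
            pair.duplication_class = "ambiguous"
        pair.distance_bp = None
        pair.intervening_genes = None
        return pair
    lo, hi = sorted((ga.start, gb.start))
    pair.distance_bp = hi - lo
    pair.intervening_genes = sum(
        1
        for g in genes
        if g.chromosome == ga.chromosome
        and g.id not in (ga.id, gb.id)
        and lo < g.start < hi
    )
    if pair.distance_bp <= tandem_window_bp and pair.intervening_genes <= max_intervening:
        pair.duplication_class = "tandem"
    else:
        pair.duplication_class = "ambiguous"
    return pair


def classify_pairs(
    pairs: list[ParalogPair], genes: list[GeneModel], **kwargs
) -> list[ParalogPair]:
    return [classify_pair(p, genes, **kwargs) for p in pairs]
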