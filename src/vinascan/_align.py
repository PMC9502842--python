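"""Low-level alignment kernels shared by the profile engine, the aligner and host search.

All dynamic programs operate on a precomputed position-by-position score matrix
``S`` (float64), so one local and one global affine-gap kernel serve
sequence-vs-PSSM, sequence-vs-sequence and profile-vs-profile alignment alike.
"""

from __future__ import annotations

import numpy as np
from numba import njit
from Bio import Align
from Bio.Align import substitution_matrices

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
AA_X = len(AA_ALPHABET)  # index for unknown residues
_AA_INDEX = {a: i for i, a in enumerate(AA_ALPHABET)}

NT_ALPHABET = "ACGT"
_NT_INDEX = {a: i for i, a in enumerate(NT_ALPHABET)}


def encode_aa(seq: str) -> np.ndarray:
    """Encode a protein as int8 indices into AA_ALPHABET; unknowns map to AA_X."""
    return np.array([_AA_INDEX.get(a, AA_X) for a in seq], dtype=np.int8)


def encode_nt(seq: str) -> np.ndarray:
    return np.array([_NT_INDEX.get(a, 0) for a in seq], dtype=np.int8)


def blosum62_matrix() -> np.ndarray:
    """BLOSUM62 as a (21, 21) array over AA_ALPHABET + X (X rows/cols = 0)."""
    b62 = substitution_matrices.load("BLOSUM62")
    m = np.zeros((AA_X + 1, AA_X + 1))
    for i, a in enumerate(AA_ALPHABET):
        for j, b in enumerate(AA_ALPHABET):
            m[i, j] = b62[a, b]
    return m


_B62 = None


def b62() -> np.ndarray:
    global _B62
    if _B62 is None:
        _B62 = blosum62_matrix()
    return _B62


# ------------------------------------------------------------------ numba kernels
#
# States: M = match/substitute, X = gap in the column axis (consume row only),
# Y = gap in the row axis. Affine penalties: opening a gap costs open+extend.


@njit(cache=True)
def local_affine_score(S, gap_open, gap_extend):
    """Best Smith–Waterman score over score matrix S (rows x cols)."""
    n, m = S.shape
    NEG = -1e30
    M = np.zeros(m + 1)
    X = np.full(m + 1, NEG)
    best = 0.0
    for i in range(1, n + 1):
        prev_diag = 0.0
        Y = NEG
        for j in range(1, m + 1):
            x = max(M[j] - gap_open - gap_extend, X[j] - gap_extend)
            y = max(M[j - 1] - gap_open - gap_extend, Y - gap_extend)
            mm = prev_diag + S[i - 1, j - 1]
            v = max(0.0, mm, x, y)
            prev_diag = M[j]
            M[j] = v
            X[j] = x
            Y = y
            if v > best:
                best = v
    return best


@njit(cache=True)
def local_affine(S, gap_open, gap_extend):
    """Smith–Waterman with traceback.

    Returns (score, i0, i1, j0, j1, path) where the aligned block covers rows
    [i0, i1) and columns [j0, j1) of S, and ``path`` is an int8 array of moves
    (0 = diagonal, 1 = consume row only, 2 = consume column only), oriented
    from (i0, j0) to (i1, j1).
    """
    n, m = S.shape
    NEG = -1e30
    M = np.zeros((n + 1, m + 1))
    X = np.full((n + 1, m + 1), NEG)
    Y = np.full((n + 1, m + 1), NEG)
    ptrM = np.zeros((n + 1, m + 1), dtype=np.int8)  # 0 stop,1 diagM,2 diagX,3 diagY
    ptrX = np.zeros((n + 1, m + 1), dtype=np.int8)  # 1 fromM, 2 fromX
    ptrY = np.zeros((n + 1, m + 1), dtype=np.int8)
    best = 0.0
    bi = 0
    bj = 0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            xo = M[i - 1, j] - gap_open - gap_extend
            xe = X[i - 1, j] - gap_extend
            if xo >= xe:
                X[i, j] = xo
                ptrX[i, j] = 1
            else:
                X[i, j] = xe
                ptrX[i, j] = 2
            yo = M[i, j - 1] - gap_open - gap_extend
            ye = Y[i, j - 1] - gap_extend
            if yo >= ye:
                Y[i, j] = yo
                ptrY[i, j] = 1
            else:
                Y[i, j] = ye
                ptrY[i, j] = 2
            s = S[i - 1, j - 1]
            vM = M[i - 1, j - 1] + s
            vX = X[i - 1, j - 1] + s
            vY = Y[i - 1, j - 1] + s
            v = vM
            p = 1
            if vX > v:
                v = vX
                p = 2
            if vY > v:
                v = vY
                p = 3
            if v <= 0.0:
                v = 0.0
                p = 0
            M[i, j] = v
            ptrM[i, j] = p
            if v > best:
                best = v
                bi = i
                bj = j
    # traceback from (bi, bj) in state M
    path = np.empty(n + m, dtype=np.int8)
    k = 0
    i = bi
    j = bj
    state = 0  # 0=M,1=X,2=Y
    while i > 0 and j > 0:
        if state == 0:
            p = ptrM[i, j]
            if p == 0:
                break
            path[k] = 0
            k += 1
            i -= 1
            j -= 1
            if p == 1:
                state = 0
            elif p == 2:
                state = 1
            else:
                state = 2
            if state == 0 and ptrM[i, j] == 0 and M[i, j] == 0.0:
                break
        elif state == 1:
            p = ptrX[i, j]
            path[k] = 1
            k += 1
            i -= 1
            state = 0 if p == 1 else 1
        else:
            p = ptrY[i, j]
            path[k] = 2
            k += 1
            j -= 1
            state = 0 if p == 1 else 2
    return best, i, bi, j, bj, path[:k][::-1].copy()


@njit(cache=True)
def global_affine(S, gap_open, gap_extend):
    """Needleman–Wunsch with affine gaps and traceback over score matrix S.

    End gaps are charged. Returns (score, path) with path moves as in
    :func:`local_affine`, oriented from (0, 0) to (n, m).
    """
    n, m = S.shape
    NEG = -1e30
    M = np.full((n + 1, m + 1), NEG)
    X = np.full((n + 1, m + 1), NEG)
    Y = np.full((n + 1, m + 1), NEG)
    ptrM = np.zeros((n + 1, m + 1), dtype=np.int8)
    ptrX = np.zeros((n + 1, m + 1), dtype=np.int8)
    ptrY = np.zeros((n + 1, m + 1), dtype=np.int8)
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        X[i, 0] = -gap_open - gap_extend * i
        ptrX[i, 0] = 2 if i > 1 else 1
    for j in range(1, m + 1):
        Y[0, j] = -gap_open - gap_extend * j
        ptrY[0, j] = 2 if j > 1 else 1
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            xo = M[i - 1, j] - gap_open - gap_extend
            xe = X[i - 1, j] - gap_extend
            if xo >= xe:
                X[i, j] = xo
                ptrX[i, j] = 1
            else:
                X[i, j] = xe
                ptrX[i, j] = 2
            yo = M[i, j - 1] - gap_open - gap_extend
            ye = Y[i, j - 1] - gap_extend
            if yo >= ye:
                Y[i, j] = yo
                ptrY[i, j] = 1
            else:
                Y[i, j] = ye
                ptrY[i, j] = 2
            s = S[i - 1, j - 1]
            vM = M[i - 1, j - 1] + s
            vX = X[i - 1, j - 1] + s
            vY = Y[i - 1, j - 1] + s
            v = vM
            p = 1
            if vX > v:
                v = vX
                p = 2
            if vY > v:
                v = vY
                p = 3
            M[i, j] = v
            ptrM[i, j] = p
    # pick best terminal state
    state = 0
    score = M[n, m]
    if X[n, m] > score:
        score = X[n, m]
        state = 1
    if Y[n, m] > score:
        score = Y[n, m]
        state = 2
    path = np.empty(n + m, dtype=np.int8)
    k = 0
    i = n
    j = m
    while i > 0 or j > 0:
        if state == 0:
            p = ptrM[i, j]
            path[k] = 0
            k += 1
            i -= 1
            j -= 1
            state = 0 if p == 1 else (1 if p == 2 else 2)
        elif state == 1:
            p = ptrX[i, j]
            path[k] = 1
            k += 1
            i -= 1
            state = 0 if p == 1 else 1
        else:
            p = ptrY[i, j]
            path[k] = 2
            k += 1
            j -= 1
            state = 0 if p == 1 else 2
    return score, path[:k][::-1].copy()


# ------------------------------------------------------------------ Biopython aligners


def make_protein_aligner(mode: str = "global", gap_open: float = 11.0, gap_extend: float = 1.0):
    aligner = Align.PairwiseAligner()
    aligner.mode = mode
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -(gap_open + gap_extend)
    aligner.extend_gap_score = -gap_extend
    if mode == "global":
        # cheap end gaps keep length-mismatched homologs aligned sanely
        aligner.open_end_insertion_score = -gap_extend
        aligner.extend_end_insertion_score = -gap_extend
        aligner.open_end_deletion_score = -gap_extend
        aligner.extend_end_deletion_score = -gap_extend
    return aligner


_GLOBAL_ALIGNER = None
_LOCAL_ALIGNER = None


def global_identity(a: str, b: str) -> float:
    """Identity of the best global alignment = matches / alignment columns.

    Gap columns count in the denominator, matching the clustering convention.
    """
    global _GLOBAL_ALIGNER
    if _GLOBAL_ALIGNER is None:
        _GLOBAL_ALIGNER = make_protein_aligner("global")
    a = a.replace("*", "X")
    b = b.replace("*", "X")
    aln = next(iter(_GLOBAL_ALIGNER.align(a, b)))
    counts = aln.counts()
    return counts.identities / aln.length


def local_protein_score(a: str, b: str) -> float:
    """Best BLOSUM62 local alignment score (affine 11/1) between two proteins."""
    global _LOCAL_ALIGNER
    if _LOCAL_ALIGNER is None:
        _LOCAL_ALIGNER = make_protein_aligner("local")
    return _LOCAL_ALIGNER.score(a.replace("*", "X"), b.replace("*", "X"))


def local_protein_alignment(a: str, b: str):
    """Best local alignment; returns (score, aligned_length)."""
    global _LOCAL_ALIGNER
    if _LOCAL_ALIGNER is None:
        _LOCAL_ALIGNER = make_protein_aligner("local")
    aln = next(iter(_LOCAL_ALIGNER.align(a.replace("*", "X"), b.replace("*", "X"))))
    return aln.score, aln.length


def kmer_set(seq: str, k: int = 4) -> set:
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


def shares_kmer(set_a: set, seq_b: str, k: int = 4, min_shared: int = 1) -> bool:
    """Cheap prefilter: do the sequences share >= min_shared k-words?"""
    found = 0
    for i in range(len(seq_b) - k + 1):
        if seq_b[i : i + k] in set_a:
            found += 1
            if found >= min_shared:
                return True
    return False
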