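"""Matrix-of-sequence (MOS) descriptor.

Given a group sequence s_1..s_L over N=7 classes, the sequence matrix
``m`` counts ordered position pairs::

    m[i, j] = |{(p, q) : 1 <= p <= q <= L, s_p = i, s_q = j}|

so the whole residue order of the sequence contributes, not just local
windows.  Three exact conservation identities follow and are enforced as
invariants on every computed matrix (``C_i`` is the count of class ``i``):

* ``sum_ij m_ij = L (L + 1) / 2``
* ``m_ii = C_i (C_i + 1) / 2``
* ``m_ij + m_ji = C_i * C_j`` for ``i != j``

The matrix is computed by a single right-to-left streaming scan: walk the
positions from L down to 1, maintain the running suffix class counts
(the VOS vector), and at each position p add the whole suffix-count vector
to row s_p.  This costs O(L * N) time; an O(L^2) explicit pair-enumeration
oracle is provided for cross-checking.

Normalizing by the forced total L(L+1)/2 gives p_ij in [0, 1] summing to
one.  The 28 cells on and above the diagonal (row-major) plus a sequence
tag 1/L form the 29-dimensional per-protein MOS feature vector; the tag
separates equal-composition proteins of different lengths.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .groups import N_GROUPS, map_to_groups

__all__ = [
    "SequenceMatrix",
    "compute_vos",
    "compute_mos_streaming",
    "compute_mos_bruteforce",
    "normalize_matrix",
    "mos_features",
    "mos_feature_names",
    "MOS_DIM",
    "MOSEncoder",
]

#: 28 upper-triangle cells + the 1/L sequence tag.
MOS_DIM: int = N_GROUPS * (N_GROUPS + 1) // 2 + 1


@dataclass(frozen=True)
class SequenceMatrix:
    """An N x N pair-count matrix together with the source sequence length."""

    m: np.ndarray  # (n_groups, n_groups) int64
    length: int

    def __post_init__(self):
        if self.length < 1:
            raise ValueError("source length must be >= 1")
        total = int(self.m.sum())
        expected = self.length * (self.length + 1) // 2
        if total != expected:
            raise ValueError(
                f"sum of matrix entries {total} != L(L+1)/2 = {expected}"
            )

    @property
    def n_groups(self) -> int:
        return self.m.shape[0]


def _as_group_array(gseq) -> np.ndarray:
    g = np.asarray(gseq, dtype=np.int64)
    if g.ndim != 1 or g.size == 0:
        raise ValueError("group sequence must be a non-empty 1-D array")
    if g.min() < 1 or g.max() > N_GROUPS:
        raise ValueError(f"group indices must lie in 1..{N_GROUPS}")
    return g


def compute_vos(gseq) -> np.ndarray:
    """Per-class occurrence counts (C_1, ..., C_7) of a group sequence."""
    g = _as_group_array(gseq)
    return np.bincount(g - 1, minlength=N_GROUPS).astype(np.int64)


def compute_mos_streaming(gseq) -> SequenceMatrix:
    """Compute the sequence matrix by the O(L*N) suffix-count scan.

    Scan positions from L down to 1; at position p increment the running
    class-count vector at class s_p, then add the whole vector to row s_p
    of the matrix.
    """
    g = _as_group_array(gseq)
    vos = np.zeros(N_GROUPS, dtype=np.int64)
    mos = np.zeros((N_GROUPS, N_GROUPS), dtype=np.int64)
    for p in range(len(g) - 1, -1, -1):
        k = g[p] - 1
        vos[k] += 1
        mos[k] += vos
    return SequenceMatrix(m=mos, length=len(g))


def compute_mos_bruteforce(gseq) -> SequenceMatrix:
    """Independent O(L^2) oracle: enumerate every position pair p <= q.

    Each pair contributes one count to cell (s_p, s_q).  Intended for
    cross-checking the streaming scan on short sequences.
    """
    g = _as_group_array(gseq)
    L = len(g)
    p_idx, q_idx = np.triu_indices(L)
    cells = (g[p_idx] - 1) * N_GROUPS + (g[q_idx] - 1)
    m = np.bincount(cells, minlength=N_GROUPS * N_GROUPS).reshape(
        N_GROUPS, N_GROUPS
    )
    return SequenceMatrix(m=m.astype(np.int64), length=L)


def normalize_matrix(mos: SequenceMatrix) -> np.ndarray:
    """Normalize the pair counts to p_ij = m_ij / (L(L+1)/2); entries sum to 1."""
    denom = mos.length * (mos.length + 1) / 2.0
    return mos.m / denom


# Row-major upper-triangle index pair, fixed once.
_TRIU = np.triu_indices(N_GROUPS)


def mos_feature_names() -> list[str]:
    """Column labels: m11, m12, ..., m17, m22, ..., m77, invlen."""
    names = [f"m{i + 1}{j + 1}" for i, j in zip(*_TRIU)]
    names.append("invlen")
    return names


def mos_features(p: np.ndarray, length: int) -> np.ndarray:
    """Assemble the 29-dim MOS feature vector from a normalized matrix.

    The first 28 entries are the diagonal and above-diagonal cells in
    row-major order ([1,1], [1,2], ..., [1,7], [2,2], ..., [7,7]); the
    29th is the sequence tag 1/L.
    """
    if length < 1:
        raise ValueError("length must be >= 1")
    p = np.asarray(p, dtype=np.float64)
    if p.shape != (N_GROUPS, N_GROUPS):
        raise ValueError(f"normalized matrix must be {N_GROUPS}x{N_GROUPS}")
    return np.concatenate([p[_TRIU], [1.0 / length]])


class MOSEncoder(TransformerMixin, BaseEstimator):
    """Transform protein sequences into 29-dim MOS feature vectors.

    Stateless scikit-learn transformer: ``fit`` is a no-op, ``transform``
    maps an iterable of protein letter strings to an (n, 29) float array.

    Examples
    --------
    >>> MOSEncoder().transform(["AGCRQTSPLGVKSE"]).shape
    (1, 29)
    """

    name = "MOS"
    per_protein_dim = MOS_DIM
    min_sequence_length = 1

    def fit(self, X=None, y=None):
        return self

    def encode_one(self, seq: str) -> np.ndarray:
        g = map_to_groups(seq)
        mat = compute_mos_streaming(g)
        return mos_features(normalize_matrix(mat), mat.length)

    def transform(self, X) -> np.ndarray:
        rows = [self.encode_one(seq) for seq in X]
        if not rows:
            return np.empty((0, self.per_protein_dim))
        return np.vstack(rows)

    def get_feature_names_out(self, input_features=None):
        return np.asarray(mos_feature_names(), dtype=object)
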