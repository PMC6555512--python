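"""Comparison encoders: conjoint triad (CT), auto covariance (AC), local descriptor (LD).

These are the three classical sequence-only protein representations the
MOS descriptor is benchmarked against.  Per-protein dimensionalities are
343 (CT), 210 (AC) and 630 (LD), giving pair vectors of 686, 420 and 1260
once two proteins are concatenated.

CT
    Slide a window of three residues along the 7-group reduced sequence
    and count each of the 7^3 = 343 triad types; scale the count vector f
    per protein as d = (f - min f) / max f.

AC
    For each of seven physicochemical scales (hydrophobicity,
    hydrophilicity, side-chain volume, polarity, polarizability,
    solvent-accessible surface area, net charge index) standardized over
    the 20 residues, compute the mean-centered auto-covariance of the
    per-residue property series at lags 1..30:

        AC(lag, j) = (1/(L-lag)) * sum_i (X[i,j] - mean_j)(X[i+lag,j] - mean_j)

    7 scales x 30 lags = 210 features, ordered scale-major.

LD
    Ten overlapping regions of the sequence (four quarters, two halves,
    central 50%, first 75%, last 75%, central 75%); per region, over the 7
    groups: 7 composition, 21 transition and 35 distribution features
    (positions of the first, 25%, 50%, 75% and last residue of each group,
    normalized by region length) -> 63 per region, 630 total.  Region
    endpoints use floor arithmetic on 0-based half-open slices.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .groups import N_GROUPS, STANDARD_RESIDUES, map_to_groups

__all__ = [
    "CT_DIM",
    "AC_DIM",
    "LD_DIM",
    "AC_PROPERTY_NAMES",
    "AC_PROPERTY_TABLE",
    "ct_features",
    "ac_features",
    "ld_features",
    "ld_region_bounds",
    "CTEncoder",
    "ACEncoder",
    "LDEncoder",
]

CT_DIM = N_GROUPS**3          # 343
AC_DIM = 7 * 30               # 210
LD_DIM = 10 * (7 + 21 + 35)   # 630


class SequenceTooShortError(ValueError):
    """Sequence shorter than an encoder's minimum usable length."""


# ---------------------------------------------------------------------------
# Conjoint triad
# ---------------------------------------------------------------------------

def ct_triad_counts(seq: str) -> np.ndarray:
    """Raw counts of the 343 group triads over all L-2 sliding windows."""
    g = map_to_groups(seq)
    if len(g) < 3:
        raise SequenceTooShortError(
            f"conjoint triad needs length >= 3, got {len(g)}"
        )
    g0 = g.astype(np.int64) - 1
    idx = g0[:-2] * 49 + g0[1:-1] * 7 + g0[2:]
    return np.bincount(idx, minlength=CT_DIM).astype(np.int64)


def ct_features(seq: str) -> np.ndarray:
    """343-dim conjoint-triad vector, scaled as d = (f - min f) / max f."""
    f = ct_triad_counts(seq).astype(np.float64)
    # max f >= 1 whenever L >= 3, so the scaling is always defined
    return (f - f.min()) / f.max()


# ---------------------------------------------------------------------------
# Auto covariance
# ---------------------------------------------------------------------------

AC_PROPERTY_NAMES = (
    "hydrophobicity",
    "hydrophilicity",
    "side_chain_volume",
    "polarity",
    "polarizability",
    "solvent_accessible_surface_area",
    "net_charge_index",
)

# Raw per-residue values for the seven scales, residue order ACDEFGHIKLMNPQRSTVWY.
# Standard published scales used by the auto-covariance descriptor lineage.
AC_PROPERTY_TABLE = np.array(
    [
        # hydrophobicity
        [0.62, 0.29, -0.90, -0.74, 1.19, 0.48, -0.40, 1.38, -1.50, 1.06,
         0.64, -0.78, 0.12, -0.85, -2.53, -0.18, -0.05, 1.08, 0.81, 0.26],
        # hydrophilicity
        [-0.5, -1.0, 3.0, 3.0, -2.5, 0.0, -0.5, -1.8, 3.0, -1.8,
         -1.3, 0.2, 0.0, 0.2, 3.0, 0.3, -0.4, -1.5, -3.4, -2.3],
        # side-chain volume (A^3)
        [27.5, 44.6, 40.0, 62.0, 115.5, 0.0, 79.0, 93.5, 100.0, 93.5,
         94.1, 58.7, 41.9, 80.7, 105.0, 29.3, 51.3, 71.5, 145.5, 117.3],
        # polarity
        [8.1, 5.5, 13.0, 12.3, 5.2, 9.0, 10.4, 5.2, 11.3, 4.9,
         5.7, 11.6, 8.0, 10.5, 10.5, 9.2, 8.6, 5.9, 5.4, 6.2],
        # polarizability
        [0.046, 0.128, 0.105, 0.151, 0.290, 0.000, 0.230, 0.186, 0.219, 0.186,
         0.221, 0.134, 0.131, 0.180, 0.291, 0.062, 0.108, 0.140, 0.409, 0.298],
        # solvent-accessible surface area (nm^2)
        [1.181, 1.461, 1.587, 1.862, 2.228, 0.881, 2.025, 1.810, 2.258, 1.931,
         2.034, 1.655, 1.468, 1.932, 2.560, 1.298, 1.525, 1.645, 2.663, 2.368],
        # net charge index of side chains
        [0.007187, -0.036610, -0.023820, 0.006802, 0.037552, 0.179052,
         -0.010690, 0.021631, 0.017708, 0.051672, 0.002683, 0.005392,
         0.239531, 0.049211, 0.043587, 0.004627, 0.003352, 0.057004,
         0.037977, 0.023599],
    ],
    dtype=np.float64,
)

# z-standardize each scale over the 20 residues (population std)
_AC_STD_TABLE = (
    AC_PROPERTY_TABLE - AC_PROPERTY_TABLE.mean(axis=1, keepdims=True)
) / AC_PROPERTY_TABLE.std(axis=1, keepdims=True)

_AC_RESIDUE_INDEX = {res: i for i, res in enumerate(STANDARD_RESIDUES)}


def _property_series(seq: str) -> np.ndarray:
    """(L, 7) matrix of standardized property values along the sequence."""
    seq = seq.upper()
    try:
        idx = np.array([_AC_RESIDUE_INDEX[ch] for ch in seq], dtype=np.int64)
    except KeyError as exc:
        from .groups import InvalidResidueError

        ch = exc.args[0]
        raise InvalidResidueError(ch, seq.index(ch)) from None
    return _AC_STD_TABLE[:, idx].T


def ac_features(seq: str, max_lag: int = 30) -> np.ndarray:
    """210-dim auto-covariance vector (7 scales x lags 1..max_lag, scale-major)."""
    X = _property_series(seq)
    L = X.shape[0]
    if L <= max_lag:
        raise SequenceTooShortError(
            f"auto covariance needs length > {max_lag}, got {L}"
        )
    Xc = X - X.mean(axis=0, keepdims=True)
    out = np.empty((7, max_lag), dtype=np.float64)
    for lag in range(1, max_lag + 1):
        out[:, lag - 1] = (Xc[:-lag] * Xc[lag:]).sum(axis=0) / (L - lag)
    return out.ravel()


# ---------------------------------------------------------------------------
# Local descriptor
# ---------------------------------------------------------------------------

def ld_region_bounds(L: int) -> list[tuple[int, int]]:
    """The ten 0-based half-open region slices of a length-L sequence.

    Four quarters, two halves, the central 50%, the first 75%, the last
    75% and the central 75%, with floor rounding at every cut point.
    """
    q1, q2, q3 = L // 4, L // 2, 3 * L // 4
    e8 = L // 8
    return [
        (0, q1), (q1, q2), (q2, q3), (q3, L),    # quarters
        (0, q2), (q2, L),                        # halves
        (q1, q3),                                # central 50%
        (0, q3),                                 # first 75%
        (q1, L),                                 # last 75%
        (e8, L - e8),                            # central 75%
    ]


# fixed order of the 21 unordered group pairs (i < j), row-major
_LD_PAIRS = [(i, j) for i in range(N_GROUPS) for j in range(i + 1, N_GROUPS)]


def _ld_region_features(region: np.ndarray) -> np.ndarray:
    """63 composition/transition/distribution features of one region."""
    n = len(region)
    comp = np.bincount(region - 1, minlength=N_GROUPS) / n

    trans = np.zeros(len(_LD_PAIRS), dtype=np.float64)
    if n > 1:
        a, b = region[:-1], region[1:]
        for k, (i, j) in enumerate(_LD_PAIRS):
            trans[k] = np.sum(
                ((a == i + 1) & (b == j + 1)) | ((a == j + 1) & (b == i + 1))
            )
        trans /= n - 1

    dist = np.zeros((N_GROUPS, 5), dtype=np.float64)
    for g in range(N_GROUPS):
        pos = np.flatnonzero(region == g + 1)
        if pos.size == 0:
            continue
        cnt = pos.size
        # occurrence ranks of the first, 25%, 50%, 75% and last residue
        ranks = [1, max(1, int(np.ceil(0.25 * cnt))),
                 max(1, int(np.ceil(0.50 * cnt))),
                 max(1, int(np.ceil(0.75 * cnt))), cnt]
        dist[g] = [(pos[r - 1] + 1) / n for r in ranks]
    return np.concatenate([comp, trans, dist.ravel()])


def ld_features(seq: str) -> np.ndarray:
    """630-dim local descriptor (10 regions x 63 features)."""
    g = map_to_groups(seq)
    L = len(g)
    if L < 10:
        raise SequenceTooShortError(
            f"local descriptor needs length >= 10, got {L}"
        )
    blocks = [
        _ld_region_features(g[a:b]) for a, b in ld_region_bounds(L)
    ]
    return np.concatenate(blocks)


# ---------------------------------------------------------------------------
# scikit-learn transformer wrappers
# ---------------------------------------------------------------------------

class _FunctionEncoder(TransformerMixin, BaseEstimator):
    """Stateless transformer over an iterable of protein letter strings."""

    name: str = ""
    per_protein_dim: int = 0
    min_sequence_length: int = 1

    def fit(self, X=None, y=None):
        return self

    def encode_one(self, seq: str) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def transform(self, X) -> np.ndarray:
        rows = [self.encode_one(seq) for seq in X]
        if not rows:
            return np.empty((0, self.per_protein_dim))
        return np.vstack(rows)


class CTEncoder(_FunctionEncoder):
    """Conjoint-triad encoder (343 features per protein)."""

    name = "CT"
    per_protein_dim = CT_DIM
    min_sequence_length = 3

    def encode_one(self, seq: str) -> np.ndarray:
        return ct_features(seq)


class ACEncoder(_FunctionEncoder):
    """Auto-covariance encoder (210 features per protein)."""

    name = "AC"
    per_protein_dim = AC_DIM

    def __init__(self, max_lag: int = 30):
        self.max_lag = max_lag

    @property
    def min_sequence_length(self) -> int:
        return self.max_lag + 1

    @property
    def per_protein_dim(self) -> int:  # type: ignore[override]
        return 7 * self.max_lag

    def encode_one(self, seq: str) -> np.ndarray:
        return ac_features(seq, max_lag=self.max_lag)


class LDEncoder(_FunctionEncoder):
    """Local-descriptor encoder (630 features per protein)."""

    name = "LD"
    per_protein_dim = LD_DIM
    min_sequence_length = 10

    def encode_one(self, seq: str) -> np.ndarray:
        return ld_features(seq)
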