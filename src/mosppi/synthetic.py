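"""Synthetic proteomes and interaction pairs with a planted composition signal.

The generator emulates the shape of a sequence-based interaction benchmark
(a FASTA proteome plus positive/negative pair lists) without any external
database.  Interaction structure is planted at the level of 7-group
amino-acid composition: a small number of latent *archetypes* (Dirichlet
centers over the seven group frequencies) are drawn per seed, each protein
is assigned to one archetype, and its group-frequency target is the
mixture

    t = (1 - effect) * baseline + effect * archetype_center

with the baseline the neutral frequency of each group under uniform
residue usage.  Interacting (positive) pairs join two proteins of the same
archetype; non-interacting (negative) pairs join different archetypes.
At ``effect = 0`` every protein is drawn from the same baseline, so labels
carry no recoverable signal; increasing ``effect`` strengthens class
separation.  The planted signal lives in group composition, which all four
encoders in this package can see (for MOS it determines the matrix
diagonal exactly).

All randomness flows from ``config.seed`` through a fixed
``numpy.random.SeedSequence`` spawning scheme, so outputs are reproducible
byte-for-byte.  Generated sequences use only the 20 standard residues and
respect the 50-residue minimum, so they pass dataset filtering with zero
exclusions.  What this generator does *not* emulate: homology and shared
domains, interface-level (rather than composition-level) interaction
determinants, and the length/abundance biases of curated databases.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

from .groups import GROUP_MEMBERS, N_GROUPS
from .dataset_io import InteractionRecord

__all__ = ["SyntheticConfig", "Proteome", "generate_proteome", "generate_interactions"]


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for one synthetic dataset.

    ``effect`` in [0, 1] is the archetype mixing strength (0 = no signal);
    ``n_archetypes`` latent composition classes; lengths are drawn
    uniformly in ``length_range`` (min >= 50 keeps every protein past the
    dataset filters).
    """

    n_proteins: int = 600
    length_range: tuple[int, int] = (50, 200)
    n_pos: int = 2000
    n_neg: int = 2000
    effect: float = 0.8
    n_archetypes: int = 4
    concentration: float = 60.0
    seed: int = 0

    def __post_init__(self):
        lo, hi = self.length_range
        if lo < 50:
            raise ValueError("length_range minimum must be >= 50")
        if hi < lo:
            raise ValueError("length_range must be (min, max) with max >= min")
        if not 0.0 <= self.effect <= 1.0:
            raise ValueError("effect must lie in [0, 1]")
        if self.n_archetypes < 2:
            raise ValueError("need at least 2 archetypes")
        if self.n_proteins < 2 * self.n_archetypes:
            raise ValueError("n_proteins too small for the archetype count")

    def as_dict(self) -> dict:
        d = asdict(self)
        d["length_range"] = list(self.length_range)
        return d


class Proteome(dict):
    """id -> sequence mapping that also remembers each protein's archetype."""

    def __init__(self, sequences: dict[str, str], archetype: dict[str, int]):
        super().__init__(sequences)
        self.archetype = archetype


# neutral group frequencies under uniform usage of the 20 residues
_BASELINE = np.array(
    [len(GROUP_MEMBERS[g]) / 20.0 for g in range(1, N_GROUPS + 1)]
)

_GROUP_RESIDUES = [list(GROUP_MEMBERS[g]) for g in range(1, N_GROUPS + 1)]


def _spawn(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def _archetype_centers(config: SyntheticConfig, rng: np.random.Generator) -> np.ndarray:
    return rng.dirichlet(np.full(N_GROUPS, 2.0), size=config.n_archetypes)


def generate_proteome(config: SyntheticConfig) -> Proteome:
    """Generate ``n_proteins`` random protein sequences.

    Protein ``i`` belongs to archetype ``i mod n_archetypes`` (balanced
    assignment).  Its per-protein group distribution is a Dirichlet draw
    around the effect-mixed target; residues are drawn i.i.d. from that
    distribution, uniformly within each group.
    """
    rng_arch, rng_prot = _spawn(config.seed, 3)[:2]
    centers = _archetype_centers(config, rng_arch)
    lo, hi = config.length_range

    sequences: dict[str, str] = {}
    archetype: dict[str, int] = {}
    width = len(str(config.n_proteins - 1))
    for i in range(config.n_proteins):
        k = i % config.n_archetypes
        target = (1.0 - config.effect) * _BASELINE + config.effect * centers[k]
        p = rng_prot.dirichlet(config.concentration * target)
        L = int(rng_prot.integers(lo, hi + 1))
        groups = rng_prot.choice(N_GROUPS, size=L, p=p)
        chars = [
            _GROUP_RESIDUES[g][rng_prot.integers(len(_GROUP_RESIDUES[g]))]
            for g in groups
        ]
        pid = f"SYN{i:0{width}d}"
        sequences[pid] = "".join(chars)
        archetype[pid] = k
    return Proteome(sequences, archetype)


def generate_interactions(
    proteome: Proteome, config: SyntheticConfig
) -> tuple[list[InteractionRecord], list[InteractionRecord]]:
    """Sample exact counts of positive (same-archetype) and negative
    (different-archetype) pairs — no self pairs, no duplicates.

    Raises
    ------
    ValueError
        If the proteome cannot supply the requested pair counts.
    """
    rng = _spawn(config.seed, 3)[2]
    ids = list(proteome.keys())
    by_arch: dict[int, list[str]] = {}
    for pid in ids:
        by_arch.setdefault(proteome.archetype[pid], []).append(pid)

    n_same = sum(len(v) * (len(v) - 1) // 2 for v in by_arch.values())
    n_total = len(ids) * (len(ids) - 1) // 2
    if config.n_pos > n_same or config.n_neg > n_total - n_same:
        raise ValueError(
            f"proteome of {len(ids)} proteins cannot supply "
            f"{config.n_pos} same-archetype and {config.n_neg} "
            f"cross-archetype pairs"
        )

    arch_keys = sorted(by_arch)
    seen: set[tuple[str, str]] = set()

    def sample(n: int, same: bool, label: int) -> list[InteractionRecord]:
        out: list[InteractionRecord] = []
        attempts = 0
        max_attempts = 200 * n + 10_000
        while len(out) < n:
            attempts += 1
            if attempts > max_attempts:  # pragma: no cover - defensive
                raise ValueError("pair sampling failed to find enough pairs")
            if same:
                k = arch_keys[rng.integers(len(arch_keys))]
                pool = by_arch[k]
                if len(pool) < 2:
                    continue
                a, b = rng.choice(len(pool), size=2, replace=False)
                pa, pb = pool[a], pool[b]
            else:
                ka, kb = rng.choice(len(arch_keys), size=2, replace=False)
                pa = by_arch[arch_keys[ka]][rng.integers(len(by_arch[arch_keys[ka]]))]
                pb = by_arch[arch_keys[kb]][rng.integers(len(by_arch[arch_keys[kb]]))]
            key = (pa, pb) if pa < pb else (pb, pa)
            if pa == pb or key in seen:
                continue
            seen.add(key)
            out.append(InteractionRecord(pa, pb, label))
        return out

    positives = sample(config.n_pos, same=True, label=1)
    negatives = sample(config.n_neg, same=False, label=0)
    return positives, negatives
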