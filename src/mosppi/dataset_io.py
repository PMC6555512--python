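"""Reading sequence/pair files and assembling labeled pair-feature tables.

Inputs are a FASTA file of protein sequences and two-column, whitespace- or
tab-delimited interaction lists (one protein identifier per column, one
pair per line) — the shape interaction benchmarks are distributed in.

Before encoding, pair lists pass through the standard cleaning cascade:
pairs referring to unknown ids, self-interactions, duplicate pairs
(unordered by default), and pairs where either protein contains a
non-standard residue (B/J/O/U/X/Z, ...) or is shorter than 50 residues are
removed, each category counted in an :class:`ExclusionReport`.  An
optional *collision filter* additionally removes pairs whose two proteins
have equal length and identical group-count vectors — such proteins are
indistinguishable to composition-level descriptors; it is off by default.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio.SeqIO.FastaIO import SimpleFastaParser

from .groups import compute_group_counts_key, validate_protein

__all__ = [
    "InteractionRecord",
    "ExclusionReport",
    "PairFeatureTable",
    "read_fasta",
    "read_pairs",
    "filter_records",
    "build_pair_table",
    "split_train_holdout",
]


@dataclass(frozen=True)
class InteractionRecord:
    """One labeled protein pair: ids are opaque strings, label is 0 or 1."""

    id_a: str
    id_b: str
    label: int

    def __post_init__(self):
        if not self.id_a or not self.id_b:
            raise ValueError("protein ids must be non-empty")
        if self.label not in (0, 1):
            raise ValueError(f"label must be 0 or 1, got {self.label}")


class FastaParseError(ValueError):
    """Malformed FASTA input (e.g. sequence data before the first header)."""


def read_fasta(path) -> dict[str, str]:
    """Read a FASTA file into an id -> sequence mapping.

    Ids are the header token up to the first whitespace; wrapped sequence
    lines are concatenated and upper-cased.  A duplicate id overwrites the
    earlier record (last wins) with a warning.

    Raises
    ------
    FastaParseError
        If sequence data precedes the first ``>`` header, naming the line.
    """
    out: dict[str, str] = {}
    with open(path) as fh:
        # locate the first non-blank line: it must be a header
        pos = fh.tell()
        for lineno, line in enumerate(fh, start=1):
            if line.strip():
                if not line.startswith(">"):
                    raise FastaParseError(
                        f"line {lineno}: sequence data before first FASTA header"
                    )
                break
        fh.seek(pos)
        for header, seq in SimpleFastaParser(fh):
            pid = header.split()[0] if header.split() else header
            if pid in out:
                warnings.warn(
                    f"duplicate FASTA id {pid!r}: keeping the last record",
                    stacklevel=2,
                )
            out[pid] = seq.upper()
    return out


# Tokens that mark a first line as a column header rather than data.
_HEADER_TOKENS = {
    "protein", "proteina", "proteinb", "protein1", "protein2",
    "proteinid", "id", "ida", "idb", "interactor", "interactora",
    "interactorb",
}


def _looks_like_header(tokens: Sequence[str]) -> bool:
    def norm(t: str) -> str:
        return "".join(ch for ch in t.lower() if ch.isalnum())

    return all(norm(t) in _HEADER_TOKENS for t in tokens)


def read_pairs(path, label: int) -> list[InteractionRecord]:
    """Read a two-column pair list, attaching ``label`` to every record.

    Columns may be separated by tabs or any whitespace.  A first line
    whose tokens look like column names (e.g. ``proteinA proteinB``) is
    skipped with a warning.  Blank lines are ignored; any other line with
    a token count other than two raises with its line number.
    """
    records: list[InteractionRecord] = []
    with open(path) as fh:
        first_data_line = True
        for lineno, line in enumerate(fh, start=1):
            tokens = line.split()
            if not tokens:
                continue
            if len(tokens) != 2:
                raise ValueError(
                    f"{path}: line {lineno}: expected 2 columns, got {len(tokens)}"
                )
            if first_data_line and _looks_like_header(tokens):
                warnings.warn(
                    f"{path}: line {lineno} looks like a header and was skipped",
                    stacklevel=2,
                )
                first_data_line = False
                continue
            first_data_line = False
            records.append(InteractionRecord(tokens[0], tokens[1], label))
    return records


@dataclass
class ExclusionReport:
    """Counts of pairs removed by each cleaning rule, in application order."""

    missing_sequence: int = 0
    self_interactions: int = 0
    duplicates: int = 0
    unusual_residue: int = 0
    too_short: int = 0
    composition_collisions: int = 0

    @property
    def total(self) -> int:
        return (
            self.missing_sequence + self.self_interactions + self.duplicates
            + self.unusual_residue + self.too_short
            + self.composition_collisions
        )

    def as_dict(self) -> dict[str, int]:
        return asdict(self)


def filter_records(
    records: Iterable[InteractionRecord],
    sequences: Mapping[str, str],
    min_length: int = 50,
    drop_self: bool = True,
    drop_duplicates: bool = True,
    unordered_duplicates: bool = True,
    collision_filter: bool = False,
) -> tuple[list[InteractionRecord], ExclusionReport]:
    """Apply the cleaning cascade to a pair list.

    Rules apply in order, each pair charged to the first rule it fails:
    missing sequence, self-interaction, duplicate pair ((a,b) == (b,a)
    when ``unordered_duplicates``), invalid protein (non-standard residue,
    then length < ``min_length``), and optionally the composition
    collision rule (equal length and equal group-count vectors).
    Order-stable and idempotent; nothing is raised, every removal is
    counted in the returned :class:`ExclusionReport`.
    """
    report = ExclusionReport()
    kept: list[InteractionRecord] = []
    seen: set[tuple[str, str]] = set()
    validity_cache: dict[str, str | None] = {}
    collision_cache: dict[str, tuple] = {}

    def invalid_reason(pid: str) -> str | None:
        if pid not in validity_cache:
            verdict = validate_protein(sequences[pid], min_length=min_length)
            validity_cache[pid] = verdict.reason
        return validity_cache[pid]

    for rec in records:
        if rec.id_a not in sequences or rec.id_b not in sequences:
            report.missing_sequence += 1
            continue
        if drop_self and rec.id_a == rec.id_b:
            report.self_interactions += 1
            continue
        if drop_duplicates:
            key = (rec.id_a, rec.id_b)
            if unordered_duplicates and rec.id_b < rec.id_a:
                key = (rec.id_b, rec.id_a)
            if key in seen:
                report.duplicates += 1
                continue
            seen.add(key)
        reasons = {invalid_reason(rec.id_a), invalid_reason(rec.id_b)}
        reasons.discard(None)
        if reasons:
            # residue problems take precedence over length, as in validation
            if "unusual_residue" in reasons or "empty" in reasons:
                report.unusual_residue += 1
            else:
                report.too_short += 1
            continue
        if collision_filter:
            for pid in (rec.id_a, rec.id_b):
                if pid not in collision_cache:
                    collision_cache[pid] = compute_group_counts_key(
                        sequences[pid]
                    )
            if collision_cache[rec.id_a] == collision_cache[rec.id_b]:
                report.composition_collisions += 1
                continue
        kept.append(rec)
    return kept, report


@dataclass
class PairFeatureTable:
    """Labeled pair features: one row per pair, columns = concat(vec_a, vec_b)."""

    pair_ids: list[tuple[str, str]]
    X: np.ndarray  # (n_pairs, per_pair_dim) float64
    y: np.ndarray  # (n_pairs,) int
    encoder_name: str
    skipped: list[tuple[str, str, str]] = field(default_factory=list)

    def __post_init__(self):
        self.X = np.asarray(self.X, dtype=np.float64)
        self.y = np.asarray(self.y, dtype=np.int64)
        if self.X.shape[0] != self.y.shape[0] or self.X.shape[0] != len(
            self.pair_ids
        ):
            raise ValueError("pair_ids, X and y must have equal row counts")

    @property
    def n_rows(self) -> int:
        return self.X.shape[0]

    @property
    def per_pair_dim(self) -> int:
        return self.X.shape[1]

    @property
    def n_pos(self) -> int:
        return int((self.y == 1).sum())

    @property
    def n_neg(self) -> int:
        return int((self.y == 0).sum())

    def subset(self, idx: np.ndarray) -> "PairFeatureTable":
        idx = np.asarray(idx)
        return PairFeatureTable(
            pair_ids=[self.pair_ids[i] for i in idx],
            X=self.X[idx],
            y=self.y[idx],
            encoder_name=self.encoder_name,
        )


def build_pair_table(
    records: Sequence[InteractionRecord],
    sequences: Mapping[str, str],
    encoder,
) -> PairFeatureTable:
    """Encode every pair as concat(features(seq_a), features(seq_b)).

    Each distinct protein is encoded once.  A protein the encoder cannot
    handle (e.g. too short for its window) drops every pair involving it;
    dropped pairs are listed in ``table.skipped`` with the reason.
    """
    cache: dict[str, np.ndarray | None] = {}
    reasons: dict[str, str] = {}

    def vec(pid: str):
        if pid not in cache:
            try:
                cache[pid] = encoder.encode_one(sequences[pid])
            except Exception as exc:  # noqa: BLE001 - reported per row
                cache[pid] = None
                reasons[pid] = str(exc)
        return cache[pid]

    pair_ids, rows, labels, skipped = [], [], [], []
    for rec in records:
        va, vb = vec(rec.id_a), vec(rec.id_b)
        if va is None or vb is None:
            bad = rec.id_a if va is None else rec.id_b
            skipped.append((rec.id_a, rec.id_b, reasons[bad]))
            continue
        pair_ids.append((rec.id_a, rec.id_b))
        rows.append(np.concatenate([va, vb]))
        labels.append(rec.label)

    dim = 2 * encoder.per_protein_dim
    X = np.vstack(rows) if rows else np.empty((0, dim))
    return PairFeatureTable(
        pair_ids=pair_ids,
        X=X,
        y=np.asarray(labels, dtype=np.int64),
        encoder_name=encoder.name,
        skipped=skipped,
    )


def split_train_holdout(
    table: PairFeatureTable,
    n_train_pos: int,
    n_train_neg: int,
    seed: int,
) -> tuple[PairFeatureTable, PairFeatureTable]:
    """Stratified random split: exact per-class training counts, rest held out.

    Deterministic for a given seed; train and holdout are disjoint and
    together exhaust the table.
    """
    pos_idx = np.flatnonzero(table.y == 1)
    neg_idx = np.flatnonzero(table.y == 0)
    if n_train_pos > pos_idx.size or n_train_neg > neg_idx.size:
        raise ValueError(
            f"requested {n_train_pos} positives / {n_train_neg} negatives "
            f"but table has {pos_idx.size} / {neg_idx.size}"
        )
    rng = np.random.default_rng(seed)
    train_pos = rng.choice(pos_idx, size=n_train_pos, replace=False)
    train_neg = rng.choice(neg_idx, size=n_train_neg, replace=False)
    train_idx = np.sort(np.concatenate([train_pos, train_neg]))
    mask = np.zeros(table.n_rows, dtype=bool)
    mask[train_idx] = True
    holdout_idx = np.flatnonzero(~mask)
    return table.subset(train_idx), table.subset(holdout_idx)
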