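"""Multiple-sequence-alignment container, I/O, filtering and reweighting.

An alignment is held as an ``(M, N)`` integer matrix over the 21-state
alphabet (:mod:`coevonet.alphabet`), with optional per-sequence organism and
age metadata.  Filtering follows the conventions of mean-field direct
coupling analysis: sequences with ≥ 30 % gaps are discarded and sequences
that are > 70 % identical to others are down-weighted, so that the effective
number of sequences M_eff counts roughly-independent family members.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

from .alphabet import GAP_STATE, N_STATES, decode_sequence, encode_sequence


@dataclass
class AlignmentMatrix:
    """Aligned sequences over the 21-letter alphabet.

    Parameters
    ----------
    ids
        Unique sequence identifiers, length M.
    matrix
        ``(M, N)`` int8 array of alphabet states.
    organisms
        Optional per-sequence organism tags (length M).
    ages
        Optional per-sequence ages in My before present (extant = 0).
    """

    ids: list[str]
    matrix: np.ndarray
    organisms: list[str] | None = None
    ages: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.int8)
        if self.matrix.ndim != 2:
            raise ValueError("alignment matrix must be 2-D")
        if len(self.ids) != self.matrix.shape[0]:
            raise ValueError("number of ids does not match number of rows")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("sequence ids must be unique")
        if self.matrix.size and (self.matrix.min() < 0 or self.matrix.max() >= N_STATES):
            raise ValueError("matrix entries outside the 21-state alphabet")
        if self.ages is not None:
            self.ages = np.asarray(self.ages, dtype=float)

    @property
    def n_sequences(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_columns(self) -> int:
        return self.matrix.shape[1]

    def sequence(self, index: int) -> str:
        return decode_sequence(self.matrix[index])

    def gap_fractions(self) -> np.ndarray:
        """Per-sequence fraction of gap states."""
        if self.n_columns == 0:
            return np.zeros(self.n_sequences)
        return (self.matrix == GAP_STATE).mean(axis=1)

    def subset(self, indices: Sequence[int] | np.ndarray) -> "AlignmentMatrix":
        """Row subset preserving order and metadata."""
        idx = np.asarray(indices, dtype=int)
        return AlignmentMatrix(
            ids=[self.ids[i] for i in idx],
            matrix=self.matrix[idx],
            organisms=None if self.organisms is None else [self.organisms[i] for i in idx],
            ages=None if self.ages is None else self.ages[idx],
        )

    def with_metadata(self, meta: pd.DataFrame) -> "AlignmentMatrix":
        """Attach organism/age metadata from a table with columns
        ``id``, ``organism``, ``age_My`` (matched on id)."""
        table = meta.set_index("id")
        missing = [i for i in self.ids if i not in table.index]
        if missing:
            raise ValueError(f"metadata missing for ids: {missing[:5]}")
        organisms = [str(table.loc[i, "organism"]) for i in self.ids]
        ages = np.array([float(table.loc[i, "age_My"]) for i in self.ids])
        return replace(self, organisms=organisms, ages=ages)

    def write_fasta(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for i, sid in enumerate(self.ids):
                fh.write(f">{sid}\n{self.sequence(i)}\n")


@dataclass
class SequenceWeights:
    """Per-sequence down-weighting of redundant family members."""

    w: np.ndarray
    m_eff: float = field(init=False)

    def __post_init__(self) -> None:
        self.w = np.asarray(self.w, dtype=float)
        if self.w.size and (np.any(self.w <= 0) or np.any(self.w > 1 + 1e-12)):
            raise ValueError("weights must be in (0, 1]")
        self.m_eff = float(self.w.sum())


def read_alignment(path: str | Path, format: str = "fasta") -> AlignmentMatrix:
    """Read an alignment from a FASTA or Stockholm file.

    Lowercase letters (insert states), ``.``, ambiguity codes and
    non-standard residues are stored as gaps.  Ragged alignments raise a
    ``ValueError`` naming the offending sequence.
    """
    if format not in {"fasta", "stockholm"}:
        raise ValueError(f"unsupported alignment format: {format!r}")
    path = Path(path)
    records = list(SeqIO.parse(str(path), format))
    if not records:
        raise ValueError(f"no sequences found in {path}")
    ids = [r.id for r in records]
    rows = [str(r.seq) for r in records]
    n = len(rows[0])
    for sid, row in zip(ids, rows):
        if len(row) != n:
            raise ValueError(
                f"ragged alignment: sequence {sid!r} has length {len(row)}, expected {n}"
            )
    matrix = np.vstack([encode_sequence(r) for r in rows]) if n else np.zeros((len(rows), 0), np.int8)
    return AlignmentMatrix(ids=ids, matrix=matrix)


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Read the id/organism/age_My metadata TSV."""
    meta = pd.read_csv(path, sep="\t")
    required = {"id", "organism", "age_My"}
    if not required.issubset(meta.columns):
        raise ValueError(f"metadata must have columns {sorted(required)}")
    return meta


def filter_gap_fraction(aln: AlignmentMatrix, max_gap: float = 0.30) -> AlignmentMatrix:
    """Retain sequences whose gap fraction is strictly below ``max_gap``."""
    if not 0 <= max_gap <= 1:
        raise ValueError("max_gap must be in [0, 1]")
    keep = np.flatnonzero(aln.gap_fractions() < max_gap)
    if keep.size == 0:
        warnings.warn("gap filter removed every sequence", stacklevel=2)
    return aln.subset(keep)


def _mutual_gap_fraction(matrix: np.ndarray) -> np.ndarray:
    """Pairwise fraction of columns gapped in either sequence."""
    g = (matrix == GAP_STATE).astype(np.float32)
    n = matrix.shape[1]
    # |union| = |A| + |B| - |A ∩ B|
    inter = g @ g.T
    counts = g.sum(axis=1)
    union = counts[:, None] + counts[None, :] - inter
    return union / n


def select_representatives(
    aln: AlignmentMatrix, max_mutual_gap: float = 0.20
) -> AlignmentMatrix:
    """Select one sequence per organism and prune to mutual-gap compatibility.

    Within an organism the sequence with fewest gaps wins (ties: first in
    input order).  The surviving set is then greedily pruned — repeatedly
    dropping the sequence with most gaps (ties: later index) — until every
    retained pair has a union-gap fraction strictly below ``max_mutual_gap``.
    """
    if aln.organisms is None:
        raise ValueError("select_representatives requires organism metadata")
    gaps = (aln.matrix == GAP_STATE).sum(axis=1)
    best: dict[str, int] = {}
    for i, org in enumerate(aln.organisms):
        if org not in best or gaps[i] < gaps[best[org]]:
            best[org] = i
    keep = sorted(best.values())

    while len(keep) > 1:
        sub = aln.matrix[keep]
        mg = _mutual_gap_fraction(sub)
        np.fill_diagonal(mg, 0.0)
        if mg.max() < max_mutual_gap:
            break
        bad = np.flatnonzero((mg >= max_mutual_gap).any(axis=1))
        sub_gaps = gaps[np.asarray(keep)][bad]
        # drop the offender with most gaps; ties broken towards later rows
        worst = bad[np.flatnonzero(sub_gaps == sub_gaps.max())[-1]]
        keep.pop(int(worst))
    return aln.subset(keep)


def pairwise_identity(matrix: np.ndarray) -> np.ndarray:
    """All-against-all fraction of identical columns (gap–gap counts as a
    match), computed over all N columns via one-hot matrix products."""
    m, n = matrix.shape
    if n == 0:
        return np.ones((m, m))
    onehot = np.zeros((m, n * N_STATES), dtype=np.float32)
    cols = np.arange(n) * N_STATES
    onehot[np.arange(m)[:, None], cols[None, :] + matrix] = 1.0
    return (onehot @ onehot.T) / n


def compute_weights(
    aln: AlignmentMatrix, identity_threshold: float = 0.70
) -> SequenceWeights:
    """Down-weight redundant sequences.

    Each sequence s gets weight ``1 / |{t : identity(s, t) > threshold}|``
    with the neighbourhood including s itself, so weights lie in (0, 1] and
    M_eff = Σ w counts effectively independent sequences.
    """
    if aln.n_sequences < 1:
        raise ValueError("empty alignment")
    ident = pairwise_identity(aln.matrix)
    neighbours = (ident > identity_threshold).sum(axis=1)
    return SequenceWeights(w=1.0 / neighbours)
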