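"""Per-protein contact energies: tensor projection, native energy, profiles.

Projecting the family tensor onto one sequence gives the two-dimensional
interaction matrix ε_ij between its residues; the native energy E_N is the
sum over native contacts, and lower E_N means a more stable protein.  Gap
positions contribute zero automatically through the gap gauge.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .alphabet import (
    ALPHABET,
    GAP_STATE,
    HYDROPHOBIC_STATES,
    N_STATES,
    encode_sequence,
)
from .coevolution import CouplingTensor
from .structure import ContactMap


@dataclass
class ContactEnergyMatrix:
    """Symmetric ``(N, N)`` energy matrix of one protein, zero outside
    native contacts; units of evolutive temperature.

    ``contacts`` optionally records the native-contact support explicitly
    (so a genuinely zero-energy contact still counts as a contact); when
    absent, the nonzero entries define the support.
    """

    e: np.ndarray
    protein_id: str = "protein"
    age: float = 0.0
    contacts: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.e = np.asarray(self.e, dtype=float)
        n = self.e.shape[0]
        if self.e.shape != (n, n):
            raise ValueError("energy matrix must be square")
        if not np.allclose(self.e, self.e.T):
            raise ValueError("energy matrix must be symmetric")
        if self.contacts is not None:
            self.contacts = np.asarray(self.contacts, dtype=bool)
            if self.contacts.shape != (n, n):
                raise ValueError("contact support must match the matrix shape")

    @property
    def n_residues(self) -> int:
        return self.e.shape[0]

    def contact_support(self) -> np.ndarray:
        """Boolean native-contact adjacency (explicit or nonzero support)."""
        if self.contacts is not None:
            return self.contacts
        return self.e != 0


@dataclass
class SiteProfile:
    """Per-site scalar profile (e.g. E_i or f_i) of one protein."""

    values: np.ndarray
    protein_id: str = "protein"
    age: float = 0.0
    kind: str = "E_i"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)


def _as_codes(seq) -> np.ndarray:
    if isinstance(seq, str):
        return encode_sequence(seq)
    codes = np.asarray(seq)
    if codes.size and (codes.min() < 0 or codes.max() >= N_STATES):
        raise ValueError("sequence codes outside the 21-state alphabet")
    return codes.astype(np.int64)


def project_energies(
    t: CouplingTensor,
    seq,
    cm: ContactMap | None = None,
    protein_id: str = "protein",
    age: float = 0.0,
) -> ContactEnergyMatrix:
    """Project the family tensor on one sequence: e(i,j) = ε_ij(σ_i, σ_j).

    If a contact map is given, non-contact entries are zeroed.  Gapped
    positions yield zero rows/columns via the gap gauge.
    """
    codes = _as_codes(seq)
    n = t.n_columns
    if len(codes) != n:
        raise ValueError(f"sequence length {len(codes)} != tensor size {n}")
    e = t.eps[np.arange(n)[:, None], np.arange(n)[None, :], codes[:, None], codes[None, :]]
    contacts = None
    if cm is not None:
        if cm.n_residues != n:
            raise ValueError("contact map size does not match tensor")
        e = e * cm.adj
        contacts = cm.adj.copy()
    return ContactEnergyMatrix(e=e, protein_id=protein_id, age=age, contacts=contacts)


def native_energy(m: ContactEnergyMatrix) -> float:
    """E_N = Σ_{i<j} e(i,j); lower is more stable."""
    return float(np.triu(m.e, k=1).sum())


def site_energy_profile(
    m: ContactEnergyMatrix, eps_th: float, strong_only: bool = True
) -> SiteProfile:
    """Per-site sum E_i of strongly attractive contact energies.

    By default only contacts with e < eps_th contribute (the strongly
    interacting contacts of each site); with ``strong_only=False`` every
    negative energy is summed instead.
    """
    mask = m.e < eps_th if strong_only else m.e < 0
    values = (m.e * mask).sum(axis=1)
    return SiteProfile(values=values, protein_id=m.protein_id, age=m.age, kind="E_i")


@dataclass
class CompositionProfile:
    """Residue-type fractions of one sequence (21 states, summing to 1)
    plus the fraction of hydrophobic residues {A,V,L,I,M,F,W,C} among
    non-gap positions."""

    fractions: np.ndarray
    hydrophobic_fraction: float


def composition_profile(seq) -> CompositionProfile:
    codes = _as_codes(seq)
    counts = np.bincount(codes, minlength=N_STATES).astype(float)
    fractions = counts / counts.sum() if counts.sum() else counts
    non_gap = counts.sum() - counts[GAP_STATE]
    hydro = sum(counts[s] for s in HYDROPHOBIC_STATES)
    hfrac = float(hydro / non_gap) if non_gap else 0.0
    return CompositionProfile(fractions=fractions, hydrophobic_fraction=hfrac)
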