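"""Mean-field inverse-Potts inference of residue–residue contact energies.

Homologous sequences in a family alignment are treated as equilibrium
samples of a Potts model over 21 states (20 residues + gap).  Weighted,
pseudocounted one- and two-site frequencies are inverted — in the mean-field
approximation, by inverting the connected-correlation matrix over the 20
non-gap states — into an ``(N, N, 21, 21)`` tensor of pair interaction
energies ε_ij(σ, ρ) expressed in units of the evolutive temperature.

Sign convention: a residue pair that co-occurs more often than its
single-site frequencies predict receives a *negative* (attractive) energy,
so lower projected native energies mean more stable proteins.  The gauge is
fixed by setting every interaction that involves the gap state to zero
("gap gauge"); the inversion works in the gap-excluded 20-state space, so
the gauge holds exactly by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .alignment_io import AlignmentMatrix, SequenceWeights
from .alphabet import ALPHABET, GAP_STATE, N_STATES

N_RESIDUES = N_STATES - 1  # non-gap states


@dataclass(frozen=True)
class PseudocountConfig:
    """Relative pseudocount masses, all scaling with M_eff.

    x weights a uniform prior over the 21 states, y the alignment-wide
    residue composition and z the per-site composition.
    """

    x: float = 0.5
    y: float = 0.1
    z: float = 1.0

    def __post_init__(self) -> None:
        if self.x < 0 or self.y < 0 or self.z < 0:
            raise ValueError("pseudocount masses must be non-negative")

    @property
    def total(self) -> float:
        return self.x + self.y + self.z


@dataclass
class FrequencyTables:
    """One-site ``(N, 21)`` and two-site ``(N, N, 21, 21)`` frequencies."""

    f1: np.ndarray
    f2: np.ndarray

    def __post_init__(self) -> None:
        self.f1 = np.asarray(self.f1, dtype=float)
        self.f2 = np.asarray(self.f2, dtype=float)
        n = self.f1.shape[0]
        if self.f1.shape != (n, N_STATES) or self.f2.shape != (n, n, N_STATES, N_STATES):
            raise ValueError("inconsistent frequency-table shapes")

    @property
    def n_columns(self) -> int:
        return self.f1.shape[0]


@dataclass
class CouplingTensor:
    """Pair interaction energies ε_ij(σ, ρ) for one protein family.

    Invariants: ε_ij(σ, ρ) = ε_ji(ρ, σ); all entries involving the gap
    state are zero (gap gauge); diagonal site blocks i = j are zero.
    """

    eps: np.ndarray
    family: str = "family"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.eps = np.asarray(self.eps, dtype=float)
        n = self.eps.shape[0]
        if self.eps.shape != (n, n, N_STATES, N_STATES):
            raise ValueError("coupling tensor must be (N, N, 21, 21)")

    @property
    def n_columns(self) -> int:
        return self.eps.shape[0]

    def save(self, path: str | Path) -> None:
        """Serialise to an .npz container with alphabet and provenance."""
        np.savez_compressed(
            path,
            eps=self.eps,
            family=np.array(self.family),
            alphabet=np.array(ALPHABET),
            **{f"meta_{k}": np.array(v) for k, v in self.meta.items()},
        )

    @classmethod
    def load(cls, path: str | Path) -> "CouplingTensor":
        data = np.load(path, allow_pickle=False)
        if str(data["alphabet"]) != ALPHABET:
            raise ValueError("tensor was built with a different alphabet order")
        meta = {k[5:]: data[k].item() for k in data.files if k.startswith("meta_")}
        return cls(eps=data["eps"], family=str(data["family"]), meta=meta)

    def pair_summary(self):
        """Per-pair min/mean/max over (σ, ρ) as a tidy table (i, j 1-based)."""
        import pandas as pd

        n = self.n_columns
        i, j = np.triu_indices(n, k=1)
        block = self.eps[i, j]
        return pd.DataFrame(
            {
                "i": i + 1,
                "j": j + 1,
                "min_eps": block.min(axis=(1, 2)),
                "mean_eps": block.mean(axis=(1, 2)),
                "max_eps": block.max(axis=(1, 2)),
            }
        )


def _one_hot(matrix: np.ndarray) -> np.ndarray:
    m, n = matrix.shape
    x = np.zeros((m, n, N_STATES), dtype=np.float64)
    x[np.arange(m)[:, None], np.arange(n)[None, :], matrix] = 1.0
    return x


def count_frequencies(
    aln: AlignmentMatrix,
    weights: SequenceWeights | None = None,
    pc: PseudocountConfig = PseudocountConfig(),
) -> FrequencyTables:
    """Weighted, pseudocounted one- and two-site frequencies.

    With weighted counts n_i(σ), weighted alignment composition c(σ) and
    site composition c_i(σ) = n_i(σ)/M_eff::

        f1(i,σ) = [n_i(σ) + x·M_eff/21 + y·M_eff·c(σ) + z·M_eff·c_i(σ)]
                  / [M_eff·(1 + x + y + z)]

    The two-site pseudocount mass factorises into the product of the
    one-site pseudocount distributions, which keeps the f2 → f1
    marginalisation exact.  Diagonal blocks f2(i,i,σ,ρ) = δ_σρ f1(i,σ).
    """
    m = aln.n_sequences
    if m == 0:
        raise ValueError("empty alignment")
    w = np.ones(m) if weights is None else np.asarray(weights.w, dtype=float)
    m_eff = float(w.sum())
    if m_eff <= 0:
        raise ValueError("M_eff must be positive")
    n = aln.n_columns

    x1 = _one_hot(aln.matrix)
    n1 = np.einsum("s,sia->ia", w, x1)  # (N, 21) weighted counts
    c_aln = n1.sum(axis=0) / (m_eff * n)  # alignment-wide composition
    c_site = n1 / m_eff

    total = pc.total
    if total > 0:
        # per-site pseudocount distribution (normalised to 1 over states)
        p_site = (pc.x / N_STATES + pc.y * c_aln[None, :] + pc.z * c_site) / total
    else:
        p_site = np.zeros_like(n1)
    denom = m_eff * (1.0 + total)
    f1 = (n1 + total * m_eff * p_site) / denom

    flat = x1.reshape(m, n * N_STATES)
    n2 = (flat * w[:, None]).T @ flat  # (N·21, N·21)
    n2 = n2.reshape(n, N_STATES, n, N_STATES).transpose(0, 2, 1, 3)
    f2 = (n2 + total * m_eff * np.einsum("ia,jb->ijab", p_site, p_site)) / denom
    # diagonal blocks: a site is jointly itself, consistent with f1
    for i in range(n):
        f2[i, i] = np.diag(f1[i])
    return FrequencyTables(f1=f1, f2=f2)


def infer_couplings(freqs: FrequencyTables, family: str = "family") -> CouplingTensor:
    """Invert connected correlations into the coupling tensor (mean field).

    The correlation matrix C_ij(σ,ρ) = f2 − f1 f1 restricted to the 20
    non-gap states is inverted as an (N·20, N·20) matrix; its off-diagonal
    blocks are the couplings, embedded into 21 states with zeros for every
    gap entry and for the diagonal site blocks.
    """
    n = freqs.n_columns
    q = N_RESIDUES
    c = freqs.f2[:, :, :q, :q] - np.einsum(
        "ia,jb->ijab", freqs.f1[:, :q], freqs.f1[:, :q]
    )
    c = c.transpose(0, 2, 1, 3).reshape(n * q, n * q)
    c = 0.5 * (c + c.T)
    try:
        cinv = np.linalg.inv(c)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            "singular correlation matrix; increase the pseudocount masses "
            "(PseudocountConfig) so every residue state has support"
        ) from exc
    cinv = 0.5 * (cinv + cinv.T)
    blocks = cinv.reshape(n, q, n, q).transpose(0, 2, 1, 3)
    eps = np.zeros((n, n, N_STATES, N_STATES))
    # ε = +C⁻¹ off-diagonal blocks: positive connected correlation (pair
    # co-occurring above independence) gives a negative, attractive energy.
    eps[:, :, :q, :q] = blocks
    idx = np.arange(n)
    eps[idx, idx] = 0.0
    eps = 0.5 * (eps + eps.transpose(1, 0, 3, 2))
    return CouplingTensor(eps=eps, family=family)


def apply_gap_gauge(t: CouplingTensor) -> CouplingTensor:
    """Re-gauge an externally supplied tensor so gap interactions vanish.

    ε'(σ,ρ) = ε(σ,ρ) − ε(σ,gap) − ε(gap,ρ) + ε(gap,gap).  The transform
    is a pure gauge shift: double differences over (σ,ρ) pairs are
    unchanged.  Idempotent; tensors from :func:`infer_couplings` are
    already in this gauge.
    """
    e = t.eps
    g = GAP_STATE
    gauged = (
        e
        - e[:, :, :, g][:, :, :, None]
        - e[:, :, g, :][:, :, None, :]
        + e[:, :, g, g][:, :, None, None]
    )
    # analytically zero; enforce bit-exactly against float round-off
    gauged[:, :, g, :] = 0.0
    gauged[:, :, :, g] = 0.0
    return CouplingTensor(eps=gauged, family=t.family, meta=dict(t.meta))
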