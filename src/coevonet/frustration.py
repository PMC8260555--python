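"""Frustration via the scaling of segment interfacial energies.

Following Anderson's criterion, the protein is partitioned into a
contiguous chain segment of length L and the rest; the interfacial energy
E is the signed sum of native-contact energies crossing the cut.  For a
frustration-free ("ferromagnetic-like") system the mean square energy
E²(L), normalised by L², is flat in L; compensation between attractive and
repulsive interactions in a frustrated system makes it decay as 1/L^α.
The exponent α — fitted in the pre-drop linear region of the log-log
curve — is the frustration measure: larger α, more frustrated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .energetics import ContactEnergyMatrix


@dataclass
class ScalingResult:
    """Fitted interfacial-energy scaling: mean_sq(L) = E²(L)/L² and the
    exponent α of its 1/L^α decay over ``fit_range`` (inclusive bounds)."""

    L_values: np.ndarray
    mean_sq: np.ndarray
    alpha: float
    fit_range: tuple[int, int]
    fit_quality: float  # R² of the log-log linear fit


def interfacial_energy(m: ContactEnergyMatrix, start: int, length: int) -> float:
    """Signed energy across the cut between segment [start, start+length)
    (0-based) and the rest of the chain."""
    n = m.n_residues
    if start < 0 or length < 1 or start + length > n:
        raise ValueError("segment out of chain bounds")
    inside = np.zeros(n, dtype=bool)
    inside[start : start + length] = True
    return float(m.e[inside][:, ~inside].sum())


def mean_square_interfacial(m: ContactEnergyMatrix, L: int) -> float:
    """Average of E² over all N−L+1 contiguous windows, divided by L²."""
    n = m.n_residues
    if not 1 <= L <= n - 1:
        raise ValueError(f"L must be in [1, {n - 1}]")
    energies = [interfacial_energy(m, s, L) for s in range(n - L + 1)]
    return float(np.mean(np.square(energies)) / L**2)


def scaling_curve(m: ContactEnergyMatrix, L_values=None) -> tuple[np.ndarray, np.ndarray]:
    """mean_square_interfacial over a set of segment lengths."""
    n = m.n_residues
    if L_values is None:
        L_values = np.arange(1, n)
    L_values = np.asarray(L_values, dtype=int)
    return L_values, np.array([mean_square_interfacial(m, int(L)) for L in L_values])


def min_contact_separation(m: ContactEnergyMatrix) -> int:
    """Smallest chain separation |i−j| among native contacts (0 if none)."""
    iu, ju = np.where(np.triu(m.contact_support(), k=1))
    return int((ju - iu).min()) if iu.size else 0


def default_fit_range(m: ContactEnergyMatrix) -> tuple[int, int]:
    """Pre-drop linear-region bounds for the log-log fit.

    The Anderson exponent is meaningful where the cut area (number of
    contacts crossing the segment boundary) grows proportionally to the
    segment length L.  That holds exactly while L stays below the shortest
    contact separation of the map — beyond it, contacts start falling
    inside the window and the curve enters its geometric drop regardless
    of the energies.  The default range is therefore
    [1, max(3, min separation)]; the lower bound of 3 distinct lengths is
    required by the fit.
    """
    return 1, max(3, min_contact_separation(m))


def fit_power_law(
    L_values: np.ndarray, mean_sq: np.ndarray, fit_range: tuple[int, int]
) -> ScalingResult:
    """Fit mean_sq ∝ 1/L^α by least squares on log-log within fit_range."""
    L_values = np.asarray(L_values, dtype=float)
    mean_sq = np.asarray(mean_sq, dtype=float)
    lo, hi = fit_range
    mask = (L_values >= lo) & (L_values <= hi)
    if mask.sum() < 3:
        raise ValueError("fit range must contain at least 3 segment lengths")
    if np.any(mean_sq[mask] <= 0):
        raise ValueError("non-positive mean-square energy inside fit range")
    x = np.log(L_values[mask])
    y = np.log(mean_sq[mask])
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 1.0
    return ScalingResult(
        L_values=L_values.astype(int),
        mean_sq=mean_sq,
        alpha=float(-slope),
        fit_range=(int(lo), int(hi)),
        fit_quality=r2,
    )


def scaling_exponent(
    m: ContactEnergyMatrix,
    fit_range: tuple[int, int] | None = None,
    auto: bool = False,
    r2_min: float = 0.9,
) -> ScalingResult:
    """Frustration exponent α of one protein.

    With ``auto=True`` the upper fit bound is extended beyond the default
    while the log-log fit keeps R² >= ``r2_min``; otherwise the fixed
    ``fit_range`` (default: :func:`default_fit_range`) is used.  Report α
    together with the fit range used.
    """
    n = m.n_residues
    lo, hi = fit_range if fit_range is not None else default_fit_range(m)
    L_all = np.arange(1, n)
    L_vals, curve = scaling_curve(m, L_all)
    result = fit_power_law(L_vals, curve, (lo, hi))
    if not auto:
        return result
    best = result
    for hi_ext in range(hi + 1, n - 1):
        try:
            cand = fit_power_law(L_vals, curve, (lo, hi_ext))
        except ValueError:
            break
        if cand.fit_quality < r2_min:
            break
        best = cand
    return best
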