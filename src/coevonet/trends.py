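"""Trend statistics of per-protein quantities against evolutionary time.

Ages are given in My before present (extant = 0).  All regressions use the
forward time coordinate t = −age, so a *positive* slope means the quantity
increases towards the present (e.g. destabilisation when the quantity is
the native energy E_N).  Significance comes from a two-sided permutation
test on the slope (the value↔age pairing is reshuffled, preserving both
marginals) and from Kendall's tau-b monotonicity test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .energetics import SiteProfile

DEFAULT_N_BOOT = 100_000


@dataclass
class TrendResult:
    """Slope (per My, positive towards the present), permutation p-value of
    the slope, and Kendall tau-b with its p-value."""

    slope: float
    p_bootstrap: float
    kendall_tau: float
    p_kendall: float
    n: int
    n_boot: int
    seed: int | None = None


def _validate(values, ages, min_n: int = 3) -> tuple[np.ndarray, np.ndarray]:
    values = np.asarray(values, dtype=float)
    ages = np.asarray(ages, dtype=float)
    if values.shape != ages.shape or values.ndim != 1:
        raise ValueError("values and ages must be 1-D arrays of equal length")
    if values.size < min_n:
        raise ValueError(f"need at least {min_n} proteins")
    return values, ages


def linear_trend(values, ages) -> float:
    """OLS slope of the quantity against forward time t = −age (per My)."""
    values, ages = _validate(values, ages)
    t = -ages
    if np.ptp(t) == 0:
        raise ValueError("all ages are equal; slope undefined")
    tc = t - t.mean()
    return float(tc @ (values - values.mean()) / (tc @ tc))


def bootstrap_slope_pvalue(
    values, ages, n_boot: int = DEFAULT_N_BOOT, seed=None
) -> float:
    """Two-sided permutation p-value of the slope.

    The value↔age pairing is permuted ``n_boot`` times and
    p = (1 + #{|slope_perm| >= |slope_obs|}) / (n_boot + 1); the add-one
    correction keeps p > 0.
    """
    values, ages = _validate(values, ages)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    observed = abs(linear_trend(values, ages))
    t = -ages
    tc = t - t.mean()
    sxx = float(tc @ tc)
    vc = values - values.mean()
    perms = np.empty((n_boot, values.size))
    for b in range(n_boot):
        perms[b] = vc[rng.permutation(values.size)]
    slopes = perms @ tc / sxx
    exceed = int(np.sum(np.abs(slopes) >= observed - 1e-15))
    return (1 + exceed) / (n_boot + 1)


def kendall_trend(values, ages) -> tuple[float, float]:
    """Kendall tau-b (with tie correction) of the quantity vs forward time.

    Uses exact enumeration for small tie-free samples and the normal
    approximation otherwise (scipy's default policy)."""
    values, ages = _validate(values, ages)
    if np.ptp(values) == 0 and np.ptp(ages) == 0:
        raise ValueError("all values and all ages tied; tau undefined")
    res = stats.kendalltau(-ages, values)
    tau, p = float(res.statistic), float(res.pvalue)
    if np.isnan(tau):
        raise ValueError("Kendall tau undefined (fully tied input)")
    return tau, p


def trend_result(
    values, ages, n_boot: int = DEFAULT_N_BOOT, seed: int | None = None
) -> TrendResult:
    """Bundle slope, permutation p and Kendall test for one quantity."""
    values, ages = _validate(values, ages)
    slope = linear_trend(values, ages)
    tau, p_k = kendall_trend(values, ages)
    if n_boot > 0:
        p_b = bootstrap_slope_pvalue(values, ages, n_boot=n_boot, seed=seed)
    else:
        p_b = float("nan")
    return TrendResult(
        slope=slope,
        p_bootstrap=p_b,
        kendall_tau=tau,
        p_kendall=p_k,
        n=values.size,
        n_boot=n_boot,
        seed=seed,
    )


def trend_table(
    df: pd.DataFrame,
    quantities: list[str],
    age_column: str = "age_My",
    n_boot: int = DEFAULT_N_BOOT,
    seed: int | None = None,
) -> pd.DataFrame:
    """Per-quantity trend summary (slope, p_bootstrap, kendall_tau,
    p_kendall) from a tidy per-protein results table."""
    rows = []
    for q in quantities:
        sub = df[[age_column, q]].dropna()
        try:
            res = trend_result(sub[q].to_numpy(), sub[age_column].to_numpy(), n_boot, seed)
        except ValueError:
            # degenerate quantity (e.g. constant across proteins): no trend
            nan = float("nan")
            res = TrendResult(nan, nan, nan, nan, len(sub), n_boot, seed)
        rows.append(
            {
                "quantity": q,
                "slope_per_My": res.slope,
                "p_bootstrap": res.p_bootstrap,
                "kendall_tau": res.kendall_tau,
                "p_kendall": res.p_kendall,
                "n": res.n,
            }
        )
    return pd.DataFrame(rows)


def age_binned_profile(profiles: list[SiteProfile]) -> pd.DataFrame:
    """Mean site profile per age group, ordered by age.

    Proteins with identical age are averaged site-wise; returns a tidy
    frame with columns age_My, site (1-based), value."""
    if not profiles:
        raise ValueError("no profiles given")
    by_age: dict[float, list[np.ndarray]] = {}
    for p in profiles:
        by_age.setdefault(float(p.age), []).append(p.values)
    rows = []
    for age in sorted(by_age):
        mean = np.mean(np.vstack(by_age[age]), axis=0)
        for site, value in enumerate(mean, start=1):
            rows.append({"age_My": age, "site": site, "value": float(value)})
    return pd.DataFrame(rows)
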