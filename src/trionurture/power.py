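"""Design power under family clustering via effective sample size.

Clustered observations (twin pairs and siblings share family environment
and genes) are converted to an effective number of independent
observations with the design-effect formula

    N_e = N * M / (1 + ICC * (M - 1))

per family stratum (N families of size M with phenotypic intraclass
correlation ICC); strata contribute additively.  The power of the test of
a single standardized regression coefficient explaining a fraction ``r2``
of phenotypic variance is then evaluated from the noncentral F
distribution with df1 = 1, df2 = floor(N_e) - 2 and noncentrality
``N_e * r2 / (1 - r2)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats


@dataclass
class FamilyBlock:
    """A stratum of equally-sized families with a common ICC."""

    n_families: int
    family_size: int
    icc: float

    def __post_init__(self) -> None:
        if self.n_families < 1 or self.family_size < 1:
            raise ValueError("n_families and family_size must be >= 1")
        if not (0.0 <= self.icc < 1.0):
            raise ValueError("icc must be in [0, 1)")


@dataclass
class PowerQuery:
    """Power query over one or more family strata.

    Exactly one of ``r2`` (solve for power) or ``target_power`` (solve for
    detectable R2) must be set.
    """

    blocks: list[FamilyBlock]
    alpha: float = 0.01
    r2: float | None = None
    target_power: float | None = None

    def __post_init__(self) -> None:
        if not self.blocks:
            raise ValueError("at least one family block required")
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must be in (0, 1)")
        if (self.r2 is None) == (self.target_power is None):
            raise ValueError("set exactly one of r2 and target_power")
        if self.r2 is not None and not (0.0 < self.r2 < 1.0):
            raise ValueError("r2 must be in (0, 1)")
        if self.target_power is not None and not (
                self.alpha < self.target_power < 1.0):
            raise ValueError("target_power must be in (alpha, 1)")


def effective_n(block: FamilyBlock | list[FamilyBlock]) -> float:
    """Effective independent sample size; strata sum."""
    blocks = block if isinstance(block, list) else [block]
    return float(sum(
        b.n_families * b.family_size / (1.0 + b.icc * (b.family_size - 1))
        for b in blocks))


def power_at(effective_n: float, r2: float, alpha: float = 0.01) -> float:
    """Power of the single-coefficient test from the noncentral F."""
    if effective_n <= 2:
        raise ValueError("effective_n must exceed 2")
    if not (0.0 < r2 < 1.0):
        raise ValueError("r2 must be in (0, 1)")
    df2 = int(np.floor(effective_n)) - 2
    f_crit = stats.f.ppf(1.0 - alpha, 1, df2)
    lam = effective_n * r2 / (1.0 - r2)
    return float(stats.ncf.sf(f_crit, 1, df2, lam))


def detectable_r2(effective_n: float, alpha: float = 0.01,
                  target_power: float = 0.80) -> float:
    """Smallest R2 detectable with the requested power (bracketing search)."""
    if not (alpha < target_power < 1.0):
        raise ValueError("target_power must be in (alpha, 1)")

    def gap(r2: float) -> float:
        return power_at(effective_n, r2, alpha) - target_power

    return float(optimize.brentq(gap, 1e-10, 1.0 - 1e-10, xtol=1e-12))


def power_curve(query: PowerQuery, r2_grid: np.ndarray,
                icc_shift: float = 0.1) -> pd.DataFrame:
    """Power over an R2 grid, with ICC +/- ``icc_shift`` sensitivity bands."""
    r2_grid = np.asarray(r2_grid, dtype=float)
    rows = {}
    for label, shift in [("power", 0.0), ("power_icc_low", -icc_shift),
                         ("power_icc_high", icc_shift)]:
        blocks = [FamilyBlock(b.n_families, b.family_size,
                              float(np.clip(b.icc + shift, 0.0, 1.0 - 1e-9)))
                  for b in query.blocks]
        ne = effective_n(blocks)
        rows[label] = [power_at(ne, r2, query.alpha) for r2 in r2_grid]
    out = pd.DataFrame({"r2": r2_grid, **rows})
    out.attrs["effective_n"] = effective_n(query.blocks)
    return out
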