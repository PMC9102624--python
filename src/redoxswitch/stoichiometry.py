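"""Stoichiometry inference and thiol/disulfide assay bookkeeping.

Covers the power-law relation between fractional H2O2 consumption and
fractional irreversible inactivation (whose exponent ratio reads off the
reacting stoichiometry), end-point titration summaries, and the
Beer-Lambert / Ellman arithmetic converting TNB absorbances into cysteine,
disulfide and adduct counts.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np

__all__ = [
    "InactivationSeries",
    "PowerLawFit",
    "AssayConstants",
    "power_law_stoichiometry",
    "fraction_irreversible",
    "endpoint_titration",
    "tnb_concentration",
    "cysteines_per_subunit",
    "disulfides_from_ntsb",
    "adduct_stoichiometry",
]


@dataclass(frozen=True)
class AssayConstants:
    """Extinction coefficients and fixed assay stoichiometries.

    The TNB extinction at 412 nm is reported both as 14,150 and
    14,100 M-1 cm-1 in the source protocols; the default is 14,150 with
    14,100 selectable, and reports record which was used.
    """

    epsilon_tnb_412: float = 14150.0
    ntsb_disulfide_yield: int = 1  # mol TNB per mol disulfide on sulfitolysis
    allicin_tnb_stoich: int = 2  # mol TNB consumed per mol thiosulfinate

    def __post_init__(self) -> None:
        if self.epsilon_tnb_412 <= 0:
            raise ValueError("extinction coefficient must be positive")
        if self.ntsb_disulfide_yield < 1 or self.allicin_tnb_stoich < 1:
            raise ValueError("stoichiometries must be positive integers")


@dataclass
class InactivationSeries:
    """Paired fractions sampled during an oxidation time course.

    ``x`` is fractional thiol-irreversible inactivation (P0 - P')/P0 and
    ``y`` fractional H2O2 consumption (B0 - B') normalized by the total
    consumable H2O2 (two equivalents per subunit), so both live on [0, 1].
    """

    x: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.x.shape != self.y.shape or self.x.ndim != 1:
            raise ValueError("x and y must be 1-D arrays of equal length")
        for name, v in (("x", self.x), ("y", self.y)):
            if np.any(v < 0) or np.any(v > 1):
                raise ValueError(f"{name} must lie in [0, 1]")

    def __len__(self) -> int:
        return len(self.x)


@dataclass(frozen=True)
class PowerLawFit:
    """Exponents of ``y**alpha_prime = x**beta_prime``; alpha'/beta' is the
    ratio of reacting stoichiometries (H2O2 per inactivation event)."""

    alpha_prime: float
    beta_prime: float
    r_squared: float

    def __post_init__(self) -> None:
        if self.alpha_prime <= 0 or self.beta_prime <= 0:
            raise ValueError("power-law exponents must be positive")

    @property
    def ratio(self) -> float:
        return self.alpha_prime / self.beta_prime


def power_law_stoichiometry(
    series: InactivationSeries,
    fix_beta: Optional[float] = 1.0,
    floor: float = 0.02,
) -> PowerLawFit:
    """Fit ``y**alpha' = x**beta'`` by least squares in log-log space.

    Only the ratio beta'/alpha' (the log-log slope of y on x) is
    identifiable, so ``beta_prime`` is fixed — at 1 by default, matching
    the one-subunit normalization of the inactivation axis.  Pairs with
    x or y below ``floor`` are dropped before the log transform to avoid
    log-space noise amplification near zero.
    """
    if fix_beta is None:
        fix_beta = 1.0
    if fix_beta <= 0:
        raise ValueError("fix_beta must be positive")
    keep = (series.x >= floor) & (series.y >= floor)
    x, y = series.x[keep], series.y[keep]
    if len(x) < 6:
        raise ValueError("need at least 6 pairs above the noise floor")
    if x.max() - x.min() < 0.3:
        raise ValueError("degenerate span: x must cover a substantial part of [0, 1]")
    lx, ly = np.log(x), np.log(y)
    slope, intercept = np.polyfit(lx, ly, 1)
    if slope <= 0:
        raise ValueError("non-positive log-log slope; series is not a power law")
    pred = slope * lx + intercept
    sst = float(np.sum((ly - ly.mean()) ** 2))
    r2 = 1.0 - float(np.sum((ly - pred) ** 2)) / sst if sst > 0 else 1.0
    return PowerLawFit(alpha_prime=fix_beta / slope, beta_prime=fix_beta, r_squared=r2)


def fraction_irreversible(activity_with_dtt: float, native_activity: float) -> float:
    """Fractional irreversible inactivation x = (P0 - P')/P0, clamped to [0, 1].

    ``activity_with_dtt`` is the rate remaining after excess DTT (P');
    activity lost even in the presence of DTT is irreversibly gone.
    """
    if native_activity <= 0:
        raise ValueError("native activity must be positive")
    if activity_with_dtt < 0:
        raise ValueError("activities cannot be negative")
    return float(np.clip(1.0 - activity_with_dtt / native_activity, 0.0, 1.0))


def endpoint_titration(endpoints: Sequence[float]) -> Tuple[float, float]:
    """Mean and sample SD of replicate end-point consumptions (mol/mol)."""
    e = np.asarray(endpoints, dtype=float)
    if e.ndim != 1 or len(e) < 2:
        raise ValueError("need at least 2 replicate end points")
    return float(e.mean()), float(e.std(ddof=1))


def tnb_concentration(
    a412: float, constants: AssayConstants = AssayConstants(), path_cm: float = 1.0
) -> float:
    """Beer-Lambert conversion of 412-nm absorbance to molar TNB."""
    if a412 < 0:
        raise ValueError("absorbance must be non-negative")
    if path_cm <= 0:
        raise ValueError("path length must be positive")
    return a412 / (constants.epsilon_tnb_412 * path_cm)


def cysteines_per_subunit(tnb: float, protein_tetramer: float, subunits: int = 4) -> float:
    """Titratable cysteines per subunit from molar TNB released."""
    if protein_tetramer <= 0:
        raise ValueError("protein concentration must be positive")
    if subunits < 1:
        raise ValueError("subunits must be >= 1")
    return (tnb / protein_tetramer) / subunits


def disulfides_from_ntsb(
    tnb: float, protein: float, constants: AssayConstants = AssayConstants()
) -> float:
    """Disulfides per mol protein: alkaline sulfitolysis releases
    ``ntsb_disulfide_yield`` (=1) mol TNB per mol disulfide."""
    if protein <= 0:
        raise ValueError("protein concentration must be positive")
    return (tnb / protein) / constants.ntsb_disulfide_yield


def adduct_stoichiometry(
    tnb_after_dtt: float, protein: float, per_subunit: bool = False, subunits: int = 4
) -> float:
    """Mol bound CSSTNB per mol protein (or per subunit) from the TNB
    released by DTT reduction of the adducts."""
    if protein <= 0:
        raise ValueError("protein concentration must be positive")
    if tnb_after_dtt < 0:
        raise ValueError("TNB concentration must be non-negative")
    per_mol = tnb_after_dtt / protein
    return per_mol / subunits if per_subunit else per_mol
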