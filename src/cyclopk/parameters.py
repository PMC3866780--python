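"""Compound definitions and scalar rate-constant calibration.

First-order rate constants are stored internally in min^-1. Published
rate-constant tables for these compounds quote the same quantities scaled
by 10^3 (e.g. a 30 min GI half-life gives k = ln2/30 = 0.0231 min^-1,
tabulated as 23.1); :func:`display_rate` applies that convention. The
short-range kinetics deliberately use the x10^3 magnitudes at face value
(see :mod:`cyclopk.shortrange`), because only that reading reproduces the
reference peak times at sub-minute scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

LN2 = math.log(2.0)

__all__ = [
    "CompoundParameters",
    "RateConstants",
    "FoldRefinement",
    "ReportedPeaks",
    "half_life_to_rate",
    "rate_to_half_life",
    "dissolution_fold",
    "fold_factor",
    "refine_rates",
    "hydrophobic_initial_scaling",
    "round_half_away",
    "display_rate",
    "rates_from_half_lives",
]

RATE_DISPLAY_SCALE = 1e3  # tabulated value = rate [min^-1] * 10^3


def round_half_away(x: float, ndigits: int = 0) -> float:
    """Round half away from zero (decimal convention, not banker's).

    Table reproduction compares at the printed number of decimals; numpy's
    and Python's round-half-to-even would misreproduce e.g. 0.985 -> 0.99.
    Operates on the shortest decimal representation of ``x`` so that
    decimal ties behave as they read (0.985 -> 0.99 despite the binary
    float being fractionally below the tie).
    """
    import decimal

    quantum = decimal.Decimal(1).scaleb(-ndigits)
    d = decimal.Decimal(repr(float(x))).quantize(
        quantum, rounding=decimal.ROUND_HALF_UP
    )
    return float(d)


def half_life_to_rate(t_half: float) -> float:
    """First-order rate constant k = ln2 / t_half.

    Parameters
    ----------
    t_half : float
        Half-life in minutes; must be strictly positive.

    Returns
    -------
    float
        Rate constant in min^-1.
    """
    if not t_half > 0:
        raise ValueError(f"half-life must be strictly positive, got {t_half!r}")
    return LN2 / t_half


def rate_to_half_life(k: float) -> float:
    """Inverse of :func:`half_life_to_rate`: t_half = ln2 / k."""
    if not k > 0:
        raise ValueError(f"rate constant must be strictly positive, got {k!r}")
    return LN2 / k


def display_rate(k: float, decimals: int = 2) -> float:
    """Tabulated display value of a rate constant: k * 10^3, rounded."""
    return round_half_away(k * RATE_DISPLAY_SCALE, decimals)


def dissolution_fold(t_complex: float, t_reference: float) -> float:
    """Dissolution-time ratio DR = t_complex / t_reference.

    The fastest-dissolving formulation is the reference; the delivered dose
    D(t) of a slower formulation is scaled by 1/DR (e.g. dissolution times
    of 180 vs 15 min give DR = 12, hence dose D(t)/12).
    """
    if not (t_complex > 0 and t_reference > 0):
        raise ValueError("dissolution times must be strictly positive")
    return t_complex / t_reference


def fold_factor(
    tmax_exp: float, cmax_pre: float, tmax_pre: float, cmax_exp: float
) -> float:
    """Calibration fold aligning simulated and experimental plasma peaks.

    Fold = (Tmax * Cmax_pre) / (Tmax_pre * Cmax), where the ``pre`` values
    are the model's precalculated peak and the others are experimental.
    Raw rate constants divided by this fold reproduce the experimental
    timescale. Invariant under common rescaling of both concentrations or
    of both times.
    """
    if not all(v > 0 for v in (tmax_exp, cmax_pre, tmax_pre, cmax_exp)):
        raise ValueError("fold_factor arguments must all be strictly positive")
    return (tmax_exp * cmax_pre) / (tmax_pre * cmax_exp)


def hydrophobic_initial_scaling(k_gi_drug: float, k_gi_complex: float) -> float:
    """GI absorption-rate ratio k_GI(drug) / k_GI(complex).

    For the slow-dissolving hydrophobic complex the short-range initial GI
    concentration C_A(0) is divided by this ratio (4.38 for the triacetyl
    complex, from the tabulated 23.1/5.28).
    """
    if not (k_gi_drug > 0 and k_gi_complex > 0):
        raise ValueError("rates must be strictly positive")
    return k_gi_drug / k_gi_complex


@dataclass(frozen=True)
class ReportedPeaks:
    """Reference (published) peak values carried alongside a compound.

    These printed, rounded values are inputs to the calibration chain —
    the fold factors and the Tmax-scaled validation concentrations are
    reproducible only from the rounded values, not from full-precision
    intermediates. ``None`` means no reference value is available.
    """

    cmax_pre: Optional[float] = None  # ng/mL, precalculated run
    tmax_pre: Optional[float] = None  # min
    cmax_refined: Optional[float] = None  # ng/mL, refined-rate run
    tmax_refined: Optional[float] = None  # min


@dataclass(frozen=True)
class CompoundParameters:
    """Half-lives, dissolution time and experimental peak data for one substance.

    All durations in minutes, concentrations in ng/mL.
    """

    name: str
    t_half_gi: float
    t_half_plasma: float
    dissolution_time: float
    cmax_exp: float
    cmax_exp_sd: float
    tmax_exp: float
    reported: ReportedPeaks = field(default_factory=ReportedPeaks)

    def __post_init__(self) -> None:
        for attr in (
            "t_half_gi",
            "t_half_plasma",
            "dissolution_time",
            "cmax_exp",
            "cmax_exp_sd",
            "tmax_exp",
        ):
            value = getattr(self, attr)
            if not value > 0:
                raise ValueError(f"{attr} must be strictly positive, got {value!r}")

    def rate_constants(self) -> "RateConstants":
        """Rate constants k = ln2/t_half for the GI and plasma compartments."""
        return rates_from_half_lives(self.t_half_gi, self.t_half_plasma)


@dataclass(frozen=True)
class RateConstants:
    """First-order GI and plasma rate constants in min^-1.

    ``scale_note`` records that tabulated values are rate * 10^3.
    """

    k_gi: float
    k_plasma: float
    scale_note: str = "tabulated display value = rate [min^-1] x 10^3"

    def __post_init__(self) -> None:
        if not (self.k_gi > 0 and self.k_plasma > 0):
            raise ValueError("rate constants must be strictly positive")

    def display(self, decimals_gi: int = 2, decimals_plasma: int = 2) -> tuple[float, float]:
        """(k_gi, k_plasma) on the x10^3 display scale, rounded."""
        return (
            display_rate(self.k_gi, decimals_gi),
            display_rate(self.k_plasma, decimals_plasma),
        )

    @property
    def ratio(self) -> float:
        return self.k_gi / self.k_plasma


def rates_from_half_lives(t_half_gi: float, t_half_plasma: float) -> RateConstants:
    return RateConstants(
        k_gi=half_life_to_rate(t_half_gi),
        k_plasma=half_life_to_rate(t_half_plasma),
    )


@dataclass(frozen=True)
class FoldRefinement:
    """A calibration fold together with the precalculated peak it came from."""

    fold: float
    cmax_pre: float
    tmax_pre: float

    def __post_init__(self) -> None:
        if not self.fold > 0:
            raise ValueError("fold must be strictly positive")


def refine_rates(raw: RateConstants, fold: float) -> RateConstants:
    """Divide both rate constants by the calibration fold.

    Preserves the GI/plasma rate ratio exactly.
    """
    if not fold > 0:
        raise ValueError(f"fold must be strictly positive, got {fold!r}")
    return replace(raw, k_gi=raw.k_gi / fold, k_plasma=raw.k_plasma / fold)
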