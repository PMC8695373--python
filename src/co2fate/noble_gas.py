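"""Noble-gas tracer arithmetic: helium air correction, mantle/crust unmixing
and CO2/3He-based CO2-removal accounting.

3He is inert, insoluble and has no significant crustal source, so once the
injected gas is emplaced the CO2/3He ratio changes only when CO2 itself is
added or removed.  The helium isotope ratio (R/R_A, sample 3He/4He relative to
air) first has its atmospheric component removed using 4He/20Ne, then the
corrected ratio Rc/R_A is unmixed between a mantle and a crustal endmember.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm

from .errors import AirDominatedError, ValidationError
from .samples import EndmemberSet


@dataclass
class HeliumPartition:
    """Air-corrected helium ratio and its mantle/crust decomposition."""

    rc_over_ra: float
    mantle_fraction: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.mantle_fraction <= 1.0:
            raise ValidationError(f"invariant violated: mantle_fraction in [0,1] (got {self.mantle_fraction})")


def air_correct_helium(
    r_over_ra: float,
    he4_ne20_sample: float,
    he4_ne20_air: float = 0.318,
) -> float:
    """Remove atmospheric helium from a measured 3He/4He ratio.

    Assumes all 20Ne is atmospheric, so the air-derived share of the 4He
    budget is (4He/20Ne)_air / (4He/20Ne)_sample.  With
    X = (4He/20Ne)_sample / (4He/20Ne)_air the corrected ratio is

        Rc/R_A = (R/R_A * X - 1) / (X - 1)

    which is the two-component subtraction of air 3He and 4He from the
    measured budgets.  The correction vanishes as X -> infinity.

    Raises
    ------
    AirDominatedError
        if X <= 1, i.e. the sample contains no resolvable non-atmospheric He.
    """
    if he4_ne20_sample <= 0 or he4_ne20_air <= 0:
        raise ValidationError("4He/20Ne ratios must be positive")
    x = he4_ne20_sample / he4_ne20_air
    if x <= 1.0:
        raise AirDominatedError(
            f"air-dominated sample: 4He/20Ne = {he4_ne20_sample} is not above the atmospheric value {he4_ne20_air}"
        )
    return (r_over_ra * x - 1.0) / (x - 1.0)


def mantle_helium_fraction(
    rc_over_ra: float,
    endmembers: EndmemberSet | None = None,
    clamp: bool = True,
) -> float:
    """Mantle share of total helium from two-endmember mixing, linear in Rc.

    f = (Rc - R_crust) / (R_mantle - R_crust); exactly 0 at the crustal
    endmember and 1 at the mantle endmember.  Values of Rc outside the
    endmember interval are clamped with a warning (``clamp=True``) or raise.
    """
    em = endmembers or EndmemberSet()
    denom = em.r_mantle_ra - em.r_crust_ra
    if denom == 0:
        raise ValidationError("degenerate endmembers: r_mantle_ra == r_crust_ra")
    f = (rc_over_ra - em.r_crust_ra) / denom
    if not 0.0 <= f <= 1.0:
        if not clamp:
            raise ValidationError(f"Rc/R_A = {rc_over_ra} outside endmember interval")
        warnings.warn(
            f"Rc/R_A = {rc_over_ra} outside endmember interval "
            f"[{em.r_crust_ra}, {em.r_mantle_ra}]; clamping mantle fraction",
            stacklevel=2,
        )
        f = min(max(f, 0.0), 1.0)
    return f


def mantle_he3_fraction(
    rc_over_ra: float,
    endmembers: EndmemberSet | None = None,
) -> float:
    """Mantle share of the 3He budget (secondary, non-default convention).

    If a fraction ``x`` of total He (4He-weighted) is mantle derived, the
    mantle share of 3He is x * R_mantle / Rc.  Provided as a clearly named
    alternative to the default total-He-weighted :func:`mantle_helium_fraction`.
    """
    em = endmembers or EndmemberSet()
    x = mantle_helium_fraction(rc_over_ra, em)
    if rc_over_ra <= 0:
        raise ValidationError("rc_over_ra must be positive")
    return x * em.r_mantle_ra / rc_over_ra


def co2_removal_fraction(co2_he3_sample: float, co2_he3_reference: float) -> float:
    """Fraction of CO2 removed since the reference state.

    Because 3He is conservative, f = sample/reference is the remaining-CO2
    fraction and 1 - f the removed fraction.  A negative return value means
    the sample gained CO2 relative to the reference; callers must flag and
    exclude such samples from removal modelling rather than clamping.
    """
    if co2_he3_sample <= 0 or co2_he3_reference <= 0:
        raise ValidationError("CO2/3He ratios must be positive")
    return 1.0 - co2_he3_sample / co2_he3_reference


def extrapolate_initial_co2_he3(
    co2_fractions: np.ndarray,
    co2_he3: np.ndarray,
) -> tuple[float, float]:
    """Estimate the pre-removal CO2/3He endmember of a natural field.

    Ordinary least squares of CO2/3He against CO2 mole fraction, evaluated at
    mole fraction 1.0 (a hypothetical pure-CO2, zero-removal gas).  Returns
    the endmember estimate and the standard error of the fitted mean at that
    point.
    """
    x = np.asarray(co2_fractions, dtype=float)
    y = np.asarray(co2_he3, dtype=float)
    if x.size < 3:
        raise ValidationError(f"need >= 3 points for extrapolation, got {x.size}")
    if np.any((x <= 0) | (x > 1)):
        raise ValidationError("co2_fractions must lie in (0, 1]")
    if np.ptp(x) == 0:
        raise ValidationError("zero variance in CO2 fractions; cannot extrapolate")
    res = sm.OLS(y, sm.add_constant(x)).fit()
    pred = res.get_prediction(np.array([[1.0, 1.0]]))
    return float(pred.predicted_mean[0]), float(pred.se_mean[0])
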