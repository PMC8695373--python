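"""Carbon-isotope fractionation models for CO2 removal and their inversion.

Three forward models describe how the delta13C of a residual CO2 pool evolves
as a fraction (1 - f) of it is removed:

* open-system Rayleigh fractionation (dissolution into formation water that is
  then swept away, or carbonate precipitation), with constant factor alpha:
  the residual follows (1000 + delta) = (1000 + delta_i) * f**(alpha - 1);

* closed-system equilibrium exchange (net microbial methanogenesis--AOM
  cycling, where product CH4 stays in isotopic contact with the CO2):
  delta = delta_i - (alpha_m - 1) * (1 - f) * 1000, linear in the converted
  fraction;

* the hybrid of both, where a share F_d of the removed CO2 was dissolved and
  (1 - F_d) microbially converted.  The two pathways blend through the
  apparent fractionation factor

      alpha_A = F_d * alpha_d + (1 - F_d) * alpha_m

  and the residual CO2 follows

      delta = delta_i * f**(alpha_A - 1) - (alpha_A - 1) * (1 - f) * 1000.

The hybrid expression is evaluated on the delta scale (delta multiplied
directly by f**(alpha_A - 1)), with alpha_A in both terms.  On this scale the
pure-methanogenesis limit (F_d = 0) is recovered exactly at delta_i = 0 and to
within |f**(alpha_m - 1) - 1| * |delta_i| (hundredths of a permil) otherwise;
the pure-dissolution limit differs from the standalone (1000 + delta)-scale
Rayleigh curve only by the scale-convention term
1000 * (alpha_d - 1) * (ln f + 1 - f), below ~5 permil even at f ~ 0.1.  A
sequential partitioned variant (Rayleigh step for the dissolved share followed
by a closed-system step for the converted share) is available as a robustness
check via ``mode="sequential"``.

Because delta is strictly decreasing in F_d at fixed f < 1 (more dissolution
means less 13C enrichment of the residue), the observed delta13C of CO2 at a
known remaining fraction f inverts to a unique dissolution share F_d.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.optimize import brentq

from .errors import EnvelopeError, InconsistentInputError, ValidationError
from .noble_gas import co2_removal_fraction
from .samples import AnalysisConfig, FractionationFactors, GasSample

__all__ = [
    "HybridFitResult",
    "rayleigh_residual_delta",
    "closed_system_residual_delta",
    "apparent_alpha",
    "hybrid_residual_delta",
    "invert_dissolution_share",
    "consumption_partition",
    "fit_field_model",
    "crossover_dissolution_share",
]


@dataclass
class HybridFitResult:
    """Per-sample removal fraction and dissolution/methanogenesis partition.

    ``f`` is the remaining-CO2 fraction, ``f_d`` the dissolution share F_d of
    the removed CO2, ``meth_fraction`` = (1-f)(1-F_d) and ``diss_fraction`` =
    (1-f)F_d the shares of the *original* CO2 consumed by methanogenesis and
    removed by dissolution.  ``m_to_d`` is the methanogenesis:dissolution
    removal ratio (1-F_d)/F_d.
    """

    sample_id: str
    f: float
    f_d: float
    alpha_a: float
    meth_fraction: float = field(init=False)
    diss_fraction: float = field(init=False)
    m_to_d: float = field(init=False)

    def __post_init__(self) -> None:
        if not 0.0 < self.f <= 1.0:
            raise ValidationError(f"invariant violated: f in (0,1] (got {self.f})")
        if not 0.0 <= self.f_d <= 1.0:
            raise ValidationError(f"invariant violated: f_d in [0,1] (got {self.f_d})")
        self.meth_fraction, self.diss_fraction = consumption_partition(self.f, self.f_d)
        self.m_to_d = (1.0 - self.f_d) / self.f_d if self.f_d > 0 else math.inf


def rayleigh_residual_delta(delta_i: float, f, alpha: float):
    """Residual-CO2 delta13C after open-system Rayleigh removal.

    Computed on the (1000 + delta) scale:
    (1000 + delta) = (1000 + delta_i) * f**(alpha - 1).  ``f`` may be a scalar
    or array of remaining fractions in (0, 1]; ``alpha`` > 0.
    """
    f_arr = np.asarray(f, dtype=float)
    if np.any(f_arr <= 0) or np.any(f_arr > 1):
        raise ValidationError(f"f must lie in (0, 1] (got {f})")
    if alpha <= 0:
        raise ValidationError(f"alpha must be positive (got {alpha})")
    out = (1000.0 + delta_i) * f_arr ** (alpha - 1.0) - 1000.0
    return float(out) if np.isscalar(f) else out


def closed_system_residual_delta(delta_i: float, f, alpha_m: float):
    """Residual-CO2 delta13C after closed-system equilibrium conversion.

    delta = delta_i - (alpha_m - 1) * (1 - f) * 1000; with alpha_m < 1 the
    residual CO2 is enriched linearly in the converted fraction (1 - f).
    """
    f_arr = np.asarray(f, dtype=float)
    if np.any(f_arr < 0) or np.any(f_arr > 1):
        raise ValidationError(f"f must lie in [0, 1] (got {f})")
    out = delta_i - (alpha_m - 1.0) * (1.0 - f_arr) * 1000.0
    return float(out) if np.isscalar(f) else out


def apparent_alpha(f_d: float, factors: FractionationFactors) -> float:
    """Apparent system fractionation factor alpha_A = F_d a_d + (1-F_d) a_m."""
    if not 0.0 <= f_d <= 1.0:
        raise ValidationError(f"f_d must lie in [0, 1] (got {f_d})")
    return f_d * factors.alpha_d + (1.0 - f_d) * factors.alpha_m


def crossover_dissolution_share(factors: FractionationFactors) -> float:
    """The F_d* where alpha_A = 1 and the hybrid curve changes sign of slope in f."""
    return (1.0 - factors.alpha_m) / (factors.alpha_d - factors.alpha_m)


def hybrid_residual_delta(
    delta_i: float,
    f: float,
    f_d: float,
    factors: FractionationFactors,
    mode: str = "apparent",
) -> float:
    """Residual-CO2 delta13C under combined dissolution and methanogenesis.

    ``mode="apparent"`` (default) evaluates the blended single-pool form
    delta = delta_i * f**(alpha_A - 1) - (alpha_A - 1)(1 - f) * 1000 with
    alpha_A from :func:`apparent_alpha`.  ``mode="sequential"`` is the
    partitioned robustness check: a (1000 + delta)-scale Rayleigh step
    removing the dissolved share (1-f) F_d, then a closed-system step
    converting the methanogenic share (1-f)(1-F_d) of the original pool.
    """
    if not 0.0 < f <= 1.0:
        raise ValidationError(f"f must lie in (0, 1] (got {f})")
    if not 0.0 <= f_d <= 1.0:
        raise ValidationError(f"f_d must lie in [0, 1] (got {f_d})")
    if mode == "apparent":
        a_a = apparent_alpha(f_d, factors)
        return delta_i * f ** (a_a - 1.0) - (a_a - 1.0) * (1.0 - f) * 1000.0
    if mode == "sequential":
        diss = (1.0 - f) * f_d
        meth = (1.0 - f) * (1.0 - f_d)
        f1 = 1.0 - diss
        d1 = rayleigh_residual_delta(delta_i, f1, factors.alpha_d) if diss > 0 else delta_i
        return d1 - (factors.alpha_m - 1.0) * meth * 1000.0
    raise ValueError(f"unknown mode {mode!r}")


def invert_dissolution_share(
    delta_obs: float,
    delta_i: float,
    f: float,
    factors: FractionationFactors,
    mode: str = "apparent",
    xtol: float = 1e-12,
) -> float:
    """Invert the hybrid model for the dissolution share F_d.

    Requires f < 1 and delta_obs inside the envelope bounded by the
    pure-dissolution (F_d = 1, minimum) and pure-methanogenesis (F_d = 0,
    maximum) curves at this f.  The forward model is strictly monotone
    (decreasing) in F_d, so bisection on [0, 1] yields the unique solution.

    Raises
    ------
    InconsistentInputError
        if f = 1 (no removal) but delta_obs != delta_i.
    EnvelopeError
        if delta_obs falls outside the model envelope; carries the signed
        per-mil distance to the nearest bound.
    """
    if f >= 1.0:
        if abs(delta_obs - delta_i) > 1e-9:
            raise InconsistentInputError(
                f"f = 1 (no removal) but delta_obs = {delta_obs} differs from delta_i = {delta_i}"
            )
        return math.nan  # partition undefined when nothing was removed

    hi = hybrid_residual_delta(delta_i, f, 0.0, factors, mode)  # pure methanogenesis
    lo = hybrid_residual_delta(delta_i, f, 1.0, factors, mode)  # pure dissolution
    if hi <= lo:
        raise ValidationError("hybrid model not monotone in F_d for these factors")
    if delta_obs > hi:
        raise EnvelopeError(delta_obs - hi)
    if delta_obs < lo:
        raise EnvelopeError(delta_obs - lo)

    def g(f_d: float) -> float:
        return hybrid_residual_delta(delta_i, f, f_d, factors, mode) - delta_obs

    return float(brentq(g, 0.0, 1.0, xtol=xtol))


def consumption_partition(f: float, f_d: float) -> tuple[float, float]:
    """Split the removed fraction (1 - f) into methanogenic and dissolved shares.

    Returns (meth, diss) = ((1-f)(1-F_d), (1-f)F_d); their sum is exactly 1-f.
    """
    if not 0.0 <= f <= 1.0 or not 0.0 <= f_d <= 1.0:
        raise ValidationError("f and f_d must lie in [0, 1]")
    removed = 1.0 - f
    return removed * (1.0 - f_d), removed * f_d


@dataclass
class FieldFitSummary:
    """Field-level aggregation of per-sample hybrid fits."""

    reference_id: str
    delta_i: float
    n_fitted: int
    mean_f_d: float
    d_to_m: float
    m_to_d: float
    meth_fraction_range: tuple[float, float]
    diss_fraction_range: tuple[float, float]
    removal_range: tuple[float, float]
    flagged: dict[str, str]


def _select_reference(samples: Sequence[GasSample], reference_id: str | None) -> GasSample:
    if reference_id is not None:
        for s in samples:
            if s.sample_id == reference_id:
                return s
        raise ValidationError(f"reference sample {reference_id!r} not found")
    # most pristine = highest CO2/3He; ties broken lexicographically on id
    return min(samples, key=lambda s: (-s.co2_he3, s.sample_id))


def fit_field_model(
    samples: Iterable[GasSample],
    reference_id: str | None = None,
    config: AnalysisConfig | None = None,
) -> tuple[list[HybridFitResult], FieldFitSummary]:
    """Fit the hybrid dissolution/methanogenesis model to a field of samples.

    The most pristine sample (highest CO2/3He, or an explicit ``reference_id``)
    sets the pre-removal state: its delta13C-CO2 is the initial composition
    delta_i and its CO2/3He (or CO2 mol% when ``config.f_source`` is
    ``"co2_molpct"``) the no-removal baseline.  Each remaining sample yields a
    remaining fraction f and, by inversion, a dissolution share F_d.

    Samples with apparent CO2 *gain* (f > 1), missing inputs, or delta13C
    outside the model envelope are excluded and reported in
    ``summary.flagged`` with the reason, never silently clamped.
    """
    cfg = config or AnalysisConfig()
    samples = list(samples)
    if not samples:
        raise ValidationError("no samples supplied")
    ref = _select_reference(samples, reference_id or cfg.reference_sample)
    delta_i = ref.d13c_co2

    results: list[HybridFitResult] = []
    flagged: dict[str, str] = {}
    for s in samples:
        if s.sample_id == ref.sample_id:
            continue
        if cfg.f_source == "co2_molpct":
            if s.co2_molpct <= 0 or ref.co2_molpct <= 0:
                flagged[s.sample_id] = "non-positive CO2 mol% for concentration-based f"
                continue
            f = s.co2_molpct / ref.co2_molpct
        else:
            f = 1.0 - co2_removal_fraction(s.co2_he3, ref.co2_he3)
        if f > 1.0:
            flagged[s.sample_id] = f"negative apparent removal (f = {f:.4f} > 1)"
            continue
        try:
            f_d = invert_dissolution_share(s.d13c_co2, delta_i, f, cfg.factors, cfg.hybrid_mode)
        except EnvelopeError as exc:
            flagged[s.sample_id] = f"outside model envelope ({exc.distance:+.3f} permil)"
            continue
        except InconsistentInputError as exc:
            flagged[s.sample_id] = str(exc)
            continue
        if math.isnan(f_d):
            flagged[s.sample_id] = "no removal relative to reference (f = 1)"
            continue
        results.append(
            HybridFitResult(
                sample_id=s.sample_id,
                f=f,
                f_d=f_d,
                alpha_a=apparent_alpha(f_d, cfg.factors),
            )
        )

    if not results:
        if len(samples) == 1:
            import warnings

            warnings.warn("single-sample field: reference only, nothing to fit", stacklevel=2)
            summary = FieldFitSummary(
                reference_id=ref.sample_id,
                delta_i=delta_i,
                n_fitted=0,
                mean_f_d=math.nan,
                d_to_m=math.nan,
                m_to_d=math.nan,
                meth_fraction_range=(math.nan, math.nan),
                diss_fraction_range=(math.nan, math.nan),
                removal_range=(math.nan, math.nan),
                flagged=flagged,
            )
            return [], summary
        raise ValidationError("no invertible samples: " + "; ".join(f"{k}: {v}" for k, v in flagged.items()))

    mean_f_d = float(np.mean([r.f_d for r in results]))
    meth = [r.meth_fraction for r in results]
    diss = [r.diss_fraction for r in results]
    summary = FieldFitSummary(
        reference_id=ref.sample_id,
        delta_i=delta_i,
        n_fitted=len(results),
        mean_f_d=mean_f_d,
        d_to_m=mean_f_d / (1.0 - mean_f_d) if mean_f_d < 1 else math.inf,
        m_to_d=(1.0 - mean_f_d) / mean_f_d if mean_f_d > 0 else math.inf,
        meth_fraction_range=(min(meth), max(meth)),
        diss_fraction_range=(min(diss), max(diss)),
        removal_range=(min(1 - r.f for r in results), max(1 - r.f for r in results)),
        flagged=flagged,
    )
    return results, summary
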