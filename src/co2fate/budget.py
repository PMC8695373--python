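"""Volume/mole/rate budgets for microbial CH4 production and the
environmental feasibility screen for methanogenesis.

Hydrogenotrophic methanogenesis converts CO2 to CH4 one-to-one
(CO2 + 4 H2 -> CH4 + 2 H2O), so a consumed CO2 volume maps directly onto a
produced CH4 volume at the same reference conditions.  Gas volumes are m3
(STP); moles use a configurable molar volume (default 24.465 L/mol, i.e.
25 degC / 1 atm).  Rates are reported in mmol CH4 per m3 of a normalisation
volume per year.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import ValidationError
from .samples import WaterChemistry

# hard physiological limits; any breach rules methanogenesis out
HARD_LIMITS = {
    "temperature_max_c": 80.0,
    "ph_min": 4.0,
    "ph_max": 9.0,
    "cl_max_mM": 1500.0,
    "so4_max_mM": 1.0,
    "fe_max_mM": 1.0,
}

# ranges of greatest methanogenic activity (reported, not gating)
OPTIMAL_RANGES = {
    "temperature_c": (40.0, 50.0),
    "cl_mM": (200.0, 600.0),
}

# supporting geochemical indicators that methanogenesis has occurred
INDICATOR_THRESHOLDS = {
    "alkalinity_min_meq_kg": 10.0,
    "ca_mg_max": 1.5,
    "d13c_dic_min": 20.0,
}


@dataclass
class BudgetResult:
    """CH4 production budget: volume, moles, and field-normalised rate."""

    ch4_volume_m3_stp: float
    ch4_moles: float
    rate_mmol_per_m3_per_yr: float
    years_elapsed: float
    normalization_volume_m3: float

    def __post_init__(self) -> None:
        for name in ("ch4_volume_m3_stp", "ch4_moles", "rate_mmol_per_m3_per_yr"):
            if getattr(self, name) < 0:
                raise ValidationError(f"invariant violated: {name} >= 0")
        implied = self.ch4_moles * 1000.0 / self.years_elapsed / self.normalization_volume_m3
        if self.rate_mmol_per_m3_per_yr > 0 and abs(implied / self.rate_mmol_per_m3_per_yr - 1.0) > 1e-9:
            raise ValidationError("invariant violated: rate inconsistent with components")


@dataclass
class WindowVerdict:
    """Outcome of the environmental screen for methanogenesis."""

    favourable: bool
    flags: list[str] = field(default_factory=list)
    indicators: list[str] = field(default_factory=list)
    notes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.favourable != (len(self.flags) == 0):
            raise ValidationError("invariant violated: favourable == (no hard-limit breaches)")


def methane_produced(v_co2_retained_m3: float, consumed_fraction: float) -> float:
    """CH4 volume (m3 STP) from a consumed share of the retained CO2 (1:1)."""
    if not 0.0 <= consumed_fraction <= 1.0:
        raise ValidationError(f"consumed_fraction must lie in [0, 1] (got {consumed_fraction})")
    if v_co2_retained_m3 < 0:
        raise ValidationError("retained CO2 volume must be non-negative")
    return v_co2_retained_m3 * consumed_fraction


def methanogenesis_rate(
    v_ch4_m3: float,
    years: float,
    normalization_volume_m3: float,
    molar_volume_l_per_mol: float = 24.465,
) -> BudgetResult:
    """Field-normalised net methanogenesis rate, mmol CH4 m^-3 (STP) yr^-1.

    moles = v_ch4 * 1000 / molar_volume; rate = moles * 1000 (mmol) / years /
    normalisation volume.
    """
    if years <= 0:
        raise ValidationError(f"years must be positive (got {years})")
    if normalization_volume_m3 <= 0:
        raise ValidationError("normalization volume must be positive")
    if molar_volume_l_per_mol <= 0:
        raise ValidationError("molar volume must be positive")
    if v_ch4_m3 < 0:
        raise ValidationError("CH4 volume must be non-negative")
    moles = v_ch4_m3 * 1000.0 / molar_volume_l_per_mol
    rate = moles * 1000.0 / years / normalization_volume_m3
    return BudgetResult(
        ch4_volume_m3_stp=v_ch4_m3,
        ch4_moles=moles,
        rate_mmol_per_m3_per_yr=rate,
        years_elapsed=years,
        normalization_volume_m3=normalization_volume_m3,
    )


def biogenic_gas_fraction(c1cn_obs: float, c1cn_thermogenic: float = 0.909) -> tuple[float, float]:
    """Biogenic gas share from the excess in gas dryness C1/sum(Cn).

    Mixing a purely thermogenic gas (dryness r_t) with pure biogenic CH4
    (dryness 1) gives observed dryness r_obs at a biogenic share of total gas

        b = (r_obs - r_t) / (1 - r_t).

    Returns ``(b, b / r_obs)``: the biogenic fraction of total gas and the
    biogenic fraction of the CH4 specifically.

    Raises
    ------
    ValidationError
        if r_obs < r_t ("thermogenic-only or invalid endmember").
    """
    if not 0.0 < c1cn_thermogenic <= 1.0 or not c1cn_obs <= 1.0:
        raise ValidationError("dryness ratios must lie in (0, 1]")
    if c1cn_obs < c1cn_thermogenic:
        raise ValidationError(
            f"thermogenic-only or invalid endmember: observed C1/Cn {c1cn_obs} below "
            f"thermogenic endmember {c1cn_thermogenic}"
        )
    if c1cn_thermogenic == 1.0:
        raise ValidationError("degenerate thermogenic endmember (dryness 1)")
    b = (c1cn_obs - c1cn_thermogenic) / (1.0 - c1cn_thermogenic)
    return b, b / c1cn_obs


def screen_methanogenesis_window(
    water_chem: WaterChemistry | None,
    temperature_c: float,
    hard_limits: dict | None = None,
) -> WindowVerdict:
    """Screen reservoir conditions against the methanogenesis window.

    Hard limits (any breach -> unfavourable, breach named in ``flags``):
    T <= 80 degC, 4 <= pH <= 9, Cl- <= 1500 mM, SO4(2-) <= 1 mM, Fe <= 1 mM.
    Optimal-range observations (40-50 degC; Cl- 200-600 mM) are reported in
    ``notes`` and supporting indicators of past methanogenesis (alkalinity
    > 10 meq/kg, Ca/Mg < 1.5, d13C-DIC > +20 permil) in ``indicators``;
    missing optional fields are simply not evaluated.
    """
    limits = dict(HARD_LIMITS)
    if hard_limits:
        limits.update(hard_limits)
    if water_chem is None or water_chem.ph is None:
        raise ValidationError("screen requires at least temperature and pH")

    flags: list[str] = []
    notes: list[str] = []
    indicators: list[str] = []

    if temperature_c > limits["temperature_max_c"]:
        flags.append("temperature")
    elif OPTIMAL_RANGES["temperature_c"][0] <= temperature_c <= OPTIMAL_RANGES["temperature_c"][1]:
        notes.append("temperature in optimal 40-50 degC range")

    if not limits["ph_min"] <= water_chem.ph <= limits["ph_max"]:
        flags.append("pH")

    if water_chem.cl_mM is not None:
        if water_chem.cl_mM > limits["cl_max_mM"]:
            flags.append("chloride")
        elif OPTIMAL_RANGES["cl_mM"][0] <= water_chem.cl_mM <= OPTIMAL_RANGES["cl_mM"][1]:
            notes.append("salinity in optimal 200-600 mM Cl- range")
    if water_chem.so4_mM is not None and water_chem.so4_mM > limits["so4_max_mM"]:
        flags.append("sulfate")
    if water_chem.fe_mM is not None and water_chem.fe_mM > limits["fe_max_mM"]:
        flags.append("iron")

    if water_chem.alkalinity_meq_kg is not None and water_chem.alkalinity_meq_kg > INDICATOR_THRESHOLDS["alkalinity_min_meq_kg"]:
        indicators.append("alkalinity > 10 meq/kg")
    if water_chem.ca_mg_ratio is not None and water_chem.ca_mg_ratio < INDICATOR_THRESHOLDS["ca_mg_max"]:
        indicators.append("Ca/Mg < 1.5")
    if water_chem.d13c_dic is not None and water_chem.d13c_dic > INDICATOR_THRESHOLDS["d13c_dic_min"]:
        indicators.append("d13C-DIC > +20 permil")

    return WindowVerdict(favourable=not flags, flags=flags, indicators=indicators, notes=notes)
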