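"""Domain types and table IO for wellhead gas geochemistry.

A :class:`GasSample` is one wellhead gas analysis: bulk composition (CO2 and
CH4 mole per cent, gas dryness C1/sum(Cn)), carbon isotope ratios of CO2, CH4
and propane (permil VPDB), helium systematics (3He/4He relative to air,
4He/20Ne, CO2/3He), the two measurable clumped isotopologues of methane
(cap-delta 13CH3D and 12CH2D2, permil relative to the stochastic
distribution), the reservoir temperature, and optionally the chemistry of the
co-produced formation water.

Delta values are carried in permil VPDB throughout; temperatures are stored in
degrees Celsius on the sample (as reported at the wellhead) and converted to
kelvin where thermodynamic calibrations are evaluated.

CSV dialect: UTF-8, comma-separated, header row required, empty cell = value
missing (never zero -- zero is a valid delta).
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import RowError, SchemaError, ValidationError

ABSOLUTE_ZERO_C = -273.15

#: canonical column order of the sample CSV dialect
MANDATORY_COLUMNS = (
    "sample_id",
    "field_name",
    "co2_molpct",
    "ch4_molpct",
    "d13c_co2",
    "d13c_ch4",
    "r_over_ra",
    "he4_ne20",
    "co2_he3",
    "reservoir_t",
)

OPTIONAL_COLUMNS = (
    "c1_over_cn",
    "d13c_c3h8",
    "r_over_ra_sigma",
    "d13ch3d",
    "d13ch3d_sigma",
    "d12ch2d2",
    "d12ch2d2_sigma",
    "ph",
    "cl_mM",
    "so4_mM",
    "fe_mM",
    "alkalinity_meq_kg",
    "ca_mg_ratio",
    "d13c_dic",
)

WATER_COLUMNS = ("ph", "cl_mM", "so4_mM", "fe_mM", "alkalinity_meq_kg", "ca_mg_ratio", "d13c_dic")


def _check(cond: bool, invariant: str) -> None:
    if not cond:
        raise ValidationError(f"invariant violated: {invariant}")


@dataclass
class WaterChemistry:
    """Formation-water chemistry block; every field optional."""

    ph: float | None = None
    cl_mM: float | None = None
    so4_mM: float | None = None
    fe_mM: float | None = None
    alkalinity_meq_kg: float | None = None
    ca_mg_ratio: float | None = None
    d13c_dic: float | None = None

    def __post_init__(self) -> None:
        for name in ("cl_mM", "so4_mM", "fe_mM", "alkalinity_meq_kg", "ca_mg_ratio"):
            v = getattr(self, name)
            if v is not None:
                _check(v >= 0, f"{name} >= 0 (got {v})")


@dataclass
class GasSample:
    """One wellhead gas analysis."""

    sample_id: str
    field_name: str
    co2_molpct: float
    ch4_molpct: float
    d13c_co2: float
    d13c_ch4: float
    r_over_ra: float
    he4_ne20: float
    co2_he3: float
    reservoir_t: float  # degrees C
    c1_over_cn: float | None = None
    d13c_c3h8: float | None = None
    r_over_ra_sigma: float | None = None
    d13ch3d: float | None = None
    d13ch3d_sigma: float | None = None
    d12ch2d2: float | None = None
    d12ch2d2_sigma: float | None = None
    water_chem: WaterChemistry | None = None

    def __post_init__(self) -> None:
        _check(0.0 <= self.co2_molpct <= 100.0, f"co2_molpct in [0, 100] (got {self.co2_molpct})")
        _check(0.0 <= self.ch4_molpct <= 100.0, f"ch4_molpct in [0, 100] (got {self.ch4_molpct})")
        _check(self.co2_he3 > 0, f"co2_he3 > 0 (got {self.co2_he3})")
        _check(self.he4_ne20 > 0, f"he4_ne20 > 0 (got {self.he4_ne20})")
        _check(self.reservoir_t > ABSOLUTE_ZERO_C, f"reservoir_t > {ABSOLUTE_ZERO_C} C")
        if self.c1_over_cn is not None:
            _check(0.0 < self.c1_over_cn <= 1.0, f"c1_over_cn in (0, 1] (got {self.c1_over_cn})")
        for name in ("r_over_ra_sigma", "d13ch3d_sigma", "d12ch2d2_sigma"):
            v = getattr(self, name)
            if v is not None:
                _check(v >= 0, f"{name} >= 0 (got {v})")

    @property
    def reservoir_t_k(self) -> float:
        return self.reservoir_t - ABSOLUTE_ZERO_C

    def has_clumped(self) -> bool:
        return self.d13ch3d is not None and self.d12ch2d2 is not None


@dataclass
class EndmemberSet:
    """Mantle / crust / air / thermogenic endmember constants.

    Defaults: subcontinental lithospheric mantle 3He/4He = 6.1 R_A, crustal
    radiogenic 0.02 R_A, atmospheric 4He/20Ne = 0.318, mantle CO2/3He
    2 +/- 1 x 1e9, mantle d13C-CO2 between -5 and -2 permil, purely
    thermogenic gas dryness C1/sum(Cn) = 0.909.
    """

    r_mantle_ra: float = 6.1
    r_crust_ra: float = 0.02
    he4_ne20_air: float = 0.318
    co2_he3_mantle: float = 2e9
    co2_he3_mantle_sigma: float = 1e9
    d13c_mantle_range: tuple[float, float] = (-5.0, -2.0)
    c1cn_thermogenic: float = 0.909

    def __post_init__(self) -> None:
        _check(self.r_mantle_ra > self.r_crust_ra > 0, "r_mantle_ra > r_crust_ra > 0")
        _check(0 < self.c1cn_thermogenic < 1, "0 < c1cn_thermogenic < 1")
        _check(self.he4_ne20_air > 0, "he4_ne20_air > 0")


@dataclass
class FractionationFactors:
    """Carbon isotope fractionation factors for the CO2-removal pathways.

    alpha_d  -- CO2 dissolution into formation water (pH dependent),
    alpha_p  -- carbonate precipitation at reservoir temperature,
    alpha_m  -- net methanogenesis--AOM cycling (thermal equilibration at
                reservoir temperature; < 1 because the residual CO2 is
                enriched in 13C as CH4 is produced).
    """

    alpha_d: float = 1.0038
    alpha_d_sigma: float = 0.0012
    alpha_p: float = 1.0086
    alpha_p_sigma: float = 0.0012
    alpha_m: float = 0.9363
    alpha_m_sigma: float = 0.003

    def __post_init__(self) -> None:
        _check(self.alpha_d > 0 and self.alpha_p > 0 and self.alpha_m > 0, "all alpha > 0")
        _check(
            self.alpha_m < 1.0 < self.alpha_d <= self.alpha_p,
            "alpha_m < 1 < alpha_d <= alpha_p",
        )
        for name in ("alpha_d_sigma", "alpha_p_sigma", "alpha_m_sigma"):
            _check(getattr(self, name) >= 0, f"{name} >= 0")


@dataclass
class CalibrationCoefficients:
    """Polynomial isotope-equilibrium calibrations.

    Every curve is a polynomial in x = 1000 / T[K], coefficients in ascending
    powers of x.  ``co2_ch4_coeffs`` gives 1000 ln alpha(CO2-CH4) in permil;
    the clumped coefficient vectors give the equilibrium cap-delta values of
    13CH3D and 12CH2D2 in permil.  All three curves must be strictly
    decreasing in T over ``valid_t_range`` (checked at 1 K steps).
    """

    co2_ch4_coeffs: tuple[float, ...]
    d13ch3d_coeffs: tuple[float, ...]
    d12ch2d2_coeffs: tuple[float, ...]
    valid_t_range: tuple[float, float] = (270.0, 700.0)

    def __post_init__(self) -> None:
        self.co2_ch4_coeffs = tuple(float(c) for c in self.co2_ch4_coeffs)
        self.d13ch3d_coeffs = tuple(float(c) for c in self.d13ch3d_coeffs)
        self.d12ch2d2_coeffs = tuple(float(c) for c in self.d12ch2d2_coeffs)
        self.valid_t_range = tuple(float(t) for t in self.valid_t_range)
        tmin, tmax = self.valid_t_range
        _check(tmax > tmin > 0, "valid_t_range must satisfy 0 < T_min < T_max")
        t = np.arange(tmin, tmax + 1.0, 1.0)
        for name, coeffs in (
            ("co2_ch4", self.co2_ch4_coeffs),
            ("d13ch3d", self.d13ch3d_coeffs),
            ("d12ch2d2", self.d12ch2d2_coeffs),
        ):
            vals = np.polynomial.polynomial.polyval(1000.0 / t, coeffs)
            if not np.all(np.diff(vals) < 0) and any(c != 0 for c in coeffs):
                raise ValidationError(
                    f"invariant violated: {name} calibration not strictly decreasing in T "
                    f"over {self.valid_t_range}"
                )

    def coeffs_for(self, thermometer: str) -> tuple[float, ...]:
        try:
            return {
                "co2_ch4": self.co2_ch4_coeffs,
                "d13ch3d": self.d13ch3d_coeffs,
                "d12ch2d2": self.d12ch2d2_coeffs,
            }[thermometer]
        except KeyError:
            raise ValueError(f"unknown thermometer {thermometer!r}") from None


@dataclass
class BudgetInputs:
    """Field-scale volumes and elapsed time for the CH4 production budget."""

    retained_co2_volume_m3: float
    normalization_volume_m3: float
    years_elapsed: float

    def __post_init__(self) -> None:
        _check(self.retained_co2_volume_m3 > 0, "retained_co2_volume_m3 > 0")
        _check(self.normalization_volume_m3 > 0, "normalization_volume_m3 > 0")
        _check(self.years_elapsed > 0, "years_elapsed > 0")


@dataclass
class AnalysisConfig:
    """Everything the analysis pipeline needs besides the sample table."""

    endmembers: EndmemberSet = field(default_factory=EndmemberSet)
    factors: FractionationFactors = field(default_factory=FractionationFactors)
    calibrations: CalibrationCoefficients | None = None
    molar_volume_l_per_mol: float = 24.465
    mc_draws: int = 100_000
    rng_seed: int = 0
    reference_sample: str | None = None
    hybrid_mode: str = "apparent"  # or "sequential"
    f_source: str = "co2_he3"  # or "co2_molpct"
    budget: BudgetInputs | None = None

    def __post_init__(self) -> None:
        _check(self.molar_volume_l_per_mol > 0, "molar_volume > 0")
        _check(self.mc_draws >= 1000, "mc_draws >= 1000")
        if self.calibrations is None:
            from .thermometry import load_default_calibrations

            self.calibrations = load_default_calibrations()
        if self.hybrid_mode not in ("apparent", "sequential"):
            raise ValidationError(f"hybrid_mode must be 'apparent' or 'sequential', got {self.hybrid_mode!r}")
        if self.f_source not in ("co2_he3", "co2_molpct"):
            raise ValidationError(f"f_source must be 'co2_he3' or 'co2_molpct', got {self.f_source!r}")

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "AnalysisConfig":
        d = dict(d)
        if "endmembers" in d and isinstance(d["endmembers"], Mapping):
            em = dict(d["endmembers"])
            if "d13c_mantle_range" in em:
                em["d13c_mantle_range"] = tuple(em["d13c_mantle_range"])
            d["endmembers"] = EndmemberSet(**em)
        if "factors" in d and isinstance(d["factors"], Mapping):
            d["factors"] = FractionationFactors(**d["factors"])
        if "calibrations" in d and isinstance(d["calibrations"], Mapping):
            cal = dict(d["calibrations"])
            cal["valid_t_range"] = tuple(cal.get("valid_t_range", (270.0, 700.0)))
            d["calibrations"] = CalibrationCoefficients(**cal)
        if "budget" in d and isinstance(d["budget"], Mapping):
            d["budget"] = BudgetInputs(**d["budget"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        with open(path, "r", encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)


# ---------------------------------------------------------------------------
# table IO


def read_samples(
    path: str | Path,
    schema: Mapping[str, str] | None = None,
) -> list[GasSample]:
    """Read a sample CSV into validated :class:`GasSample` objects.

    Parameters
    ----------
    path
        CSV file with a header row.
    schema
        Optional map from canonical field names (keys) to the actual column
        names in the file.  Columns not mentioned keep their canonical name.

    Raises
    ------
    SchemaError
        if a mandatory column is absent (names the column).
    RowError
        if a cell cannot be parsed as a number (names the row).
    ValidationError
        if a row violates a GasSample invariant.
    """
    df = pd.read_csv(path, dtype=str, skipinitialspace=True)
    colmap = {name: name for name in MANDATORY_COLUMNS + OPTIONAL_COLUMNS}
    if schema:
        colmap.update(schema)

    for canonical in MANDATORY_COLUMNS:
        if colmap[canonical] not in df.columns:
            raise SchemaError(f"missing mandatory column {colmap[canonical]!r} (field {canonical})")

    samples: list[GasSample] = []
    numeric_fields = [f for f in MANDATORY_COLUMNS + OPTIONAL_COLUMNS if f not in ("sample_id", "field_name")]
    for i, row in df.iterrows():
        values: dict[str, Any] = {
            "sample_id": str(row[colmap["sample_id"]]),
            "field_name": str(row[colmap["field_name"]]),
        }
        for canonical in numeric_fields:
            col = colmap[canonical]
            if col not in df.columns:
                values[canonical] = None
                continue
            raw = row[col]
            if raw is None or (isinstance(raw, float) and math.isnan(raw)) or str(raw).strip() == "":
                values[canonical] = None
                continue
            try:
                values[canonical] = float(raw)
            except (TypeError, ValueError):
                raise RowError(int(i), f"non-numeric value {raw!r} in column {col!r}") from None
        for canonical in MANDATORY_COLUMNS[2:]:
            if values.get(canonical) is None:
                raise RowError(int(i), f"missing value for mandatory column {colmap[canonical]!r}")
        water_vals = {k: values.pop(k) for k in WATER_COLUMNS}
        water = WaterChemistry(**water_vals) if any(v is not None for v in water_vals.values()) else None
        samples.append(GasSample(water_chem=water, **values))
    return samples


def samples_to_dataframe(samples: Iterable[GasSample]) -> pd.DataFrame:
    """Flatten samples back into the canonical CSV column layout."""
    rows = []
    for s in samples:
        d = dataclasses.asdict(s)
        water = d.pop("water_chem") or {}
        d.update({k: water.get(k) for k in WATER_COLUMNS})
        rows.append(d)
    return pd.DataFrame(rows, columns=list(MANDATORY_COLUMNS) + list(OPTIONAL_COLUMNS))


def write_samples(samples: Sequence[GasSample], path: str | Path) -> None:
    # %.17g guarantees binary-exact float round trips through the CSV
    samples_to_dataframe(samples).to_csv(path, index=False, float_format="%.17g")


def write_report(
    report: Mapping[str, Any],
    per_sample: pd.DataFrame,
    outdir: str | Path,
) -> tuple[Path, Path]:
    """Write the machine-readable report (JSON) and per-sample table (CSV).

    ``report`` must be non-empty and must carry a config echo under the
    ``"config"`` key (seeds, alpha values, ...) so a rerun can be reproduced.
    Numbers are serialised at full precision: re-reading either file
    reproduces every value bit-for-bit.
    """
    if not report:
        raise ValidationError("invariant violated: results non-empty")
    if "config" not in report:
        raise ValidationError("report must echo the analysis config under 'config'")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    json_path = outdir / "report.json"
    csv_path = outdir / "per_sample.csv"
    with open(json_path, "w", encoding="utf-8") as fh:
        json.dump(_jsonable(report), fh, indent=2, allow_nan=True)
        fh.write("\n")
    per_sample.to_csv(csv_path, index=False, float_format="%.17g")
    return json_path, csv_path


def read_report(outdir: str | Path) -> tuple[dict[str, Any], pd.DataFrame]:
    outdir = Path(outdir)
    with open(outdir / "report.json", "r", encoding="utf-8") as fh:
        report = json.load(fh)
    per_sample = pd.read_csv(outdir / "per_sample.csv", float_precision="round_trip")
    return report, per_sample


def _jsonable(obj: Any) -> Any:
    if isinstance(obj, Mapping):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(dataclasses.asdict(obj))
    return obj
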