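"""End-to-end orchestration: read samples, run every analysis stage, write
reports with a run manifest.

Stage order follows the inference chain: air-correct helium -> mantle
fractions -> select the pristine reference -> CO2-removal fractions -> hybrid
dissolution/methanogenesis fit -> thermometry -> CH4 budget -> environmental
screen.  The orchestrator contains no inline arithmetic: every reported number
comes from an operation in the library modules.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict
from datetime import datetime, timezone
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from . import __version__
from .budget import methane_produced, methanogenesis_rate, screen_methanogenesis_window
from .errors import CalibrationRangeError, CO2FateError, PoorlyConstrainedError, ValidationError
from .model import CO2PartitionModel
from .noble_gas import air_correct_helium, mantle_helium_fraction
from .samples import AnalysisConfig, GasSample, read_samples, write_report, write_samples
from .synthetic import SyntheticFieldParams, generate_control_field, generate_field
from .thermometry import (
    apparent_temperature,
    calibration_checksum,
    carbon_exchange_delta,
    disequilibrium_vector,
    invert_carbon_equilibrium_t,
)

log = logging.getLogger("co2fate")

# field-level methanogenic consumption below this is reported as no significant removal
NEGLIGIBLE_METH_FRACTION = 0.05


def _sha256_file(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def build_manifest(config: AnalysisConfig, input_paths: list[Path]) -> dict[str, Any]:
    """Run manifest: config snapshot, input checksums, version, seed, timestamps."""
    snapshot = config.to_dict()
    checksums = {str(p): _sha256_file(Path(p)) for p in input_paths}
    manifest_id = hashlib.sha256(
        json.dumps({"config": snapshot, "inputs": checksums, "version": __version__},
                   sort_keys=True, default=str).encode()
    ).hexdigest()[:16]
    return {
        "manifest_id": manifest_id,
        "config": snapshot,
        "input_checksums": checksums,
        "package_version": __version__,
        "seed": config.rng_seed,
        "calibration_checksum": calibration_checksum(config.calibrations),
        "created_utc": datetime.now(timezone.utc).isoformat(),
    }


def _sample_metrics(s: GasSample, cfg: AnalysisConfig, thermo_seed: int) -> dict[str, Any]:
    """Per-sample noble-gas and thermometry metrics (independent of the fit)."""
    row: dict[str, Any] = {"sample_id": s.sample_id, "field_name": s.field_name}
    try:
        rc = air_correct_helium(s.r_over_ra, s.he4_ne20, cfg.endmembers.he4_ne20_air)
        row["rc_over_ra"] = rc
        row["mantle_he_fraction"] = mantle_helium_fraction(rc, cfg.endmembers)
    except CO2FateError as exc:
        log.warning("helium correction failed for %s: %s", s.sample_id, exc)
        row["rc_over_ra"] = np.nan
        row["mantle_he_fraction"] = np.nan

    row["co2_ch4_sep_ln"] = carbon_exchange_delta(s.d13c_co2, s.d13c_ch4, "ln")
    row["co2_ch4_sep_diff"] = carbon_exchange_delta(s.d13c_co2, s.d13c_ch4, "difference")
    try:
        row["t_co2_ch4_c"] = invert_carbon_equilibrium_t(s.d13c_co2, s.d13c_ch4, cfg.calibrations).t_central
    except CalibrationRangeError:
        row["t_co2_ch4_c"] = np.nan

    for therm, value, sigma in (
        ("d13ch3d", s.d13ch3d, s.d13ch3d_sigma),
        ("d12ch2d2", s.d12ch2d2, s.d12ch2d2_sigma),
    ):
        if value is None:
            row[f"t_{therm}_c"] = np.nan
            row[f"t_{therm}_ci_low"] = np.nan
            row[f"t_{therm}_ci_high"] = np.nan
            continue
        try:
            at = apparent_temperature(
                value, sigma or 0.0, therm, cfg.calibrations,
                mc_draws=cfg.mc_draws, seed=thermo_seed,
            )
            row[f"t_{therm}_c"] = at.t_central
            row[f"t_{therm}_ci_low"] = at.ci_low
            row[f"t_{therm}_ci_high"] = at.ci_high
        except (CalibrationRangeError, PoorlyConstrainedError) as exc:
            log.warning("%s thermometry failed for %s: %s", therm, s.sample_id, exc)
            row[f"t_{therm}_c"] = np.nan
            row[f"t_{therm}_ci_low"] = np.nan
            row[f"t_{therm}_ci_high"] = np.nan

    dv = disequilibrium_vector(s, cfg.calibrations)
    if dv is not None:
        (off13, off12), label = dv
        row["d13ch3d_offset"] = off13
        row["d12ch2d2_offset"] = off12
        row["disequilibrium_label"] = label
    else:
        row["d13ch3d_offset"] = np.nan
        row["d12ch2d2_offset"] = np.nan
        row["disequilibrium_label"] = "not computable"

    if s.water_chem is not None and s.water_chem.ph is not None:
        verdict = screen_methanogenesis_window(s.water_chem, s.reservoir_t)
        row["window_favourable"] = verdict.favourable
        row["window_flags"] = ";".join(verdict.flags)
        row["window_indicators"] = ";".join(verdict.indicators)
    else:
        row["window_favourable"] = None
        row["window_flags"] = ""
        row["window_indicators"] = ""
    return row


def run_analysis(
    samples_path: str | Path,
    config: AnalysisConfig | str | Path | None = None,
    output_dir: str | Path | None = None,
) -> tuple[dict[str, Any], dict[str, Any], pd.DataFrame]:
    """Run the full analysis; returns (report, manifest, per-sample table).

    When ``output_dir`` is given, writes report.json + per_sample.csv (via
    :func:`co2fate.samples.write_report`) and manifest.json.  The report is
    deterministic under a fixed config: reruns are byte-identical (timestamps
    live only in the manifest, which the report references by id).
    """
    samples_path = Path(samples_path)
    if config is None:
        cfg = AnalysisConfig()
    elif isinstance(config, AnalysisConfig):
        cfg = config
    else:
        cfg = AnalysisConfig.from_yaml(config)

    samples = read_samples(samples_path)
    log.info("read %d samples from %s", len(samples), samples_path)
    manifest = build_manifest(cfg, [samples_path])

    metric_rows = [_sample_metrics(s, cfg, thermo_seed=cfg.rng_seed) for s in samples]
    metrics = pd.DataFrame(metric_rows)

    report: dict[str, Any] = {
        "manifest_id": manifest["manifest_id"],
        "config": manifest["config"],
        "fields": {},
    }
    per_field_frames = [metrics]
    for field_name, group in _groupby_field(samples).items():
        if len(group) < 2:
            log.warning("field %s has %d sample(s); skipping removal fit", field_name, len(group))
            report["fields"][field_name] = {"fit": None, "note": "fewer than 2 samples"}
            continue
        try:
            res = CO2PartitionModel(group, cfg).fit()
        except ValidationError as exc:
            log.warning("field %s: fit failed (%s)", field_name, exc)
            report["fields"][field_name] = {"fit": None, "note": str(exc)}
            continue
        entry: dict[str, Any] = {"fit": res.to_dict()}
        meth_lo, meth_hi = res.field_summary.meth_fraction_range
        entry["no_significant_removal"] = bool(meth_hi < NEGLIGIBLE_METH_FRACTION)
        if cfg.budget is not None:
            b = cfg.budget
            budgets = {}
            for tag, frac in (("min", meth_lo), ("max", meth_hi)):
                v = methane_produced(b.retained_co2_volume_m3, frac)
                r = methanogenesis_rate(
                    v, b.years_elapsed, b.normalization_volume_m3, cfg.molar_volume_l_per_mol
                )
                budgets[tag] = asdict(r)
            entry["budget"] = budgets
        report["fields"][field_name] = entry
        per_field_frames.append(res.per_sample.set_index("sample_id"))

    per_sample = metrics.set_index("sample_id")
    if len(per_field_frames) > 1:
        fits = pd.concat(per_field_frames[1:])
        per_sample = per_sample.join(fits, how="left")
    per_sample = per_sample.reset_index()

    if output_dir is not None:
        output_dir = Path(output_dir)
        write_report(report, per_sample, output_dir)
        with open(output_dir / "manifest.json", "w", encoding="utf-8") as fh:
            json.dump(manifest, fh, indent=2)
            fh.write("\n")
        log.info("wrote report to %s", output_dir)
    return report, manifest, per_sample


def run_synthesize(
    params: SyntheticFieldParams | str | Path,
    output_dir: str | Path,
    include_control: bool = True,
) -> tuple[Path, Path]:
    """Generate a synthetic dataset and write samples.csv + ground_truth.json."""
    if not isinstance(params, SyntheticFieldParams):
        import yaml

        with open(params, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
        for key in ("f_range", "reservoir_t_range", "mantle_fraction_range",
                    "he4_ne20_range", "control_mantle_fraction_range", "control_t_range_c"):
            if key in raw:
                raw[key] = tuple(raw[key])
        params = SyntheticFieldParams(**raw)
    output_dir = Path(output_dir)
    output_dir.mkdir(parents=True, exist_ok=True)
    samples, truth = generate_field(params)
    if include_control:
        samples = samples + generate_control_field(params)
    csv_path = output_dir / "samples.csv"
    truth_path = output_dir / "ground_truth.json"
    write_samples(samples, csv_path)
    with open(truth_path, "w", encoding="utf-8") as fh:
        json.dump(truth, fh, indent=2)
        fh.write("\n")
    return csv_path, truth_path


def _groupby_field(samples: list[GasSample]) -> dict[str, list[GasSample]]:
    groups: dict[str, list[GasSample]] = {}
    for s in samples:
        groups.setdefault(s.field_name, []).append(s)
    return groups
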