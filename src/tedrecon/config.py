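"""YAML configuration for ventilation, dose coefficients, and correction factors."""

from __future__ import annotations

import datetime as dt
from importlib import resources

import yaml

from .dosimetry import (
    CorrectionFactorModel,
    DoseCoefficientSet,
    SFWindow,
    VentilationTable,
)


class ConfigError(ValueError):
    pass


def _require(mapping: dict, key: str, where: str):
    if key not in mapping:
        raise ConfigError(f"{where}: missing required key {key!r}")
    return mapping[key]


def parse_dosimetry_config(cfg: dict) -> tuple[VentilationTable, DoseCoefficientSet, CorrectionFactorModel]:
    vent = VentilationTable(
        {age: float(v) for age, v in _require(cfg, "ventilation_m3_per_day", "config").items()}
    )
    coeff_cfg = _require(cfg, "dose_coefficients_sv_per_bq", "config")
    inhal_cfg = _require(coeff_cfg, "inhalation", "dose_coefficients_sv_per_bq")
    ing_cfg = _require(coeff_cfg, "ingestion", "dose_coefficients_sv_per_bq")
    inhalation = {
        (age, form): float(e)
        for age, forms in inhal_cfg.items()
        for form, e in forms.items()
    }
    coeffs = DoseCoefficientSet(inhalation, {age: float(e) for age, e in ing_cfg.items()})
    cf_cfg = cfg.get("correction_factors", {})
    windows = tuple(
        SFWindow(_parse_date(w["start"]), _parse_date(w["end"]), float(w["multiplier"]))
        for w in cf_cfg.get(
            "sf_windows",
            [
                {"start": "2011-03-12", "end": "2011-03-13", "multiplier": 1.59},
                {"start": "2011-03-15", "end": "2011-03-16", "multiplier": 1.08},
            ],
        )
    )
    cf = CorrectionFactorModel(
        fc_central=float(cf_cfg.get("fc_central", 0.62)),
        fc_sd=float(cf_cfg.get("fc_sd", 0.20)),
        df_shelter_central=float(cf_cfg.get("df_shelter_central", 0.5)),
        df_triangular=tuple(cf_cfg.get("df_triangular", (0.1, 0.5, 0.95))),
        sf_central=float(cf_cfg.get("sf_central", 0.7)),
        sf_binomial=tuple(cf_cfg.get("sf_binomial", (100, 0.3))),
        sf_windows=windows,
    )
    return vent, coeffs, cf


def _parse_date(value) -> dt.date:
    if isinstance(value, dt.date):
        return value
    return dt.date.fromisoformat(str(value))


def load_dosimetry_config(path) -> tuple[VentilationTable, DoseCoefficientSet, CorrectionFactorModel]:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    return parse_dosimetry_config(cfg)


def load_reference_config() -> tuple[VentilationTable, DoseCoefficientSet, CorrectionFactorModel]:
    """The shipped reference configuration (ICRP-style coefficients)."""
    text = resources.files("tedrecon.data").joinpath("reference_config.yaml").read_text()
    return parse_dosimetry_config(yaml.safe_load(text))
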