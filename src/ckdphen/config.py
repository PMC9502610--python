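"""Configuration: clinical thresholds, CKD-EPI coefficients and code sets.

A single YAML document drives every tunable in the toolkit.  A versioned
default ships with the package (``ckdphen/data/default_config.yaml``);
``load_config(path)`` merges a user document over it, so deployments only
state what they change.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Any, Mapping, Optional, Union

import yaml

from .model import CodeSetLibrary, normalise_code


@dataclass(frozen=True)
class Thresholds:
    g_stage_boundaries: tuple[float, ...] = (90.0, 60.0, 45.0, 30.0, 15.0)
    a_stage_boundaries: tuple[float, float] = (3.0, 30.0)
    egfr_chronic_threshold: float = 60.0
    chronicity_min_span_days: int = 90
    require_latest_low_egfr: bool = True
    uacr_elevated: float = 3.0
    uacr_min_count: int = 2
    uacr_min_span_days: int = 0
    uacr_stringent_span_days: int = 90
    hba1c_elevated: float = 48.0
    hba1c_min_count: int = 2
    bp_systolic_elevated: float = 140.0
    bp_diastolic_elevated: float = 90.0
    bp_min_count: int = 2
    dialysis_maintenance_count: int = 3
    dialysis_maintenance_window_days: int = 90
    cvd_risk_threshold: float = 15.0

    def __post_init__(self) -> None:
        b = self.g_stage_boundaries
        if list(b) != sorted(b, reverse=True) or len(set(b)) != len(b):
            raise ValueError("G-stage boundaries must be strictly decreasing")
        lo, hi = self.a_stage_boundaries
        if not 0 < lo < hi:
            raise ValueError("A-stage boundaries must satisfy 0 < lower < upper")


@dataclass(frozen=True)
class CkdEpiCoefficients:
    """2009 CKD-EPI creatinine equation, single-equation form, no race term."""

    scale: float = 141.0
    kappa_female: float = 0.7   # mg/dL
    kappa_male: float = 0.9
    alpha_female: float = -0.329
    alpha_male: float = -0.411
    beta_high: float = -1.209
    age_factor: float = 0.993
    female_multiplier: float = 1.018


#: µmol/L per mg/dL of creatinine.
CREATININE_UMOL_PER_MGDL = 88.4
#: mg/mmol per mg/g of uACR (molar mass of creatinine, 113.12 g/mol / 10).
UACR_MGG_PER_MGMMOL = 8.84


@dataclass(frozen=True)
class AppConfig:
    thresholds: Thresholds
    ckd_epi: CkdEpiCoefficients
    codesets: CodeSetLibrary
    stage_codes: Mapping[str, Mapping[str, str]]  # system -> {normalised code: stage name}
    version: int = 1


def _deep_merge(base: dict, override: Mapping) -> dict:
    out = dict(base)
    for k, v in override.items():
        if isinstance(v, Mapping) and isinstance(out.get(k), dict):
            out[k] = _deep_merge(out[k], v)
        else:
            out[k] = v
    return out


def _default_raw() -> dict:
    text = (importlib.resources.files("ckdphen.data") / "default_config.yaml").read_text()
    return yaml.safe_load(text)


def load_config(path: Optional[Union[str, Path]] = None) -> AppConfig:
    """Load the packaged default config, optionally overlaid with *path*."""
    raw = _default_raw()
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        raw = _deep_merge(raw, user)
    return config_from_mapping(raw)


def config_from_mapping(raw: Mapping[str, Any]) -> AppConfig:
    thr_raw = dict(raw.get("thresholds", {}))
    if "g_stage_boundaries" in thr_raw:
        thr_raw["g_stage_boundaries"] = tuple(float(x) for x in thr_raw["g_stage_boundaries"])
    if "a_stage_boundaries" in thr_raw:
        thr_raw["a_stage_boundaries"] = tuple(float(x) for x in thr_raw["a_stage_boundaries"])
    thresholds = Thresholds(**thr_raw)
    ckd_epi = CkdEpiCoefficients(**{k: float(v) for k, v in raw.get("ckd_epi", {}).items()})
    codesets = CodeSetLibrary(raw.get("codesets", {}))
    stage_codes = {
        system: {normalise_code(code): stage for code, stage in mapping.items()}
        for system, mapping in raw.get("stage_codes", {}).items()
    }
    return AppConfig(
        thresholds=thresholds,
        ckd_epi=ckd_epi,
        codesets=codesets,
        stage_codes=stage_codes,
        version=int(raw.get("version", 1)),
    )


def default_config() -> AppConfig:
    return load_config(None)
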