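"""YAML configuration covering every tunable of the pipeline.

One flat-ish nested mapping holds the wavelength grid, basis shape
parameters, template weights and scales, synthetic-cohort parameters,
preprocessing settings, classification thresholds, and the score cut-off.
``default_config`` materializes the package defaults; ``load_config``
validates a user file and reports every missing key at once.
"""

from __future__ import annotations

from pathlib import Path
from typing import Any

import yaml

from . import fluorophores as fl
from .classify import TypingThresholds
from .fluorophores import Phenotype
from .preprocess import PreprocessConfig
from .scoring import DEFAULT_CUTOFF
from .simulate import (
    DEFAULT_COUNTS_SCALE,
    DEFAULT_LOW_SNR_FRACTION,
    DEFAULT_N_SPECTRA,
    DEFAULT_NOISE_LEVEL,
    DEFAULT_TYPE_MIXES,
    CohortRecipe,
)
from .spectra import Diagnosis

__all__ = ["default_config", "load_config", "save_config", "ConfigError",
           "preprocess_from_config", "thresholds_from_config",
           "cohort_recipe_from_config"]


class ConfigError(ValueError):
    """Raised when a config file is missing required keys."""


def default_config() -> dict[str, Any]:
    """The full default configuration as a plain nested mapping."""
    return {
        "grid": {"start_nm": 380.0, "stop_nm": 680.0, "step_nm": 1.0},
        "bases": {
            "shg": {"excitation_nm": 800.0, "linewidth_nm": fl.SHG_LINEWIDTH_NM},
            "nadh": {"peak_nm": fl.NADH_PEAK_NM, "fwhm_nm": fl.NADH_FWHM_NM},
            "keratin": {"peak_nm": fl.KERATIN_PEAK_NM, "fwhm_nm": fl.KERATIN_FWHM_NM},
            "melanin": {"onset_nm": fl.MELANIN_ONSET_NM,
                        "softness_nm": fl.MELANIN_SOFTNESS_NM},
        },
        "templates": {
            "weights": {p.value: dict(w) for p, w in fl.DEFAULT_TEMPLATE_WEIGHTS.items()},
            "scales": {p.value: s for p, s in fl.DEFAULT_TEMPLATE_SCALES.items()},
        },
        "cohort": {
            "n_sk": 28, "n_nevus": 5, "n_cm": 24,
            "n_spectra": DEFAULT_N_SPECTRA,
            "low_snr_fraction": DEFAULT_LOW_SNR_FRACTION,
            "noise_level": DEFAULT_NOISE_LEVEL,
            "counts_scale": DEFAULT_COUNTS_SCALE,
            "type_mixes": {d.value: {p.value: v for p, v in mix.items()}
                           for d, mix in DEFAULT_TYPE_MIXES.items()},
        },
        "preprocess": {
            "smoothing_span": 40,
            "snr_threshold": 3.0,
            "snr_band": [430.0, 650.0],
            "normalization_band": [380.0, 680.0],
        },
        "thresholds": {
            "shg_high": TypingThresholds().shg_high,
            "shg_low": TypingThresholds().shg_low,
            "blue_dominance": TypingThresholds().blue_dominance,
            "monotonicity_min": TypingThresholds().monotonicity_min,
        },
        "scoring": {"cutoff": DEFAULT_CUTOFF},
        "seed": 0,
    }


def _missing_keys(config: dict, reference: dict, prefix: str = "") -> list[str]:
    missing = []
    for key, value in reference.items():
        if key not in config:
            missing.append(prefix + key)
        elif isinstance(value, dict) and isinstance(config.get(key), dict):
            missing.extend(_missing_keys(config[key], value, prefix + key + "."))
    return missing


def load_config(path: str | Path) -> dict[str, Any]:
    """Load and validate a config file; every missing key is reported."""
    with open(path, "r", encoding="utf-8") as fh:
        config = yaml.safe_load(fh)
    if not isinstance(config, dict):
        raise ConfigError(f"{path}: config must be a mapping")
    missing = _missing_keys(config, default_config())
    if missing:
        raise ConfigError(f"{path}: missing config keys: {', '.join(sorted(missing))}")
    if config["cohort"]["n_spectra"] < 1:
        raise ConfigError(f"{path}: cohort.n_spectra must be >= 1")
    return config


def save_config(config: dict[str, Any], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(config, fh, sort_keys=False)


def preprocess_from_config(config: dict[str, Any]) -> PreprocessConfig:
    p = config["preprocess"]
    return PreprocessConfig(
        smoothing_span=int(p["smoothing_span"]),
        snr_threshold=float(p["snr_threshold"]),
        snr_band=tuple(p["snr_band"]),
        normalization_band=tuple(p["normalization_band"]),
    )


def thresholds_from_config(config: dict[str, Any]) -> TypingThresholds:
    t = config["thresholds"]
    return TypingThresholds(
        shg_high=float(t["shg_high"]), shg_low=float(t["shg_low"]),
        blue_dominance=float(t["blue_dominance"]),
        monotonicity_min=float(t["monotonicity_min"]),
    )


def cohort_recipe_from_config(config: dict[str, Any],
                              seed: int | None = None) -> CohortRecipe:
    c = config["cohort"]
    return CohortRecipe(
        n_sk=int(c["n_sk"]), n_nevus=int(c["n_nevus"]), n_cm=int(c["n_cm"]),
        n_spectra=int(c["n_spectra"]),
        low_snr_fraction=float(c["low_snr_fraction"]),
        noise_level=float(c["noise_level"]),
        counts_scale=float(c["counts_scale"]),
        type_mixes={Diagnosis(d): {Phenotype(p): float(v) for p, v in mix.items()}
                    for d, mix in c["type_mixes"].items()},
        master_seed=int(seed if seed is not None else config["seed"]),
    )


def basis_set_from_config(config: dict[str, Any]):
    """Fluorophore bases honoring the config shape parameters."""
    from .fluorophores import basis_gaussian, basis_melanin, basis_shg
    from .spectra import make_default_grid

    grid = make_default_grid()
    b = config["bases"]
    return {
        "SHG": basis_shg(float(b["shg"]["excitation_nm"]),
                         float(b["shg"]["linewidth_nm"]), grid=grid),
        "NADH": basis_gaussian("NADH", float(b["nadh"]["peak_nm"]),
                               float(b["nadh"]["fwhm_nm"]), grid=grid),
        "KERATIN": basis_gaussian("KERATIN", float(b["keratin"]["peak_nm"]),
                                  float(b["keratin"]["fwhm_nm"]), grid=grid),
        "MELANIN": basis_melanin(float(b["melanin"]["onset_nm"]),
                                 float(b["melanin"]["softness_nm"]), grid=grid),
    }


def templates_from_config(config: dict[str, Any]):
    """Composed phenotype templates honoring config bases, weights and scales."""
    from .fluorophores import compose_template
    from .spectra import make_default_grid

    grid = make_default_grid()
    basis_set = basis_set_from_config(config)
    weights = config["templates"]["weights"]
    scales = config["templates"]["scales"]
    out = {}
    for name, scale in scales.items():
        p = Phenotype(name)
        w = weights.get(name)
        out[p] = compose_template(p, grid, weights=w, overall_scale=float(scale),
                                  basis_set=basis_set)
    return out
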