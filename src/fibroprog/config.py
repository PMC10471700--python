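"""Pipeline configuration: defaults, YAML loading with strict validation,
and per-stage seeded random-number streams.

Every stage threshold defaults to the values the analysis is built around:
twofold / FDR 0.05 for expression, 1.5x / FDR 0.01 for differential mark
windows, 3 kb TSS annotation, 10 kb gene flank, 5x methylation coverage, and
{10, 33, 50} percentage-point methylation thresholds.
"""

from __future__ import annotations

import copy
import zlib
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import yaml

DEFAULTS: dict[str, Any] = {
    "seed": 1,
    "synth": {
        "n_genes": 2000,
        "n_erg": 50,
        "fraction_de": 0.25,
        "fraction_concordant_chip": 0.8,
        "fraction_concordant_meth": 0.6,
        "de_log2fc": 1.5,
        "chip_effect": 3.0,
        "meth_delta": 0.4,
        "rna_depth": 10_000_000,
        "chip_background": 5.0,
        "peak_height": 10.0,
        "cpg_coverage": 30,
        "cpgs_per_promoter": 14,
        "replicates": 1,
        "dispersion": 0.01,
        "meth_base": 0.5,
        "meth_concentration": 30.0,
        "window_size": 1000,
        "promoter_flank": 1000,
        "gene_length": 4000,
        "gene_spacing": 20000,
        "n_chroms": 2,
        "panel_delta": -0.25,
        "panel_coverage": 500,
    },
    "diffexpr": {
        "min_total": 10,
        "dispersion": 0.01,
        "fc_cut": 2.0,
        "fdr_cut": 0.05,
    },
    "diffchip": {
        "fc_cut": 1.5,
        "fdr_cut": 0.01,
        "tss_max_dist": 3000,
        "gene_flank": 10000,
    },
    "chromstate": {
        "n_states": 4,
        "p_cut": 1.0e-4,
        "n_restarts": 2,
        "max_iter": 200,
        "tol": 1.0e-6,
        "enabled": True,
    },
    "methylome": {
        "min_coverage": 5,
        "thresholds": [0.10, 0.33, 0.50],
        "promoter_flank": 1000,
    },
    "integrate": {
        "threshold": 0.33,
    },
}


class ConfigError(ValueError):
    """Raised for unknown keys or wrongly-typed values; names the key path."""


def _merge(defaults: Mapping[str, Any], overrides: Mapping[str, Any], path: str = ""
           ) -> dict[str, Any]:
    out: dict[str, Any] = copy.deepcopy(dict(defaults))
    for key, value in overrides.items():
        here = f"{path}.{key}" if path else str(key)
        if key not in defaults:
            raise ConfigError(f"unknown configuration key: {here}")
        default = defaults[key]
        if isinstance(default, Mapping):
            if not isinstance(value, Mapping):
                raise ConfigError(f"{here}: expected a mapping")
            out[key] = _merge(default, value, here)
        else:
            out[key] = _coerce(value, default, here)
    return out


def _coerce(value: Any, default: Any, here: str) -> Any:
    if isinstance(default, bool):
        if not isinstance(value, bool):
            raise ConfigError(f"{here}: expected a boolean, got {value!r}")
        return value
    if isinstance(default, int) and not isinstance(default, bool):
        if isinstance(value, bool) or not isinstance(value, (int, float)):
            raise ConfigError(f"{here}: expected a number, got {value!r}")
        if isinstance(value, float) and not value.is_integer():
            raise ConfigError(f"{here}: expected an integer, got {value!r}")
        return int(value)
    if isinstance(default, float):
        if isinstance(value, bool) or not isinstance(value, (int, float)):
            raise ConfigError(f"{here}: expected a number, got {value!r}")
        return float(value)
    if isinstance(default, list):
        if not isinstance(value, list):
            raise ConfigError(f"{here}: expected a list, got {value!r}")
        return [float(v) for v in value]
    return value


def load_config(path: str | Path | None = None,
                overrides: Mapping[str, Any] | None = None) -> dict[str, Any]:
    """Load a YAML config over the defaults; unknown keys are rejected.

    An empty or absent file yields the full default configuration.
    """
    data: dict[str, Any] = {}
    if path is not None:
        with open(path) as handle:
            loaded = yaml.safe_load(handle)
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, Mapping):
            raise ConfigError("top-level configuration must be a mapping")
        data = dict(loaded)
    cfg = _merge(DEFAULTS, data)
    if overrides:
        cfg = _merge(cfg, overrides)
    return cfg


def dump_config(cfg: Mapping[str, Any], path: str | Path) -> None:
    """Write the effective configuration (for provenance of each run)."""
    with open(path, "w") as handle:
        yaml.safe_dump(dict(cfg), handle, sort_keys=True, default_flow_style=False)


def rng_for(stage_name: str, seed: int) -> np.random.Generator:
    """An independent, reproducible random stream per (seed, stage).

    The stream is seeded from the pair (seed, CRC-32 of the stage name), so
    identical inputs give identical draws on any platform and different
    stages never share a stream.
    """
    tag = zlib.crc32(stage_name.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence([int(seed), tag]))
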