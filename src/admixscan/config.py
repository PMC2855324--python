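"""Pipeline configuration: a nested key-value file (YAML) with defaults.

Every CLI flag overrides its config key. Thresholds follow the scan
conventions: genome-wide score > 2, locus LOD > 5, |case-control Z| > 4.06.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Optional

import yaml

DEFAULTS: dict[str, Any] = {
    "simulate": {
        "n_snps": 300,
        "n_chrom": 3,
        "n_individuals": 400,
        "diff_spec": 0.75,
        "lambda_gen": 6.0,
        "theta_mean": 0.824,
        "theta_sd": 0.098,
        "effect_size": 0.0,
        "risk_locus": None,
        "strat_prevalence": 0.579,
        "missing_rate": 0.0,
        "seed": 1,
    },
    "paths": {"panel": None, "genotypes": None, "phenotypes": None, "format": "dosage_tsv"},
    "qc": {
        "sample_call_rate": 0.94,
        "snp_call_rate": 0.95,
        "dup_threshold": 0.75,
        "het_z": 10.0,
        "hwe_alpha": 0.01,
        "freqcheck_alpha": 0.001,
        "ld_window_bp": 200_000,
        "ld_r2_max": 0.05,
    },
    "hmm": {"burn_in": 100, "iters": 200, "seed": 1, "lambda_init": 6.0},
    "scan": {
        "trait": "crve_like",
        "direction": "high_is_case",
        "frac": 0.15,
        "stratum": None,  # e.g. "hypertension=1"
        "coverage": 0.95,
        "covariates": ["age", "sex", "site", "map6yr", "glucose"],
    },
    "thresholds": {"genome_score": 2.0, "locus_lod": 5.0, "cc_z": 4.06},
}


def _merge(base: dict, override: dict) -> dict:
    out = copy.deepcopy(base)
    for k, v in (override or {}).items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = v
    return out


@dataclass
class PipelineConfig:
    """Validated pipeline settings; see :data:`DEFAULTS` for the full key set."""

    settings: dict = field(default_factory=lambda: copy.deepcopy(DEFAULTS))

    def __post_init__(self) -> None:
        s = self.settings
        for key, thr in s["thresholds"].items():
            if thr <= 0:
                raise ValueError(f"threshold {key} must be positive")
        for key in ("panel", "genotypes", "phenotypes"):
            p = s["paths"].get(key)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"configured {key} file does not exist: {p}")

    @classmethod
    def load(cls, path: Optional[str] = None, overrides: Optional[dict] = None) -> "PipelineConfig":
        settings = copy.deepcopy(DEFAULTS)
        if path is not None:
            with open(path) as fh:
                settings = _merge(settings, yaml.safe_load(fh) or {})
        if overrides:
            settings = _merge(settings, overrides)
        return cls(settings)

    def __getitem__(self, key: str) -> Any:
        return self.settings[key]
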