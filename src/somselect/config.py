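"""Shared configuration: classification thresholds and significance levels.

All statistical procedures in the package read their significance threshold
from a single config mapping so that the study-wide multiple-comparison
adjustment (a tenfold-lowered threshold of 0.005) is applied consistently.
"""
from __future__ import annotations

import copy
from pathlib import Path
from typing import Any

import yaml

#: Default thresholds for microsatellite-subtype assignment and testing.
#: tmb_low / tmb_htmb bound the likely-MSI TMB window [16, 100] mut/Mb;
#: sensor / mantis are the published MSI-score cutoffs of the source studies;
#: alpha is the tree-growing criterion; significance the study-wide level.
DEFAULT_CONFIG: dict[str, Any] = {
    "thresholds": {
        "tmb_low": 16.0,
        "tmb_htmb": 100.0,
        "sensor": 3.5,
        "mantis": 0.4,
        "alpha": 0.001,
        "significance": 0.005,
    },
    # When a sample has a known MS status that conflicts with its TMB-derived
    # label (known MSS but TMB in the likely-MSI window), the known status
    # wins by default.
    "known_status_wins": True,
    # Functional dichotomization cutoffs on the continuous activity /
    # abundance scales (scores below the cutoff are damaging). The scales
    # follow deep-mutational-scanning fitness conventions where wild type
    # sits near 1; overridable per study.
    "lpa_cutoff": 0.5,
    "abundance_cutoff": 0.5,
    "indel_impact_cutoff": 0.5,
    # NA-scored substitutions are excluded from damage-fraction numerator
    # and denominator ("exclude"); alternative "wt" counts them intact.
    "na_handling": "exclude",
    # Hotspot callers gate on BH q-values by default; "p" gates on raw p.
    "hotspot_gate": "q",
}


def default_config() -> dict[str, Any]:
    """Return a deep copy of the package defaults."""
    return copy.deepcopy(DEFAULT_CONFIG)


def load_config(path: str | Path | None = None) -> dict[str, Any]:
    """Load a YAML config, recursively merged over the defaults."""
    cfg = default_config()
    if path is None:
        return cfg
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    _merge(cfg, user)
    return cfg


def _merge(base: dict, extra: dict) -> None:
    for key, val in extra.items():
        if isinstance(val, dict) and isinstance(base.get(key), dict):
            _merge(base[key], val)
        else:
            base[key] = val
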