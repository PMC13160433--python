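"""Pipeline configuration.

All tunable knobs of the pipeline live in one flat dataclass so that a run is
fully determined by (inputs, config, seed).  Values can be overridden from a
YAML mapping via :func:`load_config`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace
from pathlib import Path

import yaml


@dataclass(frozen=True)
class Config:
    # --- structure selection -------------------------------------------------
    # additive utility weights: coverage, technique diversity, quality,
    # multimer priority, redundancy penalty
    w_cov: float = 4.0
    w_div: float = 1.0
    w_qual: float = 1.0
    w_mult: float = 1.0
    w_red: float = 2.0
    #: resolution (A) mapped linearly to quality 1 at/below this value
    res_best: float = 2.0
    #: resolution (A) mapped to quality 0 at/above this value
    res_worst: float = 4.0
    #: maximum structures retained per variant
    max_structures: int = 6

    # --- spatial clustering (PathProx-style) ---------------------------------
    #: "reciprocal" -> K(d) = 1/(1+d); "exponential" -> K(d) = exp(-d/kernel_scale)
    kernel: str = "reciprocal"
    kernel_scale: float = 8.0
    n_permutations: int = 199

    # --- reporting flags -----------------------------------------------------
    #: predicted folding destabilisation (R.E.U.-like units) at/above which the
    #: case summary raises a destabilisation flag
    ddg_flag: float = 2.0
    #: clustering permutation p at/below which the case summary raises a flag
    pathprox_p_flag: float = 0.05
    #: interface / PTM / digenic probability-like scores at/above which the
    #: corresponding flags are raised
    ppi_flag: float = 0.5
    ptm_flag: float = 0.5
    digenic_flag: float = 0.5

    # --- score lookup --------------------------------------------------------
    #: fall back to the canonical table entry for "-N" isoform queries
    canonical_score_fallback: bool = False


DEFAULT_CONFIG = Config()

_FIELD_NAMES = {f.name for f in fields(Config)}


def load_config(path: str | Path | None = None, **overrides) -> Config:
    """Build a Config from an optional YAML file plus keyword overrides."""
    values: dict = {}
    if path is not None:
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - _FIELD_NAMES
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        values.update(data)
    values.update(overrides)
    return replace(Config(), **values)
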