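"""Structured-text run configuration: schema validation and presets.

A configuration file is YAML with one block per physical subsystem
(``particle``, ``electrolyte``, ``tip``, ``grid``, ``lattice``,
``slab``, ``adsorption``).  Every key carries its unit in the name
where ambiguity is possible; unknown blocks or keys are rejected with
an explicit listing so typos never pass silently.

Named presets bundle the solution-assembly parameter set of the
reference tetramer (net charge -16 e, macrodipole 1200 D, radius
4.0 nm, eps = 78, Debye length 2.1508 nm) with the open and most
compressed lattice conformations used for the electret estimates.
"""

from __future__ import annotations

import hashlib
import json
from typing import Any, Mapping

import numpy as np
import yaml

from .electrostatics import Electrolyte, PatchyParticleModel

__all__ = [
    "SCHEMA",
    "PRESETS",
    "load_config",
    "validate_config",
    "merge_config",
    "particle_from",
    "electrolyte_from",
    "config_hash",
    "provenance_header",
]

SCHEMA: dict[str, tuple[str, ...]] = {
    "particle": ("net_charge_e", "dipole_debye", "radius_nm"),
    "electrolyte": ("relative_permittivity", "temperature_K", "ionic_strength_M", "debye_length_nm"),
    "tip": ("apex_radius_A", "cone_half_angle_deg", "z_cutoff_A", "overlap_threshold"),
    "grid": ("x_min_A", "x_max_A", "y_min_A", "y_max_A", "step_A"),
    "lattice": ("edge_length_nm", "opening_angle_deg", "symmetry", "nx", "ny"),
    "slab": ("dipole_debye", "cell_area_nm2", "thickness_nm", "relative_permittivity", "orientation"),
    "adsorption": ("coverage", "n_x", "n_y", "replicates", "seed", "neighborhood"),
    "run": ("seed", "verbosity"),
}

# Opening angle that compresses an L = 7.0711 nm lattice to the most
# compressed simulated conformation (per-protein cell edge 7.5595 nm).
_THETA_COMPRESSED = float(np.rad2deg(np.arcsin(7.5595 / (7.0711 * np.sqrt(2.0)))) - 45.0)

PRESETS: dict[str, dict[str, dict[str, Any]]] = {
    "rhua-solution": {
        "particle": {"net_charge_e": -16.0, "dipole_debye": 1200.0, "radius_nm": 4.0},
        "electrolyte": {
            "relative_permittivity": 78.0,
            "temperature_K": 300.0,
            "ionic_strength_M": 0.020,
            "debye_length_nm": 2.1508,
        },
    },
    "rhua-open-p4": {
        "particle": {"net_charge_e": -16.0, "dipole_debye": 1200.0, "radius_nm": 4.0},
        "electrolyte": {
            "relative_permittivity": 78.0,
            "temperature_K": 300.0,
            "ionic_strength_M": 0.020,
            "debye_length_nm": 2.1508,
        },
        "lattice": {"edge_length_nm": 7.0711, "opening_angle_deg": 45.0, "symmetry": "p4"},
        "slab": {
            "dipole_debye": 1200.0,
            "cell_area_nm2": 100.0,
            "thickness_nm": 4.5,
            "relative_permittivity": 78.0,
            "orientation": 1,
        },
    },
    "rhua-compressed-p4": {
        "particle": {"net_charge_e": -16.0, "dipole_debye": 1200.0, "radius_nm": 4.0},
        "electrolyte": {
            "relative_permittivity": 78.0,
            "temperature_K": 300.0,
            "ionic_strength_M": 0.020,
            "debye_length_nm": 2.1508,
        },
        "lattice": {
            "edge_length_nm": 7.0711,
            "opening_angle_deg": round(_THETA_COMPRESSED, 4),
            "symmetry": "p4",
        },
        "slab": {
            "dipole_debye": 1200.0,
            "cell_area_nm2": 7.5595**2,
            "thickness_nm": 4.5,
            "relative_permittivity": 78.0,
            "orientation": 1,
        },
    },
}


def validate_config(cfg: Mapping[str, Any]) -> None:
    """Reject unknown blocks/keys and non-numeric values where numbers
    are expected; raises ValueError listing every offending field."""
    problems = []
    for block, content in cfg.items():
        if block not in SCHEMA:
            problems.append(f"unknown block '{block}'")
            continue
        if not isinstance(content, Mapping):
            problems.append(f"block '{block}' must be a mapping")
            continue
        for key in content:
            if key not in SCHEMA[block]:
                problems.append(f"unknown key '{block}.{key}'")
    if problems:
        raise ValueError("invalid configuration: " + "; ".join(problems))


def load_config(path) -> dict:
    """Load and validate a YAML configuration file."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError("configuration root must be a mapping")
    validate_config(cfg)
    return cfg


def merge_config(*layers: Mapping[str, Any] | None) -> dict:
    """Deep-merge configuration layers; later layers win."""
    out: dict[str, dict] = {}
    for layer in layers:
        if not layer:
            continue
        for block, content in layer.items():
            out.setdefault(block, {}).update(content)
    validate_config(out)
    return out


def particle_from(cfg: Mapping[str, Any]) -> PatchyParticleModel:
    p = cfg.get("particle", {})
    return PatchyParticleModel(
        net_charge=p.get("net_charge_e", -16.0),
        dipole_magnitude=p.get("dipole_debye", 1200.0),
        radius=p.get("radius_nm", 4.0),
    )


def electrolyte_from(cfg: Mapping[str, Any]) -> Electrolyte:
    e = cfg.get("electrolyte", {})
    debye_len = e.get("debye_length_nm")
    return Electrolyte(
        relative_permittivity=e.get("relative_permittivity", 78.0),
        temperature=e.get("temperature_K", 300.0),
        ionic_strength=e.get("ionic_strength_M", 0.020),
        kappa_nm=None if debye_len is None else 1.0 / debye_len,
    )


def config_hash(cfg: Mapping[str, Any]) -> str:
    """Short stable hash of a configuration for provenance headers."""
    blob = json.dumps(cfg, sort_keys=True, default=float)
    return hashlib.sha256(blob.encode()).hexdigest()[:12]


def provenance_header(subcommand: str, cfg: Mapping[str, Any]) -> str:
    """Comment lines embedded at the top of every output file."""
    from . import __version__

    params = json.dumps(cfg, sort_keys=True, default=float)
    return (
        f"# patchylat {__version__} | {subcommand} | config {config_hash(cfg)}\n"
        f"# parameters: {params}\n"
    )
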