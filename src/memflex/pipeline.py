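"""Orchestration: configuration, unit conversion, reports, aggregation.

``run_analysis`` drives geometry, diffusion and the selected
bending-modulus estimators over a single trajectory with one shared
leaflet assignment, and emits a JSON-serializable report that echoes
every default actually used.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .bw_dcf import bwdcf_modulus
from .errors import ConfigurationError, MemflexError
from .geometry_props import (
    diffusion_coefficient,
    geometry_summary,
    lateral_msd,
)
from .rsf import rsf_modulus
from .spectral_q4 import q4_modulus
from .trajectory_model import (
    KB,
    assign_leaflets_trajectory,
    read_trajectory,
    remove_com_motion,
)

REPORT_SCHEMA_VERSION = 1
METHODS = ("q4", "bwdcf", "rsf")


# ---------------------------------------------------------------------------
# unit conversion
# ---------------------------------------------------------------------------

def kbt_to_joule(value: float, temperature: float) -> float:
    """Convert an energy from k_B T units to joules (k_B = 1.380649e-23 J/K)."""
    if temperature <= 0:
        raise ConfigurationError("temperature must be positive")
    return value * KB * temperature


def joule_to_kbt(value: float, temperature: float) -> float:
    """Convert an energy from joules to k_B T units."""
    if temperature <= 0:
        raise ConfigurationError("temperature must be positive")
    return value / (KB * temperature)


# ---------------------------------------------------------------------------
# analysis driver
# ---------------------------------------------------------------------------

_DEFAULTS = {
    "methods": list(METHODS),
    "temperature": 300.0,
    "q4": {"n_shells": 5, "include_tension": False},
    "bwdcf": {"n_bw": 3, "n_shells": 5, "backend": "direct", "bin_width": 0.02},
    "rsf": {"cutoff": 1.2, "patch_radius": 1.5, "convention": "difference",
            "n_bins": 101},
    "diffusion": {"enabled": True, "fit_window": [0.1, 0.5]},
    "keep_going": False,
    "metadata": {},
}


def _merged_config(config: dict) -> dict:
    merged = json.loads(json.dumps(_DEFAULTS))
    for key, value in config.items():
        if isinstance(value, dict) and isinstance(merged.get(key), dict):
            merged[key].update(value)
        else:
            merged[key] = value
    return merged


def load_config(path) -> dict:
    import yaml

    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ConfigurationError(f"config {path} did not parse to a mapping")
    return cfg


def run_analysis(config: dict | str | Path) -> dict:
    """Run the configured estimators on one trajectory; return the report.

    ``config`` is a mapping (or a YAML path) with at least
    ``trajectory: {coordinates: <path>}``. Unknown methods raise before any
    compute; with ``keep_going`` a failing stage is recorded instead of
    raised and the partial report is returned.
    """
    if not isinstance(config, dict):
        config = load_config(config)
    cfg = _merged_config(config)

    tr_cfg = cfg.get("trajectory") or {}
    coords = tr_cfg.get("coordinates")
    if not coords:
        raise ConfigurationError("config must set trajectory.coordinates")
    if not Path(coords).exists():
        raise ConfigurationError(f"coordinate file not found: {coords}")
    methods = list(cfg["methods"])
    unknown = set(methods) - set(METHODS)
    if unknown:
        raise ConfigurationError(f"unknown methods: {sorted(unknown)}")

    traj = read_trajectory(
        coords,
        trajectory_path=tr_cfg.get("trajectory"),
        selectors=tr_cfg.get("selectors"),
        temperature=float(tr_cfg.get("temperature", cfg["temperature"])),
    )
    traj = remove_com_motion(traj)
    assignment = assign_leaflets_trajectory(traj)

    report = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "software": {"name": "memflex", "version": __version__},
        "config": cfg,
        "temperature_K": traj.temperature,
        "n_frames": traj.n_frames,
        "estimates": {},
        "errors": {},
    }
    prov = traj.provenance
    if isinstance(prov, dict) and "ground_truth" in prov:
        report["ground_truth"] = prov["ground_truth"]

    def stage(name, fn):
        try:
            return fn()
        except MemflexError as exc:
            if not cfg["keep_going"]:
                raise MemflexError(f"stage {name!r} failed: {exc}") from exc
            report["errors"][name] = str(exc)
            return None

    geom = stage("geometry", lambda: geometry_summary(traj, assignment))
    if geom is not None:
        report["geometry"] = geom.to_dict()

    if cfg["diffusion"]["enabled"] and traj.n_frames >= 4:
        def _diff():
            msd = lateral_msd(traj)
            return diffusion_coefficient(
                msd, fit_window=tuple(cfg["diffusion"]["fit_window"])
            )
        diff = stage("diffusion", _diff)
        if diff is not None:
            report["diffusion"] = {
                "D_nm2_per_ps": diff.D,
                "D_cm2_per_s": diff.D_cm2_per_s,
                "stderr_nm2_per_ps": diff.stderr,
                "r_squared": diff.r_squared,
                "warnings": diff.warnings,
            }

    runners = {
        "q4": lambda: q4_modulus(
            traj, assignment,
            n_shells=int(cfg["q4"]["n_shells"]),
            include_tension=bool(cfg["q4"]["include_tension"]),
        ),
        "bwdcf": lambda: bwdcf_modulus(
            traj, assignment,
            n_bw=int(cfg["bwdcf"]["n_bw"]),
            n_shells=int(cfg["bwdcf"]["n_shells"]),
            backend=cfg["bwdcf"]["backend"],
            bin_width=float(cfg["bwdcf"]["bin_width"]),
        ),
        "rsf": lambda: rsf_modulus(
            traj, assignment,
            cutoff=float(cfg["rsf"]["cutoff"]),
            patch_radius=float(cfg["rsf"]["patch_radius"]),
            convention=cfg["rsf"]["convention"],
            n_bins=int(cfg["rsf"]["n_bins"]),
        ),
    }
    for m in methods:
        est = stage(m, runners[m])
        if est is not None:
            report["estimates"][m] = est.to_dict()
            report["estimates"][m]["kappa_J"] = kbt_to_joule(
                est.kappa, traj.temperature
            )
    if "geometry" in report:
        report["metadata"] = dict(cfg["metadata"])
    return report


def write_report(report: dict, path) -> None:
    Path(path).write_text(json.dumps(report, indent=2, default=_json_default))


def _json_default(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    raise TypeError(f"not JSON serializable: {type(obj)}")


# ---------------------------------------------------------------------------
# aggregation
# ---------------------------------------------------------------------------

@dataclass
class AggregateSummary:
    """Mean +- sample SD (n-1 denominator) of kappa per group and method."""

    group_by: str
    rows: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {"group_by": self.group_by, "rows": self.rows}


def aggregate(reports: list[dict], group_by: str) -> AggregateSummary:
    """Group reports by a metadata key; mean and sample SD of kappa per method.

    Singleton groups are flagged (SD reported as 0 with n = 1).
    """
    groups: dict[str, list[dict]] = {}
    for rep in reports:
        key = str(rep.get("metadata", {}).get(group_by, "<missing>"))
        groups.setdefault(key, []).append(rep)
    summary = AggregateSummary(group_by=group_by)
    for key in sorted(groups):
        members = groups[key]
        if not members:
            raise ConfigurationError(f"empty group {key!r}")
        row: dict = {"group": key, "n": len(members)}
        for m in METHODS:
            vals = [
                rep["estimates"][m]["kappa_kBT"]
                for rep in members
                if m in rep.get("estimates", {})
            ]
            if not vals:
                continue
            mean = float(np.mean(vals))
            sd = float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0
            row[m] = {"mean_kBT": mean, "sd_kBT": sd, "n": len(vals),
                      "singleton": len(vals) == 1}
        summary.rows.append(row)
    return summary
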