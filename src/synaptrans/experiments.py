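"""Config-file experiment driver: reproducible artifact bundles.

An experiment config is a YAML mapping with:

    name: fig6a                  # free-form identifier
    mode: simulate | poincare | census | scan | table
    parameters: {h_x: 1, ...}    # overrides on the basic set
    delays: {tau_a: 1, ...}      # overrides on the basic delays
    history: {x: 2.5, y: 0.5, z: 5.0}        # optional, default standard
    section: {variable: x, level: 2.0, direction: increasing}
    integration: {h: 0.01, t_end: 4000}
    classifier: {transient_fraction: 0.5, ...}
    scan: {parameter: k_rz, start: 0, stop: 1, step: 0.01,
           couple_kdz: true, n_starts: 1}
    census: {n_starts: 12}
    table: {h_x: 2, h_b_values: [5,10,15,20], k_x_values: [10,20,40]}
    seed: 0

An empty config runs a single trajectory from the basic set.  Output is
a directory with TSV artifacts plus ``manifest.json`` recording the full
resolved configuration, the seed, the package version and which
parameter values were overridden relative to the basic reference set.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import yaml

from .integrate import (
    HistoryFunction,
    IntegrationSettings,
    STANDARD_HISTORY,
    integrate_dde,
)
from .parameters import (
    DelayParameters,
    ModelParameters,
    validate_parameters,
)
from .regimes import (
    ClassifierSettings,
    PoincareSection,
    attractor_census,
    classify_setting,
    poincare_crossings,
)
from .scan import ScanSpec, cell_symbol, regime_table, scan_parameter

__all__ = ["ExperimentError", "load_config", "run_experiment",
           "builtin_config_path", "builtin_configs"]

_CONFIG_DIR = Path(__file__).parent / "configs"


class ExperimentError(ValueError):
    """Config error, reported with the offending key path."""


def builtin_configs() -> list[str]:
    """Names of the shipped experiment configs (reference figures/tables)."""
    return sorted(p.stem for p in _CONFIG_DIR.glob("*.yaml")
                  if p.stem != "basic_set_2")


def builtin_config_path(name: str) -> Path:
    p = _CONFIG_DIR / f"{name}.yaml"
    if not p.exists():
        raise ExperimentError(
            f"no shipped config {name!r}; available: {builtin_configs()}")
    return p


def _pick(mapping: Mapping, key: str, cls, path: str):
    sub = mapping.get(key, {}) or {}
    if not isinstance(sub, Mapping):
        raise ExperimentError(f"{path}.{key}: expected a mapping, got {sub!r}")
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(sub) - known
    if unknown:
        raise ExperimentError(f"{path}.{key}: unknown keys {sorted(unknown)}")
    return dict(sub)


def load_config(source: str | Path | Mapping | None) -> dict:
    """Load and normalise an experiment config (file path, mapping or None)."""
    if source is None:
        data: dict = {}
    elif isinstance(source, Mapping):
        data = dict(source)
    else:
        path = Path(source)
        if not path.exists() and not path.suffix:
            path = builtin_config_path(str(source))
        data = yaml.safe_load(path.read_text()) or {}
        data.setdefault("name", path.stem)
    data.setdefault("name", "adhoc")
    data.setdefault("mode", "simulate")
    if data["mode"] not in ("simulate", "poincare", "census", "scan", "table"):
        raise ExperimentError(f"mode: unknown mode {data['mode']!r}")
    return data


def _resolve(data: dict, seed: int | None):
    base = ModelParameters()
    p_over = _pick(data, "parameters", ModelParameters, data["name"])
    d_over = _pick(data, "delays", DelayParameters, data["name"])
    p = base.replace(**p_over)
    d = DelayParameters().replace(**d_over)
    validate_parameters(p, d)
    hist_cfg = data.get("history")
    if hist_cfg:
        hist = HistoryFunction(float(hist_cfg.get("x", 2.5)),
                               float(hist_cfg.get("y", 0.5)),
                               float(hist_cfg.get("z", 5.0)), d.horizon)
    else:
        hist = STANDARD_HISTORY(d.horizon)
    sec_cfg = data.get("section", {}) or {}
    section = PoincareSection(
        variable=sec_cfg.get("variable", "x"),
        level=float(sec_cfg.get("level", 2.0)),
        direction=sec_cfg.get("direction", "increasing"))
    ints = IntegrationSettings(**_pick(data, "integration",
                                       IntegrationSettings, data["name"]))
    cls = ClassifierSettings(**_pick(data, "classifier", ClassifierSettings,
                                     data["name"]))
    if seed is None:
        seed = int(data.get("seed", 0))
    return p, d, hist, section, ints, cls, seed


def _overridden(p: ModelParameters, d: DelayParameters) -> dict[str, Any]:
    """Fields that differ from the basic reference configuration."""
    out = {}
    for name, v in p.to_dict().items():
        v0 = getattr(ModelParameters(), name)
        if v != v0:
            out[name] = {"value": v, "basic": v0}
    for name, v in d.to_dict().items():
        v0 = getattr(DelayParameters(), name)
        if v != v0:
            out[name] = {"value": v, "basic": v0}
    return out


def run_experiment(
    source: str | Path | Mapping | None,
    out_dir: str | Path,
    seed: int | None = None,
) -> dict:
    """Run one experiment config; returns the manifest (also written).

    The bundle directory holds TSV artifacts named by mode, and
    ``manifest.json`` with the resolved config, provenance of every
    overridden parameter, the seed and a config hash.
    """
    from . import __version__

    data = load_config(source)
    p, d, hist, section, ints, cls, seed = _resolve(data, seed)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: list[str] = []
    summary: dict[str, Any] = {}
    mode = data["mode"]

    if mode == "simulate":
        traj = integrate_dde(p, d, hist, ints)
        traj.to_tsv(out / "trajectory.tsv", stride=int(data.get("stride", 10)))
        artifacts.append("trajectory.tsv")
        summary["final_state"] = [float(v) for v in traj.states[-1]]
    elif mode == "poincare":
        label, traj, crossings = classify_setting(p, d, hist, ints, section, cls)
        crossings.to_tsv(out / "crossings.tsv")
        artifacts.append("crossings.tsv")
        summary["regime"] = label.symbol
        summary["n_crossings"] = len(crossings)
    elif mode == "census":
        c_cfg = data.get("census", {}) or {}
        entries = attractor_census(
            p, d, section=section, n_starts=int(c_cfg.get("n_starts", 12)),
            seed=seed, int_settings=ints, settings=cls)
        rows = ["category\tmultiplicity\tn_members\tmean_level\tamplitude\tordinates"]
        for e in entries:
            s = e.signature
            rows.append(f"{s.category.value}\t{s.multiplicity}\t{e.n_members}"
                        f"\t{s.mean_level!r}\t{s.amplitude!r}"
                        f"\t{','.join(repr(o) for o in s.ordinates)}")
        (out / "census.tsv").write_text("\n".join(rows) + "\n")
        artifacts.append("census.tsv")
        summary["cell_symbol"] = cell_symbol(entries)
        summary["n_attractors"] = len(entries)
    elif mode == "scan":
        s_cfg = data.get("scan", {}) or {}
        if "parameter" not in s_cfg:
            raise ExperimentError(f"{data['name']}.scan.parameter is required")
        if "grid" in s_cfg:
            grid = tuple(float(g) for g in s_cfg["grid"])
        else:
            start, stop = float(s_cfg["start"]), float(s_cfg["stop"])
            step = float(s_cfg.get("step", 0.01))
            grid = tuple(np.round(np.arange(start, stop + step / 2, step), 10))
        spec = ScanSpec(
            parameter=str(s_cfg["parameter"]), grid=grid,
            couple_kdz=bool(s_cfg.get("couple_kdz", True)),
            n_starts=int(s_cfg.get("n_starts", 1)), seed=seed,
            section=section, int_settings=ints, cls_settings=cls,
            continue_branches=bool(s_cfg.get("continue_branches", True)))
        diagram = scan_parameter(spec, p, d)
        diagram.to_tsv(out / "diagram.tsv")
        artifacts.append("diagram.tsv")
        summary["n_branches"] = len(diagram.branches())
        summary["categories"] = sorted(
            {c.value for i in range(diagram.grid.size)
             for c in diagram.categories_at(i)})
    elif mode == "table":
        t_cfg = data.get("table", {}) or {}
        tab = regime_table(
            h_x=float(t_cfg.get("h_x", p.h_x)), base_p=p, base_d=d,
            h_b_values=tuple(t_cfg.get("h_b_values", (5, 10, 15, 20))),
            k_x_values=tuple(t_cfg.get("k_x_values", (10, 20, 40))),
            K_a_values=tuple(t_cfg.get("K_a_values", (1, 2, 3))),
            k_rz_values=tuple(t_cfg.get("k_rz_values", (0.0, 0.5, 1.0))),
            n_starts=int(t_cfg.get("n_starts", 12)), seed=seed,
            section=section, int_settings=ints, cls_settings=cls)
        tab.to_tsv(out / "regime_table.tsv")
        (out / "regime_table.txt").write_text(tab.to_text() + "\n")
        artifacts += ["regime_table.tsv", "regime_table.txt"]
        summary["cells"] = int(tab.table.size)

    resolved = {
        "name": data["name"], "mode": mode, "seed": seed,
        "parameters": p.to_dict(), "delays": d.to_dict(),
        "history": {"x": hist.x, "y": hist.y, "z": hist.z},
        "section": dataclasses.asdict(section),
        "integration": dataclasses.asdict(ints),
        "classifier": dataclasses.asdict(cls),
    }
    blob = json.dumps(resolved, sort_keys=True).encode()
    manifest = {
        **resolved,
        "version": __version__,
        "config_hash": hashlib.sha256(blob).hexdigest()[:16],
        "overridden_from_basic_set": _overridden(p, d),
        "artifacts": artifacts,
        "summary": summary,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest
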