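"""Scenario configuration files, trajectory writers and run manifests.

Scenarios serialize to a human-readable YAML mapping whose keys carry explicit
units (``length_bp``, ``k_on_per_s``, ``concentration_uM``, ...) to prevent
unit mistakes between nM and uM settings.  ``load_scenario`` fills defaults,
rejects unknown keys and records the provenance (user vs default) of every
parameter in ``scenario.meta["provenance"]``.  A run manifest stores the fully
resolved scenario plus seed and code version, from which a trajectory can be
regenerated bit-exactly.
"""

from __future__ import annotations

import dataclasses
import time
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .engine import SimParams, Trajectory
from .genome import GenomeSpec, TranscriptionUnit
from .response import PromoterResponse, TopoisomeraseModel
from .scenarios import Scenario

__all__ = [
    "scenario_to_dict",
    "scenario_from_dict",
    "save_scenario",
    "load_scenario",
    "write_trajectory",
    "write_manifest",
]

_RESPONSE_KEYS = {"variant", "sigma_t", "epsilon", "m", "sigma_r", "epsilon_r"}
_UNIT_KEYS = {"id", "tss_bp", "terminator_bp", "strand", "k_on_per_s", "active", "response"}
_TOPO_KEYS = {
    "name", "sign", "sigma0", "width", "k_basal_per_s",
    "concentration_uM", "reference_concentration_uM",
}
_GENOME_KEYS = {"length_bp", "circular", "barriers_bp", "topoisomerases", "units"}
_PARAM_KEYS = {
    "duration_s", "dt_s", "unit_length_bp", "rnap_speed_nt_per_s", "gamma",
    "rnap_pool", "initial_sigma", "burn_in_s", "seed", "sampling_interval_s",
    "clamp_sigma",
}
_TOP_KEYS = {"name", "genome", "params", "interventions", "meta"}


def _r12(x: float) -> float:
    """Round to 12 significant digits so uM <-> M conversions round-trip."""
    return float(f"{x:.12g}")


def scenario_to_dict(sc: Scenario) -> dict:
    spec, p = sc.spec, sc.params
    d = {
        "name": sc.name,
        "genome": {
            "length_bp": spec.length,
            "circular": spec.circular,
            "barriers_bp": list(spec.barriers),
            "topoisomerases": [
                {
                    "name": t.name,
                    "sign": t.sign,
                    "sigma0": t.sigma_0,
                    "width": t.width,
                    "k_basal_per_s": t.k_basal,
                    "concentration_uM": _r12(t.concentration * 1e6),
                    "reference_concentration_uM": _r12(t.reference_concentration * 1e6),
                }
                for t in spec.topoisomerases
            ],
            "units": [
                {
                    "id": u.id,
                    "tss_bp": u.tss,
                    "terminator_bp": u.terminator,
                    "strand": u.strand,
                    "k_on_per_s": u.k_on,
                    "active": u.active,
                    "response": _response_dict(u.response),
                }
                for u in spec.units
            ],
        },
        "params": {
            "duration_s": p.duration,
            "dt_s": p.dt,
            "unit_length_bp": p.unit_length,
            "rnap_speed_nt_per_s": p.rnap_speed,
            "gamma": p.gamma,
            "rnap_pool": p.rnap_pool,
            "initial_sigma": p.initial_sigma,
            "burn_in_s": p.burn_in,
            "seed": p.seed,
            "sampling_interval_s": p.sampling_interval,
            "clamp_sigma": p.clamp_sigma,
        },
        "interventions": [
            {
                "time_s": t,
                "target": _target_str(target),
                "value": _target_value_out(target, value),
            }
            for t, target, value in sc.interventions
        ],
        "meta": {k: v for k, v in sc.meta.items() if k != "provenance"},
    }
    return d


def _response_dict(r: PromoterResponse) -> dict:
    d = {"variant": r.variant, "sigma_t": r.sigma_t, "epsilon": r.epsilon, "m": r.m}
    if r.variant == "positive_repressed":
        d["sigma_r"] = r.sigma_r
        d["epsilon_r"] = r.epsilon_r
    return d


def _target_str(target: tuple) -> str:
    kind, name, fieldname = target
    suffix = {"concentration": "concentration_uM", "k_basal": "k_basal_per_s"}[fieldname]
    return f"{kind}:{name}:{suffix}"


def _target_value_out(target: tuple, value: float) -> float:
    return _r12(value * 1e6) if target[2] == "concentration" else value


def _parse_target(s: str) -> tuple[tuple, float]:
    parts = s.split(":")
    if len(parts) != 3 or parts[0] != "topo":
        raise ValueError(f"invalid intervention target {s!r}")
    fieldmap = {"concentration_uM": ("concentration", 1e-6), "k_basal_per_s": ("k_basal", 1.0)}
    if parts[2] not in fieldmap:
        raise ValueError(f"invalid intervention field {parts[2]!r}")
    fieldname, scale = fieldmap[parts[2]]
    return ("topo", parts[1], fieldname), scale


def _check_keys(d: dict, allowed: set, where: str) -> None:
    unknown = set(d) - allowed
    if unknown:
        raise ValueError(f"unknown key(s) {sorted(unknown)} in {where}")


def scenario_from_dict(d: dict) -> Scenario:
    _check_keys(d, _TOP_KEYS, "scenario")
    g = d.get("genome")
    if g is None:
        raise ValueError("scenario is missing the 'genome' section")
    _check_keys(g, _GENOME_KEYS, "genome")
    provenance: dict[str, str] = {}
    topos = []
    for i, td in enumerate(g.get("topoisomerases", [])):
        _check_keys(td, _TOPO_KEYS, f"topoisomerases[{i}]")
        topos.append(
            TopoisomeraseModel(
                name=td["name"],
                sign=td["sign"],
                sigma_0=td["sigma0"],
                width=td["width"],
                k_basal=td.get("k_basal_per_s", 0.001),
                concentration=td.get("concentration_uM", 0.0) * 1e-6,
                reference_concentration=td["reference_concentration_uM"] * 1e-6,
            )
        )
    units = []
    for i, ud in enumerate(g.get("units", [])):
        _check_keys(ud, _UNIT_KEYS, f"units[{i}]")
        rd = dict(ud.get("response", {}))
        _check_keys(rd, _RESPONSE_KEYS, f"units[{i}].response")
        units.append(
            TranscriptionUnit(
                id=str(ud["id"]),
                tss=ud["tss_bp"],
                terminator=ud["terminator_bp"],
                strand=ud["strand"],
                k_on=ud["k_on_per_s"],
                active=ud.get("active", True),
                response=PromoterResponse(**rd),
            )
        )
    spec = GenomeSpec(
        length=g["length_bp"],
        circular=g.get("circular", True),
        barriers=tuple(g.get("barriers_bp", [])),
        units=tuple(units),
        topoisomerases=tuple(topos),
    )
    pd_ = d.get("params", {})
    _check_keys(pd_, _PARAM_KEYS, "params")
    defaults = {
        "dt_s": 2.0, "unit_length_bp": 60, "rnap_speed_nt_per_s": 30.0,
        "gamma": 0.2, "rnap_pool": 8, "initial_sigma": 0.0, "burn_in_s": 0.0,
        "seed": 0, "sampling_interval_s": 60.0, "clamp_sigma": False,
    }
    for k in _PARAM_KEYS:
        provenance[f"params.{k}"] = "user" if k in pd_ else "default"
    if "duration_s" not in pd_:
        raise ValueError("params.duration_s is required")
    params = SimParams(
        duration=pd_["duration_s"],
        dt=pd_.get("dt_s", defaults["dt_s"]),
        unit_length=pd_.get("unit_length_bp", defaults["unit_length_bp"]),
        rnap_speed=pd_.get("rnap_speed_nt_per_s", defaults["rnap_speed_nt_per_s"]),
        gamma=pd_.get("gamma", defaults["gamma"]),
        rnap_pool=pd_.get("rnap_pool", defaults["rnap_pool"]),
        initial_sigma=pd_.get("initial_sigma", defaults["initial_sigma"]),
        burn_in=pd_.get("burn_in_s", defaults["burn_in_s"]),
        seed=pd_.get("seed", defaults["seed"]),
        sampling_interval=pd_.get("sampling_interval_s", defaults["sampling_interval_s"]),
        clamp_sigma=pd_.get("clamp_sigma", defaults["clamp_sigma"]),
    )
    interventions = []
    for iv in d.get("interventions", []):
        _check_keys(iv, {"time_s", "target", "value"}, "intervention")
        target, scale = _parse_target(iv["target"])
        interventions.append((iv["time_s"], target, iv["value"] * scale))
    # validate the lattice layout (overlaps, barrier-spanning units) at load
    spec.validate_layout(params.unit_length)
    meta = dict(d.get("meta", {}))
    meta["provenance"] = provenance
    return Scenario(
        name=d.get("name", "unnamed"),
        spec=spec,
        params=params,
        interventions=tuple(interventions),
        meta=meta,
    )


def save_scenario(sc: Scenario, path: str | Path) -> None:
    Path(path).write_text(
        yaml.safe_dump(scenario_to_dict(sc), sort_keys=False, default_flow_style=False)
    )


def load_scenario(path: str | Path) -> Scenario:
    d = yaml.safe_load(Path(path).read_text())
    if not isinstance(d, dict):
        raise ValueError(f"{path}: not a mapping")
    try:
        return scenario_from_dict(d)
    except (KeyError, TypeError) as e:
        raise ValueError(f"{path}: invalid scenario ({e})") from e


def write_trajectory(traj: Trajectory, outdir: str | Path, compress: bool = False) -> dict:
    """Write a trajectory as two TSV streams: events and sigma snapshots."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    suffix = ".tsv.gz" if compress else ".tsv"
    ev_path = outdir / f"events{suffix}"
    traj.events_frame().to_csv(ev_path, sep="\t", index=False)
    rows = []
    for t, starts, ends, sigmas in traj.snapshots:
        for s, e, sg in zip(starts, ends, sigmas):
            rows.append((t, s, e, sg))
    sn_path = outdir / f"sigma_snapshots{suffix}"
    pd.DataFrame(
        rows, columns=["time_s", "domain_start_bp", "domain_end_bp", "sigma"]
    ).to_csv(sn_path, sep="\t", index=False)
    rate_path = outdir / f"unit_rates{suffix}"
    df = pd.DataFrame({"time_s": traj.times})
    for uid, arr in traj.unit_rate.items():
        df[f"rate_{uid}_per_s"] = arr
    df["mean_sigma"] = traj.mean_sigma
    df.to_csv(rate_path, sep="\t", index=False)
    return {"events": str(ev_path), "sigma_snapshots": str(sn_path), "unit_rates": str(rate_path)}


def write_manifest(
    sc: Scenario, outputs: dict, path: str | Path, wall_time_s: float | None = None
) -> None:
    manifest = {
        "scenario": scenario_to_dict(sc),
        "code_version": __version__,
        "seed": sc.params.seed,
        "outputs": outputs,
        "wall_time_s": wall_time_s,
        "written_at": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    Path(path).write_text(yaml.safe_dump(manifest, sort_keys=False))
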