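"""Replicated headline analyses: the summary numbers the simulator reports.

Each function runs a scenario over replicate seeds and aggregates the
observables: the relaxation-shock asymmetry between divergent and convergent
probe genes, the expression-strength dependence of the mean supercoiling
level, and the anchored-plasmid accumulation/recovery kinetics.  Seeds are
derived deterministically from a single base seed.
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np

from .measure import mean_sigma, shock_foldchanges
from .scenarios import (
    PROBE_CLASSES,
    anchored_plasmid_accumulation,
    toy_genome,
)

__all__ = [
    "replicate_seeds",
    "shock_asymmetry",
    "strength_sweep",
    "accumulation_kinetics",
]


def replicate_seeds(base_seed: int, n: int) -> list[int]:
    """n distinct reproducible seeds below 2**31 derived from base_seed."""
    rng = np.random.default_rng(base_seed)
    return [int(s) for s in rng.integers(0, 2**31 - 1, size=n)]


def shock_asymmetry(
    waiting_time_min: float = 2.5,
    gyrase_conc_M: float = 0.25e-6,
    seeds: Sequence[int] = tuple(range(20)),
    shock_time: float = 3600.0,
) -> dict:
    """Gyrase-inhibition shock on the toy genome: per-orientation-class mean
    initiation-rate reduction factors and the convergent/divergent relative
    fold-change, averaged over replicate seeds."""
    div, conv, tand, rel, ms_pre = [], [], [], [], []
    for s in seeds:
        traj = toy_genome(
            waiting_time_min=waiting_time_min,
            gyrase_conc_M=gyrase_conc_M,
            shock_time=shock_time,
        ).run(seed=s)
        rep = shock_foldchanges(traj, shock_time, PROBE_CLASSES)
        div.append(rep.class_mean_factor("divergent"))
        conv.append(rep.class_mean_factor("convergent"))
        tand.append(rep.class_mean_factor("tandem"))
        rel.append(rep.relative_foldchange)
        ms_pre.append(mean_sigma(traj, (shock_time - 1800.0, shock_time))[0])
    return {
        "divergent_factor": float(np.mean(div)),
        "convergent_factor": float(np.mean(conv)),
        "tandem_factor": float(np.mean(tand)),
        "relative_foldchange": float(np.mean(rel)),
        "mean_sigma_pre": float(np.mean(ms_pre)),
        "per_seed": {
            "divergent": div, "convergent": conv, "relative": rel,
        },
        "n_seeds": len(list(seeds)),
    }


def strength_sweep(
    waiting_times_min: Sequence[float] = (1.0, 2.5, 10.0),
    gyrase_conc_M: float = 0.25e-6,
    seeds: Sequence[int] = tuple(range(20)),
) -> dict:
    """Mean stationary supercoiling level and shock response at several
    expression strengths (calibrated effective waiting times)."""
    out = {}
    for w in waiting_times_min:
        rep = shock_asymmetry(
            waiting_time_min=w, gyrase_conc_M=gyrase_conc_M, seeds=seeds
        )
        out[w] = rep
    sigmas = {w: out[w]["mean_sigma_pre"] for w in waiting_times_min}
    vals = list(sigmas.values())
    return {
        "per_strength": out,
        "mean_sigma": sigmas,
        "max_sigma_difference": float(max(vals) - min(vals)),
        "min_relative_foldchange": float(
            min(out[w]["relative_foldchange"] for w in waiting_times_min)
        ),
    }


def accumulation_kinetics(
    seeds: Sequence[int] = tuple(range(20)),
    phase1_duration: float = 6 * 3600.0,
    phase2_duration: float = 2 * 3600.0,
    init_window: float = 600.0,
    plateau_window: float = 7200.0,
    recovery_fraction: float = 0.9,
    sliding_window: float = 300.0,
) -> dict:
    """Anchored-plasmid assay: plateau repression factor of the initiation
    rate under topoisomerase I alone, and recovery time after gyrase addition.

    The initial rate is the mean instantaneous rate over the first
    ``init_window`` seconds; the plateau rate is the mean over the last
    ``plateau_window`` seconds of phase 1; the recovery time is when the
    sliding-window mean rate first reaches ``recovery_fraction`` of the
    initial rate after gyrase addition.  The single-promoter rate is bursty,
    so the factor is averaged over many replicate seeds.
    """
    factors, rec_hours, sigma_plateau = [], [], []
    for s in seeds:
        sc = anchored_plasmid_accumulation(
            phase1_duration=phase1_duration, phase2_duration=phase2_duration
        )
        traj = sc.run(seed=s)
        dt = traj.params.dt
        r = traj.unit_rate["long_gene"]
        n1 = int(round(phase1_duration / dt))
        init = r[: int(round(init_window / dt))].mean()
        plateau = r[n1 - int(round(plateau_window / dt)) : n1].mean()
        factors.append(init / plateau)
        sigma_plateau.append(traj.mean_sigma[n1 - 1])
        w = int(round(sliding_window / dt))
        cs = np.cumsum(np.r_[0.0, r])
        sliding = (cs[n1 + w :] - cs[n1:-w]) / w
        hit = np.nonzero(sliding >= recovery_fraction * init)[0]
        rec_hours.append(
            (hit[0] + w) * dt / 3600.0 if hit.size else math.inf
        )
    return {
        "repression_factor": float(np.mean(factors)),
        "recovery_time_h": float(np.mean(rec_hours)),
        "sigma_plateau": float(np.mean(sigma_plateau)),
        "per_seed": {"repression": factors, "recovery_h": rec_hours},
        "n_seeds": len(list(seeds)),
    }
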