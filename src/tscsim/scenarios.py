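"""Ready-made simulation scenarios.

Each builder returns a fully parameterized :class:`Scenario` reproducing one of
the standard model systems:

* ``plasmid_expression_vs_sigma``: a freely rotating 5-kb plasmid carrying the
  supercoiling-activated pelE promoter, simulated at a grid of fixed
  superhelical densities (no barriers, no topoisomerases, so transcription-
  generated supercoils merge instantly and sigma stays constant).
* ``anchored_plasmid_accumulation``: a surface-anchored plasmid with a 12-kb
  gene.  With topoisomerase I alone (41 nM) only the negative twin-domain is
  relaxed, so positive supercoils slowly accumulate and repress the promoter;
  adding gyrase (0.1 uM) restores initiation.
* ``divergent_cassette``: the chromosomal tetP/tufB divergent pair with 300-bp
  spaced promoters inside one topological domain, showing mutual activation.
* ``isodirectional_distance_scan``: a gyrA-type promoter (reversed response
  curve) downstream of an isodirectional gene at 0-6 kb distances, probing
  kilobase-range supercoil diffusion.
* ``toy_genome``: a 30-kb circular genome with three topological domains
  (divergent, convergent and tandem 1-kb gene pairs, each with a central
  inactive probe promoter), used for relaxation-shock and topoisomerase-
  modulation experiments.

In vivo runs use gyrase 0.25 uM and topoisomerase I 0.025 uM.  Basal initiation
rates of the toy genome are calibrated so each active gene fires one transcript
every 1, 2.5 or 10 min (effective waiting time); see ``calibrate_basal_rate``
and ``scripts/calibrate.py``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np

from .engine import SimParams, Trajectory, run
from .genome import GenomeSpec, TranscriptionUnit
from .response import PromoterResponse, TopoisomeraseModel, gyrase, topo_i

__all__ = [
    "Scenario",
    "plasmid_expression_vs_sigma",
    "anchored_plasmid_accumulation",
    "divergent_cassette",
    "isodirectional_distance_scan",
    "toy_genome",
    "toy_genome_sweep",
    "topoI_modulation_pair",
    "calibrate_basal_rate",
    "CALIBRATED_KON",
    "PROBE_CLASSES",
    "GYRASE_VIVO_M",
    "TOPOI_VIVO_M",
]

GYRASE_VIVO_M = 0.25e-6
TOPOI_VIVO_M = 0.025e-6

#: basal initiation rates (1/s) of the toy-genome promoters giving effective
#: waiting times of 1, 2.5 and 10 min between transcription events per gene at
#: physiological topoisomerase concentrations (output of scripts/calibrate.py,
#: bisection to within 10% of target; see docs/methods.md)
CALIBRATED_KON: dict[float, float] = {
    1.0: 0.0026262,
    2.5: 0.0014142,
    10.0: 0.00055885,
}

#: orientation class of each toy-genome probe promoter
PROBE_CLASSES = {
    "probe_div": "divergent",
    "probe_conv": "convergent",
    "probe_tand": "tandem",
}

#: positive-supercoiling repression curve of the anchored-plasmid assay
#: (output of scripts/calibrate.py: threshold chosen so the topoI-only plateau
#: represses initiation about 3-fold)
ACCUMULATION_SIGMA_R = 0.19
ACCUMULATION_EPSILON_R = 0.05


@dataclass(frozen=True)
class Scenario:
    """A genome, engine parameters and a schedule of interventions."""

    name: str
    spec: GenomeSpec
    params: SimParams
    interventions: tuple[tuple, ...] = ()
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        times = [iv[0] for iv in self.interventions]
        if times != sorted(times):
            raise ValueError("interventions must be sorted by time")

    def with_seed(self, seed: int) -> "Scenario":
        return replace(self, params=replace(self.params, seed=seed))

    def run(self, seed: int | None = None) -> Trajectory:
        sc = self if seed is None else self.with_seed(seed)
        return run(sc.spec, sc.params, sc.interventions)


def _pelE_plasmid_units(k_on: float = 0.0005) -> tuple:
    pelE = TranscriptionUnit(
        id="pelE", tss=600, terminator=1800, strand="+", k_on=k_on,
        response=PromoterResponse(),
    )
    ampR = TranscriptionUnit(
        id="ampR", tss=4500, terminator=3900, strand="-", k_on=k_on,
        response=PromoterResponse(), active=False,
    )
    return pelE, ampR


def plasmid_expression_vs_sigma(
    sigma_values: Sequence[float] = (
        -0.06, -0.05, -0.045, -0.04, -0.035, -0.03, -0.02, 0.0
    ),
    k_on: float = 0.0005,
    duration: float = 4 * 3600.0,
) -> list[Scenario]:
    """Freely rotating pelE plasmid at clamped supercoiling levels.

    One scenario per sigma value; with no barriers and no topoisomerases the
    plasmid-average sigma is exactly constant, so the normalized expression
    curve directly reads out the promoter response f(sigma)/f(0).
    """
    scenarios = []
    units = _pelE_plasmid_units(k_on)
    for s in sigma_values:
        spec = GenomeSpec(length=5040, units=units)
        params = SimParams(
            duration=duration, rnap_pool=10, initial_sigma=s, seed=0
        )
        scenarios.append(
            Scenario(
                name=f"plasmid_sigma_{s:+.3f}",
                spec=spec,
                params=params,
                meta={"sigma": s},
            )
        )
    return scenarios


def anchored_plasmid_accumulation(
    phase1_duration: float = 5 * 3600.0,
    phase2_duration: float = 2 * 3600.0,
    k_on: float = 0.005,
    topoI_nM: float = 41.0,
    gyrase_uM: float = 0.1,
    sigma_r: float | None = None,
    epsilon_r: float | None = None,
) -> Scenario:
    """Anchored plasmid with a 12-kb gene: positive-supercoil accumulation.

    Phase 1: topoisomerase I alone at 41 nM relaxes only the negative
    twin-domain behind the elongating RNAP, so positive supercoils build up
    over hours and repress initiation about 3-fold.  Phase 2: gyrase is added
    at 0.1 uM and the initiation rate recovers in under an hour.  The promoter
    uses the effective curve repressed at positive supercoiling.
    """
    sr = ACCUMULATION_SIGMA_R if sigma_r is None else sigma_r
    er = ACCUMULATION_EPSILON_R if epsilon_r is None else epsilon_r
    unit = TranscriptionUnit(
        id="long_gene", tss=600, terminator=12600, strand="+", k_on=k_on,
        response=PromoterResponse(
            variant="positive_repressed", sigma_r=sr, epsilon_r=er
        ),
    )
    spec = GenomeSpec(
        length=13500,
        units=(unit,),
        barriers=(0,),
        topoisomerases=(topo_i(topoI_nM * 1e-9),),
    )
    params = SimParams(
        duration=phase1_duration + phase2_duration,
        rnap_pool=4,
        initial_sigma=0.0,
        seed=0,
        sampling_interval=120.0,
    )
    interventions = (
        (phase1_duration, ("topo", "gyrase", "concentration"), gyrase_uM * 1e-6),
    )
    # gyrase present from t=0 at zero concentration so the intervention can
    # switch it on
    spec = replace(spec, topoisomerases=(topo_i(topoI_nM * 1e-9), gyrase(0.0)))
    return Scenario(
        name="anchored_plasmid_accumulation",
        spec=spec,
        params=params,
        interventions=interventions,
        meta={"phase1_duration": phase1_duration, "unit": "long_gene"},
    )


def divergent_cassette(
    tetP_kon: float = 0.005,
    tufB_kon: float = 1 / 300.0,
    duration: float = 3600.0,
    initial_sigma: float = -0.03,
    clamp_sigma: bool = False,
) -> Scenario:
    """tetP/tufB divergent pair, promoters 300 bp apart in one domain."""
    tufB = TranscriptionUnit(
        id="tufB", tss=2340, terminator=1440, strand="-", k_on=tufB_kon
    )
    tetP = TranscriptionUnit(
        id="tetP", tss=2640, terminator=3540, strand="+", k_on=tetP_kon
    )
    spec = GenomeSpec(
        length=10020,
        units=(tufB, tetP),
        barriers=(0, 5040),
        topoisomerases=(gyrase(GYRASE_VIVO_M), topo_i(TOPOI_VIVO_M)),
    )
    params = SimParams(
        duration=duration,
        rnap_pool=8,
        initial_sigma=initial_sigma,
        burn_in=1200.0,
        seed=0,
        clamp_sigma=clamp_sigma,
    )
    return Scenario(
        name="divergent_cassette",
        spec=spec,
        params=params,
        meta={"tetP_kon": tetP_kon},
    )


def isodirectional_distance_scan(
    distance_bp: int = 0,
    uidA_kon: float = 1 / 300.0,
    duration: float = 3600.0,
    initial_sigma: float = -0.03,
) -> Scenario:
    """gyrA-type promoter (reversed curve) downstream of an isodirectional
    gene at the given terminator-to-promoter distance (0-6 kb)."""
    if distance_bp % 60:
        raise ValueError("distance must be a multiple of the 60-nt lattice unit")
    uidA = TranscriptionUnit(
        id="uidA", tss=600, terminator=1560, strand="+", k_on=uidA_kon
    )
    gyrA = TranscriptionUnit(
        id="gyrA",
        tss=1620 + distance_bp,
        terminator=2580 + distance_bp,
        strand="+",
        k_on=0.001,
        response=PromoterResponse(variant="reversed"),
        active=False,
    )
    spec = GenomeSpec(
        length=15000,
        units=(uidA, gyrA),
        barriers=(0, 9000),
        topoisomerases=(gyrase(GYRASE_VIVO_M), topo_i(TOPOI_VIVO_M)),
    )
    params = SimParams(
        duration=duration,
        rnap_pool=8,
        initial_sigma=initial_sigma,
        burn_in=1200.0,
        seed=0,
    )
    return Scenario(
        name=f"isodirectional_d{distance_bp}",
        spec=spec,
        params=params,
        meta={"distance_bp": distance_bp, "uidA_kon": uidA_kon},
    )


def _toy_units(k_on: float) -> tuple[TranscriptionUnit, ...]:
    """Three-domain toy genome: all promoters share k_on and the standard
    response; probes are inactive."""
    mk = lambda id, tss, term, strand, active=True: TranscriptionUnit(
        id=id, tss=tss, terminator=term, strand=strand, k_on=k_on, active=active
    )
    return (
        # divergent domain (0 - 10,020): genes transcribe away from the probe
        mk("geneDL", 3000, 2040, "-"),
        mk("probe_div", 5040, 5100, "+", active=False),
        mk("geneDR", 7020, 7980, "+"),
        # convergent domain (10,020 - 19,980): genes transcribe toward the probe
        mk("geneCL", 12000, 12960, "+"),
        mk("probe_conv", 15000, 15060, "+", active=False),
        mk("geneCR", 17040, 16080, "-"),
        # tandem domain (19,980 - 30,000): co-directional genes
        mk("geneTL", 22020, 22980, "+"),
        mk("probe_tand", 25020, 25080, "+", active=False),
        mk("geneTR", 27000, 27960, "+"),
    )


def toy_genome(
    waiting_time_min: float = 2.5,
    gyrase_conc_M: float = GYRASE_VIVO_M,
    topoI_conc_M: float = TOPOI_VIVO_M,
    shock: bool = True,
    shock_factor: float = 5.0,
    shock_time: float = 3600.0,
    post_duration: float = 2100.0,
    k_on: float | None = None,
    topoI_kbasal_factor: float = 1.0,
    seed: int = 0,
) -> Scenario:
    """30-kb three-domain toy genome with optional gyrase-inhibition shock.

    One hour of stationary transcription at the given expression strength,
    then (if ``shock``) the gyrase concentration is divided by
    ``shock_factor``.  ``waiting_time_min`` selects a calibrated basal rate
    (one transcript per 1, 2.5 or 10 min per active gene); an explicit
    ``k_on`` overrides it.
    """
    if k_on is None:
        try:
            k_on = CALIBRATED_KON[waiting_time_min]
        except KeyError:
            raise ValueError(
                f"no calibrated basal rate for waiting time {waiting_time_min}"
                f" min; available: {sorted(CALIBRATED_KON)}"
            ) from None
    topoI_model = topo_i(topoI_conc_M).scaled(topoI_kbasal_factor)
    spec = GenomeSpec(
        length=30000,
        units=_toy_units(k_on),
        barriers=(0, 10020, 19980),
        topoisomerases=(gyrase(gyrase_conc_M), topoI_model),
    )
    duration = shock_time + post_duration
    params = SimParams(
        duration=duration,
        rnap_pool=8,
        initial_sigma=-0.03,
        burn_in=1800.0,
        seed=seed,
        sampling_interval=60.0,
    )
    interventions: tuple[tuple, ...] = ()
    if shock:
        interventions = (
            (
                shock_time,
                ("topo", "gyrase", "concentration"),
                gyrase_conc_M / shock_factor,
            ),
        )
    return Scenario(
        name=f"toy_genome_w{waiting_time_min}",
        spec=spec,
        params=params,
        interventions=interventions,
        meta={
            "waiting_time_min": waiting_time_min,
            "k_on": k_on,
            "gyrase_conc_M": gyrase_conc_M,
            "shock_time": shock_time if shock else None,
            "probe_classes": dict(PROBE_CLASSES),
        },
    )


def toy_genome_sweep(
    gyrase_concentrations_M: Sequence[float] = (0.1e-6, 0.25e-6, 0.5e-6, 1.0e-6),
    waiting_times_min: Sequence[float] = (1.0, 2.5, 10.0),
    **kwargs,
) -> list[Scenario]:
    """Grid of toy-genome scenarios over gyrase concentration and expression
    strength (waiting times 1, 2.5 and 10 min)."""
    return [
        toy_genome(waiting_time_min=w, gyrase_conc_M=g, **kwargs)
        for g in gyrase_concentrations_M
        for w in waiting_times_min
    ]


def topoI_modulation_pair(
    factor: float,
    waiting_time_min: float = 2.5,
    duration: float = 5400.0,
) -> tuple[Scenario, Scenario]:
    """(modulated, control) toy-genome pair with topoisomerase I basal
    activity scaled by ``factor`` (0.5 mimics a deficient topA allele, 2 an
    over-active one); no gyrase shock."""
    common = dict(
        waiting_time_min=waiting_time_min,
        shock=False,
        shock_time=duration - 2100.0,
        post_duration=2100.0,
    )
    mod = toy_genome(topoI_kbasal_factor=factor, **common)
    ctrl = toy_genome(topoI_kbasal_factor=1.0, **common)
    mod = replace(mod, name=f"toy_topoI_x{factor}")
    ctrl = replace(ctrl, name="toy_topoI_x1")
    return mod, ctrl


def measured_waiting_time(
    traj: Trajectory, unit_ids: Sequence[str], window: tuple[float, float]
) -> float:
    """Mean interval (s) between transcription events per promoter."""
    t0, t1 = window
    counts = []
    for uid in unit_ids:
        times = traj.init_times(uid)
        counts.append(int(np.sum((times > t0) & (times <= t1))))
    total = sum(counts)
    if total == 0:
        return math.inf
    return (t1 - t0) * len(unit_ids) / total


def calibrate_basal_rate(
    build: Callable[[float], Scenario],
    unit_ids: Sequence[str],
    target_waiting_s: float,
    window: tuple[float, float],
    seeds: Sequence[int] = (0, 1, 2),
    k_lo: float = 1e-5,
    k_hi: float = 0.2,
    rel_tol: float = 0.1,
    max_iter: int = 20,
) -> float:
    """Bisect the basal initiation rate until the measured steady-state
    interval between transcription events is within ``rel_tol`` of target.

    ``build(k_on)`` must return a Scenario whose listed units all use that
    basal rate.  Deterministic given the seed list.  Raises if the target is
    unreachable (RNAP-pool-limited) at ``k_hi``.
    """
    if target_waiting_s <= 0:
        raise ValueError("target waiting time must be > 0")

    def measure(k: float) -> float:
        vals = []
        for s in seeds:
            traj = build(k).with_seed(s).run()
            vals.append(measured_waiting_time(traj, unit_ids, window))
        return float(np.mean(vals))

    w_hi = measure(k_hi)
    if w_hi > target_waiting_s:
        raise RuntimeError(
            f"target interval {target_waiting_s}s unreachable: at k_on={k_hi}"
            f" the measured interval is still {w_hi:.1f}s (pool-limited?)"
        )
    lo, hi = k_lo, k_hi
    best = hi
    for _ in range(max_iter):
        mid = math.sqrt(lo * hi)  # bisection in log space
        w = measure(mid)
        if abs(w - target_waiting_s) / target_waiting_s <= rel_tol:
            return mid
        if w > target_waiting_s:
            lo = mid
        else:
            hi = mid
        best = mid
    return best
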