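"""Discrete-time stochastic engine for the transcription-supercoiling coupling.

One step of duration ``dt`` (default 2 s), in fixed order:

1. *Initiation*: free RNAPs are assigned stochastically to available promoters.
   A promoter's instantaneous rate is ``k_on * f(sigma_local)`` where
   ``sigma_local`` is the density of the topological domain containing the
   promoter; binding occurs with probability ``min(1, k * dt)``.  Promoters are
   visited in uniformly random order and binding stops when the free pool is
   empty.  A promoter is occluded when its site, or the adjacent downstream
   site, carries an elongating RNAP.  Binding splits the promoter's domain at
   the RNAP site; both children inherit the parent density.
2. *Elongation*: each elongating RNAP advances one lattice site (60 nt at
   30 nt/s over 2 s) unless the destination site is occupied at the start of
   the step (trailing and head-on RNAPs wait).  An RNAP reaching its terminator
   dissociates back to the free pool; its two flanking domains merge with the
   length-weighted density average.
3. *Twin-domain supercoil injection*: every RNAP that moved adds
   ``+gamma / L_ahead`` to the density ahead and ``-gamma / L_behind`` behind
   (lengths in lattice units), i.e. a constant number gamma of supercoils per
   unit length transcribed, normalised by region length.  The total content
   ``sum sigma_i * L_i`` is unchanged.
4. *Topoisomerases*: every domain's density is incremented by
   ``sum_enzymes sign * k * (c/c_ref) * t(sigma) * dt`` (explicit Euler at the
   pre-update density).

Boundary motion transfers one lattice unit of DNA between the flanking domains
at the donating domain's density, so that in the absence of topoisomerases the
length-weighted mean density of the circle is conserved to machine precision.
"""

from __future__ import annotations

import math
from bisect import bisect_left
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .genome import DEFAULT_UNIT_LENGTH, DomainPartition, GenomeSpec, discretize
from .response import promoter_rate_factor, topo_sigma_rate

__all__ = ["SimParams", "RnapState", "SimState", "Trajectory", "run", "step"]


@dataclass(frozen=True)
class SimParams:
    """Engine parameters.

    dt * rnap_speed must equal unit_length: an elongating RNAP covers exactly
    one lattice site per step.
    """

    duration: float  # s
    rnap_pool: int = 8
    dt: float = 2.0  # s
    unit_length: int = DEFAULT_UNIT_LENGTH  # bp
    rnap_speed: float = 30.0  # nt/s
    gamma: float = 0.2  # supercoils generated per unit length transcribed
    initial_sigma: float = 0.0
    burn_in: float = 0.0  # s; marks where steady-state measurement windows start
    seed: int = 0
    sampling_interval: float = 60.0  # s between full domain snapshots
    clamp_sigma: bool = False  # freeze sigma at initial_sigma (control runs)

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("duration must be > 0")
        if self.rnap_pool < 1:
            raise ValueError("rnap_pool must be >= 1")
        if self.gamma < 0:
            raise ValueError("gamma must be >= 0")
        if abs(self.dt * self.rnap_speed - self.unit_length) > 1e-9:
            raise ValueError(
                "dt * rnap_speed must equal unit_length (one site per step); "
                f"got {self.dt} * {self.rnap_speed} != {self.unit_length}"
            )

    @property
    def n_steps(self) -> int:
        return int(round(self.duration / self.dt))


@dataclass
class RnapState:
    id: str
    unit_id: str
    site: int
    direction: int
    term_site: int


@dataclass
class SimState:
    """Mutable simulation state: time, RNAP pool, partition and RNG."""

    time: float
    free_pool: int
    elongating: dict[str, RnapState]
    partition: DomainPartition
    rng: np.random.Generator
    spec: GenomeSpec
    lattice: dict
    next_rnap_serial: int = 0

    def check_accounting(self, params: SimParams) -> None:
        if self.free_pool + len(self.elongating) != params.rnap_pool:
            raise AssertionError("RNAP accounting broken")


class Trajectory:
    """Recorded output of a run.

    Attributes
    ----------
    times : (n_steps,) array of step end times (s)
    unit_rate : dict unit_id -> per-step instantaneous initiation rate
        k_on * f(sigma_local) (1/s), recorded for every unit, active or probe
    unit_sigma : dict unit_id -> per-step local sigma at the promoter
    mean_sigma : per-step length-weighted mean sigma of the circle
    events : list of (time, kind, unit_id, site) with kind in {"init", "term"}
    snapshots : list of (time, starts_bp, ends_bp, sigmas) domain tables
    topo_activity : dict enzyme -> (n_regions,) time-integrated
        |d sigma/dt| * L * dt per barrier-delimited region
    region_bounds : list of (start_bp, end_bp) of barrier-delimited regions
    """

    def __init__(self, spec: GenomeSpec, params: SimParams, lattice: dict):
        self.spec = spec
        self.params = params
        self.lattice = lattice
        n = params.n_steps
        self.times = np.arange(1, n + 1) * params.dt
        self.unit_rate = {u.id: np.empty(n) for u in spec.units}
        self.unit_sigma = {u.id: np.empty(n) for u in spec.units}
        self.mean_sigma = np.empty(n)
        self.events: list[tuple[float, str, str, int]] = []
        self.snapshots: list[tuple[float, list, list, list]] = []
        bsites = lattice["barrier_sites"]
        self._region_cuts = sorted(bsites)
        nreg = max(len(bsites), 1)
        ul = params.unit_length
        if len(self._region_cuts) >= 1:
            rc = self._region_cuts
            self.region_bounds = [
                (rc[i] * ul, rc[(i + 1) % len(rc)] * ul) for i in range(len(rc))
            ]
        else:
            self.region_bounds = [(0, spec.length)]
        self.topo_activity = {
            t.name: np.zeros(nreg) for t in spec.topoisomerases
        }
        # site-resolved integral of |d sigma/dt| * dt: the spatial profile of
        # enzyme activity (ChIP-like recruitment track along the genome)
        self.topo_site_activity = {
            t.name: np.zeros(lattice["n_sites"]) for t in spec.topoisomerases
        }

    def region_of_site(self, site: int) -> int:
        rc = self._region_cuts
        if not rc:
            return 0
        return (bisect_left(rc, site) - 1) % len(rc)

    def events_frame(self):
        import pandas as pd

        return pd.DataFrame(
            self.events, columns=["time_s", "event", "unit_id", "site"]
        )

    def init_times(self, unit_id: str) -> np.ndarray:
        return np.array(
            [t for t, kind, uid, _ in self.events if kind == "init" and uid == unit_id]
        )


def initialize(spec: GenomeSpec, params: SimParams) -> SimState:
    lattice = discretize(spec, params.unit_length)
    cut_sites = list(lattice["barrier_sites"])
    labels = [f"barrier:{s}" for s in cut_sites]
    part = DomainPartition.uniform(
        lattice["n_sites"], cut_sites, labels, params.initial_sigma
    )
    return SimState(
        time=0.0,
        free_pool=params.rnap_pool,
        elongating={},
        partition=part,
        rng=np.random.default_rng(params.seed),
        spec=spec,
        lattice=lattice,
    )


def _unit_sites(state: SimState, unit_id: str) -> dict:
    return state.lattice["units"][unit_id]


def attempt_initiations(
    state: SimState, params: SimParams, traj: Trajectory | None = None
) -> list[str]:
    """Stochastic assignment of free RNAPs to available promoters.

    Returns the ids of units that fired this step.  Probe (inactive) units
    never bind; their instantaneous rate is recorded by the run loop.
    """
    spec = state.spec
    part = state.partition
    fired: list[str] = []  # ids of freshly bound RNAPs (elongate next step)
    n_units = len(spec.units)
    if n_units == 0:
        return fired
    order = state.rng.permutation(n_units)
    cutset = set(part.cuts)
    for idx in order:
        u = spec.units[idx]
        if not u.active or u.k_on == 0.0:
            continue
        if state.free_pool == 0:
            break
        tss_site = _unit_sites(state, u.id)["tss_site"]
        occluded = (
            tss_site in cutset
            or (tss_site + u.direction) % part.n_sites in cutset
        )
        if occluded:
            continue
        sigma = part.sigma_at_site(tss_site)
        k = u.k_on * promoter_rate_factor(sigma, u.response)
        p = min(1.0, k * params.dt)
        if state.rng.random() < p:
            rid = f"r{state.next_rnap_serial}"
            state.next_rnap_serial += 1
            part.split(tss_site, f"rnap:{rid}")
            cutset.add(tss_site)
            state.elongating[rid] = RnapState(
                id=rid,
                unit_id=u.id,
                site=tss_site,
                direction=u.direction,
                term_site=_unit_sites(state, u.id)["term_site"],
            )
            state.free_pool -= 1
            fired.append(rid)
            if traj is not None:
                traj.events.append((state.time + params.dt, "init", u.id, tss_site))
    return fired


def advance_elongation(
    state: SimState,
    params: SimParams,
    traj: Trajectory | None = None,
    skip: set[str] | frozenset[str] = frozenset(),
) -> list[str]:
    """Move every elongating RNAP one site (or wait), terminate at terminators.

    Movement is decided against the start-of-step occupancy plus destinations
    already claimed this step, so a trailing RNAP waits even when its leader
    vacates the site.  Returns ids of RNAPs that moved and did not terminate.
    """
    part = state.partition
    n = part.n_sites
    start_cuts = set(part.cuts)
    claimed: set[int] = set()
    moved: list[str] = []
    ids = list(state.elongating.keys())
    if len(ids) > 1:
        ids = [ids[i] for i in state.rng.permutation(len(ids))]
    for rid in ids:
        if rid in skip:  # bound this very step; starts moving next step
            continue
        r = state.elongating[rid]
        dest = (r.site + r.direction) % n
        if dest in start_cuts or dest in claimed:
            continue  # blocked: wait this step
        j = part.cut_index(f"rnap:{rid}")
        part.move_cut(j, r.direction)
        r.site = dest
        claimed.add(dest)
        if r.site == r.term_site:
            j = part.cut_index(f"rnap:{rid}")
            part.merge_at(j)
            del state.elongating[rid]
            state.free_pool += 1
            if traj is not None:
                traj.events.append(
                    (state.time + params.dt, "term", r.unit_id, r.site)
                )
        else:
            moved.append(rid)
    return moved


def apply_twin_domain(state: SimState, moved: Sequence[str], params: SimParams) -> None:
    """Inject +-gamma supercoils around each RNAP that moved this step.

    The domain ahead gains ``gamma / L_ahead`` in density, the domain behind
    loses ``gamma / L_behind``; on a barrier-free circle with a single RNAP the
    two contributions address the same domain and cancel exactly.
    """
    part = state.partition
    gamma = params.gamma
    if gamma == 0.0:
        return
    k = len(part.cuts)
    for rid in moved:
        r = state.elongating[rid]
        j = part.cut_index(f"rnap:{rid}")
        if k <= 1:
            continue  # whole circle: +gamma/L and -gamma/L cancel
        if r.direction > 0:
            ahead, behind = j, (j - 1) % k
        else:
            ahead, behind = (j - 1) % k, j
        la = part.domain_length(ahead)
        lb = part.domain_length(behind)
        if la == 0 or lb == 0:
            raise RuntimeError("zero-length flanking domain during injection")
        part.sigma[ahead] += gamma / la
        part.sigma[behind] -= gamma / lb


def apply_topoisomerases(
    state: SimState, params: SimParams, traj: Trajectory | None = None
) -> None:
    """Explicit-Euler topoisomerase increment, evaluated at pre-update sigma."""
    part = state.partition
    topos = state.spec.topoisomerases
    if not topos:
        return
    dt = params.dt
    nd = part.n_domains
    increments = [0.0] * nd
    for i in range(nd):
        s = part.sigma[i]
        li = part.domain_length(i)
        for t in topos:
            rate = topo_sigma_rate(s, t)
            increments[i] += rate * dt
            if traj is not None and rate != 0.0:
                site_in = (part.cuts[i] + 1) % part.n_sites if part.cuts else 0
                traj.topo_activity[t.name][traj.region_of_site(site_in)] += (
                    abs(rate) * dt * li
                )
                _add_arc(
                    traj.topo_site_activity[t.name],
                    part.cuts[i] if part.cuts else 0,
                    li,
                    abs(rate) * dt,
                )
    for i in range(nd):
        part.sigma[i] += increments[i]


def _add_arc(arr: np.ndarray, cut: int, length: int, value: float) -> None:
    """Add ``value`` to the ``length`` sites of the arc starting after ``cut``."""
    n = arr.shape[0]
    a = (cut + 1) % n
    b = a + length
    if b <= n:
        arr[a:b] += value
    else:
        arr[a:] += value
        arr[: b - n] += value


def step(state: SimState, params: SimParams, traj: Trajectory | None = None) -> None:
    """Advance the state by one timestep dt."""
    bound = attempt_initiations(state, params, traj)
    moved = advance_elongation(state, params, traj, skip=frozenset(bound))
    apply_twin_domain(state, moved, params)
    apply_topoisomerases(state, params, traj)
    if params.clamp_sigma:
        part = state.partition
        part.sigma = [params.initial_sigma] * len(part.sigma)
    state.time += params.dt


def run(
    spec: GenomeSpec,
    params: SimParams,
    interventions: Sequence[tuple] = (),
    check_every: int = 0,
) -> Trajectory:
    """Execute a full simulation and return its trajectory.

    ``interventions`` is a sorted list of ``(time_s, target, value)`` applied
    when simulated time reaches ``time_s``; ``target`` is
    ``("topo", name, field)`` with field ``concentration`` or ``k_basal``.
    ``check_every`` > 0 enables periodic internal-consistency checks.
    """
    state = initialize(spec, params)
    traj = Trajectory(spec, params, state.lattice)
    pending = sorted(interventions, key=lambda iv: iv[0])
    ivi = 0
    n_steps = params.n_steps
    sample_every = max(int(round(params.sampling_interval / params.dt)), 1)
    tss_sites = {u.id: state.lattice["units"][u.id]["tss_site"] for u in spec.units}
    for istep in range(n_steps):
        while ivi < len(pending) and state.time >= pending[ivi][0] - 1e-9:
            _apply_intervention(state, pending[ivi])
            traj.spec = state.spec
            ivi += 1
        step(state, params, traj)
        part = state.partition
        for u in spec.units:
            s_loc = part.sigma_at_site(tss_sites[u.id])
            traj.unit_sigma[u.id][istep] = s_loc
            traj.unit_rate[u.id][istep] = u.k_on * promoter_rate_factor(
                s_loc, u.response
            )
        ms = part.mean_sigma()
        traj.mean_sigma[istep] = ms
        if not math.isfinite(ms):
            raise RuntimeError(
                f"non-finite sigma at t={state.time}s; domains: "
                f"{list(zip(part.cuts, part.sigma))}"
            )
        if (istep + 1) % sample_every == 0:
            ul = params.unit_length
            k = len(part.cuts)
            if k:
                starts = [part.cuts[i] * ul for i in range(k)]
                ends = [part.cuts[(i + 1) % k] * ul for i in range(k)]
            else:
                starts, ends = [0], [spec.length]
            traj.snapshots.append(
                (state.time, starts, ends, list(part.sigma))
            )
        if check_every and (istep + 1) % check_every == 0:
            part.check()
            state.check_accounting(params)
    traj.final_state = state
    return traj


def _apply_intervention(state: SimState, iv: tuple) -> None:
    _, target, value = iv
    kind = target[0]
    if kind != "topo":
        raise ValueError(f"unknown intervention target {target!r}")
    _, name, fieldname = target
    found = False
    new_topos = []
    for t in state.spec.topoisomerases:
        if t.name == name:
            found = True
            t = replace(t, **{fieldname: value})
        new_topos.append(t)
    if not found:
        raise ValueError(f"no topoisomerase named {name!r} in genome spec")
    state.spec = replace(state.spec, topoisomerases=tuple(new_topos))
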