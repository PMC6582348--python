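"""Estimators turning simulation trajectories into reported observables.

All estimators are deterministic functions of a trajectory; replicate-to-
replicate variance comes only from the simulation seeds.  Rates are reported
in events per minute.  For active genes the initiation rate is the event count
divided by the window length; for inactive probe promoters it is the time
average of the recorded instantaneous rate ``k_on * f(sigma_local)``, which
reads out purely contextual (supercoiling-mediated) regulation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .engine import Trajectory

__all__ = [
    "RateEstimate",
    "ShockReport",
    "initiation_rate",
    "shock_foldchanges",
    "aggregate_shock_reports",
    "mean_sigma",
    "topo_recruitment",
    "bootstrap_ci",
]


@dataclass(frozen=True)
class RateEstimate:
    unit_id: str
    window: tuple[float, float]
    events: int | None  # None for probe promoters (rate from recorded k)
    rate_per_min: float
    ci_low: float
    ci_high: float


@dataclass(frozen=True)
class ShockReport:
    """Pre/post-shock initiation rates and reduction factors.

    ``reduction_factor[u] = pre_rate[u] / post_rate[u]`` (> 1 when the shock
    represses); ``relative_foldchange`` is the convergent-to-divergent ratio
    of (post/pre) fold-changes, > 1 when relaxation favours convergent genes.
    """

    pre_rate: dict[str, float]
    post_rate: dict[str, float]
    reduction_factor: dict[str, float]
    class_of: dict[str, str]
    pre_window: tuple[float, float]
    post_window: tuple[float, float]

    def class_mean_factor(self, cls: str) -> float:
        vals = [f for u, f in self.reduction_factor.items() if self.class_of.get(u) == cls]
        if not vals:
            raise ValueError(f"no unit in orientation class {cls!r}")
        return float(np.mean(vals))

    @property
    def relative_foldchange(self) -> float:
        conv = 1.0 / self.class_mean_factor("convergent")
        div = 1.0 / self.class_mean_factor("divergent")
        return conv / div


def _window_steps(traj: Trajectory, window: tuple[float, float]) -> np.ndarray:
    t0, t1 = window
    if t1 <= t0:
        raise ValueError(f"empty window {window}")
    if t0 < 0 or t1 > traj.times[-1] + 1e-9:
        raise ValueError(f"window {window} outside recorded span")
    return (traj.times > t0) & (traj.times <= t1)


def initiation_rate(
    traj: Trajectory, unit_id: str, window: tuple[float, float]
) -> RateEstimate:
    """Initiation-rate estimate of a unit over a time window.

    Active units: event count / window length, with an exact Poisson 95% CI.
    Probe units: time average of the recorded instantaneous rate, with a CI
    from the standard error of the per-step rate series.
    """
    unit = next(u for u in traj.spec.units if u.id == unit_id)
    t0, t1 = window
    minutes = (t1 - t0) / 60.0
    if unit.active:
        times = traj.init_times(unit_id)
        n = int(np.sum((times > t0) & (times <= t1))) if times.size else 0
        rate = n / minutes
        lo = stats.chi2.ppf(0.025, 2 * n) / 2 / minutes if n > 0 else 0.0
        hi = stats.chi2.ppf(0.975, 2 * (n + 1)) / 2 / minutes
        return RateEstimate(unit_id, window, n, rate, lo, hi)
    mask = _window_steps(traj, window)
    series = traj.unit_rate[unit_id][mask] * 60.0  # per min
    rate = float(series.mean())
    se = float(series.std(ddof=1) / math.sqrt(len(series))) if len(series) > 1 else 0.0
    return RateEstimate(unit_id, window, None, rate, rate - 1.96 * se, rate + 1.96 * se)


def shock_foldchanges(
    traj: Trajectory,
    shock_time: float,
    class_of: dict[str, str],
    pre_window: tuple[float, float] | None = None,
    post_window: tuple[float, float] | None = None,
    settle: float = 300.0,
    window_length: float = 1800.0,
) -> ShockReport:
    """Compare initiation rates before and after a parameter shock.

    Default windows: ``window_length`` seconds ending at the shock, and the
    same length starting ``settle`` seconds after it (a settling gap lets the
    supercoiling field re-equilibrate before measuring).
    """
    if pre_window is None:
        pre_window = (shock_time - window_length, shock_time)
    if post_window is None:
        post_window = (shock_time + settle, shock_time + settle + window_length)
    if pre_window[1] > shock_time or post_window[0] < shock_time:
        raise ValueError("windows must lie on opposite sides of the shock")
    pre, post, factor = {}, {}, {}
    for uid in class_of:
        r0 = initiation_rate(traj, uid, pre_window).rate_per_min
        r1 = initiation_rate(traj, uid, post_window).rate_per_min
        pre[uid], post[uid] = r0, r1
        factor[uid] = r0 / r1 if r1 > 0 else math.inf
    return ShockReport(pre, post, factor, dict(class_of), pre_window, post_window)


def aggregate_shock_reports(
    reports: list[ShockReport], cls: str
) -> tuple[float, tuple[float, float]]:
    """Mean reduction factor of a class over replicate reports, with a 95%
    bootstrap CI over replicates."""
    vals = np.array([r.class_mean_factor(cls) for r in reports])
    return float(vals.mean()), bootstrap_ci(vals)


def bootstrap_ci(
    values: np.ndarray, n_boot: int = 2000, seed: int = 12345
) -> tuple[float, float]:
    """Percentile 95% bootstrap CI of the mean."""
    values = np.asarray(values, dtype=float)
    if values.size == 1:
        return float(values[0]), float(values[0])
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, values.size, size=(n_boot, values.size))
    means = values[idx].mean(axis=1)
    return float(np.quantile(means, 0.025)), float(np.quantile(means, 0.975))


def mean_sigma(
    traj: Trajectory, window: tuple[float, float]
) -> tuple[float, dict[tuple[int, int], float]]:
    """Length-weighted time-averaged superhelical density over a window.

    Returns the genome-wide mean and a per-region breakdown (keyed by the
    barrier-delimited region bounds in bp), the latter computed from the
    recorded domain snapshots.
    """
    mask = _window_steps(traj, window)
    overall = float(traj.mean_sigma[mask].mean())
    per_region: dict[tuple[int, int], list[float]] = {
        tuple(b): [] for b in traj.region_bounds
    }
    t0, t1 = window
    ul = traj.params.unit_length
    for t, starts, ends, sigmas in traj.snapshots:
        if not (t0 < t <= t1):
            continue
        acc = {k: [0.0, 0] for k in per_region}
        for s_bp, e_bp, sg in zip(starts, ends, sigmas):
            length = (e_bp - s_bp) % traj.spec.length or traj.spec.length
            reg = traj.region_bounds[traj.region_of_site((s_bp // ul + 1) % traj.lattice["n_sites"])]
            a = acc[tuple(reg)]
            a[0] += sg * length
            a[1] += length
        for k, (w, L) in acc.items():
            if L:
                per_region[k].append(w / L)
    return overall, {k: float(np.mean(v)) if v else math.nan for k, v in per_region.items()}


def topo_recruitment(
    traj: Trajectory,
    intervals: dict[str, tuple[int, int]] | None = None,
    normalize: bool = True,
) -> dict[str, np.ndarray | dict[str, float]]:
    """Time-integrated topoisomerase activity along the genome.

    The engine accumulates, per lattice site, the integral of
    ``|d sigma/dt| * dt`` of each enzyme over the run -- a ChIP-like
    recruitment track.  Without ``intervals`` the full per-site profile is
    returned (optionally normalized to mean 1); with ``intervals`` (bp spans,
    e.g. the intergenic regions between convergent or divergent gene pairs)
    the per-bp average activity of each interval is returned, normalized to
    the genome-wide mean so values > 1 read as enrichment.
    """
    ul = traj.params.unit_length
    n = next(iter(traj.topo_site_activity.values())).shape[0] if traj.topo_site_activity else 0
    out: dict = {}
    for name, prof in traj.topo_site_activity.items():
        baseline = prof.mean() if prof.mean() > 0 else 1.0
        if intervals is None:
            out[name] = prof / baseline if normalize else prof.copy()
            continue
        vals = {}
        for label, (a_bp, b_bp) in intervals.items():
            a, b = a_bp // ul, b_bp // ul
            sites = (
                np.arange(a, b) % n
                if b > a
                else np.r_[np.arange(a, n), np.arange(0, b)]
            )
            v = float(prof[sites].mean())
            vals[label] = v / baseline if normalize else v
        out[name] = vals
    return out
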