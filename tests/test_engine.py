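"""Stochastic stepping engine: conservation laws, kinetics and reproducibility."""

import math

import numpy as np
import pytest

from tscsim.engine import (
    SimParams,
    Trajectory,
    advance_elongation,
    apply_twin_domain,
    attempt_initiations,
    initialize,
    run,
    step,
)
from tscsim.genome import GenomeSpec, TranscriptionUnit
from tscsim.response import PromoterResponse, gyrase, promoter_rate_factor, topo_i


def tu(id="g", tss=600, term=1800, strand="+", k_on=0.005, **kw):
    return TranscriptionUnit(id=id, tss=tss, terminator=term, strand=strand, k_on=k_on, **kw)


def random_genome(rng):
    """A random circular genome with 1-3 barriers and 2-4 non-overlapping genes."""
    n_genes = rng.integers(2, 5)
    length = 3000 * n_genes + 6000
    genes, pos = [], 1200
    for i in range(n_genes):
        strand = "+" if rng.random() < 0.5 else "-"
        a, b = pos, pos + 1200
        genes.append(
            tu(
                id=f"g{i}",
                tss=a if strand == "+" else b,
                term=b if strand == "+" else a,
                strand=strand,
                k_on=float(rng.uniform(0.002, 0.02)),
            )
        )
        pos += 3000
    return GenomeSpec(length=length, units=tuple(genes), barriers=(0,))


def test_linking_number_conserved_without_topoisomerases():
    """Length-weighted mean sigma is a constant of motion when only
    transcription acts on the supercoiling field."""
    for seed in range(3):
        rng = np.random.default_rng(100 + seed)
        spec = random_genome(rng)
        params = SimParams(duration=4000.0, rnap_pool=6, initial_sigma=-0.04, seed=seed)
        traj = run(spec, params, check_every=200)
        dev = np.abs(traj.mean_sigma - (-0.04)).max()
        assert dev < 1e-12
        assert sum(1 for e in traj.events if e[1] == "init") > 10


def test_rnap_pool_accounting():
    spec = random_genome(np.random.default_rng(7))
    params = SimParams(duration=2000.0, rnap_pool=3, seed=1)
    state = initialize(spec, params)
    for _ in range(1000):
        step(state, params)
        state.check_accounting(params)
        assert 0 <= state.free_pool <= 3


def test_initiation_matches_binomial_oracle():
    """An isolated promoter at clamped sigma fires as Bernoulli(k_on f dt)."""
    sigma = -0.045
    spec = GenomeSpec(length=6000, units=(tu(k_on=0.002),))
    params = SimParams(
        duration=20000.0, rnap_pool=10, initial_sigma=sigma, seed=42, clamp_sigma=True
    )
    traj = run(spec, params)
    n = len(traj.init_times("g"))
    p = 0.002 * promoter_rate_factor(sigma, PromoterResponse()) * params.dt
    n_steps = params.n_steps
    mean, sd = n_steps * p, math.sqrt(n_steps * p * (1 - p))
    # occlusion by the just-launched RNAP slightly lowers the count; allow
    # the dead-time correction band plus 4 binomial standard deviations
    assert mean * (1 - 3.5 * p) - 4 * sd < n < mean + 4 * sd


def test_trailing_rnap_waits_for_leader():
    from tscsim.engine import RnapState

    spec = GenomeSpec(length=6000, units=(tu(tss=600, term=3000, k_on=0.0),))
    params = SimParams(duration=200.0, rnap_pool=2, seed=0)
    state = initialize(spec, params)
    # place two co-directional RNAPs on adjacent sites by hand
    for rid, site in (("r0", 21), ("r1", 20)):
        state.partition.split(site, f"rnap:{rid}")
        state.elongating[rid] = RnapState(rid, "g", site, +1, 50)
        state.free_pool -= 1
    moved = advance_elongation(state, params)
    # leader moved; trailer stays blocked against the leader's
    # start-of-step position even though that site was vacated
    assert state.elongating["r0"].site == 22
    assert state.elongating["r1"].site == 20
    assert sorted(moved) == ["r0"]


def test_termination_returns_rnap_and_merges_domains():
    spec = GenomeSpec(length=6000, units=(tu(tss=600, term=1200, k_on=1.0),), barriers=(0,))
    params = SimParams(duration=200.0, rnap_pool=1, seed=0)
    state = initialize(spec, params)
    attempt_initiations(state, params)
    assert state.free_pool == 0 and state.partition.n_domains == 2
    for _ in range(10):
        advance_elongation(state, params)
    assert state.free_pool == 1
    assert state.partition.n_domains == 1


def test_twelve_kb_gene_residence_time():
    """At 30 nt/s a 12-kb transcript takes 400 s (200 steps) to complete."""
    spec = GenomeSpec(length=13500, units=(tu(tss=600, term=12600, k_on=0.5),), barriers=(0,))
    params = SimParams(duration=1200.0, rnap_pool=1, seed=3)
    traj = run(spec, params)
    t_init = [t for t, k, u, _ in traj.events if k == "init"][0]
    t_term = [t for t, k, u, _ in traj.events if k == "term"][0]
    assert t_term - t_init == pytest.approx(400.0)


def test_twin_domain_injection_magnitude():
    """A moved RNAP shifts sigma by +gamma/L ahead and -gamma/L behind."""
    spec = GenomeSpec(length=6000, units=(tu(tss=600, term=3000, k_on=1.0),), barriers=(0,))
    params = SimParams(duration=100.0, rnap_pool=1, seed=0, gamma=0.2)
    state = initialize(spec, params)
    attempt_initiations(state, params)
    moved = advance_elongation(state, params)
    p = state.partition
    j = p.cut_index("rnap:r0")
    la, lb = p.domain_length(j), p.domain_length((j - 1) % 2)
    apply_twin_domain(state, moved, params)
    assert p.sigma[j] == pytest.approx(0.2 / la)
    assert p.sigma[(j - 1) % 2] == pytest.approx(-0.2 / lb)
    # weighted content is unchanged by the injection
    assert p.weighted_content() == pytest.approx(0.0, abs=1e-12)


def test_lone_rnap_on_barrier_free_circle_conserves_sigma_exactly():
    spec = GenomeSpec(length=6000, units=(tu(k_on=0.05),))
    params = SimParams(duration=4000.0, rnap_pool=1, initial_sigma=-0.03, seed=5)
    traj = run(spec, params)
    assert np.all(traj.mean_sigma == -0.03)


def test_seeded_runs_are_bit_reproducible():
    spec = random_genome(np.random.default_rng(11))
    spec = GenomeSpec(
        length=spec.length,
        units=spec.units,
        barriers=spec.barriers,
        topoisomerases=(gyrase(0.25e-6), topo_i(0.025e-6)),
    )
    params = SimParams(duration=1500.0, rnap_pool=4, initial_sigma=-0.03, seed=9)
    t1, t2 = run(spec, params), run(spec, params)
    assert t1.events == t2.events
    assert np.array_equal(t1.mean_sigma, t2.mean_sigma)
    t3 = run(spec, SimParams(duration=1500.0, rnap_pool=4, initial_sigma=-0.03, seed=10))
    assert t1.events != t3.events


@pytest.mark.parametrize(
    "strands, comparator",
    [(("-", "+"), np.less), (("+", "-"), np.greater)],
    ids=["divergent-pair", "convergent-pair"],
)
def test_inter_promoter_sigma_sign(strands, comparator):
    """Steady transcription drives the region between a divergent pair more
    negative than the initial level, and between a convergent pair more
    positive (no topoisomerases, so the deviation is purely transcriptional)."""
    s1, s2 = strands
    if s1 == "-":  # divergent: genes transcribe away from the central region
        g1 = tu(id="a", tss=2400, term=1200, strand="-", k_on=0.01)
        g2 = tu(id="b", tss=4800, term=6000, strand="+", k_on=0.01)
    else:  # convergent: genes transcribe toward the central region
        g1 = tu(id="a", tss=1200, term=2400, strand="+", k_on=0.01)
        g2 = tu(id="b", tss=6000, term=4800, strand="-", k_on=0.01)
    probe = tu(id="mid", tss=3600, term=3660, k_on=0.001, active=False)
    spec = GenomeSpec(length=9000, units=(g1, probe, g2), barriers=(0,))
    signs = []
    for seed in range(5):
        params = SimParams(duration=3000.0, rnap_pool=4, initial_sigma=-0.03, seed=seed)
        traj = run(spec, params)
        signs.append(comparator(traj.unit_sigma["mid"].mean(), -0.03))
    assert sum(signs) >= 4


def test_intervention_rescales_topoisomerase():
    spec = GenomeSpec(length=6000, topoisomerases=(gyrase(0.25e-6),))
    params = SimParams(duration=400.0, rnap_pool=1, initial_sigma=0.0, seed=0)
    traj = run(spec, params, interventions=[(200.0, ("topo", "gyrase", "concentration"), 0.05e-6)])
    drift_before = traj.mean_sigma[99] - traj.mean_sigma[0]
    drift_after = traj.mean_sigma[199] - traj.mean_sigma[100]
    assert drift_before < 0  # gyrase supercoils the domain
    assert abs(drift_after) < abs(drift_before)  # five-fold weaker after shock
    with pytest.raises(ValueError, match="no topoisomerase"):
        run(spec, params, interventions=[(0.0, ("topo", "topoIV", "concentration"), 1e-9)])


def test_step_without_events_only_topo_drift():
    spec = GenomeSpec(length=6000, topoisomerases=(topo_i(41e-9),))
    params = SimParams(duration=10.0, rnap_pool=1, initial_sigma=-0.1, seed=0)
    state = initialize(spec, params)
    step(state, params)
    # deep-negative plateau: topoI relaxes at ~k_basal
    assert state.partition.sigma[0] == pytest.approx(-0.1 + 0.001 * 2, rel=0.02)
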