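import pytest

from tscsim.reports import accumulation_kinetics, strength_sweep


@pytest.fixture(scope="session")
def sweep_report():
    """Shock-response grid over the three calibrated expression strengths,
    20 replicate seeds each (shared by several analyses)."""
    return strength_sweep(seeds=tuple(range(20)))


@pytest.fixture(scope="session")
def shock_report(sweep_report):
    """Moderate-expression (2.5-min waiting time) shock report."""
    return sweep_report["per_strength"][2.5]


@pytest.fixture(scope="session")
def accumulation_report():
    """Anchored-plasmid topoI-accumulation / gyrase-recovery kinetics."""
    return accumulation_kinetics(seeds=tuple(range(20)))
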