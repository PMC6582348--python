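"""Scenario builders, configuration round-trips and the command line."""

from pathlib import Path

import numpy as np
import pytest
import yaml
from click.testing import CliRunner

from tscsim import scenarios as S
from tscsim.cli import main as cli_main
from tscsim.io import load_scenario, save_scenario, scenario_to_dict
from tscsim.orientation import read_de_table, read_gff3_genes, classify_orientation
from tscsim.response import promoter_rate_factor, PromoterResponse
from tscsim.scenarios import calibrate_basal_rate, measured_waiting_time, toy_genome

SCENARIO_DIR = Path(__file__).resolve().parents[1] / "src/tscsim/scenario_files"


def test_builders_are_pure():
    for build in (
        lambda: S.toy_genome(),
        lambda: S.anchored_plasmid_accumulation(),
        lambda: S.divergent_cassette(),
        lambda: S.isodirectional_distance_scan(),
    ):
        assert scenario_to_dict(build()) == scenario_to_dict(build())


@pytest.mark.parametrize("fname", [p.name for p in sorted(SCENARIO_DIR.glob("*.yaml"))])
def test_shipped_scenarios_validate_and_roundtrip(fname, tmp_path):
    path = SCENARIO_DIR / fname
    sc = load_scenario(path)
    save_scenario(sc, tmp_path / "rt.yaml")
    assert (tmp_path / "rt.yaml").read_text() == path.read_text()


def test_printed_calibration_values_in_toy_scenario_file():
    """The in vivo and calibrated settings appear verbatim in the config."""
    txt = (SCENARIO_DIR / "toy_genome.yaml").read_text()
    d = yaml.safe_load(txt)
    topos = {t["name"]: t for t in d["genome"]["topoisomerases"]}
    assert topos["gyrase"]["concentration_uM"] == 0.25
    assert topos["topoI"]["concentration_uM"] == 0.025
    assert topos["gyrase"]["sigma0"] == 0.01 and topos["gyrase"]["width"] == 0.025
    assert topos["topoI"]["sigma0"] == -0.04 and topos["topoI"]["width"] == 0.012
    assert topos["gyrase"]["k_basal_per_s"] == 0.001
    resp = d["genome"]["units"][0]["response"]
    assert (resp["sigma_t"], resp["epsilon"], resp["m"]) == (-0.042, 0.005, 2.5)
    assert d["params"]["dt_s"] == 2 and d["params"]["unit_length_bp"] == 60
    assert d["params"]["rnap_speed_nt_per_s"] == 30 and d["params"]["gamma"] == 0.2
    assert d["genome"]["length_bp"] == 30000


def test_unknown_key_rejected(tmp_path):
    d = yaml.safe_load((SCENARIO_DIR / "toy_genome.yaml").read_text())
    d["params"]["warp_factor"] = 9
    p = tmp_path / "bad.yaml"
    p.write_text(yaml.safe_dump(d))
    with pytest.raises(ValueError, match="warp_factor"):
        load_scenario(p)


def test_unit_spanning_barrier_rejected_at_load(tmp_path):
    d = yaml.safe_load((SCENARIO_DIR / "toy_genome.yaml").read_text())
    d["genome"]["units"][0]["tss_bp"] = 9000  # now spans the barrier at 10020
    d["genome"]["units"][0]["terminator_bp"] = 11040
    d["genome"]["units"][0]["strand"] = "+"
    p = tmp_path / "bad.yaml"
    p.write_text(yaml.safe_dump(d))
    with pytest.raises(ValueError, match="barrier"):
        load_scenario(p)


def test_intervention_units_roundtrip():
    sc = S.toy_genome()
    d = scenario_to_dict(sc)
    iv = d["interventions"][0]
    assert iv["target"] == "topo:gyrase:concentration_uM"
    assert iv["value"] == pytest.approx(0.05)  # 0.25 uM / 5


def test_clamped_sigma_calibration_closed_form():
    """With sigma clamped, the measured transcription interval of a lone gene
    matches 1 / (k_on f(sigma)) -- here tuned for one event per 2.5 min."""
    sigma = -0.03
    f = promoter_rate_factor(sigma, PromoterResponse())
    k_on = 1.0 / (150.0 * f)
    sc = S.divergent_cassette(
        tetP_kon=0.0, tufB_kon=k_on, duration=20000.0,
        initial_sigma=sigma, clamp_sigma=True,
    )
    intervals = [
        measured_waiting_time(sc.with_seed(s).run(), ["tufB"], (0.0, 20000.0))
        for s in range(4)
    ]
    assert np.mean(intervals) == pytest.approx(150.0, rel=0.1)


def test_calibration_bisection_hits_target_and_is_monotone():
    active = ["geneDL", "geneDR", "geneCL", "geneCR", "geneTL", "geneTR"]

    def build(k):
        return toy_genome(k_on=k, shock=False, shock_time=3600.0, post_duration=1800.0)

    k_fast = calibrate_basal_rate(build, active, 150.0, (1800.0, 5400.0), seeds=(0,), max_iter=10)
    k_slow = calibrate_basal_rate(build, active, 600.0, (1800.0, 5400.0), seeds=(0,), max_iter=10)
    assert k_slow < k_fast
    w = measured_waiting_time(build(k_fast).with_seed(5).run(), active, (1800.0, 5400.0))
    assert w == pytest.approx(150.0, rel=0.25)  # one check seed, sampling noise


def test_unreachable_calibration_target_raises():
    def build(k):
        return toy_genome(k_on=k, shock=False, shock_time=3600.0, post_duration=1800.0)

    with pytest.raises(RuntimeError, match="unreachable"):
        calibrate_basal_rate(
            build, ["geneDL"], 1.0, (1800.0, 5400.0), seeds=(0,), k_hi=0.05
        )


class TestCli:
    def test_run_reproducible_and_manifested(self, tmp_path):
        runner = CliRunner()
        args = [
            "run", "--scenario", str(SCENARIO_DIR / "divergent_cassette.yaml"),
            "--seed", "3", "--out",
        ]
        r1 = runner.invoke(cli_main, args + [str(tmp_path / "a")])
        r2 = runner.invoke(cli_main, args + [str(tmp_path / "b")])
        assert r1.exit_code == 0, r1.output
        assert (tmp_path / "a/seed_3/events.tsv").read_text() == (
            tmp_path / "b/seed_3/events.tsv"
        ).read_text()
        manifest = yaml.safe_load((tmp_path / "a/seed_3/manifest.yaml").read_text())
        assert manifest["seed"] == 3
        assert manifest["scenario"]["genome"]["length_bp"] == 10020

    def test_fixture_and_orientation_analysis_pipeline(self, tmp_path):
        runner = CliRunner()
        fx = tmp_path / "fx"
        r = runner.invoke(
            cli_main,
            ["fixtures", "--n-genes", "300", "--seed", "2", "--out", str(fx)],
        )
        assert r.exit_code == 0, r.output
        genes = read_gff3_genes(fx / "genes.gff3")
        assert len(genes) == 300
        classes = classify_orientation(genes)
        assert {"convergent", "divergent", "tandem"} <= set(classes.values())
        r = runner.invoke(
            cli_main,
            [
                "analyze-orientation", "--gff", str(fx / "genes.gff3"),
                "--de", str(fx / "de_table.tsv"), "--out", str(tmp_path / "res"),
            ],
        )
        assert r.exit_code == 0, r.output
        assert "chi2" in r.output
        assert (tmp_path / "res/contingency.tsv").exists()

    def test_missing_de_column_is_schema_error(self, tmp_path):
        bad = tmp_path / "de.tsv"
        bad.write_text("gene_id\tlfc\ng1\t2.0\n")
        with pytest.raises(ValueError, match="missing column"):
            read_de_table(bad)

    def test_unknown_scenario_name_fails_cleanly(self, tmp_path):
        runner = CliRunner()
        r = runner.invoke(
            cli_main, ["run", "--scenario", "nope", "--out", str(tmp_path)]
        )
        assert r.exit_code != 0
        assert "unknown scenario" in r.output
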