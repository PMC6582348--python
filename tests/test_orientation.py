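"""Gene-orientation classification and the convergent/divergent response test."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from tscsim.orientation import (
    GeneRecord,
    call_de,
    classify_orientation,
    orientation_response_test,
    simulate_to_de_bridge,
    synthesize_de_fixture,
)


def circle(strands, gene_length=900, gap=100):
    return [
        GeneRecord(f"g{i}", i * (gene_length + gap), i * (gene_length + gap) + gene_length, s)
        for i, s in enumerate(strands)
    ]


class TestClassification:
    def test_head_to_head_boundary_is_convergent(self):
        cls = classify_orientation(circle(["+", "+", "-", "-"]))
        assert cls["g1"] == "convergent" and cls["g2"] == "convergent"

    def test_tail_to_tail_boundary_is_divergent(self):
        cls = classify_orientation(circle(["-", "-", "+", "+"]))
        assert cls["g1"] == "divergent" and cls["g2"] == "divergent"

    def test_interior_of_run_is_tandem(self):
        cls = classify_orientation(circle(["+", "+", "+", "-", "-", "-"]))
        assert cls["g1"] == "tandem" and cls["g4"] == "tandem"

    def test_alternating_circle_all_ambiguous(self):
        cls = classify_orientation(circle(["+", "-", "+", "-", "+", "-"]))
        assert set(cls.values()) == {"ambiguous"}

    def test_rotation_invariance(self):
        strands = ["+", "+", "-", "-", "+", "-", "-", "+"]
        base = classify_orientation(circle(strands))
        for shift in range(1, len(strands)):
            rotated = strands[shift:] + strands[:shift]
            rot = classify_orientation(circle(rotated))
            for i in range(len(strands)):
                assert rot[f"g{(i - shift) % len(strands)}"] == base[f"g{i}"]

    def test_strand_flip_swaps_convergent_and_divergent(self):
        strands = ["+", "+", "-", "-", "+", "+", "+", "-"]
        base = classify_orientation(circle(strands))
        flip = {"+": "-", "-": "+"}
        flipped = classify_orientation(circle([flip[s] for s in strands]))
        swap = {"convergent": "divergent", "divergent": "convergent"}
        for g, c in base.items():
            assert flipped[g] == swap.get(c, c)

    def test_overlapping_genes_warn(self):
        genes = [
            GeneRecord("a", 0, 1000, "+"),
            GeneRecord("b", 900, 1900, "+"),
            GeneRecord("c", 2000, 2900, "-"),
        ]
        with pytest.warns(UserWarning, match="overlapping"):
            classify_orientation(genes)


def _manual_chi2(table):
    """Pearson chi-square from first principles: sum (O-E)^2 / E."""
    table = np.asarray(table, dtype=float)
    rows, cols, n = table.sum(1), table.sum(0), table.sum()
    expected = np.outer(rows, cols) / n
    chi2 = ((table - expected) ** 2 / expected).sum()
    return chi2, stats.chi2.sf(chi2, 1)


def _de_table_for(table):
    """A DE table + classes realizing a given convergent/divergent 2x2 table."""
    rows, classes = [], {}
    i = 0
    for cls, (na, nr) in zip(("convergent", "divergent"), table):
        for k in range(na + nr):
            gid = f"g{i}"
            classes[gid] = cls
            rows.append((gid, 1.0 if k < na else -1.0, 1e-9, 1e-9))
            i += 1
    df = pd.DataFrame(rows, columns=["gene_id", "log2FC", "pvalue", "padj"]).set_index("gene_id")
    return classes, df


@pytest.mark.parametrize(
    "table",
    [
        [[30, 30], [30, 30]],
        [[40, 20], [20, 40]],
        [[5, 1], [2, 7]],
        [[12, 3], [9, 11]],
    ],
)
def test_chi2_matches_textbook_formula(table):
    classes, df = _de_table_for(table)
    res = orientation_response_test(classes, df)
    chi2, p = _manual_chi2(table)
    assert res.chi2 == pytest.approx(chi2, rel=1e-12)
    assert res.pvalue == pytest.approx(p, rel=1e-9)
    assert res.n_responding == int(np.sum(table))


def test_no_association_table_gives_p_one():
    classes, df = _de_table_for([[30, 30], [30, 30]])
    res = orientation_response_test(classes, df)
    assert res.chi2 == 0.0 and res.pvalue == 1.0


def test_chi2_equals_bruteforce_on_small_table_grid():
    """Exhaustive agreement with the expected-counts oracle on small tables."""
    for a in range(0, 7):
        for b in range(0, 7):
            for c in range(0, 7):
                for d in range(0, 7):
                    t = np.array([[a, b], [c, d]])
                    if (t.sum(1) == 0).any() or (t.sum(0) == 0).any():
                        continue
                    chi2_ours = stats.chi2_contingency(t, correction=False)[0]
                    chi2_manual, _ = _manual_chi2(t)
                    assert chi2_ours == pytest.approx(chi2_manual, abs=1e-10)


def test_empty_class_is_reported_by_name():
    classes, df = _de_table_for([[5, 5], [0, 0]])
    with pytest.raises(ValueError, match="divergent"):
        orientation_response_test(classes, df)


class TestDECalls:
    def test_thresholding_rules(self):
        df = pd.DataFrame(
            {
                "log2FC": [2.0, -1.5, 0.5, 0.0],
                "pvalue": [1e-6, 1e-6, 0.2, 1e-6],
                "padj": [1e-4, 1e-4, 0.6, 1e-4],
            },
            index=["up", "down", "ns", "flat"],
        )
        call = call_de(df, padj_threshold=0.05)
        assert call["up"] == "activated"
        assert call["down"] == "repressed"
        assert call["ns"] == "not-significant"
        assert call["flat"] == "not-significant"  # zero fold-change dropped
        loose = call_de(df, padj_threshold=None, pvalue_threshold=0.25)
        assert loose["ns"] == "activated"


class TestFixture:
    def test_requested_class_counts_realized(self):
        genes, _ = synthesize_de_fixture(
            400,
            class_proportions={"convergent": 0.25, "divergent": 0.25, "tandem": 0.5},
            seed=3,
        )
        from collections import Counter

        counts = Counter(classify_orientation(genes).values())
        assert abs(counts["convergent"] - 100) <= 1
        assert abs(counts["divergent"] - 100) <= 1

    def test_zero_genes_rejected(self):
        with pytest.raises(ValueError):
            synthesize_de_fixture(0)

    def test_unbalanced_classes_rejected(self):
        with pytest.raises(ValueError, match="infeasible"):
            synthesize_de_fixture(
                100, class_proportions={"convergent": 0.4, "divergent": 0.1, "tandem": 0.5}
            )

    def test_seeded_fixture_reproducible(self):
        g1, d1 = synthesize_de_fixture(120, seed=5)
        g2, d2 = synthesize_de_fixture(120, seed=5)
        assert g1 == g2 and d1.equals(d2)

    def test_null_fixture_rejection_rate_nominal(self):
        rej = 0
        n = 400
        for s in range(n):
            genes, de = synthesize_de_fixture(200, seed=10_000 + s)
            res = orientation_response_test(classify_orientation(genes), de)
            rej += res.pvalue < 0.05
        # binomial 99% band around 0.05 with n=400
        assert abs(rej / n - 0.05) < 2.58 * math.sqrt(0.05 * 0.95 / n)


class TestBridge:
    def test_equal_foldchanges_normalize_to_zero(self):
        df = simulate_to_de_bridge({"a": 2.0, "b": 2.0, "c": 2.0})
        assert np.allclose(df["log2FC"], 0.0)

    def test_single_gene_identity(self):
        df = simulate_to_de_bridge({"a": 3.0})
        assert df.loc["a", "log2FC"] == pytest.approx(0.0)  # median is itself

    def test_relative_ordering_preserved(self):
        df = simulate_to_de_bridge({"conv": 0.6, "tand": 0.4, "div": 0.25})
        assert df.loc["conv", "log2FC"] > 0 > df.loc["div", "log2FC"]

    def test_nonpositive_foldchange_rejected(self):
        with pytest.raises(ValueError):
            simulate_to_de_bridge({"a": 0.0})
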