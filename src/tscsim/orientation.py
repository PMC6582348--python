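"""Gene-orientation analysis of differential-expression tables.

Adjacent bacterial genes interact torsionally: negative supercoils accumulate
between divergent promoters, positive ones between convergent gene ends, so a
global change in supercoiling (gyrase inhibition, topA mutations) shifts the
balance of expression between the two classes.  This module classifies genes
by their local orientation context on a (circular) genome, joins the classes
with differential-expression calls and tests whether the activated proportion
differs between convergent and divergent genes with a Pearson chi-square test
on the 2x2 contingency table (activated/repressed x convergent/divergent),
as done for relaxation-shock and evolution-experiment transcriptomes.

A synthetic fixture generator plants an orientation-dependent activation bias
in a random differential-expression table so the whole analysis is testable
without any external dataset.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GeneRecord",
    "classify_orientation",
    "OrientationTestResult",
    "orientation_response_test",
    "call_de",
    "synthesize_de_fixture",
    "simulate_to_de_bridge",
    "read_gff3_genes",
    "read_de_table",
]

CLASSES = ("divergent", "convergent", "tandem", "ambiguous")


@dataclass(frozen=True)
class GeneRecord:
    """A gene interval; ``start <= end`` in 0-based half-open coordinates."""

    id: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"gene {self.id}: start > end")
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.id}: strand must be '+' or '-'")


def classify_orientation(
    genes: Sequence[GeneRecord], circular: bool = True
) -> dict[str, str]:
    """Classify each gene from the strands of its two flanking neighbors.

    divergent: the upstream neighbor transcribes away (opposite strand);
    convergent: the downstream neighbor transcribes toward it; tandem: both
    neighbors co-directional; ambiguous: both a divergent and a convergent
    context.  On a circular genome the neighbor relation wraps around;
    on a linear one terminal genes are classified from their single neighbor
    (a missing neighbor counts as co-directional).
    """
    n = len(genes)
    if n == 0:
        return {}
    order = sorted(range(n), key=lambda i: genes[i].start)
    overlaps = sum(
        1
        for a, b in zip(order, order[1:])
        if genes[a].end > genes[b].start
    )
    if overlaps:
        warnings.warn(
            f"{overlaps} overlapping gene pairs; classified from nearest "
            "neighbors in start order",
            stacklevel=2,
        )
    out: dict[str, str] = {}
    for pos, i in enumerate(order):
        g = genes[i]
        if circular:
            prev = genes[order[(pos - 1) % n]] if n > 1 else None
            nxt = genes[order[(pos + 1) % n]] if n > 1 else None
        else:
            prev = genes[order[pos - 1]] if pos > 0 else None
            nxt = genes[order[pos + 1]] if pos < n - 1 else None
        if g.strand == "+":
            up, down = prev, nxt
        else:
            up, down = nxt, prev
        div = up is not None and up.strand != g.strand
        conv = down is not None and down.strand != g.strand
        if div and conv:
            out[g.id] = "ambiguous"
        elif div:
            out[g.id] = "divergent"
        elif conv:
            out[g.id] = "convergent"
        else:
            out[g.id] = "tandem"
    return out


def call_de(
    de_table: pd.DataFrame,
    padj_threshold: float | None = 0.05,
    pvalue_threshold: float | None = None,
) -> pd.Series:
    """Call genes activated / repressed / not-significant.

    Significance uses the adjusted p-value (default threshold 0.05) or, when
    ``pvalue_threshold`` is given instead, the raw p-value (the looser
    selection used when larger gene sets are needed).  Activated means
    significant with log2FC > 0, repressed with log2FC < 0; significant genes
    with exactly zero fold-change are dropped (not-significant).
    """
    if pvalue_threshold is not None:
        sig = de_table["pvalue"] <= pvalue_threshold
    elif padj_threshold is not None:
        sig = de_table["padj"] <= padj_threshold
    else:
        raise ValueError("one of padj_threshold / pvalue_threshold is required")
    lfc = de_table["log2FC"]
    call = pd.Series("not-significant", index=de_table.index)
    call[sig & (lfc > 0)] = "activated"
    call[sig & (lfc < 0)] = "repressed"
    return call


@dataclass(frozen=True)
class OrientationTestResult:
    table: pd.DataFrame  # 2x2: rows convergent/divergent, cols activated/repressed
    chi2: float
    pvalue: float
    proportion_activated: dict[str, tuple[float, float, float]]  # p, lo, hi
    n_responding: int  # convergent + divergent responding genes


def orientation_response_test(
    classes: dict[str, str],
    de_table: pd.DataFrame,
    padj_threshold: float | None = 0.05,
    pvalue_threshold: float | None = None,
    continuity_correction: bool = False,
) -> OrientationTestResult:
    """Chi-square test of activated-proportion difference between convergent
    and divergent differentially expressed genes.

    Builds the 2x2 table over responding (activated or repressed) genes in
    the convergent and divergent classes (tandem/ambiguous excluded), applies
    the plain Pearson chi-square with 1 df (no continuity correction by
    default) and reports the per-class activated proportion with a 95%
    Wilson confidence interval.
    """
    call = call_de(de_table, padj_threshold, pvalue_threshold)
    counts = {c: {"activated": 0, "repressed": 0} for c in ("convergent", "divergent")}
    for gid, cl in classes.items():
        if cl not in counts or gid not in call.index:
            continue
        v = call[gid]
        if v in ("activated", "repressed"):
            counts[cl][v] += 1
    table = pd.DataFrame(counts).T[["activated", "repressed"]]
    for cls in ("convergent", "divergent"):
        if table.loc[cls].sum() == 0:
            raise ValueError(f"no responding gene in class {cls!r}")
    chi2, p, _, _ = stats.chi2_contingency(
        table.values, correction=continuity_correction
    )
    props = {}
    for cls in ("convergent", "divergent"):
        a, r = table.loc[cls, "activated"], table.loc[cls, "repressed"]
        lo, hi = _wilson_ci(a, a + r)
        props[cls] = (a / (a + r), lo, hi)
    return OrientationTestResult(
        table=table,
        chi2=float(chi2),
        pvalue=float(p),
        proportion_activated=props,
        n_responding=int(table.values.sum()),
    )


def _wilson_ci(k: int, n: int, z: float = 1.959963984540054) -> tuple[float, float]:
    if n == 0:
        return (0.0, 1.0)
    p = k / n
    denom = 1 + z * z / n
    center = (p + z * z / (2 * n)) / denom
    half = z * math.sqrt(p * (1 - p) / n + z * z / (4 * n * n)) / denom
    return (max(0.0, center - half), min(1.0, center + half))


def synthesize_de_fixture(
    n_genes: int,
    class_proportions: dict[str, float] | None = None,
    p_activated_by_class: dict[str, float] | None = None,
    fraction_responding: float = 0.5,
    seed: int = 0,
    gene_length: int = 900,
    gap: int = 100,
) -> tuple[list[GeneRecord], pd.DataFrame]:
    """Synthetic circular genome + differential-expression table with a
    planted orientation-dependent activation bias.

    The strand layout is built from alternating runs of co-directional genes:
    every run of length >= 2 contributes exactly one convergent and one
    divergent gene (its two ends) plus interior tandem genes, which is why a
    circular genome always carries equal numbers of convergent and divergent
    genes -- requested proportions must respect that.  Responding genes are
    drawn per class with the planted activation probabilities; everything is
    driven by ``seed``.
    """
    if n_genes <= 0:
        raise ValueError("n_genes must be > 0")
    props = class_proportions or {"convergent": 0.25, "divergent": 0.25, "tandem": 0.5}
    p_act = p_activated_by_class or {c: 0.5 for c in CLASSES}
    if not all(0 <= v <= 1 for v in list(props.values()) + list(p_act.values())):
        raise ValueError("probabilities must lie in [0, 1]")
    n_conv = round(props.get("convergent", 0) * n_genes)
    n_div = round(props.get("divergent", 0) * n_genes)
    if abs(n_conv - n_div) > 1:
        raise ValueError(
            "infeasible proportions: a circular genome has equally many "
            f"convergent and divergent genes (requested {n_conv} vs {n_div})"
        )
    # each strand run supplies one convergent and one divergent gene, and a
    # circle alternates +/- runs an even number of times; rounding down keeps
    # realized class counts within one of the request
    n_runs = min(n_conv, n_div)
    n_runs -= n_runs % 2
    if n_runs < 2 or 2 * n_runs > n_genes:
        raise ValueError("infeasible proportions: need 2 <= 2*n_runs <= n_genes")
    rng = np.random.default_rng(seed)
    run_lengths = np.full(n_runs, 2, dtype=int)
    extra = n_genes - 2 * n_runs
    if extra:
        run_lengths += rng.multinomial(extra, np.full(n_runs, 1 / n_runs))
    strands: list[str] = []
    for i, L in enumerate(run_lengths):
        strands.extend(["+" if i % 2 == 0 else "-"] * int(L))
    genes = [
        GeneRecord(
            id=f"g{i:04d}",
            start=i * (gene_length + gap),
            end=i * (gene_length + gap) + gene_length,
            strand=strands[i],
        )
        for i in range(n_genes)
    ]
    classes = classify_orientation(genes, circular=True)
    responding = rng.random(n_genes) < fraction_responding
    rows = []
    for i, g in enumerate(genes):
        cls = classes[g.id]
        if responding[i]:
            act = rng.random() < p_act.get(cls, 0.5)
            lfc = rng.gamma(2.0, 0.75) * (1 if act else -1)
            p = rng.uniform(1e-10, 1e-3)
        else:
            lfc = rng.normal(0, 0.2)
            p = rng.uniform(0.1, 1.0)
        rows.append((g.id, lfc, p))
    df = pd.DataFrame(rows, columns=["gene_id", "log2FC", "pvalue"]).set_index(
        "gene_id"
    )
    df["padj"] = stats.false_discovery_control(df["pvalue"].to_numpy(), method="bh")
    return genes, df


def simulate_to_de_bridge(
    foldchanges: dict[str, float], pseudo_p: float = 1e-6
) -> pd.DataFrame:
    """Convert per-gene expression fold-changes from a simulation into a
    median-normalized differential-expression-like table.

    Transcriptomics normalizes expression within each condition, so only
    *relative* fold-changes are observable: each gene's fold-change is divided
    by the median over genes before taking log2.  The returned table plugs
    directly into :func:`orientation_response_test`.
    """
    ids = list(foldchanges)
    fc = np.array([foldchanges[i] for i in ids], dtype=float)
    if np.any(fc <= 0):
        raise ValueError("fold-changes must be positive")
    rel = fc / np.median(fc)
    return pd.DataFrame(
        {
            "log2FC": np.log2(rel),
            "pvalue": pseudo_p,
            "padj": pseudo_p,
        },
        index=pd.Index(ids, name="gene_id"),
    )


def read_gff3_genes(path: str, feature_type: str = "gene") -> list[GeneRecord]:
    """Read gene records from a GFF3 annotation (1-based inclusive
    coordinates converted to 0-based half-open)."""
    import gffutils

    db = gffutils.create_db(
        str(path),
        ":memory:",
        merge_strategy="create_unique",
        keep_order=True,
    )
    genes = []
    for f in db.features_of_type(feature_type, order_by="start"):
        gid = f.attributes.get("ID", [f.id])[0]
        genes.append(GeneRecord(id=gid, start=f.start - 1, end=f.end, strand=f.strand))
    return genes


def read_de_table(path: str) -> pd.DataFrame:
    """Read a tabular differential-expression table (TSV with header
    gene_id, log2FC, pvalue[, padj])."""
    df = pd.read_csv(path, sep="\t")
    missing = {"gene_id", "log2FC", "pvalue"} - set(df.columns)
    if missing:
        raise ValueError(f"DE table missing column(s): {sorted(missing)}")
    if "padj" not in df.columns:
        df["padj"] = np.nan
    return df.set_index("gene_id")
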