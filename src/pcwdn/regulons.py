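"""Regulon calling against two controls, exclusive intersections, unique fractions.

A regulon for a carbon source is the set of genes significantly
differentially expressed and induced (>= 2-fold, adjusted p < 0.05) relative
to BOTH the no-carbon starvation control (NoC) and the sucrose control; a
down-regulon applies the same thresholds in the opposite direction.
Membership is decided on precomputed differential-expression tables when
available (the external DE engine's q-values are used verbatim); a built-in
fallback — Welch's t-test on log2(FPKM + 1) replicate values with
Benjamini-Hochberg adjustment per comparison — closes the pipeline over
simulated expression data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "Thresholds",
    "RegulonSet",
    "ExpressionMatrix",
    "expression_from_long",
    "fallback_differential",
    "call_regulon",
    "exclusive_intersections",
    "unique_fraction",
]

CONTROLS = ("NoC", "sucrose")


@dataclass(frozen=True)
class Thresholds:
    """DE calling thresholds: fold (linear, inclusive), alpha, pseudocount FPKM."""

    min_fold: float = 2.0
    alpha: float = 0.05
    pseudocount: float = 1.0

    def __post_init__(self) -> None:
        if self.min_fold < 1:
            raise ValueError("min_fold must be >= 1")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.pseudocount <= 0:
            raise ValueError("pseudocount must be positive")


@dataclass(frozen=True)
class RegulonSet:
    condition: str
    direction: str  # "up" | "down"
    members: frozenset[str]

    def __post_init__(self) -> None:
        if self.direction not in ("up", "down"):
            raise ValueError(f"direction must be 'up' or 'down', got {self.direction!r}")

    def sorted_members(self) -> list[str]:
        return sorted(self.members)


@dataclass
class ExpressionMatrix:
    """FPKM indexed gene x condition x replicate.

    ``values[condition]`` is a (n_genes, n_replicates) non-negative array;
    all conditions share the gene index.
    """

    genes: list[str]
    values: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for cond, arr in self.values.items():
            arr = np.asarray(arr, dtype=float)
            if arr.ndim != 2 or arr.shape[0] != len(self.genes):
                raise ValueError(f"condition {cond}: expected (n_genes, n_reps) array")
            if (arr < 0).any() or not np.isfinite(arr).all():
                raise ValueError(f"condition {cond}: FPKM must be finite and >= 0")
            self.values[cond] = arr

    @property
    def conditions(self) -> list[str]:
        return list(self.values)

    def condition_means(self) -> pd.DataFrame:
        return pd.DataFrame(
            {c: self.values[c].mean(axis=1) for c in self.values}, index=self.genes
        )


def expression_from_long(source) -> ExpressionMatrix:
    """Build an :class:`ExpressionMatrix` from a long-form TSV or DataFrame
    with columns gene_id, condition, replicate, fpkm."""
    df = source if isinstance(source, pd.DataFrame) else pd.read_csv(source, sep="\t")
    wide = df.pivot_table(index="gene_id", columns=["condition", "replicate"], values="fpkm")
    genes = sorted(wide.index)
    wide = wide.loc[genes]
    values = {
        cond: wide[cond].to_numpy(dtype=float)
        for cond in wide.columns.get_level_values(0).unique()
    }
    return ExpressionMatrix(genes=genes, values=values)


def fallback_differential(
    expr: ExpressionMatrix, test: str, control: str, th: Thresholds = Thresholds()
) -> pd.DataFrame:
    """Welch t-test DE table for one test-vs-control comparison.

    Fold change is the ratio of condition-mean FPKM after adding the
    pseudocount; the test runs on log2(FPKM + pseudocount) replicate values
    and raw p-values are Benjamini-Hochberg adjusted across genes within the
    comparison.  Stands in for an external DE engine over simulated data
    only; precomputed tables take precedence in :func:`call_regulon`.
    """
    for cond in (test, control):
        if cond not in expr.values:
            raise ValueError(f"condition {cond!r} absent from expression matrix")
        if expr.values[cond].shape[1] < 2:
            raise ValueError(
                f"condition {cond!r} has fewer than 2 replicates; "
                "supply a precomputed differential-expression table instead"
            )
    a = np.log2(expr.values[test] + th.pseudocount)
    b = np.log2(expr.values[control] + th.pseudocount)
    log2fc = (
        np.log2(expr.values[test].mean(axis=1) + th.pseudocount)
        - np.log2(expr.values[control].mean(axis=1) + th.pseudocount)
    )
    tstat, p_raw = stats.ttest_ind(a, b, axis=1, equal_var=False)
    # zero-variance identical groups give nan; identical values mean no evidence
    p_raw = np.where(np.isnan(p_raw), 1.0, p_raw)
    p_adj = multipletests(p_raw, method="fdr_bh")[1]
    return pd.DataFrame(
        {
            "gene_id": expr.genes,
            "test_condition": test,
            "control_condition": control,
            "log2fc": log2fc,
            "p_raw": p_raw,
            "p_adj": p_adj,
        }
    )


def _prepare_de(df: pd.DataFrame) -> pd.DataFrame:
    df = df.copy()
    if "p_adj" not in df or df["p_adj"].isna().all():
        if "p_raw" not in df:
            raise ValueError("DE table needs p_adj or p_raw")
        df["p_adj"] = multipletests(df["p_raw"].to_numpy(dtype=float), method="fdr_bh")[1]
    else:
        # fill row-wise gaps from raw p (BH over the available raw values)
        missing = df["p_adj"].isna()
        if missing.any():
            df.loc[missing, "p_adj"] = multipletests(
                df.loc[missing, "p_raw"].to_numpy(dtype=float), method="fdr_bh"
            )[1]
    return df


def call_regulon(
    de_vs_noc: pd.DataFrame,
    de_vs_sucrose: pd.DataFrame,
    direction: str = "up",
    th: Thresholds = Thresholds(),
) -> RegulonSet:
    """Two-control regulon: thresholds must pass in BOTH comparisons.

    Membership requires adjusted p < alpha and |fold| >= min_fold in the
    stated direction against NoC and against sucrose.
    """
    if direction not in ("up", "down"):
        raise ValueError(f"direction must be 'up' or 'down', got {direction!r}")
    tests = set(de_vs_noc.get("test_condition", pd.Series(dtype=str))) | set(
        de_vs_sucrose.get("test_condition", pd.Series(dtype=str))
    )
    if len(tests) > 1:
        raise ValueError(f"mismatched test conditions across DE tables: {sorted(tests)}")
    condition = next(iter(tests), "?")

    lfc_cut = math.log2(th.min_fold)
    members: frozenset[str] | None = None
    for df in (de_vs_noc, de_vs_sucrose):
        if df.empty:
            return RegulonSet(condition=condition, direction=direction, members=frozenset())
        df = _prepare_de(df)
        lfc = df["log2fc"].to_numpy(dtype=float)
        ok = df["p_adj"].to_numpy(dtype=float) < th.alpha
        ok &= lfc >= lfc_cut if direction == "up" else lfc <= -lfc_cut
        passing = frozenset(df.loc[ok, "gene_id"])
        members = passing if members is None else members & passing
    return RegulonSet(condition=condition, direction=direction, members=members or frozenset())


def exclusive_intersections(
    regulons: list[RegulonSet], min_size: int = 1
) -> dict[tuple[str, ...], frozenset[str]]:
    """Exclusive membership-pattern decomposition (UpSet semantics).

    Every gene in the union is assigned to exactly one combination — the
    tuple of condition labels of precisely the regulons containing it.
    Combinations smaller than ``min_size`` are dropped from the returned
    mapping (the decomposition itself always partitions the union).
    """
    if len(regulons) < 2:
        raise ValueError("need at least two regulons")
    directions = {r.direction for r in regulons}
    if len(directions) > 1:
        raise ValueError(f"mixed regulon directions: {sorted(directions)}")
    patterns: dict[tuple[str, ...], set[str]] = {}
    union = set().union(*(r.members for r in regulons))
    for gid in union:
        key = tuple(r.condition for r in regulons if gid in r.members)
        patterns.setdefault(key, set()).add(gid)
    return {
        key: frozenset(v)
        for key, v in sorted(patterns.items())
        if len(v) >= min_size
    }


def unique_fraction(target: RegulonSet, others: list[RegulonSet]) -> tuple[int, float | None]:
    """Genes unique to ``target`` and their fraction of the regulon.

    Returns (unique count, fraction in [0, 1]); the fraction is ``None`` for
    an empty target regulon.
    """
    for o in others:
        if o.direction != target.direction:
            raise ValueError("regulon directions must match")
    other_union = set().union(*(o.members for o in others)) if others else set()
    unique = target.members - other_union
    if not target.members:
        return 0, None
    return len(unique), len(unique) / len(target.members)
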