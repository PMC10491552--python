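"""Aggregation and comparison statistics for QA reports.

The per-acquisition metric rows are kept in a long-format table (one row
per acquisition × metric) from which Table-style summaries are built:
mean (SD) per acquisition method and metric, paired t-tests between
matched motorized settings (stepwise vs continuous, compounding on vs
off), and the inter-operator agreement as the two-way random-effects,
absolute-agreement, single-measure intraclass correlation ICC(2,1).

A linear mixed model across methods is deliberately not fitted here —
the long table this module emits is exactly what an off-the-shelf
mixed-model routine consumes; Welch's t-test is reported as the built-in
approximation for the freehand-vs-motorized contrast.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "make_metric_table",
    "summarize",
    "operator_table",
    "paired_ttest",
    "welch_ttest",
    "icc_agreement",
    "ComparisonResult",
    "ICCResult",
]

#: Columns identifying one acquisition in the long-format metric table.
ID_COLUMNS = ["acquisition_id", "method", "movement", "step_size_mm",
              "compounding", "operator"]


def make_metric_table(rows: list[dict]) -> pd.DataFrame:
    """Melt per-acquisition report dicts into the long format
    (one row per acquisition × metric, finite values only)."""
    from .metrics import METRIC_COLUMNS

    df = pd.DataFrame(rows)
    value_cols = [c for c in df.columns if c in METRIC_COLUMNS]
    if not value_cols:
        value_cols = [c for c in df.columns if c not in ID_COLUMNS]
    long = df.melt(id_vars=[c for c in ID_COLUMNS if c in df.columns],
                   value_vars=value_cols, var_name="metric", value_name="value")
    return long[np.isfinite(long["value"].astype(float))].reset_index(drop=True)


def summarize(table: pd.DataFrame) -> pd.DataFrame:
    """Mean (SD) and n per method per metric — the method-comparison
    summary. Freehand pools all FA acquisitions; motorized pools every
    motorized setting of the experiment grid."""
    if not {"freehand", "motorized"} <= set(table["method"].unique()):
        raise ValueError("summary requires both freehand and motorized rows")
    g = table.groupby(["metric", "method"])["value"]
    out = g.agg(mean="mean", sd="std", n="count").reset_index()
    return out.pivot(index="metric", columns="method", values=["mean", "sd", "n"])


def operator_table(table: pd.DataFrame) -> pd.DataFrame:
    """Per metric × method × movement: operator A and B mean (SD) and the
    ICC(2,1) between operators over matched repeated acquisitions —
    the inter-/intra-operator variability summary."""
    recs = []
    for (metric, method, movement), sub in table.groupby(
        ["metric", "method", "movement"]
    ):
        ops = sorted(sub["operator"].unique())
        if len(ops) < 2:
            continue
        a = sub[sub["operator"] == ops[0]]["value"].to_numpy()
        b = sub[sub["operator"] == ops[1]]["value"].to_numpy()
        m = min(a.size, b.size)
        rec = {
            "metric": metric, "method": method, "movement": movement,
            "operator_a_mean": a.mean(), "operator_a_sd": a.std(ddof=1),
            "operator_b_mean": b.mean(), "operator_b_sd": b.std(ddof=1),
        }
        if m >= 3:
            icc = icc_agreement(np.column_stack([a[:m], b[:m]]))
            rec["icc"] = icc.icc
            rec["icc_p"] = icc.p_value
        recs.append(rec)
    return pd.DataFrame(recs)


@dataclass
class ComparisonResult:
    metric: str
    test: str
    statistic: float
    p_value: float
    mean_a: float
    sd_a: float
    mean_b: float
    sd_b: float


def paired_ttest(a, b, metric: str = "") -> ComparisonResult:
    """Classical paired-samples t-test (two-sided, α = 0.05 by
    convention). Raises on all-zero differences, where the statistic is
    undefined (0/0); this error path is the documented behavior."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size != b.size or a.size < 2:
        raise ValueError("paired t-test needs two equal-length samples, n >= 2")
    d = a - b
    if np.all(d == d[0]) and d[0] == 0:
        raise ValueError("all paired differences are zero: t statistic undefined "
                         "(zero variance)")
    res = sps.ttest_rel(a, b)
    return ComparisonResult(metric, "paired t", float(res.statistic),
                            float(res.pvalue), a.mean(), a.std(ddof=1),
                            b.mean(), b.std(ddof=1))


def welch_ttest(a, b, metric: str = "") -> ComparisonResult:
    """Welch's unequal-variance t-test — the built-in approximation for
    the freehand-vs-motorized contrast."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    res = sps.ttest_ind(a, b, equal_var=False)
    return ComparisonResult(metric, "welch t", float(res.statistic),
                            float(res.pvalue), a.mean(), a.std(ddof=1),
                            b.mean(), b.std(ddof=1))


@dataclass
class ICCResult:
    icc: float
    p_value: float
    model: str = "ICC(2,1) two-way random, absolute agreement, single measures"


def icc_agreement(ratings: np.ndarray) -> ICCResult:
    """Inter-operator agreement as ICC(2,1).

    ``ratings`` is (targets/acquisitions × raters/operators), ≥ 3 × 2.
    Computed from the two-way ANOVA mean squares (via pingouin); a
    degenerate between-target variance yields a warning, not a crash.
    """
    import pingouin as pg

    r = np.asarray(ratings, dtype=float)
    if r.ndim != 2 or r.shape[0] < 3 or r.shape[1] < 2:
        raise ValueError("ICC needs at least 3 acquisitions by 2 operators")
    n, k = r.shape
    long = pd.DataFrame({
        "targets": np.repeat(np.arange(n), k),
        "raters": np.tile(np.arange(k), n),
        "ratings": r.ravel(),
    })
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        tab = pg.intraclass_corr(long, targets="targets", raters="raters",
                                 ratings="ratings")
    # two-way random, absolute agreement, single measures: labeled ICC2
    # (Shrout–Fleiss) or ICC(A,1) (McGraw–Wong) depending on version
    sel = tab[tab["Type"].isin(["ICC2", "ICC(A,1)"])]
    row = sel.iloc[0]
    icc, pval = float(row["ICC"]), float(row["pval"])
    if not np.isfinite(icc):
        warnings.warn("ICC undefined (zero between-target variance); "
                      "reporting as computed", RuntimeWarning, stacklevel=2)
    return ICCResult(icc, pval)
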