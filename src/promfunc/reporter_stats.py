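"""Reporter-assay statistics: from replicate luminosities to functional calls.

Each construct (a promoter cloned upstream of luciferase) is assayed as a
wild-type / mutant pair, nine replicates per allele per cell line (three
plasmid preps x three transfections).  Wells are normalized per plate,
alleles compared by Welch's t-test, p-values pooled into one global
Benjamini-Hochberg family, and a site is called functional in a cell line
when the mutation's FDR falls below 0.025.  Mutant luminosity below wild
type means the site activates transcription; above, it represses.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

CELL_LINES = ("K562", "HCT116", "HT1080", "HepG2")

REQUIRED_COLUMNS = ("construct_id", "allele", "cell_line", "prep_rep", "txn_rep", "plate_id", "raw")


def normalize_plate(table: pd.DataFrame) -> pd.DataFrame:
    """Normalize raw luminosities by the per-plate median of all wells
    (controls included).  Adds a ``normalized`` column; scale invariant per
    plate.  Raises on a plate with fewer than two wells."""
    missing = [c for c in ("plate_id", "raw") if c not in table.columns]
    if missing:
        raise ValueError(f"missing columns: {missing}")
    sizes = table.groupby("plate_id").size()
    small = sizes[sizes < 2]
    if len(small):
        raise ValueError(f"plates with fewer than 2 wells: {list(small.index)}")
    out = table.copy()
    out["normalized"] = out["raw"] / out.groupby("plate_id")["raw"].transform("median")
    return out


def test_construct(wt, mt) -> tuple[float, float]:
    """Welch two-sided t-test of mutant vs wild-type normalized luminosities.

    Returns ``(p, log2fc)`` with ``log2fc = log2(mean(mt) / mean(wt))``.
    If both groups have zero variance, p is 1 when the means are equal and
    0 otherwise.
    """
    wt = np.asarray(wt, dtype=float)
    mt = np.asarray(mt, dtype=float)
    if wt.size < 2 or mt.size < 2:
        raise ValueError("need at least two replicates per allele")
    if np.any(wt <= 0) or np.any(mt <= 0):
        raise ValueError("luminosities must be positive")
    log2fc = float(np.log2(mt.mean() / wt.mean()))
    if wt.std() == 0 and mt.std() == 0:
        return (1.0 if wt.mean() == mt.mean() else 0.0), log2fc
    p = float(stats.ttest_ind(mt, wt, equal_var=False).pvalue)
    return p, log2fc


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (clipped at 1).

    ``q_(i) = min_{j >= i} m * p_(j) / j`` over the sorted p-values, mapped
    back to the input order.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def call_functions(tests: pd.DataFrame, alpha: float = 0.025) -> pd.DataFrame:
    """Pool all experiments into one BH family and call function per
    (construct, cell line).

    ``tests`` needs columns construct_id, cell_line, p, log2fc (optional:
    tf, exp_class).  Functional iff q < alpha (strict); direction is
    'activating' when the mutant is dimmer than wild type (log2fc < 0),
    'repressing' when brighter, 'none' otherwise.
    """
    required = {"construct_id", "cell_line", "p", "log2fc"}
    missing = required - set(tests.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    dup = tests.duplicated(subset=["construct_id", "cell_line"])
    if dup.any():
        raise ValueError(
            f"duplicate (construct, cell line) rows: "
            f"{tests.loc[dup, ['construct_id', 'cell_line']].values.tolist()[:5]}"
        )
    calls = tests.copy().reset_index(drop=True)
    calls["q"] = bh_adjust(calls["p"].to_numpy())
    calls["functional"] = calls["q"] < alpha
    direction = np.where(
        ~calls["functional"], "none",
        np.where(calls["log2fc"] < 0, "activating",
                 np.where(calls["log2fc"] > 0, "repressing", "none")),
    )
    calls["direction"] = direction
    return calls


def functional_rate(n_functional: int, n_total: int, decimals: int = 0) -> float:
    """Percentage of experiments called functional, rounded for reporting."""
    if n_total == 0:
        raise ValueError("empty experiment class")
    return round(100.0 * n_functional / n_total, decimals) if decimals else round(
        100.0 * n_functional / n_total
    )


def _per_construct(calls: pd.DataFrame, n_cell_lines: int) -> pd.DataFrame:
    grp = calls.groupby("construct_id")
    per = pd.DataFrame(
        {
            "n_cell_lines": grp.size(),
            "n_functional": grp["functional"].sum(),
        }
    )
    if "tf" in calls.columns:
        per["tf"] = grp["tf"].first()
    complete = per["n_cell_lines"] == n_cell_lines
    if not complete.all():
        warnings.warn(
            f"{(~complete).sum()} constructs missing cell lines; excluded from ubiquity counts"
        )
    per["complete"] = complete
    # directionality among functional calls only
    func = calls[calls["functional"]]
    dirs = func.groupby("construct_id")["direction"].agg(lambda d: set(d))
    per["directions"] = per.index.map(lambda c: dirs.get(c, set()))
    return per


def summarize_calls(calls: pd.DataFrame, n_cell_lines: int = 4) -> dict:
    """Overall and per-TF summary of functional calls.

    Returns a dict with: n_constructs, n_functional_any and its percent,
    per-cell-line functional counts and percents, the cross-cell-line count
    distribution (how many constructs were functional in 4/3/2/1/0 cell
    lines), ubiquitous counts split by consistent direction, and a per-TF
    table when a ``tf`` column is present.
    """
    if "exp_class" in calls.columns:
        calls = calls[calls["exp_class"].isin(["tfbs"])].copy()
    per = _per_construct(calls, n_cell_lines)
    n_constructs = len(per)
    n_any = int((per["n_functional"] >= 1).sum())
    dist = {
        k: int((per.loc[per["complete"], "n_functional"] == k).sum())
        for k in range(n_cell_lines, 0, -1)
    }
    dist[0] = int((per["n_functional"] == 0).sum())

    ubiq = per[per["complete"] & (per["n_functional"] == n_cell_lines)]
    n_ubiq = len(ubiq)
    n_ubiq_act = int((ubiq["directions"] == {"activating"}).sum())
    n_ubiq_rep = int((ubiq["directions"] == {"repressing"}).sum())

    per_cell = calls.groupby("cell_line")["functional"].sum().astype(int).to_dict()
    summary = {
        "n_constructs": n_constructs,
        "n_functional_any": n_any,
        "pct_functional_any": functional_rate(n_any, n_constructs),
        "per_cell_line_functional": per_cell,
        "per_cell_line_pct": {
            c: functional_rate(k, n_constructs) for c, k in per_cell.items()
        },
        "n_ubiquitous": n_ubiq,
        "n_ubiquitous_activating": n_ubiq_act,
        "n_ubiquitous_repressing": n_ubiq_rep,
        "n_never_functional": dist[0],
        "cell_line_count_distribution": dist,
    }
    if "tf" in calls.columns:
        rows = []
        for tf, sub in per.groupby("tf"):
            row = {
                "tf": tf,
                "tested": len(sub),
                "functional": int((sub["n_functional"] >= 1).sum()),
                "ubiquitous": int(
                    (sub["complete"] & (sub["n_functional"] == n_cell_lines)).sum()
                ),
            }
            tf_calls = calls[calls["tf"] == tf]
            for cl, k in tf_calls.groupby("cell_line")["functional"].sum().items():
                row[f"functional_{cl}"] = int(k)
            rows.append(row)
        summary["per_tf"] = pd.DataFrame(rows).set_index("tf")
    return summary


def concordance(
    calls_a: pd.DataFrame, calls_b: pd.DataFrame, validated_ids=None
) -> float:
    """Spearman correlation of |log2fc| between two cell lines.

    Pairs are restricted to constructs functionally validated in at least
    one cell line (by default, functional in either of the two supplied).
    """
    a = calls_a.set_index("construct_id")
    b = calls_b.set_index("construct_id")
    common = a.index.intersection(b.index)
    if validated_ids is None:
        validated_ids = set(a.index[a["functional"]]) | set(b.index[b["functional"]])
    ids = [c for c in common if c in set(validated_ids)]
    if len(ids) < 3:
        raise ValueError(f"need >= 3 paired constructs, got {len(ids)}")
    rho = stats.spearmanr(a.loc[ids, "log2fc"].abs(), b.loc[ids, "log2fc"].abs()).statistic
    return float(rho)


def analyze(
    luminosity: pd.DataFrame,
    alpha: float = 0.025,
    average_technical: bool = False,
) -> pd.DataFrame:
    """Full reporter pipeline: plate normalization, per-(construct, cell
    line) Welch test of MT vs WT, one global BH family, functional calls.

    ``average_technical=True`` averages the three transfections within each
    prep before testing (3 v 3 instead of 9 v 9).
    """
    table = normalize_plate(luminosity)
    table = table[table["allele"].isin(["WT", "MT"])]
    rows = []
    for (construct, cell), sub in table.groupby(["construct_id", "cell_line"], sort=True):
        wt = sub.loc[sub["allele"] == "WT"]
        mt = sub.loc[sub["allele"] == "MT"]
        if average_technical:
            wt_vals = wt.groupby("prep_rep")["normalized"].mean().to_numpy()
            mt_vals = mt.groupby("prep_rep")["normalized"].mean().to_numpy()
        else:
            wt_vals = wt["normalized"].to_numpy()
            mt_vals = mt["normalized"].to_numpy()
        p, log2fc = test_construct(wt_vals, mt_vals)
        row = {"construct_id": construct, "cell_line": cell, "p": p, "log2fc": log2fc}
        for extra in ("tf", "exp_class"):
            if extra in sub.columns:
                row[extra] = sub[extra].iloc[0]
        rows.append(row)
    return call_functions(pd.DataFrame(rows), alpha=alpha)
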