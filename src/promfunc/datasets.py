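"""Reference summary counts from the published four-cell-line promoter screen.

The screen mutagenized 455 predicted binding sites (CTCF, E2F, GABP, GATA2,
STAT1, YY1 and a few others) in human promoters and assayed each wild-type /
mutant pair in K562, HCT116, HT1080 and HepG2 cells.  Only the printed
summary counts are bundled here, as plain data: the per-TF table (tested,
functional in >= 1 cell line, ubiquitously functional / activating /
repressing, per-cell-line functional counts, best PWM AUC) and the
cross-cell-line distribution of functional calls.  ``reference_calls``
expands these counts into a concrete per-construct calls table whose
summary statistics reproduce the printed numbers; the per-TF x cell-line
interior cells are not uniquely determined by the printed tables, so the
expansion fixes them deterministically (greedy assignment).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

CELL_LINES = ("K562", "HCT116", "HT1080", "HepG2")

#: Per-TF summary: functional (>=1 cell line), tested, ubiquitously
#: functional / activating / repressing, per-cell-line functional counts,
#: and the AUC of the most predictive PWM on ChIP-seq peaks vs background.
REFERENCE_TF_COUNTS = pd.DataFrame(
    [
        # tf, func, tested, ubq, ubq_act, ubq_rep, K562, HCT116, HT1080, HepG2, auc
        ("CTCF", 104, 168, 9, 9, 0, 62, 52, 49, 53, 0.84),
        ("E2F4", 7, 12, 0, 0, 0, 3, 3, 3, 0, 0.83),
        ("E2F6", 2, 3, 0, 0, 0, 1, 0, 1, 0, 0.78),
        ("EGR1", 1, 2, 0, 0, 0, 0, 1, 0, 0, 0.76),
        ("GABP", 7, 11, 4, 4, 0, 5, 5, 6, 5, 0.77),
        ("GATA1", 4, 4, 1, 1, 0, 4, 4, 1, 1, 0.69),
        ("GATA2", 47, 80, 4, 3, 1, 36, 20, 18, 14, 0.81),
        ("JUND", 3, 3, 1, 1, 0, 2, 2, 1, 3, 0.65),
        ("MAX", 3, 3, 1, 0, 1, 2, 2, 2, 2, 0.77),
        ("STAT1", 54, 69, 16, 11, 5, 41, 27, 29, 39, 0.74),
        ("USF1", 2, 2, 1, 1, 0, 2, 2, 2, 1, 0.86),
        ("YY1", 86, 98, 26, 9, 16, 63, 56, 53, 58, 0.82),
    ],
    columns=["tf", "func", "tested", "ubq_func", "ubq_act", "ubq_rep",
             "func_K562", "func_HCT116", "func_HT1080", "func_HepG2", "auc"],
)

#: How many of the 455 sites were functional in exactly 4/3/2/1/0 cell lines.
REFERENCE_CELL_LINE_DISTRIBUTION = {4: 63, 3: 75, 2: 77, 1: 105, 0: 135}

#: Experiment-class sizes entering the single BH family.
N_SITES = 455
N_CELL_LINES = 4
N_NEGATIVE_CONTROLS = 12   # K562 only; 1 called functional (false positive)
N_UNBOUND = 23             # PWM matches with no in-vivo binding; 7 functional
N_NEGATIVE_FUNCTIONAL = 1
N_UNBOUND_FUNCTIONAL = 7


def bh_family_size() -> int:
    """Total hypothesis tests pooled into the single BH correction family."""
    return N_SITES * N_CELL_LINES + N_NEGATIVE_CONTROLS + N_UNBOUND


def reference_calls() -> pd.DataFrame:
    """Expand the printed per-TF counts into a per-construct calls table.

    One row per (construct, cell line) with columns construct_id, tf,
    cell_line, functional, direction, log2fc.  The expansion respects, per
    TF: tested / functional-in->=1 / ubiquitous counts and the ubiquitous
    direction split; globally: the per-cell-line functional totals and the
    exactly-4/3/2/1/0 cross-cell-line distribution.  Cell-line memberships
    of partially functional constructs are assigned greedily toward the
    cell lines with the largest remaining totals (deterministic).
    """
    dist = REFERENCE_CELL_LINE_DISTRIBUTION
    constructs = []  # (construct_id, tf, n_cells, directions dict or tag)

    # ubiquitous constructs, with their printed direction split
    for _, row in REFERENCE_TF_COUNTS.iterrows():
        mixed = row["ubq_func"] - row["ubq_act"] - row["ubq_rep"]
        tags = (["activating"] * row["ubq_act"] + ["repressing"] * row["ubq_rep"]
                + ["mixed"] * mixed)
        for j, tag in enumerate(tags):
            constructs.append((f"{row['tf']}_ubq_{j:03d}", row["tf"], 4, tag))

    # partially functional constructs: per-TF totals, global exactly-k split
    partial_pool = []
    for _, row in REFERENCE_TF_COUNTS.iterrows():
        for j in range(row["func"] - row["ubq_func"]):
            partial_pool.append((f"{row['tf']}_part_{j:03d}", row["tf"]))
    ks = [3] * dist[3] + [2] * dist[2] + [1] * dist[1]
    if len(ks) != len(partial_pool):
        raise RuntimeError("cross-cell-line distribution inconsistent with per-TF counts")
    for (cid, tf), k in zip(partial_pool, ks):
        constructs.append((cid, tf, k, "activating"))

    # never-functional constructs
    for _, row in REFERENCE_TF_COUNTS.iterrows():
        for j in range(row["tested"] - row["func"]):
            constructs.append((f"{row['tf']}_null_{j:03d}", row["tf"], 0, "none"))

    # remaining per-cell-line functional totals after the ubiquitous block
    need = {
        cl: int(REFERENCE_TF_COUNTS[f"func_{cl}"].sum()) - dist[4] for cl in CELL_LINES
    }

    rows = []
    order = {cl: i for i, cl in enumerate(CELL_LINES)}
    for cid, tf, k, tag in constructs:
        if k == 4:
            members = list(CELL_LINES)
        elif k == 0:
            members = []
        else:
            members = sorted(CELL_LINES, key=lambda c: (-need[c], order[c]))[:k]
            for c in members:
                need[c] -= 1
        for cl in CELL_LINES:
            functional = cl in members
            if not functional:
                direction = "none"
                log2fc = 0.0
            elif tag == "mixed":
                # the one cell-line-dependent ubiquitous site: repressed in
                # HCT116, activating elsewhere
                direction = "repressing" if cl == "HCT116" else "activating"
                log2fc = 1.0 if direction == "repressing" else -1.0
            else:
                direction = tag
                log2fc = -1.0 if tag == "activating" else 1.0
            rows.append((cid, tf, cl, functional, direction, log2fc))

    if any(v != 0 for v in need.values()):
        raise RuntimeError(f"greedy cell-line assignment failed: residual {need}")
    return pd.DataFrame(
        rows,
        columns=["construct_id", "tf", "cell_line", "functional", "direction", "log2fc"],
    )
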