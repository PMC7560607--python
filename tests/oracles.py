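"""Independent reference implementations shared across test modules.

These deliberately avoid the package's own code paths: the BH oracle is a
direct step-up transcription and the pull-down oracle applies the filter
clauses row by row.
"""

import numpy as np


def bh_oracle(p, alpha=0.05):
    """Step-up oracle: q_(i) = min_{j>=i} p_(j) * m / j over ascending p."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    q_sorted = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    # 1e-9 absorbs float ordering differences at the alpha boundary.
    ranks = (q[order] <= alpha + 1e-9).nonzero()[0]
    return q, (int(ranks.max()) + 1) if ranks.size else 0


def pulldown_brute_force(table, max_control, min_bait):
    """Row-by-row oracle applying both pull-down filter clauses literally."""
    keep = []
    baits = [c for c in table.columns if c.startswith("spc_bait_")]
    ctrls = [c for c in table.columns if c.startswith("spc_ctrl_")]
    for _, row in table.iterrows():
        if all(row[c] >= min_bait for c in baits) and \
                all(row[c] <= max_control for c in ctrls):
            keep.append(row["protein_id"])
    return set(keep)
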