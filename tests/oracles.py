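"""Independent brute-force oracles used by unit and acceptance tests.

These deliberately avoid the library code paths they check.
"""

import numpy as np


def brute_force_bh(p_values):
    """Benjamini-Hochberg step-up, straight from the definition:
    adj_p(i) = min over j >= i of (n * p_(j) / j), capped at 1."""
    p = np.asarray(p_values, dtype=float)
    n = len(p)
    order = np.argsort(p, kind="mergesort")
    adjusted = np.empty(n)
    running_min = 1.0
    for rank_from_top in range(n, 0, -1):
        idx = order[rank_from_top - 1]
        candidate = min(1.0, n * p[idx] / rank_from_top)
        running_min = min(running_min, candidate)
        adjusted[idx] = running_min
    return adjusted


def ols_slope(x, y):
    """Closed-form least-squares slope: sum((x-xbar)(y-ybar)) / sum((x-xbar)^2)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    xbar, ybar = x.mean(), y.mean()
    return float(((x - xbar) * (y - ybar)).sum() / ((x - xbar) ** 2).sum())


def per_residue_domain(orientation, length, tm_spans, start, end):
    """Brute-force peptide domain: classify every residue independently,
    then collapse (mixed labels -> spanning)."""
    def classify(pos):
        for a, b in tm_spans:
            if a <= pos <= b:
                return "transmembrane"
        if pos < tm_spans[0][0]:
            return "extracellular" if orientation == "type_I" else "intracellular"
        if pos > tm_spans[-1][1]:
            return "intracellular" if orientation == "type_I" else "extracellular"
        return "spanning"

    labels = {classify(pos) for pos in range(start, end + 1)}
    if len(labels) == 1:
        return labels.pop()
    return "spanning"


def random_topology_and_peptide(rng):
    """One random (model parameters, peptide interval) pair, possibly
    multi-pass, for oracle comparisons."""
    length = int(rng.integers(60, 500))
    n_spans = int(rng.integers(1, 4))
    spans = []
    cursor = int(rng.integers(5, 20))
    for _ in range(n_spans):
        width = int(rng.integers(15, 26))
        if cursor + width > length - 10:
            break
        spans.append((cursor, cursor + width - 1))
        cursor += width + int(rng.integers(5, 40))
    if not spans:
        spans = [(10, 30)]
    orientation = "type_I" if rng.random() < 0.5 else "type_II"
    pep_len = int(rng.integers(7, 31))
    start = int(rng.integers(1, length - pep_len + 2))
    return orientation, length, tuple(spans), start, start + pep_len - 1
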