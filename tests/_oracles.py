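"""Independent brute-force reference implementations used as test oracles.

Everything here is deliberately written as plain double loops over rows and
columns, sharing no code path with the package: distances are summed term
by term, neighbours found by sorting full distance lists, and votes counted
with dict arithmetic.
"""

from __future__ import annotations


def squared_distance(a, b, cols) -> float:
    return sum((float(a[c]) - float(b[c])) ** 2 for c in cols)


def brute_majority(labels) -> str:
    counts: dict[str, int] = {}
    for lab in labels:
        counts[lab] = counts.get(lab, 0) + 1
    best = max(counts.values())
    return sorted(c for c, v in counts.items() if v == best)[0]


def brute_knn_predict(base_X, base_y, base_ids, query_row, k, cols) -> str:
    """Majority label of the k nearest base rows, ties by (distance, id)."""
    ranked = sorted(
        (squared_distance(base_X[i], query_row, cols), str(base_ids[i]), base_y[i])
        for i in range(len(base_X))
    )
    return brute_majority([lab for _, _, lab in ranked[:k]])


def brute_base_classifier_acc(X, y, ids, base_idx, query_idx, k, cols) -> float:
    correct = 0
    base_X = [X[i] for i in base_idx]
    base_y = [y[i] for i in base_idx]
    base_ids = [ids[i] for i in base_idx]
    for qi in query_idx:
        pred = brute_knn_predict(base_X, base_y, base_ids, X[qi], k, cols)
        correct += pred == y[qi]
    return correct / len(query_idx)


def brute_supports(subsets, accs, p):
    """Per-feature mean accuracy over containing classifiers (None if unseen)."""
    sums = [0.0] * p
    mult = [0] * p
    for cols, acc in zip(subsets, accs):
        for c in cols:
            sums[c] += acc
            mult[c] += 1
    return [sums[j] / mult[j] if mult[j] else None for j in range(p)], mult
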