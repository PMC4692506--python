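"""Independent brute-force MDR reference implementation.

Deliberately naive and structurally unlike the package: individuals are
dicts, cells are tuples in Python sets/dicts, ratios are exact
``fractions.Fraction``s, and every fold/cell/label is enumerated with
literal set operations. Used to cross-check labeling, cross-validated
evaluation and the exhaustive search on small cohorts.
"""

from __future__ import annotations

import itertools
from fractions import Fraction


def rows_of(cohort):
    recs = cohort.data.to_dict(orient="records")
    for r in recs:
        r["phenotype"] = int(r["phenotype"])
    return recs


def label_cells_bf(rows, combo):
    """Map cell-tuple -> 'high'/'low'; unseen cells are simply absent."""
    rows = [r for r in rows if all(r[l] != "NA" for l in combo)]
    n_ca = sum(r["phenotype"] for r in rows)
    n_co = len(rows) - n_ca
    T = Fraction(n_ca, n_co)
    cells: dict[tuple, list[int]] = {}
    for r in rows:
        key = tuple(r[l] for l in combo)
        cells.setdefault(key, [0, 0])
        cells[key][r["phenotype"]] += 1
    labels = {}
    for key, (co, ca) in cells.items():
        if co == 0:
            labels[key] = "high"  # cases only: infinite ratio
        else:
            labels[key] = "high" if Fraction(ca, co) >= T else "low"
    return labels


def balanced_accuracy_bf(preds, phens):
    pairs = list(zip(preds, phens))
    cases = [p for p, y in pairs if y == 1]
    controls = [p for p, y in pairs if y == 0]
    sens = Fraction(sum(cases), len(cases)) if cases else Fraction(1, 2)
    spec = Fraction(len(controls) - sum(controls), len(controls)) if controls else Fraction(1, 2)
    return (sens + spec) / 2


def fold_accuracies_bf(rows, combo, fold_index, k):
    """(train BA, test BA) per fold, as exact Fractions."""
    train_acc, test_acc = [], []
    for f in range(k):
        train = [r for r, fi in zip(rows, fold_index) if fi != f and all(r[l] != "NA" for l in combo)]
        test = [r for r, fi in zip(rows, fold_index) if fi == f and all(r[l] != "NA" for l in combo)]
        labels = label_cells_bf(train, combo)

        def predict(r):
            return 1 if labels.get(tuple(r[l] for l in combo), "low") == "high" else 0

        train_acc.append(balanced_accuracy_bf([predict(r) for r in train],
                                              [r["phenotype"] for r in train]))
        test_acc.append(balanced_accuracy_bf([predict(r) for r in test],
                                             [r["phenotype"] for r in test]))
    return train_acc, test_acc


def search_bf(rows, locus_names, orders, fold_index, k):
    """Per-order (combo, fold wins, mean test BA), mirroring the contract:
    fold winner = best training BA (first in lexicographic order on ties);
    per-order model = most wins, ties to higher mean test BA then order."""
    result = {}
    for order in orders:
        combos = list(itertools.combinations(locus_names, order))
        if not combos:
            continue
        accs = {c: fold_accuracies_bf(rows, c, fold_index, k) for c in combos}
        wins = {c: 0 for c in combos}
        for f in range(k):
            best = max(combos, key=lambda c: accs[c][0][f])
            best = next(c for c in combos if accs[c][0][f] == accs[best][0][f])
            wins[best] += 1
        max_w = max(wins.values())
        top = [c for c in combos if wins[c] == max_w]
        best_mean = max(sum(accs[c][1]) / k for c in top)
        winner = next(c for c in top if sum(accs[c][1]) / k == best_mean)
        result[order] = (winner, wins[winner], accs[winner])
    return result
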