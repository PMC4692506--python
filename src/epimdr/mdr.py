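"""Multifactor dimensionality reduction (MDR) for case-control genotypes.

MDR detects gene-gene interaction without a parametric model: for a
combination of k loci it tabulates cases and controls in every cell of the
k-way genotype table, labels a cell high-risk when its case:control ratio
meets or exceeds the threshold T (the case:control ratio of the data the
labels are fit on), and collapses the k-locus genotype into the single
binary high/low attribute. Candidate combinations are compared by the
balanced accuracy of that attribute under stratified 10-fold
cross-validation: within each fold, the combination with the best training
balanced accuracy is the fold winner, cross-validation consistency counts
the folds a combination wins, and the selected model maximises consistency
with prediction error (1 - mean testing balanced accuracy) as the
tie-break. Significance comes from an exact binomial sign test on the
per-fold testing accuracies and from a permutation test that re-runs the
whole search on outcome-shuffled data.

Cell labeling is done in exact integer arithmetic
(``cases_cell * n_controls >= n_cases * controls_cell``), so threshold
ties are handled identically at any scale; ties are labeled high-risk,
making the rule a closed half-line, and cells never seen in training are
labeled ``empty`` and treated as low-risk at prediction time.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np
import scipy.stats as sps

from .cohort import Cohort, ContingencyTable


class MdrError(ValueError):
    pass


HIGH, LOW, EMPTY = 1, 0, -1


@dataclass
class CellLabels:
    """Risk labels for every cell of a k-locus genotype table."""

    combo: tuple[str, ...]
    sizes: tuple[int, ...]            # per-locus category counts
    labels: np.ndarray                # flat, values HIGH/LOW/EMPTY
    threshold: float                  # cases:controls of the labeling data
    case_counts: np.ndarray
    control_counts: np.ndarray

    def cell_index(self, categories: tuple[str, ...], cohort: Cohort) -> int:
        idx = 0
        for name, size, cat in zip(self.combo, self.sizes, categories):
            idx = idx * size + cohort.locus(name).categories.index(cat)
        return idx

    def label_of(self, categories: tuple[str, ...], cohort: Cohort) -> int:
        return int(self.labels[self.cell_index(categories, cohort)])

    def high_cells(self, cohort: Cohort) -> set[tuple[str, ...]]:
        cats = [cohort.locus(n).categories for n in self.combo]
        out = set()
        for i, combo_cats in enumerate(itertools.product(*cats)):
            if self.labels[i] == HIGH:
                out.add(combo_cats)
        return out

    def grid_frame(self, cohort: Cohort):
        """Long-format cell grid: combination, case/control counts, label."""
        import pandas as pd

        cats = [cohort.locus(n).categories for n in self.combo]
        rows = []
        names = {HIGH: "high", LOW: "low", EMPTY: "empty"}
        for i, cc in enumerate(itertools.product(*cats)):
            rows.append({"cell": " x ".join(cc),
                         "cases": int(self.case_counts[i]),
                         "controls": int(self.control_counts[i]),
                         "label": names[int(self.labels[i])]})
        return pd.DataFrame(rows)


@dataclass
class FoldPlan:
    """Stratified k-fold assignment: fold index per individual."""

    k: int
    fold_index: np.ndarray
    seed: int
    stratified: bool = True


@dataclass
class RiskRecode:
    """Per-individual binary high-risk indicator under a CellLabels."""

    indicator: np.ndarray     # aligned to the cohort; meaningful where used
    used: np.ndarray          # complete genotypes at the model loci
    n_empty: int              # individuals that fell in empty (unseen) cells
    n_missing: int


@dataclass
class ModelEvaluation:
    combo: tuple[str, ...]
    train_accuracy: np.ndarray
    test_accuracy: np.ndarray
    cv_consistency: int
    sign_test_p: float
    permutation_p: float | None = None
    warnings: list[str] = field(default_factory=list)

    @property
    def mean_test_accuracy(self) -> float:
        return float(np.mean(self.test_accuracy))

    @property
    def prediction_error(self) -> float:
        return 1.0 - self.mean_test_accuracy


@dataclass
class MdrSearchResult:
    per_order: dict[int, ModelEvaluation]
    best: ModelEvaluation
    loci: tuple[str, ...]

    def table(self):
        """Report frame: one row per order, the usual MDR report columns."""
        import pandas as pd

        rows = []
        for order in sorted(self.per_order):
            ev = self.per_order[order]
            rows.append({
                "order": order,
                "best_model": ", ".join(ev.combo),
                "testing_balanced_accuracy": ev.mean_test_accuracy,
                "cv_consistency": f"{ev.cv_consistency}/{len(ev.test_accuracy)}",
                "sign_test_p": ev.sign_test_p,
                "permutation_p": ev.permutation_p,
            })
        return pd.DataFrame(rows)


# -- folds ----------------------------------------------------------------


def make_folds(cohort: Cohort, k: int = 10, seed: int = 0) -> FoldPlan:
    """Stratified k-fold plan: within each class, a seeded permutation is
    dealt round-robin so fold sizes differ by at most one per class."""
    if k < 2:
        raise MdrError("need k >= 2 folds")
    rng = np.random.default_rng(seed)
    phen = cohort.phenotype
    fold = np.empty(len(cohort), dtype=np.int64)
    for cls in (0, 1):
        idx = np.flatnonzero(phen == cls)
        if len(idx) < k:
            raise MdrError(f"class {cls} has {len(idx)} members, fewer than k={k}")
        perm = rng.permutation(idx)
        fold[perm] = np.arange(len(perm)) % k
    return FoldPlan(k=k, fold_index=fold, seed=seed)


# -- labeling and reduction ----------------------------------------------


def _encode_cells(cohort: Cohort, combo) -> tuple[np.ndarray, tuple[int, ...], int]:
    codes, sizes = cohort.genotype_codes(tuple(combo))
    ok = (codes >= 0).all(axis=1)
    cell = np.zeros(len(cohort), dtype=np.int64)
    for j, size in enumerate(sizes):
        cell = cell * size + codes[:, j]
    cell[~ok] = -1
    return cell, sizes, int(np.prod(sizes))


def _label_from_counts(case_counts: np.ndarray, control_counts: np.ndarray,
                       n_cases: int, n_controls: int) -> np.ndarray:
    """High iff cell case:control ratio >= T = n_cases:n_controls, in exact
    integer arithmetic; a cell with cases and no controls is high; a cell
    with no one is empty."""
    labels = np.where(case_counts * n_controls >= n_cases * control_counts, HIGH, LOW)
    labels[(case_counts == 0) & (control_counts == 0)] = EMPTY
    return labels.astype(np.int64)


def label_cells(training: Cohort, combo, threshold_policy: str = "ratio") -> CellLabels:
    """Fit high/low-risk labels for the cells of a locus combination."""
    combo = tuple([combo] if isinstance(combo, str) else combo)
    if not combo:
        raise MdrError("empty locus combination")
    if threshold_policy != "ratio":
        raise MdrError(f"unknown threshold policy {threshold_policy!r}")
    n_ca, n_co = training.n_cases, training.n_controls
    if n_ca == 0 or n_co == 0:
        raise MdrError("training data must contain both classes")
    cell, sizes, n_cells = _encode_cells(training, combo)
    phen = training.phenotype
    ok = cell >= 0
    case_counts = np.bincount(cell[ok & (phen == 1)], minlength=n_cells)
    control_counts = np.bincount(cell[ok & (phen == 0)], minlength=n_cells)
    labels = _label_from_counts(case_counts, control_counts, n_ca, n_co)
    return CellLabels(combo=combo, sizes=sizes, labels=labels, threshold=n_ca / n_co,
                      case_counts=case_counts, control_counts=control_counts)


def reduce(cohort: Cohort, labels: CellLabels) -> RiskRecode:
    """Collapse each individual's k-locus genotype to the binary attribute.

    Individuals in empty (training-unseen) cells are classified low-risk
    and counted; individuals missing a genotype at a model locus are
    excluded and counted.
    """
    cell, sizes, n_cells = _encode_cells(cohort, labels.combo)
    if sizes != labels.sizes:
        raise MdrError("labels do not cover this cohort's category product")
    used = cell >= 0
    lab = np.full(len(cohort), LOW, dtype=np.int64)
    lab[used] = labels.labels[cell[used]]
    n_empty = int((lab[used] == EMPTY).sum())
    indicator = (lab == HIGH).astype(np.int64)
    return RiskRecode(indicator=indicator, used=used, n_empty=n_empty,
                      n_missing=int((~used).sum()))


def balanced_accuracy(pred, phenotype) -> float:
    """(sensitivity + specificity) / 2; an absent class contributes 0.5."""
    pred = np.asarray(pred)
    y = np.asarray(phenotype)
    if pred.shape != y.shape:
        raise MdrError("prediction and phenotype lengths differ")
    pos, neg = y == 1, y == 0
    sens = float((pred[pos] == 1).mean()) if pos.any() else 0.5
    spec = float((pred[neg] == 0).mean()) if neg.any() else 0.5
    return (sens + spec) / 2


# -- cross-validation and search -----------------------------------------


def _ba_float(tp: int, n_pos: int, fp: int, n_neg: int) -> float:
    sens = tp / n_pos if n_pos else 0.5
    spec = (n_neg - fp) / n_neg if n_neg else 0.5
    return (sens + spec) / 2


def _ba_exact(tp: int, n_pos: int, fp: int, n_neg: int) -> Fraction:
    sens = Fraction(tp, n_pos) if n_pos else Fraction(1, 2)
    spec = Fraction(n_neg - fp, n_neg) if n_neg else Fraction(1, 2)
    return (sens + spec) / 2


class _Workspace:
    """Cell encodings and per-fold class counts shared across a search.

    Encoding depends only on genotypes, so one workspace serves the
    observed data and every phenotype permutation of it.
    """

    def __init__(self, cohort: Cohort, combos: list[tuple[str, ...]]):
        self.cohort = cohort
        self.combos = combos
        self.enc = {c: _encode_cells(cohort, c) for c in combos}

    def fold_accuracies(self, phen: np.ndarray, folds: FoldPlan,
                        combo: tuple[str, ...]):
        """Per-fold training/testing balanced accuracy for one combination.

        Returns float accuracy arrays plus the integer confusion counts
        (tp, n_cases, fp, n_controls) per fold; model selection compares
        the counts in exact rational arithmetic so that ties are decided
        identically at any scale.
        """
        cell, sizes, n_cells = self.enc[combo]
        ok = cell >= 0
        k = folds.k
        # per-fold cell counts by class, then train = total - fold
        case_f = np.zeros((k, n_cells), dtype=np.int64)
        ctrl_f = np.zeros((k, n_cells), dtype=np.int64)
        sel_ca = ok & (phen == 1)
        sel_co = ok & (phen == 0)
        np.add.at(case_f, (folds.fold_index[sel_ca], cell[sel_ca]), 1)
        np.add.at(ctrl_f, (folds.fold_index[sel_co], cell[sel_co]), 1)
        case_tot = case_f.sum(axis=0)
        ctrl_tot = ctrl_f.sum(axis=0)
        n_ca_f = case_f.sum(axis=1)
        n_co_f = ctrl_f.sum(axis=1)
        n_ca, n_co = n_ca_f.sum(), n_co_f.sum()
        train_acc = np.empty(k)
        test_acc = np.empty(k)
        train_counts = np.empty((k, 4), dtype=np.int64)
        test_counts = np.empty((k, 4), dtype=np.int64)
        for f in range(k):
            tr_case = case_tot - case_f[f]
            tr_ctrl = ctrl_tot - ctrl_f[f]
            tr_nca, tr_nco = int(n_ca - n_ca_f[f]), int(n_co - n_co_f[f])
            labels = _label_from_counts(tr_case, tr_ctrl, tr_nca, tr_nco)
            high = labels == HIGH
            # training accuracy from the same counts
            tp = int(tr_case[high].sum())
            fp = int(tr_ctrl[high].sum())
            train_counts[f] = (tp, tr_nca, fp, tr_nco)
            train_acc[f] = _ba_float(tp, tr_nca, fp, tr_nco)
            # testing accuracy on the held-out fold (empty cells -> low)
            te_tp = int(case_f[f][high].sum())
            te_fp = int(ctrl_f[f][high].sum())
            test_counts[f] = (te_tp, int(n_ca_f[f]), te_fp, int(n_co_f[f]))
            test_acc[f] = _ba_float(te_tp, int(n_ca_f[f]), te_fp, int(n_co_f[f]))
        return train_acc, test_acc, train_counts, test_counts


def cv_evaluate(cohort: Cohort, combo, folds: FoldPlan) -> ModelEvaluation:
    """Cross-validated evaluation of a single locus combination.

    Within each fold the labels are fit on the training nine-tenths and
    the balanced accuracy measured on the held-out tenth. Consistency is a
    search-level notion (folds won against competitors), so a lone
    combination evaluated here wins every fold unopposed: consistency = k.
    """
    combo = tuple([combo] if isinstance(combo, str) else combo)
    ws = _Workspace(cohort, [combo])
    train, test, _, _ = ws.fold_accuracies(cohort.phenotype, folds, combo)
    ev = ModelEvaluation(combo=combo, train_accuracy=train, test_accuracy=test,
                         cv_consistency=folds.k, sign_test_p=1.0)
    ev.sign_test_p = sign_test(ev)
    return ev


def sign_test(evaluation: ModelEvaluation) -> float:
    """One-sided exact binomial test on folds beating chance.

    Counts folds with testing balanced accuracy strictly above 0.5 (a fold
    exactly at 0.5 counts as a failure) and returns P(X >= count) for
    X ~ Binomial(k, 1/2).
    """
    k = len(evaluation.test_accuracy)
    c = int((np.asarray(evaluation.test_accuracy) > 0.5).sum())
    return float(sps.binom.sf(c - 1, k, 0.5))


def _search(ws: _Workspace, phen: np.ndarray, folds: FoldPlan,
            orders) -> tuple[dict[int, ModelEvaluation], ModelEvaluation]:
    by_order: dict[int, list[tuple[str, ...]]] = {}
    for combo in ws.combos:
        by_order.setdefault(len(combo), []).append(combo)
    per_order: dict[int, ModelEvaluation] = {}
    for order in sorted(o for o in orders if o in by_order):
        combos = by_order[order]
        accs = {c: ws.fold_accuracies(phen, folds, c) for c in combos}
        wins = {c: 0 for c in combos}
        for f in range(folds.k):
            # exact-rational comparison; combos are enumerated in
            # lexicographic locus order and ties go to the first maximum
            best = max(range(len(combos)),
                       key=lambda i: (_ba_exact(*accs[combos[i]][2][f]), -i))
            wins[combos[best]] += 1
        # most fold wins; ties broken by higher mean testing accuracy
        # (= minimum prediction error), then first in lexicographic order
        max_wins = max(wins.values())
        top = [c for c in combos if wins[c] == max_wins]
        mean_test = {c: sum(_ba_exact(*row) for row in accs[c][3]) for c in top}
        best_acc = max(mean_test.values())
        best_combo = next(c for c in top if mean_test[c] == best_acc)
        train, test = accs[best_combo][0], accs[best_combo][1]
        ev = ModelEvaluation(combo=best_combo, train_accuracy=train, test_accuracy=test,
                             cv_consistency=wins[best_combo], sign_test_p=1.0)
        ev.sign_test_p = sign_test(ev)
        per_order[order] = ev
    if not per_order:
        raise MdrError("no feasible order in requested range")
    best = max(per_order.values(),
               key=lambda ev: (ev.cv_consistency, ev.mean_test_accuracy))
    return per_order, best


def _all_combos(loci: list[str], orders) -> list[tuple[str, ...]]:
    out = []
    for order in sorted(set(orders)):
        if 1 <= order <= len(loci):
            out.extend(itertools.combinations(loci, order))
    return out


def mdr_search(cohort: Cohort, orders=(1, 2, 3, 4), folds: FoldPlan | None = None,
               loci: list[str] | None = None, k: int = 10,
               fold_seed: int = 0) -> MdrSearchResult:
    """Exhaustive MDR search over all locus combinations of the given orders.

    Per fold and order, the combination with the best training balanced
    accuracy wins the fold; the per-order model is the combination with
    the most fold wins (ties: smaller prediction error, then first in
    lexicographic locus order); the overall best model has maximal
    cross-validation consistency, ties broken by smaller prediction error.
    """
    names = loci if loci is not None else [l.name for l in cohort.loci]
    folds = folds if folds is not None else make_folds(cohort, k=k, seed=fold_seed)
    combos = _all_combos(names, orders)
    if not combos:
        raise MdrError("no locus combinations to search")
    ws = _Workspace(cohort, combos)
    per_order, best = _search(ws, cohort.phenotype, folds, orders)
    return MdrSearchResult(per_order=per_order, best=best, loci=tuple(names))


def permutation_test(cohort: Cohort, orders=(1, 2, 3, 4), folds_seed: int = 0,
                     n_perm: int = 1000, seed: int = 1, k: int = 10,
                     loci: list[str] | None = None) -> tuple[float, MdrSearchResult]:
    """Permutation p-value for the observed best model's testing accuracy.

    The phenotype labels are shuffled ``n_perm`` times (as by
    ``null_shuffle``), the full search re-run on each shuffle with
    re-stratified folds from the same fold seed, and
    p = (1 + #{permuted best mean testing accuracy >= observed}) / (n_perm + 1).
    """
    if n_perm < 1:
        raise MdrError("need n_perm >= 1")
    names = loci if loci is not None else [l.name for l in cohort.loci]
    combos = _all_combos(names, orders)
    ws = _Workspace(cohort, combos)
    folds = make_folds(cohort, k=k, seed=folds_seed)
    per_order, best = _search(ws, cohort.phenotype, folds, orders)
    observed = best.mean_test_accuracy

    rng = np.random.default_rng(seed)
    phen = cohort.phenotype
    exceed = 0
    for _ in range(n_perm):
        p = phen[rng.permutation(len(phen))]
        # folds restratified on the shuffled labels, same fold seed
        fold = np.empty(len(p), dtype=np.int64)
        frng = np.random.default_rng(folds_seed)
        for cls in (0, 1):
            idx = np.flatnonzero(p == cls)
            perm = frng.permutation(idx)
            fold[perm] = np.arange(len(perm)) % folds.k
        fplan = FoldPlan(k=folds.k, fold_index=fold, seed=folds_seed)
        _, pb = _search(ws, p, fplan, orders)
        if pb.mean_test_accuracy >= observed:
            exceed += 1
    pval = (1 + exceed) / (n_perm + 1)
    best.permutation_p = pval
    return pval, MdrSearchResult(per_order=per_order, best=best, loci=tuple(names))


def classify_individuals(cohort: Cohort, labels: CellLabels,
                         stratum: str | None = None) -> ContingencyTable:
    """High/low-risk counts by case-control status (optionally one subtype).

    Rows: high-risk, low-risk; columns: case, control — directly consumable
    by ``stats.odds_ratio`` (cross-product a*d/(b*c) is the high-vs-low
    case-control odds ratio).
    """
    sub = cohort.stratum(stratum)
    rec = reduce(sub, labels)
    phen = sub.phenotype
    counts = np.zeros((2, 2), dtype=np.int64)
    for i, hi in enumerate((1, 0)):
        for j, cls in enumerate((1, 0)):
            counts[i, j] = int(((rec.indicator == hi) & (phen == cls) & rec.used).sum())
    return ContingencyTable(["high-risk", "low-risk"], ["case", "control"], counts,
                            n_excluded=rec.n_missing)
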