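"""Published summary statistics of the motivating ischemic-stroke study.

The pipeline was built around a hospital-based case-control study of
ischemic stroke (IS) in a southern Han Chinese population: 712 cases and
774 controls genotyped at six candidate polymorphisms selected by
meta-analysis. The study released genotype distributions, clinical
characteristics and the high/low-risk combination counts as printed
tables; those numbers are collected here verbatim and serve two purposes:

* they parametrise the synthetic cohort generator (allele frequencies by
  allele counting in controls, covariate marginals per class), and
* they are desk-checkable inputs for the classical statistics (chi-square
  on printed genotype counts, cross-product odds ratio on the printed
  risk-combination 2x2).

``reconstructed_cohort`` builds a per-individual cohort that is consistent
with the printed margins. It is synthetic: the study's individual-level
joint genotype data is not redistributed here, so the ACE x FGB_T148C
joint cell counts are one integer-feasible solution matching the printed
row/column margins and the printed high/low-risk totals, and the other
four loci are assigned independently within class. Quantities that depend
only on the constrained margins (single-locus tables, risk-combination
counts, crude odds ratios, the high/low cell labeling) are exact; anything
depending on the unconstrained joint structure is not.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .cohort import Cohort, default_loci

N_CONTROLS = 774
N_CASES = 712

#: case counts per TOAST subtype (LAA, SAO, CE, SOE, SUE)
SUBTYPE_SIZES = {"LAA": 327, "SAO": 221, "CE": 54, "SOE": 52, "SUE": 58}

#: single-locus genotype counts, category order as in ``default_loci``.
#: The overall-case FGB_T148C TT entry is 56 = 712 - 243 - 413; the value
#: printed in the source table (29) does not sum to the case total and
#: reproduces neither the printed percentages nor the printed p-value.
GENOTYPE_COUNTS: dict[str, dict[str, tuple[int, ...]]] = {
    "ACE": {
        "control": (64, 351, 359), "case": (74, 356, 282),
        "LAA": (32, 158, 137), "SAO": (26, 114, 81), "CE": (4, 29, 21),
    },
    "FGB_T148C": {
        "control": (77, 301, 396), "case": (56, 243, 413),
        "LAA": (29, 106, 192), "SAO": (15, 71, 135), "CE": (4, 24, 26),
    },
    "FGB_A455G": {
        "control": (62, 302, 410), "case": (46, 245, 421),
        "LAA": (23, 107, 197), "SAO": (12, 72, 137), "CE": (4, 24, 26),
    },
    "MTHFR_C677T": {
        "control": (52, 299, 423), "case": (55, 269, 388),
        "LAA": (25, 124, 178), "SAO": (17, 86, 118), "CE": (5, 21, 28),
    },
    "APOE": {
        "control": (3, 107, 8, 535, 113, 8), "case": (4, 93, 13, 494, 101, 7),
        "LAA": (2, 35, 7, 225, 54, 4), "SAO": (1, 36, 2, 152, 28, 2),
        "CE": (1, 6, 1, 38, 8, 0),
    },
    "ENOS_G894T": {
        "control": (12, 143, 619), "case": (14, 142, 556),
        "LAA": (8, 62, 257), "SAO": (5, 44, 172), "CE": (0, 14, 40),
    },
}

#: clinical covariate marginals per class: age mean (sd) in years, and
#: prevalences of male sex, hypertension history, diabetes history and
#: family history of ischemic stroke.
COVARIATE_SUMMARY = {
    "control": {"age_mean": 51.5, "age_sd": 16.9, "male": 0.540,
                "hypertension": 0.190, "diabetes": 0.071,
                "family_history_IS": 0.006},
    "case": {"age_mean": 65.2, "age_sd": 13.9, "male": 0.653,
             "hypertension": 0.573, "diabetes": 0.202,
             "family_history_IS": 0.056},
}

#: the high-risk two-locus genotype combinations (ACE, FGB_T148C)
HIGH_RISK_CELLS = frozenset({("DD", "CC"), ("DD", "CT"), ("ID", "CC")})

#: (high, low) counts of individuals in the risk-combination dichotomy
RISK_COMBINATION_COUNTS = {
    "control": (233, 542),
    "case": (288, 424),
    "LAA": (129, 198),
    "SAO": (99, 122),
}

# One integer-feasible ACE x FGB_T148C joint table per case stratum and for
# controls, consistent with every printed margin above and with the printed
# high/low totals. Rows: ACE DD/ID/II; columns: FGB_T148C TT/CT/CC.
_JOINT_CONTROL = np.array([[8, 26, 30], [34, 140, 177], [35, 135, 189]])
_JOINT_CASE_BY_SUBTYPE = {
    "LAA": np.array([[2, 12, 18], [12, 47, 99], [15, 47, 75]]),
    "SAO": np.array([[1, 10, 15], [6, 34, 74], [8, 27, 46]]),
    "CE": np.array([[0, 2, 2], [2, 14, 13], [2, 8, 11]]),
    "SOE": np.array([[1, 2, 3], [1, 10, 16], [2, 8, 9]]),
    "SUE": np.array([[0, 2, 4], [1, 11, 16], [3, 9, 12]]),
}


def control_allele_frequencies() -> dict[str, dict[str, float]]:
    """Allele frequencies by allele counting in the control genotype counts."""
    freqs: dict[str, dict[str, float]] = {}
    for locus in default_loci():
        counts = GENOTYPE_COUNTS[locus.name]["control"]
        tally = {a: 0 for a in locus.alleles}
        for cat, n in zip(locus.categories, counts):
            for allele in locus.genotype_alleles[cat]:
                tally[allele] += n
        total = sum(tally.values())
        freqs[locus.name] = {a: c / total for a, c in tally.items()}
    return freqs


def _expand_joint(joint: np.ndarray, ace_cats, fgb_cats) -> tuple[list[str], list[str]]:
    ace_col, fgb_col = [], []
    for i, a in enumerate(ace_cats):
        for j, b in enumerate(fgb_cats):
            ace_col.extend([a] * int(joint[i, j]))
            fgb_col.extend([b] * int(joint[i, j]))
    return ace_col, fgb_col


def _expand_marginal(counts, cats) -> list[str]:
    out: list[str] = []
    for cat, n in zip(cats, counts):
        out.extend([cat] * int(n))
    return out


def reconstructed_cohort(seed: int = 0) -> Cohort:
    """Synthetic per-individual cohort matching the study's printed margins.

    ACE and FGB_T148C come from the joint tables above (so subtype strata,
    risk-combination counts and the two-locus cell labeling are exact); the
    other four loci are drawn without replacement to match the printed
    class margins but independent of everything else; covariates are
    sampled per class from the printed marginals. ``seed`` only affects the
    unconstrained assignments.
    """
    rng = np.random.default_rng(seed)
    loci = default_loci()
    by = {l.name: l for l in loci}
    rows: dict[str, list] = {"phenotype": [], "subtype": [], "ACE": [], "FGB_T148C": []}

    ace_cats = by["ACE"].categories
    fgb_cats = by["FGB_T148C"].categories
    a_col, f_col = _expand_joint(_JOINT_CONTROL, ace_cats, fgb_cats)
    rows["ACE"] += a_col
    rows["FGB_T148C"] += f_col
    rows["phenotype"] += [0] * N_CONTROLS
    rows["subtype"] += ["control"] * N_CONTROLS
    for sub in ("LAA", "SAO", "CE", "SOE", "SUE"):
        a_col, f_col = _expand_joint(_JOINT_CASE_BY_SUBTYPE[sub], ace_cats, fgb_cats)
        rows["ACE"] += a_col
        rows["FGB_T148C"] += f_col
        rows["phenotype"] += [1] * len(a_col)
        rows["subtype"] += [sub] * len(a_col)

    df = pd.DataFrame(rows)
    for name in ("FGB_A455G", "MTHFR_C677T", "APOE", "ENOS_G894T"):
        col = np.empty(len(df), dtype=object)
        for cls, label in ((0, "control"), (1, "case")):
            vals = _expand_marginal(GENOTYPE_COUNTS[name][label], by[name].categories)
            col[np.flatnonzero(df["phenotype"].to_numpy() == cls)] = rng.permutation(vals)
        df[name] = col

    for cls, label in ((0, "control"), (1, "case")):
        idx = df.index[df["phenotype"] == cls]
        cs = COVARIATE_SUMMARY[label]
        age = rng.normal(cs["age_mean"], cs["age_sd"], size=len(idx)).clip(18, 100)
        df.loc[idx, "age"] = np.round(age).astype(int)
        df.loc[idx, "sex"] = np.where(rng.random(len(idx)) < cs["male"], "male", "female")
        for cov in ("family_history_IS", "hypertension", "diabetes"):
            df.loc[idx, cov] = (rng.random(len(idx)) < cs[cov]).astype(int)
    df.insert(0, "id", [f"R{i:04d}" for i in range(len(df))])
    return Cohort(df, loci)
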