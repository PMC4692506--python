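"""Classical case-control association statistics.

Hardy-Weinberg chi-square by allele counting, Pearson chi-square on
genotype contingency tables (no continuity correction), Bonferroni
thresholds, Woolf odds-ratio confidence intervals, and maximum-likelihood
logistic regression (iteratively reweighted least squares via statsmodels)
with Wald intervals — the standard toolkit around a candidate-gene study.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats as sps
import statsmodels.api as sm

from .cohort import Cohort, ContingencyTable, Locus, MISSING


class StatsError(ValueError):
    pass


class SeparationError(StatsError):
    """Logistic likelihood is unbounded along some coefficient direction."""


@dataclass
class TestResult:
    statistic: float
    df: int
    p_value: float
    n_used: int
    warnings: list[str] = field(default_factory=list)


@dataclass
class OddsRatioResult:
    odds_ratio: float
    ci_low: float
    ci_high: float
    se_log: float
    p_value: float
    corrected: bool = False  # Haldane-Anscombe +0.5 applied


@dataclass
class LogisticFit:
    """Logistic regression summary on the odds-ratio scale.

    ``params`` are log-odds coefficients indexed by predictor name;
    ``odds_ratios``/``ci_low``/``ci_high`` exponentiate the Wald interval
    exp(beta +/- 1.96 se).
    """

    params: pd.Series
    bse: pd.Series
    log_likelihood: float
    iterations: int
    converged: bool
    n_used: int
    warnings: list[str] = field(default_factory=list)

    @property
    def odds_ratios(self) -> pd.Series:
        return np.exp(self.params)

    @property
    def ci_low(self) -> pd.Series:
        return np.exp(self.params - 1.959963984540054 * self.bse)

    @property
    def ci_high(self) -> pd.Series:
        return np.exp(self.params + 1.959963984540054 * self.bse)

    @property
    def p_values(self) -> pd.Series:
        z = self.params / self.bse
        return pd.Series(2 * sps.norm.sf(np.abs(z)), index=self.params.index)

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "coef": self.params, "se": self.bse, "OR": self.odds_ratios,
            "ci_low": self.ci_low, "ci_high": self.ci_high, "p": self.p_values,
        })


def hwe_chisq(genotype_counts, locus: Locus) -> TestResult:
    """Chi-square test of Hardy-Weinberg proportions.

    Allele frequencies are estimated by allele counting from the observed
    genotype counts; expected counts are n*p_i^2 for homozygotes and
    2*n*p_i*p_j for heterozygotes. Degrees of freedom equal the number of
    genotype categories minus the number of alleles (1 for a biallelic
    locus, 3 for a three-allele locus such as ApoE).
    """
    if isinstance(genotype_counts, dict):
        counts = np.array([genotype_counts.get(c, 0) for c in locus.categories], dtype=float)
    else:
        counts = np.asarray(genotype_counts, dtype=float)
    if counts.shape != (len(locus.categories),):
        raise StatsError("genotype_counts must cover every category of the locus")
    if (counts < 0).any():
        raise StatsError("negative genotype count")
    n = counts.sum()
    if n <= 0:
        raise StatsError("no individuals")
    alleles = locus.alleles
    tally = dict.fromkeys(alleles, 0.0)
    for cat, c in zip(locus.categories, counts):
        for a in locus.genotype_alleles[cat]:
            tally[a] += c
    freqs = {a: t / (2 * n) for a, t in tally.items()}
    if sum(f > 0 for f in freqs.values()) < 2:
        raise StatsError(f"locus {locus.name!r} is monomorphic; HWE test undefined")
    expected = np.empty_like(counts)
    for i, cat in enumerate(locus.categories):
        a, b = locus.genotype_alleles[cat]
        expected[i] = n * (freqs[a] ** 2 if a == b else 2 * freqs[a] * freqs[b])
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(expected > 0, (counts - expected) ** 2 / expected, 0.0)
    stat = float(terms.sum())
    dof = len(locus.categories) - len(alleles)
    warns = []
    if (expected < 5).any():
        warns.append("expected genotype count < 5")
    return TestResult(stat, dof, float(sps.chi2.sf(stat, dof)), int(n), warns)


def chisq_independence(table: ContingencyTable) -> TestResult:
    """Pearson chi-square of independence, no continuity correction."""
    counts = table.counts
    if counts.shape[0] < 2 or counts.shape[1] < 2:
        raise StatsError("need at least a 2x2 table")
    warns = []
    keep = table.row_margins > 0
    if not keep.all():
        # unobserved genotype categories carry no information; drop them
        warns.append(f"{int((~keep).sum())} empty row(s) dropped")
        counts = counts[keep]
    if counts.shape[0] < 2 or (counts.sum(axis=0) == 0).any():
        raise StatsError("zero row or column margin")
    stat, p, dof, expected = sps.chi2_contingency(counts, correction=False)
    if (expected < 5).any():
        warns.append("expected cell count < 5")
    return TestResult(float(stat), int(dof), float(p), table.total, warns)


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Per-test significance level alpha/m for m comparisons."""
    if not 0 < alpha < 1:
        raise StatsError("alpha must be in (0, 1)")
    if m < 1:
        raise StatsError("m must be >= 1")
    return alpha / m


def odds_ratio(table: ContingencyTable | np.ndarray, alpha: float = 0.05) -> OddsRatioResult:
    """Cross-product odds ratio of a 2x2 table with a Woolf (log-normal) CI.

    Layout: rows = exposure (exposed first), columns = outcome with the
    *case* column first, i.e. [[a, b], [c, d]] -> OR = a*d / (b*c). If any
    cell is zero the Haldane-Anscombe +0.5 correction is applied to all
    four cells and flagged.
    """
    counts = table.counts if isinstance(table, ContingencyTable) else np.asarray(table)
    if counts.shape != (2, 2):
        raise StatsError("odds_ratio needs a 2x2 table")
    if (counts.sum(axis=0) == 0).any() or (counts.sum(axis=1) == 0).any():
        raise StatsError("zero margin; odds ratio undefined")
    work = counts.astype(float)
    corrected = bool((counts == 0).any())
    if corrected:
        work = work + 0.5
    a, b = work[0]
    c, d = work[1]
    or_ = (a * d) / (b * c)
    se = float(np.sqrt((1 / work).sum()))
    z = sps.norm.ppf(1 - alpha / 2)
    logor = np.log(or_)
    return OddsRatioResult(float(or_), float(np.exp(logor - z * se)),
                           float(np.exp(logor + z * se)), se,
                           float(2 * sps.norm.sf(abs(logor) / se)), corrected)


_MAX_ABS_BETA = 15.0


def fit_logistic(y, X: pd.DataFrame, *, add_intercept: bool = True,
                 tol: float = 1e-10, max_iter: int = 100) -> LogisticFit:
    """Maximum-likelihood logistic fit (IRLS) with Wald intervals.

    Raises :class:`SeparationError` when a coefficient runs away
    (|beta| > 15 on the log-odds scale, the classical symptom of complete
    or quasi-complete separation) and a rank-deficiency error for
    collinear designs.
    """
    y = np.asarray(y, dtype=float)
    if not set(np.unique(y)) <= {0.0, 1.0}:
        raise StatsError("response must be binary 0/1")
    if y.min() == y.max():
        raise StatsError("response has a single class")
    X = X.astype(float)
    if add_intercept:
        X = sm.add_constant(X, has_constant="add")
    if len(y) <= X.shape[1]:
        raise StatsError("more parameters than observations")
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        raise StatsError("rank-deficient (collinear) design matrix")
    model = sm.GLM(y, X, family=sm.families.Binomial())
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = model.fit(maxiter=max_iter, tol=tol, scale=1.0)
    params = pd.Series(res.params, index=X.columns)
    runaway = params[params.abs() > _MAX_ABS_BETA]
    if len(runaway):
        err = SeparationError(
            f"separation suspected: |coefficient| > {_MAX_ABS_BETA} for "
            f"{list(runaway.index)}")
        err.predictors = list(runaway.index)
        raise err
    return LogisticFit(params=params, bse=pd.Series(res.bse, index=X.columns),
                       log_likelihood=float(res.llf),
                       iterations=int(getattr(res, "fit_history", {}).get("iteration", max_iter)),
                       converged=bool(res.converged), n_used=len(y))


def genotype_design(cohort: Cohort, locus: Locus, reference: str,
                    coding: str = "codominant") -> tuple[pd.DataFrame, np.ndarray, list[str]]:
    """Design matrix for one locus under a genetic coding.

    codominant: one dummy per non-reference genotype; dominant/recessive/
    additive: collapse by the dosage of the non-reference allele inferred
    from the reference homozygote. Returns (design, complete-case mask,
    warnings).
    """
    if reference not in locus.categories:
        raise StatsError(f"reference {reference!r} not a category of {locus.name}")
    geno = cohort.data[locus.name]
    mask = (geno != MISSING).to_numpy()
    warns: list[str] = []
    if coding == "codominant":
        cols = {}
        for cat in locus.categories:
            if cat == reference:
                continue
            ind = (geno == cat).to_numpy()[mask].astype(float)
            if ind.sum() == 0:
                warns.append(f"category {cat!r} unobserved; term dropped")
                continue
            cols[f"{locus.name}[{cat}]"] = ind
        return pd.DataFrame(cols, index=np.flatnonzero(mask)), mask, warns
    ra, rb = locus.genotype_alleles[reference]
    if ra != rb:
        raise StatsError("dominant/recessive/additive coding needs a homozygous reference")
    dose = np.full(len(cohort), -1.0)
    for cat in locus.categories:
        dose[(geno == cat).to_numpy()] = sum(a != ra for a in locus.genotype_alleles[cat])
    d = dose[mask]
    if coding == "additive":
        col = d
    elif coding == "dominant":
        col = (d >= 1).astype(float)
    elif coding == "recessive":
        col = (d == 2).astype(float)
    else:
        raise StatsError(f"unknown coding {coding!r}")
    return (pd.DataFrame({f"{locus.name}[{coding}]": col}, index=np.flatnonzero(mask)),
            mask, warns)


def univariate_locus_logistic(cohort: Cohort, locus_name: str, reference: str | None = None,
                              coding: str = "codominant") -> LogisticFit:
    """Single-locus logistic regression of case status on genotype."""
    locus = cohort.locus(locus_name)
    ref = reference if reference is not None else locus.categories[-1]
    X, mask, warns = genotype_design(cohort, locus, ref, coding)
    fit = fit_logistic(cohort.phenotype[mask], X)
    fit.warnings.extend(warns)
    return fit


def covariate_design(cohort: Cohort, covariates: list[str]) -> tuple[pd.DataFrame, np.ndarray]:
    """Full-length numeric covariate block (sex coded male=1) + complete-case mask."""
    cols, masks = {}, []
    df = cohort.data
    for cov in covariates:
        if cov not in df.columns:
            raise StatsError(f"covariate {cov!r} not in cohort")
        if cov == "sex":
            v = df[cov]
            masks.append((v != MISSING).to_numpy())
            cols[cov] = (v == "male").to_numpy().astype(float)
        else:
            v = pd.to_numeric(df[cov], errors="coerce")
            masks.append(v.notna().to_numpy())
            cols[cov] = v.to_numpy(dtype=float)
    mask = np.logical_and.reduce(masks) if masks else np.ones(len(df), bool)
    return pd.DataFrame(cols), mask


def adjusted_logistic(cohort: Cohort, exposure: np.ndarray, exposure_mask: np.ndarray,
                      covariates: list[str], name: str = "exposure") -> LogisticFit:
    """Logistic fit of case status on a binary exposure plus covariates.

    ``exposure`` and ``exposure_mask`` are aligned to the full cohort;
    individuals missing the exposure or any covariate are dropped
    (complete case).
    """
    Xc, cmask = covariate_design(cohort, covariates)
    mask = np.asarray(exposure_mask, bool) & cmask
    X = Xc.loc[mask].reset_index(drop=True)
    X.insert(0, name, np.asarray(exposure, dtype=float)[mask])
    return fit_logistic(cohort.phenotype[mask], X)
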