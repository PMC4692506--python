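"""Seeded case-control cohort simulator with a planted two-locus interaction.

The generator emulates the sampling design of a hospital-based
case-control study: a prospective source population is simulated —
genotypes in Hardy-Weinberg proportions and linkage equilibrium at the
control-population allele frequencies, covariates from the population
marginals — disease is assigned by a logistic penetrance model, and the
requested numbers of cases and controls are then drawn from the simulated
population. Because case-control sampling leaves odds ratios invariant
(only the intercept shifts), every odds ratio planted in the penetrance
model is the estimable truth for the sampled cohort; with the disease kept
rare (~10% of the population) the control covariate marginals also stay
close to the population marginals.

The planted effect is a pure two-locus interaction: a log-odds increment
for individuals whose (ACE, FGB T148C) genotype combination falls in the
high-risk cell set {DD*CC, DD*CT, ID*CC}; per-locus main effects default
to zero but are exposed. Covariate penetrance coefficients are derived
from the per-class marginals (log cross-ratio of prevalences for binary
covariates, the linear-discriminant slope (mu1-mu0)/sigma0^2 for age), so
the simulated case group reproduces the target clinical profile.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import calibration
from .cohort import Cohort, Locus, default_loci

DEFAULT_SEED = 20151228  # fixed master seed; any int < 2**31 works


class SimulationError(RuntimeError):
    pass


@dataclass(frozen=True)
class GeneratorConfig:
    """All parameters of the synthetic cohort generator.

    ``allele_freqs`` maps locus name -> {allele: frequency}; genotypes are
    drawn under Hardy-Weinberg proportions from these. ``interaction_log_or``
    is the planted log odds ratio of membership in ``high_risk_cells`` at
    the ``interaction_pair`` loci. ``covariates`` holds per-class marginals
    (class "control" doubles as the population under the rare-disease
    design). ``target_case_fraction`` fixes the population disease
    prevalence; the intercept is calibrated to it by bisection.
    """

    n_controls: int = calibration.N_CONTROLS
    n_cases: int = calibration.N_CASES
    allele_freqs: dict[str, dict[str, float]] = field(
        default_factory=calibration.control_allele_frequencies)
    interaction_pair: tuple[str, str] = ("ACE", "FGB_T148C")
    high_risk_cells: frozenset[tuple[str, str]] = calibration.HIGH_RISK_CELLS
    interaction_log_or: float = math.log(1.57)
    main_effects: dict[str, dict[str, float]] = field(default_factory=dict)
    covariates: dict[str, dict[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in calibration.COVARIATE_SUMMARY.items()})
    include_covariates: bool = True
    target_case_fraction: float = 0.10
    age_bounds: tuple[float, float] = (18.0, 100.0)
    seed: int = DEFAULT_SEED

    def __post_init__(self) -> None:
        if self.n_controls < 1 or self.n_cases < 1:
            raise ValueError("need at least one case and one control")
        if not 0 < self.target_case_fraction < 1:
            raise ValueError("target_case_fraction must be in (0, 1)")
        if math.exp(self.interaction_log_or) <= 0:
            raise ValueError("interaction odds ratio must be positive")
        for name, freqs in self.allele_freqs.items():
            vals = np.array(list(freqs.values()))
            if (vals <= 0).any() or (vals >= 1).any() or abs(vals.sum() - 1) > 1e-9:
                raise ValueError(f"allele frequencies for {name!r} must lie in (0,1) and sum to 1")


def default_config(**overrides) -> GeneratorConfig:
    """Generator configured to the motivating study's published marginals."""
    return replace(GeneratorConfig(), **overrides) if overrides else GeneratorConfig()


def _covariate_coefficients(cov: dict[str, dict[str, float]]) -> dict[str, float]:
    """Penetrance log-odds per covariate from the per-class marginals."""
    ctl, cas = cov["control"], cov["case"]
    coef = {"age": (cas["age_mean"] - ctl["age_mean"]) / ctl["age_sd"] ** 2}
    for key, ck in (("sex", "male"), ("family_history_IS", "family_history_IS"),
                    ("hypertension", "hypertension"), ("diabetes", "diabetes")):
        p0, p1 = ctl[ck], cas[ck]
        coef[key] = math.log(p1 / (1 - p1)) - math.log(p0 / (1 - p0))
    return coef


def _genotype_probs(locus: Locus, freqs: dict[str, float]) -> np.ndarray:
    probs = np.empty(len(locus.categories))
    for i, cat in enumerate(locus.categories):
        a, b = locus.genotype_alleles[cat]
        probs[i] = freqs[a] ** 2 if a == b else 2 * freqs[a] * freqs[b]
    return probs


class _Penetrance:
    """Linear predictor of the disease model, minus the intercept."""

    def __init__(self, config: GeneratorConfig, loci: list[Locus]):
        self.config = config
        self.loci = loci
        self.cov_coef = _covariate_coefficients(config.covariates) if config.include_covariates else {}

    def risk_indicator(self, geno: pd.DataFrame) -> np.ndarray:
        la, lb = self.config.interaction_pair
        pairs = list(zip(geno[la], geno[lb]))
        hr = self.config.high_risk_cells
        return np.fromiter((p in hr for p in pairs), dtype=float, count=len(pairs))

    def eta(self, geno: pd.DataFrame, cov: pd.DataFrame | None) -> np.ndarray:
        out = self.config.interaction_log_or * self.risk_indicator(geno)
        for name, effects in self.config.main_effects.items():
            out += geno[name].map(lambda g: effects.get(g, 0.0)).to_numpy(dtype=float)
        if cov is not None and self.cov_coef:
            c = self.cov_coef
            ctl = self.config.covariates["control"]
            out = out + c["age"] * (cov["age"].to_numpy() - ctl["age_mean"])
            out = out + c["sex"] * (cov["sex"] == "male").to_numpy()
            for key in ("family_history_IS", "hypertension", "diabetes"):
                out = out + c[key] * cov[key].to_numpy(dtype=float)
        return out

    def calibrate_intercept(self, geno: pd.DataFrame, cov: pd.DataFrame | None) -> float:
        """Bisection on beta0 so that mean P(case) hits the target fraction."""
        eta = self.eta(geno, cov)
        target = self.config.target_case_fraction

        def frac(b0: float) -> float:
            return float(np.mean(1 / (1 + np.exp(-(b0 + eta)))))

        lo, hi = -30.0, 30.0
        for _ in range(200):
            mid = (lo + hi) / 2
            if frac(mid) < target:
                lo = mid
            else:
                hi = mid
        return (lo + hi) / 2


def _draw_population(config: GeneratorConfig, loci: list[Locus], n: int,
                     rng: np.random.Generator) -> tuple[pd.DataFrame, pd.DataFrame | None]:
    geno = {}
    for locus in loci:
        probs = _genotype_probs(locus, config.allele_freqs[locus.name])
        idx = rng.choice(len(locus.categories), size=n, p=probs / probs.sum())
        geno[locus.name] = np.array(locus.categories, dtype=object)[idx]
    geno_df = pd.DataFrame(geno)
    cov_df = None
    if config.include_covariates:
        ctl = config.covariates["control"]
        lo, hi = config.age_bounds
        cov_df = pd.DataFrame({
            "age": np.round(rng.normal(ctl["age_mean"], ctl["age_sd"], n).clip(lo, hi)),
            "sex": np.where(rng.random(n) < ctl["male"], "male", "female"),
            "family_history_IS": (rng.random(n) < ctl["family_history_IS"]).astype(int),
            "hypertension": (rng.random(n) < ctl["hypertension"]).astype(int),
            "diabetes": (rng.random(n) < ctl["diabetes"]).astype(int),
        })
    return geno_df, cov_df


_MAX_BATCHES = 40


def generate(config: GeneratorConfig | None = None, seed: int | None = None) -> Cohort:
    """Simulate a case-control cohort (deterministic given the seed).

    Batches of the source population are simulated until the requested
    numbers of cases and controls exist, then exactly ``n_cases`` cases and
    ``n_controls`` controls are sampled. Raises :class:`SimulationError`
    if the limit on resampling batches is hit (pathological configs).
    """
    config = config if config is not None else default_config()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    loci = default_loci()
    penet = _Penetrance(config, loci)

    margin = 1.3
    batch = int(margin * max(config.n_cases / config.target_case_fraction,
                             config.n_controls / (1 - config.target_case_fraction)))
    batch = max(batch, 200)

    genos, covs, phens = [], [], []
    beta0 = None
    n_case = n_ctrl = 0
    for _ in range(_MAX_BATCHES):
        g, c = _draw_population(config, loci, batch, rng)
        if beta0 is None:
            beta0 = penet.calibrate_intercept(g, c)
        p = 1 / (1 + np.exp(-(beta0 + penet.eta(g, c))))
        y = (rng.random(len(g)) < p).astype(int)
        genos.append(g)
        covs.append(c)
        phens.append(y)
        n_case += int(y.sum())
        n_ctrl += int((1 - y).sum())
        if n_case >= config.n_cases and n_ctrl >= config.n_controls:
            break
    else:
        raise SimulationError(
            f"could not obtain {config.n_cases} cases / {config.n_controls} controls "
            f"within {_MAX_BATCHES} population batches of {batch}")

    geno = pd.concat(genos, ignore_index=True)
    phen = np.concatenate(phens)
    cov = pd.concat(covs, ignore_index=True) if config.include_covariates else None

    case_idx = rng.choice(np.flatnonzero(phen == 1), size=config.n_cases, replace=False)
    ctrl_idx = rng.choice(np.flatnonzero(phen == 0), size=config.n_controls, replace=False)
    order = np.concatenate([ctrl_idx, case_idx])

    df = geno.iloc[order].reset_index(drop=True)
    df.insert(0, "phenotype", np.r_[np.zeros(config.n_controls, int), np.ones(config.n_cases, int)])
    subtype = np.array(["control"] * len(df), dtype=object)
    # split synthetic cases across TOAST subtypes at the study's proportions
    sizes = calibration.SUBTYPE_SIZES
    labels = list(sizes)
    probs = np.array([sizes[s] for s in labels], dtype=float)
    subtype[df["phenotype"] == 1] = rng.choice(labels, size=config.n_cases, p=probs / probs.sum())
    df.insert(1, "subtype", subtype)
    if cov is not None:
        df = pd.concat([df, cov.iloc[order].reset_index(drop=True)], axis=1)
    df.insert(0, "id", [f"S{i:06d}" for i in range(len(df))])
    return Cohort(df, loci)


def null_shuffle(cohort: Cohort, seed: int) -> Cohort:
    """Permute the outcome labels uniformly at random.

    Phenotype and subtype travel together (the subtype annotates the case
    label); genotypes and covariates are untouched, so case/control totals
    are preserved and any genotype-phenotype association is broken.
    """
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(cohort))
    df = cohort.data.copy()
    df["phenotype"] = df["phenotype"].to_numpy()[perm]
    df["subtype"] = df["subtype"].to_numpy()[perm]
    return Cohort(df, cohort.loci)
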