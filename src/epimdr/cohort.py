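"""Cohort data model and tabular I/O.

A :class:`Cohort` is a case-control sample: one row per individual with a
binary phenotype (1 = case, 0 = control), categorical genotypes at a set of
named loci, a small covariate block (age, sex, family history of ischemic
stroke, hypertension history, diabetes history) and an optional etiologic
stroke-subtype label for cases (TOAST classes LAA, SAO, CE, SOE, SUE).

Loci are assay-level categorical variables, not sequence variants: a
biallelic SNP or insertion/deletion has three genotype categories, a
three-allele polymorphism such as ApoE epsilon2-4 has six. The on-disk
format is a wide, comma-separated, UTF-8 table with a header row, one
column per locus, and ``NA`` as the missing code.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MISSING = "NA"

SUBTYPES = ("LAA", "SAO", "CE", "SOE", "SUE")

COVARIATE_COLUMNS = ("age", "sex", "family_history_IS", "hypertension", "diabetes")

SEX_LEVELS = ("female", "male")


class CohortError(ValueError):
    """Schema or validation failure while building a cohort."""


@dataclass(frozen=True)
class Locus:
    """A named polymorphism with an ordered set of genotype categories.

    ``genotype_alleles`` maps each category to its (unordered) allele pair;
    it drives allele counting for Hardy-Weinberg testing and allele-dosage
    genotype codings.
    """

    name: str
    categories: tuple[str, ...]
    genotype_alleles: dict[str, tuple[str, str]] = field(compare=False)

    def __post_init__(self) -> None:
        if len(self.categories) == 0 or len(set(self.categories)) != len(self.categories):
            raise CohortError(f"locus {self.name!r}: categories must be unique and non-empty")
        if set(self.genotype_alleles) != set(self.categories):
            raise CohortError(f"locus {self.name!r}: genotype_alleles must cover the categories")
        arity = self.allele_arity
        expected = arity * (arity + 1) // 2
        if len(self.categories) != expected:
            raise CohortError(
                f"locus {self.name!r}: {arity} alleles imply {expected} genotype "
                f"categories, got {len(self.categories)}"
            )

    @property
    def alleles(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for cat in self.categories:
            for a in self.genotype_alleles[cat]:
                seen.setdefault(a)
        return tuple(seen)

    @property
    def allele_arity(self) -> int:
        return len(self.alleles)


def biallelic_locus(name: str, allele_a: str, allele_b: str) -> Locus:
    """Three-category locus ordered homozygous-A, heterozygous, homozygous-B."""
    cats = (allele_a * 2, allele_a + allele_b, allele_b * 2)
    pairs = {cats[0]: (allele_a, allele_a), cats[1]: (allele_a, allele_b), cats[2]: (allele_b, allele_b)}
    return Locus(name, cats, pairs)


def _apoe_locus() -> Locus:
    alleles = ("e2", "e3", "e4")
    cats, pairs = [], {}
    for i, a in enumerate(alleles):
        for b in alleles[i:]:
            cats.append(a + b)
            pairs[a + b] = (a, b)
    return Locus("APOE", tuple(cats), pairs)


def default_loci() -> list[Locus]:
    """The six candidate polymorphisms of the ischemic-stroke panel.

    Order matters: it is the locus numbering used throughout reports
    (1 = ACE I/D, 2 = FGB T148C, 3 = FGB A455G, 4 = MTHFR C677T,
    5 = ApoE, 6 = eNOS G894T). Category order follows the conventional
    presentation (variant homozygote, heterozygote, wild-type homozygote).
    """
    ace = Locus("ACE", ("DD", "ID", "II"),
                {"DD": ("D", "D"), "ID": ("I", "D"), "II": ("I", "I")})
    fgb148 = Locus("FGB_T148C", ("TT", "CT", "CC"),
                   {"TT": ("T", "T"), "CT": ("C", "T"), "CC": ("C", "C")})
    fgb455 = Locus("FGB_A455G", ("AA", "GA", "GG"),
                   {"AA": ("A", "A"), "GA": ("G", "A"), "GG": ("G", "G")})
    mthfr = Locus("MTHFR_C677T", ("TT", "CT", "CC"),
                  {"TT": ("T", "T"), "CT": ("C", "T"), "CC": ("C", "C")})
    enos = Locus("ENOS_G894T", ("TT", "GT", "GG"),
                 {"TT": ("T", "T"), "GT": ("G", "T"), "GG": ("G", "G")})
    return [ace, fgb148, fgb455, mthfr, _apoe_locus(), enos]


@dataclass
class Cohort:
    """Individuals x loci genotype matrix plus phenotype and covariates.

    ``data`` holds one row per individual with columns ``id``, ``phenotype``
    (0/1), ``subtype``, one column per locus, and the covariate block. The
    frame is validated on construction; genotype values must be members of
    the locus categories or the ``NA`` missing code.
    """

    data: pd.DataFrame
    loci: list[Locus]

    def __post_init__(self) -> None:
        df = self.data
        required = ["id", "phenotype", "subtype"] + [l.name for l in self.loci]
        for col in required:
            if col not in df.columns:
                raise CohortError(f"missing column {col!r}")
        if len(df) == 0:
            raise CohortError("empty cohort")
        phen = df["phenotype"]
        if not phen.isin([0, 1]).all():
            raise CohortError("phenotype must be 0 (control) or 1 (case)")
        self.data = df = df.reset_index(drop=True)
        for loc in self.loci:
            vals = df[loc.name].astype(str)
            bad = ~(vals.isin(loc.categories) | (vals == MISSING))
            if bad.any():
                row = int(np.flatnonzero(bad.to_numpy())[0])
                raise CohortError(
                    f"row {row + 2}: invalid genotype {vals.iloc[row]!r} at locus {loc.name!r}"
                    " (line number counts the header)"
                )
            df[loc.name] = vals
        sub = df["subtype"].astype(str)
        bad_sub = ~sub.isin(SUBTYPES + ("control", MISSING))
        if bad_sub.any():
            row = int(np.flatnonzero(bad_sub.to_numpy())[0])
            raise CohortError(f"row {row + 2}: unknown subtype {sub.iloc[row]!r}")
        if ((sub.isin(SUBTYPES)) & (phen == 0)).any():
            raise CohortError("subtype labels are only valid for cases")
        df["subtype"] = sub
        for col in COVARIATE_COLUMNS:
            if col not in df.columns:
                continue
            if col == "sex":
                sx = df[col].astype(str)
                if not (sx.isin(SEX_LEVELS) | (sx == MISSING)).all():
                    raise CohortError("sex must be 'male', 'female' or NA")
                df[col] = sx
            else:
                vals = pd.to_numeric(df[col], errors="coerce")
                known = df[col].astype(str) != MISSING
                if vals[known].isna().any():
                    raise CohortError(f"non-numeric value in covariate {col!r}")
                if col == "age" and ((vals < 0) | (vals > 130)).any():
                    raise CohortError("age out of range [0, 130]")
                if col != "age" and not vals.dropna().isin([0, 1]).all():
                    raise CohortError(f"covariate {col!r} must be 0/1 or NA")
                df[col] = vals.astype(np.float64)

    # -- basic accessors -------------------------------------------------

    def __len__(self) -> int:
        return len(self.data)

    @property
    def n_cases(self) -> int:
        return int((self.data["phenotype"] == 1).sum())

    @property
    def n_controls(self) -> int:
        return int((self.data["phenotype"] == 0).sum())

    @property
    def phenotype(self) -> np.ndarray:
        return self.data["phenotype"].to_numpy(dtype=np.int64)

    def locus(self, name: str) -> Locus:
        for loc in self.loci:
            if loc.name == name:
                return loc
        raise CohortError(f"unknown locus {name!r}")

    def subset(self, mask: np.ndarray) -> "Cohort":
        return Cohort(self.data.loc[np.asarray(mask)].reset_index(drop=True), self.loci)

    def stratum(self, name: str | None) -> "Cohort":
        """All controls plus the cases of one subtype (or all cases)."""
        if name in (None, "overall"):
            return self
        if name not in SUBTYPES:
            raise CohortError(f"unknown subtype stratum {name!r}")
        keep = (self.data["phenotype"] == 0) | (self.data["subtype"] == name)
        return self.subset(keep.to_numpy())

    def genotype_codes(self, names: list[str] | tuple[str, ...]) -> tuple[np.ndarray, tuple[int, ...]]:
        """Integer-code genotypes at the named loci; missing -> -1.

        Returns (n x m) int array and the per-locus category counts.
        """
        cols, sizes = [], []
        for nm in names:
            loc = self.locus(nm)
            cat = pd.Categorical(self.data[nm], categories=list(loc.categories))
            cols.append(cat.codes.astype(np.int64))
            sizes.append(len(loc.categories))
        return np.column_stack(cols), tuple(sizes)


@dataclass
class ContingencyTable:
    """Genotype (or genotype-combination) counts by case/control status."""

    row_labels: list
    col_labels: list
    counts: np.ndarray
    n_excluded: int = 0

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (len(self.row_labels), len(self.col_labels)):
            raise ValueError("counts shape does not match labels")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def row_margins(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def col_margins(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_frame(self) -> pd.DataFrame:
        labels = [" x ".join(r) if isinstance(r, tuple) else r for r in self.row_labels]
        return pd.DataFrame(self.counts, index=labels, columns=self.col_labels)

    def to_tsv(self, path) -> None:
        df = self.to_frame()
        df.loc["__total__"] = self.col_margins
        df["__total__"] = df.sum(axis=1)
        df.to_csv(path, sep="\t")


# -- I/O -----------------------------------------------------------------


def read_cohort(path, loci: list[Locus] | None = None,
                column_map: dict[str, str] | None = None) -> Cohort:
    """Read a cohort CSV (or the same layout from a spreadsheet export).

    ``column_map`` maps on-disk column names to the canonical names used by
    :class:`Cohort` (e.g. a supplementary-table export whose genotype
    columns carry assay labels); canonical files need no map.
    """
    loci = loci if loci is not None else default_loci()
    if str(path).endswith((".xlsx", ".xlsm")):
        # supplementary-table style spreadsheet export, same schema mapping
        df = pd.read_excel(path, dtype=str, keep_default_na=False)
    else:
        try:
            df = pd.read_csv(path, dtype=str, keep_default_na=False)
        except pd.errors.EmptyDataError:
            raise CohortError(f"empty cohort file: {path}") from None
    if len(df) == 0:
        raise CohortError(f"cohort file has a header but no rows: {path}")
    if column_map:
        missing = [src for src in column_map if src not in df.columns]
        if missing:
            raise CohortError(f"mapped columns not in file: {missing}")
        df = df.rename(columns=column_map)
    required = ["id", "phenotype", "subtype"] + [l.name for l in loci]
    absent = [c for c in required if c not in df.columns]
    if absent:
        raise CohortError(f"missing required columns: {absent}")
    df["phenotype"] = pd.to_numeric(df["phenotype"], errors="raise")
    return Cohort(df, loci)


def write_cohort(cohort: Cohort, path) -> None:
    """Write the cohort in the canonical CSV dialect (round-trip lossless)."""
    df = cohort.data.copy()
    if "age" in df.columns:
        # keep integral ages integral so the round trip is textual too
        age = df["age"]
        if age.notna().all() and (age == age.round()).all():
            df["age"] = age.astype(np.int64)
    for col in ("family_history_IS", "hypertension", "diabetes"):
        if col in df.columns and df[col].notna().all():
            df[col] = df[col].astype(np.int64)
    df.to_csv(path, index=False, na_rep=MISSING)


def genotype_table(cohort: Cohort, loci: str | list[str],
                   stratum: str | None = None) -> ContingencyTable:
    """Case/control genotype counts at one locus or a combination of loci.

    For multiple loci the rows are the Cartesian product of category lists
    (input order). A subtype stratum keeps all controls and restricts cases
    to that subtype. Individuals missing any required genotype are excluded
    and counted in ``n_excluded``.
    """
    names = [loci] if isinstance(loci, str) else list(loci)
    sub = cohort.stratum(stratum)
    codes, sizes = sub.genotype_codes(names)
    ok = (codes >= 0).all(axis=1)
    phen = sub.phenotype
    cell = np.zeros(len(sub), dtype=np.int64)
    for j, size in enumerate(sizes):
        cell = cell * size + codes[:, j]
    n_cells = int(np.prod(sizes))
    counts = np.zeros((n_cells, 2), dtype=np.int64)
    for col, cls in enumerate((0, 1)):
        sel = ok & (phen == cls)
        counts[:, col] = np.bincount(cell[sel], minlength=n_cells)
    cats = [list(cohort.locus(nm).categories) for nm in names]
    rows = [t if len(t) > 1 else t[0] for t in itertools.product(*cats)]
    return ContingencyTable(rows, ["control", "case"], counts,
                            n_excluded=int((~ok).sum()))
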