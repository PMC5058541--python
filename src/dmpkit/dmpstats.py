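"""Habitat comparisons and the nested binomial GLM for diploid male proportion.

The population-level analysis relates DMP (diploid over all genotyped males)
to habitat type (mainland / island / captive) and to two diversity covariates
nested within habitat: overall allelic richness and the number of private
alleles.  The model is a binomial GLM with logit link on per-population
(n_diploid, n_haploid) counts; terms are tested with type-II analysis of
deviance (likelihood-ratio chi-square), respecting marginality.  Because the
nesting makes some design columns aliased (a covariate constant within a
habitat, or a habitat stratum saturated by its intercept and one slope),
rank-deficient columns are detected in column order and reported, never
silently absorbed.

Nonparametric habitat comparisons (Kruskal-Wallis with tie correction),
pooled-SD Cohen's d effect sizes, Yates-corrected two-proportion tests,
Welch t tests and Benjamini-Hochberg FDR adjustment round out the layer.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

HABITATS = ("mainland", "island", "captive")

__all__ = [
    "PopulationRecord",
    "HabitatModelResult",
    "kruskal_wallis",
    "cohens_d",
    "effect_magnitude",
    "two_proportion_yates",
    "welch_t",
    "bh_adjust",
    "fit_dmp_glm",
    "lr_type2_tests",
    "records_from_frame",
]


@dataclass(frozen=True)
class PopulationRecord:
    """One population's male counts and diversity covariates."""

    population: str
    habitat: str
    n_haploid: int
    n_diploid: int
    allelic_richness: float
    private_alleles: float

    def __post_init__(self) -> None:
        if self.habitat not in HABITATS:
            raise ValueError(f"habitat must be one of {HABITATS}")
        if self.n_haploid < 0 or self.n_diploid < 0:
            raise ValueError("counts must be non-negative")


def records_from_frame(df: pd.DataFrame) -> list[PopulationRecord]:
    return [
        PopulationRecord(
            population=str(r["population"]),
            habitat=str(r["habitat"]),
            n_haploid=int(r["n_haploid"]),
            n_diploid=int(r["n_diploid"]),
            allelic_richness=float(r["allelic_richness"]),
            private_alleles=float(r["private_alleles"]),
        )
        for _, r in df.iterrows()
    ]


def kruskal_wallis(*groups: Sequence[float]) -> tuple[float, int, float]:
    """Kruskal-Wallis H with midranks and tie correction.

    Returns (H, df, p) with df = number of groups - 1 and p from the
    chi-square approximation.  All observations identical gives H = 0.
    """
    if len(groups) < 2:
        raise ValueError("need >=2 groups")
    if any(len(g) == 0 for g in groups):
        raise ValueError("empty group")
    pooled = np.concatenate([np.asarray(g, dtype=float) for g in groups])
    df = len(groups) - 1
    if np.all(pooled == pooled[0]):
        return 0.0, df, 1.0
    H, p = sps.kruskal(*groups)
    return float(H), df, float(p)


def cohens_d(group1: Sequence[float], group2: Sequence[float]) -> float:
    """Pooled-SD standardized mean difference (sign follows argument order)."""
    a = np.asarray(group1, dtype=float)
    b = np.asarray(group2, dtype=float)
    n1, n2 = len(a), len(b)
    if n1 < 2 or n2 < 1 or n1 + n2 < 3:
        raise ValueError("cohens_d needs n1 >= 2 and n2 >= 1")
    v1 = a.var(ddof=1)
    v2 = b.var(ddof=1) if n2 > 1 else 0.0
    sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
    if sp2 <= 0:
        raise ValueError("zero pooled variance")
    return float((a.mean() - b.mean()) / np.sqrt(sp2))


def effect_magnitude(d: float) -> str:
    """Conventional |d| bands: negligible < 0.2 <= small < 0.5 <= medium < 0.8 <= large."""
    a = abs(d)
    if a < 0.2:
        return "negligible"
    if a < 0.5:
        return "small"
    if a < 0.8:
        return "medium"
    return "large"


def two_proportion_yates(
    k1: int, n1: int, k2: int, n2: int
) -> tuple[float, int, float]:
    """Continuity-corrected chi-square comparison of two proportions.

    The correction term (|O - E| - 0.5) is truncated at zero, so identical
    tables give exactly 0.
    """
    if not (0 <= k1 <= n1 and 0 <= k2 <= n2) or n1 == 0 or n2 == 0:
        raise ValueError("invalid counts")
    obs = np.array([[k1, n1 - k1], [k2, n2 - k2]], dtype=float)
    if np.any(obs.sum(axis=0) == 0):
        raise ValueError("a margin of the 2x2 table is zero")
    exp = np.outer(obs.sum(axis=1), obs.sum(axis=0)) / obs.sum()
    chi2 = float((np.maximum(np.abs(obs - exp) - 0.5, 0.0) ** 2 / exp).sum())
    return chi2, 1, float(sps.chi2.sf(chi2, 1))


def welch_t(
    group1: Sequence[float], group2: Sequence[float]
) -> tuple[float, float, float]:
    """Unequal-variance t test with Welch-Satterthwaite df; two-sided p."""
    a = np.asarray(group1, dtype=float)
    b = np.asarray(group2, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs n >= 2")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        raise ValueError("both variances are zero")
    res = sps.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, order-preserving."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values outside [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# Nested binomial GLM


@dataclass
class HabitatModelResult:
    """Fit of the nested habitat GLM with aliasing report."""

    params: pd.Series
    deviance: float
    null_deviance: float
    df_model: int
    column_names: list[str]
    dropped_columns: list[str]
    terms: dict[str, list[str]]  # term -> surviving column names
    converged: bool
    separation_flag: bool
    lr_table: Optional[pd.DataFrame] = None
    records: list[PopulationRecord] = field(default_factory=list)


def _design(
    records: Sequence[PopulationRecord], include: Sequence[str]
) -> tuple[np.ndarray, list[str], dict[str, list[int]]]:
    habitats = [h for h in HABITATS if any(r.habitat == h for r in records)]
    ind = np.array(
        [[1.0 * (r.habitat == h) for h in habitats] for r in records]
    )
    rich = np.array([r.allelic_richness for r in records])
    priv = np.array([r.private_alleles for r in records])
    cols: list[np.ndarray] = []
    names: list[str] = []
    term_cols: dict[str, list[int]] = {}
    blocks = {
        "Habit": (ind, [f"Habit[{h}]" for h in habitats]),
        "Habit:All_rich": (ind * rich[:, None], [f"Habit[{h}]:All_rich" for h in habitats]),
        "Habit:Priv_all": (ind * priv[:, None], [f"Habit[{h}]:Priv_all" for h in habitats]),
    }
    for term in include:
        block, bnames = blocks[term]
        term_cols[term] = list(range(len(names), len(names) + block.shape[1]))
        cols.append(block)
        names.extend(bnames)
    X = np.column_stack(cols) if cols else np.ones((len(records), 1))
    return X, names, term_cols


def _drop_aliased(X: np.ndarray, names: list[str]) -> tuple[list[int], list[str]]:
    """Greedy in-column-order rank selection: keep a column iff it raises rank."""
    keep: list[int] = []
    dropped: list[str] = []
    for j in range(X.shape[1]):
        cand = X[:, keep + [j]]
        if np.linalg.matrix_rank(cand, tol=1e-9 * max(1.0, np.abs(X).max())) > len(keep):
            keep.append(j)
        else:
            dropped.append(names[j])
    return keep, dropped


def _fit_glm(
    records: Sequence[PopulationRecord], include: Sequence[str], tol: float = 1e-10
):
    X, names, term_cols = _design(records, include)
    keep, dropped = _drop_aliased(X, names)
    y = np.array([[r.n_diploid, r.n_haploid] for r in records], dtype=float)
    model = sm.GLM(y, X[:, keep], family=sm.families.Binomial())
    import warnings

    from statsmodels.tools.sm_exceptions import PerfectSeparationWarning

    with warnings.catch_warnings():
        # separation is detected and reported via the result's flag instead
        warnings.simplefilter("ignore", PerfectSeparationWarning)
        fit = model.fit(maxiter=200, tol=tol)
    surviving = {
        t: [names[j] for j in cols if j in keep] for t, cols in term_cols.items()
    }
    return fit, [names[j] for j in keep], dropped, surviving


def fit_dmp_glm(
    records: Sequence[PopulationRecord],
    include: Sequence[str] = ("Habit", "Habit:All_rich", "Habit:Priv_all"),
) -> HabitatModelResult:
    """Fit the nested logit-binomial model of DMP on habitat and diversity.

    Design: habitat indicator intercepts plus habitat-specific slopes for
    allelic richness and private alleles.  Rank-deficient columns are
    detected in column order and dropped with a report; the likelihood is
    maximized by IRLS.  Complete separation (a fitted proportion pinned at
    0 or 1 with exploding coefficients) is flagged rather than hidden.
    """
    if len({r.habitat for r in records}) < 2:
        raise ValueError("need >=2 habitats")
    if sum(r.n_diploid + r.n_haploid for r in records) == 0:
        raise ValueError("no male counts")
    fit, kept_names, dropped, surviving = _fit_glm(records, include)
    if not fit.converged:
        history = getattr(fit, "fit_history", {})
        raise RuntimeError(f"GLM did not converge (deviance trace: {history.get('deviance')})")
    separation = bool(np.any(np.abs(fit.params) > 15))
    return HabitatModelResult(
        params=pd.Series(fit.params, index=kept_names),
        deviance=float(fit.deviance),
        null_deviance=float(fit.null_deviance),
        df_model=len(kept_names),
        column_names=kept_names,
        dropped_columns=dropped,
        terms=surviving,
        converged=bool(fit.converged),
        separation_flag=separation,
        records=list(records),
    )


def _contains(term_a: str, term_b: str) -> bool:
    """Marginality: term_a contains term_b if b's factors are a subset of a's."""
    fa = set(term_a.split(":"))
    fb = set(term_b.split(":"))
    return fb < fa


def lr_type2_tests(
    full: HabitatModelResult, records: Optional[Sequence[PopulationRecord]] = None
) -> pd.DataFrame:
    """Type-II likelihood-ratio table for the nested habitat model.

    For each term T, the comparison model contains every term that does not
    contain T (marginality); T is tested by the deviance difference between
    that model with and without T.  Degrees of freedom are the number of
    surviving (non-aliased) columns removed, so aliasing in one stratum
    lowers the df of its term.  Terms whose columns are all aliased are
    reported with df 0 and no test.
    """
    records = list(records if records is not None else full.records)
    all_terms = list(full.terms)
    rows = []
    for term in all_terms:
        base_terms = [t for t in all_terms if t != term and not _contains(t, term)]
        with_terms = base_terms + [term]
        fit_with, _, _, surv_with = _fit_glm(records, with_terms)
        n_cols_term = len(surv_with[term])
        if n_cols_term == 0:
            rows.append(
                {"term": term, "lr_chi2": np.nan, "df": 0, "p": np.nan,
                 "note": "all columns aliased; test omitted"}
            )
            continue
        if base_terms:
            fit_without, _, _, _ = _fit_glm(records, base_terms)
            dev_without = fit_without.deviance
            df_without = len(fit_without.params)
        else:
            null_model = sm.GLM(
                np.array([[r.n_diploid, r.n_haploid] for r in records], dtype=float),
                np.ones((len(records), 1)),
                family=sm.families.Binomial(),
            ).fit()
            dev_without = null_model.deviance
            df_without = 1
        lr = float(dev_without - fit_with.deviance)
        df = len(fit_with.params) - df_without
        if df <= 0:
            rows.append(
                {"term": term, "lr_chi2": np.nan, "df": 0, "p": np.nan,
                 "note": "no surviving columns beyond comparison model"}
            )
            continue
        rows.append(
            {
                "term": term,
                "lr_chi2": lr,
                "df": df,
                "p": float(sps.chi2.sf(lr, df)),
                "note": "",
            }
        )
    table = pd.DataFrame(rows)
    full.lr_table = table
    return table
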