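"""Per-locus and per-population diversity statistics on mixed-ploidy samples.

Heterozygosities, exact Hardy-Weinberg tests (Levene's conditional
distribution, enumerated or Monte-Carlo), genotypic linkage-disequilibrium
permutation tests, Fisher's combination across populations, null-allele
frequency estimation by EM, rarefied allelic richness and private-allele
counts, assembled into one summary table per dataset.

Haploid males carry a single gene copy: they contribute to allele counts and
rarefaction but never to observed heterozygosity or HW/LD tests, which are
defined on diploids only.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .popdata import (
    AlleleFrequencyTable,
    GenotypeDataset,
    Individual,
    PopulationSample,
    allele_frequencies,
    merge_haploid_pairs,
)
from . import ploidy as _ploidy

__all__ = [
    "DiversitySummary",
    "observed_heterozygosity",
    "expected_heterozygosity_unbiased",
    "hw_exact_test",
    "genotypic_ld_test",
    "fisher_combine",
    "null_allele_em",
    "rarefied_allelic_richness",
    "private_allele_counts",
    "population_summary",
]


def _diploid_genotypes(pop: PopulationSample, locus: str) -> list[tuple[int, int]]:
    out = []
    for ind in pop.individuals:
        g = ind.genotype(locus)
        if len(g) == 2:
            out.append((min(g), max(g)))
    return out


def observed_heterozygosity(pop: PopulationSample, locus: str) -> float:
    """Fraction of typed diploid individuals with two distinct alleles.

    Haploids are excluded (their heterozygosity is undefined).  Returns NaN
    when no diploid is typed at the locus.
    """
    genos = _diploid_genotypes(pop, locus)
    if not genos:
        return float("nan")
    return sum(1 for a, b in genos if a != b) / len(genos)


def expected_heterozygosity_unbiased(freqs: AlleleFrequencyTable) -> float:
    """Nei's unbiased expected heterozygosity on gene copies.

    He = n/(n-1) * (1 - sum p_i^2) with n the number of gene copies,
    truncated at 1.
    """
    n = freqs.n_copies
    if n < 2:
        raise ValueError("expected heterozygosity needs >=2 gene copies")
    he = n / (n - 1) * (1.0 - freqs.homozygosity)
    return min(he, 1.0)


# ---------------------------------------------------------------------------
# Exact Hardy-Weinberg test (Levene's conditional distribution)


def _log_table_prob(
    table: dict[tuple[int, int], int], allele_counts: dict[int, int], n: int
) -> float:
    """log P(genotype table | allele counts) under random pairing of copies."""
    two_n = 2 * n
    h = sum(c for (a, b), c in table.items() if a != b)
    lp = (
        math.lgamma(n + 1)
        - math.lgamma(two_n + 1)
        + sum(math.lgamma(c + 1) for c in allele_counts.values())
        + h * math.log(2.0)
        - sum(math.lgamma(c + 1) for c in table.values())
    )
    return lp


def _enumerate_tables(allele_counts: dict[int, int], cap: int):
    """Yield all genotype tables with the given allele-count margins.

    Raises OverflowError once more than ``cap`` tables have been produced.
    """
    alleles = sorted(allele_counts)
    k = len(alleles)
    produced = 0

    def rec(idx: int, rem: list[int], cells: dict[tuple[int, int], int]):
        nonlocal produced
        if idx == k:
            produced += 1
            if produced > cap:
                raise OverflowError("table count exceeds enumeration cap")
            yield dict(cells)
            return
        ai = alleles[idx]
        r = rem[idx]
        # distribute r copies of allele ai into (ai,ai) pairs and hets with j>idx
        def comp(j: int, left: int):
            if j == k:
                if left == 0:
                    yield from rec(idx + 1, rem, cells)
                return
            aj = alleles[j]
            for f in range(min(left, rem[j]) + 1):
                rem[j] -= f
                if f:
                    cells[(ai, aj)] = f
                yield from comp(j + 1, left - f)
                if f:
                    del cells[(ai, aj)]
                rem[j] += f

        for f_ii in range(r // 2 + 1):
            if f_ii:
                cells[(ai, ai)] = f_ii
            yield from comp(idx + 1, r - 2 * f_ii)
            if f_ii:
                del cells[(ai, ai)]

    yield from rec(0, [allele_counts[a] for a in alleles], {})


def hw_exact_test(
    pop: PopulationSample,
    locus: str,
    n_mc: int = 100_000,
    seed: int = 0,
    enum_cap: int = 1_000_000,
) -> float:
    """Exact probability test for Hardy-Weinberg proportions at one locus.

    Conditional on the observed allele counts, genotype tables follow
    Levene's distribution; the p-value is the total probability of tables no
    more probable than the observed one.  Tables are enumerated completely
    when their number is at most ``enum_cap``; otherwise ``n_mc`` random
    pairings of the gene copies are drawn and the p-value is estimated as
    (k + 1)/(n_mc + 1).

    Monomorphic loci (or fewer than two typed diploids) return p = 1.
    """
    genos = _diploid_genotypes(pop, locus)
    n = len(genos)
    if n < 2:
        return 1.0
    allele_counts: dict[int, int] = {}
    table: dict[tuple[int, int], int] = {}
    for a, b in genos:
        allele_counts[a] = allele_counts.get(a, 0) + 1
        allele_counts[b] = allele_counts.get(b, 0) + 1
        table[(a, b)] = table.get((a, b), 0) + 1
    if len(allele_counts) < 2:
        return 1.0

    lp_obs = _log_table_prob(table, allele_counts, n)
    tol = 1e-9

    try:
        total = 0.0
        for t in _enumerate_tables(allele_counts, enum_cap):
            lp = _log_table_prob(t, allele_counts, n)
            if lp <= lp_obs + tol:
                total += math.exp(lp)
        return min(total, 1.0)
    except OverflowError:
        pass

    rng = np.random.default_rng(seed)
    copies = np.repeat(
        np.fromiter(allele_counts.keys(), dtype=np.int64),
        np.fromiter(allele_counts.values(), dtype=np.int64),
    )
    lgam = np.cumsum(np.log(np.arange(1, n + 2)))  # lgamma(i+1) for i>=1
    lgam = np.concatenate([[0.0], lgam])  # index by count
    const = (
        math.lgamma(n + 1)
        - math.lgamma(2 * n + 1)
        + sum(math.lgamma(c + 1) for c in allele_counts.values())
    )
    k_le = 0
    for _ in range(n_mc):
        perm = rng.permutation(copies).reshape(n, 2)
        lo = perm.min(axis=1)
        hi = perm.max(axis=1)
        code = lo * 100_000 + hi
        _, counts = np.unique(code, return_counts=True)
        h = int((lo != hi).sum())
        lp = const + h * math.log(2.0) - float(lgam[counts].sum())
        if lp <= lp_obs + tol:
            k_le += 1
    return (k_le + 1) / (n_mc + 1)


# ---------------------------------------------------------------------------
# Genotypic linkage disequilibrium


def _g_statistic(xcode: np.ndarray, ycode: np.ndarray, kx: int, ky: int) -> float:
    """Log-likelihood-ratio G on the genotype x genotype contingency table.

    ``xcode``/``ycode`` are dense integer codes in [0, kx) / [0, ky); the
    margins (hence the expected table) are permutation-invariant, so callers
    precompute nothing else.
    """
    tab = np.bincount(xcode * ky + ycode, minlength=kx * ky).astype(float).reshape(kx, ky)
    exp = np.outer(tab.sum(axis=1), tab.sum(axis=0)) / tab.sum()
    mask = tab > 0
    return float(2.0 * (tab[mask] * np.log(tab[mask] / exp[mask])).sum())


def genotypic_ld_test(
    pop: PopulationSample,
    locusA: str,
    locusB: str,
    n_perm: int = 10_000,
    seed: int = 0,
) -> float:
    """Permutation test of genotypic association between two loci.

    The G statistic is computed on the genotype-by-genotype table over
    diploids typed at both loci; the null distribution is obtained by
    permuting one locus's genotypes across individuals.  Either locus
    monomorphic returns p = 1.
    """
    pairs = []
    for ind in pop.individuals:
        ga, gb = ind.genotype(locusA), ind.genotype(locusB)
        if len(ga) == 2 and len(gb) == 2:
            pairs.append((tuple(sorted(ga)), tuple(sorted(gb))))
    if len(pairs) < 2:
        return 1.0
    xa, ka = pd.factorize(pd.Index([a for a, _ in pairs]))
    xb, kb = pd.factorize(pd.Index([b for _, b in pairs]))
    ka, kb = len(ka), len(kb)
    if ka < 2 or kb < 2:
        return 1.0
    xa = np.asarray(xa)
    xb = np.asarray(xb)
    g_obs = _g_statistic(xa, xb, ka, kb)
    rng = np.random.default_rng(seed)
    k_ge = 0
    for _ in range(n_perm):
        if _g_statistic(xa, rng.permutation(xb), ka, kb) >= g_obs - 1e-12:
            k_ge += 1
    return (k_ge + 1) / (n_perm + 1)


def fisher_combine(pvalues: Sequence[float]) -> tuple[float, int, float]:
    """Fisher's method: chi2 = -2 sum(ln p), df = 2 * len(pvalues).

    Inputs must lie in (0, 1]; Monte-Carlo p-values floored at 1/(n+1)
    upstream keep the statistic finite.
    """
    ps = [float(p) for p in pvalues]
    if not ps:
        raise ValueError("no p-values to combine")
    if any(p <= 0.0 or p > 1.0 for p in ps):
        raise ValueError("p-values must be in (0, 1]")
    chi2 = -2.0 * sum(math.log(p) for p in ps)
    df = 2 * len(ps)
    return chi2, df, float(sps.chi2.sf(chi2, df))


# ---------------------------------------------------------------------------
# Null alleles (EM)


def null_allele_em(
    pop: PopulationSample,
    locus: str,
    tol: float = 1e-8,
    max_iter: int = 10_000,
) -> tuple[float, dict[int, float]]:
    """EM estimate of the null-allele frequency at one locus.

    Model: visible alleles i with frequency p_i plus a null allele with
    frequency r, genotypes in Hardy-Weinberg proportions.  An apparent
    homozygote i/i pools true i/i with i/null; a blank (diploid typed at
    other loci but missing here) is null/null.  The E-step apportions the
    apparent counts with the current frequencies, the M-step re-normalizes
    gene-copy counts; iterated to ``tol`` on the parameter change.

    Returns (r_hat, visible allele frequency dict).
    """
    genos = _diploid_genotypes(pop, locus)
    n_blank = sum(
        1
        for ind in pop.individuals
        if not ind.is_typed(locus)
        and any(len(g) == 2 for g in ind.genotypes.values())
    )
    if len(genos) < 2:
        raise ValueError("null_allele_em needs >=2 typed diploids")

    het: dict[tuple[int, int], int] = {}
    hom: dict[int, int] = {}
    for a, b in genos:
        if a == b:
            hom[a] = hom.get(a, 0) + 1
        else:
            het[(a, b)] = het.get((a, b), 0) + 1

    alleles = sorted(set([a for ab in het for a in ab]) | set(hom))
    n_ind = len(genos) + n_blank
    two_n = 2 * n_ind

    # init from raw counts with a small null mass
    counts = {a: 0.0 for a in alleles}
    for (a, b), c in het.items():
        counts[a] += c
        counts[b] += c
    for a, c in hom.items():
        counts[a] += 2 * c
    r = max(2 * n_blank / two_n, 0.01)
    total = sum(counts.values())
    p = {a: (1 - r) * counts[a] / total for a in alleles}

    def loglik(r_: float, p_: dict[int, float]) -> float:
        ll = 0.0
        for (a, b), c in het.items():
            ll += c * math.log(2 * p_[a] * p_[b])
        for a, c in hom.items():
            ll += c * math.log(p_[a] ** 2 + 2 * p_[a] * r_)
        if n_blank:
            ll += n_blank * (2 * math.log(r_) if r_ > 0 else -math.inf)
        return ll

    converged = False
    ll_old = loglik(r, p)
    for _ in range(max_iter):
        new_copies = {a: 0.0 for a in alleles}
        null_copies = 2.0 * n_blank
        for (a, b), c in het.items():
            new_copies[a] += c
            new_copies[b] += c
        for a, c in hom.items():
            denom = p[a] ** 2 + 2 * p[a] * r
            w_true = 1.0 if denom == 0 else p[a] ** 2 / denom
            new_copies[a] += c * (2 * w_true + (1 - w_true))
            null_copies += c * (1 - w_true)
        r_new = null_copies / two_n
        p_new = {a: new_copies[a] / two_n for a in alleles}
        delta = abs(r_new - r) + sum(abs(p_new[a] - p[a]) for a in alleles)
        r, p = r_new, p_new
        ll = loglik(r, p)
        # EM increases the likelihood monotonically; near the flat r = 0
        # boundary the parameters crawl while the likelihood has plateaued
        if delta < tol or abs(ll - ll_old) < tol * 1e-2:
            converged = True
            break
        ll_old = ll
    if not converged:
        raise RuntimeError(
            f"null_allele_em did not converge in {max_iter} iterations "
            f"(last delta {delta:.3e}, r {r:.6f})"
        )
    # the null frequency has zero gradient at the r = 0 boundary when the
    # data fit HW exactly; EM then crawls sublinearly, so check the boundary
    total_p = sum(p.values())
    if total_p > 0:
        p0 = {a: v / total_p for a, v in p.items()}
        if loglik(0.0, p0) >= loglik(r, p) - 1e-9:
            return 0.0, p0
    return r, p


# ---------------------------------------------------------------------------
# Rarefaction and private alleles


def rarefied_allelic_richness(
    counts_by_pop: dict[str, AlleleFrequencyTable], g: Optional[int] = None
) -> dict[str, float]:
    """Expected number of alleles in a subsample of g gene copies per population.

    richness = sum_i [1 - C(N - N_i, g) / C(N, g)] with N the population's
    gene copies at the locus and N_i the copies of allele i.  ``g`` defaults
    to the minimum N across populations, which puts all populations on the
    same footing regardless of sample size.  Exact integer binomials are used.
    """
    if not counts_by_pop:
        raise ValueError("no populations")
    ns = {name: t.n_copies for name, t in counts_by_pop.items()}
    if any(n < 1 for n in ns.values()):
        raise ValueError("every population needs >=1 gene copy at the locus")
    if g is None:
        g = min(ns.values())
    if g < 1 or any(g > n for n in ns.values()):
        raise ValueError(f"rarefaction size g={g} exceeds a population's gene copies")
    out: dict[str, float] = {}
    for name, t in counts_by_pop.items():
        N = t.n_copies
        denom = math.comb(N, g)
        out[name] = float(
            sum(1.0 - math.comb(N - Ni, g) / denom for Ni in t.counts.values())
        )
    return out


def private_allele_counts(dataset: GenotypeDataset) -> dict[str, int]:
    """Number of alleles observed in exactly one population, summed over loci."""
    if len(dataset.populations) < 2:
        warnings.warn(
            "private alleles on a single population: every allele is private",
            stacklevel=2,
        )
    counts = {p.name: 0 for p in dataset.populations}
    for locus in dataset.locus_names:
        seen: dict[int, set[str]] = {}
        for pop in dataset.populations:
            tab = allele_frequencies(pop, locus)
            for a in tab.counts:
                seen.setdefault(a, set()).add(pop.name)
        for a, pops in seen.items():
            if len(pops) == 1:
                counts[next(iter(pops))] += 1
    return counts


# ---------------------------------------------------------------------------
# Summary assembly


@dataclass
class DiversitySummary:
    """Per-locus and per-population diversity statistics for one dataset."""

    mode: Literal["females_diploid", "males_merged_pairs"]
    per_locus: pd.DataFrame
    per_population: pd.DataFrame
    dropped: list[str] = field(default_factory=list)

    def to_tsv(self, per_locus_path, per_population_path) -> None:
        self.per_locus.to_csv(per_locus_path, sep="\t", index=False)
        self.per_population.to_csv(per_population_path, sep="\t", index=False)


def population_summary(
    dataset: GenotypeDataset,
    mode: Literal["females_diploid", "males_merged_pairs"] = "females_diploid",
    min_typed: int = 8,
    n_mc: int = 10_000,
    enum_cap: int = 50_000,
    seed: int = 0,
    fdr_alpha: float = 0.05,
) -> DiversitySummary:
    """Assemble He, Ho, HW p-values (raw and BH-adjusted), null-allele
    frequencies, allele counts, rarefied richness and private alleles.

    ``females_diploid`` analyses the diploid females of each population (the
    marker-validation design); ``males_merged_pairs`` first calls ploidy on
    the males, merges called haploids pairwise into pseudo-diploids and keeps
    called diploids as-is (the mixed-ploidy workaround).  HW and Monte-Carlo
    sizes are reduced from the single-test defaults for throughput across the
    loci-by-populations grid.
    """
    dropped: list[str] = []
    analysis_pops: list[PopulationSample] = []
    dmp_rows: dict[str, tuple[int, int]] = {}
    for pop in dataset.populations:
        if mode == "females_diploid":
            inds = [i for i in pop.females() if i.declared_ploidy != "haploid"]
        else:
            calls = _ploidy.call_population(pop.males(), min_typed=min_typed, population=pop.name)
            by_id = {i.id: i for i in pop.males()}
            haploids = []
            keep: list[Individual] = []
            for c in calls:
                if c.call == "excluded":
                    dropped.append(f"{pop.name}/{c.id}: only {c.n_typed} typed loci")
                elif c.call == "haploid":
                    h = by_id[c.id]
                    haploids.append(
                        Individual(
                            id=h.id,
                            sex="male",
                            declared_ploidy="haploid",
                            genotypes={
                                l: g[:1] for l, g in h.genotypes.items() if g
                            },
                        )
                    )
                else:
                    keep.append(by_id[c.id])
            n_hap = len(haploids)
            if n_hap % 2:
                dropped.append(f"{pop.name}: odd haploid count, one male unpaired")
            keep = keep + merge_haploid_pairs(haploids)
            dmp_rows[pop.name] = (sum(1 for c in calls if c.call == "diploid"), n_hap)
            inds = keep
        analysis_pops.append(
            PopulationSample(
                name=pop.name, habitat=pop.habitat, year=pop.year, individuals=inds
            )
        )
    sub = GenotypeDataset(loci=dataset.loci, populations=analysis_pops)

    # per-locus rarefaction across populations (per-locus minimum gene copies)
    richness: dict[tuple[str, str], float] = {}
    for locus in sub.locus_names:
        tabs = {
            p.name: allele_frequencies(p, locus)
            for p in sub.populations
        }
        tabs = {k: v for k, v in tabs.items() if v.n_copies > 0}
        if len(tabs) == len(sub.populations):
            for name, r in rarefied_allelic_richness(tabs).items():
                richness[(name, locus)] = r

    private = private_allele_counts(sub) if len(sub.populations) > 1 else {
        p.name: 0 for p in sub.populations
    }

    rows = []
    for k, pop in enumerate(sub.populations):
        for j, locus in enumerate(sub.locus_names):
            tab = allele_frequencies(pop, locus)
            genos = _diploid_genotypes(pop, locus)
            row = {
                "population": pop.name,
                "locus": locus,
                "n_typed_diploid": len(genos),
                "n_copies": tab.n_copies,
                "n_alleles": len(tab.counts),
                "Ho": observed_heterozygosity(pop, locus),
                "He": (
                    expected_heterozygosity_unbiased(tab)
                    if tab.n_copies >= 2
                    else float("nan")
                ),
                "hw_p": (
                    hw_exact_test(
                        pop, locus, n_mc=n_mc, seed=seed + 1000 * k + j, enum_cap=enum_cap
                    )
                    if len(genos) >= 2
                    else float("nan")
                ),
                "richness": richness.get((pop.name, locus), float("nan")),
            }
            if len(genos) >= 2:
                r_null, _ = null_allele_em(pop, locus)
                row["null_freq"] = r_null
            else:
                row["null_freq"] = float("nan")
            rows.append(row)
    per_locus = pd.DataFrame(rows)

    mask = per_locus["hw_p"].notna()
    adj = np.full(len(per_locus), np.nan)
    if mask.any():
        adj[mask.to_numpy()] = multipletests(
            per_locus.loc[mask, "hw_p"], alpha=fdr_alpha, method="fdr_bh"
        )[1]
    per_locus["hw_p_fdr"] = adj

    pop_rows = []
    for pop in sub.populations:
        sel = per_locus[per_locus["population"] == pop.name]
        n_all = sel["n_alleles"].to_numpy(dtype=float)
        rec = {
            "population": pop.name,
            "habitat": pop.habitat,
            "n_individuals": len(pop.individuals),
            "mean_n_alleles": float(np.mean(n_all)),
            "se_n_alleles": float(np.std(n_all, ddof=1) / np.sqrt(len(n_all)))
            if len(n_all) > 1
            else float("nan"),
            "overall_richness": float(np.nanmean(sel["richness"].to_numpy(dtype=float))),
            "private_alleles": private[pop.name],
        }
        if pop.name in dmp_rows:
            rec["n_diploid"], rec["n_haploid"] = dmp_rows[pop.name]
        pop_rows.append(rec)
    per_population = pd.DataFrame(pop_rows)

    return DiversitySummary(
        mode=mode, per_locus=per_locus, per_population=per_population, dropped=dropped
    )
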