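"""Diploid-male detection and the mis-scoring probability model.

A male heterozygous at one or more microsatellite loci must carry two gene
copies and is called diploid; an all-homozygous male is called haploid.  The
call is wrong exactly when a diploid male is homozygous at every typed locus,
which is likely only under inbreeding.  This module provides the caller, a
small pedigree engine that derives the relevant kinship coefficient by
enumerating transmission paths (haplodiploid or diplodiploid), the closed-form
probability that a diploid male goes undetected, and binomial summaries of the
diploid male proportion (DMP).
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from itertools import product
from typing import Iterable, Literal, Optional, Sequence, Union

import numpy as np
from statsmodels.stats.proportion import proportion_confint

from .popdata import AlleleFrequencyTable, Individual

__all__ = [
    "PloidyCall",
    "DmpEstimate",
    "Pedigree",
    "call_ploidy",
    "call_population",
    "sibling_kinship_haplodiploid",
    "all_homozygous_probability",
    "simulate_sibmated_all_homozygous",
    "summarize_dmp",
]


@dataclass(frozen=True)
class PloidyCall:
    id: str
    n_typed: int
    n_het: int
    call: Literal["haploid", "diploid", "excluded"]
    population: Optional[str] = None


@dataclass(frozen=True)
class DmpEstimate:
    """Diploid male proportion with binomial SE and exact 95% CI."""

    n_diploid: int
    n_haploid: int
    dmp: float
    se: float
    ci_low: float
    ci_high: float
    method: Literal["clopper_pearson", "wilson"]

    @property
    def n(self) -> int:
        return self.n_diploid + self.n_haploid


def call_ploidy(ind: Individual, min_typed: int = 8) -> PloidyCall:
    """Classify a male as haploid/diploid from multilocus heterozygosity.

    Heterozygous at >=1 typed locus -> diploid; otherwise haploid.  Males with
    fewer than ``min_typed`` typed loci are excluded (too little power to rule
    out diploidy).  Single-allele (haploid-coded) genotypes count as typed
    homozygous observations.
    """
    if ind.sex == "female":
        raise ValueError(f"call_ploidy: {ind.id} is female")
    typed = [g for g in ind.genotypes.values() if len(g) > 0]
    n_typed = len(typed)
    n_het = sum(1 for g in typed if len(set(g)) == 2)
    if n_typed < min_typed:
        call = "excluded"
    elif n_het >= 1:
        call = "diploid"
    else:
        call = "haploid"
    return PloidyCall(id=ind.id, n_typed=n_typed, n_het=n_het, call=call)


def call_population(
    males: Iterable[Individual], min_typed: int = 8, population: Optional[str] = None
) -> list[PloidyCall]:
    return [
        PloidyCall(
            id=c.id,
            n_typed=c.n_typed,
            n_het=c.n_het,
            call=c.call,
            population=population,
        )
        for c in (call_ploidy(m, min_typed) for m in males)
    ]


# ---------------------------------------------------------------------------
# Pedigree kinship by transmission-path enumeration


class Pedigree:
    """Small pedigree with haploid or diploid members.

    Founders carry unique allele labels (two for diploids, one for haploids).
    Non-founders receive one maternal gamete and, if diploid, one paternal
    gamete.  :meth:`kinship` enumerates every transmission configuration with
    its probability and returns the exact coefficient of kinship — the chance
    that one allele drawn at random from each of two individuals is identical
    by descent.
    """

    def __init__(self) -> None:
        self._members: dict[str, dict] = {}
        self._order: list[str] = []
        self._next_label = 0

    def add_founder(self, name: str, ploidy: Literal["haploid", "diploid"] = "diploid") -> None:
        n = 2 if ploidy == "diploid" else 1
        labels = tuple(range(self._next_label, self._next_label + n))
        self._next_label += n
        self._members[name] = {"founder": True, "labels": labels}
        self._order.append(name)

    def add_individual(
        self,
        name: str,
        mother: str,
        father: Optional[str] = None,
        ploidy: Literal["haploid", "diploid"] = "diploid",
    ) -> None:
        """Add offspring; ``father=None`` means an unfertilized (haploid) egg."""
        if ploidy == "diploid" and father is None:
            raise ValueError("diploid offspring needs a father")
        if ploidy == "haploid" and father is not None:
            raise ValueError("haploid offspring arises from an unfertilized egg")
        for parent in (mother,) + ((father,) if father else ()):
            if parent not in self._members:
                raise KeyError(parent)
        self._members[name] = {"founder": False, "mother": mother, "father": father}
        self._order.append(name)

    def _configurations(self):
        """Yield (probability, {name: allele tuple}) over all gamete choices."""
        def n_alleles(name: str) -> int:
            m = self._members[name]
            if m["founder"]:
                return len(m["labels"])
            return 2 if m["father"] is not None else 1

        choice_slots: list[tuple[str, str, int]] = []  # (child, parent_role, n_options)
        for name in self._order:
            m = self._members[name]
            if m["founder"]:
                continue
            choice_slots.append((name, "mother", n_alleles(m["mother"])))
            if m["father"] is not None:
                choice_slots.append((name, "father", n_alleles(m["father"])))

        for choices in product(*(range(n) for _, _, n in choice_slots)):
            prob = Fraction(1)
            realized: dict[str, tuple[int, ...]] = {}
            it = iter(choices)
            picks = {slot[:2]: next(it) for slot in choice_slots}
            for name in self._order:
                m = self._members[name]
                if m["founder"]:
                    realized[name] = m["labels"]
                    continue
                mat_alleles = realized[m["mother"]]
                i = picks[(name, "mother")] % len(mat_alleles)
                if len(mat_alleles) == 2:
                    prob *= Fraction(1, 2)
                gam = (mat_alleles[i],)
                if m["father"] is not None:
                    pat_alleles = realized[m["father"]]
                    j = picks[(name, "father")] % len(pat_alleles)
                    if len(pat_alleles) == 2:
                        prob *= Fraction(1, 2)
                    gam = gam + (pat_alleles[j],)
                realized[name] = gam
            yield prob, realized

    def kinship(self, x: str, y: str) -> Fraction:
        total = Fraction(0)
        norm = Fraction(0)
        for prob, realized in self._configurations():
            ax, ay = realized[x], realized[y]
            match = Fraction(
                sum(1 for a in ax for b in ay if a == b), len(ax) * len(ay)
            )
            total += prob * match
            norm += prob
        assert norm == 1
        return total

    def sample_kinship(
        self, x: str, y: str, n: int, rng: np.random.Generator
    ) -> float:
        """Forward Monte-Carlo estimate of kinship (independent of enumeration)."""
        hits = 0
        for _ in range(n):
            realized: dict[str, tuple[int, ...]] = {}
            for name in self._order:
                m = self._members[name]
                if m["founder"]:
                    realized[name] = m["labels"]
                    continue
                mat = realized[m["mother"]]
                gam = (mat[rng.integers(len(mat))],)
                if m["father"] is not None:
                    pat = realized[m["father"]]
                    gam = gam + (pat[rng.integers(len(pat))],)
                realized[name] = gam
            ax, ay = realized[x], realized[y]
            if ax[rng.integers(len(ax))] == ay[rng.integers(len(ay))]:
                hits += 1
        return hits / n


def sibling_kinship_haplodiploid() -> Fraction:
    """Kinship between full siblings (sister, brother) under haplodiploidy.

    The brother develops from an unfertilized egg and carries a single
    maternal allele; the sister carries one maternal and the paternal allele.
    Enumerated from the four-member pedigree, not hard-coded.
    """
    ped = Pedigree()
    ped.add_founder("mother", "diploid")
    ped.add_founder("father", "haploid")
    ped.add_individual("sister", "mother", "father", ploidy="diploid")
    ped.add_individual("brother", "mother", ploidy="haploid")
    return ped.kinship("sister", "brother")


LocusInput = Union[AlleleFrequencyTable, float]


def _homozygosity(value: LocusInput) -> float:
    if isinstance(value, AlleleFrequencyTable):
        return value.homozygosity
    h = float(value)
    if not 0.0 <= h <= 1.0:
        raise ValueError(f"per-locus homozygosity {h} outside [0, 1]")
    return h


def all_homozygous_probability(
    loci: Sequence[LocusInput], F: Optional[float] = None
) -> float:
    """Probability a diploid male is homozygous at every locus of a panel.

    Per locus, P(homozygous) = F + (1 - F) * sum(p_i^2), with F the kinship of
    the parents (probability the male's two alleles are identical by descent);
    loci are treated as independent, so the panel value is the product.  Each
    entry of ``loci`` is either an :class:`AlleleFrequencyTable` or a
    pre-computed homozygosity-by-state value (i.e. 1 - He).

    F defaults to the enumerated haplodiploid full-sib kinship (brother-sister
    mating, the worst realistic case for a monoandrous wasp).
    """
    if len(loci) == 0:
        raise ValueError("empty locus panel")
    if F is None:
        F = float(sibling_kinship_haplodiploid())
    if not 0.0 <= F <= 1.0:
        raise ValueError("F outside [0, 1]")
    p = 1.0
    for value in loci:
        p *= F + (1.0 - F) * _homozygosity(value)
    return p


def simulate_sibmated_all_homozygous(
    freqs: Sequence[Sequence[float]], n_pedigrees: int, rng: np.random.Generator
) -> float:
    """Monte-Carlo oracle for :func:`all_homozygous_probability` at F = 1/4.

    Simulates ``n_pedigrees`` brother-sister matings: grandparents drawn from
    the supplied per-locus allele frequencies, a diploid son produced by the
    sib pair, and returns the fraction of sons homozygous at all loci.
    """
    freqs = [np.asarray(f, dtype=float) for f in freqs]
    n_all_hom = 0
    for _ in range(n_pedigrees):
        all_hom = True
        for p in freqs:
            k = len(p)
            gm = rng.choice(k, size=2, p=p)  # grandmother, diploid
            gf = rng.choice(k, p=p)  # grandfather, haploid
            # Track founder copy identity alongside allelic state.
            copies = [(0, gm[0]), (1, gm[1]), (2, gf)]
            sister = [copies[rng.integers(2)], copies[2]]
            brother = copies[rng.integers(2)]
            son = (sister[rng.integers(2)], brother)
            if son[0][1] != son[1][1]:
                all_hom = False
                break
        n_all_hom += all_hom
    return n_all_hom / n_pedigrees


def summarize_dmp(
    calls: Sequence[PloidyCall],
    ci_method: Literal["clopper_pearson", "wilson"] = "clopper_pearson",
) -> DmpEstimate:
    """DMP over non-excluded calls with binomial SE and exact 95% CI."""
    n_dip = sum(1 for c in calls if c.call == "diploid")
    n_hap = sum(1 for c in calls if c.call == "haploid")
    return dmp_from_counts(n_dip, n_hap, ci_method)


def dmp_from_counts(
    n_diploid: int,
    n_haploid: int,
    ci_method: Literal["clopper_pearson", "wilson"] = "clopper_pearson",
) -> DmpEstimate:
    n = n_diploid + n_haploid
    if n == 0:
        raise ValueError("no usable (non-excluded) ploidy calls")
    dmp = n_diploid / n
    se = float(np.sqrt(dmp * (1 - dmp) / n))
    method = "beta" if ci_method == "clopper_pearson" else "wilson"
    lo, hi = proportion_confint(n_diploid, n, alpha=0.05, method=method)
    return DmpEstimate(
        n_diploid=n_diploid,
        n_haploid=n_haploid,
        dmp=dmp,
        se=se,
        ci_low=float(lo),
        ci_high=float(hi),
        method=ci_method,
    )
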