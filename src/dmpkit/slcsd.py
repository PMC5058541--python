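"""Forward simulator of haplodiploid populations under single-locus CSD.

Sex determination follows the sl-CSD rule: unfertilized eggs are hemizygous
at the csd locus and develop into haploid males; fertilized eggs develop into
females when csd-heterozygous and into sterile diploid males when
csd-homozygous.  Females are monoandrous; a female mated to a diploid male
produces only sons (her eggs behave as unfertilized).  Generations are
discrete and non-overlapping, clutch sizes are Poisson, and the adult
population is truncated uniformly at random to a carrying capacity — the
simplest demography that exhibits founder effects and drift.

Neutral microsatellite markers are inherited Mendelianly alongside the csd
locus (which is simulator truth only and is never genotyped).  Genotyping
noise — missing data and heritable null alleles — is applied at observation
time by :func:`sample_trap_survey`, which emits the package's standard
genotype dataset with hidden true ploidy for validation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .popdata import GenotypeDataset, Individual, Locus, PopulationSample

__all__ = ["SimConfig", "SimPopulation", "build_scenario", "simulate_population", "sample_trap_survey"]

#: allele counts of a realistic 10-marker panel (2-12 alleles per locus)
DEFAULT_MARKER_ALLELES = (7, 11, 7, 4, 8, 7, 7, 12, 2, 8)


@dataclass
class SimConfig:
    """Full parameterization of one simulated population.

    ``fertilization_prob`` is the probability an egg of a haploid-mated
    female is fertilized; ``sibmating_rate`` is the probability a female
    mates with a brother when one is available; ``migration_rate`` is the
    per-generation fraction of adults replaced by individuals drawn from the
    founder allele pool; ``null_allele_rate`` seeds a heritable non-amplifying
    allele at that founder frequency at every locus.
    """

    n_founder_females: int = 50
    n_csd_alleles: int = 20
    csd_frequencies: Optional[Sequence[float]] = None
    n_loci: int = 10
    marker_allele_counts: Sequence[int] = DEFAULT_MARKER_ALLELES
    marker_founder_frequencies: Union[float, Sequence[Sequence[float]]] = 1.0
    generations: int = 10
    carrying_capacity: int = 500
    fertilization_prob: float = 0.5
    sibmating_rate: float = 0.0
    diploid_male_mating: Literal["sterile_sons_only", "excluded"] = "sterile_sons_only"
    missing_rate: float = 0.0
    null_allele_rate: float = 0.0
    migration_rate: float = 0.0
    mean_clutch: float = 8.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_csd_alleles < 2:
            raise ValueError("need k >= 2 csd alleles")
        if self.generations < 0:
            raise ValueError("generations must be >= 0")
        if len(self.marker_allele_counts) != self.n_loci:
            raise ValueError("marker_allele_counts length must equal n_loci")
        for name in (
            "fertilization_prob",
            "sibmating_rate",
            "missing_rate",
            "null_allele_rate",
            "migration_rate",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.csd_frequencies is not None:
            f = np.asarray(self.csd_frequencies, dtype=float)
            if len(f) != self.n_csd_alleles or not np.isclose(f.sum(), 1.0):
                raise ValueError("csd_frequencies must be a simplex of length k")


PRESETS = {
    "mainland": dict(
        n_founder_females=200,
        carrying_capacity=1000,
        generations=10,
        migration_rate=0.05,
    ),
    "island": dict(
        n_founder_females=50,
        carrying_capacity=300,
        generations=20,
        migration_rate=0.0,
    ),
    "captive_large": dict(
        n_founder_females=120,
        carrying_capacity=200,
        generations=25,
        migration_rate=0.0,
    ),
    "captive_small": dict(
        n_founder_females=11,
        carrying_capacity=150,
        generations=18,
        migration_rate=0.0,
    ),
}


def build_scenario(preset: str, **overrides) -> SimConfig:
    """Preset configurations for the habitat types under study.

    ``mainland``: large connected population; ``island``: moderate closed
    population; ``captive_large``: ~120 foundresses, tens of generations of
    closed mass rearing; ``captive_small``: 11 foundresses (a severely
    bottlenecked culture).  Keyword overrides win over the preset.
    """
    if preset not in PRESETS:
        raise ValueError(f"unknown preset {preset!r}; choose from {sorted(PRESETS)}")
    params = dict(PRESETS[preset])
    params.update(overrides)
    return SimConfig(**params)


@dataclass
class SimPopulation:
    """Simulator state after the last generation, plus per-generation history.

    ``history`` columns: generation, n_females, n_hap_males, n_dip_males,
    adult_dmp, frac_homozygous_fertilized (diploid-male fraction among that
    generation's fertilized eggs), mean_he (expected heterozygosity of the
    markers among adults).
    """

    config: SimConfig
    female_csd: np.ndarray  # (F, 2)
    female_markers: np.ndarray  # (F, L, 2)
    female_family: np.ndarray
    hapmale_csd: np.ndarray  # (M,)
    hapmale_markers: np.ndarray  # (M, L)
    hapmale_family: np.ndarray
    dipmale_csd: np.ndarray  # (D, 2)
    dipmale_markers: np.ndarray  # (D, L, 2)
    dipmale_family: np.ndarray
    history: pd.DataFrame
    extinct: bool
    founder_marker_freqs: list[np.ndarray]

    @property
    def n_females(self) -> int:
        return len(self.female_csd)

    @property
    def n_males(self) -> int:
        return len(self.hapmale_csd) + len(self.dipmale_csd)

    def check_invariants(self) -> None:
        """Every female csd-heterozygous; every diploid male csd-homozygous."""
        if len(self.female_csd) and np.any(self.female_csd[:, 0] == self.female_csd[:, 1]):
            raise AssertionError("csd-homozygous female")
        if len(self.dipmale_csd) and np.any(self.dipmale_csd[:, 0] != self.dipmale_csd[:, 1]):
            raise AssertionError("csd-heterozygous diploid male")

    def marker_allele_set(self) -> list[set[int]]:
        """Distinct marker alleles present among adults, per locus."""
        out = []
        for l in range(self.config.n_loci):
            alleles = set(np.unique(self.female_markers[:, l, :]).tolist()) if len(self.female_markers) else set()
            if len(self.hapmale_markers):
                alleles |= set(np.unique(self.hapmale_markers[:, l]).tolist())
            if len(self.dipmale_markers):
                alleles |= set(np.unique(self.dipmale_markers[:, l, :]).tolist())
            out.append(alleles)
        return out


def _founder_marker_freqs(config: SimConfig, rng: np.random.Generator) -> list[np.ndarray]:
    freqs: list[np.ndarray] = []
    if isinstance(config.marker_founder_frequencies, (int, float)):
        conc = float(config.marker_founder_frequencies)
        for k in config.marker_allele_counts:
            freqs.append(rng.dirichlet(np.full(k, conc)))
    else:
        for f in config.marker_founder_frequencies:
            f = np.asarray(f, dtype=float)
            if not np.isclose(f.sum(), 1.0):
                raise ValueError("marker founder frequencies must sum to 1")
            freqs.append(f)
    if config.null_allele_rate > 0:
        freqs = [
            np.concatenate([f * (1 - config.null_allele_rate), [config.null_allele_rate]])
            for f in freqs
        ]
    return freqs


def _csd_freqs(config: SimConfig) -> np.ndarray:
    if config.csd_frequencies is None:
        return np.full(config.n_csd_alleles, 1.0 / config.n_csd_alleles)
    return np.asarray(config.csd_frequencies, dtype=float)


def _draw_het_pairs(n: int, freqs: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """n csd genotypes heterozygous by construction (conditional sampling)."""
    out = np.empty((n, 2), dtype=np.int32)
    filled = 0
    while filled < n:
        need = n - filled
        a = rng.choice(len(freqs), size=2 * need, p=freqs).reshape(need, 2)
        ok = a[:, 0] != a[:, 1]
        take = a[ok]
        out[filled : filled + len(take)] = take
        filled += len(take)
    return out


def _draw_markers(n: int, ploidy: int, freqs: list[np.ndarray], rng: np.random.Generator) -> np.ndarray:
    L = len(freqs)
    shape = (n, L, ploidy) if ploidy == 2 else (n, L)
    out = np.empty(shape, dtype=np.int16)
    for l, f in enumerate(freqs):
        draws = rng.choice(len(f), size=n * ploidy, p=f)
        if ploidy == 2:
            out[:, l, :] = draws.reshape(n, 2)
        else:
            out[:, l] = draws
    return out


def _mean_he(pop: SimPopulation) -> float:
    """Mean expected heterozygosity (1 - sum p^2) of markers among adults."""
    hes = []
    for l in range(pop.config.n_loci):
        copies = []
        if len(pop.female_markers):
            copies.append(pop.female_markers[:, l, :].ravel())
        if len(pop.hapmale_markers):
            copies.append(pop.hapmale_markers[:, l])
        if len(pop.dipmale_markers):
            copies.append(pop.dipmale_markers[:, l, :].ravel())
        if not copies:
            return float("nan")
        allc = np.concatenate(copies)
        _, counts = np.unique(allc, return_counts=True)
        p = counts / counts.sum()
        hes.append(1.0 - float((p**2).sum()))
    return float(np.mean(hes))


def simulate_population(config: SimConfig) -> SimPopulation:
    """Run the forward simulation; fully reproducible given ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    csd_f = _csd_freqs(config)
    marker_f = _founder_marker_freqs(config, rng)

    nF = config.n_founder_females
    pop = SimPopulation(
        config=config,
        female_csd=_draw_het_pairs(nF, csd_f, rng),
        female_markers=_draw_markers(nF, 2, marker_f, rng),
        female_family=np.arange(nF, dtype=np.int64),
        hapmale_csd=rng.choice(len(csd_f), size=nF, p=csd_f).astype(np.int32),
        hapmale_markers=_draw_markers(nF, 1, marker_f, rng),
        hapmale_family=np.arange(nF, 2 * nF, dtype=np.int64),
        dipmale_csd=np.empty((0, 2), dtype=np.int32),
        dipmale_markers=np.empty((0, config.n_loci, 2), dtype=np.int16),
        dipmale_family=np.empty(0, dtype=np.int64),
        history=pd.DataFrame(),
        extinct=False,
        founder_marker_freqs=marker_f,
    )

    records = [_history_row(pop, 0, float("nan"))]
    family_counter = 2 * nF

    for gen in range(1, config.generations + 1):
        n_mothers = pop.n_females
        frac_hom = _step(pop, rng, csd_f, marker_f, family_counter)
        family_counter += n_mothers  # one family id per mother per generation
        records.append(_history_row(pop, gen, frac_hom))
        if pop.extinct:
            break
    pop.history = pd.DataFrame(records)
    return pop


def _history_row(pop: SimPopulation, gen: int, frac_hom: float) -> dict:
    nH, nD = len(pop.hapmale_csd), len(pop.dipmale_csd)
    return {
        "generation": gen,
        "n_females": pop.n_females,
        "n_hap_males": nH,
        "n_dip_males": nD,
        "adult_dmp": nD / (nH + nD) if nH + nD else float("nan"),
        "frac_homozygous_fertilized": frac_hom,
        "mean_he": _mean_he(pop),
    }


def _step(
    pop: SimPopulation,
    rng: np.random.Generator,
    csd_f: np.ndarray,
    marker_f: list[np.ndarray],
    family_base: int,
) -> float:
    cfg = pop.config
    nF = pop.n_females
    nH = len(pop.hapmale_csd)
    nD = len(pop.dipmale_csd)
    use_dip = cfg.diploid_male_mating == "sterile_sons_only" and nD > 0
    n_mates = nH + (nD if use_dip else 0)
    if nF == 0 or n_mates == 0:
        pop.extinct = True
        return float("nan")

    # --- mate choice (monoandry): brother with prob alpha, else random male
    mate_idx = rng.integers(n_mates, size=nF)
    if cfg.sibmating_rate > 0:
        fam_mates: dict[int, np.ndarray] = {}
        male_fams = np.concatenate(
            [pop.hapmale_family] + ([pop.dipmale_family] if use_dip else [])
        )
        for f in np.unique(male_fams):
            fam_mates[int(f)] = np.flatnonzero(male_fams == f)
        sib = rng.random(nF) < cfg.sibmating_rate
        for i in np.flatnonzero(sib):
            cands = fam_mates.get(int(pop.female_family[i]))
            if cands is not None and len(cands):
                mate_idx[i] = cands[rng.integers(len(cands))]
    mate_is_dip = mate_idx >= nH

    # --- eggs
    clutch = rng.poisson(cfg.mean_clutch, size=nF)
    mother = np.repeat(np.arange(nF), clutch)
    father = np.repeat(mate_idx, clutch)
    father_dip = np.repeat(mate_is_dip, clutch)
    E = len(mother)
    if E == 0:
        pop.extinct = True
        return float("nan")
    fert = (rng.random(E) < cfg.fertilization_prob) & ~father_dip

    # --- csd transmission
    mat_bit = rng.integers(2, size=E)
    egg_mat_csd = pop.female_csd[mother, mat_bit]
    pat_csd = np.zeros(E, dtype=np.int32)
    pat_csd[fert] = pop.hapmale_csd[father[fert]]
    is_female = fert & (egg_mat_csd != pat_csd)
    is_dipmale = fert & (egg_mat_csd == pat_csd)
    n_fert = int(fert.sum())
    frac_hom = float(is_dipmale.sum() / n_fert) if n_fert else float("nan")

    # --- marker transmission
    L = cfg.n_loci
    bits = rng.integers(2, size=(E, L))
    mat_gam = pop.female_markers[mother[:, None], np.arange(L)[None, :], bits]
    pat_gam = np.zeros((E, L), dtype=np.int16)
    if fert.any():
        pat_gam[fert] = pop.hapmale_markers[father[fert]]

    family = family_base + mother

    # --- assemble offspring classes
    f_sel = np.flatnonzero(is_female)
    h_sel = np.flatnonzero(~fert)
    d_sel = np.flatnonzero(is_dipmale)

    new_female_csd = np.stack([egg_mat_csd[f_sel], pat_csd[f_sel]], axis=1)
    new_female_mk = np.stack([mat_gam[f_sel], pat_gam[f_sel]], axis=2)
    new_hap_csd = egg_mat_csd[h_sel]
    new_hap_mk = mat_gam[h_sel]
    new_dip_csd = np.stack([egg_mat_csd[d_sel], pat_csd[d_sel]], axis=1)
    new_dip_mk = np.stack([mat_gam[d_sel], pat_gam[d_sel]], axis=2)

    # --- regulation: uniform truncation to carrying capacity
    total = len(f_sel) + len(h_sel) + len(d_sel)
    if total > cfg.carrying_capacity:
        keep = rng.choice(total, size=cfg.carrying_capacity, replace=False)
        keep_mask = np.zeros(total, dtype=bool)
        keep_mask[keep] = True
        fm = keep_mask[: len(f_sel)]
        hm = keep_mask[len(f_sel) : len(f_sel) + len(h_sel)]
        dm = keep_mask[len(f_sel) + len(h_sel) :]
        new_female_csd, new_female_mk = new_female_csd[fm], new_female_mk[fm]
        new_hap_csd, new_hap_mk = new_hap_csd[hm], new_hap_mk[hm]
        new_dip_csd, new_dip_mk = new_dip_csd[dm], new_dip_mk[dm]
        fam_f = family[f_sel][fm]
        fam_h = family[h_sel][hm]
        fam_d = family[d_sel][dm]
    else:
        fam_f, fam_h, fam_d = family[f_sel], family[h_sel], family[d_sel]

    # --- migration: replace a fraction of adults from the founder pool
    if cfg.migration_rate > 0:
        n_f = len(new_female_csd)
        if n_f:
            rep = rng.random(n_f) < cfg.migration_rate
            n_rep = int(rep.sum())
            if n_rep:
                new_female_csd[rep] = _draw_het_pairs(n_rep, csd_f, rng)
                new_female_mk[rep] = _draw_markers(n_rep, 2, marker_f, rng)
                fam_f[rep] = -1
        n_h = len(new_hap_csd)
        if n_h:
            rep = rng.random(n_h) < cfg.migration_rate
            n_rep = int(rep.sum())
            if n_rep:
                new_hap_csd[rep] = rng.choice(len(csd_f), size=n_rep, p=csd_f)
                new_hap_mk[rep] = _draw_markers(n_rep, 1, marker_f, rng)
                fam_h[rep] = -1

    pop.female_csd, pop.female_markers, pop.female_family = (
        new_female_csd,
        new_female_mk,
        fam_f,
    )
    pop.hapmale_csd, pop.hapmale_markers, pop.hapmale_family = (
        new_hap_csd,
        new_hap_mk,
        fam_h,
    )
    pop.dipmale_csd, pop.dipmale_markers, pop.dipmale_family = (
        new_dip_csd,
        new_dip_mk,
        fam_d,
    )
    if pop.n_females == 0 or pop.n_males == 0:
        pop.extinct = True
    return frac_hom


# ---------------------------------------------------------------------------
# Observation


def _fragment_label(locus_index: int, allele_index: int) -> int:
    """Map internal allele indices to plausible fragment sizes in bp."""
    return 100 + 30 * locus_index + 2 * allele_index


def sample_trap_survey(
    pop: SimPopulation,
    n_males: int,
    n_females: int,
    seed: int,
    population_name: str = "sim",
    habitat: str = "mainland",
) -> GenotypeDataset:
    """Sample adults uniformly without replacement and genotype them.

    Males are recorded with declared ploidy "unknown" (the field situation);
    the simulator's true ploidy is retained on each individual as hidden
    truth.  Null-allele copies are invisible: a diploid with one null reads
    as an apparent homozygote, with two nulls (or a haploid with a null) as
    missing.  Independent per-genotype dropout is then applied at
    ``config.missing_rate``.
    """
    cfg = pop.config
    rng = np.random.default_rng(seed)
    nH, nD = len(pop.hapmale_csd), len(pop.dipmale_csd)
    if n_males > nH + nD:
        raise ValueError(f"requested {n_males} males, only {nH + nD} available")
    if n_females > pop.n_females:
        raise ValueError(f"requested {n_females} females, only {pop.n_females} available")

    null_idx = {
        l: cfg.marker_allele_counts[l] if cfg.null_allele_rate > 0 else -1
        for l in range(cfg.n_loci)
    }
    loci = [
        Locus(name=f"L{l + 1:02d}", multiplex_id="I")
        for l in range(cfg.n_loci)
    ]

    def observe(alleles: tuple[int, ...], l: int) -> tuple[int, ...]:
        visible = tuple(a for a in alleles if a != null_idx[l])
        if len(visible) == 0:
            return ()
        if len(alleles) == 2 and len(visible) == 1:
            visible = visible * 2  # apparent homozygote
        if rng.random() < cfg.missing_rate:
            return ()
        return tuple(_fragment_label(l, a) for a in visible)

    individuals: list[Individual] = []
    male_pick = rng.choice(nH + nD, size=n_males, replace=False)
    for j, idx in enumerate(male_pick):
        if idx < nH:
            raw = [(int(pop.hapmale_markers[idx, l]),) for l in range(cfg.n_loci)]
            truth = "haploid"
        else:
            i = idx - nH
            raw = [tuple(int(a) for a in pop.dipmale_markers[i, l]) for l in range(cfg.n_loci)]
            truth = "diploid"
        genotypes = {}
        for l in range(cfg.n_loci):
            obs = observe(raw[l], l)
            if obs:
                genotypes[loci[l].name] = obs
        individuals.append(
            Individual(
                id=f"{population_name}_m{j + 1:04d}",
                sex="male",
                declared_ploidy="unknown",
                genotypes=genotypes,
                true_ploidy=truth,
            )
        )
    female_pick = rng.choice(pop.n_females, size=n_females, replace=False)
    for j, idx in enumerate(female_pick):
        genotypes = {}
        for l in range(cfg.n_loci):
            obs = observe(tuple(int(a) for a in pop.female_markers[idx, l]), l)
            if obs:
                genotypes[loci[l].name] = obs
        individuals.append(
            Individual(
                id=f"{population_name}_f{j + 1:04d}",
                sex="female",
                declared_ploidy="diploid",
                genotypes=genotypes,
                true_ploidy="diploid",
            )
        )
    return GenotypeDataset(
        loci=loci,
        populations=[
            PopulationSample(
                name=population_name, habitat=habitat, individuals=individuals
            )
        ],
    )
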