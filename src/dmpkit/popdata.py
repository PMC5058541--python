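"""Data model and GENEPOP I/O for mixed-ploidy multilocus genotypes.

Microsatellite genotypes of haplodiploid wasps mix haploid males (one gene
copy per locus), diploid males and diploid females in the same population
sample.  The classical GENEPOP text format has no haploid notation, so this
module keeps ploidy in a sidecar table (tab-separated: id, population, sex,
ploidy) that is the authoritative carrier; on export haploids are either
duplicated ("104" -> "104104", the FSTAT workaround) or merged pairwise into
pseudo-diploid records that preserve allele frequencies.

Allele labels are fragment sizes in base pairs (positive integers).  Labels
that do not fit the 2/3-digit GENEPOP code space are remapped through a
persisted lookup written next to the output file.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Optional, Sequence

import Bio.PopGen.GenePop as _genepop

logger = logging.getLogger(__name__)

Sex = Literal["male", "female", "unknown"]
Ploidy = Literal["haploid", "diploid", "unknown"]

HABITATS = ("mainland", "island", "captive")

MISSING: tuple[int, ...] = ()


@dataclass(frozen=True)
class Locus:
    """A microsatellite marker.

    ``size_range`` is the expected fragment-length window in base pairs;
    ``multiplex_id`` tags the PCR multiplex the marker belongs to.
    """

    name: str
    repeat_motif: Optional[str] = None
    size_range: Optional[tuple[int, int]] = None
    multiplex_id: Optional[str] = None

    def __post_init__(self) -> None:
        if self.size_range is not None and self.size_range[0] > self.size_range[1]:
            raise ValueError(f"locus {self.name}: size_range lower > upper")


@dataclass
class Individual:
    """One genotyped wasp.

    ``genotypes`` maps locus name to a tuple of 0 (missing), 1 (haploid) or
    2 allele labels.  ``true_ploidy`` is simulator-only hidden truth and is
    never serialized.
    """

    id: str
    sex: Sex = "unknown"
    declared_ploidy: Ploidy = "unknown"
    genotypes: dict[str, tuple[int, ...]] = field(default_factory=dict)
    true_ploidy: Optional[Ploidy] = None

    def __post_init__(self) -> None:
        if self.sex == "female" and self.declared_ploidy == "haploid":
            raise ValueError(f"individual {self.id}: females cannot be haploid")
        for locus, g in self.genotypes.items():
            if len(g) > 2:
                raise ValueError(f"individual {self.id}, locus {locus}: >2 alleles")
            if any(a <= 0 for a in g):
                raise ValueError(
                    f"individual {self.id}, locus {locus}: allele labels must be positive"
                )
            if len(g) == 1 and self.declared_ploidy == "diploid":
                raise ValueError(
                    f"individual {self.id}, locus {locus}: single allele on a diploid"
                )

    def genotype(self, locus: str) -> tuple[int, ...]:
        return self.genotypes.get(locus, MISSING)

    def is_typed(self, locus: str) -> bool:
        return len(self.genotype(locus)) > 0


@dataclass
class PopulationSample:
    name: str
    habitat: str = "mainland"
    year: Optional[int] = None
    individuals: list[Individual] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.habitat not in HABITATS:
            raise ValueError(f"habitat must be one of {HABITATS}, got {self.habitat!r}")

    def males(self) -> list[Individual]:
        return [i for i in self.individuals if i.sex == "male"]

    def females(self) -> list[Individual]:
        return [i for i in self.individuals if i.sex == "female"]


@dataclass
class GenotypeDataset:
    loci: list[Locus]
    populations: list[PopulationSample]

    def __post_init__(self) -> None:
        names = [l.name for l in self.loci]
        if len(set(names)) != len(names):
            raise ValueError("duplicate locus name")
        pnames = [p.name for p in self.populations]
        if len(set(pnames)) != len(pnames):
            raise ValueError("duplicate population name")
        known = set(names)
        for pop in self.populations:
            for ind in pop.individuals:
                extra = set(ind.genotypes) - known
                if extra:
                    raise ValueError(
                        f"individual {ind.id} typed at unknown loci {sorted(extra)}"
                    )

    @property
    def locus_names(self) -> list[str]:
        return [l.name for l in self.loci]

    def population(self, name: str) -> PopulationSample:
        for p in self.populations:
            if p.name == name:
                return p
        raise KeyError(name)


@dataclass
class AlleleFrequencyTable:
    """Gene-copy counts at one locus: haploids contribute 1, diploids 2."""

    locus: str
    counts: dict[int, int]
    n_copies: int

    def __post_init__(self) -> None:
        if sum(self.counts.values()) != self.n_copies:
            raise ValueError("n_copies must equal the sum of counts")

    @property
    def frequencies(self) -> dict[int, float]:
        if self.n_copies == 0:
            return {}
        return {a: c / self.n_copies for a, c in self.counts.items()}

    @property
    def homozygosity(self) -> float:
        """Sum of squared allele frequencies (expected identity in state)."""
        return sum(f * f for f in self.frequencies.values())


def allele_frequencies(
    pop: PopulationSample,
    locus: str,
    use: Literal["all", "haploids_only", "diploids_only"] = "all",
) -> AlleleFrequencyTable:
    """Exact gene-copy counts at ``locus`` in ``pop``.

    Haploid genotypes contribute one copy, diploid two; missing genotypes are
    excluded.  ``use`` restricts the tally to one ploidy class, judged by the
    number of recorded alleles (1 vs 2).
    """
    counts: Counter[int] = Counter()
    for ind in pop.individuals:
        g = ind.genotype(locus)
        if not g:
            continue
        if use == "haploids_only" and len(g) != 1:
            continue
        if use == "diploids_only" and len(g) != 2:
            continue
        counts.update(g)
    n = sum(counts.values())
    return AlleleFrequencyTable(locus=locus, counts=dict(counts), n_copies=n)


def merge_haploid_pairs(
    males: Sequence[Individual], seed: Optional[int] = None
) -> list[Individual]:
    """Merge haploid males pairwise into pseudo-diploid "false diploid" records.

    Individuals are sorted by id and paired sequentially, so per-locus allele
    counts are conserved exactly (up to the one dropped male when the count is
    odd).  ``seed`` switches to a seeded random pairing; allele frequencies are
    invariant to pairing order either way.
    """
    for m in males:
        if m.declared_ploidy != "haploid":
            raise ValueError(f"merge_haploid_pairs: {m.id} is not haploid")
    ordered = sorted(males, key=lambda m: m.id)
    if seed is not None:
        import random

        random.Random(seed).shuffle(ordered)
    if len(ordered) % 2:
        dropped = ordered.pop()
        logger.info("merge_haploid_pairs: odd count, dropped %s", dropped.id)
    merged: list[Individual] = []
    for a, b in zip(ordered[::2], ordered[1::2]):
        genotypes: dict[str, tuple[int, ...]] = {}
        for locus in set(a.genotypes) | set(b.genotypes):
            alleles = a.genotype(locus) + b.genotype(locus)
            if alleles:
                genotypes[locus] = tuple(alleles)
        merged.append(
            Individual(
                id=f"{a.id}+{b.id}",
                sex="male",
                declared_ploidy="diploid",
                genotypes=genotypes,
            )
        )
    return merged


# ---------------------------------------------------------------------------
# GENEPOP I/O


def _read_sidecar(path: Path) -> dict[str, dict[str, str]]:
    """Sidecar TSV: id, population, sex, ploidy and optional habitat, year."""
    rows: dict[str, dict[str, str]] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        required = {"id", "population", "sex", "ploidy"}
        if not required <= set(header):
            raise ValueError(f"sidecar {path}: header must contain {sorted(required)}")
        for line in fh:
            if not line.strip():
                continue
            rec = dict(zip(header, line.rstrip("\n").split("\t")))
            rows[rec["id"]] = rec
    return rows


def _validate_genepop_lines(path: Path) -> None:
    """Cheap line-level checks so parse failures name a line number."""
    with open(path) as fh:
        lines = fh.readlines()
    if len(lines) < 3:
        raise ValueError(f"{path}: not a GENEPOP file (fewer than 3 lines)")
    seen_pop = False
    for lineno, line in enumerate(lines[1:], start=2):
        stripped = line.strip()
        if stripped.upper() == "POP":
            seen_pop = True
            continue
        if not seen_pop or not stripped:
            continue
        if "," not in line:
            raise ValueError(f"{path}:{lineno}: expected 'id , genotypes' record")
        codes = line.split(",", 1)[1].split()
        for c in codes:
            if not c.isdigit() or len(c) not in (2, 4, 3, 6):
                raise ValueError(f"{path}:{lineno}: bad allele code {c!r}")


def read_genepop(
    path: str | Path, ploidy_sidecar: Optional[str | Path] = None
) -> GenotypeDataset:
    """Read a GENEPOP file, optionally with a ploidy/sex sidecar table.

    "00"/"000" codes become missing alleles.  Without a sidecar every
    individual is recorded as sex-unknown with unknown declared ploidy (the
    format itself is diploid-only).  With a sidecar, individuals whose declared
    ploidy is haploid have their duplicated-allele coding collapsed back to a
    single gene copy; a heterozygous genotype on a declared haploid is an
    error.
    """
    path = Path(path)
    _validate_genepop_lines(path)
    with open(path) as fh:
        rec = _genepop.read(fh)

    loci = [Locus(name=n) for n in rec.loci_list]
    sidecar = _read_sidecar(Path(ploidy_sidecar)) if ploidy_sidecar else None

    populations: list[PopulationSample] = []
    for k, poprecs in enumerate(rec.populations):
        individuals: list[Individual] = []
        pop_name = f"pop{k + 1}"
        habitat = "mainland"
        year: Optional[int] = None
        for raw_id, genos in poprecs:
            ind_id = raw_id.strip()
            sex: Sex = "unknown"
            ploidy: Ploidy = "unknown"
            if sidecar is not None:
                if ind_id not in sidecar:
                    raise ValueError(f"sidecar has no entry for individual {ind_id!r}")
                meta = sidecar[ind_id]
                sex = meta["sex"]  # type: ignore[assignment]
                ploidy = meta["ploidy"]  # type: ignore[assignment]
                pop_name = meta["population"]
                habitat = meta.get("habitat", habitat) or habitat
                if meta.get("year"):
                    year = int(meta["year"])
            genotypes: dict[str, tuple[int, ...]] = {}
            for locus, pair in zip(rec.loci_list, genos):
                alleles = tuple(a for a in pair if a)
                if not alleles:
                    continue
                if ploidy == "haploid":
                    if len(set(alleles)) > 1:
                        raise ValueError(
                            f"{ind_id} at {locus}: heterozygous genotype on a "
                            "declared haploid"
                        )
                    alleles = alleles[:1]
                genotypes[locus] = alleles
            individuals.append(
                Individual(id=ind_id, sex=sex, declared_ploidy=ploidy, genotypes=genotypes)
            )
        populations.append(
            PopulationSample(
                name=pop_name, habitat=habitat, year=year, individuals=individuals
            )
        )
    return GenotypeDataset(loci=loci, populations=populations)


def _allele_codes(dataset: GenotypeDataset) -> dict[str, dict[int, int]]:
    """Map allele labels to 3-digit codes per locus, preserving labels that fit."""
    table: dict[str, dict[int, int]] = {}
    for locus in dataset.locus_names:
        labels = sorted(
            {
                a
                for pop in dataset.populations
                for ind in pop.individuals
                for a in ind.genotype(locus)
            }
        )
        if all(1 <= a <= 999 for a in labels):
            table[locus] = {a: a for a in labels}
        else:
            if len(labels) > 999:
                raise ValueError(f"locus {locus}: >999 alleles cannot be coded")
            table[locus] = {a: i + 1 for i, a in enumerate(labels)}
    return table


def write_genepop(
    dataset: GenotypeDataset,
    path: str | Path,
    haploid_mode: Literal["duplicate", "merge_pairs"] = "duplicate",
    title: str = "dmpkit export",
) -> None:
    """Write GENEPOP text plus sidecar TSV and allele-code lookup TSV.

    ``duplicate`` writes each haploid allele twice (flagged haploid in the
    sidecar); ``merge_pairs`` first merges haploid males into pseudo-diploids
    via :func:`merge_haploid_pairs`.  Diploid records are written unchanged.
    Companion files are ``<path>.sidecar.tsv`` and ``<path>.codes.tsv``.
    """
    path = Path(path)
    codes = _allele_codes(dataset)

    def fmt(locus: str, alleles: tuple[int, ...]) -> str:
        if not alleles:
            return "000000"
        a = alleles if len(alleles) == 2 else alleles * 2
        return f"{codes[locus][a[0]]:03d}{codes[locus][a[1]]:03d}"

    sidecar_rows: list[tuple[str, str, str, str]] = []
    with open(path, "w") as out:
        out.write(title + "\n")
        for name in dataset.locus_names:
            out.write(name + "\n")
        for pop in dataset.populations:
            out.write("POP\n")
            individuals = pop.individuals
            if haploid_mode == "merge_pairs":
                haploids = [i for i in individuals if i.declared_ploidy == "haploid"]
                others = [i for i in individuals if i.declared_ploidy != "haploid"]
                individuals = others + merge_haploid_pairs(haploids)
            for ind in individuals:
                row = " ".join(fmt(l, ind.genotype(l)) for l in dataset.locus_names)
                out.write(f"{ind.id} , {row}\n")
                sidecar_rows.append((ind.id, pop.name, ind.sex, ind.declared_ploidy))

    with open(path.with_suffix(path.suffix + ".sidecar.tsv"), "w") as out:
        out.write("id\tpopulation\tsex\tploidy\thabitat\tyear\n")
        by_pop = {p.name: p for p in dataset.populations}
        for ind_id, pop_name, sex, ploidy in sidecar_rows:
            pop = by_pop[pop_name]
            year = "" if pop.year is None else str(pop.year)
            out.write(f"{ind_id}\t{pop_name}\t{sex}\t{ploidy}\t{pop.habitat}\t{year}\n")

    with open(path.with_suffix(path.suffix + ".codes.tsv"), "w") as out:
        out.write("locus\tallele_label\tcode\n")
        for locus, mapping in codes.items():
            for label, code in mapping.items():
                out.write(f"{locus}\t{label}\t{code:03d}\n")
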