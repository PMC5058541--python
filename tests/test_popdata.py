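"""Data model, GENEPOP round-trips, allele counting, false-diploid merging."""

import logging

import pytest
from hypothesis import given
from hypothesis import strategies as st

from dmpkit.popdata import (
    GenotypeDataset,
    Individual,
    Locus,
    PopulationSample,
    allele_frequencies,
    merge_haploid_pairs,
    read_genepop,
    write_genepop,
)


def test_read_genepop_three_digit(tmp_path):
    path = tmp_path / "x.gen"
    path.write_text(
        "title\nlocA\nlocB\nPOP\nm1 , 104104 000000\nm2 , 104120 095097\n"
    )
    ds = read_genepop(path)
    assert ds.locus_names == ["locA", "locB"]
    (pop,) = ds.populations
    m1, m2 = pop.individuals
    assert m1.genotype("locA") == (104, 104)
    assert m1.genotype("locB") == ()  # "000000" is missing
    assert m2.genotype("locB") == (95, 97)
    assert m1.declared_ploidy == "unknown"


def test_read_genepop_two_digit_dialect(tmp_path):
    path = tmp_path / "x.gen"
    path.write_text("t\nl1\nl2\nPop\na , 0104 0000\nb , 0304 0102\n")
    ds = read_genepop(path)
    a, b = ds.populations[0].individuals
    assert a.genotype("l1") == (1, 4)
    assert a.genotype("l2") == ()
    assert b.genotype("l2") == (1, 2)


def test_read_genepop_malformed_line_names_lineno(tmp_path):
    path = tmp_path / "bad.gen"
    path.write_text("t\nl1\nPOP\nm1 , 1x4104\n")
    with pytest.raises(ValueError, match="bad.gen:4"):
        read_genepop(path)


def test_sidecar_controls_ploidy_and_missing_id_errors(tmp_path):
    gen = tmp_path / "x.gen"
    gen.write_text("t\nl1\nPOP\nm1 , 104104\nm2 , 104120\n")
    side = tmp_path / "x.sidecar.tsv"
    side.write_text(
        "id\tpopulation\tsex\tploidy\nm1\tNice11\tmale\thaploid\nm2\tNice11\tmale\tdiploid\n"
    )
    ds = read_genepop(gen, side)
    m1, m2 = ds.populations[0].individuals
    assert m1.genotype("l1") == (104,)  # duplicated coding collapsed
    assert m2.genotype("l1") == (104, 120)
    assert ds.populations[0].name == "Nice11"

    side.write_text("id\tpopulation\tsex\tploidy\nm1\tNice11\tmale\thaploid\n")
    with pytest.raises(ValueError, match="m2"):
        read_genepop(gen, side)


def test_heterozygous_declared_haploid_is_error(tmp_path):
    gen = tmp_path / "x.gen"
    gen.write_text("t\nl1\nPOP\nm1 , 104120\n")
    side = tmp_path / "s.tsv"
    side.write_text("id\tpopulation\tsex\tploidy\nm1\tP\tmale\thaploid\n")
    with pytest.raises(ValueError, match="heterozygous"):
        read_genepop(gen, side)


def test_duplicate_locus_name_rejected():
    with pytest.raises(ValueError, match="duplicate locus"):
        GenotypeDataset(loci=[Locus("A"), Locus("A")], populations=[])


names = st.integers(0, 6)


@st.composite
def datasets(draw):
    n_loci = draw(st.integers(1, 4))
    loci = [Locus(f"L{i}") for i in range(n_loci)]
    n_pops = draw(st.integers(1, 2))
    pops = []
    uid = 0
    for p in range(n_pops):
        n_ind = draw(st.integers(1, 5))
        inds = []
        for _ in range(n_ind):
            uid += 1
            kind = draw(st.sampled_from(["female", "hap_male", "dip_male"]))
            genotypes = {}
            for l in loci:
                if draw(st.booleans()):
                    continue  # missing
                a = draw(st.integers(100, 300))
                if kind == "hap_male":
                    genotypes[l.name] = (a,)
                else:
                    genotypes[l.name] = (a, draw(st.integers(100, 300)))
            inds.append(
                Individual(
                    id=f"p{p}i{uid}",
                    sex="female" if kind == "female" else "male",
                    declared_ploidy="haploid" if kind == "hap_male" else "diploid",
                    genotypes=genotypes,
                )
            )
        pops.append(
            PopulationSample(
                name=f"P{p}",
                habitat=draw(st.sampled_from(["mainland", "island", "captive"])),
                year=draw(st.one_of(st.none(), st.integers(2010, 2013))),
                individuals=inds,
            )
        )
    return GenotypeDataset(loci=loci, populations=pops)


@given(datasets())
def test_genepop_roundtrip_identity(tmp_path_factory, ds):
    """write -> read restores the dataset exactly (sidecar carries ploidy)."""
    tmp = tmp_path_factory.mktemp("rt")
    path = tmp / "d.gen"
    write_genepop(ds, path, haploid_mode="duplicate")
    back = read_genepop(path, path.with_suffix(path.suffix + ".sidecar.tsv"))
    assert back == ds


def test_merge_haploid_pairs_conserves_allele_counts():
    males = [
        Individual(id=f"m{i}", sex="male", declared_ploidy="haploid", genotypes={"L": (a,)})
        for i, a in enumerate([104, 120, 104, 130, 140])
    ]
    merged = merge_haploid_pairs(males)
    assert len(merged) == 2  # 5 males -> 2 pairs, 1 dropped
    pooled = [a for m in merged for a in m.genotype("L")]
    # dropped male is the lexicographically last id (m4 carries 140)
    assert sorted(pooled) == [104, 104, 120, 130]
    assert all(m.declared_ploidy == "diploid" for m in merged)


def test_merge_haploid_pairs_two_males_single_pseudo_diploid():
    males = [
        Individual(id="a", sex="male", declared_ploidy="haploid", genotypes={"L": (104,)}),
        Individual(id="b", sex="male", declared_ploidy="haploid", genotypes={"L": (120,)}),
    ]
    (fd,) = merge_haploid_pairs(males)
    assert fd.genotype("L") == (104, 120)


def test_merge_haploid_pairs_rejects_diploids_and_handles_empty():
    assert merge_haploid_pairs([]) == []
    dip = Individual(id="d", sex="male", declared_ploidy="diploid", genotypes={})
    with pytest.raises(ValueError, match="not haploid"):
        merge_haploid_pairs([dip])


def test_allele_frequencies_gene_copy_counting():
    inds = [
        Individual(id="h", sex="male", declared_ploidy="haploid", genotypes={"L": (1,)}),
        Individual(id="d", sex="female", declared_ploidy="diploid", genotypes={"L": (1, 2)}),
    ]
    pop = PopulationSample(name="p", habitat="mainland", individuals=inds)
    tab = allele_frequencies(pop, "L")
    assert tab.n_copies == 3
    assert tab.frequencies == {1: 2 / 3, 2: 1 / 3}
    assert sum(tab.counts.values()) == tab.n_copies

    assert allele_frequencies(pop, "L", use="haploids_only").counts == {1: 1}
    empty = PopulationSample(name="e", habitat="mainland", individuals=[])
    assert allele_frequencies(empty, "L").n_copies == 0


def test_allele_frequencies_all_missing():
    inds = [Individual(id="d", sex="female", declared_ploidy="diploid", genotypes={})]
    pop = PopulationSample(name="p", habitat="mainland", individuals=inds)
    assert allele_frequencies(pop, "L").n_copies == 0
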