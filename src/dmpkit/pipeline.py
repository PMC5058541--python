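"""End-to-end orchestration: simulate or read data, call ploidy, summarize
diversity, fit the habitat model, and recompute the bundled reference
statistics.

Two packaged fixtures transcribe the published summary tables for
*Venturia canescens*: ``table3`` (per-locus diversity of the two female
validation samples, Nice10 and Val10) and ``table4`` (per-population male
counts, allelic richness and private alleles for eleven mainland / island /
captive populations).  :func:`reproduce_reference` recomputes every statistic
derivable from those fixtures alone and compares it to the published value.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Literal, Optional, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .diversity import DiversitySummary, population_summary
from .dmpstats import (
    HabitatModelResult,
    PopulationRecord,
    cohens_d,
    fit_dmp_glm,
    kruskal_wallis,
    lr_type2_tests,
    two_proportion_yates,
    welch_t,
)
from .ploidy import (
    all_homozygous_probability,
    call_population,
    dmp_from_counts,
    summarize_dmp,
)
from .popdata import GenotypeDataset, read_genepop
from .slcsd import build_scenario, sample_trap_survey, simulate_population

__all__ = [
    "PipelineConfig",
    "PipelineResult",
    "load_table3",
    "load_table4",
    "records_from_table4",
    "run_pipeline",
    "reproduce_reference",
]


def _data_path(name: str):
    return resources.files("dmpkit").joinpath("data", name)


def load_table3() -> pd.DataFrame:
    with resources.as_file(_data_path("table3.tsv")) as p:
        return pd.read_csv(p, sep="\t")


def load_table4() -> pd.DataFrame:
    with resources.as_file(_data_path("table4.tsv")) as p:
        return pd.read_csv(p, sep="\t")


def records_from_table4(df: Optional[pd.DataFrame] = None) -> list[PopulationRecord]:
    if df is None:
        df = load_table4()
    return [
        PopulationRecord(
            population=r["population"],
            habitat=r["habitat"],
            n_haploid=int(r["n_haploid"]),
            n_diploid=int(r["n_diploid"]),
            allelic_richness=float(r["allelic_richness"]),
            private_alleles=float(r["private_alleles"]),
        )
        for _, r in df.iterrows()
    ]


_PRESET_HABITAT = {
    "mainland": "mainland",
    "island": "island",
    "captive_large": "captive",
    "captive_small": "captive",
}


@dataclass
class PipelineConfig:
    """Exactly one of (``genepop``, ``scenarios``) must be set.

    ``scenarios`` is a sequence of (population_name, preset) pairs simulated
    with seeds derived from ``seed``; ``genepop``/``sidecar`` read an existing
    dataset instead.
    """

    genepop: Optional[Path] = None
    sidecar: Optional[Path] = None
    scenarios: Optional[Sequence[tuple[str, str]]] = None
    min_typed: int = 8
    ci_method: Literal["clopper_pearson", "wilson"] = "clopper_pearson"
    n_mc: int = 5000
    enum_cap: int = 20000
    n_males: int = 60
    n_females: int = 0
    seed: int = 0
    outdir: Optional[Path] = None

    def __post_init__(self) -> None:
        if (self.genepop is None) == (self.scenarios is None):
            raise ValueError("set exactly one of genepop or scenarios")


@dataclass
class PipelineResult:
    dataset: GenotypeDataset
    calls: pd.DataFrame
    dmp_by_population: pd.DataFrame
    summary: DiversitySummary
    records: list[PopulationRecord]
    model: Optional[HabitatModelResult]
    lr_table: Optional[pd.DataFrame]
    log_lines: list[str] = field(default_factory=list)


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute read/simulate -> ploidy calling -> diversity -> habitat model.

    Fully deterministic given the config and seed; every discarded individual
    is accounted for in the log lines (and the run log file when ``outdir``
    is set).
    """
    log = [f"dmpkit {__version__}", f"seed {config.seed}"]
    if config.scenarios is not None:
        pops = []
        loci = None
        for i, (name, preset) in enumerate(config.scenarios):
            cfg = build_scenario(preset, seed=config.seed + 1000 * i)
            sim = simulate_population(cfg)
            if sim.extinct:
                log.append(f"{name}: population extinct, resimulating is up to caller")
            n_males = min(config.n_males, sim.n_males)
            n_females = min(config.n_females, sim.n_females)
            ds = sample_trap_survey(
                sim,
                n_males=n_males,
                n_females=n_females,
                seed=config.seed + 1000 * i + 500,
                population_name=name,
                habitat=_PRESET_HABITAT[preset],
            )
            loci = ds.loci
            pops.append(ds.populations[0])
            log.append(f"{name}: preset {preset}, sampled {n_males} males, {n_females} females")
        dataset = GenotypeDataset(loci=loci, populations=pops)
    else:
        dataset = read_genepop(config.genepop, config.sidecar)
        log.append(f"read {config.genepop}")

    call_rows = []
    dmp_rows = []
    for pop in dataset.populations:
        calls = call_population(pop.males(), min_typed=config.min_typed, population=pop.name)
        for c in calls:
            call_rows.append(
                {
                    "id": c.id,
                    "population": pop.name,
                    "n_typed": c.n_typed,
                    "n_het": c.n_het,
                    "call": c.call,
                }
            )
            if c.call == "excluded":
                log.append(f"excluded {pop.name}/{c.id}: {c.n_typed} typed loci")
        usable = [c for c in calls if c.call != "excluded"]
        if usable:
            est = summarize_dmp(usable, ci_method=config.ci_method)
            dmp_rows.append(
                {
                    "population": pop.name,
                    "habitat": pop.habitat,
                    "n_diploid": est.n_diploid,
                    "n_haploid": est.n_haploid,
                    "dmp": est.dmp,
                    "se": est.se,
                    "ci_low": est.ci_low,
                    "ci_high": est.ci_high,
                }
            )
    calls_df = pd.DataFrame(call_rows)
    dmp_df = pd.DataFrame(dmp_rows)

    summary = population_summary(
        dataset,
        mode="males_merged_pairs",
        min_typed=config.min_typed,
        n_mc=config.n_mc,
        enum_cap=config.enum_cap,
        seed=config.seed,
    )
    log.extend(f"dropped: {d}" for d in summary.dropped)

    records = [
        PopulationRecord(
            population=r["population"],
            habitat=r["habitat"],
            n_haploid=int(r["n_haploid"]),
            n_diploid=int(r["n_diploid"]),
            allelic_richness=float(r["overall_richness"]),
            private_alleles=float(r["private_alleles"]),
        )
        for _, r in summary.per_population.iterrows()
        if "n_haploid" in r and r["n_haploid"] + r["n_diploid"] > 0
    ]

    model = None
    lr = None
    if len({r.habitat for r in records}) >= 2:
        model = fit_dmp_glm(records)
        lr = lr_type2_tests(model)
        log.append(f"GLM dropped columns: {model.dropped_columns}")
    else:
        log.append("habitat model skipped: fewer than 2 habitats present")

    result = PipelineResult(
        dataset=dataset,
        calls=calls_df,
        dmp_by_population=dmp_df,
        summary=summary,
        records=records,
        model=model,
        lr_table=lr,
        log_lines=log,
    )
    if config.outdir is not None:
        _write_outputs(result, Path(config.outdir))
    return result


def _write_outputs(result: PipelineResult, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    result.calls.to_csv(outdir / "ploidy_calls.tsv", sep="\t", index=False)
    result.dmp_by_population.to_csv(outdir / "dmp_by_population.tsv", sep="\t", index=False)
    result.summary.to_tsv(outdir / "per_locus.tsv", outdir / "per_population.tsv")
    if result.lr_table is not None:
        result.lr_table.to_csv(outdir / "model_lr.tsv", sep="\t", index=False)
    (outdir / "run_log.txt").write_text("\n".join(result.log_lines) + "\n")


# ---------------------------------------------------------------------------
# Reference reproduction


def _check(statistic, computed, reference, tol, unit=""):
    passed = abs(computed - reference) <= tol
    return {
        "statistic": statistic,
        "computed": computed,
        "reference": reference,
        "tolerance": tol,
        "unit": unit,
        "passed": bool(passed),
    }


def reproduce_reference(fixture: Literal["table3", "table4"]) -> pd.DataFrame:
    """Recompute the published statistics derivable from one fixture.

    Returns a pass/fail comparison table.  Printed 2-decimal statistics are
    matched to +-0.005; proportions to the printed decimal; the all-homozygous
    mis-scoring probability is checked for order of magnitude only (the exact
    published computation pooled information not printed with the tables).
    """
    rows = []
    if fixture == "table4":
        t4 = load_table4()
        n_dip = int(t4["n_diploid"].sum())
        n_hap = int(t4["n_haploid"].sum())
        overall = dmp_from_counts(n_dip, n_hap)
        rows.append(_check("total genotyped males", overall.n, 599, 0))
        rows.append(_check("overall DMP", 100 * overall.dmp, 6.8, 0.05, "%"))
        rows.append(_check("overall DMP CI low", 100 * overall.ci_low, 5.0, 0.05, "%"))
        rows.append(_check("overall DMP CI high", 100 * overall.ci_high, 9.2, 0.05, "%"))
        for pop, ref_dmp, ref_se in [("CapIsr", 0.16, 0.05), ("CapVal", 0.02, 0.02)]:
            r = t4[t4["population"] == pop].iloc[0]
            est = dmp_from_counts(int(r["n_diploid"]), int(r["n_haploid"]))
            rows.append(_check(f"{pop} DMP", est.dmp, ref_dmp, 0.005))
            rows.append(_check(f"{pop} DMP SE", est.se, ref_se, 0.005))
        groups = {
            h: g["private_alleles"].to_numpy(dtype=float)
            for h, g in t4.groupby("habitat", sort=False)
        }
        H, df, _ = kruskal_wallis(groups["mainland"], groups["island"], groups["captive"])
        rows.append(_check("Kruskal-Wallis H (private alleles ~ habitat)", H, 5.68, 0.005))
        rows.append(_check("Kruskal-Wallis df", df, 2, 0))
        rows.append(
            _check(
                "Cohen's d private alleles mainland-captive",
                cohens_d(groups["mainland"], groups["captive"]), 1.52, 0.005,
            )
        )
        rows.append(
            _check(
                "Cohen's d private alleles island-captive",
                cohens_d(groups["island"], groups["captive"]), 1.41, 0.005,
            )
        )
        rows.append(
            _check(
                "Cohen's d private alleles mainland-island",
                cohens_d(groups["mainland"], groups["island"]), 1.09, 0.005,
            )
        )
        n11 = t4[t4["population"] == "Nice11"].iloc[0]
        n13 = t4[t4["population"] == "Nice13"].iloc[0]
        chi2, _, _ = two_proportion_yates(
            int(n11["n_diploid"]), int(n11["n_diploid"] + n11["n_haploid"]),
            int(n13["n_diploid"]), int(n13["n_diploid"] + n13["n_haploid"]),
        )
        rows.append(_check("Yates chi2 DMP Nice11 vs Nice13", chi2, 0.760, 0.005))
        model = fit_dmp_glm(records_from_table4(t4))
        lr = lr_type2_tests(model)
        habit = lr[lr["term"] == "Habit"].iloc[0]
        rows.append(_check("GLM habitat LR chi2", habit["lr_chi2"], 7.071, 0.005))
        rows.append(_check("GLM habitat df", habit["df"], 2, 0))
    elif fixture == "table3":
        t3 = load_table3()
        mI = t3[t3["multiplex"] == "I"]
        mII = t3[t3["multiplex"] == "II"]
        t, df, _ = welch_t(mI["n_alleles"], mII["n_alleles"])
        rows.append(_check("Welch t allele counts multiplex I vs II", t, -0.88, 0.005))
        ho_I = np.concatenate([mI["nice10_ho"], mI["val10_ho"]])
        ho_II = np.concatenate([mII["nice10_ho"], mII["val10_ho"]])
        t, df, _ = welch_t(ho_I, ho_II)
        rows.append(_check("Welch t Ho multiplex I vs II", t, -0.54, 0.005))
        p_allhom = all_homozygous_probability(
            [1.0 - he for he in mI["nice10_he"]], F=0.25
        )
        ok = 1e-3 <= p_allhom <= 1e-2
        rows.append(
            {
                "statistic": "P(all 10 loci homozygous | sib-mated diploid), Nice10",
                "computed": p_allhom,
                "reference": 0.0023,
                "tolerance": "order of magnitude [1e-3, 1e-2]",
                "unit": "",
                "passed": bool(ok),
            }
        )
    else:
        raise ValueError("fixture must be 'table3' or 'table4'")
    return pd.DataFrame(rows)
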