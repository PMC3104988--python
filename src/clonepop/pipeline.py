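"""End-to-end orchestration and the breeding-mode classifier.

For every population the pipeline computes the clonality statistics
(MLMG partition, R, GD ratio, P_sex), heterozygosity and Fis (raw and
clone-corrected), Hardy-Weinberg score tests per locus with a combined
population-level p per tail, and optionally the r_d linkage tests (raw
and clone-corrected) and the PCoA/K-means ordination.  The verdict rules:

* GD ratio < threshold AND Hardy-Weinberg rejected (Bonferroni-adjusted)
  -> obligate;
* GD ratio > threshold AND Hardy-Weinberg not rejected -> cyclic;
* anything else -> mixed-or-uncertain.

The Bonferroni family is populations x test tails.  P_sex counts, Fis
sign and the r_d pair are advisory evidence recorded in the rule trace,
not part of the binary rule.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import clonal, hwe_ld, ordination as ord_mod
from .genotypes_io import GenotypeDataset, complete_cases, read_genepop, read_genotype_csv
from .simulate import PopulationSpec, merge_datasets, simulate_population

logger = logging.getLogger(__name__)

OBLIGATE = "obligate"
CYCLIC = "cyclic"
MIXED = "mixed-or-uncertain"


@dataclass
class PopulationStats:
    population: str
    G: int
    N: int
    R: Optional[float]
    gd_ratio: float
    gd: clonal.GDRatioResult
    fis_raw: Optional[float]
    fis_clone_corrected: Optional[float]
    hwe_excess_p: float
    hwe_deficiency_p: float
    hwe_fisher_excess_p: Optional[float]
    hwe_fisher_deficiency_p: Optional[float]
    hwe_per_locus: Dict[str, Dict[str, Optional[float]]]
    het: hwe_ld.HetStats
    psex_rows: List[Tuple[str, int, Optional[float], Optional[float]]]
    rd_raw: Optional[hwe_ld.TestResult] = None
    rd_clone_corrected: Optional[hwe_ld.TestResult] = None


@dataclass
class Verdict:
    population: str
    verdict: str
    trace: List[str]


@dataclass
class BreedingModeReport:
    populations: Dict[str, PopulationStats]
    verdicts: Dict[str, Verdict]
    parameters: Dict

    def to_json(self) -> str:
        def default(o):
            if hasattr(o, "__dict__"):
                return o.__dict__
            if isinstance(o, (np.floating, np.integer)):
                return o.item()
            if isinstance(o, np.ndarray):
                return o.tolist()
            return str(o)
        payload = {
            "parameters": self.parameters,
            "populations": {
                p: asdict(s) for p, s in self.populations.items()
            },
            "verdicts": {p: asdict(v) for p, v in self.verdicts.items()},
        }
        return json.dumps(payload, indent=2, sort_keys=True, default=default)


def compute_population_stats(pop_dataset: GenotypeDataset,
                             seed: int,
                             hwe_method: str = "sampling",
                             hwe_samples: int = 10000,
                             hwe_chain: Optional[Dict[str, int]] = None,
                             gd_replicates: int = 1000,
                             gd_method: str = "auto",
                             run_ld: bool = True,
                             ld_permutations: int = 1000) -> PopulationStats:
    """All per-population statistics on a complete single-population
    dataset."""
    pop = pop_dataset.population_names()[0]
    rng = np.random.default_rng(seed)
    part = clonal.partition_mlmg(pop_dataset)
    fis_raw = hwe_ld.fis_wc(pop_dataset).multilocus
    reps = part.representatives()
    fis_cc = (hwe_ld.fis_wc(pop_dataset.subset(reps)).multilocus
              if len(reps) >= 2 else None)

    cstats = clonal.clonal_stats(
        pop_dataset, fis=fis_raw if fis_raw is not None else 0.0,
        n_replicates=gd_replicates, seed=int(rng.integers(2 ** 31)),
        gd_method=gd_method)

    # population-level decision statistic: the global score test (sum of
    # het counts over loci under the per-locus conditional null), which
    # stays calibrated where Fisher-combining discrete per-locus
    # p-values is badly conservative
    glob = {
        tail: hwe_ld.global_hwe_score_test(
            pop_dataset, tail, n_samples=hwe_samples,
            seed=int(rng.integers(2 ** 31)))
        for tail in ("excess", "deficiency")
    }
    hwe = hwe_ld.multilocus_hwe(
        pop_dataset, method=hwe_method, chain=hwe_chain,
        n_samples=hwe_samples, seed=int(rng.integers(2 ** 31)))
    het = hwe_ld.het_stats(pop_dataset)
    per_locus: Dict[str, Dict[str, Optional[float]]] = {}
    fis_loci = hwe_ld.fis_wc(pop_dataset).per_locus
    for locus in pop_dataset.loci:
        ho, he, _n = het.per_locus[locus]
        per_locus[locus] = {
            "Ho": ho, "He": he, "Fis": fis_loci[locus],
            "p_excess": hwe.per_locus[locus]["excess"].p_value,
            "p_deficiency": hwe.per_locus[locus]["deficiency"].p_value,
        }

    rd_raw = rd_cc = None
    if run_ld:
        rd_raw = hwe_ld.rbar_d(pop_dataset, n_perm=ld_permutations,
                               seed=int(rng.integers(2 ** 31)))
        rd_cc = hwe_ld.rbar_d(pop_dataset, n_perm=ld_permutations,
                              seed=int(rng.integers(2 ** 31)),
                              clone_correct=True)

    return PopulationStats(
        population=pop, G=part.G, N=part.N,
        R=clonal.genotypic_richness(part),
        gd_ratio=cstats.gd.ratio, gd=cstats.gd,
        fis_raw=fis_raw, fis_clone_corrected=fis_cc,
        hwe_excess_p=glob["excess"].p_value,
        hwe_deficiency_p=glob["deficiency"].p_value,
        hwe_fisher_excess_p=hwe.combined["excess"],
        hwe_fisher_deficiency_p=hwe.combined["deficiency"],
        hwe_per_locus=per_locus, het=het,
        psex_rows=cstats.repeated_mlmgs,
        rd_raw=rd_raw, rd_clone_corrected=rd_cc)


def classify_population(stats: PopulationStats, alpha: float = 0.05,
                        gd_threshold: float = 0.75,
                        psex_threshold: float = 0.01,
                        bonferroni_m: int = 1) -> Verdict:
    """Apply the GD-ratio / Hardy-Weinberg decision rules.

    ``bonferroni_m`` is the size of the test family (populations x
    tails); the Hardy-Weinberg null is rejected when the smaller of the
    combined excess/deficiency p-values falls below alpha/bonferroni_m.
    """
    for name, value in (("gd_ratio", stats.gd_ratio),
                        ("hwe_excess_p", stats.hwe_excess_p),
                        ("hwe_deficiency_p", stats.hwe_deficiency_p)):
        if value is None or (isinstance(value, float) and np.isnan(value)):
            raise ValueError(f"missing required statistic {name!r} "
                             f"for population {stats.population}")
    threshold = alpha / max(bonferroni_m, 1)
    p_min = min(stats.hwe_excess_p, stats.hwe_deficiency_p)
    rejected = p_min < threshold
    direction = ("excess" if stats.hwe_excess_p <= stats.hwe_deficiency_p
                 else "deficiency")
    trace = [
        f"GD ratio = {stats.gd_ratio:.4f} (threshold {gd_threshold})",
        f"HWE combined p: excess = {stats.hwe_excess_p:.4g}, "
        f"deficiency = {stats.hwe_deficiency_p:.4g}; "
        f"Bonferroni-adjusted alpha = {threshold:.4g}; "
        f"{'rejected (' + direction + ')' if rejected else 'not rejected'}",
    ]
    n_sig_psex = sum(1 for _, _, ps, _ in stats.psex_rows
                     if ps is not None and ps < psex_threshold)
    trace.append(f"significant P_sex (<{psex_threshold}): {n_sig_psex} of "
                 f"{len(stats.psex_rows)} repeated MLMGs")
    if stats.fis_raw is not None:
        trace.append(f"multilocus Fis (raw) = {stats.fis_raw:.3f}"
                     + (f", clone-corrected = {stats.fis_clone_corrected:.3f}"
                        if stats.fis_clone_corrected is not None else ""))
    for tag, rd in (("raw", stats.rd_raw),
                    ("clone-corrected", stats.rd_clone_corrected)):
        if rd is not None and rd.p_value is not None:
            trace.append(f"r_d ({tag}) = {rd.statistic:.4f}, p = {rd.p_value:.4g}")

    if stats.gd_ratio < gd_threshold and rejected:
        verdict = OBLIGATE
        trace.append("rule 1 fired: GD < threshold and HWE rejected -> obligate")
    elif stats.gd_ratio > gd_threshold and not rejected:
        verdict = CYCLIC
        trace.append("rule 2 fired: GD > threshold and HWE not rejected -> cyclic")
    else:
        verdict = MIXED
        trace.append("no rule fired -> mixed-or-uncertain")
    return Verdict(population=stats.population, verdict=verdict, trace=trace)


DEFAULT_CONFIG = {
    "seed": 0,
    "alpha": 0.05,
    "gd_threshold": 0.75,
    "psex_threshold": 0.01,
    "hwe_method": "sampling",
    "hwe_samples": 10000,
    "hwe_chain": None,
    "gd_replicates": 1000,
    "gd_method": "auto",
    "run_ld": True,
    "ld_permutations": 1000,
    "run_ordination": False,
}


def load_dataset_from_config(config: Dict) -> GenotypeDataset:
    if "simulate" in config:
        parts = []
        for spec_dict in config["simulate"]:
            spec = PopulationSpec(**spec_dict)
            ds, _ = simulate_population(spec)
            parts.append(ds)
        return merge_datasets(parts)
    inp = config["input"]
    if inp["format"] == "genepop":
        return read_genepop(inp["path"])
    if inp["format"] == "csv":
        return read_genotype_csv(inp["path"])
    raise ValueError(f"unknown input format {inp['format']!r}")


def run_pipeline(config: Dict, outdir=None) -> BreedingModeReport:
    """Execute the full per-population pipeline from a config mapping.

    The run is reproducible from (config, seed): per-population seeds are
    spawned deterministically from the master seed.
    """
    cfg = dict(DEFAULT_CONFIG)
    cfg.update(config)
    dataset = load_dataset_from_config(cfg)
    dataset = complete_cases(dataset)
    master = np.random.SeedSequence(cfg["seed"])
    by_pop = dataset.split_populations()
    pop_seeds = {pop: int(child.generate_state(1)[0] % (2 ** 31))
                 for pop, child in zip(by_pop, master.spawn(len(by_pop)))}
    stats: Dict[str, PopulationStats] = {}
    for pop, sub in by_pop.items():
        try:
            stats[pop] = compute_population_stats(
                sub, seed=pop_seeds[pop],
                hwe_method=cfg["hwe_method"], hwe_samples=cfg["hwe_samples"],
                hwe_chain=cfg["hwe_chain"], gd_replicates=cfg["gd_replicates"],
                gd_method=cfg["gd_method"], run_ld=cfg["run_ld"],
                ld_permutations=cfg["ld_permutations"])
        except Exception as exc:
            raise RuntimeError(
                f"pipeline stage failed for population {pop!r}: {exc}"
            ) from exc
    bonferroni_m = 2 * len(stats)
    verdicts = {
        pop: classify_population(s, alpha=cfg["alpha"],
                                 gd_threshold=cfg["gd_threshold"],
                                 psex_threshold=cfg["psex_threshold"],
                                 bonferroni_m=bonferroni_m)
        for pop, s in stats.items()
    }
    report = BreedingModeReport(
        populations=stats, verdicts=verdicts,
        parameters={k: cfg[k] for k in DEFAULT_CONFIG} | {
            "bonferroni_m": bonferroni_m})
    if outdir is not None:
        write_report(report, dataset, outdir,
                     run_ordination=cfg["run_ordination"],
                     seed=cfg["seed"])
    return report


def write_report(report: BreedingModeReport, dataset: GenotypeDataset,
                 outdir, run_ordination: bool = False,
                 seed: int = 0) -> None:
    """Write TSV/JSON artifacts for every pipeline stage."""
    import pathlib

    out = pathlib.Path(outdir)
    out.mkdir(parents=True, exist_ok=True)

    rows = []
    for pop, s in report.populations.items():
        rows.append({
            "population": pop, "G": s.G, "N": s.N,
            "R": s.R, "GD_ratio": s.gd_ratio,
            "mlmg": "", "n_copies": "", "P_sex": "", "P_sex_fis": "",
        })
        for mlmg, n, ps, psf in s.psex_rows:
            rows.append({"population": pop, "G": "", "N": "", "R": "",
                         "GD_ratio": "", "mlmg": mlmg, "n_copies": n,
                         "P_sex": ps, "P_sex_fis": psf})
    pd.DataFrame(rows).to_csv(out / "clonal_stats.tsv", sep="\t", index=False)

    locus_rows = []
    for pop, s in report.populations.items():
        for locus, vals in s.hwe_per_locus.items():
            locus_rows.append({"population": pop, "locus": locus, **vals})
    pd.DataFrame(locus_rows).to_csv(out / "hwe_per_locus.tsv", sep="\t",
                                    index=False)

    summary_rows = []
    for pop, s in report.populations.items():
        summary_rows.append({
            "population": pop,
            "Fis1": s.fis_raw, "Fis2": s.fis_clone_corrected,
            "Ho": s.het.ho_overall, "He": s.het.he_overall,
            "hwe_excess_p": s.hwe_excess_p,
            "hwe_deficiency_p": s.hwe_deficiency_p,
            "rd1": s.rd_raw.statistic if s.rd_raw else None,
            "rd1_p": s.rd_raw.p_value if s.rd_raw else None,
            "rd2": (s.rd_clone_corrected.statistic
                    if s.rd_clone_corrected else None),
            "rd2_p": (s.rd_clone_corrected.p_value
                      if s.rd_clone_corrected else None),
            "verdict": report.verdicts[pop].verdict,
        })
    pd.DataFrame(summary_rows).to_csv(out / "population_summary.tsv",
                                      sep="\t", index=False)

    (out / "report.json").write_text(report.to_json(), encoding="utf-8")

    if run_ordination and not dataset.has_missing():
        mat, _cols = ord_mod.binary_allele_matrix(dataset)
        dm = ord_mod.nei_binary_distance(mat, labels=dataset.individuals)
        ordn = ord_mod.pcoa(dm)
        n_axes = min(10, ordn.coordinates.shape[1])
        ord_df = pd.DataFrame(
            ordn.coordinates[:, :n_axes],
            columns=[f"axis{k + 1}" for k in range(n_axes)])
        ord_df.insert(0, "individual", dataset.individuals)
        ord_df.insert(1, "population",
                      [dataset.populations[i] for i in dataset.individuals])
        if dataset.n_individuals >= 11:
            clusters = ord_mod.cascade_kmeans(ordn, seed=seed)
            ord_df["cluster"] = clusters.labels
        ord_df.to_csv(out / "ordination.tsv", sep="\t", index=False)
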