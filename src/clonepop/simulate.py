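"""Seeded generators for genotype datasets and haplotype sets.

The generators emulate the three population archetypes the inference
pipeline must tell apart:

* ``cyclic`` - panmictic draws from per-locus Dirichlet allele
  frequencies, with an optional inbreeding coefficient F;
* ``obligate`` - a handful of founder genotypes copied clonally, with
  skewed (geometric) copy numbers, optionally of F1-hybrid origin (one
  allele from each of two divergent pools per locus, which fixes
  heterozygosity when the pools share no alleles) and optional stepwise
  mutation on copies;
* ``mixed`` - a cyclic and an obligate draw concatenated over shared
  allele pools.

All generators are bit-reproducible given (spec, seed) and return a
machine-readable truth record alongside the dataset.  Allele labels are
integer ladders rendered as 3-digit strings so that stepwise mutation
(+/-1) and GenePop export both work.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, asdict
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .genotypes_io import GenotypeDataset
from .mtdna import APOI_RE, HaplotypeSet, collapse_haplotypes

logger = logging.getLogger(__name__)

Pool = Dict[str, float]  # allele label -> frequency


@dataclass
class PopulationSpec:
    """Parameters of one simulated population."""

    mode: str                       # "cyclic" | "obligate" | "mixed"
    name: str = "pop1"
    n: int = 30
    n_loci: int = 8
    alleles_min: int = 5
    alleles_max: int = 22
    dirichlet_conc: float = 1.0
    inbreeding_f: float = 0.0       # cyclic component only
    clone_count: int = 5            # obligate component only
    copy_geom_q: float = 0.5        # geometric decay of clone copy numbers
    hybrid: bool = True             # obligate founders of F1-hybrid origin
    asexual_fraction: float = 0.5   # mixed mode only
    mixed_clone_fraction: float = 0.5  # clones per asexual individual (mixed)
    missing_rate: float = 0.0
    mutation_rate: float = 0.0      # per allele copy, stepwise +/-1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("cyclic", "obligate", "mixed"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if not 0 <= self.missing_rate <= 1:
            raise ValueError("missing_rate must lie in [0, 1]")
        if self.clone_count > self.n:
            raise ValueError("clone_count cannot exceed n")


def _label(value: int) -> str:
    if not 1 <= value <= 999:
        raise ValueError("allele ladder value out of 3-digit range")
    return f"{value:03d}"


def _draw_pool(rng: np.random.Generator, k: int, conc: float,
               base: int) -> Pool:
    freqs = rng.dirichlet(np.full(k, conc))
    return {_label(base + i): float(f) for i, f in enumerate(freqs)}


def draw_pools(rng: np.random.Generator, spec: PopulationSpec,
               base: int = 100) -> List[Pool]:
    """One allele frequency pool per locus."""
    pools = []
    for _ in range(spec.n_loci):
        k = int(rng.integers(spec.alleles_min, spec.alleles_max + 1))
        pools.append(_draw_pool(rng, k, spec.dirichlet_conc, base))
    return pools


def _genotype_distribution(pool: Pool, f: float
                           ) -> Tuple[List[Tuple[str, str]], np.ndarray]:
    alleles = sorted(pool)
    p = np.asarray([pool[a] for a in alleles])
    pmin = p.min()
    if f < -pmin / (1 - pmin) - 1e-12 or f > 1.0 + 1e-12:
        raise ValueError(
            f"inbreeding F={f} outside valid range "
            f"({-pmin / (1 - pmin):.4f}, 1] for this frequency vector")
    genotypes: List[Tuple[str, str]] = []
    probs: List[float] = []
    for i, a in enumerate(alleles):
        for j in range(i, len(alleles)):
            b = alleles[j]
            if i == j:
                g = p[i] ** 2 + p[i] * (1 - p[i]) * f
            else:
                g = 2 * p[i] * p[j] * (1 - f)
            genotypes.append((a, b))
            probs.append(max(float(g), 0.0))
    arr = np.asarray(probs)
    return genotypes, arr / arr.sum()


def _sample_cyclic_calls(rng: np.random.Generator, pools: Sequence[Pool],
                         n: int, f: float) -> List[List[Tuple[str, str]]]:
    columns = []
    for pool in pools:
        genotypes, probs = _genotype_distribution(pool, f)
        draws = rng.choice(len(genotypes), size=n, p=probs)
        columns.append([genotypes[d] for d in draws])
    return [[columns[l][i] for l in range(len(pools))] for i in range(n)]


def _dataset(spec: PopulationSpec, calls, loci=None) -> GenotypeDataset:
    loci = loci or [f"L{j + 1}" for j in range(spec.n_loci)]
    individuals = [f"{spec.name}_i{i + 1:03d}" for i in range(len(calls))]
    return GenotypeDataset(
        individuals=individuals,
        populations={ind: spec.name for ind in individuals},
        loci=list(loci),
        calls=[list(row) for row in calls],
    )


def inject_missing(dataset: GenotypeDataset, rate: float,
                   seed: Optional[int] = None) -> GenotypeDataset:
    """Set each call to MISSING independently with probability ``rate``."""
    rng = np.random.default_rng(seed)
    out = dataset.subset(dataset.individuals)
    for row in out.calls:
        for j in range(len(row)):
            if rng.random() < rate:
                row[j] = None
    return out


def simulate_cyclic(spec: PopulationSpec,
                    pools: Optional[Sequence[Pool]] = None
                    ) -> Tuple[GenotypeDataset, Dict]:
    """Panmictic (optionally inbred) population draw."""
    rng = np.random.default_rng(spec.seed)
    if pools is None:
        pools = draw_pools(rng, spec)
    calls = _sample_cyclic_calls(rng, pools, spec.n, spec.inbreeding_f)
    ds = _dataset(spec, calls)
    if spec.missing_rate > 0:
        ds = inject_missing(ds, spec.missing_rate,
                            seed=int(rng.integers(2 ** 31)))
    truth = {"mode": "cyclic", "pools": [dict(p) for p in pools],
             "F": spec.inbreeding_f, "spec": asdict(spec)}
    return ds, truth


def _mutate_call(rng: np.random.Generator, call: Tuple[str, str],
                 rate: float) -> Tuple[str, str]:
    if rate <= 0:
        return call
    out = list(call)
    for k in range(2):
        if rng.random() < rate:
            step = 1 if rng.random() < 0.5 else -1
            value = max(1, min(999, int(out[k]) + step))
            out[k] = _label(value)
    return tuple(sorted(out))  # type: ignore[return-value]


def simulate_obligate(spec: PopulationSpec,
                      pools: Optional[Sequence[Pool]] = None,
                      pools_b: Optional[Sequence[Pool]] = None
                      ) -> Tuple[GenotypeDataset, Dict]:
    """Clonal population of ``clone_count`` founder genotypes.

    Hybrid founders take one allele from pool A and one from pool B per
    locus; with disjoint pools this fixes heterozygosity at every locus.
    Copy numbers follow a geometric law (every founder is represented at
    least once).  Overlapping pools under ``hybrid`` are allowed but
    logged.
    """
    rng = np.random.default_rng(spec.seed)
    if pools is None:
        pools = draw_pools(rng, spec, base=100)
    if spec.hybrid and pools_b is None:
        pools_b = draw_pools(rng, spec, base=500)
    if spec.hybrid:
        overlap = any(set(a) & set(b) for a, b in zip(pools, pools_b))
        if overlap:
            logger.info("hybrid founder pools overlap; heterozygosity not fixed")

    def draw_allele(pool: Pool) -> str:
        alleles = sorted(pool)
        p = np.asarray([pool[a] for a in alleles])
        return alleles[int(rng.choice(len(alleles), p=p / p.sum()))]

    founders: List[List[Tuple[str, str]]] = []
    for _ in range(spec.clone_count):
        geno = []
        for l in range(spec.n_loci):
            a = draw_allele(pools[l])
            b = draw_allele(pools_b[l] if spec.hybrid else pools[l])
            geno.append(tuple(sorted((a, b))))
        founders.append(geno)

    # copy numbers: one guaranteed copy each, remainder geometric-weighted
    weights = spec.copy_geom_q ** np.arange(spec.clone_count)
    weights /= weights.sum()
    assignment = list(range(spec.clone_count))
    extra = spec.n - spec.clone_count
    if extra > 0:
        assignment.extend(rng.choice(spec.clone_count, size=extra, p=weights))
    assignment = [int(a) for a in assignment]

    calls = []
    for founder_idx in assignment:
        row = [
            _mutate_call(rng, call, spec.mutation_rate)
            for call in founders[founder_idx]
        ]
        calls.append(row)
    ds = _dataset(spec, calls)
    if spec.missing_rate > 0:
        ds = inject_missing(ds, spec.missing_rate,
                            seed=int(rng.integers(2 ** 31)))
    truth = {"mode": "obligate",
             "founders": [[list(c) for c in f] for f in founders],
             "assignment": assignment,
             "pools": [dict(p) for p in pools],
             "pools_b": [dict(p) for p in pools_b] if spec.hybrid else None,
             "spec": asdict(spec)}
    return ds, truth


def simulate_mixed(spec: PopulationSpec,
                   pools: Optional[Sequence[Pool]] = None
                   ) -> Tuple[GenotypeDataset, Dict]:
    """Cyclic + obligate concatenation over shared allele pools."""
    if not 0.0 < spec.asexual_fraction < 1.0:
        raise ValueError("asexual_fraction must lie strictly in (0, 1) "
                         "for mixed mode")
    rng = np.random.default_rng(spec.seed)
    if pools is None:
        pools = draw_pools(rng, spec)
    n_asex = max(1, round(spec.n * spec.asexual_fraction))
    n_sex = spec.n - n_asex
    sex_calls = _sample_cyclic_calls(rng, pools, n_sex, spec.inbreeding_f)

    ob_spec = PopulationSpec(
        mode="obligate", name=spec.name, n=n_asex, n_loci=spec.n_loci,
        clone_count=max(2, min(round(n_asex * spec.mixed_clone_fraction),
                               n_asex)),
        copy_geom_q=spec.copy_geom_q, hybrid=False,
        mutation_rate=spec.mutation_rate,
        seed=int(rng.integers(2 ** 31)))
    ob_ds, ob_truth = simulate_obligate(ob_spec, pools=pools)

    calls = sex_calls + [list(row) for row in ob_ds.calls]
    ds = _dataset(spec, calls)
    if spec.missing_rate > 0:
        ds = inject_missing(ds, spec.missing_rate,
                            seed=int(rng.integers(2 ** 31)))
    origin = ["sexual"] * n_sex + ["asexual"] * n_asex
    truth = {"mode": "mixed",
             "origin": dict(zip(ds.individuals, origin)),
             "pools": [dict(p) for p in pools],
             "obligate": ob_truth, "spec": asdict(spec)}
    return ds, truth


def simulate_population(spec: PopulationSpec) -> Tuple[GenotypeDataset, Dict]:
    if spec.mode == "cyclic":
        return simulate_cyclic(spec)
    if spec.mode == "obligate":
        return simulate_obligate(spec)
    return simulate_mixed(spec)


def merge_datasets(datasets: Sequence[GenotypeDataset]) -> GenotypeDataset:
    """Concatenate single-population datasets sharing the same loci."""
    loci = datasets[0].loci
    individuals: List[str] = []
    populations: Dict[str, str] = {}
    calls: List[List] = []
    regions: Dict[str, str] = {}
    for ds in datasets:
        if ds.loci != loci:
            raise ValueError("datasets must share identical loci")
        individuals.extend(ds.individuals)
        populations.update(ds.populations)
        regions.update(ds.regions)
        calls.extend(list(row) for row in ds.calls)
    return GenotypeDataset(individuals=individuals, populations=populations,
                           loci=list(loci), calls=calls, regions=regions)


def simulate_hybrid_trio(seed: int, n_per_group: int = 20, n_loci: int = 8,
                         alleles_min: int = 5, alleles_max: int = 22,
                         conc: float = 1.0
                         ) -> Tuple[GenotypeDataset, Dict]:
    """Two divergent parental populations plus F1 hybrids between them.

    Parent A draws from pool A, parent B from a disjoint pool B, and each
    hybrid takes one allele from each pool per locus.
    """
    rng = np.random.default_rng(seed)
    base_spec = PopulationSpec(mode="cyclic", n=n_per_group, n_loci=n_loci,
                               alleles_min=alleles_min,
                               alleles_max=alleles_max,
                               dirichlet_conc=conc, seed=seed)
    pools_a = draw_pools(rng, base_spec, base=100)
    pools_b = draw_pools(rng, base_spec, base=500)

    def sub_spec(name: str) -> PopulationSpec:
        s = PopulationSpec(mode="cyclic", name=name, n=n_per_group,
                           n_loci=n_loci, seed=int(rng.integers(2 ** 31)))
        return s

    ds_a, _ = simulate_cyclic(sub_spec("parentA"), pools=pools_a)
    ds_b, _ = simulate_cyclic(sub_spec("parentB"), pools=pools_b)

    hyb_spec = PopulationSpec(mode="obligate", name="hybrids", n=n_per_group,
                              n_loci=n_loci, clone_count=n_per_group,
                              hybrid=True, seed=int(rng.integers(2 ** 31)))
    ds_h, truth_h = simulate_obligate(hyb_spec, pools=pools_a,
                                      pools_b=pools_b)
    merged = merge_datasets([ds_a, ds_b, ds_h])
    truth = {"pools_a": [dict(p) for p in pools_a],
             "pools_b": [dict(p) for p in pools_b],
             "hybrids": truth_h}
    return merged, truth


# ----------------------------------------------------------------------
# Haplotype sets
# ----------------------------------------------------------------------

BASES = np.array(list("ACGT"))


def plant_apoi_site(sequence: str, position: int,
                    site: str = "GAATTC") -> str:
    """Write an ApoI site so the cut falls after 1-based ``position``, and
    scrub any other match so the planted site is the only one."""
    if not APOI_RE.match(site):
        raise ValueError(f"{site!r} is not an ApoI site")
    i = position - 1
    if i < 0 or i + len(site) > len(sequence):
        raise ValueError("site does not fit at the requested position")
    seq = sequence[:i] + site + sequence[i + len(site):]
    return _scrub_other_sites(seq, keep=i)


def remove_apoi_sites(sequence: str) -> str:
    return _scrub_other_sites(sequence, keep=None)


def _scrub_other_sites(seq: str, keep: Optional[int]) -> str:
    chars = list(seq)
    while True:
        positions = [m.start() for m in APOI_RE.finditer("".join(chars))]
        extra = [p for p in positions if p != keep]
        if not extra:
            return "".join(chars)
        # break the match by flipping its leading purine to a pyrimidine
        chars[extra[0]] = "C"


def simulate_haplotypes(n_sequences: int, n_haplotypes: int, length: int,
                        divergence: float,
                        region_labels: Optional[Sequence[str]] = None,
                        seed: int = 0,
                        plant_apoi_at: Optional[int] = None,
                        copy_geom_q: float = 0.6
                        ) -> Tuple[HaplotypeSet, Dict]:
    """Haplotype set built from mutated copies of a random ancestor.

    Each template haplotype differs from the ancestor at
    ``round(divergence * length)`` random positions (at least 1), and
    templates are guaranteed pairwise distinct.  Sequence counts per
    template follow a geometric law with every template represented at
    least once.  If ``plant_apoi_at`` is set, an ApoI site is planted at
    that 1-based position in every template and all other matches are
    scrubbed (logged if a mutation had created one).
    """
    if not 1 <= n_haplotypes <= n_sequences:
        raise ValueError("need 1 <= n_haplotypes <= n_sequences")
    if not 0.0 < divergence < 1.0:
        raise ValueError("divergence must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    ancestor = "".join(rng.choice(BASES, size=length))
    n_mut = max(1, round(divergence * length))

    def mutate(seq: str) -> str:
        chars = list(seq)
        sites = rng.choice(length, size=n_mut, replace=False)
        for pos in sites:
            current = chars[pos]
            options = [b for b in "ACGT" if b != current]
            chars[pos] = options[int(rng.integers(3))]
        return "".join(chars)

    templates: List[str] = []
    guard = 0
    while len(templates) < n_haplotypes:
        cand = mutate(ancestor)
        if plant_apoi_at is not None:
            before = cand
            cand = plant_apoi_site(cand, plant_apoi_at)
            if before != cand and APOI_RE.search(before) is None:
                logger.info("planted ApoI site overwrote mutated bases")
        if cand not in templates:
            templates.append(cand)
        guard += 1
        if guard > 100 * n_haplotypes:
            raise RuntimeError("could not generate distinct haplotypes; "
                               "increase length or divergence")

    assignment = list(range(n_haplotypes))
    extra = n_sequences - n_haplotypes
    if extra > 0:
        weights = copy_geom_q ** np.arange(n_haplotypes)
        weights /= weights.sum()
        assignment.extend(rng.choice(n_haplotypes, size=extra, p=weights))
    assignment = [int(a) for a in assignment]
    rng.shuffle(assignment)

    labels = [f"seq{i + 1:03d}" for i in range(n_sequences)]
    groups: Dict[str, str] = {}
    if region_labels is not None:
        if len(region_labels) != n_sequences:
            raise ValueError("one region label per sequence required")
        groups = dict(zip(labels, region_labels))
    hs = HaplotypeSet(sequences=[templates[a] for a in assignment],
                      labels=labels, groups=groups)
    collapse_haplotypes(hs)
    truth = {"ancestor": ancestor, "templates": templates,
             "assignment": assignment, "seed": seed}
    return hs, truth
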