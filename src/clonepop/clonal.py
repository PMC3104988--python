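"""Clonality statistics for diploid multilocus genotypes.

Partitions individuals into identical multilocus genotypes (MLMGs) and
computes the statistics used to decide whether repeated genotypes are
clonal copies or coincident products of sex:

* probability of identity P_ID and its sibling variant P_ID_sib,
* the number of loci needed to resolve non-identical individuals,
* round-robin allele frequency estimation on unique MLMGs,
* the genotype probability P_gen (with optional inbreeding correction),
* P_sex, the binomial probability that the observed copies of an MLMG
  arose from distinct sexual events,
* genotypic richness R = (G-1)/(N-1), and
* the genotypic diversity ratio G_obs / E[G | independent loci, HWE].
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from .genotypes_io import GenotypeDataset

logger = logging.getLogger(__name__)


@dataclass
class ClonalPartition:
    """Grouping of individuals into identical multilocus genotypes."""

    mlmg_id: Dict[str, str]           # individual -> MLMG id
    members: Dict[str, List[str]]     # MLMG id -> individuals
    n_individuals: int

    @property
    def G(self) -> int:
        return len(self.members)

    @property
    def N(self) -> int:
        return self.n_individuals

    def copy_numbers(self) -> Dict[str, int]:
        return {m: len(v) for m, v in self.members.items()}

    def representatives(self) -> List[str]:
        """First-listed individual of each MLMG (clone correction)."""
        return [v[0] for v in self.members.values()]


@dataclass
class AlleleFrequencyTable:
    """Per-locus allele relative frequencies.

    ``mode`` records how the frequencies were estimated (``plain`` or
    ``round-robin``) and ``basis`` on what sample (``individuals`` or
    ``unique-mlmgs``).
    """

    freqs: Dict[str, Dict[str, float]]
    mode: str = "plain"
    basis: str = "individuals"

    def __post_init__(self) -> None:
        for locus, table in self.freqs.items():
            tot = sum(table.values())
            if table and abs(tot - 1.0) > 1e-9:
                raise ValueError(f"frequencies at {locus} sum to {tot}, not 1")
            if any(v < 0 for v in table.values()):
                raise ValueError(f"negative frequency at {locus}")


def _genotype_key(row, loci_idx: Sequence[int]) -> Tuple:
    return tuple(row[j] for j in loci_idx)


def partition_mlmg(dataset: GenotypeDataset) -> ClonalPartition:
    """Group individuals sharing the same call at every locus.

    MLMG ids are deterministic: genotypes are sorted lexicographically by
    their genotype string and labelled ``mlmg001``, ``mlmg002``, ...

    Raises
    ------
    ValueError
        If the dataset still contains MISSING calls.
    """
    if dataset.has_missing():
        raise ValueError("partition_mlmg requires a complete dataset "
                         "(run complete_cases first)")
    idx = range(dataset.n_loci)
    groups: Dict[Tuple, List[str]] = {}
    for ind, row in zip(dataset.individuals, dataset.calls):
        groups.setdefault(_genotype_key(row, idx), []).append(ind)
    ordered = sorted(groups.items(), key=lambda kv: kv[0])
    width = max(3, len(str(len(ordered))))
    members = {f"mlmg{i + 1:0{width}d}": inds for i, (_, inds) in enumerate(ordered)}
    mlmg_id = {ind: m for m, inds in members.items() for ind in inds}
    return ClonalPartition(mlmg_id=mlmg_id, members=members,
                           n_individuals=dataset.n_individuals)


def genotypic_richness(partition: ClonalPartition) -> Optional[float]:
    """R = (G-1)/(N-1); NA (None) for N < 2."""
    if partition.N < 2:
        return None
    return (partition.G - 1) / (partition.N - 1)


# -- probability of identity -------------------------------------------


def pid_locus(freqs: Dict[str, float]) -> Tuple[float, float]:
    """Single-locus probability of identity for unrelated pairs and sibs.

    P_ID = 2 (sum p_i^2)^2 - sum p_i^4
    P_ID_sib = 0.25 + 0.5 sum p_i^2 + 0.5 (sum p_i^2)^2 - 0.25 sum p_i^4
    """
    p = np.asarray(list(freqs.values()), dtype=float)
    if abs(p.sum() - 1.0) > 1e-9 or (p < 0).any():
        raise ValueError("invalid allele frequency vector")
    s2 = float(np.sum(p ** 2))
    s4 = float(np.sum(p ** 4))
    pid = 2 * s2 ** 2 - s4
    pid_sib = 0.25 + 0.5 * s2 + 0.5 * s2 ** 2 - 0.25 * s4
    return pid, pid_sib


@dataclass
class LociNeededResult:
    m: Optional[int]                  # smallest number of loci, or None
    loci_ranked: List[str]            # ascending P_ID_sib
    cumulative: List[float]           # cumulative product of P_ID_sib
    insufficient: bool


def plain_freqs(dataset: GenotypeDataset) -> AlleleFrequencyTable:
    """Sample allele relative frequencies per locus (all individuals)."""
    freqs: Dict[str, Dict[str, float]] = {}
    for locus in dataset.loci:
        counts = dataset.allele_counts(locus)
        tot = sum(counts.values())
        freqs[locus] = {a: c / tot for a, c in counts.items()} if tot else {}
    return AlleleFrequencyTable(freqs=freqs, mode="plain", basis="individuals")


def loci_needed_from_sibs(sibs: Dict[str, float],
                          threshold: float = 0.01) -> LociNeededResult:
    """Rank loci by ascending P_ID_sib and find the smallest panel whose
    cumulative product drops below ``threshold``."""
    ranked = sorted(sibs, key=lambda l: sibs[l])
    cumulative: List[float] = []
    prod = 1.0
    m: Optional[int] = None
    for rank, locus in enumerate(ranked, start=1):
        prod *= sibs[locus]
        cumulative.append(prod)
        if m is None and prod < threshold:
            m = rank
    return LociNeededResult(m=m, loci_ranked=ranked, cumulative=cumulative,
                            insufficient=m is None)


def loci_needed(dataset: GenotypeDataset, threshold: float = 0.01) -> LociNeededResult:
    """Smallest panel of loci resolving non-identical individuals.

    Loci are ranked by ascending single-locus P_ID_sib (most informative
    first); the returned ``m`` is the smallest rank at which the product
    of the ``m`` smallest P_ID_sib values drops below ``threshold``.
    """
    table = plain_freqs(dataset)
    sibs = {locus: pid_locus(f)[1] for locus, f in table.freqs.items() if f}
    return loci_needed_from_sibs(sibs, threshold)


# -- round-robin frequencies -------------------------------------------


def round_robin_freqs(dataset: GenotypeDataset) -> AlleleFrequencyTable:
    """Allele frequencies estimated on unique MLMGs, per-locus round robin.

    For each locus ``l``, individuals are collapsed into MLMGs defined on
    every locus *except* ``l``; the frequency of each allele at ``l`` is
    then estimated from one representative per such MLMG.  This avoids
    counting a large clone many times while still letting variation at
    ``l`` itself contribute.

    With a single locus no round robin is possible; frequencies then come
    from one representative of each (single-locus) genotype, with a
    warning.
    """
    if dataset.has_missing():
        raise ValueError("round_robin_freqs requires a complete dataset")
    freqs: Dict[str, Dict[str, float]] = {}
    n_loci = dataset.n_loci
    if n_loci < 2:
        logger.warning("single locus: falling back to unique-genotype frequencies")
    for j, locus in enumerate(dataset.loci):
        other = [k for k in range(n_loci) if k != j] or [j]
        seen: Dict[Tuple, int] = {}
        counts: Dict[str, int] = {}
        for i, row in enumerate(dataset.calls):
            key = _genotype_key(row, other)
            if key in seen:
                continue
            seen[key] = i
            for a in row[j]:
                counts[a] = counts.get(a, 0) + 1
        tot = sum(counts.values())
        freqs[locus] = {a: c / tot for a, c in counts.items()}
    return AlleleFrequencyTable(freqs=freqs, mode="round-robin",
                                basis="unique-mlmgs")


# -- P_gen / P_sex ------------------------------------------------------


def p_gen(mlmg: Sequence[Tuple[str, str]], loci: Sequence[str],
          freqs: AlleleFrequencyTable, fis: float = 0.0) -> float:
    """Probability of drawing ``mlmg`` from the population gene pool.

    Per locus: homozygote ``p^2 + p(1-p) Fis``; heterozygote
    ``2 p q (1 - Fis)``.  Product over loci.  Negative per-locus values
    under extreme negative Fis are clamped to 0 (no renormalization).
    """
    if not -1.0 <= fis <= 1.0:
        raise ValueError("fis must lie in [-1, 1]")
    prob = 1.0
    for call, locus in zip(mlmg, loci):
        table = freqs.freqs[locus]
        a, b = call
        for allele in (a, b):
            if allele not in table:
                raise KeyError(
                    f"allele {allele!r} at {locus} absent from frequency table "
                    "(frequency basis mismatch)"
                )
        if a == b:
            p = table[a]
            g = p * p + p * (1 - p) * fis
        else:
            g = 2 * table[a] * table[b] * (1 - fis)
        prob *= max(g, 0.0)
    return min(prob, 1.0)


def p_sex(n_copies: int, n_total: int, p_gen_value: float) -> Optional[float]:
    """Upper-tail binomial probability that ``n_copies`` identical MLMGs
    among ``n_total`` sampled individuals arose from independent sexual
    events.

    Returns None (NA) for ``n_copies < 2``.  Convention: tail over all
    ``n_total`` samples including the focal copies.
    """
    if n_copies < 2:
        return None
    if not 0.0 <= p_gen_value <= 1.0:
        raise ValueError("p_gen must lie in [0, 1]")
    if n_copies > n_total:
        raise ValueError("n_copies cannot exceed n_total")
    return float(stats.binom.sf(n_copies - 1, n_total, p_gen_value))


# -- genotypic diversity ratio -----------------------------------------


def _locus_genotype_distribution(freq: Dict[str, float]) -> Tuple[List[Tuple[str, str]], np.ndarray]:
    alleles = sorted(freq)
    genotypes: List[Tuple[str, str]] = []
    probs: List[float] = []
    for i, a in enumerate(alleles):
        for b in alleles[i:]:
            genotypes.append((a, b))
            probs.append(freq[a] ** 2 if a == b else 2 * freq[a] * freq[b])
    return genotypes, np.asarray(probs)


def expected_g_analytic(freqs: AlleleFrequencyTable, n: int) -> float:
    """E[number of distinct multilocus genotypes] among ``n`` HWE draws,
    loci independent: sum over the genotype space of 1 - (1 - P_g)^n.

    Only tractable when the multilocus genotype space is enumerable.
    """
    probs = np.asarray([1.0])
    for locus in freqs.freqs:
        _, locus_probs = _locus_genotype_distribution(freqs.freqs[locus])
        probs = np.outer(probs, locus_probs).ravel()
        if probs.size > 200_000:
            raise ValueError("genotype space too large for analytic E[G]")
    return float(np.sum(1.0 - (1.0 - probs) ** n))


def genotype_space_size(freqs: AlleleFrequencyTable) -> float:
    size = 1.0
    for table in freqs.freqs.values():
        k = len(table)
        size *= k * (k + 1) / 2
    return size


@dataclass
class GDRatioResult:
    ratio: float
    g_obs: int
    e_g: float
    se_e_g: float        # 0 for the analytic route
    se_ratio: float
    method: str          # "mc" or "analytic"
    n_replicates: int


def gd_ratio(dataset: GenotypeDataset, partition: ClonalPartition,
             n_replicates: int = 1000, seed: Optional[int] = None,
             method: str = "auto") -> GDRatioResult:
    """Observed / expected number of distinct multilocus genotypes.

    The expectation assumes Hardy-Weinberg proportions at each locus and
    independent loci, using plain sample allele frequencies.  ``method``
    is ``"mc"`` (seeded Monte Carlo over ``n_replicates`` resampled
    datasets), ``"analytic"`` (exact sum over the genotype space), or
    ``"auto"`` (analytic when the space has at most 1e4 genotypes).
    """
    if n_replicates < 100:
        raise ValueError("n_replicates must be >= 100")
    freqs = plain_freqs(dataset)
    n = dataset.n_individuals
    g_obs = partition.G
    if method == "auto":
        method = "analytic" if genotype_space_size(freqs) <= 1e4 else "mc"
    if method == "analytic":
        e_g = expected_g_analytic(freqs, n)
        ratio = g_obs / e_g
        return GDRatioResult(ratio=ratio, g_obs=g_obs, e_g=e_g, se_e_g=0.0,
                             se_ratio=0.0, method="analytic", n_replicates=0)
    rng = np.random.default_rng(seed)
    loci_draws = []
    for locus in dataset.loci:
        alleles = sorted(freqs.freqs[locus])
        p = np.asarray([freqs.freqs[locus][a] for a in alleles])
        draws = rng.choice(len(alleles), size=(n_replicates, n, 2), p=p)
        draws.sort(axis=2)
        # encode unordered pair as one small int
        k = len(alleles)
        loci_draws.append(draws[..., 0] * k + draws[..., 1])
    stacked = np.stack(loci_draws, axis=2)  # (B, n, L)
    g_rep = np.empty(n_replicates)
    for b in range(n_replicates):
        g_rep[b] = np.unique(stacked[b], axis=0).shape[0]
    e_g = float(g_rep.mean())
    se = float(g_rep.std(ddof=1) / math.sqrt(n_replicates))
    ratio = g_obs / e_g
    se_ratio = g_obs * se / (e_g ** 2)
    return GDRatioResult(ratio=ratio, g_obs=g_obs, e_g=e_g, se_e_g=se,
                         se_ratio=se_ratio, method="mc",
                         n_replicates=n_replicates)


# -- per-population summary --------------------------------------------


@dataclass
class ClonalStats:
    """Per-population clonality summary mirroring a Table-1 style layout."""

    population: str
    G: int
    N: int
    R: Optional[float]
    gd: GDRatioResult
    # rows: (mlmg id, n copies, P_sex, P_sex(Fis))
    repeated_mlmgs: List[Tuple[str, int, Optional[float], Optional[float]]] = field(
        default_factory=list)


def clonal_stats(pop_dataset: GenotypeDataset, fis: float = 0.0,
                 n_replicates: int = 1000, seed: Optional[int] = None,
                 gd_method: str = "auto",
                 use_round_robin: bool = True) -> ClonalStats:
    """All clonality statistics for a single-population complete dataset."""
    pops = pop_dataset.population_names()
    if len(pops) != 1:
        raise ValueError("clonal_stats expects a single-population dataset")
    part = partition_mlmg(pop_dataset)
    if use_round_robin and pop_dataset.n_loci >= 2:
        freqs = round_robin_freqs(pop_dataset)
    else:
        freqs = plain_freqs(pop_dataset)
    gd = gd_ratio(pop_dataset, part, n_replicates=n_replicates, seed=seed,
                  method=gd_method)
    rows = []
    index = {ind: i for i, ind in enumerate(pop_dataset.individuals)}
    for mlmg, inds in part.members.items():
        if len(inds) < 2:
            continue
        geno = pop_dataset.calls[index[inds[0]]]
        pg0 = p_gen(geno, pop_dataset.loci, freqs, fis=0.0)
        pgf = p_gen(geno, pop_dataset.loci, freqs, fis=fis)
        rows.append((mlmg, len(inds),
                     p_sex(len(inds), part.N, pg0),
                     p_sex(len(inds), part.N, pgf)))
    return ClonalStats(population=pops[0], G=part.G, N=part.N,
                       R=genotypic_richness(part), gd=gd,
                       repeated_mlmgs=rows)
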