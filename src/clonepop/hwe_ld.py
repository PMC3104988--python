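"""Heterozygosity, Fis, exact Hardy-Weinberg score tests, and the
multilocus linkage-disequilibrium index r_d.

The Hardy-Weinberg score (U) test conditions on the observed allele
counts: the null is the Levene conditional distribution over genotype
tables, the test statistic is the Weir-Cockerham Fis, and the one-sided
p-value is the null probability of a table with Fis as or more extreme
in the direction of the alternative (heterozygote excess = more negative
Fis).  Because allele counts are fixed, Fis is a strictly decreasing
function of the heterozygote count, so extremeness reduces to comparing
heterozygote counts.  Three estimation routes are provided:

``enumerate``
    complete enumeration of all genotype tables (small tables only);
``chain``
    a Guo-Thompson style switch Markov chain with dememorization and
    batching, reporting a batch-mean standard error;
``sampling``
    i.i.d. draws from the conditional null by random pairing of the
    allele copies (fast, vectorized).

r_d is the standardized index of association over per-locus pairwise
genotype distances, with a permutation null built by reshuffling allele
copies among individuals independently at each locus; clone correction
(one individual per MLMG) gives the paper-style second variant.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats as sps

from .genotypes_io import GenotypeDataset

logger = logging.getLogger(__name__)


@dataclass
class TestResult:
    statistic: Optional[float]
    p_value: Optional[float]
    tail: str                      # "excess" | "deficiency" | "two-sided"
    method: str
    replicates: Optional[int] = None
    seed: Optional[int] = None
    se: Optional[float] = None
    params: Dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.p_value is not None and not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p_value outside [0, 1]")


# ----------------------------------------------------------------------
# Heterozygosity
# ----------------------------------------------------------------------


@dataclass
class HetStats:
    per_locus: Dict[str, Tuple[Optional[float], Optional[float], int]]  # locus -> (Ho, He, n)
    ho_overall: Optional[float]
    he_overall: Optional[float]


def het_stats(dataset: GenotypeDataset) -> HetStats:
    """Observed heterozygosity and Nei unbiased expected heterozygosity.

    He = (2n / (2n - 1)) (1 - sum p_hat^2) per locus; the overall values
    are unweighted means over loci with data.
    """
    per_locus: Dict[str, Tuple[Optional[float], Optional[float], int]] = {}
    hos, hes = [], []
    for j, locus in enumerate(dataset.loci):
        calls = [row[j] for row in dataset.calls if row[j] is not None]
        n = len(calls)
        if n == 0:
            per_locus[locus] = (None, None, 0)
            continue
        ho = sum(1 for a, b in calls if a != b) / n
        counts: Dict[str, int] = {}
        for a, b in calls:
            counts[a] = counts.get(a, 0) + 1
            counts[b] = counts.get(b, 0) + 1
        tot = 2 * n
        s2 = sum((c / tot) ** 2 for c in counts.values())
        he = (tot / (tot - 1)) * (1 - s2) if tot > 1 else None
        per_locus[locus] = (ho, he, n)
        hos.append(ho)
        if he is not None:
            hes.append(he)
    return HetStats(
        per_locus=per_locus,
        ho_overall=float(np.mean(hos)) if hos else None,
        he_overall=float(np.mean(hes)) if hes else None,
    )


# ----------------------------------------------------------------------
# Weir-Cockerham Fis
# ----------------------------------------------------------------------


def _wc_components(calls: Sequence[Tuple[str, str]]) -> Tuple[float, float]:
    """Sum over alleles of the within-individual (c) and among-individual
    (b) variance components for one locus in one population.

    Returns (sum_c, sum_bc).  For allele a with sample frequency p and
    observed heterozygote carrier frequency hbar:
        c = hbar / 2
        b = n/(n-1) * (p(1-p) - (2n-1)/(4n) * hbar)
    """
    n = len(calls)
    allele_count: Dict[str, int] = {}
    het_carrier: Dict[str, int] = {}
    for a, b in calls:
        allele_count[a] = allele_count.get(a, 0) + 1
        allele_count[b] = allele_count.get(b, 0) + 1
        if a != b:
            het_carrier[a] = het_carrier.get(a, 0) + 1
            het_carrier[b] = het_carrier.get(b, 0) + 1
    sum_c = 0.0
    sum_bc = 0.0
    for allele, cnt in allele_count.items():
        p = cnt / (2 * n)
        hbar = het_carrier.get(allele, 0) / n
        c = hbar / 2
        b = (n / (n - 1)) * (p * (1 - p) - (2 * n - 1) / (4 * n) * hbar)
        sum_c += c
        sum_bc += b + c
    return sum_c, sum_bc


@dataclass
class FisResult:
    per_locus: Dict[str, Optional[float]]
    multilocus: Optional[float]
    skipped_monomorphic: List[str]


def fis_wc(dataset: GenotypeDataset) -> FisResult:
    """Weir-Cockerham within-population inbreeding coefficient.

    The multilocus estimate sums the per-locus variance components over
    loci before forming the ratio.  Monomorphic loci are skipped and
    flagged.
    """
    if dataset.n_individuals < 2:
        raise ValueError("fis_wc requires at least 2 individuals")
    per_locus: Dict[str, Optional[float]] = {}
    skipped: List[str] = []
    tot_c = 0.0
    tot_bc = 0.0
    for j, locus in enumerate(dataset.loci):
        calls = [row[j] for row in dataset.calls if row[j] is not None]
        alleles = {a for call in calls for a in call}
        if len(alleles) < 2:
            per_locus[locus] = None
            skipped.append(locus)
            continue
        sum_c, sum_bc = _wc_components(calls)
        per_locus[locus] = 1.0 - sum_c / sum_bc if sum_bc != 0 else None
        tot_c += sum_c
        tot_bc += sum_bc
    multilocus = 1.0 - tot_c / tot_bc if tot_bc != 0 else None
    return FisResult(per_locus=per_locus, multilocus=multilocus,
                     skipped_monomorphic=skipped)


def _locus_allele_arrays(dataset: GenotypeDataset) -> List[np.ndarray]:
    """Per locus, the flat (2n,) array of integer-coded allele copies."""
    arrays = []
    for j, locus in enumerate(dataset.loci):
        alleles = dataset.alleles_at(locus)
        code = {a: i for i, a in enumerate(alleles)}
        flat = np.empty(2 * dataset.n_individuals, dtype=np.int64)
        for i, row in enumerate(dataset.calls):
            a, b = row[j]
            flat[2 * i] = code[a]
            flat[2 * i + 1] = code[b]
        arrays.append(flat)
    return arrays


def _fis_from_het_counts(h: np.ndarray, n: int, a_const: np.ndarray) -> np.ndarray:
    """Multilocus W&C Fis as a function of per-locus heterozygote counts.

    ``h`` has shape (..., L); ``a_const[l] = sum_a p_a (1 - p_a)`` at
    locus ``l`` (fixed under permutation of allele copies).
    """
    num = h.sum(axis=-1) / n
    den = (n / (n - 1)) * a_const.sum() - h.sum(axis=-1) / (2 * n * (n - 1))
    return 1.0 - num / den


def fis_permutation_test(dataset: GenotypeDataset, n_perm: int = 10000,
                         seed: Optional[int] = None) -> TestResult:
    """Two-sided permutation test of multilocus Fis = 0.

    The null reshuffles the 2N allele copies among individuals within the
    population, independently per locus; p = (1 + #{|null| >= |obs|}) /
    (n_perm + 1).
    """
    if dataset.has_missing():
        raise ValueError("fis_permutation_test requires a complete dataset")
    n = dataset.n_individuals
    poly = [j for j, locus in enumerate(dataset.loci)
            if len(dataset.alleles_at(locus)) >= 2]
    if not poly:
        return TestResult(statistic=None, p_value=None, tail="two-sided",
                          method="permutation", replicates=n_perm, seed=seed)
    sub = dataset.subset(dataset.individuals)
    sub.loci = [dataset.loci[j] for j in poly]
    sub.calls = [[row[j] for j in poly] for row in dataset.calls]

    arrays = _locus_allele_arrays(sub)
    a_const = np.empty(len(arrays))
    h_obs = np.empty(len(arrays))
    for l, flat in enumerate(arrays):
        _, cnt = np.unique(flat, return_counts=True)
        p = cnt / flat.size
        a_const[l] = float(np.sum(p * (1 - p)))
        pairs = flat.reshape(n, 2)
        h_obs[l] = int(np.sum(pairs[:, 0] != pairs[:, 1]))
    obs = float(_fis_from_het_counts(h_obs, n, a_const))

    rng = np.random.default_rng(seed)
    h_null = np.empty((n_perm, len(arrays)))
    for l, flat in enumerate(arrays):
        order = np.argsort(rng.random((n_perm, flat.size)), axis=1)
        shuffled = flat[order].reshape(n_perm, n, 2)
        h_null[:, l] = np.sum(shuffled[:, :, 0] != shuffled[:, :, 1], axis=1)
    null = _fis_from_het_counts(h_null, n, a_const)
    p = (1 + int(np.sum(np.abs(null) >= abs(obs) - 1e-12))) / (n_perm + 1)
    return TestResult(statistic=obs, p_value=p, tail="two-sided",
                      method="permutation", replicates=n_perm, seed=seed)


# ----------------------------------------------------------------------
# Exact Hardy-Weinberg score tests
# ----------------------------------------------------------------------


def _counts_to_pairs(genotype_counts: Dict[Tuple[str, str], int]
                     ) -> Tuple[List[List[int]], List[str]]:
    alleles = sorted({a for g in genotype_counts for a in g})
    code = {a: i for i, a in enumerate(alleles)}
    pairs: List[List[int]] = []
    for (a, b), cnt in sorted(genotype_counts.items()):
        pairs.extend([code[a], code[b]] for _ in range(cnt))
    return pairs, alleles


def _fis_single_locus(h: float, n: int, a_const: float) -> float:
    num = h / n
    den = (n / (n - 1)) * a_const - h / (2 * n * (n - 1))
    return 1.0 - num / den


def enumerate_het_distribution(allele_counts: Sequence[int]
                               ) -> Dict[int, float]:
    """Exact Levene conditional distribution of the heterozygote count.

    Enumerates every genotype table with the given allele copy counts,
    weighting each by 2^h * n! * prod(a_i!) / ((2n)! * prod(g_ij!)).
    Returns {h: probability}.  Intended for small tables.
    """
    k = len(allele_counts)
    cells = [(i, j) for i in range(k) for j in range(i, k)]
    out: Dict[int, float] = {}

    def rec(cell_idx: int, remaining: List[int], h: int, log_g_fact: float) -> None:
        if cell_idx == len(cells):
            if all(r == 0 for r in remaining):
                w = h * math.log(2.0) - log_g_fact
                out[h] = out.get(h, 0.0) + math.exp(w)
            return
        i, j = cells[cell_idx]
        if i == j:
            gmax = remaining[i] // 2
        else:
            gmax = min(remaining[i], remaining[j])
        for g in range(gmax + 1):
            remaining[i] -= 2 * g if i == j else g
            if i != j:
                remaining[j] -= g
            rec(cell_idx + 1, remaining,
                h + (g if i != j else 0),
                log_g_fact + math.lgamma(g + 1))
            remaining[i] += 2 * g if i == j else g
            if i != j:
                remaining[j] += g

    rec(0, list(allele_counts), 0, 0.0)
    total = sum(out.values())
    return {h: w / total for h, w in out.items()}


def _tail_weights(h: np.ndarray, h_obs: int, tail: str, ties: str) -> np.ndarray:
    """Per-table tail weight: 1 if strictly more extreme, and for ties
    (h == h_obs) 1 under the inclusive convention or 0.5 under mid-p."""
    if tail == "excess":
        strict = h > h_obs
    elif tail == "deficiency":
        strict = h < h_obs
    else:
        raise ValueError("tail must be 'excess' or 'deficiency'")
    tie_w = {"inclusive": 1.0, "midp": 0.5}[ties]
    return strict.astype(float) + tie_w * (h == h_obs)


DEFAULT_CHAIN = {"dememorization": 20000, "batches": 1000,
                 "iters_per_batch": 20000}


def hwe_score_test(genotype_counts: Dict[Tuple[str, str], int], tail: str,
                   chain: Optional[Dict[str, int]] = None,
                   seed: Optional[int] = None,
                   method: str = "auto",
                   n_samples: int = 10000,
                   ties: str = "inclusive") -> TestResult:
    """One-locus exact score (U) test against heterozygote excess or
    deficiency, conditional on the observed allele counts.

    ``method``: ``"enumerate"`` (complete enumeration; exact),
    ``"chain"`` (switch Markov chain; batch-mean SE reported),
    ``"sampling"`` (i.i.d. random pairings of allele copies; binomial
    SE), or ``"auto"`` (enumeration for small tables, chain otherwise).

    ``ties``: how null tables whose statistic equals the observed one are
    counted.  ``"inclusive"`` (default) counts them fully, so the p-value
    is the null probability of a statistic as or more extreme than
    observed; ``"midp"`` counts them half (mid-p), which restores
    calibration for this strongly discrete statistic and is the variant
    the combined multi-locus test uses.  Returns NA for monomorphic
    tables.
    """
    if tail not in ("excess", "deficiency"):
        raise ValueError("tail must be 'excess' or 'deficiency'")
    pairs, alleles = _counts_to_pairs(genotype_counts)
    n = len(pairs)
    if len(alleles) < 2:
        return TestResult(statistic=None, p_value=None, tail=tail,
                          method="NA", params={"reason": "monomorphic"})
    flat = np.asarray([a for pair in pairs for a in pair])
    _, counts = np.unique(flat, return_counts=True)
    p_freq = counts / flat.size
    a_const = float(np.sum(p_freq * (1 - p_freq)))
    h_obs = sum(1 for a, b in pairs if a != b)
    fis_obs = _fis_single_locus(h_obs, n, a_const)

    if method == "auto":
        method = "enumerate" if (len(alleles) <= 4 and n <= 50) else "chain"

    if method == "enumerate":
        dist = enumerate_het_distribution(list(counts))
        hs = np.asarray(sorted(dist))
        ps = np.asarray([dist[int(h)] for h in hs])
        p_val = float((ps * _tail_weights(hs, h_obs, tail, ties)).sum())
        return TestResult(statistic=fis_obs, p_value=min(p_val, 1.0),
                          tail=tail, method="enumerate",
                          params={"ties": ties})

    if method == "sampling":
        rng = np.random.default_rng(seed)
        order = np.argsort(rng.random((n_samples, flat.size)), axis=1)
        resampled = flat[order].reshape(n_samples, n, 2)
        h_null = np.sum(resampled[:, :, 0] != resampled[:, :, 1], axis=1)
        w = _tail_weights(h_null, h_obs, tail, ties)
        p_val = float(w.mean())
        se = float(w.std(ddof=1) / math.sqrt(n_samples))
        return TestResult(statistic=fis_obs, p_value=min(p_val, 1.0),
                          tail=tail, method="sampling", replicates=n_samples,
                          seed=seed, se=se, params={"ties": ties})

    if method != "chain":
        raise ValueError(f"unknown method {method!r}")
    cfg = dict(DEFAULT_CHAIN)
    if chain:
        cfg.update(chain)
    demem = int(cfg["dememorization"])
    batches = int(cfg["batches"])
    iters = int(cfg["iters_per_batch"])
    if demem < 100 or batches < 10 or iters < 100:
        raise ValueError("chain parameters below minimum "
                         "(dememorization>=100, batches>=10, iters>=100)")
    p_val, se = _switch_chain_p(pairs, h_obs, tail, demem, batches, iters,
                                seed, ties)
    return TestResult(statistic=fis_obs, p_value=p_val, tail=tail,
                      method="chain", replicates=batches * iters, seed=seed,
                      se=se, params={**cfg, "ties": ties})


def _switch_chain_p(pairs: List[List[int]], h_obs: int, tail: str,
                    demem: int, batches: int, iters: int,
                    seed: Optional[int], ties: str = "inclusive"
                    ) -> Tuple[float, float]:
    """Switch Markov chain on allele-copy slot assignments.

    State: the 2n allele copies laid out in n ordered slots-pairs.  Move:
    pick two individuals and one allele copy of each, exchange them.  The
    proposal is symmetric and the uniform distribution over slot
    assignments marginalizes to the Levene conditional distribution over
    genotype tables (each table corresponds to n!/prod(g!) * 2^h
    assignments), so every proposed exchange is accepted.
    """
    rng = np.random.default_rng(seed)
    n = len(pairs)
    state = [list(p) for p in pairs]
    h = sum(1 for a, b in state if a != b)
    excess = tail == "excess"
    tie_w = {"inclusive": 1.0, "midp": 0.5}[ties]
    batch_means = np.empty(batches)

    def run_block(n_iter: int, record: bool) -> float:
        nonlocal h
        ii = rng.integers(0, n, size=n_iter)
        jj = rng.integers(0, n - 1, size=n_iter)
        xx = rng.integers(0, 2, size=n_iter)
        yy = rng.integers(0, 2, size=n_iter)
        hits = 0.0
        for t in range(n_iter):
            i = ii[t]
            j = jj[t]
            if j >= i:
                j += 1
            gi = state[i]
            gj = state[j]
            x = xx[t]
            y = yy[t]
            ai, aj = gi[x], gj[y]
            if ai != aj:
                old = (gi[0] != gi[1]) + (gj[0] != gj[1])
                new = ((aj != gi[1 - x]) + (ai != gj[1 - y]))
                gi[x], gj[y] = aj, ai
                h += new - old
            if record:
                if h == h_obs:
                    hits += tie_w
                elif (h > h_obs) if excess else (h < h_obs):
                    hits += 1.0
        return hits / n_iter if record else 0.0

    run_block(demem, record=False)
    for b in range(batches):
        batch_means[b] = run_block(iters, record=True)
    p = float(batch_means.mean())
    se = float(batch_means.std(ddof=1) / math.sqrt(batches))
    return min(p, 1.0), se


def combine_pvalues_fisher(p_values: Sequence[float]) -> float:
    """Fisher's method; zero p-values propagate to a combined p of 0."""
    ps = [p for p in p_values if p is not None]
    if not ps:
        return float("nan")
    stat = -2.0 * sum(math.log(p) if p > 0 else -math.inf for p in ps)
    if math.isinf(stat):
        return 0.0
    return float(sps.chi2.sf(stat, 2 * len(ps)))


def global_hwe_score_test(dataset: GenotypeDataset, tail: str,
                          n_samples: int = 10000,
                          seed: Optional[int] = None,
                          ties: str = "midp") -> TestResult:
    """Population-level score test across all loci at once.

    The statistic is the multilocus Weir-Cockerham Fis (variance
    components summed over loci); the null resamples each locus's
    genotype table from its conditional (fixed allele counts)
    distribution by random re-pairing of allele copies, independently per
    locus.  With allele counts fixed the statistic is a monotone function
    of the total heterozygote count, giving a nearly continuous null and
    hence good calibration where per-locus tests are too discrete.
    """
    if tail not in ("excess", "deficiency"):
        raise ValueError("tail must be 'excess' or 'deficiency'")
    if dataset.has_missing():
        raise ValueError("global_hwe_score_test requires a complete dataset")
    n = dataset.n_individuals
    poly = [j for j, locus in enumerate(dataset.loci)
            if len(dataset.alleles_at(locus)) >= 2]
    if not poly:
        return TestResult(statistic=None, p_value=None, tail=tail,
                          method="global-sampling",
                          params={"reason": "no polymorphic locus"})
    sub = dataset.subset(dataset.individuals)
    sub.loci = [dataset.loci[j] for j in poly]
    sub.calls = [[row[j] for j in poly] for row in dataset.calls]
    arrays = _locus_allele_arrays(sub)
    a_const = np.empty(len(arrays))
    h_obs = 0
    for l, flat in enumerate(arrays):
        _, cnt = np.unique(flat, return_counts=True)
        p = cnt / flat.size
        a_const[l] = float(np.sum(p * (1 - p)))
        pairs = flat.reshape(n, 2)
        h_obs += int(np.sum(pairs[:, 0] != pairs[:, 1]))
    den = (n / (n - 1)) * a_const.sum() - h_obs / (2 * n * (n - 1))
    fis_obs = 1.0 - (h_obs / n) / den if den != 0 else None

    rng = np.random.default_rng(seed)
    h_null = np.zeros(n_samples, dtype=np.int64)
    for flat in arrays:
        order = np.argsort(rng.random((n_samples, flat.size)), axis=1)
        shuffled = flat[order].reshape(n_samples, n, 2)
        h_null += np.sum(shuffled[:, :, 0] != shuffled[:, :, 1], axis=1)
    # excess alternative: extreme = more heterozygotes (smaller Fis)
    w = _tail_weights(h_null, h_obs, tail, ties)
    p_val = float(w.mean())
    se = float(w.std(ddof=1) / math.sqrt(n_samples))
    return TestResult(statistic=fis_obs, p_value=min(p_val, 1.0), tail=tail,
                      method="global-sampling", replicates=n_samples,
                      seed=seed, se=se, params={"ties": ties})


@dataclass
class MultilocusHWEResult:
    per_locus: Dict[str, Dict[str, TestResult]]  # locus -> tail -> result
    combined: Dict[str, float]                   # tail -> Fisher combined p


def multilocus_hwe(dataset: GenotypeDataset,
                   method: str = "auto",
                   chain: Optional[Dict[str, int]] = None,
                   n_samples: int = 10000,
                   seed: Optional[int] = None,
                   ties: str = "midp") -> MultilocusHWEResult:
    """Score tests at every testable locus, both tails, plus the Fisher
    combination across loci per tail.

    The per-locus statistic is strongly discrete, so the combination
    defaults to mid-p per-locus values (``ties="midp"``); the inclusive
    convention would make the combined test severely conservative.
    """
    per_locus: Dict[str, Dict[str, TestResult]] = {}
    combined: Dict[str, float] = {}
    rng = np.random.default_rng(seed)
    for locus in dataset.loci:
        counts = dataset.genotype_counts(locus)
        res = {}
        for tail in ("excess", "deficiency"):
            res[tail] = hwe_score_test(
                counts, tail, chain=chain, method=method,
                n_samples=n_samples, seed=int(rng.integers(2 ** 31)),
                ties=ties)
        per_locus[locus] = res
    for tail in ("excess", "deficiency"):
        ps = [per_locus[l][tail].p_value for l in per_locus
              if per_locus[l][tail].p_value is not None]
        combined[tail] = combine_pvalues_fisher(ps) if ps else float("nan")
    return MultilocusHWEResult(per_locus=per_locus, combined=combined)


# ----------------------------------------------------------------------
# Multilocus linkage disequilibrium: r_d
# ----------------------------------------------------------------------


def _pair_distance(P0: np.ndarray, P1: np.ndarray,
                   iu: Tuple[np.ndarray, np.ndarray]) -> np.ndarray:
    """Per-locus genotype distance over condensed pairs.

    Genotypes are sorted integer pairs (columns P0 <= P1); the distance is
    (2 - shared allele count)/2 with multiset sharing (AB vs AA -> 0.5).
    Supports a leading batch axis.
    """
    i, j = iu
    a0i, a0j = P0[..., i], P0[..., j]
    a1i, a1j = P1[..., i], P1[..., j]
    eq00 = a0i == a0j
    eq11 = a1i == a1j
    both = eq00 & eq11
    anym = eq00 | eq11 | (a0i == a1j) | (a1i == a0j)
    shared = both.astype(np.int8) + anym.astype(np.int8)
    return (2 - shared) / 2.0


def _rbar_from_locus_distances(d_loci: np.ndarray) -> np.ndarray:
    """r_d from per-locus condensed distances, shape (..., L, npairs)."""
    var_l = d_loci.var(axis=-1)                      # (..., L)
    var_D = d_loci.sum(axis=-2).var(axis=-1)         # (...,)
    sum_var = var_l.sum(axis=-1)
    sqrt_v = np.sqrt(np.clip(var_l, 0.0, None))
    denom = sqrt_v.sum(axis=-1) ** 2 - var_l.sum(axis=-1)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.where(denom > 0, (var_D - sum_var) / denom, 0.0)
    return r


def rbar_d(dataset: GenotypeDataset, n_perm: int = 1000,
           seed: Optional[int] = None,
           clone_correct: bool = False) -> TestResult:
    """Standardized index of association with a permutation null.

    p = (1 + #{permuted r_d >= observed}) / (n_perm + 1); permutations
    reshuffle allele copies among individuals independently per locus.
    Loci whose pairwise distances have zero variance are excluded (with a
    warning); with fewer than 2 usable loci the result is NA.
    """
    if dataset.has_missing():
        raise ValueError("rbar_d requires a complete dataset")
    sub = dataset
    if clone_correct:
        from .clonal import partition_mlmg
        sub = dataset.subset(partition_mlmg(dataset).representatives())
    n = sub.n_individuals
    tag = "clone-corrected" if clone_correct else "raw"
    if n < 3 or sub.n_loci < 2:
        return TestResult(statistic=None, p_value=None, tail="excess",
                          method=f"permutation/{tag}", replicates=n_perm,
                          seed=seed, params={"reason": "too few individuals/loci"})
    iu = np.triu_indices(n, 1)
    arrays = _locus_allele_arrays(sub)
    d_obs: List[np.ndarray] = []
    usable: List[int] = []
    for l, flat in enumerate(arrays):
        pairs = np.sort(flat.reshape(n, 2), axis=1)
        d = _pair_distance(pairs[:, 0], pairs[:, 1], iu)
        if d.var() <= 0:
            logger.warning("rbar_d: locus %s has zero distance variance, excluded",
                           sub.loci[l])
            continue
        usable.append(l)
        d_obs.append(d)
    if len(usable) < 2:
        return TestResult(statistic=None, p_value=None, tail="excess",
                          method=f"permutation/{tag}", replicates=n_perm,
                          seed=seed, params={"reason": "<2 usable loci"})
    obs = float(_rbar_from_locus_distances(np.stack(d_obs, axis=0)))

    rng = np.random.default_rng(seed)
    d_perm = np.empty((n_perm, len(usable), iu[0].size), dtype=np.float32)
    for pos, l in enumerate(usable):
        flat = arrays[l]
        order = np.argsort(rng.random((n_perm, flat.size)), axis=1)
        shuffled = np.sort(flat[order].reshape(n_perm, n, 2), axis=2)
        d_perm[:, pos, :] = _pair_distance(shuffled[:, :, 0],
                                           shuffled[:, :, 1], iu)
    null = _rbar_from_locus_distances(d_perm)
    p = (1 + int(np.sum(null >= obs - 1e-12))) / (n_perm + 1)
    return TestResult(statistic=obs, p_value=p, tail="excess",
                      method=f"permutation/{tag}", replicates=n_perm,
                      seed=seed)
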