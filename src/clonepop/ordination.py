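"""Individual-level ordination and population-level distance statistics.

Pipeline: genotypes -> binary allele presence/absence matrix -> Dice/Nei
similarity (shared absences ignored) -> principal coordinate analysis
(Gower double centering) -> cascaded K-means with the Calinski-Harabasz
criterion.  Also: centroid intermediacy of a putative hybrid group,
Cavalli-Sforza/Edwards chord distances between population allele
frequency tables, and rarefied allelic richness.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from sklearn.cluster import KMeans
from sklearn.metrics import calinski_harabasz_score

from .genotypes_io import GenotypeDataset

logger = logging.getLogger(__name__)


@dataclass
class DistanceMatrix:
    labels: List[str]
    matrix: np.ndarray
    metric: str

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError("distance matrix must be square")
        if not np.allclose(m, m.T, atol=1e-12):
            raise ValueError("distance matrix must be symmetric")
        if (np.diag(m) != 0).any() or (m < -1e-12).any():
            raise ValueError("distances must be nonnegative with zero diagonal")
        self.matrix = m


@dataclass
class Ordination:
    labels: List[str]
    coordinates: np.ndarray        # (n, n_axes), axes by decreasing eigenvalue
    eigenvalues: np.ndarray        # positive eigenvalues, decreasing
    percent_variation: np.ndarray  # over positive eigenvalues only
    negative_eigenvalues: np.ndarray


def binary_allele_matrix(dataset: GenotypeDataset
                         ) -> Tuple[np.ndarray, List[Tuple[str, str]]]:
    """Individuals x (locus, allele) presence/absence matrix.

    One column per (locus, allele) pair observed anywhere in the dataset;
    1 iff the individual carries at least one copy.
    """
    if dataset.has_missing():
        raise ValueError("binary_allele_matrix requires a complete dataset")
    columns: List[Tuple[str, str]] = []
    for locus in dataset.loci:
        columns.extend((locus, a) for a in dataset.alleles_at(locus))
    col_index = {c: k for k, c in enumerate(columns)}
    mat = np.zeros((dataset.n_individuals, len(columns)), dtype=np.int8)
    for i, row in enumerate(dataset.calls):
        for locus, call in zip(dataset.loci, row):
            for a in call:
                mat[i, col_index[(locus, a)]] = 1
    return mat, columns


def nei_binary_distance(matrix: np.ndarray,
                        labels: Optional[List[str]] = None) -> DistanceMatrix:
    """Dice/Nei-Li distance on a 0/1 matrix: 1 - 2a/(2a + b + c).

    ``a`` counts shared presences, ``b``/``c`` presences unique to either
    row; shared absences never contribute.
    """
    m = np.asarray(matrix)
    if ((m != 0) & (m != 1)).any():
        raise ValueError("matrix must be 0/1")
    if (m.sum(axis=1) == 0).any():
        raise ValueError("all-zero rows are not allowed")
    m = m.astype(float)
    a = m @ m.T                              # shared presences
    totals = m.sum(axis=1)
    denom = totals[:, None] + totals[None, :]  # 2a + b + c
    d = 1.0 - 2.0 * a / denom
    np.fill_diagonal(d, 0.0)
    if labels is None:
        labels = [str(i) for i in range(m.shape[0])]
    return DistanceMatrix(labels=labels, matrix=d, metric="nei-binary")


def pcoa(dm: DistanceMatrix) -> Ordination:
    """Principal coordinate analysis by Gower double centering.

    Axes for negative eigenvalues are dropped (their magnitudes are
    reported); percent variation is computed over positive eigenvalues.
    """
    d = dm.matrix
    n = d.shape[0]
    a = -0.5 * d ** 2
    centered = a - a.mean(axis=0) - a.mean(axis=1)[:, None] + a.mean()
    eigval, eigvec = np.linalg.eigh(centered)
    order = np.argsort(eigval)[::-1]
    eigval = eigval[order]
    eigvec = eigvec[:, order]
    tol = max(1e-10, 1e-10 * abs(eigval).max() if n else 0)
    pos = eigval > tol
    neg = eigval < -tol
    coords = eigvec[:, pos] * np.sqrt(eigval[pos])
    pct = 100.0 * eigval[pos] / eigval[pos].sum() if pos.any() else np.array([])
    return Ordination(labels=list(dm.labels), coordinates=coords,
                      eigenvalues=eigval[pos], percent_variation=pct,
                      negative_eigenvalues=np.abs(eigval[neg]))


@dataclass
class CascadeKMeansResult:
    best_k: int
    labels: np.ndarray
    criterion: Dict[int, float]     # K -> Calinski-Harabasz value
    labels_per_k: Dict[int, np.ndarray]
    low_confidence: bool
    skipped_k: List[int] = field(default_factory=list)


def cascade_kmeans(ordination: Ordination, k_min: int = 2, k_max: int = 10,
                   n_starts: int = 25, seed: Optional[int] = None
                   ) -> CascadeKMeansResult:
    """K-means over K = k_min..k_max on all retained axes; the best K
    maximizes the Calinski-Harabasz criterion.  Deterministic given seed.

    Structureless data make the criterion keep rising all the way to
    ``k_max``; in that case no optimum is supported, so ``k_min`` is
    reported with ``low_confidence`` set.  An argmax at ``k_min`` (curve
    decaying from the start) or in the interior is reported as-is.
    """
    x = ordination.coordinates
    n = x.shape[0]
    if n < k_max + 1:
        raise ValueError("need at least k_max + 1 points")
    n_distinct = np.unique(x, axis=0).shape[0]
    criterion: Dict[int, float] = {}
    labels_per_k: Dict[int, np.ndarray] = {}
    skipped: List[int] = []
    rng = np.random.default_rng(seed)
    for k in range(k_min, k_max + 1):
        if n_distinct < k:
            logger.warning("cascade_kmeans: only %d distinct points, skipping K=%d",
                           n_distinct, k)
            skipped.append(k)
            continue
        km = KMeans(n_clusters=k, n_init=n_starts,
                    random_state=int(rng.integers(2 ** 31)))
        import warnings
        with warnings.catch_warnings():
            # duplicate points (clones) can collapse clusters; handled below
            warnings.simplefilter("ignore")
            lab = km.fit_predict(x)
        if len(np.unique(lab)) < 2:
            skipped.append(k)
            continue
        criterion[k] = float(calinski_harabasz_score(x, lab))
        labels_per_k[k] = lab
    if not criterion:
        raise ValueError("no K produced a valid partition")
    ks = sorted(criterion)
    peak = max(criterion, key=lambda k: criterion[k])
    if peak == ks[-1] and len(ks) > 1:
        best_k = ks[0]
        low_confidence = True
        logger.warning("cascade_kmeans: criterion still rising at K=%d; "
                       "no optimum supported, reporting K=%d", peak, best_k)
    else:
        best_k = peak
        low_confidence = False
    return CascadeKMeansResult(best_k=best_k, labels=labels_per_k[best_k],
                               criterion=criterion, labels_per_k=labels_per_k,
                               low_confidence=low_confidence, skipped_k=skipped)


@dataclass
class IntermediacyResult:
    t: float              # 0 = parent A centroid, 1 = parent B centroid
    off_axis: float       # distance from the A-B segment line
    intermediate: bool    # 0 < t < 1


def hybrid_intermediacy(ordination: Ordination, groups: Dict[str, str],
                        parent_a: str, parent_b: str, test: str
                        ) -> IntermediacyResult:
    """Position of the test group's centroid along the segment joining the
    parental centroids in retained-axis space."""
    coords = {lab: ordination.coordinates[i]
              for i, lab in enumerate(ordination.labels)}
    cents = {}
    for g in (parent_a, parent_b, test):
        members = [lab for lab in ordination.labels if groups.get(lab) == g]
        if not members:
            raise ValueError(f"group {g!r} has no members")
        cents[g] = np.mean([coords[m] for m in members], axis=0)
    ab = cents[parent_b] - cents[parent_a]
    denom = float(ab @ ab)
    if denom == 0:
        raise ValueError("parental centroids coincide")
    t = float((cents[test] - cents[parent_a]) @ ab / denom)
    proj = cents[parent_a] + t * ab
    off = float(np.linalg.norm(cents[test] - proj))
    return IntermediacyResult(t=t, off_axis=off, intermediate=0.0 < t < 1.0)


# ----------------------------------------------------------------------
# Population-level statistics
# ----------------------------------------------------------------------


def chord_distance(pop_freqs_a: Dict[str, Dict[str, float]],
                   pop_freqs_b: Dict[str, Dict[str, float]]) -> float:
    """Cavalli-Sforza/Edwards chord distance between two populations.

    D^2 = 4 sum_l (1 - sum_a sqrt(x_la y_la)) / sum_l (m_l - 1), where
    m_l is the number of distinct alleles at locus l across both
    populations (the PHYLIP GENDIST normalization); returns D.
    """
    if set(pop_freqs_a) != set(pop_freqs_b):
        raise ValueError("populations must share the same loci")
    num = 0.0
    den = 0
    for locus in pop_freqs_a:
        xa = pop_freqs_a[locus]
        xb = pop_freqs_b[locus]
        alleles = set(xa) | set(xb)
        num += 1.0 - sum(math.sqrt(xa.get(a, 0.0) * xb.get(a, 0.0))
                         for a in alleles)
        den += len(alleles) - 1
    if den <= 0:
        return 0.0
    d2 = 4.0 * num / den
    return math.sqrt(max(d2, 0.0))


def allelic_richness(dataset: GenotypeDataset, g: Optional[int] = None
                     ) -> Dict[str, Dict[str, float]]:
    """Rarefied allelic richness per population per locus.

    AR = sum_a [1 - C(N - N_a, g) / C(N, g)] with N the gene copies in
    the population at the locus and N_a the copies of allele a.  ``g``
    defaults to the smallest per-population gene count across loci; the
    returned dict maps population -> {locus: AR, "mean": mean over loci}.
    """
    if g is not None and g < 1:
        raise ValueError("g must be >= 1")
    by_pop = dataset.split_populations()
    if g is None:
        g = min(
            sum(sub.allele_counts(locus).values())
            for sub in by_pop.values() for locus in dataset.loci
        )
    out: Dict[str, Dict[str, float]] = {}
    for pop, sub in by_pop.items():
        per_locus: Dict[str, float] = {}
        for locus in dataset.loci:
            counts = sub.allele_counts(locus)
            n_total = sum(counts.values())
            if n_total < g:
                raise ValueError(
                    f"g={g} exceeds gene count {n_total} in {pop} at {locus}")
            denom = math.comb(n_total, g)
            ar = sum(1.0 - math.comb(n_total - na, g) / denom
                     for na in counts.values())
            per_locus[locus] = ar
        per_locus["mean"] = float(np.mean([per_locus[l] for l in dataset.loci]))
        out[pop] = per_locus
    return out


def population_frequency_tables(dataset: GenotypeDataset
                                ) -> Dict[str, Dict[str, Dict[str, float]]]:
    """Plain per-population allele frequency tables (for chord distances)."""
    out = {}
    for pop, sub in dataset.split_populations().items():
        tables = {}
        for locus in dataset.loci:
            counts = sub.allele_counts(locus)
            tot = sum(counts.values())
            tables[locus] = {a: c / tot for a, c in counts.items()} if tot else {}
        out[pop] = tables
    return out
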