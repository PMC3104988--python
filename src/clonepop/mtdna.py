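"""Mitochondrial haplotype statistics and in-silico restriction digestion.

Covers haplotype collapsing, unbiased haplotype diversity h with its
standard deviation, nucleotide diversity pi with its standard deviation,
the count of segregating sites S, pairwise p-distance summaries within
and between regions, and ApoI (R^AATTY) digestion with a two-group
species call based on the presence of a cut in a diagnostic window.

Sites containing N or a gap are excluded pairwise (comparable-site
denominators); complete deletion is available by flag.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

VALID = set("ACGTN-")
AMBIGUOUS = set("N-")

#: ApoI recognition site: R^AATTY, cleavage after the leading purine.
APOI_RE = re.compile(r"(?=([AG]AATT[CT]))")


@dataclass
class HaplotypeSet:
    """Aligned sequences collapsed to unique haplotypes with counts."""

    sequences: List[str]
    labels: List[str]
    groups: Dict[str, str] = field(default_factory=dict)  # label -> region
    haplotypes: List[str] = field(default_factory=list)
    haplotype_of: Dict[str, str] = field(default_factory=dict)  # label -> hap id
    counts: Dict[str, int] = field(default_factory=dict)        # hap id -> count

    def __post_init__(self) -> None:
        if len(self.sequences) != len(self.labels):
            raise ValueError("one label per sequence required")
        lengths = {len(s) for s in self.sequences}
        if len(lengths) > 1:
            raise ValueError("sequences must be aligned to equal length")
        for s in self.sequences:
            bad = set(s.upper()) - VALID
            if bad:
                raise ValueError(f"invalid characters in sequence: {bad}")
        self.sequences = [s.upper() for s in self.sequences]
        if self.counts and sum(self.counts.values()) != len(self.sequences):
            raise ValueError("haplotype counts must sum to sequence count")

    @property
    def n(self) -> int:
        return len(self.sequences)

    @property
    def length(self) -> int:
        return len(self.sequences[0]) if self.sequences else 0

    def subset(self, labels: Sequence[str]) -> "HaplotypeSet":
        index = {lab: i for i, lab in enumerate(self.labels)}
        seqs = [self.sequences[index[lab]] for lab in labels]
        sub = HaplotypeSet(sequences=seqs, labels=list(labels),
                           groups={l: self.groups[l] for l in labels
                                   if l in self.groups})
        return collapse_haplotypes(sub)


def read_fasta(path, groups: Optional[Dict[str, str]] = None) -> HaplotypeSet:
    records = list(SeqIO.parse(str(path), "fasta"))
    hs = HaplotypeSet(sequences=[str(r.seq) for r in records],
                      labels=[r.id for r in records],
                      groups=dict(groups or {}))
    return collapse_haplotypes(hs)


def write_fasta(hapset: HaplotypeSet, path) -> None:
    records = [SeqRecord(Seq(s), id=lab, description="")
               for lab, s in zip(hapset.labels, hapset.sequences)]
    SeqIO.write(records, str(path), "fasta")


def collapse_haplotypes(hapset: HaplotypeSet) -> HaplotypeSet:
    """Assign deterministic haplotype ids by first occurrence.

    Two sequences belong to the same haplotype iff their strings are
    identical (sites with N/- compare literally).
    """
    hap_ids: Dict[str, str] = {}
    haplotypes: List[str] = []
    counts: Dict[str, int] = {}
    haplotype_of: Dict[str, str] = {}
    for lab, seq in zip(hapset.labels, hapset.sequences):
        if seq not in hap_ids:
            hap_ids[seq] = f"H{len(hap_ids) + 1:03d}"
            haplotypes.append(seq)
        hid = hap_ids[seq]
        counts[hid] = counts.get(hid, 0) + 1
        haplotype_of[lab] = hid
    hapset.haplotypes = haplotypes
    hapset.haplotype_of = haplotype_of
    hapset.counts = counts
    return hapset


# ----------------------------------------------------------------------
# Diversity
# ----------------------------------------------------------------------


def haplotype_diversity(hapset: HaplotypeSet
                        ) -> Tuple[Optional[float], Optional[float]]:
    """Unbiased haplotype diversity h = n(1 - sum f_i^2)/(n - 1) and its
    standard deviation (Nei 1987 variance).  NA for n < 2."""
    n = hapset.n
    if n < 2:
        return None, None
    if not hapset.counts:
        collapse_haplotypes(hapset)
    f = np.asarray(list(hapset.counts.values()), dtype=float) / n
    s2 = float(np.sum(f ** 2))
    s3 = float(np.sum(f ** 3))
    h = n * (1.0 - s2) / (n - 1)
    var = (2.0 / (n * (n - 1))) * (
        2.0 * (n - 2) * (s3 - s2 ** 2) + s2 - s2 ** 2
    )
    return h, math.sqrt(max(var, 0.0))


def _comparable(a: str, b: str) -> Iterable[Tuple[str, str]]:
    for x, y in zip(a, b):
        if x not in AMBIGUOUS and y not in AMBIGUOUS:
            yield x, y


def p_distance(a: str, b: str) -> float:
    """Proportion of differing sites among pairwise-comparable sites."""
    diff = 0
    comp = 0
    for x, y in _comparable(a, b):
        comp += 1
        if x != y:
            diff += 1
    if comp == 0:
        return float("nan")
    return diff / comp


def segregating_sites(sequences: Sequence[str],
                      complete_deletion: bool = False) -> int:
    """Number of variable sites; N/- are ignored per site (or the whole
    site is dropped under complete deletion)."""
    if not sequences:
        return 0
    length = len(sequences[0])
    s = 0
    for pos in range(length):
        column = [seq[pos] for seq in sequences]
        if complete_deletion and any(c in AMBIGUOUS for c in column):
            continue
        bases = {c for c in column if c not in AMBIGUOUS}
        if len(bases) > 1:
            s += 1
    return s


def nucleotide_diversity(hapset: HaplotypeSet,
                         complete_deletion: bool = False
                         ) -> Tuple[Optional[float], Optional[float], int]:
    """Nucleotide diversity pi (mean pairwise p-distance), its standard
    deviation (Nei 1987 eq. 10.7), and the segregating site count S."""
    n = hapset.n
    seqs = hapset.sequences
    if complete_deletion:
        keep = [pos for pos in range(hapset.length)
                if all(s[pos] not in AMBIGUOUS for s in seqs)]
        seqs = ["".join(s[pos] for pos in keep) for s in seqs]
    s_sites = segregating_sites(seqs)
    if n < 2:
        return None, None, s_sites
    dists = [p_distance(seqs[i], seqs[j])
             for i in range(n) for j in range(i + 1, n)]
    dists = [d for d in dists if not math.isnan(d)]
    if not dists:
        return None, None, s_sites
    pi = float(np.mean(dists))
    length = len(seqs[0]) if seqs[0] else 0
    if length == 0:
        return None, None, s_sites
    var = ((n + 1) / (3.0 * (n - 1) * length)) * pi \
        + (2.0 * (n ** 2 + n + 3) / (9.0 * n * (n - 1))) * pi ** 2
    return pi, math.sqrt(max(var, 0.0)), s_sites


@dataclass
class DiversitySummary:
    region: str
    n: int
    k: int
    S: int
    h: Optional[float]
    h_sd: Optional[float]
    pi: Optional[float]
    pi_sd: Optional[float]


def diversity_summary(hapset: HaplotypeSet,
                      by_region: bool = True) -> List[DiversitySummary]:
    """Per-region (and total) n, k, S, h +/- SD, pi +/- SD."""
    out: List[DiversitySummary] = []
    groupings: List[Tuple[str, List[str]]] = []
    if by_region and hapset.groups:
        regions: Dict[str, List[str]] = {}
        for lab in hapset.labels:
            regions.setdefault(hapset.groups.get(lab, "?"), []).append(lab)
        groupings.extend(sorted(regions.items()))
    groupings.append(("Total", list(hapset.labels)))
    for region, labels in groupings:
        sub = hapset.subset(labels)
        h, h_sd = haplotype_diversity(sub)
        pi, pi_sd, s = nucleotide_diversity(sub)
        out.append(DiversitySummary(region=region, n=sub.n,
                                    k=len(sub.counts), S=s,
                                    h=h, h_sd=h_sd, pi=pi, pi_sd=pi_sd))
    return out


# ----------------------------------------------------------------------
# Region distances
# ----------------------------------------------------------------------


@dataclass
class RegionDistances:
    regions: List[str]
    within: Dict[str, Optional[float]]
    between: Dict[Tuple[str, str], float]
    net: Dict[Tuple[str, str], Optional[float]]


def region_distance_summary(hapset: HaplotypeSet) -> RegionDistances:
    """Mean pairwise p-distance within and between regions; net between
    distance = between - (within_A + within_B)/2."""
    regions: Dict[str, List[int]] = {}
    for i, lab in enumerate(hapset.labels):
        regions.setdefault(hapset.groups.get(lab, "?"), []).append(i)
    if len(regions) < 2:
        raise ValueError("need at least 2 regions")
    names = sorted(regions)
    within: Dict[str, Optional[float]] = {}
    for r, idx in regions.items():
        if len(idx) < 2:
            within[r] = None
            continue
        ds = [p_distance(hapset.sequences[i], hapset.sequences[j])
              for a, i in enumerate(idx) for j in idx[a + 1:]]
        within[r] = float(np.mean(ds))
    between: Dict[Tuple[str, str], float] = {}
    net: Dict[Tuple[str, str], Optional[float]] = {}
    for a_pos, ra in enumerate(names):
        for rb in names[a_pos + 1:]:
            ds = [p_distance(hapset.sequences[i], hapset.sequences[j])
                  for i in regions[ra] for j in regions[rb]]
            b = float(np.mean(ds))
            between[(ra, rb)] = b
            if within[ra] is None or within[rb] is None:
                net[(ra, rb)] = None
            else:
                net[(ra, rb)] = b - (within[ra] + within[rb]) / 2.0
    return RegionDistances(regions=names, within=within, between=between,
                           net=net)


# ----------------------------------------------------------------------
# In-silico ApoI digestion
# ----------------------------------------------------------------------

PULICARIA = "pulicaria-group"
TENEBROSA = "tenebrosa-group"
AMBIGUOUS_CALL = "ambiguous"


@dataclass
class DigestResult:
    cut_positions: List[int]     # 1-based index of the last base of the
                                 # 5' fragment at each cut
    fragments: List[int]
    group_call: str

    def __post_init__(self) -> None:
        if self.cut_positions != sorted(self.cut_positions):
            raise ValueError("cut positions must be sorted")


def apoi_digest(sequence: str,
                diagnostic_window: Tuple[int, int] = (300, 400)
                ) -> DigestResult:
    """Scan for ApoI sites (R^AATTY) and digest the linear sequence.

    Cleavage occurs after the leading purine, so a site starting at
    1-based position p yields a cut position p (the last base of the 5'
    fragment).  Ambiguous bases never match.  The group call is
    ``pulicaria-group`` when at least one cut falls inside the diagnostic
    window (1-based, inclusive), ``tenebrosa-group`` when none does, and
    ``ambiguous`` when the sequence does not span the window start.
    """
    if not sequence:
        raise ValueError("empty sequence")
    seq = sequence.upper()
    cuts = [m.start() + 1 for m in APOI_RE.finditer(seq)]
    fragments: List[int] = []
    prev = 0
    for cut in cuts:
        fragments.append(cut - prev)
        prev = cut
    fragments.append(len(seq) - prev)
    lo, hi = diagnostic_window
    if any(lo <= c <= hi for c in cuts):
        call = PULICARIA
    elif len(seq) >= lo or not cuts:
        # window evaluable, or no site anywhere (absence is diagnostic)
        call = TENEBROSA
    else:
        call = AMBIGUOUS_CALL

    return DigestResult(cut_positions=cuts, fragments=fragments,
                        group_call=call)
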