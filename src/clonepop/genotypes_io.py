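"""Diploid multilocus genotype data model and file I/O.

A :class:`GenotypeDataset` holds one diploid call (an unordered pair of
allele labels) per individual per locus, with individuals grouped into
populations and populations optionally grouped into regions.  Allele
labels are opaque strings: every downstream statistic depends only on
label identity, never on fragment size.

Supported container formats:

* GenePop 4 dialect (title line, locus names, ``POP`` separators,
  ``ind , a1a2 a1a2 ...`` rows with 2- or 3-digit allele codes,
  ``00``/``000`` meaning a missing allele).
* A flat CSV dialect with header
  ``individual,population,<locus>_a,<locus>_b,...`` where an empty cell
  is a missing allele.

Missingness is whole-call: a half-missing diploid call is coerced to
MISSING, because every downstream formula assumes two observed alleles.
"""

from __future__ import annotations

import csv
import logging
import re
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

logger = logging.getLogger(__name__)

#: Sentinel for a missing diploid call.
MISSING = None

Call = Optional[Tuple[str, str]]


class FormatError(ValueError):
    """Raised when an input file violates the expected dialect."""


@dataclass
class GenotypeDataset:
    """Diploid multilocus genotypes with population/region labels.

    Parameters
    ----------
    individuals:
        Individual identifiers, in input order.
    populations:
        Map individual id -> population label (non-empty).
    loci:
        Ordered, unique locus names.
    calls:
        ``calls[i][l]`` is the call of individual ``i`` at locus ``l``:
        either a sorted 2-tuple of allele label strings or ``None``
        (MISSING).  Pairs are order-normalized so AB == BA.
    regions:
        Optional map population label -> region label.
    """

    individuals: List[str]
    populations: Dict[str, str]
    loci: List[str]
    calls: List[List[Call]]
    regions: Dict[str, str] = field(default_factory=dict)
    ploidy: int = 2

    def __post_init__(self) -> None:
        if len(set(self.loci)) != len(self.loci):
            raise ValueError("locus names must be unique")
        if len(self.individuals) != len(self.calls):
            raise ValueError("one call row per individual required")
        if len(set(self.individuals)) != len(self.individuals):
            raise ValueError("duplicate individual IDs")
        n_loci = len(self.loci)
        for ind, row in zip(self.individuals, self.calls):
            if len(row) != n_loci:
                raise ValueError(
                    f"individual {ind!r} has {len(row)} calls, expected {n_loci}"
                )
            pop = self.populations.get(ind)
            if not pop:
                raise ValueError(f"individual {ind!r} has no population label")
        # order-normalize in place so AB == BA everywhere downstream
        for row in self.calls:
            for j, call in enumerate(row):
                if call is not None:
                    a, b = call
                    row[j] = (a, b) if a <= b else (b, a)

    # -- basic accessors ------------------------------------------------

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    def population_names(self) -> List[str]:
        """Population labels in order of first appearance."""
        seen: List[str] = []
        for ind in self.individuals:
            pop = self.populations[ind]
            if pop not in seen:
                seen.append(pop)
        return seen

    def call(self, individual: str, locus: str) -> Call:
        i = self.individuals.index(individual)
        return self.calls[i][self.loci.index(locus)]

    def subset(self, individuals: List[str]) -> "GenotypeDataset":
        """New dataset restricted to ``individuals`` (kept in given order)."""
        index = {ind: i for i, ind in enumerate(self.individuals)}
        rows = [list(self.calls[index[ind]]) for ind in individuals]
        pops = {ind: self.populations[ind] for ind in individuals}
        return GenotypeDataset(
            individuals=list(individuals),
            populations=pops,
            loci=list(self.loci),
            calls=rows,
            regions=dict(self.regions),
        )

    def split_populations(self) -> Dict[str, "GenotypeDataset"]:
        """One single-population dataset per population, in file order."""
        out: Dict[str, GenotypeDataset] = {}
        for pop in self.population_names():
            members = [i for i in self.individuals if self.populations[i] == pop]
            out[pop] = self.subset(members)
        return out

    def has_missing(self) -> bool:
        return any(call is None for row in self.calls for call in row)

    def alleles_at(self, locus: str) -> List[str]:
        """Sorted distinct allele labels observed at ``locus``."""
        j = self.loci.index(locus)
        alleles = set()
        for row in self.calls:
            if row[j] is not None:
                alleles.update(row[j])
        return sorted(alleles)

    def allele_counts(self, locus: str) -> Dict[str, int]:
        """Observed allele copy counts at ``locus`` (missing calls skipped)."""
        j = self.loci.index(locus)
        counts: Dict[str, int] = {}
        for row in self.calls:
            if row[j] is not None:
                for a in row[j]:
                    counts[a] = counts.get(a, 0) + 1
        return counts

    def genotype_counts(self, locus: str) -> Dict[Tuple[str, str], int]:
        """Observed genotype counts at ``locus`` (missing calls skipped)."""
        j = self.loci.index(locus)
        counts: Dict[Tuple[str, str], int] = {}
        for row in self.calls:
            if row[j] is not None:
                counts[row[j]] = counts.get(row[j], 0) + 1
        return counts


# -- GenePop ------------------------------------------------------------


def _parse_genepop_field(fieldtext: str, line_no: int) -> Call:
    if len(fieldtext) % 2 != 0 or len(fieldtext) not in (4, 6):
        raise FormatError(
            f"line {line_no}: allele field {fieldtext!r} has odd or "
            "unsupported width (expected 4 or 6 digits)"
        )
    w = len(fieldtext) // 2
    a1, a2 = fieldtext[:w], fieldtext[w:]
    zero = "0" * w
    if a1 == zero or a2 == zero:
        # whole-call missingness: half-missing is coerced to MISSING
        return MISSING
    return tuple(sorted((a1, a2)))  # type: ignore[return-value]


def read_genepop(path) -> GenotypeDataset:
    """Read a GenePop 4 dialect file.

    Populations are named ``pop1``, ``pop2``, ... in file order unless an
    individual id of the form ``name_xx`` is present; the raw individual
    ids are always preserved.
    """
    with open(path, "r", encoding="utf-8") as fh:
        lines = fh.read().splitlines()
    if not lines:
        raise FormatError("empty GenePop file")
    # title line is lines[0]; locus names follow until first POP
    loci: List[str] = []
    i = 1
    while i < len(lines) and lines[i].strip().upper() != "POP":
        for name in lines[i].split(","):
            name = name.strip()
            if name:
                loci.append(name)
        i += 1
    if i == len(lines):
        raise FormatError("no POP separator found")

    individuals: List[str] = []
    populations: Dict[str, str] = {}
    calls: List[List[Call]] = []
    pop_idx = 0
    pop_label = ""
    for line_no, raw in enumerate(lines[i:], start=i + 1):
        text = raw.strip()
        if not text:
            continue
        if text.upper() == "POP":
            pop_idx += 1
            pop_label = f"pop{pop_idx}"
            continue
        if "," not in text:
            raise FormatError(f"line {line_no}: expected 'id , alleles' row")
        ind_id, _, geno = text.partition(",")
        ind_id = ind_id.strip()
        fields = geno.split()
        if len(fields) != len(loci):
            raise FormatError(
                f"line {line_no}: {len(fields)} genotype fields for "
                f"{len(loci)} loci"
            )
        row = [_parse_genepop_field(f, line_no) for f in fields]
        if ind_id in populations:
            # GenePop permits repeated ids across pops; disambiguate
            ind_id = f"{ind_id}@{pop_label}"
        individuals.append(ind_id)
        populations[ind_id] = pop_label
        calls.append(row)
    return GenotypeDataset(individuals, populations, loci, calls)


def write_genepop(dataset: GenotypeDataset, path, title: str = "clonepop export") -> None:
    """Write ``dataset`` in GenePop dialect (3-digit codes, LF endings).

    Raises
    ------
    ValueError
        If any allele label cannot be represented as a 3-digit code.
    """
    width = 3
    for locus in dataset.loci:
        for a in dataset.alleles_at(locus):
            if not re.fullmatch(r"\d{1,3}", a) or int(a) == 0 or int(a) > 999:
                raise ValueError(
                    f"allele label {a!r} at locus {locus} not representable "
                    "as a 3-digit GenePop code"
                )
    lines = [title]
    lines.extend(dataset.loci)
    by_pop = dataset.split_populations()
    for pop, sub in by_pop.items():
        lines.append("POP")
        for ind, row in zip(sub.individuals, sub.calls):
            fields = []
            for call in row:
                if call is None:
                    fields.append("0" * (2 * width))
                else:
                    fields.append("".join(a.zfill(width) for a in call))
            lines.append(f"{ind} , " + " ".join(fields))
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("\n".join(lines) + "\n")


# -- CSV ----------------------------------------------------------------


def read_genotype_csv(path) -> GenotypeDataset:
    """Read the flat CSV dialect.

    Header must be ``individual,population,<locus>_a,<locus>_b,...``.
    A blank allele cell makes the whole call MISSING (logged).
    """
    with open(path, "r", encoding="utf-8", newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header is None:
            raise FormatError("empty CSV file")
        if header[:2] != ["individual", "population"]:
            raise FormatError(
                "CSV header must start with 'individual,population'"
            )
        allele_cols = header[2:]
        if len(allele_cols) % 2 != 0:
            raise FormatError("odd number of allele columns")
        loci: List[str] = []
        for k in range(0, len(allele_cols), 2):
            a, b = allele_cols[k], allele_cols[k + 1]
            if not (a.endswith("_a") and b.endswith("_b") and a[:-2] == b[:-2]):
                raise FormatError(
                    f"allele columns {a!r},{b!r} must be <locus>_a,<locus>_b"
                )
            loci.append(a[:-2])

        individuals: List[str] = []
        populations: Dict[str, str] = {}
        calls: List[List[Call]] = []
        for line_no, rec in enumerate(reader, start=2):
            if not rec or not any(cell.strip() for cell in rec):
                continue
            if len(rec) != 2 + 2 * len(loci):
                raise FormatError(f"line {line_no}: wrong number of columns")
            ind, pop = rec[0].strip(), rec[1].strip()
            if ind in populations:
                raise FormatError(f"line {line_no}: duplicate individual id {ind!r}")
            row: List[Call] = []
            for k, locus in enumerate(loci):
                a1 = rec[2 + 2 * k].strip()
                a2 = rec[3 + 2 * k].strip()
                if a1 and a2:
                    row.append(tuple(sorted((a1, a2))))  # type: ignore[arg-type]
                else:
                    if bool(a1) != bool(a2):
                        logger.warning(
                            "half-missing call for %s at %s coerced to MISSING",
                            ind, locus,
                        )
                    row.append(MISSING)
            individuals.append(ind)
            populations[ind] = pop
            calls.append(row)
    return GenotypeDataset(individuals, populations, loci, calls)


def write_genotype_csv(dataset: GenotypeDataset, path) -> None:
    """Write the flat CSV dialect (inverse of :func:`read_genotype_csv`)."""
    header = ["individual", "population"]
    for locus in dataset.loci:
        header += [f"{locus}_a", f"{locus}_b"]
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(header)
        for ind, row in zip(dataset.individuals, dataset.calls):
            rec = [ind, dataset.populations[ind]]
            for call in row:
                rec += ["", ""] if call is None else list(call)
            writer.writerow(rec)


# -- filtering ----------------------------------------------------------


def complete_cases(dataset: GenotypeDataset) -> GenotypeDataset:
    """Keep only individuals with no MISSING call at any locus.

    Removal counts are logged per population.  Idempotent; may return an
    empty dataset.
    """
    keep: List[str] = []
    removed: Dict[str, int] = {}
    for ind, row in zip(dataset.individuals, dataset.calls):
        if any(call is None for call in row):
            pop = dataset.populations[ind]
            removed[pop] = removed.get(pop, 0) + 1
        else:
            keep.append(ind)
    for pop, n in sorted(removed.items()):
        logger.info("complete_cases: removed %d incomplete individuals from %s", n, pop)
    if not keep:
        logger.warning("complete_cases: no complete individuals remain")
    return dataset.subset(keep)
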