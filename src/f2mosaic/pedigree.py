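"""Genomes, individuals and nuclear families.

The unit of imputation is the *nuclear family*: one F2 offspring, its two F1
parents and the four line-labelled F0 grandparents.  Founder lines are called
``H`` (high) and ``L`` (low) after the divergently selected lines that
motivate the design; any two-line intercross fits the model.

Coordinates are 1-based inclusive throughout the library (VCF convention);
exporters that emit BED-style intervals perform the 0-based half-open
conversion themselves.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

GENERATIONS = ("F0", "F1", "F2")
LINES = ("H", "L")


class PedigreeError(ValueError):
    """Structural problem in a pedigree table (broken link, missing label)."""


class GenomeError(ValueError):
    """Invalid genome description."""


@dataclass(frozen=True)
class Individual:
    """One pedigree member.  Only F0 individuals carry a line label."""

    id: str
    generation: str
    line: str | None = None

    def __post_init__(self) -> None:
        if self.generation not in GENERATIONS:
            raise PedigreeError(f"{self.id}: unknown generation {self.generation!r}")
        if self.generation == "F0":
            if self.line not in LINES:
                raise PedigreeError(f"F0 individual {self.id} has no line label (H/L)")
        elif self.line is not None:
            raise PedigreeError(f"{self.generation} individual {self.id} must not carry a line label")


@dataclass(frozen=True)
class NuclearFamily:
    """One F2 with its two F1 parents and four F0 grandparents (2 H, 2 L)."""

    f2: Individual
    f1_sire: Individual
    f1_dam: Individual
    f0_h: tuple[Individual, Individual]
    f0_l: tuple[Individual, Individual]

    def __post_init__(self) -> None:
        if self.f1_sire.id == self.f1_dam.id:
            raise PedigreeError(f"family of {self.f2.id}: F1 sire and dam are the same individual")
        for ind in self.f0_h:
            if ind.line != "H":
                raise PedigreeError(f"family of {self.f2.id}: {ind.id} is not an H-line founder")
        for ind in self.f0_l:
            if ind.line != "L":
                raise PedigreeError(f"family of {self.f2.id}: {ind.id} is not an L-line founder")

    @property
    def id(self) -> str:
        return self.f2.id

    @property
    def founders(self) -> tuple[Individual, Individual, Individual, Individual]:
        return (*self.f0_h, *self.f0_l)


class GenomeSpec:
    """Ordered chromosomes with lengths and an imputation-eligible subset.

    Parameters
    ----------
    chromosomes
        Ordered ``(name, length_bp)`` pairs.
    exclude
        Chromosome names accepted in the spec but excluded from imputation
        (sex chromosomes, unplaced scaffolds).  They still validate positions.
    """

    def __init__(self, chromosomes: Sequence[tuple[str, int]], exclude: Iterable[str] = ()) -> None:
        names = [c for c, _ in chromosomes]
        if len(set(names)) != len(names):
            raise GenomeError("duplicate chromosome names")
        for name, length in chromosomes:
            if int(length) <= 0:
                raise GenomeError(f"chromosome {name} has non-positive length")
        self._chromosomes: list[tuple[str, int]] = [(str(n), int(l)) for n, l in chromosomes]
        self._lengths: dict[str, int] = dict(self._chromosomes)
        unknown = set(exclude) - set(names)
        if unknown:
            raise GenomeError(f"excluded chromosomes not in genome: {sorted(unknown)}")
        self.excluded: frozenset[str] = frozenset(exclude)

    @property
    def names(self) -> list[str]:
        return [n for n, _ in self._chromosomes]

    @property
    def imputable(self) -> list[str]:
        return [n for n, _ in self._chromosomes if n not in self.excluded]

    def length(self, chrom: str) -> int:
        return self._lengths[chrom]

    @property
    def total_length(self) -> int:
        return sum(l for _, l in self._chromosomes)

    @property
    def imputable_length(self) -> int:
        return sum(l for n, l in self._chromosomes if n not in self.excluded)

    def __iter__(self):
        return iter(self._chromosomes)

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._lengths

    def validate_position(self, chrom: str, pos: int) -> None:
        if chrom not in self._lengths:
            raise GenomeError(f"unknown chromosome {chrom!r}")
        if not 1 <= pos <= self._lengths[chrom]:
            raise GenomeError(f"position {chrom}:{pos} outside [1, {self._lengths[chrom]}]")

    def size_classes(self, marker_counts: Mapping[str, int], small_threshold: int = 2000) -> dict[str, str]:
        """Classify chromosomes as ``large``/``small`` by informative marker count.

        Window sizes for parameter estimation differ between large and small
        chromosomes; the class is decided per family from how many informative
        markers the chromosome carries.
        """
        return {
            name: ("small" if marker_counts.get(name, 0) < small_threshold else "large")
            for name in self.names
        }


@dataclass(frozen=True)
class VariantSite:
    """A biallelic SNP."""

    chrom: str
    pos: int
    ref: str
    alt: str


def load_genome(path: str | Path, exclude: Iterable[str] = ()) -> GenomeSpec:
    """Read a two-column ``chrom length`` TSV (header optional)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    if df.iloc[0, 0] in ("chrom", "chr", "name"):
        df = df.iloc[1:]
    return GenomeSpec([(r.iloc[0], int(r.iloc[1])) for _, r in df.iterrows()], exclude=exclude)


def _individual_from_row(row: pd.Series) -> Individual:
    line = row["line"]
    line = None if (pd.isna(line) or line in ("NA", "", "none")) else str(line)
    return Individual(id=str(row["id"]), generation=str(row["generation"]), line=line)


def load_pedigree(source: str | Path | pd.DataFrame, strict: bool = True):
    """Build nuclear families from a pedigree table.

    The table has columns ``id generation line sire dam`` with ``NA`` for
    unknown entries.  One family is emitted per F2 row; the four grandparents
    are resolved through the F1 parent links and split by line label.

    With ``strict=True`` (default) the first structural problem raises
    :class:`PedigreeError`; with ``strict=False`` a ``(families, problems)``
    pair is returned and every F2 lands either in a family or in a problem
    report.  F1 parents may be shared between families (many-to-many F1
    matings are the norm in large intercrosses).
    """
    if isinstance(source, pd.DataFrame):
        df = source.copy()
    else:
        df = pd.read_csv(source, sep="\t", dtype=str, comment="#")
    required = {"id", "generation", "line", "sire", "dam"}
    missing_cols = required - set(df.columns)
    if missing_cols:
        raise PedigreeError(f"pedigree table missing columns: {sorted(missing_cols)}")

    individuals: dict[str, Individual] = {}
    parents: dict[str, tuple[str | None, str | None]] = {}
    problems: list[str] = []

    def fail(msg: str) -> None:
        if strict:
            raise PedigreeError(msg)
        problems.append(msg)

    for _, row in df.iterrows():
        try:
            ind = _individual_from_row(row)
        except PedigreeError as exc:
            fail(str(exc))
            continue
        if ind.id in individuals:
            fail(f"duplicate individual id {ind.id}")
            continue
        individuals[ind.id] = ind
        sire = None if pd.isna(row["sire"]) or row["sire"] in ("NA", "") else str(row["sire"])
        dam = None if pd.isna(row["dam"]) or row["dam"] in ("NA", "") else str(row["dam"])
        parents[ind.id] = (sire, dam)

    def resolve(child: str, which: int, context: str) -> Individual | None:
        pid = parents[child][which]
        role = "sire" if which == 0 else "dam"
        if pid is None:
            fail(f"{context}: {role} of {child} is unknown")
            return None
        if pid not in individuals:
            fail(f"{context}: {role} {pid!r} of {child} not present in the table")
            return None
        return individuals[pid]

    families: list[NuclearFamily] = []
    for f2 in (i for i in individuals.values() if i.generation == "F2"):
        ctx = f"F2 {f2.id}"
        f1_sire = resolve(f2.id, 0, ctx)
        f1_dam = resolve(f2.id, 1, ctx)
        if f1_sire is None or f1_dam is None:
            continue
        if {f1_sire.generation, f1_dam.generation} != {"F1"}:
            fail(f"{ctx}: parents must be F1 individuals")
            continue
        grands = []
        ok = True
        for f1 in (f1_sire, f1_dam):
            for which in (0, 1):
                g = resolve(f1.id, which, ctx)
                if g is None or g.generation != "F0":
                    if g is not None:
                        fail(f"{ctx}: grandparent {g.id} is not an F0 individual")
                    ok = False
                else:
                    grands.append(g)
        if not ok:
            continue
        f0_h = tuple(g for g in grands if g.line == "H")
        f0_l = tuple(g for g in grands if g.line == "L")
        if len(f0_h) != 2 or len(f0_l) != 2:
            fail(f"{ctx}: grandparents are not 2 H-line + 2 L-line founders")
            continue
        try:
            families.append(
                NuclearFamily(f2=f2, f1_sire=f1_sire, f1_dam=f1_dam, f0_h=f0_h, f0_l=f0_l)
            )
        except PedigreeError as exc:
            fail(str(exc))

    families.sort(key=lambda fam: fam.id)
    if strict:
        return families
    return families, problems


def write_pedigree(families: Sequence[NuclearFamily], path: str | Path) -> None:
    """Write families back to the canonical five-column TSV."""
    rows: dict[str, tuple[str, str, str, str, str]] = {}
    for fam in families:
        for f0 in fam.founders:
            rows[f0.id] = (f0.id, "F0", f0.line or "NA", "NA", "NA")
        # F1 parentage: sire's parents are the first H and first L founder by
        # convention; the table is regenerable but line origin is what matters.
        sh, dh = fam.f0_h
        sl, dl = fam.f0_l
        rows.setdefault(fam.f1_sire.id, (fam.f1_sire.id, "F1", "NA", sh.id, sl.id))
        rows.setdefault(fam.f1_dam.id, (fam.f1_dam.id, "F1", "NA", dh.id, dl.id))
        rows[fam.f2.id] = (fam.f2.id, "F2", "NA", fam.f1_sire.id, fam.f1_dam.id)
    df = pd.DataFrame(list(rows.values()), columns=["id", "generation", "line", "sire", "dam"])
    df.to_csv(path, sep="\t", index=False)
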