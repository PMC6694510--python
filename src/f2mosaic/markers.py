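"""Founder variant filtering and informative-marker selection.

A marker is *informative within a family* when the two H-line founders are
homozygous for one allele and the two L-line founders are homozygous for the
other.  At such sites every offspring read reveals the line origin of the
sequenced chromosome, which is what makes sub-1x coverage sufficient for
mosaic reconstruction.  The alternative, pool-based mode selects markers
fixed (or nearly fixed, under a frequency slack ``delta``) between the whole
founder lines.

Genotype codes used throughout: 0 = hom ref, 1 = het, 2 = hom alt,
-1 = missing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .pedigree import NuclearFamily

HOM_REF, HET, HOM_ALT, MISSING = 0, 1, 2, -1

_NUCS = {"A", "C", "G", "T"}


@dataclass
class FounderFilterConfig:
    """Thresholds for the founder variant filter (all strict inequalities)."""

    min_maf: float = 0.043
    min_ac: int = 5
    min_qual: float = 30.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.min_maf <= 0.5:
            raise ValueError("min_maf must lie in [0, 0.5]")


class FounderVariants:
    """Biallelic founder sites with a genotype matrix.

    ``sites`` is a DataFrame with columns ``chrom pos ref alt qual ac an``
    (``ac``/``an`` may be NaN when the source VCF lacks them); ``gt`` is an
    ``(n_sites, n_samples)`` int8 matrix of genotype codes.
    """

    def __init__(self, sites: pd.DataFrame, gt: np.ndarray, samples: Sequence[str],
                 ingest_counters: Mapping[str, int] | None = None) -> None:
        if len(sites) != gt.shape[0]:
            raise ValueError("sites/genotype row mismatch")
        if gt.shape[1] != len(samples):
            raise ValueError("samples/genotype column mismatch")
        self.sites = sites.reset_index(drop=True)
        self.gt = np.asarray(gt, dtype=np.int8)
        self.samples = list(samples)
        self._col = {s: j for j, s in enumerate(self.samples)}
        self.ingest_counters = dict(ingest_counters or {})

    def __len__(self) -> int:
        return len(self.sites)

    def column(self, sample: str) -> np.ndarray:
        if sample not in self._col:
            raise KeyError(f"founder {sample!r} has no genotype data")
        return self.gt[:, self._col[sample]]

    def subset(self, mask: np.ndarray) -> "FounderVariants":
        return FounderVariants(self.sites.loc[mask], self.gt[mask], self.samples,
                               self.ingest_counters)

    def allele_numbers(self) -> tuple[np.ndarray, np.ndarray]:
        """(alt allele count, called allele number) computed from genotypes."""
        called = self.gt >= 0
        ac = np.where(called, self.gt, 0).sum(axis=1)
        an = 2 * called.sum(axis=1)
        return ac.astype(np.int64), an.astype(np.int64)


def read_founder_vcf(path: str | Path) -> FounderVariants:
    """Load founder GT calls from a (possibly uncompressed) VCF.

    Multi-allelic sites and indels are dropped with counters; sites are
    sorted by (chrom, pos) in file chromosome order.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    samples = list(vcf.samples)
    chroms, poss, refs, alts, quals, acs, ans = [], [], [], [], [], [], []
    gts = []
    counters = {"multiallelic_dropped": 0, "non_snp_dropped": 0}
    for v in vcf:
        if len(v.ALT) != 1:
            counters["multiallelic_dropped"] += 1
            continue
        if v.REF not in _NUCS or v.ALT[0] not in _NUCS:
            counters["non_snp_dropped"] += 1
            continue
        chroms.append(v.CHROM)
        poss.append(v.POS)
        refs.append(v.REF)
        alts.append(v.ALT[0])
        quals.append(v.QUAL if v.QUAL is not None else np.nan)
        info_ac = v.INFO.get("AC")
        acs.append(info_ac if isinstance(info_ac, (int, float)) else np.nan)
        info_an = v.INFO.get("AN")
        ans.append(info_an if isinstance(info_an, (int, float)) else np.nan)
        # gts012: 0 hom-ref, 1 het, 2 hom-alt, 3 missing
        g = np.asarray(v.gt_types, dtype=np.int8)
        g[g == 3] = MISSING
        gts.append(g)
    sites = pd.DataFrame(
        {"chrom": chroms, "pos": poss, "ref": refs, "alt": alts,
         "qual": quals, "ac": acs, "an": ans}
    )
    gt = np.vstack(gts) if gts else np.empty((0, len(samples)), dtype=np.int8)
    fv = FounderVariants(sites, gt, samples, counters)
    order = np.lexsort((fv.sites["pos"].to_numpy(),
                        fv.sites["chrom"].map({c: i for i, c in enumerate(pd.unique(fv.sites["chrom"]))}).to_numpy()))
    if not np.array_equal(order, np.arange(len(fv))):
        fv = fv.subset(order)
    return fv


def filter_founder_variants(fv: FounderVariants, cfg: FounderFilterConfig | None = None
                            ) -> tuple[FounderVariants, dict[str, int]]:
    """Apply the MAF/AC/QUAL founder filter (strict inequalities).

    MAF is computed across all genotyped founders jointly unless the VCF
    INFO already supplies AC/AN.  Sites where every founder call is missing
    are excluded and counted, not raised.
    """
    cfg = cfg or FounderFilterConfig()
    ac_gt, an_gt = fv.allele_numbers()
    ac = fv.sites["ac"].to_numpy(dtype=float)
    an = fv.sites["an"].to_numpy(dtype=float)
    ac = np.where(np.isnan(ac), ac_gt, ac)
    an = np.where(np.isnan(an), an_gt, an)
    qual = fv.sites["qual"].to_numpy(dtype=float)

    all_missing = an == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        af = np.where(an > 0, ac / an, 0.0)
    maf = np.minimum(af, 1.0 - af)

    pass_maf = maf > cfg.min_maf
    pass_ac = ac > cfg.min_ac
    pass_qual = qual > cfg.min_qual
    keep = pass_maf & pass_ac & pass_qual & ~all_missing
    counts = {
        "input": len(fv),
        "removed_all_missing": int(all_missing.sum()),
        "removed_maf": int((~pass_maf & ~all_missing).sum()),
        "removed_ac": int((~pass_ac & ~all_missing).sum()),
        "removed_qual": int((~pass_qual & ~all_missing).sum()),
        "retained": int(keep.sum()),
    }
    return fv.subset(keep), counts


@dataclass
class InformativeMarkerSet:
    """Markers informative for line origin, with the H-line allele recorded.

    ``table`` columns: ``chrom pos ref alt h_allele`` where ``h_allele`` is
    ``"ref"`` or ``"alt"``.  Sorted by (chrom, pos) in genome order.
    """

    family_id: str
    table: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        self.table = self.table.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.table)

    def chrom_table(self, chrom: str) -> pd.DataFrame:
        return self.table[self.table["chrom"] == chrom]

    def positions(self, chrom: str) -> np.ndarray:
        return self.chrom_table(chrom)["pos"].to_numpy(dtype=np.int64)

    def h_is_alt(self, chrom: str) -> np.ndarray:
        return (self.chrom_table(chrom)["h_allele"] == "alt").to_numpy()

    def counts_per_chrom(self) -> dict[str, int]:
        return self.table.groupby("chrom", sort=False).size().to_dict()

    def write_tsv(self, path: str | Path, header_comment: str | None = None) -> None:
        with open(path, "w") as fh:
            if header_comment:
                fh.write(f"# {header_comment}\n")
            fh.write(f"# family={self.family_id}\n")
            self.table.to_csv(fh, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path: str | Path) -> "InformativeMarkerSet":
        family_id = "unknown"
        with open(path) as fh:
            comments = []
            pos = fh.tell()
            line = fh.readline()
            while line.startswith("#"):
                comments.append(line)
                pos = fh.tell()
                line = fh.readline()
            fh.seek(pos)
            table = pd.read_csv(fh, sep="\t")
        for c in comments:
            if c.startswith("# family="):
                family_id = c.strip().split("=", 1)[1]
        return cls(family_id=family_id, table=table)


def _informative_mask(gh1: np.ndarray, gh2: np.ndarray, gl1: np.ndarray, gl2: np.ndarray
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized fixation predicate; returns (mask, h_is_alt)."""
    h_hom = ((gh1 == HOM_REF) | (gh1 == HOM_ALT)) & (gh1 == gh2)
    l_hom = ((gl1 == HOM_REF) | (gl1 == HOM_ALT)) & (gl1 == gl2)
    mask = h_hom & l_hom & (gh1 != gl1)
    return mask, gh1 == HOM_ALT


def select_family_informative(fv: FounderVariants, family: NuclearFamily) -> InformativeMarkerSet:
    """Markers fixed for alternative alleles between a family's founder pairs.

    A site is included iff both H founders share one homozygous call, both L
    founders share the homozygous call for the other allele, and none of the
    four calls is missing or heterozygous.
    """
    h1, h2 = (fv.column(f.id) for f in family.f0_h)
    l1, l2 = (fv.column(f.id) for f in family.f0_l)
    mask, h_is_alt = _informative_mask(h1, h2, l1, l2)
    table = fv.sites.loc[mask, ["chrom", "pos", "ref", "alt"]].copy()
    table["h_allele"] = np.where(h_is_alt[mask], "alt", "ref")
    return InformativeMarkerSet(family_id=family.id, table=table)


def select_pooled_informative(fv: FounderVariants, line_of: Mapping[str, str],
                              delta: float = 0.0) -> InformativeMarkerSet:
    """Line-level marker selection from pooled founder genotypes.

    A marker is included iff one allele has frequency >= 1 - ``delta`` among
    the H-line founders and <= ``delta`` among the L-line founders (strictly
    fixed by default).  Sites with no genotyped founder in either line are
    never informative.
    """
    if not 0.0 <= delta < 0.5:
        raise ValueError("delta must lie in [0, 0.5)")
    h_cols = [fv._col[s] for s, ln in line_of.items() if ln == "H" and s in fv._col]
    l_cols = [fv._col[s] for s, ln in line_of.items() if ln == "L" and s in fv._col]
    if not h_cols or not l_cols:
        raise ValueError("need at least one genotyped founder per line")

    def alt_freq(cols: list[int]) -> tuple[np.ndarray, np.ndarray]:
        g = fv.gt[:, cols]
        called = g >= 0
        an = 2 * called.sum(axis=1)
        ac = np.where(called, g, 0).sum(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            f = np.where(an > 0, ac / np.maximum(an, 1), np.nan)
        return f, an

    fh, an_h = alt_freq(h_cols)
    fl, an_l = alt_freq(l_cols)
    genotyped = (an_h > 0) & (an_l > 0)
    alt_in_h = (fh >= 1.0 - delta) & (fl <= delta)
    ref_in_h = (fh <= delta) & (fl >= 1.0 - delta)
    mask = genotyped & (alt_in_h | ref_in_h)
    table = fv.sites.loc[mask, ["chrom", "pos", "ref", "alt"]].copy()
    table["h_allele"] = np.where(alt_in_h[mask], "alt", "ref")
    return InformativeMarkerSet(family_id="pooled", table=table)
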