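"""Offspring allele-depth ingestion, polarization and density filtering.

Low-coverage offspring reads are consumed only at a family's informative
markers.  Ref/alt depths are *polarized* into line counts ``(n_H, n_L)``
using each marker's recorded H-line allele, so downstream code never needs
to know which physical allele belongs to which line.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .markers import InformativeMarkerSet
from .pedigree import GenomeSpec


@dataclass(frozen=True)
class SiteObservation:
    """Polarized read counts at one informative site for one individual."""

    chrom: str
    pos: int
    n_h: int
    n_l: int

    @property
    def depth(self) -> int:
        return self.n_h + self.n_l


@dataclass
class DensityFilterConfig:
    """Minimum genome-wide density of read-covered markers (per Mb)."""

    min_snps_per_mb: float = 5.0

    def __post_init__(self) -> None:
        if self.min_snps_per_mb < 0:
            raise ValueError("min_snps_per_mb must be >= 0")


@dataclass
class Observations:
    """All polarized observations for one individual, arrays per chromosome.

    ``by_chrom`` maps a chromosome name to ``(positions, n_h, n_l)`` arrays
    aligned with the marker set order on that chromosome.
    """

    individual: str
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = field(default_factory=dict)

    def n_covered(self) -> int:
        return int(sum(((nh + nl) > 0).sum() for _, nh, nl in self.by_chrom.values()))

    def total_reads(self) -> int:
        return int(sum(nh.sum() + nl.sum() for _, nh, nl in self.by_chrom.values()))

    def sites(self) -> list[SiteObservation]:
        out = []
        for chrom, (pos, nh, nl) in self.by_chrom.items():
            out.extend(SiteObservation(chrom, int(p), int(h), int(l))
                       for p, h, l in zip(pos, nh, nl))
        return out


def polarize(n_ref: np.ndarray, n_alt: np.ndarray, h_is_alt: np.ndarray
             ) -> tuple[np.ndarray, np.ndarray]:
    """Map (ref, alt) depths to (n_H, n_L) given the markers' H alleles."""
    n_ref = np.asarray(n_ref)
    n_alt = np.asarray(n_alt)
    n_h = np.where(h_is_alt, n_alt, n_ref)
    n_l = np.where(h_is_alt, n_ref, n_alt)
    return n_h, n_l


def extract_depths(source: str | Path | pd.DataFrame, markers: InformativeMarkerSet,
                   samples: list[str] | None = None) -> dict[str, Observations]:
    """Read per-sample ref/alt depths at marker sites and polarize them.

    ``source`` is a multi-sample VCF with a per-sample allele-depth (AD)
    field, or a TSV/DataFrame with columns ``chrom pos sample n_ref n_alt``.
    Marker sites absent from the input yield ``(0, 0)``.  Requesting a
    sample absent from the input is a hard error; malformed depth entries
    are skipped and counted in the returned Observations objects'
    ``skipped`` attribute (set on the dict as ``extract_depths.counters``).
    """
    if isinstance(source, (str, Path)) and str(source).endswith((".vcf", ".vcf.gz", ".bcf")):
        return _extract_from_vcf(source, markers, samples)
    if isinstance(source, pd.DataFrame):
        table = source
    else:
        table = pd.read_csv(source, sep="\t", comment="#",
                            dtype={"chrom": str, "pos": np.int64, "sample": str})
    return _extract_from_table(table, markers, samples)


def _empty_obs(markers: InformativeMarkerSet, sample: str) -> Observations:
    obs = Observations(individual=sample)
    for chrom in pd.unique(markers.table["chrom"]):
        pos = markers.positions(chrom)
        obs.by_chrom[chrom] = (pos, np.zeros(len(pos), dtype=np.int32),
                               np.zeros(len(pos), dtype=np.int32))
    return obs


def _extract_from_table(table: pd.DataFrame, markers: InformativeMarkerSet,
                        samples: list[str] | None) -> dict[str, Observations]:
    present = set(table["sample"].unique())
    if samples is None:
        samples = sorted(present)
    missing = set(samples) - present
    if missing:
        raise KeyError(f"samples absent from depth table: {sorted(missing)}")
    out = {s: _empty_obs(markers, s) for s in samples}
    index: dict[tuple[str, int], tuple[str, int, bool]] = {}
    for chrom in pd.unique(markers.table["chrom"]):
        pos = markers.positions(chrom)
        h_alt = markers.h_is_alt(chrom)
        for i, p in enumerate(pos):
            index[(chrom, int(p))] = (chrom, i, bool(h_alt[i]))
    skipped = 0
    for row in table.itertuples(index=False):
        if row.sample not in out:
            continue
        key = (str(row.chrom), int(row.pos))
        if key not in index:
            continue
        chrom, i, h_alt_i = index[key]
        try:
            n_ref, n_alt = int(row.n_ref), int(row.n_alt)
            if n_ref < 0 or n_alt < 0:
                raise ValueError
        except (TypeError, ValueError):
            skipped += 1
            continue
        _, nh, nl = out[row.sample].by_chrom[chrom]
        nh[i] += n_alt if h_alt_i else n_ref
        nl[i] += n_ref if h_alt_i else n_alt
    extract_depths.counters = {"malformed_skipped": skipped}
    return out


def _extract_from_vcf(path: str | Path, markers: InformativeMarkerSet,
                      samples: list[str] | None) -> dict[str, Observations]:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    file_samples = list(vcf.samples)
    if samples is None:
        samples = file_samples
    missing = set(samples) - set(file_samples)
    if missing:
        raise KeyError(f"samples absent from VCF: {sorted(missing)}")
    cols = [file_samples.index(s) for s in samples]
    out = {s: _empty_obs(markers, s) for s in samples}
    index: dict[tuple[str, int], tuple[str, int, bool]] = {}
    for chrom in pd.unique(markers.table["chrom"]):
        pos = markers.positions(chrom)
        h_alt = markers.h_is_alt(chrom)
        for i, p in enumerate(pos):
            index[(str(chrom), int(p))] = (str(chrom), i, bool(h_alt[i]))
    skipped = 0
    for v in vcf:
        key = (v.CHROM, v.POS)
        if key not in index:
            continue
        chrom, i, h_alt_i = index[key]
        ad = v.format("AD")
        if ad is None or ad.shape[1] < 2:
            skipped += 1
            continue
        ad = np.asarray(ad)
        for s, c in zip(samples, cols):
            n_ref, n_alt = int(ad[c, 0]), int(ad[c, 1])
            if n_ref < 0 or n_alt < 0:  # cyvcf2 encodes missing as negative
                continue
            _, nh, nl = out[s].by_chrom[chrom]
            nh[i] += n_alt if h_alt_i else n_ref
            nl[i] += n_ref if h_alt_i else n_alt
    extract_depths.counters = {"malformed_skipped": skipped}
    return out


def density(obs: Observations, genome: GenomeSpec) -> float:
    """Read-covered markers per Mb over the imputation-eligible genome."""
    return obs.n_covered() / (genome.imputable_length / 1e6)


def density_filter(obs: Observations, genome: GenomeSpec,
                   cfg: DensityFilterConfig | None = None) -> tuple[bool, float]:
    """Keep/drop decision for one individual plus its realized density.

    An individual is dropped when fewer than ``min_snps_per_mb`` marker
    sites per Mb carry at least one read, genome-wide.
    """
    cfg = cfg or DensityFilterConfig()
    d = density(obs, genome)
    return d >= cfg.min_snps_per_mb, d


def density_report(all_obs: Mapping[str, Observations], genome: GenomeSpec,
                   cfg: DensityFilterConfig | None = None) -> pd.DataFrame:
    """Per-individual coverage/density diagnostics table."""
    cfg = cfg or DensityFilterConfig()
    rows = []
    for ind, obs in all_obs.items():
        keep, d = density_filter(obs, genome, cfg)
        n_sites = sum(len(p) for p, _, _ in obs.by_chrom.values())
        rows.append({
            "individual": ind,
            "markers": n_sites,
            "covered_markers": obs.n_covered(),
            "total_reads": obs.total_reads(),
            "mean_depth": obs.total_reads() / max(n_sites, 1),
            "snps_per_mb": d,
            "pass_density": keep,
        })
    return pd.DataFrame(rows)
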