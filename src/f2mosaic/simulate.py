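"""Synthetic two-line pedigrees, founder genomes, meioses and skim reads.

The generator emulates the study design the pipeline targets: two divergent
but outbred founder lines, nuclear F0-F2 families, and very low coverage
sequencing of the F2s.  Sites are placed uniformly at random; a fraction
``fixed_fraction`` is fixed for alternative alleles between the lines, and
the remainder segregates within lines with allele frequencies drawn from a
symmetric Beta whose shape is set by the founder heterozygosity.  With the
defaults (2.8% line-fixed sites, within-line heterozygosity 1/3, i.e.
uniform allele frequencies) a family's informative markers are ~10.6% of
all sites, so the default total site density is chosen as
``informative_density_per_mb`` / 0.106 ~ 7.5k sites/Mb, which reproduces
both the target informative density (791/Mb) and a realistic total SNP
density for a livestock intercross.

Meioses place crossovers by drawing a Poisson count from the genetic map
length and rejection-sampling positions subject to a hard minimum gap
(absolute crossover interference over short distances).  Reads are
simulated at marker sites only: per-site depth is Poisson(coverage), each
read samples one of the two true alleles and flips line with probability
``seq_error``.  Everything is deterministic given the seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .hmm import STATES, MosaicSegmentation, Segment
from .markers import FounderVariants, _informative_mask
from .pedigree import GenomeSpec, Individual, NuclearFamily, write_pedigree

_BASES = np.array(list("ACGT"))


@dataclass
class SimConfig:
    genome: GenomeSpec
    n_families: int = 10
    fixed_fraction: float = 0.028
    within_line_het: float = 1.0 / 3.0
    informative_density_per_mb: float = 791.0
    coverage: float = 0.33
    seq_error: float = 0.005
    interference_min_gap_bp: int = 5_000_000
    map_rate_cm_per_mb: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("fixed_fraction", "seq_error"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if not 0.0 <= self.within_line_het < 0.5:
            raise ValueError("within_line_het must lie in [0, 0.5)")
        if self.informative_density_per_mb <= 0 or self.coverage < 0:
            raise ValueError("densities must be > 0 and coverage >= 0")
        if self.n_families < 1:
            raise ValueError("need at least one family")


def informative_site_probability(cfg: SimConfig) -> float:
    """P(a random site is informative for a random family).

    Non-fixed sites are informative when both H founders happen to be
    homozygous for one allele and both L founders for the other:
    2 * E[p^4]^2 under independent symmetric-Beta line frequencies.
    """
    h = cfg.within_line_het
    if h == 0.0:
        e_p4 = 0.5  # frequencies are point masses at 0 or 1
    else:
        a = h / (1.0 - 2.0 * h)  # Beta(a, a) has E[2pq] = a/(2a+1) = h
        e_p4 = np.prod([(a + k) / (2 * a + k) for k in range(4)])
    p_incidental = 2.0 * e_p4 ** 2
    return cfg.fixed_fraction + (1.0 - cfg.fixed_fraction) * p_incidental


def total_site_density(cfg: SimConfig) -> float:
    """Sites/Mb needed to reach the target informative density."""
    return cfg.informative_density_per_mb / informative_site_probability(cfg)


def _unique_sorted_positions(rng: np.random.Generator, n: int, length: int) -> np.ndarray:
    pos = np.unique(rng.integers(1, length + 1, size=n))
    while len(pos) < n:
        extra = rng.integers(1, length + 1, size=n - len(pos))
        pos = np.unique(np.concatenate([pos, extra]))
    return np.sort(pos[:n])


@dataclass
class FounderModel:
    """Site list plus per-line allele frequencies; samples founder genomes."""

    sites: pd.DataFrame  # chrom pos ref alt
    line_fixed: np.ndarray  # bool per site
    freq_h: np.ndarray  # alt-allele frequency in the H line
    freq_l: np.ndarray

    def sample_founder_genotypes(self, line: str, n: int, rng: np.random.Generator
                                 ) -> np.ndarray:
        """HWE genotype codes (alt dosage 0/1/2) for ``n`` founders of a line."""
        freq = self.freq_h if line == "H" else self.freq_l
        hap1 = rng.random((len(freq), n)) < freq[:, None]
        hap2 = rng.random((len(freq), n)) < freq[:, None]
        return (hap1.astype(np.int8) + hap2.astype(np.int8))


def simulate_founders(cfg: SimConfig, rng: np.random.Generator | None = None) -> FounderModel:
    """Place sites and draw per-line allele frequencies.

    A ``fixed_fraction`` subset is fixed for alternative alleles between the
    lines (the fixed allele choosing ref/alt at random); the rest segregates
    within lines at the configured heterozygosity.
    """
    rng = rng or np.random.default_rng(cfg.seed)
    density = total_site_density(cfg)
    chroms, poss = [], []
    for chrom, length in cfg.genome:
        n = int(round(density * length / 1e6))
        p = _unique_sorted_positions(rng, n, length)
        chroms.extend([chrom] * len(p))
        poss.append(p)
    pos = np.concatenate(poss) if poss else np.empty(0, dtype=np.int64)
    n_sites = len(pos)
    ref_idx = rng.integers(0, 4, size=n_sites)
    alt_idx = (ref_idx + rng.integers(1, 4, size=n_sites)) % 4
    sites = pd.DataFrame({"chrom": chroms, "pos": pos,
                          "ref": _BASES[ref_idx], "alt": _BASES[alt_idx]})
    line_fixed = rng.random(n_sites) < cfg.fixed_fraction
    h = cfg.within_line_het
    if h == 0.0:
        freq_h = rng.integers(0, 2, size=n_sites).astype(float)
        freq_l = rng.integers(0, 2, size=n_sites).astype(float)
    else:
        a = h / (1.0 - 2.0 * h)
        freq_h = rng.beta(a, a, size=n_sites)
        freq_l = rng.beta(a, a, size=n_sites)
    alt_in_h = rng.random(n_sites) < 0.5
    freq_h[line_fixed] = np.where(alt_in_h[line_fixed], 1.0, 0.0)
    freq_l[line_fixed] = np.where(alt_in_h[line_fixed], 0.0, 1.0)
    return FounderModel(sites=sites, line_fixed=line_fixed, freq_h=freq_h, freq_l=freq_l)


def sample_crossovers(length_bp: int, cfg: SimConfig, rng: np.random.Generator,
                      max_tries: int = 1000) -> np.ndarray:
    """Crossover positions for one meiosis on one chromosome.

    The count is Poisson with mean equal to the map length in Morgans;
    positions are uniform subject to pairwise gaps of at least
    ``interference_min_gap_bp`` (rejection sampling).  An infeasible count
    is redrawn with a warning.
    """
    morgans = length_bp / 1e6 * cfg.map_rate_cm_per_mb / 100.0
    while True:
        n = int(rng.poisson(morgans))
        if n == 0:
            return np.empty(0, dtype=np.int64)
        if (n - 1) * cfg.interference_min_gap_bp >= length_bp:
            warnings.warn(f"{n} crossovers infeasible on {length_bp} bp with "
                          f"{cfg.interference_min_gap_bp} bp interference; redrawing")
            continue
        for _ in range(max_tries):
            pos = np.sort(rng.integers(1, length_bp + 1, size=n))
            if n == 1 or np.all(np.diff(pos) >= cfg.interference_min_gap_bp):
                return pos.astype(np.int64)
        # extremely unlucky: fall through and redraw the count


def simulate_meiosis(hap_a: np.ndarray, hap_b: np.ndarray, positions: np.ndarray,
                     length_bp: int, cfg: SimConfig, rng: np.random.Generator
                     ) -> tuple[np.ndarray, np.ndarray, int]:
    """One gamete from two parental haplotypes on one chromosome.

    Returns ``(gamete, crossover_positions, start_phase)`` where the gamete
    alternates between the haplotypes at the crossover positions and
    ``start_phase`` is 0 when it begins on ``hap_a``.
    """
    crossovers = sample_crossovers(length_bp, cfg, rng)
    start_phase = int(rng.integers(0, 2))
    phase = (start_phase + np.searchsorted(crossovers, positions, side="left")) % 2
    gamete = np.where(phase == 0, hap_a, hap_b)
    return gamete, crossovers, start_phase


@dataclass
class TruthMosaic:
    """Ground-truth line-origin segments and crossovers for one F2."""

    individual: str
    segments: dict[str, MosaicSegmentation] = field(default_factory=dict)
    crossovers: dict[str, list[int]] = field(default_factory=dict)

    def state_at(self, chrom: str, pos: int) -> str:
        return self.segments[chrom].state_at(pos)


def _truth_from_gametes(individual: str, chrom: str, length: int,
                        sire: tuple[np.ndarray, int], dam: tuple[np.ndarray, int]
                        ) -> tuple[MosaicSegmentation, list[int]]:
    """Combine two gametes' line phases into HH/HL/LL segments.

    Phase 0 means the gamete carries the H-line chromosome.
    """
    s_co, s_phase = sire
    d_co, d_phase = dam
    cuts = sorted(set(int(c) for c in s_co) | set(int(c) for c in d_co))
    edges = [0] + cuts + [length]
    segments = []
    for a, b in zip(edges, edges[1:]):
        mid = a + 1  # phase is constant on (a, b]
        sp = (s_phase + np.searchsorted(s_co, mid, side="left")) % 2
        dp = (d_phase + np.searchsorted(d_co, mid, side="left")) % 2
        n_l = int(sp) + int(dp)
        segments.append(Segment(a + 1, b, STATES[n_l]))
    merged: list[Segment] = []
    for s in segments:
        if merged and merged[-1].state == s.state:
            merged[-1] = Segment(merged[-1].start, s.end, s.state)
        else:
            merged.append(s)
    seg = MosaicSegmentation(individual=individual, chrom=chrom, chrom_length=length,
                             segments=merged)
    seg.validate()
    return seg, cuts


def simulate_reads(alt_dosage: np.ndarray, cfg: SimConfig, rng: np.random.Generator
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Per-site (n_ref, n_alt) skim-sequencing depths for one individual.

    Depth is Poisson(``coverage``); each read samples one of the two true
    alleles and is mis-read as the other allele with probability
    ``seq_error``.
    """
    g = np.asarray(alt_dosage)
    n = rng.poisson(cfg.coverage, size=g.shape)
    p_alt = g / 2.0
    p_alt = p_alt * (1.0 - cfg.seq_error) + (1.0 - p_alt) * cfg.seq_error
    n_alt = rng.binomial(n, p_alt)
    return (n - n_alt).astype(np.int64), n_alt.astype(np.int64)


@dataclass
class SimulatedFamily:
    family: NuclearFamily
    informative_mask: np.ndarray  # over the global site table
    h_is_alt: np.ndarray  # per informative site
    truth: TruthMosaic
    n_ref: np.ndarray  # reads at informative sites, site-table order
    n_alt: np.ndarray


@dataclass
class SimulatedDataset:
    """Everything the pipeline consumes, plus ground truth."""

    cfg: SimConfig
    model: FounderModel
    founders: FounderVariants
    families: list[NuclearFamily]
    sim_families: dict[str, SimulatedFamily]  # keyed by F2 id

    @property
    def truth(self) -> dict[str, TruthMosaic]:
        return {fid: sf.truth for fid, sf in self.sim_families.items()}

    def observations(self, f2_id: str):
        """Polarized (positions, n_H, n_L) arrays per chromosome for one F2."""
        from .readcalls import Observations, polarize

        sf = self.sim_families[f2_id]
        sites = self.model.sites.loc[sf.informative_mask]
        n_h, n_l = polarize(sf.n_ref, sf.n_alt, sf.h_is_alt)
        obs = Observations(individual=f2_id)
        chrom_arr = sites["chrom"].to_numpy()
        pos_arr = sites["pos"].to_numpy(dtype=np.int64)
        for chrom, _ in self.cfg.genome:
            m = chrom_arr == chrom
            obs.by_chrom[chrom] = (pos_arr[m], n_h[m].astype(np.int32),
                                   n_l[m].astype(np.int32))
        return obs

    def marker_set(self, f2_id: str):
        from .markers import InformativeMarkerSet

        sf = self.sim_families[f2_id]
        table = self.model.sites.loc[sf.informative_mask, ["chrom", "pos", "ref", "alt"]].copy()
        table["h_allele"] = np.where(sf.h_is_alt, "alt", "ref")
        return InformativeMarkerSet(family_id=f2_id, table=table)


def simulate_dataset(cfg: SimConfig) -> SimulatedDataset:
    """Full cohort simulation: founders, pedigree, truth mosaics and reads."""
    rng = np.random.default_rng(cfg.seed)
    model = simulate_founders(cfg, rng)
    n_sites = len(model.sites)

    families: list[NuclearFamily] = []
    sim_families: dict[str, SimulatedFamily] = {}
    founder_ids: list[str] = []
    founder_gt_cols: list[np.ndarray] = []
    qual = np.round(rng.uniform(31.0, 99.0, size=n_sites), 2)

    for j in range(cfg.n_families):
        f0_h = (Individual(f"fam{j}_H1", "F0", "H"), Individual(f"fam{j}_H2", "F0", "H"))
        f0_l = (Individual(f"fam{j}_L1", "F0", "L"), Individual(f"fam{j}_L2", "F0", "L"))
        f1_sire = Individual(f"fam{j}_F1s", "F1")
        f1_dam = Individual(f"fam{j}_F1d", "F1")
        f2 = Individual(f"fam{j}_F2", "F2")
        fam = NuclearFamily(f2=f2, f1_sire=f1_sire, f1_dam=f1_dam, f0_h=f0_h, f0_l=f0_l)
        families.append(fam)

        gt_h = model.sample_founder_genotypes("H", 2, rng)
        gt_l = model.sample_founder_genotypes("L", 2, rng)
        founder_ids.extend([f.id for f in (*f0_h, *f0_l)])
        founder_gt_cols.extend([gt_h[:, 0], gt_h[:, 1], gt_l[:, 0], gt_l[:, 1]])

        mask, h_is_alt_full = _informative_mask(gt_h[:, 0], gt_h[:, 1],
                                                gt_l[:, 0], gt_l[:, 1])
        h_is_alt = h_is_alt_full[mask]

        # F1s carry one pure-H and one pure-L chromosome set; an F1 gamete's
        # line origin is therefore its meiotic phase.  Only line origin is
        # tracked: informative markers are homozygous within each founder.
        truth = TruthMosaic(individual=f2.id)
        chrom_arr = model.sites["chrom"].to_numpy()
        state_per_site = np.empty(int(mask.sum()), dtype=np.int8)
        inf_chrom = chrom_arr[mask]
        inf_pos = model.sites["pos"].to_numpy()[mask]
        for chrom, length in cfg.genome:
            s_co = sample_crossovers(length, cfg, rng)
            s_phase = int(rng.integers(0, 2))
            d_co = sample_crossovers(length, cfg, rng)
            d_phase = int(rng.integers(0, 2))
            seg, cuts = _truth_from_gametes(f2.id, chrom, length,
                                            (s_co, s_phase), (d_co, d_phase))
            truth.segments[chrom] = seg
            truth.crossovers[chrom] = cuts
            m = inf_chrom == chrom
            p = inf_pos[m]
            sp = (s_phase + np.searchsorted(s_co, p, side="left")) % 2
            dp = (d_phase + np.searchsorted(d_co, p, side="left")) % 2
            state_per_site[m] = (sp + dp).astype(np.int8)  # 0=HH 1=HL 2=LL

        # alt dosage at informative sites given line-origin state
        n_h_alleles = 2 - state_per_site  # copies of the H-line allele
        alt_dosage = np.where(h_is_alt, n_h_alleles, 2 - n_h_alleles)
        n_ref, n_alt = simulate_reads(alt_dosage, cfg, rng)
        sim_families[f2.id] = SimulatedFamily(
            family=fam, informative_mask=mask, h_is_alt=h_is_alt, truth=truth,
            n_ref=n_ref, n_alt=n_alt)

    gt = (np.column_stack(founder_gt_cols) if founder_gt_cols
          else np.empty((n_sites, 0), dtype=np.int8))
    ac = np.where(gt >= 0, gt, 0).sum(axis=1)
    an = np.full(n_sites, gt.shape[1] * 2)
    sites = model.sites.copy()
    sites["qual"] = qual
    sites["ac"] = ac.astype(float)
    sites["an"] = an.astype(float)
    founders = FounderVariants(sites, gt.astype(np.int8), founder_ids)
    return SimulatedDataset(cfg=cfg, model=model, founders=founders,
                            families=families, sim_families=sim_families)


def thin_reads(dataset: SimulatedDataset, coverage: float, seed: int) -> SimulatedDataset:
    """Binomially thin every read to emulate a lower sequencing coverage.

    Produces a coupled dataset sharing sites, founders and truth mosaics,
    with each read kept independently with probability
    ``coverage / dataset.cfg.coverage``.
    """
    if coverage > dataset.cfg.coverage:
        raise ValueError("can only thin to a lower coverage")
    keep_p = coverage / dataset.cfg.coverage
    rng = np.random.default_rng(seed)
    new_cfg = replace(dataset.cfg, coverage=coverage)
    new_fams = {}
    for fid, sf in dataset.sim_families.items():
        n_ref = rng.binomial(sf.n_ref, keep_p)
        n_alt = rng.binomial(sf.n_alt, keep_p)
        new_fams[fid] = SimulatedFamily(family=sf.family,
                                        informative_mask=sf.informative_mask,
                                        h_is_alt=sf.h_is_alt, truth=sf.truth,
                                        n_ref=n_ref, n_alt=n_alt)
    return SimulatedDataset(cfg=new_cfg, model=dataset.model,
                            founders=dataset.founders, families=dataset.families,
                            sim_families=new_fams)


# ---------------------------------------------------------------------------
# file emission (the exact input dialects the pipeline consumes)

_VCF_HEADER = """##fileformat=VCFv4.2
##source=f2mosaic-simulate
{extra}##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
"""


def write_genome_tsv(genome: GenomeSpec, path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom, length in genome:
            fh.write(f"{chrom}\t{length}\n")


def write_founder_vcf(dataset: SimulatedDataset, path: str | Path) -> None:
    """Founder GT calls as an uncompressed VCF with QUAL and INFO/AC/AN."""
    fv = dataset.founders
    gt_str = {0: "0/0", 1: "0/1", 2: "1/1", -1: "./."}
    with open(path, "w") as fh:
        fh.write(_VCF_HEADER.format(
            extra='##INFO=<ID=AC,Number=A,Type=Integer,Description="Alt allele count">\n'
                  '##INFO=<ID=AN,Number=1,Type=Integer,Description="Allele number">\n'))
        for chrom, length in dataset.cfg.genome:
            fh.write(f"##contig=<ID={chrom},length={length}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(fv.samples) + "\n")
        sites = fv.sites
        for i in range(len(sites)):
            row = sites.iloc[i]
            gts = "\t".join(gt_str[int(g)] for g in fv.gt[i])
            fh.write(f"{row.chrom}\t{row.pos}\t.\t{row.ref}\t{row.alt}\t"
                     f"{row.qual:.2f}\t.\tAC={int(row.ac)};AN={int(row.an)}\tGT\t{gts}\n")


def write_offspring_vcf(dataset: SimulatedDataset, path: str | Path) -> None:
    """Multi-sample offspring VCF with per-sample allele depths (AD).

    Sites are the union of the families' informative markers; a sample has
    depth only at its own family's markers (others are 0,0), mirroring the
    per-family read-calling step.
    """
    ids = sorted(dataset.sim_families)
    union_mask = np.zeros(len(dataset.model.sites), dtype=bool)
    for sf in dataset.sim_families.values():
        union_mask |= sf.informative_mask
    union_idx = np.nonzero(union_mask)[0]
    pos_in_union = {int(g): i for i, g in enumerate(union_idx)}
    n_ref = np.zeros((len(union_idx), len(ids)), dtype=np.int32)
    n_alt = np.zeros_like(n_ref)
    for j, fid in enumerate(ids):
        sf = dataset.sim_families[fid]
        rows = [pos_in_union[int(g)] for g in np.nonzero(sf.informative_mask)[0]]
        n_ref[rows, j] = sf.n_ref
        n_alt[rows, j] = sf.n_alt
    sites = dataset.model.sites.iloc[union_idx]
    with open(path, "w") as fh:
        fh.write(_VCF_HEADER.format(extra=""))
        fh.write('##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">\n')
        for chrom, length in dataset.cfg.genome:
            fh.write(f"##contig=<ID={chrom},length={length}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(ids) + "\n")
        for i in range(len(sites)):
            row = sites.iloc[i]
            cells = "\t".join(f"./.:{n_ref[i, j]},{n_alt[i, j]}" for j in range(len(ids)))
            fh.write(f"{row.chrom}\t{row.pos}\t.\t{row.ref}\t{row.alt}\t.\t.\t.\tGT:AD\t{cells}\n")


def write_truth_tsv(dataset: SimulatedDataset, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("individual\tchrom\tstart\tend\tstate\n")
        for fid in sorted(dataset.sim_families):
            truth = dataset.sim_families[fid].truth
            for chrom, seg in truth.segments.items():
                for s in seg.segments:
                    fh.write(f"{fid}\t{chrom}\t{s.start}\t{s.end}\t{s.state}\n")


def read_truth_tsv(path: str | Path, genome: GenomeSpec) -> dict[str, TruthMosaic]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    out: dict[str, TruthMosaic] = {}
    for (fid, chrom), grp in df.groupby(["individual", "chrom"], sort=True):
        grp = grp.sort_values("start")
        segs = [Segment(int(r.start), int(r.end), r.state) for r in grp.itertuples()]
        mosaic = out.setdefault(fid, TruthMosaic(individual=fid))
        seg = MosaicSegmentation(individual=fid, chrom=chrom,
                                 chrom_length=genome.length(chrom), segments=segs)
        seg.validate()
        mosaic.segments[chrom] = seg
        cuts = [s.end for s in segs[:-1]]
        mosaic.crossovers[chrom] = cuts
    return out


def write_dataset(dataset: SimulatedDataset, outdir: str | Path) -> dict[str, Path]:
    """Emit founder VCF, offspring VCF, pedigree, genome and truth files."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "founder_vcf": outdir / "founders.vcf",
        "offspring_vcf": outdir / "offspring.vcf",
        "pedigree": outdir / "pedigree.tsv",
        "genome": outdir / "genome.tsv",
        "truth": outdir / "truth_segments.tsv",
    }
    write_founder_vcf(dataset, paths["founder_vcf"])
    write_offspring_vcf(dataset, paths["offspring_vcf"])
    write_pedigree(dataset.families, paths["pedigree"])
    write_genome_tsv(dataset.cfg.genome, paths["genome"])
    write_truth_tsv(dataset, paths["truth"])
    return paths
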