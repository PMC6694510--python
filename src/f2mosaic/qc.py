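"""Post-reconstruction quality control, binning and export.

Nearby double crossovers are biologically implausible (crossover
interference is effectively absolute over short distances), so internal
decided segments shorter than a threshold that are flanked by crossovers on
both sides are removed: merged away when the flanking segments agree in
state, masked to UU when they disagree.  Individuals whose genome-wide call
rate drops below a threshold after this filter — or that are gross outliers
in crossover count — are flagged as likely sample mix-ups or pedigree
errors.  Surviving mosaics are summarized into fixed-size physical bins and
exported in R/qtl's rotated CSV dialect for linkage/QTL analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .hmm import STATES, BreakpointInterval, MosaicSegmentation, Segment
from .pedigree import GenomeSpec

RQTL_CODES = {"HH": "A", "HL": "H", "LL": "B", "missing": "-"}
RQTL_DECODE = {v: k for k, v in RQTL_CODES.items()}


@dataclass
class QCConfig:
    min_double_co_span_bp: int = 3_000_000
    min_call_rate: float = 0.90
    bin_size_bp: int = 1_000_000
    outlier_mode: str = "call_rate"  # or "crossover_count"
    outlier_multiplier: float = 3.0
    double_co_mode: str = "mask"  # or "merge_left" when flanks disagree

    def __post_init__(self) -> None:
        if self.min_double_co_span_bp <= 0 or self.bin_size_bp <= 0:
            raise ValueError("spans and bins must be > 0")
        if not 0.0 <= self.min_call_rate <= 1.0:
            raise ValueError("min_call_rate must lie in [0, 1]")
        if self.outlier_mode not in ("call_rate", "crossover_count"):
            raise ValueError("unknown outlier_mode")
        if self.double_co_mode not in ("mask", "merge_left"):
            raise ValueError("unknown double_co_mode")


@dataclass
class BinnedGenotypes:
    """Per-chromosome fixed-size bins with codes HH/HL/LL/missing.

    ``bins`` maps chromosome -> DataFrame with columns ``start end code``;
    terminal partial bins keep their true span.
    """

    individual: str
    bins: dict[str, pd.DataFrame] = field(default_factory=dict)

    def codes(self, chrom: str) -> np.ndarray:
        return self.bins[chrom]["code"].to_numpy()

    def n_bins(self) -> int:
        return sum(len(df) for df in self.bins.values())


def _state_distance(a: str, b: str) -> int:
    """Number of crossovers implied by moving between two decided states."""
    return abs(STATES.index(a) - STATES.index(b))


def crossover_count(seg: MosaicSegmentation) -> int:
    """Crossovers on one chromosome: transitions between consecutive decided
    states, skipping UU; HH<->LL counts as two."""
    decided = [s.state for s in seg.segments if s.state in STATES]
    return sum(_state_distance(a, b) for a, b in zip(decided, decided[1:]))


def genome_crossover_count(segs: Iterable[MosaicSegmentation]) -> int:
    return sum(crossover_count(s) for s in segs)


def remove_close_double_crossovers(seg: MosaicSegmentation, cfg: QCConfig | None = None
                                   ) -> tuple[MosaicSegmentation, list[dict]]:
    """Remove implausibly short double-crossover segments.

    Every internal *decided* segment shorter than ``min_double_co_span_bp``
    whose two neighbours are both decided (i.e. the segment is flanked by
    two crossovers) is removed: if the flanks share a state the three
    segments merge (removing two crossovers); if they differ the short
    segment is masked to UU (``mask`` mode, default) or absorbed into the
    left flank (``merge_left``).  The filter iterates until stable and
    returns a removal log.
    """
    cfg = cfg or QCConfig()
    segments = list(seg.segments)
    boundary_bp = {s.start: bp for s, bp in zip(seg.segments[1:], seg.breakpoints)}
    log: list[dict] = []
    changed = True
    while changed:
        changed = False
        for j in range(1, len(segments) - 1):
            s = segments[j]
            if s.state not in STATES or s.length >= cfg.min_double_co_span_bp:
                continue
            left, right = segments[j - 1], segments[j + 1]
            if left.state not in STATES or right.state not in STATES:
                continue
            if left.state == right.state:
                merged = Segment(left.start, right.end, left.state)
                boundary_bp.pop(s.start, None)
                boundary_bp.pop(right.start, None)
                segments[j - 1: j + 2] = [merged]
                log.append({"chrom": seg.chrom, "start": s.start, "end": s.end,
                            "state": s.state, "action": "merged",
                            "crossovers_removed": 2})
            elif cfg.double_co_mode == "merge_left":
                boundary_bp.pop(s.start, None)
                segments[j - 1: j + 1] = [Segment(left.start, s.end, left.state)]
                log.append({"chrom": seg.chrom, "start": s.start, "end": s.end,
                            "state": s.state, "action": "merged_left",
                            "crossovers_removed":
                                _state_distance(left.state, s.state)
                                + _state_distance(s.state, right.state)
                                - _state_distance(left.state, right.state)})
            else:
                segments[j] = Segment(s.start, s.end, "UU")
                log.append({"chrom": seg.chrom, "start": s.start, "end": s.end,
                            "state": s.state, "action": "masked",
                            "crossovers_removed":
                                _state_distance(left.state, s.state)
                                + _state_distance(s.state, right.state)
                                - _state_distance(left.state, right.state)})
            changed = True
            break
    # collapse any adjacent equal states produced by masking
    collapsed: list[Segment] = []
    for s in segments:
        if collapsed and collapsed[-1].state == s.state:
            boundary_bp.pop(s.start, None)
            collapsed[-1] = Segment(collapsed[-1].start, s.end, s.state)
        else:
            collapsed.append(s)
    breakpoints = [boundary_bp[s.start] for s in collapsed[1:] if s.start in boundary_bp]
    out = MosaicSegmentation(individual=seg.individual, chrom=seg.chrom,
                             chrom_length=seg.chrom_length, segments=collapsed,
                             breakpoints=breakpoints)
    out.validate()
    return out, log


def call_rate(segs: Sequence[MosaicSegmentation], genome: GenomeSpec) -> float:
    """Fraction of the imputation-eligible genome in decided states.

    Chromosomes without a segmentation count as fully undecided.
    """
    decided = sum(s.decided_length() for s in segs)
    total = genome.imputable_length
    return decided / total if total else float("nan")


def crossover_outliers(segs_by_individual: Mapping[str, Sequence[MosaicSegmentation]],
                       genome: GenomeSpec, cfg: QCConfig | None = None
                       ) -> tuple[list[str], pd.DataFrame]:
    """Flag individuals with implausible genome-wide recombination.

    ``call_rate`` mode flags individuals below ``min_call_rate``;
    ``crossover_count`` mode flags counts above
    median + multiplier * MAD-equivalent (1.4826 * MAD).  The report lists
    both statistics for every individual regardless of mode.
    """
    cfg = cfg or QCConfig()
    rows = []
    for ind in sorted(segs_by_individual):
        segs = segs_by_individual[ind]
        rows.append({"individual": ind,
                     "call_rate": call_rate(segs, genome),
                     "crossovers": genome_crossover_count(segs)})
    report = pd.DataFrame(rows)
    if report.empty:
        return [], report
    if cfg.outlier_mode == "call_rate":
        flagged_mask = report["call_rate"] < cfg.min_call_rate
    else:
        counts = report["crossovers"].to_numpy(dtype=float)
        med = np.median(counts)
        mad = np.median(np.abs(counts - med))
        threshold = med + cfg.outlier_multiplier * 1.4826 * mad
        flagged_mask = report["crossovers"] > threshold
    report["flagged"] = flagged_mask
    return report.loc[flagged_mask, "individual"].tolist(), report


def bin_genotypes(segs: Sequence[MosaicSegmentation], genome: GenomeSpec,
                  cfg: QCConfig | None = None, individual: str | None = None
                  ) -> BinnedGenotypes:
    """Summarize one individual's mosaics into fixed-size physical bins.

    A bin takes the state of the single decided segment that covers it
    entirely; bins containing a crossover (a segment boundary) or touching
    any UU segment are coded ``missing``.
    """
    cfg = cfg or QCConfig()
    by_chrom = {s.chrom: s for s in segs}
    if individual is None:
        individual = segs[0].individual if segs else "unknown"
    out = BinnedGenotypes(individual=individual)
    for chrom in genome.imputable:
        length = genome.length(chrom)
        starts = np.arange(1, length + 1, cfg.bin_size_bp, dtype=np.int64)
        ends = np.minimum(starts + cfg.bin_size_bp - 1, length)
        codes = np.full(len(starts), "missing", dtype=object)
        seg = by_chrom.get(chrom)
        if seg is not None:
            for s in seg.segments:
                if s.state not in STATES:
                    continue
                # bins fully inside [s.start, s.end]
                covered = (starts >= s.start) & (ends <= s.end)
                codes[covered] = s.state
        out.bins[chrom] = pd.DataFrame({"start": starts, "end": ends, "code": codes})
    return out


def export_rqtl(binned: Sequence[BinnedGenotypes], genome: GenomeSpec,
                path: str | Path, cm_per_mb: float = 3.0,
                phenotypes: Mapping[str, float] | None = None,
                header_comment: str | None = None) -> None:
    """Write R/qtl ``csv``-format genotypes (markers as columns).

    Header rows carry marker names (``chrom_binstart``), chromosome, and cM
    position approximated as Mb * ``cm_per_mb``; genotype codes are
    HH -> A, HL -> H, LL -> B, missing -> ``-``.  A constant phenotype stub
    is written unless real values are supplied.
    """
    ids = [b.individual for b in binned]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate individual ids in R/qtl export")
    if not binned:
        raise ValueError("nothing to export")
    ref = binned[0]
    marker_names, chroms, cms = [], [], []
    for chrom in genome.imputable:
        for start in ref.bins[chrom]["start"]:
            marker_names.append(f"{chrom}_{int(start)}")
            chroms.append(chrom)
            cms.append((int(start) - 1) / 1e6 * cm_per_mb)
    lines = []
    if header_comment:
        lines.append(f"# {header_comment}")
    lines.append(",".join(["id", "pheno"] + marker_names))
    lines.append(",".join(["", ""] + chroms))
    lines.append(",".join(["", ""] + [f"{c:.6g}" for c in cms]))
    phenotypes = phenotypes or {}
    for b in binned:
        codes = []
        for chrom in genome.imputable:
            codes.extend(RQTL_CODES[c] for c in b.bins[chrom]["code"])
        pheno = phenotypes.get(b.individual, 0.0)
        lines.append(",".join([b.individual, f"{pheno:g}"] + codes))
    Path(path).write_text("\n".join(lines) + "\n")


def read_rqtl(path: str | Path, genome: GenomeSpec,
              bin_size_bp: int = 1_000_000) -> list[BinnedGenotypes]:
    """Re-parse an R/qtl CSV written by :func:`export_rqtl`."""
    rows = [ln for ln in Path(path).read_text().splitlines() if not ln.startswith("#")]
    header = rows[0].split(",")
    chrom_row = rows[1].split(",")
    markers = header[2:]
    chroms = chrom_row[2:]
    out = []
    for line in rows[3:]:
        cells = line.split(",")
        ind = cells[0]
        codes = cells[2:]
        b = BinnedGenotypes(individual=ind)
        per_chrom: dict[str, list[tuple[int, str]]] = {}
        for name, chrom, code in zip(markers, chroms, codes):
            start = int(name.rsplit("_", 1)[1])
            per_chrom.setdefault(chrom, []).append((start, RQTL_DECODE[code]))
        for chrom, entries in per_chrom.items():
            entries.sort()
            starts = np.array([s for s, _ in entries], dtype=np.int64)
            ends = np.minimum(starts + bin_size_bp - 1, genome.length(chrom))
            b.bins[chrom] = pd.DataFrame(
                {"start": starts, "end": ends, "code": [c for _, c in entries]})
        out.append(b)
    return out


def breakpoint_resolution(segs: Iterable[MosaicSegmentation]) -> tuple[np.ndarray, dict]:
    """Distribution of breakpoint-interval lengths across a segment set.

    Returns the raw lengths and a summary with the median and quartiles;
    an empty input yields an empty summary.
    """
    lengths = np.array(sorted(bp.length for s in segs for bp in s.breakpoints),
                       dtype=np.int64)
    if len(lengths) == 0:
        return lengths, {"n": 0}
    summary = {
        "n": int(len(lengths)),
        "median": float(np.median(lengths)),
        "q25": float(np.quantile(lengths, 0.25)),
        "q75": float(np.quantile(lengths, 0.75)),
        "mean": float(np.mean(lengths)),
    }
    return lengths, summary


def write_segments_tsv(segs_by_individual: Mapping[str, Sequence[MosaicSegmentation]],
                       path: str | Path, header_comment: str | None = None) -> None:
    """Segment table: 1-based inclusive coordinates with breakpoint flanks."""
    rows = []
    for ind in sorted(segs_by_individual):
        for seg in segs_by_individual[ind]:
            bp_by_start = {s.start: bp for s, bp in zip(seg.segments[1:], seg.breakpoints)}
            for s in seg.segments:
                bp = bp_by_start.get(s.start)
                rows.append((ind, seg.chrom, s.start, s.end, s.state,
                             bp.left_bp if bp else "NA", bp.right_bp if bp else "NA"))
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        fh.write("individual\tchrom\tstart\tend\tstate\tleft_flank\tright_flank\n")
        for row in rows:
            fh.write("\t".join(str(x) for x in row) + "\n")


def write_segments_bed(segs_by_individual: Mapping[str, Sequence[MosaicSegmentation]],
                       path: str | Path) -> None:
    """BED export (0-based half-open)."""
    with open(path, "w") as fh:
        for ind in sorted(segs_by_individual):
            for seg in segs_by_individual[ind]:
                for s in seg.segments:
                    fh.write(f"{seg.chrom}\t{s.start - 1}\t{s.end}\t{ind}:{s.state}\n")
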