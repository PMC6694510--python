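"""Agreement between reconstructed genotypes and validation/truth sets.

Accuracy is reported as the proportion of genotypes in agreement per
individual (across loci) and per marker (across individuals), over the
*comparable* set: loci where both sources carry a decided HH/HL/LL code.
Validation loci falling in bins masked by inferred recombination are
excluded from the comparison, and the dropped count is reported.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .hmm import STATES, MosaicSegmentation
from .pedigree import GenomeSpec
from .qc import BinnedGenotypes, QCConfig, bin_genotypes

DECIDED = set(STATES)


@dataclass
class ValidationGenotypes:
    """External per-locus genotype codes: columns chrom pos individual code."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"chrom", "pos", "individual", "code"}
        if required - set(self.table.columns):
            raise ValueError(f"validation table needs columns {sorted(required)}")
        self.table = self.table.sort_values(["chrom", "pos"]).reset_index(drop=True)
        bad = set(self.table["code"]) - (DECIDED | {"missing"})
        if bad:
            raise ValueError(f"unknown validation codes: {sorted(bad)}")

    @classmethod
    def read_tsv(cls, path: str | Path) -> "ValidationGenotypes":
        return cls(pd.read_csv(path, sep="\t", comment="#", dtype={"chrom": str}))


@dataclass
class AgreementReport:
    per_individual: pd.DataFrame  # individual, n_comparable, agreement
    per_marker: pd.DataFrame  # chrom, pos, n_comparable, agreement
    n_dropped_masked: int

    @property
    def mean_individual_agreement(self) -> float:
        vals = self.per_individual["agreement"].dropna()
        return float(vals.mean()) if len(vals) else float("nan")

    @property
    def mean_marker_agreement(self) -> float:
        vals = self.per_marker["agreement"].dropna()
        return float(vals.mean()) if len(vals) else float("nan")

    def summary_text(self) -> str:
        lines = [
            "agreement summary",
            f"  individuals compared : {len(self.per_individual)}",
            f"  markers compared     : {len(self.per_marker)}",
            f"  loci dropped (masked): {self.n_dropped_masked}",
            f"  mean per-individual agreement: {self.mean_individual_agreement:.4f}",
            f"  mean per-marker agreement    : {self.mean_marker_agreement:.4f}",
        ]
        return "\n".join(lines)


def _bin_code(binned: BinnedGenotypes, chrom: str, pos: int,
              bin_size: int) -> str | None:
    if chrom not in binned.bins:
        return None
    df = binned.bins[chrom]
    i = (pos - 1) // bin_size
    if i >= len(df):
        return None
    return df["code"].iloc[i]


def agreement(binned: Mapping[str, BinnedGenotypes], validation: ValidationGenotypes,
              bin_size_bp: int = 1_000_000) -> AgreementReport:
    """Compare binned reconstructed genotypes against validation loci.

    Each validation locus is mapped into the bin containing it; a locus is
    comparable for an individual iff both the bin code and the validation
    code are decided.  Individuals with zero comparable loci report NaN
    agreement (undefined, not zero).
    """
    per_ind: dict[str, list[int]] = {}
    per_marker: dict[tuple[str, int], list[int]] = {}
    dropped = 0
    for row in validation.table.itertuples(index=False):
        ind = row.individual
        if ind not in binned:
            continue
        code = _bin_code(binned[ind], str(row.chrom), int(row.pos), bin_size_bp)
        if code is None or code not in DECIDED:
            dropped += 1
            continue
        if row.code not in DECIDED:
            continue
        match = int(code == row.code)
        per_ind.setdefault(ind, []).append(match)
        per_marker.setdefault((str(row.chrom), int(row.pos)), []).append(match)
    ind_rows = [{"individual": ind,
                 "n_comparable": len(m),
                 "agreement": (np.mean(m) if m else np.nan)}
                for ind, m in sorted(per_ind.items())]
    # individuals present in the reconstruction but with no comparable loci
    for ind in sorted(set(binned) - set(per_ind)):
        ind_rows.append({"individual": ind, "n_comparable": 0, "agreement": np.nan})
    marker_rows = [{"chrom": c, "pos": p, "n_comparable": len(m),
                    "agreement": float(np.mean(m))}
                   for (c, p), m in sorted(per_marker.items())]
    return AgreementReport(
        per_individual=pd.DataFrame(ind_rows,
                                    columns=["individual", "n_comparable", "agreement"]),
        per_marker=pd.DataFrame(marker_rows,
                                columns=["chrom", "pos", "n_comparable", "agreement"]),
        n_dropped_masked=dropped)


def truth_bins(truth_segments: Mapping[str, MosaicSegmentation], genome: GenomeSpec,
               cfg: QCConfig | None = None, individual: str = "truth") -> BinnedGenotypes:
    """Bin a ground-truth mosaic; bins containing true crossovers go missing."""
    return bin_genotypes(list(truth_segments.values()), genome, cfg, individual=individual)


@dataclass
class TruthAgreement:
    report: AgreementReport
    per_individual_bins: pd.DataFrame  # individual, n_comparable, agreement
    crossovers_in_interval: float  # fraction of true crossovers inside inferred intervals

    @property
    def mean_individual_agreement(self) -> float:
        vals = self.per_individual_bins["agreement"].dropna()
        return float(vals.mean()) if len(vals) else float("nan")


def truth_agreement(segs_by_individual: Mapping[str, Sequence[MosaicSegmentation]],
                    truth, genome: GenomeSpec, cfg: QCConfig | None = None
                    ) -> TruthAgreement:
    """Bin-level agreement of reconstructed mosaics with simulated truth.

    For every individual, both the reconstruction and the truth are binned;
    bins are comparable where both are decided (bins containing true or
    inferred crossovers, or UU overlap, are missing by construction).  Also
    reports the fraction of true crossovers that fall inside an inferred
    breakpoint interval on the same chromosome.
    """
    cfg = cfg or QCConfig()
    rows = []
    marker_rows: dict[tuple[str, int], list[int]] = {}
    n_true_co = 0
    n_contained = 0
    for ind in sorted(segs_by_individual):
        segs = segs_by_individual[ind]
        if ind not in truth:
            continue
        t = truth[ind]
        rec = bin_genotypes(segs, genome, cfg, individual=ind)
        tru = truth_bins(t.segments, genome, cfg, individual=ind)
        matches: list[int] = []
        for chrom in genome.imputable:
            rc = rec.codes(chrom)
            tc = tru.codes(chrom)
            comparable = np.array([(a in DECIDED) and (b in DECIDED)
                                   for a, b in zip(rc, tc)])
            eq = rc == tc
            matches.extend(eq[comparable].astype(int).tolist())
            starts = rec.bins[chrom]["start"].to_numpy()
            for s, ok, comp in zip(starts, eq, comparable):
                if comp:
                    marker_rows.setdefault((chrom, int(s)), []).append(int(ok))
        rows.append({"individual": ind, "n_comparable": len(matches),
                     "agreement": (float(np.mean(matches)) if matches else np.nan)})
        intervals = {chrom: [(bp.left_bp, bp.right_bp)
                             for s in segs if s.chrom == chrom for bp in s.breakpoints]
                     for chrom in genome.imputable}
        for chrom, cuts in t.crossovers.items():
            for c in cuts:
                n_true_co += 1
                if any(l <= c <= r for l, r in intervals.get(chrom, [])):
                    n_contained += 1
    per_ind = pd.DataFrame(rows, columns=["individual", "n_comparable", "agreement"])
    per_marker = pd.DataFrame(
        [{"chrom": c, "pos": p, "n_comparable": len(m), "agreement": float(np.mean(m))}
         for (c, p), m in sorted(marker_rows.items())],
        columns=["chrom", "pos", "n_comparable", "agreement"])
    report = AgreementReport(per_individual=per_ind, per_marker=per_marker,
                             n_dropped_masked=0)
    frac = (n_contained / n_true_co) if n_true_co else float("nan")
    return TruthAgreement(report=report, per_individual_bins=per_ind,
                          crossovers_in_interval=frac)
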