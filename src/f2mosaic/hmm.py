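"""Chromosome-specific HMM for founder-mosaic reconstruction.

The hidden state space is the three decided genotypes {HH, HL, LL} (line
origin of the two homologues).  Observation-level ambiguity is expressed by
the six-state alphabet {HH, HU, HL, LL, LU, UU}, where U marks read counts
compatible with more than one decided state; the U states are likelihood
statements about single sites and are never emitted in final segmentations.

Emissions are per-site binomials on the polarized counts ``(n_H, n_L)``:
each read supports the H line with probability 1-eps' under HH, 0.5+b under
HL and eps' under LL, where eps' folds the sequencing/mapping error with a
chromosome-level allele-ratio bias b estimated from sliding-window read
fractions.  Transitions between adjacent markers follow Haldane's map
function on the physical gap: with map distance d Morgans the per-gamete
recombination fraction is r = 0.5(1 - exp(-2d)); single-crossover moves
(HH<->HL, HL<->LL) have probability r and the double move HH<->LL has r^2.
Each chromosome gets its own parameter set (window statistics, bias,
transitions), which accommodates uneven chromosome lengths and marker
densities.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import binom

STATES = ("HH", "HL", "LL")
STATE_INDEX = {s: i for i, s in enumerate(STATES)}
OBS_STATES = ("HH", "HU", "HL", "LL", "LU", "UU")

# Mendelian prior for an F2 genotype.
INIT_PROBS = np.array([0.25, 0.5, 0.25])


@dataclass
class HMMConfig:
    """Tunable parameters of the reconstruction HMM.

    window_large / window_small
        Number of consecutive markers averaged per window when estimating
        chromosome-level read-ratio statistics, for large and small
        chromosomes respectively.
    small_chrom_marker_threshold
        A chromosome with fewer informative markers than this is treated as
        "small" (uses ``window_small``).
    recomb_rate_cm_per_mb
        Physical-to-genetic map rate used in Haldane transitions.
    seq_error
        Per-read probability that a read supports the wrong line at an
        informative marker (sequencing + mapping error).
    min_hom_reads
        Reads of a single line required to call a site-level homozygous
        observation state (below it, HU/LU).
    decode_mode
        ``viterbi`` (default, joint most probable path) or ``posterior``
        (per-marker max posterior).
    """

    window_large: int = 200
    window_small: int = 50
    small_chrom_marker_threshold: int = 2000
    recomb_rate_cm_per_mb: float = 3.0
    seq_error: float = 0.01
    min_hom_reads: int = 2
    decode_mode: str = "viterbi"

    def __post_init__(self) -> None:
        if self.window_large < 1 or self.window_small < 1:
            raise ValueError("window sizes must be >= 1")
        if not 0.0 < self.seq_error < 0.5:
            raise ValueError("seq_error must lie in (0, 0.5)")
        if self.min_hom_reads < 1:
            raise ValueError("min_hom_reads must be >= 1")
        if self.decode_mode not in ("viterbi", "posterior"):
            raise ValueError("decode_mode must be 'viterbi' or 'posterior'")


@dataclass(frozen=True)
class Segment:
    start: int
    end: int
    state: str  # HH / HL / LL / UU

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class BreakpointInterval:
    """Uncertainty interval of one inferred crossover.

    ``left_bp``/``right_bp`` are the positions of the last read-covered
    informative marker supporting the left-hand state and the first
    supporting the right-hand state.
    """

    chrom: str
    left_bp: int
    right_bp: int

    def __post_init__(self) -> None:
        if not self.left_bp < self.right_bp:
            raise ValueError("breakpoint interval requires left_bp < right_bp")

    @property
    def point_estimate(self) -> int:
        return (self.left_bp + self.right_bp) // 2

    @property
    def length(self) -> int:
        return self.right_bp - self.left_bp


@dataclass
class MosaicSegmentation:
    """Ordered founder-origin segments tiling one chromosome."""

    individual: str
    chrom: str
    chrom_length: int
    segments: list[Segment]
    breakpoints: list[BreakpointInterval] = field(default_factory=list)

    def validate(self) -> None:
        if not self.segments:
            raise ValueError("segmentation must contain at least one segment")
        if self.segments[0].start != 1 or self.segments[-1].end != self.chrom_length:
            raise ValueError("segments must tile [1, chrom_length]")
        for a, b in zip(self.segments, self.segments[1:]):
            if b.start != a.end + 1:
                raise ValueError("segments must be contiguous")
            if b.state == a.state:
                raise ValueError("adjacent segments must differ in state")

    def decided_length(self) -> int:
        return sum(s.length for s in self.segments if s.state in STATES)

    def state_at(self, pos: int) -> str:
        for s in self.segments:
            if s.start <= pos <= s.end:
                return s.state
        raise ValueError(f"position {pos} outside chromosome")


def translate_state(n_h: int, n_l: int, cfg: HMMConfig | None = None) -> str:
    """Six-state observation alphabet for a single site's read counts."""
    k = (cfg or HMMConfig()).min_hom_reads
    if n_h == 0 and n_l == 0:
        return "UU"
    if n_h >= 1 and n_l >= 1:
        return "HL"
    if n_l == 0:
        return "HH" if n_h >= k else "HU"
    return "LL" if n_l >= k else "LU"


def translate_states(n_h: np.ndarray, n_l: np.ndarray, cfg: HMMConfig | None = None) -> np.ndarray:
    """Vectorized :func:`translate_state`; returns an array of state strings."""
    k = (cfg or HMMConfig()).min_hom_reads
    n_h = np.asarray(n_h)
    n_l = np.asarray(n_l)
    out = np.full(n_h.shape, "UU", dtype="<U2")
    out[(n_h >= 1) & (n_l >= 1)] = "HL"
    out[(n_h >= 1) & (n_h < k) & (n_l == 0)] = "HU"
    out[(n_h >= k) & (n_l == 0)] = "HH"
    out[(n_l >= 1) & (n_l < k) & (n_h == 0)] = "LU"
    out[(n_l >= k) & (n_h == 0)] = "LL"
    return out


def window_ratios(positions: np.ndarray, n_h: np.ndarray, n_l: np.ndarray,
                  window: int) -> pd.DataFrame:
    """Non-overlapping windows of ``window`` consecutive markers.

    Returns per-window H-read fraction ``f`` and read totals; the trailing
    partial window is merged into the previous one.  A chromosome with fewer
    markers than one window becomes a single whole-chromosome window (with a
    warning).
    """
    n = len(positions)
    if n == 0:
        return pd.DataFrame(columns=["start_idx", "end_idx", "start_pos", "end_pos",
                                     "n_h", "n_l", "depth", "f", "zero_reads"])
    if n < window:
        warnings.warn(f"chromosome has {n} markers (< window {window}); "
                      "using one whole-chromosome window")
        edges = [0, n]
    else:
        n_windows = n // window
        edges = [i * window for i in range(n_windows)] + [n]
    rows = []
    for a, b in zip(edges, edges[1:]):
        wh = int(np.sum(n_h[a:b]))
        wl = int(np.sum(n_l[a:b]))
        depth = wh + wl
        rows.append({
            "start_idx": a, "end_idx": b - 1,
            "start_pos": int(positions[a]), "end_pos": int(positions[b - 1]),
            "n_h": wh, "n_l": wl, "depth": depth,
            "f": (wh / depth) if depth > 0 else np.nan,
            "zero_reads": depth == 0,
        })
    return pd.DataFrame(rows)


def estimate_bias(windows: pd.DataFrame, het_band: tuple[float, float] = (0.25, 0.75),
                  max_bias: float = 0.2) -> float:
    """Chromosome-level allele-ratio bias from putatively heterozygous windows.

    Windows with H-read fraction inside ``het_band`` are treated as coming
    from heterozygous regions; the bias b is the median deviation of their
    fractions from 0.5, clipped to ``[-max_bias, max_bias]``.
    """
    if windows.empty:
        return 0.0
    f = windows.loc[(~windows["zero_reads"]) &
                    (windows["f"] >= het_band[0]) & (windows["f"] <= het_band[1]), "f"]
    if f.empty:
        return 0.0
    return float(np.clip(np.median(f) - 0.5, -max_bias, max_bias))


def adjusted_read_probs(seq_error: float, bias: float) -> np.ndarray:
    """Per-read P(H-supporting read | state) for (HH, HL, LL).

    The bias is applied as a uniform shift on the log-odds scale chosen so
    that the heterozygous state lands exactly at 0.5 + b; probabilities of 0
    or 1 (the noiseless limit) are left untouched.
    """
    base = np.array([1.0 - seq_error, 0.5, seq_error])
    if bias == 0.0:
        return base
    beta = math.log(0.5 + bias) - math.log(0.5 - bias)
    out = base.copy()
    interior = (base > 0.0) & (base < 1.0)
    logit = np.log(base[interior]) - np.log1p(-base[interior])
    out[interior] = 1.0 / (1.0 + np.exp(-(logit + beta)))
    return out


def emission_log_likelihood(n_h: np.ndarray, n_l: np.ndarray, p_h: np.ndarray) -> np.ndarray:
    """Binomial log emission matrix, shape (n_sites, 3).

    ``p_h`` gives the per-read H probability for each hidden state; sites
    with no reads emit log-probability 0 under every state.
    """
    n_h = np.asarray(n_h, dtype=np.int64)
    n_l = np.asarray(n_l, dtype=np.int64)
    n = n_h + n_l
    cols = [binom.logpmf(n_h, n, p) for p in p_h]
    return np.column_stack(cols)


def haldane_r(d_bp: np.ndarray, rate_cm_per_mb: float) -> np.ndarray:
    """Recombination fraction across a physical gap via Haldane's map function."""
    morgans = np.asarray(d_bp, dtype=float) * rate_cm_per_mb / 1e8
    return 0.5 * (1.0 - np.exp(-2.0 * morgans))


def transition_matrices(r: np.ndarray) -> np.ndarray:
    """Stack of 3x3 transition matrices, one per adjacent-marker gap.

    Single-crossover moves have probability r, the two-crossover move
    HH<->LL has r^2, and self-transitions take the remaining mass.
    """
    r = np.asarray(r, dtype=float)
    t = np.empty((len(r), 3, 3))
    t[:, 0, 0] = 1.0 - r - r ** 2
    t[:, 0, 1] = r
    t[:, 0, 2] = r ** 2
    t[:, 1, 0] = r
    t[:, 1, 1] = 1.0 - 2.0 * r
    t[:, 1, 2] = r
    t[:, 2, 0] = r ** 2
    t[:, 2, 1] = r
    t[:, 2, 2] = 1.0 - r - r ** 2
    return t


class ChromosomeHMM:
    """One chromosome's HMM bound to one individual's observations."""

    def __init__(self, chrom: str, chrom_length: int, positions: np.ndarray,
                 n_h: np.ndarray, n_l: np.ndarray, cfg: HMMConfig,
                 p_h: np.ndarray, bias: float, windows: pd.DataFrame) -> None:
        self.chrom = chrom
        self.chrom_length = int(chrom_length)
        self.positions = np.asarray(positions, dtype=np.int64)
        self.n_h = np.asarray(n_h, dtype=np.int64)
        self.n_l = np.asarray(n_l, dtype=np.int64)
        self.cfg = cfg
        self.p_h = np.asarray(p_h, dtype=float)
        self.bias = float(bias)
        self.windows = windows
        self.log_init = np.log(INIT_PROBS)
        self.log_emit = emission_log_likelihood(self.n_h, self.n_l, self.p_h)
        if len(self.positions) > 1:
            gaps = np.diff(self.positions)
            r = haldane_r(gaps, cfg.recomb_rate_cm_per_mb)
            with np.errstate(divide="ignore"):
                self.log_trans = np.log(transition_matrices(r))
        else:
            self.log_trans = np.empty((0, 3, 3))

    @property
    def n_markers(self) -> int:
        return len(self.positions)

    # -- likelihood ------------------------------------------------------

    def forward_loglik(self) -> float:
        """Total log-likelihood of the observations (forward algorithm)."""
        if self.n_markers == 0:
            return 0.0
        em = self.log_emit
        v = self.log_init + em[0]
        lt = self.log_trans
        for t in range(1, self.n_markers):
            step = lt[t - 1]
            v = em[t] + _logsumexp3_cols(v, step)
        m = float(np.max(v))
        return m + math.log(float(np.sum(np.exp(v - m))))

    # -- decoding --------------------------------------------------------

    def viterbi(self) -> np.ndarray:
        """Most probable joint state path (indices into STATES).

        Ties are broken toward the state of the preceding marker, which
        favors paths with fewer crossovers.
        """
        n = self.n_markers
        if n == 0:
            return np.empty(0, dtype=np.int8)
        em = self.log_emit.tolist()
        lt = self.log_trans.reshape(-1, 9).tolist()
        v0, v1, v2 = (self.log_init + self.log_emit[0]).tolist()
        back = np.empty((n, 3), dtype=np.int8)
        for t in range(1, n):
            a00, a01, a02, a10, a11, a12, a20, a21, a22 = lt[t - 1]
            e0, e1, e2 = em[t]
            # into HH: prefer staying in HH on ties
            c0, c1, c2 = v0 + a00, v1 + a10, v2 + a20
            if c0 >= c1 and c0 >= c2:
                b0, m0 = 0, c0
            elif c1 >= c2:
                b0, m0 = 1, c1
            else:
                b0, m0 = 2, c2
            # into HL: prefer staying in HL
            c0, c1, c2 = v0 + a01, v1 + a11, v2 + a21
            if c1 >= c0 and c1 >= c2:
                b1, m1 = 1, c1
            elif c0 >= c2:
                b1, m1 = 0, c0
            else:
                b1, m1 = 2, c2
            # into LL: prefer staying in LL
            c0, c1, c2 = v0 + a02, v1 + a12, v2 + a22
            if c2 >= c0 and c2 >= c1:
                b2, m2 = 2, c2
            elif c0 >= c1:
                b2, m2 = 0, c0
            else:
                b2, m2 = 1, c1
            back[t, 0], back[t, 1], back[t, 2] = b0, b1, b2
            v0, v1, v2 = m0 + e0, m1 + e1, m2 + e2
        path = np.empty(n, dtype=np.int8)
        if v0 >= v1 and v0 >= v2:
            path[-1] = 0
        elif v1 >= v2:
            path[-1] = 1
        else:
            path[-1] = 2
        for t in range(n - 1, 0, -1):
            path[t - 1] = back[t, path[t]]
        return path

    def posterior(self) -> np.ndarray:
        """Posterior state probabilities, shape (n_markers, 3)."""
        n = self.n_markers
        if n == 0:
            return np.empty((0, 3))
        log_a = np.empty((n, 3))
        log_a[0] = self.log_init + self.log_emit[0]
        for t in range(1, n):
            log_a[t] = self.log_emit[t] + _logsumexp3_cols(log_a[t - 1], self.log_trans[t - 1])
        log_b = np.zeros((n, 3))
        for t in range(n - 2, -1, -1):
            log_b[t] = _logsumexp3_rows(self.log_trans[t], self.log_emit[t + 1] + log_b[t + 1])
        lg = log_a + log_b
        lg -= lg.max(axis=1, keepdims=True)
        g = np.exp(lg)
        g /= g.sum(axis=1, keepdims=True)
        return g

    def decode_states(self) -> np.ndarray:
        if self.cfg.decode_mode == "posterior":
            return np.argmax(self.posterior(), axis=1).astype(np.int8)
        return self.viterbi()


def _logsumexp3_cols(v: np.ndarray, logt: np.ndarray) -> np.ndarray:
    """logsumexp over previous states: out[j] = LSE_i(v[i] + logt[i, j])."""
    x = v[:, None] + logt
    m = x.max(axis=0)
    out = m + np.log(np.exp(x - m).sum(axis=0))
    return np.where(np.isfinite(m), out, -np.inf)


def _logsumexp3_rows(logt: np.ndarray, w: np.ndarray) -> np.ndarray:
    """logsumexp over next states: out[i] = LSE_j(logt[i, j] + w[j])."""
    x = logt + w[None, :]
    m = x.max(axis=1)
    out = m + np.log(np.exp(x - m[:, None]).sum(axis=1))
    return np.where(np.isfinite(m), out, -np.inf)


def build_hmm(chrom: str, chrom_length: int, positions: np.ndarray,
              n_h: np.ndarray, n_l: np.ndarray, cfg: HMMConfig | None = None,
              size_class: str | None = None) -> ChromosomeHMM:
    """Estimate chromosome-specific parameters and assemble the HMM.

    Window statistics over 200 (large chromosomes) or 50 (small
    chromosomes) consecutive markers provide the allele-ratio bias folded
    into the emissions; transitions use the configured cM/Mb rate.
    """
    cfg = cfg or HMMConfig()
    positions = np.asarray(positions, dtype=np.int64)
    if len(positions) and np.any(np.diff(positions) <= 0):
        raise ValueError("marker positions must be strictly increasing")
    if size_class is None:
        size_class = ("small" if len(positions) < cfg.small_chrom_marker_threshold
                      else "large")
    window = cfg.window_small if size_class == "small" else cfg.window_large
    if len(positions) == 0:
        warnings.warn(f"chromosome {chrom}: no informative markers; "
                      "segmentation will be a single UU segment")
        windows = window_ratios(positions, np.asarray(n_h), np.asarray(n_l), window)
        return ChromosomeHMM(chrom, chrom_length, positions, n_h, n_l, cfg,
                             adjusted_read_probs(cfg.seq_error, 0.0), 0.0, windows)
    windows = window_ratios(positions, np.asarray(n_h), np.asarray(n_l), window)
    bias = estimate_bias(windows)
    p_h = adjusted_read_probs(cfg.seq_error, bias)
    return ChromosomeHMM(chrom, chrom_length, positions, n_h, n_l, cfg, p_h, bias, windows)


def decode(hmm: ChromosomeHMM, individual: str) -> MosaicSegmentation:
    """Decode the mosaic and build the segmentation with breakpoints.

    Consecutive identical marker states are merged into segments; each
    boundary is placed at the midpoint of its breakpoint interval (the gap
    between the flanking read-covered markers), and chromosome ends are
    extended to [1, length].  A chromosome without any reads yields a
    single UU segment.
    """
    n = hmm.n_markers
    if n == 0 or int(hmm.n_h.sum() + hmm.n_l.sum()) == 0:
        return MosaicSegmentation(
            individual=individual, chrom=hmm.chrom, chrom_length=hmm.chrom_length,
            segments=[Segment(1, hmm.chrom_length, "UU")], breakpoints=[])
    states = hmm.decode_states()
    covered = (hmm.n_h + hmm.n_l) > 0
    pos = hmm.positions
    change = np.nonzero(np.diff(states))[0]  # boundary between i and i+1
    segments: list[Segment] = []
    breakpoints: list[BreakpointInterval] = []
    prev_end = 0
    run_start_idx = 0
    for i in change:
        left_cov = np.nonzero(covered[: i + 1])[0]
        right_cov = np.nonzero(covered[i + 1:])[0]
        left_bp = int(pos[left_cov[-1]]) if len(left_cov) else 1
        right_bp = int(pos[i + 1 + right_cov[0]]) if len(right_cov) else hmm.chrom_length
        if right_bp <= left_bp:  # degenerate; fall back to the marker gap
            left_bp, right_bp = int(pos[i]), int(pos[i + 1])
        cut = (left_bp + right_bp) // 2
        cut = max(cut, prev_end + 1)  # keep boundaries strictly ordered
        cut = min(cut, hmm.chrom_length - 1)
        segments.append(Segment(prev_end + 1, cut, STATES[states[run_start_idx]]))
        breakpoints.append(BreakpointInterval(hmm.chrom, left_bp, right_bp))
        prev_end = cut
        run_start_idx = i + 1
    segments.append(Segment(prev_end + 1, hmm.chrom_length, STATES[states[run_start_idx]]))
    # merge adjacent equal states created by boundary clamping, dropping the
    # breakpoint of each removed boundary so segments/breakpoints stay paired
    merged: list[Segment] = []
    kept_bp: list[BreakpointInterval] = []
    for j, seg in enumerate(segments):
        if merged and merged[-1].state == seg.state:
            merged[-1] = Segment(merged[-1].start, seg.end, seg.state)
        else:
            merged.append(seg)
            if j > 0:
                kept_bp.append(breakpoints[j - 1])
    out = MosaicSegmentation(individual=individual, chrom=hmm.chrom,
                             chrom_length=hmm.chrom_length, segments=merged,
                             breakpoints=kept_bp)
    out.validate()
    return out


def reconstruct_chromosome(individual: str, chrom: str, chrom_length: int,
                           positions: np.ndarray, n_h: np.ndarray, n_l: np.ndarray,
                           cfg: HMMConfig | None = None,
                           size_class: str | None = None) -> MosaicSegmentation:
    """Convenience wrapper: build the chromosome HMM and decode it."""
    hmm = build_hmm(chrom, chrom_length, positions, n_h, n_l, cfg, size_class)
    return decode(hmm, individual)
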