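"""Independent brute-force oracles shared across test modules."""

import itertools

import numpy as np


def enumerate_paths_loglik(hmm) -> float:
    """Total likelihood by exhaustive summation over all 3^n state paths."""
    n = hmm.n_markers
    paths = np.array(list(itertools.product(range(3), repeat=n)), dtype=np.int8)
    lp = hmm.log_init[paths[:, 0]] + hmm.log_emit[0][paths[:, 0]]
    for t in range(1, n):
        lp = lp + hmm.log_trans[t - 1][paths[:, t - 1], paths[:, t]]
        lp = lp + hmm.log_emit[t][paths[:, t]]
    m = lp.max()
    return float(m + np.log(np.exp(lp - m).sum()))


def enumerate_best_path(hmm):
    """(argmax path, max log-prob) by exhaustive enumeration."""
    n = hmm.n_markers
    paths = np.array(list(itertools.product(range(3), repeat=n)), dtype=np.int8)
    lp = hmm.log_init[paths[:, 0]] + hmm.log_emit[0][paths[:, 0]]
    for t in range(1, n):
        lp = lp + hmm.log_trans[t - 1][paths[:, t - 1], paths[:, t]]
        lp = lp + hmm.log_emit[t][paths[:, t]]
    best = int(np.argmax(lp))
    return paths[best], float(lp[best])


def path_logprob(hmm, path) -> float:
    lp = hmm.log_init[path[0]] + hmm.log_emit[0][path[0]]
    for t in range(1, len(path)):
        lp += hmm.log_trans[t - 1][path[t - 1], path[t]] + hmm.log_emit[t][path[t]]
    return float(lp)


def random_hmm_instance(rng, max_markers=12):
    """A small random chromosome HMM with irregular spacing and counts."""
    from f2mosaic.hmm import HMMConfig, build_hmm

    n = int(rng.integers(2, max_markers + 1))
    length = 10_000_000
    positions = np.sort(rng.choice(np.arange(1, length), size=n, replace=False))
    n_reads = rng.poisson(1.0, size=n)
    n_h = rng.binomial(n_reads, rng.uniform(0.1, 0.9))
    n_l = n_reads - n_h
    cfg = HMMConfig(seq_error=float(rng.uniform(0.001, 0.2)),
                    recomb_rate_cm_per_mb=float(rng.uniform(0.5, 20.0)))
    return build_hmm("chr1", length, positions, n_h, n_l, cfg)
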