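"""Shared test utilities, including the exhaustive Viterbi oracle."""

from __future__ import annotations

import numpy as np
import pandas as pd

from seqcnv.hmm import HMMParams
from seqcnv.evaluate import BedCNV


def exhaustive_decode(E: np.ndarray, params: HMMParams) -> tuple[np.ndarray, float]:
    """Best state path by enumerating all k^n paths.

    Keeps the score of every path (progressive expansion), so it is an
    oracle independent of the dynamic-programming recursion it checks.
    """
    n, k = E.shape
    with np.errstate(divide="ignore"):
        logA = np.log(params.transition_matrix())
        logpi = np.log(params.initial_distribution())
    scores = logpi + E[0]  # index = path encoded in base k, most recent digit last
    for t in range(1, n):
        last = np.arange(len(scores)) % k
        scores = (scores[:, None] + logA[last, :] + E[t][None, :]).reshape(-1)
    best_idx = int(np.argmax(scores))
    path = np.empty(n, dtype=np.int64)
    for t in range(n - 1, -1, -1):
        path[t] = best_idx % k
        best_idx //= k
    return path, float(np.max(scores))


def emissions_frame(lrr, baf=None, pop_freq=None, depth=None, chrom="chr1", spacing=100):
    """Build a minimal marker table from per-marker signal arrays."""
    lrr = np.asarray(lrr, dtype=float)
    n = len(lrr)
    baf = np.full(n, 2.0) if baf is None else np.asarray(baf, dtype=float)
    pf = np.full(n, np.nan) if pop_freq is None else np.asarray(pop_freq, dtype=float)
    d = np.full(n, np.nan) if depth is None else np.asarray(depth, dtype=float)
    pos = 1 + spacing * np.arange(n)
    return pd.DataFrame(
        {
            "chrom": chrom,
            "start": pos,
            "end": pos,
            "kind": np.where(baf == 2.0, "interval", "snv"),
            "lrr": lrr,
            "baf": baf,
            "depth": d,
            "pop_freq": pf,
        }
    )


def truth_to_bed(truth) -> list[BedCNV]:
    return [
        BedCNV(
            chrom=t.chrom,
            start=t.start - 1,
            end=t.end,
            copy_number=t.copy_number,
            is_loh=t.is_loh,
        )
        for t in truth
    ]


def draw_state_emissions(state: str, n: int, rng: np.random.Generator, params: HMMParams,
                         snv_frac: float = 0.5, pop_freq: float = 0.5):
    """Draw (lrr, baf, pop_freq) arrays from one state's emission model."""
    from seqcnv.hmm import _baf_cluster_centers, _baf_cluster_logweights

    lrr = rng.normal(params.lrr_mean[state], params.lrr_sd[state], n)
    baf = np.full(n, 2.0)
    pf = np.full(n, np.nan)
    centers = _baf_cluster_centers(state)
    for i in np.flatnonzero(rng.random(n) < snv_frac):
        if centers is None:
            baf[i] = rng.random()
        else:
            w = _baf_cluster_logweights(state, np.array([pop_freq]))[0]
            c = centers[rng.choice(len(centers), p=w / w.sum())]
            baf[i] = float(np.clip(rng.normal(c, params.baf_het_sd), 0.0, 1.0))
        pf[i] = pop_freq
    return lrr, baf, pf
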