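"""Six-state hidden Markov model for copy-number decoding.

States are ordered ``CN0, CN1, CN2, LOH, CN3, CN4`` with copy numbers
0, 1, 2, 2, 3, 4.  The copy-neutral LOH state shares the diploid LRR
emission but admits only homozygous BAF clusters, which is what lets
the decoder separate a two-copy uniparental region from ordinary
diploid sequence.

Emissions factorize per marker into an LRR term and a BAF term:

* LRR: a Gaussian per state (means/SDs calibrated for ~20X sequencing
  coverage), robustified by a small uniform outlier component so no
  observation has -inf log-likelihood.
* BAF: a genotype-cluster mixture of truncated Gaussians.  Cluster
  centers are the possible alternate-allele fractions of the state's
  allele composition (e.g. 0, 1/3, 2/3, 1 for three copies); weights
  follow Hardy-Weinberg given the marker's population allele frequency,
  or are uniform when no frequency is attached.  The sentinel BAF value
  2 contributes nothing (log-likelihood 0).

Decoding is exact Viterbi in log space with deterministic tie-breaking
toward the lower state index; maximal runs of non-diploid states become
CNV/LOH calls.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence, TextIO

import numpy as np
import pandas as pd
from scipy.special import ndtr

from .signal import NO_BAF, SignalTrack

STATES = ("CN0", "CN1", "CN2", "LOH", "CN3", "CN4")
STATE_INDEX = {s: i for i, s in enumerate(STATES)}
COPY_NUMBER = {"CN0": 0, "CN1": 1, "CN2": 2, "LOH": 2, "CN3": 3, "CN4": 4}
_CN2 = STATE_INDEX["CN2"]

#: number of allele copies whose composition defines the BAF clusters
_N_ALLELES = {"CN0": 0, "CN1": 1, "CN2": 2, "LOH": 2, "CN3": 3, "CN4": 4}

_LRR_OUTLIER_DENSITY = 1.0 / 8.0  # uniform over the plausible LRR range [-6, 2]


class HMMError(ValueError):
    pass


@dataclass
class HMMParams:
    """State space, emission and transition parameters of the CNV HMM.

    The default LRR means and standard deviations are the sequencing
    calibration for ~20X coverage; the diploid state is sticky
    (self-probability 0.999) while CNV states revert more readily
    (0.89).  LOH shares the diploid LRR emission and stickiness.
    """

    lrr_mean: dict[str, float] = field(
        default_factory=lambda: {
            "CN0": -3.739099,
            "CN1": -0.727964,
            "CN2": 0.0,
            "LOH": 0.0,
            "CN3": 0.395454,
            "CN4": 0.658622,
        }
    )
    lrr_sd: dict[str, float] = field(
        default_factory=lambda: {
            "CN0": 2.56,
            "CN1": 0.3,
            "CN2": 0.16,
            "LOH": 0.16,
            "CN3": 0.127,
            "CN4": 0.124,
        }
    )
    self_prob: dict[str, float] = field(
        default_factory=lambda: {
            "CN0": 0.89,
            "CN1": 0.89,
            "CN2": 0.999,
            "LOH": 0.999,
            "CN3": 0.89,
            "CN4": 0.89,
        }
    )
    baf_het_sd: float = 0.05
    outlier_frac: float = 0.01
    cn2_revert_frac: float = 0.9  # share of off-diagonal mass that returns to CN2
    initial_cn2_prob: float = 0.995

    def __post_init__(self) -> None:
        for s in STATES:
            if s not in self.lrr_mean or s not in self.lrr_sd or s not in self.self_prob:
                raise HMMError(f"missing parameters for state {s}")
            if not self.lrr_sd[s] > 0:
                raise HMMError(f"non-positive LRR sd for state {s}")
            if not 0 < self.self_prob[s] < 1:
                raise HMMError(f"self probability for {s} must be in (0,1)")
        means = [self.lrr_mean[s] for s in ("CN0", "CN1", "CN2", "CN3", "CN4")]
        if any(a >= b for a, b in zip(means, means[1:])):
            raise HMMError("LRR means must increase strictly with copy number")
        if self.lrr_mean["LOH"] != self.lrr_mean["CN2"] or self.lrr_sd["LOH"] != self.lrr_sd["CN2"]:
            raise HMMError("LOH must share the CN2 LRR emission")
        if not self.baf_het_sd > 0:
            raise HMMError("baf_het_sd must be positive")
        if not 0 <= self.outlier_frac < 1:
            raise HMMError("outlier_frac must be in [0,1)")

    def transition_matrix(self) -> np.ndarray:
        """Row-stochastic 6x6 transition matrix.

        Off-diagonal mass from a non-diploid state goes 90% to CN2 and
        the remainder uniformly to the other states; from CN2 it is
        split uniformly over the five non-diploid states.
        """
        k = len(STATES)
        A = np.zeros((k, k))
        for i, s in enumerate(STATES):
            sp = self.self_prob[s]
            A[i, i] = sp
            off = 1.0 - sp
            if i == _CN2:
                others = [j for j in range(k) if j != i]
                A[i, others] = off / len(others)
            else:
                A[i, _CN2] = self.cn2_revert_frac * off
                rest = [j for j in range(k) if j not in (i, _CN2)]
                A[i, rest] = (1.0 - self.cn2_revert_frac) * off / len(rest)
        return A

    def initial_distribution(self) -> np.ndarray:
        pi = np.full(len(STATES), (1.0 - self.initial_cn2_prob) / (len(STATES) - 1))
        pi[_CN2] = self.initial_cn2_prob
        return pi


@dataclass
class StatePath:
    """Decoded per-marker state sequence for one chromosome."""

    states: np.ndarray  # int indices into STATES
    loglik: float

    @property
    def labels(self) -> list[str]:
        return [STATES[i] for i in self.states]

    def __len__(self) -> int:
        return len(self.states)


@dataclass
class CNVCall:
    """A decoded non-diploid segment spanning its first to last marker."""

    chrom: str
    start: int  # 1-based inclusive
    end: int
    state: str
    copy_number: int
    n_markers: int
    confidence: float  # emission log-lik margin of the called state over CN2

    @property
    def is_loh(self) -> bool:
        return self.state == "LOH"

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class RegionLikelihood:
    """Emission log-likelihood of a region under the five copy-number hypotheses."""

    chrom: str
    start: int
    end: int
    loglik: dict[int, float]
    best: int
    n_markers: int


# ---------------------------------------------------------------------------
# emissions
# ---------------------------------------------------------------------------


def _check_state(state: str) -> None:
    if state not in STATE_INDEX:
        raise HMMError(f"unknown state {state!r}; expected one of {STATES}")


def _lrr_loglik_vec(state: str, lrr: np.ndarray, params: HMMParams) -> np.ndarray:
    mu = params.lrr_mean[state]
    sd = params.lrr_sd[state]
    log_gauss = -0.5 * ((lrr - mu) / sd) ** 2 - math.log(sd * math.sqrt(2 * math.pi))
    of = params.outlier_frac
    if of == 0:
        return log_gauss
    with np.errstate(divide="ignore"):
        return np.logaddexp(
            math.log1p(-of) + log_gauss,
            math.log(of * _LRR_OUTLIER_DENSITY) * np.ones_like(log_gauss),
        )


def lrr_loglik(state: str, lrr: float, params: HMMParams | None = None) -> float:
    """Log density of one LRR value under a state's robustified Gaussian."""
    params = params or HMMParams()
    _check_state(state)
    return float(_lrr_loglik_vec(state, np.asarray([float(lrr)]), params)[0])


def _baf_cluster_centers(state: str) -> np.ndarray | None:
    """Cluster centers (possible alt-allele fractions), or None for the
    uniform zero-copy model."""
    n = _N_ALLELES[state]
    if n == 0:
        return None
    if state == "LOH":
        return np.array([0.0, 1.0])
    return np.arange(n + 1) / n


def _baf_cluster_logweights(state: str, pop_freq: np.ndarray) -> np.ndarray:
    """Hardy-Weinberg cluster weights, shape (n_markers, n_clusters).

    NaN pop_freq rows get uniform weights.  For LOH the two copies are
    one parental allele duplicated, so weights are (1-p, p).
    """
    centers = _baf_cluster_centers(state)
    assert centers is not None
    k = len(centers)
    p = np.clip(pop_freq, 0.0, 1.0)
    w = np.empty((len(p), k))
    nan = np.isnan(p)
    if state == "LOH":
        w[:, 0] = 1.0 - p
        w[:, 1] = p
    else:
        n = _N_ALLELES[state]
        for j in range(k):
            w[:, j] = math.comb(n, j) * p**j * (1.0 - p) ** (n - j)
    w[nan] = 1.0 / k
    return w


def _baf_loglik_vec(
    state: str,
    baf: np.ndarray,
    pop_freq: np.ndarray,
    params: HMMParams,
    depth: np.ndarray | None = None,
) -> np.ndarray:
    out = np.zeros_like(baf, dtype=float)
    mask = baf != NO_BAF
    if not np.any(mask):
        return out
    x = baf[mask]
    if np.any((x < 0) | (x > 1)):
        raise HMMError("BAF values must lie in [0,1] or equal the sentinel 2")
    centers = _baf_cluster_centers(state)
    if centers is None:  # zero-copy: any allele fraction equally (un)informative
        return out
    weights = _baf_cluster_logweights(state, pop_freq[mask])
    d = depth[mask] if depth is not None else None
    density = np.zeros_like(x)
    for j, c in enumerate(centers):
        # cluster spread follows the binomial read-sampling model,
        # floored at the array-style minimum baf_het_sd; markers without
        # depth information keep the floor
        if d is None or c in (0.0, 1.0):
            s = np.full_like(x, params.baf_het_sd)
        else:
            s = np.where(
                np.isnan(d) | (d < 1),
                params.baf_het_sd,
                np.maximum(params.baf_het_sd, np.sqrt(c * (1.0 - c) / np.maximum(d, 1.0))),
            )
        z = ndtr((1.0 - c) / s) - ndtr((0.0 - c) / s)  # truncation to [0,1]
        phi = np.exp(-0.5 * ((x - c) / s) ** 2) / (s * math.sqrt(2 * math.pi))
        density += weights[:, j] * phi / z
    of = params.outlier_frac
    density = (1.0 - of) * density + of * 1.0  # uniform floor on [0,1]
    out[mask] = np.log(density)
    return out


def baf_loglik(
    state: str,
    baf: float,
    pop_freq: float | None = None,
    params: HMMParams | None = None,
    depth: float | None = None,
) -> float:
    """Log density of one BAF value under a state's genotype-cluster mixture.

    The sentinel value 2 carries no information and returns 0.  When the
    marker's read depth is given, heterozygous cluster spreads widen to
    the binomial sampling scale sqrt(c(1-c)/depth).
    """
    params = params or HMMParams()
    _check_state(state)
    pf = math.nan if pop_freq is None else float(pop_freq)
    d = None if depth is None else np.asarray([float(depth)])
    return float(
        _baf_loglik_vec(state, np.asarray([float(baf)]), np.asarray([pf]), params, d)[0]
    )


def emission_matrix(markers: pd.DataFrame, params: HMMParams) -> np.ndarray:
    """Per-marker, per-state emission log-likelihoods, shape (n, 6)."""
    lrr = markers["lrr"].to_numpy(dtype=float)
    baf = markers["baf"].to_numpy(dtype=float)
    if "pop_freq" in markers.columns:
        pf = markers["pop_freq"].to_numpy(dtype=float)
    else:
        pf = np.full(len(markers), np.nan)
    depth = markers["depth"].to_numpy(dtype=float) if "depth" in markers.columns else None
    E = np.empty((len(markers), len(STATES)))
    for j, state in enumerate(STATES):
        E[:, j] = _lrr_loglik_vec(state, lrr, params) + _baf_loglik_vec(
            state, baf, pf, params, depth
        )
    return E


# ---------------------------------------------------------------------------
# Viterbi decoding
# ---------------------------------------------------------------------------


def _viterbi_core_py(logA: np.ndarray, logpi: np.ndarray, E: np.ndarray):
    n, k = E.shape
    delta = logpi + E[0]
    psi = np.zeros((n, k), dtype=np.int32)
    for t in range(1, n):
        new = np.empty(k)
        for j in range(k):
            best = -np.inf
            arg = 0
            for i in range(k):
                v = delta[i] + logA[i, j]
                if v > best:  # strict: ties resolve to the lower previous index
                    best = v
                    arg = i
            new[j] = best + E[t, j]
            psi[t, j] = arg
        delta = new
    last = 0
    best = delta[0]
    for j in range(1, k):
        if delta[j] > best:
            best = delta[j]
            last = j
    path = np.empty(n, dtype=np.int32)
    path[n - 1] = last
    for t in range(n - 2, -1, -1):
        path[t] = psi[t + 1, path[t + 1]]
    return path, best


try:  # pragma: no cover - exercised implicitly
    from numba import njit

    _viterbi_core = njit(cache=False)(_viterbi_core_py)
except Exception:  # pragma: no cover
    _viterbi_core = _viterbi_core_py


def _viterbi_from_emissions(E: np.ndarray, params: HMMParams) -> StatePath:
    with np.errstate(divide="ignore"):
        logA = np.log(params.transition_matrix())
        logpi = np.log(params.initial_distribution())
    path, loglik = _viterbi_core(
        np.ascontiguousarray(logA), np.ascontiguousarray(logpi), np.ascontiguousarray(E)
    )
    return StatePath(states=np.asarray(path), loglik=float(loglik))


def viterbi(markers: pd.DataFrame, params: HMMParams | None = None) -> StatePath:
    """Maximum-probability state path for the markers of one chromosome."""
    params = params or HMMParams()
    if len(markers) == 0:
        raise HMMError("cannot decode an empty marker list")
    return _viterbi_from_emissions(emission_matrix(markers, params), params)


# ---------------------------------------------------------------------------
# segmentation and calling
# ---------------------------------------------------------------------------


def _segment_from_emissions(
    path: StatePath, markers: pd.DataFrame, E: np.ndarray
) -> list[CNVCall]:
    states = path.states
    starts = markers["start"].to_numpy()
    ends = markers["end"].to_numpy()
    chroms = markers["chrom"].to_numpy()
    calls: list[CNVCall] = []
    n = len(states)
    boundaries = np.flatnonzero(np.diff(states)) + 1
    run_starts = np.concatenate([[0], boundaries])
    run_ends = np.concatenate([boundaries, [n]])
    for a, b in zip(run_starts, run_ends):
        s = int(states[a])
        if s == _CN2:
            continue
        label = STATES[s]
        conf = float(E[a:b, s].sum() - E[a:b, _CN2].sum())
        calls.append(
            CNVCall(
                chrom=str(chroms[a]),
                start=int(starts[a]),
                end=int(ends[b - 1]),
                state=label,
                copy_number=COPY_NUMBER[label],
                n_markers=int(b - a),
                confidence=conf,
            )
        )
    return calls


def segment(
    path: StatePath, markers: pd.DataFrame, params: HMMParams | None = None
) -> list[CNVCall]:
    """Run-length encode the decoded path into non-diploid calls.

    Confidence is the emission-only log-likelihood margin of the called
    state over the diploid state across the segment's markers.
    """
    params = params or HMMParams()
    if len(path) != len(markers):
        raise HMMError(f"path length {len(path)} does not match marker count {len(markers)}")
    return _segment_from_emissions(path, markers, emission_matrix(markers, params))


_VALIDATION_STATES = ("CN0", "CN1", "CN2", "CN3", "CN4")


def validate_region(
    markers: pd.DataFrame,
    chrom: str,
    start: int,
    end: int,
    params: HMMParams | None = None,
) -> RegionLikelihood:
    """Score a fixed region under the five copy-number hypotheses.

    Sums per-marker emission log-likelihoods over the markers overlapping
    [start, end] (1-based inclusive) for copy numbers 0..4; LOH is not a
    hypothesis here.  Ties prefer copy number 2, then the lower copy
    number.
    """
    params = params or HMMParams()
    sub = markers[
        (markers["chrom"] == chrom) & (markers["end"] >= start) & (markers["start"] <= end)
    ]
    if len(sub) == 0:
        raise HMMError(f"no signal in region {chrom}:{start}-{end}")
    E = emission_matrix(sub, params)
    loglik = {
        COPY_NUMBER[s]: float(E[:, STATE_INDEX[s]].sum()) for s in _VALIDATION_STATES
    }
    top = max(loglik.values())
    tied = [cn for cn, v in loglik.items() if v == top]
    best = 2 if 2 in tied else min(tied)
    return RegionLikelihood(
        chrom=chrom, start=start, end=end, loglik=loglik, best=best, n_markers=len(sub)
    )


def merge_calls(calls: Sequence[CNVCall], max_gap_frac: float = 0.2) -> list[CNVCall]:
    """Join adjacent same-state calls separated by small gaps.

    Long events can decode as several same-state runs broken by brief
    excursions; following the standard post-processing of segmented CNV
    output, two calls on the same chromosome in the same state merge
    when the gap between them is at most ``max_gap_frac`` of the merged
    span.  Applied iteratively left to right; marker counts and
    confidences add.
    """
    if max_gap_frac < 0:
        raise HMMError("max_gap_frac must be non-negative")
    by_key: dict[tuple[str, str], list[CNVCall]] = {}
    for c in sorted(calls, key=lambda c: (c.chrom, c.start)):
        by_key.setdefault((c.chrom, c.state), []).append(c)
    merged: list[CNVCall] = []
    for (_, _), group in by_key.items():
        cur = group[0]
        for nxt in group[1:]:
            gap = nxt.start - cur.end - 1
            span = nxt.end - cur.start + 1
            if gap >= 0 and gap <= max_gap_frac * span:
                cur = CNVCall(
                    chrom=cur.chrom,
                    start=cur.start,
                    end=nxt.end,
                    state=cur.state,
                    copy_number=cur.copy_number,
                    n_markers=cur.n_markers + nxt.n_markers,
                    confidence=cur.confidence + nxt.confidence,
                )
            else:
                merged.append(cur)
                cur = nxt
        merged.append(cur)
    merged.sort(key=lambda c: (c.chrom, c.start))
    return merged


def calibrate_lrr_params(
    track: SignalTrack,
    truth: Sequence,
    params: HMMParams | None = None,
    sd_floor: float = 0.05,
) -> HMMParams:
    """Recalculate the expected per-class LRR from regions of known copy number.

    Sequencing platforms, coverage levels and pipelines shift the
    class-conditional LRR distributions, so the expected LRR per copy
    number is recalculated from data with known copy-number regions and
    fed to the HMM as prior knowledge.  ``truth`` is a sequence of
    objects with ``chrom``/``start``/``end`` (1-based inclusive),
    ``copy_number`` and ``is_loh`` attributes; markers fully inside a
    non-LOH truth interval contribute to that copy number's class,
    markers outside every truth interval to the diploid class.  Returns
    a copy of ``params`` with updated ``lrr_mean``/``lrr_sd`` (LOH kept
    tied to CN2); classes without markers keep their previous values.
    """
    params = params or HMMParams()
    df = track.markers
    starts = df["start"].to_numpy()
    ends = df["end"].to_numpy()
    chroms = df["chrom"].to_numpy()
    lrr = df["lrr"].to_numpy(dtype=float)
    label = np.full(len(df), -1, dtype=np.int8)  # -1: not in any truth interval
    for t in truth:
        m = (chroms == t.chrom) & (starts >= t.start) & (ends <= t.end)
        label[m] = 2 if t.is_loh else t.copy_number
    lrr_mean = dict(params.lrr_mean)
    lrr_sd = dict(params.lrr_sd)
    for cn, state in ((0, "CN0"), (1, "CN1"), (2, "CN2"), (3, "CN3"), (4, "CN4")):
        sel = (label == -1) | (label == 2) if cn == 2 else label == cn
        if np.count_nonzero(sel) < 2:
            continue
        lrr_mean[state] = float(lrr[sel].mean())
        lrr_sd[state] = max(float(lrr[sel].std()), sd_floor)
    lrr_mean["LOH"] = lrr_mean["CN2"]
    lrr_sd["LOH"] = lrr_sd["CN2"]
    return HMMParams(
        lrr_mean=lrr_mean,
        lrr_sd=lrr_sd,
        self_prob=dict(params.self_prob),
        baf_het_sd=params.baf_het_sd,
        outlier_frac=params.outlier_frac,
        cn2_revert_frac=params.cn2_revert_frac,
        initial_cn2_prob=params.initial_cn2_prob,
    )


def call_sample(
    track: SignalTrack,
    params: HMMParams | None = None,
    min_markers: int = 3,
    min_length: int = 0,
) -> list[CNVCall]:
    """Decode every chromosome of a signal track and emit filtered calls.

    Deterministic given identical input; a chromosome present in the
    track with no markers is an error.
    """
    params = params or HMMParams()
    calls: list[CNVCall] = []
    chroms = list(track.chrom_mean_depth)
    for chrom in chroms:
        sub = track.chrom_markers(chrom)
        if len(sub) == 0:
            raise HMMError(f"chromosome {chrom}: no markers to decode")
        try:
            E = emission_matrix(sub, params)
            path = _viterbi_from_emissions(E, params)
            chrom_calls = _segment_from_emissions(path, sub, E)
        except HMMError as exc:
            raise HMMError(f"chromosome {chrom}: {exc}") from exc
        calls.extend(
            c
            for c in chrom_calls
            if c.n_markers >= min_markers and c.length >= min_length
        )
    return calls


# ---------------------------------------------------------------------------
# parameter and call I/O
# ---------------------------------------------------------------------------


def write_hmm_config(params: HMMParams, stream: TextIO | str) -> None:
    own = isinstance(stream, str)
    fh: TextIO = open(stream, "w") if own else stream  # type: ignore[arg-type]
    try:
        for s in STATES:
            fh.write(f"state.{s}.lrr_mean={params.lrr_mean[s]!r}\n")
            fh.write(f"state.{s}.lrr_sd={params.lrr_sd[s]!r}\n")
            fh.write(f"state.{s}.self_prob={params.self_prob[s]!r}\n")
        fh.write(f"baf_het_sd={params.baf_het_sd!r}\n")
        fh.write(f"outlier_frac={params.outlier_frac!r}\n")
        fh.write(f"cn2_revert_frac={params.cn2_revert_frac!r}\n")
        fh.write(f"initial_cn2_prob={params.initial_cn2_prob!r}\n")
    finally:
        if own:
            fh.close()


def read_hmm_config(stream: TextIO | str) -> HMMParams:
    own = isinstance(stream, str)
    fh: TextIO = open(stream) if own else stream  # type: ignore[arg-type]
    try:
        params = HMMParams()
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise HMMError(f"HMM config line {lineno}: expected key=value")
            key, value_s = line.split("=", 1)
            value = float(value_s)
            if key.startswith("state."):
                _, state, attr = key.split(".")
                _check_state(state)
                getattr(params, attr)[state] = value
            else:
                setattr(params, key, value)
        params.__post_init__()  # re-validate after overrides
        return params
    finally:
        if own:
            fh.close()


def write_calls_bed(calls: Sequence[CNVCall], stream: TextIO | str) -> None:
    """Write calls as BED (0-based half-open): chrom, start, end, name, score."""
    own = isinstance(stream, str)
    fh: TextIO = open(stream, "w") if own else stream  # type: ignore[arg-type]
    try:
        for c in calls:
            name = "loh" if c.is_loh else f"cn={c.copy_number}"
            fh.write(f"{c.chrom}\t{c.start - 1}\t{c.end}\t{name}\t{c.confidence:.4f}\n")
    finally:
        if own:
            fh.close()


def write_calls_rawcnv(calls: Sequence[CNVCall], stream: TextIO | str) -> None:
    """Write calls in a rawcnv-style text (1-based inclusive coordinates)."""
    own = isinstance(stream, str)
    fh: TextIO = open(stream, "w") if own else stream  # type: ignore[arg-type]
    try:
        for c in calls:
            fh.write(
                f"{c.chrom}:{c.start}-{c.end}\tnumsnp={c.n_markers}\t"
                f"cn={c.copy_number}\tstate={c.state}\tconf={c.confidence:.4f}\n"
            )
    finally:
        if own:
            fh.close()
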