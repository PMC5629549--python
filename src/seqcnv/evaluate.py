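"""Precision/recall benchmarking of CNV calls against truth intervals.

A call and a truth interval match when they share at least a fraction
``overlap_frac`` of their lengths (reciprocally by default, i.e. of
*both* lengths) and are copy-number compatible.  Matching is one-to-one
and greedy in decreasing overlap, so multiple calls hitting one truth
interval can contribute at most one true positive; the surplus counts
as false positives.  Precision/recall are reported per copy-number
class (0, 1, 3, 4), for LOH, and for the grouped "deletions" (0+1) and
"duplications" (3+4) sets, optionally swept over minimum-length
thresholds for ROC-style curves.

All interval arithmetic here uses 0-based half-open (BED) coordinates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Sequence, TextIO

from .hmm import CNVCall


class EvaluationError(ValueError):
    pass


@dataclass(frozen=True)
class BedCNV:
    """A CNV interval in BED coordinates (0-based half-open)."""

    chrom: str
    start: int
    end: int
    copy_number: int | None  # None when unknown
    is_loh: bool = False

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class MatchConfig:
    overlap_frac: float = 0.70
    reciprocal: bool = True
    require_cn_match: bool = True
    min_length: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.overlap_frac <= 1:
            raise EvaluationError("overlap fraction must be in (0, 1]")
        if self.min_length < 0:
            raise EvaluationError("minimum length must be non-negative")


@dataclass
class PRPoint:
    """Precision/recall at one class and length threshold.

    ``precision``/``recall`` are None (undefined) on empty denominators,
    never silently 0 or 1.
    """

    label: str
    min_length: int
    tp: int
    fp: int
    fn: int

    @property
    def precision(self) -> float | None:
        return self.tp / (self.tp + self.fp) if self.tp + self.fp > 0 else None

    @property
    def recall(self) -> float | None:
        return self.tp / (self.tp + self.fn) if self.tp + self.fn > 0 else None


# ---------------------------------------------------------------------------
# interval arithmetic
# ---------------------------------------------------------------------------


def overlap_fraction(
    a: tuple[int, int], b: tuple[int, int]
) -> tuple[float, float]:
    """Shared length as a fraction of each half-open interval's length."""
    (a0, a1), (b0, b1) = a, b
    if a1 <= a0 or b1 <= b0:
        raise EvaluationError("zero-length interval")
    ov = max(0, min(a1, b1) - max(a0, b0))
    return ov / (a1 - a0), ov / (b1 - b0)


# ---------------------------------------------------------------------------
# class definitions
# ---------------------------------------------------------------------------

#: evaluation classes: label -> (call predicate, exact-cn within class?)
def _class_members(require_cn_match: bool) -> dict[str, Callable[[BedCNV], bool]]:
    return {
        "0": lambda r: not r.is_loh and r.copy_number == 0,
        "1": lambda r: not r.is_loh and r.copy_number == 1,
        "3": lambda r: not r.is_loh and r.copy_number == 3,
        "4": lambda r: not r.is_loh and r.copy_number == 4,
        "loh": lambda r: r.is_loh,
        "deletions": lambda r: not r.is_loh and r.copy_number in (0, 1),
        "duplications": lambda r: not r.is_loh and r.copy_number in (3, 4),
    }


_EXACT_CN_CLASSES = {"0", "1", "3", "4"}


def _check_chrom_naming(calls: Sequence[BedCNV], truth: Sequence[BedCNV]) -> None:
    if not calls or not truth:
        return
    call_chroms = {c.chrom for c in calls}
    truth_chroms = {t.chrom for t in truth}
    if call_chroms & truth_chroms:
        return
    strip = lambda s: s[3:] if s.lower().startswith("chr") else s
    if {strip(c) for c in call_chroms} & {strip(t) for t in truth_chroms}:
        raise EvaluationError(
            "inconsistent chromosome naming between calls and truth: "
            f"calls use {sorted(call_chroms)[:5]}, truth uses {sorted(truth_chroms)[:5]}"
        )


def match_calls(
    calls: Sequence[BedCNV],
    truth: Sequence[BedCNV],
    cfg: MatchConfig | None = None,
) -> tuple[dict[str, list[tuple[int, int]]], dict[str, PRPoint]]:
    """Match calls to truth per class and compute precision/recall.

    Returns ``(matches, points)`` where ``matches[label]`` holds the
    matched (call index, truth index) pairs (indices into the full input
    sequences) and ``points[label]`` the corresponding counts.  LOH only
    ever matches LOH.  When ``require_cn_match`` is false, the per-cn
    classes still partition by the *truth* side but accept any non-LOH
    call copy number.
    """
    cfg = cfg or MatchConfig()
    _check_chrom_naming(calls, truth)
    classes = _class_members(cfg.require_cn_match)
    matches: dict[str, list[tuple[int, int]]] = {}
    points: dict[str, PRPoint] = {}
    for label, member in classes.items():
        if cfg.require_cn_match or label in ("loh",):
            call_sel = [i for i, c in enumerate(calls) if member(c) and c.length >= cfg.min_length]
        elif label in _EXACT_CN_CLASSES:
            call_sel = [
                i
                for i, c in enumerate(calls)
                if not c.is_loh and c.length >= cfg.min_length
            ]
        else:
            call_sel = [i for i, c in enumerate(calls) if member(c) and c.length >= cfg.min_length]
        truth_sel = [j for j, t in enumerate(truth) if member(t) and t.length >= cfg.min_length]

        candidates: list[tuple[int, int, int]] = []  # (-overlap_bp ordering via sort key)
        for i in call_sel:
            c = calls[i]
            for j in truth_sel:
                t = truth[j]
                if t.chrom != c.chrom:
                    continue
                f_call, f_truth = overlap_fraction((c.start, c.end), (t.start, t.end))
                ok = (
                    f_call >= cfg.overlap_frac and f_truth >= cfg.overlap_frac
                    if cfg.reciprocal
                    else f_call >= cfg.overlap_frac
                )
                if ok:
                    ov = min(c.end, t.end) - max(c.start, t.start)
                    candidates.append((ov, i, j))
        candidates.sort(key=lambda x: (-x[0], x[1], x[2]))
        used_calls: set[int] = set()
        used_truth: set[int] = set()
        pairs: list[tuple[int, int]] = []
        for _, i, j in candidates:
            if i in used_calls or j in used_truth:
                continue
            used_calls.add(i)
            used_truth.add(j)
            pairs.append((i, j))
        tp = len(pairs)
        matches[label] = pairs
        points[label] = PRPoint(
            label=label,
            min_length=cfg.min_length,
            tp=tp,
            fp=len(call_sel) - tp,
            fn=len(truth_sel) - tp,
        )
    return matches, points


def pr_by_min_length(
    calls: Sequence[BedCNV],
    truth: Sequence[BedCNV],
    cfg: MatchConfig | None = None,
    thresholds: Sequence[int] | None = None,
) -> list[PRPoint]:
    """Sweep minimum-length thresholds (default 0..50 kb in 1 kb steps).

    At each threshold both calls and truth are filtered to length >=
    threshold before matching, giving the points of a ROC-style curve.
    """
    cfg = cfg or MatchConfig()
    if thresholds is None:
        thresholds = list(range(0, 50_001, 1_000))
    if any(t < 0 for t in thresholds):
        raise EvaluationError("negative length threshold")
    if list(thresholds) != sorted(thresholds):
        raise EvaluationError("thresholds must be sorted ascending")
    out: list[PRPoint] = []
    for thr in thresholds:
        step_cfg = MatchConfig(
            overlap_frac=cfg.overlap_frac,
            reciprocal=cfg.reciprocal,
            require_cn_match=cfg.require_cn_match,
            min_length=int(thr),
        )
        _, points = match_calls(calls, truth, step_cfg)
        out.extend(points.values())
    return out


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def _parse_bed_name(name: str) -> tuple[int | None, bool]:
    n = name.strip().lower()
    if n in ("loh", "state=loh"):
        return 2, True
    for token in n.replace(";", " ").split():
        if token.startswith("cn="):
            return int(token[3:]), False
        if token in ("cn0", "cn1", "cn2", "cn3", "cn4"):
            return int(token[2]), False
    return None, False


def read_cnv_bed(stream: TextIO | str) -> list[BedCNV]:
    """Read CNV intervals from BED; the name column carries 'cn=K' or 'loh'."""
    own = isinstance(stream, str)
    fh: TextIO = open(stream) if own else stream  # type: ignore[arg-type]
    try:
        out: list[BedCNV] = []
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise EvaluationError(f"BED line {lineno}: expected >=3 columns")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise EvaluationError(f"BED line {lineno}: non-integer coordinates") from exc
            if end <= start:
                raise EvaluationError(f"BED line {lineno}: empty interval")
            cn, is_loh = _parse_bed_name(fields[3]) if len(fields) > 3 else (None, False)
            out.append(BedCNV(chrom=fields[0], start=start, end=end, copy_number=cn, is_loh=is_loh))
        return out
    finally:
        if own:
            fh.close()


def calls_to_bed(calls: Sequence[CNVCall]) -> list[BedCNV]:
    """Convert 1-based inclusive HMM calls to BED intervals."""
    return [
        BedCNV(
            chrom=c.chrom,
            start=c.start - 1,
            end=c.end,
            copy_number=c.copy_number,
            is_loh=c.is_loh,
        )
        for c in calls
    ]


def write_report(points: Sequence[PRPoint], stream: TextIO | str) -> None:
    """Write a tab-delimited class/threshold/tp/fp/fn/precision/recall table."""
    own = isinstance(stream, str)
    fh: TextIO = open(stream, "w") if own else stream  # type: ignore[arg-type]
    try:
        fh.write("class\tmin_length\ttp\tfp\tfn\tprecision\trecall\n")
        for p in points:
            prec = "NA" if p.precision is None else f"{p.precision:.4f}"
            rec = "NA" if p.recall is None else f"{p.recall:.4f}"
            fh.write(f"{p.label}\t{p.min_length}\t{p.tp}\t{p.fp}\t{p.fn}\t{prec}\t{rec}\n")
    finally:
        if own:
            fh.close()
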