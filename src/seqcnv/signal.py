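"""Per-sample marker signal extraction from sequencing coverage.

Whole-genome sequencing data is reduced to an array-like marker track:
every sample SNV becomes a *snv* marker carrying a B allele frequency
(BAF, the fraction of reads supporting the non-reference allele), and
every maximal run of positions without a sample SNV becomes an *interval*
marker carrying only coverage information.  Interval markers are split at
common population-SNP positions so that marker boundaries line up with
the sites a genotyping array would have probed.

The coverage signal is expressed as a log R ratio (LRR):

    LRR = log2((depth + c) / (chromosome mean depth + c))

with a small pseudocount ``c`` so that homozygous deletions (depth 0)
map to a finite, very negative value.  Markers without allele
information carry the conventional BAF sentinel value ``2``.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence, TextIO

import numpy as np
import pandas as pd

NO_BAF = 2.0
"""Sentinel BAF value for markers without allele information."""

DEFAULT_PSEUDOCOUNT = 0.5

SUPERPOPULATIONS = ("ALL", "AFR", "AMR", "EAS", "EUR", "SAS")

#: canonical column order of the marker table inside a SignalTrack
MARKER_COLUMNS = ("chrom", "start", "end", "kind", "lrr", "baf", "depth", "pop_freq")


class SignalError(ValueError):
    """Raised for malformed signal inputs (pileup, VCF, signal files)."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class SiteCoverage:
    """Read support at a single 1-based genomic position."""

    chrom: str
    pos: int
    depth: int
    ref_count: int
    alt_count: int
    has_snv: bool = False
    ref_allele: str | None = None
    alt_allele: str | None = None

    def __post_init__(self) -> None:
        if self.depth < 0:
            raise SignalError(f"negative depth at {self.chrom}:{self.pos}")
        if self.ref_count + self.alt_count > self.depth:
            raise SignalError(
                f"allele counts exceed depth at {self.chrom}:{self.pos}"
            )


@dataclass(frozen=True)
class PopulationSNP:
    """A common SNP with its alternate-allele frequency in one superpopulation."""

    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str
    freq: float
    superpop: str = "ALL"

    def __post_init__(self) -> None:
        if not 0.0 <= self.freq <= 1.0:
            raise SignalError(f"frequency {self.freq} outside [0,1] at {self.chrom}:{self.pos}")
        if self.superpop not in SUPERPOPULATIONS:
            raise SignalError(
                f"unknown superpopulation {self.superpop!r}; valid codes: {', '.join(SUPERPOPULATIONS)}"
            )


@dataclass
class Marker:
    """One signal unit: a sample SNV site or an inter-SNV interval.

    Coordinates are 1-based inclusive; ``start == end`` for snv markers.
    """

    chrom: str
    start: int
    end: int
    kind: str  # "snv" | "interval"
    lrr: float
    baf: float
    depth: float
    pop_freq: float | None = None

    @property
    def id(self) -> str:
        return marker_name(self.chrom, self.start, self.end, self.kind)

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def marker_name(chrom: str, start: int, end: int, kind: str) -> str:
    if kind == "snv" or start == end:
        return f"{chrom}:{start}" if kind == "snv" else f"{chrom}:{start}-{end}"
    return f"{chrom}:{start}-{end}"


@dataclass
class SignalTrack:
    """Ordered marker table for one sample plus per-chromosome mean depth."""

    sample_id: str
    markers: pd.DataFrame
    chrom_mean_depth: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [c for c in MARKER_COLUMNS if c not in self.markers.columns]
        if missing:
            raise SignalError(f"marker table missing columns: {missing}")
        for chrom in self.chromosomes:
            if chrom not in self.chrom_mean_depth:
                raise SignalError(f"no mean depth recorded for chromosome {chrom}")
            if not self.chrom_mean_depth[chrom] > 0:
                raise SignalError(f"non-positive mean depth for chromosome {chrom}")

    @property
    def chromosomes(self) -> list[str]:
        return list(dict.fromkeys(self.markers["chrom"]))

    def chrom_markers(self, chrom: str) -> pd.DataFrame:
        return self.markers[self.markers["chrom"] == chrom]

    def __len__(self) -> int:
        return len(self.markers)


def markers_to_frame(markers: Sequence[Marker]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chrom": [m.chrom for m in markers],
            "start": np.asarray([m.start for m in markers], dtype=np.int64),
            "end": np.asarray([m.end for m in markers], dtype=np.int64),
            "kind": [m.kind for m in markers],
            "lrr": np.asarray([m.lrr for m in markers], dtype=float),
            "baf": np.asarray([m.baf for m in markers], dtype=float),
            "depth": np.asarray([m.depth for m in markers], dtype=float),
            "pop_freq": np.asarray(
                [np.nan if m.pop_freq is None else m.pop_freq for m in markers], dtype=float
            ),
        },
        columns=list(MARKER_COLUMNS),
    )


# ---------------------------------------------------------------------------
# pileup parsing
# ---------------------------------------------------------------------------

_INDEL_RE = re.compile(r"[+-](\d+)")


def _decode_read_bases(bases: str, chrom: str, pos: int) -> tuple[int, int]:
    """Count reference / alternate supporting reads in a pileup base column.

    '.'/',' support the reference, ACGT (any case) a non-reference base.
    Read-start ('^' plus mapping quality), read-end ('$'), indel spans
    ('+n'/'-n' followed by n bases) and deletion placeholders '*' carry no
    allele information and are skipped.
    """
    ref = alt = 0
    i, n = 0, len(bases)
    while i < n:
        c = bases[i]
        if c in ".,":
            ref += 1
            i += 1
        elif c in "ACGTacgt":
            alt += 1
            i += 1
        elif c == "^":
            i += 2  # caret is followed by a mapping-quality character
        elif c == "$":
            i += 1
        elif c in "+-":
            m = _INDEL_RE.match(bases, i)
            if m is None:
                raise SignalError(f"malformed indel span in pileup at {chrom}:{pos}")
            i = m.end() + int(m.group(1))
        elif c in "*#<>Nn":
            i += 1
        else:
            raise SignalError(f"unexpected pileup symbol {c!r} at {chrom}:{pos}")
    return ref, alt


def read_pileup(stream: TextIO | Iterable[str]) -> list[SiteCoverage]:
    """Parse samtools-mpileup-style text into per-position coverage records.

    Expects at least chrom, 1-based position, reference base, depth and the
    read-bases column.  ``has_snv`` is provisionally set when non-reference
    reads are observed; :func:`annotate_snvs` restricts it to positions with
    an actual variant call.
    """
    sites: list[SiteCoverage] = []
    for lineno, line in enumerate(stream, start=1):
        line = line.rstrip("\n")
        if not line:
            continue
        fields = line.split("\t")
        if len(fields) == 1:
            fields = line.split()
        if len(fields) < 5:
            raise SignalError(f"pileup line {lineno}: expected >=5 columns, got {len(fields)}")
        chrom, pos_s, ref_base, depth_s, bases = fields[0], fields[1], fields[2], fields[3], fields[4]
        try:
            pos = int(pos_s)
            depth = int(depth_s)
        except ValueError as exc:
            raise SignalError(f"pileup line {lineno}: non-numeric position/depth") from exc
        if depth < 0:
            raise SignalError(f"pileup line {lineno}: negative depth")
        ref_count, alt_count = _decode_read_bases(bases, chrom, pos)
        # depth column is authoritative; clip decoded counts to it
        if ref_count + alt_count > depth:
            scale_excess = ref_count + alt_count - depth
            ref_count = max(0, ref_count - scale_excess)
        sites.append(
            SiteCoverage(
                chrom=chrom,
                pos=pos,
                depth=depth,
                ref_count=ref_count,
                alt_count=alt_count,
                has_snv=alt_count > 0,
                ref_allele=ref_base.upper() if ref_base else None,
            )
        )
    return sites


def annotate_snvs(
    sites: Sequence[SiteCoverage],
    snvs: dict[tuple[str, int], tuple[str, str]],
) -> list[SiteCoverage]:
    """Restrict ``has_snv`` to positions with a variant call.

    ``snvs`` maps (chrom, pos) to (ref, alt) alleles, typically from a VCF.
    At positions without a call, stray non-reference reads are treated as
    noise: the alternate count is cleared so the marker carries no BAF.
    """
    out: list[SiteCoverage] = []
    for s in sites:
        key = (s.chrom, s.pos)
        if key in snvs:
            ref, alt = snvs[key]
            out.append(replace(s, has_snv=True, ref_allele=ref, alt_allele=alt))
        else:
            out.append(replace(s, has_snv=False, alt_count=0))
    return out


def read_vcf_snvs(path: str, pass_only: bool = True) -> dict[tuple[str, int], tuple[str, str]]:
    """Read biallelic SNV records from a VCF into a (chrom, pos) -> (ref, alt) map."""
    from cyvcf2 import VCF

    snvs: dict[tuple[str, int], tuple[str, str]] = {}
    for rec in VCF(path):
        if not rec.is_snp:
            continue
        if pass_only and rec.FILTER is not None:  # cyvcf2: None means PASS/'.'
            continue
        if not rec.ALT:
            continue
        snvs[(rec.CHROM, rec.POS)] = (rec.REF, rec.ALT[0])
    return snvs


def read_population_frequencies(path: str, superpop: str = "ALL") -> list[PopulationSNP]:
    """Read a tab-delimited chrom/pos/ref/alt/freq allele-frequency table."""
    if superpop not in SUPERPOPULATIONS:
        raise SignalError(
            f"unknown superpopulation {superpop!r}; valid codes: {', '.join(SUPERPOPULATIONS)}"
        )
    snps: list[PopulationSNP] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 5:
                raise SignalError(f"{path} line {lineno}: expected 5 columns")
            try:
                snps.append(
                    PopulationSNP(
                        chrom=fields[0],
                        pos=int(fields[1]),
                        ref_allele=fields[2].upper(),
                        alt_allele=fields[3].upper(),
                        freq=float(fields[4]),
                        superpop=superpop,
                    )
                )
            except ValueError as exc:
                raise SignalError(f"{path} line {lineno}: {exc}") from exc
    return snps


# ---------------------------------------------------------------------------
# core signal quantities
# ---------------------------------------------------------------------------


def chromosome_mean_depth(sites: Sequence[SiteCoverage], chrom: str) -> float:
    """Arithmetic mean read depth over the covered positions of one chromosome."""
    depths = [s.depth for s in sites if s.chrom == chrom]
    if not depths or not any(d > 0 for d in depths):
        raise SignalError(f"no coverage on chromosome {chrom}")
    return float(np.mean(depths))


def compute_lrr(observed_depth, expected_depth, pseudocount: float = DEFAULT_PSEUDOCOUNT):
    """log2((observed + c) / (expected + c)); accepts scalars or arrays.

    The pseudocount keeps the ratio defined at zero observed depth while
    preserving monotonicity in the observed depth.
    """
    if np.any(np.asarray(expected_depth) <= 0):
        raise SignalError("expected depth must be positive")
    if pseudocount < 0:
        raise SignalError("pseudocount must be non-negative")
    result = np.log2(
        (np.asarray(observed_depth, dtype=float) + pseudocount)
        / (np.asarray(expected_depth, dtype=float) + pseudocount)
    )
    return float(result) if np.ndim(result) == 0 else result


def compute_baf(ref_count, alt_count, has_snv):
    """Fraction of reads supporting the alternate allele, or the sentinel 2.

    Degenerate inputs (no variant call, or zero informative reads) map to
    the sentinel, never to an error.
    """
    ref = np.asarray(ref_count)
    alt = np.asarray(alt_count)
    snv = np.asarray(has_snv, dtype=bool)
    if np.any(ref < 0) or np.any(alt < 0):
        raise SignalError("allele counts must be non-negative")
    total = ref + alt
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = np.where(total > 0, alt / np.where(total > 0, total, 1), NO_BAF)
    result = np.where(snv & (total > 0), frac, NO_BAF)
    return float(result) if np.ndim(result) == 0 else result


# ---------------------------------------------------------------------------
# marker construction
# ---------------------------------------------------------------------------


def build_marker_set(
    sites: Sequence[SiteCoverage],
    pop_snps: Sequence[PopulationSNP],
    chrom_mean: float,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> list[Marker]:
    """Build the ordered marker list for one chromosome.

    Every sample SNV becomes an snv marker; maximal runs of covered
    positions without a sample SNV become interval markers, additionally
    split at every interior population-SNP position so that each common
    SNP coincides with a marker boundary.  Interval LRR is computed from
    the mean depth over the interval.
    """
    if chrom_mean <= 0:
        raise SignalError("chromosome mean depth must be positive")
    if not sites:
        return []
    chroms = {s.chrom for s in sites}
    if len(chroms) > 1:
        raise SignalError(f"sites span multiple chromosomes: {sorted(chroms)}")
    chrom = next(iter(chroms))
    pop_chroms = {p.chrom for p in pop_snps}
    if pop_chroms and pop_chroms != {chrom}:
        raise SignalError(
            f"population SNPs on {sorted(pop_chroms)} do not match site chromosome {chrom}"
        )
    positions = np.asarray([s.pos for s in sites], dtype=np.int64)
    if np.any(np.diff(positions) <= 0):
        raise SignalError("sites must be sorted by strictly increasing position")

    depths = np.asarray([s.depth for s in sites], dtype=float)
    prefix = np.concatenate([[0.0], np.cumsum(depths)])
    pos_index = {int(p): i for i, p in enumerate(positions)}

    pop_by_pos: dict[int, PopulationSNP] = {p.pos: p for p in pop_snps}

    def interval_marker(lo: int, hi: int) -> Marker:
        i0, i1 = pos_index[lo], pos_index[hi]
        mean_depth = (prefix[i1 + 1] - prefix[i0]) / (i1 - i0 + 1)
        return Marker(
            chrom=chrom,
            start=lo,
            end=hi,
            kind="interval",
            lrr=compute_lrr(mean_depth, chrom_mean, pseudocount),
            baf=NO_BAF,
            depth=float(mean_depth),
        )

    def snv_marker(site: SiteCoverage) -> Marker:
        pop_freq: float | None = None
        psnp = pop_by_pos.get(site.pos)
        if (
            psnp is not None
            and site.ref_allele is not None
            and site.alt_allele is not None
            and psnp.ref_allele == site.ref_allele
            and psnp.alt_allele == site.alt_allele
        ):
            pop_freq = psnp.freq
        return Marker(
            chrom=chrom,
            start=site.pos,
            end=site.pos,
            kind="snv",
            lrr=compute_lrr(site.depth, chrom_mean, pseudocount),
            baf=compute_baf(site.ref_count, site.alt_count, site.has_snv),
            depth=float(site.depth),
            pop_freq=pop_freq,
        )

    site_by_pos = {s.pos: s for s in sites}
    snv_positions = {s.pos for s in sites if s.has_snv}
    markers: list[Marker] = []

    # contiguous covered runs
    run_breaks = np.flatnonzero(np.diff(positions) > 1)
    run_bounds = zip(
        np.concatenate([[0], run_breaks + 1]),
        np.concatenate([run_breaks, [len(positions) - 1]]),
    )
    for a_idx, b_idx in run_bounds:
        a, b = int(positions[a_idx]), int(positions[b_idx])
        # split points: sample SNVs and covered population-SNP positions
        specials = sorted(
            {p for p in snv_positions if a <= p <= b}
            | {p for p in pop_by_pos if a <= p <= b}
        )
        cursor = a
        for p in specials:
            if cursor <= p - 1:
                markers.append(interval_marker(cursor, p - 1))
            site = site_by_pos[p]
            markers.append(snv_marker(site) if site.has_snv else interval_marker(p, p))
            cursor = p + 1
        if cursor <= b:
            markers.append(interval_marker(cursor, b))
    return markers


def center_lrr(track: SignalTrack) -> SignalTrack:
    """Subtract the per-chromosome median LRR so the diploid mode sits at 0.

    The median is robust to the minority of markers inside CNV regions;
    ordering and marker count are unchanged, and the operation is
    idempotent on already-centered tracks.
    """
    df = track.markers.copy()
    for chrom in track.chromosomes:
        mask = df["chrom"] == chrom
        df.loc[mask, "lrr"] = df.loc[mask, "lrr"] - df.loc[mask, "lrr"].median()
    return SignalTrack(
        sample_id=track.sample_id,
        markers=df,
        chrom_mean_depth=dict(track.chrom_mean_depth),
    )


# ---------------------------------------------------------------------------
# signal file I/O (PennCNV-compatible layout plus Depth / Pop Freq columns)
# ---------------------------------------------------------------------------


def write_signal_file(track: SignalTrack, stream: TextIO | str) -> None:
    """Write a tab-delimited signal file.

    Layout: ``Name  Chr  Position  <sample>.Log R Ratio  <sample>.B Allele
    Freq  <sample>.Depth  <sample>.Pop Freq``.  Interval markers are
    serialized at their start position with a ``chrom:start-end`` name so
    the interval round-trips.  Mean depths are recorded in ``#`` header
    comments.
    """
    own = isinstance(stream, str)
    fh: TextIO = open(stream, "w") if own else stream  # type: ignore[arg-type]
    try:
        sid = track.sample_id
        fh.write(f"#sample_id={sid}\n")
        for chrom, md in track.chrom_mean_depth.items():
            fh.write(f"#mean_depth\t{chrom}\t{md:.6f}\n")
        fh.write(
            f"Name\tChr\tPosition\t{sid}.Log R Ratio\t{sid}.B Allele Freq"
            f"\t{sid}.Depth\t{sid}.Pop Freq\n"
        )
        df = track.markers
        names = np.where(
            (df["kind"] == "snv").to_numpy(),
            df["chrom"].astype(str) + ":" + df["start"].astype(str),
            df["chrom"].astype(str) + ":" + df["start"].astype(str) + "-" + df["end"].astype(str),
        )
        out = pd.DataFrame(
            {
                "Name": names,
                "Chr": df["chrom"].to_numpy(),
                "Position": df["start"].to_numpy(),
                "lrr": np.round(df["lrr"].to_numpy(float), 4),
                "baf": np.round(df["baf"].to_numpy(float), 4),
                "depth": np.round(df["depth"].to_numpy(float), 4),
                "pop_freq": np.round(df["pop_freq"].to_numpy(float), 4),
            }
        )
        out.to_csv(fh, sep="\t", header=False, index=False, float_format="%.4f", na_rep="")
    finally:
        if own:
            fh.close()


_NAME_RE = re.compile(r"^(?P<chrom>[^:]+):(?P<start>\d+)(?:-(?P<end>\d+))?$")


def read_signal_file(stream: TextIO | str) -> SignalTrack:
    """Read a signal file written by :func:`write_signal_file`.

    Also accepts the plain 5-column layout (no Depth / Pop Freq columns);
    missing depths are then reported as NaN and the per-chromosome mean
    depth defaults to 1.0 unless header comments provide it.
    """
    own = isinstance(stream, str)
    fh: TextIO = open(stream) if own else stream  # type: ignore[arg-type]
    try:
        sample_id = "sample"
        mean_depth: dict[str, float] = {}
        header: list[str] | None = None
        rows: dict[str, list] = {k: [] for k in MARKER_COLUMNS}
        lineno = 0
        for line in fh:
            lineno += 1
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                if line.startswith("#sample_id="):
                    sample_id = line.split("=", 1)[1]
                elif line.startswith("#mean_depth"):
                    _, chrom, value = line.split("\t")
                    mean_depth[chrom] = float(value)
                continue
            fields = line.split("\t")
            if header is None:
                if fields[0] != "Name" or len(fields) < 5:
                    raise SignalError(f"line {lineno}: missing signal-file header")
                header = fields
                continue
            if len(fields) < 5:
                raise SignalError(f"line {lineno}: expected >=5 columns, got {len(fields)}")
            m = _NAME_RE.match(fields[0])
            if m is None:
                raise SignalError(f"line {lineno}: unparseable marker name {fields[0]!r}")
            chrom = fields[1]
            try:
                start = int(fields[2])
                lrr = float(fields[3])
                baf = float(fields[4])
                depth = float(fields[5]) if len(fields) > 5 and fields[5] != "" else math.nan
                pop_freq = float(fields[6]) if len(fields) > 6 and fields[6] != "" else math.nan
            except ValueError as exc:
                raise SignalError(f"line {lineno}: non-numeric field ({exc})") from exc
            end = int(m.group("end")) if m.group("end") else start
            kind = "interval" if m.group("end") else "snv"
            rows["chrom"].append(chrom)
            rows["start"].append(start)
            rows["end"].append(end)
            rows["kind"].append(kind)
            rows["lrr"].append(lrr)
            rows["baf"].append(baf)
            rows["depth"].append(depth)
            rows["pop_freq"].append(pop_freq)
        if header is None:
            raise SignalError("missing signal-file header")
        df = pd.DataFrame(rows, columns=list(MARKER_COLUMNS))
        df["start"] = df["start"].astype(np.int64)
        df["end"] = df["end"].astype(np.int64)
        if not mean_depth:
            for chrom in dict.fromkeys(df["chrom"]):
                sub = df[df["chrom"] == chrom]
                lengths = (sub["end"] - sub["start"] + 1).to_numpy(float)
                d = sub["depth"].to_numpy(float)
                if np.all(np.isnan(d)):
                    mean_depth[chrom] = 1.0
                else:
                    mean_depth[chrom] = float(np.nansum(d * lengths) / np.sum(lengths[~np.isnan(d)]))
        return SignalTrack(sample_id=sample_id, markers=df, chrom_mean_depth=mean_depth)
    finally:
        if own:
            fh.close()
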