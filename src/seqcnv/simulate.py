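"""Diploid CNV/LOH simulator with exact truth coordinates.

A simulated individual carries two haplotypes whose SNV alleles are
drawn from different superpopulation frequency profiles (maternal
European, paternal African by default), mirroring an admixed trio-less
design in which copy-neutral LOH blocks are detectable purely from
genotypes.  Planted events cover copy numbers 0/1/3/4 on a fixed length
grid from 1 kb to 5 Mb plus 5 Mb copy-neutral LOH blocks; coverage is
drawn around a 20X target with a unimodal GC-content bias.

Two output modes:

* signal mode (canonical, desk scale): emits a marker-level
  :class:`~seqcnv.signal.SignalTrack` directly, with per-marker depth
  Poisson around ``mean_coverage * cn/2 * gc_multiplier`` and allele
  counts binomial over the sample's allele composition.
* sequence mode: edits a (small) reference FASTA breakpoint-exactly,
  for read-level workflows outside this package's scope.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence, TextIO

import numpy as np
import pandas as pd

from .signal import (
    MARKER_COLUMNS,
    NO_BAF,
    PopulationSNP,
    SignalTrack,
    compute_lrr,
)

DEFAULT_LENGTH_GRID = (
    1_000, 1_500, 2_000, 2_500, 3_000, 3_500, 4_000, 5_000, 6_000, 8_000,
    10_000, 20_000, 30_000, 40_000, 50_000, 75_000, 100_000, 150_000,
    200_000, 500_000, 1_000_000, 5_000_000,
)

DEFAULT_CNV_COUNTS = {"CN0": 54, "CN1": 64, "CN3": 74, "CN4": 44, "LOH": 4}

_CNV_TYPES = ("CN0", "CN1", "CN3", "CN4", "LOH")
_TYPE_CN = {"CN0": 0, "CN1": 1, "CN3": 3, "CN4": 4, "LOH": 2}


class SimulationError(ValueError):
    pass


@dataclass
class SimConfig:
    """Generation settings; the seed must be set explicitly.

    Defaults encode the simulation design this package targets: 240
    CNVs per sample (54/64/74/44 events of copy number 0/1/3/4 plus 4
    LOH blocks), the 22-value length grid, 100 kb mean inter-event
    distance, 4.83 markers/kb, 20X coverage, maternal EUR / paternal
    AFR allele frequencies.  The chromosome lengths are a desk-scale
    three-chromosome genome large enough to host the default event load
    while keeping every chromosome majority-diploid.
    """

    seed: int
    chrom_lengths: dict[str, int] = field(
        default_factory=lambda: {
            "chr1": 140_000_000,
            "chr2": 120_000_000,
            "chr3": 100_000_000,
        }
    )
    marker_density: float = 4.83  # markers per kb
    mean_coverage: float = 20.0
    read_length: int = 100  # sequence mode only
    insert_size: int = 300  # sequence mode only
    maternal_pop: str = "EUR"
    paternal_pop: str = "AFR"
    cnv_counts: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_CNV_COUNTS))
    cnv_length_grid: tuple[int, ...] = DEFAULT_LENGTH_GRID
    loh_length: int = 5_000_000
    inter_cnv_distance_mean: float = 100_000.0
    gc_curvature: float = 1.5
    gc_mult_range: tuple[float, float] = (0.2, 1.2)
    gc_beta_params: tuple[float, float] = (20.0, 25.0)
    freq_beta_params: tuple[float, float] = (2.0, 2.0)
    exact_counts: bool = False

    def __post_init__(self) -> None:
        if any(c < 0 for c in self.cnv_counts.values()):
            raise SimulationError("CNV counts must be non-negative")
        if any(l <= 0 for l in self.chrom_lengths.values()):
            raise SimulationError("chromosome lengths must be positive")
        if not self.marker_density > 0:
            raise SimulationError("marker density must be positive")
        if not self.mean_coverage > 0:
            raise SimulationError("mean coverage must be positive")
        if any(l <= 0 for l in self.cnv_length_grid):
            raise SimulationError("grid lengths must be positive")


@dataclass(frozen=True)
class TruthCNV:
    """A planted event with exact 1-based inclusive truth coordinates."""

    chrom: str
    start: int
    end: int
    copy_number: int
    is_loh: bool = False
    parent_of_origin: str | None = None  # LOH only: "maternal" | "paternal"

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class Haplotype:
    """Alternate-allele positions carried by one chromosome copy."""

    chrom: str
    positions: np.ndarray  # sorted positions carrying the alternate allele


# ---------------------------------------------------------------------------
# haplotypes and population frequencies
# ---------------------------------------------------------------------------


def simulate_site_frequencies(
    chrom: str,
    length: int,
    density_per_kb: float,
    rng: np.random.Generator,
    beta_params: tuple[float, float] = (2.0, 2.0),
) -> pd.DataFrame:
    """Lay common-SNP sites along a chromosome with per-population frequencies.

    Inter-site gaps are exponential around the target density; alternate
    allele frequencies per superpopulation are drawn from a symmetric
    Beta (common, array-like variants), independently per population so
    the two parental profiles genuinely differ.
    """
    mean_gap = 1000.0 / density_per_kb
    scale = max(mean_gap - 1.0, 0.01)
    n_guess = int(length / mean_gap * 1.2) + 16
    gaps = np.floor(rng.exponential(scale, size=n_guess)).astype(np.int64) + 1
    pos = 1 + np.cumsum(gaps)
    while pos[-1] < length - 1:
        extra = np.floor(rng.exponential(scale, size=n_guess // 4 + 16)).astype(np.int64) + 1
        pos = np.concatenate([pos, pos[-1] + np.cumsum(extra)])
    pos = pos[pos <= length - 1]
    a, b = beta_params
    freq = {
        "EUR": rng.beta(a, b, size=len(pos)),
        "AFR": rng.beta(a, b, size=len(pos)),
    }
    return pd.DataFrame({"chrom": chrom, "pos": pos, "freq_EUR": freq["EUR"], "freq_AFR": freq["AFR"]})


def simulate_haplotypes(
    freqs: Sequence[PopulationSNP] | pd.DataFrame,
    pop: str,
    seed: int,
) -> tuple[Haplotype, Haplotype]:
    """Draw a pair of haplotypes carrying alternate alleles at population
    frequencies.

    Each haplotype carries the alternate allele at site *i* independently
    with that site's frequency in the named superpopulation.
    """
    if isinstance(freqs, pd.DataFrame):
        col = f"freq_{pop}"
        if col not in freqs.columns:
            raise SimulationError(f"unknown population code {pop!r}")
        chrom = str(freqs["chrom"].iloc[0]) if len(freqs) else "chr?"
        pos = freqs["pos"].to_numpy(np.int64)
        p = freqs[col].to_numpy(float)
    else:
        recs = [f for f in freqs if f.superpop == pop]
        if freqs and not recs:
            raise SimulationError(f"unknown population code {pop!r}")
        chrom = recs[0].chrom if recs else "chr?"
        pos = np.asarray([f.pos for f in recs], dtype=np.int64)
        p = np.asarray([f.freq for f in recs], dtype=float)
    rng = np.random.default_rng(seed)
    haps = []
    for _ in range(2):
        carry = rng.random(len(p)) < p
        haps.append(Haplotype(chrom=chrom, positions=pos[carry]))
    return haps[0], haps[1]


# ---------------------------------------------------------------------------
# event placement
# ---------------------------------------------------------------------------


def plant_cnvs(config: SimConfig, rng: np.random.Generator | None = None) -> list[TruthCNV]:
    """Place the configured CNV/LOH events without overlap.

    Per-type counts are Poisson around the configured means (or exact
    with ``exact_counts``); grid lengths are assigned by cycling so that
    small runs still cover the whole grid.  Events are spread over
    chromosomes by remaining capacity and placed left to right within a
    chromosome with exponential gaps of the configured mean.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    entries: list[tuple[str, int]] = []
    for cnv_type in _CNV_TYPES:
        mean = config.cnv_counts.get(cnv_type, 0)
        n = int(mean) if config.exact_counts else int(rng.poisson(mean))
        if cnv_type == "LOH":
            entries.extend(("LOH", config.loh_length) for _ in range(n))
        else:
            entries.extend(
                (cnv_type, config.cnv_length_grid[i % len(config.cnv_length_grid)])
                for i in range(n)
            )
    order = rng.permutation(len(entries))
    entries = [entries[i] for i in order]

    chroms = list(config.chrom_lengths)
    cursor = {c: 1 for c in chroms}
    events: list[TruthCNV] = []
    required = sum(l for _, l in entries) + int(
        len(entries) * config.inter_cnv_distance_mean
    )
    available = sum(config.chrom_lengths.values())
    for cnv_type, length in entries:
        gap = 1 + int(rng.exponential(config.inter_cnv_distance_mean))
        placed = False
        # most remaining headroom first
        for chrom in sorted(chroms, key=lambda c: config.chrom_lengths[c] - cursor[c], reverse=True):
            start = cursor[chrom] + gap
            end = start + length - 1
            if end <= config.chrom_lengths[chrom]:
                parent = None
                if cnv_type == "LOH":
                    parent = "maternal" if rng.random() < 0.5 else "paternal"
                events.append(
                    TruthCNV(
                        chrom=chrom,
                        start=start,
                        end=end,
                        copy_number=_TYPE_CN[cnv_type],
                        is_loh=cnv_type == "LOH",
                        parent_of_origin=parent,
                    )
                )
                cursor[chrom] = end + 1
                placed = True
                break
        if not placed:
            raise SimulationError(
                f"genome too small for requested events: ~{required} bp required, "
                f"{available} bp available"
            )
    events.sort(key=lambda e: (chroms.index(e.chrom), e.start))
    return events


# ---------------------------------------------------------------------------
# signal-mode simulation
# ---------------------------------------------------------------------------


def _gc_multiplier(g: np.ndarray, config: SimConfig) -> np.ndarray:
    lo, hi = config.gc_mult_range
    return np.clip(1.0 - config.gc_curvature * (g - 0.45) ** 2, lo, hi)


def _simulate_chromosome(
    chrom: str,
    length: int,
    truth: list[TruthCNV],
    config: SimConfig,
    rng: np.random.Generator,
) -> pd.DataFrame:
    # --- site scaffold: common-SNP sites at half the marker density, so
    # site markers plus inter-site interval markers hit the target density
    sites = simulate_site_frequencies(
        chrom, length, config.marker_density / 2.0, rng, config.freq_beta_params
    )
    pos = sites["pos"].to_numpy(np.int64)
    if len(pos) == 0:
        raise SimulationError(f"chromosome {chrom} too short for any marker sites")
    p_mat = sites[f"freq_{config.maternal_pop}"].to_numpy(float) \
        if f"freq_{config.maternal_pop}" in sites.columns else sites["freq_EUR"].to_numpy(float)
    p_pat = sites[f"freq_{config.paternal_pop}"].to_numpy(float) \
        if f"freq_{config.paternal_pop}" in sites.columns else sites["freq_AFR"].to_numpy(float)
    m_alt = (rng.random(len(pos)) < p_mat).astype(np.int8)
    p_alt = (rng.random(len(pos)) < p_pat).astype(np.int8)

    # --- marker scaffold: leading interval, then per site a 1-bp site
    # marker and the following inter-site interval
    n_sites = len(pos)
    starts = np.empty(2 * n_sites + 1, dtype=np.int64)
    ends = np.empty_like(starts)
    is_site = np.zeros(len(starts), dtype=bool)
    starts[0], ends[0] = 1, pos[0] - 1
    starts[1::2] = pos
    ends[1::2] = pos
    is_site[1::2] = True
    starts[2::2] = pos + 1
    ends[2::2] = np.concatenate([pos[1:] - 1, [length]])
    keep = ends >= starts
    starts, ends, is_site = starts[keep], ends[keep], is_site[keep]
    site_idx_of_marker = np.full(len(starts), -1, dtype=np.int64)
    site_idx_of_marker[is_site] = np.arange(n_sites)
    n = len(starts)
    lengths = (ends - starts + 1).astype(np.int64)

    # --- copy-number assignment
    weighted_cn = np.full(n, 2.0)
    discrete_cn = np.full(n, 2, dtype=np.int8)
    loh_mask = np.zeros(n, dtype=bool)
    hap_choice = np.zeros(n, dtype=np.int8)  # 0 keep/duplicate maternal, 1 paternal
    for t in truth:
        i0 = int(np.searchsorted(ends, t.start, side="left"))
        i1 = int(np.searchsorted(starts, t.end, side="right")) - 1
        if i1 < i0:
            continue
        ov = (
            np.minimum(ends[i0 : i1 + 1], t.end)
            - np.maximum(starts[i0 : i1 + 1], t.start)
            + 1
        )
        frac = ov / lengths[i0 : i1 + 1]
        weighted_cn[i0 : i1 + 1] += (t.copy_number - 2.0) * frac
        mid = (starts[i0 : i1 + 1] + ends[i0 : i1 + 1]) // 2
        inside = (mid >= t.start) & (mid <= t.end)
        sel = np.arange(i0, i1 + 1)[inside]
        discrete_cn[sel] = t.copy_number
        if t.is_loh:
            loh_mask[sel] = True
            hap_choice[sel] = 0 if t.parent_of_origin == "maternal" else 1
        elif t.copy_number in (1, 3):
            hap_choice[sel] = 0 if rng.random() < 0.5 else 1

    # --- coverage with GC bias; the unit of sampling noise is the read,
    # so a marker of length L averages over ~(L + rl - 1)/rl independent
    # read events (a single base is covered by ~depth reads)
    gc = rng.beta(*config.gc_beta_params, size=n)
    mult = _gc_multiplier(gc, config)
    lam = config.mean_coverage * (weighted_cn / 2.0) * mult
    units = (lengths + config.read_length - 1.0) / config.read_length
    depth = rng.poisson(lam * units) / units
    site_rows = is_site

    # --- allele composition and BAF at site markers
    si = site_idx_of_marker[site_rows]
    m = m_alt[si].astype(np.int64)
    p = p_alt[si].astype(np.int64)
    cn = discrete_cn[site_rows].astype(np.int64)
    choice = hap_choice[site_rows]
    loh = loh_mask[site_rows]
    kept = np.where(choice == 0, m, p)
    other = np.where(choice == 0, p, m)
    alt_alleles = np.select(
        [cn == 0, cn == 1, loh, cn == 2, cn == 3, cn == 4],
        [0, kept, 2 * kept, m + p, 2 * kept + other, 2 * (m + p)],
    )
    n_alleles = np.where(cn == 0, 0, np.where(loh, 2, cn))
    d_site = depth[site_rows].astype(np.int64)
    called = (alt_alleles >= 1) & (d_site >= 1)
    alt_frac = np.divide(alt_alleles, np.maximum(n_alleles, 1), dtype=float)
    alt_count = np.zeros(len(si), dtype=np.int64)
    alt_count[called] = rng.binomial(d_site[called], alt_frac[called])
    baf_site = np.full(len(si), NO_BAF)
    baf_site[called] = alt_count[called] / d_site[called]

    baf = np.full(n, NO_BAF)
    baf[site_rows] = baf_site
    kind = np.full(n, "interval", dtype=object)
    kind[np.flatnonzero(site_rows)[called]] = "snv"
    pop_freq = np.full(n, np.nan)
    pf_site = np.full(len(si), np.nan)
    pf_site[called] = 0.5 * (p_mat[si][called] + p_pat[si][called])
    pop_freq[site_rows] = pf_site

    # --- LRR against the chromosome mean depth (length-weighted)
    chrom_mean = float(np.sum(depth * lengths) / np.sum(lengths))
    lrr = compute_lrr(depth, chrom_mean)

    df = pd.DataFrame(
        {
            "chrom": chrom,
            "start": starts,
            "end": ends,
            "kind": kind,
            "lrr": lrr,
            "baf": baf,
            "depth": depth,
            "pop_freq": pop_freq,
        },
        columns=list(MARKER_COLUMNS),
    )
    df.attrs["chrom_mean_depth"] = chrom_mean
    return df


def simulate_signal(
    config: SimConfig,
    truth: Sequence[TruthCNV] | None = None,
    sample_id: str = "sim",
) -> tuple[SignalTrack, list[TruthCNV]]:
    """Generate a marker-level signal track plus its ground truth.

    Reproducible bit-for-bit for a given config (a single seeded
    generator drives placement, haplotypes, coverage and allele counts
    in a fixed order).
    """
    rng = np.random.default_rng(config.seed)
    if truth is None:
        truth_list = plant_cnvs(config, rng)
    else:
        truth_list = sorted(
            truth, key=lambda e: (list(config.chrom_lengths).index(e.chrom), e.start)
        )
    frames = []
    mean_depth: dict[str, float] = {}
    by_chrom: dict[str, list[TruthCNV]] = {c: [] for c in config.chrom_lengths}
    for t in truth_list:
        if t.chrom not in by_chrom:
            raise SimulationError(f"truth chromosome {t.chrom} not in config")
        by_chrom[t.chrom].append(t)
    for chrom, length in config.chrom_lengths.items():
        df = _simulate_chromosome(chrom, length, by_chrom[chrom], config, rng)
        mean_depth[chrom] = df.attrs["chrom_mean_depth"]
        frames.append(df)
    markers = pd.concat(frames, ignore_index=True)
    track = SignalTrack(sample_id=sample_id, markers=markers, chrom_mean_depth=mean_depth)
    return track, list(truth_list)


def write_truth_bed(truth: Sequence[TruthCNV], stream: TextIO | str) -> None:
    """Write ground truth as BED (0-based half-open, name 'cn=K' or 'loh')."""
    own = isinstance(stream, str)
    fh: TextIO = open(stream, "w") if own else stream  # type: ignore[arg-type]
    try:
        for t in truth:
            name = "loh" if t.is_loh else f"cn={t.copy_number}"
            fh.write(f"{t.chrom}\t{t.start - 1}\t{t.end}\t{name}\t.\n")
    finally:
        if own:
            fh.close()


# ---------------------------------------------------------------------------
# sequence mode
# ---------------------------------------------------------------------------

_BASES = np.frombuffer(b"ACGT", dtype="S1")
_ALT_ROTATE = {"A": "G", "C": "T", "G": "A", "T": "C"}  # transition-biased substitution


def random_reference(chrom_lengths: dict[str, int], seed: int) -> dict[str, str]:
    """Generate a uniform-random reference sequence per chromosome."""
    rng = np.random.default_rng(seed)
    return {
        chrom: rng.choice(_BASES, size=length).tobytes().decode()
        for chrom, length in chrom_lengths.items()
    }


def generate_fasta(
    truth: Sequence[TruthCNV],
    config: SimConfig,
    reference: dict[str, str] | None = None,
) -> tuple[dict[str, str], list[dict]]:
    """Edit a reference into a diploid genome with breakpoint-exact events.

    Applies SNVs per haplotype first, then deletes / tandem-duplicates
    the truth intervals (LOH copies one parent's sequence over the
    other's).  Returns the edited haplotype sequences keyed
    ``{chrom}_maternal`` / ``{chrom}_paternal`` plus a breakpoint table
    in reference coordinates.  Intended for small (<=5 Mb) fixtures.
    """
    rng = np.random.default_rng(config.seed)
    if reference is None:
        reference = random_reference(config.chrom_lengths, config.seed)
    for t in truth:
        if t.chrom not in reference or t.end > len(reference[t.chrom]):
            raise SimulationError(
                f"truth interval {t.chrom}:{t.start}-{t.end} outside reference"
            )
    haplos: dict[str, str] = {}
    breakpoints: list[dict] = []
    for chrom, ref in reference.items():
        sites = simulate_site_frequencies(chrom, len(ref), config.marker_density / 2.0, rng)
        p_mat = sites["freq_EUR"].to_numpy()
        p_pat = sites["freq_AFR"].to_numpy()
        pos = sites["pos"].to_numpy(np.int64)
        seqs = {}
        for hap, p in (("maternal", p_mat), ("paternal", p_pat)):
            carry = pos[rng.random(len(pos)) < p]
            chars = list(ref)
            for q in carry:
                chars[q - 1] = _ALT_ROTATE[chars[q - 1]]
            seqs[hap] = "".join(chars)
        events = sorted(
            (t for t in truth if t.chrom == chrom), key=lambda t: t.start, reverse=True
        )
        for t in events:  # right to left keeps earlier coordinates valid
            s0, s1 = t.start - 1, t.end
            if t.is_loh:
                src = t.parent_of_origin or "maternal"
                dst = "paternal" if src == "maternal" else "maternal"
                seqs[dst] = seqs[dst][:s0] + seqs[src][s0:s1] + seqs[dst][s1:]
                affected = [dst]
            elif t.copy_number == 0:
                for hap in seqs:
                    seqs[hap] = seqs[hap][:s0] + seqs[hap][s1:]
                affected = ["maternal", "paternal"]
            elif t.copy_number == 1:
                hap = "maternal" if rng.random() < 0.5 else "paternal"
                seqs[hap] = seqs[hap][:s0] + seqs[hap][s1:]
                affected = [hap]
            elif t.copy_number == 3:
                hap = "maternal" if rng.random() < 0.5 else "paternal"
                seqs[hap] = seqs[hap][:s1] + seqs[hap][s0:s1] + seqs[hap][s1:]
                affected = [hap]
            elif t.copy_number == 4:
                for hap in seqs:
                    seqs[hap] = seqs[hap][:s1] + seqs[hap][s0:s1] + seqs[hap][s1:]
                affected = ["maternal", "paternal"]
            else:
                continue
            breakpoints.append(
                {
                    "chrom": chrom,
                    "start": t.start,
                    "end": t.end,
                    "copy_number": t.copy_number,
                    "is_loh": t.is_loh,
                    "haplotypes": ",".join(affected),
                }
            )
        for hap, seq in seqs.items():
            haplos[f"{chrom}_{hap}"] = seq
    return haplos, breakpoints


def write_fasta(haplotypes: dict[str, str], stream: TextIO | str, width: int = 60) -> None:
    own = isinstance(stream, str)
    fh: TextIO = open(stream, "w") if own else stream  # type: ignore[arg-type]
    try:
        for name, seq in haplotypes.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
    finally:
        if own:
            fh.close()
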