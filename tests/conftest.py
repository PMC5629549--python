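import numpy as np
import pytest

from seqcnv.signal import center_lrr
from seqcnv.simulate import SimConfig, simulate_signal


@pytest.fixture(scope="session")
def default_sim():
    """One sample at the default study conditions (exact event counts).

    Session-scoped: several tests inspect the same sample, which keeps
    the suite inside a desk-scale time budget.
    Returns (config, raw track, centered track, truth).
    """
    cfg = SimConfig(seed=11, exact_counts=True)
    track, truth = simulate_signal(cfg, sample_id="s11")
    return cfg, track, center_lrr(track), truth


@pytest.fixture()
def small_cfg():
    """A small, fast configuration for unit tests (not the study defaults)."""
    def make(seed=5, **kw):
        defaults = dict(
            chrom_lengths={"chrA": 4_000_000},
            cnv_counts={"CN0": 2, "CN1": 2, "CN3": 2, "CN4": 2, "LOH": 0},
            cnv_length_grid=(50_000, 100_000),
            inter_cnv_distance_mean=50_000.0,
            exact_counts=True,
        )
        defaults.update(kw)
        return SimConfig(seed=seed, **defaults)
    return make


@pytest.fixture()
def pileup_lines():
    """A tiny pileup covering chr1:1000-1009 with one non-reference site."""
    lines = []
    for pos in range(1000, 1010):
        if pos == 1005:
            lines.append(f"chr1\t{pos}\tA\t20\t{'.' * 10}{'G' * 10}\tIIII")
        else:
            lines.append(f"chr1\t{pos}\tC\t20\t{'.' * 12}{',' * 8}\tIIII")
    return lines


@pytest.fixture()
def tiny_vcf(tmp_path):
    path = tmp_path / "sample.vcf"
    path.write_text(
        "##fileformat=VCFv4.2\n"
        '##contig=<ID=chr1,length=2000000>\n'
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"
        "chr1\t1005\t.\tA\tG\t60\tPASS\t.\n"
        "chr1\t1500\t.\tC\tT\t60\tq10\t.\n"  # filtered record
        "chr1\t1600\t.\tC\tCT\t60\tPASS\t.\n"  # indel, not an SNV
    )
    return str(path)


@pytest.fixture()
def popfreq_file(tmp_path):
    path = tmp_path / "freq_EUR.tsv"
    path.write_text(
        "chr1\t1005\tA\tG\t0.45\n"
        "chr1\t1007\tC\tT\t0.10\n"
    )
    return str(path)
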