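"""Shared fixtures: small methylomes, the reference text file, feature sets."""

import pandas as pd
import pytest

import bsmethkit as bk

# Six rows of the per-base text dialect with known coverage/freqC/freqT.
TABLE1_TEXT = (
    "chrBase\tchr\tbase\tstrand\tcoverage\tfreqC\tfreqT\n"
    "chr21.9764539\tchr21\t9764539\tR\t12\t25\t75\n"
    "chr21.9764513\tchr21\t9764513\tR\t12\t0\t100\n"
    "chr21.9820622\tchr21\t9820622\tF\t13\t0\t100\n"
    "chr21.9837545\tchr21\t9837545\tF\t11\t0\t100\n"
    "chr21.9849022\tchr21\t9849022\tF\t124\t72.58\t27.42\n"
    "chr21.9853326\tchr21\t9853326\tF\t17\t70.59\t29.41\n"
)

# (chrom, base, strand, coverage, freqC, freqT) per row, file order.
TABLE1_ROWS = [
    ("chr21", 9764539, "-", 12, 25.0, 75.0),
    ("chr21", 9764513, "-", 12, 0.0, 100.0),
    ("chr21", 9820622, "+", 13, 0.0, 100.0),
    ("chr21", 9837545, "+", 11, 0.0, 100.0),
    ("chr21", 9849022, "+", 124, 72.58, 27.42),
    ("chr21", 9853326, "+", 17, 70.59, 29.41),
]


@pytest.fixture
def table1_path(tmp_path):
    p = tmp_path / "table1.txt"
    p.write_text(TABLE1_TEXT)
    return p


def make_methylome(rows, sample_id="s", treatment=0, context="CpG", resolution="base"):
    """rows: iterable of (chrom, start, n_meth, n_unmeth) or 6-tuples with end/strand."""
    full = []
    for r in rows:
        if len(r) == 4:
            chrom, start, m, u = r
            full.append((chrom, start, start, "+", m, u))
        else:
            full.append(r)
    df = pd.DataFrame(full, columns=["chrom", "start", "end", "strand", "n_meth", "n_unmeth"])
    return bk.SampleMethylome(df, sample_id, treatment, context, resolution)


@pytest.fixture
def two_base_methylome():
    """Bases at 50 (3 meth / 9 unmeth) and 120 (5/5) on chr1."""
    return make_methylome([("chr1", 50, 3, 9), ("chr1", 120, 5, 5)])


@pytest.fixture
def feature_cols():
    return ["chrom", "start", "end", "strand", "name"]


def make_features(rows, kind="custom"):
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "strand", "name"])
    return bk.FeatureSet(df, kind)
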