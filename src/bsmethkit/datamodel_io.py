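"""Core data types and I/O for per-cytosine bisulfite methylation calls.

Methylation levels from bisulfite sequencing are fractions of read-level
cytosine calls: at every covered cytosine a read reports either C (the base
was methylated, hence protected from bisulfite conversion) or T (unmethylated,
converted).  The package-wide containers defined here hold those two counts
per position per sample; percent methylation is always ``100*C/(C+T)``.

Coordinates are 1-based inclusive throughout the package (``start == end`` at
base resolution).  bedGraph export converts to the 0-based half-open
convention of that format.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Literal, Sequence

import numpy as np
import pandas as pd
import pysam

logger = logging.getLogger("bsmethkit")

# -- shared constants --------------------------------------------------------

CONTEXTS = ("CpG", "CHG", "CHH")
STRANDS = ("+", "-", "*")

#: Bismark-style per-read methylation call letters by context.
#: Upper case = methylated, lower case = unmethylated.
XM_LETTERS = {"CpG": ("Z", "z"), "CHG": ("X", "x"), "CHH": ("H", "h")}

#: Columns of the per-base text dialect, in file order.
TEXT_COLUMNS = ("chrBase", "chr", "base", "strand", "coverage", "freqC", "freqT")

#: Tolerance on freqC + freqT == 100 (allows two-decimal rounding in files).
FREQ_SUM_TOL = 0.05

_RECORD_COLUMNS = ["chrom", "start", "end", "strand", "n_meth", "n_unmeth"]


class MethylKitError(Exception):
    """Base error for this package."""


class ParseError(MethylKitError):
    """Malformed input file."""


class ValidationError(MethylKitError):
    """Input violates an invariant of the data model."""


def round_half_up(x) -> np.ndarray:
    """Round to nearest integer with ties going up (0.5 -> 1).

    numpy's default rounds half to even; count reconstruction from
    percentages uses conventional half-up rounding instead.
    """
    return np.floor(np.asarray(x, dtype=float) + 0.5).astype(np.int64)


# -- domain types -------------------------------------------------------------


@dataclass(frozen=True)
class MethylRecord:
    """One cytosine (or region) in one sample."""

    chrom: str
    start: int
    end: int
    strand: str
    n_meth: int
    n_unmeth: int
    context: str = "CpG"

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValidationError("chrom must be non-empty")
        if self.start > self.end:
            raise ValidationError(f"start {self.start} > end {self.end}")
        if self.n_meth < 0 or self.n_unmeth < 0:
            raise ValidationError("counts must be non-negative")
        if self.n_meth + self.n_unmeth < 1:
            raise ValidationError("coverage must be >= 1")
        if self.strand not in STRANDS:
            raise ValidationError(f"strand must be one of {STRANDS}")

    @property
    def coverage(self) -> int:
        return self.n_meth + self.n_unmeth

    @property
    def percent(self) -> float:
        return 100.0 * self.n_meth / self.coverage


@dataclass
class SampleMethylome:
    """All methylation records of one sample.

    The backing store is a DataFrame with columns
    ``chrom, start, end, strand, n_meth, n_unmeth`` sorted by
    ``(chrom, start, strand)`` with unique position keys.

    Parameters
    ----------
    df :
        Record table; copied, coerced and sorted on construction.
    sample_id :
        Free-text sample name.
    treatment :
        Integer group indicator; 0 denotes the control group.
    context :
        Cytosine context, one of ``CpG, CHG, CHH``.
    resolution :
        ``"base"`` for single cytosines, ``"region"`` for summarized units.
    """

    df: pd.DataFrame
    sample_id: str = "sample"
    treatment: int = 0
    context: str = "CpG"
    resolution: Literal["base", "region"] = "base"

    def __post_init__(self) -> None:
        if self.context not in CONTEXTS:
            raise ValidationError(f"unknown context {self.context!r}; expected one of {CONTEXTS}")
        if self.resolution not in ("base", "region"):
            raise ValidationError(f"resolution must be 'base' or 'region', got {self.resolution!r}")
        df = pd.DataFrame(self.df, columns=_RECORD_COLUMNS).copy()
        for col in ("start", "end", "n_meth", "n_unmeth"):
            df[col] = df[col].astype(np.int64)
        df["chrom"] = df["chrom"].astype(str)
        df["strand"] = df["strand"].astype(str)
        if len(df):
            if (df["n_meth"] < 0).any() or (df["n_unmeth"] < 0).any():
                raise ValidationError("negative call counts")
            if ((df["n_meth"] + df["n_unmeth"]) < 1).any():
                raise ValidationError("every record needs coverage >= 1")
            if (df["start"] > df["end"]).any():
                raise ValidationError("start > end in records")
            if not df["strand"].isin(STRANDS).all():
                raise ValidationError(f"strand values must be in {STRANDS}")
            df = df.sort_values(["chrom", "start", "strand"], kind="mergesort")
            dup = df.duplicated(subset=["chrom", "start", "strand"])
            if dup.any():
                first = df[dup].iloc[0]
                raise ValidationError(
                    f"duplicate position key {first['chrom']}:{first['start']}({first['strand']})"
                )
        self.df = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    def __iter__(self) -> Iterator[MethylRecord]:
        for row in self.df.itertuples(index=False):
            yield MethylRecord(
                row.chrom, row.start, row.end, row.strand,
                row.n_meth, row.n_unmeth, self.context,
            )

    @property
    def coverage(self) -> pd.Series:
        return self.df["n_meth"] + self.df["n_unmeth"]

    @property
    def percent(self) -> pd.Series:
        """Percent methylation per record, in [0, 100]."""
        cov = self.coverage
        return 100.0 * self.df["n_meth"] / cov

    def with_records(self, df: pd.DataFrame) -> "SampleMethylome":
        """Same sample metadata, different record table."""
        return SampleMethylome(df, self.sample_id, self.treatment, self.context, self.resolution)


@dataclass(frozen=True)
class FilterPolicy:
    """Coverage and base-quality thresholds for importing and filtering calls.

    Defaults follow common bisulfite practice: at least 10 reads covering a
    base and at least PHRED 20 per call.  ``high_coverage_percentile``
    optionally removes bases whose coverage exceeds that empirical percentile,
    guarding against PCR-duplication (clonal read) artifacts.
    """

    min_coverage: int = 10
    min_base_quality: int = 20
    high_coverage_percentile: float | None = None

    def __post_init__(self) -> None:
        if self.min_coverage < 1:
            raise ValidationError("min_coverage must be >= 1")
        if self.high_coverage_percentile is not None and not (
            0.0 < self.high_coverage_percentile < 100.0
        ):
            raise ValidationError("high_coverage_percentile must be in (0, 100)")


# -- per-base text reader ------------------------------------------------------

_STRAND_MAP = {"F": "+", "R": "-", "+": "+", "-": "-"}


def read_methylation_text(path: str | Path, context: str = "CpG",
                          sample_id: str | None = None,
                          treatment: int = 0) -> SampleMethylome:
    """Read a per-base methylation text file.

    The dialect is tab- (or whitespace-) separated with a header line and
    columns ``chrBase chr base strand coverage freqC freqT``; strand is coded
    F/R (or +/-), and freqC + freqT must sum to 100 within rounding tolerance.
    Methylated counts are reconstructed as
    ``round_half_up(coverage * freqC / 100)``.
    """
    path = Path(path)
    try:
        table = pd.read_csv(path, sep=r"\s+", header=0, dtype=str)
    except pd.errors.EmptyDataError as exc:
        raise ParseError(f"{path}: empty file (missing header)") from exc
    missing = [c for c in TEXT_COLUMNS if c not in table.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing}; expected {list(TEXT_COLUMNS)}")
    if table.isna().any(axis=None):
        bad = int(table.isna().any(axis=1).idxmax()) + 2  # header is line 1
        raise ParseError(f"{path}: malformed row at line {bad} (wrong field count)")
    if len(table) == 0:
        return SampleMethylome(
            pd.DataFrame(columns=_RECORD_COLUMNS),
            sample_id or path.stem, treatment, context, "base",
        )

    try:
        base = table["base"].astype(np.int64)
        coverage = table["coverage"].astype(np.int64)
        freq_c = table["freqC"].astype(float)
        freq_t = table["freqT"].astype(float)
    except ValueError as exc:
        raise ParseError(f"{path}: non-numeric value: {exc}") from exc

    bad_sum = (freq_c + freq_t - 100.0).abs() > FREQ_SUM_TOL
    if bad_sum.any():
        i = int(bad_sum.idxmax())
        raise ValidationError(
            f"{path}: line {i + 2}: freqC + freqT = {freq_c[i] + freq_t[i]:g}, expected 100"
        )
    strand = table["strand"].map(_STRAND_MAP)
    if strand.isna().any():
        i = int(strand.isna().idxmax())
        raise ValidationError(f"{path}: line {i + 2}: unknown strand code {table['strand'][i]!r}")

    n_meth = round_half_up(coverage * freq_c / 100.0)
    df = pd.DataFrame(
        {
            "chrom": table["chr"].astype(str),
            "start": base,
            "end": base,
            "strand": strand,
            "n_meth": n_meth,
            "n_unmeth": coverage.to_numpy() - n_meth,
        }
    )
    return SampleMethylome(df, sample_id or path.stem, treatment, context, "base")


def write_methylation_text(m: SampleMethylome, path: str | Path) -> None:
    """Write a base-resolution methylome back in the per-base text dialect."""
    if m.resolution != "base":
        raise ValidationError("text dialect is base-resolution only")
    cov = m.coverage
    freq_c = (100.0 * m.df["n_meth"] / cov).round(2)
    out = pd.DataFrame(
        {
            "chrBase": m.df["chrom"].astype(str) + "." + m.df["start"].astype(str),
            "chr": m.df["chrom"],
            "base": m.df["start"],
            "strand": m.df["strand"].map({"+": "F", "-": "R", "*": "F"}),
            "coverage": cov,
            "freqC": freq_c,
            "freqT": (100.0 - freq_c).round(2),
        }
    )
    out.to_csv(path, sep="\t", index=False)


# -- Bismark-style SAM reader --------------------------------------------------


def read_bismark_sam(path: str | Path, policy: FilterPolicy | None = None,
                     context: str = "CpG", sample_id: str | None = None,
                     treatment: int = 0) -> SampleMethylome:
    """Count per-cytosine methylation calls from Bismark-style SAM alignments.

    Each aligned read must carry an XM-style methylation call string (tag
    ``XM``) aligned to its bases: ``Z/z`` mark methylated/unmethylated CpG
    calls, ``X/x`` CHG and ``H/h`` CHH.  Calls whose base quality is below
    ``policy.min_base_quality`` are excluded; positions whose remaining
    coverage is below ``policy.min_coverage`` are dropped.  The reported
    strand is the strand of the cytosine (the read's mapping strand).
    """
    if context not in CONTEXTS:
        raise ValidationError(f"unknown context {context!r}")
    policy = policy or FilterPolicy()
    path = Path(path)
    meth_letter, unmeth_letter = XM_LETTERS[context]

    counts: dict[tuple[str, int, str], list[int]] = {}
    n_unmapped = 0
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for read in sam:
            if read.is_unmapped:
                n_unmapped += 1
                continue
            try:
                xm = read.get_tag("XM")
            except KeyError as exc:
                raise ParseError(
                    f"{path}: read {read.query_name!r} lacks the XM methylation call string"
                ) from exc
            quals = read.query_qualities
            strand = "-" if read.is_reverse else "+"
            chrom = read.reference_name
            for qpos, rpos in read.get_aligned_pairs(matches_only=True):
                call = xm[qpos]
                if call == meth_letter:
                    is_meth = True
                elif call == unmeth_letter:
                    is_meth = False
                else:
                    continue
                if quals is not None and quals[qpos] < policy.min_base_quality:
                    continue
                key = (chrom, rpos + 1, strand)  # pysam is 0-based
                pair = counts.setdefault(key, [0, 0])
                pair[0 if is_meth else 1] += 1
    if n_unmapped:
        logger.info("read_bismark_sam: skipped %d unmapped reads in %s", n_unmapped, path)

    rows = [
        (chrom, pos, pos, strand, c[0], c[1])
        for (chrom, pos, strand), c in counts.items()
        if c[0] + c[1] >= policy.min_coverage
    ]
    df = pd.DataFrame(rows, columns=_RECORD_COLUMNS)
    return SampleMethylome(df, sample_id or path.stem, treatment, context, "base")


# -- filtering -----------------------------------------------------------------


def filter_by_coverage(m: SampleMethylome, policy: FilterPolicy) -> SampleMethylome:
    """Apply coverage thresholds to an existing methylome.

    Records below ``min_coverage`` are removed.  When
    ``high_coverage_percentile`` is set, records whose coverage is strictly
    above that empirical percentile of this sample's coverage distribution are
    removed as putative clonal/PCR-duplication artifacts; records exactly at
    the percentile are retained.
    """
    if len(m) == 0:
        return m.with_records(m.df)
    cov = m.coverage.to_numpy()
    keep = cov >= policy.min_coverage
    if policy.high_coverage_percentile is not None:
        cutoff = np.percentile(cov, policy.high_coverage_percentile)
        keep &= cov <= cutoff
    return m.with_records(m.df[keep])


# -- bedGraph writer -----------------------------------------------------------


def write_bedgraph(d: pd.DataFrame, path: str | Path,
                   track: Literal["hyper", "hypo", "all"] = "all",
                   value_column: str = "meth_diff") -> None:
    """Write differential-methylation events as a bedGraph track.

    ``d`` is a DiffTable-style frame with ``chrom, start, end`` (1-based
    inclusive) and a numeric value column (default the methylation difference
    in percentage points).  Output is 0-based half-open per the bedGraph
    standard, preceded by a ``track type=bedGraph`` header.  ``track`` selects
    hypermethylated (value > 0), hypomethylated (value < 0) or all rows.
    """
    if track not in ("hyper", "hypo", "all"):
        raise ValidationError("track must be hyper, hypo or all")
    rows = d
    if track == "hyper":
        rows = d[d[value_column] > 0]
    elif track == "hypo":
        rows = d[d[value_column] < 0]
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f'track type=bedGraph name="methylation diff ({track})"\n')
        for row in rows.itertuples(index=False):
            value = getattr(row, value_column)
            fh.write(f"{row.chrom}\t{row.start - 1}\t{row.end}\t{value:g}\n")
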