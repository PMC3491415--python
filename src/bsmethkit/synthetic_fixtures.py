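"""Synthetic bisulfite data with known ground truth.

Every input the package consumes — per-base methylomes, Bismark-style SAM
alignments, feature BED files — can be generated here with parameters that
mimic a typical reduced-representation bisulfite experiment: read coverage is
negative-binomial around a mean of 30x with an optional clonal
(PCR-duplication) spike, and baseline percent methylation is bimodal, with
roughly 70% of sites nearly unmethylated (< 10%) and 20% nearly fully
methylated (> 90%).  A configurable fraction of sites carries a true
methylation shift in the treatment group, recorded in a truth table so that
downstream calls can be scored.

All generators are pure functions of their spec plus seed (numpy PCG64), so
fixtures are reproducible across machines.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .annotate import FeatureSet
from .datamodel_io import FilterPolicy, SampleMethylome, ValidationError

DEFAULT_CHROM_LENGTHS = {"chr1": 1_000_000, "chr2": 800_000}


@dataclass(frozen=True)
class SimSpec:
    """Parameters of the methylome simulator.

    Coverage per site and sample is negative-binomial with mean
    ``coverage_mean`` and dispersion ``coverage_dispersion`` (variance
    mu + mu^2/dispersion), floored at 1; with probability ``clonal_fraction``
    a site's coverage is drawn instead from a clonal mode with mean
    ``clonal_mean``, emulating PCR-duplication bias.  Baseline methylation is
    a three-part mixture: ``frac_low`` of sites ~ Beta(1, 25) (mostly < 10%),
    ``frac_high`` ~ Beta(25, 1) (mostly > 90%), the remainder uniform on
    [0.2, 0.8].  A fraction ``effect_fraction`` of sites is shifted by
    ``effect_delta`` percentage points in every non-control group (clipped to
    [0, 100]).
    """

    n_sites: int = 1000
    chrom_lengths: dict = field(default_factory=lambda: dict(DEFAULT_CHROM_LENGTHS))
    coverage_mean: float = 30.0
    coverage_dispersion: float = 8.0
    clonal_fraction: float = 0.0
    clonal_mean: float = 300.0
    frac_low: float = 0.7
    frac_high: float = 0.2
    effect_fraction: float = 0.0
    effect_delta: float = 0.0
    samples_per_group: tuple = (1, 1)
    context: str = "CpG"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sites < 1:
            raise ValidationError("n_sites must be >= 1")
        if not self.chrom_lengths:
            raise ValidationError("chrom_lengths must be non-empty")
        if not (0 <= self.frac_low and 0 <= self.frac_high and self.frac_low + self.frac_high <= 1):
            raise ValidationError("mixture fractions must be probabilities summing to <= 1")
        if not (0 <= self.effect_fraction <= 1):
            raise ValidationError("effect_fraction must be in [0, 1]")
        if not (-100 <= self.effect_delta <= 100):
            raise ValidationError("effect_delta must be in [-100, 100]")
        if self.coverage_mean <= 0 or self.coverage_dispersion <= 0:
            raise ValidationError("coverage model parameters must be positive")
        if len(self.samples_per_group) < 1 or any(k < 1 for k in self.samples_per_group):
            raise ValidationError("samples_per_group needs >= 1 sample per listed group")


def _site_positions(spec: SimSpec, rng: np.random.Generator) -> pd.DataFrame:
    lengths = spec.chrom_lengths
    chroms = list(lengths)
    weights = np.array([lengths[c] for c in chroms], dtype=float)
    counts = rng.multinomial(spec.n_sites, weights / weights.sum())
    rows = []
    for chrom, k in zip(chroms, counts):
        k = int(min(k, lengths[chrom]))
        pos = np.sort(rng.choice(np.arange(1, lengths[chrom] + 1), size=k, replace=False))
        rows.append(pd.DataFrame({"chrom": chrom, "pos": pos}))
    return pd.concat(rows, ignore_index=True)


def _draw_coverage(spec: SimSpec, rng: np.random.Generator, size: int) -> np.ndarray:
    r = spec.coverage_dispersion

    def nb(mean, n):
        return rng.negative_binomial(r, r / (r + mean), size=n)

    cov = nb(spec.coverage_mean, size)
    if spec.clonal_fraction > 0:
        clonal = rng.random(size) < spec.clonal_fraction
        cov[clonal] = nb(spec.clonal_mean, int(clonal.sum()))
    return np.maximum(cov, 1).astype(np.int64)


def simulate_methylomes(spec: SimSpec) -> tuple[list[SampleMethylome], pd.DataFrame]:
    """Simulate per-sample base-resolution methylomes plus a truth table.

    Returns ``(samples, truth)`` where ``truth`` has one row per site with
    its baseline proportion, whether it carries a true effect, and the
    per-group true proportions.  ``n_meth`` for each site/sample is binomial
    in the site's group proportion; determinism is guaranteed by the spec
    seed.
    """
    rng = np.random.default_rng(spec.seed)
    sites = _site_positions(spec, rng)
    n = len(sites)

    mix = rng.random(n)
    p0 = np.empty(n)
    low = mix < spec.frac_low
    high = mix >= 1.0 - spec.frac_high
    mid = ~(low | high)
    p0[low] = rng.beta(1.0, 25.0, int(low.sum()))
    p0[high] = rng.beta(25.0, 1.0, int(high.sum()))
    p0[mid] = rng.uniform(0.2, 0.8, int(mid.sum()))

    affected = rng.random(n) < spec.effect_fraction
    p1 = np.clip(p0 + np.where(affected, spec.effect_delta / 100.0, 0.0), 0.0, 1.0)

    truth = sites.copy()
    truth["strand"] = "+"
    truth["affected"] = affected
    truth["p_control"] = p0
    truth["p_treatment"] = p1

    samples: list[SampleMethylome] = []
    for group, k in enumerate(spec.samples_per_group):
        p_group = p0 if group == 0 else p1
        for rep in range(k):
            cov = _draw_coverage(spec, rng, n)
            n_meth = rng.binomial(cov, p_group)
            df = pd.DataFrame(
                {
                    "chrom": sites["chrom"],
                    "start": sites["pos"],
                    "end": sites["pos"],
                    "strand": "+",
                    "n_meth": n_meth,
                    "n_unmeth": cov - n_meth,
                }
            )
            samples.append(
                SampleMethylome(df, f"g{group}_r{rep}", group, spec.context, "base")
            )
    return samples, truth


# -- SAM simulation ------------------------------------------------------------

_XM_BY_CONTEXT = {"CpG": ("Z", "z"), "CHG": ("X", "x"), "CHH": ("H", "h")}


def simulate_sam(sites: pd.DataFrame, path: str | Path,
                 context: str = "CpG",
                 chrom_lengths: dict | None = None,
                 read_length: int = 6,
                 base_quality: int = 40,
                 low_quality: int = 10,
                 n_unmapped: int = 0) -> None:
    """Write a Bismark-style SAM file realizing specified per-site calls.

    ``sites`` columns: ``chrom, pos, strand, n_meth, n_unmeth`` plus optional
    ``n_lowq_meth, n_lowq_unmeth`` for calls emitted with ``low_quality``
    (below the default PHRED-20 cutoff, so a compliant reader must drop
    them).  One single-end read per call, with the cytosine at the first
    aligned base and an XM call string of dots elsewhere.
    """
    if context not in _XM_BY_CONTEXT:
        raise ValidationError(f"unknown context {context!r}")
    meth_letter, unmeth_letter = _XM_BY_CONTEXT[context]
    chroms = chrom_lengths or {
        c: int(sites[sites["chrom"] == c]["pos"].max()) + read_length + 10
        for c in sites["chrom"].unique()
    }
    hi_q = chr(base_quality + 33)
    lo_q = chr(low_quality + 33)

    lines = ["@HD\tVN:1.6\tSO:unsorted"]
    for chrom, length in chroms.items():
        lines.append(f"@SQ\tSN:{chrom}\tLN:{length}")

    def read_line(idx, chrom, pos, strand, letter, qual_char):
        flag = 16 if strand == "-" else 0
        seq = ("C" + "A" * (read_length - 1)) if letter.isupper() else ("T" + "A" * (read_length - 1))
        qual = qual_char + hi_q * (read_length - 1)
        xm = letter + "." * (read_length - 1)
        return (
            f"r{idx}\t{flag}\t{chrom}\t{pos}\t42\t{read_length}M\t*\t0\t0\t{seq}\t{qual}\tXM:Z:{xm}"
        )

    idx = 0
    for row in sites.itertuples(index=False):
        plan = [
            (meth_letter, hi_q, int(row.n_meth)),
            (unmeth_letter, hi_q, int(row.n_unmeth)),
            (meth_letter, lo_q, int(getattr(row, "n_lowq_meth", 0) or 0)),
            (unmeth_letter, lo_q, int(getattr(row, "n_lowq_unmeth", 0) or 0)),
        ]
        for letter, qc, count in plan:
            for _ in range(count):
                lines.append(read_line(idx, row.chrom, int(row.pos), row.strand, letter, qc))
                idx += 1
    for _ in range(n_unmapped):
        lines.append(f"r{idx}\t4\t*\t0\t0\t*\t*\t0\t0\t{'A' * read_length}\t{hi_q * read_length}")
        idx += 1
    Path(path).write_text("\n".join(lines) + "\n")


def expected_from_sam_sites(sites: pd.DataFrame, policy: FilterPolicy | None = None,
                            context: str = "CpG",
                            sample_id: str = "expected") -> SampleMethylome:
    """Ground-truth methylome a compliant SAM reader must recover.

    Low-quality calls are excluded; sites whose remaining coverage falls
    below ``policy.min_coverage`` are absent.
    """
    policy = policy or FilterPolicy()
    keep = (sites["n_meth"] + sites["n_unmeth"]) >= policy.min_coverage
    kept = sites[keep]
    df = pd.DataFrame(
        {
            "chrom": kept["chrom"],
            "start": kept["pos"],
            "end": kept["pos"],
            "strand": kept["strand"],
            "n_meth": kept["n_meth"],
            "n_unmeth": kept["n_unmeth"],
        }
    )
    return SampleMethylome(df, sample_id, 0, context, "base")


# -- feature simulation --------------------------------------------------------


def simulate_features(chrom_lengths: dict | None = None,
                      n_genes: int = 20, n_islands: int = 15,
                      n_custom: int = 10, seed: int = 0) -> dict[str, FeatureSet]:
    """Generate non-degenerate gene models, CpG islands and custom regions.

    Per gene: a TSS (random strand), a promoter spanning TSS +/- 1000 bp and
    an alternating exon/intron structure downstream of the TSS.  Islands and
    custom regions are random intervals.  Returns a dict with keys
    ``tss, promoter, exon, intron, cpg_island, custom``.
    """
    rng = np.random.default_rng(seed)
    lengths = chrom_lengths or dict(DEFAULT_CHROM_LENGTHS)
    chroms = list(lengths)

    def rand_chrom():
        return chroms[int(rng.integers(len(chroms)))]

    tss_rows, prom_rows, exon_rows, intron_rows = [], [], [], []
    for i in range(n_genes):
        chrom = rand_chrom()
        tss = int(rng.integers(5000, lengths[chrom] - 20000))
        strand = "+" if rng.random() < 0.5 else "-"
        name = f"gene{i}"
        tss_rows.append((chrom, tss, tss, strand, name))
        prom_rows.append((chrom, max(1, tss - 1000), tss + 1000, strand, name))
        pos = tss
        for j in range(int(rng.integers(2, 5))):
            exon_len = int(rng.integers(100, 400))
            intron_len = int(rng.integers(500, 2000))
            exon_rows.append((chrom, pos, pos + exon_len - 1, strand, f"{name}_exon{j}"))
            pos += exon_len
            intron_rows.append((chrom, pos, pos + intron_len - 1, strand, f"{name}_intron{j}"))
            pos += intron_len

    def rand_intervals(n, min_len, max_len, prefix):
        rows = []
        for i in range(n):
            chrom = rand_chrom()
            length = int(rng.integers(min_len, max_len))
            start = int(rng.integers(1, lengths[chrom] - length))
            rows.append((chrom, start, start + length - 1, "*", f"{prefix}{i}"))
        return rows

    cols = ["chrom", "start", "end", "strand", "name"]
    return {
        "tss": FeatureSet(pd.DataFrame(tss_rows, columns=cols), "tss"),
        "promoter": FeatureSet(pd.DataFrame(prom_rows, columns=cols), "promoter"),
        "exon": FeatureSet(pd.DataFrame(exon_rows, columns=cols), "exon"),
        "intron": FeatureSet(pd.DataFrame(intron_rows, columns=cols), "intron"),
        "cpg_island": FeatureSet(
            pd.DataFrame(rand_intervals(n_islands, 300, 2000, "cgi"), columns=cols), "cpg_island"
        ),
        "custom": FeatureSet(
            pd.DataFrame(rand_intervals(n_custom, 500, 5000, "enh"), columns=cols), "custom"
        ),
    }
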