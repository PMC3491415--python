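"""Joining samples on commonly covered units and regional summarization.

Cross-sample statistics (correlation, clustering, differential testing) are
only meaningful on cytosines covered in every sample, so the central container
here, :class:`UnitedMethylome`, is a complete-case join: the unit set is the
intersection of position keys across samples, never an imputed union.

Base-level calls can also be summarized over fixed tiling windows or
user-supplied regions before joining; counts are summed over the cytosines a
window/region contains, which weights each base by its coverage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from functools import reduce
from typing import Sequence

import numpy as np
import pandas as pd

from .datamodel_io import SampleMethylome, ValidationError

logger = logging.getLogger("bsmethkit")

_KEY = ["chrom", "start", "end", "strand"]


@dataclass(frozen=True)
class TilingSpec:
    """Genome tiling parameters: window size and step, both in bp (>= 1)."""

    window_size: int = 1000
    step_size: int = 1000

    def __post_init__(self) -> None:
        if self.window_size < 1 or self.step_size < 1:
            raise ValidationError("window_size and step_size must be >= 1")


@dataclass
class UnitedMethylome:
    """Matrix-like join of N samples on units covered in all of them.

    ``df`` holds one row per unit with key columns ``chrom, start, end,
    strand`` followed by ``n_meth_<sample>, n_unmeth_<sample>`` count pairs in
    sample order.  Every unit has coverage >= 1 in every sample.
    """

    df: pd.DataFrame
    samples: list[str]
    treatments: list[int]
    context: str = "CpG"
    resolution: str = "base"

    def __post_init__(self) -> None:
        if len(self.samples) != len(self.treatments):
            raise ValidationError("treatments length must equal number of samples")
        if len(set(self.samples)) != len(self.samples):
            raise ValidationError("duplicate sample ids")

    def __len__(self) -> int:
        return len(self.df)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def counts(self, sample: str) -> tuple[np.ndarray, np.ndarray]:
        """(n_meth, n_unmeth) arrays for one sample, in unit order."""
        return (
            self.df[f"n_meth_{sample}"].to_numpy(),
            self.df[f"n_unmeth_{sample}"].to_numpy(),
        )

    def percent_matrix(self) -> pd.DataFrame:
        """Units x samples matrix of percent methylation (no missing cells)."""
        cols = {}
        for s in self.samples:
            meth, unmeth = self.counts(s)
            cols[s] = 100.0 * meth / (meth + unmeth)
        index = (
            self.df["chrom"].astype(str)
            + ":" + self.df["start"].astype(str)
            + "-" + self.df["end"].astype(str)
            + "(" + self.df["strand"].astype(str) + ")"
        )
        return pd.DataFrame(cols, index=index)

    def treatment_groups(self) -> dict[int, list[str]]:
        groups: dict[int, list[str]] = {}
        for s, t in zip(self.samples, self.treatments):
            groups.setdefault(int(t), []).append(s)
        return groups


def unite(samples: Sequence[SampleMethylome]) -> UnitedMethylome:
    """Join samples on the intersection of their covered units.

    All samples must share context and resolution.  Counts are carried over
    unchanged; the unit order is sorted by position.  An empty intersection is
    valid (a warning is logged).
    """
    if not samples:
        raise ValidationError("unite needs at least one sample")
    contexts = {m.context for m in samples}
    if len(contexts) > 1:
        raise ValidationError(f"mixed contexts: {sorted(contexts)}")
    resolutions = {m.resolution for m in samples}
    if len(resolutions) > 1:
        raise ValidationError(f"mixed resolutions: {sorted(resolutions)}")

    frames = []
    for m in samples:
        f = m.df[_KEY + ["n_meth", "n_unmeth"]].rename(
            columns={"n_meth": f"n_meth_{m.sample_id}", "n_unmeth": f"n_unmeth_{m.sample_id}"}
        )
        frames.append(f)
    joined = reduce(lambda a, b: a.merge(b, on=_KEY, how="inner"), frames)
    joined = joined.sort_values(["chrom", "start", "strand"], kind="mergesort").reset_index(drop=True)
    if len(joined) == 0:
        logger.warning("unite: no unit is covered in all %d samples", len(samples))
    return UnitedMethylome(
        joined,
        samples=[m.sample_id for m in samples],
        treatments=[m.treatment for m in samples],
        context=samples[0].context,
        resolution=samples[0].resolution,
    )


def tile(m: SampleMethylome, spec: TilingSpec, min_bases: int = 1) -> SampleMethylome:
    """Summarize a base-resolution methylome over tiling windows.

    Windows are laid per chromosome anchored at position 1: window ``w``
    (0-based) spans ``[w*step + 1, w*step + window]`` (1-based inclusive).
    A window's counts are the sums over the covered cytosines it contains,
    strand-agnostic (window strand ``*``); windows holding fewer than
    ``min_bases`` covered cytosines are omitted.  With ``step < window`` a
    base falls into several windows and is deliberately counted in each.
    """
    if m.resolution != "base":
        raise ValidationError("tile expects a base-resolution methylome")
    if min_bases < 1:
        raise ValidationError("min_bases must be >= 1")
    w, s = spec.window_size, spec.step_size
    pieces = []
    for chrom, grp in m.df.groupby("chrom", sort=False):
        pos = grp["start"].to_numpy()
        # window indices covering each base: ceil((pos-w)/s) .. floor((pos-1)/s)
        lo = np.maximum(0, -(-(pos - w) // s))
        hi = (pos - 1) // s
        reps = (hi - lo + 1).astype(np.int64)
        widx = np.concatenate([np.arange(a, b + 1) for a, b in zip(lo, hi)]) if len(pos) else np.array([], dtype=np.int64)
        meth = np.repeat(grp["n_meth"].to_numpy(), reps)
        unmeth = np.repeat(grp["n_unmeth"].to_numpy(), reps)
        agg = pd.DataFrame({"w": widx, "n_meth": meth, "n_unmeth": unmeth}).groupby("w").agg(
            n_meth=("n_meth", "sum"), n_unmeth=("n_unmeth", "sum"), n_bases=("n_meth", "size")
        )
        agg = agg[agg["n_bases"] >= min_bases].reset_index()
        pieces.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "start": agg["w"] * s + 1,
                    "end": agg["w"] * s + w,
                    "strand": "*",
                    "n_meth": agg["n_meth"],
                    "n_unmeth": agg["n_unmeth"],
                }
            )
        )
    df = pd.concat(pieces, ignore_index=True) if pieces else pd.DataFrame(
        columns=["chrom", "start", "end", "strand", "n_meth", "n_unmeth"]
    )
    return SampleMethylome(df, m.sample_id, m.treatment, m.context, "region")


def summarize_regions(m: SampleMethylome, regions) -> SampleMethylome:
    """Summarize base-level calls over user-supplied regions.

    ``regions`` is a :class:`~bsmethkit.annotate.FeatureSet` (or any frame
    with ``chrom, start, end, strand`` 1-based inclusive intervals).  Counts
    are summed over the covered cytosines inside each region; regions with no
    covered cytosine are omitted.  A base inside two overlapping regions
    contributes to both.
    """
    if m.resolution != "base":
        raise ValidationError("summarize_regions expects a base-resolution methylome")
    rdf = regions.df if hasattr(regions, "df") else pd.DataFrame(regions)
    rows = []
    for chrom, grp in rdf.groupby("chrom", sort=False):
        bases = m.df[m.df["chrom"] == chrom]
        if len(bases) == 0:
            continue
        pos = bases["start"].to_numpy()
        meth = bases["n_meth"].to_numpy()
        unmeth = bases["n_unmeth"].to_numpy()
        csum_m = np.concatenate([[0], np.cumsum(meth)])
        csum_u = np.concatenate([[0], np.cumsum(unmeth)])
        lo = np.searchsorted(pos, grp["start"].to_numpy(), side="left")
        hi = np.searchsorted(pos, grp["end"].to_numpy(), side="right")
        for (row, a, b) in zip(grp.itertuples(index=False), lo, hi):
            if b <= a:
                continue
            rows.append(
                (
                    chrom, row.start, row.end,
                    getattr(row, "strand", "*") or "*",
                    int(csum_m[b] - csum_m[a]), int(csum_u[b] - csum_u[a]),
                )
            )
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "strand", "n_meth", "n_unmeth"])
    return SampleMethylome(df, m.sample_id, m.treatment, m.context, "region")
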