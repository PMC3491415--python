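"""Genomic-context annotation of differential methylation events.

Differentially methylated cytosines/regions are interpreted through their
position relative to gene models and CpG islands: distance to the nearest
transcription start site (TSS), membership in promoter/exon/intron/intergenic
compartments, and membership in CpG islands versus their shores (the 2 kb
flanks, where methylation is most variable) versus everything else.  Custom
region sets (enhancers, repeats, ...) are supported as a simple
inside/outside annotation.

All feature coordinates are 1-based inclusive internally; BED input (0-based
half-open) is converted on read.  Strand is ignored for overlap — methylation
events hit features on either strand — and used only to sign TSS distances.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .datamodel_io import ValidationError

logger = logging.getLogger("bsmethkit")

FEATURE_KINDS = ("tss", "promoter", "exon", "intron", "cpg_island", "custom")

#: Default CpG island shore width in bp.
DEFAULT_SHORE_FLANK = 2000
#: Default promoter extent around the TSS in bp (the field has no single
#: convention; +/- 1 kb is a common choice and is configurable).
DEFAULT_PROMOTER_FLANK = 1000


@dataclass
class FeatureSet:
    """Strand-aware genomic intervals of one kind.

    ``df`` columns: ``chrom, start, end, strand, name`` with 1-based
    inclusive coordinates and ``start <= end``.
    """

    df: pd.DataFrame
    kind: str = "custom"

    def __post_init__(self) -> None:
        if self.kind not in FEATURE_KINDS:
            raise ValidationError(f"kind must be one of {FEATURE_KINDS}")
        df = pd.DataFrame(self.df, columns=["chrom", "start", "end", "strand", "name"]).copy()
        if len(df):
            df["start"] = df["start"].astype(np.int64)
            df["end"] = df["end"].astype(np.int64)
            df["strand"] = df["strand"].fillna("*").astype(str)
            df["name"] = df["name"].fillna("").astype(str)
            if (df["start"] > df["end"]).any():
                raise ValidationError("feature start > end")
            if (df["start"] < 1).any():
                raise ValidationError("features are 1-based; start must be >= 1")
        self.df = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    @classmethod
    def from_bed(cls, path: str | Path, kind: str = "custom") -> "FeatureSet":
        """Read BED (0-based half-open; optional name/score/strand columns)."""
        names = ["chrom", "start0", "end", "name", "score", "strand"]
        try:
            bed = pd.read_csv(path, sep="\t", header=None, comment="#",
                              names=names, usecols=range(6), engine="python")
        except pd.errors.EmptyDataError:
            return cls(pd.DataFrame(columns=["chrom", "start", "end", "strand", "name"]), kind)
        bed = bed.dropna(subset=["chrom", "start0", "end"])
        df = pd.DataFrame(
            {
                "chrom": bed["chrom"].astype(str),
                "start": bed["start0"].astype(np.int64) + 1,
                "end": bed["end"].astype(np.int64),
                "strand": bed["strand"].where(bed["strand"].isin(["+", "-"]), "*"),
                "name": bed["name"].fillna(""),
            }
        )
        return cls(df, kind)

    def to_bed(self, path: str | Path) -> None:
        out = pd.DataFrame(
            {
                "chrom": self.df["chrom"],
                "start0": self.df["start"] - 1,
                "end": self.df["end"],
                "name": self.df["name"].replace("", "."),
                "score": 0,
                "strand": self.df["strand"].replace("*", "."),
            }
        )
        out.to_csv(path, sep="\t", header=False, index=False)

    def trees(self) -> dict[str, IntervalTree]:
        """Per-chromosome interval trees (half-open internal representation)."""
        trees: dict[str, IntervalTree] = {}
        for row in self.df.itertuples(index=False):
            trees.setdefault(row.chrom, IntervalTree()).addi(row.start, row.end + 1, row.name)
        return trees


@dataclass
class AnnotationSummary:
    """Per-event labels plus category percentages (summing to 100)."""

    assignments: pd.DataFrame   # event keys + 'label' column
    percentages: dict[str, float]

    def __post_init__(self) -> None:
        total = sum(self.percentages.values())
        if self.percentages and abs(total - 100.0) > 0.1:
            raise ValidationError(f"category percentages sum to {total}, expected 100")


def _event_frame(events) -> pd.DataFrame:
    df = events.df if hasattr(events, "df") else pd.DataFrame(events)
    return df[["chrom", "start", "end", "strand"]].reset_index(drop=True)


def _overlaps(ev: pd.DataFrame, feats: FeatureSet) -> np.ndarray:
    """Boolean any-overlap flag per event (strand-blind, 1-based inclusive)."""
    trees = feats.trees()
    out = np.zeros(len(ev), dtype=bool)
    for i, row in enumerate(ev.itertuples(index=False)):
        tree = trees.get(row.chrom)
        if tree is not None and tree.overlap(row.start, row.end + 1):
            out[i] = True
    return out


def _percentages(labels: pd.Series, categories) -> dict[str, float]:
    n = len(labels)
    if n == 0:
        return {}
    return {c: 100.0 * float((labels == c).sum()) / n for c in categories}


# -- operations ----------------------------------------------------------------


def nearest_tss(events, tss: FeatureSet) -> pd.DataFrame:
    """Signed distance from each event to the nearest TSS.

    Distance = event position - TSS position, with the sign flipped for
    TSSs on the - strand so that positive always means downstream of the
    TSS.  Nearest is by absolute distance; ties are broken by the lower TSS
    coordinate, then by name.  Events on chromosomes absent from the TSS set
    get NaN distances (logged).
    """
    if len(tss) == 0:
        raise ValidationError("TSS set is empty")
    ev = _event_frame(events)
    by_chrom: dict[str, pd.DataFrame] = {}
    for chrom, grp in tss.df.groupby("chrom"):
        by_chrom[chrom] = grp.sort_values(["start", "name"]).reset_index(drop=True)

    distances = np.full(len(ev), np.nan)
    names = np.full(len(ev), "", dtype=object)
    n_missing = 0
    for i, row in enumerate(ev.itertuples(index=False)):
        cand = by_chrom.get(row.chrom)
        if cand is None:
            n_missing += 1
            continue
        pos = row.start  # point events; region events use their start
        tss_pos = cand["start"].to_numpy()
        absd = np.abs(pos - tss_pos)
        best = np.flatnonzero(absd == absd.min())[0]  # lowest coord, then name
        t = cand.iloc[best]
        d = pos - int(t["start"])
        if t["strand"] == "-":
            d = -d
        distances[i] = d
        names[i] = t["name"]
    if n_missing:
        logger.warning("nearest_tss: %d events on chromosomes absent from the TSS set", n_missing)
    out = ev.copy()
    out["dist_to_tss"] = distances
    out["tss_name"] = names
    return out


def annotate_gene_parts(events, promoters: FeatureSet, exons: FeatureSet,
                        introns: FeatureSet) -> AnnotationSummary:
    """Assign each event one gene-part label.

    Any-overlap with precedence promoter > exon > intron; events overlapping
    none are intergenic.  The labels partition the events, so the summary
    percentages sum to 100.
    """
    ev = _event_frame(events)
    labels = np.full(len(ev), "intergenic", dtype=object)
    for kind, feats in (("intron", introns), ("exon", exons), ("promoter", promoters)):
        labels[_overlaps(ev, feats)] = kind
    ev["label"] = labels
    return AnnotationSummary(ev, _percentages(ev["label"], ["promoter", "exon", "intron", "intergenic"]))


def shores_of(islands: FeatureSet, flank: int = DEFAULT_SHORE_FLANK) -> FeatureSet:
    """The two ``flank``-bp shores of every CpG island, clipped at position 1."""
    rows = []
    for row in islands.df.itertuples(index=False):
        left_start = max(1, row.start - flank)
        if left_start <= row.start - 1:
            rows.append((row.chrom, left_start, row.start - 1, row.strand, f"{row.name}_shoreL"))
        rows.append((row.chrom, row.end + 1, row.end + flank, row.strand, f"{row.name}_shoreR"))
    return FeatureSet(
        pd.DataFrame(rows, columns=["chrom", "start", "end", "strand", "name"]), "custom"
    )


def annotate_cpg(events, islands: FeatureSet,
                 shore_flank: int = DEFAULT_SHORE_FLANK) -> AnnotationSummary:
    """Label events as CpG island / shore / other.

    Shores are the ``shore_flank``-bp intervals on both sides of each island,
    clipped at position 1.  Precedence island > shore > other, so an event
    inside an island is never counted as a shore of a neighboring island.
    """
    ev = _event_frame(events)
    labels = np.full(len(ev), "other", dtype=object)
    labels[_overlaps(ev, shores_of(islands, shore_flank))] = "shore"
    labels[_overlaps(ev, islands)] = "island"
    ev["label"] = labels
    return AnnotationSummary(ev, _percentages(ev["label"], ["island", "shore", "other"]))


def annotate_custom(events, regions: FeatureSet) -> AnnotationSummary:
    """Inside/outside annotation against a user-supplied region set."""
    ev = _event_frame(events)
    inside = _overlaps(ev, regions)
    ev["label"] = np.where(inside, "inside", "outside")
    return AnnotationSummary(ev, _percentages(ev["label"], ["inside", "outside"]))
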