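"""Per-SE genomic/epigenomic features from tracks and cluster files.

Tracks are bedGraph-like text (chrom, start, end, value); SPRITE
clusters are one-per-line text records.  Genomic distances for tether
metrics are in megabases and restricted to cis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .locus_model_io import SELocus

logger = logging.getLogger(__name__)

SPECKLE_RNAS = frozenset({"Malat1", "U1.snRNA", "U2.snRNA", "U4.snRNA", "U6.snRNA"})
MB = 1_000_000


class TrackError(ValueError):
    pass


@dataclass
class GenomicTrack:
    """bedGraph-like signal: non-overlapping (chrom, start, end, value)."""

    intervals: pd.DataFrame  # columns chrom, start, end, value
    genome_build: str = "mm10"

    def __post_init__(self) -> None:
        need = {"chrom", "start", "end", "value"}
        if not need.issubset(self.intervals.columns):
            raise TrackError(f"track requires columns {sorted(need)}")
        if not np.isfinite(self.intervals["value"]).all():
            raise TrackError("track values must be finite")
        df = self.intervals.sort_values(["chrom", "start"]).reset_index(drop=True)
        overlap = (df["chrom"] == df["chrom"].shift()) & (df["start"] < df["end"].shift())
        if overlap.any():
            raise TrackError("track intervals overlap after sorting")
        self.intervals = df

    @property
    def total_signal(self) -> float:
        iv = self.intervals
        return float((iv["value"] * (iv["end"] - iv["start"])).sum())

    @classmethod
    def read_bedgraph(cls, path: str | Path, genome_build: str = "mm10") -> "GenomicTrack":
        df = pd.read_csv(
            path, sep="\t", comment="#", header=None,
            names=["chrom", "start", "end", "value"],
            dtype={"chrom": str},
        )
        return cls(intervals=df, genome_build=genome_build)

    def write_bedgraph(self, path: str | Path) -> None:
        self.intervals.to_csv(path, sep="\t", header=False, index=False)


def coverage_over_intervals(
    track: GenomicTrack,
    loci: Sequence[SELocus],
    normalize: bool = True,
    genome_build: str | None = None,
) -> pd.Series:
    """Sum of value x overlap-length over each SE interval.

    With ``normalize=True`` values are scaled to signal-per-million of
    the track's total signal (library-size normalization).
    """
    if genome_build is not None and genome_build != track.genome_build:
        raise TrackError(
            f"genome build mismatch: track {track.genome_build}, loci {genome_build}"
        )
    by_chrom = {c: g for c, g in track.intervals.groupby("chrom", sort=False)}
    out = {}
    for l in loci:
        g = by_chrom.get(l.chrom)
        if g is None:
            out[l.se_id] = 0.0
            continue
        starts = g["start"].to_numpy()
        ends = g["end"].to_numpy()
        vals = g["value"].to_numpy()
        ov = np.minimum(ends, l.end) - np.maximum(starts, l.start)
        ov = np.clip(ov, 0, None)
        out[l.se_id] = float((vals * ov).sum())
    cov = pd.Series(out, name="coverage")
    if normalize:
        total = track.total_signal
        if total <= 0:
            raise TrackError("cannot normalize: track total signal is zero")
        cov = cov / total * 1e6
    return cov


def damid_window_score(
    track: GenomicTrack, loci: Sequence[SELocus], window: int = 30_000
) -> pd.Series:
    """Mean binned value in a window centered on the largest-overlap bin.

    The track must be uniformly binned; bins whose center falls within
    window/2 of the anchor bin's center are averaged.  SEs with no
    overlapping bin get NaN (flagged via log).
    """
    widths = track.intervals["end"] - track.intervals["start"]
    bin_size = int(widths.mode().iloc[0])
    by_chrom = {c: g.reset_index(drop=True) for c, g in track.intervals.groupby("chrom", sort=False)}
    out = {}
    for l in loci:
        g = by_chrom.get(l.chrom)
        if g is None:
            out[l.se_id] = np.nan
            logger.warning("SE %s: no bins on %s", l.se_id, l.chrom)
            continue
        ov = np.clip(
            np.minimum(g["end"].to_numpy(), l.end) - np.maximum(g["start"].to_numpy(), l.start),
            0, None,
        )
        if ov.max() <= 0:
            out[l.se_id] = np.nan
            logger.warning("SE %s: no overlapping bin", l.se_id)
            continue
        anchor = int(np.argmax(ov))  # first maximal-overlap bin wins ties
        centers = (g["start"].to_numpy() + g["end"].to_numpy()) / 2.0
        sel = np.abs(centers - centers[anchor]) <= window / 2.0
        out[l.se_id] = float(g["value"].to_numpy()[sel].mean())
    return pd.Series(out, name="damid_window")


@dataclass
class SpriteCluster:
    barcode: str
    rnas: frozenset[str]
    dna_reads: tuple[tuple[str, int], ...]  # (chrom, position)

    @property
    def n_dna(self) -> int:
        return len(self.dna_reads)


def read_sprite_clusters(path: str | Path) -> list[SpriteCluster]:
    """Parse the simple cluster text format.

    One cluster per line: ``barcode<TAB>rna1,rna2<TAB>chr1:100,chr2:200``
    (RNA field may be empty).
    """
    clusters = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise TrackError(f"{path}:{lineno}: expected 3 tab-separated fields")
            barcode, rna_s, dna_s = parts
            rnas = frozenset(r for r in rna_s.split(",") if r)
            reads = []
            for tok in dna_s.split(","):
                if not tok:
                    continue
                chrom, _, p = tok.partition(":")
                reads.append((chrom, int(p)))
            if not reads and not rnas:
                raise TrackError(f"{path}:{lineno}: empty cluster")
            clusters.append(SpriteCluster(barcode, rnas, tuple(reads)))
    if not clusters:
        raise TrackError(f"{path}: empty cluster file")
    return clusters


def filter_speckle_clusters(
    clusters: Iterable[SpriteCluster],
    speckle_rnas: frozenset[str] = SPECKLE_RNAS,
    max_dna: int = 100,
) -> list[SpriteCluster]:
    """Keep clusters with >= 1 speckle RNA and <= max_dna DNA loci.

    The two filters commute; order is RNA filter then size filter.
    """
    return [
        cl for cl in clusters
        if cl.rnas & speckle_rnas and cl.n_dna <= max_dna
    ]


def speckle_association(
    clusters: Iterable[SpriteCluster],
    speckle_rnas: frozenset[str] = SPECKLE_RNAS,
    max_dna: int = 100,
    bin_size: int = 250_000,
    loci: Sequence[SELocus] | None = None,
) -> pd.Series:
    """Unique speckle-cluster DNA reads summed per genomic bin.

    Returns per-bin counts indexed by (chrom, bin_start); with ``loci``
    given, returns instead the per-SE value of the largest-overlap bin.
    """
    kept = filter_speckle_clusters(clusters, speckle_rnas, max_dna)
    counts: dict[tuple[str, int], int] = {}
    for cl in kept:
        for chrom, p in set(cl.dna_reads):  # unique reads within a cluster
            key = (chrom, (p // bin_size) * bin_size)
            counts[key] = counts.get(key, 0) + 1
    bins = pd.Series(counts, name="speckle_reads").sort_index()
    if loci is None:
        return bins
    out = {}
    for l in loci:
        best_bin, best_ov = None, 0
        first = (l.start // bin_size) * bin_size
        b = first
        while b < l.end:
            ov = min(l.end, b + bin_size) - max(l.start, b)
            if ov > best_ov:
                best_ov, best_bin = ov, b
            b += bin_size
        out[l.se_id] = float(counts.get((l.chrom, best_bin), 0)) if best_bin is not None else 0.0
    return pd.Series(out, name="speckle_score")


def tether_metrics(loci: Sequence[SELocus]) -> pd.DataFrame:
    """Genomic-tether metrics per SE.

    n_se_1mb: count of other same-chromosome SEs with center distance
    <= 1 Mb.  inv_dist_sum: sum over other cis SEs of 1 / (center
    distance in Mb).  Row order follows ``loci``.
    """
    centers = np.asarray([l.center for l in loci], dtype=float)
    chroms = np.asarray([l.chrom for l in loci])
    n = len(loci)
    n_1mb = np.zeros(n, dtype=int)
    inv_sum = np.zeros(n, dtype=float)
    for i in range(n):
        same = (chroms == chroms[i])
        same[i] = False
        d = np.abs(centers[same] - centers[i])
        n_1mb[i] = int((d <= MB).sum())
        with np.errstate(divide="ignore"):
            inv = MB / d
        inv_sum[i] = float(inv[np.isfinite(inv)].sum())
    return pd.DataFrame(
        {"se_id": [l.se_id for l in loci], "n_se_1mb": n_1mb, "inv_dist_sum": inv_sum}
    )


def build_feature_table(
    loci: Sequence[SELocus],
    chip_tracks: dict[str, GenomicTrack] | None = None,
    lad_track: GenomicTrack | None = None,
    sprite_clusters: Iterable[SpriteCluster] | None = None,
    impute: bool = True,
) -> pd.DataFrame:
    """Assemble the per-SE predictor table (one row per non-dropped SE).

    Missing values (e.g. SEs outside all DamID bins) are imputed with
    the column median when ``impute`` is set; imputations are logged.
    """
    active = [l for l in loci if not l.dropped]
    table = tether_metrics(active).set_index("se_id")
    table["chrom"] = [l.chrom for l in active]
    for name, track in (chip_tracks or {}).items():
        table[name] = coverage_over_intervals(track, active)
    if lad_track is not None:
        table["lad_score"] = damid_window_score(lad_track, active)
    if sprite_clusters is not None:
        table["speckle_score"] = speckle_association(sprite_clusters, loci=active)
    if impute:
        numeric = table.select_dtypes(include=[np.number]).columns
        for col in numeric:
            n_missing = int(table[col].isna().sum())
            if n_missing:
                logger.info("imputing %d missing %s values with median", n_missing, col)
                table[col] = table[col].fillna(table[col].median())
    return table.reset_index()
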