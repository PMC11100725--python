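"""Per-cell distance maps, contact calling and cluster-size statistics.

Cluster/community size is the star count: 1 + number of other detected
spots strictly within the radius (ties at exactly the radius excluded).
A connected-component variant is available behind a flag for
sensitivity analysis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from scipy.spatial.distance import pdist, squareform
from scipy.stats import pearsonr

from .locus_model_io import CellTable, SELocus

logger = logging.getLogger(__name__)

PARTNER_BINS = ("0", "1", "2", "3", "4+")


@dataclass
class DistanceMap:
    """Symmetric all-vs-all spot distance matrix for one cell (nm).

    Rows/columns follow ``ids`` ((se_id, allele) pairs); entries
    involving an undetected spot are NaN and are never imputed.
    """

    cell_id: str
    ids: list[tuple[str, int]]
    values: np.ndarray  # (n, n), NaN where missing

    def __post_init__(self) -> None:
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError("distance matrix shape does not match ids")


def pairwise_distance_map(cell: CellTable, cell_id=None) -> DistanceMap:
    """All-vs-all Euclidean distances for one cell's spots."""
    spots = cell.spots
    if cell_id is None:
        cells = spots["cell_id"].unique()
        if len(cells) != 1:
            raise ValueError("table holds multiple cells; pass cell_id")
        cell_id = cells[0]
    sub = spots[spots["cell_id"] == cell_id].sort_values(["se_id", "allele"])
    ids = list(zip(sub["se_id"], sub["allele"]))
    xyz = sub[["x", "y", "z"]].to_numpy(dtype=float)
    detected = sub["detected"].to_numpy()
    n = len(ids)
    values = np.full((n, n), np.nan)
    det_idx = np.where(detected)[0]
    if len(det_idx) >= 2:
        d = squareform(pdist(xyz[det_idx]))
        values[np.ix_(det_idx, det_idx)] = d
    elif len(det_idx) == 1:
        values[det_idx[0], det_idx[0]] = 0.0
    if len(det_idx) >= 2:
        values[det_idx, det_idx] = 0.0
    return DistanceMap(cell_id=str(cell_id), ids=ids, values=values)


def neighbor_counts(dmap: DistanceMap, radius: float) -> pd.Series:
    """Per detected spot: count of other detected spots at distance < radius."""
    if radius <= 0:
        raise ValueError("radius must be positive")
    v = dmap.values.copy()
    np.fill_diagonal(v, np.nan)
    with np.errstate(invalid="ignore"):
        counts = np.nansum(v < radius, axis=1)
    detected = ~np.isnan(np.diagonal(dmap.values))
    idx = pd.MultiIndex.from_tuples(dmap.ids, names=["se_id", "allele"])
    return pd.Series(counts, index=idx, name="count")[detected]


def table_neighbor_counts(table: CellTable, radius: float) -> pd.DataFrame:
    """Neighbor counts for every detected spot in every cell (kd-tree).

    Returns a tidy frame: cell_id, se_id, allele, count.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    det = table.spots[table.spots["detected"]]
    out = []
    for cell_id, sub in det.groupby("cell_id", sort=False):
        xyz = sub[["x", "y", "z"]].to_numpy(dtype=float)
        if len(xyz) == 0:
            continue
        tree = cKDTree(xyz)
        # strict inequality: shrink by epsilon relative to radius
        pairs = tree.query_pairs(r=radius * (1 - 1e-12), output_type="ndarray")
        counts = np.zeros(len(xyz), dtype=int)
        if len(pairs):
            exact = np.linalg.norm(xyz[pairs[:, 0]] - xyz[pairs[:, 1]], axis=1) < radius
            pairs = pairs[exact]
            np.add.at(counts, pairs[:, 0], 1)
            np.add.at(counts, pairs[:, 1], 1)
        out.append(
            pd.DataFrame(
                {
                    "cell_id": cell_id,
                    "se_id": sub["se_id"].to_numpy(),
                    "allele": sub["allele"].to_numpy(),
                    "count": counts,
                }
            )
        )
    if not out:
        return pd.DataFrame(columns=["cell_id", "se_id", "allele", "count"])
    return pd.concat(out, ignore_index=True)


@dataclass
class ClusterProfile:
    """Per-SE clustering statistics at one radius."""

    radius: float
    per_se: pd.DataFrame  # mean_cluster_size, p95_cluster_size, freq_0..freq_4plus, n_obs
    per_cell_mean: pd.Series  # average cluster size per cell
    detection_normalized: bool

    @property
    def mean_cluster_size(self) -> float:
        return float(self.per_se["mean_cluster_size"].mean())


def _partner_freqs(counts: np.ndarray) -> dict[str, float]:
    n = len(counts)
    freqs = {}
    for b in range(4):
        freqs[f"freq_{PARTNER_BINS[b]}"] = float((counts == b).sum() / n)
    freqs["freq_4+"] = float((counts >= 4).sum() / n)
    return freqs


def cluster_size_profile(
    table: CellTable,
    radius: float,
    detection: pd.Series | None = None,
    components: bool = False,
) -> ClusterProfile:
    """Per-SE mean/95th-percentile cluster size and partner-count mix.

    Mean cluster size is ``1 + mean neighbor count / mean partner
    detection frequency``; partner-count frequencies and per-cell means
    are raw (unnormalized).  ``detection`` maps se_id -> per-spot
    detection frequency; SEs with frequency 0 are excluded with a
    warning.  ``components=True`` switches to transitive
    connected-component sizes instead of star counts.
    """
    counts = (
        _component_sizes(table, radius)
        if components
        else table_neighbor_counts(table, radius)
    )
    if counts.empty:
        raise ValueError("no detected spots in table")
    se_ids = [l.se_id for l in table.active_loci()]
    normalized = detection is not None
    if detection is not None:
        zero = [s for s in se_ids if detection.get(s, 0.0) <= 0]
        if zero:
            logger.warning("excluding %d SEs with zero detection frequency", len(zero))
            se_ids = [s for s in se_ids if s not in set(zero)]
    rows = {}
    grouped = counts.groupby("se_id", sort=False)
    for se in se_ids:
        if se not in grouped.groups:
            continue
        sub = grouped.get_group(se)
        c = sub["count"].to_numpy()
        if detection is not None:
            partner_freqs = [detection.get(s, 0.0) for s in se_ids if s != se]
            partner_eff = float(np.mean(partner_freqs)) if partner_freqs else 1.0
            mean_size = 1.0 + c.mean() / partner_eff
        else:
            mean_size = 1.0 + c.mean()
        row = {
            "mean_cluster_size": mean_size,
            "p95_cluster_size": float(np.percentile(1 + c, 95)),
            "n_obs": len(c),
        }
        row.update(_partner_freqs(c))
        rows[se] = row
    per_se = pd.DataFrame.from_dict(rows, orient="index")
    per_se.index.name = "se_id"
    per_cell = (1 + counts.set_index("cell_id")["count"]).groupby("cell_id").mean()
    per_cell.name = "mean_cluster_size"
    return ClusterProfile(
        radius=radius,
        per_se=per_se,
        per_cell_mean=per_cell,
        detection_normalized=normalized,
    )


def _component_sizes(table: CellTable, radius: float) -> pd.DataFrame:
    """Connected-component cluster sizes minus one, per spot (tidy frame)."""
    from scipy.sparse.csgraph import connected_components
    from scipy.sparse import coo_matrix

    det = table.spots[table.spots["detected"]]
    out = []
    for cell_id, sub in det.groupby("cell_id", sort=False):
        xyz = sub[["x", "y", "z"]].to_numpy(dtype=float)
        tree = cKDTree(xyz)
        pairs = tree.query_pairs(r=radius * (1 - 1e-12), output_type="ndarray")
        n = len(xyz)
        if len(pairs):
            adj = coo_matrix(
                (np.ones(len(pairs)), (pairs[:, 0], pairs[:, 1])), shape=(n, n)
            )
            _, labels = connected_components(adj, directed=False)
        else:
            labels = np.arange(n)
        sizes = np.bincount(labels)[labels]
        out.append(
            pd.DataFrame(
                {
                    "cell_id": cell_id,
                    "se_id": sub["se_id"].to_numpy(),
                    "allele": sub["allele"].to_numpy(),
                    "count": sizes - 1,
                }
            )
        )
    return pd.concat(out, ignore_index=True)


def pairwise_contact_frequency(
    table: CellTable,
    radius: float,
    scope: str = "cis",
    include_homolog: bool = False,
) -> pd.DataFrame:
    """Per-pair contact frequency.

    cis pairs (same chromosome): allele-matched observations, frequency
    over alleles.  trans/all: any spot-pair proximity per cell,
    frequency over cells.  Only co-detected observations enter the
    denominator; never co-detected pairs get NaN with ``flagged=True``.
    """
    if scope not in {"cis", "trans", "all"}:
        raise ValueError(f"unknown scope {scope!r}")
    loci = table.active_loci()
    chrom_of = {l.se_id: l.chrom for l in loci}
    se_ids = [l.se_id for l in loci]
    se_index = {s: i for i, s in enumerate(se_ids)}
    cells = list(table.spots["cell_id"].unique())
    cell_index = {c: i for i, c in enumerate(cells)}

    coords = np.full((len(se_ids), len(cells), 2, 3), np.nan)
    det = table.spots[table.spots["detected"] & table.spots["se_id"].isin(se_index)]
    si = det["se_id"].map(se_index).to_numpy()
    ci = det["cell_id"].map(cell_index).to_numpy()
    ai = det["allele"].to_numpy()
    coords[si, ci, ai] = det[["x", "y", "z"]].to_numpy(dtype=float)

    rows = []
    for i in range(len(se_ids)):
        for j in range(i + 1, len(se_ids)):
            same = chrom_of[se_ids[i]] == chrom_of[se_ids[j]]
            if scope == "cis" and not same:
                continue
            if scope == "trans" and same:
                continue
            if scope == "cis":
                d = np.linalg.norm(coords[i] - coords[j], axis=-1)  # (cells, 2)
                ok = np.isfinite(d)
                n_obs = int(ok.sum())
                freq = float((d[ok] < radius).mean()) if n_obs else np.nan
            else:
                # any allele combination per cell
                diff = coords[i][:, :, None, :] - coords[j][:, None, :, :]
                d = np.linalg.norm(diff, axis=-1)  # (cells, 2, 2)
                ok = np.isfinite(d).any(axis=(1, 2))
                n_obs = int(ok.sum())
                with np.errstate(invalid="ignore"):
                    hit = np.nanmin(d[ok], axis=(1, 2)) < radius if n_obs else np.array([])
                freq = float(hit.mean()) if n_obs else np.nan
            rows.append(
                {
                    "se_a": se_ids[i],
                    "se_b": se_ids[j],
                    "frequency": freq,
                    "n_obs": n_obs,
                    "flagged": n_obs == 0,
                }
            )
    return pd.DataFrame(rows)


def threshold_sweep(
    table: CellTable,
    radii: Sequence[float],
    detection: pd.Series | None = None,
) -> tuple[dict[float, ClusterProfile], pd.DataFrame]:
    """Cluster profiles per radius plus cross-radius Pearson correlation.

    ``radii`` must be sorted ascending.  The correlation matrix compares
    per-SE mean cluster sizes between radii.
    """
    radii = list(radii)
    if radii != sorted(radii):
        raise ValueError("radii must be sorted ascending")
    profiles = {r: cluster_size_profile(table, r, detection=detection) for r in radii}
    corr = pd.DataFrame(np.eye(len(radii)), index=radii, columns=radii)
    for a in radii:
        for b in radii:
            if a < b:
                joined = profiles[a].per_se["mean_cluster_size"].align(
                    profiles[b].per_se["mean_cluster_size"], join="inner"
                )
                if len(joined[0]) >= 3 and joined[0].std() > 0 and joined[1].std() > 0:
                    r = pearsonr(joined[0], joined[1]).statistic
                else:
                    r = np.nan
                corr.loc[a, b] = corr.loc[b, a] = r
    return profiles, corr
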