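"""Coupling between SE community size and nascent-transcription bursts.

Burst records carry one row per (cell, gene, allele); an allele is "on"
iff its intensity is positive.  "Active SE" means the allele-linked
gene is associated with a burst.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import pearsonr

from .interaction_stats import ContingencyTable, odds_ratio
from .locus_model_io import CellTable

logger = logging.getLogger(__name__)

BURST_COLUMNS = ["cell_id", "gene", "se_id", "allele", "intensity", "on"]


class ExpressionError(ValueError):
    pass


def associate_bursts(
    table: CellTable,
    puncta: pd.DataFrame,
    genes: Sequence[tuple[str, str]],
    search_radius: float = 1000.0,
) -> pd.DataFrame:
    """Assign nascent-RNA puncta to gene-linked SE alleles.

    ``puncta`` columns: cell_id, gene, x, y, z, amplitude.  Each
    gene-allele receives the amplitude of the nearest punctum within
    ``search_radius`` of its own SE spot, else 0; each punctum is
    assigned to at most one allele (nearest wins, exact ties go to the
    lower allele index and are logged).
    """
    det = table.spots[table.spots["detected"]]
    pos = det.set_index(["cell_id", "se_id", "allele"])[["x", "y", "z"]]
    records = []
    puncta_by = dict(tuple(puncta.groupby(["cell_id", "gene"], sort=False))) if len(puncta) else {}
    for cell_id in table.spots["cell_id"].unique():
        for gene, se_id in genes:
            cands = []
            pk = puncta_by.get((cell_id, gene))
            alleles_present = []
            for allele in (0, 1):
                key = (cell_id, se_id, allele)
                if key not in pos.index:
                    continue
                alleles_present.append(allele)
                if pk is None or pk.empty:
                    continue
                axyz = pos.loc[key].to_numpy(dtype=float)
                d = np.linalg.norm(pk[["x", "y", "z"]].to_numpy(dtype=float) - axyz, axis=1)
                for pi, dist in zip(pk.index, d):
                    if dist < search_radius:
                        cands.append((dist, allele, pi, float(pk.loc[pi, "amplitude"])))
            # greedy nearest assignment; punctum used at most once, allele at most once
            cands.sort(key=lambda t: (t[0], t[1]))
            used_puncta: set = set()
            assigned: dict[int, float] = {}
            for dist, allele, pi, amp in cands:
                if pi in used_puncta or allele in assigned:
                    continue
                tied = [
                    t for t in cands
                    if t[2] == pi and t[0] == dist and t[1] != allele and t[1] not in assigned
                ]
                if tied:
                    logger.info(
                        "cell %s gene %s: punctum equidistant between alleles; "
                        "assigned to allele %d",
                        cell_id, gene, min(allele, *(t[1] for t in tied)),
                    )
                assigned[allele] = amp
                used_puncta.add(pi)
            for allele in alleles_present:
                intensity = assigned.get(allele, 0.0)
                records.append(
                    {
                        "cell_id": cell_id,
                        "gene": gene,
                        "se_id": se_id,
                        "allele": allele,
                        "intensity": intensity,
                        "on": intensity > 0,
                    }
                )
    return pd.DataFrame(records, columns=BURST_COLUMNS)


def burst_vs_community(
    records: pd.DataFrame, sizes: pd.Series
) -> tuple[float, float, pd.DataFrame]:
    """Correlation of burst intensity with community size.

    ``sizes`` is indexed by (cell_id, gene, allele) or shares the
    records index.  Returns (pearson r, p-value, per-size summary with
    allele counts); raises on < 3 records or zero intensity variance.
    """
    merged = records.copy()
    if isinstance(sizes.index, pd.MultiIndex):
        merged["size"] = [
            sizes.get((r.cell_id, r.gene, r.allele), np.nan)
            for r in merged.itertuples()
        ]
    else:
        merged["size"] = sizes.reindex(merged.index)
    merged = merged.dropna(subset=["size"])
    if len(merged) < 3:
        raise ExpressionError("need >= 3 records with community sizes")
    if merged["intensity"].std() == 0 or merged["size"].std() == 0:
        raise ExpressionError("zero variance; correlation undefined")
    res = pearsonr(merged["size"], merged["intensity"])
    per_size = (
        merged.groupby("size")["intensity"]
        .agg(["count", "mean", "median", "std"])
        .rename(columns={"count": "n_alleles"})
    )
    return float(res.statistic), float(res.pvalue), per_size


def bursting_odds_by_size(
    records: pd.DataFrame,
    sizes: pd.Series | None = None,
    baseline_size: int = 1,
    correction: str = "none",
) -> pd.DataFrame:
    """OR of bursting per community size versus the isolated baseline.

    Exposure: community size == s; condition: allele on.  Returns one
    row per size with the contingency counts and OR.
    """
    df = records.copy()
    if "size" not in df.columns:
        if sizes is None:
            raise ExpressionError("community sizes required")
        df["size"] = sizes.reindex(df.index)
    base = df[df["size"] == baseline_size]
    if base.empty:
        raise ExpressionError(f"no records at baseline size {baseline_size}")
    c = int(base["on"].sum())
    d = int((~base["on"].astype(bool)).sum())
    rows = []
    for s, sub in df.groupby("size"):
        if s == baseline_size:
            continue
        a = int(sub["on"].sum())
        b = int((~sub["on"].astype(bool)).sum())
        or_val, flagged = odds_ratio(ContingencyTable(a, b, c, d), correction=correction)
        rows.append(
            {"size": s, "a": a, "b": b, "c": c, "d": d,
             "odds_ratio": or_val, "flagged": flagged}
        )
    return pd.DataFrame(rows)


def conditional_distance_maps(
    table: CellTable,
    records: pd.DataFrame,
    gene: str,
    min_alleles: int = 20,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, float]:
    """Median per-pair distance maps split by the gene's burst state.

    Returns (map_on, map_off, difference = off - on, fraction of finite
    pairs with positive difference).  An allele observation contributes
    the cell's allele-matched distances.
    """
    sub = records[records["gene"] == gene]
    on_keys = {(r.cell_id, r.allele) for r in sub[sub["on"]].itertuples()}
    off_keys = {(r.cell_id, r.allele) for r in sub[~sub["on"].astype(bool)].itertuples()}
    if len(on_keys) < min_alleles or len(off_keys) < min_alleles:
        raise ExpressionError(
            f"need >= {min_alleles} alleles in each burst state "
            f"(on={len(on_keys)}, off={len(off_keys)})"
        )
    se_ids = [l.se_id for l in table.active_loci()]
    se_index = {s: i for i, s in enumerate(se_ids)}
    det = table.spots[table.spots["detected"] & table.spots["se_id"].isin(se_index)]

    def _median_map(keys: set) -> pd.DataFrame:
        stacks: list[np.ndarray] = []
        for (cell_id, allele), grp in det.groupby(["cell_id", "allele"], sort=False):
            if (cell_id, allele) not in keys:
                continue
            coords = np.full((len(se_ids), 3), np.nan)
            coords[grp["se_id"].map(se_index)] = grp[["x", "y", "z"]].to_numpy(dtype=float)
            diff = coords[:, None, :] - coords[None, :, :]
            stacks.append(np.linalg.norm(diff, axis=-1))
        with np.errstate(all="ignore"):
            med = np.nanmedian(np.stack(stacks), axis=0)
        return pd.DataFrame(med, index=se_ids, columns=se_ids)

    map_on = _median_map(on_keys)
    map_off = _median_map(off_keys)
    diff = map_off - map_on
    tri = diff.to_numpy()[np.triu_indices(len(se_ids), k=1)]
    finite = tri[np.isfinite(tri)]
    frac_positive = float((finite > 0).mean()) if len(finite) else float("nan")
    return map_on, map_off, diff, frac_positive


def coburst_statistics(
    records: pd.DataFrame,
    table: CellTable,
    radius: float = 600.0,
    theta_grid: Sequence[float] | None = None,
) -> tuple[float, float, pd.DataFrame]:
    """Burst-size vs active-neighbor coupling.

    For each active (on) allele, counts other active gene-alleles within
    ``radius``.  Returns (pearson r of intensity vs active-neighbor
    count, p-value, OR(theta) frame) where OR(theta) contrasts the
    exposure "has >= 1 active neighbor" with the condition "intensity >
    theta".  ``theta_grid`` defaults to the deciles of positive
    intensities.
    """
    if records["gene"].nunique() < 2:
        raise ExpressionError("coburst statistics need >= 2 assayed genes")
    det = table.spots[table.spots["detected"]]
    pos = det.set_index(["cell_id", "se_id", "allele"])[["x", "y", "z"]]
    active = records[records["on"].astype(bool)].copy()
    neighbor_counts = []
    for row in active.itertuples():
        key = (row.cell_id, row.se_id, row.allele)
        if key not in pos.index:
            neighbor_counts.append(np.nan)
            continue
        xyz = pos.loc[key].to_numpy(dtype=float)
        others = active[(active["cell_id"] == row.cell_id) & (active.index != row.Index)]
        n = 0
        for o in others.itertuples():
            okey = (o.cell_id, o.se_id, o.allele)
            if okey == key or okey not in pos.index:
                continue
            if np.linalg.norm(pos.loc[okey].to_numpy(dtype=float) - xyz) < radius:
                n += 1
        neighbor_counts.append(n)
    active["active_neighbors"] = neighbor_counts
    active = active.dropna(subset=["active_neighbors"])
    if len(active) < 3 or active["intensity"].std() == 0 or active["active_neighbors"].std() == 0:
        r_val, p_val = float("nan"), float("nan")
    else:
        res = pearsonr(active["active_neighbors"], active["intensity"])
        r_val, p_val = float(res.statistic), float(res.pvalue)
    if theta_grid is None:
        positives = active["intensity"][active["intensity"] > 0]
        theta_grid = np.quantile(positives, np.arange(0.0, 1.0, 0.1)) if len(positives) else []
    exposed = active["active_neighbors"] >= 1
    rows = []
    for theta in theta_grid:
        cond = active["intensity"] > theta
        t = ContingencyTable(
            a=int((exposed & cond).sum()),
            b=int((exposed & ~cond).sum()),
            c=int((~exposed & cond).sum()),
            d=int((~exposed & ~cond).sum()),
        )
        or_val, flagged = odds_ratio(t, correction="haldane")
        rows.append({"theta": float(theta), "odds_ratio": or_val, "flagged": flagged})
    return r_val, p_val, pd.DataFrame(rows)
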