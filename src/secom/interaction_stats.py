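"""Partner entropy, triplet cooperativity, odds ratios, map correlation.

Triplet conventions: a "hub" triplet (A, B, C) requires A-B and B-C
proximity (B is the hub); the "clique" definition additionally requires
A-C.  Cooperativity is observed/expected, so cooperative assembly gives
ratios > 1.  Trans proximity between the two homologous alleles of one
SE is not counted as a contact.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from scipy.stats import pearsonr

from .locus_model_io import CellTable, SELocus

logger = logging.getLogger(__name__)


class StatsError(ValueError):
    pass


@dataclass
class PartnerDistribution:
    """Probability distribution of one SE's proximity partners."""

    se_id: str
    p: pd.Series  # index: partner se_id; sums to 1 (or empty)
    n_obs: int

    @property
    def empty(self) -> bool:
        return len(self.p) == 0


def _se_proximity_by_cell(
    table: CellTable, radius: float
) -> tuple[dict, pd.DataFrame]:
    """Per cell: set of SE-level proximal pairs (any allele combination).

    Returns ({cell_id: set of frozenset({se_a, se_b})}, detection frame
    indexed by (cell_id, se_id) -> bool any-allele detected).
    """
    det = table.spots[table.spots["detected"]]
    prox: dict = {}
    for cell_id, sub in det.groupby("cell_id", sort=False):
        xyz = sub[["x", "y", "z"]].to_numpy(dtype=float)
        ses = sub["se_id"].to_numpy()
        tree = cKDTree(xyz)
        pairs = tree.query_pairs(r=radius * (1 - 1e-12), output_type="ndarray")
        links = set()
        if len(pairs):
            exact = np.linalg.norm(xyz[pairs[:, 0]] - xyz[pairs[:, 1]], axis=1) < radius
            for i, j in pairs[exact]:
                if ses[i] != ses[j]:  # homolog trans contact excluded
                    links.add(frozenset((ses[i], ses[j])))
        prox[cell_id] = links
    detected = (
        det.groupby(["cell_id", "se_id"], sort=False)
        .size()
        .rename("n")
        .reset_index()
    )
    return prox, detected


def partner_distribution(
    table: CellTable, se_id: str, radius: float
) -> PartnerDistribution:
    """Distribution p(e) of the SE's contact partners at ``radius``.

    Contact events are counted over spot pairs, scaled by the number of
    times each partner was co-observed, and normalized to sum to 1.
    """
    if radius <= 0:
        raise StatsError("radius must be positive")
    det = table.spots[table.spots["detected"]]
    mine = det[det["se_id"] == se_id]
    if mine.empty:
        raise StatsError(f"SE {se_id!r} never detected")
    contact_counts: dict[str, int] = {}
    obs_counts: dict[str, int] = {}
    for cell_id, sub in det.groupby("cell_id", sort=False):
        ses = sub["se_id"].to_numpy()
        sel = ses == se_id
        if not sel.any():
            continue
        xyz = sub[["x", "y", "z"]].to_numpy(dtype=float)
        my_xyz = xyz[sel]
        other_xyz = xyz[~sel]
        other_se = ses[~sel]
        for s in np.unique(other_se):
            obs_counts[s] = obs_counts.get(s, 0) + int(sel.sum()) * int((other_se == s).sum())
        if len(other_xyz):
            d = np.linalg.norm(my_xyz[:, None, :] - other_xyz[None, :, :], axis=-1)
            hit = d < radius
            for k in np.where(hit.any(axis=0))[0]:
                s = other_se[k]
                contact_counts[s] = contact_counts.get(s, 0) + int(hit[:, k].sum())
    n_obs = sum(contact_counts.values())
    if n_obs == 0:
        logger.warning("SE %s has zero partners at radius %.0f", se_id, radius)
        return PartnerDistribution(se_id=se_id, p=pd.Series(dtype=float), n_obs=0)
    rate = pd.Series(
        {s: contact_counts[s] / obs_counts[s] for s in contact_counts}, dtype=float
    )
    p = rate / rate.sum()
    return PartnerDistribution(se_id=se_id, p=p.sort_index(), n_obs=n_obs)


def entropy(p: PartnerDistribution | pd.Series | np.ndarray) -> float:
    """Shannon entropy in bits, with 0*log(0) == 0.

    Raises on an empty distribution (undefined).
    """
    vals = p.p if isinstance(p, PartnerDistribution) else pd.Series(p)
    vals = np.asarray(vals, dtype=float)
    if vals.size == 0:
        raise StatsError("entropy undefined for empty distribution")
    if (vals < 0).any():
        raise StatsError("negative probabilities")
    total = vals.sum()
    if total <= 0:
        raise StatsError("distribution sums to zero")
    q = vals / total
    q = q[q > 0]
    return float(-(q * np.log2(q)).sum())


def triplet_frequencies(
    table: CellTable, radius: float, definition: str = "hub"
) -> pd.DataFrame:
    """Catalog of three-way proximity frequencies.

    Hub definition: A-B and B-C proximal (B the hub); clique adds A-C.
    Frequency is per cell with all three SEs detected; SE-level
    proximity collapses alleles (any combination counts).
    """
    if definition not in {"hub", "clique"}:
        raise StatsError(f"unknown triplet definition {definition!r}")
    prox, detected = _se_proximity_by_cell(table, radius)
    counts: dict[tuple[str, str, str], int] = {}
    for cell_id, links in prox.items():
        if not links:
            continue
        neigh: dict[str, set[str]] = {}
        for pair in links:
            a, b = tuple(pair)
            neigh.setdefault(a, set()).add(b)
            neigh.setdefault(b, set()).add(a)
        for hub, partners in neigh.items():
            for a, c in itertools.combinations(sorted(partners), 2):
                if definition == "clique" and frozenset((a, c)) not in links:
                    continue
                key = (a, hub, c)
                counts[key] = counts.get(key, 0) + 1
    if not counts:
        return pd.DataFrame(
            columns=["se_a", "hub", "se_c", "count", "n_cells_detected", "frequency"]
        )
    det_cells: dict[str, set] = {}
    for cell_id, se in zip(detected["cell_id"], detected["se_id"]):
        det_cells.setdefault(se, set()).add(cell_id)
    rows = []
    for (a, hub, c), n in counts.items():
        co = len(det_cells[a] & det_cells[hub] & det_cells[c])
        rows.append(
            {
                "se_a": a,
                "hub": hub,
                "se_c": c,
                "count": n,
                "n_cells_detected": co,
                "frequency": n / co if co else np.nan,
            }
        )
    return (
        pd.DataFrame(rows)
        .sort_values("frequency", ascending=False)
        .reset_index(drop=True)
    )


@dataclass
class CooperativityResult:
    """Observed vs independence-expected hub-triplet frequency."""

    triplet: tuple[str, str, str]  # (A, B, C); B is the shared hub
    p_ab: float
    p_bc: float
    observed_abc: float
    expected_abc: float
    ratio: float  # observed / expected; NaN when expected == 0
    flagged: bool = False


def cooperativity(
    table: CellTable, a: str, b: str, c: str, radius: float
) -> CooperativityResult:
    """Cooperativity of the hub triplet (a, b, c) with hub ``b``.

    Pairwise frequencies are per cells with both members detected;
    observed three-way frequency is per cells with all three detected.
    Ratio is observed/expected (1 = independent assembly).
    """
    if len({a, b, c}) != 3:
        raise StatsError("triplet members must be distinct")
    prox, detected = _se_proximity_by_cell(table, radius)
    det_cells: dict[str, set] = {}
    for cell_id, se in zip(detected["cell_id"], detected["se_id"]):
        det_cells.setdefault(se, set()).add(cell_id)
    for se in (a, b, c):
        if se not in det_cells:
            raise StatsError(f"SE {se!r} never detected")
    cells_ab = det_cells[a] & det_cells[b]
    cells_bc = det_cells[b] & det_cells[c]
    cells_abc = cells_ab & det_cells[c]
    if not cells_abc:
        raise StatsError("triplet never co-detected in any cell")

    def _freq(pair: frozenset, cells: set) -> float:
        return sum(1 for cl in cells if pair in prox[cl]) / len(cells)

    p_ab = _freq(frozenset((a, b)), cells_ab)
    p_bc = _freq(frozenset((b, c)), cells_bc)
    observed = sum(
        1
        for cl in cells_abc
        if frozenset((a, b)) in prox[cl] and frozenset((b, c)) in prox[cl]
    ) / len(cells_abc)
    expected = p_ab * p_bc
    flagged = expected == 0
    ratio = observed / expected if expected > 0 else np.nan
    if flagged:
        logger.warning("triplet (%s, %s, %s): expected frequency 0", a, b, c)
    return CooperativityResult(
        triplet=(a, b, c),
        p_ab=p_ab,
        p_bc=p_bc,
        observed_abc=observed,
        expected_abc=expected,
        ratio=ratio,
        flagged=flagged,
    )


def expected_triplet_frequency(p_ab: float, p_bc: float) -> float:
    """Independence expectation for a hub triplet: the product rule."""
    if not (0 <= p_ab <= 1 and 0 <= p_bc <= 1):
        raise StatsError("pairwise frequencies must lie in [0, 1]")
    return p_ab * p_bc


@dataclass
class ContingencyTable:
    """2x2 exposure/condition counts."""

    a: float  # exposed, condition
    b: float  # exposed, no condition
    c: float  # not exposed, condition
    d: float  # not exposed, no condition

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise StatsError("contingency counts must be nonnegative")

    def flipped(self) -> "ContingencyTable":
        return ContingencyTable(self.b, self.a, self.d, self.c)


def odds_ratio(t: ContingencyTable, correction: str = "none") -> tuple[float, bool]:
    """(a*d)/(b*c) with optional Haldane-Anscombe correction.

    With ``correction='haldane'`` 0.5 is added to every cell when any
    cell is zero; the returned flag marks corrected or undefined
    results.
    """
    if correction not in {"none", "haldane"}:
        raise StatsError(f"unknown correction {correction!r}")
    a, b, c, d = t.a, t.b, t.c, t.d
    flagged = False
    if correction == "haldane" and 0 in (a, b, c, d):
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
        flagged = True
    if b * c == 0:
        logger.warning("odds ratio undefined (b*c == 0)")
        return float("nan"), True
    return (a * d) / (b * c), flagged


def correlate_contact_maps(
    map_a: pd.DataFrame,
    map_b: pd.DataFrame,
    loci: list[SELocus] | None = None,
    scope: str = "cis",
) -> tuple[float, int]:
    """Pearson r between two square contact maps over cis pairs.

    Maps must share their locus index; only upper-triangle entries
    finite in both maps are used.  Returns (r, n_pairs).
    """
    if not map_a.index.equals(map_b.index) or not map_a.columns.equals(map_b.columns):
        raise StatsError("maps must share locus index")
    ids = list(map_a.index)
    chrom_of = {l.se_id: l.chrom for l in loci} if loci else None
    va, vb = [], []
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            if scope == "cis" and chrom_of is not None:
                if chrom_of.get(ids[i]) != chrom_of.get(ids[j]):
                    continue
            x, y = map_a.iloc[i, j], map_b.iloc[i, j]
            if np.isfinite(x) and np.isfinite(y):
                va.append(x)
                vb.append(y)
    if len(va) < 3:
        raise StatsError(f"need >= 3 shared finite pairs, got {len(va)}")
    r = pearsonr(va, vb).statistic
    return float(r), len(va)
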