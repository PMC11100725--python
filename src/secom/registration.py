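"""Point-level corrections applied before spatial analysis.

Chromatic-aberration correction (second-order 3D polynomial fit on
mutually matched control pairs), allele-to-chromosome assignment,
detection-efficiency bookkeeping and replicate-error quantification.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .locus_model_io import CellTable

logger = logging.getLogger(__name__)

MIN_WARP_PAIRS = 30
EXACT_ASSIGNMENT_LIMIT = 10  # max two-spot SEs for exhaustive search


class RegistrationError(ValueError):
    pass


@dataclass
class PointPairSet:
    """Mutually matched point pairs between two channels (nm)."""

    a: np.ndarray  # (n, 3)
    b: np.ndarray  # (n, 3)
    rejected: int = 0

    def __len__(self) -> int:
        return len(self.a)

    @property
    def distances(self) -> np.ndarray:
        return np.linalg.norm(self.a - self.b, axis=1)


def match_point_pairs(
    set_a: np.ndarray, set_b: np.ndarray, max_dist: float = 1000.0
) -> PointPairSet:
    """Pair points across channels by unique mutual proximity.

    A pair (a, b) is retained only when b is the sole point of set_b
    within ``max_dist`` of a and vice versa; points with zero or several
    candidates are rejected outright (no tie resolution by distance).
    """
    set_a = np.atleast_2d(np.asarray(set_a, dtype=float))
    set_b = np.atleast_2d(np.asarray(set_b, dtype=float))
    if set_a.size == 0 or set_b.size == 0:
        return PointPairSet(np.empty((0, 3)), np.empty((0, 3)), rejected=len(set_a) + len(set_b))
    tree_b = cKDTree(set_b)
    cand_ab = tree_b.query_ball_point(set_a, r=max_dist)
    tree_a = cKDTree(set_a)
    cand_ba = tree_a.query_ball_point(set_b, r=max_dist)
    keep_a, keep_b = [], []
    for i, cands in enumerate(cand_ab):
        if len(cands) != 1:
            continue
        j = cands[0]
        if len(cand_ba[j]) == 1 and cand_ba[j][0] == i:
            keep_a.append(i)
            keep_b.append(j)
    rejected = (len(set_a) - len(keep_a)) + (len(set_b) - len(keep_b))
    return PointPairSet(a=set_a[keep_a], b=set_b[keep_b], rejected=rejected)


def _poly_basis(p: np.ndarray) -> np.ndarray:
    """Full second-order basis in (x, y, z) incl. cross terms; (n, 10)."""
    x, y, z = p[:, 0], p[:, 1], p[:, 2]
    return np.column_stack(
        [np.ones_like(x), x, y, z, x * x, y * y, z * z, x * y, x * z, y * z]
    )


@dataclass
class PolynomialWarp3D:
    """Second-order polynomial map of channel-b points onto channel-a.

    Inputs are centered/scaled (``center``, ``scale``) before applying
    the per-axis coefficient rows for conditioning.
    """

    coefficients: np.ndarray  # (3, 10)
    center: np.ndarray = field(default_factory=lambda: np.zeros(3))
    scale: np.ndarray = field(default_factory=lambda: np.ones(3))
    fit_residual_median_before: float = float("nan")
    fit_residual_median: float = float("nan")

    @classmethod
    def identity(cls) -> "PolynomialWarp3D":
        coeff = np.zeros((3, 10))
        coeff[0, 1] = coeff[1, 2] = coeff[2, 3] = 1.0
        return cls(coefficients=coeff)

    def apply(self, points: np.ndarray) -> np.ndarray:
        points = np.atleast_2d(np.asarray(points, dtype=float))
        q = (points - self.center) / self.scale
        mapped = _poly_basis(q) @ self.coefficients.T
        return mapped * self.scale + self.center

    def to_dict(self) -> dict:
        return {
            "basis": "1,x,y,z,x2,y2,z2,xy,xz,yz (centered/scaled inputs)",
            "coefficients": self.coefficients.tolist(),
            "center": self.center.tolist(),
            "scale": self.scale.tolist(),
            "fit_residual_median_before": self.fit_residual_median_before,
            "fit_residual_median": self.fit_residual_median,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PolynomialWarp3D":
        return cls(
            coefficients=np.asarray(d["coefficients"], dtype=float),
            center=np.asarray(d["center"], dtype=float),
            scale=np.asarray(d["scale"], dtype=float),
            fit_residual_median_before=d.get("fit_residual_median_before", float("nan")),
            fit_residual_median=d.get("fit_residual_median", float("nan")),
        )


def fit_chromatic_warp(pairs: PointPairSet) -> PolynomialWarp3D:
    """Least-squares second-order warp mapping ``pairs.b`` onto ``pairs.a``.

    Falls back to the identity warp (keeping the uncorrected residual)
    in the degenerate case where the fit would increase the median
    training-pair distance.
    """
    if len(pairs) < MIN_WARP_PAIRS:
        raise RegistrationError(
            f"need >= {MIN_WARP_PAIRS} pairs to fit 10 coefficients per axis, got {len(pairs)}"
        )
    before = float(np.median(pairs.distances))
    center = pairs.b.mean(axis=0)
    scale = pairs.b.std(axis=0)
    scale[scale == 0] = 1.0
    q = (pairs.b - center) / scale
    target = (pairs.a - center) / scale
    design = _poly_basis(q)
    coeff, _, rank, _ = np.linalg.lstsq(design, target, rcond=None)
    if rank < design.shape[1]:
        raise RegistrationError(
            "rank-deficient polynomial design (degenerate point geometry); "
            "provide more pairs spanning all three axes"
        )
    warp = PolynomialWarp3D(
        coefficients=coeff.T,
        center=center,
        scale=scale,
        fit_residual_median_before=before,
    )
    after = float(np.median(np.linalg.norm(warp.apply(pairs.b) - pairs.a, axis=1)))
    if after > before:
        logger.warning("fitted warp increased median pair distance; using identity")
        warp = PolynomialWarp3D.identity()
        warp.fit_residual_median_before = before
        after = before
    warp.fit_residual_median = after
    return warp


@dataclass
class AlleleAssignment:
    """Partition of one chromosome's detected spots into two groups."""

    chromosome: str
    groups: tuple[list[int], list[int]]  # spot row indices into the cell's table
    objective_value: float
    exact: bool


def _partition_cost(points: np.ndarray, labels: np.ndarray) -> float:
    total = 0.0
    for g in (0, 1):
        sub = points[labels == g]
        if len(sub) > 1:
            diff = sub[:, None, :] - sub[None, :, :]
            total += float(np.sqrt((diff**2).sum(-1)).sum()) / 2.0
    return total


def assign_alleles(cell: CellTable, chromosome: str, cell_id=None) -> AlleleAssignment:
    """Split one chromosome's spots into two allele groups.

    Minimizes the summed intra-group pairwise distance.  SEs with two
    detected spots are constrained to split across groups.  Exhaustive
    when the chromosome carries <= 10 two-spot SEs, otherwise
    farthest-pair seeding + greedy insertion + swap refinement.  Group
    labels are arbitrary (maternal/paternal identity is not resolved).
    """
    chrom_of = {l.se_id: l.chrom for l in cell.loci}
    spots = cell.spots
    if cell_id is not None:
        spots = spots[spots["cell_id"] == cell_id]
    mask = spots["detected"] & spots["se_id"].map(chrom_of).eq(chromosome)
    sub = spots[mask].sort_values(["se_id", "allele"])
    if sub.empty:
        return AlleleAssignment(chromosome, ([], []), 0.0, exact=True)
    points = sub[["x", "y", "z"]].to_numpy(dtype=float)
    rows = list(sub.index)
    by_se: dict[str, list[int]] = {}
    for pos, se in enumerate(sub["se_id"]):
        by_se.setdefault(se, []).append(pos)
    pairs = [v for v in by_se.values() if len(v) == 2]
    singles = [v[0] for v in by_se.values() if len(v) == 1]

    n = len(points)
    if len(pairs) <= EXACT_ASSIGNMENT_LIMIT and n <= 2 * EXACT_ASSIGNMENT_LIMIT:
        labels, cost = _exact_assignment(points, pairs, singles)
        exact = True
    else:
        labels, cost = _heuristic_assignment(points, pairs, singles)
        exact = False
    g0 = [rows[i] for i in range(n) if labels[i] == 0]
    g1 = [rows[i] for i in range(n) if labels[i] == 1]
    return AlleleAssignment(chromosome, (g0, g1), cost, exact=exact)


def _exact_assignment(points, pairs, singles):
    n = len(points)
    best_labels, best_cost = None, np.inf
    n_pair_conf = 2 ** max(len(pairs) - 1, 0) if pairs else 1
    for pc in range(n_pair_conf):
        base = np.zeros(n, dtype=int)
        for k, (i, j) in enumerate(pairs):
            flip = (pc >> max(k - 1, 0)) & 1 if k > 0 else 0  # first pair pinned
            base[i], base[j] = flip, 1 - flip
        for sc in range(2 ** len(singles)):
            labels = base.copy()
            for k, i in enumerate(singles):
                labels[i] = (sc >> k) & 1
            cost = _partition_cost(points, labels)
            if cost < best_cost:
                best_cost, best_labels = cost, labels.copy()
    return best_labels, best_cost


def _heuristic_assignment(points, pairs, singles):
    n = len(points)
    diff = points[:, None, :] - points[None, :, :]
    dmat = np.sqrt((diff**2).sum(-1))
    labels = np.full(n, -1, dtype=int)
    i0, j0 = np.unravel_index(np.argmax(dmat), dmat.shape)
    labels[i0], labels[j0] = 0, 1
    paired_with = {}
    for i, j in pairs:
        paired_with[i], paired_with[j] = j, i
    if i0 in paired_with and labels[paired_with[i0]] == -1:
        labels[paired_with[i0]] = 1
    if j0 in paired_with and labels[paired_with[j0]] == -1:
        labels[paired_with[j0]] = 0

    def added_cost(i, g):
        members = np.where(labels == g)[0]
        return dmat[i, members].sum() if len(members) else 0.0

    for i in range(n):
        if labels[i] != -1:
            continue
        if i in paired_with and labels[paired_with[i]] != -1:
            labels[i] = 1 - labels[paired_with[i]]
        else:
            labels[i] = 0 if added_cost(i, 0) <= added_cost(i, 1) else 1
            if i in paired_with:
                labels[paired_with[i]] = 1 - labels[i]
    # swap refinement: flip whole SEs while it helps
    improved = True
    while improved:
        improved = False
        for unit in pairs + [[s] for s in singles]:
            cur = _partition_cost(points, labels)
            trial = labels.copy()
            for i in unit:
                trial[i] = 1 - trial[i]
            if _partition_cost(points, trial) < cur - 1e-12:
                labels = trial
                improved = True
    return labels, _partition_cost(points, labels)


@dataclass
class DetectionStats:
    """Per-SE both-allele detection frequencies across cells."""

    per_se: pd.Series  # index se_id, values in [0, 1]
    overall_median: float
    flagged: list[str]  # below-floor drop candidates

    def per_spot_rate(self) -> pd.Series:
        """Per-spot detection rate implied by the both-allele frequency."""
        return np.sqrt(self.per_se.clip(lower=0.0))


def detection_efficiency(table: CellTable, floor: float = 0.5) -> DetectionStats:
    """Fraction of cells in which both alleles of each SE are detected."""
    spots = table.spots
    n_cells = spots["cell_id"].nunique()
    both = (
        spots.groupby(["se_id", "cell_id"], sort=False)["detected"]
        .agg(lambda s: bool(s.all()) and len(s) == 2)
        .groupby("se_id")
        .sum()
    )
    freq = (both / n_cells).reindex([l.se_id for l in table.loci]).fillna(0.0)
    flagged = sorted(freq[freq < floor].index)
    if flagged:
        logger.info("%d SEs below detection floor %.2f", len(flagged), floor)
    return DetectionStats(
        per_se=freq, overall_median=float(freq.median()), flagged=flagged
    )


def replicate_error(first: np.ndarray, repeat: np.ndarray) -> pd.Series:
    """Per-locus 3D displacement magnitudes between replicate labelings."""
    first = np.atleast_2d(np.asarray(first, dtype=float))
    repeat = np.atleast_2d(np.asarray(repeat, dtype=float))
    if first.shape != repeat.shape or len(first) == 0:
        raise RegistrationError("replicate sets must be matched, non-empty, equal-shape")
    ok = np.isfinite(first).all(axis=1) & np.isfinite(repeat).all(axis=1)
    if not ok.any():
        raise RegistrationError("no co-detected replicate pairs")
    disp = np.linalg.norm(first[ok] - repeat[ok], axis=1)
    return pd.Series(disp, name="displacement_nm")
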