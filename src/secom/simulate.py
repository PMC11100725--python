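"""Synthetic-data generators.

Provides the uniform-random nuclear null, a diploid chromosome-territory
model with optional attractor ("speckle") nucleation, detection dropout
and localization noise, a calibrated transcription-burst model, and
synthetic per-SE feature tracks — so every downstream stage is testable
without the imaging dataset.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .locus_model_io import STANDARD_PROBE_LENGTH, CellTable, SELocus, SPOT_COLUMNS

logger = logging.getLogger(__name__)


@dataclass
class BurstModel:
    """Generative model of nascent-transcription bursts.

    Burst probability at community size ``s`` is
    ``logistic(logit(baseline_p) + delta(s))`` with ``delta(1) = 0``;
    ``delta`` is defined by per-size log-odds offsets with linear
    interpolation between listed sizes and flat extrapolation beyond.
    Burst intensity is log-normal, multiplied by ``coburst_gain`` per
    actively bursting neighbor.
    """

    baseline_p: float = 0.2
    logodds_offset: dict[int, float] = field(default_factory=lambda: {1: 0.0})
    intensity_mu: float = 0.0
    intensity_sigma: float = 0.5
    coburst_gain: float = 1.0

    def delta(self, size) -> np.ndarray:
        sizes = np.sort(np.asarray(list(self.logodds_offset), dtype=float))
        offsets = np.asarray([self.logodds_offset[int(s)] for s in sizes])
        return np.interp(np.asarray(size, dtype=float), sizes, offsets)

    def burst_prob(self, size) -> np.ndarray:
        return expit(logit(self.baseline_p) + self.delta(size))


@dataclass
class SimConfig:
    """Parameters shared by all generators (distances in nm)."""

    nucleus_radius: float = 5_000.0
    n_cells: int = 4_000
    n_points: int = 752
    seed: int = 0
    detection_eff: float = 0.9
    loc_noise_sigma: float = 60.0
    territory_spread: float = 400.0
    persistence_scale: float = 500.0  # nm per sqrt(Mb)
    n_attractors: int = 8
    attractor_bias: float = 0.0
    burst_model: BurstModel = field(default_factory=BurstModel)

    def __post_init__(self) -> None:
        if self.nucleus_radius <= 0:
            raise ValueError("nucleus_radius must be positive")
        if not 0 <= self.detection_eff <= 1:
            raise ValueError("detection_eff must lie in [0, 1]")


def sample_uniform_nucleus(
    n_points: int, radius: float, rng: np.random.Generator
) -> np.ndarray:
    """Points i.i.d. uniform in a ball via inverse-CDF spherical sampling.

    theta = 2*pi*u, phi = acos(1 - 2*u), r = R * u**(1/3);
    x = r sin(phi) sin(theta), y = r sin(phi) cos(theta), z = r cos(phi).
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    if n_points < 1:
        raise ValueError("n_points must be >= 1")
    theta = 2.0 * np.pi * rng.random(n_points)
    phi = np.arccos(1.0 - 2.0 * rng.random(n_points))
    r = radius * rng.random(n_points) ** (1.0 / 3.0)
    sin_phi = np.sin(phi)
    return np.column_stack(
        [r * sin_phi * np.sin(theta), r * sin_phi * np.cos(theta), r * np.cos(phi)]
    )


def _default_loci(n_se: int) -> list[SELocus]:
    return [
        SELocus(
            se_id=f"SE{i:03d}",
            name=f"SE{i:03d}",
            chrom=f"chr{(i % 19) + 1}",
            start=(i // 19) * 2_000_000,
            end=(i // 19) * 2_000_000 + STANDARD_PROBE_LENGTH,
        )
        for i in range(n_se)
    ]


def _assemble_table(
    cell_ids: np.ndarray,
    se_ids: np.ndarray,
    alleles: np.ndarray,
    xyz: np.ndarray,
    loci: list[SELocus],
    meta: dict,
) -> CellTable:
    df = pd.DataFrame(
        {
            "cell_id": cell_ids,
            "fov_id": "0",
            "se_id": se_ids,
            "allele": alleles,
            "x": xyz[:, 0],
            "y": xyz[:, 1],
            "z": xyz[:, 2],
            "detected": True,
            "quality": 1.0,
        }
    )[SPOT_COLUMNS]
    return CellTable(spots=df, loci=loci, meta=meta)


def simulate_null_cells(
    config: SimConfig, loci: Sequence[SELocus] | None = None
) -> CellTable:
    """Uniform-random null: ``n_points`` points per nucleus, no structure.

    Both alleles of every SE are placed independently; spot labels are
    the 2-allele expansion of ``loci`` (or a generic catalog covering
    ``n_points`` spots).
    """
    rng = np.random.default_rng(config.seed)
    if loci is None:
        loci = _default_loci((config.n_points + 1) // 2)
    else:
        loci = list(loci)
    se_ids, alleles = _diploid_labels(loci, config.n_points)
    n = config.n_cells * config.n_points
    xyz = sample_uniform_nucleus(n, config.nucleus_radius, rng)
    cell_ids = np.repeat([f"c{i:05d}" for i in range(config.n_cells)], config.n_points)
    meta = {"generator": "uniform_null", "seed": config.seed, "units": "nm"}
    return _assemble_table(
        cell_ids, np.tile(se_ids, config.n_cells), np.tile(alleles, config.n_cells),
        xyz, loci, meta,
    )


def _diploid_labels(loci: Sequence[SELocus], n_points: int):
    se_ids = np.repeat([l.se_id for l in loci], 2)[:n_points]
    alleles = np.tile([0, 1], len(loci))[:n_points]
    return se_ids, alleles


def simulate_territory_cells(
    loci: Sequence[SELocus],
    config: SimConfig,
    high_affinity: set[str] | frozenset[str] = frozenset(),
) -> CellTable:
    """Diploid chromosome-territory model.

    Per cell and allele each chromosome receives a territory center
    uniform in the nucleus; SE positions follow a coarse random walk in
    genomic order with per-axis step sigma
    ``persistence_scale * sqrt(genomic gap in Mb)`` plus per-axis
    ``territory_spread`` jitter.  SEs in ``high_affinity`` are displaced
    toward the nearest of ``n_attractors`` attractor points by fraction
    ``attractor_bias``.  Points are radially clipped to the nucleus.
    """
    rng = np.random.default_rng(config.seed)
    loci = sorted(loci, key=lambda l: (l.chrom, l.start))
    by_chrom: dict[str, list[SELocus]] = {}
    for l in loci:
        by_chrom.setdefault(l.chrom, []).append(l)

    rows_se, rows_allele, rows_cell, coords = [], [], [], []
    for ci in range(config.n_cells):
        cell = f"c{ci:05d}"
        attractors = (
            sample_uniform_nucleus(config.n_attractors, config.nucleus_radius, rng)
            if config.n_attractors > 0
            else None
        )
        for allele in (0, 1):
            for chrom, members in by_chrom.items():
                center = sample_uniform_nucleus(1, config.nucleus_radius, rng)[0]
                gaps_mb = np.diff([l.center for l in members]) / 1e6
                steps = np.zeros((len(members), 3))
                if len(members) > 1:
                    steps[1:] = rng.normal(
                        0.0,
                        config.persistence_scale * np.sqrt(np.abs(gaps_mb))[:, None],
                        size=(len(members) - 1, 3),
                    )
                walk = center + np.cumsum(steps, axis=0)
                jitter = rng.normal(0.0, config.territory_spread, size=(len(members), 3))
                pos = walk + jitter
                if attractors is not None and config.attractor_bias > 0:
                    for k, l in enumerate(members):
                        if l.se_id in high_affinity:
                            d = np.linalg.norm(attractors - pos[k], axis=1)
                            pos[k] += config.attractor_bias * (attractors[np.argmin(d)] - pos[k])
                norms = np.linalg.norm(pos, axis=1)
                over = norms > config.nucleus_radius
                if over.any():
                    pos[over] *= (config.nucleus_radius / norms[over])[:, None]
                for k, l in enumerate(members):
                    rows_se.append(l.se_id)
                    rows_allele.append(allele)
                    rows_cell.append(cell)
                coords.append(pos)
    xyz = np.concatenate(coords, axis=0)
    meta = {"generator": "territory", "seed": config.seed, "units": "nm"}
    return _assemble_table(
        np.asarray(rows_cell), np.asarray(rows_se, dtype=object),
        np.asarray(rows_allele), xyz, list(loci), meta,
    )


def apply_detection_noise(
    table: CellTable,
    eff: float,
    sigma: float,
    rng: np.random.Generator,
) -> CellTable:
    """Bernoulli dropout plus isotropic localization noise.

    Each spot is dropped independently with probability ``1 - eff``;
    retained coordinates are perturbed with per-axis Gaussian sigma
    ``sigma / sqrt(3)`` so the 3D displacement is on the order of
    ``sigma``.
    """
    if not 0 <= eff <= 1:
        raise ValueError("eff must lie in [0, 1]")
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    spots = table.spots.copy()
    n = len(spots)
    keep = rng.random(n) < eff
    detected = spots["detected"].to_numpy() & keep
    xyz = spots[["x", "y", "z"]].to_numpy(dtype=float)
    if sigma > 0:
        xyz = xyz + rng.normal(0.0, sigma / np.sqrt(3.0), size=xyz.shape)
    xyz[~detected] = np.nan
    spots[["x", "y", "z"]] = xyz
    spots["detected"] = detected
    meta = dict(table.meta, detection_eff=eff, loc_noise_sigma=sigma)
    return CellTable(spots=spots, loci=list(table.loci), meta=meta)


def sample_burst_alleles(
    n_alleles: int,
    model: BurstModel,
    rng: np.random.Generator,
    size_low: int = 1,
    size_high: int = 10,
) -> pd.DataFrame:
    """Geometry-free calibrated burst generator.

    Community sizes are drawn uniformly from ``size_low..size_high``;
    bursts fire with the model's per-size probability.  Used for
    odds-ratio parameter-recovery checks.
    """
    sizes = rng.integers(size_low, size_high + 1, size=n_alleles)
    on = rng.random(n_alleles) < model.burst_prob(sizes)
    intensity = np.where(
        on, rng.lognormal(model.intensity_mu, model.intensity_sigma, size=n_alleles), 0.0
    )
    return pd.DataFrame({"size": sizes, "on": on, "intensity": intensity})


def attach_bursts(
    table: CellTable,
    genes: Sequence[tuple[str, str]],
    model: BurstModel,
    rng: np.random.Generator,
    community_radius: float = 600.0,
) -> pd.DataFrame:
    """Draw burst records for gene-linked SE alleles.

    ``genes`` maps gene symbol -> se_id.  Burst probability follows the
    model at each allele's community size (spots within
    ``community_radius``); intensity is scaled by ``coburst_gain`` per
    actively bursting neighbor gene-allele within the same radius.
    Returns one record per (cell, gene, allele).
    """
    from .proximity import table_neighbor_counts

    known = {l.se_id for l in table.loci}
    for gene, se_id in genes:
        if se_id not in known:
            raise KeyError(f"gene {gene!r}: se_id {se_id!r} not in locus catalog")
    counts = table_neighbor_counts(table, community_radius)
    counts = counts.set_index(["cell_id", "se_id", "allele"])["count"]
    spots = table.spots[table.spots["detected"]]
    pos = spots.set_index(["cell_id", "se_id", "allele"])[["x", "y", "z"]]

    records = []
    for cell_id, cell_pos in pos.groupby(level="cell_id", sort=False):
        cand = []
        for gene, se_id in genes:
            for allele in (0, 1):
                key = (cell_id, se_id, allele)
                if key not in cell_pos.index:
                    continue
                size = int(counts.get(key, 0)) + 1
                on = bool(rng.random() < model.burst_prob(size))
                cand.append(
                    {
                        "cell_id": cell_id,
                        "gene": gene,
                        "se_id": se_id,
                        "allele": allele,
                        "size": size,
                        "on": on,
                        "xyz": cell_pos.loc[key].to_numpy(dtype=float),
                    }
                )
        active = [c for c in cand if c["on"]]
        for c in cand:
            if not c["on"]:
                intensity = 0.0
            else:
                neighbors = sum(
                    1
                    for o in active
                    if o is not c
                    and np.linalg.norm(o["xyz"] - c["xyz"]) < community_radius
                )
                intensity = float(
                    rng.lognormal(model.intensity_mu, model.intensity_sigma)
                    * model.coburst_gain**neighbors
                )
            records.append(
                {
                    "cell_id": c["cell_id"],
                    "gene": c["gene"],
                    "se_id": c["se_id"],
                    "allele": c["allele"],
                    "size": c["size"],
                    "on": c["on"],
                    "intensity": intensity,
                }
            )
    return pd.DataFrame(
        records, columns=["cell_id", "gene", "se_id", "allele", "size", "on", "intensity"]
    )


DEFAULT_FEATURE_LOADINGS: dict[str, tuple[float, float]] = {
    # feature: (loading on tether driver, loading on attractor affinity)
    "pol2": (0.3, 0.5),
    "med1": (0.2, 0.4),
    "oct4": (-0.1, 0.0),
    "sox2": (-0.1, 0.0),
    "nanog": (-0.1, 0.0),
    "k27ac": (0.0, 0.0),
    "lad_score": (0.0, -0.6),
    "speckle_score": (0.1, 0.8),
}


def synth_feature_tracks(
    loci: Sequence[SELocus],
    rng: np.random.Generator,
    loadings: dict[str, tuple[float, float]] | None = None,
    noise: float = 0.1,
    high_affinity: set[str] | frozenset[str] = frozenset(),
    out_dir: str | Path | None = None,
) -> pd.DataFrame:
    """Per-SE synthetic feature table with configurable driver loadings.

    Each feature is ``w_tether * z_tether + w_affinity * z_affinity +
    noise * N(0,1)`` where z_tether is the standardized inverse-distance
    tether sum and z_affinity the standardized attractor-affinity
    indicator.  Matching bedGraph files are written to ``out_dir`` when
    given.  Tether metrics are appended as columns.
    """
    from .feature_tracks import tether_metrics

    loadings = DEFAULT_FEATURE_LOADINGS if loadings is None else loadings
    tether = tether_metrics(loci)

    def _z(v: np.ndarray) -> np.ndarray:
        sd = v.std()
        return (v - v.mean()) / sd if sd > 0 else np.zeros_like(v)

    z_tether = _z(tether["inv_dist_sum"].to_numpy(dtype=float))
    affinity = np.asarray([1.0 if l.se_id in high_affinity else 0.0 for l in loci])
    z_aff = _z(affinity)
    out = tether.copy()
    out["chrom"] = [l.chrom for l in loci]
    for feat, (w_t, w_a) in loadings.items():
        out[feat] = w_t * z_tether + w_a * z_aff + noise * rng.standard_normal(len(loci))
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for feat in loadings:
            with open(out_dir / f"{feat}.bedgraph", "w") as fh:
                for l, v in zip(loci, out[feat]):
                    fh.write(f"{l.chrom}\t{l.start}\t{l.end}\t{v:.6f}\n")
    return out
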