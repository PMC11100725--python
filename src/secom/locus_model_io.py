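"""Locus tables, spot tables and the core data model.

Coordinate conventions: genomic intervals are 0-based half-open (BED
style) in base pairs; spatial coordinates are nanometers throughout.
Undetected spots carry NaN coordinates, never zero.
"""

from __future__ import annotations

import io
import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

STANDARD_PROBE_LENGTH = 15_000
STANDARD_FLANK = STANDARD_PROBE_LENGTH // 2

#: canonical column order for the flat spot-table dialect
SPOT_COLUMNS = [
    "cell_id",
    "fov_id",
    "se_id",
    "allele",
    "x",
    "y",
    "z",
    "detected",
    "quality",
]

_FOFCT_COLUMNS = [
    "Spot_ID",
    "Trace_ID",
    "X",
    "Y",
    "Z",
    "Chrom",
    "Chrom_Start",
    "Chrom_End",
    "Cell_ID",
    "Allele",
    "Locus_Name",
    "FOV_ID",
    "Quality",
]

#: decimal places preserved by every serialization dialect (nm)
COORD_DECIMALS = 3


class LocusTableError(ValueError):
    """Raised for malformed or invalid locus-table input."""


class SpotTableError(ValueError):
    """Raised for malformed or invalid spot-table input."""


@dataclass(frozen=True)
class SELocus:
    """A single super-enhancer probe target.

    ``start``/``end`` are 0-based half-open base-pair coordinates.
    ``dropped`` loci are retained in tables but excluded from analysis.
    """

    se_id: str
    name: str
    chrom: str
    start: int
    end: int
    linked_gene: str = ""
    rank_suffix: int | None = None
    dropped: bool = False

    def __post_init__(self) -> None:
        if self.start < 0:
            raise LocusTableError(
                f"locus {self.se_id!r}: negative start coordinate {self.start}"
            )
        if self.end <= self.start:
            raise LocusTableError(
                f"locus {self.se_id!r}: end ({self.end}) must exceed start ({self.start})"
            )

    @property
    def center(self) -> int:
        return (self.start + self.end) // 2

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class ProximityConfig:
    """Distance thresholds (nm) shared across the pipeline."""

    contact_radius: float = 200.0
    community_radius: float = 600.0
    sweep_radii: Sequence[float] = (200.0, 300.0, 400.0, 500.0, 600.0, 700.0, 800.0, 900.0, 1000.0)
    burst_search_radius: float = 1000.0

    def __post_init__(self) -> None:
        if not (0 < self.contact_radius <= self.community_radius <= max(self.sweep_radii)):
            raise ValueError(
                "require 0 < contact_radius <= community_radius <= max(sweep_radii)"
            )


@dataclass
class CellTable:
    """All spot records for a dataset plus the locus catalog.

    ``spots`` is a DataFrame with :data:`SPOT_COLUMNS`; one row per
    (cell, SE, allele).  Coordinates are nm; undetected rows carry NaN.
    """

    spots: pd.DataFrame
    loci: list[SELocus]
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [c for c in SPOT_COLUMNS if c not in self.spots.columns]
        if missing:
            raise SpotTableError(f"spot table missing mandatory columns: {missing}")
        known = {l.se_id for l in self.loci}
        unknown = set(self.spots["se_id"]) - known
        if unknown:
            raise SpotTableError(
                f"spot records reference unknown se_ids: {sorted(unknown)[:5]}"
            )

    @property
    def locus_index(self) -> dict[str, SELocus]:
        return {l.se_id: l for l in self.loci}

    def active_loci(self) -> list[SELocus]:
        """Loci not flagged as dropped."""
        return [l for l in self.loci if not l.dropped]

    def detected(self) -> pd.DataFrame:
        return self.spots[self.spots["detected"]]

    def cells(self) -> np.ndarray:
        return self.spots["cell_id"].unique()


def _coerce_bool(value: str) -> bool:
    return str(value).strip().lower() in {"1", "true", "yes", "y"}


def read_locus_table(path: str | Path) -> list[SELocus]:
    """Read a BED-like TSV of SE loci.

    Columns: chrom, start, end, name[, gene, rank, dropped].  A header
    row (first field ``chrom``) and ``#`` comments are both tolerated.
    """
    path = Path(path)
    loci: list[SELocus] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if lineno == 1 and fields[0].strip().lower() in {"chrom", "chr", "chromosome"}:
                continue
            if len(fields) < 4:
                raise LocusTableError(
                    f"{path.name}:{lineno}: expected >= 4 tab-separated fields, got {len(fields)}"
                )
            chrom, start_s, end_s, name = (f.strip() for f in fields[:4])
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise LocusTableError(
                    f"{path.name}:{lineno}: non-integer coordinates {start_s!r}/{end_s!r}"
                ) from exc
            gene = fields[4].strip() if len(fields) > 4 else ""
            rank: int | None = None
            if len(fields) > 5 and fields[5].strip() not in {"", ".", "NA"}:
                rank = int(fields[5])
            dropped = _coerce_bool(fields[6]) if len(fields) > 6 else False
            if name in seen:
                raise LocusTableError(f"{path.name}:{lineno}: duplicate locus name {name!r}")
            seen.add(name)
            try:
                loci.append(
                    SELocus(
                        se_id=name,
                        name=name,
                        chrom=chrom,
                        start=start,
                        end=end,
                        linked_gene=gene,
                        rank_suffix=rank,
                        dropped=dropped,
                    )
                )
            except LocusTableError as exc:
                raise LocusTableError(f"{path.name}:{lineno}: {exc}") from exc
    if not loci:
        logger.warning("locus table %s is empty", path)
    return loci


def write_locus_table(loci: Iterable[SELocus], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tstart\tend\tname\tgene\trank\tdropped\n")
        for l in loci:
            rank = "" if l.rank_suffix is None else str(l.rank_suffix)
            fh.write(
                f"{l.chrom}\t{l.start}\t{l.end}\t{l.name}\t{l.linked_gene}\t{rank}\t"
                f"{int(l.dropped)}\n"
            )


def standardize_region(center: int) -> tuple[int, int]:
    """Return the standardized probe interval around ``center``.

    The interval spans ``center - 7500 .. center + 7500``; centers
    closer than 7.5 kb to the chromosome start are clipped at 0 with a
    warning (the resulting interval is then shorter than 15 kb).
    """
    start = center - STANDARD_FLANK
    end = center + STANDARD_FLANK
    if start < 0:
        warnings.warn(
            f"center {center} < {STANDARD_FLANK}; interval clipped at 0", stacklevel=2
        )
        start = 0
    return start, end


def merge_proximal_loci(
    loci: Sequence[SELocus],
    max_gap: int = STANDARD_PROBE_LENGTH,
    names: dict[frozenset[str], str] | None = None,
) -> list[SELocus]:
    """Merge same-chromosome loci whose intervals lie within ``max_gap``.

    Runs of mergeable loci collapse into one locus spanning their
    union.  The merged name comes from ``names`` (keyed by the frozenset
    of member se_ids) or is the '+'-joined member names.
    """
    ordered = sorted(loci, key=lambda l: (l.chrom, l.start))
    merged: list[SELocus] = []
    run: list[SELocus] = []

    def _flush() -> None:
        if not run:
            return
        if len(run) == 1:
            merged.append(run[0])
        else:
            key = frozenset(l.se_id for l in run)
            name = (names or {}).get(key) or "+".join(l.name for l in run)
            gene = next((l.linked_gene for l in run if l.linked_gene), "")
            merged.append(
                SELocus(
                    se_id=name,
                    name=name,
                    chrom=run[0].chrom,
                    start=min(l.start for l in run),
                    end=max(l.end for l in run),
                    linked_gene=gene,
                    dropped=all(l.dropped for l in run),
                )
            )
        run.clear()

    for locus in ordered:
        if run and locus.chrom == run[-1].chrom and locus.start - max(l.end for l in run) <= max_gap:
            run.append(locus)
        else:
            _flush()
            run.append(locus)
    _flush()
    return merged


def combine_locus_lists(primary: Sequence[SELocus], extra: Sequence[SELocus]) -> list[SELocus]:
    """Concatenate two locus lists, keeping the primary entry on name clash."""
    seen = {l.se_id for l in primary}
    out = list(primary)
    out.extend(l for l in extra if l.se_id not in seen)
    return sorted(out, key=lambda l: (l.chrom, l.start))


def _fmt_coord(v: float) -> str:
    return "" if not np.isfinite(v) else f"{v:.{COORD_DECIMALS}f}"


def write_spot_table(table: CellTable, path: str | Path, dialect: str = "flat_tsv") -> None:
    """Serialize a :class:`CellTable` as text.

    Dialects: ``flat_tsv`` (canonical columns) and ``fofct_core``
    (FOF-CT-style core spot table with extra locus columns).  Both are
    lossless at :data:`COORD_DECIMALS` decimal places of nm.
    """
    if dialect == "flat_tsv":
        _write_flat(table, path)
    elif dialect == "fofct_core":
        _write_fofct(table, path)
    else:
        raise SpotTableError(f"unknown spot-table dialect {dialect!r}")


def _write_flat(table: CellTable, path: str | Path) -> None:
    with open(path, "w") as fh:
        for k, v in table.meta.items():
            fh.write(f"#{k}={v}\n")
        fh.write("\t".join(SPOT_COLUMNS) + "\n")
        for row in table.spots.itertuples(index=False):
            fh.write(
                f"{row.cell_id}\t{row.fov_id}\t{row.se_id}\t{row.allele}\t"
                f"{_fmt_coord(row.x)}\t{_fmt_coord(row.y)}\t{_fmt_coord(row.z)}\t"
                f"{int(row.detected)}\t{row.quality:.4f}\n"
            )


def _write_fofct(table: CellTable, path: str | Path) -> None:
    idx = table.locus_index
    with open(path, "w") as fh:
        fh.write("##Table_namespace=4dn_FOF-CT_core\n")
        fh.write("##XYZ_unit=nm\n")
        for k, v in table.meta.items():
            fh.write(f"##{k}={v}\n")
        fh.write("#columns=(" + ", ".join(_FOFCT_COLUMNS) + ")\n")
        for i, row in enumerate(table.spots.itertuples(index=False)):
            locus = idx[row.se_id]
            fh.write(
                f"{i}\t{row.cell_id}_{row.allele}\t"
                f"{_fmt_coord(row.x)}\t{_fmt_coord(row.y)}\t{_fmt_coord(row.z)}\t"
                f"{locus.chrom}\t{locus.start}\t{locus.end}\t"
                f"{row.cell_id}\t{row.allele}\t{row.se_id}\t{row.fov_id}\t{row.quality:.4f}\n"
            )


def read_spot_table(
    path: str | Path, dialect: str = "flat_tsv", loci: Sequence[SELocus] | None = None
) -> CellTable:
    """Read a spot table written by :func:`write_spot_table`.

    For the ``fofct_core`` dialect a locus catalog must be supplied (or
    is reconstructed from the Chrom/Chrom_Start/Chrom_End columns).
    """
    if dialect == "flat_tsv":
        return _read_flat(path, loci)
    if dialect == "fofct_core":
        return _read_fofct(path, loci)
    raise SpotTableError(f"unknown spot-table dialect {dialect!r}")


def _finalize_spots(df: pd.DataFrame) -> pd.DataFrame:
    df = df.copy()
    df["allele"] = df["allele"].astype(int)
    for c in ("x", "y", "z", "quality"):
        df[c] = pd.to_numeric(df[c], errors="coerce")
    df["quality"] = df["quality"].fillna(0.0)
    df["detected"] = df["detected"].astype(bool)
    df.loc[~df["detected"], ["x", "y", "z"]] = np.nan
    return df[SPOT_COLUMNS].reset_index(drop=True)


def _read_flat(path: str | Path, loci: Sequence[SELocus] | None) -> CellTable:
    meta: dict[str, str] = {}
    body = io.StringIO()
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                k, _, v = line[1:].rstrip("\n").partition("=")
                meta[k] = v
            else:
                body.write(line)
    body.seek(0)
    df = pd.read_csv(body, sep="\t", dtype={"cell_id": str, "fov_id": str, "se_id": str})
    missing = [c for c in SPOT_COLUMNS if c not in df.columns]
    if missing:
        raise SpotTableError(f"{path}: missing mandatory column(s) {missing}")
    df["detected"] = df["detected"].astype(int).astype(bool)
    if loci is None:
        loci = _loci_from_ids(df["se_id"].unique())
    return CellTable(spots=_finalize_spots(df), loci=list(loci), meta=meta)


def _read_fofct(path: str | Path, loci: Sequence[SELocus] | None) -> CellTable:
    meta: dict[str, str] = {}
    rows = []
    columns: list[str] | None = None
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("##"):
                k, _, v = line[2:].partition("=")
                meta[k] = v
            elif line.startswith("#columns="):
                columns = [c.strip() for c in line[len("#columns=("):].rstrip(")").split(",")]
            elif line.startswith("#") or not line.strip():
                continue
            else:
                rows.append(line.split("\t"))
    if columns is None:
        raise SpotTableError(f"{path}: missing #columns header")
    for mandatory in ("Trace_ID", "X", "Y", "Z", "Chrom", "Chrom_Start", "Chrom_End"):
        if mandatory not in columns:
            raise SpotTableError(f"{path}: missing mandatory column {mandatory!r}")
    raw = pd.DataFrame(rows, columns=columns)
    coords = raw[["X", "Y", "Z"]].replace("", np.nan).astype(float)
    detected = coords.notna().all(axis=1)
    if "Locus_Name" in raw.columns:
        se_id = raw["Locus_Name"]
    else:
        if loci is None:
            raise SpotTableError("fofct_core without Locus_Name requires a locus catalog")
        lookup = {(l.chrom, str(l.start), str(l.end)): l.se_id for l in loci}
        se_id = [
            lookup[(c, s, e)]
            for c, s, e in zip(raw["Chrom"], raw["Chrom_Start"], raw["Chrom_End"])
        ]
    allele = (
        raw["Allele"].astype(int)
        if "Allele" in raw.columns
        else raw["Trace_ID"].str.rsplit("_", n=1).str[1].astype(int)
    )
    cell = (
        raw["Cell_ID"]
        if "Cell_ID" in raw.columns
        else raw["Trace_ID"].str.rsplit("_", n=1).str[0]
    )
    df = pd.DataFrame(
        {
            "cell_id": cell.astype(str).values,
            "fov_id": (raw["FOV_ID"] if "FOV_ID" in raw.columns else "0"),
            "se_id": np.asarray(se_id, dtype=object),
            "allele": allele.values,
            "x": coords["X"].values,
            "y": coords["Y"].values,
            "z": coords["Z"].values,
            "detected": detected.values,
            "quality": (raw["Quality"].astype(float) if "Quality" in raw.columns else 0.0),
        }
    )
    if loci is None:
        chrom_info = {
            str(n): (c, int(s), int(e))
            for n, c, s, e in zip(se_id, raw["Chrom"], raw["Chrom_Start"], raw["Chrom_End"])
        }
        loci = [
            SELocus(se_id=k, name=k, chrom=v[0], start=v[1], end=v[2])
            for k, v in chrom_info.items()
        ]
    return CellTable(spots=_finalize_spots(df), loci=list(loci), meta=meta)


def _loci_from_ids(ids: Iterable[str]) -> list[SELocus]:
    """Placeholder catalog for tables read without locus metadata."""
    return [
        SELocus(se_id=str(i), name=str(i), chrom="chrUn", start=k * 20_000, end=k * 20_000 + STANDARD_PROBE_LENGTH)
        for k, i in enumerate(sorted(map(str, ids)))
    ]
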