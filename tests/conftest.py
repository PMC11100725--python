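from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from secom.locus_model_io import (
    STANDARD_PROBE_LENGTH,
    CellTable,
    SELocus,
    SPOT_COLUMNS,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_loci(n: int, per_chrom: int = 5, spacing: int = 500_000) -> list[SELocus]:
    """Evenly spaced synthetic loci over as many chromosomes as needed."""
    loci = []
    for i in range(n):
        chrom = f"chr{i // per_chrom + 1}"
        start = (i % per_chrom) * spacing + 100_000
        loci.append(
            SELocus(
                se_id=f"SE{i:03d}",
                name=f"SE{i:03d}",
                chrom=chrom,
                start=start,
                end=start + STANDARD_PROBE_LENGTH,
            )
        )
    return loci


def make_cell_table(
    loci: list[SELocus],
    positions: dict[tuple[str, str, int], tuple[float, float, float]],
    undetected: set[tuple[str, str, int]] = frozenset(),
) -> CellTable:
    """Build a CellTable from explicit (cell, se, allele) -> xyz placements."""
    rows = []
    for (cell, se, allele), xyz in positions.items():
        rows.append(
            {
                "cell_id": cell,
                "fov_id": "0",
                "se_id": se,
                "allele": allele,
                "x": xyz[0],
                "y": xyz[1],
                "z": xyz[2],
                "detected": (cell, se, allele) not in undetected,
                "quality": 1.0,
            }
        )
    df = pd.DataFrame(rows)[SPOT_COLUMNS]
    df.loc[~df["detected"], ["x", "y", "z"]] = np.nan
    return CellTable(spots=df, loci=loci, meta={})


@pytest.fixture
def loci10() -> list[SELocus]:
    return make_loci(10)


@pytest.fixture
def locus_table_file(tmp_path):
    """376-row locus table fixture on disk (231 + 145 sources merged)."""
    path = tmp_path / "loci.tsv"
    loci = make_loci(376, per_chrom=20, spacing=2_000_000)
    with open(path, "w") as fh:
        fh.write("chrom\tstart\tend\tname\tgene\trank\tdropped\n")
        for l in loci:
            fh.write(f"{l.chrom}\t{l.start}\t{l.end}\t{l.name}\t\t\t0\n")
    return path
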