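import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from secom.proximity import (
    ClusterProfile,
    cluster_size_profile,
    neighbor_counts,
    pairwise_contact_frequency,
    pairwise_distance_map,
    table_neighbor_counts,
    threshold_sweep,
)
from secom.simulate import SimConfig, simulate_null_cells, simulate_territory_cells

from conftest import make_cell_table, make_loci


def brute_force_counts(xyz: np.ndarray, radius: float) -> np.ndarray:
    """Independent double-loop neighbor-count oracle."""
    n = len(xyz)
    counts = np.zeros(n, dtype=int)
    for i in range(n):
        for j in range(n):
            if i != j and np.linalg.norm(xyz[i] - xyz[j]) < radius:
                counts[i] += 1
    return counts


class TestDistanceMap:
    def test_two_spots(self):
        loci = make_loci(1)
        table = make_cell_table(
            loci,
            {("c0", "SE000", 0): (0.0, 0.0, 0.0), ("c0", "SE000", 1): (0.0, 0.0, 300.0)},
        )
        dmap = pairwise_distance_map(table)
        assert dmap.values[0, 1] == pytest.approx(300.0)
        assert dmap.values[1, 0] == pytest.approx(300.0)
        assert dmap.values[0, 0] == 0.0

    def test_undetected_row_missing(self):
        loci = make_loci(2)
        table = make_cell_table(
            loci,
            {
                ("c0", "SE000", 0): (0.0, 0.0, 0.0),
                ("c0", "SE000", 1): (100.0, 0.0, 0.0),
                ("c0", "SE001", 0): (200.0, 0.0, 0.0),
            },
            undetected={("c0", "SE001", 0)},
        )
        dmap = pairwise_distance_map(table)
        missing_row = [i for i, t in enumerate(dmap.ids) if t == ("SE001", 0)][0]
        assert np.isnan(dmap.values[missing_row]).all()
        assert np.isnan(dmap.values[:, missing_row]).all()

    def test_matches_independent_reimplementation(self, rng):
        loci = make_loci(10)
        pos = {
            ("c0", l.se_id, a): tuple(rng.uniform(0, 2_000, 3))
            for l in loci
            for a in (0, 1)
        }
        table = make_cell_table(loci, pos)
        dmap = pairwise_distance_map(table)
        sub = table.spots.sort_values(["se_id", "allele"])
        xyz = sub[["x", "y", "z"]].to_numpy()
        for i in range(len(xyz)):
            for j in range(len(xyz)):
                assert dmap.values[i, j] == pytest.approx(np.linalg.norm(xyz[i] - xyz[j]))

    def test_symmetry_and_triangle(self, rng):
        loci = make_loci(5)
        pos = {("c0", l.se_id, 0): tuple(rng.uniform(0, 500, 3)) for l in loci}
        dmap = pairwise_distance_map(make_cell_table(loci, pos))
        v = dmap.values
        np.testing.assert_allclose(v, v.T)
        n = len(v)
        for i in range(n):
            for j in range(n):
                for k in range(n):
                    assert v[i, j] <= v[i, k] + v[k, j] + 1e-9


class TestNeighborCounts:
    def _collinear(self):
        loci = make_loci(3)
        return make_cell_table(
            loci,
            {
                ("c0", "SE000", 0): (0.0, 0.0, 0.0),
                ("c0", "SE001", 0): (150.0, 0.0, 0.0),
                ("c0", "SE002", 0): (400.0, 0.0, 0.0),
            },
        )

    def test_collinear_at_200(self):
        counts = neighbor_counts(pairwise_distance_map(self._collinear()), 200.0)
        assert list(counts) == [1, 1, 0]

    def test_collinear_at_600(self):
        counts = neighbor_counts(pairwise_distance_map(self._collinear()), 600.0)
        assert list(counts) == [2, 2, 2]

    def test_strict_inequality_at_threshold(self):
        loci = make_loci(2)
        table = make_cell_table(
            loci,
            {("c0", "SE000", 0): (0.0, 0.0, 0.0), ("c0", "SE001", 0): (200.0, 0.0, 0.0)},
        )
        assert list(neighbor_counts(pairwise_distance_map(table), 200.0)) == [0, 0]
        counts = table_neighbor_counts(table, 200.0)
        assert list(counts["count"]) == [0, 0]

    @pytest.mark.parametrize("seed", range(4))
    def test_random_cell_matches_brute_force(self, seed):
        r = np.random.default_rng(seed)
        loci = make_loci(50)
        pos = {
            ("c0", l.se_id, a): tuple(r.uniform(0, 1_500, 3))
            for l in loci
            for a in (0, 1)
        }
        table = make_cell_table(loci, pos)
        xyz = table.spots.sort_values(["se_id", "allele"])[["x", "y", "z"]].to_numpy()
        oracle = brute_force_counts(xyz, 400.0)
        counts = neighbor_counts(pairwise_distance_map(table), 400.0)
        assert list(counts) == list(oracle)
        tidy = (
            table_neighbor_counts(table, 400.0)
            .sort_values(["se_id", "allele"])["count"]
            .to_numpy()
        )
        assert list(tidy) == list(oracle)

    def test_rotation_translation_invariance(self, rng):
        from scipy.spatial.transform import Rotation

        loci = make_loci(20)
        pos = {("c0", l.se_id, 0): rng.uniform(0, 1_000, 3) for l in loci}
        table = make_cell_table(loci, {k: tuple(v) for k, v in pos.items()})
        base = table_neighbor_counts(table, 300.0)["count"].to_numpy()
        rot = Rotation.random(rng=42).as_matrix()
        moved = {k: tuple(rot @ v + [500, -200, 100]) for k, v in pos.items()}
        table2 = make_cell_table(loci, moved)
        np.testing.assert_array_equal(
            base, table_neighbor_counts(table2, 300.0)["count"].to_numpy()
        )


class TestClusterSizeProfile:
    def test_detection_normalization_arithmetic(self):
        # raw mean neighbor count 2 with partner detection 0.8
        # -> normalized contacts 2.5 -> cluster size 3.5
        loci = make_loci(3)
        pos = {
            ("c0", "SE000", 0): (0.0, 0.0, 0.0),
            ("c0", "SE001", 0): (50.0, 0.0, 0.0),
            ("c0", "SE002", 0): (100.0, 0.0, 0.0),
        }
        table = make_cell_table(loci, pos)
        detection = pd.Series({"SE000": 0.8, "SE001": 0.8, "SE002": 0.8})
        profile = cluster_size_profile(table, 200.0, detection=detection)
        assert profile.per_se.loc["SE001", "mean_cluster_size"] == pytest.approx(3.5)

    def test_unit_detection_matches_raw(self):
        cfg = SimConfig(n_cells=30, n_points=40, seed=4)
        table = simulate_null_cells(cfg)
        raw = cluster_size_profile(table, 600.0)
        ones = pd.Series(1.0, index=[l.se_id for l in table.loci])
        norm = cluster_size_profile(table, 600.0, detection=ones)
        pd.testing.assert_frame_equal(raw.per_se, norm.per_se)

    def test_isolated_spots(self):
        loci = make_loci(3)
        pos = {
            ("c0", l.se_id, 0): (float(i) * 10_000, 0.0, 0.0)
            for i, l in enumerate(loci)
        }
        profile = cluster_size_profile(make_cell_table(loci, pos), 200.0)
        assert (profile.per_se["freq_0"] == 1.0).all()
        assert (profile.per_se["p95_cluster_size"] == 1.0).all()

    def test_partner_freqs_sum_to_one(self):
        cfg = SimConfig(n_cells=20, n_points=30, seed=5, nucleus_radius=1_000)
        profile = cluster_size_profile(simulate_null_cells(cfg), 600.0)
        freq_cols = [c for c in profile.per_se.columns if c.startswith("freq_")]
        np.testing.assert_allclose(profile.per_se[freq_cols].sum(axis=1), 1.0)

    def test_zero_detection_excluded(self, caplog):
        loci = make_loci(2)
        pos = {
            ("c0", "SE000", 0): (0.0, 0.0, 0.0),
            ("c0", "SE001", 0): (50.0, 0.0, 0.0),
        }
        table = make_cell_table(loci, pos)
        detection = pd.Series({"SE000": 0.9, "SE001": 0.0})
        profile = cluster_size_profile(table, 200.0, detection=detection)
        assert "SE001" not in profile.per_se.index

    def test_component_variant_at_least_star(self):
        cfg = SimConfig(n_cells=20, n_points=40, seed=6, nucleus_radius=1_500)
        table = simulate_null_cells(cfg)
        star = cluster_size_profile(table, 600.0)
        comp = cluster_size_profile(table, 600.0, components=True)
        joined = star.per_se["mean_cluster_size"].align(comp.per_se["mean_cluster_size"])
        assert (joined[1] >= joined[0] - 1e-9).all()


class TestPairwiseContactFrequency:
    def test_constructed_9_percent(self):
        # pair in contact in 9 of 100 observed alleles -> 9%
        loci = make_loci(2)
        pos = {}
        for c in range(50):
            for a in (0, 1):
                idx = c * 2 + a
                near = idx < 9
                pos[(f"c{c:02d}", "SE000", a)] = (0.0, 0.0, 0.0)
                pos[(f"c{c:02d}", "SE001", a)] = (
                    (100.0 if near else 5_000.0), 0.0, 0.0,
                )
        table = make_cell_table(loci, pos)
        freq = pairwise_contact_frequency(table, 200.0, scope="cis")
        assert freq.loc[0, "frequency"] == pytest.approx(0.09)
        assert freq.loc[0, "n_obs"] == 100

    def test_never_codetected_flagged_not_zero(self):
        loci = make_loci(2)
        pos = {
            ("c0", "SE000", 0): (0.0, 0.0, 0.0),
            ("c1", "SE001", 0): (0.0, 0.0, 0.0),
        }
        table = make_cell_table(loci, pos)
        freq = pairwise_contact_frequency(table, 200.0, scope="cis")
        row = freq.iloc[0]
        assert np.isnan(row["frequency"]) and row["flagged"]

    def test_null_unlinked_pair_rare(self):
        cfg = SimConfig(n_cells=150, n_points=20, seed=7)
        table = simulate_null_cells(cfg)
        freq = pairwise_contact_frequency(table, 200.0, scope="all")
        assert freq["frequency"].max() < 0.01

    def test_unknown_scope(self):
        cfg = SimConfig(n_cells=2, n_points=4, seed=0)
        with pytest.raises(ValueError, match="scope"):
            pairwise_contact_frequency(simulate_null_cells(cfg), 200.0, scope="bogus")


@pytest.fixture(scope="module")
def territory_table():
    # heterogeneous genomic density so per-SE cluster sizes genuinely differ:
    # a dense histone-cluster-like chromosome plus sparse ones
    from secom.locus_model_io import STANDARD_PROBE_LENGTH, SELocus

    loci = []
    for i in range(10):  # dense cluster, 100 kb spacing
        s = 1_000_000 + i * 100_000
        loci.append(SELocus(f"D{i:02d}", f"D{i:02d}", "chr1", s, s + STANDARD_PROBE_LENGTH))
    for i in range(20):  # sparse, 3 Mb spacing over 4 chromosomes
        s = 1_000_000 + (i % 5) * 3_000_000
        chrom = f"chr{2 + i // 5}"
        loci.append(SELocus(f"S{i:02d}", f"S{i:02d}", chrom, s, s + STANDARD_PROBE_LENGTH))
    cfg = SimConfig(
        n_cells=200, territory_spread=250.0, persistence_scale=250.0,
        n_attractors=0, seed=8,
    )
    return simulate_territory_cells(loci, cfg)


class TestThresholdSweep:

    def test_monotone_in_radius(self, territory_table):
        profiles, _ = threshold_sweep(territory_table, [200.0, 400.0, 600.0, 800.0])
        sizes = [profiles[r].per_se["mean_cluster_size"] for r in (200.0, 400.0, 600.0, 800.0)]
        for a, b in zip(sizes, sizes[1:]):
            joined = a.align(b, join="inner")
            assert (joined[1] >= joined[0] - 1e-9).all()

    def test_below_min_distance_all_one(self):
        loci = make_loci(4)
        pos = {("c0", l.se_id, 0): (float(i) * 1_000, 0.0, 0.0) for i, l in enumerate(loci)}
        table = make_cell_table(loci, pos)
        profiles, _ = threshold_sweep(table, [10.0])
        assert (profiles[10.0].per_se["mean_cluster_size"] == 1.0).all()

    def test_400_700_rank_correlation(self, territory_table):
        _, corr = threshold_sweep(territory_table, [400.0, 700.0])
        assert corr.loc[400.0, 700.0] > 0.9

    def test_unsorted_radii_rejected(self, territory_table):
        with pytest.raises(ValueError, match="sorted"):
            threshold_sweep(territory_table, [600.0, 200.0])


@settings(max_examples=20, deadline=None)
@given(
    radius=st.floats(min_value=50.0, max_value=2_000.0),
    seed=st.integers(min_value=0, max_value=100),
)
def test_property_counts_match_oracle(radius, seed):
    r = np.random.default_rng(seed)
    loci = make_loci(8)
    pos = {("c0", l.se_id, a): tuple(r.uniform(0, 1_000, 3)) for l in loci for a in (0, 1)}
    table = make_cell_table(loci, pos)
    xyz = table.spots.sort_values(["se_id", "allele"])[["x", "y", "z"]].to_numpy()
    oracle = brute_force_counts(xyz, radius)
    counts = neighbor_counts(pairwise_distance_map(table), radius)
    assert list(counts) == list(oracle)
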