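"""Periodic DBSCAN, size-binned time series, protein connectivity."""

import numpy as np
import pytest

import membranekit as mk
from membranekit.clusters import (
    ClusterParameters,
    cluster_timeseries,
    dbscan_periodic,
    protein_clusters,
    size_bin_fractions,
)


def oracle_dbscan(points, box_xy, eps, min_elements):
    """Independent reference: neighbours by explicit image enumeration,
    clusters via networkx components, border to lowest-index core
    neighbour, noise as singletons."""
    import networkx as nx

    points = np.asarray(points, dtype=float)
    n = len(points)
    box_xy = np.asarray(box_xy, dtype=float)
    neigh = [set() for _ in range(n)]
    for i in range(n):
        for j in range(i + 1, n):
            best = np.inf
            for sx in (-1, 0, 1):
                for sy in (-1, 0, 1):
                    q = points[j, :2] + box_xy * np.array([sx, sy])
                    best = min(best, np.linalg.norm(q - points[i, :2]))
            if best <= eps:
                neigh[i].add(j)
                neigh[j].add(i)
    core = [len(neigh[i]) + 1 >= min_elements for i in range(n)]
    g = nx.Graph()
    g.add_nodes_from(i for i in range(n) if core[i])
    for i in range(n):
        if core[i]:
            for j in neigh[i]:
                if core[j]:
                    g.add_edge(i, j)
    labels = np.full(n, -1)
    for ci, comp in enumerate(sorted(nx.connected_components(g), key=min)):
        for i in comp:
            labels[i] = ci
    n_clusters = labels.max() + 1
    for i in range(n):
        if labels[i] < 0:
            cores = sorted(j for j in neigh[i] if core[j])
            if cores:
                labels[i] = labels[cores[0]]
    noise = np.flatnonzero(labels < 0)
    labels[noise] = n_clusters + np.arange(len(noise))
    return labels


def partitions_equal(a, b):
    pa = {}
    pb = {}
    for i, l in enumerate(a):
        pa.setdefault(l, set()).add(i)
    for i, l in enumerate(b):
        pb.setdefault(l, set()).add(i)
    return set(map(frozenset, pa.values())) == set(map(frozenset, pb.values()))


class TestDbscanPeriodic:
    def test_three_collinear_points_form_one_cluster(self):
        # middle point is core (3 points within 15 A), ends are border
        pts = np.array([[10, 50], [20, 50], [30, 50]])
        labels = dbscan_periodic(pts, (100, 100), 15.0, 3)
        assert len(set(labels)) == 1

    def test_two_isolated_points_are_noise_singletons(self):
        labels = dbscan_periodic(np.array([[0, 0], [50, 50]]), (100, 100), 15.0, 3)
        assert len(set(labels)) == 2

    def test_cluster_straddling_boundary_is_single(self):
        pts = np.array([[1, 50], [99, 50], [95, 50], [5, 50]])
        labels = dbscan_periodic(pts, (100, 100), 15.0, 3)
        assert len(set(labels)) == 1
        assert partitions_equal(labels, oracle_dbscan(pts, (100, 100), 15.0, 3))

    def test_empty_input(self):
        assert len(dbscan_periodic(np.zeros((0, 2)), (100, 100), 15.0, 3)) == 0

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_oracle_on_random_instances(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(5, 60)
        box = rng.uniform(60, 120)
        pts = rng.uniform(0, box, size=(n, 2))
        mine = dbscan_periodic(pts, (box, box), 15.0, 3)
        assert partitions_equal(mine, oracle_dbscan(pts, (box, box), 15.0, 3))

    @pytest.mark.parametrize("seed", range(3))
    def test_core_and_noise_match_sklearn_without_periodicity(self, seed):
        """With the box far larger than the point cloud, the periodic
        implementation must agree with the reference library DBSCAN on
        core-point clusters and on the noise set (border assignment is
        convention-dependent and excluded)."""
        sklearn_cluster = pytest.importorskip("sklearn.cluster")
        rng = np.random.default_rng(seed)
        pts = rng.uniform(100, 200, size=(60, 2))
        mine = dbscan_periodic(pts, (1000.0, 1000.0), 15.0, 3)
        ref = sklearn_cluster.DBSCAN(eps=15.0, min_samples=3).fit(pts)
        core = np.zeros(60, dtype=bool)
        core[ref.core_sample_indices_] = True
        # identical noise sets
        mine_sizes = np.bincount(mine)
        assert set(np.flatnonzero(ref.labels_ == -1)) == {
            i for i in range(60) if mine_sizes[mine[i]] == 1 and not core[i]
        }
        # identical partition restricted to core points
        pa = {}
        pb = {}
        for i in np.flatnonzero(core):
            pa.setdefault(mine[i], set()).add(i)
            pb.setdefault(ref.labels_[i], set()).add(i)
        assert set(map(frozenset, pa.values())) == set(map(frozenset, pb.values()))

    def test_partition_stable_under_reordering(self):
        rng = np.random.default_rng(42)
        pts = rng.uniform(0, 100, size=(40, 2))
        labels = dbscan_periodic(pts, (100, 100), 15.0, 3)
        perm = rng.permutation(40)
        labels_p = dbscan_periodic(pts[perm], (100, 100), 15.0, 3)
        # compare as partitions of the original indices
        back = np.empty(40, dtype=int)
        back[perm] = np.arange(40)
        assert partitions_equal(labels, labels_p[back])


class TestSizeBins:
    def test_fractions_sum_to_one(self):
        labels = np.array([0, 0, 0, 0, 1, 1, 1, 2])
        fr = size_bin_fractions(labels)
        assert fr.sum() == pytest.approx(1.0)

    def test_bin_boundaries(self):
        # one 3-cluster (non-clustered bin), one 4-cluster (small)
        labels = np.array([0] * 3 + [1] * 4)
        fr = size_bin_fractions(labels)
        assert fr[0] == pytest.approx(3 / 7)
        assert fr[1] == pytest.approx(4 / 7)

    def test_invalid_bins_rejected(self):
        with pytest.raises(ValueError, match="contiguous"):
            ClusterParameters(size_bins=((1, 3), (5, 20), (21, None)))


class TestClusterTimeseries:
    def test_planted_partition_recovered_exactly(self):
        frame, man = mk.make_clustered_leaflet(
            cluster_sizes=(10, 25, 50), n_singletons=21, background={"POPC": 1.0}, n_background=200, seed=1
        )
        records, df, summary = cluster_timeseries([frame], "GM3", "outer")
        n = man["n_target"]
        expect = np.array([21 / n, 10 / n, 25 / n, 50 / n])
        assert np.allclose(records[0].bin_fractions, expect)
        # exact partition match against the manifest
        sel = frame.select_molecules(species="GM3")
        id2row = {int(mid): k for k, mid in enumerate(frame.mol_ids[sel])}
        truth = np.empty(len(sel), dtype=int)
        for ci, members in enumerate(man["cluster_members"]):
            for mid in members:
                truth[id2row[mid]] = ci
        for si, mid in enumerate(man["singletons"]):
            truth[id2row[mid]] = 1000 + si
        assert partitions_equal(records[0].labels, truth)

    def test_all_sparse_is_fully_nonclustered(self):
        frame, _ = mk.make_clustered_leaflet(cluster_sizes=(), n_singletons=15, background=None, seed=2)
        records, _, _ = cluster_timeseries([frame], "GM3", "outer")
        assert records[0].bin_fractions[0] == pytest.approx(1.0)

    def test_missing_species_rejected(self):
        frame, _ = mk.make_clustered_leaflet(cluster_sizes=(5,), n_singletons=0, background=None, seed=3)
        with pytest.raises(ValueError, match="no PIP2"):
            cluster_timeseries([frame], "PIP2", "outer")


class TestProteinClusters:
    def _grid_frame(self, spacing):
        f = mk.generate_template_bilayer(900, apl=53.3, seed=0)
        return mk.place_protein_grid(f, 16, spacing, exclusion_radius=0.0)

    def test_separated_proteins_are_singletons(self):
        g = self._grid_frame(50.0)
        df = protein_clusters([g])
        assert df.iloc[0].n_clusters == 16
        assert df.iloc[0].largest == 1

    def test_chain_connectivity_is_transitive(self):
        f = mk.generate_template_bilayer(900, apl=53.3, seed=0)
        # place three helices in a line, 7 A apart: A-B and B-C linked, A-C not
        from membranekit.templates import ideal_tm_helix
        from membranekit.species import PROTEIN_SPECIES

        helix = ideal_tm_helix() + np.array([0, 0, f.box[2] / 2])
        mols = [
            (str(f.species[i]), int(f.mol_ids[i]), str(f.leaflets[i]), f.mol_coords(i), list(f.mol_bead_names(i)))
            for i in range(f.n_molecules)
        ]
        for k, dx in enumerate((0.0, 11.0, 22.0)):
            mols.append(
                (PROTEIN_SPECIES, 10000 + k, "protein", helix + np.array([50 + dx, 50, 0]), ["BB"] * len(helix))
            )
        g = mk.MembraneFrame.from_molecules(mols, box=f.box)
        df = protein_clusters([g])
        assert df.iloc[0].largest == 3
        assert df.iloc[0].n_clusters == 1

    def test_no_proteins_rejected(self, pm_frame):
        with pytest.raises(ValueError, match="no proteins"):
            protein_clusters([pm_frame])
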