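"""Split algorithms, sphere-exclusion clustering and MDS diagnostics."""

import itertools

import numpy as np
import pytest

import qsar_workbench as qw
from qsar_workbench.prep import Dataset, MoleculeRecord
from qsar_workbench.splitting import classical_mds, similarity_matrix


def _mini_dataset(smiles, responses=None):
    responses = responses or [1.0] * len(smiles)
    recs = []
    for i, (smi, resp) in enumerate(zip(smiles, responses)):
        r = MoleculeRecord(f"m{i}", smi, response_raw=resp, smiles_std=smi)
        r.response = resp
        recs.append(r)
    return Dataset(recs, endpoint_type="continuous")


class TestRandomSplit:
    def test_counts_follow_rounded_fraction(self, clf_dataset):
        a = qw.random_split(clf_dataset, 0.75, seed=3)
        n = len(clf_dataset)
        assert len(a.train_ids) == round(n * 0.75)
        assert len(a.test_ids) == n - round(n * 0.75)

    def test_eight_records_three_quarters(self):
        ds = _mini_dataset(["C" * k for k in range(1, 9)])
        a = qw.random_split(ds, 0.75, seed=0)
        assert (len(a.train_ids), len(a.test_ids)) == (6, 2)

    def test_same_seed_reproduces(self, clf_dataset):
        a = qw.random_split(clf_dataset, 0.5, seed=42)
        b = qw.random_split(clf_dataset, 0.5, seed=42)
        assert a.train_ids == b.train_ids and a.test_ids == b.test_ids

    def test_single_record_is_an_error(self):
        with pytest.raises(ValueError):
            qw.random_split(_mini_dataset(["CCO"]), 0.5, seed=0)

    def test_degenerate_fraction_is_an_error(self):
        ds = _mini_dataset(["CCO", "CCC", "CCN"])
        with pytest.raises(ValueError):
            qw.random_split(ds, 0.01, seed=0)


class TestStratifiedSplit:
    def test_two_classes_split_evenly(self):
        smiles = [f"{'C' * (i + 1)}O" for i in range(20)]
        ds = _mini_dataset(smiles, ["a"] * 10 + ["b"] * 10)
        ds.endpoint_type = "categorical"
        a = qw.stratified_split(ds, 0.5, seed=1)
        resp = ds.responses()
        for cls in ("a", "b"):
            ids = set(resp[resp == cls].index)
            assert len(ids & set(a.train_ids)) == 5

    def test_per_bin_fraction_within_one_record(self, reg_dataset):
        a = qw.stratified_split(reg_dataset, 0.75, seed=5, n_bins=4)
        import pandas as pd

        resp = reg_dataset.responses().astype(float)
        codes = pd.Categorical(pd.qcut(resp, 4, duplicates="drop")).codes
        for b in set(codes):
            members = set(resp.index[codes == b])
            got = len(members & set(a.train_ids))
            assert abs(got - len(members) * 0.75) <= 1

    def test_emitted_assignment_is_a_valid_per_bin_assignment(self):
        # n=6, 2 bins: enumerate every assignment respecting per-bin train
        # counts and check membership
        ds = _mini_dataset(["CO", "CCO", "CCCO", "CN", "CCN", "CCCN"],
                           [1.0, 1.1, 1.2, 9.0, 9.1, 9.2])
        resp = ds.responses()
        bins = [set(resp.index[:3]), set(resp.index[3:])]
        valid = set()
        for tr0 in itertools.combinations(sorted(bins[0]), 2):  # round(3*0.5)=2
            for tr1 in itertools.combinations(sorted(bins[1]), 2):
                valid.add(frozenset(tr0) | frozenset(tr1))
        for seed in range(10):
            a = qw.stratified_split(ds, 0.5, seed=seed, n_bins=2)
            assert frozenset(a.train_ids) in valid


class TestClustering:
    def test_duplicate_structures_share_a_cluster(self):
        ds = _mini_dataset(["c1ccccc1O", "c1ccccc1O", "CC(C)(C)CC(C)(C)C"])
        c = qw.cluster_molecules(ds)
        assert c["m0"] == c["m1"] != c["m2"]

    def test_dissimilar_molecules_form_singletons(self):
        ds = _mini_dataset(["c1ccccc1", "NC(=O)CS"])
        c = qw.cluster_molecules(ds, similarity_threshold=0.9)
        assert c["m0"] != c["m1"]

    def test_matches_brute_force_sphere_exclusion_oracle(self, clf_dataset):
        sub = Dataset(clf_dataset.records[:30], endpoint_type="categorical",
                      label_set=clf_dataset.label_set)
        threshold = 0.35  # low enough to form multi-member clusters
        got = qw.cluster_molecules(sub, similarity_threshold=threshold)

        # oracle: recompute neighbour lists over the unassigned set each
        # round; centroid = most unassigned neighbours, tie -> input order
        sim = similarity_matrix(sub)
        ids = sub.record_ids
        unassigned = set(range(len(ids)))
        expected = {}
        k = 0
        while unassigned:
            best, best_count = None, -1
            for i in sorted(unassigned):
                count = sum(
                    1 for j in unassigned
                    if j != i and sim[i, j] >= threshold
                )
                if count > best_count:
                    best, best_count = i, count
            members = [j for j in sorted(unassigned)
                       if j == best or sim[best, j] >= threshold]
            for m in members:
                expected[ids[m]] = k
                unassigned.discard(m)
            k += 1
        assert got == expected


class TestIndependentClusterSplit:
    def test_spec_example_sizes_5_3_2(self):
        ds = _mini_dataset([f"{'C' * (i + 1)}O" for i in range(10)])
        cluster_of = {f"m{i}": (0 if i < 5 else 1 if i < 8 else 2) for i in range(10)}
        a = qw.independent_cluster_split(ds, cluster_of, train_fraction=0.8, seed=0)
        assert sorted(a.test_ids) == ["m8", "m9"]  # the size-2 cluster

    def test_no_cluster_spans_both_sides(self, clf_dataset, clf_clusters):
        a = qw.independent_cluster_split(clf_dataset, clf_clusters, 0.75, seed=2)
        train_clusters = {clf_clusters[r] for r in a.train_ids}
        test_clusters = {clf_clusters[r] for r in a.test_ids}
        assert not (train_clusters & test_clusters)

    def test_single_cluster_is_an_error(self):
        ds = _mini_dataset(["CCO", "CCC"])
        with pytest.raises(ValueError, match="single cluster"):
            qw.independent_cluster_split(ds, {"m0": 0, "m1": 0}, 0.5, seed=0)

    @pytest.mark.parametrize("seed", range(8))
    def test_achieves_exhaustive_optimum_up_to_12_clusters(self, seed, rng):
        sizes_rng = np.random.default_rng(1000 + seed)
        n_clusters = int(sizes_rng.integers(2, 13))
        sizes = sizes_rng.integers(1, 9, size=n_clusters)
        n = int(sizes.sum())
        smiles = [f"{'C' * ((i % 12) + 1)}O" for i in range(n)]
        ds = _mini_dataset(smiles)
        cluster_of, k = {}, 0
        for c, sz in enumerate(sizes):
            for _ in range(sz):
                cluster_of[f"m{k}"] = c
                k += 1
        frac = float(sizes_rng.choice([0.5, 0.75, 0.8]))
        a = qw.independent_cluster_split(ds, cluster_of, frac, seed=seed)
        achieved = abs(len(a.test_ids) - n * (1 - frac))
        # exhaustive search over all proper cluster subsets
        best = min(
            abs(sum(sizes[list(sub)]) - n * (1 - frac))
            for r in range(1, n_clusters)
            for sub in itertools.combinations(range(n_clusters), r)
        )
        assert achieved == pytest.approx(best)


class TestRandomPerCluster:
    def test_one_cluster_of_four(self):
        ds = _mini_dataset(["CO", "CCO", "CCCO", "CCCCO"])
        a = qw.random_per_cluster_split(ds, {f"m{i}": 0 for i in range(4)}, 0.75, seed=0)
        assert (len(a.train_ids), len(a.test_ids)) == (3, 1)

    def test_all_singletons_converge_to_target_fraction(self):
        n = 1000
        ds = _mini_dataset([f"{'C' * ((i % 20) + 1)}O" for i in range(n)])
        cluster_of = {f"m{i}": i for i in range(n)}
        for seed in range(5):
            a = qw.random_per_cluster_split(ds, cluster_of, 0.75, seed=seed)
            assert 0.70 <= len(a.train_ids) / n <= 0.80

    def test_same_seed_reproduces(self, clf_dataset, clf_clusters):
        a = qw.random_per_cluster_split(clf_dataset, clf_clusters, 0.75, seed=9)
        b = qw.random_per_cluster_split(clf_dataset, clf_clusters, 0.75, seed=9)
        assert a.train_ids == b.train_ids


class TestPredefined:
    def _write(self, tmp_path, pairs):
        p = tmp_path / "split.tsv"
        p.write_text("\n".join(f"{r}\t{s}" for r, s in pairs) + "\n")
        return p

    def test_full_coverage_round_trips(self, tmp_path):
        ds = _mini_dataset(["CCO", "CCC", "CCN"])
        p = self._write(tmp_path, [("m0", "train"), ("m1", "test"), ("m2", "train")])
        a = qw.load_predefined_split(ds, p)
        assert a.train_ids == ["m0", "m2"] and a.test_ids == ["m1"]
        assert a.spec.algorithm == "predefined"

    def test_missing_id_is_an_error(self, tmp_path):
        ds = _mini_dataset(["CCO", "CCC"])
        p = self._write(tmp_path, [("m0", "train")])
        with pytest.raises(ValueError, match="m1"):
            qw.load_predefined_split(ds, p)

    def test_extra_id_is_an_error(self, tmp_path):
        ds = _mini_dataset(["CCO"])
        p = self._write(tmp_path, [("m0", "train"), ("ghost", "test")])
        with pytest.raises(ValueError, match="ghost"):
            qw.load_predefined_split(ds, p)


class TestPartitionInvariant:
    @pytest.mark.parametrize("algorithm", ["random", "stratified", "indopt", "rpc"])
    def test_every_algorithm_partitions_exactly(self, algorithm, clf_dataset,
                                                clf_clusters):
        ids = set(clf_dataset.record_ids)
        for seed in range(10):
            if algorithm == "random":
                a = qw.random_split(clf_dataset, 0.7, seed)
            elif algorithm == "stratified":
                a = qw.stratified_split(clf_dataset, 0.7, seed)
            elif algorithm == "indopt":
                a = qw.independent_cluster_split(clf_dataset, clf_clusters, 0.7, seed)
            else:
                a = qw.random_per_cluster_split(clf_dataset, clf_clusters, 0.7, seed)
            assert set(a.train_ids) | set(a.test_ids) == ids
            assert not set(a.train_ids) & set(a.test_ids)


class TestAnalyzeSplit:
    def test_equilateral_distances_embed_as_equilateral_triangle(self):
        d = np.ones((3, 3)) - np.eye(3)
        coords, stress = classical_mds(d)
        emb = np.sqrt(((coords[:, None] - coords[None]) ** 2).sum(-1))
        off = emb[np.triu_indices(3, 1)]
        assert np.allclose(off, off[0], atol=1e-9)
        assert stress < 1e-9

    def test_matches_double_centering_eigendecomposition_oracle(self, clf_dataset):
        # independent oracle: scikit-bio's principal-coordinates analysis
        from skbio.stats.ordination import pcoa
        from scipy.linalg import orthogonal_procrustes

        sub = Dataset(clf_dataset.records[:8], endpoint_type="categorical",
                      label_set=clf_dataset.label_set)
        d = 1.0 - similarity_matrix(sub)
        coords, _ = classical_mds(d)
        ref = pcoa(d, number_of_dimensions=2).samples.to_numpy()
        r, _ = orthogonal_procrustes(coords, ref)
        assert np.linalg.norm(coords @ r - ref) < 1e-8

    def test_duplicates_get_identical_coordinates(self):
        ds = _mini_dataset(["c1ccccc1O", "c1ccccc1O", "CCCCCCCC", "NCCS"])
        a = qw.random_split(ds, 0.5, seed=0)
        analysis = qw.analyze_split(ds, a)
        c = analysis.coordinates
        assert np.allclose(c.loc["m0", ["x", "y"]].astype(float),
                           c.loc["m1", ["x", "y"]].astype(float), atol=1e-9)

    def test_overlap_summary_reports_nearest_train_similarity(self, clf_dataset,
                                                              clf_clusters):
        a = qw.random_split(clf_dataset, 0.75, seed=1)
        analysis = qw.analyze_split(clf_dataset, a)
        assert set(analysis.nearest_train_similarity.index) == set(a.test_ids)
        assert 0.0 <= analysis.overlap["mean_nearest_train_similarity"] <= 1.0

    def test_whole_cluster_test_sets_are_less_similar_to_train(self, clf_dataset,
                                                               clf_clusters):
        """The split-bias diagnostic: independent-cluster test sets sit farther
        from the training chemistry than random-per-cluster test sets."""
        sim = similarity_matrix(clf_dataset)
        ids = clf_dataset.record_ids
        pos = {r: i for i, r in enumerate(ids)}

        def mean_nn(a):
            tr = [pos[r] for r in a.train_ids]
            te = [pos[r] for r in a.test_ids]
            return float(sim[np.ix_(te, tr)].max(axis=1).mean())

        ind, rpc = [], []
        for seed in range(20):
            ind.append(mean_nn(qw.independent_cluster_split(
                clf_dataset, clf_clusters, 0.75, seed)))
            rpc.append(mean_nn(qw.random_per_cluster_split(
                clf_dataset, clf_clusters, 0.75, seed)))
        assert np.mean(ind) < np.mean(rpc)
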