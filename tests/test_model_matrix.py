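"""Learner registry, matrix enumeration, failure isolation, protocols."""

import numpy as np
import pandas as pd
import pytest

import qsar_workbench as qw
from qsar_workbench.descriptors import DescriptorMatrix
from qsar_workbench.model_matrix import (
    ModelSpec,
    default_learners,
    make_estimator,
    model_id_for,
    replay_protocol,
    save_protocol,
)


@pytest.fixture(scope="module")
def small_project(tmp_path_factory):
    """Project with 2 splits × 2 subsets × all categorical learners on the
    120-record fixture."""
    from qsar_workbench.fixtures import SyntheticSpec, generate_classification_set

    ds = generate_classification_set(
        SyntheticSpec(120, 7, "classification", noise=0.1, salt_fraction=0.1))
    ds = qw.standardize(ds, ["desalt", "neutralize", "canonicalize"])
    proj = qw.Project(tmp_path_factory.mktemp("proj"))
    proj.set_dataset(ds)
    proj.add_split(qw.random_split(ds, 0.75, seed=1, label="Rand75"))
    proj.add_split(qw.random_split(ds, 0.5, seed=2, label="Rand50"))
    proj.set_subsets({"Molprops": ["Molprops"], "Chi_Molprops": ["Chi", "Molprops"]},
                     fold_width=128)
    proj.compute_descriptors()
    proj.set_learners(seed=0)
    return proj


class TestEnumerate:
    def test_seven_by_ten_by_five_is_350(self):
        splits = [f"s{i}" for i in range(7)]
        subsets = qw.default_subsets()
        specs = qw.enumerate_models(splits, subsets, default_learners(), "categorical")
        assert len(specs) == 350

    def test_seven_by_ten_by_four_is_280(self):
        splits = [f"s{i}" for i in range(7)]
        specs = qw.enumerate_models(splits, qw.default_subsets(), default_learners(),
                                    "continuous")
        assert len(specs) == 280

    def test_cardinality_is_product_of_dimensions(self):
        learners = default_learners()
        n_cat = sum("categorical" in s.supports for s in learners.values())
        specs = qw.enumerate_models(["a"], {"x": None, "y": None}, learners,
                                    "categorical")
        assert len(specs) == 1 * 2 * n_cat

    def test_single_cell(self):
        specs = qw.enumerate_models(["s"], ["d"],
                                    {"svm": default_learners()["svm"]}, "continuous")
        assert specs == [ModelSpec("s", "d", "svm")]

    def test_ordering_is_split_subset_learner(self):
        specs = qw.enumerate_models(["s1", "s2"], ["d1", "d2"],
                                    default_learners(), "continuous")
        assert specs[0].split_label == "s1" and specs[-1].split_label == "s2"
        assert [s.subset_label for s in specs[:8]] == ["d1"] * 4 + ["d2"] * 4

    def test_no_supporting_learner_is_an_error(self):
        only_pls = {"pls": default_learners()["pls"]}
        with pytest.raises(ValueError, match="no learner"):
            qw.enumerate_models(["s"], ["d"], only_pls, "categorical")

    def test_capability_flags(self):
        learners = default_learners()
        for name in ("pp_bayes", "rp_tree", "rp_forest"):
            assert learners[name].supports == ("categorical",)
        for name in ("pls", "pls_fixed"):
            assert learners[name].supports == ("continuous",)
        for name in ("nn", "svm"):
            assert set(learners[name].supports) == {"categorical", "continuous"}


class TestTrainModel:
    def test_separable_toy_set_tree_train_accuracy_one(self):
        recs = [qw.MoleculeRecord(f"r{i}", "C", response_raw="+" if i < 6 else "-")
                for i in range(12)]
        for r in recs:
            r.response = r.response_raw
        ds = qw.Dataset(recs, "categorical", positive_class="+")
        X = pd.DataFrame({"f": [float(i < 6) for i in range(12)]},
                         index=[f"r{i}" for i in range(12)])
        matrix = DescriptorMatrix(X, ("Molprops",), 128, [])
        assignment = qw.SplitAssignment(
            qw.SplitSpec("s", "predefined"),
            train_ids=[f"r{i}" for i in range(0, 12, 2)],
            test_ids=[f"r{i}" for i in range(1, 12, 2)])
        res = qw.train_model(ModelSpec("s", "Molprops", "rp_tree"), ds, matrix,
                             assignment, default_learners()["rp_tree"])
        assert res.status == "built"
        assert res.train_stats.accuracy == 1.0
        assert res.test_stats.accuracy == 1.0

    def test_constant_matrix_pls_fails_and_is_captured(self, reg_dataset):
        n = len(reg_dataset)
        X = pd.DataFrame({"c": np.ones(n)}, index=reg_dataset.record_ids)
        matrix = DescriptorMatrix(X, ("Molprops",), 128, [])
        assignment = qw.random_split(reg_dataset, 0.75, seed=0)
        res = qw.train_model(ModelSpec("s", "Molprops", "pls"), reg_dataset, matrix,
                             assignment, default_learners()["pls"])
        assert res.status == "failed"
        assert "variance" in res.failure_reason
        assert res.fitted_model is None

    def test_nn_same_seed_identical_predictions(self, small_project):
        p = small_project
        spec = ModelSpec("Rand75", "Molprops", "nn")
        kw = dict(dataset=p.dataset, matrix=p.matrices["Molprops"],
                  assignment=p.splits["Rand75"], learner=p.learners["nn"])
        a = qw.train_model(spec, **kw)
        b = qw.train_model(spec, **kw)
        assert a.test_predictions.equals(b.test_predictions)


class TestRunMatrix:
    def test_full_small_matrix_builds(self, small_project):
        results = qw.run_matrix(small_project)
        assert len(results) == 2 * 2 * 5
        assert all(r.status == "built" for r in results)

    def test_rerun_is_idempotent_and_skips_retraining(self, small_project):
        first = qw.run_matrix(small_project)
        again = qw.run_matrix(small_project)
        assert [r.model_id for r in again] == [r.model_id for r in first]
        assert [r.test_stats.roc_auc for r in again] == [
            r.test_stats.roc_auc for r in first]

    def test_failure_isolation(self, tmp_path, reg_dataset):
        """A failing cell does not change any other cell's result."""
        proj = qw.Project(tmp_path / "p1")
        proj.set_dataset(reg_dataset)
        proj.add_split(qw.random_split(reg_dataset, 0.75, seed=0, label="R"))
        proj.set_subsets({"Molprops": ["Molprops"]}, fold_width=64)
        proj.compute_descriptors()
        proj.set_learners(seed=0)
        ok_specs = [ModelSpec("R", "Molprops", l) for l in ("svm", "pls")]
        baseline = qw.run_matrix(proj, ok_specs)

        proj2 = qw.Project(tmp_path / "p2")
        proj2.set_dataset(reg_dataset)
        proj2.add_split(proj.splits["R"])
        proj2.set_subsets({"Molprops": ["Molprops"], "Broken": ["Chi"]}, fold_width=64)
        proj2.compute_descriptors()
        # sabotage one subset matrix to a constant so pls fails on it
        proj2.matrices["Broken"].frame.iloc[:, :] = 1.0
        proj2.set_learners(seed=0)
        specs = [ModelSpec("R", "Broken", "pls")] + ok_specs
        mixed = qw.run_matrix(proj2, specs)
        assert mixed[0].status == "failed"
        by_id = {r.model_id: r for r in mixed}
        for b in baseline:
            assert by_id[b.model_id].test_stats.rmse == pytest.approx(
                b.test_stats.rmse)

    def test_model_id_depends_on_data_digest(self, small_project):
        spec = ModelSpec("Rand75", "Molprops", "svm")
        learner = small_project.learners["svm"]
        assert model_id_for(spec, learner, "digest_a") != \
            model_id_for(spec, learner, "digest_b")


class TestProtocols:
    def test_full_protocol_replay_reproduces_statistics(self, small_project, tmp_path):
        results = qw.run_matrix(small_project)
        path = tmp_path / "protocol.yaml"
        save_protocol(small_project, ["prepare", "split", "descriptors", "build"], path)

        raw = qw.Dataset(
            [qw.MoleculeRecord(r.record_id, r.smiles_raw, response_raw=r.response_raw)
             for r in small_project.dataset.records],
            endpoint_type="categorical",
            positive_class=small_project.dataset.positive_class,
            label_set=small_project.dataset.label_set,
        )
        for r in raw.records:
            r.response = r.response_raw
        replayed = replay_protocol(path, raw, tmp_path / "replay")
        new = qw.run_matrix(replayed)
        a = {r.model_id: r.test_stats.roc_auc for r in results}
        b = {r.model_id: r.test_stats.roc_auc for r in new}
        assert a == b

    def test_prep_only_protocol(self, small_project, tmp_path):
        path = tmp_path / "prep_only.yaml"
        save_protocol(small_project, ["prepare"], path)
        raw = qw.Dataset(
            [qw.MoleculeRecord("x", "CCO.Cl", response_raw="active")],
            endpoint_type="categorical", label_set=["active", "inactive"])
        raw.records[0].response = "active"
        replayed = replay_protocol(path, raw, tmp_path / "replay2")
        assert replayed.dataset.records[0].smiles_std == "CCO"
        assert not replayed.splits and not replayed.matrices

    def test_categorical_protocol_on_continuous_endpoint_errors_before_compute(
            self, small_project, tmp_path):
        path = tmp_path / "protocol2.yaml"
        save_protocol(small_project, ["prepare", "split"], path)
        cont = qw.Dataset([qw.MoleculeRecord("x", "CCO", response_raw=1.0),
                           qw.MoleculeRecord("y", "CCC", response_raw=2.0)],
                          endpoint_type="continuous")
        with pytest.raises(ValueError, match="endpoint"):
            replay_protocol(path, cont, tmp_path / "replay3")

    def test_non_contiguous_stages_rejected(self, small_project, tmp_path):
        with pytest.raises(ValueError, match="contiguous"):
            save_protocol(small_project, ["prepare", "descriptors"],
                          tmp_path / "bad.yaml")


class TestYScrambleModel:
    def test_planted_signal_beats_scrambled_baseline(self, small_project):
        p = small_project
        spec = ModelSpec("Rand75", "Chi_Molprops", "rp_forest")
        out = qw.y_scramble_model(spec, p.dataset, p.matrices["Chi_Molprops"],
                                  p.splits["Rand75"], p.learners["rp_forest"],
                                  n_permutations=12, seed=5)
        assert 0.4 <= out["scrambled_mean"] <= 0.6
        assert out["observed"] > out["scrambled_max"]
        assert out["exceedance_fraction"] == 0.0
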