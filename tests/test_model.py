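"""The read-across engine: neighbors, local models, tiered prediction."""

import numpy as np
import pytest

from readacross.chem import Structure, canonicalize, tanimoto
from readacross.data import dataset_from_records
from readacross.model import (
    LocalFitError,
    Neighbor,
    NoPrediction,
    Prediction,
    ReadAcrossModel,
    remove_uninformative_features,
    weighted_mean_prediction,
)


def fake_structure(label: str, features: set[str]) -> Structure:
    """A stand-in structure with a chosen fingerprint, for unit tests."""
    return Structure(
        input_smiles=label,
        canonical_smiles=label,
        fingerprint=frozenset(features),
        mol_weight=100.0,
        heavy_atoms=max(1, len(features)),
    )


def make_neighbor(label, features, similarity, measurements):
    return Neighbor(
        structure=fake_structure(label, features),
        similarity=similarity,
        measurements=tuple(measurements),
    )


@pytest.fixture(scope="module")
def model(synth_training):
    return ReadAcrossModel(synth_training)


class TestNeighborSearch:
    def test_lower_threshold_gives_superset(self, model, synth_training):
        query = synth_training.structures[sorted(synth_training.structure_set())[0]]
        at_05 = {n.structure.canonical_smiles for n in model.find_neighbors(query, 0.5)}
        at_02 = {n.structure.canonical_smiles for n in model.find_neighbors(query, 0.2)}
        assert at_05 <= at_02

    def test_query_structure_always_excluded(self, model, synth_training):
        for smi in sorted(synth_training.structure_set())[:10]:
            neighbors = model.find_neighbors(synth_training.structures[smi], 0.2)
            assert all(n.structure.canonical_smiles != smi for n in neighbors)

    def test_sorted_by_descending_similarity(self, model, synth_training):
        query = synth_training.structures[sorted(synth_training.structure_set())[3]]
        sims = [n.similarity for n in model.find_neighbors(query, 0.2)]
        assert sims == sorted(sims, reverse=True)

    def test_threshold_gates_a_mid_similarity_compound(self):
        # one training compound at similarity ~0.3 to the query
        query = canonicalize("CCCCCOC(=O)c1ccccc1")
        training = dataset_from_records("t", [("CCCCCOC(=O)C1CCCCC1", 0.1)])
        model = ReadAcrossModel(training)
        sim = tanimoto(
            query.fingerprint,
            training.records[0].structure.fingerprint,
        )
        assert 0.2 <= sim < 0.5  # guard: the fixture sits in the band
        assert model.find_neighbors(query, 0.5) == []
        assert len(model.find_neighbors(query, 0.2)) == 1


class TestUninformativeFeatures:
    def test_identical_fingerprints_leave_nothing(self):
        nbs = [make_neighbor(f"n{i}", {"a", "b"}, 0.9, [1.0]) for i in range(3)]
        assert remove_uninformative_features(nbs) == []

    def test_single_differing_feature_retained(self):
        nbs = [
            make_neighbor("n1", {"a", "b"}, 0.9, [1.0]),
            make_neighbor("n2", {"a"}, 0.8, [2.0]),
        ]
        assert remove_uninformative_features(nbs) == ["b"]

    def test_feature_absent_from_query_is_irrelevant(self):
        # only the neighbor set defines informativeness
        nbs = [
            make_neighbor("n1", {"shared", "x"}, 0.9, [1.0]),
            make_neighbor("n2", {"shared", "y"}, 0.8, [2.0]),
        ]
        assert remove_uninformative_features(nbs) == ["x", "y"]


class TestWeightedMean:
    def test_closed_form_on_random_neighbors(self):
        rng = np.random.default_rng(7)
        nbs = [
            make_neighbor(
                f"n{i}",
                {f"f{i}"},
                float(rng.uniform(0.2, 1.0)),
                rng.normal(2.0, 0.5, rng.integers(1, 4)).tolist(),
            )
            for i in range(6)
        ]
        value, spread = weighted_mean_prediction(nbs)
        num = den = 0.0
        for nb in nbs:
            for y in nb.measurements:
                num += nb.similarity * y
                den += nb.similarity
        assert value == pytest.approx(num / den, abs=1e-12)
        assert spread >= 0.0


class TestLocalModel:
    def _model(self, **kw):
        training = dataset_from_records("t", [("CCO", 1.0)])
        return ReadAcrossModel(training, **kw)

    def test_identical_responses_give_zero_rmse(self):
        nbs = [
            make_neighbor("n1", {"a", "b"}, 0.9, [2.0, 2.0]),
            make_neighbor("n2", {"a", "c"}, 0.8, [2.0]),
        ]
        local = self._model().fit_local_model(nbs, ["b", "c"], seed=1)
        assert local.rmse == 0.0
        assert local.predict_structure(fake_structure("q", {"a"})) == pytest.approx(2.0)

    def test_deterministic_under_fixed_seed(self):
        rng = np.random.default_rng(0)
        nbs = [
            make_neighbor(
                f"n{i}",
                set(rng.choice([f"f{j}" for j in range(8)], 4, replace=False)),
                float(rng.uniform(0.5, 1.0)),
                [float(rng.normal(2.0, 0.3))],
            )
            for i in range(8)
        ]
        m = self._model()
        a = m.fit_local_model(nbs, remove_uninformative_features(nbs), seed=11)
        b = m.fit_local_model(nbs, remove_uninformative_features(nbs), seed=11)
        q = fake_structure("q", {"f0", "f1"})
        assert a.rmse == b.rmse
        assert a.predict_structure(q) == b.predict_structure(q)

    def test_bootstrap_rmse_tracks_noise_level(self):
        # 30 neighbors, pure noise around a constant: the out-of-resample
        # RMSE estimate should land within a factor of two of sigma
        sigma = 0.3
        rng = np.random.default_rng(5)
        nbs = [
            make_neighbor(
                f"n{i}",
                set(rng.choice([f"f{j}" for j in range(10)], 5, replace=False)),
                0.8,
                [float(rng.normal(2.0, sigma))],
            )
            for i in range(30)
        ]
        local = self._model().fit_local_model(
            nbs, remove_uninformative_features(nbs), seed=3
        )
        assert 0.5 * sigma <= local.rmse <= 2.0 * sigma

    def test_too_few_neighbors_signal_fallback(self):
        nbs = [make_neighbor("n1", {"a"}, 0.9, [1.0])]
        with pytest.raises(LocalFitError):
            self._model().fit_local_model(nbs, ["a"], seed=1)

    def test_no_informative_features_signal_fallback(self):
        nbs = [
            make_neighbor("n1", {"a"}, 0.9, [1.0]),
            make_neighbor("n2", {"a"}, 0.8, [2.0]),
        ]
        with pytest.raises(LocalFitError):
            self._model().fit_local_model(nbs, [], seed=1)


class TestTieredPrediction:
    def test_close_neighbors_no_warnings(self, synth_training):
        model = ReadAcrossModel(synth_training)
        # a clustered compound: plenty of neighbors above 0.5
        smi = max(synth_training.structure_set(),
                  key=lambda s: len(model.find_neighbors(synth_training.structures[s], 0.5)))
        pred = model.predict_structure(synth_training.structures[smi], seed=1)
        assert isinstance(pred, Prediction)
        assert pred.threshold_used == 0.5
        assert pred.warnings == ()
        assert pred.ad_close
        assert pred.interval_low <= pred.value <= pred.interval_high
        assert pred.interval_high - pred.value == pytest.approx(1.96 * pred.rmse)

    def test_single_neighbor_falls_back_to_weighted_mean(self):
        # one training compound at similarity >= 0.5: the random forest
        # cannot be built, so the weighted mean (= the single value) is
        # returned with warnings at the lowered threshold
        training = dataset_from_records(
            "t", [("NC(=O)c1ccc(OCC(=O)O)cc1CCCC", 0.01)]
        )
        model = ReadAcrossModel(training)
        query = "NC(=O)c1ccc(OCC(=O)O)cc1CCCCC"
        sim = tanimoto(
            canonicalize(query).fingerprint,
            training.records[0].structure.fingerprint,
        )
        assert sim >= 0.5  # guard
        pred = model.predict(query, seed=1)
        assert isinstance(pred, Prediction)
        assert pred.method_used == "weighted-mean"
        assert pred.value == pytest.approx(2.0)  # -log10(0.01)
        assert pred.warnings != ()
        assert pred.threshold_used == 0.2

    def test_isolated_query_yields_no_prediction(self, synth_training, synth):
        _, _, truth = synth
        model = ReadAcrossModel(synth_training)
        singleton = truth[truth.cluster == -1].iloc[0]
        pred = model.predict(singleton.smiles, seed=1)
        assert isinstance(pred, NoPrediction)
        assert "no similar compounds" in pred.reason

    def test_duplicate_of_training_structure_never_uses_itself(self):
        rows = [
            ("NC(=O)c1ccc(OCC(=O)O)cc1CCCC", 0.01),
            ("NC(=O)c1ccc(OCC(=O)O)cc1CCCC", 0.02),  # duplicate structure
            ("NC(=O)c1ccc(OCC(=O)O)cc1CCCCC", 0.05),
            ("NC(=O)c1ccc(OCC(=O)O)cc1CCCCO", 0.03),
        ]
        training = dataset_from_records("t", rows)
        model = ReadAcrossModel(training)
        query_canonical = canonicalize(rows[0][0]).canonical_smiles
        pred = model.predict(rows[0][0], seed=1)
        assert isinstance(pred, Prediction)
        assert all(
            nb.structure.canonical_smiles != query_canonical for nb in pred.neighbors
        )

    def test_reproducible_under_fixed_seed(self, synth_training):
        model = ReadAcrossModel(synth_training)
        smi = sorted(synth_training.structure_set())[5]
        p1 = model.predict_structure(synth_training.structures[smi], seed=9)
        p2 = model.predict_structure(synth_training.structures[smi], seed=9)
        assert isinstance(p1, Prediction)
        assert (p1.value, p1.rmse, p1.warnings) == (p2.value, p2.rmse, p2.warnings)
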