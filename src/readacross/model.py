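"""The read-across prediction engine.

For a query structure the engine

1. collects training compounds with Tanimoto similarity >= 0.5 (*neighbors*),
2. fits a local random-forest regression on the neighbors' atom environments
   with similarities as observation weights, and
3. predicts the query's -log10 LOAEL with a 95% prediction interval of
   +/- 1.96 x RMSE, where the RMSE is estimated from bootstrap
   out-of-resample residuals of the local model.

If any step fails, the whole procedure is repeated at threshold 0.2 and the
prediction is flagged as distant from the applicability domain.  If the
random forest cannot be fit there either, the engine falls back to the
similarity-weighted mean of the neighbors' values (also flagged).  With no
neighbors at 0.2 at all, a typed no-prediction result is returned.

Compounds whose canonical structure equals the query are always excluded
from the neighbor set.  This rule is hardcoded here — not in the validation
layer — so that duplicate structures in the training data can never leak
into their own predictions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.ensemble import RandomForestRegressor

from .chem import SmilesParseError, Structure, canonicalize, tanimoto
from .data import ToxDataset

DEFAULT_THRESHOLDS = (0.5, 0.2)

WARN_LOW_SIMILARITY = "similarity threshold lowered to {threshold} (out of applicability domain of the 0.5 neighbors)"
WARN_WEIGHTED_MEAN = "local random forest failed; prediction is the similarity-weighted mean of neighbor values"


class LocalFitError(RuntimeError):
    """A local random forest could not be fit (too few neighbors / no signal)."""


@dataclass(frozen=True)
class Neighbor:
    """A training compound together with its similarity to the query."""

    structure: Structure
    similarity: float
    measurements: tuple[float, ...]  # -log10(mmol/kg bw/day)


@dataclass(frozen=True)
class Prediction:
    """A successful read-across prediction on the -log10(mmol/kg/day) scale.

    ``warnings`` is non-empty exactly when the similarity threshold had to be
    lowered to 0.2 or the weighted-mean fallback fired; warning-free
    predictions are considered close to the applicability domain.
    """

    query: Structure
    value: float
    rmse: float
    interval_low: float
    interval_high: float
    threshold_used: float
    method_used: str  # "local-rf" | "weighted-mean"
    warnings: tuple[str, ...]
    neighbors: tuple[Neighbor, ...]

    @property
    def ok(self) -> bool:
        return True

    @property
    def ad_close(self) -> bool:
        """Inside the applicability domain: no warnings were raised."""
        return not self.warnings

    @property
    def value_mmol(self) -> float:
        """Point estimate back on the mmol/kg bw/day scale."""
        return 10.0 ** (-self.value)

    @property
    def value_mg(self) -> float:
        """Point estimate in mg/kg bw/day (via the query's molecular weight)."""
        return self.value_mmol * self.query.mol_weight

    def contains(self, observed: float) -> bool:
        """Whether an experimental -log10 value lies in the 95% interval."""
        return self.interval_low <= observed <= self.interval_high


@dataclass(frozen=True)
class NoPrediction:
    """Typed no-prediction outcome (query outside the applicability domain)."""

    query: Structure
    reason: str

    @property
    def ok(self) -> bool:
        return False


@dataclass
class LocalModel:
    """A fitted local regressor with its feature list and RMSE estimate."""

    regressor: RandomForestRegressor
    features: list[str]
    rmse: float
    mtry: int

    def predict_structure(self, structure: Structure) -> float:
        x = np.array(
            [[1.0 if f in structure.fingerprint else 0.0 for f in self.features]]
        )
        return float(self.regressor.predict(x)[0])


def remove_uninformative_features(neighbors: list[Neighbor]) -> list[str]:
    """Atom environments whose presence varies across the neighbor set.

    Features shared by every neighbor, or absent from every neighbor, carry
    no information for the local model and are dropped.  Only the neighbors
    count: a feature present in all neighbors is removed even if the query
    lacks it.  The result is sorted for deterministic model building.
    """
    n = len(neighbors)
    counts: dict[str, int] = {}
    for nb in neighbors:
        for f in nb.structure.fingerprint:
            counts[f] = counts.get(f, 0) + 1
    return sorted(f for f, c in counts.items() if 0 < c < n)


def weighted_mean_prediction(neighbors: list[Neighbor]) -> tuple[float, float]:
    """Similarity-weighted mean of neighbor measurements and its weighted RMS spread.

    Every measurement of a neighbor contributes with the neighbor's
    similarity as weight: value = sum(sim_i * y_ij) / sum(sim_i).
    """
    w, y = [], []
    for nb in neighbors:
        for v in nb.measurements:
            w.append(nb.similarity)
            y.append(v)
    w_arr = np.asarray(w)
    y_arr = np.asarray(y)
    value = float(np.sum(w_arr * y_arr) / np.sum(w_arr))
    spread = float(np.sqrt(np.sum(w_arr * (y_arr - value) ** 2) / np.sum(w_arr)))
    return value, spread


class ReadAcrossModel:
    """Read-across LOAEL model over a preprocessed training dataset.

    This is a lazy learner: construction only indexes the training data, and
    a local model is fit per query at prediction time.

    Parameters
    ----------
    training : ToxDataset
        Preprocessed training data (the union of the source databases).
    thresholds : (float, float)
        Tiered similarity thresholds; defaults to (0.5, 0.2).
    min_neighbors : int
        Minimum number of distinct neighbor structures to attempt a random
        forest; below this the fallback fires.
    n_bootstrap : int
        Bootstrap resamples used to tune the forest and estimate its RMSE.
    tune_trees, final_trees : int
        Forest sizes during hyperparameter tuning and for the final fit.
    """

    def __init__(
        self,
        training: ToxDataset,
        thresholds: tuple[float, float] = DEFAULT_THRESHOLDS,
        min_neighbors: int = 2,
        n_bootstrap: int = 25,
        tune_trees: int = 10,
        final_trees: int = 100,
        default_seed: int = 42,
    ):
        if training.n_records == 0:
            raise ValueError("training dataset is empty")
        self.training = training
        self.thresholds = thresholds
        self.min_neighbors = min_neighbors
        self.n_bootstrap = n_bootstrap
        self.tune_trees = tune_trees
        self.final_trees = final_trees
        self.default_seed = default_seed

    # -- constructors ------------------------------------------------------
    @classmethod
    def from_dataframe(
        cls, frame, smiles_column: str, value_column: str,
        unit: str = "mmol/kg_bw/day", name: str = "training", **kwargs,
    ) -> "ReadAcrossModel":
        from .data import dataset_from_records

        rows = list(zip(frame[smiles_column], frame[value_column]))
        return cls(dataset_from_records(name, rows, unit=unit), **kwargs)

    @classmethod
    def from_csv(
        cls, path, smiles_column: str, value_column: str,
        unit: str = "mg/kg_bw/day", **kwargs,
    ) -> "ReadAcrossModel":
        from .data import read_loael_table

        return cls(read_loael_table(path, smiles_column, value_column, unit=unit), **kwargs)

    # -- neighbor search ---------------------------------------------------
    def find_neighbors(self, query: Structure, threshold: float) -> list[Neighbor]:
        """Training structures with similarity >= threshold, query excluded.

        The query's own canonical structure never appears among the
        neighbors, which keeps predictions unbiased in the presence of
        duplicates.  Sorted by descending similarity, ties broken by
        canonical SMILES so the ordering is platform-stable.
        """
        neighbors = []
        for smi, structure in self.training.structures.items():
            if smi == query.canonical_smiles:
                continue
            sim = tanimoto(query.fingerprint, structure.fingerprint)
            if sim >= threshold:
                neighbors.append(
                    Neighbor(
                        structure=structure,
                        similarity=sim,
                        measurements=tuple(self.training.measurements(smi)),
                    )
                )
        neighbors.sort(key=lambda nb: (-nb.similarity, nb.structure.canonical_smiles))
        return neighbors

    # -- local model -------------------------------------------------------
    def _design_matrix(self, neighbors: list[Neighbor], features: list[str]):
        rows, y, w = [], [], []
        for nb in neighbors:
            vec = [1.0 if f in nb.structure.fingerprint else 0.0 for f in features]
            for v in nb.measurements:
                rows.append(vec)
                y.append(v)
                w.append(nb.similarity)
        return np.asarray(rows), np.asarray(y), np.asarray(w)

    def fit_local_model(
        self, neighbors: list[Neighbor], features: list[str], seed: int
    ) -> LocalModel:
        """Fit a similarity-weighted random forest on the neighbor set.

        The features-per-split hyperparameter (mtry) is selected over the
        grid {sqrt(p), p/2, p} by bootstrap resampling: each resample draws
        neighbor compounds with replacement, fits candidate forests on their
        rows (with similarity weights) and scores them on the rows of the
        compounds left out of the resample; the candidate with the smallest
        pooled out-of-resample RMSE wins, and that RMSE becomes the
        prediction-interval estimate.

        Resampling is at the compound level, not the row level: the query is
        always a compound the local model has never seen, so held-out rows
        must come from compounds entirely absent from the resample —
        otherwise replicate measurements of a compound leak across the split
        and the RMSE collapses toward replicate noise.

        Each neighbor contributes one row per measurement, so experimental
        variability propagates into the local model and its interval.
        """
        if len({nb.structure.canonical_smiles for nb in neighbors}) < self.min_neighbors:
            raise LocalFitError("fewer distinct neighbors than required for a random forest")
        if not features:
            raise LocalFitError("no informative features across the neighbor set")
        X, y, w = self._design_matrix(neighbors, features)
        if len(y) < 2:
            raise LocalFitError("fewer than two training rows")
        p = len(features)
        grid = sorted({max(1, int(np.sqrt(p))), max(1, p // 2), p})
        rng = np.random.default_rng(seed)
        # rows of each distinct neighbor, for compound-level resampling
        row_groups: list[np.ndarray] = []
        start = 0
        for nb in neighbors:
            k = len(nb.measurements)
            row_groups.append(np.arange(start, start + k))
            start += k
        n_groups = len(row_groups)
        residuals: dict[int, list[np.ndarray]] = {m: [] for m in grid}
        for _ in range(self.n_bootstrap):
            drawn = rng.integers(0, n_groups, n_groups)
            idx = np.concatenate([row_groups[g] for g in drawn])
            held_out = set(range(n_groups)) - set(drawn.tolist())
            if not held_out:
                continue
            oob = np.concatenate([row_groups[g] for g in sorted(held_out)])
            fit_seed = int(rng.integers(0, 2**31 - 1))
            for m in grid:
                rf = RandomForestRegressor(
                    n_estimators=self.tune_trees, max_features=m, random_state=fit_seed
                )
                rf.fit(X[idx], y[idx], sample_weight=w[idx])
                residuals[m].append(rf.predict(X[oob]) - y[oob])
        scores = {}
        for m in grid:
            if not residuals[m]:
                raise LocalFitError("no out-of-resample rows in any bootstrap resample")
            res = np.concatenate(residuals[m])
            scores[m] = float(np.sqrt(np.mean(res**2)))
        best = min(grid, key=lambda m: (scores[m], m))
        final = RandomForestRegressor(
            n_estimators=self.final_trees, max_features=best, random_state=seed
        )
        final.fit(X, y, sample_weight=w)
        return LocalModel(regressor=final, features=features, rmse=scores[best], mtry=best)

    # -- prediction --------------------------------------------------------
    def predict(self, query_smiles: str, seed: int | None = None) -> Prediction | NoPrediction:
        """Tiered read-across prediction for one query SMILES.

        Raises :class:`~readacross.chem.SmilesParseError` for unparsable
        queries; returns :class:`NoPrediction` when no neighbors exist at
        the lower threshold.
        """
        seed = self.default_seed if seed is None else seed
        query = canonicalize(query_smiles)
        return self.predict_structure(query, seed)

    def predict_structure(self, query: Structure, seed: int) -> Prediction | NoPrediction:
        low_threshold = self.thresholds[-1]
        any_neighbors = False
        for tier, threshold in enumerate(self.thresholds):
            neighbors = self.find_neighbors(query, threshold)
            if not neighbors:
                continue
            any_neighbors = True
            warnings: list[str] = []
            if tier > 0:
                warnings.append(WARN_LOW_SIMILARITY.format(threshold=threshold))
            features = remove_uninformative_features(neighbors)
            try:
                local = self.fit_local_model(neighbors, features, seed)
            except LocalFitError:
                if threshold > low_threshold:
                    continue  # retry the whole procedure at the lower tier
                value, spread = weighted_mean_prediction(neighbors)
                warnings.append(WARN_WEIGHTED_MEAN)
                return Prediction(
                    query=query,
                    value=value,
                    rmse=spread,
                    interval_low=value - 1.96 * spread,
                    interval_high=value + 1.96 * spread,
                    threshold_used=threshold,
                    method_used="weighted-mean",
                    warnings=tuple(warnings),
                    neighbors=tuple(neighbors),
                )
            value = local.predict_structure(query)
            return Prediction(
                query=query,
                value=value,
                rmse=local.rmse,
                interval_low=value - 1.96 * local.rmse,
                interval_high=value + 1.96 * local.rmse,
                threshold_used=threshold,
                method_used="local-rf",
                warnings=tuple(warnings),
                neighbors=tuple(neighbors),
            )
        reason = (
            "no similar compounds in the training data"
            if not any_neighbors
            else "local model could not be fit at any threshold"
        )
        return NoPrediction(query=query, reason=reason)
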