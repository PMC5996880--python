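"""Leakage-proof model validation.

Evaluates the read-across engine on a test set of compounds with replicate
measurements and by repeated k-fold cross-validation, always splitting at
the level of unique structures so that no measurement of a query compound
can inform its own prediction.  (The engine additionally excludes the
query's canonical structure from every neighbor search, so the leakage
guard holds even for datasets with duplicated structures.)

Predictions are scored against the MEDIAN of a compound's experimental
-log10 values, and summaries are stratified by applicability-domain tier:
``ad-close`` (no warnings), ``ad-distant`` (warnings raised) and ``all``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .data import ConfigurationError, ToxDataset
from .model import NoPrediction, Prediction, ReadAcrossModel

TIERS = ("ad-close", "ad-distant", "all")


class ConstantInputError(ValueError):
    """Correlation of a constant vector is undefined."""


def correlation_stats(predicted, observed) -> tuple[float, float, float]:
    """(r², RMSE, p-value) of predicted vs observed values.

    r² is the squared Pearson correlation; the p-value is from the
    two-sided Pearson correlation test.
    """
    predicted = np.asarray(predicted, dtype=float)
    observed = np.asarray(observed, dtype=float)
    if predicted.shape != observed.shape:
        raise ValueError("predicted and observed must have equal length")
    if predicted.size < 3:
        raise ValueError("need at least 3 points for correlation statistics")
    if np.ptp(predicted) == 0 or np.ptp(observed) == 0:
        raise ConstantInputError("correlation is undefined for a constant vector")
    r, p = stats.pearsonr(predicted, observed)
    rmse = float(np.sqrt(np.mean((predicted - observed) ** 2)))
    return float(r**2), rmse, float(p)


@dataclass
class ValidationSummary:
    """Prediction quality within one applicability-domain tier."""

    tier: str
    r_squared: float
    rmse: float
    n_predicted: int
    n_attempted: int
    pi_coverage: float
    p_value: float = float("nan")


def _tier_summary(tier: str, frame: pd.DataFrame, n_attempted: int) -> ValidationSummary:
    """Summarize the per-compound prediction table of one tier."""
    n = len(frame)
    r2 = rmse = p = float("nan")
    if n >= 1:
        rmse = float(np.sqrt(np.mean((frame["predicted"] - frame["observed"]) ** 2)))
    if n >= 3:
        try:
            r2, rmse, p = correlation_stats(frame["predicted"], frame["observed"])
        except ConstantInputError:
            pass
    cov_n = int(frame["n_measurements"].sum()) if n else 0
    coverage = float(frame["n_in_interval"].sum() / cov_n) if cov_n else float("nan")
    return ValidationSummary(
        tier=tier,
        r_squared=r2,
        rmse=rmse,
        n_predicted=n,
        n_attempted=n_attempted,
        pi_coverage=coverage,
        p_value=p,
    )


def _summaries_from_table(table: pd.DataFrame, n_attempted: int) -> dict[str, ValidationSummary]:
    ok = table[table["predicted"].notna()]
    return {
        "ad-close": _tier_summary("ad-close", ok[ok["ad_close"]], n_attempted),
        "ad-distant": _tier_summary("ad-distant", ok[~ok["ad_close"]], n_attempted),
        "all": _tier_summary("all", ok, n_attempted),
    }


def _summary_frame(summaries: dict[str, ValidationSummary]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "tier": s.tier,
                "r2": s.r_squared,
                "rmse": s.rmse,
                "n_predicted": s.n_predicted,
                "n_attempted": s.n_attempted,
                "pi_coverage": s.pi_coverage,
            }
            for s in summaries.values()
        ]
    )


class TestSetResult:
    """Predictions and tier-stratified summaries for a fixed test set."""

    def __init__(self, table: pd.DataFrame, predictions: dict, n_attempted: int):
        self.table = table
        self.predictions = predictions
        self.n_attempted = n_attempted
        self.summaries = _summaries_from_table(table, n_attempted)

    @property
    def n_failed(self) -> int:
        return int(self.table["predicted"].isna().sum())

    def summary(self) -> str:
        frame = _summary_frame(self.summaries)
        lines = [
            f"test-set evaluation: {self.n_attempted} compounds attempted, "
            f"{self.n_attempted - self.n_failed} predicted, {self.n_failed} without prediction",
            frame.to_string(index=False, float_format=lambda v: f"{v:.3f}"),
        ]
        return "\n".join(lines)


def evaluate_test_set(
    test: ToxDataset,
    training: ToxDataset,
    seed: int = 42,
    model: ReadAcrossModel | None = None,
    **model_kwargs,
) -> TestSetResult:
    """Predict every unique test structure and score against its median.

    The engine's hardcoded structure exclusion guarantees that none of the
    query's own training records (which are present in the training set by
    construction of the test set) contribute to its prediction.
    """
    model = model or ReadAcrossModel(training, **model_kwargs)
    rows = []
    predictions: dict[str, Prediction | NoPrediction] = {}
    structures = sorted(test.structure_set())
    rng = np.random.default_rng(seed)
    for smi in structures:
        query_seed = int(rng.integers(0, 2**31 - 1))
        values = test.measurements(smi)
        pred = model.predict_structure(test.structures[smi], query_seed)
        predictions[smi] = pred
        row = {
            "canonical_smiles": smi,
            "observed": float(np.median(values)),
            "n_measurements": len(values),
        }
        if isinstance(pred, Prediction):
            # leakage guard, asserted on every prediction
            assert all(
                nb.structure.canonical_smiles != smi for nb in pred.neighbors
            ), "query structure leaked into its own neighbor list"
            row.update(
                predicted=pred.value,
                rmse_estimate=pred.rmse,
                interval_low=pred.interval_low,
                interval_high=pred.interval_high,
                ad_close=pred.ad_close,
                method=pred.method_used,
                threshold=pred.threshold_used,
                n_neighbors=len(pred.neighbors),
                n_in_interval=sum(pred.contains(v) for v in values),
            )
        else:
            row.update(
                predicted=np.nan,
                rmse_estimate=np.nan,
                interval_low=np.nan,
                interval_high=np.nan,
                ad_close=False,
                method="none",
                threshold=np.nan,
                n_neighbors=0,
                n_in_interval=0,
            )
        rows.append(row)
    table = pd.DataFrame(rows)
    return TestSetResult(table, predictions, n_attempted=len(structures))


class CrossValidationResult:
    """Per-repeat summaries of repeated k-fold CV and their mean +/- SD."""

    def __init__(self, repeats: list[dict[str, ValidationSummary]], k: int):
        self.repeats = repeats
        self.k = k

    def aggregate(self) -> pd.DataFrame:
        """Mean and SD over repeats of r², RMSE and predicted count, per tier."""
        rows = []
        for tier in TIERS:
            for stat_name, attr in (("r2", "r_squared"), ("rmse", "rmse"),
                                    ("n_predicted", "n_predicted"),
                                    ("pi_coverage", "pi_coverage")):
                vals = np.array([getattr(rep[tier], attr) for rep in self.repeats], float)
                rows.append(
                    {
                        "tier": tier,
                        "statistic": stat_name,
                        "mean": float(np.nanmean(vals)) if vals.size else float("nan"),
                        "sd": float(np.nanstd(vals, ddof=1)) if vals.size > 1 else float("nan"),
                    }
                )
        return pd.DataFrame(rows)

    def tier_mean(self, tier: str, statistic: str = "rmse") -> float:
        agg = self.aggregate()
        sel = agg[(agg["tier"] == tier) & (agg["statistic"] == statistic)]
        return float(sel["mean"].iloc[0])

    def summary(self) -> str:
        header = f"{len(self.repeats)} repeats of {self.k}-fold cross-validation (structure-level splits)"
        return "\n".join(
            [header, self.aggregate().to_string(index=False, float_format=lambda v: f"{v:.3f}")]
        )


def repeated_kfold(
    training: ToxDataset,
    k: int = 10,
    repeats: int = 50,
    seed: int = 42,
    **model_kwargs,
) -> CrossValidationResult:
    """Repeated k-fold cross-validation with independent structure-level splits.

    All measurements of a compound stay in the same fold; the held-out
    compounds of each fold are predicted from a model built on the remaining
    folds and scored against the median of their own measurements.
    """
    if k < 2:
        raise ConfigurationError("k must be at least 2")
    structures = sorted(training.structure_set())
    if len(structures) < k:
        raise ConfigurationError(
            f"dataset has {len(structures)} structures, fewer than k={k}"
        )
    rng = np.random.default_rng(seed)
    repeat_summaries = []
    for _ in range(repeats):
        order = rng.permutation(len(structures))
        fold_of = {structures[j]: i % k for i, j in enumerate(order)}
        rows = []
        for fold in range(k):
            held_out = {s for s, f in fold_of.items() if f == fold}
            train_part = training.subset(
                {s for s in structures if s not in held_out}, name="cv-train"
            )
            model = ReadAcrossModel(train_part, **model_kwargs)
            for smi in sorted(held_out):
                # fold integrity: none of the held-out structure's records
                # are in the fold's training part
                assert smi not in train_part.structure_set()
                values = training.measurements(smi)
                pred = model.predict_structure(
                    training.structures[smi], int(rng.integers(0, 2**31 - 1))
                )
                row = {
                    "canonical_smiles": smi,
                    "observed": float(np.median(values)),
                    "n_measurements": len(values),
                }
                if isinstance(pred, Prediction):
                    row.update(
                        predicted=pred.value,
                        ad_close=pred.ad_close,
                        n_in_interval=sum(pred.contains(v) for v in values),
                    )
                else:
                    row.update(predicted=np.nan, ad_close=False, n_in_interval=0)
                rows.append(row)
        table = pd.DataFrame(rows)
        repeat_summaries.append(_summaries_from_table(table, len(structures)))
    return CrossValidationResult(repeat_summaries, k=k)
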