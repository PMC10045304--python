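"""Head-to-head comparison of the Weibull AFT and RSF model tracks.

Produces a compact report with one row per (model, data partition):
prediction error rate (1 - C), Harrell C-index, and the variables each
track selects as most predictive — backward Wald elimination at a fixed
significance level for the Weibull track, positive-VIMP ranking for the
forest track.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cohort import CohortDataset, CohortError
from .rsf import (
    ForestConfig,
    SurvivalForest,
    fit_forest,
    mortality_score,
    oob_mortality_scores,
    variable_importance,
)
from .survival_core import concordance_index
from .weibull import WeibullAFTFit, encode_pattern, fit_weibull_aft

logger = logging.getLogger(__name__)

_HOLDOUT_STREAM = 986_527  # sub-stream tag for the train/test shuffle


def weibull_risk_score(fit: WeibullAFTFit, covariates: Mapping[str, object]) -> float:
    """Monotone worse-outcome score for an AFT fit: -x' beta.

    A shorter predicted time means a higher risk, making the score directly
    comparable with forest mortality under the same concordance rules.
    """
    return -fit.linear_predictor(covariates)


def weibull_risk_scores(fit: WeibullAFTFit, data: CohortDataset) -> np.ndarray:
    """Vectorized ``weibull_risk_score`` over a cohort."""
    from .weibull import build_design_matrix

    design = build_design_matrix(data, fit.design.covariates_used)
    return -(design.matrix @ fit.beta.to_numpy())


def weibull_selected_variables(
    data: CohortDataset,
    alpha: float = 0.05,
    covariates: Sequence[str] | None = None,
) -> list[str]:
    """Backward elimination at significance level ``alpha``.

    Starting from the full fit, repeatedly drop the covariate whose worst
    (largest) Wald p-value across its design columns exceeds ``alpha``;
    stop when every remaining covariate has all columns significant, or no
    covariates remain.  Returns survivors in schema order.
    """
    current = list(data.schema.names if covariates is None else covariates)
    while current:
        fit = fit_weibull_aft(data, covariates=current)
        worst_name, worst_p = None, -np.inf
        for name in current:
            cols = [
                c for c, parent in zip(fit.design.column_names, fit.design.covariate_of)
                if parent == name
            ]
            p = float(fit.wald_p[cols].max())
            if p > worst_p:
                worst_name, worst_p = name, p
        if worst_p <= alpha:
            break
        logger.info("backward elimination: dropping %r (max Wald p=%.4f)", worst_name, worst_p)
        current.remove(worst_name)  # type: ignore[arg-type]
    return current


def rsf_selected_variables(
    vimp: Mapping[str, float], threshold: float = 0.0
) -> list[str]:
    """Variables with VIMP above ``threshold``, sorted descending by VIMP."""
    keep = [(name, value) for name, value in vimp.items() if value > threshold]
    keep.sort(key=lambda item: (-item[1], item[0]))
    return [name for name, _ in keep]


@dataclass
class ComparisonRow:
    model: str
    error_rate: float
    c_index: float
    selected_variables: list[str]


@dataclass
class ComparisonReport:
    """Per-model error rate, C-index and selected variables.

    ``metadata`` records the configuration and seed so a report can be
    regenerated; the canonical serialization is stable (sorted keys, floats
    at 6 significant digits) and deliberately excludes wall-clock
    timestamps so that regeneration under the same seed is byte-identical.
    """

    rows: list[ComparisonRow]
    metadata: dict = field(default_factory=dict)
    created: str | None = None  # informational only; never serialized

    def __post_init__(self) -> None:
        for row in self.rows:
            if abs(row.error_rate - (1.0 - row.c_index)) > 1e-12:
                raise ValueError(f"row {row.model!r}: error_rate must equal 1 - c_index")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "model": [r.model for r in self.rows],
                "error_rate": [r.error_rate for r in self.rows],
                "c_index": [r.c_index for r in self.rows],
                "most_predictive_variables": [
                    ", ".join(r.selected_variables) for r in self.rows
                ],
            }
        )

    def to_json(self) -> str:
        payload = {
            "rows": [
                {
                    "model": r.model,
                    "error_rate": _sig6(r.error_rate),
                    "c_index": _sig6(r.c_index),
                    "most_predictive_variables": list(r.selected_variables),
                }
                for r in self.rows
            ],
            "metadata": self.metadata,
        }
        return json.dumps(payload, indent=2, sort_keys=True)

    def to_csv(self) -> str:
        frame = self.to_frame()
        frame["error_rate"] = frame["error_rate"].map(_sig6)
        frame["c_index"] = frame["c_index"].map(_sig6)
        return frame.to_csv(index=False)


def _sig6(x: float) -> float:
    return float(f"{x:.6g}")


def stratified_holdout(
    data: CohortDataset, fraction: float, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """Seeded train/test split stratified by the event indicator.

    Returns (train_indices, test_indices); ``fraction`` is the test share.
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError("holdout fraction must lie in (0, 1)")
    rng = np.random.default_rng([seed, _HOLDOUT_STREAM])
    test_parts = []
    for value in (0, 1):
        members = np.flatnonzero(data.events == value)
        if members.size == 0:
            continue
        perm = rng.permutation(members)
        n_test = int(round(fraction * members.size))
        n_test = min(max(n_test, 1), members.size - 1)
        test_parts.append(perm[:n_test])
    test = np.sort(np.concatenate(test_parts))
    train = np.setdiff1d(np.arange(len(data)), test)
    return train, test


def compare_models(
    data: CohortDataset,
    forest_config: ForestConfig | None = None,
    alpha: float = 0.05,
    holdout: float = 0.3,
    holdout_weibull: bool = False,
    covariates: Sequence[str] | None = None,
) -> ComparisonReport:
    """Fit both tracks and assemble the three-row comparison report.

    The forest is fitted on a seeded stratified training partition; its
    training row uses the OOB error and its testing row scores the held-out
    records with the all-tree ensemble hazard.  The Weibull row fits (after
    backward selection at ``alpha``) on the full cohort and reports the
    in-sample C-index of its risk score, unless ``holdout_weibull``
    restricts fitting to the training partition and scoring to the test one.
    """
    config = forest_config if forest_config is not None else ForestConfig()
    train_idx, test_idx = stratified_holdout(data, holdout, config.seed)
    train, test = data.subset(train_idx), data.subset(test_idx)
    for name, part in (("training", train), ("testing", test)):
        if part.n_events == 0:
            raise CohortError(f"{name} partition contains no deaths")

    forest = fit_forest(train, config, covariates)
    oob_scores = oob_mortality_scores(forest)
    c_train = concordance_index(oob_scores, train)
    vimp = variable_importance(forest, train)
    rsf_vars = rsf_selected_variables(vimp)

    # all-tree ensemble mortality for held-out records
    from .rsf import build_feature_space

    test_features = build_feature_space(test, covariates)
    acc = np.zeros((len(test), forest.event_time_grid.size))
    for b in range(forest.n_trees):
        tree = forest.trees[b]
        terminal_ids = tree.route(test_features.matrix)
        acc += forest.terminal_grid_values(b)[terminal_ids]
    test_scores = np.sum(acc / forest.n_trees, axis=1)
    c_test = concordance_index(test_scores, test)

    weibull_data = train if holdout_weibull else data
    selected = weibull_selected_variables(weibull_data, alpha=alpha, covariates=covariates)
    fit = fit_weibull_aft(weibull_data, covariates=selected or None)
    score_data = test if holdout_weibull else data
    w_scores = weibull_risk_scores(fit, score_data)
    c_weibull = concordance_index(w_scores, score_data)

    rows = [
        ComparisonRow("RSF (training)", 1.0 - c_train, c_train, list(rsf_vars)),
        ComparisonRow("RSF (testing)", 1.0 - c_test, c_test, list(rsf_vars)),
        ComparisonRow("Weibull regression", 1.0 - c_weibull, c_weibull, list(selected)),
    ]
    metadata = {
        "seed": config.seed,
        "n_trees": config.n_trees,
        "mtry": config.resolved_mtry(build_feature_space(data, covariates).n_covariates),
        "min_terminal_size": config.min_terminal_size,
        "alpha": alpha,
        "holdout_fraction": holdout,
        "holdout_weibull": holdout_weibull,
        "n_records": len(data),
        "n_train": len(train),
        "n_test": len(test),
        "vimp": {k: _sig6(v) for k, v in vimp.items()},
    }
    return ComparisonReport(rows=rows, metadata=metadata)
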