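"""Random survival forest with log-rank splitting.

Trees are grown on bootstrap samples of the cohort; at every splittable
node ``mtry`` candidate covariates are drawn and the split maximizing the
absolute standardized log-rank statistic |LR(x, c)| over all midpoint
thresholds is taken.  Terminal nodes store the Nelson–Aalen cumulative
hazard of their in-bag records.  Predictions are ensemble averages of
per-tree cumulative hazards; out-of-bag (OOB) averages restrict to trees
whose bootstrap sample excluded the record.  Prediction error is
1 - Harrell C-index of the OOB mortality scores, and variable importance
(VIMP) is the error increase when a variable's split decisions are
replaced by random child assignment.

Randomness contract (all draws from numpy Generators, reproducible):

* tree ``b``: ``rng_b = np.random.default_rng([seed, b])``; first draw is
  the bootstrap ``rng_b.integers(0, n, size=n)``, then tree growth is
  depth-first (left child fully grown before the right) drawing
  ``rng_b.choice(n_covariates, size=mtry, replace=False)`` at every node
  that passes the size/death checks;
* VIMP for covariate index ``v``:
  ``rng_v = np.random.default_rng([seed, 2**20 + v])``; trees are visited
  in index order, each tree's OOB records are routed together depth-first,
  and at every node splitting on ``v`` one uniform per record at the node
  (ascending record order) decides the child (< 0.5 goes left).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .cohort import CohortDataset, CohortError
from .survival_core import (
    CUMULATIVE_HAZARD,
    StepEstimate,
    _na_arrays,
    concordance_index,
)
from .weibull import build_design_matrix

logger = logging.getLogger(__name__)

_VIMP_STREAM_OFFSET = 2**20


@dataclass
class ForestConfig:
    """Forest hyper-parameters.

    ``mtry`` defaults to ceil(sqrt(#covariates)); ``min_terminal_size`` is
    the node-size splitting floor: a node is terminal when it holds fewer
    than ``2 * min_terminal_size`` records, contains no death, or admits no
    valid split.
    """

    n_trees: int = 1000
    mtry: int | None = None
    min_terminal_size: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise ValueError("n_trees must be positive")
        if self.min_terminal_size < 1:
            raise ValueError("min_terminal_size must be >= 1")
        if self.mtry is not None and self.mtry < 1:
            raise ValueError("mtry must be positive")

    def resolved_mtry(self, n_covariates: int) -> int:
        if self.mtry is None:
            return int(np.ceil(np.sqrt(n_covariates)))
        return min(self.mtry, n_covariates)


@dataclass
class FeatureSpace:
    """Tree feature columns: numerics plus reference-skipping 0/1 indicators.

    Each column is tagged with the index of its parent covariate so that
    candidate sampling and VIMP operate per covariate, not per column.
    """

    matrix: np.ndarray
    column_names: list[str]
    covariate_names: tuple[str, ...]
    column_covariate: np.ndarray  # covariate index per column
    schema: object = field(repr=False)

    @property
    def n_covariates(self) -> int:
        return len(self.covariate_names)

    def encode_pattern(self, covariates: Mapping[str, object]) -> np.ndarray:
        from .weibull import DesignMatrix, encode_pattern

        design = DesignMatrix(
            matrix=np.ones((0, len(self.column_names) + 1)),
            column_names=["intercept"] + self.column_names,
            covariate_of=[None] + [self.covariate_names[c] for c in self.column_covariate],
            schema=self.schema,  # type: ignore[arg-type]
            covariates_used=self.covariate_names,
        )
        return encode_pattern(design, covariates)[1:]


def build_feature_space(
    data: CohortDataset, covariates: Sequence[str] | None = None
) -> FeatureSpace:
    design = build_design_matrix(data, covariates)
    cov_names = design.covariates_used
    cov_index = {name: i for i, name in enumerate(cov_names)}
    return FeatureSpace(
        matrix=np.ascontiguousarray(design.matrix[:, 1:]),
        column_names=design.column_names[1:],
        covariate_names=cov_names,
        column_covariate=np.array([cov_index[c] for c in design.covariate_of[1:]]),
        schema=data.schema,
    )


def log_rank_split_statistic(
    times: np.ndarray, events: np.ndarray, x: np.ndarray, threshold: float
) -> float:
    """Standardized log-rank statistic LR(x, c) for the split x <= c vs x > c.

    LR = sum_j (d_Lj - n_Lj d_j / n_j) /
         sqrt( sum_j (n_Lj/n_j)(1 - n_Lj/n_j)((n_j - d_j)/(n_j - 1)) d_j )
    over the node's distinct death times, skipping times with n_j <= 1.
    Zero variance yields LR = 0 by convention.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events)
    x = np.asarray(x, dtype=float)
    left = x <= threshold
    if not left.any() or left.all():
        raise CohortError("invalid threshold: one child is empty")
    if events.sum() == 0:
        raise CohortError("node contains no deaths")
    death_times = np.unique(times[events == 1])
    at_risk = times[:, None] >= death_times[None, :]
    dying = (times[:, None] == death_times[None, :]) & (events[:, None] == 1)
    n_tot = at_risk.sum(axis=0).astype(float)
    d_tot = dying.sum(axis=0).astype(float)
    n_left = at_risk[left].sum(axis=0).astype(float)
    d_left = dying[left].sum(axis=0).astype(float)
    usable = n_tot > 1
    ratio = np.where(usable, d_tot / np.maximum(n_tot, 1.0), 0.0)
    p_left = np.where(usable, n_left / np.maximum(n_tot, 1.0), 0.0)
    numerator = float(np.sum(np.where(usable, d_left - n_left * ratio, 0.0)))
    variance = float(
        np.sum(
            np.where(
                usable,
                p_left * (1.0 - p_left) * ((n_tot - d_tot) / np.maximum(n_tot - 1.0, 1.0)) * d_tot,
                0.0,
            )
        )
    )
    if variance <= 0.0:
        return 0.0
    return numerator / np.sqrt(variance)


def find_best_split(
    times: np.ndarray,
    events: np.ndarray,
    features: np.ndarray,
    column_covariate: np.ndarray,
    candidate_covariates: np.ndarray,
) -> tuple[int, float, float] | None:
    """Exhaustive |LR| scan over candidate covariates and midpoint thresholds.

    Candidate thresholds are the midpoints between consecutive distinct
    sorted values of each feature column.  Ties in |LR| go to the first
    covariate in schema order, then to the smallest threshold.  Returns
    ``(column, threshold, |LR|)`` or ``None`` when no valid split exists.
    """
    events = np.asarray(events)
    if events.sum() == 0:
        return None
    times = np.asarray(times, dtype=float)
    death_times = np.unique(times[events == 1])
    # per-record at-risk / dying indicators, shared across candidate columns
    at_risk_all = (times[:, None] >= death_times[None, :]).astype(float)
    dying_all = ((times[:, None] == death_times[None, :]) & (events[:, None] == 1)).astype(float)
    n_tot = at_risk_all.sum(axis=0)
    d_tot = dying_all.sum(axis=0)
    usable = n_tot > 1
    best: tuple[int, float, float] | None = None
    for cov in np.sort(np.asarray(candidate_covariates)):
        for col in np.flatnonzero(column_covariate == cov):
            x = features[:, col]
            order = np.argsort(x, kind="stable")
            xs = x[order]
            boundaries = np.flatnonzero(xs[:-1] < xs[1:])
            if boundaries.size == 0:
                continue  # constant within the node
            cum_risk = np.cumsum(at_risk_all[order], axis=0)
            cum_dead = np.cumsum(dying_all[order], axis=0)
            ratio = np.where(usable, d_tot / np.maximum(n_tot, 1.0), 0.0)
            n_left = cum_risk[boundaries]
            d_left = cum_dead[boundaries]
            p_left = np.where(usable, n_left / np.maximum(n_tot, 1.0), 0.0)
            numerator = np.sum(np.where(usable, d_left - n_left * ratio, 0.0), axis=1)
            variance = np.sum(
                np.where(
                    usable,
                    p_left
                    * (1.0 - p_left)
                    * ((n_tot - d_tot) / np.maximum(n_tot - 1.0, 1.0))
                    * d_tot,
                    0.0,
                ),
                axis=1,
            )
            with np.errstate(invalid="ignore", divide="ignore"):
                lr = np.where(variance > 0.0, numerator / np.sqrt(variance), 0.0)
            abs_lr = np.abs(lr)
            s = int(np.argmax(abs_lr))  # first max = smallest threshold
            score = float(abs_lr[s])
            if best is None or score > best[2]:
                threshold = float((xs[boundaries[s]] + xs[boundaries[s] + 1]) / 2.0)
                best = (int(col), threshold, score)
    return best


@dataclass
class TreeNode:
    feature: int = -1  # column index; -1 marks a terminal node
    covariate: int = -1  # parent covariate index of the split column
    threshold: float = np.nan
    left: "TreeNode | None" = None
    right: "TreeNode | None" = None
    chf: StepEstimate | None = None
    in_bag_records: np.ndarray | None = None  # original record indices (with multiplicity)
    terminal_id: int = -1

    @property
    def is_terminal(self) -> bool:
        return self.feature < 0


@dataclass
class SurvivalTree:
    """One bootstrap survival tree with terminal Nelson–Aalen hazards."""

    root: TreeNode
    in_bag: np.ndarray  # bootstrap draw, size n, with multiplicity
    oob_indices: np.ndarray  # sorted unique record indices absent from in_bag
    terminals: list[TreeNode]
    features: FeatureSpace = field(repr=False)

    def route(self, feature_rows: np.ndarray) -> np.ndarray:
        """Terminal id for every row of a feature matrix."""
        rows = np.atleast_2d(feature_rows)
        out = np.empty(rows.shape[0], dtype=np.int64)
        self._route(self.root, np.arange(rows.shape[0]), rows, out)
        return out

    def _route(self, node: TreeNode, idx: np.ndarray, rows: np.ndarray, out: np.ndarray) -> None:
        if node.is_terminal:
            out[idx] = node.terminal_id
            return
        go_left = rows[idx, node.feature] <= node.threshold
        self._route(node.left, idx[go_left], rows, out)  # type: ignore[arg-type]
        self._route(node.right, idx[~go_left], rows, out)  # type: ignore[arg-type]


def grow_tree(
    data: CohortDataset,
    config: ForestConfig,
    rng: np.random.Generator,
    features: FeatureSpace | None = None,
) -> SurvivalTree:
    """Grow one survival tree on a fresh bootstrap sample.

    Terminal nodes store the Nelson–Aalen cumulative hazard of the in-bag
    records routed to them.
    """
    if features is None:
        features = build_feature_space(data)
    return _grow_tree(data.times, data.events, features, config, rng)


def _grow_tree(
    times: np.ndarray,
    events: np.ndarray,
    features: FeatureSpace,
    config: ForestConfig,
    rng: np.random.Generator,
) -> SurvivalTree:
    n = len(times)
    mtry = config.resolved_mtry(features.n_covariates)
    in_bag = rng.integers(0, n, size=n)
    bt = times[in_bag]
    be = events[in_bag]
    bF = features.matrix[in_bag]
    terminals: list[TreeNode] = []

    def make_terminal(pos: np.ndarray) -> TreeNode:
        node = TreeNode(
            chf=_na_arrays(bt[pos], be[pos]),
            in_bag_records=in_bag[pos],
            terminal_id=len(terminals),
        )
        terminals.append(node)
        return node

    def grow(pos: np.ndarray) -> TreeNode:
        if len(pos) < 2 * config.min_terminal_size or be[pos].sum() == 0:
            return make_terminal(pos)
        candidates = rng.choice(features.n_covariates, size=mtry, replace=False)
        split = find_best_split(
            bt[pos], be[pos], bF[pos], features.column_covariate, candidates
        )
        if split is None:
            return make_terminal(pos)
        col, threshold, _ = split
        go_left = bF[pos, col] <= threshold
        node = TreeNode(
            feature=col,
            covariate=int(features.column_covariate[col]),
            threshold=threshold,
        )
        node.left = grow(pos[go_left])
        node.right = grow(pos[~go_left])
        return node

    root = grow(np.arange(n))
    oob = np.setdiff1d(np.arange(n), in_bag)
    return SurvivalTree(root=root, in_bag=in_bag, oob_indices=oob, terminals=terminals, features=features)


def tree_chf(tree: SurvivalTree, covariates: Mapping[str, object]) -> StepEstimate:
    """Cumulative hazard of the terminal node a covariate pattern routes to."""
    row = tree.features.encode_pattern(covariates)
    terminal = tree.terminals[int(tree.route(row[None, :])[0])]
    return terminal.chf  # type: ignore[return-value]


@dataclass
class SurvivalForest:
    """Bagged survival trees with OOB machinery.

    ``membership[i, b]`` is True when record ``i`` is in-bag for tree ``b``;
    OOB averages run over the trees where it is False.
    ``event_time_grid`` holds the distinct
    ordered training death times t*_1 < ... < t*_k used for mortality
    scores.
    """

    trees: list[SurvivalTree]
    membership: np.ndarray
    config: ForestConfig
    features: FeatureSpace = field(repr=False)
    times: np.ndarray = field(repr=False)
    events: np.ndarray = field(repr=False)
    event_time_grid: np.ndarray = field(repr=False)
    _terminal_grid_values: list[np.ndarray] = field(default_factory=list, repr=False)
    _oob_scores: np.ndarray | None = field(default=None, repr=False)

    @property
    def n_trees(self) -> int:
        return len(self.trees)

    @property
    def n_records(self) -> int:
        return self.membership.shape[0]

    def terminal_grid_values(self, b: int) -> np.ndarray:
        """Terminal CHFs of tree b evaluated on the training death-time grid."""
        if not self._terminal_grid_values:
            self._terminal_grid_values = [None] * self.n_trees  # type: ignore[list-item]
        if self._terminal_grid_values[b] is None:
            tree = self.trees[b]
            vals = np.vstack(
                [t.chf.evaluate(self.event_time_grid) for t in tree.terminals]
            ) if tree.terminals else np.zeros((0, self.event_time_grid.size))
            self._terminal_grid_values[b] = vals
        return self._terminal_grid_values[b]


def fit_forest(
    data: CohortDataset, config: ForestConfig, covariates: Sequence[str] | None = None
) -> SurvivalForest:
    """Grow the full forest (deterministic given data and config.seed)."""
    features = build_feature_space(data, covariates)
    n = len(data)
    trees = []
    membership = np.zeros((n, config.n_trees), dtype=bool)
    for b in range(config.n_trees):
        rng = np.random.default_rng([config.seed, b])
        tree = _grow_tree(data.times, data.events, features, config, rng)
        trees.append(tree)
        membership[np.unique(tree.in_bag), b] = True
    grid = np.unique(data.times[data.events == 1])
    logger.info(
        "grew %d trees on n=%d (seed=%d, mtry=%d, min_terminal_size=%d)",
        config.n_trees, n, config.seed,
        config.resolved_mtry(features.n_covariates), config.min_terminal_size,
    )
    return SurvivalForest(
        trees=trees,
        membership=membership,
        config=config,
        features=features,
        times=data.times.copy(),
        events=data.events.copy(),
        event_time_grid=grid,
    )


def ensemble_chf(
    forest: SurvivalForest,
    covariates: Mapping[str, object] | None = None,
    oob_only: bool = False,
    record_index: int | None = None,
) -> StepEstimate:
    """Pointwise average of per-tree cumulative hazards.

    With ``oob_only`` a training ``record_index`` is required and the
    average runs over the trees whose bootstrap sample excluded that record;
    otherwise all trees contribute (the all-tree ensemble hazard) for the
    given covariate pattern.
    """
    if oob_only:
        if record_index is None:
            raise ValueError("oob_only requires record_index")
        tree_ids = np.flatnonzero(~forest.membership[record_index])
        if tree_ids.size == 0:
            raise CohortError(
                f"record {record_index} is in-bag in every tree; grow more trees"
            )
        row = forest.features.matrix[record_index]
    else:
        if covariates is None:
            raise ValueError("covariates required unless oob_only")
        tree_ids = np.arange(forest.n_trees)
        row = forest.features.encode_pattern(covariates)

    chfs = []
    for b in tree_ids:
        tree = forest.trees[b]
        terminal = tree.terminals[int(tree.route(row[None, :])[0])]
        chfs.append(terminal.chf)
    grid = np.unique(np.concatenate([c.times for c in chfs])) if chfs else np.empty(0)
    if grid.size:
        acc = np.zeros_like(grid)
        for c in chfs:
            acc += c.evaluate(grid)
        values = acc / len(chfs)
    else:
        values = np.empty(0)
    return StepEstimate(grid, values, None, None, kind=CUMULATIVE_HAZARD)


def mortality_score(chf: StepEstimate, event_time_grid: np.ndarray) -> float:
    """Sum of the cumulative hazard over the training death-time grid.

    A record with a uniformly higher ensemble hazard gets a higher score,
    i.e. a predicted worse outcome.
    """
    values = chf.evaluate(np.asarray(event_time_grid, dtype=float))
    return float(np.sum(values))


def _oob_chf_matrix(forest: SurvivalForest) -> tuple[np.ndarray, np.ndarray]:
    """Per-record OOB-averaged CHF on the forest grid, plus OOB tree counts."""
    n, k = forest.n_records, forest.event_time_grid.size
    acc = np.zeros((n, k))
    count = np.zeros(n)
    for b in range(forest.n_trees):
        tree = forest.trees[b]
        oob = tree.oob_indices
        if oob.size == 0:
            continue
        terminal_ids = tree.route(forest.features.matrix[oob])
        acc[oob] += forest.terminal_grid_values(b)[terminal_ids]
        count[oob] += 1
    if np.any(count == 0):
        missing = np.flatnonzero(count == 0).tolist()
        raise CohortError(
            f"record(s) {missing} are in-bag in every tree; increase n_trees"
        )
    return acc / count[:, None], count


def oob_mortality_scores(forest: SurvivalForest) -> np.ndarray:
    """OOB ensemble mortality score per training record."""
    if forest._oob_scores is None:
        chf_matrix, _ = _oob_chf_matrix(forest)
        forest._oob_scores = np.sum(chf_matrix, axis=1)
    return forest._oob_scores


def oob_error_rate(forest: SurvivalForest, data: CohortDataset) -> float:
    """OOB prediction error: 1 - C-index of the OOB mortality scores."""
    scores = oob_mortality_scores(forest)
    return 1.0 - concordance_index(scores, data)


def _noised_route(
    node: TreeNode,
    idx: np.ndarray,
    rows: np.ndarray,
    out: np.ndarray,
    covariate: int,
    rng: np.random.Generator,
) -> None:
    """Route rows, replacing splits on ``covariate`` with random children."""
    if node.is_terminal:
        out[idx] = node.terminal_id
        return
    if node.covariate == covariate:
        go_left = rng.random(idx.size) < 0.5
    else:
        go_left = rows[idx, node.feature] <= node.threshold
    _noised_route(node.left, idx[go_left], rows, out, covariate, rng)  # type: ignore[arg-type]
    _noised_route(node.right, idx[~go_left], rows, out, covariate, rng)  # type: ignore[arg-type]


def variable_importance(
    forest: SurvivalForest, data: CohortDataset, rng: np.random.Generator | None = None
) -> dict[str, float]:
    """Random-daughter VIMP per covariate.

    For covariate v, every OOB record is dropped down each tree again but
    sent to a uniformly random child at nodes splitting on v; VIMP(v) is
    the noised OOB error minus the original one.  A covariate never chosen
    by any node leaves the routing untouched and scores exactly 0.
    ``rng`` overrides the default per-covariate streams (see module
    docstring); passing it trades reproducibility-by-contract for caller
    control.
    """
    base_error = oob_error_rate(forest, data)
    n, k = forest.n_records, forest.event_time_grid.size
    vimp: dict[str, float] = {}
    for v, name in enumerate(forest.features.covariate_names):
        used = any(
            _tree_uses_covariate(tree.root, v) for tree in forest.trees
        )
        if not used:
            vimp[name] = 0.0
            continue
        stream = (
            rng
            if rng is not None
            else np.random.default_rng([forest.config.seed, _VIMP_STREAM_OFFSET + v])
        )
        acc = np.zeros((n, k))
        count = np.zeros(n)
        for b in range(forest.n_trees):
            tree = forest.trees[b]
            oob = tree.oob_indices
            if oob.size == 0:
                continue
            out = np.empty(oob.size, dtype=np.int64)
            _noised_route(
                tree.root,
                np.arange(oob.size),
                forest.features.matrix[oob],
                out,
                v,
                stream,
            )
            acc[oob] += forest.terminal_grid_values(b)[out]
            count[oob] += 1
        scores = np.sum(acc / count[:, None], axis=1)
        noised_error = 1.0 - concordance_index(scores, data)
        vimp[name] = noised_error - base_error
    return vimp


def _tree_uses_covariate(node: TreeNode, covariate: int) -> bool:
    if node.is_terminal:
        return False
    if node.covariate == covariate:
        return True
    return _tree_uses_covariate(node.left, covariate) or _tree_uses_covariate(node.right, covariate)  # type: ignore[arg-type]
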