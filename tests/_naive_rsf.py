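"""Naive reference random survival forest for small-instance cross-checks.

Direct, loop-based evaluation of every formula (per-death-time log-rank
terms, per-threshold split scans, per-record routing, sequential ensemble
accumulation, pair-by-pair concordance) sharing the package's randomness
contract: tree b draws from ``default_rng([seed, b])`` (bootstrap first,
then depth-first mtry draws), VIMP for covariate index v draws from
``default_rng([seed, 2**20 + v])`` with one uniform per record at each
node splitting on v, visited depth-first with trees in index order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class NaiveNode:
    feature: int = -1
    covariate: int = -1
    threshold: float = np.nan
    left: "NaiveNode | None" = None
    right: "NaiveNode | None" = None
    step_times: np.ndarray | None = None
    step_values: np.ndarray | None = None


def naive_nelson_aalen(times, events):
    death_times = sorted(set(t for t, e in zip(times, events) if e == 1))
    values = []
    acc = 0.0
    for dt in death_times:
        n_j = sum(1 for t in times if t >= dt)
        d_j = sum(1 for t, e in zip(times, events) if t == dt and e == 1)
        acc = acc + d_j / n_j
        values.append(acc)
    return np.array(death_times, dtype=float), np.array(values, dtype=float)


def naive_step_eval(step_times, step_values, t):
    value = 0.0
    for st, sv in zip(step_times, step_values):
        if st <= t:
            value = sv
        else:
            break
    return value


def naive_lr(times, events, x, threshold):
    """Standardized log-rank statistic for the split x <= threshold."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events)
    x = np.asarray(x, dtype=float)
    death_times = np.unique(times[events == 1])
    k = death_times.size
    n_left = np.zeros(k)
    d_left = np.zeros(k)
    n_tot = np.zeros(k)
    d_tot = np.zeros(k)
    for j, dt in enumerate(death_times):
        for t, e, xv in zip(times, events, x):
            if t >= dt:
                n_tot[j] += 1.0
                if xv <= threshold:
                    n_left[j] += 1.0
            if t == dt and e == 1:
                d_tot[j] += 1.0
                if xv <= threshold:
                    d_left[j] += 1.0
    usable = n_tot > 1
    ratio = np.where(usable, d_tot / np.maximum(n_tot, 1.0), 0.0)
    p_left = np.where(usable, n_left / np.maximum(n_tot, 1.0), 0.0)
    numerator = np.sum(np.where(usable, d_left - n_left * ratio, 0.0))
    variance = np.sum(
        np.where(
            usable,
            p_left * (1.0 - p_left) * ((n_tot - d_tot) / np.maximum(n_tot - 1.0, 1.0)) * d_tot,
            0.0,
        )
    )
    if variance <= 0.0:
        return 0.0
    return numerator / np.sqrt(variance)


def naive_best_split(times, events, features, column_covariate, candidates):
    if np.asarray(events).sum() == 0:
        return None
    best = None
    for cov in sorted(candidates):
        for col in [c for c, cc in enumerate(column_covariate) if cc == cov]:
            xs = np.sort(np.asarray(features[:, col], dtype=float), kind="stable")
            distinct = []
            for i in range(len(xs) - 1):
                if xs[i] < xs[i + 1]:
                    distinct.append((xs[i] + xs[i + 1]) / 2.0)
            for thr in distinct:
                score = abs(naive_lr(times, events, features[:, col], thr))
                if best is None or score > best[2]:
                    best = (col, thr, score)
    return best


def naive_grow_tree(times, events, features, column_covariate, n_cov, config, b):
    rng = np.random.default_rng([config.seed, b])
    n = len(times)
    in_bag = rng.integers(0, n, size=n)
    mtry = config.resolved_mtry(n_cov)
    bt, be, bF = times[in_bag], events[in_bag], features[in_bag]

    def grow(pos):
        node = NaiveNode()
        if len(pos) < 2 * config.min_terminal_size or be[pos].sum() == 0:
            node.step_times, node.step_values = naive_nelson_aalen(bt[pos], be[pos])
            return node
        candidates = rng.choice(n_cov, size=mtry, replace=False)
        split = naive_best_split(bt[pos], be[pos], bF[pos], column_covariate, candidates)
        if split is None:
            node.step_times, node.step_values = naive_nelson_aalen(bt[pos], be[pos])
            return node
        node.feature, node.threshold, _ = split
        node.covariate = int(column_covariate[node.feature])
        go_left = bF[pos, node.feature] <= node.threshold
        node.left = grow(pos[go_left])
        node.right = grow(pos[~go_left])
        return node

    root = grow(np.arange(n))
    oob = np.array(sorted(set(range(n)) - set(in_bag.tolist())), dtype=int)
    return root, in_bag, oob


def naive_route(node, row):
    while node.feature >= 0:
        node = node.left if row[node.feature] <= node.threshold else node.right
    return node


def naive_chf_on_grid(node, grid):
    return np.array([naive_step_eval(node.step_times, node.step_values, t) for t in grid])


def naive_concordance(scores, times, events):
    n = len(times)
    permissible = 0
    credit = 0.0
    for i in range(n):
        for j in range(i + 1, n):
            ti, tj, di, dj = times[i], times[j], events[i], events[j]
            si, sj = scores[i], scores[j]
            if ti != tj:
                short, long_, d_short = (i, j, di) if ti < tj else (j, i, dj)
                if not d_short:
                    continue
                permissible += 1
                s_short, s_long = scores[short], scores[long_]
                if s_short > s_long:
                    credit += 1.0
                elif s_short == s_long:
                    credit += 0.5
            else:
                if di and dj:
                    permissible += 1
                    credit += 1.0 if si == sj else 0.5
                elif di or dj:
                    permissible += 1
                    s_death, s_other = (si, sj) if di else (sj, si)
                    credit += 1.0 if s_death > s_other else 0.5
    return credit / permissible


@dataclass
class NaiveForest:
    roots: list = field(default_factory=list)
    oob_lists: list = field(default_factory=list)
    grid: np.ndarray | None = None
    column_covariate: np.ndarray | None = None
    features: np.ndarray | None = None
    config: object = None
    n_cov: int = 0


def naive_fit_forest(times, events, features, column_covariate, n_cov, config):
    forest = NaiveForest(
        grid=np.unique(np.asarray(times)[np.asarray(events) == 1]),
        column_covariate=column_covariate,
        features=features,
        config=config,
        n_cov=n_cov,
    )
    for b in range(config.n_trees):
        root, _, oob = naive_grow_tree(times, events, features, column_covariate, n_cov, config, b)
        forest.roots.append(root)
        forest.oob_lists.append(oob)
    return forest


def naive_oob_scores(forest, n):
    k = forest.grid.size
    acc = np.zeros((n, k))
    count = np.zeros(n)
    for root, oob in zip(forest.roots, forest.oob_lists):
        for i in oob:
            terminal = naive_route(root, forest.features[i])
            acc[i] += naive_chf_on_grid(terminal, forest.grid)
            count[i] += 1
    scores = np.empty(n)
    for i in range(n):
        scores[i] = np.sum(acc[i] / count[i])
    return scores


def _uses(node, v):
    if node.feature < 0:
        return False
    return node.covariate == v or _uses(node.left, v) or _uses(node.right, v)


def naive_vimp(forest, times, events, n):
    base = 1.0 - naive_concordance(naive_oob_scores(forest, n), times, events)
    k = forest.grid.size
    out = {}
    for v in range(forest.n_cov):
        if not any(_uses(root, v) for root in forest.roots):
            out[v] = 0.0
            continue
        rng = np.random.default_rng([forest.config.seed, 2**20 + v])
        acc = np.zeros((n, k))
        count = np.zeros(n)
        for root, oob in zip(forest.roots, forest.oob_lists):
            if len(oob) == 0:
                continue
            assignment = {}

            def walk(node, group):
                if node.feature < 0:
                    for i in group:
                        assignment[i] = node
                    return
                if node.covariate == v:
                    u = rng.random(len(group))
                    left = [i for i, ui in zip(group, u) if ui < 0.5]
                    right = [i for i, ui in zip(group, u) if ui >= 0.5]
                else:
                    left = [i for i in group if forest.features[i][node.feature] <= node.threshold]
                    right = [i for i in group if forest.features[i][node.feature] > node.threshold]
                walk(node.left, left)
                walk(node.right, right)

            walk(root, list(oob))
            for i in oob:
                acc[i] += naive_chf_on_grid(assignment[i], forest.grid)
                count[i] += 1
        scores = np.empty(n)
        for i in range(n):
            scores[i] = np.sum(acc[i] / count[i])
        out[v] = (1.0 - naive_concordance(scores, times, events)) - base
    return out
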