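"""Feature optimization: correlation pruning, outlier removal, RF ranking.

The pipeline order is: Pearson redundancy pruning of the feature set, then
a per-feature 3-sigma outlier filter on the rows, then a random-forest
regression of the strength target whose impurity importances rank the
retained features; the top-k become the model inputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor
from sklearn.model_selection import train_test_split

from tracheidnet.grading import classify_grade

#: Canonical column order used for deterministic tie-breaking.
CANONICAL_COLUMNS: tuple[str, ...] = (
    "ASM", "CON", "CORR", "ENT", "VAR", "SA", "SV", "IDM", "SE",
    "AREA", "PERIMETER",
)

#: The feature set the headline model consumes.
SELECTED_FEATURES: tuple[str, ...] = ("CON", "CORR", "AREA", "PERIMETER", "ASM")


@dataclass
class SelectionReport:
    """Everything the optimization decided, for audit."""

    correlation_matrix: pd.DataFrame
    dropped_redundant: list[str]
    outlier_rows: np.ndarray
    importances: pd.Series
    selected: list[str]
    grade_accuracy: float | None = None
    mae: float | None = None
    extras: dict = field(default_factory=dict)


def _canonical_sort(names: list[str]) -> list[str]:
    order = {c: i for i, c in enumerate(CANONICAL_COLUMNS)}
    return sorted(names, key=lambda n: (order.get(n, len(order)), n))


def pearson_matrix(table: pd.DataFrame) -> pd.DataFrame:
    """Pearson correlation matrix of the feature columns.

    Raises on zero-variance columns (their correlation is undefined).
    """
    if len(table) < 3:
        raise ValueError("need at least 3 rows for a correlation matrix")
    sds = table.std(ddof=1)
    dead = sds[sds == 0].index.tolist()
    if dead:
        raise ValueError(f"zero-variance column(s): {dead}; correlation undefined")
    return table.corr(method="pearson")


def prune_redundant(matrix: pd.DataFrame, threshold: float = 0.9) -> list[str]:
    """Drop redundant features until no |r| above ``threshold`` remains.

    At each step the highest off-diagonal |r| pair is examined and the
    member judged less independent is dropped.  Independence is measured
    against the retained features that are *not* themselves entangled in
    any above-threshold pair: within a redundant group this baseline
    identifies which member carries the most unique signal.  Ties fall to
    the later name in canonical column order.  Returns the retained names
    in canonical order.
    """
    names = list(matrix.columns)
    retained = list(names)
    m = matrix.abs()

    def mean_r_to(feature: str, others: list[str]) -> float:
        others = [o for o in others if o != feature]
        if not others:
            return 0.0
        return float(m.loc[feature, others].mean())

    while True:
        sub = m.loc[retained, retained].to_numpy(copy=True)
        np.fill_diagonal(sub, 0.0)
        if sub.max() <= threshold:
            break
        i, j = np.unravel_index(np.argmax(sub), sub.shape)
        a, b = retained[i], retained[j]
        # features free of any above-threshold entanglement
        offender_idx = np.nonzero((sub > threshold).any(axis=1))[0]
        offenders = {retained[r] for r in offender_idx}
        clean = [f for f in retained if f not in offenders]
        baseline = clean if clean else retained
        ra, rb = mean_r_to(a, baseline), mean_r_to(b, baseline)
        if ra > rb:
            drop = a
        elif rb > ra:
            drop = b
        else:
            drop = _canonical_sort([a, b])[-1]
        retained.remove(drop)
    return _canonical_sort(retained)


def outlier_filter(
    table: pd.DataFrame,
    n_sigma: float = 3.0,
    columns: list[str] | None = None,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Remove rows deviating more than ``n_sigma`` SDs on any feature.

    Column means and sample SDs are computed once on the full table, not
    iteratively; zero-variance columns flag nothing.  Returns the filtered
    table and the removed row positions.
    """
    if len(table) < 2:
        raise ValueError("need at least 2 rows")
    cols = columns if columns is not None else [
        c for c in table.columns if pd.api.types.is_numeric_dtype(table[c])
        and c not in ("specimen_id", "sigma_w_MPa")
    ]
    x = table[cols].to_numpy(dtype=float)
    mu = x.mean(axis=0)
    sd = x.std(axis=0, ddof=1)
    safe = np.where(sd > 0, sd, np.inf)      # sigma = 0 flags nothing
    bad = (np.abs(x - mu) > n_sigma * safe).any(axis=1)
    removed = np.nonzero(bad)[0]
    return table.iloc[~bad].reset_index(drop=True), removed


def rf_rank(
    table: pd.DataFrame,
    target: str = "sigma_w_MPa",
    n_trees: int = 900,
    max_depth: int = 35,
    seed: int = 0,
    split: float = 0.8,
    columns: list[str] | None = None,
) -> SelectionReport:
    """Random-forest importance ranking of the features against strength.

    Fits a forest regressor of the strength target on the feature columns,
    reports impurity importances normalized to sum 1, plus the held-out
    mean absolute error and the grade accuracy obtained by thresholding
    the predicted strengths.
    """
    if len(table) < 10:
        raise ValueError("need at least 10 rows to fit a forest")
    if target not in table.columns:
        raise ValueError(f"target column {target!r} missing")
    cols = columns if columns is not None else [
        c for c in CANONICAL_COLUMNS if c in table.columns
    ]
    # canonical row order before fitting keeps importances permutation-stable
    work = table.sort_values(cols + [target], kind="mergesort").reset_index(drop=True)
    x = work[cols].to_numpy(dtype=float)
    y = work[target].to_numpy(dtype=float)
    x_tr, x_te, y_tr, y_te = train_test_split(
        x, y, test_size=1.0 - split, random_state=seed
    )
    forest = RandomForestRegressor(
        n_estimators=n_trees, max_depth=max_depth, random_state=seed, n_jobs=1
    )
    forest.fit(x_tr, y_tr)
    imp = forest.feature_importances_
    imp = imp / imp.sum()
    pred = forest.predict(x_te)
    mae = float(np.mean(np.abs(pred - y_te)))
    acc = float(np.mean(
        [classify_grade(max(0.0, p)) == classify_grade(t) for p, t in zip(pred, y_te)]
    ))
    return SelectionReport(
        correlation_matrix=pd.DataFrame(),
        dropped_redundant=[],
        outlier_rows=np.array([], dtype=int),
        importances=pd.Series(imp, index=cols),
        selected=[],
        grade_accuracy=acc,
        mae=mae,
    )


def select_top(importances: pd.Series, k: int = 5) -> list[str]:
    """The ``k`` highest-importance feature names, descending.

    Ties fall to canonical column order.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    if k > len(importances):
        raise ValueError("k exceeds the number of features")
    order = {c: i for i, c in enumerate(CANONICAL_COLUMNS)}
    ranked = sorted(
        importances.items(),
        key=lambda kv: (-kv[1], order.get(kv[0], len(order)), kv[0]),
    )
    return [name for name, _ in ranked[:k]]


def run_selection(
    table: pd.DataFrame,
    threshold: float = 0.9,
    n_sigma: float = 3.0,
    n_trees: int = 900,
    max_depth: int = 35,
    top_k: int = 5,
    seed: int = 0,
    split: float = 0.8,
) -> tuple[pd.DataFrame, SelectionReport]:
    """Full optimization: prune -> outlier filter -> RF rank -> top-k.

    ``table`` must contain feature columns plus ``sigma_w_MPa`` (and may
    carry ``grade``/id columns, which pass through untouched).  Returns
    the filtered table restricted to the selected features and the report.
    """
    feat_cols = [c for c in CANONICAL_COLUMNS if c in table.columns]
    corr = pearson_matrix(table[feat_cols])
    retained = prune_redundant(corr, threshold)
    dropped = [c for c in feat_cols if c not in retained]
    filtered, removed = outlier_filter(table, n_sigma=n_sigma, columns=retained)
    report = rf_rank(
        filtered, n_trees=n_trees, max_depth=max_depth, seed=seed,
        split=split, columns=retained,
    )
    report.correlation_matrix = corr
    report.dropped_redundant = dropped
    report.outlier_rows = removed
    report.selected = select_top(report.importances, k=top_k)
    keep_cols = [c for c in table.columns if c not in feat_cols or c in report.selected]
    return filtered[keep_cols], report
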