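"""Prediction of spot-level electrophysiological features from gene-family
expression with gradient-boosted tree ensembles.

For each (gene family, feature) pair the spots are repeatedly split 70/30
into train/test sets, a gradient-boosted regressor is fitted per split,
and the Pearson correlation plus explained-variance score between
predictions and held-out truth are averaged over iterations.  Chance level
is estimated by refitting on permuted targets; real accuracies are flagged
against a ``null mean + 3 SD`` threshold.  Condition contrasts (e.g.
enriched vs standard housing) compare per-iteration scores with two-sample
t tests, BH-adjusted across families.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import explained_variance_score
from statsmodels.stats.multitest import multipletests
from xgboost import XGBRegressor

DEFAULT_XGB_PARAMS = dict(
    n_estimators=300,
    learning_rate=0.05,
    max_depth=3,
    subsample=1.0,
    n_jobs=1,
    tree_method="hist",
    verbosity=0,
)


def balance_datasets(
    dataset_a: pd.DataFrame | np.ndarray,
    dataset_b: pd.DataFrame | np.ndarray,
    seed: int = 0,
    fraction: float = 0.5,
) -> tuple[object, object, dict]:
    """Subsample the larger of two datasets to ``fraction`` of its size.

    Mirrors balancing a condition with inherently more spots before
    comparing prediction performance.  Returns the (possibly) reduced
    datasets and a report of sizes before/after.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must lie in (0, 1]")
    n_a, n_b = len(dataset_a), len(dataset_b)
    if n_a == 0 or n_b == 0:
        raise ValueError("both datasets must be nonempty")
    rng = np.random.default_rng(seed)

    def _subsample(data, n_keep):
        idx = np.sort(rng.choice(len(data), size=n_keep, replace=False))
        if isinstance(data, pd.DataFrame):
            return data.iloc[idx]
        return np.asarray(data)[idx]

    out_a, out_b = dataset_a, dataset_b
    if fraction < 1:
        if n_a > n_b:
            out_a = _subsample(dataset_a, int(round(fraction * n_a)))
        elif n_b > n_a:
            out_b = _subsample(dataset_b, int(round(fraction * n_b)))
    report = {
        "before": (n_a, n_b),
        "after": (len(out_a), len(out_b)),
        "fraction": fraction,
    }
    return out_a, out_b, report


@dataclass
class PredictionEntry:
    """Repeated-split performance for one (family, feature) pair."""

    family: str
    feature: str
    r_values: np.ndarray
    accuracy_values: np.ndarray
    n_iterations: int
    seed: int

    @property
    def mean_r(self) -> float:
        return float(np.mean(self.r_values))

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean(self.accuracy_values))

    @property
    def sd_accuracy(self) -> float:
        return float(np.std(self.accuracy_values))


def train_predict(
    x: np.ndarray | pd.DataFrame,
    y: np.ndarray | pd.Series,
    n_iterations: int = 100,
    split_fraction: float = 0.7,
    seed: int = 0,
    family: str = "family",
    feature: str = "feature",
    xgb_params: dict | None = None,
) -> PredictionEntry:
    """Repeated random-split gradient-boosted regression.

    Each iteration draws a fresh ``split_fraction`` train split, fits the
    regressor, and records the Pearson r and explained-variance score on
    the held-out spots.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape[0] != y.size:
        raise ValueError("x and y disagree on sample count")
    if x.shape[0] < 50:
        raise ValueError("need >= 50 spots for repeated splitting")
    if np.std(y) == 0:
        raise ValueError("constant target cannot be predicted")
    params = dict(DEFAULT_XGB_PARAMS, **(xgb_params or {}))
    rng = np.random.default_rng(seed)
    n = x.shape[0]
    n_train = int(round(split_fraction * n))
    r_vals, acc_vals = [], []
    for it in range(n_iterations):
        perm = rng.permutation(n)
        train, test = perm[:n_train], perm[n_train:]
        model = XGBRegressor(random_state=int(rng.integers(2**31 - 1)), **params)
        model.fit(x[train], y[train])
        pred = model.predict(x[test])
        if np.std(pred) == 0 or np.std(y[test]) == 0:
            r_vals.append(0.0)
        else:
            r_vals.append(float(stats.pearsonr(y[test], pred)[0]))
        acc_vals.append(float(explained_variance_score(y[test], pred)))
    return PredictionEntry(
        family=family,
        feature=feature,
        r_values=np.asarray(r_vals),
        accuracy_values=np.asarray(acc_vals),
        n_iterations=n_iterations,
        seed=seed,
    )


@dataclass
class ChanceReport:
    threshold: float
    null_mean: float
    null_sd: float
    null_accuracies: np.ndarray
    above_chance: bool


def chance_threshold(
    x: np.ndarray | pd.DataFrame,
    y: np.ndarray | pd.Series,
    real_mean_accuracy: float,
    n_permutations: int = 100,
    split_fraction: float = 0.7,
    seed: int = 0,
    xgb_params: dict | None = None,
) -> ChanceReport:
    """Permutation null for the prediction accuracy.

    Each permutation shuffles the target, refits on a fresh split and
    scores the held-out spots; the chance threshold is
    ``null mean + 3 * null SD`` and the real mean accuracy is flagged
    against it.
    """
    if n_permutations < 20:
        raise ValueError("need >= 20 permutations")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    params = dict(DEFAULT_XGB_PARAMS, **(xgb_params or {}))
    rng = np.random.default_rng(seed)
    n = x.shape[0]
    n_train = int(round(split_fraction * n))
    null_acc = []
    for _ in range(n_permutations):
        y_perm = rng.permutation(y)
        perm = rng.permutation(n)
        train, test = perm[:n_train], perm[n_train:]
        model = XGBRegressor(random_state=int(rng.integers(2**31 - 1)), **params)
        model.fit(x[train], y_perm[train])
        pred = model.predict(x[test])
        null_acc.append(float(explained_variance_score(y_perm[test], pred)))
    null_acc = np.asarray(null_acc)
    thr = float(null_acc.mean() + 3.0 * null_acc.std())
    return ChanceReport(
        threshold=thr,
        null_mean=float(null_acc.mean()),
        null_sd=float(null_acc.std()),
        null_accuracies=null_acc,
        above_chance=bool(real_mean_accuracy > thr),
    )


def compare_conditions(
    report_a: list[PredictionEntry],
    report_b: list[PredictionEntry],
) -> pd.DataFrame:
    """Per-family contrast of prediction performance between conditions.

    Matches entries by (family, feature), takes the difference of mean r,
    a two-sample t statistic over the per-iteration r values, and
    BH-adjusts the p-values across families.
    """
    key_a = {(e.family, e.feature): e for e in report_a}
    key_b = {(e.family, e.feature): e for e in report_b}
    if set(key_a) != set(key_b):
        raise ValueError("reports cover different (family, feature) designs")
    rows = []
    for key in sorted(key_a):
        ea, eb = key_a[key], key_b[key]
        if ea.n_iterations != eb.n_iterations:
            raise ValueError(f"iteration counts differ for {key}")
        t, p = stats.ttest_ind(ea.r_values, eb.r_values)
        rows.append(
            {
                "family": key[0],
                "feature": key[1],
                "mean_r_a": ea.mean_r,
                "mean_r_b": eb.mean_r,
                "diff_mean_r": ea.mean_r - eb.mean_r,
                "t_stat": float(t),
                "p_value": float(p),
            }
        )
    out = pd.DataFrame(rows)
    out["p_adj"] = multipletests(out["p_value"], method="fdr_bh")[1]
    return out
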