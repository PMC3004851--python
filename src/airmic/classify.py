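"""Bootstrap random-forest classification harness.

Protocol: for each of ``rf_n_iterations`` iterations, draw a training
set of the original sample size with replacement; samples never drawn
form the validation set.  A random forest (``rf_n_trees`` trees,
``rf_features_per_node`` candidate features per split, trees grown to
purity) is fitted on the training set and its misclassification
fraction on the validation set recorded, alongside a guessing baseline
that predicts the training set's majority class for every validation
sample.  Median accuracy is 1 − median misclassification over
iterations; Gini (mean-decrease-in-impurity) importances are averaged
over iterations to rank taxa.  A whole-data forest's out-of-bag score
is also reported.  The model-vs-guess error distributions are compared
with a Friedman rank-sum test (blocks = iterations) plus a percentile
bootstrap confidence interval for the paired error difference.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier

from .config import PipelineConfig
from .io import CountTable

logger = logging.getLogger(__name__)

__all__ = ["RFEvaluation", "evaluate_classifier", "friedman_compare"]


@dataclass
class RFEvaluation:
    model_errors: np.ndarray  # misclassification fraction per iteration
    guess_errors: np.ndarray
    median_accuracy: float
    oob_accuracy: float
    friedman_statistic: float
    friedman_p: float
    error_difference_ci: tuple[float, float]  # 95% CI of mean(model − guess)
    importances: pd.DataFrame  # index taxon, columns mean_gini, rank
    n_iterations: int
    seed: int | None


def friedman_compare(
    model_errors,
    guess_errors,
    ci_level: float = 0.95,
    n_boot_ci: int = 2_000,
    seed: int | np.random.SeedSequence = 0,
) -> tuple[float, float, tuple[float, float]]:
    """Friedman rank-sum test for two paired treatments across blocks.

    Midranks handle ties; the chi-square statistic uses the standard
    tie correction.  All-tied input gives (0, 1).  Also returns a
    percentile bootstrap CI for the mean paired difference
    model − guess (negative = model better).
    """
    x = np.asarray(model_errors, dtype=float)
    y = np.asarray(guess_errors, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("need equal-length 1-D paired vectors")
    n = x.size
    if n < 10:
        raise ValueError("need at least 10 paired blocks")
    k = 2
    both = np.stack([x, y], axis=1)
    ranks = stats.rankdata(both, axis=1)  # midranks within block
    rank_sums = ranks.sum(axis=0)
    chi2 = (12.0 / (n * k * (k + 1))) * np.sum(rank_sums**2) - 3.0 * n * (k + 1)
    # tie correction: blocks with equal values contribute t^3 - t
    tie_term = float(np.sum(np.where(x == y, k**3 - k, 0.0)))
    denom = 1.0 - tie_term / (n * k * (k * k - 1))
    if denom <= 0:  # every pair tied
        statistic, p = 0.0, 1.0
    else:
        statistic = chi2 / denom
        p = float(stats.chi2.sf(statistic, df=k - 1))
    rng = np.random.default_rng(seed)
    diffs = x - y
    boot_means = np.array(
        [diffs[rng.integers(0, n, n)].mean() for _ in range(n_boot_ci)]
    )
    lo_q = (1.0 - ci_level) / 2.0
    ci = (
        float(np.quantile(boot_means, lo_q)),
        float(np.quantile(boot_means, 1.0 - lo_q)),
    )
    return float(statistic), p, ci


def _filter_features(
    table: CountTable, sample_ids, filter_fraction: float | None
) -> pd.DataFrame:
    rel = table.relative_abundance().loc[list(sample_ids)]
    if filter_fraction is None:
        return rel
    keep = rel.mean(axis=0) > filter_fraction
    kept = rel.loc[:, keep]
    if kept.shape[1] == 0:
        logger.warning("abundance filter removed every feature; keeping all")
        return rel
    return kept


def evaluate_classifier(
    genus_table: CountTable,
    metadata: pd.DataFrame,
    site: str,
    side: str,
    config: PipelineConfig | None = None,
    seed: int | np.random.SeedSequence | None = None,
    filter_fraction: float | None = None,
    time_index: int | None = 0,
    max_redraws: int = 100,
) -> RFEvaluation:
    """Run the bootstrap RF protocol on one (site, side) stratum,
    predicting smoking status from genus relative abundances."""
    config = config or PipelineConfig()
    if seed is None:
        seed = config.rng_seed
    if filter_fraction is None:
        filter_fraction = config.genus_filter_fraction
    md = metadata.loc[genus_table.sample_ids]
    mask = (md["site"] == site) & (md["side"] == side)
    if time_index is not None:
        mask &= md["time"] == time_index
    md = md[mask]
    classes, y = np.unique(md["group"].to_numpy(), return_inverse=True)
    if len(classes) < 2:
        raise ValueError(f"stratum ({site}, {side}) has a single class")
    if min(np.bincount(y)) < 5:
        raise ValueError("need at least 5 samples per class in the stratum")
    features = _filter_features(genus_table, md.index, filter_fraction)
    x = features.to_numpy(dtype=float)
    n, n_feat = x.shape
    mtry = min(config.rf_features_per_node, n_feat)

    ss = (
        seed
        if isinstance(seed, np.random.SeedSequence)
        else np.random.SeedSequence(seed)
    )
    rng = np.random.default_rng(ss.spawn(1)[0])
    model_errors = np.empty(config.rf_n_iterations)
    guess_errors = np.empty(config.rf_n_iterations)
    importance_sum = np.zeros(n_feat)
    for it in range(config.rf_n_iterations):
        for attempt in range(max_redraws):
            train_idx = rng.integers(0, n, size=n)
            val_mask = np.ones(n, dtype=bool)
            val_mask[train_idx] = False
            if not val_mask.any():
                logger.info("iteration %d: empty validation set, redrawn", it)
                continue
            if len(np.unique(y[train_idx])) < 2:
                logger.info("iteration %d: single-class training set, redrawn", it)
                continue
            break
        else:
            raise RuntimeError("could not draw a usable bootstrap split")
        forest = RandomForestClassifier(
            n_estimators=config.rf_n_trees,
            max_features=mtry,
            bootstrap=True,
            random_state=int(rng.integers(2**31 - 1)),
            n_jobs=1,
        )
        forest.fit(x[train_idx], y[train_idx])
        pred = forest.predict(x[val_mask])
        model_errors[it] = float(np.mean(pred != y[val_mask]))
        majority = np.bincount(y[train_idx]).argmax()
        guess_errors[it] = float(np.mean(y[val_mask] != majority))
        importance_sum += forest.feature_importances_

    median_accuracy = 1.0 - float(np.median(model_errors))
    oob_forest = RandomForestClassifier(
        n_estimators=config.rf_n_trees,
        max_features=mtry,
        bootstrap=True,
        oob_score=True,
        random_state=int(rng.integers(2**31 - 1)),
        n_jobs=1,
    )
    oob_forest.fit(x, y)
    statistic, p, ci = friedman_compare(
        model_errors, guess_errors, seed=ss.spawn(1)[0]
    )
    mean_gini = importance_sum / config.rf_n_iterations
    importances = pd.DataFrame(
        {"mean_gini": mean_gini}, index=features.columns
    ).sort_values("mean_gini", ascending=False, kind="stable")
    importances["rank"] = np.arange(1, n_feat + 1)
    return RFEvaluation(
        model_errors=model_errors,
        guess_errors=guess_errors,
        median_accuracy=median_accuracy,
        oob_accuracy=float(oob_forest.oob_score_),
        friedman_statistic=statistic,
        friedman_p=p,
        error_difference_ci=ci,
        importances=importances,
        n_iterations=config.rf_n_iterations,
        seed=seed if isinstance(seed, int) else None,
    )
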