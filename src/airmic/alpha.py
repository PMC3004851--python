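"""Alpha diversity: rarefaction, Chao1 richness, Shannon diversity.

All samples are rarefied (subsampled without replacement) to one common
depth before estimation, removing sequencing-effort bias; samples below
the target depth are flagged and excluded from comparisons.  Estimates
are averaged over several independent rarefaction draws to reduce
subsampling variance.

Chao1 uses the classic estimator ``S_obs + F1^2 / (2 F2)`` (F1 =
singletons, F2 = doubletons), falling back to the bias-corrected form
``S_obs + F1 (F1 - 1) / (2 (F2 + 1))`` when F2 = 0.  Shannon is the
entropy ``H = -sum p_i log p_i`` of the relative abundances, natural
log by default.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .io import SIDES, SITES, CountTable

logger = logging.getLogger(__name__)

__all__ = ["rarefy", "chao1", "shannon", "alpha_diversity", "compare_alpha"]


def rarefy(
    counts,
    depth: int,
    n_draws: int = 1,
    seed: int | np.random.SeedSequence | np.random.Generator = 0,
) -> np.ndarray:
    """Subsample one sample's count vector to ``depth`` reads without
    replacement, ``n_draws`` times.  Returns an array (n_draws, n_taxa);
    each row sums to ``depth`` exactly."""
    counts = np.asarray(counts, dtype=np.int64)
    if depth < 1:
        raise ValueError(f"depth must be >= 1, got {depth}")
    total = int(counts.sum())
    if total < depth:
        raise ValueError(f"sample total {total} is below rarefaction depth {depth}")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    if total == depth:
        return np.tile(counts, (n_draws, 1))
    out = np.empty((n_draws, counts.size), dtype=np.int64)
    for d in range(n_draws):
        out[d] = rng.multivariate_hypergeometric(counts, depth)
    return out


def chao1(counts) -> float:
    """Chao1 richness estimate of one (rarefied) count vector."""
    counts = np.asarray(counts)
    if counts.size == 0:
        raise ValueError("empty count vector")
    s_obs = int((counts > 0).sum())
    f1 = int((counts == 1).sum())
    f2 = int((counts == 2).sum())
    if f1 == 0:
        return float(s_obs)
    if f2 > 0:
        return s_obs + f1 * f1 / (2.0 * f2)
    return s_obs + f1 * (f1 - 1) / 2.0


def shannon(counts, base: float | None = None) -> float:
    """Shannon entropy of the relative abundances; natural log unless a
    ``base`` is given."""
    counts = np.asarray(counts, dtype=float)
    total = counts.sum()
    if total <= 0:
        raise ValueError("count vector has no reads")
    p = counts[counts > 0] / total
    h = float(-(p * np.log(p)).sum())
    if base is not None:
        h /= np.log(base)
    return h


def alpha_diversity(
    table: CountTable,
    depth: int = 800,
    n_draws: int = 10,
    seed: int | np.random.SeedSequence = 0,
    log_base: float | None = None,
) -> pd.DataFrame:
    """Per-sample Chao1 and Shannon at a common rarefaction depth.

    Returns a DataFrame indexed by sample with columns ``chao1``,
    ``shannon``, ``depth``, ``n_draws``, ``excluded``.  Estimates are
    means over ``n_draws`` independent rarefactions; samples shallower
    than ``depth`` get NaN estimates and ``excluded=True``.
    """
    rng = np.random.default_rng(seed)
    rows = {}
    n_excluded = 0
    for sample_id, counts in table.counts.iterrows():
        vec = counts.to_numpy()
        if vec.sum() < depth:
            rows[sample_id] = (np.nan, np.nan, depth, n_draws, True)
            n_excluded += 1
            continue
        draws = rarefy(vec, depth, n_draws=n_draws, seed=rng)
        rows[sample_id] = (
            float(np.mean([chao1(d) for d in draws])),
            float(np.mean([shannon(d, base=log_base) for d in draws])),
            depth,
            n_draws,
            False,
        )
    if n_excluded:
        logger.warning(
            "%d sample(s) below rarefaction depth %d excluded from alpha diversity",
            n_excluded,
            depth,
        )
    return pd.DataFrame.from_dict(
        rows,
        orient="index",
        columns=["chao1", "shannon", "depth", "n_draws", "excluded"],
    )


def compare_alpha(
    alpha_df: pd.DataFrame,
    metadata: pd.DataFrame,
    contrast: str = "site",
    metrics: tuple[str, ...] = ("chao1", "shannon"),
    paired: bool | None = None,
    time_index: int | None = 0,
) -> pd.DataFrame:
    """Compare alpha diversity between the two levels of a contrast.

    ``contrast="site"`` compares nasopharynx vs oropharynx within each
    body side (paired within subject by default, Wilcoxon signed-rank);
    ``contrast="group"`` compares smokers vs nonsmokers within each
    (site, side) stratum (unpaired, two-sided Wilcoxon rank-sum).
    Strata with fewer than two usable values per level are skipped with
    a warning.  Restricted to one ``time_index`` (default 0) to avoid
    pseudo-replication from repeat sampling; pass ``None`` to use all.
    """
    if contrast not in {"site", "group"}:
        raise ValueError(f"contrast must be 'site' or 'group', got {contrast!r}")
    md = metadata.loc[alpha_df.index[~alpha_df["excluded"].astype(bool)]]
    if time_index is not None:
        md = md[md["time"] == time_index]
    if paired is None:
        paired = contrast == "site"
    results = []
    if contrast == "site":
        strata = [("side", side) for side in SIDES]
        level_col, levels = "site", SITES
    else:
        strata = [("stratum", (site, side)) for site in SITES for side in SIDES]
        level_col, levels = "group", ("nonsmoker", "smoker")
    for metric in metrics:
        values = alpha_df[metric]
        for _, stratum in strata:
            if contrast == "site":
                sub = md[md["side"] == stratum]
                label = f"side={stratum}"
            else:
                site, side = stratum
                sub = md[(md["site"] == site) & (md["side"] == side)]
                label = f"site={site},side={side}"
            a_ids = sub.index[sub[level_col] == levels[0]]
            b_ids = sub.index[sub[level_col] == levels[1]]
            if paired:
                # one sample per subject per level at this time/stratum
                a_by_subj = {sub.at[i, "subject"]: values.at[i] for i in a_ids}
                b_by_subj = {sub.at[i, "subject"]: values.at[i] for i in b_ids}
                shared = sorted(set(a_by_subj) & set(b_by_subj))
                x = np.array([a_by_subj[s] for s in shared])
                y = np.array([b_by_subj[s] for s in shared])
                n_a = n_b = len(shared)
                if len(shared) < 2:
                    logger.warning("stratum %s skipped: <2 paired subjects", label)
                    continue
                diffs = x - y
                if np.all(diffs == 0):
                    stat, p = 0.0, 1.0
                else:
                    stat, p = stats.wilcoxon(x, y, alternative="two-sided")
                test = "signed-rank"
            else:
                x = values.loc[a_ids].to_numpy()
                y = values.loc[b_ids].to_numpy()
                n_a, n_b = len(x), len(y)
                if n_a < 2 or n_b < 2:
                    logger.warning("stratum %s skipped: <2 samples per level", label)
                    continue
                stat, p = stats.mannwhitneyu(x, y, alternative="two-sided")
                test = "rank-sum"
            results.append(
                {
                    "metric": metric,
                    "stratum": label,
                    "level_a": levels[0],
                    "level_b": levels[1],
                    "n_a": n_a,
                    "n_b": n_b,
                    "median_a": float(np.median(x)),
                    "median_b": float(np.median(y)),
                    "test": test,
                    "statistic": float(stat),
                    "p_value": float(p),
                }
            )
    return pd.DataFrame(results)
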