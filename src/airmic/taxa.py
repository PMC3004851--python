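"""Univariate differential-abundance testing with prevalence-aware
test selection, pooled fold differences, and Bonferroni correction.

Test-selection rule: a taxon is compared by an *abundance* test
(two-sided Wilcoxon rank-sum unpaired, signed-rank paired) only when it
is detected (count > 0) in more than half the samples of *every*
comparison level; otherwise a *presence/absence* test is used
(Fisher's exact unpaired, exact McNemar paired).

Fold differences are ratios of pooled relative abundances
(group-summed counts, normalised); with both groups non-zero the ratio
is exact and reciprocal under label swap, and a zero group total is
regularised by a pseudo-abundance ε = half the smallest non-zero pooled
relative abundance in the stratum.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .io import SIDES, SITES, CountTable

__all__ = ["select_test", "test_taxa", "site_contrast", "bonferroni"]

RESULT_COLUMNS = [
    "taxon",
    "test_used",
    "fold_difference",
    "p_value",
    "p_bonferroni",
    "detected_fraction_a",
    "detected_fraction_b",
]


def select_test(detected_fractions, paired: bool) -> str:
    """Pick the test from per-level detection fractions.

    ``detected_fractions`` maps each comparison level (or location) to
    the fraction of its samples in which the taxon was detected.  The
    abundance test requires strictly more than half in every level;
    exactly half falls to the presence/absence branch.
    """
    fractions = list(detected_fractions.values() if isinstance(detected_fractions, dict) else detected_fractions)
    if not fractions:
        raise ValueError("no comparison levels defined")
    common = all(f > 0.5 for f in fractions)
    if paired:
        return "signed-rank" if common else "mcnemar"
    return "rank-sum" if common else "fisher-exact"


def bonferroni(p: float, m: int) -> float:
    return min(1.0, p * m)


def _rank_sum(x: np.ndarray, y: np.ndarray) -> float:
    if np.all(x == x[0]) and np.all(y == y[0]) and x[0] == y[0]:
        return 1.0
    return float(stats.mannwhitneyu(x, y, alternative="two-sided").pvalue)


def _signed_rank(x: np.ndarray, y: np.ndarray) -> float:
    diffs = x - y
    if np.all(diffs == 0):
        return 1.0
    return float(stats.wilcoxon(x, y, alternative="two-sided").pvalue)


def _fisher(det_a: int, n_a: int, det_b: int, n_b: int) -> float:
    table = [[det_a, n_a - det_a], [det_b, n_b - det_b]]
    return float(stats.fisher_exact(table, alternative="two-sided")[1])


def _mcnemar(pres_a: np.ndarray, pres_b: np.ndarray) -> float:
    """Exact McNemar: binomial test on the discordant pairs."""
    b = int((pres_a & ~pres_b).sum())
    c = int((~pres_a & pres_b).sum())
    if b + c == 0:
        return 1.0
    return float(stats.binomtest(b, b + c, 0.5, alternative="two-sided").pvalue)


def _fold_difference(
    pooled_a: np.ndarray, pooled_b: np.ndarray
) -> np.ndarray:
    """Per-taxon ratio of pooled relative abundances a/b with ε
    regularisation only where a group total is zero."""
    rel_a = pooled_a / pooled_a.sum()
    rel_b = pooled_b / pooled_b.sum()
    nonzero = np.concatenate([rel_a[rel_a > 0], rel_b[rel_b > 0]])
    eps = nonzero.min() / 2.0 if nonzero.size else 1.0
    out = np.empty_like(rel_a)
    both = (rel_a > 0) & (rel_b > 0)
    out[both] = rel_a[both] / rel_b[both]
    rest = ~both
    out[rest] = (rel_a[rest] + eps) / (rel_b[rest] + eps)
    return out


def test_taxa(
    table: CountTable,
    metadata: pd.DataFrame,
    site: str,
    side: str,
    contrast: str = "group",
    correction: str = "bonferroni",
    time_index: int | None = 0,
) -> pd.DataFrame:
    """Per-taxon smoker-vs-nonsmoker tests within one (site, side)
    stratum of an aggregated (genus/family) table.

    Fold difference follows the smoker/nonsmoker convention: values > 1
    mean higher pooled abundance in smokers.  ``p_bonferroni`` corrects
    across the taxa tested in this stratum.
    """
    if contrast != "group":
        raise ValueError("test_taxa handles the group contrast; use site_contrast")
    md = metadata.loc[table.sample_ids]
    mask = (md["site"] == site) & (md["side"] == side)
    if time_index is not None:
        mask &= md["time"] == time_index
    md = md[mask]
    ids_smoker = md.index[md["group"] == "smoker"]
    ids_nonsmoker = md.index[md["group"] == "nonsmoker"]
    if len(ids_smoker) == 0 or len(ids_nonsmoker) == 0:
        raise ValueError(f"stratum ({site}, {side}) lacks one group entirely")
    counts_s = table.counts.loc[ids_smoker]
    counts_n = table.counts.loc[ids_nonsmoker]
    rel_s = counts_s.div(counts_s.sum(axis=1), axis=0).to_numpy()
    rel_n = counts_n.div(counts_n.sum(axis=1), axis=0).to_numpy()
    pres_s = counts_s.to_numpy() > 0
    pres_n = counts_n.to_numpy() > 0
    folds = _fold_difference(
        counts_s.sum(axis=0).to_numpy(dtype=float),
        counts_n.sum(axis=0).to_numpy(dtype=float),
    )
    rows = []
    for t, taxon in enumerate(table.taxon_ids):
        frac_s = pres_s[:, t].mean()
        frac_n = pres_n[:, t].mean()
        test = select_test({"smoker": frac_s, "nonsmoker": frac_n}, paired=False)
        if test == "rank-sum":
            p = _rank_sum(rel_s[:, t], rel_n[:, t])
        else:
            p = _fisher(
                int(pres_s[:, t].sum()), len(ids_smoker),
                int(pres_n[:, t].sum()), len(ids_nonsmoker),
            )
        rows.append(
            {
                "taxon": taxon,
                "test_used": test,
                "fold_difference": float(folds[t]),
                "p_value": p,
                "detected_fraction_a": float(frac_s),
                "detected_fraction_b": float(frac_n),
            }
        )
    return _finish(rows, correction)


def site_contrast(
    table: CountTable,
    metadata: pd.DataFrame,
    correction: str = "bonferroni",
    time_index: int | None = 0,
) -> pd.DataFrame:
    """Paired nasopharynx-vs-oropharynx contrast per taxon.

    Each subject's left/right relative abundances are averaged per site
    before pairing; only subjects with both sites sampled enter.  Fold
    difference is nasopharynx/oropharynx pooled abundance (> 1 means
    more abundant in the nasopharynx).
    """
    md = metadata.loc[table.sample_ids]
    if time_index is not None:
        md = md[md["time"] == time_index]
    rel = table.relative_abundance()
    per_subject: dict[str, dict[str, list]] = {}
    for i in md.index:
        per_subject.setdefault(md.at[i, "subject"], {}).setdefault(
            md.at[i, "site"], []
        ).append(i)
    pairs_naso, pairs_oro = [], []
    for subject, sites in sorted(per_subject.items()):
        if set(SITES) <= set(sites):
            pairs_naso.append(rel.loc[sites["nasopharynx"]].mean(axis=0))
            pairs_oro.append(rel.loc[sites["oropharynx"]].mean(axis=0))
    if not pairs_naso:
        raise ValueError("no subjects with both sites sampled")
    naso = np.vstack([p.to_numpy() for p in pairs_naso])
    oro = np.vstack([p.to_numpy() for p in pairs_oro])
    ids_naso = md.index[md["site"] == "nasopharynx"]
    ids_oro = md.index[md["site"] == "oropharynx"]
    folds = _fold_difference(
        table.counts.loc[ids_naso].sum(axis=0).to_numpy(dtype=float),
        table.counts.loc[ids_oro].sum(axis=0).to_numpy(dtype=float),
    )
    rows = []
    for t, taxon in enumerate(table.taxon_ids):
        pres_n = naso[:, t] > 0
        pres_o = oro[:, t] > 0
        test = select_test(
            {"nasopharynx": pres_n.mean(), "oropharynx": pres_o.mean()}, paired=True
        )
        if test == "signed-rank":
            p = _signed_rank(naso[:, t], oro[:, t])
        else:
            p = _mcnemar(pres_n, pres_o)
        rows.append(
            {
                "taxon": taxon,
                "test_used": test,
                "fold_difference": float(folds[t]),
                "p_value": p,
                "detected_fraction_a": float(pres_n.mean()),
                "detected_fraction_b": float(pres_o.mean()),
            }
        )
    return _finish(rows, correction)


def _finish(rows: list[dict], correction: str) -> pd.DataFrame:
    if correction not in {"bonferroni", "none"}:
        raise ValueError(f"correction must be 'bonferroni' or 'none', got {correction!r}")
    df = pd.DataFrame(rows)
    m = len(df)
    if correction == "bonferroni":
        df["p_bonferroni"] = (df["p_value"] * m).clip(upper=1.0)
    else:
        df["p_bonferroni"] = df["p_value"]
    return df[RESULT_COLUMNS].sort_values("p_value", kind="stable").reset_index(drop=True)
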