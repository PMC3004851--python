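"""Distance-based community comparison tests and bootstrap clustering.

Three permutation tests on a distance matrix:

* :func:`within_group_test` — difference of mean within-group pairwise
  distances between two groups (a dispersion/heterogeneity contrast);
* :func:`within_vs_between_test` — mean between-group distance minus
  mean within-group distance (a membership/clustering contrast);
* :func:`permanova` — permutational multivariate ANOVA pseudo-F from
  the distance sum-of-squares decomposition.

All use label permutation with an add-one p-value
``p = (1 + #extreme) / (1 + n_perm)`` so p is never 0 and respects the
floor ``1/(n_perm+1)``.  When a subject contributes several samples to
one matrix, labels are permuted at the subject level, preserving
within-subject dependence.

:func:`temporal_stability_test` asks whether repeat samples of one
subject are closer to each other than to other subjects' samples, and
:func:`cluster_with_bootstrap` builds a complete-linkage dendrogram of
stratum-mean genus profiles with bootstrap (subject-resampling) support
percentages per split.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist
from skbio import DistanceMatrix

from .io import CountTable

logger = logging.getLogger(__name__)

__all__ = [
    "PermResult",
    "ClusterSupport",
    "within_group_test",
    "within_vs_between_test",
    "permanova",
    "temporal_stability_test",
    "cluster_with_bootstrap",
]

_EPS = 1e-12


@dataclass
class PermResult:
    statistic: float
    n_permutations: int
    p_value: float
    tail: str  # "one-sided" | "two-sided"
    direction: str | None
    seed: int | None
    extras: dict | None = None

    def asdict(self) -> dict:
        out = {
            "statistic": self.statistic,
            "n_permutations": self.n_permutations,
            "p_value": self.p_value,
            "tail": self.tail,
            "direction": self.direction,
            "seed": self.seed,
        }
        if self.extras:
            out.update(self.extras)
        return out


# ---------------------------------------------------------------------------
# shared machinery


def _align_labels(dm: DistanceMatrix, labels) -> np.ndarray:
    if isinstance(labels, pd.Series):
        return labels.loc[list(dm.ids)].to_numpy()
    labels = np.asarray(labels)
    if labels.shape[0] != len(dm.ids):
        raise ValueError("labels length does not match distance matrix")
    return labels


def _codes(values: np.ndarray) -> tuple[np.ndarray, list]:
    levels = sorted(set(values.tolist()))
    lookup = {v: i for i, v in enumerate(levels)}
    return np.array([lookup[v] for v in values]), levels


def _permuted_codes(
    codes: np.ndarray,
    n_perm: int,
    rng: np.random.Generator,
    subjects: np.ndarray | None,
) -> np.ndarray:
    """(n_perm, n) matrix of permuted label codes; subject-level
    exchange when a subject contributes multiple samples."""
    n = codes.size
    if subjects is not None:
        subjects = np.asarray(subjects)
        uniq, inverse = np.unique(subjects, return_inverse=True)
        if uniq.size < n:  # repeated subjects: permute subject labels
            subj_codes = np.empty(uniq.size, dtype=codes.dtype)
            subj_codes[inverse] = codes  # constant within subject
            out = np.empty((n_perm, n), dtype=codes.dtype)
            for p in range(n_perm):
                out[p] = rng.permutation(subj_codes)[inverse]
            return out
    out = np.empty((n_perm, n), dtype=codes.dtype)
    for p in range(n_perm):
        out[p] = rng.permutation(codes)
    return out


def _group_pair_sums(d: np.ndarray, z: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Sums and counts of within-group pairwise distances for each row
    of the membership matrix ``z`` (rows = permutations)."""
    zf = z.astype(float)
    sums = ((zf @ d) * zf).sum(axis=1) / 2.0
    sizes = zf.sum(axis=1)
    counts = sizes * (sizes - 1) / 2.0
    return sums, counts


def _check_two_groups(codes: np.ndarray, levels: list, minimum: int) -> None:
    if len(levels) != 2:
        raise ValueError(f"expected exactly 2 groups, got {len(levels)}: {levels}")
    for g, name in enumerate(levels):
        if (codes == g).sum() < minimum:
            raise ValueError(f"group {name!r} has fewer than {minimum} samples")


def _pvalue(t_obs: float, t_perm: np.ndarray, tail: str) -> float:
    scale = max(1.0, abs(t_obs))
    if tail == "two-sided":
        extreme = np.abs(t_perm) >= abs(t_obs) - _EPS * scale
    else:  # greater
        extreme = t_perm >= t_obs - _EPS * scale
    return (1 + int(extreme.sum())) / (1 + t_perm.size)


def _warn_small(n_perm: int) -> None:
    if n_perm < 100:
        logger.warning("n_perm=%d is small; p-values will be coarse", n_perm)


# ---------------------------------------------------------------------------
# tests


def within_group_test(
    dm: DistanceMatrix,
    labels,
    n_perm: int = 10_000,
    seed: int | np.random.SeedSequence = 0,
    subjects=None,
    tail: str = "two-sided",
) -> PermResult:
    """Dispersion contrast: T = mean within-group distance of group A
    minus that of group B, null by label permutation."""
    values = _align_labels(dm, labels)
    codes, levels = _codes(values)
    _check_two_groups(codes, levels, minimum=3)
    _warn_small(n_perm)
    subjects = _align_labels(dm, subjects) if subjects is not None else None
    d = np.asarray(dm.data, dtype=float)
    rng = np.random.default_rng(seed)

    def stat(label_rows: np.ndarray) -> np.ndarray:
        s0, c0 = _group_pair_sums(d, label_rows == 0)
        s1, c1 = _group_pair_sums(d, label_rows == 1)
        return s0 / c0 - s1 / c1

    t_obs = float(stat(codes[None, :])[0])
    t_perm = stat(_permuted_codes(codes, n_perm, rng, subjects))
    direction = None
    if t_obs != 0.0:
        direction = f"{levels[0] if t_obs > 0 else levels[1]} more dispersed"
    return PermResult(
        statistic=t_obs,
        n_permutations=n_perm,
        p_value=_pvalue(t_obs, t_perm, tail),
        tail=tail,
        direction=direction,
        seed=_seed_int(seed),
    )


def within_vs_between_test(
    dm: DistanceMatrix,
    labels,
    n_perm: int = 10_000,
    seed: int | np.random.SeedSequence = 0,
    subjects=None,
    tail: str = "greater",
) -> PermResult:
    """Membership contrast: T = mean between-group distance minus mean
    within-group distance (both groups pooled); one-sided (greater) by
    default — distinct communities give positive T."""
    values = _align_labels(dm, labels)
    codes, levels = _codes(values)
    _check_two_groups(codes, levels, minimum=3)
    _warn_small(n_perm)
    subjects = _align_labels(dm, subjects) if subjects is not None else None
    d = np.asarray(dm.data, dtype=float)
    total_sum = d.sum() / 2.0
    n = d.shape[0]
    total_pairs = n * (n - 1) / 2.0
    rng = np.random.default_rng(seed)

    def stat(label_rows: np.ndarray) -> np.ndarray:
        s0, c0 = _group_pair_sums(d, label_rows == 0)
        s1, c1 = _group_pair_sums(d, label_rows == 1)
        within_sum = s0 + s1
        within_pairs = c0 + c1
        between_sum = total_sum - within_sum
        between_pairs = total_pairs - within_pairs
        return between_sum / between_pairs - within_sum / within_pairs

    t_obs = float(stat(codes[None, :])[0])
    t_perm = stat(_permuted_codes(codes, n_perm, rng, subjects))
    direction = None
    if t_obs != 0.0:
        direction = "between greater" if t_obs > 0 else "within greater"
    return PermResult(
        statistic=t_obs,
        n_permutations=n_perm,
        p_value=_pvalue(t_obs, t_perm, tail),
        tail=tail,
        direction=direction,
        seed=_seed_int(seed),
    )


def permanova(
    dm: DistanceMatrix,
    labels,
    n_perm: int = 10_000,
    seed: int | np.random.SeedSequence = 0,
    subjects=None,
) -> PermResult:
    """Permutational multivariate ANOVA on a distance matrix.

    SS_total = (1/n) Σ_{i<j} d²; SS_within = Σ_g (1/n_g) Σ_{i<j∈g} d²;
    pseudo-F = (SS_between/(k−1)) / (SS_within/(n−k)); one-sided
    permutation p-value.
    """
    values = _align_labels(dm, labels)
    codes, levels = _codes(values)
    k = len(levels)
    if k < 2:
        raise ValueError("PERMANOVA needs at least 2 groups")
    for g, name in enumerate(levels):
        if (codes == g).sum() < 2:
            raise ValueError(f"group {name!r} has fewer than 2 samples")
    _warn_small(n_perm)
    subjects = _align_labels(dm, subjects) if subjects is not None else None
    d2 = np.asarray(dm.data, dtype=float) ** 2
    n = d2.shape[0]
    ss_total = d2.sum() / 2.0 / n
    rng = np.random.default_rng(seed)

    def stat(label_rows: np.ndarray) -> np.ndarray:
        ss_within = np.zeros(label_rows.shape[0])
        for g in range(k):
            s, _ = _group_pair_sums(d2, label_rows == g)
            sizes = (label_rows == g).sum(axis=1)
            ss_within += s / sizes
        ss_between = ss_total - ss_within
        return (ss_between / (k - 1)) / (ss_within / (n - k))

    f_obs = float(stat(codes[None, :])[0])
    f_perm = stat(_permuted_codes(codes, n_perm, rng, subjects))
    return PermResult(
        statistic=f_obs,
        n_permutations=n_perm,
        p_value=_pvalue(f_obs, f_perm, "greater"),
        tail="one-sided",
        direction=None,
        seed=_seed_int(seed),
    )


def temporal_stability_test(
    dm: DistanceMatrix,
    metadata: pd.DataFrame,
    n_perm: int = 10_000,
    seed: int | np.random.SeedSequence = 0,
) -> PermResult:
    """Are repeat samples of a subject closer to each other than to
    other subjects?  T = mean between-subject distance − mean
    within-subject (across-time) distance; null permutes the subject
    assignment of samples; one-sided (greater)."""
    subjects = metadata.loc[list(dm.ids), "subject"].to_numpy()
    uniq, counts = np.unique(subjects, return_counts=True)
    if (counts >= 2).sum() < 2:
        raise ValueError(
            "temporal stability needs >= 2 subjects with >= 2 samples over time"
        )
    _warn_small(n_perm)
    d = np.asarray(dm.data, dtype=float)
    n = d.shape[0]
    codes = np.unique(subjects, return_inverse=True)[1]
    rng = np.random.default_rng(seed)
    total_sum = d.sum() / 2.0
    total_pairs = n * (n - 1) / 2.0

    def stat(rows: np.ndarray) -> np.ndarray:
        same = rows[:, :, None] == rows[:, None, :]
        within_sum = (same * d).sum(axis=(1, 2)) / 2.0
        same_pairs = (same.sum(axis=(1, 2)) - n) / 2.0
        between_sum = total_sum - within_sum
        between_pairs = total_pairs - same_pairs
        return between_sum / between_pairs - within_sum / same_pairs

    t_obs = float(stat(codes[None, :])[0])
    # chunked to bound the (chunk, n, n) broadcast memory
    chunks = []
    remaining = n_perm
    while remaining > 0:
        m = min(remaining, 500)
        rows = np.empty((m, n), dtype=codes.dtype)
        for p in range(m):
            rows[p] = rng.permutation(codes)
        chunks.append(stat(rows))
        remaining -= m
    t_perm = np.concatenate(chunks)
    direction = None
    if t_obs != 0.0:
        direction = (
            "within-subject more similar" if t_obs > 0 else "within-subject less similar"
        )
    return PermResult(
        statistic=t_obs,
        n_permutations=n_perm,
        p_value=_pvalue(t_obs, t_perm, "greater"),
        tail="one-sided",
        direction=direction,
        seed=_seed_int(seed),
    )


def _seed_int(seed) -> int | None:
    if isinstance(seed, (int, np.integer)):
        return int(seed)
    if isinstance(seed, np.random.SeedSequence):
        ent = seed.entropy
        return int(ent) if isinstance(ent, (int, np.integer)) else None
    return None


# ---------------------------------------------------------------------------
# hierarchical clustering with bootstrap support


@dataclass
class ClusterSupport:
    """Complete-linkage dendrogram over stratum leaves with bootstrap
    support (percent of replicates reproducing each split)."""

    leaf_names: list[str]
    linkage: np.ndarray  # scipy linkage matrix
    node_leaf_sets: list[frozenset]  # per internal node, merge order
    support: np.ndarray  # percent, same order
    n_bootstraps: int
    kept_genera: list[str]

    def to_newick(self) -> str:
        n = len(self.leaf_names)
        names = {i: self.leaf_names[i] for i in range(n)}
        heights = {i: 0.0 for i in range(n)}
        for row_idx, (a, b, h, _) in enumerate(self.linkage):
            a, b = int(a), int(b)
            branch_a = h - heights[a]
            branch_b = h - heights[b]
            label = f"{self.support[row_idx]:.1f}"
            names[n + row_idx] = (
                f"({names[a]}:{branch_a:.6g},{names[b]}:{branch_b:.6g}){label}"
            )
            heights[n + row_idx] = h
        return names[n + len(self.linkage) - 1] + ";"


def _cluster_sets(linkage_matrix: np.ndarray, n_leaves: int) -> list[frozenset]:
    sets: dict[int, frozenset] = {i: frozenset([i]) for i in range(n_leaves)}
    out = []
    for row_idx, (a, b, _, _) in enumerate(linkage_matrix):
        merged = sets[int(a)] | sets[int(b)]
        sets[n_leaves + row_idx] = merged
        out.append(merged)
    return out


def _stratum_profiles(
    rel: pd.DataFrame,
    metadata: pd.DataFrame,
    strata: list[tuple],
    sample_sets: dict[tuple, list[str]],
) -> np.ndarray:
    return np.vstack([rel.loc[sample_sets[s]].mean(axis=0).to_numpy() for s in strata])


def cluster_with_bootstrap(
    genus_table: CountTable,
    metadata: pd.DataFrame,
    n_boot: int = 1_000,
    seed: int | np.random.SeedSequence = 0,
    filter_fraction: float = 0.002,
    use_relative: bool = True,
    linkage_method: str = "complete",
) -> ClusterSupport:
    """Cluster (site, side, group) stratum-mean genus profiles and
    attach bootstrap support to each split.

    Genera are kept when their stratum-mean relative abundance exceeds
    ``filter_fraction`` in at least one stratum.  Bootstrap replicates
    resample subjects with replacement within each stratum, rebuild the
    profiles, recluster, and count recurrence of each original leaf
    bipartition.
    """
    md = metadata.loc[genus_table.sample_ids]
    strata = sorted(
        {(r["site"], r["side"], r["group"]) for _, r in md.iterrows()}
    )
    if len(strata) < 3:
        raise ValueError("need at least 3 strata (leaves) to cluster")
    sample_sets: dict[tuple, list[str]] = {}
    subject_samples: dict[tuple, dict[str, list[str]]] = {}
    for stratum in strata:
        site, side, group = stratum
        ids = md.index[
            (md["site"] == site) & (md["side"] == side) & (md["group"] == group)
        ]
        if len(ids) == 0:
            raise ValueError(f"stratum {stratum} has no samples")
        sample_sets[stratum] = list(ids)
        per_subject: dict[str, list[str]] = {}
        for i in ids:
            per_subject.setdefault(md.at[i, "subject"], []).append(i)
        subject_samples[stratum] = per_subject

    rel = genus_table.relative_abundance()
    profiles_rel = _stratum_profiles(rel, md, strata, sample_sets)
    keep = (profiles_rel > filter_fraction).any(axis=0)
    kept_genera = [g for g, k in zip(genus_table.taxon_ids, keep) if k]
    if not kept_genera:
        raise ValueError(
            f"no genera pass the {filter_fraction:g} stratum-abundance filter"
        )
    feats = rel if use_relative else genus_table.counts.astype(float)
    feats = feats[kept_genera]

    leaf_names = [f"{site[:4]}.{side[0].upper()}.{group}" for site, side, group in strata]
    x = np.vstack(
        [feats.loc[sample_sets[s]].mean(axis=0).to_numpy() for s in strata]
    )
    linkage_matrix = hierarchy.linkage(x, method=linkage_method, metric="euclidean")
    node_sets = _cluster_sets(linkage_matrix, len(strata))
    all_leaves = frozenset(range(len(strata)))

    rng = np.random.default_rng(seed)
    hits = np.zeros(len(node_sets), dtype=np.int64)
    for _ in range(n_boot):
        rows = []
        for stratum in strata:
            per_subject = subject_samples[stratum]
            subj_ids = sorted(per_subject)
            chosen = rng.integers(0, len(subj_ids), size=len(subj_ids))
            samples: list[str] = []
            for c in chosen:
                samples.extend(per_subject[subj_ids[c]])
            rows.append(feats.loc[samples].mean(axis=0).to_numpy())
        xb = np.vstack(rows)
        lb = hierarchy.linkage(xb, method=linkage_method, metric="euclidean")
        boot_sets = set(_cluster_sets(lb, len(strata)))
        for i, s in enumerate(node_sets):
            if s in boot_sets or (all_leaves - s) in boot_sets:
                hits[i] += 1
    support = 100.0 * hits / n_boot
    return ClusterSupport(
        leaf_names=leaf_names,
        linkage=linkage_matrix,
        node_leaf_sets=node_sets,
        support=support,
        n_bootstraps=n_boot,
        kept_genera=kept_genera,
    )
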