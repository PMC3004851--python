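"""Synthetic study generator.

Emulates the design of a two-group upper-airway 16S survey: ~62
subjects in two smoking-status groups (33 nonsmokers, 29 smokers), four
airway samples per subject (nasopharynx/oropharynx × left/right) with
near-replicated left/right sides, sequencing depth ~1,335 ± 603 reads
per sample, site-dominant composition, group-specific genus fold
changes, and greater compositional dispersion in the smoker group.

The generative model is hierarchical Dirichlet-multinomial:

1. per site, a baseline mean composition ``m_site`` on the simplex
   (log-normal weights, normalised); sites are distinct by independent
   draws, with a per-site evenness parameter (log-normal sigma) so that
   the oropharynx is more even (higher Shannon) than the nasopharynx;
2. the group effect multiplies affected taxa of the smoker mean by
   ``2**log2_fc`` and renormalises;
3. each subject's latent composition ~ Dirichlet(theta_group · m);
   a smaller theta for smokers yields greater within-group dispersion;
4. each side/time replicate ~ Dirichlet(theta_rep · subject
   composition), giving left/right near-replication;
5. counts ~ Multinomial(depth, replicate), depth ~ round(max(100,
   Normal(depth_mean, depth_sd))).

Every latent quantity is recorded in :class:`GroundTruth` so that
downstream stages can be tested for parameter recovery.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from skbio import TreeNode

from .io import (
    GROUPS,
    RANKS,
    SIDES,
    SITES,
    UNASSIGNED,
    CountTable,
    read_count_table,
    read_metadata,
    read_tree,
    validate_metadata,
    write_count_table,
    write_metadata,
    write_tree,
)

__all__ = [
    "SimulationDesign",
    "EffectSpec",
    "GroundTruth",
    "StudyBundle",
    "simulate_tree",
    "simulate_study",
    "simulate_bundle",
    "simulate_null_groups",
    "write_study",
    "read_study",
]


@dataclass(frozen=True)
class EffectSpec:
    """One planted group effect: the taxa of ``genus`` at ``site`` have
    their smoker-group mean abundance multiplied by ``2**log2_fc``."""

    genus: str
    site: str
    log2_fc: float
    taxa: tuple[str, ...]


@dataclass
class SimulationDesign:
    # (nonsmoker, smoker) subject counts; Table-1-style defaults
    n_subjects_per_group: tuple[int, int] = (33, 29)
    n_taxa: int = 200
    n_genera: int = 40
    depth_mean: float = 1335.0
    depth_sd: float = 603.0
    # Dirichlet concentration per group; smaller = more dispersed
    dispersion: dict = field(
        default_factory=lambda: {"nonsmoker": 60.0, "smoker": 20.0}
    )
    # concentration for left/right (and repeat-time) within-subject resampling
    replicate_noise: float = 400.0
    # log-normal sigma of the site baseline; smaller = more even community
    site_evenness_sigma: dict = field(
        default_factory=lambda: {"nasopharynx": 2.0, "oropharynx": 1.2}
    )
    n_effect_genera: int = 5
    effect_log2fc_range: tuple[float, float] = (0.5, 1.5)
    # effects are planted on genera at or above this baseline abundance
    min_effect_abundance: float = 0.01
    effect_taxa: list[EffectSpec] | None = None
    # subjects sampled at >1 timepoint, per group (nonsmoker, smoker)
    n_repeat_subjects_per_group: tuple[int, int] = (1, 5)
    n_timepoints_repeat: int = 2
    contaminant_fraction: float = 0.0
    frac_unassigned_genus: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        for g, theta in self.dispersion.items():
            if theta <= 0:
                raise ValueError(f"dispersion for {g} must be > 0, got {theta}")
        if self.replicate_noise <= 0:
            raise ValueError("replicate_noise must be > 0")
        if self.depth_mean <= 0:
            raise ValueError("depth_mean must be > 0")
        if self.effect_taxa is not None:
            for eff in self.effect_taxa:
                if not np.isfinite(eff.log2_fc):
                    raise ValueError("effect log2 fold changes must be finite")


@dataclass
class GroundTruth:
    """Latent quantities of a simulated study, for recovery tests."""

    site_baselines: dict
    group_site_means: dict  # "site|group" -> composition list
    differential_taxa: list  # dicts: genus, site, log2_fc, taxa
    subject_compositions: dict  # "subject|site" -> composition list
    contaminant_taxa: list

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, sort_keys=True, indent=1)

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        with open(path) as fh:
            return cls(**json.load(fh))


@dataclass
class StudyBundle:
    table: CountTable
    metadata: pd.DataFrame
    tree: TreeNode
    truth: GroundTruth


# ---------------------------------------------------------------------------
# tree + taxonomy simulation


def _yule_topology(n_taxa: int, rng: np.random.Generator) -> TreeNode:
    root = TreeNode()
    root.extend([TreeNode(), TreeNode()])
    tips = list(root.children)
    while len(tips) < n_taxa:
        k = int(rng.integers(len(tips)))
        node = tips.pop(k)
        node.extend([TreeNode(), TreeNode()])
        tips.extend(node.children)
    return root


def _frontier_partition(root: TreeNode, k: int) -> list[list[TreeNode]]:
    """Split the tree into ``k`` monophyletic clades by repeatedly
    dividing the largest frontier clade; returns tip lists per clade."""
    tip_count: dict[int, int] = {}
    for node in root.postorder():
        tip_count[id(node)] = 1 if node.is_tip() else sum(
            tip_count[id(c)] for c in node.children
        )
    frontier = [root]
    while len(frontier) < k:
        splittable = [n for n in frontier if not n.is_tip()]
        if not splittable:
            break
        biggest = max(splittable, key=lambda n: tip_count[id(n)])
        idx = frontier.index(biggest)
        frontier[idx : idx + 1] = list(biggest.children)
    return [list(node.tips()) if not node.is_tip() else [node] for node in frontier]


def simulate_tree(
    n_taxa: int,
    seed: int | np.random.SeedSequence = 0,
    n_genera: int = 40,
    n_phyla: int = 4,
    n_families: int | None = None,
    branch_length_mean: float = 0.1,
    frac_unassigned_genus: float = 0.0,
) -> tuple[TreeNode, pd.DataFrame]:
    """Rooted bifurcating pure-birth (Yule) tree with i.i.d. exponential
    branch lengths, tips ``taxon_0001``…, and a tree-consistent taxonomy:
    genera (and families, phyla) are monophyletic clades.

    Returns ``(tree, lineage)`` where ``lineage`` is indexed by taxon id
    with the standard ranks (class/order left unassigned).
    """
    if n_taxa < 2:
        raise ValueError(f"n_taxa must be >= 2, got {n_taxa}")
    if n_families is None:
        n_families = max(1, n_genera // 4)
    rng = np.random.default_rng(seed)
    root = _yule_topology(n_taxa, rng)
    for node in root.traverse(include_self=False):
        node.length = float(rng.exponential(branch_length_mean))
    root.length = None
    width = max(4, len(str(n_taxa)))
    for i, tip in enumerate(root.tips(), start=1):
        tip.name = f"taxon_{i:0{width}d}"

    lineage = pd.DataFrame(
        UNASSIGNED, index=[t.name for t in root.tips()], columns=list(RANKS)
    )
    for rank, k, prefix in (
        ("phylum", n_phyla, "phylum"),
        ("family", n_families, "family"),
        ("genus", n_genera, "genus"),
    ):
        clades = _frontier_partition(root, min(k, n_taxa))
        for j, tips in enumerate(clades, start=1):
            label = f"{prefix}_{j:03d}"
            lineage.loc[[t.name for t in tips], rank] = label
    if frac_unassigned_genus > 0:
        n_blank = int(round(frac_unassigned_genus * n_taxa))
        if n_blank:
            blank = rng.choice(lineage.index.to_numpy(), size=n_blank, replace=False)
            lineage.loc[blank, "genus"] = UNASSIGNED
    return root, lineage


# ---------------------------------------------------------------------------
# study simulation


def _dirichlet(rng: np.random.Generator, alpha: np.ndarray) -> np.ndarray:
    # gamma-based draw; robust to very small concentrations (zeros stay zero)
    g = rng.gamma(np.maximum(alpha, 0.0))
    total = g.sum()
    if total <= 0:
        g = np.asarray(alpha, dtype=float)
        total = g.sum()
    return g / total


def _default_effects(
    design: SimulationDesign,
    lineage: pd.DataFrame,
    rng: np.random.Generator,
    site_baselines: dict[str, np.ndarray],
) -> list[EffectSpec]:
    """Plant group effects on moderately abundant genera (baseline
    relative abundance ≥ ``min_effect_abundance``), as smoking-
    associated taxa in airway surveys are abundant lineages; a doubling
    of a vanishingly rare genus would carry no information at realistic
    depth and sample size."""
    assigned = lineage[lineage["genus"] != UNASSIGNED]
    pos = {t: i for i, t in enumerate(lineage.index)}
    lo, hi = design.effect_log2fc_range
    effects = []
    for site in SITES:
        baseline = site_baselines[site]
        abundance = {
            g: float(
                baseline[[pos[t] for t in assigned.index[assigned["genus"] == g]]].sum()
            )
            for g in sorted(assigned["genus"].unique())
        }
        eligible = [g for g, a in abundance.items() if a >= design.min_effect_abundance]
        if len(eligible) < design.n_effect_genera:
            eligible = sorted(abundance, key=abundance.get, reverse=True)[
                : design.n_effect_genera
            ]
        chosen = rng.choice(
            sorted(eligible), size=min(design.n_effect_genera, len(eligible)), replace=False
        )
        for j, genus in enumerate(sorted(chosen)):
            sign = 1.0 if j % 2 == 0 else -1.0
            lfc = float(sign * rng.uniform(lo, hi))
            members = tuple(assigned.index[assigned["genus"] == genus])
            effects.append(EffectSpec(genus=genus, site=site, log2_fc=lfc, taxa=members))
    return effects


def simulate_study(
    design: SimulationDesign, tree: TreeNode, lineage: pd.DataFrame
) -> tuple[CountTable, pd.DataFrame, GroundTruth]:
    """Draw one study (counts, metadata, ground truth) from the
    hierarchical Dirichlet-multinomial model described in the module
    docstring.  Fully deterministic given ``design.seed``."""
    taxa = list(lineage.index)
    n_taxa = len(taxa)
    taxon_pos = {t: i for i, t in enumerate(taxa)}
    ss = np.random.SeedSequence(design.seed)
    rng_base, rng_eff, rng_subj, rng_rep, rng_depth = (
        np.random.default_rng(c) for c in ss.spawn(5)
    )

    site_baselines = {}
    for site in SITES:
        sigma = design.site_evenness_sigma[site]
        w = rng_base.lognormal(mean=0.0, sigma=sigma, size=n_taxa)
        site_baselines[site] = w / w.sum()

    contaminants: list[str] = []
    contaminant_profile = None
    if design.contaminant_fraction > 0:
        contaminants = sorted(
            rng_base.choice(np.array(taxa), size=3, replace=False).tolist()
        )
        w = rng_base.lognormal(0.0, 0.5, size=3)
        contaminant_profile = np.zeros(n_taxa)
        contaminant_profile[[taxon_pos[t] for t in contaminants]] = w / w.sum()

    effects = design.effect_taxa
    if effects is None:
        effects = _default_effects(design, lineage, rng_eff, site_baselines)
    for eff in effects:
        unknown = set(eff.taxa) - set(taxa)
        if unknown:
            raise ValueError(f"effect taxa not in taxon set: {sorted(unknown)[:5]}")

    group_site_means = {}
    for site in SITES:
        for group in GROUPS:
            m = site_baselines[site].copy()
            if group == "smoker":
                for eff in effects:
                    if eff.site != site:
                        continue
                    idx = [taxon_pos[t] for t in eff.taxa]
                    m[idx] *= 2.0 ** eff.log2_fc
                m /= m.sum()
            group_site_means[f"{site}|{group}"] = m

    # subjects and their sampling schedule
    records = []
    subject_compositions = {}
    counts_rows = {}
    for gi, group in enumerate(GROUPS):
        n_subj = design.n_subjects_per_group[gi]
        n_repeat = design.n_repeat_subjects_per_group[gi]
        theta = float(design.dispersion[group])
        prefix = "NS" if group == "nonsmoker" else "SM"
        for s in range(n_subj):
            subject = f"{prefix}{s + 1:03d}"
            n_time = design.n_timepoints_repeat if s < n_repeat else 1
            for site in SITES:
                m = group_site_means[f"{site}|{group}"]
                p_subj = _dirichlet(rng_subj, theta * m)
                subject_compositions[f"{subject}|{site}"] = p_subj.tolist()
                for side in SIDES:
                    for t in range(n_time):
                        p_rep = _dirichlet(rng_rep, design.replicate_noise * p_subj)
                        if contaminant_profile is not None:
                            f = design.contaminant_fraction
                            p_rep = (1.0 - f) * p_rep + f * contaminant_profile
                        depth = int(
                            max(
                                100,
                                round(
                                    rng_depth.normal(design.depth_mean, design.depth_sd)
                                ),
                            )
                        )
                        sample_id = f"{subject}-{site[:4]}-{side[0].upper()}-t{t}"
                        counts_rows[sample_id] = rng_rep.multinomial(
                            depth, p_rep / p_rep.sum()
                        )
                        records.append(
                            {
                                "sample_id": sample_id,
                                "subject": subject,
                                "site": site,
                                "side": side,
                                "group": group,
                                "time": t,
                            }
                        )

    counts = pd.DataFrame.from_dict(counts_rows, orient="index", columns=taxa)
    table = CountTable(counts, lineage.copy())
    metadata = pd.DataFrame.from_records(records, index="sample_id")
    metadata = validate_metadata(metadata)
    truth = GroundTruth(
        site_baselines={s: v.tolist() for s, v in site_baselines.items()},
        group_site_means={k: v.tolist() for k, v in group_site_means.items()},
        differential_taxa=[
            {
                "genus": e.genus,
                "site": e.site,
                "log2_fc": e.log2_fc,
                "taxa": list(e.taxa),
            }
            for e in effects
        ],
        subject_compositions=subject_compositions,
        contaminant_taxa=contaminants,
    )
    return table, metadata, truth


def simulate_bundle(design: SimulationDesign) -> StudyBundle:
    """Simulate tree + taxonomy + study in one call (seeds derived from
    ``design.seed``)."""
    tree_seed, _ = np.random.SeedSequence(design.seed).spawn(2)
    tree, lineage = simulate_tree(
        design.n_taxa,
        seed=tree_seed,
        n_genera=design.n_genera,
        frac_unassigned_genus=design.frac_unassigned_genus,
    )
    table, metadata, truth = simulate_study(design, tree, lineage)
    return StudyBundle(table=table, metadata=metadata, tree=tree, truth=truth)


def simulate_null_groups(
    n_per_group: int,
    n_taxa: int = 60,
    theta: float = 20.0,
    depth: int = 500,
    sigma: float = 1.5,
    seed: int | np.random.SeedSequence = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Exchangeable two-group null: every sample i.i.d. Dirichlet-
    multinomial around one shared baseline, equal dispersion in both
    groups.  Returns ``(counts, labels)`` arrays for type-I-error
    calibration of the permutation tests."""
    rng = np.random.default_rng(seed)
    w = rng.lognormal(0.0, sigma, size=n_taxa)
    m = w / w.sum()
    n = 2 * n_per_group
    counts = np.empty((n, n_taxa), dtype=np.int64)
    for i in range(n):
        p = _dirichlet(rng, theta * m)
        counts[i] = rng.multinomial(depth, p)
    labels = np.repeat([0, 1], n_per_group)
    return counts, labels


# ---------------------------------------------------------------------------
# persistence


def write_study(bundle: StudyBundle, out_dir: str | Path) -> dict[str, Path]:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "counts": out / "counts.tsv",
        "taxonomy": out / "taxonomy.tsv",
        "tree": out / "tree.nwk",
        "metadata": out / "metadata.tsv",
        "truth": out / "ground_truth.json",
    }
    write_count_table(bundle.table, paths["counts"], paths["taxonomy"])
    write_tree(bundle.tree, paths["tree"])
    write_metadata(bundle.metadata, paths["metadata"])
    bundle.truth.to_json(paths["truth"])
    return paths


def read_study(in_dir: str | Path) -> StudyBundle:
    src = Path(in_dir)
    table = read_count_table(src / "counts.tsv", src / "taxonomy.tsv")
    tree = read_tree(src / "tree.nwk")
    metadata = read_metadata(src / "metadata.tsv")
    truth_path = src / "ground_truth.json"
    truth = GroundTruth.from_json(truth_path) if truth_path.exists() else None
    return StudyBundle(table=table, metadata=metadata, tree=tree, truth=truth)
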