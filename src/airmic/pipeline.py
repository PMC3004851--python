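"""End-to-end orchestration: simulate → alpha → beta → community tests
→ taxa tests → classify → cluster → temporal stability.

One :class:`~airmic.config.PipelineConfig` plus one seed fully
determines a run; rerunning with the same config and seed reproduces
the report byte-identically.  Every stage writes its own TSV/JSON
output under the run directory, and the consolidated
:class:`RunReport` holds the headline numbers (a Table-2-style p-value
grid across site × side × metric × test, alpha comparisons,
significant-taxa counts, RF accuracies, cluster supports).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import alpha as alpha_mod
from . import beta as beta_mod
from . import classify as classify_mod
from . import community as community_mod
from . import taxa as taxa_mod
from .config import PipelineConfig
from .io import SIDES, SITES, write_count_table, write_distance_matrix
from .simulate import SimulationDesign, StudyBundle, simulate_bundle, write_study

logger = logging.getLogger(__name__)

__all__ = ["RunReport", "run_all"]


@dataclass
class RunReport:
    config: dict
    design_seed: int | None
    output_dir: str
    stage_outputs: dict
    summary: dict

    def to_json(self, path: str | Path) -> None:
        payload = dataclasses.asdict(self)
        with open(path, "w") as fh:
            json.dump(payload, fh, sort_keys=True, indent=1)

    def summary_text(self) -> str:
        lines = ["airway microbiota community analysis — run summary", ""]
        lines.append(f"seed: {self.config.get('rng_seed')}")
        lines.append("")
        lines.append("community tests (p-values):")
        grid = self.summary.get("community_tests", {})
        for key in sorted(grid):
            entry = grid[key]
            lines.append(
                f"  {key}: within-group p={entry['within_group']['p_value']:.4g}"
                f" ({entry['within_group']['direction']}),"
                f" within-vs-between p={entry['within_vs_between']['p_value']:.4g},"
                f" PERMANOVA p={entry['permanova']['p_value']:.4g}"
            )
        lines.append("")
        lines.append("alpha diversity comparisons:")
        for row in self.summary.get("alpha_comparisons", []):
            lines.append(
                f"  {row['metric']} {row['stratum']}: {row['test']}"
                f" p={row['p_value']:.4g}"
                f" (medians {row['median_a']:.3g} vs {row['median_b']:.3g})"
            )
        lines.append("")
        lines.append("taxa association (genus, smoker vs nonsmoker):")
        for key in sorted(self.summary.get("taxa_tests", {})):
            entry = self.summary["taxa_tests"][key]
            lines.append(
                f"  {key}: {entry['n_significant_bonferroni']} of {entry['n_tested']}"
                f" genera significant after Bonferroni"
            )
        lines.append("")
        lines.append("random-forest classification:")
        for key in sorted(self.summary.get("classification", {})):
            entry = self.summary["classification"][key]
            lines.append(
                f"  {key}: median accuracy {entry['median_accuracy']:.3f},"
                f" OOB {entry['oob_accuracy']:.3f},"
                f" Friedman p={entry['friedman_p']:.3g},"
                f" top genus {entry['top_genus']}"
            )
        lines.append("")
        cluster = self.summary.get("cluster", {})
        if cluster:
            lines.append(
                f"cluster bootstrap: site split support {cluster['site_split_support']:.1f}%"
                f" over {cluster['n_bootstraps']} replicates"
            )
        temporal = self.summary.get("temporal", {})
        if temporal:
            lines.append("temporal stability (p-values):")
            for key in sorted(temporal):
                lines.append(f"  {key}: p={temporal[key]['p_value']:.4g}")
        lines.append("")
        return "\n".join(lines)


def _stage_seeds(seed: int) -> dict[str, np.random.SeedSequence]:
    names = ["simulate", "alpha", "beta", "community", "taxa", "classify", "cluster", "temporal"]
    children = np.random.SeedSequence(seed).spawn(len(names))
    return dict(zip(names, children))


def run_all(
    config: PipelineConfig | None = None,
    design: SimulationDesign | None = None,
    bundle: StudyBundle | None = None,
    out_dir: str | Path = "airmic_run",
) -> RunReport:
    """Execute every stage on a provided study bundle or a freshly
    simulated one; returns the consolidated report (also written to
    ``out_dir/report.json`` and ``out_dir/summary.txt``)."""
    config = config or PipelineConfig()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(config.rng_seed)
    stage_outputs: dict[str, str] = {}
    summary: dict = {}

    # -- stage 0: inputs ----------------------------------------------------
    if bundle is None:
        if design is None:
            design = SimulationDesign(seed=config.rng_seed)
        logger.info("simulating study (seed %s)", design.seed)
        bundle = simulate_bundle(design)
        write_study(bundle, out / "sim")
        stage_outputs["simulation"] = "sim"
    table = bundle.table.drop_empty_samples()
    metadata = bundle.metadata.loc[table.sample_ids]
    genus_table = table.aggregate_to_rank("genus")
    write_count_table(genus_table, out / "genus_counts.tsv")
    stage_outputs["genus_table"] = "genus_counts.tsv"

    # -- stage 1: alpha diversity ------------------------------------------
    logger.info("alpha diversity at depth %d", config.rarefaction_depth)
    alpha_df = alpha_mod.alpha_diversity(
        table,
        depth=config.rarefaction_depth,
        n_draws=config.n_rarefaction_draws,
        seed=seeds["alpha"],
    )
    alpha_df.to_csv(out / "alpha_per_sample.tsv", sep="\t")
    site_cmp = alpha_mod.compare_alpha(alpha_df, metadata, contrast="site")
    group_cmp = alpha_mod.compare_alpha(alpha_df, metadata, contrast="group")
    alpha_report = pd.concat([site_cmp, group_cmp], ignore_index=True)
    alpha_report.to_csv(out / "alpha_comparisons.tsv", sep="\t", index=False)
    stage_outputs["alpha"] = "alpha_comparisons.tsv"
    summary["alpha_comparisons"] = alpha_report.to_dict(orient="records")

    # -- stage 2+3: beta diversity & community tests ------------------------
    community_grid: dict[str, dict] = {}
    comm_seeds = seeds["community"].spawn(len(SITES) * len(SIDES) * 2)
    beta_dir = out / "beta"
    beta_dir.mkdir(exist_ok=True)
    si = 0
    baseline = metadata[metadata["time"] == 0]
    for site in SITES:
        for side in SIDES:
            ids = baseline.index[
                (baseline["site"] == site) & (baseline["side"] == side)
            ]
            ids = [i for i in ids if i in table.counts.index]
            sub = table.select_samples(ids)
            labels = metadata.loc[ids, "group"]
            for metric in ("unweighted", "weighted"):
                dm = beta_mod.distance_matrix(sub, bundle.tree, metric=metric)
                write_distance_matrix(dm, beta_dir / f"{site}_{side}_{metric}.tsv")
                test_seeds = comm_seeds[si].spawn(3)
                si += 1
                wg = community_mod.within_group_test(
                    dm, labels, n_perm=config.n_permutations, seed=test_seeds[0]
                )
                wb = community_mod.within_vs_between_test(
                    dm, labels, n_perm=config.n_permutations, seed=test_seeds[1]
                )
                pm = community_mod.permanova(
                    dm, labels, n_perm=config.n_permutations, seed=test_seeds[2]
                )
                community_grid[f"{site}|{side}|{metric}"] = {
                    "within_group": wg.asdict(),
                    "within_vs_between": wb.asdict(),
                    "permanova": pm.asdict(),
                }
    with open(out / "community_tests.json", "w") as fh:
        json.dump(community_grid, fh, sort_keys=True, indent=1)
    stage_outputs["community_tests"] = "community_tests.json"
    summary["community_tests"] = community_grid

    # -- stage 4: taxa association -----------------------------------------
    taxa_summary: dict[str, dict] = {}
    taxa_dir = out / "taxa"
    taxa_dir.mkdir(exist_ok=True)
    for site in SITES:
        for side in SIDES:
            res = taxa_mod.test_taxa(genus_table, metadata, site=site, side=side)
            res.to_csv(taxa_dir / f"group_{site}_{side}.tsv", sep="\t", index=False)
            taxa_summary[f"{site}|{side}"] = {
                "n_tested": int(len(res)),
                "n_significant_bonferroni": int(
                    (res["p_bonferroni"] < config.alpha).sum()
                ),
                "top_taxa": res.head(5)["taxon"].tolist(),
            }
    site_res = taxa_mod.site_contrast(genus_table, metadata)
    site_res.to_csv(taxa_dir / "site_contrast.tsv", sep="\t", index=False)
    stage_outputs["taxa"] = "taxa"
    summary["taxa_tests"] = taxa_summary
    summary["site_contrast"] = {
        "n_tested": int(len(site_res)),
        "n_significant_bonferroni": int(
            (site_res["p_bonferroni"] < config.alpha).sum()
        ),
    }

    # -- stage 5: classification -------------------------------------------
    class_summary: dict[str, dict] = {}
    cls_seeds = seeds["classify"].spawn(len(SITES) * len(SIDES))
    errors_rows = []
    for idx, (site, side) in enumerate(
        [(a, b) for a in SITES for b in SIDES]
    ):
        ev = classify_mod.evaluate_classifier(
            genus_table, metadata, site=site, side=side,
            config=config, seed=cls_seeds[idx],
        )
        class_summary[f"{site}|{side}"] = {
            "median_accuracy": ev.median_accuracy,
            "oob_accuracy": ev.oob_accuracy,
            "friedman_statistic": ev.friedman_statistic,
            "friedman_p": ev.friedman_p,
            "error_difference_ci": list(ev.error_difference_ci),
            "top_genus": ev.importances.index[0],
        }
        ev.importances.to_csv(out / f"rf_importance_{site}_{side}.tsv", sep="\t")
        for it, (me, ge) in enumerate(zip(ev.model_errors, ev.guess_errors)):
            errors_rows.append(
                {"site": site, "side": side, "iteration": it, "model": me, "guess": ge}
            )
    pd.DataFrame(errors_rows).to_csv(out / "rf_errors.tsv", sep="\t", index=False)
    stage_outputs["classification"] = "rf_errors.tsv"
    summary["classification"] = class_summary

    # -- stage 6: cluster bootstrap ----------------------------------------
    baseline_ids = [i for i in baseline.index if i in genus_table.counts.index]
    support = community_mod.cluster_with_bootstrap(
        genus_table.select_samples(baseline_ids),
        metadata,
        n_boot=config.n_cluster_bootstraps,
        seed=seeds["cluster"],
        filter_fraction=config.genus_filter_fraction,
    )
    with open(out / "cluster.nwk", "w") as fh:
        fh.write(support.to_newick() + "\n")
    # the split separating the two sites = the root split of the dendrogram
    site_split = float(support.support[-1])
    summary["cluster"] = {
        "site_split_support": site_split,
        "supports": support.support.tolist(),
        "n_bootstraps": support.n_bootstraps,
        "n_genera_kept": len(support.kept_genera),
    }
    stage_outputs["cluster"] = "cluster.nwk"

    # -- stage 7: temporal stability ---------------------------------------
    temporal_summary: dict[str, dict] = {}
    temp_seeds = seeds["temporal"].spawn(len(SITES) * len(SIDES))
    for idx, (site, side) in enumerate([(a, b) for a in SITES for b in SIDES]):
        ids = metadata.index[
            (metadata["site"] == site) & (metadata["side"] == side)
        ]
        ids = [i for i in ids if i in table.counts.index]
        sub_md = metadata.loc[ids]
        repeats = sub_md.groupby("subject").size()
        if (repeats >= 2).sum() < 2:
            continue
        dm = beta_mod.distance_matrix(
            table.select_samples(ids), bundle.tree, metric="unweighted"
        )
        res = community_mod.temporal_stability_test(
            dm, metadata, n_perm=config.n_permutations, seed=temp_seeds[idx]
        )
        temporal_summary[f"{site}|{side}"] = res.asdict()
    summary["temporal"] = temporal_summary

    report = RunReport(
        config=config.asdict(),
        design_seed=design.seed if design is not None else None,
        output_dir=out.name,
        stage_outputs=stage_outputs,
        summary=summary,
    )
    report.to_json(out / "report.json")
    with open(out / "summary.txt", "w") as fh:
        fh.write(report.summary_text())
    return report
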