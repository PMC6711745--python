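"""The two reproducible arms of the analysis.

* The **image arm** simulates (or loads) tumor images per genotype, segments
  them, measures per-cell medians, aggregates tumors, fits the mean - 1 SD
  negativity threshold on the reference genotype, classifies quadrant
  positivity, and runs the genotype statistics (chi-squared on the quadrant
  table, rank-sum on tumor summaries).
* The **expression arm** simulates a block-structured count matrix, runs the
  NB Wald differential-expression test, preranked GSEA over the cell-type
  marker sets plus decoy sets, co-expression module detection, and the
  three-factor regulator screen.

Each stage draws its randomness from an independent, documented substream
of the single run seed: ``stage_seed(seed, name)`` hashes the stage name
with CRC-32 and spawns ``SeedSequence([seed, crc32(name)])``, so any stage
can be re-run in isolation bit-identically.
"""

from __future__ import annotations

import zlib
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import de as de_mod
from . import io as io_mod
from . import plots as plots_mod
from . import screen as screen_mod
from . import stats as stats_mod
from .enrichment import GeneSet, RankedList, build_marker_sets, gsea_collection
from .imaging import measure_cells, segment_image
from .simulate import ExprSimConfig, ImageSimConfig, generate_expression_matrix, \
    generate_celltype_markers, generate_tumor_image, tf_gene_list

__all__ = [
    "stage_seed",
    "DEFAULT_IMAGE_ARM_CONFIG",
    "DEFAULT_EXPR_ARM_CONFIG",
    "run_image_arm",
    "run_expr_arm",
]


def stage_seed(seed: int, stage: str, index: int = 0) -> np.random.SeedSequence:
    """Deterministic per-stage seed substream (see module docstring)."""
    return np.random.SeedSequence([int(seed), zlib.crc32(stage.encode("utf-8")), int(index)])


def _seed_int(seed: int, stage: str, index: int = 0) -> int:
    return int(stage_seed(seed, stage, index).generate_state(1)[0] % (2**31))


DEFAULT_IMAGE_ARM_CONFIG: dict = {
    "seed": 0,
    "reference_genotype": "control",
    "genotypes": {
        "control": {"marker_loss_fraction": 0.0, "n_tumors": 3},
        "double_mutant": {"marker_loss_fraction": 0.5, "n_tumors": 3},
    },
    "image": {
        "image_height_px": 320,
        "image_width_px": 320,
        "n_cells": 80,
        "nucleus_radius_mean": 6.0,
        "nucleus_radius_sd": 1.0,
        "cytoplasm_width_px": 10.0,
        "inter_channel_rank_correlation": 0.3,
        "background_level": 200.0,
        "gradient_amplitude": 100.0,
        "read_noise_sd": 20.0,
    },
    "segmentation": {
        "seed_channel_role": "nuclear_tf",
        "cell_mode": "propagation",
        "max_distance_px": 10.0,
        "ring_width_px": 3.0,
        "smoothing_sigma": 1.5,
        "min_area_px": 30,
        "max_area_px": 5000,
        "declump": True,
        "declump_min_distance": 5,
        "exclude_border": True,
    },
    "classify": {
        "channel_a": "tf",
        "compartment_a": "nucleus",
        "channel_b": "marker",
        "compartment_b": "cytoplasm",
    },
    "plots": True,
    "write_images": False,
}


def run_image_arm(config: dict, out_dir: str | Path) -> dict:
    """Run the full imaging arm into ``out_dir``; returns the stats report.

    Artifacts: per-tumor label rasters (optional image bundles), the
    per-cell record CSV, tumor summaries, per-cell quadrant classes, the
    genotype x class quadrant table, a stats JSON and the quadrant scatter
    plot, plus the fully resolved config for re-derivation.
    """
    cfg = io_mod.resolve_config(DEFAULT_IMAGE_ARM_CONFIG, config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "resolved_config.yaml").write_text(yaml.safe_dump(cfg, sort_keys=True))
    seed = int(cfg["seed"])

    # --- simulate + segment + measure ------------------------------------
    all_records = []
    tumor_index = 0
    for geno in sorted(cfg["genotypes"]):
        gcfg = cfg["genotypes"][geno]
        for t in range(int(gcfg["n_tumors"])):
            tumor_index += 1
            sim = ImageSimConfig(
                genotype_label=geno,
                tumor_id=f"{geno}_T{t + 1}",
                marker_loss_fraction=float(gcfg["marker_loss_fraction"]),
                rng_seed=_seed_int(seed, "simulate_images", tumor_index),
                **cfg["image"],
            )
            image, truth = generate_tumor_image(sim)
            try:
                seg = segment_image(image, **cfg["segmentation"])
            except Exception as exc:  # noqa: BLE001 - stage-named abort
                raise RuntimeError(f"segmentation failed on tumor {sim.tumor_id}: {exc}") from exc
            io_mod.write_tiff_labels(out / f"labels_{sim.tumor_id}.tif", seg.cell_labels)
            if cfg["write_images"]:
                io_mod.write_image_bundle(out / f"image_{sim.tumor_id}", image, truth)
            all_records.append(measure_cells(image, seg))
    records = pd.concat(all_records, ignore_index=True)
    records.to_csv(out / "cell_records.csv", index=False)

    # --- statistics -------------------------------------------------------
    summaries = stats_mod.aggregate_tumors(records)
    summaries.to_csv(out / "tumor_summaries.csv", index=False)

    cls = cfg["classify"]
    ref = cfg["reference_genotype"]
    rule_a = stats_mod.fit_threshold(records, cls["channel_a"], cls["compartment_a"], ref)
    rule_b = stats_mod.fit_threshold(records, cls["channel_b"], cls["compartment_b"], ref)
    labeled, table, exclusions = stats_mod.classify_quadrants(records, rule_a, rule_b)
    labeled.to_csv(out / "cell_classes.csv", index=False)
    table.to_csv(out / "quadrant_table.csv")

    chi2, dof, chi2_p = stats_mod.chi_squared_genotype(table)
    report: dict = {
        "seed": seed,
        "n_cells": int(len(records)),
        "n_tumors": int(len(summaries)),
        "thresholds": {
            "A": {"channel": rule_a.channel, "compartment": rule_a.compartment, "cutoff": rule_a.cutoff},
            "B": {"channel": rule_b.channel, "compartment": rule_b.compartment, "cutoff": rule_b.cutoff},
        },
        "exclusions": exclusions,
        "chi_squared": {"statistic": chi2, "df": dof, "p": chi2_p},
        "quadrant_table": {str(g): table.loc[g].to_dict() for g in table.index},
    }
    genos = sorted(cfg["genotypes"])
    if len(genos) == 2:
        w, p = stats_mod.tumor_wilcoxon(
            summaries, genos[0], genos[1], cls["channel_b"], cls["compartment_b"]
        )
        report["wilcoxon_marker"] = {"groups": genos, "U": w, "p": p}
        w2, p2 = stats_mod.tumor_wilcoxon(
            summaries, genos[0], genos[1], cls["channel_a"], cls["compartment_a"]
        )
        report["wilcoxon_tf"] = {"groups": genos, "U": w2, "p": p2}
    rho = stats_mod.spearman_by_genotype(
        records, cls["channel_a"], cls["compartment_a"], cls["channel_b"], cls["compartment_b"]
    )
    report["spearman"] = rho.to_dict(orient="records")

    io_mod.write_report_json(out / "stats.json", report)
    if cfg["plots"]:
        plots_mod.quadrant_scatter(records, rule_a, rule_b, out / "quadrant_scatter.png")
    return report


DEFAULT_EXPR_ARM_CONFIG: dict = {
    "seed": 0,
    "expression": {
        "n_genes": 2000,
        "n_samples_per_group": 8,
        "effect_log2fc": -1.0,
        "module_latent_sd": 0.28,
        "gene_noise_sd": 0.12,
        "nb_dispersion": 0.01,
        "n_decoy_tfs": 50,
    },
    "de": {"dispersion_mode": "trend-shrunk", "shrink_weight": 0.5},
    "gsea": {
        "weight": 1.0,
        "n_perm": 2000,
        "n_random_sets": 10,
        "random_set_size": 100,
        "rank_by": "wald_stat",
    },
    "modules": {
        "min_level": 40.0,
        "beta": 3.0,
        "use_tom": True,
        "cut_height": 0.8,
        "min_module_size": 10,
        "reassign_by_kme": True,
        "kme_min": 0.4,
        "merge_cor": 0.75,
    },
    "screen": {"adjp_cutoff": 0.2},
    "plots": True,
}


def run_expr_arm(config: dict, out_dir: str | Path) -> dict:
    """Run the full expression arm into ``out_dir``; returns the report.

    Artifacts: counts + group labels, DE results, marker-set GMT, GSEA
    results, module assignment, the per-module marker-count table, the
    candidate table of the three-factor screen, a report JSON, and the NES
    bar plot.
    """
    cfg = io_mod.resolve_config(DEFAULT_EXPR_ARM_CONFIG, config)
    if int(cfg["gsea"]["n_perm"]) < 1:
        raise ValueError("gsea.n_perm must be >= 1 (permutation null needs permutations)")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "resolved_config.yaml").write_text(yaml.safe_dump(cfg, sort_keys=True))
    seed = int(cfg["seed"])

    sim = ExprSimConfig(rng_seed=_seed_int(seed, "simulate_expr"), **cfg["expression"])
    counts, groups, truth = generate_expression_matrix(sim)
    profiles = generate_celltype_markers(sim)
    tfs = tf_gene_list(sim)
    counts.to_csv(out / "counts.csv")
    groups.rename_axis("sample_id").reset_index().to_csv(out / "groups.csv", index=False)
    truth.to_csv(out / "truth.csv")
    (out / "tf_list.txt").write_text("\n".join(tfs) + "\n")

    de_res = de_mod.nb_wald_test(counts, groups, **cfg["de"])
    de_res.sort_values("p").to_csv(out / "de_results.csv")

    marker_sets = build_marker_sets(profiles, k=sim.marker_set_size)
    io_mod.write_gmt(out / "marker_sets.gmt", marker_sets)
    rng = np.random.default_rng(stage_seed(seed, "random_sets"))
    decoy_sets = {}
    for i in range(int(cfg["gsea"]["n_random_sets"])):
        members = rng.choice(counts.index.to_numpy(), int(cfg["gsea"]["random_set_size"]), replace=False)
        decoy_sets[f"random_{i + 1}"] = GeneSet(f"random_{i + 1}", frozenset(members), "decoy")
    all_sets = {**marker_sets, **decoy_sets}

    ranked = RankedList.from_series(de_res[cfg["gsea"]["rank_by"]])
    enr = gsea_collection(
        ranked,
        all_sets,
        weight=float(cfg["gsea"]["weight"]),
        n_perm=int(cfg["gsea"]["n_perm"]),
        rng_seed=_seed_int(seed, "gsea"),
    )
    enr.rename_axis("gene_set").to_csv(out / "enrichment_results.csv")

    norm = counts / de_mod.size_factors(counts)
    expressed = screen_mod.filter_expressed(norm, float(cfg["modules"]["min_level"]))
    assignment = screen_mod.coexpression_modules(
        expressed,
        beta=float(cfg["modules"]["beta"]),
        use_tom=bool(cfg["modules"]["use_tom"]),
        cut_height=float(cfg["modules"]["cut_height"]),
        min_module_size=int(cfg["modules"]["min_module_size"]),
        reassign_by_kme=bool(cfg["modules"]["reassign_by_kme"]),
        kme_min=float(cfg["modules"]["kme_min"]),
        merge_cor=float(cfg["modules"]["merge_cor"]),
        groups=groups,
    )
    assignment.modules.rename_axis("gene_id").reset_index().to_csv(
        out / "module_assignment.csv", index=False
    )
    at_sets = {
        name: marker_sets[name].members for name in list(marker_sets)[:2]  # AT2-like, AT1-like
    }
    marker_module, counts_table = screen_mod.select_marker_module(assignment, at_sets)
    counts_table.to_csv(out / "module_marker_counts.csv")

    candidates = screen_mod.three_factor_screen(
        assignment, marker_module, tfs, de_res, float(cfg["screen"]["adjp_cutoff"])
    )
    candidates.to_csv(out / "candidate_table.csv")

    passing = candidates.index[candidates["passes_all"]].tolist()
    report = {
        "seed": seed,
        "n_genes": int(counts.shape[0]),
        "n_samples": int(counts.shape[1]),
        "n_expressed": int(expressed.shape[0]),
        "n_modules": int(assignment.module_stats.shape[0]),
        "marker_module": int(marker_module),
        "marker_module_size": int(counts_table.loc[marker_module, "size"]),
        "candidates": passing,
        "planted_regulator": sim.planted_regulator_gene,
        "regulator_recovered": sim.planted_regulator_gene in passing,
        "enrichment": {
            name: {"nes": float(enr.loc[name, "nes"]), "adjp": float(enr.loc[name, "adjp"])}
            for name in marker_sets
        },
    }
    io_mod.write_report_json(out / "report.json", report)
    if cfg["plots"]:
        plots_mod.nes_barplot(enr, out / "nes_barplot.png")
    return report
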