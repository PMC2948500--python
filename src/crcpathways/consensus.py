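"""Consensus assembly and the end-to-end pipeline.

The pipeline mirrors a multidirectional microarray analysis of the
colorectal adenoma-carcinoma sequence:

1. two normalization arms (global trimmed-mean scaling; least-variant-set);
2. per-arm detection and fold-change filtering;
3. per contrast, two probe orderings — supervised (permutation-t adjusted
   p-values) and unsupervised (absolute loading on the first SVD mode, with
   advisory flagging of low-separation tumor samples);
4. one-sided KS rank enrichment of every pathway in every
   (normalization, ordering) cell;
5. the dual-normalization significance rule applied per ordering, then
   intersection across orderings (the consensus set per contrast);
6. subtraction of the epithelium-versus-mucosa background — pathways
   significant in at least 3 of the 4 microdissected epithelium/mucosa
   comparisons (NC, NT, AD, CA);
7. monotone progression-marker selection across three sample arms (whole
   sections, microdissected epithelium, microdissected mucosa) and both
   normalizations.

Inputs are synthetic experiments from :mod:`crcpathways.syndata`, so every
reported set can be scored against ground truth.
"""

from __future__ import annotations

import dataclasses
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from . import diffexpr, ksenrich, normalize, qcfilter, svdmode, syndata
from .io import (
    write_expression_tsv,
    write_gmt,
    write_json,
    write_probe_annotation,
    write_sample_annotation,
)
from .syndata import PlantedPathway, SimulationDesign

__all__ = [
    "ConsensusReport",
    "default_config",
    "null_config",
    "load_config",
    "epithelium_mucosa_background",
    "consensus_pathways",
    "subtract_background",
    "normalize_arm",
    "filter_arm",
    "log2_matrix",
    "contrast_rankings",
    "run_pipeline",
]

log = logging.getLogger("crcpathways")

NORM_ARMS = ("scaling", "lvs")
ORDERINGS = ("pairwise", "svd")


@dataclass
class ConsensusReport:
    """Everything the pipeline decided, with full per-cell traceability."""

    background: list[str]
    background_per_comparison: dict[str, list[str]]
    consensus_by_contrast: dict[str, list[str]]
    final_by_contrast: dict[str, list[str]]
    progression_up: list[str]
    progression_down: list[str]
    grid: dict[str, dict[str, dict[str, pd.DataFrame]]]
    background_grid: dict[str, dict[str, pd.DataFrame]]
    flagged_samples: dict[str, dict[str, list[str]]]
    filter_counts: dict[str, dict[str, int]]
    parameters: dict
    truth: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        def grid_records(g):
            return {
                k: {
                    a: {o: df.reset_index().to_dict("records") for o, df in per.items()}
                    for a, per in arms.items()
                }
                for k, arms in g.items()
            }

        return {
            "background": self.background,
            "background_per_comparison": self.background_per_comparison,
            "consensus_by_contrast": self.consensus_by_contrast,
            "final_by_contrast": self.final_by_contrast,
            "progression_up": self.progression_up,
            "progression_down": self.progression_down,
            "grid": grid_records(self.grid),
            "background_grid": {
                c: {a: df.reset_index().to_dict("records") for a, df in arms.items()}
                for c, arms in self.background_grid.items()
            },
            "flagged_samples": self.flagged_samples,
            "filter_counts": self.filter_counts,
            "parameters": self.parameters,
            "truth": self.truth,
        }


# ---------------------------------------------------------------------------
# configuration

def _base_config(seed: int) -> dict:
    return {
        "seed": int(seed),
        # deep enough that the permutation-p floor, after FDR adjustment over
        # ~5,000 probes, stays clear of the 0.01 marker threshold
        "n_perm": 20_000,
        "marker_alpha": 0.01,
        "ks": {"strict_alpha": 0.01, "lenient_alpha": 0.05, "min_size": 5, "method": "auto"},
        "filter": {
            "percentile": 98.0,
            "min_fraction": 0.05,
            "fc": 1.5,
            "fc_min_samples": 6,
            # Y-linked probes anchor the detection threshold but are removed
            # from the analysis universe afterwards: in a mixed-sex cohort
            # their bimodal male/female signal would otherwise dominate the
            # unsupervised variability modes.
            "drop_y_probes": True,
        },
        "normalize": {"trim": 0.02, "target": 500.0, "lvs_proportion": 0.6},
        "svd": {"center": True, "log2": True, "mode": 1},
        "discard_flagged": True,
        # tumor specimens below this histological malignant-content percent
        # are excluded from whole-tissue pairwise comparisons
        "min_tumor_content": 35.0,
        "background_min_support": 3,
        "background_stages": ["NC", "NT", "AD", "CA"],
        "contrasts": {
            "NC_vs_neoplasm": (["NC"], ["AD", "CA"]),
            "AD_vs_CA": (["AD"], ["CA"]),
        },
        "out_dir": None,
    }


def _micro_groups(n_per_cell: int, stages) -> dict[str, int]:
    return {f"{t}_{s}": n_per_cell for s in stages for t in ("CEC", "MUC")}


def _micro_epithelium(stages) -> dict[str, tuple[float, float]]:
    out = {}
    # microdissection yields tightly controlled composition: ~95% pure
    # epithelium captures and ~25%-epithelium mucosa with small spread
    for s in stages:
        out[f"CEC_{s}"] = (80.0, 4.0)
        out[f"MUC_{s}"] = (16.0, 48.0)
    return out


def _micro_effect_map(stages) -> dict[str, str]:
    out = {}
    for s in stages:
        eg = "NC" if s == "NT" else s
        out[f"CEC_{s}"] = eg
        out[f"MUC_{s}"] = eg
    return out


def default_config(
    seed: int = 0,
    n_probes: int = 5000,
    n_samples_whole: int = 20,
    n_samples_micro: int = 15,
) -> dict:
    """The standard synthetic study: 5,000 probes, 20 whole-tissue samples
    per disease group, 15 microdissected samples per tissue/stage cell, three
    planted pathways per disease contrast, two epithelium-confound pathways,
    10+10 monotone progression markers.  Probe count can be shrunk for quick
    runs."""
    cfg = _base_config(seed)
    n_whole = n_samples_whole
    n_micro = n_samples_micro
    planted = tuple(
        [PlantedPathway(f"PW{i:03d}", "NC_vs_AD+CA", 1.0) for i in (1, 2, 3)]
        + [PlantedPathway(f"PW{i:03d}", "AD_vs_CA", 1.0) for i in (4, 5, 6)]
        + [PlantedPathway(f"PW{i:03d}", "epithelium", 1.5) for i in (7, 8)]
    )
    stages = cfg["background_stages"]
    whole = SimulationDesign(
        n_probes=n_probes,
        n_samples_per_group={"NC": n_whole, "AD": n_whole, "CA": n_whole},
        # KEGG-like flat categories, non-overlapping by default so planted
        # effects stay attributable to single pathways; count scales with the
        # universe so the disjoint pool suffices
        n_pathways=min(100, max(10, n_probes // 50)),
        pathway_size_range=(10, 40),
        planted_pathways=planted,
        n_monotone_up=10,
        n_monotone_down=10,
        monotone_step=1.0,
        epithelium_fraction_by_group={"NC": (14, 6), "AD": (10, 10), "CA": (9, 11)},
        handling_arm="whole",
        seed=seed,
    )
    micro = dataclasses.replace(
        whole,
        n_samples_per_group=_micro_groups(n_micro, stages),
        epithelium_fraction_by_group=_micro_epithelium(stages),
        group_effect_map=_micro_effect_map(stages),
        scale_effects_by_purity=False,
        handling_arm="microdissected",
        seed=seed + 1,
    )
    cfg["designs"] = {"whole": whole, "micro": micro}
    return cfg


def null_config(seed: int = 0, **sizes) -> dict:
    """Zero-effect variant of :func:`default_config`: no planted pathways, no
    monotone markers, no cell-type mixture axis, identical epithelium
    distributions across disease groups."""
    cfg = default_config(seed, **sizes)
    whole = dataclasses.replace(
        cfg["designs"]["whole"],
        planted_pathways=(),
        n_monotone_up=0,
        n_monotone_down=0,
        monotone_up_ids=(),
        monotone_down_ids=(),
        epithelium_affinity_sd=0.0,
        epithelium_fraction_by_group={"NC": (10, 10), "AD": (10, 10), "CA": (10, 10)},
    )
    stages = cfg["background_stages"]
    micro = dataclasses.replace(
        whole,
        n_samples_per_group=cfg["designs"]["micro"].n_samples_per_group,
        epithelium_fraction_by_group={
            g: (10, 10) for g in cfg["designs"]["micro"].n_samples_per_group
        },
        group_effect_map=_micro_effect_map(stages),
        handling_arm="microdissected",
        seed=cfg["seed"] + 1,
    )
    cfg["designs"] = {"whole": whole, "micro": micro}
    return cfg


def load_config(path: str | Path) -> dict:
    """Load a YAML/JSON pipeline config; design blocks become SimulationDesign."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    cfg = _base_config(raw.get("seed", 0))
    for key, value in raw.items():
        if key == "designs":
            continue
        if isinstance(value, dict) and key in cfg and isinstance(cfg[key], dict):
            cfg[key].update(value)
        else:
            cfg[key] = value
    designs = {}
    for name, block in raw.get("designs", {}).items():
        planted = tuple(
            PlantedPathway(p["pathway_id"], p["contrast"], float(p["log2_effect"]))
            for p in block.pop("planted_pathways", [])
        )
        block["epithelium_fraction_by_group"] = {
            g: tuple(ab) for g, ab in block.get("epithelium_fraction_by_group", {}).items()
        } or SimulationDesign().epithelium_fraction_by_group
        designs[name] = SimulationDesign(planted_pathways=planted, **block)
    if designs:
        cfg["designs"] = designs
    return cfg


# ---------------------------------------------------------------------------
# consensus operations

def epithelium_mucosa_background(
    per_comparison_sets: Mapping[str, set[str]], min_support: int = 3
) -> set[str]:
    """Pathways significant in at least ``min_support`` of the
    epithelium-versus-mucosa comparisons."""
    if len(per_comparison_sets) < min_support:
        raise ValueError(
            f"{len(per_comparison_sets)} comparisons cannot reach support {min_support}"
        )
    counts: dict[str, int] = {}
    for s in per_comparison_sets.values():
        for pw in s:
            counts[pw] = counts.get(pw, 0) + 1
    return {pw for pw, c in counts.items() if c >= min_support}


def consensus_pathways(
    grid: Mapping[str, Mapping[str, Mapping[str, pd.DataFrame]]],
    contrast: str,
    strict_alpha: float = 0.01,
    lenient_alpha: float = 0.05,
) -> set[str]:
    """Apply the significance rule to a complete 2x2
    (normalization x ordering) grid cell set for one contrast."""
    if contrast not in grid:
        raise ValueError(f"contrast {contrast!r} absent from grid")
    arms = grid[contrast]
    orderings = {o for per in arms.values() for o in per}
    for arm, per in arms.items():
        if set(per) != orderings:
            raise ValueError(f"incomplete grid for contrast {contrast!r}, arm {arm!r}")
    return ksenrich.significant_pathways(arms, strict_alpha, lenient_alpha)


def subtract_background(consensus: set[str], background: set[str]) -> list[str]:
    """Order-stable set difference (sorted by pathway id)."""
    return sorted(set(consensus) - set(background))


# ---------------------------------------------------------------------------
# pipeline stages

def _seed_for(base_seed: int, tag: str) -> int:
    return (int(base_seed) + zlib.crc32(tag.encode())) % (2**31)


def normalize_arm(raw: pd.DataFrame, arm: str, cfg: dict) -> pd.DataFrame:
    ncfg = cfg["normalize"]
    if arm == "scaling":
        return normalize.global_scaling_normalize(raw, ncfg["trim"], ncfg["target"])
    if arm == "lvs":
        lvs = normalize.select_least_variant_set(raw, ncfg["lvs_proportion"])
        return normalize.lvs_normalize(raw, lvs)
    raise ValueError(f"unknown normalization arm {arm!r}")


def filter_arm(
    normalized: pd.DataFrame,
    probe_annot: pd.DataFrame,
    sample_annot: pd.DataFrame,
    cfg: dict,
    apply_fc: bool,
) -> tuple[pd.DataFrame, dict[str, int]]:
    fcfg = cfg["filter"]
    y_probes = probe_annot.index[probe_annot["is_chrY"] == 1]
    females = sample_annot.index[sample_annot["sex"] == "F"]
    threshold = qcfilter.compute_detection_threshold(
        normalized, y_probes, females, fcfg["percentile"]
    )
    expressed = qcfilter.filter_expressed(normalized, threshold, fcfg["min_fraction"])
    counts = {"input": normalized.shape[0], "expressed": expressed.shape[0]}
    if apply_fc:
        expressed = qcfilter.filter_fold_change(
            expressed, fcfg["fc"], fcfg["fc_min_samples"]
        )
        counts["fold_change"] = expressed.shape[0]
    if fcfg.get("drop_y_probes", True):
        expressed = expressed.loc[
            expressed.index.map(lambda p: probe_annot.loc[p, "is_chrY"] == 0)
        ]
        counts["autosomal"] = expressed.shape[0]
    log.info("filtering: %s", counts)
    return expressed, counts


def log2_matrix(m: pd.DataFrame) -> pd.DataFrame:
    return pd.DataFrame(
        np.log2(m.to_numpy(dtype=float) + 1.0), index=m.index, columns=m.columns
    )


def contrast_rankings(
    log2m: pd.DataFrame,
    labels: pd.Series,
    case_label: str,
    cfg: dict,
    seed_tag: str,
) -> tuple[dict[str, object], list[str]]:
    """Supervised and unsupervised orderings for one two-group contrast."""
    scfg = cfg["svd"]
    modes = svdmode.decompose(log2m, center=scfg["center"])
    flagged = svdmode.flag_low_separation_samples(
        modes, scfg["mode"], labels, case_group=case_label
    )
    keep = [s for s in log2m.columns if s not in flagged] if cfg["discard_flagged"] else list(log2m.columns)
    stats = diffexpr.permutation_t_test(
        log2m[keep],
        labels.loc[keep],
        n_perm=cfg["n_perm"],
        seed=_seed_for(cfg["seed"], seed_tag),
    )
    return (
        {
            "pairwise": diffexpr.rank_probes_by_p(stats),
            "svd": svdmode.rank_probes_by_mode(modes, scfg["mode"]),
        },
        flagged,
    )


def run_pipeline(config: Mapping) -> ConsensusReport:
    """Execute the full multidirectional analysis on a synthetic study.

    ``config`` comes from :func:`default_config` / :func:`null_config` /
    :func:`load_config`.  Fully deterministic for a fixed config and seed;
    when ``out_dir`` is set all intermediate artifacts are persisted as
    TSV/GMT/JSON.
    """
    cfg = dict(config)
    seed = cfg["seed"]
    kcfg = cfg["ks"]
    whole_design: SimulationDesign = cfg["designs"]["whole"]
    micro_design: SimulationDesign = cfg["designs"]["micro"]

    # --- simulate (shared probe universe and dictionary)
    annot = syndata.probe_annotation(whole_design)
    universe = annot.loc[annot["is_chrY"] == 0, "gene_symbol"].tolist()
    dictionary = cfg.get("dictionary") or syndata.generate_pathway_dictionary(
        whole_design.n_pathways,
        whole_design.pathway_size_range,
        universe,
        overlap_fraction=cfg.get("pathway_overlap_fraction", 0.0),
        seed=seed,
    )
    whole_m, whole_s, whole_truth = syndata.simulate_experiment(whole_design, dictionary)
    if micro_design.monotone_up_ids is None and whole_truth.monotone_up_ids:
        micro_design = dataclasses.replace(
            micro_design,
            monotone_up_ids=tuple(whole_truth.monotone_up_ids),
            monotone_down_ids=tuple(whole_truth.monotone_down_ids),
        )
    micro_m, micro_s, micro_truth = syndata.simulate_experiment(micro_design, dictionary)
    probe_sets = ksenrich.pathway_probe_sets(dictionary, annot)

    # --- normalize + filter per arm
    arm_data: dict[tuple[str, str], pd.DataFrame] = {}
    filter_counts: dict[str, dict[str, int]] = {}
    for ds_name, raw, samples, apply_fc in (
        ("whole", whole_m, whole_s, True),
        ("micro", micro_m, micro_s, False),
    ):
        for arm in NORM_ARMS:
            normalized = normalize_arm(raw, arm, cfg)
            filtered, counts = filter_arm(normalized, annot, samples, cfg, apply_fc)
            arm_data[(ds_name, arm)] = log2_matrix(filtered)
            filter_counts[f"{ds_name}/{arm}"] = counts

    # --- whole-tissue contrasts: 2 orderings x 2 normalizations -> KS grid
    grid: dict[str, dict[str, dict[str, pd.DataFrame]]] = {}
    flagged_samples: dict[str, dict[str, list[str]]] = {}
    for contrast, (base_groups, case_groups) in cfg["contrasts"].items():
        grid[contrast] = {}
        flagged_samples[contrast] = {}
        members = whole_s["group"].isin([*base_groups, *case_groups])
        sample_ids = whole_s.index[members]
        labels = pd.Series(
            np.where(whole_s.loc[sample_ids, "group"].isin(case_groups), "case", "base"),
            index=sample_ids,
        )
        for arm in NORM_ARMS:
            sub = arm_data[("whole", arm)][list(sample_ids)]
            rankings, flagged = contrast_rankings(
                sub, labels, "case", cfg, seed_tag=f"{contrast}|{arm}"
            )
            flagged_samples[contrast][arm] = flagged
            grid[contrast][arm] = {
                ordering: ksenrich.test_all_pathways(
                    ranked, probe_sets, kcfg["min_size"], kcfg["method"]
                )
                for ordering, ranked in rankings.items()
            }

    consensus_by_contrast = {
        contrast: sorted(
            consensus_pathways(grid, contrast, kcfg["strict_alpha"], kcfg["lenient_alpha"])
        )
        for contrast in cfg["contrasts"]
    }

    # --- epithelium-vs-mucosa background from the microdissected comparisons
    background_grid: dict[str, dict[str, pd.DataFrame]] = {}
    per_comparison_sets: dict[str, set[str]] = {}
    for stage in cfg["background_stages"]:
        cells = [f"CEC_{stage}", f"MUC_{stage}"]
        sample_ids = micro_s.index[micro_s["group"].isin(cells)]
        labels = micro_s.loc[sample_ids, "group"].str.split("_").str[0]
        background_grid[stage] = {}
        for arm in NORM_ARMS:
            sub = arm_data[("micro", arm)][list(sample_ids)]
            stats = diffexpr.permutation_t_test(
                sub, labels, n_perm=cfg["n_perm"],
                seed=_seed_for(seed, f"background|{stage}|{arm}"),
            )
            ranked = diffexpr.rank_probes_by_p(stats)
            background_grid[stage][arm] = ksenrich.test_all_pathways(
                ranked, probe_sets, kcfg["min_size"], kcfg["method"]
            )
        per_comparison_sets[stage] = ksenrich.significant_pathways(
            {arm: {"pairwise": background_grid[stage][arm]} for arm in NORM_ARMS},
            kcfg["strict_alpha"],
            kcfg["lenient_alpha"],
        )
    background = epithelium_mucosa_background(
        per_comparison_sets, cfg["background_min_support"]
    )

    final_by_contrast = {
        contrast: subtract_background(set(sel), background)
        for contrast, sel in consensus_by_contrast.items()
    }

    # --- progression markers across three sample arms and both normalizations
    order = whole_design.monotone_group_order
    adjacent = [(order[0], order[1]), (order[1], order[2])]
    stats_by_arm: dict[tuple[str, str], dict[str, pd.DataFrame]] = {}
    for arm in NORM_ARMS:
        arm_samples = {
            "whole": (whole_s, arm_data[("whole", arm)], whole_s["group"]),
            "CEC": (
                micro_s,
                arm_data[("micro", arm)],
                micro_s["group"].str.split("_").str[1],
            ),
            "MUC": (
                micro_s,
                arm_data[("micro", arm)],
                micro_s["group"].str.split("_").str[1],
            ),
        }
        for ds_name, (samples, log2m, stage_of) in arm_samples.items():
            if ds_name in ("CEC", "MUC"):
                tissue = samples["group"].str.split("_").str[0]
                usable = samples.index[(tissue == ds_name) & stage_of.isin(order)]
            else:
                # histology rule: tumor specimens with low malignant-cell
                # content carry attenuated tumor expression programs and are
                # excluded from the whole-tissue pairwise comparisons
                enough_tumor = (stage_of == order[0]) | (
                    samples["tumor_content_percent"] >= cfg["min_tumor_content"]
                )
                usable = samples.index[stage_of.isin(order) & enough_tumor]
            contrasts = {}
            for g_low, g_high in adjacent:
                ids = [s for s in usable if stage_of[s] in (g_low, g_high)]
                contrasts[f"{g_low}_vs_{g_high}"] = diffexpr.permutation_t_test(
                    log2m[ids],
                    stage_of[ids],
                    n_perm=cfg["n_perm"],
                    seed=_seed_for(seed, f"markers|{ds_name}|{arm}|{g_low}|{g_high}"),
                )
            stats_by_arm[(ds_name, arm)] = contrasts
    progression_up, progression_down = diffexpr.select_progression_markers(
        stats_by_arm, cfg["marker_alpha"], order
    )

    report = ConsensusReport(
        background=sorted(background),
        background_per_comparison={k: sorted(v) for k, v in per_comparison_sets.items()},
        consensus_by_contrast=consensus_by_contrast,
        final_by_contrast=final_by_contrast,
        progression_up=progression_up,
        progression_down=progression_down,
        grid=grid,
        background_grid=background_grid,
        flagged_samples=flagged_samples,
        filter_counts=filter_counts,
        parameters={
            "seed": seed,
            "n_perm": cfg["n_perm"],
            "marker_alpha": cfg["marker_alpha"],
            "ks": dict(kcfg),
            "filter": dict(cfg["filter"]),
            "normalize": dict(cfg["normalize"]),
            "svd": dict(cfg["svd"]),
            "discard_flagged": cfg["discard_flagged"],
            "background_min_support": cfg["background_min_support"],
        },
        truth={
            "whole": whole_truth.to_dict(),
            "micro": micro_truth.to_dict(),
        },
    )
    if cfg.get("out_dir"):
        _persist(
            Path(cfg["out_dir"]), report, dictionary, annot,
            {"whole": (whole_m, whole_s), "micro": (micro_m, micro_s)},
        )
    return report


def _indicator_table(sets_by_comparison: Mapping[str, set[str]]) -> pd.DataFrame:
    """Table-style +/- indicator matrix over the union of reported pathways."""
    universe = sorted(set().union(*sets_by_comparison.values())) if sets_by_comparison else []
    data = {
        comp: ["+" if pw in hits else "-" for pw in universe]
        for comp, hits in sets_by_comparison.items()
    }
    return pd.DataFrame(data, index=pd.Index(universe, name="pathway"))


def _persist(out_dir, report, dictionary, annot, datasets) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    write_gmt(dictionary, out_dir / "pathways.gmt")
    write_probe_annotation(annot, out_dir / "probe_annotation.tsv")
    for name, (m, s) in datasets.items():
        write_expression_tsv(m, out_dir / f"{name}_expression.tsv")
        write_sample_annotation(s, out_dir / f"{name}_samples.tsv")
    for contrast, arms in report.grid.items():
        for arm, per in arms.items():
            for ordering, df in per.items():
                df.to_csv(out_dir / f"ks_{contrast}_{arm}_{ordering}.tsv", sep="\t")
    for stage, arms in report.background_grid.items():
        for arm, df in arms.items():
            df.to_csv(out_dir / f"ks_background_{stage}_{arm}.tsv", sep="\t")
    _indicator_table(
        {k: set(v) for k, v in report.background_per_comparison.items()}
    ).to_csv(out_dir / "background_indicator.tsv", sep="\t")
    write_json(report.to_dict(), out_dir / "report.json")
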