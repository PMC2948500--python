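#!/usr/bin/env python
"""Assemble the consensus pathway sets and subtract the cell-type background.

Per contrast: applies the dual-normalization significance rule to both
orderings from results/enrichment/ and intersects.  The epithelium-vs-mucosa
background is derived from the microdissected CEC-vs-MUC comparisons (one
ranking per stage and arm, KS-tested, rule applied, support >= 3 of 4) and
subtracted.  Writes the final sets, the per-comparison indicator matrix and a
ground-truth scorecard under results/consensus/.
"""

from pathlib import Path

import pandas as pd

from crcpathways import consensus, diffexpr, io, ksenrich

BASE = Path(__file__).resolve().parent.parent / "results"
SEED = 1
PLANTED = {
    "NC_vs_neoplasm": {"PW001", "PW002", "PW003"},
    "AD_vs_CA": {"PW004", "PW005", "PW006"},
}
CONFOUNDS = {"PW007", "PW008"}


def main() -> None:
    out = BASE / "consensus"
    out.mkdir(parents=True, exist_ok=True)
    cfg = consensus.default_config(seed=SEED)
    kcfg = cfg["ks"]
    dictionary = io.read_gmt(BASE / "synthetic" / "pathways.gmt")
    annot = io.read_probe_annotation(BASE / "synthetic" / "probe_annotation.tsv")
    probe_sets = ksenrich.pathway_probe_sets(dictionary, annot)

    # whole-tissue grid from persisted enrichment tables
    grid = {}
    for contrast in cfg["contrasts"]:
        grid[contrast] = {
            arm: {
                ordering: pd.read_csv(
                    BASE / "enrichment" / f"{contrast}_{arm}_{ordering}.tsv",
                    sep="\t",
                    index_col="pathway",
                )
                for ordering in consensus.ORDERINGS
            }
            for arm in consensus.NORM_ARMS
        }
    consensus_sets = {
        c: consensus.consensus_pathways(grid, c, kcfg["strict_alpha"], kcfg["lenient_alpha"])
        for c in cfg["contrasts"]
    }

    # epithelium-vs-mucosa background from the microdissected comparisons
    micro_s = io.read_sample_annotation(BASE / "synthetic" / "micro_samples.tsv")
    per_comparison = {}
    for stage in cfg["background_stages"]:
        cells = [f"CEC_{stage}", f"MUC_{stage}"]
        ids = micro_s.index[micro_s["group"].isin(cells)]
        labels = micro_s.loc[ids, "group"].str.split("_").str[0]
        by_arm = {}
        for arm in consensus.NORM_ARMS:
            log2m = io.read_expression_tsv(BASE / "normalized" / f"micro_{arm}_log2.tsv")
            stats = diffexpr.permutation_t_test(
                log2m[list(ids)], labels, n_perm=cfg["n_perm"],
                seed=consensus._seed_for(SEED, f"background|{stage}|{arm}"),
            )
            ranked = diffexpr.rank_probes_by_p(stats)
            by_arm[arm] = {"pairwise": ksenrich.test_all_pathways(
                ranked, probe_sets, kcfg["min_size"], kcfg["method"]
            )}
        per_comparison[stage] = ksenrich.significant_pathways(
            by_arm, kcfg["strict_alpha"], kcfg["lenient_alpha"]
        )
        print(f"CEC vs MUC in {stage}: {sorted(per_comparison[stage])}")

    background = consensus.epithelium_mucosa_background(
        per_comparison, cfg["background_min_support"]
    )
    final = {
        c: consensus.subtract_background(s, background) for c, s in consensus_sets.items()
    }

    consensus._indicator_table(per_comparison).to_csv(
        out / "background_indicator.tsv", sep="\t"
    )
    io.write_json(
        {
            "background": sorted(background),
            "consensus_by_contrast": {c: sorted(s) for c, s in consensus_sets.items()},
            "final_by_contrast": final,
        },
        out / "consensus_sets.json",
    )

    print(f"\nbackground (>= {cfg['background_min_support']} of 4): {sorted(background)}")
    for c in cfg["contrasts"]:
        planted, fin = PLANTED[c], set(final[c])
        print(f"{c}: final={final[c]}  planted recovered "
              f"{len(planted & fin)}/{len(planted)}, confounds excluded "
              f"{len(CONFOUNDS - fin)}/{len(CONFOUNDS)}")


if __name__ == "__main__":
    main()
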