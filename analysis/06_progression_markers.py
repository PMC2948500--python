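#!/usr/bin/env python
"""Select monotone progression markers across all three sample arms.

For whole sections, microdissected epithelium (CEC) and microdissected
mucosa (MUC), under both normalizations, tests the adjacent contrasts
NC vs AD and AD vs CA and keeps probes whose means increase (or decrease)
strictly at both steps with FDR-adjusted p < 0.01 everywhere.  Whole-tissue
tumor samples under 35% malignant content are excluded.  Writes the marker
table and a ground-truth scorecard under results/markers/.
"""

from pathlib import Path

import pandas as pd

from crcpathways import consensus, diffexpr, io

BASE = Path(__file__).resolve().parent.parent / "results"
SEED = 1


def main() -> None:
    out = BASE / "markers"
    out.mkdir(parents=True, exist_ok=True)
    cfg = consensus.default_config(seed=SEED)
    whole_s = io.read_sample_annotation(BASE / "synthetic" / "whole_samples.tsv")
    micro_s = io.read_sample_annotation(BASE / "synthetic" / "micro_samples.tsv")
    order = ("NC", "AD", "CA")

    stats_by_arm = {}
    for arm in consensus.NORM_ARMS:
        whole_m = io.read_expression_tsv(BASE / "normalized" / f"whole_{arm}_log2.tsv")
        micro_m = io.read_expression_tsv(BASE / "normalized" / f"micro_{arm}_log2.tsv")
        stage_micro = micro_s["group"].str.split("_").str[1]
        tissue_micro = micro_s["group"].str.split("_").str[0]
        arm_datasets = {
            "whole": (whole_m, whole_s["group"], whole_s),
            "CEC": (micro_m, stage_micro[tissue_micro == "CEC"], None),
            "MUC": (micro_m, stage_micro[tissue_micro == "MUC"], None),
        }
        for ds, (log2m, stage_of, annot) in arm_datasets.items():
            contrasts = {}
            for g_low, g_high in ((order[0], order[1]), (order[1], order[2])):
                ids = [s for s in stage_of.index if stage_of[s] in (g_low, g_high)]
                if annot is not None:
                    ids = [
                        s
                        for s in ids
                        if stage_of[s] == order[0]
                        or annot.loc[s, "tumor_content_percent"]
                        >= cfg["min_tumor_content"]
                    ]
                contrasts[f"{g_low}_vs_{g_high}"] = diffexpr.permutation_t_test(
                    log2m[ids], stage_of[ids], n_perm=cfg["n_perm"],
                    seed=consensus._seed_for(SEED, f"markers|{ds}|{arm}|{g_low}|{g_high}"),
                )
            stats_by_arm[(ds, arm)] = contrasts

    up, down = diffexpr.select_progression_markers(
        stats_by_arm, cfg["marker_alpha"], order
    )
    pd.DataFrame(
        {"probe_id": up + down, "direction": ["up"] * len(up) + ["down"] * len(down)}
    ).to_csv(out / "progression_markers.tsv", sep="\t", index=False)

    truth = io.read_json(BASE / "synthetic" / "ground_truth.json")["whole"]
    up_truth, down_truth = set(truth["monotone_up_ids"]), set(truth["monotone_down_ids"])
    recovered = len(set(up) & up_truth) + len(set(down) & down_truth)
    false_pos = len(set(up) - up_truth) + len(set(down) - down_truth)
    print(f"markers: {len(up)} up, {len(down)} down")
    print(f"recovered {recovered}/{len(up_truth) + len(down_truth)} planted markers, "
          f"{false_pos} false positives")


if __name__ == "__main__":
    main()
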