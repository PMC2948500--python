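#!/usr/bin/env python
"""Generate the synthetic study: whole-tissue and microdissected experiments.

Writes the expression matrices, sample/probe annotation, pathway dictionary
(GMT) and ground truth under results/synthetic/.
"""

import dataclasses
from pathlib import Path

from crcpathways import consensus, io, syndata

OUT = Path(__file__).resolve().parent.parent / "results" / "synthetic"
SEED = 1


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    cfg = consensus.default_config(seed=SEED)
    whole_design = cfg["designs"]["whole"]

    annot = syndata.probe_annotation(whole_design)
    universe = annot.loc[annot["is_chrY"] == 0, "gene_symbol"].tolist()
    dictionary = syndata.generate_pathway_dictionary(
        whole_design.n_pathways,
        whole_design.pathway_size_range,
        universe,
        overlap_fraction=cfg.get("pathway_overlap_fraction", 0.0),
        seed=SEED,
    )
    whole_m, whole_s, whole_truth = syndata.simulate_experiment(whole_design, dictionary)
    micro_design = dataclasses.replace(
        cfg["designs"]["micro"],
        monotone_up_ids=tuple(whole_truth.monotone_up_ids),
        monotone_down_ids=tuple(whole_truth.monotone_down_ids),
    )
    micro_m, micro_s, micro_truth = syndata.simulate_experiment(micro_design, dictionary)

    io.write_gmt(dictionary, OUT / "pathways.gmt")
    io.write_probe_annotation(annot, OUT / "probe_annotation.tsv")
    io.write_expression_tsv(whole_m, OUT / "whole_expression.tsv")
    io.write_sample_annotation(whole_s, OUT / "whole_samples.tsv")
    io.write_expression_tsv(micro_m, OUT / "micro_expression.tsv")
    io.write_sample_annotation(micro_s, OUT / "micro_samples.tsv")
    io.write_json(
        {"whole": whole_truth.to_dict(), "micro": micro_truth.to_dict()},
        OUT / "ground_truth.json",
    )

    summary = syndata.summarize_cell_composition(syndata.reference_composition_table())
    summary.to_csv(OUT / "cell_composition_summary.tsv", sep="\t")

    print(f"whole-tissue matrix: {whole_m.shape[0]} probes x {whole_m.shape[1]} samples")
    print(f"microdissected matrix: {micro_m.shape[0]} probes x {micro_m.shape[1]} samples")
    print(f"pathways: {len(dictionary)} (planted: "
          f"{sum(len(v) for v in whole_truth.planted_pathway_ids.values())})")
    print(f"monotone markers: {len(whole_truth.monotone_up_ids)} up, "
          f"{len(whole_truth.monotone_down_ids)} down")
    print(f"artifacts under {OUT}")


if __name__ == "__main__":
    main()
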