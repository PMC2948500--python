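#!/usr/bin/env python
"""One-sided KS pathway enrichment of every ranking cell.

Reads the per-cell probe rankings from 03_rank_probes.py and the pathway
dictionary, tests every pathway's concentration at the top of each list, and
writes one enrichment TSV per (contrast, arm, ordering) cell under
results/enrichment/.
"""

from pathlib import Path

import pandas as pd

from crcpathways import consensus, io, ksenrich
from crcpathways.ranking import RankedProbeList

BASE = Path(__file__).resolve().parent.parent / "results"
SEED = 1


def main() -> None:
    out = BASE / "enrichment"
    out.mkdir(parents=True, exist_ok=True)
    cfg = consensus.default_config(seed=SEED)
    dictionary = io.read_gmt(BASE / "synthetic" / "pathways.gmt")
    annot = io.read_probe_annotation(BASE / "synthetic" / "probe_annotation.tsv")
    probe_sets = ksenrich.pathway_probe_sets(dictionary, annot)
    kcfg = cfg["ks"]

    for path in sorted((BASE / "rankings").glob("*_*_*.tsv")):
        if path.name == "flagged_samples.tsv":
            continue
        table = pd.read_csv(path, sep="\t")
        ranked = RankedProbeList(
            probe_ids=tuple(table["probe_id"].astype(str)),
            scores=tuple(table["score"].astype(float)),
            provenance=path.stem,
        )
        results = ksenrich.test_all_pathways(
            ranked, probe_sets, kcfg["min_size"], kcfg["method"]
        )
        results.to_csv(out / path.name, sep="\t")
        top = results.head(3)
        print(f"{path.stem}: {len(results)} pathways tested; top: "
              + ", ".join(f"{p} (p_adj={results.loc[p,'p_adj']:.2e})" for p in top.index))


if __name__ == "__main__":
    main()
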