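#!/usr/bin/env python
"""Rank whole-tissue probes per contrast by both criteria.

For each disease contrast (NC vs neoplasm; AD vs CA) and each normalization
arm, computes the supervised ordering (permutation-t adjusted p-values, with
low-separation tumor samples flagged on SVD mode 1 and excluded) and the
unsupervised ordering (absolute mode-1 loading).  Writes one ranking TSV per
(contrast, arm, ordering) cell under results/rankings/.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from crcpathways import consensus, io

BASE = Path(__file__).resolve().parent.parent / "results"
SEED = 1


def main() -> None:
    out = BASE / "rankings"
    out.mkdir(parents=True, exist_ok=True)
    cfg = consensus.default_config(seed=SEED)
    samples = io.read_sample_annotation(BASE / "synthetic" / "whole_samples.tsv")

    flagged_rows = []
    for arm in consensus.NORM_ARMS:
        log2m = io.read_expression_tsv(BASE / "normalized" / f"whole_{arm}_log2.tsv")
        for contrast, (base_groups, case_groups) in cfg["contrasts"].items():
            ids = samples.index[samples["group"].isin([*base_groups, *case_groups])]
            labels = pd.Series(
                np.where(samples.loc[ids, "group"].isin(case_groups), "case", "base"),
                index=ids,
            )
            rankings, flagged = consensus.contrast_rankings(
                log2m[list(ids)], labels, "case", cfg, seed_tag=f"{contrast}|{arm}"
            )
            for ordering, ranked in rankings.items():
                pd.DataFrame(
                    {"probe_id": ranked.probe_ids, "score": ranked.scores}
                ).to_csv(out / f"{contrast}_{arm}_{ordering}.tsv", sep="\t", index=False)
            flagged_rows.append(
                {"contrast": contrast, "arm": arm, "flagged": ";".join(flagged)}
            )
            print(f"{contrast}/{arm}: {len(ids)} samples, "
                  f"{len(flagged)} low-separation tumors flagged ({flagged})")
    pd.DataFrame(flagged_rows).to_csv(out / "flagged_samples.tsv", sep="\t", index=False)


if __name__ == "__main__":
    main()
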