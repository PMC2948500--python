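#!/usr/bin/env python
"""Normalize both arms (trimmed-mean scaling; least-variant-set) and apply
the detection and fold-change filters.

Reads the matrices written by 01_simulate.py and writes the filtered,
normalized log2 matrices plus a filtering-count summary under
results/normalized/.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from crcpathways import consensus, io

BASE = Path(__file__).resolve().parent.parent / "results"
SEED = 1


def main() -> None:
    out = BASE / "normalized"
    out.mkdir(parents=True, exist_ok=True)
    cfg = consensus.default_config(seed=SEED)
    annot = io.read_probe_annotation(BASE / "synthetic" / "probe_annotation.tsv")

    rows = []
    for ds, apply_fc in (("whole", True), ("micro", False)):
        raw = io.read_expression_tsv(BASE / "synthetic" / f"{ds}_expression.tsv")
        samples = io.read_sample_annotation(BASE / "synthetic" / f"{ds}_samples.tsv")
        for arm in consensus.NORM_ARMS:
            normalized = consensus.normalize_arm(raw, arm, cfg)
            filtered, counts = consensus.filter_arm(
                normalized, annot, samples, cfg, apply_fc
            )
            log2 = np.log2(filtered + 1.0)
            io.write_expression_tsv(
                pd.DataFrame(log2, index=filtered.index, columns=filtered.columns),
                out / f"{ds}_{arm}_log2.tsv",
            )
            rows.append({"dataset": ds, "arm": arm, **counts})
            print(f"{ds}/{arm}: {counts}")
    pd.DataFrame(rows).to_csv(out / "filter_counts.tsv", sep="\t", index=False)


if __name__ == "__main__":
    main()
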