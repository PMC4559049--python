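#!/usr/bin/env python
"""Pairwise Lynch-Ritland relatedness over all consolidated
individuals.

Computes the full symmetric relatedness matrix from the autosomal
panel (allele frequencies estimated from all individuals), writes the
matrix and long-format pair table to scratch, and a distribution
summary to results/.
"""

import json
from pathlib import Path

import numpy as np

from snpdispersal import io
from snpdispersal.relatedness import estimated_freq_a, relatedness_matrix

ROOT = Path(__file__).resolve().parents[1]
SCRATCH = ROOT / "scratch" / "pipeline"
RESULTS = ROOT / "results"


def main() -> None:
    panel = io.read_panel(SCRATCH / "panel.csv")
    cons = io.read_genotypes(SCRATCH / "consensus_genotypes.csv")
    calls = cons.calls[:, panel.autosomal_idx]
    freq_a = estimated_freq_a(calls)
    m = relatedness_matrix(calls, cons.group_ids, freq_a)

    np.save(SCRATCH / "relatedness_matrix.npy", m.r)
    m.to_long().to_csv(SCRATCH / "relatedness_pairs.csv", index=False)

    vals = m.to_long()["r"].dropna()
    summary = {
        "n_individuals": len(m.ids),
        "n_pairs": int(len(vals)),
        "mean_r": float(vals.mean()),
        "sd_r": float(vals.std(ddof=1)),
        "min_r": float(vals.min()),
        "max_r": float(vals.max()),
    }
    (RESULTS / "03_relatedness_summary.json").write_text(
        json.dumps(summary, indent=2) + "\n")
    print("relatedness over all sampled individuals:")
    print(json.dumps(summary, indent=2))


if __name__ == "__main__":
    main()
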