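#!/usr/bin/env python
"""Quality control of the replicated fecal genotypes.

Consolidates replicate samples into individuals (majority vote,
contamination screen), estimates the genotyping error and allelic
dropout rates from replicate concordance, calls sex from the Y/X
markers, assigns mtDNA haplotypes, and summarizes the panel (call
rate, MAFs, probability of identity). Writes the consolidated
individual table for downstream steps and a QC report in results/.
"""

import json
from pathlib import Path

import numpy as np

from snpdispersal import io, qc

ROOT = Path(__file__).resolve().parents[1]
SCRATCH = ROOT / "scratch" / "pipeline"
RESULTS = ROOT / "results"


def main() -> None:
    panel = io.read_panel(SCRATCH / "panel.csv")
    table = io.read_genotypes(SCRATCH / "genotypes.csv")
    cons = qc.consolidate_replicates(table, panel)
    ind = qc.build_individuals(cons, panel)
    try:
        err = qc.estimate_error_rates(table, panel)
        err_report = {
            "mismatch_error_rate": err.mismatch_error_rate,
            "allelic_dropout_rate": err.allelic_dropout_rate,
            "n_het_comparisons": err.n_het_comparisons,
            "n_discordant": err.n_discordant,
        }
    except ValueError:
        err_report = None
    summ = qc.panel_summaries(cons.individuals, panel)

    io.write_genotypes(cons.individuals, SCRATCH / "consensus_genotypes.csv")
    ind.to_csv(SCRATCH / "individuals.csv", index=False)

    report = {
        "n_individuals": len(ind),
        "n_contaminated_dropped": len(cons.contaminated),
        "sex_counts": ind["sex"].value_counts().to_dict(),
        "mt_haplotype_counts": ind["mt_haplotype"].value_counts().to_dict(),
        "error_rates": err_report,
        "call_rate": summ.call_rate,
        "mean_autosomal_maf": float(np.nanmean(summ.maf)),
        "probability_of_identity": summ.pid,
    }
    (RESULTS / "02_qc_report.json").write_text(json.dumps(report, indent=2) + "\n")
    print("QC report:")
    print(json.dumps(report, indent=2))


if __name__ == "__main__":
    main()
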