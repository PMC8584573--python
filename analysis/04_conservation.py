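#!/usr/bin/env python
"""Residue conservation: cohort JSD summary and scorer validation.

Summarises the stored JSD conservation scores of the cohort's missense
variants (median ~0.747, i.e., mostly conserved residues), then validates
the in-package JSD scorer on a synthetic 10-species alignment whose true
per-column conservation is dialled from 0 to 1 (Spearman correlation of the
recovered scores with the truth). Writes results/conservation.json.
"""

import json
from pathlib import Path

import numpy as np
from scipy.stats import spearmanr

from pcd_triage import (
    AlignmentSimulationConfig,
    Consequence,
    conservation_profile,
    load_packaged_cohort,
    simulate_alignment,
)

OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    cohort = load_packaged_cohort()
    jsd = np.array([
        r.panel.jsd for r in cohort
        if r.record.consequence is Consequence.MISSENSE and r.panel.jsd is not None
    ])
    conserved = sum(
        1 for r in cohort
        if r.record.consequence is Consequence.MISSENSE and r.panel.conserved
    )

    levels = np.tile([0.0, 0.25, 0.5, 0.75, 1.0], 100)
    aln, truth = simulate_alignment(AlignmentSimulationConfig(
        n_species=10, length=500, conservation=levels, gap_rate=0.1, seed=7))
    profile = conservation_profile(aln, window=0)
    rho = float(spearmanr(truth, profile.jsd).statistic)

    report = {
        "cohort_missense_jsd": {
            "n": int(len(jsd)),
            "mean": round(float(jsd.mean()), 4),
            "sd": round(float(jsd.std(ddof=1)), 4),
            "median": round(float(np.median(jsd)), 4),
            "n_fully_conserved_sites": conserved,
        },
        "synthetic_recovery": {
            "n_columns": 500,
            "n_species": 10,
            "gap_rate": 0.1,
            "spearman_truth_vs_jsd": round(rho, 4),
        },
    }
    OUT.mkdir(exist_ok=True)
    (OUT / "conservation.json").write_text(json.dumps(report, indent=2))
    c = report["cohort_missense_jsd"]
    print(f"missense JSD (n={c['n']}): {c['mean']} +/- {c['sd']} "
          f"(median {c['median']}); {conserved} sites fully conserved")
    print(f"synthetic 10-species recovery: Spearman(truth, JSD) = {rho:.3f}")
    print(f"wrote {OUT / 'conservation.json'}")


if __name__ == "__main__":
    main()
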