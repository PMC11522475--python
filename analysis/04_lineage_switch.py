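#!/usr/bin/env python
"""Paired lineage-switch analysis on a synthetic patient-matched pair.

Simulates a diagnosis/relapse pair sharing 30 oncoprotein sites, with 20
phase-A-only and 20 phase-B-only sites and a reduced oncoprotein level at
relapse, then: calls phase-specific differential target sites, partitions
the B-specific genes against the rest of the cohort's targets (the
non-overlapping half being a GMP-like-style program), and tests the paired
expression matrix with per-gene z-scaling and one-sided Wilcoxon signed-rank
tests. Writes results/04_lineage_switch/.
"""

import sys
from pathlib import Path

import pandas as pd

from nccall import validation
from nccall.model import ModelConfig
from nccall.simulate import SimConfig, simulate_switch_pair
from nccall.switching import (
    differential_target_sites, paired_comparison, partition_specific_genes,
    signature_zscore_compare,
)

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 1
OUT = Path("results/04_lineage_switch")
OUT.mkdir(parents=True, exist_ok=True)


def main() -> None:
    cfg = SimConfig(
        genome=(("chr1", 5_000_000),), n_wt_sites=200, n_onco_sites=0,
        depth=200_000, igg_artifacts=0, seed=SEED,
    )
    sw = simulate_switch_pair(cfg, n_shared=30, n_a_only=20, n_b_only=20,
                              lambda_a=1.0, lambda_b=0.5)
    config = ModelConfig(seed=SEED)
    scores_a = validation._score_planted_sample(sw["sample_a"], config)
    scores_b = validation._score_planted_sample(sw["sample_b"], config)
    pair = paired_comparison(scores_a, scores_b, "phaseA", "phaseB")
    a_spec, b_spec = differential_target_sites(pair)
    a_spec.to_csv(OUT / "phaseA_specific_sites.tsv", sep="\t", index=False)
    b_spec.to_csv(OUT / "phaseB_specific_sites.tsv", sep="\t", index=False)

    planted_a, planted_b = set(sw["a_only_sites"]), set(sw["b_only_sites"])
    sens_a = len(set(a_spec["interval_id"]) & planted_a) / len(planted_a)
    sens_b = len(set(b_spec["interval_id"]) & planted_b) / len(planted_b)

    # partition B-specific genes against all other samples' target genes
    # (here: phase-A targets stand in for the rest of the cohort)
    site_gene = sw["site_gene"].set_index("site_id")["gene"]
    b_genes = [site_gene[s] for s in b_spec["interval_id"] if s in site_gene.index]
    a_genes = [site_gene[s] for s in a_spec["interval_id"] if s in site_gene.index]
    overlapping, gmp_like = partition_specific_genes(b_genes, a_genes)

    wa = signature_zscore_compare(sw["expression"], sw["a_genes"], sw["pairing"],
                                  alternative="greater")
    wb = signature_zscore_compare(sw["expression"], sw["b_genes"], sw["pairing"],
                                  alternative="less")
    wa["sample_scores"].rename("A_program_z").to_csv(OUT / "A_program_sample_z.tsv", sep="\t")
    wb["sample_scores"].rename("B_program_z").to_csv(OUT / "B_program_sample_z.tsv", sep="\t")

    summary = pd.DataFrame(
        [{
            "seed": SEED,
            "a_specific_sites": len(a_spec), "b_specific_sites": len(b_spec),
            "a_recovery": sens_a, "b_recovery": sens_b,
            "b_genes_non_overlapping": len(gmp_like),
            "avg_delta_score": pair["delta"].mean(),
            "wilcoxon_p_A_higher_in_A": wa["p"], "wilcoxon_p_B_higher_in_B": wb["p"],
        }]
    )
    summary.to_csv(OUT / "summary.tsv", sep="\t", index=False)
    print(summary.to_string(index=False))
    print(f"\nRecovered {sens_a:.0%} of planted phase-A-only and {sens_b:.0%} of "
          f"phase-B-only sites; mean score shift A-B = {pair['delta'].mean():.2f} "
          f"(level reduced at relapse). Expression programs move with occupancy "
          f"(one-sided signed-rank p = {wa['p']:.2g} and {wb['p']:.2g}).")


if __name__ == "__main__":
    main()
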