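#!/usr/bin/env python
"""Cofactor signal enrichment over site programs vs an internal control.

A chromatin cofactor that co-binds the oncoprotein leaves elevated fragment
density at bound sites, so the cofactor track is emulated with the
generator's density-inflation mode (4-fold at 50 bound sites). Per-site
signal is length- and depth-normalized (CPM base pairs / site length) and
each program half is tested against the unbound internal control with a
two-sided Mann-Whitney U test (Bonferroni-adjusted). A second check compares
paired-phase expression log2 fold changes of an occupancy program against
control genes. Writes results/05_cofactor_enrichment/.
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

from nccall.genomic_io import count_bp_overlap
from nccall.simulate import SimConfig, simulate_sample, simulate_switch_pair
from nccall.switching import foldchange_group_test, interval_signal_enrichment

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 1
OUT = Path("results/05_cofactor_enrichment")
OUT.mkdir(parents=True, exist_ok=True)


def main() -> None:
    cofactor_cfg = SimConfig(
        n_wt_sites=200, n_onco_sites=50, onco_fold=4.0, fold_mode="n_inflation",
        depth=200_000, igg_artifacts=0, seed=SEED,
    )
    sim = simulate_sample(cofactor_cfg, "cofactor")
    sites = sim.sites
    track = sim.fragments_n  # density-inflated track stands in for the cofactor
    bp = count_bp_overlap(track, sites)
    cpm_per_bp = bp * (1e6 / len(track)) / (sites["end"] - sites["start"]).to_numpy()
    signal = pd.Series(cpm_per_bp.to_numpy(), index=sites["id"].to_numpy(), name="signal")
    signal.rename_axis("interval_id").reset_index().to_csv(
        OUT / "normalized_signal.tsv", sep="\t", index=False)

    bound = sites.loc[sites["class"] == "oncoprotein", "id"].tolist()
    control = sites.loc[sites["class"] == "wild_type", "id"].tolist()
    sets = {"program-1": bound[:25], "program-2": bound[25:]}
    res = interval_signal_enrichment(signal, sets, control)
    res.to_csv(OUT / "enrichment.tsv", sep="\t", index=False)

    # paired-phase expression: log2FC of an occupancy program vs control genes
    sw = simulate_switch_pair(
        SimConfig(n_wt_sites=200, n_onco_sites=0, depth=200_000,
                  igg_artifacts=0, seed=SEED),
        n_shared=30, n_a_only=20, n_b_only=20, lambda_a=1.0, lambda_b=0.5,
    )
    expr = sw["expression"]
    a_cols = [p[0] for p in sw["pairing"]]
    b_cols = [p[1] for p in sw["pairing"]]
    log2fc = np.log2(expr[a_cols].mean(axis=1) / expr[b_cols].mean(axis=1))
    fc = foldchange_group_test(log2fc[sw["a_genes"]], log2fc[sw["control_genes"]],
                               alternative="greater")
    pd.DataFrame([fc]).to_csv(OUT / "foldchange_test.tsv", sep="\t", index=False)

    print(res.to_string(index=False))
    print(f"\nA-program log2FC vs control genes: t = {fc['t']:.2f}, "
          f"one-sided p = {fc['p']:.3g} (n = {fc['n_a']} vs {fc['n_b']}).")
    print("Cofactor signal is enriched over both bound-site programs relative "
          "to the unbound internal control.")


if __name__ == "__main__":
    main()
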