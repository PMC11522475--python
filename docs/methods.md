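# Methods

## Background and model

Leukemias bearing a rearranged *MLL* (*KMT2A*) locus express a fusion
oncoprotein that retains only the N-terminal portion of MLL. Chromatin
profiling with two antibodies — one against the MLL N terminus (seen on both
the oncoprotein and the remaining wild-type protein) and one against the C
terminus (wild-type only) — therefore distinguishes oncoprotein-specific
binding sites: at a site bound by the fusion protein the N-terminal track is
enriched over the C-terminal track, while wild-type sites show balanced
signal.

`nccall` quantifies this with a Bayesian Dirichlet–multinomial model. Over a
shared universe of `m` genomic intervals (the master site list), the base
pairs of N- and C-terminal fragment signal per interval are treated as counts
from two independent multinomial distributions. With a uniform prior, each
terminus' posterior over interval fractions is Dirichlet(counts + **1**). For
interval *i* the N/C score is

    r_NC(i) = log2( p_N(i) / p_C(i) )

where p_N, p_C are posterior simplex fractions. The posterior of r_NC is
summarized by Monte-Carlo sampling: `n_draws` (default 1000) independent
simplex draws per terminus give a mean μ_i and standard deviation s_i, a
z-score z_i = μ_i / s_i, and a normal-tail p-value, BH-corrected across
intervals (statsmodels `fdrcorrection`). An interval is called an
oncoprotein target site when μ_i > 1.75 (strict) and the configured p-value
is < 1e-5 (strict). Every interval, called or not, receives an oncoprotein
score

    onco_score(i) = μ_i × −log10( p_i + 1e-10 )

and the per-sample average oncoprotein score is the mean over the full
combined site universe. A digamma closed form,
μ_i = (ψ(α_N,i) − ψ(α_N,0) − ψ(α_C,i) + ψ(α_C,0)) / ln 2, follows from
E[ln p_k] = ψ(α_k) − ψ(α_0); it is used only as an independent test oracle —
the pipeline's primary path is the Monte-Carlo procedure.

## Master site list

Per-sample N- and C-terminal peak calls (consumed as SEACR-style BED; a
quantile fallback caller is provided as plumbing for synthetic tracks) are
concatenated and merged; bookended intervals coalesce by default (flag
available, since the merge convention is a genuine choice). IgG negative
controls are pooled per 96-well plate and peak-called on an FDR grid
(default {1e-3, 5e-4, 2e-4, 1e-4}), choosing the most lenient FDR that
yields at most 2500 control peaks. Any master interval overlapping an IgG
peak by ≥ 1 bp is removed whole, never truncated.

## Key parameters

| parameter | default | units / meaning |
|---|---|---|
| `n_draws` | 1000 | Monte-Carlo posterior draws per terminus |
| `prior_pseudocount` | 1 | add-one Dirichlet prior (uniform) |
| `nc_threshold` | 1.75 | calling threshold on μ (log2 ratio) |
| `p_threshold` | 1e-5 | calling threshold on the configured p |
| `log_pseudo` | 1e-10 | pseudo count inside −log10 of the score |
| `p_sidedness` | one-sided-upper | only N-over-C enrichment is meaningful |
| `p_for_calling` | bh | BH-adjusted p used for calling and the score |
| IgG peak cap | 2500 | per pooled control set |
| top fraction | 0.05 | PCA program size (floor of fraction × sites) |
| components used | 4 | PCs fed to UMAP |
| promoter window | 2000 bp | upstream of TSS for site→gene assignment |

Choices made where the procedure is genuinely open:

* **Sidedness.** Calling requires μ > 1.75, so the one-sided upper tail is
  the coherent default; a two-sided mode is a flag.
* **Which p.** BH-adjusted p is used both for calling and inside the
  oncoprotein score (the correction step immediately precedes thresholding
  in the procedure the model mirrors); `p_for_calling="raw"` switches both.
* **Pseudo count placement.** Inside the logarithm, −log10(p + 1e-10), so
  p = 0 stays finite and the significance factor is capped at 10.
* **s_i** is the across-draw sample standard deviation (ddof = 1).
* **Counting unit.** Fragments are counted as whole intervals of base-pair
  overlap (no midpoint reduction), strand-blind, on 0-based half-open
  coordinates; duplicates (identical chrom/start/end) are removed per
  replicate before pooling, never across replicates.
* **Determinism.** All randomness flows from one seed through named
  substreams (CRC-32 of (sample, terminus/stage) mixed into a
  `SeedSequence`), so reruns are bit-identical and the N and C termini never
  share a stream.
* **PCA** operates on mean-centered, unscaled columns (scores share a
  scale); component signs are fixed by making the largest-|loading| entry
  positive; program extraction ranks by signed loading (descending, an
  |loading| mode is available) and breaks ties toward the lower genomic
  coordinate; the program size is floor(fraction × m).
* **UMAP** is a pluggable third-party step (umap-learn), seed fixed,
  neighbors auto-reduced below the cohort size, hyperparameters recorded in
  the output metadata.

## Synthetic data generator

`simulate_sample` draws each track's fragments multinomially over a planted
site layout plus uniform genomic background (default 20% of depth), mirroring
the model's generative assumption. Site classes: wild-type (N ≈ C),
oncoprotein, and IgG-artifact sites (sticky regions present in every track at
10× density, exercising control subtraction). Fragment lengths are
Normal(150, 30) truncated to [50, 500] bp — typical CUT&RUN-scale fragments —
and placed uniformly inside their site. A per-sample oncoprotein level λ
scales enrichment linearly: effective fold f_eff = 1 + λ(f − 1).

Because the C-terminal antibody sees only wild-type protein and
oncoprotein-specific sites are new sites not bound by wild-type MLL, the
default enrichment mechanism divides the C-track weight at oncoprotein sites
by f_eff (`fold_mode="c_depletion"`). This keeps wild-type sites near N ≈ C
(μ ≈ log2 of a mild normalization shift, −0.28 at the default layout) and
puts the full planted ratio at oncoprotein sites. The alternative
`fold_mode="n_inflation"` multiplies the N-track weight instead; with
multinomial renormalization this depresses wild-type sites to μ ≈ −1.26 at
the default layout and caps oncoprotein sites at μ ≈ 1.74 — below the 1.75
calling threshold — so it is kept as a flag (and is the right emulation for
cofactor-style tracks, where binding adds fragment density), not the default.

What the generator does **not** emulate: GC and mappability bias, chromatin-
state-dependent background, site-length heterogeneity (sites are fixed-width
by default), fragment-length differences between antibodies, replicate-level
batch structure, and read-level error. Passing recovery benchmarks therefore
shows the statistical machinery is correct under the model's own
assumptions, not that those assumptions hold in any given real dataset.

## Benchmark study conditions

The reference checks in `nccall.validation` (run by `scripts/acceptance.py`
and asserted in `tests/test_acceptance.py`) use:

1. **Closed-form agreement** — 200 random count pairs up to 2e4 bp; μ must
   match the digamma closed form within 4·s_i/√1000 on ≥ 99% of intervals.
2. **Null calibration** — λ = 0, 1000 intervals, 2e5 fragments/track; at the
   joint thresholds at most one false call is tolerated.
3. **Recovery** — 8-fold enrichment at 50 of 250 sites, 2e5 fragments/track:
   sensitivity and precision ≥ 0.9; mean planted-site score monotone across
   folds {1, 2, 4, 8}.
4. **BH exactness** — 1000 random p-vectors against an independent step-up
   enumeration, exact.
5. **Cohort program recovery** — 2 groups × 4 samples with disjoint 40-site
   programs in an 800-site universe (so the top 5% is exactly 40 sites),
   levels λ_A = {0.6, 1.0, 1.5, 2.0} and λ_B = {0.2, 0.3, 0.4, 0.5}, 1e6
   fragments/track. The level ranges are deliberately asymmetric: with two
   disjoint programs the principal axes of the centered score matrix are
   rotations of the program-contrast and program-sum directions, and equal
   group variances would place the sum direction at 45°, mixing the programs
   in PC2's loadings. The chosen separation puts the loading gap between
   programs at ≈ 3× the per-site loading noise at this depth (C-track counts
   at depleted sites are the noise bottleneck), so PC1 recovers the stronger
   program and PC2 the weaker one at Jaccard ≥ 0.8. The average oncoprotein
   score must be monotone in λ across all 8 samples.
6. **Exact small-sample statistics** — five concordant pairs give the exact
   one-sided signed-rank p = 1/32; complete separation at n1 = n2 = 5 gives
   the exact two-sided Mann-Whitney p = 2/252; both are cross-checked
   against brute-force null enumerations in the test suite.

These problem sizes keep the whole benchmark under a couple of minutes on
one CPU while leaving wide statistical margins.

## Known limitations

* Base-pair counts feed the Dirichlet as if each base were independent,
  while bases within one ~150 bp fragment are perfectly correlated. The
  posterior s_i is therefore understated by roughly √(fragment length) and
  the p-values are anticonservative; the procedure relies on the joint
  threshold with μ > 1.75 for calibration (the null benchmark shows ~0 false
  calls despite the liberal p). This mirrors the published procedure rather
  than correcting it; a fragment-count mode would be the natural extension.
* The site→gene rule (body or 2-kb promoter-window overlap) is deliberately
  simple; counts of "target genes" depend strongly on the annotation used.
* `differential_target_sites` operationalizes "most dramatic differences" as
  call-status discordance ranked by score difference, with an optional
  top-k; other reasonable definitions exist.
* The fallback peak caller is a quantile thresholder for synthetic tracks,
  not a replacement for a dedicated sparse-enrichment caller on real data.
* Cofactor signal normalization (CPM base pairs per interval divided by
  interval length) is one reasonable choice among several.
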