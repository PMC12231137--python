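# Methods

`microtraits` analyses amplicon (16S) surveys of soil communities in which
each ASV carries inferred genomic traits — genome size, rRNA operon copy
number and GC content — and a co-occurrence-based niche-breadth score.
This note records the models, their assumptions, the numerical choices
made where the design was open, and what the synthetic data generator does
and does not emulate.

## Pipeline model

The analysis assumes a standard amplicon workflow upstream: denoised ASV
counts, a SILVA-style seven-rank taxonomy, soil physicochemical metadata
and a phylogeny (or pairwise distance matrix) over ASVs. The pipeline then
proceeds in a fixed order:

1. **Taxon filtering.** ASVs flagged as Chloroplast or Mitochondria at any
   rank, or outside Bacteria/Archaea, are removed. ASVs without a lineage
   count as unclassified at the domain rank and are removed.
2. **Sample filtering and rarefaction.** Samples with fewer than 8000
   reads are dropped; remaining samples are subsampled without replacement
   to 7555 reads (single multivariate-hypergeometric draw per sample,
   seed-controlled). A single draw, rather than an average over draws, is
   used; downstream quantities are therefore conditional on that draw and
   exactly reproducible from the seed.
3. **Community descriptors.** Bray–Curtis dissimilarities
   BC(x, y) = 1 − 2·Σ min(xᵢ, yᵢ) / (Σ xᵢ + Σ yᵢ), non-metric MDS in two
   dimensions, Gini–Simpson diversity 1 − Σ pᵢ², a phylum-level Spearman
   screen against soil variables, and per-sample archaea:bacteria read
   ratios.
4. **Trait assignment.** Per ASV and per trait independently, ranks are
   walked from the lowest classified rank upward (species → … → domain);
   the first rank at which the reference holds a value supplies the trait,
   and that rank is recorded as provenance. Reference rows sharing a
   (name, rank) are aggregated by the arithmetic mean (median available
   via `statistic="median"`); rows carrying lineage columns also
   contribute to their ancestors' aggregates.
5. **Consensus rRNA.** When an external per-ASV rRNA prediction is
   supplied, the working value is the arithmetic mean of the database and
   predicted values, kept fractional. The mean is the symmetric choice
   when neither source is privileged; provenance is marked `consensus`.
   Non-positive predictions are rejected with a warning.
6. **Social niche breadth (SNB).** For each ASV, SNB is the mean
   Bray–Curtis dissimilarity between all unordered pairs of samples in
   which it occurs (count > 0), computed on ASV-level relative-abundance
   profiles that include the focal taxon. Occupancy below 2 yields a
   missing score — a singleton provides no pair, and coding it as 0 would
   conflate rarity with extreme specialism. Profile aggregation rank and
   the dissimilarity are configurable.
7. **Community-weighted means.** Per sample, ave.gs / ave.rrna / ave.gc /
   ave.snb are Σ nᵢₛ·tᵢ / Σ nᵢₛ over taxa with the trait defined and
   nᵢₛ > 0 — weights renormalised over the annotated subset, which avoids
   biasing means toward zero in poorly annotated samples. The fraction of
   reads carrying each trait is logged per sample, and the modelling stage
   refuses samples below a configurable floor (default 50% of reads).
8. **Phylofactorization.** Greedy edge selection on the unrooted tree. At
   each step every edge interior to a current bin is scored; the winner
   splits its bin and the process repeats (default 15 factors,
   significance threshold 0.01). Two objectives are implemented:
   *taxon* mode (default) scores an edge by the absolute two-sample
   t statistic comparing a per-ASV covariate (SNB) between the edge's two
   groups; *sample* mode scores it by the regression F statistic of the
   groups' ILR balance on a per-sample covariate. The ILR balance of
   groups R, S is √(rs/(r+s))·ln(gm_R/gm_S) on relative abundances after
   adding a pseudocount (default 1) to the counts and re-closing. The
   taxon-mode objective is this package's concretization of modelling
   abundances against per-ASV SNB; the mapping of that idea onto a single
   regression is not unique, which is why both modes exist and the choice
   is a config knob rather than an assertion.
9. **Phylogenetic signal.** Blomberg's K and Pagel's λ for SNB (or any
   tip trait), plus phylogenetic GLS. The shared-path covariance C
   requires a root; unrooted working trees are midpoint-rooted solely to
   define C (for Brownian motion with an estimated ancestral mean the
   likelihood is root-invariant, so this is a convention, not an
   assumption). K is the MSE₀/MSE ratio scaled by its Brownian
   expectation, with a tip-permutation p-value (default 999 permutations,
   seeded). λ scales the off-diagonal of C; mean and variance are profiled
   analytically and λ maximised over [0, 1] by bounded scalar search
   (tolerance 1e-6), with both endpoints checked against the interior
   optimum. PGLS estimates β = (X'C⁻¹X)⁻¹X'C⁻¹y with Wald t tests on
   n − p degrees of freedom; λ is profiled from the regression likelihood
   unless supplied.
10. **Trait–environment models.** Two penalized-regression-spline additive
    models (Gaussian family, identity link):
    `pH ~ s(Organic_Matter_LOI) + s(ave.gs) + s(ave.rrna) + s(ave.gc)` and
    `ave.snb ~ s(Organic_Matter_LOI) + s(pH) + s(ave.gs) + s(ave.rrna) + s(ave.gc)`,
    plus four ordinary least-squares regressions (pH~OM, ave.gs~ave.rrna,
    simpson~pH, ave.snb~ave.gs). Gaussian/identity is the natural family
    for continuous responses on these scales; the basis dimension is 10
    per smooth (configurable).

## Numerical choices

- **NMDS.** Best configuration over 20 random SMACOF starts plus one
  start initialised from the metric MDS solution. Reported stress is
  Kruskal stress-1 against an isotonic (monotone) regression of
  configuration distances on dissimilarities, ties averaged (Kruskal's
  primary approach). Coordinates are centred at the origin.
- **Neighbor joining.** Classic Saitou–Nei Q-criterion agglomeration.
  Negative branch lengths are clamped to zero with the deficit moved to
  the sister branch, preserving the pair's path length; on additive
  matrices the tree reproduces the input distances exactly.
- **Smoothing selection and term tests.** Smoothing parameters minimise
  GCV via basinhopping with a fixed internal seed, so refits are
  bit-for-bit reproducible. Per-term effective degrees of freedom come
  from the influence matrix at the selected penalties; the approximate F
  test for a term compares residual sums of squares with and without the
  term at those penalties, on (edf_term, n − edf_total) degrees of
  freedom. Under a pure-noise response this test is slightly conservative
  (≈1–2% of terms reach p < 0.01), which the calibration tests pin down.
  "Maximal smoothing" means a large finite penalty (≈1e8); beyond ≈1e12
  floating-point conditioning erodes the penalty null space and the fit
  collapses below its linear component, a property of penalized-spline
  arithmetic generally.
- **Multiple testing.** The phylum–environment screen and the per-model
  GAM term lists are Benjamini–Hochberg adjusted; significance stars
  (0.001/0.01/0.05) refer to adjusted p in the screen and raw p in the
  GAM tables, with the adjusted column reported alongside.
- **Degenerate inputs.** Constant covariates yield undefined correlations
  (reported missing) or zero objectives (never significant); constant tip
  traits are an error for K and λ; zero-sum samples are errors for
  closure-based statistics; empty filter results raise instead of
  returning empty tables.

## The synthetic-data generator

`synthetic_data.generate_dataset` emulates a managed-agricultural-soil
survey: 245 samples with pH ~ Uniform(5.6, 8.7) and organic matter (% LOI)
weakly positively coupled to pH (target r² ≈ 0.08, residual sd 2.2%);
300 taxa with Gaussian pH niches whose expected relative abundance in a
sample is exp(−(pH_s − optᵢ)²/2σᵢ²) perturbed by lognormal noise and
sampled multinomially at lognormal depths (mean 20 000; two samples forced
below 8000 reads to exercise the read filter). Niche widths mix
generalists (σ median 1.5 pH units, 30% of taxa) and specialists (0.4),
with widths increasing toward low pH optima (coupling 0.25 per pH unit) —
so community niche breadth declines with pH. Planted traits follow the
survey's gradients: genome size 4.7 Mb at optimum 5.5 falling 350 kb per
pH unit (noise sd 120 kb), GC rising 3% per pH unit, rRNA copies a clipped
affine function of genome size (1.7 copies/Mb, noise sd 0.6, range 1–15).
pH optima evolve as Brownian motion on a Yule tree, planting phylogenetic
signal; `phylo_signal=False` shuffles optima across tips as a null.
Taxonomy nests 4 ASVs per genus, 5 genera per family, 3 families per
phylum, with the first phylum labelled Archaea; 15% of ASVs get an
unclassified genus. The trait reference holds genus rows (member-taxon
means) for 70% of genera and family aggregates for every family, so each
ASV's expected provenance rank is decidable by construction.

What the generator does **not** emulate: sequence-level error, chimeras or
contaminants (organelle spike-ins are available but off by default),
compositional interactions between taxa, spatial or farm-level structure,
non-Gaussian (e.g. skewed or bimodal) niche responses, and trait
uncertainty in the reference itself. Passing recovery tests therefore
demonstrates that the estimators are correct and well calibrated under a
clean pH-structured model — not that real surveys satisfy that model.

## Problem sizes used by the test suite

The suite runs the full generator conditions (300 taxa × 245 samples) for
recovery and direction-level checks, 128–200-tip Yule trees with 200
replicates for signal calibration, 32-tip trees over five seeds for
planted-clade phylofactor recovery, 500 fixed-seed rarefaction draws of a
six-taxon composition for the hypergeometric check, and 20 × n=200 null
datasets for additive-model calibration. `scripts/acceptance.py` runs the
complete pipeline once at the default conditions.

## Known limitations

- SNB is defined relative to the sample set at hand; scores are not
  comparable across surveys with different environmental coverage.
- The taxon-mode phylofactor objective is one concretization of relating
  abundance structure to per-ASV SNB (see above); results are reported
  descriptively, and the greedy search shares phylofactorization's usual
  caveat that factor k is conditional on factors 1..k−1.
- GAM term p-values are approximate (penalized fits have no exact finite
  degrees of freedom); they are calibrated slightly conservative.
- Trait assignment inherits every bias of the reference: a rank-level mean
  hides within-rank variance, and provenance at high ranks (family and
  above) can dominate poorly classified communities — the per-sample read
  coverage report and the modelling floor exist to surface this.
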