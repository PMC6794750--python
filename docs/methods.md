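# Methods

This note documents the statistical model, the algorithmic choices made
where published descriptions are incomplete, the synthetic data the tests
rely on, and the limits of what those tests demonstrate.

## Observation model and meta-QTL estimation

A QTL observation is a peak position `x_i` (cM, on the consensus map) with
a 95% confidence interval of length `L_i`. Treating the interval as a
symmetric normal CI gives a known standard deviation `σ_i = L_i / 3.92`
(more generally `L_i / (2 z_{(1+level)/2})`). Co-located observations on a
linkage group are modelled as draws from K underlying loci:

    x_i ~ Σ_k π_k N(μ_k, σ_i²)

Only the K means and K−1 independent weights are estimated; the variances
are data. EM updates are

    E:  z_ik ∝ π_k φ(x_i; μ_k, σ_i²)
    M:  μ_k = (Σ_i z_ik x_i/σ_i²) / (Σ_i z_ik/σ_i²),  π_k = mean_i z_ik

The observed-data log-likelihood is asserted non-decreasing at every
iteration. Convergence: improvement < `tol` (default 1e-8, configurable).
Ten restarts per K: the first seeds means at the K sample quantiles of the
peaks, the rest draw K peaks at random from a seeded generator; the best
non-degenerate fit (no empty hard cluster) wins, falling back to the best
overall (flagged) if every restart degenerates. With K=1 the EM fixed
point is the inverse-variance weighted mean; the test suite checks
agreement to 1e-9.

**Model selection.** For each K in 1…min(n, K_max) (K_max defaults to 10,
a runtime cap over scanning all n), five criteria are computed with
p = 2K−1:

    AIC  = −2logL + 2p
    AICc = AIC + 2p(p+1)/(n−p−1)        (undefined when n−p−1 ≤ 0;
                                         excluded from voting)
    AIC3 = −2logL + 3p
    BIC  = −2logL + p ln n
    AWE  = −2logL_c + 2p(3/2 + ln n)

AWE is defined on the classification (hard-assignment) log-likelihood
`logL_c`; the acronym is used in the meta-QTL literature without a printed
formula, and this is the standard Banfield–Raftery-style form. Each
defined criterion votes for its minimizing K; the modal K wins, vote ties
resolve to the smallest tied K, then smallest AIC.

**Summaries.** Members are hard assignments. The meta-QTL CI combines
member precisions, `σ_meta² = 1/Σ σ_i⁻²`, so `σ_meta` can never exceed the
best member's σ. Mean R² is the unweighted member mean — the weighting
behind published "mean R²" columns is not specified anywhere, and the
unweighted mean is the transparent choice.

**Two rounds.** Single-trait mode clusters only the focal trait (after
pruning same-study CI-overlapping QTLs to the highest-R² member; R² ties
prefer the longer CI, then input order). Cross-trait mode additionally
pools QTLs of related traits whose CIs overlap a focal QTL — intended for
linkage groups where the focal trait alone has too few observations, and
justified only under an assumption of shared (pleiotropic) control. The
pipeline's `auto` mode runs single-trait first and falls back to
cross-trait per linkage group.

## Consensus map construction

The merge procedure of the established interactive tool is unpublished, so
the implementation is a deterministic stand-in designed for order-level
agreement, not coordinate equivalence:

1. Orientation: flip a linkage group (pos → max − pos) iff the Spearman
   correlation of shared-marker positions against the reference map is
   negative; exact zero keeps the original orientation.
2. Groups sharing < 2 markers with all other maps are removed (they can
   neither be oriented nor calibrated).
3. Conflict resolution: while any marker pair is ordered differently by
   two maps, remove (from every map) the conflicting marker with the
   lowest occurrence count across maps; ties break by name. Each round
   removes one marker, so termination is guaranteed.
4. Merge: the map with the most markers on the group is the initial frame
   (ties → lexicographically smallest map id); remaining maps join in
   decreasing order of markers shared with the current consensus. Each
   joining map is calibrated by monotone piecewise-linear interpolation
   through its shared markers (terminal-segment slopes extrapolate beyond
   the shared span); consensus positions are refreshed as means of
   calibrated positions after every merge, and the group is finally
   shifted so its first marker sits at 0 cM. Equal consensus positions
   order by descending shared-map count, then name.

Consequences worth knowing: the consensus cM scale inherits the frame
map's scale (it is not an average scale), and averaging across maps
shrinks very short marker intervals toward zero — occasionally two markers
become nearly coincident on the consensus while separated on a source map.
Downstream, that is exactly the situation the projection scale rule
rejects.

## Projection

The flank pair is the closest pair of shared markers bracketing the peak
(minimal source-side span; distinct source positions required). Peaks
outside the shared span use the two nearest shared markers as an
extrapolation pair and the result is flagged `extrapolated`. The scale
rejection threshold is `s < 0.25`: the published wording ("not reduced by
a factor greater than 0.25") is ambiguous about which ratio shrinks, and
this reading — consensus flank span less than a quarter of the source
span — rejects exactly the degenerate-compression cases. No upper bound on
`s` is applied by default (`max_scale` exposes one). QTLs published
without a CI get the population-size fallback `CI95 = 530/(N·R²)` cM
centred on the peak, the standard empirical relation for biparental
populations; with R² also missing the peak alone is projected and the
record is excluded from meta-analysis.

## Co-localization test

The consensus map is cut into 5-cM bins (configurable); each bin is scored
covered/uncovered by each trait's CIs, and the 2×2 table (both, a-only,
b-only, neither) is tested with a Yates-corrected χ² (1 df). The exact
binning of the test this imitates is not restated in the meta-QTL
literature, so a permutation alternative (per-LG circular shifts of one
trait's intervals, empirical p of the jointly covered bin count) is
provided as a robustness check; permutation p-values live in
[1/(n_perm+1), 1]. Adjacent bins covered by one long CI are correlated, so
the χ² approximation is trustworthy only when CIs are comparable to the
bin width and bins are plentiful; the calibration experiment (4 × 250 cM
groups, 30 QTLs per trait, CI length 2–6 cM) measures a type-I error of
≈ 0.05–0.07 at α = 0.05.

## Genome anchoring

Anchor candidates with multiple hits, hits on a chromosome other than
their linkage group's (majority vote of unique hits defines the LG →
chromosome assignment unless supplied), or positions breaking the cM/bp
monotone relation are excluded. Incongruence is resolved greedily —
repeatedly drop the anchor involved in the most order violations — which
maximizes retained anchors in the common case of isolated bad anchors. A
chromosome whose physical axis runs against the genetic axis is detected
by negative rank correlation and handled transparently. cM → bp conversion
is piecewise-linear interpolation between flanking anchors with
terminal-segment extrapolation, clamped to [1, chromosome length]; the
established tool's internal conversion formula is unpublished, and linear
interpolation is the declared stand-in. Gene retrieval uses any-overlap on
closed 1-based intervals.

## Expression integration

"Never expressed" in the RNA-seq course means: no (year, time point) has
≥ 2 replicates with FPKM ≥ 1. The transcriptomic onset interval of a year
is the adjacent pre-veraison time-point pair (days-before-veraison ≥ 0)
across which the most biomarker genes are modulated; ties take the
earliest pair, since the target is the *first* molecular event.
"Modulated" is operationalized as |log2((m₂+1)/(m₁+1))| ≥ 1 on replicate
means with pseudocount 1 — the verbal description this encodes ("highest
modulation, by inspecting FPKM values") is not quantified anywhere, and
the threshold is configurable. Transcriptomic candidates are genes
modulated across the onset interval in ≥ 2 of the years, unioned with an
externally curated all-genotype DE list (that list is an input, not
recomputed). Final candidates are positional ∩ (expressed in
berry/rachis/seed per the organ atlas) ∩ transcriptomic; a fixed 18-term
GO-slim set (nucleotide/nucleic-acid binding, transcription factor
activity, signalling, development, growth, etc.) flags the regulatory
subset. Every filter is monotone in its threshold.

## Synthetic data: what it emulates and what it does not

Defaults (one place, `SimulationConfig`): 2 linkage groups × 100 cM,
80-marker pools, 10 maps × 60 markers with a 40% shared backbone, per-map
affine scale in [0.8, 1.25] plus order-preserving positional jitter
(sd 0.5 cM); planted loci 1 (LG 1) + 3 (LG 2: 20/50/80 cM), the LG 2
layout carrying 12 QTLs with σ ∈ [1.5, 4] cM — the configuration of the
recovery experiment; 100 kb/cM physical scale, 120 grid genes per
chromosome plus 3 planted candidates within ±0.5 cM of each locus; 3 years
× 7 time points × 3 replicates, log2-normal baseline (noise sd 0.2),
effect size 2 log2 units at the planted year-specific transition; planted
same-study duplicates, silent-in-organ genes, never-expressed genes, and a
known regulatory GO subset. The default seed (17) makes the documented
example bit-reproducible.

Distortions are affine + jitter, not recombination-based — enough to
exercise calibration and projection, honest about not simulating meioses.
Expression is a step change plus log-normal noise, not an RNA-seq count
model. Passing tests therefore demonstrate correctness of the algorithms
under the stated observation models, not robustness to real-data
pathologies (segregation distortion, genuinely different marker orders
between populations, count overdispersion).

## Known limitations and numerical notes

- Meta-QTL CIs are 95% intervals, so gene retrieval over them misses a
  gene sitting at the locus boundary in a few percent of simulations; the
  end-to-end exact-recovery check is anchored at the generator's default
  seed, and multi-seed runs report a recovery Jaccard index that is
  occasionally below 1 for exactly this reason.
- The jitter in component maps makes incidental order conflicts common;
  conflict resolution removes the involved low-occurrence markers, which
  mirrors practice but can discard an appreciable fraction of close marker
  pairs. Order recovery (Spearman ρ ≥ 0.95 against the generated truth)
  holds comfortably under the defaults.
- EM is run on log densities with per-observation variances; empty-cluster
  restarts and a floor on mixing weights guard the degenerate corners.
  All randomness flows from explicit seeds; reruns are byte-identical.
- Problem sizes in the test and acceptance runs (2 linkage groups, tens of
  QTLs, hundreds of genes, 100-seed recovery) were chosen so the full
  suite completes in a couple of minutes on one CPU while keeping every
  statistical check adequately powered.
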