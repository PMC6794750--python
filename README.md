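# metaqtl-forge

A pipeline for meta-analysis of quantitative trait loci (QTLs) across
independently published genetic maps, with candidate-gene prioritization
through genome anchoring and expression data. It was built around the
grapevine veraison (onset of berry ripening) use case — merging dozens of
SSR-based linkage maps, projecting literature QTLs onto the merged map, and
narrowing wide QTL regions down to a short list of candidate genes — but
every stage is generic over traits and organisms.

It is aimed at geneticists and breeders who have collected published QTL
tables (trait, linkage group, peak, confidence interval, R², population
size) from heterogeneous studies and want a reproducible, scriptable
alternative to interactive meta-QTL GUIs.

## What it computes

**Consensus map.** Component maps are normalized (marker synonym table),
oriented against a reference, stripped of linkage groups that share fewer
than two markers with the rest, and de-conflicted: while any marker pair
has inconsistent order between two maps, the least-represented conflicting
marker is removed. Maps are then merged per linkage group by monotone
piecewise-linear calibration through shared markers; a marker's consensus
position is the mean of its calibrated positions.

**Projection.** Each QTL is moved onto the consensus by the homothetic rule
`f(x) = b_L + s (x − a_L)` with `s = (b_R − b_L)/(a_R − a_L)`, where
`a`/`b` are source/consensus positions of the closest shared markers
bracketing the peak. Projections with `s < 0.25` are rejected, as are QTLs
without two shared anchoring markers. Missing confidence intervals fall
back to `CI95 = 530/(N · R²)` cM.

**Meta-QTLs.** Projected peaks on one linkage group are modelled as a
mixture of K true loci with *known* per-observation variances,

    x_i ~ Σ_k π_k N(μ_k, σ_i²),   σ_i = CI_i / 3.92,

fitted by EM for K = 1…K_max. Five information criteria (AIC, AICc, AIC3,
BIC, AWE; p = 2K−1 free parameters) each vote for the K they minimize and
the majority wins (ties → smaller K). Each cluster becomes a meta-QTL with
peak μ_k and CI95 `μ_k ± 1.96·σ_meta`, `σ_meta² = 1/Σ σ_i⁻²`. Same-study
overlapping QTLs are pruned to the highest-R² member beforehand, and a
second, cross-trait round pools the focal trait with overlapping QTLs of
related traits.

**Anchoring & candidates.** Markers with unique, congruent physical
positions interpolate cM intervals to bp; genes under each meta-QTL are
read from GFF3. Candidates are intersected with expression-derived
candidates (organ atlas calls, FPKM ≥ 1 in ≥ 2 replicates, |log2 FC| ≥ 1
across the year-specific transcriptomic onset interval in ≥ 2 years, plus
an externally curated DE list) and flagged with a regulatory GO-slim set.

A `synthetic_data` generator (`metaqtl_forge.simulate`) emulates every
input with known ground truth, so the whole pipeline is testable offline.

## Worked example

```bash
metaqtl-forge all --input-dir demo/in --out demo/out --seed 17
```

This simulates an input bundle (10 distorted component maps on 2 linkage
groups, 16 QTL observations drawn around four planted loci — one on LG 1,
three on LG 2 — a 20 Mb two-chromosome genome with 252 genes, and a
3-year × 7-time-point FPKM course), then runs every stage. Key outputs:

`demo/out/metaqtls.tsv`:

| name | lg | peak_cm | start_cm | end_cm | n_original_qtls |
|---|---|---|---|---|---|
| ver_1.1 | 1 | 31.09 | 25.18 | 37.00 | 2 |
| ver_2.1 | 2 | 22.83 | 17.52 | 28.13 | 3 |
| ver_2.2 | 2 | 54.25 | 51.51 | 56.98 | 3 |
| ver_2.3 | 2 | 85.30 | 80.20 | 90.40 | 3 |

The four fitted meta-QTLs match the planted 1+3 layout; LG 2 clusters have
three members each because one same-study duplicate per locus was pruned.
`demo/out/funnel_counts.tsv` shows the candidate funnel:

| stage | n_genes |
|---|---|
| positional (under meta-QTLs) | 56 |
| expressed in berry/rachis/seed | 52 |
| positional ∩ transcriptomic | 8 |
| regulatory (GO slim) | 4 |

and the 8 genes in `candidates_final.tsv` are exactly the generator's
planted candidate set (`ground_truth.json`).

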