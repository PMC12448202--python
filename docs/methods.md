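# Methods

## Model

A distorting locus *i* on a chromosome biases the transmission of the
maternal allele among surviving gametes to 0.5 + k, with the signed
distortion coefficient k ∈ [−0.5, 0.5] (positive = toward the maternal
genome). A gamete recombinant between *i* and a linked site *p* carries
the maternal haplotype at *p* with probability

    f_p = (0.5 + k)(1 − r) + (0.5 − k) r = 0.5 + k (1 − 2 r(d_pi)),

where r(d) is the recombination fraction at map distance d Morgans between
the two positions. With a symmetric per-read error rate e, a read maps to
the maternal haplotype with probability

    q_p = f_p (1 − e) + (1 − f_p) e = 0.5 + k (1 − 2r)(1 − 2e),

the collapse of the four transmission × error outcomes for each allele.
Observed maternal read counts at each site are modelled as independent
binomials in q_p. Independence across linked sites is false in principle
(reads descend from a shared, linked gamete pool) — this is a composite
likelihood, used for point estimation only; see Limitations.

### Scan and effect call

For each candidate position (by default every retained site, optionally
thinned), k is fitted by maximizing the composite log-likelihood separately
on pollen and on leaf counts. The leaf fit is a null model: leaf tissue is
diploid 50:50, so any apparent leaf "distortion" measures residual mapping
or reference bias shared by both libraries. Candidates are ranked by

    Λ(i) = 2 [ ℓ_pollen(k̂_pollen; i) − ℓ_pollen(k̂_leaf; i) ],

the germline-vs-somatic likelihood ratio evaluated on the pollen data; the
ML position is the Λ-argmax (smallest coordinate on ties). The reported
effect is k̂_pollen − k̂_leaf at that position, rounded to two decimals,
and set to zero below the 0.02 threshold. A configuration switch reports
raw k̂_pollen instead; the leaf-corrected difference is the default because
it operationalizes the somatic null. The likelihood itself carries no
significance calibration beyond the effect threshold — none is defined for
this procedure.

### Map function

Haldane's map function, r = (1 − exp(−2d))/2, is used both in the generator
and the likelihood: it is the standard no-interference choice, and using
the same function on both sides keeps simulation and inference
self-consistent. Real-data runs should supply the species' recombination
map as a TSV of (chrom, pos_bp, pos_cM) anchors; positions are linearly
interpolated between anchors.

### Confidence intervals

Position uncertainty: resample sites with replacement (one resample applied
to both tissues — the leaf/pollen contrast is per-site and stays paired),
rerun the scan with multiplicity weights on the unchanged candidate grid,
record the replicate ML position; the CI is the 2.5th/97.5th percentile of
B = 100 replicate positions (linear interpolation between order
statistics, the numpy default). Joint intervals across crosses presumed to
share a distorter: replicates are paired by index, per-cross Λ profiles are
linearly interpolated onto the union of their physical grids and summed,
and the joint CI is the percentile interval of the summed-profile argmaxes,
clipped to the envelope of the individual CIs (a pooled estimate outside
the region any individual cross supports is not meaningful). Pairing by
replicate index preserves B; a full cross-product of replicates would be
the main alternative reading and differs only in Monte-Carlo noise.

## Filters and descriptive layer

- Depth-quantile filter: per tissue sample, sites with total depth strictly
  below the 5% or strictly above the 95% depth quantile (linear
  interpolation between order statistics) are removed — a guard against
  structural variants and repeats.
- Proximity filter: any site closer than 100 bp to another site is removed,
  both members of a close pair (the conservative literal reading; a
  keep-one variant would retain marginally more sites). A gap of exactly
  100 bp is kept. The rule is evaluated on the original positions, which
  makes it idempotent.
- After per-tissue filtering the site sets are re-intersected.
- The ancestry "ratio" is computed as the maternal proportion
  mat/(mat+pat), centred on 0.5, not the literal quotient centred on 1.
  Windowed summaries average per-site proportions in non-overlapping
  1,000-SNP windows; the difference is pollen − leaf so its sign matches
  the k convention.

## Cohort statistics

The sampling unit is the chromosome (crosses × 8 chromosomes); a
chromosome is distorted iff its called effect is nonzero (calls are already
thresholded at |k| ≥ 0.02). This is the only unit under which the
between-species vs between-region sample odds ratio reproduces as
(18·29)/(22·11) = 2.157. Fisher's exact test (two-sided, point-probability
rule, via scipy) tests occurrence; Mann–Whitney U (asymptotic, tie and
continuity corrected) compares |k|, including zero entries by default —
among nonzero entries alone the between-species values are not
stochastically larger, so the inclusive comparison is the informative one;
a flag exposes the nonzero-only variant. Both are cross-checked in the test
suite against exhaustive enumeration oracles.

## Permutation tests

**Genome-wide antiparallel nonindependence.** Under gametic DMIs, maternal-
and paternal-direction distorters co-occur within a progeny and their
signed effects cancel. Statistic (default): the mean over distorted
progeny of |mean signed k among that progeny's distorted chromosomes|.
Null: reshuffle the multiset of observed nonzero signed effects across
chromosome slots, conditioning on each progeny's count of distorted
chromosomes; p = proportion of permuted statistics ≤ observed, floored at
1/n. All 14 progeny enter (shared-parent exclusion applies only to the
pairwise test). Two alternative statistics are exposed: the mean of
absolute per-progeny sums, and the absolute grand mean of per-progeny sums.
The last is the natural descriptive summary (`progeny_sum_statistic`) but
is *invariant* under this null — the grand sum of a reshuffled multiset
never changes — so it cannot serve as a test statistic; the per-progeny
absolute statistics are the ones that measure within-individual
cancellation, and the default reproduces the published p on the packaged
matrix.

**Pairwise chromosome interaction.** For each of the 28 unordered
chromosome pairs, count progeny whose two entries have opposite signs.
Null: permute each progeny's eight entries across its chromosomes
(preserving each individual's effect multiset — the observed statistic is
a per-progeny co-occurrence; a whole-matrix shuffle is available as an
option). Raw p uses the add-one estimator (b+1)/(n+1), which cannot reach
an impossible zero at n = 10^6; Bonferroni multiplies by 28, capped at 1.
Crosses sharing one or more parents are removed first
(`remove_all_sharing`, the literal reading; `keep_one` and `none` are
configurable) — with all four sharing crosses removed the packaged
matrix's chr4–chr5 antiparallel count drops from 5 to 2.

## Synthetic generator

`simulate_cross` emulates the structure of the real data: uniformly placed
ancestry-informative sites on a linear (or supplied) genetic map, leaf
counts binomial at q = 0.5, pollen counts binomial at the q_p above, depths
negative-binomial (mean 100, dispersion 5 by default — the study reports
~144× mean depth but no distribution; depth is configurable and clamped at
≥ 1) or fixed. Defaults (5,000 sites, 20 Mb, 1 Morgan, e = 0.005) are the
scale at which the acceptance checks run. At most one distorter per
chromosome, matching the inference model's assumption.

Two modes: `marginal` (default) draws counts from the marginal per-site
probability — the generative process exactly matched to the composite
likelihood; `linked` simulates whole recombinant gametes (Poisson
crossovers on the map, viability selection at the distorter) and samples
reads from the surviving pool, reintroducing the linkage correlations real
data have. The generator does not emulate read-level artifacts, mapping
bias, structural variation, or depth heterogeneity along the chromosome —
so a green recovery test establishes correctness of the estimator under
the stated model, not robustness to alignment pathologies.

`simulate_effect_matrix` builds random effect matrices (per-cross distorted
counts, values drawn without replacement from a pool) as null fixtures for
the permutation tests.

## Numerical choices

- The per-candidate likelihood is concave in k (q is affine in k), so the
  bounded MLE is found by damped Newton iteration with clipping to
  [−0.5+1e−6, 0.5−1e−6], tolerance 1e−8 on k, vectorized across candidates
  with an active set; it is verified against scipy bounded scalar
  optimization in the tests.
- Bootstrap rescans reuse the candidate×site coupling matrix (it depends
  only on positions and e) and warm-start Newton from the previous fit.
- `site_bin_cM` optionally aggregates sites into genetic-position bins for
  the likelihood sums (default off). Binning at 0.1 cM changes fitted k by
  < 1e−3 at the default scale and is used by the heavier tests; candidate
  positions are never binned.
- Λ is clipped at 0 (it is non-negative by construction; tiny negative
  values can arise from the convergence tolerance). Ties at the maximum
  resolve to the smallest coordinate.
- e is a single fixed nuisance parameter per cross (default 0.005), shared
  by both tissues; leaf deviations from 0.5 absorb error plus residual
  mapping bias through the leaf k fit.
- Degenerate inputs: chromosomes with fewer than 10 shared sites are
  refused; zero-depth sites are rejected by the proportion layer; an
  all-zero effect matrix yields p = 1 with a warning in the genome-wide
  test.

## Limitations

- Composite likelihood: point estimates are approximately unbiased even
  under the linked-gamete generator, but likelihood-ratio magnitudes and
  interval coverage are not guaranteed when per-site independence fails;
  the bootstrap CIs are over sites, which partially (not fully) absorbs
  this. Coverage is verified empirically under the matched generator only.
- One distorter per chromosome; no multi-distorter deconvolution, no
  interference-aware map functions.
- The cohort and permutation layers treat crosses as exchangeable up to
  shared-parent removal; full genealogical (phylogenetic) correction is
  out of scope.
- The packaged cross metadata contains only the two published parent IDs;
  all other parent IDs are synthetic placeholders, so parent-sharing
  structure beyond the two published pairs is absent by construction.
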