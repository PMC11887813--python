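# Methods

This note documents the models, defaults and numerical choices behind each
pipeline stage, what the synthetic generators do and do not emulate, and
the design decisions taken where more than one reasonable convention
exists.

## Biogeographic clustering

Occurrence records (one genus detection at a georeferenced site) are
clustered with DBSCAN under the great-circle metric. Distances use the
haversine formula on a sphere of radius 6371.0088 km (the IUGG mean
radius); at the radii of interest (25–300 km) the sub-kilometre difference
to an ellipsoidal formula is irrelevant. `min_pts` defaults to 1 so that
no site is discarded as noise — with that setting DBSCAN provably equals
the connected components of the graph joining sites at most `d_max_km`
apart, which is also how the tests verify it (union-find oracle). Cluster
labels are assigned by ascending (minimum latitude, minimum longitude) of
the members so output is order-independent. Records with missing habitat
or physicochemical values are excluded from the affected summary and
counted, never imputed.

## COG occupancy and PCA

Genome occupancy is the per-genome share of coding nucleotides per COG
functional category: a gene of length L annotated with k categories
contributes L/k to each ("equal allotment"); genes without assignment form
the explicit NIC category, which is part of the same denominator, so each
genome's shares sum to 1. Nucleotide length is used directly (`length_bp`
per gene). PCA is the plain centred SVD; component signs are fixed by
making the largest-magnitude loading positive, so results are fully
deterministic. A constant input matrix yields all-zero scores and zero
explained variance rather than an error.

## Core and pan genome

A group is core when present (count ≥ 1) in at least
`ceil(prevalence * n_genomes)` genomes; the 0.95 default reproduces the
41-of-43 rule of family-scale collections. Accumulation curves count
groups first seen at each step of a genome ordering, averaged over random
permutations (or enumerated exhaustively for ≤ 8 genomes, which the tests
exploit for an exact oracle; or taken in the matrix's own row order for
planted discovery processes).

Heaps' law is fitted by unweighted nonlinear least squares of
`n_new(g) = kappa * g**-alpha` on steps g ≥ 2; step 1 is excluded because
every gene is new there by definition. Start values come from a log-log
regression; the reported `alpha_se` is the asymptotic standard error from
the fit covariance. `alpha <= 1` is reported as an open pan genome. The
fit is scale-equivariant (scaling the curve scales κ, leaves α unchanged),
which is tested numerically.

"Binary distance" between genomes is Jaccard distance on ortho-group
presence/absence (a `hamming` alternative is exposed; the coefficient is a
convention, not a derivable fact). The 2-D embedding is classical
(Torgerson) metric MDS — double-centred squared distances, top-2
eigenpairs, negative eigenvalues clipped — with the orientation fixed per
axis by making the largest-magnitude coordinate positive. A stochastic
neighbourhood embedding would serve the same layout purpose but is
deliberately avoided: cluster recovery, not layout aesthetics, is the
tested contract, and classical MDS is deterministic and reconstructs any
2-D-realisable metric exactly (verified to 1e-6 after Procrustes
alignment). k-means runs with 50 restarts at a fixed seed per candidate k;
the chosen k maximises the mean silhouette, ties going to the smallest k.

## Proteome pipeline

Peptide counts are semi-quantitative spectral observations per protein.
The stages and their conventions:

1. **Fraction merging.** Per (strain, condition, replicate, protein), the
   higher of the soluble and membrane-fraction counts is kept. Idempotent.
2. **Replicate filter.** A protein is detected in a condition iff it
   appears in ≥ `min_reps` (default 2) replicates; its abundance is the
   *mean* merged count over the detecting replicates. The summary
   statistic is a choice, not a given — mean was picked as the least
   surprising for replicate counts. Conditions designed with fewer than
   `min_reps` replicates are dropped with a warning. Raw counts are
   never silently lost: the result carries kept/dropped totals that sum
   to the merged table's total.
3. **Constitutive proteome.** Proteins detected under every condition of
   a strain. Antitone in the condition set (adding a condition can only
   shrink it), which is property-tested.
4. **Categories.** The 2×2 cross of core-gene encoded × constitutive,
   with per-category protein counts and peptide-count shares (shares of
   the summed detection-matrix abundance; they sum to 1 per strain).
5. **Abundance distributions.** All logs are base 10; "one log bin" is
   one decade. Per strain × condition, the detected abundances are
   summarised by: richness (number of detected proteins), a decade-binned
   histogram, and a log-normal fitted by moments of log10 abundance. The
   reported mode is the fitted density peak on the count scale,
   `10**(mu - sigma**2 * ln 10)`; the tallest-bin (geometric centre)
   alternative is emitted alongside. Below 10 detected proteins the fit
   is refused and only richness is reported. Per-protein variability is
   the SD (ddof = 1) of log10 abundance over the detecting conditions,
   requiring ≥ 2 conditions (others are excluded and counted); its cdf is
   smoothed with a Gaussian kernel, Silverman bandwidth.
6. **Discrimination diagram.** Per strain, the (richness, log10 mode)
   points over conditions are summarised by a covariance ellipse: centre
   at the mean, axes 2·sqrt(eigenvalue) along the eigenvectors; collinear
   point sets are flagged degenerate.
7. **Co-abundance groups.** Average-linkage hierarchical clustering under
   correlation distance (1 − Pearson) on log10(abundance + 1) profiles
   across conditions, tree cut at 0.5 by default. The +1 shift handles
   undetected-condition zeros; proteins with flat profiles cannot be
   correlated and are reported as trailing groups per distinct profile.
   The grouping algorithm itself is a documented stand-in — hierarchical
   clustering on correlation is the field's default — not an inference
   about any specific published grouping.
8. **Fold-change flags.** A protein is significant between two conditions
   iff its abundance ratio is ≥ 1.5 or ≤ 1/1.5. One-sided detections are
   reported qualitatively as on/off rather than as infinite ratios;
   proteins absent on both sides are excluded.

## Conservation screening

Full profile HMMs iterated against an external homolog database are out of
scope for an offline package; the module instead builds a
position-specific log-odds profile from the seed alignment and preserves
the delta-bitscore contract exactly. Per alignment column (columns with
> 50 % gaps are dropped and counted):

    score(a) = log2( (count_a + pc * bg_a) / (n_eff + pc) / bg_a )

with pseudocount `pc` (default 1), background `bg` (default uniform 1/20,
a supplied vector is accepted) and `n_eff` the non-gap residue count.
Sequences are scored by optimal global alignment to the profile with
affine gap penalties (Gotoh recurrences, vectorised per profile column);
defaults are 11 bits to open and 1 bit to extend a gap — fixed, documented
constants chosen in the range conventional for protein scoring, since the
scoring scheme itself is the free parameter here. The delta bitscore is
reference score minus query score, hence 0 for the reference and
increasingly positive with divergence; it is invariant under adding a
constant to every column (tested) and, for a single substitution on an
unchanged alignment path, equals exactly that column's score difference
(tested against a hand-computed profile). Screening keeps the best hit
per (profile, genome) and filters on a single bitscore threshold; e-value
and bias filters would require a calibrated null model and database
context and are intentionally not imitated.

The operator scanner reports every window offset whose k-mer equals its
own reverse complement up to `max_mismatches` violated symmetric base
pairs (default 0 — strict palindromes). Offsets are 1-based distances
upstream from the 3' end of the supplied sequence to the motif's
downstream edge; the default window (20–40 bp) and motif length (16 bp)
match TetR-type operator placement relative to a transcription start.

## Synthetic generators

All generators are deterministic given `SimulationConfig.seed`; each block
draws from `numpy`'s PCG64 seeded with a fixed (block id, seed) pair, so
enabling or reconfiguring one generator never shifts another's stream.

* **Sites.** Cluster centres are rejection-sampled on the globe (latitude
  −60°…70°) at ≥ 1500 km separation; sites are offset on a local tangent
  plane uniformly within `spread_km` (adequate for spreads ≪ Earth
  radius), 30 clusters × 17 sites ≈ 510 sites by default, with a second
  genus record at ~30 % of sites so occurrences outnumber sites as in
  literature surveys. Genus and habitat weights default to the field
  situation for the five focal genera (the *Desulfosarcina/Desulfococcus*
  group dominating, the marine realm most frequent); physicochemical
  values are uniform over sediment-plausible ranges with ~20 %
  missingness. Not emulated: real coastline/basin geography, spatial
  autocorrelation of the parameters.
* **Pan genome.** 43 genomes, 713 core groups present everywhere, 2000
  shell groups carried per genome with probability 0.3, and
  Poisson(κ·g^−α) novel singleton groups for the g-th genome (κ = 500,
  α = 0.9). Cloud genes being singletons matches the "new genes per
  genome added" reading of openness. Note an exchangeability fact the
  tests rely on: averaging the accumulation curve over random genome
  permutations flattens per-genome planted singleton counts to a
  constant, so planted-α recovery must read the curve in generation order
  (`permute=False`); recovery experiments also switch the shell off,
  because shell turnover decays exponentially with genome index — a
  different mechanism that would otherwise contaminate the early steps of
  the power law. With those settings, mean |α̂ − 0.9| ≈ 0.015 over 20
  seeds at 200 genomes.
* **Proteome.** Per strain (six by default, 8 conditions × 3 replicates ×
  2 fractions, 1000 proteins), latent abundances are log-normal with
  natural-log parameters μ = 3, σ = 1 (median ≈ 20 counts — the scale of
  shotgun spectral counts); 25 % of proteins are constitutive (expressed
  under every condition), the rest belong to substrate modules active
  under random proper subsets of 1–3 conditions. Replicate counts are
  Poisson around the latent abundance (secondary fraction attenuated
  ×0.25); a protein is undetected in a replicate iff its Poisson draw is
  0 (`poisson_zero`), or never (`none`) for exact-recovery tests. This is
  a minimal detection model producing realistic low-abundance dropout; it
  is not a model of any mass spectrometer, and passing recovery tests
  says nothing about identification error, shared peptides, or
  run-to-run normalisation in real data.
* **Family.** Homologs derive from a random ancestor by a fixed number of
  point substitutions at distinct positions; the alignment is the trivial
  ungapped one. This supports exact column-level oracles for the
  delta-bitscore stage; it is not a phylogenetic evolution model.

## Problem sizes and tolerances

The test suite and the acceptance script run at desk scale: 200 sites for
the clustering oracle, 5 genomes for exhaustive permutation enumeration,
200-genome × 20-seed pan genomes for α recovery (tolerance: mean absolute
error ≤ 0.05), 2000 proteins for abundance-mode recovery (tolerance: one
decade; observed ≈ 0.01–0.02), and 20-seed screening of planted homologs
(5 substitutions on a 60-residue ancestor) against random decoys, where
score distributions separate cleanly and sensitivity = specificity = 1.0
is required exactly. Metric axioms are asserted to 1e-9 km, MDS
reconstruction to 1e-6 after Procrustes alignment, silhouette and
eigen-oracles to 1e-9.

## Known limitations

* Ortholog inference, genome annotation and homolog harvesting are
  consumed as pre-made tables/FASTA, never recomputed.
* The profile scorer is a PSSM with affine gaps, not a profile HMM; its
  bitscores are not comparable to HMMER's, only its delta contract is.
* The log-normal abundance fit uses moments of detected (truncated-at-
  zero) counts; at very low abundance the Poisson detection floor biases
  the mode upward — negligible at the default μ = 3, σ = 1.
* Co-abundance grouping and the replicate summary statistic (mean) are
  conventions exposed as parameters, not uniquely determined procedures.
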