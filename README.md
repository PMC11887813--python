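# congenerics

Comparative proteogenomics toolkit for families of sulfate-reducing
bacteria (*Desulfobacteraceae*-style studies): where do the organisms
occur, how open is their pan genome, which proteins do they always make,
and how conserved are their catabolic genes?

The package implements, as a tested and reusable pipeline, the analysis
stages such studies chain together:

* **Biogeography** — density-based clustering (DBSCAN) of georeferenced
  occurrence records under the great-circle metric (`d_max` = 300 km for a
  global view, 25 km for regional detail), with per-cluster genus
  composition, habitat frequency, and physicochemical summaries.
* **Comparative genomics** — COG genome-occupancy profiles (per-genome
  nucleotide share per functional category, multi-category genes split
  equally) with PCA; and ortho-group count-matrix analytics: core-genome
  calling at ≥ 95 % prevalence (41 of 43 genomes), gene accumulation
  curves, Heaps' power-law openness fit *n*<sub>new</sub>(*g*) = κ·*g*<sup>−α</sup>
  (α ≤ 1 ⇒ open pan genome), Jaccard presence/absence distances, a
  deterministic 2-D metric-MDS embedding, and silhouette-selected k-means.
* **Proteomics** — the replicate peptide-count pipeline: merge soluble and
  membrane fractions by the higher count, require detection in ≥ 2
  replicates per condition, call the constitutive proteome (proteins
  detected under *every* growth condition), cross it with core-genome
  membership into a 2×2 category table with peptide-count shares,
  characterise per-condition abundance distributions (log-normal fits,
  density mode, richness, decade-binned histograms, per-protein log-SD
  cdf), group proteins by co-abundance, and flag |1.5|-fold changes.
* **Conservation screening** — position-specific log-odds profiles built
  from seed alignments, affine-gap (Gotoh) bitscores, and delta bitscores
  (reference minus query; 0 at the reference) for gene-conservation
  heatmaps, plus a scanner for 16-bp palindromic operator motifs ~20–40 bp
  upstream of a transcription start.
* **Synthetic data** — generators for all of the above with planted ground
  truth (cluster centres, core ortho-groups and the cloud power-law
  exponent, constitutive protein sets, substitution positions), used by
  the test suite for exact recovery checks.

## Worked example

```python
from congenerics import (SimulationConfig, simulate_pangenome,
                         simulate_proteome_counts)
from congenerics.genomics import accumulation_curve, core_genome, fit_heaps
from congenerics.proteomics import (constitutive_set, merge_fractions,
                                    replicate_filter)

cfg = SimulationConfig(seed=1)          # 43 genomes, 713-group core, alpha 0.9
matrix, truth = simulate_pangenome(cfg)

core = core_genome(matrix, prevalence=0.95)
fit = fit_heaps(accumulation_curve(matrix, n_permutations=100, seed=1))
print(len(core), round(fit.alpha, 2), fit.openness)
# -> 713 0.89 True

cfg.pangenome.shell_size = 0            # isolate the planted discovery law
matrix, truth = simulate_pangenome(cfg)
fit = fit_heaps(accumulation_curve(matrix, permute=False))
print(round(fit.alpha, 3), "+/-", round(fit.alpha_se, 3), fit.openness)
# -> 0.905 +/- 0.018 True

counts, truth = simulate_proteome_counts(cfg)
dm = replicate_filter(merge_fractions(counts), min_reps=2)
const = constitutive_set(dm)
print({s: len(p) for s, p in sorted(const.items())})
# -> {'Dbt': 250, 'Dcm': 248, 'Dnl': 247, 'Dnm': 249, 'Dsv': 249, 'Dta': 248}
```

All 713 planted core groups are called at the 41-of-43 prevalence
threshold and the pan genome is diagnosed as open (α ≤ 1).  On the pure
discovery process (generation order, shell component off) the planted
α = 0.9 is recovered within the fit's standard error.  The constitutive
proteomes recover the planted 250 constitutive proteins per strain up to
a few Poisson-dropout losses.

The same stages are scriptable from the shell:

```bash
congenerics simulate --seed 1 --out data/
congenerics biogeo    --occurrences data/occurrences.csv --dmax-km 300 --out out/
congenerics pangenome --matrix data/ortho_groups.tsv --out out/
congenerics proteome  --counts data/peptide_counts.tsv --min-reps 2 --out out/
congenerics conserve  --msa-dir msas/ --genes-dir genomes/ --ref-genome ref --score-min 0 --out out/
congenerics operators --fasta upstream.fna --len 16 --window 20:40 --out ops.tsv
```

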