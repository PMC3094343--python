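# qkforest

Association mapping for collections scored with dominant binary markers
(AFLP-style bands, binarized SSR alleles), with explicit control of population
structure. The package implements, as one tested pipeline:

- **Synthetic data** (`qkforest.simdata`) — admixed populations
  (Balding–Nichols subpopulation frequencies, Dirichlet memberships), dominant
  marker sampling, and confounded multi-trait phenotypes with a polygenic term
  `g ~ MVN(0, sigma_g2 * K)`; ground truth stores every phenotype component.
  Also houses marker preprocessing (per-allele SSR binarization,
  most-frequent-allele reduction, the >10% allele-frequency filter) and
  TSV/CSV I/O.
- **Population structure** (`qkforest.popstruct`) — Jaccard distances,
  principal coordinates, kernel-density mode clustering with bootstrap
  stability, and a haploid admixture Gibbs sampler producing the membership
  matrix Q (plus per-K log-likelihood reporting and >0.70 hard assignment).
- **Kinship** (`qkforest.kinship`) — frequency-corrected allele-sharing and
  Jaccard-similarity estimators, and the kinship-class histogram.
- **Association scans** (`qkforest.assoc`) — four nested models per marker:
  naive OLS, +Q covariates, K-only mixed model, and the Q+K mixed model
  (spectral REML, EMMAX-style null-model-once whitening by default, with an
  exact per-marker strategy). Multiple testing via Benjamini–Hochberg FDR or
  step-down maxT resampling; one-way ANOVA + LSD subpopulation summaries.
- **Random forest** (`qkforest.rf_assoc`) — regression forests with OOB-tuned
  mtry, unscaled IncMSE importance, and a per-marker permutation null
  (forests refit on permuted responses) for significance calls.
- **Networks** (`qkforest.netstats`) — full-order partial correlations
  (matrix inversion or identity-target shrinkage), trait–trait edges at
  alpha = 0.05, marker–trait edges weighted by −log10(adjusted p), exported
  as Pajek `.net` and TSV edge lists.
- **Pipeline** (`qkforest.pipeline`) — simulate → structure → kinship →
  scans → RF → network → comparison report, with per-stage seeds, content-hash
  manifest, and bitwise-reproducible reruns.

## Tests

```sh
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the end-to-end acceptance properties
(confounding contrast across the four models, brute-force GLS/REML and
partial-correlation oracles, admixture and variance-component recovery, RF
permutation-test calibration, multiple-testing calibration, format fidelity).
One assertion is intentionally red — see
`TestCriterion1Confounding::test_crit1_k_only_tracks_naive` and its
docstring: a kinship matrix estimated from the same differentiated markers
that generate the confounding necessarily corrects structure, so the K-only
model cannot track the naive model under that simulation design.

## CLI

```sh
qkforest simulate --n 168 --subpops 4 --fst 0.25 --markers 400 --out sim/
qkforest structure sim/markers.tsv --k 4 --iters 3000 --burnin 1000 --out struct/
qkforest kinship sim/markers.tsv --estimator freqcorr --out K.tsv
qkforest assoc sim/markers.tsv sim/phenotypes.tsv --model 4 \
    --q-file struct/Q.tsv --k-file K.tsv --correction bh --out scan4.tsv
qkforest rf sim/markers.tsv sim/phenotypes.tsv --trees 5000 --perm 1000 --out rf.tsv
qkforest network sim/phenotypes.tsv --scan-file scan4.tsv --out network
qkforest compare scan1.tsv scan4.tsv rf.tsv --out overlaps.tsv
qkforest run config.yaml        # full pipeline from a YAML config
```

A pipeline YAML config mirrors `qkforest.pipeline.PipelineConfig`, e.g.:

```yaml
sim:
  n_accessions: 168
  n_subpops: 4
  fst: 0.25
  admix_alpha: 0.5
  n_markers: 400
  n_traits: 3
  pop_effects: [1.0, 0.3, -0.3, -1.0]
  seed: 1
outdir: run_out
seed: 1
structure_k: 4
correction: bh
rf_trees: 500
rf_perm: 200
```

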