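# keyhabitat

A tested pipeline for identifying *key habitats* — areas that combine a
high modelled probability of historic species occurrence with currently
optimal habitat condition — and for turning the result into an IUCN A2
extinction-risk assessment. All inputs are synthetic: a generator module
produces spatially autocorrelated environmental layers, presence-only
records, ground-truth designs, and 16-day vegetation-index (EVI) time
series with known structure, so every stage is testable offline.

## Stages

1. **synth** — seeded synthetic landscapes (coarse ≈ 1 km / fine ≈ 250 m
   grids), presence records drawn from a logistic occurrence surface with
   known coefficients, ordinal ground-truth labels
   (poor < acceptable < good < excellent), and EVI series with a seasonal
   cycle, a single change point, and multinomial QA ranks.
2. **studyarea** — nearest-neighbour resampling, closed-interval
   binarization of elevation / tree cover / aridity, and mask intersection.
3. **occurrence** — presence-only maximum-likelihood occurrence model
   (logistic ψ, likelihood normalized over study-area cells), covariate
   clustering by |Pearson r|, replicated 75/25 partitions, AICc model
   selection, evaluation against pseudo-absences (AUC, point-biserial cor,
   max kappa, maxSSS), threshold selection as the mean max-kappa of the
   best replicates, and fine-grid prediction.
4. **evi** — QA filtering (best available rank per composite date),
   at-most-one-change detection in mean and variance under a two-segment
   Gaussian likelihood with an MBIC-style penalty, prior/current segment
   contrasts, and 23-period post-change phenology medians.
5. **classify** — random-forest mapping of phenology to the ordinal
   suitability category, ordered-weight correction of the out-of-bag
   confusion matrix, and a vote-weighted suitability index in [0, 3].
6. **keyhab** — overlap index (ψ × suitability index), key-habitat
   delineation, Area of Occupancy, percent decline, protected fraction,
   and the IUCN A2 category (≥30 Vulnerable / ≥50 Endangered /
   ≥80 Critically Endangered).

## CLI

Every command reads an optional YAML config (see
`keyhabitat.pipeline.DEFAULT_CONFIG` for the schema and demo defaults) and
runs the pipeline deterministically up to the named stage:

```bash
keyhabitat run --seed 1 --out scratch/demo          # full pipeline
keyhabitat simulate --seed 1 --out scratch/demo     # synthetic data only
keyhabitat key-habitats --t-psi 0.743 --include excellent,good \
    --seed 1 --out scratch/demo
```

Outputs are text artifacts — ESRI ASCII grids (`.asc`), CSV, JSON — plus a
`manifest.json` with SHA-256 checksums; a rerun with the same config and
seed reproduces the checksums. The demo profile uses a 60×60 coarse grid
and a 500-tree forest; the full-scale analysis (50,000 trees) is the
`classify.n_trees` knob and is slow.

Note: the demo config's study-area bounds differ from the module defaults
in `keyhabitat.studyarea` — the defaults describe real-world layer ranges
which a synthetic smoothed-noise field occupies very differently.

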