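# menet

A mixed-effect deep network for genomic prediction — predicting quantitative
traits of genotyped individuals (crop lines, breeding populations) from a
model trained on genotyped and phenotyped individuals, so that field testing
can be reduced to a fraction of the panel.

Classical mixed models split a trait into fixed marker effects and a random
effect carried by genetic relatedness:

    y = b0 + Σ_i beta_i X_i + Σ_{(i,j) ∈ C} theta_ij X_i X_j + Z gamma + eps

with genotype codes X ∈ {1, 0, −1}, pairwise epistatic terms theta_ij over
an unknown pair set C, and a relatedness-driven random effect Z gamma.
`menet` learns both halves neurally and fuses them:

* **RepGeno** (random-effect branch): an encoder trained with a trait-aware
  triplet loss, `L = log(1 + exp(d⁺ − d⁻ + m_γ))` with adaptive margin
  `m_γ = Δ⁻ − Δ⁺ + ε·margin`, producing unit-norm embeddings whose
  distances encode phenotype-aware genetic relatedness (exported as a
  [0, 1]-scaled kinship-style matrix).
* **VE** (fixed-effect branch): a residual 1-D convolutional network over
  the marker sequence capturing cumulative, possibly nonlinear variant
  effects; chromosome-aware windowing keeps it tractable for large marker
  counts.
* **Cross-information feature fusion**: residual corrections
  `ẑ_VE = z_VE + F_VE([z_VE; z_RepGeno])` (and symmetrically for RepGeno)
  followed by a three-layer prediction head.

The package also provides the surrounding tool chain: VCF/matrix genotype
I/O with MAF filtering and sliding-window LD pruning, a synthetic
multi-family panel and trait simulator (LD blocks, epistasis, G×E,
family random effects, heritability calibration), two-stage training with
checkpointing by validation R², cross-environment transfer learning
(fine-tune F_VE + head on 10% of a target environment), integrated-gradients
branch attribution, and standard metrics with a ridge-regression linearity
baseline. Everything runs on plain NumPy with hand-verified gradients — no
GPU or deep-learning framework required at the bundled desk scale.

## Worked example

```python
import menet

# a 3-family panel with LD blocks and an additive + family trait
gm, labels = menet.simulate_genotypes(
    menet.PopulationSpec(n_samples=600, n_markers=500, n_populations=3,
                         divergence=0.15, seed=7))
arch = menet.random_architecture(500, n_additive=30, family_variance=1.0,
                                 target_h2=0.7, seed=8)
phenos = menet.simulate_trait(gm, labels, arch)

model = menet.MeNet(gm, phenos, labels=labels)
res = model.fit(seed=7)          # stage 1: triplet encoder; stage 2: VE+fusion+head
print(res.summary())
rep = res.contributions()        # integrated-gradients branch weights
print(f"w_VE = {rep.w_ve:.2f}, w_RepGeno = {rep.w_repgeno:.2f}")
```

The output printed by this exact script:

```
                Mixed-Effect Genomic Prediction Results
====================================================================
Environment:        E1                   N samples:     600
N markers:          500                  Embed dim:     64
VE channels:        8                    Segments:      1
Best epoch:         100                  Seed:          7
--------------------------------------------------------------------
metric        validation          test
R2                0.2685        0.2774
PCC               0.5181        0.5267
MAE               5.4650        5.3061
NMSE              0.8165        0.8322
====================================================================
R2 is the squared Pearson correlation between predicted and
observed phenotypes on the held-out split.
w_VE = 0.88, w_RepGeno = 0.12
```

Read it as: on the 20% held-out test split the model explains ~28% of
phenotypic variance (R² as squared Pearson correlation; the trait's
heritability is 0.70, so roughly 40% of the heritable signal is recovered
at this small desk-scale sample size), and the integrated-gradients
attribution assigns most of the prediction to the variant branch —
consistent with a trait driven by 30 moderate additive effects rather than
by family structure.

A YAML-driven command-line interface wraps the same pipeline
(`menet --config cfg.yaml --seed 1 --out runs/demo`); stages are
`simulate`, `preprocess`, `train-repgeno`, `train`, `transfer`, `attribute`,
`evaluate`, or `pipeline` for the whole chain.

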