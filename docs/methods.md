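# Methods

## The model

`menet` implements a mixed-effect deep network for genomic prediction. The
starting point is the nonlinear mixed model for a quantitative trait,

    y = b0 + Σ_i beta_i X_i + Σ_{(i,j) in C} theta_ij X_i X_j + Z gamma + eps,

where `X_i` in {1, 0, -1} codes the genotype at marker *i* (homozygous
alternate / heterozygous / homozygous reference), `C` is a set of pairwise
epistatic interactions, `Z gamma` is a family-level random effect carrying
genetic relatedness, and `eps` is environmental noise. Fitting this model
explicitly is impractical (the pair set `C` is unknown and enormous), so the
network learns its two halves as two branches:

* **Random-effect branch (RepGeno).** A fully connected encoder
  (p → hidden → E, L2-normalised rows) maps a genotype vector to a unit-norm
  embedding. It is trained with a trait-aware triplet loss

      L = log(1 + exp(d+ − d− + m_gamma)),   m_gamma = D− − D+ + eps_m · margin,

  where `d±` are Euclidean distances between the normalised embeddings of the
  anchor and a positive (same family) / negative (other family) sample, and
  `D±` are the corresponding absolute phenotype differences (phenotypes are
  z-scored before computing `D±` so the adaptive margin lives on a unit
  scale). Without family labels, two random candidates are drawn per anchor
  and the phenotypically closer one serves as positive. Relatedness between
  two samples is the embedding distance scaled to [0, 1] by its analytic
  maximum (division by 2 for unit vectors); min–max scaling is available as an
  option.

* **Fixed-effect branch (VE).** A one-dimensional residual-convolutional
  network over the marker sequence: one convolution (kernel 3, stride 1, same
  padding), two residual blocks (two convolutions plus a skip each), adaptive
  average pooling to a fixed length, then two fully connected layers to an
  E-dimensional embedding. Adaptive pooling makes the embedding size
  independent of the marker count.

* **Cross-information feature fusion.** With z = [z_VE; z_RepGeno],

      z_VE_hat      = z_VE      + F_VE(z)
      z_RepGeno_hat = z_RepGeno + F_RepGeno(z),

  where F_VE and F_RepGeno are independent three-layer bottleneck networks
  (2E → E/2 → E/2 → E) whose output layers are zero-initialised, so the
  correction starts exactly at the identity. The corrected pair, concatenated,
  passes through a three-layer head to the scalar prediction.

* **Chromosome-aware windowing.** Above a marker-count threshold (100 000 by
  default) the genotype is partitioned by chromosome, each segment gets its
  own VE instance, and segment embeddings are merged by an extended fusion
  step (each segment corrected against the concatenation of all segments,
  then projected back to E) before branch fusion. Over-long chromosomes fall
  back to fixed-size windows.

## Training

Training is two-stage. Stage 1 trains the RepGeno encoder alone with the
triplet loss (one triplet per anchor per epoch, resampled every epoch;
AdamW). Stage 2 freezes the encoder by default and trains VE + fusion + head
with mean absolute error, AdamW (batch 128, weight decay 1e-4), a
reduce-on-plateau schedule on validation R² (patience 10, factor 0.5, floor
1e-6), and checkpoint selection by validation R². The two-stage split follows
from the transfer protocol, which treats the relatedness encoder as a
separable frozen unit; a joint fine-tuning flag exists for the variant where
stage 2 also updates the encoder.

Targets are standardised on the training split inside the network (the head
learns on unit scale; `forward` returns trait units), so the MAE gradient
scale is independent of the trait's units. R² is, throughout, the squared
Pearson correlation between predictions and observations — the convention
under which a linear predictor is bounded by heritability — with the
1 − SSres/SStot form also computed and reported.

Cross-environment transfer freezes the RepGeno encoder, the VE trunk and
F_RepGeno and fine-tunes exactly F_VE and the head on 10% of the target
samples (5% train, 5% validation); the remaining 90% is the held-out test
set. The frozen tensors are bit-identical before and after fine-tuning, a
property asserted in the tests.

Branch contributions are measured post hoc with integrated gradients on the
fused embedding z (zero baseline, midpoint Riemann rule, 256 steps by
default): S_branch sums the per-dimension mean absolute attribution over the
branch's named index set, and w_VE = S_VE / (S_VE + S_RepGeno). The
concatenation order of the fused vector is tracked explicitly by index sets
rather than assumed.

## Numerical and design choices

* **NumPy network core.** All layers (dense, 1-D convolution, residual
  blocks, adaptive pooling) carry hand-written backward passes verified
  against central finite differences in the test suite; AdamW is implemented
  with decoupled weight decay. Everything is float64 and driven by explicit
  `numpy.random.Generator` seeds, so training is bit-reproducible.
* **Smooth activations in fusion and head.** The attribution function
  F = head ∘ fusion is the integrand of the IG path integral. With ReLU
  units its gradient jumps at kink crossings and the midpoint rule stalls at
  1–4% completeness error at 256 steps; with `softplus(βx)/β` (β = 8) units —
  ReLU-like in optimisation, infinitely differentiable — the completeness gap
  drops below 0.01%. The VE trunk, which IG never differentiates, keeps
  plain ReLU.
* **Branch scale.** The unit-norm RepGeno embedding has per-entry scale
  ~1/√E while VE entries are O(1); the network rescales the RepGeno embedding
  by √E before fusion so neither branch is favoured at initialisation
  (`ModelConfig.rescale_repgeno`).
* **Allele orientation.** Hom-alternate = 1, hom-reference = −1; any
  consistent orientation yields the same model class. Heterozygote and
  imputed-missing both code to 0 — a property of the coding, documented, not
  repaired.
* **LD pruning.** r² is the squared Pearson correlation of encoded columns;
  windows are base-pair sliding windows (2000 bp / step 1000 bp by default)
  with a marker-count mode available; the greedy rule keeps the
  earlier-position marker of a violating pair, a deterministic tie-break.
  MAF is computed after encoding; filtering precedes pruning.
* **Desk-scale defaults.** Embedding dimension 64, 8 convolution channels,
  pooling length 64, learning rate 3e-3. The full-scale search grids
  (margin {0.1–0.5}, channels {1,2,4,8,16,64}, embedding {512–8192}) are
  preserved as constants and in `grid_search`, but the synthetic studies all
  run at the desk-scale point so the whole suite fits in CPU minutes.

## The synthetic-data generator

The generator emulates the statistical structure of multi-family breeding
panels (recombinant inbred lines):

* **Families.** `n_populations` families; family-specific allele-frequency
  offsets drawn N(0, divergence²) around the base frequency create
  between-family divergence. Family labels are returned for triplet
  sampling.
* **LD blocks.** Within a block, every sample copies one of a small pool of
  founder haplotypes (default 4) and mutates each marker independently
  (default 0.03); LD strength falls with pool size and mutation rate, blocks
  are independent. Blocks of size one are drawn i.i.d., making single-marker
  allele frequencies exactly binomial.
* **Inbreeding.** The second haplotype equals the first apart from a small
  residual heterozygosity (default 0.05), so codes are mostly ±1, as in RIL
  panels.
* **Traits.** Per environment e: y = b0 + s_e ⊙ (additive + epistatic) +
  Z gamma + eps_e. Epistatic partners are drawn within a small marker
  distance of each other (default 3), emulating cis interactions between
  variants on a shared haplotype block — which also respects the locality
  assumption built into the convolutional branch. Noise is solved from the
  realised heritable variance so the target h² holds regardless of epistasis
  or family effects. Two environments with genetic correlation ρ are built
  by scaling every marker effect in the second environment by
  ρ + √(1−ρ²)·z_i, z_i ~ N(0,1).

What the generator does **not** emulate: recombination maps and
coalescent-grade LD decay, dominance, multi-allelic sites, genotyping error,
phenotype non-normality, and selection-induced allele-frequency structure.
Passing tests therefore show that the implementation realises the method's
mechanisms under its own assumptions — not that those mechanisms transfer to
any particular real panel.

## Study conditions used by the tests and the acceptance script

* **Embedding structure**: 3 families, n = 600, p = 500, divergence 0.15,
  additive + family trait (h² = 0.7); after 30 triplet epochs, within-family
  embedding distances must fall below between-family distances and correlate
  positively (Spearman) with phenotype differences.
* **Nonlinearity capture**: purely epistatic trait (20 pairs with a
  decaying interaction spectrum, θ_k = ±2·0.8^k, h² = 0.6; n = 1500 in the
  tests, 2000 in the acceptance script; p = 500) on a balanced-haplotype
  panel (base MAF 0.5, symmetric founder pools), where marker products
  carry exactly zero linear signal and the ridge baseline (α = 1) sits at
  R² ≈ 0 for any penalty; the trained network (16 channels, pooling length
  128) must exceed the ridge test R² on every seed.
* **Adaptive contributions**: oligogenic trait (5 loci, |β| large, h² = 0.8,
  n = 1000, p = 300) must attribute the majority of IG mass to the VE
  branch; a polygenic trait (every marker a small effect, strong family
  structure: n = 300, p = 500, 12 families, divergence 0.2, family variance
  dominating) must attribute the majority to RepGeno; majority over 3
  seeds. The contrast works because adaptive pooling limits the variant
  branch to coarse-grained marker weightings while the dense relatedness
  encoder, trained with explicit family supervision, weights every marker
  individually.
* **Transfer**: two environments at genetic correlation 0.7 (n = 1000,
  p = 300); a source-trained model fine-tuned on 10% of the target must beat
  from-scratch training on the same 10% for the majority of 3 seeds.
* **Determinism**: the full pipeline run twice with one seed must produce
  byte-identical metric files.

Problem sizes are the package's chosen desk-scale study conditions; they are
what the bundled acceptance script (`scripts/acceptance.py`) re-runs from
scratch.

## Known limitations

* The VE branch's receptive field before pooling spans ~11 markers; distant
  epistatic pairs (beyond the receptive field) are effectively invisible to
  the desk-scale configuration, and at these sample sizes neural fits do not
  reliably beat a well-conditioned linear baseline on the *linear* share of
  genetic variance. Both behaviours match the method's stated motivation for
  large panels rather than contradicting it.
* The relatedness embedding fed to fusion is the encoder output (the
  distance-profile variant mentioned as an alternative is exposed only
  through `relatedness_matrix`).
* `transfer_finetune` keeps the source environment's target-standardisation
  constants; with very different target trait scales the head compensates
  through its trainable weights.
* Heterozygote/missing conflation is inherent to the {1, 0, −1} coding.
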