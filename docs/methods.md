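# Methods

## Overview

`igwas` implements, at desk scale, a complete imaging-genetics workflow:
learn quantitative phenotypes ("endophenotypes") from paired left/right
retinal fundus images with self-supervised contrastive learning, then run
linear-mixed-model GWAS on every learned coordinate, replicate across the
two eyes, merge significant variants into loci, and interpret the summary
statistics with LD-score regression. Because the real cohorts such a study
needs are access-controlled, the package is driven end to end by a
synthetic genotype-to-image simulator with known ground truth; every
statistical claim the test suite makes is a claim about recovery of that
ground truth.

## Synthetic cohort model

**Genotypes.** SNPs are laid out in blocks of `ld_block_size` on
`n_chromosomes` autosomes, positions on a fixed stride (default 5 kb, 1-based).
Within a block a latent Gaussian follows an AR(1) process with parameter
`within_block_r`; each SNP's latent value is cut at the Hardy–Weinberg
quantiles of its minor-allele frequency (drawn uniformly from `maf_range`),
yielding dosages in {0,1,2} with exactly HWE marginals and tunable
between-SNP correlation. Blocks are independent, which gives clean ground
truth for locus clumping. This Gaussian-copula construction trades
population-genetic realism (no recombination maps, no allele-frequency
spectrum) for direct control of the two quantities the downstream methods
are sensitive to: MAF and local r².

**Latent traits.** Pigmentation and vessel density are unit-variance traits
built as Σ_k √(v_k)·z_k + e, where z_k is the sample-standardized dosage of
causal SNP k, v_k its variance explained, and e Gaussian noise topping the
variance up to 1. The disease grade (0–4) is a threshold function of the
vessel trait, giving the auxiliary classification head an ordinal target.
Age is uniform on 40–70 years; sex is Bernoulli(1/2) and has no effect on
the images (it exists to exercise covariate adjustment).

**Images.** Each subject has a deterministic base rendering (subject-seeded):
a circular field of view whose background color darkens with pigmentation
(channel slopes −20/−14/−8 intensity units per pigment SD), a radial
vignette, a foveal dark spot, and a recursive bifurcating vessel tree whose
recursion depth grows with the vessel trait and whose angles/lengths come
from the subject's own random stream — so the tree is a subject-identifying
texture shared by both eyes. The right eye is the horizontal mirror of the
base rendering. Per-image nuisance is then applied independently: rotation
uniform in ±15°, multiplicative illumination noise (default SD 1%), and
optional Gaussian blur. With all nuisance disabled, flip(left) == right
bit-exactly. Defaults are 128×128 pixels rather than the 1536×2048 of real
fundus photographs; every window defined on the full-scale grid is mapped
fractionally.

What the simulator does **not** model: camera vignetting profiles, real
vessel anatomy, lesions with spatial pathology structure, cross-site domain
shift, or any pleiotropy between pigment and vessel traits. Passing tests
therefore demonstrate that the pipeline machinery is correct and calibrated,
not that the learned phenotypes transfer to real retinas.

**Quality corpus.** Bad-quality images are good renderings degraded by heavy
blur (σ 3–6), severe under-/over-exposure with mild defocus, or a large
occluding patch followed by mild defocus; the defocus reflects that badly
acquired fundus photographs are rarely sharp, and it makes Laplacian-variance
sharpness a faithful separator of the two classes.

## Quality control

A 4-layer convolutional scorer (two 3×3 conv blocks with average pooling,
then two dense layers) maps a block-averaged 32×32 image to a score in
[0,1], trained with binary cross-entropy, an 80/20 seeded split and early
stopping (patience 5). Downstream selection keeps images with score > 0.5
and ranks by score (the top-quality floor 0.95 is exposed). AUROC is the
Mann–Whitney rank statistic (ties count ½); PPV/NPV/sensitivity/specificity
come from the 2×2 table at threshold 0.5.

## Contrastive phenotyper

Each subject is a class with a learnable unit-norm template vector. The
encoder (same convolutional body as the quality net, with a d-dimensional
head, L2-normalized output) is trained with an additive-angular-margin
softmax: the target logit is s·cos(θ_target + m), non-target logits are
s·cos(θ_j) over all other subjects' templates, and the loss is the mean
negative log-probability of the correct template. Defaults s = 30 and
m = 0.5 rad, the standard operating point for this loss family; both are
exposed. With m = 0 the loss is exactly softmax cross-entropy over cosine
logits, which the tests verify against an independent implementation.

Right-eye images are mirrored before encoding (train and inference);
random rotations in ±15° are applied at train time only. When disease
grades are supplied, an auxiliary 5-class head on the shared features is
weighted 1:10 against the contrastive loss. The train/validation split is
80/20 **by subject**; because held-out subjects have no learned template,
the model-selection criterion is a template-free variant of the same loss
in which each held-out subject's left-eye embedding acts as their template
and their right-eye embedding is scored against all of them. The parameters
with the lowest such held-out loss are retained.

The default learning rate is 1×10⁻⁴ (Adam), appropriate for long schedules
on a large backbone. The desk-scale experiments in `igwas.experiments` use
3×10⁻³ for the small encoder trained ≤30 epochs; with the small rate the
encoder barely moves in so few steps. Both are ordinary config knobs.

Pair diagnostics: matched pairs are each subject's (left, right) cosine
similarity; random pairs are sampled across subjects without replacement.
The Jensen–Shannon distance (base 2, square root of the divergence) and the
Jaccard index (histogram intersection over union) are computed on fixed
80-bin histograms over [−1, 1]; KDE curves use Scott's bandwidth × 0.5.
The mean random-pair similarity is reported (deep encoders typically show a
"cone effect" with random pairs centered well above 0); no numeric target
is asserted for it on synthetic data.

## Retina color phenotypes

Per image, the mean R/G/B of the central foveal patch: on the 1536×2048
reference grid the half-open 0-based window rows [600:1000), cols
[800:1200) — exactly 400×400 pixels, slightly off the geometric center; at
other resolutions the same fractional window with floor rounding, which
preserves the offset rather than recentering. Right eyes are mirrored first.

## LMM association engine

The GRM is K = ZZᵀ/M with Z the GCTA-standardized dosages
(z = (d − 2p̂)/√(2p̂(1−p̂)), sample allele frequency p̂, mean-imputed
missing values) over SNPs passing the MAF filter (default 0.01) with
nonzero variance. Ancestral PCs are the top eigenvectors of K, sign-fixed.
REML for y = Xβ + g + e (g ~ N(0, σ²_g K)) uses one eigendecomposition of
K and a bounded scalar search over log(σ²_g/σ²_e) ∈ [−10, 10] (tolerance
1e-8); the exact σ²_g = 0 boundary is also evaluated so the OLS limit is
hit exactly. Per-SNP tests are GLS Wald χ²₁ under the fitted covariance,
with covariates projected out in the V⁻¹ metric — the exact statistic that
large-cohort infinitesimal-model solvers approximate iteratively. LOCO is
on by default: each chromosome is tested under the GRM built from all
other chromosomes, with variance components refitted per left-out
chromosome. Monomorphic or filtered SNPs are emitted with β = 0, p = 1 and
a flag so both eyes always share one SNP universe. P-values are floored at
1e-300. λ_GC is median(χ²)/0.454936 (the χ²₁ median at full precision).

## Post-GWAS

Dual-eye replication: a variant is selected iff the minimum p over traits
passes 5×10⁻⁸ in the left eye **and** in the right eye (the eyes are never
meta-analyzed); the smaller minimum is reported. Loci are connected
components (union-find) of the graph linking same-chromosome selected
variants with r² > 0.2 **or** distance ≤ 250 kb — single-link closure, with
the lead SNP the smallest reported p (ties broken by position). LD scores
are windowed sums of r² (default 1 Mb, self term included). LDSC fits
E[χ²_j] = 1 + N·h²·l_j/M by unweighted OLS with a free intercept (h² =
slope·M/N); the bivariate form regresses z₁z₂ on l with rg = ρ_g/√(h²₁h²₂),
clipped to ±1.25 with a warning. Standard errors use a 20-block jackknife.
Full LDSC weighting/regularization is deliberately out of scope. Catalog
range queries use closed intervals with a 250 kb flank and refuse
mismatched genome builds.

## Pipeline and determinism

`run_pipeline` executes the stages in order, writes every tabular artifact
as TSV with floats at 6 significant digits, and records sha256 checksums in
a manifest. All randomness derives from one master seed through named
CRC-keyed substreams, so two runs from the same config and seed are
byte-identical; numpy's CPU kernels are deterministic. Stage toggles let a
run reuse on-disk artifacts; a missing upstream artifact raises an error
naming the stage to enable.

## Experiment scales

The standard evaluation conditions (in `igwas.experiments`) are: null
calibration at 500 subjects × 2,000 independent SNPs; recovery cohorts of
1,000 subjects × 500 SNPs on 5 chromosomes with five causal pigmentation
SNPs at 5% variance explained each (one per chromosome, so "causal locus
recovered" is unambiguous); contrastive separation at 200 subjects, d = 16,
30 epochs; quality benchmark at 200 good / 200 bad training images
evaluated on a fresh corpus; LDSC recovery at h² = 0.3, N = 1,000,
M = 2,000, 50 replicates. The phenotyper in the recovery experiment trains
on 150 subjects (d = 8, 20 epochs) and embeds the full cohort, mirroring
the design where the phenotype-development set and the GWAS cohort are
different populations.

## Known limitations

- The loss is optimized with plain Adam on a small CNN; no learning-rate
  schedule, weight decay, or large-batch tricks.
- REML assumes a single genetic variance component; no binary-trait or
  X-chromosome models.
- LDSC here is the unweighted textbook regression; intercept-based
  confounding diagnostics are less stable than the fully weighted original.
- The simulator's block-LD world makes clumping easier than real LD does;
  recovery rates on synthetic data are upper bounds.
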