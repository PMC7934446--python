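# Methods

## Generative model

`atacsim` models one cell group's bin-by-cell count matrix with three
coupled components, estimated from data and then sampled in a fixed
order.

**Library sizes.** Per-cell totals are modeled on the log₂ scale as a
two-component Gaussian mixture, log₂ lᵢ′ ~ w·N(μ₁, σ₁²) +
(1−w)·N(μ₂, σ₂²). The EM fit initializes responsibilities by a median
split of the data, iterates to a log-likelihood tolerance of 1e-6 with
at most 500 iterations, and floors each component variance at 1e-6 so a
point mass cannot collapse the fit. Components are reported with
μ₁ ≤ μ₂ so parameter order is reproducible. A starved component (zero
responsibility mass, e.g. on constant input) is re-centred on the
pooled mean rather than drifting to zero. The unimodal convention
(`platform_hint="unimodal"`, appropriate for non-droplet platforms)
returns w = 1 with both components equal; `"auto"` fits both and picks
by BIC (2 vs 5 free parameters). Sampled library sizes are kept
continuous — they only ever enter as Poisson means.

**Sparsity.** The per-bin non-zero cell proportion p_j is the exact
fraction of cells with a positive count. Simulation draws a Bernoulli
mask X_{j,i} ~ Bernoulli(p_j) and records the realized proportions
p′_j = Σᵢ X_{j,i}/C.

**Bin means.** A quadratic m′ = β₀ + β₁p′ + β₂p′² links proportions to
mean accessibility. β is fitted by OLS of the normalized bin means
(counts divided by the cell's library size and multiplied by the median
library size, so every column sums to the median) on [1, p, p²], over
all bins, unweighted, including bins with p = 0. At simulation time the
quadratic is evaluated at the *simulated* p′_j; negative values are
clamped to 0 and bins with p′_j = 0 are forced to 0 so closed bins
carry no Poisson mass.

**Counts.** c_{j,i} = X_{j,i} · Poisson(γ · lᵢ′ · m′_j / Σₖ m′ₖ). The
bin-mean vector acts only through its normalized weights, so the
absolute scale of β cancels. γ (default 1) multiplies every Poisson
mean: expected totals scale linearly in it, and the realized zero
fraction falls as γ grows.

**Noise (optional, off by default).** c ← max(0, c + int(N(mean, sd)))
applied to every entry, including zeros; int(·) rounds half away from
zero. Negative-mean noise can only keep or raise sparsity, positive
noise densifies.

## Known model asymmetry

A masked-in entry (X = 1) may still draw a Poisson zero, so realized
sparsity exceeds Bernoulli sparsity, and realized library sizes are the
Poisson-thinned totals Σⱼ p_j·λ_{j,i} of the sampled lᵢ′ rather than lᵢ′
itself. Two visible consequences, both inherent to taking the
mask-then-Poisson sampling literally:

* the mixture refitted from a simulated matrix reproduces the mode
  separation and weight of the generating mixture but sits at a lower
  absolute location (shifted by log₂ of the retained mass fraction);
* iterating estimate → simulate thins the non-zero proportions slightly
  each round, so a resimulated matrix is a little sparser than its
  input.

Forcing positivity at masked-in entries would remove the asymmetry but
distort the Poisson means; we keep the literal model and document it.

## Estimation details

Cells with zero library size are dropped with a warning before any
estimation (never imputed). Estimation needs at least 10 cells. The
quadratic fit refuses rank-deficient designs (all p_j equal). Estimation
is invariant to cell permutation up to floating-point summation order
and equivariant to bin permutation.

## Synthetic fixtures

`make_fixture` generates a synthetic "real" matrix from known
parameters so estimation and resemblance are testable without any
download; its defaults are documented synthetic choices, not estimates
from any published dataset:

* library sizes: bimodal mixture μ = (11, 13.5), σ = (0.5, 0.6),
  w = 0.4 on the log₂ scale — two well-separated coverage modes as seen
  on droplet platforms (`toy-unimodal`: μ = 12, σ = 0.6, w = 1);
* accessibility: 60% of bins fully closed (p = 0), the rest
  p ~ Beta(0.5, 8) — heavy zero-inflation with a long right tail,
  matching the extreme sparsity of scATAC-seq;
* bin-mean quadratic β = (0, 1, 2): a convex increasing relation —
  highly open bins accumulate disproportionately many reads — chosen at
  design time (with a pilot of the estimate→resimulate loop) to mirror
  the convex p-vs-mean curves of real accessibility data.

What the fixtures do *not* emulate: chromosome-scale spatial structure
(p is drawn i.i.d. across bins), cross-bin correlation within a cell
beyond the shared library size, batch effects, doublets, and
platform-specific artifacts. Tests that pass on fixtures therefore
establish the correctness of the estimation/simulation machinery, not
fidelity to any particular real dataset.

## Evaluation metrics

Resemblance: MAD = median(|R−S|), MAE = mean(|R−S|),
RMSE = √mean((R−S)²) over sorted library-size vectors (sorted so the
comparison is distributional), bin means and non-zero proportions,
plus Pearson correlations of the two bin-wise vectors, averaged over
repeated simulation runs (default 20). When real and simulated cell
counts differ, sorted library sizes are compared on matched quantiles
and the report flags the fallback.

Clustering agreement: NMI = MI/max(H(gt), H(pred)) with natural-log
plug-in entropies; AMI = (MI − E[MI]) / (mean(H) − E[MI]) with the
exact hypergeometric (permutation-model) expectation of MI and the
arithmetic-mean denominator; ARI via the standard pair-counting
contingency formula. Degenerate cases: both labelings constant gives
NMI = AMI = 1 (the defined limit), exactly one constant gives 0; a
vanishing AMI denominator returns 1 iff the partitions coincide. The
implementations match scikit-learn's (`average_method="max"` for NMI,
`"arithmetic"` for AMI) to 1e-10 on random label pairs, but are
independent code paths.

## Numerical and design choices

* Genome bins are 0-based half-open (BED convention), 5 kbp by default;
  the trailing partial bin per chromosome is kept so bins exactly cover
  [0, L). Chromosome order follows the input chrom.sizes verbatim.
* Matrix exchange format: Matrix Market coordinate integer with BED and
  barcode sidecars (language-neutral, streamable); rows are always
  bins, columns cells. Duplicate triplets on input are summed with a
  warning.
* Peak selection ranks bins by mean count with ties broken by ascending
  genomic index, and emits rows in genomic order. Region aggregation
  counts a bin toward a region on any overlap (≥ 1 bp), unweighted;
  pre-split regions at bin boundaries for proportional assignment.
* One seeded `numpy` Generator per simulation run, consumed in the
  documented order (library sizes → mask → Poisson → noise, bin-major),
  makes outputs bit-reproducible; Poisson means above 2³¹ are refused.
* The scikit-learn front end (`ATACSimulator`, `PeakSelector`,
  `RegionAggregator`, `CountBinarizer`) uses the sklearn orientation
  (cells × bins); the domain functions keep bins × cells. Both share
  the same kernels.

## Problem sizes

The standard resemblance loop runs at C = 1000 cells × B = 2000 bins
with 20 simulation runs, large enough for binomial noise in p′ to be
negligible relative to the spread of p while keeping the whole suite
fast; parameter-recovery checks use 10,000 library-size draws. The
human-genome binning check is exact integer arithmetic over the 24
canonical chromosomes.

## Limitations

* One cell group per profile; simulate heterogeneous datasets by
  looping over groups and concatenating columns.
* No read-level output (BAM/fragments): the simulator produces count
  matrices only.
* The Bernoulli mask is independent across bins and cells given p, so
  co-accessibility structure is not preserved.
* Goodness-of-fit testing of the mixture choice is delegated to the
  user via `platform_hint`; the package does not run distributional
  hypothesis tests per input.
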