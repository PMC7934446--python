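# atacsim

Simulation of single-cell ATAC-seq (scATAC-seq) count data at the
bin-by-cell level, for developers and benchmarkers of chromatin
accessibility analysis tools.

scATAC-seq measures chromatin openness per cell, but annotated real
datasets are scarce and noisy, which makes systematic benchmarking of
clustering and peak-analysis pipelines difficult. `atacsim` estimates a
compact statistical model of a real bin-by-cell count matrix (rows:
fixed-width genomic windows, default 5 kbp; columns: cells; entries:
read counts) for one group of biologically similar cells, then samples
synthetic matrices that resemble the input in library size, sparsity
and per-bin signal — with known ground truth and as many cells as
desired.

## Model

For a B×C count matrix M of one cell group:

* **Library size** (per-cell total reads): log₂ lᵢ′ ~
  w·N(μ₁, σ₁²) + (1−w)·N(μ₂, σ₂²), a two-component Gaussian mixture
  fitted by EM. Droplet (10x-style) platforms are typically bimodal;
  for other platforms the unimodal convention sets w = 1.
* **Sparsity**: each entry is switched on by X_{j,i} ~ Bernoulli(p_j),
  where p_j is the fraction of cells with a non-zero count in bin j of
  the input.
* **Bin mean**: m′_j = β₀ + β₁p′_j + β₂p′_j², a quadratic in the
  *simulated* non-zero proportion p′_j = Σᵢ X_{j,i}/C, with β fitted by
  OLS on the library-size-normalized input (counts scaled per cell to
  the median library size).
* **Counts**: c_{j,i} = X_{j,i} · Poisson(γ · lᵢ′ · m′_j / Σₖ m′ₖ),
  where γ (default 1) is a sparsity adjustment factor; γ < 1 makes the
  matrix sparser, γ > 1 denser. Optionally, integer-rounded Gaussian
  noise is added to every entry and clamped at zero (off by default).

The package also converts simulated matrices to peak-by-cell
(top bins by mean), region-by-cell (user BED) and binary feature
matrices, and scores resemblance (MAD/MAE/RMSE and Pearson r of sorted
library sizes, bin means, non-zero proportions) and clustering
agreement (NMI, AMI with exact hypergeometric E[MI], ARI).

## Worked example

```python
from atacsim import ATACSimulator, FixtureSpec, compare_matrices, make_fixture

# a synthetic "real" matrix with known parameters (no download needed)
real, truth = make_fixture(FixtureSpec(n_cells=1000, n_bins=2000, seed=17))

sim = ATACSimulator(platform_hint="bimodal", random_state=0).fit(real)
lm = sim.library_model_
print(f"library-size mixture: mu=({lm.mu1:.2f}, {lm.mu2:.2f}), "
      f"sigma=({lm.sigma1:.2f}, {lm.sigma2:.2f}), w={lm.w:.2f}")

synth = sim.sample_matrix(1000, random_state=1)
report = compare_matrices(real, synth, n_runs=1)
print(f"Pearson r, bin means:             {report.mean['pearson_bin_mean']:.3f}")
print(f"Pearson r, non-zero proportions:  {report.mean['pearson_nonzero_prop']:.3f}")
```

prints

```
library-size mixture: mu=(8.54, 11.05), sigma=(0.57, 0.65), w=0.41
Pearson r, bin means:             0.968
Pearson r, non-zero proportions:  0.961
```

The fitted mixture has two clear modes about 2.5 log₂ units apart with
weight 0.41 on the lower one, and the resimulated matrix reproduces the
per-bin accessibility structure of the input at r ≈ 0.96. (The absolute
mixture means sit below the generating values of the fixture because
realized library sizes are the Bernoulli-thinned Poisson totals of the
sampled ones; see `docs/methods.md`.)

The same pipeline is available from the shell:

```sh
atacsim fixture --tag toy-bimodal --n-cells 1000 --n-bins 2000 --seed 17 --out fx/
atacsim estimate --matrix fx/matrix.mtx --bins fx/bins.bed \
    --barcodes fx/barcodes.tsv --out prof/
atacsim simulate --profile prof/ --n-cells 1000 --seed 1 --out sim/
atacsim evaluate --real fx/ --sim sim/ --runs 20 --profile prof/ --out report.json
```

Matrices are exchanged as a Matrix Market triplet
(`matrix.mtx` + `bins.bed` + `barcodes.tsv`); profiles as
`profile.json` + `p.tsv` + `bins.bed`.

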