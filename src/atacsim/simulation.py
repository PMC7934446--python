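"""Sampling synthetic bin-by-cell count matrices.

Generation proceeds in a fixed order with a single seeded random
generator so a given seed reproduces the matrix bit for bit:

1. library sizes ``l'_i`` from the log2-scale Gaussian mixture
   (continuous, never rounded);
2. the zero/non-zero mask ``X_{j,i} ~ Bernoulli(p_j)`` (bin-major);
3. realized simulated proportions ``p'_j = sum_i X_{j,i} / C``;
4. bin means ``m'_j = beta0 + beta1 p'_j + beta2 p'_j^2`` evaluated at
   the *simulated* proportions, clamped at 0 and forced to 0 where
   ``p'_j = 0``;
5. counts ``c_{j,i} = X_{j,i} * Poisson(gamma * l'_i * m'_j / sum_k m'_k)``
   (Poisson draws at masked entries, bin-major);
6. optional integer-rounded Gaussian noise added to every entry and
   clamped at 0 (off by default).

Because the Poisson can emit 0 at a masked-in entry, realized sparsity
is at least the Bernoulli sparsity.  The sparsity adjustment factor
``gamma`` scales the Poisson mean: values below 1 make the matrix
sparser, above 1 denser.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from .estimation import LibrarySizeModel, SimulationProfile
from .genome import InputError
from .matrix_io import BinByCellMatrix

MAX_POISSON_MEAN = 2.0**31


class SimulationError(RuntimeError):
    """Raised when a profile cannot produce counts (degenerate inputs)."""


@dataclass(frozen=True)
class SimulationSettings:
    """Knobs of one simulation run.

    ``gamma`` is the sparsity adjustment factor (default 1); noise is
    disabled by default (mean 0, sd 0).
    """

    n_cells: int
    gamma: float = 1.0
    noise_mean: float = 0.0
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells < 1:
            raise InputError("n_cells must be >= 1")
        if self.gamma <= 0:
            raise InputError("gamma must be positive")
        if self.noise_sd < 0:
            raise InputError("noise_sd must be non-negative")


@dataclass
class SimulationDraw:
    """Intermediate quantities of one run, kept for diagnostics."""

    library_sizes: np.ndarray  # l'_i, continuous
    mask: np.ndarray  # X_{j,i}, B x C boolean
    sim_nonzero_prop: np.ndarray  # p'_j
    bin_means: np.ndarray  # m'_j
    counts: sp.csr_matrix = field(default=None)


def sample_library_sizes(
    model: LibrarySizeModel, n_cells: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw continuous library sizes ``l' = 2 ** N(mu_k, sigma_k^2)``.

    Each cell picks component 1 with probability ``w``, else component 2.
    """
    if n_cells < 1:
        raise InputError("n_cells must be >= 1")
    first = rng.random(n_cells) < model.w
    mu = np.where(first, model.mu1, model.mu2)
    sigma = np.where(first, model.sigma1, model.sigma2)
    return 2.0 ** rng.normal(mu, sigma)


def sample_nonzero_mask(
    p: np.ndarray, n_cells: int, rng: np.random.Generator
) -> np.ndarray:
    """Independent Bernoulli(p_j) mask, B x C, bin-major draw order."""
    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise InputError("p must lie in [0, 1]")
    return rng.random((len(p), n_cells)) < p[:, None]


def compute_bin_means(
    sim_nonzero_prop: np.ndarray, beta0: float, beta1: float, beta2: float
) -> np.ndarray:
    """Evaluate the quadratic at the simulated proportions.

    Negative polynomial values are clamped to 0, and bins with no
    masked-in cell (``p'_j == 0``) are forced to 0 so fully closed bins
    contribute no Poisson mass.
    """
    pp = np.asarray(sim_nonzero_prop, dtype=float)
    m = beta0 + beta1 * pp + beta2 * pp * pp
    m = np.clip(m, 0.0, None)
    m[pp == 0] = 0.0
    if m.sum() <= 0:
        raise SimulationError(
            "all simulated bin means are zero; the profile is degenerate"
        )
    return m


def sample_counts(
    lib: np.ndarray,
    bin_means: np.ndarray,
    mask: np.ndarray,
    gamma: float,
    rng: np.random.Generator,
) -> sp.csr_matrix:
    """Poisson counts at masked entries with mean ``gamma * l'_i * m'_j / sum m'``."""
    total = bin_means.sum()
    if total <= 0:
        raise SimulationError("sum of bin means must be positive")
    if gamma <= 0:
        raise InputError("gamma must be positive")
    weights = bin_means / total
    rows, cols = np.nonzero(mask)  # bin-major (row-major) order
    lam = gamma * weights[rows] * lib[cols]
    if lam.size and lam.max() > MAX_POISSON_MEAN:
        raise SimulationError(
            f"Poisson mean {lam.max():.3g} exceeds {MAX_POISSON_MEAN:.3g}"
        )
    data = rng.poisson(lam)
    out = sp.csr_matrix(
        (data, (rows, cols)), shape=mask.shape, dtype=np.int64
    )
    out.eliminate_zeros()
    return out


def add_noise(
    counts: sp.csr_matrix,
    noise_mean: float,
    noise_sd: float,
    rng: np.random.Generator,
) -> sp.csr_matrix:
    """Add integer-rounded Gaussian noise to every entry, clamped at 0.

    With mean 0 and sd 0 this is the identity (the default).  Rounding
    is half-away-from-zero; noise lands on zero entries too, so negative
    mean noise can only keep or raise sparsity while positive noise
    densifies the matrix.
    """
    if noise_sd == 0 and noise_mean == 0:
        return counts
    dense = np.asarray(counts.todense(), dtype=np.int64)
    noise = rng.normal(noise_mean, noise_sd, size=dense.shape)
    rounded = np.sign(noise) * np.floor(np.abs(noise) + 0.5)
    noisy = np.clip(dense + rounded.astype(np.int64), 0, None)
    out = sp.csr_matrix(noisy)
    out.eliminate_zeros()
    return out


def _barcodes(n_cells: int) -> list[str]:
    return [f"simcell_{i + 1:06d}" for i in range(n_cells)]


def simulate(
    profile: SimulationProfile, settings: SimulationSettings
) -> tuple[BinByCellMatrix, SimulationDraw]:
    """Run the full generative pipeline for one cell group.

    A single ``numpy`` Generator seeded from ``settings.seed`` drives
    all sampling in the documented order, so identical settings yield
    bit-identical matrices.
    """
    rng = np.random.default_rng(settings.seed)
    bm = profile.bin_model
    lib = sample_library_sizes(profile.library_model, settings.n_cells, rng)
    mask = sample_nonzero_mask(bm.p, settings.n_cells, rng)
    pp = mask.mean(axis=1)
    if np.any(pp > 0):
        means = compute_bin_means(pp, bm.beta0, bm.beta1, bm.beta2)
        counts = sample_counts(lib, means, mask, settings.gamma, rng)
    else:
        # nothing is masked in: an all-zero matrix, no Poisson mass needed
        means = np.zeros_like(pp)
        counts = sp.csr_matrix((len(pp), settings.n_cells), dtype=np.int64)
    counts = add_noise(counts, settings.noise_mean, settings.noise_sd, rng)
    draw = SimulationDraw(
        library_sizes=lib,
        mask=mask,
        sim_nonzero_prop=pp,
        bin_means=means,
        counts=counts,
    )
    matrix = BinByCellMatrix(
        counts=counts,
        bins=profile.bins,
        barcodes=_barcodes(settings.n_cells),
        group_label=profile.group_label or None,
    )
    return matrix, draw
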