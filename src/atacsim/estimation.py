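"""Model estimation from a real bin-by-cell matrix.

Three quantities parameterize the generative model of one cell group:

* a two-component Gaussian mixture on log2 library sizes
  (``log2 l ~ w N(mu1, sigma1^2) + (1 - w) N(mu2, sigma2^2)``);
* the per-bin proportion ``p_j`` of cells with a non-zero count;
* a quadratic linking normalized bin means to ``p_j``
  (``m_j = beta0 + beta1 p_j + beta2 p_j^2``).

Droplet (10x-style) data typically shows a bimodal library-size
distribution; for other platforms a single Gaussian suffices and the
mixture degenerates to one component (weight 1).
"""

from __future__ import annotations

import json
import logging
import os
import warnings
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from .genome import GenomeBins, InputError, read_bins_bed, write_bins_bed
from .matrix_io import BinByCellMatrix

logger = logging.getLogger(__name__)

VARIANCE_FLOOR = 1e-6
MIN_CELLS = 10


class EstimationError(RuntimeError):
    """Raised when model parameters cannot be estimated from the input."""


@dataclass(frozen=True)
class LibrarySizeModel:
    """Two-component Gaussian mixture on log2 library sizes.

    ``w`` is the weight of the first component; components are stored
    with ``mu1 <= mu2`` so parameter reports are reproducible.  A
    unimodal model is the degenerate case ``w == 1`` with both
    components equal.
    """

    mu1: float
    sigma1: float
    mu2: float
    sigma2: float
    w: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.w <= 1.0:
            raise InputError(f"mixture weight w={self.w} outside [0, 1]")
        if self.sigma1 <= 0 or self.sigma2 <= 0:
            raise InputError("mixture standard deviations must be positive")
        if self.mu1 > self.mu2:
            raise InputError("components must be ordered mu1 <= mu2")


@dataclass(frozen=True)
class BinModel:
    """Per-bin non-zero proportions plus the quadratic bin-mean fit."""

    p: np.ndarray
    beta0: float
    beta1: float
    beta2: float
    median_library_size: float

    def __post_init__(self) -> None:
        p = np.asarray(self.p, dtype=float)
        if p.ndim != 1 or len(p) == 0:
            raise InputError("p must be a non-empty 1-D vector")
        if np.any((p < 0) | (p > 1)):
            raise InputError("non-zero proportions must lie in [0, 1]")
        if self.median_library_size <= 0:
            raise InputError("median library size must be positive")
        object.__setattr__(self, "p", p)


@dataclass(frozen=True)
class SimulationProfile:
    """Everything needed to simulate one cell group."""

    library_model: LibrarySizeModel
    bin_model: BinModel
    bins: GenomeBins
    n_cells_source: int
    group_label: str = ""

    def __post_init__(self) -> None:
        if len(self.bin_model.p) != len(self.bins):
            raise InputError(
                f"bin model has {len(self.bin_model.p)} proportions for "
                f"{len(self.bins)} bins"
            )


@dataclass(frozen=True)
class PolynomialFit:
    beta0: float
    beta1: float
    beta2: float
    residual_rms: float
    r_squared: float

    def __iter__(self):
        return iter((self.beta0, self.beta1, self.beta2))


def _normal_logpdf(x: np.ndarray, mu: float, var: float) -> np.ndarray:
    return -0.5 * (np.log(2 * np.pi * var) + (x - mu) ** 2 / var)


def _em_two_component(x: np.ndarray, max_iter: int, tol: float) -> tuple:
    """EM for a 1-D two-component Gaussian mixture.

    Responsibilities are initialized by a median split of the data; the
    per-component variance is floored at ``VARIANCE_FLOOR`` to prevent
    collapse onto a single point.
    """
    n = len(x)
    r1 = (x <= np.median(x)).astype(float)  # responsibility of component 1
    prev_ll = -np.inf
    w = mu = var = None
    for it in range(max_iter):
        # M step
        n1 = r1.sum()
        n2 = n - n1
        w = np.array([n1, n2]) / n
        w = np.clip(w, 1e-12, None)
        mu = np.array(
            [
                (r1 * x).sum() / max(n1, 1e-12),
                ((1 - r1) * x).sum() / max(n2, 1e-12),
            ]
        )
        var = np.array(
            [
                (r1 * (x - mu[0]) ** 2).sum() / max(n1, 1e-12),
                ((1 - r1) * (x - mu[1]) ** 2).sum() / max(n2, 1e-12),
            ]
        )
        var = np.maximum(var, VARIANCE_FLOOR)
        # a starved component is re-centred on the pooled data instead of
        # collapsing to the origin (happens e.g. for constant input)
        if n1 < 1e-8:
            mu[0], var[0] = x.mean(), max(x.var(), VARIANCE_FLOOR)
        if n2 < 1e-8:
            mu[1], var[1] = x.mean(), max(x.var(), VARIANCE_FLOOR)
        # E step
        log1 = np.log(w[0]) + _normal_logpdf(x, mu[0], var[0])
        log2 = np.log(w[1]) + _normal_logpdf(x, mu[1], var[1])
        m = np.maximum(log1, log2)
        lse = m + np.log(np.exp(log1 - m) + np.exp(log2 - m))
        r1 = np.exp(log1 - lse)
        ll = lse.sum()
        if abs(ll - prev_ll) < tol:
            return w, mu, var, ll, True
        prev_ll = ll
    return w, mu, var, prev_ll, False


def estimate_library_model(
    library_sizes,
    n_components: int = 2,
    max_iter: int = 500,
    tol: float = 1e-6,
    seed: int | None = None,
) -> LibrarySizeModel:
    """Fit the Gaussian mixture to log2 library sizes by EM.

    Parameters
    ----------
    library_sizes
        Positive per-cell totals; at least ``MIN_CELLS`` values.
    n_components
        2 for the bimodal (droplet-platform) model, 1 for the unimodal
        convention in which the returned weight is 1 and both components
        coincide.
    seed
        Accepted for interface uniformity; the median-split
        initialization makes the fit deterministic.
    """
    del seed  # deterministic initialization
    lib = np.asarray(library_sizes, dtype=float)
    if np.any(lib <= 0):
        raise EstimationError("library sizes must be positive (drop zero-size cells)")
    if len(lib) < MIN_CELLS:
        raise EstimationError(
            f"need at least {MIN_CELLS} cells to fit the library-size model, "
            f"got {len(lib)}"
        )
    x = np.log2(lib)
    if n_components == 1:
        mu = float(x.mean())
        sigma = float(max(x.std(), np.sqrt(VARIANCE_FLOOR)))
        return LibrarySizeModel(mu1=mu, sigma1=sigma, mu2=mu, sigma2=sigma, w=1.0)
    if n_components != 2:
        raise InputError("n_components must be 1 or 2")
    w, mu, var, _, converged = _em_two_component(x, max_iter=max_iter, tol=tol)
    if not converged:
        warnings.warn(
            f"EM did not converge within {max_iter} iterations; "
            "returning best parameters so far",
            stacklevel=2,
        )
    order = np.argsort(mu)
    mu, var, w = mu[order], var[order], w[order]
    return LibrarySizeModel(
        mu1=float(mu[0]),
        sigma1=float(np.sqrt(var[0])),
        mu2=float(mu[1]),
        sigma2=float(np.sqrt(var[1])),
        w=float(w[0]),
    )


def estimate_nonzero_proportions(m: BinByCellMatrix) -> np.ndarray:
    """Exact per-bin fraction of cells with a non-zero count."""
    return m.nonzero_proportions()


def normalize_matrix(m: BinByCellMatrix) -> sp.csr_matrix:
    """Median-of-library-sizes normalization.

    Each primary count is divided by its cell's library size and
    multiplied by the median library size, so every column of the result
    sums to the median.
    """
    lib = m.library_sizes()
    if np.any(lib == 0):
        raise EstimationError(
            "cells with zero library size must be dropped before normalization"
        )
    med = float(np.median(lib))
    scale = sp.diags(med / lib)
    return sp.csr_matrix(m.counts @ scale)


def fit_bin_mean_polynomial(p, normalized_bin_means) -> PolynomialFit:
    """OLS fit of normalized bin means on ``[1, p, p^2]`` over all bins."""
    p = np.asarray(p, dtype=float)
    y = np.asarray(normalized_bin_means, dtype=float)
    if p.shape != y.shape or p.ndim != 1:
        raise InputError("p and bin means must be 1-D vectors of equal length")
    if len(p) < 3:
        raise InputError("need at least 3 bins to fit a quadratic")
    if np.any((p < 0) | (p > 1)):
        raise InputError("proportions must lie in [0, 1]")
    design = np.column_stack([np.ones_like(p), p, p * p])
    if np.linalg.matrix_rank(design) < 3:
        raise EstimationError(
            "rank-deficient design: non-zero proportions are degenerate "
            "(e.g. all bins share the same value)"
        )
    beta, _, _, _ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ beta
    tss = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - float((resid**2).sum()) / tss if tss > 0 else 1.0
    fit = PolynomialFit(
        beta0=float(beta[0]),
        beta1=float(beta[1]),
        beta2=float(beta[2]),
        residual_rms=float(np.sqrt((resid**2).mean())),
        r_squared=r2,
    )
    logger.debug(
        "bin-mean quadratic: beta=(%.4g, %.4g, %.4g), residual RMS %.4g, R^2 %.4f",
        fit.beta0, fit.beta1, fit.beta2, fit.residual_rms, fit.r_squared,
    )
    return fit


def drop_zero_cells(m: BinByCellMatrix) -> BinByCellMatrix:
    """Remove cells with zero library size, warning if any are found."""
    lib = m.library_sizes()
    keep = lib > 0
    if keep.all():
        return m
    dropped = [bc for bc, k in zip(m.barcodes, keep) if not k]
    warnings.warn(
        f"dropping {len(dropped)} cell(s) with zero library size", stacklevel=2
    )
    logger.warning("dropped zero-library-size cells: %s", dropped[:10])
    return BinByCellMatrix(
        counts=m.counts[:, keep],
        bins=m.bins,
        barcodes=[bc for bc, k in zip(m.barcodes, keep) if k],
        group_label=m.group_label,
    )


def estimate_profile(
    m: BinByCellMatrix,
    platform_hint: str = "bimodal",
    seed: int | None = None,
    max_iter: int = 500,
    tol: float = 1e-6,
) -> SimulationProfile:
    """Estimate the full simulation profile from a bin-by-cell matrix.

    ``platform_hint`` selects the library-size model: ``"bimodal"``
    (droplet platforms), ``"unimodal"`` (others; returns weight 1), or
    ``"auto"`` (fit both, choose by BIC).
    """
    if platform_hint not in ("bimodal", "unimodal", "auto"):
        raise InputError(f"unknown platform_hint {platform_hint!r}")
    m = drop_zero_cells(m)
    lib = m.library_sizes()
    if platform_hint == "auto":
        library_model = _select_by_bic(lib, max_iter=max_iter, tol=tol, seed=seed)
    else:
        n_comp = 2 if platform_hint == "bimodal" else 1
        library_model = estimate_library_model(
            lib, n_components=n_comp, max_iter=max_iter, tol=tol, seed=seed
        )
    p = estimate_nonzero_proportions(m)
    norm = normalize_matrix(m)
    norm_means = np.asarray(norm.sum(axis=1)).ravel() / m.n_cells
    fit = fit_bin_mean_polynomial(p, norm_means)
    bin_model = BinModel(
        p=p,
        beta0=fit.beta0,
        beta1=fit.beta1,
        beta2=fit.beta2,
        median_library_size=float(np.median(lib)),
    )
    return SimulationProfile(
        library_model=library_model,
        bin_model=bin_model,
        bins=m.bins,
        n_cells_source=m.n_cells,
        group_label=m.group_label or "",
    )


def _gmm_loglik(x: np.ndarray, model: LibrarySizeModel) -> float:
    l1 = np.log(max(model.w, 1e-300)) + _normal_logpdf(x, model.mu1, model.sigma1**2)
    l2 = np.log(max(1 - model.w, 1e-300)) + _normal_logpdf(
        x, model.mu2, model.sigma2**2
    )
    m = np.maximum(l1, l2)
    return float((m + np.log(np.exp(l1 - m) + np.exp(l2 - m))).sum())


def _select_by_bic(lib, max_iter, tol, seed) -> LibrarySizeModel:
    x = np.log2(np.asarray(lib, dtype=float))
    n = len(x)
    uni = estimate_library_model(lib, n_components=1, max_iter=max_iter, tol=tol,
                                 seed=seed)
    bi = estimate_library_model(lib, n_components=2, max_iter=max_iter, tol=tol,
                                seed=seed)
    bic_uni = 2 * np.log(n) - 2 * _gmm_loglik(x, uni)
    bic_bi = 5 * np.log(n) - 2 * _gmm_loglik(x, bi)
    return uni if bic_uni <= bic_bi else bi


# --- profile serialization -------------------------------------------------

PROFILE_JSON = "profile.json"
PROFILE_P = "p.tsv"
PROFILE_BINS = "bins.bed"


def write_profile(profile: SimulationProfile, out_dir) -> None:
    """Serialize a profile as profile.json + p.tsv + bins.bed."""
    os.makedirs(out_dir, exist_ok=True)
    lm, bm = profile.library_model, profile.bin_model
    scalars = {
        "mu1": lm.mu1, "sigma1": lm.sigma1, "mu2": lm.mu2, "sigma2": lm.sigma2,
        "w": lm.w,
        "beta0": bm.beta0, "beta1": bm.beta1, "beta2": bm.beta2,
        "median_library_size": bm.median_library_size,
        "n_cells_source": profile.n_cells_source,
        "group_label": profile.group_label,
        "bin_width": profile.bins.bin_width,
    }
    with open(os.path.join(out_dir, PROFILE_JSON), "w") as fh:
        json.dump(scalars, fh, indent=2)
        fh.write("\n")
    np.savetxt(os.path.join(out_dir, PROFILE_P), bm.p, fmt="%.10g")
    write_bins_bed(profile.bins, os.path.join(out_dir, PROFILE_BINS))


def read_profile(in_dir) -> SimulationProfile:
    """Load a profile directory written by :func:`write_profile`."""
    with open(os.path.join(in_dir, PROFILE_JSON)) as fh:
        s = json.load(fh)
    p = np.loadtxt(os.path.join(in_dir, PROFILE_P), ndmin=1)
    bins = read_bins_bed(os.path.join(in_dir, PROFILE_BINS),
                         bin_width=int(s.get("bin_width", 0)) or None)
    return SimulationProfile(
        library_model=LibrarySizeModel(
            mu1=s["mu1"], sigma1=s["sigma1"], mu2=s["mu2"], sigma2=s["sigma2"],
            w=s["w"],
        ),
        bin_model=BinModel(
            p=p, beta0=s["beta0"], beta1=s["beta1"], beta2=s["beta2"],
            median_library_size=s["median_library_size"],
        ),
        bins=bins,
        n_cells_source=int(s["n_cells_source"]),
        group_label=s.get("group_label", ""),
    )
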