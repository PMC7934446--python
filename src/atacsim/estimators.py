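"""scikit-learn style estimator and transformer interfaces.

`ATACSimulator` is the fit/sample front end to the whole framework:
``fit`` estimates the generative model from a real matrix and
``sample`` draws synthetic matrices from it, in the spirit of
``sklearn.mixture.GaussianMixture``.  The transformers convert a
cells-by-bins count array into the common downstream feature formats
and compose with sklearn pipelines.

Arrays follow the sklearn orientation (rows = cells/samples, columns =
bins/features); the domain functions in the sibling modules keep the
genomics bins-by-cells orientation and the two front ends share their
kernels.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from . import estimation, simulation
from .features import region_bin_map, top_bin_indices
from .genome import GenomeBins, InputError
from .matrix_io import BinByCellMatrix


def _as_bin_by_cell(X, bins: GenomeBins | None) -> BinByCellMatrix:
    if isinstance(X, BinByCellMatrix):
        return X
    counts = sp.csr_matrix(X).T  # sklearn orientation: cells x bins
    if bins is None:
        from .fixtures import _toy_bins  # synthetic placeholder bin space

        bins = _toy_bins(counts.shape[0])
    barcodes = [f"cell_{i + 1:06d}" for i in range(counts.shape[1])]
    return BinByCellMatrix(counts=counts, bins=bins, barcodes=barcodes)


class ATACSimulator(BaseEstimator):
    """Estimate the generative model of one cell group and sample from it.

    Parameters
    ----------
    platform_hint : {"bimodal", "unimodal", "auto"}
        Library-size model choice: two Gaussian modes (droplet
        platforms), one mode, or BIC selection between the two.
    gamma : float
        Sparsity adjustment factor; Poisson means scale linearly in it.
    noise_mean, noise_sd : float
        Optional integer-rounded Gaussian noise on final counts
        (disabled by default).
    random_state : int or None
        Seed for ``sample`` when no per-call seed is given.

    Attributes
    ----------
    library_model_ : LibrarySizeModel
    bin_model_ : BinModel
    profile_ : SimulationProfile
    n_features_in_ : int
        Number of bins seen during fit.
    """

    def __init__(
        self,
        platform_hint: str = "bimodal",
        gamma: float = 1.0,
        noise_mean: float = 0.0,
        noise_sd: float = 0.0,
        max_iter: int = 500,
        tol: float = 1e-6,
        random_state: int | None = None,
    ):
        self.platform_hint = platform_hint
        self.gamma = gamma
        self.noise_mean = noise_mean
        self.noise_sd = noise_sd
        self.max_iter = max_iter
        self.tol = tol
        self.random_state = random_state

    def fit(self, X, y=None, bins: GenomeBins | None = None):
        """Estimate the profile from counts (cells x bins array or
        :class:`BinByCellMatrix`)."""
        m = _as_bin_by_cell(X, bins)
        self.profile_ = estimation.estimate_profile(
            m,
            platform_hint=self.platform_hint,
            seed=self.random_state,
            max_iter=self.max_iter,
            tol=self.tol,
        )
        self.library_model_ = self.profile_.library_model
        self.bin_model_ = self.profile_.bin_model
        self.n_features_in_ = m.n_bins
        return self

    def sample(
        self,
        n_cells: int,
        random_state: int | None = None,
        return_draw: bool = False,
    ):
        """Draw a synthetic matrix; returns (cells x bins CSR, draw?)."""
        check_is_fitted(self, "profile_")
        seed = random_state if random_state is not None else (self.random_state or 0)
        settings = simulation.SimulationSettings(
            n_cells=n_cells,
            gamma=self.gamma,
            noise_mean=self.noise_mean,
            noise_sd=self.noise_sd,
            seed=seed,
        )
        matrix, draw = simulation.simulate(self.profile_, settings)
        X = sp.csr_matrix(matrix.counts.T)
        return (X, draw) if return_draw else X

    def sample_matrix(
        self, n_cells: int, random_state: int | None = None
    ) -> BinByCellMatrix:
        """Like :meth:`sample` but returns the annotated bins x cells matrix."""
        check_is_fitted(self, "profile_")
        seed = random_state if random_state is not None else (self.random_state or 0)
        settings = simulation.SimulationSettings(
            n_cells=n_cells,
            gamma=self.gamma,
            noise_mean=self.noise_mean,
            noise_sd=self.noise_sd,
            seed=seed,
        )
        matrix, _ = simulation.simulate(self.profile_, settings)
        return matrix


class PeakSelector(BaseEstimator, TransformerMixin):
    """Keep the ``n_peaks`` columns (bins) with the largest mean count.

    Selection happens at fit time from the training matrix; transform
    subsets any matrix on the same bin space, preserving genomic order.
    """

    def __init__(self, n_peaks: int = 500):
        self.n_peaks = n_peaks

    def fit(self, X, y=None):
        X = sp.csr_matrix(X)
        means = np.asarray(X.mean(axis=0)).ravel()
        self.support_ = top_bin_indices(means, self.n_peaks)
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        check_is_fitted(self, "support_")
        X = sp.csr_matrix(X)
        if X.shape[1] != self.n_features_in_:
            raise InputError(
                f"expected {self.n_features_in_} bins, got {X.shape[1]}"
            )
        return X[:, self.support_]


class RegionAggregator(BaseEstimator, TransformerMixin):
    """Sum bin counts into user-supplied regions (>= 1 bp overlap rule)."""

    def __init__(self, regions=None, bins: GenomeBins | None = None):
        self.regions = regions
        self.bins = bins

    def fit(self, X, y=None):
        if self.regions is None or self.bins is None:
            raise InputError("RegionAggregator requires regions and bins")
        self.indicator_ = region_bin_map(self.bins, self.regions)
        self.n_features_in_ = len(self.bins)
        return self

    def transform(self, X):
        check_is_fitted(self, "indicator_")
        X = sp.csr_matrix(X)
        return sp.csr_matrix(X @ self.indicator_.T)


class CountBinarizer(BaseEstimator, TransformerMixin):
    """Map counts to presence/absence: 1 iff the entry is positive."""

    def fit(self, X, y=None):
        self.n_features_in_ = sp.csr_matrix(X).shape[1]
        return self

    def transform(self, X):
        X = sp.csr_matrix(X).copy()
        X.data = np.ones_like(X.data)
        X.eliminate_zeros()
        return X
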