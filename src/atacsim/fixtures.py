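"""Self-contained synthetic inputs with known ground truth.

These generators stand in for real bin-by-cell matrices so estimation
and resemblance can be exercised without any download.  The default
parameter values are documented synthetic choices — a bimodal library
size mixture typical of droplet platforms, heavy zero-inflation of the
per-bin accessibility proportions, and a convex quadratic linking
proportions to bin means — not values fitted to any published dataset.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq
from scipy.stats import norm

from .estimation import BinModel, LibrarySizeModel, SimulationProfile
from .genome import ChromSizes, InputError, make_bins
from .matrix_io import BinByCellMatrix
from .simulation import SimulationDraw, SimulationSettings, simulate

TOY_BIMODAL_LIBRARY = LibrarySizeModel(
    mu1=11.0, sigma1=0.5, mu2=13.5, sigma2=0.6, w=0.4
)
TOY_UNIMODAL_LIBRARY = LibrarySizeModel(
    mu1=12.0, sigma1=0.6, mu2=12.0, sigma2=0.6, w=1.0
)
#: convex increasing quadratic: bin means grow faster in highly open bins
TOY_BETA = (0.0, 1.0, 2.0)


@dataclass(frozen=True)
class FixtureSpec:
    """Recipe for a synthetic "real" matrix with known parameters.

    ``p_zero_fraction`` of the bins are fully closed (p = 0); the rest
    draw their non-zero proportion from ``Beta(p_beta_a, p_beta_b)``,
    mimicking the heavy sparsity of chromatin accessibility data.
    """

    n_cells: int = 1000
    n_bins: int = 2000
    library_model: LibrarySizeModel = field(default=TOY_BIMODAL_LIBRARY)
    p_zero_fraction: float = 0.6
    p_beta_a: float = 0.5
    p_beta_b: float = 8.0
    beta: tuple[float, float, float] = TOY_BETA
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells < 1 or self.n_bins < 1:
            raise InputError("n_cells and n_bins must be positive")
        if not 0.0 <= self.p_zero_fraction < 1.0:
            raise InputError("p_zero_fraction must lie in [0, 1)")
        b0, b1, b2 = self.beta
        grid = np.linspace(0, 1, 101)
        if np.all(b0 + b1 * grid + b2 * grid**2 <= 0):
            raise InputError("the bin-mean quadratic is non-positive on [0, 1]")


def mixture_median_library_size(model: LibrarySizeModel) -> float:
    """Median of ``2 ** GMM`` found by inverting the mixture CDF."""
    def cdf(x):
        return (
            model.w * norm.cdf(x, model.mu1, model.sigma1)
            + (1 - model.w) * norm.cdf(x, model.mu2, model.sigma2)
            - 0.5
        )
    lo = min(model.mu1, model.mu2) - 10 * max(model.sigma1, model.sigma2)
    hi = max(model.mu1, model.mu2) + 10 * max(model.sigma1, model.sigma2)
    return float(2.0 ** brentq(cdf, lo, hi))


def _toy_bins(n_bins: int, bin_width: int = 5000):
    sizes = ChromSizes((("chrS", n_bins * bin_width),))
    return make_bins(sizes, bin_width)


def build_profile_from_spec(spec: FixtureSpec) -> SimulationProfile:
    """Draw per-bin proportions and assemble the generating profile."""
    rng = np.random.default_rng(spec.seed)
    zero = rng.random(spec.n_bins) < spec.p_zero_fraction
    p = np.where(zero, 0.0, rng.beta(spec.p_beta_a, spec.p_beta_b, spec.n_bins))
    if not np.any(p > 0):
        raise InputError("all bins closed; increase n_bins or lower p_zero_fraction")
    b0, b1, b2 = spec.beta
    bin_model = BinModel(
        p=p,
        beta0=b0,
        beta1=b1,
        beta2=b2,
        median_library_size=mixture_median_library_size(spec.library_model),
    )
    return SimulationProfile(
        library_model=spec.library_model,
        bin_model=bin_model,
        bins=_toy_bins(spec.n_bins),
        n_cells_source=spec.n_cells,
        group_label="fixture",
    )


def make_fixture(spec: FixtureSpec) -> tuple[BinByCellMatrix, SimulationProfile]:
    """Generate a synthetic "real" matrix plus its generating profile.

    Deterministic given ``spec.seed``: the profile draw and the matrix
    simulation use seeds derived from it.
    """
    profile = build_profile_from_spec(spec)
    settings = SimulationSettings(n_cells=spec.n_cells, seed=spec.seed + 1)
    matrix, _ = simulate(profile, settings)
    return matrix, profile


def default_profile(tag: str, n_bins: int = 2000, seed: int = 7) -> SimulationProfile:
    """A fully specified profile usable with no input data.

    Tags: ``"toy-bimodal"`` (droplet-like, two library-size modes) and
    ``"toy-unimodal"`` (single mode, weight 1).  These are documented
    synthetic defaults, not estimates from any real dataset.
    """
    if tag == "toy-bimodal":
        lib = TOY_BIMODAL_LIBRARY
    elif tag == "toy-unimodal":
        lib = TOY_UNIMODAL_LIBRARY
    else:
        raise InputError(f"unknown profile tag {tag!r}")
    spec = FixtureSpec(n_bins=n_bins, library_model=lib, seed=seed)
    profile = build_profile_from_spec(spec)
    return SimulationProfile(
        library_model=profile.library_model,
        bin_model=profile.bin_model,
        bins=profile.bins,
        n_cells_source=profile.n_cells_source,
        group_label=tag,
    )
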