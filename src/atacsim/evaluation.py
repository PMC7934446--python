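"""Resemblance and clustering-agreement metrics.

Resemblance between a real and a simulated matrix is summarized by the
median absolute deviation, mean absolute error and root-mean-square
error of three vectors — sorted library sizes, per-bin means and
per-bin non-zero cell proportions — plus the Pearson correlation of the
two bin-wise vectors, averaged over repeated simulation runs.

Clustering agreement against ground-truth labels uses normalized mutual
information NMI = MI / max(H(gt), H(pred)), adjusted mutual information
AMI = (MI - E[MI]) / (mean(H(gt), H(pred)) - E[MI]) with the exact
hypergeometric (permutation-model) expectation of MI, and the adjusted
Rand index.  Entropies use natural logarithms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .genome import InputError
from .matrix_io import BinByCellMatrix

# --- error metrics ---------------------------------------------------------


def _check_pair(r, s) -> tuple[np.ndarray, np.ndarray]:
    r = np.asarray(r, dtype=float)
    s = np.asarray(s, dtype=float)
    if r.shape != s.shape or r.ndim != 1 or len(r) == 0:
        raise InputError("vectors must be 1-D, non-empty and of equal length")
    return r, s


def mad(r, s) -> float:
    """Median absolute deviation, median(|R - S|)."""
    r, s = _check_pair(r, s)
    return float(np.median(np.abs(r - s)))


def mae(r, s) -> float:
    """Mean absolute error, mean(|R - S|)."""
    r, s = _check_pair(r, s)
    return float(np.mean(np.abs(r - s)))


def rmse(r, s) -> float:
    """Root mean square error, sqrt(mean((R - S)^2))."""
    r, s = _check_pair(r, s)
    return float(np.sqrt(np.mean((r - s) ** 2)))


# --- matrix resemblance ----------------------------------------------------


@dataclass
class ResemblanceReport:
    """Per-run and averaged resemblance metrics between real and simulated."""

    per_run: list[dict] = field(default_factory=list)
    mean: dict = field(default_factory=dict)
    sd: dict = field(default_factory=dict)
    n_runs: int = 0
    library_sizes_resampled: bool = False

    def to_dict(self) -> dict:
        return {
            "n_runs": self.n_runs,
            "mean": self.mean,
            "sd": self.sd,
            "per_run": self.per_run,
            "library_sizes_resampled": self.library_sizes_resampled,
        }


def _sorted_library_pair(real_lib, sim_lib) -> tuple[np.ndarray, np.ndarray, bool]:
    r = np.sort(real_lib)
    s = np.sort(sim_lib)
    if len(r) == len(s):
        return r, s, False
    # unequal cell counts: compare matched quantiles instead
    n = min(len(r), len(s))
    q = np.linspace(0, 1, n)
    return np.quantile(r, q), np.quantile(s, q), True


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    if a.std() == 0 or b.std() == 0:
        return float("nan")
    return float(np.corrcoef(a, b)[0, 1])


def _one_run(real: BinByCellMatrix, sim: BinByCellMatrix) -> tuple[dict, bool]:
    if real.n_bins != sim.n_bins:
        raise InputError(
            f"matrices live on different bin spaces ({real.n_bins} vs {sim.n_bins})"
        )
    lr, ls, resampled = _sorted_library_pair(real.library_sizes(),
                                             sim.library_sizes())
    mr, ms = real.bin_means(), sim.bin_means()
    pr, ps = real.nonzero_proportions(), sim.nonzero_proportions()
    run = {}
    for name, (a, b) in {
        "library_size": (lr, ls),
        "bin_mean": (mr, ms),
        "nonzero_prop": (pr, ps),
    }.items():
        run[f"mad_{name}"] = mad(a, b)
        run[f"mae_{name}"] = mae(a, b)
        run[f"rmse_{name}"] = rmse(a, b)
    run["pearson_bin_mean"] = _pearson(mr, ms)
    run["pearson_nonzero_prop"] = _pearson(pr, ps)
    return run, resampled


def compare_matrices(
    real: BinByCellMatrix,
    sim: BinByCellMatrix | None = None,
    n_runs: int = 20,
    simulate_fn=None,
    seed: int | None = None,
) -> ResemblanceReport:
    """Compare a real matrix against one or many simulated matrices.

    With ``simulate_fn`` (a callable ``seed -> BinByCellMatrix``), the
    simulation is regenerated ``n_runs`` times with seeds derived from
    ``seed`` and the metrics are averaged; otherwise the single ``sim``
    matrix is scored once.  Library sizes are compared after sorting;
    unequal cell counts fall back to matched quantiles and are flagged.
    """
    report = ResemblanceReport()
    if simulate_fn is None:
        if sim is None:
            raise InputError("provide either sim or simulate_fn")
        sims = [sim]
    else:
        ss = np.random.SeedSequence(seed)
        seeds = [int(s) for s in ss.generate_state(n_runs) >> 1]
        sims = (simulate_fn(k) for k in seeds)
    for s in sims:
        run, resampled = _one_run(real, s)
        report.per_run.append(run)
        report.library_sizes_resampled |= resampled
    report.n_runs = len(report.per_run)
    keys = report.per_run[0].keys()
    for k in keys:
        vals = np.array([r[k] for r in report.per_run], dtype=float)
        report.mean[k] = float(vals.mean())
        report.sd[k] = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
    return report


def bin_sparsity_qq(
    real: BinByCellMatrix, sim: BinByCellMatrix, n_quantiles: int = 100
) -> pd.DataFrame:
    """Matched quantiles of per-bin zero fractions for QQ plotting."""
    if real.n_bins != sim.n_bins:
        raise InputError("matrices live on different bin spaces")
    if n_quantiles < 2:
        raise InputError("n_quantiles must be >= 2")
    zr = 1.0 - real.nonzero_proportions()
    zs = 1.0 - sim.nonzero_proportions()
    q = np.linspace(0, 1, n_quantiles)
    return pd.DataFrame(
        {
            "quantile": q,
            "real": np.quantile(zr, q),
            "sim": np.quantile(zs, q),
        }
    )


# --- clustering agreement --------------------------------------------------


def _contingency(gt, pred) -> np.ndarray:
    gt = np.asarray(gt)
    pred = np.asarray(pred)
    if gt.shape != pred.shape or gt.ndim != 1 or len(gt) == 0:
        raise InputError("label vectors must be 1-D, non-empty, equal length")
    _, gi = np.unique(gt, return_inverse=True)
    _, pi = np.unique(pred, return_inverse=True)
    k1, k2 = gi.max() + 1, pi.max() + 1
    table = np.zeros((k1, k2), dtype=np.int64)
    np.add.at(table, (gi, pi), 1)
    return table


def _entropy(counts: np.ndarray) -> float:
    n = counts.sum()
    p = counts[counts > 0] / n
    return float(-(p * np.log(p)).sum())


def _mutual_information(table: np.ndarray) -> float:
    n = table.sum()
    a = table.sum(axis=1)
    b = table.sum(axis=0)
    nz = table > 0
    t = table[nz].astype(float)
    outer = np.outer(a, b)[nz].astype(float)
    return float((t / n * (np.log(t * n) - np.log(outer))).sum())


def expected_mutual_information(table: np.ndarray) -> float:
    """Exact E[MI] under the permutation (hypergeometric) null model."""
    n = int(table.sum())
    a = table.sum(axis=1).astype(int)
    b = table.sum(axis=0).astype(int)
    lgfact = gammaln(np.arange(n + 2))  # lgfact[k] = log((k-1)!)

    def lf(k):  # log k!
        return lgfact[k + 1]

    emi = 0.0
    for ai in a:
        for bj in b:
            lo = max(1, ai + bj - n)
            hi = min(ai, bj)
            if hi < lo:
                continue
            nij = np.arange(lo, hi + 1)
            log_term = (
                lf(ai) + lf(bj) + lf(n - ai) + lf(n - bj) - lf(n)
                - lf(nij) - lf(ai - nij) - lf(bj - nij)
                - lf(n - ai - bj + nij)
            )
            emi += float(
                ((nij / n) * np.log(n * nij / (ai * bj)) * np.exp(log_term)).sum()
            )
    return float(emi)


def _same_partition(table: np.ndarray) -> bool:
    """True iff the two labelings induce identical partitions (up to renaming)."""
    nz = table > 0
    return bool((nz.sum(axis=1) == 1).all() and (nz.sum(axis=0) == 1).all())


def nmi(gt, pred) -> float:
    """Normalized mutual information, MI / max(H(gt), H(pred)).

    Both labelings constant is the defined limit 1; exactly one
    constant gives 0.
    """
    table = _contingency(gt, pred)
    h1 = _entropy(table.sum(axis=1))
    h2 = _entropy(table.sum(axis=0))
    hmax = max(h1, h2)
    if hmax == 0.0:
        return 1.0
    return _mutual_information(table) / hmax


def ami(gt, pred) -> float:
    """Adjusted mutual information with arithmetic-mean normalization."""
    table = _contingency(gt, pred)
    h1 = _entropy(table.sum(axis=1))
    h2 = _entropy(table.sum(axis=0))
    if h1 == 0.0 and h2 == 0.0:
        return 1.0
    mi = _mutual_information(table)
    emi = expected_mutual_information(table)
    denom = 0.5 * (h1 + h2) - emi
    if abs(denom) < 1e-15:
        return 1.0 if _same_partition(table) else 0.0
    return (mi - emi) / denom


def ari(gt, pred) -> float:
    """Adjusted Rand index via the pair-counting contingency formula."""
    table = _contingency(gt, pred)
    n = int(table.sum())
    if n < 2:
        raise InputError("need at least 2 items to compute the Rand index")
    def comb2(x):
        x = np.asarray(x, dtype=float)
        return x * (x - 1) / 2.0
    sum_ij = comb2(table).sum()
    sum_a = comb2(table.sum(axis=1)).sum()
    sum_b = comb2(table.sum(axis=0)).sum()
    total = comb2(np.array([n]))[0]
    expected = sum_a * sum_b / total
    max_index = 0.5 * (sum_a + sum_b)
    if max_index == expected:  # both partitions trivial
        return 1.0
    return float((sum_ij - expected) / (max_index - expected))


@dataclass(frozen=True)
class ClusterScores:
    nmi: float
    ami: float
    ari: float


def score_clusters(gt, pred) -> ClusterScores:
    """All three agreement scores for one (ground truth, predicted) pair."""
    return ClusterScores(nmi=nmi(gt, pred), ami=ami(gt, pred), ari=ari(gt, pred))
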