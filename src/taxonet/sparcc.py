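"""SparCC basis-correlation inference and edge sparsification.

SparCC estimates "basis" correlations between taxa from the variation matrix
``t_ij = Var(log(x_i / x_j))`` under a sparsity assumption: for mostly
uncorrelated taxa the pairwise log-ratio variances decompose as
``t_ij ~ w_i + w_j - 2 rho_ij sqrt(w_i w_j)`` with the correlation terms
averaging out, giving a linear system for the basis variances ``w``.  Strongly
correlated pairs violate the assumption, so the estimator iteratively excludes
the most correlated pair from the system and re-solves.

Edges are then sparsified by a one-sample t-test on each correlation and a
local-false-discovery-rate (lfdr) cut-off, with Benjamini-Hochberg as a
fallback when there are too few pairs to estimate the lfdr mixture density.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "VariationMatrix",
    "CorrelationEstimate",
    "EdgeTest",
    "variation_matrix",
    "basis_variances",
    "sparcc",
    "sparcc_resampled",
    "edge_significance",
    "lfdr_adjust",
    "estimate_lfdr",
]

OMEGA_FLOOR = 1e-10
MIN_PAIRS_FOR_LFDR = 50


@dataclass
class VariationMatrix:
    t: np.ndarray                  # D x D, symmetric, zero diagonal
    n_samples: int
    genus_ids: list[str] | None = None


@dataclass
class CorrelationEstimate:
    rho: np.ndarray                # D x D in [-1, 1], unit diagonal
    basis_variance: np.ndarray     # per-genus w_i > 0
    excluded_pairs: set[tuple[int, int]]
    n_samples: int
    genus_ids: list[str] | None = None

    def rho_frame(self) -> pd.DataFrame:
        ids = self.genus_ids or [str(i) for i in range(self.rho.shape[0])]
        return pd.DataFrame(self.rho, index=ids, columns=ids)


@dataclass
class EdgeTest:
    """Per unordered pair (i < j): statistic, p-value, lfdr and keep flag."""

    pairs: np.ndarray              # (n_pairs, 2) int indices
    rho: np.ndarray
    t_stat: np.ndarray
    p_value: np.ndarray
    n_samples: int
    alpha: float = 0.05
    lfdr: np.ndarray | None = None
    keep: np.ndarray | None = None
    method: str | None = None
    genus_ids: list[str] | None = None

    def frame(self) -> pd.DataFrame:
        ids = self.genus_ids or [str(i) for i in range(int(self.pairs.max()) + 1)]
        df = pd.DataFrame(
            {
                "genus_i": [ids[i] for i in self.pairs[:, 0]],
                "genus_j": [ids[j] for j in self.pairs[:, 1]],
                "rho": self.rho,
                "t": self.t_stat,
                "p": self.p_value,
            }
        )
        if self.lfdr is not None:
            df["lfdr"] = self.lfdr
        if self.keep is not None:
            df["keep"] = self.keep
        return df


def _composition_array(comp) -> np.ndarray:
    frac = getattr(comp, "fractions", comp)
    return frac.to_numpy(dtype=float) if hasattr(frac, "to_numpy") else np.asarray(frac, float)


def variation_matrix(comp) -> VariationMatrix:
    """Sample variance of all pairwise log-ratios (unbiased, n-1 denominator)."""
    arr = _composition_array(comp)
    D, n = arr.shape
    if D < 3:
        raise ValueError("need at least 3 taxa for the SparCC basis system")
    if n < 3:
        raise ValueError("need at least 3 samples")
    if (arr <= 0).any():
        raise ValueError("compositions must be strictly positive")
    logs = np.log(arr)
    cov = np.cov(logs, ddof=1)                      # D x D covariance over samples
    v = np.diag(cov)
    t = v[:, None] + v[None, :] - 2.0 * cov
    np.fill_diagonal(t, 0.0)
    t = np.clip((t + t.T) / 2.0, 0.0, None)
    ids = list(comp.fractions.index) if hasattr(comp, "fractions") else None
    return VariationMatrix(t=t, n_samples=n, genus_ids=ids)


def basis_variances(t: np.ndarray, excluded: set[tuple[int, int]] | None = None) -> np.ndarray:
    """Solve the sparsity approximation ``t_i = |K_i| w_i + sum_{j in K_i} w_j``.

    ``K_i`` is the set of partners of taxon ``i`` whose pair has not been
    excluded.  Without exclusions this reduces to the closed form
    ``w_i = (t_i - T) / (D - 2)`` with ``T = sum_i t_i / (2 (D - 1))``.
    """
    D = t.shape[0]
    if D < 3:
        raise ValueError("basis system requires at least 3 taxa")
    include = np.ones((D, D), dtype=bool)
    np.fill_diagonal(include, False)
    for i, j in excluded or ():
        include[i, j] = include[j, i] = False
    if (include.sum(axis=1) < 2).any():
        bad = np.flatnonzero(include.sum(axis=1) < 2)
        raise ValueError(
            f"excluded pairs leave taxa {bad.tolist()} with fewer than two partners"
        )
    M = include.astype(float)
    np.fill_diagonal(M, include.sum(axis=1))
    t_row = (t * include).sum(axis=1)
    try:
        w = np.linalg.solve(M, t_row)
    except np.linalg.LinAlgError as exc:
        raise ValueError(f"singular basis system with exclusions {sorted(excluded or ())}") from exc
    return np.maximum(w, OMEGA_FLOOR)


def _rho_from_omega(t: np.ndarray, w: np.ndarray) -> np.ndarray:
    rho = (w[:, None] + w[None, :] - t) / (2.0 * np.sqrt(np.outer(w, w)))
    rho = np.clip(rho, -1.0, 1.0)
    np.fill_diagonal(rho, 1.0)
    return rho


def sparcc(
    comp,
    exclusion_threshold: float = 0.1,
    max_exclusion_iters: int = 10,
) -> CorrelationEstimate:
    """Iterative SparCC estimate on a zero-replaced composition.

    Runs a single deterministic pass (zeros are handled upstream, so the
    original tool's Dirichlet resampling adds nothing but noise here): solve
    for basis variances, form correlations, exclude the most strongly
    correlated still-included pair above ``exclusion_threshold``, re-solve;
    stop after ``max_exclusion_iters`` exclusions or when no pair exceeds the
    threshold.
    """
    vm = variation_matrix(comp)
    t = vm.t
    D = t.shape[0]
    excluded: set[tuple[int, int]] = set()
    w = basis_variances(t, excluded)
    rho = _rho_from_omega(t, w)
    for _ in range(max_exclusion_iters):
        cand = np.abs(rho).copy()
        np.fill_diagonal(cand, 0.0)
        for i, j in excluded:
            cand[i, j] = cand[j, i] = 0.0
        i, j = np.unravel_index(np.argmax(cand), cand.shape)
        if cand[i, j] <= exclusion_threshold:
            break
        trial = excluded | {(min(i, j), max(i, j))}
        try:
            w = basis_variances(t, trial)
        except ValueError:
            break                                    # exclusion would degenerate the system
        excluded = trial
        rho = _rho_from_omega(t, w)
    return CorrelationEstimate(
        rho=rho,
        basis_variance=w,
        excluded_pairs=excluded,
        n_samples=vm.n_samples,
        genus_ids=vm.genus_ids,
    )


def sparcc_resampled(
    table,
    n_resamples: int = 20,
    seed: int = 0,
    exclusion_threshold: float = 0.1,
    max_exclusion_iters: int = 10,
) -> CorrelationEstimate:
    """SparCC with the original tool's Dirichlet resampling, for fidelity
    checks against the deterministic single pass.

    Each inner iteration draws per-sample fractions from Dirichlet(counts +
    1/2), runs the deterministic estimator, and the element-wise median of
    the resampled correlation matrices is reported.
    """
    counts = table.counts.to_numpy(dtype=float) if hasattr(table, "counts") else np.asarray(table, float)
    if n_resamples < 1:
        raise ValueError("n_resamples must be at least 1")
    rng = np.random.default_rng(seed)
    rhos = []
    last = None
    for _ in range(n_resamples):
        frac = np.column_stack(
            [rng.dirichlet(counts[:, j] + 0.5) for j in range(counts.shape[1])]
        )
        last = sparcc(frac, exclusion_threshold, max_exclusion_iters)
        rhos.append(last.rho)
    rho = np.median(rhos, axis=0)
    np.fill_diagonal(rho, 1.0)
    ids = list(table.counts.index) if hasattr(table, "counts") else None
    return CorrelationEstimate(
        rho=rho,
        basis_variance=last.basis_variance,
        excluded_pairs=last.excluded_pairs,
        n_samples=counts.shape[1],
        genus_ids=ids,
    )


def edge_significance(est: CorrelationEstimate, alpha: float = 0.05) -> EdgeTest:
    """One-sample t-test of each correlation against zero.

    Uses Pearson's sampling distribution ``t = rho sqrt((n-2)/(1-rho^2))``
    with ``n - 2`` degrees of freedom; ``rho = +-1`` maps to ``p = 0``.
    """
    n = est.n_samples
    if n <= 3:
        raise ValueError("need more than 3 samples for the edge t-test")
    D = est.rho.shape[0]
    iu, ju = np.triu_indices(D, k=1)
    rho = est.rho[iu, ju]
    with np.errstate(divide="ignore"):
        t_stat = rho * np.sqrt((n - 2) / np.maximum(1.0 - rho**2, 0.0))
    p = np.where(
        np.isfinite(t_stat),
        2.0 * stats.t.sf(np.abs(t_stat), df=n - 2),
        0.0,
    )
    return EdgeTest(
        pairs=np.column_stack([iu, ju]),
        rho=rho,
        t_stat=t_stat,
        p_value=p,
        n_samples=n,
        alpha=alpha,
        genus_ids=est.genus_ids,
    )


def estimate_lfdr(z: np.ndarray) -> tuple[np.ndarray, dict]:
    """Local false discovery rate via an empirical-null mixture estimate.

    The mixture density ``f(z)`` is fitted by Lindsey's method (Poisson
    regression of bin counts on a polynomial basis); the null component
    ``pi0 N(mu0, sigma0^2)`` is recovered by central matching: a quadratic fit
    to ``log f`` around its mode.  Returns ``lfdr(z) = pi0 phi(z) / f(z)``
    capped at one, plus the fitted null parameters.
    """
    z = np.asarray(z, float)
    n = z.size
    n_bins = int(np.clip(n // 8, 20, 120))
    counts, edges = np.histogram(z, bins=n_bins)
    mids = (edges[:-1] + edges[1:]) / 2.0
    width = edges[1] - edges[0]
    degree = min(7, max(3, n_bins // 10))
    basis = np.vander((mids - mids.mean()) / mids.std(), degree + 1, increasing=True)

    import statsmodels.api as sm

    fit = sm.GLM(counts, basis, family=sm.families.Poisson()).fit()
    dens = np.maximum(fit.mu, 1e-12) / (n * width)   # fitted mixture density at bin mids

    # central matching: quadratic log-density around the mode
    mode = mids[np.argmax(dens)]
    half = max(4, n_bins // 4)
    sel = np.argsort(np.abs(mids - mode))[:half]
    sel = np.sort(sel)
    coef = np.polyfit(mids[sel], np.log(dens[sel]), 2)
    if coef[0] < 0:
        sigma0 = float(np.sqrt(-1.0 / (2.0 * coef[0])))
        mu0 = float(coef[1] * sigma0**2)
        f_mu0 = float(np.exp(np.polyval(coef, mu0)))
        pi0 = min(1.0, f_mu0 * sigma0 * np.sqrt(2.0 * np.pi))
    else:                                            # flat center: theoretical null
        mu0, sigma0 = 0.0, 1.0
        pi0 = min(1.0, 2.0 * np.mean(np.abs(z - np.median(z)) < 0.6745) / 0.5)
        pi0 = min(pi0, 1.0)

    f_z = np.interp(z, mids, dens)
    f_z = np.maximum(f_z, 1e-12)
    lfdr = np.minimum(pi0 * stats.norm.pdf(z, mu0, sigma0) / f_z, 1.0)
    return lfdr, {"pi0": pi0, "mu0": mu0, "sigma0": sigma0}


def lfdr_adjust(test: EdgeTest, alpha: float = 0.05, method: str = "lfdr") -> EdgeTest:
    """Fill lfdr values and the keep mask.

    ``method="lfdr"`` keeps pairs with lfdr <= alpha; ``method="bh"`` is the
    Benjamini-Hochberg fallback on the t-test p-values (recommended when there
    are few pairs, where the lfdr density estimate is unstable).
    """
    n_pairs = test.rho.size
    if method == "lfdr":
        if n_pairs < MIN_PAIRS_FOR_LFDR:
            raise ValueError(
                f"{n_pairs} pairs is too few for lfdr density estimation; "
                "use method='bh' instead"
            )
        if test.n_samples <= 3:
            raise ValueError("lfdr z-scores need more than 3 samples")
        z = np.arctanh(np.clip(test.rho, -1 + 1e-12, 1 - 1e-12)) * np.sqrt(test.n_samples - 3)
        lfdr, _ = estimate_lfdr(z)
        keep = lfdr <= alpha
    elif method == "bh":
        keep, lfdr, _, _ = multipletests(test.p_value, alpha=alpha, method="fdr_bh")
        keep = lfdr <= alpha
    else:
        raise ValueError(f"unknown sparsification method {method!r}")
    return EdgeTest(
        pairs=test.pairs,
        rho=test.rho,
        t_stat=test.t_stat,
        p_value=test.p_value,
        n_samples=test.n_samples,
        alpha=alpha,
        lfdr=lfdr,
        keep=keep,
        method=method,
        genus_ids=test.genus_ids,
    )
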