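"""Reduced K x K eigenproblem for the axes of variation.

The mean-adjusted block covariance of n individuals from K populations has
two families of eigenpairs: n - K "small" within-population eigenvalues
sigma2_s - c_s, and K "large" eigenpairs whose eigenvectors are constant
within populations.  The large pairs solve a K x K eigen-equation built from
the adjusted parameters and the sample sizes; its solutions are the axes of
variation on which each population is a single representative point.

Conventions used throughout:

* the reduced matrix R has entries R_st = n_t d~_st (+ sigma2~ - c~ on the
  diagonal, with d~_ss = c~_s); its rows sum to zero after adjustment;
* solving goes through the symmetrized form B = S R S^-1, S = diag(sqrt n_s);
* axis coefficients a_s are normalized to sum_s n_s a_s^2 = 1; nontrivial
  axes satisfy the contrast constraint sum_s n_s a_s = 0;
* per axis, the coefficient of largest magnitude is made positive (scatter
  plots are otherwise mirror-ambiguous).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .model import CovParams, ModelError, PopulationLayout, mean_adjust

__all__ = [
    "ReducedSystem",
    "ReducedEigenSolution",
    "AsymptoticSolution",
    "build_reduced",
    "solve_reduced",
    "reduce_and_solve",
    "small_eigenvalues",
    "two_pop_closed_form",
    "asymptotic_solve",
    "asymptotic_error_ratio",
    "critical_size",
    "representative_distances",
]

ZERO_EIG_RTOL = 1e-9


@dataclass(frozen=True)
class ReducedSystem:
    """The reduced matrix R, its symmetrized form B, and their provenance."""

    R: np.ndarray
    B: np.ndarray
    layout: PopulationLayout
    source: CovParams


@dataclass(frozen=True)
class ReducedEigenSolution:
    """Eigenvalues (descending) and per-population axis coefficients.

    ``coefficients[j]`` is the length-K coefficient vector of axis j; the
    trivial axis (zero eigenvalue, constant coefficients, a by-product of the
    mean adjustment) sits at ``trivial_index``.
    """

    eigenvalues: np.ndarray
    coefficients: np.ndarray
    layout: PopulationLayout
    trivial_index: int

    @property
    def K(self) -> int:
        return self.eigenvalues.shape[0]

    def nontrivial_axes(self) -> list[int]:
        return [j for j in range(self.K) if j != self.trivial_index]

    def nontrivial_coefficients(self) -> np.ndarray:
        """Coefficient vectors of the K-1 structure axes, top eigenvalue first."""
        return self.coefficients[self.nontrivial_axes()]


@dataclass(frozen=True)
class AsymptoticSolution:
    """n-independent limit of the axes of variation at fixed proportions.

    ``unit_eigenvalues`` are the eigenvalues of the limiting matrix A; the
    large eigenvalues of the finite problem grow as n * eig(A).  ``neglected``
    is the per-population O(1/n) term (sigma2_s - c_s)/n dropped from the
    eigen-equation, reported for a caller-supplied reference n.
    """

    A: np.ndarray
    unit_eigenvalues: np.ndarray
    coefficients: np.ndarray
    proportions: np.ndarray
    trivial_index: int
    neglected: np.ndarray | None = None

    def nontrivial_axes(self) -> list[int]:
        return [
            j for j in range(self.unit_eigenvalues.shape[0]) if j != self.trivial_index
        ]

    def nontrivial_coefficients(self) -> np.ndarray:
        return self.coefficients[self.nontrivial_axes()]


def build_reduced(adj: CovParams, layout: PopulationLayout) -> ReducedSystem:
    """Assemble the reduced matrix from mean-adjusted parameters."""
    if not adj.adjusted:
        raise ModelError(
            "build_reduced requires mean-adjusted parameters; call mean_adjust first"
        )
    adj.require_layout(layout)
    ns = layout.sizes_array
    excess = adj.sigma2 - adj.c
    R = adj.d * ns[None, :]
    R[np.diag_indices(layout.K)] += excess
    sqrt_ns = np.sqrt(ns)
    B = adj.d * np.outer(sqrt_ns, sqrt_ns)
    B[np.diag_indices(layout.K)] += excess
    return ReducedSystem(R=R, B=B, layout=layout, source=adj)


def _fix_signs(coefficients: np.ndarray) -> np.ndarray:
    out = coefficients.copy()
    for j in range(out.shape[0]):
        dom = int(np.argmax(np.abs(out[j])))
        if out[j, dom] < 0:
            out[j] = -out[j]
    return out


def solve_reduced(system: ReducedSystem) -> ReducedEigenSolution:
    """Solve the reduced eigenproblem via its symmetric form.

    Returns eigenvalues in descending order with coefficients normalized to
    sum_s n_s a_s^2 = 1.  Eigenvalue ties (degenerate populations) are broken
    by the ascending population index of each axis's dominant coefficient.
    """
    ns = system.layout.sizes_array
    eigvals, eigvecs = np.linalg.eigh(system.B)  # ascending
    order = np.argsort(-eigvals, kind="stable")
    eigvals = eigvals[order]
    a = (eigvecs[:, order] / np.sqrt(ns)[:, None]).T  # rows = axes
    # exact weighted normalization (eigh already gives unit b = sqrt(n) a)
    a /= np.sqrt(np.sum(ns * a**2, axis=1))[:, None]
    a = _fix_signs(a)
    # tie-break within numerically equal eigenvalues
    scale = max(np.max(np.abs(eigvals)), 1.0)
    j = 0
    while j < len(eigvals):
        k = j + 1
        while k < len(eigvals) and abs(eigvals[k] - eigvals[j]) <= 1e-12 * scale:
            k += 1
        if k - j > 1:
            dom = np.argmax(np.abs(a[j:k]), axis=1)
            sub = np.argsort(dom, kind="stable")
            eigvals[j:k] = eigvals[j:k][sub]
            a[j:k] = a[j:k][sub]
        j = k
    trivial = int(np.argmin(np.abs(eigvals)))
    if abs(eigvals[trivial]) > ZERO_EIG_RTOL * scale:
        raise ModelError(
            "no zero eigenvalue found; reduced system does not look mean-adjusted"
        )
    return ReducedEigenSolution(
        eigenvalues=eigvals,
        coefficients=a,
        layout=system.layout,
        trivial_index=trivial,
    )


def reduce_and_solve(
    params: CovParams, layout: PopulationLayout
) -> ReducedEigenSolution:
    """Convenience pipeline: mean-adjust raw parameters, build, and solve."""
    adj, _ = mean_adjust(params, layout)
    return solve_reduced(build_reduced(adj, layout))


def small_eigenvalues(
    params: CovParams, layout: PopulationLayout
) -> list[tuple[float, int]]:
    """Within-population eigenvalues sigma2_s - c_s, multiplicity n_s - 1.

    Unaffected by the mean adjustment; equal values across populations are
    merged into a single (value, multiplicity) entry.
    """
    params.require_layout(layout)
    excess = params.sigma2 - params.c
    merged: list[tuple[float, int]] = []
    for s in range(layout.K):
        mult = layout.sizes[s] - 1
        if mult == 0:
            continue
        for i, (val, m) in enumerate(merged):
            if np.isclose(val, excess[s], rtol=1e-12, atol=1e-15):
                merged[i] = (val, m + mult)
                break
        else:
            merged.append((float(excess[s]), mult))
    return merged


def two_pop_closed_form(
    layout: PopulationLayout, adj: CovParams
) -> tuple[float, np.ndarray]:
    """Closed-form nontrivial axis for exactly two populations.

    The contrast and normalization constraints alone force the coefficients
    a = (sqrt(n2/(n1 n)), -sqrt(n1/(n2 n))) up to sign -- the axis depends
    only on the sample-size ratio.  The associated large eigenvalue is
    -n * d~_12, which the reduced solver reproduces.
    """
    if layout.K != 2:
        raise ModelError("closed form applies to exactly two populations")
    if not adj.adjusted:
        raise ModelError("closed form expects mean-adjusted parameters")
    n1, n2 = layout.sizes
    n = layout.n
    a = np.array([np.sqrt(n2 / (n1 * n)), -np.sqrt(n1 / (n2 * n))])
    a = _fix_signs(a[None, :])[0]
    eigenvalue = -n * float(adj.d[0, 1])
    return eigenvalue, a


def _limit_adjust(params: CovParams, w: np.ndarray) -> np.ndarray:
    """Mean adjustment of the covariance block in the n -> infinity limit.

    Replacing n_s/n by w_s and dropping the O(1/n) diagonal corrections gives
    r_s = sum_t w_t d_st and g = w' D w; returns the adjusted D~ (diag c~).
    """
    D = params.d
    r = D @ w
    g = float(w @ D @ w)
    return D - r[:, None] - r[None, :] + g


def asymptotic_solve(
    params: CovParams,
    proportions: np.ndarray,
    n_ref: int | None = None,
) -> AsymptoticSolution:
    """Solve the large-n limit of the reduced eigen-equation.

    At fixed population proportions w_s the axis coefficients stop depending
    on the total sample size and, notably, on the variances sigma2_s: the
    limiting matrix A_st = w_t d~_st is built from covariances alone (the
    diagonal variance excess enters only the neglected O(1/n) term).  Large
    eigenvalues of the finite problem grow as n * eig(A).
    """
    if params.adjusted:
        raise ModelError("asymptotic_solve expects raw parameters")
    w = np.asarray(proportions, dtype=float)
    if w.shape != (params.K,):
        raise ModelError("proportions must have one weight per population")
    if np.any(w <= 0) or not np.isclose(w.sum(), 1.0, atol=1e-9):
        raise ModelError("proportions must be positive and sum to 1")
    D_adj = _limit_adjust(params, w)
    sqrt_w = np.sqrt(w)
    B = D_adj * np.outer(sqrt_w, sqrt_w)
    eigvals, eigvecs = np.linalg.eigh(B)
    order = np.argsort(-eigvals, kind="stable")
    eigvals = eigvals[order]
    a = (eigvecs[:, order] / sqrt_w[:, None]).T
    a /= np.sqrt(np.sum(w * a**2, axis=1))[:, None]
    a = _fix_signs(a)
    trivial = int(np.argmin(np.abs(eigvals)))
    neglected = None
    if n_ref is not None:
        neglected = (params.sigma2 - params.c) / n_ref
    return AsymptoticSolution(
        A=D_adj * w[None, :],
        unit_eigenvalues=eigvals,
        coefficients=a,
        proportions=w,
        trivial_index=trivial,
        neglected=neglected,
    )


def asymptotic_error_ratio(
    params: CovParams, proportions: np.ndarray, n: int
) -> float:
    """Size of the neglected term relative to the smallest structure eigenvalue.

    Ratio max_s (sigma2_s - c_s) / (n * lambda_min_nontrivial(A)); the
    asymptotic pattern is trustworthy once this is well below 1.
    """
    sol = asymptotic_solve(params, proportions)
    lams = sol.unit_eigenvalues[sol.nontrivial_axes()]
    lam_min = float(np.min(np.abs(lams)))
    if lam_min <= 0:
        raise ModelError("degenerate limit: no positive structure eigenvalue")
    return float(np.max(params.sigma2 - params.c) / (n * lam_min))


def critical_size(params: CovParams, K: int | None = None) -> float:
    """Sample size beyond which the PC-plot pattern is essentially asymptotic.

    Closed form for the exchangeable case (equal sigma2, c, and equal
    between-population d): n* = K (sigma2 - c) / (c - d), the n at which the
    neglected within-population term matches the structure eigenvalue
    (c - d)/K of the limiting matrix.  Diverges as d -> c: near-identical
    populations need ever larger samples before the pattern stabilises.
    """
    if K is None:
        K = params.K
    if K != params.K:
        raise ModelError("K does not match the parameter dimension")
    sigma2 = params.sigma2
    c = params.c
    off = params.d[~np.eye(K, dtype=bool)]
    if K < 2:
        raise ModelError("critical size needs at least two populations")
    if not (
        np.allclose(sigma2, sigma2[0], rtol=1e-9)
        and np.allclose(c, c[0], rtol=1e-9)
        and (off.size == 0 or np.allclose(off, off[0], rtol=1e-9))
    ):
        raise ModelError(
            "closed form requires exchangeable populations; "
            "use asymptotic_error_ratio for the general case"
        )
    d = float(off[0])
    if c[0] <= d:
        raise ModelError(
            "c <= d: populations are indistinguishable, critical size undefined"
        )
    if K == 2:
        warnings.warn(
            "with two populations the structure axis is fixed by the sample-size "
            "ratio at any n; the critical size only gauges the eigenvalue",
            stacklevel=2,
        )
    return float(K * (sigma2[0] - c[0]) / (c[0] - d))


def representative_distances(
    sol: ReducedEigenSolution, axis: int, pair: tuple[str, str]
) -> float:
    """Distance |a_s - a_t| between two populations on one nontrivial axis."""
    if axis == sol.trivial_index:
        raise ModelError("the trivial axis carries no population contrast")
    labels = list(sol.layout.labels)
    try:
        s, t = labels.index(pair[0]), labels.index(pair[1])
    except ValueError as exc:
        raise ModelError(f"unknown population in pair {pair}") from exc
    return float(abs(sol.coefficients[axis, s] - sol.coefficients[axis, t]))
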