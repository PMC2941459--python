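"""Block-structured covariance model for genotypes of stratified samples.

Individuals sampled from K discrete populations share allele frequencies
drawn per marker, which makes their allele counts correlated: the n x n
variance-covariance matrix of the vector of allele counts is block
compound-symmetric.  Three kinds of parameters describe it completely:

* ``sigma2[s]`` -- variance of the allele count of one individual from
  population s,
* ``c[s]``     -- covariance of two *distinct* individuals from s,
* ``d[s, t]``  -- covariance of individuals from different populations s, t.

This module holds those parameters, derives them from an allele-frequency
model (mean vector and frequency covariance matrix), applies the per-marker
mean adjustment that removes the single co-variation eigenvalue, and can
materialise the full n x n matrix as a brute-force oracle for small n.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "PopulationLayout",
    "AlleleFreqModel",
    "CovParams",
    "AdjustmentAggregates",
    "ModelError",
    "OversizeError",
    "freq_to_cov",
    "mean_adjust",
    "build_full_cov",
]

_PSD_TOL = 1e-9


class ModelError(ValueError):
    """Raised when model parameters violate their invariants."""


class OversizeError(ValueError):
    """Raised when the dense n x n constructor is asked for too large an n."""


@dataclass(frozen=True)
class PopulationLayout:
    """Sample composition: which populations, and how many from each.

    Individuals are implicitly ordered population-by-population: first all
    ``sizes[0]`` members of ``labels[0]``, then ``labels[1]``, and so on.
    """

    labels: tuple[str, ...]
    sizes: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.labels) != len(self.sizes):
            raise ModelError(
                f"{len(self.labels)} labels but {len(self.sizes)} sizes"
            )
        if len(self.labels) < 1:
            raise ModelError("need at least one population")
        if len(set(self.labels)) != len(self.labels):
            raise ModelError("population labels must be unique")
        if any(int(s) != s or s < 1 for s in self.sizes):
            raise ModelError(f"sizes must be positive integers, got {self.sizes}")
        object.__setattr__(self, "labels", tuple(str(x) for x in self.labels))
        object.__setattr__(self, "sizes", tuple(int(s) for s in self.sizes))

    @property
    def K(self) -> int:
        return len(self.labels)

    @property
    def n(self) -> int:
        return int(sum(self.sizes))

    @property
    def proportions(self) -> np.ndarray:
        """Relative sample sizes w_s = n_s / n."""
        return np.asarray(self.sizes, dtype=float) / self.n

    @property
    def sizes_array(self) -> np.ndarray:
        return np.asarray(self.sizes, dtype=float)

    def slices(self) -> list[slice]:
        """Per-population index ranges in the implied individual order."""
        edges = np.concatenate([[0], np.cumsum(self.sizes)]).astype(int)
        return [slice(edges[k], edges[k + 1]) for k in range(self.K)]

    def individual_labels(self) -> list[str]:
        out: list[str] = []
        for lab, size in zip(self.labels, self.sizes):
            out.extend([lab] * size)
        return out

    def expand(self, per_pop: np.ndarray) -> np.ndarray:
        """Repeat a length-K vector into a length-n per-individual vector."""
        per_pop = np.asarray(per_pop)
        if per_pop.shape[0] != self.K:
            raise ModelError("per-population vector has wrong length")
        return np.repeat(per_pop, self.sizes, axis=0)

    @classmethod
    def from_individual_labels(cls, labels) -> "PopulationLayout":
        """Build a layout from per-individual labels (first-appearance order).

        The individuals need not be sorted by population; the returned layout
        records populations in order of first appearance with their counts.
        """
        labels = [str(x) for x in labels]
        seen: dict[str, int] = {}
        for lab in labels:
            seen[lab] = seen.get(lab, 0) + 1
        return cls(tuple(seen.keys()), tuple(seen.values()))


@dataclass(frozen=True)
class AlleleFreqModel:
    """Per-population allele-frequency law for a random marker.

    ``mu[s]`` is the mean frequency in population s and ``psi[s, t]`` the
    covariance of the frequency vector across populations.  Genotypes are
    modelled as Binomial(2, f_s) given the frequencies (Hardy-Weinberg,
    diploid), with individuals conditionally independent.
    """

    mu: np.ndarray
    psi: np.ndarray

    def __post_init__(self) -> None:
        mu = np.atleast_1d(np.asarray(self.mu, dtype=float))
        psi = np.atleast_2d(np.asarray(self.psi, dtype=float))
        object.__setattr__(self, "mu", mu)
        object.__setattr__(self, "psi", psi)
        K = mu.shape[0]
        if psi.shape != (K, K):
            raise ModelError(f"psi must be {K}x{K}, got {psi.shape}")
        if np.any(mu < 0) or np.any(mu > 1):
            raise ModelError("mean allele frequencies must lie in [0, 1]")
        if not np.allclose(psi, psi.T, atol=1e-12):
            raise ModelError("psi must be symmetric")
        if np.linalg.eigvalsh(psi).min() < -_PSD_TOL:
            raise ModelError("psi must be positive semidefinite")
        if np.any(np.diag(psi) > mu * (1 - mu) + _PSD_TOL):
            raise ModelError("frequency variance exceeds mu(1-mu) bound")

    @property
    def K(self) -> int:
        return self.mu.shape[0]


@dataclass(frozen=True)
class CovParams:
    """The (sigma2, c, d) triple of the block compound-symmetric covariance.

    ``d`` is a K x K symmetric matrix whose diagonal holds, by convention,
    the within-population covariances ``c`` (the convention under which the
    adjusted parameters satisfy a zero-sum identity row by row).  ``adjusted``
    marks whether the per-marker mean adjustment has been applied.
    """

    sigma2: np.ndarray
    c: np.ndarray
    d: np.ndarray
    adjusted: bool = False

    def __post_init__(self) -> None:
        sigma2 = np.atleast_1d(np.asarray(self.sigma2, dtype=float))
        c = np.atleast_1d(np.asarray(self.c, dtype=float))
        K = sigma2.shape[0]
        if c.shape != (K,):
            raise ModelError("sigma2 and c must have the same length")
        d = np.atleast_2d(np.asarray(self.d, dtype=float)).copy()
        if d.shape != (K, K):
            raise ModelError(f"d must be {K}x{K}, got {d.shape}")
        if not np.allclose(d, d.T, atol=1e-10):
            raise ModelError("d must be symmetric")
        d = (d + d.T) / 2.0
        np.fill_diagonal(d, c)
        if not self.adjusted and np.any(sigma2 < c - 1e-12):
            raise ModelError("raw parameters require sigma2 >= c (variance bound)")
        object.__setattr__(self, "sigma2", sigma2)
        object.__setattr__(self, "c", c)
        object.__setattr__(self, "d", d)

    @property
    def K(self) -> int:
        return self.sigma2.shape[0]

    def d_between(self, s: int, t: int) -> float:
        """Between-population covariance; equals c[s] when s == t."""
        return float(self.d[s, t])

    def require_layout(self, layout: PopulationLayout) -> None:
        if layout.K != self.K:
            raise ModelError(
                f"parameters are for K={self.K} populations, layout has K={layout.K}"
            )


@dataclass(frozen=True)
class AdjustmentAggregates:
    """Auxiliary quantities of the mean adjustment.

    ``r[s]`` is the covariance of an individual from population s with the
    grand individual mean; ``g`` is the variance of that grand mean.
    """

    r: np.ndarray
    g: float


def freq_to_cov(model: AlleleFreqModel) -> CovParams:
    """Derive the raw covariance parameters from the allele-frequency model.

    With allele counts X | f ~ Binomial(2, f_s) and individuals conditionally
    independent given the frequency vector,

        sigma2[s] = 2 mu_s (1 - mu_s) + 2 psi_ss     (law of total variance)
        c[s]      = 4 psi_ss                          (shared frequency only)
        d[s, t]   = 4 psi_st                          (s != t)

    so all between-individual covariance is inherited from the frequency law.
    """
    psi_diag = np.diag(model.psi)
    sigma2 = 2.0 * model.mu * (1.0 - model.mu) + 2.0 * psi_diag
    c = 4.0 * psi_diag
    d = 4.0 * model.psi
    return CovParams(sigma2=sigma2, c=c, d=d, adjusted=False)


def mean_adjust(
    params: CovParams, layout: PopulationLayout
) -> tuple[CovParams, AdjustmentAggregates]:
    """Apply the per-marker mean adjustment to the covariance parameters.

    Subtracting from every allele count the grand mean over all n individuals
    leaves the block structure intact and transforms the parameters as

        r_s       = (1/n) [sigma2_s + (n_s - 1) c_s + sum_{t != s} n_t d_st]
        g         = (1/n^2) [sum_t n_t sigma2_t + sum_t n_t (n_t - 1) c_t
                              + sum_{t != u} n_t n_u d_tu]
        sigma2~_s = sigma2_s - 2 r_s + g
        c~_s      = c_s - 2 r_s + g
        d~_st     = d_st - r_s - r_t + g

    The within-population differences sigma2_s - c_s (the small eigenvalues)
    are exactly preserved, and the adjusted parameters satisfy the zero-sum
    identity (sigma2~_t - c~_t) + n_t c~_t + sum_{s != t} n_s d~_st = 0 that
    makes the constant vector a null eigenvector.
    """
    if params.adjusted:
        raise ModelError("parameters are already mean-adjusted")
    params.require_layout(layout)
    ns = layout.sizes_array
    n = layout.n
    D = params.d  # diagonal already holds c
    excess = params.sigma2 - params.c
    r = (excess + D @ ns) / n
    g = float((ns @ excess + ns @ D @ ns) / n**2)
    sigma2_adj = params.sigma2 - 2.0 * r + g
    c_adj = params.c - 2.0 * r + g
    d_adj = D - r[:, None] - r[None, :] + g
    adjusted = CovParams(sigma2=sigma2_adj, c=c_adj, d=d_adj, adjusted=True)
    return adjusted, AdjustmentAggregates(r=r, g=g)


def build_full_cov(
    params: CovParams, layout: PopulationLayout, max_n: int = 2000
) -> np.ndarray:
    """Materialise the dense n x n covariance matrix (brute-force oracle).

    Diagonal block s is (sigma2_s - c_s) I + c_s J, off-diagonal block (s, t)
    is d_st J.  Exists for validation at small n; the reduced K x K solver is
    the production path and must be used beyond ``max_n``.
    """
    params.require_layout(layout)
    n = layout.n
    if n > max_n:
        raise OversizeError(
            f"n={n} exceeds the dense-oracle cap {max_n}; use the reduced solver"
        )
    # Block-constant part from d (diag = c), then the diagonal variance excess.
    per_ind = layout.expand(np.arange(layout.K))
    cov = params.d[np.ix_(per_ind, per_ind)].astype(float)
    excess = params.sigma2 - params.c
    cov[np.diag_indices(n)] += layout.expand(excess)
    return cov
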