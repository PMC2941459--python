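"""Estimation of the covariance parameters and PCs from genotype data.

The n x n sample variance-covariance matrix across markers is the empirical
twin of the model's block covariance: averaging its cells block by block
estimates (sigma2, c, d), and its eigenvectors after per-marker centering
are the familiar "sample PCs" of Eigenstrat analyses.  The representative
points of the populations -- the model's axes of variation evaluated at the
estimated parameters -- should sit at the centroids of the sample-PC
clusters.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .model import CovParams, PopulationLayout, mean_adjust
from .reduced import ReducedEigenSolution, build_reduced, solve_reduced

__all__ = [
    "GenotypeMatrix",
    "SampleCov",
    "ParamEstimates",
    "PCAResult",
    "EstimationError",
    "sample_cov",
    "estimate_params",
    "correlations",
    "representative_points",
    "sample_pca",
]

logger = logging.getLogger(__name__)


class EstimationError(ValueError):
    """Raised for data configurations under which an estimate is undefined."""


@dataclass(frozen=True)
class GenotypeMatrix:
    """Allele-count matrix: M markers (rows) x n individuals (columns).

    Entries are counts of the variant allele in {0, 1, 2}; missing genotypes
    are NaN.  ``labels`` gives the population membership of each individual
    (any order; individuals need not be grouped).
    """

    values: np.ndarray
    marker_ids: tuple[str, ...]
    individual_ids: tuple[str, ...]
    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 2:
            raise EstimationError("genotype values must be a 2-D array")
        M, n = values.shape
        if len(self.marker_ids) != M:
            raise EstimationError(f"{len(self.marker_ids)} marker ids for {M} rows")
        if len(self.individual_ids) != n:
            raise EstimationError(
                f"{len(self.individual_ids)} individual ids for {n} columns"
            )
        if len(self.labels) != n:
            raise EstimationError(f"{len(self.labels)} labels for {n} individuals")
        observed = values[~np.isnan(values)]
        if observed.size and not np.isin(observed, [0.0, 1.0, 2.0]).all():
            raise EstimationError("genotypes must be 0, 1, 2 or missing")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "marker_ids", tuple(str(x) for x in self.marker_ids))
        object.__setattr__(
            self, "individual_ids", tuple(str(x) for x in self.individual_ids)
        )
        object.__setattr__(self, "labels", tuple(str(x) for x in self.labels))

    @property
    def M(self) -> int:
        return self.values.shape[0]

    @property
    def n(self) -> int:
        return self.values.shape[1]

    @property
    def mask(self) -> np.ndarray:
        """Boolean mask, True where the genotype is observed."""
        return ~np.isnan(self.values)

    def layout(self) -> PopulationLayout:
        return PopulationLayout.from_individual_labels(self.labels)

    def population_indices(self) -> dict[str, np.ndarray]:
        labels = np.asarray(self.labels)
        return {
            lab: np.flatnonzero(labels == lab) for lab in dict.fromkeys(self.labels)
        }

    @classmethod
    def from_values(cls, values, labels, marker_ids=None, individual_ids=None):
        values = np.asarray(values, dtype=float)
        M, n = values.shape
        if marker_ids is None:
            marker_ids = tuple(f"snp{i}" for i in range(M))
        if individual_ids is None:
            individual_ids = tuple(f"ind{i}" for i in range(n))
        return cls(values, tuple(marker_ids), tuple(individual_ids), tuple(labels))


@dataclass(frozen=True)
class SampleCov:
    """Sample variance-covariance matrix of individuals across markers."""

    C: np.ndarray
    centering: str  # "individual" or "marker+individual"
    individual_ids: tuple[str, ...]
    labels: tuple[str, ...]


@dataclass(frozen=True)
class ParamEstimates:
    """Block-averaged covariance parameter estimates with standard errors.

    SEs treat the averaged matrix cells as independent, which they are not
    (cells share individuals); they are first-order gauges, not exact.
    """

    params: CovParams
    se_sigma2: np.ndarray
    se_c: np.ndarray
    se_d: np.ndarray
    cells_sigma2: np.ndarray
    cells_c: np.ndarray
    cells_d: np.ndarray
    layout: PopulationLayout


@dataclass(frozen=True)
class PCAResult:
    """Top sample eigenvectors (columns, unit norm) and eigenvalues."""

    eigenvalues: np.ndarray
    eigenvectors: np.ndarray
    dropped_monomorphic: int


def sample_cov(G: GenotypeMatrix, marker_adjust: bool = False) -> SampleCov:
    """Pairwise-complete covariance of individuals across markers.

    Each pair (i, j) is estimated over the markers where both genotypes are
    observed, with per-individual means taken over those same markers.  With
    ``marker_adjust`` each marker row is first centered across individuals
    (the per-marker mean adjustment); the eigenvectors of the resulting
    matrix are the Eigenstrat sample eigenvectors.
    """
    if G.M < 2:
        raise EstimationError("need at least two markers for a covariance")
    W = G.mask
    per_ind = W.sum(axis=0)
    if np.any(per_ind == 0):
        bad = [G.individual_ids[i] for i in np.flatnonzero(per_ind == 0)]
        raise EstimationError(f"individuals with no observed genotypes: {bad}")
    X = G.values.copy()
    if marker_adjust:
        marker_mean = np.nanmean(np.where(W, X, np.nan), axis=1, keepdims=True)
        X = X - marker_mean
    X0 = np.where(W, X, 0.0)
    Wf = W.astype(float)
    N = Wf.T @ Wf
    if np.any(N < 2):
        raise EstimationError(
            "some individual pairs share fewer than two observed markers"
        )
    S1 = X0.T @ X0
    P = X0.T @ Wf  # P[i, j] = sum of x_i over markers observed for both i and j
    C = (S1 - P * P.T / N) / (N - 1.0)
    C = (C + C.T) / 2.0
    return SampleCov(
        C=C,
        centering="marker+individual" if marker_adjust else "individual",
        individual_ids=G.individual_ids,
        labels=G.labels,
    )


def _block_stats(cells: np.ndarray) -> tuple[float, float, int]:
    m = float(np.mean(cells))
    k = cells.size
    se = float(np.std(cells, ddof=1) / np.sqrt(k)) if k > 1 else 0.0
    return m, se, k


def estimate_params(C: SampleCov, labels=None) -> ParamEstimates:
    """Block averages of the sample covariance as parameter estimates.

    sigma2_s is the mean of diagonal cells of population s, c_s the mean of
    its within-block off-diagonal cells, d_st the mean of the cross-block
    cells.  Raw (unadjusted) centering is expected; adjusted parameters are
    then derived analytically via ``mean_adjust`` so that the zero-sum
    identity of the reduced system holds exactly.
    """
    labels = tuple(labels) if labels is not None else C.labels
    if len(labels) != C.C.shape[0]:
        raise EstimationError("label count does not match covariance dimension")
    layout = PopulationLayout.from_individual_labels(labels)
    singles = [lab for lab, sz in zip(layout.labels, layout.sizes) if sz < 2]
    if singles:
        raise EstimationError(
            f"populations with a single member have undefined within-population "
            f"covariance: {singles}"
        )
    labels_arr = np.asarray(labels)
    idx = [np.flatnonzero(labels_arr == lab) for lab in layout.labels]
    K = layout.K
    sigma2 = np.empty(K)
    c = np.empty(K)
    d = np.zeros((K, K))
    se_sigma2 = np.empty(K)
    se_c = np.empty(K)
    se_d = np.zeros((K, K))
    cells_sigma2 = np.empty(K, dtype=int)
    cells_c = np.empty(K, dtype=int)
    cells_d = np.zeros((K, K), dtype=int)
    for s in range(K):
        block = C.C[np.ix_(idx[s], idx[s])]
        diag = np.diag(block)
        off = block[~np.eye(len(idx[s]), dtype=bool)]
        sigma2[s], se_sigma2[s], cells_sigma2[s] = _block_stats(diag)
        c[s], se_c[s], cells_c[s] = _block_stats(off)
        for t in range(s + 1, K):
            cross = C.C[np.ix_(idx[s], idx[t])].ravel()
            d[s, t], se_d[s, t], cells_d[s, t] = _block_stats(cross)
            d[t, s], se_d[t, s], cells_d[t, s] = d[s, t], se_d[s, t], cells_d[s, t]
    params = CovParams(sigma2=sigma2, c=c, d=d, adjusted=False)
    se_d[np.diag_indices(K)] = se_c
    cells_d[np.diag_indices(K)] = cells_c
    return ParamEstimates(
        params=params,
        se_sigma2=se_sigma2,
        se_c=se_c,
        se_d=se_d,
        cells_sigma2=cells_sigma2,
        cells_c=cells_c,
        cells_d=cells_d,
        layout=layout,
    )


def correlations(est: ParamEstimates) -> np.ndarray:
    """Correlation form of the estimates: rho_st = d_st / sqrt(s2_s s2_t).

    Diagonal entries use c_s.  Unlike the representative points, these do not
    depend on the sample sizes, which makes them the better summary of
    population distances.
    """
    sigma2 = est.params.sigma2
    if np.any(sigma2 <= 0):
        bad = [est.layout.labels[i] for i in np.flatnonzero(sigma2 <= 0)]
        raise EstimationError(f"non-positive variance estimate for {bad}")
    denom = np.sqrt(np.outer(sigma2, sigma2))
    return est.params.d / denom


def representative_points(
    est: ParamEstimates, layout: PopulationLayout | None = None
) -> ReducedEigenSolution:
    """Axes of variation evaluated at the estimated parameters.

    Runs mean adjustment, reduced-matrix construction and the eigensolver on
    the estimates; the nontrivial coefficient vectors are the representative
    points, one coordinate per population per axis.  On simulated data they
    sit at the centroids of the sample-eigenvector clusters.
    """
    if layout is None:
        layout = est.layout
    adj, _ = mean_adjust(est.params, layout)
    return solve_reduced(build_reduced(adj, layout))


def sample_pca(G: GenotypeMatrix, m: int) -> PCAResult:
    """Top-m sample eigenvectors of the marker-centered covariance.

    Markers monomorphic across the sample carry no information after
    per-marker centering and are dropped (count reported and logged).
    Eigenvectors have unit norm, descending eigenvalues, and the same
    largest-entry-positive sign convention as the reduced solver.
    """
    if m > G.n:
        raise EstimationError(f"requested {m} axes for {G.n} individuals")
    with np.errstate(invalid="ignore"):
        lo = np.nanmin(G.values, axis=1)
        hi = np.nanmax(G.values, axis=1)
    poly = hi > lo
    dropped = int(G.M - poly.sum())
    if dropped:
        logger.info("sample_pca: dropped %d monomorphic markers", dropped)
    Gp = GenotypeMatrix(
        G.values[poly],
        tuple(np.asarray(G.marker_ids)[poly]),
        G.individual_ids,
        G.labels,
    )
    C = sample_cov(Gp, marker_adjust=True).C
    eigvals, eigvecs = np.linalg.eigh(C)
    order = np.argsort(-eigvals, kind="stable")[:m]
    vecs = eigvecs[:, order]
    for j in range(vecs.shape[1]):
        dom = int(np.argmax(np.abs(vecs[:, j])))
        if vecs[dom, j] < 0:
            vecs[:, j] = -vecs[:, j]
    return PCAResult(
        eigenvalues=eigvals[order], eigenvectors=vecs, dropped_monomorphic=dropped
    )
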