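"""Balding-Nichols genotype simulation and the named study designs.

Allele frequencies for each population are drawn around an ancestral
frequency p ~ Uniform(0.1, 0.9) from Beta(p(1-F)/F, (1-p)(1-F)/F), so that
E[f | p] = p and Var(f | p) = F p(1-p): F is the differentiation of the
population from the ancestral pool.  Genotypes are Binomial(2, f) given the
frequencies (Hardy-Weinberg), with no linkage disequilibrium.

Also provided: the case-control study used to benchmark stratification
corrections (three populations, expected case counts 30/60/150 against
80/80/80 controls, four SNP categories), and the subtle-structure scenario
in which one population is a small uniform perturbation of another.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .estimate import GenotypeMatrix
from .model import AlleleFreqModel, ModelError, PopulationLayout

__all__ = [
    "ScenarioConfig",
    "StudyDesign",
    "SimulatedStudy",
    "P_LOW",
    "P_HIGH",
    "draw_freqs_bn",
    "simulate_scenario",
    "genotypes_from_freqs",
    "case_genotypes",
    "study_table5",
    "subtle_structure_scenario",
    "bn_freq_model",
    "subtle_structure_freq_model",
]

logger = logging.getLogger(__name__)

# Ancestral allele-frequency law: uniform on [P_LOW, P_HIGH].
P_LOW = 0.1
P_HIGH = 0.9

STUDY_CATEGORIES = (
    "null_struinfo",
    "causal_struinfo",
    "null_specific_a",
    "causal_specific_a",
    "null_specific_b",
    "causal_specific_b",
)


@dataclass(frozen=True)
class ScenarioConfig:
    """A Balding-Nichols scenario: K populations, their F values, M markers."""

    layout: PopulationLayout
    fst: tuple[float, ...]
    M: int
    seed: int = 0
    p_low: float = P_LOW
    p_high: float = P_HIGH

    def __post_init__(self) -> None:
        if len(self.fst) != self.layout.K:
            raise ModelError("one F value per population is required")
        if any(f < 0 or f >= 1 for f in self.fst):
            raise ModelError("F values must lie in [0, 1)")
        if self.M < 1:
            raise ModelError("need at least one marker")


@dataclass(frozen=True)
class StudyDesign:
    """Case-control composition and SNP panel sizes of the benchmark study.

    Case counts are the expected values under a rare disease with prevalence
    ratio 1:2:5 across three equally sampled populations.  ``specific_freqs``
    are the two fixed per-population frequency sets of the Specific SNPs:
    one proportional to the case-count ratio, one inversely proportional.
    """

    cases: tuple[int, ...] = (30, 60, 150)
    controls: tuple[int, ...] = (80, 80, 80)
    relative_risk: float = 1.5
    snps_per_category: int = 10_000
    specific_freqs: tuple[tuple[float, ...], ...] = (
        (0.75, 0.30, 0.15),
        (0.15, 0.30, 0.75),
    )
    prevalence_ratio: tuple[int, ...] = (1, 2, 5)
    labels: tuple[str, ...] = ("P1", "P2", "P3")

    def __post_init__(self) -> None:
        if not (len(self.cases) == len(self.controls) == len(self.labels) == 3):
            raise ModelError("the benchmark design uses exactly three populations")
        if any(x < 0 for x in self.cases + self.controls):
            raise ModelError("case/control counts must be nonnegative")
        if self.relative_risk <= 0:
            raise ModelError("relative risk must be positive")

    @property
    def layout(self) -> PopulationLayout:
        sizes = tuple(a + b for a, b in zip(self.cases, self.controls))
        return PopulationLayout(self.labels, sizes)

    def phenotype(self) -> np.ndarray:
        """Per-individual case (1) / control (0) status, cases first per pop."""
        parts = []
        for nca, nco in zip(self.cases, self.controls):
            parts.append(np.r_[np.ones(nca), np.zeros(nco)])
        return np.concatenate(parts)


@dataclass(frozen=True)
class SimulatedStudy:
    """Genotype blocks of the four SNP categories plus shared metadata.

    ``blocks`` maps category name -> (M, n) allele-count array.  The counted
    allele of every causal SNP is the risk allele, so a positive
    genotype-phenotype correlation is the correct direction.  The
    ``null_struinfo`` block doubles as the panel from which sample PCs are
    inferred.
    """

    design: StudyDesign
    fst: float
    seed: int
    y: np.ndarray
    labels: tuple[str, ...]
    layout: PopulationLayout
    blocks: dict[str, np.ndarray]
    pc_panel: str = "null_struinfo"


def draw_freqs_bn(
    rng: np.random.Generator,
    M: int,
    fst,
    p_low: float = P_LOW,
    p_high: float = P_HIGH,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw per-marker frequency vectors under the Balding-Nichols model.

    Returns (f, p): f has shape (M, K) with population frequencies drawn
    independently given the ancestral p; F = 0 degenerates to f = p exactly.
    """
    fst = np.atleast_1d(np.asarray(fst, dtype=float))
    p = rng.uniform(p_low, p_high, size=M)
    f = np.empty((M, fst.shape[0]))
    for s, F in enumerate(fst):
        if F == 0.0:
            f[:, s] = p
        else:
            ratio = (1.0 - F) / F
            f[:, s] = rng.beta(p * ratio, (1.0 - p) * ratio)
    return f, p


def simulate_scenario(cfg: ScenarioConfig) -> GenotypeMatrix:
    """Draw the full genotype matrix for a configured scenario (seeded)."""
    rng = np.random.default_rng(cfg.seed)
    f, _ = draw_freqs_bn(rng, cfg.M, cfg.fst, cfg.p_low, cfg.p_high)
    return genotypes_from_freqs(rng, f, cfg.layout)


def genotypes_from_freqs(
    rng: np.random.Generator, f: np.ndarray, layout: PopulationLayout
) -> GenotypeMatrix:
    """Hardy-Weinberg genotypes: each count ~ Binomial(2, f_s) given f."""
    f = np.asarray(f, dtype=float)
    if f.ndim != 2 or f.shape[1] != layout.K:
        raise ModelError("frequency array must be (M, K)")
    if np.any(f < 0) or np.any(f > 1):
        raise ModelError("allele frequencies must lie in [0, 1]")
    per_marker = f[:, np.repeat(np.arange(layout.K), layout.sizes)]
    values = rng.binomial(2, per_marker).astype(float)
    return GenotypeMatrix.from_values(values, layout.individual_labels())


def case_genotypes(
    rng: np.random.Generator, f: np.ndarray, r: float, n_cases: int
) -> np.ndarray:
    """Genotypes of affected individuals under a multiplicative risk model.

    P(g | case) is the Hardy-Weinberg probability tilted by r^g, which
    normalises to Binomial(2, f') with f' = r f / (1 - f + r f).
    """
    if r <= 0:
        raise ModelError("relative risk must be positive")
    f = np.asarray(f, dtype=float)
    f_case = r * f / (1.0 - f + r * f)
    shape = f.shape + (n_cases,)
    return rng.binomial(2, np.broadcast_to(f_case[..., None], shape)).astype(float)


def _simulate_block(
    rng: np.random.Generator,
    f: np.ndarray,
    design: StudyDesign,
    causal: bool,
) -> np.ndarray:
    """One (M, n) category block; columns follow the design's layout order."""
    M = f.shape[0]
    r = design.relative_risk if causal else 1.0
    cols = []
    for s, (nca, nco) in enumerate(zip(design.cases, design.controls)):
        fs = f[:, s]
        if causal and r != 1.0:
            case_block = case_genotypes(rng, fs, r, nca)
        else:
            case_block = rng.binomial(2, np.broadcast_to(fs[:, None], (M, nca)))
        ctrl_block = rng.binomial(2, np.broadcast_to(fs[:, None], (M, nco)))
        cols.append(case_block.astype(float))
        cols.append(ctrl_block.astype(float))
    return np.concatenate(cols, axis=1)


def study_table5(
    design: StudyDesign, fst: float, seed: int
) -> SimulatedStudy:
    """Simulate the four-category benchmark study at one differentiation level.

    * StruInfo SNPs: Balding-Nichols frequencies with the same F in all three
      populations (structure-informative).
    * Specific SNPs: the two fixed frequency sets of the design.
    * Null blocks are disease-independent; causal blocks tilt case genotypes
      by the design's relative risk.
    """
    rng = np.random.default_rng(seed)
    layout = design.layout
    M = design.snps_per_category
    blocks: dict[str, np.ndarray] = {}
    f_null, _ = draw_freqs_bn(rng, M, [fst] * 3)
    blocks["null_struinfo"] = _simulate_block(rng, f_null, design, causal=False)
    f_causal, _ = draw_freqs_bn(rng, M, [fst] * 3)
    blocks["causal_struinfo"] = _simulate_block(rng, f_causal, design, causal=True)
    for tag, freqs in zip(("a", "b"), design.specific_freqs):
        f_fix = np.tile(np.asarray(freqs, dtype=float), (M, 1))
        blocks[f"null_specific_{tag}"] = _simulate_block(
            rng, f_fix, design, causal=False
        )
        blocks[f"causal_specific_{tag}"] = _simulate_block(
            rng, f_fix, design, causal=True
        )
    return SimulatedStudy(
        design=design,
        fst=fst,
        seed=seed,
        y=design.phenotype(),
        labels=tuple(layout.individual_labels()),
        layout=layout,
        blocks=blocks,
    )


def subtle_structure_scenario(
    M: int,
    n_per_pop: int,
    fst: float = 0.003,
    delta: float = 0.01,
    seed: int = 0,
) -> tuple[GenotypeMatrix, np.ndarray]:
    """Four populations, one pair nearly identical.

    P1, P2 and P4 are independent Balding-Nichols draws at the same F; P3's
    frequency vector is P2's plus an independent Uniform(-delta, delta)
    perturbation per marker (clipped to [0, 1], clip count logged).  P2+P3
    behaves as one population with a subtle substructure that only shows up
    beyond the first two axes.

    Returns the labelled genotype matrix and the (M, 4) frequency matrix.
    """
    rng = np.random.default_rng(seed)
    f3, _ = draw_freqs_bn(rng, M, [fst] * 3)  # P1, P2, P4
    bump = rng.uniform(-delta, delta, size=M)
    f_p3 = f3[:, 1] + bump
    clipped = int(np.sum((f_p3 < 0) | (f_p3 > 1)))
    if clipped:
        logger.info("subtle_structure_scenario: clipped %d perturbed frequencies",
                    clipped)
    f = np.column_stack([f3[:, 0], f3[:, 1], np.clip(f_p3, 0.0, 1.0), f3[:, 2]])
    layout = PopulationLayout(("P1", "P2", "P3", "P4"), (n_per_pop,) * 4)
    return genotypes_from_freqs(rng, f, layout), f


def _uniform_moments(p_low: float, p_high: float) -> tuple[float, float, float]:
    ep = 0.5 * (p_low + p_high)
    vp = (p_high - p_low) ** 2 / 12.0
    epq = ep * (1.0 - ep) - vp  # E[p(1-p)]
    return ep, vp, epq


def bn_freq_model(
    fst, p_low: float = P_LOW, p_high: float = P_HIGH
) -> AlleleFreqModel:
    """Exact frequency moments of the Balding-Nichols draw.

    mu_s = E[p]; Var(f_s) = F_s E[p(1-p)] + Var(p) by total variance; pairs
    of populations share only the ancestral draw, so Cov(f_s, f_t) = Var(p).
    """
    fst = np.atleast_1d(np.asarray(fst, dtype=float))
    ep, vp, epq = _uniform_moments(p_low, p_high)
    K = fst.shape[0]
    mu = np.full(K, ep)
    psi = np.full((K, K), vp)
    psi[np.diag_indices(K)] = fst * epq + vp
    return AlleleFreqModel(mu=mu, psi=psi)


def subtle_structure_freq_model(
    fst: float = 0.003,
    delta: float = 0.01,
    p_low: float = P_LOW,
    p_high: float = P_HIGH,
) -> AlleleFreqModel:
    """Frequency moments of the subtle-structure scenario (clipping ignored).

    Populations ordered P1, P2, P3, P4.  P3 = P2 + Uniform(-delta, delta), so
    Var(f_3) = Var(f_2) + delta^2/3 and Cov(f_2, f_3) = Var(f_2); covariances
    with P1 and P4 reduce to the shared ancestral variance.
    """
    ep, vp, epq = _uniform_moments(p_low, p_high)
    v_bn = fst * epq + vp
    psi = np.full((4, 4), vp)
    for s in range(4):
        psi[s, s] = v_bn
    psi[2, 2] = v_bn + delta**2 / 3.0
    psi[1, 2] = psi[2, 1] = v_bn
    return AlleleFreqModel(mu=np.full(4, ep), psi=psi)
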