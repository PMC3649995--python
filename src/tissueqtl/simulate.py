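"""Synthetic multi-tissue eQTL data.

The generator reproduces the standard simulation designs for this class of
methods: genotypes are Binomial(2, MAF) draws under Hardy-Weinberg (MAF
0.3 by default), eQTL effects are set on the standardized scale either to
hit a target proportion of variance explained (PVE, 20% by default) or by
drawing from the two-level normal prior at given grid scales, and
expression is the linear model signal plus Gaussian noise with per-tissue
error variances and, optionally, intra-individual residual correlation for
designs where tissues share individuals.

Three ready-made scenarios cover the canonical experiments: a power study
(5 or 20 tissues, 2,000 gene-SNP pairs, half null, eQTLs active in q
tissues), a sharing-recovery study (8 active configurations with unequal
sample sizes), and a three-tissue study with predominantly consistent
eQTLs at moderate power, shaped like the fibroblast/LCL/T-cell data this
methodology was developed on.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .configs import Configuration
from .priors import GridPoint

__all__ = [
    "SimScenario",
    "SimStudy",
    "sim_genotypes",
    "sim_effects",
    "sim_expression",
    "sim_study",
    "standardized_effect_for_pve",
    "power_scenario",
    "sharing_recovery_scenario",
    "consistent_sharing_scenario",
]


def standardized_effect_for_pve(pve: float, maf: float) -> float:
    """Standardized effect |b| = |beta|/sigma with expected PVE ``pve``.

    Solves PVE = b^2 v / (b^2 v + 1) with genotype variance
    v = 2 maf (1 - maf) under Hardy-Weinberg.
    """
    if not (0.0 <= pve < 1.0):
        raise ValueError("pve must lie in [0, 1)")
    v = 2.0 * maf * (1.0 - maf)
    return float(np.sqrt(pve / ((1.0 - pve) * v)))


@dataclass
class SimScenario:
    """Specification of one synthetic study.

    ``config_counts`` maps binary activity tuples (including the all-zero
    null) to gene counts.  Effects are standardized: if ``pve`` is set,
    each active tissue gets a shared mean of magnitude
    ``standardized_effect_for_pve(pve, maf)`` plus heterogeneity jitter of
    relative fraction ``heterogeneity``; if ``pve`` is None, effects are
    drawn from the two-level normal prior at a grid point sampled from
    ``effect_grid``.
    """

    n_s: list[int]
    config_counts: dict[tuple[int, ...], int]
    maf: float = 0.3
    pve: float | None = 0.2
    heterogeneity: float = 0.25
    error_variances: list[float] | None = None
    shared_individuals: bool = False
    intra_corr: float = 0.0
    effect_grid: list[GridPoint] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        self.n_s = [int(n) for n in self.n_s]
        if self.error_variances is None:
            self.error_variances = [1.0] * self.S
        if len(self.error_variances) != self.S:
            raise ValueError("one error variance per tissue required")
        if not (0.0 < self.maf <= 0.5):
            raise ValueError("maf must be in (0, 0.5]")
        if self.pve is not None and not (0.0 <= self.pve < 1.0):
            raise ValueError("pve must be in [0, 1)")
        if self.pve is None and not self.effect_grid:
            raise ValueError("either pve or effect_grid must be given")
        for gamma, count in self.config_counts.items():
            if len(gamma) != self.S:
                raise ValueError(f"configuration {gamma} has wrong length")
            if count < 0:
                raise ValueError("configuration counts must be >= 0")
        if self.shared_individuals and len(set(self.n_s)) != 1:
            raise ValueError("shared individuals require equal per-tissue sample sizes")
        if not (-1.0 < self.intra_corr < 1.0):
            raise ValueError("intra_corr must lie in (-1, 1)")
        if self.intra_corr != 0.0 and not self.shared_individuals:
            raise ValueError("intra-individual correlation requires shared individuals")

    @property
    def S(self) -> int:
        return len(self.n_s)

    @property
    def n_genes(self) -> int:
        return sum(self.config_counts.values())

    def residual_correlation_matrix(self) -> np.ndarray:
        R = np.full((self.S, self.S), self.intra_corr)
        np.fill_diagonal(R, 1.0)
        if np.linalg.eigvalsh(R).min() <= 0:
            raise ValueError("intra-individual correlation matrix not positive definite")
        return R


@dataclass
class SimStudy:
    """Generated dataset: one candidate SNP per gene.

    ``genotypes[s]`` and ``expression[s]`` are (genes, n_s) arrays for
    tissue index s; ``truth`` records each gene's configuration and
    standardized effects.
    """

    scenario: SimScenario
    gene_ids: list[str]
    configurations: list[Configuration]
    effects: np.ndarray  # (genes, S) standardized effects
    genotypes: list[np.ndarray] = field(repr=False)
    expression: list[np.ndarray] = field(repr=False)

    @property
    def is_null(self) -> np.ndarray:
        return np.array([c.q == 0 for c in self.configurations])


def sim_genotypes(n: int, maf: float, rng) -> np.ndarray:
    """I.i.d. Binomial(2, maf) dosages for n individuals."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(rng)
    return rng.binomial(2, maf, size=n).astype(float)


def sim_effects(
    gamma: Configuration,
    grid_point: GridPoint | None,
    pve: float | None,
    maf: float,
    rng,
    heterogeneity: float = 0.25,
) -> np.ndarray:
    """Standardized effects per tissue for one gene.

    Active tissues receive a shared mean bbar ~ N(0, omega^2) plus
    N(0, phi^2) deviations; inactive tissues are exactly zero.  With
    ``pve`` given, the total scale sqrt(phi^2 + omega^2) is set to
    ``standardized_effect_for_pve(pve, maf)`` — so the *expected* squared
    standardized effect solves the PVE identity for the target — and the
    ``heterogeneity`` fraction splits it between phi and omega.  With
    ``pve`` None, both scales come directly from the grid point.
    """
    rng = np.random.default_rng(rng)
    b = np.zeros(gamma.S)
    active = list(gamma.active)
    if not active:
        return b
    if pve is not None:
        if pve >= 1.0:
            raise ValueError("pve must be < 1")
        if not (0.0 <= heterogeneity < 1.0):
            raise ValueError("heterogeneity fraction must be in [0, 1)")
        scale = standardized_effect_for_pve(pve, maf)
        bbar = rng.normal(0.0, scale * np.sqrt(1.0 - heterogeneity))
        phi = scale * np.sqrt(heterogeneity)
    else:
        if grid_point is None:
            raise ValueError("grid_point required when pve is None")
        bbar = rng.normal(0.0, grid_point.omega)
        phi = grid_point.phi
    for s in active:
        b[s] = bbar + (rng.normal(0.0, phi) if phi > 0 else 0.0)
    return b


def sim_expression(
    genotypes: list[np.ndarray],
    effects: np.ndarray,
    error_variances: list[float],
    intra_corr: float,
    rng,
) -> list[np.ndarray]:
    """Expression vectors y_s = beta_s g_s + eps_s for one gene.

    ``genotypes`` holds one dosage vector per tissue (identical objects
    for shared-individual designs); ``effects`` are standardized, so the
    raw slope in tissue s is beta_s = b_s * sigma_s.  With nonzero
    ``intra_corr`` the residual vectors across tissues are drawn from an
    S-variate normal per individual (requires equal sample sizes).
    """
    rng = np.random.default_rng(rng)
    S = len(genotypes)
    sig = np.sqrt(np.asarray(error_variances, dtype=float))
    if intra_corr != 0.0:
        n = genotypes[0].size
        R = np.full((S, S), intra_corr)
        np.fill_diagonal(R, 1.0)
        L = np.linalg.cholesky(R)
        eps = (rng.standard_normal((n, S)) @ L.T) * sig  # rows i.i.d. MVN
        return [
            effects[s] * sig[s] * genotypes[s] + eps[:, s] for s in range(S)
        ]
    return [
        effects[s] * sig[s] * genotypes[s] + sig[s] * rng.standard_normal(genotypes[s].size)
        for s in range(S)
    ]


def sim_study(scenario: SimScenario) -> SimStudy:
    """Generate a full one-SNP-per-gene study from a scenario.

    Deterministic given the scenario (including its seed): the same
    scenario object always yields byte-identical arrays.
    """
    rng = np.random.default_rng(scenario.seed)
    S = scenario.S
    gene_ids: list[str] = []
    configs: list[Configuration] = []
    effects_rows: list[np.ndarray] = []
    geno = [np.empty((scenario.n_genes, n)) for n in scenario.n_s]
    expr = [np.empty((scenario.n_genes, n)) for n in scenario.n_s]

    gi = 0
    for gamma_t in sorted(scenario.config_counts):
        gamma = Configuration(tuple(gamma_t))
        for _ in range(scenario.config_counts[gamma_t]):
            gene_ids.append(f"gene{gi:05d}")
            configs.append(gamma)
            if scenario.shared_individuals:
                g = sim_genotypes(scenario.n_s[0], scenario.maf, rng)
                gvecs = [g] * S
            else:
                gvecs = [sim_genotypes(n, scenario.maf, rng) for n in scenario.n_s]
            if scenario.pve is not None:
                b = sim_effects(
                    gamma, None, scenario.pve, scenario.maf, rng,
                    heterogeneity=scenario.heterogeneity,
                )
            else:
                gp = scenario.effect_grid[rng.integers(len(scenario.effect_grid))]
                b = sim_effects(gamma, gp, None, scenario.maf, rng)
            ys = sim_expression(
                gvecs, b, scenario.error_variances, scenario.intra_corr, rng
            )
            for s in range(S):
                geno[s][gi] = gvecs[s]
                expr[s][gi] = ys[s]
            effects_rows.append(b)
            gi += 1

    return SimStudy(
        scenario=scenario,
        gene_ids=gene_ids,
        configurations=configs,
        effects=np.vstack(effects_rows),
        genotypes=geno,
        expression=expr,
    )


def grid_scaled_to_pve(pve: float, maf: float, kind: str = "default"):
    """Effect-size grid rescaled so the *expected* PVE over the grid
    equals ``pve``.

    Mimics drawing eQTL effects "according to the grid": a grid point is
    sampled uniformly, the shared mean and per-tissue deviations are
    drawn from the two-level normal at that point, and a single global
    scale factor c solves mean_E[(cE)^2 v / ((cE)^2 v + 1)] = pve over
    the grid's effect sizes E (v = genotype variance).  This yields a
    realistic mixture of undetectable, borderline and strong eQTLs.
    """
    from scipy.optimize import brentq

    from .priors import DEFAULT_SIZES, build_grid

    v = 2.0 * maf * (1.0 - maf)
    sizes = np.asarray(DEFAULT_SIZES)

    def mean_pve(c):
        x = (c * sizes) ** 2 * v
        return np.mean(x / (x + 1.0)) - pve

    c = brentq(mean_pve, 1e-3, 1e3)
    base = build_grid(kind)
    return [GridPoint(phi=c * p.phi, omega=c * p.omega) for p in base.points]


def power_scenario(
    q_active: int,
    S: int = 5,
    n: int = 100,
    n_pairs: int = 2000,
    equal_variances: bool = True,
    seed: int = 0,
) -> SimScenario:
    """Power-study design: half the gene-SNP pairs null, half with an eQTL
    active in exactly ``q_active`` tissues (the first q).

    Effects are drawn across the default grid rescaled so the expected
    PVE is 20%.  With ``equal_variances=False`` the per-tissue error
    variances cycle through {1, 1.5, 2}.
    """
    if not (1 <= q_active <= S):
        raise ValueError("q_active must be in 1..S")
    gamma = tuple(1 if i < q_active else 0 for i in range(S))
    ev = [1.0] * S if equal_variances else [(1.0, 1.5, 2.0)[i % 3] for i in range(S)]
    return SimScenario(
        n_s=[n] * S,
        config_counts={(0,) * S: n_pairs // 2, gamma: n_pairs - n_pairs // 2},
        error_variances=ev,
        pve=None,
        effect_grid=grid_scaled_to_pve(0.2, 0.3),
        seed=seed,
    )


def sharing_recovery_scenario(
    genes_per_config: int = 200, n_null: int = 200, seed: int = 0
) -> SimScenario:
    """Sharing-recovery design: five tissues, eight active configurations
    (all shared, the five singletons, tissues 1-2, tissues 3-5) in equal
    numbers plus nulls; tissue 1 has 60 samples, the others 100."""
    S = 5
    active = [
        (1, 1, 1, 1, 1),
        (1, 0, 0, 0, 0),
        (0, 1, 0, 0, 0),
        (0, 0, 1, 0, 0),
        (0, 0, 0, 1, 0),
        (0, 0, 0, 0, 1),
        (1, 1, 0, 0, 0),
        (0, 0, 1, 1, 1),
    ]
    counts = {g: genes_per_config for g in active}
    counts[(0,) * S] = n_null
    return SimScenario(n_s=[60, 100, 100, 100, 100], config_counts=counts, seed=seed)


def consistent_sharing_scenario(
    n_genes: int = 2000,
    pi0: float = 0.5,
    n: int = 75,
    eta: dict[tuple[int, ...], float] | None = None,
    intra_corr: float = 0.0,
    seed: int = 0,
) -> SimScenario:
    """Three tissues sampled from the same individuals, with 88% of eQTLs
    consistent across all tissues and effect sizes drawn from the default
    grid (so per-tissue power is moderate and incomplete)."""
    from .priors import build_grid

    if eta is None:
        # sharing pattern estimated on the fibroblast/LCL/T-cell data:
        # overwhelmingly consistent, small singleton fractions
        eta = {
            (1, 1, 1): 0.88,
            (0, 1, 1): 0.052,
            (1, 1, 0): 0.005,
            (1, 0, 1): 0.002,
            (1, 0, 0): 0.033,
            (0, 1, 0): 0.016,
            (0, 0, 1): 0.012,
        }
    tot = sum(eta.values())
    n_alt = n_genes - int(round(pi0 * n_genes))
    counts: dict[tuple[int, ...], int] = {(0, 0, 0): n_genes - n_alt}
    # largest-remainder apportionment keeps every class count >= 0 and
    # the total exactly n_alt
    items = sorted(eta.items(), key=lambda kv: -kv[1])
    quotas = [(g, w / tot * n_alt) for g, w in items]
    floors = {g: int(q) for g, q in quotas}
    leftover = n_alt - sum(floors.values())
    for g, q in sorted(quotas, key=lambda gq: -(gq[1] - int(gq[1])))[:leftover]:
        floors[g] += 1
    counts.update(floors)
    grid = build_grid("default")
    return SimScenario(
        n_s=[n, n, n],
        config_counts=counts,
        pve=None,
        effect_grid=list(grid.points),
        shared_individuals=True,
        intra_corr=intra_corr,
        seed=seed,
    )
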