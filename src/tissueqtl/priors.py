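"""Effect-size priors: the (phi, omega) grid.

Standardized eQTL effects in the tissues where the eQTL is active follow a
two-level normal prior: a shared mean bbar ~ N(0, omega^2) with per-tissue
deviations b_s ~ N(bbar, phi^2).  omega sets the typical (shared) effect
size; phi the between-tissue heterogeneity.  A fixed grid of (phi, omega)
pairs with mixture weights lambda_l covers a range of sizes and
heterogeneity levels; phi = 0 is the fixed-effects limit where all active
tissues share one effect.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["GridPoint", "Grid", "build_grid", "DEFAULT_SIZES",
           "DEFAULT_HETEROGENEITY", "LITE_HETEROGENEITY"]

#: Average standardized effect sizes sqrt(phi^2 + omega^2) spanned by the grid.
DEFAULT_SIZES = (0.1, 0.2, 0.4, 0.8, 1.6)
#: Heterogeneity fractions phi^2 / (phi^2 + omega^2): limited range for the
#: full-configuration analyses ...
DEFAULT_HETEROGENEITY = (0.0, 0.25, 0.5)
#: ... and a much wider range for the "lite" statistic, whose few
#: configurations must absorb subset-activity through heterogeneity.
LITE_HETEROGENEITY = (0.0, 0.25, 0.5, 0.75, 1.0)


@dataclass(frozen=True)
class GridPoint:
    """One prior scale pair on the standardized-effect scale."""

    phi: float
    omega: float

    def __post_init__(self) -> None:
        if self.phi < 0 or self.omega < 0:
            raise ValueError("phi and omega must be non-negative")

    @property
    def total_variance(self) -> float:
        return self.phi**2 + self.omega**2

    @property
    def heterogeneity(self) -> float:
        tv = self.total_variance
        return self.phi**2 / tv if tv > 0 else 0.0


@dataclass
class Grid:
    """Ordered grid points with mixture weights lambda summing to 1."""

    points: list[GridPoint]
    weights: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if len(self.points) < 1:
            raise ValueError("grid needs at least one point")
        if self.weights is None:
            self.weights = np.full(len(self.points), 1.0 / len(self.points))
        w = np.asarray(self.weights, dtype=float)
        if w.shape != (len(self.points),):
            raise ValueError("one weight per grid point required")
        if np.any(w < 0) or not np.isclose(w.sum(), 1.0):
            raise ValueError("grid weights must be non-negative and sum to 1")
        self.weights = w

    def __len__(self) -> int:
        return len(self.points)

    @property
    def phis(self) -> np.ndarray:
        return np.array([p.phi for p in self.points])

    @property
    def omegas(self) -> np.ndarray:
        return np.array([p.omega for p in self.points])

    def with_weights(self, weights) -> "Grid":
        return Grid(points=list(self.points), weights=np.asarray(weights, dtype=float))


def build_grid(
    kind: str = "default",
    sizes=None,
    heterogeneity=None,
) -> Grid:
    """Cartesian (size, heterogeneity) grid with equal weights.

    Each (size E, heterogeneity h) pair maps to phi = E*sqrt(h),
    omega = E*sqrt(1-h), so that phi^2 + omega^2 = E^2 and
    phi^2/(phi^2+omega^2) = h.  ``kind="default"`` allows only modest
    heterogeneity; ``kind="lite"`` allows the full range up to
    tissue-independent effects (h = 1).
    """
    if kind not in ("default", "lite"):
        raise ValueError(f"unknown grid kind {kind!r}")
    if sizes is None:
        sizes = DEFAULT_SIZES
    if heterogeneity is None:
        heterogeneity = DEFAULT_HETEROGENEITY if kind == "default" else LITE_HETEROGENEITY
    sizes = np.asarray(sizes, dtype=float)
    heterogeneity = np.asarray(heterogeneity, dtype=float)
    if np.any(sizes < 0) or np.any(heterogeneity < 0) or np.any(heterogeneity > 1):
        raise ValueError("sizes must be >= 0 and heterogeneity fractions in [0, 1]")
    points = [
        GridPoint(phi=float(E * np.sqrt(h)), omega=float(E * np.sqrt(1.0 - h)))
        for E in sizes
        for h in heterogeneity
    ]
    return Grid(points=points)
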