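"""Activity configurations and their prior weights.

A configuration gamma is a binary vector over the S tissues saying in
which tissues a SNP is an active eQTL.  The all-zero vector is the global
null and is never enumerated among the alternatives.  Two fixed weighting
schemes are provided: "default", which spreads mass uniformly over the
number of active tissues q and then uniformly within each q (eta =
1/(S*C(S,q))), and "lite", which puts mass 0.5 on the consistent
(all-active) configuration and 0.5 split over the S singletons — the only
scheme that stays practical for large S.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np

__all__ = [
    "Configuration",
    "ConfigWeights",
    "enumerate_configs",
    "default_weights",
    "lite_weights",
    "MAX_TISSUES_FULL_ENUM",
]

#: Hard cap on full configuration enumeration (2^S - 1 terms).
MAX_TISSUES_FULL_ENUM = 20


@dataclass(frozen=True)
class Configuration:
    """Binary tissue-activity vector."""

    gamma: tuple[int, ...]

    def __post_init__(self) -> None:
        if not all(g in (0, 1) for g in self.gamma):
            raise ValueError("gamma entries must be 0 or 1")

    @property
    def q(self) -> int:
        return sum(self.gamma)

    @property
    def active(self) -> tuple[int, ...]:
        return tuple(i for i, g in enumerate(self.gamma) if g)

    @property
    def S(self) -> int:
        return len(self.gamma)

    def label(self, tissue_names=None) -> str:
        if tissue_names is None:
            return "".join(str(g) for g in self.gamma)
        return "-".join(t for t, g in zip(tissue_names, self.gamma) if g)


def enumerate_configs(S: int) -> list[Configuration]:
    """All 2^S - 1 nonzero configurations, ordered by q then lexicographically."""
    if S < 1:
        raise ValueError("need at least one tissue")
    if S > MAX_TISSUES_FULL_ENUM:
        raise ValueError(
            f"full enumeration of 2^{S}-1 configurations is impractical for "
            f"S > {MAX_TISSUES_FULL_ENUM}; use the lite statistic instead"
        )
    configs = []
    for q in range(1, S + 1):
        for active in combinations(range(S), q):
            gamma = [0] * S
            for i in active:
                gamma[i] = 1
            configs.append(Configuration(tuple(gamma)))
    return configs


@dataclass
class ConfigWeights:
    """Prior weights eta over nonzero configurations (sum to 1)."""

    configs: list[Configuration]
    eta: np.ndarray

    def __post_init__(self) -> None:
        w = np.asarray(self.eta, dtype=float)
        if w.shape != (len(self.configs),):
            raise ValueError("one weight per configuration required")
        if np.any(w < 0) or not np.isclose(w.sum(), 1.0):
            raise ValueError("eta must be non-negative and sum to 1")
        self.eta = w

    def __len__(self) -> int:
        return len(self.configs)

    def weight(self, config: Configuration) -> float:
        return float(self.eta[self.configs.index(config)])

    def with_eta(self, eta) -> "ConfigWeights":
        return ConfigWeights(configs=list(self.configs), eta=np.asarray(eta, dtype=float))


def default_weights(S: int) -> ConfigWeights:
    """eta_gamma = 1 / (S * C(S, q(gamma))): uniform over q, then within q."""
    configs = enumerate_configs(S)
    eta = np.array([1.0 / (S * comb(S, c.q)) for c in configs])
    return ConfigWeights(configs=configs, eta=eta)


def lite_weights(S: int) -> ConfigWeights:
    """Mass 0.5 on the consistent configuration, 0.5/S on each singleton.

    Only S + 1 configurations carry mass, so the scheme scales to tissue
    counts where full enumeration is hopeless.  For S = 1 the two classes
    coincide and all mass sits on the single configuration.
    """
    if S < 1:
        raise ValueError("need at least one tissue")
    if S == 1:
        cfg = Configuration((1,))
        return ConfigWeights(configs=[cfg], eta=np.array([1.0]))
    configs = []
    eta = []
    for i in range(S):
        gamma = [0] * S
        gamma[i] = 1
        configs.append(Configuration(tuple(gamma)))
        eta.append(0.5 / S)
    configs.append(Configuration((1,) * S))
    eta.append(0.5)
    return ConfigWeights(configs=configs, eta=np.array(eta))
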