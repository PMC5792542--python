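"""Quantitative genetics of socially plastic phenotypes on a network.

Each individual carries a direct breeding value ``a`` and a nonsocial
environmental deviation ``e``.  Its phenotype is

    z_i = a_i + e_i + psi_g * eta_i,

where ``eta_i`` is the social environment value: the weighted mean,
over the other ``n - 1`` group members, of their nonplastic phenotypes
``a_j + e_j``, weighted by connection strength.  ``psi_g`` is the
interaction coefficient: positive values pull individuals toward their
partners' phenotypes, negative values push them away.  There is no
phenotypic feedback: the social environment is built from nonplastic
components only.

The total breeding value ``t_i`` adds to ``a_i`` the effect of i's genes
on its partners' phenotypes through the same connections; its variance
governs the response to selection.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "GeneticValues",
    "Group",
    "sample_breeding_values",
    "sample_env",
    "social_environment",
    "phenotypes",
    "total_breeding_values",
    "build_group",
]

BV_DISTRIBUTIONS = ("uniform_pm1", "normal_01")


@dataclass(frozen=True)
class GeneticValues:
    """Per-individual direct breeding values and environmental deviations."""

    a: np.ndarray
    e: np.ndarray

    @property
    def nonplastic(self) -> np.ndarray:
        """The nonplastic phenotype component ``a + e``."""
        return self.a + self.e


@dataclass(frozen=True)
class Group:
    """One realized population with its network and derived phenotypes.

    Fields
    ------
    points : (n, 2) spatial positions in the unit square
    genetics : direct breeding values ``a`` and environmental deviations ``e``
    w : symmetric zero-diagonal weight matrix of connection strengths
    eta : social environment value experienced by each individual
    z : realized phenotypes
    t : total breeding values
    psi_g : interaction coefficient used to build ``z`` and ``t``
    """

    points: np.ndarray
    genetics: GeneticValues
    w: np.ndarray
    eta: np.ndarray
    z: np.ndarray
    t: np.ndarray
    psi_g: float

    @property
    def n(self) -> int:
        return self.genetics.a.shape[0]


def sample_breeding_values(
    n: int, dist: str = "uniform_pm1", rng: np.random.Generator | None = None
) -> np.ndarray:
    """Draw ``n`` i.i.d. direct breeding values from a centred distribution.

    ``uniform_pm1`` is uniform on [-1, 1] (variance 1/3); ``normal_01``
    is standard normal (variance 1).
    """
    if n < 2:
        raise ValueError(f"group size must be at least 2, got {n}")
    if rng is None:
        rng = np.random.default_rng()
    if dist == "uniform_pm1":
        return rng.uniform(-1.0, 1.0, size=n)
    if dist == "normal_01":
        return rng.normal(0.0, 1.0, size=n)
    raise ValueError(
        f"unknown breeding-value distribution {dist!r}; expected one of {BV_DISTRIBUTIONS}"
    )


def sample_env(
    n: int, variance: float = 0.0625, rng: np.random.Generator | None = None
) -> np.ndarray:
    """Draw ``n`` i.i.d. normal environmental deviations with mean 0."""
    if variance < 0:
        raise ValueError(f"variance must be nonnegative, got {variance}")
    if rng is None:
        rng = np.random.default_rng()
    return rng.normal(0.0, np.sqrt(variance), size=n)


def social_environment(w: np.ndarray, a: np.ndarray, e: np.ndarray) -> np.ndarray:
    """Social environment value ``eta_i = sum_j w_ij (a_j + e_j) / (n - 1)``.

    The divisor is ``n - 1`` (the number of possible partners), not the
    sum of weights, so eta scales with realized connection strength and
    vanishes on the empty network.  The zero diagonal of ``w`` enforces
    self-exclusion: eta_i never depends on individual i's own values.
    """
    w = np.asarray(w, dtype=float)
    a = np.asarray(a, dtype=float)
    e = np.asarray(e, dtype=float)
    n = a.shape[0]
    if n < 2:
        raise ValueError("need at least 2 individuals")
    if w.shape != (n, n) or e.shape[0] != n:
        raise ValueError("inconsistent lengths between weights and values")
    return w @ (a + e) / (n - 1)


def phenotypes(a, e, eta, psi_g: float) -> np.ndarray:
    """Phenotype ``z = a + e + psi_g * eta``."""
    a = np.asarray(a, dtype=float)
    e = np.asarray(e, dtype=float)
    eta = np.asarray(eta, dtype=float)
    if not a.shape == e.shape == eta.shape:
        raise ValueError("inconsistent lengths")
    return a + e + psi_g * eta


def total_breeding_values(w: np.ndarray, a, psi_g: float) -> np.ndarray:
    """Total breeding value: direct value plus the effect of own genes on others.

    ``t_i = a_i * (1 + psi_g * sbar_i)`` where ``sbar_i`` is i's mean
    connection strength, ``sum_j w_ji / (n - 1)``.  With all weights
    equal to ``sbar`` this reduces to ``t_i = a_i (1 + psi_g sbar)``, so
    ``Var(t) = (1 + psi_g sbar)**2 Var(a)``.
    """
    w = np.asarray(w, dtype=float)
    a = np.asarray(a, dtype=float)
    n = a.shape[0]
    if w.shape != (n, n):
        raise ValueError("inconsistent lengths")
    mean_strength = w.sum(axis=0) / (n - 1)
    return a * (1.0 + psi_g * mean_strength)


def build_group(
    points: np.ndarray,
    a: np.ndarray,
    e: np.ndarray,
    w: np.ndarray,
    psi_g: float,
) -> Group:
    """Assemble a :class:`Group` by computing eta, z and t from its parts."""
    eta = social_environment(w, a, e)
    z = phenotypes(a, e, eta, psi_g)
    t = total_breeding_values(w, a, psi_g)
    return Group(
        points=np.asarray(points, dtype=float),
        genetics=GeneticValues(a=np.asarray(a, dtype=float), e=np.asarray(e, dtype=float)),
        w=np.asarray(w, dtype=float),
        eta=eta,
        z=z,
        t=t,
        psi_g=float(psi_g),
    )
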