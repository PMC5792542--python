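"""Spatially explicit generation of weighted social networks.

Individuals live in the unit square; the strength of the connection
between two individuals decays with the squared Euclidean distance
between them through a Gaussian kernel ``s = exp(-d**2 / r)``, where
``r`` is an interaction range.  Larger ``r`` produces denser networks.
Individuals may additionally up- or down-weight connections to partners
with similar trait values (homophily / heterophily), and very weak
connections are pruned below a cutoff.

All weight matrices are symmetric with a zero diagonal and entries in
``[0, 1]``.  Network density is the mean realized edge weight over all
dyads; assortativity is the Newman-style weighted continuous-trait
assortativity coefficient.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "NetworkMetrics",
    "sample_positions",
    "attract_to_nearest",
    "base_weights",
    "similarity_multiplier",
    "apply_similarity",
    "threshold_weights",
    "network_density",
    "weighted_assortativity",
    "measure_network",
]

MODES = ("none", "homophily", "heterophily")

#: logistic steepness of the similarity preference curve
_SIGMOID_SLOPE = 20.0
#: trait difference at which the preference multiplier crosses its midpoint
_SIGMOID_MIDPOINT = 0.5


@dataclass(frozen=True)
class NetworkMetrics:
    """Density and trait assortativity of one weighted network.

    ``assortativity`` is ``nan`` when undefined (empty network, or no
    trait variance over edge ends).
    """

    density: float
    assortativity: float


def sample_positions(n: int, rng: np.random.Generator) -> np.ndarray:
    """Draw ``n`` independent uniform positions in the unit square.

    Returns an ``(n, 2)`` array of coordinates.
    """
    if n < 2:
        raise ValueError(f"group size must be at least 2, got {n}")
    return rng.uniform(0.0, 1.0, size=(n, 2))


def _pairwise_distances(points: np.ndarray) -> np.ndarray:
    diff = points[:, None, :] - points[None, :, :]
    return np.sqrt((diff**2).sum(axis=-1))


def attract_to_nearest(points: np.ndarray, fraction: float = 0.15) -> np.ndarray:
    """Move every individual toward its nearest neighbour.

    A single synchronous step: nearest neighbours are identified on the
    input configuration and every individual is displaced along the
    segment to its nearest neighbour by ``fraction`` of that distance.
    Ties are broken by lowest index, so the step is deterministic.
    Moving toward an interior point cannot leave the unit square.
    """
    points = np.asarray(points, dtype=float)
    if points.ndim != 2 or points.shape[0] < 2:
        raise ValueError("need at least 2 positions")
    if not 0.0 <= fraction < 1.0:
        raise ValueError(f"fraction must be in [0, 1), got {fraction}")
    d = _pairwise_distances(points)
    np.fill_diagonal(d, np.inf)
    nearest = d.argmin(axis=1)
    return points + fraction * (points[nearest] - points)


def base_weights(points: np.ndarray, r: float) -> np.ndarray:
    """Gaussian-kernel connection strengths ``w_ij = exp(-d_ij**2 / r)``.

    The diagonal is zero.  ``r = 0`` yields the empty network, the
    kernel's limit as ``r -> 0+`` for any positive distance.
    """
    if r < 0:
        raise ValueError(f"interaction range must be nonnegative, got {r}")
    points = np.asarray(points, dtype=float)
    n = points.shape[0]
    if r == 0:
        return np.zeros((n, n))
    d = _pairwise_distances(points)
    w = np.exp(-(d**2) / r)
    np.fill_diagonal(w, 0.0)
    return w


def similarity_multiplier(trait_diff, H: float, mode: str):
    """Preference multiplier applied to a connection given a trait difference.

    For ``mode="none"`` the multiplier is identically 1 (the baseline
    network is untouched).  Otherwise

        m = 0.5 + sigma * H * L(d),   L(d) = 1 / (1 + exp(20 * (d - 0.5)))

    with ``sigma = +1`` for homophily and ``-1`` for heterophily, so the
    multiplier lies in ``[0.5 - H, 0.5 + H]``.  Identical individuals
    (``d = 0``) are multiplied by roughly ``0.5 + H`` under homophily and
    ``0.5 - H`` under heterophily; a trait difference at the midpoint 0.5
    gives exactly 0.5 +/- H/2.
    """
    if mode not in MODES:
        raise ValueError(f"unknown mode {mode!r}; expected one of {MODES}")
    trait_diff = np.asarray(trait_diff, dtype=float)
    if mode == "none":
        return np.ones_like(trait_diff)
    if not 0.0 <= H <= 0.5:
        raise ValueError(f"homophily magnitude must be in [0, 0.5], got {H}")
    sigma = 1.0 if mode == "homophily" else -1.0
    logistic = 1.0 / (1.0 + np.exp(_SIGMOID_SLOPE * (trait_diff - _SIGMOID_MIDPOINT)))
    return 0.5 + sigma * H * logistic


def apply_similarity(w: np.ndarray, traits, H: float, mode: str) -> np.ndarray:
    """Modulate every weight by the trait-similarity preference multiplier.

    Traits are the nonplastic component of the phenotype (``a + e``), so
    that the network does not depend on network-dependent phenotypes.
    Symmetry is preserved because the multiplier depends only on
    ``|trait_i - trait_j|``.  ``mode="none"`` returns the matrix unchanged.
    """
    w = np.asarray(w, dtype=float)
    traits = np.asarray(traits, dtype=float)
    if traits.shape[0] != w.shape[0]:
        raise ValueError(
            f"traits length {traits.shape[0]} does not match matrix size {w.shape[0]}"
        )
    if mode == "none":
        return w
    diff = np.abs(traits[:, None] - traits[None, :])
    out = w * similarity_multiplier(diff, H, mode)
    np.fill_diagonal(out, 0.0)
    return out


def threshold_weights(w: np.ndarray, cutoff: float = 0.05) -> np.ndarray:
    """Remove very weak connections: entries strictly below ``cutoff`` become 0.

    Entries equal to the cutoff are retained.
    """
    if not 0.0 <= cutoff <= 1.0:
        raise ValueError(f"cutoff must be in [0, 1], got {cutoff}")
    w = np.asarray(w, dtype=float)
    return np.where(w < cutoff, 0.0, w)


def network_density(w: np.ndarray) -> float:
    """Sum of realized edge weights over the maximum possible sum.

    Equals the mean weight over all ``n (n - 1) / 2`` dyads, i.e. the
    mean connection strength of the group.
    """
    w = np.asarray(w, dtype=float)
    n = w.shape[0]
    if n < 2:
        raise ValueError("density undefined for fewer than 2 nodes")
    iu = np.triu_indices(n, k=1)
    return float(w[iu].sum() / (n * (n - 1) / 2))


def weighted_assortativity(w: np.ndarray, traits) -> float:
    """Weighted continuous-trait assortativity coefficient.

    Each undirected edge is counted once in each direction.  With
    ``W = sum(w_ij)`` and weighted trait mean ``xbar = sum(w_ij x_i) / W``,

        rho = (sum(w_ij x_i x_j)/W - xbar**2) / (sum(w_ij x_i**2)/W - xbar**2)

    Returns ``nan`` when the network is empty or when the trait variance
    over edge ends is zero (the coefficient is then undefined).
    """
    w = np.asarray(w, dtype=float)
    x = np.asarray(traits, dtype=float)
    if x.shape[0] != w.shape[0]:
        raise ValueError("traits length does not match matrix size")
    total = w.sum()
    if total <= 0:
        return float("nan")
    strength = w.sum(axis=1)
    xbar = float(strength @ x) / total
    num = float(x @ w @ x) / total - xbar**2
    second_moment = float(strength @ (x**2)) / total
    den = second_moment - xbar**2
    # zero trait variance over edge ends, up to rounding
    if den <= 1e-13 * max(1.0, second_moment):
        return float("nan")
    return num / den


def measure_network(w: np.ndarray, traits) -> NetworkMetrics:
    """Convenience: density and assortativity of one matrix."""
    return NetworkMetrics(
        density=network_density(w),
        assortativity=weighted_assortativity(w, traits),
    )
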