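"""Per-group summary statistics of phenotypes, variances and selection response.

All sample statistics use the ``n - 1`` denominator.  Undefined
quantities (zero-variance correlations, assortment on an empty network)
propagate as ``nan``, never as zeros.
"""

from __future__ import annotations

from dataclasses import dataclass, fields

import numpy as np

from .quantgen import Group

__all__ = ["GroupSummary", "summarize_group", "among_group_dispersion"]


@dataclass(frozen=True)
class GroupSummary:
    """Summary statistics of one simulated group.

    Fields
    ------
    mean_z : group mean phenotype
    var_indirect : variance across individuals of the realized indirect
        contribution ``psi_g * eta``
    corr_direct_indirect : Pearson correlation between the nonplastic
        phenotype ``a + e`` and the social environment ``eta``
    var_z : sample phenotypic variance
    var_z_ratio : ``var_z / Var(a + e)`` — phenotypic variance relative
        to what the group would show with no interactions
    var_t : sample variance of total breeding values
    var_t_ratio : ``var_t / Var(a)`` — total genetic variance relative
        to the direct genetic variance
    response : predicted one-generation change in the group mean under a
        linear selection gradient beta, ``beta * Cov(t, z)``
    r_hat : empirical genetic-assortment coefficient,
        ``Cov(a_i, ahat'_i) / Var(a)`` with ``ahat'_i`` the
        weight-weighted mean breeding value of i's partners over the
        ``n - 1`` possible partners (individuals with no partners are
        excluded from the covariance)
    """

    mean_z: float
    var_indirect: float
    corr_direct_indirect: float
    var_z: float
    var_z_ratio: float
    var_t: float
    var_t_ratio: float
    response: float
    r_hat: float


def _corr(x: np.ndarray, y: np.ndarray) -> float:
    vx = np.var(x, ddof=1)
    vy = np.var(y, ddof=1)
    if vx <= 0 or vy <= 0:
        return float("nan")
    return float(np.cov(x, y, ddof=1)[0, 1] / np.sqrt(vx * vy))


def summarize_group(group: Group, psi_g: float, beta: float) -> GroupSummary:
    """Compute the full set of per-group statistics.

    ``response`` uses the covariance identity: under a linear fitness
    gradient beta on the phenotype, the expected change in the group
    mean is ``beta * Cov(t, z)``, the covariance between total breeding
    values and phenotypes.

    ``r_hat`` measures genetic assortment: individuals with no partners
    have no defined partner mean and are excluded from the covariance;
    if no individual has a partner, ``r_hat`` is ``nan``.
    """
    a = group.genetics.a
    e = group.genetics.e
    n = a.shape[0]
    if n < 3:
        raise ValueError("summaries need at least 3 individuals")
    direct = a + e

    indirect = psi_g * group.eta
    var_z = float(np.var(group.z, ddof=1))
    var_direct = float(np.var(direct, ddof=1))
    var_t = float(np.var(group.t, ddof=1))
    var_a = float(np.var(a, ddof=1))

    strength = group.w.sum(axis=1)
    connected = strength > 0
    if connected.sum() >= 2 and var_a > 0:
        # weighted mean breeding value of partners, normalized by the n-1
        # possible partners (the same normalization as the social
        # environment), so genetic assortment scales with realized
        # connection strength
        partner_mean = (group.w @ a)[connected] / (n - 1)
        r_hat = float(
            np.cov(a[connected], partner_mean, ddof=1)[0, 1] / var_a
        )
    else:
        r_hat = float("nan")

    return GroupSummary(
        mean_z=float(np.mean(group.z)),
        var_indirect=float(np.var(indirect, ddof=1)),
        corr_direct_indirect=_corr(direct, group.eta),
        var_z=var_z,
        var_z_ratio=var_z / var_direct if var_direct > 0 else float("nan"),
        var_t=var_t,
        var_t_ratio=var_t / var_a if var_a > 0 else float("nan"),
        response=float(beta * np.cov(group.t, group.z, ddof=1)[0, 1]),
        r_hat=r_hat,
    )


def among_group_dispersion(summaries) -> dict[str, float]:
    """Variance across groups of the mean phenotype, response and variance ratio.

    Quantifies how much replicate groups diverge from one another, e.g.
    the fan-out of group means at high network density.
    """
    summaries = list(summaries)
    if len(summaries) < 2:
        raise ValueError("need at least 2 groups")
    return {
        "var_mean_z": float(np.var([s.mean_z for s in summaries], ddof=1)),
        "var_response": float(np.var([s.response for s in summaries], ddof=1)),
        "var_var_z_ratio": float(np.var([s.var_z_ratio for s in summaries], ddof=1)),
    }


def summary_fields() -> list[str]:
    """Ordered field names of :class:`GroupSummary` (for tabular output)."""
    return [f.name for f in fields(GroupSummary)]
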