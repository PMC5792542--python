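"""Closed-form predictions of the no-feedback interacting-phenotype model.

The model treats a group whose members are connected with mean
connection strength ``s_bar`` (the network density) and respond to
their social environment with a shared interaction coefficient
``psi_g``.  Writing ``G`` for the additive-genetic variance, ``E`` for
the environmental variance, ``R`` for the genetic-assortment
coefficient and ``beta`` for the selection gradient:

    mean phenotype        zbar = (1 + psi_g s_bar) abar
    phenotypic variance   Var(z) = G + E + psi_g**2 Var_social
                                     + 2 psi_g Cov_direct_social
    response to selection dzbar ~= (1 + psi_g s_bar) G (1 + R psi_g) beta
    total-BV variance     Var(t) = (1 + psi_g s_bar)**2 G

The variance expression is an exact algebraic decomposition of the
phenotype equation when fed within-group sample moments (the social
variance and the direct-social covariance are supplied empirically);
the response expression is an approximation whose accuracy is checked
against simulations.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "AnalyticInputs",
    "predict_mean",
    "predict_variance",
    "predict_response",
    "predict_var_tbv",
]


def predict_mean(psi_g: float, s_bar: float, a_bar: float) -> float:
    """Predicted group mean phenotype ``(1 + psi_g s_bar) a_bar``.

    With centred breeding values the expectation is 0; nonzero group
    means arise from sampling of ``a_bar`` and are amplified by the
    factor ``1 + psi_g s_bar``.
    """
    return (1.0 + psi_g * s_bar) * a_bar


def predict_variance(
    G: float,
    E: float,
    psi_g: float,
    var_social: float,
    cov_direct_social: float,
) -> float:
    """Predicted within-group phenotypic variance.

    ``var_social`` is the variance across individuals of the social
    environment value and ``cov_direct_social`` the covariance between
    the nonplastic phenotype and the social environment; both are
    supplied empirically (they depend on the realized network).
    """
    if G < 0 or E < 0 or var_social < 0:
        raise ValueError("variances must be nonnegative")
    return G + E + psi_g**2 * var_social + 2.0 * psi_g * cov_direct_social


def predict_response(
    psi_g: float, s_bar: float, G: float, R: float, beta: float
) -> float:
    """Predicted one-generation response ``(1 + psi_g s_bar) G (1 + R psi_g) beta``.

    Genetic assortment ``R`` plays the role relatedness plays in dyadic
    models: positive assortment amplifies the response when ``psi_g > 0``.
    """
    return (1.0 + psi_g * s_bar) * G * (1.0 + R * psi_g) * beta


def predict_var_tbv(G: float, psi_g: float, s_bar: float) -> float:
    """Predicted variance of total breeding values ``(1 + psi_g s_bar)**2 G``."""
    return (1.0 + psi_g * s_bar) ** 2 * G


@dataclass(frozen=True)
class AnalyticInputs:
    """Scalar inputs of the closed-form model, bundled for convenience."""

    psi_g: float
    s_bar: float
    a_bar: float = 0.0
    G: float = 1.0 / 3.0
    E: float = 0.0625
    R: float = 0.0
    beta: float = 0.2

    def __post_init__(self) -> None:
        if not 0.0 <= self.s_bar <= 1.0:
            raise ValueError(f"s_bar must be in [0, 1], got {self.s_bar}")
        if self.G < 0 or self.E < 0:
            raise ValueError("G and E must be nonnegative")

    def mean(self) -> float:
        return predict_mean(self.psi_g, self.s_bar, self.a_bar)

    def response(self) -> float:
        return predict_response(self.psi_g, self.s_bar, self.G, self.R, self.beta)

    def var_tbv(self) -> float:
        return predict_var_tbv(self.G, self.psi_g, self.s_bar)
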