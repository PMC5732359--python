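"""Analytic core of the maternal-effects selection-response model.

The model treats two interacting traits on a standardized scale (each trait
has mean 0 and, nominally, phenotypic variance 1): a maternal trait — daily
energy expenditure (DEE), the energetic proxy for parental-care effort — and
an offspring trait, growth rate. The maternal phenotype is an ordinary
additive trait,

    z_DEE = a_DEE + e_DEE,

while the offspring phenotype receives the mother's *entire* DEE phenotype as
part of its environment (a unidirectional maternal effect with coefficient 1):

    z_O = a_O + e_O + z_DEE(dam).

Because offspring inherit half of the dam's genes, genetic variation in DEE
and the genetic covariance Cov(A_O, A_DEE) between the two breeding values
re-enter the response to selection on growth rate with coefficients 1/2 and
3/2, and selection on either trait produces a correlated response in the
other. This module holds the parameter containers and every closed-form
quantity of the model: the classical breeder's equation, the total breeding
value, the joint two-trait per-generation responses with a term-by-term
decomposition, and the stationary kin covariances implied by the phenotype
rule (the basis of moment estimation in :mod:`maternalqg.estimate`).

Selection on DEE is female-limited by default (DEE is expressed by mothers),
which puts a factor 1/2 on every beta_DEE term; the both-sex variant is
exposed separately as :func:`maternal_response_both_sexes`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Tuple

import numpy as np

__all__ = [
    "GeneticArchitecture",
    "SelectionRegime",
    "ResponsePrediction",
    "StationaryMoments",
    "TERM_LABELS",
    "breeders_equation",
    "total_breeding_value",
    "offspring_response_terms",
    "maternal_response_terms",
    "predict_offspring_response",
    "predict_maternal_response",
    "predict_response",
    "maternal_response_both_sexes",
    "decompose_phenotype_model",
]

#: Fixed vocabulary for term decompositions, so scenario tables diff cleanly.
TERM_LABELS: Tuple[str, ...] = (
    "direct",
    "cov_via_beta_o",
    "maternal_var_via_beta_o",
    "cov_via_beta_dee",
    "maternal_var_via_beta_dee",
)

# Slack for the positive-semidefiniteness check; covers round-off in
# user-supplied components, not genuinely invalid matrices.
_PSD_TOL = 1e-9


def _require_finite(name: str, value: float) -> float:
    value = float(value)
    if not math.isfinite(value):
        raise ValueError(f"{name} must be finite, got {value!r}")
    return value


@dataclass(frozen=True)
class GeneticArchitecture:
    """Variance components of the two-trait maternal-effects model.

    Parameters
    ----------
    v_ao : float
        Additive genetic variance of offspring growth rate, V_AO (>= 0).
    v_adee : float
        Additive genetic variance of maternal DEE, V_A(DEE) (>= 0).
    cov_a : float
        Additive genetic covariance Cov(A_O, A_DEE) between the direct and
        maternal breeding values. Any sign, but the 2x2 genetic covariance
        matrix must be positive semidefinite.
    v_eo, v_edee : float
        Residual (non-additive genetic plus environmental) variances of the
        two traits (>= 0).

    All components are on the standardized scale of the model; nothing is
    rescaled internally.
    """

    v_ao: float
    v_adee: float
    cov_a: float = 0.0
    v_eo: float = 0.0
    v_edee: float = 0.0

    def __post_init__(self) -> None:
        for name in ("v_ao", "v_adee", "cov_a", "v_eo", "v_edee"):
            object.__setattr__(self, name, _require_finite(name, getattr(self, name)))
        for name in ("v_ao", "v_adee", "v_eo", "v_edee"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative, got {getattr(self, name)}")
        if self.cov_a**2 > self.v_ao * self.v_adee + _PSD_TOL:
            raise ValueError(
                "genetic covariance matrix is not positive semidefinite: "
                f"cov_a^2 = {self.cov_a**2:.6g} exceeds v_ao*v_adee = "
                f"{self.v_ao * self.v_adee:.6g}"
            )

    @property
    def g_matrix(self) -> np.ndarray:
        """2x2 additive genetic covariance matrix [[V_AO, C], [C, V_A(DEE)]]."""
        return np.array([[self.v_ao, self.cov_a], [self.cov_a, self.v_adee]])

    @property
    def var_zdee(self) -> float:
        """Stationary phenotypic variance of DEE: V_A(DEE) + V_E(DEE)."""
        return self.v_adee + self.v_edee

    @property
    def var_zo(self) -> float:
        """Stationary phenotypic variance of growth rate under random mating.

        var(z_O) = V_AO + V_EO + var(z_DEE) + 2*cov(a_O, z_DEE,dam), where
        cov(a_O, z_DEE,dam) = C/2 by mother-offspring transmission, hence
        V_AO + V_EO + V_A(DEE) + V_E(DEE) + C. Exceeds 1 whenever the
        maternal pathway contributes even if every single component is <= 1.
        """
        return self.v_ao + self.v_eo + self.var_zdee + self.cov_a

    def heritability(self, trait: str = "offspring") -> float:
        """Narrow-sense h^2 = V_A / var(z) for ``"offspring"`` or ``"maternal"``."""
        if trait == "offspring":
            return self.v_ao / self.var_zo if self.var_zo > 0 else math.nan
        if trait == "maternal":
            return self.v_adee / self.var_zdee if self.var_zdee > 0 else math.nan
        raise ValueError(f"trait must be 'offspring' or 'maternal', got {trait!r}")


@dataclass(frozen=True)
class SelectionRegime:
    """Directional selection gradients (per standardized trait unit).

    beta_o acts on offspring growth rate in both sexes; beta_dee acts on
    expressed maternal DEE, i.e. on females only under the model's default
    convention. Either gradient may be zero or negative.
    """

    beta_o: float = 0.0
    beta_dee: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "beta_o", _require_finite("beta_o", self.beta_o))
        object.__setattr__(self, "beta_dee", _require_finite("beta_dee", self.beta_dee))

    def scaled(self, factor: float) -> "SelectionRegime":
        """Both gradients multiplied by ``factor`` (weak-selection scaling)."""
        return SelectionRegime(self.beta_o * factor, self.beta_dee * factor)

    @staticmethod
    def from_differential(s: float, var_z: float) -> "SelectionRegime":
        """Single-trait regime from a selection differential S on growth rate.

        Under the Lande-Arnold relation S = beta * var(z), so beta = S/var(z).
        """
        if var_z <= 0:
            raise ValueError("var_z must be positive to convert a differential")
        return SelectionRegime(beta_o=s / var_z, beta_dee=0.0)


@dataclass(frozen=True)
class ResponsePrediction:
    """Expected one-generation responses with term-by-term decomposition.

    ``terms_zo``/``terms_zdee`` map each :data:`TERM_LABELS` entry to its
    numeric contribution; each total equals the sum of its terms.
    """

    delta_zo: float
    delta_zdee: float
    terms_zo: Dict[str, float] = field(default_factory=dict)
    terms_zdee: Dict[str, float] = field(default_factory=dict)

    def to_record(self) -> Dict[str, float]:
        """Flat mapping (totals plus prefixed terms) for TSV/JSON output."""
        rec: Dict[str, float] = {"delta_zo": self.delta_zo, "delta_zdee": self.delta_zdee}
        rec.update({f"zo_{k}": v for k, v in self.terms_zo.items()})
        rec.update({f"zdee_{k}": v for k, v in self.terms_zdee.items()})
        return rec


@dataclass(frozen=True)
class StationaryMoments:
    """Model-implied stationary phenotypic (co)variances under neutrality.

    Kin covariances follow from z_O = a_O + e_O + z_DEE(dam) and the r = 0.5
    transmission of breeding values under random mating:

    - cov(z_DEE,dam; z_DEE,off) = V_A(DEE)/2
    - cov(z_DEE,dam; z_O,off)   = C/2 + var(z_DEE)   (the maternal pathway
      passes the dam's full phenotype, genes add C/2)
    - cov(z_O,sire; z_O,off)    = V_AO/2 + C/4       (the C/4 is the
      grand-maternal term: the sire's own maternal environment covaries with
      the genes he transmits)
    """

    var_zdee: float
    var_zo: float
    cov_dam_off_dee: float
    cov_dam_dee_off_zo: float
    cov_sire_zo_off_zo: float


def breeders_equation(v_a: float, beta: float) -> float:
    """Classical single-trait response to selection, Delta z = V_A * beta.

    Equivalent to h^2 * S on the standardized scale. Raises ``ValueError``
    for a negative additive variance.
    """
    v_a = _require_finite("v_a", v_a)
    beta = _require_finite("beta", beta)
    if v_a < 0:
        raise ValueError(f"additive variance must be non-negative, got {v_a}")
    return v_a * beta


def total_breeding_value(a_o, a_dee):
    """Total breeding value A = A_O + A_DEE/2 of a maternally affected trait.

    The 1/2 reflects diploid transmission: only half of an individual's genes
    come from its mother, so its maternal breeding value is expressed (in its
    offspring's environment) at half weight. Accepts scalars or arrays.
    """
    return a_o + 0.5 * a_dee


def offspring_response_terms(arch: GeneticArchitecture, sel: SelectionRegime) -> Dict[str, float]:
    """Additive terms of the growth-rate response.

    Delta z_O = [V_AO + 3/2 C + 1/2 V_A(DEE)] beta_O + [V_A(DEE) + C] beta_DEE / 2.
    """
    return {
        "direct": arch.v_ao * sel.beta_o,
        "cov_via_beta_o": 1.5 * arch.cov_a * sel.beta_o,
        "maternal_var_via_beta_o": 0.5 * arch.v_adee * sel.beta_o,
        "cov_via_beta_dee": 0.5 * arch.cov_a * sel.beta_dee,
        "maternal_var_via_beta_dee": 0.5 * arch.v_adee * sel.beta_dee,
    }


def maternal_response_terms(arch: GeneticArchitecture, sel: SelectionRegime) -> Dict[str, float]:
    """Additive terms of the maternal-DEE response (female-limited beta_DEE).

    Delta z_DEE = [1/2 V_A(DEE) + C] beta_O + V_A(DEE) beta_DEE / 2.

    There is no "direct" breeder's-equation term here because selection on
    DEE reaches only mothers: its direct contribution carries the 1/2. The
    unused labels are reported as exact zeros to keep records diffable.
    """
    return {
        "direct": 0.0,
        "cov_via_beta_o": arch.cov_a * sel.beta_o,
        "maternal_var_via_beta_o": 0.5 * arch.v_adee * sel.beta_o,
        "cov_via_beta_dee": 0.0,
        "maternal_var_via_beta_dee": 0.5 * arch.v_adee * sel.beta_dee,
    }


def predict_offspring_response(
    arch: GeneticArchitecture, sel: SelectionRegime
) -> Tuple[float, Dict[str, float]]:
    """Expected per-generation change in mean growth rate, with decomposition.

    With beta_dee = 0 this reduces to the maternal-effects single-trait
    response [V_AO + 3/2 C + 1/2 V_A(DEE)] beta_O, and with all maternal
    terms zero to the breeder's equation V_AO * beta_O.
    """
    terms = offspring_response_terms(arch, sel)
    return sum(terms.values()), terms


def predict_maternal_response(
    arch: GeneticArchitecture, sel: SelectionRegime
) -> Tuple[float, Dict[str, float]]:
    """Expected per-generation change in mean maternal DEE, with decomposition."""
    terms = maternal_response_terms(arch, sel)
    return sum(terms.values()), terms


def predict_response(arch: GeneticArchitecture, sel: SelectionRegime) -> ResponsePrediction:
    """Joint two-trait response prediction."""
    dzo, tzo = predict_offspring_response(arch, sel)
    dzdee, tzdee = predict_maternal_response(arch, sel)
    return ResponsePrediction(delta_zo=dzo, delta_zdee=dzdee, terms_zo=tzo, terms_zdee=tzdee)


def maternal_response_both_sexes(arch: GeneticArchitecture, sel: SelectionRegime) -> float:
    """Univariate DEE response when selection on DEE reaches both sexes.

    Delta z_DEE = V_A(DEE) * beta_DEE — the breeder's equation for DEE
    without the mother-only 1/2. Provided for study designs where the trait
    (or a correlate) is selected in males as well; the default model keeps
    the female-limited convention of :func:`predict_maternal_response`.
    """
    return breeders_equation(arch.v_adee, sel.beta_dee)


def decompose_phenotype_model(arch: GeneticArchitecture) -> StationaryMoments:
    """Stationary phenotypic moments implied by the phenotype rule.

    These are the expected values, under neutrality and random mating, of
    exactly the sample statistics that :func:`maternalqg.estimate.
    compute_kin_covariances` measures on a pedigree table; inverting this map
    is how variance components are estimated from data.
    """
    var_zdee = arch.var_zdee
    return StationaryMoments(
        var_zdee=var_zdee,
        var_zo=arch.var_zo,
        cov_dam_off_dee=0.5 * arch.v_adee,
        cov_dam_dee_off_zo=0.5 * arch.cov_a + var_zdee,
        cov_sire_zo_off_zo=0.5 * arch.v_ao + 0.25 * arch.cov_a,
    )
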