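"""Moment-based variance-component estimation from pedigreed phenotypes.

The estimation design is a dam-offspring / sire-offspring covariance design:
from a two-generation (or deeper) pedigree table with the two phenotypes it
computes five sample statistics and inverts the linear map that
:func:`maternalqg.model.decompose_phenotype_model` predicts for them,

    V_A(DEE)       = 2 cov(z_DEE,dam; z_DEE,off)
    V_E(DEE)       = var(z_DEE) - V_A(DEE)
    Cov(A_O,A_DEE) = 2 [cov(z_DEE,dam; z_O,off) - var(z_DEE)]
    V_AO           = 2 cov(z_O,sire; z_O,off) - Cov(A_O,A_DEE)/2
    V_EO           = var(z_O) - V_AO - var(z_DEE) - Cov(A_O,A_DEE)

(the sire-offspring covariance contains a Cov/4 grand-maternal term that
must be subtracted before doubling). Moment estimators are used instead of
an animal model because they are transparent, exactly invertible against the
analytic forward map, and make explicit *which* kin covariances carry the
information; REML/animal-model fitting is a deliberate non-goal. Estimation
assumes neutral or weakly selected data. Only phenotype and pedigree columns
are ever consulted — breeding-value columns present in simulator output are
ignored by construction. Uncertainty comes from a nonparametric bootstrap
over dams (each dam resampled with all her descendants), and other defensible
designs (e.g. cross-fostering, which would split e_DEE differently) exist;
this one only needs an ordinary two-generation pedigree.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Optional, Tuple, Union

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .model import (
    GeneticArchitecture,
    ResponsePrediction,
    SelectionRegime,
    StationaryMoments,
    predict_response,
)

__all__ = [
    "KinCovarianceSet",
    "ArchitectureEstimate",
    "ResponseInterval",
    "compute_kin_covariances",
    "estimate_architecture",
    "predict_from_estimates",
    "MaternalMomentEstimator",
]

#: Phenotype-only view: the columns estimation is allowed to read.
PHENOTYPE_COLUMNS = ("id", "dam_id", "sire_id", "sex", "generation", "z_o", "z_dee")

COMPONENT_NAMES = ("v_ao", "v_adee", "cov_a", "v_eo", "v_edee")

_LOW_CONFIDENCE_N = 30


@dataclass(frozen=True)
class KinCovarianceSet:
    """Sample kin (co)variances with their pair counts.

    Statistics with fewer than 30 pairs are flagged low-confidence.
    """

    var_zdee: float
    var_zo: float
    cov_dam_off_dee: float
    cov_dam_dee_off_zo: float
    cov_sire_zo_off_zo: float
    n_pairs: Dict[str, int]

    @property
    def low_confidence(self) -> Tuple[str, ...]:
        return tuple(k for k, n in self.n_pairs.items() if n < _LOW_CONFIDENCE_N)


@dataclass(frozen=True)
class ArchitectureEstimate:
    """Raw and truncated moment solutions for the five components.

    ``raw`` is the exact inverse of the moment map and may contain negative
    variances or a PSD-violating covariance in finite samples; ``truncated``
    clips variances at zero and the covariance to the PSD bound of the
    truncated variances. Both are always reported; nothing is silently
    clipped.
    """

    raw: Dict[str, float]
    truncated: Dict[str, float]
    truncation_applied: bool

    @property
    def architecture(self) -> GeneticArchitecture:
        """Valid :class:`GeneticArchitecture` built from the truncated solution."""
        return GeneticArchitecture(**self.truncated)


@dataclass(frozen=True)
class ResponseInterval:
    """Point response prediction with bootstrap-propagated uncertainty."""

    prediction: ResponsePrediction
    se_zo: float
    se_zdee: float
    ci_zo: Tuple[float, float]
    ci_zdee: Tuple[float, float]


def _is_female(sex: pd.Series) -> np.ndarray:
    s = sex.astype(str).str.upper().str[0]
    return s.isin(("F", "1")).to_numpy()


def _cov(x: np.ndarray, y: np.ndarray) -> float:
    if x.size < 2:
        return math.nan
    return float(np.cov(x, y, ddof=1)[0, 1])


def _var(x: np.ndarray) -> float:
    return float(np.var(x, ddof=1)) if x.size >= 2 else math.nan


def compute_kin_covariances(
    table: pd.DataFrame, include_male_dee: bool = False
) -> KinCovarianceSet:
    """Kin covariances from a pedigree/phenotype table.

    Parameters
    ----------
    table
        Pedigree table with at least :data:`PHENOTYPE_COLUMNS` (the
        simulator's TSV contract); missing parents are coded 0. At least two
        generations with resolvable dam and sire links are required.
    include_male_dee
        If True, males' latent z_dee values (available in synthetic data,
        unmeasurable in real studies) also enter the DEE statistics, roughly
        halving their sampling variance.

    Each offspring contributes one pair per statistic; a parent with several
    offspring contributes several pairs (pair-level weighting).
    """
    missing = [c for c in PHENOTYPE_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"pedigree table lacks required column(s): {missing}")
    table = table.loc[:, list(PHENOTYPE_COLUMNS)]

    ids = table["id"].to_numpy()
    if ids.size != np.unique(ids).size:
        raise ValueError("pedigree table has duplicate individual ids")
    pos = pd.Series(np.arange(ids.size), index=ids)
    dam_known = table["dam_id"].isin(pos.index) & (table["dam_id"] != 0)
    sire_known = table["sire_id"].isin(pos.index) & (table["sire_id"] != 0)
    if not dam_known.any() or not sire_known.any():
        raise ValueError(
            "no resolvable dam/sire links: need >= 2 generations whose "
            "parents appear in the table"
        )

    female = _is_female(table["sex"])
    z_o = table["z_o"].to_numpy(float)
    z_dee = table["z_dee"].to_numpy(float)

    dam_pos = pos[table.loc[dam_known, "dam_id"]].to_numpy()
    off_pos = np.flatnonzero(dam_known.to_numpy())
    sire_pos = pos[table.loc[sire_known, "sire_id"]].to_numpy()
    off_pos_s = np.flatnonzero(sire_known.to_numpy())

    dee_mask = np.ones(off_pos.size, bool) if include_male_dee else female[off_pos]
    expressed = np.ones(ids.size, bool) if include_male_dee else female

    n_pairs = {
        "var_zdee": int(expressed.sum()),
        "var_zo": int(ids.size),
        "cov_dam_off_dee": int(dee_mask.sum()),
        "cov_dam_dee_off_zo": int(off_pos.size),
        "cov_sire_zo_off_zo": int(off_pos_s.size),
    }
    return KinCovarianceSet(
        var_zdee=_var(z_dee[expressed]),
        var_zo=_var(z_o),
        cov_dam_off_dee=_cov(z_dee[dam_pos[dee_mask]], z_dee[off_pos[dee_mask]]),
        cov_dam_dee_off_zo=_cov(z_dee[dam_pos], z_o[off_pos]),
        cov_sire_zo_off_zo=_cov(z_o[sire_pos], z_o[off_pos_s]),
        n_pairs=n_pairs,
    )


def _invert_moments(
    var_zdee, var_zo, cov_dam_off_dee, cov_dam_dee_off_zo, cov_sire_zo_off_zo
):
    """Closed-form inverse of the moment map; vectorized over arrays."""
    v_adee = 2.0 * cov_dam_off_dee
    v_edee = var_zdee - v_adee
    cov_a = 2.0 * (cov_dam_dee_off_zo - var_zdee)
    v_ao = 2.0 * cov_sire_zo_off_zo - 0.5 * cov_a
    v_eo = var_zo - v_ao - var_zdee - cov_a
    return v_ao, v_adee, cov_a, v_eo, v_edee


def estimate_architecture(
    kin: Union[KinCovarianceSet, StationaryMoments]
) -> ArchitectureEstimate:
    """Invert the kin-covariance moment system for the five components.

    Accepts either measured :class:`KinCovarianceSet` statistics or analytic
    :class:`~maternalqg.model.StationaryMoments`; on the latter the inverse
    is exact (forward-inverse identity).
    """
    stats = [
        getattr(kin, name)
        for name in (
            "var_zdee",
            "var_zo",
            "cov_dam_off_dee",
            "cov_dam_dee_off_zo",
            "cov_sire_zo_off_zo",
        )
    ]
    if not all(math.isfinite(s) for s in stats):
        raise ValueError(f"kin statistics must be finite, got {stats}")
    raw = dict(zip(COMPONENT_NAMES, _invert_moments(*stats)))

    trunc = dict(raw)
    for name in ("v_ao", "v_adee", "v_eo", "v_edee"):
        trunc[name] = max(0.0, trunc[name])
    bound = math.sqrt(trunc["v_ao"] * trunc["v_adee"])
    trunc["cov_a"] = min(max(trunc["cov_a"], -bound), bound)
    applied = any(
        not math.isclose(raw[k], trunc[k], rel_tol=0.0, abs_tol=0.0) for k in raw
    )
    return ArchitectureEstimate(raw=raw, truncated=trunc, truncation_applied=applied)


def predict_from_estimates(
    est: Union["MaternalMomentEstimator", ArchitectureEstimate],
    sel: SelectionRegime,
) -> ResponseInterval:
    """Selection responses from estimated components, with uncertainty.

    The response equations are linear in the components, so the bootstrap
    component draws map directly to a bootstrap response distribution
    (percentile 95% intervals). Without bootstrap draws (e.g. an analytic
    :class:`ArchitectureEstimate`) the interval has zero width.
    """
    if isinstance(est, MaternalMomentEstimator):
        comps = est.estimate_.raw
        draws = est.bootstrap_components_
    else:
        comps = est.raw
        draws = None

    terms = _response_pair(
        comps["v_ao"], comps["v_adee"], comps["cov_a"], sel.beta_o, sel.beta_dee
    )
    prediction = ResponsePrediction(
        delta_zo=float(sum(terms[0].values())),
        delta_zdee=float(sum(terms[1].values())),
        terms_zo=terms[0],
        terms_zdee=terms[1],
    )
    if draws is None or len(draws) == 0:
        return ResponseInterval(
            prediction=prediction,
            se_zo=0.0,
            se_zdee=0.0,
            ci_zo=(prediction.delta_zo, prediction.delta_zo),
            ci_zdee=(prediction.delta_zdee, prediction.delta_zdee),
        )
    dzo = (
        (draws[:, 0] + 1.5 * draws[:, 2] + 0.5 * draws[:, 1]) * sel.beta_o
        + (draws[:, 1] + draws[:, 2]) * 0.5 * sel.beta_dee
    )
    dzdee = (0.5 * draws[:, 1] + draws[:, 2]) * sel.beta_o + 0.5 * draws[:, 1] * sel.beta_dee
    return ResponseInterval(
        prediction=prediction,
        se_zo=float(np.std(dzo, ddof=1)),
        se_zdee=float(np.std(dzdee, ddof=1)),
        ci_zo=tuple(np.percentile(dzo, [2.5, 97.5])),
        ci_zdee=tuple(np.percentile(dzdee, [2.5, 97.5])),
    )


def _response_pair(v_ao, v_adee, cov_a, beta_o, beta_dee):
    """Term decompositions from raw component values (PSD not required).

    Finite-sample moment estimates may sit slightly outside the PSD cone;
    the response equations remain well-defined there, so this bypasses the
    :class:`GeneticArchitecture` validity guard on purpose.
    """
    terms_zo = {
        "direct": v_ao * beta_o,
        "cov_via_beta_o": 1.5 * cov_a * beta_o,
        "maternal_var_via_beta_o": 0.5 * v_adee * beta_o,
        "cov_via_beta_dee": 0.5 * cov_a * beta_dee,
        "maternal_var_via_beta_dee": 0.5 * v_adee * beta_dee,
    }
    terms_zdee = {
        "direct": 0.0,
        "cov_via_beta_o": cov_a * beta_o,
        "maternal_var_via_beta_o": 0.5 * v_adee * beta_o,
        "cov_via_beta_dee": 0.0,
        "maternal_var_via_beta_dee": 0.5 * v_adee * beta_dee,
    }
    return terms_zo, terms_zdee


class MaternalMomentEstimator(BaseEstimator):
    """Scikit-learn style estimator of the maternal-effects architecture.

    ``fit`` takes a pedigree/phenotype table (DataFrame or path to the
    simulator's TSV), computes the kin covariances, inverts the moment
    system, and bootstraps families (dams with all their offspring pairs)
    for standard errors. ``predict`` maps selection gradients to expected
    responses using the fitted components.

    Parameters
    ----------
    include_male_dee : bool, default False
        Use males' latent DEE values in the DEE statistics (synthetic
        studies only).
    n_bootstrap : int, default 500
        Family-bootstrap resamples; 0 disables uncertainty estimation.
    random_state : int or None
        Seed for the bootstrap; fixed seed gives identical intervals.

    Attributes
    ----------
    kin_ : KinCovarianceSet
    estimate_ : ArchitectureEstimate
        Raw and truncated component solutions.
    components_ : ndarray of shape (5,)
        Raw solution in :data:`COMPONENT_NAMES` order.
    se_ : dict
        Bootstrap standard error per component.
    bootstrap_components_ : ndarray of shape (n_bootstrap, 5)
    n_families_ : int
    """

    def __init__(
        self,
        include_male_dee: bool = False,
        n_bootstrap: int = 500,
        random_state: Optional[int] = None,
    ):
        self.include_male_dee = include_male_dee
        self.n_bootstrap = n_bootstrap
        self.random_state = random_state

    # -- fitting ---------------------------------------------------------

    def fit(self, X: Union[pd.DataFrame, str, Path], y=None) -> "MaternalMomentEstimator":
        table = pd.read_csv(X, sep="\t") if isinstance(X, (str, Path)) else X
        view = table.loc[:, [c for c in PHENOTYPE_COLUMNS if c in table.columns]]
        self.kin_ = compute_kin_covariances(view, self.include_male_dee)
        self.estimate_ = estimate_architecture(self.kin_)
        self.components_ = np.array(
            [self.estimate_.raw[k] for k in COMPONENT_NAMES]
        )
        self.bootstrap_components_, self.n_families_ = self._bootstrap(view)
        if self.bootstrap_components_.size:
            se = np.std(self.bootstrap_components_, axis=0, ddof=1)
        else:
            se = np.full(5, np.nan)
        self.se_ = dict(zip(COMPONENT_NAMES, se.astype(float)))
        return self

    def predict(self, X) -> np.ndarray:
        """Responses for gradient pairs ``X`` of shape (n, 2) = (beta_o, beta_dee).

        Returns an (n, 2) array of (delta_zo, delta_zdee).
        """
        if not hasattr(self, "estimate_"):
            raise RuntimeError("estimator is not fitted")
        X = np.atleast_2d(np.asarray(X, dtype=float))
        v_ao, v_adee, cov_a = (
            self.estimate_.raw["v_ao"],
            self.estimate_.raw["v_adee"],
            self.estimate_.raw["cov_a"],
        )
        dzo = (v_ao + 1.5 * cov_a + 0.5 * v_adee) * X[:, 0] + (
            v_adee + cov_a
        ) * 0.5 * X[:, 1]
        dzdee = (0.5 * v_adee + cov_a) * X[:, 0] + 0.5 * v_adee * X[:, 1]
        return np.column_stack([dzo, dzdee])

    def predict_response(self, sel: SelectionRegime) -> ResponseInterval:
        """Full response prediction with bootstrap-propagated intervals."""
        if not hasattr(self, "estimate_"):
            raise RuntimeError("estimator is not fitted")
        return predict_from_estimates(self, sel)

    # -- bootstrap machinery --------------------------------------------

    def _bootstrap(self, table: pd.DataFrame) -> Tuple[np.ndarray, int]:
        """Family bootstrap: resample dams, carry their pairs and members.

        Per-dam sufficient statistics (n, Sx, Sy, Sxy per covariance; n, S,
        S2 per variance) make each resample a single weighted sum, so the
        whole bootstrap is three matrix products. Sires are attached to
        their mate's family; a sire with several mates is counted once per
        mate, an accepted approximation of family non-independence.
        """
        ids = table["id"].to_numpy()
        pos = pd.Series(np.arange(ids.size), index=ids)
        dam_known = table["dam_id"].isin(pos.index) & (table["dam_id"] != 0)
        sire_known = table["sire_id"].isin(pos.index) & (table["sire_id"] != 0)
        female = _is_female(table["sex"])
        z_o = table["z_o"].to_numpy(float)
        z_dee = table["z_dee"].to_numpy(float)

        off = np.flatnonzero(dam_known.to_numpy())
        dam_of = pos[table.loc[dam_known, "dam_id"]].to_numpy()
        dams, fam_of_pair = np.unique(dam_of, return_inverse=True)
        n_fam = dams.size
        if n_fam < 2 or self.n_bootstrap <= 0:
            return np.empty((0, 5)), int(n_fam)

        def cov_suff(x, y, fam, mask=None):
            if mask is not None:
                x, y, fam = x[mask], y[mask], fam[mask]
            cols = [
                np.bincount(fam, minlength=n_fam),
                np.bincount(fam, weights=x, minlength=n_fam),
                np.bincount(fam, weights=y, minlength=n_fam),
                np.bincount(fam, weights=x * y, minlength=n_fam),
            ]
            return np.column_stack(cols)

        def var_suff(x, fam, mask=None):
            if mask is not None:
                x, fam = x[mask], fam[mask]
            cols = [
                np.bincount(fam, minlength=n_fam),
                np.bincount(fam, weights=x, minlength=n_fam),
                np.bincount(fam, weights=x * x, minlength=n_fam),
            ]
            return np.column_stack(cols)

        dee_mask = None if self.include_male_dee else female[off]
        s_dee = cov_suff(z_dee[dam_of], z_dee[off], fam_of_pair, dee_mask)
        s_dzo = cov_suff(z_dee[dam_of], z_o[off], fam_of_pair)

        # sire pairs keyed by the offspring's dam-family (offspring with a
        # known sire but unknown dam are rare in well-formed tables and are
        # dropped from the bootstrap)
        both = dam_known & sire_known
        both_off = np.flatnonzero(both.to_numpy())
        sire_of = pos[table.loc[both, "sire_id"]].to_numpy()
        fam_of_both = fam_of_pair[np.isin(off, both_off)]
        s_sire = cov_suff(z_o[sire_of], z_o[both_off], fam_of_both)

        # family membership for the plain variances: dam + mates + offspring
        member_fam = np.concatenate(
            [np.arange(n_fam), fam_of_pair, fam_of_both]
        )
        member_idx = np.concatenate([dams, off, sire_of])
        expressed = np.ones(member_idx.size, bool) if self.include_male_dee else female[member_idx]
        s_vdee = var_suff(z_dee[member_idx], member_fam, expressed)
        s_vzo = var_suff(z_o[member_idx], member_fam)

        rng = np.random.default_rng(self.random_state)
        counts = rng.multinomial(
            n_fam, np.full(n_fam, 1.0 / n_fam), size=self.n_bootstrap
        ).astype(float)

        def boot_cov(s):
            n, sx, sy, sxy = (counts @ s).T
            with np.errstate(invalid="ignore", divide="ignore"):
                return (sxy - sx * sy / n) / (n - 1)

        def boot_var(s):
            n, sx, sxx = (counts @ s).T
            with np.errstate(invalid="ignore", divide="ignore"):
                return (sxx - sx * sx / n) / (n - 1)

        comps = _invert_moments(
            boot_var(s_vdee), boot_var(s_vzo), boot_cov(s_dee), boot_cov(s_dzo), boot_cov(s_sire)
        )
        return np.column_stack(comps), int(n_fam)
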