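"""Individual-based forward simulation of the maternal-effects model.

Discrete, non-overlapping generations; infinitesimal-model inheritance. Each
individual carries a bivariate breeding value (a_o, a_dee), environmental
deviations (e_o, e_dee), and the phenotypes

    z_dee = a_dee + e_dee                  (expressed by females; carried,
                                            latent, by males)
    z_o   = a_o + e_o + z_dee(dam)         (the dam's full DEE phenotype is
                                            the offspring's maternal
                                            environment; no feedback from
                                            offspring to mother exists)

Offspring breeding values are midparent values plus a Mendelian segregation
deviation drawn from N(0, G0/2) with G0 the founder genetic covariance
matrix, held constant across generations (no gametic-disequilibrium
bookkeeping, so the Bulmer effect appears as a small systematic deficit at
larger gradients). Fitness is linear in phenotypes centered at the current
generation means, w = max(0, 1 + beta_o (z_o - mean) [+ beta_dee (z_dee -
mean) for females]), and parents are sampled with probability proportional
to w, which keeps realized Lande-Arnold gradients equal to the nominal
coefficients throughout a run. Founders have no simulated mothers; each
receives a virtual parental pair drawn from the stationary distribution so
that generation 0 already has the model's stationary variances and kin
covariances.

The simulator doubles as the package's synthetic-data generator: pedigreed
two-trait phenotype tables come out of :func:`simulate_pedigree` /
:meth:`Population.to_frame`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .model import GeneticArchitecture, SelectionRegime

__all__ = [
    "SimulationConfig",
    "Population",
    "SelectionStats",
    "SimulationResult",
    "SimulationError",
    "init_founders",
    "select",
    "reproduce",
    "run",
    "simulate_pedigree",
]

TRAJECTORY_COLUMNS = (
    "generation",
    "phase",
    "mean_z_o",
    "mean_z_dee",
    "var_z_o",
    "var_z_dee",
    "delta_z_o",
    "delta_z_dee",
    "var_a_o",
    "var_a_dee",
    "cov_a",
    "realized_beta_o",
    "realized_beta_dee",
    "frac_clamped",
)

PEDIGREE_COLUMNS = (
    "id",
    "dam_id",
    "sire_id",
    "sex",
    "generation",
    "a_o",
    "a_dee",
    "e_o",
    "e_dee",
    "z_o",
    "z_dee",
    "fitness",
)


class SimulationError(RuntimeError):
    """Raised when a run cannot continue (e.g. no parent has fitness > 0)."""


@dataclass
class SimulationConfig:
    """Parameters of a forward-simulation run.

    Parameters
    ----------
    arch, sel
        Genetic architecture and nominal selection gradients.
    n_per_generation : int
        Census size of every generation (even, >= 2).
    n_generations : int
        Number of generations simulated *under selection* (after burn-in).
    n_replicates : int
        Independent replicates; replicate RNGs are spawned from ``seed`` via
        ``numpy.random.SeedSequence`` so runs are reproducible bit-for-bit.
    seed : int
        Master seed; mandatory.
    offspring_per_pair : int
        Litter size (equal across pairs).
    female_only_dee_selection : bool
        If True (default, the model's convention) beta_dee enters fitness for
        females only; if False both sexes are selected on their (latent) DEE.
    monogamous : bool
        If True, distinct parents are drawn without replacement (strict
        monogamy). Under selection this attenuates realized gradients below
        the nominal betas, so the default (False) samples parents with
        replacement, fitness-proportionally.
    burn_in : int
        Neutral generations simulated before selection switches on.
    response_window : (int, int)
        Inclusive range of selection-phase generations whose realized
        per-generation responses are averaged into the asymptotic rate.
    segregation_variance : {"stationary", "constant"}
        ``"stationary"`` (default) recalibrates the Mendelian segregation
        covariance every generation to G0 minus the realized midparent
        covariance, holding the population's additive covariance matrix at
        its founder value G0 — the constant-components assumption of the
        analytic theory. ``"constant"`` uses the textbook fixed G0/2, under
        which directional selection builds negative gametic-phase
        disequilibrium (the Bulmer effect) and realized responses fall a few
        percent short of the constant-G predictions.
    keep_pedigree : bool
        Retain the full per-replicate pedigree/phenotype tables in the
        result (memory grows with n_per_generation x generations).
    """

    arch: GeneticArchitecture
    sel: SelectionRegime
    seed: int
    n_per_generation: int = 2000
    n_generations: int = 30
    n_replicates: int = 1
    offspring_per_pair: int = 4
    female_only_dee_selection: bool = True
    monogamous: bool = False
    burn_in: int = 5
    response_window: Tuple[int, int] = (11, 30)
    segregation_variance: str = "stationary"
    keep_pedigree: bool = False

    def __post_init__(self) -> None:
        if self.segregation_variance not in ("stationary", "constant"):
            raise ValueError(
                "segregation_variance must be 'stationary' or 'constant', "
                f"got {self.segregation_variance!r}"
            )
        if self.seed is None:
            raise ValueError("seed is mandatory for every run")
        if self.n_per_generation < 2 or self.n_per_generation % 2:
            raise ValueError("n_per_generation must be an even integer >= 2")
        if self.offspring_per_pair < 1:
            raise ValueError("offspring_per_pair must be >= 1")
        if self.n_generations < 1 or self.n_replicates < 1 or self.burn_in < 0:
            raise ValueError("n_generations/n_replicates >= 1 and burn_in >= 0 required")
        lo, hi = self.response_window
        if not (1 <= lo <= hi <= self.n_generations):
            raise ValueError(
                f"response_window {self.response_window} must lie within "
                f"[1, n_generations={self.n_generations}]"
            )


@dataclass
class Population:
    """One generation of simulated individuals (column-oriented arrays)."""

    id: np.ndarray
    dam_id: np.ndarray
    sire_id: np.ndarray
    sex: np.ndarray  # 1 = female, 0 = male
    generation: int
    a_o: np.ndarray
    a_dee: np.ndarray
    e_o: np.ndarray
    e_dee: np.ndarray
    z_o: np.ndarray
    z_dee: np.ndarray
    fitness: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.fitness is None:
            self.fitness = np.full(self.size, np.nan)

    @property
    def size(self) -> int:
        return self.id.size

    @property
    def females(self) -> np.ndarray:
        return np.flatnonzero(self.sex == 1)

    @property
    def males(self) -> np.ndarray:
        return np.flatnonzero(self.sex == 0)

    def to_frame(self) -> pd.DataFrame:
        """Pedigree/phenotype table (missing parents encoded as 0)."""
        return pd.DataFrame(
            {
                "id": self.id,
                "dam_id": self.dam_id,
                "sire_id": self.sire_id,
                "sex": np.where(self.sex == 1, "F", "M"),
                "generation": np.full(self.size, self.generation),
                "a_o": self.a_o,
                "a_dee": self.a_dee,
                "e_o": self.e_o,
                "e_dee": self.e_dee,
                "z_o": self.z_o,
                "z_dee": self.z_dee,
                "fitness": self.fitness,
            }
        )


@dataclass(frozen=True)
class SelectionStats:
    """Realized selection within one generation."""

    realized_beta_o: float
    realized_beta_dee: float
    frac_clamped: float


@dataclass
class SimulationResult:
    """Trajectories and across-replicate response summary of :func:`run`."""

    config: SimulationConfig
    trajectories: List[pd.DataFrame]
    responses: pd.DataFrame  # per replicate: response_zo, response_zdee
    response_zo_mean: float
    response_zo_se: float
    response_zdee_mean: float
    response_zdee_se: float
    pedigrees: Optional[List[pd.DataFrame]] = None  # when keep_pedigree is set


def _mvn(rng: np.random.Generator, cov: np.ndarray, size: int) -> np.ndarray:
    """Zero-mean multivariate normal draws tolerant of singular PSD matrices."""
    cov = np.asarray(cov, dtype=float)
    w, v = np.linalg.eigh(cov)
    w = np.clip(w, 0.0, None)
    factor = v * np.sqrt(w)
    return rng.standard_normal((size, cov.shape[0])) @ factor.T


def _balanced_sexes(rng: np.random.Generator, n: int) -> np.ndarray:
    sex = np.zeros(n, dtype=np.int8)
    sex[: n // 2] = 1
    rng.shuffle(sex)
    return sex


def init_founders(config: SimulationConfig, rng: np.random.Generator) -> Population:
    """Founder generation drawn from the model's stationary distribution.

    Each founder is assigned a *virtual* parental pair: breeding values are
    midparent plus segregation as in any later generation, and the virtual
    dam's z_DEE is the founder's maternal input. This gives generation 0 the
    stationary variances and the stationary covariances between own breeding
    values and maternal environment (Cov(m, a_o) = C/2, Cov(m, a_dee) =
    V_A(DEE)/2), so no variance deficit or kin-covariance transient exists at
    the boundary.
    """
    arch = config.arch
    n = config.n_per_generation
    g = arch.g_matrix
    a_vdam = _mvn(rng, g, n)
    a_vsire = _mvn(rng, g, n)
    a = 0.5 * (a_vdam + a_vsire) + _mvn(rng, 0.5 * g, n)
    maternal_input = a_vdam[:, 1] + rng.normal(0.0, math.sqrt(arch.v_edee), n)
    e_o = rng.normal(0.0, math.sqrt(arch.v_eo), n)
    e_dee = rng.normal(0.0, math.sqrt(arch.v_edee), n)
    z_dee = a[:, 1] + e_dee
    z_o = a[:, 0] + e_o + maternal_input
    return Population(
        id=np.arange(1, n + 1, dtype=np.int64),
        dam_id=np.zeros(n, dtype=np.int64),
        sire_id=np.zeros(n, dtype=np.int64),
        sex=_balanced_sexes(rng, n),
        generation=0,
        a_o=a[:, 0],
        a_dee=a[:, 1],
        e_o=e_o,
        e_dee=e_dee,
        z_o=z_o,
        z_dee=z_dee,
    )


def select(pop: Population, sel: SelectionRegime, config: SimulationConfig) -> SelectionStats:
    """Assign relative fitness in place and report realized gradients.

    w = max(0, 1 + beta_o (z_o - mean_z_o) + [expressed] beta_dee (z_dee -
    mean)); the beta_dee term applies to females only unless
    ``female_only_dee_selection`` is off. Realized gradients are the partial
    regression coefficients of relative fitness on the centered phenotypes,
    i.e. exactly the Lande-Arnold measurement an empiricist would make.
    """
    zo_c = pop.z_o - pop.z_o.mean()
    females = pop.sex == 1
    if config.female_only_dee_selection:
        ref = pop.z_dee[females].mean() if females.any() else 0.0
        zdee_sel = np.where(females, pop.z_dee - ref, 0.0)
    else:
        zdee_sel = pop.z_dee - pop.z_dee.mean()
    w = 1.0 + sel.beta_o * zo_c + sel.beta_dee * zdee_sel
    clamped = w < 0
    w = np.where(clamped, 0.0, w)
    if not np.any(w > 0):
        raise SimulationError(
            f"all individuals have zero fitness in generation {pop.generation}"
        )
    pop.fitness = w

    w_rel = w / w.mean()
    design = np.column_stack([np.ones(pop.size), zo_c, zdee_sel])
    coef, *_ = np.linalg.lstsq(design, w_rel, rcond=None)
    return SelectionStats(
        realized_beta_o=float(coef[1]),
        realized_beta_dee=float(coef[2]),
        frac_clamped=float(clamped.mean()),
    )


def _sample_parents(
    rng: np.random.Generator,
    candidates: np.ndarray,
    weights: np.ndarray,
    n_pairs: int,
    monogamous: bool,
) -> np.ndarray:
    total = weights.sum()
    if candidates.size == 0 or total <= 0:
        raise SimulationError("no candidate parent has positive fitness")
    p = weights / total
    if monogamous:
        if n_pairs > np.count_nonzero(weights):
            raise SimulationError(
                f"monogamy needs {n_pairs} distinct parents but only "
                f"{np.count_nonzero(weights)} have positive fitness"
            )
        return rng.choice(candidates, size=n_pairs, replace=False, p=p)
    return rng.choice(candidates, size=n_pairs, replace=True, p=p)


def reproduce(
    parents: Population,
    config: SimulationConfig,
    rng: np.random.Generator,
    start_id: int,
    n_offspring: Optional[int] = None,
    n_pairs: Optional[int] = None,
) -> Population:
    """Next generation from fitness-weighted parents.

    Pairs are formed at random between sampled dams and sires; each pair
    produces ``offspring_per_pair`` young (the tail pair may be truncated).
    Offspring breeding values are midparent plus N(0, G0/2) segregation;
    environmental deviations are fresh; z_o receives the dam's z_dee. Parent
    arrays are never written to — the maternal effect is unidirectional by
    construction.
    """
    if np.isnan(parents.fitness).any():
        raise SimulationError("call select() before reproduce(): fitness not assigned")
    n_off = config.n_per_generation if n_offspring is None else n_offspring
    if n_pairs is None:
        n_pairs = -(-n_off // config.offspring_per_pair)  # ceil
    fem, mal = parents.females, parents.males
    dams = _sample_parents(rng, fem, parents.fitness[fem], n_pairs, config.monogamous)
    sires = _sample_parents(rng, mal, parents.fitness[mal], n_pairs, config.monogamous)
    pair_of = np.repeat(np.arange(n_pairs), config.offspring_per_pair)[:n_off]
    d, s = dams[pair_of], sires[pair_of]

    arch = config.arch
    mid = 0.5 * np.column_stack(
        [parents.a_o[d] + parents.a_o[s], parents.a_dee[d] + parents.a_dee[s]]
    )
    if config.segregation_variance == "stationary" and n_off > 1:
        # hold offspring additive covariance at G0: segregation makes up the
        # difference between G0 and the realized midparent covariance
        # (negative eigenvalues are clipped inside _mvn)
        seg_cov = arch.g_matrix - np.cov(mid, rowvar=False, ddof=0)
    else:
        seg_cov = 0.5 * arch.g_matrix
    a = mid + _mvn(rng, seg_cov, n_off)
    e_o = rng.normal(0.0, math.sqrt(arch.v_eo), n_off)
    e_dee = rng.normal(0.0, math.sqrt(arch.v_edee), n_off)
    z_dee = a[:, 1] + e_dee
    z_o = a[:, 0] + e_o + parents.z_dee[d]
    return Population(
        id=np.arange(start_id, start_id + n_off, dtype=np.int64),
        dam_id=parents.id[d],
        sire_id=parents.id[s],
        sex=_balanced_sexes(rng, n_off),
        generation=parents.generation + 1,
        a_o=a[:, 0],
        a_dee=a[:, 1],
        e_o=e_o,
        e_dee=e_dee,
        z_o=z_o,
        z_dee=z_dee,
    )


def _trajectory_row(pop: Population) -> dict:
    return {
        "generation": pop.generation,
        "mean_z_o": pop.z_o.mean(),
        "mean_z_dee": pop.z_dee.mean(),
        "var_z_o": pop.z_o.var(ddof=1),
        "var_z_dee": pop.z_dee.var(ddof=1),
        "var_a_o": pop.a_o.var(ddof=1),
        "var_a_dee": pop.a_dee.var(ddof=1),
        "cov_a": float(np.cov(pop.a_o, pop.a_dee, ddof=1)[0, 1]),
    }


def _run_replicate(
    config: SimulationConfig, rng: np.random.Generator
) -> Tuple[pd.DataFrame, Optional[pd.DataFrame]]:
    neutral = SelectionRegime(0.0, 0.0)
    total = config.burn_in + config.n_generations
    pop = init_founders(config, rng)
    next_id = pop.size + 1
    rows = []
    frames = [] if config.keep_pedigree else None
    for g in range(total + 1):
        row = _trajectory_row(pop)
        row["phase"] = "burn_in" if g < config.burn_in else "selection"
        if g < total:
            sel_now = config.sel if g >= config.burn_in else neutral
            try:
                stats = select(pop, sel_now, config)
                child = reproduce(pop, config, rng, start_id=next_id)
            except SimulationError as err:
                raise SimulationError(f"generation {g}: {err}") from err
            if frames is not None:
                frames.append(pop.to_frame())
            pop = child
            next_id += pop.size
            row.update(
                realized_beta_o=stats.realized_beta_o,
                realized_beta_dee=stats.realized_beta_dee,
                frac_clamped=stats.frac_clamped,
            )
        else:
            row.update(realized_beta_o=np.nan, realized_beta_dee=np.nan, frac_clamped=np.nan)
            if frames is not None:
                frames.append(pop.to_frame())
        rows.append(row)
    traj = pd.DataFrame(rows)
    traj["delta_z_o"] = traj["mean_z_o"].diff()
    traj["delta_z_dee"] = traj["mean_z_dee"].diff()
    pedigree = pd.concat(frames, ignore_index=True) if frames is not None else None
    return traj[list(TRAJECTORY_COLUMNS)], pedigree


def _window_response(traj: pd.DataFrame, config: SimulationConfig) -> Tuple[float, float]:
    lo, hi = config.response_window
    s = config.burn_in
    sl = traj.iloc[s + lo : s + hi + 1]
    return float(sl["delta_z_o"].mean()), float(sl["delta_z_dee"].mean())


def run(config: SimulationConfig) -> SimulationResult:
    """Simulate all replicates and summarize asymptotic responses.

    The per-replicate asymptotic response is the mean realized per-generation
    change of each trait over ``response_window`` (selection-phase
    generations); the summary reports the across-replicate mean and its
    Monte-Carlo standard error.
    """
    children = np.random.SeedSequence(config.seed).spawn(config.n_replicates)
    outputs = [_run_replicate(config, np.random.default_rng(child)) for child in children]
    trajectories = [t for t, _ in outputs]
    pedigrees = [p for _, p in outputs] if config.keep_pedigree else None
    resp = pd.DataFrame(
        [_window_response(t, config) for t in trajectories],
        columns=["response_zo", "response_zdee"],
    )
    resp.insert(0, "replicate", np.arange(config.n_replicates))
    n = config.n_replicates
    se = resp[["response_zo", "response_zdee"]].std(ddof=1) / math.sqrt(n) if n > 1 else pd.Series(
        {"response_zo": np.nan, "response_zdee": np.nan}
    )
    return SimulationResult(
        config=config,
        trajectories=trajectories,
        responses=resp,
        response_zo_mean=float(resp["response_zo"].mean()),
        response_zo_se=float(se["response_zo"]),
        response_zdee_mean=float(resp["response_zdee"].mean()),
        response_zdee_se=float(se["response_zdee"]),
        pedigrees=pedigrees,
    )


def simulate_pedigree(
    arch: GeneticArchitecture,
    n_families: int,
    seed: int,
    offspring_per_pair: int = 4,
    n_generations: int = 1,
    sel: Optional[SelectionRegime] = None,
) -> pd.DataFrame:
    """Neutral (by default) pedigreed phenotype table for estimation studies.

    Generation 0 holds ``2 * n_families`` founders; each later generation
    holds ``n_families * offspring_per_pair`` offspring from ``n_families``
    distinct monogamous pairs (under neutrality, fitness-weighted and
    uniform sampling coincide, so strict monogamy is used for a clean family
    structure). Returns the concatenated pedigree table of all generations.
    """
    if n_families < 1:
        raise ValueError("n_families must be >= 1")
    sel = sel or SelectionRegime(0.0, 0.0)
    config = SimulationConfig(
        arch=arch,
        sel=sel,
        seed=seed,
        n_per_generation=2 * n_families,
        n_generations=max(n_generations, 1),
        offspring_per_pair=offspring_per_pair,
        monogamous=True,
        burn_in=0,
        response_window=(1, max(n_generations, 1)),
    )
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    pop = init_founders(config, rng)
    next_id = pop.size + 1
    frames = []
    for _ in range(n_generations):
        select(pop, sel, config)
        child = reproduce(
            pop,
            config,
            rng,
            start_id=next_id,
            n_offspring=n_families * offspring_per_pair,
            n_pairs=n_families,
        )
        frames.append(pop.to_frame())
        next_id += child.size
        pop = child
    frames.append(pop.to_frame())
    return pd.concat(frames, ignore_index=True)
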