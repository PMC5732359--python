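"""Scenario grids: responses with effects toggled on (1) or off (0).

Three grids explore how the maternal pathway reshapes the response to
selection, all evaluated on the unit scale (every active parameter set to 1):

- grid 2 — growth-rate response: V_AO = 1 and beta_O = 1 always, with every
  admissible 0/1 combination of V_A(DEE), beta_DEE and Cov(A_O, A_DEE);
- grid 3 — maternal-DEE response: V_A(DEE) = 1 always, with combinations of
  beta_O, beta_DEE, Cov and V_AO;
- grid 4 — a nested progression for both traits: univariate selection on
  each trait alone (no covariance), then multivariate selection, then
  multivariate selection plus a positive covariance, showing how indirect
  selection and co-inheritance act synergistically.

Cells with Cov = 1 but the corresponding variance 0 violate positive
semidefiniteness and are skipped with a logged reason — a covariance cannot
be "present" without variance in both traits. Scenarios can be evaluated
analytically (exact) or by forward simulation at a weak gradient epsilon,
rescaled by 1/epsilon for comparison, since unit gradients would violate the
weak-selection assumption behind the analytic responses.
"""

from __future__ import annotations

import itertools
import logging
import time
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, List, Optional, Sequence

import numpy as np
import pandas as pd

from .model import GeneticArchitecture, SelectionRegime, predict_response
from .simulate import SimulationConfig, run

__all__ = ["Scenario", "build_figure_grids", "run_scenarios", "render"]

logger = logging.getLogger("maternalqg.scenarios")

TABLE_COLUMNS = (
    "figure",
    "label",
    "v_ao",
    "v_adee",
    "cov_a",
    "beta_o",
    "beta_dee",
    "delta_zo",
    "delta_zdee",
    "se_zo",
    "se_zdee",
    "engine",
)

#: Residual variances used by the simulation engine (the analytic responses
#: do not depend on them; phenotypes are given realistic non-genetic noise).
SIM_V_EO = 1.0
SIM_V_EDEE = 1.0


@dataclass(frozen=True)
class Scenario:
    """One toggle combination of the 0/1 grids (free-valued in exploratory use)."""

    label: str
    figure: int
    v_ao: float
    v_adee: float
    cov_a: float
    beta_o: float
    beta_dee: float

    @property
    def complexity(self) -> float:
        return self.v_adee + self.cov_a + self.beta_o + self.beta_dee + self.v_ao

    def architecture(self, v_eo: float = 0.0, v_edee: float = 0.0) -> GeneticArchitecture:
        return GeneticArchitecture(
            v_ao=self.v_ao, v_adee=self.v_adee, cov_a=self.cov_a, v_eo=v_eo, v_edee=v_edee
        )

    def selection(self, epsilon: float = 1.0) -> SelectionRegime:
        return SelectionRegime(self.beta_o * epsilon, self.beta_dee * epsilon)


def _psd_ok(v_ao: float, v_adee: float, cov_a: float) -> bool:
    return cov_a**2 <= v_ao * v_adee + 1e-12


def build_figure_grids(figures: Sequence[int] = (2, 3, 4)) -> List[Scenario]:
    """All admissible scenarios of the requested grids, simplest first."""
    out: List[Scenario] = []
    if 2 in figures:
        for v_adee, beta_dee, cov_a in itertools.product((0, 1), repeat=3):
            if not _psd_ok(1, v_adee, cov_a):
                logger.info(
                    "figure 2: skipping PSD-invalid toggle v_adee=%s cov_a=%s "
                    "(covariance requires maternal genetic variance)",
                    v_adee,
                    cov_a,
                )
                continue
            out.append(
                Scenario(
                    label=f"VA(DEE)={v_adee}, betaDEE={beta_dee}, Cov={cov_a}",
                    figure=2,
                    v_ao=1,
                    v_adee=v_adee,
                    cov_a=cov_a,
                    beta_o=1,
                    beta_dee=beta_dee,
                )
            )
    if 3 in figures:
        for beta_o, beta_dee, cov_a, v_ao in itertools.product((0, 1), repeat=4):
            if not _psd_ok(v_ao, 1, cov_a):
                logger.info(
                    "figure 3: skipping PSD-invalid toggle v_ao=%s cov_a=%s",
                    v_ao,
                    cov_a,
                )
                continue
            out.append(
                Scenario(
                    label=(
                        f"betaO={beta_o}, betaDEE={beta_dee}, Cov={cov_a}, VAO={v_ao}"
                    ),
                    figure=3,
                    v_ao=v_ao,
                    v_adee=1,
                    cov_a=cov_a,
                    beta_o=beta_o,
                    beta_dee=beta_dee,
                )
            )
    if 4 in figures:
        out.extend(
            [
                Scenario("univariate selection on growth", 4, 1, 1, 0, 1, 0),
                Scenario("univariate selection on DEE", 4, 1, 1, 0, 0, 1),
                Scenario("multivariate selection, no covariance", 4, 1, 1, 0, 1, 1),
                Scenario("multivariate selection + covariance", 4, 1, 1, 1, 1, 1),
            ]
        )
    out.sort(key=lambda s: (s.figure, s.complexity, s.label))
    return out


def run_scenarios(
    scenarios: Iterable[Scenario],
    engine: str = "analytic",
    epsilon: float = 0.05,
    n_replicates: int = 200,
    n_per_generation: int = 2000,
    n_generations: int = 30,
    seed: Optional[int] = None,
    v_eo: float = SIM_V_EO,
    v_edee: float = SIM_V_EDEE,
    response_window: Optional[tuple] = None,
) -> pd.DataFrame:
    """Evaluate scenarios and return the comparison table.

    The analytic engine computes the exact per-generation responses; the
    simulation engine runs the forward simulator with gradients scaled by
    ``epsilon`` and rescales the asymptotic responses (and their Monte-Carlo
    standard errors) by 1/epsilon. Scenarios whose parameters violate
    positive semidefiniteness are skipped with a logged reason.
    """
    if engine not in ("analytic", "simulation"):
        raise ValueError(f"engine must be 'analytic' or 'simulation', got {engine!r}")
    if engine == "simulation" and seed is None:
        raise ValueError("the simulation engine requires a seed")
    if response_window is None:
        response_window = (min(11, n_generations), n_generations)

    rows = []
    warned = False
    ss = np.random.SeedSequence(seed) if seed is not None else None
    for sc in scenarios:
        t0 = time.perf_counter()
        try:
            arch = sc.architecture(v_eo=v_eo, v_edee=v_edee)
        except ValueError as err:
            logger.warning("skipping scenario %r: %s", sc.label, err)
            continue
        if engine == "analytic":
            if not warned and abs(arch.var_zo - 1.0) > 1e-9:
                warnings.warn(
                    "scenario phenotypic variances differ from 1 (e.g. "
                    f"var(z_O)={arch.var_zo:g} for {sc.label!r}); gradients "
                    "are interpreted per trait unit, not per realized SD",
                    UserWarning,
                    stacklevel=2,
                )
                warned = True
            pred = predict_response(arch, sc.selection())
            dzo, dzdee, se_zo, se_zdee = pred.delta_zo, pred.delta_zdee, 0.0, 0.0
        else:
            config = SimulationConfig(
                arch=arch,
                sel=sc.selection(epsilon),
                seed=int(np.random.default_rng(ss.spawn(1)[0]).integers(2**31)),
                n_per_generation=n_per_generation,
                n_generations=n_generations,
                n_replicates=n_replicates,
                response_window=response_window,
            )
            res = run(config)
            dzo = res.response_zo_mean / epsilon
            dzdee = res.response_zdee_mean / epsilon
            se_zo = res.response_zo_se / epsilon
            se_zdee = res.response_zdee_se / epsilon
        logger.info(
            "scenario=%r engine=%s seed=%s runtime=%.2fs",
            sc.label,
            engine,
            seed,
            time.perf_counter() - t0,
        )
        rows.append(
            {
                "figure": sc.figure,
                "label": sc.label,
                "v_ao": sc.v_ao,
                "v_adee": sc.v_adee,
                "cov_a": sc.cov_a,
                "beta_o": sc.beta_o,
                "beta_dee": sc.beta_dee,
                "delta_zo": dzo,
                "delta_zdee": dzdee,
                "se_zo": se_zo,
                "se_zdee": se_zdee,
                "engine": engine,
            }
        )
    return pd.DataFrame(rows, columns=list(TABLE_COLUMNS))


def render(
    table: pd.DataFrame,
    out_dir: str | Path,
    formats: Sequence[str] = ("png",),
) -> List[Path]:
    """Write ``scenario_table.tsv`` plus one bar-chart file per format.

    The TSV is the testable artifact (full float precision, byte-stable for
    identical inputs); the figure is a horizontal bar panel per grid,
    scenarios ordered bottom-to-top by increasing complexity as in the
    grids' definition.
    """
    if table.empty:
        raise ValueError("cannot render an empty scenario table")
    allowed = {"png", "svg", "pdf"}
    bad = [f for f in formats if f not in allowed]
    if bad:
        raise ValueError(f"unknown figure format(s) {bad}; choose from {sorted(allowed)}")

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    tsv_path = out_dir / "scenario_table.tsv"
    table.to_csv(tsv_path, sep="\t", index=False, float_format="%.17g")
    paths = [tsv_path]

    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    figures = sorted(table["figure"].unique())
    fig, axes = plt.subplots(
        1, len(figures), figsize=(5.5 * len(figures), 0.45 * len(table) + 2), squeeze=False
    )
    for ax, fignum in zip(axes[0], figures):
        sub = table[table["figure"] == fignum]
        y = np.arange(len(sub))
        ax.barh(y - 0.2, sub["delta_zo"], height=0.4, label=r"$\Delta\bar{z}_O$")
        ax.barh(y + 0.2, sub["delta_zdee"], height=0.4, label=r"$\Delta\bar{z}_{DEE}$")
        if (sub[["se_zo", "se_zdee"]].to_numpy() > 0).any():
            ax.errorbar(sub["delta_zo"], y - 0.2, xerr=sub["se_zo"], fmt="none", ecolor="k")
            ax.errorbar(sub["delta_zdee"], y + 0.2, xerr=sub["se_zdee"], fmt="none", ecolor="k")
        ax.set_yticks(y)
        ax.set_yticklabels(sub["label"], fontsize=8)
        ax.set_xlabel("response per generation (unit-gradient scale)")
        ax.set_title(f"grid {fignum} ({sub['engine'].iloc[0]})")
        ax.legend(fontsize=8)
    fig.tight_layout()
    for fmt in formats:
        p = out_dir / f"scenario_responses.{fmt}"
        fig.savefig(p)
        paths.append(p)
    plt.close(fig)
    return paths
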