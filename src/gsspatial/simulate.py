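"""Synthetic field trials with controlled genotypic, spatial and residual
variance, for testing when spatial modeling improves genomic prediction.

Phenotypes are assembled per plot as

    y = g(genotype) + s(plot) + r(plot)

with genotypic effects i.i.d. standard normal (no relationship matrix:
genotypes are unrelated, so analysis uses an identity kinship on the
labels), spatial effects drawn from a multivariate normal whose
covariance is a chosen correlation kernel on the isotropic plot-distance
matrix, and i.i.d. residuals.  Two ratios control the variance budget:

* ``genotypic_ratio`` (h): share of genotypic variance in total
  phenotypic variance.  With sigma2_g = 1 the total error variance is
  sigma2_e = (1 - h) / h.
* ``fra_sp``: share of the error variance that is spatial,
  sigma2_s = fra_sp * sigma2_e and sigma2_r = (1 - fra_sp) * sigma2_e.
  ``fra_sp = 0`` is allowed and means no spatial effect (null trials).

The default layout emulates a large single-site screening trial: 829
genotypes of which 11 are replicated checks, planted on a regular grid of
2 m x 1 m plots, test genotypes unreplicated (``checks_only``), half
replicated, or all replicated twice.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .kernels import GenomicKinship, distance_matrix, spatial_correlation
from .reml import ModelSpec, SolverOptions, fit_reml
from .trial import PlotDimension, TrialTable

__all__ = [
    "SimulationConfig",
    "SimulatedTrial",
    "REPLICATION_SCENARIOS",
    "default_layout",
    "apply_replication",
    "simulate_trial",
    "evaluate_models",
    "run_grid",
]

REPLICATION_SCENARIOS = ("checks_only", "half_replicated", "fully_replicated")

#: default plot footprint for simulated fields: 2 m along Columns, 1 m
#: along Ranges, so adjacent Ranges are closer than adjacent Columns
SIM_PLOT_DIM = PlotDimension(length_m=2.0, width_m=1.0)


@dataclass(frozen=True)
class SimulationConfig:
    """Generator settings for one simulated trial."""

    genotypic_ratio: float
    fra_sp: float
    kernel_family: str
    kernel_param: float
    replication: str = "checks_only"
    seed: int = 0
    plot_dim: PlotDimension = SIM_PLOT_DIM

    def __post_init__(self) -> None:
        if not 0.0 < self.genotypic_ratio < 1.0:
            raise ValueError("genotypic_ratio must be in (0, 1)")
        if not 0.0 <= self.fra_sp < 1.0:
            raise ValueError("fra_sp must be in [0, 1)")
        if self.replication not in REPLICATION_SCENARIOS:
            raise ValueError(f"replication must be one of {REPLICATION_SCENARIOS}")

    @property
    def variances(self) -> dict[str, float]:
        """True (sigma2_g, sigma2_s, sigma2_r) implied by the ratios."""
        h = self.genotypic_ratio
        sigma2_e = (1.0 - h) / h
        return {
            "g": 1.0,
            "s": self.fra_sp * sigma2_e,
            "r": (1.0 - self.fra_sp) * sigma2_e,
        }


@dataclass
class SimulatedTrial:
    """A simulated phenotype table carrying its true effect vectors."""

    phenotypes: TrialTable
    true_g: pd.Series
    true_s: np.ndarray
    true_r: np.ndarray
    config: SimulationConfig

    @property
    def trait(self) -> str:
        return self.phenotypes.traits[0]


def default_layout(n_genotypes: int = 829, n_checks: int = 11,
                   check_reps: int = 6, n_cols: int = 22) -> TrialTable:
    """Regular-grid layout: unreplicated test genotypes plus replicated
    checks spread evenly through the planting order.

    This is a synthetic stand-in for a real single-site trial layout:
    ``n_genotypes`` labels of which ``n_checks`` are checks planted
    ``check_reps`` times each, filled row-major onto a grid ``n_cols``
    Columns wide.
    """
    if n_checks >= n_genotypes:
        raise ValueError("need fewer checks than genotypes")
    checks = [f"check{i + 1:02d}" for i in range(n_checks)]
    tests = [f"g{i + 1:04d}" for i in range(n_genotypes - n_checks)]
    n_plots = len(tests) + n_checks * check_reps

    # spread check plots evenly across the planting sequence
    check_positions = np.linspace(0, n_plots - 1, n_checks * check_reps).astype(int)
    check_labels = [checks[i % n_checks] for i in range(n_checks * check_reps)]
    sequence: list[tuple[str, bool]] = []
    it_test = iter(tests)
    pos_to_check = dict(zip(check_positions, check_labels))
    for p in range(n_plots):
        if p in pos_to_check:
            sequence.append((pos_to_check[p], True))
        else:
            sequence.append((next(it_test), False))

    rows = []
    for p, (geno, is_check) in enumerate(sequence):
        rng_idx, col_idx = divmod(p, n_cols)
        rows.append(
            {
                "plot_id": f"P{p + 1:04d}",
                "range_idx": rng_idx + 1,
                "col_idx": col_idx + 1,
                "genotype": geno,
                "is_check": is_check,
            }
        )
    return TrialTable(pd.DataFrame(rows))


def apply_replication(layout: TrialTable, scenario: str, seed: int = 0) -> TrialTable:
    """Add replicate plots for test genotypes on extended grid rows.

    ``checks_only`` leaves the layout unchanged; ``half_replicated``
    duplicates a seeded random half of the test genotypes once;
    ``fully_replicated`` duplicates every test genotype once.
    """
    if scenario not in REPLICATION_SCENARIOS:
        raise ValueError(f"replication must be one of {REPLICATION_SCENARIOS}")
    if scenario == "checks_only":
        return layout
    df = layout.data
    tests = df.loc[~df["is_check"], "genotype"].unique()
    if scenario == "half_replicated":
        rng = np.random.default_rng(seed)
        tests = np.sort(rng.choice(tests, size=len(tests) // 2, replace=False))
    n_cols = int(df["col_idx"].max())
    start = int(df["range_idx"].max()) * n_cols  # continue the row-major fill
    rows = []
    for i, geno in enumerate(tests):
        p = start + i
        rng_idx, col_idx = divmod(p, n_cols)
        rows.append(
            {
                "plot_id": f"P{p + 1:04d}",
                "range_idx": rng_idx + 1,
                "col_idx": col_idx + 1,
                "genotype": geno,
                "is_check": False,
            }
        )
    return TrialTable(pd.concat([df, pd.DataFrame(rows)], ignore_index=True))


def simulate_trial(cfg: SimulationConfig, layout: TrialTable | None = None) -> SimulatedTrial:
    """Draw one phenotype vector on a layout under ``cfg``.

    Spatial effects are drawn on the (possibly replication-extended)
    layout's own isotropic distance matrix.
    """
    rng = np.random.default_rng(cfg.seed)
    if layout is None:
        layout = default_layout()
    layout = apply_replication(layout, cfg.replication, seed=cfg.seed)
    var = cfg.variances
    genotypes = layout.genotypes
    g_eff = pd.Series(rng.normal(0.0, 1.0, len(genotypes)), index=genotypes)
    n = layout.n_plots
    if var["s"] > 0:
        d = distance_matrix(layout, cfg.plot_dim, "isotropic")
        kernel = spatial_correlation(d, cfg.kernel_family, cfg.kernel_param)
        try:
            chol = np.linalg.cholesky(
                kernel.matrix + 1e-10 * np.eye(n)
            )
        except np.linalg.LinAlgError as e:
            raise ValueError(f"spatial kernel not positive definite: {e}")
        s_eff = np.sqrt(var["s"]) * (chol @ rng.standard_normal(n))
    else:
        s_eff = np.zeros(n)
    r_eff = rng.normal(0.0, np.sqrt(var["r"]), n) if var["r"] > 0 else np.zeros(n)

    df = layout.data.copy()
    df["y"] = g_eff.loc[df["genotype"]].to_numpy() + s_eff + r_eff
    return SimulatedTrial(TrialTable(df, ["y"]), g_eff, s_eff, r_eff, cfg)


def evaluate_models(sim: SimulatedTrial, candidates: list[ModelSpec],
                    opts: SolverOptions | None = None) -> pd.DataFrame:
    """Fit candidates on all plots and score recovery of the true
    genotypic effects.

    Per candidate the table reports RMSE and correlation between true and
    estimated genotypic effects, the estimated variance components, and a
    convergence flag; the converged fit with (lowest RMSE, highest
    correlation) is marked best.
    """
    if not any(c.spatial is None and not (c.range_effect or c.column_effect)
               for c in candidates):
        raise ValueError("candidate list must include a base (no-spatial) model")
    t = sim.phenotypes
    truth = sim.true_g
    rows = []
    for spec in candidates:
        rec = {"model": spec.name, "family": spec.spatial.family if spec.spatial else "",
               "param": spec.spatial.param if spec.spatial else np.nan}
        try:
            fit = fit_reml(t, spec, opts)
            g_hat = fit.blup_g.loc[truth.index].to_numpy()
            tg = truth.to_numpy()
            rec.update(
                rmse_g=float(np.sqrt(np.mean((tg - g_hat) ** 2))),
                cor_g=float(np.corrcoef(tg, g_hat)[0, 1]),
                sigma2_g_hat=fit.varcomps.get("g", np.nan),
                sigma2_s_hat=fit.varcomps.get("s", np.nan),
                sigma2_r_hat=fit.varcomps.get("r", np.nan),
                converged=fit.converged,
            )
        except Exception as e:
            rec.update(rmse_g=np.nan, cor_g=np.nan, sigma2_g_hat=np.nan,
                       sigma2_s_hat=np.nan, sigma2_r_hat=np.nan, converged=False)
            rec["error"] = str(e)
        rows.append(rec)
    out = pd.DataFrame(rows)
    ok = out["converged"].fillna(False).astype(bool)
    out["best"] = False
    if ok.any():
        ranked = out.loc[ok].sort_values(["rmse_g", "cor_g"],
                                         ascending=[True, False])
        out.loc[ranked.index[0], "best"] = True
    return out


def _analysis_candidates(sim: SimulatedTrial, analysis_params: dict) -> list[ModelSpec]:
    layout = sim.phenotypes
    kinship = GenomicKinship.identity(layout.genotypes)
    trait = sim.trait
    specs = [ModelSpec(trait, kinship)]
    d = distance_matrix(layout, sim.config.plot_dim, "isotropic")
    for family, params in analysis_params.items():
        for p in params:
            specs.append(
                ModelSpec(trait, kinship,
                          spatial=spatial_correlation(d, family, p))
            )
    return specs


def run_grid(h_grid, fra_grid, kernel_grid, scenarios=("checks_only",),
             n_seeds: int = 20, master_seed: int = 20170307,
             layout: TrialTable | None = None,
             analysis_params: dict | None = None,
             opts: SolverOptions | None = None) -> pd.DataFrame:
    """Run the full simulation grid and return a long-format table.

    The Cartesian product of (kernel family, true parameter) x h x fra_sp
    x replication scenario is executed ``n_seeds`` times per cell with
    per-cell seeds derived from ``master_seed``.  Each fitted candidate
    contributes one row.  By default the analysis candidates are the base
    model plus the matched kernel (the family and parameter that
    generated the data); pass ``analysis_params`` (family -> parameter
    list) to analyze with other kernels, e.g. to measure the cost of a
    mismatched family.
    """
    rows = []
    base_layout = layout if layout is not None else default_layout()
    cells = [
        (fam, par, h, fra, scen)
        for fam, par in kernel_grid
        for h in h_grid
        for fra in fra_grid
        for scen in scenarios
    ]
    ss = np.random.SeedSequence(master_seed)
    cell_seeds = ss.generate_state(len(cells) * n_seeds).reshape(len(cells), n_seeds)
    for (cell_i, (fam, par, h, fra, scen)) in enumerate(cells):
        for s_i in range(n_seeds):
            seed = int(cell_seeds[cell_i, s_i] % (2 ** 31))
            cfg = SimulationConfig(
                genotypic_ratio=h, fra_sp=fra, kernel_family=fam,
                kernel_param=par, replication=scen, seed=seed,
            )
            sim = simulate_trial(cfg, base_layout)
            params = analysis_params if analysis_params is not None else {fam: [par]}
            table = evaluate_models(sim, _analysis_candidates(sim, params), opts)
            table.insert(0, "kernel_family_true", fam)
            table.insert(1, "param_true", par)
            table.insert(2, "h", h)
            table.insert(3, "fra_sp", fra)
            table.insert(4, "scenario", scen)
            table.insert(5, "seed", seed)
            rows.append(table)
    return pd.concat(rows, ignore_index=True)
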