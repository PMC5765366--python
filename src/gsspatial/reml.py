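"""REML fitting of genomic-selection mixed models with spatial kernels.

The model for a vector of plot phenotypes y is

    y = mu * 1 + Z g + s + Z2 ra + Z3 cl + r

with g ~ N(0, K sg2) the genotypic effects (K a genomic relationship
matrix over all genotypes, observed or not), s ~ N(0, S ss2) the
plot-level spatial effects (S a spatial correlation kernel), optional
random Range and Column effects ra ~ N(0, I sra2), cl ~ N(0, I scl2)
capturing extraneous (operational) variation, and r ~ N(0, I sr2) the
residual.  "Base" is the model with only g and r; "Model 1" adds s;
"Model 2" adds Range/Column effects.

Variance components are estimated by maximizing the restricted
log-likelihood with Fisher scoring (expected-information updates, step
halving, nonnegativity by projection with boundary detection).  BLUPs,
prediction-error variances and held-out predictions come from the
mixed-model equations at the REML estimates.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg
from scipy.stats import chi2

from .kernels import GenomicKinship, SpatialKernel
from .trial import TrialTable

__all__ = [
    "ModelSpec",
    "FitResult",
    "LRTResult",
    "SolverOptions",
    "fit_reml",
    "restricted_loglik",
    "lrt",
    "cullis_h2",
    "predict_heldout",
]

_LOG2PI = math.log(2.0 * math.pi)


@dataclass(frozen=True)
class SolverOptions:
    """Fisher-scoring settings.

    ``tol`` is the convergence threshold on the change in restricted
    log-likelihood.  Components proposed negative are projected to
    ``floor_frac`` times the phenotypic variance; a floored component
    stays out of the update (active-set) while its score is nonpositive
    and is reported as a boundary zero if still floored at convergence.
    """

    max_iter: int = 100
    tol: float = 1e-6
    floor_frac: float = 1e-9
    max_halvings: int = 30


@dataclass
class ModelSpec:
    """Which variance components enter the model for one trait."""

    trait: str
    genomic: GenomicKinship
    spatial: SpatialKernel | None = None
    range_effect: bool = False
    column_effect: bool = False

    @property
    def component_names(self) -> list[str]:
        names = ["g"]
        if self.spatial is not None:
            names.append("s")
        if self.range_effect:
            names.append("ra")
        if self.column_effect:
            names.append("cl")
        names.append("r")
        return names

    @property
    def name(self) -> str:
        if self.spatial is None and not (self.range_effect or self.column_effect):
            return "Base"
        parts = []
        if self.spatial is not None:
            parts.append(self.spatial.label)
        if self.range_effect:
            parts.append("Range")
        if self.column_effect:
            parts.append("Column")
        kind = "Model2" if (self.range_effect or self.column_effect) else "Model1"
        return f"{kind}[{' + '.join(parts)}]"


@dataclass
class FitResult:
    """REML estimates, BLUPs and diagnostics for one model fit."""

    spec: ModelSpec
    mu_hat: float
    varcomps: dict[str, float]
    boundary: dict[str, bool]
    restricted_loglik: float
    converged: bool
    n_iter: int
    n_obs: int
    blup_g: pd.Series
    blup_s: pd.Series | None
    blup_ra: pd.Series | None
    blup_cl: pd.Series | None
    _Py: np.ndarray = field(repr=False)
    _P: np.ndarray = field(repr=False)
    _train_plot_ids: np.ndarray = field(repr=False)
    _geno_idx: np.ndarray = field(repr=False)
    _sigma_int: dict[str, float] = field(default_factory=dict, repr=False)
    _pev_g: np.ndarray | None = field(default=None, repr=False)

    @property
    def residuals(self) -> np.ndarray:
        """Estimated residuals r_hat on the training plots."""
        return self._sigma_int.get("r", self.varcomps["r"]) * self._Py

    @property
    def fitted(self) -> np.ndarray:
        """mu + all effect BLUPs per training plot (reproduces y exactly)."""
        out = np.full(self.n_obs, self.mu_hat)
        geno = self.spec.genomic.genotypes[self._geno_idx]
        out += self.blup_g.loc[geno].to_numpy()
        if self.blup_s is not None:
            out += self.blup_s.loc[self._train_plot_ids].to_numpy()
        return out

    @property
    def pev_g(self) -> np.ndarray:
        """Prediction-error variance matrix of the genotypic BLUPs."""
        if self._pev_g is None:
            k = self.spec.genomic.matrix
            sg = self.varcomps["g"]
            kz = k[:, self._geno_idx]
            self._pev_g = sg * k - sg ** 2 * (kz @ self._P @ kz.T)
        return self._pev_g

    def summary(self) -> str:
        lines = [
            f"model: {self.spec.name}",
            f"trait: {self.spec.trait}",
            f"n_obs: {self.n_obs}",
            f"converged: {self.converged} ({self.n_iter} iterations)",
            f"restricted log-likelihood: {self.restricted_loglik:.4f}",
            f"mu_hat: {self.mu_hat:.6g}",
        ]
        for k, v in self.varcomps.items():
            tag = " (boundary)" if self.boundary.get(k) else ""
            lines.append(f"sigma2_{k}: {v:.6g}{tag}")
        return "\n".join(lines)


@dataclass
class LRTResult:
    """Likelihood-ratio comparison of nested variance-component models."""

    statistic: float
    df: int
    threshold: float
    significant: bool
    p_value: float


def _component_matrices(t: TrialTable, spec: ModelSpec):
    """Per-component n x n covariance structures and index maps."""
    geno_idx = spec.genomic.index_of(t.data["genotype"])
    comps: dict[str, np.ndarray] = {
        "g": spec.genomic.matrix[np.ix_(geno_idx, geno_idx)]
    }
    if spec.spatial is not None:
        pos = _plot_positions(spec.spatial, t.plot_ids)
        comps["s"] = spec.spatial.matrix[np.ix_(pos, pos)]
    if spec.range_effect:
        r = t.data["range_idx"].to_numpy()
        comps["ra"] = (r[:, None] == r[None, :]).astype(float)
    if spec.column_effect:
        c = t.data["col_idx"].to_numpy()
        comps["cl"] = (c[:, None] == c[None, :]).astype(float)
    comps["r"] = np.eye(t.n_plots)
    return comps, geno_idx


def _plot_positions(kernel: SpatialKernel, plot_ids: np.ndarray) -> np.ndarray:
    lookup = {p: i for i, p in enumerate(kernel.plot_ids)}
    try:
        return np.array([lookup[p] for p in plot_ids], dtype=int)
    except KeyError as e:
        raise KeyError(f"plot {e.args[0]!r} absent from spatial kernel") from None


def _profile(y: np.ndarray, v: np.ndarray):
    """Restricted log-likelihood pieces at fixed V (intercept-only X)."""
    n = len(y)
    try:
        cho = linalg.cho_factor(v, lower=True, check_finite=False)
    except linalg.LinAlgError as e:
        raise linalg.LinAlgError(f"covariance matrix not positive definite: {e}")
    logdet = 2.0 * float(np.sum(np.log(np.diag(cho[0]))))
    vinv = linalg.cho_solve(cho, np.eye(n), check_finite=False)
    u = vinv.sum(axis=1)              # V^-1 1
    c = float(u.sum())                # 1' V^-1 1
    if c <= 0:
        raise linalg.LinAlgError("singular coefficient matrix (1'V^-1 1 <= 0)")
    p = vinv - np.outer(u, u) / c
    py = p @ y
    llk = -0.5 * (logdet + math.log(c) + float(y @ py) + (n - 1) * _LOG2PI)
    mu = float(u @ y) / c
    return llk, mu, p, py


def restricted_loglik(t: TrialTable, spec: ModelSpec, varcomps: dict[str, float]) -> float:
    """Restricted log-likelihood at fixed variance components."""
    names = spec.component_names
    missing = [k for k in names if k not in varcomps]
    if missing:
        raise KeyError(f"missing variance components: {missing}")
    vals = np.array([float(varcomps[k]) for k in names])
    if (vals < 0).any():
        raise ValueError("variance components must be nonnegative")
    if not (vals > 0).any():
        raise ValueError("all variance components are zero")
    comps, _ = _component_matrices(t, spec)
    y = t.values(spec.trait)
    if not np.isfinite(y).all():
        raise ValueError(f"trait {spec.trait!r} has missing values; drop them first")
    v = sum(s * comps[k] for k, s in zip(names, vals))
    llk, *_ = _profile(y, v)
    return llk


def fit_reml(t: TrialTable, spec: ModelSpec, opts: SolverOptions | None = None) -> FitResult:
    """Fit a model by REML (Fisher scoring on the variance components)."""
    opts = opts or SolverOptions()
    names = spec.component_names
    comps, geno_idx = _component_matrices(t, spec)
    y = t.values(spec.trait)
    if not np.isfinite(y).all():
        raise ValueError(f"trait {spec.trait!r} has missing values; drop them first")
    n = len(y)
    if n < len(names) + 1:
        raise ValueError(f"{n} observations cannot support {len(names)} components")
    vary = float(np.var(y, ddof=1)) if n > 1 else 0.0
    if vary < 1e-30:
        return _degenerate_fit(t, spec, y, geno_idx)
    floor = opts.floor_frac * vary

    mats = [comps[k] for k in names]
    m = len(names)
    sigma = np.full(m, vary / m)

    def build_v(sig):
        v = sig[0] * mats[0]
        for k in range(1, m):
            v = v + sig[k] * mats[k]
        return v

    llk, mu, p, py = _profile(y, build_v(sigma))
    converged = False
    it = 0
    for it in range(1, opts.max_iter + 1):
        # score for every component; a floored component re-enters the
        # update only if increasing it would raise the likelihood
        a = [p @ mats[k] if names[k] != "r" else p for k in range(m)]
        score_all = np.array(
            [-0.5 * (np.trace(a[k]) - float(py @ (mats[k] @ py)))
             for k in range(m)]
        )
        at_floor = sigma <= floor * (1 + 1e-12)
        free = np.where(~at_floor | (score_all > 0))[0]
        if free.size == 0:
            converged = True
            break
        info = np.empty((free.size, free.size))
        for i, ki in enumerate(free):
            for j, kj in enumerate(free[i:], start=i):
                info[i, j] = info[j, i] = 0.5 * float(np.sum(a[ki] * a[kj].T))
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", linalg.LinAlgWarning)
                delta = linalg.solve(info, score_all[free], assume_a="pos")
        except linalg.LinAlgError:
            delta = np.linalg.lstsq(info, score_all[free], rcond=None)[0]

        # step halving until the restricted likelihood does not decrease
        step = 1.0
        accepted = False
        for _ in range(opts.max_halvings):
            cand = sigma.copy()
            cand[free] = np.maximum(sigma[free] + step * delta, floor)
            try:
                llk_new, mu_new, p_new, py_new = _profile(y, build_v(cand))
            except linalg.LinAlgError:
                step *= 0.5
                continue
            if llk_new >= llk - 1e-12:
                accepted = True
                break
            step *= 0.5
        if not accepted:
            converged = True  # no uphill step exists at working precision
            break
        dllk = llk_new - llk
        sigma, llk, mu, p, py = cand, llk_new, mu_new, p_new, py_new
        if abs(dllk) < opts.tol:
            converged = True
            break

    boundary = {k: bool(sigma[i] <= floor * (1 + 1e-12)) for i, k in enumerate(names)}
    reported = {
        k: (0.0 if boundary[k] else float(sigma[i])) for i, k in enumerate(names)
    }
    return _assemble(t, spec, y, geno_idx, mu, sigma, reported, boundary,
                     llk, converged, it, p, py)


def _degenerate_fit(t, spec, y, geno_idx) -> FitResult:
    """Constant response: every variance component is zero."""
    n = len(y)
    names = spec.component_names
    zero = {k: 0.0 for k in names}
    bnd = {k: True for k in names}
    return _assemble(t, spec, y, geno_idx, float(y[0]), np.zeros(len(names)),
                     zero, bnd, math.nan, True, 0, np.zeros((n, n)), np.zeros(n))


def _assemble(t, spec, y, geno_idx, mu, sigma_int, reported, boundary,
              llk, converged, n_iter, p, py) -> FitResult:
    names = spec.component_names
    sig = dict(zip(names, [float(s) for s in sigma_int]))
    k = spec.genomic.matrix
    blup_g = pd.Series(sig["g"] * (k[:, geno_idx] @ py), index=spec.genomic.genotypes)
    blup_s = None
    if spec.spatial is not None:
        pos = _plot_positions(spec.spatial, t.plot_ids)
        s_sub = spec.spatial.matrix[np.ix_(pos, pos)]
        blup_s = pd.Series(sig["s"] * (s_sub @ py), index=t.plot_ids)
    blup_ra = blup_cl = None
    if spec.range_effect:
        r = t.data["range_idx"].to_numpy()
        levels = np.unique(r)
        z2 = (r[:, None] == levels[None, :]).astype(float)
        blup_ra = pd.Series(sig["ra"] * (z2.T @ py), index=levels)
    if spec.column_effect:
        c = t.data["col_idx"].to_numpy()
        levels = np.unique(c)
        z3 = (c[:, None] == levels[None, :]).astype(float)
        blup_cl = pd.Series(sig["cl"] * (z3.T @ py), index=levels)
    return FitResult(
        spec=spec, mu_hat=mu, varcomps=reported, boundary=boundary,
        restricted_loglik=llk, converged=converged, n_iter=n_iter,
        n_obs=len(y), blup_g=blup_g, blup_s=blup_s, blup_ra=blup_ra,
        blup_cl=blup_cl, _Py=py, _P=p, _train_plot_ids=t.plot_ids.copy(),
        _geno_idx=geno_idx, _sigma_int=sig,
    )


def lrt(model: FitResult, base: FitResult, extra_df: int, alpha: float = 0.1) -> LRTResult:
    """Likelihood-ratio test for the extra variance component(s).

    The statistic is twice the gain in restricted log-likelihood, floored
    at zero.  Because the null value lies on the boundary of the parameter
    space the statistic follows a 1/2 chi2(0) : 1/2 chi2(df) mixture; the
    p-value reported uses that mixture.  The significance decision uses
    the plain upper-alpha chi2(df) quantile as threshold (2.706 for one
    added component at alpha = 0.1, 4.605 for two), the conservative
    convention common in field-trial analysis.
    """
    if model.n_obs != base.n_obs:
        raise ValueError(
            f"fits have different numbers of observations "
            f"({model.n_obs} vs {base.n_obs})"
        )
    if extra_df < 1:
        raise ValueError("extra_df must be >= 1")
    stat = max(0.0, 2.0 * (model.restricted_loglik - base.restricted_loglik))
    threshold = float(chi2.ppf(1.0 - alpha, extra_df))
    p_value = 1.0 if stat == 0.0 else 0.5 * float(chi2.sf(stat, extra_df))
    return LRTResult(stat, extra_df, threshold, stat > threshold, p_value)


def cullis_h2(fit: FitResult) -> float:
    """Generalized (Cullis) heritability h2 = 1 - mean(PEV of BLUP
    differences) / (2 sigma2_g), valid for unbalanced designs.

    Returns NaN with a warning when the genotypic variance is zero.  The
    value is reported unclamped; values outside [0, 1] trigger a warning.
    """
    sg = fit.varcomps["g"]
    if sg <= 0:
        warnings.warn("genotypic variance is zero; heritability undefined")
        return math.nan
    pev = fit.pev_g
    g = pev.shape[0]
    if g < 2:
        raise ValueError("need at least two genotypes for heritability")
    tr = float(np.trace(pev))
    total = float(pev.sum())
    vbar_delta = 2.0 * (g * tr - total) / (g * (g - 1))
    h2 = 1.0 - vbar_delta / (2.0 * sg)
    if not 0.0 <= h2 <= 1.0:
        warnings.warn(f"Cullis heritability {h2:.3f} outside [0, 1]")
    return h2


def predict_heldout(fit: FitResult, test: TrialTable) -> np.ndarray:
    """Predict held-out plots: Y_hat = mu + g_hat(genotype) + s_hat(plot).

    g_hat for genotypes never observed in training flows from the genomic
    relationship matrix; s_hat at held-out locations is the joint BLUP
    (kriging) given the training observations,
    ``ss2 * S(test, train) @ V(train)^-1 (y - mu 1)``.  Models without a
    spatial component omit s_hat; Range/Column effect BLUPs are carried
    over for levels seen in training (zero for unseen levels).
    """
    spec = fit.spec
    geno = test.data["genotype"].to_numpy()
    spec.genomic.index_of(geno)  # hard error if any genotype absent from K
    pred = fit.mu_hat + fit.blup_g.loc[geno].to_numpy()
    if spec.spatial is not None and fit.varcomps["s"] > 0:
        test_pos = _plot_positions(spec.spatial, test.plot_ids)
        train_pos = _plot_positions(spec.spatial, fit._train_plot_ids)
        s_cross = spec.spatial.matrix[np.ix_(test_pos, train_pos)]
        pred = pred + fit.varcomps["s"] * (s_cross @ fit._Py)
    if fit.blup_ra is not None:
        ra = fit.blup_ra.reindex(test.data["range_idx"]).fillna(0.0)
        pred = pred + ra.to_numpy()
    if fit.blup_cl is not None:
        cl = fit.blup_cl.reindex(test.data["col_idx"]).fillna(0.0)
        pred = pred + cl.to_numpy()
    return pred
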