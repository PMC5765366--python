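"""Exploratory spatial-model selection by repeated cross-validation.

Candidate models combine a spatial kernel family (power / gaussian /
spherical), a correlation direction (isotropic / range / column) and a
standardizing parameter from a grid.  Each candidate is compared to the
no-spatial base model on the same cross-validation plan: genotypes (not
plots) are split into folds so that training and test sets never share a
genotype, and held-out plots are predicted as mu + g_hat + s_hat.  The
winner is the candidate with the lowest prediction RMSE; prediction
correlation (accuracy) is reported alongside.  Random Range/Column
effects (extraneous variation) are then offered as an extension of the
winner.
"""

from __future__ import annotations

import hashlib
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .kernels import (
    DIRECTIONS,
    FAMILIES,
    GenomicKinship,
    distance_matrix,
    parameter_grid,
    spatial_correlation,
)
from .reml import (
    FitResult,
    LRTResult,
    ModelSpec,
    SolverOptions,
    fit_reml,
    lrt,
    predict_heldout,
)
from .trial import PlotDimension, TrialTable

__all__ = [
    "CVPlan",
    "CVResult",
    "SelectionReport",
    "DEFAULT_SEED",
    "make_folds",
    "cross_validate",
    "relative_metrics",
    "search_model1",
    "extend_model2",
]

log = logging.getLogger(__name__)

DEFAULT_SEED = 20170307


@dataclass(frozen=True)
class CVPlan:
    """Genotype-to-fold assignments for repeated k-fold CV."""

    n_folds: int
    n_repeats: int
    seed: int
    assignments: tuple[dict, ...]  # per repeat: genotype -> fold

    def folds(self, repeat: int):
        """Yield (fold index, frozenset of genotypes) for one repeat."""
        a = self.assignments[repeat]
        for f in range(self.n_folds):
            yield f, frozenset(g for g, ff in a.items() if ff == f)

    @property
    def plan_hash(self) -> str:
        h = hashlib.sha256()
        for a in self.assignments:
            for g in sorted(a, key=str):
                h.update(f"{g}:{a[g]};".encode())
        return h.hexdigest()[:16]


@dataclass
class CVResult:
    """Mean predictability of one model under a CV plan."""

    model: ModelSpec
    pRMSE: float
    pCOR: float
    per_fold: pd.DataFrame
    n_failed_fits: int
    plan_hash: str


@dataclass
class SelectionReport:
    """Outcome of a model search against the base model."""

    base: CVResult
    candidates: list[CVResult]
    best: ModelSpec
    best_cv: CVResult
    rel_pcor_increase: float
    rel_prmse_decrease: float
    lrt: LRTResult | None
    best_fit: FitResult | None = None
    base_fit: FitResult | None = None
    notes: list[str] = field(default_factory=list)

    def table(self) -> pd.DataFrame:
        rows = []
        for cv in [self.base] + self.candidates:
            sp = cv.model.spatial
            rows.append(
                {
                    "model": cv.model.name,
                    "family": sp.family if sp else "",
                    "direction": sp.direction if sp else "",
                    "param": sp.param if sp else np.nan,
                    "range_effect": cv.model.range_effect,
                    "column_effect": cv.model.column_effect,
                    "pRMSE": cv.pRMSE,
                    "pCOR": cv.pCOR,
                    "n_failed_fits": cv.n_failed_fits,
                }
            )
        return pd.DataFrame(rows)


def make_folds(genotypes, k: int = 10, repeats: int = 5,
               seed: int = DEFAULT_SEED) -> CVPlan:
    """Randomly partition genotypes into k near-equal folds, per repeat."""
    genotypes = list(dict.fromkeys(genotypes))  # preserve order, unique
    if k < 2:
        raise ValueError("need at least two folds")
    if len(genotypes) < k:
        raise ValueError(f"{len(genotypes)} genotypes cannot fill {k} folds")
    rng = np.random.default_rng(seed)
    assignments = []
    for _ in range(repeats):
        perm = rng.permutation(len(genotypes))
        folds = np.array_split(perm, k)
        a = {}
        for f, idx in enumerate(folds):
            for i in idx:
                a[genotypes[i]] = f
        assignments.append(a)
    return CVPlan(k, repeats, seed, tuple(assignments))


def _pearson(obs: np.ndarray, pred: np.ndarray) -> float:
    if np.std(obs) == 0 or np.std(pred) == 0:
        warnings.warn("degenerate fold: zero-variance observations or "
                      "predictions; correlation recorded as 0")
        return 0.0
    return float(np.corrcoef(obs, pred)[0, 1])


def cross_validate(t: TrialTable, spec: ModelSpec, plan: CVPlan,
                   opts: SolverOptions | None = None) -> CVResult:
    """Genotype-level repeated CV of one model.

    Fold fits that fail (solver error or non-convergence) are skipped and
    counted; an error is raised if more than half of all fold fits fail.
    """
    geno = t.data["genotype"].to_numpy()
    records, n_failed = [], 0
    for rep in range(plan.n_repeats):
        for f, fold_genos in plan.folds(rep):
            test_mask = np.isin(geno, list(fold_genos))
            if not test_mask.any():
                continue
            try:
                fit = fit_reml(t.subset(~test_mask), spec, opts)
                if not fit.converged:
                    raise RuntimeError("fold fit did not converge")
                test = t.subset(test_mask)
                pred = predict_heldout(fit, test)
            except Exception as e:  # trapped, counted, reported
                log.warning("fold fit failed (%s, repeat %d fold %d): %s",
                            spec.name, rep, f, e)
                n_failed += 1
                continue
            obs = test.values(spec.trait)
            records.append(
                {
                    "repeat": rep,
                    "fold": f,
                    "pRMSE": float(np.sqrt(np.mean((obs - pred) ** 2))),
                    "pCOR": _pearson(obs, pred),
                }
            )
    total = plan.n_repeats * plan.n_folds
    if n_failed > total / 2:
        raise RuntimeError(
            f"{n_failed}/{total} fold fits failed for model {spec.name}"
        )
    per_fold = pd.DataFrame(records)
    return CVResult(
        model=spec,
        pRMSE=float(per_fold["pRMSE"].mean()),
        pCOR=float(per_fold["pCOR"].mean()),
        per_fold=per_fold,
        n_failed_fits=n_failed,
        plan_hash=plan.plan_hash,
    )


def relative_metrics(base: CVResult, model: CVResult) -> tuple[float, float]:
    """Relative accuracy gain and error reduction, in percent.

    ``rel_pcor_increase = 100 * (pCOR_m - pCOR_b) / (1 - pCOR_b)`` and
    ``rel_prmse_decrease = 100 * (pRMSE_b - pRMSE_m) / pRMSE_b``.
    """
    if base.pCOR >= 1.0:
        raise ValueError("base accuracy is 1; relative increase undefined")
    if base.pRMSE == 0.0:
        raise ValueError("base pRMSE is 0; relative decrease undefined")
    rel_pcor = 100.0 * (model.pCOR - base.pCOR) / (1.0 - base.pCOR)
    rel_prmse = 100.0 * (base.pRMSE - model.pRMSE) / base.pRMSE
    return rel_pcor, rel_prmse


def _candidate_specs(t, kinship, dim, trait, families, directions, grids):
    specs = []
    for direction in directions:
        d = distance_matrix(t, dim, direction)
        for family in families:
            user = None if grids is None else grids.get(family)
            for param in parameter_grid(family, d, grid=user):
                try:
                    kernel = spatial_correlation(d, family, param)
                except ValueError:
                    continue
                specs.append(ModelSpec(trait, kinship, spatial=kernel))
    return specs


#: relative tolerance below which two CV metrics count as tied; candidates
#: whose extra component is pinned at zero predict identically to the
#: reference up to solver noise, and must lose the tie to it
_TIE_RTOL = 1e-6


def _pick_best(base_cv: CVResult, cand_cvs: list[CVResult]) -> CVResult:
    """Lowest pRMSE; ties broken by higher pCOR, then the reference
    (base) model, then the smaller standardizing parameter."""
    pool = [base_cv] + cand_cvs
    best_rmse = min(cv.pRMSE for cv in pool)
    tol = _TIE_RTOL * max(abs(best_rmse), 1e-12)
    tied = [cv for cv in pool if cv.pRMSE <= best_rmse + tol]
    best_pcor = max(cv.pCOR for cv in tied)
    tied = [cv for cv in tied if cv.pCOR >= best_pcor - _TIE_RTOL]
    for cv in tied:
        if cv is base_cv:
            return cv
    return min(tied, key=lambda cv: cv.model.spatial.param
               if cv.model.spatial is not None else 0.0)


def search_model1(t: TrialTable, kinship: GenomicKinship, dim: PlotDimension,
                  plan: CVPlan, trait: str,
                  families=FAMILIES, directions=DIRECTIONS,
                  grids: dict | None = None,
                  opts: SolverOptions | None = None) -> SelectionReport:
    """Search spatial-kernel candidates against the base model.

    Every candidate (family x direction x grid parameter) is evaluated
    under the identical CV plan; the model with the lowest pRMSE wins.
    A full-data likelihood-ratio test of the winner against the base
    model (one extra variance component) is reported.
    """
    base_spec = ModelSpec(trait, kinship)
    base_cv = cross_validate(t, base_spec, plan, opts)
    cand_cvs = []
    for spec in _candidate_specs(t, kinship, dim, trait, families, directions, grids):
        try:
            cand_cvs.append(cross_validate(t, spec, plan, opts))
        except RuntimeError as e:
            log.warning("candidate %s dropped: %s", spec.name, e)
    notes = []
    if not cand_cvs:
        notes.append("all spatial candidates failed; base model retained")
    best_cv = _pick_best(base_cv, cand_cvs)
    rel_pcor, rel_prmse = relative_metrics(base_cv, best_cv)

    base_fit = fit_reml(t, base_spec, opts)
    test = None
    best_fit = base_fit
    if best_cv.model.spatial is not None:
        best_fit = fit_reml(t, best_cv.model, opts)
        test = lrt(best_fit, base_fit, extra_df=1)
    return SelectionReport(
        base=base_cv, candidates=cand_cvs, best=best_cv.model,
        best_cv=best_cv, rel_pcor_increase=rel_pcor,
        rel_prmse_decrease=rel_prmse, lrt=test,
        best_fit=best_fit, base_fit=base_fit, notes=notes,
    )


def extend_model2(t: TrialTable, kinship: GenomicKinship,
                  best_so_far: ModelSpec, plan: CVPlan,
                  opts: SolverOptions | None = None) -> SelectionReport:
    """Offer random Range / Column / both effects on top of the winner.

    Extensions model extraneous (operational) field variation as steps
    between Ranges or Columns.  They are judged by the same CV criterion;
    the likelihood-ratio test against ``best_so_far`` uses one degree of
    freedom per added component.  Extensions whose factor has a single
    level in the field are skipped with a warning.
    """
    n_ranges = t.data["range_idx"].nunique()
    n_cols = t.data["col_idx"].nunique()
    variants = []
    notes = []
    for ra, cl in ((True, False), (False, True), (True, True)):
        if ra and n_ranges < 2:
            notes.append("range effect skipped: single Range in the field")
            continue
        if cl and n_cols < 2:
            notes.append("column effect skipped: single Column in the field")
            continue
        variants.append(
            ModelSpec(best_so_far.trait, kinship, spatial=best_so_far.spatial,
                      range_effect=ra, column_effect=cl)
        )
    if notes:
        for msg in notes:
            warnings.warn(msg)
    ref_cv = cross_validate(t, best_so_far, plan, opts)
    cand_cvs = []
    for spec in variants:
        try:
            cand_cvs.append(cross_validate(t, spec, plan, opts))
        except RuntimeError as e:
            log.warning("extension %s dropped: %s", spec.name, e)
    best_cv = _pick_best(ref_cv, cand_cvs)
    rel_pcor, rel_prmse = relative_metrics(ref_cv, best_cv)
    ref_fit = fit_reml(t, best_so_far, opts)
    test = None
    best_fit = ref_fit
    extra = (best_cv.model.range_effect - best_so_far.range_effect) + (
        best_cv.model.column_effect - best_so_far.column_effect
    )
    if extra > 0:
        best_fit = fit_reml(t, best_cv.model, opts)
        test = lrt(best_fit, ref_fit, extra_df=int(extra))
    return SelectionReport(
        base=ref_cv, candidates=cand_cvs, best=best_cv.model,
        best_cv=best_cv, rel_pcor_increase=rel_pcor,
        rel_prmse_decrease=rel_prmse, lrt=test,
        best_fit=best_fit, base_fit=ref_fit, notes=notes,
    )
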