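import numpy as np
import pandas as pd
import pytest

import gsspatial as gs
from gsspatial.trial import MarkerMatrix


def grid_trial(values_by_geno: dict, n_cols: int = 8, traits=("y",)) -> gs.TrialTable:
    """Small trial from genotype -> list-of-values, filled row-major."""
    rows, p = [], 0
    for geno, vals in values_by_geno.items():
        for v in np.atleast_1d(vals):
            rows.append(
                {
                    "plot_id": f"P{p:03d}",
                    "range_idx": p // n_cols + 1,
                    "col_idx": p % n_cols + 1,
                    "genotype": geno,
                    "is_check": False,
                    "y": float(v),
                }
            )
            p += 1
    return gs.TrialTable(pd.DataFrame(rows), list(traits))


def balanced_trial(n_geno: int, reps: int, seed: int,
                   sigma_g: float = 1.2, sigma_r: float = 0.8,
                   mu: float = 10.0) -> gs.TrialTable:
    """Balanced replicated trial with i.i.d. genotype effects."""
    rng = np.random.default_rng(seed)
    eff = rng.normal(0.0, sigma_g, n_geno)
    vals = {
        f"G{i:02d}": mu + eff[i] + rng.normal(0.0, sigma_r, reps)
        for i in range(n_geno)
    }
    return grid_trial(vals, n_cols=max(8, reps * 3))


@pytest.fixture(scope="session")
def marker_panel():
    """A 100-genotype layout with a marker-derived kinship.

    Genotypic effects drawn from this kinship give genotype-disjoint CV
    real predictive signal (unlike an identity kinship), which the
    selection-engine tests need.
    """
    rng = np.random.default_rng(99)
    layout = gs.default_layout(n_genotypes=100, n_checks=4, check_reps=3, n_cols=12)
    genos = layout.genotypes
    p = rng.uniform(0.1, 0.9, 300)
    dosages = rng.binomial(2, p, size=(len(genos), 300)).astype(float)
    kinship = gs.vanraden_kinship(MarkerMatrix(genos, dosages))
    chol = np.linalg.cholesky(kinship.matrix + 1e-6 * np.eye(len(genos)))
    return layout, kinship, chol


def kinship_trial(marker_panel, seed: int, sigma_r: float = 1.0,
                  spatial: np.ndarray | None = None) -> gs.TrialTable:
    """Phenotypes on the marker panel: g ~ N(0, K), plus noise and an
    optional fixed per-plot spatial surface."""
    layout, _, chol = marker_panel
    rng = np.random.default_rng(seed)
    g = pd.Series(chol @ rng.standard_normal(chol.shape[0]), index=layout.genotypes)
    df = layout.data.copy()
    y = g.loc[df["genotype"]].to_numpy() + rng.normal(0.0, sigma_r, layout.n_plots)
    if spatial is not None:
        y = y + spatial
    df["y"] = y
    return gs.TrialTable(df, ["y"])
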