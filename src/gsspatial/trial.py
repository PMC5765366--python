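"""Field-trial tables: loading, validation and preprocessing.

A trial is a set of plots on a regular grid addressed by a Range index
(North-South partition) and a Column index (East-West partition), each
plot carrying a genotype label, a check flag and one or more trait values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "TrialTable",
    "PlotDimension",
    "MarkerMatrix",
    "load_trial",
    "load_markers",
    "drop_missing_for_trait",
    "match_genotypes",
    "remove_outliers",
]

#: default column-name map for delimited trial files
DEFAULT_SCHEMA = {
    "genotype": "genotype",
    "range": "range",
    "column": "column",
    "plot_id": None,   # synthesized if absent
    "is_check": None,  # all-False if absent
}


@dataclass(frozen=True)
class PlotDimension:
    """Plot footprint in meters.

    ``length_m`` is the extent along the Column direction (East-West),
    ``width_m`` the extent along the Range direction (North-South).
    Center-to-center distance between adjacent Ranges is therefore
    ``width_m`` and between adjacent Columns ``length_m``.
    """

    length_m: float
    width_m: float

    def __post_init__(self) -> None:
        if not (self.length_m > 0 and self.width_m > 0):
            raise ValueError("plot dimensions must be strictly positive")


@dataclass
class TrialTable:
    """Per-plot records of a single field trial.

    ``data`` holds one row per plot with columns ``plot_id``, ``range_idx``,
    ``col_idx``, ``genotype``, ``is_check`` plus one float column per trait.
    Coordinates are 1-based integers and (range_idx, col_idx) pairs are
    unique within a trial.
    """

    data: pd.DataFrame
    traits: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        required = ["plot_id", "range_idx", "col_idx", "genotype", "is_check"]
        missing = [c for c in required if c not in self.data.columns]
        if missing:
            raise ValueError(f"trial table missing columns: {missing}")
        self.data = self.data.reset_index(drop=True)
        dup = self.data.duplicated(subset=["range_idx", "col_idx"], keep=False)
        if dup.any():
            plots = self.data.loc[dup, "plot_id"].tolist()
            raise ValueError(f"duplicate (range, column) coordinates for plots {plots}")
        for t in self.traits:
            vals = self.data[t].to_numpy(dtype=float)
            if np.isinf(vals).any():
                raise ValueError(f"non-finite value in trait {t!r}")
        if self.data["genotype"].nunique() < 2:
            raise ValueError("a trial needs at least two distinct genotypes")

    @property
    def n_plots(self) -> int:
        return len(self.data)

    @property
    def genotypes(self) -> np.ndarray:
        """Unique genotype labels in order of first appearance."""
        return self.data["genotype"].unique()

    @property
    def plot_ids(self) -> np.ndarray:
        return self.data["plot_id"].to_numpy()

    def values(self, trait: str) -> np.ndarray:
        if trait not in self.traits:
            raise KeyError(f"unknown trait {trait!r}")
        return self.data[trait].to_numpy(dtype=float)

    def subset(self, mask: np.ndarray) -> "TrialTable":
        return TrialTable(self.data.loc[np.asarray(mask)].copy(), list(self.traits))


def load_trial(path, schema: dict | None = None, sep: str = ",") -> TrialTable:
    """Read a delimited trial file into a validated :class:`TrialTable`.

    ``schema`` maps the roles ``genotype``/``range``/``column`` (and
    optionally ``plot_id``/``is_check``) to column names in the file; every
    remaining numeric column is treated as a trait.  Rows without
    coordinates are rejected; missing trait values (empty or ``NA``) are
    kept as missing.
    """
    sch = dict(DEFAULT_SCHEMA)
    if schema:
        sch.update(schema)
    raw = pd.read_csv(path, sep=sep, na_values=["NA", "NaN", ""])
    for role in ("genotype", "range", "column"):
        if sch[role] not in raw.columns:
            raise ValueError(f"column {sch[role]!r} (role {role}) not in {path}")
    for role in ("plot_id", "is_check"):
        if sch[role] is not None and sch[role] not in raw.columns:
            raise ValueError(f"column {sch[role]!r} (role {role}) not in {path}")

    coords_ok = raw[sch["range"]].notna() & raw[sch["column"]].notna()
    if not coords_ok.all():
        warnings.warn(f"dropping {(~coords_ok).sum()} rows with missing coordinates")
        raw = raw.loc[coords_ok]

    df = pd.DataFrame(
        {
            "range_idx": raw[sch["range"]].astype(int).to_numpy(),
            "col_idx": raw[sch["column"]].astype(int).to_numpy(),
            "genotype": raw[sch["genotype"]].astype(str).to_numpy(),
        }
    )
    df["plot_id"] = (
        raw[sch["plot_id"]].astype(str).to_numpy()
        if sch["plot_id"]
        else [f"R{r}C{c}" for r, c in zip(df["range_idx"], df["col_idx"])]
    )
    df["is_check"] = (
        raw[sch["is_check"]].astype(bool).to_numpy() if sch["is_check"] else False
    )
    used = {sch[r] for r in sch if sch[r]}
    traits = [
        c
        for c in raw.columns
        if c not in used and pd.api.types.is_numeric_dtype(raw[c])
    ]
    for t in traits:
        df[t] = raw[t].astype(float).to_numpy()
    return TrialTable(df, traits)


def drop_missing_for_trait(t: TrialTable, trait: str) -> TrialTable:
    """Keep only plots with a finite value for ``trait``."""
    vals = t.values(trait)
    keep = np.isfinite(vals)
    if not keep.any():
        raise ValueError(f"all values missing for trait {trait!r}")
    return t.subset(keep)


def match_genotypes(t: TrialTable, kinship) -> tuple[TrialTable, int]:
    """Drop plots whose genotype is absent from the relationship matrix.

    Returns the filtered table and the number of plots removed.
    """
    known = set(kinship.genotypes)
    keep = t.data["genotype"].isin(known).to_numpy()
    n_removed = int((~keep).sum())
    if not keep.any():
        raise ValueError("no trial genotype found in the relationship matrix")
    return (t if n_removed == 0 else t.subset(keep)), n_removed


def remove_outliers(t: TrialTable, trait: str, base_fit, c: float = 2.5) -> TrialTable:
    """Drop plots whose base-model residual exceeds ``c`` residual SDs.

    A single pass: residuals come from ``base_fit`` (a no-spatial fit of
    ``trait`` on ``t``), the threshold is ``c`` times their sample standard
    deviation (ddof=1), and plots with ``|r| > c * SD`` are removed.  The
    comparison is strict, so a residual exactly at the threshold is kept.
    """
    if c <= 0:
        raise ValueError("outlier multiplier must be positive")
    resid = np.asarray(base_fit.residuals, dtype=float)
    if len(resid) != t.n_plots:
        raise ValueError("base fit does not match the trial (different n)")
    sd = float(np.std(resid, ddof=1))
    keep = np.abs(resid) <= c * sd
    if not keep.any():
        raise ValueError("outlier rule removed every plot")
    return t if keep.all() else t.subset(keep)


@dataclass
class MarkerMatrix:
    """Biallelic SNP dosages (0/1/2, missing allowed) per genotype."""

    genotypes: np.ndarray
    dosages: np.ndarray  # genotypes x markers, float with NaN for missing

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes)
        self.dosages = np.asarray(self.dosages, dtype=float)
        if len(self.genotypes) != len(set(self.genotypes)):
            raise ValueError("duplicate genotype identifiers in marker matrix")
        if self.dosages.shape[0] != len(self.genotypes):
            raise ValueError("dosage rows must match genotype list")
        vals = self.dosages[~np.isnan(self.dosages)]
        if not np.isin(vals, (0.0, 1.0, 2.0)).all():
            raise ValueError("dosages must be in {0, 1, 2} or missing")


def load_markers(path, sep: str = ",") -> MarkerMatrix:
    """Read a delimited dosage file (first column = genotype identifier)."""
    raw = pd.read_csv(path, sep=sep, na_values=["NA", "NaN", ""])
    genotypes = raw.iloc[:, 0].astype(str).to_numpy()
    dosages = raw.iloc[:, 1:].to_numpy(dtype=float)
    return MarkerMatrix(genotypes, dosages)
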