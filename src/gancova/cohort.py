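"""Cohort and methylation-panel containers, QC, autoscaling and PCA1.

The predictor side of the analysis is a cohort table: one row per subject
with a binary sex label and 16 continuous exposures (age, anthropometry,
folate status, blood counts, micronutrients).  The response side is a
panel of percent-methylation values for gene-associated CpG islands plus
LINE-1 as a global-methylation index, with per-cell missingness allowed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.decomposition import PCA

EXPOSURES = [
    "age", "height", "weight", "BMI", "waist", "hip", "WHR", "RCF", "PF",
    "homocysteine", "WC", "MC", "vitD", "Se", "FI", "vitB12",
]

EXPOSURE_UNITS = {
    "age": "years", "height": "m", "weight": "kg", "BMI": "kg/m^2",
    "waist": "cm", "hip": "cm", "WHR": "ratio", "RCF": "ng/mL",
    "PF": "nmol/L", "homocysteine": "umol/L", "WC": "1e6/mL",
    "MC": "1e3/mL", "vitD": "nmol/L", "Se": "umol/L", "FI": "%",
    "vitB12": "pmol/L",
}

GENE_LOCI = [
    "SFRP1", "SFRP2", "AXIN2", "WIF1", "APC", "HPP1", "DKK1", "SOX17",
    "ESR1", "MYOD1", "N33",
]
LINE1 = "LINE-1"
ALL_LOCI = GENE_LOCI + [LINE1]


@dataclass
class CohortTable:
    """Per-subject sex and continuous exposures (the predictor side)."""

    data: pd.DataFrame  # index: subject id; columns: sex + exposures

    def __post_init__(self):
        df = self.data
        if df.index.has_duplicates:
            dupes = df.index[df.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicated subject ids: {dupes}")
        if "sex" not in df.columns:
            raise ValueError("cohort table must have a 'sex' column")
        levels = set(df["sex"].unique())
        if levels != {"male", "female"}:
            raise ValueError(
                f"sex must have exactly the two levels male/female, got {sorted(levels)}")
        for col in self.exposure_names:
            x = df[col].to_numpy()
            if not np.issubdtype(x.dtype, np.number):
                raise TypeError(f"exposure {col!r} is not numeric")
            if not np.all(np.isfinite(x)):
                raise ValueError(f"exposure {col!r} has missing/non-finite values")
            if np.any(x <= 0):
                raise ValueError(f"exposure {col!r} has non-positive values")

    @property
    def exposure_names(self) -> list:
        return [c for c in self.data.columns if c != "sex"]

    @property
    def n_subjects(self) -> int:
        return len(self.data)

    @property
    def n_by_sex(self) -> dict:
        counts = self.data["sex"].value_counts()
        return {"male": int(counts.get("male", 0)),
                "female": int(counts.get("female", 0))}

    @property
    def subjects(self) -> pd.Index:
        return self.data.index

    def subset(self, subjects) -> "CohortTable":
        return CohortTable(self.data.loc[subjects])


@dataclass
class MethylationPanel:
    """Subjects x loci percent-methylation matrix with missingness mask."""

    values: pd.DataFrame

    def __post_init__(self):
        v = self.values.to_numpy(dtype=float)
        with np.errstate(invalid="ignore"):
            bad = (v < 0) | (v > 100)
        if np.any(bad & ~np.isnan(v)):
            i, j = np.argwhere(bad & ~np.isnan(v))[0]
            raise ValueError(
                "methylation outside [0, 100] at subject "
                f"{self.values.index[i]!r}, locus {self.values.columns[j]!r}")

    @property
    def mask(self) -> pd.DataFrame:
        """True where a value was observed."""
        return self.values.notna()

    @property
    def loci(self) -> list:
        return list(self.values.columns)

    def complete_cases(self, loci=None) -> pd.Index:
        cols = list(loci) if loci is not None else self.loci
        return self.values.index[self.values[cols].notna().all(axis=1)]

    def subset(self, loci) -> "MethylationPanel":
        return MethylationPanel(self.values[list(loci)])


# ---------------------------------------------------------------------------
# autoscaling

def autoscale(v, lo: float = 0.01, hi: float = 1.0):
    """Affine min-max map of the observed values onto [lo, hi].

    Missing entries stay missing; the observed minimum maps exactly to
    ``lo`` and the maximum exactly to ``hi``.  Raises on a (near)
    constant input, for which the map is undefined.
    """
    arr = np.asarray(v, dtype=float)
    obs = arr[np.isfinite(arr)]
    if np.unique(obs).size < 2:
        raise ValueError("degenerate input: fewer than 2 distinct observed values")
    vmin, vmax = obs.min(), obs.max()
    # convex-combination form: exact lo/hi at the observed endpoints
    ratio = (arr - vmin) / (vmax - vmin)
    out = lo * (1.0 - ratio) + hi * ratio
    if isinstance(v, pd.Series):
        return pd.Series(out, index=v.index, name=v.name)
    return out


class IntervalScaler(TransformerMixin, BaseEstimator):
    """Column-wise min-max scaler onto a target interval (default [0.01, 1]).

    Observed-case statistics only; NaNs pass through untouched.  The
    fitted per-column (min, max) are frozen, so ``transform`` on new data
    is an affine map with the training provenance.
    """

    def __init__(self, lo: float = 0.01, hi: float = 1.0):
        self.lo = lo
        self.hi = hi

    def fit(self, X: pd.DataFrame, y=None):
        X = pd.DataFrame(X)
        mins, maxs = {}, {}
        for col in X.columns:
            obs = X[col].dropna().to_numpy(dtype=float)
            if np.unique(obs).size < 2:
                raise ValueError(
                    f"degenerate input: column {col!r} has <2 distinct values")
            mins[col], maxs[col] = float(obs.min()), float(obs.max())
        self.min_ = mins
        self.max_ = maxs
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        X = pd.DataFrame(X)
        out = {}
        for col in X.columns:
            lo_, hi_ = self.min_[col], self.max_[col]
            ratio = (X[col] - lo_) / (hi_ - lo_)
            out[col] = self.lo * (1.0 - ratio) + self.hi * ratio
        return pd.DataFrame(out, index=X.index)


@dataclass
class ScaledResponse:
    """Autoscaled methylation responses with scaling provenance."""

    values: pd.DataFrame
    provenance: dict  # locus -> (observed min, observed max)
    lo: float = 0.01
    hi: float = 1.0


def autoscale_panel(panel: MethylationPanel, lo: float = 0.01,
                    hi: float = 1.0) -> ScaledResponse:
    scaler = IntervalScaler(lo, hi).fit(panel.values)
    scaled = scaler.transform(panel.values)
    prov = {c: (scaler.min_[c], scaler.max_[c]) for c in scaled.columns}
    return ScaledResponse(scaled, prov, lo, hi)


# ---------------------------------------------------------------------------
# gene-level QC

@dataclass
class GeneQCReport:
    table: pd.DataFrame  # locus, median, r_age, p_age, kept, reason

    def kept(self) -> list:
        return list(self.table.loc[self.table["kept"], "locus"])


def qc_filter_genes(panel: MethylationPanel, age,
                    median_floor: float = 1.0,
                    alpha: float = 0.05) -> tuple:
    """Exclude loci that are both very low and uncorrelated with age.

    A locus is excluded iff its observed median methylation is below
    ``median_floor`` percent AND its age correlation is non-significant
    (p >= alpha).  LINE-1, the global methylation index, is always
    retained.  Returns the filtered panel and a per-locus report.
    """
    age = np.asarray(age, dtype=float)
    if len(age) != len(panel.values):
        raise ValueError("age vector not aligned to panel subjects")
    rows = []
    for locus in panel.loci:
        col = panel.values[locus]
        obs = col.notna().to_numpy()
        x = col.to_numpy(dtype=float)[obs]
        med = float(np.median(x))
        if obs.sum() >= 3 and np.unique(x).size > 1 and np.unique(age[obs]).size > 1:
            r, p = stats.pearsonr(age[obs], x)
            if not np.isfinite(p):
                r, p = 0.0, 1.0
        else:
            r, p = 0.0, 1.0
        if locus == LINE1:
            kept, reason = True, "global index, always retained"
        elif med < median_floor and p >= alpha:
            kept, reason = False, (
                f"median {med:.3g}% < {median_floor:g}% and no age "
                f"correlation (p={p:.3g} >= {alpha:g})")
        else:
            kept, reason = True, ""
        rows.append((locus, med, float(r), float(p), kept, reason))
    table = pd.DataFrame(
        rows, columns=["locus", "median", "r_age", "p_age", "kept", "reason"])
    kept_loci = table.loc[table["kept"], "locus"].tolist()
    if not kept_loci:
        raise ValueError("QC excluded every locus")
    return panel.subset(kept_loci), GeneQCReport(table)


# ---------------------------------------------------------------------------
# PCA1 composite score

@dataclass
class Pca1Score:
    scores: pd.Series            # autoscaled to [0.01, 1], complete cases only
    loadings: pd.Series          # per gene, sign convention sum >= 0
    variance_explained: float    # fraction of total variance on PC1
    subjects: pd.Index           # complete-case subject ids


class MethylationPCA(TransformerMixin, BaseEstimator):
    """First-principal-component summary of a multi-gene methylation panel.

    Covariance-basis PCA of the autoscaled gene matrix (autoscaling is
    the route to equal per-gene weighting, so no further standardisation
    is applied).  The component sign is fixed so the loading sum is
    non-negative, making the score rise with overall methylation.
    """

    def __init__(self, lo: float = 0.01, hi: float = 1.0):
        self.lo = lo
        self.hi = hi

    def fit(self, X: pd.DataFrame, y=None):
        X = pd.DataFrame(X).dropna()
        if len(X) < 3:
            raise ValueError("need at least 3 complete-case subjects for PCA")
        if len(X) < X.shape[1] + 1:
            warnings.warn(
                f"only {len(X)} complete cases for {X.shape[1]} genes; "
                "PC1 may be unstable", stacklevel=2)
        if float(X.var(ddof=1).sum()) == 0:
            raise ValueError("zero-variance panel")
        pca = PCA(n_components=1, svd_solver="full")
        pca.fit(X.to_numpy(dtype=float))
        load = pca.components_[0]
        if load.sum() < 0:
            load = -load
        self.loadings_ = pd.Series(load, index=X.columns)
        self.mean_ = X.mean()
        self.variance_explained_ = float(pca.explained_variance_ratio_[0])
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X: pd.DataFrame) -> pd.Series:
        X = pd.DataFrame(X).dropna()
        centred = X - self.mean_
        raw = centred.to_numpy(dtype=float) @ self.loadings_.to_numpy()
        return pd.Series(raw, index=X.index, name="PCA1")


def compute_pca1(scaled: ScaledResponse | pd.DataFrame,
                 lo: float = 0.01, hi: float = 1.0) -> Pca1Score:
    """PCA1 score over the (scaled) gene panel, autoscaled to [lo, hi]."""
    frame = scaled.values if isinstance(scaled, ScaledResponse) else scaled
    est = MethylationPCA(lo, hi).fit(frame)
    raw = est.transform(frame)
    scores = autoscale(raw, lo, hi)
    return Pca1Score(scores, est.loadings_, est.variance_explained_,
                     scores.index)


# ---------------------------------------------------------------------------
# cohort summary (Table-1 style)

def summarize_cohort(cohort: CohortTable) -> pd.DataFrame:
    """Min/median/max per exposure for all subjects, males and females."""
    df = cohort.data
    groups = {
        "all": df,
        "male": df[df["sex"] == "male"],
        "female": df[df["sex"] == "female"],
    }
    rows = {}
    for var in cohort.exposure_names:
        row = {}
        for label, g in groups.items():
            x = g[var].to_numpy(dtype=float)
            row[f"{label}_min"] = float(np.min(x))
            row[f"{label}_median"] = float(np.median(x))
            row[f"{label}_max"] = float(np.max(x))
        rows[var] = row
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "variable"
    out.attrs["n"] = {k: len(v) for k, v in groups.items()}
    return out
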