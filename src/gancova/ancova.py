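"""Sex-interaction ANCOVA: design construction, least-squares fit, term tests.

Sex is coded sum-to-zero (+1 male, -1 female) so that a "common" slope is
the average slope across sexes and the interaction coefficient is half the
male-female slope difference.  Continuous covariates are centred at their
(training) mean before products are formed; the centring constants are
frozen at fit time and reused for prediction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, stats
from sklearn.base import BaseEstimator, RegressorMixin

from .modelspec import COMMON, SEX_SPLIT, ModelSpec

SEX_CODES = {"male": 1.0, "female": -1.0}


def sex_code(values) -> np.ndarray:
    """Map sex labels (or +/-1 codes) to the +/-1 sum-to-zero coding."""
    arr = np.asarray(values)
    if arr.dtype.kind in "if":
        codes = arr.astype(float)
        if not np.all(np.isin(codes, (1.0, -1.0))):
            raise ValueError("numeric sex codes must be +/-1")
        return codes
    out = np.empty(arr.shape, dtype=float)
    for i, v in enumerate(arr.ravel()):
        key = str(v).strip().lower()
        if key in ("male", "m", "1"):
            out.ravel()[i] = 1.0
        elif key in ("female", "f", "-1", "2"):
            out.ravel()[i] = -1.0
        else:
            raise ValueError(f"unrecognized sex label {v!r}")
    return out


@dataclass
class DesignMatrix:
    """A named least-squares design for a :class:`ModelSpec`."""

    X: np.ndarray
    columns: list
    centers: dict
    spec: ModelSpec
    index: np.ndarray | None = None

    @property
    def shape(self):
        return self.X.shape


def build_design(spec: ModelSpec, data: pd.DataFrame,
                 centers: dict | None = None) -> DesignMatrix:
    """Build the design matrix for ``spec`` from a subject table.

    ``data`` must contain a ``sex`` column and every covariate in the
    spec.  Columns, in order: intercept; sex (if the main effect is in);
    then per covariate its centred value and, for sex-split terms, the
    product of the centred value with the sex code.  If ``centers`` is
    given those constants are used (prediction on new data); otherwise
    means of ``data`` are taken and recorded.
    """
    missing = [c for c in spec.covariates if c not in data.columns]
    if missing:
        raise KeyError(f"covariates missing from data: {missing}")
    n = len(data)
    codes = sex_code(data["sex"].to_numpy())
    cols: list = [np.ones(n)]
    names: list = ["intercept"]
    if spec.sex_main:
        cols.append(codes)
        names.append("sex")
    used_centers = {}
    for name, kind in spec.terms:
        x = data[name].to_numpy(dtype=float)
        mu = centers[name] if centers is not None else float(np.mean(x))
        used_centers[name] = mu
        xc = x - mu
        cols.append(xc)
        names.append(name)
        if kind == SEX_SPLIT:
            cols.append(xc * codes)
            names.append(f"sex*{name}")
    X = np.column_stack(cols)
    return DesignMatrix(X, names, used_centers, spec,
                        index=np.asarray(data.index))


def spec_from_columns(columns) -> ModelSpec:
    """Reconstruct the :class:`ModelSpec` encoded by design column names."""
    terms: dict = {}
    sex_main = False
    for name in columns:
        if name == "intercept":
            continue
        if name == "sex":
            sex_main = True
        elif name.startswith("sex*"):
            terms[name[4:]] = SEX_SPLIT
        else:
            terms.setdefault(name, COMMON)
    return ModelSpec(tuple(sorted(terms.items())), sex_main)


@dataclass
class FitResult:
    """Ordinary least-squares fit of an ANCOVA design."""

    coef: pd.Series
    r2: float
    fitted: np.ndarray
    residuals: np.ndarray
    df_resid: int
    sigma2: float
    xtx_inv: np.ndarray
    centers: dict
    spec: ModelSpec
    columns: list = field(default_factory=list)

    @property
    def sex_slopes(self) -> dict:
        """Per-sex slopes, ``name -> (male, female)``, for sex-split terms."""
        out = {}
        for name, kind in self.spec.terms:
            if kind == SEX_SPLIT:
                b = self.coef[name]
                d = self.coef[f"sex*{name}"]
                out[name] = (b + d, b - d)
        return out


def _check_rank(X: np.ndarray, columns) -> None:
    q, r, piv = linalg.qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps if diag.size else 0.0
    bad = [columns[piv[i]] for i in range(len(diag)) if diag[i] <= tol]
    if bad:
        raise np.linalg.LinAlgError(
            f"design is rank deficient; offending columns: {bad}")


def fit_ancova(design: DesignMatrix, y) -> FitResult:
    """Least-squares fit; R^2 is the squared correlation of fitted vs actual."""
    y = np.asarray(y, dtype=float)
    X = design.X
    n, p = X.shape
    if n != len(y):
        raise ValueError("response length does not match design rows")
    if n <= p:
        raise ValueError(f"too few observations (n={n}) for {p} columns")
    if not np.all(np.isfinite(y)):
        raise ValueError("response contains non-finite values")
    _check_rank(X, design.columns)
    xtx = X.T @ X
    xtx_inv = linalg.inv(xtx)
    beta = xtx_inv @ (X.T @ y)
    fitted = X @ beta
    resid = y - fitted
    df_resid = n - p
    sigma2 = float(resid @ resid) / df_resid
    if np.std(fitted) > 1e-12 * (np.std(y) + 1.0) and np.std(y) > 0:
        r2 = float(np.corrcoef(fitted, y)[0, 1] ** 2)
    else:
        r2 = 0.0
    coef = pd.Series(beta, index=design.columns)
    return FitResult(coef, r2, fitted, resid, df_resid, sigma2, xtx_inv,
                     dict(design.centers), design.spec,
                     list(design.columns))


def ancova_table(fit: FitResult, design: DesignMatrix) -> pd.DataFrame:
    """Marginal (drop-one-column, Type-III-style) F test per model term.

    With the sum-to-zero sex coding every non-intercept design column is
    one model term, so its marginal F equals the squared t statistic.
    Terms are returned ordered by ascending p.
    """
    rows = []
    for j, name in enumerate(design.columns):
        if name == "intercept":
            continue
        se2 = fit.xtx_inv[j, j] * fit.sigma2
        if se2 <= 0:
            raise np.linalg.LinAlgError(f"singular reduced model at {name!r}")
        F = float(fit.coef.iloc[j] ** 2 / se2)
        p = float(stats.f.sf(F, 1, fit.df_resid))
        rows.append((name, F, max(p, np.finfo(float).tiny)))
    table = pd.DataFrame(rows, columns=["term", "F", "p"])
    table = table.sort_values(["p", "term"], kind="mergesort")
    table["rank"] = np.arange(1, len(table) + 1)
    return table.reset_index(drop=True)


def predict_response(fit: FitResult, spec: ModelSpec,
                     data: pd.DataFrame) -> np.ndarray:
    """Linear predictor for new subjects, using the training centres."""
    design = build_design(spec, data, centers=fit.centers)
    return design.X @ fit.coef.to_numpy()


def wedge_diagnostic(residuals, age) -> tuple:
    """Glejser-style test for age-increasing residual spread.

    Regresses |residual| on age; a significantly positive slope indicates
    the wedge-shaped (heteroscedastic) methylation-age pattern.  Returns
    ``(slope, t, p)`` with a two-sided p-value.
    """
    r = np.abs(np.asarray(residuals, dtype=float))
    a = np.asarray(age, dtype=float)
    if len(r) != len(a):
        raise ValueError("residuals and age must be aligned")
    if np.ptp(r) == 0:
        raise ValueError("degenerate input: residuals are constant")
    res = stats.linregress(a, r)
    t = res.slope / res.stderr
    return float(res.slope), float(t), float(res.pvalue)


class AncovaRegressor(RegressorMixin, BaseEstimator):
    """ANCOVA regression for a fixed :class:`ModelSpec`.

    Scikit-learn style estimator: ``fit(X, y)`` takes a subject DataFrame
    (``sex`` column plus covariates) and a numeric response; ``predict``
    applies the frozen linear predictor to new subjects.

    Attributes (after fit)
    ----------------------
    coef_ : pd.Series of coefficients indexed by design column name
    r2_ : squared correlation between fitted and actual values (no CV)
    anova_table_ : per-term marginal F/p, ordered by significance
    sex_slopes_ : per-sex slopes for sex-split covariates
    """

    def __init__(self, spec: ModelSpec | str = ""):
        self.spec = spec

    def _resolved_spec(self) -> ModelSpec:
        if isinstance(self.spec, ModelSpec):
            return self.spec
        return ModelSpec.from_string(str(self.spec))

    def fit(self, X: pd.DataFrame, y):
        spec = self._resolved_spec()
        design = build_design(spec, X)
        result = fit_ancova(design, np.asarray(y, dtype=float))
        self.spec_ = spec
        self.result_ = result
        self.design_columns_ = list(design.columns)
        self.coef_ = result.coef
        self.centers_ = result.centers
        self.r2_ = result.r2
        self.df_resid_ = result.df_resid
        self.residuals_ = result.residuals
        self.anova_table_ = ancova_table(result, design)
        self.sex_slopes_ = result.sex_slopes
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        return predict_response(self.result_, self.spec_, X)

    def ordered_terms(self) -> list:
        """Design terms ordered by their significance in the model."""
        return list(self.anova_table_["term"])
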