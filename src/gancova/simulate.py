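"""Synthetic cohort generator with known ground truth.

Emulates the statistical structure the pipeline consumes: per-sex
min/median/max exposure marginals (matched with scaled Beta
distributions coupled through a Gaussian copula), sex-split linear
methylation signals on standardized covariates, a shared latent
co-methylation factor, age-increasing ("wedge") noise, and a
missingness plan for the loci that lose subjects to failed
amplification.  Every generated effect is recorded in a
:class:`SyntheticTruth` so recovery tests know the generating model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml
from scipy import optimize, stats

from .ancova import sex_code
from .cohort import EXPOSURES, CohortTable, MethylationPanel
from .modelspec import COMMON, SEX_SPLIT, ModelSpec

# Per-sex (min, median, max) marginals of the 16 exposures in a rectal
# biopsy screening cohort of 84 men and 101 women aged 17-77.
DEFAULT_MARGINALS = {
    "age":          {"male": (17, 45, 77),       "female": (18, 52, 76)},
    "height":       {"male": (1.62, 1.79, 1.98), "female": (1.49, 1.62, 1.75)},
    "weight":       {"male": (50, 88, 163),      "female": (45, 72, 125)},
    "BMI":          {"male": (17, 28, 50),       "female": (19, 27, 51)},
    "waist":        {"male": (65, 99, 150),      "female": (64, 86, 118)},
    "hip":          {"male": (84, 103, 143),     "female": (80, 102, 141)},
    "WHR":          {"male": (0.77, 0.95, 1.13), "female": (0.71, 0.83, 0.99)},
    "RCF":          {"male": (77, 382, 815),     "female": (154, 321, 922)},
    "PF":           {"male": (1.00, 6.30, 14.60), "female": (2.70, 6.50, 18.10)},
    "homocysteine": {"male": (3.22, 11.70, 63.90), "female": (4.69, 8.77, 47.48)},
    "WC":           {"male": (3.50, 7.50, 15.70), "female": (4.10, 7.60, 16.70)},
    "MC":           {"male": (0.21, 0.54, 1.30), "female": (0.12, 0.49, 1.23)},
    "vitD":         {"male": (23, 68, 224),      "female": (19, 75, 258)},
    "Se":           {"male": (0.64, 1.07, 1.73), "female": (0.61, 1.09, 1.87)},
    "FI":           {"male": (5.8, 27.0, 38.3),  "female": (22.1, 36.6, 49.7)},
    "vitB12":       {"male": (125, 359, 953),    "female": (110, 377, 1133)},
}

DEFAULT_MALE_FRACTION = 84 / 185
_CALIBRATION_SEED = 987654321
_CALIBRATION_N = 20000


def default_exposure_correlation(variables=None) -> pd.DataFrame:
    """Declared default exposure intercorrelations (a labelled stand-in).

    Built from factor loadings (body size, stature, folate status,
    age/metabolic, leukocyte) so the matrix is positive semi-definite by
    construction; fully user-overridable.
    """
    variables = list(variables) if variables is not None else list(EXPOSURES)
    factors = {
        "body":    {"weight": 0.75, "BMI": 0.80, "waist": 0.75, "hip": 0.65,
                    "FI": 0.55, "WHR": 0.40},
        "stature": {"height": 0.85, "weight": 0.40},
        "folate":  {"RCF": 0.60, "PF": 0.60, "vitB12": 0.25},
        "agefac":  {"age": 0.90, "WHR": 0.25, "homocysteine": 0.30},
        "immune":  {"WC": 0.80, "MC": 0.60},
    }
    L = np.zeros((len(variables), len(factors)))
    for j, (_, loads) in enumerate(factors.items()):
        for var, w in loads.items():
            if var in variables:
                L[variables.index(var), j] = w
    R = L @ L.T
    np.fill_diagonal(R, 1.0)
    return pd.DataFrame(R, index=variables, columns=variables)


def _beta_params(vmin, vmed, vmax, concentration: float = 4.0) -> tuple:
    """Beta(a, b) with a+b = concentration whose median matches vmed."""
    if not vmin < vmed < vmax:
        raise ValueError(
            f"infeasible marginal: median {vmed} outside ({vmin}, {vmax})")
    u = (vmed - vmin) / (vmax - vmin)

    def err(a):
        return stats.beta.median(a, concentration - a) - u

    a = optimize.brentq(err, 1e-3, concentration - 1e-3)
    return a, concentration - a


@dataclass
class LocusTruth:
    """Generating model for one methylation locus.

    ``shares`` maps terms (covariate, ``"sex*covariate"`` or ``"sex"``)
    to signed fractions of the response variance; their absolute values
    sum to the locus' target out-of-sample explained variance.  ``betas``
    are the calibrated standardized coefficients derived from the shares.
    """

    shares: dict = field(default_factory=dict)
    target_ev: float = 0.0
    baseline: float = 20.0        # percent methylation at the signal centre
    scale: float = 8.0            # percent per standardized response unit
    latent_loading: float = 0.0   # co-methylation factor loading
    wedge_s0: float = 0.5         # noise sd profile intercept (age anchored)
    wedge_s1: float = 1.0 / 60.0  # noise sd growth per year of age
    betas: dict = field(default_factory=dict)      # set by calibration
    noise_sd: float = 1.0                          # set by calibration
    wedge_norm: float = 1.0                        # set by calibration

    def spec(self, response: str = "") -> ModelSpec:
        terms, sex_main = {}, False
        for key in self.shares:
            if key == "sex":
                sex_main = True
            elif key.startswith("sex*"):
                terms[key[4:]] = SEX_SPLIT
            else:
                terms.setdefault(key, COMMON)
        return ModelSpec(tuple(sorted(terms.items())), sex_main, response)


@dataclass
class SyntheticTruth:
    """Complete ground-truth record for a synthetic cohort scenario."""

    marginals: dict = field(default_factory=lambda: dict(DEFAULT_MARGINALS))
    correlation: pd.DataFrame | None = None
    male_fraction: float = DEFAULT_MALE_FRACTION
    loci: dict = field(default_factory=dict)       # name -> LocusTruth
    missing_loci: tuple = ()
    n_missing: int = 0
    concentration: float = 4.0
    standardization: dict = field(default_factory=dict)  # var -> (mu, sd)

    def __post_init__(self):
        if self.correlation is None:
            self.correlation = default_exposure_correlation(
                list(self.marginals))
        eig = np.linalg.eigvalsh(self.correlation.to_numpy())
        if eig.min() < -1e-10:
            raise ValueError("exposure correlation matrix is not PSD")

    @property
    def variables(self) -> list:
        return list(self.marginals)

    # -- serialization ---------------------------------------------------
    def to_dict(self) -> dict:
        d = {
            "variables": list(self.marginals),
            "marginals": {k: {s: list(v) for s, v in m.items()}
                          if isinstance(m, dict) else list(m)
                          for k, m in self.marginals.items()},
            "correlation": self.correlation.to_numpy().tolist(),
            "male_fraction": self.male_fraction,
            "missing_loci": list(self.missing_loci),
            "n_missing": self.n_missing,
            "concentration": self.concentration,
            "standardization": {k: list(v) for k, v in
                                self.standardization.items()},
            "loci": {name: asdict(lt) for name, lt in self.loci.items()},
        }
        return d

    def save(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticTruth":
        order = d.get("variables", list(d["marginals"]))
        marginals = {
            k: ({s: tuple(v) for s, v in d["marginals"][k].items()}
                if isinstance(d["marginals"][k], dict)
                else tuple(d["marginals"][k]))
            for k in order}
        corr = pd.DataFrame(np.asarray(d["correlation"]),
                            index=list(marginals), columns=list(marginals))
        loci = {name: LocusTruth(**spec) for name, spec in d["loci"].items()}
        return cls(marginals, corr, d["male_fraction"], loci,
                   tuple(d["missing_loci"]), d["n_missing"],
                   d["concentration"],
                   {k: tuple(v) for k, v in d["standardization"].items()})

    @classmethod
    def load(cls, path) -> "SyntheticTruth":
        with open(path, "r", encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh))


# ---------------------------------------------------------------------------
# exposure generation (Gaussian copula + Beta marginals)

def _marginal_for(truth: SyntheticTruth, var: str, sex: str) -> tuple:
    m = truth.marginals[var]
    return m[sex] if isinstance(m, dict) else m


def generate_exposures(n: int, male_fraction: float, truth: SyntheticTruth,
                       seed: int = 0) -> CohortTable:
    """Draw a cohort of ``n`` subjects with the truth's exposure structure."""
    if not 0 < male_fraction < 1:
        raise ValueError("male_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    n_male = int(round(n * male_fraction))
    sexes = np.array(["male"] * n_male + ["female"] * (n - n_male))
    sexes = sexes[rng.permutation(n)]
    variables = truth.variables
    R = truth.correlation.loc[variables, variables].to_numpy()
    w, V = np.linalg.eigh(R)
    L = V @ np.diag(np.sqrt(np.clip(w, 0, None)))
    Z = rng.standard_normal((n, len(variables))) @ L.T
    U = stats.norm.cdf(Z)
    U = np.clip(U, 1e-9, 1 - 1e-9)
    data = {"sex": sexes}
    for j, var in enumerate(variables):
        x = np.empty(n)
        for sex in ("male", "female"):
            mask = sexes == sex
            vmin, vmed, vmax = _marginal_for(truth, var, sex)
            a, b = _beta_params(vmin, vmed, vmax, truth.concentration)
            x[mask] = vmin + (vmax - vmin) * stats.beta.ppf(U[mask, j], a, b)
        data[var] = x
    frame = pd.DataFrame(
        data, index=pd.Index([f"S{i+1:04d}" for i in range(n)],
                             name="subject_id"))
    return CohortTable(frame)


# ---------------------------------------------------------------------------
# truth calibration

def _standardized(truth: SyntheticTruth, cohort: CohortTable) -> pd.DataFrame:
    z = {}
    for var in truth.variables:
        mu, sd = truth.standardization[var]
        z[var] = (cohort.data[var] - mu) / sd
    return pd.DataFrame(z, index=cohort.data.index)


def _signal(locus: LocusTruth, z: pd.DataFrame, codes: np.ndarray,
            betas: dict) -> np.ndarray:
    g = np.zeros(len(z))
    for key, beta in sorted(betas.items()):  # canonical summation order
        if key == "sex":
            g += beta * codes
        elif key.startswith("sex*"):
            var = key[4:]
            if var not in z.columns:
                raise KeyError(f"truth references unknown covariate {var!r}")
            g += beta * z[var].to_numpy() * codes
        else:
            if key not in z.columns:
                raise KeyError(f"truth references unknown covariate {key!r}")
            g += beta * z[key].to_numpy()
    return g


def calibrate_truth(truth: SyntheticTruth,
                    calib_n: int = _CALIBRATION_N,
                    calib_seed: int = _CALIBRATION_SEED) -> SyntheticTruth:
    """Fix standardization constants and coefficients from a large draw.

    A single large calibration cohort defines the population mean/sd of
    each exposure; locus coefficients start at ``sign * sqrt(|share|)``
    on the standardized scale and are rescaled jointly so the realised
    signal variance equals the locus target explained variance.  Noise
    is then sized to make the total response variance one, with the
    wedge profile normalised to unit mean square, so the target EV is an
    out-of-sample explained-variance fraction by construction.
    """
    probe = SyntheticTruth(truth.marginals, truth.correlation,
                           truth.male_fraction, {}, (), 0,
                           truth.concentration, {})
    calib = generate_exposures(calib_n, truth.male_fraction, probe,
                               seed=calib_seed)
    std = {var: (float(calib.data[var].mean()),
                 float(calib.data[var].std(ddof=0)))
           for var in truth.variables}
    truth.standardization = std
    z = _standardized(truth, calib)
    codes = sex_code(calib.data["sex"].to_numpy())
    age = calib.data["age"].to_numpy()
    age_min = float(np.floor(age.min()))
    for name, locus in truth.loci.items():
        raw = {k: np.sign(s) * np.sqrt(abs(s))
               for k, s in locus.shares.items()}
        target = float(sum(abs(s) for s in locus.shares.values()))
        locus.target_ev = target
        if raw:
            g = _signal(locus, z, codes, raw)
            var_g = float(np.var(g))
            adj = np.sqrt(target / var_g) if var_g > 0 else 0.0
            locus.betas = {k: float(v * adj) for k, v in raw.items()}
        else:
            locus.betas = {}
        resid_var = 1.0 - target - locus.latent_loading ** 2
        if resid_var <= 0:
            raise ValueError(f"locus {name}: shares + latent exceed unit variance")
        locus.noise_sd = float(np.sqrt(resid_var))
        prof = locus.wedge_s0 + locus.wedge_s1 * (age - age_min)
        locus.wedge_norm = float(np.sqrt(np.mean(prof ** 2)))
    return truth


# ---------------------------------------------------------------------------
# methylation generation

def generate_methylation(cohort: CohortTable, truth: SyntheticTruth,
                         seed: int = 0) -> MethylationPanel:
    """Generate the percent-methylation panel for a cohort draw."""
    if not truth.standardization:
        raise ValueError("truth must be calibrated (see calibrate_truth)")
    rng = np.random.default_rng(seed)
    z = _standardized(truth, cohort)
    codes = sex_code(cohort.data["sex"].to_numpy())
    age = cohort.data["age"].to_numpy(dtype=float)
    age_min = 17.0
    n = len(cohort.data)
    latent = rng.standard_normal(n)
    out = {}
    n_clipped = 0
    for name in sorted(truth.loci):  # canonical rng consumption order
        locus = truth.loci[name]
        g = _signal(locus, z, codes, locus.betas)
        prof = (locus.wedge_s0 + locus.wedge_s1 * (age - age_min))
        prof = prof / locus.wedge_norm
        eps = rng.standard_normal(n) * prof * locus.noise_sd
        y_std = g + locus.latent_loading * latent + eps
        pct = locus.baseline + locus.scale * y_std
        clipped = (pct < 0) | (pct > 100)
        n_clipped += int(clipped.sum())
        out[name] = np.clip(pct, 0.0, 100.0)
    total = n * max(len(truth.loci), 1)
    if n_clipped > 0.01 * total:
        warnings.warn(
            f"{n_clipped}/{total} methylation values clipped to [0, 100]",
            stacklevel=2)
    values = pd.DataFrame(out, index=cohort.data.index)
    if truth.missing_loci and truth.n_missing > 0:
        drop = rng.choice(n, size=truth.n_missing, replace=False)
        for locus in truth.missing_loci:
            values.iloc[drop, values.columns.get_loc(locus)] = np.nan
    return MethylationPanel(values)


def generate_cohort(truth: SyntheticTruth, n: int = 185,
                    seed: int = 0) -> tuple:
    """Full draw: ``(CohortTable, MethylationPanel)`` from one seed."""
    ss = np.random.SeedSequence(int(seed))
    s_exp, s_meth = (int(c.generate_state(1)[0] % (2 ** 31))
                     for c in ss.spawn(2))
    cohort = generate_exposures(n, truth.male_fraction, truth, seed=s_exp)
    panel = generate_methylation(cohort, truth, seed=s_meth)
    return cohort, panel


# ---------------------------------------------------------------------------
# shipped scenarios

def pca1_like_truth(target_ev: float = 0.38) -> SyntheticTruth:
    """Single-response scenario mirroring the composite-score model shape.

    Age is sex-split (steeper in males), plasma folate positive, selenium
    and vitamin D negative, plus a small positive male offset.  Shares
    are sized so each generating term is individually well-determined at
    a cohort of ~185 subjects; they scale jointly with ``target_ev``.
    """
    base = {"age": 0.085, "sex*age": 0.075, "sex": 0.02,
            "PF": 0.0667, "Se": -0.0667, "vitD": -0.0666}
    f = target_ev / 0.38
    shares = {k: v * f for k, v in base.items()}
    loci = {"PCA1like": LocusTruth(shares=shares, baseline=45.0, scale=10.0)}
    truth = SyntheticTruth(loci=loci)
    return calibrate_truth(truth)


def default_truth() -> SyntheticTruth:
    """Full 12-locus panel scenario.

    Nine gene CpG islands with age-led signals (seven sharing a latent
    co-methylation factor), two near-zero loci with no age relation that
    the QC step should exclude, and LINE-1 with a weak negative age
    trend; three loci lose 11 subjects to the missingness plan.
    """
    lam7 = np.sqrt(0.2)
    loci = {
        "SFRP1": LocusTruth({"age": 0.10, "RCF": 0.03, "sex*RCF": 0.03,
                             "sex": 0.02, "MC": 0.02},
                            baseline=25, scale=8, latent_loading=lam7),
        "SFRP2": LocusTruth({"age": 0.08, "FI": 0.03},
                            baseline=30, scale=9, latent_loading=lam7),
        "AXIN2": LocusTruth({}, baseline=0.4, scale=0.1, wedge_s1=0.0),
        "WIF1": LocusTruth({"age": 0.18, "MC": 0.04, "Se": -0.04},
                           baseline=20, scale=7, latent_loading=lam7),
        "APC": LocusTruth({"vitD": -0.02, "FI": 0.02, "age": 0.02},
                          baseline=10, scale=4),
        "HPP1": LocusTruth({"age": 0.08, "sex*age": 0.04, "sex": 0.02,
                            "MC": 0.04},
                           baseline=25, scale=8, latent_loading=lam7),
        "DKK1": LocusTruth({}, baseline=0.3, scale=0.1, wedge_s1=0.0),
        "SOX17": LocusTruth({"age": 0.08, "sex*age": 0.04, "sex": 0.02,
                             "WC": -0.03},
                            baseline=15, scale=5, latent_loading=lam7),
        "ESR1": LocusTruth({"age": 0.10, "height": 0.02, "sex*height": -0.03,
                            "sex": 0.02},
                           baseline=30, scale=8, latent_loading=lam7),
        "MYOD1": LocusTruth({"age": 0.10, "PF": 0.04, "vitD": -0.03},
                            baseline=35, scale=9, latent_loading=lam7),
        "N33": LocusTruth({"age": 0.06, "PF": 0.02, "sex*PF": -0.04,
                           "sex": 0.01},
                          baseline=20, scale=6, latent_loading=0.15),
        "LINE-1": LocusTruth({"age": -0.01, "height": -0.01,
                              "sex*height": 0.02, "Se": 0.01, "sex": 0.01,
                              "vitB12": -0.02},
                             baseline=70, scale=4, wedge_s1=0.0),
    }
    truth = SyntheticTruth(loci=loci,
                           missing_loci=("ESR1", "MYOD1", "N33"),
                           n_missing=11)
    return calibrate_truth(truth)
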