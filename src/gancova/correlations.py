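"""Pearson correlation surfaces: exposures vs methylation and intergene.

All correlations are pairwise complete-case (so 185-subject exposures
keep full n against 174-subject genes) with unadjusted two-sided
p-values from the t transform with n-2 degrees of freedom.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class CorrelationReport:
    stratum: str
    r: pd.DataFrame
    p: pd.DataFrame
    n: pd.DataFrame

    def to_long(self, stars_at=()) -> pd.DataFrame:
        """Long-format rows (stratum, var1, var2, n, r, p, stars)."""
        rows = []
        for v1 in self.r.index:
            for v2 in self.r.columns:
                r = self.r.loc[v1, v2]
                p = self.p.loc[v1, v2]
                stars = "".join("*" for a in sorted(stars_at) if p < a) \
                    if np.isfinite(p) else ""
                rows.append((self.stratum, v1, v2, int(self.n.loc[v1, v2]),
                             r, p, stars))
        return pd.DataFrame(
            rows, columns=["stratum", "var1", "var2", "n", "r", "p", "stars"])


def _pairwise(xs: pd.DataFrame, ys: pd.DataFrame, stratum: str) -> CorrelationReport:
    r = pd.DataFrame(np.nan, index=xs.columns, columns=ys.columns)
    p = pd.DataFrame(np.nan, index=xs.columns, columns=ys.columns)
    n = pd.DataFrame(0, index=xs.columns, columns=ys.columns)
    for a in xs.columns:
        xa = xs[a]
        for b in ys.columns:
            yb = ys[b]
            ok = xa.notna() & yb.notna()
            m = int(ok.sum())
            n.loc[a, b] = m
            if m < 3:
                continue  # flagged by NaN r/p with the observed n
            if a == b and xs is ys:
                r.loc[a, b], p.loc[a, b] = 1.0, np.finfo(float).tiny
                continue
            x = xa[ok].to_numpy(dtype=float)
            v = yb[ok].to_numpy(dtype=float)
            if np.std(x) == 0 or np.std(v) == 0:
                continue
            rr, pp = stats.pearsonr(x, v)
            r.loc[a, b] = float(rr)
            p.loc[a, b] = float(max(pp, np.finfo(float).tiny))
    return CorrelationReport(stratum, r, p, n)


def pearson_strata(cohort, responses: pd.DataFrame,
                   strata=("all", "male", "female")) -> dict:
    """Exposure-vs-response correlations for all / males / females.

    ``cohort`` is a CohortTable or a DataFrame with a ``sex`` column;
    ``responses`` is a subjects x loci frame aligned on the same index.
    """
    data = cohort.data if hasattr(cohort, "data") else cohort
    responses = responses.reindex(data.index)
    exposures = data.drop(columns=["sex"])
    out = {}
    for stratum in strata:
        if stratum == "all":
            keep = pd.Series(True, index=data.index)
        else:
            keep = data["sex"] == stratum
        if not keep.any():
            raise ValueError(f"empty stratum {stratum!r}")
        out[stratum] = _pairwise(exposures.loc[keep], responses.loc[keep],
                                 stratum)
    return out


def intergene_matrix(panel: pd.DataFrame,
                     significance_levels=(0.001, 0.01, 0.05)) -> tuple:
    """Gene x gene co-methylation screen with per-pair significance stars.

    Returns the symmetric CorrelationReport and a star-annotation frame;
    p-values are unadjusted by design (the screen mirrors an unadjusted
    intercorrelation table).  More stars mean a smaller p: one star per
    significance level passed.
    """
    report = _pairwise(panel, panel, "intergene")
    stars = pd.DataFrame("", index=panel.columns, columns=panel.columns)
    for a in panel.columns:
        for b in panel.columns:
            pv = report.p.loc[a, b]
            if a != b and np.isfinite(pv):
                stars.loc[a, b] = "".join(
                    "*" for lvl in sorted(significance_levels) if pv < lvl)
    return report, stars
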