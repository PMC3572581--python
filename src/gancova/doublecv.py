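"""Double (nested) cross-validation of the whole selection + fit procedure.

For each outer fold the complete GA model selection is rerun on the
training portion only, the selected model is fit there, and the held-out
subjects are predicted.  Pooled out-of-fold predictions yield the
percentage of variance the modelling process would explain on a new
cohort; a subject-level percentile bootstrap gives its 95% CI, and the
model passes iff the lower bound is above zero (failing models are
reported with an empty cell, the dash convention).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ancova import AncovaRegressor, sex_code
from .ga import GAConfig, _as_frame, run_epochs, stratified_folds


@dataclass
class CVResult:
    explained_variance: float          # percent
    ci_lower: float                    # percent
    ci_upper: float                    # percent
    passed: bool
    fold_specs: list                   # selected ModelSpec per outer fold
    predictions: pd.Series             # pooled out-of-fold predictions
    baselines: np.ndarray              # per-subject training-fold mean of y
    seeds: dict
    fold_assignment: np.ndarray | None = None  # outer fold per subject


def _explained_variance_pct(y, yhat, ybar) -> float:
    rss = float(np.sum((y - yhat) ** 2))
    tss = float(np.sum((y - ybar) ** 2))
    return 100.0 * (1.0 - rss / tss)


def double_cross_validate(cohort, y, candidates,
                          ga_config: GAConfig = GAConfig(),
                          outer_folds: int = 7, seed: int = 0,
                          inner_epochs: int = 3,
                          n_bootstrap: int = 1000) -> CVResult:
    """Nested CV estimate of out-of-sample explained variance (percent).

    Outer folds are stratified by sex and derived from ``seed`` and the
    subject order only, never from the response, so a held-out subject's
    value cannot influence its own fold's selection or fit.
    """
    data = _as_frame(cohort)
    y = np.asarray(y, dtype=float)
    n = len(y)
    if n != len(data):
        raise ValueError("response not aligned to cohort")
    if outer_folds < 2:
        raise ValueError("need at least 2 outer folds")
    if np.ptp(y) == 0:
        raise ValueError("degenerate response: constant y")
    ss = np.random.SeedSequence(int(seed))
    fold_child, *epoch_children = ss.spawn(1 + outer_folds)
    codes = sex_code(data["sex"].to_numpy())
    fold = stratified_folds(codes, outer_folds,
                            np.random.default_rng(fold_child))
    largest = min(np.bincount(fold, minlength=outer_folds))
    if largest < 2:
        raise ValueError("an outer fold is too small")
    yhat = np.empty(n)
    ybar = np.empty(n)
    fold_specs = []
    seeds = {"outer": int(seed)}
    for f in range(outer_folds):
        tr = fold != f
        te = ~tr
        train = data.loc[tr]
        base = int(epoch_children[f].generate_state(1)[0] % (2 ** 31))
        seeds[f"fold_{f}"] = base
        sel = run_epochs(train, y[tr], candidates, ga_config,
                         n_epochs=inner_epochs, base_seed=base)
        fold_specs.append(sel.modal_spec)
        est = AncovaRegressor(sel.modal_spec).fit(train, y[tr])
        yhat[te] = est.predict(data.loc[te])
        ybar[te] = y[tr].mean()
    ev = _explained_variance_pct(y, yhat, ybar)
    boot_rng = np.random.default_rng(ss.spawn(1)[0])
    idx = boot_rng.integers(0, n, size=(int(n_bootstrap), n))
    rss = np.sum((y[idx] - yhat[idx]) ** 2, axis=1)
    tss = np.sum((y[idx] - ybar[idx]) ** 2, axis=1)
    boots = 100.0 * (1.0 - rss / tss)
    lo, hi = np.percentile(boots, [2.5, 97.5])
    result = CVResult(ev, float(lo), float(hi), bool(lo > 0), fold_specs,
                      pd.Series(yhat, index=data.index, name="prediction"),
                      ybar, seeds, fold)
    return result


def cv_pass_fail(result: CVResult) -> tuple:
    """Pass flag and the report cell: ``"EV (lo-hi)"`` or empty on failure."""
    passed = result.ci_lower > 0
    if passed:
        cell = (f"{result.explained_variance:.1f} "
                f"({result.ci_lower:.1f}-{result.ci_upper:.1f})")
    else:
        cell = ""
    return passed, cell
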