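"""Genetic-algorithm search over sex-interaction ANCOVA covariate subsets.

Each candidate model is scored by cross-validated explained variance
(sex-stratified k-fold, averaged over a few independent fold splits)
minus a BIC-style complexity penalty ``ln(n) * df / n``.  The penalty
gives the selection the parsimony pressure needed for the search to
return the same model across repeated epochs; without it, some
chance-correlated covariate almost always buys a marginal CV gain and no
stable consensus model exists.  Consensus over epochs is the modal
best-of-run model, with its frequency (n1CV) as a stability measure.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from collections import Counter
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import linalg
from sklearn.base import BaseEstimator

from .ancova import AncovaRegressor, ancova_table, build_design, fit_ancova, sex_code
from .modelspec import (SEX_SPLIT, ModelSpec, decode_chromosome, encode_spec)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GAConfig:
    """Hyperparameters of the subset search.

    Defaults are sized for 16-candidate pools at cohort sizes near 185:
    a population of 50 with uniform crossover and per-locus mutation
    converges well inside 100 generations, and patience stops most runs
    far earlier.
    """

    population_size: int = 50
    max_generations: int = 100
    tournament_size: int = 2
    crossover_prob: float = 0.5
    mutation_prob: float | None = None  # default 1/chromosome length
    elitism: int = 1
    patience: int = 20
    cv_folds: int = 7
    cv_repeats: int = 3
    complexity_penalty: float | str = "bic"
    max_terms: int = 8

    def __post_init__(self):
        if min(self.population_size, self.max_generations + 1,
               self.tournament_size, self.elitism + 1, self.patience,
               self.cv_folds - 1, self.cv_repeats, self.max_terms) <= 0:
            raise ValueError("GAConfig fields must be positive (cv_folds >= 2)")
        if not 0 <= self.crossover_prob <= 1:
            raise ValueError("crossover_prob must be in [0, 1]")
        if self.mutation_prob is not None and not 0 <= self.mutation_prob <= 1:
            raise ValueError("mutation_prob must be in [0, 1]")


def _as_frame(cohort) -> pd.DataFrame:
    if hasattr(cohort, "data"):
        return cohort.data
    return cohort


def _resolve_penalty(penalty, n: int) -> float:
    if penalty in (None, 0, "none"):
        return 0.0
    if penalty == "bic":
        return float(np.log(n))
    return float(penalty)


def stratified_folds(codes: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    """Sex-stratified fold labels in 0..k-1, shuffled within each sex."""
    n = len(codes)
    fold = np.empty(n, dtype=int)
    for s in (1.0, -1.0):
        idx = np.flatnonzero(codes == s)
        idx = rng.permutation(idx)
        fold[idx] = np.arange(len(idx)) % k
    return fold


class FitnessEvaluator:
    """Penalized repeated-CV fitness with per-run caching.

    Fold assignments and per-fold centring statistics are precomputed
    once from ``seed``, so every model evaluated by one GA run (or by the
    exhaustive oracle sharing the seed) sees identical folds.
    """

    def __init__(self, cohort, y, candidates, *, folds=7, repeats=3,
                 penalty="bic", seed=0, max_terms=None):
        data = _as_frame(cohort)
        self.candidates = list(candidates)
        missing = [c for c in self.candidates if c not in data.columns]
        if missing:
            raise KeyError(f"candidates not in cohort: {missing}")
        self.y = np.asarray(y, dtype=float)
        n = len(self.y)
        if n != len(data):
            raise ValueError("response not aligned to cohort")
        self.n = n
        self.codes = sex_code(data["sex"].to_numpy())
        self.k = int(folds)
        if self.k < 2:
            raise ValueError("need at least 2 folds")
        self.max_terms = max_terms
        self.gamma = _resolve_penalty(penalty, n)
        self._sex_ok = min((self.codes == 1).sum(),
                           (self.codes == -1).sum()) >= self.k
        X = data[self.candidates].to_numpy(dtype=float)
        rng = np.random.default_rng(seed)
        self._splits = []
        for _ in range(int(repeats)):
            fold = stratified_folds(self.codes, self.k, rng)
            per_fold = []
            for f in range(self.k):
                tr = fold != f
                mu = X[tr].mean(axis=0)
                C = X - mu
                per_fold.append((tr, C, C * self.codes[:, None],
                                 float(self.y[tr].mean())))
            self._splits.append(per_fold)
        self._cache: dict = {}

    def __call__(self, spec: ModelSpec) -> float:
        key = spec.key()
        hit = self._cache.get(key)
        if hit is not None:
            return hit
        if self.max_terms is not None and spec.n_covariates > self.max_terms:
            raise ValueError(
                f"spec has {spec.n_covariates} covariates > max_terms={self.max_terms}")
        if (spec.sex_main or any(k == SEX_SPLIT for _, k in spec.terms)) \
                and not self._sex_ok:
            raise ValueError(
                "a fold would contain one sex only; cannot score sex terms")
        pos = {name: i for i, name in enumerate(self.candidates)}
        idx_main = [pos[name] for name, _ in spec.terms]
        idx_int = [pos[name] for name, kind in spec.terms if kind == SEX_SPLIT]
        n = self.n
        evs = []
        for per_fold in self._splits:
            press = tss = 0.0
            for tr, C, CI, ytr_mean in per_fold:
                cols = [np.ones(n)]
                if spec.sex_main:
                    cols.append(self.codes)
                if idx_main:
                    cols.append(C[:, idx_main])
                if idx_int:
                    cols.append(CI[:, idx_int])
                X = np.column_stack(cols)
                Xtr = X[tr]
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore", linalg.LinAlgWarning)
                    try:
                        beta = linalg.solve(Xtr.T @ Xtr, Xtr.T @ self.y[tr],
                                            assume_a="pos")
                    except linalg.LinAlgError:
                        beta = np.linalg.lstsq(Xtr, self.y[tr], rcond=None)[0]
                te = ~tr
                resid = self.y[te] - X[te] @ beta
                press += float(resid @ resid)
                dev = self.y[te] - ytr_mean
                tss += float(dev @ dev)
            evs.append(1.0 - press / tss)
        score = float(np.mean(evs)) - self.gamma * spec.n_columns / n
        self._cache[key] = score
        return score


def cv_fitness(spec: ModelSpec, cohort, y, folds: int = 7, seed: int = 0,
               *, repeats: int = 3, penalty="bic",
               max_terms: int | None = None) -> float:
    """Penalized cross-validated explained variance of one model.

    Deterministic for a fixed seed: the fold assignment (stratified by
    sex), the fold centres and hence the score are functions of
    ``(data, spec, folds, repeats, seed)`` only.
    """
    ev = FitnessEvaluator(cohort, y, list(spec.covariates) or [],
                          folds=folds, repeats=repeats, penalty=penalty,
                          seed=seed, max_terms=max_terms)
    return ev(spec)


def _run_seeds(seed: int) -> tuple:
    """Derive (cv seed, ga rng) from one run seed, shared with the oracle."""
    ss = np.random.SeedSequence(int(seed))
    cv_child, ga_child = ss.spawn(2)
    cv_seed = int(cv_child.generate_state(1)[0])
    return cv_seed, np.random.default_rng(ga_child)


def _mutate(genes: np.ndarray, rate: float, rng) -> np.ndarray:
    out = genes.copy()
    L = len(out)
    hits = np.flatnonzero(rng.random(L) < rate)
    for i in hits:
        if i == L - 1:
            out[i] = 1 - out[i]
        else:
            out[i] = (out[i] + rng.integers(1, 3)) % 3
    return out


def run_ga(cohort, y, candidates, config: GAConfig = GAConfig(),
           seed: int = 0, evaluator: FitnessEvaluator | None = None) -> tuple:
    """One GA epoch; returns ``(best ModelSpec, best fitness)``.

    Tournament selection, uniform crossover, per-locus mutation, elitism;
    stops after ``max_generations`` or ``patience`` generations without
    improvement of the best-ever model.
    """
    candidates = list(candidates)
    if not candidates:
        raise ValueError("need at least one candidate covariate")
    cv_seed, rng = _run_seeds(seed)
    if evaluator is None:
        evaluator = FitnessEvaluator(
            cohort, y, candidates, folds=config.cv_folds,
            repeats=config.cv_repeats, penalty=config.complexity_penalty,
            seed=cv_seed, max_terms=None)
    L = len(candidates) + 1
    mut = config.mutation_prob if config.mutation_prob is not None else 1.0 / L
    pop = np.empty((config.population_size, L), dtype=int)
    pop[:, :-1] = rng.choice(3, size=(config.population_size, L - 1),
                             p=[0.7, 0.2, 0.1])
    pop[:, -1] = rng.random(config.population_size) < 0.3

    def fitness_of(genes):
        spec = decode_chromosome(genes, candidates, config.max_terms)
        return evaluator(spec), spec

    best = None  # (fitness, genes, spec)
    stale = 0
    for gen in range(config.max_generations + 1):
        scored = [fitness_of(ind) for ind in pop]
        fits = np.array([s[0] for s in scored])
        gen_best = int(np.argmax(fits))
        if best is None or fits[gen_best] > best[0]:
            best = (float(fits[gen_best]), pop[gen_best].copy(),
                    scored[gen_best][1])
            stale = 0
            logger.debug("gen %d: best %.5f  %s", gen, best[0],
                         best[2].to_string())
        else:
            stale += 1
        if gen == config.max_generations or stale >= config.patience:
            break
        children = [best[1].copy() for _ in range(config.elitism)]
        while len(children) < config.population_size:
            picks = rng.integers(0, config.population_size,
                                 size=(2, config.tournament_size))
            pa = pop[picks[0][np.argmax(fits[picks[0]])]]
            pb = pop[picks[1][np.argmax(fits[picks[1]])]]
            swap = rng.random(L) < config.crossover_prob
            child = np.where(swap, pb, pa)
            children.append(_mutate(child, mut, rng))
        pop = np.array(children)
    return best[2], best[0]


@dataclass
class ExhaustiveResult:
    spec: ModelSpec
    fitness: float
    n_enumerated: int


def exhaustive_search(cohort, y, candidates, config: GAConfig = GAConfig(),
                      seed: int = 0) -> ExhaustiveResult:
    """Enumerate every spec in the pool; oracle twin of :func:`run_ga`.

    Uses the same fold seed derivation as ``run_ga(seed)`` so both score
    identical CV folds.  Ties go to fewer design columns, then to the
    lexically smaller model string.
    """
    candidates = list(candidates)
    n_space = 3 ** len(candidates) * 2
    if n_space > 10_000:
        raise ValueError(f"pool too large to enumerate ({n_space} specs)")
    cv_seed, _ = _run_seeds(seed)
    evaluator = FitnessEvaluator(
        cohort, y, candidates, folds=config.cv_folds,
        repeats=config.cv_repeats, penalty=config.complexity_penalty,
        seed=cv_seed)
    best = None
    count = 0
    for alleles in itertools.product((0, 1, 2), repeat=len(candidates)):
        for sex_bit in (0, 1):
            count += 1
            genes = np.array(alleles + (sex_bit,), dtype=int)
            spec = decode_chromosome(genes, candidates, config.max_terms)
            fit = evaluator(spec)
            rankkey = (-fit, spec.n_columns, spec.to_string())
            if best is None or rankkey < best[0]:
                best = (rankkey, spec, fit)
    return ExhaustiveResult(best[1], best[2], count)


@dataclass
class ModelSelectionResult:
    """Consensus of repeated GA epochs plus the full-data fit."""

    modal_spec: ModelSpec
    n1cv: int
    tie: bool
    epoch_specs: list
    epoch_fitnesses: list
    estimator: AncovaRegressor
    r2: float
    anova_table: pd.DataFrame

    def ordered_terms(self) -> list:
        return list(self.anova_table["term"])


def run_epochs(cohort, y, candidates, config: GAConfig = GAConfig(),
               n_epochs: int = 10, base_seed: int = 0) -> ModelSelectionResult:
    """Repeat the GA over independent epochs and form the modal consensus.

    Epoch ``i`` runs with seed ``base_seed + i``.  Ties on the modal
    count are flagged and broken toward the spec with the higher mean
    fitness over its epochs.  The winning spec is refit on the full data
    for the no-CV R^2 and the significance-ordered term list.
    """
    if n_epochs < 1:
        raise ValueError("n_epochs must be >= 1")
    data = _as_frame(cohort)
    specs, fits = [], []
    for i in range(n_epochs):
        spec, fit = run_ga(cohort, y, candidates, config, seed=base_seed + i)
        specs.append(spec)
        fits.append(fit)
    counts = Counter(s.key() for s in specs)
    top = counts.most_common()
    modal_count = top[0][1]
    tied = [k for k, c in top if c == modal_count]
    tie = len(tied) > 1
    by_key = {}
    for s, f in zip(specs, fits):
        by_key.setdefault(s.key(), []).append((s, f))
    def mean_fit(key):
        return float(np.mean([f for _, f in by_key[key]]))
    winner_key = max(tied, key=lambda k: (mean_fit(k),
                                          -len(by_key[k][0][0].terms),
                                          by_key[k][0][0].to_string()))
    winner = by_key[winner_key][0][0]
    est = AncovaRegressor(winner).fit(data, np.asarray(y, dtype=float))
    return ModelSelectionResult(winner, modal_count, tie, specs, fits, est,
                                est.r2_, est.anova_table_)


class GAAncovaSelector(BaseEstimator):
    """Scikit-learn style wrapper: GA covariate-subset selection + ANCOVA fit.

    ``fit(X, y)`` expects a subject DataFrame with a ``sex`` column; all
    remaining columns are candidate covariates unless ``candidates`` is
    given.  After fitting, ``best_spec_`` holds the consensus model,
    ``n1cv_`` its epoch frequency, and ``estimator_`` the full-data
    :class:`AncovaRegressor` used by ``predict``.
    """

    def __init__(self, candidates=None, config: GAConfig = GAConfig(),
                 n_epochs: int = 10, base_seed: int = 0):
        self.candidates = candidates
        self.config = config
        self.n_epochs = n_epochs
        self.base_seed = base_seed

    def fit(self, X: pd.DataFrame, y):
        data = _as_frame(X)
        cands = (list(self.candidates) if self.candidates is not None
                 else [c for c in data.columns if c != "sex"])
        res = run_epochs(data, y, cands, self.config, self.n_epochs,
                         self.base_seed)
        self.result_ = res
        self.best_spec_ = res.modal_spec
        self.n1cv_ = res.n1cv
        self.tie_ = res.tie
        self.estimator_ = res.estimator
        self.r2_ = res.r2
        self.n_features_in_ = data.shape[1]
        return self

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        return self.estimator_.predict(_as_frame(X))
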