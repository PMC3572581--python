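import numpy as np
import pytest

import gancova as g
from gancova.modelspec import COMMON, SEX_SPLIT, ModelSpec
from tests.conftest import random_cohort_frame

SMALL = g.GAConfig(population_size=24, max_generations=40, patience=10)


def _signal_frame(rng, n=120, n_cands=4):
    names = ["age", "PF", "Se", "vitD", "MC", "BMI"][:n_cands]
    frame = random_cohort_frame(rng, n=n, covariates=names)
    return frame, names


def test_cv_fitness_is_deterministic_for_fixed_seed():
    rng = np.random.default_rng(0)
    frame, names = _signal_frame(rng)
    y = rng.normal(size=len(frame))
    spec = ModelSpec((("age", COMMON), ("PF", SEX_SPLIT)))
    a = g.cv_fitness(spec, frame, y, folds=7, seed=42)
    b = g.cv_fitness(spec, frame, y, folds=7, seed=42)
    assert a == b
    assert a != g.cv_fitness(spec, frame, y, folds=7, seed=43)


def test_noise_response_scores_near_zero():
    rng = np.random.default_rng(1)
    scores = []
    for _ in range(20):
        frame, names = _signal_frame(rng, n=150)
        y = rng.normal(size=len(frame))
        spec = ModelSpec((("age", COMMON),))
        scores.append(g.cv_fitness(spec, frame, y, seed=0))
    assert np.mean(scores) <= 0.02


def test_true_model_beats_null_under_signal():
    rng = np.random.default_rng(2)
    wins = 0
    reps = 30
    for _ in range(reps):
        frame, names = _signal_frame(rng, n=185)
        # true explained variance ~ 0.3 through a single covariate
        y = np.sqrt(0.3 / 0.7) * frame["age"].to_numpy() + rng.normal(size=185)
        true = ModelSpec((("age", COMMON),))
        null = ModelSpec()
        wins += (g.cv_fitness(true, frame, y, seed=7)
                 > g.cv_fitness(null, frame, y, seed=7))
    assert wins >= int(0.95 * reps)


def test_exhaustive_enumerates_the_whole_pool():
    rng = np.random.default_rng(3)
    frame, _ = _signal_frame(rng, n=60, n_cands=2)
    y = rng.normal(size=60)
    res = g.exhaustive_search(frame, y, ["age", "PF"], SMALL, seed=0)
    assert res.n_enumerated == 3 ** 2 * 2


def test_exhaustive_with_no_candidates_compares_intercept_and_sex():
    rng = np.random.default_rng(4)
    frame, _ = _signal_frame(rng, n=60, n_cands=1)
    codes = np.where(frame["sex"] == "male", 1.0, -1.0)
    y = 0.8 * codes + rng.normal(size=60)
    res = g.exhaustive_search(frame, y, [], SMALL, seed=0)
    assert res.n_enumerated == 2
    assert res.spec.key() == ((), True)  # sex-only model wins


def test_ga_matches_exhaustive_on_small_pools():
    rng = np.random.default_rng(5)
    frame, names = _signal_frame(rng, n=120, n_cands=3)
    codes = np.where(frame["sex"] == "male", 1.0, -1.0)
    y = (0.5 * frame["age"].to_numpy() + 0.3 * frame["PF"].to_numpy() * codes
         + rng.normal(size=120))
    agree = 0
    for seed in range(3):
        oracle = g.exhaustive_search(frame, y, names, SMALL, seed=seed)
        spec, fit = g.run_ga(frame, y, names, SMALL, seed=seed)
        agree += fit == pytest.approx(oracle.fitness, abs=1e-12)
    assert agree == 3


def test_zero_generations_returns_best_of_initial_population():
    rng = np.random.default_rng(6)
    frame, names = _signal_frame(rng, n=80, n_cands=2)
    y = rng.normal(size=80)
    cfg = g.GAConfig(population_size=12, max_generations=0)
    spec, fit = g.run_ga(frame, y, names, cfg, seed=0)
    oracle = g.exhaustive_search(frame, y, names, cfg, seed=0)
    worst = min(
        g.cv_fitness(s, frame, y, seed=0) for s in [ModelSpec(), oracle.spec])
    assert fit >= worst - 1e-12
    assert fit <= oracle.fitness + 1e-12


def test_run_ga_fully_reproducible():
    rng = np.random.default_rng(7)
    frame, names = _signal_frame(rng, n=100)
    y = 0.4 * frame["age"].to_numpy() + rng.normal(size=100)
    r1 = g.run_ga(frame, y, names, SMALL, seed=3)
    r2 = g.run_ga(frame, y, names, SMALL, seed=3)
    assert r1[0].key() == r2[0].key() and r1[1] == r2[1]


def test_epoch_consensus_on_dominant_landscape():
    rng = np.random.default_rng(8)
    frame, names = _signal_frame(rng, n=185, n_cands=4)
    y = 1.2 * frame["age"].to_numpy() + 0.3 * rng.normal(size=185)
    res = g.run_epochs(frame, y, names, SMALL, n_epochs=5, base_seed=0)
    assert res.modal_spec.kind("age") == COMMON
    assert res.n1cv == 5
    assert not res.tie
    assert 0 < res.n1cv <= 5
    assert res.r2 > 0.8


def test_epoch_tie_is_flagged():
    # two identical covariate columns: the two single-covariate specs are
    # exactly equally fit, so epochs split between them
    rng = np.random.default_rng(9)
    frame, _ = _signal_frame(rng, n=100, n_cands=1)
    frame = frame.copy()
    frame["age2"] = frame["age"]
    y = 1.0 * frame["age"].to_numpy() + 0.5 * rng.normal(size=100)
    cfg = g.GAConfig(population_size=16, max_generations=30, patience=30)
    res = g.run_epochs(frame, y, ["age", "age2"], cfg, n_epochs=4,
                       base_seed=0)
    counts = {}
    for s in res.epoch_specs:
        counts[s.key()] = counts.get(s.key(), 0) + 1
    top = sorted(counts.values(), reverse=True)
    if len(top) > 1 and top[0] == top[1]:
        assert res.tie
    else:
        assert not res.tie


def test_selector_estimator_interface(cohort185):
    cohort, y = cohort185
    sel = g.GAAncovaSelector(candidates=["age", "PF", "Se", "vitD"],
                             config=SMALL, n_epochs=2, base_seed=0)
    sel.fit(cohort.data, y)
    assert hasattr(sel, "best_spec_") and 0 < sel.n1cv_ <= 2
    pred = sel.predict(cohort.data)
    assert pred.shape == y.shape
    # sklearn params protocol
    params = sel.get_params()
    assert params["n_epochs"] == 2


def test_invalid_config_rejected():
    with pytest.raises(ValueError):
        g.GAConfig(population_size=0)
    with pytest.raises(ValueError):
        g.GAConfig(crossover_prob=1.5)
    with pytest.raises(ValueError):
        g.GAConfig(cv_folds=1)


def test_spec_over_max_terms_rejected_by_fitness():
    rng = np.random.default_rng(10)
    frame, names = _signal_frame(rng, n=80, n_cands=4)
    y = rng.normal(size=80)
    spec = ModelSpec(tuple((n, COMMON) for n in names))
    with pytest.raises(ValueError, match="max_terms"):
        g.cv_fitness(spec, frame, y, seed=0, max_terms=2)
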