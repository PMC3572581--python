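"""One-command orchestration of the full analysis.

Pipeline order (enforced): load/simulate -> cohort summary -> gene QC ->
autoscaling -> PCA1 -> correlation reports -> per-response GA epochs ->
double cross-validation -> summary table.  Every stochastic stage
derives its seed from the base seed and logs it, so a rerun with the
same config and seed is byte-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .cohort import (GENE_LOCI, LINE1, CohortTable, MethylationPanel,
                     autoscale_panel, compute_pca1, qc_filter_genes,
                     summarize_cohort)
from .correlations import intergene_matrix, pearson_strata
from .doublecv import cv_pass_fail, double_cross_validate
from .ga import GAConfig, run_epochs
from .io import load_cohort, read_schema
from .simulate import SyntheticTruth, default_truth, generate_cohort


@dataclass
class RunConfig:
    """Resolved settings of one pipeline run."""

    input_path: str | None = None
    schema_path: str | None = None
    truth: SyntheticTruth | str | None = None
    n_subjects: int = 185
    candidates: list | None = None
    ga: GAConfig = field(default_factory=GAConfig)
    n_epochs: int = 10
    outer_folds: int = 7
    inner_epochs: int = 3
    n_bootstrap: int = 1000
    qc_median_floor: float = 1.0
    qc_alpha: float = 0.05
    seed: int = 0
    out_dir: str = "gancova_out"


class PipelineError(RuntimeError):
    """An analysis stage failed; the message carries the stage tag."""


def _stage(tag):
    def wrap(fn):
        def inner(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:  # noqa: BLE001 - stage-tagged rethrow
                raise PipelineError(f"[{tag}] {exc}") from exc
        return inner
    return wrap


_FMT = "%.6g"


def _derived_seeds(base_seed: int, labels: list) -> dict:
    children = np.random.SeedSequence(int(base_seed)).spawn(len(labels))
    return {lab: int(c.generate_state(1)[0] % (2 ** 31))
            for lab, c in zip(labels, children)}


@_stage("input")
def _load_input(config: RunConfig, seed: int) -> tuple:
    if config.input_path is not None:
        schema = read_schema(config.schema_path) if config.schema_path else None
        return load_cohort(config.input_path, schema)
    truth = config.truth
    if truth is None:
        truth = default_truth()
    elif isinstance(truth, (str, Path)):
        truth = SyntheticTruth.load(truth)
    return generate_cohort(truth, config.n_subjects, seed=seed)


def run_full_analysis(config: RunConfig) -> dict:
    """Run the whole pipeline and write the report bundle to ``out_dir``.

    Returns a dict with the in-memory results (summary frame, QC report,
    per-response selection and CV results) for programmatic use.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_lines = []

    def log(msg):
        log_lines.append(str(msg))

    responses_labels = None
    seeds = _derived_seeds(config.seed, ["input"])
    log(f"base seed: {config.seed}")
    log(f"input seed: {seeds['input']}")
    cohort, panel = _load_input(config, seeds["input"])
    log(f"subjects: {cohort.n_subjects} "
        f"({cohort.n_by_sex['male']} male / {cohort.n_by_sex['female']} female)")

    # Table-1-style summary
    summary1 = summarize_cohort(cohort)
    summary1.to_csv(out / "table1_summary.csv", float_format=_FMT)

    # gene QC
    age = cohort.data["age"].to_numpy()
    try:
        kept_panel, qc = qc_filter_genes(panel, age, config.qc_median_floor,
                                         config.qc_alpha)
    except Exception as exc:
        raise PipelineError(f"[qc] {exc}") from exc
    qc.table.to_csv(out / "qc_report.csv", index=False, float_format=_FMT)
    for _, row in qc.table[~qc.table["kept"]].iterrows():
        log(f"excluded locus {row['locus']}: {row['reason']}")

    # autoscaling and PCA1
    try:
        scaled = autoscale_panel(kept_panel)
        gene_cols = [c for c in scaled.values.columns if c != LINE1]
        pca1 = compute_pca1(scaled.values[gene_cols]) if len(gene_cols) >= 2 \
            else None
    except Exception as exc:
        raise PipelineError(f"[scaling] {exc}") from exc

    responses = scaled.values.copy()
    if pca1 is not None:
        responses["PCA1"] = pca1.scores
        log(f"PCA1: {len(pca1.subjects)} complete cases, "
            f"variance explained {pca1.variance_explained:.3f}")

    # correlation reports
    try:
        strata = pearson_strata(cohort, responses)
        for name, report in strata.items():
            report.to_long(stars_at=(0.001, 0.01, 0.05)).to_csv(
                out / f"correlations_{name}.csv", index=False,
                float_format=_FMT)
        if len(gene_cols) >= 2:
            inter, _stars = intergene_matrix(scaled.values[gene_cols])
            inter.to_long(stars_at=(0.001, 0.01, 0.05)).to_csv(
                out / "correlations_intergene.csv", index=False,
                float_format=_FMT)
    except Exception as exc:
        raise PipelineError(f"[correlations] {exc}") from exc

    # per-response modelling
    candidates = (list(config.candidates) if config.candidates is not None
                  else [c for c in cohort.data.columns if c != "sex"])
    responses_labels = list(responses.columns)
    model_seeds = _derived_seeds(config.seed + 1,
                                 [f"ga_{r}" for r in responses_labels] +
                                 [f"cv_{r}" for r in responses_labels])
    rows = []
    details = {}
    for label in responses_labels:
        y_all = responses[label]
        keep = y_all.notna()
        sub = CohortTable(cohort.data.loc[keep])
        y = y_all[keep].to_numpy(dtype=float)
        ga_seed = model_seeds[f"ga_{label}"]
        cv_seed = model_seeds[f"cv_{label}"]
        log(f"response {label}: n={keep.sum()} ga_seed={ga_seed} "
            f"cv_seed={cv_seed}")
        try:
            sel = run_epochs(sub, y, candidates, config.ga,
                             n_epochs=config.n_epochs, base_seed=ga_seed)
            cv = double_cross_validate(sub, y, candidates, config.ga,
                                       outer_folds=config.outer_folds,
                                       seed=cv_seed,
                                       inner_epochs=config.inner_epochs,
                                       n_bootstrap=config.n_bootstrap)
        except Exception as exc:
            raise PipelineError(f"[model:{label}] {exc}") from exc
        passed, cell = cv_pass_fail(cv)
        rows.append({
            "response": label,
            "n": int(keep.sum()),
            "terms": ", ".join(sel.ordered_terms()) or "(intercept only)",
            "n1CV": sel.n1cv,
            "tie": int(sel.tie),
            "R2": f"{sel.r2:.3f}",
            "cv2_explained_variance": cell,
            "cv2_pass": int(passed),
        })
        details[label] = {"selection": sel, "cv": cv}
    summary = pd.DataFrame(rows)
    summary.to_csv(out / "summary.csv", index=False)

    (out / "run_log.txt").write_text("\n".join(log_lines) + "\n",
                                     encoding="utf-8")
    resolved = {
        "seed": config.seed,
        "n_epochs": config.n_epochs,
        "outer_folds": config.outer_folds,
        "inner_epochs": config.inner_epochs,
        "n_bootstrap": config.n_bootstrap,
        "qc_median_floor": config.qc_median_floor,
        "qc_alpha": config.qc_alpha,
        "candidates": candidates,
        "responses": responses_labels,
        "ga": {k: getattr(config.ga, k) for k in
               ("population_size", "max_generations", "tournament_size",
                "crossover_prob", "mutation_prob", "elitism", "patience",
                "cv_folds", "cv_repeats", "complexity_penalty", "max_terms")},
    }
    with open(out / "config_resolved.yaml", "w", encoding="utf-8") as fh:
        yaml.safe_dump(resolved, fh, sort_keys=True)
    return {"summary": summary, "qc": qc, "table1": summary1,
            "details": details, "cohort": cohort, "panel": panel}
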