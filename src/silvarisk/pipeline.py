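"""End-to-end rule-model analysis of an adenocarcinoma cohort.

The pipeline mirrors the study design it implements: exclude high-risk
patients (nodal, margin or parametrial disease), screen the candidate
dichotomized variables by univariate Cox regression on recurrence-free
survival, enumerate the Silva-based four-/three-/two-factor model
families, evaluate every model and the Sedlis criteria (univariate Cox
HR with 95% CI and p, two-group log-rank chi-square, Harrell's C with
bootstrap CI), rank by discrimination, and drill down the best model's
k-subsets.  :class:`RuleModelSearch` packages the same flow as a
scikit-learn-style estimator whose ``fit`` evaluates all models and
whose ``predict`` applies the best one.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import zlib
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .cohort import (
    Cohort,
    CutoffConfig,
    CutoffVariable,
    factor_value,
    filter_intermediate,
    is_high_risk,
    make_cutoff_variables,
)
from .rules import (
    EnumerationConfig,
    RuleModel,
    apply_rule,
    enumerate_all_models,
    model_label,
    sedlis_from_record,
    sedlis_positive,
)
from .survival import (
    CoxPHModel,
    CoxResult,
    SurvivalSample,
    harrell_c,
    logrank,
)

__all__ = [
    "AnalysisConfig",
    "ModelEvaluation",
    "ScreenedVariable",
    "AnalysisReport",
    "CollinearityError",
    "RuleModelSearch",
    "cohort_sample",
    "univariate_screen",
    "multivariate_fit",
    "evaluate_model",
    "evaluate_sedlis",
    "rank_models",
    "drilldown_best",
    "run_full_analysis",
]

logger = logging.getLogger(__name__)

SEDLIS_MODEL_ID = "sedlis"


class CollinearityError(ValueError):
    """The joint design matrix is singular; names the offending columns."""


@dataclass(frozen=True)
class AnalysisConfig:
    """Knobs of the full analysis; defaults follow the study design."""

    endpoint: str = "rfs"  # screening/evaluation endpoint
    alpha: float = 0.05  # two-sided screening significance level
    force_include: tuple[str, ...] = ("silva_BC",)
    seed: int = 0
    n_bootstrap: int = 200  # C-index bootstrap replicates per evaluation
    ties: str = "efron"
    evaluate_full_cohort: bool = False  # skip high-risk exclusion (sensitivity)
    cutoffs: CutoffConfig = field(default_factory=CutoffConfig)
    enumeration: EnumerationConfig = field(default_factory=EnumerationConfig)

    def replace(self, **changes) -> "AnalysisConfig":
        return dataclasses.replace(self, **changes)


@dataclass(frozen=True)
class ScreenedVariable:
    """A candidate variable with its univariate Cox statistics."""

    variable: CutoffVariable
    hr: float
    ci_low: float
    ci_high: float
    p_value: float
    n_positive: int
    retained: bool
    forced: bool
    degenerate: bool


@dataclass(frozen=True)
class ModelEvaluation:
    """Evaluation of one decision rule on one cohort."""

    model_id: str
    family: str
    label: str
    k: int
    hr: float
    ci_low: float
    ci_high: float
    cox_p: float
    chi_square: float
    logrank_p: float
    c_index: float
    c_ci_low: float
    c_ci_high: float
    n_positive: int
    n_negative: int
    events_positive: int
    events_negative: int
    degenerate: bool


@dataclass(frozen=True)
class AnalysisReport:
    """Everything one run produces, serializable to TSV tables + JSON."""

    n_total: int
    n_intermediate: int
    n_high_risk: int
    endpoint: str
    seed: int
    n_tests_screen: int
    screen: tuple[ScreenedVariable, ...]
    evaluations: tuple[ModelEvaluation, ...]  # 58 models + Sedlis
    ranking: tuple[str, ...]  # model_ids, best first
    best_model_id: str
    drilldown: tuple[ModelEvaluation, ...]
    ranking_disagreement: bool  # C-index winner differs from chi-square winner

    def evaluation_by_id(self, model_id: str) -> ModelEvaluation:
        for ev in self.evaluations:
            if ev.model_id == model_id:
                return ev
        raise KeyError(model_id)

    # -- serialization ------------------------------------------------

    def screen_frame(self) -> pd.DataFrame:
        rows = [
            {
                "name": s.variable.name,
                "factor": s.variable.factor,
                "hr": s.hr,
                "ci_low": s.ci_low,
                "ci_high": s.ci_high,
                "p_value": s.p_value,
                "n_positive": s.n_positive,
                "retained": int(s.retained),
                "forced": int(s.forced),
                "degenerate": int(s.degenerate),
            }
            for s in self.screen
        ]
        return pd.DataFrame(rows)

    def evaluations_frame(self, family: str | None = None) -> pd.DataFrame:
        evs = [e for e in self.evaluations if family is None or e.family == family]
        return pd.DataFrame([dataclasses.asdict(e) for e in evs])

    def ranking_frame(self) -> pd.DataFrame:
        by_id = {e.model_id: e for e in self.evaluations}
        rows = []
        for rank, mid in enumerate(self.ranking, start=1):
            row = dataclasses.asdict(by_id[mid])
            rows.append({"rank": rank, **row})
        return pd.DataFrame(rows)

    def summary_dict(self) -> dict:
        best = self.evaluation_by_id(self.best_model_id)
        sedlis = self.evaluation_by_id(SEDLIS_MODEL_ID)
        return {
            "n_total": self.n_total,
            "n_intermediate": self.n_intermediate,
            "n_high_risk": self.n_high_risk,
            "endpoint": self.endpoint,
            "seed": self.seed,
            "n_tests_screen": self.n_tests_screen,
            "n_evaluations": len(self.evaluations),
            "n_models": len(self.evaluations) - 1,
            "retained_variables": [
                s.variable.name for s in self.screen if s.retained
            ],
            "best_model_id": self.best_model_id,
            "best_model_label": best.label,
            "best_model": dataclasses.asdict(best),
            "sedlis": dataclasses.asdict(sedlis),
            "ranking": list(self.ranking),
            "ranking_disagreement": self.ranking_disagreement,
            "n_drilldown": len(self.drilldown),
        }

    def write(self, outdir: str | Path) -> Path:
        """Write TSV tables and a JSON summary; deterministic bytes."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        kwargs = dict(sep="\t", index=False, float_format="%.10g", lineterminator="\n")
        self.screen_frame().to_csv(outdir / "screen.tsv", **kwargs)
        for family in ("four_factor", "three_factor", "two_factor"):
            self.evaluations_frame(family).to_csv(
                outdir / f"models_{family}.tsv", **kwargs
            )
        self.ranking_frame().to_csv(outdir / "ranking.tsv", **kwargs)
        pd.DataFrame([dataclasses.asdict(e) for e in self.drilldown]).to_csv(
            outdir / "drilldown.tsv", **kwargs
        )
        with open(outdir / "summary.json", "w", encoding="utf-8") as fh:
            json.dump(self.summary_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")
        return outdir


# ---------------------------------------------------------------------------
# Survival-sample construction


def cohort_sample(
    cohort: Cohort,
    endpoint: str = "rfs",
    covariates: np.ndarray | None = None,
) -> SurvivalSample:
    """Extract (times, events) for the chosen endpoint."""
    if endpoint == "rfs":
        t = np.array([r.rfs_time for r in cohort])
        e = np.array([r.rfs_event for r in cohort])
    elif endpoint == "os":
        t = np.array([r.os_time for r in cohort])
        e = np.array([r.os_event for r in cohort])
    else:
        raise ValueError(f"endpoint must be 'rfs' or 'os', got {endpoint!r}")
    return SurvivalSample(times=t, events=e, covariates=covariates)


def _indicator(cohort: Cohort, variable: CutoffVariable) -> np.ndarray:
    return np.array([factor_value(r, variable) for r in cohort], dtype=float)


# ---------------------------------------------------------------------------
# Screening and multivariate fit


def univariate_screen(
    cohort: Cohort,
    variables: Sequence[CutoffVariable],
    endpoint: str = "rfs",
    alpha: float = 0.05,
    force_include: Sequence[str] = (),
    ties: str = "efron",
) -> list[ScreenedVariable]:
    """Univariate Cox screen: keep variables with p < alpha, plus the
    forced ones, each carrying its HR / CI / p.

    Variables that are constant in the cohort are excluded with a
    logged warning (their partial likelihood carries no information).
    Returns the full annotated table; retained entries are flagged.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    forced = set(force_include)
    out: list[ScreenedVariable] = []
    for var in variables:
        ind = _indicator(cohort, var)
        n_pos = int(ind.sum())
        if ind.min() == ind.max():
            logger.warning(
                "screen: variable %s is constant in the cohort; excluded", var.name
            )
            out.append(
                ScreenedVariable(var, np.nan, np.nan, np.nan, np.nan,
                                 n_pos, False, var.name in forced, True)
            )
            continue
        sample = cohort_sample(cohort, endpoint, covariates=ind[:, None])
        model = CoxPHModel(ties=ties).fit(sample.covariates, (sample.times, sample.events))
        p = float(model.p_values_[0])
        retained = p < alpha or var.name in forced
        out.append(
            ScreenedVariable(
                variable=var,
                hr=float(model.hazard_ratios_[0]),
                ci_low=float(model.ci_low_[0]),
                ci_high=float(model.ci_high_[0]),
                p_value=p,
                n_positive=n_pos,
                retained=retained and not model.degenerate_,
                forced=var.name in forced,
                degenerate=bool(model.degenerate_),
            )
        )
    return out


def retained_variables(screen: Sequence[ScreenedVariable]) -> list[CutoffVariable]:
    return [s.variable for s in screen if s.retained]


def multivariate_fit(
    cohort: Cohort,
    variables: Sequence[CutoffVariable],
    endpoint: str = "rfs",
    ties: str = "efron",
) -> CoxResult:
    """Joint Cox fit over all variable indicators.

    Exactly collinear indicator columns raise :class:`CollinearityError`
    naming the columns; overlapping (nested) indicators such as
    Silva B+C with Silva C are permitted but logged.
    """
    if len(variables) < 2:
        raise ValueError("multivariate fit requires at least two variables")
    X = np.column_stack([_indicator(cohort, v) for v in variables])
    names = [v.name for v in variables]
    for i, j in combinations(range(len(names)), 2):
        if np.array_equal(X[:, i], X[:, j]):
            raise CollinearityError(
                f"indicator columns {names[i]!r} and {names[j]!r} are identical"
            )
        if np.all(X[:, i] >= X[:, j]) or np.all(X[:, j] >= X[:, i]):
            logger.info(
                "multivariate: %s and %s are nested indicators", names[i], names[j]
            )
    centered = X - X.mean(axis=0)
    rank = np.linalg.matrix_rank(centered)
    if rank < X.shape[1]:
        raise CollinearityError(
            f"design matrix of {names} is rank-deficient (rank {rank} < {X.shape[1]})"
        )
    cond = float(np.linalg.cond(centered.T @ centered))
    logger.info("multivariate: information-matrix condition number %.3g", cond)
    sample = cohort_sample(cohort, endpoint, covariates=X)
    model = CoxPHModel(ties=ties).fit(sample.covariates, (sample.times, sample.events))
    return model.result_()


# ---------------------------------------------------------------------------
# Model evaluation


def _bootstrap_seed(seed: int, model_id: str) -> int:
    return (seed * 1_000_003 + zlib.crc32(model_id.encode())) % (2**31 - 1)


def _evaluate_indicator(
    cohort: Cohort,
    indicator: np.ndarray,
    model_id: str,
    family: str,
    label: str,
    k: int,
    endpoint: str,
    n_bootstrap: int,
    seed: int,
    ties: str,
) -> ModelEvaluation:
    sample = cohort_sample(cohort, endpoint)
    ind = indicator.astype(bool)
    n_pos = int(ind.sum())
    n_neg = int((~ind).sum())
    ev_pos = int(sample.events[ind].sum())
    ev_neg = int(sample.events[~ind].sum())
    degenerate = n_pos == 0 or n_neg == 0 or ev_pos + ev_neg == 0

    hr = ci_low = ci_high = cox_p = np.nan
    chi = lr_p = np.nan
    c = c_lo = c_hi = np.nan
    if not degenerate:
        model = CoxPHModel(ties=ties).fit(
            ind.astype(float)[:, None], (sample.times, sample.events)
        )
        hr = float(model.hazard_ratios_[0])
        ci_low = float(model.ci_low_[0])
        ci_high = float(model.ci_high_[0])
        cox_p = float(model.p_values_[0])
        degenerate = degenerate or model.degenerate_
        lr = logrank(
            SurvivalSample(sample.times[~ind], sample.events[~ind]),
            SurvivalSample(sample.times[ind], sample.events[ind]),
        )
        chi, lr_p = float(lr.chi_square), float(lr.p_value)
        degenerate = degenerate or lr.degenerate
        try:
            conc = harrell_c(
                ind.astype(float),
                sample,
                n_bootstrap=n_bootstrap,
                seed=_bootstrap_seed(seed, model_id),
            )
            c, c_lo, c_hi = conc.c_index, conc.ci_low, conc.ci_high
        except ValueError:
            degenerate = True
    return ModelEvaluation(
        model_id=model_id,
        family=family,
        label=label,
        k=k,
        hr=hr,
        ci_low=ci_low,
        ci_high=ci_high,
        cox_p=cox_p,
        chi_square=chi,
        logrank_p=lr_p,
        c_index=c,
        c_ci_low=c_lo,
        c_ci_high=c_hi,
        n_positive=n_pos,
        n_negative=n_neg,
        events_positive=ev_pos,
        events_negative=ev_neg,
        degenerate=bool(degenerate),
    )


def evaluate_model(
    cohort: Cohort,
    model: RuleModel,
    endpoint: str = "rfs",
    n_bootstrap: int = 200,
    seed: int = 0,
    ties: str = "efron",
) -> ModelEvaluation:
    """Apply a rule to every record and evaluate the binary split."""
    if len(cohort) == 0:
        raise ValueError("cannot evaluate a model on an empty cohort")
    indicator = np.array([apply_rule(model, r) for r in cohort], dtype=float)
    return _evaluate_indicator(
        cohort,
        indicator,
        model.model_id,
        model.family,
        model_label(model),
        model.k,
        endpoint,
        n_bootstrap,
        seed,
        ties,
    )


def evaluate_sedlis(
    cohort: Cohort,
    endpoint: str = "rfs",
    n_bootstrap: int = 200,
    seed: int = 0,
    ties: str = "efron",
) -> ModelEvaluation:
    """Evaluate the Sedlis criteria with the same machinery."""
    if len(cohort) == 0:
        raise ValueError("cannot evaluate a model on an empty cohort")
    indicator = np.array(
        [sedlis_positive(sedlis_from_record(r)) for r in cohort], dtype=float
    )
    return _evaluate_indicator(
        cohort,
        indicator,
        SEDLIS_MODEL_ID,
        "sedlis",
        "Sedlis criteria",
        0,
        endpoint,
        n_bootstrap,
        seed,
        ties,
    )


def rank_models(evaluations: Sequence[ModelEvaluation]) -> list[ModelEvaluation]:
    """Descending C-index, chi-square tiebreak, then model_id;
    degenerate evaluations rank last."""
    if not evaluations:
        raise ValueError("nothing to rank")

    def key(ev: ModelEvaluation):
        c = ev.c_index if np.isfinite(ev.c_index) else -np.inf
        chi = ev.chi_square if np.isfinite(ev.chi_square) else -np.inf
        return (ev.degenerate, -c, -chi, ev.model_id)

    return sorted(evaluations, key=key)


def drilldown_best(
    cohort: Cohort,
    model: RuleModel,
    endpoint: str = "rfs",
    n_bootstrap: int = 200,
    seed: int = 0,
    ties: str = "efron",
) -> list[ModelEvaluation]:
    """Evaluate every all-of-subset rule of size k inside the model.

    An any-3-of-4 rule yields its four 3-factor combinations, each
    scored as "patient positive iff all subset factors present".
    """
    out = []
    for subset in combinations(model.variables, model.k):
        sub = RuleModel(
            model_id=f"{model.model_id}>all:{'+'.join(subset)}",
            family=model.family,
            variables=subset,
            k=len(subset),
        )
        indicator = np.array([apply_rule(sub, r) for r in cohort], dtype=float)
        label = "All of: " + model_label(sub).split(": ", 1)[1]
        out.append(
            _evaluate_indicator(
                cohort,
                indicator,
                sub.model_id,
                model.family,
                label,
                sub.k,
                endpoint,
                n_bootstrap,
                seed,
                ties,
            )
        )
    return out


# ---------------------------------------------------------------------------
# Full pipeline


def run_full_analysis(cohort: Cohort, config: AnalysisConfig | None = None) -> AnalysisReport:
    """High-risk exclusion -> screen -> enumerate -> evaluate -> rank
    -> drill down.  Deterministic given cohort + config."""
    config = config or AnalysisConfig()
    n_total = len(cohort)
    analysis_cohort = cohort if config.evaluate_full_cohort else filter_intermediate(cohort)
    if len(analysis_cohort) == 0:
        raise ValueError(
            "no patients remain after high-risk exclusion; nothing to analyze"
        )
    n_high_risk = sum(is_high_risk(r) for r in cohort)

    candidates = make_cutoff_variables(config.cutoffs)
    screen = univariate_screen(
        analysis_cohort,
        candidates,
        endpoint=config.endpoint,
        alpha=config.alpha,
        force_include=config.force_include,
        ties=config.ties,
    )

    models = enumerate_all_models(config.enumeration)
    evaluations = [
        evaluate_model(
            analysis_cohort,
            m,
            endpoint=config.endpoint,
            n_bootstrap=config.n_bootstrap,
            seed=config.seed,
            ties=config.ties,
        )
        for m in models
    ]
    evaluations.append(
        evaluate_sedlis(
            analysis_cohort,
            endpoint=config.endpoint,
            n_bootstrap=config.n_bootstrap,
            seed=config.seed,
            ties=config.ties,
        )
    )

    ranked = rank_models(evaluations)
    ranking = tuple(e.model_id for e in ranked)
    best = next((e for e in ranked if e.model_id != SEDLIS_MODEL_ID), ranked[0])
    by_chi = max(
        (e for e in evaluations if e.model_id != SEDLIS_MODEL_ID and not e.degenerate),
        key=lambda e: e.chi_square if np.isfinite(e.chi_square) else -np.inf,
        default=best,
    )
    disagreement = by_chi.model_id != best.model_id
    if disagreement:
        logger.info(
            "ranking: C-index winner %s differs from chi-square winner %s",
            best.model_id,
            by_chi.model_id,
        )

    best_model = next(m for m in models if m.model_id == best.model_id)
    if best_model.k < len(best_model.variables):
        drill = drilldown_best(
            analysis_cohort,
            best_model,
            endpoint=config.endpoint,
            n_bootstrap=config.n_bootstrap,
            seed=config.seed,
            ties=config.ties,
        )
    else:
        drill = [best]

    return AnalysisReport(
        n_total=n_total,
        n_intermediate=n_total - n_high_risk,
        n_high_risk=n_high_risk,
        endpoint=config.endpoint,
        seed=config.seed,
        n_tests_screen=sum(1 for s in screen if not s.degenerate),
        screen=tuple(screen),
        evaluations=tuple(evaluations),
        ranking=ranking,
        best_model_id=best.model_id,
        drilldown=tuple(drill),
        ranking_disagreement=disagreement,
    )


class RuleModelSearch(BaseEstimator):
    """Exhaustive rule-model search as a scikit-learn-style estimator.

    ``fit(cohort)`` runs the full analysis; fitted attributes expose
    the per-model evaluations (``evaluations_``), the ranking
    (``ranking_``), the winning rule (``best_model_``) and the whole
    report (``report_``).  ``predict(cohort)`` applies the winning rule.
    """

    def __init__(self, config: AnalysisConfig | None = None) -> None:
        self.config = config

    def fit(self, X: Cohort, y=None) -> "RuleModelSearch":
        report = run_full_analysis(X, self.config)
        self.report_ = report
        self.evaluations_ = report.evaluations
        self.ranking_ = report.ranking
        config = self.config or AnalysisConfig()
        models = enumerate_all_models(config.enumeration)
        self.best_model_ = next(
            m for m in models if m.model_id == report.best_model_id
        )
        return self

    def predict(self, X: Cohort) -> np.ndarray:
        return np.array([apply_rule(self.best_model_, r) for r in X], dtype=bool)
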