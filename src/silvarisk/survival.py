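"""Censored-survival statistics implemented from first principles.

Provides the four primitives every rule-model evaluation in this
package rests on: the Kaplan–Meier product-limit estimator, the
two-group log-rank test, Cox proportional-hazards regression by
Newton–Raphson on the partial likelihood (Efron or Breslow tie
handling), and Harrell's concordance index with a percentile-bootstrap
confidence interval.  The Cox solver is exposed both as a
scikit-learn-style estimator (:class:`CoxPHModel`) and as the thin
functional wrapper :func:`cox_fit`.

Times are months throughout; event flags are 1 for an observed event
and 0 for censoring at the recorded time.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator

__all__ = [
    "SurvivalSample",
    "KMCurve",
    "LogRankResult",
    "CoxResult",
    "ConcordanceResult",
    "CoxPHModel",
    "km_curve",
    "survival_at",
    "logrank",
    "cox_fit",
    "harrell_c",
    "three_year_rate",
]

#: coefficient magnitude at which a fit is declared separated (monotone
#: partial likelihood); the diverging coefficient is reported capped here.
COEF_CAP = 15.0


@dataclass(frozen=True)
class SurvivalSample:
    """Aligned times / event flags, with optional covariate columns."""

    times: np.ndarray
    events: np.ndarray
    covariates: np.ndarray | None = None

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        events = np.asarray(self.events, dtype=bool)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "events", events)
        if times.ndim != 1 or events.shape != times.shape:
            raise ValueError("times and events must be equal-length 1-d arrays")
        if times.size and not np.all(times > 0):
            raise ValueError("all times must be strictly positive")
        if self.covariates is not None:
            X = np.atleast_2d(np.asarray(self.covariates, dtype=float))
            if X.shape[0] != times.size:
                X = X.T
            if X.shape[0] != times.size:
                raise ValueError("covariate rows must align with times")
            object.__setattr__(self, "covariates", X)

    def __len__(self) -> int:
        return int(self.times.size)


@dataclass(frozen=True)
class KMCurve:
    event_times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray


@dataclass(frozen=True)
class LogRankResult:
    chi_square: float
    df: int
    p_value: float
    degenerate: bool = False


@dataclass(frozen=True)
class CoxResult:
    coef: np.ndarray
    hr: np.ndarray
    se: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    p_values: np.ndarray
    loglik: float
    iterations: int
    converged: bool
    degenerate: bool


@dataclass(frozen=True)
class ConcordanceResult:
    c_index: float
    ci_low: float
    ci_high: float
    n_comparable: int
    n_tied_score: int


# ---------------------------------------------------------------------------
# Kaplan–Meier


def km_curve(sample: SurvivalSample) -> KMCurve:
    """Product-limit survival estimate over the distinct event times."""
    if len(sample) == 0:
        raise ValueError("cannot estimate a survival curve from an empty sample")
    order = np.argsort(sample.times, kind="stable")
    t = sample.times[order]
    e = sample.events[order]
    n = t.size
    uniq, start = np.unique(t, return_index=True)
    counts = np.diff(np.append(start, n))
    deaths = np.add.reduceat(e.astype(float), start)
    at_risk = n - start  # subjects with time >= uniq (sorted ascending)
    mask = deaths > 0
    ev_times = uniq[mask]
    d = deaths[mask]
    r = at_risk[mask].astype(float)
    surv = np.cumprod(1.0 - d / r)
    return KMCurve(event_times=ev_times, survival=surv, at_risk=r.astype(int))


def survival_at(curve: KMCurve, t: float) -> float:
    """Right-continuous step-function evaluation of a KM curve."""
    if t < 0:
        raise ValueError("time must be non-negative")
    idx = int(np.searchsorted(curve.event_times, t, side="right"))
    return 1.0 if idx == 0 else float(curve.survival[idx - 1])


def three_year_rate(sample: SurvivalSample) -> float:
    """Kaplan–Meier survival probability at 36 months."""
    return survival_at(km_curve(sample), 36.0)


# ---------------------------------------------------------------------------
# Log-rank test


def logrank(group_a: SurvivalSample, group_b: SurvivalSample) -> LogRankResult:
    """Two-group log-rank test: sum of (O - E) with hypergeometric
    variance at each distinct event time, chi-square with 1 df."""
    if len(group_a) == 0 or len(group_b) == 0:
        raise ValueError("both groups must be non-empty")
    t = np.concatenate([group_a.times, group_b.times])
    e = np.concatenate([group_a.events, group_b.events])
    g = np.concatenate([np.zeros(len(group_a), bool), np.ones(len(group_b), bool)])
    if not e.any():
        return LogRankResult(chi_square=0.0, df=1, p_value=1.0, degenerate=True)
    obs_minus_exp = 0.0
    variance = 0.0
    for tau in np.unique(t[e]):
        at_risk = t >= tau
        n_j = float(at_risk.sum())
        n_1j = float((at_risk & ~g).sum())
        d_j = float((e & (t == tau)).sum())
        d_1j = float((e & (t == tau) & ~g).sum())
        obs_minus_exp += d_1j - d_j * n_1j / n_j
        if n_j > 1:
            variance += d_j * (n_1j / n_j) * (1 - n_1j / n_j) * (n_j - d_j) / (n_j - 1)
    if variance <= 0:
        return LogRankResult(chi_square=0.0, df=1, p_value=1.0, degenerate=True)
    chi = obs_minus_exp**2 / variance
    return LogRankResult(
        chi_square=float(chi), df=1, p_value=float(stats.chi2.sf(chi, 1)), degenerate=False
    )


# ---------------------------------------------------------------------------
# Cox proportional hazards


def _cox_quantities(
    beta: np.ndarray,
    X: np.ndarray,
    start: np.ndarray,
    d: np.ndarray,
    e: np.ndarray,
    ties: str,
) -> tuple[float, np.ndarray, np.ndarray]:
    """Partial log-likelihood, score and observed information.

    ``X`` must be sorted ascending in time; ``start`` marks the first
    index of each distinct time, ``d`` the event count there.
    """
    n, p = X.shape
    eta = X @ beta
    shift = float(np.max(eta)) if n else 0.0
    w = np.exp(eta - shift)
    wX = w[:, None] * X
    wXX = wX[:, :, None] * X[:, None, :]
    # suffix (risk-set) sums at each distinct-time start index
    rw = np.cumsum(w[::-1])[::-1]
    rwx = np.cumsum(wX[::-1], axis=0)[::-1]
    rwxx = np.cumsum(wXX[::-1], axis=0)[::-1]

    ef = e.astype(float)
    d_all = d
    sum_eta_d = np.add.reduceat(ef * eta, start)
    s = np.add.reduceat(ef[:, None] * X, start, axis=0)
    wd = np.add.reduceat(ef * w, start)
    vd = np.add.reduceat(ef[:, None] * wX, start, axis=0)
    qd = np.add.reduceat(ef[:, None, None] * wXX, start, axis=0)

    mask = d_all > 0
    W_R, V_R, Q_R = rw[start][mask], rwx[start][mask], rwxx[start][mask]
    W_D, V_D, Q_D = wd[mask], vd[mask], qd[mask]
    dk = d_all[mask].astype(float)
    s_k = s[mask]
    sum_eta_k = sum_eta_d[mask]

    ll = 0.0
    grad = np.zeros(p)
    info = np.zeros((p, p))

    if ties == "breslow":
        phi = W_R
        mu = V_R / phi[:, None]
        ll = float(np.sum(sum_eta_k) - np.sum(dk * (np.log(phi) + shift)))
        grad = np.sum(s_k - dk[:, None] * mu, axis=0)
        info = np.einsum(
            "k,kpq->pq", dk, Q_R / phi[:, None, None] - mu[:, :, None] * mu[:, None, :]
        )
        return ll, grad, info

    # Efron: vectorize the untied groups, loop over tied ones.
    single = dk == 1.0
    if single.any():
        phi = W_R[single]
        mu = V_R[single] / phi[:, None]
        ll += float(np.sum(sum_eta_k[single]) - np.sum(np.log(phi) + shift))
        grad += np.sum(s_k[single] - mu, axis=0)
        info += np.einsum(
            "kpq->pq",
            Q_R[single] / phi[:, None, None] - mu[:, :, None] * mu[:, None, :],
        )
    for k in np.nonzero(~single)[0]:
        dkk = dk[k]
        ll += float(sum_eta_k[k])
        grad += s_k[k]
        for l in range(int(dkk)):
            frac = l / dkk
            phi = W_R[k] - frac * W_D[k]
            mu = (V_R[k] - frac * V_D[k]) / phi
            ll -= float(np.log(phi) + shift)
            grad -= mu
            info += (Q_R[k] - frac * Q_D[k]) / phi - np.outer(mu, mu)
    return ll, grad, info


def _fit_cox(
    X: np.ndarray,
    times: np.ndarray,
    events: np.ndarray,
    ties: str,
    tol: float,
    max_iter: int,
) -> tuple[np.ndarray, np.ndarray, float, int, bool, bool]:
    """Newton–Raphson with step-halving; returns
    (coef, covariance, loglik, iterations, converged, degenerate)."""
    order = np.argsort(times, kind="stable")
    Xs, ts, es = X[order], times[order], events[order]
    n, p = Xs.shape
    _, start = np.unique(ts, return_index=True)
    d = np.add.reduceat(es.astype(float), start)

    beta = np.zeros(p)
    degenerate = False
    converged = False
    ll, grad, info = _cox_quantities(beta, Xs, start, d, es, ties)
    it = 0
    for it in range(1, max_iter + 1):
        if np.max(np.abs(grad)) < tol:
            converged = True
            it -= 1
            break
        try:
            step = np.linalg.solve(info, grad)
        except np.linalg.LinAlgError:
            degenerate = True
            break
        # step-halving on likelihood decrease
        factor = 1.0
        for _ in range(30):
            cand = beta + factor * step
            ll_new, grad_new, info_new = _cox_quantities(cand, Xs, start, d, es, ties)
            if ll_new >= ll - 1e-12:
                break
            factor *= 0.5
        beta, ll, grad, info = cand, ll_new, grad_new, info_new
        if np.max(np.abs(beta)) > COEF_CAP:
            # monotone partial likelihood (separation): cap and flag
            beta = np.clip(beta, -COEF_CAP, COEF_CAP)
            ll, grad, info = _cox_quantities(beta, Xs, start, d, es, ties)
            degenerate = True
            break
    else:
        it = max_iter
    if not degenerate and not converged and np.max(np.abs(grad)) < tol:
        converged = True
    try:
        cov = np.linalg.inv(info)
        if not np.all(np.isfinite(cov)) or np.any(np.diag(cov) < 0):
            raise np.linalg.LinAlgError
    except np.linalg.LinAlgError:
        cov = np.full((p, p), np.nan)
        degenerate = True
    return beta, cov, ll, it, converged, degenerate


class CoxPHModel(BaseEstimator):
    """Cox proportional-hazards regression (scikit-learn style).

    Parameters
    ----------
    ties : {"efron", "breslow"}
        Tie correction for the partial likelihood.  Efron is the
        default because clinical follow-up recorded in months produces
        many tied event times.
    alpha : float
        Two-sided level for the Wald confidence intervals (0.05 gives
        95% intervals).
    tol : float
        Convergence threshold on the max-norm of the score vector.
    max_iter : int
        Newton–Raphson iteration cap.

    Attributes (after :meth:`fit`)
    ------------------------------
    coef_ : (p,) log hazard ratios
    hazard_ratios_ : exp(coef_)
    se_, ci_low_, ci_high_, p_values_ : Wald inference on the HR scale
    loglik_ : maximized partial log-likelihood
    n_iter_, converged_, degenerate_ : solver diagnostics; ``degenerate_``
        marks separation (a diverging coefficient is reported capped)
        or a zero-variance covariate, never silently hidden.
    """

    def __init__(
        self,
        ties: str = "efron",
        alpha: float = 0.05,
        tol: float = 1e-9,
        max_iter: int = 50,
    ) -> None:
        self.ties = ties
        self.alpha = alpha
        self.tol = tol
        self.max_iter = max_iter

    def fit(self, X, y) -> "CoxPHModel":
        """Fit to covariates ``X`` (n, p) and censored outcomes ``y``,
        given either as a ``(times, events)`` pair or an (n, 2) array
        with time in the first column and the event flag in the second."""
        if self.ties not in ("efron", "breslow"):
            raise ValueError(f"ties must be 'efron' or 'breslow', got {self.ties!r}")
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        if isinstance(y, tuple) or (isinstance(y, list) and len(y) == 2):
            times = np.asarray(y[0], dtype=float)
            events = np.asarray(y[1], dtype=bool)
        else:
            y = np.asarray(y)
            times = y[:, 0].astype(float)
            events = y[:, 1].astype(bool)
        if X.shape[0] != times.size:
            raise ValueError("X rows must align with outcome length")
        if X.shape[1] < 1:
            raise ValueError("at least one covariate column is required")
        if not events.any():
            raise ValueError("at least one observed event is required")
        n, p = X.shape
        z = stats.norm.ppf(1 - self.alpha / 2)

        if np.any(np.ptp(X, axis=0) == 0.0):
            # zero-variance column: partial likelihood is flat in it
            self.coef_ = np.zeros(p)
            self.se_ = np.full(p, np.inf)
            self.loglik_ = float(
                _cox_quantities(
                    np.zeros(p),
                    X[np.argsort(times, kind="stable")],
                    *self._group_info(times, events),
                    events[np.argsort(times, kind="stable")],
                    self.ties,
                )[0]
            )
            self.n_iter_ = 0
            self.converged_ = False
            self.degenerate_ = True
        else:
            coef, cov, ll, it, converged, degenerate = _fit_cox(
                X, times, events, self.ties, self.tol, self.max_iter
            )
            self.coef_ = coef
            self.se_ = np.sqrt(np.diag(cov))
            self.loglik_ = float(ll)
            self.n_iter_ = it
            self.converged_ = bool(converged)
            self.degenerate_ = bool(degenerate)
        self.hazard_ratios_ = np.exp(self.coef_)
        with np.errstate(invalid="ignore", over="ignore"):
            self.ci_low_ = np.exp(self.coef_ - z * self.se_)
            self.ci_high_ = np.exp(self.coef_ + z * self.se_)
            zscores = np.where(self.se_ > 0, np.abs(self.coef_) / self.se_, 0.0)
        self.p_values_ = 2 * stats.norm.sf(zscores)
        self.n_features_in_ = p
        return self

    @staticmethod
    def _group_info(times: np.ndarray, events: np.ndarray):
        order = np.argsort(times, kind="stable")
        _, start = np.unique(times[order], return_index=True)
        d = np.add.reduceat(events[order].astype(float), start)
        return start, d

    def predict(self, X) -> np.ndarray:
        """Linear predictor (log relative hazard) for each row of X."""
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        return X @ self.coef_

    def score(self, X, y) -> float:
        """Harrell's concordance index of the linear predictor."""
        if isinstance(y, tuple) or (isinstance(y, list) and len(y) == 2):
            times, events = np.asarray(y[0], float), np.asarray(y[1], bool)
        else:
            y = np.asarray(y)
            times, events = y[:, 0].astype(float), y[:, 1].astype(bool)
        sample = SurvivalSample(times=times, events=events)
        return harrell_c(self.predict(X), sample, n_bootstrap=0).c_index

    def result_(self) -> CoxResult:
        """Bundle the fitted attributes into a :class:`CoxResult`."""
        return CoxResult(
            coef=self.coef_,
            hr=self.hazard_ratios_,
            se=self.se_,
            ci_low=self.ci_low_,
            ci_high=self.ci_high_,
            p_values=self.p_values_,
            loglik=self.loglik_,
            iterations=self.n_iter_,
            converged=self.converged_,
            degenerate=self.degenerate_,
        )


def cox_fit(sample: SurvivalSample, ties: str = "efron") -> CoxResult:
    """Fit a Cox model to a :class:`SurvivalSample` with covariates."""
    if sample.covariates is None:
        raise ValueError("sample must carry at least one covariate column")
    model = CoxPHModel(ties=ties)
    model.fit(sample.covariates, (sample.times, sample.events))
    return model.result_()


# ---------------------------------------------------------------------------
# Harrell's concordance index


def _concordance_counts(
    scores: np.ndarray, times: np.ndarray, events: np.ndarray
) -> tuple[float, float, int]:
    """(concordant, score-tied, comparable) pair counts.

    A pair is comparable when the subject with the strictly smaller
    time has an observed event; concordant when that subject also has
    the strictly higher risk score.
    """
    uniq = np.unique(scores)
    if uniq.size <= 2:
        # counting path: O(n log n), exact
        hi = uniq[-1]
        t_hi = np.sort(times[scores == hi])
        t_lo = np.sort(times[scores != hi])
        ev_t = times[events]
        ev_s = scores[events]
        n_hi_after = t_hi.size - np.searchsorted(t_hi, ev_t, side="right")
        n_lo_after = t_lo.size - np.searchsorted(t_lo, ev_t, side="right")
        is_hi = ev_s == hi
        if uniq.size == 1:
            comparable = int(n_hi_after.sum() + n_lo_after.sum())
            return 0.0, float(comparable), comparable
        concordant = float(n_lo_after[is_hi].sum())
        tied = float(n_hi_after[is_hi].sum() + n_lo_after[~is_hi].sum())
        comparable = int(n_hi_after.sum() + n_lo_after.sum())
        return concordant, tied, comparable
    comp = events[:, None] & (times[:, None] < times[None, :])
    sdiff = scores[:, None] - scores[None, :]
    concordant = float(np.sum(comp & (sdiff > 0)))
    tied = float(np.sum(comp & (sdiff == 0)))
    return concordant, tied, int(comp.sum())


def harrell_c(
    scores: Sequence[float] | np.ndarray,
    sample: SurvivalSample,
    n_bootstrap: int = 1000,
    seed: int = 0,
) -> ConcordanceResult:
    """Harrell's C over comparable pairs, ties in score counted half.

    The confidence interval is a percentile bootstrap over subjects
    (``n_bootstrap`` replicates, seeded); pass ``n_bootstrap=0`` to
    skip it, in which case the bounds equal the point estimate.
    """
    scores = np.asarray(scores, dtype=float)
    if scores.shape != sample.times.shape:
        raise ValueError("scores must align with the sample")
    conc, tied, comp = _concordance_counts(scores, sample.times, sample.events)
    if comp == 0:
        raise ValueError("no comparable pairs under censoring")
    c = (conc + 0.5 * tied) / comp
    if n_bootstrap <= 0:
        return ConcordanceResult(float(c), float(c), float(c), comp, int(tied))
    rng = np.random.default_rng(seed)
    n = len(sample)
    reps = []
    for _ in range(n_bootstrap):
        idx = rng.integers(0, n, n)
        bc, bt, bcomp = _concordance_counts(
            scores[idx], sample.times[idx], sample.events[idx]
        )
        if bcomp > 0:
            reps.append((bc + 0.5 * bt) / bcomp)
    lo, hi = np.quantile(reps, [0.025, 0.975])
    return ConcordanceResult(float(c), float(lo), float(hi), comp, int(tied))
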