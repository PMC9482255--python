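"""Calibration experiments for the survival machinery.

Monte-Carlo checks that the inferential pieces behave at their nominal
levels under known generative truth: Wald confidence-interval coverage
for a true hazard ratio, and the type-I error (selection fraction) of
the univariate screen on cohorts generated with every factor effect
set to zero.
"""

from __future__ import annotations

import numpy as np

from .cohort import make_cutoff_variables
from .pipeline import univariate_screen
from .simulate import default_config, generate_cohort
from .survival import CoxPHModel

__all__ = ["wald_coverage_experiment", "null_screen_experiment"]


def wald_coverage_experiment(
    true_hr: float = 2.0,
    n: int = 2000,
    replicates: int = 200,
    seed: int = 0,
    baseline_scale: float = 300.0,
    censor_window: tuple[float, float] = (36.0, 168.0),
) -> float:
    """Fraction of replicates whose 95% Wald CI covers the true HR.

    Each replicate draws a balanced binary exposure, exponential event
    times under proportional hazards, and uniform administrative
    censoring, then fits the univariate Cox model.
    """
    hits = 0
    for r in range(replicates):
        rng = np.random.default_rng(
            np.random.SeedSequence(entropy=int(seed), spawn_key=(r,))
        )
        x = (rng.random(n) < 0.5).astype(float)
        t = rng.exponential(baseline_scale / np.exp(np.log(true_hr) * x), n)
        c = rng.uniform(censor_window[0], censor_window[1], n)
        obs, e = np.minimum(t, c), t <= c
        model = CoxPHModel().fit(x[:, None], (obs, e))
        hits += bool(model.ci_low_[0] <= true_hr <= model.ci_high_[0])
    return hits / replicates


def null_screen_experiment(
    n: int = 300,
    replicates: int = 200,
    seed: int = 10_000,
    alpha: float = 0.05,
) -> float:
    """Mean selection fraction of the univariate screen on null cohorts.

    Cohorts are generated with every per-factor log hazard ratio set to
    zero, so each of the candidate dichotomized variables is a true
    null; at level ``alpha`` the screen should select about that
    fraction of the non-degenerate candidates.
    """
    null_log_hr = {k: 0.0 for k in default_config().log_hr}
    selected = total = 0
    for r in range(replicates):
        cfg = default_config().replace(
            n=n,
            seed=int(seed) + r,
            log_hr=null_log_hr,
            baseline_hazard=(1.2, 400.0),
        )
        cohort = generate_cohort(cfg)
        for s in univariate_screen(cohort, make_cutoff_variables(), alpha=alpha):
            if not s.degenerate:
                selected += s.p_value < alpha
                total += 1
    return selected / total
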