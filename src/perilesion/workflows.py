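"""High-level study workflows shared by the analysis scripts and tests.

These helpers pin down the package's canonical study conditions — the
cohort shape of the emulated trial (26 participants, visits at baseline,
month 3 and every 6 months to month 45) with the default generative
parameters — and run the end-to-end simulate -> annotate -> fit loop.

Estimator-validation runs (`recovery_cohort_config`, `recovery_study`,
`fit_simulated_cohort`) use the continuous, uncensored "gaussian"
measurement mode, because they test the marginal-ML estimator under its
own assumptions; see docs/methods.md for the reasoning.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .lesions import annotate_dataset
from .model import FitOptions, FitResult, fit
from .simulate import CohortData, LesionFieldConfig, SimulationConfig, simulate_cohort

__all__ = [
    "recovery_cohort_config",
    "fit_simulated_cohort",
    "recovery_study",
    "RecoveryStudyResult",
]


def recovery_cohort_config(
    seed: int,
    n_participants: int = 26,
    raster_size: int = 768,
    dropout_prob: float = 0.0,
    **overrides,
) -> SimulationConfig:
    """Study conditions for parameter-recovery runs.

    Full visit schedule (no dropout) at the default generative parameters,
    uncensored gaussian measurements.  ``raster_size`` can be reduced for
    replicate studies where mask rendering dominates runtime.
    """
    lesions = LesionFieldConfig(raster_size=raster_size)
    return SimulationConfig(
        n_participants=n_participants,
        dropout_prob=dropout_prob,
        lesions=lesions,
        measurement_mode="gaussian",
        rng_seed=seed,
        **overrides,
    )


def fit_simulated_cohort(
    config: SimulationConfig, options: FitOptions | None = None
) -> tuple[FitResult, CohortData, pd.DataFrame]:
    """Simulate a cohort, annotate it against its own masks, fit the model."""
    cohort = simulate_cohort(config)
    annotated = annotate_dataset(cohort.records, cohort.masks, cohort.grid)
    result = fit(annotated, options)
    return result, cohort, annotated


@dataclass
class RecoveryStudyResult:
    estimates: pd.DataFrame  # one row per replicate
    truth: dict[str, float]
    seeds: list[int]

    def summary(self) -> pd.DataFrame:
        """Bias and Monte-Carlo SE of each fixed effect across replicates."""
        rows = []
        for name, true_val in self.truth.items():
            est = self.estimates[name]
            bias = est.mean() - true_val
            mc_se = est.std(ddof=1) / np.sqrt(len(est))
            rows.append((name, true_val, est.mean(), bias, mc_se))
        return pd.DataFrame(
            rows, columns=["parameter", "truth", "mean_estimate", "bias", "mc_se"]
        )


FIXED_EFFECTS = ("beta0", "beta_t", "b1", "b2", "b3", "knot")


def recovery_study(
    n_replicates: int,
    base_seed: int = 0,
    n_participants: int = 26,
    raster_size: int = 256,
    knot_step: float = 0.5,
    **config_overrides,
) -> RecoveryStudyResult:
    """Repeated simulate-and-fit replicates at the default generative truth.

    Each replicate uses seed ``base_seed + i`` and the recovery conditions
    of :func:`recovery_cohort_config`.  A coarser knot grid is the default
    here purely for runtime; the knot is still refined locally.
    """
    options = FitOptions(knot_step=knot_step)
    rows = []
    seeds = []
    truth_params = None
    for i in range(n_replicates):
        seed = base_seed + i
        seeds.append(seed)
        cfg = recovery_cohort_config(
            seed, n_participants=n_participants, raster_size=raster_size, **config_overrides
        )
        truth_params = cfg.true_params
        result, _, _ = fit_simulated_cohort(cfg, options)
        rows.append(
            {name: getattr(result.params, name) for name in FIXED_EFFECTS}
            | {"converged": result.converged, "seed": seed}
        )
    estimates = pd.DataFrame(rows)
    truth = {name: getattr(truth_params, name) for name in FIXED_EFFECTS}
    return RecoveryStudyResult(estimates, truth, seeds)
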