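"""Two-dimensional method-of-adjustment outcome model.

In the adjustment task an observer tunes a stimulus body's fat mass and
muscle mass until it matches an internal standard (their believed or ideal
body).  Classical psychophysics reads the per-dimension mean of the chosen
settings as the point of subjective equality (PSE) and their standard
deviation as the difference limen (DL), the task's precision.  The response
model here is the minimal classical one: settings are bivariate-normal
around the internal PSE with per-dimension SDs equal to the true DLs; the
arbitrary trial start points are recorded but do not influence responses.

``dl_variability_curve`` runs the planning Monte Carlo: how variable is the
DL estimate as a function of the number of trials?  The exact answer for
normal data is known — the sample SD of n draws has standard deviation
sigma * sqrt(1 - c4(n)^2) — and serves as an oracle for the simulation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln

DIMS = ("fat", "muscle")


@dataclass
class TrialSet:
    """Recorded method-of-adjustment trials for one observer/condition."""

    settings: np.ndarray  # (n, 2) chosen (fat, muscle) per trial, kg
    starts: np.ndarray  # (n, 2) arbitrary start composition per trial, kg
    true_pse: tuple[float, float] | None = None
    true_dl: tuple[float, float] | None = None
    seed: int | None = None

    @property
    def n_trials(self) -> int:
        return len(self.settings)


@dataclass
class AdjustmentEstimate:
    """PSE (per-dimension mean) and DL (per-dimension sample SD), in kg."""

    pse: np.ndarray  # (2,)
    dl: np.ndarray  # (2,)
    n_trials: int


def simulate_adjustment(
    true_pse: tuple[float, float],
    true_dl: tuple[float, float],
    trial_corr: float = 0.0,
    n_trials: int = 30,
    seed: int | None = None,
    start_box: tuple[tuple[float, float], tuple[float, float]] = ((2.0, 50.0), (15.0, 65.0)),
) -> TrialSet:
    """Simulate adjustment trials around an internal (fat, muscle) PSE.

    Settings are drawn from a bivariate normal centred at ``true_pse`` with
    componentwise SDs ``true_dl`` and correlation ``trial_corr``.  Start
    points are uniform over ``start_box`` and inert.
    """
    pse = np.asarray(true_pse, float)
    dl = np.asarray(true_dl, float)
    if pse.shape != (2,) or dl.shape != (2,):
        raise ValueError("true_pse and true_dl must be (fat, muscle) pairs")
    if np.any(dl < 0):
        raise ValueError("true_dl must be nonnegative")
    if not -1.0 <= trial_corr <= 1.0:
        raise ValueError("trial_corr must be in [-1, 1]")
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    rng = np.random.default_rng(seed)
    # Cholesky-style construction keeps dl = 0 exact (no degenerate MVN call)
    z = rng.standard_normal((n_trials, 2))
    z1 = z[:, 0]
    z2 = trial_corr * z[:, 0] + np.sqrt(max(0.0, 1 - trial_corr**2)) * z[:, 1]
    settings = pse + np.column_stack([dl[0] * z1, dl[1] * z2])
    (f_lo, f_hi), (m_lo, m_hi) = start_box
    starts = np.column_stack(
        [rng.uniform(f_lo, f_hi, n_trials), rng.uniform(m_lo, m_hi, n_trials)]
    )
    return TrialSet(
        settings=settings,
        starts=starts,
        true_pse=tuple(pse),
        true_dl=tuple(dl),
        seed=seed,
    )


def estimate_adjustment(trials: TrialSet) -> AdjustmentEstimate:
    """PSE and DL estimates from a trial set.

    DL uses the n − 1 denominator (sample SD); with a single trial the DL is
    undefined and reported as NaN with a warning.
    """
    n = trials.n_trials
    if n < 1:
        raise ValueError("at least one trial required")
    pse = trials.settings.mean(axis=0)
    if n < 2:
        warnings.warn("DL undefined with a single trial; reporting NaN")
        dl = np.full(2, np.nan)
    else:
        dl = trials.settings.std(axis=0, ddof=1)
    return AdjustmentEstimate(pse=pse, dl=dl, n_trials=n)


def c4(n: int) -> float:
    """Normal-sample SD bias factor: E[s] = sigma * c4(n)."""
    if n < 2:
        raise ValueError("c4 requires n >= 2")
    return float(np.sqrt(2.0 / (n - 1)) * np.exp(gammaln(n / 2) - gammaln((n - 1) / 2)))


def sd_of_sample_sd(sigma: float, n: int) -> float:
    """Exact SD of the sample SD of n normal draws with SD sigma."""
    return sigma * np.sqrt(max(0.0, 1.0 - c4(n) ** 2))


def dl_variability_curve(
    target_dls: tuple[float, ...] = (0.5, 1.0, 2.0),
    trial_counts: tuple[int, ...] = (5, 10, 20, 30, 40, 50, 60, 70, 80, 90),
    resamples: int = 10_000,
    seed: int | None = None,
) -> pd.DataFrame:
    """Monte Carlo of DL-estimate variability vs number of trials.

    For each (target DL, n) cell, ``resamples`` independent trial sets of
    size n are drawn from a normal with SD equal to the target DL; each
    set's sample SD is one DL estimate.  The returned table has columns
    ``target_dl, n_trials, dl_sd`` (SD of the estimates — the variability
    plotted against trial count) and ``dl_mean``.  The curve elbows around
    20–60 trials, which is what makes the simulation useful for choosing a
    trial budget.
    """
    if any(d <= 0 for d in target_dls):
        raise ValueError("target DLs must be positive")
    if any(n < 2 for n in trial_counts):
        raise ValueError("trial counts must be >= 2")
    if resamples < 1:
        raise ValueError("resamples must be >= 1")
    rng = np.random.default_rng(seed)
    rows = []
    for dl in target_dls:
        for n in trial_counts:
            est = (rng.standard_normal((resamples, n)) * dl).std(axis=1, ddof=1)
            rows.append(
                {
                    "target_dl": dl,
                    "n_trials": n,
                    "dl_sd": est.std(ddof=1) if resamples > 1 else np.nan,
                    "dl_mean": est.mean(),
                }
            )
    return pd.DataFrame(rows)
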