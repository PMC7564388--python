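"""Synthetic participant cohorts with the published distributional shape.

Questionnaire sum-scores are drawn from truncated normal distributions.
Because the printed mean/SD describe the observed (i.e., bounded)
scores, the parent normal is moment-matched so that the *truncated*
distribution reproduces the requested mean and SD within the requested
range; a naive parameterization would bias the mean by ~1 point for the
asymmetrically bounded hyperaroused group.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.optimize
import scipy.stats

DX_CLASSES = ("cancer", "neuroinflammatory_autoimmune")


@dataclass(frozen=True)
class CohortParams:
    """Cohort sizes and questionnaire distribution parameters.

    Defaults reproduce the published sample: 19 hyperaroused (14 f) and
    41 non-hyperaroused (19 f) fatigued participants, IDS-SR
    20.6 +/- 7.3 in [10, 41] vs. 12.6 +/- 6.2 in [1, 24], all with an
    MFI-20 fatigue sum-score above ``mfi_min``.
    """

    n_hyper: int = 19
    n_nonhyper: int = 41
    ids_mean_hyper: float = 20.6
    ids_sd_hyper: float = 7.3
    ids_min_hyper: float = 10.0
    ids_max_hyper: float = 41.0
    ids_mean_non: float = 12.6
    ids_sd_non: float = 6.2
    ids_min_non: float = 1.0
    ids_max_non: float = 24.0
    female_hyper: int | None = None  # default: published fraction 14/19
    female_non: int | None = None  # default: published fraction 19/41
    mfi_min: int = 40  # inclusion requires mfi_sum > mfi_min
    seed: int = 0

    def __post_init__(self):
        if self.n_hyper < 0 or self.n_nonhyper < 0:
            raise ValueError("group sizes must be non-negative")
        for mean, lo, hi, tag in (
            (self.ids_mean_hyper, self.ids_min_hyper, self.ids_max_hyper, "hyper"),
            (self.ids_mean_non, self.ids_min_non, self.ids_max_non, "non"),
        ):
            if lo > hi:
                raise ValueError(f"infeasible truncation for {tag}: {lo} > {hi}")
            if not (lo <= mean <= hi):
                raise ValueError(f"{tag} mean {mean} outside [{lo}, {hi}]")
        for count, n, tag in (
            (self.female_hyper, self.n_hyper, "female_hyper"),
            (self.female_non, self.n_nonhyper, "female_non"),
        ):
            if count is None:
                continue
            if count < 0:
                raise ValueError(f"{tag} must be non-negative")
            if count > n:
                raise ValueError(f"{tag} cannot exceed the group size")

    def resolved_female_counts(self) -> tuple[int, int]:
        """Explicit female counts, defaulting to the published fractions."""
        hyper = (
            self.female_hyper
            if self.female_hyper is not None
            else round(self.n_hyper * 14 / 19)
        )
        non = (
            self.female_non
            if self.female_non is not None
            else round(self.n_nonhyper * 19 / 41)
        )
        return hyper, non


def matched_truncnorm(
    mean: float, sd: float, lo: float, hi: float
) -> scipy.stats.rv_continuous:
    """Truncated normal whose truncated mean/SD equal ``mean``/``sd``.

    Solves for the parent normal's location/scale so the distribution
    clipped to [lo, hi] has the requested first two moments.  Falls back
    to the naive parameterization when the target SD is infeasible for
    the interval.
    """
    if sd <= 0:
        raise ValueError("sd must be positive")
    if lo >= hi:
        raise ValueError("empty truncation interval")

    def frozen(mu, sigma):
        a, b = (lo - mu) / sigma, (hi - mu) / sigma
        return scipy.stats.truncnorm(a, b, loc=mu, scale=sigma)

    def residual(params):
        mu, log_sigma = params
        dist = frozen(mu, np.exp(log_sigma))
        return [dist.mean() - mean, dist.std() - sd]

    sol = scipy.optimize.least_squares(
        residual, x0=[mean, np.log(sd)], xtol=1e-12, ftol=1e-12
    )
    mu, sigma = sol.x[0], float(np.exp(sol.x[1]))
    if max(abs(np.asarray(residual(sol.x)))) > 0.05:
        # target moments not attainable on this interval; use the parent
        mu, sigma = mean, sd
    return frozen(mu, sigma)


def _draw_scores(
    rng: np.random.Generator,
    n: int,
    mean: float,
    sd: float,
    lo: float,
    hi: float,
    *,
    match_moments: bool = True,
) -> np.ndarray:
    """Integer questionnaire scores from a truncated normal."""
    if n == 0:
        return np.zeros(0, dtype=int)
    if match_moments:
        dist = matched_truncnorm(mean, sd, lo, hi)
    else:
        a, b = (lo - mean) / sd, (hi - mean) / sd
        dist = scipy.stats.truncnorm(a, b, loc=mean, scale=sd)
    values = dist.rvs(size=n, random_state=rng)
    return np.clip(np.round(values), np.ceil(lo), np.floor(hi)).astype(int)


def _gender_column(rng: np.random.Generator, n: int, n_female: int) -> np.ndarray:
    gender = np.array(["f"] * n_female + ["m"] * (n - n_female))
    rng.shuffle(gender)
    return gender


def generate_cohort(params: CohortParams | None = None) -> pd.DataFrame:
    """Generate a participant table.

    Columns: ``id``, ``group`` (ground-truth arousal group), ``gender``,
    ``dx_class``, ``mfi_sum``, ``ids_sr_sum``, ``psqi_total``,
    ``ess_total``.  Gender counts are matched exactly; IDS-SR scores are
    truncated-normal integers inside the configured ranges; every MFI
    sum-score exceeds ``mfi_min``.
    """
    params = params or CohortParams()
    rng = np.random.default_rng(params.seed)
    female_hyper, female_non = params.resolved_female_counts()
    frames = []
    for group, n, n_female, mean, sd, lo, hi, psqi_mu, psqi_sd, ess_mu, ess_sd in (
        (
            "hyperaroused", params.n_hyper, female_hyper,
            params.ids_mean_hyper, params.ids_sd_hyper,
            params.ids_min_hyper, params.ids_max_hyper,
            8.4, 3.6, 6.8, 3.0,
        ),
        (
            "non_hyperaroused", params.n_nonhyper, female_non,
            params.ids_mean_non, params.ids_sd_non,
            params.ids_min_non, params.ids_max_non,
            5.6, 3.1, 8.3, 3.6,
        ),
    ):
        n_cancer = int(round(n / 2))
        dx = np.array(
            [DX_CLASSES[0]] * n_cancer + [DX_CLASSES[1]] * (n - n_cancer)
        )
        rng.shuffle(dx)
        frames.append(
            pd.DataFrame(
                {
                    "group": group,
                    "gender": _gender_column(rng, n, n_female),
                    "dx_class": dx,
                    "mfi_sum": _draw_scores(
                        rng, n, 52.0, 8.0, params.mfi_min + 1, 100,
                        match_moments=False,
                    ),
                    "ids_sr_sum": _draw_scores(rng, n, mean, sd, lo, hi),
                    "psqi_total": _draw_scores(
                        rng, n, psqi_mu, psqi_sd, 0, 21, match_moments=False
                    ),
                    "ess_total": _draw_scores(
                        rng, n, ess_mu, ess_sd, 0, 24, match_moments=False
                    ),
                }
            )
        )
    table = pd.concat(frames, ignore_index=True)
    table.insert(0, "id", [f"S{i:03d}" for i in range(len(table))])
    return table
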