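"""Synthetic cohort generator.

Emulates a prospective natural-family-planning cohort: couple-level
baseline covariates, per-window binary conception outcomes drawn from a
two-state latent Markov model, and daily symptothermal charts (biphasic
basal body temperature plus an ordinal cervical-mucus trajectory) realistic
enough to exercise the fertile-window rule engine end to end.

All draws are reproducible: a single global seed is expanded into
per-couple (and per-cycle) substreams keyed by the couple index, so a
given couple's data does not change when the cohort grows.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from .reference import MODEL_COVARIATES

__all__ = [
    "CovariateSpec",
    "ChartSpec",
    "SimulatedPanel",
    "DailyChart",
    "simulate_covariates",
    "simulate_lm_sequences",
    "simulate_daily_charts",
    "simulate_cohort",
]


@dataclass(frozen=True)
class CovariateSpec:
    """Distributional spec for couple-level baseline covariates.

    Defaults reproduce the cohort's descriptive statistics: mean (SD) of
    30 (3.98) years for the woman's age, 32 (4.72) for the man's, 12 (3.12)
    days of fertile-window length, 3 (1.99) intercourse acts per window,
    48% of women with at least one previous pregnancy and 29.6% with prior
    hormonal contraception.
    """

    woman_age_mean: float = 30.0
    woman_age_sd: float = 3.98
    man_age_mean: float = 32.0
    man_age_sd: float = 4.72
    fertile_len_mean: float = 12.0
    fertile_len_sd: float = 3.12
    intercourse_mean: float = 3.0
    intercourse_sd: float = 1.99
    prev_pregnancy_prob: float = 0.4799
    contraception_prob: float = 0.2957

    def validate(self) -> None:
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if f.name.endswith("_sd") and v < 0:
                raise ValueError(f"{f.name} must be >= 0, got {v}")
            if f.name.endswith("_prob") and not (0.0 <= v <= 1.0):
                raise ValueError(f"{f.name} must be in [0,1], got {v}")


@dataclass(frozen=True)
class ChartSpec:
    """Parameters of the daily-chart generator.

    The chart is a two-level BBT step at a latent ovulation day with i.i.d.
    Gaussian noise, and a stepwise cervical-mucus trajectory that rises
    1 -> 2 -> 3 -> 4 and peaks the day before ovulation, then falls back
    to 1.  ``cms_onset_before_ovulation`` controls how many days before
    ovulation the mucus symptoms open (8 gives a 12-day fertile window
    under the rule engine: onset .. third high-temperature day).
    """

    cycle_length_mean: float = 28.0
    cycle_length_sd: float = 3.0
    bbt_low: float = 36.5
    bbt_shift: float = 0.35
    bbt_noise_sd: float = 0.07
    ovulation_day_mean: float = 14.0
    ovulation_day_sd: float = 1.5
    cms_peak_level: int = 4
    missing_day_prob: float = 0.03
    intercourse_day_prob: float = 0.25
    cms_onset_before_ovulation: int = 8
    protected_day_prob: float = 0.0
    disturbance_day_prob: float = 0.0

    def validate(self) -> None:
        if self.bbt_shift <= 0:
            raise ValueError("bbt_shift must be > 0")
        if self.cms_peak_level not in (0, 1, 2, 3, 4):
            raise ValueError("cms_peak_level must be in 0..4")
        for name in ("missing_day_prob", "intercourse_day_prob",
                     "protected_day_prob", "disturbance_day_prob"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0,1], got {v}")
        if self.cycle_length_sd < 0 or self.ovulation_day_sd < 0:
            raise ValueError("standard deviations must be >= 0")


@dataclass
class DailyChart:
    """One menstrual cycle of daily symptothermal observations.

    Days are 1-based from the first day of menses.  ``bbt`` uses NaN for
    unrecorded days; ``cms_level`` uses 0 for "not registered" (treated as
    missing, never as dry).
    """

    woman_id: str
    cycle_id: int
    day: np.ndarray
    bbt: np.ndarray
    cms_level: np.ndarray
    intercourse: np.ndarray
    protected: np.ndarray
    disturbance: np.ndarray
    ovulation_day: int | None = None  # generator ground truth, if synthetic

    def __post_init__(self) -> None:
        self.day = np.asarray(self.day, dtype=int)
        if np.any(np.diff(self.day) <= 0) or (self.day.size and self.day[0] < 1):
            raise ValueError("days must be strictly increasing and >= 1")
        self.bbt = np.asarray(self.bbt, dtype=float)
        self.cms_level = np.asarray(self.cms_level, dtype=int)
        if np.any((self.cms_level < 0) | (self.cms_level > 4)):
            raise ValueError("cms_level must be in 0..4")
        self.intercourse = np.asarray(self.intercourse, dtype=int)
        self.protected = np.asarray(self.protected, dtype=int)
        self.disturbance = np.asarray(self.disturbance, dtype=int)

    @property
    def n_days(self) -> int:
        return int(self.day.size)

    def to_frame(self) -> pd.DataFrame:
        from .windows import CMS_TEXT  # level -> canonical (feeling, appearance, secretion)

        feel, app, sec = zip(*(CMS_TEXT[l] for l in self.cms_level))
        return pd.DataFrame(
            {
                "woman_id": self.woman_id,
                "cycle_id": self.cycle_id,
                "day": self.day,
                "bbt": self.bbt,
                "cms_feeling": feel,
                "cms_appearance": app,
                "cms_secretion": sec,
                "cms_level": self.cms_level,
                "intercourse": self.intercourse,
                "protected": self.protected,
                "disturbance": self.disturbance,
            }
        )


@dataclass
class SimulatedPanel:
    """Couple-level panel: covariates, hidden states, conception outcomes.

    ``states`` and ``y`` are (n, T_max) arrays padded with -1 beyond each
    couple's length; ``lengths[i]`` is the number of observed fertile
    windows for couple i (sequences stop at the first conception when the
    generator runs in absorbing mode).
    """

    couple_ids: np.ndarray
    X: np.ndarray
    covariate_names: list[str]
    states: np.ndarray
    y: np.ndarray
    lengths: np.ndarray

    @property
    def n(self) -> int:
        return int(self.X.shape[0])

    def to_panel_frame(self) -> pd.DataFrame:
        rows = []
        for i in range(self.n):
            for t in range(self.lengths[i]):
                rows.append((self.couple_ids[i], t + 1, int(self.y[i, t])))
        return pd.DataFrame(rows, columns=["couple_id", "window_index", "y"])

    def to_covariate_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.X, columns=self.covariate_names)
        df.insert(0, "couple_id", self.couple_ids)
        return df


def _couple_rng(seed: int, index: int, stream: int) -> np.random.Generator:
    """Substream for couple ``index``; invariant to the cohort size."""
    ss = np.random.SeedSequence(entropy=int(seed), spawn_key=(int(index), int(stream)))
    return np.random.Generator(np.random.Philox(ss))


def _trunc_normal_from_uniform(u: np.ndarray, mean: float, sd: float,
                               lo: float, hi: float) -> np.ndarray:
    """Inverse-CDF transform of uniforms to a truncated normal."""
    if sd == 0:
        return np.full_like(u, mean)
    a = norm.cdf((lo - mean) / sd)
    b = norm.cdf((hi - mean) / sd)
    return mean + sd * norm.ppf(a + u * (b - a))


def simulate_covariates(n: int, spec: CovariateSpec | None = None,
                        seed: int = 0) -> pd.DataFrame:
    """Draw ``n`` couples' baseline covariates.

    Ages are truncated normal on [18, 45]; window length and intercourse
    frequency are truncated to (0, inf).  Binary indicators are Bernoulli.
    The returned frame carries both the contraception indicator and its
    complement ``no_contraception``, the form entering the model.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    spec = spec or CovariateSpec()
    spec.validate()

    u = np.empty((n, 6))
    for i in range(n):
        u[i] = _couple_rng(seed, i, 0).uniform(size=6)

    woman_age = _trunc_normal_from_uniform(u[:, 0], spec.woman_age_mean,
                                           spec.woman_age_sd, 18.0, 45.0)
    man_age = _trunc_normal_from_uniform(u[:, 1], spec.man_age_mean,
                                         spec.man_age_sd, 18.0, 45.0)
    fertile_len = _trunc_normal_from_uniform(u[:, 2], spec.fertile_len_mean,
                                             spec.fertile_len_sd, 0.0, np.inf)
    intercourse = _trunc_normal_from_uniform(u[:, 3], spec.intercourse_mean,
                                             spec.intercourse_sd, 0.0, np.inf)
    prev_preg = (u[:, 4] < spec.prev_pregnancy_prob).astype(int)
    contraception = (u[:, 5] < spec.contraception_prob).astype(int)

    return pd.DataFrame(
        {
            "couple_id": [f"C{i + 1:05d}" for i in range(n)],
            "woman_age": woman_age,
            "man_age": man_age,
            "fertile_len": fertile_len,
            "intercourse_freq": intercourse,
            "prev_pregnancy": prev_preg,
            "contraception": contraception,
            "no_contraception": 1 - contraception,
        }
    )


def _covariate_matrix(covariates: pd.DataFrame,
                      names: Sequence[str]) -> np.ndarray:
    missing = [c for c in names if c not in covariates.columns]
    if missing:
        raise ValueError(f"covariate table lacks columns {missing}")
    return covariates.loc[:, list(names)].to_numpy(dtype=float)


def simulate_lm_sequences(params, covariates: pd.DataFrame, T_max: int,
                          seed: int = 0, absorbing: bool = True) -> SimulatedPanel:
    """Draw hidden-state and conception sequences from the latent Markov model.

    For each couple the first state follows the initial probabilities, later
    states the transition matrix, and the conception indicator a Bernoulli
    whose logit is ``mu + alpha_u + x'beta``.  In absorbing mode (the
    default, matching pregnancy as a drop-out reason) the sequence stops at
    the first conception.
    """
    from .lm import LMParameters  # local import to avoid a cycle

    if T_max < 1:
        raise ValueError("T_max must be >= 1")
    if not isinstance(params, LMParameters):
        raise TypeError("params must be LMParameters")
    params.validate()

    names = params.covariate_names or MODEL_COVARIATES
    X = _covariate_matrix(covariates, names)
    n = X.shape[0]
    xb = X @ params.beta
    # success probability per state: (n, 2)
    logit = params.mu + np.array([0.0, params.alpha2])[None, :] + xb[:, None]
    p_conc = 1.0 / (1.0 + np.exp(-logit))

    u = np.empty((n, 2 * T_max + 1))
    for i in range(n):
        u[i] = _couple_rng(seed, i, 1).uniform(size=2 * T_max + 1)

    states = np.full((n, T_max), -1, dtype=int)
    y = np.full((n, T_max), -1, dtype=int)
    lengths = np.zeros(n, dtype=int)

    alive = np.ones(n, dtype=bool)
    # state coded 0/1 internally; exported as 1/2
    s = (u[:, 0] < params.pi[1]).astype(int)
    for t in range(T_max):
        if t > 0:
            # transition: move to state 2 with prob Pi[s, 1]
            s = np.where(alive, (u[:, 2 * t] < params.Pi[s, 1]).astype(int), s)
        yt = (u[:, 2 * t + 1] < p_conc[np.arange(n), s]).astype(int)
        states[alive, t] = s[alive] + 1
        y[alive, t] = yt[alive]
        lengths[alive] = t + 1
        if absorbing:
            alive = alive & (yt == 0)
        if not alive.any():
            break

    couple_ids = covariates["couple_id"].to_numpy() if "couple_id" in covariates \
        else np.array([f"C{i + 1:05d}" for i in range(n)])
    return SimulatedPanel(couple_ids=couple_ids, X=X,
                          covariate_names=list(names),
                          states=states, y=y, lengths=lengths)


def _make_chart(rng: np.random.Generator, spec: ChartSpec, woman_id: str,
                cycle_id: int) -> DailyChart:
    L = int(np.clip(np.rint(rng.normal(spec.cycle_length_mean,
                                       spec.cycle_length_sd)), 21, 40))
    o = int(np.clip(np.rint(rng.normal(spec.ovulation_day_mean,
                                       spec.ovulation_day_sd)),
                    max(10, spec.cms_onset_before_ovulation + 2), L - 5))
    day = np.arange(1, L + 1)

    bbt = np.where(day <= o, spec.bbt_low, spec.bbt_low + spec.bbt_shift)
    if spec.bbt_noise_sd > 0:
        bbt = bbt + rng.normal(0.0, spec.bbt_noise_sd, size=L)
    missing = rng.uniform(size=L) < spec.missing_day_prob
    bbt = np.where(missing, np.nan, bbt)

    # mucus trajectory: dry (1) -> rising 2/3 -> peak level the two days
    # before ovulation -> back to 1 from ovulation day on
    cms = np.ones(L, dtype=int)
    onset = o - spec.cms_onset_before_ovulation
    span = o - onset  # days carrying level >= 2
    peak = max(1, min(int(spec.cms_peak_level), 4))
    lv4 = min(2, span)
    lv3 = min(3, span - lv4)
    for k, d in enumerate(range(onset, o)):
        idx = d - 1
        if d >= o - lv4:
            cms[idx] = min(4, peak)
        elif d >= o - lv4 - lv3:
            cms[idx] = min(3, peak)
        else:
            cms[idx] = min(2, peak)

    intercourse = (rng.uniform(size=L) < spec.intercourse_day_prob).astype(int)
    protected = ((rng.uniform(size=L) < spec.protected_day_prob)
                 & (intercourse == 1)).astype(int)
    disturbance = (rng.uniform(size=L) < spec.disturbance_day_prob).astype(int)

    return DailyChart(woman_id=woman_id, cycle_id=cycle_id, day=day, bbt=bbt,
                      cms_level=cms, intercourse=intercourse,
                      protected=protected, disturbance=disturbance,
                      ovulation_day=o)


def simulate_daily_charts(n_cycles: int, spec: ChartSpec | None = None,
                          seed: int = 0) -> list[DailyChart]:
    """Generate ``n_cycles`` daily charts, one synthetic woman per cycle."""
    if n_cycles < 1:
        raise ValueError("n_cycles must be >= 1")
    spec = spec or ChartSpec()
    spec.validate()
    charts = []
    for i in range(n_cycles):
        rng = _couple_rng(seed, i, 2)
        charts.append(_make_chart(rng, spec, woman_id=f"W{i + 1:05d}", cycle_id=1))
    return charts


def simulate_cohort(n_couples: int, cov_spec: CovariateSpec | None = None,
                    chart_spec: ChartSpec | None = None, params=None,
                    T_max: int = 4, seed: int = 0, absorbing: bool = True):
    """Full synthetic cohort: covariates, conception panel, and daily charts.

    Charts are tied to the drawn covariates so the chart-derived aggregate
    covariates resemble the drawn ones: each couple's mucus onset is placed
    so the rule-engine window length is near their drawn ``fertile_len``,
    and the daily intercourse probability targets their drawn
    ``intercourse_freq`` acts per window.  One chart per observed fertile
    window is produced.

    Returns ``(couples, panel, charts)``.
    """
    from .reference import reference_parameters

    cov_spec = cov_spec or CovariateSpec()
    chart_spec = chart_spec or ChartSpec()
    params = params if params is not None else reference_parameters()

    couples = simulate_covariates(n_couples, cov_spec, seed=seed)
    panel = simulate_lm_sequences(params, couples, T_max=T_max, seed=seed,
                                  absorbing=absorbing)
    charts: list[DailyChart] = []
    for i in range(n_couples):
        L = float(couples["fertile_len"].iloc[i])
        acts = float(couples["intercourse_freq"].iloc[i])
        onset = int(np.clip(np.rint(L) - 4, 2, 14))
        per_day = float(np.clip(acts / max(L, 1.0), 0.05, 0.9))
        c_spec = dataclasses.replace(chart_spec,
                                     cms_onset_before_ovulation=onset,
                                     intercourse_day_prob=per_day)
        for t in range(int(panel.lengths[i])):
            rng = _couple_rng(seed, i, 3 + t)
            charts.append(_make_chart(rng, c_spec,
                                      woman_id=str(couples["couple_id"].iloc[i]),
                                      cycle_id=t + 1))
    return couples, panel, charts
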