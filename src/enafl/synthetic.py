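"""Synthetic inputs emulating the study's measurements.

Every generator is seeded and bit-reproducible, and returns its ground-truth
parameters alongside the data so downstream estimators can be tested by
parameter recovery:

* ordinal tumour-grade trajectories for a 5-treated vs 4-control cohort with
  a configurable treatment growth delay,
* (grade, fluorescence mean-grey) pairs whose attenuation makes the
  population grade-signal correlation approximately zero,
* thermography frame stacks with a Gaussian hot spot, linear 2 s rise,
  exponential cooling and sensor noise,
* Bernoulli implantation outcomes at method-specific success rates.

Grade trajectories use a logistic latent: the log-odds of the covered
circumference fraction grows linearly in time, so the fraction saturates at 1
as a real circumferential tumour must.  Noise enters on the latent scale
before grade discretisation, producing the heavy ties typical of endoscopic
ordinal scores.  The study's day-1 inclusion criterion (every mouse at grade
0 or 1 one day after implantation) is emulated by per-mouse rejection
sampling.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .tumor_stats import GradeSeries, MethodOutcomeTable, grade_from_fraction
from .thermal import ThermalFrameStack

__all__ = [
    "GradeTrajectoryParams",
    "ThermalFrameParams",
    "ImplantOutcomeParams",
    "gen_grade_trajectories",
    "gen_fluorescence_pairs",
    "gen_thermal_frames",
    "gen_implantation_outcomes",
    "reference_outcome_table",
]


def _logit(p: float) -> float:
    return math.log(p / (1.0 - p))


def _expit(x):
    return 1.0 / (1.0 + np.exp(-x))


# ---------------------------------------------------------------------------
# Grade trajectories
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GradeTrajectoryParams:
    """Cohort and latent-growth parameters for the grade generator.

    ``growth_rate`` is the slope of the latent log-odds of the covered
    circumference fraction (day^-1); ``start_fraction`` is the fraction at
    day 0; treated mice follow the same curve shifted right by
    ``delay_days``.  ``noise_sd`` (log-odds units) splits into a per-mouse
    random intercept and half-sd per-day jitter.
    """

    n_control: int = 4
    n_treated: int = 5
    days: int = 7
    growth_rate: float = 0.9
    start_fraction: float = 0.004
    delay_days: float = 2.0
    noise_sd: float = 0.35
    seed: int = 0
    grade1_max_fraction: float = 0.02
    detect_fraction: float = 0.005

    def __post_init__(self) -> None:
        if self.n_control < 1 or self.n_treated < 1:
            raise ValueError("group sizes must be >= 1")
        if self.growth_rate <= 0:
            raise ValueError("growth_rate must be > 0")
        if not 0.0 < self.start_fraction < 1.0:
            raise ValueError("start_fraction must lie in (0, 1)")
        if self.delay_days < 0:
            raise ValueError("delay_days must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.days < 1:
            raise ValueError("at least one observation day required")

    def latent_fraction(self, t, delay: float = 0.0):
        """Noise-free circumference fraction at time t (days)."""
        return _expit(_logit(self.start_fraction)
                      + self.growth_rate * (np.asarray(t, float) - delay))


def gen_grade_trajectories(params: GradeTrajectoryParams
                           ) -> tuple[GradeSeries, dict]:
    """Simulate a graded cohort; returns the series and its ground truth.

    Raises if the noise-free trajectory already exceeds grade 1 on day 1
    (such parameters cannot satisfy the day-1 inclusion criterion).
    """
    if params.latent_fraction(1.0) > params.grade1_max_fraction:
        raise ValueError(
            "params produce a noise-free day-1 grade above 1 "
            f"(fraction {params.latent_fraction(1.0):.4f} > "
            f"{params.grade1_max_fraction}); lower start_fraction or "
            "growth_rate")
    rng = np.random.default_rng(params.seed)
    days = np.arange(1, params.days + 1)
    lam0 = _logit(params.start_fraction)

    records = []
    groups = ([("control", 0.0)] * params.n_control
              + [("irradiated", params.delay_days)] * params.n_treated)
    for m, (group, delay) in enumerate(groups):
        for attempt in range(1000):
            offset = rng.normal(0.0, params.noise_sd)
            jitter = rng.normal(0.0, params.noise_sd / 2.0, size=days.size)
            lam = lam0 + params.growth_rate * (days - delay) + offset + jitter
            frac = _expit(lam)
            if frac[0] <= params.grade1_max_fraction:
                break
        else:
            raise ValueError(
                "could not satisfy the day-1 grade <= 1 inclusion criterion; "
                "params are too aggressive for the configured noise")
        for day, f in zip(days, frac):
            detectable = f >= params.detect_fraction
            grade = grade_from_fraction(
                f, detectable, True,
                grade1_max_fraction=params.grade1_max_fraction)
            records.append(dict(mouse_id=f"m{m:02d}", group=group,
                                day=int(day), grade=grade,
                                fluorescence_detected=True))
    series = GradeSeries(pd.DataFrame.from_records(records))
    return series, asdict(params)


# ---------------------------------------------------------------------------
# Fluorescence / grade pairs
# ---------------------------------------------------------------------------

# Circumference-fraction bands of the six grades (band 0: sub-detection).
_GRADE_SIZE_BANDS = ((0.0005, 0.005), (0.005, 0.02), (0.02, 0.125),
                     (0.125, 0.25), (0.25, 0.5), (0.5, 1.0))

# Attenuation at which cov(grade(size), size * exp(-a * size)) = 0 under the
# grade-stratified size draw below (root of the population moment condition;
# see docs/methods.md).
DECORRELATING_ATTENUATION = 8.79


def gen_fluorescence_pairs(n: int = 64,
                           attenuation_strength: float = DECORRELATING_ATTENUATION,
                           seed: int = 0, *, noise_sd: float = 0.4,
                           base_signal: float = 1000.0
                           ) -> tuple[pd.DataFrame, dict]:
    """(grade, mean grey value) pairs with a non-monotone size-signal map.

    Tumour sizes are drawn stratified across the six grade bands (each mouse
    equally likely to sit in any grade, near the centre of its band), which
    emulates a correlation cohort spanning the whole grading scale.  The
    fluorescence signal is base * size * exp(-attenuation * size) times
    log-normal noise: small tumours emit little, large tumours re-absorb
    (blood, tissue thickness), so at the default attenuation the population
    Pearson correlation between grade and signal is approximately zero.
    With ``attenuation_strength = 0`` and ``noise_sd = 0`` the signal is
    strictly increasing in tumour size.
    """
    if n < 3:
        raise ValueError("need n >= 3 pairs")
    if attenuation_strength < 0 or noise_sd < 0:
        raise ValueError("attenuation_strength and noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    band = rng.integers(0, len(_GRADE_SIZE_BANDS), size=n)
    lo = np.array([_GRADE_SIZE_BANDS[b][0] for b in band])
    hi = np.array([_GRADE_SIZE_BANDS[b][1] for b in band])
    size = (lo + hi) / 2 + rng.uniform(-0.25, 0.25, size=n) * (hi - lo)
    signal = (base_signal * size
              * np.exp(-attenuation_strength * size)
              * np.exp(rng.normal(0.0, noise_sd, size=n)))
    grades = np.array([
        grade_from_fraction(s, s >= 0.005, True) for s in size])
    df = pd.DataFrame({"grade": grades, "mean_grey_value": signal})
    truth = dict(n=n, attenuation_strength=attenuation_strength,
                 noise_sd=noise_sd, base_signal=base_signal, seed=seed,
                 sizes=size)
    return df, truth


# ---------------------------------------------------------------------------
# Thermography frames
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ThermalFrameParams:
    """Synthetic thermography of one or more irradiation sites.

    Default spatial sigma (88 um) puts the hot-spot full width at half
    maximum near the ~207 um scale of the mucosal lesion; the temporal shape
    is a linear 2 s rise (the irradiation) followed by exponential decay.
    ``sites`` maps site label -> peak amplitude (degC); sites are laid out on
    a centred square lattice.
    """

    shape: tuple[int, int] = (64, 64)
    pixel_pitch: float = 25.0e-6
    baseline: float = 30.0
    peak_delta: float = 20.0
    sigma: float = 88.0e-6
    on_time: float = 2.0
    decay_tau: float = 1.0
    frame_rate: float = 10.0
    duration: float = 6.0
    noise_sd: float = 0.2
    sites: dict[str, float] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("pixel_pitch", "peak_delta", "sigma", "on_time",
                     "decay_tau", "frame_rate", "duration"):
            if getattr(self, name) <= 0 and not (name == "peak_delta"
                                                 and self.peak_delta == 0.0):
                raise ValueError(f"{name} must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.frame_rate * self.duration < 3:
            raise ValueError("need at least 3 frames")

    def site_map(self) -> dict[str, float]:
        if self.sites is not None:
            return dict(self.sites)
        return {"spot": self.peak_delta}


def _site_centres(n_sites: int, shape: tuple[int, int]) -> list[tuple[int, int]]:
    """Centres (row, col) of up to n sites on a centred square lattice.

    Centres sit on integer pixels so a noiseless hot spot attains its full
    amplitude at one pixel exactly.
    """
    if n_sites == 1:
        return [((shape[0] - 1) // 2, (shape[1] - 1) // 2)]
    per_side = math.ceil(math.sqrt(n_sites))
    rows = np.rint(np.linspace(0.25, 0.75, per_side) * (shape[0] - 1))
    cols = np.rint(np.linspace(0.25, 0.75, per_side) * (shape[1] - 1))
    centres = [(int(r), int(c)) for r in rows for c in cols]
    return centres[:n_sites]


def gen_thermal_frames(params: ThermalFrameParams
                       ) -> tuple[ThermalFrameStack, dict]:
    """Simulate a frame stack; returns the stack and its ground truth."""
    rng = np.random.default_rng(params.seed)
    n_frames = int(round(params.frame_rate * params.duration)) + 1
    times = np.arange(n_frames) / params.frame_rate
    ny, nx = params.shape
    yy, xx = np.mgrid[0:ny, 0:nx]
    sites = params.site_map()
    centres = _site_centres(len(sites), params.shape)

    ramp = np.minimum(times / params.on_time, 1.0)
    decay = np.exp(-np.maximum(0.0, times - params.on_time) / params.decay_tau)
    temporal = ramp * decay

    frames = np.full((n_frames, ny, nx), params.baseline, dtype=float)
    sigma_px = params.sigma / params.pixel_pitch
    truth_sites = {}
    for (label, amp), (cy, cx) in zip(sites.items(), centres):
        rho2 = (yy - cy) ** 2 + (xx - cx) ** 2
        spatial = amp * np.exp(-rho2 / (2.0 * sigma_px ** 2))
        frames += temporal[:, None, None] * spatial[None, :, :]
        truth_sites[label] = dict(amplitude=amp, centre=(cy, cx))
    if params.noise_sd > 0:
        frames += rng.normal(0.0, params.noise_sd, size=frames.shape)

    stack = ThermalFrameStack(times=times, frames=frames,
                              pixel_pitch=params.pixel_pitch,
                              laser_on_time=0.0)
    truth = dict(baseline=params.baseline, peak_time=params.on_time,
                 sites=truth_sites, noise_sd=params.noise_sd,
                 sigma=params.sigma, seed=params.seed)
    return stack, truth


# ---------------------------------------------------------------------------
# Implantation outcomes
# ---------------------------------------------------------------------------

_METHODS = ("intra_luminal_seeding", "intra_colonic_wall_injection",
            "endoscopic_implantation")


@dataclass(frozen=True)
class ImplantOutcomeParams:
    """Bernoulli success model per implantation method."""

    probabilities: tuple[float, ...] = (0.20, 0.75, 0.923)
    n_mice: tuple[int, ...] = (15, 8, 13)
    last_follow_up_days: tuple[int, ...] = (45, 21, 10)
    methods: tuple[str, ...] = _METHODS
    seed: int = 0

    def __post_init__(self) -> None:
        if not (len(self.probabilities) == len(self.n_mice)
                == len(self.methods) == len(self.last_follow_up_days)):
            raise ValueError("per-method fields must have equal length")
        if any(not 0.0 <= p <= 1.0 for p in self.probabilities):
            raise ValueError("probabilities must lie in [0, 1]")
        if any(n < 1 for n in self.n_mice):
            raise ValueError("n_mice must be >= 1")


def gen_implantation_outcomes(params: ImplantOutcomeParams
                              ) -> tuple[MethodOutcomeTable, dict]:
    """Draw per-method Bernoulli outcomes; returns table and ground truth."""
    rng = np.random.default_rng(params.seed)
    rows = []
    for method, p, n, fup in zip(params.methods, params.probabilities,
                                 params.n_mice, params.last_follow_up_days):
        successes = int(rng.binomial(n, p))
        rows.append(dict(method=method, successes=successes, total=n,
                         last_follow_up_days=fup))
    table = MethodOutcomeTable(pd.DataFrame(rows))
    return table, asdict(params)


def reference_outcome_table() -> MethodOutcomeTable:
    """The fixed 3/15, 6/8, 12/13 outcome counts used in validation examples
    (bypasses all randomness)."""
    return MethodOutcomeTable(pd.DataFrame([
        dict(method="intra_luminal_seeding", successes=3, total=15,
             last_follow_up_days=45),
        dict(method="intra_colonic_wall_injection", successes=6, total=8,
             last_follow_up_days=21),
        dict(method="endoscopic_implantation", successes=12, total=13,
             last_follow_up_days=10),
    ]))
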