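"""Seeded two-class synthetic MFC cohorts.

No patient MFC recordings are publicly deposited, so this module generates
normalized stride series whose group statistics match the published cohort
profile: the *unimproved* class sits at a higher normalized level with a
smaller stride-to-stride SD and a stable, sustained low-frequency
oscillation; the *improved* class sits lower, varies more, and its
low-frequency content wanders (unstable amplitude, phase and local level),
which raises its across-frame spectral variance.

Each subject draws a level ``mu_s`` and a target series SD ``sigma_s`` from
truncated normal between-subject distributions, then receives three
stationary components whose variances sum to ``sigma_s**2``:

* a slow AR(1) drift of the local level (low-frequency instability),
* a sinusoid at ``osc_freq`` cycles/stride whose log-amplitude follows an
  AR(1) process and whose phase performs a random walk, both with
  innovation scale proportional to ``1 - osc_stability``,
* white Gaussian stride noise.

With ``osc_stability = 1`` the oscillation is a constant-amplitude,
constant-phase sinusoid and the drift vanishes.  Values are clipped to the
open unit interval (clip counts recorded in the series metadata) and the
series is marked normalized.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .mfc_core import Cohort, MFCSeries, ValidationError

__all__ = [
    "ClassParams",
    "CohortConfig",
    "improved_params",
    "unimproved_params",
    "default_config",
    "null_config",
    "generate_subject",
    "generate_cohort",
]

# fraction of the variance budget assigned to the slow level drift,
# scaled by (1 - osc_stability); the remainder splits between the
# oscillation and white stride noise
_DRIFT_BUDGET = 0.5
_DRIFT_RHO = 0.985  # AR(1) pole of the level drift (decorrelates over ~66 strides)
_AMP_JITTER = 0.6  # innovation scale of the log-amplitude AR(1)
_PHASE_JITTER = 0.4  # radians per stride of phase random walk, times (1 - stability)
_CLIP_EPS = 1e-6


@dataclass(frozen=True)
class ClassParams:
    """Generative parameters of one outcome class.

    ``mean_mu``/``mean_sd`` are the between-subject center/spread of the
    normalized series level; ``sd_mu``/``sd_sd`` the center/spread of the
    within-subject stride SD.  ``osc_freq`` (cycles/stride) places the
    dominant oscillation; ``osc_amp_mu`` is its nominal amplitude and
    ``osc_stability`` in [0, 1] sets how sustained it is (1 = constant
    amplitude and phase, 0 = strongly wandering).
    """

    mean_mu: float
    mean_sd: float
    sd_mu: float
    sd_sd: float
    osc_freq: float = 0.03
    osc_amp_mu: float = 0.08
    osc_stability: float = 0.5

    def __post_init__(self) -> None:
        if not (0.0 < self.mean_mu < 1.0):
            raise ValidationError("mean_mu must lie in (0, 1)")
        for name in ("mean_sd", "sd_mu", "sd_sd", "osc_amp_mu"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        if not (0.0 < self.osc_freq < 0.5):
            raise ValidationError("osc_freq must lie in (0, 0.5) cycles/stride")
        if not (0.0 <= self.osc_stability <= 1.0):
            raise ValidationError("osc_stability must lie in [0, 1]")
        if self.mean_mu - 3 * self.mean_sd <= 0.0 or self.mean_mu + 3 * self.mean_sd >= 1.0:
            raise ValidationError(
                "infeasible level distribution: mean_mu +/- 3*mean_sd must lie "
                "inside (0, 1)"
            )


def improved_params() -> ClassParams:
    """Defaults for the improved class: lower level, higher and unstable
    variability."""
    return ClassParams(
        mean_mu=0.5164,
        mean_sd=0.1282,
        sd_mu=0.1351,
        sd_sd=0.0319,
        osc_freq=0.03,
        osc_amp_mu=0.08,
        osc_stability=0.2,
    )


def unimproved_params() -> ClassParams:
    """Defaults for the unimproved class: higher level, lower and stable
    variability."""
    return ClassParams(
        mean_mu=0.7148,
        mean_sd=0.0537,
        sd_mu=0.0933,
        sd_sd=0.0186,
        osc_freq=0.03,
        osc_amp_mu=0.08,
        osc_stability=0.9,
    )


@dataclass(frozen=True)
class CohortConfig:
    """Cohort composition, series length and per-class parameters."""

    n_per_class: dict[str, int] = field(
        default_factory=lambda: {"improved": 14, "unimproved": 5}
    )
    n_strides: int = 200
    params: dict[str, ClassParams] = field(
        default_factory=lambda: {
            "improved": improved_params(),
            "unimproved": unimproved_params(),
        }
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_strides < 50:
            raise ValidationError("n_strides must be >= 50")
        for label, n in self.n_per_class.items():
            if n < 1:
                raise ValidationError(f"count for {label!r} must be >= 1")
            if label not in self.params:
                raise ValidationError(f"no parameters for class {label!r}")


def default_config(
    seed: int = 0,
    n_improved: int = 14,
    n_unimproved: int = 5,
    n_strides: int = 200,
) -> CohortConfig:
    """The default study-like cohort: 14 improved / 5 unimproved subjects."""
    return CohortConfig(
        n_per_class={"improved": n_improved, "unimproved": n_unimproved},
        n_strides=n_strides,
        seed=seed,
    )


def null_config(
    seed: int = 0, n_per_class: int = 10, n_strides: int = 200
) -> CohortConfig:
    """A no-effect cohort: both labels share the improved-class parameters."""
    p = improved_params()
    return CohortConfig(
        n_per_class={"improved": n_per_class, "unimproved": n_per_class},
        n_strides=n_strides,
        params={"improved": p, "unimproved": p},
        seed=seed,
    )


def _truncated_normal(
    rng: np.random.Generator, mu: float, sd: float, lo: float, hi: float
) -> float:
    if sd == 0.0:
        return float(np.clip(mu, lo, hi))
    for _ in range(1000):
        x = rng.normal(mu, sd)
        if lo < x < hi:
            return float(x)
    raise ValidationError(
        f"could not draw from Normal({mu}, {sd}) truncated to ({lo}, {hi})"
    )


def generate_subject(
    p: ClassParams,
    n_strides: int,
    rng: np.random.Generator,
    subject_id: str = "synthetic",
    label: str | None = None,
) -> MFCSeries:
    """Draw one subject's normalized MFC series from the class model."""
    mu_s = _truncated_normal(rng, p.mean_mu, p.mean_sd, 0.0, 1.0)
    sigma_s = _truncated_normal(rng, p.sd_mu, p.sd_sd, 0.0, np.inf)
    wander = 1.0 - p.osc_stability
    i = np.arange(n_strides)

    if sigma_s == 0.0 and p.osc_amp_mu == 0.0:
        # degenerate limit: a constant series at the subject level
        return MFCSeries(
            subject_id,
            np.full(n_strides, np.clip(mu_s, _CLIP_EPS, 1.0 - _CLIP_EPS)),
            label=label,
            normalized=True,
            meta={"mu_s": mu_s, "sigma_s": 0.0, "n_clipped": 0,
                  "osc_stability": p.osc_stability},
        )
    sigma_s = max(sigma_s, 1e-6)

    # variance budget: drift + oscillation + white noise = sigma_s^2
    drift_var = _DRIFT_BUDGET * wander * sigma_s**2
    # stationary variance of the log-amplitude AR(1)
    if p.osc_stability < 1.0:
        sig_g2 = (wander * _AMP_JITTER) ** 2 / (1.0 - p.osc_stability**2)
    else:
        sig_g2 = 0.0
    # E[A^2] = A0^2 exp(sig_g2) for mean-corrected log-normal amplitude
    amp_cap = np.sqrt(1.8 * max(sigma_s**2 - drift_var, 0.0) / np.exp(sig_g2))
    a0 = min(p.osc_amp_mu, amp_cap)
    osc_var = 0.5 * a0**2 * np.exp(sig_g2)
    noise_var = max(sigma_s**2 - drift_var - osc_var, 1e-10)

    # slow AR(1) drift of the local level
    if drift_var > 0.0:
        innov_sd = np.sqrt(drift_var * (1.0 - _DRIFT_RHO**2))
        eps = rng.normal(0.0, innov_sd, size=n_strides)
        drift = np.empty(n_strides)
        drift[0] = rng.normal(0.0, np.sqrt(drift_var))
        for t in range(1, n_strides):
            drift[t] = _DRIFT_RHO * drift[t - 1] + eps[t]
    else:
        drift = np.zeros(n_strides)

    # oscillation with AR(1) log-amplitude and random-walk phase
    if sig_g2 > 0.0:
        g = np.empty(n_strides)
        g_innov = wander * _AMP_JITTER
        g[0] = rng.normal(0.0, np.sqrt(sig_g2))
        eta = rng.normal(0.0, g_innov, size=n_strides)
        for t in range(1, n_strides):
            g[t] = p.osc_stability * g[t - 1] + eta[t]
        amps = a0 * np.exp(g - 0.5 * sig_g2)
    else:
        amps = np.full(n_strides, a0)
    phase0 = rng.uniform(0.0, 2.0 * np.pi)
    steps = rng.normal(0.0, wander * _PHASE_JITTER, size=n_strides)
    steps[0] = 0.0
    phases = phase0 + np.cumsum(steps)
    osc = amps * np.sin(2.0 * np.pi * p.osc_freq * i + phases)

    noise = rng.normal(0.0, np.sqrt(noise_var), size=n_strides)
    # condition the fluctuation on its realized moments: center it and scale
    # its sample SD to sigma_s exactly, so the pre-clip series mean and SD
    # equal the drawn subject parameters (the between-subject spreads then
    # reproduce the calibration targets without finite-window bias)
    fluct = drift + osc + noise
    fluct = fluct - fluct.mean()
    realized = fluct.std(ddof=1)
    if realized > 0.0:
        fluct *= sigma_s / realized
    x = mu_s + fluct
    clipped = int(np.sum((x <= 0.0) | (x >= 1.0)))
    x = np.clip(x, _CLIP_EPS, 1.0 - _CLIP_EPS)
    return MFCSeries(
        subject_id,
        x,
        label=label,
        normalized=True,
        meta={
            "mu_s": mu_s,
            "sigma_s": sigma_s,
            "n_clipped": clipped,
            "osc_stability": p.osc_stability,
        },
    )


def generate_cohort(cfg: CohortConfig) -> Cohort:
    """Generate a labelled cohort; fully determined by ``cfg`` (incl. seed)."""
    rng = np.random.default_rng(cfg.seed)
    series: list[MFCSeries] = []
    for label in cfg.n_per_class:  # insertion order, deterministic
        params = cfg.params[label]
        for j in range(cfg.n_per_class[label]):
            series.append(
                generate_subject(
                    params,
                    cfg.n_strides,
                    rng,
                    subject_id=f"{label}_{j + 1:03d}",
                    label=label,
                )
            )
    return Cohort(series)
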