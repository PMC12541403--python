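"""Seeded generators for every input the analysis modules consume.

Provides mediator-only CVs (ideal surface-confined waves or a
diffusion-tailed variant), closed-form catalytic CV/CA surrogates (so the
trace-analysis functions can be exercised without the PDE solver), exposure
series with geometric decay, and the named default parameter sets of the
film model.  Identical spec + seed always produces identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .potentials import F, R, RedoxCouple, h2_equilibrium_potential
from .film_model import FilmParameters, InactivationModel
from .voltammetry import Trace
from .exposure import ExposureSeries

__all__ = [
    "GeneratorSpec",
    "generate_mediator_cv",
    "generate_catalytic_cv",
    "generate_catalytic_ca",
    "generate_exposure_series",
    "default_parameter_set",
    "PROFILE_NAMES",
]


@dataclass(frozen=True)
class GeneratorSpec:
    """Declarative description of one synthetic data set.

    ``kind`` is one of mediator_cv / catalytic_cv / catalytic_ca /
    exposure_series; ``truth`` holds the generator's ground-truth
    parameters; ``noise_sd`` is the additive Gaussian noise level as a
    fraction of the signal scale.
    """

    kind: str
    truth: dict = field(default_factory=dict)
    noise_sd: float = 0.0
    seed: int | None = None

    def __post_init__(self) -> None:
        kinds = ("mediator_cv", "catalytic_cv", "catalytic_ca", "exposure_series")
        if self.kind not in kinds:
            raise ValueError(f"kind must be one of {kinds}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")

    def generate(self):
        fn = {
            "mediator_cv": generate_mediator_cv,
            "catalytic_cv": generate_catalytic_cv,
            "catalytic_ca": generate_catalytic_ca,
            "exposure_series": generate_exposure_series,
        }[self.kind]
        return fn(noise_sd=self.noise_sd, seed=self.seed, **self.truth)


def _triangle(e_start, e_vertex, scan_rate, n_per_sweep):
    up = np.linspace(e_start, e_vertex, n_per_sweep + 1)
    down = np.linspace(e_vertex, e_start, n_per_sweep + 1)[1:]
    e = np.concatenate([up, down])
    t = np.arange(e.size) * abs(e_vertex - e_start) / (scan_rate * n_per_sweep)
    return t, e


def _semiderivative(y: np.ndarray, dt: float) -> np.ndarray:
    """Grunwald-Letnikov half-order derivative (for diffusion-shaped waves)."""
    n = y.size
    w = np.empty(n)
    w[0] = 1.0
    for k in range(1, n):
        w[k] = w[k - 1] * (k - 1.5) / k
    out = np.convolve(y, w)[:n]
    return out / math.sqrt(dt)


def generate_mediator_cv(
    e0: float = -0.40,
    peak_current: float = 1.0,
    scan_rate: float = 0.01,
    span: float = 0.25,
    n_per_sweep: int = 500,
    shape: str = "surface",
    temperature: float = 293.15,
    noise_sd: float = 0.0,
    seed: int | None = None,
) -> Trace:
    """Non-catalytic CV of the mediator film centered on the true ``e0``.

    ``shape="surface"`` gives the ideal surface-confined wave (anodic and
    cathodic peaks both exactly at e0, zero separation); ``"diffusion"``
    gives a semi-infinite-diffusion-shaped wave with the familiar
    tailing (peak positions shift symmetrically, so the midpoint still
    recovers e0).  Additive Gaussian noise of sd ``noise_sd * peak_current``
    is applied when requested; identical arguments + seed give identical
    traces.
    """
    t, e = _triangle(e0 - span, e0 + span, scan_rate, n_per_sweep)
    f = F / (R * temperature)
    theta = 1.0 / (1.0 + np.exp(-f * (e - e0)))  # oxidized fraction
    if shape == "surface":
        current = 4.0 * theta * (1.0 - theta)
        current[: n_per_sweep + 1] *= 1.0
        current[n_per_sweep + 1 :] *= -1.0
        current *= peak_current
    elif shape == "diffusion":
        dt = t[1] - t[0]
        current = _semiderivative(theta, dt)
        current *= peak_current / np.max(np.abs(current))
    else:
        raise ValueError("shape must be 'surface' or 'diffusion'")
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        current = current + rng.normal(0.0, noise_sd * peak_current, current.size)
    return Trace(
        time=t, potential=e, current=current, kind="CV",
        temperature=temperature, scan_rate=scan_rate,
        meta={"generator": "mediator_cv", "true_e0": e0, "shape": shape},
    )


def generate_catalytic_cv(
    e0_mediator: float = -0.40,
    pH: float = 7.0,
    plateau: float = 1.0,
    e_start: float = -0.65,
    e_vertex: float = 0.25,
    scan_rate: float = 0.01,
    n_per_sweep: int = 500,
    inactivation_drop: float = 0.0,
    e_drop: float = 0.0,
    drop_width: float = 0.05,
    temperature: float = 293.15,
    noise_sd: float = 0.0,
    seed: int | None = None,
) -> Trace:
    """Closed-form sigmoidal catalytic CV surrogate.

    The wave crosses zero exactly at E_eq(pH), rises with a mediator-limited
    Nernstian slope centered near the mediator E0, and saturates at
    ``plateau`` (H2 oxidation) with the thermodynamically coupled
    H2-evolution branch below E_eq.  ``inactivation_drop`` in (0, 1]
    attenuates the high-potential end around ``e_drop`` to emulate
    anaerobic inactivation.
    """
    t, e = _triangle(e_start, e_vertex, scan_rate, n_per_sweep)
    f = F / (R * temperature)
    e_eq = h2_equilibrium_potential(pH).value
    e_cat = max(e0_mediator, e_eq)  # catalysis centered on the mediator wave
    sig = 1.0 / (1.0 + np.exp(-f * (e - e_cat)))
    sig0 = 1.0 / (1.0 + math.exp(-f * (e_eq - e_cat)))
    # i = A*sig - B with A*sig0 = B so the crossing sits at E_eq
    a = plateau / (1.0 - sig0)
    current = a * (sig - sig0)
    if inactivation_drop > 0:
        gate = 1.0 - inactivation_drop / (1.0 + np.exp(-(e - e_drop) / drop_width))
        current = current * gate
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        current = current + rng.normal(0.0, noise_sd * plateau, current.size)
    return Trace(
        time=t, potential=e, current=current, kind="CV",
        pH=pH, temperature=temperature, scan_rate=scan_rate,
        meta={"generator": "catalytic_cv", "true_plateau": plateau,
              "true_e0": e0_mediator},
    )


def generate_catalytic_ca(
    steps=((-0.6, 120.0), (0.2, 120.0)),
    plateau_ox: float = 1.0,
    plateau_red: float = -0.5,
    e_eq: float = -0.42,
    tau: float = 5.0,
    dt: float = 0.5,
    noise_sd: float = 0.0,
    seed: int | None = None,
) -> Trace:
    """Closed-form CA surrogate: exponential relaxation to the quasi-steady
    current of each potential step (oxidation above ``e_eq``, evolution
    below)."""
    times, pots, curs = [], [], []
    t0 = 0.0
    i_prev = 0.0
    for e_step, dur in steps:
        target = plateau_ox if e_step > e_eq else (0.0 if e_step == e_eq else plateau_red)
        tt = np.arange(dt, dur + dt / 2, dt)
        ii = target + (i_prev - target) * np.exp(-tt / tau)
        times.append(t0 + tt)
        pots.append(np.full(tt.size, e_step))
        curs.append(ii)
        i_prev = ii[-1]
        t0 += dur
    t = np.concatenate(times)
    e = np.concatenate(pots)
    i = np.concatenate(curs)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        i = i + rng.normal(0.0, noise_sd * abs(plateau_ox), i.size)
    return Trace(time=t, potential=e, current=i, kind="CA",
                 meta={"generator": "catalytic_ca"})


def generate_exposure_series(
    r: float = 0.2,
    n: int = 4,
    noise_sd: float = 0.0,
    seed: int | None = None,
    exposure_duration_h: float = 1.0,
) -> ExposureSeries:
    """Geometric-decay exposure series activity[k] = (1-r)^k * (1 + eps_k).

    ``eps_k ~ N(0, noise_sd^2)``; the pre-exposure activity (cycle 0) is
    forced to exactly 1.
    """
    if not (0.0 <= r <= 1.0):
        raise ValueError("r must lie in [0, 1]")
    if n < 0:
        raise ValueError("n must be non-negative")
    k = np.arange(n + 1)
    activity = (1.0 - r) ** k
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        activity = activity * (1.0 + rng.normal(0.0, noise_sd, activity.size))
    activity = np.maximum(activity, 0.0)
    activity[0] = 1.0
    return ExposureSeries(
        cycle_index=k, activity=activity,
        exposure_duration_h=exposure_duration_h,
        meta={"generator": "exposure_series", "true_r": r},
    )


# named study conditions: mediator E0 (V vs SHE) per film chemistry
_MEDIATORS = {"DV1": -0.22, "DV2": -0.40, "PV2": -0.431}
PROFILE_NAMES = (
    "DV1_pH6", "DV1_pH7", "DV1_pH8.8",
    "DV2_pH6", "DV2_pH7", "DV2_pH8.8",
    "PV2_pH7",
)


def default_parameter_set(profile_name: str) -> FilmParameters:
    """Default :class:`FilmParameters` for a named film/pH condition.

    The inactivation potential is pinned at +0.17 V vs RHE (its pH-7 value
    of -0.25 V vs SHE), reflecting that the enzyme's oxidative inactivation
    tracks the H+/H2 scale while the viologen E0 does not -- this is what
    makes high-pH operation harsher for the high-potential mediator.
    """
    if profile_name not in PROFILE_NAMES:
        raise ValueError(
            f"unknown profile {profile_name!r}; choose from {PROFILE_NAMES}"
        )
    label, ph_part = profile_name.split("_pH")
    ph = float(ph_part)
    e_inact = 0.17 + h2_equilibrium_potential(ph).value
    return FilmParameters(
        mediator=RedoxCouple(_MEDIATORS[label], 1, label),
        pH=ph,
        inactivation=InactivationModel(e_inact=e_inact),
    )
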