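"""Synthetic longitudinal cohorts of GA lesions and microperimetry records.

The generator emulates the data structure of a longitudinal GA
microperimetry study: a cohort of participants, each with a growing
(possibly multifocal) atrophic lesion rasterized on a 30-degree
fundus-autofluorescence-like field, tested at baseline, month 3 and every
6 months thereafter on the T-shaped grid.  Sensitivities follow the
segmented distance/time model of :mod:`perilesion.model` with a shared
random intercept per participant-visit and i.i.d. residual noise.

Lesion foci are star-shaped blobs — discs perturbed by a fixed set of 8
low-order radial Fourier harmonics, normalised so the continuous area of a
focus is exactly ``pi * R^2``.  Growth dilates every focus about its own
centre so that the square root of total lesion area increases linearly
with time, the standard kinetic summary for GA enlargement.

Measurement modes:

``gaussian_rounded`` (default)
    latent threshold rounded to integer dB and clipped to [0, 20]; clipped
    zeros arising from a negative latent threshold are flagged as absolute
    scotomas.  This is what device exports look like.
``gaussian``
    the raw continuous latent threshold, neither rounded nor clipped.  A
    diagnostic mode matching the fitted model's own assumptions exactly,
    used for estimator-validation studies.
``staircase_4_2``
    a simulated 4-2 staircase with a deterministic observer, starting at
    10 dB attenuation.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable

import numpy as np
import pandas as pd

from .grid import GridLocus, build_t_grid
from .lesions import LesionMask, distances_to_ga
from .model import SegmentedModelParams, mean_function

__all__ = [
    "LesionFieldConfig",
    "SimulationConfig",
    "CohortData",
    "DEFAULT_TRUE_PARAMS",
    "DEFAULT_VISIT_MONTHS",
    "simulate_lesions",
    "simulate_cohort",
    "latent_sensitivity",
    "staircase_4_2",
]

#: Generative fixed effects used as simulation truth by default: the
#: segmented distance-response published for mesopic sensitivity around GA
#: borders (time slope -0.07 dB/month; before-knot -1.53 and -0.46 on
#: (k-d) and (k-d)^2; after-knot slope 0.56 dB/deg; knot 2.05 deg).  The
#: intercept 9.0 dB places the far-field plateau a few dB below age-normal.
DEFAULT_TRUE_PARAMS = SegmentedModelParams(
    beta0=9.0, beta_t=-0.07, b1=-1.53, b2=-0.46, b3=0.56, knot=2.05,
    sigma_u=2.0, sigma_e=3.0,
)

#: Baseline, month 3, then every 6 months to month 45.
DEFAULT_VISIT_MONTHS = (0.0, 3.0, 9.0, 15.0, 21.0, 27.0, 33.0, 39.0, 45.0)

_N_HARMONICS = 8  # radial perturbation harmonics (orders 2..9)


@dataclass(frozen=True)
class LesionFieldConfig:
    """Geometry of simulated lesions and their raster.

    ``sqrt_area_*`` control the participant-level baseline lesion size
    (square root of total area, degrees); growth is linear in sqrt-area at
    ``growth_rate_deg_per_month``.  Foci centres are placed within
    ``center_offset_max_deg`` of the fovea.  ``raster_size`` pixels cover a
    ``field_deg`` square field.
    """

    n_foci_range: tuple[int, int] = (1, 3)
    sqrt_area_mean_deg: float = 9.0
    sqrt_area_sd_deg: float = 2.0
    sqrt_area_min_deg: float = 4.0
    growth_rate_deg_per_month: float = 0.09
    center_offset_max_deg: float = 4.0
    harmonic_amplitude: float = 0.08
    raster_size: int = 768
    field_deg: float = 30.0

    @property
    def deg_per_pixel(self) -> float:
        return self.field_deg / self.raster_size


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for a synthetic cohort."""

    n_participants: int = 26
    visit_months: tuple[float, ...] = DEFAULT_VISIT_MONTHS
    dropout_prob: float = 0.15
    true_params: SegmentedModelParams = DEFAULT_TRUE_PARAMS
    sigma_u: float = 2.0
    sigma_e: float = 3.0
    lesions: LesionFieldConfig = field(default_factory=LesionFieldConfig)
    measurement_mode: str = "gaussian_rounded"
    start_db: float = 10.0  # staircase starting attenuation
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_participants < 0:
            raise ValueError("n_participants must be non-negative")
        months = tuple(self.visit_months)
        if months and (months[0] != 0 or any(b <= a for a, b in zip(months, months[1:]))):
            raise ValueError("visit months must start at 0 and strictly increase")
        if not 0.0 <= self.dropout_prob <= 1.0:
            raise ValueError("dropout_prob must be in [0, 1]")
        if self.sigma_u < 0 or self.sigma_e < 0:
            raise ValueError("noise SDs must be non-negative")
        if self.measurement_mode not in ("gaussian_rounded", "gaussian", "staircase_4_2"):
            raise ValueError(f"unknown measurement mode {self.measurement_mode!r}")


@dataclass
class CohortData:
    """Everything :func:`simulate_cohort` produced."""

    records: pd.DataFrame
    masks: dict[tuple[str, float], LesionMask]
    truth: pd.DataFrame  # one row per participant-visit: random intercept u
    config: SimulationConfig
    grid: list[GridLocus]


def latent_sensitivity(d_deg, t_months, params: SegmentedModelParams, foveal_deg=0.0):
    """Noise-free model sensitivity; delegates to :func:`model.mean_function`."""
    return mean_function(d_deg, t_months, params, foveal_deg)


# ---------------------------------------------------------------------------
# Lesion geometry


@dataclass(frozen=True)
class _Focus:
    cx_deg: float  # temporal-positive x of the focus centre
    cy_deg: float  # superior-positive y
    radius_deg: float  # base (month-0) equivalent-disc radius
    amps: tuple[float, ...]
    phases: tuple[float, ...]


def _sample_foci(rng: np.random.Generator, cfg: LesionFieldConfig) -> tuple[list[_Focus], float]:
    lo, hi = cfg.n_foci_range
    n = int(rng.integers(lo, hi + 1))
    s0 = max(cfg.sqrt_area_min_deg, float(rng.normal(cfg.sqrt_area_mean_deg, cfg.sqrt_area_sd_deg)))
    weights = rng.dirichlet(np.full(n, 2.0))
    radii = np.sqrt(weights * s0**2 / math.pi)
    foci: list[_Focus] = []
    for r in radii:
        amps = tuple(rng.uniform(-cfg.harmonic_amplitude, cfg.harmonic_amplitude, _N_HARMONICS))
        phases = tuple(rng.uniform(0.0, 2.0 * math.pi, _N_HARMONICS))
        placed = None
        for _ in range(200):
            rho = float(rng.uniform(0.0, cfg.center_offset_max_deg))
            ang = float(rng.uniform(0.0, 2.0 * math.pi))
            cand = (rho * math.cos(ang), rho * math.sin(ang))
            sep_ok = all(
                math.hypot(cand[0] - f.cx_deg, cand[1] - f.cy_deg)
                > 1.1 * (1 + 2 * cfg.harmonic_amplitude) * (r + f.radius_deg)
                for f in foci
            )
            if sep_ok:
                placed = cand
                break
            if placed is None:
                placed = cand  # keep first candidate as fallback; overlap allowed
        foci.append(_Focus(placed[0], placed[1], float(r), amps, phases))
    return foci, s0


def _render_mask(
    foci: Iterable[_Focus],
    scale: float,
    cfg: LesionFieldConfig,
    visit_month: float,
    participant_id: str,
) -> LesionMask:
    size = cfg.raster_size
    dpp = cfg.deg_per_pixel
    fovea = (size - 1) / 2.0
    pixels = np.zeros((size, size), dtype=bool)
    clipped = False
    for f in foci:
        # zero-mean perturbation is orthonormalised so the focus area stays
        # exactly pi * (R*scale)^2 in the continuum
        norm = math.sqrt(1.0 + 0.5 * sum(a * a for a in f.amps))
        R = f.radius_deg * scale
        r_max = R * (1.0 + sum(abs(a) for a in f.amps)) / norm
        c_row = fovea - f.cy_deg / dpp
        c_col = fovea + f.cx_deg / dpp
        half = int(math.ceil(r_max / dpp)) + 1
        r0 = int(math.floor(c_row)) - half
        r1 = int(math.ceil(c_row)) + half + 1
        c0 = int(math.floor(c_col)) - half
        c1 = int(math.ceil(c_col)) + half + 1
        if r0 < 0 or c0 < 0 or r1 > size or c1 > size:
            clipped = True
        r0c, r1c = max(r0, 0), min(r1, size)
        c0c, c1c = max(c0, 0), min(c1, size)
        if r0c >= r1c or c0c >= c1c:
            continue
        rows = np.arange(r0c, r1c)
        cols = np.arange(c0c, c1c)
        y = (fovea - rows[:, None]) * dpp - f.cy_deg
        x = (cols[None, :] - fovea) * dpp - f.cx_deg
        rr = np.hypot(x, y)
        theta = np.arctan2(y, x)
        boundary = np.ones_like(theta)
        for h, (a, ph) in enumerate(zip(f.amps, f.phases), start=2):
            boundary += a * np.cos(h * theta + ph)
        boundary *= R / norm
        pixels[r0c:r1c, c0c:c1c] |= rr <= boundary
    if clipped:
        warnings.warn(
            f"lesion for {participant_id} at month {visit_month} clipped at the field edge",
            stacklevel=2,
        )
    return LesionMask(
        pixels,
        deg_per_pixel=dpp,
        visit_month=visit_month,
        participant_id=participant_id,
    )


def _participant_ids(n: int) -> list[str]:
    return [f"P{i + 1:03d}" for i in range(n)]


def simulate_lesions(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> dict[tuple[str, float], LesionMask]:
    """Masks for every participant at every scheduled visit (no dropout).

    Sqrt of total lesion area grows linearly:
    ``sqrt(area)(m) = sqrt(area)(0) + growth_rate * m``, realised by
    scaling each focus about its own centre.
    """
    rng = np.random.default_rng(config.rng_seed) if rng is None else rng
    masks: dict[tuple[str, float], LesionMask] = {}
    for pid in _participant_ids(config.n_participants):
        foci, s0 = _sample_foci(rng, config.lesions)
        for m in config.visit_months:
            scale = (s0 + config.lesions.growth_rate_deg_per_month * m) / s0
            masks[(pid, m)] = _render_mask(foci, scale, config.lesions, m, pid)
    return masks


# ---------------------------------------------------------------------------
# Measurement


def staircase_4_2(
    true_threshold_db: float,
    start_db: float = 10.0,
    rng: np.random.Generator | None = None,
    db_min: float = 0.0,
    db_max: float = 20.0,
) -> tuple[float, bool]:
    """Simulate a 4-2 staircase with a deterministic observer.

    The observer responds iff the presented attenuation is at or below the
    true threshold.  Steps of 4 dB until the first reversal, then 2 dB
    until the second; returns ``(last_seen_attenuation, scotoma)``.  If the
    observer never responds — not even at 0 dB attenuation, the maximum
    intensity — the locus is an absolute scotoma and 0 dB is returned.

    ``rng`` is accepted for interface symmetry with probabilistic
    observers; the default observer ignores it.
    """
    if not db_min <= start_db <= db_max:
        raise ValueError("start_db outside the attainable range")
    level = start_db
    step = 4.0
    last_seen: float | None = None
    prev_resp: bool | None = None
    reversals = 0
    while True:
        seen = level <= true_threshold_db
        if seen:
            last_seen = level
        if prev_resp is not None and seen != prev_resp:
            reversals += 1
            if reversals == 1:
                step = 2.0
            else:
                break
        prev_resp = seen
        nxt = min(db_max, level + step) if seen else max(db_min, level - step)
        if nxt == level:  # pinned at a range boundary
            break
        level = nxt
    if last_seen is None:
        return 0.0, True
    return float(last_seen), False


def _measure(latent: float, mode: str, rng: np.random.Generator, start_db: float) -> tuple[float, bool]:
    if mode == "gaussian":
        return float(latent), False
    if mode == "gaussian_rounded":
        v = float(np.clip(round(latent), 0.0, 20.0))
        return v, bool(v == 0.0 and latent < 0.0)
    return staircase_4_2(latent, start_db, rng)


def simulate_cohort(config: SimulationConfig | None = None) -> CohortData:
    """Generate one synthetic cohort: records, per-visit masks and truth.

    Per retained participant-visit a random intercept
    ``u ~ N(0, sigma_u^2)`` is drawn once; each extralesional locus then
    measures ``mean_function(d, t) + u + N(0, sigma_e^2)`` through the
    configured measurement mode.  Intralesional loci are emitted as
    absolute scotomas (0 dB).  Dropout is monotone: after each attended
    visit the participant leaves the study with probability
    ``dropout_prob``.  Output is bit-identical for a fixed ``rng_seed``.
    """
    config = config or SimulationConfig()
    rng = np.random.default_rng(config.rng_seed)
    grid = build_t_grid()
    params = config.true_params

    rows = []
    truth_rows = []
    masks: dict[tuple[str, float], LesionMask] = {}
    for pid in _participant_ids(config.n_participants):
        foci, s0 = _sample_foci(rng, config.lesions)
        attended = list(config.visit_months[:1])
        for m in config.visit_months[1:]:
            if rng.random() < config.dropout_prob:
                break
            attended.append(m)
        for m in attended:
            scale = (s0 + config.lesions.growth_rate_deg_per_month * m) / s0
            mask = _render_mask(foci, scale, config.lesions, m, pid)
            masks[(pid, m)] = mask
            dists, inside = distances_to_ga(grid, mask)
            u = float(rng.normal(0.0, config.sigma_u)) if config.sigma_u > 0 else 0.0
            truth_rows.append((pid, m, u))
            for locus, dd, ins in zip(grid, dists, inside):
                if ins:
                    value, scot = 0.0, True
                else:
                    mu = mean_function(dd, m, params, locus.foveal_distance_deg)
                    eps = float(rng.normal(0.0, config.sigma_e)) if config.sigma_e > 0 else 0.0
                    value, scot = _measure(mu + u + eps, config.measurement_mode, rng, config.start_db)
                rows.append(
                    (pid, m, locus.locus_id, locus.axis, locus.axis_orientation, value, scot)
                )

    records = pd.DataFrame(
        rows,
        columns=[
            "participant_id",
            "visit_month",
            "locus_id",
            "axis",
            "axis_orientation",
            "sensitivity_db",
            "scotoma",
        ],
    )
    truth = pd.DataFrame(truth_rows, columns=["participant_id", "visit_month", "u"])
    return CohortData(records, masks, truth, config, grid)
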