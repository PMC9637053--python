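"""Synthetic phantom cohorts with analytically known radial FI structure.

Each muscle is modeled as an annular sector around a fixed center of
rotation, so a pixel's normalized radial depth has the closed form
``(d - r_in) / (r_out - r_in)``.  A subject's expected FI% at a pixel is
the muscle's baseline radial curve (deep Gaussian peak over a plateau for
multifidus and erector spinae; flatter, low-amplitude psoas) evaluated at
that depth, plus — for patients in the target muscle — a Gaussian
group-difference bump, plus smooth within-subject noise.  Noise is drawn
in the radial-depth domain (smooth 1D Gaussian noise of configurable
FWHM) and painted onto pixels by depth, so the extracted curves satisfy
the smoothness the 1D random-field model assumes.

Because the full geometry and curves are known, the generator doubles as
the pipeline's oracle: the ground-truth record predicts every downstream
expected output (curves, peak depth, cluster location).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .core import NormalizedProfile
from .geometry import COR_FRACTION, CenterOfRotation
from .io import FatFractionSlice, MuscleMask, write_fat_fraction, write_mask
from .spm import smooth_gaussian_noise

logger = logging.getLogger(__name__)

__all__ = [
    "MuscleGeometry",
    "BaselineCurve",
    "EffectSpec",
    "NoiseSpec",
    "SyntheticCohortConfig",
    "simulate_subject",
    "generate_cohort",
    "generate_null_profiles",
    "generate_effect_profiles",
]

_FWHM_TO_SIGMA = 1.0 / np.sqrt(8.0 * np.log(2.0))


@dataclass(frozen=True)
class MuscleGeometry:
    """Annular sector: radial span [r_inner, r_outer) pixels, angular span degrees.

    Angles are measured in the (row, col) plane as ``atan2(drow, dcol)``
    in degrees within (-180, 180].
    """

    r_inner: float
    r_outer: float
    theta_start: float
    theta_end: float

    def __post_init__(self) -> None:
        if not 0 <= self.r_inner < self.r_outer:
            raise ValueError("need 0 <= r_inner < r_outer")
        if not self.theta_start < self.theta_end:
            raise ValueError("need theta_start < theta_end")


@dataclass(frozen=True)
class BaselineCurve:
    """Radial FI% baseline: plateau plus a Gaussian peak.

    ``FI(depth) = plateau + amplitude * exp(-(depth - peak_depth)^2 / (2 s^2))``
    with ``s`` from ``peak_width`` (FWHM, % radial width); depth in % of
    the muscle's radial width.
    """

    plateau: float
    amplitude: float
    peak_depth: float
    peak_width: float

    def __call__(self, depth: np.ndarray | float) -> np.ndarray:
        depth = np.asarray(depth, dtype=float)
        if self.amplitude == 0:
            return np.full_like(depth, self.plateau)
        s = self.peak_width * _FWHM_TO_SIGMA
        return self.plateau + self.amplitude * np.exp(
            -((depth - self.peak_depth) ** 2) / (2.0 * s**2)
        )


@dataclass(frozen=True)
class EffectSpec:
    """Gaussian group-difference bump added to patients in one muscle."""

    muscle: str = "multifidus"
    center: float = 15.0  # % radial depth
    fwhm: float = 15.0  # % radial width
    amplitude: float = 8.0  # FI points

    def bump(self, depth: np.ndarray) -> np.ndarray:
        s = self.fwhm * _FWHM_TO_SIGMA
        return self.amplitude * np.exp(-((np.asarray(depth, float) - self.center) ** 2) / (2.0 * s**2))


@dataclass(frozen=True)
class NoiseSpec:
    """Smooth within-subject noise: SD in FI points, FWHM in depth nodes (%)."""

    sd: float = 5.0
    fwhm: float = 15.0


def _default_muscles() -> dict[str, MuscleGeometry]:
    # Disjoint angular sectors around the CoR; radial spans differ per muscle.
    # Half-integer radii align annulus centers (k + 0.5) with the normalized
    # depth grid, so extraction introduces no systematic depth shift.
    return {
        "multifidus": MuscleGeometry(6.5, 34.5, -55.0, 55.0),
        "erector_spinae": MuscleGeometry(8.5, 40.5, 65.0, 150.0),
        "psoas": MuscleGeometry(10.5, 42.5, -170.0, -70.0),
    }


def _default_baselines() -> dict[str, BaselineCurve]:
    # Deep-peaked multifidus / erector spinae, flat low psoas.
    return {
        "multifidus": BaselineCurve(plateau=15.0, amplitude=28.0, peak_depth=15.0, peak_width=25.0),
        "erector_spinae": BaselineCurve(plateau=16.0, amplitude=32.0, peak_depth=20.0, peak_width=28.0),
        "psoas": BaselineCurve(plateau=10.0, amplitude=5.0, peak_depth=70.0, peak_width=45.0),
    }


@dataclass
class SyntheticCohortConfig:
    """Everything needed to generate a reproducible phantom cohort."""

    n_patients: int = 20
    n_controls: int = 20
    image_shape: tuple[int, int] = (96, 96)
    pixel_spacing: float = 1.0
    # Off-lattice CoR: with the pivot on the integer pixel grid, all
    # center-to-pixel distances are square roots of integers, whose
    # number-theoretic clumping biases annulus means; a sub-pixel CoR (as
    # the 12.5% disc construction yields in practice) removes this.
    cor: tuple[float, float] = (48.2, 47.7)
    disc_length: float = 24.0
    muscles: dict[str, MuscleGeometry] = field(default_factory=_default_muscles)
    baselines: dict[str, BaselineCurve] = field(default_factory=_default_baselines)
    effect: EffectSpec = field(default_factory=EffectSpec)
    noise: NoiseSpec = field(default_factory=NoiseSpec)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 2 or self.n_controls < 2:
            raise ValueError("need at least 2 subjects per group")
        if self.effect.amplitude < 0 or self.noise.sd < 0:
            raise ValueError("amplitudes and noise SD must be non-negative")
        nr, nc = self.image_shape
        r0, c0 = self.cor
        for name, g in self.muscles.items():
            if (
                r0 - g.r_outer < 0
                or c0 - g.r_outer < 0
                or r0 + g.r_outer > nr - 1
                or c0 + g.r_outer > nc - 1
            ):
                raise ValueError(f"muscle {name!r} geometry overflows image bounds")

    def disc_endpoints(self) -> tuple[tuple[float, float], tuple[float, float]]:
        """Posterior/anterior points whose 12.5 % interpolation lands on the CoR."""
        r0, c0 = self.cor
        posterior = (r0, c0 - COR_FRACTION * self.disc_length)
        anterior = (posterior[0], posterior[1] + self.disc_length)
        return posterior, anterior


def _sector_masks(config: SyntheticCohortConfig) -> dict[str, np.ndarray]:
    nr, nc = config.image_shape
    rows = np.arange(nr, dtype=float)[:, None]
    cols = np.arange(nc, dtype=float)[None, :]
    dr = rows - config.cor[0]
    dc = cols - config.cor[1]
    dist = np.hypot(dr, dc)
    theta = np.degrees(np.arctan2(dr, dc))
    masks = {}
    for name, g in config.muscles.items():
        masks[name] = (
            (dist >= g.r_inner)
            & (dist < g.r_outer)
            & (theta >= g.theta_start)
            & (theta < g.theta_end)
        )
    return masks


def _depth_maps(config: SyntheticCohortConfig, masks: dict[str, np.ndarray]) -> dict[str, np.ndarray]:
    nr, nc = config.image_shape
    rows = np.arange(nr, dtype=float)[:, None]
    cols = np.arange(nc, dtype=float)[None, :]
    dist = np.hypot(rows - config.cor[0], cols - config.cor[1])
    depths = {}
    for name, g in config.muscles.items():
        d = 100.0 * (dist - g.r_inner) / (g.r_outer - g.r_inner)
        depths[name] = np.where(masks[name], d, np.nan)
    return depths


def _noise_curve(noise: NoiseSpec, rng: np.random.Generator, n_nodes: int = 101) -> np.ndarray:
    """One smooth noise realization over depth 0–100 % (unit grid of n_nodes)."""
    if noise.sd == 0:
        return np.zeros(n_nodes)
    return noise.sd * smooth_gaussian_noise(1, n_nodes, noise.fwhm, rng)[0]


def simulate_subject(
    config: SyntheticCohortConfig,
    is_patient: bool,
    rng: np.random.Generator,
    masks: dict[str, np.ndarray] | None = None,
    depths: dict[str, np.ndarray] | None = None,
    subject_id: str = "",
) -> tuple[FatFractionSlice, list[MuscleMask]]:
    """Generate one subject's FI image and muscle masks in memory.

    Pixels outside every muscle are marked missing.  FI is clipped to
    [0, 100].
    """
    if masks is None:
        masks = _sector_masks(config)
    if depths is None:
        depths = _depth_maps(config, masks)
    values = np.full(config.image_shape, np.nan)
    depth_grid = np.linspace(0.0, 100.0, 101)
    for name, mask in masks.items():
        curve = config.baselines[name](depth_grid)
        if is_patient and name == config.effect.muscle:
            curve = curve + config.effect.bump(depth_grid)
        curve = curve + _noise_curve(config.noise, rng)
        d = depths[name][mask]
        values[mask] = np.interp(d, depth_grid, curve)
    np.clip(values, 0.0, 100.0, out=values)
    fi = FatFractionSlice(
        values, pixel_spacing=config.pixel_spacing, subject_id=subject_id
    )
    muscle_masks = [MuscleMask(m, muscle=name, side="merged") for name, m in masks.items()]
    return fi, muscle_masks


def expected_profile(
    config: SyntheticCohortConfig,
    muscle: str,
    is_patient: bool,
    n_nodes: int = 101,
) -> np.ndarray:
    """Closed-form prediction of the noise-free extracted normalized curve.

    Mirrors the extraction pipeline analytically: each one-pixel annulus
    ``[k, k+1)`` intersected with the muscle's radial span has continuum
    mean radius ``(2/3)(b^3 - a^3)/(b^2 - a^2)``; the true curve (baseline
    plus bump for patients in the target muscle) is evaluated at the
    corresponding depth, three-point smoothed, and linearly resampled on
    the node grid exactly as :func:`fatmap.core.normalize_profile` does.
    The only term not modeled is pixel discretization within annuli.
    """
    g = config.muscles[muscle]
    first, last = int(np.floor(g.r_inner)), int(np.ceil(g.r_outer)) - 1
    ks = np.arange(first, last + 1)
    a = np.maximum(ks.astype(float), g.r_inner)
    b = np.minimum(ks + 1.0, g.r_outer)
    mean_r = (2.0 / 3.0) * (b**3 - a**3) / (b**2 - a**2)
    depth = 100.0 * (mean_r - g.r_inner) / (g.r_outer - g.r_inner)
    y = np.asarray(config.baselines[muscle](depth), dtype=float)
    if is_patient and muscle == config.effect.muscle:
        y = y + config.effect.bump(depth)
    y = np.clip(y, 0.0, 100.0)
    sm = y.copy()
    if y.size >= 3:
        sm[1:-1] = (y[:-2] + y[1:-1] + y[2:]) / 3.0
        sm[0] = (y[0] + y[1]) / 2.0
        sm[-1] = (y[-2] + y[-1]) / 2.0
    nodes = np.linspace(0.0, 100.0, n_nodes)
    positions = first + (last - first) * nodes / 100.0
    return np.interp(positions, ks.astype(float), sm)


def _sample_metadata(config: SyntheticCohortConfig, is_patient: bool, rng: np.random.Generator) -> dict:
    if is_patient:
        vas = float(np.clip(np.round(rng.normal(6.5, 1.6), 1), 4.0, 10.0))
        odi = float(np.clip(np.round(rng.normal(38.0, 12.0)), 30, 100))
        cep = bool(rng.random() < 0.6)
        pfirrmann = int(rng.choice([2, 3, 4, 5], p=[0.15, 0.3, 0.35, 0.2]))
        modic = bool(rng.random() < 0.4)
    else:
        vas = float(np.clip(np.round(rng.normal(0.8, 0.8), 1), 0.0, 3.0))
        odi = float(np.clip(np.round(rng.normal(5.0, 4.0)), 0, 20))
        cep = bool(rng.random() < 0.2)
        pfirrmann = int(rng.choice([1, 2, 3], p=[0.4, 0.4, 0.2]))
        modic = bool(rng.random() < 0.1)
    return {
        "vas": vas,
        "odi": odi,
        "cep_damage": cep,
        "pfirrmann": pfirrmann,
        "modic": modic,
        "age": float(np.round(rng.normal(46.0, 12.0), 1)),
        "sex": str(rng.choice(["F", "M"])),
        "bmi": float(np.round(rng.normal(24.5, 4.0), 1)),
    }


def generate_cohort(config: SyntheticCohortConfig, out_dir: str | Path) -> dict:
    """Write a full phantom cohort to disk; return the ground-truth record.

    Layout: one directory per subject holding ``fat_fraction.nii`` and one
    ``mask_<muscle>.png`` per muscle; a top-level ``cohort.csv`` with
    metadata and disc-geometry columns; ``ground_truth.json`` with the
    true baseline curves and effect.  Deterministic given ``config.seed``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    masks = _sector_masks(config)
    depths = _depth_maps(config, masks)
    posterior, anterior = config.disc_endpoints()

    rows = []
    groups = ["patient"] * config.n_patients + ["control"] * config.n_controls
    for i, group in enumerate(groups):
        sid = f"sub-{i + 1:03d}"
        is_patient = group == "patient"
        fi, muscle_masks = simulate_subject(
            config, is_patient, rng, masks=masks, depths=depths, subject_id=sid
        )
        sdir = out_dir / sid
        sdir.mkdir(exist_ok=True)
        write_fat_fraction(fi, sdir / "fat_fraction.nii")
        for m in muscle_masks:
            write_mask(m, sdir / f"mask_{m.muscle}.png")
        meta = _sample_metadata(config, is_patient, rng)
        rows.append(
            {
                "subject_id": sid,
                "group": group,
                **meta,
                "posterior_row": posterior[0],
                "posterior_col": posterior[1],
                "anterior_row": anterior[0],
                "anterior_col": anterior[1],
            }
        )
    cohort = pd.DataFrame(rows)
    cohort.to_csv(out_dir / "cohort.csv", index=False)

    depth_grid = np.linspace(0.0, 100.0, 101)
    truth = {
        "seed": config.seed,
        "n_patients": config.n_patients,
        "n_controls": config.n_controls,
        "cor": list(config.cor),
        "effect": asdict(config.effect),
        "noise": asdict(config.noise),
        "baselines": {
            name: {
                "params": asdict(curve),
                "depth_percent": depth_grid.tolist(),
                "fi_percent": curve(depth_grid).tolist(),
            }
            for name, curve in config.baselines.items()
        },
        "muscle_geometry": {name: asdict(g) for name, g in config.muscles.items()},
    }
    with open(out_dir / "ground_truth.json", "w") as fh:
        json.dump(truth, fh, sort_keys=True, indent=1)
    logger.info("wrote synthetic cohort of %d subjects to %s", len(groups), out_dir)
    return truth


def generate_null_profiles(
    n_per_group: int,
    q_nodes: int,
    fwhm: float,
    seed: int,
    baseline: np.ndarray | float = 0.0,
    noise_sd: float = 1.0,
    muscle: str = "multifidus",
) -> tuple[list[NormalizedProfile], list[NormalizedProfile]]:
    """Two groups of identically distributed smooth curves (null hypothesis).

    Each curve is the shared baseline plus smooth unit-variance Gaussian
    noise scaled by ``noise_sd``; both groups are drawn from the same
    distribution, so any SPM detection is a false positive.
    """
    if n_per_group < 2:
        raise ValueError("need n >= 2 per group")
    rng = np.random.default_rng(seed)
    nodes = np.linspace(0.0, 100.0, q_nodes)
    base = np.broadcast_to(np.asarray(baseline, dtype=float), (q_nodes,))
    curves = base + noise_sd * smooth_gaussian_noise(2 * n_per_group, q_nodes, fwhm, rng)

    def wrap(rows: np.ndarray, prefix: str) -> list[NormalizedProfile]:
        return [
            NormalizedProfile(
                nodes=nodes, fi=row, muscle=muscle, subject_id=f"{prefix}{i:03d}", smoothed=True
            )
            for i, row in enumerate(rows)
        ]

    return wrap(curves[:n_per_group], "A"), wrap(curves[n_per_group:], "B")


def generate_effect_profiles(
    n_per_group: int,
    q_nodes: int,
    seed: int,
    effect: EffectSpec | None = None,
    noise: NoiseSpec | None = None,
    baseline: np.ndarray | float = 0.0,
    muscle: str = "multifidus",
) -> tuple[list[NormalizedProfile], list[NormalizedProfile]]:
    """Curve-level two-group cohort with a known Gaussian group difference.

    Group A receives the effect bump; group B does not.  Used for power /
    parameter-recovery studies without the imaging round trip.
    """
    effect = effect or EffectSpec()
    noise = noise or NoiseSpec()
    rng = np.random.default_rng(seed)
    nodes = np.linspace(0.0, 100.0, q_nodes)
    base = np.broadcast_to(np.asarray(baseline, dtype=float), (q_nodes,))
    bump = effect.bump(nodes)
    z = smooth_gaussian_noise(2 * n_per_group, q_nodes, noise.fwhm, rng)
    A = base + bump + noise.sd * z[:n_per_group]
    B = base + noise.sd * z[n_per_group:]

    def wrap(rows: np.ndarray, prefix: str) -> list[NormalizedProfile]:
        return [
            NormalizedProfile(
                nodes=nodes, fi=row, muscle=muscle, subject_id=f"{prefix}{i:03d}", smoothed=True
            )
            for i, row in enumerate(rows)
        ]

    return wrap(A, "A"), wrap(B, "B")
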