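"""Radial fat-distribution curves ("fat-maps") for individual muscles.

Concentric one-pixel-wide annuli radiate outward from the motion-segment
center of rotation (CoR).  Annulus ``k`` holds the mask pixels whose
center-to-CoR distance ``d`` satisfies ``k <= d < k+1``; every mask pixel
belongs to exactly one annulus.  The mean FI% per annulus forms the raw
radial profile, which is then smoothed with a three-point moving average
and distance-normalized onto a fixed grid spanning 0–100 % of the
muscle's radial width.  Peak location within thirds of the radial width
(deep / intermediate / superficial) summarizes the curve shape.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .geometry import CenterOfRotation, distance_map
from .io import FatFractionSlice, MuscleMask

__all__ = [
    "RadialProfile",
    "NormalizedProfile",
    "PeakSummary",
    "build_radial_profile",
    "overall_mean_fi",
    "smooth_profile",
    "normalize_profile",
    "detect_peak",
    "peak_prevalence",
    "write_profiles_csv",
    "read_profiles_csv",
    "write_peaks_csv",
]

#: Default radial-width tertile boundaries (percent) for deep/intermediate/superficial.
DEEP_CUT = 33.3
SUPERFICIAL_CUT = 66.7

#: Default resampling resolution: nodes at 0, 1, ..., 100 % radial width.
N_NODES = 101


@dataclass
class RadialProfile:
    """Mean FI% per one-pixel annulus around the CoR for one muscle.

    ``mean_fi[k]`` is the mean over mask pixels in annulus ``k`` (NaN where
    the annulus holds no contributing pixel); ``pixel_count[k]`` counts the
    contributing (non-missing FI) pixels.
    """

    muscle: str
    mean_fi: np.ndarray
    pixel_count: np.ndarray
    cor: CenterOfRotation
    subject_id: str = ""
    side: str = "merged"
    smoothed: bool = False

    def __post_init__(self) -> None:
        self.mean_fi = np.asarray(self.mean_fi, dtype=float)
        self.pixel_count = np.asarray(self.pixel_count, dtype=int)
        if self.mean_fi.shape != self.pixel_count.shape or self.mean_fi.ndim != 1:
            raise ValueError("mean_fi and pixel_count must be matching 1D arrays")

    @property
    def occupied(self) -> np.ndarray:
        """Boolean array: annuli with a defined mean."""
        return np.isfinite(self.mean_fi)

    @property
    def n_annuli(self) -> int:
        return self.mean_fi.size


@dataclass
class NormalizedProfile:
    """FI% curve resampled on equally spaced nodes over 0–100 % radial width.

    Node 0 maps to the innermost occupied annulus and node 100 to the
    outermost, so the grid is identical across subjects regardless of each
    muscle's absolute radial extent.
    """

    nodes: np.ndarray
    fi: np.ndarray
    muscle: str
    subject_id: str = ""
    side: str = "merged"
    smoothed: bool = False

    def __post_init__(self) -> None:
        self.nodes = np.asarray(self.nodes, dtype=float)
        self.fi = np.asarray(self.fi, dtype=float)
        if self.nodes.shape != self.fi.shape or self.nodes.ndim != 1:
            raise ValueError("nodes and fi must be matching 1D arrays")
        if not np.all(np.isfinite(self.fi)):
            raise ValueError("normalized profile must be finite at every node")

    @property
    def n_nodes(self) -> int:
        return self.nodes.size


@dataclass(frozen=True)
class PeakSummary:
    """Global maximum of a normalized curve and its radial-region label."""

    peak_fi: float
    peak_depth: float
    region: str


def build_radial_profile(
    fi: FatFractionSlice, mask: MuscleMask, cor: CenterOfRotation
) -> RadialProfile:
    """Bin mask pixels into one-pixel annuli around the CoR and average FI%.

    Annulus ``k`` is the half-open radial band ``[k, k+1)`` in pixel units,
    so the annuli partition the mask with no double counting.  Missing FI
    pixels are excluded from the means; an annulus whose pixels are all
    missing gets a NaN mean and zero count.
    """
    if fi.values.shape != mask.mask.shape:
        raise ValueError(
            f"image shape {fi.values.shape} does not match mask shape {mask.mask.shape}"
        )
    if not mask.usable:
        raise ValueError(f"empty mask for muscle {mask.muscle!r}")
    values = fi.values[mask.mask]
    finite = np.isfinite(values)
    if not finite.any():
        raise ValueError(f"all FI values missing under {mask.muscle!r} mask")
    dist = distance_map(fi.values.shape, cor)[mask.mask]
    k = np.floor(dist).astype(int)
    n_annuli = int(k.max()) + 1
    counts = np.bincount(k[finite], minlength=n_annuli)
    sums = np.bincount(k[finite], weights=values[finite], minlength=n_annuli)
    with np.errstate(invalid="ignore"):
        means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return RadialProfile(
        muscle=mask.muscle,
        mean_fi=means,
        pixel_count=counts,
        cor=cor,
        subject_id=fi.subject_id,
        side=mask.side,
    )


def overall_mean_fi(fi: FatFractionSlice, mask: MuscleMask) -> float:
    """Unweighted mean FI% over all (non-missing) mask pixels."""
    if fi.values.shape != mask.mask.shape:
        raise ValueError("image and mask shapes differ")
    if not mask.usable:
        raise ValueError(f"empty mask for muscle {mask.muscle!r}")
    values = fi.values[mask.mask]
    if not np.isfinite(values).any():
        raise ValueError(f"all FI values missing under {mask.muscle!r} mask")
    return float(np.nanmean(values))


def _fill_interior_gaps(mean_fi: np.ndarray) -> tuple[np.ndarray, int, int]:
    """Linearly interpolate missing annuli between the first and last occupied.

    Returns the filled curve plus the indices of the occupied span.  Annuli
    outside the span stay missing.
    """
    occ = np.flatnonzero(np.isfinite(mean_fi))
    if occ.size == 0:
        raise ValueError("profile has no occupied annulus")
    first, last = int(occ[0]), int(occ[-1])
    filled = mean_fi.copy()
    span = np.arange(first, last + 1)
    filled[span] = np.interp(span, occ, mean_fi[occ])
    return filled, first, last


def smooth_profile(p: RadialProfile) -> RadialProfile:
    """Three-point moving average along the occupied radial span.

    Interior missing annuli are first filled by linear interpolation
    between their nearest occupied neighbors so the window always has
    defined values.  Endpoints use the one-sided two-point mean; a span of
    one or two annuli is returned unchanged apart from gap filling.
    """
    filled, first, last = _fill_interior_gaps(p.mean_fi)
    y = filled[first : last + 1]
    if y.size >= 3:
        sm = y.copy()
        sm[1:-1] = (y[:-2] + y[1:-1] + y[2:]) / 3.0
        sm[0] = (y[0] + y[1]) / 2.0
        sm[-1] = (y[-2] + y[-1]) / 2.0
    else:
        sm = y
    out = filled.copy()
    out[first : last + 1] = sm
    return replace(p, mean_fi=out, smoothed=True)


def normalize_profile(p: RadialProfile, n_nodes: int = N_NODES) -> NormalizedProfile:
    """Resample a radial profile onto ``n_nodes`` nodes over 0–100 % width.

    The curve is linearly interpolated between annulus centers; node 0
    takes the innermost occupied annulus mean exactly and the last node the
    outermost, so endpoint values are preserved.
    """
    if n_nodes < 2:
        raise ValueError("n_nodes must be at least 2")
    occ = np.flatnonzero(p.occupied)
    if occ.size < 2:
        raise ValueError(
            f"need at least 2 occupied annuli to normalize, got {occ.size}"
        )
    filled, first, last = _fill_interior_gaps(p.mean_fi)
    nodes = np.linspace(0.0, 100.0, n_nodes)
    positions = first + (last - first) * nodes / 100.0
    fi = np.interp(positions, np.arange(first, last + 1), filled[first : last + 1])
    return NormalizedProfile(
        nodes=nodes,
        fi=fi,
        muscle=p.muscle,
        subject_id=p.subject_id,
        side=p.side,
        smoothed=p.smoothed,
    )


def detect_peak(
    profile: NormalizedProfile,
    deep_cut: float = DEEP_CUT,
    superficial_cut: float = SUPERFICIAL_CUT,
) -> PeakSummary:
    """Global curve maximum, its radial depth, and its region label.

    Ties are broken toward the smallest depth.  The region is ``deep``
    below ``deep_cut``, ``superficial`` above ``superficial_cut`` and
    ``intermediate`` between.
    """
    idx = int(np.argmax(profile.fi))  # first occurrence == smallest depth
    depth = float(profile.nodes[idx])
    if depth < deep_cut:
        region = "deep"
    elif depth > superficial_cut:
        region = "superficial"
    else:
        region = "intermediate"
    return PeakSummary(peak_fi=float(profile.fi[idx]), peak_depth=depth, region=region)


def peak_prevalence(
    profiles: Iterable[NormalizedProfile],
    muscle: str | None = None,
    region: str = "deep",
    deep_cut: float = DEEP_CUT,
    superficial_cut: float = SUPERFICIAL_CUT,
) -> float:
    """Fraction of curves whose global peak falls in the queried region."""
    pool = [p for p in profiles if muscle is None or p.muscle == muscle]
    if not pool:
        raise ValueError("no profiles to evaluate")
    hits = sum(
        detect_peak(p, deep_cut=deep_cut, superficial_cut=superficial_cut).region == region
        for p in pool
    )
    return hits / len(pool)


def write_profiles_csv(profiles: Sequence[NormalizedProfile], path: str | Path) -> None:
    """Long-format CSV: subject_id, muscle, side, node_percent, fi_percent."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["subject_id", "muscle", "side", "node_percent", "fi_percent"])
        for p in profiles:
            for x, y in zip(p.nodes, p.fi):
                w.writerow([p.subject_id, p.muscle, p.side, repr(float(x)), repr(float(y))])


def read_profiles_csv(path: str | Path) -> list[NormalizedProfile]:
    """Read the long-format profile CSV back into NormalizedProfile objects."""
    import pandas as pd

    df = pd.read_csv(path)
    out: list[NormalizedProfile] = []
    for (sid, muscle, side), grp in df.groupby(
        ["subject_id", "muscle", "side"], sort=True
    ):
        grp = grp.sort_values("node_percent")
        out.append(
            NormalizedProfile(
                nodes=grp["node_percent"].to_numpy(float),
                fi=grp["fi_percent"].to_numpy(float),
                muscle=str(muscle),
                subject_id=str(sid),
                side=str(side),
                smoothed=True,
            )
        )
    return out


def write_peaks_csv(
    profiles: Sequence[NormalizedProfile],
    path: str | Path,
    deep_cut: float = DEEP_CUT,
    superficial_cut: float = SUPERFICIAL_CUT,
) -> None:
    """Per-curve peak summary CSV: subject_id, muscle, peak_fi, peak_depth, region."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["subject_id", "muscle", "peak_fi", "peak_depth", "region"])
        for p in profiles:
            pk = detect_peak(p, deep_cut=deep_cut, superficial_cut=superficial_cut)
            w.writerow([p.subject_id, p.muscle, repr(pk.peak_fi), repr(pk.peak_depth), pk.region])
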