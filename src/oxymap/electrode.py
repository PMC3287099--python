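"""Virtual polarographic needle-electrode sampling.

Oxygen readings are taken along linear insertion tracks at fixed spacing
(0.2 mm by default, 20-30 readings per track), mimicking clinical
polarographic electrode protocols.  Each reading reports the oxygen value
of the 60 µm grid cell containing the electrode tip — at the default grid
resolution one cell *is* the instrument's averaging volume (a group of
5-6 tumor cells).

Four placement strategies are provided:

``uniform``
    parallel vertical tracks at equally spaced x-positions across the
    tumor bounding box, entering from the top;
``random``
    entry points uniform on the tumor boundary, each aimed at a uniformly
    random interior tumor point;
``half_radial``
    entry angles evenly spaced over a limited arc (default the
    10-to-2-o'clock arc, 60°-120°, the case of a tumor accessible from one
    side only), aimed at the tumor centroid;
``full_radial``
    entry angles evenly spaced around the full circle, aimed at the
    centroid.

The arc is a parameter, so the 10-2, 9-3 and full-circle variants are all
expressible.  Angles follow the clock-face convention: measured from the
+x axis with 12 o'clock at 90° (the y axis of the raster points down).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from .grid import GridGeometry, VascularDomain

__all__ = [
    "Track",
    "SamplingPlan",
    "ReadingSet",
    "GeometryError",
    "EmptySampleError",
    "make_plan",
    "sample",
    "hp_from_readings",
]

Strategy = Literal["uniform", "random", "half_radial", "full_radial"]


class GeometryError(ValueError):
    """Requested tracks cannot be kept distinct at the grid resolution."""


class EmptySampleError(ValueError):
    """A sampling plan produced no in-domain readings."""


@dataclass(frozen=True)
class Track:
    """One linear electrode track: entry point, unit direction, spacing."""

    entry_mm: tuple[float, float]
    direction: tuple[float, float]
    step_mm: float = 0.2
    n_readings: int = 25

    def __post_init__(self) -> None:
        if self.step_mm <= 0:
            raise ValueError("step_mm must be positive")
        if self.n_readings < 1:
            raise ValueError("n_readings must be >= 1")
        norm = float(np.hypot(*self.direction))
        if norm == 0:
            raise ValueError("direction must be a nonzero vector")
        object.__setattr__(
            self, "direction", (self.direction[0] / norm, self.direction[1] / norm)
        )

    @property
    def length_mm(self) -> float:
        return self.step_mm * (self.n_readings - 1)

    def positions(self) -> np.ndarray:
        """(n_readings, 2) array of (x, y) sample positions in mm."""
        k = np.arange(self.n_readings)[:, None]
        return np.asarray(self.entry_mm) + k * self.step_mm * np.asarray(self.direction)


@dataclass(frozen=True)
class SamplingPlan:
    strategy: str
    tracks: tuple[Track, ...]
    seed: int | None = None

    def __post_init__(self) -> None:
        if len(self.tracks) < 1:
            raise ValueError("a plan needs at least one track")


def _ray_boundary_exit(
    domain: VascularDomain, origin: np.ndarray, u: np.ndarray
) -> np.ndarray:
    """Outermost tumor point along the ray origin + t*u (t >= 0)."""
    g = domain.geometry
    s = g.spacing_mm
    t_max = g.extent_mm * np.sqrt(2.0)
    ts = np.arange(0.0, t_max, s / 2.0)
    pts = origin + ts[:, None] * u
    jj = np.floor(pts[:, 0] / s).astype(int)
    ii = np.floor(pts[:, 1] / s).astype(int)
    ok = (ii >= 0) & (ii < g.n) & (jj >= 0) & (jj < g.n)
    inside = np.zeros(ts.shape, bool)
    inside[ok] = domain.tumor_mask[ii[ok], jj[ok]]
    if not inside.any():
        return origin
    return pts[np.nonzero(inside)[0][-1]]


def _boundary_cells(domain: VascularDomain) -> np.ndarray:
    from scipy import ndimage

    t = domain.tumor_mask
    return np.argwhere(t & ~ndimage.binary_erosion(t))


def make_plan(
    strategy: Strategy,
    n_tracks: int,
    domain: VascularDomain,
    seed: int | None = None,
    step_mm: float = 0.2,
    n_readings: int = 25,
    arc_deg: tuple[float, float] = (60.0, 120.0),
) -> SamplingPlan:
    """Build a sampling plan over a domain for one placement strategy.

    ``arc_deg`` bounds the entry angles of ``half_radial`` (default the
    10-2 o'clock arc); ``full_radial`` ignores it and spans 360°.  Random
    strategies are reproducible from ``seed``.
    """
    if n_tracks < 1:
        raise ValueError("n_tracks must be >= 1")
    g = domain.geometry
    s = g.spacing_mm
    cx, cy = domain.tumor_centroid_mm()
    centroid = np.array([cx, cy])
    tracks: list[Track] = []

    if strategy == "uniform":
        x0, y0, x1, _ = domain.tumor_bbox_mm()
        w = x1 - x0
        if n_tracks > max(1, int(round(w / s))):
            raise GeometryError(
                f"{n_tracks} parallel tracks cannot be distinct over a {w:.2f} mm box"
            )
        for k in range(1, n_tracks + 1):
            tracks.append(
                Track((x0 + w * k / (n_tracks + 1), y0), (0.0, 1.0), step_mm, n_readings)
            )
    elif strategy == "random":
        rng = np.random.default_rng(seed)
        boundary = _boundary_cells(domain)
        interior = np.argwhere(domain.tumor_mask)
        for _ in range(n_tracks):
            for _attempt in range(100):
                bi, bj = boundary[rng.integers(len(boundary))]
                ti, tj = interior[rng.integers(len(interior))]
                entry = np.array([(bj + 0.5) * s, (bi + 0.5) * s])
                target = np.array([(tj + 0.5) * s, (ti + 0.5) * s])
                d = target - entry
                if np.hypot(*d) > s:
                    break
            tracks.append(Track(tuple(entry), tuple(d), step_mm, n_readings))
    elif strategy in ("half_radial", "full_radial"):
        if strategy == "full_radial":
            angles = 90.0 + 360.0 * np.arange(n_tracks) / n_tracks
        else:
            a0, a1 = arc_deg
            if n_tracks == 1:
                angles = np.array([(a0 + a1) / 2.0])
            else:
                angles = np.linspace(a0, a1, n_tracks)
        entry_cells = set()
        for ang in np.deg2rad(angles):
            u = np.array([np.cos(ang), -np.sin(ang)])  # y axis points down
            entry = _ray_boundary_exit(domain, centroid, u)
            cell = g.cell_of(*entry)
            if cell in entry_cells:
                raise GeometryError(
                    f"{n_tracks} {strategy} tracks collide at grid resolution"
                )
            entry_cells.add(cell)
            tracks.append(Track(tuple(entry), tuple(centroid - entry), step_mm, n_readings))
    else:
        raise ValueError(f"unknown strategy {strategy!r}")
    return SamplingPlan(strategy, tuple(tracks), seed)


@dataclass
class ReadingSet:
    """Pooled electrode readings with per-reading positions and provenance."""

    frame: pd.DataFrame  # columns: track, x_mm, y_mm, value
    plan: SamplingPlan | None = None
    field_id: str | None = None

    @property
    def values(self) -> np.ndarray:
        return self.frame["value"].to_numpy()

    def per_track(self) -> dict[int, np.ndarray]:
        return {
            int(t): grp["value"].to_numpy() for t, grp in self.frame.groupby("track")
        }


def sample(
    plan: SamplingPlan,
    K: np.ndarray,
    geometry: GridGeometry,
    tumor_mask: np.ndarray | None = None,
    noise_sigma: float = 0.0,
    seed: int | None = None,
    field_id: str | None = None,
) -> ReadingSet:
    """Read the oxygen field along every track of a plan.

    Each reading is the value of the grid cell containing the sample
    position (the cell is the 60 µm measurement volume).  Positions
    outside the grid are discarded with a warning; positions outside the
    tumor mask, when one is given, are discarded silently (the electrode
    protocol samples tumor tissue; pass ``tumor_mask=None`` to keep every
    in-grid reading).  Optional zero-mean Gaussian instrument noise of
    standard deviation ``noise_sigma`` is added and clipped at zero;
    the default is noise-free.
    """
    s = geometry.spacing_mm
    rows = []
    n_dropped = 0
    for t_id, track in enumerate(plan.tracks):
        pos = track.positions()
        jj = np.floor(pos[:, 0] / s).astype(int)
        ii = np.floor(pos[:, 1] / s).astype(int)
        ok = (ii >= 0) & (ii < geometry.n) & (jj >= 0) & (jj < geometry.n)
        n_dropped += int((~ok).sum())
        if tumor_mask is not None:
            in_tumor = np.zeros(ok.shape, bool)
            in_tumor[ok] = np.asarray(tumor_mask, bool)[ii[ok], jj[ok]]
            ok &= in_tumor
        for p, i, j in zip(pos[ok], ii[ok], jj[ok]):
            rows.append((t_id, p[0], p[1], float(K[i, j])))
    if n_dropped:
        warnings.warn(f"{n_dropped} electrode readings fell outside the grid and were dropped")
    if not rows:
        raise EmptySampleError("sampling plan produced no in-domain readings")
    frame = pd.DataFrame(rows, columns=["track", "x_mm", "y_mm", "value"])
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        frame["value"] = np.clip(
            frame["value"] + rng.normal(0.0, noise_sigma, len(frame)), 0.0, None
        )
    return ReadingSet(frame, plan, field_id)


def hp_from_readings(
    readings: ReadingSet | np.ndarray,
    k_max: float,
    thresholds: Sequence[float] = (2.5, 5.0, 10.0),
) -> Mapping[float, float]:
    """Hypoxic fractions from pooled electrode readings.

    For each threshold, the fraction of all readings (pooled over tracks)
    strictly below ``pct/100 * k_max``.  ``k_max`` is normally the global
    field maximum, so the estimate shares its reference with the area
    method; pass ``max(readings)`` to normalize by the readings instead.
    """
    if k_max <= 0:
        raise ValueError("k_max must be positive")
    vals = readings.values if isinstance(readings, ReadingSet) else np.asarray(readings)
    return {
        float(pct): float((vals < (float(pct) / 100.0) * k_max).mean())
        for pct in thresholds
    }
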