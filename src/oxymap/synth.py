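"""Synthetic vascular domains emulating histologic tumor cross-sections.

Generates :class:`~oxymap.grid.VascularDomain` fixtures with controllable
vascular density, perfusion fraction, and a distance-based reference
hypoxia mask.  The masks emulate what thresholded immunofluorescence
images of a xenograft section provide: sparse single-cell vessel
cross-sections inside a blob-shaped tumor, a perfused subset of those
vessels, and a hypoxia stain whose geometric proxy here is "farther than a
diffusion limit from any perfused vessel".

Vessel placement is either uniform over the tumor or sequential with
nearest-neighbor spacing drawn from a lognormal intervascular-distance
distribution, the standard description of tumor capillary spacing.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Literal, Sequence

import numpy as np
from scipy import ndimage

from .grid import DomainError, GridGeometry, VascularDomain

__all__ = [
    "SynthParams",
    "CapacityError",
    "generate_domain",
    "generate_cohort",
    "cohort_params",
]


class CapacityError(DomainError):
    """More vessels requested than tumor cells available."""


@dataclass(frozen=True)
class SynthParams:
    """Knobs of the synthetic tumor-section generator.

    Parameters
    ----------
    n_vessels:
        Number of single-cell vessel cross-sections placed in the tumor.
    perfused_fraction:
        Fraction of vessels carrying flow; ``round(perfused_fraction *
        n_vessels)`` vessels form a simple random perfused subset.
    clustering:
        ``"uniform"`` scatters vessels uniformly over tumor cells;
        ``"lognormal-spacing"`` grows the set sequentially with
        inter-vessel distances drawn lognormal (mm).
    lognormal_mu, lognormal_sigma:
        Log-scale location/shape of the intervascular distance draw; the
        defaults give a median spacing of ~0.35 mm, typical of capillary
        spacing in poorly vascularized tumor regions.
    tumor_shape:
        ``"ellipse"`` or ``"blob"`` (ellipse with smooth random radial
        perturbation; star-convex, hence connected).
    diffusion_limit_mm:
        Distance-to-perfused-vessel threshold beyond which tumor tissue is
        marked reference-hypoxic, a geometric proxy for nitroimidazole
        marker binding.  0.15 mm is the classic oxygen diffusion distance.
    seed:
        Seed of the generator's private RNG; same seed, same masks.
    """

    n_vessels: int = 40
    perfused_fraction: float = 0.6
    clustering: Literal["uniform", "lognormal-spacing"] = "uniform"
    lognormal_mu: float = -1.05
    lognormal_sigma: float = 0.4
    tumor_shape: Literal["ellipse", "blob"] = "blob"
    diffusion_limit_mm: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_vessels < 1:
            raise ValueError("n_vessels must be >= 1")
        if not 0.0 <= self.perfused_fraction <= 1.0:
            raise ValueError("perfused_fraction must lie in [0, 1]")
        if self.diffusion_limit_mm <= 0:
            raise ValueError("diffusion_limit_mm must be positive")


def _tumor_mask(params: SynthParams, geometry: GridGeometry, rng: np.random.Generator) -> np.ndarray:
    """Connected tumor region covering >= 25% of the grid."""
    ext = geometry.extent_mm
    x, y = geometry.cell_centers()
    cx = ext / 2 + rng.uniform(-0.03, 0.03) * ext
    cy = ext / 2 + rng.uniform(-0.03, 0.03) * ext
    dx, dy = x - cx, y - cy
    theta = np.arctan2(dy, dx)
    rad = np.hypot(dx, dy)
    # base radius 0.38*extent -> ~45% coverage before perturbation
    r0 = 0.38 * ext * rng.uniform(0.95, 1.05)
    aniso = rng.uniform(0.85, 1.0)
    r = r0 * np.sqrt(aniso) / np.sqrt(aniso**2 * np.cos(theta) ** 2 + np.sin(theta) ** 2)
    if params.tumor_shape == "blob":
        for k in (2, 3, 4):
            amp = rng.uniform(0.0, 0.10) / (k - 1)
            phase = rng.uniform(0, 2 * np.pi)
            r = r * (1.0 + amp * np.cos(k * theta + phase))
    return rad <= r


def _place_vessels(
    params: SynthParams,
    geometry: GridGeometry,
    tumor: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    cells = np.flatnonzero(tumor)
    if params.n_vessels > cells.size:
        raise CapacityError(
            f"{params.n_vessels} vessels requested but tumor has {cells.size} cells"
        )
    n = geometry.n
    if params.clustering == "uniform":
        chosen = rng.choice(cells, size=params.n_vessels, replace=False)
        idx = set(int(c) for c in chosen)
    else:  # lognormal-spacing: sequential growth
        s = geometry.spacing_mm
        start = int(rng.choice(cells))
        idx = {start}
        pts = [np.array([start // n, start % n], dtype=float)]
        tries = 0
        max_tries = 400 * params.n_vessels
        while len(idx) < params.n_vessels and tries < max_tries:
            tries += 1
            parent = pts[rng.integers(len(pts))]
            d_cells = rng.lognormal(params.lognormal_mu, params.lognormal_sigma) / s
            ang = rng.uniform(0, 2 * np.pi)
            cand = parent + d_cells * np.array([np.sin(ang), np.cos(ang)])
            ci, cj = int(np.floor(cand[0])), int(np.floor(cand[1]))
            if not (0 <= ci < n and 0 <= cj < n):
                continue
            flat = ci * n + cj
            if flat in idx or not tumor[ci, cj]:
                continue
            idx.add(flat)
            pts.append(np.array([ci, cj], dtype=float))
        if len(idx) < params.n_vessels:  # degenerate geometry: fill uniformly
            remaining = np.setdiff1d(cells, np.fromiter(idx, dtype=int))
            extra = rng.choice(remaining, size=params.n_vessels - len(idx), replace=False)
            idx.update(int(c) for c in extra)
    mask = np.zeros(geometry.shape, dtype=bool)
    flat_idx = np.fromiter(sorted(idx), dtype=int)
    mask.flat[flat_idx] = True
    return mask


def reference_hypoxia_mask(
    tumor: np.ndarray,
    perfused: np.ndarray,
    spacing_mm: float,
    diffusion_limit_mm: float,
) -> np.ndarray:
    """Tumor cells farther than the diffusion limit from any perfused vessel.

    The distance to an empty perfused set is taken as +inf, so with no
    perfused vessel every tumor cell is reference-hypoxic.
    """
    if not perfused.any():
        return tumor.copy()
    dist = ndimage.distance_transform_edt(~perfused) * spacing_mm
    return tumor & (dist > diffusion_limit_mm)


def generate_domain(params: SynthParams, geometry: GridGeometry | None = None) -> VascularDomain:
    """Generate one synthetic tumor section; bit-reproducible from ``params.seed``."""
    geometry = geometry or GridGeometry()
    rng = np.random.default_rng(params.seed)
    tumor = _tumor_mask(params, geometry, rng)
    vessels = _place_vessels(params, geometry, tumor, rng)
    n_perf = int(round(params.perfused_fraction * params.n_vessels))
    vessel_cells = np.flatnonzero(vessels)
    perf_cells = rng.choice(vessel_cells, size=n_perf, replace=False) if n_perf else []
    perfusion = np.zeros(geometry.shape, dtype=bool)
    perfusion.flat[np.asarray(perf_cells, dtype=int)] = True
    perfused = vessels & perfusion
    ref = reference_hypoxia_mask(tumor, perfused, geometry.spacing_mm, params.diffusion_limit_mm)
    return VascularDomain(geometry, vessels, perfusion, tumor, ref)


def generate_cohort(
    n_tumors: int,
    params_list: Sequence[SynthParams],
    geometry: GridGeometry | None = None,
) -> list[VascularDomain]:
    """Generate an independent cohort of synthetic tumors.

    ``params_list`` must have one entry per tumor (vary density and seed to
    create genuine between-tumor variance).
    """
    if n_tumors < 2:
        raise ValueError("a cohort needs n_tumors >= 2")
    if len(params_list) != n_tumors:
        raise ValueError(f"expected {n_tumors} parameter sets, got {len(params_list)}")
    return [generate_domain(p, geometry) for p in params_list]


def cohort_params(
    n_tumors: int = 8,
    seed: int = 0,
    n_vessels_range: tuple[int, int] = (12, 68),
    base: SynthParams | None = None,
) -> list[SynthParams]:
    """Per-tumor parameter sets spanning a range of vascular densities.

    Vessel counts are evenly spaced across ``n_vessels_range`` and each
    tumor receives a distinct seed derived from ``seed``, giving a cohort
    with real between-tumor heterogeneity in hypoxic fraction.
    """
    base = base or SynthParams()
    counts = np.linspace(n_vessels_range[0], n_vessels_range[1], n_tumors).round().astype(int)
    ss = np.random.SeedSequence(seed)
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n_tumors)]
    return [replace(base, n_vessels=int(c), seed=sd) for c, sd in zip(counts, seeds)]
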