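"""Co-registered binary-mask domains for tumor cross-sections.

A tumor section is represented by four binary rasters on a uniform square
grid: stained blood vessels, perfused (flow-carrying) regions, the total
tumor area, and optionally a marker-derived hypoxia mask used for
validation.  The oxygen sources of the transport model are the *perfused
vessels*, the elementwise AND of the vessel and perfusion masks.

Coordinate convention: arrays are row-major with cell (0, 0) at the
top-left; the center of cell (i, j) sits at ``((j + 0.5) * s, (i + 0.5) * s)``
in millimetres, where ``s`` is the grid spacing.  Continuous positions map
to cells by ``floor(position / s)``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np

__all__ = [
    "GridGeometry",
    "VascularDomain",
    "DomainError",
    "DimensionMismatchError",
    "EmptyDomainError",
    "load_domain",
    "load_domain_dir",
    "save_domain",
    "perfused_vascular_fraction",
]


class DomainError(ValueError):
    """Base class for invalid vascular-domain inputs."""


class DimensionMismatchError(DomainError):
    """Input masks do not share a common pixel shape."""


class EmptyDomainError(DomainError):
    """The tumor mask contains no foreground cell."""


@dataclass(frozen=True)
class GridGeometry:
    """Uniform square grid: physical side length and points per side.

    The default (6 mm, 100 points) gives 60 µm cells, one capillary
    cross-section or a small group of tumor cells per cell.
    """

    extent_mm: float = 6.0
    n: int = 100

    def __post_init__(self) -> None:
        if self.extent_mm <= 0:
            raise ValueError(f"extent_mm must be positive, got {self.extent_mm}")
        if self.n < 8:
            raise ValueError(f"n must be at least 8, got {self.n}")

    @property
    def spacing_mm(self) -> float:
        return self.extent_mm / self.n

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n, self.n)

    def cell_of(self, x_mm: float, y_mm: float) -> tuple[int, int]:
        """Grid cell (row, col) containing a physical position (x right, y down)."""
        s = self.spacing_mm
        return int(np.floor(y_mm / s)), int(np.floor(x_mm / s))

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(x, y) coordinates (mm) of every cell center, each shaped (n, n)."""
        s = self.spacing_mm
        ax = (np.arange(self.n) + 0.5) * s
        x, y = np.meshgrid(ax, ax)  # x varies along columns, y along rows
        return x, y


def _as_mask(a: np.ndarray, name: str, shape: tuple[int, int]) -> np.ndarray:
    m = np.asarray(a).astype(bool)
    if m.shape != shape:
        raise DimensionMismatchError(
            f"{name} has shape {m.shape}, expected {shape}"
        )
    return m


@dataclass
class VascularDomain:
    """One tumor cross-section: co-registered masks plus grid geometry.

    ``perfused_mask`` is derived, never supplied: the logical AND of the
    vessel and perfusion masks.  It is the indicator field m_p(x) that
    sources oxygen in the transport model.
    """

    geometry: GridGeometry
    vessel_mask: np.ndarray
    perfusion_mask: np.ndarray
    tumor_mask: np.ndarray
    hypoxia_reference_mask: np.ndarray | None = None
    perfused_mask: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        shape = self.geometry.shape
        self.vessel_mask = _as_mask(self.vessel_mask, "vessel_mask", shape)
        self.perfusion_mask = _as_mask(self.perfusion_mask, "perfusion_mask", shape)
        self.tumor_mask = _as_mask(self.tumor_mask, "tumor_mask", shape)
        if self.hypoxia_reference_mask is not None:
            self.hypoxia_reference_mask = _as_mask(
                self.hypoxia_reference_mask, "hypoxia_reference_mask", shape
            )
        if not self.tumor_mask.any():
            raise EmptyDomainError("tumor_mask has no true cell")
        self.perfused_mask = self.vessel_mask & self.perfusion_mask

    @property
    def n_tumor_cells(self) -> int:
        return int(self.tumor_mask.sum())

    def tumor_centroid_mm(self) -> tuple[float, float]:
        """(x, y) centroid of tumor cell centers, in mm."""
        i, j = np.nonzero(self.tumor_mask)
        s = self.geometry.spacing_mm
        return float((j.mean() + 0.5) * s), float((i.mean() + 0.5) * s)

    def tumor_bbox_mm(self) -> tuple[float, float, float, float]:
        """Bounding box of the tumor mask as (x0, y0, x1, y1) outer edges, mm."""
        i, j = np.nonzero(self.tumor_mask)
        s = self.geometry.spacing_mm
        return (j.min() * s, i.min() * s, (j.max() + 1) * s, (i.max() + 1) * s)


def _read_mask_image(path: str | Path) -> np.ndarray:
    img = np.asarray(iio.imread(path))
    if img.ndim == 3:  # RGB(A) input: any stained channel counts as foreground
        img = img.max(axis=2)
    if img.ndim != 2:
        raise DomainError(f"{path}: expected a single-channel raster, got ndim={img.ndim}")
    return img > 0


def _resample_nearest(mask: np.ndarray, n: int) -> np.ndarray:
    """Nearest-neighbor resample of a binary mask to n x n (preserves binarity)."""
    h, w = mask.shape
    rows = np.floor((np.arange(n) + 0.5) * h / n).astype(int)
    cols = np.floor((np.arange(n) + 0.5) * w / n).astype(int)
    return mask[np.ix_(rows, cols)]


def load_domain(
    vessel_path: str | Path,
    perfusion_path: str | Path,
    tumor_path: str | Path,
    hypoxia_path: str | Path | None = None,
    geometry: GridGeometry | None = None,
) -> VascularDomain:
    """Load co-registered binary mask images into a :class:`VascularDomain`.

    Pixels with any nonzero value are foreground (inputs are already
    thresholded binary stains).  Images must share pixel dimensions; they
    are resampled to the solver grid by nearest neighbor if needed.
    """
    geometry = geometry or GridGeometry()
    paths = [vessel_path, perfusion_path, tumor_path]
    if hypoxia_path is not None:
        paths.append(hypoxia_path)
    masks = [_read_mask_image(p) for p in paths]
    shapes = {m.shape for m in masks}
    if len(shapes) != 1:
        raise DimensionMismatchError(f"input images disagree in shape: {sorted(shapes)}")
    masks = [_resample_nearest(m, geometry.n) for m in masks]
    hypoxia = masks[3] if hypoxia_path is not None else None
    return VascularDomain(geometry, masks[0], masks[1], masks[2], hypoxia)


_MASK_FILES = {
    "vessel_mask": "vessels.png",
    "perfusion_mask": "perfusion.png",
    "tumor_mask": "tumor.png",
    "hypoxia_reference_mask": "hypoxia_reference.png",
}


def save_domain(domain: VascularDomain, outdir: str | Path) -> Path:
    """Write a domain as a directory of PNG masks plus a JSON geometry sidecar."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for attr, fname in _MASK_FILES.items():
        mask = getattr(domain, attr)
        if mask is None:
            continue
        iio.imwrite(outdir / fname, (mask.astype(np.uint8) * 255))
    sidecar = {
        "extent_mm": domain.geometry.extent_mm,
        "n": domain.geometry.n,
        "has_hypoxia_reference": domain.hypoxia_reference_mask is not None,
    }
    (outdir / "geometry.json").write_text(json.dumps(sidecar, indent=2))
    return outdir


def load_domain_dir(path: str | Path) -> VascularDomain:
    """Read back a directory written by :func:`save_domain`."""
    path = Path(path)
    meta = json.loads((path / "geometry.json").read_text())
    geometry = GridGeometry(extent_mm=meta["extent_mm"], n=meta["n"])
    hyp = path / _MASK_FILES["hypoxia_reference_mask"]
    return load_domain(
        path / _MASK_FILES["vessel_mask"],
        path / _MASK_FILES["perfusion_mask"],
        path / _MASK_FILES["tumor_mask"],
        hyp if (meta.get("has_hypoxia_reference") and hyp.exists()) else None,
        geometry,
    )


def perfused_vascular_fraction(domain: VascularDomain) -> float:
    """Fraction of tumor cells occupied by perfused vessels, in [0, 1]."""
    return float(
        (domain.perfused_mask & domain.tumor_mask).sum() / domain.n_tumor_cells
    )
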