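"""Relative-threshold hypoxia quantification.

A tumor cell is hypoxic at level ``pct`` if its oxygen concentration is
below ``pct`` percent of the field maximum; HP2.5, HP5 and HP10 are the
conventional severe / moderate / mild thresholds.  Because the definition
is relative, it is invariant to the absolute oxygen scale and stable in
computational time once the field is well diffused.

Spatial validation compares a simulated hypoxic mask with a reference
(marker-derived) mask pixel by pixel over the tumor area.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Literal, Mapping

import numpy as np

from .grid import EmptyDomainError

__all__ = [
    "HypoxiaThreshold",
    "HypoxiaReport",
    "field_maximum",
    "hypoxic_mask",
    "hypoxic_area_fraction",
    "spatial_agreement",
    "jaccard_overlap",
]

DEFAULT_THRESHOLDS = (2.5, 5.0, 10.0)


@dataclass(frozen=True)
class HypoxiaThreshold:
    """A relative hypoxia level, as a percentage of the field maximum."""

    pct: float

    def __post_init__(self) -> None:
        if not 0 < self.pct < 100:
            raise ValueError(f"pct must lie in (0, 100), got {self.pct}")

    @property
    def label(self) -> str:
        return f"HP{self.pct:g}"

    def __float__(self) -> float:
        return float(self.pct)


def _pct(threshold: float | HypoxiaThreshold) -> float:
    pct = float(threshold)
    if not 0 < pct < 100:
        raise ValueError(f"threshold pct must lie in (0, 100), got {pct}")
    return pct


def field_maximum(K: np.ndarray, tumor_mask: np.ndarray | None = None,
                  max_over: Literal["grid", "tumor"] = "grid") -> float:
    """Reference maximum for relative thresholds (whole grid by default)."""
    if max_over == "tumor":
        if tumor_mask is None:
            raise ValueError("max_over='tumor' requires a tumor mask")
        return float(K[tumor_mask].max())
    return float(K.max())


def hypoxic_mask(
    K: np.ndarray,
    tumor_mask: np.ndarray,
    threshold: float | HypoxiaThreshold,
    max_over: Literal["grid", "tumor"] = "grid",
) -> np.ndarray:
    """Binary mask of tumor cells below ``pct`` percent of the field maximum.

    Degenerate case: a field with nonpositive maximum has no oxic
    reference, and every tumor cell is hypoxic.
    """
    pct = _pct(threshold)
    k_max = field_maximum(K, tumor_mask, max_over)
    if k_max <= 0:
        return tumor_mask.copy()
    return tumor_mask & (K < (pct / 100.0) * k_max)


def hypoxic_area_fraction(
    K: np.ndarray,
    tumor_mask: np.ndarray,
    threshold: float | HypoxiaThreshold,
    max_over: Literal["grid", "tumor"] = "grid",
) -> float:
    """Fraction of the tumor area that is hypoxic at the given level."""
    n_tumor = int(np.asarray(tumor_mask, bool).sum())
    if n_tumor == 0:
        raise EmptyDomainError("tumor mask is empty")
    return float(hypoxic_mask(K, tumor_mask, threshold, max_over).sum() / n_tumor)


def spatial_agreement(
    sim_mask: np.ndarray,
    ref_mask: np.ndarray,
    tumor_mask: np.ndarray | None = None,
) -> float:
    """Percent of pixels where the simulated and reference masks agree.

    Restricted to the tumor mask when one is given (the default analysis),
    otherwise computed over the full frame.  Symmetric in its two mask
    arguments.
    """
    sim = np.asarray(sim_mask, bool)
    ref = np.asarray(ref_mask, bool)
    if sim.shape != ref.shape:
        raise ValueError(f"mask shapes differ: {sim.shape} vs {ref.shape}")
    agree = sim == ref
    if tumor_mask is not None:
        tumor = np.asarray(tumor_mask, bool)
        if tumor.shape != sim.shape:
            raise ValueError("tumor mask shape differs from comparison masks")
        if not tumor.any():
            raise EmptyDomainError("tumor mask is empty")
        agree = agree[tumor]
    return float(100.0 * agree.mean())


def jaccard_overlap(
    sim_mask: np.ndarray,
    ref_mask: np.ndarray,
    tumor_mask: np.ndarray | None = None,
) -> float:
    """Jaccard index of the two hypoxic masks (alternative overlap measure).

    Returns 1.0 when both masks are empty on the evaluation region.
    """
    sim = np.asarray(sim_mask, bool)
    ref = np.asarray(ref_mask, bool)
    if tumor_mask is not None:
        tumor = np.asarray(tumor_mask, bool)
        sim, ref = sim[tumor], ref[tumor]
    union = (sim | ref).sum()
    if union == 0:
        return 1.0
    return float((sim & ref).sum() / union)


@dataclass
class HypoxiaReport:
    """Per-threshold hypoxic fractions by area and by electrode, plus
    optional spatial agreement against a reference mask (percent)."""

    hp_area: Mapping[float, float] = dc_field(default_factory=dict)
    hp_electrode: Mapping[float, float] = dc_field(default_factory=dict)
    spatial_agreement_pct: Mapping[float, float] = dc_field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "hp_area": {f"HP{k:g}": v for k, v in self.hp_area.items()},
            "hp_electrode": {f"HP{k:g}": v for k, v in self.hp_electrode.items()},
            "spatial_agreement_pct": {
                f"HP{k:g}": v for k, v in self.spatial_agreement_pct.items()
            },
        }
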