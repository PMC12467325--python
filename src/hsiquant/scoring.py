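"""Cell delineation and per-core immunohistochemistry scores (H-score, Allred).

From a classified label map, nuclei are 8-connected components of NUCLEI
pixels at or above a minimum size; each cell's cytoplasm is the set of
DAB-positive pixels within a fixed-radius ring of its nucleus, every pixel
assigned to its nearest nucleus only so cells partition the positive area.
Each cell's DAB signal is the mean optical density over the 520-650 nm
chromogen absorption window, binned into negative/weak/moderate/strong tiers
by fixed OD thresholds.

Per-core scores follow the two standard semi-quantitative IHC systems:

* H-score = 1 * %weak + 2 * %moderate + 3 * %strong, range 0-300, where the
  percentages are of all tumour cells.
* Allred = proportion score (0-5, from the % of positive cells) + intensity
  score (0-3, the rounded mean tier of positive cells), total 0 or 2-8.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .classes import Tier, TissueClass
from .segmentation import LabelMap
from .spectral_io import SignalKind, SpectralCube, crop_spectral_window

__all__ = [
    "IntensityThresholds",
    "CellRecord",
    "ScoreFractions",
    "CoreScore",
    "segment_cells",
    "bin_intensity",
    "compute_h_score",
    "compute_allred",
    "score_core",
    "DEFAULT_OD_WINDOW",
]

#: Spectral window over which the per-cell DAB optical density is averaged:
#: the chromogen's absorption band.
DEFAULT_OD_WINDOW = (520.0, 650.0)

_EIGHT_CONNECTED = np.ones((3, 3), dtype=bool)


@dataclass(frozen=True)
class IntensityThresholds:
    """OD cut points for the weak/moderate/strong bins (lower-inclusive)."""

    t_weak: float = 0.2
    t_moderate: float = 0.45
    t_strong: float = 0.9

    def __post_init__(self) -> None:
        if not 0 < self.t_weak < self.t_moderate < self.t_strong:
            raise ValueError("thresholds must satisfy 0 < t_weak < t_moderate < t_strong")


@dataclass
class CellRecord:
    cell_id: int
    centroid: tuple[float, float]
    nucleus_area: int
    cytoplasm_pixels: tuple[np.ndarray, np.ndarray]  # (rows, cols) index arrays
    mean_od: float = 0.0
    tier: Tier = Tier.NEGATIVE


@dataclass(frozen=True)
class ScoreFractions:
    """Percentages of all tumour cells per positive tier."""

    pct_weak: float
    pct_moderate: float
    pct_strong: float

    def __post_init__(self) -> None:
        for value in (self.pct_weak, self.pct_moderate, self.pct_strong):
            if not 0.0 <= value <= 100.0:
                raise ValueError("tier percentages must lie in [0, 100]")
        if self.pct_weak + self.pct_moderate + self.pct_strong > 100.0 + 1e-9:
            raise ValueError("tier percentages sum beyond 100")

    @property
    def pct_positive(self) -> float:
        return self.pct_weak + self.pct_moderate + self.pct_strong


@dataclass
class CoreScore:
    core_id: str
    n_cells: int
    fractions: ScoreFractions
    h_score: float
    allred_ps: int
    allred_is: int
    allred_total: int
    positive_area_pct: float = 0.0
    representative: bool = True

    def as_dict(self) -> dict:
        return {
            "core_id": self.core_id,
            "n_cells": self.n_cells,
            "pct_weak": self.fractions.pct_weak,
            "pct_moderate": self.fractions.pct_moderate,
            "pct_strong": self.fractions.pct_strong,
            "pct_positive": self.fractions.pct_positive,
            "h_score": self.h_score,
            "allred_ps": self.allred_ps,
            "allred_is": self.allred_is,
            "allred_total": self.allred_total,
            "positive_area_pct": self.positive_area_pct,
            "representative": self.representative,
        }


def segment_cells(
    labels: LabelMap,
    min_nucleus_px: int = 4,
    ring_radius: float = 3.0,
    absorbance: SpectralCube | None = None,
    od_window: tuple[float, float] = DEFAULT_OD_WINDOW,
    thresholds: IntensityThresholds | None = None,
) -> list[CellRecord]:
    """Delineate cells from a label map; optionally measure and tier them.

    Nuclei are 8-connected NUCLEI components of at least ``min_nucleus_px``
    pixels. Cytoplasm pixels are DAB-positive pixels within Euclidean
    distance ``ring_radius`` of a retained nucleus, each assigned only to its
    nearest nucleus. When an absorbance cube is supplied, each cell's
    ``mean_od`` (mean OD over ``od_window``) and tier are filled in.
    """
    nuclei_mask = labels.mask(TissueClass.NUCLEI)
    comp, n_comp = ndimage.label(nuclei_mask, structure=_EIGHT_CONNECTED)
    if n_comp == 0:
        return []
    sizes = ndimage.sum_labels(nuclei_mask, comp, index=np.arange(1, n_comp + 1))
    keep = np.nonzero(sizes >= min_nucleus_px)[0] + 1
    relabel = np.zeros(n_comp + 1, dtype=int)
    relabel[keep] = np.arange(1, keep.size + 1)
    comp = relabel[comp]
    n_cells = keep.size
    if n_cells == 0:
        return []

    # nearest retained nucleus for every pixel, via EDT with index return
    dist, (ir, ic) = ndimage.distance_transform_edt(comp == 0, return_indices=True)
    nearest = comp[ir, ic]
    dkk3 = labels.mask(TissueClass.DKK3_POSITIVE)
    eligible = dkk3 & (dist <= ring_radius) & (nearest > 0)

    centroids = ndimage.center_of_mass(
        np.ones_like(comp), comp, index=np.arange(1, n_cells + 1)
    )
    od_image = None
    if absorbance is not None:
        if absorbance.signal_kind is not SignalKind.ABSORBANCE:
            raise ValueError("segment_cells expects an ABSORBANCE cube for OD measurement")
        windowed = crop_spectral_window(absorbance, *od_window)
        od_image = windowed.data.mean(axis=2)
    thresholds = thresholds or IntensityThresholds()

    cells: list[CellRecord] = []
    for cid in range(1, n_cells + 1):
        cyto = np.nonzero(eligible & (nearest == cid))
        record = CellRecord(
            cell_id=cid,
            centroid=tuple(float(x) for x in centroids[cid - 1]),
            nucleus_area=int(sizes[keep[cid - 1] - 1]),
            cytoplasm_pixels=cyto,
        )
        if od_image is not None:
            if cyto[0].size:
                record.mean_od = float(od_image[cyto].mean())
            record.tier = bin_intensity(record.mean_od, thresholds)
        cells.append(record)
    return cells


def bin_intensity(mean_od: float, thresholds: IntensityThresholds) -> Tier:
    """Tier from mean OD; bins are half-open, lower-inclusive."""
    if mean_od < 0:
        raise ValueError("mean OD must be non-negative")
    if mean_od < thresholds.t_weak:
        return Tier.NEGATIVE
    if mean_od < thresholds.t_moderate:
        return Tier.WEAK
    if mean_od < thresholds.t_strong:
        return Tier.MODERATE
    return Tier.STRONG


def compute_h_score(fractions: ScoreFractions) -> float:
    """H-score = 1 * %weak + 2 * %moderate + 3 * %strong, in [0, 300]."""
    return (
        1.0 * fractions.pct_weak
        + 2.0 * fractions.pct_moderate
        + 3.0 * fractions.pct_strong
    )


def _proportion_score(pct_positive: float) -> int:
    if not -1e-9 <= pct_positive <= 100.0 + 1e-9:
        raise ValueError("pct_positive must lie in [0, 100]")
    pct_positive = min(max(pct_positive, 0.0), 100.0)
    if pct_positive == 0.0:
        return 0
    if pct_positive < 1.0:
        return 1
    if pct_positive <= 10.0:
        return 2
    if pct_positive <= 33.0:
        return 3
    if pct_positive <= 66.0:
        return 4
    return 5


def compute_allred(pct_positive: float, mean_positive_tier: float) -> tuple[int, int, int]:
    """Allred (proportion score, intensity score, total).

    ``mean_positive_tier`` is the arithmetic mean tier of positive cells
    (1 = weak .. 3 = strong); the core's intensity category is that mean
    rounded half-up. A core with no positive cells scores (0, 0, 0).
    """
    ps = _proportion_score(pct_positive)
    if ps == 0:
        return 0, 0, 0
    if not 1.0 - 1e-9 <= mean_positive_tier <= 3.0 + 1e-9:
        raise ValueError("mean positive tier must lie in [1, 3]")
    intensity = int(np.floor(mean_positive_tier + 0.5))  # round half-up
    intensity = min(max(intensity, 1), 3)
    return ps, intensity, ps + intensity


def score_core(
    cells: list[CellRecord],
    core_id: str = "core",
    labels: LabelMap | None = None,
    ring_radius: float = 3.0,
) -> CoreScore:
    """Aggregate per-cell tiers into the core's fractions, H-score and Allred score.

    ``positive_area_pct`` is the DAB-positive pixel fraction of the evaluable
    area (DAB-positive, nuclei, and ring pixels eligible to host cytoplasm),
    computed when the label map is supplied. An empty cell list yields an
    all-zero score flagged non-representative.
    """
    if not cells:
        return CoreScore(
            core_id, 0, ScoreFractions(0.0, 0.0, 0.0), 0.0, 0, 0, 0,
            positive_area_pct=0.0, representative=False,
        )
    n = len(cells)
    counts = {tier: sum(c.tier == tier for c in cells) for tier in Tier}
    fractions = ScoreFractions(
        pct_weak=100.0 * counts[Tier.WEAK] / n,
        pct_moderate=100.0 * counts[Tier.MODERATE] / n,
        pct_strong=100.0 * counts[Tier.STRONG] / n,
    )
    h = compute_h_score(fractions)
    n_pos = n - counts[Tier.NEGATIVE]
    if n_pos:
        mean_tier = sum(int(c.tier) for c in cells if c.tier is not Tier.NEGATIVE) / n_pos
        ps, inten, total = compute_allred(fractions.pct_positive, mean_tier)
    else:
        ps, inten, total = compute_allred(0.0, 0.0)

    area_pct = 0.0
    if labels is not None:
        dkk3 = labels.mask(TissueClass.DKK3_POSITIVE)
        nuclei = labels.mask(TissueClass.NUCLEI)
        dist = ndimage.distance_transform_edt(~nuclei)
        evaluable = dkk3 | nuclei | (dist <= ring_radius)
        if evaluable.any():
            area_pct = 100.0 * dkk3.sum() / evaluable.sum()
    return CoreScore(core_id, n, fractions, h, ps, inten, total, area_pct)


def cells_to_dataframe(cells: list[CellRecord]) -> pd.DataFrame:
    """Per-cell table with documented column names."""
    return pd.DataFrame(
        {
            "cell_id": [c.cell_id for c in cells],
            "row": [c.centroid[0] for c in cells],
            "col": [c.centroid[1] for c in cells],
            "nucleus_area_px": [c.nucleus_area for c in cells],
            "cytoplasm_px": [c.cytoplasm_pixels[0].size for c in cells],
            "mean_dab_od": [c.mean_od for c in cells],
            "tier": [c.tier.name for c in cells],
        }
    )
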