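"""Synthetic DAB/hematoxylin-stained tissue hypercubes with full ground truth.

The generator stands in for transmitted-light hyperspectral acquisition of an
immunostained tissue core. Cells are non-overlapping discs: a hematoxylin
nucleus surrounded by a cytoplasm annulus that carries the DAB chromogen when
the cell is positive, at a concentration set by its staining tier
(weak/moderate/strong). Reflectance follows Beer-Lambert mixing in base 10,

    R(lambda) = 10 ** (-sum_e c_e * A_e(lambda)),

with optional additive Gaussian noise in the reflectance domain, clipped to
[0, 1.5]. Because mixing is exact and tier counts are apportioned
deterministically (largest remainder), the H-score implied by a layout is an
exact number that the downstream pipeline can be tested against.

A tissue-microarray (TMA) manifest generator emulates a multi-array study
design in which some cores are flagged non-representative and excluded.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .classes import Tier, TissueClass
from .exceptions import LayoutError
from .spectral_io import SignalKind, SpectralCube, WavelengthAxis

__all__ = [
    "EndmemberSpectrum",
    "TissueLayout",
    "Cell",
    "GroundTruth",
    "TMAManifest",
    "build_endmember_library",
    "generate_layout",
    "render_cube",
    "generate_tma_manifest",
    "DEFAULT_TIER_CONCENTRATIONS",
    "DEFAULT_HEMATOXYLIN_CONCENTRATION",
]

BACKGROUND_MAX_OD = 0.02

#: Relative DAB concentration per tier; chosen to straddle the default
#: optical-density bin thresholds of cell scoring with margin.
DEFAULT_TIER_CONCENTRATIONS: dict[Tier, float] = {
    Tier.WEAK: 0.3,
    Tier.MODERATE: 0.7,
    Tier.STRONG: 1.2,
}
DEFAULT_HEMATOXYLIN_CONCENTRATION = 0.8


@dataclass(frozen=True)
class EndmemberSpectrum:
    """Pure-constituent absorbance as a sum of Gaussian peaks (center, width, peak OD)."""

    name: str
    peaks: tuple[tuple[float, float, float], ...]

    def __post_init__(self) -> None:
        for center, width, amplitude in self.peaks:
            if amplitude < 0:
                raise ValueError(f"endmember {self.name}: negative peak OD {amplitude}")
            if width <= 0:
                raise ValueError(f"endmember {self.name}: non-positive peak width {width}")
        if self.name == "BACKGROUND":
            grid = np.linspace(400.0, 1100.0, 1401)
            if self.absorbance_at(grid).max() > BACKGROUND_MAX_OD + 1e-12:
                raise ValueError("BACKGROUND endmember peak OD must not exceed 0.02")

    def absorbance_at(self, wavelengths: np.ndarray) -> np.ndarray:
        lam = np.asarray(wavelengths, dtype=float)
        od = np.zeros_like(lam)
        for center, width, amplitude in self.peaks:
            od += amplitude * np.exp(-((lam - center) ** 2) / (2.0 * width**2))
        return od

    def absorbance(self, axis: WavelengthAxis) -> np.ndarray:
        return self.absorbance_at(axis.values)


#: DAB: broad chromogen peak so absorbance in 520-650 nm dominates the NIR tail.
#: Hematoxylin: narrower nuclear counterstain peak. Background: faint sloped
#: baseline (glass + unstained tissue) kept below 0.02 OD; it is deliberately
#: non-flat so a background pixel has a well-defined spectral shape.
DEFAULT_ENDMEMBER_PEAKS: dict[str, tuple[tuple[float, float, float], ...]] = {
    "DAB": ((560.0, 80.0, 1.0),),
    "HEMATOXYLIN": ((600.0, 45.0, 0.7),),
    "BACKGROUND": ((600.0, 300.0, 0.012), (520.0, 60.0, 0.006)),
}


def build_endmember_library(
    params: dict[str, tuple[tuple[float, float, float], ...]] | None = None,
) -> list[EndmemberSpectrum]:
    """Endmember spectra for DAB, hematoxylin and background (defaults built in)."""
    peaks = dict(DEFAULT_ENDMEMBER_PEAKS)
    if params:
        peaks.update(params)
    return [EndmemberSpectrum(name, tuple(p)) for name, p in peaks.items()]


@dataclass(frozen=True)
class Cell:
    center: tuple[int, int]
    nucleus_radius: int
    cytoplasm_radius: int
    tier: Tier

    def __post_init__(self) -> None:
        if self.nucleus_radius < 1:
            raise ValueError("nucleus radius must be >= 1 px")
        if self.cytoplasm_radius <= self.nucleus_radius:
            raise ValueError("cytoplasm radius must exceed nucleus radius")


@dataclass
class TissueLayout:
    shape: tuple[int, int]
    cells: list[Cell]
    seed: int

    def __post_init__(self) -> None:
        rows, cols = self.shape
        for cell in self.cells:
            r, c = cell.center
            rad = cell.cytoplasm_radius
            if r - rad < 0 or c - rad < 0 or r + rad >= rows or c + rad >= cols:
                raise ValueError("cell extends beyond the layout bounds")


@dataclass
class GroundTruth:
    """Generator-side truth: per-pixel labels, per-cell tiers, implied score inputs."""

    label_image: np.ndarray
    cell_tiers: list[Tier]
    tier_fractions: dict[Tier, float]  # % of positive cells per positive tier
    percent_positive: float  # % of all cells with tier != NEGATIVE

    @property
    def implied_fractions(self) -> dict[Tier, float]:
        """% of ALL cells in each positive tier (the H-score formula inputs)."""
        n = len(self.cell_tiers)
        return {
            t: 100.0 * sum(ct == t for ct in self.cell_tiers) / n
            for t in (Tier.WEAK, Tier.MODERATE, Tier.STRONG)
        }

    @property
    def implied_h_score(self) -> float:
        f = self.implied_fractions
        return 1.0 * f[Tier.WEAK] + 2.0 * f[Tier.MODERATE] + 3.0 * f[Tier.STRONG]


def _largest_remainder_counts(fractions: np.ndarray, total: int) -> np.ndarray:
    """Apportion `total` items to categories in proportion to `fractions` (sum 100)."""
    quotas = fractions * total / 100.0
    counts = np.floor(quotas).astype(int)
    shortfall = total - counts.sum()
    order = np.argsort(-(quotas - counts), kind="stable")
    counts[order[:shortfall]] += 1
    return counts


def generate_layout(
    shape: tuple[int, int],
    n_cells: int,
    percent_positive: float,
    tier_mix: tuple[float, float, float],
    seed: int,
    nucleus_radius: int = 3,
    cytoplasm_radius: int = 6,
    min_separation: int = 1,
    max_tries_per_cell: int = 400,
) -> TissueLayout:
    """Place non-overlapping disc cells and assign staining tiers.

    `tier_mix` gives the weak/moderate/strong percentages among positive cells
    and must sum to 100. Tier counts are a deterministic largest-remainder
    apportionment, so the layout-implied H-score is exact; which cells carry
    which tier is a seeded permutation.
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    if not 0 <= percent_positive <= 100:
        raise ValueError("percent_positive must be in [0, 100]")
    mix = np.asarray(tier_mix, dtype=float)
    if mix.min() < 0 or abs(mix.sum() - 100.0) > 1e-9:
        raise ValueError("tier_mix must be non-negative and sum to 100")

    rng = np.random.default_rng(seed)
    rows, cols = shape
    rad = cytoplasm_radius
    centers: list[tuple[int, int]] = []
    min_dist2 = (2 * rad + min_separation) ** 2
    for _ in range(n_cells):
        for _attempt in range(max_tries_per_cell):
            r = int(rng.integers(rad, rows - rad))
            c = int(rng.integers(rad, cols - rad))
            if all((r - r0) ** 2 + (c - c0) ** 2 >= min_dist2 for r0, c0 in centers):
                centers.append((r, c))
                break
        else:
            raise LayoutError(
                f"could not place {n_cells} non-overlapping cells in {shape}; "
                "reduce n_cells or cell radii"
            )

    n_positive = int(round(n_cells * percent_positive / 100.0))
    tier_counts = _largest_remainder_counts(mix, n_positive)
    tiers = (
        [Tier.WEAK] * tier_counts[0]
        + [Tier.MODERATE] * tier_counts[1]
        + [Tier.STRONG] * tier_counts[2]
        + [Tier.NEGATIVE] * (n_cells - n_positive)
    )
    tiers = [tiers[i] for i in rng.permutation(n_cells)]
    cells = [
        Cell(center, nucleus_radius, cytoplasm_radius, tier)
        for center, tier in zip(centers, tiers)
    ]
    return TissueLayout(shape, cells, seed)


def _disc_masks(shape: tuple[int, int], cell: Cell) -> tuple[np.ndarray, np.ndarray]:
    rows, cols = shape
    r0, c0 = cell.center
    rad = cell.cytoplasm_radius
    rr, cc = np.ogrid[
        max(r0 - rad, 0) : min(r0 + rad + 1, rows),
        max(c0 - rad, 0) : min(c0 + rad + 1, cols),
    ]
    d2 = (rr - r0) ** 2 + (cc - c0) ** 2
    nucleus = np.zeros(shape, dtype=bool)
    cytoplasm = np.zeros(shape, dtype=bool)
    window = (
        slice(max(r0 - rad, 0), min(r0 + rad + 1, rows)),
        slice(max(c0 - rad, 0), min(c0 + rad + 1, cols)),
    )
    nucleus[window] = d2 <= cell.nucleus_radius**2
    cytoplasm[window] = (d2 > cell.nucleus_radius**2) & (d2 <= rad**2)
    return nucleus, cytoplasm


def render_cube(
    layout: TissueLayout,
    endmembers: list[EndmemberSpectrum] | None = None,
    axis: WavelengthAxis | None = None,
    tier_concentrations: dict[Tier, float] | None = None,
    noise_sd: float = 0.0,
    seed: int = 0,
    hematoxylin_concentration: float = DEFAULT_HEMATOXYLIN_CONCENTRATION,
) -> tuple[SpectralCube, GroundTruth]:
    """Render a layout to a reflectance cube plus its ground truth."""
    from .spectral_io import DEFAULT_WAVELENGTHS

    if axis is None:
        axis = WavelengthAxis(DEFAULT_WAVELENGTHS)
    if endmembers is None:
        endmembers = build_endmember_library()
    if tier_concentrations is None:
        tier_concentrations = DEFAULT_TIER_CONCENTRATIONS
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    by_name = {e.name: e for e in endmembers}
    for required in ("DAB", "HEMATOXYLIN", "BACKGROUND"):
        if required not in by_name:
            raise ValueError(f"endmember library lacks {required}")

    shape = layout.shape
    c_dab = np.zeros(shape)
    c_hem = np.zeros(shape)
    labels = np.full(shape, int(TissueClass.BACKGROUND), dtype=np.uint8)
    for cell in layout.cells:
        nucleus, cytoplasm = _disc_masks(shape, cell)
        c_hem[nucleus] = hematoxylin_concentration
        labels[nucleus] = int(TissueClass.NUCLEI)
        if cell.tier is not Tier.NEGATIVE:
            c_dab[cytoplasm] = tier_concentrations[cell.tier]
            labels[cytoplasm] = int(TissueClass.DKK3_POSITIVE)

    a_dab = by_name["DAB"].absorbance(axis)
    a_hem = by_name["HEMATOXYLIN"].absorbance(axis)
    a_bg = by_name["BACKGROUND"].absorbance(axis)
    od = (
        c_dab[:, :, None] * a_dab[None, None, :]
        + c_hem[:, :, None] * a_hem[None, None, :]
        + a_bg[None, None, :]
    )
    refl = np.power(10.0, -od)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        refl = refl + rng.normal(0.0, noise_sd, size=refl.shape)
    refl = np.clip(refl, 0.0, 1.5)
    cube = SpectralCube(refl, axis, SignalKind.REFLECTANCE, meta={"seed": seed})

    tiers = [cell.tier for cell in layout.cells]
    n_pos = sum(t is not Tier.NEGATIVE for t in tiers)
    if n_pos:
        tier_fractions = {
            t: 100.0 * sum(ct == t for ct in tiers) / n_pos
            for t in (Tier.WEAK, Tier.MODERATE, Tier.STRONG)
        }
    else:
        tier_fractions = {t: 0.0 for t in (Tier.WEAK, Tier.MODERATE, Tier.STRONG)}
    truth = GroundTruth(
        label_image=labels,
        cell_tiers=tiers,
        tier_fractions=tier_fractions,
        percent_positive=100.0 * n_pos / len(tiers),
    )
    return cube, truth


@dataclass
class TMAManifest:
    """Tissue-microarray core inventory with representativeness flags."""

    cores: list[tuple[str, str, bool]] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen = set()
        for array_id, core_id, _flag in self.cores:
            key = (array_id, core_id)
            if key in seen:
                raise ValueError(f"duplicate core id {core_id} in array {array_id}")
            seen.add(key)

    @property
    def n_representative(self) -> int:
        return sum(flag for _, _, flag in self.cores)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.cores, columns=["array_id", "core_id", "representative"])


def generate_tma_manifest(
    arrays: tuple[int, ...] = (30, 30, 30, 16),
    n_nonrepresentative: int = 9,
    seed: int = 0,
) -> TMAManifest:
    """Build a core manifest and flag a seeded choice of cores non-representative.

    The default study design is four arrays of 30/30/30/16 cores with nine
    cores excluded for insufficient tumour tissue, leaving 97.
    """
    if n_nonrepresentative < 0 or any(n < 0 for n in arrays):
        raise ValueError("core counts must be non-negative")
    total = sum(arrays)
    if n_nonrepresentative > total:
        raise ValueError("cannot flag more cores than exist")
    rng = np.random.default_rng(seed)
    excluded = set(rng.choice(total, size=n_nonrepresentative, replace=False).tolist())
    cores = []
    idx = 0
    for a, count in enumerate(arrays, start=1):
        for k in range(1, count + 1):
            cores.append((f"TMA{a}", f"core{k:02d}", idx not in excluded))
            idx += 1
    return TMAManifest(cores)
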