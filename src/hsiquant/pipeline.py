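"""End-to-end pipeline: simulate cores, analyse cubes, reproduce the reference tables.

Every stage is driven by a :class:`PipelineConfig` (TOML-serialisable) and a
single base seed; all randomness flows from seeded generators so two runs
with the same config produce byte-identical CSV/JSON outputs. Per-core
failures during analysis are logged and the core is flagged
non-representative; the batch continues.
"""

from __future__ import annotations

import itertools
import json
import logging
import tomllib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from . import reference_data as ref
from .classes import Tier, TissueClass
from .concordance import (
    Dichotomy,
    agreement_table,
    cohen_kappa,
    dichotomise_allred,
    dichotomise_hscore,
    spearman_rho,
    wilcoxon_signed_rank,
)
from .scoring import IntensityThresholds, score_core, segment_cells
from .segmentation import (
    LabelMap,
    ROISet,
    cf_classify,
    extract_references,
    fit_pca,
    pca_false_colour,
    pca_segment,
)
from .spectral_io import (
    SpectralCube,
    WavelengthAxis,
    crop_spectral_window,
    read_cube,
    reflectance_to_absorbance,
    write_cube,
)
from .synthetic import (
    DEFAULT_TIER_CONCENTRATIONS,
    build_endmember_library,
    generate_layout,
    generate_tma_manifest,
    render_cube,
)

__all__ = ["PipelineConfig", "run_simulate", "run_analyse", "run_reproduce"]

log = logging.getLogger("hsiquant")


@dataclass
class PipelineConfig:
    """All tunables of the simulate/analyse pipeline, with validated defaults."""

    # acquisition grid and spectral windows (nm)
    wavelength_start: float = 500.0
    wavelength_stop: float = 1000.0
    wavelength_step: float = 5.0
    window_lo: float = 520.0
    window_hi: float = 725.0
    od_lo: float = 520.0
    od_hi: float = 650.0
    # synthetic tissue
    shape: tuple[int, int] = (128, 128)
    n_cells: int = 40
    nucleus_radius: int = 3
    cytoplasm_radius: int = 6
    tier_concentrations: dict = field(
        default_factory=lambda: {t.name: c for t, c in DEFAULT_TIER_CONCENTRATIONS.items()}
    )
    noise_sd: float = 0.0
    percent_positive: float | None = None  # None -> per-core seeded draw in [50, 100]
    tier_mix: tuple[float, float, float] | None = None  # None -> per-core seeded draw
    # classification
    classifier: str = "cf"  # "cf", "pca" or "both"
    min_corr: float = 0.8
    metric: str = "pearson"
    n_components: int = 3
    # scoring
    t_weak: float = 0.2
    t_moderate: float = 0.45
    t_strong: float = 0.9
    min_nucleus_px: int = 4
    ring_radius: float = 3.0
    # concordance
    pooling: str = "pooled_all"
    # randomness
    seed: int = 0

    def validate(self) -> None:
        if not self.wavelength_start < self.wavelength_stop:
            raise ValueError("config: wavelength_start must be below wavelength_stop")
        if self.wavelength_step <= 0:
            raise ValueError("config: wavelength_step must be positive")
        if not self.window_lo < self.window_hi:
            raise ValueError("config: window_lo must be below window_hi")
        if self.classifier not in ("cf", "pca", "both"):
            raise ValueError(f"config: unknown classifier '{self.classifier}'")
        if not -1.0 <= self.min_corr <= 1.0:
            raise ValueError("config: min_corr must lie in [-1, 1]")
        if self.noise_sd < 0:
            raise ValueError("config: noise_sd must be non-negative")
        if self.n_cells < 1:
            raise ValueError("config: n_cells must be >= 1")
        IntensityThresholds(self.t_weak, self.t_moderate, self.t_strong)  # ordering check
        if self.pooling not in ("pooled_all", "per_method"):
            raise ValueError(f"config: unknown pooling '{self.pooling}'")

    def axis(self) -> WavelengthAxis:
        values = np.arange(
            self.wavelength_start,
            self.wavelength_stop + self.wavelength_step / 2,
            self.wavelength_step,
        )
        return WavelengthAxis(values)

    def thresholds(self) -> IntensityThresholds:
        return IntensityThresholds(self.t_weak, self.t_moderate, self.t_strong)

    def tier_conc(self) -> dict[Tier, float]:
        return {Tier[name]: float(c) for name, c in self.tier_concentrations.items()}

    @classmethod
    def from_toml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
        cfg = cls(**raw)
        for key in ("shape", "tier_mix"):
            value = getattr(cfg, key)
            if isinstance(value, list):
                setattr(cfg, key, tuple(value))
        cfg.validate()
        return cfg

    def to_toml(self) -> str:
        lines = []
        for key, value in asdict(self).items():
            if value is None:
                continue
            if isinstance(value, str):
                lines.append(f'{key} = "{value}"')
            elif isinstance(value, dict):
                inner = ", ".join(f'"{k}" = {v}' for k, v in value.items())
                lines.append(f"{key} = {{{inner}}}")
            elif isinstance(value, (tuple, list)):
                lines.append(f"{key} = [{', '.join(str(v) for v in value)}]")
            elif isinstance(value, bool):
                lines.append(f"{key} = {str(value).lower()}")
            else:
                lines.append(f"{key} = {value}")
        return "\n".join(lines) + "\n"


def _core_seed(base_seed: int, index: int) -> int:
    """Derived per-core seed, deterministic in (base_seed, index), < 2^31."""
    ss = np.random.SeedSequence([base_seed, index])
    return int(ss.generate_state(1)[0] % (2**31))


def _core_composition(config: PipelineConfig, seed: int) -> tuple[float, tuple]:
    """Per-core staining composition: seeded draw unless pinned in the config."""
    rng = np.random.default_rng(seed)
    if config.percent_positive is not None:
        pct = float(config.percent_positive)
    else:
        pct = float(rng.uniform(50.0, 100.0))
    if config.tier_mix is not None:
        mix = tuple(float(v) for v in config.tier_mix)
    else:
        raw = rng.dirichlet([1.0, 1.0, 1.0]) * 100.0
        raw = np.round(raw, 6)
        raw[2] = 100.0 - raw[0] - raw[1]
        mix = tuple(float(v) for v in raw)
    return pct, mix


def simulate_core(config: PipelineConfig, index: int):
    """One seeded synthetic core: (cube, ground_truth, layout)."""
    seed = _core_seed(config.seed, index)
    pct, mix = _core_composition(config, seed)
    layout = generate_layout(
        config.shape,
        config.n_cells,
        pct,
        mix,
        seed=seed,
        nucleus_radius=config.nucleus_radius,
        cytoplasm_radius=config.cytoplasm_radius,
    )
    cube, truth = render_cube(
        layout,
        build_endmember_library(),
        config.axis(),
        config.tier_conc(),
        noise_sd=config.noise_sd,
        seed=seed,
    )
    return cube, truth, layout


def run_simulate(config: PipelineConfig, n_cores: int, out_dir: str | Path) -> pd.DataFrame:
    """Write n_cores seeded cubes + ground truth + a manifest CSV; returns the manifest."""
    config.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for i in range(n_cores):
        cube, truth, _layout = simulate_core(config, i)
        stem = f"core_{i:03d}"
        write_cube(cube, out / f"{stem}.dat", format="ENVI")
        iio.imwrite(out / f"{stem}_truth.png", truth.label_image)
        fr = truth.implied_fractions
        rows.append(
            {
                "core_id": stem,
                "cube_file": f"{stem}.dat",
                "truth_file": f"{stem}_truth.png",
                "n_cells": len(truth.cell_tiers),
                "percent_positive": truth.percent_positive,
                "pct_weak": fr[Tier.WEAK],
                "pct_moderate": fr[Tier.MODERATE],
                "pct_strong": fr[Tier.STRONG],
                "implied_h_score": truth.implied_h_score,
            }
        )
        log.info("simulate: wrote %s", stem)
    manifest = pd.DataFrame(
        rows,
        columns=[
            "core_id", "cube_file", "truth_file", "n_cells", "percent_positive",
            "pct_weak", "pct_moderate", "pct_strong", "implied_h_score",
        ],
    )
    manifest.to_csv(out / "manifest.csv", index=False)
    return manifest


def _rois_from_truth(label_image: np.ndarray) -> ROISet:
    masks = {}
    for cls in (TissueClass.DKK3_POSITIVE, TissueClass.NUCLEI, TissueClass.BACKGROUND):
        mask = label_image == int(cls)
        if mask.any():
            masks[cls] = mask
    return ROISet(masks)


def analyse_cube(
    config: PipelineConfig,
    cube: SpectralCube,
    rois: ROISet,
    classifier: str | None = None,
) -> tuple[LabelMap, list]:
    """Classify one calibrated reflectance cube and delineate its cells."""
    od = reflectance_to_absorbance(cube)
    windowed = crop_spectral_window(od, config.window_lo, config.window_hi)
    method = classifier or config.classifier
    if method == "cf":
        refs = extract_references(windowed, rois)
        label_map = cf_classify(windowed, refs, min_corr=config.min_corr, metric=config.metric)
    elif method == "pca":
        label_map = pca_segment(windowed, rois, n_components=config.n_components)
    else:
        raise ValueError(f"unknown classifier '{method}'")
    cells = segment_cells(
        label_map,
        min_nucleus_px=config.min_nucleus_px,
        ring_radius=config.ring_radius,
        absorbance=windowed,
        od_window=(config.od_lo, config.od_hi),
        thresholds=config.thresholds(),
    )
    return label_map, cells


def run_analyse(
    config: PipelineConfig,
    cube_dir: str | Path,
    out_dir: str | Path,
    write_images: bool = True,
) -> pd.DataFrame:
    """Score every cube in a directory; per-core failures are flagged, not fatal.

    ROIs come from the ground-truth label PNGs written by :func:`run_simulate`
    (the stand-in for histopathological annotation). With
    ``config.classifier == "both"`` each core is scored by the correlation
    classifier and the PCA segmenter and the between-classifier agreement
    (Cohen's kappa on dichotomised scores) is written alongside.
    """
    config.validate()
    cube_dir = Path(cube_dir)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    methods = ["cf", "pca"] if config.classifier == "both" else [config.classifier]
    rows = []
    for cube_path in sorted(cube_dir.glob("*.dat")):
        stem = cube_path.stem
        truth_path = cube_dir / f"{stem}_truth.png"
        try:
            cube = read_cube(cube_path, format="ENVI")
            labels_img = iio.imread(truth_path) if truth_path.exists() else None
            if labels_img is None:
                raise FileNotFoundError(f"no ROI source for {stem}")
            rois = _rois_from_truth(np.asarray(labels_img))
            for method in methods:
                label_map, cells = analyse_cube(config, cube, rois, classifier=method)
                score = score_core(cells, core_id=stem, labels=label_map,
                                   ring_radius=config.ring_radius)
                row = score.as_dict()
                row["classifier"] = method
                rows.append(row)
                if write_images:
                    iio.imwrite(out / f"{stem}_{method}_labels.png", label_map.classes)
            if write_images:
                od = crop_spectral_window(
                    reflectance_to_absorbance(cube), config.window_lo, config.window_hi
                )
                model = fit_pca(od, max(config.n_components, 3))
                rgb = (pca_false_colour(od, model) * 255).astype(np.uint8)
                iio.imwrite(out / f"{stem}_falsecolour.png", rgb)
        except Exception:  # noqa: BLE001 - a failed core must not abort the batch
            log.exception("analyse: core %s failed; flagged non-representative", stem)
            rows.append(
                {
                    "core_id": stem, "n_cells": 0, "pct_weak": 0.0, "pct_moderate": 0.0,
                    "pct_strong": 0.0, "pct_positive": 0.0, "h_score": 0.0,
                    "allred_ps": 0, "allred_is": 0, "allred_total": 0,
                    "positive_area_pct": 0.0, "representative": False,
                    "classifier": methods[0],
                }
            )
    scores = pd.DataFrame(rows)
    scores.to_csv(out / "core_scores.csv", index=False)
    if config.classifier == "both" and not scores.empty:
        _write_classifier_agreement(scores, out, pooling=config.pooling)
    return scores


def _write_classifier_agreement(scores: pd.DataFrame, out: Path, pooling: str) -> None:
    wide_h = scores.pivot(index="core_id", columns="classifier", values="h_score")
    wide_a = scores.pivot(index="core_id", columns="classifier", values="allred_total")
    h_cat = dichotomise_hscore(
        {m: wide_h[m].to_numpy() for m in wide_h.columns}, pooling=pooling
    )
    a_cat = {
        m: np.array([int(dichotomise_allred(v)) for v in wide_a[m]])
        for m in wide_a.columns
    }
    result = {}
    for label, cats in (("h_score", h_cat), ("allred", a_cat)):
        for a, b in itertools.combinations(sorted(cats), 2):
            table = agreement_table(cats[a], cats[b],
                                    categories=[int(Dichotomy.LOW), int(Dichotomy.HIGH)])
            kappa, band = cohen_kappa(table)
            result[f"{label}:{a}/{b}"] = {"kappa": kappa, "band": band}
    (out / "classifier_agreement.json").write_text(json.dumps(result, indent=2))


# ---------------------------------------------------------------------------
# Reproduction of the bundled reference tables
# ---------------------------------------------------------------------------


def run_reproduce(out_dir: str | Path | None = None) -> dict:
    """Recompute every derivable statistic from the bundled reference tables.

    Returns a dict of computed-vs-printed entries; known non-reproductions
    are surfaced under ``discrepancies`` rather than silently corrected.
    Writes JSON (and a CSV of the pairwise statistics) when ``out_dir`` is
    given.
    """
    table = ref.SIX_CASE_SCORES
    report: dict = {"entries": [], "discrepancies": list(ref.KNOWN_DISCREPANCIES)}

    def entry(name, computed, printed, note=""):
        report["entries"].append(
            {"name": name, "computed": computed, "printed": printed, "note": note}
        )

    kappa97, band97 = cohen_kappa(ref.TABLE1_COUNTS)
    entry("kappa_visual_digital_allred_97cores", round(kappa97, 3),
          ref.TABLE1_PRINTED_KAPPA, f"band: {band97}")

    for column, printed in ref.PRINTED_MEANS.items():
        entry(f"mean_{column}", round(float(table[column].mean()), 2), printed)

    manifest = generate_tma_manifest(ref.TMA_ARRAYS, ref.TMA_EXCLUDED, seed=0)
    entry("representative_cores", manifest.n_representative, ref.TMA_ANALYSED)

    # pairwise kappas on the printed dichotomised vectors
    for (a, b), printed in ref.PRINTED_KAPPAS.items():
        cats_a = ref.PRINTED_CATEGORIES[("Allred", a)]
        cats_b = ref.PRINTED_CATEGORIES[("Allred", b)]
        kappa, band = cohen_kappa(agreement_table(cats_a, cats_b, categories=[1, 2]))
        entry(f"kappa_{a}_{b}_dichotomised", round(kappa, 3), printed, f"band: {band}")

    # recomputed H-score dichotomisation at the pooled mean
    h_values = {m: table[f"h_{m}"].to_numpy() for m in ("visual", "digital", "hsi")}
    h_cat = dichotomise_hscore(h_values, pooling="pooled_all")
    for m, cats in h_cat.items():
        entry(
            f"h_categories_{m}",
            [int(c) for c in cats],
            ref.PRINTED_CATEGORIES[("H", m)],
        )

    # six-case pairwise Spearman and exact Wilcoxon on raw H-scores
    for a, b in itertools.combinations(("visual", "digital", "hsi"), 2):
        rho, _p = spearman_rho(h_values[a], h_values[b])
        printed_rho = (
            ref.PRINTED_RHO_VISUAL_HSI if {a, b} == {"visual", "hsi"} else None
        )
        entry(f"spearman_h_{a}_{b}", round(rho, 3), printed_rho)
        _w, p = wilcoxon_signed_rank(h_values[a], h_values[b], mode="exact")
        printed_p = (
            ref.PRINTED_WILCOXON_P_97 if {a, b} == {"visual", "digital"} else None
        )
        entry(
            f"wilcoxon_h_{a}_{b}", round(p, 5), printed_p,
            "printed value refers to the 97-core dataset"
            if {a, b} == {"visual", "digital"} else "",
        )

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "reproduce.json").write_text(json.dumps(report, indent=2))
        pd.DataFrame(report["entries"]).to_csv(out / "reproduce.csv", index=False)
    return report
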