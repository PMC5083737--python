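"""Synthetic karyometry cohorts for the three-class pancreatic lesion problem.

The reference cohort this package analyzes (12 chronic pancreatitis, 16
IPMN, 16 pancreatic carcinoma tissues; roughly 180 +/- 22 imaged nuclei per
tissue) is not publicly deposited, so the generators here produce data with
the same statistical structure at two tiers:

* feature tier -- one row per tissue, six informative karyometric features
  drawn from per-class normal distributions whose means/SDs are the
  published group statistics, embedded in a 93-dimensional panel whose
  remaining 87 dimensions are class-independent standard-normal noise;
* image tier -- rasterized elliptical nuclei with blob-textured chromatin,
  whose shape and staining knobs are set so the extractor recovers
  class-typical feature values.

Only means and SDs are published, so features are drawn independently per
class; independence is the minimal assumption and is documented as such.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.optimize import brentq

from .features import DISCRIMINATING_FEATURES, LIGHT_THRESHOLD_DEFAULT, NucleusImage

CLASS_ORDER = ("CP", "IPMN", "PC")

#: Per-class (mean, SD) of the six informative features: group statistics of
#: the reference cohort, used as generative parameters.
DEFAULT_INFORMATIVE_PARAMS: dict[str, dict[str, tuple[float, float]]] = {
    "nuclear_roundness": {"CP": (1.63, 0.04), "IPMN": (1.79, 0.10), "PC": (1.69, 0.04)},
    "rlm_summary": {"CP": (12.80, 1.16), "IPMN": (10.08, 2.44), "PC": (10.85, 1.98)},
    "short_run_emphasis": {"CP": (0.51, 0.03), "IPMN": (0.47, 0.04), "PC": (0.46, 0.03)},
    "long_run_emphasis": {"CP": (9.83, 0.91), "IPMN": (11.50, 0.86), "PC": (10.58, 0.84)},
    "run_percentage": {"CP": (467.37, 47.33), "IPMN": (511.37, 128.25), "PC": (723.86, 165.97)},
    "n_light_pixels": {"CP": (230.17, 51.18), "IPMN": (340.87, 171.84), "PC": (581.29, 227.73)},
}


@dataclass(frozen=True)
class CohortConfig:
    """Generative parameters for a synthetic cohort.

    ``within_tissue_sd_scale`` sets per-nucleus dispersion around a tissue's
    latent mean as a multiple of that feature's tissue-level SD; within-
    tissue variance must exceed the between-tissue variance of the mean for
    pooling by averaging to matter, hence the default of 3.
    """

    n_per_class: tuple[int, int, int] = (12, 16, 16)
    nuclei_mean: float = 180.0
    nuclei_sd: float = 22.0
    n_noise_features: int = 87
    informative_params: dict[str, dict[str, tuple[float, float]]] = field(
        default_factory=lambda: {
            f: dict(v) for f, v in DEFAULT_INFORMATIVE_PARAMS.items()
        }
    )
    within_tissue_sd_scale: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.n_per_class) != len(CLASS_ORDER):
            raise ValueError("n_per_class must give one count per class")
        if any(n < 0 for n in self.n_per_class):
            raise ValueError("class counts must be >= 0")
        if self.nuclei_sd < 0:
            raise ValueError("nuclei_sd must be >= 0")
        if self.n_noise_features < 0:
            raise ValueError("n_noise_features must be >= 0")
        for feat, per_class in self.informative_params.items():
            for cls, (_, sd) in per_class.items():
                if sd <= 0:
                    raise ValueError(f"SD for {feat}/{cls} must be > 0")

    @property
    def feature_names(self) -> list[str]:
        informative = list(self.informative_params)
        width = len(informative) + self.n_noise_features
        noise = [f"f_{i:03d}" for i in range(len(informative) + 1, width + 1)]
        return informative + noise

    def to_json(self) -> str:
        payload = {
            "n_per_class": list(self.n_per_class),
            "nuclei_mean": self.nuclei_mean,
            "nuclei_sd": self.nuclei_sd,
            "n_noise_features": self.n_noise_features,
            "informative_params": {
                f: {c: list(ms) for c, ms in v.items()}
                for f, v in self.informative_params.items()
            },
            "within_tissue_sd_scale": self.within_tissue_sd_scale,
            "seed": self.seed,
        }
        return json.dumps(payload, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "CohortConfig":
        payload = json.loads(text)
        if "n_per_class" in payload:
            payload["n_per_class"] = tuple(payload["n_per_class"])
        if "informative_params" in payload:
            payload["informative_params"] = {
                f: {c: tuple(ms) for c, ms in v.items()}
                for f, v in payload["informative_params"].items()
            }
        return cls(**payload)


@dataclass(frozen=True)
class SyntheticNucleusSpec:
    """Knobs for rasterizing one synthetic nucleus."""

    class_label: str
    axis_ratio: float = 1.0
    chromatin_blob_density: float = 0.02
    blob_contrast: float = 60.0
    light_fraction: float = 0.1
    diameter_px: int = 51

    def __post_init__(self) -> None:
        if self.class_label not in CLASS_ORDER:
            raise ValueError(f"unknown class label {self.class_label!r}")
        if self.axis_ratio < 1:
            raise ValueError("axis_ratio must be >= 1")
        if self.chromatin_blob_density < 0:
            raise ValueError("chromatin_blob_density must be >= 0")
        if not 0 <= self.light_fraction <= 1:
            raise ValueError("light_fraction must lie in [0, 1]")
        if self.diameter_px < 8:
            raise ValueError("nucleus too small to rasterize")


@dataclass
class TissueSample:
    """A labeled tissue with per-nucleus feature vectors (one row each)."""

    tissue_id: str
    true_class: str | None
    features: pd.DataFrame

    def __post_init__(self) -> None:
        if len(self.features) < 1:
            raise ValueError("tissue must contain at least one nucleus")


def _class_seeds(config: CohortConfig, seed: int | None) -> np.random.Generator:
    return np.random.default_rng(config.seed if seed is None else seed)


def _draw_tissue_row(rng, config: CohortConfig, cls: str) -> np.ndarray:
    informative = np.array(
        [rng.normal(*config.informative_params[f][cls]) for f in config.informative_params]
    )
    noise = rng.standard_normal(config.n_noise_features)
    return np.concatenate([informative, noise])


def gen_feature_cohort(config: CohortConfig, seed: int | None = None) -> pd.DataFrame:
    """Tissue-level feature table: one row per tissue.

    Informative features are independent normals with the class's generative
    mean/SD; noise features are standard normal identically across classes.
    Deterministic given the seed.  Raises if every class count is zero.
    """
    if sum(config.n_per_class) == 0:
        raise ValueError("empty cohort")
    rng = _class_seeds(config, seed)
    rows, ids, labels = [], [], []
    for cls, n in zip(CLASS_ORDER, config.n_per_class):
        for i in range(n):
            rows.append(_draw_tissue_row(rng, config, cls))
            ids.append(f"{cls}_{i + 1:03d}")
            labels.append(cls)
    table = pd.DataFrame(rows, columns=config.feature_names)
    table.insert(0, "class", labels)
    table.insert(0, "tissue_id", ids)
    return table


def gen_nucleus_cohort(
    config: CohortConfig, seed: int | None = None
) -> list[TissueSample]:
    """Nucleus-level cohort: per-tissue collections of noisy feature vectors.

    Nuclei counts are drawn normal(nuclei_mean, nuclei_sd), rounded and
    truncated at 1.  Each nucleus's vector is the tissue's latent mean plus
    independent normal noise with SD ``within_tissue_sd_scale`` times the
    tissue-level SD (1.0 for noise dimensions).
    """
    if config.nuclei_mean <= 0:
        raise ValueError("nuclei_mean must be > 0")
    if sum(config.n_per_class) == 0:
        raise ValueError("empty cohort")
    rng = _class_seeds(config, seed)
    names = config.feature_names
    samples: list[TissueSample] = []
    for cls, n_tissues in zip(CLASS_ORDER, config.n_per_class):
        sds = np.array(
            [config.informative_params[f][cls][1] for f in config.informative_params]
            + [1.0] * config.n_noise_features
        )
        for i in range(n_tissues):
            latent = _draw_tissue_row(rng, config, cls)
            n_nuclei = max(1, int(round(rng.normal(config.nuclei_mean, config.nuclei_sd))))
            noise = rng.normal(
                0.0, config.within_tissue_sd_scale * sds, size=(n_nuclei, len(names))
            )
            tissue_id = f"{cls}_{i + 1:03d}"
            frame = pd.DataFrame(latent + noise, columns=names)
            frame.insert(0, "nucleus_id", [f"{tissue_id}_n{k + 1:04d}" for k in range(n_nuclei)])
            samples.append(TissueSample(tissue_id=tissue_id, true_class=cls, features=frame))
    return samples


def nucleus_cohort_to_frame(samples: list[TissueSample]) -> pd.DataFrame:
    """Flatten a nucleus-level cohort into one long table."""
    parts = []
    for s in samples:
        frame = s.features.copy()
        frame.insert(0, "class", s.true_class)
        frame.insert(0, "tissue_id", s.tissue_id)
        parts.append(frame)
    return pd.concat(parts, ignore_index=True)


def ellipse_form_factor(axis_ratio: float) -> float:
    """Form factor P^2/(4 pi A) of a continuous ellipse with the given
    major/minor axis ratio, using Ramanujan's perimeter approximation."""
    a, b = float(axis_ratio), 1.0
    perimeter = np.pi * (3 * (a + b) - np.sqrt((3 * a + b) * (a + 3 * b)))
    area = np.pi * a * b
    return perimeter**2 / (4 * np.pi * area)


def class_image_preset(
    class_label: str,
    config: CohortConfig | None = None,
    diameter_px: int = 61,
) -> SyntheticNucleusSpec:
    """Rendering knobs whose extracted features land near a class's
    generative means.

    The axis ratio inverts the continuous-ellipse form factor at the class's
    mean roundness; the light fraction divides the class's mean light-pixel
    count by the ellipse area.  Both are closed-form, so no stored
    calibration constants are needed.
    """
    cfg = config or CohortConfig()
    target_ff = cfg.informative_params["nuclear_roundness"][class_label][0]
    target_light = cfg.informative_params["n_light_pixels"][class_label][0]
    ratio = brentq(lambda r: ellipse_form_factor(r) - target_ff, 1.0 + 1e-9, 20.0)
    a = diameter_px / 2.0
    area = np.pi * a * (a / ratio)
    return SyntheticNucleusSpec(
        class_label=class_label,
        axis_ratio=float(ratio),
        light_fraction=float(np.clip(target_light / area, 0.0, 1.0)),
        diameter_px=diameter_px,
    )


def render_nucleus(spec: SyntheticNucleusSpec, seed: int = 0) -> NucleusImage:
    """Rasterize one synthetic nucleus.

    Elliptical mask with the requested axis ratio; interior texture is a
    dark base plus Gaussian-smoothed random chromatin blobs; intensities are
    then shifted so the in-mask fraction of pixels above the light-staining
    threshold approximates ``light_fraction``.  Deterministic given seed.
    """
    rng = np.random.default_rng(seed)
    a = spec.diameter_px / 2.0
    b = a / spec.axis_ratio
    margin = 3
    H, W = int(np.ceil(2 * b)) + 2 * margin, int(np.ceil(2 * a)) + 2 * margin
    rr, cc = np.mgrid[0:H, 0:W]
    cy, cx = (H - 1) / 2.0, (W - 1) / 2.0
    mask = ((cc - cx) / a) ** 2 + ((rr - cy) / b) ** 2 <= 1.0
    area = mask.sum()

    base = np.full((H, W), 100.0)
    n_blobs = rng.poisson(spec.chromatin_blob_density * area)
    blob_field = np.zeros((H, W))
    if n_blobs and spec.blob_contrast:
        ys = rng.integers(0, H, n_blobs)
        xs = rng.integers(0, W, n_blobs)
        np.add.at(blob_field, (ys, xs), spec.blob_contrast)
        blob_field = ndimage.gaussian_filter(blob_field, sigma=2.0)
    texture = base + blob_field + rng.normal(0.0, 3.0, size=(H, W))

    inside = texture[mask]
    if spec.light_fraction <= 0:
        shift = LIGHT_THRESHOLD_DEFAULT - inside.max()
    elif spec.light_fraction >= 1:
        shift = (LIGHT_THRESHOLD_DEFAULT + 1) - inside.min()
    else:
        q = np.quantile(inside, 1.0 - spec.light_fraction)
        shift = LIGHT_THRESHOLD_DEFAULT + 0.5 - q
    pixels = np.clip(np.round(texture + shift), 0, 255)
    pixels[~mask] = 255  # light background outside the nucleus
    return NucleusImage(pixels=pixels, mask=mask)


def gen_image_cohort(
    config: CohortConfig,
    seed: int | None = None,
    nuclei_per_tissue: int | None = None,
    diameter_px: int = 51,
) -> list[tuple[str, str, list[NucleusImage]]]:
    """Image-tier cohort: rendered nuclei per tissue using class presets.

    ``nuclei_per_tissue`` overrides the normal(nuclei_mean, nuclei_sd) draw,
    which keeps rendering affordable when only a subset of images is needed.
    Per-nucleus shape jitter perturbs the preset axis ratio and light
    fraction so extracted features vary within a tissue.
    """
    if sum(config.n_per_class) == 0:
        raise ValueError("empty cohort")
    rng = _class_seeds(config, seed)
    cohort = []
    for cls, n_tissues in zip(CLASS_ORDER, config.n_per_class):
        preset = class_image_preset(cls, config, diameter_px=diameter_px)
        for i in range(n_tissues):
            if nuclei_per_tissue is None:
                n_nuclei = max(1, int(round(rng.normal(config.nuclei_mean, config.nuclei_sd))))
            else:
                n_nuclei = nuclei_per_tissue
            images = []
            for _ in range(n_nuclei):
                jittered = replace(
                    preset,
                    axis_ratio=max(1.0, preset.axis_ratio + rng.normal(0, 0.08)),
                    light_fraction=float(
                        np.clip(preset.light_fraction + rng.normal(0, 0.02), 0, 1)
                    ),
                )
                images.append(render_nucleus(jittered, seed=int(rng.integers(2**31))))
            cohort.append((f"{cls}_{i + 1:03d}", cls, images))
    return cohort
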