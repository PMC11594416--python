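"""Synthetic psychophysics stimuli for two-choice orientation/color discrimination.

Four stimulus families, each a binary discrimination task:

* ``gabor_array`` — 90x90 arrays of eight noisy 30x30 Gabor patches; judge
  whether the *mean* tilt across patches is clockwise (CW) or
  counterclockwise (CCW) of horizontal.
* ``superimposed`` — 100x100 pairs of orthogonal +/-45 deg sinusoidal
  gratings under a noise mask; judge the orientation of the higher-contrast
  (dominant) grating.
* ``single_gabor`` — 100x100 single noisy Gabor tilted +/-45 deg from
  vertical; judge the tilt direction.
* ``color_array`` — 90x90 arrays of eight colored circles on a red--blue
  axis; judge whether the mean color is more red or more blue.

Stimulus "energy" is manipulated by jointly increasing a signal-like feature
(contrast, or color-intensity distance from neutral) and a variability-like
feature (orientation spread, non-dominant contrast, pixel noise, color
spread) so that accuracy stays matched while confidence is free to move.

All images are float arrays in [0, 1]; grayscale images have shape (H, W)
and color images (H, W, 3).  Generation is deterministic given a seed: a set
uses one master seed, and per-image generators are spawned by counter so the
set is order-independent.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "StimulusParams",
    "ImageSample",
    "EnergyCondition",
    "ENERGY_CONDITIONS",
    "TRAINING_RANGES",
    "GABOR_CYCLES_PER_PATCH",
    "render_gabor",
    "make_gabor_array",
    "make_superimposed",
    "make_single_gabor",
    "make_color_array",
    "make_training_set",
    "make_test_set",
    "image_shape",
    "save_set",
]

EXPERIMENTS = ("gabor_array", "superimposed", "single_gabor", "color_array")

#: carrier spatial frequency, cycles per patch width
GABOR_CYCLES_PER_PATCH = 3.0
#: Gaussian envelope SD as a fraction of patch width
GABOR_ENVELOPE_FRACTION = 1.0 / 6.0
#: fixed nuisance pixel-noise SD for experiments whose noise level is not a
#: manipulated parameter (gabor_array, superimposed)
DEFAULT_MASK_NOISE_SD = 0.1

#: uniform sampling intervals for the training / validation distributions
TRAINING_RANGES = {
    "gabor_array": {
        "tilt": (1.0, 10.0),
        "orientation_sd": (1.0, 20.0),
        "contrast": (0.01, 1.0),
    },
    "superimposed": {
        "orientation": (1.0, 45.0),
        "contrast": (0.01, 1.0),
        "contrast_difference_min": 0.01,
    },
    "single_gabor": {
        "contrast": (0.01, 1.0),
        "noise_sd": (0.01, 2.0),
    },
    "color_array": {
        "color_intensity": (0.0, 1.0),
        "color_spread": (0.0, 1.0),
    },
}

# Fixed (signal, variability) pairs per energy level for the 4-layer CNN.
# Low/mid/high jointly increase the signal feature and the variability
# feature; accuracies were matched near 70% for trained networks.
ENERGY_CONDITIONS = {
    "gabor_array": {
        "low": {"contrast": 0.2, "orientation_sd": 7.35},
        "mid": {"contrast": 0.25, "orientation_sd": 21.28},
        "high": {"contrast": 0.3, "orientation_sd": 27.28},
    },
    "superimposed": {
        "low": {"contrast": 0.2, "nondominant_contrast": 0.168},
        "mid": {"contrast": 0.4, "nondominant_contrast": 0.375},
        "high": {"contrast": 0.6, "nondominant_contrast": 0.575},
    },
    "single_gabor": {
        "low": {"contrast": 0.05, "noise_sd": 0.42},
        "mid": {"contrast": 0.1, "noise_sd": 0.82},
        "high": {"contrast": 0.15, "noise_sd": 1.21},
    },
    "color_array": {
        "low": {"color_intensity": 0.493, "color_spread": 0.4},
        "mid": {"color_intensity": 0.492, "color_spread": 0.494},
        "high": {"color_intensity": 0.49, "color_spread": 0.626},
    },
}

LEVELS = ("low", "mid", "high")


def _check_energy_ordering() -> None:
    """Both members of each (signal, variability) pair must increase
    low -> mid -> high.  For the color task the signal member is the
    distance of the mean intensity from the neutral point 0.5."""
    for exp, table in ENERGY_CONDITIONS.items():
        rows = [table[lvl] for lvl in LEVELS]
        keys = list(rows[0])
        for k in keys:
            vals = [r[k] for r in rows]
            if exp == "color_array" and k == "color_intensity":
                vals = [abs(v - 0.5) for v in vals]
            if not (vals[0] < vals[1] < vals[2]):
                raise AssertionError(
                    f"energy levels not strictly increasing for {exp}/{k}: {vals}"
                )


_check_energy_ordering()


@dataclass
class StimulusParams:
    """Generative parameters of one stimulus image."""

    experiment: str
    label: int  # 0 = S1 (CCW / red), 1 = S2 (CW / blue)
    tilt_magnitude: float = 45.0
    orientation_sd: float = 0.0
    contrast: float = 1.0
    nondominant_contrast: float = 0.0
    noise_sd: float = 0.0
    color_intensity: float = 0.5
    color_spread: float = 0.0
    seed: int = 0
    #: realized per-patch orientations / intensities, recorded for audit
    realized: Optional[list] = field(default=None)

    def __post_init__(self):
        if self.experiment not in EXPERIMENTS:
            raise ValueError(f"unknown experiment {self.experiment!r}")
        for name in ("tilt_magnitude", "orientation_sd", "contrast",
                     "nondominant_contrast", "noise_sd",
                     "color_intensity", "color_spread"):
            v = getattr(self, name)
            if not math.isfinite(v):
                raise ValueError(f"{name} must be finite, got {v!r}")
        if not 0.0 <= self.contrast <= 1.0:
            raise ValueError(f"contrast must be in [0,1], got {self.contrast}")
        if self.orientation_sd < 0 or self.noise_sd < 0:
            raise ValueError("orientation_sd and noise_sd must be >= 0")
        if not 0.0 <= self.color_intensity <= 1.0:
            raise ValueError("color_intensity must be in [0,1]")
        if self.color_spread < 0:
            raise ValueError("color_spread must be >= 0")
        if self.experiment == "superimposed" and self.nondominant_contrast > self.contrast:
            raise ValueError("nondominant_contrast must not exceed contrast")


@dataclass
class ImageSample:
    """One rendered stimulus: pixel grid, class label, and provenance."""

    pixels: np.ndarray
    label: int
    params: StimulusParams


@dataclass(frozen=True)
class EnergyCondition:
    """One level of the energy manipulation of an experiment."""

    experiment: str
    level: str

    @property
    def params(self) -> dict:
        try:
            return ENERGY_CONDITIONS[self.experiment][self.level]
        except KeyError:
            raise ValueError(
                f"no energy condition {self.level!r} for {self.experiment!r}"
            ) from None


def image_shape(experiment: str) -> tuple:
    """(H, W) or (H, W, 3) of the experiment's canvas."""
    if experiment in ("gabor_array",):
        return (90, 90)
    if experiment == "color_array":
        return (90, 90, 3)
    if experiment in ("superimposed", "single_gabor"):
        return (100, 100)
    raise ValueError(f"unknown experiment {experiment!r}")


# ---------------------------------------------------------------------------
# low-level renderers
# ---------------------------------------------------------------------------

def _gabor_pattern(orientation_deg: float, size: int) -> np.ndarray:
    """Unit Gabor: Gaussian-windowed sinusoid, odd (sine) phase about the
    patch center.  Odd phase gives the pattern zero mean and a symmetric
    range, so a patch of contrast ``c`` has mean intensity exactly 0.5 and
    peak-to-trough amplitude ``c`` after scaling."""
    half = (size - 1) / 2.0
    y, x = np.mgrid[0:size, 0:size].astype(np.float64)
    x -= half
    y -= half
    theta = np.deg2rad(orientation_deg)
    # coordinate along the modulation axis (perpendicular to the stripes);
    # positive angle = clockwise rotation of the stripes
    u = x * np.sin(theta) + y * np.cos(theta)
    freq = GABOR_CYCLES_PER_PATCH / size
    envelope = np.exp(-(x ** 2 + y ** 2) / (2.0 * (GABOR_ENVELOPE_FRACTION * size) ** 2))
    g = envelope * np.sin(2.0 * np.pi * freq * u)
    peak = np.abs(g).max()
    if peak > 0:
        g /= peak  # range now [-1, 1] (odd symmetry)
    return g


def render_gabor(orientation: float, contrast: float, size: int = 30,
                 noise_sd: float = 0.0,
                 rng: Optional[np.random.Generator] = None,
                 seed: Optional[int] = None) -> np.ndarray:
    """Render one Gabor patch on a mid-gray background.

    Peak-to-trough amplitude of the noise-free pattern equals ``contrast``;
    additive zero-mean Gaussian pixel noise of SD ``noise_sd`` is applied
    afterwards and the result is clipped to [0, 1].
    """
    for name, v in (("orientation", orientation), ("contrast", contrast),
                    ("noise_sd", noise_sd)):
        if not math.isfinite(v):
            raise ValueError(f"{name} must be finite, got {v!r}")
    if not 0.0 <= contrast <= 1.0:
        raise ValueError(f"contrast must be in [0,1], got {contrast}")
    if size < 8:
        raise ValueError("size must be >= 8")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    img = 0.5 + 0.5 * contrast * _gabor_pattern(orientation, size)
    if noise_sd > 0:
        if rng is None:
            rng = np.random.default_rng(seed)
        img = img + rng.normal(0.0, noise_sd, img.shape)
    return np.clip(img, 0.0, 1.0)


def _grating_pattern(orientation_deg: float, size: int) -> np.ndarray:
    """Full-field unit sinusoidal grating (no envelope), odd phase."""
    half = (size - 1) / 2.0
    y, x = np.mgrid[0:size, 0:size].astype(np.float64)
    x -= half
    y -= half
    theta = np.deg2rad(orientation_deg)
    u = x * np.sin(theta) + y * np.cos(theta)
    freq = GABOR_CYCLES_PER_PATCH / size
    return np.sin(2.0 * np.pi * freq * u)


_ARRAY_CELLS = [(r, c) for r in range(3) for c in range(3) if (r, c) != (1, 1)]


def make_gabor_array(mean_tilt: float, orientation_sd: float, contrast: float,
                     noise_sd: float = DEFAULT_MASK_NOISE_SD,
                     seed: int = 0) -> ImageSample:
    """Array of eight noisy Gabors in a 3x3 grid (center empty) on a 90x90
    canvas.  Per-patch orientations ~ Normal(mean_tilt, orientation_sd),
    tilts measured from horizontal, positive = clockwise.  Label is S2 (CW)
    iff ``mean_tilt > 0``."""
    rng = np.random.default_rng(seed)
    orientations = rng.normal(mean_tilt, orientation_sd, 8)
    canvas = np.full((90, 90), 0.5)
    for (r, c), ori in zip(_ARRAY_CELLS, orientations):
        patch = 0.5 + 0.5 * contrast * _gabor_pattern(ori, 30)
        canvas[r * 30:(r + 1) * 30, c * 30:(c + 1) * 30] = patch
    if noise_sd > 0:
        canvas = canvas + rng.normal(0.0, noise_sd, canvas.shape)
    canvas = np.clip(canvas, 0.0, 1.0)
    label = 1 if mean_tilt > 0 else 0
    params = StimulusParams(
        experiment="gabor_array", label=label, tilt_magnitude=abs(mean_tilt),
        orientation_sd=orientation_sd, contrast=contrast, noise_sd=noise_sd,
        seed=seed, realized=list(orientations),
    )
    return ImageSample(canvas, label, params)


def make_superimposed(dominant_contrast: float, nondominant_contrast: float,
                      dominant_label: int, orientation: float = 45.0,
                      noise_sd: float = DEFAULT_MASK_NOISE_SD,
                      seed: int = 0) -> ImageSample:
    """Two orthogonal sinusoidal gratings (+/- ``orientation`` deg from
    vertical) superimposed about mid-gray, plus a Gaussian noise mask.  The
    higher-contrast (dominant) grating defines the label: S2 = CW."""
    if not dominant_contrast > nondominant_contrast:
        raise ValueError(
            "dominant_contrast must exceed nondominant_contrast "
            f"({dominant_contrast} <= {nondominant_contrast})"
        )
    # orientation measured from vertical: vertical stripes = 0 deg
    sign = 1.0 if dominant_label == 1 else -1.0
    dom = _grating_pattern(90.0 + sign * orientation, 100)
    nond = _grating_pattern(90.0 - sign * orientation, 100)
    img = 0.5 + 0.5 * dominant_contrast * dom + 0.5 * nondominant_contrast * nond
    rng = np.random.default_rng(seed)
    if noise_sd > 0:
        img = img + rng.normal(0.0, noise_sd, img.shape)
    img = np.clip(img, 0.0, 1.0)
    params = StimulusParams(
        experiment="superimposed", label=int(dominant_label),
        tilt_magnitude=orientation, contrast=dominant_contrast,
        nondominant_contrast=nondominant_contrast, noise_sd=noise_sd, seed=seed,
    )
    return ImageSample(img, int(dominant_label), params)


def make_single_gabor(contrast: float, noise_sd: float, label: int,
                      seed: int = 0) -> ImageSample:
    """Single noisy Gabor on a 100x100 canvas, tilted 45 deg from vertical.
    Label S2 = CW (+45), S1 = CCW (-45)."""
    tilt = 45.0 if label == 1 else -45.0
    img = render_gabor(90.0 + tilt, contrast, size=100, noise_sd=noise_sd,
                       rng=np.random.default_rng(seed))
    params = StimulusParams(
        experiment="single_gabor", label=int(label), tilt_magnitude=45.0,
        contrast=contrast, noise_sd=noise_sd, seed=seed,
    )
    return ImageSample(img, int(label), params)


_RED = np.array([1.0, 0.0, 0.0])
_BLUE = np.array([0.0, 0.0, 1.0])


def _circle_mask(size: int = 30, diameter: float = 28.0) -> np.ndarray:
    half = (size - 1) / 2.0
    y, x = np.mgrid[0:size, 0:size].astype(np.float64)
    return ((x - half) ** 2 + (y - half) ** 2) <= (diameter / 2.0) ** 2


_CIRCLE = _circle_mask()


def make_color_array(color_intensity: float, color_spread: float,
                     seed: int = 0) -> ImageSample:
    """Eight colored circles in a 3x3 grid (center empty) on a gray 90x90
    canvas.  Per-patch intensity ~ Uniform(c - v/2, c + v/2) (clipped to
    [0, 1] for display), mapped linearly from pure red (0) to pure blue (1).
    Label is S2 (blue) iff the mean of the *pre-clip* intensities > 0.5."""
    if color_spread < 0:
        raise ValueError("color_spread must be >= 0")
    rng = np.random.default_rng(seed)
    raw = rng.uniform(color_intensity - color_spread / 2.0,
                      color_intensity + color_spread / 2.0, 8)
    shown = np.clip(raw, 0.0, 1.0)
    canvas = np.full((90, 90, 3), 0.5)
    for (r, c), t in zip(_ARRAY_CELLS, shown):
        cell = canvas[r * 30:(r + 1) * 30, c * 30:(c + 1) * 30]
        cell[_CIRCLE] = (1.0 - t) * _RED + t * _BLUE
    label = 1 if raw.mean() > 0.5 else 0
    params = StimulusParams(
        experiment="color_array", label=label, color_intensity=color_intensity,
        color_spread=color_spread, seed=seed, realized=list(raw),
    )
    return ImageSample(canvas, label, params)


# ---------------------------------------------------------------------------
# set generation
# ---------------------------------------------------------------------------

def _spawn_seed(master_seed: int, index: int) -> int:
    # stable per-image seed; independent of generation order
    return int(np.random.SeedSequence([int(master_seed), int(index)]).generate_state(1)[0] % (2 ** 31))


def _sample_training_image(experiment: str, rng: np.random.Generator,
                           img_seed: int) -> ImageSample:
    if experiment == "gabor_array":
        r = TRAINING_RANGES["gabor_array"]
        tilt = rng.uniform(*r["tilt"])
        sign = 1.0 if rng.random() < 0.5 else -1.0
        return make_gabor_array(sign * tilt, rng.uniform(*r["orientation_sd"]),
                                rng.uniform(*r["contrast"]), seed=img_seed)
    if experiment == "superimposed":
        r = TRAINING_RANGES["superimposed"]
        ori = rng.uniform(*r["orientation"])
        dom = rng.uniform(*r["contrast"])
        # contrast difference sampled on [0.01, dom]; non-dominant = dom - diff
        diff = rng.uniform(r["contrast_difference_min"], dom)
        label = int(rng.random() < 0.5)
        return make_superimposed(dom, max(dom - diff, 0.0), label,
                                 orientation=ori, seed=img_seed)
    if experiment == "single_gabor":
        r = TRAINING_RANGES["single_gabor"]
        return make_single_gabor(rng.uniform(*r["contrast"]),
                                 rng.uniform(*r["noise_sd"]),
                                 int(rng.random() < 0.5), seed=img_seed)
    if experiment == "color_array":
        r = TRAINING_RANGES["color_array"]
        return make_color_array(rng.uniform(*r["color_intensity"]),
                                rng.uniform(*r["color_spread"]), seed=img_seed)
    raise ValueError(f"unknown experiment {experiment!r}")


def make_training_set(experiment: str, n: int = 10000, seed: int = 0) -> list:
    """``n`` images with parameters sampled uniformly from the training
    intervals; class labels balanced up to binomial noise."""
    rng = np.random.default_rng(seed)
    return [
        _sample_training_image(experiment, rng, _spawn_seed(seed, i))
        for i in range(n)
    ]


def _condition_image(experiment: str, cparams: dict, label: int,
                     rng: np.random.Generator, img_seed: int) -> ImageSample:
    if experiment == "gabor_array":
        tilt = rng.uniform(*TRAINING_RANGES["gabor_array"]["tilt"])
        sign = 1.0 if label == 1 else -1.0
        return make_gabor_array(sign * tilt, cparams["orientation_sd"],
                                cparams["contrast"], seed=img_seed)
    if experiment == "superimposed":
        return make_superimposed(cparams["contrast"],
                                 cparams["nondominant_contrast"], label,
                                 seed=img_seed)
    if experiment == "single_gabor":
        return make_single_gabor(cparams["contrast"], cparams["noise_sd"],
                                 label, seed=img_seed)
    if experiment == "color_array":
        # labels arise from the sampled mean color; condition params fix c, v
        return make_color_array(cparams["color_intensity"],
                                cparams["color_spread"], seed=img_seed)
    raise ValueError(f"unknown experiment {experiment!r}")


def make_test_set(experiment: str, condition, n: int = 1000,
                  seed: int = 0, overrides: Optional[dict] = None) -> list:
    """``n`` images at the fixed parameters of one energy condition.

    ``condition`` is an :class:`EnergyCondition`, a level name, or a dict of
    explicit parameters; ``overrides`` patch individual parameters (used by
    the factorized manipulations and the accuracy-matching search).
    """
    if isinstance(condition, EnergyCondition):
        if condition.experiment != experiment:
            raise ValueError("condition/experiment mismatch")
        cparams = dict(condition.params)
    elif isinstance(condition, str):
        cparams = dict(EnergyCondition(experiment, condition).params)
    else:
        cparams = dict(condition)
    if overrides:
        cparams.update(overrides)
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n):
        label = int(rng.random() < 0.5)
        out.append(_condition_image(experiment, cparams, label, rng,
                                    _spawn_seed(seed, i)))
    return out


# ---------------------------------------------------------------------------
# export / packing
# ---------------------------------------------------------------------------

def stack_pixels(samples: Sequence[ImageSample]) -> np.ndarray:
    """(N, H, W, C) float32 array ready for the network."""
    arrs = []
    for s in samples:
        p = s.pixels
        if p.ndim == 2:
            p = p[..., None]
        arrs.append(p.astype(np.float32))
    return np.stack(arrs) if arrs else np.zeros((0,), np.float32)


def labels_of(samples: Sequence[ImageSample]) -> np.ndarray:
    return np.array([s.label for s in samples], dtype=np.int64)


def save_set(samples: Sequence[ImageSample], outdir) -> Path:
    """Persist a stimulus set as 8-bit PNGs plus a CSV manifest."""
    from PIL import Image

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = outdir / "manifest.csv"
    fields = ["filename", "experiment", "label", "tilt_magnitude",
              "orientation_sd", "contrast", "nondominant_contrast",
              "noise_sd", "color_intensity", "color_spread", "seed"]
    with open(manifest, "w", newline="") as fh:
        w = csv.DictWriter(fh, fieldnames=fields)
        w.writeheader()
        for i, s in enumerate(samples):
            fname = f"img_{i:05d}.png"
            arr = np.round(s.pixels * 255).astype(np.uint8)
            Image.fromarray(arr).save(outdir / fname)
            row = {k: v for k, v in asdict(s.params).items() if k in fields}
            row["filename"] = fname
            w.writerow(row)
    return manifest
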