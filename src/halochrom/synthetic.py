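"""Synthetic data generators for the sensor-film analysis pipeline.

The experimental raw data (film videos and per-film response times) are not
publicly deposited, so every pipeline stage is exercised on synthetic data
with the same statistical structure:

* per-channel color kinetics that follow a logistic (sigmoidal) transition
  from a baseline color to a pH-dependent plateau color, with Gaussian
  frame noise — mimicking the hue/saturation trajectories of a film dipped
  into a buffer;
* a formulation -> response-time dataset on the full factorial design
  (3 PEG levels x 3 BTB levels x 5 pH levels x 4 replicates = 180 records);
* small film images with a rectangular foreground mask, for testing the
  image-side feature extraction.

Defaults encode the qualitative behavior of the films: yellow plateau at
pH 6, green at pH 7, blue at pH 8-10 with hue increasing from 8 to 10, and
transition midpoints that are fastest at pH 6, slowest at pH 7, and fastest
among the alkaline buffers at pH 8.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from halochrom.color import CHANNEL_BOUNDS, CHANNELS, FilmImage, convert_color_spaces

# Baseline film color (acidic yellow form of bromothymol blue in the dry film)
# and plateau colors after equilibration in each buffer.
_BASELINE_RGB = (0.86, 0.80, 0.25)
_PLATEAU_RGB: dict[int, tuple[float, float, float]] = {
    6: (0.90, 0.84, 0.28),   # yellow: visually near-unchanged at pH 6
    7: (0.35, 0.68, 0.33),   # green
    8: (0.22, 0.45, 0.74),   # blue, hue increasing with pH ...
    9: (0.19, 0.38, 0.79),
    10: (0.15, 0.30, 0.85),  # ... highest hue at pH 10
}

# Transition midpoints (s): fastest at pH 6, slowest at pH 7, fastest
# alkaline response at pH 8, slightly slower again toward pH 10.
_MIDPOINT_S: dict[int, float] = {6: 120.0, 7: 260.0, 8: 160.0, 9: 190.0, 10: 220.0}

# Additive per-pH response-time offsets (s) for the formulation dataset,
# reproducing the same ordering on the response-time scale.
DEFAULT_PH_EFFECT: dict[int, float] = {6: -60.0, 7: 60.0, 8: -20.0, 9: 0.0, 10: 20.0}


@dataclass
class KineticsConfig:
    """Parameters of one logistic color-transition experiment.

    Each channel value follows
    ``v(t) = v0 + (vinf - v0) / (1 + exp(-r (t - t0))) + eps``,
    ``eps ~ N(0, noise_sd^2)``, sampled at ``frame_rate`` frames per second
    for ``duration_s`` seconds and clipped to the channel's physical range.
    """

    baseline_features: Mapping[str, float]
    plateau_features: Mapping[str, float]
    transition_midpoint_s: float = 160.0
    transition_rate: float = 0.05  # 1/s
    # Frame noise on the masked-mean features. Averaging a film mask of a
    # few thousand pixels with per-pixel noise ~0.01 leaves a standard
    # error of a few 1e-4 channel units, so 5e-4 is the realistic scale;
    # per-frame noise of the order of the 0.001 slope threshold would bury
    # the steady-state criterion in noise for any detector.
    noise_sd: float = 0.0005
    frame_rate: float = 1.0
    duration_s: float = 600.0

    def validate(self) -> None:
        for name in ("baseline_features", "plateau_features"):
            vec = getattr(self, name)
            missing = [c for c in CHANNELS if c not in vec]
            if missing:
                raise ValueError(f"{name} missing channels {missing}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.transition_rate <= 0:
            raise ValueError("transition_rate must be > 0")
        if not 0 < self.transition_midpoint_s < self.duration_s:
            raise ValueError("transition_midpoint_s must lie in (0, duration_s)")
        n = self.duration_s * self.frame_rate
        if n <= 0 or abs(n - round(n)) > 1e-9:
            raise ValueError("duration_s * frame_rate must be a positive integer")

    @property
    def n_frames(self) -> int:
        return int(round(self.duration_s * self.frame_rate))


@dataclass
class DesignSpec:
    """The full factorial formulation design.

    Defaults are the study design: PEG at 6/8/10 % w/v, BTB at
    0.01/0.03/0.05 % w/v, buffers at pH 6-10, and 4 replicate films per
    (formulation, pH) cell — 20 films per formulation, 180 in total.
    """

    peg_levels: Sequence[float] = (6.0, 8.0, 10.0)
    btb_levels: Sequence[float] = (0.01, 0.03, 0.05)
    ph_levels: Sequence[int] = (6, 7, 8, 9, 10)
    replicates_per_cell: int = 4

    def validate(self) -> None:
        for name in ("peg_levels", "btb_levels", "ph_levels"):
            if len(getattr(self, name)) == 0:
                raise ValueError(f"{name} must be non-empty")
        if self.replicates_per_cell < 1:
            raise ValueError("replicates_per_cell must be >= 1")


def default_kinetics_config(ph: int = 8, **overrides) -> KineticsConfig:
    """Kinetics configuration for a film equilibrating at the given pH.

    The baseline/plateau 12-channel vectors are derived from representative
    RGB colors via :func:`halochrom.color.convert_color_spaces`; midpoints
    follow the pH ordering described in the module docstring.
    """
    if ph not in _PLATEAU_RGB:
        raise ValueError(f"ph must be one of {sorted(_PLATEAU_RGB)}, got {ph}")
    cfg = KineticsConfig(
        baseline_features=convert_color_spaces(_BASELINE_RGB),
        plateau_features=convert_color_spaces(_PLATEAU_RGB[ph]),
        transition_midpoint_s=_MIDPOINT_S[ph],
    )
    for key, value in overrides.items():
        if not hasattr(cfg, key):
            raise ValueError(f"unknown KineticsConfig field {key!r}")
        setattr(cfg, key, value)
    return cfg


def generate_color_kinetics(config: KineticsConfig, seed: int) -> pd.DataFrame:
    """Simulate one film's 12-channel color time series.

    Returns the standard series schema (``frame``, ``t_s``, 12 channels).
    Identical seeds give bit-identical output.
    """
    config.validate()
    rng = np.random.default_rng(seed)
    t = np.arange(config.n_frames) / config.frame_rate
    df = pd.DataFrame({"frame": np.arange(1, config.n_frames + 1), "t_s": t})
    for ch in CHANNELS:
        v0 = float(config.baseline_features[ch])
        vinf = float(config.plateau_features[ch])
        curve = v0 + (vinf - v0) / (
            1.0 + np.exp(-config.transition_rate * (t - config.transition_midpoint_s))
        )
        if config.noise_sd > 0:
            curve = curve + rng.normal(0.0, config.noise_sd, size=t.size)
            lo, hi = CHANNEL_BOUNDS[ch]
            curve = np.clip(curve, lo, hi)
        df[ch] = curve
    return df


def generate_formulation_dataset(
    design: DesignSpec,
    surface: Callable[[float, float], float],
    ph_effect: Mapping[int, float] | Callable[[int], float] | None = None,
    noise_sd: float = 111.5,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate the formulation -> response-time dataset.

    One record per (PEG, BTB, pH, replicate):
    ``y = surface(x1, x2) + ph_effect(pH) + N(0, noise_sd^2)`` seconds,
    floored at 1 s so response times stay physical. The full study design
    yields 180 records. Raises ``ValueError`` if the surface is undefined
    (non-finite) at any design point.

    The default ``noise_sd`` is calibrated so that the within-cell variance
    of a formulation cell (pH-effect spread ~1600 s^2 plus replicate noise)
    reproduces the study's within mean square of ~14,043 s^2:
    sqrt(14043 - 1600) ~ 111.5 s.
    """
    design.validate()
    if ph_effect is None:
        ph_effect = DEFAULT_PH_EFFECT
    if isinstance(ph_effect, Mapping):
        eff = ph_effect
        ph_effect = lambda ph: eff[ph]  # noqa: E731
    rng = np.random.default_rng(seed)
    records = []
    for x1 in design.peg_levels:
        for x2 in design.btb_levels:
            base = float(surface(x1, x2))
            if not np.isfinite(base):
                raise ValueError(f"surface undefined at design point ({x1}, {x2})")
            for ph in design.ph_levels:
                mu = base + float(ph_effect(ph))
                y = mu + rng.normal(0.0, noise_sd, size=design.replicates_per_cell)
                y = np.maximum(y, 1.0)  # response times are physical durations
                for rep, yi in enumerate(y, start=1):
                    records.append(
                        {
                            "peg_pct": float(x1),
                            "btb_pct": float(x2),
                            "ph": ph,
                            "replicate": rep,
                            "response_time_s": float(yi),
                        }
                    )
    return pd.DataFrame.from_records(records)


def generate_film_image(
    mean_rgb: Sequence[float],
    shape: tuple[int, int] = (64, 64),
    noise_sd: float = 0.0,
    seed: int = 0,
) -> FilmImage:
    """Render a flat-color film patch on a dark background.

    The foreground (film) is a centered rectangle covering ~75% of each
    side; pixel noise is i.i.d. Gaussian, clipped to [0, 1] per channel.
    """
    rgb = np.asarray(mean_rgb, dtype=float)
    if rgb.shape != (3,) or rgb.min() < 0 or rgb.max() > 1:
        raise ValueError("mean_rgb must be three components in [0, 1]")
    h, w = shape
    if h <= 0 or w <= 0:
        raise ValueError("shape must be positive")
    rng = np.random.default_rng(seed)
    pixels = np.full((h, w, 3), 0.05)
    mask = np.zeros((h, w), dtype=bool)
    mask[h // 8 : h - h // 8, w // 8 : w - w // 8] = True
    pixels[mask] = rgb
    if noise_sd > 0:
        pixels = np.clip(pixels + rng.normal(0.0, noise_sd, size=pixels.shape), 0.0, 1.0)
    return FilmImage(pixels=pixels, mask=mask)


def write_series_csv(series: pd.DataFrame, path) -> None:
    """Write a color time series in the standard CSV schema."""
    series.to_csv(path, index=False)


def read_series_csv(path) -> pd.DataFrame:
    """Read a color time series written by :func:`write_series_csv`."""
    return pd.read_csv(path)
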