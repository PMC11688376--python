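"""Synthetic gestational-sac fixtures with known ground-truth geometry.

The generator emulates the post-crop 512x512 view of an early-pregnancy
scan: the sac is a rotated (optionally irregular) ellipse, the mask is
strictly binary (pixel centers inside the curve), and the pseudo-ultrasound
rendering shows a dark anechoic lumen, a bright rim, and a speckled
background.  Ground truth is analytic: for a regular ellipse with semi-axes
``a >= b`` (pixels) and isotropic spacing ``s`` (cm/px) the minimum-area
rectangle has sides ``2a x 2b``, hence ``DM = 2*a*s``, ``Dm = 2*b*s`` and
the gestational age follows the Hellman formula.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .biometry import PixelSpacing, estimate_gw

__all__ = ["SacParams", "SyntheticCase", "generate_sac", "render_us_image",
           "generate_dataset", "IMAGE_SIZE"]

IMAGE_SIZE = 512

# GA range of the emulated cohort, weeks.
GA_RANGE = (4.0, 10.0)
# Invert the Hellman formula: mean sac diameter implied by a GA.
def msd_cm_for_gw(gw_weeks: float) -> float:
    """Mean sac diameter (cm) whose Hellman estimate equals ``gw_weeks``."""
    return 0.7 * gw_weeks - 2.543


@dataclass(frozen=True)
class SacParams:
    """Geometry and acquisition parameters of one synthetic sac."""

    a: float                       # semi-major axis, px
    b: float                       # semi-minor axis, px
    angle: float = 0.0             # degrees, major axis vs column axis
    center: tuple[float, float] = (IMAGE_SIZE / 2, IMAGE_SIZE / 2)  # (row, col)
    irregularity: float = 0.0      # radial perturbation amplitude, [0, 0.3]
    spacing: PixelSpacing = field(default_factory=lambda: PixelSpacing.isotropic(0.01))
    label: str = "normal"          # normal | abnormal
    modality: str = "TAS"          # TAS | TVS
    size: int = IMAGE_SIZE

    def __post_init__(self) -> None:
        if not (self.a >= self.b > 0):
            raise ValueError(f"need a >= b > 0, got a={self.a}, b={self.b}")
        if not (0.0 <= self.irregularity <= 0.3):
            raise ValueError("irregularity must lie in [0, 0.3]")
        if self.label not in ("normal", "abnormal"):
            raise ValueError(f"unknown label {self.label!r}")
        if self.modality not in ("TAS", "TVS"):
            raise ValueError(f"unknown modality {self.modality!r}")
        # The rotated (possibly dilated) ellipse must fit inside the image.
        reach = self.a * (1.0 + self.irregularity) + 2.0
        r, c = self.center
        if (r - reach < 0 or c - reach < 0
                or r + reach > self.size - 1 or c + reach > self.size - 1):
            raise ValueError("ellipse (with perturbation margin) exceeds image bounds")


@dataclass(frozen=True)
class SyntheticCase:
    """A generated sac: mask, optional rendering, and analytic truth."""

    mask: np.ndarray
    params: SacParams
    truth: dict                   # DM_cm, Dm_cm, GW_weeks (unperturbed ellipse)
    image: np.ndarray | None = None

    @property
    def metadata(self) -> dict:
        p = self.params
        return {
            "a_px": p.a, "b_px": p.b, "angle_deg": p.angle,
            "center": list(p.center), "irregularity": p.irregularity,
            "row_spacing_mm": p.spacing.row_spacing * 10.0,
            "col_spacing_mm": p.spacing.col_spacing * 10.0,
            "label": p.label, "modality": p.modality,
            **self.truth,
        }

    def metadata_json(self) -> str:
        return json.dumps(self.metadata, indent=1)


def _radial_profile(phi: np.ndarray, amplitude: float,
                    rng: np.random.Generator) -> np.ndarray:
    """Low-frequency radial perturbation rho(phi) in [1-A, 1+A]."""
    if amplitude == 0.0:
        return np.ones_like(phi)
    harmonics = rng.integers(2, 5, size=2)
    phases = rng.uniform(0, 2 * math.pi, size=2)
    weights = rng.dirichlet(np.ones(2))
    wave = sum(w * np.cos(h * phi + p)
               for w, h, p in zip(weights, harmonics, phases))
    return 1.0 + amplitude * wave


def generate_sac(params: SacParams, seed: int = 0) -> SyntheticCase:
    """Rasterize a (possibly perturbed) rotated ellipse into a binary mask.

    A pixel is foreground iff its center lies inside the perturbed ellipse
    ``(x'/a)^2 + (y'/b)^2 <= rho(phi)^2`` in the rotated frame -- no
    anti-aliasing, so the mask is strictly binary.  Truth geometry is always
    reported for the unperturbed ellipse.
    """
    rng = np.random.default_rng(seed)
    size = params.size
    rows, cols = np.mgrid[0:size, 0:size].astype(np.float64)
    dr = rows - params.center[0]
    dc = cols - params.center[1]
    theta = math.radians(params.angle)
    # Rotate into the ellipse frame: u along the major axis (column-ish).
    u = dc * math.cos(theta) + dr * math.sin(theta)
    v = -dc * math.sin(theta) + dr * math.cos(theta)
    nr = np.hypot(u / params.a, v / params.b)
    phi = np.arctan2(v / params.b, u / params.a)
    rho = _radial_profile(phi, params.irregularity, rng)
    mask = (nr <= rho).astype(np.uint8)

    s_row = params.spacing.row_spacing
    s_col = params.spacing.col_spacing
    # Effective spacing along each principal axis (exact when isotropic).
    s_major = math.hypot(s_col * math.cos(theta), s_row * math.sin(theta))
    s_minor = math.hypot(s_col * math.sin(theta), s_row * math.cos(theta))
    DM = 2.0 * params.a * s_major
    Dm = 2.0 * params.b * s_minor
    DM, Dm = max(DM, Dm), min(DM, Dm)
    truth = {"DM_cm": DM, "Dm_cm": Dm, "GW_weeks": estimate_gw(DM, Dm)}
    return SyntheticCase(mask=mask, params=params, truth=truth)


def render_us_image(case: SyntheticCase, noise_seed: int = 0,
                    noise_amplitude: float = 0.25,
                    rim_width_px: float = 3.0) -> np.ndarray:
    """Pseudo-ultrasound rendering: dark lumen, bright rim, speckled background.

    Intensities are float32 in [0, 1].  Speckle is multiplicative
    (gamma-distributed, mean 1); with ``noise_amplitude=0`` the image is
    piecewise constant with exactly three levels.
    """
    from scipy import ndimage

    rng = np.random.default_rng(noise_seed)
    mask = case.mask.astype(bool)
    # Rim: background band adjacent to the sac (decidual reaction).
    grown = ndimage.binary_dilation(mask, iterations=int(round(rim_width_px)))
    rim = grown & ~mask

    img = np.full(mask.shape, 0.55, dtype=np.float64)  # echogenic background
    img[rim] = 0.85                                    # bright rim
    img[mask] = 0.12                                   # anechoic lumen
    if noise_amplitude > 0:
        k = 1.0 / noise_amplitude ** 2  # shape: var of speckle = amplitude^2
        speckle = rng.gamma(shape=k, scale=1.0 / k, size=img.shape)
        img = img * speckle
    return np.clip(img, 0.0, 1.0).astype(np.float32)


def generate_dataset(n: int, seed: int = 0, ga_range: tuple = GA_RANGE,
                     class_mix: float = 274 / 500, modality_mix: float = 305 / 500,
                     render: bool = False,
                     size: int = IMAGE_SIZE) -> tuple[list[SyntheticCase], pd.DataFrame]:
    """Generate ``n`` cases spanning a GA range, with a normal/abnormal mix.

    Sac sizes are drawn by inverting the Hellman formula so the implied GW is
    uniform over ``ga_range``; pixel spacing is isotropic in the 0.1-0.5
    mm/px range, chosen finer for small sacs (as a sonographer would zoom).
    Abnormal cases receive a positive boundary irregularity.  Returns the
    cases plus a manifest with per-case analytic truth.

    ``class_mix`` / ``modality_mix`` are the normal and TAS fractions
    (defaults mirror a 274/226 normal/abnormal, 305/195 TAS/TVS cohort).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    lo, hi = ga_range
    if not (GA_RANGE[0] <= lo < hi <= GA_RANGE[1] + 1e-9):
        raise ValueError(f"ga_range must be within {GA_RANGE}")
    if not (0.0 <= class_mix <= 1.0 and 0.0 <= modality_mix <= 1.0):
        raise ValueError("infeasible class/modality mix")

    rng = np.random.default_rng(seed)
    n_normal = int(round(n * class_mix))
    labels = ["normal"] * n_normal + ["abnormal"] * (n - n_normal)
    n_tas = int(round(n * modality_mix))
    modalities = ["TAS"] * n_tas + ["TVS"] * (n - n_tas)
    rng.shuffle(labels)
    rng.shuffle(modalities)

    cases: list[SyntheticCase] = []
    records = []
    for i in range(n):
        gw = rng.uniform(lo, hi)
        msd = msd_cm_for_gw(gw)                  # DM/2 + Dm/2, cm
        ratio = rng.uniform(0.6, 1.0)            # b/a aspect
        # Spacing: aim for a sac diameter of roughly half the frame, clipped
        # to the 0.1-0.5 mm/px acquisition range.
        s = float(np.clip(msd / (0.55 * size) * rng.uniform(0.8, 1.2),
                          0.01, 0.05))
        a = msd / (s * (1.0 + ratio))
        b = a * ratio
        angle = rng.uniform(0.0, 180.0)
        irregularity = rng.uniform(0.05, 0.25) if labels[i] == "abnormal" else 0.0
        margin = a * (1.0 + irregularity) + 3.0
        center = (rng.uniform(margin, size - 1 - margin),
                  rng.uniform(margin, size - 1 - margin))
        params = SacParams(a=a, b=b, angle=angle, center=center,
                           irregularity=irregularity,
                           spacing=PixelSpacing.isotropic(s),
                           label=labels[i], modality=modalities[i], size=size)
        case = generate_sac(params, seed=int(rng.integers(0, 2**31 - 1)))
        if render:
            case = SyntheticCase(
                mask=case.mask, params=case.params, truth=case.truth,
                image=render_us_image(case,
                                      noise_seed=int(rng.integers(0, 2**31 - 1))))
        cases.append(case)
        records.append({"case_id": f"case_{i:04d}", "a_px": a, "b_px": b,
                        "angle_deg": angle, "spacing_cm": s,
                        "irregularity": irregularity,
                        **case.truth, "label": labels[i],
                        "modality": modalities[i]})
    manifest = pd.DataFrame.from_records(records)
    return cases, manifest
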