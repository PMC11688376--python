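import numpy as np
import pytest


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)


def random_blob(size: int, seed: int) -> np.ndarray:
    """A random simply connected (star-shaped) binary blob for tracing tests."""
    from sacmetry.biometry import PixelSpacing
    from sacmetry.synth import SacParams, generate_sac

    g = np.random.default_rng(seed)
    a = g.uniform(size * 0.12, size * 0.3)
    b = a * g.uniform(0.5, 1.0)
    irregularity = g.uniform(0.0, 0.3)
    margin = a * (1 + irregularity) + 3
    params = SacParams(
        a=a, b=b, angle=g.uniform(0, 180),
        center=(g.uniform(margin, size - 1 - margin),
                g.uniform(margin, size - 1 - margin)),
        irregularity=irregularity,
        spacing=PixelSpacing.isotropic(0.01),
        size=size)
    return generate_sac(params, seed=seed).mask


def boundary_oracle(mask: np.ndarray) -> set:
    """Foreground pixels with at least one background (or border) 8-neighbor."""
    from scipy import ndimage

    interior = ndimage.binary_erosion(mask.astype(bool),
                                      structure=np.ones((3, 3)),
                                      border_value=0)
    return set(map(tuple, np.argwhere(mask.astype(bool) & ~interior)))


def sweep_min_area(points: np.ndarray, step_deg: float = 0.01) -> float:
    """Dense angle-sweep oracle for the minimum enclosing-rectangle area."""
    thetas = np.deg2rad(np.arange(0.0, 180.0, step_deg))
    dirs_u = np.stack([np.cos(thetas), np.sin(thetas)])        # (2, K)
    dirs_v = np.stack([-np.sin(thetas), np.cos(thetas)])
    pu = points @ dirs_u
    pv = points @ dirs_v
    areas = (pu.max(0) - pu.min(0)) * (pv.max(0) - pv.min(0))
    return float(areas.min())
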