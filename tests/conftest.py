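"""Shared fixtures: small seeded bead images and synthetic scenes."""

from __future__ import annotations

import numpy as np
import pytest

from mechphen.piv import BeadImage
from mechphen.synth import _render_spots


def render_bead_pair(
    seed: int,
    shift_px: tuple[float, float] = (0.0, 0.0),
    n: int = 128,
    n_beads: int | None = None,
    noise_sd: float = 0.0,
    pixel_size_um: float = 1.0,
    displace=None,
) -> tuple[BeadImage, BeadImage]:
    """Reference/deformed bead images with a uniform shift or a callable
    per-bead displacement field ``displace(ys, xs) -> (dy, dx)``."""
    rng = np.random.default_rng(seed)
    if n_beads is None:
        n_beads = int(0.02 * n * n)
    ys = rng.uniform(5, n - 5, n_beads)
    xs = rng.uniform(5, n - 5, n_beads)
    amp = rng.uniform(0.6, 1.0, n_beads)
    if displace is not None:
        dy, dx = displace(ys, xs)
    else:
        dy, dx = shift_px
    ref = _render_spots(n, n, ys, xs, amp, 1.5)
    de = _render_spots(n, n, ys + dy, xs + dx, amp, 1.5)
    if noise_sd > 0:
        ref = np.clip(ref + rng.normal(0, noise_sd, ref.shape), 0, None)
        de = np.clip(de + rng.normal(0, noise_sd, de.shape), 0, None)
    return BeadImage(ref, pixel_size_um), BeadImage(de, pixel_size_um)


@pytest.fixture
def bead_pair_shift3():
    """Bead pair with an exact 3 px shift along x."""
    return render_bead_pair(seed=7, shift_px=(0.0, 3.0))
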