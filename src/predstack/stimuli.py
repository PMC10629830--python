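"""Parametric probe stimuli: drifting gratings, plaids, binary noise, blanks.

All stimuli are (y, x, t) tensors expressed in the same dimensionless
luminance units as the normalized training clips: a gray background is 0
and gratings swing to +/- their amplitude (default 3) around it. Time is
sampled at the training frame interval, 40 ms/frame, so temporal frequency
in Hz maps to ``tf * 0.04`` cycles per frame.

Orientation ``theta`` is the stripe orientation; the direction of motion is
perpendicular to it. :func:`grating_for_direction` converts a motion
direction (the quantity tuning curves are indexed by, over 0-360 degrees)
into grating parameters.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "FRAME_DT",
    "GratingParams",
    "PlaidParams",
    "make_grating",
    "grating_for_direction",
    "make_plaid",
    "make_binary_noise",
    "make_blank",
]

FRAME_DT = 0.04  # seconds per frame (25 frames/s)


@dataclass(frozen=True)
class GratingParams:
    """Full-field drifting sinusoidal grating.

    orientation : stripe orientation theta in degrees (0 = vertical
        stripes varying along x); spatial_frequency in cycles/px;
        temporal_frequency in Hz (40 ms frames); amplitude in normalized
        luminance units; phase in radians.
    """

    orientation: float
    spatial_frequency: float
    temporal_frequency: float
    amplitude: float = 3.0
    phase: float = 0.0
    size: int = 64
    duration: int = 40
    frame_dt: float = FRAME_DT

    def __post_init__(self):
        if self.amplitude <= 0:
            raise ValueError("amplitude must be positive")
        if not 0 <= self.orientation < 360:
            raise ValueError("orientation must lie in [0, 360)")


@dataclass(frozen=True)
class PlaidParams:
    """Two superimposed half-amplitude gratings drifting at +/- half the
    component separation around the pattern direction."""

    pattern_direction: float
    component_separation: float
    spatial_frequency: float
    temporal_frequency: float
    component_amplitude: float = 1.5
    size: int = 64
    duration: int = 40
    mask_radius: float | None = None
    frame_dt: float = FRAME_DT

    @property
    def component_directions(self):
        half = self.component_separation / 2.0
        return (self.pattern_direction - half, self.pattern_direction + half)


def make_grating(p: GratingParams):
    """value(y, x, t) = A sin(2 pi sf (x cos th + y sin th) - 2 pi tf t dt + phase)."""
    if p.spatial_frequency > 0.5:
        raise ValueError(
            f"spatial frequency {p.spatial_frequency} cycles/px exceeds Nyquist (0.5)"
        )
    th = np.deg2rad(p.orientation)
    y = np.arange(p.size)[:, None, None]
    x = np.arange(p.size)[None, :, None]
    t = np.arange(p.duration)[None, None, :]
    spatial = p.spatial_frequency * (x * np.cos(th) + y * np.sin(th))
    temporal = p.temporal_frequency * t * p.frame_dt
    return p.amplitude * np.sin(2 * np.pi * (spatial - temporal) + p.phase)


def grating_for_direction(direction_deg, sf, tf, **kwargs):
    """Grating whose motion direction (degrees, 0-360) is ``direction_deg``.

    Motion is perpendicular to the stripes: orientation = direction - 90
    (mod 360). With the sign conventions of :func:`make_grating`, positive
    temporal frequency moves the pattern along +(cos th, sin th), i.e.
    toward increasing x for direction 90... the returned params place the
    drift along the requested compass direction on the (x right, y down)
    pixel grid.
    """
    theta = (direction_deg - 90.0) % 360.0
    return GratingParams(orientation=theta, spatial_frequency=sf,
                         temporal_frequency=tf, **kwargs)


def make_plaid(p: PlaidParams):
    """Elementwise sum of the two component gratings, optionally masked."""
    d1, d2 = p.component_directions
    kwargs = dict(sf=p.spatial_frequency, tf=p.temporal_frequency,
                  amplitude=p.component_amplitude, size=p.size,
                  duration=p.duration, frame_dt=p.frame_dt)
    g1 = make_grating(grating_for_direction(d1 % 360.0, **kwargs))
    g2 = make_grating(grating_for_direction(d2 % 360.0, **kwargs))
    plaid = g1 + g2
    if p.mask_radius is not None:
        c = (p.size - 1) / 2.0
        yy, xx = np.mgrid[0 : p.size, 0 : p.size]
        mask = (yy - c) ** 2 + (xx - c) ** 2 <= p.mask_radius ** 2
        plaid = plaid * mask[:, :, None]
    return plaid


def make_binary_noise(n_samples, size, depth, amplitude=3.0, seed=0):
    """i.i.d. equiprobable +/-amplitude pixels, (n, y, x, t)."""
    rng = np.random.default_rng(seed)
    signs = rng.integers(0, 2, size=(n_samples, size, size, depth)) * 2 - 1
    return amplitude * signs.astype(float)


def make_blank(size, duration):
    """Uniform gray (0) stimulus."""
    return np.zeros((size, size, duration))
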