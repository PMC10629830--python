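"""Movie ingestion, augmentation, and synthetic training footage.

Training material is handled as short fixed-length *clips*: grayscale
(y, x, t) tensors, each normalized to zero mean and unit variance on its
own. The default clip format is 181x181 pixels by 20 frames (800 ms at
25 frames/s); the miniature configurations in the tests use 64x64.

Because the wildlife footage the model was originally trained on cannot be
redistributed, :func:`synth_movies` generates movies with the statistics
that matter for one-step prediction: spatially correlated (approximately
1/f-amplitude-spectrum) random textures undergoing rigid translation at a
per-clip velocity, with a share of still and horizontally panning clips.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Clip",
    "ClipSet",
    "DegenerateClipError",
    "normalize_clip",
    "preprocess_video",
    "pan_augment",
    "frame_shuffle",
    "synth_movies",
    "split_train_validation",
]

DEFAULT_FRAME_RATE = 25.0


class DegenerateClipError(ValueError):
    """A clip with (near-)zero variance cannot be normalized."""


@dataclass
class Clip:
    """One grayscale movie clip, axes (y, x, t)."""

    data: np.ndarray
    frame_rate: float = DEFAULT_FRAME_RATE
    normalized: bool = False
    meta: dict = field(default_factory=dict)

    @property
    def n_frames(self):
        return self.data.shape[2]


@dataclass
class ClipSet:
    """A list of clips with provenance and an (optional) train/val split."""

    clips: list
    provenance: str = "natural"
    meta: dict = field(default_factory=dict)

    def __len__(self):
        return len(self.clips)

    def __iter__(self):
        return iter(self.clips)

    def __getitem__(self, i):
        return self.clips[i]

    def to_array(self):
        """Stack into a training array (n, y, x, t, 1)."""
        return np.stack([c.data for c in self.clips])[..., None]

    def subset(self, split):
        return ClipSet(
            [c for c in self.clips if c.meta.get("split") == split],
            provenance=self.provenance,
            meta=dict(self.meta),
        )


def normalize_clip(x, tol=1e-12):
    """Subtract the clip's own mean and divide by its standard deviation."""
    x = np.asarray(x, dtype=float)
    sd = x.std()
    if sd < tol:
        raise DegenerateClipError("zero-variance clip cannot be normalized")
    return (x - x.mean()) / sd


def _center_crop_square(frame):
    h, w = frame.shape
    side = min(h, w)
    top = (h - side) // 2
    left = (w - side) // 2
    return frame[top : top + side, left : left + side]


def preprocess_video(frames, target_side=181, clip_len=20,
                     frame_rate=DEFAULT_FRAME_RATE):
    """Crop, downsample, cut, and normalize a raw frame sequence.

    Parameters
    ----------
    frames : ndarray (n_frames, h, w) or iterable of 2D grayscale frames.
    target_side : output resolution (square, bilinear downsampling).
    clip_len : frames per clip; the trailing remainder is dropped.

    Returns
    -------
    ClipSet of normalized ``target_side x target_side x clip_len`` clips.
    Constant (zero-variance) clips are rejected and reported in
    ``clipset.meta['rejected']``.
    """
    from skimage.transform import resize

    frames = [np.asarray(f, dtype=float) for f in frames]
    if clip_len < 2:
        raise ValueError("clip_len must be at least 2")
    if not frames:
        raise ValueError("no frames provided")
    shape0 = frames[0].shape
    if any(f.shape != shape0 for f in frames):
        raise ValueError("all frames must share one resolution")
    proc = []
    for f in frames:
        f = _center_crop_square(f)
        if f.shape[0] != target_side:
            f = resize(f, (target_side, target_side), order=1,
                       anti_aliasing=False, preserve_range=True)
        proc.append(f)
    n_clips = len(proc) // clip_len
    clips, rejected = [], []
    for i in range(n_clips):
        block = np.stack(proc[i * clip_len : (i + 1) * clip_len], axis=2)
        try:
            data = normalize_clip(block)
        except DegenerateClipError:
            rejected.append({"clip_index": i, "reason": "zero variance"})
            continue
        clips.append(Clip(data=data, frame_rate=frame_rate, normalized=True,
                          meta={"source_clip": i}))
    return ClipSet(clips, provenance="natural", meta={"rejected": rejected})


def pan_augment(clipset: ClipSet, shifts_px=(1, -1, 2, -2, 3, -3)):
    """Add horizontally panning copies of every clip.

    Frame t of a panned copy is the source frame t translated horizontally
    by ``shift * t`` pixels with wrap-around (circular shift); a positive
    shift moves content rightward. The output contains the originals plus
    one copy per signed shift, each re-normalized.
    """
    out = [Clip(c.data.copy(), c.frame_rate, c.normalized,
                {**c.meta, "pan": 0}) for c in clipset]
    for shift in shifts_px:
        for c in clipset:
            h, w, t = c.data.shape
            if abs(shift) * t >= w:
                raise ValueError(
                    f"cumulative shift {abs(shift) * t} px exceeds frame width {w}"
                )
            panned = np.empty_like(c.data)
            for ti in range(t):
                panned[:, :, ti] = np.roll(c.data[:, :, ti], shift * ti, axis=1)
            if shift != 0:
                panned = normalize_clip(panned)
            out.append(Clip(panned, c.frame_rate, True, {**c.meta, "pan": shift}))
    return ClipSet(out, provenance="panned", meta=dict(clipset.meta))


def frame_shuffle(clipset: ClipSet, seed=0):
    """Uniformly permute the frame order within each clip (content preserved)."""
    rng = np.random.default_rng(seed)
    out = []
    for c in clipset:
        perm = rng.permutation(c.n_frames)
        out.append(Clip(c.data[:, :, perm], c.frame_rate, c.normalized,
                        {**c.meta, "frame_perm": perm}))
    return ClipSet(out, provenance="frame_shuffled", meta=dict(clipset.meta))


def _power_law_texture(side, exponent, rng):
    """Periodic random-phase texture with amplitude spectrum ~ f^-exponent."""
    white = rng.standard_normal((side, side))
    spec = np.fft.fft2(white)
    fy = np.fft.fftfreq(side)[:, None]
    fx = np.fft.fftfreq(side)[None, :]
    f = np.hypot(fy, fx)
    f[0, 0] = np.inf  # kill DC
    spec = spec * f ** (-exponent)
    tex = np.fft.ifft2(spec).real
    return tex


def _fourier_translate(tex_fft, fy, fx, dy, dx):
    ramp = np.exp(-2j * np.pi * (fy * dy + fx * dx))
    return np.fft.ifft2(tex_fft * ramp).real


def synth_movies(
    n_clips,
    velocity_range=3.0,
    spectrum_exponent=1.0,
    seed=0,
    side=181,
    clip_len=20,
    frac_static=0.2,
    frac_pan=0.3,
    velocities=None,
    frame_rate=DEFAULT_FRAME_RATE,
):
    """Synthetic translating-texture movies emulating filmed natural footage.

    Each clip is an independent periodic random-phase texture whose radial
    amplitude spectrum falls as ``f**-spectrum_exponent`` (power slope
    ``-2 * spectrum_exponent``), rigidly translated at a per-clip constant
    velocity (wrap-around boundaries, subpixel Fourier translation). By
    default 20% of the clips are still, 30% pan horizontally only, and the
    rest translate in a uniformly random direction with per-component speed
    up to ``velocity_range`` px/frame — mimicking footage shot with still,
    panning, and freely moving cameras.

    ``velocities``: optional (n_clips, 2) array of (vy, vx) overriding the
    random draw. The per-clip velocity is stored in ``clip.meta``.
    """
    rng = np.random.default_rng(seed)
    clips = []
    for i in range(n_clips):
        if velocities is not None:
            vy, vx = velocities[i]
        else:
            kind = rng.random()
            if kind < frac_static:
                vy = vx = 0.0
            elif kind < frac_static + frac_pan:
                vy = 0.0
                vx = rng.uniform(-velocity_range, velocity_range)
            else:
                vy = rng.uniform(-velocity_range, velocity_range)
                vx = rng.uniform(-velocity_range, velocity_range)
        tex = _power_law_texture(side, spectrum_exponent, rng)
        tex_fft = np.fft.fft2(tex)
        fy = np.fft.fftfreq(side)[:, None]
        fx = np.fft.fftfreq(side)[None, :]
        frames = np.empty((side, side, clip_len))
        for t in range(clip_len):
            if vy == 0.0 and vx == 0.0:
                frames[:, :, t] = tex
            else:
                frames[:, :, t] = _fourier_translate(tex_fft, fy, fx, vy * t, vx * t)
        clips.append(
            Clip(
                normalize_clip(frames),
                frame_rate=frame_rate,
                normalized=True,
                meta={"velocity": (float(vy), float(vx)), "clip_index": i},
            )
        )
    return ClipSet(clips, provenance="synthetic",
                   meta={"seed": seed, "spectrum_exponent": spectrum_exponent})


def split_train_validation(clipset: ClipSet, val_fraction=0.1, seed=0):
    """Assign a disjoint train/validation split at clip granularity (90/10)."""
    rng = np.random.default_rng(seed)
    n = len(clipset)
    n_val = max(1, int(round(val_fraction * n))) if n > 1 else 0
    val_idx = set(rng.choice(n, size=n_val, replace=False).tolist())
    for i, c in enumerate(clipset):
        c.meta["split"] = "validation" if i in val_idx else "train"
    return clipset
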