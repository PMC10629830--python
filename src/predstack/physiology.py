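"""In-silico electrophysiology for model units.

Units are probed exactly as an electrophysiologist would probe neurons:

* linear receptive fields (RFs) — read directly from the input kernels for
  stack 1, estimated by reverse correlation to binary noise for deeper
  stacks;
* 2D Gabor fits to the most recent time-step of the RF (putative simple
  cells are those with pixel-wise fit correlation > 0.4);
* drifting-grating tuning — optimal grating search, circular variance,
  orientation bandwidth, modulation ratio (F1/F0), and three direction
  selectivity indices;
* drifting-plaid tuning with pattern/component partial-correlation
  classification.

A *convolutional unit* is one learned kernel replicated over space; its
"response" is the activity of the spatially central copy. Probe stimuli
are cropped to the unit's spatiotemporal extent, which makes the central
copy the only one and keeps deep-stack protocols tractable; full-field
drifting stimuli make the position immaterial up to phase.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .model import HierarchicalModel, receptive_extent
from .stimuli import (
    FRAME_DT,
    GratingParams,
    PlaidParams,
    grating_for_direction,
    make_blank,
    make_binary_noise,
    make_grating,
    make_plaid,
)

__all__ = [
    "ReceptiveField",
    "GaborFit",
    "TuningResult",
    "PlaidResult",
    "central_responses",
    "rf_from_weights",
    "rf_by_reverse_correlation",
    "gabor_image",
    "fit_gabor",
    "rf_size_and_polarity",
    "find_optimal_gratings",
    "unit_exclusion",
    "circular_variance",
    "orientation_bandwidth",
    "modulation_ratio",
    "direction_selectivity",
    "classify_unit",
    "plaid_analysis",
    "characterize_stack",
]

DEFAULT_DIRECTIONS = np.arange(0.0, 360.0, 5.0)
DEFAULT_SFS = np.logspace(np.log10(0.02), np.log10(0.4), 8)
# capped at 7.5 Hz (3.3 samples/cycle at 25 frames/s): higher values
# approach the temporal Nyquist rate, where a "drifting" grating degenerates
# into counterphase flicker and every unit aliases onto the same response
DEFAULT_TFS = np.array([0.625, 1.25, 2.5, 5.0, 7.5])
GABOR_FIT_THRESHOLD = 0.4


@dataclass
class ReceptiveField:
    """Linear RF as a (y, x, lag) tensor, most recent lag last."""

    weights: np.ndarray
    source: str
    unit_id: tuple
    defined: bool = True

    @property
    def latest(self):
        return self.weights[:, :, -1]


@dataclass
class GaborFit:
    amplitude: float
    x0: float
    y0: float
    sigma_x: float
    sigma_y: float
    theta: float
    frequency: float
    phase: float
    fit_correlation: float
    converged: bool = True


@dataclass
class TuningResult:
    optimal_grating: GratingParams
    mean_response: float
    f0: float
    f1: float
    modulation_ratio: float
    circular_variance: float
    orientation_bandwidth: float
    dsi1: float
    dsi2: float
    dsi3: float
    rp: float
    rnp: float
    rnull: float
    direction_tuning: np.ndarray = field(repr=False, default=None)
    directions: np.ndarray = field(repr=False, default=None)


@dataclass
class PlaidResult:
    directions: np.ndarray
    grating_tuning: np.ndarray
    plaid_tuning: dict  # separation -> tuning curve
    partial_r_pattern: float
    partial_r_component: float
    z_pattern: float
    z_component: float
    classification: str
    n_peaks: int


# ---------------------------------------------------------------------------
# responses


def _crop_center(stim, ey, ex):
    if stim.ndim == 3:
        sy, sx, _ = stim.shape
    else:
        _, sy, sx, _ = stim.shape
    if sy < ey or sx < ex:
        raise ValueError(
            f"stimulus ({sy}x{sx}) smaller than the receptive extent ({ey}x{ex})"
        )
    top, left = (sy - ey) // 2, (sx - ex) // 2
    if stim.ndim == 3:
        return stim[top : top + ey, left : left + ex]
    return stim[:, top : top + ey, left : left + ex]


def central_responses(model: HierarchicalModel, stack, stim, batch=256):
    """Central-unit activity traces for all units of one stack.

    ``stim`` is (y, x, t) or a batch (n, y, x, t) at the stack-1 input
    resolution (single channel). The stimulus is center-cropped to the
    spatial receptive extent of the stack, run through stacks 1..stack, and
    the hidden activity at the central spatial position is returned as
    (n, th, j) (or (th, j) for a single stimulus).
    """
    single = stim.ndim == 3
    if single:
        stim = stim[None]
    ey, ex, _ = receptive_extent(model.specs[:stack])
    u = _crop_center(stim, ey, ex)[..., None]
    h = model.forward(u, n_stacks=stack, batch=batch)
    yc, xc = h.shape[1] // 2, h.shape[2] // 2
    out = h[:, yc, xc]  # (n, th, j)
    return out[0] if single else out


# ---------------------------------------------------------------------------
# receptive fields


def rf_from_weights(model: HierarchicalModel, stack=1, unit=0):
    """The stack-1 input kernel read directly as the unit's linear RF."""
    if stack != 1:
        raise ValueError("direct-weight RFs are only defined for stack 1")
    w = model.weights[0].w[unit, 0]
    return ReceptiveField(weights=w.copy(), source="stack1_weights",
                          unit_id=(1, unit))


def rf_by_reverse_correlation(model: HierarchicalModel, stack, unit=None,
                              n_samples=100_000, amplitude=3.0, seed=0,
                              batch=2000):
    """Response-weighted average of binary noise (graded-activity STA).

    Noise is generated at the stack-1 input resolution, cropped (by
    construction, generated) at the unit's receptive extent, with temporal
    depth equal to the temporal extent so the probed unit responds exactly
    once per sample. Returns the RF of ``unit``, or a list over all units
    of the stack when ``unit`` is None. Units with an all-zero summed
    response are flagged undefined.
    """
    ey, ex, et = receptive_extent(model.specs[:stack])
    j_total = model.specs[stack - 1].conv_units
    num = np.zeros((j_total, ey, ex, et))
    denom = np.zeros(j_total)
    done = 0
    chunk_seed = seed
    while done < n_samples:
        take = min(batch, n_samples - done)
        noise = make_binary_noise(take, size=max(ey, ex), depth=et,
                                  amplitude=amplitude, seed=chunk_seed)
        chunk_seed += 1
        noise = noise[:, :ey, :ex]
        h = model.forward(noise[..., None], n_stacks=stack)
        yc, xc = h.shape[1] // 2, h.shape[2] // 2
        r = h[:, yc, xc, -1, :]  # (take, j) — single valid step by design
        num += np.einsum("nj,nyxt->jyxt", r, noise)
        denom += r.sum(axis=0)
        done += take
    rfs = []
    for j in range(j_total):
        if denom[j] <= 0:
            rfs.append(ReceptiveField(np.zeros((ey, ex, et)),
                                      "reverse_correlation", (stack, j),
                                      defined=False))
        else:
            rfs.append(ReceptiveField(num[j] / denom[j],
                                      "reverse_correlation", (stack, j)))
    return rfs if unit is None else rfs[unit]


# ---------------------------------------------------------------------------
# Gabor fitting


def gabor_image(shape, amplitude, x0, y0, sigma_x, sigma_y, theta, frequency,
                phase):
    """2D Gabor: A exp(-(x'/2sx)^2 - (y'/2sy)^2) cos(2 pi f x' + phi),

    where (x', y') rotate (x - x0, y - y0) by the orientation theta.
    """
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    xr = (xx - x0) * np.cos(theta) + (yy - y0) * np.sin(theta)
    yr = -(xx - x0) * np.sin(theta) + (yy - y0) * np.cos(theta)
    env = np.exp(-((xr / (2 * sigma_x)) ** 2) - ((yr / (2 * sigma_y)) ** 2))
    return amplitude * env * np.cos(2 * np.pi * frequency * xr + phase)


def _pearson(a, b):
    a = a.ravel() - a.mean()
    b = b.ravel() - b.mean()
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        return 0.0
    return float(a @ b / (na * nb))


def _gabor_resid_jac(shape, rf_flat):
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    yy, xx = yy.ravel(), xx.ravel()

    def resid(p):
        a, x0, y0, sx, sy, th, f, ph = p
        xr = (xx - x0) * np.cos(th) + (yy - y0) * np.sin(th)
        yr = -(xx - x0) * np.sin(th) + (yy - y0) * np.cos(th)
        env = np.exp(-((xr / (2 * sx)) ** 2) - ((yr / (2 * sy)) ** 2))
        return a * env * np.cos(2 * np.pi * f * xr + ph) - rf_flat

    def jac(p):
        a, x0, y0, sx, sy, th, f, ph = p
        ct, st = np.cos(th), np.sin(th)
        xr = (xx - x0) * ct + (yy - y0) * st
        yr = -(xx - x0) * st + (yy - y0) * ct
        env = np.exp(-((xr / (2 * sx)) ** 2) - ((yr / (2 * sy)) ** 2))
        arg = 2 * np.pi * f * xr + ph
        cosv, sinv = np.cos(arg), np.sin(arg)
        g = a * env * cosv
        dG_dxr = a * (-xr / (2 * sx ** 2)) * env * cosv - a * env * sinv * 2 * np.pi * f
        dG_dyr = a * (-yr / (2 * sy ** 2)) * env * cosv
        out = np.empty((len(xx), 8))
        out[:, 0] = env * cosv
        out[:, 1] = dG_dxr * (-ct) + dG_dyr * st
        out[:, 2] = dG_dxr * (-st) + dG_dyr * (-ct)
        out[:, 3] = g * xr ** 2 / (2 * sx ** 3)
        out[:, 4] = g * yr ** 2 / (2 * sy ** 3)
        out[:, 5] = dG_dxr * yr + dG_dyr * (-xr)
        out[:, 6] = -a * env * sinv * 2 * np.pi * xr
        out[:, 7] = -a * env * sinv
        return out

    return resid, jac


def _spectral_seed(rf_slice):
    """Dominant (frequency, orientation, phase) from the 2D spectrum peak."""
    h, w = rf_slice.shape
    spec = np.fft.fft2(rf_slice - rf_slice.mean())
    mag = np.abs(spec)
    mag[0, 0] = 0.0
    iy, ix = np.unravel_index(np.argmax(mag), mag.shape)
    fy = np.fft.fftfreq(h)[iy]
    fx = np.fft.fftfreq(w)[ix]
    f0 = float(np.hypot(fy, fx))
    th0 = float(np.arctan2(fy, fx)) % np.pi
    ph0 = float(np.angle(spec[iy, ix]))
    return f0, th0, ph0


def fit_gabor(rf_slice, extra_starts=4, max_nfev=200):
    """Least-squares Gabor fit with spectral seeding and multi-start.

    The slice (the most recent time-step of an RF) is fitted by minimizing
    the pixel-wise squared error over all eight Gabor parameters. The main
    start reads the dominant frequency, orientation and phase off the 2D
    spectrum peak; ``extra_starts`` additional orientation seeds (with low-
    and mid-frequency carriers) guard against spectral ambiguity. Returns
    the best fit with its pixel-wise Pearson correlation; if every start
    fails, ``fit_correlation`` is 0 and the fit is flagged unconverged.
    """
    rf_slice = np.asarray(rf_slice, dtype=float)
    if not np.all(np.isfinite(rf_slice)):
        raise ValueError("RF slice contains non-finite values")
    h, w = rf_slice.shape
    peak = np.unravel_index(np.argmax(np.abs(rf_slice)), rf_slice.shape)
    y0_init, x0_init = float(peak[0]), float(peak[1])
    a_init = float(rf_slice[peak]) or 1e-3
    sig_init = max(h, w) / 5.0
    f0, th0, ph0 = _spectral_seed(rf_slice)
    starts = [
        [a_init, x0_init, y0_init, sig_init, sig_init, th0, max(f0, 0.02), ph0],
        [a_init, x0_init, y0_init, sig_init, sig_init, th0, max(f0, 0.02),
         ph0 + np.pi / 2],
        # near-Gaussian start for blob-like (center-surround) slices
        [a_init, x0_init, y0_init, sig_init, sig_init, th0, 0.02, 0.0],
    ]
    for th in np.linspace(0, np.pi, extra_starts, endpoint=False):
        starts.append([a_init, x0_init, y0_init, sig_init, sig_init, th, 0.1, 0.0])
    resid, jac = _gabor_resid_jac((h, w), rf_slice.ravel())
    lb = [-np.inf, -w, -h, 0.2, 0.2, -np.inf, 0.0, -np.inf]
    ub = [np.inf, 2 * w, 2 * h, 4 * w, 4 * h, np.inf, 0.6, np.inf]
    best = None
    for p0 in starts:
        try:
            sol = least_squares(resid, p0, jac=jac, bounds=(lb, ub),
                                max_nfev=max_nfev)
        except Exception:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        return GaborFit(0, 0, 0, 1, 1, 0, 0, 0, fit_correlation=0.0,
                        converged=False)
    p = best.x
    fitted = gabor_image((h, w), *p)
    r = _pearson(fitted, rf_slice)
    theta = float(p[5]) % np.pi  # canonical orientation in [0, pi)
    return GaborFit(amplitude=float(p[0]), x0=float(p[1]), y0=float(p[2]),
                    sigma_x=float(p[3]), sigma_y=float(p[4]), theta=theta,
                    frequency=float(p[6]), phase=float(p[7]),
                    fit_correlation=r)


def rf_size_and_polarity(rf: ReceptiveField):
    """RF pixel count and polarity-switch fraction.

    RF pixels are those in the most recent time-step whose |weight| is at
    least half the maximum |weight| in that step; the switch fraction is
    the share of those pixels whose sign differs between the two most
    recent time-steps.
    """
    latest = rf.weights[:, :, -1]
    prev = rf.weights[:, :, -2]
    peak = np.abs(latest).max()
    if peak == 0:
        raise ValueError("all-zero RF slice: size/polarity undefined")
    mask = np.abs(latest) >= 0.5 * peak
    size = int(mask.sum())
    switched = np.sign(latest[mask]) != np.sign(prev[mask])
    return size, float(switched.mean())


# ---------------------------------------------------------------------------
# grating protocol


def _grating_grid_responses(model, stack, directions, sfs, tfs, duration,
                            amplitude, batch=64):
    """Time-mean central responses on the direction x sf x tf grid.

    Returns (grid, traces_shape_info) where grid is (D, S, F, J). Traces
    are not stored; they are recomputed at the optimum.
    """
    ey, ex, _ = receptive_extent(model.specs[:stack])
    size = max(ey, ex)
    j = model.specs[stack - 1].conv_units
    grid = np.empty((len(directions), len(sfs), len(tfs), j))
    stims, index = [], []
    for di, d in enumerate(directions):
        for si, sf in enumerate(sfs):
            for fi, tf in enumerate(tfs):
                stims.append(make_grating(grating_for_direction(
                    d, sf, tf, amplitude=amplitude, size=size,
                    duration=duration)))
                index.append((di, si, fi))
                if len(stims) == batch:
                    resp = central_responses(model, stack, np.stack(stims))
                    for (a, b, c), r in zip(index, resp.mean(axis=1)):
                        grid[a, b, c] = r
                    stims, index = [], []
    if stims:
        resp = central_responses(model, stack, np.stack(stims))
        for (a, b, c), r in zip(index, resp.mean(axis=1)):
            grid[a, b, c] = r
    return grid, size


def find_optimal_gratings(model, stack, directions=DEFAULT_DIRECTIONS,
                          sfs=DEFAULT_SFS, tfs=DEFAULT_TFS, duration=40,
                          amplitude=3.0):
    """Per-unit argmax of the time-mean response over the search grid.

    Ties are broken toward the lowest spatial frequency, then the lowest
    temporal frequency, then the lowest direction. Returns
    ``(params_list, mean_responses, grid)`` with grid (D, S, F, J).
    """
    grid, size = _grating_grid_responses(model, stack, directions, sfs, tfs,
                                         duration, amplitude)
    j = grid.shape[3]
    params, best_resp = [], np.empty(j)
    # order (sf, tf, direction) so the first flat argmax realizes the tie-break
    reordered = grid.transpose(1, 2, 0, 3)
    for jj in range(j):
        g = reordered[:, :, :, jj]
        flat = np.argmax(np.isclose(g, g.max(), rtol=1e-12, atol=0).ravel())
        si, fi, di = np.unravel_index(flat, g.shape)
        params.append(grating_for_direction(
            float(directions[di]), float(sfs[si]), float(tfs[fi]),
            amplitude=amplitude, size=size, duration=duration))
        best_resp[jj] = g[si, fi, di]
    return params, best_resp, grid


def unit_exclusion(mean_responses, threshold_fraction=0.01):
    """Keep flags: response at least ``threshold_fraction`` of the maximum.

    The 1% rule is applied per stack for the tuning protocol; a 0.1%
    population-wide variant is used when pooling stacks.
    """
    r = np.asarray(mean_responses, dtype=float)
    if r.size == 0:
        return np.zeros(0, dtype=bool)
    return r >= threshold_fraction * r.max()


# ---------------------------------------------------------------------------
# tuning metrics


def circular_variance(responses, directions_deg):
    """CV = 1 - |sum r exp(2i theta)| / sum r (angle-doubled resultant)."""
    r = np.asarray(responses, dtype=float)
    th = np.deg2rad(np.asarray(directions_deg, dtype=float))
    total = r.sum()
    if total == 0:
        raise ValueError("zero total response: circular variance undefined")
    resultant = np.abs(np.sum(r * np.exp(2j * th)))
    return float(1.0 - resultant / total)


def _hanning_kernel(step_deg, hwhh_deg):
    """Raised-cosine kernel with the requested half-width at half-height.

    cos^2(pi d / (4 hwhh)) reaches 1/2 at d = hwhh and 0 at d = 2 hwhh.
    """
    support = int(np.floor(2 * hwhh_deg / step_deg))
    d = np.arange(-support, support + 1) * step_deg
    k = np.cos(np.pi * d / (4 * hwhh_deg)) ** 2
    return k / k.sum()


def orientation_bandwidth(responses, directions_deg, hwhh_deg=13.5,
                          criterion=1 / np.sqrt(2)):
    """Half the angular width of the smoothed tuning curve at 70.7% of peak.

    The direction tuning curve (equally spaced, circular) is smoothed with
    a Hanning-window filter of half-width-at-half-height 13.5 degrees, the
    peak located, and the nearest crossings of ``criterion * peak`` found
    on either side by linear interpolation. The bandwidth is half the
    angular difference between the two crossings, capped at 180 degrees.
    ``criterion=0.5`` gives the half-amplitude variant.
    """
    r = np.asarray(responses, dtype=float)
    dirs = np.asarray(directions_deg, dtype=float)
    step = dirs[1] - dirs[0]
    k = _hanning_kernel(step, hwhh_deg)
    n = len(r)
    pad = len(k) // 2
    rp = np.concatenate([r[-pad:], r, r[:pad]])
    sm = np.convolve(rp, k, mode="valid")
    pk = int(np.argmax(sm))
    level = criterion * sm[pk]
    if sm[pk] <= 0:
        return 180.0

    def walk(direction):
        dist = 0.0
        prev = sm[pk]
        for i in range(1, n // 2 + 1):
            cur = sm[(pk + direction * i) % n]
            if cur <= level:
                frac = (prev - level) / (prev - cur) if prev != cur else 1.0
                return (i - 1 + frac) * step
            prev = cur
            dist = i * step
        return 180.0

    bw = 0.5 * (walk(+1) + walk(-1))
    return float(min(bw, 180.0))


def modulation_ratio(trace, tf_hz, frame_dt=FRAME_DT):
    """MR = F1 / F0 for a response trace to a drifting grating.

    F0 is the time-mean; F1 is the amplitude of the least-squares sinusoid
    at the known stimulus temporal frequency (fitted with an intercept, so
    non-integer cycle counts are tolerated). MR > 1 marks simple-cell-like
    modulated responses, MR < 1 complex-cell-like sustained ones.
    """
    trace = np.asarray(trace, dtype=float)
    f0 = trace.mean()
    if f0 == 0:
        raise ValueError("zero mean response: modulation ratio undefined")
    t = np.arange(len(trace)) * frame_dt
    w = 2 * np.pi * tf_hz
    design = np.column_stack([np.ones_like(t), np.cos(w * t), np.sin(w * t)])
    coef, *_ = np.linalg.lstsq(design, trace, rcond=None)
    f1 = float(np.hypot(coef[1], coef[2]))
    return float(f1 / f0), float(f0), f1


def direction_selectivity(responses, directions_deg, rnull):
    """Three direction-selectivity indices from a direction tuning curve.

    DSI1 = (rp - rnp) / (rp + rnp); DSI2 = (rp - rnp) / rp;
    DSI3 = 1 - (rnp - rnull) / (rp - rnull), which exceeds 1 when the
    non-preferred direction is suppressed below the blank response.
    Undefined indices are returned as nan.
    """
    r = np.asarray(responses, dtype=float)
    dirs = np.asarray(directions_deg, dtype=float)
    ip = int(np.argmax(r))
    rp = float(r[ip])
    opp = (dirs[ip] + 180.0) % 360.0
    inp = int(np.argmin(np.abs((dirs - opp + 180.0) % 360.0 - 180.0)))
    rnp = float(r[inp])
    dsi1 = (rp - rnp) / (rp + rnp) if rp + rnp != 0 else np.nan
    dsi2 = (rp - rnp) / rp if rp != 0 else np.nan
    dsi3 = 1.0 - (rnp - rnull) / (rp - rnull) if rp != rnull else np.nan
    return dsi1, dsi2, dsi3, rp, rnp


def classify_unit(modulation_ratio, circ_var, gabor_fit_correlation,
                  dsi1=np.nan, excluded=False):
    """Simple / complex / non-oriented labels with a direction-tuned flag.

    simple: Gabor fit correlation > 0.4, CV < 0.9 and MR > 1;
    complex: CV < 0.9 and MR < 1; otherwise non_oriented. Undefined MR or
    CV (nan), or an upstream exclusion, yields 'excluded'. Simple or
    complex units with DSI1 > 0.5 are flagged direction-tuned.
    """
    if excluded or not np.isfinite(modulation_ratio) or not np.isfinite(circ_var):
        return "excluded", False
    if circ_var < 0.9 and modulation_ratio > 1 and gabor_fit_correlation > GABOR_FIT_THRESHOLD:
        label = "simple"
    elif circ_var < 0.9 and modulation_ratio < 1:
        label = "complex"
    else:
        label = "non_oriented"
    direction_tuned = label in ("simple", "complex") and dsi1 > 0.5
    return label, direction_tuned


# ---------------------------------------------------------------------------
# plaids


def _partial_corr(r_xy, r_xz, r_yz):
    den = np.sqrt((1 - r_xz ** 2) * (1 - r_yz ** 2))
    if den == 0:
        return 0.0
    return (r_xy - r_xz * r_yz) / den


def _count_peaks(curve, step_deg=5.0):
    """Local maxima above half height of the lightly smoothed tuning curve."""
    k = _hanning_kernel(step_deg, 13.5)
    n = len(curve)
    pad = len(k) // 2
    sm = np.convolve(np.concatenate([curve[-pad:], curve, curve[:pad]]), k,
                     mode="valid")[:n]
    peaks = 0
    thresh = 0.5 * sm.max()
    for i in range(n):
        if sm[i] >= thresh and sm[i] > sm[(i - 1) % n] and sm[i] >= sm[(i + 1) % n]:
            peaks += 1
    return peaks


def plaid_analysis(model, stack, unit, optimal_grating: GratingParams,
                   component_separations=(120.0,), directions=None,
                   duration=40, z_criterion=1.28):
    """Pattern/component classification from plaid direction tuning.

    The unit's grating direction tuning g(d) (at its optimal sf/tf) is the
    *pattern* prediction; the *component* prediction is the average of g
    displaced to the two component directions. Observed plaid tuning is
    compared with both via partial correlation; Fisher-z scores decide the
    class: pattern if z_p - z_c > 1.28, component if z_c - z_p > 1.28,
    otherwise unclassified. A descriptive peak count of the plaid curve is
    reported alongside. Unresponsive units are returned unclassified.
    """
    if directions is None:
        directions = DEFAULT_DIRECTIONS
    directions = np.asarray(directions, dtype=float)
    sf, tf = optimal_grating.spatial_frequency, optimal_grating.temporal_frequency
    size = optimal_grating.size
    g = np.empty(len(directions))
    for i, d in enumerate(directions):
        stim = make_grating(grating_for_direction(
            d, sf, tf, amplitude=optimal_grating.amplitude, size=size,
            duration=duration))
        g[i] = central_responses(model, stack, stim)[:, unit].mean()
    step = directions[1] - directions[0]
    plaid_tuning = {}
    sep0 = component_separations[0]
    for sep in component_separations:
        curve = np.empty(len(directions))
        for i, d in enumerate(directions):
            stim = make_plaid(PlaidParams(
                pattern_direction=float(d), component_separation=float(sep),
                spatial_frequency=sf, temporal_frequency=tf, size=size,
                duration=duration))
            curve[i] = central_responses(model, stack, stim)[:, unit].mean()
        plaid_tuning[sep] = curve
    observed = plaid_tuning[sep0]
    if observed.max() <= 0 or g.max() <= 0:
        return PlaidResult(directions, g, plaid_tuning, np.nan, np.nan,
                           np.nan, np.nan, "unclassified", 0)
    half = int(round((sep0 / 2) / step))
    component_pred = 0.5 * (np.roll(g, half) + np.roll(g, -half))
    pattern_pred = g
    r_p = _pearson(observed, pattern_pred)
    r_c = _pearson(observed, component_pred)
    r_pc = _pearson(pattern_pred, component_pred)
    rp_part = _partial_corr(r_p, r_c, r_pc)
    rc_part = _partial_corr(r_c, r_p, r_pc)
    n = len(directions)
    clip = lambda r: np.clip(r, -0.9999, 0.9999)  # noqa: E731
    zp = np.arctanh(clip(rp_part)) * np.sqrt(max(n - 3, 1))
    zc = np.arctanh(clip(rc_part)) * np.sqrt(max(n - 3, 1))
    if zp - zc > z_criterion and zp > 0:
        label = "pattern"
    elif zc - zp > z_criterion and zc > 0:
        label = "component"
    else:
        label = "unclassified"
    return PlaidResult(directions, g, plaid_tuning, rp_part, rc_part,
                       float(zp), float(zc), label,
                       _count_peaks(observed, step))


# ---------------------------------------------------------------------------
# orchestration


def characterize_stack(model, stack, directions=DEFAULT_DIRECTIONS,
                       sfs=DEFAULT_SFS, tfs=DEFAULT_TFS, duration=40,
                       amplitude=3.0, rf_noise_samples=20_000, seed=0,
                       exclusion_fraction=0.01):
    """Full grating characterization of every unit in one stack.

    Returns a tidy DataFrame (one row per unit) with the optimal grating,
    CV, bandwidth, MR, the three DSIs, the Gabor fit correlation of the
    unit's RF (direct weights for stack 1, reverse-correlation STA
    otherwise) and the class label.
    """
    params, best_resp, grid = find_optimal_gratings(
        model, stack, directions, sfs, tfs, duration, amplitude)
    keep = unit_exclusion(best_resp, exclusion_fraction)
    j = len(params)
    if stack == 1:
        rfs = [rf_from_weights(model, 1, u) for u in range(j)]
    else:
        rfs = rf_by_reverse_correlation(model, stack, n_samples=rf_noise_samples,
                                        seed=seed)
    ey, ex, _ = receptive_extent(model.specs[:stack])
    size = max(ey, ex)
    blank = make_blank(size, duration)
    rnull_all = central_responses(model, stack, blank).mean(axis=0)
    sf_idx = {float(s): i for i, s in enumerate(sfs)}
    tf_idx = {float(t): i for i, t in enumerate(tfs)}
    rows = []
    for u in range(j):
        p = params[u]
        row = {"stack": stack, "unit": u, "excluded": not keep[u],
               "opt_direction": (p.orientation + 90.0) % 360.0,
               "opt_sf": p.spatial_frequency, "opt_tf": p.temporal_frequency,
               "mean_response": best_resp[u], "rnull": float(rnull_all[u])}
        fit = (fit_gabor(rfs[u].latest) if rfs[u].defined
               else GaborFit(0, 0, 0, 1, 1, 0, 0, 0, 0.0, converged=False))
        row["gabor_fit_correlation"] = fit.fit_correlation
        if not keep[u]:
            row.update(cv=np.nan, bandwidth=np.nan, mr=np.nan, f0=np.nan,
                       f1=np.nan, dsi1=np.nan, dsi2=np.nan, dsi3=np.nan,
                       rp=np.nan, rnp=np.nan, label="excluded",
                       direction_tuned=False)
            rows.append(row)
            continue
        tuning = grid[:, sf_idx[p.spatial_frequency], tf_idx[p.temporal_frequency], u]
        try:
            cv = circular_variance(tuning, directions)
        except ValueError:
            cv = np.nan
        bw = orientation_bandwidth(tuning, directions)
        stim = make_grating(p)
        trace = central_responses(model, stack, stim)[:, u]
        try:
            mr, f0, f1 = modulation_ratio(trace, p.temporal_frequency)
        except ValueError:
            mr, f0, f1 = np.nan, 0.0, np.nan
        dsi1, dsi2, dsi3, rp, rnp = direction_selectivity(
            tuning, directions, float(rnull_all[u]))
        label, dirflag = classify_unit(mr, cv, fit.fit_correlation, dsi1)
        row.update(cv=cv, bandwidth=bw, mr=mr, f0=f0, f1=f1, dsi1=dsi1,
                   dsi2=dsi2, dsi3=dsi3, rp=rp, rnp=rnp, label=label,
                   direction_tuned=dirflag)
        rows.append(row)
    return pd.DataFrame(rows)
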