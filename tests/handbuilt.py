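"""Hand-built model units with known tuning, used as physiology oracles.

Constructs single- and two-stack models whose units are planted filters:
linear-rectified Gabors (simple-cell-like), opponent-energy quadrature sets
(complex, direction-selective), and center-surround difference-of-Gaussians
(non-oriented). Because every kernel is written down explicitly, the
expected classification of each unit is known by construction.
"""

import numpy as np

from predstack.model import HierarchicalModel, StackSpec, StackWeights
from predstack.physiology import gabor_image


def spatial_gabor(size, theta_deg, f=0.15, sigma=None, phase=0.0):
    sigma = sigma or size / 5.0
    c = (size - 1) / 2.0
    return gabor_image((size, size), 1.0, c, c, sigma, sigma,
                       np.deg2rad(theta_deg), f, phase)


def drifting_gabor_kernel(size, depth, direction_deg, f=0.15, tf_cpf=0.15,
                          sigma=None, phase=0.0):
    """Spatiotemporal Gabor drifting toward ``direction_deg``.

    The carrier advances by ``tf_cpf`` cycles per lag step toward the most
    recent frame, making the kernel selective for motion in that direction.
    """
    sigma = sigma or size / 5.0
    c = (size - 1) / 2.0
    th = np.deg2rad(direction_deg - 90.0)
    yy, xx = np.mgrid[0:size, 0:size].astype(float)
    xr = (xx - c) * np.cos(th) + (yy - c) * np.sin(th)
    yr = -(xx - c) * np.sin(th) + (yy - c) * np.cos(th)
    env = np.exp(-((xr / (2 * sigma)) ** 2) - ((yr / (2 * sigma)) ** 2))
    out = np.empty((size, size, depth))
    for lag in range(depth):
        # lag index depth-1 is the most recent frame
        t_back = depth - 1 - lag
        out[:, :, lag] = env * np.cos(2 * np.pi * (f * xr + tf_cpf * t_back)
                                      + phase)
    return out


def center_surround(size, sigma_c=1.5, ratio=2.0):
    c = (size - 1) / 2.0
    yy, xx = np.mgrid[0:size, 0:size].astype(float)
    r2 = (yy - c) ** 2 + (xx - c) ** 2
    center = np.exp(-r2 / (2 * sigma_c ** 2))
    surround = np.exp(-r2 / (2 * (ratio * sigma_c) ** 2))
    dog = center / center.sum() - surround / surround.sum()
    return dog / np.abs(dog).max()


def planted_population(size=16, depth=4):
    """Two-stack model with planted simple/complex/non-oriented units.

    Stack 1 (8 units): two spatial Gabors (simple), two center-surround
    units (non-oriented), and a +/-even, +/-odd quadrature set of drifting
    Gabors at 120 degrees. Stack 2 (3 units, 1x1x1 kernels): the energy sum
    of the quadrature set (complex), and passthroughs of one simple and one
    center-surround unit. Returns (model, expected_labels_by_stack).
    """
    spec1 = StackSpec(index=1, input_shape=(size, size, 20, 1), conv_units=8,
                      kernel=(size, size, depth), stride=(1, 1, 1))
    w1 = np.zeros((8, 1, size, size, depth))
    w1[0, 0, :, :, -1] = spatial_gabor(size, 0.0)
    w1[1, 0, :, :, -1] = spatial_gabor(size, 60.0)
    w1[2, 0, :, :, -1] = center_surround(size)
    w1[3, 0, :, :, -1] = -center_surround(size)
    even = drifting_gabor_kernel(size, depth, 120.0, phase=0.0)
    odd = drifting_gabor_kernel(size, depth, 120.0, phase=np.pi / 2)
    w1[4, 0] = even
    w1[5, 0] = -even
    w1[6, 0] = odd
    w1[7, 0] = -odd
    wts1 = StackWeights(w=w1, b=np.zeros(8), m=np.zeros((1, 8, size, size)),
                        c=np.zeros(1))

    spec2 = StackSpec(index=2, input_shape=spec1.hidden_shape, conv_units=3,
                      kernel=(1, 1, 1), stride=(1, 1, 1))
    w2 = np.zeros((3, 8, 1, 1, 1))
    w2[0, 4:8] = 1.0  # |even| + |odd| opponent energy -> complex
    w2[1, 0] = 1.0  # passthrough simple
    w2[2, 2] = 1.0  # passthrough center-surround
    wts2 = StackWeights(w=w2, b=np.zeros(3), m=np.zeros((8, 3, 1, 1)),
                        c=np.zeros(8))
    model = HierarchicalModel(specs=[spec1, spec2], weights=[wts1, wts2])
    expected = {
        1: ["simple", "simple", "non_oriented", "non_oriented",
            "simple", "simple", "simple", "simple"],
        2: ["complex", "simple", "non_oriented"],
    }
    return model, expected


def single_gabor_model(size=15, depth=3, theta_deg=45.0, f=0.12, n_units=2):
    """One-stack model whose unit 0 is a planted spatial Gabor (unit 1 zero)."""
    spec = StackSpec(index=1, input_shape=(size, size, 20, 1),
                     conv_units=n_units, kernel=(size, size, depth),
                     stride=(1, 1, 1))
    w = np.zeros((n_units, 1, size, size, depth))
    w[0, 0, :, :, -1] = spatial_gabor(size, theta_deg, f=f)
    wts = StackWeights(w=w, b=np.zeros(n_units),
                       m=np.zeros((1, n_units, size, size)), c=np.zeros(1))
    return HierarchicalModel(specs=[spec], weights=[wts])


class PatternOracleModel:
    """Test double whose single unit responds to the stimulus's net motion.

    Estimates the global displacement between consecutive frames by
    circular cross-correlation and responds with a von-Mises tuning on the
    displacement angle — a unit that, by construction, cares only about
    pattern motion direction. Quacks like a HierarchicalModel for
    :func:`predstack.physiology.central_responses`.
    """

    def __init__(self, size=32, preferred_deg=180.0, kappa=4.0):
        self.specs = [StackSpec(index=1, input_shape=(size, size, 20, 1),
                                conv_units=1, kernel=(size, size, 2),
                                stride=(1, 1, 1))]
        self.preferred = np.deg2rad(preferred_deg)
        self.kappa = kappa
        self.n_stacks = 1

    def forward(self, u, n_stacks=None, batch=None, return_all=False):
        n, y, x, t, _ = u.shape
        th = t - 1
        out = np.zeros((n, 1, 1, th, 1))
        for ni in range(n):
            for ti in range(th):
                a = u[ni, :, :, ti, 0]
                b = u[ni, :, :, ti + 1, 0]
                if a.std() == 0 or b.std() == 0:
                    continue
                xc = np.fft.ifft2(np.fft.fft2(b) * np.conj(np.fft.fft2(a))).real
                dy, dx = np.unravel_index(np.argmax(xc), xc.shape)
                dy = dy - y if dy > y // 2 else dy
                dx = dx - x if dx > x // 2 else dx
                if dy == 0 and dx == 0:
                    continue
                # direction convention of grating_for_direction: direction d
                # moves content along (sin d, -cos d) in (x, y)
                ang = np.arctan2(dx, -dy)
                out[ni, 0, 0, ti, 0] = np.exp(
                    self.kappa * (np.cos(ang - self.preferred) - 1.0))
        return out
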