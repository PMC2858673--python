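"""Stereo energy model: monocular filtering, binocular correlation, spiking.

For each binocular simple cell the monocular drive is the inner product of
the eye's image with the eye's Gabor receptive field.  The energy-model
complex cell sums squared simple-cell outputs over the two carrier phases
(0 and pi/2, the standard quadrature shortcut); splitting the energy into
monocular and binocular terms,

    M = sum_phi (v_L^2 + v_R^2),      B = sum_phi 2 v_L v_R,

gives the effective binocular correlation C = B / M, the correlation
coefficient between the filtered local image patches.  C lies in [-1, 1],
is exactly +1 whenever the stimulus is a pure shift equal to the unit's
interocular receptive-field transformation (for any image), and flips sign
under anticorrelation.  Spiking converts C to a Poisson count with mean
U * (1 + C), where U is the mean count for an uncorrelated stimulus.

Implementation note
-------------------
A quadrature pair of Gabors is one complex Gabor: with
z(c) = sum_x G(x - c) exp(2i pi f u.(x - c)) I(x) the two phase outputs are
the real and imaginary parts of exp(i psi) z, so

    M = |z_L|^2 + |z_R|^2,   B = 2 Re{ z_L conj(z_R) exp(i dphi) e^{i k} }

with a fixed per-unit phase constant.  Because the envelope is isotropic,
the sum factorises into 1D Gaussian contractions of the plane-wave-
modulated image, which `EncoderBank` evaluates with BLAS matrix products.
The result agrees with the naive per-pixel inner products
(`population.gabor_rf`) to floating-point precision; both routes are kept
and cross-checked in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .population import PopulationGrid, image_coords, make_population
from .stimuli import Stereogram

KINDS = ("correlation", "mean_spikes", "spike_counts")


@dataclass
class ResponseVector:
    """Per-complex-unit responses in the population's fixed ordering."""

    values: np.ndarray
    kind: str
    stimulus: dict = field(default_factory=dict)
    units_hash: str | None = None

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"kind must be one of {KINDS}")
        self.values = np.asarray(self.values)


class EncoderBank:
    """Precomputed filters for one population on one image geometry.

    Groups units by (theta, f): within a group the plane wave is shared
    and only the Gaussian envelope centres differ across (dphi, dx_enc).
    """

    def __init__(self, grid: PopulationGrid | None = None,
                 shape: tuple[int, int] = (81, 81)) -> None:
        self.grid = grid or make_population()
        self.shape = shape
        self.units_hash = self.grid.units_hash()
        cfg = self.grid.config
        if tuple(cfg.phases) != (0.0, np.pi / 2):
            raise ValueError(
                "EncoderBank implements the quadrature (0, pi/2) phase pair; "
                f"got phases {cfg.phases}"
            )
        x, y = image_coords(shape)
        units = self.grid.complex_units
        self._groups = []
        n_sub = len(cfg.dphis) * len(cfg.dx_encs)
        start = 0
        for theta in cfg.thetas:
            th = np.deg2rad(theta)
            ux, uy = np.cos(th), np.sin(th)
            for f in cfg.freqs:
                sl = slice(start, start + n_sub)
                sub = units.iloc[sl]
                assert (sub.theta == theta).all() and (sub.f == f).all()
                sigma = cfg.sigma(f)
                # plane wave exp(2i pi f u.x) over the pixel grid
                plane = np.exp(
                    2j * np.pi * f * (ux * x[None, :] + uy * y[:, None])
                )
                cxr = sub.dx_pos.to_numpy() / 2.0  # right-eye centres
                cyr = sub.dy_pos.to_numpy() / 2.0
                gxs, gys = [], []
                for cx, cy in ((-cxr, -cyr), (cxr, cyr)):  # left, right
                    gxs.append(np.exp(-((x[None, :] - cx[:, None]) ** 2)
                                      / (2 * sigma**2)))
                    gys.append(np.exp(-((y[None, :] - cy[:, None]) ** 2)
                                      / (2 * sigma**2)))
                # B = 2 Re{ z_L conj(z_R) kappa },
                # kappa = exp(i (2 pi f u.dpos + dphi))
                kappa = np.exp(
                    1j * (2 * np.pi * f * (ux * sub.dx_pos.to_numpy()
                                           + uy * sub.dy_pos.to_numpy())
                          + sub.dphi.to_numpy())
                )
                self._groups.append(
                    dict(sl=sl, plane=plane, gx=gxs, gy=gys, kappa=kappa,
                         theta=theta, f=f)
                )
                start += n_sub

    @property
    def n_units(self) -> int:
        return self.grid.n_complex

    # -- core filtering -----------------------------------------------------

    def _complex_responses(self, left: np.ndarray, right: np.ndarray
                           ) -> tuple[np.ndarray, np.ndarray]:
        """Quadrature filter outputs z_L, z_R for all units and images.

        ``left``/``right``: (n, H, W).  Returns complex arrays (n, n_units)
        of the separable Gaussian contractions S(c) (the centre-dependent
        phase is folded into ``kappa``; |S| = |z|).
        """
        n = left.shape[0]
        z_l = np.empty((n, self.n_units), dtype=complex)
        z_r = np.empty_like(z_l)
        for g in self._groups:
            for imgs, gx, gy, out in (
                (left, g["gx"][0], g["gy"][0], z_l),
                (right, g["gx"][1], g["gy"][1], z_r),
            ):
                j = g["plane"][None, :, :] * imgs  # (n, H, W)
                # contract rows (y) then columns (x), per unit
                jv = np.ascontiguousarray(j.transpose(1, 0, 2)).reshape(
                    self.shape[0], -1
                )
                t = (gy @ jv.view(float)).view(complex)  # (k, n*W)
                t = t.reshape(-1, n, self.shape[1])
                out[:, g["sl"]] = np.einsum("knw,kw->nk", t, gx)
        return z_l, z_r

    def correlations_batch(self, left: np.ndarray, right: np.ndarray
                           ) -> np.ndarray:
        """Effective binocular correlation C for a batch of image pairs.

        ``left``/``right``: (n, H, W) or (H, W).  Returns (n, n_units).
        Units seeing zero monocular energy in both eyes get C = 0
        (neutral evidence; only arises for degenerate constant stimuli).
        """
        left = np.asarray(left, dtype=float)
        right = np.asarray(right, dtype=float)
        if left.ndim == 2:
            left, right = left[None], right[None]
        if left.shape != right.shape or left.shape[1:] != self.shape:
            raise ValueError(
                f"expected image pairs of shape {self.shape}, got "
                f"{left.shape} / {right.shape}"
            )
        z_l, z_r = self._complex_responses(left, right)
        m = np.abs(z_l) ** 2 + np.abs(z_r) ** 2
        b = np.empty_like(m)
        for g in self._groups:
            sl = g["sl"]
            b[:, sl] = 2.0 * np.real(z_l[:, sl] * np.conj(z_r[:, sl])
                                     * g["kappa"][None, :])
        return np.divide(b, m, out=np.zeros_like(b), where=m > 0)

    def encode(self, stereogram: Stereogram) -> ResponseVector:
        """Binocular correlations of the full population for one stimulus."""
        c = self.correlations_batch(stereogram.left, stereogram.right)[0]
        return ResponseVector(
            c, "correlation",
            stimulus=dict(dx=stereogram.dx, dy=stereogram.dy,
                          polarity=stereogram.polarity, seed=stereogram.seed),
            units_hash=self.units_hash,
        )

    def monocular_responses(self, stereogram: Stereogram
                            ) -> tuple[np.ndarray, np.ndarray]:
        """Simple-cell drives (v_L, v_R), one entry per simple cell.

        Ordering matches ``PopulationGrid.simple_cells`` (complex-unit
        order with carrier phase fastest).  v(phi) = Re{e^{i psi} z} with
        psi the eye's carrier phase; phi = pi/2 is the quadrature partner.
        """
        z_l, z_r = self._complex_responses(
            stereogram.left[None].astype(float),
            stereogram.right[None].astype(float),
        )
        units = self.grid.complex_units
        out = []
        for z, eye_sign in ((z_l[0], -1.0), (z_r[0], 1.0)):
            # fold back the centre-dependent carrier phase exp(-2i pi f u.c)
            th = np.deg2rad(units.theta.to_numpy())
            f = units.f.to_numpy()
            cx = eye_sign * units.dx_pos.to_numpy() / 2.0
            cy = eye_sign * units.dy_pos.to_numpy() / 2.0
            psi0 = -eye_sign * units.dphi.to_numpy() / 2.0  # phase at phi=0
            carrier = np.exp(
                1j * (psi0 - 2 * np.pi * f * (np.cos(th) * cx + np.sin(th) * cy))
            )
            a = carrier * z
            v = np.empty(2 * self.n_units)
            v[0::2] = np.real(a)  # phi = 0
            v[1::2] = -np.imag(a)  # phi = pi/2
            out.append(v)
        return out[0], out[1]


def monocular_responses_direct(grid: PopulationGrid, stereogram: Stereogram
                               ) -> tuple[np.ndarray, np.ndarray]:
    """Naive per-pixel inner products for every simple cell.

    Independent evaluation route used to validate `EncoderBank`; O(cells x
    pixels), intended for reduced populations.
    """
    from .population import gabor_rf

    vl = np.array([
        np.sum(gabor_rf(s, "left", stereogram.shape) * stereogram.left)
        for s in grid.simple_cells
    ])
    vr = np.array([
        np.sum(gabor_rf(s, "right", stereogram.shape) * stereogram.right)
        for s in grid.simple_cells
    ])
    return vl, vr


def mean_spikes(correlations: ResponseVector | np.ndarray, u: float = 1.0
                ) -> ResponseVector | np.ndarray:
    """Mean spike count R_m = U (1 + C), in [0, 2U]."""
    if u <= 0:
        raise ValueError("U must be positive")
    if isinstance(correlations, ResponseVector):
        if correlations.kind != "correlation":
            raise ValueError("expected a correlation ResponseVector")
        return ResponseVector(
            poisson_means(correlations.values, u), "mean_spikes",
            stimulus=dict(correlations.stimulus, U=u),
            units_hash=correlations.units_hash,
        )
    return poisson_means(np.asarray(correlations), u)


def poisson_means(c: np.ndarray, u: float) -> np.ndarray:
    """U (1 + C) clipped to [0, 2U]; C only leaves [-1, 1] by float noise."""
    return np.clip(u * (1.0 + c), 0.0, 2.0 * u)


def spike_counts(
    correlations: ResponseVector | np.ndarray,
    u: float = 1.0,
    rng: np.random.Generator | int | None = None,
) -> ResponseVector | np.ndarray:
    """One Poisson draw per unit with mean U (1 + C); deterministic given
    the seed.  Models a single stimulus presentation."""
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    m = mean_spikes(correlations, u)
    if isinstance(m, ResponseVector):
        return ResponseVector(
            rng.poisson(m.values), "spike_counts",
            stimulus=m.stimulus, units_hash=m.units_hash,
        )
    return rng.poisson(m)
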