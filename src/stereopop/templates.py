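"""Template bank: mean population spike counts per 2D stimulus disparity.

For every candidate disparity on the decoding grid (default 21x21,
-10..10 pixels), many fresh Gaussian-noise stereograms with that disparity
are encoded and the per-unit binocular correlation averaged.  The stored
template is the noise-free mean spike count

    W(unit; dx, dy) = U * (1 + <C>_images),

i.e. the analytic Poisson expectation: averaging over repeated
presentations of the same images removes the spiking noise exactly, so
Poisson draws are not simulated when building W (a config switch forces
empirical draw-averaging for validation).  W doubles as the synaptic
weight from each encoding unit onto the decoding unit for that disparity.

Image seed streams are derived from ``SeedSequence([master_seed, 1])`` and
are therefore disjoint from the test-image streams (which the experiments
module derives from spawn key 2).
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import h5py
import numpy as np

from . import stimuli
from .encoder import EncoderBank, poisson_means
from .population import PopulationConfig

TEMPLATE_STREAM_KEY = 1
TEST_STREAM_KEY = 2


def default_grid(radius: int = 10) -> np.ndarray:
    """Decoding-disparity grid: (dx, dy) pairs, dy fastest, -radius..radius."""
    d = np.arange(-radius, radius + 1)
    return np.array([(dx, dy) for dx in d for dy in d], dtype=int)


@dataclass
class TemplateBank:
    """Stored mean spike counts W, shape (n_units, n_disparities)."""

    w: np.ndarray
    grid: np.ndarray  # (n_disparities, 2) int, columns (dx, dy)
    n_images: int
    u: float
    units_hash: str
    seed: int
    config: PopulationConfig

    @property
    def n_units(self) -> int:
        return self.w.shape[0]

    @property
    def n_disparities(self) -> int:
        return self.w.shape[1]

    def index_of(self, dx: int, dy: int) -> int:
        hit = np.flatnonzero((self.grid[:, 0] == dx) & (self.grid[:, 1] == dy))
        if len(hit) == 0:
            raise KeyError(f"disparity ({dx},{dy}) not in the template grid")
        return int(hit[0])

    def column(self, dx: int, dy: int) -> np.ndarray:
        return self.w[:, self.index_of(dx, dy)]

    def save(self, path) -> None:
        with h5py.File(path, "w") as h5:
            h5.create_dataset("w", data=self.w)
            h5.create_dataset("grid", data=self.grid)
            h5.attrs["n_images"] = self.n_images
            h5.attrs["u"] = self.u
            h5.attrs["units_hash"] = self.units_hash
            h5.attrs["seed"] = self.seed
            h5.attrs["config"] = json.dumps(self.config.to_dict())

    @classmethod
    def load(cls, path) -> "TemplateBank":
        with h5py.File(path, "r") as h5:
            return cls(
                w=h5["w"][()],
                grid=h5["grid"][()],
                n_images=int(h5.attrs["n_images"]),
                u=float(h5.attrs["u"]),
                units_hash=str(h5.attrs["units_hash"]),
                seed=int(h5.attrs["seed"]),
                config=PopulationConfig.from_dict(json.loads(h5.attrs["config"])),
            )


def build_templates(
    encoder: EncoderBank,
    grid: np.ndarray | None = None,
    n_images: int = 50,
    u: float = 1.0,
    seed: int = 0,
    empirical_noise: bool = False,
    batch: int = 50,
) -> TemplateBank:
    """Average the population response over ``n_images`` stereograms at
    each grid disparity.

    ``empirical_noise=True`` averages actual Poisson draws instead of the
    analytic expectation (equivalent in the large-sample limit; for
    validation only).  Deterministic given ``seed``.
    """
    if grid is None:
        grid = default_grid()
    grid = np.asarray(grid, dtype=int)
    if len(grid) == 0:
        raise ValueError("template grid is empty")
    if n_images < 1:
        raise ValueError("n_images must be >= 1")
    h, w_px = encoder.shape
    ss = np.random.SeedSequence([seed, TEMPLATE_STREAM_KEY])
    children = ss.spawn(len(grid))
    w = np.empty((encoder.n_units, len(grid)))
    for j, (dx, dy) in enumerate(grid):
        rng = np.random.default_rng(children[j])
        acc = np.zeros(encoder.n_units)
        done = 0
        while done < n_images:
            nb = min(batch, n_images - done)
            left, right = stimuli.generate_batch(
                nb, w_px, h, int(dx), int(dy), stimuli.CORRELATED, rng
            )
            c = encoder.correlations_batch(left, right)
            if empirical_noise:
                acc += rng.poisson(poisson_means(c, u)).sum(axis=0) / u - nb
            else:
                acc += c.sum(axis=0)
            done += nb
        w[:, j] = u * (1.0 + acc / n_images)
    return TemplateBank(
        w=w, grid=grid, n_images=int(n_images), u=float(u),
        units_hash=encoder.units_hash, seed=int(seed),
        config=encoder.grid.config,
    )


def template_slice(
    bank: TemplateBank, dx: int, dy: int, dphi: float = 0.0
) -> dict[float, np.ndarray]:
    """Per-frequency matrices of W over (theta x dx_enc) at one template
    disparity, for the sub-population with phase disparity ``dphi``.

    Returns ``{f: matrix (n_thetas, n_dx_enc)}`` — the layout of the
    mean-population-response maps (preferred horizontal disparity on the
    horizontal axis, orientation on the vertical axis).
    """
    cfg = bank.config
    if dphi not in cfg.dphis:
        raise KeyError(f"phase disparity {dphi} not in the population grid")
    col = bank.column(dx, dy)
    n_f, n_p, n_d = len(cfg.freqs), len(cfg.dphis), len(cfg.dx_encs)
    cube = col.reshape(len(cfg.thetas), n_f, n_p, n_d)
    kp = cfg.dphis.index(dphi)
    return {f: cube[:, jf, kp, :] for jf, f in enumerate(cfg.freqs)}
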