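"""Template-matching decoder: Pearson correlation + half-wave rectification.

A decoding unit exists for every disparity on the template grid.  Its
response to a test stimulus is the half-wave-rectified Pearson
product-moment correlation, across the encoding population, between the
single-trial spike counts and the stored mean counts W for its disparity:

    r(dx_dec, dy_dec) = Corr( R_test , W(.; dx_dec, dy_dec) )
    P = max(r, 0)

The stimulus disparity estimate is the grid point maximising P.
Rectification makes the decoder blind to anticorrelated stimuli, whose r
map is almost always entirely negative — such trials are flagged as
degenerate rather than silently reported as a confident estimate.

Edge conventions (the underlying statistic does not define them):
* zero variance in either vector -> r = 0 (no template can be favoured);
* argmax ties -> smallest dx^2 + dy^2, then lexicographic (dy, dx); the
  full tie set is recorded and the estimate flagged degenerate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import stimuli
from .encoder import EncoderBank, ResponseVector, poisson_means
from .templates import TemplateBank, TEST_STREAM_KEY


@dataclass
class DisparityEstimate:
    dx_hat: int
    dy_hat: int
    r_map: np.ndarray  # Pearson coefficient per grid disparity
    p_map: np.ndarray  # half-wave rectified map
    degenerate: bool  # max P == 0, or ties at the max
    tie_set: list[tuple[int, int]] = field(default_factory=list)

    @property
    def max_p(self) -> float:
        return float(self.p_map.max())


def _as_counts(r_test: ResponseVector | np.ndarray, bank: TemplateBank
               ) -> np.ndarray:
    if isinstance(r_test, ResponseVector):
        if r_test.units_hash is not None and r_test.units_hash != bank.units_hash:
            raise ValueError(
                "response vector and template bank use different unit "
                "orderings (hash mismatch)"
            )
        values = r_test.values
    else:
        values = np.asarray(r_test)
    if values.shape[-1] != bank.n_units:
        raise ValueError(
            f"expected {bank.n_units} units, got {values.shape[-1]}"
        )
    return np.atleast_2d(values).astype(float)


def pearson_maps(r_test, bank: TemplateBank) -> np.ndarray:
    """Pearson correlation of response vectors against every template.

    ``r_test``: (n_units,) or (n_trials, n_units).  Returns
    (n_trials, n_disparities); zero-variance vectors give r = 0.
    """
    counts = _as_counts(r_test, bank)
    wc = bank.w - bank.w.mean(axis=0, keepdims=True)
    wn = np.sqrt(np.sum(wc**2, axis=0))
    rc = counts - counts.mean(axis=1, keepdims=True)
    rn = np.sqrt(np.sum(rc**2, axis=1))
    num = rc @ wc
    den = rn[:, None] * wn[None, :]
    return np.divide(num, den, out=np.zeros_like(num), where=den > 0)


def pearson_map(r_test, bank: TemplateBank) -> np.ndarray:
    """Pearson map for a single response vector, shape (n_disparities,)."""
    return pearson_maps(r_test, bank)[0]


def estimate_disparity(r_test, bank: TemplateBank) -> DisparityEstimate:
    """Argmax of the rectified Pearson map with deterministic tie-breaking."""
    r = pearson_map(r_test, bank)
    p = np.maximum(r, 0.0)
    pmax = p.max()
    ties = np.flatnonzero(p == pmax)
    if len(ties) > 1:
        g = bank.grid[ties]
        order = np.lexsort((g[:, 0], g[:, 1], g[:, 0] ** 2 + g[:, 1] ** 2))
        pick = ties[order[0]]
    else:
        pick = ties[0]
    dx, dy = (int(v) for v in bank.grid[pick])
    return DisparityEstimate(
        dx_hat=dx, dy_hat=dy, r_map=r, p_map=p,
        degenerate=bool(pmax == 0.0 or len(ties) > 1),
        tie_set=[(int(a), int(b)) for a, b in bank.grid[ties]],
    )


def decode_batch(counts: np.ndarray, bank: TemplateBank) -> dict[str, np.ndarray]:
    """Vectorised decoding of many trials.

    ``counts``: (n_trials, n_units).  Returns arrays ``dx_hat``,
    ``dy_hat``, ``max_p``, ``degenerate`` of length n_trials, with the
    same tie-breaking as `estimate_disparity`.
    """
    r = pearson_maps(counts, bank)
    p = np.maximum(r, 0.0)
    pmax = p.max(axis=1)
    # tie-break order: distance from zero disparity, then (dy, dx)
    rank = np.lexsort(
        (bank.grid[:, 0], bank.grid[:, 1],
         bank.grid[:, 0] ** 2 + bank.grid[:, 1] ** 2)
    )
    inv = np.empty(len(rank), dtype=int)
    inv[rank] = np.arange(len(rank))
    is_max = p == pmax[:, None]
    pick = rank[np.where(is_max, inv[None, :], len(rank)).min(axis=1)]
    n_ties = is_max.sum(axis=1)
    return dict(
        dx_hat=bank.grid[pick, 0],
        dy_hat=bank.grid[pick, 1],
        max_p=pmax,
        degenerate=(pmax == 0.0) | (n_ties > 1),
    )


def map_to_grid(values: np.ndarray, bank: TemplateBank
                ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Arrange a per-disparity vector as a 2D (dy x dx) image.

    Returns (dx_axis, dy_axis, image) with image[iy, ix] at
    (dx_axis[ix], dy_axis[iy]); suitable for plotting decoder maps.
    """
    dxs = np.unique(bank.grid[:, 0])
    dys = np.unique(bank.grid[:, 1])
    img = np.full((len(dys), len(dxs)), np.nan)
    ix = np.searchsorted(dxs, bank.grid[:, 0])
    iy = np.searchsorted(dys, bank.grid[:, 1])
    img[iy, ix] = values
    return dxs, dys, img


def decoder_tuning_surface(
    bank: TemplateBank,
    encoder: EncoderBank,
    target: tuple[int, int],
    test_disparities: np.ndarray | None = None,
    n_images: int = 40,
    polarity: str = stimuli.CORRELATED,
    u: float | None = None,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Mean rectified response <P> of one decoding unit across test
    disparities.

    For each test disparity, ``n_images`` stereograms are generated,
    encoded, converted to Poisson spike counts, and correlated against the
    target's template.  Peaked at ``target`` for correlated stimuli;
    near-flat at zero for anticorrelated ones.
    """
    if n_images < 1:
        raise ValueError("n_images must be >= 1")
    target_idx = bank.index_of(*target)
    if test_disparities is None:
        test_disparities = bank.grid
    test_disparities = np.asarray(test_disparities, dtype=int)
    u = bank.u if u is None else u
    h, w_px = encoder.shape
    ss = np.random.SeedSequence([seed, TEST_STREAM_KEY, 77])
    out = np.empty(len(test_disparities))
    for i, (dx, dy) in enumerate(test_disparities):
        rng = np.random.default_rng(ss.spawn(1)[0])
        left, right = stimuli.generate_batch(
            n_images, w_px, h, int(dx), int(dy), polarity, rng
        )
        c = encoder.correlations_batch(left, right)
        counts = rng.poisson(poisson_means(c, u))
        p = np.maximum(pearson_maps(counts, bank)[:, target_idx], 0.0)
        out[i] = p.mean()
    return test_disparities, out
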