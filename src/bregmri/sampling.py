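"""k-space sampling trajectories and the partial Fourier operator.

Three mask families are provided: variable-density 2D random sampling,
row-wise (frequency-encode line) Cartesian undersampling, and its
column-wise phase-encode analogue.  The partial Fourier operator F_p is the
orthonormal 2D FFT restricted to the mask; its adjoint is the inverse FFT of
the zero-filled data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .synthetic import KSpaceData

TRAJECTORIES = ("random2d", "cartesian", "phase_encode")


@dataclass
class SamplingMask:
    """Boolean k-space sampling pattern.

    ``factor`` is the requested acceleration; :attr:`realized_factor` is
    M*N / number of sampled points actually achieved.
    """

    mask: np.ndarray
    factor: float
    trajectory: str
    center_fraction: float
    seed: int

    def __post_init__(self):
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise ValueError("mask must be 2D")
        if self.n_sampled < 1:
            raise ValueError("mask must sample at least one point")
        if self.trajectory not in TRAJECTORIES:
            raise ValueError(f"unknown trajectory {self.trajectory!r}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.mask.shape

    @property
    def n_sampled(self) -> int:
        return int(self.mask.sum())

    @property
    def realized_factor(self) -> float:
        return self.mask.size / self.n_sampled


def _check_factor(shape: tuple[int, int], factor: float) -> None:
    if not 1.0 <= factor <= min(shape[0] * shape[1], 20):
        raise ValueError(
            f"acceleration factor must lie in [1, 20], got {factor}"
        )


def make_random2d_mask(
    shape: tuple[int, int],
    factor: float,
    center_fraction: float = 0.04,
    seed: int = 0,
    density_sigma: float = 0.25,
) -> SamplingMask:
    """Variable-density 2D random mask.

    Exactly ``floor(M*N / factor)`` points are sampled: a fully sampled
    central block of per-axis width ``center_fraction`` first, then the
    remaining budget drawn without replacement with Gaussian weighting
    (std ``density_sigma`` in normalized frequency) toward the k-space
    center, so low frequencies are favored but the mid band is only
    partially covered.
    """
    M, N = shape
    _check_factor(shape, factor)
    if not 0.0 <= center_fraction < 1.0:
        raise ValueError("center_fraction must lie in [0, 1)")

    budget = int(M * N // factor)
    mask = np.zeros((M, N), dtype=bool)

    ch = int(round(center_fraction * M))
    cw = int(round(center_fraction * N))
    if ch > 0 and cw > 0:
        r0 = (M - ch) // 2
        c0 = (N - cw) // 2
        mask[r0:r0 + ch, c0:c0 + cw] = True
    n_center = int(mask.sum())
    if n_center > budget:
        raise ValueError(
            f"center block ({n_center} points) exceeds the sampling budget "
            f"({budget}) at factor {factor}; lower center_fraction"
        )

    # Gaussian variable density over the remaining (non-center) positions,
    # distances measured from the k-space center in centered coordinates.
    yy = (np.arange(M) - M / 2) / M
    xx = (np.arange(N) - N / 2) / N
    d2 = yy[:, None] ** 2 + xx[None, :] ** 2
    if density_sigma <= 0:
        raise ValueError("density_sigma must be positive")
    weights = np.exp(-d2 / (2 * density_sigma ** 2))
    weights[mask] = 0.0
    flat = weights.ravel()
    flat = flat / flat.sum()

    rng = np.random.default_rng(seed)
    extra = budget - n_center
    if extra > 0:
        idx = rng.choice(M * N, size=extra, replace=False, p=flat)
        mask.ravel()[idx] = True

    # masks are stored in FFT (unshifted) frequency order
    mask = np.fft.ifftshift(mask)
    return SamplingMask(mask=mask, factor=factor, trajectory="random2d",
                        center_fraction=center_fraction, seed=seed)


def _line_mask(n_lines: int, factor: float, center_lines: int,
               seed: int) -> np.ndarray:
    """Pick kept line indices (centered order): contiguous central block of
    ``center_lines`` plus a uniform random subset."""
    n_keep = max(1, int(round(n_lines / factor)))
    center_lines = min(center_lines, n_keep)
    keep = np.zeros(n_lines, dtype=bool)
    c0 = (n_lines - center_lines) // 2
    keep[c0:c0 + center_lines] = True
    remaining = n_keep - int(keep.sum())
    if remaining > 0:
        pool = np.flatnonzero(~keep)
        rng = np.random.default_rng(seed)
        keep[rng.choice(pool, size=remaining, replace=False)] = True
    return keep


def make_cartesian_mask(
    shape: tuple[int, int],
    factor: float,
    center_lines: int = 4,
    seed: int = 0,
) -> SamplingMask:
    """Row-wise undersampling: full frequency-encode lines kept or dropped,
    with ``center_lines`` contiguous central rows always kept."""
    M, N = shape
    _check_factor(shape, factor)
    keep = _line_mask(M, factor, center_lines, seed)
    mask = np.zeros((M, N), dtype=bool)
    mask[keep, :] = True
    mask = np.fft.ifftshift(mask, axes=0)
    return SamplingMask(mask=mask, factor=factor, trajectory="cartesian",
                        center_fraction=center_lines / M, seed=seed)


def make_phase_encode_mask(
    shape: tuple[int, int],
    factor: float,
    seed: int = 0,
    center_lines: int = 4,
) -> SamplingMask:
    """Column-wise (phase-encode) analogue of the Cartesian mask."""
    M, N = shape
    _check_factor(shape, factor)
    keep = _line_mask(N, factor, center_lines, seed)
    mask = np.zeros((M, N), dtype=bool)
    mask[:, keep] = True
    mask = np.fft.ifftshift(mask, axes=1)
    return SamplingMask(mask=mask, factor=factor, trajectory="phase_encode",
                        center_fraction=center_lines / N, seed=seed)


def make_mask(trajectory: str, shape: tuple[int, int], factor: float,
              seed: int = 0, **kwargs) -> SamplingMask:
    """Dispatch by trajectory name."""
    if trajectory == "random2d":
        return make_random2d_mask(shape, factor, seed=seed, **kwargs)
    if trajectory == "cartesian":
        return make_cartesian_mask(shape, factor, seed=seed, **kwargs)
    if trajectory == "phase_encode":
        return make_phase_encode_mask(shape, factor, seed=seed, **kwargs)
    raise ValueError(f"unknown trajectory {trajectory!r}")


# --------------------------------------------------------------------------
# partial Fourier operator
# --------------------------------------------------------------------------

def partial_fourier(image: np.ndarray, mask: SamplingMask) -> KSpaceData:
    """F_p u = mask * FFT(u), orthonormal convention."""
    image = np.asarray(image)
    if image.shape != mask.shape:
        raise ValueError(
            f"image shape {image.shape} does not match mask shape {mask.shape}"
        )
    return KSpaceData(values=mask.mask * np.fft.fft2(image, norm="ortho"))


def partial_fourier_adjoint(kspace: KSpaceData | np.ndarray,
                            mask: SamplingMask) -> np.ndarray:
    """F_p^H v = IFFT(zero-filled v); returns the complex image."""
    values = kspace.values if isinstance(kspace, KSpaceData) else np.asarray(kspace)
    if values.shape != mask.shape:
        raise ValueError(
            f"k-space shape {values.shape} does not match mask shape {mask.shape}"
        )
    return np.fft.ifft2(mask.mask * values, norm="ortho")
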