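"""Outer split-Bregman reconstruction loop and baselines.

The dictionary route alternates, from a zero-filled start:

    patches of u^k -> (re)train dictionary -> sparse-code -> closed-form
    image update -> additive residual feedback f^{k+1} = f^k + f - F_p u^{k+1}

The image subproblem

    min_u (beta/2) sum_i ||D a_i - R_i u||^2 + (mu/2)||F_p u - f^k||^2

is solved exactly in k-space: with periodic stride-1 patches
sum_i R_i^T R_i = p^2 I, so

    FFT(u) = (beta p^2 FFT(ubar) + mu mask*f^k) / (beta p^2 + mu mask)

where ubar is the patch-consensus image (overlap-averaged D Gamma).

A split-Bregman isotropic-TV solver and a zero-fill inverse serve as
baselines.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from . import sparse_model as sm
from .sampling import SamplingMask, partial_fourier
from .synthetic import KSpaceData


@dataclass
class ReconConfig:
    """Knobs of the dictionary reconstruction (all weights positive)."""

    mu: float = 300.0           # k-space data-consistency weight
    beta: float = 1.0           # split penalty / patch-fit weight
    lam: float = 0.1            # z-residual weight in the l1 coder
    mu_graph: float = 0.0       # graph-Laplacian coupling (0 disables graph)
    xi: float = 1.0             # dictionary gradient step scale
    n_outer: int = 15
    n_inner: int = 10
    n_ista: int = 5
    patch_size: int = 8
    n_atoms: int = 256
    sparsity_T: int = 8
    train_stride: int = 2
    dict_updates: int = 3
    coder: str = "omp"          # "omp" | "l1"
    dict_init: str = "dct"
    k_neighbors: int = 8
    kernel_sigma: Optional[float] = None
    tol: float = 1e-4
    seed: int = 0
    regularizer: str = "dictionary"   # "dictionary" | "tv"
    lambda_tv: float = 1.0

    def __post_init__(self):
        for name in ("mu", "beta", "lam", "xi"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.mu_graph < 0:
            raise ValueError("mu_graph must be nonnegative")
        if self.n_outer < 1:
            raise ValueError("n_outer must be at least 1")
        if self.coder not in ("omp", "l1"):
            raise ValueError(f"unknown coder {self.coder!r}")
        if self.regularizer not in ("dictionary", "tv"):
            raise ValueError(f"unknown regularizer {self.regularizer!r}")


@dataclass
class BregmanState:
    """Outer-loop state and per-iteration history."""

    u_k: np.ndarray
    f_k: np.ndarray
    k: int
    history: dict = field(default_factory=dict)
    f0: np.ndarray | None = None
    feedback_sum: np.ndarray | None = None


# --------------------------------------------------------------------------
# subproblems
# --------------------------------------------------------------------------

def zero_fill_baseline(kspace: KSpaceData, mask: SamplingMask) -> np.ndarray:
    """Real part of the inverse FFT of the zero-filled data."""
    values = kspace.values if isinstance(kspace, KSpaceData) else np.asarray(kspace)
    if values.shape != mask.shape:
        raise ValueError("k-space and mask shapes differ")
    return np.real(np.fft.ifft2(mask.mask * values, norm="ortho"))


def update_image(codes: sm.CodeMatrix, dictionary: sm.Dictionary,
                 patch_geometry: sm.PatchSet, f_k: np.ndarray,
                 mask: SamplingMask, mu: float, beta: float,
                 return_complex: bool = False) -> np.ndarray:
    """Closed-form minimizer of the patch-consensus + data-consistency
    quadratic (see module docstring).  Requires periodic stride-1 geometry
    so the patch normal matrix is p^2 I.

    The imaginary part of the minimizer is discarded unless
    ``return_complex`` is set (useful for verifying the k-space identity
    exactly)."""
    if mu == 0 and beta == 0:
        raise ValueError("mu and beta cannot both be zero (undetermined u)")
    if not (patch_geometry.periodic and patch_geometry.stride == 1):
        raise ValueError("update_image requires periodic stride-1 patches")
    p2 = patch_geometry.patch_dim
    recon_patches = dictionary.atoms @ codes.codes
    ubar = sm.reassemble_patches(patch_geometry, recon_patches)
    m = mask.mask
    num = beta * p2 * np.fft.fft2(ubar, norm="ortho") + mu * (m * f_k)
    den = beta * p2 + mu * m
    u = np.fft.ifft2(num / den, norm="ortho")
    if return_complex:
        return u
    imag_max = float(np.abs(u.imag).max())
    if imag_max > 1e-6:
        logging.getLogger(__name__).debug(
            "update_image: discarding imaginary part (max %.3g)", imag_max)
    return u.real


def bregman_feedback(f_k: np.ndarray, f_measured: np.ndarray,
                     u_next: np.ndarray, mask: SamplingMask) -> np.ndarray:
    """f^{k+1} = f^k + f - F_p u^{k+1}, supported on the mask only."""
    if f_k.shape != f_measured.shape or f_k.shape != mask.shape:
        raise ValueError("shape mismatch in bregman feedback")
    fp_u = partial_fourier(u_next, mask).values
    return mask.mask * (f_k + f_measured - fp_u)


# --------------------------------------------------------------------------
# dictionary-regularized reconstruction
# --------------------------------------------------------------------------

def reconstruct(kspace: KSpaceData, mask: SamplingMask,
                config: ReconConfig | None = None,
                reference: np.ndarray | None = None
                ) -> tuple[np.ndarray, BregmanState]:
    """Run the outer split-Bregman dictionary reconstruction.

    Parameters
    ----------
    kspace : KSpaceData
        Measured data (meaningful on the mask support).
    mask : SamplingMask
        k-space sampling pattern.
    config : ReconConfig
        Hyperparameters; defaults are suitable for 64-256 px phantoms.
    reference : ndarray, optional
        Ground-truth image; enables the per-iteration PSNR history.

    Returns
    -------
    (image, BregmanState)
        Final estimate clipped to [0, 255], plus the loop state/history.
    """
    cfg = config or ReconConfig()
    if cfg.regularizer == "tv":
        img = reconstruct_tv(kspace, mask, lambda_tv=cfg.lambda_tv, mu=cfg.mu,
                             n_outer=cfg.n_outer)
        state = BregmanState(u_k=img, f_k=mask.mask * kspace.values,
                             k=cfg.n_outer, history={})
        return img, state

    from .metrics import psnr  # local import: metrics depends on us too

    f_meas = mask.mask * kspace.values
    f_k = f_meas.copy()
    u = zero_fill_baseline(kspace, mask)
    p = cfg.patch_size

    D = sm.init_dictionary(p * p, cfg.n_atoms, method=cfg.dict_init,
                           seed=cfg.seed)
    history = {"objective": [], "data_resid": [], "rel_change": [], "psnr": []}
    feedback_sum = np.zeros_like(f_meas)

    for k in range(cfg.n_outer):
        # dictionary refresh on strided training patches (warm-started atoms)
        train = sm.extract_patches(u, p, stride=cfg.train_stride, periodic=True)
        for _ in range(cfg.dict_updates):
            t_codes = sm.sparse_code_omp(train, D, sparsity_T=cfg.sparsity_T)
            D = sm.update_dictionary(D, train, t_codes, xi=cfg.xi)

        patches = sm.extract_patches(u, p, stride=1, periodic=True)
        if cfg.coder == "l1":
            graph = None
            if cfg.mu_graph > 0:
                graph = sm.build_similarity_graph(
                    patches, k_neighbors=cfg.k_neighbors,
                    kernel_sigma=cfg.kernel_sigma)
            codes, _ = sm.sparse_code_bregman(
                patches, D, graph=graph, lam=cfg.lam, mu_graph=cfg.mu_graph,
                beta=cfg.beta, n_inner=cfg.n_inner, n_ista=cfg.n_ista)
        else:
            codes = sm.sparse_code_omp(patches, D, sparsity_T=cfg.sparsity_T)

        u_next = update_image(codes, D, patches, f_k, mask,
                              mu=cfg.mu, beta=cfg.beta)
        if not np.all(np.isfinite(u_next)):
            raise RuntimeError(
                f"non-finite image at outer iteration {k} (image update)")

        fp_u = partial_fourier(u_next, mask).values
        resid = float(np.linalg.norm(fp_u - f_meas))
        fit = float(np.linalg.norm(D.atoms @ codes.codes - patches.patches))
        history["objective"].append(0.5 * cfg.beta * fit ** 2
                                    + 0.5 * cfg.mu * resid ** 2)
        history["data_resid"].append(resid)
        denom = max(float(np.linalg.norm(u)), 1e-12)
        rel = float(np.linalg.norm(u_next - u)) / denom
        history["rel_change"].append(rel)
        if reference is not None:
            history["psnr"].append(psnr(reference, np.clip(u_next, 0, 255)))

        feedback_sum += mask.mask * (f_meas - fp_u)
        f_k = bregman_feedback(f_k, f_meas, u_next, mask)
        u = u_next
        if rel < cfg.tol:
            break

    # telescoping identity: sum_k (f - F_p u^k) == f^K - f^0 on the mask
    if not np.allclose(feedback_sum, f_k - f_meas, atol=1e-8):
        raise RuntimeError("bregman feedback telescoping identity violated")

    state = BregmanState(u_k=u, f_k=f_k, k=len(history["data_resid"]),
                         history=history, f0=f_meas,
                         feedback_sum=feedback_sum)
    return np.clip(u, 0.0, 255.0), state


# --------------------------------------------------------------------------
# total-variation baseline
# --------------------------------------------------------------------------

def _grad(u):
    return u - np.roll(u, 1, axis=0), u - np.roll(u, 1, axis=1)


def _div(gx, gy):
    return (np.roll(gx, -1, axis=0) - gx) + (np.roll(gy, -1, axis=1) - gy)


def reconstruct_tv(kspace: KSpaceData, mask: SamplingMask,
                   lambda_tv: float = 1.0, mu: float = 1000.0,
                   n_outer: int = 15, n_inner: int = 8,
                   beta_tv: float = 10.0) -> np.ndarray:
    """Split-Bregman isotropic-TV reconstruction with the same additive
    f-feedback outer loop.  ``lambda_tv = 0`` degenerates to the zero-filled
    data-consistency-only solution."""
    values = kspace.values if isinstance(kspace, KSpaceData) else np.asarray(kspace)
    if values.shape != mask.shape:
        raise ValueError("k-space and mask shapes differ")
    if lambda_tv < 0 or mu <= 0:
        raise ValueError("need lambda_tv >= 0 and mu > 0")
    if lambda_tv == 0:
        return zero_fill_baseline(kspace, mask)

    M, N = mask.shape
    m = mask.mask
    f_meas = m * values
    f_k = f_meas.copy()

    # periodic backward-difference symbol: |1 - e^{-i w}|^2 per axis
    wy = 2.0 * np.pi * np.fft.fftfreq(M)[:, None]
    wx = 2.0 * np.pi * np.fft.fftfreq(N)[None, :]
    lap_symbol = (2 - 2 * np.cos(wy)) + (2 - 2 * np.cos(wx))

    u = zero_fill_baseline(kspace, mask)
    dx = np.zeros((M, N)); dy = np.zeros((M, N))
    bx = np.zeros((M, N)); by = np.zeros((M, N))
    shrink = lambda_tv / beta_tv

    for _ in range(n_outer):
        for _ in range(n_inner):
            rhs = mu * (m * f_k) + beta_tv * np.fft.fft2(
                -_div(dx - bx, dy - by), norm="ortho")
            den = mu * m + beta_tv * lap_symbol
            u_hat = np.divide(rhs, den, out=np.zeros_like(rhs),
                              where=den > 1e-14)
            u = np.real(np.fft.ifft2(u_hat, norm="ortho"))
            gx, gy = _grad(u)
            sx, sy = gx + bx, gy + by
            mag = np.sqrt(sx ** 2 + sy ** 2)
            scale = np.maximum(mag - shrink, 0.0) / np.maximum(mag, 1e-14)
            dx, dy = scale * sx, scale * sy
            bx, by = sx - dx, sy - dy
        if not np.all(np.isfinite(u)):
            raise RuntimeError("non-finite image in TV reconstruction")
        f_k = bregman_feedback(f_k, f_meas, u, mask)

    return np.clip(u, 0.0, 255.0)
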