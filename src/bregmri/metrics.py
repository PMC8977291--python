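"""Image-quality evaluation: PSNR and the benchmark sweep.

PSNR uses a fixed 255 peak:

    PSNR = 10 log10( 255^2 M N / sum |u - f|^2 )  [dB]

so inputs are expected on (or rescaled to) the [0, 255] intensity scale.
Identical images return ``math.inf``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import reconstruction as rc
from . import sampling as sp
from . import synthetic as syn
from ._seeds import child_seed

logger = logging.getLogger(__name__)

BENCHMARK_COLUMNS = ["trajectory", "factor", "noise_sigma", "seed", "method",
                     "psnr_db", "n_iter", "error"]


def psnr(reference: np.ndarray, reconstruction: np.ndarray) -> float:
    """Peak signal-to-noise ratio in dB with a fixed 255 peak."""
    ref = np.asarray(reference, dtype=float)
    rec = np.asarray(reconstruction, dtype=float)
    if ref.shape != rec.shape:
        raise ValueError(
            f"shape mismatch: reference {ref.shape} vs reconstruction {rec.shape}"
        )
    err = np.sum((ref - rec) ** 2)
    if err == 0.0:
        return math.inf
    return 10.0 * math.log10(255.0 ** 2 * ref.size / err)


def rescale_to_255(image: np.ndarray) -> np.ndarray:
    """Affinely map an image onto [0, 255] (logged); constant images map to 0."""
    image = np.asarray(image, dtype=float)
    lo, hi = float(image.min()), float(image.max())
    if hi == lo:
        logger.info("rescale_to_255: constant image (value %g) mapped to 0", lo)
        return np.zeros_like(image)
    logger.info("rescale_to_255: original range [%g, %g]", lo, hi)
    return (image - lo) * (255.0 / (hi - lo))


@dataclass
class BenchmarkResult:
    """Tidy table of benchmark rows (one per sweep cell)."""

    table: pd.DataFrame

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def run_benchmark(
    phantom: syn.Phantom,
    trajectories=("random2d",),
    factors=(2.5, 4.0),
    noise_sigmas=(0.0,),
    methods=("dictionary", "tv", "zero_fill"),
    seeds=(0,),
    recon_config: rc.ReconConfig | None = None,
    tv_lambda: float = 2.0,
) -> BenchmarkResult:
    """Full-factorial PSNR sweep over trajectories x factors x noise x
    methods x seeds.  Any failing cell is recorded with its error message
    and the sweep continues."""
    unknown = set(methods) - {"dictionary", "tv", "zero_fill"}
    if unknown:
        raise ValueError(f"unknown methods: {sorted(unknown)}")

    ref = phantom.image
    clean = syn.simulate_kspace(ref)
    rows = []
    for traj in trajectories:
        for factor in factors:
            for sigma in noise_sigmas:
                for seed in seeds:
                    mask = sp.make_mask(traj, ref.shape, factor,
                                        seed=child_seed(seed, "mask", traj, factor))
                    data = syn.add_gaussian_noise(
                        clean, sigma, seed=child_seed(seed, "noise", traj,
                                                      factor, sigma))
                    data = syn.KSpaceData(values=mask.mask * data.values)
                    for method in methods:
                        row = {"trajectory": traj, "factor": factor,
                               "noise_sigma": sigma, "seed": seed,
                               "method": method, "psnr_db": np.nan,
                               "n_iter": 0, "error": ""}
                        try:
                            if method == "zero_fill":
                                img = rc.zero_fill_baseline(data, mask)
                                n_iter = 0
                            elif method == "tv":
                                cfg = recon_config or rc.ReconConfig()
                                img = rc.reconstruct_tv(
                                    data, mask, lambda_tv=tv_lambda,
                                    mu=cfg.mu, n_outer=cfg.n_outer)
                                n_iter = cfg.n_outer
                            else:
                                img, state = rc.reconstruct(
                                    data, mask, config=recon_config)
                                n_iter = state.k
                            row["psnr_db"] = psnr(ref, np.clip(img, 0, 255))
                            row["n_iter"] = n_iter
                        except Exception as exc:  # flagged row, keep sweeping
                            row["error"] = f"{type(exc).__name__}: {exc}"
                            logger.warning("benchmark cell failed: %s", row)
                        rows.append(row)
    return BenchmarkResult(table=pd.DataFrame(rows, columns=BENCHMARK_COLUMNS))
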