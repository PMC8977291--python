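"""On-disk formats: PNG / NIfTI images, CSV tables, YAML configs, and a
named-array container for k-space data, masks and dictionaries."""

from __future__ import annotations

import json
import logging
from dataclasses import asdict
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml
from PIL import Image

from .diagnostics import COHORT_COLUMNS, validate_cohort_table
from .reconstruction import ReconConfig

logger = logging.getLogger(__name__)


# --------------------------------------------------------------------------
# images
# --------------------------------------------------------------------------

def read_image(path) -> np.ndarray:
    """Read an 8-bit grayscale PNG or a single NIfTI slice as a float image
    on the [0, 255] scale."""
    path = Path(path)
    suffixes = "".join(path.suffixes).lower()
    if path.suffix.lower() == ".png":
        with Image.open(path) as im:
            return np.asarray(im.convert("L"), dtype=float)
    if suffixes.endswith((".nii", ".nii.gz")):
        data = np.asanyarray(nib.load(str(path)).dataobj).squeeze()
        if data.ndim == 3:
            data = data[:, :, data.shape[2] // 2]
        if data.ndim != 2:
            raise ValueError(f"expected a 2D NIfTI slice, got shape {data.shape}")
        data = data.astype(float)
        lo, hi = float(data.min()), float(data.max())
        logger.info("NIfTI %s original range [%g, %g]; rescaled to [0, 255]",
                    path, lo, hi)
        if hi > lo:
            data = (data - lo) * (255.0 / (hi - lo))
        else:
            data = np.zeros_like(data)
        return data
    raise ValueError(f"unsupported image format {path.suffix!r} (PNG or NIfTI)")


def write_image(image: np.ndarray, path) -> None:
    """Write an image: PNG gets rounded uint8 [0, 255]; NIfTI keeps floats."""
    path = Path(path)
    image = np.asarray(image, dtype=float)
    suffixes = "".join(path.suffixes).lower()
    if path.suffix.lower() == ".png":
        u8 = np.clip(np.rint(image), 0, 255).astype(np.uint8)
        Image.fromarray(u8, mode="L").save(path)
        return
    if suffixes.endswith((".nii", ".nii.gz")):
        nib.save(nib.Nifti1Image(image.astype(np.float64), np.eye(4)), str(path))
        return
    raise ValueError(f"unsupported image format {path.suffix!r} (PNG or NIfTI)")


# --------------------------------------------------------------------------
# named-array container (k-space, masks, dictionaries)
# --------------------------------------------------------------------------

def save_arrays(path, roles: dict[str, str] | None = None, **arrays) -> None:
    """Save named arrays to a compressed .npz with a JSON manifest recording
    shape, dtype and an optional semantic role per entry."""
    manifest = {
        name: {"shape": list(np.asarray(a).shape),
               "dtype": str(np.asarray(a).dtype),
               "role": (roles or {}).get(name, "")}
        for name, a in arrays.items()
    }
    np.savez_compressed(path, __manifest__=np.frombuffer(
        json.dumps(manifest).encode(), dtype=np.uint8), **arrays)


def load_arrays(path) -> tuple[dict[str, np.ndarray], dict]:
    """Load a named-array container; returns (arrays, manifest)."""
    with np.load(path) as z:
        arrays = {k: z[k] for k in z.files if k != "__manifest__"}
        manifest = {}
        if "__manifest__" in z.files:
            manifest = json.loads(z["__manifest__"].tobytes().decode())
    for name, meta in manifest.items():
        if name in arrays and list(arrays[name].shape) != meta["shape"]:
            raise ValueError(f"manifest/shape mismatch for entry {name!r}")
    return arrays, manifest


def save_dictionary(dictionary, path, patch_size: int | None = None,
                    provenance: str = "") -> None:
    """Serialize a Dictionary to the array container with a JSON sidecar
    describing patch size, overcompleteness and provenance."""
    from .sparse_model import Dictionary  # local: avoid import cycle at load

    assert isinstance(dictionary, Dictionary)
    atoms = dictionary.atoms
    save_arrays(path, roles={"atoms": "dictionary atoms (columns)"},
                atoms=atoms)
    p = patch_size or int(round(atoms.shape[0] ** 0.5))
    sidecar = {"patch_size": p, "patch_dim": atoms.shape[0],
               "n_atoms": atoms.shape[1],
               "overcompleteness": atoms.shape[1] / atoms.shape[0],
               "provenance": provenance}
    with open(str(path) + ".json", "w") as fh:
        json.dump(sidecar, fh, indent=2)


def load_dictionary(path):
    """Load a Dictionary written by :func:`save_dictionary`."""
    from .sparse_model import Dictionary

    arrays, _ = load_arrays(path)
    if "atoms" not in arrays:
        raise ValueError(f"{path} has no 'atoms' entry")
    return Dictionary(atoms=arrays["atoms"])


# --------------------------------------------------------------------------
# tables
# --------------------------------------------------------------------------

def read_table(path, kind: str = "cohort") -> pd.DataFrame:
    """Read a schema-validated CSV table (``kind`` in {cohort, benchmark}).
    Extra columns pass through untouched."""
    path = Path(path)
    if path.stat().st_size == 0:
        raise ValueError(f"empty table file: {path}")
    table = pd.read_csv(path)
    if table.empty:
        raise ValueError(f"table has no data rows: {path}")
    if kind == "cohort":
        try:
            validate_cohort_table(table)
        except ValueError as exc:
            raise ValueError(f"{path}: {exc}") from exc
    elif kind == "benchmark":
        from .metrics import BENCHMARK_COLUMNS
        missing = [c for c in BENCHMARK_COLUMNS if c not in table.columns
                   and c != "error"]
        if missing:
            raise ValueError(f"{path}: benchmark table missing columns {missing}")
    else:
        raise ValueError(f"unknown table kind {kind!r}")
    return table


def write_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False)


# --------------------------------------------------------------------------
# config
# --------------------------------------------------------------------------

def read_recon_config(path) -> ReconConfig:
    """Load a ReconConfig from a YAML mapping (unknown keys rejected)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    valid = set(ReconConfig.__dataclass_fields__)
    unknown = set(raw) - valid
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return ReconConfig(**raw)


def write_recon_config(config: ReconConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(asdict(config), fh, sort_keys=True)
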