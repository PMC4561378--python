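"""Readers, writers and run configuration.

Images are read with imageio (PNG/TIFF, 8- or 16-bit) and rescaled to
[0, 1] by the dtype maximum; masks are written as 8-bit PNGs with values
{0, 255}; contours and descriptors travel as plain CSV; run configuration
round-trips through YAML.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass

import imageio.v3 as iio
import numpy as np
import pandas as pd
import yaml

from .errors import ParameterError
from .initcontour import Contour, manual_contour
from .shapedesc import ShapeDescriptors

__all__ = [
    "read_image",
    "write_image",
    "write_mask_png",
    "read_contour_csv",
    "write_contour_csv",
    "write_descriptors_csv",
    "RunConfig",
]


def read_image(path) -> np.ndarray:
    """Load a grayscale image and rescale to [0, 1] by the dtype maximum."""
    try:
        a = iio.imread(path)
    except Exception as exc:
        raise ParameterError(f"cannot read image {path}: {exc}") from exc
    if a.ndim == 3:
        if a.shape[2] not in (1, 3, 4):
            raise ParameterError(f"unsupported image shape {a.shape}")
        a = a[..., :3].mean(axis=2) if a.shape[2] > 1 else a[..., 0]
    if np.issubdtype(a.dtype, np.integer):
        a = a.astype(float) / np.iinfo(a.dtype).max
    else:
        a = a.astype(float)
        if a.max() > 1.0:
            a = a / a.max()
    return np.clip(a, 0.0, 1.0)


def write_image(img, path):
    """Save a [0, 1] float image as 16-bit TIFF/PNG."""
    a = np.clip(np.asarray(img, dtype=float), 0, 1)
    iio.imwrite(path, (a * 65535).astype(np.uint16))


def write_mask_png(mask, path):
    """Save a binary mask as an 8-bit {0, 255} PNG."""
    iio.imwrite(path, np.where(np.asarray(mask).astype(bool), 255, 0).astype(np.uint8))


def read_contour_csv(path) -> Contour:
    """Read a closed contour from a CSV with header ``x,y``.

    Extra columns are ignored with a warning; fewer than 3 rows or
    unparseable cells raise a parse error naming the line.
    """
    try:
        df = pd.read_csv(path)
    except Exception as exc:
        raise ParameterError(f"cannot parse contour CSV {path}: {exc}") from exc
    if "x" not in df.columns or "y" not in df.columns:
        raise ParameterError(f"{path}: contour CSV must have 'x' and 'y' columns")
    extra = [c for c in df.columns if c not in ("x", "y")]
    if extra:
        warnings.warn(f"{path}: ignoring extra columns {extra}", stacklevel=2)
    for col in ("x", "y"):
        bad = pd.to_numeric(df[col], errors="coerce").isna()
        if bad.any():
            line = int(bad.idxmax()) + 2  # header is line 1
            raise ParameterError(f"{path}: malformed value in column {col}, line {line}")
    if len(df) < 3:
        raise ParameterError(f"{path}: need at least 3 contour points")
    return manual_contour(df[["x", "y"]].to_numpy(dtype=float))


def write_contour_csv(contour: Contour, path):
    pd.DataFrame(contour.points, columns=["x", "y"]).to_csv(path, index=False)


def write_descriptors_csv(desc: ShapeDescriptors, path):
    """One-row CSV: area, F1, F2, F3, SC, SR, FD_1..FD_k."""
    row = {"area": desc.area, "F1": desc.f1, "F2": desc.f2, "F3": desc.f3,
           "SC": desc.sc, "SR": desc.sr}
    row.update({f"FD_{i + 1}": v for i, v in enumerate(desc.fd)})
    pd.DataFrame([row]).to_csv(path, index=False)


@dataclass
class RunConfig:
    """Full-pipeline configuration; round-trips losslessly through YAML."""

    model: str = "chanvese"
    lam: float = 0.05
    gamma: float = 10.0
    sigma: float = 1.5
    n_levels: int = 24
    n_sigma: int = 1
    rays: int = 360
    mu: float = 0.2
    nu: float = 0.0
    lam1: float = 2.5
    lam2: float = 1.0
    alpha: float = 5.0
    fill_holes: bool = False
    out_dir: str = "."
    verbosity: str = "info"

    def __post_init__(self):
        if self.model not in ("chanvese", "spf"):
            raise ParameterError("model must be 'chanvese' or 'spf'")
        if self.n_sigma not in (1, 2):
            raise ParameterError("n_sigma must be 1 or 2")

    def to_yaml(self, path):
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ParameterError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)
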