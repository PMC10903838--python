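"""Movement visualisation: HSV colour maps and quiver maps of a slice.

The HSV map encodes the three displacement components of each lung voxel:
hue from |dx| (left-right), saturation from |dy| (anterior-posterior) and
value from |dz| (inferior-superior), each normalized by ``dmax_mm`` and
clamped at 1. Non-lung voxels show the anatomical background in greyscale.
Rendering is deterministic: identical inputs give byte-identical PNGs.
"""

from __future__ import annotations

from dataclasses import dataclass

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
from matplotlib.colors import hsv_to_rgb
from PIL import Image

from .core_io import LabelMap, Volume3D
from .errors import ValidationError
from .register_deformable import DisplacementField

_AXES = {"x": 0, "y": 1, "z": 2}


@dataclass(frozen=True)
class VizConfig:
    slice_axis: str = "z"
    slice_fraction: float = 0.5
    slice_index: int | None = None
    dmax_mm: float = 30.0     # colour-scale saturation point
    quiver_stride: int = 6
    output_dpi: int = 150

    def __post_init__(self):
        if self.slice_axis not in _AXES:
            raise ValidationError("slice_axis must be one of x, y, z")
        if self.dmax_mm <= 0:
            raise ValidationError("dmax_mm must be positive")
        if self.quiver_stride < 1:
            raise ValidationError("quiver_stride must be >= 1")


def _slice_index(cfg: VizConfig, n: int) -> int:
    idx = cfg.slice_index if cfg.slice_index is not None else int(round(cfg.slice_fraction * (n - 1)))
    if not 0 <= idx < n:
        raise ValidationError(f"slice index {idx} outside volume (axis size {n})")
    return idx


def _take_slice(arr: np.ndarray, axis: int, idx: int) -> np.ndarray:
    return np.take(arr, idx, axis=axis)


def hsv_movement_map(field: DisplacementField, mask: LabelMap, cfg: VizConfig | None = None,
                     background: Volume3D | None = None, out_path=None) -> np.ndarray:
    """RGB image of per-voxel movement on one slice (H=|dx|, S=|dy|, V=|dz|).

    Returns the float RGB array (rows = first remaining axis); optionally
    writes a PNG. Zero movement renders lung voxels black (V = 0); pure
    z-motion at ``dmax_mm`` renders them white.
    """
    cfg = cfg or VizConfig()
    if not field.grid.approx_equal(mask.grid):
        raise ValidationError("field and mask must share a grid")
    ax = _AXES[cfg.slice_axis]
    idx = _slice_index(cfg, field.grid.shape[ax])
    comp = [np.abs(_take_slice(field.vectors[..., c], ax, idx)) for c in range(3)]
    lung = _take_slice(mask.lung_mask(), ax, idx)
    h = np.clip(comp[0] / cfg.dmax_mm, 0.0, 1.0)
    s = np.clip(comp[1] / cfg.dmax_mm, 0.0, 1.0)
    v = np.clip(comp[2] / cfg.dmax_mm, 0.0, 1.0)
    rgb = hsv_to_rgb(np.stack([h, s, v], axis=-1))
    if background is not None:
        bg = _take_slice(np.asarray(background.values, dtype=np.float64), ax, idx)
        lo, hi = (-1024.0, 600.0) if background.unit_tag == "HU" else (bg.min(), max(bg.max(), bg.min() + 1e-6))
        grey = np.clip((bg - lo) / (hi - lo), 0.0, 1.0)
    else:
        grey = np.zeros(lung.shape)
    out = np.where(lung[..., None], rgb, grey[..., None])
    if out_path is not None:
        Image.fromarray((np.clip(out, 0, 1) * 255).round().astype(np.uint8)).save(out_path, format="PNG")
    return out


def quiver_map(field: DisplacementField, mask: LabelMap, cfg: VizConfig | None = None,
               out_path=None):
    """Quiver plot of the in-plane displacement components on one slice.

    Arrows are drawn at every ``quiver_stride``-th lung voxel, with length
    proportional to millimetres and a reference arrow in the legend.
    """
    cfg = cfg or VizConfig()
    if not field.grid.approx_equal(mask.grid):
        raise ValidationError("field and mask must share a grid")
    ax_i = _AXES[cfg.slice_axis]
    idx = _slice_index(cfg, field.grid.shape[ax_i])
    plane_axes = [a for a in range(3) if a != ax_i]
    lung = _take_slice(mask.lung_mask(), ax_i, idx)
    u = _take_slice(field.vectors[..., plane_axes[0]], ax_i, idx)
    v = _take_slice(field.vectors[..., plane_axes[1]], ax_i, idx)
    stride = cfg.quiver_stride
    rr, cc = np.meshgrid(np.arange(lung.shape[0]), np.arange(lung.shape[1]), indexing="ij")
    sel = lung & (rr % stride == 0) & (cc % stride == 0)
    fig, axp = plt.subplots(figsize=(6, 6), dpi=cfg.output_dpi)
    q = axp.quiver(cc[sel], rr[sel], v[sel], u[sel], angles="xy", scale_units="xy", scale=1.0,
                   width=0.003, color="tab:red")
    axp.quiverkey(q, 0.9, 1.02, 10.0, "10 mm", labelpos="E")
    axp.set_xlim(-0.5, lung.shape[1] - 0.5)
    axp.set_ylim(lung.shape[0] - 0.5, -0.5)
    axp.set_aspect("equal")
    names = ["x", "y", "z"]
    axp.set_xlabel(f"{names[plane_axes[1]]} (voxels)")
    axp.set_ylabel(f"{names[plane_axes[0]]} (voxels)")
    axp.set_title(f"In-plane lung movement, {cfg.slice_axis}-slice {idx}")
    if out_path is not None:
        fig.savefig(out_path, dpi=cfg.output_dpi, metadata={"Software": None})
    plt.close(fig)
    return fig
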