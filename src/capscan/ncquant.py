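"""Nuclear/cytoplasmic intensity ratio quantification.

The in-vivo binding read-out: a fluorescent nanobody fusion co-expressed with
a nuclear-anchored antigen accumulates in the nucleus when it binds, so the
ratio of background-subtracted mean nuclear intensity to mean cytoplasmic
intensity (N/C) reports binding — near 1 for a non-binder, elevated for a
binder.  Masks are inputs (segmentation is out of scope); the cytoplasm of a
cell is its cell mask minus its nucleus mask.

A synthetic-cell generator (concentric discs, controllable true ratio and
noise) closes the loop for testing: at zero noise the measured ratio equals
the generating ratio exactly.
"""

from __future__ import annotations

import dataclasses

import numpy as np

__all__ = ["CellMeasurement", "compute_nc_ratio", "generate_synthetic_cell"]


@dataclasses.dataclass
class CellMeasurement:
    cell_id: int
    nuc_mean: float
    cyto_mean: float
    nc_ratio: float
    n_pixels_nuc: int
    n_pixels_cyto: int


def _background_value(image: np.ndarray, cell_mask: np.ndarray, background) -> float:
    if isinstance(background, (int, float)):
        if background < 0:
            raise ValueError("background must be >= 0")
        return float(background)
    if background == "outside-cells-median":
        outside = image[cell_mask == 0]
        if outside.size == 0:
            raise ValueError("no pixels outside cells for background estimation")
        return float(np.median(outside))
    if background == "mode":
        vals, counts = np.unique(np.round(image).astype(np.int64), return_counts=True)
        return float(vals[np.argmax(counts)])
    raise ValueError(f"unknown background spec {background!r}")


def compute_nc_ratio(
    image: np.ndarray,
    nucleus_mask: np.ndarray,
    cell_mask: np.ndarray,
    background="outside-cells-median",
) -> list[CellMeasurement]:
    """Per-cell background-subtracted N/C mean intensity ratios.

    ``nucleus_mask`` and ``cell_mask`` are integer label arrays sharing the
    image shape; every nucleus label must lie within exactly one cell label
    and every cell must retain a non-empty cytoplasm (cell minus nuclei).
    """
    image = np.asarray(image, dtype=float)
    nucleus_mask = np.asarray(nucleus_mask)
    cell_mask = np.asarray(cell_mask)
    if not (image.shape == nucleus_mask.shape == cell_mask.shape):
        raise ValueError("image and masks must share one shape")
    if image.ndim != 2:
        raise ValueError("only 2-D single-channel images are supported")

    bg = _background_value(image, cell_mask, background)
    corrected = np.clip(image - bg, 0.0, None)

    # map each nucleus to its unique parent cell
    nucleus_of_cell: dict[int, np.ndarray] = {}
    for nuc_label in np.unique(nucleus_mask):
        if nuc_label == 0:
            continue
        npix = nucleus_mask == nuc_label
        parents = np.unique(cell_mask[npix])
        if len(parents) != 1 or parents[0] == 0:
            raise ValueError(
                f"nucleus label {int(nuc_label)} does not lie within exactly one cell"
            )
        cell = int(parents[0])
        nucleus_of_cell[cell] = nucleus_of_cell.get(cell, np.zeros_like(npix)) | npix

    out: list[CellMeasurement] = []
    for cell_label in np.unique(cell_mask):
        if cell_label == 0:
            continue
        cell = int(cell_label)
        if cell not in nucleus_of_cell:
            continue  # cell without a nucleus mask: nothing to measure
        nuc = nucleus_of_cell[cell]
        cyto = (cell_mask == cell_label) & ~nuc
        if not cyto.any():
            raise ValueError(f"cell {cell}: nucleus covers the entire cell")
        nuc_mean = float(corrected[nuc].mean())
        cyto_mean = float(corrected[cyto].mean())
        out.append(
            CellMeasurement(
                cell_id=cell,
                nuc_mean=nuc_mean,
                cyto_mean=cyto_mean,
                nc_ratio=nuc_mean / cyto_mean,
                n_pixels_nuc=int(nuc.sum()),
                n_pixels_cyto=int(cyto.sum()),
            )
        )
    return out


def generate_synthetic_cell(
    true_nc: float,
    nuc_radius: int = 13,
    cell_radius: int = 40,
    base_intensity: float = 100.0,
    background: float = 10.0,
    noise: str | tuple[str, float] = "none",
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Concentric-disc synthetic cell with a known true N/C ratio.

    Cytoplasm intensity = base, nucleus = base * true_nc, plus a uniform
    background, plus optional noise: ``"none"``, ``("gaussian", sigma)`` or
    ``"poisson"``.  Reproducible per seed.  Returns (image, nucleus_mask,
    cell_mask).
    """
    if nuc_radius >= cell_radius:
        raise ValueError("nuc_radius must be smaller than cell_radius")
    if true_nc < 1:
        raise ValueError("true_nc must be >= 1")
    size = 2 * cell_radius + 11
    yy, xx = np.mgrid[:size, :size]
    c = size // 2
    r2 = (yy - c) ** 2 + (xx - c) ** 2
    cell_mask = (r2 <= cell_radius**2).astype(np.int32)
    nucleus_mask = (r2 <= nuc_radius**2).astype(np.int32)

    image = np.full((size, size), float(background))
    image[cell_mask == 1] += base_intensity
    image[nucleus_mask == 1] += base_intensity * (true_nc - 1.0)

    rng = np.random.default_rng(seed)
    if noise == "none":
        pass
    elif noise == "poisson":
        image = rng.poisson(image).astype(float)
    elif isinstance(noise, tuple) and noise[0] == "gaussian":
        image = image + rng.normal(0.0, float(noise[1]), image.shape)
    else:
        raise ValueError(f"unknown noise spec {noise!r}")
    return image, nucleus_mask, cell_mask
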