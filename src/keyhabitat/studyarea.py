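"""Study-area delineation: resample layers, binarize by suitability
intervals, and intersect the resulting masks.

The study area acts as a proxy Extent of Occurrence: each environmental
layer is reduced to a {0,1} suitability mask over a closed value interval
and the masks are overlaid (cellwise product).
"""

from __future__ import annotations

from collections.abc import Sequence

import numpy as np

from .grid import BinaryMask, GeometryError, GridLayer

#: Default suitability intervals (closed on both ends).
DEFAULT_BOUNDS = {
    "ELEV": (200.0, 1500.0),
    "TREE": (10.0, 100.0),
    "AI": (2000.0, 6500.0),
}


def resample_nearest(layer: GridLayer, target_cell: float) -> GridLayer:
    """Nearest-neighbour resampling by centering.

    Each output cell takes the value of the input cell that contains the
    output cell's center point. Cells are half-open ``[x, x+w)``, so a
    center falling exactly on a cell edge resolves to the larger index.
    ``target_cell`` must be an integer multiple (aggregation) or integer
    divisor (disaggregation) of the input cell size.
    """
    cs = layer.cell_size
    if np.isclose(target_cell, cs):
        return layer.with_values(layer.values.copy())
    if target_cell > cs:
        factor = target_cell / cs
        if not np.isclose(factor, round(factor)):
            raise ValueError(
                f"target cell {target_cell} is not a multiple of {cs}")
        f = int(round(factor))
        nr, nc = layer.shape
        if nr % f or nc % f:
            raise ValueError(
                f"grid shape {layer.shape} not divisible by factor {f}")
        out_shape = (nr // f, nc // f)
    else:
        factor = cs / target_cell
        if not np.isclose(factor, round(factor)):
            raise ValueError(
                f"target cell {target_cell} is not a divisor of {cs}")
        f = int(round(factor))
        out_shape = (layer.shape[0] * f, layer.shape[1] * f)

    scale = target_cell / cs
    rows = np.floor((np.arange(out_shape[0]) + 0.5) * scale).astype(int)
    cols = np.floor((np.arange(out_shape[1]) + 0.5) * scale).astype(int)
    rows = np.clip(rows, 0, layer.shape[0] - 1)
    cols = np.clip(cols, 0, layer.shape[1] - 1)
    values = layer.values[np.ix_(rows, cols)]
    return GridLayer(values.copy(), target_cell, layer.origin, layer.nodata)


def binarize(layer: GridLayer, lo: float, hi: float) -> BinaryMask:
    """1 where ``lo <= value <= hi`` (closed interval), else 0; nodata → 0."""
    if lo > hi:
        raise ValueError(f"lo ({lo}) must not exceed hi ({hi})")
    ok = layer.mask & (layer.values >= lo) & (layer.values <= hi)
    return BinaryMask(ok.astype(np.uint8), layer.cell_size, layer.origin)


def intersect(masks: Sequence[BinaryMask]) -> BinaryMask:
    """Cellwise product of masks sharing one grid geometry."""
    if not masks:
        raise ValueError("need at least one mask")
    first = masks[0]
    out = first.values.astype(np.uint8).copy()
    for m in masks[1:]:
        first.require_same_geometry(m)
        out &= m.values
    return BinaryMask(out, first.cell_size, first.origin)


def delineate_study_area(
    layers: dict[str, GridLayer],
    bounds: dict[str, tuple[float, float]] | None = None,
    target_cell: float | None = None,
) -> BinaryMask:
    """Resample the named layers to a common cell size, binarize each by its
    interval, and intersect. ``bounds`` defaults to :data:`DEFAULT_BOUNDS`.
    """
    bounds = dict(DEFAULT_BOUNDS if bounds is None else bounds)
    missing = set(bounds) - set(layers)
    if missing:
        raise KeyError(f"missing layers for study-area bounds: {sorted(missing)}")
    masks = []
    for name, (lo, hi) in bounds.items():
        layer = layers[name]
        if target_cell is not None and not np.isclose(layer.cell_size, target_cell):
            layer = resample_nearest(layer, target_cell)
        masks.append(binarize(layer, lo, hi))
    for m in masks[1:]:
        if not masks[0].same_geometry(m):
            raise GeometryError("study-area layers do not share a geometry "
                                "after resampling")
    return intersect(masks)
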