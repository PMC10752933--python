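"""Parkes (consensus) error grid analysis for glucose forecasts.

The grid partitions the (reference, prediction) plane into zones of
increasing clinical risk: A — no effect on clinical action; B — altered
clinical action with little or no effect on outcome; C — likely to affect
outcome; D — could have significant medical risk; E — could have dangerous
consequences.

Zone boundaries use the published consensus vertex coordinates for type 1
diabetes (mg/dl), widely reproduced from the digitisation by Pfützner and
colleagues (J Diabetes Sci Technol, 2013). Glucose in mmol/l is converted
with the molar-mass factor 18.016 mg/dl per mmol/l. The published polylines
end at 550 mg/dl; terminal segments are extended along their final slope so
that any value up to the sensor saturation limit (33.3 mmol/l ≈ 600 mg/dl)
classifies. Boundary points belong to the safer zone.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np

MGDL_PER_MMOLL = 18.016

#: Classification bounding box, mg/dl (covers the sensor saturation limit).
_BOX = 630.0

# Boundary polylines for the type-1 grid, mg/dl, axes (reference, prediction).
# "Upper" lines (overestimation side) are functions y(x); "lower" lines
# (underestimation side) are functions x(y).
_TYPE1_UPPER = {
    "B": [(0, 50), (30, 50), (140, 170), (280, 380), (430, 550)],
    "C": [(0, 60), (30, 60), (50, 80), (70, 110), (260, 550)],
    "D": [(0, 100), (25, 100), (50, 125), (80, 215), (125, 550)],
    "E": [(0, 150), (35, 155), (50, 550)],
}
_TYPE1_LOWER = {
    "B": [(50, 0), (50, 30), (170, 145), (385, 300), (550, 450)],
    "C": [(120, 0), (120, 30), (260, 130), (550, 250)],
    "D": [(250, 0), (250, 40), (550, 150)],
}

ZONES = ("A", "B", "C", "D", "E")


def _extend(points: list[tuple[float, float]]) -> tuple[np.ndarray, np.ndarray]:
    """Extend the final segment of a polyline to the bounding box."""
    xs = np.array([p[0] for p in points], dtype=float)
    ys = np.array([p[1] for p in points], dtype=float)
    dx, dy = xs[-1] - xs[-2], ys[-1] - ys[-2]
    scale = 0.0
    if dx > 0:
        scale = max(scale, (_BOX - xs[-1]) / dx)
    if dy > 0:
        scale = max(scale, (_BOX - ys[-1]) / dy)
    if scale > 0:
        xs = np.append(xs, xs[-1] + scale * dx)
        ys = np.append(ys, ys[-1] + scale * dy)
    return xs, ys


@lru_cache(maxsize=None)
def _zone_polygons(grid_kind: str = "type1"):
    """Shapely polygons per zone (A..D explicit; E is the complement).

    Each cumulative region {A}, {A,B}, {A,B,C} is the set below its upper
    boundary line and left of its lower boundary line inside the box; the
    zone polygons are the differences of successive cumulative regions.
    """
    if grid_kind != "type1":
        raise ValueError(f"unsupported grid kind {grid_kind!r}")
    from shapely.geometry import Polygon, box
    from shapely.prepared import prep

    frame = box(0.0, 0.0, _BOX, _BOX)

    def cumulative(upper_key: str, lower_key: str | None):
        ux, uy = _extend(_TYPE1_UPPER[upper_key])
        # region below the upper line: upper polyline, then down the right
        # or along the top edge back to the origin
        pts = list(zip(ux, uy))
        if pts[-1][1] >= _BOX:  # exits through the top: include top-right area
            pts += [(_BOX, _BOX)]
        pts += [(_BOX, 0.0), (0.0, 0.0)]
        below_upper = Polygon(pts).buffer(0)
        region = frame.intersection(below_upper)
        if lower_key is not None:
            lx, ly = _extend(_TYPE1_LOWER[lower_key])
            pts = list(zip(lx, ly))
            if pts[-1][0] >= _BOX:
                pts += [(_BOX, _BOX)]
            pts += [(0.0, _BOX), (0.0, 0.0)]
            left_of_lower = Polygon(pts).buffer(0)
            region = region.intersection(left_of_lower)
        return region

    reg_a = cumulative("B", "B")
    reg_ab = cumulative("C", "C")
    reg_abc = cumulative("D", "D")
    reg_abcd = cumulative("E", None)
    polys = {"A": reg_a, "B": reg_ab, "C": reg_abc, "D": reg_abcd}
    return {k: prep(v) for k, v in polys.items()}, polys


def parkes_zone(
    reference: float, prediction: float, grid_kind: str = "type1"
) -> str:
    """Zone letter for a single (reference, prediction) pair in mmol/l."""
    return parkes_zones(
        np.array([reference]), np.array([prediction]), grid_kind
    )[0]


def parkes_zones(
    references: np.ndarray, predictions: np.ndarray, grid_kind: str = "type1"
) -> np.ndarray:
    """Vectorised zone assignment; inputs in mmol/l.

    Cumulative regions are tested from safest outward, so points on a
    boundary land in the safer zone.
    """
    references = np.asarray(references, dtype=float)
    predictions = np.asarray(predictions, dtype=float)
    if references.shape != predictions.shape:
        raise ValueError("reference and prediction arrays differ in shape")
    if np.any(references <= 0) or np.any(predictions <= 0):
        raise ValueError("glucose values must be positive")
    if np.any(references > 33.3 + 1e-9) or np.any(predictions > 33.3 + 1e-9):
        raise ValueError("glucose values above the 33.3 mmol/l sensor limit")
    from shapely.geometry import Point

    prepared, _ = _zone_polygons(grid_kind)
    x = references * MGDL_PER_MMOLL
    y = predictions * MGDL_PER_MMOLL
    out = np.full(references.shape, "E", dtype="<U1")
    flat_x, flat_y = x.ravel(), y.ravel()
    flat_out = out.ravel()
    for i in range(flat_x.size):
        p = Point(flat_x[i], flat_y[i])
        for zone in ("A", "B", "C", "D"):
            if prepared[zone].covers(p):
                flat_out[i] = zone
                break
    return flat_out.reshape(references.shape)


def parkes_report(
    references: np.ndarray,
    predictions: np.ndarray,
    *,
    grid_kind: str = "type1",
    plot_path=None,
    title: str | None = None,
) -> dict[str, float]:
    """Percentage of predictions per zone (two decimals), optionally with a
    scatter-over-grid figure written to ``plot_path``."""
    references = np.asarray(references, dtype=float)
    predictions = np.asarray(predictions, dtype=float)
    if references.size == 0:
        raise ValueError("empty input")
    zones = parkes_zones(references, predictions, grid_kind)
    fractions = {
        z: round(100.0 * float(np.mean(zones == z)), 2) for z in ZONES
    }
    if plot_path is not None:
        plot_parkes_grid(references, predictions, plot_path, grid_kind=grid_kind, title=title)
    return fractions


def plot_parkes_grid(
    references: np.ndarray,
    predictions: np.ndarray,
    path,
    *,
    grid_kind: str = "type1",
    title: str | None = None,
) -> None:
    """Scatter of (reference, prediction) pairs over the zone boundaries."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 6))
    lim = 33.3
    for key, pts in _TYPE1_UPPER.items():
        xs, ys = _extend(pts)
        ax.plot(xs / MGDL_PER_MMOLL, ys / MGDL_PER_MMOLL, "k-", lw=0.8)
    for key, pts in _TYPE1_LOWER.items():
        xs, ys = _extend(pts)
        ax.plot(xs / MGDL_PER_MMOLL, ys / MGDL_PER_MMOLL, "k-", lw=0.8)
    ax.plot([0, lim], [0, lim], "k--", lw=0.5)
    ax.scatter(references, predictions, s=4, alpha=0.4, color="tab:blue")
    labels = {  # approximate label anchors, mmol/l
        "A": (14, 14), "B": (9, 17), "C": (4.5, 21), "D": (2.2, 26), "E": (1.2, 31),
    }
    for z, (x, y) in labels.items():
        ax.text(x, y, z, fontsize=11, weight="bold")
    ax.set_xlim(0, lim)
    ax.set_ylim(0, lim)
    ax.set_xlabel("reference glucose (mmol/l)")
    ax.set_ylabel("predicted glucose (mmol/l)")
    ax.set_title(title or "Parkes consensus error grid (type 1)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


__all__ = [
    "MGDL_PER_MMOLL",
    "ZONES",
    "parkes_zone",
    "parkes_zones",
    "parkes_report",
    "plot_parkes_grid",
]
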