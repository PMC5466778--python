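"""Coordinate standardisation and subdomain classification in the DA3 frame.

The late stage-14 DA3 muscle has an angled shape with three morphologically
defined subdomains — antero-ventral, central and postero-dorsal.  Dot and
nucleus positions are made comparable between fibres by centring them on the
muscle centroid and normalising by the muscle area:

    dX = X - X_muscle           dY = -(Y - Y_muscle)
    std_dX = dX * 100 / area    std_dY = dY * 100 / area

The Y sign flip converts the image convention (y increasing downward) into
anatomical coordinates (dorsal up) for dorsal-up, anterior-left images.
A point is antero-ventral when std_dY < -1, postero-dorsal when std_dX > 1,
and central otherwise; antero-ventral takes priority when both strict
inequalities hold, and boundary equalities fall to central.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.measure import regionprops
from skimage.transform import rotate as _sk_rotate

ANTERO_VENTRAL = "antero_ventral"
CENTRAL = "central"
POSTERO_DORSAL = "postero_dorsal"
SUBDOMAINS = (ANTERO_VENTRAL, CENTRAL, POSTERO_DORSAL)


@dataclass(frozen=True)
class SubdomainThresholds:
    """Cut-offs in standardized units; antero-ventral has priority over
    postero-dorsal and equalities at the cuts fall to central."""

    av_cut: float = -1.0
    pd_cut: float = 1.0

    def __post_init__(self) -> None:
        if not self.av_cut < self.pd_cut:
            raise ValueError("av_cut must be below pd_cut")


@dataclass(frozen=True)
class BoundingRect:
    """Axis-aligned bounding rectangle, pixel-counting convention
    (a mask spanning columns 0..9 has x=0, width=10)."""

    x: float
    y: float
    width: float
    height: float

    def __post_init__(self) -> None:
        if self.width <= 0 or self.height <= 0:
            raise ValueError("bounding rectangle must have positive width and height")

    @property
    def anterior_anchor(self) -> tuple[float, float]:
        """BRant: bottom-left corner (anterior-ventral extreme)."""
        return (self.x, self.y + self.height)

    @property
    def posterior_anchor(self) -> tuple[float, float]:
        """BRpost: top-right corner (postero-dorsal extreme)."""
        return (self.x + self.width, self.y)


@dataclass(frozen=True)
class MuscleFrame:
    """Reference frame of one muscle: centroid, area and bounding rect."""

    centroid: tuple[float, float]  # (x, y), px
    area: float  # px^2
    rect: BoundingRect


@dataclass(frozen=True)
class StandardizedCoordinate:
    dx: float
    dy: float
    std_dx: float
    std_dy: float
    subdomain: str


def compute_frame(region) -> MuscleFrame:
    """Compute the muscle frame from a boolean mask or an (n, 2) polygon.

    For a mask: area is the pixel count, centroid the mean of member pixel
    coordinates.  For a polygon (vertices as (x, y) rows): shoelace area and
    polygon centroid.
    """
    arr = np.asarray(region)
    if arr.ndim == 2 and arr.dtype != bool and arr.shape[1] == 2:
        return _frame_from_polygon(arr)
    mask = arr.astype(bool)
    if mask.ndim != 2:
        raise ValueError("mask must be 2-D")
    ys, xs = np.nonzero(mask)
    if xs.size == 0:
        raise ValueError("empty muscle region")
    rect = BoundingRect(x=float(xs.min()), y=float(ys.min()),
                        width=float(xs.max() - xs.min() + 1),
                        height=float(ys.max() - ys.min() + 1))
    return MuscleFrame(centroid=(float(xs.mean()), float(ys.mean())),
                       area=float(xs.size), rect=rect)


def _frame_from_polygon(vertices: np.ndarray) -> MuscleFrame:
    x, y = vertices[:, 0], vertices[:, 1]
    if len(vertices) < 3:
        raise ValueError("polygon needs at least 3 vertices")
    xs, ys = np.roll(x, -1), np.roll(y, -1)
    cross = x * ys - xs * y
    signed = cross.sum() / 2.0
    if signed == 0:
        raise ValueError("degenerate polygon (zero area)")
    cx = ((x + xs) * cross).sum() / (6.0 * signed)
    cy = ((y + ys) * cross).sum() / (6.0 * signed)
    rect = BoundingRect(x=float(x.min()), y=float(y.min()),
                        width=float(x.max() - x.min()), height=float(y.max() - y.min()))
    return MuscleFrame(centroid=(float(cx), float(cy)), area=float(abs(signed)), rect=rect)


def standardize(point: tuple[float, float], frame: MuscleFrame,
                thresholds: SubdomainThresholds = SubdomainThresholds()) -> StandardizedCoordinate:
    """Standardize a point into the muscle frame and classify its subdomain."""
    if frame.area == 0:
        raise ValueError("cannot standardize against a zero-area frame")
    dx = point[0] - frame.centroid[0]
    dy = -(point[1] - frame.centroid[1])
    std_dx = dx * 100.0 / frame.area
    std_dy = dy * 100.0 / frame.area
    return StandardizedCoordinate(
        dx=dx, dy=dy, std_dx=std_dx, std_dy=std_dy,
        subdomain=classify_subdomain(std_dx, std_dy, thresholds))


def classify_subdomain(std_dx: float, std_dy: float,
                       thresholds: SubdomainThresholds = SubdomainThresholds()) -> str:
    if std_dy < thresholds.av_cut:
        return ANTERO_VENTRAL
    if std_dx > thresholds.pd_cut:
        return POSTERO_DORSAL
    return CENTRAL


def repartition(coords) -> dict[str, float]:
    """Percentage of items per subdomain; percentages sum to 100."""
    labels = [c.subdomain if isinstance(c, StandardizedCoordinate) else str(c) for c in coords]
    if not labels:
        raise ValueError("cannot compute a repartition of zero items")
    n = len(labels)
    return {s: 100.0 * labels.count(s) / n for s in SUBDOMAINS}


def classify_mask_pixels(mask: np.ndarray,
                         thresholds: SubdomainThresholds = SubdomainThresholds()) -> np.ndarray:
    """Label every pixel of a muscle mask with its subdomain index
    (0 = antero-ventral, 1 = central, 2 = postero-dorsal, -1 = background).

    Vectorised form of ``standardize`` over the mask's own frame; used both
    for analytic subdomain areas and by the generator's FC positional law.
    """
    frame = compute_frame(mask)
    ys, xs = np.nonzero(np.asarray(mask, bool))
    std_dx = (xs - frame.centroid[0]) * 100.0 / frame.area
    std_dy = -(ys - frame.centroid[1]) * 100.0 / frame.area
    lab = np.full(mask.shape, -1, dtype=np.int8)
    idx = np.ones(xs.size, dtype=np.int8)  # central
    idx[(~(std_dy < thresholds.av_cut)) & (std_dx > thresholds.pd_cut)] = 2
    idx[std_dy < thresholds.av_cut] = 0
    lab[ys, xs] = idx
    return lab


def orient_and_crop(mask: np.ndarray, stack: np.ndarray | None = None,
                    pad: int = 2):
    """Rotate a fibre so its principal axis lies along X, then crop to the
    rotated mask's bounding rectangle.

    Returns ``(cropped_mask, cropped_stack_or_None, angle_deg)`` where
    ``angle_deg`` is the rotation applied (counter-clockwise in image
    coordinates).  A degenerate (rotationally symmetric) region gets the
    identity rotation.
    """
    mask = np.asarray(mask, bool)
    if not mask.any():
        raise ValueError("empty muscle region")
    props = regionprops(mask.astype(np.uint8))[0]
    # regionprops orientation: angle between the major axis and the row
    # (vertical) axis, in (-pi/2, pi/2].
    if props.axis_major_length - props.axis_minor_length < 1e-6:
        angle_deg = 0.0
    else:
        angle_deg = 90.0 - np.degrees(props.orientation)
        if angle_deg > 90.0:
            angle_deg -= 180.0
    rot_mask = _sk_rotate(mask.astype(float), angle_deg, resize=True, order=0,
                          preserve_range=True) > 0.5
    ys, xs = np.nonzero(rot_mask)
    y0, y1 = max(ys.min() - pad, 0), min(ys.max() + 1 + pad, rot_mask.shape[0])
    x0, x1 = max(xs.min() - pad, 0), min(xs.max() + 1 + pad, rot_mask.shape[1])
    out_stack = None
    if stack is not None:
        stack = np.asarray(stack, float)
        planes = stack[None] if stack.ndim == 2 else stack
        rot = np.stack([_sk_rotate(p, angle_deg, resize=True, order=1,
                                   preserve_range=True) for p in planes])
        rot = rot[:, y0:y1, x0:x1]
        out_stack = rot[0] if stack.ndim == 2 else rot
    return rot_mask[y0:y1, x0:x1], out_stack, float(angle_deg)


def spatial_table(points, frames, genes=None, item_types=None,
                  thresholds: SubdomainThresholds = SubdomainThresholds()):
    """Standardize many (x, y) points, each against its own frame, into a
    tidy table of rows (x, y, dX, dY, std_dX, std_dY, subdomain)."""
    import pandas as pd

    rows = []
    for i, (pt, frame) in enumerate(zip(points, frames)):
        c = standardize(pt, frame, thresholds)
        rows.append({
            "gene": genes[i] if genes is not None else "",
            "item_type": item_types[i] if item_types is not None else "dot",
            "x": pt[0], "y": pt[1], "dX": c.dx, "dY": c.dy,
            "std_dX": c.std_dx, "std_dY": c.std_dy, "subdomain": c.subdomain,
        })
    return pd.DataFrame(rows)
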