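"""Synthetic sagittal lumbar-spine phantom with analytic ground truth.

The phantom renders the 14-class scene the quantitation pipeline expects:
five stacked vertebral bodies (L1..L5), the five intervening discs
(L1/L2..L5/S1), a tilted sacrum block below L5, a presacral fat blob
anterior to the sacrum, and a bright CSF band posterior to the column.
Discs carry a two-component intensity model — a bright central nucleus
pulposus inside a darker annulus fibrosus — so their intensity histogram is
bimodal like a healthy disc on T2-weighted MRI.

Every quantitation parameter (VD, VH, DH, DHI, HDR, ΔSI, areas, corner
coordinates) has a closed-form truth value derived from the generating
geometry, never from the rendered mask, so the phantom serves as ground
truth for parameter-recovery experiments.

Default geometry approximates a mid-sagittal lumbar acquisition rendered at
512×512 (the working resolution of the segmentation model): a ~47 mm
vertebral body and ~11 mm disc at ~0.55 mm/px give a 76 px wide column with
50 px vertebrae and 18 px discs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from typing import Literal

import numpy as np

from .maskio import DEFAULT_CLASS_MAP, ClassMap, LabelMask

__all__ = [
    "PhantomSpec",
    "PhantomSample",
    "StructureTruth",
    "LayoutError",
    "generate_phantom",
    "degeneration_series",
    "healthy_spec",
    "degenerate_spec",
]


class LayoutError(ValueError):
    """A structure overlaps another or leaves the image bounds."""


@dataclass(frozen=True)
class PhantomSpec:
    """Generative parameters of the phantom scene.

    Sizes are ``(width, height)`` in pixels; intensities are arbitrary
    signal-intensity (SI) units.  ``tilt_deg`` rotates the whole scene
    rigidly about the image centre (every structure rotates by the same
    angle), which preserves vertebra/disc adjacency; the sacrum carries an
    additional tilt of its own.
    """

    image_size: tuple[int, int] = (512, 512)      # (rows, cols)
    n_vertebrae: int = 5
    vb_size: tuple[int, int] = (76, 50)           # (width, height) px
    disc_size: tuple[int, int] = (76, 18)
    disc_shape: Literal["rectangle", "ellipse", "rounded"] = "rectangle"
    np_intensity: float = 180.0
    af_intensity: float = 60.0
    csf_intensity: float = 200.0
    vb_intensity: float = 110.0
    sacrum_intensity: float = 100.0
    fat_intensity: float = 230.0
    background_intensity: float = 10.0
    nucleus_fraction: float = 0.5                 # of disc area
    noise_sd: float = 0.0
    tilt_deg: float = 0.0
    sacrum_tilt_deg: float = 15.0
    anterior_col: int | None = None               # anterior edge of column
    anterior_low_col: bool = True
    seed: int = 0

    def __post_init__(self):
        for name in ("vb_size", "disc_size"):
            w, h = getattr(self, name)
            if w <= 0 or h <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_vertebrae < 2:
            raise ValueError("need at least 2 vertebrae")
        if min(self.np_intensity, self.af_intensity, self.csf_intensity) < 0:
            raise ValueError("intensities must be nonnegative")
        if self.np_intensity < self.af_intensity:
            raise ValueError("nucleus must be at least as bright as annulus")
        if not 0 < self.nucleus_fraction < 1:
            raise ValueError("nucleus_fraction must be in (0, 1)")


@dataclass
class StructureTruth:
    """Closed-form ground truth for one structure (continuum geometry)."""

    role: str
    class_id: int
    center: tuple[float, float]                  # (row, col)
    area: float
    corners: dict[str, tuple[float, float]] | None = None   # sa/sp/ia/ip
    VD: float | None = None
    VH: float | None = None
    diameter: float | None = None
    max_diameter: float | None = None
    DH: float | None = None
    DHI: float | None = None
    HDR: float | None = None
    delta_si: float | None = None


@dataclass
class PhantomSample:
    """Rendered phantom: intensity image, label mask and analytic truth."""

    image: np.ndarray
    mask: LabelMask
    truth: dict[str, StructureTruth]
    spec: PhantomSpec

    def truth_json(self) -> str:
        def enc(o):
            if isinstance(o, StructureTruth):
                return {k: v for k, v in o.__dict__.items() if v is not None}
            if isinstance(o, (np.floating, np.integer)):
                return float(o)
            raise TypeError(type(o))
        return json.dumps(self.truth, default=enc, indent=1)


def healthy_spec(**overrides) -> PhantomSpec:
    """Preset emulating a non-degenerate lumbar spine."""
    return PhantomSpec(**overrides)


def degenerate_spec(**overrides) -> PhantomSpec:
    """Preset emulating severe degeneration: collapsed, signal-poor discs.

    The nucleus/annulus contrast vanishes (unimodal disc histogram) and disc
    height drops to 40% of the healthy preset.
    """
    base = healthy_spec()
    params = dict(
        np_intensity=base.af_intensity,
        disc_size=(base.disc_size[0], max(2, round(0.4 * base.disc_size[1]))),
    )
    params.update(overrides)
    return PhantomSpec(**params)


# ---------------------------------------------------------------------------
# rasterization helpers

def _rect_mask(shape, center, w, h, tilt_deg):
    """Pixel-centre membership of a (possibly tilted) w×h rectangle."""
    rr, cc = np.mgrid[0:shape[0], 0:shape[1]]
    dr = rr - center[0]
    dc = cc - center[1]
    t = np.deg2rad(tilt_deg)
    u = dc * np.cos(t) + dr * np.sin(t)     # along width
    v = -dc * np.sin(t) + dr * np.cos(t)    # along height
    if tilt_deg == 0.0:
        # exact pixel-grid rectangle: w columns × h rows
        return (np.abs(u) <= (w - 1) / 2 + 1e-9) & (np.abs(v) <= (h - 1) / 2 + 1e-9)
    return (np.abs(u) <= w / 2) & (np.abs(v) <= h / 2)


def _ellipse_mask(shape, center, w, h, tilt_deg):
    rr, cc = np.mgrid[0:shape[0], 0:shape[1]]
    dr = rr - center[0]
    dc = cc - center[1]
    t = np.deg2rad(tilt_deg)
    u = dc * np.cos(t) + dr * np.sin(t)
    v = -dc * np.sin(t) + dr * np.cos(t)
    return (u / (w / 2)) ** 2 + (v / (h / 2)) ** 2 <= 1.0


def _rounded_mask(shape, center, w, h, tilt_deg):
    """Rectangle with elliptical (rounded) anterior/posterior ends."""
    rr, cc = np.mgrid[0:shape[0], 0:shape[1]]
    dr = rr - center[0]
    dc = cc - center[1]
    t = np.deg2rad(tilt_deg)
    u = dc * np.cos(t) + dr * np.sin(t)
    v = -dc * np.sin(t) + dr * np.cos(t)
    r = h / 2
    body = (np.abs(u) <= w / 2 - r) & (np.abs(v) <= r)
    caps = ((np.abs(u) - (w / 2 - r)) / r) ** 2 + (v / r) ** 2 <= 1.0
    caps &= np.abs(u) > w / 2 - r
    return body | caps


_SHAPES = {"rect": _rect_mask, "rectangle": _rect_mask,
           "ellipse": _ellipse_mask, "rounded": _rounded_mask}


def _rect_corners(center, w, h, tilt_deg, anterior_low_col=True):
    """Pixel-centre corner coordinates with anatomical roles."""
    t = np.deg2rad(tilt_deg)
    R = np.array([[np.cos(t), np.sin(t)], [-np.sin(t), np.cos(t)]])
    out = {}
    hw, hh = (w - 1) / 2, (h - 1) / 2
    for role, (su, sv) in {"sa": (-1, -1), "sp": (1, -1),
                           "ia": (-1, 1), "ip": (1, 1)}.items():
        u, v = su * hw, sv * hh
        dc = u * np.cos(t) - v * np.sin(t)
        dr = u * np.sin(t) + v * np.cos(t)
        out[role] = (center[0] + dr, center[1] + dc)
    if not anterior_low_col:
        out = {"sa": out["sp"], "sp": out["sa"], "ia": out["ip"], "ip": out["ia"]}
    return out


def _disc_analytic(shape_name, w, h, mu=0.8):
    """Continuum (diameter, max_diameter, DH, area) for each disc shape.

    DH is the central-band area divided by mu·diameter; for a rectangle that
    is exactly the height, for an ellipse the mean ordinate height over the
    central band.
    """
    if shape_name == "rectangle":
        area = w * h
        dh = h
    elif shape_name == "ellipse":
        area = np.pi * w * h / 4
        # band area = ∫ 2b·sqrt(1-(x/a)²) dx over [-mu·a, mu·a], a=w/2, b=h/2
        band = (w * h / 2) * (np.arcsin(mu) + mu * np.sqrt(1 - mu ** 2))
        dh = band / (mu * w)
    else:  # rounded
        r = h / 2
        area = (w - h) * h + np.pi * r ** 2
        # central mu band of width mu·w; caps start at |x| = w/2 - r
        half = mu * w / 2
        flat = min(half, w / 2 - r)
        band = 2 * flat * h
        if half > w / 2 - r:
            # partial elliptical caps (circular, radius r)
            x1 = half - (w / 2 - r)
            band += 2 * (r ** 2 * np.arcsin(x1 / r) + x1 * np.sqrt(r ** 2 - x1 ** 2))
        dh = band / (mu * w)
    return dict(diameter=float(w), max_diameter=float(w), DH=float(dh),
                area=float(area))


# ---------------------------------------------------------------------------

def _layout(spec: PhantomSpec):
    """Place every structure; returns list of (role, class_id, kind, params)."""
    rows, cols = spec.image_size
    vw, vh = spec.vb_size
    dw, dh = spec.disc_size
    n = spec.n_vertebrae
    sac_w, sac_h = vw, round(1.2 * vh)
    t = abs(np.deg2rad(spec.sacrum_tilt_deg))
    sac_bbox_h = sac_w * np.sin(t) + sac_h * np.cos(t)
    sac_gap = 1
    column_h = n * vh + n * dh
    total_h = column_h + sac_gap + sac_bbox_h
    top = (rows - total_h) / 2
    if top < 1:
        raise LayoutError(f"column of height {total_h:.0f} does not fit in "
                          f"{rows} rows (vertebral column)")
    top = int(round(top))
    ant = spec.anterior_col
    if ant is None:
        ant = int(round(cols * 0.27))
    structures = []
    r = top
    for i in range(1, n + 1):
        center = (r + (vh - 1) / 2, ant + (vw - 1) / 2)
        structures.append((f"VB_L{i}", "rect", dict(center=center, w=vw, h=vh,
                                                    tilt=0.0)))
        r += vh
        if i <= 5 and i <= n:
            dcenter = (r + (dh - 1) / 2, ant + (dw - 1) / 2)
            seg = f"DISC_L{i}L{i + 1}" if i < 5 else "DISC_L5S1"
            structures.append((seg, spec.disc_shape,
                               dict(center=dcenter, w=dw, h=dh, tilt=0.0)))
            r += dh
    # sacrum: tilted rectangle below the last disc
    sac_center_r = r + sac_gap + sac_bbox_h / 2
    sac_center = (sac_center_r, ant + (vw - 1) / 2 + 6)
    structures.append(("SACRUM", "rect", dict(center=sac_center, w=sac_w,
                                              h=sac_h, tilt=spec.sacrum_tilt_deg)))
    # presacral fat: ellipse anterior to the sacrum
    fat_center = (sac_center_r + 2, ant - round(0.30 * vw))
    structures.append(("PRESACRAL_FAT", "ellipse",
                       dict(center=fat_center, w=round(0.45 * vw),
                            h=round(0.6 * vh), tilt=0.0)))
    # CSF: vertical band posterior to the column, spanning the column rows
    csf_left = ant + vw + max(4, round(0.08 * vw))
    csf_w = max(6, round(0.35 * vw))
    structures.append(("CSF", "rect",
                       dict(center=((top + r - 1) / 2,
                                    csf_left + (csf_w - 1) / 2),
                            w=csf_w, h=r - top, tilt=0.0)))
    # scene tilt: rigid rotation of every structure about the image centre,
    # so adjacency between vertebrae and discs is preserved
    if spec.tilt_deg != 0.0:
        t = np.deg2rad(spec.tilt_deg)
        c_img = np.array([(rows - 1) / 2, (cols - 1) / 2])
        rotated = []
        for role, kind, p in structures:
            p = dict(p)
            dr, dc = np.asarray(p["center"]) - c_img
            p["center"] = tuple(c_img + np.array(
                [dr * np.cos(t) + dc * np.sin(t),
                 -dr * np.sin(t) + dc * np.cos(t)]))
            p["tilt"] = p["tilt"] + spec.tilt_deg
            rotated.append((role, kind, p))
        structures = rotated
    if not spec.anterior_low_col:
        flipped = []
        for role, kind, p in structures:
            p = dict(p)
            cr, cc = p["center"]
            p["center"] = (cr, cols - 1 - cc)
            p["tilt"] = -p["tilt"]
            flipped.append((role, kind, p))
        structures = flipped
    return structures


def generate_phantom(spec: PhantomSpec,
                     class_map: ClassMap = DEFAULT_CLASS_MAP) -> PhantomSample:
    """Render the phantom scene and its analytic ground truth.

    Deterministic for identical ``spec`` (noise is drawn from
    ``default_rng(spec.seed)``).  Raises :class:`LayoutError`, naming the
    offending structure, if any structure overlaps another or leaves the
    image.
    """
    rows, cols = spec.image_size
    mask = np.zeros((rows, cols), dtype=np.int64)
    image = np.full((rows, cols), spec.background_intensity, dtype=float)
    intensities = {
        "SACRUM": spec.sacrum_intensity,
        "PRESACRAL_FAT": spec.fat_intensity,
        "CSF": spec.csf_intensity,
    }
    truth: dict[str, StructureTruth] = {}
    vb_truths = []
    for role, kind, p in _layout(spec):
        cid = class_map.id_of(role)
        fn = _SHAPES[kind]
        m = fn((rows, cols), p["center"], p["w"], p["h"], p["tilt"])
        # bounds check: analytic bounding box must stay inside the grid
        t = np.deg2rad(p["tilt"])
        bb_h = abs(p["w"] * np.sin(t)) + abs(p["h"] * np.cos(t))
        bb_w = abs(p["w"] * np.cos(t)) + abs(p["h"] * np.sin(t))
        if (p["center"][0] - bb_h / 2 < -0.5 or p["center"][0] + bb_h / 2 > rows - 0.5
                or p["center"][1] - bb_w / 2 < -0.5
                or p["center"][1] + bb_w / 2 > cols - 0.5):
            raise LayoutError(f"{role} leaves the image bounds")
        if kind in ("rect", "rectangle"):
            area = float(p["w"] * p["h"])
        elif kind == "ellipse":
            area = float(np.pi * p["w"] * p["h"] / 4)
        else:
            r_ = p["h"] / 2
            area = float((p["w"] - p["h"]) * p["h"] + np.pi * r_ ** 2)
        center = p["center"]
        if (mask[m] != 0).any():
            other = int(mask[m][mask[m] != 0][0])
            raise LayoutError(
                f"{role} overlaps class {other} "
                f"({class_map.id_to_role[other]})")
        mask[m] = cid
        rec = StructureTruth(role=role, class_id=cid, center=tuple(center),
                             area=area)
        if role.startswith("VB"):
            rec.corners = _rect_corners(p["center"], p["w"], p["h"], p["tilt"],
                                        spec.anterior_low_col)
            rec.VD = float(p["w"])
            rec.VH = float(p["h"])
            image[m] = spec.vb_intensity
            vb_truths.append(rec)
        elif role.startswith("DISC"):
            ana = _disc_analytic(spec.disc_shape, p["w"], p["h"])
            rec.diameter = ana["diameter"]
            rec.max_diameter = ana["max_diameter"]
            rec.DH = ana["DH"]
            rec.area = ana["area"]
            rec.HDR = rec.DH / rec.max_diameter
            rec.delta_si = ((spec.np_intensity - spec.af_intensity)
                            / spec.csf_intensity * 255.0)
            # two-component disc intensity: nucleus inside annulus, each
            # dimension scaled by sqrt(nucleus_fraction)
            s = np.sqrt(spec.nucleus_fraction)
            nuc = _SHAPES[kind]((rows, cols), p["center"], p["w"] * s,
                                p["h"] * s, p["tilt"]) & m
            image[m] = spec.af_intensity
            image[nuc] = spec.np_intensity
        else:
            image[m] = intensities[role]
        truth[role] = rec
    # disc DHI from adjacent vertebral heights (L5/S1 uses 2×VH(L5))
    vh = {i + 1: vb_truths[i].VH for i in range(len(vb_truths))}
    for i in range(1, spec.n_vertebrae + 1):
        seg = f"DISC_L{i}L{i + 1}" if i < 5 else "DISC_L5S1"
        if seg not in truth:
            continue
        lower = vh.get(i + 1, vh[i])
        truth[seg].DHI = 2 * truth[seg].DH / (vh[i] + lower)
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        image = image + rng.normal(0.0, spec.noise_sd, image.shape)
        image = np.clip(image, 0.0, None)
    return PhantomSample(image=image, mask=LabelMask(mask, class_map),
                         truth=truth, spec=spec)


def degeneration_series(spec: PhantomSpec, n_steps: int,
                        end: PhantomSpec | None = None) -> list[PhantomSample]:
    """Linear series of phantoms from ``spec`` to a collapsed endpoint.

    The nucleus/annulus contrast and the disc height interpolate linearly
    from the start to the end preset, so the analytic ΔSI is strictly
    decreasing and the disc height non-increasing along the series.
    """
    if n_steps < 2:
        raise ValueError("n_steps must be >= 2")
    if end is None:
        end = replace(spec, np_intensity=spec.af_intensity,
                      disc_size=(spec.disc_size[0],
                                 max(2, round(0.4 * spec.disc_size[1]))))
    out = []
    for k in range(n_steps):
        t = k / (n_steps - 1)
        np_i = (1 - t) * spec.np_intensity + t * end.np_intensity
        h = round((1 - t) * spec.disc_size[1] + t * end.disc_size[1])
        s = replace(spec, np_intensity=float(np_i),
                    disc_size=(spec.disc_size[0], int(h)))
        out.append(generate_phantom(s))
    return out
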