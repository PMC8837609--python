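"""Geometric quantitation of vertebral bodies and intervertebral discs.

From a 14-class segmentation the module detects the four corner vertices of
each vertebral body (Shi–Tomasi minimum-eigenvalue corners), derives disc
feature points from the adjacent corners, and computes:

* VD — vertebral body diameter, the distance between the anterior and
  posterior edge midpoints,
* VH — vertebral body height, pixel area divided by VD,
* DH — average disc height, the pixel area of the central μ-band of the
  disc (default μ = 80% of the diameter) divided by μ·diameter,
* DHI — disc height index, 2·DH over the sum of the two adjacent vertebral
  heights,
* HDR — disc height-to-maximum-diameter ratio.

DHI and HDR are dimensionless and therefore invariant to pixel spacing; DH,
VD and VH are in pixels unless a spacing (mm/px) is supplied.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy.spatial import cKDTree
from skimage.feature import corner_peaks, corner_shi_tomasi
from scipy.ndimage import binary_erosion as _binary_erosion

from .histogram import (NoPeakError, csf_reference, delta_si, find_two_peaks,
                        region_histogram)
from .maskio import AbsentStructureError, BinaryRegion, LabelMask, extract_structure

__all__ = [
    "CornerSet",
    "VertebraMeasure",
    "DiscLandmarks",
    "DiscMeasure",
    "SpineMeasurements",
    "CornerDetectionError",
    "AdjacencyError",
    "detect_vb_corners",
    "vertebral_diameter",
    "vertebral_height",
    "disc_landmarks",
    "disc_height",
    "disc_height_index",
    "disc_hdr",
    "measure_spine",
]

DEFAULT_MU = 0.8            # central fraction of the diameter (area band)
DEFAULT_QUALITY = 0.4       # corner response, fraction of ideal L-corner;
#   right-angle corners respond at >= 1x ideal, a smooth disk boundary at
#   ~0.3x, so 0.4 separates quadrilaterals from corner-free regions
DEFAULT_MIN_DIST = 5        # px between corner candidates
DEFAULT_ADJACENCY_TOL = 3   # px gap tolerated between disc and vertebra


class CornerDetectionError(RuntimeError):
    """Fewer than four admissible corners found on a vertebral body."""


class AdjacencyError(ValueError):
    """Disc is not adjacent to both neighbouring vertebrae."""


@dataclass
class CornerSet:
    """Vertebral corner vertices (row, col): superior/inferior × ant/post."""

    L_sa: np.ndarray
    L_sp: np.ndarray
    L_ia: np.ndarray
    L_ip: np.ndarray

    def __post_init__(self):
        for name in ("L_sa", "L_sp", "L_ia", "L_ip"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))

    @property
    def L_ma(self) -> np.ndarray:
        """Anterior edge midpoint."""
        return 0.5 * (self.L_sa + self.L_ia)

    @property
    def L_mp(self) -> np.ndarray:
        """Posterior edge midpoint."""
        return 0.5 * (self.L_sp + self.L_ip)


@dataclass
class VertebraMeasure:
    role: str
    corners: CornerSet
    VD: float
    area: float
    VH: float


@dataclass
class DiscLandmarks:
    """Disc feature points derived from the adjacent vertebral corners."""

    D_1a: np.ndarray   # boundary point nearest upper L_ia
    D_1p: np.ndarray   # boundary point nearest upper L_ip
    D_2a: np.ndarray   # boundary point nearest lower L_sa
    D_2p: np.ndarray   # boundary point nearest lower L_sp
    D_al: np.ndarray   # anterior-most boundary point (extreme projection)
    D_pr: np.ndarray   # posterior-most boundary point

    def __post_init__(self):
        for name in ("D_1a", "D_1p", "D_2a", "D_2p", "D_al", "D_pr"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))

    @property
    def D_a(self) -> np.ndarray:
        return 0.5 * (self.D_1a + self.D_2a)

    @property
    def D_p(self) -> np.ndarray:
        return 0.5 * (self.D_1p + self.D_2p)

    @property
    def diameter(self) -> float:
        return float(np.linalg.norm(self.D_p - self.D_a))

    @property
    def max_diameter(self) -> float:
        return float(np.linalg.norm(self.D_pr - self.D_al))


@dataclass
class DiscMeasure:
    role: str
    landmarks: DiscLandmarks
    area: float
    area_central: float
    DH: float
    DHI: float | None
    HDR: float
    delta_si: float | None
    flags: list[str] = field(default_factory=list)


@dataclass
class SpineMeasurements:
    """Per-structure measurements with per-structure failure collection."""

    vertebrae: dict[str, VertebraMeasure]
    discs: dict[str, DiscMeasure]
    flags: list[str]
    errors: dict[str, str]


@lru_cache(maxsize=8)
def _ideal_corner_response(sigma: float) -> float:
    """Peak Shi–Tomasi response of an ideal binary right-angle corner.

    Used as the reference scale for the ``quality`` threshold, so the
    threshold is meaningful for binary masks of any size.
    """
    n = int(np.ceil(16 * sigma)) | 1
    patch = np.zeros((2 * n + 1, 2 * n + 1))
    patch[n:, n:] = 1.0
    return float(corner_shi_tomasi(patch, sigma=sigma).max())


def detect_vb_corners(region: BinaryRegion, max_corners: int = 10,
                      quality: float = DEFAULT_QUALITY,
                      min_dist: int = DEFAULT_MIN_DIST,
                      sigma: float = 1.0,
                      anterior_low_col: bool = True) -> CornerSet:
    """Shi–Tomasi corners of a vertebral-body region, with anatomical roles.

    Corner candidates are local maxima of the minimum-eigenvalue response
    whose value is at least ``quality`` times the response of an ideal
    right-angle corner.  The four retained corners are assigned roles
    (superior/inferior × anterior/posterior) by quadrant relative to the
    region centroid; within a quadrant the strongest response wins, ties
    broken by distance to the bounding-box vertex.  Each retained corner is
    then snapped to the outermost region pixel within a 2-px window, since
    the response peak of a rasterised corner sits up to ~2 px inside the
    vertex.  Regions without four corner-like points (e.g. a disk) raise
    :class:`CornerDetectionError`.
    """
    pix = region.pixels.astype(float)
    resp = corner_shi_tomasi(pix, sigma=sigma)
    thr = quality * _ideal_corner_response(sigma)
    cand = corner_peaks(resp, min_distance=min_dist, threshold_abs=thr,
                        threshold_rel=0.0, num_peaks=max_corners)
    if len(cand) < 4:
        raise CornerDetectionError(
            f"only {len(cand)} admissible corners (need 4) for class "
            f"{region.class_id}")
    coords = region.coords()
    cen = coords.mean(axis=0)
    rmin, cmin = coords.min(axis=0)
    rmax, cmax = coords.max(axis=0)
    bbox = {"sa": (rmin, cmin), "sp": (rmin, cmax),
            "ia": (rmax, cmin), "ip": (rmax, cmax)}
    if not anterior_low_col:
        bbox = {"sa": bbox["sp"], "sp": bbox["sa"],
                "ia": bbox["ip"], "ip": bbox["ia"]}
    chosen = {}
    for role, vertex in bbox.items():
        superior = role[0] == "s"
        anterior = role[1] == "a"
        rows, cls_ = cand[:, 0], cand[:, 1]
        in_quad = ((rows < cen[0]) if superior else (rows >= cen[0]))
        ant_side = (cls_ < cen[1]) if anterior_low_col else (cls_ >= cen[1])
        in_quad &= ant_side if anterior else ~ant_side
        quad = cand[in_quad]
        if len(quad) == 0:
            raise CornerDetectionError(
                f"no corner candidate in {role} quadrant for class "
                f"{region.class_id}")
        scores = resp[quad[:, 0], quad[:, 1]]
        best = scores == scores.max()
        tied = quad[best]
        d = np.linalg.norm(tied - np.asarray(vertex, float), axis=1)
        peak = tied[int(np.argmin(d))].astype(float)
        chosen[role] = _snap_to_vertex(peak, coords, cen, window=2)
    return CornerSet(L_sa=chosen["sa"], L_sp=chosen["sp"],
                     L_ia=chosen["ia"], L_ip=chosen["ip"])


def _snap_to_vertex(peak: np.ndarray, coords: np.ndarray, cen: np.ndarray,
                    window: int = 2) -> np.ndarray:
    """Move a corner-response peak to the outermost region pixel nearby.

    Among region pixels within a Chebyshev ``window`` of the peak, pick the
    one farthest from the centroid along the peak's outward direction
    (ties: closest to the peak).  On an axis-aligned rectangle the peak
    already sits on the vertex and is unchanged.
    """
    near = coords[(np.abs(coords - peak).max(axis=1) <= window)]
    if len(near) == 0:
        return peak
    u = peak - cen
    n = np.linalg.norm(u)
    if n == 0:
        return peak
    u = u / n
    proj = (near - cen) @ u
    cand = near[proj >= proj.max() - 1e-9]
    d = np.linalg.norm(cand - peak, axis=1)
    return cand[int(np.argmin(d))].astype(float)


def vertebral_diameter(corners: CornerSet,
                       spacing_mm: tuple[float, float] | None = None) -> float:
    """VD: Euclidean distance between the anterior and posterior midpoints."""
    d = corners.L_ma - corners.L_mp
    if spacing_mm is not None:
        d = d * np.asarray(spacing_mm, float)
    return float(np.linalg.norm(d))


def vertebral_height(region: BinaryRegion, vd: float,
                     spacing_mm: tuple[float, float] | None = None) -> float:
    """VH: region pixel area divided by the vertebral diameter."""
    if vd <= 0:
        raise ValueError("vertebral diameter must be positive")
    area = float(region.area_px)
    if spacing_mm is not None:
        area *= spacing_mm[0] * spacing_mm[1]
    return area / vd


def _boundary(region: BinaryRegion) -> np.ndarray:
    pix = region.pixels
    inner = _binary_erosion(pix)
    return np.argwhere(pix & ~inner)


def disc_landmarks(disc_region: BinaryRegion, upper_vb: CornerSet,
                   lower_vb: CornerSet,
                   adjacency_tol: float = DEFAULT_ADJACENCY_TOL) -> DiscLandmarks:
    """Derive the disc feature points from the adjacent vertebral corners.

    The four primary points are the disc-boundary pixels nearest the upper
    vertebra's inferior corners and the lower vertebra's superior corners.
    The anterior/posterior midpoints of those pairs define the disc axis;
    the extreme signed projections of the boundary onto that axis give the
    anterior-most / posterior-most points and hence the maximum diameter.

    Adjacency: the vertical gap between the disc and either vertebral
    endplate must not exceed ``adjacency_tol`` pixels.
    """
    bnd = _boundary(disc_region)
    if bnd.size == 0:
        raise ValueError("empty disc region")
    rows = disc_region.coords()[:, 0]
    gap_sup = rows.min() - max(upper_vb.L_ia[0], upper_vb.L_ip[0])
    gap_inf = min(lower_vb.L_sa[0], lower_vb.L_sp[0]) - rows.max()
    for gap, side in ((gap_sup, "superior"), (gap_inf, "inferior")):
        if gap > adjacency_tol + 1:
            raise AdjacencyError(
                f"disc separated from {side} vertebra by {gap:.1f} px "
                f"(> {adjacency_tol} px tolerance)")
    tree = cKDTree(bnd)
    near = lambda p: bnd[tree.query(np.asarray(p, float))[1]].astype(float)
    d1a, d1p = near(upper_vb.L_ia), near(upper_vb.L_ip)
    d2a, d2p = near(lower_vb.L_sa), near(lower_vb.L_sp)
    da, dp = 0.5 * (d1a + d2a), 0.5 * (d1p + d2p)
    axis = dp - da
    norm = np.linalg.norm(axis)
    if norm <= 0:
        raise ValueError("degenerate disc axis (anterior == posterior midpoint)")
    u = axis / norm
    t = (bnd - da) @ u
    perp = np.abs((bnd - da) @ np.array([-u[1], u[0]]))
    # extreme projections; ties resolved toward the axis line, then by row
    def extreme(idx_pool):
        order = np.lexsort((bnd[idx_pool][:, 0], perp[idx_pool]))
        return bnd[idx_pool][order[0]].astype(float)
    lo_pool = np.flatnonzero(t <= t.min() + 1e-9)
    hi_pool = np.flatnonzero(t >= t.max() - 1e-9)
    return DiscLandmarks(D_1a=d1a, D_1p=d1p, D_2a=d2a, D_2p=d2p,
                         D_al=extreme(lo_pool), D_pr=extreme(hi_pool))


def disc_height(disc_region: BinaryRegion, landmarks: DiscLandmarks,
                mu: float = DEFAULT_MU,
                spacing_mm: tuple[float, float] | None = None
                ) -> tuple[float, float]:
    """(area_central, DH): central-band pixel area and average disc height.

    The central band holds the disc pixels whose projection onto the
    anterior→posterior axis lies within the central ``mu`` fraction of the
    diameter; DH = area_central / (mu · diameter).
    """
    if not 0 < mu <= 1:
        raise ValueError("mu must be in (0, 1]")
    s = np.asarray(spacing_mm, float) if spacing_mm is not None else np.ones(2)
    da = landmarks.D_a * s
    dp = landmarks.D_p * s
    diam = float(np.linalg.norm(dp - da))
    if diam <= 0:
        raise ValueError("disc diameter must be positive")
    pts = disc_region.coords().astype(float) * s
    u = (dp - da) / diam
    t = (pts - da) @ u
    half = mu * diam / 2.0
    in_band = np.abs(t - diam / 2.0) <= half + 1e-9
    area_central = float(in_band.sum()) * float(s[0] * s[1])
    dh = area_central / (mu * diam)
    return area_central, float(dh)


def disc_height_index(dh: float, vh_upper: float, vh_lower: float) -> float:
    """DHI = 2·DH / (VH_upper + VH_lower); dimensionless."""
    denom = vh_upper + vh_lower
    if denom <= 0:
        raise ValueError("sum of vertebral heights must be positive")
    return 2.0 * dh / denom


def disc_hdr(dh: float, max_diameter: float) -> float:
    """HDR = DH / maximum disc diameter; dimensionless."""
    if max_diameter <= 0:
        raise ValueError("maximum diameter must be positive")
    return dh / max_diameter


def measure_spine(image: np.ndarray, mask: LabelMask,
                  mu: float = DEFAULT_MU,
                  quality: float = DEFAULT_QUALITY,
                  min_dist: int = DEFAULT_MIN_DIST,
                  adjacency_tol: float = DEFAULT_ADJACENCY_TOL,
                  n_bins: int = 64,
                  anterior_low_col: bool = True,
                  spacing_mm: tuple[float, float] | None = None
                  ) -> SpineMeasurements:
    """Quantify all five vertebrae and discs of a segmented sagittal scene.

    Per-structure failures (absent class, corner-detection failure) are
    collected in ``errors`` and flagged; the remaining structures are still
    measured.  The L5/S1 disc uses the sacrum's superior corners as its
    lower landmarks and — since the sacrum has no area/diameter height —
    2·VH(L5) as the DHI denominator (flagged ``l5s1_dhi_uses_l5``).
    Missing CSF leaves ΔSI as ``None`` with flag ``csf_absent``.
    """
    cm = mask.class_map
    flags: list[str] = []
    errors: dict[str, str] = {}
    vertebrae: dict[str, VertebraMeasure] = {}
    corners: dict[str, CornerSet] = {}
    regions: dict[str, BinaryRegion] = {}

    for i, cid in enumerate(cm.vertebra_ids, start=1):
        role = f"VB_L{i}"
        try:
            reg = extract_structure(mask, cid)
            cs = detect_vb_corners(reg, quality=quality, min_dist=min_dist,
                                   anterior_low_col=anterior_low_col)
            vd = vertebral_diameter(cs, spacing_mm)
            vh = vertebral_height(reg, vd, spacing_mm)
            area = reg.area_px * (spacing_mm[0] * spacing_mm[1]
                                  if spacing_mm else 1.0)
            vertebrae[role] = VertebraMeasure(role, cs, vd, area, vh)
            corners[role] = cs
            regions[role] = reg
        except (AbsentStructureError, CornerDetectionError, ValueError) as exc:
            errors[role] = str(exc)
            flags.append(f"{role}_failed")

    # sacrum corners (geometry reference only, no height measurement)
    sac_corners = None
    try:
        sac = extract_structure(mask, cm.id_of("SACRUM"))
        sac_corners = detect_vb_corners(sac, quality=quality,
                                        min_dist=min_dist,
                                        anterior_low_col=anterior_low_col)
    except (AbsentStructureError, CornerDetectionError) as exc:
        errors["SACRUM"] = str(exc)
        flags.append("sacrum_failed")

    # CSF reference for ΔSI
    si_csf = None
    try:
        csf = extract_structure(mask, cm.id_of("CSF"))
        si_csf = csf_reference(image, csf, n_bins=n_bins)
    except AbsentStructureError:
        flags.append("csf_absent")

    disc_roles = ["DISC_L1L2", "DISC_L2L3", "DISC_L3L4", "DISC_L4L5",
                  "DISC_L5S1"]
    discs: dict[str, DiscMeasure] = {}
    for i, role in enumerate(disc_roles, start=1):
        upper_role = f"VB_L{i}"
        lower_role = f"VB_L{i + 1}" if i < 5 else "SACRUM"
        dflags: list[str] = []
        try:
            reg = extract_structure(mask, cm.id_of(role))
            upper = corners.get(upper_role)
            lower = corners.get(lower_role) if i < 5 else sac_corners
            if upper is None or lower is None:
                raise AdjacencyError(
                    f"adjacent structure corners unavailable for {role}")
            lm = disc_landmarks(reg, upper, lower, adjacency_tol)
            area_central, dh = disc_height(reg, lm, mu, spacing_mm)
            sarr = (np.asarray(spacing_mm, float) if spacing_mm is not None
                    else np.ones(2))
            maxd = float(np.linalg.norm((lm.D_pr - lm.D_al) * sarr))
            hdr = disc_hdr(dh, maxd)
            vh_up = vertebrae[upper_role].VH if upper_role in vertebrae else None
            if i < 5:
                vh_lo = (vertebrae[lower_role].VH
                         if lower_role in vertebrae else None)
            else:
                vh_lo = vh_up
                dflags.append("l5s1_dhi_uses_l5")
            dhi = (disc_height_index(dh, vh_up, vh_lo)
                   if vh_up is not None and vh_lo is not None else None)
            dsi = None
            if si_csf is not None:
                try:
                    hist = region_histogram(image, reg, n_bins=n_bins)
                    peaks = find_two_peaks(hist)
                    if peaks.degenerate:
                        dflags.append("unimodal_histogram")
                    dsi = delta_si(peaks, si_csf)
                except NoPeakError:
                    dflags.append("no_histogram_peak")
            else:
                dflags.append("csf_absent")
            area = reg.area_px * (spacing_mm[0] * spacing_mm[1]
                                  if spacing_mm else 1.0)
            discs[role] = DiscMeasure(role, lm, area, area_central, dh, dhi,
                                      hdr, dsi, dflags)
        except (AbsentStructureError, AdjacencyError, ValueError) as exc:
            errors[role] = str(exc)
            flags.append(f"{role}_failed")
    return SpineMeasurements(vertebrae, discs, flags, errors)
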