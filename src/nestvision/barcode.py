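"""Cage-label localisation and EAN-13 decoding.

The cage position travels on a printed EAN-13 label. The pipeline that
recovers it from a scene image is entirely classical:

    RGB -> weighted grayscale -> 3x3 median filter -> OTSU binarisation
        -> Canny edges -> contour extraction -> min-area-rect screening
        (2:1 aspect, area floor) -> scanline EAN-13 decode -> checksum.

Every stage is implemented here from first principles so the chain is
self-contained and each step can be tested against an independent oracle.
The decoder reads at least five horizontal scanlines across the rectified
label, re-binarises each scanline with OTSU on its own histogram (robust to
uneven lighting), measures the 95-module structure (guard 101, 42 modules,
center 01010, 42 modules, guard 101), decodes the left six digits via L/G
parity — which yields the implicit leading digit — and the right six via R
patterns, majority-votes the digits across scanlines, and verifies the
weighted-sum check digit.

Grayscale default is ITU-R BT.601 (0.299, 0.587, 0.114). A variant with a
0.229 red weight circulates in print; it is selectable but, since its
weights do not sum to one, it darkens the image slightly and is not the
default.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from shapely.geometry import LineString, MultiPoint, Point

from .codes import ean13_check_digit
from .geometry import Box

__all__ = [
    "GrayscaleCoeffs",
    "BT601",
    "PRINTED_VARIANT",
    "BarcodeRegion",
    "NoBarcodeError",
    "CorruptCodeError",
    "to_grayscale",
    "median_filter_3x3",
    "histogram256",
    "otsu_threshold",
    "binarize",
    "canny_edges",
    "find_contours",
    "min_area_rect",
    "screen_barcode_candidates",
    "ean13_modules",
    "render_ean13",
    "decode_ean13",
    "locate_barcode",
    "read_position_code",
]


class NoBarcodeError(ValueError):
    """No decodable barcode structure found."""


class CorruptCodeError(ValueError):
    """Barcode structure found but the check digit does not verify."""


# --------------------------------------------------------------------------
# grayscale


@dataclass(frozen=True)
class GrayscaleCoeffs:
    """RGB-to-luminance weights; expected to sum to 1 unless check_sum=False."""

    r_coef: float
    g_coef: float
    b_coef: float
    check_sum: bool = True

    def __post_init__(self) -> None:
        if min(self.r_coef, self.g_coef, self.b_coef) < 0:
            raise ValueError("coefficients must be non-negative")
        total = self.r_coef + self.g_coef + self.b_coef
        if self.check_sum and abs(total - 1.0) > 1e-6:
            raise ValueError(f"coefficients sum to {total}, expected 1")


BT601 = GrayscaleCoeffs(0.299, 0.587, 0.114)
#: the in-print variant with a 0.229 red weight; does not sum to one
PRINTED_VARIANT = GrayscaleCoeffs(0.229, 0.587, 0.114, check_sum=False)


def to_grayscale(rgb: np.ndarray, coeffs: GrayscaleCoeffs = BT601) -> np.ndarray:
    """Weighted-average luminance, rounded and clamped to uint8."""
    arr = np.asarray(rgb)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ValueError("expected an H x W x 3 image")
    y = (
        coeffs.r_coef * arr[..., 0].astype(float)
        + coeffs.g_coef * arr[..., 1].astype(float)
        + coeffs.b_coef * arr[..., 2].astype(float)
    )
    return np.clip(np.rint(y), 0, 255).astype(np.uint8)


# --------------------------------------------------------------------------
# filtering, thresholding


def median_filter_3x3(img: np.ndarray) -> np.ndarray:
    """3x3 median filter with edge replication; removes impulse noise while
    preserving step edges (bar/space boundaries)."""
    arr = np.asarray(img)
    if arr.ndim != 2 or arr.shape[0] < 3 or arr.shape[1] < 3:
        raise ValueError("image must be 2-D and at least 3x3")
    return ndimage.median_filter(arr, size=3, mode="nearest")


def histogram256(img: np.ndarray) -> np.ndarray:
    """256-bin histogram of an 8-bit image."""
    arr = np.asarray(img)
    if arr.min() < 0 or arr.max() > 255:
        raise ValueError("values must lie in [0, 255]")
    return np.bincount(arr.ravel().astype(np.int64), minlength=256)


def otsu_threshold(hist: np.ndarray) -> int:
    """Threshold maximising the between-class variance w0*w1*(mu0-mu1)^2.

    Class 0 holds pixels with value <= t.  All 256 thresholds are scanned
    and ties break to the smallest t.
    """
    h = np.asarray(hist, dtype=float)
    if h.shape != (256,):
        raise ValueError("histogram must have 256 bins")
    if np.count_nonzero(h) < 2:
        raise ValueError("degenerate image: fewer than two occupied gray levels")
    total = h.sum()
    levels = np.arange(256, dtype=float)
    w0 = np.cumsum(h) / total
    cum_mean = np.cumsum(h * levels) / total
    grand_mean = cum_mean[-1]
    w1 = 1.0 - w0
    valid = (w0 > 0) & (w1 > 0)
    sigma_b = np.zeros(256)
    mu0 = np.divide(cum_mean, w0, out=np.zeros(256), where=valid)
    mu1 = np.divide(grand_mean - cum_mean, w1, out=np.zeros(256), where=valid)
    sigma_b[valid] = w0[valid] * w1[valid] * (mu0[valid] - mu1[valid]) ** 2
    return int(np.argmax(sigma_b))


def binarize(img: np.ndarray, t: int) -> np.ndarray:
    """Foreground = pixel value strictly above t."""
    if not 0 <= t <= 255:
        raise ValueError("threshold must lie in [0, 255]")
    return np.asarray(img) > t


# --------------------------------------------------------------------------
# Canny


def canny_edges(
    img: np.ndarray, sigma: float = 1.4, low: float = 50.0, high: float = 150.0
) -> np.ndarray:
    """Canny edge map: Gaussian smoothing, Sobel gradients, 4-sector
    non-maximum suppression, double threshold with 8-connected hysteresis."""
    if low >= high:
        raise ValueError("low threshold must be below high threshold")
    f = ndimage.gaussian_filter(np.asarray(img, dtype=float), sigma, mode="nearest")
    kx = np.array([[-1.0, 0.0, 1.0], [-2.0, 0.0, 2.0], [-1.0, 0.0, 1.0]])
    ky = kx.T
    gx = ndimage.convolve(f, kx, mode="nearest")
    gy = ndimage.convolve(f, ky, mode="nearest")
    mag = np.hypot(gx, gy)

    ang = np.rad2deg(np.arctan2(gy, gx)) % 180.0
    sector = np.zeros(ang.shape, dtype=np.uint8)
    sector[(ang >= 22.5) & (ang < 67.5)] = 1
    sector[(ang >= 67.5) & (ang < 112.5)] = 2
    sector[(ang >= 112.5) & (ang < 157.5)] = 3

    def shifted(dr: int, dc: int) -> np.ndarray:
        out = np.zeros_like(mag)
        h, w = mag.shape
        rs = slice(max(dr, 0), h + min(dr, 0))
        cs = slice(max(dc, 0), w + min(dc, 0))
        rs2 = slice(max(-dr, 0), h + min(-dr, 0))
        cs2 = slice(max(-dc, 0), w + min(-dc, 0))
        out[rs2, cs2] = mag[rs, cs]
        return out

    # neighbour offsets along the gradient direction, per sector
    nbr = {0: ((0, 1), (0, -1)), 1: ((1, 1), (-1, -1)),
           2: ((1, 0), (-1, 0)), 3: ((1, -1), (-1, 1))}
    keep = np.zeros(mag.shape, dtype=bool)
    for s, ((dr1, dc1), (dr2, dc2)) in nbr.items():
        m = sector == s
        n1 = shifted(dr1, dc1)
        n2 = shifted(dr2, dc2)
        keep |= m & (mag > n1) & (mag >= n2)

    strong = keep & (mag >= high)
    weak = keep & (mag >= low)
    if not strong.any():
        return strong
    lab, n = ndimage.label(weak, structure=np.ones((3, 3), dtype=int))
    good = np.zeros(n + 1, dtype=bool)
    good[np.unique(lab[strong])] = True
    good[0] = False
    return good[lab]


# --------------------------------------------------------------------------
# contours


_MOORE = [(0, -1), (-1, -1), (-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1)]


def _trace_boundary(mask: np.ndarray, start: tuple[int, int]) -> list[tuple[int, int]]:
    """Moore-neighbour boundary following from the topmost-leftmost pixel of
    an 8-connected component (mask must be padded with a background rim).

    The backtrack point is tracked explicitly; tracing stops when the first
    (pixel, next-move) state recurs (Jacob's stopping criterion)."""
    cur = start
    bt = (start[0], start[1] - 1)  # west neighbour, background by start choice
    first_state: tuple | None = None
    contour: list[tuple[int, int]] = []
    limit = 4 * int(mask.sum()) + 8
    for _ in range(limit):
        d = _MOORE.index((bt[0] - cur[0], bt[1] - cur[1]))
        nxt = None
        for k in range(1, 9):
            cand = (d + k) % 8
            nr, nc = cur[0] + _MOORE[cand][0], cur[1] + _MOORE[cand][1]
            if mask[nr, nc]:
                nxt = (nr, nc)
                prev = (d + k - 1) % 8
                new_bt = (cur[0] + _MOORE[prev][0], cur[1] + _MOORE[prev][1])
                break
        if nxt is None:  # isolated pixel
            return [start]
        state = (cur, nxt)
        if first_state is None:
            first_state = state
        elif state == first_state:
            return contour
        contour.append(cur)
        bt, cur = new_bt, nxt
    raise RuntimeError("boundary tracing did not terminate")


def _shoelace(points: list[tuple[int, int]]) -> float:
    """Signed polygon area of (row, col) vertices, positive for
    counter-clockwise order in x=col, y=row (y down) coordinates."""
    if len(points) < 3:
        return 0.0
    ys = np.array([p[0] for p in points], dtype=float)
    xs = np.array([p[1] for p in points], dtype=float)
    return float(np.dot(xs, np.roll(ys, -1)) - np.dot(ys, np.roll(xs, -1))) / 2.0


def find_contours(binary: np.ndarray) -> list[np.ndarray]:
    """External boundary of every 8-connected foreground component.

    Each contour is an (N, 2) array of (row, col) boundary pixels traced in
    counter-clockwise order under the y-down image convention (positive
    shoelace area in x=col, y=row coordinates).
    """
    mask = np.asarray(binary, dtype=bool)
    if mask.ndim != 2:
        raise ValueError("binary image must be 2-D")
    if not mask.any():
        return []
    lab, n = ndimage.label(mask, structure=np.ones((3, 3), dtype=int))
    objects = ndimage.find_objects(lab)
    contours = []
    for i, sl in enumerate(objects, start=1):
        comp = np.pad(lab[sl] == i, 1)
        off_r, off_c = sl[0].start - 1, sl[1].start - 1
        rows, cols = np.nonzero(comp)
        k = np.lexsort((cols, rows))[0]
        pts = _trace_boundary(comp, (int(rows[k]), int(cols[k])))
        if _shoelace(pts) < 0:
            pts = pts[::-1]
        contours.append(np.array(pts, dtype=int) + [off_r, off_c])
    return contours


# --------------------------------------------------------------------------
# min-area rectangle and screening


@dataclass(frozen=True)
class BarcodeRegion:
    """Min-area rotated rectangle of a candidate label.

    ``width`` is the long side, ``height`` the short side; ``angle_deg`` is
    the orientation of the long side w.r.t. the x axis, in (-90, 90].
    """

    center_x: float
    center_y: float
    width: float
    height: float
    angle_deg: float
    box: Box

    def __post_init__(self) -> None:
        if self.width <= 0 or self.height <= 0:
            raise ValueError("region sides must be positive")

    @property
    def aspect(self) -> float:
        return self.width / self.height

    @property
    def rect_area(self) -> float:
        return self.width * self.height


def min_area_rect(points: np.ndarray) -> BarcodeRegion | None:
    """Minimum-area rotated rectangle of (row, col) points.

    Returns None for degenerate (empty or sub-2x2) point sets.
    """
    pts = np.asarray(points)
    if pts.ndim != 2 or pts.shape[0] < 3:
        return None
    xy = [(float(c), float(r)) for r, c in pts]
    rect = MultiPoint(xy).minimum_rotated_rectangle
    if isinstance(rect, (Point, LineString)):
        return None
    corners = np.array(rect.exterior.coords[:4])
    e1 = corners[1] - corners[0]
    e2 = corners[2] - corners[1]
    l1, l2 = float(np.hypot(*e1)), float(np.hypot(*e2))
    if l1 >= l2:
        long_side, width, height = e1, l1, l2
    else:
        long_side, width, height = e2, l2, l1
    if height <= 0:
        return None
    angle = math.degrees(math.atan2(long_side[1], long_side[0]))
    if angle <= -90.0:
        angle += 180.0
    elif angle > 90.0:
        angle -= 180.0
    cx, cy = corners.mean(axis=0)
    x0, y0 = corners.min(axis=0)
    x1, y1 = corners.max(axis=0)
    box = Box(float(x0), float(y0), float(max(x1, x0 + 1e-6)), float(max(y1, y0 + 1e-6)))
    return BarcodeRegion(float(cx), float(cy), width, height, angle, box)


def screen_barcode_candidates(
    contours: list[np.ndarray],
    min_area: float,
    target_ratio: float = 2.0,
    ratio_tol: float = 0.25,
) -> list[BarcodeRegion]:
    """Keep contours whose min-area rectangle is big enough and close to the
    target (long/short) aspect ratio; sorted by rectangle area descending."""
    if target_ratio <= 1:
        raise ValueError("target_ratio must be > 1")
    out = []
    lo = target_ratio * (1.0 - ratio_tol)
    hi = target_ratio * (1.0 + ratio_tol)
    for cnt in contours:
        region = min_area_rect(cnt)
        if region is None:
            continue
        if region.rect_area < min_area:
            continue
        if not lo <= region.aspect <= hi:
            continue
        out.append(region)
    out.sort(key=lambda r: -r.rect_area)
    return out


# --------------------------------------------------------------------------
# EAN-13 encode / render


_L_CODES = {
    "0": "0001101", "1": "0011001", "2": "0010011", "3": "0111101",
    "4": "0100011", "5": "0110001", "6": "0101111", "7": "0111011",
    "8": "0110111", "9": "0001011",
}
_R_CODES = {d: "".join("1" if c == "0" else "0" for c in p) for d, p in _L_CODES.items()}
_G_CODES = {d: p[::-1] for d, p in _R_CODES.items()}
_L_LOOKUP = {p: d for d, p in _L_CODES.items()}
_G_LOOKUP = {p: d for d, p in _G_CODES.items()}
_R_LOOKUP = {p: d for d, p in _R_CODES.items()}
_PARITY = {
    "LLLLLL": "0", "LLGLGG": "1", "LLGGLG": "2", "LLGGGL": "3", "LGLLGG": "4",
    "LGGLLG": "5", "LGGGLL": "6", "LGLGLG": "7", "LGLGGL": "8", "LGGLGL": "9",
}
_PARITY_BY_DIGIT = {d: p for p, d in _PARITY.items()}


def _validate_ean13(code: str) -> None:
    if len(code) != 13 or not code.isdigit():
        raise ValueError("EAN-13 must be 13 decimal digits")
    if int(code[12]) != ean13_check_digit(code[:12]):
        raise ValueError(f"invalid check digit in {code}")


def ean13_modules(code: str) -> np.ndarray:
    """95-element bar pattern (True = bar) of a checksum-valid EAN-13."""
    _validate_ean13(code)
    parity = _PARITY_BY_DIGIT[code[0]]
    bits = "101"
    for p, d in zip(parity, code[1:7]):
        bits += _L_CODES[d] if p == "L" else _G_CODES[d]
    bits += "01010"
    for d in code[7:13]:
        bits += _R_CODES[d]
    bits += "101"
    return np.array([c == "1" for c in bits], dtype=bool)


def render_ean13(
    code: str,
    module_px: int = 4,
    height_px: int | None = None,
    quiet_modules: int = 11,
) -> np.ndarray:
    """Rasterise an EAN-13 as a white label with black bars.

    Total width is (95 + 2*quiet_modules) * module_px; default height makes
    the label backing approximately 2:1.  Bars are inset vertically so the
    white backing stays a single connected region.
    """
    if quiet_modules < 9:
        raise ValueError("EAN-13 requires a quiet zone of at least 9 modules")
    if module_px < 1:
        raise ValueError("module_px must be >= 1")
    modules = ean13_modules(code)
    width = (95 + 2 * quiet_modules) * module_px
    if height_px is None:
        height_px = int(round(width / 2))
    vmargin = max(2 * module_px, height_px // 12)
    img = np.full((height_px, width), 255, dtype=np.uint8)
    x0 = quiet_modules * module_px
    for i, bar in enumerate(modules):
        if bar:
            xs = x0 + i * module_px
            img[vmargin : height_px - vmargin, xs : xs + module_px] = 0
    return img


# --------------------------------------------------------------------------
# EAN-13 decode


def _decode_scanline(line: np.ndarray) -> str | None:
    vals = np.unique(line)
    if vals.size < 2:
        return None
    t = otsu_threshold(np.bincount(line.astype(np.int64), minlength=256))
    bars = line <= t  # bars are dark
    idx = np.flatnonzero(bars)
    if idx.size == 0:
        return None
    first, last = int(idx[0]), int(idx[-1]) + 1
    span = last - first
    if span < 95:
        return None
    edges = first + np.rint(np.arange(96) * span / 95.0).astype(int)
    bits = np.empty(95, dtype=bool)
    for i in range(95):
        seg = bars[edges[i] : edges[i + 1]]
        if seg.size == 0:
            return None
        bits[i] = seg.mean() > 0.5
    s = "".join("1" if b else "0" for b in bits)
    if s[0:3] != "101" or s[45:50] != "01010" or s[92:95] != "101":
        return None
    parity = ""
    digits = ""
    for j in range(6):
        pat = s[3 + 7 * j : 10 + 7 * j]
        if pat in _L_LOOKUP:
            parity += "L"
            digits += _L_LOOKUP[pat]
        elif pat in _G_LOOKUP:
            parity += "G"
            digits += _G_LOOKUP[pat]
        else:
            return None
    if parity not in _PARITY:
        return None
    first_digit = _PARITY[parity]
    for j in range(6):
        pat = s[50 + 7 * j : 57 + 7 * j]
        if pat not in _R_LOOKUP:
            return None
        digits += _R_LOOKUP[pat]
    return first_digit + digits


def _rectify(gray: np.ndarray, region: BarcodeRegion, inset: int = 3) -> np.ndarray:
    """Extract an upright crop of the region (in-plane rotation undone)."""
    h, w = gray.shape
    if abs(region.angle_deg) < 1.0:
        x0 = max(int(region.box.x_min) + inset, 0)
        x1 = min(int(math.ceil(region.box.x_max)) - inset, w)
        y0 = max(int(region.box.y_min) + inset, 0)
        y1 = min(int(math.ceil(region.box.y_max)) - inset, h)
        if x1 - x0 < 95 or y1 - y0 < 3:
            raise NoBarcodeError("candidate region too small to carry a barcode")
        return gray[y0:y1, x0:x1]
    pad = int(math.hypot(region.width, region.height) / 2) + 4
    cx, cy = int(round(region.center_x)), int(round(region.center_y))
    x0, x1 = max(cx - pad, 0), min(cx + pad, w)
    y0, y1 = max(cy - pad, 0), min(cy + pad, h)
    crop = gray[y0:y1, x0:x1].astype(float)
    rot = ndimage.rotate(crop, region.angle_deg, reshape=True, order=1, mode="nearest")
    rh, rw = rot.shape
    half_w = int(region.width / 2) - inset
    half_h = int(region.height / 2) - inset
    rcy, rcx = rh // 2, rw // 2
    out = rot[
        max(rcy - half_h, 0) : rcy + half_h,
        max(rcx - half_w, 0) : rcx + half_w,
    ]
    if out.shape[0] < 3 or out.shape[1] < 95:
        raise NoBarcodeError("candidate region too small to carry a barcode")
    return np.clip(np.rint(out), 0, 255).astype(np.uint8)


def decode_ean13(
    gray: np.ndarray,
    region: BarcodeRegion | None = None,
    n_scanlines: int = 9,
) -> str:
    """Decode an EAN-13 from a grayscale image (optionally a located region).

    Scans evenly spaced horizontal lines over the central band, decodes each
    independently, majority-votes digits across successful scanlines, and
    verifies the check digit.
    """
    if n_scanlines < 5:
        raise ValueError("need at least 5 scanlines")
    patch = _rectify(gray, region) if region is not None else np.asarray(gray)
    if patch.ndim != 2:
        raise ValueError("expected a grayscale image")
    h = patch.shape[0]
    rows = np.linspace(0.25 * h, 0.75 * h, n_scanlines).astype(int)
    decoded = [d for d in (_decode_scanline(patch[r]) for r in rows) if d is not None]
    if not decoded:
        raise NoBarcodeError("no guard pattern / digit structure on any scanline")
    code = "".join(Counter(col).most_common(1)[0][0] for col in zip(*decoded))
    if int(code[12]) != ean13_check_digit(code[:12]):
        raise CorruptCodeError(f"check digit mismatch in decoded code {code}")
    return code


# --------------------------------------------------------------------------
# full locate-then-decode chain


def locate_barcode(
    image: np.ndarray,
    coeffs: GrayscaleCoeffs = BT601,
    min_area_frac: float = 0.001,
    target_ratio: float = 2.0,
    ratio_tol: float = 0.25,
    debug: dict | None = None,
) -> tuple[BarcodeRegion, np.ndarray]:
    """Locate the label in a scene: grayscale, median, OTSU, Canny, contour
    screening.  Returns the largest surviving candidate and the filtered
    grayscale image the decoder should read from."""
    arr = np.asarray(image)
    gray = to_grayscale(arr, coeffs) if arr.ndim == 3 else arr.astype(np.uint8)
    med = median_filter_3x3(gray)
    t = otsu_threshold(histogram256(med))
    binary = binarize(med, t)
    edges = canny_edges(binary.astype(np.uint8) * 255)
    contours = find_contours(edges)
    min_area = min_area_frac * gray.shape[0] * gray.shape[1]
    cands = screen_barcode_candidates(contours, min_area, target_ratio, ratio_tol)
    if debug is not None:
        debug.update(gray=gray, median=med, threshold=t, binary=binary,
                     edges=edges, candidates=cands)
    if not cands:
        raise NoBarcodeError("no contour satisfies the area / 2:1 aspect screen")
    return cands[0], med


def read_position_code(image: np.ndarray, **locate_kwargs) -> str:
    """Scene image -> 13-digit code of its cage label."""
    region, med = locate_barcode(image, **locate_kwargs)
    return decode_ean13(med, region)
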