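"""Nuclear-envelope heterogeneity quantification (Distribution Index).

The Distribution Index (D.I.) of a nucleus is the standard deviation of
fluorescence intensity within a nuclear region of interest divided by
the mean intensity — a coefficient of variation, so 0 for a perfectly
homogeneous lamin rim and increasing with patchiness.

The ROI construction re-implements an ImageJ macro recipe primitive by
primitive with ImageJ semantics: linear min-max 8-bit conversion, Huang
fuzzy / Mean auto-thresholding on the 256-bin histogram, disc median
filtering, count-based 8-neighborhood binary erosion/dilation, and
particle analysis with hole filling, edge exclusion and a calibrated
minimum area. Three ROI protocols are provided: ``lamin`` (threshold +
erode), ``npc`` (median + dilate/erode cycle, for punctate pore
staining), and ``costain`` (ROI from a co-stained channel, measured on
the target channel).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .group_stats import TestResult, anova_tukey, ttest

__all__ = [
    "IntensityImage",
    "ThresholdResult",
    "Particle",
    "ParticleSet",
    "DIResult",
    "GroupedDI",
    "to_8bit",
    "auto_threshold",
    "median_filter",
    "binary_morph",
    "analyze_particles",
    "make_roi",
    "compute_di",
    "aggregate_individuals",
]


@dataclass
class IntensityImage:
    """Single-channel image with physical pixel size in micrometres."""

    data: np.ndarray
    pixel_size_um: float = 0.1

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 2:
            raise ValueError("expected a 2D single-channel image")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel size must be positive")
        if np.issubdtype(self.data.dtype, np.floating) and (self.data < 0).any():
            raise ValueError("negative intensities")

    @classmethod
    def load(cls, path, pixel_size_um: float = 0.1) -> "IntensityImage":
        path = str(path)
        if path.lower().endswith((".tif", ".tiff")):
            import tifffile

            data = tifffile.imread(path)
        else:
            from PIL import Image

            data = np.asarray(Image.open(path).convert("I"))
        return cls(np.squeeze(data), pixel_size_um)


def to_8bit(image: np.ndarray) -> np.ndarray:
    """Linear min-max conversion onto [0, 255], rounded to nearest.

    A degenerate (constant) image maps to all zeros with a warning.
    """
    img = np.asarray(image, dtype=float)
    lo, hi = img.min(), img.max()
    if hi == lo:
        warnings.warn("constant image: 8-bit conversion maps all pixels to 0")
        return np.zeros(img.shape, dtype=np.uint8)
    scaled = (img - lo) / (hi - lo) * 255.0
    return np.rint(scaled).astype(np.uint8)


# ---------------------------------------------------------------------------
# auto-thresholding
# ---------------------------------------------------------------------------

@dataclass
class ThresholdResult:
    mask: np.ndarray
    threshold: float
    degenerate: bool = False


def _huang_fuzziness(hist: np.ndarray, t: int, c: float) -> float:
    """Huang-Wang fuzziness (Shannon entropy of class membership) at
    threshold ``t`` over a 256-bin histogram."""
    levels = np.arange(256)
    w = hist.astype(float)
    lo_w = w[: t + 1]
    hi_w = w[t + 1:]
    total = w.sum()
    s = 0.0
    if lo_w.sum() > 0:
        mu0 = np.sum(levels[: t + 1] * lo_w) / lo_w.sum()
        m = 1.0 / (1.0 + np.abs(levels[: t + 1] - mu0) / c)
        ent = -(m * np.log(m) + np.where(m < 1, (1 - m) * np.log(np.clip(1 - m, 1e-300, None)), 0.0))
        s += np.sum(lo_w * ent)
    if hi_w.sum() > 0:
        mu1 = np.sum(levels[t + 1:] * hi_w) / hi_w.sum()
        m = 1.0 / (1.0 + np.abs(levels[t + 1:] - mu1) / c)
        ent = -(m * np.log(m) + np.where(m < 1, (1 - m) * np.log(np.clip(1 - m, 1e-300, None)), 0.0))
        s += np.sum(hi_w * ent)
    return float(s / total)


def huang_threshold(image8: np.ndarray) -> float:
    """Threshold minimizing the Huang-Wang fuzziness over the 8-bit
    histogram; ties resolve to the midpoint of the minimizing plateau."""
    hist = np.bincount(image8.ravel(), minlength=256)
    nz = np.flatnonzero(hist)
    first, last = int(nz[0]), int(nz[-1])
    if first == last:
        return float(first)
    c = float(last - first)
    fuzz = np.array([
        _huang_fuzziness(hist, t, c) for t in range(first, last)
    ])
    winners = np.flatnonzero(np.isclose(fuzz, fuzz.min(), rtol=0, atol=1e-12))
    return float(first + (winners[0] + winners[-1]) / 2.0)


def auto_threshold(
    image8: np.ndarray, method: str = "huang", dark_background: bool = True
) -> ThresholdResult:
    """Auto-threshold an 8-bit image (``huang`` or ``mean``).

    With a dark background the foreground is pixels strictly above the
    threshold. An empty foreground or background sets the degenerate
    flag rather than raising.
    """
    img = np.asarray(image8)
    if img.dtype != np.uint8:
        raise ValueError("auto_threshold expects an 8-bit image")
    if method == "huang":
        thr = huang_threshold(img)
    elif method == "mean":
        thr = float(img.mean())
    else:
        raise ValueError(f"unknown threshold method {method!r}")
    mask = img > thr if dark_background else img <= thr
    degenerate = bool(mask.all() or (~mask).all())
    return ThresholdResult(mask=mask, threshold=thr, degenerate=degenerate)


# ---------------------------------------------------------------------------
# filtering and binary morphology
# ---------------------------------------------------------------------------

def _disc_footprint(radius: float) -> np.ndarray:
    r = int(np.floor(radius))
    yy, xx = np.mgrid[-r: r + 1, -r: r + 1]
    return (yy**2 + xx**2) <= radius**2


def median_filter(image: np.ndarray, radius: float = 2) -> np.ndarray:
    """Disc median filter (13-pixel neighborhood at radius 2), edges
    handled by replication."""
    if radius < 1:
        raise ValueError("radius must be >= 1")
    return ndimage.median_filter(
        np.asarray(image), footprint=_disc_footprint(radius), mode="nearest"
    )


_NEIGH8 = np.array([[1, 1, 1], [1, 0, 1], [1, 1, 1]])


def binary_morph(mask: np.ndarray, op: str, iterations: int = 1, count: int = 1) -> np.ndarray:
    """Count-based 8-neighborhood binary erosion/dilation.

    Erode removes a foreground pixel when at least ``count`` of its 8
    neighbors are background; dilate adds a background pixel when at
    least ``count`` neighbors are foreground. Off-image neighbors are
    background.
    """
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    if not 1 <= count <= 8:
        raise ValueError("count must be in 1..8")
    m = np.asarray(mask, dtype=bool)
    for _ in range(iterations):
        fg_neighbors = ndimage.correlate(m.astype(np.uint8), _NEIGH8,
                                         mode="constant", cval=0)
        if op == "erode":
            bg_neighbors = 8 - fg_neighbors
            m = m & (bg_neighbors < count)
        elif op == "dilate":
            m = m | (~m & (fg_neighbors >= count))
        else:
            raise ValueError(f"unknown op {op!r}")
    return m


# ---------------------------------------------------------------------------
# particle analysis
# ---------------------------------------------------------------------------

@dataclass
class Particle:
    label: int
    mask: np.ndarray
    area_px: int
    area: float  # calibrated units^2 (or px when uncalibrated)
    bbox: tuple[int, int, int, int]  # (row0, col0, row1, col1)
    edge_touching: bool


@dataclass
class ParticleSet:
    particles: list[Particle]
    shape: tuple[int, int]

    def __len__(self) -> int:
        return len(self.particles)

    @property
    def labels(self) -> np.ndarray:
        out = np.zeros(self.shape, dtype=int)
        for p in self.particles:
            out[p.mask] = p.label
        return out

    def union_mask(self) -> np.ndarray:
        out = np.zeros(self.shape, dtype=bool)
        for p in self.particles:
            out |= p.mask
        return out


_STRUCT8 = np.ones((3, 3), dtype=bool)


def analyze_particles(
    mask: np.ndarray,
    min_size: float = 0.0,
    pixel_size_um: float | None = 0.1,
    exclude_edge_touching: bool = True,
    fill_holes: bool = True,
) -> ParticleSet:
    """ImageJ-style particle analysis of a binary mask.

    8-connected components; per-component holes are filled before area
    measurement when ``fill_holes``; components touching the image
    border are removed when ``exclude_edge_touching``; components with
    area below ``min_size`` (calibrated micrometres^2 when
    ``pixel_size_um`` is set, else pixels) are removed.
    """
    m = np.asarray(mask, dtype=bool)
    labeled, n = ndimage.label(m, structure=_STRUCT8)
    px_area = pixel_size_um**2 if pixel_size_um else 1.0
    particles = []
    slices = ndimage.find_objects(labeled)
    for lab in range(1, n + 1):
        sl = slices[lab - 1]
        comp = labeled[sl] == lab
        r0, c0 = sl[0].start, sl[1].start
        r1, c1 = sl[0].stop, sl[1].stop
        touching = r0 == 0 or c0 == 0 or r1 == m.shape[0] or c1 == m.shape[1]
        if exclude_edge_touching and touching:
            continue
        if fill_holes:
            comp = ndimage.binary_fill_holes(comp)
        area_px = int(comp.sum())
        area = area_px * px_area
        if area < min_size:
            continue
        full = np.zeros(m.shape, dtype=bool)
        full[sl] = comp
        particles.append(Particle(
            label=len(particles) + 1, mask=full, area_px=area_px, area=area,
            bbox=(r0, c0, r1, c1), edge_touching=touching,
        ))
    return ParticleSet(particles=particles, shape=m.shape)


# ---------------------------------------------------------------------------
# ROI protocols and the Distribution Index
# ---------------------------------------------------------------------------

def _lamin_rois(image: np.ndarray, pixel_size_um: float) -> tuple[list[np.ndarray], np.ndarray]:
    img8 = to_8bit(image)
    thr = auto_threshold(img8, "huang")
    ps = analyze_particles(thr.mask, min_size=30, pixel_size_um=pixel_size_um)
    eroded = binary_morph(ps.union_mask(), "erode", iterations=5, count=1)
    ps2 = analyze_particles(eroded, min_size=30, pixel_size_um=pixel_size_um)
    return [p.mask for p in ps2.particles], img8


def _npc_rois(image: np.ndarray, pixel_size_um: float) -> tuple[list[np.ndarray], np.ndarray]:
    img8 = to_8bit(image)
    filtered = median_filter(img8, radius=2)
    thr = auto_threshold(filtered, "mean")
    ps = analyze_particles(thr.mask, min_size=5, pixel_size_um=pixel_size_um)
    dilated = binary_morph(ps.union_mask(), "dilate", iterations=5, count=1)
    ps2 = analyze_particles(dilated, min_size=5, pixel_size_um=pixel_size_um)
    eroded = binary_morph(ps2.union_mask(), "erode", iterations=10, count=1)
    ps3 = analyze_particles(eroded, min_size=5, pixel_size_um=pixel_size_um)
    return [p.mask for p in ps3.particles], img8


def make_roi(
    image: np.ndarray,
    protocol: str = "lamin",
    pixel_size_um: float = 0.1,
    roi_source_image: np.ndarray | None = None,
) -> tuple[list[np.ndarray], np.ndarray]:
    """Construct per-nucleus ROI masks from a single-channel image.

    Protocols: ``lamin`` (8-bit, Huang threshold, particles >= 30 um^2,
    erode x5, particles again), ``npc`` (8-bit, median radius 2, Mean
    threshold, particles >= 5 um^2, dilate x5, erode x10), ``costain``
    (lamin protocol applied to ``roi_source_image``; returned ROIs are
    to be measured on the 8-bit conversion of ``image``).

    Returns ``(rois, measurement_image8)`` — per-nucleus boolean masks
    and the 8-bit image on which intensities are measured.
    """
    if protocol == "lamin":
        rois, img8 = _lamin_rois(image, pixel_size_um)
    elif protocol == "npc":
        rois, img8 = _npc_rois(image, pixel_size_um)
    elif protocol == "costain":
        if roi_source_image is None:
            raise ValueError("costain protocol requires roi_source_image")
        rois, _ = _lamin_rois(roi_source_image, pixel_size_um)
        img8 = to_8bit(image)
    else:
        raise ValueError(f"unknown protocol {protocol!r}")
    if not rois:
        warnings.warn(f"{protocol} protocol produced zero ROIs")
    return rois, img8


@dataclass
class DIResult:
    """Per-nucleus Distribution Index: sample SD / mean within the ROI."""

    nucleus_id: str
    di: float
    n_pixels: int
    mean: float
    sd: float


def compute_di(image8: np.ndarray, roi: np.ndarray, nucleus_id: str = "") -> DIResult:
    """D.I. = sample SD (n-1) of intensities in the ROI / their mean."""
    roi = np.asarray(roi, dtype=bool)
    vals = np.asarray(image8, dtype=float)[roi]
    if vals.size == 0:
        raise ValueError("empty ROI")
    mean = float(vals.mean())
    if mean <= 0:
        raise ValueError("zero mean intensity in ROI")
    sd = float(vals.std(ddof=1)) if vals.size > 1 else 0.0
    return DIResult(nucleus_id=nucleus_id, di=sd / mean, n_pixels=int(vals.size),
                    mean=mean, sd=sd)


# ---------------------------------------------------------------------------
# per-individual aggregation and group testing
# ---------------------------------------------------------------------------

@dataclass
class GroupedDI:
    """Per-nucleus D.I. values keyed by individual, with group labels."""

    values: dict[str, list[float]]  # individual -> D.I. per nucleus
    groups: dict[str, str] = field(default_factory=dict)  # individual -> group


def aggregate_individuals(grouped: GroupedDI) -> tuple[dict[str, float], TestResult]:
    """Per-individual mean D.I. plus the between-group test.

    Two groups are compared by the unpaired two-tailed t-test on
    individual means; more than two by one-way ANOVA with Tukey's
    multiple comparison. Warns when an individual has a nucleus count
    outside the 10-12 range used for acquisition.
    """
    means = {}
    for indiv, vals in grouped.values.items():
        if not 10 <= len(vals) <= 12:
            warnings.warn(f"individual {indiv!r} has {len(vals)} nuclei (expected 10-12)")
        means[indiv] = float(np.mean(vals))
    by_group: dict[str, list[float]] = {}
    for indiv, mean in means.items():
        by_group.setdefault(grouped.groups.get(indiv, "all"), []).append(mean)
    for g, v in by_group.items():
        if len(v) < 2:
            raise ValueError(f"group {g!r} has fewer than 2 individuals")
    samples = list(by_group.values())
    if len(samples) < 2:
        raise ValueError("need at least two groups to test")
    if len(samples) == 2:
        result = ttest(samples[0], samples[1])
    else:
        result = anova_tukey(samples)
    return means, result
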