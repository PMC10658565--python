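"""Time-lapse crystal-dissolution image analysis.

Segments the single crystal in each bright-field frame, tracks its 2D projected
area, normalizes to the first frame to give a percent-remaining release curve,
and compares complete-dissolution times between groups with one-way ANOVA.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage, stats
from skimage.filters import threshold_otsu
from skimage.measure import label

DEFAULT_FRAME_INTERVAL_MIN = 2.0  # assay default when timestamps are absent
DEFAULT_DETECTION_FLOOR = 0.01  # fraction of initial area counted as "dissolved"


class SegmentationError(ValueError):
    pass


@dataclass(frozen=True)
class Frame:
    """Single-channel micrograph with physical pixel size (µm) and timestamp (min)."""

    pixels: np.ndarray
    pixel_size: float
    timestamp: float

    def __post_init__(self):
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be > 0")
        px = np.asarray(self.pixels)
        if px.ndim != 2 or px.size == 0:
            raise ValueError("pixels must be a non-empty 2D grid")


@dataclass
class ImageStack:
    """Time-ordered frames of one crystal."""

    frames: list[Frame]
    label: str = ""

    def __post_init__(self):
        ts = [f.timestamp for f in self.frames]
        if any(t1 <= t0 for t0, t1 in zip(ts, ts[1:])):
            raise ValueError("frame timestamps must be strictly increasing")
        sizes = {f.pixel_size for f in self.frames}
        if len(sizes) > 1:
            raise ValueError("frames must share one pixel size")


@dataclass
class AreaSeries:
    """Projected area (µm²) and percent-remaining vs time for one crystal."""

    t: np.ndarray  # minutes
    area: np.ndarray  # µm²
    percent_remaining: np.ndarray  # % of first frame
    label: str = ""

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"label": self.label, "t_min": self.t,
                             "area_um2": self.area,
                             "percent_remaining": self.percent_remaining})


@dataclass(frozen=True)
class GroupComparison:
    """One-way fixed-effects ANOVA across groups of dissolution times."""

    group_labels: tuple
    n_per_group: tuple
    F_statistic: float
    p_value: float


@dataclass(frozen=True)
class StackDissolutionTime:
    time_min: float
    censored: bool


# ---------------------------------------------------------------------------
# Segmentation and area measurement
# ---------------------------------------------------------------------------

def segment_crystal(frame: Frame, polarity: str = "dark",
                    threshold: float | None = None) -> np.ndarray:
    """Binary mask of the crystal in one frame.

    Global Otsu threshold (or a caller-supplied one) at the configured contrast
    polarity — ``dark`` means a dark crystal on a bright background — followed
    by hole filling and retention of the largest 8-connected component.  A
    constant-intensity frame yields an empty mask with a low-contrast warning.
    """
    if polarity not in ("dark", "bright"):
        raise ValueError("polarity must be 'dark' or 'bright'")
    img = np.asarray(frame.pixels, dtype=float)
    if np.ptp(img) == 0.0 and threshold is None:
        warnings.warn("constant-intensity frame: no contrast to segment",
                      stacklevel=2)
        return np.zeros(img.shape, dtype=bool)
    thr = threshold_otsu(img) if threshold is None else threshold
    raw = img < thr if polarity == "dark" else img > thr
    if not raw.any():
        return raw
    filled = ndimage.binary_fill_holes(raw)
    labels, n = label(filled, connectivity=2, return_num=True)
    if n == 0:
        return np.zeros(img.shape, dtype=bool)
    counts = np.bincount(labels.ravel())[1:]
    return labels == (int(np.argmax(counts)) + 1)


def projected_area(mask: np.ndarray, pixel_size: float) -> float:
    """2D projected area in µm²: pixel count × pixel_size²."""
    return float(np.count_nonzero(mask)) * pixel_size ** 2


def percent_remaining_series(stack: ImageStack, polarity: str = "dark") -> AreaSeries:
    """Per-frame projected area normalized to the first frame (= 100%).

    The Otsu threshold is computed on the first frame (where the crystal is
    present by precondition) and reused for every later frame, so frames where
    the crystal has fully dissolved segment as empty instead of thresholding
    pure background noise.
    """
    if not stack.frames:
        raise ValueError("empty stack")
    first = stack.frames[0]
    img0 = np.asarray(first.pixels, dtype=float)
    thr = threshold_otsu(img0) if np.ptp(img0) > 0 else None
    mask0 = segment_crystal(first, polarity, threshold=thr)
    a0 = projected_area(mask0, first.pixel_size)
    if a0 == 0.0:
        raise SegmentationError("first frame segments to an empty mask; "
                                "nothing to normalize against")
    t = np.array([f.timestamp for f in stack.frames], dtype=float)
    areas = np.array([a0] + [
        projected_area(segment_crystal(f, polarity, threshold=thr), f.pixel_size)
        for f in stack.frames[1:]])
    return AreaSeries(t=t, area=areas, percent_remaining=100.0 * areas / a0,
                      label=stack.label)


def complete_dissolution_time_from_stack(
        stack: ImageStack, floor: float = DEFAULT_DETECTION_FLOOR,
        polarity: str = "dark") -> StackDissolutionTime:
    """Timestamp of the first frame whose area drops below ``floor`` × initial.

    Censored at the last timestamp if the floor is never reached.
    """
    series = percent_remaining_series(stack, polarity)
    below = series.percent_remaining < 100.0 * floor
    if below.any():
        return StackDissolutionTime(time_min=float(series.t[np.argmax(below)]),
                                    censored=False)
    return StackDissolutionTime(time_min=float(series.t[-1]), censored=True)


# ---------------------------------------------------------------------------
# Group statistics
# ---------------------------------------------------------------------------

def compare_groups_anova(groups: list, labels: list | None = None) -> GroupComparison:
    """One-way fixed-effects ANOVA on dissolution times (unequal n allowed)."""
    if len(groups) < 2:
        raise ValueError("ANOVA needs at least two groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    for i, g in enumerate(arrays):
        if len(g) < 2:
            raise ValueError(f"group {i} has n < 2")
    if labels is None:
        labels = [f"group{i}" for i in range(len(arrays))]
    if all(np.ptp(g) == 0 for g in arrays) and np.ptp(np.concatenate(arrays)) == 0:
        # identical constant groups: no between- or within-group variation
        F, p = 0.0, 1.0
    else:
        F, p = stats.f_oneway(*arrays)
    return GroupComparison(group_labels=tuple(labels),
                           n_per_group=tuple(len(g) for g in arrays),
                           F_statistic=float(F), p_value=float(p))


def group_summary(times_by_group: dict) -> pd.DataFrame:
    """Tidy per-group summary: label, n, mean and SD of dissolution times (min)."""
    rows = [{"group": key, "n": len(v), "mean_time_min": float(np.mean(v)),
             "sd_min": float(np.std(v, ddof=1))}
            for key, v in times_by_group.items()]
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Stack IO
# ---------------------------------------------------------------------------

_FRAME_NAME = re.compile(r"^(?P<label>.+)_t(?P<minutes>\d+(?:\.\d+)?)\.(tif|tiff|png)$")


def _read_image(path: Path) -> np.ndarray:
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile
        return np.asarray(tifffile.imread(path))
    import imageio.v3 as iio
    img = np.asarray(iio.imread(path))
    if img.ndim == 3:  # collapse any color channels
        img = img.mean(axis=-1)
    return img


def read_stacks(source, pixel_size: float | None = None,
                interval_min: float = DEFAULT_FRAME_INTERVAL_MIN) -> list[ImageStack]:
    """Load image stacks from a frame directory or a manifest CSV.

    Directory mode expects files named ``<label>_t<minutes>.tif`` (or .png);
    ``pixel_size`` (µm/px) must then be supplied.  Manifest mode reads columns
    ``path,label,t_min,pixel_size_um`` (extra columns such as ``zn_mM`` pass
    through via :func:`read_manifest_groups`).  Files without parsable
    timestamps fall back to uniform ``interval_min`` spacing in name order.
    """
    source = Path(source)
    entries: list[tuple[str, Path, float | None, float]] = []
    if source.is_dir():
        if pixel_size is None:
            raise ValueError("pixel_size is required for directory input")
        files = sorted(p for p in source.iterdir()
                       if p.suffix.lower() in (".tif", ".tiff", ".png"))
        if not files:
            raise FileNotFoundError(f"no TIFF/PNG frames in {source}")
        for p in files:
            m = _FRAME_NAME.match(p.name)
            if m:
                entries.append((m["label"], p, float(m["minutes"]), pixel_size))
            else:
                entries.append((p.stem, p, None, pixel_size))
    else:
        df = pd.read_csv(source)
        for _, row in df.iterrows():
            entries.append((str(row["label"]), Path(row["path"]),
                            float(row["t_min"]), float(row["pixel_size_um"])))

    stacks: dict[str, list[tuple[float | None, Path, float]]] = {}
    for lab, path, t, ps in entries:
        stacks.setdefault(lab, []).append((t, path, ps))
    out = []
    for lab, items in stacks.items():
        if any(t is None for t, _, _ in items):
            items = [(i * interval_min, p, ps)
                     for i, (_, p, ps) in enumerate(items)]
        items.sort(key=lambda x: x[0])
        frames = [Frame(pixels=_read_image(p), pixel_size=ps, timestamp=t)
                  for t, p, ps in items]
        out.append(ImageStack(frames=frames, label=lab))
    return out
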