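"""Synthetic-data generators with exact ground truth for every pipeline stage.

Generates crystal-form tables for the five polymorphs of the model anti-VEGF
nanobody, time-lapse dissolution stacks (a convex crystal silhouette whose
projected area follows a prescribed law, rendered with exact sub-pixel
coverage), two-transition DSC-like thermograms, and SLS traces with a flat
baseline followed by a saturating rise.  All randomness is driven by an
explicit seed and every generator returns its ground truth alongside the data.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import shapely
from shapely import affinity
from shapely.geometry import Polygon, box

from . import pk
from .imaging import AreaSeries, Frame, ImageStack
from .lattice import (CrystalForm, SpaceGroupInfo, UnitCell, cell_volume,
                      infer_molar_mass)
from .thermal import SLSTrace, Thermogram

# ---------------------------------------------------------------------------
# Crystal-form table
# ---------------------------------------------------------------------------

#: The five measured polymorphs of the model nanobody: cell parameters, space
#: group, copies per asymmetric unit, and the published Matthews coefficient /
#: solvent percentage used to back-fill the molar mass.
REFERENCE_FORM_RECORDS: list[dict] = [
    {"name": "mNb-WT", "cell": (31.468, 39.369, 39.952, 102.140, 90.231, 90.948),
     "space_group": "P1", "copies": 2, "matthews": 1.76, "solvent_pct": 30.0,
     "pdb_code": "8IIU"},
    {"name": "mutant 2", "cell": (31.220, 41.090, 74.050, 90.0, 90.0, 90.0),
     "space_group": "P212121", "copies": 1, "matthews": 1.73, "solvent_pct": 29.0,
     "pdb_code": "8IJZ"},
    {"name": "mutant 7", "cell": (24.985, 53.267, 65.364, 90.0, 90.0, 90.0),
     "space_group": "P212121", "copies": 1, "matthews": 1.57, "solvent_pct": 21.92,
     "pdb_code": "8IJS"},
    {"name": "analogue 1", "cell": (30.326, 38.419, 38.781, 101.846, 90.036, 92.225),
     "space_group": "P1", "copies": 2, "matthews": 1.59, "solvent_pct": 22.79,
     "pdb_code": None},
    {"name": "analogue 2", "cell": (30.381, 38.201, 38.773, 102.137, 90.1, 92.211),
     "space_group": "P1", "copies": 2, "matthews": 1.58, "solvent_pct": 22.30,
     "pdb_code": None},
]

#: Published cell volumes (Å³) for cross-checks.  The mutant 7 entry is known
#: to be ~0.4% below a·b·c from its own cell parameters (source-table
#: inconsistency) and is excluded from exact-volume checks.
REFERENCE_CELL_VOLUMES: dict[str, float] = {
    "mNb-WT": 48380.15, "mutant 2": 94993.55, "mutant 7": 86662.6,
    "analogue 1": 44186.2, "analogue 2": 43958.52,
}

#: Ordinal crystallization-propensity ranking (most to least crystallizable)
#: from screening-condition counts; used only as an ordinal fixture.
CRYSTALLIZATION_RANKING = ["analogue 1", "analogue 2", "mNb-WT", "mutant 2"]


def make_crystal_table(n_random: int = 0, seed: int | None = None) -> list[CrystalForm]:
    """The five reference polymorphs, molar masses back-filled from the
    published Matthews coefficients; optionally plus randomized valid variants."""
    forms = []
    for rec in REFERENCE_FORM_RECORDS:
        cell = UnitCell(*rec["cell"])
        sg = SpaceGroupInfo.from_symbol(rec["space_group"])
        mass = infer_molar_mass(cell_volume(cell), sg.multiplicity,
                                rec["copies"], rec["matthews"])
        forms.append(CrystalForm(name=rec["name"], cell=cell, space_group=sg,
                                 copies_per_asu=rec["copies"], molar_mass=mass))
    if n_random:
        rng = np.random.default_rng(seed)
        for i in range(n_random):
            a, b, c = rng.uniform(20, 120, size=3)
            if rng.random() < 0.5:
                angles = (90.0, 90.0, 90.0)
                sg = SpaceGroupInfo.from_symbol("P212121")
            else:
                angles = tuple(rng.uniform(75, 105, size=3))
                sg = SpaceGroupInfo.from_symbol("P1")
            cell = UnitCell(a, b, c, *angles)
            forms.append(CrystalForm(
                name=f"random {i}", cell=cell, space_group=sg,
                copies_per_asu=int(rng.integers(1, 3)),
                molar_mass=float(rng.uniform(10e3, 50e3))))
    return forms


# ---------------------------------------------------------------------------
# Dissolution image stacks
# ---------------------------------------------------------------------------

def _unit_polygon(shape: str) -> Polygon:
    if shape == "lamella":  # regular hexagon
        ang = np.pi / 3 * np.arange(6)
        pts = np.c_[np.cos(ang), np.sin(ang)]
    elif shape == "prism":  # elongated 4:1 rectangle
        pts = np.array([[-2, -0.5], [2, -0.5], [2, 0.5], [-2, 0.5]])
    else:
        raise ValueError("shape must be 'lamella' or 'prism'")
    return Polygon(pts)


def _render_coverage(poly: Polygon, shape_hw: tuple[int, int]) -> np.ndarray:
    """Exact per-pixel area coverage of *poly* on an integer pixel grid.

    Pixels well inside (outside) a 1.5 px buffer of the boundary get coverage
    1 (0); pixels in the boundary band get the exact polygon∩pixel area.
    """
    h, w = shape_hw
    cov = np.zeros((h, w), dtype=float)
    if poly.is_empty or poly.area == 0.0:
        return cov
    minx, miny, maxx, maxy = poly.bounds
    x0, x1 = max(int(np.floor(minx)) - 1, 0), min(int(np.ceil(maxx)) + 1, w)
    y0, y1 = max(int(np.floor(miny)) - 1, 0), min(int(np.ceil(maxy)) + 1, h)
    if x0 >= x1 or y0 >= y1:
        return cov
    xs = np.arange(x0, x1) + 0.5
    ys = np.arange(y0, y1) + 0.5
    X, Y = np.meshgrid(xs, ys)
    inner = poly.buffer(-1.5)
    outer = poly.buffer(1.5)
    full = (shapely.contains_xy(inner, X.ravel(), Y.ravel()).reshape(X.shape)
            if not inner.is_empty else np.zeros(X.shape, dtype=bool))
    near = shapely.contains_xy(outer, X.ravel(), Y.ravel()).reshape(X.shape)
    band = near & ~full
    cov[y0:y1, x0:x1][full] = 1.0
    for iy, ix in zip(*np.nonzero(band)):
        px, py = x0 + ix, y0 + iy
        cov[py, px] = poly.intersection(box(px, py, px + 1, py + 1)).area
    return cov


@dataclass(frozen=True)
class StackSpec:
    """Conditions for one synthetic dissolution stack.

    Defaults mirror the release assay the generator emulates: frames at 2-min
    intervals, bright-field contrast (dark crystal on bright background), a
    crystal silhouette of ~10,000 px initially, and additive Gaussian noise.
    """

    seed: int = 0
    noise_level: float = 0.05  # SD as a fraction of the crystal/background contrast
    shape: str = "lamella"
    orientation_deg: float = 20.0  # crystals lie at arbitrary angles; an oblique
    # default avoids the degenerate grid-aligned case where every pixel along a
    # straight edge quantizes identically
    n_frames: int = 11
    interval_min: float = 2.0
    pixel_size_um: float = 0.5
    initial_area_px: float = 10_000.0
    canvas: tuple[int, int] = (192, 192)
    background: float = 0.9
    foreground: float = 0.25


def make_dissolution_stack(spec: StackSpec = StackSpec(), law: str = "linear",
                           depot: "pk.CrystalDepot | None" = None,
                           params: "pk.PKParameters | None" = None,
                           label: str | None = None
                           ) -> tuple[ImageStack, AreaSeries]:
    """Render a shrinking-crystal time-lapse with exact ground-truth areas.

    ``law='linear'`` shrinks the projected area linearly from the initial value
    to zero across the stack.  ``law='pk_profile'`` follows M(t)/M0 from the
    sink-condition lamellar dissolution model (projected area ∝ remaining mass
    for constant-thickness lamellae); *depot* and *params* default to a
    scenario that decays to ~20% over the stack.  Returns the stack and the
    ground-truth :class:`AreaSeries`.
    """
    rng = np.random.default_rng(spec.seed)
    t_min = spec.interval_min * np.arange(spec.n_frames)

    if law == "linear":
        frac = 1.0 - np.arange(spec.n_frames) / (spec.n_frames - 1)
    elif law == "pk_profile":
        if depot is None:
            depot = pk.CrystalDepot(M0=1.0, A0=1.0, geometry_mode="lamellar")
        if params is None:
            # sink dissolution rate chosen so mass falls to ~20% over the stack
            t_end_days = t_min[-1] / (24.0 * 60.0)
            rate = np.log(5.0) / t_end_days  # A0*h*Cs/M0
            params = pk.PKParameters(k=1e-6, h=rate, V=1.0, Cs=1.0)
        t_days = t_min / (24.0 * 60.0)
        grid = t_days if t_days[0] == 0.0 else np.r_[0.0, t_days]
        prof = pk.simulate_crystal_depot(depot, params, grid, sink=True)
        frac = prof.M[-spec.n_frames:] / depot.M0
    else:
        raise ValueError("law must be 'linear' or 'pk_profile'")

    clipped = frac < 0
    if clipped.any():
        warnings.warn("area law went negative; clipped to 0", stacklevel=2)
        frac = np.clip(frac, 0.0, None)

    base = _unit_polygon(spec.shape)
    h, w = spec.canvas
    cx, cy = w / 2.0, h / 2.0
    contrast = spec.background - spec.foreground
    frames, truth_area_px = [], []
    for i, f in enumerate(frac):
        target_px = spec.initial_area_px * f
        if target_px > 0:
            s = float(np.sqrt(target_px / base.area))
            poly = affinity.scale(base, xfact=s, yfact=s, origin=(0, 0))
            poly = affinity.rotate(poly, spec.orientation_deg, origin=(0, 0))
            poly = affinity.translate(poly, xoff=cx, yoff=cy)
            cov = _render_coverage(poly, spec.canvas)
        else:
            cov = np.zeros(spec.canvas, dtype=float)
        truth_area_px.append(float(cov.sum()))
        img = spec.background - contrast * cov
        if spec.noise_level > 0:
            img = img + rng.normal(0.0, spec.noise_level * contrast, size=img.shape)
        frames.append(Frame(pixels=img.astype(np.float32),
                            pixel_size=spec.pixel_size_um, timestamp=float(t_min[i])))

    lab = label or f"{spec.shape}_{law}_seed{spec.seed}"
    areas_um2 = np.array(truth_area_px) * spec.pixel_size_um ** 2
    truth = AreaSeries(t=t_min.astype(float), area=areas_um2,
                       percent_remaining=100.0 * np.asarray(frac), label=lab)
    return ImageStack(frames=frames, label=lab), truth


def write_stack(stack: ImageStack, truth: AreaSeries, out_dir) -> list[Path]:
    """Write frames as ``<label>_t<minutes>.tif`` plus a ``.truth.json`` sidecar."""
    import tifffile

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = []
    for fr in stack.frames:
        t = fr.timestamp
        tag = f"{t:g}" if t == int(t) else f"{t:.2f}"
        p = out / f"{stack.label}_t{tag}.tif"
        tifffile.imwrite(p, np.asarray(fr.pixels, dtype=np.float32))
        paths.append(p)
    sidecar = out / f"{stack.label}.truth.json"
    sidecar.write_text(json.dumps({
        "label": truth.label,
        "t_min": truth.t.tolist(),
        "area_um2": truth.area.tolist(),
        "percent_remaining": truth.percent_remaining.tolist(),
        "pixel_size_um": stack.frames[0].pixel_size,
    }, indent=1))
    paths.append(sidecar)
    return paths


# ---------------------------------------------------------------------------
# Thermal curves
# ---------------------------------------------------------------------------

DSC_GRID = np.round(np.arange(15.0, 100.0 + 1e-9, 0.2), 6)  # °C, scan range
SLS_GRID = np.round(np.arange(15.0, 95.0 + 1e-9, 0.2), 6)


def make_thermogram(Tm1: float = 55.0, Tm2: float = 63.0,
                    widths: tuple[float, float] = (2.5, 3.0),
                    amps: tuple[float, float] = (1.0, 0.8),
                    baseline: tuple[float, float] = (0.002, 0.05),
                    noise: float = 0.02, seed: int | None = 0) -> Thermogram:
    """Two Gaussian unfolding peaks on a linear baseline over the 15–100 °C scan.

    *noise* is the additive Gaussian SD as a fraction of the taller peak.
    Peaks closer than the 3 °C detector separation limit trigger a warning.
    """
    if not Tm1 < Tm2:
        raise ValueError("Tm1 must be below Tm2")
    for tm in (Tm1, Tm2):
        if not 15.0 < tm < 100.0:
            raise ValueError("transitions must lie inside the 15-100 degC scan")
    if Tm2 - Tm1 < MIN_SEP_WARN:
        warnings.warn(f"peaks only {Tm2 - Tm1:.1f} degC apart: below the "
                      "detector's 3 degC separation limit", stacklevel=2)
    T = DSC_GRID
    y = (amps[0] * np.exp(-0.5 * ((T - Tm1) / widths[0]) ** 2)
         + amps[1] * np.exp(-0.5 * ((T - Tm2) / widths[1]) ** 2)
         + baseline[0] * T + baseline[1])
    if noise > 0:
        rng = np.random.default_rng(seed)
        y = y + rng.normal(0.0, noise * max(amps), size=T.shape)
    return Thermogram(T=T, signal=y)


MIN_SEP_WARN = 3.0


def make_sls_trace(Tagg: float | None = 45.0, steepness: float = 1.0,
                   wavelength: int = 266, amp: float = 1.0,
                   baseline_level: float = 0.1, noise: float = 0.02,
                   seed: int | None = 0) -> SLSTrace:
    """Flat baseline then a saturating aggregation rise beginning at *Tagg*.

    The rise is amp·(1 − exp(−(T − Tagg)/steepness)) for T > Tagg and exactly
    zero below, so the onset temperature is unambiguous ground truth.
    ``Tagg=None`` yields a flat (noise-only) trace.  *noise* is the additive
    Gaussian SD as a fraction of *amp*.
    """
    T = SLS_GRID
    y = np.full_like(T, baseline_level)
    if Tagg is not None:
        if not 15.0 < Tagg < 95.0:
            raise ValueError("Tagg must lie inside the 15-95 degC scan")
        u = np.clip((T - Tagg) / steepness, 0.0, None)
        y = y + amp * (1.0 - np.exp(-u))
    if noise > 0:
        rng = np.random.default_rng(seed)
        y = y + rng.normal(0.0, noise * amp, size=T.shape)
    return SLSTrace(T=T, signal=y, wavelength=wavelength)


def write_curve(T: np.ndarray, signal: np.ndarray, path) -> Path:
    """Write a curve in the ``T_C,signal`` CSV dialect."""
    import pandas as pd

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame({"T_C": T, "signal": signal}).to_csv(path, index=False)
    return path
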