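"""Thermal unfolding and aggregation-onset analysis, and crystallization-propensity calls.

Nanobodies in this family show two unfolding transitions in a DSC scan (Tm1,
Tm2, with Tm2 the structure-destroying event) and an aggregation onset (Tagg)
in static light scattering — 266 nm reports small assemblies, 473 nm large
aggregates.  Empirically, thermostable variants (high Tm2) whose 266 nm Tagg
sits in a moderate window crystallize readily, those with very low Tagg
precipitate, and those with very high Tagg stay in solution; the classifier
encodes that three-way partition with configurable thresholds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import find_peaks, savgol_filter

#: Default Tagg(266 nm) partition (°C): below → precipitation-prone, above →
#: solution-stable, between → crystallization-prone, with a favored sub-band.
DEFAULT_PRECIP_MAX = 36.1
DEFAULT_STABLE_MIN = 55.6
DEFAULT_FAVORED_BAND = (45.0, 50.0)
#: Tm2 above this marks the variant as thermostable in the rationale.
DEFAULT_HIGH_TM = 61.6

MIN_PEAK_SEPARATION_C = 3.0


@dataclass(frozen=True)
class Thermogram:
    """DSC-like excess-heat trace on a strictly increasing temperature grid (°C)."""

    T: np.ndarray
    signal: np.ndarray

    def __post_init__(self):
        T = np.asarray(self.T, dtype=float)
        if len(T) < 50:
            raise ValueError("thermogram needs >= 50 grid points")
        if np.any(np.diff(T) <= 0):
            raise ValueError("temperature grid must be strictly increasing")
        if len(self.signal) != len(T):
            raise ValueError("signal length must match temperature grid")


@dataclass(frozen=True)
class SLSTrace:
    """Static-light-scattering intensity trace at 266 or 473 nm."""

    T: np.ndarray
    signal: np.ndarray
    wavelength: int

    def __post_init__(self):
        T = np.asarray(self.T, dtype=float)
        if np.any(np.diff(T) <= 0):
            raise ValueError("temperature grid must be strictly increasing")
        if len(self.signal) != len(T):
            raise ValueError("signal length must match temperature grid")
        if self.wavelength not in (266, 473):
            raise ValueError("wavelength must be 266 or 473 nm")


@dataclass(frozen=True)
class ThermalSummary:
    """Extracted transition temperatures for one protein (°C; None = absent)."""

    Tm1: float | None
    Tm2: float | None
    Tagg266: float | None = None
    Tagg473: float | None = None

    def __post_init__(self):
        if self.Tm1 is not None and self.Tm2 is not None and not self.Tm1 < self.Tm2:
            raise ValueError("Tm1 must be below Tm2")


@dataclass(frozen=True)
class UnfoldingResult:
    Tm1: float | None
    Tm2: float | None
    single_event: bool


@dataclass(frozen=True)
class PropensityCall:
    label: str  # crystallization-prone | precipitation-prone | solution-stable | indeterminate
    rationale: str


# ---------------------------------------------------------------------------
# Curve analysis
# ---------------------------------------------------------------------------

def _subtract_linear_baseline(T: np.ndarray, y: np.ndarray,
                              edge_frac: float = 0.1) -> np.ndarray:
    # fit the baseline to the outer edges of the scan, where no transition sits
    n = max(int(edge_frac * len(T)), 3)
    idx = np.r_[0:n, len(T) - n:len(T)]
    coef = np.polyfit(T[idx], y[idx], 1)
    return y - np.polyval(coef, T)


def _refine_quadratic(T: np.ndarray, y: np.ndarray, i: int, half: int = 7) -> float:
    # sub-grid peak position from a local quadratic fit around grid index i
    lo, hi = max(i - half, 0), min(i + half + 1, len(T))
    if hi - lo < 3:
        return float(T[i])
    a, b, _ = np.polyfit(T[lo:hi] - T[i], y[lo:hi], 2)
    if a >= 0:
        return float(T[i])
    shift = -b / (2.0 * a)
    step = float(np.median(np.diff(T[lo:hi])))
    return float(T[i] + np.clip(shift, -step * half, step * half))


def detect_unfolding_events(tg: Thermogram, prominence_frac: float = 0.05,
                            min_separation: float = MIN_PEAK_SEPARATION_C
                            ) -> UnfoldingResult:
    """Locate the two unfolding transitions in a thermogram.

    Baseline-subtract (linear fit to the scan edges), smooth lightly, and take
    the two most prominent local maxima separated by at least *min_separation*
    °C, each refined to sub-grid precision by a local quadratic fit.  If only
    one peak clears the prominence threshold the result is flagged as a single
    event with Tm2 = None.
    """
    T = np.asarray(tg.T, dtype=float)
    y = _subtract_linear_baseline(T, np.asarray(tg.signal, dtype=float))
    win = min(17, len(y) - (1 - len(y) % 2))  # odd, <= series length
    ys = savgol_filter(y, window_length=win, polyorder=2) if win >= 5 else y
    span = float(np.ptp(ys))
    if span == 0.0:
        return UnfoldingResult(Tm1=None, Tm2=None, single_event=True)
    peaks, props = find_peaks(ys, prominence=prominence_frac * span)
    if len(peaks) == 0:
        return UnfoldingResult(Tm1=None, Tm2=None, single_event=True)
    order = np.argsort(props["prominences"])[::-1]
    chosen = [peaks[order[0]]]
    for j in order[1:]:
        if all(abs(T[peaks[j]] - T[c]) >= min_separation for c in chosen):
            chosen.append(peaks[j])
        if len(chosen) == 2:
            break
    temps = sorted(_refine_quadratic(T, ys, i) for i in chosen)
    if len(temps) == 1:
        return UnfoldingResult(Tm1=temps[0], Tm2=None, single_event=True)
    return UnfoldingResult(Tm1=temps[0], Tm2=temps[1], single_event=False)


def detect_onset(trace: SLSTrace, n_sd: float = 5.0, persistence: int = 3,
                 baseline_span_C: float = 8.0) -> float | None:
    """Aggregation onset: first temperature where the signal exceeds the
    initial-plateau median + *n_sd* robust SDs and stays above for
    *persistence* consecutive points.  Returns None if never exceeded.

    The initial plateau is the first *baseline_span_C* degrees of the scan
    (at least 10 points).  Robust SD = 1.4826 × MAD, floored at 0.1% of the
    signal range so a noiseless trace still needs a genuine rise; the rule is
    invariant to uniform scaling of the signal.
    """
    T = np.asarray(trace.T, dtype=float)
    y = np.asarray(trace.signal, dtype=float)
    n_base = max(int(np.searchsorted(T, T[0] + baseline_span_C)), 10)
    base = y[:n_base]
    med = float(np.median(base))
    mad = float(np.median(np.abs(base - med)))
    robust_sd = 1.4826 * mad
    span = float(np.ptp(y))
    if span == 0.0:
        return None
    threshold = med + n_sd * max(robust_sd, 1e-3 * span)
    above = y > threshold
    run = 0
    for i, flag in enumerate(above):
        run = run + 1 if flag else 0
        if run >= persistence:
            return float(T[i - persistence + 1])
    return None


# ---------------------------------------------------------------------------
# Propensity classification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PropensityThresholds:
    """Configurable Tagg(266) partition; defaults follow the observed windows."""

    precip_max: float = DEFAULT_PRECIP_MAX
    stable_min: float = DEFAULT_STABLE_MIN
    favored_band: tuple[float, float] = DEFAULT_FAVORED_BAND
    high_tm: float = DEFAULT_HIGH_TM


def classify_propensity(summary: ThermalSummary,
                        thresholds: PropensityThresholds = PropensityThresholds()
                        ) -> PropensityCall:
    """Three-way crystallization-propensity call from Tagg(266 nm).

    The Tagg266 axis partitions closed-left/open-right:
    (-inf, precip_max) → precipitation-prone; [precip_max, stable_min) →
    crystallization-prone (annotated "favored" inside the favored band);
    [stable_min, inf) → solution-stable.  Absent Tagg266 → indeterminate.
    Tm2 is required and noted in the rationale when above the high-Tm mark.
    """
    if summary.Tm2 is None:
        raise ValueError("classification requires Tm2")
    th = thresholds
    tm_note = (f"Tm2={summary.Tm2:.1f}degC "
               + (f">= {th.high_tm} (thermostable)" if summary.Tm2 >= th.high_tm
                  else f"< {th.high_tm}"))
    tagg = summary.Tagg266
    if tagg is None:
        return PropensityCall("indeterminate", f"no Tagg(266) onset detected; {tm_note}")
    if tagg < th.precip_max:
        return PropensityCall(
            "precipitation-prone",
            f"Tagg266={tagg:.1f} < {th.precip_max}degC: strong aggregation; {tm_note}")
    if tagg >= th.stable_min:
        return PropensityCall(
            "solution-stable",
            f"Tagg266={tagg:.1f} >= {th.stable_min}degC: aggregation too weak; {tm_note}")
    lo, hi = th.favored_band
    favored = " (favored band {:.0f}-{:.0f}degC)".format(lo, hi) if lo <= tagg < hi else ""
    return PropensityCall(
        "crystallization-prone",
        f"Tagg266={tagg:.1f} in [{th.precip_max}, {th.stable_min})degC{favored}; {tm_note}")


# ---------------------------------------------------------------------------
# Batch IO
# ---------------------------------------------------------------------------

def read_curve_csv(path) -> pd.DataFrame:
    """Read a single-curve CSV with columns ``T_C,signal``."""
    df = pd.read_csv(path)
    if not {"T_C", "signal"} <= set(df.columns):
        raise ValueError(f"{path}: curve CSV must have columns T_C,signal")
    return df


def summarize_panel(manifest: pd.DataFrame, base_dir=".") -> pd.DataFrame:
    """Run the full extraction over a manifest ``path,protein,curve_type``.

    ``curve_type`` is one of dsc / sls266 / sls473.  Returns one row per
    protein: Tm1, Tm2, Tagg266, Tagg473 and the propensity label.
    """
    from pathlib import Path

    results: dict[str, dict] = {}
    for _, row in manifest.iterrows():
        protein = str(row["protein"])
        curve = read_curve_csv(Path(base_dir) / str(row["path"]))
        rec = results.setdefault(protein, {})
        ctype = str(row["curve_type"])
        if ctype == "dsc":
            res = detect_unfolding_events(
                Thermogram(T=curve["T_C"].to_numpy(), signal=curve["signal"].to_numpy()))
            rec["Tm1"], rec["Tm2"] = res.Tm1, res.Tm2
        elif ctype in ("sls266", "sls473"):
            wl = 266 if ctype == "sls266" else 473
            onset = detect_onset(SLSTrace(T=curve["T_C"].to_numpy(),
                                          signal=curve["signal"].to_numpy(),
                                          wavelength=wl))
            rec[f"Tagg{wl}"] = onset
        else:
            raise ValueError(f"unknown curve_type {ctype!r}")

    rows = []
    for protein, rec in results.items():
        summary = ThermalSummary(Tm1=rec.get("Tm1"), Tm2=rec.get("Tm2"),
                                 Tagg266=rec.get("Tagg266"),
                                 Tagg473=rec.get("Tagg473"))
        label = (classify_propensity(summary).label
                 if summary.Tm2 is not None else "indeterminate")
        rows.append({"protein": protein, "Tm1": summary.Tm1, "Tm2": summary.Tm2,
                     "Tagg266": summary.Tagg266, "Tagg473": summary.Tagg473,
                     "label": label})
    return pd.DataFrame(rows)
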