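"""UV/Vis heme spectroscopy: band detection, state calls, titration analysis.

The Soret band near 400 nm is an intense porphyrin pi->pi* absorption whose
exact position reports the oxidation and ligation state of the heme iron,
and the weaker beta/alpha bands near 525/553 nm are diagnostic of
6-coordinate ferrous heme.  The classifier implements window-based rules
around the canonical positions for a histidine-ligated heme protein:

* 408 nm Soret                          -> ferric, His-ligated
* 418 nm Soret + 525/553 nm beta/alpha  -> ferrous 6-coordinate
* 398 nm Soret                          -> ferrous 5-coordinate nitrosyl
* 436 nm Soret (~400 nm shoulder)       -> free hemin in buffer
* no Soret at all                       -> apo (no heme incorporated)

Rules are ordered so the beta/alpha requirement disambiguates the 418 nm
ferrous peak from nearby 408/398 shoulders.  The transient 6-coordinate
NO intermediate (~420 nm) is not a built-in state — it can be added via a
custom :class:`ClassifierConfig` — because it is typically not observed
on the mixing timescale of plate-reader titrations.

Titrations with an NO donor are judged saturated once consecutive spectra
stop changing (max-norm below tolerance), the operational criterion for
"further donor addition causes no spectral change".
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.signal import find_peaks, savgol_filter

SORET = "SORET"
BETA = "BETA"
ALPHA = "ALPHA"
OTHER = "OTHER"

FERRIC_HIS_LIGATED = "FERRIC_HIS_LIGATED"
FERROUS_6C = "FERROUS_6C"
FERROUS_5C_NO = "FERROUS_5C_NO"
FREE_HEMIN = "FREE_HEMIN"
APO_NO_HEME = "APO_NO_HEME"
AMBIGUOUS = "AMBIGUOUS"

HEME_STATES = (FERRIC_HIS_LIGATED, FERROUS_6C, FERROUS_5C_NO, FREE_HEMIN, APO_NO_HEME)


class SpectrumError(ValueError):
    """Invalid spectrum or series input."""


@dataclass(frozen=True)
class Spectrum:
    """A wavelength grid (nm, strictly ascending) with absorbance values (AU)."""

    wavelengths: np.ndarray
    absorbance: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths, dtype=float)
        ab = np.asarray(self.absorbance, dtype=float)
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "absorbance", ab)
        if wl.ndim != 1 or ab.shape != wl.shape:
            raise SpectrumError("wavelengths and absorbance must be equal-length 1-D")
        if wl.size < 3:
            raise SpectrumError("spectrum needs at least 3 points")
        if not np.all(np.diff(wl) > 0):
            raise SpectrumError("wavelength grid must be strictly ascending")

    @property
    def n_points(self) -> int:
        return int(self.wavelengths.size)

    def covers(self, lo: float, hi: float) -> bool:
        return self.wavelengths[0] <= lo and self.wavelengths[-1] >= hi

    def resampled(self, grid: np.ndarray) -> "Spectrum":
        return Spectrum(grid, np.interp(grid, self.wavelengths, self.absorbance), self.label)


def read_spectrum_csv(path: str | Path, label: str | None = None) -> Spectrum:
    """Two-column CSV/TSV (wavelength_nm, absorbance_AU), optional header."""
    df = pd.read_csv(path, sep=None, engine="python", comment="#", header=None)
    if df.shape[1] < 2:
        raise SpectrumError(f"{path}: expected two columns")
    first = df.iloc[0]
    try:
        float(first[0]), float(first[1])
        skip = 0
    except (TypeError, ValueError):
        skip = 1
    wl = pd.to_numeric(df.iloc[skip:, 0]).to_numpy()
    ab = pd.to_numeric(df.iloc[skip:, 1]).to_numpy()
    return Spectrum(wl, ab, label or Path(path).stem)


def write_spectrum_csv(spectrum: Spectrum, path: str | Path) -> None:
    pd.DataFrame(
        {"wavelength_nm": spectrum.wavelengths, "absorbance_AU": spectrum.absorbance}
    ).to_csv(path, index=False)


@dataclass(frozen=True)
class PeakCall:
    lambda_max: float
    height: float
    prominence: float
    band_class: str

    def __post_init__(self) -> None:
        if self.prominence < 0:
            raise SpectrumError("prominence must be non-negative")


@dataclass(frozen=True)
class HemeStateCall:
    state: str
    supporting_peaks: tuple[PeakCall, ...]
    rationale: str


@dataclass(frozen=True)
class ClassifierConfig:
    """Windows (nm) and thresholds for band assignment and state calls.

    Centers are the canonical values for a His-ligated heme-b protein;
    half-widths default to 4-6 nm since only center wavelengths are
    typically reported.
    """

    soret_region: tuple[float, float] = (380.0, 450.0)
    beta_region: tuple[float, float] = (515.0, 535.0)
    alpha_region: tuple[float, float] = (545.0, 565.0)
    ferric_soret: tuple[float, float] = (408.0, 4.0)      # (center, half-width)
    ferrous_soret: tuple[float, float] = (418.0, 4.0)
    ferrous_beta: tuple[float, float] = (525.0, 6.0)
    ferrous_alpha: tuple[float, float] = (553.0, 6.0)
    no5c_soret: tuple[float, float] = (398.0, 4.0)
    hemin_soret: tuple[float, float] = (436.0, 5.0)
    # Noise bumps on a 1-nm grid survive smoothing with prominence up to
    # ~0.02 AU at sd 0.01; the weakest genuine bands (beta/alpha) sit near
    # 0.08 AU.  0.04 separates the two floors with margin on both sides.
    min_prominence: float = 0.04
    baseline_region: tuple[float, float] = (570.0, 600.0)
    smooth_window: int = 11
    smooth_order: int = 2
    min_points: int = 20
    required_coverage: tuple[float, float] = (350.0, 600.0)


DEFAULT_CONFIG = ClassifierConfig()


def _in_window(value: float, window: tuple[float, float]) -> bool:
    center, half = window
    return abs(value - center) <= half


# ---------------------------------------------------------------------------
# smoothing and peak detection

def smooth(spectrum: Spectrum, window: int, order: int) -> Spectrum:
    """Savitzky-Golay (moving least-squares polynomial) smoothing.

    The grid is unchanged; endpoints are handled by fitting the edge
    polynomial over the terminal window.  A polynomial of degree <= order
    is reproduced exactly.
    """
    if window % 2 == 0:
        raise SpectrumError(f"window must be odd, got {window}")
    if order >= window:
        raise SpectrumError(f"order ({order}) must be < window ({window})")
    if window > spectrum.n_points:
        raise SpectrumError(
            f"window ({window}) exceeds number of points ({spectrum.n_points})"
        )
    sm = savgol_filter(spectrum.absorbance, window, order, mode="interp")
    return Spectrum(spectrum.wavelengths, sm, spectrum.label)


def _baseline(spectrum: Spectrum, region: tuple[float, float]) -> np.ndarray:
    """Linear baseline fitted on the flat long-wavelength tail."""
    wl, ab = spectrum.wavelengths, spectrum.absorbance
    mask = (wl >= region[0]) & (wl <= region[1])
    if mask.sum() >= 2:
        slope, intercept = np.polyfit(wl[mask], ab[mask], 1)
        return intercept + slope * wl
    return np.full_like(ab, float(np.min(ab)))


def detect_peaks(
    spectrum: Spectrum,
    min_prominence: float = DEFAULT_CONFIG.min_prominence,
    region: tuple[float, float] | None = None,
    config: ClassifierConfig = DEFAULT_CONFIG,
) -> list[PeakCall]:
    """Local maxima above a prominence threshold, sub-grid refined.

    A linear baseline estimated over ``config.baseline_region`` is removed
    first; ``lambda_max`` is refined by 3-point parabolic interpolation.
    Calls are sorted by descending prominence and classed as SORET, BETA,
    ALPHA or OTHER by the config's band regions.
    """
    wl = spectrum.wavelengths
    if region is not None:
        lo, hi = region
        if lo >= hi or hi < wl[0] or lo > wl[-1]:
            raise SpectrumError(f"empty or out-of-grid region {region}")
    y = spectrum.absorbance - _baseline(spectrum, config.baseline_region)
    idx, props = find_peaks(y, prominence=min_prominence)
    calls: list[PeakCall] = []
    for i, prom in zip(idx, props["prominences"]):
        # parabolic apex refinement: least-squares quadratic over a small
        # window around the maximum (reduces to the classic 3-point formula
        # when the window collapses); symmetric window => no position bias
        # for symmetric bands, and the averaging suppresses apex noise
        lo_i = max(i - 9, 0)
        hi_i = min(i + 9, len(wl) - 1)
        lam = wl[i]
        if hi_i - lo_i >= 2:
            xw = wl[lo_i : hi_i + 1] - wl[i]
            yw = y[lo_i : hi_i + 1]
            a, b, _ = np.polyfit(xw, yw, 2)
            if a < 0:
                delta = float(np.clip(-b / (2 * a), xw[0], xw[-1]))
                lam = wl[i] + delta
        if region is not None and not (region[0] <= lam <= region[1]):
            continue
        if config.soret_region[0] <= lam <= config.soret_region[1]:
            band = SORET
        elif config.beta_region[0] <= lam <= config.beta_region[1]:
            band = BETA
        elif config.alpha_region[0] <= lam <= config.alpha_region[1]:
            band = ALPHA
        else:
            band = OTHER
        calls.append(PeakCall(float(lam), float(y[i]), float(prom), band))
    calls.sort(key=lambda c: -c.prominence)
    return calls


# ---------------------------------------------------------------------------
# state classification

def classify_heme_state(
    peaks: Sequence[PeakCall], config: ClassifierConfig = DEFAULT_CONFIG
) -> HemeStateCall:
    """Window-based, ordered decision rules over detected peaks.

    Uses the most prominent SORET call.  Order: apo (no Soret) -> free
    hemin (436) -> ferrous 6c (418 + beta + alpha) -> 5c-NO (398) ->
    ferric (408) -> AMBIGUOUS listing the near-miss candidates.
    """
    sorets = [p for p in peaks if p.band_class == SORET]
    if not sorets:
        return HemeStateCall(
            APO_NO_HEME, tuple(), "no Soret peak detected in the 380-450 nm region"
        )
    soret = sorets[0]
    betas = [p for p in peaks if p.band_class == BETA]
    alphas = [p for p in peaks if p.band_class == ALPHA]

    if _in_window(soret.lambda_max, config.hemin_soret):
        return HemeStateCall(
            FREE_HEMIN,
            (soret,),
            f"Soret at {soret.lambda_max:.1f} nm within "
            f"{config.hemin_soret[0]:.0f}±{config.hemin_soret[1]:.0f} (free hemin)",
        )
    if _in_window(soret.lambda_max, config.ferrous_soret):
        beta_hit = next(
            (p for p in betas if _in_window(p.lambda_max, config.ferrous_beta)), None
        )
        alpha_hit = next(
            (p for p in alphas if _in_window(p.lambda_max, config.ferrous_alpha)), None
        )
        if beta_hit and alpha_hit:
            return HemeStateCall(
                FERROUS_6C,
                (soret, beta_hit, alpha_hit),
                f"Soret {soret.lambda_max:.1f} nm with beta "
                f"{beta_hit.lambda_max:.1f} and alpha {alpha_hit.lambda_max:.1f} nm",
            )
    if _in_window(soret.lambda_max, config.no5c_soret):
        return HemeStateCall(
            FERROUS_5C_NO,
            (soret,),
            f"Soret at {soret.lambda_max:.1f} nm within "
            f"{config.no5c_soret[0]:.0f}±{config.no5c_soret[1]:.0f} (5c nitrosyl)",
        )
    if _in_window(soret.lambda_max, config.ferric_soret):
        return HemeStateCall(
            FERRIC_HIS_LIGATED,
            (soret,),
            f"Soret at {soret.lambda_max:.1f} nm within "
            f"{config.ferric_soret[0]:.0f}±{config.ferric_soret[1]:.0f} "
            f"(His-ligated ferric)",
        )
    candidates = []
    for name, window in (
        (FREE_HEMIN, config.hemin_soret),
        (FERROUS_6C, config.ferrous_soret),
        (FERROUS_5C_NO, config.no5c_soret),
        (FERRIC_HIS_LIGATED, config.ferric_soret),
    ):
        candidates.append((abs(soret.lambda_max - window[0]), name))
    candidates.sort()
    near = ", ".join(f"{n} (|Δ|={d:.1f} nm)" for d, n in candidates[:2])
    return HemeStateCall(
        AMBIGUOUS,
        (soret,),
        f"Soret at {soret.lambda_max:.1f} nm matches no state window; "
        f"nearest candidates: {near}",
    )


def classify_spectrum(
    spectrum: Spectrum, config: ClassifierConfig = DEFAULT_CONFIG
) -> HemeStateCall:
    """Full pipeline on one spectrum: validate, smooth, detect, classify."""
    if spectrum.n_points < config.min_points:
        raise SpectrumError(
            f"classification needs >= {config.min_points} points, "
            f"got {spectrum.n_points}"
        )
    lo, hi = config.required_coverage
    if not spectrum.covers(lo, hi):
        raise SpectrumError(
            f"classification needs coverage of {lo:.0f}-{hi:.0f} nm; grid is "
            f"{spectrum.wavelengths[0]:.0f}-{spectrum.wavelengths[-1]:.0f} nm"
        )
    window = min(config.smooth_window, spectrum.n_points - (spectrum.n_points + 1) % 2)
    sm = smooth(spectrum, window, config.smooth_order)
    peaks = detect_peaks(sm, config.min_prominence, config=config)
    return classify_heme_state(peaks, config)


# ---------------------------------------------------------------------------
# titration / dissociation series

@dataclass(frozen=True)
class TitrationStep:
    donor_concentration: float  # µM NO donor
    spectrum: Spectrum


@dataclass(frozen=True)
class TitrationSeries:
    """Spectra at non-decreasing NO-donor concentrations (µM)."""

    steps: tuple[TitrationStep, ...]

    def __post_init__(self) -> None:
        concs = [s.donor_concentration for s in self.steps]
        if any(b < a for a, b in zip(concs, concs[1:])):
            raise SpectrumError("donor concentrations must be non-decreasing")

    def __len__(self) -> int:
        return len(self.steps)


@dataclass(frozen=True)
class SaturationResult:
    saturated: bool
    saturation_index: int
    saturation_concentration: float
    max_residual_change: float


def _common_grid(spectra: Sequence[Spectrum]) -> list[np.ndarray]:
    """Absorbances on a shared grid (resampled linearly if grids differ)."""
    ref = spectra[0].wavelengths
    if all(
        s.wavelengths.shape == ref.shape and np.allclose(s.wavelengths, ref)
        for s in spectra
    ):
        return [s.absorbance for s in spectra]
    lo = max(s.wavelengths[0] for s in spectra)
    hi = min(s.wavelengths[-1] for s in spectra)
    if lo >= hi:
        raise SpectrumError("series spectra have no overlapping wavelength range")
    grid = ref[(ref >= lo) & (ref <= hi)]
    return [s.resampled(grid).absorbance for s in spectra]


def analyze_titration(series: TitrationSeries, tolerance: float) -> SaturationResult:
    """Find the step beyond which further donor addition changes nothing.

    The saturation index is the smallest i such that every consecutive
    max-norm spectral change after step i is below ``tolerance``; the
    series is saturated only if at least the final change is below it.
    """
    if len(series) < 3:
        raise SpectrumError(f"titration needs >= 3 steps, got {len(series)}")
    ys = _common_grid([s.spectrum for s in series.steps])
    diffs = [
        float(np.max(np.abs(b - a))) for a, b in zip(ys, ys[1:])
    ]  # diffs[j] compares step j vs j+1
    last_bad = -1
    for j, d in enumerate(diffs):
        if d >= tolerance:
            last_bad = j
    saturation_index = last_bad + 1
    saturated = saturation_index < len(series) - 1 or last_bad == -1
    if last_bad == -1:
        saturation_index = 0
    residual = diffs[saturation_index:] if saturation_index < len(diffs) else []
    return SaturationResult(
        saturated=saturated,
        saturation_index=saturation_index,
        saturation_concentration=series.steps[saturation_index].donor_concentration,
        max_residual_change=float(max(residual)) if residual else 0.0,
    )


@dataclass(frozen=True)
class DissociationResult:
    recovered: bool
    recovery_time: float | None
    states: tuple[str, ...]


def analyze_dissociation(
    series: Sequence[tuple[float, Spectrum]],
    config: ClassifierConfig = DEFAULT_CONFIG,
) -> DissociationResult:
    """First time at which the spectrum classifies as His-ligated ferric.

    Models nothing kinetically: NO release from the 5c-nitrosyl complex is
    read directly off the spectral state trajectory (reappearance of the
    ~408 nm Soret peak).
    """
    if len(series) < 3:
        raise SpectrumError(f"dissociation series needs >= 3 time points")
    times = [t for t, _ in series]
    if any(b <= a for a, b in zip(times, times[1:])):
        raise SpectrumError("time points must be strictly increasing")
    states = []
    recovery_time = None
    for t, spec in series:
        call = classify_spectrum(spec, config)
        states.append(call.state)
        if recovery_time is None and call.state == FERRIC_HIS_LIGATED:
            recovery_time = float(t)
    return DissociationResult(
        recovered=recovery_time is not None,
        recovery_time=recovery_time,
        states=tuple(states),
    )
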