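"""Visual-pigment absorbance processing and A1/A2 chromophore unmixing.

A photoreceptor's measured absorbance (microspectrophotometry, MSP) is the
sum of the A1 (retinal) and A2 (3-dehydroretinal) forms of one pigment at
some mixing ratio; the A2 form peaks at a longer wavelength.  This module
offers the processing chain used on such data: dark-minus-bleached
difference spectra, λmax estimation with standard errors from replicate
curves, construction of an empirical standard template by peak-aligning and
averaging measured curves, shifting that template to any target λmax, and
estimating the A2 fraction φ by adjusting the mixture until it matches an
observed peak (or full curve).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd


@dataclass
class SpectrumCurve:
    """Absorbance sampled on a strictly increasing wavelength grid (nm)."""

    wavelengths: np.ndarray
    absorbance: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        w = np.asarray(self.wavelengths, dtype=float)
        a = np.asarray(self.absorbance, dtype=float)
        if w.ndim != 1 or w.shape != a.shape:
            raise ValueError("wavelengths and absorbance must be 1-D and equal length")
        if w.size < 3:
            raise ValueError("need at least 3 points")
        if np.any(np.diff(w) <= 0):
            raise ValueError("wavelength grid must be strictly increasing")
        if np.any(~np.isfinite(a)):
            raise ValueError("absorbance contains missing values")
        self.wavelengths, self.absorbance = w, a

    @classmethod
    def read_csv(cls, path: str | Path, label: str | None = None) -> "SpectrumCurve":
        df = pd.read_csv(path)
        return cls(df.iloc[:, 0].to_numpy(), df.iloc[:, 1].to_numpy(),
                   label=label or Path(path).stem)

    def write_csv(self, path: str | Path) -> None:
        pd.DataFrame({
            "wavelength_nm": self.wavelengths,
            "absorbance": self.absorbance,
        }).to_csv(path, index=False)

    def resampled(self, grid: np.ndarray) -> "SpectrumCurve":
        grid = np.asarray(grid, dtype=float)
        if grid[0] < self.wavelengths[0] or grid[-1] > self.wavelengths[-1]:
            raise ValueError("resampling grid extends beyond curve coverage")
        return SpectrumCurve(
            grid, np.interp(grid, self.wavelengths, self.absorbance), self.label)


@dataclass
class StandardTemplate:
    """Normalized pigment shape on a peak-relative wavelength grid.

    ``delta_grid`` holds offsets λ − λmax; ``shape`` peaks at 1 at offset 0
    (to interpolation accuracy).  ``reference_lambda_max`` records the mean
    peak of the curves the template was built from.
    """

    delta_grid: np.ndarray
    shape: np.ndarray
    reference_lambda_max: float


def difference_spectrum(dark: SpectrumCurve, bleached: SpectrumCurve
                        ) -> SpectrumCurve:
    """Pointwise dark − bleached absorbance, isolating the photolabile pigment.

    Curves on different grids are linearly interpolated onto the overlap of
    the two grids (sampled at the dark curve's wavelengths); disjoint grids
    raise ``ValueError``.
    """
    if np.array_equal(dark.wavelengths, bleached.wavelengths):
        return SpectrumCurve(dark.wavelengths.copy(),
                             dark.absorbance - bleached.absorbance,
                             label=f"{dark.label}-{bleached.label}")
    lo = max(dark.wavelengths[0], bleached.wavelengths[0])
    hi = min(dark.wavelengths[-1], bleached.wavelengths[-1])
    if lo >= hi:
        raise ValueError("wavelength grids do not overlap")
    grid = dark.wavelengths[(dark.wavelengths >= lo) & (dark.wavelengths <= hi)]
    d = dark.resampled(grid)
    b = bleached.resampled(grid)
    return SpectrumCurve(grid, d.absorbance - b.absorbance,
                         label=f"{dark.label}-{bleached.label}")


def _peak_quadratic(curve: SpectrumCurve, window_nm: float) -> tuple[float, float]:
    """(λmax, peak value) from a quadratic fit around the grid argmax."""
    w, a = curve.wavelengths, curve.absorbance
    i = int(np.argmax(a))
    if i == 0 or i == w.size - 1:
        raise ValueError(
            f"curve {curve.label!r}: maximum on grid boundary, peak not bracketed")
    mask = np.abs(w - w[i]) <= window_nm / 2.0
    if mask.sum() < 3:
        mask = np.zeros_like(mask)
        mask[max(i - 1, 0):i + 2] = True
    coef = np.polyfit(w[mask], a[mask], 2)
    if coef[0] >= 0:  # no interior maximum in the window
        return float(w[i]), float(a[i])
    vertex = -coef[1] / (2.0 * coef[0])
    peak = np.polyval(coef, vertex)
    return float(vertex), float(peak)


def estimate_lambda_max(curves: list[SpectrumCurve], window_nm: float = 20.0
                        ) -> tuple[float, float]:
    """Mean λmax and standard error over replicate curves.

    Per curve, λmax is the vertex of a quadratic fitted to points within
    ±``window_nm``/2 of the grid argmax (robust to 1 nm grid quantization).
    The standard error of the mean is 0 for a single curve.
    """
    if not curves:
        raise ValueError("need at least one curve")
    peaks = np.array([_peak_quadratic(c, window_nm)[0] for c in curves])
    mean = float(peaks.mean())
    se = float(peaks.std(ddof=1) / np.sqrt(peaks.size)) if peaks.size > 1 else 0.0
    return mean, se


def build_standard_template(curves: list[SpectrumCurve],
                            smooth_window_nm: float = 5.0,
                            peak_window_nm: float = 20.0) -> StandardTemplate:
    """Empirical standard pigment shape from ≥2 measured curves.

    Each curve is rescaled to peak 1 and shifted so its λmax sits at offset
    0; the curves are averaged pointwise on the common peak-relative grid,
    smoothed by a centered moving average of width ``smooth_window_nm``,
    and renormalized to peak 1.
    """
    if len(curves) < 2:
        raise ValueError("need at least 2 curves to build a standard template")
    aligned = []
    lmaxes = []
    for c in curves:
        lmax, peak = _peak_quadratic(c, peak_window_nm)
        lmaxes.append(lmax)
        aligned.append((c.wavelengths - lmax, c.absorbance / peak))
    lo = max(d[0] for d, _ in aligned)
    hi = min(d[-1] for d, _ in aligned)
    if lo >= hi:
        raise ValueError("curves share no peak-relative overlap")
    step = float(np.min(np.diff(curves[0].wavelengths)))
    grid = np.arange(lo, hi + step / 2, step)
    stack = np.vstack([np.interp(grid, d, v) for d, v in aligned])
    mean = stack.mean(axis=0)
    k = max(int(round(smooth_window_nm / step)), 1)
    if k % 2 == 0:
        k += 1
    if k > 1:
        kernel = np.ones(k) / k
        pad = k // 2
        padded = np.pad(mean, pad, mode="edge")
        mean = np.convolve(padded, kernel, mode="valid")
    mean = mean / mean.max()
    return StandardTemplate(grid, mean, float(np.mean(lmaxes)))


def shift_template(template: StandardTemplate, target_lambda_max: float,
                   wavelengths: np.ndarray | None = None) -> SpectrumCurve:
    """Place the standard shape at a target peak wavelength.

    With no output grid given, the curve is returned on the template's own
    grid translated to the target (identity round trips are exact); with a
    grid, values come from linear interpolation and the target must lie
    within the grid.
    """
    native = template.delta_grid + target_lambda_max
    if wavelengths is None:
        return SpectrumCurve(native, template.shape.copy(),
                             label=f"template@{target_lambda_max:g}")
    wavelengths = np.asarray(wavelengths, dtype=float)
    if not (wavelengths[0] <= target_lambda_max <= wavelengths[-1]):
        raise ValueError("target lambda_max outside requested grid")
    if wavelengths[0] < native[0] or wavelengths[-1] > native[-1]:
        raise ValueError("requested grid extends beyond template coverage")
    return SpectrumCurve(
        wavelengths, np.interp(wavelengths, native, template.shape),
        label=f"template@{target_lambda_max:g}")


@dataclass
class MixtureFit:
    """Estimated A2 fraction of an A1/A2 pigment mixture."""

    a2_fraction: float
    lambda_max: float
    residual: float
    mode: str


def _mixture_lambda_max(template_a1: SpectrumCurve, template_a2: SpectrumCurve,
                        grid: np.ndarray, phi: float,
                        window_nm: float = 20.0) -> tuple[float, np.ndarray]:
    a1 = np.interp(grid, template_a1.wavelengths, template_a1.absorbance)
    a2 = np.interp(grid, template_a2.wavelengths, template_a2.absorbance)
    mix = (1.0 - phi) * a1 + phi * a2
    curve = SpectrumCurve(grid, mix)
    lmax, peak = _peak_quadratic(curve, window_nm)
    return lmax, mix / peak


def fit_a1_a2_mixture(
    template_a1: SpectrumCurve,
    template_a2: SpectrumCurve,
    observed: SpectrumCurve | None = None,
    observed_lambda_max: float | None = None,
    mode: str = "peak-match",
    phi_step: float = 0.01,
) -> MixtureFit:
    """Estimate the A2 fraction φ of an observed pigment spectrum.

    The mixture (1−φ)·A1 + φ·A2 is evaluated on a φ grid of step
    ``phi_step``.  ``peak-match`` (default) minimizes |λmax(φ) − observed
    λmax|, the convention when only the measured peak is trusted;
    ``curve-match`` minimizes the sum of squared residuals between the
    observed curve and the mixture after rescaling both to unit peak.  An
    observed λmax outside the [A1, A2] peak interval is clamped to φ=0 or
    φ=1 with a warning.
    """
    if mode not in ("peak-match", "curve-match"):
        raise ValueError("mode must be 'peak-match' or 'curve-match'")
    l1, _ = _peak_quadratic(template_a1, 20.0)
    l2, _ = _peak_quadratic(template_a2, 20.0)
    if not l2 > l1:
        raise ValueError("template A2 peak must exceed template A1 peak")
    lo = max(template_a1.wavelengths[0], template_a2.wavelengths[0])
    hi = min(template_a1.wavelengths[-1], template_a2.wavelengths[-1])
    if lo >= hi:
        raise ValueError("templates share no wavelength overlap")
    step = float(np.min(np.diff(template_a1.wavelengths)))
    grid = np.arange(lo, hi + step / 2, step)
    phis = np.arange(0.0, 1.0 + phi_step / 2, phi_step)

    if mode == "peak-match":
        if observed_lambda_max is None:
            if observed is None:
                raise ValueError("peak-match needs observed_lambda_max or a curve")
            observed_lambda_max, _ = _peak_quadratic(observed, 20.0)
        if observed_lambda_max < l1 or observed_lambda_max > l2:
            warnings.warn(
                "observed lambda_max outside template interval; clamping")
            phi = 0.0 if observed_lambda_max < l1 else 1.0
            lmax, _ = _mixture_lambda_max(template_a1, template_a2, grid, phi)
            return MixtureFit(phi, lmax, abs(lmax - observed_lambda_max), mode)
        best = None
        for phi in phis:
            lmax, _ = _mixture_lambda_max(template_a1, template_a2, grid, phi)
            err = abs(lmax - observed_lambda_max)
            if best is None or err < best[0]:
                best = (err, phi, lmax)
        err, phi, lmax = best
        return MixtureFit(float(phi), float(lmax), float(err), mode)

    if observed is None:
        raise ValueError("curve-match requires an observed curve")
    olo = max(lo, observed.wavelengths[0])
    ohi = min(hi, observed.wavelengths[-1])
    if olo >= ohi:
        raise ValueError("observed curve does not overlap templates")
    ogrid = grid[(grid >= olo) & (grid <= ohi)]
    obs = np.interp(ogrid, observed.wavelengths, observed.absorbance)
    obs = obs / obs.max()
    best = None
    for phi in phis:
        lmax, mix_unit = _mixture_lambda_max(template_a1, template_a2, grid, phi)
        mix = np.interp(ogrid, grid, mix_unit)
        ssr = float(np.sum((obs - mix) ** 2))
        if best is None or ssr < best[0]:
            best = (ssr, phi, lmax)
    ssr, phi, lmax = best
    return MixtureFit(float(phi), float(lmax), float(ssr), mode)
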