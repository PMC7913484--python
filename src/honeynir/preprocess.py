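"""Mathematical treatments for NIR spectra.

Implements the classical scatter corrections (SNV, MSC, detrend, SNV-DT)
and gap-segment derivatives identified by a four-digit code ``d,g,s1,s2``:
derivative order, gap in channels, first and second running-average widths.

Treatment strings follow the reporting dialect
``"<None|SNV|MSC|Detrend only|SNV-DT> d,g,s1,s2"``, e.g. ``"None 1,4,4,1"``.

Conventions (documented choices, applied consistently):

* the derivative pipeline is smooth(s1) -> gap-difference applied d times
  -> smooth(s2);
* a single gap difference over ``g`` channels is
  ``y_j = x[j+g] - x[j]`` carried at the midpoint wavelength, so a linear
  ramp ``x_i = k*i`` maps to the constant ``k*g``;
* edges are truncated, never padded: the output wavelength axis shrinks to
  fully supported channels;
* detrend removes a degree-2 polynomial baseline (configurable order);
* absorbance is log base 10.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .spectra import ABSORBANCE, REFLECTANCE, SpectraSet, SpectraError

SCATTER_NONE = "none"
SCATTER_SNV = "snv"
SCATTER_MSC = "msc"
SCATTER_DT = "detrend"
SCATTER_SNV_DT = "snv-dt"

_SCATTER_TOKENS = {
    "None": SCATTER_NONE,
    "SNV": SCATTER_SNV,
    "MSC": SCATTER_MSC,
    "Detrend only": SCATTER_DT,
    "SNV-DT": SCATTER_SNV_DT,
}
_SCATTER_NAMES = {v: k for k, v in _SCATTER_TOKENS.items()}


class TreatmentError(ValueError):
    """Malformed treatment code or string."""


@dataclass(frozen=True)
class MathTreatment:
    """One preprocessing recipe: scatter correction + derivative code."""

    scatter: str = SCATTER_NONE
    d: int = 0
    g: int = 0
    s1: int = 1
    s2: int = 1

    def __post_init__(self) -> None:
        if self.scatter not in _SCATTER_NAMES:
            raise TreatmentError(f"unknown scatter correction {self.scatter!r}")
        if self.d < 0:
            raise TreatmentError("derivative order d must be >= 0")
        if self.d >= 1 and self.g < 1:
            raise TreatmentError("gap g must be >= 1 when d >= 1")
        if self.s1 < 0 or self.s2 < 0:
            raise TreatmentError("smoothing widths must be >= 0")

    def __str__(self) -> str:
        return f"{_SCATTER_NAMES[self.scatter]} {self.d},{self.g},{self.s1},{self.s2}"

    @classmethod
    def parse(cls, text: str) -> "MathTreatment":
        text = text.strip()
        for token in sorted(_SCATTER_TOKENS, key=len, reverse=True):
            if text.startswith(token):
                rest = text[len(token):].strip()
                break
        else:
            raise TreatmentError(f"unknown scatter token in {text!r}")
        digits = [p.strip() for p in rest.split(",")] if rest else []
        if len(digits) != 4:
            raise TreatmentError(
                f"expected 4-digit derivative code 'd,g,s1,s2' in {text!r}")
        try:
            d, g, s1, s2 = (int(p) for p in digits)
        except ValueError as exc:
            raise TreatmentError(f"non-integer derivative code in {text!r}") from exc
        return cls(_SCATTER_TOKENS[token], d, g, s1, s2)


def to_log_inv_reflectance(spectra: SpectraSet) -> SpectraSet:
    """Convert reflectance R in (0, 1] to absorbance log10(1/R)."""
    if spectra.representation != REFLECTANCE:
        raise SpectraError("spectra are not in reflectance representation")
    bad = np.argwhere(spectra.values <= 0)
    if bad.size:
        i, j = bad[0]
        raise SpectraError(
            f"non-positive reflectance for sample {spectra.sample_ids[i]!r} "
            f"at {spectra.wavelengths[j]:g} nm"
        )
    return spectra.with_values(-np.log10(spectra.values), representation=ABSORBANCE)


def snv(spectra: SpectraSet) -> SpectraSet:
    """Standard normal variate: per-spectrum centre and scale to unit sd."""
    x = spectra.values
    mean = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, ddof=1, keepdims=True)
    degenerate = np.flatnonzero(sd.ravel() == 0)
    if degenerate.size:
        raise SpectraError(
            f"constant spectrum (zero variance) for sample "
            f"{spectra.sample_ids[degenerate[0]]!r}"
        )
    return spectra.with_values((x - mean) / sd)


def msc(spectra: SpectraSet, reference: np.ndarray | None = None) -> SpectraSet:
    """Multiplicative scatter correction against a reference spectrum.

    Each spectrum x is regressed on the reference (OLS, x = a + b*ref)
    and replaced by (x - a) / b. The reference defaults to the set mean.
    """
    x = spectra.values
    ref = x.mean(axis=0) if reference is None else np.asarray(reference, float)
    if ref.shape != (spectra.n_channels,):
        raise SpectraError("reference length does not match channel count")
    ref_c = ref - ref.mean()
    denom = ref_c @ ref_c
    if denom == 0:
        raise SpectraError("zero-variance MSC reference spectrum")
    b = (x - x.mean(axis=1, keepdims=True)) @ ref_c / denom
    a = x.mean(axis=1) - b * ref.mean()
    if np.any(b == 0):
        i = int(np.flatnonzero(b == 0)[0])
        raise SpectraError(f"zero MSC slope for sample {spectra.sample_ids[i]!r}")
    return spectra.with_values((x - a[:, None]) / b[:, None])


def detrend(spectra: SpectraSet, order: int = 2) -> SpectraSet:
    """Remove a degree-``order`` polynomial baseline fit on the wavelength axis."""
    if spectra.n_channels <= order:
        raise SpectraError(
            f"detrend of order {order} needs more than {order} channels")
    wl = spectra.wavelengths
    # orthonormal polynomial basis on a scaled axis -> exact projection
    span = np.ptp(wl)
    u = (wl - wl.mean()) / (span / 2 if span else 1.0)
    basis = np.vander(u, order + 1, increasing=True)
    q, _ = np.linalg.qr(basis)
    x = spectra.values
    return spectra.with_values(x - (x @ q) @ q.T)


def _boxcar(values: np.ndarray, wavelengths: np.ndarray, width: int):
    """Running mean of ``width`` points, valid region only; axis follows."""
    if width <= 1:
        return values, wavelengths
    kernel = np.full(width, 1.0 / width)
    out = np.apply_along_axis(lambda r: np.convolve(r, kernel, mode="valid"), 1, values)
    wl = np.convolve(wavelengths, kernel, mode="valid")
    return out, wl


def _gap_difference(values: np.ndarray, wavelengths: np.ndarray, gap: int):
    out = values[:, gap:] - values[:, :-gap]
    wl = (wavelengths[gap:] + wavelengths[:-gap]) / 2.0
    return out, wl


def gap_segment_derivative(spectra: SpectraSet, d: int, g: int,
                           s1: int = 1, s2: int = 1) -> SpectraSet:
    """Gap-segment derivative encoded ``d,g,s1,s2``; d=0 smooths only."""
    s1 = max(s1, 1)
    s2 = max(s2, 1)
    needed = (s1 - 1) + d * max(g, 0) + (s2 - 1) + 1
    if spectra.n_channels < needed:
        raise SpectraError(
            f"derivative code ({d},{g},{s1},{s2}) needs at least {needed} "
            f"channels, got {spectra.n_channels}"
        )
    values, wl = _boxcar(spectra.values, spectra.wavelengths, s1)
    for _ in range(d):
        values, wl = _gap_difference(values, wl, g)
    values, wl = _boxcar(values, wl, s2)
    return spectra.with_values(values, wavelengths=wl)


def apply_treatment(spectra: SpectraSet, treatment: MathTreatment | str,
                    msc_reference: np.ndarray | None = None) -> SpectraSet:
    """Scatter correction first, then the derivative code.

    SNV-DT applies SNV followed by detrend before differentiation.
    ``msc_reference`` fixes the MSC reference spectrum (e.g. the
    calibration-set mean) so new samples are corrected consistently.
    """
    if isinstance(treatment, str):
        treatment = MathTreatment.parse(treatment)
    out = spectra
    if treatment.scatter == SCATTER_SNV:
        out = snv(out)
    elif treatment.scatter == SCATTER_MSC:
        out = msc(out, reference=msc_reference)
    elif treatment.scatter == SCATTER_DT:
        out = detrend(out)
    elif treatment.scatter == SCATTER_SNV_DT:
        out = detrend(snv(out))
    if treatment.d > 0 or treatment.s1 > 1 or treatment.s2 > 1:
        out = gap_segment_derivative(out, treatment.d, treatment.g,
                                     treatment.s1, treatment.s2)
    return out
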