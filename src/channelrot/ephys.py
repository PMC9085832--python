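"""Electrophysiology and confocal patch-clamp fluorometry (cPCF) analysis.

Steady-state activation of the channel is summarised by a Boltzmann fit to
relative tail-current amplitudes,

    I/Imax = a / (1 + exp(zδ·F·(V − V½) / (R·T))),

where V½ is the voltage of half-maximal activation, zδ the effective
gating charge, and a the relative amplitude at saturating voltage.  With
zδ > 0 activation grows toward hyperpolarised voltages, as appropriate
for HCN channels.  Activation/deactivation time courses are fitted with a
single exponential starting after an initial delay; concentration–binding
relationships with the Hill equation

    F/Fmax = 1 / (1 + (BC50/[agonist])^H),

fitted to averaged data.  cPCF background subtraction scales the
reference-dye (red) image onto the ligand (green) image over the bath and
pipette regions — which contain only free dye — subtracts, and quantifies
bound ligand in the patch dome only.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

from .ensemble_stats import summarize

__all__ = [
    "FARADAY",
    "GAS_CONSTANT",
    "DEFAULT_TEMPERATURE",
    "ActivationRecording",
    "BoltzmannFit",
    "ExpFit",
    "HillFit",
    "CPCFMeasurement",
    "boltzmann",
    "hill",
    "normalize_tail_currents",
    "fit_boltzmann",
    "delta_v12",
    "fit_exponential",
    "fit_hill",
    "cpcf_subtract",
]

log = logging.getLogger(__name__)

FARADAY = 96485.33212  # C/mol
GAS_CONSTANT = 8.31446261815324  # J/(mol K)
#: room-temperature oocyte recordings; configurable — zδ scales with 1/T
DEFAULT_TEMPERATURE = 293.15  # K


class FitError(RuntimeError):
    """Nonlinear least squares failed to converge."""


@dataclass
class ActivationRecording:
    """Tail-current amplitudes of one voltage family."""

    command_voltages: np.ndarray  # mV
    tail_amplitudes: np.ndarray  # arbitrary units (raw or normalised)
    cAMP_state: str = "zero"  # 'zero' | 'saturating'
    recording_id: str = ""

    def __post_init__(self) -> None:
        self.command_voltages = np.asarray(self.command_voltages, float)
        self.tail_amplitudes = np.asarray(self.tail_amplitudes, float)
        if self.command_voltages.shape != self.tail_amplitudes.shape:
            raise ValueError("voltages and amplitudes must have equal length")
        if self.command_voltages.size < 5:
            warnings.warn("fewer than 5 voltages: Boltzmann fit may be unstable")


@dataclass
class BoltzmannFit:
    V_half: float  # mV
    z_delta: float  # effective gating charge (dimensionless)
    amp_satV: float  # relative amplitude at saturating voltage
    temperature: float  # K
    covariance: np.ndarray | None = None

    def predict(self, voltages: np.ndarray) -> np.ndarray:
        return boltzmann(np.asarray(voltages, float), self.V_half, self.z_delta,
                         self.amp_satV, self.temperature)


@dataclass
class ExpFit:
    amplitude: float
    tau: float  # same unit as the input time axis
    delay: float
    offset: float = 0.0

    def predict(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, float)
        return self.offset + self.amplitude * np.exp(
            -np.clip(t - self.delay, 0.0, None) / self.tau
        )


@dataclass
class HillFit:
    BC50: float  # µM
    H: float
    amplitude: float = 1.0
    covariance: np.ndarray | None = None

    def predict(self, conc: np.ndarray) -> np.ndarray:
        return hill(np.asarray(conc, float), self.BC50, self.H, self.amplitude)


@dataclass
class CPCFMeasurement:
    """Two-channel cPCF image (or ROI means) with its region masks."""

    green: np.ndarray
    red: np.ndarray
    roi_dome: np.ndarray  # boolean masks, pairwise disjoint
    roi_bath: np.ndarray
    roi_pipette: np.ndarray
    F_max: float

    def __post_init__(self) -> None:
        if self.F_max <= 0:
            raise ValueError("F_max must be > 0")
        if np.any(self.roi_dome & (self.roi_bath | self.roi_pipette)) or np.any(
            self.roi_bath & self.roi_pipette
        ):
            raise ValueError("ROIs must be disjoint")


# ---------------------------------------------------------------------------
# model functions
# ---------------------------------------------------------------------------


def boltzmann(
    V: np.ndarray,
    V_half: float,
    z_delta: float,
    amp: float = 1.0,
    temperature: float = DEFAULT_TEMPERATURE,
) -> np.ndarray:
    """Steady-state activation vs command voltage (mV)."""
    x = z_delta * FARADAY * ((V - V_half) * 1e-3) / (GAS_CONSTANT * temperature)
    return amp / (1.0 + np.exp(x))


def hill(conc: np.ndarray, BC50: float, H: float, amp: float = 1.0) -> np.ndarray:
    """Bound fraction vs agonist concentration (same unit as BC50)."""
    conc = np.asarray(conc, float)
    out = np.zeros_like(conc, dtype=float)
    nz = conc > 0
    out[nz] = amp / (1.0 + (BC50 / conc[nz]) ** H)
    return out


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------


def normalize_tail_currents(amplitudes: np.ndarray) -> np.ndarray:
    """Relative currents I/Imax: division by the maximal |amplitude|.

    Inward (negative) tail currents are normalised by the magnitude of the
    largest amplitude, preserving monotonicity; the result has max |value|
    of 1.
    """
    a = np.asarray(amplitudes, float)
    m = np.abs(a).max()
    if m == 0:
        raise ValueError("all tail amplitudes are zero")
    return np.abs(a) / m


def fit_boltzmann(
    recording: ActivationRecording,
    temperature: float = DEFAULT_TEMPERATURE,
    normalized: bool = False,
) -> BoltzmannFit:
    """Fit the Boltzmann activation curve to one recording.

    Tail amplitudes are normalised to the recording maximum unless
    ``normalized=True``.  Unweighted nonlinear least squares; the model
    value at V = V½ is amp/2 by construction.
    """
    V = recording.command_voltages
    y = recording.tail_amplitudes if normalized else normalize_tail_currents(
        recording.tail_amplitudes
    )
    if y[np.argmin(V)] < y[np.argmax(V)]:
        warnings.warn(
            "activation increases toward depolarised voltages; "
            "check sign conventions"
        )
    v0 = float(np.interp(0.5 * y.max(), np.sort(y), V[np.argsort(y)]))

    def model(V, V_half, z_delta, amp):
        return boltzmann(V, V_half, z_delta, amp, temperature)

    try:
        popt, pcov = curve_fit(
            model, V, y, p0=[v0, 2.0, float(y.max())], maxfev=20000
        )
    except RuntimeError as exc:  # pragma: no cover - pathological data
        raise FitError(f"Boltzmann fit did not converge: {exc}") from exc
    fit = BoltzmannFit(
        V_half=float(popt[0]),
        z_delta=float(abs(popt[1])),
        amp_satV=float(popt[2]),
        temperature=temperature,
        covariance=pcov,
    )
    log.debug("Boltzmann fit at T=%.2f K: V1/2=%.2f mV zδ=%.2f", temperature,
              fit.V_half, fit.z_delta)
    return fit


def delta_v12(
    fits_zero_cAMP: list[BoltzmannFit], fits_sat_cAMP: list[BoltzmannFit]
) -> tuple[float, float]:
    """cAMP-induced shift ΔV½ = mean(V½,sat) − mean(V½,zero), with SEM.

    The SEM is propagated from the two groups' SEMs in quadrature
    (independent recordings).
    """
    if not fits_zero_cAMP or not fits_sat_cAMP:
        raise ValueError("both fit sets must be non-empty")
    m0, s0, _ = summarize(np.array([f.V_half for f in fits_zero_cAMP]))
    m1, s1, _ = summarize(np.array([f.V_half for f in fits_sat_cAMP]))
    return m1 - m0, float(np.hypot(s0, s1))


def fit_exponential(
    time: np.ndarray,
    current: np.ndarray,
    delay: float | None = None,
    fit_offset: bool = True,
) -> ExpFit:
    """Fit a single exponential I(t) = C + A·exp(−(t−delay)/τ).

    ``delay`` fixes the fit start; if ``None`` the start is placed
    automatically at the first time the signal crosses 10% of its final
    span (from its initial value toward its final value).  Only points
    with t >= delay enter the least squares.
    """
    t = np.asarray(time, float)
    y = np.asarray(current, float)
    if t.shape != y.shape or t.size < 4:
        raise ValueError("need matching time/current arrays with >= 4 points")
    span = y[-1] - y[0]
    if delay is None:
        if span == 0:
            delay = float(t[0])
        else:
            crossed = np.abs(y - y[0]) >= 0.1 * abs(span)
            delay = float(t[np.argmax(crossed)]) if crossed.any() else float(t[0])
    m = t >= delay
    tt, yy = t[m], y[m]
    if tt.size < 3:
        raise ValueError("fewer than 3 points after the delay")
    tau0 = max((tt[-1] - tt[0]) / 3.0, np.finfo(float).tiny)
    if fit_offset:

        def model(t, A, tau, C):
            return C + A * np.exp(-(t - delay) / tau)

        p0 = [yy[0] - yy[-1], tau0, yy[-1]]
    else:

        def model(t, A, tau):
            return A * np.exp(-(t - delay) / tau)

        p0 = [yy[0], tau0]
    try:
        popt, _ = curve_fit(model, tt, yy, p0=p0, maxfev=20000)
    except RuntimeError as exc:
        raise FitError(f"exponential fit did not converge: {exc}") from exc
    if (tt[-1] - tt[0]) < 3 * abs(popt[1]):
        warnings.warn("trace shorter than ~3 τ: time constant may be unstable")
    return ExpFit(
        amplitude=float(popt[0]),
        tau=float(abs(popt[1])),
        delay=float(delay),
        offset=float(popt[2]) if fit_offset else 0.0,
    )


def fit_hill(
    concentrations: np.ndarray,
    mean_F_over_Fmax: np.ndarray,
    free_amplitude: bool = False,
) -> HillFit:
    """Fit the Hill equation to an averaged concentration–binding relation.

    By default the saturating amplitude is fixed at 1 (F is already
    normalised to Fmax); ``free_amplitude=True`` fits it too.  The model
    at [agonist] = BC50 equals half the amplitude by construction.
    """
    c = np.asarray(concentrations, float)
    y = np.asarray(mean_F_over_Fmax, float)
    if c.size < 3:
        raise ValueError("need >= 3 concentrations")
    if np.ptp(y) == 0:
        raise ValueError("responses are all equal; Hill fit undefined")
    c50_0 = float(np.interp(0.5 * y.max(), np.sort(y), c[np.argsort(y)]))
    c50_0 = c50_0 if c50_0 > 0 else float(np.median(c))
    try:
        if free_amplitude:
            popt, pcov = curve_fit(
                lambda c, b, h, a: hill(c, b, h, a), c, y,
                p0=[c50_0, 1.5, float(y.max())], maxfev=20000,
            )
            return HillFit(BC50=float(abs(popt[0])), H=float(abs(popt[1])),
                           amplitude=float(popt[2]), covariance=pcov)
        popt, pcov = curve_fit(
            lambda c, b, h: hill(c, b, h), c, y, p0=[c50_0, 1.5], maxfev=20000
        )
    except RuntimeError as exc:
        raise FitError(f"Hill fit did not converge: {exc}") from exc
    return HillFit(BC50=float(abs(popt[0])), H=float(abs(popt[1])),
                   covariance=pcov)


def cpcf_subtract(measurement: CPCFMeasurement) -> float:
    """Bound-ligand fraction from a two-channel cPCF image.

    The red reference-dye channel is scaled onto the green channel over
    the bath and pipette ROIs (free dye only), subtracted pixel-wise, and
    the corrected green intensity averaged over the patch dome is divided
    by F_max.  A negative bound signal (possible under noise at zero
    binding) is reported as is, with a log note.
    """
    scaling = measurement.roi_bath | measurement.roi_pipette
    red_ref = float(measurement.red[scaling].mean())
    if red_ref == 0:
        raise ValueError("red channel is zero over the scaling ROIs")
    s = float(measurement.green[scaling].mean()) / red_ref
    corrected = measurement.green - s * measurement.red
    bound = float(corrected[measurement.roi_dome].mean())
    frac = bound / measurement.F_max
    if frac < 0:
        log.info("negative bound fraction %.4f (noise at zero binding)", frac)
    return frac
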