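"""Spatial and temporal front-end filters of opponent motion detectors.

Two filter vocabularies are supported, reflecting the two classes of early
visual filtering found in animals:

* **Insect-style**: a pair of identical lowpass Gaussians (the angular
  sensitivity of an ommatidium, ``sigma`` in degrees) displaced by a fixed
  spatial offset ``delta_x``, combined with a first-order temporal lowpass
  and an impulse-minus-lowpass (highpass) temporal filter.
* **Mammal-style**: bandpass derivative-of-Gaussian spatial filters (orders
  2 and 3, same position, constant pi/2 phase offset), combined with a
  difference-of-gamma temporal filter pair.

Conventions
-----------
The *spatial* phase of a filter is the phase advance it imparts on a
rightward-increasing spatial sinusoid: for a kernel centred at
``center_offset`` degrees it equals ``2*pi*f*center_offset`` (the complex
conjugate of the kernel's Fourier transform).  The *temporal* phase is the
argument of the Laplace transform evaluated at ``s = i*2*pi*f``.  With these
two conventions the closed-form opponent-energy expressions in
:mod:`motionmask.motion_model` agree sign-for-sign with causal numerical
convolution.

Spatial filters are normalised to unit DC gain (Gaussians) or unit peak gain
(Gaussian derivatives); temporal gains follow the Laplace transform without
extra normalisation (a first-order lowpass has DC gain ``tau``).  Absolute
scale is irrelevant downstream because the full detector array is normalised
to give a mean response of 1 to its optimal drifting grating.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Union

import numpy as np
from numpy.polynomial import hermite_e
from scipy.special import gammainc

__all__ = [
    "SpatialFilterSpec",
    "TemporalFilterSpec",
    "FrequencyResponse",
    "FilterBank",
    "spatial_frequency_response",
    "temporal_frequency_response",
    "spatial_transfer",
    "temporal_transfer",
    "temporal_transfer_sampled",
    "impulse_response",
    "temporal_kernel_weights",
    "insect_bank",
    "mammal_bank",
    "bank_from_dict",
    "wrap_phase",
]

SpatialFamily = Literal["offset-gaussian", "gaussian-derivative"]
TemporalFamily = Literal["first-order-lowpass", "impulse-minus-lowpass", "gamma-difference"]


@dataclass(frozen=True)
class SpatialFilterSpec:
    """One spatial filter of a detector.

    Parameters
    ----------
    family:
        ``"offset-gaussian"`` (insect, lowpass) or ``"gaussian-derivative"``
        (mammal, bandpass).
    sigma:
        Gaussian envelope width in degrees of visual angle (> 0).
    center_offset:
        Signed centre displacement in degrees (offset-gaussian only); the two
        filters of an insect detector sit at +/- delta_x / 2.
    derivative_order:
        Order m >= 1 of the Gaussian derivative (gaussian-derivative only).
    """

    family: SpatialFamily
    sigma: float
    center_offset: float = 0.0
    derivative_order: int = 0

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.family == "gaussian-derivative":
            if self.derivative_order < 1:
                raise ValueError("derivative_order must be >= 1")
            if self.center_offset != 0.0:
                raise ValueError("gaussian-derivative filters are centred at 0")
        elif self.family == "offset-gaussian":
            if self.derivative_order != 0:
                raise ValueError("offset-gaussian filters take no derivative_order")
        else:
            raise ValueError(f"unknown spatial family {self.family!r}")


@dataclass(frozen=True)
class TemporalFilterSpec:
    """One temporal filter of a detector.

    ``first-order-lowpass`` is ``exp(-t/tau)``; ``impulse-minus-lowpass`` is
    ``delta(t) - exp(-t/tau)``; ``gamma-difference`` is
    ``(k t)^n exp(-k t) (1/n! - (k t)^2/(n+2)!)`` with rate ``k`` per second
    (a zero-DC biphasic kernel).
    """

    family: TemporalFamily
    tau: float = 0.0
    n: int = 0
    k: float = 0.0

    def __post_init__(self) -> None:
        if self.family in ("first-order-lowpass", "impulse-minus-lowpass"):
            if self.tau <= 0:
                raise ValueError("tau must be positive")
        elif self.family == "gamma-difference":
            if self.n < 1:
                raise ValueError("n must be >= 1")
            if self.k <= 0:
                raise ValueError("k must be positive")
        else:
            raise ValueError(f"unknown temporal family {self.family!r}")


@dataclass(frozen=True)
class FrequencyResponse:
    """Gain and phase of a filter at one or more frequencies.

    ``frequency`` is in cycles/degree (spatial) or Hz (temporal); ``gain`` is
    a non-negative amplitude; ``phase`` is wrapped to (-pi, pi].
    """

    frequency: np.ndarray
    gain: np.ndarray
    phase: np.ndarray

    @property
    def complex(self) -> np.ndarray:
        return self.gain * np.exp(1j * self.phase)


def wrap_phase(phi: np.ndarray) -> np.ndarray:
    """Wrap an angle (radians) to the interval (-pi, pi]."""
    phi = np.asarray(phi, dtype=float)
    wrapped = -((-phi + np.pi) % (2 * np.pi) - np.pi)
    return wrapped


# ---------------------------------------------------------------------------
# frequency responses
# ---------------------------------------------------------------------------

def _derivative_peak_gain(m: int, sigma: float) -> float:
    # max_f (2 pi f)^m exp(-2 pi^2 sigma^2 f^2), attained at f = sqrt(m)/(2 pi sigma)
    return (math.sqrt(m) / sigma) ** m * math.exp(-m / 2.0)


def spatial_transfer(spec: SpatialFilterSpec, f_s) -> np.ndarray:
    """Complex spatial response at spatial frequency ``f_s`` (cpd, signed).

    Returns ``gain * exp(i*phase)`` under the module's phase convention.
    """
    f = np.asarray(f_s, dtype=float)
    if spec.family == "offset-gaussian":
        gain = np.exp(-2 * np.pi**2 * spec.sigma**2 * f**2)
        phase = 2 * np.pi * f * spec.center_offset
        return gain * np.exp(1j * phase)
    m = spec.derivative_order
    gain = (2 * np.pi * np.abs(f)) ** m * np.exp(
        -2 * np.pi**2 * spec.sigma**2 * f**2
    ) / _derivative_peak_gain(m, spec.sigma)
    phase = m * (np.pi / 2) * np.sign(f)
    return gain * np.exp(1j * phase)


def temporal_transfer(spec: TemporalFilterSpec, f_t) -> np.ndarray:
    """Complex temporal response: Laplace transform at ``s = i*2*pi*f_t``."""
    f = np.asarray(f_t, dtype=float)
    s = 1j * 2 * np.pi * f
    if spec.family == "first-order-lowpass":
        return 1.0 / (s + 1.0 / spec.tau)
    if spec.family == "impulse-minus-lowpass":
        return 1.0 - 1.0 / (s + 1.0 / spec.tau)
    # gamma-difference, term by term:
    # L{(kt)^n e^{-kt}/n!} = k^n/(k+s)^(n+1);  L{(kt)^(n+2) e^{-kt}/(n+2)!} * k^n...
    n, k = spec.n, spec.k
    return k**n * ((k + s) ** -(n + 1) - k**2 * (k + s) ** -(n + 3))


def spatial_frequency_response(spec: SpatialFilterSpec, f_s) -> FrequencyResponse:
    """Gain and (wrapped) phase of a spatial filter at frequency ``f_s`` (cpd)."""
    h = spatial_transfer(spec, f_s)
    return FrequencyResponse(
        frequency=np.asarray(f_s, dtype=float),
        gain=np.abs(h),
        phase=wrap_phase(np.angle(h)),
    )


def temporal_frequency_response(spec: TemporalFilterSpec, f_t) -> FrequencyResponse:
    """Gain and (wrapped) phase of a temporal filter at frequency ``f_t`` (Hz).

    Computed from the closed-form Laplace transform of each family (the
    gamma-difference family term-by-term, avoiding truncation artifacts of
    sampled kernels).  For the transfer function of the *sampled* kernel used
    in numerical simulation see :func:`temporal_transfer_sampled`.
    """
    h = temporal_transfer(spec, f_t)
    return FrequencyResponse(
        frequency=np.asarray(f_t, dtype=float),
        gain=np.abs(h),
        phase=wrap_phase(np.angle(h)),
    )


# ---------------------------------------------------------------------------
# sampled kernels
# ---------------------------------------------------------------------------

def _gamma_bin_areas(p: int, k: float, edges: np.ndarray) -> np.ndarray:
    # integral over bins of (k t)^p e^{-k t} / p!  ==  P(p+1, k*edges) diffs / k
    reg = gammainc(p + 1, k * edges)
    return np.diff(reg) / k


def _lowpass_bin_areas(tau: float, edges: np.ndarray) -> np.ndarray:
    # integral over bins of exp(-t/tau)
    return tau * -np.diff(np.exp(-edges / tau))


def temporal_kernel_weights(
    spec: TemporalFilterSpec, dt: float, duration: float | None = None
) -> np.ndarray:
    """Discrete causal convolution weights for a temporal filter.

    Each weight is the exact integral of the continuous kernel over one
    sample bin ``[i*dt, (i+1)*dt)`` (so the weights carry the kernel's area
    and the filter output is ``sum_i w[i] * x[t - i*dt]``).  The Dirac
    impulse in the impulse-minus-lowpass family contributes area 1 to the
    first bin.  Kernels are truncated where the remaining tail area falls
    below 1e-6 of the total.
    """
    if dt <= 0:
        raise ValueError("grid step must be positive")
    if duration is None:
        if spec.family == "gamma-difference":
            duration = (spec.n + 3) / spec.k + 14.0 / spec.k
        else:
            duration = 14.0 * spec.tau
    n_bins = max(1, int(np.ceil(duration / dt)))
    edges = np.arange(n_bins + 1) * dt
    if spec.family == "first-order-lowpass":
        return _lowpass_bin_areas(spec.tau, edges)
    if spec.family == "impulse-minus-lowpass":
        w = -_lowpass_bin_areas(spec.tau, edges)
        w[0] += 1.0
        return w
    w = _gamma_bin_areas(spec.n, spec.k, edges) - _gamma_bin_areas(
        spec.n + 2, spec.k, edges
    )
    return w


def temporal_transfer_sampled(spec: TemporalFilterSpec, f_t, dt: float) -> np.ndarray:
    """Complex transfer function of the sampled (bin-integrated) kernel.

    This is the transfer function the numerical simulation actually applies
    when it convolves the discrete kernel at time step ``dt``; it converges
    to :func:`temporal_transfer` as ``dt -> 0`` but differs by a few percent
    at the 1/85 s step for the fastest time constants.
    """
    w = temporal_kernel_weights(spec, dt)
    f = np.atleast_1d(np.asarray(f_t, dtype=float))
    n = np.arange(len(w))
    h = (w[None, :] * np.exp(-1j * 2 * np.pi * f[:, None] * n[None, :] * dt)).sum(axis=1)
    if np.isscalar(f_t) or np.asarray(f_t).ndim == 0:
        return h[0]
    return h


def impulse_response(
    spec: Union[SpatialFilterSpec, TemporalFilterSpec], grid: np.ndarray
) -> np.ndarray:
    """Sample a filter kernel on a uniform grid.

    For spatial specs ``grid`` is in degrees; for temporal specs it is a
    causal time grid starting at 0 (seconds) and the Dirac impulse of the
    impulse-minus-lowpass family is realised as a discrete impulse of area 1
    (value ``1/dt`` in the first bin).
    """
    grid = np.asarray(grid, dtype=float)
    if grid.size > 1:
        steps = np.diff(grid)
        if np.any(steps <= 0) or not np.allclose(steps, steps[0]):
            raise ValueError("grid must be uniform and increasing")
        dt = float(steps[0])
    else:
        dt = None
    if isinstance(spec, SpatialFilterSpec):
        return _spatial_kernel(spec, grid)
    if spec.family == "first-order-lowpass":
        out = np.where(grid >= 0, np.exp(-np.maximum(grid, 0.0) / spec.tau), 0.0)
        return out
    if spec.family == "impulse-minus-lowpass":
        if dt is None:
            raise ValueError("grid step must be positive")
        out = -np.where(grid >= 0, np.exp(-np.maximum(grid, 0.0) / spec.tau), 0.0)
        out[grid == 0] += 1.0 / dt
        return out
    n, k = spec.n, spec.k
    kt = k * np.maximum(grid, 0.0)
    out = kt**n * np.exp(-kt) * (1.0 / math.factorial(n) - kt**2 / math.factorial(n + 2))
    return np.where(grid >= 0, out, 0.0)


def _spatial_kernel(spec: SpatialFilterSpec, x: np.ndarray) -> np.ndarray:
    if spec.family == "offset-gaussian":
        u = x - spec.center_offset
        return np.exp(-(u**2) / (2 * spec.sigma**2)) / (spec.sigma * math.sqrt(2 * np.pi))
    m = spec.derivative_order
    u = x / spec.sigma
    # (-1)^m d^m/dx^m of the unit-area Gaussian, normalised to unit peak
    # frequency gain; He_m is the probabilists' Hermite polynomial.
    coeffs = np.zeros(m + 1)
    coeffs[m] = 1.0
    he = hermite_e.hermeval(u, coeffs)
    g = np.exp(-(u**2) / 2.0) / (spec.sigma * math.sqrt(2 * np.pi))
    return he * g / (spec.sigma**m) / _derivative_peak_gain(m, spec.sigma)


# ---------------------------------------------------------------------------
# filter banks
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FilterBank:
    """The four front-end filters of one opponent motion detector."""

    sf1: SpatialFilterSpec
    sf2: SpatialFilterSpec
    tf1: TemporalFilterSpec
    tf2: TemporalFilterSpec
    label: str = "custom"


def insect_bank(
    sigma: float = 2.56,
    delta_x: float = 4.0,
    tau_low: float = 0.013,
    tau_high: float = 0.040,
) -> FilterBank:
    """Insect (mantis-style) bank: offset Gaussians + lowpass/highpass pair.

    Defaults: sigma = 2.56 deg (ommatidial acceptance), delta_x = 4 deg
    (receptor separation), tau_low = 13 ms, tau_high = 40 ms.
    """
    return FilterBank(
        sf1=SpatialFilterSpec("offset-gaussian", sigma=sigma, center_offset=+delta_x / 2),
        sf2=SpatialFilterSpec("offset-gaussian", sigma=sigma, center_offset=-delta_x / 2),
        tf1=TemporalFilterSpec("first-order-lowpass", tau=tau_low),
        tf2=TemporalFilterSpec("impulse-minus-lowpass", tau=tau_high),
        label="insect",
    )


def mammal_bank(
    sigma: float = 0.08, n1: int = 3, n2: int = 5, k: float = 105.0
) -> FilterBank:
    """Mammal (human-style) bank: Gaussian-derivative pair + gamma-difference pair.

    Defaults: sigma = 0.08 deg with derivative orders 2 and 3 (bandpass,
    constant pi/2 spatial phase offset); temporal orders n = 3 and 5 with
    rate k = 105 / s (peak temporal sensitivity in the 5-10 Hz range).
    """
    return FilterBank(
        sf1=SpatialFilterSpec("gaussian-derivative", sigma=sigma, derivative_order=2),
        sf2=SpatialFilterSpec("gaussian-derivative", sigma=sigma, derivative_order=3),
        tf1=TemporalFilterSpec("gamma-difference", n=n1, k=k),
        tf2=TemporalFilterSpec("gamma-difference", n=n2, k=k),
        label="mammal",
    )


def _spatial_from_dict(d: dict) -> SpatialFilterSpec:
    return SpatialFilterSpec(
        family=d["family"],
        sigma=float(d["sigma"]),
        center_offset=float(d.get("center_offset", 0.0)),
        derivative_order=int(d.get("derivative_order", 0)),
    )


def _temporal_from_dict(d: dict) -> TemporalFilterSpec:
    return TemporalFilterSpec(
        family=d["family"],
        tau=float(d.get("tau", 0.0)),
        n=int(d.get("n", 0)),
        k=float(d.get("k", 0.0)),
    )


def bank_from_dict(config: dict) -> FilterBank:
    """Build a bank from a JSON/YAML-style mapping.

    Either ``{"label": "insect"|"mammal", ...overrides}`` or an explicit
    ``{"sf1": {...}, "sf2": {...}, "tf1": {...}, "tf2": {...}}`` mapping.
    """
    label = config.get("label", "custom")
    if label == "insect" and "sf1" not in config:
        kwargs = {k: config[k] for k in ("sigma", "delta_x", "tau_low", "tau_high") if k in config}
        return insect_bank(**kwargs)
    if label == "mammal" and "sf1" not in config:
        kwargs = {k: config[k] for k in ("sigma", "n1", "n2", "k") if k in config}
        return mammal_bank(**kwargs)
    return FilterBank(
        sf1=_spatial_from_dict(config["sf1"]),
        sf2=_spatial_from_dict(config["sf2"]),
        tf1=_temporal_from_dict(config["tf1"]),
        tf2=_temporal_from_dict(config["tf2"]),
        label=label,
    )
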