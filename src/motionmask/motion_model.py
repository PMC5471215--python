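"""Opponent motion-energy computation: circuits and closed-form predictions.

A single opponent detector filters the stimulus with two spatial kernels,
passes each result through two temporal filters (four separable responses
``A, A', B, B'``), and combines them into a direction-signed *opponent
energy*.  Two classic circuits do this:

* the energy model (EM): ``(A+B')^2 + (A'-B)^2 - (A-B')^2 - (A'+B)^2``;
* the Reichardt detector (RD): ``A B' - B A'``.

With shared separable filters the two are identical up to a factor of 4.

For stimuli that are sums of drifting sinusoidal gratings the time-averaged
output has a closed form: each component contributes
``C^2 G sin(phi_S2 - phi_S1) sin(phi_T1 - phi_T2)`` on its own, and every
pair of components sharing a temporal frequency adds a DC interaction term
``Cj Ck G(j,k) sin(beta_j - beta_k + phi_S1j - phi_S2k) sin(phi_T2 - phi_T1)``.
The interaction term is what lets noise at a spatial frequency the detector
cannot see (zero spatial phase difference, hence zero solo response) shift
the response to a visible signal -- masking by invisible noise.

These closed forms serve as analytic oracles for the numerical simulation;
pass ``dt`` to evaluate them with the transfer functions of the sampled
temporal kernels the simulation actually convolves.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .filters import (
    FilterBank,
    impulse_response,
    spatial_transfer,
    temporal_kernel_weights,
    temporal_transfer,
    temporal_transfer_sampled,
)

__all__ = [
    "GratingComponent",
    "SeparableResponses",
    "OpponentOutput",
    "OutOfRetinaError",
    "separable_responses",
    "em_opponent",
    "rd_opponent",
    "analytic_single_grating",
    "analytic_interaction",
    "analytic_compound_mean",
    "energy_spectrum",
    "spatial_kernel_halfwidth",
]

DEFAULT_DT = 1.0 / 85.0
DEFAULT_DX = 0.01


class OutOfRetinaError(ValueError):
    """Detector position (plus kernel support) falls outside the stimulus."""


@dataclass(frozen=True)
class GratingComponent:
    """One drifting sinusoidal grating.

    ``contrast`` is a Michelson amplitude; ``f_s`` (cpd) and ``f_t`` (Hz) are
    non-negative; ``direction`` is +1 or -1 and flips the sign of the
    spatial frequency, so the luminance profile is
    ``contrast * sin(2*pi*(f_t*t + direction*f_s*x) + phase)``.
    """

    contrast: float
    f_s: float
    f_t: float
    phase: float = 0.0
    direction: int = +1

    def __post_init__(self) -> None:
        if self.contrast < 0:
            raise ValueError("contrast must be >= 0")
        if self.f_s < 0 or self.f_t < 0:
            raise ValueError("frequencies must be >= 0")
        if self.direction not in (+1, -1):
            raise ValueError("direction must be +1 or -1")

    @property
    def signed_f_s(self) -> float:
        """Spatial frequency signed by drift direction."""
        return self.direction * self.f_s

    def profile(self, x: np.ndarray, t: np.ndarray) -> np.ndarray:
        """Luminance-contrast profile on an (x, t) grid (space x time)."""
        return self.contrast * np.sin(
            2 * np.pi * (self.f_t * t[None, :] + self.signed_f_s * x[:, None])
            + self.phase
        )


@dataclass(frozen=True)
class SeparableResponses:
    """The four separable filter outputs of one detector (common time base)."""

    a: np.ndarray
    a_prime: np.ndarray
    b: np.ndarray
    b_prime: np.ndarray
    dt: float

    def __post_init__(self) -> None:
        n = len(self.a)
        if not (len(self.a_prime) == len(self.b) == len(self.b_prime) == n):
            raise ValueError("separable responses must share a time base")


@dataclass(frozen=True)
class OpponentOutput:
    """Opponent-energy time series with its time average."""

    series: np.ndarray
    mean: float
    circuit: str


def spatial_kernel_halfwidth(bank: FilterBank, n_sigma: float = 6.0) -> float:
    """Half-width in degrees needed to sample both spatial kernels."""
    return max(
        abs(sf.center_offset) + n_sigma * sf.sigma for sf in (bank.sf1, bank.sf2)
    )


def _components_movie(
    components: Sequence[GratingComponent], x: np.ndarray, t: np.ndarray
) -> np.ndarray:
    s = np.zeros((len(x), len(t)))
    for c in components:
        s += c.profile(x, t)
    return s


def separable_responses(
    stimulus,
    bank: FilterBank,
    position: float = 0.0,
    *,
    dt: float = DEFAULT_DT,
    dx: float = DEFAULT_DX,
    duration: float = 1.0,
    warmup: str = "cold",
) -> SeparableResponses:
    """Filter a stimulus through one detector's four separable filters.

    ``stimulus`` is either a rendered movie (any object with ``luminance``
    (space x time), ``x_deg`` and ``dt`` attributes) or a sequence of
    :class:`GratingComponent`, in which case the components are sampled on a
    local grid of step ``dx`` spanning the detector's kernel support for
    ``duration`` seconds.  ``position`` is the detector centre in degrees.
    Temporal filtering is causal convolution with bin-integrated kernels.

    ``warmup`` controls the state of the temporal filters at stimulus onset:
    ``"cold"`` (default, matching a presentation that starts abruptly from a
    blank screen) starts the convolution with empty history, so the output
    carries an onset transient; ``"periodic"`` primes the history with the
    end of the stimulus, which yields the exact steady-state response for
    stimuli that are periodic over the presentation (e.g. drifting gratings
    with an integer number of temporal cycles) and is used when comparing
    against the steady-state closed forms.
    """
    if hasattr(stimulus, "luminance"):
        movie = stimulus
        x = np.asarray(movie.x_deg, dtype=float)
        lum = np.asarray(movie.luminance, dtype=float)
        dt = float(movie.dt)
        dx_m = float(x[1] - x[0])
        half = spatial_kernel_halfwidth(bank)
        if position - half < x[0] or position + half > x[-1]:
            raise OutOfRetinaError(
                f"detector at {position} deg (kernel half-width {half:.1f} deg) "
                f"exceeds stimulus support [{x[0]:.1f}, {x[-1]:.1f}] deg"
            )
        lo = np.searchsorted(x, position - half)
        hi = np.searchsorted(x, position + half, side="right")
        xs = x[lo:hi]
        k1 = impulse_response(bank.sf1, xs - position) * dx_m
        k2 = impulse_response(bank.sf2, xs - position) * dx_m
        r1 = k1 @ lum[lo:hi]
        r2 = k2 @ lum[lo:hi]
    else:
        components = list(stimulus)
        half = spatial_kernel_halfwidth(bank)
        xs = position + np.arange(-half, half + dx / 2, dx)
        t = np.arange(0.0, duration, dt)
        lum = _components_movie(components, xs, t)
        k1 = impulse_response(bank.sf1, xs - position) * dx
        k2 = impulse_response(bank.sf2, xs - position) * dx
        r1 = k1 @ lum
        r2 = k2 @ lum

    w1 = temporal_kernel_weights(bank.tf1, dt)
    w2 = temporal_kernel_weights(bank.tf2, dt)
    n = len(r1)
    if warmup == "periodic":
        pad = max(len(w1), len(w2))
        if pad > n:
            raise ValueError("stimulus shorter than the temporal kernels")
        r1 = np.concatenate([r1[-pad:], r1])
        r2 = np.concatenate([r2[-pad:], r2])
        sl = slice(pad, pad + n)
    elif warmup == "cold":
        sl = slice(0, n)
    else:
        raise ValueError("warmup must be 'cold' or 'periodic'")
    a = np.convolve(r1, w1)[sl]
    a_prime = np.convolve(r1, w2)[sl]
    b = np.convolve(r2, w1)[sl]
    b_prime = np.convolve(r2, w2)[sl]
    return SeparableResponses(a=a, a_prime=a_prime, b=b, b_prime=b_prime, dt=dt)


def em_opponent(resp: SeparableResponses) -> OpponentOutput:
    """Energy-model opponent output: rightward minus leftward energy."""
    a, ap, b, bp = resp.a, resp.a_prime, resp.b, resp.b_prime
    series = (a + bp) ** 2 + (ap - b) ** 2 - (a - bp) ** 2 - (ap + b) ** 2
    return OpponentOutput(series=series, mean=float(series.mean()), circuit="EM")


def rd_opponent(resp: SeparableResponses) -> OpponentOutput:
    """Reichardt-detector opponent output ``A B' - B A'``."""
    series = resp.a * resp.b_prime - resp.b * resp.a_prime
    return OpponentOutput(series=series, mean=float(series.mean()), circuit="RD")


# ---------------------------------------------------------------------------
# closed forms
# ---------------------------------------------------------------------------

def _temporal_pair(bank: FilterBank, f_t: float, dt: float | None):
    if dt is None:
        return temporal_transfer(bank.tf1, f_t), temporal_transfer(bank.tf2, f_t)
    return (
        temporal_transfer_sampled(bank.tf1, f_t, dt),
        temporal_transfer_sampled(bank.tf2, f_t, dt),
    )


def analytic_single_grating(
    c: GratingComponent, bank: FilterBank, *, dt: float | None = None
) -> float:
    """Time-averaged Reichardt opponent output to one drifting grating.

    ``C^2 G sin(phi_S2 - phi_S1) sin(phi_T1 - phi_T2)`` with
    ``G = G_S1 G_S2 G_T1 G_T2``; the sign encodes direction.  With ``dt``
    set, the temporal responses are those of the sampled kernels at that
    time step (matching the numerical simulation); phase differences are
    evaluated through complex products, immune to phase wrapping.
    """
    u = c.signed_f_s
    s1 = spatial_transfer(bank.sf1, u)
    s2 = spatial_transfer(bank.sf2, u)
    t1, t2 = _temporal_pair(bank, c.f_t, dt)
    return float(c.contrast**2 * np.imag(s2 * np.conj(s1)) * np.imag(t1 * np.conj(t2)))


def analytic_interaction(
    cj: GratingComponent, ck: GratingComponent, bank: FilterBank, *, dt: float | None = None
) -> float:
    """DC cross term ``Aj Bk' - Bk Aj'`` contributed by an ordered pair.

    Zero unless the two components share a temporal frequency (terms at
    different temporal frequencies oscillate and average out); otherwise
    ``Cj Ck G(j,k) sin(beta_j - beta_k + phi_S1j - phi_S2k)
    sin(phi_T2j - phi_T1j)``.
    """
    if cj.f_t != ck.f_t:
        return 0.0
    s1j = spatial_transfer(bank.sf1, cj.signed_f_s)
    s2k = spatial_transfer(bank.sf2, ck.signed_f_s)
    t1, t2 = _temporal_pair(bank, cj.f_t, dt)
    spatial = np.imag(np.exp(1j * (cj.phase - ck.phase)) * s1j * np.conj(s2k))
    temporal = np.imag(t2 * np.conj(t1))
    return float(cj.contrast * ck.contrast * spatial * temporal)


def analytic_compound_mean(
    components: Iterable[GratingComponent], bank: FilterBank, *, dt: float | None = None
) -> float:
    """Closed-form mean opponent output to a sum of drifting gratings.

    Sum of each component's solo term plus all ordered same-temporal-
    frequency interaction terms.
    """
    comps = list(components)
    total = sum(analytic_single_grating(c, bank, dt=dt) for c in comps)
    for j, cj in enumerate(comps):
        for k, ck in enumerate(comps):
            if j != k:
                total += analytic_interaction(cj, ck, bank, dt=dt)
    return float(total)


def energy_spectrum(
    bank: FilterBank, f_s_grid: np.ndarray, f_t_grid: np.ndarray
) -> dict[str, np.ndarray]:
    """Directional and opponent energy over a signed (f_s, f_t) grid.

    Returns time-averaged rightward and leftward energies of the energy
    model and their difference (opponent), each of shape
    ``(len(f_s_grid), len(f_t_grid))``, for unit-contrast gratings.  The
    opponent map is positive in the first/third Fourier quadrants and
    negative in the second/fourth.
    """
    f_s = np.asarray(f_s_grid, dtype=float)[:, None]
    f_t = np.asarray(f_t_grid, dtype=float)[None, :]
    s1 = spatial_transfer(bank.sf1, f_s)
    s2 = spatial_transfer(bank.sf2, f_s)
    t1 = temporal_transfer(bank.tf1, f_t)
    t2 = temporal_transfer(bank.tf2, f_t)
    p1 = np.abs(s1) * np.abs(t1)  # A
    p2 = np.abs(s1) * np.abs(t2)  # A'
    p3 = np.abs(s2) * np.abs(t1)  # B
    p4 = np.abs(s2) * np.abs(t2)  # B'
    # phase differences via complex products (wrap-safe)
    d_ab = np.angle(s1 * np.conj(s2) * t1 * np.conj(t2))  # (phiS1+phiT1)-(phiS2+phiT2)
    d_ba = np.angle(s1 * np.conj(s2) * np.conj(t1) * t2)  # (phiS1+phiT2)-(phiS2+phiT1)
    right = 0.5 * (p1**2 + p4**2) + p1 * p4 * np.cos(d_ab) + 0.5 * (p2**2 + p3**2) - p2 * p3 * np.cos(d_ba)
    left = 0.5 * (p1**2 + p4**2) - p1 * p4 * np.cos(d_ab) + 0.5 * (p2**2 + p3**2) + p2 * p3 * np.cos(d_ba)
    return {"rightward": right, "leftward": left, "opponent": right - left}
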