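"""Analysis of optomotor trial records: response rates, masking rates, CIs
and masking-curve fits.

A trial is one presentation of a masked (or unmasked) drifting grating to
one animal; the coded response is the direction the animal leaned ("L",
"R") or "none".  The response rate ``R`` of a condition is the fraction of
its trials whose response matches the stimulus direction ("none" counts in
the denominator only).  Masking is quantified as the fractional drop from
the no-noise baseline rate, ``M = (R0 - R) / R0``; it can be negative when
a condition happens to beat its baseline.

Confidence intervals on rates are exact Clopper-Pearson binomial intervals
(valid at the small per-condition trial counts typical of insect work) and
are propagated to ``M`` holding the baseline fixed, matching per-point
error bars; joint uncertainty in ``R0`` is deliberately not folded in.

Masking curves are summarised by the three-parameter form
``M(f) = a - exp(b*log(f) - c)``: a low-frequency plateau ``a`` with a
high-frequency fall-off whose position is set by ``c/b`` -- lowpass masking,
in contrast to the bandpass masking of systems with bandpass front ends.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from statsmodels.stats.proportion import proportion_confint

__all__ = [
    "TrialRecord",
    "MaskingEstimate",
    "MaskingFit",
    "trials_to_frame",
    "read_trials",
    "write_trials",
    "response_rate",
    "masking_rate",
    "binomial_ci",
    "masking_estimates",
    "fit_masking_curve",
    "masking_model",
]

TRIAL_COLUMNS = ["individual", "signal_cpd", "noise_cpd", "direction", "response"]


@dataclass(frozen=True)
class TrialRecord:
    """One behavioural (or synthetic) trial.

    ``noise_cpd`` is ``None`` for unmasked baseline trials; ``direction`` is
    "L" or "R"; ``response`` is "L", "R" or "none".
    """

    individual: str
    signal_cpd: float
    noise_cpd: Optional[float]
    direction: str
    response: str

    def __post_init__(self) -> None:
        if self.direction not in ("L", "R"):
            raise ValueError("direction must be 'L' or 'R'")
        if self.response not in ("L", "R", "none"):
            raise ValueError("response must be 'L', 'R' or 'none'")


@dataclass(frozen=True)
class MaskingEstimate:
    """Masking rate of one condition with its 95% CI."""

    signal_cpd: float
    noise_cpd: float
    m: float
    ci_low: float
    ci_high: float
    r: float
    r0: float
    n_trials: int


@dataclass(frozen=True)
class MaskingFit:
    """Parameters of ``M(f) = a - exp(b*log(f) - c)`` with fit diagnostics."""

    a: float
    b: float
    c: float
    rms_residual: float
    converged: bool

    def __call__(self, f) -> np.ndarray:
        return masking_model(f, self.a, self.b, self.c)


def masking_model(f, a: float, b: float, c: float) -> np.ndarray:
    """Lowpass masking curve ``a - exp(b*log(f) - c)`` (natural log, f in cpd)."""
    return a - np.exp(b * np.log(np.asarray(f, dtype=float)) - c)


def trials_to_frame(trials: Iterable[TrialRecord]) -> pd.DataFrame:
    rows = [
        (t.individual, t.signal_cpd, t.noise_cpd, t.direction, t.response)
        for t in trials
    ]
    return pd.DataFrame(rows, columns=TRIAL_COLUMNS)


def _as_frame(trials) -> pd.DataFrame:
    if isinstance(trials, pd.DataFrame):
        return trials
    return trials_to_frame(trials)


def read_trials(path) -> pd.DataFrame:
    """Read a trial CSV (columns individual, signal_cpd, noise_cpd,
    direction, response; empty noise_cpd marks baseline trials)."""
    df = pd.read_csv(path, dtype={"individual": str})
    missing = set(TRIAL_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"trial file lacks columns: {sorted(missing)}")
    return df


def write_trials(trials, path) -> None:
    _as_frame(trials).to_csv(path, index=False)


def response_rate(trials) -> tuple[float, int]:
    """Fraction of trials whose response matches the stimulus direction.

    "none" responses count in the denominator only.  Raises on an empty
    trial set.
    """
    df = _as_frame(trials)
    n = len(df)
    if n == 0:
        raise ValueError("cannot compute a response rate from zero trials")
    k = int((df["response"] == df["direction"]).sum())
    return k / n, n


def masking_rate(r: float, r0: float) -> float:
    """Fractional drop in response rate, ``(r0 - r) / r0`` (may be < 0)."""
    if r0 <= 0:
        raise ValueError("undefined masking rate: baseline rate must be > 0")
    return (r0 - r) / r0


def binomial_ci(k: int, n: int, level: float = 0.95) -> tuple[float, float]:
    """Exact (Clopper-Pearson) confidence interval for a binomial rate."""
    if n <= 0:
        raise ValueError("need at least one trial")
    if not 0 <= k <= n:
        raise ValueError("successes must lie in [0, n]")
    lo, hi = proportion_confint(k, n, alpha=1.0 - level, method="beta")
    return float(lo), float(hi)


def masking_estimates(
    trials, level: float = 0.95, by_individual: bool = False
) -> pd.DataFrame:
    """Masking rate with CI for every masked condition of a trial set.

    Baseline rates are computed per signal frequency from the rows with
    missing ``noise_cpd`` (trials pooled across individuals unless
    ``by_individual``).  The rate CI is transformed to an M interval holding
    the baseline fixed: ``M_low = (R0 - R_high)/R0`` etc.
    """
    df = _as_frame(trials)
    group_cols = ["individual"] if by_individual else []
    out = []
    for keys, sub in df.groupby(group_cols + ["signal_cpd"], dropna=False):
        if not isinstance(keys, tuple):
            keys = (keys,)
        signal = keys[-1]
        base = sub[sub["noise_cpd"].isna()]
        if len(base) == 0:
            raise ValueError(f"no baseline trials for signal {signal} cpd")
        r0, _ = response_rate(base)
        if r0 <= 0:
            raise ValueError(f"baseline rate is 0 for signal {signal} cpd")
        for f_n, cond in sub[sub["noise_cpd"].notna()].groupby("noise_cpd"):
            r, n = response_rate(cond)
            k = int(round(r * n))
            r_lo, r_hi = binomial_ci(k, n, level)
            rec = {
                "signal_cpd": float(signal),
                "noise_cpd": float(f_n),
                "m": masking_rate(r, r0),
                "ci_low": masking_rate(r_hi, r0),
                "ci_high": masking_rate(r_lo, r0),
                "r": r,
                "r0": r0,
                "n_trials": n,
            }
            if by_individual:
                rec["individual"] = keys[0]
            out.append(rec)
    return pd.DataFrame(out).sort_values(
        (["individual"] if by_individual else []) + ["signal_cpd", "noise_cpd"]
    ).reset_index(drop=True)


_FIT_STARTS = ((1.0, 0.5, 0.0), (0.8, 1.0, 3.0), (0.5, 2.0, 8.0))
_FIT_BOUNDS = ([-2.0, 1e-3, -30.0], [2.0, 10.0, 30.0])


def fit_masking_curve(
    noise_frequencies: Sequence[float],
    m_values: Sequence[float],
    weights: Sequence[float] | None = None,
) -> MaskingFit:
    """Least-squares fit of ``M(f) = a - exp(b*log(f) - c)``.

    Requires >= 4 points at distinct frequencies.  Bounded trust-region
    least squares from three fixed starting points (deterministic); the best
    converged solution wins.  A fit that never converges is returned with
    ``converged=False`` and the least-bad parameters.
    """
    f = np.asarray(noise_frequencies, dtype=float)
    m = np.asarray(m_values, dtype=float)
    if len(np.unique(f)) < 4:
        raise ValueError("need at least 4 distinct noise frequencies")
    if np.any(f <= 0):
        raise ValueError("noise frequencies must be positive")
    w = np.ones_like(m) if weights is None else np.asarray(weights, dtype=float)

    def residuals(p):
        return w * (masking_model(f, *p) - m)

    best = None
    for start in _FIT_STARTS:
        try:
            res = least_squares(residuals, start, bounds=_FIT_BOUNDS, method="trf")
        except ValueError:
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None:
        raise RuntimeError("masking-curve fit failed from every start")
    rms = float(np.sqrt(np.mean((masking_model(f, *best.x) - m) ** 2)))
    return MaskingFit(
        a=float(best.x[0]), b=float(best.x[1]), c=float(best.x[2]),
        rms_residual=rms, converged=bool(best.success),
    )
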