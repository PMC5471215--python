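"""Synthetic optomotor trial datasets with known ground truth.

The behavioural experiment presented four signal spatial frequencies, each
unmasked and with noise at ten log-spaced spatial frequencies between
0.0012 and 0.5 cpd -- 44 conditions in all -- with equal numbers of left-
and right-moving trials per condition.  This module replicates that design
with per-condition response probabilities that are known exactly, so the
analysis stage can be validated end to end without animal data.

A :class:`TruthTable` holds, per condition, the probabilities that a trial
is coded as matching the stimulus direction, opposite to it, or "did not
move".  Truth tables can be written directly (e.g. from a masking-curve
formula) or derived from the opponent-detector simulation via
:func:`rates_from_model`; a *lapse* parameter mixes in non-responses:
``p_match = (1 - lapse) * rate``, ``p_none = lapse``,
``p_opposite = (1 - lapse) * (1 - rate)``.  The masking rate
``M = (R0 - R)/R0`` is invariant to the lapse (it scales numerator and
denominator alike), which is how a deterministic simulation with a
no-noise rate of 1 can emulate a baseline response rate of 0.6.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .behavior_analysis import TRIAL_COLUMNS

__all__ = [
    "SIGNAL_FREQUENCIES",
    "DesignSpec",
    "TruthTable",
    "rates_from_model",
    "truth_from_curves",
    "generate_trials",
]

#: signal spatial frequencies of the replicated design (cpd)
SIGNAL_FREQUENCIES = (0.0185, 0.0376, 0.0885, 0.177)


@dataclass(frozen=True)
class DesignSpec:
    """Experimental design: conditions, trial counts and individuals."""

    signal_frequencies: tuple = SIGNAL_FREQUENCIES
    noise_frequencies: tuple = tuple(np.geomspace(0.0012, 0.5, 10))
    trials_per_condition_per_direction: int = 15
    individuals: int = 11

    def __post_init__(self) -> None:
        if self.trials_per_condition_per_direction < 1:
            raise ValueError("need at least one trial per condition and direction")
        if self.individuals < 1:
            raise ValueError("need at least one individual")

    def conditions(self) -> list[tuple[float, Optional[float]]]:
        """All (signal, noise) conditions; ``None`` noise marks baselines."""
        out: list[tuple[float, Optional[float]]] = []
        for f_s in self.signal_frequencies:
            out.append((float(f_s), None))
            out.extend((float(f_s), float(f_n)) for f_n in self.noise_frequencies)
        return out

    @property
    def n_conditions(self) -> int:
        return len(self.signal_frequencies) * (len(self.noise_frequencies) + 1)


@dataclass
class TruthTable:
    """Per-condition true (match, opposite, none) response probabilities."""

    probabilities: dict

    def __post_init__(self) -> None:
        for cond, p in self.probabilities.items():
            p = np.asarray(p, dtype=float)
            if p.shape != (3,) or np.any(p < 0) or abs(p.sum() - 1.0) > 1e-9:
                raise ValueError(f"invalid probability triple for {cond}: {p}")
            self.probabilities[cond] = tuple(p)

    def p_match(self, condition) -> float:
        return self.probabilities[condition][0]

    def true_masking_rate(self, signal: float, noise: float) -> float:
        r0 = self.p_match((signal, None))
        return (r0 - self.p_match((signal, noise))) / r0

    def to_json(self, path) -> None:
        payload = [
            {"signal_cpd": s, "noise_cpd": n, "p_match": p[0],
             "p_opposite": p[1], "p_none": p[2]}
            for (s, n), p in self.probabilities.items()
        ]
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "TruthTable":
        with open(path) as fh:
            payload = json.load(fh)
        probs = {
            (row["signal_cpd"], row["noise_cpd"]):
                (row["p_match"], row["p_opposite"], row["p_none"])
            for row in payload
        }
        return cls(probabilities=probs)


def _triple(rate: float, lapse: float) -> tuple[float, float, float]:
    rate = float(np.clip(rate, 0.0, 1.0))
    return ((1 - lapse) * rate, (1 - lapse) * (1 - rate), lapse)


def rates_from_model(
    design: DesignSpec,
    array=None,
    *,
    signal_contrast: float | None = None,
    noise_amplitude: float = 0.198,
    f_t: float = 8.0,
    lapse: float = 0.4,
    n_presentations: int = 200,
    seed: int = 0,
) -> TruthTable:
    """Truth table whose match rates come from the insect simulation.

    Each condition's direction-matching probability is the simulated
    response rate of the opponent-detector model for that masked grating,
    scaled by ``1 - lapse`` (the lapse emulates trials on which the animal
    does not move; the default 0.4 reproduces a baseline response rate of
    about 0.6).  The default signal contrast is the simulated-masking
    default (near the deterministic model's noise-limited threshold), not
    the behavioural display contrast.
    """
    from .motion_model import GratingComponent
    from .simulation import (
        INSECT_SIM_SIGNAL_CONTRAST,
        NoiseSpec,
        insect_model,
        simulate_response_rate,
    )

    if signal_contrast is None:
        signal_contrast = INSECT_SIM_SIGNAL_CONTRAST
    if not 0 <= lapse < 1:
        raise ValueError("lapse must lie in [0, 1)")
    array = array if array is not None else insect_model()
    probs = {}
    for i, (f_s, f_n) in enumerate(design.conditions()):
        signal = GratingComponent(signal_contrast, f_s, f_t, 0.0, +1)
        noise = None if f_n is None else NoiseSpec(noise_amplitude, f_n)
        n = 1 if noise is None else n_presentations
        rate, _ = simulate_response_rate(signal, noise, array,
                                         n_presentations=n, seed=seed + i)
        probs[(f_s, f_n)] = _triple(rate, lapse)
    return TruthTable(probabilities=probs)


def truth_from_curves(
    design: DesignSpec,
    masking_of_frequency,
    baseline_rate: float = 0.6,
    lapse: float = 0.4,
) -> TruthTable:
    """Truth table from an explicit masking-rate function ``M(f_s, f_n)``.

    The baseline match probability is ``baseline_rate``; masked conditions
    get ``baseline_rate * (1 - M)``.  The ``lapse`` fills the remainder of
    each triple as in :func:`rates_from_model` (applied to the rates on the
    pre-lapse scale ``baseline_rate / (1 - lapse)``).
    """
    probs = {}
    r0 = baseline_rate / (1 - lapse)
    if not 0 < r0 <= 1:
        raise ValueError("baseline_rate and lapse are inconsistent")
    for f_s, f_n in design.conditions():
        rate = r0 if f_n is None else r0 * (1.0 - masking_of_frequency(f_s, f_n))
        probs[(f_s, f_n)] = _triple(rate, lapse)
    return TruthTable(probabilities=probs)


def generate_trials(
    truth: TruthTable, design: DesignSpec, seed: int = 0
) -> pd.DataFrame:
    """Draw a balanced trial set from a truth table.

    Per condition and per direction (L and R, equal counts) the configured
    number of trials is drawn from the condition's categorical response
    distribution; individuals are assigned round-robin.  Deterministic for a
    fixed seed, down to the CSV bytes.
    """
    rng = np.random.default_rng(seed)
    rows = []
    n_per = design.trials_per_condition_per_direction
    counter = 0
    for f_s, f_n in design.conditions():
        p = truth.probabilities[(f_s, f_n)]
        for direction in ("L", "R"):
            opposite = "R" if direction == "L" else "L"
            outcomes = rng.choice(3, size=n_per, p=p)
            for o in outcomes:
                response = (direction, opposite, "none")[o]
                individual = f"mantis{counter % design.individuals + 1:02d}"
                counter += 1
                rows.append((individual, f_s, f_n, direction, response))
    df = pd.DataFrame(rows, columns=TRIAL_COLUMNS)
    return df.astype({"noise_cpd": float})
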