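"""Two-pool magnetization-exchange (MEX) recovery model.

After selective suppression of the free-water signal, longitudinal
magnetization recovers through two channels: exchange with the semisolid
(macromolecular-bound) proton pool, with characteristic time ``tau_exc``,
and ordinary spin--lattice relaxation of free water with time ``T1``.
Under fast exchange (``tau_exc << T1``) and a 90-degree excitation the
normalized recovered signal is

    S(t) / S_eq = F * (1 - exp(-t/tau_exc)) + (1 - F) * (1 - exp(-t/T1))

where ``F`` is the fraction of protons residing in semisolids. At very
short delays (``t << T1``) the first term dominates, so the early signal
directly reflects macromolecular content. Measured series are normalized
by the longest-delay acquisition, giving the ratio form fitted in practice.

All times are in milliseconds; schedules supplied in other units must be
converted at the I/O boundary. The 90-degree flip-angle assumption is a
precondition of the model, not a parameter.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "RecoveryParams",
    "AcquisitionSchedule",
    "SignalCurve",
    "RAT_SCHEDULE",
    "MOUSE_SCHEDULE",
    "recovery_fraction",
    "normalized_recovery",
    "DegenerateModelError",
]

#: Delay schedule used for rat acquisitions (ms).
RAT_DELAYS_MS = (15.0, 50.0, 100.0, 200.0, 400.0, 800.0, 1600.0, 2500.0, 3000.0)
#: Delay schedule used for mouse acquisitions (ms).
MOUSE_DELAYS_MS = (15.0, 25.0, 50.0, 75.0, 100.0, 200.0, 600.0, 1200.0, 2500.0)


class DegenerateModelError(ValueError):
    """Raised when the model denominator vanishes (normalization impossible)."""


@dataclass(frozen=True)
class RecoveryParams:
    """Parameter triple (F, T1, tau_exc) of one voxel's or ROI's kinetics.

    Attributes
    ----------
    F : float
        Fraction of protons in semisolids, dimensionless, in [0, 1].
    T1 : float
        Longitudinal relaxation time of free water, ms, > 0.
    tau_exc : float
        Exchange time between pools, ms, > 0.
    """

    F: float
    T1: float
    tau_exc: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.F) and 0.0 <= self.F <= 1.0):
            raise ValueError(f"F must be a finite fraction in [0, 1], got {self.F}")
        if not (np.isfinite(self.T1) and self.T1 > 0):
            raise ValueError(f"T1 must be positive and finite (ms), got {self.T1}")
        if not (np.isfinite(self.tau_exc) and self.tau_exc > 0):
            raise ValueError(
                f"tau_exc must be positive and finite (ms), got {self.tau_exc}"
            )

    @property
    def fast_exchange(self) -> bool:
        """True when exchange is much faster than relaxation (tau_exc < T1/10)."""
        return self.tau_exc < self.T1 / 10.0


@dataclass(frozen=True)
class AcquisitionSchedule:
    """Ordered recovery delays t_LM (ms) with a designated maximum.

    Delays must be strictly increasing and positive; at least three are
    required (a fit needs more points than parameters).
    """

    delays: tuple[float, ...]

    def __post_init__(self) -> None:
        d = np.asarray(self.delays, dtype=float)
        if d.ndim != 1 or d.size < 3:
            raise ValueError("schedule needs at least 3 delays")
        if not np.all(np.isfinite(d)) or np.any(d <= 0):
            raise ValueError("all delays must be positive and finite (ms)")
        if np.any(np.diff(d) <= 0):
            raise ValueError("delays must be strictly increasing")
        object.__setattr__(self, "delays", tuple(float(x) for x in d))

    @property
    def t_max(self) -> float:
        return self.delays[-1]

    def __len__(self) -> int:
        return len(self.delays)

    def as_array(self) -> np.ndarray:
        return np.asarray(self.delays, dtype=float)


RAT_SCHEDULE = AcquisitionSchedule(RAT_DELAYS_MS)
MOUSE_SCHEDULE = AcquisitionSchedule(MOUSE_DELAYS_MS)


@dataclass
class SignalCurve:
    """One measured (or simulated) recovery curve on a schedule."""

    schedule: AcquisitionSchedule
    values: np.ndarray
    normalized: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.schedule),):
            raise ValueError(
                f"curve has {self.values.size} values for "
                f"{len(self.schedule)} delays"
            )


def _validate_t(t) -> np.ndarray:
    t = np.asarray(t, dtype=float)
    if not np.all(np.isfinite(t)) or np.any(t < 0):
        raise ValueError("delay t must be finite and non-negative (ms)")
    return t


def recovery_fraction(params: RecoveryParams, t) -> np.ndarray | float:
    """Fractional recovered signal S(t)/S_eq of the two-pool model.

    Parameters
    ----------
    params : RecoveryParams
    t : float or array-like
        Recovery delay(s), ms, >= 0.

    Returns
    -------
    float or ndarray in [0, 1), monotonically non-decreasing in ``t`` and
    approaching 1 as ``t -> inf``.
    """
    t = _validate_t(t)
    F, T1, tau = params.F, params.T1, params.tau_exc
    out = F * (1.0 - np.exp(-t / tau)) + (1.0 - F) * (1.0 - np.exp(-t / T1))
    return float(out) if out.ndim == 0 else out


def normalized_recovery(
    params: RecoveryParams, schedule: AcquisitionSchedule, t
) -> np.ndarray | float:
    """Recovery signal normalized by its value at the longest delay.

    Equals ``recovery_fraction(params, t) / recovery_fraction(params, t_max)``
    and is exactly 1 at ``t = t_max``.
    """
    denom = recovery_fraction(params, schedule.t_max)
    if denom <= 0:
        raise DegenerateModelError(
            "recovery at t_max is zero; normalized model undefined"
        )
    return recovery_fraction(params, t) / denom
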