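"""Photon-by-photon MINSTED localization state machine.

The localizer circles the STED doughnut (and with it the Gaussian E-PSF of
FWHM ``d_i``) on a circle of radius ``R_i`` around the current position
estimate ``C_i``.  On every photon detection the centre is pulled a fraction
``alpha`` of the radius toward the doughnut position at the detection phase,
and ``R_i`` and ``d_i`` shrink by a factor ``gamma`` until the floor
``d_min`` / ``R_min`` is reached — from then on only the centre is updated.
The final position estimate is the average of the centre positions collected
after the floor was reached.

This module contains only the deterministic update rule and bookkeeping;
photon statistics live in :mod:`minsted.simulate`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .psf import EPSFModel, epsf_fwhm, intensity_for_fwhm

__all__ = [
    "LocalizerParams",
    "LocalizerState",
    "LocalizationRecord",
    "new_state",
    "scan_position",
    "update_on_detection",
    "steps_to_dmin",
    "finalize",
    "min_separation",
]

#: Calibration constant of the per-localization precision estimate
#: sigma_hat = KAPPA * d_min / sqrt(N - N_c + 1).  Calibrated once against
#: this package's own Monte-Carlo simulator at SBR = 20, d_min = 40 nm
#: (seed 1); see docs/methods.md.
DEFAULT_PRECISION_KAPPA = 0.58


@dataclass(frozen=True)
class LocalizerParams:
    """Constants of the MINSTED homing-in schedule.

    alpha : fraction of the scan radius the centre moves per detection.
    gamma : per-detection shrink factor of d and R (3% shrink = 0.97).
    ratio_Rd : scan radius as a fraction of the E-PSF FWHM (R = ratio * d).
    d0 : starting (diffraction-limited) E-PSF FWHM in nm.
    d_min : FWHM floor in nm.
    R_min : scan-radius floor in nm; defaults to ratio_Rd * d_min.
    I_max : doughnut intensity cap in units of I_s; may imply a FWHM floor
        above d_min (enforced through the E-PSF model).
    N_max : hard cap on detections per localization.
    precision_kappa : constant of the precision estimate (see module docs).
    """

    alpha: float = 0.15
    gamma: float = 0.97
    ratio_Rd: float = 0.5
    d0: float = 775.0 / (2.0 * 1.4)
    d_min: float = 40.0
    R_min: float | None = None
    I_max: float = math.inf
    N_max: int = 100_000
    precision_kappa: float = DEFAULT_PRECISION_KAPPA

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must be in (0, 1)")
        if not (0.0 < self.gamma < 1.0):
            raise ValueError("gamma must be in (0, 1)")
        if self.ratio_Rd <= 0:
            raise ValueError("ratio_Rd must be positive")
        if not (0.0 < self.d_min <= self.d0):
            raise ValueError("d_min must be in (0, d0]")
        if self.R_min is not None and self.R_min <= 0:
            raise ValueError("R_min must be positive")
        if self.N_max < 1:
            raise ValueError("N_max must be at least 1")

    @property
    def r_min(self) -> float:
        """Effective scan-radius floor."""
        return self.ratio_Rd * self.d_min if self.R_min is None else self.R_min

    def d_floor(self, model: EPSFModel | None = None) -> float:
        """FWHM floor including the intensity cap.

        With a finite ``I_max`` the FWHM cannot shrink below
        ``epsf_fwhm(I_max)`` even if that is larger than ``d_min``.
        """
        if model is None or not math.isfinite(self.I_max):
            return self.d_min
        if intensity_for_fwhm(model, self.d_min) > self.I_max:
            return float(epsf_fwhm(model, self.I_max))
        return self.d_min


@dataclass
class LocalizerState:
    """Evolving state of one localization.

    ``history`` holds one ``(Cx, Cy, R, d, phi)`` row per detection, i.e.
    the state *after* applying detection ``i``; its length equals ``i``.
    """

    C: np.ndarray
    R: float
    d: float
    i: int = 0
    d_floor: float = 40.0
    r_floor: float = 20.0
    history: list = field(default_factory=list)


def new_state(params: LocalizerParams, C0=(0.0, 0.0),
              model: EPSFModel | None = None) -> LocalizerState:
    """Fresh localizer state at the starting estimate ``C0``."""
    return LocalizerState(
        C=np.array(C0, dtype=float),
        R=params.ratio_Rd * params.d0,
        d=params.d0,
        i=0,
        d_floor=params.d_floor(model),
        r_floor=params.r_min,
    )


def scan_position(state: LocalizerState, phi) -> np.ndarray:
    """Doughnut position ``S = C + R (cos phi, sin phi)`` at scan phase phi."""
    phi = np.asarray(phi, dtype=float)
    return state.C + state.R * np.stack([np.cos(phi), np.sin(phi)], axis=-1)


def update_on_detection(state: LocalizerState, params: LocalizerParams,
                        phi: float) -> LocalizerState:
    """Apply one photon detection at scan phase ``phi`` (in-place).

    The centre is shifted by ``alpha * R`` toward the doughnut position
    first; then ``d`` and ``R`` shrink by ``gamma`` down to their floors.
    Once the floors are reached only the centre moves.
    """
    state.C = state.C + params.alpha * state.R * np.array(
        [math.cos(phi), math.sin(phi)])
    state.d = max(params.gamma * state.d, state.d_floor)
    state.R = max(params.gamma * state.R, state.r_floor)
    state.i += 1
    state.history.append((state.C[0], state.C[1], state.R, state.d, phi))
    return state


def steps_to_dmin(params: LocalizerParams) -> int:
    """Smallest k with ``d0 * gamma**k <= d_min`` (detections to the floor)."""
    if params.d0 <= params.d_min:
        return 0
    k = math.ceil(math.log(params.d_min / params.d0) / math.log(params.gamma))
    # guard against floating-point off-by-one on the boundary
    while k > 0 and params.d0 * params.gamma ** (k - 1) <= params.d_min:
        k -= 1
    while params.d0 * params.gamma ** k > params.d_min:
        k += 1
    return k


@dataclass(frozen=True)
class LocalizationRecord:
    """Result of one localization."""

    C_bar: np.ndarray      # final 2D estimate (nm)
    N: int                 # total detections
    N_c: int               # detection index at which the FWHM floor was reached
    sigma_C: float         # pooled per-axis std of the floor-phase C_i (nm)
    sigma_hat: float       # estimated localization precision (nm)
    converged: bool


def finalize(state: LocalizerState, params: LocalizerParams) -> LocalizationRecord:
    """Reduce a finished trace to a :class:`LocalizationRecord`.

    The estimate averages ``C_i`` for ``N_c <= i <= N`` where ``N_c`` is the
    first detection at which the FWHM floor was reached.  If the floor was
    never reached the trace did not converge: ``C_bar`` is the last centre
    and ``N_c`` is reported as ``N``.
    """
    if not state.history:
        raise ValueError("cannot finalize an empty trace")
    h = np.asarray(state.history, dtype=float)
    N = state.i
    d_col = h[:, 3]
    floor_tol = state.d_floor * (1.0 + 1e-12)
    at_floor = d_col <= floor_tol
    if at_floor.any():
        N_c = int(np.argmax(at_floor)) + 1  # detections are 1-based
    else:
        N_c = N
    tail = h[N_c - 1:, 0:2] if at_floor.any() else h[-1:, 0:2]
    C_bar = tail.mean(axis=0)
    n_tail = tail.shape[0]
    if n_tail >= 2:
        var = tail.var(axis=0, ddof=1)
        sigma_C = float(np.sqrt(var.mean()))
    else:
        sigma_C = 0.0
    sigma_hat = params.precision_kappa * params.d_min / math.sqrt(N - N_c + 1)
    converged = bool(at_floor.any() and N > N_c)
    return LocalizationRecord(C_bar=C_bar, N=N, N_c=N_c, sigma_C=sigma_C,
                              sigma_hat=sigma_hat, converged=converged)


def min_separation(params: LocalizerParams, d_i: float, R_i: float) -> float:
    """Closest distance another active fluorophore may have without
    corrupting the current localization: ``d_i + (1 + 2 alpha) R_i``."""
    if d_i <= 0 or R_i <= 0:
        raise ValueError("d_i and R_i must be positive")
    return d_i + (1.0 + 2.0 * params.alpha) * R_i
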