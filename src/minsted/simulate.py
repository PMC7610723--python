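"""Monte-Carlo photon source for MINSTED localization.

A single active fluorophore at ``r_FL`` is probed by the circling E-PSF.
Conditioned on a photon detection, the scan phase ``phi`` at which it
occurred follows

    p(phi)  proportional to  epsf(d, |S(phi) - r_FL|) + 1/SBR

with ``S(phi) = C + R (cos phi, sin phi)`` — the Gaussian emission
probability at the doughnut position plus a phase-uniform background term
whose weight is set by the peak signal-to-background ratio.  Because
``|S - r_FL|^2 = R^2 + rho0^2 - 2 R rho0 cos(phi - phi0)``, the signal part
is exactly a von Mises density with concentration
``kappa = 8 ln2 R rho0 / d^2`` pointing toward the emitter, so detections
are drawn exactly (no grid or rejection step) as a Bernoulli mixture of a
von Mises draw and a uniform background draw.

Scan phases are sampled i.i.d. from this instantaneous density: the beam
circles many times between detections, so only the detection statistics —
not the revolution phase — matter.  Background photons are indistinguishable
from signal photons and drive the same centre update; that is exactly how a
low SBR degrades convergence.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import i0e

from .localizer import (LocalizerParams, LocalizerState, finalize,
                        min_separation, new_state, update_on_detection)
from .psf import EPSFModel

__all__ = [
    "PhotonScene",
    "EmitterLayout",
    "detection_phase_pdf",
    "signal_background_split",
    "sample_detection",
    "run_localization",
    "run_ensemble",
    "EnsembleRun",
    "generate_scene_ensemble",
]

logger = logging.getLogger(__name__)

_4LN2 = 4.0 * math.log(2.0)


@dataclass(frozen=True)
class PhotonScene:
    """Ground truth and photon statistics of one emitter.

    r_FL : true fluorophore position (nm).
    sbr : peak signal-to-background ratio; ``math.inf`` for no background.
    budget_mean : mean of the geometric photon budget before bleaching.
    sigma0 : per-axis std (nm) of the starting-centre offset, emulating the
        5-10 detection pre-identification of the emitter.
    seed : RNG seed used when no generator is passed explicitly.
    """

    r_FL: tuple = (0.0, 0.0)
    sbr: float = 20.0
    budget_mean: float = 1000.0
    sigma0: float = 60.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.sbr > 0:
            raise ValueError("sbr must be positive (math.inf allowed)")
        if self.budget_mean <= 0:
            raise ValueError("budget_mean must be positive")
        if self.sigma0 < 0:
            raise ValueError("sigma0 must be non-negative")

    @property
    def position(self) -> np.ndarray:
        return np.asarray(self.r_FL, dtype=float)


def _geometry(state: LocalizerState, scene: PhotonScene):
    """(rho0, phi0, kappa) of the emitter relative to the scan circle."""
    delta = scene.position - state.C
    rho0 = float(np.hypot(delta[0], delta[1]))
    phi0 = float(math.atan2(delta[1], delta[0]))
    kappa = 2.0 * _4LN2 * state.R * rho0 / state.d ** 2
    return rho0, phi0, kappa


def signal_background_split(state: LocalizerState, scene: PhotonScene):
    """Probability that the next detection is signal vs background.

    The phase-integrated signal weight is ``exp(-4ln2 (R^2+rho0^2)/d^2) I0(kappa)``
    against a background weight of ``1/sbr``; the two fractions sum to 1.
    """
    rho0, _, kappa = _geometry(state, scene)
    a = _4LN2 * (state.R ** 2 + rho0 ** 2) / state.d ** 2
    with np.errstate(over="ignore", under="ignore"):
        w_sig = math.exp(min(kappa - a, 700.0)) * float(i0e(kappa))
    if not math.isfinite(scene.sbr):
        return 1.0, 0.0
    w_bg = 1.0 / scene.sbr
    p_sig = w_sig / (w_sig + w_bg)
    return p_sig, 1.0 - p_sig


def detection_phase_pdf(state: LocalizerState, scene: PhotonScene):
    """Normalized detection-phase density on [0, 2pi) as a callable.

    ``pdf(phi)`` evaluates ``(epsf(d, |S(phi)-r_FL|) + 1/sbr) / Z`` with the
    normalization constant computed in closed form.  With ``sbr = inf`` the
    background term vanishes and the density is a pure von Mises law.
    """
    rho0, phi0, kappa = _geometry(state, scene)
    d, R = state.d, state.R
    a = _4LN2 * (R ** 2 + rho0 ** 2) / d ** 2
    bg = 0.0 if not math.isfinite(scene.sbr) else 1.0 / scene.sbr
    with np.errstate(over="ignore", under="ignore"):
        Z = 2.0 * math.pi * (math.exp(min(kappa - a, 700.0)) * float(i0e(kappa)) + bg)

    def pdf(phi):
        phi = np.asarray(phi, dtype=float)
        sig = np.exp(-a + kappa * np.cos(phi - phi0))
        out = (sig + bg) / Z
        return float(out) if out.ndim == 0 else out

    return pdf


def sample_detection(state: LocalizerState, scene: PhotonScene,
                     rng: np.random.Generator) -> float:
    """Draw one detection phase in [0, 2pi) from the current state."""
    _, phi0, kappa = _geometry(state, scene)
    p_sig, _ = signal_background_split(state, scene)
    if rng.random() < p_sig:
        phi = rng.vonmises(phi0, kappa) if kappa > 0 else rng.uniform(-math.pi, math.pi)
    else:
        phi = rng.uniform(-math.pi, math.pi)
    return float(phi % (2.0 * math.pi))


def run_localization(scene: PhotonScene, params: LocalizerParams,
                     model: EPSFModel | None = None, N: int | None = None,
                     rng: np.random.Generator | None = None):
    """Simulate one full localization of ``scene``.

    The starting centre is the true position plus a Gaussian offset of std
    ``scene.sigma0`` per axis (pre-identification).  Detections are drawn
    photon by photon and fed to the localizer update; the run stops after
    ``N`` detections, or after a geometric photon-budget draw with mean
    ``scene.budget_mean`` when ``N`` is not given (capped at
    ``params.N_max`` either way).

    Returns ``(record, trace)`` where ``trace`` is a DataFrame with columns
    ``i, phi, Cx, Cy, R, d`` (one row per detection).
    """
    if rng is None:
        rng = np.random.default_rng(scene.seed)
    C0 = scene.position + rng.normal(0.0, scene.sigma0, size=2)
    state = new_state(params, C0, model)
    if N is None:
        N = int(rng.geometric(1.0 / scene.budget_mean))
    N = min(int(N), params.N_max)
    if N < 1:
        raise ValueError("need at least one detection")
    for _ in range(N):
        phi = sample_detection(state, scene, rng)
        update_on_detection(state, params, phi)
    record = finalize(state, params)
    h = np.asarray(state.history, dtype=float)
    trace = pd.DataFrame({
        "i": np.arange(1, N + 1),
        "phi": h[:, 4],
        "Cx": h[:, 0],
        "Cy": h[:, 1],
        "R": h[:, 2],
        "d": h[:, 3],
    })
    return record, trace


@dataclass
class EnsembleRun:
    """Vectorized replicate traces of identical localizations.

    C : centre positions after each detection, shape (replicates, N, 2).
    d_sched, R_sched : the (deterministic) post-update FWHM and radius
        schedules, shape (N,).
    N_c : 1-based detection index at which the FWHM floor is reached,
        or 0 if it is not reached within N.
    """

    C: np.ndarray
    d_sched: np.ndarray
    R_sched: np.ndarray
    N_c: int
    r_FL: np.ndarray
    params: LocalizerParams

    @property
    def n_detections(self) -> int:
        return self.C.shape[1]

    def estimates(self, N: int | None = None) -> np.ndarray:
        """Per-replicate estimates C_bar at total detection count ``N``."""
        N = self.n_detections if N is None else int(N)
        if self.N_c == 0 or N < self.N_c:
            return self.C[:, N - 1, :].copy()      # not converged: last centre
        return self.C[:, self.N_c - 1:N, :].mean(axis=1)

    def lost_mask(self, N: int | None = None, threshold: float | None = None) -> np.ndarray:
        """Replicates whose centre ended further than ``threshold`` (default:
        the current FWHM) from the true position — classified as lost."""
        N = self.n_detections if N is None else int(N)
        if threshold is None:
            threshold = float(self.d_sched[N - 1])
        dist = np.hypot(*(self.C[:, N - 1, :] - self.r_FL).T)
        return dist > threshold


def run_ensemble(scene: PhotonScene, params: LocalizerParams, N: int,
                 replicates: int, rng: np.random.Generator | None = None,
                 model: EPSFModel | None = None,
                 static_d: float | None = None) -> EnsembleRun:
    """Run ``replicates`` independent localizations of ``scene`` in lockstep.

    Statistically identical to repeated :func:`run_localization` calls (the
    update rule and phase density are shared); all replicates advance one
    photon per step with vectorized draws.  ``static_d`` freezes the FWHM
    and radius at the given value (no shrinkage, ``R = ratio_Rd * static_d``)
    as used in the fixed-width precision and convergence studies.
    """
    if rng is None:
        rng = np.random.default_rng(scene.seed)
    N = int(N)
    reps = int(replicates)
    r = scene.position

    if static_d is not None:
        d_use = np.full(N, float(static_d))
        R_use = np.full(N, params.ratio_Rd * float(static_d))
        d_post, R_post = d_use, R_use
        N_c = 1
    else:
        d_floor = params.d_floor(model)
        r_floor = params.r_min
        k = np.arange(N)
        d_use = np.maximum(params.d0 * params.gamma ** k, d_floor)
        R_use = np.maximum(params.ratio_Rd * params.d0 * params.gamma ** k, r_floor)
        d_post = np.maximum(params.d0 * params.gamma ** (k + 1), d_floor)
        R_post = np.maximum(params.ratio_Rd * params.d0 * params.gamma ** (k + 1), r_floor)
        at_floor = d_post <= d_floor * (1 + 1e-12)
        N_c = int(np.argmax(at_floor)) + 1 if at_floor.any() else 0

    C = r + rng.normal(0.0, scene.sigma0, size=(reps, 2))
    out = np.empty((reps, N, 2))
    bg = 0.0 if not math.isfinite(scene.sbr) else 1.0 / scene.sbr
    for step in range(N):
        d, R = d_use[step], R_use[step]
        delta = r - C
        rho0 = np.hypot(delta[:, 0], delta[:, 1])
        phi0 = np.arctan2(delta[:, 1], delta[:, 0])
        kappa = 2.0 * _4LN2 * R * rho0 / d ** 2
        a = _4LN2 * (R ** 2 + rho0 ** 2) / d ** 2
        with np.errstate(over="ignore", under="ignore"):
            w_sig = np.exp(np.minimum(kappa - a, 700.0)) * i0e(kappa)
        p_sig = 1.0 if bg == 0.0 else w_sig / (w_sig + bg)
        is_sig = rng.random(reps) < p_sig
        phi = rng.vonmises(phi0, np.maximum(kappa, 1e-300))
        phi_bg = rng.uniform(-math.pi, math.pi, size=reps)
        phi = np.where(is_sig, phi, phi_bg)
        C = C + params.alpha * R * np.stack([np.cos(phi), np.sin(phi)], axis=1)
        out[:, step, :] = C
    return EnsembleRun(C=out, d_sched=np.asarray(d_post),
                       R_sched=np.asarray(R_post), N_c=N_c,
                       r_FL=np.asarray(r, dtype=float), params=params)


@dataclass(frozen=True)
class EmitterLayout:
    """Specification of a synthetic multi-emitter scene.

    kind : 'explicit' (use ``positions``), 'uniform' (``n_emitters`` points
        uniform in a square field of side ``field_size`` nm) or 'ring'
        (``n_emitters`` points equally spaced on a circle of ``ring_radius``
        nm around ``center``).
    """

    kind: str = "explicit"
    positions: tuple = ()
    n_emitters: int = 0
    field_size: float = 500.0
    ring_radius: float = 50.0
    center: tuple = (0.0, 0.0)
    sbr: float = 20.0
    budget_mean: float = 1000.0
    sigma0: float = 60.0


def generate_scene_ensemble(layout: EmitterLayout, seed: int = 0,
                            params: LocalizerParams | None = None) -> list[PhotonScene]:
    """One :class:`PhotonScene` per emitter, activated one at a time.

    Only one fluorophore is active at any given time, so every emitter is
    localized independently; per-scene seeds are derived deterministically
    from the top-level ``seed`` via ``np.random.SeedSequence(seed)``.
    If ``params`` is given, emitter pairs closer than the minimum separation
    at the FWHM floor trigger a warning (not an error).
    """
    rng = np.random.default_rng(seed)
    if layout.kind == "explicit":
        pos = np.asarray(layout.positions, dtype=float).reshape(-1, 2)
    elif layout.kind == "uniform":
        pos = rng.uniform(0.0, layout.field_size, size=(layout.n_emitters, 2))
    elif layout.kind == "ring":
        theta = 2.0 * math.pi * np.arange(layout.n_emitters) / layout.n_emitters
        pos = np.asarray(layout.center) + layout.ring_radius * np.stack(
            [np.cos(theta), np.sin(theta)], axis=1)
    else:
        raise ValueError(f"unknown layout kind {layout.kind!r}")
    if params is not None and len(pos) > 1:
        sep = min_separation(params, params.d_min, params.r_min)
        diff = pos[:, None, :] - pos[None, :, :]
        dist = np.hypot(diff[..., 0], diff[..., 1])
        iu = np.triu_indices(len(pos), k=1)
        if (dist[iu] < sep).any():
            logger.warning(
                "emitter pairs closer than the minimum separation %.1f nm "
                "at the FWHM floor; sequential localizations may interfere", sep)
    seeds = np.random.SeedSequence(seed).generate_state(max(len(pos), 1))
    return [
        PhotonScene(r_FL=(float(p[0]), float(p[1])), sbr=layout.sbr,
                    budget_mean=layout.budget_mean, sigma0=layout.sigma0,
                    seed=int(seeds[j]))
        for j, p in enumerate(pos)
    ]
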