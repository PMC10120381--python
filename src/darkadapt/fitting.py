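"""Nelder--Mead least-squares fitting of the two-stage dark-adaptation model.

One :class:`DarkAdaptationModel` holds the (time, intensity) points of a
single response sequence; its :meth:`~DarkAdaptationModel.fit` minimises the
unweighted sum of squared residuals in log10 cd/m^2 by derivative-free
simplex search and returns a :class:`DarkAdaptationResults`.

The simplex runs in an unconstrained reparameterisation -- magnitudes as
``exp(u)``, rates as ``-exp(v)``, break time through a logistic map into
``(0, test duration)`` -- so every iterate satisfies the model invariants
without penalty terms.  Fits are deterministic: the same points and the same
seed parameters always give bit-identical results.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Optional, Tuple

import numpy as np
from scipy.optimize import minimize

from .model import (
    DAOutcome,
    DAParams,
    DEFAULT_TEST_DURATION_S,
    derive_outcomes,
    eval_model,
    rod_asymptote,
)

__all__ = [
    "ResponseSequence",
    "FitConfig",
    "FitResult",
    "DarkAdaptationModel",
    "DarkAdaptationResults",
    "InsufficientDataError",
    "ParticipantFit",
    "extract_fit_points",
    "fit_sequence",
    "fit_participant",
    "DEFAULT_SEED_PARAMS",
]

CHANNELS = ("red625", "green527")

#: Fixed simplex starting point used for every fit (overridable in config).
DEFAULT_SEED_PARAMS = DAParams(Bc=-1.5, Ic=2.5, Rc=-0.01, Ir=3.0, Rr=-0.003, tb=660.0)


class InsufficientDataError(ValueError):
    """Fewer usable points than the model can be fitted to."""


@dataclass(frozen=True)
class ResponseSequence:
    """Ordered staircase presentations of one stimulus channel.

    ``times``/``intensities``/``detected`` are parallel arrays: presentation
    time (s since bleach offset, strictly increasing), presented intensity
    (log10 cd/m^2) and whether the participant reported seeing it.
    """

    channel: str
    times: np.ndarray
    intensities: np.ndarray
    detected: np.ndarray
    protocol_id: str = "default"
    test_duration: float = DEFAULT_TEST_DURATION_S

    def __post_init__(self):
        object.__setattr__(self, "times", np.asarray(self.times, float))
        object.__setattr__(self, "intensities", np.asarray(self.intensities, float))
        object.__setattr__(self, "detected", np.asarray(self.detected, bool))
        if self.channel not in CHANNELS:
            raise ValueError(f"channel must be one of {CHANNELS}, got {self.channel!r}")
        n = len(self.times)
        if len(self.intensities) != n or len(self.detected) != n:
            raise ValueError("times/intensities/detected lengths differ")
        if n and (np.any(np.diff(self.times) <= 0)):
            raise ValueError("trial times must be strictly increasing")
        if n and (self.times[0] < 0 or self.times[-1] > self.test_duration):
            raise ValueError("trial times outside [0, test_duration]")

    def __len__(self) -> int:
        return len(self.times)


@dataclass(frozen=True)
class FitConfig:
    """Knobs of the simplex fit; defaults reproduce the standard analysis."""

    seed_params: DAParams = DEFAULT_SEED_PARAMS
    auto_seed: bool = True             # also consider data-driven starts
    multi_start: bool = False          # run the simplex from every candidate start
    mode: str = "seen_only"            # which trials enter the fit
    rel_sse_tol: float = 1e-10         # relative objective tolerance
    param_tol: float = 1e-8            # simplex parameter tolerance
    max_evals: int = 5000              # per simplex run
    n_restarts: int = 1                # sequential re-starts from the incumbent
    min_points: int = 7                # more points than free parameters
    tb_min: float = 300.0              # earliest fittable break, s after bleach
    test_duration: float = DEFAULT_TEST_DURATION_S
    trcb_channel: str = "green"
    rod_threshold_mode: str = "asymptote"


def extract_fit_points(seq: ResponseSequence, mode: str = "seen_only",
                       min_points: int = 7) -> Tuple[np.ndarray, np.ndarray]:
    """Select the (time, intensity) points the curve is fitted to.

    ``seen_only`` keeps detected trials only -- each detection bounds the
    momentary threshold from above and the staircase keeps those bounds
    tight -- while ``all_trials`` keeps every presentation.  Chronological
    order is preserved.

    Raises
    ------
    InsufficientDataError
        If fewer than ``min_points`` points remain.
    """
    if len(seq) == 0:
        raise InsufficientDataError("empty response sequence")
    if mode == "seen_only":
        mask = seq.detected
    elif mode == "all_trials":
        mask = np.ones(len(seq), bool)
    else:
        raise ValueError(f"mode must be 'seen_only' or 'all_trials', got {mode!r}")
    t, y = seq.times[mask], seq.intensities[mask]
    if len(t) < min_points:
        raise InsufficientDataError(
            f"{len(t)} fit points < required {min_points} ({seq.channel})")
    return t, y


# ---------------------------------------------------------------------------
# parameter transform: R^6 <-> valid DAParams
#
# Magnitudes are bounded to [e^-12, e^8] log units and rate magnitudes to
# [e^-16, e^3] 1/s: generous for any physiological curve, but keeping a
# poorly identified rod branch from running off to a numerically absurd
# asymptote.

_CLIP_LO = np.array([-np.inf, -12.0, -16.0, -12.0, -16.0, -36.0])
_CLIP_HI = np.array([np.inf, 8.0, 3.0, 8.0, 3.0, 36.0])


def _to_unconstrained(p: DAParams, duration: float, tb_min: float = 0.0) -> np.ndarray:
    frac = min(max((p.tb - tb_min) / (duration - tb_min), 1e-9), 1 - 1e-9)
    return np.array([
        p.Bc,
        math.log(max(p.Ic, 1e-12)),
        math.log(max(-p.Rc, 1e-12)),
        math.log(max(p.Ir, 1e-12)),
        math.log(max(-p.Rr, 1e-12)),
        math.log(frac / (1 - frac)),
    ])


def _from_unconstrained(x: np.ndarray, duration: float, tb_min: float = 0.0) -> DAParams:
    z = np.clip(x, _CLIP_LO, _CLIP_HI)
    return DAParams(
        Bc=float(z[0]),
        Ic=float(math.exp(z[1])),
        Rc=float(-math.exp(z[2])),
        Ir=float(math.exp(z[3])),
        Rr=float(-math.exp(z[4])),
        tb=float(tb_min + (duration - tb_min) / (1.0 + math.exp(-z[5]))),
    )


def _data_driven_seed(t: np.ndarray, y: np.ndarray, base: DAParams,
                      duration: float, tb0: float) -> DAParams:
    """Plateau-matching starting point built from the fit points.

    Reads the late plateau off the last portion of the run and the cone
    plateau off a window before the candidate break time ``tb0``, then
    solves the rod magnitude so the curve's rod asymptote hits the late
    plateau.  Rates are taken from ``base``.
    """
    late = y[t >= 0.85 * duration]
    asym = float(np.mean(late)) if len(late) else float(np.min(y))
    win = y[(t >= tb0 - 240.0) & (t <= tb0)]
    Bc0 = float(np.mean(win)) if len(win) >= 3 else float(np.median(y))
    early = y[np.argsort(t)[:3]]
    Ic0 = max(float(np.mean(early)) - Bc0, 0.5)
    level_tb = Bc0 + Ic0 * math.exp(base.Rc * tb0)
    Ir0 = max((level_tb - asym) / math.exp(base.Rr * tb0), 0.1)
    return DAParams(Bc=Bc0, Ic=Ic0, Rc=base.Rc, Ir=Ir0, Rr=base.Rr, tb=tb0)


#: Break-time fractions of the fittable break window scanned for a start.
_TB_SCAN_FRACTIONS = (0.04, 0.10, 0.17, 0.25, 0.34, 0.44, 0.55, 0.67, 0.80, 0.90)
#: Rate multipliers applied to the seed rates during the scan.
_RATE_SCAN_MULTIPLIERS = (0.25, 0.5, 1.0, 2.0, 4.0)


def _profile_scan(t, y, ones, tb_values, rc_values, rr_values):
    """Scan (tb, Rc, Rr) with (Bc, Ic, Ir) profiled out by least squares.

    The model is linear in the asymptote and the two magnitudes once break
    time and rates are fixed; negative magnitudes are clipped back into the
    valid region and rescored.
    """
    best, best_sse = None, math.inf
    for tb in tb_values:
        for rc in rc_values:
            f2 = np.exp(rc * np.minimum(t, tb))
            for rr in rr_values:
                f3 = np.where(t >= tb, np.exp(rr * t) - math.exp(rr * tb), 0.0)
                X = np.column_stack([ones, f2, f3])
                beta, *_ = np.linalg.lstsq(X, y, rcond=None)
                Bc, Ic, Ir = float(beta[0]), max(float(beta[1]), 1e-6), \
                    max(float(beta[2]), 1e-6)
                pred = Bc + Ic * f2 + Ir * f3
                r = y - pred
                sse = float(r @ r)
                if sse < best_sse:
                    best = DAParams(Bc=Bc, Ic=Ic, Rc=rc, Ir=Ir, Rr=rr, tb=float(tb))
                    best_sse = sse
    return best, best_sse


def _profiled_seed(t: np.ndarray, y: np.ndarray, base: DAParams,
                   duration: float, tb_min: float = 0.0) -> DAParams:
    """Coarse-to-fine profiled scan for a simplex starting point."""
    ones = np.ones_like(t)
    tb_coarse = [tb_min + f * (duration - tb_min) for f in _TB_SCAN_FRACTIONS]
    rc_coarse = [base.Rc * m for m in _RATE_SCAN_MULTIPLIERS]
    rr_coarse = [base.Rr * m for m in _RATE_SCAN_MULTIPLIERS]
    best, _ = _profile_scan(t, y, ones, tb_coarse, rc_coarse, rr_coarse)
    tb_fine = np.clip(np.linspace(best.tb - 0.08 * duration,
                                  best.tb + 0.08 * duration, 7),
                      tb_min + 1.0, duration - 1.0)
    rc_fine = [best.Rc * m for m in (0.5, 0.7, 1.0, 1.4, 2.0)]
    rr_fine = [best.Rr * m for m in (0.5, 0.7, 1.0, 1.4, 2.0)]
    refined, _ = _profile_scan(t, y, ones, tb_fine, rc_fine, rr_fine)
    return refined


class DarkAdaptationModel:
    """Two-stage exponential decay model bound to one response sequence.

    Parameters
    ----------
    times, intensities : array-like
        The fit points (s since bleach offset; log10 cd/m^2).
    test_duration : float
        Protocol test duration in seconds; bounds the break time.
    channel : str, optional
        Stimulus channel label carried through to results.

    Examples
    --------
    >>> model = DarkAdaptationModel.from_sequence(seq)        # doctest: +SKIP
    >>> res = model.fit()                                     # doctest: +SKIP
    >>> res.params.tb / 60                                    # doctest: +SKIP
    """

    def __init__(self, times, intensities, *, test_duration: float = DEFAULT_TEST_DURATION_S,
                 channel: Optional[str] = None):
        self.times = np.asarray(times, float)
        self.intensities = np.asarray(intensities, float)
        if self.times.shape != self.intensities.shape:
            raise ValueError("times and intensities must have the same shape")
        self.test_duration = float(test_duration)
        self.channel = channel
        self.nobs = len(self.times)

    @classmethod
    def from_sequence(cls, seq: ResponseSequence, mode: str = "seen_only",
                      min_points: int = 7) -> "DarkAdaptationModel":
        t, y = extract_fit_points(seq, mode=mode, min_points=min_points)
        return cls(t, y, test_duration=seq.test_duration, channel=seq.channel)

    def loss(self, params: DAParams) -> float:
        """Sum of squared residuals of the model at ``params``."""
        resid = self.intensities - eval_model(params, self.times)
        return float(resid @ resid)

    def fit(self, start_params: Optional[DAParams] = None,
            config: Optional[FitConfig] = None) -> "DarkAdaptationResults":
        """Minimise the SSE by Nelder--Mead from fixed seed parameters.

        Non-convergence within the evaluation budget is flagged on the
        result (``converged=False``), never raised.  A degenerate input
        (all intensities identical) returns a flagged flat fit with the
        break pinned to mid-test.
        """
        config = config or FitConfig()
        seed = start_params or config.seed_params
        duration = self.test_duration
        # breaks earlier than tb_min are non-physiological after a full
        # bleach and leave the cone asymptote unidentified
        tb_min = min(config.tb_min, 0.45 * duration)
        if seed.tb <= tb_min:
            seed = replace(seed, tb=tb_min + 0.5 * (duration - tb_min))

        if self.nobs < config.min_points:
            raise InsufficientDataError(f"{self.nobs} points < {config.min_points}")

        if np.ptp(self.intensities) == 0.0:
            flat = DAParams(Bc=float(self.intensities[0]), Ic=1e-9, Rc=-1e-3,
                            Ir=1e-9, Rr=-1e-3, tb=duration / 2.0)
            return DarkAdaptationResults(self, flat, sse=0.0, converged=False,
                                         n_evals=0, seed_params=seed,
                                         flags=("degenerate_constant_intensity",))

        t, y = self.times, self.intensities

        def objective(x):
            z = np.clip(x, _CLIP_LO, _CLIP_HI)
            Bc = z[0]
            Ic, Ir = math.exp(z[1]), math.exp(z[3])
            Rc, Rr = -math.exp(z[2]), -math.exp(z[4])
            tb = tb_min + (duration - tb_min) / (1.0 + math.exp(-z[5]))
            level_at_tb = Bc + Ic * math.exp(Rc * tb) - Ir * math.exp(Rr * tb)
            pred = np.where(t < tb, Bc + Ic * np.exp(Rc * t),
                            level_at_tb + Ir * np.exp(Rr * t))
            r = y - pred
            return float(r @ r)

        if start_params is None and config.auto_seed:
            # the break time is the main axis of multimodality: consider
            # the fixed seed, a plateau-matched seed, and the best point of
            # a coarse-to-fine profiled (tb, rates) scan
            candidates = [seed, _data_driven_seed(t, y, seed, duration, seed.tb),
                          _profiled_seed(t, y, seed, duration, tb_min)]
            candidates.sort(key=self.loss)
            if not config.multi_start:
                candidates = candidates[:1]
            seed = candidates[0]
        else:
            candidates = [seed]

        def run_simplex(start: DAParams):
            x0 = _to_unconstrained(start, duration, tb_min)
            sse0 = objective(x0)
            fatol = max(config.rel_sse_tol * max(sse0, 1.0), 1e-300)
            x, fval, nfev, success = x0, sse0, 0, False
            for _ in range(max(config.n_restarts, 1)):
                res = minimize(objective, x, method="Nelder-Mead",
                               options=dict(xatol=config.param_tol, fatol=fatol,
                                            maxfev=config.max_evals,
                                            adaptive=False))
                nfev += res.nfev
                improved = res.fun < fval - fatol
                if res.fun <= fval:
                    x, fval = res.x, res.fun
                success = bool(res.success)
                if success and not improved:
                    break
            return x, min(fval, sse0), sse0, nfev, success

        n_evals, best = 0, None
        for start in candidates:
            x, fval, sse0, nfev, success = run_simplex(start)
            n_evals += nfev
            if best is None or fval < best[1]:
                best = (x, fval, sse0, success, start)
        x, fval, sse0, success, seed = best

        params = _from_unconstrained(x, duration, tb_min)
        sse = fval
        if sse0 < fval:  # never return worse than the seed
            params, sse = seed, sse0
        flags = []
        if rod_asymptote(params) < np.min(y) - 3.0 or -params.Rr < 1e-7:
            # late plateau never expressed in the data: asymptote not identified
            flags.append("rod_asymptote_unidentified")
        if params.Ic * math.exp(params.Rc * params.tb) > 0.1:
            # cone branch still descending at the break: Bc weakly identified
            flags.append("cone_asymptote_unidentified")
        flags = tuple(flags)
        return DarkAdaptationResults(self, params, sse=float(sse), converged=success,
                                     n_evals=n_evals, seed_params=seed, flags=flags)


class DarkAdaptationResults:
    """Fit of the two-stage decay to one response sequence.

    Attributes
    ----------
    params : DAParams
        Fitted parameters.
    sse : float
        Residual sum of squares, (log10 cd/m^2)^2.
    n_points : int
        Number of fitted points.
    converged : bool
    n_evals : int
        Total objective evaluations used.
    seed_params : DAParams
        Simplex starting point.
    """

    def __init__(self, model: DarkAdaptationModel, params: DAParams, *, sse: float,
                 converged: bool, n_evals: int, seed_params: DAParams,
                 flags: tuple = ()):
        self.model = model
        self.params = params
        self.sse = sse
        self.n_points = model.nobs
        self.converged = converged
        self.n_evals = n_evals
        self.seed_params = seed_params
        self.flags = flags

    @property
    def rod_asymptote(self) -> float:
        return rod_asymptote(self.params)

    @property
    def rmse(self) -> float:
        return math.sqrt(self.sse / self.n_points)

    def predict(self, t) -> np.ndarray:
        return eval_model(self.params, t)

    def resid(self) -> np.ndarray:
        return self.model.intensities - eval_model(self.params, self.model.times)

    def summary(self) -> str:
        p = self.params
        lines = [
            "Two-stage dark-adaptation fit",
            "=" * 46,
            f"channel:        {self.model.channel or '-'}",
            f"n points:       {self.n_points}",
            f"converged:      {self.converged}   (n_evals={self.n_evals})",
            f"SSE:            {self.sse:.6g}   RMSE: {self.rmse:.4f} log cd/m^2",
            "-" * 46,
            f"cone asymptote Bc:  {p.Bc:10.4f} log cd/m^2",
            f"cone magnitude Ic:  {p.Ic:10.4f} log cd/m^2",
            f"cone rate Rc:       {p.Rc:10.6f} /s",
            f"rod magnitude Ir:   {p.Ir:10.4f} log cd/m^2",
            f"rod rate Rr:        {p.Rr:10.6f} /s",
            f"break time tb:      {p.tb:10.1f} s  ({p.tb / 60:.2f} min)",
            f"rod asymptote:      {self.rod_asymptote:10.4f} log cd/m^2",
        ]
        if self.flags:
            lines.append(f"flags: {', '.join(self.flags)}")
        return "\n".join(lines)

    def plot(self, ax=None):
        """Plot fitted curve over the fit points (threshold vs minutes)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        color = {"red625": "tab:red", "green527": "tab:green"}.get(self.model.channel, "tab:blue")
        tt = np.linspace(0, self.model.test_duration, 400)
        ax.plot(self.model.times / 60, self.model.intensities, ".", ms=4, color=color, alpha=0.5)
        ax.plot(tt / 60, self.predict(tt), "-", color=color)
        ax.axvline(self.params.tb / 60, ls="--", color="k", lw=0.8)
        ax.set_xlabel("time after bleach offset (min)")
        ax.set_ylabel("threshold (log cd/m$^2$)")
        return ax


# ---------------------------------------------------------------------------
# spec-surface wrappers

#: Alias: a fit result in the flat record sense.
FitResult = DarkAdaptationResults


def fit_sequence(seq: ResponseSequence, config: Optional[FitConfig] = None) -> FitResult:
    """Fit one channel's response sequence (see :meth:`DarkAdaptationModel.fit`)."""
    config = config or FitConfig()
    model = DarkAdaptationModel.from_sequence(seq, mode=config.mode,
                                              min_points=config.min_points)
    return model.fit(config=config)


@dataclass(frozen=True)
class ParticipantFit:
    """Both channel fits of one participant plus the derived outcomes.

    ``excluded`` marks participants whose data could not be fitted (e.g. a
    channel with too few usable responses); the reason is kept explicit, as
    exclusions must never be silent.  Iterates as ``(red, green, outcome)``.
    """

    red: Optional[FitResult]
    green: Optional[FitResult]
    outcome: Optional[DAOutcome]
    excluded: bool = False
    reason: Optional[str] = None

    def __iter__(self):
        return iter((self.red, self.green, self.outcome))


def fit_participant(red: ResponseSequence, green: ResponseSequence,
                    config: Optional[FitConfig] = None) -> ParticipantFit:
    """Fit the red and green sequences independently and derive the outcomes."""
    config = config or FitConfig()
    try:
        red_fit = fit_sequence(red, config)
        green_fit = fit_sequence(green, config)
    except InsufficientDataError as err:
        return ParticipantFit(None, None, None, excluded=True,
                              reason=f"insufficient_data: {err}")
    outcome = derive_outcomes(red_fit.params, green_fit.params,
                              trcb_channel=config.trcb_channel,
                              rod_threshold_mode=config.rod_threshold_mode,
                              test_duration=config.test_duration)
    return ParticipantFit(red_fit, green_fit, outcome)
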