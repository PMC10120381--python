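"""Synthetic dark-adaptometry data with the statistical structure the
analysis assumes.

Two generators:

* :func:`simulate_staircase` -- a simulated observer whose true momentary
  sensitivity follows the two-stage decay responds, via a logistic
  psychometric function with lapses and guesses, to a 6 dB-down / 2 dB-up
  adaptive staircase alternating 625 nm and 527 nm stimuli.  The transformed
  up/down rule converges on the intensity detected with probability
  p* = step_up / (step_up + step_down) = 0.25.
* :func:`generate_cohort` -- per-participant true curve parameters drawn so
  that group-level distributions of cone threshold, rod threshold and TRCB
  match configured means/SDs, with thresholds tied linearly to foveal outer
  retinal thickness and age via configurable slopes (defaults follow the
  published group summaries and regression slopes for the aniridia and
  control groups).

Everything is a pure function of (config, seed): the same inputs always give
byte-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd

from .model import DAParams, DAOutcome, eval_model
from .fitting import ResponseSequence

__all__ = [
    "StaircaseProtocol",
    "ObserverModel",
    "GroupConfig",
    "CohortConfig",
    "simulate_staircase",
    "make_observer",
    "generate_cohort",
    "cohort_to_staircases",
    "TRUE_PARAM_COLUMNS",
]


@dataclass(frozen=True)
class StaircaseProtocol:
    """The simulated dark adaptometer.

    A 5-min 7000 cd/m^2 bleach is followed by a 35-min test in which 2-deg
    stimuli at 625 and 527 nm, ~20 deg temporal, alternate every
    ``trial_period`` seconds.  After a detection the stimulus is dimmed by
    ``step_down`` dB, otherwise brightened by ``step_up`` dB, with
    ``db_per_log`` dB per log10 unit (so 6 dB = 0.6 and 2 dB = 0.2 log
    units).  Intensities are clamped to the instrument dynamic range.
    """

    bleach_luminance: float = 7000.0   # cd/m^2
    bleach_duration: float = 300.0     # s
    test_duration: float = 2100.0      # s
    wavelengths: Tuple[int, int] = (625, 527)
    stimulus_diameter: float = 2.0     # deg
    eccentricity: float = 20.0         # deg temporal
    step_down: float = 6.0             # dB
    step_up: float = 2.0               # dB
    db_per_log: float = 10.0           # dB per log10 unit
    trial_period: float = 2.0          # s per presentation, channels alternate
    start_intensity: float = 1.0       # log10 cd/m^2
    intensity_floor: float = -6.0      # log10 cd/m^2
    intensity_ceiling: float = 2.0     # log10 cd/m^2
    protocol_id: str = "default"

    def __post_init__(self):
        if not (self.step_down > self.step_up > 0):
            raise ValueError("require step_down > step_up > 0")
        if self.test_duration <= 0:
            raise ValueError("test_duration must be positive")
        if self.intensity_floor >= self.intensity_ceiling:
            raise ValueError("intensity floor must lie below ceiling")

    @property
    def step_down_log(self) -> float:
        return self.step_down / self.db_per_log

    @property
    def step_up_log(self) -> float:
        return self.step_up / self.db_per_log

    @property
    def equilibrium_p(self) -> float:
        """Detection probability at which the expected staircase step is zero."""
        return self.step_up / (self.step_up + self.step_down)


@dataclass(frozen=True)
class ObserverModel:
    """A simulated psychophysical subject.

    Detection of a stimulus of intensity ``I`` at time ``t`` is Bernoulli
    with probability

        p = guess + (1 - guess - lapse) / (1 + exp(-slope * (I - y(t))))

    where ``y(t)`` is the observer's true momentary threshold from the
    channel's two-stage curve.
    """

    true_red: DAParams
    true_green: DAParams
    slope: float = 10.0        # psychometric steepness per log10 unit
    lapse_rate: float = 0.02
    guess_rate: float = 0.0
    rng_seed: int = 0

    def __post_init__(self):
        if not (0 <= self.lapse_rate <= 0.1 and 0 <= self.guess_rate <= 0.1):
            raise ValueError("lapse/guess rates must lie in [0, 0.1]")
        if self.slope <= 0:
            raise ValueError("psychometric slope must be positive")

    def p_detect(self, channel: str, intensity: float, t: float) -> float:
        true = self.true_red if channel == "red625" else self.true_green
        y = eval_model(true, t)
        x = self.slope * (intensity - y)
        if x > 700:
            f = 1.0
        elif x < -700:
            f = 0.0
        else:
            f = 1.0 / (1.0 + math.exp(-x))
        return self.guess_rate + (1.0 - self.guess_rate - self.lapse_rate) * f

    def true_outcome(self) -> DAOutcome:
        from .model import derive_outcomes
        return derive_outcomes(self.true_red, self.true_green)


def simulate_staircase(observer: ObserverModel,
                       protocol: StaircaseProtocol = StaircaseProtocol(),
                       ) -> Tuple[ResponseSequence, ResponseSequence]:
    """Run one full dark-adaptation test on a simulated observer.

    Presentations alternate red/green every ``trial_period`` seconds (red
    first); each channel keeps its own running intensity, dimmed by the down
    step on detection and brightened by the up step otherwise.  Returns the
    (red, green) response sequences, reproducible from ``observer.rng_seed``.
    """
    rng = np.random.default_rng(observer.rng_seed)
    down, up = protocol.step_down_log, protocol.step_up_log
    lo, hi = protocol.intensity_floor, protocol.intensity_ceiling

    level = {"red625": protocol.start_intensity, "green527": protocol.start_intensity}
    logs: Dict[str, list] = {"red625": [], "green527": []}

    n_trials = int(protocol.test_duration // protocol.trial_period)
    for i in range(n_trials):
        t = (i + 1) * protocol.trial_period
        if t > protocol.test_duration:
            break
        channel = "red625" if i % 2 == 0 else "green527"
        intensity = level[channel]
        seen = rng.random() < observer.p_detect(channel, intensity, t)
        logs[channel].append((t, intensity, seen))
        level[channel] = min(max(intensity + (-down if seen else up), lo), hi)

    out = []
    for channel in ("red625", "green527"):
        rows = logs[channel]
        out.append(ResponseSequence(
            channel=channel,
            times=np.array([r[0] for r in rows]),
            intensities=np.array([r[1] for r in rows]),
            detected=np.array([r[2] for r in rows]),
            protocol_id=protocol.protocol_id,
            test_duration=protocol.test_duration,
        ))
    return out[0], out[1]


# ---------------------------------------------------------------------------
# cohort generation


@dataclass(frozen=True)
class GroupConfig:
    """Generative targets for one cohort group.

    Outcome means/SDs are on the reported clinical scales (log10 cd/m^2,
    minutes).  Thresholds are generated as linear functions of centred
    foveal outer retinal thickness and age,

        cone = cone_mean + b_ct*(th - th_mean) + b_ca*(age - age_mean) + e,

    with the residual SD chosen so the total SD hits ``cone_sd`` (and
    likewise for the rod threshold).  A slope/SD combination whose explained
    variance exceeds the requested total variance is rejected.
    """

    cone_mean: float
    cone_sd: float
    rod_mean: float
    rod_sd: float
    trcb_mean_min: float
    trcb_sd_min: float
    age_mean: float
    age_sd: float
    thickness_mean: float          # central outer retinal layer, um
    thickness_sd: float
    beta_cone_thickness: float = 0.0   # log cd/m^2 per um
    beta_cone_age: float = 0.0         # log cd/m^2 per year
    beta_rod_thickness: float = 0.0
    beta_rod_age: float = 0.0
    beta_trcb_age: float = 0.06        # min per year; TRCB lengthens with age
    perifoveal_total_mean: float = 310.0
    perifoveal_total_sd: float = 18.0
    perifoveal_outer_mean: float = 185.0
    perifoveal_outer_sd: float = 10.0
    aak_probs: Tuple[float, ...] = (1.0, 0.0, 0.0, 0.0)
    foveal_hypoplasia_probs: Tuple[float, ...] = (1.0, 0.0, 0.0, 0.0, 0.0)
    lens_status_probs: Tuple[float, float, float] = (1.0, 0.0, 0.0)  # phakic/aphakic/pseudophakic
    axial_length_mean: float = 23.5
    axial_length_sd: float = 1.0


#: Aniridia group: outcome means/SDs and regression slopes follow the
#: published cohort; thickness distribution reflects foveal hypoplasia.
ANIRIDIA_DEFAULTS = GroupConfig(
    cone_mean=-0.84, cone_sd=0.66,
    rod_mean=-3.50, rod_sd=0.76,
    trcb_mean_min=11.6, trcb_sd_min=2.3,
    age_mean=33.8, age_sd=16.5,
    thickness_mean=145.0, thickness_sd=25.0,
    beta_cone_thickness=-0.011, beta_cone_age=0.015,
    beta_rod_thickness=-0.014, beta_rod_age=0.019,
    perifoveal_total_mean=295.0, perifoveal_total_sd=20.0,
    perifoveal_outer_mean=175.0, perifoveal_outer_sd=12.0,
    aak_probs=(0.15, 0.23, 0.43, 0.19),
    foveal_hypoplasia_probs=(0.05, 0.15, 0.25, 0.30, 0.25),
    lens_status_probs=(0.54, 0.12, 0.34),
)

#: Healthy controls: published outcome distributions; thresholds are not
#: tied to foveal thickness (no structural deficit), only TRCB ages.
CONTROL_DEFAULTS = GroupConfig(
    cone_mean=-1.56, cone_sd=0.36,
    rod_mean=-4.23, rod_sd=0.34,
    trcb_mean_min=11.4, trcb_sd_min=2.5,
    age_mean=32.8, age_sd=18.6,
    thickness_mean=180.0, thickness_sd=12.0,
)


@dataclass(frozen=True)
class CohortConfig:
    """Cohort-level generation settings: per-group targets plus the shape
    parameters of the underlying true curves."""

    aniridia: GroupConfig = ANIRIDIA_DEFAULTS
    control: GroupConfig = CONTROL_DEFAULTS
    cone_magnitude: float = 2.2        # Ic of the true curves
    cone_rate: float = -0.012          # Rc, 1/s
    rod_rate: float = -0.0045          # Rr, 1/s
    red_rod_drop: float = 0.4          # red-channel rod stage depth, log units
    min_rod_cone_gap: float = 0.5      # enforce rod threshold < cone threshold
    trcb_min_minutes: float = 5.0
    trcb_max_minutes: float = 21.0


TRUE_PARAM_COLUMNS = [f"true_{ch}_{p}" for ch in ("red", "green")
                      for p in ("Bc", "Ic", "Rc", "Ir", "Rr", "tb")]


def _residual_sd(total_sd: float, *components: float) -> float:
    explained = sum(c * c for c in components)
    resid_var = total_sd ** 2 - explained
    if resid_var <= 0:
        raise ValueError(
            f"infeasible variance decomposition: explained SD "
            f"{math.sqrt(explained):.3f} >= total SD {total_sd:.3f}")
    return math.sqrt(resid_var)


def true_params_from_outcome(cone: float, rod: float, trcb_min: float,
                             cfg: CohortConfig = CohortConfig()
                             ) -> Tuple[DAParams, DAParams]:
    """Construct (red, green) true curves realising the three outcomes.

    The green curve gets ``Bc = cone`` and a rod magnitude solved so its rod
    asymptote equals ``rod``; the red curve's rod stage descends only
    ``red_rod_drop`` below the cone plateau (rods contribute little at
    625 nm).  Shared shape parameters (Ic, Rc, Rr) come from ``cfg``.
    """
    tb = trcb_min * 60.0
    Ic, Rc, Rr = cfg.cone_magnitude, cfg.cone_rate, cfg.rod_rate
    if rod > cone - cfg.min_rod_cone_gap:
        rod = cone - cfg.min_rod_cone_gap
    level_at_tb = cone + Ic * math.exp(Rc * tb)

    def solve_ir(asym):
        return (level_at_tb - asym) / math.exp(Rr * tb)

    green = DAParams(Bc=cone, Ic=Ic, Rc=Rc, Ir=solve_ir(rod), Rr=Rr, tb=tb)
    red = DAParams(Bc=cone, Ic=Ic, Rc=Rc,
                   Ir=solve_ir(cone - cfg.red_rod_drop), Rr=Rr, tb=tb)
    return red, green


def _generate_group(group: str, n: int, gcfg: GroupConfig, cfg: CohortConfig,
                    rng: np.random.Generator, id_offset: int) -> pd.DataFrame:
    sd_cone_resid = _residual_sd(gcfg.cone_sd,
                                 gcfg.beta_cone_thickness * gcfg.thickness_sd,
                                 gcfg.beta_cone_age * gcfg.age_sd)
    sd_rod_resid = _residual_sd(gcfg.rod_sd,
                                gcfg.beta_rod_thickness * gcfg.thickness_sd,
                                gcfg.beta_rod_age * gcfg.age_sd)
    sd_trcb_resid = _residual_sd(gcfg.trcb_sd_min, gcfg.beta_trcb_age * gcfg.age_sd)

    age = rng.normal(gcfg.age_mean, gcfg.age_sd, n)
    thickness = np.clip(rng.normal(gcfg.thickness_mean, gcfg.thickness_sd, n), 40.0, None)
    d_age, d_th = age - gcfg.age_mean, thickness - gcfg.thickness_mean

    cone = (gcfg.cone_mean + gcfg.beta_cone_thickness * d_th
            + gcfg.beta_cone_age * d_age + rng.normal(0.0, sd_cone_resid, n))
    rod = (gcfg.rod_mean + gcfg.beta_rod_thickness * d_th
           + gcfg.beta_rod_age * d_age + rng.normal(0.0, sd_rod_resid, n))
    trcb = np.clip(gcfg.trcb_mean_min + gcfg.beta_trcb_age * d_age
                   + rng.normal(0.0, sd_trcb_resid, n),
                   cfg.trcb_min_minutes, cfg.trcb_max_minutes)

    sex = rng.choice(["M", "F"], n)
    aak = rng.choice(len(gcfg.aak_probs), n, p=np.asarray(gcfg.aak_probs))
    fh = rng.choice(len(gcfg.foveal_hypoplasia_probs), n,
                    p=np.asarray(gcfg.foveal_hypoplasia_probs))
    lens_status = rng.choice(["phakic", "aphakic", "pseudophakic"], n,
                             p=np.asarray(gcfg.lens_status_probs))
    lens_opacity = np.where(lens_status == "phakic",
                            np.round(np.clip(rng.gamma(2.0, 1.0, n), 0, 10), 1), 0.0)
    axial = rng.normal(gcfg.axial_length_mean, gcfg.axial_length_sd, n)
    peri_total = rng.normal(gcfg.perifoveal_total_mean, gcfg.perifoveal_total_sd, n)
    peri_outer = rng.normal(gcfg.perifoveal_outer_mean, gcfg.perifoveal_outer_sd, n)

    rows = []
    for i in range(n):
        red, green = true_params_from_outcome(cone[i], rod[i], trcb[i], cfg)
        rows.append([*red.as_array(), *green.as_array()])
    true_block = pd.DataFrame(rows, columns=TRUE_PARAM_COLUMNS)

    df = pd.DataFrame({
        "id": [f"{group[:3].upper()}{id_offset + i + 1:04d}" for i in range(n)],
        "group": group,
        "age": np.round(age, 1),
        "sex": sex,
        "aak_grade": aak,
        "lens_opacity_sum": lens_opacity,
        "lens_status": lens_status,
        "axial_length": np.round(axial, 2),
        "foveal_hypoplasia_grade": fh,
        "central_outer_retinal_thickness": np.round(thickness, 1),
        "perifoveal_total_thickness": np.round(peri_total, 1),
        "perifoveal_outer_thickness": np.round(peri_outer, 1),
        "cone_threshold": cone,
        "rod_threshold": rod,
        "trcb_minutes": trcb,
    })
    return pd.concat([df, true_block], axis=1)


def generate_cohort(n_aniridia: int, n_control: int,
                    gen_config: Optional[CohortConfig] = None,
                    rng_seed: int = 0) -> pd.DataFrame:
    """Generate a cohort table of aniridia patients and healthy controls.

    Each row carries covariates, the generative ("true") outcome values and
    the true curve parameters of both channels, so the cohort can be pushed
    through the staircase simulator and refitted end to end.  Deterministic
    under ``rng_seed``.
    """
    if n_aniridia < 2 or n_control < 2:
        raise ValueError("need at least two participants per group")
    cfg = gen_config or CohortConfig()
    rng = np.random.default_rng(rng_seed)
    a = _generate_group("aniridia", n_aniridia, cfg.aniridia, cfg, rng, 0)
    c = _generate_group("control", n_control, cfg.control, cfg, rng, n_aniridia)
    return pd.concat([a, c], ignore_index=True)


def observer_from_row(row, slope: float = 10.0, lapse_rate: float = 0.02,
                      guess_rate: float = 0.0, rng_seed: int = 0) -> ObserverModel:
    """Build the simulated observer encoded in one cohort-table row."""
    red = DAParams(*[float(row[f"true_red_{p}"]) for p in ("Bc", "Ic", "Rc", "Ir", "Rr", "tb")])
    green = DAParams(*[float(row[f"true_green_{p}"]) for p in ("Bc", "Ic", "Rc", "Ir", "Rr", "tb")])
    return ObserverModel(true_red=red, true_green=green, slope=slope,
                         lapse_rate=lapse_rate, guess_rate=guess_rate,
                         rng_seed=rng_seed)


def make_observer(cone: float, rod: float, trcb_min: float,
                  cfg: CohortConfig = CohortConfig(), *, slope: float = 10.0,
                  lapse_rate: float = 0.02, guess_rate: float = 0.0,
                  rng_seed: int = 0) -> ObserverModel:
    """Observer whose true outcomes are exactly (cone, rod, trcb_min)."""
    red, green = true_params_from_outcome(cone, rod, trcb_min, cfg)
    return ObserverModel(true_red=red, true_green=green, slope=slope,
                         lapse_rate=lapse_rate, guess_rate=guess_rate,
                         rng_seed=rng_seed)


def cohort_to_staircases(cohort: pd.DataFrame,
                         protocol: StaircaseProtocol = StaircaseProtocol(),
                         rng_seed: int = 0, *, slope: float = 10.0,
                         lapse_rate: float = 0.02, guess_rate: float = 0.0,
                         ) -> Dict[str, Tuple[ResponseSequence, ResponseSequence]]:
    """Simulate one red+green trial log per cohort participant.

    Per-participant RNG seeds are spawned deterministically from
    ``rng_seed``, so the whole mapping is reproducible.
    """
    missing = [c for c in TRUE_PARAM_COLUMNS if c not in cohort.columns]
    if missing:
        raise ValueError(f"cohort table lacks true-parameter columns: {missing[:3]}...")
    ss = np.random.SeedSequence(rng_seed)
    children = ss.spawn(len(cohort))
    out = {}
    for (_, row), child in zip(cohort.iterrows(), children):
        seed = int(child.generate_state(1)[0] % (2 ** 31))
        obs = observer_from_row(row, slope=slope, lapse_rate=lapse_rate,
                                guess_rate=guess_rate, rng_seed=seed)
        out[str(row["id"])] = simulate_staircase(obs, protocol)
    return out
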