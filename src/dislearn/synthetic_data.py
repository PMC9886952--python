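"""Synthetic additional-singleton search experiments.

Generates trial schedules for the distractor-location learning design --
8 display locations on a circle, 50% distractor-present trials, two thirds
of present trials at one fixed high-probability (HP) location, 1 practice +
7 experimental blocks of 48 trials -- and simulates reaction times from the
same generative equations the analysis models fit:

* a power-law learning curve per distractor condition,
  ``mu = a + (s - a) * (x + 1) ** -c`` with block index ``x``;
* an exponential spatial suppression gradient,
  ``mu = (1 - exp(-r * x)) * (m - d) + d`` with distance ``x`` in cm.

Every downstream stage of the package is therefore testable without any
external download.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "DesignConfig",
    "TaskCurveParams",
    "SuppressionCurve",
    "GeneratingParams",
    "chord_distance",
    "angular_separation",
    "generate_design",
    "simulate_rts",
    "simulate_experiment",
    "write_trials",
    "read_trials",
    "TRIAL_COLUMNS",
]

logger = logging.getLogger(__name__)

#: Canonical trial-table column order (also the CSV header).
TRIAL_COLUMNS = [
    "participant_id",
    "task",
    "block",
    "trial",
    "condition",
    "distractor_location",
    "target_location",
    "distance_to_hp",
    "rt",
    "correct",
]

#: Distractor-to-HP distances (cm) by angular separation (degrees) as used
#: in the analysis.  These differ in the second decimal from the exact chord
#: lengths at radius 5.6 cm (see :func:`chord_distance`); both are kept and
#: neither is "corrected".
DEFAULT_DISTANCE_TABLE: Mapping[int, float] = {
    45: 4.25,
    90: 7.85,
    135: 10.30,
    180: 11.20,
}


@dataclass(frozen=True)
class DesignConfig:
    """Experiment-design constants.

    Defaults reproduce the study design: 8 locations on a radius-5.6 cm
    circle, 8 blocks (1 practice + 7 experimental) of 48 trials, distractor
    present on 50% of trials, 2/3 of those at the HP location, and a
    1200 ms response deadline.
    """

    n_locations: int = 8
    radius: float = 5.6
    n_blocks: int = 8
    trials_per_block: int = 48
    p_distractor_present: float = 0.5
    p_high_given_present: float = 2.0 / 3.0
    rt_deadline: float = 1200.0
    distance_table: Mapping[int, float] = field(
        default_factory=lambda: dict(DEFAULT_DISTANCE_TABLE)
    )
    tasks: tuple[str, ...] = ("fixed", "mixed")
    n_participants_per_task: int = 30

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_distractor_present <= 1.0):
            raise ValueError("p_distractor_present must be in [0, 1]")
        if not (0.0 <= self.p_high_given_present <= 1.0):
            raise ValueError("p_high_given_present must be in [0, 1]")
        if self.n_locations < 2 or self.radius <= 0:
            raise ValueError("need >= 2 locations on a positive radius")
        for task in self.tasks:
            if task not in ("fixed", "mixed"):
                raise ValueError(f"unknown task {task!r}")

    @property
    def n_present(self) -> int:
        n = self.trials_per_block * self.p_distractor_present
        if abs(n - round(n)) > 1e-9:
            raise ValueError(
                "trials_per_block * p_distractor_present must be an integer, "
                f"got {n}"
            )
        return round(n)

    @property
    def n_high(self) -> int:
        n = self.n_present * self.p_high_given_present
        if abs(n - round(n)) > 1e-9:
            raise ValueError(
                "present-trial count * p_high_given_present must be an "
                f"integer, got {n}"
            )
        return round(n)

    @property
    def n_low(self) -> int:
        return self.n_present - self.n_high

    @property
    def n_absent(self) -> int:
        return self.trials_per_block - self.n_present

    def separation_degrees(self, loc_a: int, loc_b: int) -> float:
        return angular_separation(loc_a, loc_b, self.n_locations)

    def distance(self, loc_a: int, loc_b: int) -> float:
        """Distance between two locations per the analysis distance table."""
        sep = round(self.separation_degrees(loc_a, loc_b))
        if sep == 0:
            return 0.0
        return float(self.distance_table[sep])


def _check_location(loc: int, n_locations: int) -> int:
    loc = int(loc)
    if not (0 <= loc < n_locations):
        raise ValueError(f"location index {loc} outside 0..{n_locations - 1}")
    return loc


def angular_separation(loc_a: int, loc_b: int, n_locations: int = 8) -> float:
    """Minimal angular separation between two display locations, degrees."""
    loc_a = _check_location(loc_a, n_locations)
    loc_b = _check_location(loc_b, n_locations)
    step = 360.0 / n_locations
    d = abs(loc_a - loc_b) % n_locations
    return step * min(d, n_locations - d)


def chord_distance(loc_a: int, loc_b: int, radius: float = 5.6,
                   n_locations: int = 8) -> float:
    """Euclidean chord length between two locations on the display circle.

    ``2 * radius * sin(dtheta / 2)`` with ``dtheta`` the minimal angular
    separation.  At 180 deg this is exactly the diameter (11.20 cm for the
    default radius).
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    dtheta = np.deg2rad(angular_separation(loc_a, loc_b, n_locations))
    return float(2.0 * radius * np.sin(dtheta / 2.0))


# ---------------------------------------------------------------------------
# Generating parameters


@dataclass(frozen=True)
class TaskCurveParams:
    """Learning-curve generating values for one task.

    ``s`` is the RT level at an imaginary block 0 (shared between the high-
    and low-probability distractor conditions, separate for the absent
    baseline), ``a`` the asymptotic level and ``c`` the decrease rate.
    """

    s_absent: float
    s_present: float
    a_absent: float
    a_high: float
    a_low: float
    c_absent: float
    c_high: float
    c_low: float

    def __post_init__(self) -> None:
        for name in ("s_absent", "s_present", "a_absent", "a_high", "a_low"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive (ms)")
        for name in ("c_absent", "c_high", "c_low"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def s(self, condition: str) -> float:
        return self.s_absent if condition == "absent" else self.s_present

    def a(self, condition: str) -> float:
        return getattr(self, f"a_{condition}")

    def c(self, condition: str) -> float:
        return getattr(self, f"c_{condition}")


@dataclass(frozen=True)
class SuppressionCurve:
    """Spatial suppression gradient generating values (r in 1/cm, m, d in ms)."""

    r: float = 0.11
    m: float = 64.0
    d: float = 13.0

    def __post_init__(self) -> None:
        if self.r < 0:
            raise ValueError("gradient r must be non-negative")
        if self.d > self.m:
            raise ValueError("residual capture d cannot exceed maximum capture m")


def _default_curves() -> dict[str, TaskCurveParams]:
    # Asymptotic costs and decrease-rate differences follow the group-level
    # estimates of the study (DI 40/68 ms, high-probability cost 12 ms,
    # rate differences 0.16/0.13 and 0.4/0.11); absolute levels are chosen
    # to match the reported between-task differences (320 ms in s, 76 ms in
    # the absent asymptote).  See docs/methods.md.
    return {
        "fixed": TaskCurveParams(
            s_absent=720.0, s_present=760.0,
            a_absent=600.0, a_high=612.0, a_low=640.0,
            c_absent=1.0, c_high=1.13, c_low=1.16,
        ),
        "mixed": TaskCurveParams(
            s_absent=1040.0, s_present=1080.0,
            a_absent=676.0, a_high=688.0, a_low=744.0,
            c_absent=1.0, c_high=1.11, c_low=1.4,
        ),
    }


@dataclass(frozen=True)
class GeneratingParams:
    """Full generative parameter set for RT simulation.

    ``participant_sd_scale`` scales all between-participant spreads (50 ms
    reference scale on the ms-valued parameters; proportionally smaller
    spreads on rates); ``correlation_strength`` is the common pairwise
    correlation of the standardized participant-level offsets (an
    exchangeable correlation matrix), emulating a dominant general-speed
    factor.
    """

    curves: Mapping[str, TaskCurveParams] = field(default_factory=_default_curves)
    suppression: Mapping[str, SuppressionCurve] = field(
        default_factory=lambda: {"fixed": SuppressionCurve(),
                                 "mixed": SuppressionCurve()}
    )
    participant_sd_scale: float = 50.0
    #: Gaussian trial noise; 100 ms corresponds to a coefficient of
    #: variation of ~0.15 at the ~700 ms mean RTs of this paradigm, the
    #: standard figure for speeded visual search, and yields group-level
    #: posterior precision comparable to the published fits.
    trial_sd: float = 100.0
    accuracy: float = 0.95
    correlation_strength: float = 0.8
    p_no_response: float = 0.01

    def __post_init__(self) -> None:
        if self.participant_sd_scale < 0 or self.trial_sd < 0:
            raise ValueError("spread parameters must be non-negative")
        if not (0.0 <= self.correlation_strength <= 1.0):
            raise ValueError("correlation_strength must be in [0, 1]")
        if not (0.0 <= self.accuracy <= 1.0):
            raise ValueError("accuracy must be a probability")
        if not (0.0 <= self.p_no_response <= 1.0):
            raise ValueError("p_no_response must be a probability")

    def with_zero_heterogeneity(self) -> "GeneratingParams":
        return replace(self, participant_sd_scale=0.0, trial_sd=0.0,
                       accuracy=1.0, p_no_response=0.0)


# ---------------------------------------------------------------------------
# Design generation


def generate_design(config: DesignConfig | None = None, seed: int = 0) -> pd.DataFrame:
    """Generate a full trial schedule (rt/correct unset).

    Per participant one HP location is drawn uniformly and kept for all
    blocks.  Every block realizes the design proportions exactly: with the
    default 48 trials, 24 absent / 16 high / 8 low in shuffled order.
    Low-probability distractor locations are uniform over the 7 non-HP
    locations; the target is uniform over the locations not occupied by the
    distractor (all locations in absent trials).
    """
    config = config or DesignConfig()
    rng = np.random.default_rng(seed)
    n_abs, n_high, n_low = config.n_absent, config.n_high, config.n_low

    rows: list[tuple] = []
    for task in config.tasks:
        for p in range(config.n_participants_per_task):
            pid = f"{task}{p + 1:02d}"
            hp = int(rng.integers(config.n_locations))
            non_hp = [loc for loc in range(config.n_locations) if loc != hp]
            for block in range(1, config.n_blocks + 1):
                conditions = np.array(
                    ["absent"] * n_abs + ["high"] * n_high + ["low"] * n_low
                )
                rng.shuffle(conditions)
                for trial, cond in enumerate(conditions, start=1):
                    if cond == "absent":
                        dloc = None
                        tloc = int(rng.integers(config.n_locations))
                    elif cond == "high":
                        dloc = hp
                        tloc = non_hp[int(rng.integers(config.n_locations - 1))]
                    else:
                        dloc = non_hp[int(rng.integers(config.n_locations - 1))]
                        others = [loc for loc in range(config.n_locations)
                                  if loc != dloc]
                        tloc = others[int(rng.integers(config.n_locations - 1))]
                    ref = tloc if dloc is None else dloc
                    dist = config.distance(ref, hp)
                    rows.append((pid, task, block, trial, cond,
                                 np.nan if dloc is None else float(dloc),
                                 tloc, dist, np.nan, False))

    df = pd.DataFrame(rows, columns=TRIAL_COLUMNS)
    df["block"] = df["block"].astype(np.int64)
    df["trial"] = df["trial"].astype(np.int64)
    df["target_location"] = df["target_location"].astype(np.int64)
    return df


# ---------------------------------------------------------------------------
# RT simulation

# Participant-level offset scales at the 50 ms reference scale; scaled by
# participant_sd_scale / 50 so that a zero scale removes all heterogeneity.
_REFERENCE_SCALE = 50.0
_LOGC_SD = 0.15        # sd of participant log decrease-rate offsets
_R_SD = 0.02           # 1/cm, spatial gradient
_M_SD = 15.0           # ms, maximum capture
_D_SD = 8.0            # ms, residual capture
_LOGSD_SD = 0.15       # sd of participant log trial-noise offsets

_CURVE_NAMES = ["s_absent", "s_present", "a_absent", "a_high", "a_low",
                "logc_absent", "logc_high", "logc_low"]
_SPATIAL_NAMES = ["r", "m", "d"]


def _exchangeable_chol(k: int, rho: float) -> np.ndarray:
    corr = np.full((k, k), rho)
    np.fill_diagonal(corr, 1.0)
    return np.linalg.cholesky(corr)


def _draw_participant_params(task_curves: TaskCurveParams,
                             supp: SuppressionCurve,
                             params: GeneratingParams,
                             rng: np.random.Generator) -> dict[str, float]:
    """Draw one participant's generative parameters around the group values.

    All standardized offsets share an exchangeable correlation matrix with
    pairwise correlation ``correlation_strength``.  Draws implying
    non-positive time scales, non-positive rates or a negative gradient are
    redrawn (truncation) and logged.
    """
    factor = params.participant_sd_scale / _REFERENCE_SCALE
    means = np.array([
        task_curves.s_absent, task_curves.s_present,
        task_curves.a_absent, task_curves.a_high, task_curves.a_low,
        np.log(task_curves.c_absent), np.log(task_curves.c_high),
        np.log(task_curves.c_low),
        supp.r, supp.m, supp.d,
    ])
    scales = factor * np.array(
        [_REFERENCE_SCALE] * 5 + [_LOGC_SD] * 3 + [_R_SD, _M_SD, _D_SD]
    )
    names = _CURVE_NAMES + _SPATIAL_NAMES
    chol = _exchangeable_chol(len(names), params.correlation_strength)

    for attempt in range(100):
        z = chol @ rng.standard_normal(len(names))
        values = means + scales * z
        out = dict(zip(names, values))
        ok = (
            min(out["s_absent"], out["s_present"], out["a_absent"],
                out["a_high"], out["a_low"], out["m"]) > 0
            and out["r"] >= 0 and out["d"] >= 0
        )
        if ok:
            if attempt:
                logger.debug("participant parameter redraws: %d", attempt)
            out["sd"] = (
                params.trial_sd
                * float(np.exp(_LOGSD_SD * factor * rng.standard_normal()))
                if params.trial_sd > 0 else 0.0
            )
            return out
    raise RuntimeError("participant parameter redraw limit exceeded")


def _positive_normal(rng: np.random.Generator, mean: np.ndarray,
                     sd: float) -> np.ndarray:
    """Gaussian draws truncated to positive values by resampling."""
    out = rng.normal(mean, sd)
    bad = out <= 0
    for _ in range(100):
        if not np.any(bad):
            return out
        out[bad] = rng.normal(mean[bad], sd)
        bad = out <= 0
    raise RuntimeError("trial RT redraw limit exceeded")


def simulate_rts(schedule: pd.DataFrame, params: GeneratingParams | None = None,
                 mode: str = "condition", seed: int = 0) -> pd.DataFrame:
    """Fill rt/correct on a generated schedule.

    mode="condition": the trial mean follows the learning curve of the
    trial's condition at its block (practice block is x = 1; the start
    level is shared between the high- and low-probability conditions).
    mode="spatial": the trial mean is the participant's absent baseline
    (the asymptote ``a_absent``, block-invariant) plus the suppression-curve
    cost at the trial's distractor distance; zero cost in absent trials.

    Gaussian trial noise is added, correctness is Bernoulli(accuracy) and a
    fraction ``p_no_response`` of trials is marked as no-response (rt NaN).
    """
    if mode not in ("condition", "spatial"):
        raise ValueError(f"unknown mode {mode!r}")
    params = params or GeneratingParams()
    rng = np.random.default_rng(seed)
    out = schedule.copy()
    rt = np.empty(len(out))
    for (pid, task), idx in out.groupby(["participant_id", "task"],
                                        sort=True).groups.items():
        pp = _draw_participant_params(params.curves[task],
                                      params.suppression[task], params, rng)
        sub = out.loc[idx]
        if mode == "condition":
            x = sub["block"].to_numpy(float)
            cond = sub["condition"].to_numpy()
            s = np.where(cond == "absent", pp["s_absent"], pp["s_present"])
            a = np.select([cond == "absent", cond == "high"],
                          [pp["a_absent"], pp["a_high"]], pp["a_low"])
            c = np.exp(np.select([cond == "absent", cond == "high"],
                                 [pp["logc_absent"], pp["logc_high"]],
                                 pp["logc_low"]))
            mu = a + (s - a) * (x + 1.0) ** (-c)
        else:
            present = sub["condition"].to_numpy() != "absent"
            xdist = sub["distance_to_hp"].to_numpy(float)
            cost = (1.0 - np.exp(-pp["r"] * xdist)) * (pp["m"] - pp["d"]) + pp["d"]
            mu = pp["a_absent"] + np.where(present, cost, 0.0)
        if pp["sd"] > 0:
            rt[out.index.get_indexer(idx)] = _positive_normal(rng, mu, pp["sd"])
        else:
            rt[out.index.get_indexer(idx)] = mu
    out["rt"] = rt
    out["correct"] = rng.random(len(out)) < params.accuracy
    no_resp = rng.random(len(out)) < params.p_no_response
    out.loc[no_resp, "rt"] = np.nan
    out.loc[no_resp, "correct"] = False
    return out


def simulate_experiment(config: DesignConfig | None = None,
                        params: GeneratingParams | None = None,
                        mode: str = "condition", seed: int = 0) -> pd.DataFrame:
    """Convenience wrapper: generate a design and simulate its RTs.

    The schedule and the RT draws use independent streams derived from
    ``seed`` so the pair (config, params, seed) reproduces bit-for-bit.
    """
    ss = np.random.SeedSequence(seed)
    s_design, s_rt = (int(c.generate_state(1)[0] % (2 ** 31)) for c in ss.spawn(2))
    schedule = generate_design(config, seed=s_design)
    return simulate_rts(schedule, params, mode=mode, seed=s_rt)


# ---------------------------------------------------------------------------
# Canonical trial-table I/O


def write_trials(trials: pd.DataFrame, path) -> None:
    """Write the canonical trial CSV (missing values as empty fields)."""
    out = trials.loc[:, TRIAL_COLUMNS].copy()
    out["correct"] = out["correct"].astype(bool)
    out.to_csv(path, index=False, na_rep="")


def read_trials(path) -> pd.DataFrame:
    df = pd.read_csv(
        path,
        dtype={"participant_id": str, "task": str, "condition": str},
    )
    missing = set(TRIAL_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"trial table missing columns: {sorted(missing)}")
    df["correct"] = df["correct"].map(
        {True: True, False: False, "True": True, "False": False}
    ).astype(bool)
    return df[TRIAL_COLUMNS]
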