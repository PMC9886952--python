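"""Hierarchical exponential spatial-suppression-gradient model.

Distractor interference is summarized per participant as a delta-RT
(distractor-present minus distractor-absent mean RT) at each distance x of
the distractor from the high-probability (HP) location.  The model assumes
the interference rises exponentially with distance,

    delta_RT_i(x) ~ Normal(mu = (1 - exp(-r_i * x)) * (m_i - d_i) + d_i,
                           sigma = sd_i)

with participant-level gradient r_i (1/cm), maximum capture m_i (ms, where
suppression has faded out) and residual capture d_i (ms, at the HP
location), partially pooled under group-level hyperparameters.  The m and d
hyperparameters are shared across the two tasks; the gradient r gets
task-specific hyperparameters, and the fit reports the between-task
gradient difference.  A suppression map (m minus the curve, radiating from
the HP location) visualizes the fitted gradient.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from . import bayes_core
from .bayes_core import PosteriorSummary, SamplerConfig

__all__ = [
    "SuppressionPriors",
    "SuppressionFit",
    "suppression_mean",
    "compute_delta_rt",
    "fit_suppression",
    "render_map",
    "save_map_figure",
]

logger = logging.getLogger(__name__)


def suppression_mean(r, m, d, x):
    """Mean interference at distance x: (1 - exp(-r x)) (m - d) + d.

    Equals d at x = 0 and tends to m as x grows; monotone non-decreasing in
    x whenever m >= d.
    """
    r, x = np.asarray(r, float), np.asarray(x, float)
    if np.any(r < 0) or np.any(x < 0):
        raise ValueError("r and x must be non-negative")
    return (1.0 - np.exp(-r * x)) * (np.asarray(m, float) - np.asarray(d, float)) \
        + np.asarray(d, float)


def compute_delta_rt(trials: pd.DataFrame) -> pd.DataFrame:
    """Per-participant delta-RT by distractor distance to the HP location.

    Mean present-trial RT at each distance minus the participant's overall
    absent-trial mean, experimental blocks only.  Participants lacking
    trials at a distance simply have no row for it (logged).
    """
    df = trials.loc[trials["block"] > 1]
    absent = (
        df.loc[df["condition"] == "absent"]
        .groupby(["participant_id", "task"])["rt"]
        .mean()
        .rename("absent_mean")
    )
    present = (
        df.loc[df["condition"] != "absent"]
        .groupby(["participant_id", "task", "distance_to_hp"])["rt"]
        .agg(present_mean="mean", n_trials="size")
        .reset_index()
    )
    out = present.merge(absent.reset_index(), on=["participant_id", "task"])
    out["delta_rt"] = out["present_mean"] - out["absent_mean"]
    out = out.rename(columns={"distance_to_hp": "x"})
    n_expected = out.groupby("participant_id")["x"].nunique()
    short = n_expected[n_expected < 5]
    if len(short):
        logger.warning("participants missing distances: %s",
                       ", ".join(short.index))
    return out[["participant_id", "task", "x", "delta_rt", "n_trials"]]


@dataclass(frozen=True)
class SuppressionPriors:
    """Weakly-informative defaults around capture magnitudes typical of
    additional-singleton experiments; all scales in the parameter's units.

    The between-participant spread of the gradient (``tau_r_scale``) is
    kept tight: with five delta-RT points per participant the individual
    gradient is barely identified, and a loose spread lets participant
    gradients wander into the saturated regime (r above ~0.4 /cm, where the
    curve flattens before the smallest inter-location distance and the data
    cannot distinguish gradients), dragging the group estimate with them.
    """

    r_scale: float = 0.5          # half-normal on the group gradient, 1/cm
    m_loc: float = 60.0
    m_scale: float = 40.0         # normal truncated at 0, ms
    d_loc: float = 15.0
    d_scale: float = 30.0         # normal truncated at 0, ms
    sd_scale: float = 50.0        # half-normal on residual sd, ms
    tau_r_scale: float = 0.05
    tau_m_scale: float = 30.0
    tau_d_scale: float = 20.0
    tau_logsd_scale: float = 0.5


class _SuppressionModel:
    """Vectorized log-posterior over chains (non-centered).

    Layout: per task [mu_r_t, log_tau_r_t], then shared
    [mu_m, log_tau_m, mu_d, log_tau_d, mu_logsd, log_tau_logsd], then per
    participant the standardized offsets [z_r, z_m, z_d, z_logsd]; natural
    values are mu + tau * z.
    """

    def __init__(self, points: pd.DataFrame, priors: SuppressionPriors):
        self.priors = priors
        self.tasks = sorted(points["task"].unique())
        self.participants = (
            points[["participant_id", "task"]].drop_duplicates()
            .sort_values(["task", "participant_id"]).reset_index(drop=True)
        )
        self.n_part = len(self.participants)
        pid_pos = {pid: i for i, pid in
                   enumerate(self.participants["participant_id"])}
        self.part_task = self.participants["task"].map(
            {t: i for i, t in enumerate(self.tasks)}).to_numpy()
        self.obs_pid = points["participant_id"].map(pid_pos).to_numpy()
        self.obs_x = points["x"].to_numpy(float)
        self.obs_y = points["delta_rt"].to_numpy(float)

        self.n_hyper = 2 * len(self.tasks) + 6
        self.ndim = self.n_hyper + 4 * self.n_part
        self.names = []
        for t in self.tasks:
            self.names += [f"mu_r[{t}]", f"log_tau_r[{t}]"]
        self.names += ["mu_m", "log_tau_m", "mu_d", "log_tau_d",
                       "mu_logsd", "log_tau_logsd"]
        for pid in self.participants["participant_id"]:
            self.names += [f"z_r[{pid}]", f"z_m[{pid}]", f"z_d[{pid}]",
                           f"z_log_sd[{pid}]"]

    # -- parameter views -------------------------------------------------
    def _split(self, theta: np.ndarray):
        nt = len(self.tasks)
        mu_r = theta[:, 0:2 * nt:2]
        log_tau_r = theta[:, 1:2 * nt:2]
        h = theta[:, 2 * nt:2 * nt + 6]
        part = theta[:, self.n_hyper:].reshape(theta.shape[0], self.n_part, 4)
        return mu_r, log_tau_r, h, part

    def natural_part(self, theta: np.ndarray) -> np.ndarray:
        """Natural participant values [r, m, d, log_sd], (n, n_part, 4)."""
        theta = np.atleast_2d(np.asarray(theta, float))
        mu_r, log_tau_r, h, z = self._split(theta)
        with np.errstate(over="ignore", invalid="ignore"):
            tau_r = np.exp(np.clip(log_tau_r, -12, 12))
            out = np.empty_like(z)
            out[..., 0] = mu_r[:, self.part_task] \
                + tau_r[:, self.part_task] * z[..., 0]
            for col_p, col_h in ((1, 0), (2, 2), (3, 4)):
                tau = np.exp(np.clip(h[:, col_h + 1], -12, 12))
                out[..., col_p] = h[:, None, col_h] \
                    + tau[:, None] * z[..., col_p]
        return out

    def logp_grad(self, theta: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Joint log-density and gradient, vectorized over chains."""
        theta = np.atleast_2d(np.asarray(theta, float))
        C = theta.shape[0]
        nt = len(self.tasks)
        p = self.priors
        mu_r, log_tau_r, h, z = self._split(theta)
        mu_m, mu_d, mu_logsd = h[:, 0], h[:, 2], h[:, 4]

        grad = np.zeros_like(theta)
        g_mu_r = grad[:, 0:2 * nt:2]
        g_lt_r = grad[:, 1:2 * nt:2]
        g_h = grad[:, 2 * nt:2 * nt + 6]
        g_lik = np.zeros((C, self.n_part, 4))

        tau_r = np.exp(np.clip(log_tau_r, -12, 12))
        part = self.natural_part(theta)
        r, m, d, log_sd = (part[..., 0], part[..., 1], part[..., 2],
                           part[..., 3])

        # Positivity is enforced on the group means only; participant-level
        # draws may graze zero (their hierarchical priors keep them near the
        # group mean) so that trajectories are not rejected wholesale.
        lp = np.zeros(C)
        bad = (mu_r < 0).any(axis=1) | (mu_m < 0) | (mu_d < 0) \
            | (np.abs(log_tau_r) > 12).any(axis=1) \
            | (np.abs(h[:, 1::2]) > 12).any(axis=1)

        with np.errstate(over="ignore", invalid="ignore"):
            # hyperpriors
            lp += -0.5 * (mu_r ** 2).sum(axis=1) / p.r_scale ** 2
            g_mu_r += -mu_r / p.r_scale ** 2
            lp += -0.5 * ((mu_m - p.m_loc) / p.m_scale) ** 2
            g_h[:, 0] += -(mu_m - p.m_loc) / p.m_scale ** 2
            lp += -0.5 * ((mu_d - p.d_loc) / p.d_scale) ** 2
            g_h[:, 2] += -(mu_d - p.d_loc) / p.d_scale ** 2
            lp += -0.5 * ((mu_logsd - np.log(40.0)) / 1.0) ** 2
            g_h[:, 4] += -(mu_logsd - np.log(40.0))

            lp += (-0.5 * (tau_r / p.tau_r_scale) ** 2 + log_tau_r).sum(axis=1)
            g_lt_r += -(tau_r / p.tau_r_scale) ** 2 + 1.0
            for col, scale in ((1, p.tau_m_scale), (3, p.tau_d_scale),
                               (5, p.tau_logsd_scale)):
                tau = np.exp(np.clip(h[:, col], -12, 12))
                lp += -0.5 * (tau / scale) ** 2 + h[:, col]
                g_h[:, col] += -(tau / scale) ** 2 + 1.0

            # standardized offsets
            lp += -0.5 * (z ** 2).sum(axis=(1, 2))

            # likelihood
            ro, mo, do = r[:, self.obs_pid], m[:, self.obs_pid], d[:, self.obs_pid]
            lsdo = log_sd[:, self.obs_pid]
            sdo = np.exp(np.clip(lsdo, -12, 12))
            E = np.exp(-ro * self.obs_x)
            mu_obs = (1.0 - E) * (mo - do) + do
            e = (self.obs_y - mu_obs) / sdo
            lp += (-0.5 * e ** 2 - np.log(sdo)).sum(axis=1)
            e_over_sd = e / sdo
            dr = e_over_sd * (self.obs_x * E * (mo - do))
            dm = e_over_sd * (1.0 - E)
            dd = e_over_sd * E
            dlsd = e ** 2 - 1.0

        with np.errstate(over="ignore", invalid="ignore"):
            gl_flat = g_lik.reshape(C, self.n_part * 4)
            base = self.obs_pid * 4
            np.add.at(gl_flat, (slice(None), base + 0), dr)
            np.add.at(gl_flat, (slice(None), base + 1), dm)
            np.add.at(gl_flat, (slice(None), base + 2), dd)
            np.add.at(gl_flat, (slice(None), base + 3), dlsd)

            # chain rule: natural value = mu + tau * z
            for t in range(nt):
                mask = self.part_task == t
                g_mu_r[:, t] += g_lik[:, mask, 0].sum(axis=1)
                g_lt_r[:, t] += (g_lik[:, mask, 0]
                                 * (r[:, mask] - mu_r[:, t, None])).sum(axis=1)
            for col_p, col_h, val, mu in ((1, 0, m, mu_m), (2, 2, d, mu_d),
                                          (3, 4, log_sd, mu_logsd)):
                g_h[:, col_h] += g_lik[:, :, col_p].sum(axis=1)
                g_h[:, col_h + 1] += (g_lik[:, :, col_p]
                                      * (val - mu[:, None])).sum(axis=1)
            g_z = np.empty_like(g_lik)
            g_z[..., 0] = g_lik[..., 0] * tau_r[:, self.part_task]
            for col_p, col_h in ((1, 0), (2, 2), (3, 4)):
                tau = np.exp(np.clip(h[:, col_h + 1], -12, 12))
                g_z[..., col_p] = g_lik[..., col_p] * tau[:, None]
            g_z -= z
            grad[:, self.n_hyper:] += g_z.reshape(C, -1)

        lp = np.where(bad | ~np.isfinite(lp), -np.inf, lp)
        return lp, grad

    def log_prob(self, theta: np.ndarray) -> np.ndarray:
        return self.logp_grad(theta)[0]

    # -- initialization --------------------------------------------------
    def initial_point(self) -> tuple[np.ndarray, np.ndarray]:
        init = np.zeros(self.ndim)
        scale = np.zeros(self.ndim)
        per_part = np.zeros((self.n_part, 4))
        for i in range(self.n_part):
            pts = self.obs_pid == i
            x, y = self.obs_x[pts], self.obs_y[pts]
            # moment start: residual capture from the nearest point, maximum
            # capture from the farthest points, a mid-range gradient
            d0 = float(np.clip(y[np.argmin(x)], 1.0, 150.0))
            m0 = float(np.clip(np.mean(y[x >= np.median(x)]), d0 + 1.0, 250.0))
            r0 = 0.15
            try:
                popt, _ = curve_fit(
                    lambda x, r, m, d: (1 - np.exp(-r * x)) * (m - d) + d,
                    x, y, p0=[r0, m0, d0],
                    bounds=([0.0, 1.0, 0.0], [2.0, 400.0, 300.0]), maxfev=500,
                )
                r0, m0, d0 = (float(np.clip(popt[0], 0.03, 0.8)),
                              float(np.clip(popt[1], 5.0, 250.0)),
                              float(np.clip(popt[2], 1.0, 150.0)))
            except RuntimeError:  # pragma: no cover - keep moment start
                pass
            resid_sd = max(float(np.std(y - suppression_mean(r0, m0, d0, x))),
                           5.0)
            per_part[i] = [r0, m0, d0, np.log(resid_sd)]
        nt = len(self.tasks)
        for t in range(nt):
            mask = self.part_task == t
            init[2 * t] = float(np.clip(per_part[mask, 0].mean(), 0.03, 0.5))
            init[2 * t + 1] = np.log(np.clip(per_part[mask, 0].std(), 0.02, 0.2))
            scale[2 * t] = 0.03
            scale[2 * t + 1] = 0.3
        init[2 * nt:2 * nt + 6] = [
            per_part[:, 1].mean(), np.log(max(per_part[:, 1].std(), 5.0)),
            per_part[:, 2].mean(), np.log(max(per_part[:, 2].std(), 5.0)),
            per_part[:, 3].mean(), np.log(max(per_part[:, 3].std(), 0.1)),
        ]
        scale[2 * nt:2 * nt + 6] = [5.0, 0.3, 5.0, 0.3, 0.1, 0.3]
        # standardized participant offsets around the hyper means
        z = np.zeros((self.n_part, 4))
        mu_r_i = init[2 * self.part_task]
        tau_r_i = np.exp(init[2 * self.part_task + 1])
        z[:, 0] = (per_part[:, 0] - mu_r_i) / tau_r_i
        for col_p, col_h in ((1, 0), (2, 2), (3, 4)):
            mu = init[2 * nt + col_h]
            tau = np.exp(init[2 * nt + col_h + 1])
            z[:, col_p] = (per_part[:, col_p] - mu) / tau
        init[self.n_hyper:] = np.clip(z, -2.5, 2.5).ravel()
        scale[self.n_hyper:] = 0.5
        return init, scale


@dataclass
class SuppressionFit:
    """Posterior summaries of the spatial model."""

    samples: bayes_core.PosteriorSamples
    model: _SuppressionModel
    summaries: dict[str, PosteriorSummary]

    @property
    def converged(self) -> bool:
        return self.samples.converged

    def summary_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                name: {"mode": s.mode, "hpd_low": s.hpd_low,
                       "hpd_high": s.hpd_high}
                for name, s in self.summaries.items()
            }
        ).T


def fit_suppression(points: pd.DataFrame,
                    priors: SuppressionPriors | None = None,
                    config: SamplerConfig | None = None) -> SuppressionFit:
    """Fit the hierarchical suppression-gradient model to delta-RT points.

    Returns group-level summaries for the task-specific gradients, the
    shared m and d, the across-task averaged map parameters (r_map, m_map,
    d_map) and -- with two tasks -- the between-task gradient difference
    (mixed minus fixed).
    """
    counts = points.groupby("task")["participant_id"].nunique()
    if (counts < 2).any():
        raise ValueError("need at least 2 participants per task")
    model = _SuppressionModel(points, priors or SuppressionPriors())
    init, scale = model.initial_point()
    samples = bayes_core.sample_posterior(
        model.logp_grad, init, scale, names=model.names,
        config=config or SamplerConfig(),
    )

    def draws(name: str) -> np.ndarray:
        return samples.get(name)

    summaries: dict[str, PosteriorSummary] = {}
    r_by_task = {t: draws(f"mu_r[{t}]") for t in model.tasks}
    for t, dr in r_by_task.items():
        summaries[f"r[{t}]"] = bayes_core.summarize(dr)
    summaries["m"] = bayes_core.summarize(draws("mu_m"))
    summaries["d"] = bayes_core.summarize(draws("mu_d"))
    r_map = np.mean(np.column_stack(list(r_by_task.values())), axis=1)
    summaries["r_map"] = bayes_core.summarize(r_map)
    summaries["m_map"] = summaries["m"]
    summaries["d_map"] = summaries["d"]
    if len(model.tasks) == 2 and set(model.tasks) == {"fixed", "mixed"}:
        summaries["r_diff"] = bayes_core.summarize(
            r_by_task["mixed"] - r_by_task["fixed"]
        )
    return SuppressionFit(samples=samples, model=model, summaries=summaries)


def render_map(r: float, m: float, d: float, extent: float = 12.0,
               n: int = 201, hp_xy: tuple[float, float] = (0.0, 5.6)
               ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Suppression field on a square grid around the display centre.

    The value at a point at distance x from the HP location is
    ``m - suppression_mean(r, m, d, x)``: maximal (m - d) at the HP
    location, fading to 0 far away; radially symmetric around the HP
    location (placed on the top vertical of the display circle).
    Returns (xs, ys, field).
    """
    xs = np.linspace(-extent, extent, n)
    ys = np.linspace(-extent, extent, n)
    gx, gy = np.meshgrid(xs, ys)
    dist = np.hypot(gx - hp_xy[0], gy - hp_xy[1])
    field = m - suppression_mean(r, m, d, dist)
    return xs, ys, field


def save_map_figure(r: float, m: float, d: float, path,
                    radius: float = 5.6, **kwargs) -> None:
    """Render the suppression map to an image file."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    xs, ys, field = render_map(r, m, d, **kwargs)
    fig, ax = plt.subplots(figsize=(5, 4.2))
    im = ax.pcolormesh(xs, ys, field, shading="auto", cmap="viridis")
    theta = np.linspace(0, 2 * np.pi, 9)[:-1] + np.pi / 2
    ax.plot(radius * np.cos(theta), radius * np.sin(theta), "wo", ms=6,
            mec="k")
    fig.colorbar(im, ax=ax, label="suppression (ms)")
    ax.set_xlabel("x (cm)")
    ax.set_ylabel("y (cm)")
    ax.set_aspect("equal")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
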