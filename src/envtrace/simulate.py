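"""Synthetic grazing-herd simulator with known environment-behaviour coupling.

The generator emulates the study system the pipeline is built for: a small
herd (default 8 animals) confined to a bounded pasture plot, observed over
several multi-day sessions.  Per animal a semi-Markov activity process
(exponential bout durations over grazing / walking / standing / lying,
with a rumination overlay on the two resting postures) drives

* 1 Hz positions from an activity-dependent correlated random walk with
  herd-cohesion attraction and reflecting plot boundaries, plus GPS noise
  and an HDOP column with a small fraction of poor fixes;
* 32 Hz tri-axial accelerometer signals from per-activity posture offsets
  and oscillators plus Gaussian noise — the grazing oscillation's
  amplitude and frequency are modulated by standardized grass biomass;
* an environment series: grass biomass depleting in proportion to the
  fraction of the herd currently grazing (resetting at each session's
  fresh plot), a twice-daily time-since-milking sawtooth, and a wind-like
  AR(1) nuisance variable that shares a slow trend with biomass (target
  correlation about 0.37) but has zero behavioural effect.

The grazing propensity depends log-linearly (logistic odds) on
standardized biomass (negative: depleted pasture demands more foraging
time) and on time since milking (positive: hunger builds up), with
configurable coupling coefficients; setting them to zero severs the
environment-behaviour link, which is the null case the influence metric
must report as approximately zero.

All randomness derives from one mandatory integer seed; identical seeds
give identical outputs.  Accelerometer data are synthesized lazily per
animal-hour from derived sub-seeds so multi-day sessions never hold the
full 32 Hz stream in memory.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .geo import UtmZone, geodetic_to_utm, utm_to_geodetic
from .io import MAIN_CLASSES

logger = logging.getLogger("envtrace")

ACTIVITIES = MAIN_CLASSES  # ("grazing", "walking", "standing", "lying")
_GRAZ, _WALK, _STAND, _LIE = range(4)

#: default epoch: local midnight, UTC+2
_DEFAULT_T0 = 1493071200.0  # 2017-04-25T00:00:00+02:00


def _zb(biomass, centre=1000.0, scale=300.0):
    return (np.asarray(biomass, float) - centre) / scale


def _zt(tsm, centre=4.5, scale=3.0):
    return (np.asarray(tsm, float) - centre) / scale


@dataclass
class SimConfig:
    """Study-condition parameters of the synthetic herd."""

    seed: int
    n_cows: int = 8
    n_sessions: int = 3
    session_hours: int = 48
    plot_size_m: float = 56.6                      # sqrt(0.32 ha)
    t0: float = _DEFAULT_T0
    utc_offset_h: float = 2.0
    origin_lat: float = 51.9856
    origin_lon: float = 5.6531

    # activity semi-Markov process
    mean_bout_s: tuple = (1200.0, 120.0, 600.0, 1500.0)   # per activity
    base_weights: tuple = (1.0, 0.8, 0.9, 0.9)
    beta_biomass: float = 1.0     # grazing log-odds per -z(biomass)
    beta_milking: float = 0.8     # grazing log-odds per +z(time since milking)
    rumination_prob: float = 0.5  # per standing/lying bout

    # environment
    biomass0: float = 1400.0              # kg DM / ha at session start
    depletion_kappa: float = 40.0         # kg DM / ha / h at full-herd grazing
    milking_times_h: tuple = (7.5, 16.5)  # local clock
    wind_mean: float = 4.0
    wind_sd: float = 1.5
    wind_tau_s: float = 10800.0           # AR(1) decorrelation time
    wind_biomass_coupling: float = 0.6    # shared slow trend -> r ~ 0.37
    env_step_s: float = 60.0

    # movement (per activity)
    speed_mps: tuple = (0.08, 1.0, 0.015, 0.008)
    heading_sd: tuple = (0.5, 0.2, 2.0, 2.0)
    cohesion_weight: float = 0.06
    cohesion_dist_m: float = 12.0
    gps_noise_m: float = 0.25
    hdop_bad_frac: float = 0.005

    # accelerometer generators (axis order x fwd / y lateral / z vertical)
    accel_rate: float = 32.0
    accel_offsets: tuple = ((2.0, 0.0, -9.3), (0.5, 0.0, -9.7),
                            (0.3, 0.0, -9.8), (6.0, 2.0, -7.5))
    accel_amp: tuple = ((3.0, 1.0, 2.0), (1.2, 0.8, 2.5),
                       (0.1, 0.1, 0.1), (0.1, 0.1, 0.1))
    accel_freq_hz: tuple = (1.2, 1.8, 0.3, 0.3)
    rumination_amp: float = 0.8
    rumination_freq_hz: float = 1.1
    accel_noise_sd: float = 0.3
    amp_biomass_coupling: float = 0.4
    freq_biomass_coupling: float = 0.15

    def validate(self):
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if self.n_cows < 2 or self.n_sessions < 1 or self.session_hours < 1:
            raise ValueError("need n_cows >= 2 and positive session dimensions")
        if min(self.mean_bout_s) <= 0 or self.depletion_kappa < 0:
            raise ValueError("rates and bout durations must be positive")
        return self

    @property
    def total_s(self) -> int:
        return int(self.n_sessions * self.session_hours * 3600)

    @property
    def cow_ids(self) -> list:
        return [f"cow{i + 1:02d}" for i in range(self.n_cows)]


def with_couplings(cfg: SimConfig, scale: float) -> SimConfig:
    """Scale every environment-behaviour coupling by one factor (0 = inert)."""
    return replace(cfg,
                   beta_biomass=cfg.beta_biomass * scale,
                   beta_milking=cfg.beta_milking * scale,
                   amp_biomass_coupling=cfg.amp_biomass_coupling * scale,
                   freq_biomass_coupling=cfg.freq_biomass_coupling * scale)


def time_since_milking(t: np.ndarray, cfg: SimConfig) -> np.ndarray:
    """Sawtooth: hours since the most recent milking (local clock times)."""
    local_h = (np.asarray(t, float) - cfg.t0) / 3600.0 % 24.0
    days = np.floor((np.asarray(t, float) - cfg.t0) / 86400.0)
    milks = np.sort(np.asarray(cfg.milking_times_h, float))
    out = np.full_like(local_h, np.nan)
    # before first milking of the day: since the last milking of yesterday
    prev = local_h + 24.0 - milks[-1]
    out = np.where(local_h < milks[0], prev, out)
    for i, m in enumerate(milks):
        upper = milks[i + 1] if i + 1 < len(milks) else np.inf
        sel = (local_h >= m) & (local_h < upper)
        out = np.where(sel, local_h - m, out)
    # the very first part of the simulation has no preceding milking event;
    # the wrapped sawtooth value is kept (steady-state schedule)
    return out + 0.0 * days


class SimOutput:
    """In-memory simulation product with lazy accelerometer synthesis."""

    def __init__(self, config: SimConfig, activities, ruminating, positions,
                 env: pd.DataFrame):
        self.config = config
        self.activities = activities      # (n_cows, total_s) int8
        self.ruminating = ruminating      # (n_cows, total_s) bool
        self.positions = positions        # (n_cows, total_s, 2) float32
        self.env = env
        self._zb_per_s = np.interp(
            np.arange(config.total_s, dtype=float),
            env["t"].to_numpy() - config.t0, _zb(env["biomass"].to_numpy()))

    # -- ground truth -----------------------------------------------------
    def truth_manifest(self) -> dict:
        c = self.config
        return {
            "seed": c.seed,
            "beta_biomass": c.beta_biomass,
            "beta_milking": c.beta_milking,
            "amp_biomass_coupling": c.amp_biomass_coupling,
            "freq_biomass_coupling": c.freq_biomass_coupling,
            "wind_behaviourally_inert": True,
            "n_cows": c.n_cows,
            "n_sessions": c.n_sessions,
            "session_hours": c.session_hours,
        }

    def truth_summary(self) -> pd.DataFrame:
        """Per-target coupling level and the expected sign of the influence
        estimate, plus per-hour true grazing proportions for validation."""
        c = self.config
        strength = lambda b: ("zero" if b == 0 else
                              "weak" if abs(b) < 0.5 else "strong")
        rows = [
            {"target": "biomass", "coupling": strength(c.beta_biomass),
             "expected_influence": "> 0" if c.beta_biomass else "~ 0"},
            {"target": "time_since_milking",
             "coupling": strength(c.beta_milking),
             "expected_influence": "> 0" if c.beta_milking else "~ 0"},
            {"target": "wind", "coupling": "zero", "expected_influence": "~ 0"},
        ]
        return pd.DataFrame(rows)

    def hourly_true_proportions(self) -> pd.DataFrame:
        """True per-animal-hour activity proportions (sum to 1)."""
        c = self.config
        n_hours = c.total_s // 3600
        rows = []
        for ci, cow in enumerate(c.cow_ids):
            act = self.activities[ci, : n_hours * 3600].reshape(n_hours, 3600)
            for h in range(n_hours):
                counts = np.bincount(act[h], minlength=4) / 3600.0
                rows.append({"animal_id": cow, "hour": h,
                             **{a: counts[k] for k, a in enumerate(ACTIVITIES)}})
        return pd.DataFrame(rows)

    # -- sensor streams ---------------------------------------------------
    def gps(self, cow_indices=None) -> pd.DataFrame:
        """1 Hz GPS fixes (lat, lon, hdop) with noise.

        ``cow_indices`` restricts the frame to selected animals, which
        keeps the memory of long simulations bounded when callers process
        one animal at a time.
        """
        c = self.config
        e0, n0 = geodetic_to_utm(c.origin_lat, c.origin_lon, UtmZone())
        t = c.t0 + np.arange(c.total_s, dtype=float)
        frames = []
        indices = range(c.n_cows) if cow_indices is None else cow_indices
        for ci in indices:
            cow = c.cow_ids[ci]
            rng = np.random.default_rng(np.random.SeedSequence((c.seed, 31, ci)))
            noise = rng.normal(0.0, c.gps_noise_m, (c.total_s, 2))
            x = self.positions[ci, :, 0] + noise[:, 0] + e0 - c.plot_size_m / 2
            y = self.positions[ci, :, 1] + noise[:, 1] + n0 - c.plot_size_m / 2
            lat, lon = utm_to_geodetic(x, y, UtmZone())
            hdop = np.round(rng.lognormal(0.0, 0.25, c.total_s), 2)
            bad = rng.random(c.total_s) < c.hdop_bad_frac
            hdop = np.where(bad, np.round(rng.uniform(5.1, 9.0, c.total_s), 2),
                            hdop)
            frames.append(pd.DataFrame({"animal_id": cow, "t": t, "lat": lat,
                                        "lon": lon, "hdop": hdop}))
        return pd.concat(frames, ignore_index=True)

    def accel_hour(self, cow_index: int, hour_index: int):
        """Synthesize one animal-hour of 32 Hz accelerometer data.

        Returns (t, xyz) with t in epoch seconds; deterministic in
        (seed, cow, hour) regardless of evaluation order.
        """
        c = self.config
        rate = c.accel_rate
        n_sub = int(round(rate))
        s0 = hour_index * 3600
        n_s = min(3600, c.total_s - s0)
        n = n_s * n_sub
        rng = np.random.default_rng(
            np.random.SeedSequence((c.seed, 71, cow_index, hour_index)))

        act_s = self.activities[cow_index, s0: s0 + n_s]
        rum_s = self.ruminating[cow_index, s0: s0 + n_s]
        zb_s = self._zb_per_s[s0: s0 + n_s]
        act = np.repeat(act_s, n_sub)
        rum = np.repeat(rum_s, n_sub)
        zb = np.repeat(zb_s, n_sub)
        tt = np.arange(n) / rate

        offs = np.asarray(c.accel_offsets, float)[act]      # (n, 3)
        amps = np.asarray(c.accel_amp, float)[act]
        freq = np.asarray(c.accel_freq_hz, float)[act]
        grazing = act == _GRAZ
        mod_amp = np.where(grazing, 1.0 + c.amp_biomass_coupling * zb, 1.0)
        mod_freq = np.where(grazing, 1.0 + c.freq_biomass_coupling * zb, 1.0)
        phase = rng.uniform(0, 2 * np.pi)
        osc = np.sin(2 * np.pi * freq * mod_freq * tt + phase)
        xyz = offs + amps * (mod_amp * osc)[:, None]
        xyz[:, 0] += np.where(
            rum, c.rumination_amp * np.sin(2 * np.pi * c.rumination_freq_hz * tt
                                           + phase), 0.0)
        xyz += rng.normal(0.0, c.accel_noise_sd, (n, 3))
        t = c.t0 + s0 + tt
        return t, xyz

    def accel(self, cow_indices=None, hours=None) -> pd.DataFrame:
        """Materialized accelerometer frame (use for short simulations)."""
        c = self.config
        cow_indices = range(c.n_cows) if cow_indices is None else cow_indices
        hours = range(c.total_s // 3600) if hours is None else hours
        frames = []
        for ci in cow_indices:
            for h in hours:
                t, xyz = self.accel_hour(ci, h)
                frames.append(pd.DataFrame({
                    "animal_id": c.cow_ids[ci], "t": t,
                    "ax": xyz[:, 0], "ay": xyz[:, 1], "az": xyz[:, 2]}))
        return pd.concat(frames, ignore_index=True)

    def ethogram(self) -> pd.DataFrame:
        """Observed activity bouts in the six-type ethogram encoding."""
        c = self.config
        rows = []
        for ci, cow in enumerate(c.cow_ids):
            act = self.activities[ci].astype(int) + 10 * self.ruminating[ci]
            change = np.flatnonzero(np.diff(act)) + 1
            starts = np.concatenate([[0], change])
            ends = np.concatenate([change, [c.total_s]])
            for s, e in zip(starts, ends):
                a = int(act[s])
                main = ACTIVITIES[a % 10]
                rum = a >= 10
                name = (f"ruminating_{main}" if rum and main in
                        ("standing", "lying") else main)
                rows.append({"animal_id": cow, "start": c.t0 + s,
                             "end": c.t0 + e, "activity": name})
        return pd.DataFrame(rows)

    def write(self, outdir):
        """Write GPS, accelerometer, ethogram and environment CSVs plus the
        ground-truth manifest into a directory."""
        import json
        from pathlib import Path

        from . import io as io_mod

        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        io_mod.write_gps(self.gps(), out / "gps.csv")
        io_mod.write_accel(self.accel(), out / "accel.csv")
        io_mod.write_ethogram(self.ethogram(), out / "ethogram.csv")
        io_mod.write_env(self.env, out / "env.csv")
        (out / "truth.json").write_text(json.dumps(self.truth_manifest(),
                                                   indent=2))
        logger.info("simulation written to %s", out)


def _simulate_activities_env(cfg: SimConfig):
    """Joint semi-Markov activity + environment simulation on a coarse grid."""
    rng = np.random.default_rng(np.random.SeedSequence((cfg.seed, 11)))
    total = cfg.total_s
    step = int(cfg.env_step_s)
    n_steps = total // step

    activities = np.empty((cfg.n_cows, total), dtype=np.int8)
    ruminating = np.zeros((cfg.n_cows, total), dtype=bool)

    t_env = cfg.t0 + step * np.arange(n_steps, dtype=float)
    tsm = time_since_milking(t_env, cfg)
    biomass = np.empty(n_steps)
    session = (np.arange(n_steps) * step // (cfg.session_hours * 3600)) + 1

    state = rng.integers(0, 4, cfg.n_cows)
    bout_end = np.zeros(cfg.n_cows)
    rum_state = np.zeros(cfg.n_cows, dtype=bool)
    means = np.asarray(cfg.mean_bout_s, float)
    base_w = np.asarray(cfg.base_weights, float)

    b = cfg.biomass0
    for k in range(n_steps):
        if k > 0 and session[k] != session[k - 1]:
            b = cfg.biomass0  # fresh plot
        biomass[k] = b
        zb, zt = _zb(b), _zt(tsm[k])
        t_lo = k * step
        for ci in range(cfg.n_cows):
            t_cur = t_lo
            while bout_end[ci] < t_lo + step:
                t_cur = max(t_lo, int(bout_end[ci]))
                w = base_w.copy()
                w[_GRAZ] *= np.exp(-cfg.beta_biomass * zb
                                   + cfg.beta_milking * zt)
                w[state[ci]] = 0.0  # leave the current state
                w /= w.sum()
                state[ci] = rng.choice(4, p=w)
                rum_state[ci] = (state[ci] in (_STAND, _LIE)
                                 and rng.random() < cfg.rumination_prob)
                bout_end[ci] = t_cur + rng.exponential(means[state[ci]])
            span = slice(t_lo, min(t_lo + step, total))
            activities[ci, span] = state[ci]
            ruminating[ci, span] = rum_state[ci]
        frac_grazing = np.mean(activities[:, t_lo] == _GRAZ)
        b = max(b - cfg.depletion_kappa * frac_grazing * step / 3600.0, 0.0)

    # wind: AR(1) plus a slow trend shared with biomass, behaviourally inert
    phi = np.exp(-step / cfg.wind_tau_s)
    innov_sd = cfg.wind_sd * np.sqrt(1 - phi**2)
    ar = np.empty(n_steps)
    ar[0] = rng.normal(0, cfg.wind_sd)
    shocks = rng.normal(0, innov_sd, n_steps)
    for k in range(1, n_steps):
        ar[k] = phi * ar[k - 1] + shocks[k]
    wind = np.maximum(cfg.wind_mean + ar
                      + cfg.wind_biomass_coupling * _zb(biomass) * cfg.wind_sd,
                      0.0)

    env = pd.DataFrame({"t": t_env, "biomass": biomass,
                        "time_since_milking": tsm, "wind": wind,
                        "session_id": session})
    return activities, ruminating, env


def _simulate_positions(cfg: SimConfig, activities: np.ndarray) -> np.ndarray:
    """Correlated random walk with herd cohesion, per second, all cows."""
    rng = np.random.default_rng(np.random.SeedSequence((cfg.seed, 21)))
    total, n = cfg.total_s, cfg.n_cows
    lo, hi = 0.0, cfg.plot_size_m
    pos = np.empty((n, total, 2), dtype=np.float32)
    xy = rng.uniform(hi * 0.3, hi * 0.7, (n, 2))
    theta = rng.uniform(-np.pi, np.pi, n)
    speeds = np.asarray(cfg.speed_mps, float)
    hsd = np.asarray(cfg.heading_sd, float)
    pos[:, 0] = xy

    chunk = 3600
    for start in range(1, total, chunk):
        end = min(start + chunk, total)
        normals = rng.standard_normal((end - start, n, 2))
        for t in range(start, end):
            act = activities[:, t]
            centroid = xy.mean(axis=0)
            rel = centroid - xy
            dist = np.hypot(rel[:, 0], rel[:, 1])
            target = np.arctan2(rel[:, 1], rel[:, 0])
            pull = np.where(dist > cfg.cohesion_dist_m, cfg.cohesion_weight, 0.0)
            dtheta = np.pi - np.mod(np.pi - (target - theta), 2 * np.pi)
            theta = theta + pull * dtheta + hsd[act] * normals[t - start, :, 0]
            step = speeds[act] * np.exp(0.3 * normals[t - start, :, 1])
            xy = xy + np.column_stack([step * np.cos(theta),
                                       step * np.sin(theta)])
            # reflect at the plot boundary
            over = xy > hi
            under = xy < lo
            xy = np.where(over, 2 * hi - xy, xy)
            xy = np.where(under, -xy, xy)
            np.clip(xy, lo, hi, out=xy)
            pos[:, t] = xy
    return pos


def simulate(config: SimConfig) -> SimOutput:
    """Run the full herd simulation for the configured sessions."""
    cfg = config.validate()
    activities, ruminating, env = _simulate_activities_env(cfg)
    positions = _simulate_positions(cfg, activities)
    logger.info("simulated %d cows x %d h (seed %d)", cfg.n_cows,
                cfg.total_s // 3600, cfg.seed)
    return SimOutput(cfg, activities, ruminating, positions, env)
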