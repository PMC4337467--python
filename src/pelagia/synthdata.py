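"""Seeded synthetic biologging cohorts with known ground truth.

Generates the three data streams the analysis pipeline consumes — true daily
tracks, noisy geolocation observations, and wet/dry immersion series — for a
cohort of non-breeding seabirds, together with the truth needed to score
recovery: movement phase boundaries, the 720-km departure/return crossing
dates, per-sample activity labels, and per-day target activity proportions.

The movement model has three phases: fast directed outbound transit away from
the colony along a per-bird great-circle bearing, a localized overwinter
random walk, and directed inbound transit back. Observation noise is
independent Gaussian per day in degrees, with optional inflation of latitude
noise inside the ±15-day fall-equinox window (emulating degraded light-level
latitudes; exclusion of that window is the filter's job, not the
generator's). Immersion series are built by concatenating bouts whose
interval durations follow a two-timescale exponential mixture: sustained dry
(flight) and wet (float) intervals from the slow process, rapid wet/dry
alternation (active foraging) from the fast process.

Defaults emulate the study system: Midway Atoll colony, departure late June
± ~2 weeks, ~10-day transits at ~300 km/day, ~125-day overwinter, tag
resolutions in {32, 90, 100} s, observation SDs at the published
double-tagging scale, and a day-to-day activity trend with a quasi-flightless
trough (flight minimum, float maximum) centred near 50 days since departure.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Callable

import numpy as np
import pandas as pd

from .geotrack import fall_equinox
from .immersion import ImmersionSeries
from .spatial import destination_point, great_circle_km, initial_bearing_deg, wrap180

#: tag resolutions deployed across study years, seconds
VALID_SAMPLING_INTERVALS = (32, 90, 100)

#: colony: Sand Island, Midway Atoll (lon, lat)
MIDWAY = (-177.23, 28.12)

#: km beyond which a bird has definitively left the colony's foraging range
DEPARTURE_RADIUS_KM = 720.0

FLIGHT_CODE, FLOAT_CODE, FORAGE_CODE = 0, 1, 2
ACTIVITY_NAMES = {FLIGHT_CODE: "flight", FLOAT_CODE: "float", FORAGE_CODE: "forage"}


def default_trend_shape(dsd):
    """Expected daily (flight, float, forage) proportions vs days since departure.

    Flight is U-shaped with its minimum at 50 DSD (the quasi-flightless
    trough), foraging dips in parallel, and floating takes the remainder, so
    the three sum to 1 at every day.
    """
    dsd = np.asarray(dsd, dtype=float)
    flight = 0.30 - 0.28 * np.exp(-((dsd - 50.0) / 22.0) ** 2)
    forage = 0.25 - 0.15 * np.exp(-((dsd - 45.0) / 25.0) ** 2)
    flt = 1.0 - flight - forage
    return np.stack([flight, flt, forage], axis=-1)


@dataclass
class BoutParams:
    """Mean bout durations (minutes) and the fast forage-interval scale."""

    flight_mean_min: float = 90.0      # sustained dry bout
    float_mean_min: float = 250.0      # sustained wet bout
    forage_bout_mean_min: float = 75.0  # total duration of a forage episode
    forage_interval_mean_min: float = 5.0  # individual wet/dry flips inside it

    def __post_init__(self):
        for name, v in asdict(self).items():
            if v <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class SimConfig:
    """Study conditions for one synthetic cohort."""

    seed: int = 0
    n_birds: int = 20
    colony: tuple = MIDWAY
    departure_date_mean: str = "2008-06-29"
    departure_date_sd_days: float = 16.0
    outbound_days: int = 10
    overwinter_days: int = 125
    inbound_days: int = 9
    transit_speed: float = 300.0       # km/day
    overwinter_speed: float = 60.0     # km/day mean daily displacement
    obs_sd_lon: float = 3.8            # deg
    obs_sd_lat: float = 1.9            # deg
    equinox_lat_inflation: float = 1.0  # multiply lat SD within +/-15 d of equinox
    sampling_interval: int = 90        # s
    bout_params: BoutParams = field(default_factory=BoutParams)
    trend_shape: Callable = default_trend_shape
    pre_days: int = 5
    post_days: int = 5

    def __post_init__(self):
        if self.sampling_interval not in VALID_SAMPLING_INTERVALS:
            raise ValueError(
                f"sampling_interval must be one of {VALID_SAMPLING_INTERVALS}")
        for name in ("outbound_days", "overwinter_days", "inbound_days"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.transit_speed <= 0:
            raise ValueError("transit_speed must be positive")
        if self.overwinter_speed < 0:
            raise ValueError("overwinter_speed must be nonnegative")
        if self.obs_sd_lon < 0 or self.obs_sd_lat < 0:
            raise ValueError("observation SDs must be nonnegative")
        props = np.atleast_2d(self.trend_shape(np.arange(0, 200)))
        if np.any(props < -1e-9) or np.any(props.sum(axis=-1) > 1.0 + 1e-9):
            raise ValueError("trend_shape proportions must be >= 0 and sum to <= 1")

    def rng(self, bird: int, stream: int) -> np.random.Generator:
        """Independent deterministic stream per (seed, bird, purpose)."""
        return np.random.default_rng([self.seed, bird, stream])


@dataclass
class TruePhenology:
    """Ground truth for one simulated bird.

    ``move_start``/``arrival`` bound the actual movement; ``departure`` and
    ``return_date`` are the dates the 720-km criterion first trips on the
    *noiseless* track (the recovery target for detectors working on noisy
    data), and the phase bounds follow the generator's construction.
    """

    bird_id: str
    move_start: pd.Timestamp
    departure: pd.Timestamp
    outbound_end: pd.Timestamp
    overwinter_start: pd.Timestamp
    overwinter_end: pd.Timestamp
    inbound_start: pd.Timestamp
    return_date: pd.Timestamp
    arrival: pd.Timestamp

    def to_json_dict(self):
        return {k: (str(v.date()) if isinstance(v, pd.Timestamp) else v)
                for k, v in asdict(self).items()}


def simulate_track(cfg: SimConfig, bird: int):
    """True daily positions and phenology for one bird.

    Returns ``(track, truth)``: a frame (date, lon, lat, phase) with one row
    per day from ``pre_days`` before movement onset to ``post_days`` after
    colony arrival, and the :class:`TruePhenology`.
    """
    rng = cfg.rng(bird, stream=1)
    dep_offset = rng.normal(0.0, cfg.departure_date_sd_days)
    move_start = (pd.Timestamp(cfg.departure_date_mean)
                  + pd.Timedelta(days=int(round(dep_offset)))).normalize()
    bearing = rng.uniform(285.0, 345.0)  # toward the NW Pacific

    lon, lat = cfg.colony
    pts = [(lon % 360.0, lat)]
    phases = ["pre"]

    # outbound: directed transit with small speed/heading jitter
    for _ in range(cfg.outbound_days):
        speed = cfg.transit_speed * rng.lognormal(0.0, 0.15)
        head = bearing + rng.normal(0.0, 8.0)
        lon, lat = destination_point(pts[-1][0], pts[-1][1], head, speed)
        pts.append((float(lon), float(lat)))
        phases.append("outbound")

    # overwinter: isotropic tangent-plane random walk
    s = cfg.overwinter_speed / np.sqrt(np.pi / 2.0)  # mean |step| = speed
    for _ in range(cfg.overwinter_days):
        dx, dy = rng.normal(0.0, s, size=2)
        dist = float(np.hypot(dx, dy))
        head = float(np.degrees(np.arctan2(dx, dy)) % 360.0)
        lon, lat = destination_point(pts[-1][0], pts[-1][1], head, dist)
        pts.append((float(lon), float(lat)))
        phases.append("overwinter")

    # inbound: directed transit back to the colony
    colony360 = (cfg.colony[0] % 360.0, cfg.colony[1])
    max_inbound = cfg.inbound_days * 4 + 10
    n_in = 0
    while n_in < max_inbound:
        cur = pts[-1]
        d_col = float(great_circle_km(cur[0], cur[1], *colony360))
        speed = cfg.transit_speed * rng.lognormal(0.0, 0.15)
        if d_col <= speed:
            pts.append(colony360)
            phases.append("inbound")
            n_in += 1
            break
        head = float(initial_bearing_deg(cur[0], cur[1], *colony360)) + rng.normal(0.0, 5.0)
        lon, lat = destination_point(cur[0], cur[1], head, speed)
        pts.append((float(lon), float(lat)))
        phases.append("inbound")
        n_in += 1

    for _ in range(cfg.post_days):
        pts.append(colony360)
        phases.append("post")

    start = move_start - pd.Timedelta(days=cfg.pre_days)
    pre = [(colony360[0], colony360[1])] * cfg.pre_days
    pts = pre + pts
    phases = ["pre"] * cfg.pre_days + phases
    dates = pd.date_range(start, periods=len(pts), freq="D")
    arr = np.asarray(pts)
    track = pd.DataFrame({
        "bird_id": f"bird{bird:02d}", "date": dates,
        "lon": wrap180(arr[:, 0]), "lat": arr[:, 1], "phase": phases,
    })

    dist = great_circle_km(arr[:, 0], arr[:, 1], colony360[0], colony360[1])
    phases_arr = np.asarray(phases)
    beyond = dist > DEPARTURE_RADIUS_KM
    dep_i = int(np.argmax(beyond)) if beyond.any() else None
    in_mask = (phases_arr == "inbound") & ~beyond
    ret_i = int(np.argmax(in_mask)) if in_mask.any() else len(dates) - cfg.post_days - 1
    ow = np.flatnonzero(phases_arr == "overwinter")
    inb = np.flatnonzero(phases_arr == "inbound")
    truth = TruePhenology(
        bird_id=f"bird{bird:02d}",
        move_start=dates[cfg.pre_days],
        departure=dates[dep_i] if dep_i is not None else pd.NaT,
        outbound_end=dates[ow[0] - 1],
        overwinter_start=dates[ow[0]],
        overwinter_end=dates[ow[-1]],
        inbound_start=dates[inb[0]],
        return_date=dates[ret_i],
        arrival=dates[inb[-1]],
    )
    return track, truth


def observe_track(track: pd.DataFrame, cfg: SimConfig, bird: int) -> pd.DataFrame:
    """Add independent Gaussian observation noise to a true track.

    Latitude noise is multiplied by ``cfg.equinox_lat_inflation`` for fixes
    within 15 days of the fall equinox of the fix's year (1.0 = no
    degradation). Returns a fixes frame (bird_id, date, lon, lat, equinox_flag).
    """
    rng = cfg.rng(bird, stream=2)
    dates = pd.to_datetime(track["date"])
    n = len(track)
    noise_lon = rng.normal(0.0, cfg.obs_sd_lon, n) if cfg.obs_sd_lon > 0 else np.zeros(n)
    sd_lat = np.full(n, float(cfg.obs_sd_lat))
    eq = {y: fall_equinox(int(y)).normalize() for y in dates.dt.year.unique()}
    off = np.array([(d.normalize() - eq[d.year]).days for d in dates])
    flag = np.abs(off) <= 15
    if cfg.equinox_lat_inflation != 1.0:
        sd_lat = np.where(flag, sd_lat * cfg.equinox_lat_inflation, sd_lat)
    noise_lat = rng.normal(0.0, 1.0, n) * sd_lat if cfg.obs_sd_lat > 0 else np.zeros(n)
    return pd.DataFrame({
        "bird_id": track["bird_id"].values, "date": dates,
        "lon": wrap180(np.asarray(track["lon"], float) + noise_lon),
        "lat": np.clip(np.asarray(track["lat"], float) + noise_lat, -89.9, 89.9),
        "equinox_flag": flag,
    })


# ---------------------------------------------------------------------------
# Immersion series
# ---------------------------------------------------------------------------

def simulate_interval_durations(n: int, p_fast: float, mean_fast_min: float,
                                mean_slow_min: float, seed: int = 0) -> np.ndarray:
    """Draw n interval durations (minutes) from the two-process mixture."""
    rng = np.random.default_rng(seed)
    fast = rng.random(n) < p_fast
    out = np.where(fast, rng.exponential(mean_fast_min, n),
                   rng.exponential(mean_slow_min, n))
    return out


def activity_schedule(cfg: SimConfig, truth: TruePhenology,
                      dates: pd.DatetimeIndex) -> pd.DataFrame:
    """Per-day target (flight, float, forage) proportions along a record.

    Days before movement onset use the trend at DSD 0 and days after arrival
    its final value; in between the configured trend shape applies.
    """
    dsd = (dates.normalize() - truth.move_start).days.values.astype(float)
    span = (truth.arrival - truth.move_start).days
    dsd = np.clip(dsd, 0.0, span)
    props = np.atleast_2d(cfg.trend_shape(dsd))
    return pd.DataFrame({
        "date": dates, "dsd": dsd,
        "flight_target": props[:, 0], "float_target": props[:, 1],
        "forage_target": props[:, 2],
    })


def simulate_immersion(schedule: pd.DataFrame, cfg: SimConfig, bird: int):
    """Wet/dry series built by concatenating bouts to match daily targets.

    At each step the next bout's type is drawn with probability proportional
    to (daily target proportion / mean bout duration), so expected time
    shares track the targets; bout durations are exponential. Forage bouts
    alternate wet and dry sub-intervals from the fast process until the
    bout's drawn duration is filled. Everything is discretized to the tag's
    sampling interval.

    Returns ``(series, labels, bout_truth)``: the :class:`ImmersionSeries`,
    per-sample ground-truth activity codes, and a frame of generated bouts.
    """
    for col in ("flight_target", "float_target", "forage_target"):
        if (schedule[col] < -1e-9).any():
            raise ValueError("negative target proportion")
    if ((schedule[["flight_target", "float_target", "forage_target"]].sum(axis=1))
            > 1.0 + 1e-9).any():
        raise ValueError("daily target proportions sum to > 1")

    rng = cfg.rng(bird, stream=3)
    dt = float(cfg.sampling_interval)
    bp = cfg.bout_params
    day_samples = int(round(86400.0 / dt))
    n_days = len(schedule)
    total = n_days * day_samples

    targets = schedule[["flight_target", "float_target", "forage_target"]].values
    means = np.array([bp.flight_mean_min, bp.float_mean_min, bp.forage_bout_mean_min])

    states = np.empty(total, dtype=np.uint8)
    labels = np.empty(total, dtype=np.uint8)
    bouts = []
    pos = 0
    while pos < total:
        day = min(pos // day_samples, n_days - 1)
        w = targets[day] / means
        if w.sum() <= 0:
            w = np.array([0.0, 1.0, 0.0])
        typ = rng.choice(3, p=w / w.sum())
        dur_min = rng.exponential(means[typ])
        n_samp = max(int(round(dur_min * 60.0 / dt)), 2)
        n_samp = min(n_samp, total - pos)
        if typ == FORAGE_CODE:
            # alternate wet/dry fast intervals inside the bout
            sub = pos
            wet = bool(rng.integers(0, 2))
            while sub < pos + n_samp:
                k = max(int(round(rng.exponential(bp.forage_interval_mean_min)
                                  * 60.0 / dt)), 1)
                k = min(k, pos + n_samp - sub)
                states[sub:sub + k] = 1 if wet else 0
                wet = not wet
                sub += k
        else:
            states[pos:pos + n_samp] = 1 if typ == FLOAT_CODE else 0
        labels[pos:pos + n_samp] = typ
        bouts.append({"type": ACTIVITY_NAMES[typ], "start_sample": pos,
                      "n_samples": n_samp,
                      "duration_min": n_samp * dt / 60.0})
        pos += n_samp

    start = pd.Timestamp(schedule["date"].iloc[0]).normalize()
    series = ImmersionSeries(bird_id=f"bird{bird:02d}", sampling_interval=dt,
                             start=start, states=states)
    return series, labels, pd.DataFrame(bouts)


# ---------------------------------------------------------------------------
# Activity panels for trend modelling
# ---------------------------------------------------------------------------

def simulate_activity_panel(n_birds: int = 20, n_days: int = 145, seed: int = 0,
                            species=("LAAL", "BFAL"),
                            trend_shape: Callable = default_trend_shape,
                            species_flight_shift: float = 0.0,
                            bird_sd: float = 0.35, ar_rho: float = 0.5,
                            ar_sd: float = 0.45,
                            flight_bout_mean_min: float = 90.0,
                            outbound_days: int = 10,
                            inbound_days: int = 9) -> pd.DataFrame:
    """Bird-day activity panel drawn directly around a known trend.

    Flight time arises through a bout mechanism — the day's bout count is
    Poisson with mean (target proportion x 1440 / mean bout length) — so zero-
    flight days (the hurdle's zeros) occur naturally when the target is low.
    Bird-level heterogeneity is a logit-scale random intercept and day-to-day
    noise is AR(1) within bird. ``species_flight_shift`` adds a logit-scale
    flight offset for the second species (0 = species null).
    """
    rng = np.random.default_rng([seed, 11])
    rows = []
    for b in range(n_birds):
        sp = species[b % len(species)]
        b_int = rng.normal(0.0, bird_sd)
        eps = np.empty(n_days)
        eps[0] = rng.normal(0.0, ar_sd)
        for t in range(1, n_days):
            eps[t] = ar_rho * eps[t - 1] + rng.normal(0.0, ar_sd * np.sqrt(1 - ar_rho ** 2))
        dsd = np.arange(n_days)
        props = np.atleast_2d(trend_shape(dsd))
        logit = np.log(np.clip(props, 1e-4, 1 - 1e-4) / (1 - np.clip(props, 1e-4, 1 - 1e-4)))
        shift = species_flight_shift if sp == species[1 % len(species)] else 0.0
        p_flight = 1.0 / (1.0 + np.exp(-(logit[:, 0] + b_int + eps + shift)))
        p_forage = 1.0 / (1.0 + np.exp(-(logit[:, 2] + 0.5 * b_int + 0.5 * eps)))

        n_bouts = rng.poisson(p_flight * 1440.0 / flight_bout_mean_min)
        flight_min = np.where(
            n_bouts > 0,
            rng.gamma(np.maximum(n_bouts, 1), flight_bout_mean_min),
            0.0)
        excl = rng.uniform(0.0, 120.0, n_days)  # midnight-excluded minutes
        flight_min = np.minimum(flight_min, 1440.0 - excl)
        avail = np.maximum(1440.0 - excl - flight_min, 0.0)
        forage_min = np.minimum(p_forage * 1440.0, avail * 0.8)
        float_min = avail - forage_min
        phase = np.where(dsd < outbound_days, "outbound",
                         np.where(dsd >= n_days - inbound_days, "inbound", "overwinter"))
        daily_km = np.where(phase == "outbound", 300.0,
                            np.where(phase == "inbound", 300.0,
                                     60.0 + 140.0 * np.abs(dsd - 50.0) / 95.0))
        daily_km = daily_km * rng.lognormal(0.0, 0.25, n_days)
        rows.append(pd.DataFrame({
            "bird_id": f"bird{b:02d}", "species": sp, "dsd": dsd, "phase": phase,
            "flight_prop": flight_min / 1440.0,
            "float_prop": float_min / 1440.0,
            "forage_prop": forage_min / 1440.0,
            "excluded_min": excl,
            "daily_km": daily_km,
        }))
    panel = pd.concat(rows, ignore_index=True)
    panel["flight_any"] = (panel["flight_prop"] > 0).astype(int)
    return panel


# ---------------------------------------------------------------------------
# Cohorts and file output
# ---------------------------------------------------------------------------

@dataclass
class BirdSim:
    """All simulated streams and truth for one bird."""

    bird_id: str
    truth: TruePhenology
    track: pd.DataFrame
    fixes: pd.DataFrame
    schedule: pd.DataFrame
    series: ImmersionSeries | None = None
    labels: np.ndarray | None = None
    bout_truth: pd.DataFrame | None = None


def simulate_cohort(cfg: SimConfig, with_immersion: bool = False) -> list[BirdSim]:
    """Simulate the full cohort; immersion series are optional (they are the
    bulky stream and many analyses only need tracks)."""
    birds = []
    for b in range(cfg.n_birds):
        track, truth = simulate_track(cfg, b)
        fixes = observe_track(track, cfg, b)
        sched = activity_schedule(cfg, truth, pd.DatetimeIndex(track["date"]))
        sim = BirdSim(bird_id=truth.bird_id, truth=truth, track=track,
                      fixes=fixes, schedule=sched)
        if with_immersion:
            series, labels, bout_truth = simulate_immersion(sched, cfg, b)
            sim.series, sim.labels, sim.bout_truth = series, labels, bout_truth
        birds.append(sim)
    return birds


def write_bird(sim: BirdSim, outdir) -> None:
    """Write one bird's streams as delimited text plus a JSON truth sidecar."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sim.fixes.assign(date=pd.to_datetime(sim.fixes["date"]).dt.date).to_csv(
        outdir / f"{sim.bird_id}_fixes.csv", index=False)
    sim.track.assign(date=pd.to_datetime(sim.track["date"]).dt.date).to_csv(
        outdir / f"{sim.bird_id}_track_true.csv", index=False)
    if sim.series is not None:
        sim.series.to_frame().to_csv(outdir / f"{sim.bird_id}_immersion.csv",
                                     index=False)
    with open(outdir / f"{sim.bird_id}_truth.json", "w") as fh:
        json.dump(sim.truth.to_json_dict(), fh, indent=1)
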