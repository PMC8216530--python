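"""Synthetic tracking, environment and isotope data with the structure the
downstream analyses assume.

Tracks are state-switching correlated random walks from the colony at a
constant 5-minute fix interval: a four-state Markov chain (rest, forage,
travel, relocate) drives per-state speed and turning distributions, and a
colony-attraction term whose weight grows with time-in-trip closes each
excursion.  Environmental layers are smooth harmonic fields plus noise on
the 0.08 degree analysis grid.  Consumer isotope values follow the mixing
forward model from the three prey source groups.

All randomness flows from ``SimConfig.seed`` through spawned child
generators, so the three generators are independently reproducible.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import xarray as xr

from .config import STATES, GroupDesign, SimConfig
from .trajectories import haversine_km, initial_bearing_deg

KM_PER_DEG_LAT = 111.32

SEASON_MONTHS = {"NovMay": (11, 12, 1, 2, 3, 4, 5), "JunOct": (6, 7, 8, 9, 10)}

ENV_VARS = ("SST", "CHLA", "SSH", "OMLT")


@dataclass
class GroundTruth:
    """Generating truth: per-fix state, per-bird trait means, per-group diet."""

    fix_states: pd.DataFrame  # bird_id, trip_id, at_sea, state per fix
    bird_traits: pd.DataFrame  # bird_id, group, true_range_km, true_bearing_deg
    group_diets: pd.DataFrame  # group, source, proportion


def _rngs(config: SimConfig, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(config.seed).spawn(n)]


def stationary_distribution(transitions: np.ndarray) -> np.ndarray:
    """Stationary distribution of a row-stochastic matrix (left eigenvector)."""
    w, v = np.linalg.eig(np.asarray(transitions, float).T)
    i = int(np.argmin(np.abs(w - 1.0)))
    pi = np.real(v[:, i])
    return pi / pi.sum()


def _step_lonlat(lon, lat, dist_km, heading_deg):
    h = np.radians(heading_deg)
    dlat = dist_km * np.cos(h) / KM_PER_DEG_LAT
    dlon = dist_km * np.sin(h) / (KM_PER_DEG_LAT * np.cos(np.radians(lat)))
    return lon + dlon, lat + dlat


def _simulate_trip(
    rng: np.random.Generator,
    config: SimConfig,
    target_range_km: float,
    outbound_bearing: float,
    max_steps: int = 1500,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """One excursion; returns lon, lat arrays (at-sea fixes) and states."""
    clon, clat = config.colony_lonlat
    dt_h = config.fix_interval_min / 60.0
    tmat = np.asarray(config.transitions, float)
    lon, lat = clon, clat
    heading = outbound_bearing
    # Start travelling out; state then evolves by the Markov chain.
    state = 2  # travel
    lons, lats, states = [], [], []
    homing = False
    for step in range(max_steps):
        kin = config.kinematics[STATES[state]]
        # Truncate at drift speed: a bird on the water still moves with the
        # surface current, and an atom at exactly zero would be unphysical.
        speed = max(rng.normal(kin.speed_mean, kin.speed_sd), 0.3)
        turn = rng.vonmises(kin.turn_mu, kin.turn_kappa) * rng.choice([-1.0, 1.0])
        heading = (heading + np.degrees(turn)) % 360.0
        dist_home = haversine_km(lon, lat, clon, clat)
        if not homing and dist_home >= target_range_km:
            homing = True
        # Attraction: outbound toward the foraging axis, inbound toward the
        # colony, with weight ramping up as the trip ages.  Directed states
        # (travel, relocate) feel it much more than rest/forage, so the
        # per-state turning-angle signature survives the trip constraint.
        directed = state in (2, 3)
        if homing:
            attract = initial_bearing_deg(lon, lat, clon, clat)
            w = min(0.25 + 0.01 * step, 0.85) if directed else 0.08
        else:
            attract = outbound_bearing
            w = 0.2 if directed else 0.05
        dh = (attract - heading + 180.0) % 360.0 - 180.0
        heading = (heading + w * dh) % 360.0
        lon, lat = _step_lonlat(lon, lat, speed * dt_h, heading)
        lons.append(lon)
        lats.append(lat)
        states.append(state)
        if homing and haversine_km(lon, lat, clon, clat) <= config.colony_radius_km:
            break
        state = rng.choice(4, p=tmat[state])
    states = np.asarray(states)
    # Report the state DEPARTING each fix (the move to the next fix), which
    # is what per-step (speed, turn) features measure; the final at-sea fix
    # keeps its arriving state.
    dep_states = np.concatenate([states[1:], states[-1:]]) if len(states) else states
    return np.asarray(lons), np.asarray(lats), dep_states


def _group_name(g: GroupDesign) -> str:
    return f"{g.species}_{g.sex}_{g.season}"


def generate_tracks(config: SimConfig) -> tuple[pd.DataFrame, GroundTruth]:
    """Simulate GPS fix streams for every bird of every group.

    Each trip starts and ends inside the colony radius (the bounding fixes
    sit at the colony itself) and runs at the constant fix interval.
    Per-bird foraging-range and bearing preferences are drawn around the
    group means, giving genuinely repeatable trip metrics.
    """
    rng = _rngs(config, 3)[0]
    dt = pd.Timedelta(minutes=config.fix_interval_min)
    clon, clat = config.colony_lonlat
    fix_rows, truth_rows, trait_rows, diet_rows = [], [], [], []
    for g in config.groups:
        gname = _group_name(g)
        for k, src in enumerate(config.source_groups):
            diet_rows.append({"group": gname, "source": src.name, "proportion": g.true_diet[k]})
        months = SEASON_MONTHS[g.season]
        for b in range(g.n_birds):
            bird_id = f"{gname}_b{b:03d}"
            true_range = g.range_km * float(np.exp(rng.normal(0.0, 0.18)))
            true_bearing = g.bearing_deg + float(rng.normal(0.0, 12.0))
            trait_rows.append(
                {
                    "bird_id": bird_id,
                    "group": gname,
                    "species": g.species,
                    "sex": g.sex,
                    "season": g.season,
                    "true_range_km": true_range,
                    "true_bearing_deg": true_bearing % 360.0,
                }
            )
            month = int(rng.choice(months))
            year = 2019 if month < 11 else 2018
            t = pd.Timestamp(year=year, month=month, day=1, hour=6, tz="UTC") + pd.Timedelta(
                hours=float(rng.uniform(0, 48))
            )
            for trip in range(g.trips_per_bird):
                trip_id = f"{bird_id}_trip{trip:02d}"
                rng_trip = np.random.default_rng(rng.integers(2**31))
                trip_range = max(true_range * float(np.exp(rng_trip.normal(0.0, 0.10))), 3.0)
                bearing = true_bearing + float(rng_trip.normal(0.0, 8.0))
                lons, lats, states = _simulate_trip(rng_trip, config, trip_range, bearing % 360.0)
                # colony fix, at-sea fixes, colony fix
                seq_lon = np.concatenate(([clon], lons, [clon]))
                seq_lat = np.concatenate(([clat], lats, [clat]))
                seq_state = np.concatenate(([0], states, [0]))
                at_sea = np.concatenate(([False], np.ones(len(lons), bool), [False]))
                times = t + dt * np.arange(len(seq_lon))
                for i in range(len(seq_lon)):
                    fix_rows.append(
                        {
                            "bird_id": bird_id,
                            "trip_id": trip_id,
                            "timestamp": times[i],
                            "lon": seq_lon[i],
                            "lat": seq_lat[i],
                        }
                    )
                    truth_rows.append(
                        {
                            "bird_id": bird_id,
                            "trip_id": trip_id,
                            "at_sea": bool(at_sea[i]),
                            "state": STATES[int(seq_state[i])],
                        }
                    )
                # Overnight gap at the colony before the next trip.
                t = times[-1] + pd.Timedelta(hours=float(rng.uniform(10, 16)))
    cols = ["bird_id", "trip_id", "timestamp", "lon", "lat"]
    fixes = pd.DataFrame(fix_rows, columns=cols)
    truth = GroundTruth(
        fix_states=pd.DataFrame(truth_rows, columns=["bird_id", "trip_id", "at_sea", "state"]),
        bird_traits=pd.DataFrame(trait_rows),
        group_diets=pd.DataFrame(diet_rows, columns=["group", "source", "proportion"]),
    )
    return fixes, truth


def default_extent(config: SimConfig, pad_deg: float = 1.2) -> tuple[float, float, float, float]:
    """(lon_min, lon_max, lat_min, lat_max) covering the foraging ranges."""
    clon, clat = config.colony_lonlat
    r = max((g.range_km for g in config.groups), default=60.0) / KM_PER_DEG_LAT + pad_deg
    return (clon - r, clon + r, clat - r, clat + r)


def generate_environment(
    extent: tuple[float, float, float, float],
    months,
    config: SimConfig,
    res_deg: float = 0.08,
    constant_fields: bool = False,
) -> xr.Dataset:
    """Static depth plus monthly SST/CHLA/SSH/OMLT layers on the analysis grid.

    Fields are sums of low-order spatial harmonics with a smooth seasonal
    modulation and a little white noise, so moving-window gradients are
    non-trivial.  ``months`` is an iterable of calendar months (or an int
    count mapped to 1..n).  ``constant_fields`` yields spatially flat layers
    (gradient must then be zero downstream).  Same seed, same arrays.
    """
    if isinstance(months, int):
        if months < 1:
            raise ValueError("months must be >= 1")
        months = list(range(1, months + 1))
    months = [int(m) for m in months]
    if not months:
        raise ValueError("months must be non-empty")
    lon0, lon1, lat0, lat1 = extent
    if not (lon1 > lon0 and lat1 > lat0):
        raise ValueError("degenerate extent")
    rng = _rngs(config, 3)[1]
    lon = np.arange(lon0 + res_deg / 2, lon1, res_deg)
    lat = np.arange(lat0 + res_deg / 2, lat1, res_deg)
    LON, LAT = np.meshgrid(lon, lat)
    u = (LON - lon.mean()) / max(lon1 - lon0, 1e-9)
    v = (LAT - lat.mean()) / max(lat1 - lat0, 1e-9)

    def field(base, amp, kx, ky, phase, noise_sd):
        if constant_fields:
            return np.full_like(LON, base)
        f = base + amp * (
            np.sin(2 * np.pi * (kx * u + phase)) * np.cos(2 * np.pi * ky * v)
            + 0.5 * np.cos(2 * np.pi * (kx * v - phase))
        )
        return f + rng.normal(0.0, noise_sd, LON.shape)

    depth = np.abs(field(3000.0, 1500.0, 1.3, 0.8, 0.1, 25.0))
    data = {"DEP": (("lat", "lon"), depth)}
    season_amp = {m: 1.0 + 0.3 * np.sin(2 * np.pi * (m - 1) / 12.0) for m in months}
    spec = {  # base, amplitude, kx, ky, noise
        "SST": (24.0, 2.0, 1.0, 1.2, 0.05),
        "CHLA": (0.35, 0.25, 1.7, 1.1, 0.01),
        "SSH": (0.3, 0.25, 0.9, 1.4, 0.005),
        "OMLT": (35.0, 15.0, 1.2, 0.7, 0.5),
    }
    for name, (base, amp, kx, ky, nsd) in spec.items():
        layers = [field(base, amp * season_amp[m], kx, ky, 0.05 * m, nsd) for m in months]
        arr = np.stack(layers)
        if name in ("CHLA", "OMLT"):
            arr = np.abs(arr)
        data[name] = (("month", "lat", "lon"), arr)
    ds = xr.Dataset(data, coords={"lon": lon, "lat": lat, "month": months})
    ds.attrs["res_deg"] = res_deg
    return ds


def generate_isotopes(config: SimConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Consumer plasma and prey muscle isotope tables.

    Prey samples are drawn from each source group's bivariate normal
    moments.  Consumers follow the mixing forward model with the group's
    true diet p: mean_j = sum_k p_k (mu_kj + c_j) and variance_j =
    sum_k p_k^2 (sigma_kj^2 + sigma_c,j^2) + epsilon^2, where c is the
    diet–tissue discrimination factor.
    """
    if not config.source_groups:
        raise ValueError("source_groups must be non-empty")
    rng = _rngs(config, 3)[2]
    prey_rows = []
    for src in config.source_groups:
        d13 = rng.normal(src.mean_d13c, src.sd_d13c, src.n)
        d15 = rng.normal(src.mean_d15n, src.sd_d15n, src.n)
        for i in range(src.n):
            prey_rows.append(
                {"source": src.name, "sample_id": f"{src.name}_{i:03d}", "d13C": d13[i], "d15N": d15[i]}
            )
    prey = pd.DataFrame(prey_rows, columns=["source", "sample_id", "d13C", "d15N"])

    tef = config.tef
    mu = np.array([[s.mean_d13c, s.mean_d15n] for s in config.source_groups])
    sd = np.array([[s.sd_d13c, s.sd_d15n] for s in config.source_groups])
    c = np.array([tef.mean_d13c, tef.mean_d15n])
    c_sd = np.array([tef.sd_d13c, tef.sd_d15n])
    consumer_rows = []
    for g in config.groups:
        p = np.asarray(g.true_diet, float)
        mean = p @ (mu + c)
        var = (p**2) @ (sd**2 + c_sd**2) + config.epsilon**2
        for b in range(g.n_birds):
            draw = rng.normal(mean, np.sqrt(var))
            consumer_rows.append(
                {
                    "individual": f"{_group_name(g)}_b{b:03d}",
                    "species": g.species,
                    "sex": g.sex,
                    "season": g.season,
                    "group": _group_name(g),
                    "d13C": draw[0],
                    "d15N": draw[1],
                }
            )
    consumers = pd.DataFrame(
        consumer_rows,
        columns=["individual", "species", "sex", "season", "group", "d13C", "d15N"],
    )
    return consumers, prey


def generate_morphometrics(config: SimConfig, seed_offset: int = 17) -> pd.DataFrame:
    """Wing length (mm) and body mass (g) per bird, for the condition index.

    Mass scales linearly with wing length within species plus individual
    scatter; females of both species are the larger sex.
    """
    rng = np.random.default_rng(np.random.SeedSequence(config.seed + seed_offset))
    rows = []
    base = {"BRBO": (400.0, 1250.0, 4.5), "RFBO": (380.0, 1040.0, 4.0)}
    for g in config.groups:
        wing_mu, mass_mu, slope = base.get(g.species, (390.0, 1100.0, 4.2))
        sex_shift = 25.0 if g.sex == "F" else -25.0
        for b in range(g.n_birds):
            wing = rng.normal(wing_mu + sex_shift, 8.0)
            mass = mass_mu + slope * (wing - wing_mu) + rng.normal(0.0, 60.0)
            rows.append(
                {
                    "bird_id": f"{_group_name(g)}_b{b:03d}",
                    "species": g.species,
                    "sex": g.sex,
                    "season": g.season,
                    "wing_mm": wing,
                    "mass_g": mass,
                }
            )
    return pd.DataFrame(rows)
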