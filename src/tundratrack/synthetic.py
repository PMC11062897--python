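"""Synthetic tundra landscapes and ground-truthed hare trajectories.

The generator emulates the study system the analysis is designed for: a
low-productivity polar-desert landscape (sparse vegetation patches, rugged
relief, scattered lakes) over which ~25 individuals are tracked with daily
Argos fixes for about a year. Each simulated animal holds a summer
residency, then (with high probability) relocates ~100 km to a winter
ground, alternating stopover and traveling behavior driven by a two-state
Markov chain with gamma step lengths and wrapped Cauchy turns, and finally
holds a winter residency. Argos observation error is isotropic bivariate
normal with a root-mean-square radial error equal to the nominal class
radius (250/500/1500 m for classes 3/2/1; class A, which carries no error
estimate, is treated as 1500 m).

Everything is reproducible from a single integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .hmm import HmmParameters, sample_wrapped_cauchy, wrap_angle
from .raster import Raster

__all__ = [
    "ARGOS_ERROR_RADII",
    "VegParams",
    "ReliefParams",
    "WaterParams",
    "RelocationParams",
    "LandscapeBundle",
    "TrueTrack",
    "default_hmm_params",
    "make_landscape",
    "simulate_state_sequence",
    "simulate_tracks",
    "apply_argos_error",
    "write_tracks_csv",
    "read_tracks_csv",
]

#: Nominal isotropic error radius (m) per Argos location class.
ARGOS_ERROR_RADII = {"3": 250.0, "2": 500.0, "1": 1500.0, "A": 1500.0}

DEFAULT_CLASS_PROBS = {"3": 0.25, "2": 0.25, "1": 0.25, "A": 0.25}


@dataclass
class VegParams:
    """Vegetation-index surface.

    A smooth Gaussian random field (correlation range ``range_m``,
    variance ``sill``) carries the broad productivity gradient; on top of
    it a fine-scale patchiness component (range ``het_range_m``, sd
    ``het_sd``) whose local amplitude is modulated by a third smooth field
    (range ``het_mod_range_m``) emulates mosaics of vegetation patches
    whose heterogeneity itself varies across the landscape — what a
    local SAVI standard deviation measures. The sum is shifted to ``mean``
    and clipped to [0, vmax]; defaults give a sparse polar-desert surface
    (mean 0.15, broad-scale sd 0.1)."""

    range_m: float = 5000.0
    sill: float = 0.004
    mean: float = 0.2
    vmax: float = 0.6
    het_sd: float = 0.05
    het_range_m: float = 100.0
    het_mod_range_m: float = 2000.0


@dataclass
class ReliefParams:
    """Smooth correlated elevation surface: base elevation plus a Gaussian
    random field of sd ``amplitude`` (m) and range ``range_m``; clipped at
    sea level."""

    range_m: float = 8000.0
    amplitude: float = 200.0
    base: float = 400.0


@dataclass
class WaterParams:
    """Lakes drawn as random ellipses until ``fraction`` of the area is
    covered."""

    fraction: float = 0.03
    mean_radius_m: float = 500.0


@dataclass
class RelocationParams:
    """Fall-relocation regime.

    fraction_relocating : probability an individual relocates (21 of the 25
        tracked hares did)
    departure_window_days : (earliest, latest) departure day, counted from
        track start (mid-June), i.e. departures late Aug-late Sep
    goal_distance_m : straight-line displacement to the winter ground
    arrive_radius_m : relocation ends when within this radius of the goal
    max_days : hard cap on relocation duration
    """

    fraction_relocating: float = 21 / 25
    departure_window_days: tuple[int, int] = (70, 100)
    goal_distance_m: float = 100_000.0
    arrive_radius_m: float = 4000.0
    max_days: int = 60
    #: optional habitat-dependent stopping: additive effects (logit scale,
    #: per landscape-wide sd of the local field) on the probability that
    #: the next relocation day is a stopover. Keys: 'SAVI_mean', 'SAVI_sd'.
    stopover_logit_effects: dict | None = None
    #: scale of the local field the stopping decision responds to —
    #: patch-mosaic heterogeneity, the scale the error-radius buffers
    #: measure
    selection_window_m: float = 1500.0


@dataclass
class LandscapeBundle:
    """Co-registered environmental rasters."""

    veg_index: Raster
    dem: Raster
    water_mask: Raster
    nir: Raster | None = None
    red: Raster | None = None

    def __post_init__(self) -> None:
        for r in (self.dem, self.water_mask, self.nir, self.red):
            if r is not None and not self.veg_index.same_grid(r):
                raise ValueError("landscape rasters must share grid geometry")


@dataclass
class TrueTrack:
    """Ground-truth daily positions and behavioral states of one animal."""

    individual_id: str
    day: np.ndarray           # day index from track start
    x: np.ndarray             # m
    y: np.ndarray             # m
    state: np.ndarray         # 1 = stopover/resident, 2 = traveling
    phase: np.ndarray         # 'summer' | 'relocation' | 'winter'
    start_date: pd.Timestamp = field(
        default_factory=lambda: pd.Timestamp("2019-06-15"))
    clipped: np.ndarray | None = None  # True where clipped to the landscape

    def timestamps(self) -> pd.DatetimeIndex:
        return self.start_date + pd.to_timedelta(self.day, unit="D") \
            + pd.Timedelta(hours=12)


def default_hmm_params() -> HmmParameters:
    """Movement kernel in the regime of relocating hares: short weakly
    directed stopover steps vs long persistent traveling steps (km/day).
    The transition matrix has stationary distribution (2/3, 1/3), matching
    a relocation budget of about twice as much time at stopovers as spent
    traveling, with mean bout lengths of 5 (stopover) and 2.5 (travel)
    days."""
    return HmmParameters(
        step_mean=[0.4, 6.0],
        step_sd=[0.4, 3.0],
        angle_mean=[0.0, 0.0],
        angle_conc=[0.2, 0.8],
        tpm=[[0.8, 0.2], [0.4, 0.6]],
        delta=[0.5, 0.5],
    )


# ---------------------------------------------------------------------------
# Landscape
# ---------------------------------------------------------------------------

def _gaussian_field(rng: np.random.Generator, shape, sigma_cells: float
                    ) -> np.ndarray:
    """White noise smoothed by a Gaussian kernel, standardized to zero mean
    and unit variance over the grid."""
    z = rng.standard_normal(shape)
    if sigma_cells > 0:
        z = gaussian_filter(z, sigma=sigma_cells, mode="reflect")
    sd = z.std()
    if sd > 0:
        z = (z - z.mean()) / sd
    else:
        z = np.zeros_like(z)
    return z


def make_landscape(seed, extent_m=(60_000.0, 60_000.0), cell_size=100.0,
                   veg_params: VegParams | None = None,
                   relief_params: ReliefParams | None = None,
                   water_params: WaterParams | None = None,
                   reflectance: bool = True) -> LandscapeBundle:
    """Generate a co-registered landscape bundle.

    The vegetation index and DEM are Gaussian random fields (white noise
    filtered with a Gaussian kernel whose sd is half the stated correlation
    range); lakes are random ellipses accumulated until the requested areal
    fraction is reached. Water cells are nodata in the vegetation index.
    When ``reflectance`` is set, NIR and Red bands consistent with the
    vegetation index under the soil-adjusted formula (L = 0.5, Red fixed at
    0.1) are included.
    """
    vp = veg_params or VegParams()
    rp = relief_params or ReliefParams()
    wp = water_params or WaterParams()
    ex, ey = float(extent_m[0]), float(extent_m[1])
    if ex <= 0 or ey <= 0:
        raise ValueError("landscape extent must be positive")
    if cell_size <= 0:
        raise ValueError("cell_size must be > 0")
    n_cols = max(1, int(round(ex / cell_size)))
    n_rows = max(1, int(round(ey / cell_size)))
    rng = np.random.default_rng(seed)
    grid = dict(origin_x=0.0, origin_y=n_rows * cell_size,
                cell_size=cell_size)

    z = _gaussian_field(rng, (n_rows, n_cols), vp.range_m / (2 * cell_size))
    veg = vp.mean + np.sqrt(vp.sill) * z
    if vp.het_sd > 0:
        fine = _gaussian_field(rng, (n_rows, n_cols),
                               vp.het_range_m / (2 * cell_size))
        mod = _gaussian_field(rng, (n_rows, n_cols),
                              vp.het_mod_range_m / (2 * cell_size))
        # positive amplitude with mean ~1: patchiness varies across space
        amp = np.log1p(np.exp(mod)) / np.log(2.0)
        veg = veg + vp.het_sd * amp * fine
    veg = np.clip(veg, 0.0, vp.vmax)

    if rp.amplitude > 0:
        zd = _gaussian_field(rng, (n_rows, n_cols),
                             rp.range_m / (2 * cell_size))
        dem = np.maximum(rp.base + rp.amplitude * zd, 0.0)
    else:
        dem = np.full((n_rows, n_cols), float(rp.base))

    water = np.zeros((n_rows, n_cols), dtype=bool)
    if wp.fraction > 0:
        xs = (np.arange(n_cols) + 0.5) * cell_size
        ys = (np.arange(n_rows) + 0.5) * cell_size  # y up from the south edge
        target = wp.fraction * n_rows * n_cols
        covered = 0
        for _ in range(100_000):
            if covered >= target:
                break
            cx, cy = rng.uniform(0, ex), rng.uniform(0, ey)
            a = wp.mean_radius_m * rng.lognormal(0.0, 0.4)
            b = a * rng.uniform(0.4, 1.0)
            ang = rng.uniform(0, np.pi)
            j0, j1 = np.searchsorted(xs, (cx - a, cx + a))
            i0, i1 = np.searchsorted(ys, (cy - a, cy + a))
            if j0 >= j1 or i0 >= i1:
                continue
            Xl, Yl = np.meshgrid(xs[j0:j1], ys[i0:i1])
            dx, dy = Xl - cx, Yl - cy
            u = dx * np.cos(ang) + dy * np.sin(ang)
            v = -dx * np.sin(ang) + dy * np.cos(ang)
            ell = (u / a) ** 2 + (v / b) ** 2 <= 1.0
            # rows count from the north edge
            rows = slice(n_rows - i1, n_rows - i0)
            win = water[rows, j0:j1][::-1]
            covered += int((ell & ~win).sum())
            water[rows, j0:j1] |= ell[::-1]

    veg = np.where(water, np.nan, veg)
    bundle = LandscapeBundle(
        veg_index=Raster(veg, **grid),
        dem=Raster(dem, **grid),
        water_mask=Raster(water.astype(float), categorical=True, **grid),
    )
    if reflectance:
        red = np.full((n_rows, n_cols), 0.1)
        # invert SAVI = (nir-red)(1+L)/(nir+red+L) for L=0.5, red=0.1
        nir = (0.15 + 0.6 * bundle.veg_index.values) / \
            (1.5 - bundle.veg_index.values)
        bundle.nir = Raster(nir, **grid)
        bundle.red = Raster(np.where(water, np.nan, red), **grid)
    return bundle


# ---------------------------------------------------------------------------
# Trajectories
# ---------------------------------------------------------------------------

def _selection_fields(landscape: LandscapeBundle, effects: dict,
                      window_m: float) -> dict[str, Raster]:
    """Moving-window local habitat fields, z-scored landscape-wide, for
    habitat-dependent stopping."""
    from scipy.ndimage import uniform_filter

    veg = landscape.veg_index
    v = veg.values.copy()
    fill = np.nanmean(v)
    v = np.where(np.isnan(v), fill, v)
    size = max(3, 2 * int(round(window_m / veg.cell_size)) + 1)
    m1 = uniform_filter(v, size=size, mode="nearest")
    m2 = uniform_filter(v * v, size=size, mode="nearest")
    local_sd = np.sqrt(np.maximum(m2 - m1**2, 0.0))
    fields = {"SAVI_mean": m1, "SAVI_sd": local_sd}
    out = {}
    for name in effects:
        if name not in fields:
            raise ValueError(f"unsupported stopping covariate {name!r}")
        f = fields[name]
        z = (f - f.mean()) / f.std()
        out[name] = veg.copy_with(z)
    return out


def simulate_state_sequence(rng: np.random.Generator, tpm: np.ndarray,
                            n_days: int, start_state: int = 2) -> np.ndarray:
    """Simulate a 1-based Markov state sequence."""
    tpm = np.asarray(tpm, dtype=float)
    if np.any(tpm < 0) or not np.allclose(tpm.sum(axis=1), 1.0, atol=1e-8):
        raise ValueError("transition matrix rows must sum to 1")
    states = np.empty(n_days, dtype=int)
    s = start_state - 1
    for t in range(n_days):
        states[t] = s + 1
        s = rng.choice(tpm.shape[0], p=tpm[s])
    return states


def _gamma_step_m(rng, params: HmmParameters, state: int) -> float:
    j = state - 1
    return 1000.0 * rng.gamma(shape=params.gamma_shape[j],
                              scale=params.gamma_scale[j])


def _clip_to(landscape: LandscapeBundle, x: float, y: float
             ) -> tuple[float, float, bool]:
    xmin, ymin, xmax, ymax = landscape.veg_index.extent
    m = landscape.veg_index.cell_size
    cx = min(max(x, xmin + m), xmax - m)
    cy = min(max(y, ymin + m), ymax - m)
    return cx, cy, (cx != x or cy != y)


def _weighted_site(rng, candidates_xy, zvals, beta):
    """Pick one site among candidates with probability proportional to
    exp(beta * z); NaN covariates (water, off-map) get zero weight."""
    z = np.where(np.isfinite(zvals), zvals, -np.inf if beta > 0 else np.inf)
    w = np.exp(beta * z - np.nanmax(beta * z))
    w[~np.isfinite(w)] = 0.0
    if w.sum() == 0:
        w = np.ones(len(w))
    k = rng.choice(len(w), p=w / w.sum())
    return candidates_xy[0][k], candidates_xy[1][k]


def simulate_tracks(seed, landscape: LandscapeBundle,
                    n_individuals: int = 25,
                    hmm_params: HmmParameters | None = None,
                    relocation_params: RelocationParams | None = None,
                    n_days: int = 365,
                    home_radius_m: float = 1500.0,
                    summer_elevation_beta: float = -1.0,
                    winter_savi_beta: float = 1.0,
                    n_site_candidates: int = 100) -> list[TrueTrack]:
    """Simulate daily ground-truth tracks over a landscape.

    Residency phases are state-1 movement tethered to a range center (the
    heading turns toward the center whenever the animal strays beyond
    ``home_radius_m``). During relocation the behavioral state follows the
    Markov chain of ``hmm_params``; within-state step-length and turn
    distributions are kept intact, and the directional pull to the winter
    goal enters only through the traveling state's heading, which is drawn
    around the bearing to the goal.

    Residency sites embody the seasonal selection the landscape is built
    to test: each summer center is drawn from candidate sites weighted by
    exp(summer_elevation_beta * z(elevation)) — low ground preferred by
    default — and each winter goal from candidates around the nominal
    ~100 km displacement weighted by exp(winter_savi_beta * z(SAVI)) —
    vegetation-rich ground preferred. Setting both betas to 0 removes
    residency selection.
    """
    hp = hmm_params or default_hmm_params()
    rp = relocation_params or RelocationParams()
    rng = np.random.default_rng(seed)
    xmin, ymin, xmax, ymax = landscape.veg_index.extent
    sel_fields = None
    if rp.stopover_logit_effects:
        sel_fields = _selection_fields(landscape, rp.stopover_logit_effects,
                                       rp.selection_window_m)
    dem_z = landscape.dem.copy_with(
        (landscape.dem.values - np.nanmean(landscape.dem.values))
        / np.nanstd(landscape.dem.values))
    # winter sites are chosen by neighborhood-scale vegetation (the scale
    # of a home range), not the 1-cell value, so range means carry the
    # designed contrast
    veg = landscape.veg_index
    vfill = np.where(np.isnan(veg.values), np.nanmean(veg.values),
                     veg.values)
    vsm = gaussian_filter(vfill, sigma=2000.0 / veg.cell_size,
                          mode="nearest")
    veg_z = veg.copy_with((vsm - vsm.mean()) / vsm.std())
    tracks = []
    for i in range(n_individuals):
        # summer centers in the northern band, low elevation preferred
        cxs = rng.uniform(xmin + 0.1 * (xmax - xmin),
                          xmax - 0.1 * (xmax - xmin), n_site_candidates)
        cys = rng.uniform(ymax - 0.18 * (ymax - ymin),
                          ymax - 0.04 * (ymax - ymin), n_site_candidates)
        cx, cy = _weighted_site(rng, (cxs, cys),
                                dem_z.sample(cxs, cys, "nearest"),
                                summer_elevation_beta)
        relocates = rng.uniform() < rp.fraction_relocating
        depart = int(rng.integers(rp.departure_window_days[0],
                                  rp.departure_window_days[1] + 1))
        # winter goal ~goal_distance away, vegetation-rich ground preferred
        bearings = -np.pi / 2 + rng.normal(0.0, 0.25, n_site_candidates)
        dists = rp.goal_distance_m * rng.uniform(0.85, 1.15,
                                                 n_site_candidates)
        gxs = np.clip(cx + dists * np.cos(bearings), xmin + 1000,
                      xmax - 1000)
        gys = np.clip(cy + dists * np.sin(bearings), ymin + 1000,
                      ymax - 1000)
        gx, gy = _weighted_site(rng, (gxs, gys),
                                veg_z.sample(gxs, gys, "nearest"),
                                winter_savi_beta)

        x = np.empty(n_days); y = np.empty(n_days)
        state = np.ones(n_days, dtype=int)
        phase = np.empty(n_days, dtype=object)
        clipped = np.zeros(n_days, dtype=bool)
        x[0], y[0] = cx + rng.normal(0, 300), cy + rng.normal(0, 300)
        phase[0] = "summer"
        heading = rng.uniform(-np.pi, np.pi)
        mode = "summer"
        center = (cx, cy)
        cur_state = 1
        for t in range(1, n_days):
            if mode == "summer" and relocates and t >= depart:
                mode = "relocation"
                cur_state = 2
                reloc_start = t
            if mode == "relocation":
                dist_goal = np.hypot(gx - x[t - 1], gy - y[t - 1])
                if dist_goal < rp.arrive_radius_m or \
                        t - reloc_start >= rp.max_days:
                    mode = "winter"
                    center = (x[t - 1], y[t - 1])
                    cur_state = 1
            phase[t] = mode
            if mode in ("summer", "winter"):
                cur_state = 1
                step = _gamma_step_m(rng, hp, 1)
                d = np.hypot(center[0] - x[t - 1], center[1] - y[t - 1])
                if d > home_radius_m:
                    heading = np.arctan2(center[1] - y[t - 1],
                                         center[0] - x[t - 1]) \
                        + sample_wrapped_cauchy(rng, 0.0, 0.5)
                else:
                    heading = wrap_angle(heading + sample_wrapped_cauchy(
                        rng, hp.angle_mean[0], hp.angle_conc[0]))
            else:
                if t > reloc_start:  # advance the behavioral chain
                    p_stop = hp.tpm[cur_state - 1][0]
                    if sel_fields is not None:
                        from scipy.special import expit, logit
                        tilt = 0.0
                        for name, eff in rp.stopover_logit_effects.items():
                            z = sel_fields[name].sample(x[t - 1], y[t - 1],
                                                        method="nearest")
                            if np.isfinite(z):
                                tilt += eff * z
                        p_stop = float(expit(logit(np.clip(
                            p_stop, 1e-6, 1 - 1e-6)) + tilt))
                    cur_state = 1 if rng.uniform() < p_stop else 2
                step = _gamma_step_m(rng, hp, cur_state)
                if cur_state == 2:
                    to_goal = np.arctan2(gy - y[t - 1], gx - x[t - 1])
                    heading = sample_wrapped_cauchy(
                        rng, to_goal, hp.angle_conc[1])
                else:
                    heading = wrap_angle(heading + sample_wrapped_cauchy(
                        rng, hp.angle_mean[0], hp.angle_conc[0]))
            state[t] = cur_state if mode == "relocation" else 1
            nx = x[t - 1] + step * np.cos(heading)
            ny = y[t - 1] + step * np.sin(heading)
            x[t], y[t], clipped[t] = _clip_to(landscape, nx, ny)
        state[phase == "summer"] = 1
        tracks.append(TrueTrack(
            individual_id=f"hare{i + 1:02d}", day=np.arange(n_days),
            x=x, y=y, state=state, phase=phase.astype(str), clipped=clipped))
    return tracks


def apply_argos_error(seed, track: TrueTrack,
                      class_probs: dict[str, float] | None = None,
                      missing_rate: float = 0.09,
                      noise_scale: float = 1.0) -> pd.DataFrame:
    """Degrade a true track into Argos-like telemetry.

    Each retained day draws a location class and perturbs the position with
    isotropic bivariate normal noise whose per-axis sd is radius/sqrt(2), so
    the RMS radial error equals the class's nominal radius. A fraction of
    days (default 9%, the regime of the real collars) is dropped at random;
    the first and last day are always kept so phase intervals stay anchored.
    """
    probs = dict(DEFAULT_CLASS_PROBS if class_probs is None else class_probs)
    classes = list(probs)
    p = np.array([probs[c] for c in classes], dtype=float)
    if abs(p.sum() - 1.0) > 1e-8:
        raise ValueError("Argos class probabilities must sum to 1")
    unknown = set(classes) - set(ARGOS_ERROR_RADII)
    if unknown:
        raise ValueError(f"unknown Argos classes {sorted(unknown)}")
    rng = np.random.default_rng(seed)
    n = len(track.day)
    keep = rng.uniform(size=n) >= missing_rate
    keep[0] = keep[-1] = True
    idx = np.flatnonzero(keep)
    drawn = rng.choice(len(classes), size=len(idx), p=p)
    cls = np.array([classes[k] for k in drawn])
    radii = np.array([ARGOS_ERROR_RADII[c] for c in cls])
    sd = radii / np.sqrt(2.0) * noise_scale
    return pd.DataFrame({
        "individual_id": track.individual_id,
        "timestamp": track.timestamps()[idx],
        "x": track.x[idx] + rng.normal(0, 1, size=len(idx)) * sd,
        "y": track.y[idx] + rng.normal(0, 1, size=len(idx)) * sd,
        "argos_class": cls,
        "error_radius": radii,
        "interpolated": False,
        "true_state": track.state[idx],
        "phase": track.phase[idx],
    })


def write_tracks_csv(frames, path: str | Path) -> None:
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_tracks_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, parse_dates=["timestamp"],
                     dtype={"argos_class": str, "individual_id": str})
    return df
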