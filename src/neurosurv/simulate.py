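"""Synthetic single-neuron survival experiments with exact ground truth.

Generates neuron fates from a proportional-hazards model
``h(t | x) = h0(t) * exp(beta_group + gamma * z(t))`` with a Weibull (or
exponential) baseline and a piecewise-constant standardized reporter
level ``z(t)``, then renders each imaging field as a two-channel noisy
time-lapse stack (red: construct expression, green: stress reporter).

Death times are drawn exactly by inverse-transform sampling of the
piecewise cumulative hazard; neurons still alive at the end of follow-up
are right-censored.  The green trajectory of a configurable fraction of
dying neurons ramps up ahead of death (anticipatory stress surge); the
surge is applied after death times are drawn, so the hazard acts on the
basal + drift trajectory only.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .design import ConfigurationError, ExperimentDesign, HazardModel, ImagingModel

__all__ = [
    "GroundTruth",
    "MovieStack",
    "PlacementError",
    "simulate_fates",
    "render_movie",
    "render_experiment",
    "write_truth_tables",
    "read_truth_tables",
    "write_layout",
    "write_movie",
    "read_movie",
    "truth_to_fates",
    "gamma_for_quartile_hr",
    "simulate_crossing_fates",
    "snr_to_intensity",
]

FATE_COLUMNS = [
    "neuron_id", "plate", "well", "field", "group",
    "x", "y", "death_time_h", "censored",
]
TRAJ_COLUMNS = ["neuron_id", "frame", "time_h", "red_true", "green_true"]

# mean of a standard normal within its outer quartiles: phi(q75) / 0.25
_QUARTILE_TAIL_MEAN = float(
    np.exp(-0.5 * 0.6744897501960817**2) / np.sqrt(2 * np.pi) / 0.25
)


class PlacementError(RuntimeError):
    """Neuron centers cannot be placed at the required separation."""


@dataclass
class GroundTruth:
    """Simulator output: one fate row per neuron, one trajectory row per
    neuron x frame while alive, plus the design that produced them."""

    fates: pd.DataFrame
    trajectories: pd.DataFrame
    design: ExperimentDesign

    def field_truth(self, plate: int, well: int, field: int) -> "GroundTruth":
        f = self.fates
        sel = (f["plate"] == plate) & (f["well"] == well) & (f["field"] == field)
        ids = f.loc[sel, "neuron_id"]
        return GroundTruth(
            fates=f.loc[sel].reset_index(drop=True),
            trajectories=self.trajectories[
                self.trajectories["neuron_id"].isin(ids)
            ].reset_index(drop=True),
            design=self.design,
        )


@dataclass
class MovieStack:
    """One field's time-ordered two-channel frames plus metadata."""

    red: np.ndarray      # (T, H, W) float
    green: np.ndarray    # (T, H, W) float
    times: np.ndarray    # hours
    plate: int = 0
    well: int = 0
    field: int = 0


def gamma_for_quartile_hr(target_hr: float) -> float:
    """Reporter log-HR per unit z inducing ``target_hr`` between the top and
    bottom quartile of a standard-normal reporter distribution.

    Uses the mean of z in the outer quartiles (+-1.2711), so the contrast
    between mean Q4 and mean Q1 hazard equals the target.
    """
    if target_hr <= 0:
        raise ConfigurationError("target_hr must be > 0")
    return float(np.log(target_hr) / (2.0 * _QUARTILE_TAIL_MEAN))


def _place_centers(n: int, shape: tuple[int, int], min_sep: float,
                   rng: np.random.Generator, max_tries: int = 20000) -> np.ndarray:
    """Rejection-sample n centers >= min_sep apart, min_sep from borders."""
    h, w = shape
    margin = min_sep
    if w - 2 * margin <= 0 or h - 2 * margin <= 0:
        raise PlacementError("image too small for the requested separation")
    pts: list[np.ndarray] = []
    tries = 0
    while len(pts) < n:
        cand = np.array([rng.uniform(margin, w - margin),
                         rng.uniform(margin, h - margin)])
        if all(np.hypot(*(cand - p)) >= min_sep for p in pts):
            pts.append(cand)
        tries += 1
        if tries > max_tries:
            raise PlacementError(
                f"could not place {n} neurons at separation {min_sep} "
                f"in a {shape} image"
            )
    return np.array(pts)


def simulate_fates(
    design: ExperimentDesign,
    model: HazardModel,
    seed: int,
    imaging: ImagingModel | None = None,
    place: bool = True,
) -> GroundTruth:
    """Draw per-neuron death/censoring times and true fluorescence
    trajectories for a whole experiment.

    The hazard for neuron i is ``h0(t) * exp(b_g + u_well + gamma * z_i(t))``
    with ``z_i(t)`` the standardized log green level, held constant within
    each inter-frame interval.  Inverse-transform sampling against a unit
    exponential draw gives exact continuous death times; neurons whose
    cumulative hazard at end of follow-up falls short are censored.

    With ``place=False`` neuron centers are skipped (statistics-only runs).
    """
    rng = np.random.default_rng(seed)
    groups = design.groups
    for g, b in model.group_log_hr.items():
        if g not in groups:
            raise ConfigurationError(f"group_log_hr refers to unknown group {g!r}")
    rep = model.reporter
    for g in rep.green_rise_per_h:
        if g not in groups:
            raise ConfigurationError(f"green_rise_per_h refers to unknown group {g!r}")

    times = design.frame_times
    n = design.n_neurons
    plates = np.repeat(np.arange(design.plates),
                       design.wells_per_plate * design.fields_per_well * design.neurons_per_field)
    wells = np.tile(np.repeat(np.arange(design.wells_per_plate),
                              design.fields_per_well * design.neurons_per_field),
                    design.plates)
    fields_ = np.tile(np.repeat(np.arange(design.fields_per_well), design.neurons_per_field),
                      design.plates * design.wells_per_plate)
    group = np.array([design.group_of_well[w] for w in wells])

    beta_g = np.array([model.group_log_hr.get(g, 0.0) for g in group])
    if model.well_frailty_sd > 0:
        fr = rng.normal(0.0, model.well_frailty_sd,
                        size=(design.plates, design.wells_per_plate))
        beta_g = beta_g + fr[plates, wells]

    # latent per-cell log-levels
    u_green = rng.standard_normal(n)
    u_red = rng.standard_normal(n)
    rise = np.array([rep.green_rise_per_h.get(g, 0.0) for g in group])

    # z(t) on the frame grid: standardized log green (pre-surge)
    z = u_green[:, None] + (rise[:, None] * times[None, :]) / rep.cell_sd_log
    eta = beta_g[:, None] + model.reporter_log_hr * z  # (n, T)

    h0 = model.cumulative_baseline(times)
    dh0 = np.diff(h0)                        # (T-1,) per-interval baseline increments
    inc = dh0[None, :] * np.exp(eta[:, :-1])  # hazard increment per interval
    cum = np.concatenate([np.zeros((n, 1)), np.cumsum(inc, axis=1)], axis=1)  # (n, T)

    e_draw = rng.exponential(size=n)
    censored = e_draw >= cum[:, -1]
    death = np.full(n, np.nan)
    if not censored.all():
        idx = np.argmax(cum > e_draw[:, None], axis=1)  # first frame index exceeding draw
        j = idx - 1                                     # interval of death
        alive = ~censored
        jj = j[alive]
        rem = (e_draw[alive] - cum[alive, jj]) / np.exp(eta[alive, jj])
        death[alive] = model.invert_cumulative_baseline(h0[jj] + rem)

    # fluorescence trajectories (true integrated intensities, pre-bleach)
    red_level = rep.basal_red * np.exp(rep.cell_sd_log * u_red)
    green = rep.basal_green * np.exp(rep.cell_sd_log * z)
    responder = (~censored) & (rng.uniform(size=n) < rep.responder_fraction)
    if rep.surge_fold > 1.0 and responder.any():
        t0 = death[:, None] - rep.surge_lead_h
        ramp = np.clip((times[None, :] - t0) / rep.surge_lead_h, 0.0, 1.0)
        factor = 1.0 + (rep.surge_fold - 1.0) * ramp
        green = np.where(responder[:, None], green * factor, green)

    alive_at = censored[:, None] | (times[None, :] < np.where(censored, np.inf, death)[:, None])

    if place:
        centers = np.full((n, 2), np.nan)
        im = imaging or ImagingModel()
        per_field = design.neurons_per_field
        for start in range(0, n, per_field):
            centers[start:start + per_field] = _place_centers(
                per_field, design.image_shape, im.min_separation, rng
            )
        x, y = centers[:, 0], centers[:, 1]
    else:
        x = np.full(n, np.nan)
        y = np.full(n, np.nan)

    fates = pd.DataFrame({
        "neuron_id": np.arange(n),
        "plate": plates, "well": wells, "field": fields_, "group": group,
        "x": x, "y": y,
        "death_time_h": death, "censored": censored,
    })

    nid, fr_idx = np.nonzero(alive_at)
    trajectories = pd.DataFrame({
        "neuron_id": nid,
        "frame": fr_idx,
        "time_h": times[fr_idx],
        "red_true": np.broadcast_to(red_level[:, None], green.shape)[nid, fr_idx],
        "green_true": green[nid, fr_idx],
    })
    return GroundTruth(fates=fates, trajectories=trajectories, design=design)


def truth_to_fates(truth: GroundTruth) -> pd.DataFrame:
    """Observed fates on the imaging grid: survival time is the last frame
    time strictly before the true death time; censored neurons carry the
    end of follow-up.  Matches what an ideal tracker recovers."""
    design = truth.design
    times = design.frame_times
    f = truth.fates
    died = ~f["censored"].to_numpy()
    surv = np.full(len(f), times[-1])
    if died.any():
        d = f.loc[died, "death_time_h"].to_numpy()
        # last frame with frame_time < death time
        last_alive = np.searchsorted(times, d, side="left") - 1
        surv[died] = times[np.clip(last_alive, 0, None)]
    return pd.DataFrame({
        "track_id": f["neuron_id"],
        "plate": f["plate"], "well": f["well"], "field": f["field"],
        "survival_time_h": surv,
        "died": died,
    })


# ---------------------------------------------------------------------------
# rendering

def _gaussian_blob(frame: np.ndarray, x: float, y: float, sigma: float,
                   intensity: float) -> None:
    """Add an isotropic Gaussian of given integrated intensity in place."""
    h, w = frame.shape
    r = int(np.ceil(6 * sigma))
    x0, x1 = max(int(np.floor(x)) - r, 0), min(int(np.floor(x)) + r + 1, w)
    y0, y1 = max(int(np.floor(y)) - r, 0), min(int(np.floor(y)) + r + 1, h)
    if x0 >= x1 or y0 >= y1:
        return
    xs = np.arange(x0, x1) - x
    ys = np.arange(y0, y1) - y
    amp = intensity / (2 * np.pi * sigma**2)
    frame[y0:y1, x0:x1] += amp * np.exp(
        -(ys[:, None] ** 2 + xs[None, :] ** 2) / (2 * sigma**2)
    )


def snr_to_intensity(snr: float, imaging: ImagingModel) -> float:
    """Integrated blob intensity whose peak amplitude is ``snr`` background
    noise standard deviations."""
    return snr * imaging.noise_sd_at_background * 2 * np.pi * imaging.psf_sigma**2


def render_movie(
    truth: GroundTruth,
    imaging: ImagingModel,
    seed: int,
    plate: int | None = None,
    well: int | None = None,
    field: int | None = None,
) -> MovieStack:
    """Render one field of a ground-truth collection as a two-channel stack.

    Living neurons appear as Gaussian blobs with integrated intensity equal
    to their true trajectory value attenuated by photobleaching; dead
    neurons are absent from the first frame at or after death.  Poisson shot
    noise on signal + background and Gaussian read noise are applied last.
    """
    f = truth.fates
    if plate is None:
        if f[["plate", "well", "field"]].drop_duplicates().shape[0] != 1:
            raise ValueError("truth spans several fields; pass plate/well/field")
        plate, well, field = (int(f[c].iloc[0]) for c in ("plate", "well", "field"))
    ft = truth.field_truth(plate, well, field)
    f = ft.fates
    design = truth.design
    times = design.frame_times
    h, w = design.image_shape

    pts = f[["x", "y"]].to_numpy(dtype=float)
    if len(pts) and np.isnan(pts).any():
        raise PlacementError("neuron centers missing (simulated with place=False?)")
    if (pts[:, 0] < 0).any() or (pts[:, 0] > w).any() or (pts[:, 1] < 0).any() or (pts[:, 1] > h).any():
        raise PlacementError("neuron center outside image bounds")
    if len(pts) > 1:
        d = np.hypot(*(pts[:, None, :] - pts[None, :, :]).transpose(2, 0, 1))
        np.fill_diagonal(d, np.inf)
        if d.min() < imaging.min_separation:
            raise PlacementError(
                f"neuron centers closer than min_separation ({d.min():.2f} px)"
            )

    rng = np.random.default_rng(seed)
    traj = ft.trajectories.set_index(["neuron_id", "frame"])
    nid_order = f["neuron_id"].to_numpy()
    red = np.empty((len(times), h, w))
    green = np.empty_like(red)
    for t_idx in range(len(times)):
        fr_r = np.full((h, w), float(imaging.background_level))
        fr_g = np.full((h, w), float(imaging.background_level))
        atten = (1.0 - imaging.photobleach_rate) ** t_idx
        for row, nid in enumerate(nid_order):
            key = (nid, t_idx)
            if key not in traj.index:
                continue  # dead (or never alive) at this frame
            rec = traj.loc[key]
            x, y = pts[row]
            if imaging.motion_sd > 0:
                x += rng.normal(0, imaging.motion_sd)
                y += rng.normal(0, imaging.motion_sd)
            _gaussian_blob(fr_r, x, y, imaging.psf_sigma, float(rec["red_true"]) * atten)
            _gaussian_blob(fr_g, x, y, imaging.psf_sigma, float(rec["green_true"]) * atten)
        if imaging.poisson_noise:
            fr_r = rng.poisson(np.clip(fr_r, 0, None)).astype(float)
            fr_g = rng.poisson(np.clip(fr_g, 0, None)).astype(float)
        if imaging.read_noise_sd > 0:
            fr_r = fr_r + rng.normal(0, imaging.read_noise_sd, fr_r.shape)
            fr_g = fr_g + rng.normal(0, imaging.read_noise_sd, fr_g.shape)
        red[t_idx] = fr_r
        green[t_idx] = fr_g
    return MovieStack(red=red, green=green, times=times,
                      plate=plate, well=well, field=field)


def render_experiment(truth: GroundTruth, imaging: ImagingModel, seed: int,
                      out_dir: str | Path | None = None):
    """Render every field; yield stacks (writing TIFFs when out_dir given)."""
    ss = np.random.SeedSequence(seed)
    combos = truth.fates[["plate", "well", "field"]].drop_duplicates().to_numpy()
    children = ss.spawn(len(combos))
    for (p, wl, fd), child in zip(combos, children):
        stack = render_movie(truth, imaging, int(child.generate_state(1)[0] % 2**31),
                             plate=int(p), well=int(wl), field=int(fd))
        if out_dir is not None:
            write_movie(stack, out_dir)
        yield stack


# ---------------------------------------------------------------------------
# file I/O

def _movie_name(plate: int, well: int, field: int, channel: str | None) -> str:
    base = f"plate{plate}_well{well}_field{field}"
    return f"{base}_{channel}.tif" if channel else f"{base}.tif"


def write_movie(stack: MovieStack, out_dir: str | Path, combined: bool = False) -> list[Path]:
    """Write a stack as 16-bit multi-page TIFF(s), frame order = time order.

    Default dialect: one file per channel; ``combined=True`` writes a single
    (T, 2, H, W) stack instead.  Values are clipped to the uint16 range.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    def to16(a: np.ndarray) -> np.ndarray:
        return np.clip(np.round(a), 0, 65535).astype(np.uint16)

    paths = []
    if combined:
        p = out / _movie_name(stack.plate, stack.well, stack.field, None)
        tifffile.imwrite(p, np.stack([to16(stack.red), to16(stack.green)], axis=1))
        paths.append(p)
    else:
        for ch, arr in (("red", stack.red), ("green", stack.green)):
            p = out / _movie_name(stack.plate, stack.well, stack.field, ch)
            tifffile.imwrite(p, to16(arr))
            paths.append(p)
    return paths


def read_movie(directory: str | Path, plate: int, well: int, field: int,
               frame_interval: float = 24.0) -> MovieStack:
    """Read either movie dialect (per-channel files or one 2-channel stack)."""
    d = Path(directory)
    combined = d / _movie_name(plate, well, field, None)
    if combined.exists():
        arr = tifffile.imread(combined).astype(float)
        if arr.ndim != 4 or arr.shape[1] != 2:
            raise IOError(f"{combined}: expected a (T, 2, H, W) stack")
        red, green = arr[:, 0], arr[:, 1]
    else:
        rp = d / _movie_name(plate, well, field, "red")
        gp = d / _movie_name(plate, well, field, "green")
        if not rp.exists() or not gp.exists():
            raise FileNotFoundError(f"no movie for plate{plate}_well{well}_field{field} in {d}")
        red = tifffile.imread(rp).astype(float)
        green = tifffile.imread(gp).astype(float)
        if red.ndim == 2:
            red, green = red[None], green[None]
    times = np.arange(red.shape[0]) * frame_interval
    return MovieStack(red=red, green=green, times=times,
                      plate=plate, well=well, field=field)


def write_truth_tables(truth: GroundTruth, out_dir: str | Path) -> tuple[Path, Path]:
    """Write the fate and trajectory tables as CSV (round-trip exact)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    fp = out / "truth_fates.csv"
    tp = out / "truth_trajectories.csv"
    truth.fates.to_csv(fp, index=False, float_format="%.17g")
    truth.trajectories.to_csv(tp, index=False, float_format="%.17g")
    return fp, tp


def read_truth_tables(directory: str | Path,
                      design: ExperimentDesign | None = None) -> GroundTruth:
    d = Path(directory)
    fates = pd.read_csv(d / "truth_fates.csv")
    if len(fates) == 0:
        fates = pd.DataFrame(columns=FATE_COLUMNS)
    traj = pd.read_csv(d / "truth_trajectories.csv")
    if len(traj) == 0:
        traj = pd.DataFrame(columns=TRAJ_COLUMNS)
    if "censored" in fates.columns and fates["censored"].dtype != bool:
        fates["censored"] = fates["censored"].astype(bool)
    return GroundTruth(fates=fates, trajectories=traj,
                       design=design or ExperimentDesign())


def write_layout(design: ExperimentDesign, path: str | Path) -> Path:
    """Plate/well -> group mapping used by the statistics stage."""
    rows = [
        {"plate": p, "well": w, "group": design.group_of_well[w]}
        for p in range(design.plates)
        for w in range(design.wells_per_plate)
    ]
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(rows).to_csv(path, index=False)
    return path


# ---------------------------------------------------------------------------
# proportional-hazards violation scenario (diagnostics power studies)

def simulate_crossing_fates(
    n_per_group: int,
    beta_early: float,
    beta_late: float,
    crossing_time: float,
    rate: float,
    end_of_followup: float,
    seed: int,
    n_wells: int = 8,
) -> pd.DataFrame:
    """Two-group exponential survival where the second group's log hazard
    ratio switches from ``beta_early`` to ``beta_late`` at ``crossing_time``
    — a deliberate proportional-hazards violation.  Returns analysis-ready
    records (time, event, group, well, plate)."""
    rng = np.random.default_rng(seed)
    n = 2 * n_per_group
    grp = np.array(["A"] * n_per_group + ["B"] * n_per_group)
    beta1 = np.where(grp == "B", beta_early, 0.0)
    beta2 = np.where(grp == "B", beta_late, 0.0)
    e = rng.exponential(size=n)
    h_cross = rate * np.exp(beta1) * crossing_time
    t = np.where(
        e < h_cross,
        e / (rate * np.exp(beta1)),
        crossing_time + (e - h_cross) / (rate * np.exp(beta2)),
    )
    event = t <= end_of_followup
    t = np.minimum(t, end_of_followup)
    return pd.DataFrame({
        "neuron_id": np.arange(n),
        "time": t,
        "event": event,
        "group": grp,
        "well": [f"P0W{i % n_wells}" for i in range(n)],
        "plate": "P0",
    })
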