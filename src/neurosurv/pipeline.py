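"""One-config orchestration: simulate -> track -> analyze.

A run is described by a single YAML/JSON mapping with per-stage blocks
(see :func:`load_config`); every stage writes plain CSV intermediates so
it can be re-run individually, and a manifest records the config hash,
seed, per-stage row counts and warnings.  All CSVs carry a first comment
line ``# neurosurv seed=... config=...`` so any output can be traced to
the run that produced it; :func:`read_table` strips it.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field as dfield
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .design import ConfigurationError, ExperimentDesign, HazardModel, ImagingModel, ReporterDynamics
from . import simulate as sim
from . import survival as surv
from . import track as trk

__all__ = [
    "RunConfig",
    "RunManifest",
    "StageError",
    "load_config",
    "run_pipeline",
    "write_table",
    "read_table",
]


class StageError(RuntimeError):
    """A pipeline stage failed; the stage name is in the message."""


@dataclass
class RunConfig:
    seed: int
    out: Path
    simulate: dict | None = None
    images: Path | None = None
    layout: Path | None = None
    statistics_only: bool = False
    track: dict = dfield(default_factory=dict)
    analyze: dict = dfield(default_factory=dict)
    raw: dict = dfield(default_factory=dict)

    @property
    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.raw, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


@dataclass
class RunManifest:
    config_hash: str
    version: str
    seed: int
    counts: dict = dfield(default_factory=dict)
    warnings: list = dfield(default_factory=list)

    def write(self, path: Path) -> None:
        path.write_text(json.dumps(self.__dict__, indent=2, default=str))


def _design_from(block: dict) -> ExperimentDesign:
    b = dict(block)
    groups = b.pop("groups", None)
    if groups is not None:
        b["group_of_well"] = {int(k): v for k, v in groups.items()}
    if "image_shape" in b:
        b["image_shape"] = tuple(b["image_shape"])
    return ExperimentDesign(**b)


def _hazard_from(block: dict) -> HazardModel:
    b = dict(block)
    rep = b.pop("reporter", None)
    if rep is not None:
        b["reporter"] = ReporterDynamics(**rep)
    rate = b.pop("constant_rate", None)
    if rate is not None:
        return HazardModel.constant_rate(rate, **b)
    return HazardModel(**b)


def load_config(path: str | Path) -> RunConfig:
    """Parse and validate a YAML/JSON run configuration."""
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"config file not found: {path}")
    raw = yaml.safe_load(path.read_text())
    if not isinstance(raw, dict):
        raise ConfigurationError("config must be a mapping")
    out = Path(raw.get("out", "results"))
    cfg = RunConfig(
        seed=int(raw.get("seed", 0)),
        out=out,
        simulate=raw.get("simulate"),
        images=Path(raw["images"]) if raw.get("images") else None,
        layout=Path(raw["layout"]) if raw.get("layout") else None,
        statistics_only=bool(raw.get("statistics_only", False)),
        track=raw.get("track", {}) or {},
        analyze=raw.get("analyze", {}) or {},
        raw=raw,
    )
    if cfg.simulate is None:
        if cfg.layout is None or not cfg.layout.exists():
            raise ConfigurationError(
                f"layout file missing: {cfg.layout} (required without a simulate block)"
            )
        if not cfg.statistics_only and (cfg.images is None or not cfg.images.exists()):
            raise ConfigurationError(f"images directory missing: {cfg.images}")
    return cfg


def write_table(df: pd.DataFrame, path: Path, seed: int, config_hash: str) -> Path:
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(f"# neurosurv seed={seed} config={config_hash}\n")
        df.to_csv(fh, index=False, float_format="%.17g")
    return path


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def run_pipeline(config: RunConfig) -> RunManifest:
    """Execute the configured stages; deterministic given the seed.

    A failing stage aborts the run with the stage named; files written by
    the failed stage keep a ``.partial`` suffix.
    """
    out = Path(config.out)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config_hash=config.config_hash, version=__version__,
                           seed=config.seed)
    ss = np.random.SeedSequence(config.seed)
    sim_seed, render_seed = (int(c.generate_state(1)[0] % 2**31) for c in ss.spawn(2))

    def _stage(name, fn):
        written: list[Path] = []
        try:
            return fn(written)
        except Exception as exc:
            for p in written:
                if p.exists():
                    p.rename(p.with_suffix(p.suffix + ".partial"))
            raise StageError(f"stage '{name}' failed: {exc}") from exc

    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")

        # ---- simulate -------------------------------------------------
        truth = None
        design = None
        if config.simulate is not None:
            def do_sim(written):
                nonlocal truth, design
                design = _design_from(config.simulate.get("design", {}))
                hazard = _hazard_from(config.simulate.get("hazard", {}))
                imaging = ImagingModel(**config.simulate.get("imaging", {}))
                truth = sim.simulate_fates(design, hazard, sim_seed, imaging=imaging,
                                           place=not config.statistics_only)
                fp, tp = sim.write_truth_tables(truth, out)
                written += [fp, tp]
                written.append(sim.write_layout(design, out / "layout.csv"))
                if not config.statistics_only:
                    movie_dir = out / "images"
                    for _ in sim.render_experiment(truth, imaging, render_seed,
                                                   out_dir=movie_dir):
                        pass
                manifest.counts["neurons_simulated"] = len(truth.fates)
            _stage("simulate", do_sim)
            layout = read_table(out / "layout.csv")
            images_dir = out / "images"
            end_fu = design.end_of_followup
            frame_interval = design.frame_interval
        else:
            layout = read_table(config.layout)
            images_dir = config.images
            frame_interval = float(config.track.get("frame_interval", 24.0))
            end_fu = None

        # ---- track ----------------------------------------------------
        if not config.statistics_only:
            def do_track(written):
                tcfg = config.track
                all_obs, all_fates = [], []
                offset = 0
                if truth is not None:
                    combos = truth.fates[["plate", "well", "field"]].drop_duplicates().to_numpy()
                else:
                    combos = _discover_fields(images_dir)
                for p, w, f in combos:
                    stack = sim.read_movie(images_dir, int(p), int(w), int(f),
                                           frame_interval=frame_interval)
                    tracks = trk.track_movie(
                        stack,
                        threshold_method=tcfg.get("threshold", "background"),
                        min_area=int(tcfg.get("min_area", 5)),
                        morph_radius=int(tcfg.get("morph_radius", 1)),
                        search_radius=float(tcfg.get("search_radius", 10.0)),
                        background_method=tcfg.get("background", "median_outside_masks"),
                    )
                    obs, fates = trk.tracks_to_tables(tracks, int(p), int(w), int(f),
                                                      id_offset=offset)
                    offset += len(tracks)
                    all_obs.append(obs)
                    all_fates.append(fates)
                obs = pd.concat(all_obs, ignore_index=True)
                fates = pd.concat(all_fates, ignore_index=True)
                written.append(write_table(obs, out / "tracks.csv", config.seed,
                                           config.config_hash))
                written.append(write_table(fates, out / "fates.csv", config.seed,
                                           config.config_hash))
                manifest.counts["tracks"] = len(fates)
                manifest.counts["track_rows"] = len(obs)
            _stage("track", do_track)
            fates = read_table(out / "fates.csv")
            reporter = read_table(out / "tracks.csv")
            reporter = reporter[reporter["present"].astype(bool)]
        else:
            if truth is not None:
                fates = sim.truth_to_fates(truth)
                reporter = truth.trajectories.rename(columns={
                    "neuron_id": "track_id", "green_true": "mean_green",
                    "red_true": "mean_red"})
            else:
                fates_path = Path(config.raw.get("fates", config.out / "fates.csv"))
                if not fates_path.exists():
                    raise ConfigurationError(
                        f"statistics-only run: fates table not found at {fates_path}"
                    )
                fates = read_table(fates_path)
                rep_path = config.raw.get("reporter")
                reporter = read_table(rep_path) if rep_path else None

        # ---- analyze --------------------------------------------------
        def do_analyze(written):
            acfg = config.analyze
            nonlocal end_fu
            if end_fu is None:
                end_fu = float(acfg.get("end_of_followup", fates["survival_time_h"].max()))
            records = surv.build_survival_records(fates, layout, end_fu,
                                                  reporter=reporter)
            written.append(write_table(records, out / "records.csv", config.seed,
                                       config.config_hash))
            manifest.counts["records"] = len(records)

            na = surv.nelson_aalen(records, by_group=True)
            written.append(write_table(na, out / "na_curves.csv", config.seed,
                                       config.config_hash))

            ties = acfg.get("ties", "breslow")
            fit = surv.fit_cox(records, covariates=["group"], ties=ties)
            written.append(write_table(fit.summary(), out / "cox_fit.csv",
                                       config.seed, config.config_hash))
            manifest.counts["cox_events"] = fit.n_events
            if fit.n_events >= 2:
                ph = surv.schoenfeld_ph_test(fit)
                written.append(write_table(ph, out / "ph_test.csv", config.seed,
                                           config.config_hash))

            if acfg.get("model", "group") == "quartile":
                for t0 in acfg.get("ref_times", [24.0]):
                    qa = surv.assign_quartiles(records, float(t0))
                    qfit = surv.quartile_hazard_model(
                        records, qa, adjust_by_group=bool(acfg.get("adjust_group", False)),
                        ties=ties)
                    written.append(write_table(
                        qfit.hr_table(), out / f"quartile_model_{int(t0)}.csv",
                        config.seed, config.config_hash))
        _stage("analyze", do_analyze)

    manifest.warnings = [str(w.message) for w in caught]
    manifest.write(out / "manifest.json")
    return manifest


def _discover_fields(images_dir: Path) -> np.ndarray:
    import re
    combos = set()
    for p in Path(images_dir).glob("plate*_well*_field*.tif"):
        m = re.match(r"plate(\d+)_well(\d+)_field(\d+)", p.stem)
        if m:
            combos.add(tuple(int(g) for g in m.groups()))
    if not combos:
        raise ConfigurationError(f"no movie files found in {images_dir}")
    return np.array(sorted(combos))
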