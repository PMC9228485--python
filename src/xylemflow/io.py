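"""Readers, writers, run configuration and the staged pipeline.

TIFF is the only raster interchange format (microscopy frame pairs,
label images and MRI stacks all reduce to grayscale stacks); tables go
to CSV with '.' decimals and explicit headers, scalar results to JSON.
Every pipeline run writes its resolved configuration and a manifest
(config hash, input checksums, per-stage outputs and wall time) next to
its outputs, so a run directory is self-describing and a deterministic
stage re-run reproduces identical checksums.

One global seed fans out to per-stage seeds through
``numpy.random.SeedSequence(global_seed, crc32(stage_name))``, so a
single integer reproduces the whole demo.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

log = logging.getLogger("xylemflow")

__all__ = [
    "read_image_stack",
    "write_image_stack",
    "read_table",
    "write_table",
    "write_json",
    "RunConfig",
    "RunManifest",
    "derive_seed",
    "run_pipeline",
]

STAGES = ("synth_piv", "synth_vessels", "synth_mri", "piv", "morph", "mri", "hydro")
#: stages whose inputs come from another stage's outputs
DEPENDS = {"piv": "synth_piv", "morph": "synth_vessels", "mri": "synth_mri"}


# --------------------------------------------------------------------------
# readers / writers
# --------------------------------------------------------------------------

def read_image_stack(path) -> tuple[np.ndarray, dict]:
    """Read a (multi-page) TIFF as an array plus basic metadata."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    arr = tifffile.imread(path)
    meta = {"path": str(path), "shape": tuple(arr.shape), "dtype": str(arr.dtype)}
    return arr, meta


def write_image_stack(arr: np.ndarray, path) -> Path:
    """Write an array as TIFF, lossless for integer rasters."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    arr = np.asarray(arr)
    kw = {"photometric": "minisblack"} if arr.ndim >= 3 else {}
    tifffile.imwrite(path, arr, **kw)
    return path


def write_table(records, path) -> Path:
    """Write a table as CSV: '.' decimal, explicit header, no index."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df = records if isinstance(records, pd.DataFrame) else pd.DataFrame(records)
    df.to_csv(path, index=False)
    return path


def read_table(path, required_columns: list[str] | None = None) -> pd.DataFrame:
    """Read a CSV table, checking the declared schema.

    Raises a schema error naming the first missing column.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path)
    if required_columns:
        for col in required_columns:
            if col not in df.columns:
                raise ValueError(
                    f"{path}: malformed table, missing required column {col!r} "
                    f"(found {list(df.columns)})")
    return df


def write_json(obj, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(obj, indent=2, default=_json_default) + "\n")
    return path


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


# --------------------------------------------------------------------------
# configuration and manifest
# --------------------------------------------------------------------------

def derive_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31 from one global seed."""
    ss = np.random.SeedSequence([int(global_seed), zlib.crc32(stage.encode())])
    return int(ss.generate_state(1)[0] % 2**31)


@dataclass
class RunConfig:
    """Pipeline run configuration; round-trips losslessly through YAML."""

    stages: list = field(default_factory=lambda: list(STAGES))
    out_dir: str = "run_out"
    seed: int = 0
    log_level: str = "INFO"
    params: dict = field(default_factory=dict)   # per-stage parameter blocks

    def to_yaml(self, path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        path.write_text(yaml.safe_dump(asdict(self), sort_keys=True))
        return path

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        return cls.validate(raw)

    @classmethod
    def validate(cls, raw: dict) -> "RunConfig":
        if not isinstance(raw, dict):
            raise ValueError("config must be a mapping")
        unknown = set(raw) - {"stages", "out_dir", "seed", "log_level", "params"}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        bad = [s for s in cfg.stages if s not in STAGES]
        if bad:
            raise ValueError(f"unknown stages {bad}; valid: {list(STAGES)}")
        return cfg

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True).encode()).hexdigest()[:16]


@dataclass
class RunManifest:
    tool_version: str
    config_hash: str
    checksums: dict = field(default_factory=dict)  # file -> sha256
    outputs: dict = field(default_factory=dict)       # stage -> [files]
    wall_clock_s: dict = field(default_factory=dict)  # stage -> seconds
    failed: dict = field(default_factory=dict)        # stage -> message

    def to_json(self, path) -> Path:
        return write_json(asdict(self), path)


# --------------------------------------------------------------------------
# stages
# --------------------------------------------------------------------------

def _stage_synth_piv(cfg: RunConfig, out: Path, seed: int) -> list[Path]:
    from . import synthgen

    p = dict(kind="uniform", dx=2.0, dy=0.0, u_max=4.0, shape=(64, 256),
             n_pairs=5, ratio_R=1.0, mean_speed=2.0)
    p.update(cfg.params.get("synth_piv", {}))
    shape = tuple(p["shape"])
    if p["kind"] == "uniform":
        fld = synthgen.uniform_field(p["dx"], p["dy"], shape)
    elif p["kind"] == "poiseuille":
        fld = synthgen.poiseuille_field(p["u_max"], shape)
    elif p["kind"] == "y-merge":
        geo = synthgen.YMergeGeometry(height=shape[0], length=shape[1])
        fld = synthgen.make_y_merge_field(p["ratio_R"], p["mean_speed"], geo)
    else:
        raise ValueError(f"unknown field kind {p['kind']!r}")
    frames = []
    for k in range(int(p["n_pairs"])):
        pair = synthgen.make_particle_image_pair(fld, seed=seed + k)
        frames += [pair.frame_a, pair.frame_b]
    f1 = write_image_stack(np.stack(frames), out / "piv_pairs.tiff")
    f2 = write_json({"field": p, "seed": seed, "n_pairs": int(p["n_pairs"])},
                    out / "piv_pairs_truth.json")
    return [f1, f2]


def _stage_synth_vessels(cfg: RunConfig, out: Path, seed: int) -> list[Path]:
    from . import synthgen

    ph = synthgen.make_vessel_phantom(seed=seed,
                                      **cfg.params.get("synth_vessels", {}))
    f1 = write_image_stack(ph.label_image, out / "vessel_labels.tiff")
    f2 = write_table(ph.truth, out / "vessel_truth.csv")
    f3 = write_json({"pixel_size_um": ph.pixel_size, "seed": seed},
                    out / "vessel_meta.json")
    return [f1, f2, f3]


def _stage_synth_mri(cfg: RunConfig, out: Path, seed: int) -> list[Path]:
    from . import synthgen

    ph = synthgen.make_mri_phantom(seed=seed, **cfg.params.get("synth_mri", {}))
    n, t, H, W = ph.data.shape
    files = [write_image_stack(ph.data.reshape(n * t, H, W),
                               out / "mri_series.tiff")]
    for name, m in ph.masks.items():
        files.append(write_image_stack(m.astype(np.uint8),
                                       out / f"mri_mask_{name}.tiff"))
    files.append(write_json(
        {"n_slices": n, "n_times": t, "seed": seed,
         "slice_class": ph.slice_class.tolist(),
         "time_step_min": ph.params.time_step_min}, out / "mri_truth.json"))
    return files


def _stage_piv(cfg: RunConfig, out: Path, seed: int) -> list[Path]:
    from . import piv as pivmod

    stack, _ = read_image_stack(out / "piv_pairs.tiff")
    pcfg = pivmod.PivConfig(**cfg.params.get("piv", {}))
    fields = []
    for k in range(stack.shape[0] // 2):
        from .synthgen import ParticleImagePair, uniform_field

        pair = ParticleImagePair(
            frame_a=stack[2 * k], frame_b=stack[2 * k + 1],
            truth=uniform_field(0, 0, stack.shape[1:]), params=None, seed=-1)
        fields.append(pivmod.multipass_piv(pair, pcfg))
        log.info("piv: pair %d valid fraction %.2f", k, fields[-1].valid.mean())
    mean = pivmod.ensemble_average(fields)
    f1 = write_table(mean.to_table(), out / "velocity_field.csv")
    files = [f1]
    stations = cfg.params.get("piv_profile_stations_um", [160.0])
    rows = []
    for s in stations:
        try:
            prof = pivmod.extract_profile(mean, s)
        except ValueError:
            continue
        prof.insert(0, "station_um", s)
        rows.append(prof)
    if rows:
        files.append(write_table(pd.concat(rows), out / "velocity_profiles.csv"))
    return files


def _stage_morph(cfg: RunConfig, out: Path, seed: int) -> list[Path]:
    from . import morphometry as mo

    labels, _ = read_image_stack(out / "vessel_labels.tiff")
    meta = json.loads((out / "vessel_meta.json").read_text())
    p = dict(U0_um_s=221.5, ring_edges=None)
    p.update(cfg.params.get("morph", {}))
    rec = mo.measure_labels(labels, meta["pixel_size_um"])
    rec = mo.assign_rings(rec, ring_edges=p["ring_edges"])
    rec = mo.reynolds_per_vessel(rec, U0_um_s=p["U0_um_s"])
    summ = mo.summarize_stem(rec)
    f1 = write_table(rec, out / "vessel_records.csv")
    f2 = write_json(
        {"center_um": summ.center_um, "n_vessels": summ.n_vessels,
         "total_area_um2": summ.total_area_um2,
         "re_quantiles": summ.re_quantiles,
         "per_ring": summ.per_ring.to_dict("records")},
        out / "stem_summary.json")
    return [f1, f2]


def _stage_mri(cfg: RunConfig, out: Path, seed: int) -> list[Path]:
    from . import mri as mrimod

    truth = json.loads((out / "mri_truth.json").read_text())
    n, t = truth["n_slices"], truth["n_times"]
    stack, _ = read_image_stack(out / "mri_series.tiff")
    data = stack.reshape(n, t, *stack.shape[1:])
    masks = {}
    for name in ("stem", "water", "air"):
        m, _ = read_image_stack(out / f"mri_mask_{name}.tiff")
        masks[name] = m.astype(bool)
    series = mrimod.SliceSeries(data=data, masks=masks,
                                time_step_min=truth["time_step_min"])
    means = mrimod.region_means(series)
    mat = mrimod.normalize_flow_signal(means["stem"], means["air"],
                                       series.positions_mm, series.times_min)
    thr = cfg.params.get("mri", {}).get("slope_threshold")
    if thr is None:
        thr = mrimod.suggest_slope_threshold(mat)
    cls = mrimod.classify_slices(mat, thr)
    f1 = out / "flow_matrix.csv"
    f3 = out / "flow_matrix.png"
    mrimod.spacetime_map(mat, csv_path=f1, png_path=f3)
    f2 = write_table(cls, out / "slice_classification.csv")
    return [f1, f2, f3]


def _stage_hydro(cfg: RunConfig, out: Path, seed: int) -> list[Path]:
    from . import hydraulics as hy

    p = dict(target_Re=0.012, ratio_R=1.0, nu=hy.NU_WATER_26C,
             chip_um=(120.0, 240.0))
    p.update(cfg.params.get("hydro", {}))
    chip = hy.DuctGeometry(p["chip_um"][1] * 1e-6, p["chip_um"][0] * 1e-6)
    op = hy.match_chip_operating_point(p["target_Re"], chip, p["nu"],
                                       p["ratio_R"])
    y, z, u, ratio = hy.rect_duct_profile(chip, U0=op["U_chip"])
    op["duct_max_over_mean"] = ratio
    f1 = write_json(op, out / "chip_operating_point.json")
    mid = u.shape[1] // 2
    f2 = write_table(
        pd.DataFrame({"y_um": y * 1e6, "u_m_s": u[:, mid]}),
        out / "duct_centerplane_profile.csv")
    return [f1, f2]


_STAGE_FNS = {
    "synth_piv": _stage_synth_piv,
    "synth_vessels": _stage_synth_vessels,
    "synth_mri": _stage_synth_mri,
    "piv": _stage_piv,
    "morph": _stage_morph,
    "mri": _stage_mri,
    "hydro": _stage_hydro,
}


def run_pipeline(config: RunConfig) -> RunManifest:
    """Execute the requested stages in dependency order.

    Generator stages run before their consumers; a failed stage stops
    its dependents (recorded in the manifest) without aborting unrelated
    stages.  The resolved config and the manifest are written next to
    the outputs.
    """
    from . import __version__

    logging.basicConfig(level=getattr(logging, config.log_level.upper(), 20))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "resolved_config.yaml")
    manifest = RunManifest(tool_version=__version__,
                           config_hash=config.config_hash())
    ordered = [s for s in STAGES if s in config.stages]
    done = set()
    for stage in ordered:
        dep = DEPENDS.get(stage)
        if dep is not None and dep in ordered and dep not in done:
            manifest.failed[stage] = f"dependency {dep} failed or skipped"
            log.warning("skipping %s: %s", stage, manifest.failed[stage])
            continue
        if dep is not None and dep not in ordered:
            # consumer of pre-existing inputs: they must already be in out/
            pass
        t0 = time.perf_counter()
        try:
            files = _STAGE_FNS[stage](config, out, derive_seed(config.seed, stage))
        except Exception as exc:  # noqa: BLE001 - recorded, dependents stopped
            manifest.failed[stage] = f"{type(exc).__name__}: {exc}"
            log.error("stage %s failed: %s", stage, manifest.failed[stage])
            continue
        manifest.wall_clock_s[stage] = round(time.perf_counter() - t0, 3)
        manifest.outputs[stage] = [str(f) for f in files]
        for f in files:
            manifest.checksums[str(f)] = _sha256(Path(f))
        done.add(stage)
        log.info("stage %s done in %.2fs", stage, manifest.wall_clock_s[stage])
    manifest.to_json(out / "manifest.json")
    return manifest
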