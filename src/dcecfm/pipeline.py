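"""End-to-end orchestration: phantom -> kinetics -> domain -> solve -> stats.

`run_pipeline` executes the requested stages in order on a synthetic cohort
(or on a phantom directory written earlier), persisting every intermediate as
NIfTI/CSV/STL plus a JSON manifest with the config hash, seed and library
versions, so a run can be reproduced bit-identically.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__, domain as dom, kinetics, solver, stats, synthetic
from .constants import TissueConstants

__all__ = ["RunConfig", "ValidationReport", "run_pipeline", "validate_inputs"]

log = logging.getLogger(__name__)

STAGES = ("simulate", "fit", "domain", "solve", "stats")

_CONFIG_KEYS = None  # populated after RunConfig definition


@dataclass
class RunConfig:
    """Pipeline configuration.

    ``stages`` is an ordered subset of simulate/fit/domain/solve/stats;
    ``all`` expands to every stage.  Physical overrides go through
    ``tissue_constants`` (nested dicts mirroring
    :class:`~dcecfm.constants.TissueConstants`; values in SI units) and the
    cohort/phantom spec fields carry the units documented on those specs.
    """

    outdir: str = "dcecfm_run"
    stages: tuple[str, ...] = STAGES
    seed: int = 0
    input_dir: str | None = None  # load a saved phantom instead of simulating
    cohort: dict = field(default_factory=dict)  # CohortSpec overrides
    fit_mode: str = "voxel"  # "voxel" or "roi_mean"
    dilation_voxels: int = 10
    scaling_mode: str = "ktrans_scaling"
    solver_tol: float = 1e-10
    tissue_constants: dict = field(default_factory=dict)
    sigma_t_flux: float = 0.82  # reflection coefficient held fixed in flux fits

    def __post_init__(self) -> None:
        if self.stages == ("all",) or self.stages == "all":
            self.stages = STAGES
        self.stages = tuple(self.stages)
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        if self.fit_mode not in ("voxel", "roi_mean"):
            raise ValueError("fit_mode must be 'voxel' or 'roi_mean'")

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        text = path.read_text()
        if path.suffix in (".yaml", ".yml"):
            import yaml

            data = yaml.safe_load(text)
        else:
            data = json.loads(text)
        return cls.from_dict(data)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "stages" in data and isinstance(data["stages"], list):
            data = {**data, "stages": tuple(data["stages"])}
        return cls(**data)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["stages"] = list(self.stages)
        return d

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()).hexdigest()[:16]

    def constants(self) -> TissueConstants:
        if not self.tissue_constants:
            return TissueConstants()
        base = TissueConstants()
        kw: dict = {}
        for tissue in ("tumor", "normal"):
            over = self.tissue_constants.get(tissue, {})
            kw[tissue] = dataclasses.replace(getattr(base, tissue), **over)
        for key in ("pv", "pl", "pi_v"):
            kw[key] = self.tissue_constants.get(key, getattr(base, key))
        extra = set(self.tissue_constants) - {"tumor", "normal", "pv", "pl", "pi_v"}
        if extra:
            raise ValueError(f"unknown tissue-constant overrides: {sorted(extra)}")
        return TissueConstants(**kw)


@dataclass
class ValidationReport:
    fatal: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.fatal


def validate_inputs(dataset_dir: str | Path) -> ValidationReport:
    """Check a phantom/exam directory for structural problems.

    Fatal: unreadable files, grid misalignment between series/T10/mask, an
    empty tumor mask, or a non-monotone time axis.  Non-fatal oddities (e.g.
    missing optional truth maps) are listed as warnings.
    """
    import nibabel as nib
    import pandas as pd

    d = Path(dataset_dir)
    rep = ValidationReport()
    imgs = {}
    for name in ("signal", "t10", "tumor_mask"):
        path = d / f"{name}.nii"
        try:
            imgs[name] = nib.load(path)
        except Exception as exc:
            rep.fatal.append(f"unreadable {path.name}: {exc}")
    if rep.fatal:
        return rep
    base = imgs["signal"].shape[:3]
    for name in ("t10", "tumor_mask"):
        if imgs[name].shape[:3] != base:
            rep.fatal.append(
                f"grid misalignment: {name} {imgs[name].shape[:3]} vs series {base}")
        if not np.allclose(imgs[name].affine, imgs["signal"].affine):
            rep.fatal.append(f"affine mismatch between {name} and series")
    mask = np.asanyarray(imgs["tumor_mask"].dataobj)
    if not mask.any():
        rep.fatal.append("tumor mask is empty")
    prov = d / "provenance.json"
    if prov.exists():
        times = np.asarray(json.loads(prov.read_text()).get("times_s", []))
        if times.size and np.any(np.diff(times) <= 0):
            rep.fatal.append("non-monotone time axis in provenance metadata")
    else:
        rep.warnings.append("no provenance.json sidecar")
    aif = d / "aif.csv"
    if aif.exists():
        t = pd.read_csv(aif)["time_s"].to_numpy()
        if np.any(np.diff(t) <= 0):
            rep.fatal.append("non-monotone AIF time axis")
    else:
        rep.warnings.append("no aif.csv")
    for name in ("truth_ktrans", "truth_ve", "truth_vp"):
        if not (d / f"{name}.nii").exists():
            rep.warnings.append(f"optional {name}.nii absent")
    return rep


def _save_map(arr: np.ndarray, affine: np.ndarray, path: Path, unit: str) -> None:
    import nibabel as nib

    nib.save(nib.Nifti1Image(np.nan_to_num(arr).astype(np.float32), affine), path)
    sidecar = path.with_suffix(".json")
    sidecar.write_text(json.dumps({"unit": unit}))


def _fit_dataset(ds: synthetic.PhantomDataset, cfg: RunConfig) -> dict[str, np.ndarray]:
    """Signal -> concentration -> ETM maps (voxelwise or ROI-mean)."""
    conc = kinetics.concentration_from_signal(
        ds.signal, ds.t10, ds.spec.tr_s, ds.spec.flip_angle_deg,
        relaxivity=ds.spec.relaxivity, baseline_frames=ds.spec.baseline_frames,
        times=ds.times)
    mask = ds.tumor_mask
    if cfg.fit_mode == "voxel":
        maps = kinetics.fit_etm_map(conc.ct, ds.times, ds.aif.cp, mask=mask)
    else:
        roi_ct = conc.ct[mask].mean(axis=0)
        p = kinetics.fit_etm(roi_ct, ds.times, ds.aif.cp)
        maps = {k: np.where(mask, getattr(p, k), np.nan)
                for k in ("ktrans", "ve", "vp", "kep")}
        maps["converged"] = mask & p.converged
    return maps


def run_pipeline(config: RunConfig) -> Path:
    """Run the configured stages and return the artifact directory.

    A stage failure raises with the stage name; artifacts written by earlier
    stages remain on disk.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "tissue_constants": config.constants().to_dict(),
        "seed": config.seed,
        "versions": _versions(),
        "stages_run": [],
        "timings_s": {},
    }
    state: dict = {}
    try:
        for stage in config.stages:
            t0 = time.perf_counter()
            log.info("stage %s: starting", stage)
            _STAGE_FUNCS[stage](config, out, state)
            manifest["stages_run"].append(stage)
            manifest["timings_s"][stage] = round(time.perf_counter() - t0, 3)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage '{stage}' failed: {exc}") from exc
    finally:
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return out


def _versions() -> dict:
    import nibabel
    import scipy

    return {"dcecfm": __version__, "numpy": np.__version__,
            "scipy": scipy.__version__, "nibabel": nibabel.__version__}


def _stage_simulate(cfg: RunConfig, out: Path, state: dict) -> None:
    if cfg.input_dir is not None:
        state["cohort"] = [{"pre-TX": _load_dataset(cfg.input_dir)}]
        return
    spec = synthetic.CohortSpec(**{"seed": cfg.seed, **cfg.cohort})
    cohort = synthetic.generate_cohort(spec)
    state["cohort"] = cohort
    for s, exams in enumerate(cohort):
        for label, ds in exams.items():
            if ds is None:
                continue
            ds.save(out / f"subject{s:02d}" / label.replace("-TX", "TX"))


def _load_dataset(path: str | Path) -> synthetic.PhantomDataset:
    import nibabel as nib

    d = Path(path)
    rep = validate_inputs(d)
    if not rep.ok:
        raise ValueError("invalid input dataset: " + "; ".join(rep.fatal))
    meta = json.loads((d / "provenance.json").read_text())
    spec = synthetic.PhantomSpec(**{
        k: tuple(v) if isinstance(v, list) else v
        for k, v in meta["spec"].items()})
    load = lambda n: np.asanyarray(nib.load(d / n).dataobj).astype(float)
    return synthetic.PhantomDataset(
        signal=load("signal.nii"), t10=load("t10.nii"),
        tumor_mask=load("tumor_mask.nii").astype(bool),
        ktrans=load("truth_ktrans.nii"), ve=load("truth_ve.nii"),
        vp=load("truth_vp.nii"), aif=synthetic.AIF.from_csv(d / "aif.csv"),
        spec=spec)


def _iter_exams(state: dict):
    for s, exams in enumerate(state["cohort"]):
        for label, ds in exams.items():
            if ds is not None:
                yield s, label, ds


def _stage_fit(cfg: RunConfig, out: Path, state: dict) -> None:
    if "cohort" not in state:
        raise ValueError("fit stage requires simulate (or an input_dir)")
    state["maps"] = {}
    for s, label, ds in _iter_exams(state):
        maps = _fit_dataset(ds, cfg)
        state["maps"][(s, label)] = maps
        affine = np.diag(list(ds.spacing_mm) + [1.0])
        mdir = out / f"subject{s:02d}" / label.replace("-TX", "TX")
        mdir.mkdir(parents=True, exist_ok=True)
        for name, unit in (("ktrans", "min^-1"), ("ve", "1"), ("vp", "1"),
                           ("kep", "min^-1")):
            _save_map(maps[name], affine, mdir / f"fit_{name}.nii", unit)


def _stage_domain(cfg: RunConfig, out: Path, state: dict) -> None:
    if "maps" not in state:
        raise ValueError("domain stage requires fit")
    state["domains"] = {}
    for s, label, ds in _iter_exams(state):
        kt = state["maps"][(s, label)]["ktrans"]
        grid = dom.build_domain(ds.tumor_mask, ds.spacing_mm, kt,
                                dilation_voxels=cfg.dilation_voxels)
        state["domains"][(s, label)] = grid
        mdir = out / f"subject{s:02d}" / label.replace("-TX", "TX")
        mdir.mkdir(parents=True, exist_ok=True)
        dom.export_stl(ds.tumor_mask, ds.spacing_mm, mdir / "tumor.stl")
        _save_map(grid.labels.astype(float), grid.affine, mdir / "domain_labels.nii", "label")


def _stage_solve(cfg: RunConfig, out: Path, state: dict) -> None:
    if "domains" not in state:
        raise ValueError("solve stage requires domain")
    constants = cfg.constants()
    state["summaries"] = []
    diagnostics = {}
    for s, label, ds in _iter_exams(state):
        grid = state["domains"][(s, label)]
        pres = solver.solve_ifp(grid, constants, scaling_mode=cfg.scaling_mode,
                                tol=cfg.solver_tol)
        coeff = solver.assemble_coefficients(grid, constants, cfg.scaling_mode)
        vel = solver.compute_ifv(pres, coeff.kh, grid.domain_mask)
        summ = solver.summarize_fields(pres, vel, grid, label=label,
                                       subject=f"subject{s:02d}")
        state["summaries"].append(summ)
        mdir = out / f"subject{s:02d}" / label.replace("-TX", "TX")
        mdir.mkdir(parents=True, exist_ok=True)
        _save_map(pres.p / 1000.0, grid.affine, mdir / "ifp_kpa.nii", "kPa")
        _save_map(vel.magnitude, grid.affine, mdir / "ifv_magnitude.nii", "m/s")
        for ax, name in enumerate("xyz"):
            _save_map(vel.u[ax], grid.affine, mdir / f"ifv_{name}.nii", "m/s")
        diagnostics[f"subject{s:02d}/{label}"] = {
            "residual": pres.residual, "iterations": pres.iterations,
            "method": pres.method, "conservation_ratio": pres.conservation_ratio,
        }
    (out / "solver_diagnostics.json").write_text(json.dumps(diagnostics, indent=2))


def _stage_stats(cfg: RunConfig, out: Path, state: dict) -> None:
    if not state.get("summaries"):
        raise ValueError("stats stage requires solve")
    df, report = stats.cohort_table(state["summaries"])
    df.to_csv(out / "cohort_table.csv", index=False)
    (out / "cohort_report.txt").write_text(report)


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "fit": _stage_fit,
    "domain": _stage_domain,
    "solve": _stage_solve,
    "stats": _stage_stats,
}
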