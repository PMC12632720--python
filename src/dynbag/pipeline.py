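"""End-to-end orchestration: simulate -> fnc -> train -> predict -> associate.

A :class:`RunConfig` fully determines a run (cohort spec, connectivity
options, model architectures per modality, association options, master
seed). :func:`run_pipeline` executes the five stages in order, persists
every stage's outputs under the run directory, and writes a JSON
manifest echoing the config with per-stage output hashes, wall-clock
times and library versions. Stages whose outputs already exist are
reused (idempotent resume); pass ``overwrite=True`` to recompute.

With ``linear_baseline`` models the whole run is bit-reproducible from
the master seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import h5py
import numpy as np
import pandas as pd
import yaml

from . import __version__
from .bagstats import AssociationSpec, MODALITIES, compute_bag, run_suite
from .brainage import (ModelConfig, TrainedBrainAgeModel, desk_config,
                       fullscale_config, train_brainage_cv)
from .fnc import (CleanOptions, Timecourses, clean_timecourses, compute_dfnc,
                  compute_sfnc, make_taper)
from .synthcohort import CohortSpec, load_cohort, simulate_cohort, write_cohort

logger = logging.getLogger("dynbag.pipeline")

STAGES = ("simulate", "fnc", "train", "predict", "associate")

__all__ = ["FncConfig", "RunConfig", "RunManifest", "run_pipeline", "STAGES"]


@dataclass(frozen=True)
class FncConfig:
    """Connectivity-stage options."""

    window_length: int = 20     # TRs
    sigma: float = 3.0          # TRs
    stride: int = 1             # TRs
    detrend_order: int = 3
    clip_mad: Optional[float] = 3.5
    lowpass_hz: Optional[float] = 0.15


@dataclass(frozen=True)
class RunConfig:
    """Serializable description of one pipeline run."""

    cohort: CohortSpec = CohortSpec()
    fnc: FncConfig = FncConfig()
    profile: str = "desk"                       # desk | full
    sfnc_architecture: str = "linear_baseline"  # or connectome_gcn
    dfnc_architecture: str = "linear_baseline"  # or bilstm
    include_subnetworks: bool = True
    min_age: float = 38.0
    outcomes: tuple[str, ...] = ("attention", "working_memory")
    seed: int = 0

    def __post_init__(self) -> None:
        if self.profile not in ("desk", "full"):
            raise ValueError("profile must be 'desk' or 'full'")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["cohort"] = self.cohort.to_dict()
        d["outcomes"] = list(self.outcomes)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        d["cohort"] = CohortSpec.from_dict(d["cohort"])
        d["fnc"] = FncConfig(**d["fnc"])
        d["outcomes"] = tuple(d["outcomes"])
        return cls(**d)

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(text))

    def model_config(self, modality: str, model_index: int) -> ModelConfig:
        arch = self.sfnc_architecture if modality == "sfnc" else self.dfnc_architecture
        make = desk_config if self.profile == "desk" else fullscale_config
        seed = int(np.random.default_rng(
            np.random.SeedSequence([self.seed, 0x40DE1, model_index])).integers(2**31))
        return make(arch, seed=seed)


@dataclass
class RunManifest:
    """Record of a completed run, sufficient to re-run any stage."""

    config: dict
    stages: list[dict] = field(default_factory=list)
    versions: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps({"config": self.config, "stages": self.stages,
                           "versions": self.versions}, indent=2)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _versions() -> dict:
    import scipy
    import statsmodels
    return {"dynbag": __version__, "numpy": np.__version__,
            "scipy": scipy.__version__, "pandas": pd.__version__,
            "statsmodels": statsmodels.__version__}


# ---------------------------------------------------------------------------
# stage implementations


def _stage_simulate(cfg: RunConfig, outdir: Path, overwrite: bool) -> list[Path]:
    cohort_dir = outdir / "cohort"
    marker = cohort_dir / "manifest.json"
    if marker.exists() and not overwrite:
        return [cohort_dir / "phenotypes.csv", cohort_dir / "timecourses.h5", marker]
    logger.info("simulate: cohort seed consumed: %d", cfg.cohort.seed)
    pheno, scans = simulate_cohort(cfg.cohort)
    write_cohort(pheno, scans, cohort_dir, spec=cfg.cohort, overwrite=True)
    return [cohort_dir / "phenotypes.csv", cohort_dir / "timecourses.h5", marker]


def _stage_fnc(cfg: RunConfig, outdir: Path, overwrite: bool) -> list[Path]:
    path = outdir / "features.h5"
    if path.exists() and not overwrite:
        return [path]
    _, scans = load_cohort(outdir / "cohort")
    scan_ids = sorted(scans)
    # harmonize scan length: truncate to the cohort minimum T
    t_min = min(scans[s].n_timepoints for s in scan_ids)
    opts = CleanOptions(detrend_order=cfg.fnc.detrend_order,
                        clip_mad=cfg.fnc.clip_mad, lowpass_hz=cfg.fnc.lowpass_hz)
    taper = make_taper(cfg.fnc.window_length, cfg.fnc.sigma)
    sfnc_list, dfnc_list, subj = [], [], []
    for sid in scan_ids:
        tc = scans[sid]
        tc = Timecourses(data=tc.data[:t_min], tr=tc.tr, subject_id=tc.subject_id)
        tc = clean_timecourses(tc, opts)
        sfnc_list.append(compute_sfnc(tc).values)
        dfnc_list.append(compute_dfnc(tc, taper, stride=cfg.fnc.stride).windows)
        subj.append(tc.subject_id)
    with h5py.File(path, "w") as f:
        f.create_dataset("sfnc", data=np.stack(sfnc_list))
        f.create_dataset("dfnc", data=np.stack(dfnc_list))
        f.create_dataset("scan_ids", data=np.array(scan_ids, dtype="S"))
        f.create_dataset("subject_ids", data=np.array(subj, dtype="S"))
        f.attrs["window_length"] = cfg.fnc.window_length
        f.attrs["stride"] = cfg.fnc.stride
    return [path]


def _load_features(outdir: Path):
    with h5py.File(outdir / "features.h5", "r") as f:
        return (f["sfnc"][()], f["dfnc"][()],
                [s.decode() for s in f["scan_ids"][()]],
                [s.decode() for s in f["subject_ids"][()]])


def _model_keys(cfg: RunConfig) -> list[tuple[str, str]]:
    keys = [(m, "wide") for m in MODALITIES]
    if cfg.include_subnetworks:
        networks = cfg.cohort.partition.networks
        keys += [(m, n) for n in networks for m in MODALITIES]
    return keys


def _features_for(modality: str, scope: str, sfnc: np.ndarray, dfnc: np.ndarray,
                  cfg: RunConfig) -> np.ndarray:
    """Model-ready features for one (modality, scope).

    sFNC: full matrices for the connectome model, upper-triangle vectors
    otherwise. dFNC: per-window upper-triangle vectors in window order.
    """
    part = cfg.cohort.partition
    if modality == "sfnc":
        mats = sfnc
        if scope != "wide":
            idx = np.asarray(part.indices(scope))
            mats = mats[:, idx[:, None], idx[None, :]]
        if cfg.sfnc_architecture == "connectome_gcn":
            return mats
        iu = np.triu_indices(mats.shape[1], k=1)
        return mats[:, iu[0], iu[1]]
    mats = dfnc
    if scope != "wide":
        idx = np.asarray(part.indices(scope))
        mats = mats[:, :, idx[:, None], idx[None, :]]
    iu = np.triu_indices(mats.shape[2], k=1)
    return mats[:, :, iu[0], iu[1]]


def _stage_train(cfg: RunConfig, outdir: Path, overwrite: bool) -> list[Path]:
    path = outdir / "models.npz"
    summary_path = outdir / "train_summary.tsv"
    if path.exists() and summary_path.exists() and not overwrite:
        return [path, summary_path]
    sfnc, dfnc, scan_ids, subject_ids = _load_features(outdir)
    pheno, _ = load_cohort(outdir / "cohort")
    ages = pheno.set_index("id")["age"]
    y = np.array([ages[s] for s in subject_ids])
    groups = np.array(subject_ids)
    blobs: dict[str, np.ndarray] = {
        "scan_ids": np.array(scan_ids, dtype="S"),
        "subject_ids": np.array(subject_ids, dtype="S"),
    }
    meta: dict[str, dict] = {}
    rows = []
    for k, (modality, scope) in enumerate(_model_keys(cfg)):
        mcfg = cfg.model_config(modality, k)
        logger.info("train: model (%s, %s) seed consumed: %d", modality, scope, mcfg.seed)
        x = _features_for(modality, scope, sfnc, dfnc, cfg)
        model = train_brainage_cv(x, y, groups=groups, cfg=mcfg,
                                  scope=scope, modality=modality)
        key = f"{modality}:{scope}"
        blobs[f"{key}|oof"] = model.oof_predictions
        blobs[f"{key}|cv_report"] = model.cv_report
        blobs[f"{key}|folds"] = model.fold_assignments
        state_meta = _pack_state(key, model, blobs)
        meta[key] = {"config": asdict(mcfg), "selected_epoch": model.selected_epoch,
                     "scope": scope, "modality": modality, **state_meta}
        rows.append({"modality": modality, "scope": scope,
                     "architecture": mcfg.architecture,
                     "selected_epoch": model.selected_epoch,
                     "cv_mae": model.cv_mae})
    blobs["meta_json"] = np.array(json.dumps(meta).encode())
    np.savez(path, **blobs)
    pd.DataFrame(rows).to_csv(summary_path, sep="\t", index=False)
    return [path, summary_path]


def _pack_state(key: str, model: TrainedBrainAgeModel, blobs: dict) -> dict:
    st = model.state
    if model.config.architecture == "linear_baseline":
        blobs[f"{key}|coef"] = st["coef"]
        blobs[f"{key}|xmean"] = st["scaler"].mean
        blobs[f"{key}|xsd"] = st["scaler"].sd
        return {"kind": "linear", "intercept": st["intercept"],
                "n_features": st["n_features"]}
    net = st["net"]
    for name, arr in net.params.items():
        blobs[f"{key}|param|{name}"] = arr
    if st["scaler"] is not None:
        blobs[f"{key}|xmean"] = st["scaler"].mean
        blobs[f"{key}|xsd"] = st["scaler"].sd
    return {"kind": "net", "y_mean": st["y_mean"], "y_sd": st["y_sd"],
            "input_shape": list(st["input_shape"]),
            "scaled": st["scaler"] is not None}


def _unpack_model(key: str, meta: dict, npz) -> TrainedBrainAgeModel:
    from .brainage import _Scaler, _build_net  # internal reconstruction

    mcfg = ModelConfig(**meta["config"])
    model = TrainedBrainAgeModel(
        config=mcfg, scope=meta["scope"], modality=meta["modality"],
        selected_epoch=meta["selected_epoch"],
        cv_report=npz[f"{key}|cv_report"],
        oof_predictions=npz[f"{key}|oof"],
        fold_assignments=npz[f"{key}|folds"],
    )
    if meta["kind"] == "linear":
        scaler = _Scaler.__new__(_Scaler)
        scaler.mean = npz[f"{key}|xmean"]
        scaler.sd = npz[f"{key}|xsd"]
        model.state = {"scaler": scaler, "coef": npz[f"{key}|coef"],
                       "intercept": meta["intercept"],
                       "n_features": meta["n_features"]}
        return model
    shape = tuple(meta["input_shape"])
    dummy = np.zeros((1, *shape))
    net = _build_net(mcfg, dummy, seed=0)
    for name in net.params:
        net.params[name] = npz[f"{key}|param|{name}"]
    scaler = None
    if meta["scaled"]:
        scaler = _Scaler.__new__(_Scaler)
        scaler.mean = npz[f"{key}|xmean"]
        scaler.sd = npz[f"{key}|xsd"]
    model.state = {"net": net, "scaler": scaler, "y_mean": meta["y_mean"],
                   "y_sd": meta["y_sd"], "input_shape": shape}
    return model


def load_models(outdir: Path) -> dict[tuple[str, str], TrainedBrainAgeModel]:
    npz = np.load(outdir / "models.npz")
    meta = json.loads(bytes(npz["meta_json"]).decode())
    return {tuple(k.split(":")): _unpack_model(k, m, npz) for k, m in meta.items()}


def _stage_predict(cfg: RunConfig, outdir: Path, overwrite: bool) -> list[Path]:
    path = outdir / "bags.tsv"
    if path.exists() and not overwrite:
        return [path]
    sfnc, dfnc, scan_ids, subject_ids = _load_features(outdir)
    pheno, _ = load_cohort(outdir / "cohort")
    models = load_models(outdir)
    frames = []
    for (modality, scope), model in models.items():
        # out-of-fold predictions: every scan's prediction comes from the
        # fold model that never saw its subject
        preds = pd.Series(model.oof_predictions, index=subject_ids)
        per_subject = preds.groupby(level=0).mean()
        frames.append(compute_bag(per_subject, pheno, modality, scope))
    bags = pd.concat(frames, ignore_index=True)
    bags.to_csv(path, sep="\t", index=False)
    return [path]


def _stage_associate(cfg: RunConfig, outdir: Path, overwrite: bool) -> list[Path]:
    path = outdir / "associations.tsv"
    if path.exists() and not overwrite:
        return [path]
    bags = pd.read_csv(outdir / "bags.tsv", sep="\t")
    pheno, _ = load_cohort(outdir / "cohort")
    spec = AssociationSpec(min_age=cfg.min_age)
    networks = cfg.cohort.partition.networks if cfg.include_subnetworks else []
    table = run_suite(bags, pheno, outcomes=cfg.outcomes, spec=spec,
                      networks=networks)
    table.to_csv(path, sep="\t", index=False)
    return [path]


_STAGE_FNS = {
    "simulate": _stage_simulate,
    "fnc": _stage_fnc,
    "train": _stage_train,
    "predict": _stage_predict,
    "associate": _stage_associate,
}


def run_pipeline(
    cfg: RunConfig,
    outdir: str | Path,
    stages: Optional[Sequence[str]] = None,
    overwrite: bool = False,
) -> RunManifest:
    """Execute the pipeline and write ``manifest.json`` under ``outdir``.

    ``stages`` restricts execution to a subset (inputs of the first
    requested stage must already exist on disk). Existing stage outputs
    are reused unless ``overwrite`` is set.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    requested = list(stages) if stages is not None else list(STAGES)
    unknown = set(requested) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stages {sorted(unknown)}; valid: {list(STAGES)}")
    (outdir / "config.yaml").write_text(cfg.to_yaml())
    manifest = RunManifest(config=cfg.to_dict(), versions=_versions())
    for name in STAGES:
        if name not in requested:
            continue
        t0 = time.perf_counter()
        try:
            outputs = _STAGE_FNS[name](cfg, outdir, overwrite)
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
        manifest.stages.append({
            "name": name,
            "seconds": round(time.perf_counter() - t0, 3),
            "outputs": {str(p.relative_to(outdir)): _sha256(p) for p in outputs},
        })
    (outdir / "manifest.json").write_text(manifest.to_json())
    return manifest
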