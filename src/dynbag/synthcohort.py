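"""Synthetic cohort generation for brain-age pipelines.

Real training cohorts for FNC-based brain-age models (large healthy
biobank samples plus a clinical schizophrenia sample) are access
controlled, so this module generates cohorts carrying the statistical
structure the downstream analysis assumes:

* phenotypes (age, sex, site, diagnosis, two cognitive scores) with a
  latent per-subject brain-age acceleration ``true_bag``;
* a target correlation matrix per subject in which a designated set of
  "aging edges" drifts linearly with effective age
  (chronological age + true_bag), so patients' connectivity looks
  ``delta`` years older on average;
* component time courses sampled from a Gaussian process whose
  instantaneous covariance equals that target correlation plus a slow
  random-walk perturbation, re-projected to a valid correlation matrix;
* cognitive scores negatively coupled to the latent acceleration.

Everything is a pure function of the :class:`CohortSpec`, including its
seed. The latent ``true_bag`` column is written to disk but excluded by
the loader unless explicitly requested, so the pipeline cannot peek.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import h5py
import numpy as np
import pandas as pd

from .fnc import Timecourses
from .partition import NetworkPartition, default_partition

__all__ = [
    "CohortSpec",
    "default_aging_edges",
    "nearest_correlation",
    "base_correlation",
    "raw_edge_value",
    "target_fnc",
    "generate_phenotypes",
    "simulate_timecourses",
    "simulate_cohort",
    "write_cohort",
    "load_cohort",
    "read_timecourses_txt",
    "LATENT_COLUMNS",
]

LATENT_COLUMNS = ("true_bag",)

_SCORE_BASELINE = 50.0  # arbitrary cognitive-score origin


@dataclass(frozen=True)
class CohortSpec:
    """Full description of a synthetic cohort (a pure function of this spec).

    Aging edges are ``(i, j, slope)`` with i < j and slope in correlation
    units per year of effective age. ``delta`` is the mean brain-age
    acceleration injected into patients (years); ``gamma_*`` couple the
    cognitive scores to the latent acceleration (score units per year).
    """

    n_subjects: int = 200
    age_low: float = 40.0
    age_high: float = 80.0
    prop_patients: float = 0.5
    n_sites: int = 3
    n_components: int = 20
    n_timepoints: int = 160
    tr: float = 2.0
    aging_edges: Optional[tuple[tuple[int, int, float], ...]] = None
    delta: float = 5.0
    gamma_attention: float = -0.5
    gamma_memory: float = -0.5
    sigma_cog: float = 1.0
    true_bag_sd: float = 2.0
    dynamic_drift_sd: float = 0.02
    scans_per_subject: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("age_low", "age_high", "prop_patients", "delta",
                     "gamma_attention", "gamma_memory", "sigma_cog",
                     "true_bag_sd", "dynamic_drift_sd", "tr"):
            v = getattr(self, name)
            if not np.isfinite(v):
                raise ValueError(f"CohortSpec field {name!r} must be finite, got {v}")
        if self.n_subjects < 0:
            raise ValueError("n_subjects must be >= 0")
        if not 0.0 <= self.prop_patients <= 1.0:
            raise ValueError("prop_patients must lie in [0, 1]")
        if not self.age_low < self.age_high:
            raise ValueError("age_low must be strictly below age_high")
        if self.n_sites < 1 or self.n_components < 2 or self.n_timepoints < 2:
            raise ValueError("n_sites >= 1, n_components >= 2, n_timepoints >= 2 required")
        if self.tr <= 0:
            raise ValueError("tr must be positive")
        if self.scans_per_subject not in (1, 2):
            raise ValueError("scans_per_subject must be 1 or 2")
        if self.aging_edges is None:
            object.__setattr__(
                self, "aging_edges",
                default_aging_edges(self.n_components, seed=self.seed),
            )
        for (i, j, slope) in self.aging_edges:
            if not (0 <= i < j < self.n_components):
                raise ValueError(f"aging edge ({i},{j}) must satisfy 0 <= i < j < C")
            if not np.isfinite(slope):
                raise ValueError(f"aging edge ({i},{j}) has non-finite slope")

    @property
    def age_mid(self) -> float:
        return 0.5 * (self.age_low + self.age_high)

    @property
    def partition(self) -> NetworkPartition:
        return default_partition(self.n_components)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["aging_edges"] = [list(e) for e in self.aging_edges]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "CohortSpec":
        d = dict(d)
        if d.get("aging_edges") is not None:
            d["aging_edges"] = tuple(
                (int(i), int(j), float(s)) for i, j, s in d["aging_edges"]
            )
        return cls(**d)


def default_aging_edges(
    n_components: int,
    n_edges: Optional[int] = None,
    slope: float = 0.008,
    seed: int = 0,
) -> tuple[tuple[int, int, float], ...]:
    """Deterministically pick edges whose correlation drifts with age.

    By default 2C distinct edges (capped at the number available) with a
    common slope of 0.008/yr — over a 40-year span a 0.32 swing, large
    enough for a regressor to read age off the connectome yet within the
    valid correlation range.
    """
    c = n_components
    all_edges = [(i, j) for i in range(c) for j in range(i + 1, c)]
    if n_edges is None:
        n_edges = min(2 * c, len(all_edges))
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xED6E5]))
    chosen = rng.choice(len(all_edges), size=n_edges, replace=False)
    return tuple((all_edges[k][0], all_edges[k][1], float(slope)) for k in sorted(chosen))


# ---------------------------------------------------------------------------
# correlation targets


def nearest_correlation(m: np.ndarray, tol: float = 1e-8, max_iter: int = 200) -> np.ndarray:
    """Project a symmetric matrix to a positive semi-definite correlation
    matrix by alternating eigenvalue clipping at 0 and unit-diagonal
    renormalization. Raises if the iteration fails to converge."""
    a = (np.asarray(m, dtype=float) + np.asarray(m, dtype=float).T) / 2.0
    for _ in range(max_iter):
        vals, vecs = np.linalg.eigh(a)
        if vals[0] >= -tol and np.allclose(np.diag(a), 1.0, atol=tol):
            np.fill_diagonal(a, 1.0)
            return np.clip(a, -1.0, 1.0)
        vals = np.clip(vals, 0.0, None)
        a = (vecs * vals) @ vecs.T
        d = np.sqrt(np.clip(np.diag(a), 1e-12, None))
        a = a / np.outer(d, d)
        a = (a + a.T) / 2.0
    raise RuntimeError(
        "positive semi-definite correlation projection did not converge "
        f"within {max_iter} iterations (aging-edge slopes may be too large)"
    )


def base_correlation(spec: CohortSpec) -> np.ndarray:
    """Age-independent base correlation shared by the whole cohort.

    A low-rank factor structure (3 latent factors) gives realistic
    positive/negative blocks; derived from the spec seed only.
    """
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 0xBA5E]))
    c = spec.n_components
    loadings = rng.normal(0.0, 0.35, size=(c, 3))
    cov = loadings @ loadings.T + np.eye(c)
    d = 1.0 / np.sqrt(np.diag(cov))
    return nearest_correlation(cov * np.outer(d, d))


def raw_edge_value(spec: CohortSpec, edge_index: int, age: float,
                   true_bag: float = 0.0) -> float:
    """Unclipped, unprojected value of one aging edge at an effective age.

    base + slope * (age + true_bag - age_mid); exposed so the linear
    drift can be checked independently of the PSD repair.
    """
    i, j, slope = spec.aging_edges[edge_index]
    base = base_correlation(spec)[i, j]
    return float(base + slope * (age + true_bag - spec.age_mid))


def target_fnc(
    age: float,
    diagnosis: str,
    spec: CohortSpec,
    true_bag: Optional[float] = None,
    base: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Target correlation matrix for a subject.

    Aging edges take ``base + slope * (effective_age - age_mid)`` where
    the effective age is chronological age plus the subject's brain-age
    acceleration (``delta`` for patients when no latent value is given,
    0 for controls); entries are clipped to [-0.99, 0.99] and the matrix
    re-projected to the nearest PSD correlation matrix.
    """
    if not np.isfinite(age):
        raise ValueError(f"age must be finite, got {age}")
    if true_bag is None:
        true_bag = spec.delta if diagnosis == "SZ" else 0.0
    m = (base_correlation(spec) if base is None else base).copy()
    shift = age + true_bag - spec.age_mid
    for (i, j, slope) in spec.aging_edges:
        v = float(np.clip(m[i, j] + slope * shift, -0.99, 0.99))
        m[i, j] = m[j, i] = v
    return nearest_correlation(m)


# ---------------------------------------------------------------------------
# phenotypes


def generate_phenotypes(spec: CohortSpec) -> pd.DataFrame:
    """Draw the phenotype table.

    Ages are uniform on [age_low, age_high]; diagnosis is Bernoulli with
    ``prop_patients``; the latent acceleration true_bag is
    N(delta, true_bag_sd^2) for patients and N(0, true_bag_sd^2) for
    controls; each cognitive score is baseline + gamma * true_bag +
    N(0, sigma_cog^2). Fully reproducible from the spec seed.
    """
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 0x9E07]))
    n = spec.n_subjects
    cols = ["id", "age", "sex", "site", "dx", "attention", "working_memory", "true_bag"]
    if n == 0:
        return pd.DataFrame(columns=cols)
    age = rng.uniform(spec.age_low, spec.age_high, size=n)
    sex = np.where(rng.random(n) < 0.5, "F", "M")
    site = np.array([f"site{k + 1:02d}" for k in rng.integers(0, spec.n_sites, size=n)])
    dx = np.where(rng.random(n) < spec.prop_patients, "SZ", "HC")
    true_bag = rng.normal(0.0, spec.true_bag_sd, size=n)
    true_bag[dx == "SZ"] += spec.delta
    attention = (_SCORE_BASELINE + spec.gamma_attention * true_bag
                 + rng.normal(0.0, spec.sigma_cog, size=n))
    memory = (_SCORE_BASELINE + spec.gamma_memory * true_bag
              + rng.normal(0.0, spec.sigma_cog, size=n))
    return pd.DataFrame({
        "id": [f"S{k:05d}" for k in range(n)],
        "age": age,
        "sex": sex,
        "site": site,
        "dx": dx,
        "attention": attention,
        "working_memory": memory,
        "true_bag": true_bag,
    })


# ---------------------------------------------------------------------------
# time courses


def _sym_noise(rng: np.random.Generator, c: int) -> np.ndarray:
    z = rng.standard_normal((c, c))
    z = (z + z.T) / np.sqrt(2.0)
    np.fill_diagonal(z, 0.0)
    return z


def _sampling_root(r: np.ndarray) -> np.ndarray:
    """Cholesky factor of a correlation matrix, repairing if needed."""
    try:
        return np.linalg.cholesky(r + 1e-10 * np.eye(r.shape[0]))
    except np.linalg.LinAlgError:
        fixed = nearest_correlation(r)
        return np.linalg.cholesky(fixed + 1e-10 * np.eye(r.shape[0]))


def simulate_timecourses(row: pd.Series, spec: CohortSpec, seed: int,
                         subject_id: Optional[str] = None) -> Timecourses:
    """Sample one scan's T x C time courses for a phenotype row.

    A zero-mean Gaussian process whose instantaneous covariance is the
    subject's target correlation plus a slowly drifting symmetric
    perturbation (random walk with per-step scale ``dynamic_drift_sd``),
    re-projected to a valid correlation at each step. Deterministic
    given ``seed``.
    """
    if spec.partition.n_components != spec.n_components:
        raise ValueError("partition size does not match n_components")
    rng = np.random.default_rng(seed)
    c, t = spec.n_components, spec.n_timepoints
    target = target_fnc(row["age"], row["dx"], spec,
                        true_bag=row.get("true_bag"))
    sid = subject_id or str(row.get("id", ""))
    if spec.dynamic_drift_sd == 0.0:
        root = _sampling_root(target)
        data = rng.standard_normal((t, c)) @ root.T
        return Timecourses(data=data, tr=spec.tr, subject_id=sid)
    # random-walk perturbation of the off-diagonal entries
    steps = rng.standard_normal((t, c, c))
    steps = (steps + steps.transpose(0, 2, 1)) / np.sqrt(2.0)
    idx = np.arange(c)
    steps[:, idx, idx] = 0.0
    drift = np.cumsum(spec.dynamic_drift_sd * steps, axis=0)
    inst = np.clip(target[None] + drift, -0.99, 0.99)
    inst[:, idx, idx] = 1.0
    # per-step projection to a valid correlation via eigenvalue clipping,
    # keeping a matrix square root for sampling
    vals, vecs = np.linalg.eigh(inst)
    vals = np.clip(vals, 1e-10, None)
    rec = np.einsum("tik,tk,tjk->tij", vecs, vals, vecs)
    d = np.sqrt(np.einsum("tii->ti", rec))
    roots = (vecs * np.sqrt(vals)[:, None, :]) / d[:, :, None]
    z = rng.standard_normal((t, c))
    data = np.einsum("tij,tj->ti", roots, z)
    return Timecourses(data=data, tr=spec.tr, subject_id=sid)


def simulate_cohort(spec: CohortSpec) -> tuple[pd.DataFrame, dict[str, Timecourses]]:
    """Phenotypes plus one (or two) scans per subject, keyed by scan id."""
    pheno = generate_phenotypes(spec)
    scans: dict[str, Timecourses] = {}
    ss = np.random.SeedSequence([spec.seed, 0x5CAA])
    child = ss.spawn(max(1, len(pheno)) * spec.scans_per_subject)
    k = 0
    for _, row in pheno.iterrows():
        for r in range(spec.scans_per_subject):
            scan_id = row["id"] if spec.scans_per_subject == 1 else f"{row['id']}_r{r + 1}"
            seed = int(child[k].generate_state(1)[0] % (2**31))
            scans[scan_id] = simulate_timecourses(row, spec, seed, subject_id=row["id"])
            k += 1
    return pheno, scans


# ---------------------------------------------------------------------------
# cohort I/O


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def write_cohort(
    phenotypes: pd.DataFrame,
    timecourses: dict[str, Timecourses],
    outdir: str | Path,
    spec: Optional[CohortSpec] = None,
    overwrite: bool = False,
) -> dict:
    """Persist a cohort: phenotypes.csv, timecourses.h5 (one 2-D dataset
    per scan with TR and subject id attributes) and manifest.json with
    content hashes. Refuses a non-empty directory unless ``overwrite``."""
    outdir = Path(outdir)
    if outdir.exists() and any(outdir.iterdir()) and not overwrite:
        raise FileExistsError(
            f"{outdir} is not empty; pass overwrite=True to replace its contents"
        )
    outdir.mkdir(parents=True, exist_ok=True)
    pheno_path = outdir / "phenotypes.csv"
    phenotypes.to_csv(pheno_path, index=False)
    h5_path = outdir / "timecourses.h5"
    with h5py.File(h5_path, "w") as f:
        for scan_id, tc in timecourses.items():
            ds = f.create_dataset(scan_id, data=tc.data)
            ds.attrs["tr"] = tc.tr
            ds.attrs["subject_id"] = tc.subject_id or scan_id
    manifest = {
        "n_subjects": int(len(phenotypes)),
        "n_scans": len(timecourses),
        "scans": sorted(timecourses.keys()),
        "spec": spec.to_dict() if spec is not None else None,
        "seed": spec.seed if spec is not None else None,
        "files": {
            "phenotypes.csv": _sha256(pheno_path),
            "timecourses.h5": _sha256(h5_path),
        },
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def load_cohort(
    cohort_dir: str | Path,
    include_latent: bool = False,
) -> tuple[pd.DataFrame, dict[str, Timecourses]]:
    """Read a cohort written by :func:`write_cohort`.

    The latent ``true_bag`` column is dropped unless ``include_latent``
    is set (tests only), so the analysis cannot read the ground truth.
    """
    cohort_dir = Path(cohort_dir)
    pheno = pd.read_csv(cohort_dir / "phenotypes.csv")
    if not include_latent:
        pheno = pheno.drop(columns=[c for c in LATENT_COLUMNS if c in pheno], errors="ignore")
    scans: dict[str, Timecourses] = {}
    with h5py.File(cohort_dir / "timecourses.h5", "r") as f:
        for scan_id in f:
            ds = f[scan_id]
            scans[scan_id] = Timecourses(
                data=ds[()], tr=float(ds.attrs["tr"]),
                subject_id=str(ds.attrs["subject_id"]),
            )
    return pheno, scans


def read_timecourses_txt(path: str | Path, tr: float,
                         subject_id: Optional[str] = None) -> Timecourses:
    """Plain-text alternative reader: whitespace-delimited T x C matrix."""
    data = np.loadtxt(path, ndmin=2)
    return Timecourses(data=data, tr=tr, subject_id=subject_id)
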