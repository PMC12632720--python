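"""In-memory study workflows over the library modules.

These functions express the simulation studies the package ships with —
feature extraction for a whole cohort, a brain-age-gap association
replicate on a fresh synthetic cohort, and a null-calibration replicate
— without touching disk. The analysis scripts, the test suite and the
acceptance script all drive the same code paths through here.

Problem sizes are desk scale: cohorts of a few hundred subjects with
C = 14-20 components and T = 120-300 TRs at TR = 2 s, dFNC stride 5 TR.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .bagstats import AssociationSpec, compute_bag, run_suite
from .brainage import ModelConfig, desk_config, train_brainage_cv
from .fnc import CleanOptions, clean_timecourses, compute_dfnc, compute_sfnc, make_taper
from .synthcohort import CohortSpec, simulate_cohort

__all__ = [
    "cohort_sfnc_matrices",
    "cohort_dfnc_sequences",
    "oof_bag_table",
    "bag_association_replicate",
    "null_pvalue_replicate",
]


def cohort_sfnc_matrices(
    pheno: pd.DataFrame,
    scans: dict,
    clean: bool = True,
) -> np.ndarray:
    """(N, C, C) static FNC matrices, one per phenotype row."""
    opts = CleanOptions()
    out = []
    for sid in pheno["id"]:
        tc = scans[sid]
        if clean:
            tc = clean_timecourses(tc, opts)
        out.append(compute_sfnc(tc).values)
    return np.stack(out)


def cohort_dfnc_sequences(
    pheno: pd.DataFrame,
    scans: dict,
    window_length: int = 20,
    sigma: float = 3.0,
    stride: int = 5,
    clean: bool = True,
) -> np.ndarray:
    """(N, W, F) tapered sliding-window feature sequences per scan.

    Each window's connectivity matrix is reduced to its strict upper
    triangle (F = C(C-1)/2 features) in window order.
    """
    taper = make_taper(window_length, sigma)
    opts = CleanOptions()
    out = []
    for sid in pheno["id"]:
        tc = scans[sid]
        if clean:
            tc = clean_timecourses(tc, opts)
        d = compute_dfnc(tc, taper, stride=stride)
        iu = np.triu_indices(d.n_components, k=1)
        out.append(d.windows[:, iu[0], iu[1]])
    return np.stack(out)


def oof_bag_table(
    pheno: pd.DataFrame,
    features_by_test: dict[tuple[str, str], np.ndarray],
    configs_by_test: dict[tuple[str, str], ModelConfig],
) -> pd.DataFrame:
    """Train one CV model per (modality, scope) and assemble out-of-fold
    brain-age gaps (every prediction comes from the fold that never saw
    the subject)."""
    y = pheno["age"].to_numpy()
    groups = pheno["id"].to_numpy()
    frames = []
    for (modality, scope), x in features_by_test.items():
        model = train_brainage_cv(x, y, groups=groups,
                                  cfg=configs_by_test[(modality, scope)],
                                  scope=scope, modality=modality)
        preds = pd.Series(model.oof_predictions, index=pheno["id"])
        frames.append(compute_bag(preds, pheno, modality, scope))
    return pd.concat(frames, ignore_index=True)


def bag_association_replicate(
    seed: int,
    n_subjects: int = 400,
    n_components: int = 20,
    delta: float = 5.0,
    gamma: float = -0.5,
    dfnc_architecture: str = "bilstm",
    stride: int = 5,
    outcomes: tuple[str, ...] = ("attention",),
) -> pd.DataFrame:
    """One full wide-brain replicate: simulate a cohort, train desk-scale
    sFNC (ridge) and dFNC models with grouped 5-fold CV, form out-of-fold
    BAGs and run the two-modality wide-brain association family.

    Returns the suite table (2 rows per outcome, FDR-corrected together).
    """
    spec = CohortSpec(n_subjects=n_subjects, n_components=n_components,
                      delta=delta, gamma_attention=gamma, gamma_memory=gamma,
                      seed=int(seed))
    pheno, scans = simulate_cohort(spec)
    sfnc = cohort_sfnc_matrices(pheno, scans)
    iu = np.triu_indices(n_components, k=1)
    features = {
        ("sfnc", "wide"): sfnc[:, iu[0], iu[1]],
        ("dfnc", "wide"): cohort_dfnc_sequences(pheno, scans, stride=stride),
    }
    configs = {
        ("sfnc", "wide"): desk_config("linear_baseline", seed=int(seed) + 1),
        ("dfnc", "wide"): desk_config(dfnc_architecture, seed=int(seed) + 2),
    }
    bags = oof_bag_table(pheno, features, configs)
    return run_suite(bags, pheno, outcomes=outcomes, spec=AssociationSpec(),
                     networks=[])


def null_pvalue_replicate(
    seed: int,
    n_subjects: int = 160,
    n_components: int = 14,
    n_timepoints: int = 120,
    stride: int = 5,
) -> np.ndarray:
    """Raw association p-values under the global null.

    The cohort carries no injected acceleration (delta = 0) and no
    BAG-cognition coupling (gammas = 0); ridge models are trained for
    both modalities at wide-brain and all 7 network scopes, and the full
    suite (2 wide + 14 sub-network tests per outcome, 2 outcomes) is
    fit. Returns the 32 raw p-values.
    """
    spec = CohortSpec(n_subjects=n_subjects, n_components=n_components,
                      n_timepoints=n_timepoints, delta=0.0,
                      gamma_attention=0.0, gamma_memory=0.0, seed=int(seed))
    pheno, scans = simulate_cohort(spec)
    part = spec.partition
    sfnc = cohort_sfnc_matrices(pheno, scans)
    dfnc_seq_full = cohort_dfnc_sequences(pheno, scans, stride=stride)
    # rebuild per-network window sequences from the full matrices
    taper_feats: dict[tuple[str, str], np.ndarray] = {}
    iu = np.triu_indices(n_components, k=1)
    taper_feats[("sfnc", "wide")] = sfnc[:, iu[0], iu[1]]
    taper_feats[("dfnc", "wide")] = dfnc_seq_full
    from .fnc import matrix_from_upper  # local to avoid cycle at import time

    dfnc_mats = np.stack([
        np.stack([matrix_from_upper(w) for w in subj]) for subj in dfnc_seq_full
    ])
    for net in part.networks:
        idx = np.asarray(part.indices(net))
        sub_iu = np.triu_indices(idx.size, k=1)
        taper_feats[("sfnc", net)] = sfnc[:, idx[:, None], idx[None, :]][:, sub_iu[0], sub_iu[1]]
        sub = dfnc_mats[:, :, idx[:, None], idx[None, :]]
        taper_feats[("dfnc", net)] = sub[:, :, sub_iu[0], sub_iu[1]]
    configs = {key: desk_config("linear_baseline", seed=int(seed) + 7 + k)
               for k, key in enumerate(taper_feats)}
    bags = oof_bag_table(pheno, taper_feats, configs)
    table = run_suite(bags, pheno, outcomes=("attention", "working_memory"),
                      spec=AssociationSpec(), networks=list(part.networks))
    return table["p_raw"].to_numpy()
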