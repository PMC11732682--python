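"""Desk-scale experiments: parameter recovery, trend studies, MAS end-to-end.

These harnesses reproduce, on synthetic phantoms at 32^3, the qualitative
behaviours of the full-scale method: recovery of a known deformation,
improvement with more cascades, folding reduction with stronger
regularization, the multi-resolution similarity advantage, and the
multi-atlas segmentation pipeline with NCC-based atlas selection.  Problem
sizes are the package's desk profile (see docs/methods.md): 32^3 volumes,
1-3 cascades, 30 epochs x 10 iterations — minutes per run on one CPU core.

All randomness derives from the integer seed arguments.
"""

from __future__ import annotations

import numpy as np

from .losses import LossConfig, multiscale_ncc
from .mas import (AtlasSet, FusionConfig, local_weighted_vote, majority_vote,
                  rank_atlases, register_atlases)
from .metrics import mean_foreground_dice
from .network import CascadeConfig, CascadeModel
from .phantom import DeformationSpec, PhantomSpec, make_cohort, make_pair, make_phantom
from .training import TrainConfig, train
from .transform import compose_fields, jacobian_report, warp_labels

#: desk-profile optimization settings (see docs/methods.md)
DESK_EPOCHS = 30
DESK_ITERS = 10
DESK_LR = 2e-3
DESK_LAM = 0.1
DESK_PATCHES = (5,)
DESK_SIZE = 32
EVAL_PATCHES = (5, 7, 9, 11)   # multi-scale evaluation metric


def desk_pair(seed: int, size: int = DESK_SIZE, max_disp: float = 4.0,
              sigma: float = 4.0):
    """One fixed/moving phantom pair with a known smooth truth field."""
    spec = PhantomSpec(size=size, seed=seed)
    dspec = DeformationSpec(size=size, max_disp=max_disp,
                            smoothness_sigma=sigma, seed=seed)
    return make_pair(spec, dspec)


def recovery_experiment(seed: int, n_cascades: int = 3,
                        lam: float = DESK_LAM,
                        patch_sizes=DESK_PATCHES,
                        epochs: int = DESK_EPOCHS,
                        iters: int = DESK_ITERS,
                        base_lr: float = DESK_LR,
                        size: int = DESK_SIZE) -> dict:
    """Train on one synthetic pair and measure how well the truth is recovered.

    The endpoint error (EPE) is the mean norm of the composition residual
    phi(x) + t(x + phi(x)): it equals the mean pre-registration displacement
    for phi = 0 and vanishes for a perfect inverse of the truth field t.
    """
    fixed, moving, fixed_labels, moving_labels, truth = desk_pair(seed, size)
    pre_dice = mean_foreground_dice(fixed_labels, moving_labels)
    pre_epe = float(truth.magnitudes().mean())
    model = CascadeModel(CascadeConfig(n_cascades=n_cascades,
                                       image_size=size), seed=seed)
    loss_cfg = LossConfig(patch_sizes=patch_sizes, lam=lam)
    log: list = []
    train([(moving, fixed)], model, loss_cfg,
          TrainConfig(epochs=epochs, iters_per_epoch=iters, batch_size=1,
                      seed=seed, base_lr=base_lr), log=log)
    warped, _, final = model.register(moving, fixed)
    propagated = warp_labels(moving_labels, final)
    post_dice = mean_foreground_dice(fixed_labels, propagated)
    post_epe = float(compose_fields([truth, final]).magnitudes().mean())
    return {
        "seed": seed,
        "n_cascades": n_cascades,
        "lam": lam,
        "pre_dice": pre_dice,
        "post_dice": post_dice,
        "dice_gain": post_dice - pre_dice,
        "pre_epe": pre_epe,
        "post_epe": post_epe,
        "neg_jacobian_pct": jacobian_report(final).neg_fraction,
        "ms_ncc": multiscale_ncc(fixed, warped, EVAL_PATCHES),
        "log": log,
        "model": model,
    }


def cascade_trend(seeds=(0, 1, 2), cascade_counts=(1, 3)) -> dict:
    """Dice / folding as a function of the number of cascades (fixed budget)."""
    per_count = {}
    for n in cascade_counts:
        runs = [recovery_experiment(s, n_cascades=n) for s in seeds]
        per_count[n] = {
            "median_dice": float(np.median([r["post_dice"] for r in runs])),
            "median_neg_jacobian_pct": float(
                np.median([r["neg_jacobian_pct"] for r in runs])),
            "runs": runs,
        }
    return per_count


def lambda_trend(seeds=(0, 1, 2), lams=(0.1, 1.0, 2.0)) -> dict:
    """Folding fraction as a function of the regularization weight."""
    per_lam = {}
    for lam in lams:
        runs = [recovery_experiment(s, lam=lam) for s in seeds]
        per_lam[lam] = {
            "median_neg_jacobian_pct": float(
                np.median([r["neg_jacobian_pct"] for r in runs])),
            "median_dice": float(np.median([r["post_dice"] for r in runs])),
            "runs": runs,
        }
    return per_lam


def multiresolution_comparison(seeds=(0, 1, 2), n_cascades: int = 2) -> dict:
    """Single-window vs multi-window similarity training at equal budget.

    Both runs are scored on the same multi-scale metric (the mean of the
    local NCC over windows 5, 7, 9, 11 between fixed and final warp).
    """
    single, multi = [], []
    for s in seeds:
        single.append(recovery_experiment(
            s, n_cascades=n_cascades, patch_sizes=(9,))["ms_ncc"])
        multi.append(recovery_experiment(
            s, n_cascades=n_cascades, patch_sizes=EVAL_PATCHES)["ms_ncc"])
    return {
        "median_single": float(np.median(single)),
        "median_multi": float(np.median(multi)),
        "single": single,
        "multi": multi,
    }


def train_cohort_model(cohort, seed: int, epochs: int = 2 * DESK_EPOCHS,
                       iters: int = DESK_ITERS) -> CascadeModel:
    """Unsupervised training on ordered inter-subject pairs from a cohort."""
    vols = [v for v, _, _ in cohort]
    pairs = [(vols[i], vols[j])
             for i in range(len(vols)) for j in range(len(vols)) if i != j]
    model = CascadeModel(CascadeConfig(n_cascades=3,
                                       image_size=vols[0].shape[0]),
                         seed=seed)
    val_pairs = pairs[:4]
    train(pairs, model, LossConfig(patch_sizes=DESK_PATCHES, lam=DESK_LAM),
          TrainConfig(epochs=epochs, iters_per_epoch=iters, batch_size=1,
                      seed=seed, base_lr=DESK_LR), val_pairs=val_pairs)
    return model


def mas_experiment(seed: int, cohort_size: int = 20, n_select: int = 10,
                   target_ages=(0.25, 0.4, 0.55, 0.7, 0.85),
                   model: CascadeModel | None = None) -> dict:
    """End-to-end multi-atlas segmentation on a synthetic age cohort.

    Targets are phantoms at the given ages with seeds disjoint from the
    cohort's.  For each target: register all atlases, rank by NCC, keep the
    best `n_select`, fuse by LWV and MV, and score against the target's true
    labels.  Also compares the age gap of NCC-selected atlases with a
    random selection of the same size.
    """
    cohort = make_cohort(cohort_size, PhantomSpec(size=DESK_SIZE, seed=seed))
    atlases = AtlasSet.from_cohort(cohort)
    ages = np.array([a for _, _, a in cohort])
    if model is None:
        model = train_cohort_model(cohort, seed)
    rng = np.random.default_rng([seed, 0x5e1ec7])
    results = []
    for k, age in enumerate(target_ages):
        tseed = int(np.random.SeedSequence([seed, 1000 + k]).generate_state(1)[0])
        target, target_labels = make_phantom(
            PhantomSpec(size=DESK_SIZE, age=age, seed=tseed))
        registered = register_atlases(target, atlases, model)
        warped = [r[0] for r in registered]
        propagated = [r[1] for r in registered]
        order, scores = rank_atlases(target, warped, "ncc")
        keep = order[:n_select]
        sel_warped = [warped[i] for i in keep]
        sel_labels = [propagated[i] for i in keep]
        lwv = local_weighted_vote(target, sel_warped, sel_labels,
                                  FusionConfig(n_select=n_select))
        mv = majority_vote(sel_labels)
        single = [mean_foreground_dice(target_labels, p) for p in sel_labels]
        rand = rng.choice(cohort_size, size=n_select, replace=False)
        results.append({
            "age": age,
            "lwv_dice": mean_foreground_dice(target_labels, lwv),
            "mv_dice": mean_foreground_dice(target_labels, mv),
            "best_single_dice": max(single),
            "mean_single_dice": float(np.mean(single)),
            "ncc_age_gap": float(np.median(np.abs(ages[keep] - age))),
            "random_age_gap": float(np.median(np.abs(ages[rand] - age))),
        })
    med = lambda key: float(np.median([r[key] for r in results]))
    return {
        "targets": results,
        "median_lwv_dice": med("lwv_dice"),
        "median_mv_dice": med("mv_dice"),
        "median_best_single_dice": med("best_single_dice"),
        "median_ncc_age_gap": med("ncc_age_gap"),
        "median_random_age_gap": med("random_age_gap"),
        "model": model,
    }
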