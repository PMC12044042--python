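"""Simulation studies exercising every stage of the pipeline.

Each function runs one self-contained study on synthetic data at desk
scale and returns a dict of summary numbers.  The `analysis/` drivers call
these to produce the project's result tables, and the acceptance machinery
re-runs them from scratch.  All randomness flows from the single ``seed``
argument.
"""

from __future__ import annotations

import numpy as np

from .affect import (
    DESIGN_COLUMNS,
    build_affect_design,
    group_affect_test,
    piecewise_valence_regression,
    subject_affect_regression,
)
from .data import ALL_REGIONS, AMY, AMY_SUBREGIONS
from .encoding import (
    cross_validate,
    fit_encoding_model,
    group_voxel_inference,
)
from .hrf import canonical_hrf, convolve_truncate
from .image_features import spectral_band_power
from .pls import pls_predict, simpls_fit
from .selectivity import (
    build_cross_response_table,
    confusion_cluster,
    loso_classification,
    loso_classify,
    on_off_target_regression,
    randomization_control,
)
from .synthesis import evolve_maximize, synthesize_battery
from .synthetic import (
    _grating,
    make_affective_imageset,
    make_cohort_ground_truth,
    make_feature_timeseries,
    make_ground_truth_weights,
    make_parcellation,
    make_toy_networks,
    session_features_from_networks,
    simulate_session,
)


def _spawn(seed: int, n: int) -> np.ndarray:
    return np.random.default_rng(seed).integers(0, 2**31 - 1, size=n)


# ---------------------------------------------------------------------------
# 1. SIMPLS vs ordinary least squares at full rank
# ---------------------------------------------------------------------------


def pls_ols_equivalence(seed: int = 0, T: int = 60, F: int = 5, V: int = 3) -> dict:
    """Max relative prediction gap between full-rank SIMPLS and OLS."""
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((T, F))
    Y = rng.standard_normal((T, V))
    model = simpls_fit(X, Y, n_components=F)
    pred_pls = pls_predict(model, X)
    Xc = np.column_stack([np.ones(T), X])
    beta, *_ = np.linalg.lstsq(Xc, Y, rcond=None)
    pred_ols = Xc @ beta
    scale = np.abs(pred_ols).max()
    gap = np.abs(pred_pls - pred_ols).max() / scale
    return {"max_rel_err": float(gap), "n": T}


# ---------------------------------------------------------------------------
# 2. Encoding-model parameter recovery
# ---------------------------------------------------------------------------


def encoding_recovery_study(
    seed: int = 0,
    n_subjects: int = 4,
    T: int = 300,
    F: int = 50,
    latent_rank: int = 8,
    noise_frac: float = 0.1,
) -> dict:
    """Fivefold CV performance and coefficient recovery on a high-SNR cohort.

    Four synthetic subjects, 120 amygdala voxels, BOLD noise at
    ``noise_frac`` of the signal SD.  The component count is set to the
    predictor dimension so the regression operates in its coefficient-
    identifiable regime (the regularized default is for prediction, not
    recovery).
    """
    seeds = _spawn(seed, 4 * n_subjects)
    parc = make_parcellation({"LB": 40, "CM": 30, "SF": 30, "AStr": 20}, seed=seed)
    hrf = canonical_hrf(dt=1.0)
    cv_means, coef_corrs = [], []
    for s in range(n_subjects):
        feats = make_feature_timeseries(
            T, F, latent_rank, seed=int(seeds[4 * s]), noise_sd=0.3
        )
        truth = make_ground_truth_weights(
            F, parc, distinctness=1.0, seed=int(seeds[4 * s + 1])
        )
        conv = convolve_truncate(feats, hrf, T)
        signal = conv.data @ truth.W
        truth.noise_sd = noise_frac * float(signal.std())
        bold = simulate_session(feats, truth, hrf, seed=int(seeds[4 * s + 2]))
        perf = cross_validate(
            conv, bold, AMY, k=5, n_components=F, seed=int(seeds[4 * s + 3])
        )
        cv_means.append(perf.r.mean())
        model = fit_encoding_model(conv, bold, AMY, n_components=F)
        B = model.pls.coefficients
        Wt = truth.W[:, bold.parcellation.region_indices(AMY)]
        Bc = B - B.mean(axis=0)
        Wc = Wt - Wt.mean(axis=0)
        num = (Bc * Wc).sum(axis=0)
        den = np.sqrt((Bc**2).sum(axis=0) * (Wc**2).sum(axis=0))
        coef_corrs.append((num / den).mean())
    return {
        "mean_cv_r": float(np.mean(cv_means)),
        "mean_coef_r": float(np.mean(coef_corrs)),
        "n": n_subjects,
    }


# ---------------------------------------------------------------------------
# 3. FDR calibration of the group voxel inference
# ---------------------------------------------------------------------------


def fdr_calibration_study(
    seed: int = 0,
    n_reps: int = 100,
    n_subjects: int = 20,
    n_null: int = 900,
    n_signal: int = 100,
    effect: float = 1.0,
    q: float = 0.05,
) -> dict:
    """Empirical false discovery proportion of the BH-corrected t map."""
    rng = np.random.default_rng(seed)
    n_vox = n_null + n_signal
    mu = np.zeros(n_vox)
    mu[:n_signal] = effect
    fdps = []
    for _ in range(n_reps):
        Z = mu + rng.standard_normal((n_subjects, n_vox))
        res = group_voxel_inference(Z, q=q)
        sig = res["q_sig"].to_numpy()
        n_disc = int(sig.sum())
        n_false = int(sig[n_signal:].sum())
        fdps.append(n_false / n_disc if n_disc else 0.0)
    fdps = np.asarray(fdps)
    return {
        "mean_fdp": float(fdps.mean()),
        "mc_se": float(fdps.std(ddof=1) / np.sqrt(n_reps)),
        "n": n_reps,
    }


# ---------------------------------------------------------------------------
# 4. Null calibration of cross-validated performance
# ---------------------------------------------------------------------------


def null_cv_study(
    seed: int = 0, T: int = 250, F: int = 50, n_voxels: int = 200
) -> dict:
    """Mean CV correlation when the outcomes are pure noise."""
    seeds = _spawn(seed, 3)
    parc = make_parcellation({"VC": n_voxels}, seed=int(seeds[0]))
    feats = make_feature_timeseries(T, F, 8, seed=int(seeds[1]))
    hrf = canonical_hrf(dt=1.0)
    conv = convolve_truncate(feats, hrf, T)
    rng = np.random.default_rng(int(seeds[2]))
    from .data import ParcellatedBOLD

    bold = ParcellatedBOLD(
        data=rng.standard_normal((T, n_voxels)), parcellation=parc
    )
    perf = cross_validate(conv, bold, "VC", k=5, n_components=20, seed=seed)
    return {"mean_r": float(perf.r.mean()), "n": n_voxels}


# ---------------------------------------------------------------------------
# 5. Spectral band assignment and Parseval identity
# ---------------------------------------------------------------------------


def spectral_assignment_check(size: int = 128) -> dict:
    """Analytic gratings at radii 3 and 30 land entirely in their bands."""
    g_low = 0.5 + 0.25 * _grating(size, 3, 0, 0.3)
    g_high = 0.5 + 0.25 * _grating(size, 21, 21, 1.1)  # radius ~29.7 > 24
    low_l, high_l = spectral_band_power(g_low, working_size=size)
    low_h, high_h = spectral_band_power(g_high, working_size=size)
    # Parseval on a composite image
    rng = np.random.default_rng(5)
    img = rng.uniform(0, 1, size=(size, size))
    x = img - img.mean()
    spec = np.fft.fft2(x)
    total_power = float(((spec.real**2 + spec.imag**2) / (x.size**2)).sum())
    direct = float((x**2).sum() / x.size)
    parseval_rel_err = abs(total_power - direct) / direct
    return {
        "low_grating_low_power": low_l,
        "low_grating_high_power": high_l,
        "high_grating_low_power": low_h,
        "high_grating_high_power": high_h,
        "parseval_rel_err": parseval_rel_err,
        "n": size,
    }


# ---------------------------------------------------------------------------
# 6. Affect-regression recovery and type-I control
# ---------------------------------------------------------------------------

#: Generating group-level coefficients for the recovery study (units of the
#: standardized design); between-subject SD 0.25 makes the three non-null
#: effects |d| = 1.
AFFECT_TRUE_BETAS = {
    "valence_z": 0.25,
    "arousal_z": -0.25,
    "interaction": 0.25,
    "median_r": 0.0,
    "median_g": 0.0,
    "median_b": 0.0,
    "power_high": 0.0,
    "power_low": 0.0,
}
AFFECT_BETWEEN_SD = 0.25


def affect_recovery_study(
    seed: int = 0,
    n_reps: int = 50,
    n_images: int = 400,
    n_subjects: int = 20,
    within_noise_sd: float = 0.5,
) -> dict:
    """Sign recovery of large effects and false-positive rate of null ones.

    Each repetition draws a fresh synthetic image set, builds the
    8-predictor design, simulates per-subject responses from the known
    coefficients (between-subject SD 0.25, within-subject image noise SD
    0.5), fits the per-subject regressions and the group test, and records
    (a) whether each |d| = 1 effect is recovered with the generating sign
    at p < 0.05 and (b) whether each null effect falsely reaches p < 0.05.
    """
    seeds = _spawn(seed, n_reps)
    true_vec = np.array([AFFECT_TRUE_BETAS[c] for c in DESIGN_COLUMNS])
    is_effect = true_vec != 0
    n_rec, n_eff, n_fp, n_null = 0, 0, 0, 0
    for rep in range(n_reps):
        rep_rng = np.random.default_rng(int(seeds[rep]))
        _, ratings, feats = make_affective_imageset(
            n_images, seed=int(seeds[rep]) % (2**31 - 1)
        )
        design = build_affect_design(ratings, feats)
        Xd = design[DESIGN_COLUMNS].to_numpy()
        betas = []
        for s in range(n_subjects):
            subj_beta = true_vec + AFFECT_BETWEEN_SD * rep_rng.standard_normal(
                len(true_vec)
            )
            y = Xd @ subj_beta + within_noise_sd * rep_rng.standard_normal(n_images)
            betas.append(
                subject_affect_regression(y, design, subject_id=f"sub-{s:02d}")
            )
        res = group_affect_test(betas)
        sign_ok = np.sign(res["mean"].to_numpy()) == np.sign(true_vec)
        sig = res["p"].to_numpy() < 0.05
        n_rec += int((sign_ok & sig)[is_effect].sum())
        n_eff += int(is_effect.sum())
        n_fp += int(sig[~is_effect].sum())
        n_null += int((~is_effect).sum())
    return {
        "sign_recovery_rate": n_rec / n_eff,
        "null_fp_rate": n_fp / n_null,
        "n": n_reps,
    }


# ---------------------------------------------------------------------------
# 7. Piecewise valence coding
# ---------------------------------------------------------------------------


def piecewise_valence_study(
    seed: int = 0, n_subjects: int = 20, n_images: int = 300, noise_sd: float = 0.3
) -> dict:
    """A V-shaped response yields opposite-signed segment slopes."""
    rng = np.random.default_rng(seed)
    vz = rng.standard_normal(n_images)
    vz = (vz - vz.mean()) / vz.std(ddof=1)
    R = np.abs(vz)[None, :] + noise_sd * rng.standard_normal((n_subjects, n_images))
    neg = piecewise_valence_regression(R, vz, "negative")
    pos = piecewise_valence_regression(R, vz, "positive")
    neu = piecewise_valence_regression(R, vz, "neutral")
    return {
        "neg_beta": neg["mean_beta"],
        "neg_p": neg["p"],
        "pos_beta": pos["mean_beta"],
        "pos_p": pos["p"],
        "neutral_beta": neu["mean_beta"],
        "n": n_subjects,
    }


# ---------------------------------------------------------------------------
# 8. Optimizer correctness on a known optimum
# ---------------------------------------------------------------------------


def optimizer_benchmark(
    seed: int = 0,
    n_runs: int = 20,
    d_z: int = 8,
    generations: int = 200,
    tol: float = 0.1,
) -> dict:
    """Evolve on a concave quadratic with a known optimum, 20 seeded runs."""
    seeds = _spawn(seed, 2 * n_runs)
    n_hit = 0
    all_monotone = True
    dists = []
    for i in range(n_runs):
        rng = np.random.default_rng(int(seeds[2 * i]))
        z_star = rng.uniform(-2, 2, size=d_z)

        def objective(codes, z_star=z_star):
            codes = np.atleast_2d(codes)
            return -((codes - z_star) ** 2).sum(axis=1)

        res = evolve_maximize(
            objective,
            d_z=d_z,
            population=28,
            generations=generations,
            init_sigma=1.0,
            seed=int(seeds[2 * i + 1]),
        )
        dist = float(np.linalg.norm(res.final_code - z_star))
        dists.append(dist)
        n_hit += dist < tol
        all_monotone &= bool(np.all(np.diff(res.objective_trace) >= 0))
    return {
        "n_within_tol": int(n_hit),
        "n_runs": n_runs,
        "all_traces_monotone": all_monotone,
        "median_distance": float(np.median(dists)),
        "n": n_runs,
    }


# ---------------------------------------------------------------------------
# 9. End-to-end selectivity of synthesized stimuli
# ---------------------------------------------------------------------------

#: Desk-scale region sizes for the selectivity cohort.
SELECTIVITY_REGIONS = {"LB": 10, "CM": 8, "SF": 8, "AStr": 6, "VC": 16, "IT": 12}


def build_selectivity_cohort(
    seed: int,
    distinctness: float = 1.0,
    n_subjects: int = 6,
    T: int = 240,
    F: int = 48,
    d_z: int = 12,
    image_size: int = 48,
    n_components: int = 20,
    noise_frac: float = 0.5,
):
    """Simulate a cohort and fit all per-subject, per-region encoding models.

    Session features are extractor responses to random generator frames,
    so the feature geometry seen in fitting matches what activation
    maximization can reach.  Returns ``(models, networks, parcellation)``.
    """
    seeds = _spawn(seed, 2 + 2 * n_subjects)
    networks = make_toy_networks(
        d_z=d_z, F=F, H=image_size, W=image_size, seed=int(seeds[0])
    )
    parc = make_parcellation(SELECTIVITY_REGIONS, seed=int(seeds[1]))
    truths = make_cohort_ground_truth(
        F, parc, n_subjects, distinctness=distinctness, seed=seed
    )
    hrf = canonical_hrf(dt=1.0)
    models = {}
    for s in range(n_subjects):
        subject = f"sub-{s:02d}"
        feats = session_features_from_networks(networks, T, seed=int(seeds[2 + 2 * s]))
        conv = convolve_truncate(feats, hrf, T)
        signal = conv.data @ truths[s].W
        truths[s].noise_sd = noise_frac * float(signal.std())
        bold = simulate_session(feats, truths[s], hrf, seed=int(seeds[3 + 2 * s]))
        for region in ALL_REGIONS:
            models[(subject, region)] = fit_encoding_model(
                conv, bold, region, n_components=n_components, subject_id=subject
            )
    return models, networks, parc


def selectivity_study(
    seed: int = 0,
    distinctness: float = 1.0,
    n_subjects: int = 6,
    n_seeds: int = 3,
    population: int = 16,
    generations: int = 30,
    n_null_iter: int = 40,
) -> dict:
    """Synthesize, cross-score and classify a full battery, with null control.

    Seven targets per subject (AMY, the four subregions, VC, IT) with
    ``n_seeds`` runs each; selectivity is summarized by the AMY on/off-
    target regression, the four-way subregion LOSO classification against
    the random-voxel-set percentile null, and the seven-way classification
    with confusion clustering.
    """
    seeds = _spawn(seed + 7, 3)
    models, networks, parc = build_selectivity_cohort(
        seed, distinctness=distinctness, n_subjects=n_subjects
    )
    battery = synthesize_battery(
        models,
        networks,
        n_seeds_per_target=n_seeds,
        population=population,
        generations=generations,
        base_seed=int(seeds[0]),
    )
    table = build_cross_response_table(battery.results, models, networks)
    onoff = on_off_target_regression(table, AMY)
    subjects = sorted({s for s, _ in models})
    sub_cols = [(s, r) for s in subjects for r in AMY_SUBREGIONS]
    anat4 = loso_classification(
        table, n_components=4, classes=list(AMY_SUBREGIONS), response_columns=sub_cols
    )
    acc7 = loso_classification(table, n_components=7)
    clusters7 = confusion_cluster(acc7)
    amy_models = {s: models[(s, AMY)] for s in subjects}
    # the null iterations replicate the battery's synthesis configuration
    # (same seeds per target, same ES budget) so the null accuracy
    # distribution matches the anatomical statistic's sampling structure
    null = randomization_control(
        amy_models,
        networks,
        n_sets=4,
        n_iter=n_null_iter,
        seed=int(seeds[1]),
        n_seeds_per_target=n_seeds,
        population=population,
        generations=generations,
    )
    return {
        "distinctness": distinctness,
        "on_target_beta": onoff["mean_beta"],
        "on_target_t": onoff["t"],
        "on_target_p": onoff["p"],
        "on_target_d": onoff["d"],
        "anat4_accuracy": anat4.accuracy_mean,
        "anat4_se": anat4.accuracy_se,
        "acc7_accuracy": acc7.accuracy_mean,
        "n_clusters_7way": clusters7["n_clusters"],
        "null_mean": null["mean"],
        "null_ci_low": null["ci_low"],
        "null_ci_high": null["ci_high"],
        "n_stimuli": table.n_stimuli,
        "n": n_subjects,
    }


# ---------------------------------------------------------------------------
# 10. Confusion clustering with duplicated classes
# ---------------------------------------------------------------------------


def clustering_duplicates_study(
    seed: int = 0,
    n_runs: int = 20,
    n_subjects: int = 6,
    per_class: int = 6,
    n_features: int = 10,
    sep: float = 3.0,
    noise_sd: float = 1.0,
) -> dict:
    """Five classes, two with identical distributions: expect 4 clusters.

    Each run draws Gaussian response vectors for five classes whose means
    are well separated except that classes "C" and "D" share a mean; the
    LOSO PLS-DA confusion clustering should merge exactly that pair.
    """
    classes = np.array(["A", "B", "C", "D", "E"])
    seeds = _spawn(seed, n_runs)
    n_correct = 0
    cluster_counts = []
    for run in range(n_runs):
        rng = np.random.default_rng(int(seeds[run]))
        means = sep * rng.standard_normal((5, n_features))
        means[3] = means[2]  # C and D are indistinguishable
        X, labels, subjects = [], [], []
        for s in range(n_subjects):
            for ci, c in enumerate(classes):
                pts = means[ci] + noise_sd * rng.standard_normal(
                    (per_class, n_features)
                )
                X.append(pts)
                labels.extend([c] * per_class)
                subjects.extend([f"sub-{s:02d}"] * per_class)
        X = np.vstack(X)
        summary = loso_classify(X, np.array(labels), np.array(subjects), n_components=5)
        clustering = confusion_cluster(summary)
        cluster_counts.append(clustering["n_clusters"])
        merged_cd = clustering["assignments"]["C"] == clustering["assignments"]["D"]
        n_correct += int(clustering["n_clusters"] == 4 and merged_cd)
    return {
        "frac_exactly_4": n_correct / n_runs,
        "cluster_counts": cluster_counts,
        "n": n_runs,
    }
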