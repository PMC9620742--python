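"""Spatiotemporal organisation: pairwise activity correlations, pairwise
ROI distances, bootstrapped group median differences, trial-to-trial
correlation analyses, the HDA time course, and a mixed-effects test of
spatial clustering.

The clustering question — do neurons that carry movement-type information
sit closer together and fire more similarly than the rest of the
population? — is answered with a generalized linear mixed model of the
pairwise Pearson correlation::

    r ~ distance * decoding_accuracy + (1 | movement) + (1 | animal)

with distance (µm, centred) × accuracy (z-scored) as interacting fixed
effects and random intercepts for movement type and animal, estimated by
REML.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf

from .signal_prep import loess_smooth

PAIR_COLUMNS = (
    "neuron_i", "neuron_j", "pearson_r", "distance_um",
    "group_i", "group_j", "movement", "animal_id",
)


def pairwise_distances(centroids_um: np.ndarray) -> np.ndarray:
    """Euclidean distance matrix between ROI centroids (µm)."""
    d = centroids_um[:, None, :] - centroids_um[None, :, :]
    return np.sqrt((d**2).sum(axis=-1))


def pairwise_activity_correlations(
    aligned_data: np.ndarray,
    time_axis: np.ndarray,
    trial_labels: np.ndarray,
    centroids_um: np.ndarray,
    epoch: tuple[float, float],
    frame_rate: float,
    groups: np.ndarray | None = None,
    animal_id: str = "animal0",
    smooth_span_s: float = 1.0,
) -> pd.DataFrame:
    """Pearson r per unordered neuron pair per movement.

    Correlations are computed on the trial-averaged, LOESS-smoothed
    (1 s span) ΔF/F₀ within the peri-movement epoch.  Pairs containing a
    constant trace get ``pearson_r = NaN`` and ``flagged = True``.
    """
    n_neurons = aligned_data.shape[0]
    if n_neurons < 2:
        raise ValueError("need at least 2 neurons")
    if groups is None:
        groups = np.array(["all"] * n_neurons)
    f = np.flatnonzero((time_axis >= epoch[0] - 1e-9) & (time_axis < epoch[1] - 1e-9))
    dist = pairwise_distances(centroids_um)
    iu, ju = np.triu_indices(n_neurons, k=1)
    rows = []
    for mv in np.unique(trial_labels):
        mean_traces = aligned_data[:, trial_labels == mv][:, :, f].mean(axis=1)
        sm = np.stack([loess_smooth(tr, smooth_span_s, frame_rate) for tr in mean_traces])
        sd = sm.std(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            R = np.corrcoef(sm)
        for i, j in zip(iu, ju):
            r = R[i, j] if sd[i] > 1e-12 and sd[j] > 1e-12 else np.nan
            rows.append((i, j, r, dist[i, j], groups[i], groups[j], mv, animal_id))
    out = pd.DataFrame(rows, columns=list(PAIR_COLUMNS))
    out["flagged"] = ~np.isfinite(out["pearson_r"])
    return out


def group_median_difference(
    pairs: pd.DataFrame,
    value: str,
    group: str = "HDA",
    reference: str = "all",
    n_boot: int = 10_000,
    rng: np.random.Generator | None = None,
) -> tuple[float, tuple[float, float]]:
    """Bootstrapped median difference: median(group) − median(reference).

    A pair belongs to ``group`` when both neurons carry that label;
    ``reference = "all"`` uses every pair, otherwise pairs of the named
    label.  Groups are resampled independently with replacement.
    """
    rng = np.random.default_rng(0) if rng is None else rng

    def values_of(name: str) -> np.ndarray:
        if name == "all":
            v = pairs[value]
        else:
            v = pairs.loc[(pairs["group_i"] == name) & (pairs["group_j"] == name), value]
        return v.dropna().to_numpy()

    g, ref = values_of(group), values_of(reference)
    if len(g) < 5 or len(ref) < 5:
        raise ValueError("need at least 5 pairs per group")
    bg = np.median(g[rng.integers(0, len(g), size=(n_boot, len(g)))], axis=1)
    br = np.median(ref[rng.integers(0, len(ref), size=(n_boot, len(ref)))], axis=1)
    diff = bg - br
    return float(np.median(diff)), (
        float(np.percentile(diff, 2.5)), float(np.percentile(diff, 97.5))
    )


def mean_trial_pair_correlation(trials_x_time: np.ndarray) -> float:
    """Mean Pearson r over all unordered trial pairs of one neuron."""
    n = trials_x_time.shape[0]
    if n < 2:
        raise ValueError("need at least 2 trials")
    sd = trials_x_time.std(axis=1)
    ok = sd > 1e-12
    if ok.sum() < 2:
        return float("nan")
    R = np.corrcoef(trials_x_time[ok])
    iu, ju = np.triu_indices(ok.sum(), k=1)
    return float(R[iu, ju].mean())


def trial_correlation_analyses(
    aligned_data: np.ndarray,
    time_axis: np.ndarray,
    trial_labels: np.ndarray,
    epoch: tuple[float, float],
    frame_rate: float,
    bias_class: np.ndarray,
    motion_index_trials: np.ndarray | None = None,
    movement_related: np.ndarray | None = None,
    n_boot: int = 10_000,
    boot_sample: int = 50,
    n_bins: int = 5,
    smooth_span_s: float = 1.0,
    rng: np.random.Generator | None = None,
) -> dict:
    """Trial-to-trial similarity of single neurons and of the population.

    Per neuron and movement: the mean Pearson r over all trial pairs of
    the smoothed peri-movement ΔF/F₀, summarised as bootstrapped medians
    per bias class (``n_boot`` repetitions of ``boot_sample`` draws).
    When a per-trial motion index is supplied, the trial-pair r of the
    summed movement-related population ΔF/F₀ is binned by the trial-pair
    r of the motion index (bootstrapped median per bin).
    """
    rng = np.random.default_rng(0) if rng is None else rng
    f = np.flatnonzero((time_axis >= epoch[0] - 1e-9) & (time_axis < epoch[1] - 1e-9))
    labels = np.asarray(trial_labels)
    n_neurons = aligned_data.shape[0]
    per_neuron = []
    smoothed = {}  # movement -> neurons x trials x frames
    for mv in np.unique(labels):
        sel = aligned_data[:, labels == mv][:, :, f]
        sm = np.empty_like(sel)
        for i in range(n_neurons):
            for k in range(sel.shape[1]):
                sm[i, k] = loess_smooth(sel[i, k], smooth_span_s, frame_rate)
        smoothed[mv] = sm
        for i in range(n_neurons):
            per_neuron.append((i, mv, bias_class[i], mean_trial_pair_correlation(sm[i])))
    per_neuron = pd.DataFrame(per_neuron, columns=["neuron", "movement", "bias", "mean_r"])

    class_medians = {}
    for (mv, cls), sub in per_neuron.groupby(["movement", "bias"]):
        v = sub["mean_r"].dropna().to_numpy()
        if len(v) == 0:
            continue
        draws = v[rng.integers(0, len(v), size=(n_boot, min(boot_sample, len(v))))]
        med = np.median(draws, axis=1)
        class_medians[(mv, cls)] = (float(np.median(med)),
                                    (float(np.percentile(med, 2.5)),
                                     float(np.percentile(med, 97.5))))

    population = None
    if motion_index_trials is not None:
        mr = np.ones(n_neurons, bool) if movement_related is None else movement_related
        rows = []
        for mv in np.unique(labels):
            sel = labels == mv
            pop = smoothed[mv][mr].sum(axis=0)            # trials x frames
            mi = np.asarray(motion_index_trials)[sel][:, f]
            n_tr = pop.shape[0]
            iu, ju = np.triu_indices(n_tr, k=1)
            r_pop = np.corrcoef(pop)[iu, ju]
            r_mi = np.corrcoef(mi)[iu, ju]
            for a, b in zip(r_mi, r_pop):
                rows.append((mv, a, b))
        population = pd.DataFrame(rows, columns=["movement", "mi_r", "pop_r"])
        edges = np.linspace(population["mi_r"].min() - 1e-9,
                            population["mi_r"].max() + 1e-9, n_bins + 1)
        population["mi_bin"] = np.digitize(population["mi_r"], edges[1:-1])
        binned = []
        for b, sub in population.groupby("mi_bin"):
            v = sub["pop_r"].to_numpy()
            draws = v[rng.integers(0, len(v), size=(n_boot, min(boot_sample, len(v))))]
            binned.append((b, float(sub["mi_r"].median()),
                           float(np.median(np.median(draws, axis=1))), len(v)))
        population_binned = pd.DataFrame(
            binned, columns=["mi_bin", "mi_r_median", "pop_r_median", "n_pairs"]
        )
    else:
        population_binned = None

    return {
        "per_neuron": per_neuron,
        "class_medians": class_medians,
        "population_pairs": population,
        "population_binned": population_binned,
    }


def hda_timecourse(
    correct_per_neuron: list[np.ndarray],
    threshold: float,
    n_boot: int = 2000,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Fraction of neurons decoding above chance at each frame.

    For each neuron and frame, the bootstrap CI (over trials) of the LOO
    accuracy is computed; the neuron counts at that frame when the lower
    bound exceeds the session threshold.
    """
    rng = np.random.default_rng(0) if rng is None else rng
    fractions = None
    for correct in correct_per_neuron:
        n = correct.shape[0]
        idx = rng.integers(0, n, size=(n_boot, n))
        boot = correct[idx].mean(axis=1)              # n_boot x frames
        lo = np.percentile(boot, 2.5, axis=0)
        flag = (lo > threshold).astype(float)
        fractions = flag if fractions is None else fractions + flag
    return fractions / len(correct_per_neuron)


@dataclass
class ClusterModelFit:
    params: pd.Series
    bse: pd.Series
    pvalues: pd.Series
    dropped_random_terms: list = field(default_factory=list)
    converged: bool = True
    result: object = None


def fit_clustering_model(pairs: pd.DataFrame, accuracies: np.ndarray) -> ClusterModelFit:
    """Mixed model of pairwise correlation on distance × decoding accuracy.

    ``accuracies`` maps neuron index → decoding accuracy; a pair's
    accuracy covariate is the mean of its two neurons'.  Distance is
    centred (µm); accuracy is z-scored.  Random intercepts for movement
    type and animal are fitted as crossed variance components under REML.
    A singular random-effects structure triggers a refit without the
    offending term (flagged in ``dropped_random_terms``); with no random
    terms left the model falls back to OLS.
    """
    df = pairs.dropna(subset=["pearson_r"]).copy()
    if df["animal_id"].nunique() < 2 or df["movement"].nunique() < 2:
        raise ValueError("need >= 2 animals and >= 2 movement types")
    acc = np.asarray(accuracies, dtype=float)
    pair_acc = (acc[df["neuron_i"].to_numpy()] + acc[df["neuron_j"].to_numpy()]) / 2
    df["acc_z"] = (pair_acc - pair_acc.mean()) / max(pair_acc.std(), 1e-12)
    df["dist_c"] = df["distance_um"] - df["distance_um"].mean()
    df["r"] = df["pearson_r"]

    vc_full = {"movement": "0 + C(movement)", "animal": "0 + C(animal_id)"}
    dropped: list[str] = []
    vc = dict(vc_full)
    while True:
        try:
            if vc:
                model = smf.mixedlm(
                    "r ~ dist_c * acc_z", df,
                    groups=np.ones(len(df)), vc_formula=vc, re_formula="0",
                )
                fit = model.fit(reml=True, method="lbfgs")
                vcomp = dict(zip(vc.keys(), np.atleast_1d(fit.vcomp)))
                singular = [k for k, v in vcomp.items() if not np.isfinite(v) or v < 1e-10]
                if singular and len(vc) > 0:
                    for k in singular:
                        vc.pop(k, None)
                        dropped.append(k)
                    if singular:
                        continue
                return ClusterModelFit(
                    params=fit.params[["Intercept", "dist_c", "acc_z", "dist_c:acc_z"]],
                    bse=fit.bse[["Intercept", "dist_c", "acc_z", "dist_c:acc_z"]],
                    pvalues=fit.pvalues[["Intercept", "dist_c", "acc_z", "dist_c:acc_z"]],
                    dropped_random_terms=dropped,
                    converged=bool(fit.converged),
                    result=fit,
                )
            break
        except (np.linalg.LinAlgError, ValueError):
            if not vc:
                break
            k = next(iter(vc))
            vc.pop(k)
            dropped.append(k)
    ols = smf.ols("r ~ dist_c * acc_z", df).fit()
    return ClusterModelFit(
        params=ols.params, bse=ols.bse, pvalues=ols.pvalues,
        dropped_random_terms=dropped, converged=True, result=ols,
    )


def residual_diagnostics(fit: ClusterModelFit, pairs: pd.DataFrame) -> pd.DataFrame:
    """Residual-vs-fitted summary per covariate (correlation of residuals
    with each fixed-effect covariate; near zero for a well-specified mean
    model)."""
    res = fit.result
    resid = np.asarray(res.resid)
    fitted = np.asarray(res.fittedvalues)
    df = pairs.dropna(subset=["pearson_r"])
    dist = df["distance_um"].to_numpy() - df["distance_um"].mean()
    rows = [
        ("fitted", float(np.corrcoef(resid, fitted)[0, 1])),
        ("distance", float(np.corrcoef(resid, dist)[0, 1])),
    ]
    return pd.DataFrame(rows, columns=["covariate", "resid_correlation"])
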