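"""Spectral-count interaction scoring against control runs.

Each bait-prey pair observed in at least one bait replicate is scored
with a two-component count mixture in the SAINT family's spirit:

* the *background* component is a negative binomial whose mean is the
  prey's mean PSM count over all control runs (floored at a pseudocount
  of 0.1) and whose dispersion is shared across preys, estimated by
  method of moments over the whole control compendium;
* the *true interaction* component is a negative binomial with the same
  dispersion and mean ``max(bait replicate mean, 2 x background mean)``
  — a true interactor is assumed at least twofold above background.

With equal priors, each replicate count gets a posterior probability of
arising from the true component; the pair's probability is the mean of
its replicate posteriors. The Bayesian false-discovery rate (BFDR) at
rank k of the probability-sorted list is the cumulative mean of (1 - p)
over the top k pairs, with ties sharing the value of the last tied rank.

Baits are scored independently; there is no cross-bait shrinkage and no
protein-length normalization.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

#: serialized scoring table, SAINT "list" compatible
SCORE_COLUMNS = ["bait_id", "prey_id", "avg_spec", "control_avg",
                 "fold_change", "probability", "bfdr"]

PSEUDOCOUNT = 0.1
MIN_TRUE_FOLD = 2.0


@dataclass
class ScoringParams:
    pseudocount: float = PSEUDOCOUNT
    min_true_fold: float = MIN_TRUE_FOLD
    dispersion: float | None = None  # None = estimate from controls


def estimate_dispersion(control_matrix: np.ndarray) -> float:
    """Pooled method-of-moments NB dispersion over all control preys.

    ``alpha`` solves ``var = mean + alpha * mean**2`` pooled across preys:
    ``alpha = sum(var_i - mean_i) / sum(mean_i**2)``, clamped at 0
    (Poisson) when counts are underdispersed.
    """
    m = control_matrix.mean(axis=1)
    if control_matrix.shape[1] < 2:
        return 0.0
    v = control_matrix.var(axis=1, ddof=1)
    denom = float(np.sum(m ** 2))
    if denom == 0:
        return 0.0
    return max(0.0, float(np.sum(v - m)) / denom)


def _nb_logpmf(k: np.ndarray, mean: np.ndarray, alpha: float) -> np.ndarray:
    if alpha <= 0:
        return stats.poisson.logpmf(k, mean)
    r = 1.0 / alpha
    p = r / (r + mean)
    return stats.nbinom.logpmf(k, r, p)


def _pivot_counts(runs: pd.DataFrame) -> pd.DataFrame:
    """prey x run matrix of PSM counts, zeros filled."""
    return runs.pivot_table(index="prey_id", columns="run_id",
                            values="psm_count", aggfunc="sum",
                            fill_value=0)


def score_bait(bait_runs: pd.DataFrame, control_runs: pd.DataFrame,
               params: ScoringParams | None = None) -> pd.DataFrame:
    """Score every prey seen in a bait's replicates against the controls.

    Parameters
    ----------
    bait_runs : long-format run table for a single bait (>= 2 replicates).
    control_runs : long-format table of control runs (>= 2 runs).

    Returns one row per prey with nonzero count in at least one bait
    replicate, with columns :data:`SCORE_COLUMNS` (bfdr filled by
    :func:`compute_bfdr`).
    """
    params = params or ScoringParams()
    baits = bait_runs["bait_id"].unique()
    if len(baits) != 1:
        raise ValueError("score_bait expects runs of exactly one bait")
    if control_runs.empty:
        raise ValueError("at least two control runs are required")
    bait_id = baits[0]

    bait_mat = _pivot_counts(bait_runs)
    ctrl_mat = _pivot_counts(control_runs)
    n_reps = bait_mat.shape[1]
    n_ctrl = ctrl_mat.shape[1]
    if n_reps < 2:
        raise ValueError("at least two bait replicates are required")
    if n_ctrl < 2:
        raise ValueError("at least two control runs are required")

    # drop preys never observed in the bait
    bait_mat = bait_mat.loc[bait_mat.sum(axis=1) > 0]
    if bait_mat.empty:
        return compute_bfdr(pd.DataFrame(columns=SCORE_COLUMNS))

    alpha = (params.dispersion if params.dispersion is not None
             else estimate_dispersion(ctrl_mat.to_numpy(dtype=float)))

    # control mean over ALL control runs (zeros included)
    ctrl_totals = ctrl_mat.sum(axis=1)
    control_avg = (bait_mat.index.to_series()
                   .map(ctrl_totals).fillna(0.0).to_numpy() / n_ctrl)

    counts = bait_mat.to_numpy(dtype=float)          # preys x replicates
    avg_spec = counts.mean(axis=1)
    mu_bg = np.maximum(control_avg, params.pseudocount)
    mu_true = np.maximum(avg_spec, params.min_true_fold * mu_bg)

    log_true = _nb_logpmf(counts, mu_true[:, None], alpha)
    log_bg = _nb_logpmf(counts, mu_bg[:, None], alpha)
    # posterior of the true component under equal priors, per replicate
    with np.errstate(over="ignore"):
        posterior = 1.0 / (1.0 + np.exp(log_bg - log_true))
    probability = posterior.mean(axis=1)

    scored = pd.DataFrame({
        "bait_id": bait_id,
        "prey_id": bait_mat.index,
        "avg_spec": avg_spec,
        "control_avg": control_avg,
        "fold_change": avg_spec / np.maximum(control_avg, params.pseudocount),
        "probability": probability,
    }).reset_index(drop=True)
    return compute_bfdr(scored)


def compute_bfdr(scored: pd.DataFrame) -> pd.DataFrame:
    """Fill the ``bfdr`` column from probabilities.

    Sorts by probability descending (ties broken by prey identifier for
    determinism); bfdr at rank k is ``mean(1 - p)`` over the top k; tied
    probabilities share the bfdr of the last tied rank.
    """
    if scored.empty:
        out = scored.copy()
        out["bfdr"] = pd.Series(dtype=float)
        return out[[c for c in SCORE_COLUMNS if c in out.columns]
                   + [c for c in out.columns if c not in SCORE_COLUMNS]]
    out = scored.sort_values(["probability", "prey_id"],
                             ascending=[False, True],
                             kind="mergesort").reset_index(drop=True)
    ranks = np.arange(1, len(out) + 1)
    cum = np.cumsum(1.0 - out["probability"].to_numpy()) / ranks
    out["bfdr"] = cum
    # ties share the bfdr of the last tied rank
    out["bfdr"] = out.groupby("probability")["bfdr"].transform("max")
    return out


def score_all_baits(runs: pd.DataFrame,
                    params: ScoringParams | None = None) -> pd.DataFrame:
    """Score every bait in a combined run table against its controls."""
    controls = runs[runs["is_control"]]
    bait_runs = runs[~runs["is_control"]]
    frames = []
    for bait_id, group in bait_runs.groupby("bait_id", sort=True):
        frames.append(score_bait(group, controls, params))
    if not frames:
        return pd.DataFrame(columns=SCORE_COLUMNS)
    return pd.concat(frames, ignore_index=True)
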