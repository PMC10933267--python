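"""Downstream interactome analytics.

Bait-bait correlation clustering (Pearson on AvgSpec profiles, Ward
linkage on Euclidean distances), BioID/AP-MS method overlap, shared-prey
hub ranking, novelty annotation against known-PPI lists, per-prey Fisher
exact enrichment versus a reference interactome set with
Benjamini-Hochberg adjustment, and expression cross-referencing of preys
against stage-resolved embryonic RPKM tables.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from statsmodels.stats.multitest import multipletests


def build_matrix(hcis: pd.DataFrame, value: str = "avg_spec") -> pd.DataFrame:
    """Bait x prey AvgSpec matrix; preys missing from a bait are 0."""
    if hcis.empty:
        return pd.DataFrame()
    mat = hcis.pivot_table(index="bait_id", columns="prey_id",
                           values=value, aggfunc="mean", fill_value=0.0)
    return mat.sort_index().sort_index(axis=1)


@dataclass
class ClusterResult:
    correlation: pd.DataFrame
    linkage: np.ndarray
    labels: list
    newick: str
    excluded: list


def _to_newick(linkage: np.ndarray, labels: Sequence[str]) -> str:
    tree = hierarchy.to_tree(linkage)

    def render(node, parent_height):
        length = parent_height - node.dist
        if node.is_leaf():
            return f"{labels[node.id]}:{length:.6g}"
        left = render(node.left, node.dist)
        right = render(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    return render(tree, tree.dist) + ";"


def correlation_cluster(matrix: pd.DataFrame,
                        log_transform: bool = False) -> ClusterResult:
    """Pearson correlation between bait profiles + Ward dendrogram.

    Constant bait rows have undefined correlations; they are reported as
    missing in the correlation matrix and excluded from clustering with
    a warning. ``log_transform`` applies log1p first (off by default).
    """
    if matrix.shape[0] < 2:
        raise ValueError("at least two baits are required for clustering")
    data = np.log1p(matrix) if log_transform else matrix

    corr = data.T.corr(method="pearson")  # NaN for constant rows
    variances = data.var(axis=1)
    excluded = list(data.index[variances == 0])
    if excluded:
        warnings.warn(
            f"constant bait profiles excluded from clustering: {excluded}")
    usable = data.drop(index=excluded)
    if usable.shape[0] < 2:
        raise ValueError("fewer than two non-constant baits to cluster")
    linkage = hierarchy.linkage(usable.to_numpy(dtype=float), method="ward")
    labels = list(usable.index)
    return ClusterResult(correlation=corr, linkage=linkage, labels=labels,
                         newick=_to_newick(linkage, labels),
                         excluded=excluded)


def method_overlap(bioid_sets: Mapping[str, Iterable[str]],
                   apms_sets: Mapping[str, Iterable[str]]) -> dict:
    """Unique-prey overlap between BioID and AP-MS HCI sets."""
    bio = set().union(*bioid_sets.values()) if bioid_sets else set()
    ap = set().union(*apms_sets.values()) if apms_sets else set()
    return {
        "only_bioid": len(bio - ap),
        "both": len(bio & ap),
        "only_apms": len(ap - bio),
    }


def prey_sharing(hci_sets: Mapping[str, Iterable[str]]) -> pd.DataFrame:
    """Per-prey bait counts, ranked by count then prey id.

    The hub list reports how many baits' HCI sets contain each prey;
    ties rank lexicographically.
    """
    if not hci_sets:
        raise ValueError("at least one bait HCI set is required")
    counts: dict[str, int] = {}
    for prey_set in hci_sets.values():
        for prey in set(prey_set):
            counts[prey] = counts.get(prey, 0) + 1
    out = pd.DataFrame(sorted(counts.items()),
                       columns=["prey_id", "n_baits"])
    return (out.sort_values(["n_baits", "prey_id"],
                            ascending=[False, True], kind="mergesort")
            .reset_index(drop=True))


def top_hubs(sharing: pd.DataFrame) -> pd.DataFrame:
    """All preys at the maximal shared-bait count."""
    if sharing.empty:
        return sharing
    return sharing[sharing["n_baits"] == sharing["n_baits"].max()]


def novelty_annotation(hci_sets: Mapping[str, Iterable[str]],
                       known_pairs: Iterable[tuple[str, str]]) -> pd.DataFrame:
    """Label each bait's HCIs known vs novel against known-PPI lists.

    An HCI is known iff the (bait, prey) pair appears in at least one
    supplied database list; per-bait known/novel counts partition the
    HCI set.
    """
    known = set(known_pairs)
    rows = []
    for bait in sorted(hci_sets):
        preys = set(hci_sets[bait])
        n_known = sum((bait, prey) in known for prey in preys)
        rows.append((bait, n_known, len(preys) - n_known))
    return pd.DataFrame(rows, columns=["bait_id", "known", "novel"])


def fisher_vs_reference(study_sets: Mapping[str, Iterable[str]],
                        reference_sets: Mapping[str, Iterable[str]],
                        prey_universe: Iterable[str] | None = None,
                        q_max: float = 0.05) -> pd.DataFrame:
    """Per-prey Fisher exact comparison of two bait collections.

    For each prey, builds the 2x2 table of (baits detecting the prey vs
    not) x (study vs reference), computes the two-sided Fisher exact
    p-value and BH-adjusts across all tested preys. ``significant``
    flags q < ``q_max``; ``direction`` is "over" when the prey is
    detected by a larger fraction of study baits than reference baits.
    """
    if not reference_sets:
        raise ValueError("reference set collection must be non-empty")
    if set(study_sets) & set(reference_sets):
        raise ValueError("study and reference bait collections must be disjoint")
    n_study, n_ref = len(study_sets), len(reference_sets)
    if prey_universe is None:
        prey_universe = set()
        for s in (*study_sets.values(), *reference_sets.values()):
            prey_universe |= set(s)
    preys = sorted(prey_universe)

    study = {b: set(s) for b, s in study_sets.items()}
    ref = {b: set(s) for b, s in reference_sets.items()}
    rows = []
    for prey in preys:
        a = sum(prey in s for s in study.values())
        b = n_study - a
        c = sum(prey in s for s in ref.values())
        d = n_ref - c
        odds, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
        direction = "over" if a * n_ref > c * n_study else (
            "under" if a * n_ref < c * n_study else "equal")
        rows.append((prey, a, b, c, d, odds, p, direction))
    out = pd.DataFrame(rows, columns=["prey_id", "a", "b", "c", "d",
                                      "odds_ratio", "p", "direction"])
    if not out.empty:
        out["q"] = multipletests(out["p"], method="fdr_bh")[1]
        out["significant"] = out["q"] < q_max
    return out.sort_values(["q", "p", "prey_id"],
                           kind="mergesort").reset_index(drop=True)


def expression_crossref(preys: Iterable[str], expression: pd.DataFrame,
                        stage_window: Sequence[str],
                        threshold: float = 1.0,
                        inclusive: bool = False) -> dict:
    """Retain preys expressed above an RPKM threshold in a stage window.

    A prey is retained iff its maximum RPKM across the window exceeds
    the threshold (strict by default, "RPKM > 1"). Preys absent from the
    table count as not expressed and are listed under ``missing``.
    """
    window = expression[expression["stage"].isin(stage_window)]
    covered = set(window["stage"].unique())
    missing_stages = [s for s in stage_window if s not in covered]
    if missing_stages:
        raise ValueError(
            f"expression table does not cover stages: {missing_stages}")
    max_rpkm = window.groupby("gene_id")["rpkm"].max()
    retained, missing = [], []
    for prey in sorted(set(preys)):
        if prey not in max_rpkm.index:
            missing.append(prey)
            continue
        value = max_rpkm.loc[prey]
        if value >= threshold if inclusive else value > threshold:
            retained.append(prey)
    return {"retained": retained, "count": len(retained), "missing": missing}
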