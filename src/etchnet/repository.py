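"""Contaminant repository built from GFP control purifications.

A CRAPome-style database of nonspecific binders: for every prey detected
in at least one quality-passing GFP control run, the repository records
the percentage of runs in which it was detected, its average spectral
count over the runs where it was detected, and its maximum spectral
count — stratified into ``All`` (every control run), ``NLS`` (nuclear
localization-tagged GFPs only) and ``MYR`` (myristoylated GFPs only).
Runs carrying other tags (untagged, NES) contribute to ``All`` only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import pandas as pd

STRATA = ("All", "NLS", "MYR")

#: minimum detected proteins per control run, by assay
DEFAULT_QC_MIN = {"BioID": 1000, "AP-MS": 300}


class EmptyRepositoryError(ValueError):
    """No control run survived quality control."""


class UnknownStratumError(KeyError):
    pass


@dataclass(frozen=True)
class PreyStats:
    """Per-stratum repository statistics for one prey."""
    pct: float
    avg_spec: float
    max_spec: int
    present: bool = True


ABSENT = PreyStats(pct=0.0, avg_spec=0.0, max_spec=0, present=False)


@dataclass
class ContaminantRepository:
    """Per-prey, per-stratum detection statistics over control runs.

    ``table`` holds one row per (prey, stratum) with at least one
    detection: columns prey_id, stratum, n_detected, pct, avg_spec,
    max_spec. ``n_runs`` maps each stratum to the number of QC-passing
    runs it aggregates; a stratum with zero runs is marked absent rather
    than zero.
    """

    table: pd.DataFrame
    n_runs: dict = field(default_factory=dict)
    assay: str = "BioID"
    qc_min_proteins: int = DEFAULT_QC_MIN["BioID"]
    _index: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self._index = {
            (r.prey_id, r.stratum): PreyStats(r.pct, r.avg_spec,
                                              int(r.max_spec))
            for r in self.table.itertuples()
        }

    def flag_prey(self, prey_id: str, stratum: str = "All") -> PreyStats:
        """Look up a prey's contamination profile in one stratum.

        Absent preys come back with ``pct == 0`` and ``present=False``
        (callers treat avg_spec as 0). Unknown strata raise.
        """
        if stratum not in STRATA:
            raise UnknownStratumError(stratum)
        return self._index.get((prey_id, stratum), ABSENT)

    @property
    def preys(self) -> set:
        return set(self.table["prey_id"].unique())

    def to_frame(self) -> pd.DataFrame:
        out = self.table.copy()
        out["n_runs"] = out["stratum"].map(self.n_runs)
        return out[["prey_id", "stratum", "n_runs", "n_detected",
                    "pct", "avg_spec", "max_spec"]]


def qc_filter_runs(runs: pd.DataFrame, qc_min_proteins: int
                   ) -> tuple[pd.DataFrame, list[str]]:
    """Partition control runs into QC-passing and rejected.

    A run passes iff it detects at least ``qc_min_proteins`` preys with
    PSM > 0 (boundary inclusive). Raises :class:`EmptyRepositoryError`
    when nothing passes.
    """
    if qc_min_proteins <= 0:
        raise ValueError("qc_min_proteins must be positive")
    if runs.empty:
        raise EmptyRepositoryError("no control runs supplied")
    if not runs["is_control"].all():
        raise ValueError("qc_filter_runs expects control runs only")
    detected = (runs[runs["psm_count"] > 0]
                .groupby("run_id")["prey_id"].nunique())
    passing_ids = set(detected[detected >= qc_min_proteins].index)
    rejected = sorted(set(runs["run_id"].unique()) - passing_ids)
    passing = runs[runs["run_id"].isin(passing_ids)]
    if passing.empty:
        raise EmptyRepositoryError(
            f"all {runs['run_id'].nunique()} control runs fall below the "
            f"QC threshold of {qc_min_proteins} detected proteins")
    return passing.reset_index(drop=True), rejected


def _stratum_runs(runs: pd.DataFrame, stratum: str) -> pd.DataFrame:
    if stratum == "All":
        return runs
    return runs[runs["tag_class"] == stratum]


def build_repository(runs: pd.DataFrame, assay: str = "BioID",
                     qc_min_proteins: int | None = None,
                     apply_qc: bool = False) -> ContaminantRepository:
    """Aggregate QC-passing control runs into a contaminant repository.

    For each prey and stratum: ``pct`` = 100 x (runs detecting the prey) /
    (runs in the stratum); ``avg_spec`` = mean PSM over the runs where it
    was detected (not over all runs); ``max_spec`` = maximum PSM.

    Set ``apply_qc=True`` to run :func:`qc_filter_runs` first; otherwise
    the input is assumed to be already QC-passing.
    """
    if qc_min_proteins is None:
        qc_min_proteins = DEFAULT_QC_MIN.get(assay, 1000)
    if apply_qc:
        runs, _ = qc_filter_runs(runs, qc_min_proteins)
    if runs.empty:
        raise EmptyRepositoryError("no control runs to aggregate")

    detected = runs[runs["psm_count"] > 0]
    parts = []
    n_runs = {}
    for stratum in STRATA:
        sruns = _stratum_runs(runs, stratum)
        n = sruns["run_id"].nunique()
        n_runs[stratum] = n
        if n == 0:
            continue  # stratum absent, not zero
        sdet = _stratum_runs(detected, stratum)
        agg = sdet.groupby("prey_id")["psm_count"].agg(
            n_detected="count", avg_spec="mean", max_spec="max"
        ).reset_index()
        agg["stratum"] = stratum
        agg["pct"] = 100.0 * agg["n_detected"] / n
        parts.append(agg)
    table = (pd.concat(parts, ignore_index=True)
             [["prey_id", "stratum", "n_detected", "pct",
               "avg_spec", "max_spec"]]
             .sort_values(["prey_id", "stratum"], kind="mergesort")
             .reset_index(drop=True))
    return ContaminantRepository(table=table, n_runs=n_runs, assay=assay,
                                 qc_min_proteins=qc_min_proteins)


def repository_from_frame(frame: pd.DataFrame, n_runs: dict,
                          assay: str = "BioID") -> ContaminantRepository:
    """Rehydrate a repository from its serialized TSV layout."""
    cols = ["prey_id", "stratum", "n_detected", "pct", "avg_spec", "max_spec"]
    missing = [c for c in cols if c not in frame.columns]
    if missing:
        raise ValueError(f"repository table missing columns: {missing}")
    return ContaminantRepository(table=frame[cols].copy(), n_runs=dict(n_runs),
                                 assay=assay)
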