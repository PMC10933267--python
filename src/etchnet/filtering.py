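"""Compound high-confidence-interaction (HCI) filter.

A scored bait-prey pair is retained iff

1. its BFDR is below the threshold (default 0.01, strict), and
2. the prey appears in fewer than 10% of contaminant-repository control
   runs (strict), *or* is rescued because its bait AvgSpec is at least
   3x the repository AvgSpec (inclusive);
3. for BioID additionally, the prey must not be a flagged contaminant
   (frequent without rescue) in *either* the All or the NLS stratum.

Every record receives a decision log entry naming the first failing
clause (order: BFDR, elimination strata, frequency/rescue). Bait
self-detections are excluded from HCI sets. Missing repository entries
count as 0% frequency (pass) and are flagged in the log.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .repository import ContaminantRepository

DECISION_RETAINED = "retained"
DECISION_RETAINED_RESCUE = "retained_rescue"
DECISION_SELF = "excluded_self"
REJECT_BFDR = "rejected_bfdr"
REJECT_FREQUENCY = "rejected_frequency"


@dataclass
class FilterPolicy:
    """Thresholds of the compound HCI filter.

    ``bfdr_max`` and ``control_pct_max`` are strict upper bounds
    ("lower than 0.01", "less than 10%"); ``rescue_fold`` is inclusive
    ("three times higher" read as >= 3x). For BioID, a prey flagged in
    any stratum in ``elimination_strata`` is eliminated outright.
    """

    bfdr_max: float = 0.01
    control_pct_max: float = 10.0
    rescue_fold: float = 3.0
    assay: str = "BioID"
    elimination_strata: tuple[str, ...] = ("All", "NLS")
    #: stratum whose AvgSpec anchors the main rescue comparison
    rescue_stratum: str = "All"
    exclude_bait_self: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.bfdr_max < 1:
            raise ValueError("bfdr_max must lie in (0, 1)")
        if not 0 <= self.control_pct_max <= 100:
            raise ValueError("control_pct_max must lie in [0, 100]")
        if self.rescue_fold <= 1:
            raise ValueError("rescue_fold must exceed 1")
        if self.assay not in ("BioID", "AP-MS"):
            raise ValueError(f"unknown assay {self.assay!r}")


@dataclass
class FilterResult:
    hcis: pd.DataFrame
    log: pd.DataFrame
    policy: FilterPolicy = field(repr=False, default=None)


def _flagged(stats, avg_spec: float, policy: FilterPolicy) -> bool:
    """Frequent contaminant in a stratum, with no rescue there."""
    if stats.pct < policy.control_pct_max:
        return False
    return avg_spec < policy.rescue_fold * stats.avg_spec


def apply_filter(scored: pd.DataFrame, repo: ContaminantRepository,
                 policy: FilterPolicy | None = None) -> FilterResult:
    """Apply the compound HCI filter to a scored interaction table.

    Returns retained records plus a per-record decision log stating
    which clause fired. First-fail order: BFDR, elimination strata,
    frequency/rescue.
    """
    policy = policy or FilterPolicy()
    if repo.assay != policy.assay:
        raise ValueError(
            f"repository assay {repo.assay!r} does not match policy assay "
            f"{policy.assay!r}")

    decisions, notes = [], []
    for rec in scored.itertuples():
        note = ""
        if policy.exclude_bait_self and rec.prey_id == rec.bait_id:
            decisions.append(DECISION_SELF)
            notes.append(note)
            continue
        if not rec.bfdr < policy.bfdr_max:
            decisions.append(REJECT_BFDR)
            notes.append(note)
            continue
        all_stats = repo.flag_prey(rec.prey_id, policy.rescue_stratum)
        if not all_stats.present:
            note = "no repository entry"

        rejected = None
        if policy.assay == "BioID":
            for stratum in policy.elimination_strata:
                stats = repo.flag_prey(rec.prey_id, stratum)
                if stats.present and _flagged(stats, rec.avg_spec, policy):
                    rejected = f"rejected_contaminant_{stratum}"
                    break
        if rejected is None:
            if all_stats.pct < policy.control_pct_max:
                decisions.append(DECISION_RETAINED)
            elif rec.avg_spec >= policy.rescue_fold * all_stats.avg_spec:
                decisions.append(DECISION_RETAINED_RESCUE)
            else:
                decisions.append(REJECT_FREQUENCY)
        else:
            decisions.append(rejected)
        notes.append(note)

    log = scored.copy()
    log["decision"] = decisions
    log["note"] = notes
    retained = (log[log["decision"].isin(
        [DECISION_RETAINED, DECISION_RETAINED_RESCUE])]
        .reset_index(drop=True))
    return FilterResult(hcis=retained, log=log.reset_index(drop=True),
                        policy=policy)


def summarize_hcis(hcis: pd.DataFrame) -> dict:
    """Per-bait HCI counts, total interactions and unique preys.

    The total equals the sum of per-bait counts; the unique-prey count is
    the cardinality of the union of all baits' prey sets.
    """
    if hcis.empty:
        return {"per_bait": {}, "total_hcis": 0, "unique_preys": 0}
    per_bait = (hcis.groupby("bait_id")["prey_id"].nunique()
                .sort_index().to_dict())
    return {
        "per_bait": per_bait,
        "total_hcis": int(sum(per_bait.values())),
        "unique_preys": int(hcis["prey_id"].nunique()),
    }
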