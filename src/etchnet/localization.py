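"""MS-microscopy-style localization inference.

A bait's subcellular distribution is inferred by comparing its
quantitative interactome profile (prey -> AvgSpec) against reference
profiles of localization markers. For each compartment the score is the
Pearson correlation between the log1p-transformed bait and marker
profiles over the union of their preys (absent preys count as 0),
truncated at zero and max-normalized so the best-matching compartment
scores 1 whenever any correlation is positive.

The truncation + normalization scheme is this module's own scoring
formula, chosen to honor the [0, 1] score scale and the
correlation-of-profiles idea; it does not reproduce any external
service's exact published scores. Reference marker profiles are an
input file, not shipped.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd


@dataclass
class MarkerReference:
    """Per-compartment marker interactome profiles.

    ``profiles`` maps a compartment name to a prey -> reference AvgSpec
    mapping. Profiles must be non-negative and compartments unique.
    """

    profiles: dict[str, dict[str, float]]
    provenance: str = "user-supplied"

    def __post_init__(self) -> None:
        if not self.profiles:
            raise ValueError("at least one compartment profile is required")
        for comp, profile in self.profiles.items():
            if any(v < 0 for v in profile.values()):
                raise ValueError(f"negative abundance in profile {comp!r}")

    @classmethod
    def from_frame(cls, frame: pd.DataFrame,
                   provenance: str = "user-supplied") -> "MarkerReference":
        """Build from a tidy (compartment, prey_id, avg_spec) table."""
        profiles: dict[str, dict[str, float]] = {}
        for rec in frame.itertuples():
            profiles.setdefault(rec.compartment, {})[rec.prey_id] = \
                float(rec.avg_spec)
        return cls(profiles=profiles, provenance=provenance)


@dataclass
class LocalizationProfile:
    scores: dict[str, float]

    @property
    def primary(self) -> str | None:
        if not self.scores or max(self.scores.values()) == 0:
            return None
        return max(sorted(self.scores), key=lambda c: self.scores[c])


def localize(bait_profile: Mapping[str, float],
             reference: MarkerReference) -> LocalizationProfile:
    """Score a bait profile against every compartment marker profile."""
    raw: dict[str, float] = {}
    any_shared = False
    for comp, marker in reference.profiles.items():
        shared = set(bait_profile) & set(marker)
        if not shared:
            raw[comp] = 0.0
            continue
        any_shared = True
        preys = sorted(set(bait_profile) | set(marker))
        x = np.log1p([bait_profile.get(p, 0.0) for p in preys])
        y = np.log1p([marker.get(p, 0.0) for p in preys])
        if np.std(x) == 0 or np.std(y) == 0:
            raw[comp] = 0.0
            continue
        r = float(np.corrcoef(x, y)[0, 1])
        raw[comp] = max(0.0, r)
    if not any_shared:
        warnings.warn("bait profile shares no preys with any marker profile")
        return LocalizationProfile({c: 0.0 for c in reference.profiles})
    top = max(raw.values())
    if top == 0:
        return LocalizationProfile(raw)
    return LocalizationProfile({c: v / top for c, v in raw.items()})


def localize_all(bait_profiles: pd.DataFrame,
                 reference: MarkerReference) -> pd.DataFrame:
    """Localize every bait in a tidy (bait_id, prey_id, avg_spec) table."""
    rows = []
    for bait_id, group in bait_profiles.groupby("bait_id", sort=True):
        profile = dict(zip(group["prey_id"], group["avg_spec"]))
        result = localize(profile, reference)
        for comp in sorted(result.scores):
            rows.append((bait_id, comp, result.scores[comp],
                         comp == result.primary))
    return pd.DataFrame(rows, columns=["bait_id", "compartment", "score",
                                       "is_primary"])
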