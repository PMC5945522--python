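"""Candidate biomarker panels: intersection of the DE and PP tracks.

A miRNA enters the DE track when its BH-adjusted p-value is at most
``fdr_max`` and its mean raw read count at least ``min_mean``; it enters
the PP track when its predictive power is at least ``pp_min``.  The panel
for a subtype lists the intersection of the two tracks; manually curated
additions (e.g. literature candidates or count-plot picks) can be appended
but are always provenance-tagged "manual", never computed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import pandas as pd


class ConsistencyError(ValueError):
    pass


@dataclass
class CandidatePanel:
    subtype: str
    members: pd.DataFrame  # mirna_id index, column "source"
    thresholds: dict
    track_sizes: dict = field(default_factory=dict)  # n_de, n_pp, n_intersection

    @property
    def mirna_ids(self) -> list[str]:
        return list(self.members.index)


def build_panel(
    de: pd.DataFrame,
    pp: pd.DataFrame,
    subtype: str = "",
    fdr_max: float = 0.05,
    min_mean: float = 300.0,
    pp_min: float = 0.70,
    manual: list[str] | None = None,
) -> CandidatePanel:
    """Combine DE and PP results (same comparison) into a candidate panel.

    All thresholds are inclusive.  ``de`` and ``pp`` must cover the same
    miRNA universe; mismatched indices raise :class:`ConsistencyError`.
    """
    if set(de.index) != set(pp.index):
        raise ConsistencyError("DE and PP tables cover different miRNA universes")
    de_set = set(
        de.index[
            (de["fdr"] <= fdr_max).fillna(False)
            & (de["mean_read_count"] >= min_mean)
        ]
    )
    pp_set = set(pp.index[pp["pp"] >= pp_min])
    both = sorted(de_set & pp_set)

    rows = [(mid, "DE∩PP") for mid in both]
    for mid in manual or []:
        if mid not in {r[0] for r in rows}:
            rows.append((mid, "manual"))
    members = pd.DataFrame(
        rows, columns=["mirna_id", "source"]
    ).set_index("mirna_id")
    return CandidatePanel(
        subtype=subtype,
        members=members,
        thresholds={"fdr_max": fdr_max, "min_mean": min_mean, "pp_min": pp_min},
        track_sizes={
            "n_de": len(de_set),
            "n_pp": len(pp_set),
            "n_intersection": len(both),
        },
    )


def cross_subtype_overlap(panels: list[CandidatePanel]) -> pd.DataFrame:
    """Pairwise and all-way panel intersections by miRNA id.

    Returns one row per panel combination with the member ids and count.
    """
    if len(panels) < 2:
        raise ValueError("need at least 2 panels to intersect")
    sets = {p.subtype: set(p.mirna_ids) for p in panels}
    rows = []
    names = list(sets)
    for r in range(2, len(names) + 1):
        for combo in combinations(names, r):
            inter = set.intersection(*(sets[c] for c in combo))
            rows.append(
                {
                    "panels": "+".join(combo),
                    "n_common": len(inter),
                    "mirna_ids": ",".join(sorted(inter)),
                }
            )
    return pd.DataFrame(rows)


def write_panel(panel: CandidatePanel, path) -> None:
    panel.members.to_csv(path, sep="\t")
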