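"""Cut-point prognosis classification and reader/metric discordance.

Patients are called Poor prognosis when their burden metric strictly
exceeds the cohort cut point (a median in the study design) and Better
otherwise; ties at the cut go to Better, consistent with the median
split's low-group tie rule.  Discordance accounting compares the calls
made by the two readers and by the two metrics, patient by patient.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CutPoints",
    "PrognosisCall",
    "classify",
    "classify_series",
    "discordance_count",
    "discordance_matrix",
    "EXAMPLE_CUTPOINTS",
    "EXAMPLE_DISCORDANCE_PANELS",
]

POOR = "Poor"
BETTER = "Better"


@dataclass
class CutPoints:
    """Median cut points (ml for MTV, SUV·ml for TLG) per metric/reader."""

    mtv_m_cut: float
    mtv_a_cut: float
    tlg_m_cut: float
    tlg_a_cut: float

    def __post_init__(self) -> None:
        for name in ("mtv_m_cut", "mtv_a_cut", "tlg_m_cut", "tlg_a_cut"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")


@dataclass
class PrognosisCall:
    patient_id: str
    metric: str  # "MTV" | "TLG"
    reader: str  # "M" | "A"
    value: float
    group: str  # Poor | Better


#: Cut points from a published two-reader comparison in CAR-T-treated
#: large-cell lymphoma (median MTV/TLG per reader), used as the worked
#: example for discordance accounting.
EXAMPLE_CUTPOINTS = CutPoints(mtv_m_cut=86.75, mtv_a_cut=63.55,
                              tlg_m_cut=917.77, tlg_a_cut=796.06)

#: The discordant patients of that study's comparison table, panel by
#: panel: each panel lists (patient, value under series 1, value under
#: series 2) for the patients whose Poor/Better call flips between the
#: two series; all other cohort patients were concordant.  Patient 7's
#: MTV(A) is printed as 79.51 in the MTV panel but 78.88 in the reader-A
#: panel of the source table; the panel-local values are kept.
EXAMPLE_DISCORDANCE_PANELS: dict[str, list[tuple[str, float, float]]] = {
    # MTV(M) vs MTV(A)
    "mtv_m_vs_mtv_a": [
        ("1", 94.62, 27.09),
        ("4", 66.74, 64.84),
        ("6", 95.37, 26.30),
        ("7", 78.88, 79.51),
    ],
    # TLG(M) vs TLG(A)
    "tlg_m_vs_tlg_a": [
        ("3", 3598.0, 360.15),
    ],
    # MTV(M) vs TLG(M)
    "mtv_m_vs_tlg_m": [
        ("1", 94.62, 352.68),
        ("2", 169.56, 755.96),
        ("3", 33.91, 3598.0),
        ("5", 59.39, 1236.68),
        ("6", 95.37, 327.59),
    ],
    # MTV(A) vs TLG(A)
    "mtv_a_vs_tlg_a": [
        ("2", 145.33, 715.48),
        ("4", 64.84, 461.37),
        ("5", 59.39, 958.60),
        ("7", 78.88, 692.98),
    ],
}

#: Which (cut for series 1, cut for series 2) applies to each panel.
EXAMPLE_PANEL_CUTS: dict[str, tuple[float, float]] = {
    "mtv_m_vs_mtv_a": (EXAMPLE_CUTPOINTS.mtv_m_cut, EXAMPLE_CUTPOINTS.mtv_a_cut),
    "tlg_m_vs_tlg_a": (EXAMPLE_CUTPOINTS.tlg_m_cut, EXAMPLE_CUTPOINTS.tlg_a_cut),
    "mtv_m_vs_tlg_m": (EXAMPLE_CUTPOINTS.mtv_m_cut, EXAMPLE_CUTPOINTS.tlg_m_cut),
    "mtv_a_vs_tlg_a": (EXAMPLE_CUTPOINTS.mtv_a_cut, EXAMPLE_CUTPOINTS.tlg_a_cut),
}


def classify(value: float, cut: float) -> str:
    """Poor if value > cut else Better (tie at the cut → Better)."""
    if cut <= 0:
        raise ValueError("cut point must be > 0")
    return POOR if value > cut else BETTER


def classify_series(patient_ids, values, cut: float,
                    metric: str = "", reader: str = "") -> list[PrognosisCall]:
    """Classify a whole series of measurements against one cut point."""
    return [
        PrognosisCall(patient_id=str(pid), metric=metric, reader=reader,
                      value=float(v), group=classify(float(v), cut))
        for pid, v in zip(patient_ids, values, strict=True)
    ]


def _group_map(calls: list[PrognosisCall]) -> dict[str, str]:
    return {c.patient_id: c.group for c in calls}


def discordance_count(calls_x: list[PrognosisCall],
                      calls_y: list[PrognosisCall]) -> tuple[int, list[str]]:
    """Count patients whose Poor/Better call differs between two series.

    Both series must cover the same patient set.
    """
    gx, gy = _group_map(calls_x), _group_map(calls_y)
    if set(gx) != set(gy):
        raise ValueError("patient sets differ between the two call series")
    discordant = sorted(pid for pid in gx if gx[pid] != gy[pid])
    return len(discordant), discordant


def discordance_matrix(calls: dict[tuple[str, str], list[PrognosisCall]]
                       ) -> tuple[pd.DataFrame, int, list[str]]:
    """Pairwise discordance for the four study comparisons, plus the union.

    ``calls`` maps (metric, reader) — ("MTV"|"TLG", "M"|"A") — to the
    cohort's calls under that series.  The compared pairs are the two
    within-metric reader comparisons and the two within-reader metric
    comparisons.  Returns (table, union count, union patient ids).
    """
    required = {("MTV", "M"), ("MTV", "A"), ("TLG", "M"), ("TLG", "A")}
    if not required <= set(calls):
        missing = required - set(calls)
        raise ValueError(f"missing call series for {sorted(missing)}")
    pairs = [
        ("MTV(M) vs MTV(A)", ("MTV", "M"), ("MTV", "A")),
        ("TLG(M) vs TLG(A)", ("TLG", "M"), ("TLG", "A")),
        ("MTV(M) vs TLG(M)", ("MTV", "M"), ("TLG", "M")),
        ("MTV(A) vs TLG(A)", ("MTV", "A"), ("TLG", "A")),
    ]
    rows = []
    union: set[str] = set()
    for name, a, b in pairs:
        count, ids = discordance_count(calls[a], calls[b])
        union |= set(ids)
        rows.append({"comparison": name, "discordant": count,
                     "patient_ids": ";".join(ids)})
    return pd.DataFrame(rows), len(union), sorted(union)


def example_discordance() -> tuple[pd.DataFrame, int, list[str]]:
    """Recompute the worked example's discordance counts from its values.

    Every listed patient's two values are classified against the panel's
    cut points; panels compare only patients printed with both values.
    Returns (per-panel counts, union count, union patient ids).
    """
    rows = []
    union: set[str] = set()
    for panel, entries in EXAMPLE_DISCORDANCE_PANELS.items():
        cut1, cut2 = EXAMPLE_PANEL_CUTS[panel]
        ids = [pid for pid, _, _ in entries]
        calls1 = classify_series(ids, [v1 for _, v1, _ in entries], cut1)
        calls2 = classify_series(ids, [v2 for _, _, v2 in entries], cut2)
        count, disc = discordance_count(calls1, calls2)
        union |= set(disc)
        rows.append({"comparison": panel, "discordant": count,
                     "patient_ids": ";".join(disc)})
    return pd.DataFrame(rows), len(union), sorted(union)
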