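"""Subtype marker selection by directional concordance across contrasts.

Given the three pairwise differential results — (TYPE_I vs TYPE_II),
(TYPE_I vs TYPE_III), (TYPE_II vs TYPE_III), in exactly that orientation —
each significant call is read as an ordering statement between two
subtypes ("this protein is higher in TYPE_I than in TYPE_II").  A protein
becomes a subtype marker when at least two such statements agree on which
subtype sits at the extreme.

Two selection rules are shipped because published marker counts of this
kind are not always reconstructible from a single strict reading:

``strict_both``
    protein is S-specific iff it is significant in *both* contrasts
    involving S with the same sign relative to S.

``any_two`` (default)
    protein must be significant in >= 2 contrasts whose ordering
    statements are mutually consistent; the subtype that is above (below)
    both others in every total order consistent with those statements is
    assigned UP (DOWN).  Transitivity is allowed, so a protein that rises
    stepwise across the subtypes can earn two assignments (e.g. bottom
    subtype DOWN and top subtype UP) and a subtype's marker count can
    exceed the significant-call count of any single contrast involving it.

Every ``strict_both`` assignment is also an ``any_two`` assignment.
"""

from __future__ import annotations

import dataclasses
from itertools import permutations

import pandas as pd

from .data_model import DataError, TUMOUR_SUBTYPES
from .differential import DEResult
from .synthetic_data import GroundTruth

EXPECTED_CONTRASTS = (
    ("TYPE_I", "TYPE_II"),
    ("TYPE_I", "TYPE_III"),
    ("TYPE_II", "TYPE_III"),
)


@dataclasses.dataclass
class MarkerEntry:
    feature_id: str
    subtype: str
    direction: str  # UP/DOWN in the assigned subtype
    supporting_contrasts: tuple[str, ...]


@dataclasses.dataclass
class MarkerPanel:
    entries: list[MarkerEntry]
    rule: str

    @property
    def feature_ids(self) -> list[str]:
        return sorted({e.feature_id for e in self.entries})

    def entries_for(self, subtype: str) -> list[MarkerEntry]:
        return [e for e in self.entries if e.subtype == subtype]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "feature_id": e.feature_id,
                    "subtype": e.subtype,
                    "direction": e.direction,
                    "supporting_contrasts": ";".join(e.supporting_contrasts),
                    "rule": self.rule,
                }
                for e in self.entries
            ],
            columns=["feature_id", "subtype", "direction", "supporting_contrasts", "rule"],
        )


def _call_map(r: DEResult) -> dict[str, tuple[str, str, str]]:
    """feature -> (contrast_name, high_subtype, low_subtype) for significant calls."""
    a, b = r.contrast
    name = f"{a}_vs_{b}"
    sig = r.table[r.table["significant"]]
    return {
        f: (name, a, b) if d == "UP" else (name, b, a)
        for f, d in sig["direction"].items()
    }


def _assignments_from_calls(calls) -> list[tuple[str, str]]:
    """Resolve ordering statements to (subtype, direction) assignments.

    A subtype is assigned UP (DOWN) when it is first (last) in *every*
    total order of the three subtypes consistent with the >= 2 statements.
    Inconsistent statement sets (a cycle) admit no order and assign
    nothing.
    """
    if len(calls) < 2:
        return []
    consistent = []
    for order in permutations(TUMOUR_SUBTYPES):
        rank = {s: i for i, s in enumerate(order)}
        if all(rank[hi] < rank[lo] for _, hi, lo in calls):
            consistent.append(order)
    if not consistent:
        return []
    out = []
    tops = {o[0] for o in consistent}
    bottoms = {o[-1] for o in consistent}
    if len(tops) == 1:
        out.append((next(iter(tops)), "UP"))
    if len(bottoms) == 1:
        out.append((next(iter(bottoms)), "DOWN"))
    return out


def select_markers(
    r12: DEResult, r13: DEResult, r23: DEResult, rule: str = "any_two"
) -> MarkerPanel:
    """Build the marker panel under ``strict_both`` or ``any_two``.

    Contrast orientation is validated, never inferred: the inputs must be
    (TYPE_I vs TYPE_II), (TYPE_I vs TYPE_III), (TYPE_II vs TYPE_III).
    """
    if rule not in ("strict_both", "any_two"):
        raise DataError(f"unknown selection rule {rule!r}")
    results = (r12, r13, r23)
    for r, expected in zip(results, EXPECTED_CONTRASTS):
        if tuple(r.contrast) != expected:
            raise DataError(
                f"contrast orientation mismatch: got {r.contrast}, expected {expected}"
            )
    universe = r12.table.index
    for r in (r13, r23):
        if not universe.equals(r.table.index):
            universe = universe.intersection(r.table.index)
    universe_set = set(universe)
    maps = [_call_map(r) for r in results]
    candidates = [
        f for f in universe
        if sum(f in cm for cm in maps) >= 2 and f in universe_set
    ]
    entries: list[MarkerEntry] = []
    for feature in candidates:
        calls = [cm[feature] for cm in maps if feature in cm]
        assignments = _assignments_from_calls(calls)
        if rule == "strict_both":
            assignments = [
                (s, d) for s, d in assignments
                if sum(s in name.split("_vs_") for name, _, _ in calls) == 2
                and all(
                    (hi == s if d == "UP" else lo == s)
                    for name, hi, lo in calls
                    if s in name.split("_vs_")
                )
            ]
        support = tuple(name for name, _, _ in calls)
        for s, d in assignments:
            entries.append(MarkerEntry(feature, s, d, support))
    return MarkerPanel(entries, rule)


def summarize_panel(panel: MarkerPanel) -> pd.DataFrame:
    """Marker counts per (subtype, direction) plus per-subtype totals."""
    rows = []
    for subtype in TUMOUR_SUBTYPES:
        sub = panel.entries_for(subtype)
        n_up = sum(e.direction == "UP" for e in sub)
        n_down = sum(e.direction == "DOWN" for e in sub)
        rows.append(
            {"subtype": subtype, "n_up": n_up, "n_down": n_down, "n_total": n_up + n_down}
        )
    return pd.DataFrame(rows).set_index("subtype")


def evaluate_recovery(panel: MarkerPanel, truth: GroundTruth) -> dict[str, float]:
    """Precision/recall of the panel against the generator's ground truth.

    Recall counts how many planted (subtype, direction) markers reappear
    in the panel.  Precision treats an entry as correct if it matches a
    planted marker *or* is a deleted-arm (1p/19q) feature assigned
    TYPE_I/DOWN — the arm dosage shift is planted signal too, and the
    concordance rule is expected to pick it up as an oligodendroglioma
    down-marker.
    """
    planted = {
        (f, s, d) for s, fd in truth.planted_markers.items() for f, d in fd.items()
    }
    deleted_arm = set(truth.arm_features.get("1p", [])) | set(
        truth.arm_features.get("19q", [])
    )
    got = {(e.feature_id, e.subtype, e.direction) for e in panel.entries}
    tp = {
        (f, s, d) for f, s, d in got
        if (f, s, d) in planted or (f in deleted_arm and s == "TYPE_I" and d == "DOWN")
    }
    recovered_planted = got & planted
    precision = len(tp) / len(got) if got else float("nan")
    recall = len(recovered_planted) / len(planted) if planted else float("nan")
    return {"precision": precision, "recall": recall,
            "n_panel": float(len(got)), "n_planted": float(len(planted))}


def write_panel(panel: MarkerPanel, path) -> None:
    panel.to_frame().to_csv(path, sep="\t", index=False)
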