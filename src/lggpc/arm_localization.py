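"""Chromosome-arm localisation of differential features.

For each arm (1p, 1q, 19p, 19q, plus the catch-all "other") this counts
how many significant features moved up versus down and asks, via a
two-sided Fisher exact test on the 2x2 table

                on arm   off arm
    down          a         b
    up            c         d

whether down-regulation is enriched on that arm among significant
features.  In an oligodendroglioma-vs-astrocytoma contrast the 1p/19q
codeletion should manifest as an excess of down-calls on those two arms;
the same analysis between the two non-codeleted subtypes should find
nothing.  Features without an annotation are counted under "other" and
reported in the log, never dropped silently.
"""

from __future__ import annotations

import dataclasses

import pandas as pd
from scipy import stats

from .data_model import ARM_LABELS, ArmAnnotation, log
from .differential import DEResult


@dataclasses.dataclass
class ArmEnrichmentResult:
    """Per-arm up/down counts, down fraction and Fisher enrichment test."""

    contrast: tuple[str, str]
    table: pd.DataFrame  # index arm_label; n_up n_down down_fraction odds_ratio fisher_p

    def row(self, arm_label: str) -> pd.Series:
        return self.table.loc[arm_label]


def localize_de(r: DEResult, arms: ArmAnnotation) -> ArmEnrichmentResult:
    """Count significant up/down features per arm and test enrichment.

    An empty significant set yields all-zero counts with p = 1 by
    convention.  Arms with no significant features report p = 1 as well
    (the Fisher table has an empty margin).
    """
    sig = r.table[r.table["significant"]]
    feat_arm = pd.Series(arms.arms_for(sig.index), index=sig.index)
    n_unannotated = int((~pd.Index(sig.index).isin(arms.mapping.index)).sum())
    if n_unannotated:
        log.info("%d significant feature(s) without arm annotation counted as 'other'",
                 n_unannotated)
    total_up = int((sig["direction"] == "UP").sum())
    total_down = int((sig["direction"] == "DOWN").sum())
    rows = []
    for arm in ARM_LABELS:
        on = sig[feat_arm == arm]
        n_up = int((on["direction"] == "UP").sum())
        n_down = int((on["direction"] == "DOWN").sum())
        denom = n_up + n_down
        down_frac = n_down / denom if denom else float("nan")
        a, b = n_down, total_down - n_down
        c, d = n_up, total_up - n_up
        if denom == 0 or (b + d) == 0:
            odds, p = float("nan"), 1.0
        else:
            odds, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
        rows.append(
            {"arm_label": arm, "n_up": n_up, "n_down": n_down,
             "down_fraction": down_frac, "fisher_odds_ratio": odds, "fisher_p": p}
        )
    table = pd.DataFrame(rows).set_index("arm_label")
    assert int(table["n_up"].sum()) == total_up
    assert int(table["n_down"].sum()) == total_down
    return ArmEnrichmentResult(r.contrast, table)


def write_arm_table(res: ArmEnrichmentResult, path) -> None:
    res.table.to_csv(path, sep="\t")
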