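"""Two-group differential testing with fold-change and FDR gates.

The same machinery serves differential protein abundance (DPA) between
glioma subtypes and, as a declared surrogate for count-based RNA models,
differential expression on log2 RNA matrices.  The statistic is Welch's
unequal-variance t-test on log2 values; multiplicity is controlled with
Benjamini-Hochberg across *all* features tested in a contrast, and a
feature is called significant iff

    |log2fc| > log2(fc_threshold)   AND   padj < padj_cutoff

with both inequalities strict (a fold change of exactly the threshold
does not pass).  ``log2fc`` is always mean(group A) - mean(group B).
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import stats

from .data_model import DataError, ExpressionMatrix, SampleSheet, log

_VAR_FLOOR = np.finfo(float).eps  # variance floor for 0-variance, unequal-mean features


@dataclasses.dataclass
class DEResult:
    """Per-feature differential result for one ordered contrast (A vs B)."""

    contrast: tuple[str, str]
    table: pd.DataFrame  # index feature_id; log2fc, p_value, padj, significant, direction
    fc_threshold: float
    padj_cutoff: float

    @property
    def significant_features(self) -> pd.Index:
        return self.table.index[self.table["significant"]]

    @property
    def n_significant(self) -> int:
        return int(self.table["significant"].sum())

    def counts(self) -> dict[str, int]:
        sig = self.table[self.table["significant"]]
        return {
            "n_significant": len(sig),
            "n_up": int((sig["direction"] == "UP").sum()),
            "n_down": int((sig["direction"] == "DOWN").sum()),
        }


def benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    """Step-up BH adjusted p-values (monotone, capped at 1, stable in ties)."""
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise DataError("benjamini_hochberg expects a 1-D vector")
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise DataError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    # enforce monotonicity from the largest rank down
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty(m)
    out[order] = adj
    return out


def _welch(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised Welch t-test over feature rows; returns (t, p).

    Degenerate rows: zero variance in both groups with equal means gives
    p = 1 (no evidence, not NaN); zero variance with unequal means uses a
    machine-epsilon variance floor so the feature is reported as extreme
    rather than undefined.
    """
    na, nb = a.shape[1], b.shape[1]
    ma, mb = a.mean(axis=1), b.mean(axis=1)
    va = np.maximum(a.var(axis=1, ddof=1), 0.0)
    vb = np.maximum(b.var(axis=1, ddof=1), 0.0)
    degenerate = (va == 0) & (vb == 0)
    va = np.where(degenerate, _VAR_FLOOR, va)
    vb = np.where(degenerate, _VAR_FLOOR, vb)
    sa, sb = va / na, vb / nb
    se = np.sqrt(sa + sb)
    t = (ma - mb) / se
    df = (sa + sb) ** 2 / (sa**2 / (na - 1) + sb**2 / (nb - 1))
    p = 2.0 * stats.t.sf(np.abs(t), df)
    equal_degenerate = degenerate & (ma == mb)
    t = np.where(equal_degenerate, 0.0, t)
    p = np.where(equal_degenerate, 1.0, p)
    return t, np.minimum(p, 1.0)


def de_test(
    m: ExpressionMatrix,
    samples: SampleSheet,
    group_a: str,
    group_b: str,
    fc_threshold: float = 1.5,
    padj_cutoff: float = 0.05,
) -> DEResult:
    """Welch-on-log2 differential test of ``group_a`` vs ``group_b``.

    Requires a complete-case log2 matrix and at least two samples per
    group.  BH adjustment runs across every feature in the matrix; the
    fold-change and padj gates are then applied jointly.
    """
    if m.scale != "log2":
        raise DataError("de_test expects a log2-scale matrix")
    if m.data.isna().to_numpy().any():
        raise DataError("de_test requires a complete-case matrix (run the filter first)")
    samples.check_covers(m)
    ids_a = [s for s in samples.samples_of(group_a) if s in m.data.columns]
    ids_b = [s for s in samples.samples_of(group_b) if s in m.data.columns]
    for name, ids in ((group_a, ids_a), (group_b, ids_b)):
        if len(ids) < 2:
            raise DataError(f"group {name!r} has {len(ids)} sample(s) in the matrix; need >= 2")
    a = m.data.loc[:, ids_a].to_numpy()
    b = m.data.loc[:, ids_b].to_numpy()
    log2fc = a.mean(axis=1) - b.mean(axis=1)
    _, p = _welch(a, b)
    padj = benjamini_hochberg(p)
    sig = (np.abs(log2fc) > np.log2(fc_threshold)) & (padj < padj_cutoff)
    direction = np.where(log2fc > 0, "UP", "DOWN")
    table = pd.DataFrame(
        {
            "log2fc": log2fc,
            "p_value": p,
            "padj": padj,
            "significant": sig,
            "direction": np.where(sig, direction, ""),
        },
        index=m.data.index,
    )
    return DEResult((group_a, group_b), table, fc_threshold, padj_cutoff)


@dataclasses.dataclass
class OverlapReport:
    """Overlap of two significant lists with directional concordance."""

    n_overlap: int
    n_concordant: int
    concordance_fraction: float
    features: pd.DataFrame  # index feature_id; direction_1, direction_2, concordant


def overlap_de_lists(r1: DEResult, r2: DEResult) -> OverlapReport:
    """Features significant in both results; concordant = same direction.

    Used to ask whether two contrasts (e.g. CIC loss-of-function vs
    wild-type and CIC missense vs wild-type) point at the same biology.
    """
    s1 = r1.table[r1.table["significant"]]
    s2 = r2.table[r2.table["significant"]]
    shared = s1.index.intersection(s2.index)
    d1 = s1.loc[shared, "direction"]
    d2 = s2.loc[shared, "direction"]
    concordant = (d1 == d2)
    features = pd.DataFrame(
        {"direction_1": d1, "direction_2": d2, "concordant": concordant}
    )
    n = len(shared)
    n_c = int(concordant.sum())
    return OverlapReport(n, n_c, (n_c / n) if n else 0.0, features)


_LOF_CONSEQUENCES = {"frameshift", "stop_gained"}
_KNOWN_CONSEQUENCES = _LOF_CONSEQUENCES | {"missense", "other"}


def classify_cic_mutation(
    consequence: str, exon: int, c1_exon: int = 20
) -> str:
    """Classify a CIC variant as ``LOF``, ``MISSENSE`` or ``EXCLUDED``.

    Truncating frameshift or stop mutations are loss-of-function wherever
    they fall.  Missense variants count only inside the HMG DNA-binding
    domain (exon 5) or the C1 motif (``c1_exon``, 20 by default with 19
    admissible — domain annotations differ on which exon holds the C1
    motif).  Everything else is excluded from the CIC subgrouping.
    """
    if consequence not in _KNOWN_CONSEQUENCES:
        raise DataError(f"unknown variant consequence {consequence!r}")
    if exon < 1:
        raise DataError("exon must be >= 1")
    if consequence in _LOF_CONSEQUENCES:
        return "LOF"
    if consequence == "missense" and exon in (5, c1_exon):
        return "MISSENSE"
    return "EXCLUDED"


def write_de_table(r: DEResult, path) -> None:
    out = r.table.rename_axis("feature_id")
    out.to_csv(path, sep="\t")
    log.info("wrote %s (%d significant of %d features, contrast %s vs %s)",
             path, r.n_significant, len(out), *r.contrast)
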