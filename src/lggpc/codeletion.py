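"""1p/19q dosage scoring and RNA-protein dosage attenuation.

Two complementary views of whole-arm codeletion in the proteome:

* :func:`combined_zscore` — per sample, the mean over all 1p/19q proteins
  of the per-protein z-score against the normal-brain reference
  distribution.  Codeleted tumours should sit clearly below zero because
  roughly half the template for those proteins is gone; the attenuated
  protein-level dosage response keeps the shift modest.
* :func:`arm_rna_protein_regression` — per arm, ordinary least squares of
  per-gene mean protein on per-gene mean RNA within one subtype.  A low
  R^2 quantifies how much of the transcript-level dosage signal is buffered
  away before it reaches protein abundance.

Scores are *not* invariant to per-sample global shifts, so any
normalisation must happen upstream of scoring.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .data_model import (
    ArmAnnotation,
    CODELETED_ARMS,
    DataError,
    ExpressionMatrix,
    SampleSheet,
    log,
)
from .differential import benjamini_hochberg

_NORMAL_SD_FLOOR = 1e-8  # features with smaller reference SD are excluded


@dataclasses.dataclass
class CodeletionScore:
    sample_id: str
    z_combined: float
    n_features_used: int


def combined_zscore(
    m: ExpressionMatrix,
    samples: SampleSheet,
    arms: ArmAnnotation,
    target_arms: Iterable[str] = CODELETED_ARMS,
    combine: str = "mean",
) -> list[CodeletionScore]:
    """Combined dosage z-score per sample over the target-arm proteins.

    For every feature f on a target arm, z_fs = (x_fs - mean_f(NORMAL)) /
    sd_f(NORMAL) with the sample standard deviation (n-1) of the normal
    reference; z_combined(s) is the mean (or median, ``combine="median"``)
    of z_fs over features.  NORMAL samples are scored too, giving the
    reference distribution its expected centre of ~0.
    """
    if combine not in ("mean", "median"):
        raise DataError("combine must be 'mean' or 'median'")
    if m.data.isna().to_numpy().any():
        raise DataError("combined_zscore requires a complete-case matrix")
    samples.check_covers(m)
    normal_ids = [s for s in samples.samples_of("NORMAL") if s in m.data.columns]
    if len(normal_ids) < 2:
        raise DataError("need >= 2 NORMAL samples for a reference distribution")
    target = [f for f in arms.features_on(set(target_arms)) if f in m.data.index]
    if not target:
        raise DataError(f"no features on arms {sorted(set(target_arms))} in the matrix")
    sub = m.data.loc[target]
    ref = sub.loc[:, normal_ids]
    mu = ref.mean(axis=1)
    sd = ref.std(axis=1, ddof=1)
    keep = sd > _NORMAL_SD_FLOOR
    n_dropped = int((~keep).sum())
    if n_dropped:
        log.info("excluded %d target-arm feature(s) with zero NORMAL variance", n_dropped)
    if not keep.any():
        raise DataError("all target-arm features have zero NORMAL variance")
    z = sub.loc[keep].sub(mu[keep], axis=0).div(sd[keep], axis=0)
    combined = z.mean(axis=0) if combine == "mean" else z.median(axis=0)
    n_used = int(keep.sum())
    return [
        CodeletionScore(s, float(combined[s]), n_used) for s in m.sample_ids
    ]


def compare_score_groups(
    scores: Sequence[CodeletionScore], samples: SampleSheet
) -> pd.DataFrame:
    """Pairwise Welch tests of z_combined between all groups, BH-adjusted.

    Returns one row per unordered group pair with the group means, the
    Welch t statistic, raw p and BH-adjusted p across the pairs.
    """
    by_sample = {s.sample_id: s.z_combined for s in scores}
    groups: dict[str, np.ndarray] = {}
    for g in dict.fromkeys(samples.labels_for(list(by_sample))):
        ids = [s for s in samples.samples_of(g) if s in by_sample]
        if len(ids) < 2:
            raise DataError(f"group {g!r} has fewer than 2 scored samples")
        groups[g] = np.array([by_sample[s] for s in ids])
    names = list(groups)
    rows = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            a, b = groups[names[i]], groups[names[j]]
            if np.var(a, ddof=1) == 0 and np.var(b, ddof=1) == 0 and a.mean() == b.mean():
                t, p = 0.0, 1.0
            else:
                t, p = stats.ttest_ind(a, b, equal_var=False)
            rows.append(
                {"group_a": names[i], "group_b": names[j],
                 "mean_a": a.mean(), "mean_b": b.mean(),
                 "t": float(t), "p_value": float(p)}
            )
    out = pd.DataFrame(rows)
    out["padj"] = benjamini_hochberg(out["p_value"].to_numpy())
    return out


@dataclasses.dataclass
class ArmCorrelationResult:
    arm_label: str
    r_squared: float
    slope: float
    intercept: float
    n_genes: int


def arm_rna_protein_regression(
    rna: ExpressionMatrix,
    protein: ExpressionMatrix,
    samples: SampleSheet,
    arms: ArmAnnotation,
    group: str,
    arm_labels: Sequence[str] = ("1p", "1q", "19p", "19q"),
) -> list[ArmCorrelationResult]:
    """OLS of per-gene mean protein on per-gene mean RNA, one fit per arm.

    Means are taken over the ``group`` samples present in both matrices;
    genes are matched by shared feature ID.  Arms with fewer than 3 shared
    genes are skipped with a warning.  R^2 equals the squared Pearson
    correlation of the two mean vectors.
    """
    ids = [
        s for s in samples.samples_of(group)
        if s in rna.data.columns and s in protein.data.columns
    ]
    if not ids:
        raise DataError(f"no {group!r} samples shared by the RNA and protein matrices")
    shared = rna.data.index.intersection(protein.data.index)
    results = []
    for arm in arm_labels:
        genes = [f for f in arms.features_on({arm}) if f in shared]
        if len(genes) < 3:
            log.warning("arm %s has %d shared gene(s); skipping regression", arm, len(genes))
            continue
        x = rna.data.loc[genes, ids].mean(axis=1).to_numpy()
        y = protein.data.loc[genes, ids].mean(axis=1).to_numpy()
        fit = stats.linregress(x, y)
        results.append(
            ArmCorrelationResult(
                arm, float(fit.rvalue**2), float(fit.slope), float(fit.intercept),
                len(genes),
            )
        )
    return results


def write_scores(scores: Sequence[CodeletionScore], path) -> None:
    pd.DataFrame([dataclasses.asdict(s) for s in scores]).to_csv(
        path, sep="\t", index=False
    )


def write_arm_correlations(results: Sequence[ArmCorrelationResult], path) -> None:
    pd.DataFrame([dataclasses.asdict(r) for r in results]).to_csv(
        path, sep="\t", index=False
    )
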