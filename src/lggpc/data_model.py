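"""Core data containers and text-format I/O.

Everything downstream operates on three objects: an
:class:`ExpressionMatrix` (features x samples, linear or log2 scale, with
explicit missingness), a :class:`SampleSheet` carrying the molecular
subtype label of every sample, and an :class:`ArmAnnotation` mapping
features to chromosome arms (``1p``/``1q``/``19p``/``19q``/``other``).
All tables are plain TSV/CSV; parsing is strict (duplicate feature IDs or
non-numeric cells are errors, never silently repaired) and loss-free
(``write`` then ``read`` reproduces values bit-identically).

No imputation is performed anywhere in the pipeline: missing protein
quantifications are handled exclusively by complete-case filtering, the
same policy as keeping only proteins identified in every mass-spectrometry
run.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import yaml

logging.basicConfig(format="%(levelname)s %(name)s: %(message)s")
log = logging.getLogger("lggpc")

SUBTYPES = ("NORMAL", "TYPE_I", "TYPE_II", "TYPE_III")
TUMOUR_SUBTYPES = ("TYPE_I", "TYPE_II", "TYPE_III")
CIC_STATUSES = ("WT", "LOF", "MISSENSE", "NA")
GRADES = ("II", "III", "IV", "NA")
ARM_LABELS = ("1p", "1q", "19p", "19q", "other")
#: arms lost in the canonical whole-arm codeletion of oligodendroglioma
CODELETED_ARMS = frozenset({"1p", "19q"})

LINEAR = "linear"
LOG2 = "log2"


class DataError(ValueError):
    """Malformed or inconsistent input data."""


# ---------------------------------------------------------------------------
# ExpressionMatrix
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class ExpressionMatrix:
    """Features x samples abundance table with an explicit scale tag.

    Parameters
    ----------
    data:
        DataFrame indexed by feature ID with sample IDs as columns.
        ``NaN`` marks a missing quantification.
    scale:
        ``"linear"`` (non-negative intensities) or ``"log2"``.
    """

    data: pd.DataFrame
    scale: str = LOG2

    def __post_init__(self) -> None:
        if self.scale not in (LINEAR, LOG2):
            raise DataError(f"unknown scale tag {self.scale!r}")
        idx = self.data.index
        cols = self.data.columns
        if idx.has_duplicates:
            dups = idx[idx.duplicated()].unique().tolist()
            raise DataError(f"duplicate feature IDs: {dups}")
        if cols.has_duplicates:
            dups = cols[cols.duplicated()].unique().tolist()
            raise DataError(f"duplicate sample IDs: {dups}")
        try:
            self.data = self.data.astype(float)
        except (TypeError, ValueError) as exc:
            raise DataError(f"non-numeric values in matrix: {exc}") from exc
        if self.scale == LINEAR:
            vals = self.data.to_numpy()
            if np.nanmin(vals, initial=np.inf) < 0:
                raise DataError("linear-scale matrix contains negative values")

    # -- basic views --------------------------------------------------------
    @property
    def feature_ids(self) -> list[str]:
        return self.data.index.tolist()

    @property
    def sample_ids(self) -> list[str]:
        return self.data.columns.tolist()

    @property
    def n_features(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    def subset_samples(self, sample_ids: Iterable[str]) -> "ExpressionMatrix":
        ids = list(sample_ids)
        missing = set(ids) - set(self.data.columns)
        if missing:
            raise DataError(f"samples not in matrix: {sorted(missing)}")
        return ExpressionMatrix(self.data.loc[:, ids], self.scale)

    def subset_features(self, feature_ids: Iterable[str]) -> "ExpressionMatrix":
        ids = list(feature_ids)
        missing = set(ids) - set(self.data.index)
        if missing:
            raise DataError(f"features not in matrix: {sorted(missing)}")
        return ExpressionMatrix(self.data.loc[ids], self.scale)


def _detect_sep(path: Path) -> str:
    with open(path) as fh:
        header = fh.readline()
    if "\t" in header:
        return "\t"
    if "," in header:
        return ","
    raise DataError(f"{path}: cannot detect delimiter (expected tab or comma)")


def read_matrix(path: str | Path, scale: str = LOG2) -> ExpressionMatrix:
    """Read a delimited expression matrix (first column = feature IDs).

    Empty cells or ``NA`` denote missing values.  Duplicated feature IDs
    are a :class:`DataError` naming the offending features.
    """
    path = Path(path)
    sep = _detect_sep(path)
    df = pd.read_csv(path, sep=sep, index_col=0, na_values=["NA"],
                     float_precision="round_trip")
    df.index = df.index.astype(str).rename(None)
    df.columns = df.columns.astype(str).rename(None)
    for col in df.columns:
        if not pd.api.types.is_numeric_dtype(df[col]):
            bad = df[col][pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()]
            raise DataError(
                f"{path}: non-numeric cell(s) in column {col!r}"
                + (f" at feature(s) {bad.index.tolist()[:5]}" if len(bad) else "")
            )
    return ExpressionMatrix(df, scale)


def write_matrix(m: ExpressionMatrix, path: str | Path, sep: str = "\t") -> None:
    """Write a matrix loss-free; missing values serialize as ``NA``.

    Uses repr-round-trip float formatting so read_matrix recovers values
    bit-identically.
    """
    df = m.data.copy()
    df.index.name = "feature_id"
    df.to_csv(path, sep=sep, na_rep="NA", float_format=lambda v: repr(float(v)))


def filter_complete_features(m: ExpressionMatrix) -> ExpressionMatrix:
    """Keep only features quantified in every sample (complete cases).

    Mirrors retaining only proteins identified in all MS runs.  Feature
    order and the sample set are preserved; the result may be empty.
    Idempotent.
    """
    keep = ~m.data.isna().any(axis=1)
    return ExpressionMatrix(m.data.loc[keep], m.scale)


def log2_transform(m: ExpressionMatrix, pseudocount: float = 1.0) -> ExpressionMatrix:
    """log2(value + pseudocount) on a linear-scale matrix; missing stays missing."""
    if m.scale != LINEAR:
        raise DataError("log2_transform expects a linear-scale matrix")
    vals = m.data.to_numpy()
    if np.nanmin(vals + pseudocount, initial=np.inf) <= 0:
        raise DataError("value + pseudocount must be positive for log2 transform")
    return ExpressionMatrix(np.log2(m.data + pseudocount), LOG2)


# ---------------------------------------------------------------------------
# SampleSheet
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class SampleSheet:
    """Per-sample subtype label plus optional CIC mutation status and grade.

    CIC status other than ``NA`` is only permitted for TYPE_I samples,
    since CIC subgrouping is an oligodendroglioma-internal analysis.
    """

    table: pd.DataFrame  # index sample_id; columns subtype, cic_status, grade

    def __post_init__(self) -> None:
        t = self.table
        if t.index.has_duplicates:
            raise DataError("duplicate sample IDs in sample sheet")
        for col, default in (("cic_status", "NA"), ("grade", "NA")):
            if col not in t.columns:
                t = t.assign(**{col: default})
        t = t.fillna({"cic_status": "NA", "grade": "NA"})
        bad = set(t["subtype"]) - set(SUBTYPES)
        if bad:
            raise DataError(f"unknown subtype label(s): {sorted(bad)}")
        bad = set(t["cic_status"]) - set(CIC_STATUSES)
        if bad:
            raise DataError(f"unknown cic_status value(s): {sorted(bad)}")
        offending = t[(t["cic_status"] != "NA") & (t["subtype"] != "TYPE_I")]
        if len(offending):
            raise DataError(
                "cic_status set for non-TYPE_I sample(s): "
                f"{offending.index.tolist()}"
            )
        self.table = t

    @property
    def sample_ids(self) -> list[str]:
        return self.table.index.tolist()

    def samples_of(self, subtype: str) -> list[str]:
        return self.table.index[self.table["subtype"] == subtype].tolist()

    def subtype_of(self, sample_id: str) -> str:
        return str(self.table.at[sample_id, "subtype"])

    def labels_for(self, sample_ids: Iterable[str]) -> np.ndarray:
        return self.table.loc[list(sample_ids), "subtype"].to_numpy()

    def check_covers(self, m: ExpressionMatrix) -> None:
        """Reject matrices whose samples are not all described here."""
        extra = set(m.sample_ids) - set(self.table.index)
        if extra:
            raise DataError(f"matrix samples absent from sample sheet: {sorted(extra)}")


def read_sample_sheet(path: str | Path) -> SampleSheet:
    df = pd.read_csv(path, sep=_detect_sep(Path(path)), dtype=str)
    if "sample_id" not in df.columns or "subtype" not in df.columns:
        raise DataError(f"{path}: sample sheet needs sample_id and subtype columns")
    return SampleSheet(df.set_index("sample_id"))


def write_sample_sheet(s: SampleSheet, path: str | Path) -> None:
    s.table.rename_axis("sample_id").to_csv(path)


# ---------------------------------------------------------------------------
# ArmAnnotation
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class ArmAnnotation:
    """feature_id -> chromosome-arm label (``1p``, ``19q``, ... or ``other``).

    Arms of chromosomes other than 1 and 19 collapse to ``other``: only
    the codeletion arms need to be resolved for this analysis, which also
    sidesteps genome-build coordinate issues.
    """

    mapping: pd.Series  # index feature_id, values arm_label

    def __post_init__(self) -> None:
        if self.mapping.index.has_duplicates:
            raise DataError("feature mapped to more than one arm")
        bad = set(self.mapping.unique()) - set(ARM_LABELS)
        if bad:
            raise DataError(f"unknown arm label(s): {sorted(bad)}")

    def arm_of(self, feature_id: str) -> str:
        return str(self.mapping.get(feature_id, "other"))

    def arms_for(self, feature_ids: Iterable[str]) -> np.ndarray:
        ids = list(feature_ids)
        return self.mapping.reindex(ids).fillna("other").to_numpy()

    def features_on(self, arm_labels: Iterable[str]) -> list[str]:
        wanted = set(arm_labels)
        return self.mapping.index[self.mapping.isin(wanted)].tolist()


def _arm_label(chrom: str, arm: str) -> str:
    chrom = chrom.removeprefix("chr")
    return f"{chrom}{arm}" if chrom in ("1", "19") and arm in ("p", "q") else "other"


def read_arm_annotation(
    path: str | Path,
    centromeres: Mapping[str, int] | None = None,
) -> ArmAnnotation:
    """Read a feature->arm map.

    Accepts either a 2-column TSV ``feature_id, arm_label`` (pre-resolved)
    or a 4-column BED-like TSV ``chrom, start, end, feature_id`` combined
    with ``centromeres`` (chrom -> centromere position) to resolve p/q.
    """
    path = Path(path)
    sep = _detect_sep(path)
    df = pd.read_csv(path, sep=sep, header=None, dtype=str, comment="#")
    if df.iloc[0].tolist()[:2] in (["feature_id", "arm_label"], ["chrom", "start"]):
        df = df.iloc[1:].reset_index(drop=True)  # tolerate a header row
    if df.shape[1] == 2:
        mapping = pd.Series(
            df[1].to_numpy(), index=pd.Index(df[0], name="feature_id"), name="arm_label"
        )
        return ArmAnnotation(mapping)
    if df.shape[1] >= 4:
        if centromeres is None:
            raise DataError(
                f"{path}: BED-like annotation requires a centromere map to assign arms"
            )
        chrom = df[0].astype(str)
        start = df[1].astype(int)
        feats = df[3].astype(str)
        labels = []
        for c, s in zip(chrom, start):
            cen = centromeres.get(c.removeprefix("chr"))
            if cen is None:
                labels.append("other")
            else:
                labels.append(_arm_label(c, "p" if s < cen else "q"))
        return ArmAnnotation(
            pd.Series(labels, index=pd.Index(feats, name="feature_id"), name="arm_label")
        )
    raise DataError(f"{path}: expected 2-column (feature, arm) or 4-column BED-like file")


def write_arm_annotation(a: ArmAnnotation, path: str | Path) -> None:
    a.mapping.rename("arm_label").rename_axis("feature_id").to_csv(
        path, sep="\t", header=False
    )


# ---------------------------------------------------------------------------
# AnalysisConfig
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class AnalysisConfig:
    """Thresholds and knobs for the whole pipeline.

    fc_threshold is a *linear* fold change; the gate applied on log2 data
    is ``|log2fc| > log2(fc_threshold)``, strict.  padj_rna (0.01) is the
    transcriptome gate, padj_protein (0.05) the proteome gate — proteomic
    contrasts have less power, hence the looser cutoff.
    """

    fc_threshold: float = 1.5
    padj_rna: float = 0.01
    padj_protein: float = 0.05
    top_n_mad: int = 500
    cv_folds: int = 10
    ridge_lambda: float = 1.0
    rng_seed: int = 0
    cic_c1_exon: int = 20  # C1-motif exon for the missense rule; 19 admissible

    def __post_init__(self) -> None:
        if not self.fc_threshold > 1:
            raise DataError("fc_threshold must be > 1")
        for name in ("padj_rna", "padj_protein"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise DataError(f"{name} must be in (0, 1)")
        if self.cv_folds < 2:
            raise DataError("cv_folds must be >= 2")
        if self.ridge_lambda < 0:
            raise DataError("ridge_lambda must be non-negative")
        if self.cic_c1_exon not in (19, 20):
            raise DataError("cic_c1_exon must be 19 or 20")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise DataError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)
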