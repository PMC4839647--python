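"""Data model and readers/writers for composition, expression, metabolite and result tables.

The internal representation is always fractions in [0, 1] summing to exactly 1
per sample; files may use percentages (auto-detected). Canonical interchange
format is TSV; XLSX is accepted for composition and metabolite tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SchemaError",
    "ValidationError",
    "SampleRecord",
    "Cohort",
    "DifferentialResult",
    "read_composition_table",
    "write_composition_table",
    "read_matrix",
    "write_matrix",
    "write_results",
    "read_results",
]

GROUP_CANCER = "cancer"
GROUP_NORMAL = "normal"
_GROUPS = (GROUP_CANCER, GROUP_NORMAL)

_COMPOSITION_COLUMNS = ("sample_id", "group", "pct_cancer", "pct_stroma", "pct_benign")
_RESULT_COLUMNS = (
    "feature_id",
    "statistic",
    "mean_diff",
    "p_raw",
    "p_adjusted",
    "direction",
    "rank",
)


class SchemaError(ValueError):
    """A table is missing a required column or has an unusable layout."""


class ValidationError(ValueError):
    """A table parses but violates a content invariant."""


@dataclass(frozen=True)
class SampleRecord:
    """One sample's group label and tissue fractions (summing to exactly 1)."""

    sample_id: str
    group: str
    frac_cancer: float
    frac_stroma: float
    frac_benign: float
    gleason: float | None = None

    def __post_init__(self) -> None:
        if self.group not in _GROUPS:
            raise ValidationError(
                f"unknown group label {self.group!r} for sample {self.sample_id!r}; "
                f"expected one of {_GROUPS}"
            )
        for name in ("frac_cancer", "frac_stroma", "frac_benign"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0) or not math.isfinite(v):
                raise ValidationError(
                    f"{name}={v} out of [0, 1] for sample {self.sample_id!r}"
                )

    @property
    def fractions(self) -> tuple[float, float, float]:
        return (self.frac_cancer, self.frac_stroma, self.frac_benign)


@dataclass
class Cohort:
    """Sample records plus aligned gene and metabolite matrices (features x samples)."""

    samples: list[SampleRecord]
    gene_matrix: np.ndarray
    gene_ids: list[str]
    metabolite_matrix: np.ndarray | None = None
    metabolite_ids: list[str] | None = None

    def __post_init__(self) -> None:
        ids = [s.sample_id for s in self.samples]
        _check_unique(ids, "sample_id")
        _check_unique(self.gene_ids, "gene_id")
        self.gene_matrix = np.asarray(self.gene_matrix, dtype=float)
        if self.gene_matrix.shape != (len(self.gene_ids), len(ids)):
            raise ValidationError(
                f"gene_matrix shape {self.gene_matrix.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(ids)} samples"
            )
        if not np.all(np.isfinite(self.gene_matrix)):
            raise ValidationError("gene_matrix contains non-finite entries")
        if (self.metabolite_matrix is None) != (self.metabolite_ids is None):
            raise ValidationError(
                "metabolite_matrix and metabolite_ids must be supplied together"
            )
        if self.metabolite_matrix is not None:
            _check_unique(self.metabolite_ids, "metabolite_id")
            self.metabolite_matrix = np.asarray(self.metabolite_matrix, dtype=float)
            if self.metabolite_matrix.shape != (len(self.metabolite_ids), len(ids)):
                raise ValidationError(
                    f"metabolite_matrix shape {self.metabolite_matrix.shape} does not "
                    f"match {len(self.metabolite_ids)} metabolites x {len(ids)} samples"
                )
            if not np.all(np.isfinite(self.metabolite_matrix)):
                raise ValidationError("metabolite_matrix contains non-finite entries")

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    def sample_index(self, sample_ids: Iterable[str]) -> np.ndarray:
        """Column indices of the given sample ids, in the given order."""
        pos = {sid: i for i, sid in enumerate(self.sample_ids)}
        missing = [sid for sid in sample_ids if sid not in pos]
        if missing:
            raise ValidationError(f"sample ids not in cohort: {missing}")
        return np.array([pos[sid] for sid in sample_ids], dtype=int)

    def records_by_id(self) -> dict[str, SampleRecord]:
        return {s.sample_id: s for s in self.samples}


@dataclass(frozen=True)
class DifferentialResult:
    """Per-feature two-group test result."""

    feature_id: str
    mean_diff: float
    statistic: float
    p_raw: float
    p_adj: float
    direction: str  # "up_in_cancer" | "down_in_cancer"
    rank: int


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen: set[str] = set()
    dupes = sorted({x for x in ids if x in seen or seen.add(x)})
    if dupes:
        raise ValidationError(f"duplicate {what}s: {dupes}")


def _read_table(path: str | Path, fmt: str | None = None) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = fmt or path.suffix.lstrip(".").lower()
    if fmt in ("xlsx", "xls"):
        return pd.read_excel(path)
    sep = "," if fmt == "csv" else "\t"
    return pd.read_csv(path, sep=sep)


def read_composition_table(
    path: str | Path,
    fmt: str | None = None,
    *,
    values: str | None = None,
    allow_cancer_in_normal: bool = False,
) -> list[SampleRecord]:
    """Read a sample composition table into validated :class:`SampleRecord` s.

    Parameters
    ----------
    path
        CSV/TSV/XLSX file with header
        ``sample_id, group, pct_cancer, pct_stroma, pct_benign[, gleason]``.
    fmt
        Override format detection from the file suffix (``"csv"``, ``"tsv"``,
        ``"xlsx"``).
    values
        ``"percent"`` or ``"fraction"`` to bypass auto-detection (any value
        > 1.5 in the tissue columns means percent).
    allow_cancer_in_normal
        Coerce a nonzero cancer fraction in a normal sample to 0 (with
        renormalization) instead of raising.

    Returns
    -------
    list of SampleRecord with fractions renormalized to sum exactly 1,
    preserving the input row order.
    """
    df = _read_table(path, fmt)
    df.columns = [str(c).strip() for c in df.columns]
    missing = [c for c in _COMPOSITION_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"composition table missing column(s): {missing}")

    tissue = df[["pct_cancer", "pct_stroma", "pct_benign"]].to_numpy(dtype=float)
    if not np.all(np.isfinite(tissue)):
        bad = df["sample_id"].astype(str)[~np.isfinite(tissue).all(axis=1)].tolist()
        raise ValidationError(f"non-finite tissue values for samples: {bad}")
    if values is None:
        values = "percent" if np.nanmax(tissue) > 1.5 else "fraction"
    if values not in ("percent", "fraction"):
        raise ValueError(f"values must be 'percent' or 'fraction', got {values!r}")
    if values == "percent":
        tissue = tissue / 100.0

    sample_ids = df["sample_id"].astype(str).tolist()
    groups = df["group"].astype(str).str.strip().str.lower().tolist()
    unknown = sorted({g for g in groups if g not in _GROUPS})
    if unknown:
        raise ValidationError(f"unknown group label(s): {unknown}")

    sums = tissue.sum(axis=1)
    bad = (sums < 0.98) | (sums > 1.02)
    if np.any(bad):
        offenders = [sid for sid, b in zip(sample_ids, bad) if b]
        raise ValidationError(
            f"tissue fractions sum outside [0.98, 1.02] for samples: {offenders}"
        )

    gleason_col = df["gleason"] if "gleason" in df.columns else None
    records: list[SampleRecord] = []
    for i, sid in enumerate(sample_ids):
        fc, fs, fb = tissue[i]
        if groups[i] == GROUP_NORMAL and fc > 0:
            if not allow_cancer_in_normal:
                raise ValidationError(
                    f"normal sample {sid!r} has nonzero cancer fraction {fc:.4g} "
                    "(pass allow_cancer_in_normal=True to coerce to 0)"
                )
            fc = 0.0
        total = fc + fs + fb
        fc, fs, fb = fc / total, fs / total, fb / total
        gleason = None
        if gleason_col is not None and pd.notna(gleason_col.iloc[i]):
            gleason = float(gleason_col.iloc[i])
        records.append(
            SampleRecord(
                sample_id=sid,
                group=groups[i],
                frac_cancer=fc,
                frac_stroma=fs,
                frac_benign=fb,
                gleason=gleason,
            )
        )
    return records


def write_composition_table(
    records: Sequence[SampleRecord], path: str | Path, *, percent: bool = True
) -> None:
    """Write records as TSV/CSV (suffix decides), percentages by default."""
    scale = 100.0 if percent else 1.0
    df = pd.DataFrame(
        {
            "sample_id": [r.sample_id for r in records],
            "group": [r.group for r in records],
            "pct_cancer": [r.frac_cancer * scale for r in records],
            "pct_stroma": [r.frac_stroma * scale for r in records],
            "pct_benign": [r.frac_benign * scale for r in records],
            "gleason": [r.gleason for r in records],
        }
    )
    if df["gleason"].isna().all():
        df = df.drop(columns="gleason")
    sep = "," if str(path).endswith(".csv") else "\t"
    df.to_csv(path, sep=sep, index=False)


def read_matrix(
    path: str | Path,
    sample_order: Sequence[str] | None = None,
) -> tuple[list[str], list[str], np.ndarray]:
    """Read a features-x-samples TSV/CSV matrix.

    First column holds feature ids, the header row holds sample ids. When
    `sample_order` is given, columns are realigned to it; samples requested
    but absent from the file raise a :class:`ValidationError` listing them.
    """
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep, index_col=0)
    feature_ids = [str(x) for x in df.index]
    _check_unique(feature_ids, "feature id")
    sample_ids = [str(c) for c in df.columns]
    _check_unique(sample_ids, "sample id")
    try:
        matrix = df.to_numpy(dtype=float)
    except (TypeError, ValueError):
        for j, col in enumerate(df.columns):
            coerced = pd.to_numeric(df[col], errors="coerce")
            bad = coerced.isna() & df[col].notna()
            if bad.any():
                i = int(np.flatnonzero(bad)[0])
                raise ValidationError(
                    f"non-numeric cell at feature {feature_ids[i]!r}, "
                    f"sample {sample_ids[j]!r}: {df.iloc[i, j]!r}"
                ) from None
        raise
    if not np.all(np.isfinite(matrix)):
        i, j = map(int, np.argwhere(~np.isfinite(matrix))[0])
        raise ValidationError(
            f"missing/non-finite cell at feature {feature_ids[i]!r}, "
            f"sample {sample_ids[j]!r}"
        )
    if sample_order is not None:
        pos = {sid: i for i, sid in enumerate(sample_ids)}
        absent = [sid for sid in sample_order if sid not in pos]
        if absent:
            raise ValidationError(f"samples absent from matrix {path.name}: {absent}")
        order = [pos[sid] for sid in sample_order]
        matrix = matrix[:, order]
        sample_ids = list(sample_order)
    return feature_ids, sample_ids, matrix


def write_matrix(
    path: str | Path,
    feature_ids: Sequence[str],
    sample_ids: Sequence[str],
    matrix: np.ndarray,
) -> None:
    """Write a features-x-samples matrix as TSV (or CSV by suffix)."""
    sep = "," if str(path).endswith(".csv") else "\t"
    pd.DataFrame(
        np.asarray(matrix, dtype=float), index=list(feature_ids), columns=list(sample_ids)
    ).to_csv(path, sep=sep, index_label="feature_id")


def write_results(results: Sequence[DifferentialResult], path: str | Path) -> None:
    """Write differential results as TSV, rows sorted by rank."""
    rows = sorted(results, key=lambda r: r.rank)
    df = pd.DataFrame(
        {
            "feature_id": [r.feature_id for r in rows],
            "statistic": [r.statistic for r in rows],
            "mean_diff": [r.mean_diff for r in rows],
            "p_raw": [r.p_raw for r in rows],
            "p_adjusted": [r.p_adj for r in rows],
            "direction": [r.direction for r in rows],
            "rank": [r.rank for r in rows],
        }
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_results(path: str | Path) -> list[DifferentialResult]:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in _RESULT_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"results table missing column(s): {missing}")
    return [
        DifferentialResult(
            feature_id=str(row.feature_id),
            mean_diff=float(row.mean_diff),
            statistic=float(row.statistic),
            p_raw=float(row.p_raw),
            p_adj=float(row.p_adjusted),
            direction=str(row.direction),
            rank=int(row.rank),
        )
        for row in df.itertuples(index=False)
    ]
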