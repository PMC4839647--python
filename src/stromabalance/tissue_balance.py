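"""Construct balanced / unbalanced / unstratified sample splits and composition summaries.

Cancer and normal samples are sorted independently by stroma fraction.  The
*balanced* split pairs the highest-stroma half of the cancer group with the
lowest-stroma half of the normal group, pushing the two group means toward
each other; the *unbalanced* split takes the complementary halves, maximizing
the stroma difference.  *Unstratified* splits are seeded uniform draws at the
balanced split's sample size.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .cohort_io import GROUP_CANCER, GROUP_NORMAL, SampleRecord, ValidationError

__all__ = [
    "DatasetSplit",
    "CompositionSummary",
    "NetContrast",
    "split_balanced_unbalanced",
    "complete_split",
    "draw_unstratified",
    "average_composition",
    "net_tissue_contrast",
]

TISSUES = ("cancer", "stroma", "benign")


@dataclass(frozen=True)
class DatasetSplit:
    """A named selection of cancer and normal sample ids."""

    name: str
    cancer_ids: tuple[str, ...]
    normal_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        overlap = set(self.cancer_ids) & set(self.normal_ids)
        if overlap:
            raise ValidationError(f"sample ids in both arms: {sorted(overlap)}")

    def validate(self, records: Sequence[SampleRecord]) -> None:
        """Check all ids exist and carry the arm's group label."""
        by_id = {r.sample_id: r for r in records}
        for ids, group in ((self.cancer_ids, GROUP_CANCER), (self.normal_ids, GROUP_NORMAL)):
            missing = [sid for sid in ids if sid not in by_id]
            if missing:
                raise ValidationError(f"split {self.name!r}: unknown sample ids {missing}")
            wrong = [sid for sid in ids if by_id[sid].group != group]
            if wrong:
                raise ValidationError(
                    f"split {self.name!r}: samples {wrong} are not in group {group!r}"
                )


@dataclass(frozen=True)
class CompositionSummary:
    """Per-group mean tissue fractions for one split."""

    cancer_means: Mapping[str, float]  # keys: cancer/stroma/benign
    normal_means: Mapping[str, float]
    n_cancer: int
    n_normal: int

    def __post_init__(self) -> None:
        for means in (self.cancer_means, self.normal_means):
            if abs(sum(means[t] for t in TISSUES) - 1.0) > 1e-9:
                raise ValidationError(f"group means do not sum to 1: {dict(means)}")


@dataclass(frozen=True)
class NetContrast:
    """Cancel-out net tissue contrast, in percent per side."""

    cancer_side: Mapping[str, float]
    normal_side: Mapping[str, float]


def _sorted_by_stroma(records: Sequence[SampleRecord], group: str) -> list[SampleRecord]:
    # ascending stroma; sample_id ascending breaks ties deterministically
    subset = [r for r in records if r.group == group]
    return sorted(subset, key=lambda r: (r.frac_stroma, r.sample_id))


def split_balanced_unbalanced(
    records: Sequence[SampleRecord],
) -> tuple[DatasetSplit, DatasetSplit]:
    """Half-split both groups by stroma content into balanced/unbalanced selections.

    Balanced: top floor(nC/2) cancer samples by stroma + bottom floor(nN/2)
    normal samples.  Unbalanced: the remaining ceil(nC/2) cancer samples
    (lowest stroma) + top floor(nN/2) normal samples.  The two cancer sets
    partition the cancer group; for odd normal counts the median normal
    sample is left out.
    """
    cancer = _sorted_by_stroma(records, GROUP_CANCER)
    normal = _sorted_by_stroma(records, GROUP_NORMAL)
    if len(cancer) < 2 or len(normal) < 2:
        raise ValidationError(
            f"need >=2 samples per group, got {len(cancer)} cancer / {len(normal)} normal"
        )
    half_c = len(cancer) // 2
    half_n = len(normal) // 2
    balanced = DatasetSplit(
        name="balanced",
        cancer_ids=tuple(r.sample_id for r in cancer[len(cancer) - half_c :]),
        normal_ids=tuple(r.sample_id for r in normal[:half_n]),
    )
    unbalanced = DatasetSplit(
        name="unbalanced",
        cancer_ids=tuple(r.sample_id for r in cancer[: len(cancer) - half_c]),
        normal_ids=tuple(r.sample_id for r in normal[len(normal) - half_n :]),
    )
    return balanced, unbalanced


def complete_split(records: Sequence[SampleRecord]) -> DatasetSplit:
    """All cancer vs all normal samples, input order preserved."""
    return DatasetSplit(
        name="complete",
        cancer_ids=tuple(r.sample_id for r in records if r.group == GROUP_CANCER),
        normal_ids=tuple(r.sample_id for r in records if r.group == GROUP_NORMAL),
    )


def draw_unstratified(
    records: Sequence[SampleRecord],
    k: int = 50,
    n_cancer: int = 47,
    n_normal: int = 17,
    seed: int | np.random.Generator = 0,
) -> list[DatasetSplit]:
    """Draw `k` seeded uniform without-replacement subsets of each group."""
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    cancer_ids = [r.sample_id for r in records if r.group == GROUP_CANCER]
    normal_ids = [r.sample_id for r in records if r.group == GROUP_NORMAL]
    if n_cancer > len(cancer_ids) or n_normal > len(normal_ids):
        raise ValidationError(
            f"requested {n_cancer}/{n_normal} cancer/normal samples but cohort has "
            f"{len(cancer_ids)}/{len(normal_ids)}"
        )
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    splits = []
    for i in range(k):
        splits.append(
            DatasetSplit(
                name=f"unstratified_{i:03d}",
                cancer_ids=tuple(rng.choice(cancer_ids, size=n_cancer, replace=False)),
                normal_ids=tuple(rng.choice(normal_ids, size=n_normal, replace=False)),
            )
        )
    return splits


def average_composition(
    split: DatasetSplit, records: Sequence[SampleRecord]
) -> CompositionSummary:
    """Arithmetic mean tissue fractions per arm of a split."""
    split.validate(records)
    if not split.cancer_ids or not split.normal_ids:
        raise ValidationError(f"split {split.name!r} has an empty group")
    by_id = {r.sample_id: r for r in records}

    def means(ids: tuple[str, ...]) -> dict[str, float]:
        fr = np.array([by_id[sid].fractions for sid in ids], dtype=float)
        m = fr.mean(axis=0)
        return dict(zip(TISSUES, m.tolist()))

    return CompositionSummary(
        cancer_means=means(split.cancer_ids),
        normal_means=means(split.normal_ids),
        n_cancer=len(split.cancer_ids),
        n_normal=len(split.normal_ids),
    )


def net_tissue_contrast(summary: CompositionSummary) -> NetContrast:
    """Cancel equal average tissue amounts between the groups.

    What remains on each side, expressed in percent, is the net tissue
    contrast the comparison actually measures: per tissue t,
    cancer_side[t] = max(0, meanC[t] - meanN[t]) and symmetrically for the
    normal side.  When normal samples carry no cancer tissue the two side
    totals are equal by construction.
    """
    cancer_side = {}
    normal_side = {}
    for t in TISSUES:
        d = summary.cancer_means[t] - summary.normal_means[t]
        cancer_side[t] = max(0.0, d) * 100.0
        normal_side[t] = max(0.0, -d) * 100.0
    return NetContrast(cancer_side=cancer_side, normal_side=normal_side)
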