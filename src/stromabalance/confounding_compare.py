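"""Quantify disagreement between differential results from different splits.

Top-list overlap curves against a resampling baseline, p-value
order-of-magnitude shift counts, the significance-ratio (SR) score that ranks
genes by how specific they are to the balanced or unbalanced contrast,
cross-study SR concordance, and per-pathway signed significance reports.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from .cohort_io import DifferentialResult, ValidationError

__all__ = [
    "OverlapCurve",
    "SRRanking",
    "DEFAULT_GENE_SETS",
    "shared_fraction_curve",
    "pairwise_overlap_baseline",
    "pvalue_shift_counts",
    "sr_rank",
    "cross_study_concordance",
    "pathway_report",
    "signed_log10_p",
]

P_FLOOR = 1e-300

DEFAULT_GENE_SETS: dict[str, tuple[str, ...]] = {
    "polyamine": ("ODC1", "SRM", "SMS", "AMD1", "SAT1", "SMOX"),
    "tca_succinate": (
        "ACO1",
        "ACO2",
        "CS",
        "SUCLA2",
        "SUCLG1",
        "SUCLG2",
        "SDHA",
        "SDHB",
        "SDHC",
        "SDHD",
    ),
    "fatty_acid": ("ACLY", "ACACA", "ACACB", "FASN"),
}


@dataclass(frozen=True)
class OverlapCurve:
    """Shared fraction of top-N feature lists at increasing N."""

    points: tuple[tuple[int, float], ...]  # (N, shared_fraction)

    def __post_init__(self) -> None:
        ns = [n for n, _ in self.points]
        if any(b <= a for a, b in zip(ns, ns[1:])):
            raise ValidationError("N values must be strictly increasing")
        if any(not (0.0 <= f <= 1.0) for _, f in self.points):
            raise ValidationError("shared fractions must lie in [0, 1]")

    def as_dict(self) -> dict[int, float]:
        return dict(self.points)


@dataclass(frozen=True)
class SRRanking:
    """Per-gene significance-ratio scores for one context.

    sr = p_balanced / p_unbalanced in the ``balanced_specific`` context and
    its reciprocal in ``unbalanced_specific``; small scores (ascending rank)
    mark genes whose significance is specific to that context's split.
    """

    context: str  # "balanced_specific" | "unbalanced_specific"
    feature_ids: tuple[str, ...]  # in ascending score order
    scores: Mapping[str, float]
    direction_agreement: Mapping[str, bool]

    def top_n(self, n: int) -> tuple[str, ...]:
        return self.feature_ids[:n]

    def rank_of(self, feature_id: str) -> int:
        return self.feature_ids.index(feature_id) + 1


def _ordering_key(res: Sequence[DifferentialResult]):
    return sorted(res, key=lambda r: (r.p_raw, -abs(r.mean_diff), r.feature_id))


def _check_same_features(*results: Sequence[DifferentialResult]) -> None:
    sets = [frozenset(r.feature_id for r in res) for res in results]
    if any(s != sets[0] for s in sets[1:]):
        raise ValidationError("result lists cover different feature sets")


def shared_fraction_curve(
    res_a: Sequence[DifferentialResult],
    res_b: Sequence[DifferentialResult],
    ns: Sequence[int],
) -> OverlapCurve:
    """Fraction of features shared between the two top-N lists, per N."""
    _check_same_features(res_a, res_b)
    n_features = len(res_a)
    ns = sorted(set(int(n) for n in ns))
    if not ns or ns[0] < 1 or ns[-1] > n_features:
        raise ValidationError(f"N values must lie in [1, {n_features}], got {ns}")
    order_a = [r.feature_id for r in _ordering_key(res_a)]
    order_b = [r.feature_id for r in _ordering_key(res_b)]
    points = []
    for n in ns:
        shared = len(set(order_a[:n]) & set(order_b[:n]))
        points.append((n, shared / n))
    return OverlapCurve(points=tuple(points))


def pairwise_overlap_baseline(
    results_list: Sequence[Sequence[DifferentialResult]],
    ns: Sequence[int],
) -> OverlapCurve:
    """Mean shared fraction over all unordered pairs of result lists."""
    k = len(results_list)
    if k < 2:
        raise ValidationError(f"need >=2 result lists, got {k}")
    curves = [
        shared_fraction_curve(results_list[i], results_list[j], ns).as_dict()
        for i, j in itertools.combinations(range(k), 2)
    ]
    ns_sorted = sorted(curves[0])
    points = tuple(
        (n, float(np.mean([c[n] for c in curves]))) for n in ns_sorted
    )
    return OverlapCurve(points=points)


def pvalue_shift_counts(
    res_a: Sequence[DifferentialResult],
    res_b: Sequence[DifferentialResult],
    orders: Sequence[float],
) -> dict[float, int]:
    """Count features whose raw p changes by more than 10^k between results."""
    _check_same_features(res_a, res_b)
    pa = {r.feature_id: max(r.p_raw, P_FLOOR) for r in res_a}
    pb = {r.feature_id: max(r.p_raw, P_FLOOR) for r in res_b}
    shift = np.array([abs(np.log10(pa[f]) - np.log10(pb[f])) for f in pa])
    return {float(k): int((shift > k).sum()) for k in orders}


def sr_rank(
    res_balanced: Sequence[DifferentialResult],
    res_unbalanced: Sequence[DifferentialResult],
    context: Literal["balanced_specific", "unbalanced_specific"],
) -> SRRanking:
    """Rank genes by the significance ratio between the two splits (ascending)."""
    if context not in ("balanced_specific", "unbalanced_specific"):
        raise ValueError(f"unknown context {context!r}")
    _check_same_features(res_balanced, res_unbalanced)
    pb = {r.feature_id: r.p_raw for r in res_balanced}
    pu = {r.feature_id: r.p_raw for r in res_unbalanced}
    bad = [f for f in pb if pb[f] <= 0 or pu[f] <= 0]
    if bad:
        raise ValidationError(f"nonpositive p-values for features: {bad[:5]}")
    if context == "balanced_specific":
        scores = {f: pb[f] / pu[f] for f in pb}
    else:
        scores = {f: pu[f] / pb[f] for f in pb}
    db = {r.feature_id: r.direction for r in res_balanced}
    du = {r.feature_id: r.direction for r in res_unbalanced}
    ordered = tuple(sorted(scores, key=lambda f: (scores[f], f)))
    return SRRanking(
        context=context,
        feature_ids=ordered,
        scores=scores,
        direction_agreement={f: db[f] == du[f] for f in pb},
    )


def cross_study_concordance(
    sr_main: SRRanking,
    sr_validation: SRRanking,
    ns: Sequence[int],
    remove_opposite: bool = True,
) -> list[tuple[int, int]]:
    """Shared genes among the top-N SR-ranked genes of two studies.

    Rankings are restricted to the intersection of the two feature sets;
    `remove_opposite` additionally drops genes whose direction disagrees
    between the two splits within either study.
    """
    common = set(sr_main.feature_ids) & set(sr_validation.feature_ids)
    if not common:
        raise ValidationError("no shared features between the two rankings")
    if remove_opposite:
        common = {
            f
            for f in common
            if sr_main.direction_agreement[f] and sr_validation.direction_agreement[f]
        }
        if not common:
            raise ValidationError("no shared features left after direction filtering")
    main_order = [f for f in sr_main.feature_ids if f in common]
    val_order = [f for f in sr_validation.feature_ids if f in common]
    out = []
    for n in sorted(set(int(n) for n in ns)):
        if n < 1 or n > len(main_order):
            raise ValidationError(
                f"N={n} outside [1, {len(main_order)}] after restriction"
            )
        out.append((n, len(set(main_order[:n]) & set(val_order[:n]))))
    return out


def signed_log10_p(p_raw: float, mean_diff: float) -> float:
    """Presentation transform: -log10 p, positive when up in cancer."""
    v = -np.log10(max(p_raw, P_FLOOR))
    return float(v if mean_diff > 0 else -v)


def pathway_report(
    results_by_split: Mapping[str, Sequence[DifferentialResult]],
    gene_sets: Mapping[str, Sequence[str]] | None = None,
    metabolite_results_by_split: Mapping[str, Sequence[DifferentialResult]] | None = None,
    metabolite_sets: Mapping[str, Sequence[str]] | None = None,
) -> pd.DataFrame:
    """Tidy signed -log10 p table per pathway gene (and metabolite) per split.

    Genes absent from the results are emitted with status ``not_measured``
    rather than dropped.
    """
    gene_sets = DEFAULT_GENE_SETS if gene_sets is None else gene_sets
    for name, genes in gene_sets.items():
        if not genes:
            raise ValidationError(f"gene set {name!r} is empty")
    split_names = list(results_by_split)
    lookup = {
        split: {r.feature_id: r for r in res} for split, res in results_by_split.items()
    }
    rows = []

    def emit(set_name: str, feature: str, ftype: str, maps) -> None:
        row: dict[str, object] = {"pathway": set_name, "feature_id": feature, "type": ftype}
        measured = False
        for split in split_names:
            r = maps.get(split, {}).get(feature)
            if r is None:
                row[f"signed_log10_p_{split}"] = np.nan
            else:
                measured = True
                row[f"signed_log10_p_{split}"] = signed_log10_p(r.p_raw, r.mean_diff)
        row["status"] = "measured" if measured else "not_measured"
        rows.append(row)

    for set_name, genes in gene_sets.items():
        for g in genes:
            emit(set_name, g, "gene", lookup)
    if metabolite_results_by_split is not None and metabolite_sets is not None:
        mlookup = {
            split: {r.feature_id: r for r in res}
            for split, res in metabolite_results_by_split.items()
        }
        for set_name, mets in metabolite_sets.items():
            for m in mets:
                emit(set_name, m, "metabolite", mlookup)
    return pd.DataFrame(rows)
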