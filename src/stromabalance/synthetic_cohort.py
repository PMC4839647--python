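"""Synthetic mixed-tissue cohorts with known ground truth.

Samples are linear mixtures of three tissue archetypes (cancer, stroma,
benign epithelium).  Gene archetypes live on log2 scale and are mixed in
intensity space (signal adds physically), then logged and perturbed with
Gaussian noise; metabolite archetypes are linear concentrations mixed
directly, with noise truncated at zero.  Features fall into planted marker
classes:

* ``cancer_vs_epithelium`` — cancer and stroma archetypes share the shifted
  level, benign epithelium does not: a true cancer marker that stroma
  confounds (visible in the balanced split, masked in unstratified designs).
* ``stroma_vs_epithelium`` — only the stroma archetype is shifted: a tissue
  composition artifact (lights up in the unbalanced split).
* ``robust_cancer`` — only the cancer archetype is shifted: detectable
  regardless of stroma balance.
* ``null`` — identical archetypes; p-values are uniform in any split.

Normal samples carry zero cancer fraction and systematically more stroma
than cancer samples, mirroring the confounding regime the pipeline targets.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cohort_io import (
    GROUP_CANCER,
    GROUP_NORMAL,
    Cohort,
    DifferentialResult,
    SampleRecord,
    ValidationError,
)

__all__ = [
    "MARKER_CLASSES",
    "GeneratorParams",
    "TruthTable",
    "generate_cohort",
    "mix_gene_signal",
    "mix_metabolite_signal",
    "fit_dirichlet_moments",
    "resample_compositions",
    "classify_by_significance",
]

MARKER_CLASSES = (
    "cancer_vs_epithelium",
    "stroma_vs_epithelium",
    "robust_cancer",
    "null",
)

# archetype column order everywhere: (cancer, stroma, benign)
_SHIFT_PATTERN = {
    "cancer_vs_epithelium": np.array([1.0, 1.0, 0.0]),
    "stroma_vs_epithelium": np.array([0.0, 1.0, 0.0]),
    "robust_cancer": np.array([1.0, 0.0, 0.0]),
    "null": np.array([0.0, 0.0, 0.0]),
}

DEFAULT_GENE_CLASS_FRACTIONS: Mapping[str, float] = {
    "cancer_vs_epithelium": 0.05,
    "stroma_vs_epithelium": 0.05,
    "robust_cancer": 0.025,
    "null": 0.875,
}

DEFAULT_METABOLITE_CLASS_COUNTS: Mapping[str, int] = {
    "cancer_vs_epithelium": 7,
    "stroma_vs_epithelium": 4,
    "robust_cancer": 6,
    "null": 6,
}


@dataclass(frozen=True)
class GeneratorParams:
    """Knobs of the synthetic cohort generator.

    Composition priors are Dirichlet concentrations: 3-component
    (cancer, stroma, benign) for the cancer group, 2-component
    (stroma, benign) for the normal group whose cancer fraction is fixed at
    zero.  Defaults mimic a 95/34 cohort whose normal samples average more
    stroma than its cancer samples.
    """

    n_cancer: int = 95
    n_normal: int = 34
    n_genes: int = 5000
    n_metabolites: int = 23
    alpha_cancer: tuple[float, float, float] = (4.4, 2.4, 1.2)
    alpha_normal: tuple[float, float] = (1.65, 1.35)  # (stroma, benign)
    gene_class_fractions: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_GENE_CLASS_FRACTIONS)
    )
    metabolite_class_counts: Mapping[str, int] = field(
        default_factory=lambda: dict(DEFAULT_METABOLITE_CLASS_COUNTS)
    )
    gene_effect: float = 1.0  # log2 units
    gene_noise_sd: float = 0.5
    gene_base_mean: float = 7.0
    gene_base_sd: float = 1.0
    metabolite_fold: float = 2.5  # fold change of the shifted archetype
    metabolite_noise_frac: float = 0.15  # noise SD as fraction of base level
    seed: int = 0

    def __post_init__(self) -> None:
        if self.gene_effect < 0 or self.metabolite_fold <= 0:
            raise ValidationError("effect sizes must be non-negative")
        if min(self.alpha_cancer) <= 0 or min(self.alpha_normal) <= 0:
            raise ValidationError("Dirichlet concentrations must be positive")
        ac = np.asarray(self.alpha_cancer, dtype=float)
        an = np.asarray(self.alpha_normal, dtype=float)
        if ac[1] / ac.sum() >= an[0] / an.sum():
            raise ValidationError(
                "normal-group mean stroma must exceed cancer-group mean stroma"
            )
        fr = self.gene_class_fractions
        if set(fr) != set(MARKER_CLASSES) or abs(sum(fr.values()) - 1.0) > 1e-9:
            raise ValidationError(
                f"gene_class_fractions must cover {MARKER_CLASSES} and sum to 1"
            )
        counts = self.metabolite_class_counts
        if set(counts) != set(MARKER_CLASSES) or sum(counts.values()) != self.n_metabolites:
            raise ValidationError(
                f"metabolite_class_counts must cover {MARKER_CLASSES} and sum to "
                f"n_metabolites={self.n_metabolites}"
            )


@dataclass
class TruthTable:
    """Ground truth aligned with the emitted cohort."""

    gene_truth: pd.DataFrame  # index gene_id: class, arch_*, true_effect
    metabolite_truth: pd.DataFrame
    compositions: pd.DataFrame  # sample_id, group, frac_cancer/stroma/benign


def mix_gene_signal(archetypes: np.ndarray, fractions: np.ndarray) -> np.ndarray:
    """log2 of the fraction-weighted sum of per-tissue intensities.

    archetypes: (n_genes, 3) log2 levels; fractions: (n_samples, 3).
    Returns (n_genes, n_samples).
    """
    return np.log2(np.power(2.0, archetypes) @ np.asarray(fractions, dtype=float).T)


def mix_metabolite_signal(archetypes: np.ndarray, fractions: np.ndarray) -> np.ndarray:
    """Fraction-weighted sum of per-tissue concentrations (linear space)."""
    return np.asarray(archetypes, dtype=float) @ np.asarray(fractions, dtype=float).T


def _assign_gene_classes(n: int, fractions: Mapping[str, float]) -> np.ndarray:
    counts = {c: int(round(fractions[c] * n)) for c in MARKER_CLASSES[:-1]}
    counts["null"] = n - sum(counts.values())
    if counts["null"] < 0:
        raise ValidationError("class fractions exceed 1 after rounding")
    out = []
    for c in MARKER_CLASSES:
        out.extend([c] * counts[c])
    return np.array(out)


def _draw_compositions(params: GeneratorParams, rng: np.random.Generator) -> pd.DataFrame:
    fc = rng.dirichlet(params.alpha_cancer, size=params.n_cancer)
    sb = rng.dirichlet(params.alpha_normal, size=params.n_normal)
    fn = np.column_stack([np.zeros(params.n_normal), sb])
    width = len(str(max(params.n_cancer, params.n_normal)))
    rows = []
    for i in range(params.n_cancer):
        rows.append((f"C{i + 1:0{width}d}", GROUP_CANCER, *fc[i]))
    for i in range(params.n_normal):
        rows.append((f"N{i + 1:0{width}d}", GROUP_NORMAL, *fn[i]))
    return pd.DataFrame(
        rows, columns=["sample_id", "group", "frac_cancer", "frac_stroma", "frac_benign"]
    )


def generate_cohort(params: GeneratorParams) -> tuple[Cohort, TruthTable]:
    """Draw one cohort (records + gene and metabolite matrices) with its truth."""
    rng = np.random.default_rng(params.seed)
    comp = _draw_compositions(params, rng)
    fractions = comp[["frac_cancer", "frac_stroma", "frac_benign"]].to_numpy()
    n_samples = len(comp)

    # genes: log2 archetypes, classes interleaved by shuffling ids not classes
    gene_ids = [f"G{i + 1:05d}" for i in range(params.n_genes)]
    classes = _assign_gene_classes(params.n_genes, params.gene_class_fractions)
    rng.shuffle(classes)
    base = rng.normal(params.gene_base_mean, params.gene_base_sd, size=params.n_genes)
    signs = rng.choice([-1.0, 1.0], size=params.n_genes)
    shift = np.stack([_SHIFT_PATTERN[c] for c in classes])  # (n_genes, 3)
    effects = signs * params.gene_effect * (classes != "null")
    arch_genes = base[:, None] + shift * effects[:, None]
    gene_matrix = mix_gene_signal(arch_genes, fractions)
    gene_matrix += rng.normal(0.0, params.gene_noise_sd, size=gene_matrix.shape)

    # metabolites: linear concentrations; first feature is the citrate-like
    # control (high in benign epithelium, low in stroma and cancer)
    met_classes = []
    for c in MARKER_CLASSES:
        met_classes.extend([c] * params.metabolite_class_counts[c])
    met_classes = np.array(met_classes)
    met_base = rng.uniform(2.0, 20.0, size=params.n_metabolites)
    met_signs = rng.choice([-1.0, 1.0], size=params.n_metabolites)
    # citrate-like: force the first cancer_vs_epithelium slot down-in-cancer
    met_signs[0] = -1.0
    met_ids = ["citrate_like"] + [f"M{i + 1:02d}" for i in range(1, params.n_metabolites)]
    met_shift = np.stack([_SHIFT_PATTERN[c] for c in met_classes])
    # shifted archetype is base*fold (up) or base/fold (down)
    factor = np.where(met_signs > 0, params.metabolite_fold, 1.0 / params.metabolite_fold)
    factor = np.where(met_classes == "null", 1.0, factor)
    arch_mets = met_base[:, None] * np.power(factor[:, None], met_shift)
    met_matrix = mix_metabolite_signal(arch_mets, fractions)
    met_matrix += rng.normal(
        0.0, params.metabolite_noise_frac * met_base[:, None], size=met_matrix.shape
    )
    np.clip(met_matrix, 0.0, None, out=met_matrix)  # truncate noise at zero

    records = [
        SampleRecord(
            sample_id=row.sample_id,
            group=row.group,
            frac_cancer=float(row.frac_cancer),
            frac_stroma=float(row.frac_stroma),
            frac_benign=float(row.frac_benign),
        )
        for row in comp.itertuples(index=False)
    ]
    cohort = Cohort(
        samples=records,
        gene_matrix=gene_matrix,
        gene_ids=gene_ids,
        metabolite_matrix=met_matrix,
        metabolite_ids=met_ids,
    )
    gene_truth = pd.DataFrame(
        {
            "marker_class": classes,
            "arch_cancer": arch_genes[:, 0],
            "arch_stroma": arch_genes[:, 1],
            "arch_benign": arch_genes[:, 2],
            "true_effect": effects,
        },
        index=pd.Index(gene_ids, name="feature_id"),
    )
    met_effect = np.where(
        met_classes == "null", 0.0, met_signs * np.log2(params.metabolite_fold)
    )
    metabolite_truth = pd.DataFrame(
        {
            "marker_class": met_classes,
            "arch_cancer": arch_mets[:, 0],
            "arch_stroma": arch_mets[:, 1],
            "arch_benign": arch_mets[:, 2],
            "true_effect": met_effect,
        },
        index=pd.Index(met_ids, name="feature_id"),
    )
    return cohort, TruthTable(
        gene_truth=gene_truth, metabolite_truth=metabolite_truth, compositions=comp
    )


def fit_dirichlet_moments(fractions: np.ndarray) -> np.ndarray:
    """Method-of-moments Dirichlet fit: alpha = mean * concentration.

    Concentration is averaged over the per-coordinate estimates
    m_i(1-m_i)/v_i - 1.  Degenerate (zero-variance) input raises.
    """
    x = np.asarray(fractions, dtype=float)
    if x.ndim != 2 or x.shape[0] < 3:
        raise ValidationError("need >=3 composition rows to fit a Dirichlet")
    m = x.mean(axis=0)
    v = x.var(axis=0, ddof=1)
    usable = (v > 1e-12) & (m > 0) & (m < 1)
    if not usable.any():
        raise ValidationError(
            "degenerate compositions (no coordinate varies); supply explicit "
            "Dirichlet parameters instead"
        )
    s = float(np.mean(m[usable] * (1 - m[usable]) / v[usable] - 1.0))
    if s <= 0:
        raise ValidationError("moment fit produced non-positive concentration")
    return m * s


def resample_compositions(
    records: Sequence[SampleRecord],
    n_cancer: int | None = None,
    n_normal: int | None = None,
    seed: int = 0,
) -> list[SampleRecord]:
    """Draw new compositions from per-group Dirichlet fits of observed records.

    The normal group is fitted on (stroma, benign) only; its cancer fraction
    stays exactly zero.
    """
    cancer = [r for r in records if r.group == GROUP_CANCER]
    normal = [r for r in records if r.group == GROUP_NORMAL]
    if len(cancer) < 3 or len(normal) < 3:
        raise ValidationError("need >=3 samples per group to fit composition models")
    alpha_c = fit_dirichlet_moments(np.array([r.fractions for r in cancer]))
    alpha_n = fit_dirichlet_moments(
        np.array([(r.frac_stroma, r.frac_benign) for r in normal])
    )
    n_cancer = len(cancer) if n_cancer is None else n_cancer
    n_normal = len(normal) if n_normal is None else n_normal
    rng = np.random.default_rng(seed)
    fc = rng.dirichlet(alpha_c, size=n_cancer)
    sb = rng.dirichlet(alpha_n, size=n_normal)
    out = [
        SampleRecord(f"simC{i + 1:04d}", GROUP_CANCER, *fc[i]) for i in range(n_cancer)
    ]
    out += [
        SampleRecord(f"simN{i + 1:04d}", GROUP_NORMAL, 0.0, sb[i, 0], sb[i, 1])
        for i in range(n_normal)
    ]
    return out


def classify_by_significance(
    res_balanced: Sequence[DifferentialResult],
    res_unbalanced: Sequence[DifferentialResult],
    alpha: float = 0.05,
) -> dict[str, str]:
    """Infer each feature's marker class from its balanced/unbalanced pattern.

    Significant only in balanced -> stroma-confounded cancer marker; only in
    unbalanced -> stroma-vs-epithelium marker; in both -> composition-robust
    cancer marker; in neither -> null.
    """
    pb = {r.feature_id: r.p_raw for r in res_balanced}
    pu = {r.feature_id: r.p_raw for r in res_unbalanced}
    if set(pb) != set(pu):
        raise ValidationError("result lists cover different feature sets")
    out = {}
    for f in pb:
        sig_b, sig_u = pb[f] < alpha, pu[f] < alpha
        if sig_b and not sig_u:
            out[f] = "cancer_vs_epithelium"
        elif sig_u and not sig_b:
            out[f] = "stroma_vs_epithelium"
        elif sig_b and sig_u:
            out[f] = "robust_cancer"
        else:
            out[f] = "null"
    return out
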