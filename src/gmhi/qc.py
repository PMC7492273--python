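"""Sample- and feature-level quality filters for taxonomic profiles.

Three sample-level steps (BMI-based regrouping of nominally healthy
subjects, removal of samples dominated by unclassified taxonomy, and
Bray-Curtis outlier fencing against a per-phenotype median profile) and
one feature-level step (dropping viral, unclassified, and rarely observed
species). Filter order in :func:`run_qc` follows that narrative:
unclassified-sample filter, outlier filter, then feature filters.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import braycurtis

from .profiles import AbundanceTable, HEALTHY, NONHEALTHY

# BMI cut-offs for reclassifying nominally healthy subjects
BMI_UNDERWEIGHT = 18.5
BMI_OVERWEIGHT = 25.0
BMI_OBESE = 30.0

DEFAULT_PRESENCE_THRESHOLD = 1e-5


@dataclass
class QcReport:
    """Record of removals with one reason each, plus outlier distances."""

    samples_removed_unclassified: list = field(default_factory=list)
    samples_removed_outlier: list = field(default_factory=list)
    features_removed: dict = field(default_factory=dict)  # reason -> [feature]
    distances: pd.DataFrame | None = None  # sample_id, phenotype, distance, outlier

    def merge(self, other: "QcReport") -> "QcReport":
        out = QcReport(
            self.samples_removed_unclassified + other.samples_removed_unclassified,
            self.samples_removed_outlier + other.samples_removed_outlier,
            {**self.features_removed},
            other.distances if other.distances is not None else self.distances,
        )
        for reason, feats in other.features_removed.items():
            out.features_removed.setdefault(reason, []).extend(feats)
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for s in self.samples_removed_unclassified:
            rows.append(("sample", s, "unclassified_fraction"))
        for s in self.samples_removed_outlier:
            rows.append(("sample", s, "outlier"))
        for reason, feats in self.features_removed.items():
            rows.extend(("feature", f, reason) for f in feats)
        return pd.DataFrame(rows, columns=["kind", "id", "reason"])


def reclassify_by_bmi(table: AbundanceTable) -> AbundanceTable:
    """Move healthy-labeled samples with abnormal BMI to the nonhealthy group.

    Underweight (BMI < 18.5), overweight (25 <= BMI < 30) and obese
    (BMI >= 30) subjects keep their abundances but get the corresponding
    phenotype and group ``nonhealthy``. Samples without a BMI are left
    unchanged.
    """
    meta = table.metadata.copy()
    bmi = meta["bmi"].astype(float)
    if (bmi.dropna() < 0).any():
        bad = meta.index[bmi < 0][0]
        raise ValueError(f"negative BMI for sample {bad!r}")
    healthy = meta["group"] == HEALTHY
    for phenotype, mask in (
        ("underweight", bmi < BMI_UNDERWEIGHT),
        ("overweight", (bmi >= BMI_OVERWEIGHT) & (bmi < BMI_OBESE)),
        ("obese", bmi >= BMI_OBESE),
    ):
        sel = healthy & mask.fillna(False)
        meta.loc[sel, "phenotype"] = phenotype
        meta.loc[sel, "group"] = NONHEALTHY
    return table.with_metadata(meta)


def filter_unclassified_samples(
    table: AbundanceTable,
    max_unclassified_frac: float = 0.05,
) -> tuple[AbundanceTable, QcReport]:
    """Drop samples whose unclassified taxonomy fraction is strictly above cutoff."""
    unclassified = table.unclassified_features()
    frac = (table.data[unclassified].sum(axis=1) if unclassified
            else pd.Series(0.0, index=table.data.index))
    removed = list(frac.index[frac > max_unclassified_frac])
    kept = [s for s in table.sample_ids if s not in set(removed)]
    if not kept:
        warnings.warn("all samples exceeded the unclassified-fraction cutoff")
    report = QcReport(samples_removed_unclassified=removed)
    return table.subset(samples=kept), report


def detect_outliers(table: AbundanceTable, group_by: str = "phenotype",
                    fence_factor: float = 1.5) -> QcReport:
    """Flag per-phenotype Bray-Curtis outliers against the median profile.

    For each phenotype with at least 4 samples, a hypothetical sample is
    built from the feature-wise medians (used as-is, without
    renormalization) and each sample's Bray-Curtis distance to it is
    computed. Samples beyond ``fence_factor`` x IQR outside the quartiles
    (either fence) are flagged. Quartiles use linear interpolation.
    """
    records = []
    outliers: list[str] = []
    for phenotype, meta in table.metadata.groupby(group_by, sort=False):
        samples = list(meta.index)
        if len(samples) < 4:
            warnings.warn(
                f"phenotype {phenotype!r} has {len(samples)} samples (<4); "
                "outlier detection skipped")
            continue
        block = table.data.loc[samples].to_numpy()
        median_profile = np.median(block, axis=0)
        dists = np.array([_bray_curtis_safe(row, median_profile)
                          for row in block])
        q1, q3 = np.percentile(dists, [25, 75])
        iqr = q3 - q1
        lo, hi = q1 - fence_factor * iqr, q3 + fence_factor * iqr
        flags = (dists > hi) | (dists < lo)
        outliers.extend(s for s, f in zip(samples, flags) if f)
        records.extend(
            {"sample_id": s, "phenotype": phenotype, "distance": d,
             "outlier": bool(f)}
            for s, d, f in zip(samples, dists, flags))
    distances = pd.DataFrame(
        records, columns=["sample_id", "phenotype", "distance", "outlier"])
    return QcReport(samples_removed_outlier=outliers, distances=distances)


def _bray_curtis_safe(a: np.ndarray, b: np.ndarray) -> float:
    if a.sum() == 0 and b.sum() == 0:
        return 0.0
    return float(braycurtis(a, b))


def remove_outliers(table: AbundanceTable,
                    group_by: str = "phenotype") -> tuple[AbundanceTable, QcReport]:
    report = detect_outliers(table, group_by=group_by)
    kept = [s for s in table.sample_ids
            if s not in set(report.samples_removed_outlier)]
    return table.subset(samples=kept), report


def filter_features(
    table: AbundanceTable,
    min_prevalence: float = 0.01,
    drop_viruses: bool = True,
    drop_unclassified: bool = True,
    presence_threshold: float = DEFAULT_PRESENCE_THRESHOLD,
    renormalize: bool = True,
) -> tuple[AbundanceTable, QcReport]:
    """Drop viral, unclassified, and rarely observed features.

    A feature is "present" in a sample when its abundance is at or above
    ``presence_threshold``; features present in fewer than
    ``min_prevalence`` of all samples are removed. Each removed feature is
    recorded under exactly one reason, checked in the order virus,
    unclassified, low prevalence. Retained rows are renormalized to sum 1
    unless ``renormalize`` is false.
    """
    removed: dict[str, list] = {"virus": [], "unclassified": [],
                                "low_prevalence": []}
    viral = set(table.viral_features()) if drop_viruses else set()
    unclassified = set(table.unclassified_features()) if drop_unclassified else set()
    prevalence = (table.data.to_numpy() >= presence_threshold).mean(axis=0)
    kept = []
    for feat, prev in zip(table.data.columns, prevalence):
        if feat in viral:
            removed["virus"].append(feat)
        elif feat in unclassified:
            removed["unclassified"].append(feat)
        elif prev < min_prevalence:
            removed["low_prevalence"].append(feat)
        else:
            kept.append(feat)
    if not kept:
        raise ValueError("feature filtering removed every feature")
    out = table.subset(features=kept)
    if renormalize:
        out = out.normalized()
    return out, QcReport(features_removed={k: v for k, v in removed.items() if v})


def run_qc(table: AbundanceTable,
           max_unclassified_frac: float = 0.05,
           min_prevalence: float = 0.01,
           presence_threshold: float = DEFAULT_PRESENCE_THRESHOLD,
           reclassify_bmi: bool = True,
           renormalize: bool = True) -> tuple[AbundanceTable, QcReport]:
    """Full QC pipeline: BMI regrouping, sample filters, feature filters."""
    if reclassify_bmi:
        table = reclassify_by_bmi(table)
    table, r1 = filter_unclassified_samples(table, max_unclassified_frac)
    table, r2 = remove_outliers(table)
    table, r3 = filter_features(
        table, min_prevalence=min_prevalence,
        presence_threshold=presence_threshold, renormalize=renormalize)
    return table, r1.merge(r2).merge(r3)
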