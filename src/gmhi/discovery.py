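"""Prevalence-based discovery of health-prevalent and health-scarce species.

A species m is "present" in a sample when its relative abundance is at
least the presence threshold (default 1e-5); its prevalence p_{G,m} is
the fraction of a group's samples where it is present. With fold change
f = p_H/p_N and difference d = p_H - p_N, the health-prevalent set M_H
collects species with f >= theta_f and d >= theta_d; the health-scarce
set M_N mirrors the criteria. The threshold pair is chosen by maximizing
balanced accuracy of the resulting sign classifier over a grid.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from .profiles import AbundanceTable, HEALTHY, NONHEALTHY
from .scoring import (
    DEFAULT_PRESENCE_THRESHOLD,
    DEFAULT_PSEUDO_COUNT,
    GmhiSignature,
    estimate_effective_set_sizes,
    score_table,
)

#: default threshold grids; include the published optimum (1.4, 0.10)
DEFAULT_THETA_F_GRID: tuple[float, ...] = tuple(
    round(1.0 + 0.1 * i, 2) for i in range(1, 11))  # 1.1 .. 2.0
DEFAULT_THETA_D_GRID: tuple[float, ...] = tuple(
    round(0.025 * i, 3) for i in range(1, 9))  # 0.025 .. 0.20


@dataclass(frozen=True)
class Thresholds:
    """Minimum prevalence fold change and difference for set membership."""

    theta_f: float
    theta_d: float

    def __post_init__(self) -> None:
        if self.theta_f < 1:
            raise ValueError("theta_f must be >= 1")
        if not 0 <= self.theta_d <= 1:
            raise ValueError("theta_d must be in [0, 1]")


@dataclass
class AccuracyReport:
    """Balanced accuracy chi and the per-group bookkeeping behind it."""

    proportion_h_correct: float
    proportion_n_correct: float
    counts: dict  # group -> {"positive": int, "negative": int, "zero": int}

    @property
    def chi(self) -> float:
        return (self.proportion_h_correct + self.proportion_n_correct) / 2.0


def compute_prevalence(
    table: AbundanceTable, group: str,
    presence_threshold: float = DEFAULT_PRESENCE_THRESHOLD,
) -> pd.Series:
    """Per-feature prevalence within one group (inclusive >= threshold)."""
    samples = table.group_samples(group)
    if not samples:
        raise ValueError(f"group {group!r} has no samples")
    present = table.data.loc[samples].to_numpy() >= presence_threshold
    return pd.Series(present.mean(axis=0), index=table.data.columns,
                     name=f"prevalence_{group}")


def prevalence_records(
    table: AbundanceTable,
    presence_threshold: float = DEFAULT_PRESENCE_THRESHOLD,
) -> pd.DataFrame:
    """Per-feature p_H, p_N and both directed fold changes / differences.

    Fold changes with a zero denominator are +inf when the numerator is
    positive; 0/0 yields NaN (the feature is ineligible for either set).
    """
    p_h = compute_prevalence(table, HEALTHY, presence_threshold)
    p_n = compute_prevalence(table, NONHEALTHY, presence_threshold)

    def folds(num: np.ndarray, den: np.ndarray) -> np.ndarray:
        out = np.full(num.shape, np.nan)
        nz = den > 0
        out[nz] = num[nz] / den[nz]
        out[(~nz) & (num > 0)] = np.inf
        return out

    ph, pn = p_h.to_numpy(), p_n.to_numpy()
    return pd.DataFrame(
        {
            "p_H": ph,
            "p_N": pn,
            "f_HN": folds(ph, pn),
            "f_NH": folds(pn, ph),
            "d_HN": ph - pn,
            "d_NH": pn - ph,
        },
        index=p_h.index,
    )


def select_signature_from_records(
    records: pd.DataFrame, thresholds: Thresholds,
) -> tuple[list, list]:
    in_h = (records["f_HN"] >= thresholds.theta_f) & (
        records["d_HN"] >= thresholds.theta_d)
    in_n = (records["f_NH"] >= thresholds.theta_f) & (
        records["d_NH"] >= thresholds.theta_d)
    return list(records.index[in_h.fillna(False)]), list(
        records.index[in_n.fillna(False)])


def select_signature(
    table: AbundanceTable, thresholds: Thresholds,
    presence_threshold: float = DEFAULT_PRESENCE_THRESHOLD,
) -> tuple[list, list]:
    """Return (M_H, M_N) satisfying both threshold criteria.

    The sets are disjoint by construction whenever theta_d > 0 (a species
    cannot exceed the difference threshold in both directions).
    """
    records = prevalence_records(table, presence_threshold)
    return select_signature_from_records(records, thresholds)


def balanced_accuracy(scores: Sequence[float],
                      groups: Sequence[str]) -> AccuracyReport:
    """Chi: mean of the healthy fraction with h > 0 and nonhealthy with h < 0.

    Inequalities are strict; h = 0 counts as incorrect for both groups.
    """
    scores = np.asarray(scores, dtype=float)
    groups = np.asarray(groups)
    if len(scores) != len(groups):
        raise ValueError("scores and groups differ in length")
    counts = {}
    for grp in (HEALTHY, NONHEALTHY):
        mask = groups == grp
        if not mask.any():
            raise ValueError(f"group {grp!r} absent")
        s = scores[mask]
        counts[grp] = {"positive": int((s > 0).sum()),
                       "negative": int((s < 0).sum()),
                       "zero": int((s == 0).sum())}
    n_h = sum(counts[HEALTHY].values())
    n_n = sum(counts[NONHEALTHY].values())
    return AccuracyReport(
        proportion_h_correct=counts[HEALTHY]["positive"] / n_h,
        proportion_n_correct=counts[NONHEALTHY]["negative"] / n_n,
        counts=counts,
    )


def fit_signature(
    table: AbundanceTable, thresholds: Thresholds,
    presence_threshold: float = DEFAULT_PRESENCE_THRESHOLD,
    pseudo_count: float = DEFAULT_PSEUDO_COUNT,
    records: pd.DataFrame | None = None,
) -> GmhiSignature:
    """Select a signature and fit its effective set sizes on one table."""
    if records is None:
        records = prevalence_records(table, presence_threshold)
    m_h, m_n = select_signature_from_records(records, thresholds)
    if not m_h or not m_n:
        raise ValueError(
            f"empty species set at thresholds {thresholds}: "
            f"|M_H|={len(m_h)}, |M_N|={len(m_n)}")
    eff = estimate_effective_set_sizes(
        table, m_h, m_n, presence_threshold, fallback_to_cardinality=True)
    prev = pd.DataFrame({
        "p_H": records.loc[m_h + m_n, "p_H"] * 100.0,
        "p_N": records.loc[m_h + m_n, "p_N"] * 100.0,
        "group": ["H+"] * len(m_h) + ["H-"] * len(m_n),
    })
    return GmhiSignature(
        m_h, m_n, thresholds.theta_f, thresholds.theta_d,
        eff.size_h_eff, eff.size_n_eff, presence_threshold, pseudo_count,
        provenance="fitted", prevalence=prev)


@dataclass
class GridSearchResult:
    thresholds: Thresholds
    m_h: list
    m_n: list
    chi_max: float
    grid: pd.DataFrame  # theta_f, theta_d, n_MH, n_MN, chi
    signature: GmhiSignature


def grid_search(
    table: AbundanceTable,
    theta_f_grid: Sequence[float] = DEFAULT_THETA_F_GRID,
    theta_d_grid: Sequence[float] = DEFAULT_THETA_D_GRID,
    presence_threshold: float = DEFAULT_PRESENCE_THRESHOLD,
    pseudo_count: float = DEFAULT_PSEUDO_COUNT,
) -> GridSearchResult:
    """Maximize balanced accuracy over the (theta_f, theta_d) grid.

    Each cell selects a candidate signature, fits effective set sizes,
    scores all samples, and records chi. Cells with an empty set record
    chi as NaN. Ties are broken toward larger theta_f, then larger
    theta_d (the more stringent, more parsimonious signature).
    """
    if not len(theta_f_grid) or not len(theta_d_grid):
        raise ValueError("threshold grids must be nonempty")
    records = prevalence_records(table, presence_threshold)
    groups = table.metadata["group"].to_numpy()
    rows = []
    best = None  # (chi, theta_f, theta_d, signature)
    for tf in theta_f_grid:
        for td in theta_d_grid:
            thresholds = Thresholds(tf, td)
            m_h, m_n = select_signature_from_records(records, thresholds)
            chi = math.nan
            signature = None
            if m_h and m_n:
                signature = fit_signature(
                    table, thresholds, presence_threshold, pseudo_count,
                    records=records)
                scores = score_table(table, signature)["gmhi"].to_numpy()
                chi = balanced_accuracy(scores, groups).chi
                key = (chi, tf, td)
                if best is None or key > best[0]:
                    best = (key, signature)
            rows.append({"theta_f": tf, "theta_d": td,
                         "n_MH": len(m_h), "n_MN": len(m_n), "chi": chi})
    grid = pd.DataFrame(rows)
    if best is None:
        raise ValueError("every grid cell produced an empty species set")
    (chi_max, tf, td), signature = best
    return GridSearchResult(
        Thresholds(tf, td), list(signature.m_h), list(signature.m_n),
        chi_max, grid, signature)


@dataclass
class CrossValidationResult:
    mean_chi: float
    fold_reports: list = field(default_factory=list)
    fold_chis: list = field(default_factory=list)


def cross_validate(
    table: AbundanceTable,
    thresholds: Thresholds,
    k: int = 10,
    seed: int | None = 0,
    presence_threshold: float = DEFAULT_PRESENCE_THRESHOLD,
    pseudo_count: float = DEFAULT_PSEUDO_COUNT,
) -> CrossValidationResult:
    """Stratified k-fold cross-validation of the full pipeline.

    Signature selection and effective set sizes are fitted on the
    training folds only; chi is computed on the held-out fold. Folds are
    stratified by group with seeded shuffling, so results are
    deterministic under a fixed seed.
    """
    groups = table.metadata["group"].to_numpy()
    for grp in (HEALTHY, NONHEALTHY):
        n = int((groups == grp).sum())
        if n < k:
            raise ValueError(f"group {grp!r} has {n} samples < k={k}")
    ids = np.array(table.sample_ids)
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    reports, chis = [], []
    for train_idx, test_idx in skf.split(ids, groups):
        train = table.subset(samples=ids[train_idx])
        test = table.subset(samples=ids[test_idx])
        signature = fit_signature(
            train, thresholds, presence_threshold, pseudo_count)
        scores = score_table(test, signature)["gmhi"].to_numpy()
        report = balanced_accuracy(scores, groups[test_idx])
        reports.append(report)
        chis.append(report.chi)
    return CrossValidationResult(float(np.mean(chis)), reports, chis)
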