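"""Synthetic labeled cohorts with planted prevalence differentials.

The generator emulates the statistical structure the prevalence-based
selection assumes: a sparse compositional species table where a small
set of planted "healthy-associated" species is present more often in the
healthy group (base + gap vs base probability) and a mirrored set is
present more often in the nonhealthy group, against a background of
species equally prevalent in both. Present species draw abundances from
a log-normal law (spanning several orders of magnitude, as real
species-level profiles do) and each sample is closed to sum 1.

Presence and abundance are sampled independently per species and sample;
there is no inter-species correlation, batch structure, or phylogeny —
a documented simplification.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .profiles import AbundanceTable, HEALTHY, NONHEALTHY


@dataclass
class CohortSpec:
    """Parameters of one synthetic cohort.

    Defaults describe the discovery-style setting used throughout the
    test suite: 500 samples per group, 100 species of which 10 per
    direction carry a 0.25 presence-probability gap over a 0.3 baseline,
    log-normal positive abundances with location -7 and scale 1.5.
    """

    n_h: int = 500
    n_n: int = 500
    n_species: int = 100
    n_planted_h: int = 10
    n_planted_n: int = 10
    prevalence_base: float = 0.3
    prevalence_gap: float = 0.25
    abundance_mu: float = -7.0
    abundance_sigma: float = 1.5
    n_pseudo_phenotypes: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_h, self.n_n, self.n_species) <= 0:
            raise ValueError("counts must be positive")
        if self.n_planted_h + self.n_planted_n > self.n_species:
            raise ValueError("planted species exceed n_species")
        if self.prevalence_gap < 0:
            raise ValueError("prevalence_gap must be >= 0")
        if self.prevalence_base + self.prevalence_gap > 1:
            raise ValueError("prevalence_base + prevalence_gap must be <= 1")


@dataclass
class PlantedTruth:
    """Ground truth of a generated cohort."""

    planted_h: list
    planted_n: list
    realized_prevalence: pd.DataFrame = field(repr=False)  # p_H, p_N per species


def generate_cohort(spec: CohortSpec) -> tuple[AbundanceTable, PlantedTruth]:
    """Generate one labeled cohort; deterministic under ``spec.seed``.

    Healthy samples get phenotype ``healthy``; nonhealthy samples are
    spread evenly over ``n_pseudo_phenotypes`` pseudo-disease labels so
    per-phenotype operations (outlier fencing, intra-study contrasts)
    are exercisable.
    """
    rng = np.random.default_rng(spec.seed)
    n_total = spec.n_h + spec.n_n
    species = (
        [f"sp_plantH_{i:03d}" for i in range(spec.n_planted_h)]
        + [f"sp_plantN_{i:03d}" for i in range(spec.n_planted_n)]
        + [f"sp_bg_{i:03d}" for i in
           range(spec.n_species - spec.n_planted_h - spec.n_planted_n)]
    )
    planted_h = species[:spec.n_planted_h]
    planted_n = species[spec.n_planted_h:spec.n_planted_h + spec.n_planted_n]

    # per-species presence probability by group
    prob_h = np.full(spec.n_species, spec.prevalence_base)
    prob_n = np.full(spec.n_species, spec.prevalence_base)
    prob_h[:spec.n_planted_h] += spec.prevalence_gap
    prob_n[spec.n_planted_h:spec.n_planted_h + spec.n_planted_n] += \
        spec.prevalence_gap

    is_healthy = np.zeros(n_total, dtype=bool)
    is_healthy[:spec.n_h] = True
    probs = np.where(is_healthy[:, None], prob_h[None, :], prob_n[None, :])
    present = rng.random((n_total, spec.n_species)) < probs
    # a sample with no species cannot be closed to proportions: force the
    # first background (or first overall) species present in such rows
    empty = ~present.any(axis=1)
    if empty.any():
        present[empty, min(spec.n_planted_h + spec.n_planted_n,
                           spec.n_species - 1)] = True
    amounts = np.where(
        present,
        rng.lognormal(spec.abundance_mu, spec.abundance_sigma,
                      (n_total, spec.n_species)),
        0.0)
    amounts /= amounts.sum(axis=1, keepdims=True)

    sample_ids = [f"S{i:05d}" for i in range(n_total)]
    pheno = np.empty(n_total, dtype=object)
    pheno[is_healthy] = HEALTHY
    k = max(1, spec.n_pseudo_phenotypes)
    pheno[~is_healthy] = [f"disease_{i % k + 1}" for i in range(spec.n_n)]
    metadata = pd.DataFrame(
        {
            "phenotype": pheno,
            "group": np.where(is_healthy, HEALTHY, NONHEALTHY),
            "study_id": "synthetic",
            "bmi": np.nan,
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    data = pd.DataFrame(amounts, index=sample_ids, columns=species)
    table = AbundanceTable(data, metadata)

    realized = pd.DataFrame(
        {
            "p_H": present[is_healthy].mean(axis=0),
            "p_N": present[~is_healthy].mean(axis=0),
        },
        index=species,
    )
    return table, PlantedTruth(planted_h, planted_n, realized)


def evaluate_recovery(truth: PlantedTruth,
                      found: tuple[list, list]) -> dict:
    """Set precision/recall of recovered signatures against the planted truth.

    Precision of an empty found set is undefined and reported as NaN;
    recall of an empty planted set is likewise NaN.
    """
    out = {}
    for key, planted, recovered in (
        ("H", truth.planted_h, found[0]),
        ("N", truth.planted_n, found[1]),
    ):
        planted_set, found_set = set(planted), set(recovered)
        tp = len(planted_set & found_set)
        out[f"precision_{key}"] = tp / len(found_set) if found_set else float("nan")
        out[f"recall_{key}"] = tp / len(planted_set) if planted_set else float("nan")
    return out
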