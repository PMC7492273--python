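"""Model/Results interface tying discovery, scoring, and diagnostics together.

``GmhiModel`` holds a labeled abundance table and the search
configuration; ``fit()`` runs the threshold grid search, selects the
health-prevalent/health-scarce sets, estimates the effective set sizes,
and returns a ``GmhiResults`` carrying the fitted signature, the
balanced-accuracy surface, per-sample training scores, and methods to
score new cohorts, cross-validate, and summarize.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from . import discovery, qc as qc_mod
from .discovery import (
    DEFAULT_THETA_D_GRID,
    DEFAULT_THETA_F_GRID,
    CrossValidationResult,
    Thresholds,
    balanced_accuracy,
)
from .profiles import AbundanceTable
from .scoring import (
    DEFAULT_PRESENCE_THRESHOLD,
    DEFAULT_PSEUDO_COUNT,
    GmhiSignature,
    score_table,
)


class GmhiModel:
    """Health-index model over a labeled species-abundance cohort.

    Parameters
    ----------
    table : AbundanceTable
        Samples x species proportions with healthy/nonhealthy groups in
        the metadata.
    theta_f_grid, theta_d_grid : sequence of float
        Candidate prevalence fold-change and difference thresholds.
    presence_threshold : float
        Minimum relative abundance for a species to count as present.
    pseudo_count : float
        Symmetric pseudo-count added to both collective abundances so the
        log ratio stays finite when one set is absent.
    """

    def __init__(self, table: AbundanceTable,
                 theta_f_grid: Sequence[float] = DEFAULT_THETA_F_GRID,
                 theta_d_grid: Sequence[float] = DEFAULT_THETA_D_GRID,
                 presence_threshold: float = DEFAULT_PRESENCE_THRESHOLD,
                 pseudo_count: float = DEFAULT_PSEUDO_COUNT) -> None:
        self.table = table
        self.theta_f_grid = tuple(theta_f_grid)
        self.theta_d_grid = tuple(theta_d_grid)
        self.presence_threshold = presence_threshold
        self.pseudo_count = pseudo_count

    @classmethod
    def from_dataframe(cls, abundance: pd.DataFrame,
                       metadata: pd.DataFrame, *,
                       apply_qc: bool = False, **kwargs) -> "GmhiModel":
        """Build a model from raw frames; optionally run the QC pipeline."""
        table = AbundanceTable(abundance, metadata).normalized()
        if apply_qc:
            table, _ = qc_mod.run_qc(table)
        return cls(table, **kwargs)

    def fit(self, thresholds: Thresholds | None = None) -> "GmhiResults":
        """Fit the signature; grid-search thresholds unless given."""
        if thresholds is None:
            gs = discovery.grid_search(
                self.table, self.theta_f_grid, self.theta_d_grid,
                self.presence_threshold, self.pseudo_count)
            signature, grid = gs.signature, gs.grid
        else:
            signature = discovery.fit_signature(
                self.table, thresholds, self.presence_threshold,
                self.pseudo_count)
            grid = None
        return GmhiResults(self, signature, grid)


class GmhiResults:
    """Fitted signature plus training diagnostics."""

    def __init__(self, model: GmhiModel, signature: GmhiSignature,
                 grid: pd.DataFrame | None = None) -> None:
        self.model = model
        self.signature = signature
        self.grid = grid
        self.scores = score_table(model.table, signature)
        self.accuracy = balanced_accuracy(
            self.scores["gmhi"].to_numpy(),
            model.table.metadata["group"].to_numpy())

    # -- statsmodels-style accessors ------------------------------------
    @property
    def thresholds(self) -> Thresholds:
        return Thresholds(self.signature.theta_f, self.signature.theta_d)

    @property
    def chi(self) -> float:
        """Training balanced accuracy of the sign classifier."""
        return self.accuracy.chi

    def predict(self, table: AbundanceTable | None = None) -> pd.DataFrame:
        """Score a (new) table; defaults to the training table."""
        if table is None:
            return self.scores.copy()
        return score_table(table, self.signature)

    def cross_validate(self, k: int = 10,
                       seed: int | None = 0) -> CrossValidationResult:
        """Refit signature and effective sizes per training fold."""
        return discovery.cross_validate(
            self.model.table, self.thresholds, k=k, seed=seed,
            presence_threshold=self.model.presence_threshold,
            pseudo_count=self.model.pseudo_count)

    def summary(self) -> str:
        sig = self.signature
        n_h = len(self.model.table.group_samples("healthy"))
        n_n = len(self.model.table.group_samples("nonhealthy"))
        lines = [
            "Gut Microbiome Health Index — fit summary",
            "=" * 45,
            f"samples:            {n_h} healthy / {n_n} nonhealthy",
            f"thresholds:         theta_f={sig.theta_f:g}, theta_d={sig.theta_d:g}",
            f"health-prevalent:   |M_H| = {len(sig.m_h)}  (|M_H|' = {sig.size_h_eff:g})",
            f"health-scarce:      |M_N| = {len(sig.m_n)}  (|M_N|' = {sig.size_n_eff:g})",
            f"presence threshold: {sig.presence_threshold:g}",
            f"pseudo-count:       {sig.pseudo_count:g}",
            f"balanced accuracy:  chi = {self.chi:.3f}",
            f"  P(h>0 | healthy)    = {self.accuracy.proportion_h_correct:.3f}",
            f"  P(h<0 | nonhealthy) = {self.accuracy.proportion_n_correct:.3f}",
        ]
        return "\n".join(lines)

    def plot_grid(self, ax=None):
        """Heatmap of balanced accuracy over the threshold grid."""
        if self.grid is None:
            raise ValueError("model was fitted at fixed thresholds; no grid")
        import matplotlib.pyplot as plt

        pivot = self.grid.pivot(index="theta_f", columns="theta_d",
                                values="chi")
        if ax is None:
            _, ax = plt.subplots()
        im = ax.imshow(pivot.to_numpy(), origin="lower", aspect="auto",
                       cmap="viridis")
        ax.set_xticks(range(len(pivot.columns)),
                      [f"{v:g}" for v in pivot.columns])
        ax.set_yticks(range(len(pivot.index)),
                      [f"{v:g}" for v in pivot.index])
        ax.set_xlabel("theta_d (prevalence difference)")
        ax.set_ylabel("theta_f (prevalence fold change)")
        ax.figure.colorbar(im, ax=ax, label="balanced accuracy chi")
        return ax

    def plot_scores(self, ax=None):
        """Overlaid GMHI histograms for the two groups."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        groups = self.model.table.metadata["group"]
        h = self.scores.loc[(groups == "healthy").to_numpy(), "gmhi"]
        n = self.scores.loc[(groups == "nonhealthy").to_numpy(), "gmhi"]
        bins = np.histogram_bin_edges(self.scores["gmhi"], bins=40)
        ax.hist(h, bins=bins, alpha=0.6, label="healthy")
        ax.hist(n, bins=bins, alpha=0.6, label="nonhealthy")
        ax.axvline(0.0, color="k", lw=1)
        ax.set_xlabel("GMHI")
        ax.set_ylabel("samples")
        ax.legend()
        return ax
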