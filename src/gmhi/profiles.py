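"""Species-level relative-abundance tables and MetaPhlAn-style profile I/O.

The in-memory container is :class:`AbundanceTable`: a samples x features
matrix of proportions backed by a pandas DataFrame, plus a per-sample
metadata frame (phenotype, healthy/nonhealthy group, study, optional BMI).
All downstream computation assumes proportions that sum to 1 per sample;
MetaPhlAn percent output is converted at ingest.
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .lineage import CladeLineage, LineageError, is_unclassified_name, rank_letter

HEALTHY = "healthy"
NONHEALTHY = "nonhealthy"
UNASSIGNED = "unassigned"
GROUPS = (HEALTHY, NONHEALTHY, UNASSIGNED)

METADATA_COLUMNS = ("phenotype", "group", "study_id", "bmi")


class ProfileFormatError(ValueError):
    """Raised when a profile or table file violates the expected format."""


class Profile(dict):
    """Mapping feature name -> proportion for one sample.

    Behaves as a plain dict; ``lineages`` (feature name -> lineage string)
    rides along so that kingdom/unclassified information survives rank
    extraction.
    """

    def __init__(self, mapping: Mapping[str, float] | None = None,
                 lineages: Mapping[str, str] | None = None) -> None:
        super().__init__(mapping or {})
        self.lineages: dict[str, str] = dict(lineages or {})


class AbundanceTable:
    """Samples x features matrix of relative abundances with sample metadata.

    Parameters
    ----------
    data : pandas.DataFrame
        Rows are samples, columns are features; values are nonnegative
        proportions.
    metadata : pandas.DataFrame, optional
        Indexed by sample id. Recognized columns: ``phenotype``, ``group``
        (one of healthy/nonhealthy/unassigned), ``study_id``, ``bmi``.
        Missing columns are filled with defaults.
    feature_lineages : mapping, optional
        Feature name -> full lineage string, used by QC to recognize
        viral-kingdom and unclassified features.
    """

    def __init__(self, data: pd.DataFrame,
                 metadata: pd.DataFrame | None = None,
                 feature_lineages: Mapping[str, str] | None = None) -> None:
        if data.index.has_duplicates:
            raise ValueError("duplicate sample ids")
        if data.columns.has_duplicates:
            raise ValueError("duplicate feature ids")
        values = data.to_numpy(dtype=float)
        if values.size and (values < 0).any():
            bad = data.index[(values < 0).any(axis=1)][0]
            raise ValueError(f"negative abundance in sample {bad!r}")
        self.data = data.astype(float)
        self.metadata = self._init_metadata(metadata, data.index)
        self.feature_lineages = dict(feature_lineages or {})

    @staticmethod
    def _init_metadata(metadata: pd.DataFrame | None,
                       sample_index: pd.Index) -> pd.DataFrame:
        if metadata is None:
            metadata = pd.DataFrame(index=sample_index.copy())
        else:
            missing = sample_index.difference(metadata.index)
            if len(missing):
                raise ValueError(
                    f"samples missing from metadata: {list(missing)[:5]}")
            metadata = metadata.loc[sample_index].copy()
        defaults = {"phenotype": UNASSIGNED, "group": UNASSIGNED,
                    "study_id": "", "bmi": np.nan}
        for col, default in defaults.items():
            if col not in metadata.columns:
                metadata[col] = default
        bad = set(metadata["group"]) - set(GROUPS)
        if bad:
            raise ValueError(f"unknown group labels: {sorted(bad)}")
        return metadata

    # -- basic views ----------------------------------------------------
    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def group_samples(self, group: str) -> list[str]:
        return list(self.metadata.index[self.metadata["group"] == group])

    def unclassified_features(self) -> list[str]:
        """Features flagged as unknown/unclassified by name or lineage."""
        out = []
        for feat in self.data.columns:
            lin = self.feature_lineages.get(feat, "")
            if is_unclassified_name(feat) or is_unclassified_name(lin):
                out.append(feat)
        return out

    def viral_features(self) -> list[str]:
        return [f for f in self.data.columns
                if self.feature_lineages.get(f, "").startswith("k__Vir")]

    # -- manipulation ---------------------------------------------------
    def subset(self, samples: Sequence[str] | None = None,
               features: Sequence[str] | None = None) -> "AbundanceTable":
        data = self.data
        if samples is not None:
            data = data.loc[list(samples)]
        if features is not None:
            data = data[list(features)]
        lineages = {f: s for f, s in self.feature_lineages.items()
                    if f in data.columns}
        return AbundanceTable(data, self.metadata.loc[data.index], lineages)

    def normalized(self) -> "AbundanceTable":
        """Return a copy with each sample row renormalized to sum 1.

        Rows summing to zero are invalid and raise.
        """
        sums = self.data.sum(axis=1)
        zero = sums[sums == 0]
        if len(zero):
            raise ValueError(
                f"all-zero samples cannot be normalized: {list(zero.index)[:5]}")
        data = self.data.div(sums, axis=0)
        return AbundanceTable(data, self.metadata, self.feature_lineages)

    def is_normalized(self, atol: float = 1e-9) -> bool:
        sums = self.data.sum(axis=1).to_numpy()
        return bool(np.allclose(sums, 1.0, atol=atol, rtol=0.0))

    def with_metadata(self, metadata: pd.DataFrame) -> "AbundanceTable":
        return AbundanceTable(self.data, metadata, self.feature_lineages)

    def equals(self, other: "AbundanceTable", atol: float = 1e-12) -> bool:
        if self.data.shape != other.data.shape:
            return False
        if list(self.data.index) != list(other.data.index):
            return False
        if list(self.data.columns) != list(other.data.columns):
            return False
        if not np.allclose(self.data.to_numpy(), other.data.to_numpy(),
                           atol=atol, rtol=0.0):
            return False
        a, b = self.metadata, other.metadata
        for col in METADATA_COLUMNS:
            if col == "bmi":
                if not np.allclose(a[col].astype(float), b[col].astype(float),
                                   equal_nan=True, atol=atol, rtol=0.0):
                    return False
            elif not (a[col].astype(str) == b[col].astype(str)).all():
                return False
        return True


# ---------------------------------------------------------------------------
# single-sample MetaPhlAn-style profiles
# ---------------------------------------------------------------------------

def read_metaphlan_profile(path: str | Path, rank: str = "species") -> Profile:
    """Read a two-column MetaPhlAn-style profile and extract one rank.

    The file is tab-separated: column 1 a pipe-delimited clade lineage,
    column 2 a relative abundance. Lines starting with ``#`` are comments.
    Only clades whose *deepest* rank equals ``rank`` are kept (so species
    rows are not double counted through their strain children). Percent
    abundances (summing to ~100) are detected by column sum and converted
    to proportions.
    """
    letter = rank_letter(rank)
    path = Path(path)
    try:
        lines = path.read_text().splitlines()
    except OSError as exc:
        raise ProfileFormatError(f"cannot read profile {path}: {exc}") from exc

    values: dict[str, float] = {}
    lineages: dict[str, str] = {}
    for lineno, line in enumerate(lines, start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) < 2:
            raise ProfileFormatError(
                f"{path}:{lineno}: expected 2 tab-separated columns")
        clade, abundance_text = fields[0], fields[1]
        try:
            abundance = float(abundance_text)
        except ValueError:
            raise ProfileFormatError(
                f"{path}:{lineno}: non-numeric abundance {abundance_text!r}"
            ) from None
        if abundance < 0:
            raise ProfileFormatError(
                f"{path}:{lineno}: negative abundance {abundance}")
        if "__" not in clade:
            # rank-agnostic unresolved bucket (e.g. a bare UNKNOWN row):
            # retained at every rank so QC can compute unclassified fractions
            if is_unclassified_name(clade):
                values[clade] = values.get(clade, 0.0) + abundance
                lineages[clade] = clade
            continue
        try:
            lin = CladeLineage.parse(clade)
        except LineageError as exc:
            raise ProfileFormatError(f"{path}:{lineno}: {exc}") from exc
        if lin.deepest_rank != letter:
            continue
        name = lin.terminal_name
        values[name] = values.get(name, 0.0) + abundance
        lineages[name] = lin.serialize()

    if not values:
        raise ProfileFormatError(
            f"{path}: no rows at rank {rank!r}")
    total = sum(values.values())
    if total > 1.5:  # percent scale (MetaPhlAn prints ~100 per rank)
        values = {k: v / 100.0 for k, v in values.items()}
    return Profile(values, lineages)


def merge_profiles(profiles: Sequence[Mapping[str, float]],
                   sample_ids: Sequence[str],
                   metadata: pd.DataFrame | None = None) -> AbundanceTable:
    """Assemble per-sample mappings into one table over the feature union.

    Missing entries are zero; each row is renormalized to proportions.
    """
    if len(profiles) != len(sample_ids):
        raise ValueError("profiles and sample_ids differ in length")
    if len(set(sample_ids)) != len(sample_ids):
        raise ValueError("duplicate sample ids")
    features = sorted(set().union(*(p.keys() for p in profiles))) if profiles else []
    matrix = np.zeros((len(profiles), len(features)))
    index = {f: j for j, f in enumerate(features)}
    lineages: dict[str, str] = {}
    for i, prof in enumerate(profiles):
        for feat, value in prof.items():
            matrix[i, index[feat]] = value
        if isinstance(prof, Profile):
            lineages.update(prof.lineages)
    data = pd.DataFrame(matrix, index=list(sample_ids), columns=features)
    table = AbundanceTable(data, metadata, lineages)
    return table.normalized()


# ---------------------------------------------------------------------------
# merged-table round-trip I/O
# ---------------------------------------------------------------------------

def _metadata_path(path: Path) -> Path:
    return path.with_name(path.stem + ".metadata.tsv")


def write_table(table: AbundanceTable, path: str | Path,
                metadata_path: str | Path | None = None) -> None:
    """Write a merged table as TSV (features x samples) plus metadata TSV.

    Column 1 is the feature id; remaining columns are one per sample.
    Feature lineages, when known, are stored in a ``lineage`` column of a
    sidecar and restored on read.
    """
    if table.data.empty:
        raise ValueError("refusing to write an empty table")
    path = Path(path)
    frame = table.data.T
    frame.index.name = "feature_id"
    frame.to_csv(path, sep="\t")
    meta = table.metadata.copy()
    meta.index.name = "sample_id"
    mpath = Path(metadata_path) if metadata_path else _metadata_path(path)
    meta.to_csv(mpath, sep="\t")
    if table.feature_lineages:
        lin = pd.Series(table.feature_lineages, name="lineage")
        lin.index.name = "feature_id"
        lin.to_csv(path.with_name(path.stem + ".lineages.tsv"), sep="\t")


def read_table(path: str | Path,
               metadata_path: str | Path | None = None) -> AbundanceTable:
    """Read a merged feature x sample TSV written by :func:`write_table`."""
    path = Path(path)
    frame = pd.read_csv(path, sep="\t", index_col=0)
    if frame.empty:
        raise ProfileFormatError(f"{path}: empty table")
    data = frame.T
    data.index = data.index.astype(str)
    mpath = Path(metadata_path) if metadata_path else _metadata_path(path)
    metadata = None
    if mpath.exists():
        metadata = pd.read_csv(mpath, sep="\t", index_col=0)
        metadata.index = metadata.index.astype(str)
    lpath = path.with_name(path.stem + ".lineages.tsv")
    lineages = None
    if lpath.exists():
        lin = pd.read_csv(lpath, sep="\t", index_col=0)
        lineages = lin["lineage"].to_dict()
    return AbundanceTable(data, metadata, lineages)
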