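"""The Gut Microbiome Health Index: collective abundances and the log-ratio score.

For a species set M and sample i with proportions n_j, the collective
abundance is

    psi_{M,i} = (R_{M,i} / |M|') * sum_{j in M, present} |n_j ln n_j|

where R_{M,i} counts the set's species present at or above the presence
threshold (default 1e-5) and |M|' is the *effective* set size: the median
within-set richness among the samples ranked most extreme by the
(R_N ascending, R_H descending) two-key sort, taken over the closest
integer to 1% of each group. The index is

    h = log10((psi_H + eps) / (psi_N + eps))

with a small symmetric pseudo-count eps keeping h finite when one set is
entirely absent (eps = 0 restores the literal ratio). h > 0 classifies a
sample as healthy, h < 0 as nonhealthy, h = 0 as neither.
"""

from __future__ import annotations

import hashlib
import logging
import math
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .profiles import AbundanceTable, HEALTHY, NONHEALTHY

logger = logging.getLogger("gmhi")

DEFAULT_PRESENCE_THRESHOLD = 1e-5
DEFAULT_PSEUDO_COUNT = 1e-5

LABEL_HEALTHY = "healthy"
LABEL_NONHEALTHY = "nonhealthy"
LABEL_NEITHER = "neither"

#: sha256 of the packaged 50-species signature file (integrity check)
_TABLE2_SHA256 = "7e0288abd9af0f2635dbf0d04458e204e88dbe3961ece4cbf33e0af93d6dbf46"
_TABLE2_RESOURCE = "gmhi_table2.tsv"


def normalize_species_name(name: str) -> str:
    """Map a display species name onto its MetaPhlAn-style ``s__`` form.

    Spaces, slashes (composite names such as
    ``Streptococcus mitis/oralis/pneumoniae``) and the dot in ``sp.``
    become underscores.
    """
    out = name.replace("/", " ").replace(".", "")
    return "_".join(out.split())


@dataclass
class GmhiSignature:
    """A fitted health-prevalent / health-scarce species model.

    ``size_h_eff`` and ``size_n_eff`` are the effective set sizes |M_H|'
    and |M_N|' substituted for the cardinalities in psi.
    """

    m_h: list
    m_n: list
    theta_f: float
    theta_d: float
    size_h_eff: float
    size_n_eff: float
    presence_threshold: float = DEFAULT_PRESENCE_THRESHOLD
    pseudo_count: float = DEFAULT_PSEUDO_COUNT
    provenance: str = ""
    prevalence: pd.DataFrame | None = None  # species, group, p_H, p_N (percent)

    def __post_init__(self) -> None:
        overlap = set(self.m_h) & set(self.m_n)
        if overlap:
            raise ValueError(f"species in both sets: {sorted(overlap)[:3]}")
        if not (0 < self.size_h_eff <= len(self.m_h)):
            raise ValueError("size_h_eff must be in (0, |M_H|]")
        if not (0 < self.size_n_eff <= len(self.m_n)):
            raise ValueError("size_n_eff must be in (0, |M_N|]")
        if self.pseudo_count < 0:
            raise ValueError("pseudo_count must be nonnegative")

    def swapped(self) -> "GmhiSignature":
        """Exchange the two species sets (and their effective sizes)."""
        return GmhiSignature(
            list(self.m_n), list(self.m_h), self.theta_f, self.theta_d,
            self.size_n_eff, self.size_h_eff, self.presence_threshold,
            self.pseudo_count, self.provenance + " (swapped)")

    # -- TSV round trip -------------------------------------------------
    def to_tsv(self, path: str | Path) -> None:
        path = Path(path)
        prev = self.prevalence
        lines = [
            f"#theta_f: {self.theta_f}",
            f"#theta_d: {self.theta_d}",
            f"#size_H_eff: {self.size_h_eff}",
            f"#size_N_eff: {self.size_n_eff}",
            f"#presence_threshold: {self.presence_threshold}",
            f"#pseudo_count: {self.pseudo_count}",
            f"#provenance: {self.provenance}",
            "species\tgroup\tp_H\tp_N",
        ]
        for group, species_list in (("H+", self.m_h), ("H-", self.m_n)):
            for sp in species_list:
                p_h = p_n = ""
                if prev is not None and sp in prev.index:
                    p_h, p_n = prev.loc[sp, "p_H"], prev.loc[sp, "p_N"]
                lines.append(f"{sp}\t{group}\t{p_h}\t{p_n}")
        path.write_text("\n".join(lines) + "\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "GmhiSignature":
        text = Path(path).read_text()
        return cls._from_text(text)

    @classmethod
    def _from_text(cls, text: str) -> "GmhiSignature":
        header: dict[str, str] = {}
        rows = []
        columns: list[str] | None = None
        for line in text.splitlines():
            if not line.strip():
                continue
            if line.startswith("#"):
                key, _, value = line[1:].partition(":")
                header[key.strip()] = value.strip()
            elif columns is None:
                columns = line.split("\t")
            else:
                rows.append(line.split("\t"))
        frame = pd.DataFrame(rows, columns=columns)
        m_h = list(frame.loc[frame["group"] == "H+", "species"])
        m_n = list(frame.loc[frame["group"] == "H-", "species"])
        prev = frame.set_index("species")[["p_H", "p_N"]].apply(
            pd.to_numeric, errors="coerce")
        prev["group"] = frame.set_index("species")["group"]
        return cls(
            m_h, m_n,
            theta_f=float(header.get("theta_f", "nan")),
            theta_d=float(header.get("theta_d", "nan")),
            size_h_eff=float(header["size_H_eff"]),
            size_n_eff=float(header["size_N_eff"]),
            presence_threshold=float(
                header.get("presence_threshold", DEFAULT_PRESENCE_THRESHOLD)),
            pseudo_count=float(
                header.get("pseudo_count", DEFAULT_PSEUDO_COUNT)),
            provenance=header.get("provenance", ""),
            prevalence=prev,
        )


@dataclass
class SampleScore:
    """Per-sample GMHI result."""

    sample_id: str
    r_h: int
    r_n: int
    psi_h: float
    psi_n: float
    h: float
    label: str


def collective_abundance(
    sample: Mapping[str, float],
    species_set: Sequence[str],
    effective_size: float,
    presence_threshold: float = DEFAULT_PRESENCE_THRESHOLD,
) -> tuple[float, int]:
    """Return (psi, R) for one sample and one species set.

    R counts set species whose abundance is at or above the presence
    threshold; only those contribute their |n ln n| terms.
    """
    if effective_size <= 0:
        raise ValueError("effective_size must be positive")
    total = 0.0
    richness = 0
    for sp in species_set:
        n = sample.get(sp, 0.0)
        if n >= presence_threshold:
            richness += 1
            total += abs(n * math.log(n))
    return (richness / effective_size) * total, richness


def k_extreme(group_size: int, fraction: float = 0.01) -> int:
    """Closest integer (half away from zero) to ``fraction`` of a group, min 1."""
    if group_size <= 0:
        raise ValueError("group must be nonempty")
    return max(1, int(math.floor(group_size * fraction + 0.5)))


def set_richness(table: AbundanceTable, species_set: Sequence[str],
                 presence_threshold: float = DEFAULT_PRESENCE_THRESHOLD,
                 ) -> np.ndarray:
    """Within-set richness R for every sample (vectorized)."""
    present_cols = [s for s in species_set if s in table.data.columns]
    if not present_cols:
        return np.zeros(len(table.data), dtype=int)
    vals = table.data[present_cols].to_numpy()
    return (vals >= presence_threshold).sum(axis=1)


@dataclass
class EffectiveSizes:
    size_h_eff: float
    size_n_eff: float
    k_h: int
    k_n: int
    rank_order: list = field(default_factory=list, repr=False)


def estimate_effective_set_sizes(
    table: AbundanceTable,
    m_h: Sequence[str],
    m_n: Sequence[str],
    presence_threshold: float = DEFAULT_PRESENCE_THRESHOLD,
    fallback_to_cardinality: bool = False,
) -> EffectiveSizes:
    """Estimate |M_H|' and |M_N|' from the two-key extreme-sample ranking.

    All healthy and nonhealthy samples are ranked by R_{M_N} ascending
    then R_{M_H} descending (stable for residual ties, which are broken by
    input order). |M_H|' is the median R_{M_H} of the top k_H samples and
    |M_N|' the median R_{M_N} of the bottom k_N, where k is the closest
    integer to 1% of the respective group size (floor 1).
    """
    h_samples = table.group_samples(HEALTHY)
    n_samples = table.group_samples(NONHEALTHY)
    if not h_samples or not n_samples:
        raise ValueError("both healthy and nonhealthy groups must be nonempty")
    if not len(m_h) or not len(m_n):
        raise ValueError("both species sets must be nonempty")
    pool = [s for s in table.sample_ids
            if s in set(h_samples) | set(n_samples)]
    sub = table.subset(samples=pool)
    r_h = set_richness(sub, m_h, presence_threshold)
    r_n = set_richness(sub, m_n, presence_threshold)
    # primary key R_N ascending, secondary R_H descending; lexsort is stable
    order = np.lexsort((-r_h, r_n))
    k_h = k_extreme(len(h_samples))
    k_n = k_extreme(len(n_samples))
    size_h = float(np.median(r_h[order[:k_h]]))
    size_n = float(np.median(r_n[order[-k_n:]]))
    if size_h == 0 or size_n == 0:
        if fallback_to_cardinality:
            size_h = size_h or float(len(m_h))
            size_n = size_n or float(len(m_n))
        else:
            raise ValueError(
                "degenerate data: median extreme richness is 0; consider "
                "fallback_to_cardinality=True to use |M| instead")
    return EffectiveSizes(size_h, size_n, k_h, k_n,
                          rank_order=[pool[i] for i in order])


def _h_from_psi(psi_h: float, psi_n: float, eps: float) -> float:
    num, den = psi_h + eps, psi_n + eps
    if den == 0.0 and num == 0.0:
        warnings.warn("both collective abundances are zero; h defined as 0")
        return 0.0
    if den == 0.0:
        warnings.warn("psi_N = 0 with pseudo_count 0; h is +inf")
        return math.inf
    if num == 0.0:
        warnings.warn("psi_H = 0 with pseudo_count 0; h is -inf")
        return -math.inf
    return math.log10(num / den)


def _label(h: float) -> str:
    if h > 0:
        return LABEL_HEALTHY
    if h < 0:
        return LABEL_NONHEALTHY
    return LABEL_NEITHER


def gmhi_score(sample: Mapping[str, float], signature: GmhiSignature,
               sample_id: str = "") -> SampleScore:
    """Score one sample (mapping species -> proportion) against a signature."""
    psi_h, r_h = collective_abundance(
        sample, signature.m_h, signature.size_h_eff,
        signature.presence_threshold)
    psi_n, r_n = collective_abundance(
        sample, signature.m_n, signature.size_n_eff,
        signature.presence_threshold)
    h = _h_from_psi(psi_h, psi_n, signature.pseudo_count)
    return SampleScore(sample_id, r_h, r_n, psi_h, psi_n, h, _label(h))


def score_table(table: AbundanceTable,
                signature: GmhiSignature) -> pd.DataFrame:
    """Score every sample; returns a frame indexed by sample id.

    Signature species absent from the table contribute abundance 0; the
    count of such species is logged. Table columns are matched first by
    exact name, then by MetaPhlAn-style normalized name.
    """
    colmap = {c: c for c in table.data.columns}
    normmap = {normalize_species_name(c): c for c in table.data.columns}

    def resolve(species: Sequence[str]) -> tuple[list[str], int]:
        cols, missing = [], 0
        for sp in species:
            if sp in colmap:
                cols.append(sp)
            elif normalize_species_name(sp) in normmap:
                cols.append(normmap[normalize_species_name(sp)])
            else:
                missing += 1
        return cols, missing

    cols_h, miss_h = resolve(signature.m_h)
    cols_n, miss_n = resolve(signature.m_n)
    if miss_h or miss_n:
        logger.warning(
            "signature species absent from table treated as 0: "
            "%d of %d health-prevalent, %d of %d health-scarce",
            miss_h, len(signature.m_h), miss_n, len(signature.m_n))
    if not cols_h and not cols_n:
        warnings.warn("table contains none of the signature species; "
                      "all scores are 0")

    thr = signature.presence_threshold
    eps = signature.pseudo_count

    def psi_block(cols: list[str], eff: float) -> tuple[np.ndarray, np.ndarray]:
        if not cols:
            n = len(table.data)
            return np.zeros(n), np.zeros(n, dtype=int)
        vals = table.data[cols].to_numpy()
        present = vals >= thr
        safe = np.where(present, vals, 1.0)
        contrib = np.where(present, np.abs(safe * np.log(safe)), 0.0)
        r = present.sum(axis=1)
        return (r / eff) * contrib.sum(axis=1), r

    psi_h, r_h = psi_block(cols_h, signature.size_h_eff)
    psi_n, r_n = psi_block(cols_n, signature.size_n_eff)
    with np.errstate(divide="ignore"):
        h = np.array([_h_from_psi(a, b, eps) for a, b in zip(psi_h, psi_n)])
    labels = [_label(x) for x in h]
    return pd.DataFrame(
        {"R_H": r_h, "R_N": r_n, "psi_H": psi_h, "psi_N": psi_n,
         "gmhi": h, "label": labels},
        index=pd.Index(table.sample_ids, name="sample_id"))


def scores_to_tsv(scores: pd.DataFrame, path: str | Path) -> None:
    scores.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# packaged 50-species model
# ---------------------------------------------------------------------------

def load_packaged_signature(name: str = "GMHI-Table2",
                            size_h_eff: float | None = None,
                            size_n_eff: float | None = None,
                            ) -> GmhiSignature:
    """Load the packaged 50-species signature (7 health-prevalent, 43
    health-scarce) discovered at theta_f = 1.4, theta_d = 0.10.

    The effective set sizes |M_H|' and |M_N|' of the published model were
    never released, so they must be supplied (from training data or a
    comparable cohort); when omitted they default to the set cardinalities
    — the literal, unadjusted ratio — with a warning.
    """
    if name != "GMHI-Table2":
        raise ValueError(f"unknown packaged signature {name!r}")
    text = (resources.files("gmhi") / "data" / _TABLE2_RESOURCE).read_text()
    digest = hashlib.sha256(text.encode()).hexdigest()
    if digest != _TABLE2_SHA256:
        raise ValueError(
            f"packaged signature checksum mismatch: {digest}")
    sig = GmhiSignature._from_text(text)
    if size_h_eff is None or size_n_eff is None:
        warnings.warn(
            "effective set sizes for the packaged model are not published; "
            "defaulting to set cardinalities (|M_H|=7, |M_N|=43). Supply "
            "size_h_eff/size_n_eff estimated from training data for the "
            "size-adjusted index.")
    sig.size_h_eff = size_h_eff if size_h_eff is not None else float(len(sig.m_h))
    sig.size_n_eff = size_n_eff if size_n_eff is not None else float(len(sig.m_n))
    return sig
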