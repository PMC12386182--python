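"""Condition-level profiles, clustering, and the condition taxonomy.

Replicate libraries are aggregated to per-condition mean CPM profiles
(linear scale).  Conditions are compared by 1 - |Pearson r| over genes
above a mean-expression floor and clustered by UPGMA (average linkage).
Each condition also receives categorical labels:

* duration: short (<= 90 min), medium (2-16 h), long_days (1-3 days),
  plus a two-way split at 90 min / 2 h used throughout the meta-analysis
  (durations falling in the 90 min - 2 h gap join the long group);
* intensity: moderate / intensive / severe high light, with cut points
  950 and 1500 umol m-2 s-1 bisecting the gaps between the published
  ranges 500-900, 1000-1330 and 1700-2000;
* plant age: juvenile (< 21 d), mature (21-30 d), old (> 30 d).

Note that 1 - |r| is not a metric (no triangle inequality); UPGMA does
not require one.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform
from skbio.tree import TreeNode

from lightmeta.config import PipelineConfig
from lightmeta.datamodel import CountStudy, ValidationError
from lightmeta.de import cpm

log = logging.getLogger("lightmeta")


@dataclass
class ConditionProfile:
    """Mean linear-CPM expression of one condition plus its labels."""

    condition_id: str
    mean_cpm: np.ndarray
    tissue: str
    is_control: bool
    duration_group: str      # short / medium / long_days / control
    two_way_group: str       # short / long / control
    intensity_group: str     # moderate / intensive / severe / control
    age_group: str           # juvenile / mature / old
    n_replicates: int


@dataclass
class Dendrogram:
    """UPGMA merge tree over condition profiles.

    ``merges`` lists n-1 rows ``(left, right, height, size)`` in scipy
    linkage convention (nodes >= n are earlier merges); ``leaves`` gives
    the input labels in original order.
    """

    merges: np.ndarray
    leaves: list[str]

    def __post_init__(self) -> None:
        heights = self.merges[:, 2]
        if np.any(np.diff(heights) < -1e-12):
            raise ValidationError("merge heights must be non-decreasing")

    def merge_sets(self) -> list[tuple[frozenset[int], float]]:
        """Each merge as (set of member leaf indices, height) - convenient
        for order-insensitive comparison against reference implementations."""
        n = len(self.leaves)
        members: dict[int, frozenset[int]] = {i: frozenset([i]) for i in range(n)}
        out = []
        for i, (a, b, h, _size) in enumerate(self.merges):
            merged = members[int(a)] | members[int(b)]
            members[n + i] = merged
            out.append((merged, float(h)))
        return out

    def first_split_partition(self) -> tuple[set[str], set[str]]:
        """Leaf-label bipartition induced by the root (last) merge."""
        n = len(self.leaves)
        sets = self.merge_sets()
        a, b = int(self.merges[-1, 0]), int(self.merges[-1, 1])

        def leafset(node: int) -> set[str]:
            if node < n:
                return {self.leaves[node]}
            return {self.leaves[i] for i in sets[node - n][0]}

        return leafset(a), leafset(b)

    def to_newick(self) -> str:
        """Newick string with branch lengths from merge heights."""
        tree = TreeNode.from_linkage_matrix(self.merges, self.leaves)
        return str(tree).strip()


# ---------------------------------------------------------------------------
# taxonomy
# ---------------------------------------------------------------------------

def classify_condition(
    duration_min: float,
    intensity_ppfd: float,
    age_days: float,
    tissue: str,
    is_control: bool = False,
    config: PipelineConfig | None = None,
) -> dict[str, str]:
    """Categorical labels for one condition (deterministic in metadata)."""
    cfg = config or PipelineConfig()
    if is_control:
        duration_group = two_way = intensity_group = "control"
    else:
        if duration_min <= 0:
            raise ValidationError("stress conditions must have duration > 0")
        if duration_min <= cfg.short_max_min:
            duration_group = "short"
        elif duration_min < cfg.long_days_min_min:
            # 90 min - 2 h gap joins the long side of the two-way split
            duration_group = "medium"
        else:
            duration_group = "long_days"
        two_way = "short" if duration_min <= cfg.short_max_min else "long"
        if intensity_ppfd < cfg.intensity_moderate_min:
            log.warning(
                "condition intensity %.6g is below the high-light definition (%g)",
                intensity_ppfd, cfg.intensity_moderate_min,
            )
            intensity_group = "moderate"
        elif intensity_ppfd < cfg.intensity_intensive_min:
            intensity_group = "moderate"
        elif intensity_ppfd < cfg.intensity_severe_min:
            intensity_group = "intensive"
        else:
            intensity_group = "severe"
    if age_days < cfg.age_mature_min:
        age_group = "juvenile"
    elif age_days <= cfg.age_mature_max:
        age_group = "mature"
    else:
        age_group = "old"
    return {
        "duration_group": duration_group,
        "two_way_group": two_way,
        "intensity_group": intensity_group,
        "age_group": age_group,
        "tissue": tissue,
    }


# ---------------------------------------------------------------------------
# aggregation and clustering
# ---------------------------------------------------------------------------

def aggregate_condition_cpm(
    study: CountStudy,
    factors: np.ndarray | None = None,
    config: PipelineConfig | None = None,
) -> list[ConditionProfile]:
    """Per-condition arithmetic mean of replicate CPM values (linear scale)."""
    lib = study.library_sizes()
    if np.any(lib == 0):
        bad = study.sample_ids[int(np.argmax(lib == 0))]
        raise ValidationError(f"library size of sample {bad!r} is 0")
    cpm_mat = cpm(study.counts, lib, factors)
    profiles = []
    for cond in study.conditions():
        members = study.condition_samples(cond)
        idx = [study.sample_ids.index(s.sample_id) for s in members]
        ref = members[0]
        labels = classify_condition(
            ref.duration_min, ref.intensity_ppfd, ref.age_days, ref.tissue,
            is_control=ref.is_control, config=config,
        )
        profiles.append(ConditionProfile(
            condition_id=cond,
            mean_cpm=cpm_mat[:, idx].mean(axis=1),
            is_control=ref.is_control,
            n_replicates=len(idx),
            **labels,
        ))
    return profiles


def correlation_dissimilarity(
    profiles: Sequence[ConditionProfile],
    min_mean_cpm: float = 3.0,
    log_scale: bool = False,
) -> pd.DataFrame:
    """Symmetric 1 - |Pearson r| matrix over expressed genes.

    Genes enter the correlation when their mean CPM across all profiles
    is at least ``min_mean_cpm``.  Correlations run on linear CPM by
    default (dominated by abundant transcripts, but the published
    convention); ``log_scale`` switches to log2(CPM + 1).
    """
    if len(profiles) < 2:
        raise ValidationError("need >= 2 condition profiles")
    mat = np.vstack([p.mean_cpm for p in profiles])
    keep = mat.mean(axis=0) >= min_mean_cpm
    if keep.sum() < 2:
        raise ValidationError("fewer than 2 genes pass the mean-CPM filter")
    sub = np.log2(mat[:, keep] + 1.0) if log_scale else mat[:, keep]
    sd = sub.std(axis=1)
    flat = np.flatnonzero(sd == 0)
    if flat.size:
        raise ValidationError(
            f"condition {profiles[int(flat[0])].condition_id!r} has zero expression variance"
        )
    r = np.corrcoef(sub)
    d = 1.0 - np.abs(r)
    np.fill_diagonal(d, 0.0)
    d = np.clip(d, 0.0, 1.0)
    ids = [p.condition_id for p in profiles]
    return pd.DataFrame(d, index=ids, columns=ids)


def upgma(dissimilarity: pd.DataFrame | np.ndarray, leaves: Sequence[str] | None = None) -> Dendrogram:
    """Average-linkage (UPGMA) agglomeration of a dissimilarity matrix.

    Merge heights are the unweighted mean pairwise distance between the
    merged clusters' members (no height halving).
    """
    if isinstance(dissimilarity, pd.DataFrame):
        labels = list(dissimilarity.columns) if leaves is None else list(leaves)
        mat = dissimilarity.to_numpy(dtype=float)
    else:
        mat = np.asarray(dissimilarity, dtype=float)
        labels = list(leaves) if leaves is not None else [str(i) for i in range(mat.shape[0])]
    if np.any(np.isnan(mat)):
        raise ValidationError("dissimilarity matrix contains NaN")
    if mat.shape[0] != mat.shape[1] or not np.allclose(mat, mat.T, atol=1e-12):
        raise ValidationError("dissimilarity matrix must be square and symmetric")
    if not np.allclose(np.diag(mat), 0.0, atol=1e-12):
        raise ValidationError("dissimilarity diagonal must be zero")
    merges = linkage(squareform(mat, checks=False), method="average")
    return Dendrogram(merges=merges, leaves=labels)


def group_correlation_summary(
    profiles: Sequence[ConditionProfile],
    min_mean_cpm: float = 3.0,
) -> pd.DataFrame:
    """Pearson correlation between aggregated group-mean profiles.

    Groups are control plus tissue x two-way duration group (e.g.
    ``leaf_short``); empty groups are omitted with a warning.  Each
    group profile is the mean of its member condition profiles.
    """
    groups: dict[str, list[np.ndarray]] = {}
    for p in profiles:
        key = f"{p.tissue}_control" if p.is_control else f"{p.tissue}_{p.two_way_group}"
        groups.setdefault(key, []).append(p.mean_cpm)
    names = sorted(groups)
    mat = np.vstack([np.mean(groups[g], axis=0) for g in names])
    keep = mat.mean(axis=0) >= min_mean_cpm
    if keep.sum() < 2:
        raise ValidationError("fewer than 2 genes pass the mean-CPM filter")
    r = np.corrcoef(mat[:, keep])
    r = np.atleast_2d(r)
    return pd.DataFrame(r, index=names, columns=names)
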