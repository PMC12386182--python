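"""Cross-condition vote counting and temporal classification of DEGs.

The meta-analytic statistic is the per-gene *frequency profile*: in how
many short-duration conditions (and how many long-duration ones) a gene
was called up- or downregulated, as a fraction of the group size.  On
top of it sit

* the frequent-DEG selection (detected in at least half of all
  conditions, split by the sign of the median log2FC),
* the four temporal categories (upper quartile of detection frequency
  in short-up / short-down / long-up / long-down),
* combined-pattern labels for genes in two categories ("frequent" for
  three or more),
* consistency-based robust gene selection (>= 50% of a group's
  conditions in one direction; >= 80% for transcription factors).
"""

from __future__ import annotations

import logging
import math
from collections import Counter
from dataclasses import dataclass, field
from statistics import median
from typing import Mapping, Sequence

import numpy as np

from lightmeta.datamodel import GeneAnnotation, ValidationError
from lightmeta.de import DEGRecord

GROUPS = ("short", "long")
DIRECTIONS = ("up", "down")
CATEGORIES = ("short_up", "short_down", "long_up", "long_down")

_PAIR_LABELS = {
    frozenset({"short_up", "long_up"}): "short-long upregulated",
    frozenset({"short_down", "long_down"}): "short-long downregulated",
    frozenset({"short_up", "short_down"}): "short upregulated-downregulated",
    frozenset({"short_down", "long_up"}): "short downregulated-long upregulated",
    frozenset({"short_up", "long_down"}): "short upregulated-long downregulated",
    frozenset({"long_up", "long_down"}): "long upregulated-downregulated",
}

_SINGLE_LABELS = {
    "short_up": "short upregulated",
    "short_down": "short downregulated",
    "long_up": "long upregulated",
    "long_down": "long downregulated",
}


@dataclass
class FrequencyProfile:
    """Occurrence of one gene as a DEG across grouped conditions."""

    gene_id: str
    n_conditions_detected: int
    counts: dict[tuple[str, str], int]       # (group, direction) -> #conditions
    freq: dict[tuple[str, str], float]       # counts / group size
    logfc_values: list[float]                # log2FC where the gene was a DEG
    median_lfc: float


@dataclass
class CategoryAssignment:
    gene_id: str
    categories: frozenset[str]
    pattern_label: str


def pattern_label(categories: frozenset[str]) -> str:
    if len(categories) == 1:
        return _SINGLE_LABELS[next(iter(categories))]
    if len(categories) == 2:
        return _PAIR_LABELS[categories]
    return "frequent"


def deg_frequency(
    deg_records: Sequence[DEGRecord],
    condition_groups: Mapping[str, str],
    min_condition_count: int = 5,
) -> list[FrequencyProfile]:
    """Per-gene frequency profiles over short/long condition groups.

    ``condition_groups`` maps every stress condition id to ``short`` or
    ``long``.  Genes detected (any direction, any group) in fewer than
    ``min_condition_count`` conditions are excluded.
    """
    group_sizes = Counter(condition_groups.values())
    for g in GROUPS:
        if group_sizes[g] < 1:
            raise ValidationError(f"condition group {g!r} is empty")

    per_gene: dict[str, list[DEGRecord]] = {}
    for rec in deg_records:
        if rec.direction not in DIRECTIONS:
            continue
        if rec.condition_id not in condition_groups:
            continue
        per_gene.setdefault(rec.gene_id, []).append(rec)

    out: list[FrequencyProfile] = []
    for gene, recs in per_gene.items():
        detected = {r.condition_id for r in recs}
        if len(detected) < min_condition_count:
            continue
        counts = {(g, d): 0 for g in GROUPS for d in DIRECTIONS}
        lfcs = []
        for r in recs:
            counts[(condition_groups[r.condition_id], r.direction)] += 1
            lfcs.append(r.logFC)
        freq = {k: counts[k] / group_sizes[k[0]] for k in counts}
        out.append(FrequencyProfile(
            gene_id=gene,
            n_conditions_detected=len(detected),
            counts=counts,
            freq=freq,
            logfc_values=lfcs,
            median_lfc=float(median(lfcs)),
        ))
    return out


def most_frequent_degs(
    profiles: Sequence[FrequencyProfile],
    total_conditions: int,
    min_fraction: float = 0.5,
    lfc_cut: float = 0.5,
) -> tuple[set[str], set[str], set[str]]:
    """Frequent DEGs split by median log2FC sign.

    A gene qualifies when detected in at least
    ``ceil(min_fraction * total_conditions)`` conditions; it is
    upregulated when its median log2FC over detected conditions is
    >= ``lfc_cut``, downregulated when <= -``lfc_cut``, else
    unclassified.
    """
    if total_conditions <= 0:
        raise ValidationError("total_conditions must be positive")
    need = math.ceil(min_fraction * total_conditions)
    up: set[str] = set()
    down: set[str] = set()
    other: set[str] = set()
    for p in profiles:
        if p.n_conditions_detected < need:
            continue
        if p.median_lfc >= lfc_cut:
            up.add(p.gene_id)
        elif p.median_lfc <= -lfc_cut:
            down.add(p.gene_id)
        else:
            other.add(p.gene_id)
    return up, down, other


def top_quartile_categories(
    profiles: Sequence[FrequencyProfile],
    quartile: float = 0.75,
    nonzero_only: bool = True,
) -> list[CategoryAssignment]:
    """Upper-quartile-by-frequency membership in the four temporal categories.

    For each (group, direction) category the threshold is the
    ``quartile`` quantile (linear interpolation) of that category's
    frequencies - by default among genes with nonzero frequency there,
    so that sparse categories do not collapse to a zero threshold.
    Genes at or above the threshold enter the category; the pattern
    label summarises multi-category membership.
    """
    assignments: dict[str, set[str]] = {}
    for cat in CATEGORIES:
        group, direction = cat.rsplit("_", 1)
        freqs = np.array([p.freq[(group, direction)] for p in profiles])
        pool = freqs[freqs > 0] if nonzero_only else freqs
        if pool.size == 0:
            logging.getLogger("lightmeta").warning(
                "category %s has no nonzero frequencies; left empty", cat
            )
            continue
        threshold = float(np.quantile(pool, quartile))
        for p, f in zip(profiles, freqs):
            if f > 0 and f >= threshold:
                assignments.setdefault(p.gene_id, set()).add(cat)
    return [
        CategoryAssignment(gene_id=g, categories=frozenset(cats),
                           pattern_label=pattern_label(frozenset(cats)))
        for g, cats in sorted(assignments.items())
    ]


def robust_consistency_selection(
    profiles: Sequence[FrequencyProfile],
    annotation: Mapping[str, GeneAnnotation],
    group: str,
    fraction: float = 0.5,
    tf_fraction: float = 0.8,
) -> tuple[set[str], set[str]]:
    """Genes consistently up (or down) in at least a fraction of a group.

    Transcription factors face the stricter ``tf_fraction``.  When both
    directions reach the threshold (possible only at fraction <= 0.5),
    the gene goes to the side with the larger frequency; an exact tie
    excludes it.
    """
    if group not in GROUPS:
        raise ValidationError(f"group must be one of {GROUPS}, got {group!r}")
    up: set[str] = set()
    down: set[str] = set()
    for p in profiles:
        ann = annotation.get(p.gene_id)
        need = tf_fraction if (ann is not None and ann.is_tf) else fraction
        f_up = p.freq[(group, "up")]
        f_down = p.freq[(group, "down")]
        qual_up = f_up >= need
        qual_down = f_down >= need
        if qual_up and qual_down:
            if f_up > f_down:
                up.add(p.gene_id)
            elif f_down > f_up:
                down.add(p.gene_id)
            # exact tie: excluded from both
        elif qual_up:
            up.add(p.gene_id)
        elif qual_down:
            down.add(p.gene_id)
    return up, down


def venn_partition(
    assignments: Sequence[CategoryAssignment],
) -> dict[frozenset[str], int]:
    """Exact partition counts over the 4-set intersection lattice.

    Keys are the non-empty category combinations that occur; values
    count genes whose membership equals exactly that combination, so
    the values sum to the number of genes in at least one category.
    """
    out: dict[frozenset[str], int] = {}
    for a in assignments:
        if a.categories:
            out[a.categories] = out.get(a.categories, 0) + 1
    return out
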