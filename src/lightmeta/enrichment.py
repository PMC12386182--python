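"""Hypergeometric GO over-representation with BH q-values.

The universe is restricted to genes carrying at least one GO term
(typically: all genes that passed the expression filter and are
annotated).  For each term with a nonzero overlap with the target set,
the p-value is the upper hypergeometric tail P(X >= overlap) with
population size |universe|, ``term_size`` successes and |target| draws.
q-values are Benjamini-Hochberg adjusted p-values across all tested
terms.  The GO mapping is used flat, exactly as loaded - no ancestor
propagation along the GO graph (supply a pre-propagated mapping to
emulate tools that propagate internally).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.stats import hypergeom

from lightmeta.datamodel import ValidationError
from lightmeta.de import bh_adjust


@dataclass
class EnrichmentResult:
    term_id: str
    term_size: int          # annotated genes in the universe
    overlap: int            # term genes in the target set
    target_size: int
    pvalue: float
    qvalue: float
    representation: float   # overlap / target_size
    genes: tuple[str, ...] = ()


def _invert(term_map: Mapping[str, Iterable[str]], universe: set[str]) -> dict[str, set[str]]:
    by_term: dict[str, set[str]] = {}
    for gene, terms in term_map.items():
        if gene not in universe:
            continue
        for t in terms:
            by_term.setdefault(t, set()).add(gene)
    return by_term


def hypergeom_enrichment(
    target: Iterable[str],
    universe: Iterable[str],
    term_map: Mapping[str, Iterable[str]],
) -> list[EnrichmentResult]:
    """Upper-tail hypergeometric over-representation of GO terms.

    ``term_map`` maps gene -> GO terms.  Genes in the universe without
    terms are dropped from the universe; the target must be a subset of
    the (annotated) universe.  Terms absent from the target are
    skipped.
    """
    annotated = {g for g in universe if term_map.get(g)}
    target_set = set(target)
    if not target_set:
        return []
    stray = sorted(target_set - annotated)
    if stray:
        raise ValidationError(
            f"target genes outside the annotated universe: {stray[:10]}"
            + ("..." if len(stray) > 10 else "")
        )
    by_term = _invert(term_map, annotated)
    m = len(annotated)
    n_draw = len(target_set)

    rows = []
    for term, members in sorted(by_term.items()):
        hits = members & target_set
        if not hits:
            continue
        k = len(hits)
        p = float(hypergeom.sf(k - 1, m, len(members), n_draw))
        rows.append((term, len(members), k, min(1.0, p), tuple(sorted(hits))))
    if not rows:
        return []
    qvals = bh_adjust([r[3] for r in rows])
    return [
        EnrichmentResult(
            term_id=term,
            term_size=size,
            overlap=k,
            target_size=n_draw,
            pvalue=p,
            qvalue=float(q),
            representation=k / n_draw,
            genes=hit_genes,
        )
        for (term, size, k, p, hit_genes), q in zip(rows, qvals)
    ]


def filter_enriched(
    results: Sequence[EnrichmentResult],
    q_max: float = 1e-5,
    representation_min: float = 0.03,
) -> list[EnrichmentResult]:
    """Significance and representation gates, sorted by descending overlap.

    A term passes when q-value <= ``q_max`` *and* its representation
    (overlap as a fraction of the target set) is >= ``representation_min``;
    both comparisons are inclusive.
    """
    kept = [
        r for r in results
        if r.qvalue <= q_max and r.representation >= representation_min
    ]
    return sorted(kept, key=lambda r: (-r.overlap, r.qvalue, r.term_id))
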