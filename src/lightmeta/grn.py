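"""Consensus gene-regulatory-network reconstruction.

Two independent evidence streams are intersected:

1. **Coexpression**: a soft-thresholded |Pearson r|^beta adjacency over
   the classified genes, turned into an unsigned topological-overlap
   matrix (TOM); average-linkage modules are cut from 1 - TOM, and a
   gene pair becomes a coexpression edge when both genes share a module
   and |r| clears a minimum-correlation gate.
2. **Tree-ensemble regulation**: for every target gene a random-forest
   regression on all transcription-factor expressions ranks regulators
   by impurity-reduction importance (normalised per target).  The top
   ``density`` fraction of regulator->target pairs is tested against a
   permutation null built by independently shuffling each regulator's
   expression across samples and recomputing importances; empirical
   p-values carry the +1 correction.

A directed TF -> target edge enters the consensus network only when the
unordered pair is a coexpression edge *and* the directed edge survives
the permutation test.  Clusters are connected components of the
undirected skeleton, numbered by descending node count.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from lightmeta.datamodel import CountStudy, GeneAnnotation, ValidationError
from lightmeta.de import cpm
from lightmeta.enrichment import EnrichmentResult, filter_enriched, hypergeom_enrichment

log = logging.getLogger("lightmeta")


@dataclass
class GRNEdge:
    regulator: str
    target: str
    importance: float
    correlation: float
    perm_pvalue: float
    cluster: int = 0


@dataclass
class GRN:
    """Directed TF -> target network with cluster structure."""

    edges: list[GRNEdge]
    nodes: pd.DataFrame                      # index gene; is_tf, regulation, cluster
    cluster_annotations: dict[int, list[EnrichmentResult]] = field(default_factory=dict)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    def edge_frame(self) -> pd.DataFrame:
        cols = ["regulator", "target", "importance", "correlation", "perm_pvalue", "cluster"]
        if not self.edges:
            return pd.DataFrame(columns=cols)
        return pd.DataFrame([vars(e) for e in self.edges])[cols]

    def to_graphml(self, path) -> None:
        g = nx.DiGraph()
        for gene, row in self.nodes.iterrows():
            g.add_node(gene, is_tf=bool(row["is_tf"]), regulation=row["regulation"],
                       cluster=int(row["cluster"]))
        for e in self.edges:
            g.add_edge(e.regulator, e.target, importance=e.importance,
                       correlation=e.correlation, perm_pvalue=e.perm_pvalue)
        nx.write_graphml(g, path)


# ---------------------------------------------------------------------------
# expression subsets
# ---------------------------------------------------------------------------

def expression_subset(
    study: CountStudy,
    genes: Sequence[str],
    condition_ids: Iterable[str],
    factors: np.ndarray | None = None,
) -> pd.DataFrame:
    """log2(CPM + 1) for the given genes over all libraries of the conditions.

    Rows are libraries (samples), columns genes - the orientation used
    by all network stages.  CPM uses TMM effective library sizes
    computed over the full transcriptome of the selected libraries
    (pass ``factors`` to override); without the composition correction,
    coordinated expression shifts in responsive genes would leak a
    spurious common axis into every other gene's profile.
    """
    from lightmeta.de import tmm_factors

    wanted = set(condition_ids)
    sample_ids = [s.sample_id for s in study.samples if s.condition_id in wanted]
    if len(sample_ids) < 4:
        raise ValidationError(f"expression subset has {len(sample_ids)} libraries; need >= 4")
    sub_samples = study.subset_samples(sample_ids)
    if factors is None:
        factors = tmm_factors(sub_samples.counts.astype(float), sample_ids=sample_ids)
    # library sizes over the full transcriptome, not the gene subset
    lib = sub_samples.library_sizes()
    sub = sub_samples.subset_genes(list(genes))
    mat = cpm(sub.counts, lib, factors)
    return pd.DataFrame(np.log2(mat + 1.0).T, index=sample_ids, columns=list(genes))


# ---------------------------------------------------------------------------
# coexpression side
# ---------------------------------------------------------------------------

def _drop_constant(expr: pd.DataFrame) -> pd.DataFrame:
    sd = expr.std(axis=0, ddof=0)
    constant = sd[sd == 0].index
    if len(constant):
        log.warning("excluding %d constant gene(s) from coexpression", len(constant))
        expr = expr.drop(columns=constant)
    return expr


def scale_free_fit(connectivity: np.ndarray, n_bins: int = 10) -> float:
    """Signed R^2 of the log-log degree-distribution regression.

    Connectivities are binned; log10 frequency is regressed on log10
    mean connectivity per occupied bin.  The R^2 is signed by the slope
    (scale-free topology requires a decreasing fit), so positive values
    indicate power-law-like decay.
    """
    k = np.asarray(connectivity, dtype=float)
    k = k[k > 0]
    if k.size < 2 or np.allclose(k, k[0]):
        return 0.0
    edges = np.linspace(k.min(), k.max(), n_bins + 1)
    which = np.clip(np.digitize(k, edges[1:-1]), 0, n_bins - 1)
    xs, ys = [], []
    for b in range(n_bins):
        members = k[which == b]
        if members.size == 0:
            continue
        xs.append(np.log10(members.mean()))
        ys.append(np.log10(members.size / k.size))
    if len(xs) < 3:
        return 0.0
    slope, intercept = np.polyfit(xs, ys, 1)
    fitted = np.polyval([slope, intercept], xs)
    ss_res = float(np.sum((np.array(ys) - fitted) ** 2))
    ss_tot = float(np.sum((np.array(ys) - np.mean(ys)) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    return -np.sign(slope) * r2 if slope != 0 else 0.0


def select_soft_power(
    expr: pd.DataFrame,
    powers: Sequence[int] = tuple(range(1, 21)),
    r2_min: float = 0.8,
    fallback: int = 6,
    min_mean_connectivity: float = 2.0,
) -> int:
    """Smallest soft-thresholding power reaching the scale-free fit target.

    Powers whose adjacency leaves the mean connectivity below
    ``min_mean_connectivity`` are skipped: an effectively edgeless
    network fits a power law vacuously, and module detection on it is
    meaningless.  When no admissible power reaches ``r2_min``, the
    admissible power with the best fit is used (with a warning); the
    constant ``fallback`` applies only if every power on the grid is
    degenerate.
    """
    expr = _drop_constant(expr)
    if expr.shape[0] < 4 or expr.shape[1] < 3:
        raise ValidationError("soft-power selection needs >= 4 samples and >= 3 genes")
    corr = np.abs(np.corrcoef(expr.to_numpy().T))
    np.fill_diagonal(corr, 0.0)
    best_beta, best_fit = None, -np.inf
    for beta in powers:
        k = (corr ** beta).sum(axis=1)
        if k.mean() < min_mean_connectivity:
            break
        fit = scale_free_fit(k)
        if fit >= r2_min:
            return int(beta)
        if fit > best_fit:
            best_beta, best_fit = beta, fit
    if best_beta is None:
        log.warning("all soft powers give degenerate connectivity; falling back to %d",
                    fallback)
        return int(fallback)
    log.warning("no soft power reached scale-free R^2 >= %.2f; using best fit "
                "beta=%d (R^2=%.2f)", r2_min, best_beta, best_fit)
    return int(best_beta)


def adjacency(expr: pd.DataFrame, beta: int) -> pd.DataFrame:
    """Unsigned soft-threshold adjacency |r|^beta with zero diagonal."""
    expr = _drop_constant(expr)
    a = np.abs(np.corrcoef(expr.to_numpy().T)) ** beta
    np.fill_diagonal(a, 0.0)
    return pd.DataFrame(a, index=expr.columns, columns=expr.columns)


def tom(adjacency_matrix: pd.DataFrame | np.ndarray) -> np.ndarray:
    """Unsigned topological overlap matrix.

    t_ij = (sum_k a_ik a_kj + a_ij) / (min(k_i, k_j) + 1 - a_ij) off the
    diagonal, t_ii = 1, where k_i is node i's connectivity.
    """
    a = np.asarray(adjacency_matrix, dtype=float).copy()
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValidationError("adjacency must be square")
    if np.any((a < 0) | (a > 1)):
        raise ValidationError("adjacency values must lie in [0, 1]")
    np.fill_diagonal(a, 0.0)
    shared = a @ a
    k = a.sum(axis=1)
    kmin = np.minimum.outer(k, k)
    with np.errstate(invalid="ignore"):
        t = (shared + a) / (kmin + 1.0 - a)
    t = np.nan_to_num(t, nan=0.0)
    np.fill_diagonal(t, 1.0)
    return np.clip(t, 0.0, 1.0)


def detect_modules(
    tom_matrix: np.ndarray,
    min_module_size: int = 30,
    cut_height: float = 0.99,
) -> np.ndarray:
    """Module labels from a static cut of the average-linkage TOM tree.

    Genes in clusters smaller than ``min_module_size`` get label 0
    (unassigned); real modules are numbered 1, 2, ... by descending
    size.
    """
    t = np.asarray(tom_matrix, dtype=float)
    d = 1.0 - t
    np.fill_diagonal(d, 0.0)
    d = np.clip((d + d.T) / 2.0, 0.0, None)
    merges = linkage(squareform(d, checks=False), method="average")
    raw = fcluster(merges, t=cut_height, criterion="distance")
    sizes = pd.Series(raw).value_counts()
    keep = sizes[sizes >= min_module_size].index
    order = sorted(keep, key=lambda c: (-sizes[c], c))
    remap = {c: i + 1 for i, c in enumerate(order)}
    labels = np.array([remap.get(c, 0) for c in raw])
    if labels.max(initial=0) == 0:
        log.warning("no module reached min size %d; all genes unassigned", min_module_size)
    return labels


def coexpression_edges(
    expr: pd.DataFrame,
    modules: Mapping[str, int] | np.ndarray,
    min_correlation: float,
) -> dict[tuple[str, str], float]:
    """Unordered within-module gene pairs with |Pearson r| >= the gate.

    Returns pair -> signed correlation; pairs are keyed as sorted
    (gene_a, gene_b) tuples.
    """
    genes = list(expr.columns)
    if not isinstance(modules, Mapping):
        modules = dict(zip(genes, np.asarray(modules)))
    r = np.corrcoef(expr.to_numpy().T)
    out: dict[tuple[str, str], float] = {}
    for i in range(len(genes)):
        mi = modules.get(genes[i], 0)
        if mi == 0:
            continue
        for j in range(i + 1, len(genes)):
            if modules.get(genes[j], 0) != mi:
                continue
            rij = float(r[i, j])
            if np.isfinite(rij) and abs(rij) >= min_correlation:
                pair = tuple(sorted((genes[i], genes[j])))
                out[pair] = rij
    return out


# ---------------------------------------------------------------------------
# tree-ensemble side
# ---------------------------------------------------------------------------

def tree_importances(
    expr: pd.DataFrame,
    regulators: Sequence[str],
    n_trees: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Random-forest regulator importances, one column per target.

    Each target's (standardised) expression is regressed on all
    regulator expressions (K = sqrt(#regulators) candidate features per
    split), excluding the target itself when it is a regulator.
    Importances are total impurity reductions normalised to sum to one
    per target (all zero for a constant target).  Deterministic given
    the seed.
    """
    from lightmeta._forest import forest_importance

    if expr.shape[0] < 2:
        raise ValidationError("tree importances need >= 2 samples")
    regs = [r for r in regulators if r in expr.columns]
    if len(regs) < 2:
        raise ValidationError("need >= 2 regulators present in the expression matrix")
    targets = list(expr.columns)
    reg_mat = np.ascontiguousarray(expr[regs].to_numpy())

    out = np.zeros((len(regs), len(targets)))
    child_seeds = np.random.SeedSequence(seed).generate_state(len(targets), np.uint64)
    for j, tgt in enumerate(targets):
        y = expr[tgt].to_numpy().astype(float)
        sd = y.std()
        if sd == 0:
            continue
        y = (y - y.mean()) / sd
        if tgt in regs:
            cols = [i for i, r in enumerate(regs) if r != tgt]
            x = np.ascontiguousarray(reg_mat[:, cols])
        else:
            cols = list(range(len(regs)))
            x = reg_mat
        imp = forest_importance(x, y, n_trees=n_trees, seed=int(child_seeds[j]))
        total = imp.sum()
        if total > 0:
            imp = imp / total
        for ci, v in zip(cols, imp):
            out[ci, j] = v
    imp_frame = pd.DataFrame(out, index=regs, columns=targets)
    # self-regulation is undefined; mask it out
    for r in regs:
        if r in imp_frame.columns:
            imp_frame.loc[r, r] = np.nan
    return imp_frame


def _importance_pairs(importances: pd.DataFrame) -> pd.DataFrame:
    long = importances.stack(future_stack=True).rename("importance").reset_index()
    long.columns = ["regulator", "target", "importance"]
    return long[long["regulator"] != long["target"]].dropna(subset=["importance"])


def permutation_edge_test(
    expr: pd.DataFrame,
    importances: pd.DataFrame,
    density: float,
    n_shuffle: int = 1000,
    seed: int = 0,
    n_trees: int = 1000,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Permutation-null significance of the densest regulator->target edges.

    The candidate set is the top ``ceil(density * n_regulators *
    n_targets)`` edges by importance.  The null pools importances from
    ``n_shuffle`` recomputations in which every regulator's expression
    vector is independently permuted across samples.  Empirical
    p-values use the +1 correction; an edge is retained when
    p < ``alpha``.
    """
    if not (0 < density <= 1):
        raise ValidationError("density must lie in (0, 1]")
    regs = list(importances.index)
    pairs = _importance_pairs(importances)
    raw = density * importances.shape[0] * importances.shape[1]
    if raw < 1 or pairs.empty:
        raise ValidationError("empty candidate set (density too small)")
    n_candidates = math.ceil(raw)
    candidates = pairs.nlargest(n_candidates, "importance").reset_index(drop=True)

    rng = np.random.default_rng(seed)
    null_values: list[np.ndarray] = []
    for round_i in range(n_shuffle):
        shuffled = expr.copy()
        for r in regs:
            shuffled[r] = rng.permutation(shuffled[r].to_numpy())
        null_imp = tree_importances(
            shuffled, regs, n_trees=n_trees, seed=int(rng.integers(2 ** 31)),
        )
        null_values.append(_importance_pairs(null_imp)["importance"].to_numpy())
    null = np.sort(np.concatenate(null_values)) if null_values else np.array([])

    obs = candidates["importance"].to_numpy()
    if null.size:
        ge = null.size - np.searchsorted(null, obs, side="left")
    else:
        ge = np.zeros(obs.size, dtype=int)
    pvals = (1.0 + ge) / (1.0 + null.size)
    candidates["perm_pvalue"] = pvals
    candidates["retained"] = pvals < alpha
    return candidates


# ---------------------------------------------------------------------------
# consensus
# ---------------------------------------------------------------------------

def consensus_network(
    coexp: Mapping[tuple[str, str], float],
    tested_edges: pd.DataFrame,
    up_genes: Iterable[str] = (),
    down_genes: Iterable[str] = (),
    frequent_genes: Iterable[str] = (),
    annotation: Mapping[str, GeneAnnotation] | None = None,
) -> GRN:
    """Intersect coexpression pairs with permutation-confirmed edges.

    A directed edge survives when its unordered pair is coexpressed and
    the permutation test retained it.  Node regulation labels come from
    the classified up/down sets; genes in both, or in the "frequent"
    pattern, are labelled mixed.
    """
    up, down, freq = set(up_genes), set(down_genes), set(frequent_genes)
    annotation = annotation or {}
    edges: list[GRNEdge] = []
    retained = tested_edges[tested_edges["retained"]] if "retained" in tested_edges else tested_edges
    for row in retained.itertuples(index=False):
        pair = tuple(sorted((row.regulator, row.target)))
        if pair in coexp:
            edges.append(GRNEdge(
                regulator=row.regulator,
                target=row.target,
                importance=float(row.importance),
                correlation=float(coexp[pair]),
                perm_pvalue=float(row.perm_pvalue),
            ))

    skeleton = nx.Graph()
    for e in edges:
        skeleton.add_edge(e.regulator, e.target)
    components = sorted(nx.connected_components(skeleton),
                        key=lambda c: (-len(c), sorted(c)[0]))
    cluster_of = {g: i + 1 for i, comp in enumerate(components) for g in comp}
    for e in edges:
        e.cluster = cluster_of[e.regulator]

    def regulation(gene: str) -> str:
        if gene in freq or (gene in up and gene in down):
            return "mixed"
        if gene in up:
            return "up"
        if gene in down:
            return "down"
        return "unclassified"

    node_rows = {}
    for e in edges:
        for gene in (e.regulator, e.target):
            ann = annotation.get(gene)
            node_rows[gene] = {
                "is_tf": bool(ann.is_tf) if ann is not None else gene in
                         {e2.regulator for e2 in edges},
                "regulation": regulation(gene),
                "cluster": cluster_of[gene],
            }
    nodes = pd.DataFrame.from_dict(node_rows, orient="index")
    if nodes.empty:
        nodes = pd.DataFrame(columns=["is_tf", "regulation", "cluster"])
    return GRN(edges=edges, nodes=nodes.sort_index())


def reconstruct(
    expr: pd.DataFrame,
    regulators: Sequence[str],
    *,
    min_correlation: float = 0.30,
    min_module_size: int = 30,
    cut_height: float = 0.99,
    density: float = 0.065,
    n_trees: int = 1000,
    n_shuffle: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
    up_genes: Iterable[str] = (),
    down_genes: Iterable[str] = (),
    frequent_genes: Iterable[str] = (),
    annotation: Mapping[str, GeneAnnotation] | None = None,
) -> GRN:
    """Full consensus reconstruction from one expression subset.

    Runs the coexpression side (soft power selection, TOM, modules,
    correlation gate) and the tree-ensemble side (importances,
    permutation test), then intersects them.
    """
    beta = select_soft_power(expr)
    a = adjacency(expr, beta)
    t = tom(a)
    modules = detect_modules(t, min_module_size=min_module_size, cut_height=cut_height)
    module_map = dict(zip(a.columns, modules))
    coexp = coexpression_edges(expr[list(a.columns)], module_map, min_correlation)
    importances = tree_importances(expr, regulators, n_trees=n_trees, seed=seed)
    tested = permutation_edge_test(
        expr, importances, density=density, n_shuffle=n_shuffle,
        seed=seed + 1, n_trees=n_trees, alpha=alpha,
    )
    return consensus_network(
        coexp, tested, up_genes=up_genes, down_genes=down_genes,
        frequent_genes=frequent_genes, annotation=annotation,
    )


def annotate_clusters(
    grn: GRN,
    term_map: Mapping[str, Iterable[str]],
    universe: Iterable[str],
    q_max: float = 1e-5,
    representation_min: float = 0.03,
    top_n: int = 3,
) -> GRN:
    """Attach the top enriched GO terms to each network cluster.

    Enrichment runs against the supplied (expression-filtered,
    annotated) universe; clusters without a term passing the gates are
    annotated with an empty list.
    """
    universe = set(universe)
    annotations: dict[int, list[EnrichmentResult]] = {}
    if grn.n_nodes:
        for cluster_id, members in grn.nodes.groupby("cluster").groups.items():
            target = [g for g in members if term_map.get(g) and g in universe]
            if not target:
                annotations[int(cluster_id)] = []
                continue
            results = hypergeom_enrichment(target, universe, term_map)
            kept = filter_enriched(results, q_max, representation_min)
            top = sorted(kept, key=lambda r: (r.qvalue, -r.overlap, r.term_id))[:top_n]
            annotations[int(cluster_id)] = top
    grn.cluster_annotations = annotations
    return grn
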