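"""Synthetic multi-experiment high-light studies with planted ground truth.

The generator emulates the statistical structure of a cross-study
compendium: several experiments, each contributing one control group and
several stress conditions (unique duration x intensity combinations)
with replicated libraries.  Counts are negative-binomial with

* gene baseline abundances drawn log-normally,
* library sizes log-normal around 1e7 reads,
* a per-gene, per-experiment multiplicative batch effect (log-sd
  ``batch_sd``),
* planted temporal DEG classes that shift stress-condition means by
  +/- ``lfc_magnitude`` log2 units in the short (<= 90 min) and/or long
  (>= 2 h) duration group,
* planted TF -> target regulation: a regulator's realised condition-level
  expression perturbs its targets' means on the log scale, so that
  regulator-target pairs are correlated across conditions (positively or
  negatively, per edge sign).

Everything is reproducible from a single integer seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from lightmeta.datamodel import CountStudy, GeneAnnotation, SampleRecord, ValidationError

DEG_CLASSES = (
    "short_up", "short_down", "long_up", "long_down",
    "short_long_up", "short_long_down",
)

#: default stress-condition grid: durations span 2 min .. 3 days, intensities
#: span the moderate..severe high-light range
DEFAULT_DURATIONS_MIN = (2.0, 30.0, 60.0, 120.0, 480.0, 1440.0, 2880.0, 4320.0)
DEFAULT_INTENSITIES = (500.0, 800.0, 1000.0, 1200.0, 1800.0, 2000.0)

_TF_FAMILIES = (
    "AP2/ERF", "bZIP", "WRKY", "MYB", "NAC",
    "bHLH", "GATA", "C2H2", "HSF", "ARF",
)

SHORT_MAX_MIN = 90.0
LONG_MIN_MIN = 120.0


@dataclass
class GroundTruth:
    """Planted structure of a synthetic study."""

    deg_classes: dict[str, str]                      # gene -> class (non-null only)
    effect_lfc: dict[str, float]                     # gene -> signed log2 effect
    true_edges: set[tuple[str, str, int]]            # (regulator, target, sign)
    enriched_term: str | None
    dispersion: float
    seed: int

    def degs_in_group(self, group: str, direction: str) -> set[str]:
        """Genes planted to respond in a duration group with a direction."""
        wanted = {f"{group}_{direction}", f"short_long_{direction}"}
        return {g for g, c in self.deg_classes.items() if c in wanted}

    def to_json(self, path: str | Path) -> None:
        payload = {
            "deg_classes": self.deg_classes,
            "effect_lfc": self.effect_lfc,
            "true_edges": sorted([list(e) for e in self.true_edges]),
            "enriched_term": self.enriched_term,
            "dispersion": self.dispersion,
            "seed": self.seed,
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        d = json.loads(Path(path).read_text())
        return cls(
            deg_classes=d["deg_classes"],
            effect_lfc=d["effect_lfc"],
            true_edges={(r, t, int(s)) for r, t, s in d["true_edges"]},
            enriched_term=d["enriched_term"],
            dispersion=d["dispersion"],
            seed=d["seed"],
        )


def _gene_ids(n: int) -> list[str]:
    return [f"AT{(i % 5) + 1}G{(i // 5 + 1) * 10:05d}" for i in range(n)]


def _sample_nb(rng: np.random.Generator, mean: np.ndarray, phi: float) -> np.ndarray:
    """NB(mean mu, variance mu + phi mu^2); Poisson when phi == 0."""
    mean = np.maximum(mean, 1e-12)
    if phi <= 0:
        return rng.poisson(mean)
    r = 1.0 / phi
    p = r / (r + mean)
    return rng.negative_binomial(r, p)


def simulate_study(
    n_genes: int = 2000,
    n_experiments: int = 4,
    conditions_per_experiment: int = 3,
    replicates: int = 3,
    deg_fraction: float = 0.1,
    lfc_magnitude: float = 2.0,
    dispersion: float = 0.1,
    n_tfs: int = 0,
    edges_per_tf: int = 0,
    batch_sd: float = 0.1,
    seed: int = 0,
    *,
    edge_sign_neg_fraction: float = 0.5,
    coupling: float = 1.0,
    tf_activity_sd: float = 0.7,
    tf_shared_frac: float = 0.2,
    tissue: str = "leaf",
    age_days: float = 25.0,
    mean_library_size: float = 1e7,
    library_size_log_sd: float = 0.2,
    baseline_log_mean: float = 4.0,
    baseline_log_sd: float = 1.5,
    outlier_experiment: bool = False,
    outlier_batch_sd: float = 2.0,
    durations_min: Sequence[float] = DEFAULT_DURATIONS_MIN,
    intensities: Sequence[float] = DEFAULT_INTENSITIES,
) -> tuple[CountStudy, dict[str, GeneAnnotation], GroundTruth]:
    """Generate one multi-experiment count study with known ground truth.

    Each experiment contributes ``conditions_per_experiment`` stress
    conditions (``replicates`` libraries each) plus one control group of
    ``replicates`` libraries.  With ``outlier_experiment=True`` one
    extra experiment with an extreme batch shift is appended, to
    exercise outlier detection in condition clustering.
    """
    if min(n_genes, n_experiments, conditions_per_experiment, replicates) < 1:
        raise ValidationError("all sizes must be >= 1")
    if not (0 <= deg_fraction < 1):
        raise ValidationError("deg_fraction must lie in [0, 1)")
    if n_tfs > n_genes:
        raise ValidationError(f"n_tfs={n_tfs} exceeds n_genes={n_genes}")
    if edges_per_tf > n_genes - n_tfs:
        raise ValidationError(
            f"edges_per_tf={edges_per_tf} exceeds available non-TF genes "
            f"({n_genes - n_tfs})"
        )

    rng = np.random.default_rng(seed)
    genes = _gene_ids(n_genes)

    # -- planted DEG classes --------------------------------------------------
    n_deg = int(round(deg_fraction * n_genes))
    deg_idx = rng.choice(n_genes, size=n_deg, replace=False) if n_deg else np.array([], int)
    deg_classes: dict[str, str] = {}
    effect_lfc: dict[str, float] = {}
    for j, gi in enumerate(deg_idx):
        cls = DEG_CLASSES[j % len(DEG_CLASSES)]
        deg_classes[genes[gi]] = cls
        effect_lfc[genes[gi]] = lfc_magnitude if cls.endswith("_up") else -lfc_magnitude

    # -- TFs and regulatory edges ---------------------------------------------
    tf_idx = list(range(n_tfs))
    tf_genes = [genes[i] for i in tf_idx]
    non_tf_idx = [i for i in range(n_genes) if i >= n_tfs]
    true_edges: set[tuple[str, str, int]] = set()
    target_of: dict[int, tuple[int, int]] = {}  # target index -> (tf index, sign)
    if n_tfs and edges_per_tf:
        pool = rng.permutation(non_tf_idx)
        k = 0
        for ti in tf_idx:
            for _ in range(edges_per_tf):
                tgt = int(pool[k % pool.size])
                k += 1
                sign = -1 if rng.random() < edge_sign_neg_fraction else 1
                true_edges.add((genes[ti], genes[tgt], sign))
                target_of[tgt] = (ti, sign)

    # -- experiment / condition layout ----------------------------------------
    total_exps = n_experiments + (1 if outlier_experiment else 0)
    exp_ids = [f"SIM{e + 1:02d}" for e in range(total_exps)]
    base_log = rng.normal(baseline_log_mean, baseline_log_sd, size=n_genes)
    batch = rng.normal(0.0, batch_sd, size=(n_genes, total_exps)) if batch_sd > 0 else np.zeros((n_genes, total_exps))
    if outlier_experiment:
        batch[:, -1] = rng.normal(0.0, outlier_batch_sd, size=n_genes)

    ln2 = np.log(2.0)
    samples: list[SampleRecord] = []
    columns: list[np.ndarray] = []
    cond_counter = 0
    for e, exp in enumerate(exp_ids):
        # control group
        ctl_dur = 0.0
        ctl_intensity = 0.0
        ctl_cond = f"{exp}_{tissue.upper()}_{age_days:g}_CTRL"
        log_mu_ctl = base_log + batch[:, e]
        for r in range(replicates):
            lib = mean_library_size * np.exp(rng.normal(0.0, library_size_log_sd))
            mu = np.exp(log_mu_ctl)
            mu = mu / mu.sum() * lib
            columns.append(_sample_nb(rng, mu, dispersion))
            samples.append(SampleRecord(
                sample_id=f"{exp}_C_r{r + 1}",
                experiment_id=exp,
                condition_id=ctl_cond,
                tissue=tissue,
                intensity_ppfd=ctl_intensity,
                duration_min=ctl_dur,
                age_days=age_days,
                is_control=True,
            ))
        # stress conditions
        for c in range(conditions_per_experiment):
            dur = durations_min[cond_counter % len(durations_min)]
            inten = intensities[cond_counter % len(intensities)]
            cond_counter += 1
            cond_id = f"{exp}_{tissue.upper()}_{age_days:g}_{inten:g}_{dur:g}_min"
            is_short = dur <= SHORT_MAX_MIN
            is_long = dur >= LONG_MIN_MIN

            log_mu = base_log + batch[:, e]
            effect = np.zeros(n_genes)
            for gi in deg_idx:
                cls = deg_classes[genes[gi]]
                hit = (
                    (cls.startswith("short_") and not cls.startswith("short_long") and is_short)
                    or (cls.startswith("long_") and is_long)
                    or (cls.startswith("short_long") and (is_short or is_long))
                )
                if hit:
                    effect[gi] = effect_lfc[genes[gi]] * ln2
            # TF condition-level activity drives coexpression signal; a shared
            # latent stress-axis component co-activates regulons, as one
            # coordinated transcriptional program would.  Activity is injected
            # only for TFs that regulate at least one target: it exists to
            # realise planted regulation, so a study without planted edges
            # stays exchangeable.
            active_tfs = {ti for ti, _sign in target_of.values()}
            if active_tfs:
                shared = rng.normal()
                tf_act = tf_activity_sd * (
                    np.sqrt(tf_shared_frac) * shared
                    + np.sqrt(1.0 - tf_shared_frac) * rng.normal(size=n_tfs)
                )
                for ti in sorted(active_tfs):
                    effect[ti] += tf_act[ti]
                for tgt, (ti, sign) in target_of.items():
                    # realised regulator deviation on the log scale, linear link
                    effect[tgt] += sign * coupling * (effect[ti])
            log_mu = log_mu + effect

            for r in range(replicates):
                lib = mean_library_size * np.exp(rng.normal(0.0, library_size_log_sd))
                mu = np.exp(log_mu)
                mu = mu / mu.sum() * lib
                columns.append(_sample_nb(rng, mu, dispersion))
                samples.append(SampleRecord(
                    sample_id=f"{exp}_S{c + 1}_r{r + 1}",
                    experiment_id=exp,
                    condition_id=cond_id,
                    tissue=tissue,
                    intensity_ppfd=inten,
                    duration_min=dur,
                    age_days=age_days,
                    is_control=False,
                ))

    counts = np.column_stack(columns).astype(np.int64)
    study = CountStudy(genes=genes, samples=samples, counts=counts)

    annotations = {
        g: GeneAnnotation(
            gene_id=g,
            description=f"synthetic gene {i + 1}",
            tf_family=_TF_FAMILIES[i % len(_TF_FAMILIES)] if i < n_tfs else None,
        )
        for i, g in enumerate(genes)
    }
    truth = GroundTruth(
        deg_classes=deg_classes,
        effect_lfc=effect_lfc,
        true_edges=true_edges,
        enriched_term=None,
        dispersion=dispersion,
        seed=seed,
    )
    return study, annotations, truth


def simulate_go(
    genes: Sequence[str],
    n_terms: int = 50,
    term_size_range: tuple[int, int] = (10, 50),
    planted_genes: Sequence[str] = (),
    planted_term_coverage: float = 0.0,
    seed: int = 0,
    leakage: float = 0.01,
) -> tuple[dict[str, frozenset[str]], str | None]:
    """Assign background GO terms uniformly and plant one enriched term.

    The planted term covers ``planted_term_coverage`` of
    ``planted_genes`` plus a ``leakage`` fraction of the remaining
    genes.  With coverage 0 no term is planted.  Returns the gene ->
    term-set map and the planted term id (or None).
    """
    genes = list(genes)
    lo, hi = term_size_range
    if hi > len(genes):
        raise ValidationError("term sizes must not exceed the number of genes")
    if planted_term_coverage > 0 and not planted_genes:
        raise ValidationError("planted_term_coverage > 0 requires a non-empty planted class")

    rng = np.random.default_rng(seed)
    term_sets: dict[str, set[str]] = {g: set() for g in genes}
    for t in range(n_terms):
        term = f"GO:{t + 1:07d}"
        size = int(rng.integers(lo, hi + 1))
        for g in rng.choice(len(genes), size=size, replace=False):
            term_sets[genes[g]].add(term)

    enriched_term: str | None = None
    if planted_term_coverage > 0:
        enriched_term = f"GO:{n_terms + 1:07d}"
        planted = [g for g in planted_genes if g in term_sets]
        n_cover = int(round(planted_term_coverage * len(planted)))
        for g in rng.choice(planted, size=n_cover, replace=False):
            term_sets[g].add(enriched_term)
        others = [g for g in genes if g not in set(planted)]
        n_leak = int(round(leakage * len(others)))
        if n_leak:
            for g in rng.choice(others, size=n_leak, replace=False):
                term_sets[g].add(enriched_term)

    return {g: frozenset(s) for g, s in term_sets.items()}, enriched_term


def attach_go(
    annotations: dict[str, GeneAnnotation],
    go_map: dict[str, frozenset[str]],
) -> dict[str, GeneAnnotation]:
    """Return annotations with GO term sets filled in from ``go_map``."""
    out = {}
    for g, ann in annotations.items():
        out[g] = GeneAnnotation(
            gene_id=ann.gene_id,
            description=ann.description,
            tf_family=ann.tf_family,
            go_terms=go_map.get(g, frozenset()),
        )
    return out
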