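"""End-to-end orchestration of the three meta-analysis steps.

Step 1: per-experiment DEG calling, condition clustering and taxonomy,
frequent-DEG GO enrichment.  Step 2: frequency/quartile classification,
per-category enrichment, robust consistency selection.  Step 3:
per-tissue, per-duration-group consensus GRN reconstruction.

Each stage writes tab-delimited artifacts into the output directory and
records itself in a run manifest (config snapshot, seed, per-stage
record counts and output checksums) so that a rerun with the same
config and seed is byte-identical and any stage can be resumed from the
artifacts of the previous ones.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from lightmeta import classify as cls
from lightmeta import conditions as cond
from lightmeta import de, enrichment, grn, io, simulate
from lightmeta.config import PipelineConfig
from lightmeta.datamodel import CountStudy, GeneAnnotation, ValidationError

log = logging.getLogger("lightmeta")


@dataclass
class RunManifest:
    config: dict
    seed: int
    stages: dict[str, dict] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)
    status: str = "running"

    def record(self, stage: str, outputs: dict[str, Path], counts: dict[str, int]) -> None:
        self.stages[stage] = {
            "outputs": {name: _checksum(p) for name, p in outputs.items()},
            "counts": counts,
            "finished_at": time.strftime("%Y-%m-%dT%H:%M:%S"),
        }

    def save(self, path: Path) -> None:
        payload = {
            "config": self.config,
            "seed": self.seed,
            "stages": self.stages,
            "warnings": self.warnings,
            "status": self.status,
        }
        path.write_text(json.dumps(payload, indent=1, sort_keys=True))


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _need(path: Path, stage: str) -> Path:
    if not path.exists():
        raise ValidationError(
            f"stage {stage!r} needs {path.name!r}; run the producing stage first"
        )
    return path


class MetaAnalysis:
    """Stage runner bound to one output directory and configuration."""

    def __init__(self, outdir: str | Path, config: PipelineConfig | None = None):
        self.outdir = Path(outdir)
        self.outdir.mkdir(parents=True, exist_ok=True)
        self.config = config or PipelineConfig()
        self.manifest = RunManifest(config=self.config.to_dict(), seed=self.config.seed)

    # -- helpers ------------------------------------------------------------

    def _header(self) -> str:
        return f"config_hash={self.config.hash()} seed={self.config.seed}"

    def _write(self, frame, name: str) -> Path:
        path = self.outdir / name
        io.write_table(frame, path, header_comment=self._header())
        return path

    def _save_manifest(self) -> None:
        self.manifest.save(self.outdir / "manifest.json")

    # -- stage: simulate -----------------------------------------------------

    def simulate(self, **sim_kw) -> CountStudy:
        """Generate a synthetic study (plus GO and ground truth) on disk."""
        cfg = self.config
        sim_kw.setdefault("seed", cfg.seed)
        study, annotations, truth = simulate.simulate_study(**sim_kw)
        planted_class = "long_up"
        planted = [g for g, c in truth.deg_classes.items() if c == planted_class]
        go_map, term = simulate.simulate_go(
            study.genes,
            planted_genes=planted,
            planted_term_coverage=0.8 if planted else 0.0,
            seed=sim_kw["seed"] + 1,
        )
        truth.enriched_term = term
        annotations = simulate.attach_go(annotations, go_map)

        io.write_count_study(study, self.outdir / "study.csv")
        ann_frame = pd.DataFrame(
            [
                {"gene_id": a.gene_id, "description": a.description,
                 "tf_family": a.tf_family or ""}
                for a in annotations.values()
            ]
        )
        ann_path = self._write(ann_frame, "gene_annotation.tsv")
        go_rows = [
            {"gene_id": g, "go_id": t}
            for g, terms in sorted(go_map.items())
            for t in sorted(terms)
        ]
        go_path = self.outdir / "go_map.tsv"
        io.write_table(pd.DataFrame(go_rows, columns=["gene_id", "go_id"]), go_path)
        truth.to_json(self.outdir / "ground_truth.json")
        self.manifest.record(
            "simulate",
            {"study": self.outdir / "study.csv", "annotation": ann_path, "go": go_path},
            {"genes": study.n_genes, "samples": study.n_samples,
             "planted_degs": len(truth.deg_classes), "true_edges": len(truth.true_edges)},
        )
        self._save_manifest()
        return study

    # -- shared loading ------------------------------------------------------

    def load_study(self, path: str | Path | None = None,
                   metadata_path: str | Path | None = None) -> CountStudy:
        path = Path(path) if path else _need(self.outdir / "study.csv", "load")
        study = io.read_count_study(path, metadata_path)
        cfg = self.config
        if cfg.exclude_experiments:
            study = study.drop_experiments(cfg.exclude_experiments)
        keep = [
            s.sample_id for s in study.samples
            if s.is_control
            or cfg.intensity_moderate_min <= s.intensity_ppfd <= cfg.intensity_max
        ]
        if len(keep) < study.n_samples:
            log.warning("dropping %d sample(s) outside the intensity window",
                        study.n_samples - len(keep))
            study = study.subset_samples(keep)
        return study

    def load_annotation(self) -> dict[str, GeneAnnotation]:
        go = _need(self.outdir / "go_map.tsv", "annotation")
        genes = _need(self.outdir / "gene_annotation.tsv", "annotation")
        return io.read_gene_annotation(go, genes)

    # -- stage: deg ----------------------------------------------------------

    def run_deg(self, study: CountStudy) -> pd.DataFrame:
        records = []
        for exp in study.experiments():
            sub = study.subset_experiment(exp)
            recs, info = de.run_experiment_de(sub, self.config)
            records.extend(recs)
            log.info("experiment %s: dispersion %.4g, %d records",
                     exp, info["dispersion"], len(recs))
        frame = de.deg_records_frame(records)
        path = self._write(frame, "degs.tsv")
        self.manifest.record(
            "deg", {"degs": path},
            {"records": len(frame), "degs": int((frame["direction"] != "ns").sum())},
        )
        self._save_manifest()
        return frame

    # -- stage: cluster ------------------------------------------------------

    def run_cluster(self, study: CountStudy):
        profiles = cond.aggregate_condition_cpm(study, config=self.config)
        labels = pd.DataFrame(
            [
                {"condition_id": p.condition_id, "tissue": p.tissue,
                 "is_control": p.is_control, "duration_group": p.duration_group,
                 "two_way_group": p.two_way_group, "intensity_group": p.intensity_group,
                 "age_group": p.age_group, "n_replicates": p.n_replicates}
                for p in profiles
            ]
        )
        labels_path = self._write(labels, "condition_labels.tsv")
        diss = cond.correlation_dissimilarity(profiles, self.config.clustering_min_cpm)
        diss_path = self._write(diss.reset_index(names="condition_id"),
                                "condition_dissimilarity.tsv")
        tree = cond.upgma(diss)
        newick_path = self.outdir / "condition_dendrogram.nwk"
        newick_path.write_text(tree.to_newick() + "\n")
        summary = cond.group_correlation_summary(profiles, self.config.clustering_min_cpm)
        summary_path = self._write(summary.reset_index(names="group"),
                                   "group_correlations.tsv")
        self.manifest.record(
            "cluster",
            {"labels": labels_path, "dissimilarity": diss_path,
             "dendrogram": newick_path, "group_correlations": summary_path},
            {"conditions": len(profiles)},
        )
        self._save_manifest()
        return profiles, tree

    # -- stage: classify -----------------------------------------------------

    def _condition_groups(self, tissue: str) -> dict[str, str]:
        labels = io.read_table(_need(self.outdir / "condition_labels.tsv", "classify"))
        sub = labels[(labels["tissue"] == tissue) & (~labels["is_control"])]
        return dict(zip(sub["condition_id"], sub["two_way_group"]))

    def run_classify(self, tissue: str = "leaf") -> dict:
        cfg = self.config
        degs = io.read_table(_need(self.outdir / "degs.tsv", "classify"))
        groups = self._condition_groups(tissue)
        if not groups:
            raise ValidationError(f"no stress conditions for tissue {tissue!r}")
        records = [
            de.DEGRecord(**row)
            for row in degs.to_dict("records")
            if row["condition_id"] in groups
        ]
        profiles = cls.deg_frequency(records, groups, cfg.min_condition_count)
        annotation = self.load_annotation()

        up, down, unclassified = cls.most_frequent_degs(
            profiles, len(groups), cfg.frequent_fraction, cfg.lfc_min
        )
        assignments = cls.top_quartile_categories(
            profiles, cfg.quartile, cfg.quartile_nonzero_only
        )
        venn = cls.venn_partition(assignments)
        robust = {}
        for group in cls.GROUPS:
            r_up, r_down = cls.robust_consistency_selection(
                profiles, annotation, group,
                cfg.consistency_fraction, cfg.tf_consistency_fraction,
            )
            robust[group] = {"up": r_up, "down": r_down}

        freq_frame = pd.DataFrame(
            [
                {"gene_id": p.gene_id,
                 "n_conditions_detected": p.n_conditions_detected,
                 **{f"n_{g}_{d}": p.counts[(g, d)] for g in cls.GROUPS for d in cls.DIRECTIONS},
                 **{f"freq_{g}_{d}": p.freq[(g, d)] for g in cls.GROUPS for d in cls.DIRECTIONS},
                 "median_lfc": p.median_lfc,
                 "logfc_values": ";".join(f"{v:.4g}" for v in p.logfc_values),
                 "description": annotation.get(p.gene_id, GeneAnnotation(p.gene_id)).description,
                 "tf_family": annotation.get(p.gene_id, GeneAnnotation(p.gene_id)).tf_family or ""}
                for p in profiles
            ]
        )
        freq_path = self._write(freq_frame, f"frequency_{tissue}.tsv")
        cat_frame = pd.DataFrame(
            [
                {"gene_id": a.gene_id,
                 "categories": ";".join(sorted(a.categories)),
                 "pattern_label": a.pattern_label}
                for a in assignments
            ]
        )
        cat_path = self._write(cat_frame, f"categories_{tissue}.tsv")
        venn_frame = pd.DataFrame(
            [{"categories": ";".join(sorted(k)), "count": v}
             for k, v in sorted(venn.items(), key=lambda kv: sorted(kv[0]))]
        )
        venn_path = self._write(venn_frame, f"venn_{tissue}.tsv")
        frequent_frame = pd.DataFrame(
            [{"gene_id": g, "set": name}
             for name, gs in (("up", up), ("down", down), ("unclassified", unclassified))
             for g in sorted(gs)]
        )
        frequent_path = self._write(frequent_frame, f"frequent_{tissue}.tsv")
        robust_frame = pd.DataFrame(
            [{"gene_id": g, "group": grp, "direction": d}
             for grp, dirs in robust.items() for d, gs in dirs.items() for g in sorted(gs)]
        )
        robust_path = self._write(robust_frame, f"robust_{tissue}.tsv")

        self.manifest.record(
            f"classify_{tissue}",
            {"frequency": freq_path, "categories": cat_path, "venn": venn_path,
             "frequent": frequent_path, "robust": robust_path},
            {"profiles": len(profiles), "frequent_up": len(up), "frequent_down": len(down),
             "categorised": len(assignments)},
        )
        self._save_manifest()
        return {
            "profiles": profiles, "assignments": assignments,
            "frequent": (up, down, unclassified), "robust": robust,
        }

    # -- stage: enrich -------------------------------------------------------

    def run_enrich(self, tissue: str = "leaf") -> pd.DataFrame:
        cfg = self.config
        annotation = self.load_annotation()
        term_map = {g: a.go_terms for g, a in annotation.items()}
        degs = io.read_table(_need(self.outdir / "degs.tsv", "enrich"))
        universe = {
            g for g in degs["gene_id"].unique()
            if term_map.get(g)
        }
        targets: dict[str, set[str]] = {}
        frequent = io.read_table(_need(self.outdir / f"frequent_{tissue}.tsv", "enrich"))
        for name in ("up", "down"):
            targets[f"frequent_{name}"] = set(frequent[frequent["set"] == name]["gene_id"])
        cats = io.read_table(_need(self.outdir / f"categories_{tissue}.tsv", "enrich"))
        for cat in cls.CATEGORIES:
            targets[cat] = {
                r["gene_id"] for _, r in cats.iterrows()
                if cat in str(r["categories"]).split(";")
            }
        rows = []
        for name, genes in targets.items():
            genes = {g for g in genes if g in universe}
            if not genes:
                continue
            results = enrichment.hypergeom_enrichment(genes, universe, term_map)
            for r in enrichment.filter_enriched(results, cfg.q_max, cfg.representation_min):
                rows.append({"target_set": name, "term_id": r.term_id,
                             "term_size": r.term_size, "overlap": r.overlap,
                             "target_size": r.target_size, "pvalue": r.pvalue,
                             "qvalue": r.qvalue, "representation": r.representation})
        frame = pd.DataFrame(rows, columns=["target_set", "term_id", "term_size",
                                            "overlap", "target_size", "pvalue",
                                            "qvalue", "representation"])
        path = self._write(frame, f"enrichment_{tissue}.tsv")
        self.manifest.record(f"enrich_{tissue}", {"enrichment": path},
                             {"enriched_terms": len(frame)})
        self._save_manifest()
        return frame

    # -- stage: grn ----------------------------------------------------------

    def run_grn(self, tissue: str = "leaf", group: str = "long") -> grn.GRN:
        cfg = self.config
        study = self.load_study()
        annotation = self.load_annotation()
        term_map = {g: a.go_terms for g, a in annotation.items()}
        cats = io.read_table(
            _need(self.outdir / f"categories_{tissue}.tsv", "grn"))
        up = {r["gene_id"] for _, r in cats.iterrows()
              if f"{group}_up" in str(r["categories"]).split(";")}
        down = {r["gene_id"] for _, r in cats.iterrows()
                if f"{group}_down" in str(r["categories"]).split(";")}
        frequent = {r["gene_id"] for _, r in cats.iterrows()
                    if r["pattern_label"] == "frequent"}
        if len(up | down) < 3:
            raise ValidationError(
                f"too few classified genes for {tissue}/{group} network")
        labels = io.read_table(_need(self.outdir / "condition_labels.tsv", "grn"))
        conds = labels[
            (labels["tissue"] == tissue) & (~labels["is_control"])
            & (labels["two_way_group"] == group)
        ]["condition_id"]
        # regulators: TFs responding in at least one of the group's conditions;
        # the expression matrix holds the classified genes plus those TFs
        degs = io.read_table(_need(self.outdir / "degs.tsv", "grn"))
        group_degs = set(degs[(degs["direction"] != "ns")
                              & (degs["condition_id"].isin(set(conds)))]["gene_id"])
        regulators = sorted(
            g for g in group_degs
            if g in set(study.genes) and annotation.get(g) and annotation[g].is_tf
        )
        genes = sorted((up | down | set(regulators)) & set(study.genes))
        expr = grn.expression_subset(study, genes, conds)
        network = grn.reconstruct(
            expr, regulators,
            min_correlation=cfg.min_correlation,
            min_module_size=cfg.min_module_size,
            cut_height=cfg.module_cut_height,
            density=cfg.density,
            n_trees=cfg.n_trees,
            n_shuffle=cfg.n_shuffle,
            alpha=cfg.perm_alpha,
            seed=cfg.seed,
            up_genes=up, down_genes=down, frequent_genes=frequent,
            annotation=annotation,
        )
        universe = {g for g in study.genes if term_map.get(g)}
        network = grn.annotate_clusters(network, term_map, universe,
                                        cfg.q_max, cfg.representation_min)

        edge_path = self._write(network.edge_frame(), f"grn_edges_{tissue}_{group}.tsv")
        nodes = network.nodes.reset_index(names="gene_id")
        node_path = self._write(nodes, f"grn_nodes_{tissue}_{group}.tsv")
        ann_rows = [
            {"cluster": c, "rank": i + 1, "term_id": r.term_id, "qvalue": r.qvalue,
             "overlap": r.overlap}
            for c, results in sorted(network.cluster_annotations.items())
            for i, r in enumerate(results)
        ] or []
        ann_path = self._write(
            pd.DataFrame(ann_rows, columns=["cluster", "rank", "term_id", "qvalue", "overlap"]),
            f"grn_clusters_{tissue}_{group}.tsv")
        self.manifest.record(
            f"grn_{tissue}_{group}",
            {"edges": edge_path, "nodes": node_path, "clusters": ann_path},
            {"edges": network.n_edges, "nodes": network.n_nodes},
        )
        self._save_manifest()
        return network


def run_meta_analysis(
    outdir: str | Path,
    config: PipelineConfig | None = None,
    study_path: str | Path | None = None,
    metadata_path: str | Path | None = None,
    simulate_study: bool = False,
    sim_kw: dict | None = None,
    tissues: tuple[str, ...] = ("leaf",),
    groups: tuple[str, ...] = ("short", "long"),
) -> RunManifest:
    """Execute every stage in order; stop and record on first failure."""
    runner = MetaAnalysis(outdir, config)
    try:
        if simulate_study:
            study = runner.simulate(**(sim_kw or {}))
            study = runner.load_study()
        else:
            study = runner.load_study(study_path, metadata_path)
        runner.run_deg(study)
        runner.run_cluster(study)
        present_tissues = [t for t in tissues
                           if any(s.tissue == t for s in study.samples)]
        for tissue in present_tissues:
            runner.run_classify(tissue)
            runner.run_enrich(tissue)
            for group in groups:
                try:
                    runner.run_grn(tissue, group)
                except ValidationError as err:
                    log.warning("grn %s/%s skipped: %s", tissue, group, err)
                    runner.manifest.warnings.append(f"grn_{tissue}_{group}: {err}")
        runner.manifest.status = "complete"
    except Exception as err:
        runner.manifest.status = f"failed: {err}"
        runner._save_manifest()
        raise
    runner._save_manifest()
    return runner.manifest
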