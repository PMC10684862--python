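"""End-to-end subtype-discovery pipeline.

Stage order mirrors the study design: per-cohort median binarization, merge
on shared genes, a random 50/50 split into training and testing halves,
consensus clustering of the training half, subtype labelling by differential
expression + pathway enrichment, microenvironment/checkpoint/clinical/
survival characterization, gene-panel selection by SVM-RFE with the plateau
rule, replicated cross-validated grid search over four classifier families,
and external evaluation on the independently re-clustered testing half.

Note the deliberate fidelity choice: binarization happens per cohort
*before* the split, so train and test halves share per-(gene, cohort)
median thresholds.  This couples the halves through the thresholds; it is
retained because it is the integration design being studied, and the
external validation rests on the independent re-clustering of the test
half, not on threshold independence.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cohorts as ch
from . import concluster as cc
from . import diffgsea as dg
from . import models as md
from . import scores as sc
from . import survclin as sv
from . import syndata as sd


class ConfigError(ValueError):
    """Invalid or incomplete pipeline configuration."""


@dataclass
class PipelineConfig:
    """Everything a run needs; loadable from YAML.

    Either ``synth`` (generate a compendium) or ``expression_files`` +
    ``clinical_file`` + the four gene-set GMT paths must be provided.
    """

    outdir: str = "out"
    # data source
    synth: sd.SynthConfig | None = None
    expression_files: dict[str, str] | None = None  # cohort id -> path
    clinical_file: str | None = None
    gmt_hallmark: str | None = None
    gmt_oxidative: str | None = None
    gmt_signatures: str | None = None
    gmt_populations: str | None = None
    gene_universe_file: str | None = None  # optional analysis-gene restriction
    # marker sets used for OX+/IM+ labelling
    ox_marker_sets: list[str] = field(
        default_factory=lambda: ["SYN_OXIDATIVE_PHOSPHORYLATION", "SYN_REACTIVE_OXYGEN_SPECIES"]
    )
    im_marker_sets: list[str] = field(
        default_factory=lambda: ["SYN_INFLAMMATORY_RESPONSE", "SYN_INTERFERON_GAMMA_RESPONSE"]
    )
    checkpoint_genes: list[str] = field(default_factory=lambda: ["PDCD1", "CTLA4"])
    # stage parameters
    split_fraction: float = 0.5
    split_seed: int = 11
    cc_k: int = 2
    cc_reps: int = 100
    cc_p_item: float = 0.8
    cc_seed: int = 23
    deg_lfc_min: float = 0.5
    deg_padj_max: float = 0.05
    gsea_n_perm: int = 1000
    gsea_seed: int = 31
    rfe_sizes: tuple[int, ...] = (3, 6, 9, 12, 15, 18)
    rfe_tolerance: float = 0.005
    model_families: tuple[str, ...] = ("DT", "SVM", "ANN", "RF")
    model_grids: dict[str, dict[str, list]] = field(
        default_factory=lambda: {k: dict(v) for k, v in md.DEFAULT_GRIDS.items()}
    )
    cv_folds: int = 5
    cv_replicates: int = 50
    model_seed: int = 41

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        raw = dict(raw)
        synth = raw.pop("synth", None)
        cfg = cls(**{k: v for k, v in raw.items() if k in cls.__dataclass_fields__})
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        if synth is not None:
            cfg.synth = sd.SynthConfig(**synth)
        if isinstance(cfg.rfe_sizes, list):
            cfg.rfe_sizes = tuple(cfg.rfe_sizes)
        if isinstance(cfg.model_families, list):
            cfg.model_families = tuple(cfg.model_families)
        return cfg

    def validate(self) -> "PipelineConfig":
        if self.synth is None:
            needed = [
                self.expression_files, self.clinical_file, self.gmt_hallmark,
                self.gmt_oxidative, self.gmt_signatures, self.gmt_populations,
            ]
            if any(x is None for x in needed):
                raise ConfigError(
                    "without a synth block, expression_files, clinical_file and "
                    "all four GMT paths are required"
                )
            for p in [self.clinical_file, self.gmt_hallmark, self.gmt_oxidative,
                      self.gmt_signatures, self.gmt_populations,
                      *self.expression_files.values()]:
                if not Path(p).exists():
                    raise ConfigError(f"referenced file does not exist: {p}")
        else:
            self.synth.validate()
        bad = [f for f in self.model_families if f not in md.FAMILIES]
        if bad:
            raise ConfigError(f"unknown model families: {bad}")
        return self

    def digest(self) -> str:
        def _default(o):
            if hasattr(o, "__dict__"):
                return o.__dict__
            if isinstance(o, tuple):
                return list(o)
            return str(o)

        blob = json.dumps(self.__dict__, default=_default, sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _write_tsv(df: pd.DataFrame, path: Path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index, na_rep="NA", float_format="%.6g")


def _cluster_and_label(
    binary: ch.BinaryMatrix,
    config: PipelineConfig,
    hallmark: dict[str, list[str]],
    seed: int,
) -> tuple[cc.ConsensusResult, dict[str, str], pd.DataFrame, pd.DataFrame]:
    """Consensus-cluster one half and name the clusters OX+/IM+ by enrichment."""
    res = cc.consensus_cluster(
        binary, k=config.cc_k, reps=config.cc_reps, p_item=config.cc_p_item, seed=seed
    )
    cluster_of = dict(zip(res.samples, res.labels))
    lbl = np.array([f"cl{cluster_of[s]}" for s in binary.samples])
    diff = dg.binary_de(binary, lbl, group_order=("cl0", "cl1"))
    ranking = dg.make_ranking(diff)
    enr = dg.gsea_preranked(
        ranking, hallmark, n_perm=config.gsea_n_perm, seed=config.gsea_seed
    )
    mapping = dg.label_subtypes(
        enr, config.ox_marker_sets, config.im_marker_sets, cluster_names=("cl0", "cl1")
    )
    subtype_labels = {s: mapping[f"cl{c}"] for s, c in cluster_of.items()}
    return res, subtype_labels, diff, enr


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage; write outputs under ``config.outdir``; return the manifest."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config_digest": config.digest(),
        "stages": {},
        "timestamps": {},
    }

    def _stage(name: str):
        manifest["timestamps"][name] = time.strftime("%Y-%m-%dT%H:%M:%S")
        manifest["stages"][name] = {}
        return manifest["stages"][name]

    # -- stage: ingest / simulate ------------------------------------------
    rec = _stage("data")
    if config.synth is not None:
        datadir = outdir / "data"
        paths = sd.write_compendium(config.synth, datadir)
        matrices, clinical, truth = sd.generate_cohorts(config.synth)
        hallmark = dg.read_gmt(paths["gene_sets"]["hallmark"])
        oxidative = dg.read_gmt(paths["gene_sets"]["oxidative"])
        signatures = dg.read_gmt(paths["gene_sets"]["signatures"])
        populations = dg.read_gmt(paths["gene_sets"]["populations"])
        if config.gene_universe_file is None:
            config.gene_universe_file = paths["gene_universe"]
        rec.update(paths)
    else:
        matrices = [
            ch.read_expression(p, cohort_id=cid)
            for cid, p in sorted(config.expression_files.items())
        ]
        clinical = ch.read_clinical(config.clinical_file)
        truth = None
        hallmark = dg.read_gmt(config.gmt_hallmark)
        oxidative = dg.read_gmt(config.gmt_oxidative)
        signatures = dg.read_gmt(config.gmt_signatures)
        populations = dg.read_gmt(config.gmt_populations)
        rec["expression"] = dict(sorted(config.expression_files.items()))

    # -- stage: binarize + merge -------------------------------------------
    rec = _stage("integrate")
    binarized = [ch.binarize(m) for m in matrices]
    merged = ch.merge(binarized)
    merged.write(outdir / "merged_binary.tsv", sidecar=outdir / "merged_binary_meta.json")
    # batch diagnostic: silhouette of cohort labels before vs after binarization
    shared = set(merged.genes)
    cont_blocks = []
    for m in matrices:
        pos = {g: i for i, g in enumerate(m.genes)}
        cont_blocks.append(m.values[[pos[g] for g in merged.genes if g in pos], :])
    cont = np.concatenate(cont_blocks, axis=1)
    sil_before = ch.batch_silhouette(cont, merged.cohorts, scale=True)
    sil_after = ch.batch_silhouette(merged.values, merged.cohorts, scale=False)
    rec["n_samples"] = merged.n_samples
    rec["n_genes"] = merged.n_genes
    rec["silhouette_before"] = sil_before
    rec["silhouette_after"] = sil_after
    (outdir / "batch_silhouette.json").write_text(
        json.dumps({"before": sil_before, "after": sil_after}, indent=1)
    )

    # Analysis matrix: the curated gene universe (clustering, DE, panel);
    # characterization keeps the full gene complement.
    analysis = merged
    if config.gene_universe_file:
        universe = set(Path(config.gene_universe_file).read_text().split())
        keep = [g for g in merged.genes if g in universe]
        if len(keep) < 2:
            raise ConfigError("gene universe leaves fewer than 2 analysis genes")
        pos = {g: i for i, g in enumerate(merged.genes)}
        analysis = ch.BinaryMatrix(
            genes=keep,
            samples=merged.samples,
            cohorts=merged.cohorts,
            values=merged.values[[pos[g] for g in keep], :],
            thresholds=merged.thresholds,
        )
    manifest["stages"]["integrate"]["n_analysis_genes"] = analysis.n_genes

    # -- stage: split -------------------------------------------------------
    rec = _stage("split")
    (train_b, train_clin), (test_b, test_clin) = ch.split(
        merged, clinical, fraction=config.split_fraction, seed=config.split_seed
    )
    train_a = analysis.subset_samples(train_b.samples)
    test_a = analysis.subset_samples(test_b.samples)
    _write_tsv(pd.DataFrame({"sample_id": train_b.samples, "half": "training"}),
               outdir / "split_training.tsv")
    _write_tsv(pd.DataFrame({"sample_id": test_b.samples, "half": "testing"}),
               outdir / "split_testing.tsv")
    rec["n_training"] = train_b.n_samples
    rec["n_testing"] = test_b.n_samples

    # -- stage: cluster + label (training, and testing independently) -------
    rec = _stage("cluster")
    cons_tr, labels_tr, diff_tr, enr_tr = _cluster_and_label(
        train_a, config, hallmark, seed=config.cc_seed
    )
    cons_te, labels_te, diff_te, enr_te = _cluster_and_label(
        test_a, config, hallmark, seed=config.cc_seed + 1
    )
    cons_tr.write(outdir, prefix="consensus_training")
    cons_te.write(outdir, prefix="consensus_testing")
    for nm, labels in (("training", labels_tr), ("testing", labels_te)):
        _write_tsv(
            pd.DataFrame(sorted(labels.items()), columns=["sample_id", "subtype"]),
            outdir / f"subtypes_{nm}.tsv",
        )
    # re-orient differential tables so positive log2fc = higher in OX+
    def _oriented_diff(binary, labels):
        lbl = np.array([labels[s] for s in binary.samples])
        return dg.binary_de(binary, lbl, group_order=("OX+", "IM+"))

    diff_tr = _oriented_diff(train_a, labels_tr)
    diff_te = _oriented_diff(test_a, labels_te)
    _write_tsv(diff_tr, outdir / "diff_training.tsv")
    _write_tsv(diff_te, outdir / "diff_testing.tsv")
    _write_tsv(enr_tr, outdir / "enrichment_training.tsv")
    _write_tsv(enr_te, outdir / "enrichment_testing.tsv")
    rec["training_subtype_counts"] = dict(pd.Series(list(labels_tr.values())).value_counts())
    rec["testing_subtype_counts"] = dict(pd.Series(list(labels_te.values())).value_counts())
    rec = {k: (int(v) if isinstance(v, np.integer) else v) for k, v in rec.items()}
    manifest["stages"]["cluster"] = {
        "training_subtype_counts": {k: int(v) for k, v in rec["training_subtype_counts"].items()},
        "testing_subtype_counts": {k: int(v) for k, v in rec["testing_subtype_counts"].items()},
    }

    # -- stage: characterize -------------------------------------------------
    rec = _stage("characterize")
    all_labels = {**labels_tr, **labels_te}
    char_rows = []
    for half, binary, labels, clin in (
        ("training", train_b, labels_tr, train_clin),
        ("testing", test_b, labels_te, test_clin),
    ):
        lbl = np.array([labels[s] for s in binary.samples])
        score_tbl = pd.DataFrame(index=binary.samples)
        for set_name, members in oxidative.items():
            score_tbl[set_name] = sc.ssgsea(binary, members).to_numpy()
        est = sc.estimate_scores(
            binary,
            signatures["SYN_IMMUNE_SIGNATURE"],
            signatures["SYN_STROMAL_SIGNATURE"],
        )
        est.index = binary.samples
        score_tbl = pd.concat([score_tbl, est], axis=1)
        pops = sc.marker_scores(binary.values, populations, genes=binary.genes)
        pops.index = binary.samples
        score_tbl = pd.concat([score_tbl, pops], axis=1)
        score_tbl.insert(0, "subtype", lbl)
        score_tbl.index.name = "sample_id"
        _write_tsv(score_tbl, outdir / f"scores_{half}.tsv", index=True)
        for col in score_tbl.columns.drop("subtype"):
            stat, p = sc.wilcoxon_compare(score_tbl[col].to_numpy(), lbl)
            med = score_tbl.groupby("subtype")[col].median()
            higher = med.idxmax() if med.nunique() > 1 else "tie"
            char_rows.append(
                {"half": half, "score": col, "statistic": stat, "p": p, "higher_in": higher}
            )
        clin_cmp = sv.compare_clinical(clin, labels)
        _write_tsv(clin_cmp, outdir / f"clinical_compare_{half}.tsv")
        # subtype survival
        times = clin.set_index("sample_id").loc[binary.samples, "os_time_years"].to_numpy()
        events = clin.set_index("sample_id").loc[binary.samples, "os_event"].to_numpy(dtype=int)
        lr = sv.logrank(times, events, lbl)
        km_frames = [
            sv.km_estimate(times[lbl == s], events[lbl == s], s).to_frame()
            for s in ("OX+", "IM+")
        ]
        _write_tsv(pd.concat(km_frames, ignore_index=True), outdir / f"km_subtypes_{half}.tsv")
        manifest["stages"]["characterize"][f"logrank_{half}"] = {
            "chi_square": lr.chi_square, "p": lr.p,
        }
    _write_tsv(pd.DataFrame(char_rows), outdir / "score_comparisons.tsv")
    ckpt = sc.checkpoint_compare(matrices, all_labels, genes=tuple(config.checkpoint_genes))
    _write_tsv(ckpt, outdir / "checkpoint_compare.tsv")

    # -- stage: panel selection ---------------------------------------------
    rec = _stage("select")
    candidates = md.filter_degs(
        diff_tr, lfc_min=config.deg_lfc_min, padj_max=config.deg_padj_max
    )
    rec["n_candidates"] = len(candidates)
    if len(candidates) < 2:
        raise RuntimeError("stage select: fewer than 2 filter-passing genes")
    y_tr = np.array([1 if labels_tr[s] == "OX+" else 0 for s in train_a.samples])
    pos = {g: i for i, g in enumerate(train_a.genes)}
    X_tr = train_a.values[[pos[g] for g in candidates], :].T.astype(float)
    sel = md.select_size(
        X_tr, y_tr, candidates,
        sizes=config.rfe_sizes, folds=config.cv_folds,
        seed=config.model_seed, tolerance=config.rfe_tolerance,
    )
    _write_tsv(
        pd.DataFrame(
            {"size": sel.sizes, "cv_accuracy": [sel.accuracy[s] for s in sel.sizes]}
        ),
        outdir / "panel_sizes.tsv",
    )
    (outdir / "panel.json").write_text(
        json.dumps({"size": sel.chosen_size, "genes": sel.genes}, indent=1)
    )
    rec["panel_size"] = sel.chosen_size
    rec["panel"] = sel.genes

    # -- stage: train + evaluate ---------------------------------------------
    rec = _stage("models")
    panel_idx = [pos[g] for g in sel.genes]
    Xp_tr = train_a.values[panel_idx, :].T.astype(float)
    pos_te = {g: i for i, g in enumerate(test_a.genes)}
    Xp_te = test_a.values[[pos_te[g] for g in sel.genes], :].T.astype(float)
    y_te = np.array([1 if labels_te[s] == "OX+" else 0 for s in test_a.samples])
    model_rows = []
    fitted = {}
    for family in config.model_families:
        gs = md.cv_grid_search(
            Xp_tr, y_tr, family,
            grid=config.model_grids.get(family),
            folds=config.cv_folds, replicates=config.cv_replicates,
            seed=config.model_seed,
        )
        _write_tsv(gs.table, outdir / f"grid_{family}.tsv")
        model = md.train_final(
            Xp_tr, y_tr, family, gs.best_params, genes=sel.genes, seed=config.model_seed
        )
        ev = md.evaluate(model, Xp_te, y_te)
        fitted[family] = model
        model_rows.append(
            {
                "family": family,
                "best_params": json.dumps(gs.best_params, sort_keys=True),
                "cv_auc": gs.best_auc,
                "cv_accuracy": gs.best_accuracy,
                "test_auc": ev.auc,
                "test_accuracy": ev.accuracy,
            }
        )
    model_tbl = pd.DataFrame(model_rows)
    _write_tsv(model_tbl, outdir / "model_evaluation.tsv")
    rec["evaluation"] = model_rows
    (outdir / "model_manifest.json").write_text(
        json.dumps({f: m.manifest() for f, m in fitted.items()}, indent=1, sort_keys=True)
    )

    # -- stage: importance + per-gene survival --------------------------------
    rec = _stage("survival")
    imp = md.importance(Xp_tr, y_tr, sel.genes)
    imp_df = imp.rename("importance").reset_index().rename(columns={"index": "gene"})
    _write_tsv(imp_df, outdir / "importance.tsv")
    rec["hub_gene"] = imp.index[0]
    for half, binary, clin in (
        ("training", train_b, train_clin),
        ("testing", test_b, test_clin),
    ):
        gs_tbl = sv.gene_survival(binary, clin, sel.genes)
        _write_tsv(gs_tbl, outdir / f"gene_survival_{half}.tsv")

    if truth is not None:
        from sklearn.metrics import adjusted_rand_score

        truth_tr = [truth.subtype[s] for s in train_b.samples]
        pred_tr = [labels_tr[s] for s in train_b.samples]
        manifest["recovery"] = {
            "training_ari": float(adjusted_rand_score(truth_tr, pred_tr)),
            "testing_ari": float(
                adjusted_rand_score(
                    [truth.subtype[s] for s in test_b.samples],
                    [labels_te[s] for s in test_b.samples],
                )
            ),
        }

    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
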