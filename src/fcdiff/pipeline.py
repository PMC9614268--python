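"""End-to-end orchestration: simulate -> Pearson FC -> partial FC -> edge
Score -> effect-size selection -> dual-channel classifier.

A single :class:`RunConfig` (YAML-serialisable) drives the whole run.  Every
stage writes its outputs as TSV/JSON into the run directory, stages
communicate only through those documented files, and a manifest of SHA-256
output hashes plus the fully resolved config are written so a run can be
audited and reproduced bit-for-bit from its seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import edge_score as es_mod
from . import features as feat_mod
from . import partial as partial_mod
from . import pearson as pearson_mod
from . import synthetic as syn_mod
from . import tlnn as tlnn_mod

__all__ = ["RunConfig", "run_pipeline"]

log = logging.getLogger("fcdiff")

_STAGES = ("simulate", "pearson", "partial", "edge_score", "select", "train")


@dataclass
class RunConfig:
    """All pipeline parameters; defaults follow the study's printed values
    (binarization 0.1, 1e5 permutations, P < 0.001, p-FDR < 0.05, side 22,
    Adam / lr 1e-3 / batch 32 / 60 epochs / dropouts 0.1 and 0.2)."""

    out_dir: str = "fcdiff_run"
    seed: int = 0
    manifest: str | None = None  # path to an existing cohort manifest; None -> simulate
    synthetic: dict = field(default_factory=dict)  # SyntheticConfig overrides
    stages: list[str] = field(default_factory=lambda: list(_STAGES))
    # pearson stage
    fdr_alpha: float = 0.05
    equal_var: bool = True
    # partial stage
    glasso_alpha: float | str = "cv"
    binarize_threshold: float = 0.1
    # edge score stage
    n_perm: int = 100_000
    score_alpha: float = 0.001
    tail: str = "two_sided"
    # feature selection
    side: int = 22
    es_denominator: str = "as_defined"
    # classifier
    train: dict = field(default_factory=dict)  # TrainConfig overrides
    test_size: int = 50
    eval_mode: str = "single"  # or "repeated"
    n_splits: int = 5

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))


def _stage_seed(seed: int, stage: str) -> int:
    k = _STAGES.index(stage)
    return int(np.random.SeedSequence(seed, spawn_key=(k,)).generate_state(1)[0] % (2**31))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _edge_features(mats: list[np.ndarray]) -> np.ndarray:
    n_rois = mats[0].shape[0]
    iu, ju = np.triu_indices(n_rois, k=1)
    return np.stack([m[iu, ju] for m in mats])


def run_pipeline(config: RunConfig) -> Path:
    """Execute the configured stages; returns the run directory.

    Stage toggles (``config.stages``) allow stopping early; each later stage
    re-reads its inputs from the files the earlier stage wrote.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=logging.INFO, format="%(name)s %(levelname)s %(message)s")
    unknown = set(config.stages) - set(_STAGES)
    if unknown:
        raise ValueError(f"unknown stage(s) {sorted(unknown)}")
    config.to_yaml(out / "config.yaml")
    outputs: list[Path] = [out / "config.yaml"]

    # ---- cohort -----------------------------------------------------------
    if config.manifest is not None:
        cohort = syn_mod.read_cohort(config.manifest)
        log.info("loaded cohort of %d subjects from %s", len(cohort.subjects), config.manifest)
    else:
        syn_cfg = syn_mod.SyntheticConfig(**{"seed": _stage_seed(config.seed, "simulate"), **config.synthetic})
        _, _, truth = syn_mod.make_group_covariances(syn_cfg)
        cohort = syn_mod.generate_cohort(syn_cfg)
        cohort_dir = out / "cohort"
        outputs.append(syn_mod.write_cohort(cohort, cohort_dir))
        outputs.extend(sorted(cohort_dir.glob("sub-*.tsv")))
        syn_mod.write_truth(truth, out / "truth.tsv")
        outputs.append(out / "truth.tsv")
        log.info("simulated cohort: %d subjects, %d ROIs", len(cohort.subjects), syn_cfg.n_rois)
    labels = cohort.labels
    label_order = tuple(dict.fromkeys(labels.tolist()))
    sids = [s.subject_id for s in cohort.subjects]

    # ---- Pearson stage ----------------------------------------------------
    if "pearson" in config.stages:
        fc = [pearson_mod.pearson_fc_matrix(s.series, s.subject_id) for s in cohort.subjects]
        zfeat = _edge_features([m.z for m in fc])
        zdf = pd.DataFrame(zfeat, columns=partial_mod._edge_columns(fc[0].z.shape[0]))
        zdf.insert(0, "subject_id", sids)
        zdf.to_csv(out / "pearson_z.tsv", sep="\t", index=False, float_format="%.8g")
        ttable = pearson_mod.edge_group_ttest(
            fc, labels, group_order=label_order, alpha=config.fdr_alpha, equal_var=config.equal_var
        )
        ttable.to_csv(out / "pearson_edge_stats.tsv", sep="\t", index=False, float_format="%.8g")
        outputs += [out / "pearson_z.tsv", out / "pearson_edge_stats.tsv"]
        log.info("pearson: %d significant edges at p_fdr < %g", int(ttable.significant.sum()), config.fdr_alpha)

    # ---- partial stage ----------------------------------------------------
    if "partial" in config.stages:
        pcs = [
            partial_mod.glasso_partial_corr(s.series, config.glasso_alpha, s.subject_id)
            for s in cohort.subjects
        ]
        pcfeat = _edge_features([p.pc for p in pcs])
        pcdf = pd.DataFrame(pcfeat, columns=partial_mod._edge_columns(pcs[0].pc.shape[0]))
        pcdf.insert(0, "subject_id", sids)
        pcdf.to_csv(out / "partial_pc.tsv", sep="\t", index=False, float_format="%.8g")
        adjacencies = [partial_mod.binarize(p, config.binarize_threshold) for p in pcs]
        partial_mod.write_adjacency_stack(adjacencies, out / "adjacency.tsv")
        outputs += [out / "partial_pc.tsv", out / "adjacency.tsv"]
        log.info("partial: mean edge density %.3f", float(np.mean([a.adj.mean() for a in adjacencies])))

    # ---- edge score stage -------------------------------------------------
    if "edge_score" in config.stages:
        adjacencies = partial_mod.read_adjacency_stack(out / "adjacency.tsv", config.binarize_threshold)
        score_table = es_mod.permutation_p(
            adjacencies,
            labels,
            n_perm=config.n_perm,
            seed=_stage_seed(config.seed, "edge_score"),
            tail=config.tail,
            alpha=config.score_alpha,
            group_order=label_order,
        )
        es_mod.write_edge_score_table(score_table, out / "edge_scores.tsv")
        outputs.append(out / "edge_scores.tsv")
        log.info(
            "edge score: %d edges with P < %g (n_perm=%d)",
            int(score_table.significant.sum()), config.score_alpha, config.n_perm,
        )

    # ---- feature selection ------------------------------------------------
    if "select" in config.stages:
        g1 = labels == label_order[0]
        layouts = {}
        for channel, fname in (("pearson", "pearson_z.tsv"), ("partial", "partial_pc.tsv")):
            df = pd.read_csv(out / fname, sep="\t", dtype={"subject_id": str})
            vals = df.drop(columns="subject_id").to_numpy(float)
            est = feat_mod.cohens_effect_size(vals[g1], vals[~g1], config.es_denominator)
            est.to_csv(out / f"effect_size_{channel}.tsv", sep="\t", index=False, float_format="%.8g")
            layout = feat_mod.select_channel(est, config.side)
            layout.to_json(out / f"layout_{channel}.json")
            layouts[channel] = layout
            outputs += [out / f"effect_size_{channel}.tsv", out / f"layout_{channel}.json"]
        log.info("select: kept %d features per channel", config.side**2)

    # ---- classifier -------------------------------------------------------
    if "train" in config.stages:
        layouts = (
            feat_mod.ChannelLayout.from_json(out / "layout_pearson.json"),
            feat_mod.ChannelLayout.from_json(out / "layout_partial.json"),
        )
        zdf = pd.read_csv(out / "pearson_z.tsv", sep="\t", dtype={"subject_id": str})
        pcdf = pd.read_csv(out / "partial_pc.tsv", sep="\t", dtype={"subject_id": str})
        pf = {r[0]: np.array(r[1:], float) for r in zdf.itertuples(index=False)}
        qf = {r[0]: np.array(r[1:], float) for r in pcdf.itertuples(index=False)}
        label_map = dict(zip(sids, labels))
        feats = tlnn_mod.build_dual_channel(pf, qf, layouts, label_map)
        tcfg = tlnn_mod.TrainConfig(**{"seed": _stage_seed(config.seed, "train"), **config.train})
        positive = label_order[0]
        if config.eval_mode == "repeated":
            results, mean = tlnn_mod.repeated_evaluate(
                feats, tcfg, config.test_size, config.n_splits, positive
            )
            metrics_out = {"splits": [r.to_dict() for r in results], "mean": mean}
            (out / "metrics.json").write_text(json.dumps(metrics_out, indent=1))
            outputs.append(out / "metrics.json")
            log.info("train (repeated x%d): mean accuracy %.1f%%", config.n_splits, mean["accuracy"])
        else:
            train_idx, test_idx = tlnn_mod.stratified_split(
                [f.label for f in feats], config.test_size, tcfg.seed
            )
            train = [feats[i] for i in train_idx]
            test = [feats[i] for i in test_idx]
            stats = tlnn_mod.channel_norm_stats(train)
            model, history = tlnn_mod.train_classifier(
                tlnn_mod.normalize_channels(train, stats), tcfg, positive
            )
            metrics = tlnn_mod.evaluate(model, tlnn_mod.normalize_channels(test, stats))
            metrics.to_json(out / "metrics.json")
            history.to_csv(out / "history.tsv", sep="\t", index=False, float_format="%.8g")
            pd.DataFrame(metrics.roc_points, columns=["fpr", "tpr"]).to_csv(
                out / "roc.tsv", sep="\t", index=False, float_format="%.8g"
            )
            outputs += [out / "metrics.json", out / "history.tsv", out / "roc.tsv"]
            log.info(
                "train: accuracy %.1f%%, sensitivity %.1f%%, specificity %.1f%%, AUC %.3f",
                metrics.accuracy, metrics.sensitivity, metrics.specificity, metrics.auc,
            )

    hashes = {str(p.relative_to(out)): _sha256(p) for p in outputs if p.exists()}
    (out / "manifest.json").write_text(json.dumps(hashes, indent=1, sort_keys=True))
    return out
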