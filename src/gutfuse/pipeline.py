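"""End-to-end orchestration and the plain-text model bundle.

``run_pipeline`` reproduces the full analysis shape on a synthetic
cohort: simulate -> per-channel PLS-DA with leave-one-out posteriors ->
Bayesian fusion -> patient discrimination index -> diagnostic reports.
All artifacts are TSV/JSON text; identical configs give byte-identical
outputs.

Trained models are stored in a diffable key-value + matrix-block text
format (the "bundle") holding, per channel, the scaling parameters,
NIPALS weights/loadings, regression vector and posterior calibration,
plus the PDI entries, so new samples can be classified without refitting.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .evaluation import confusion_metrics, roc_curve
from .fusion import FusedPosterior, fuse_cohort
from .io import (FeatureTable, SampleMeta, write_feature_table,
                 write_sample_meta)
from .pdi import PDIEntry, PDIModel, build_pdi, pdi_cohort
from .plsda import (ChannelPosterior, PLSDAClassifier, PosteriorCalibration,
                    ScalingParams, fit_channel_model, loocv_posteriors,
                    posterior_assignments, predict_posteriors)
from .simulate import CohortConfig, CohortTruth, generate_cohort

log = logging.getLogger("gutfuse")

BUNDLE_MAGIC = "gutfuse-bundle"
BUNDLE_VERSION = "1"


# --------------------------------------------------------------------------
# model bundle
# --------------------------------------------------------------------------

def _fmt(x: float) -> str:
    return repr(float(x))


def _vector_line(name: str, v) -> str:
    return "\t".join([name] + [_fmt(x) for x in np.asarray(v, float).ravel()])


def _write_channel(fh, name: str, model: PLSDAClassifier) -> None:
    fh.write(f"[channel\t{name}]\n")
    fh.write("\t".join(["feature_ids"] + list(model.feature_ids_)) + "\n")
    fh.write(_vector_line("mean", model.scaling_.mean) + "\n")
    fh.write(_vector_line("sd", model.scaling_.sd) + "\n")
    fh.write(f"y_mean\t{_fmt(model.y_mean_)}\n")
    fh.write(_vector_line("y_loadings", model.y_loadings_) + "\n")
    fh.write(_vector_line("coef", model.coef_) + "\n")
    cal = model.calibration_
    fh.write(_vector_line("calibration",
                          [cal.mu_ibs, cal.sd_ibs, cal.mu_hlt, cal.sd_hlt,
                           cal.prior_ibs]) + "\n")
    for mat_name, M in (("weights", model.x_weights_),
                        ("x_loadings", model.x_loadings_)):
        fh.write(f"[matrix\t{name}\t{mat_name}\t{M.shape[0]}\t{M.shape[1]}]\n")
        for row in M:
            fh.write("\t".join(_fmt(x) for x in row) + "\n")


def save_bundle(path, genus_model: PLSDAClassifier, metab_model: PLSDAClassifier,
                pdi_model: PDIModel) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"{BUNDLE_MAGIC}\t{BUNDLE_VERSION}\n")
        fh.write(f"n_components\t{genus_model.n_components}\n")
        fh.write(f"prior_ibs\t{_fmt(genus_model.prior_ibs)}\n")
        _write_channel(fh, "genus", genus_model)
        _write_channel(fh, "metabolite", metab_model)
        fh.write(f"[pdi\t{pdi_model.k}]\n")
        for e in pdi_model.entries:
            fh.write("\t".join([e.feature_id, e.channel, str(e.direction),
                                _fmt(e.training_median), _fmt(e.epsilon)]) + "\n")
        fh.write("[end]\n")


@dataclass
class ModelBundle:
    genus_model: PLSDAClassifier
    metab_model: PLSDAClassifier
    pdi_model: PDIModel


def _rebuild_model(fields: dict, n_components: int, prior_ibs: float,
                   matrices: dict) -> PLSDAClassifier:
    clf = PLSDAClassifier(n_components=n_components, prior_ibs=prior_ibs)
    clf.feature_ids_ = fields["feature_ids"]
    clf.scaling_ = ScalingParams(np.array(fields["mean"]), np.array(fields["sd"]))
    clf.y_mean_ = fields["y_mean"][0]
    clf.y_loadings_ = np.array(fields["y_loadings"])
    clf.coef_ = np.array(fields["coef"])
    mu_i, sd_i, mu_h, sd_h, prior = fields["calibration"]
    clf.calibration_ = PosteriorCalibration(mu_i, sd_i, mu_h, sd_h, prior)
    clf.x_weights_ = matrices["weights"]
    clf.x_loadings_ = matrices["x_loadings"]
    clf.classes_ = np.array(["HLT", "IBS"])
    return clf


def load_bundle(path) -> ModelBundle:
    lines = Path(path).read_text(encoding="utf-8").splitlines()
    if not lines or lines[0].split("\t")[0] != BUNDLE_MAGIC:
        raise ValueError(f"{path}: not a model bundle")
    i = 1
    header: dict[str, float] = {}
    while i < len(lines) and not lines[i].startswith("["):
        key, val = lines[i].split("\t")
        header[key] = float(val)
        i += 1
    n_components = int(header["n_components"])
    prior_ibs = header["prior_ibs"]

    channels: dict[str, dict] = {}
    mats: dict[str, dict] = {}
    pdi_entries: list[PDIEntry] = []
    pdi_k = 0
    while i < len(lines):
        parts = lines[i].strip("[]").split("\t")
        if parts[0] == "channel":
            name = parts[1]
            channels[name] = {}
            mats.setdefault(name, {})
            i += 1
            while i < len(lines) and not lines[i].startswith("["):
                toks = lines[i].split("\t")
                if toks[0] == "feature_ids":
                    channels[name]["feature_ids"] = toks[1:]
                else:
                    channels[name][toks[0]] = [float(x) for x in toks[1:]]
                i += 1
        elif parts[0] == "matrix":
            name, mat_name, nrow, ncol = parts[1], parts[2], int(parts[3]), int(parts[4])
            rows = [[float(x) for x in lines[i + 1 + r].split("\t")]
                    for r in range(nrow)]
            mats.setdefault(name, {})[mat_name] = np.array(rows).reshape(nrow, ncol)
            i += 1 + nrow
        elif parts[0] == "pdi":
            pdi_k = int(parts[1])
            i += 1
            while i < len(lines) and not lines[i].startswith("["):
                fid, channel, direction, med, eps = lines[i].split("\t")
                pdi_entries.append(PDIEntry(fid, channel, int(direction),
                                            float(med), float(eps)))
                i += 1
        elif parts[0] == "end":
            break
        else:
            raise ValueError(f"{path}: unknown section {parts[0]!r}")
    return ModelBundle(
        _rebuild_model(channels["genus"], n_components, prior_ibs, mats["genus"]),
        _rebuild_model(channels["metabolite"], n_components, prior_ibs,
                       mats["metabolite"]),
        PDIModel(pdi_entries, pdi_k),
    )


# --------------------------------------------------------------------------
# pipeline
# --------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    cohort: CohortConfig = field(default_factory=CohortConfig)
    n_components: int = 2
    pdi_k: int = 3
    prior_ibs: float = 0.5
    output_dir: str = "gutfuse_out"
    log_level: str = "info"

    def __post_init__(self) -> None:
        if not (0.0 < self.prior_ibs < 1.0):
            raise ValueError("prior_ibs must be in (0, 1)")
        if self.pdi_k < 1 or self.n_components < 1:
            raise ValueError("pdi_k and n_components must be >= 1")


def _posterior_frame(posteriors: list[ChannelPosterior]) -> pd.DataFrame:
    return pd.DataFrame({
        "sample_id": [p.sample_id for p in posteriors],
        "p_ibs": [p.p_ibs for p in posteriors],
        "assigned_group": posterior_assignments(posteriors),
    })


def _fused_frame(fused: list[FusedPosterior]) -> pd.DataFrame:
    return pd.DataFrame({
        "sample_id": [f.sample_id for f in fused],
        "p_m": [f.p_m for f in fused],
        "p_c": [f.p_c for f in fused],
        "p_fused": [f.p_fused for f in fused],
        "assigned_group": [f.assigned_group for f in fused],
        "confidence": [f.confidence for f in fused],
    })


def _write_json(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n",
                    encoding="utf-8")


def _write_roc(roc, path: Path) -> None:
    pd.DataFrame({"threshold": roc.thresholds, "fpr": roc.fpr,
                  "tpr": roc.tpr}).to_csv(path, sep="\t", index=False)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full synthetic analysis; returns the manifest (also written)."""
    logging.basicConfig()
    log.setLevel(getattr(logging, config.log_level.upper(), logging.INFO))
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: list[str] = []

    def emit(name: str) -> Path:
        artifacts.append(name)
        return out / name

    stage = "simulate"
    try:
        genus, metab, meta, truth = generate_cohort(config.cohort)
        log.info("simulated cohort: %d samples, %d genera, %d metabolites",
                 genus.n_samples, genus.n_features, metab.n_features)
        write_feature_table(genus, emit("genus.tsv"))
        write_feature_table(metab, emit("metabolites.tsv"))
        write_sample_meta(meta, emit("meta.tsv"))
        pd.DataFrame({
            "feature_id": truth.driver_feature_ids,
            "direction": truth.driver_direction,
            "realized_fold_change": truth.realized_fold_changes,
        }).to_csv(emit("truth.tsv"), sep="\t", index=False)

        stage = "loocv"
        post_g = loocv_posteriors(genus, meta, config.n_components, config.prior_ibs)
        post_m = loocv_posteriors(metab, meta, config.n_components, config.prior_ibs)
        _posterior_frame(post_g).to_csv(emit("posteriors_genus.tsv"),
                                        sep="\t", index=False)
        _posterior_frame(post_m).to_csv(emit("posteriors_metabolite.tsv"),
                                        sep="\t", index=False)

        stage = "fuse"
        fused = fuse_cohort(post_g, post_m, config.prior_ibs)
        _fused_frame(fused).to_csv(emit("fused.tsv"), sep="\t", index=False)

        stage = "fit"
        genus_model = fit_channel_model(genus, meta, config.n_components,
                                        config.prior_ibs)
        metab_model = fit_channel_model(metab, meta, config.n_components,
                                        config.prior_ibs)

        stage = "pdi"
        pdi_model = build_pdi(genus_model, metab_model, genus, metab, config.pdi_k)
        pdi_values = pdi_cohort(genus, metab, pdi_model)
        pd.DataFrame({"sample_id": genus.sample_ids,
                      "pdi": pdi_values}).to_csv(emit("pdi_values.tsv"),
                                                 sep="\t", index=False)
        save_bundle(emit("model_bundle.txt"), genus_model, metab_model, pdi_model)

        stage = "evaluate"
        true_groups = list(meta.group)
        reports = {}
        for name, posts in (("genus", post_g), ("metabolite", post_m)):
            rep = confusion_metrics(true_groups, posterior_assignments(posts),
                                    [max(p.p_ibs, 1 - p.p_ibs) for p in posts])
            roc = roc_curve([p.p_ibs for p in posts], true_groups)
            d = rep.to_dict()
            d["auc"] = roc.auc
            reports[name] = d
            _write_json(d, emit(f"eval_{name}.json"))
            _write_roc(roc, emit(f"roc_{name}.tsv"))
        rep = confusion_metrics(true_groups, [f.assigned_group for f in fused],
                                [f.confidence for f in fused])
        roc = roc_curve([f.p_fused for f in fused], true_groups)
        d = rep.to_dict()
        d["auc"] = roc.auc
        reports["fused"] = d
        _write_json(d, emit("eval_fused.json"))
        _write_roc(roc, emit("roc_fused.tsv"))

        k_max = min(5, genus.n_features, metab.n_features)
        for k in range(1, k_max + 1):
            pk = build_pdi(genus_model, metab_model, genus, metab, k)
            vals = pdi_cohort(genus, metab, pk)
            assigned = ["IBS" if v >= 0 else "HLT" for v in vals]
            rep = confusion_metrics(true_groups, assigned)
            roc = roc_curve(vals, true_groups)
            d = rep.to_dict()
            d["auc"] = roc.auc
            reports[f"pdi_k{k}"] = d
            _write_json(d, emit(f"eval_pdi_k{k}.json"))
            _write_roc(roc, emit(f"roc_pdi_k{k}.tsv"))
        for name, d in reports.items():
            log.info("%s: accuracy=%.3f auc=%.3f", name, d["accuracy"], d["auc"])
    except Exception:
        log.error("pipeline failed at stage %r", stage)
        raise

    manifest = {
        "software": {"name": "gutfuse", "version": __version__},
        "config": dataclasses.asdict(config),
        "seed": config.cohort.seed,
        "artifacts": sorted(artifacts),
    }
    _write_json(manifest, out / "manifest.json")
    return manifest


def classify_new_samples(
    bundle: ModelBundle | str | Path, genus: FeatureTable, metab: FeatureTable
) -> pd.DataFrame:
    """Classify unlabeled two-channel samples with a trained bundle.

    No refitting: scaling, calibration and PDI training medians are all
    reused from the bundle.  Returns one row per sample with columns
    sample_id, p_m, p_c, p_fused, assigned_group, confidence, pdi.
    """
    if not isinstance(bundle, ModelBundle):
        bundle = load_bundle(bundle)
    if genus.sample_ids != metab.sample_ids:
        raise ValueError("genus and metabolite tables list different samples")
    cols = ["sample_id", "p_m", "p_c", "p_fused", "assigned_group",
            "confidence", "pdi"]
    if genus.n_samples == 0:
        return pd.DataFrame(columns=cols)
    post_m = predict_posteriors(bundle.genus_model, genus)
    post_c = predict_posteriors(bundle.metab_model, metab)
    fused = fuse_cohort(post_m, post_c, bundle.genus_model.prior_ibs)
    pdi_values = pdi_cohort(genus, metab, bundle.pdi_model)
    df = _fused_frame(fused)
    df["pdi"] = pdi_values
    return df[cols]
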