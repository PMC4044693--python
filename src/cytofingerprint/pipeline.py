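"""End-to-end pipeline: one config drives all four comparison methods.

All engines see the identical transformed event tables and histograms — a
precondition for comparing the methods on the same data set. Every artifact
is written with a manifest (inputs, parameters, seeds, tool version) and the
whole run is deterministic under a fixed config, so rerunning reproduces
byte-identical outputs.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, field
from itertools import combinations

import pandas as pd

from . import __version__
from .chic import chic_matrix
from .cybar import (
    ExternalParameters,
    abundance_table,
    correlate_gates,
    correlations_to_frame,
    cybar_matrix,
    normalize_cybar,
)
from .dalmatian import dalmatian_matrix, render_mask
from .dissim import DissimilarityMatrix
from .events import ChannelTransform, fingerprint_images, read_events, transform_channels
from .flowfp import fit_model, fp_matrix
from .gating import GateTemplate, build_template, count_in_gate, load_gate_set
from .indices import dynamics_all, dynamics_consecutive, index_table
from .stats import envfit, nmds, procrustes

__all__ = ["RunConfig", "run_pipeline", "PipelineError"]

log = logging.getLogger(__name__)

METHODS = ("dalmatian", "chic", "cybar", "flowfp")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """Validated pipeline configuration (see ``RunConfig.from_json``)."""

    experiment: str
    samples: list[dict]  # {"id", "path", optional "order", optional "gates"}
    methods: list[str]
    resolution: int = 128
    x_channel: str = "FSC"
    y_channel: str = "DNA"
    transforms: dict[str, str] = field(default_factory=dict)
    seed: int = 1
    n_perm: int = 999
    nmds_starts: int = 20
    dalmatian_mode: str = "binary"
    flowfp_recursions: int = 5
    flowfp_training: list[str] = field(default_factory=list)
    cybar_template: str | None = None
    metadata: str | None = None

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        with open(path) as fh:
            d = json.load(fh)
        cfg = cls(
            experiment=d.get("experiment", "experiment"),
            samples=d["samples"],
            methods=list(d.get("methods", METHODS)),
            resolution=int(d.get("resolution", 128)),
            x_channel=d.get("x_channel", "FSC"),
            y_channel=d.get("y_channel", "DNA"),
            transforms=d.get("transforms", {}),
            seed=int(d.get("seed", 1)),
            n_perm=int(d.get("n_perm", 999)),
            nmds_starts=int(d.get("nmds_starts", 20)),
            dalmatian_mode=d.get("dalmatian", {}).get("mode", "binary"),
            flowfp_recursions=int(d.get("flowfp", {}).get("recursions", 5)),
            flowfp_training=list(d.get("flowfp", {}).get("training", [])),
            cybar_template=d.get("cybar", {}).get("template"),
            metadata=d.get("metadata"),
        )
        cfg.base_dir = os.path.dirname(os.path.abspath(str(path)))
        return cfg

    base_dir: str = "."

    def _resolve(self, p: str) -> str:
        return p if os.path.isabs(p) else os.path.join(self.base_dir, p)

    def validate(self) -> None:
        if len(self.samples) < 2:
            raise PipelineError("config", "need at least 2 samples")
        bad = [m for m in self.methods if m not in METHODS]
        if bad:
            raise PipelineError("config", f"unknown methods: {bad}")
        ids = [s["id"] for s in self.samples]
        if len(set(ids)) != len(ids):
            raise PipelineError("config", "duplicate sample ids")
        missing = [s["path"] for s in self.samples
                   if not os.path.exists(self._resolve(s["path"]))]
        if "dalmatian" in self.methods:
            missing += [s["gates"] for s in self.samples
                        if "gates" in s and not os.path.exists(self._resolve(s["gates"]))]
            if any("gates" not in s for s in self.samples):
                raise PipelineError(
                    "config", "dalmatian requires a gate file per sample")
        if "cybar" in self.methods:
            if self.cybar_template is None:
                raise PipelineError("config", "cybar requires a gate template")
            if not os.path.exists(self._resolve(self.cybar_template)):
                missing.append(self.cybar_template)
        if self.metadata and not os.path.exists(self._resolve(self.metadata)):
            missing.append(self.metadata)
        if missing:
            raise PipelineError("config", f"missing input files: {missing}")
        if "flowfp" in self.methods:
            unknown = [t for t in self.flowfp_training if t not in ids]
            if unknown:
                raise PipelineError(
                    "config", f"flowfp training ids not in manifest: {unknown}")


def run_pipeline(cfg: RunConfig, out_dir) -> dict:
    """Execute every configured stage; returns the result manifest.

    Stage failures raise :class:`PipelineError` naming the stage (and sample
    where applicable); partial outputs already written are retained next to a
    ``FAILED`` marker file.
    """
    cfg.validate()
    os.makedirs(out_dir, exist_ok=True)
    manifest: dict = {
        "experiment": cfg.experiment,
        "version": __version__,
        "seed": cfg.seed,
        "resolution": cfg.resolution,
        "methods": cfg.methods,
        "n_perm": cfg.n_perm,
        "samples": cfg.samples,
        "outputs": {},
    }

    def fail(stage: str, msg: str):
        with open(os.path.join(out_dir, "FAILED"), "w") as fh:
            fh.write(f"{stage}: {msg}\n")
        return PipelineError(stage, msg)

    transforms = {c: ChannelTransform.parse(t) for c, t in cfg.transforms.items()}
    tables, order = [], []
    for s in cfg.samples:
        try:
            t = read_events(cfg._resolve(s["path"]), sample_id=s["id"])
            if transforms:
                t = transform_channels(t, transforms)
            tables.append(t)
        except Exception as exc:  # noqa: BLE001 - stage report
            raise fail("events", f"sample {s['id']!r}: {exc}") from exc
    by_id = {t.sample_id: t for t in tables}
    ordered = sorted(cfg.samples, key=lambda s: s.get("order", 0))
    order = [s["id"] for s in ordered] if any("order" in s for s in cfg.samples) else []

    matrices: dict[str, DissimilarityMatrix] = {}
    try:
        # gray images feed CHIC and the Rr/So indices
        images = fingerprint_images(
            tables, x_channel=cfg.x_channel, y_channel=cfg.y_channel,
            resolution=cfg.resolution,
        )
    except Exception as exc:
        raise fail("fingerprint", str(exc)) from exc

    if "chic" in cfg.methods:
        matrices["chic"] = chic_matrix(images)
    if "dalmatian" in cfg.methods:
        try:
            masks = []
            for s, t in zip(cfg.samples, tables):
                gs = load_gate_set(cfg._resolve(s["gates"]), sample_id=s["id"])
                counts = {g.name: count_in_gate(t, g) for g in gs.gates}
                masks.append(render_mask(gs, cfg.resolution, cfg.dalmatian_mode,
                                         counts=counts))
            matrices["dalmatian"] = dalmatian_matrix(masks)
        except Exception as exc:
            raise fail("dalmatian", str(exc)) from exc
    if "cybar" in cfg.methods:
        try:
            tpl = GateTemplate.from_json(cfg._resolve(cfg.cybar_template))
            abund = abundance_table(tables, tpl)
            abund.to_tsv(os.path.join(out_dir, "cybar_abundance.tsv"))
            normalize_cybar(abund).to_tsv(os.path.join(out_dir, "cybar_barcode.tsv"))
            matrices["cybar"] = cybar_matrix(abund)
        except Exception as exc:
            raise fail("cybar", str(exc)) from exc
    if "flowfp" in cfg.methods:
        try:
            train_ids = cfg.flowfp_training or [t.sample_id for t in tables[:2]]
            model = fit_model([by_id[i] for i in train_ids], cfg.flowfp_recursions,
                              channels=(cfg.x_channel, cfg.y_channel))
            model.to_json(os.path.join(out_dir, "flowfp_model.json"))
            matrices["flowfp"] = fp_matrix(model, tables)
        except Exception as exc:
            raise fail("flowfp", str(exc)) from exc

    ordinations = {}
    for name, mat in matrices.items():
        mat.to_tsv(os.path.join(out_dir, f"{name}_matrix.tsv"))
        manifest["outputs"][f"{name}_matrix"] = f"{name}_matrix.tsv"
        try:
            ordinations[name] = nmds(mat, n_starts=cfg.nmds_starts, seed=cfg.seed)
            ordinations[name].to_tsv(os.path.join(out_dir, f"{name}_nmds.tsv"))
        except Exception as exc:
            raise fail("nmds", f"method {name}: {exc}") from exc

    proc_rows = []
    for m1, m2 in combinations(sorted(ordinations), 2):
        pr = procrustes(ordinations[m1], ordinations[m2], n_perm=cfg.n_perm,
                        seed=cfg.seed)
        proc_rows.append({"a": m1, "b": m2, "m_squared": pr.m_squared,
                          "correlation": pr.correlation, "p_value": pr.p_value})
    if proc_rows:
        pd.DataFrame(proc_rows).to_csv(
            os.path.join(out_dir, "procrustes.tsv"), sep="\t", index=False)
        manifest["outputs"]["procrustes"] = "procrustes.tsv"

    idx = index_table(images)
    for name, mat in matrices.items():
        idx[f"Da_{name}"] = dynamics_all(mat)
        if order:
            idx[f"Dy_{name}"] = dynamics_consecutive(mat, order)
    idx.to_csv(os.path.join(out_dir, "indices.tsv"), sep="\t", index=False)
    manifest["outputs"]["indices"] = "indices.tsv"

    if cfg.metadata:
        try:
            params = ExternalParameters.from_tsv(cfg._resolve(cfg.metadata))
            env_rows = []
            for name, o in ordinations.items():
                for r in envfit(o, params, n_perm=cfg.n_perm, seed=cfg.seed):
                    env_rows.append({"method": name, "parameter": r.name,
                                     "r_squared": r.r_squared,
                                     "p_value": r.p_value, "n": r.n_used,
                                     "reason": r.reason})
            pd.DataFrame(env_rows).to_csv(
                os.path.join(out_dir, "envfit.tsv"), sep="\t", index=False)
            manifest["outputs"]["envfit"] = "envfit.tsv"
            if "cybar" in cfg.methods:
                corr = correlate_gates(abund, params, n_perm=cfg.n_perm,
                                       seed=cfg.seed)
                correlations_to_frame(corr).to_csv(
                    os.path.join(out_dir, "cybar_correlations.tsv"),
                    sep="\t", index=False)
                manifest["outputs"]["cybar_correlations"] = "cybar_correlations.tsv"
        except PipelineError:
            raise
        except Exception as exc:
            raise fail("envfit", str(exc)) from exc

    with open(os.path.join(out_dir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
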