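"""High-level workflows applying all four comparison methods to one data set.

Convenience layer for simulation studies: given synthetic samples with known
ground truth, build the Dalmatian, CHIC, CyBar and FlowFP dissimilarity
matrices from the identical event tables, emulating the operator's gating
from the generating specs.
"""

from __future__ import annotations

from .chic import chic_matrix
from .cybar import abundance_table, cybar_matrix
from .dalmatian import dalmatian_matrix, render_mask
from .dissim import DissimilarityMatrix
from .events import EventTable, fingerprint_images
from .flowfp import fit_model, fp_matrix
from .gating import GateSet, build_template, count_in_gate
from .synth import CommunitySpec, component_gate, operator_gate_sets

__all__ = ["four_method_matrices"]


def four_method_matrices(
    tables: list[EventTable],
    specs: list[CommunitySpec],
    labels: list | None = None,
    resolution: int = 128,
    recursions: int = 5,
    training: tuple[int, int] = (0, -1),
    min_gate_fraction: float = 0.05,
) -> dict[str, DissimilarityMatrix]:
    """All four dissimilarity matrices for one set of samples.

    ``specs[i]`` is the community spec sample i was generated from; gates are
    derived from the spec's components (the emulated operator), with
    per-sample Dalmatian sets keeping only clusters above
    ``min_gate_fraction`` and the CyBar template holding every distinct
    component of every distinct spec. ``labels``, when given, are per-sample
    ground-truth component indices used to decide which clusters the
    Dalmatian operator sees. FlowFP trains on the samples at the ``training``
    indices with ``recursions`` recursions.
    """
    if len(tables) != len(specs):
        raise ValueError("one generating spec per sample required")
    imgs = fingerprint_images(tables, resolution=resolution)
    mats = {"chic": chic_matrix(imgs)}

    masks = []
    for i, (t, spec) in enumerate(zip(tables, specs)):
        gs = operator_gate_sets(
            [t], spec, labels=None if labels is None else [labels[i]],
            min_fraction=min_gate_fraction,
        )[0]
        counts = {g.name: count_in_gate(t, g) for g in gs.gates}
        masks.append(render_mask(gs, resolution, "gray", counts=counts))
    mats["dalmatian"] = dalmatian_matrix(masks)

    distinct: list[CommunitySpec] = []
    for spec in specs:
        if all(spec is not d and spec != d for d in distinct):
            distinct.append(spec)
    gates = []
    for si, spec in enumerate(distinct):
        prefix = chr(ord("A") + si) if len(distinct) > 1 else "C"
        gates += [component_gate(c, f"{prefix}{k + 1}")
                  for k, c in enumerate(spec.components)]
    tpl = build_template([GateSet("template", gates)])
    mats["cybar"] = cybar_matrix(abundance_table(tables, tpl))

    model = fit_model([tables[training[0]], tables[training[1]]], recursions)
    mats["flowfp"] = fp_matrix(model, tables)
    return mats
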