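"""Objective evaluation of generated pathway maps.

Two complementary metrics:

*Causality violation* (CV) — information cannot travel backwards in
time, so an edge whose child node's latency strictly precedes its
parent's is a violation::

    CV = |{(u, v) in E : l(v) < l(u)}| / |E|

*Transform recall* (TR) — the proportion of detectable transforms (those
with at least one significant point in the raw expression data) that
survive into the generated map.  CV rewards parsimonious, causally
consistent maps; TR rewards sensitivity; the two are in tension.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .denoise import denoise_expression
from .expression import CandidateTransformList, ExpressionSet, ParameterError, merge_hemispheres
from .graph import IPPMGraph, build_ippm

__all__ = [
    "EvaluationResult",
    "causality_violation",
    "transform_recall",
    "evaluate_ippm",
    "evaluation_table",
]


@dataclass
class EvaluationResult:
    """TR/CV scores for one hemisphere (or the merged-hemisphere run)."""

    hemisphere_label: str
    tr: float
    cv: float
    n_edges: int
    n_violations: int
    detectable_transforms: set[str] = field(default_factory=set)
    recalled_transforms: set[str] = field(default_factory=set)


def causality_violation(
    g: IPPMGraph,
    include_input_edges: bool = True,
    include_identity_edges: bool = True,
) -> tuple[float, int, int]:
    """CV over the selected edge set; an edgeless graph scores 0.0.

    Violation is strict (``l(dst) < l(src)``): equal latencies are legal.
    Input-stream edges (latency 0 source) and identity edges (ordered by
    construction) can be excluded via the toggles.
    """
    edges = []
    for u, v in g.edges:
        if not include_identity_edges and g.edge_kind(u, v) == "identity":
            continue
        if not include_input_edges and g.nodes[u].is_input_stream:
            continue
        edges.append((u, v))
    n_edges = len(edges)
    if n_edges == 0:
        return 0.0, 0, 0
    n_violations = sum(1 for u, v in edges if g.latency(v) < g.latency(u))
    return n_violations / n_edges, n_violations, n_edges


def transform_recall(
    g: IPPMGraph,
    raw: ExpressionSet,
    ctl: CandidateTransformList,
    variant: str = "detectable",
) -> tuple[float, set[str], set[str]]:
    """TR plus the (detectable, recalled) transform sets.

    ``variant="detectable"`` (default): the denominator is the CTL
    transforms with at least one significant point in the raw expression
    data — a generator cannot recover a transform absent from the data,
    so it is not penalized for it.  ``variant="ctl_total"``: the
    denominator is every CTL transform (the literal |T_D|/|T_C| reading;
    appropriate when the ground truth is known to contain them all).
    An empty denominator gives TR = 0.
    """
    if variant not in ("detectable", "ctl_total"):
        raise ParameterError(f"unknown TR variant {variant!r}")
    detectable = ctl.transforms & raw.transforms_present
    in_graph = g.transforms
    recalled = detectable & in_graph
    denominator = len(ctl.transforms) if variant == "ctl_total" else len(detectable)
    tr = len(recalled) / denominator if denominator else 0.0
    return tr, detectable, recalled


def _evaluate_one(
    raw: ExpressionSet,
    ctl: CandidateTransformList,
    label: str,
    strategy: str,
    cfg,
    seed,
    missing_policy: str,
    tr_variant: str,
    include_input_edges: bool,
    include_identity_edges: bool,
) -> EvaluationResult:
    foci = denoise_expression(raw, strategy=strategy, cfg=cfg, seed=seed)
    g = build_ippm(foci, ctl, missing_policy=missing_policy)
    cv, n_viol, n_edges = causality_violation(
        g, include_input_edges=include_input_edges, include_identity_edges=include_identity_edges
    )
    tr, detectable, recalled = transform_recall(g, raw, ctl, variant=tr_variant)
    return EvaluationResult(
        hemisphere_label=label,
        tr=tr,
        cv=cv,
        n_edges=n_edges,
        n_violations=n_viol,
        detectable_transforms=detectable,
        recalled_transforms=recalled,
    )


def evaluate_ippm(
    raw_left: ExpressionSet,
    raw_right: ExpressionSet,
    ctl: CandidateTransformList,
    strategy: str = "mp",
    cfg=None,
    seed: int | None = None,
    missing_policy: str = "bypass",
    tr_variant: str = "detectable",
    include_input_edges: bool = True,
    include_identity_edges: bool = True,
) -> dict[str, EvaluationResult]:
    """Per-hemisphere and merged-hemisphere evaluation.

    Left and right are denoised and evaluated separately; the "both" row
    merges the hemispheres first, then denoises the merged set.
    """
    kwargs = dict(
        strategy=strategy,
        cfg=cfg,
        seed=seed,
        missing_policy=missing_policy,
        tr_variant=tr_variant,
        include_input_edges=include_input_edges,
        include_identity_edges=include_identity_edges,
    )
    merged = merge_hemispheres(raw_left, raw_right)
    return {
        "left": _evaluate_one(raw_left, ctl, "left", **kwargs),
        "right": _evaluate_one(raw_right, ctl, "right", **kwargs),
        "both": _evaluate_one(merged, ctl, "both", **kwargs),
    }


def evaluation_table(results: dict[str, EvaluationResult]) -> pd.DataFrame:
    """Long-format report: one row per metric x hemisphere."""
    rows = []
    for metric in ("TR", "CV"):
        for hemi in ("left", "right", "both"):
            r = results[hemi]
            rows.append(
                {
                    "metric": metric,
                    "hemisphere": hemi,
                    "score": r.tr if metric == "TR" else r.cv,
                }
            )
    return pd.DataFrame(rows)
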