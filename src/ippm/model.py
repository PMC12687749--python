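"""Model/Results interface tying the pipeline together.

`IPPM` is constructed from an expression set and a candidate transform
list; `fit()` runs denoise → build → evaluate and returns an
:class:`IPPMResults` carrying the graph, the per-transform clustering,
the TR/CV scores and a printable summary.
"""

from __future__ import annotations

from dataclasses import asdict
from pathlib import Path

import pandas as pd

from .denoise import ClusterResult, default_config, denoise_expression, STRATEGIES
from .expression import (
    CandidateTransformList,
    ExpressionSet,
    ParameterError,
    read_expression_table,
    validate_ctl,
)
from .graph import IPPMGraph, build_ippm, export_graph
from .metrics import causality_violation, transform_recall

__all__ = ["IPPM", "IPPMResults"]


class IPPM:
    """Automatic pathway-map generator for one expression set.

    Parameters
    ----------
    expression
        Significant expression points (already thresholded; merge
        hemispheres first for a combined map).
    ctl
        Candidate transform list (validated on construction).
    strategy
        Denoising strategy: ``mp``, ``amp``, ``gmm``, ``meanshift`` or
        ``dbscan``.
    config
        Strategy configuration object; defaults per strategy.
    missing_policy
        ``"bypass"`` (route edges through undetected transforms) or
        ``"prune"``.
    tr_variant
        ``"detectable"`` or ``"ctl_total"`` denominator for transform
        recall.

    Examples
    --------
    >>> model = IPPM(expr, ctl, strategy="mp")
    >>> res = model.fit(seed=0)
    >>> print(res.summary())
    """

    def __init__(
        self,
        expression: ExpressionSet,
        ctl: CandidateTransformList,
        strategy: str = "mp",
        config=None,
        missing_policy: str = "bypass",
        tr_variant: str = "detectable",
    ) -> None:
        if strategy not in STRATEGIES:
            raise ParameterError(f"unknown strategy {strategy!r}")
        validate_ctl(ctl)
        self.expression = expression
        self.ctl = ctl
        self.strategy = strategy
        self.config = config if config is not None else default_config(strategy)
        self.missing_policy = missing_policy
        self.tr_variant = tr_variant

    @classmethod
    def from_files(
        cls,
        expression_path: str | Path,
        ctl_path: str | Path,
        dialect: str = "tsv",
        **kwargs,
    ) -> "IPPM":
        expr = read_expression_table(expression_path, dialect=dialect)
        ctl = CandidateTransformList.from_file(ctl_path)
        return cls(expr, ctl, **kwargs)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, ctl: CandidateTransformList, **kwargs) -> "IPPM":
        return cls(ExpressionSet.from_dataframe(df), ctl, **kwargs)

    def fit(self, seed: int | None = None) -> "IPPMResults":
        clusters: dict[str, ClusterResult] = denoise_expression(
            self.expression,
            strategy=self.strategy,
            cfg=self.config,
            seed=seed,
            return_clusters=True,
        )
        foci = {t: r.foci for t, r in clusters.items()}
        graph = build_ippm(foci, self.ctl, missing_policy=self.missing_policy)
        return IPPMResults(self, clusters, graph, seed)


class IPPMResults:
    """Fitted pathway map with its evaluation metrics."""

    def __init__(
        self,
        model: IPPM,
        clusters: dict[str, ClusterResult],
        graph: IPPMGraph,
        seed: int | None,
    ) -> None:
        self.model = model
        self.clusters = clusters
        self.graph = graph
        self.seed = seed
        self.cv, self.n_violations, self.n_edges = causality_violation(graph)
        self.tr, self.detectable_transforms, self.recalled_transforms = transform_recall(
            graph, model.expression, model.ctl, variant=model.tr_variant
        )

    @property
    def foci(self) -> dict[str, list]:
        return {t: r.foci for t, r in self.clusters.items()}

    def foci_frame(self) -> pd.DataFrame:
        rows = []
        for t, r in sorted(self.clusters.items()):
            for label, f in enumerate(r.foci):
                rows.append(
                    {
                        "transform": t,
                        "cluster": label,
                        "hexel": f.hexel_id,
                        "hemisphere": f.hemisphere,
                        "latency_ms": f.latency_ms,
                        "logp": f.surprisal,
                    }
                )
        return pd.DataFrame(
            rows, columns=["transform", "cluster", "hexel", "hemisphere", "latency_ms", "logp"]
        )

    def save_graph(self, path: str | Path, format: str = "json") -> None:
        export_graph(self.graph, path, format=format)

    def summary(self) -> str:
        m = self.model
        n_anomalies = sum(
            int((r.labels == -1).sum()) for r in self.clusters.values()
        )
        lines = [
            "Information Processing Pathway Map",
            "=" * 50,
            f"Denoising strategy:     {m.strategy}",
            f"Configuration:          {asdict(m.config)}",
            f"Seed:                   {self.seed}",
            f"Expression points:      {len(m.expression)}",
            f"Transforms in CTL:      {len(m.ctl.transforms)}",
            f"Detectable transforms:  {len(self.detectable_transforms)}",
            f"Recalled transforms:    {len(self.recalled_transforms)}",
            f"Anomalous points:       {n_anomalies}",
            f"Graph: {len(self.graph)} nodes, {len(self.graph.edges)} edges",
            "-" * 50,
            f"Transform recall (TR):      {self.tr:.3f}  [{m.tr_variant}]",
            f"Causality violation (CV):   {self.cv:.3f}  "
            f"({self.n_violations}/{self.n_edges} edges)",
            "-" * 50,
            "Foci:",
        ]
        ff = self.foci_frame()
        lines.append(ff.to_string(index=False) if len(ff) else "  (none)")
        return "\n".join(lines)

    def plot(self, ax=None):
        """Latency-vs-pathway scatter of the fitted map (thin helper)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(8, 4))
        order = {t: i for i, t in enumerate(sorted(self.graph.transforms | self.graph.input_streams))}
        xy = {}
        for nid, node in self.graph.nodes.items():
            xy[nid] = (node.latency_ms, order[node.transform])
        for (u, v) in self.graph.edges:
            (x0, y0), (x1, y1) = xy[u], xy[v]
            style = "--" if self.graph.edge_kind(u, v) == "identity" else "-"
            ax.plot([x0, x1], [y0, y1], style, color="gray", lw=1, zorder=1)
        for nid, node in self.graph.nodes.items():
            x, y = xy[nid]
            ax.scatter([x], [y], s=40, zorder=2,
                       marker="s" if node.is_input_stream else "o")
        ax.set_yticks(list(order.values()))
        ax.set_yticklabels(list(order))
        ax.set_xlabel("latency (ms)")
        return ax
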