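"""Data model and I/O for M/EEG transform-expression data.

Expression data record, for each cortical hexel and each candidate
transform, the latency at which the transform's predicted output best
matches the hexel's activity, together with the evidence for the match
expressed as surprisal, i.e. -log10(p).  A candidate transform list
(CTL) declares, for every transform, which transforms or sensory input
streams feed it; it must be acyclic.

Only best-latency points are stored (one per hexel/transform/hemisphere),
mirroring the stems of an expression plot; full statistical maps are out
of scope.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd
import yaml

__all__ = [
    "ExpressionPoint",
    "ExpressionSet",
    "CandidateTransformList",
    "ExpressionFormatError",
    "CTLError",
    "ParameterError",
    "read_expression_table",
    "write_expression_table",
    "apply_significance_threshold",
    "merge_hemispheres",
    "validate_ctl",
    "corrected_threshold_logp",
]

HEMISPHERES = ("left", "right")

#: Cap applied to surprisal when a p-value underflows to zero.
DEFAULT_MAX_SURPRISAL = 350.0

EXPRESSION_COLUMNS = ("hexel", "transform", "hemisphere", "latency_ms", "logp")


class ExpressionFormatError(ValueError):
    """Malformed expression table or CTL document."""


class CTLError(ValueError):
    """Invalid candidate transform list (cycle or dangling parent)."""


class ParameterError(ValueError):
    """Out-of-range parameter value."""


@dataclass(frozen=True)
class ExpressionPoint:
    """One significant best-latency observation for a (hexel, transform) pair.

    Parameters
    ----------
    hexel_id
        Non-negative index of the cortical surface patch.
    transform
        Name of the candidate transform the hexel is entrained to.
    hemisphere
        ``"left"`` or ``"right"``.
    latency_ms
        Latency of the best match, in milliseconds (may be negative for
        pre-stimulus artifacts).
    surprisal
        Evidence for the match, -log10(p); non-negative.
    """

    hexel_id: int
    transform: str
    hemisphere: str
    latency_ms: float
    surprisal: float

    def __post_init__(self) -> None:
        if self.hexel_id < 0:
            raise ExpressionFormatError(f"negative hexel id {self.hexel_id}")
        if self.hemisphere not in HEMISPHERES:
            raise ExpressionFormatError(f"unknown hemisphere {self.hemisphere!r}")
        if not math.isfinite(self.latency_ms):
            raise ExpressionFormatError("latency must be finite")
        if not (self.surprisal >= 0):
            raise ExpressionFormatError("surprisal must be >= 0")


@dataclass
class ExpressionSet:
    """A collection of expression points plus dataset-level metadata."""

    points: list[ExpressionPoint]
    n_hexels_per_hemisphere: int = 10242
    alpha_threshold_logp: float | None = None

    def __post_init__(self) -> None:
        seen: set[tuple[int, str, str]] = set()
        for p in self.points:
            key = (p.hexel_id, p.transform, p.hemisphere)
            if key in seen:
                raise ExpressionFormatError(
                    f"duplicate point for hexel {p.hexel_id}, transform "
                    f"{p.transform!r}, {p.hemisphere} hemisphere"
                )
            seen.add(key)

    @property
    def transforms_present(self) -> set[str]:
        return {p.transform for p in self.points}

    @property
    def hemispheres(self) -> set[str]:
        return {p.hemisphere for p in self.points}

    @property
    def latency_range_ms(self) -> tuple[float, float] | None:
        if not self.points:
            return None
        lats = [p.latency_ms for p in self.points]
        return (min(lats), max(lats))

    def points_for(self, transform: str) -> list[ExpressionPoint]:
        return [p for p in self.points if p.transform == transform]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                (p.hexel_id, p.transform, p.hemisphere, p.latency_ms, p.surprisal)
                for p in self.points
            ],
            columns=list(EXPRESSION_COLUMNS),
        )

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        n_hexels_per_hemisphere: int = 10242,
        alpha_threshold_logp: float | None = None,
        max_surprisal: float = DEFAULT_MAX_SURPRISAL,
    ) -> "ExpressionSet":
        cols = set(df.columns)
        required = {"hexel", "transform", "hemisphere", "latency_ms"}
        missing = required - cols
        if missing:
            raise ExpressionFormatError(
                f"missing column(s): {', '.join(sorted(missing))}"
            )
        if "logp" in cols:
            surprisal = df["logp"].astype(float)
        elif "pvalue" in cols:
            surprisal = _pvalues_to_surprisal(df["pvalue"].astype(float), max_surprisal)
        else:
            raise ExpressionFormatError("missing column(s): logp (or pvalue)")
        points = [
            ExpressionPoint(
                hexel_id=int(h),
                transform=str(t),
                hemisphere=str(hemi),
                latency_ms=float(lat),
                surprisal=float(s),
            )
            for h, t, hemi, lat, s in zip(
                df["hexel"], df["transform"], df["hemisphere"], df["latency_ms"], surprisal
            )
        ]
        return cls(points, n_hexels_per_hemisphere, alpha_threshold_logp)

    def __len__(self) -> int:
        return len(self.points)


def _pvalues_to_surprisal(p: pd.Series, max_surprisal: float) -> pd.Series:
    if (p < 0).any():
        raise ExpressionFormatError("negative p-value in expression table")
    if (p > 1).any():
        raise ExpressionFormatError("p-value > 1 in expression table")
    if (p == 0).any():
        warnings.warn(
            f"p = 0 underflow: surprisal capped at {max_surprisal}", stacklevel=3
        )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        s = -pd.Series(p).apply(lambda v: math.log10(v) if v > 0 else -math.inf)
    return s.clip(upper=max_surprisal)


def read_expression_table(
    path: str | Path,
    dialect: str = "tsv",
    n_hexels_per_hemisphere: int = 10242,
    max_surprisal: float = DEFAULT_MAX_SURPRISAL,
) -> ExpressionSet:
    """Read an expression table (``hexel  transform  hemisphere  latency_ms  logp``).

    A ``pvalue`` column may stand in for ``logp``; it is converted via
    -log10, capping underflowed zeros at ``max_surprisal``.
    """
    if dialect not in ("tsv", "csv"):
        raise ParameterError(f"unknown dialect {dialect!r}")
    sep = "\t" if dialect == "tsv" else ","
    df = pd.read_csv(path, sep=sep, float_precision="round_trip")
    return ExpressionSet.from_dataframe(
        df, n_hexels_per_hemisphere=n_hexels_per_hemisphere, max_surprisal=max_surprisal
    )


def write_expression_table(
    expr: ExpressionSet, path: str | Path, dialect: str = "tsv"
) -> None:
    if dialect not in ("tsv", "csv"):
        raise ParameterError(f"unknown dialect {dialect!r}")
    sep = "\t" if dialect == "tsv" else ","
    df = expr.to_dataframe()
    # shortest round-trip float repr so write->read is field-exact
    df["latency_ms"] = df["latency_ms"].map(lambda v: repr(float(v)))
    df["logp"] = df["logp"].map(lambda v: repr(float(v)))
    df.to_csv(path, sep=sep, index=False)


def corrected_threshold_logp(
    alpha: float, correction: str, n_comparisons: int
) -> float:
    """Significance threshold in -log10 units after multiple-comparison correction."""
    if not (0 < alpha < 1):
        raise ParameterError(f"alpha must be in (0, 1), got {alpha}")
    if n_comparisons < 1:
        raise ParameterError("n_comparisons must be >= 1")
    if correction == "none":
        corrected = alpha
    elif correction == "bonferroni":
        corrected = alpha / n_comparisons
    elif correction == "sidak":
        corrected = 1.0 - (1.0 - alpha) ** (1.0 / n_comparisons)
    else:
        raise ParameterError(f"unknown correction {correction!r}")
    return -math.log10(corrected)


def apply_significance_threshold(
    raw: ExpressionSet,
    alpha: float = 0.05,
    correction: str = "bonferroni",
    n_latency_steps: int = 1,
    n_transforms: int | None = None,
) -> ExpressionSet:
    """Retain points whose surprisal clears the corrected significance threshold.

    The comparison family is ``n_hexels_per_hemisphere x n_hemispheres x
    n_transforms x n_latency_steps``; ``n_transforms`` defaults to the
    number of transforms present in ``raw``.
    """
    n_t = n_transforms if n_transforms is not None else max(1, len(raw.transforms_present))
    n_hemi = max(1, len(raw.hemispheres))
    m = raw.n_hexels_per_hemisphere * n_hemi * n_t * max(1, n_latency_steps)
    threshold = corrected_threshold_logp(alpha, correction, m)
    kept = [p for p in raw.points if p.surprisal >= threshold]
    return ExpressionSet(
        kept,
        n_hexels_per_hemisphere=raw.n_hexels_per_hemisphere,
        alpha_threshold_logp=threshold,
    )


def merge_hemispheres(left: ExpressionSet, right: ExpressionSet) -> ExpressionSet:
    """Union of two per-hemisphere sets, namespacing hexel ids.

    Right-hemisphere hexel ids are offset by ``n_hexels_per_hemisphere``
    so ids are unique in the merged set; the hemisphere field is kept.
    Used to produce the "Both"-hemisphere rows of an evaluation report
    (hemispheres are merged first, then denoised).
    """
    n_h = max(left.n_hexels_per_hemisphere, right.n_hexels_per_hemisphere)
    points = []
    for p in list(left.points) + list(right.points):
        if p.hemisphere == "right" and p.hexel_id < n_h:
            p = replace(p, hexel_id=p.hexel_id + n_h)
        points.append(p)
    thresholds = [
        t for t in (left.alpha_threshold_logp, right.alpha_threshold_logp) if t is not None
    ]
    return ExpressionSet(
        points,
        n_hexels_per_hemisphere=n_h,
        alpha_threshold_logp=min(thresholds) if thresholds else None,
    )


@dataclass
class CandidateTransformList:
    """Hypothesized transform dependency structure.

    ``parents`` maps each transform to the labels it consumes (other
    transforms or declared input streams); the transform-to-transform
    relation must be acyclic and every transform must have at least one
    parent (roots are fed by input streams).
    """

    parents: dict[str, list[str]]
    input_streams: set[str] = field(default_factory=set)

    @property
    def transforms(self) -> set[str]:
        return set(self.parents)

    @classmethod
    def from_dict(cls, doc: Mapping) -> "CandidateTransformList":
        try:
            streams = set(doc["input_streams"])
            parents = {str(k): [str(p) for p in v] for k, v in doc["transforms"].items()}
        except (KeyError, TypeError) as exc:
            raise ExpressionFormatError(
                "CTL document must contain 'input_streams' and 'transforms'"
            ) from exc
        return cls(parents=parents, input_streams=streams)

    def to_dict(self) -> dict:
        return {
            "input_streams": sorted(self.input_streams),
            "transforms": {k: list(v) for k, v in self.parents.items()},
        }

    @classmethod
    def from_file(cls, path: str | Path) -> "CandidateTransformList":
        """Load from JSON or YAML (decided by extension; YAML parses JSON too)."""
        text = Path(path).read_text()
        if str(path).endswith(".json"):
            doc = json.loads(text)
        else:
            doc = yaml.safe_load(text)
        return cls.from_dict(doc)

    def to_file(self, path: str | Path) -> None:
        path = Path(path)
        if path.suffix == ".json":
            path.write_text(json.dumps(self.to_dict(), indent=2))
        else:
            path.write_text(yaml.safe_dump(self.to_dict()))


def validate_ctl(ctl: CandidateTransformList) -> list[str]:
    """Validate a CTL; return a topological order of its transforms.

    Raises
    ------
    CTLError
        If a parent label is neither a transform nor a declared input
        stream, if a transform has no parents, or if the transform
        relation contains a cycle (one cycle is reported).
    """
    for child, parents in ctl.parents.items():
        if not parents:
            raise CTLError(f"transform {child!r} has no parents")
        for parent in parents:
            if parent not in ctl.parents and parent not in ctl.input_streams:
                raise CTLError(
                    f"parent {parent!r} of {child!r} is neither a transform "
                    "nor a declared input stream"
                )
    g = nx.DiGraph()
    g.add_nodes_from(ctl.parents)
    for child, parents in ctl.parents.items():
        for parent in parents:
            if parent in ctl.parents:
                g.add_edge(parent, child)
    try:
        cycle = nx.find_cycle(g)
    except nx.NetworkXNoCycle:
        cycle = None
    if cycle is not None:
        desc = " -> ".join(str(u) for u, _ in cycle) + f" -> {cycle[-1][1]}"
        raise CTLError(f"CTL contains a cycle: {desc}")
    # Deterministic order: lexicographic among ready nodes.
    return list(nx.lexicographical_topological_sort(g))
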