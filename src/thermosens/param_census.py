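"""Random-sampling census of cooperativity parameter relationships.

The procedure: draw a large number of parameter vectors at random, keep every
vector whose model-vs-data Pearson correlation exceeds a threshold, and
classify each accepted vector by which of three predicted cooperativity
inequalities it satisfies — Dorsal-Twist cooperativity higher in the rho-like
class (DTr > DTv), Twist-Twist higher (TTr > TTv), Snail-Snail lower
(SSr < SSv).  The three binary outcomes partition accepted sets into eight
categories, from "all correct" to "all wrong".
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .global_sensitivity import sample_uniform
from .parameter_space import ParameterSpace
from .thermo_models import ZinzenParams

__all__ = [
    "CATEGORIES",
    "RelationshipRule",
    "CensusResult",
    "classify_relationships",
    "run_census",
    "census_report",
]

CATEGORIES = (
    "all correct",
    "DT wrong",
    "TT wrong",
    "SS wrong",
    "DT and TT wrong",
    "DT and SS wrong",
    "TT and SS wrong",
    "all wrong",
)


@dataclass(frozen=True)
class RelationshipRule:
    """Predicates over the six cooperativities; ties fail (strict inequalities).

    ``dt_fold`` optionally strengthens the Dorsal-Twist predicate to
    DTr > fold * DTv, encoding a "several-fold higher" requirement.
    """

    dt_fold: Optional[float] = None

    def flags(self, p: Union[ZinzenParams, Mapping[str, float]]) -> tuple[bool, bool, bool]:
        if isinstance(p, ZinzenParams):
            vals = {k: getattr(p, k) for k in ("DTr", "TTr", "SSr", "DTv", "TTv", "SSv")}
        else:
            try:
                vals = {k: float(p[k]) for k in ("DTr", "TTr", "SSr", "DTv", "TTv", "SSv")}
            except KeyError as exc:
                raise KeyError(f"missing cooperativity field {exc}") from None
        fold = 1.0 if self.dt_fold is None else self.dt_fold
        dt_ok = vals["DTr"] > fold * vals["DTv"]
        tt_ok = vals["TTr"] > vals["TTv"]
        ss_ok = vals["SSr"] < vals["SSv"]
        return dt_ok, tt_ok, ss_ok


def classify_relationships(
    params: Union[ZinzenParams, Mapping[str, float]],
    rule: RelationshipRule = RelationshipRule(),
) -> str:
    """Map one parameter set to one of the eight census categories."""
    dt_ok, tt_ok, ss_ok = rule.flags(params)
    wrong = [name for name, ok in (("DT", dt_ok), ("TT", tt_ok), ("SS", ss_ok)) if not ok]
    if not wrong:
        return "all correct"
    if len(wrong) == 3:
        return "all wrong"
    return " and ".join(wrong) + " wrong"


@dataclass
class CensusResult:
    """Counts of threshold-passing parameter sets per relationship category."""

    counts: dict[str, int]
    n_sampled: int
    threshold: float
    seed: Optional[int]
    rule: RelationshipRule = field(default_factory=RelationshipRule)
    accepted: Optional[pd.DataFrame] = None  # full vectors + correlation
    label: str = ""
    sampling_scales: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for c in CATEGORIES:
            self.counts.setdefault(c, 0)
        unknown = set(self.counts) - set(CATEGORIES)
        if unknown:
            raise ValueError(f"unknown categories {unknown}")

    @property
    def total_accepted(self) -> int:
        return sum(self.counts.values())

    def percentages(self) -> dict[str, Optional[float]]:
        tot = self.total_accepted
        if tot == 0:
            return {c: None for c in CATEGORIES}
        return {c: 100.0 * self.counts[c] / tot for c in CATEGORIES}


def run_census(
    objective: Callable[[np.ndarray], float],
    space: ParameterSpace,
    n: int = 100_000,
    threshold: float = 0.981,
    seed: Optional[int] = None,
    rule: RelationshipRule = RelationshipRule(),
    label: str = "",
) -> CensusResult:
    """Sample n vectors, keep those with objective strictly above the threshold,
    and classify each accepted vector's cooperativity relationships.

    The objective must be correlation-like (higher is better).  An empty
    census (nothing accepted) is a valid result.
    """
    points = sample_uniform(space, n, seed)
    values = np.array([objective(x) for x in points])
    keep = values > threshold
    counts = {c: 0 for c in CATEGORIES}
    rows = []
    for x, v in zip(points[keep], values[keep]):
        d = space.as_dict(x)
        cat = classify_relationships(d, rule)
        counts[cat] += 1
        d["correlation"] = float(v)
        d["category"] = cat
        rows.append(d)
    accepted = pd.DataFrame(rows, columns=list(space.names) + ["correlation", "category"])
    return CensusResult(
        counts=counts,
        n_sampled=n,
        threshold=threshold,
        seed=seed,
        rule=rule,
        accepted=accepted,
        label=label,
        sampling_scales={p.name: p.scale for p in space},
    )


def _format_cell(count: int, pct: Optional[float]) -> str:
    if pct is None:
        return "—"
    return f"{count} ({round(pct)}%)"


def census_report(
    result: Union[CensusResult, Sequence[CensusResult], Mapping[str, CensusResult]],
) -> pd.DataFrame:
    """Counts and rounded percentages per category, one row per census."""
    if isinstance(result, CensusResult):
        items = [(result.label or "1", result)]
    elif isinstance(result, Mapping):
        items = list(result.items())
    else:
        items = [(r.label or str(i + 1), r) for i, r in enumerate(result)]
    rows = []
    for name, res in items:
        pct = res.percentages()
        row = {"Set(s)": name}
        for c in CATEGORIES:
            row[c] = _format_cell(res.counts[c], pct[c])
        row["total"] = res.total_accepted
        rows.append(row)
    return pd.DataFrame(rows)
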