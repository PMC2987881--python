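"""Objective functions that sensitivity analyses act on.

The quenching-model studies score fits by root mean square error pooled over
all construct/condition records; the site-count-model studies score fits by
the Pearson correlation between predicted and observed expression profiles.
Both are exposed as plain vector functions plus a factory that binds a
dataset, a model family and a parameter ordering into a deterministic
scalar-valued objective over parameter vectors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

import numpy as np

from .parameter_space import ParameterSpace
from .thermo_models import (
    Construct,
    DistanceBinning,
    FakhouriParams,
    ZinzenParams,
    ZinzenStructure,
    predict_expression_fakhouri,
    predict_expression_zinzen,
)

__all__ = [
    "DataRecord",
    "ExpressionDataset",
    "ObjectiveFn",
    "rmse",
    "pearson",
    "make_objective",
    "fakhouri_params_from_vector",
    "zinzen_params_from_vector",
]


def rmse(predictions: Sequence[float], observations: Sequence[float]) -> float:
    """Root mean square error pooled over all records."""
    p = np.asarray(predictions, dtype=float)
    o = np.asarray(observations, dtype=float)
    if p.shape != o.shape:
        raise ValueError(f"length mismatch: {p.shape} vs {o.shape}")
    if p.size == 0:
        raise ValueError("rmse of empty input is undefined")
    return float(np.sqrt(np.mean((p - o) ** 2)))


def pearson(x: Sequence[float], y: Sequence[float]) -> float:
    """Sample Pearson correlation coefficient in [-1, 1].

    A constant input vector makes the correlation undefined; this returns 0.0
    with a warning instead of raising, so large random-sampling censuses never
    abort on a degenerate (e.g. everywhere-zero) prediction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    if x.size < 2:
        raise ValueError("pearson requires at least 2 points")
    sx = x - x.mean()
    sy = y - y.mean()
    nx = np.sqrt((sx ** 2).sum())
    ny = np.sqrt((sy ** 2).sum())
    if nx == 0.0 or ny == 0.0:
        warnings.warn("constant vector: Pearson correlation undefined, returning 0.0", stacklevel=2)
        return 0.0
    r = float((sx * sy).sum() / (nx * ny))
    return max(-1.0, min(1.0, r))


@dataclass(frozen=True)
class DataRecord:
    """One measured expression value with its inputs.

    ``element`` is the construct or site-count structure the measurement
    belongs to; ``key`` identifies the condition (repressor level) or axis
    position; ``class_tag`` selects the cooperativity triple for site-count
    records and is None for construct records.
    """

    element: Union[Construct, ZinzenStructure]
    key: str
    concentrations: Mapping[str, float]
    observed: float
    class_tag: Optional[str] = None


@dataclass
class ExpressionDataset:
    """A collection of records plus the model family they were measured for."""

    records: list[DataRecord]
    model_family: str  # "fakhouri" | "zinzen"
    binning: Optional[DistanceBinning] = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.model_family not in ("fakhouri", "zinzen"):
            raise ValueError(f"unknown model family {self.model_family!r}")
        if self.model_family == "fakhouri" and self.binning is None:
            raise ValueError("a fakhouri dataset requires a distance binning")
        for r in self.records:
            if not np.isfinite(r.observed):
                raise ValueError(f"non-finite observation in record {r.key!r}")

    def __len__(self) -> int:
        return len(self.records)

    def observed(self) -> np.ndarray:
        return np.array([r.observed for r in self.records], dtype=float)


def fakhouri_params_from_vector(space: ParameterSpace, theta: np.ndarray, A: float = 1.0) -> FakhouriParams:
    """Interpret an ordered vector (R, Q*, C1, C2) as quenching-model parameters."""
    d = space.as_dict(theta)
    Q = {k: v for k, v in d.items() if k.startswith("Q")}
    return FakhouriParams(R=d["R"], Q=Q, C1=d.get("C1", 1.0), C2=d.get("C2", 1.0), A=A)


def zinzen_params_from_vector(space: ParameterSpace, theta: np.ndarray) -> ZinzenParams:
    d = space.as_dict(theta)
    return ZinzenParams(**{k: d[k] for k in ("D", "T", "S", "DTr", "TTr", "SSr", "DTv", "TTv", "SSv")})


class ObjectiveFn:
    """Deterministic scalar objective over ordered parameter vectors.

    Groups the dataset's records by element once at construction so each call
    runs one vectorized model evaluation per element.  ``kind`` is "rmse"
    (lower is better) or "pearson" (higher is better, used raw); sensitivity
    methods operate on the objective exactly as returned.
    """

    def __init__(
        self,
        dataset: ExpressionDataset,
        space: ParameterSpace,
        kind: str = "rmse",
        pairing: str = "two_term",
        cooperativity_mode: str = "binding",
    ):
        if kind not in ("rmse", "pearson"):
            raise ValueError(f"unknown objective kind {kind!r}")
        if len(dataset) == 0:
            raise ValueError("empty dataset")
        if kind == "pearson" and len(dataset) < 2:
            raise ValueError("pearson objective requires at least 2 records")
        self.dataset = dataset
        self.space = space
        self.kind = kind
        self.pairing = pairing
        self.cooperativity_mode = cooperativity_mode
        self.log_path: Optional[Path] = None

        # group records by element (and class tag), preserving record order
        # for the pooled observation vector
        self._groups: list[tuple] = []
        order: dict = {}
        for idx, r in enumerate(self.dataset.records):
            key = (id(r.element), r.class_tag)
            order.setdefault(key, (r.element, r.class_tag, []))[2].append(idx)
        for element, class_tag, idxs in order.values():
            recs = [self.dataset.records[i] for i in idxs]
            factors = sorted({f for r in recs for f in r.concentrations})
            conc = {f: np.array([r.concentrations[f] for r in recs], dtype=float) for f in factors}
            self._groups.append((element, class_tag, conc, np.array(idxs)))
        self._observed = self.dataset.observed()

    def __len__(self) -> int:
        return len(self.space)

    def predict(self, theta: np.ndarray) -> np.ndarray:
        """Model predictions aligned with the dataset's record order."""
        theta = np.asarray(theta, dtype=float)
        if theta.shape != (len(self.space),):
            raise ValueError(
                f"parameter vector length {theta.shape} does not match space ({len(self.space)})"
            )
        out = np.empty(len(self.dataset))
        if self.dataset.model_family == "fakhouri":
            params = fakhouri_params_from_vector(self.space, theta)
            for element, _tag, conc, idxs in self._groups:
                out[idxs] = predict_expression_fakhouri(
                    element, params, conc, self.dataset.binning,
                    pairing=self.pairing, cooperativity_mode=self.cooperativity_mode,
                )
        else:
            params = zinzen_params_from_vector(self.space, theta)
            for element, tag, conc, idxs in self._groups:
                out[idxs] = predict_expression_zinzen(element, params, tag, conc)
        return out

    def __call__(self, theta: np.ndarray) -> float:
        pred = self.predict(theta)
        if self.kind == "rmse":
            value = rmse(pred, self._observed)
        else:
            value = pearson(pred, self._observed)
        if self.log_path is not None:
            with open(self.log_path, "a", encoding="utf-8") as fh:
                row = "\t".join(f"{v:.12g}" for v in np.asarray(theta, dtype=float))
                fh.write(f"{row}\t{value:.12g}\n")
        return value

    def enable_logging(self, path: Union[str, Path]) -> None:
        """Append every subsequent evaluation (vector + value) to a TSV."""
        path = Path(path)
        if not path.exists():
            with open(path, "w", encoding="utf-8") as fh:
                fh.write("\t".join(self.space.names) + "\tobjective\n")
        self.log_path = path


def make_objective(
    dataset: ExpressionDataset,
    model_family: str,
    parameter_space: ParameterSpace,
    kind: str = "rmse",
    **model_options,
) -> ObjectiveFn:
    """Bind a dataset and parameter ordering into a scalar objective."""
    if model_family != dataset.model_family:
        raise ValueError(
            f"model family {model_family!r} does not match dataset ({dataset.model_family!r})"
        )
    return ObjectiveFn(dataset, parameter_space, kind=kind, **model_options)
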