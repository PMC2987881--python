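"""Named, bounded parameter spaces with linear or log10 sampling scales."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = ["Parameter", "ParameterSpace", "default_fakhouri_space", "default_zinzen_space"]


@dataclass(frozen=True)
class Parameter:
    name: str
    lower: float
    upper: float
    scale: str = "linear"  # "linear" | "log10"

    def __post_init__(self) -> None:
        if not self.lower < self.upper:
            raise ValueError(f"{self.name}: lower {self.lower} must be < upper {self.upper}")
        if self.scale not in ("linear", "log10"):
            raise ValueError(f"{self.name}: scale must be 'linear' or 'log10', got {self.scale!r}")
        if self.scale == "log10" and self.lower <= 0:
            raise ValueError(f"{self.name}: log10 scale requires lower > 0")


class ParameterSpace:
    """An ordered collection of bounded parameters.

    Defines the coordinate order of every parameter vector handed to
    objectives and sensitivity methods, and the map between real parameter
    values and the unit hypercube on each parameter's sampling scale.
    """

    def __init__(self, parameters: Iterable[Parameter]):
        self.parameters = tuple(parameters)
        if len({p.name for p in self.parameters}) != len(self.parameters):
            raise ValueError("duplicate parameter names")

    def __len__(self) -> int:
        return len(self.parameters)

    def __iter__(self):
        return iter(self.parameters)

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(p.name for p in self.parameters)

    def index(self, name: str) -> int:
        return self.names.index(name)

    def _scaled_bounds(self) -> tuple[np.ndarray, np.ndarray]:
        lo = np.array([p.lower if p.scale == "linear" else np.log10(p.lower) for p in self.parameters])
        hi = np.array([p.upper if p.scale == "linear" else np.log10(p.upper) for p in self.parameters])
        return lo, hi

    def from_unit(self, u: np.ndarray) -> np.ndarray:
        """Map points in [0, 1]^k to real parameter values on each scale."""
        u = np.asarray(u, dtype=float)
        lo, hi = self._scaled_bounds()
        x = lo + u * (hi - lo)
        is_log = np.array([p.scale == "log10" for p in self.parameters])
        if is_log.any():
            x = x.copy()
            x[..., is_log] = 10.0 ** x[..., is_log]
        return x

    def to_unit(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        lo, hi = self._scaled_bounds()
        is_log = np.array([p.scale == "log10" for p in self.parameters])
        xs = np.where(is_log, np.log10(np.where(x > 0, x, np.nan)), x)
        return (xs - lo) / (hi - lo)

    def midpoint(self) -> np.ndarray:
        """Scale-aware range midpoint of every parameter."""
        return self.from_unit(np.full(len(self), 0.5))

    def clip(self, x: np.ndarray) -> np.ndarray:
        lo = np.array([p.lower for p in self.parameters])
        hi = np.array([p.upper for p in self.parameters])
        return np.clip(np.asarray(x, dtype=float), lo, hi)

    def contains(self, x: np.ndarray) -> bool:
        lo = np.array([p.lower for p in self.parameters])
        hi = np.array([p.upper for p in self.parameters])
        x = np.asarray(x, dtype=float)
        return bool(np.all(x >= lo) and np.all(x <= hi))

    def as_dict(self, x: np.ndarray) -> dict[str, float]:
        return {n: float(v) for n, v in zip(self.names, np.asarray(x, dtype=float))}

    def to_records(self) -> list[dict]:
        return [
            {"name": p.name, "lower": p.lower, "upper": p.upper, "scale": p.scale}
            for p in self.parameters
        ]

    @classmethod
    def from_records(cls, records: Sequence[Mapping]) -> "ParameterSpace":
        return cls(
            Parameter(r["name"], float(r["lower"]), float(r["upper"]), r.get("scale", "linear"))
            for r in records
        )


def default_fakhouri_space() -> ParameterSpace:
    """Biologically reasonable ranges for the 9-parameter quenching model.

    Quenching efficiencies live on their natural [0, 1] scale.  The repressor
    scaling factor is taken comparable to the fixed activator weight of 1
    within +/-50%: R is shared by every construct in the panel, so a wider
    prior on this one factor would swamp the per-bin quenching efficiencies in
    any variance decomposition, which is not the regime the reporter panel was
    built to probe.  Homotypic cooperativities span none (1) to strong
    (10-fold).
    """
    params = [Parameter("R", 0.5, 1.5)]
    params += [Parameter(f"Q{i}", 0.0, 1.0) for i in range(1, 7)]
    params += [Parameter("C1", 1.0, 10.0), Parameter("C2", 1.0, 10.0)]
    return ParameterSpace(params)


def default_zinzen_space(scale: str = "linear") -> ParameterSpace:
    """Ranges for the 9-parameter site-count model.

    Scaling factors in [1e8, 1e10] and cooperativities in [1, 100]; ``scale``
    selects linear or log10-uniform sampling of the scaling factors.
    """
    params = [Parameter(n, 1e8, 1e10, scale) for n in ("D", "T", "S")]
    params += [Parameter(n, 1.0, 100.0) for n in ("DTr", "TTr", "SSr", "DTv", "TTv", "SSv")]
    return ParameterSpace(params)
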