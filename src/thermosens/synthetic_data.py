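"""Synthetic data generators emulating the two experimental designs.

Two kinds of measurement are emulated:

* Reporter-gene constructs: a panel of regulatory elements in which a
  short-range repressor (Giant) is placed at varying distances, stoichiometry
  and arrangement around Dorsal activator sites, read out as normalized
  reporter expression against a normalized repressor gradient.  The
  "original" design mirrors the published 12-construct panel's
  bin-representation pattern (two quenching bins appear in 5 constructs, two
  in 2); "uniform" represents every bin equally; "combinatorial" represents
  every bin pair exactly once.

* Ventral-dorsal embryo profiles: normalized Dorsal, Twist and Snail
  gradients along the ventral-dorsal axis plus a rho-like stripe target (and
  its vnd-like companion) generated by the site-count model itself at a
  stated true parameter vector.

The generating model and the analysis model are the same code path, so at
zero noise the true parameter vector reproduces the data exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .objectives import (
    DataRecord,
    ExpressionDataset,
    fakhouri_params_from_vector,
    zinzen_params_from_vector,
)
from .parameter_space import ParameterSpace, default_zinzen_space
from .thermo_models import (
    ACTIVATOR,
    REPRESSOR,
    BindingSite,
    Construct,
    DistanceBinning,
    ZinzenStructure,
    default_binning,
    predict_expression_fakhouri,
    predict_expression_zinzen,
)

__all__ = [
    "ACT_FACTOR",
    "REP_FACTOR",
    "DesignSpec",
    "TruthSpec",
    "FakhouriDesign",
    "ZinzenProfileSet",
    "make_fakhouri_constructs",
    "make_repressor_gradient",
    "make_zinzen_profiles",
    "simulate_dataset",
    "zinzen_dataset",
    "default_zinzen_truth",
]

ACT_FACTOR = "Dl"
REP_FACTOR = "Gt"

_ACT_POS = 100
_CONSTRUCT_LENGTH = 150

# representative bp distances per quenching bin (two variants per bin, both
# inside the default bin intervals)
_BIN_DISTANCES = {
    "Q1": (3, 5),
    "Q2": (15, 22),
    "Q3": (32, 38),
    "Q4": (45, 48),
    "Q5": (52, 54),
}
_TERMINAL_OFFSETS = (30, 40)  # bp downstream of the activator for Q6 repressors


@dataclass(frozen=True)
class DesignSpec:
    """Which construct panel to generate.

    design "original" emulates the published 12-construct panel; "uniform"
    represents every quenching bin in an equal number of single-repressor
    constructs; "combinatorial" represents every unordered bin pair exactly
    once.  ``n_constructs`` defaults to the design's natural size.
    """

    design: str = "original"
    n_constructs: Optional[int] = None

    def __post_init__(self) -> None:
        if self.design not in ("original", "uniform", "combinatorial"):
            raise ValueError(f"unknown design {self.design!r}")


@dataclass(frozen=True)
class TruthSpec:
    """The generating ("true") parameter vector and observation noise.

    ``placement`` positions the truth at the scale-aware range midpoint or at
    lower + 0.9 * width ("near-edge"); an explicit ``values`` vector overrides
    placement.  Noise is additive Gaussian with standard deviation
    ``noise_sd`` on the expression scale, clipped to [0, 1].
    """

    placement: str = "mid-range"
    values: Optional[tuple[float, ...]] = None
    noise_sd: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.placement not in ("mid-range", "near-edge"):
            raise ValueError(f"unknown placement {self.placement!r}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    def resolve(self, space: ParameterSpace) -> np.ndarray:
        if self.values is not None:
            vec = np.asarray(self.values, dtype=float)
            if vec.shape != (len(space),):
                raise ValueError(f"truth vector length {vec.size} != space size {len(space)}")
            if not space.contains(vec):
                raise ValueError("true parameter values must lie inside the declared ranges")
            return vec
        u = 0.5 if self.placement == "mid-range" else 0.9
        return space.from_unit(np.full(len(space), u))


@dataclass
class FakhouriDesign:
    constructs: list[Construct]
    bin_table: pd.DataFrame  # constructs x bins, True where the bin is exercised
    spec: DesignSpec

    @property
    def representation_counts(self) -> dict[str, int]:
        return {b: int(self.bin_table[b].sum()) for b in self.bin_table.columns}


def _construct(cid: str, rep_distances: Sequence[int], terminal_offsets: Sequence[int] = ()) -> Construct:
    """One activator at a fixed position, repressors upstream at the given
    distances and optionally downstream (3'-terminal) at the given offsets."""
    sites = [BindingSite(REPRESSOR, REP_FACTOR, _ACT_POS - d) for d in sorted(rep_distances, reverse=True)]
    sites.append(BindingSite(ACTIVATOR, ACT_FACTOR, _ACT_POS))
    sites += [BindingSite(REPRESSOR, REP_FACTOR, _ACT_POS + o) for o in sorted(terminal_offsets)]
    sites.sort(key=lambda s: s.position)
    return Construct(cid, sites, _CONSTRUCT_LENGTH)


def _original_panel() -> list[Construct]:
    return [
        _construct("c01", [3]),
        _construct("c02", [15]),
        _construct("c03", [32]),
        _construct("c04", [45]),
        _construct("c05", [52]),
        _construct("c06", [], terminal_offsets=[40]),
        _construct("c07", [34, 4]),
        _construct("c08", [40, 6, 2]),
        _construct("c09", [54, 30]),
        _construct("c10", [5], terminal_offsets=[30]),
        _construct("c11", [28, 10, 3]),
        _construct("c12", [44, 22], terminal_offsets=[35]),
    ]


def make_fakhouri_constructs(
    spec: DesignSpec = DesignSpec(),
    binning: Optional[DistanceBinning] = None,
) -> FakhouriDesign:
    """Deterministic construct panel for a design, plus its bin table.

    The "original" 12-construct panel reproduces the published representation
    counts where they are stated: Q1 and Q3 each appear in 5 constructs, Q4
    and Q5 each in 2.
    """
    binning = binning or default_binning()
    labels = list(binning.labels)
    distance_bins = [lab for lab, _ in binning.bins]

    if spec.design == "original":
        n = spec.n_constructs or 12
        if n != 12:
            raise ValueError("the original design has exactly 12 constructs")
        constructs = _original_panel()
    elif spec.design == "uniform":
        n = spec.n_constructs or 12
        per_bin, rem = divmod(n, len(labels))
        if per_bin < 1 or rem != 0:
            raise ValueError(
                f"uniform design needs a construct count divisible by {len(labels)} bins, got {n}"
            )
        constructs = []
        idx = 1
        for rep in range(per_bin):
            for lab in labels:
                if lab == binning.terminal_bin:
                    c = _construct(f"u{idx:02d}", [], terminal_offsets=[_TERMINAL_OFFSETS[rep % 2]])
                else:
                    c = _construct(f"u{idx:02d}", [_BIN_DISTANCES[lab][rep % 2]])
                constructs.append(c)
                idx += 1
    else:  # combinatorial
        pairs = [(a, b) for i, a in enumerate(labels) for b in labels[i + 1:]]
        n = spec.n_constructs or len(pairs)
        if n != len(pairs):
            raise ValueError(
                f"combinatorial design over {len(labels)} bins has exactly {len(pairs)} constructs"
            )
        constructs = []
        for idx, (a, b) in enumerate(pairs, 1):
            dists, term = [], []
            for lab, variant in ((a, 0), (b, 1)):
                if lab == binning.terminal_bin:
                    term.append(_TERMINAL_OFFSETS[variant])
                else:
                    dists.append(_BIN_DISTANCES[lab][variant])
            constructs.append(_construct(f"p{idx:02d}", dists, terminal_offsets=term))

    rows = []
    for c in constructs:
        bins = set()
        for act in c.activators:
            for rep in c.repressors:
                bins.add(binning.assign(act, rep, c))
        rows.append({"construct": c.id, **{lab: lab in bins for lab in labels}})
    table = pd.DataFrame(rows).set_index("construct")

    if spec.design == "original":
        stated = {"Q1": 5, "Q3": 5, "Q4": 2, "Q5": 2}
        got = {k: int(table[k].sum()) for k in stated}
        assert got == stated, f"original panel violates stated representation counts: {got}"
    if spec.design == "uniform":
        counts = table.sum(axis=0)
        assert counts.nunique() == 1, "uniform design must represent every bin equally"
    return FakhouriDesign(constructs=constructs, bin_table=table, spec=spec)


def make_repressor_gradient(n_conditions: int, seed: Optional[int] = None, jitter: float = 0.0) -> np.ndarray:
    """Normalized repressor levels spanning [0, 1]; activator level is fixed at 1.

    A monotone grid, optionally jittered (uniform, reproducible per seed) and
    clipped back into [0, 1].
    """
    if n_conditions < 2:
        raise ValueError("need at least 2 conditions")
    grid = np.linspace(0.0, 1.0, n_conditions)
    if jitter > 0:
        rng = np.random.default_rng(seed)
        grid = np.clip(grid + rng.uniform(-jitter, jitter, size=n_conditions), 0.0, 1.0)
        grid.sort()
    return grid


def simulate_dataset(
    constructs: Sequence[Construct],
    truth: TruthSpec,
    gradient: np.ndarray,
    binning: DistanceBinning,
    space: ParameterSpace,
    pairing: str = "two_term",
    cooperativity_mode: str = "binding",
) -> ExpressionDataset:
    """Noisy reporter observations for every construct x repressor level.

    observed = model(truth) + N(0, noise_sd), clipped to [0, 1]; with
    noise_sd = 0 the observations equal the model output exactly.
    """
    theta = truth.resolve(space)
    params = fakhouri_params_from_vector(space, theta)
    rng = np.random.default_rng(truth.seed)
    gradient = np.asarray(gradient, dtype=float)
    records = []
    for c in constructs:
        conc = {ACT_FACTOR: np.ones_like(gradient), REP_FACTOR: gradient}
        pred = predict_expression_fakhouri(
            c, params, conc, binning, pairing=pairing, cooperativity_mode=cooperativity_mode
        )
        pred = np.atleast_1d(pred)
        obs = pred if truth.noise_sd == 0 else np.clip(
            pred + rng.normal(0.0, truth.noise_sd, size=pred.shape), 0.0, 1.0
        )
        for i, (g, o) in enumerate(zip(gradient, obs)):
            records.append(
                DataRecord(
                    element=c,
                    key=f"{c.id}:g{i:02d}",
                    concentrations={ACT_FACTOR: 1.0, REP_FACTOR: float(g)},
                    observed=float(o),
                )
            )
    return ExpressionDataset(
        records=records,
        model_family="fakhouri",
        binning=binning,
        provenance={
            "generator": "simulate_dataset",
            "truth": list(map(float, theta)),
            "placement": truth.placement,
            "noise_sd": truth.noise_sd,
            "seed": truth.seed,
            "n_conditions": int(gradient.size),
            "pairing": pairing,
            "cooperativity_mode": cooperativity_mode,
        },
    )


# --- ventral-dorsal profiles -------------------------------------------------

# eight synthetic (rho-like, vnd-like) structure pairs standing in for the
# informative enhancer-structure sets; site counts (n_D, n_T, n_S)
DEFAULT_STRUCTURE_SETS: tuple[tuple[ZinzenStructure, ZinzenStructure], ...] = tuple(
    (ZinzenStructure(*r, id=f"set{i}-rho"), ZinzenStructure(*v, id=f"set{i}-vnd"))
    for i, (r, v) in enumerate(
        [
            ((2, 2, 1), (2, 2, 1)),
            ((3, 2, 1), (2, 3, 1)),
            ((2, 3, 1), (3, 2, 1)),
            ((2, 2, 2), (2, 2, 1)),
            ((3, 3, 1), (2, 2, 1)),
            ((2, 1, 1), (1, 2, 1)),
            ((3, 2, 2), (2, 2, 2)),
            ((2, 3, 2), (3, 3, 1)),
        ],
        start=1,
    )
)


def default_zinzen_truth(space: Optional[ParameterSpace] = None) -> np.ndarray:
    """A true vector satisfying all three predicted cooperativity relationships
    (DTr > DTv, TTr > TTv, SSr < SSv), with mid-range scaling factors."""
    space = space or default_zinzen_space()
    values = {
        "D": 1e9, "T": 1e9, "S": 1e9,
        "DTr": 50.0, "TTr": 40.0, "SSr": 2.0,
        "DTv": 5.0, "TTv": 10.0, "SSv": 20.0,
    }
    return np.array([values[n] for n in space.names])


@dataclass
class ZinzenProfileSet:
    """Gradients plus model-generated targets along the ventral-dorsal axis."""

    frame: pd.DataFrame  # position, Dl, Twi, Sna, target_rho, target_vnd
    structures: tuple[tuple[ZinzenStructure, ZinzenStructure], ...]
    truth: np.ndarray
    set_index: int
    noise_sd: float
    seed: Optional[int]


def make_zinzen_profiles(
    n_positions: int,
    seed: Optional[int] = None,
    space: Optional[ParameterSpace] = None,
    truth: Optional[np.ndarray] = None,
    noise_sd: float = 0.05,
    set_index: int = 0,
) -> ZinzenProfileSet:
    """Ventral-dorsal factor gradients and a rho-like stripe target.

    The axis runs ventral (0) to dorsal (1).  Dorsal nuclear concentration is
    a broad exponential decline, Twist a similar but sharper one, and Snail a
    sharp ventral domain (high for x < ~0.2, then a steep fall).  The decays
    span the dynamic range the scaling factors (1e8-1e10) act on, so factor
    occupancy switches within the axis.  Targets are the site-count model's
    own output for the chosen structure pair at the true parameter vector,
    plus clipped Gaussian noise: the rho-like target is a lateral stripe —
    off in the Snail domain, peaking where Dorsal and Twist are high and
    Snail is absent.
    """
    if n_positions < 10:
        raise ValueError("need at least 10 positions")
    space = space or default_zinzen_space()
    theta = default_zinzen_truth(space) if truth is None else np.asarray(truth, dtype=float)
    params = zinzen_params_from_vector(space, theta)

    x = np.linspace(0.0, 1.0, n_positions)
    dl = np.exp(-30.0 * x)
    twi = np.exp(-45.0 * x)
    sna = np.exp(-250.0 * np.clip(x - 0.18, 0.0, None))
    conc = {"Dl": dl, "Twi": twi, "Sna": sna}

    rho_s, vnd_s = DEFAULT_STRUCTURE_SETS[set_index]
    target_rho = np.atleast_1d(predict_expression_zinzen(rho_s, params, "rho-like", conc))
    target_vnd = np.atleast_1d(predict_expression_zinzen(vnd_s, params, "vnd-like", conc))
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        target_rho = np.clip(target_rho + rng.normal(0.0, noise_sd, n_positions), 0.0, 1.0)
        target_vnd = np.clip(target_vnd + rng.normal(0.0, noise_sd, n_positions), 0.0, 1.0)
    frame = pd.DataFrame(
        {
            "position": x,
            "Dl": dl,
            "Twi": twi,
            "Sna": sna,
            "target_rho": target_rho,
            "target_vnd": target_vnd,
        }
    )
    return ZinzenProfileSet(
        frame=frame,
        structures=DEFAULT_STRUCTURE_SETS,
        truth=theta,
        set_index=set_index,
        noise_sd=noise_sd,
        seed=seed,
    )


def zinzen_dataset(profiles: ZinzenProfileSet) -> ExpressionDataset:
    """Pooled expression dataset over the rho-like and vnd-like targets."""
    rho_s, vnd_s = profiles.structures[profiles.set_index]
    records = []
    for _, row in profiles.frame.iterrows():
        conc = {"Dl": row["Dl"], "Twi": row["Twi"], "Sna": row["Sna"]}
        records.append(
            DataRecord(
                element=rho_s,
                key=f"rho:{row['position']:.4f}",
                concentrations=conc,
                observed=float(row["target_rho"]),
                class_tag="rho-like",
            )
        )
        records.append(
            DataRecord(
                element=vnd_s,
                key=f"vnd:{row['position']:.4f}",
                concentrations=conc,
                observed=float(row["target_vnd"]),
                class_tag="vnd-like",
            )
        )
    return ExpressionDataset(
        records=records,
        model_family="zinzen",
        provenance={
            "generator": "zinzen_dataset",
            "set_index": profiles.set_index,
            "truth": list(map(float, profiles.truth)),
            "noise_sd": profiles.noise_sd,
            "seed": profiles.seed,
        },
    )
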