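"""Thermodynamic (fractional-occupancy) models of enhancer-driven transcription.

Two model families are implemented by explicit enumeration of binding states:

* A construct-based model of short-range repression ("quenching"): an enhancer
  is an ordered list of activator and repressor binding sites with bp
  coordinates.  Each of the 2^n occupancy states receives a statistical weight
  built from binding terms (activator weight ``A * [act]``, repressor weight
  ``R * [rep]``) and homotypic repressor cooperativities (``C1``, ``C2``) for
  adjacent bound repressor pairs.  A state's expression contribution is the
  fraction of the construct's activators that are bound, each attenuated by
  ``(1 - Q_bin)`` for every bound repressor, where the quenching efficiency
  ``Q`` depends on the binned activator-repressor distance.  Total expression
  is the weight-averaged contribution over all states, so quenching parameters
  appear only in the numerator of the rational expression function while
  binding and cooperativity parameters appear in both numerator and
  denominator.

* A site-count model of the ventral-dorsal patterning network: an enhancer is
  described solely by its numbers of Dorsal, Twist and Snail sites.  State
  weights combine per-factor scaling terms (``D``, ``T``, ``S``) with
  Dorsal-Twist, Twist-Twist and Snail-Snail cooperativities; expression is the
  probability of a state with at least one bound activator and no bound Snail.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence, Union

import numpy as np

__all__ = [
    "BindingSite",
    "Construct",
    "DistanceBinning",
    "FakhouriParams",
    "ZinzenStructure",
    "ZinzenParams",
    "OccupancyState",
    "default_binning",
    "enumerate_states",
    "state_weight",
    "state_expression_contribution",
    "predict_expression_fakhouri",
    "predict_expression_zinzen",
    "FakhouriEvaluator",
]

STATE_CAP = 20  # largest site count enumerated exhaustively (2^20 states)

ACTIVATOR = "activator"
REPRESSOR = "repressor"


@dataclass(frozen=True)
class BindingSite:
    """A single transcription-factor binding site.

    ``position`` is the 1-based bp coordinate of the site center along the
    construct.
    """

    role: str
    factor: str
    position: int

    def __post_init__(self) -> None:
        if self.role not in (ACTIVATOR, REPRESSOR):
            raise ValueError(f"role must be 'activator' or 'repressor', got {self.role!r}")
        if self.position < 1:
            raise ValueError(f"position must be >= 1, got {self.position}")


@dataclass(frozen=True)
class Construct:
    """An ordered arrangement of binding sites on a regulatory element."""

    id: str
    sites: tuple[BindingSite, ...]
    length: int

    def __init__(self, id: str, sites: Iterable[BindingSite], length: int):
        sites = tuple(sites)
        positions = [s.position for s in sites]
        if any(b <= a for a, b in zip(positions, positions[1:])):
            raise ValueError(f"construct {id!r}: sites must be strictly ascending by position")
        if sites and length < max(positions):
            raise ValueError(f"construct {id!r}: length {length} < max site position {max(positions)}")
        object.__setattr__(self, "id", id)
        object.__setattr__(self, "sites", sites)
        object.__setattr__(self, "length", length)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def activators(self) -> tuple[BindingSite, ...]:
        return tuple(s for s in self.sites if s.role == ACTIVATOR)

    @property
    def repressors(self) -> tuple[BindingSite, ...]:
        return tuple(s for s in self.sites if s.role == REPRESSOR)


@dataclass(frozen=True)
class ZinzenStructure:
    """An enhancer described solely by binding-site counts (no arrangement)."""

    n_D: int
    n_T: int
    n_S: int
    id: str = ""

    def __post_init__(self) -> None:
        for name in ("n_D", "n_T", "n_S"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 0:
                raise ValueError(f"{name} must be a non-negative integer, got {v!r}")

    @property
    def n_sites(self) -> int:
        return self.n_D + self.n_T + self.n_S


@dataclass(frozen=True)
class DistanceBinning:
    """Maps activator-repressor bp distances onto quenching-parameter bins.

    ``bins`` are closed, non-overlapping bp intervals; ``terminal_bin`` is the
    label applied to any repressor positioned 3' of every activator in the
    construct (a lone repressor at the downstream end), irrespective of
    distance.
    """

    bins: tuple[tuple[str, tuple[int, int]], ...]
    terminal_bin: str = "Q6"

    def __post_init__(self) -> None:
        intervals = sorted(iv for _, iv in self.bins)
        for (a, b), (c, d) in zip(intervals, intervals[1:]):
            if c <= b:
                raise ValueError(f"overlapping bins: {(a, b)} and {(c, d)}")
        for lo, hi in intervals:
            if lo > hi:
                raise ValueError(f"bin interval {lo}-{hi} is empty")

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(lab for lab, _ in self.bins) + (self.terminal_bin,)

    def bin_of_distance(self, distance: int) -> str:
        for label, (lo, hi) in self.bins:
            if lo <= distance <= hi:
                return label
        raise ValueError(
            f"distance {distance} bp falls outside all bins "
            f"{[(lab, iv) for lab, iv in self.bins]}"
        )

    def assign(self, activator: BindingSite, repressor: BindingSite, construct: Construct) -> str:
        """Bin label for one activator-repressor pair in a construct."""
        act_max = max(s.position for s in construct.activators)
        if repressor.position > act_max:
            return self.terminal_bin
        return self.bin_of_distance(abs(activator.position - repressor.position))


def default_binning() -> DistanceBinning:
    """The default scheme: five distance bins plus the 3'-terminal bin."""
    return DistanceBinning(
        bins=(
            ("Q1", (0, 6)),
            ("Q2", (7, 27)),
            ("Q3", (28, 41)),
            ("Q4", (42, 49)),
            ("Q5", (50, 56)),
        ),
        terminal_bin="Q6",
    )


@dataclass(frozen=True)
class FakhouriParams:
    """Parameters of the construct-based quenching model.

    R is the repressor scaling factor (binding affinity x activity), Q maps
    each distance-bin label to a quenching efficiency in [0, 1], C1/C2 are the
    homotypic cooperativities awarded to the first (5'-most) and second
    adjacent bound repressor pair, and A is the activator binding weight
    (fixed by convention, not part of any fitted parameter set).
    """

    R: float
    Q: Mapping[str, float]
    C1: float = 1.0
    C2: float = 1.0
    A: float = 1.0

    def __post_init__(self) -> None:
        for name in ("R", "C1", "C2", "A"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for k, q in self.Q.items():
            if not (0.0 <= q <= 1.0):
                raise ValueError(f"quenching efficiency {k}={q} outside [0, 1]")


@dataclass(frozen=True)
class ZinzenParams:
    """Parameters of the site-count model.

    D, T, S are scaling factors for Dorsal, Twist and Snail sites; the
    cooperativity triples (DTr, TTr, SSr) and (DTv, TTv, SSv) apply to the
    rho-like and vnd-like enhancer class respectively.
    """

    D: float
    T: float
    S: float
    DTr: float
    TTr: float
    SSr: float
    DTv: float
    TTv: float
    SSv: float

    def __post_init__(self) -> None:
        for name in ("D", "T", "S", "DTr", "TTr", "SSr", "DTv", "TTv", "SSv"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")

    def cooperativities(self, class_tag: str) -> tuple[float, float, float]:
        if class_tag == "rho-like":
            return (self.DTr, self.TTr, self.SSr)
        if class_tag == "vnd-like":
            return (self.DTv, self.TTv, self.SSv)
        raise ValueError(f"unknown enhancer class {class_tag!r}; expected 'rho-like' or 'vnd-like'")


@dataclass(frozen=True)
class OccupancyState:
    """One bound/unbound configuration of a construct's sites.

    ``bound`` holds the indices (into ``sites``) of occupied sites.
    """

    sites: tuple[BindingSite, ...]
    bound: frozenset[int]

    @property
    def bound_sites(self) -> tuple[BindingSite, ...]:
        return tuple(self.sites[i] for i in sorted(self.bound))


def _sites_of(obj: Union[Construct, ZinzenStructure]) -> tuple[BindingSite, ...]:
    if isinstance(obj, Construct):
        return obj.sites
    # Synthesize anonymous sites for a count-only structure; positions are
    # placeholders (the model ignores them).
    sites = []
    pos = 1
    for factor, role, n in (
        ("Dl", ACTIVATOR, obj.n_D),
        ("Twi", ACTIVATOR, obj.n_T),
        ("Sna", REPRESSOR, obj.n_S),
    ):
        for _ in range(n):
            sites.append(BindingSite(role, factor, pos))
            pos += 1
    return tuple(sites)


def enumerate_states(construct_or_structure: Union[Construct, ZinzenStructure]) -> list[OccupancyState]:
    """All 2^n occupancy states of a construct or site-count structure.

    Raises for site counts above the enumeration cap (20 sites) rather than
    approximating.
    """
    sites = _sites_of(construct_or_structure)
    n = len(sites)
    if n > STATE_CAP:
        raise ValueError(f"construct has {n} sites; exhaustive enumeration is capped at {STATE_CAP}")
    states = []
    for r in range(n + 1):
        for combo in itertools.combinations(range(n), r):
            states.append(OccupancyState(sites=sites, bound=frozenset(combo)))
    return states


def _adjacent_repressor_pairs(sites: Sequence[BindingSite]) -> list[tuple[int, int]]:
    """Index pairs of repressor sites adjacent in the construct ordering.

    Adjacency requires no intervening site of any role: cooperative binding is
    a neighbor effect, so an activator between two repressors breaks the pair.
    """
    pairs = []
    for i in range(len(sites) - 1):
        if sites[i].role == REPRESSOR and sites[i + 1].role == REPRESSOR:
            pairs.append((i, i + 1))
    return pairs


def _coop_exponents(sites: Sequence[BindingSite], bound: frozenset[int], pairing: str) -> tuple[int, int]:
    """(#C1 pairs, #C2 pairs) among bound adjacent repressor pairs."""
    bound_pairs = [p for p in _adjacent_repressor_pairs(sites) if p[0] in bound and p[1] in bound]
    if pairing == "single_term":
        return len(bound_pairs), 0
    if pairing != "two_term":
        raise ValueError(f"unknown pairing mode {pairing!r}")
    # 5'-most bound pair takes C1, every further pair takes C2
    e1 = min(len(bound_pairs), 1)
    e2 = max(len(bound_pairs) - 1, 0)
    return e1, e2


def state_weight(
    state: OccupancyState,
    params: FakhouriParams,
    concentrations: Mapping[str, float],
    pairing: str = "two_term",
) -> float:
    """Statistical weight of one occupancy state (empty state has weight 1)."""
    w = 1.0
    for i in sorted(state.bound):
        site = state.sites[i]
        if site.factor not in concentrations:
            raise KeyError(f"no concentration given for factor {site.factor!r}")
        conc = concentrations[site.factor]
        if conc < 0:
            raise ValueError(f"concentration of {site.factor!r} is negative")
        scale = params.A if site.role == ACTIVATOR else params.R
        w *= scale * conc
    e1, e2 = _coop_exponents(state.sites, state.bound, pairing)
    w *= params.C1 ** e1 * params.C2 ** e2
    return w


def state_expression_contribution(
    state: OccupancyState,
    params: FakhouriParams,
    construct: Construct,
    binning: DistanceBinning,
) -> float:
    """Expression contribution of a state, in [0, 1].

    Each bound activator contributes 1/n_A (n_A = the construct's activator
    count), attenuated by (1 - Q) for every bound repressor according to the
    binned pair distance; a state with no bound activator contributes 0.
    """
    if state.sites != construct.sites:
        raise ValueError("state does not belong to the given construct")
    n_act = len(construct.activators)
    if n_act == 0:
        return 0.0
    bound_sites = [state.sites[i] for i in sorted(state.bound)]
    bound_reps = [s for s in bound_sites if s.role == REPRESSOR]
    total = 0.0
    for act in bound_sites:
        if act.role != ACTIVATOR:
            continue
        term = 1.0
        for rep in bound_reps:
            label = binning.assign(act, rep, construct)
            if label not in params.Q:
                raise KeyError(f"no quenching efficiency for bin {label!r} (binning: {binning.labels})")
            term *= 1.0 - params.Q[label]
        total += term
    return total / n_act


class FakhouriEvaluator:
    """Precompiled state enumeration of one construct for fast evaluation.

    Builds the occupancy-state tensors once, then evaluates total expression
    for a parameter set over a whole vector of repressor/activator
    concentration conditions in a handful of numpy operations.  This is the
    same model as the per-state functions above, restated in array form.
    """

    def __init__(self, construct: Construct, binning: DistanceBinning, pairing: str = "two_term"):
        if construct.n_sites > STATE_CAP:
            raise ValueError(
                f"construct {construct.id!r} has {construct.n_sites} sites; cap is {STATE_CAP}"
            )
        self.construct = construct
        self.binning = binning
        self.pairing = pairing
        self.bin_labels = list(binning.labels)

        sites = construct.sites
        n = len(sites)
        states = list(itertools.product((0, 1), repeat=n))
        S = len(states)
        bound = np.array(states, dtype=bool)  # (S, n)
        is_act = np.array([s.role == ACTIVATOR for s in sites])
        is_rep = ~is_act
        self.factors = sorted({s.factor for s in sites})
        fidx = {f: i for i, f in enumerate(self.factors)}

        # per-state counts of bound sites per factor, and bound act/rep counts
        self.cnt_factor = np.zeros((S, len(self.factors)), dtype=np.int64)
        for j, s in enumerate(sites):
            self.cnt_factor[:, fidx[s.factor]] += bound[:, j]
        self.n_act_bound = bound[:, is_act].sum(axis=1)
        self.n_rep_bound = bound[:, is_rep].sum(axis=1)

        # cooperativity exponents
        e1 = np.zeros(S, dtype=np.int64)
        e2 = np.zeros(S, dtype=np.int64)
        for si, st in enumerate(states):
            bset = frozenset(i for i, b in enumerate(st) if b)
            e1[si], e2[si] = _coop_exponents(sites, bset, pairing)
        self.e1, self.e2 = e1, e2

        # quenching-bin exponents: cnt_bins[s, a, b] = bound repressors of
        # state s in bin b relative to activator site a
        act_idx = [j for j in range(n) if is_act[j]]
        nb = len(self.bin_labels)
        self.act_bound = bound[:, act_idx]  # (S, nA)
        cnt_bins = np.zeros((S, len(act_idx), nb), dtype=np.int64)
        lab_i = {lab: i for i, lab in enumerate(self.bin_labels)}
        for ai, j in enumerate(act_idx):
            for r in range(n):
                if not is_rep[r]:
                    continue
                lab = binning.assign(sites[j], sites[r], construct)
                cnt_bins[:, ai, lab_i[lab]] += bound[:, r]
        self.cnt_bins = cnt_bins
        self.n_act_total = len(act_idx)

    def expression(
        self,
        params: FakhouriParams,
        concentrations: Mapping[str, Union[float, np.ndarray]],
        cooperativity_mode: str = "binding",
    ) -> np.ndarray:
        """Total expression for each concentration condition, in [0, 1]."""
        if cooperativity_mode not in ("binding", "post_binding"):
            raise ValueError(f"unknown cooperativity mode {cooperativity_mode!r}")
        conc = []
        for f in self.factors:
            if f not in concentrations:
                raise KeyError(f"no concentration given for factor {f!r}")
            conc.append(np.atleast_1d(np.asarray(concentrations[f], dtype=float)))
        conc = np.broadcast_arrays(*conc)
        if np.any(np.array(conc) < 0):
            raise ValueError("concentrations must be >= 0")
        P = conc[0].shape[0]

        # binding weights without cooperativity: (S, P)
        w0 = (params.A ** self.n_act_bound * params.R ** self.n_rep_bound)[:, None] * np.ones((1, P))
        for fi in range(len(self.factors)):
            w0 = w0 * conc[fi][None, :] ** self.cnt_factor[:, fi, None]
        coop = (params.C1 ** self.e1 * params.C2 ** self.e2)[:, None]

        qvec = np.array([params.Q.get(lab, 0.0) for lab in self.bin_labels])
        for lab in self.bin_labels:
            if lab not in params.Q and np.any(self.cnt_bins[:, :, self.bin_labels.index(lab)]):
                raise KeyError(f"no quenching efficiency for bin {lab!r}")
        attenuation = np.prod((1.0 - qvec) ** self.cnt_bins, axis=2)  # (S, nA)
        if self.n_act_total:
            e_state = (attenuation * self.act_bound).sum(axis=1) / self.n_act_total
        else:
            e_state = np.zeros(w0.shape[0])

        numer = (w0 * coop * e_state[:, None]).sum(axis=0)
        denom = (w0 if cooperativity_mode == "post_binding" else w0 * coop).sum(axis=0)
        return numer / denom


_EVALUATOR_CACHE: dict[tuple, FakhouriEvaluator] = {}


def _evaluator(construct: Construct, binning: DistanceBinning, pairing: str) -> FakhouriEvaluator:
    key = (id(construct), id(binning), pairing)
    ev = _EVALUATOR_CACHE.get(key)
    if ev is None or ev.construct is not construct or ev.binning is not binning:
        ev = FakhouriEvaluator(construct, binning, pairing)
        _EVALUATOR_CACHE[key] = ev
    return ev


def predict_expression_fakhouri(
    construct: Construct,
    params: FakhouriParams,
    concentrations: Mapping[str, Union[float, np.ndarray]],
    binning: DistanceBinning,
    pairing: str = "two_term",
    cooperativity_mode: str = "binding",
) -> Union[float, np.ndarray]:
    """Total expression of a construct: E = sum_s W_s E_s / sum_s W_s.

    ``concentrations`` maps factor names to scalars (one condition) or equal
    length arrays (one value per condition).  In the default "binding"
    cooperativity mode C terms appear in both numerator and denominator; in
    "post_binding" mode cooperativity reweights only the numerator.
    """
    ev = _evaluator(construct, binning, pairing)
    out = ev.expression(params, concentrations, cooperativity_mode)
    scalar = all(np.isscalar(v) or np.ndim(v) == 0 for v in concentrations.values())
    return float(out[0]) if scalar else out


def predict_expression_zinzen(
    structure: ZinzenStructure,
    params: ZinzenParams,
    class_tag: str,
    position_concentrations: Mapping[str, Union[float, np.ndarray]],
) -> Union[float, np.ndarray]:
    """Expression of a site-count enhancer at each position along the axis.

    States are enumerated by bound-site counts (i, j, k) with binomial
    multiplicities — an exact grouping of the 2^n site-level states, since
    sites of one factor are interchangeable.  A state activates iff it has at
    least one bound activator (Dorsal or Twist) and no bound Snail; Snail
    repression is absolute.
    """
    DT, TT, SS = params.cooperativities(class_tag)
    conc = {}
    for f in ("Dl", "Twi", "Sna"):
        if f not in position_concentrations:
            raise KeyError(f"no concentration given for factor {f!r}")
        conc[f] = np.atleast_1d(np.asarray(position_concentrations[f], dtype=float))
    dl, twi, sna = np.broadcast_arrays(conc["Dl"], conc["Twi"], conc["Sna"])
    if np.any(dl < 0) or np.any(twi < 0) or np.any(sna < 0):
        raise ValueError("concentrations must be >= 0")

    nD, nT, nS = structure.n_D, structure.n_T, structure.n_S
    I, J, K = np.meshgrid(np.arange(nD + 1), np.arange(nT + 1), np.arange(nS + 1), indexing="ij")
    I, J, K = I.ravel(), J.ravel(), K.ravel()
    mult = (
        np.array([math.comb(nD, i) for i in I])
        * np.array([math.comb(nT, j) for j in J])
        * np.array([math.comb(nS, k) for k in K])
    ).astype(float)
    coop = DT ** (I * J) * TT ** (J * (J - 1) // 2) * SS ** (K * (K - 1) // 2)
    active = ((I + J) >= 1) & (K == 0)

    # weights: (P, n_states)
    w = (
        mult[None, :]
        * (params.D * dl[:, None]) ** I[None, :]
        * (params.T * twi[:, None]) ** J[None, :]
        * (params.S * sna[:, None]) ** K[None, :]
        * coop[None, :]
    )
    expr = w[:, active].sum(axis=1) / w.sum(axis=1)
    scalar = all(np.isscalar(v) or np.ndim(v) == 0 for v in position_concentrations.values())
    return float(expr[0]) if scalar else expr
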