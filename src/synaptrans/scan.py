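"""Parameter scans, bifurcation diagrams, transition location, regime tables.

A scan sweeps one model or delay parameter over a grid, runs an attractor
census at every grid value and tracks attractor branches across adjacent
values by nearest-fingerprint matching.  A branch may change character
along the sweep (a cycle can period-double its way into chaos and remain
one branch), so branch matching compares ordinate geometry, not category.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .integrate import IntegrationSettings
from .parameters import (
    DelayParameters,
    ModelParameters,
    ParameterDomainError,
)
from .regimes import (
    AttractorSignature,
    CensusEntry,
    ClassifierSettings,
    PoincareSection,
    Regime,
    attractor_census,
)

__all__ = [
    "ScanSpec",
    "BranchPoint",
    "BifurcationDiagram",
    "TransitionEstimate",
    "RegimeTable",
    "scan_parameter",
    "locate_transition",
    "regime_table",
    "cell_symbol",
]

_DELAY_FIELDS = set(DelayParameters.__dataclass_fields__)
_MODEL_FIELDS = set(ModelParameters.__dataclass_fields__)

# named category groups accepted by locate_transition
CATEGORY_GROUPS: dict[str, frozenset[Regime]] = {
    "stationary": frozenset({Regime.STATIONARY, Regime.ZERO}),
    "oscillatory": frozenset({Regime.PERIODIC, Regime.QUASIPERIODIC,
                              Regime.CHAOTIC}),
    "periodic": frozenset({Regime.PERIODIC}),
    "chaotic": frozenset({Regime.CHAOTIC}),
}


@dataclass(frozen=True)
class ScanSpec:
    """One-parameter sweep description.

    ``couple_kdz`` applies the endosomal-balance convention
    k_dz = 1 - k_rz whenever k_rz changes (the convention under which the
    reference sweeps are run); it is ignored for other parameters.
    ``n_starts = 1`` scans the standard history only, larger values run a
    multi-start census per grid value.
    """

    parameter: str
    grid: tuple[float, ...]
    couple_kdz: bool = True
    n_starts: int = 1
    seed: int = 0
    # continue each attractor found at the previous grid value by feeding
    # its final state in as an extra start (how a swept diagram tracks a
    # branch whose basin shrinks)
    continue_branches: bool = True
    section: PoincareSection = PoincareSection()
    int_settings: IntegrationSettings = IntegrationSettings()
    cls_settings: ClassifierSettings = ClassifierSettings()
    branch_tol: float = 0.3
    branch_gap_max: int = 2
    # radial probing for concentric coexisting cycles (see attractor_census);
    # disable for single-history sweeps that replicate one-trajectory diagrams
    radial_probe_factors: tuple[float, ...] = (0.5, 3.0)

    def __post_init__(self):
        if self.parameter not in _MODEL_FIELDS | _DELAY_FIELDS:
            raise ParameterDomainError(f"unknown scan parameter {self.parameter!r}")
        g = np.asarray(self.grid, dtype=float)
        if g.size == 0:
            raise ParameterDomainError("scan grid must be nonempty")
        if g.size > 1 and not (np.all(np.diff(g) > 0) or np.all(np.diff(g) < 0)):
            raise ParameterDomainError("scan grid must be strictly monotone")
        if self.parameter == "k_dz" and self.couple_kdz:
            raise ParameterDomainError(
                "cannot scan k_dz while it is coupled to k_rz")


@dataclass
class BranchPoint:
    value: float
    branch_id: int
    entry: CensusEntry


@dataclass
class BifurcationDiagram:
    """Census results along a sweep with branch identities attached."""

    parameter: str
    grid: np.ndarray
    points: list[list[BranchPoint]]          # one list per grid value
    base_params: ModelParameters
    base_delays: DelayParameters
    spec: ScanSpec

    def categories_at(self, i: int) -> set[Regime]:
        return {bp.entry.signature.category for bp in self.points[i]}

    def section_visible(self) -> np.ndarray:
        """Per grid value: does any attractor intersect the configured
        Poincaré plane?  This is what the plotted diagram shows — a cycle
        that misses the plane leaves its column empty."""
        return np.array([any(bp.entry.signature.on_section for bp in col)
                         for col in self.points])

    def branches(self) -> dict[int, list[BranchPoint]]:
        out: dict[int, list[BranchPoint]] = {}
        for col in self.points:
            for bp in col:
                out.setdefault(bp.branch_id, []).append(bp)
        return out

    def branch_extent(self, branch_id: int) -> tuple[float, float]:
        vals = [bp.value for bps in self.points for bp in bps
                if bp.branch_id == branch_id]
        return (min(vals), max(vals))

    def to_tsv(self, path: str | Path) -> None:
        """One row per plotted ordinate: value, branch, category, ordinate."""
        rows = []
        for col in self.points:
            for bp in col:
                sig = bp.entry.signature
                ords = bp.entry.ordinates_sample
                if ords is None or len(ords) == 0:
                    ords = [sig.mean_level]
                for o in np.asarray(ords, dtype=float):
                    rows.append((bp.value, bp.branch_id, sig.category.value, o))
        df = pd.DataFrame(rows, columns=[self.parameter, "branch", "category",
                                         "ordinate"])
        df.to_csv(path, sep="\t", index=False)

    def plot(self, ax=None, **kwargs):
        """Scatter of crossing ordinates vs the swept parameter, one color
        per branch (requires matplotlib)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        for bid, bps in sorted(self.branches().items()):
            vx, vy = [], []
            for bp in bps:
                ords = bp.entry.ordinates_sample
                if ords is None or len(ords) == 0:
                    ords = [bp.entry.signature.mean_level]
                vx.extend([bp.value] * len(ords))
                vy.extend(np.asarray(ords, dtype=float))
            ax.plot(vx, vy, ".", ms=2, label=f"branch {bid}", **kwargs)
        ax.set_xlabel(self.parameter)
        ax.set_ylabel("crossing ordinate")
        return ax


@dataclass
class TransitionEstimate:
    """A located regime transition with its bracketing interval."""

    parameter: str
    lower: float
    upper: float
    refined: float | None = None
    all_intervals: list[tuple[float, float]] = field(default_factory=list)

    @property
    def found(self) -> bool:
        return np.isfinite(self.lower)


def _apply_value(
    p: ModelParameters, d: DelayParameters, name: str, value: float,
    couple_kdz: bool,
) -> tuple[ModelParameters, DelayParameters]:
    if name in _DELAY_FIELDS:
        return p, d.replace(**{name: value})
    if name == "k_rz" and couple_kdz:
        return p.with_recycling(value), d
    return p.replace(**{name: value}), d


def _branch_summary(sig: AttractorSignature) -> np.ndarray:
    """(low, mid, high) ordinate geometry used for branch continuity."""
    if sig.category in (Regime.ZERO, Regime.STATIONARY):
        v = sig.mean_level
        return np.array([v, v, v])
    o = np.asarray(sig.ordinates, dtype=float)
    if o.size == 0:
        v = sig.mean_level
        return np.array([v, v, v])
    return np.array([o.min(), float(np.median(o)), o.max()])


def _branch_distance(a: AttractorSignature, b: AttractorSignature) -> float:
    osc = (Regime.PERIODIC, Regime.QUASIPERIODIC, Regime.CHAOTIC)
    a_osc, b_osc = a.category in osc, b.category in osc
    if a_osc != b_osc:
        return np.inf
    return float(np.max(np.abs(_branch_summary(a) - _branch_summary(b))))


def scan_parameter(
    spec: ScanSpec,
    base_p: ModelParameters | None = None,
    base_d: DelayParameters | None = None,
) -> BifurcationDiagram:
    """Sweep one parameter, running a census per grid value.

    Integration failures at a grid value are recorded as UNRESOLVED
    entries and the sweep continues.  Deterministic given ``spec.seed``.
    """
    base_p = base_p or ModelParameters()
    base_d = base_d or DelayParameters()
    grid = np.asarray(spec.grid, dtype=float)

    points: list[list[BranchPoint]] = []
    # open branches: branch_id -> (last signature, last grid index)
    open_branches: dict[int, tuple[AttractorSignature, int]] = {}
    next_id = 0
    carry: list = []  # trailing segments of the previous point's attractors
    for i, v in enumerate(grid):
        p, d = _apply_value(base_p, base_d, spec.parameter, float(v),
                            spec.couple_kdz)
        try:
            entries = attractor_census(
                p, d, section=spec.section, n_starts=spec.n_starts,
                seed=spec.seed, int_settings=spec.int_settings,
                settings=spec.cls_settings,
                extra_histories=carry if spec.continue_branches else (),
                radial_probe_factors=spec.radial_probe_factors)
        except Exception as exc:  # per-point failure -> UNRESOLVED cell
            from .integrate import STANDARD_HISTORY

            sig = AttractorSignature(Regime.UNRESOLVED, (), np.nan, np.nan)
            failed = CensusEntry(sig, 0, STANDARD_HISTORY(d.horizon))
            failed.error = repr(exc)  # type: ignore[attr-defined]
            entries = [failed]

        col: list[BranchPoint] = []
        taken: set[int] = set()
        for e in entries:
            best_id, best_dist = -1, np.inf
            for bid, (sig_prev, idx_prev) in open_branches.items():
                if bid in taken or i - idx_prev > spec.branch_gap_max:
                    continue
                dist = _branch_distance(e.signature, sig_prev)
                if dist < best_dist:
                    best_id, best_dist = bid, dist
            if best_dist <= spec.branch_tol:
                bid = best_id
            else:
                bid = next_id
                next_id += 1
            taken.add(bid)
            open_branches[bid] = (e.signature, i)
            col.append(BranchPoint(value=float(v), branch_id=bid, entry=e))
        points.append(col)
        # drop stale branches
        open_branches = {bid: (s, j) for bid, (s, j) in open_branches.items()
                         if i - j <= spec.branch_gap_max}
        if spec.continue_branches:
            carry = [e.tail for e in entries
                     if e.signature.category is not Regime.UNRESOLVED
                     and e.tail is not None]
    return BifurcationDiagram(
        parameter=spec.parameter, grid=grid, points=points,
        base_params=base_p, base_delays=base_d, spec=spec)


def _as_category_set(cat) -> frozenset[Regime]:
    if isinstance(cat, Regime):
        return frozenset({cat})
    if isinstance(cat, str):
        if cat in CATEGORY_GROUPS:
            return CATEGORY_GROUPS[cat]
        return frozenset({Regime(cat)})
    return frozenset(cat)


def locate_transition(
    diagram: BifurcationDiagram,
    from_category,
    to_category,
    refine_tol: float | None = None,
) -> TransitionEstimate:
    """Bracket (and optionally bisect) a regime transition along the sweep.

    Scans the grid for adjacent pairs where ``from_category`` is present
    on the left and ``to_category`` on the right (and the two differ);
    every such interval is reported.  When ``refine_tol`` is given, the
    first interval is refined by bisection, re-running the census at
    probe points; the refined value always lies inside its bracket.
    Categories may be a Regime, an iterable of Regimes, or a named group
    ("stationary", "oscillatory", "periodic", "chaotic").
    """
    want_from = _as_category_set(from_category)
    want_to = _as_category_set(to_category)
    grid = diagram.grid
    intervals: list[tuple[float, float]] = []
    for i in range(grid.size - 1):
        c0, c1 = diagram.categories_at(i), diagram.categories_at(i + 1)
        if (c0 & want_from) and (c1 & want_to) and not (c1 & want_from):
            intervals.append((float(grid[i]), float(grid[i + 1])))
    if not intervals:
        return TransitionEstimate(diagram.parameter, np.nan, np.nan,
                                  all_intervals=[])
    lo, hi = intervals[0]
    refined = None
    if refine_tol is not None:
        spec = diagram.spec
        while hi - lo > refine_tol:
            mid = 0.5 * (lo + hi)
            p, d = _apply_value(diagram.base_params, diagram.base_delays,
                                diagram.parameter, mid, spec.couple_kdz)
            entries = attractor_census(
                p, d, section=spec.section, n_starts=spec.n_starts,
                seed=spec.seed, int_settings=spec.int_settings,
                settings=spec.cls_settings,
                radial_probe_factors=spec.radial_probe_factors)
            cats = {e.signature.category for e in entries}
            if cats & want_from:
                lo = mid
            else:
                hi = mid
        refined = 0.5 * (lo + hi)
    return TransitionEstimate(diagram.parameter, lo, hi, refined,
                              all_intervals=intervals)


# --------------------------------------------------------------------------
# Regime tables
# --------------------------------------------------------------------------

def cell_symbol(entries: Iterable[CensusEntry]) -> str:
    """Render a census as a table symbol: S, 0, P, 2P, QP, C, P+C, ...

    Multiple coexisting cycles print their count ("2P"); coexisting
    periodic and chaotic attractors print "P+C".  An empty or fully
    unresolved census prints "?".
    """
    entries = list(entries)
    n_per = sum(1 for e in entries if e.signature.category is Regime.PERIODIC)
    n_chaos = sum(1 for e in entries if e.signature.category is Regime.CHAOTIC)
    n_qp = sum(1 for e in entries
               if e.signature.category is Regime.QUASIPERIODIC)
    n_stat = sum(1 for e in entries
                 if e.signature.category is Regime.STATIONARY)
    n_zero = sum(1 for e in entries if e.signature.category is Regime.ZERO)
    parts: list[str] = []
    if n_per:
        parts.append("P" if n_per == 1 else f"{n_per}P")
    if n_qp:
        parts.append("QP")
    if n_chaos:
        parts.append("C")
    if not parts:  # purely stationary cell
        if n_stat:
            return "S"
        if n_zero:
            return "0"
        return "?"
    if n_stat:
        parts.append("S")
    elif n_zero:
        parts.append("0")
    return "+".join(parts)


@dataclass
class RegimeTable:
    """Grid of regime symbols over (h_b, k_x) x K_a x k_rz."""

    h_x: float
    table: pd.DataFrame           # index (h_b, k_x); columns (K_a, k_rz)
    censuses: dict = field(default_factory=dict)

    def symbol(self, h_b: float, k_x: float, K_a: float, k_rz: float) -> str:
        return self.table.loc[(h_b, k_x), (K_a, k_rz)]

    def to_text(self) -> str:
        return self.table.to_string()

    def to_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t")


def regime_table(
    h_x: float,
    base_p: ModelParameters | None = None,
    base_d: DelayParameters | None = None,
    h_b_values: Sequence[float] = (5, 10, 15, 20),
    k_x_values: Sequence[float] = (10, 20, 40),
    K_a_values: Sequence[float] = (1, 2, 3),
    k_rz_values: Sequence[float] = (0.0, 0.5, 1.0),
    n_starts: int = 12,
    seed: int = 0,
    section: PoincareSection = PoincareSection(),
    int_settings: IntegrationSettings | None = None,
    cls_settings: ClassifierSettings = ClassifierSettings(),
) -> RegimeTable:
    """Census-backed regime table at fixed h_x (k_dz = 1 - k_rz per cell)."""
    base_p = (base_p or ModelParameters()).replace(h_x=h_x)
    base_d = base_d or DelayParameters()
    int_settings = int_settings or IntegrationSettings()
    cells: dict = {}
    censuses: dict = {}
    for h_b in h_b_values:
        for k_x in k_x_values:
            for K_a in K_a_values:
                for k_rz in k_rz_values:
                    p = base_p.replace(h_b=h_b, k_x=k_x, K_a=K_a).with_recycling(k_rz)
                    entries = attractor_census(
                        p, base_d, section=section, n_starts=n_starts,
                        seed=seed, int_settings=int_settings,
                        settings=cls_settings)
                    cells[(h_b, k_x, K_a, k_rz)] = cell_symbol(entries)
                    censuses[(h_b, k_x, K_a, k_rz)] = entries
    idx = pd.MultiIndex.from_product([h_b_values, k_x_values],
                                     names=["h_b", "k_x"])
    cols = pd.MultiIndex.from_product([K_a_values, k_rz_values],
                                      names=["K_a", "k_rz"])
    df = pd.DataFrame(index=idx, columns=cols, dtype=object)
    for (h_b, k_x, K_a, k_rz), sym in cells.items():
        df.loc[(h_b, k_x), (K_a, k_rz)] = sym
    return RegimeTable(h_x=h_x, table=df, censuses=censuses)
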