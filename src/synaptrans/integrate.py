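"""Integration of the delayed Cauchy problem.

The initial data of a delay system is a *history function* on
[-horizon, 0]; the reference runs all use the constant history
x = 2.5, y = 0.5, z = 5.  Integration is fixed-step RK4 by the method of
steps (see ``_kernel``), returning a :class:`Trajectory` with dense cubic
Hermite evaluation between nodes.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import _kernel
from .model import State
from .parameters import (
    DelayParameters,
    ModelParameters,
    ParameterDomainError,
    validate_parameters,
)

__all__ = [
    "HistoryFunction",
    "SegmentHistory",
    "IntegrationSettings",
    "Trajectory",
    "IntegrationError",
    "make_history",
    "STANDARD_HISTORY",
    "integrate_dde",
    "integrate_twin",
    "dense_eval",
]


class IntegrationError(RuntimeError):
    """The trajectory left its admissible domain during integration."""


@dataclass(frozen=True)
class HistoryFunction:
    """Constant initial history on [-horizon, 0]."""

    x: float
    y: float
    z: float
    horizon: float

    def __post_init__(self):
        if min(self.x, self.y, self.z) < 0:
            raise ParameterDomainError("history values must be >= 0")
        if self.horizon < 0:
            raise ParameterDomainError("history horizon must be >= 0")

    def __call__(self, t: float) -> State:
        if not -self.horizon <= t <= 0:
            raise ValueError(
                f"history is defined on [{-self.horizon}, 0], asked for t={t}"
            )
        return State(self.x, self.y, self.z)

    def perturbed(self, epsilon: float, components: tuple[str, ...] = ("x",)) -> "HistoryFunction":
        vals = {"x": self.x, "y": self.y, "z": self.z}
        for c in components:
            vals[c] = vals[c] + epsilon
        return HistoryFunction(vals["x"], vals["y"], vals["z"], self.horizon)

    def triple(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z], dtype=np.float64)

    def _kernel_arrays(self, h: float):
        Hs = self.triple().reshape(1, 3)
        return Hs, np.zeros((1, 3)), 0


@dataclass(frozen=True)
class SegmentHistory:
    """Piecewise dense history on [-horizon, 0]: a stored solution segment.

    Produced by :meth:`Trajectory.tail_history` to warm-start an
    integration from where a previous one ended — the proper way to
    continue an attractor branch across a parameter change, since the
    delayed state on an attractor is a whole function segment, not a
    point.  Node spacing must match the integration step.
    """

    states: np.ndarray   # (m+1, 3), node at index m is t = 0
    derivs: np.ndarray   # (m+1, 3)
    h: float

    def __post_init__(self):
        s = np.asarray(self.states, dtype=float)
        if s.ndim != 2 or s.shape[1] != 3 or s.shape[0] < 2:
            raise ParameterDomainError("segment history needs >= 2 nodes x 3")
        if np.any(s < 0):
            raise ParameterDomainError("history values must be >= 0")

    @property
    def horizon(self) -> float:
        return (self.states.shape[0] - 1) * self.h

    def __call__(self, t: float) -> State:
        if not -self.horizon - 1e-12 <= t <= 1e-12:
            raise ValueError(
                f"history is defined on [{-self.horizon}, 0], asked for t={t}")
        s = np.clip(t / self.h + (self.states.shape[0] - 1), 0,
                    self.states.shape[0] - 1)
        j = min(int(s), self.states.shape[0] - 2)
        th = s - j
        h00 = (2 * th ** 3 - 3 * th ** 2 + 1)
        h10 = (th ** 3 - 2 * th ** 2 + th)
        h01 = (-2 * th ** 3 + 3 * th ** 2)
        h11 = (th ** 3 - th ** 2)
        v = (h00 * self.states[j] + h10 * self.h * self.derivs[j]
             + h01 * self.states[j + 1] + h11 * self.h * self.derivs[j + 1])
        return State(*v)

    def perturbed(self, epsilon: float, components: tuple[str, ...] = ("x",)) -> "SegmentHistory":
        s = self.states.copy()
        for c in components:
            s[:, {"x": 0, "y": 1, "z": 2}[c]] += epsilon
        return SegmentHistory(s, self.derivs, self.h)

    def _kernel_arrays(self, h: float):
        if abs(h - self.h) > 1e-12:
            raise ParameterDomainError(
                f"segment history spacing {self.h} != integration step {h}")
        return (np.ascontiguousarray(self.states),
                np.ascontiguousarray(self.derivs),
                self.states.shape[0] - 1)


def make_history(x0: float, y0_init: float, z0: float, horizon: float) -> HistoryFunction:
    """Constant history function on [-horizon, 0]."""
    return HistoryFunction(x0, y0_init, z0, horizon)


def STANDARD_HISTORY(horizon: float) -> HistoryFunction:
    """The standard constant history x=2.5, y=0.5, z=5 of the reference runs."""
    return make_history(2.5, 0.5, 5.0, horizon)


@dataclass(frozen=True)
class IntegrationSettings:
    """Fixed-step settings.

    ``h`` must not exceed the smallest positive delay (a lag lookup must
    never land inside the current step); a warning-level guideline is
    h <= min delay / 20 for resolution of the delay kinetics.
    """

    h: float = 0.01
    t_end: float = 4000.0
    neg_tol: float = 1e-9

    def __post_init__(self):
        if self.h <= 0:
            raise ParameterDomainError(f"step h must be > 0, got {self.h}")
        if self.t_end <= 0:
            raise ParameterDomainError(f"t_end must be > 0, got {self.t_end}")

    @property
    def n_steps(self) -> int:
        return int(round(self.t_end / self.h))


@dataclass
class Trajectory:
    """Dense-output solution of one Cauchy problem on a uniform grid."""

    t: np.ndarray                 # (n+1,) uniform, t[0] = 0
    states: np.ndarray            # (n+1, 3) columns x, y, z
    derivs: np.ndarray | None = None   # (n+1, 3) node derivatives (Hermite data)
    params: ModelParameters | None = None
    delays: DelayParameters | None = None
    history: HistoryFunction | None = None
    h: float = field(default=0.0)

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.states = np.asarray(self.states, dtype=float)
        if self.t.ndim != 1 or self.states.shape != (self.t.size, 3):
            raise ValueError("t must be (n,) and states (n, 3)")
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("time grid must be strictly increasing")
        if self.h == 0.0:
            self.h = float(self.t[1] - self.t[0])
        if self.derivs is None:
            # fallback Hermite data from finite differences (O(h^2) dense error)
            self.derivs = np.gradient(self.states, self.t, axis=0)
        else:
            self.derivs = np.asarray(self.derivs, dtype=float)

    @property
    def x(self) -> np.ndarray:
        return self.states[:, 0]

    @property
    def y(self) -> np.ndarray:
        return self.states[:, 1]

    @property
    def z(self) -> np.ndarray:
        return self.states[:, 2]

    @property
    def t_end(self) -> float:
        return float(self.t[-1])

    def __call__(self, tq):
        return dense_eval(self, tq)

    def window(self, t_from: float, t_to: float | None = None) -> "Trajectory":
        """Sub-trajectory on [t_from, t_to] (node-aligned)."""
        t_to = self.t_end if t_to is None else t_to
        sel = (self.t >= t_from - 1e-12) & (self.t <= t_to + 1e-12)
        return Trajectory(
            t=self.t[sel], states=self.states[sel], derivs=self.derivs[sel],
            params=self.params, delays=self.delays, history=self.history,
            h=self.h,
        )

    def tail_history(self, horizon: float) -> "SegmentHistory":
        """The trailing ``horizon`` of the solution as a dense history,
        for warm-starting a follow-up integration at t = 0."""
        m = int(np.ceil(horizon / self.h - 1e-9))
        if m + 1 > self.t.size:
            raise ValueError(
                f"trajectory too short for a {horizon}-long history")
        return SegmentHistory(states=self.states[-(m + 1):].copy(),
                              derivs=self.derivs[-(m + 1):].copy(), h=self.h)

    # ---- TSV round-trip -------------------------------------------------
    def to_tsv(self, path: str | Path, stride: int = 1) -> None:
        """Write t, x, y, z columns with '#'-prefixed provenance header."""
        lines = ["# synaptrans trajectory"]
        if self.params is not None:
            lines.append("# params\t" + "\t".join(
                f"{k}={v!r}" for k, v in self.params.to_dict().items()))
        if self.delays is not None:
            lines.append("# delays\t" + "\t".join(
                f"{k}={v!r}" for k, v in self.delays.to_dict().items()))
        if self.history is not None:
            lines.append(f"# history\tx={self.history.x!r}\ty={self.history.y!r}"
                         f"\tz={self.history.z!r}\thorizon={self.history.horizon!r}")
        lines.append(f"# h\t{self.h!r}\tstride\t{stride}")
        lines.append("t\tx\ty\tz")
        buf = io.StringIO()
        buf.write("\n".join(lines) + "\n")
        data = np.column_stack([self.t, self.states])[::stride]
        np.savetxt(buf, data, fmt="%.17g", delimiter="\t")
        Path(path).write_text(buf.getvalue())

    @classmethod
    def from_tsv(cls, path: str | Path) -> "Trajectory":
        import pandas as pd

        df = pd.read_csv(path, sep="\t", comment="#",
                         float_precision="round_trip")
        return cls(t=df["t"].to_numpy(),
                   states=df[["x", "y", "z"]].to_numpy())


def dense_eval(traj: Trajectory, tq):
    """Interpolated state at time(s) ``tq``; exact at grid nodes.

    Uses cubic Hermite interpolation with the stored node derivatives.
    """
    tq_arr = np.atleast_1d(np.asarray(tq, dtype=float))
    t0, t1 = traj.t[0], traj.t[-1]
    if np.any(tq_arr < t0 - 1e-12) or np.any(tq_arr > t1 + 1e-12):
        raise ValueError(f"query time outside recorded range [{t0}, {t1}]")
    h = traj.h
    s = (tq_arr - t0) / h
    j = np.clip(s.astype(int), 0, traj.t.size - 2)
    th = np.clip(s - j, 0.0, 1.0)[:, None]
    x0 = traj.states[j]
    x1 = traj.states[j + 1]
    m0 = h * traj.derivs[j]
    m1 = h * traj.derivs[j + 1]
    t2 = th * th
    t3 = t2 * th
    out = ((2 * t3 - 3 * t2 + 1) * x0 + (t3 - 2 * t2 + th) * m0
           + (-2 * t3 + 3 * t2) * x1 + (t3 - t2) * m1)
    if np.isscalar(tq) or np.ndim(tq) == 0:
        return State(*out[0])
    return out


def integrate_dde(
    p: ModelParameters,
    d: DelayParameters,
    hist: HistoryFunction | None = None,
    s: IntegrationSettings | None = None,
) -> Trajectory:
    """Solve the delayed Cauchy problem; deterministic given its inputs."""
    s = s or IntegrationSettings()
    hist = hist or STANDARD_HISTORY(d.horizon)
    validate_parameters(p, d)
    minpos = d.min_positive
    if minpos > 0 and s.h > minpos + 1e-12:
        raise ParameterDomainError(
            f"step h={s.h} exceeds the smallest positive delay {minpos}; "
            "lag lookups would fall inside the current step"
        )
    Hs, HF, mh = hist._kernel_arrays(s.h)
    if mh * s.h < d.horizon - 1e-9 and mh > 0:
        raise ParameterDomainError(
            f"segment history horizon {mh * s.h} shorter than the largest "
            f"delay {d.horizon}")
    X, F, status, fail = _kernel.integrate_kernel(
        p.to_array(), d.to_array(), Hs, HF, mh, s.h, s.n_steps, s.neg_tol
    )
    if status != _kernel.STATUS_OK:
        raise IntegrationError(
            f"state left the nonnegative orthant at t={fail * s.h:.6g} "
            f"(beyond tolerance {s.neg_tol})"
        )
    t = np.arange(s.n_steps + 1) * s.h
    return Trajectory(t=t, states=X, derivs=F, params=p, delays=d,
                      history=hist, h=s.h)


def integrate_twin(
    p: ModelParameters,
    d: DelayParameters,
    hist: HistoryFunction | None = None,
    s: IntegrationSettings | None = None,
    epsilon: float = 1e-6,
    components: tuple[str, ...] = ("x",),
) -> tuple[Trajectory, Trajectory]:
    """Integrate a pair of Cauchy problems whose histories differ by epsilon.

    The default perturbation (+1e-6 on the x history) is the probe used by
    the sensitivity-to-initial-data chaos criterion.
    """
    if epsilon < 0:
        raise ParameterDomainError(f"epsilon must be >= 0, got {epsilon}")
    hist = hist or STANDARD_HISTORY(d.horizon)
    t1 = integrate_dde(p, d, hist, s)
    t2 = integrate_dde(p, d, hist.perturbed(epsilon, components), s)
    return t1, t2
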