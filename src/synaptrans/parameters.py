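"""Parameter containers for the synaptic local-translation circuit.

The model tracks three pools at an activated glutamatergic synapse:
active membrane receptors (x), active (dephosphorylated) FMRP (y) and
receptors held in the recycling endosome (z).  Rate constants follow the
naming used throughout the model: ``k_*`` are first-order rates (1/min),
``K_*`` half-saturation constants (concentration), ``h_*`` dimensionless
Hill coefficients, ``y0`` the total FMRP capacity and ``tau_*`` delays in
minutes.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator, Mapping

import numpy as np
import yaml

__all__ = [
    "ModelParameters",
    "DelayParameters",
    "ParameterDomainError",
    "ParameterRangeWarning",
    "basic_parameters",
    "basic_delays",
    "load_parameters",
    "save_parameters",
    "validate_parameters",
    "VARIATION_LIMITS",
]


class ParameterDomainError(ValueError):
    """A parameter value violates a hard model invariant."""


class ParameterRangeWarning(UserWarning):
    """A parameter lies outside the physiologically motivated scan range."""


@dataclass(frozen=True)
class ModelParameters:
    """All rate constants of the local-translation circuit.

    Defaults are the basic reference set used for most scans.  The two
    constants of the synthesis Hill term that the reference set leaves
    open default to ``K_x = 1.0`` (the FMRP capacity scale, since
    ``y0 = 1``) and ``k_x0 = 0.0`` (no constitutive, FMRP-independent
    receptor synthesis).
    """

    k_a0: float = 0.0   # constitutive FMRP dephosphorylation, 1/min
    k_a: float = 1.0    # max signal-dependent dephosphorylation, 1/min
    K_a: float = 1.0    # activation half-saturation, concentration
    h_a: float = 1.0    # activation Hill coefficient
    y0: float = 1.0     # total FMRP capacity, concentration
    k_b0: float = 1.0   # constitutive FMRP phosphorylation, 1/min
    k_b: float = 200.0  # max signal-dependent phosphorylation, 1/min
    K_b: float = 3.0    # suppression half-saturation, concentration
    h_b: float = 15.0   # suppression Hill coefficient (mTOR cascade)
    k_x0: float = 0.0   # constitutive receptor synthesis, conc/min
    k_x: float = 40.0   # max FMRP-dependent synthesis/incorporation, conc/min
    K_x: float = 1.0    # synthesis half-saturation, concentration
    h_x: float = 3.0    # synthesis/incorporation Hill coefficient
    k_dx: float = 0.1   # membrane receptor degradation, 1/min
    k_rx: float = 0.9   # endosome inclusion, 1/min
    k_dz: float = 0.8   # endosomal degradation, 1/min
    k_rz: float = 0.2   # recycling efficiency, 1/min

    def replace(self, **changes: float) -> "ModelParameters":
        return dataclasses.replace(self, **changes)

    def with_recycling(self, k_rz: float) -> "ModelParameters":
        """Set ``k_rz`` under the scan convention ``k_dz = 1 - k_rz``."""
        if not 0.0 <= k_rz <= 1.0:
            raise ParameterDomainError(
                f"scan convention requires k_rz in [0, 1], got {k_rz}"
            )
        return self.replace(k_rz=k_rz, k_dz=1.0 - k_rz)

    def to_array(self) -> np.ndarray:
        """Pack into the flat float64 layout used by the integration kernel."""
        return np.array(
            [
                self.k_a0, self.k_a, self.K_a, self.h_a, self.y0,
                self.k_b0, self.k_b, self.K_b, self.h_b,
                self.k_x0, self.k_x, self.K_x, self.h_x,
                self.k_dx, self.k_rx, self.k_dz, self.k_rz,
            ],
            dtype=np.float64,
        )

    def to_dict(self) -> dict[str, float]:
        return dataclasses.asdict(self)


@dataclass(frozen=True)
class DelayParameters:
    """The four transport/processing delays, in minutes.

    tau_a: receptor signal -> FMRP dephosphorylation (translation activation)
    tau_b: receptor signal -> FMRP phosphorylation via mTOR (suppression)
    tau_r: endosomal residence time of an internalised receptor
    tau_e: translation elongation + membrane incorporation of a new receptor
    """

    tau_a: float = 1.0
    tau_b: float = 1.0
    tau_r: float = 10.0
    tau_e: float = 15.0

    def replace(self, **changes: float) -> "DelayParameters":
        return dataclasses.replace(self, **changes)

    @property
    def horizon(self) -> float:
        """The history horizon: the largest delay."""
        return max(self.tau_a, self.tau_b, self.tau_r, self.tau_e)

    @property
    def min_positive(self) -> float:
        pos = [t for t in (self.tau_a, self.tau_b, self.tau_r, self.tau_e) if t > 0]
        return min(pos) if pos else 0.0

    def to_array(self) -> np.ndarray:
        return np.array(
            [self.tau_a, self.tau_b, self.tau_e, self.tau_r], dtype=np.float64
        )

    def to_dict(self) -> dict[str, float]:
        return dataclasses.asdict(self)

    def __iter__(self) -> Iterator[float]:
        yield from (self.tau_a, self.tau_b, self.tau_r, self.tau_e)


# Physiologically motivated variation limits used in the reference scans.
# Values outside these ranges are legal (the tool is a general explorer)
# but trigger a ParameterRangeWarning.
VARIATION_LIMITS: dict[str, tuple[float, float]] = {
    "h_x": (1, 3),
    "h_b": (5, 20),
    "k_x": (10, 40),
    "k_b": (100, 200),
    "K_a": (1, 3),
    "k_rz": (0.0, 1.0),
    "tau_b": (1, 5),
    "tau_e": (3, 20),
    "tau_r": (3, 15),
}


def basic_parameters(**overrides: float) -> ModelParameters:
    """The basic reference parameter set, with optional field overrides."""
    return ModelParameters().replace(**overrides)


def basic_delays(**overrides: float) -> DelayParameters:
    """The basic reference delays, with optional field overrides."""
    return DelayParameters().replace(**overrides)


def validate_parameters(
    p: ModelParameters,
    d: DelayParameters | None = None,
    *,
    scan_convention: bool = False,
) -> tuple[ModelParameters, DelayParameters | None]:
    """Check hard invariants; warn when outside the reference scan ranges.

    Hard invariants (raise ParameterDomainError):
      * every rate and half-saturation nonnegative; K_a, K_b, K_x, y0 > 0
      * Hill coefficients h_a, h_b, h_x >= 1
      * K_a <= K_b (activation at least as efficient as suppression)
      * all delays >= 0
      * under ``scan_convention``: k_rz in [0, 1] and k_dz == 1 - k_rz

    Soft limits (ParameterRangeWarning): the variation ranges in
    :data:`VARIATION_LIMITS`.
    """
    pd = p.to_dict()
    for name in ("k_a0", "k_a", "k_b0", "k_b", "k_x0", "k_x",
                 "k_dx", "k_rx", "k_dz", "k_rz"):
        if pd[name] < 0:
            raise ParameterDomainError(f"{name} must be >= 0, got {pd[name]}")
    for name in ("K_a", "K_b", "K_x", "y0"):
        if pd[name] <= 0:
            raise ParameterDomainError(f"{name} must be > 0, got {pd[name]}")
    for name in ("h_a", "h_b", "h_x"):
        if pd[name] < 1:
            raise ParameterDomainError(
                f"Hill coefficient {name} must be >= 1, got {pd[name]}"
            )
    if p.K_a > p.K_b:
        raise ParameterDomainError(
            f"K_a <= K_b required (activation precedes suppression); "
            f"got K_a={p.K_a}, K_b={p.K_b}"
        )
    if scan_convention:
        if not 0.0 <= p.k_rz <= 1.0:
            raise ParameterDomainError(
                f"scan convention requires k_rz in [0, 1], got {p.k_rz}"
            )
        if abs(p.k_dz - (1.0 - p.k_rz)) > 1e-12:
            raise ParameterDomainError(
                f"scan convention requires k_dz = 1 - k_rz; "
                f"got k_dz={p.k_dz}, k_rz={p.k_rz}"
            )
    if d is not None:
        for name, tau in d.to_dict().items():
            if tau < 0:
                raise ParameterDomainError(f"{name} must be >= 0, got {tau}")

    merged: dict[str, float] = dict(pd)
    if d is not None:
        merged.update(d.to_dict())
    for name, (lo, hi) in VARIATION_LIMITS.items():
        v = merged.get(name)
        if v is not None and not lo <= v <= hi:
            warnings.warn(
                f"{name} = {v} lies outside the reference variation "
                f"range [{lo}, {hi}]",
                ParameterRangeWarning,
                stacklevel=2,
            )
    return p, d


_DELAY_KEYS = ("tau_a", "tau_b", "tau_r", "tau_e")


def load_parameters(source: str | Path | Mapping) -> tuple[ModelParameters, DelayParameters]:
    """Read a flat key-value parameter file (YAML/JSON) or mapping.

    Keys are the model symbols (``k_a0`` ... ``k_rz``, ``tau_a`` ...
    ``tau_e``); missing keys take their basic-set defaults.
    """
    if isinstance(source, Mapping):
        data = dict(source)
    else:
        data = yaml.safe_load(Path(source).read_text())
        if data is None:
            data = {}
        if not isinstance(data, dict):
            raise ParameterDomainError(f"parameter file {source} is not a mapping")
    known = set(ModelParameters.__dataclass_fields__) | set(_DELAY_KEYS)
    unknown = set(data) - known
    if unknown:
        raise ParameterDomainError(f"unknown parameter keys: {sorted(unknown)}")
    delays = DelayParameters(**{k: float(data[k]) for k in _DELAY_KEYS if k in data})
    params = ModelParameters(
        **{k: float(v) for k, v in data.items() if k not in _DELAY_KEYS}
    )
    return params, delays


def save_parameters(
    p: ModelParameters, d: DelayParameters, path: str | Path
) -> None:
    """Write a flat YAML parameter file (round-trips with load_parameters)."""
    data = {**p.to_dict(), **d.to_dict()}
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False))
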