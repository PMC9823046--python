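"""Parameter containers for the bidirectional twin-instrument structural model.

The model relates two phenotypes (Ph1, Ph2) measured on both members of a
twin pair.  Each phenotype loads on its own additive-genetic (A), shared-
environmental (C) and unique-environmental (E) factor, receives a regression
path from its own polygenic score (PS1 for Ph1, PS2 for Ph2), and the two
phenotypes cause each other reciprocally (g1: Ph1 -> Ph2, g2: Ph2 -> Ph1).
Background confounding enters through the factor correlations ra, rc, re and
the instrument correlation rf.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Union

import numpy as np

__all__ = [
    "PARAM_NAMES",
    "ParamVector",
    "Zygosity",
    "MZ",
    "DZ",
    "FreePattern",
]

#: Canonical ordering of the model parameters.  ra/rc/re are the A/C/E
#: cross-trait factor correlations, rf the instrument (polygenic score)
#: correlation; a/c/e are factor loadings; g1/g2 the reciprocal causal paths;
#: b1 (PS1->Ph1) and b3 (PS2->Ph2) the instrument strengths; b2 (PS1->Ph2)
#: and b4 (PS2->Ph1) the direct horizontal-pleiotropy paths, fixed to zero in
#: the identified model; sigma_x/sigma_y the instrument standard deviations.
PARAM_NAMES = (
    "ra", "rc", "re", "rf",
    "a1", "c1", "e1", "a2", "c2", "e2",
    "g1", "g2",
    "b1", "b3", "b2", "b4",
    "sigma_x", "sigma_y",
)


@dataclass(frozen=True)
class Zygosity:
    """Twin-pair zygosity and the additive-genetic sharing it implies.

    MZ co-twins share all segregating genes (``genetic_share`` = 1), DZ
    co-twins share half on average (0.5).  Polygenic scores, being additive
    aggregates of genotype, share with the same coefficient.
    """

    label: str
    genetic_share: float

    def __post_init__(self) -> None:
        if self.genetic_share not in (1.0, 0.5):
            raise ValueError(
                f"genetic_share must be 1.0 (MZ) or 0.5 (DZ), got {self.genetic_share}"
            )


MZ = Zygosity("MZ", 1.0)
DZ = Zygosity("DZ", 0.5)

_CORRELATIONS = ("ra", "rc", "re", "rf")
_LOADINGS = ("a1", "c1", "e1", "a2", "c2", "e2")


@dataclass(frozen=True)
class ParamVector:
    """Full parameter vector theta of the two-instrument reciprocal twin model.

    Defaults give a null model: independent unit-variance phenotypes driven
    entirely by their E factors, unit-variance uncorrelated polygenic scores.
    """

    ra: float = 0.0
    rc: float = 0.0
    re: float = 0.0
    rf: float = 0.0
    a1: float = 0.0
    c1: float = 0.0
    e1: float = 1.0
    a2: float = 0.0
    c2: float = 0.0
    e2: float = 1.0
    g1: float = 0.0
    g2: float = 0.0
    b1: float = 0.0
    b3: float = 0.0
    b2: float = 0.0
    b4: float = 0.0
    sigma_x: float = 1.0
    sigma_y: float = 1.0

    # -- construction helpers ------------------------------------------------

    @classmethod
    def standardized(cls, **kwargs: float) -> "ParamVector":
        """Build a vector with e1, e2 derived as sqrt(1 - a^2 - c^2).

        This is the standardization used throughout the power designs: the
        latent A+C+E part of each phenotype has unit variance before the
        causal and instrument paths are added.
        """
        for side in ("1", "2"):
            if f"e{side}" in kwargs:
                raise TypeError(f"e{side} is derived; do not pass it to standardized()")
            a = kwargs.get(f"a{side}", 0.0)
            c = kwargs.get(f"c{side}", 0.0)
            rest = 1.0 - a * a - c * c
            if rest < -1e-12:
                raise ValueError(
                    f"a{side}^2 + c{side}^2 = {a * a + c * c:.6f} exceeds 1; "
                    "cannot derive a real e loading"
                )
            kwargs[f"e{side}"] = math.sqrt(max(rest, 0.0))
        return cls(**kwargs)

    @classmethod
    def from_dict(cls, values: Mapping[str, float]) -> "ParamVector":
        unknown = set(values) - set(PARAM_NAMES)
        if unknown:
            raise KeyError(f"unknown parameter name(s): {sorted(unknown)}")
        return cls(**{k: float(v) for k, v in values.items()})

    # -- views ---------------------------------------------------------------

    def as_dict(self) -> dict:
        return {name: getattr(self, name) for name in PARAM_NAMES}

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, name) for name in PARAM_NAMES], dtype=float)

    def replace(self, **changes: float) -> "ParamVector":
        return replace(self, **changes)

    # -- admissibility -------------------------------------------------------

    def validate(self) -> "ParamVector":
        """Raise ``ValueError`` on an inadmissible parameter vector."""
        for name in _CORRELATIONS:
            v = getattr(self, name)
            if not -1.0 <= v <= 1.0:
                raise ValueError(f"correlation {name}={v} outside [-1, 1]")
        if self.sigma_x <= 0 or self.sigma_y <= 0:
            raise ValueError("sigma_x and sigma_y must be positive")
        if abs(self.g1 * self.g2) >= 1.0:
            raise ValueError(
                f"|g1*g2| = {abs(self.g1 * self.g2):.4f} >= 1: the reciprocal "
                "causal loop has no reduced form (I - B is singular)"
            )
        return self


_FREE = "free"
_CONSTRAINED = "constrained"

StatusValue = Union[str, float]


@dataclass(frozen=True)
class FreePattern:
    """Free/fixed status for every model parameter, plus an optional
    proportionality constraint ra = m * rf.

    ``status`` maps each parameter name to the literal string ``"free"`` or
    to the numeric value it is fixed at.  When ``ra_rf_ratio`` is set, ra is
    no longer an independent parameter: it is derived as m * rf whenever the
    pattern is materialised.
    """

    status: Mapping[str, StatusValue] = field(default_factory=dict)
    ra_rf_ratio: float | None = None

    def __post_init__(self) -> None:
        unknown = set(self.status) - set(PARAM_NAMES)
        if unknown:
            raise KeyError(f"unknown parameter name(s) in pattern: {sorted(unknown)}")
        missing = set(PARAM_NAMES) - set(self.status)
        if missing:
            raise ValueError(f"pattern must assign a status to every parameter; missing {sorted(missing)}")
        for name, st in self.status.items():
            if isinstance(st, str) and st != _FREE:
                raise ValueError(f"status for {name} must be 'free' or a number, got {st!r}")
        if self.ra_rf_ratio is not None:
            if not math.isfinite(self.ra_rf_ratio):
                raise ValueError("ra_rf_ratio must be finite")
            if self.status["ra"] == _FREE:
                object.__setattr__(
                    self, "status", {**self.status, "ra": _FREE}
                )  # keep mapping type uniform
        # freeze to a plain dict for hashing-ish stability
        object.__setattr__(self, "status", dict(self.status))

    # -- constructors ----------------------------------------------------

    @classmethod
    def full(cls, *, free_pleiotropy: bool = False) -> "FreePattern":
        """The canonical identified pattern: everything free, direct
        pleiotropic paths b2 = b4 = 0 (set ``free_pleiotropy`` to free them).
        """
        status: dict = {name: _FREE for name in PARAM_NAMES}
        if not free_pleiotropy:
            status["b2"] = 0.0
            status["b4"] = 0.0
        return cls(status=status)

    @classmethod
    def ae(cls) -> "FreePattern":
        """AE background: shared-environment paths and correlation fixed at 0."""
        return cls.full().with_fixed(rc=0.0, c1=0.0, c2=0.0)

    def with_fixed(self, **fixed: float) -> "FreePattern":
        status = dict(self.status)
        for name, value in fixed.items():
            if name not in PARAM_NAMES:
                raise KeyError(f"unknown parameter name: {name}")
            status[name] = float(value)
        return FreePattern(status=status, ra_rf_ratio=self.ra_rf_ratio)

    def with_free(self, *names: str) -> "FreePattern":
        status = dict(self.status)
        for name in names:
            if name not in PARAM_NAMES:
                raise KeyError(f"unknown parameter name: {name}")
            status[name] = _FREE
        return FreePattern(status=status, ra_rf_ratio=self.ra_rf_ratio)

    def with_ra_rf_ratio(self, m: float) -> "FreePattern":
        return FreePattern(status=dict(self.status), ra_rf_ratio=float(m))

    # -- queries -----------------------------------------------------------

    @property
    def free_names(self) -> tuple:
        """Independently estimated parameters, in canonical order.

        Under the ra = m*rf constraint ra is derived, hence excluded.
        """
        names = [n for n in PARAM_NAMES if self.status[n] == _FREE]
        if self.ra_rf_ratio is not None and "ra" in names:
            names.remove("ra")
        return tuple(names)

    @property
    def n_free(self) -> int:
        return len(self.free_names)

    def is_free(self, name: str) -> bool:
        return name in self.free_names

    def is_nested_in(self, other: "FreePattern") -> bool:
        """True when every parameter free here is also free in ``other``."""
        return set(self.free_names) <= set(other.free_names)

    # -- materialisation ---------------------------------------------------

    def build(self, free_values: np.ndarray, base: ParamVector | None = None) -> ParamVector:
        """Assemble a :class:`ParamVector` from values of the free parameters.

        Fixed parameters take their fixed value; the ra = m*rf constraint is
        applied last.  ``base`` supplies values for parameters whose status is
        'free' but that are not being varied (not applicable here: the length
        of ``free_values`` must equal ``n_free``).
        """
        free_values = np.asarray(free_values, dtype=float)
        if free_values.shape != (self.n_free,):
            raise ValueError(f"expected {self.n_free} free values, got {free_values.shape}")
        values = {} if base is None else base.as_dict()
        for name, st in self.status.items():
            if st != _FREE:
                values[name] = float(st)
        for name, v in zip(self.free_names, free_values):
            values[name] = float(v)
        if self.ra_rf_ratio is not None:
            values["ra"] = self.ra_rf_ratio * values["rf"]
        return ParamVector(**values)

    def extract(self, theta: ParamVector) -> np.ndarray:
        """Free-parameter values of ``theta``, in ``free_names`` order."""
        return np.array([getattr(theta, n) for n in self.free_names], dtype=float)

    def project(self, theta: ParamVector) -> ParamVector:
        """Force ``theta`` to satisfy this pattern's fixed values and constraint."""
        return self.build(self.extract(theta))
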