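"""Kinetic parameters of the MSC mechanotransduction network.

The model has 41 indexed kinetic constants — nine maximal production rates
``k1..k9``, sixteen Hill half-saturation constants ``K1..K16`` and sixteen
Hill exponents ``n1..n16`` — plus six degradation rates ``d1..d6`` (all 1 in
the reference parameterization, which fixes the relative time unit).  The
integer index of each constant (1–41) is the canonical ordering used by the
robustness analysis: indices 1–9 are ``k1..k9`` and indices 10–41 alternate
``K_i, n_i`` for i = 1..16.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator, Union

import numpy as np
import yaml

__all__ = [
    "ParameterSet",
    "CooperativeParameters",
    "PARAM_NAMES",
    "GENES",
]

#: Lineage marker genes in state-vector order.
GENES = ("TUBB3", "PPARG", "MYOD1", "RUNX2")

_DEFAULT_K = (0.2, 2.2, 5.0, 9.0, 4.0, 2.9, 3.0, 5.0, 2.0)
_DEFAULT_KK = (600.0, 1.1, 1300.0, 0.8, 20000.0, 1.0, 60000.0, 1.1,
               0.1, 0.5, 0.89, 4.0, 12.0, 3.0, 16.0, 4.5)
_DEFAULT_N = (4.0, 2.0, 6.0, 2.0, 4.0, 20.0, 6.0, 20.0,
              2.0, 8.0, 2.0, 8.0, 20.0, 60.0, 45.0, 55.0)

#: Symbol for each canonical index 1..41.
PARAM_NAMES: tuple[str, ...] = tuple(
    [f"k{i}" for i in range(1, 10)]
    + [s for i in range(1, 17) for s in (f"K{i}", f"n{i}")]
)


def _positive(name: str, value: float) -> None:
    if not math.isfinite(value) or value <= 0:
        raise ValueError(f"parameter {name} must be finite and > 0, got {value!r}")


@dataclass(frozen=True)
class ParameterSet:
    """The 41 indexed kinetic constants plus degradation rates.

    Parameters are stored as three tuples (``k``, ``K``, ``n``) in symbol
    order; scalar access is through attributes ``k1``..``k9``, ``K1``..``K16``,
    ``n1``..``n16`` and ``d1``..``d6``.
    """

    k: tuple[float, ...] = _DEFAULT_K
    K: tuple[float, ...] = _DEFAULT_KK
    n: tuple[float, ...] = _DEFAULT_N
    d: tuple[float, ...] = (1.0,) * 6

    def __post_init__(self) -> None:
        if len(self.k) != 9 or len(self.K) != 16 or len(self.n) != 16 or len(self.d) != 6:
            raise ValueError("ParameterSet needs 9 k, 16 K, 16 n and 6 d values")
        for grp, vals in (("k", self.k), ("K", self.K), ("d", self.d)):
            for i, v in enumerate(vals, 1):
                _positive(f"{grp}{i}", float(v))
        for i, v in enumerate(self.n, 1):
            if not math.isfinite(v) or v < 1:
                raise ValueError(f"Hill exponent n{i} must be >= 1, got {v!r}")
        object.__setattr__(self, "k", tuple(float(v) for v in self.k))
        object.__setattr__(self, "K", tuple(float(v) for v in self.K))
        object.__setattr__(self, "n", tuple(float(v) for v in self.n))
        object.__setattr__(self, "d", tuple(float(v) for v in self.d))

    def __getattr__(self, name: str):
        # k1..k9 / K1..K16 / n1..n16 / d1..d6 scalar access
        if len(name) >= 2 and name[0] in "kKnd" and name[1:].isdigit():
            idx = int(name[1:]) - 1
            group = {"k": self.k, "K": self.K, "n": self.n, "d": self.d}[name[0]]
            if 0 <= idx < len(group):
                return group[idx]
        raise AttributeError(name)

    # -- canonical 41-vector ----------------------------------------------
    def indexed_values(self) -> np.ndarray:
        """The 41 constants as a vector in canonical index order (1..41)."""
        out = list(self.k)
        for Kv, nv in zip(self.K, self.n):
            out.extend((Kv, nv))
        return np.array(out, dtype=float)

    @classmethod
    def from_indexed(cls, values: np.ndarray,
                     d: tuple[float, ...] = (1.0,) * 6) -> "ParameterSet":
        """Build from a canonical 41-vector (inverse of :meth:`indexed_values`)."""
        values = np.asarray(values, dtype=float)
        if values.shape != (41,):
            raise ValueError(f"expected 41 values, got shape {values.shape}")
        k = tuple(values[:9])
        K = tuple(values[9::2])
        n = tuple(values[10::2])
        return cls(k=k, K=K, n=n, d=d)

    def with_indexed(self, index: int, value: float) -> "ParameterSet":
        """A copy with the parameter at canonical ``index`` (1-based) replaced."""
        if not 1 <= index <= 41:
            raise ValueError(f"parameter index must be in 1..41, got {index}")
        vec = self.indexed_values()
        vec[index - 1] = value
        return ParameterSet.from_indexed(vec, d=self.d)

    @staticmethod
    def index_name(index: int) -> str:
        """Symbol of the parameter at canonical ``index`` (1-based)."""
        return PARAM_NAMES[index - 1]

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict[str, float]:
        out = {f"k{i}": v for i, v in enumerate(self.k, 1)}
        out.update({f"K{i}": v for i, v in enumerate(self.K, 1)})
        out.update({f"n{i}": v for i, v in enumerate(self.n, 1)})
        out.update({f"d{i}": v for i, v in enumerate(self.d, 1)})
        return out

    @classmethod
    def from_dict(cls, data: dict[str, float]) -> "ParameterSet":
        base = cls().to_dict()
        unknown = set(data) - set(base)
        if unknown:
            raise ValueError(f"unknown parameter keys: {sorted(unknown)}")
        base.update({k: float(v) for k, v in data.items()})
        return cls(
            k=tuple(base[f"k{i}"] for i in range(1, 10)),
            K=tuple(base[f"K{i}"] for i in range(1, 17)),
            n=tuple(base[f"n{i}"] for i in range(1, 17)),
            d=tuple(base[f"d{i}"] for i in range(1, 7)),
        )

    def write_yaml(self, path: Union[str, Path]) -> None:
        """Write the parameter file (flat key-value YAML, symbol-keyed)."""
        lines = [f"{name}: {value:.17g}" for name, value in self.to_dict().items()]
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def read_yaml(cls, path: Union[str, Path]) -> "ParameterSet":
        data = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(data, dict):
            raise ValueError(f"parameter file {path} must be a flat mapping")
        return cls.from_dict(data)


@dataclass(frozen=True)
class CooperativeParameters:
    """Parameters of the cooperative (AND-gate) adhesion-area equation.

    The cooperative variant replaces the four independent OR-gates of the
    adhesion-area equation by a single shared Hill gate in which the
    stiffness term and all four gene feedback terms add inside one fraction.
    Its symbols ``K1..K5``/``n1..n5`` shadow (and are distinct from) the
    identically named constants of the non-cooperative table; defaults for
    the gene terms reuse the corresponding non-cooperative feedback
    constants, and ``K1`` (the stiffness half-saturation) is the free knob
    of the degeneracy analysis.
    """

    k1: float = 0.2
    d1: float = 1.0
    K1: float = 600.0
    n1: float = 4.0
    # gene feedback constants, order TUBB3, PPARG, MYOD1, RUNX2
    K_gene: tuple[float, ...] = (1.1, 0.8, 1.0, 1.1)
    n_gene: tuple[float, ...] = (2.0, 2.0, 20.0, 20.0)

    def __post_init__(self) -> None:
        for name in ("k1", "d1", "K1", "n1"):
            _positive(name, getattr(self, name))
        if len(self.K_gene) != 4 or len(self.n_gene) != 4:
            raise ValueError("K_gene and n_gene need one entry per lineage gene")
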