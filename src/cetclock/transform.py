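"""Log-like transforms of chronological age and their inverses.

Clocks regress transformed age on methylation and report predictions in
years after inverting the transform. Two families are provided:

``log1p``
    ``f(x) = log(x + offset)`` with ``offset = 1`` year by default, so
    ``f(0) = 0``. Compresses the adult age range, where sampling of
    long-lived species is sparse and age estimates are least certain.

``loglinear``
    Horvath-style: logarithmic below an adult-age knot ``k`` and affine
    above it, matched to be continuously differentiable at the knot:

    ``f(x) = log(x + offset) - log(k + offset)``            for x < k
    ``f(x) = (x - k) / (k + offset)``                       for x >= k

    Both pieces vanish at the knot and share slope ``1/(k + offset)``
    there. The knot is typically a species' age at sexual maturity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

_FAMILIES = ("log1p", "loglinear")


@dataclass(frozen=True)
class TransformSpec:
    """Specification of an invertible, strictly increasing age transform."""

    name: str = "log1p"
    parameters: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.name not in _FAMILIES:
            raise ValueError(f"unknown transform {self.name!r}; expected one of {_FAMILIES}")
        offset = float(self.parameters.get("offset", 1.0))
        if offset <= 0:
            raise ValueError("transform offset must be > 0")
        if self.name == "loglinear":
            knot = float(self.parameters.get("knot", 0.0))
            if knot <= 0:
                raise ValueError("loglinear transform requires a knot > 0 (years)")

    @property
    def offset(self) -> float:
        return float(self.parameters.get("offset", 1.0))

    @property
    def knot(self) -> float:
        return float(self.parameters.get("knot", 0.0))

    def to_dict(self) -> dict:
        return {"name": self.name, "parameters": dict(self.parameters)}

    @classmethod
    def from_dict(cls, d: dict) -> "TransformSpec":
        return cls(name=d["name"], parameters=dict(d.get("parameters", {})))


def transform_age(age, spec: TransformSpec = TransformSpec()):
    """Map chronological age (years, >= 0) to the transformed-age scale."""
    a = np.asarray(age, dtype=float)
    if np.any(a < 0):
        raise ValueError("age must be non-negative")
    if spec.name == "log1p":
        out = np.log(a + spec.offset) - np.log(spec.offset)
    else:
        k, off = spec.knot, spec.offset
        out = np.where(
            a < k,
            np.log(a + off) - np.log(k + off),
            (a - k) / (k + off),
        )
    return out if out.ndim else float(out)


def inverse_transform(t, spec: TransformSpec = TransformSpec()):
    """Map a transformed-age value back to years; total on the real line.

    A clock may legitimately predict slightly negative years for the
    log1p family (t < 0); values are reported as-is, not floored.
    """
    x = np.asarray(t, dtype=float)
    if spec.name == "log1p":
        out = np.exp(x + np.log(spec.offset)) - spec.offset
    else:
        k, off = spec.knot, spec.offset
        out = np.where(
            x < 0,
            np.exp(x + np.log(k + off)) - off,
            x * (k + off) + k,
        )
    return out if out.ndim else float(out)
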