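"""Shared primitive types and exceptions.

Layout boxes are stored top-left anchored throughout the package.  KGML
stores center-anchored boxes; the conversion happens once, at parse time
(see :func:`pathmodels.kgml.parse_kgml`).
"""

from __future__ import annotations

from dataclasses import dataclass


class PathModelsError(Exception):
    """Base class for all errors raised by this package."""


class KgmlParseError(PathModelsError):
    """Malformed XML or non-KGML content."""


class KgmlValidationError(PathModelsError):
    """Well-formed XML that violates the KGML dialect (unknown entry type,
    unknown relation subtype, dangling references)."""


class StructuralError(PathModelsError):
    """A model document violates a structural invariant (dangling species
    reference, duplicate id)."""


class UnitDerivationError(PathModelsError):
    """A rate expression cannot be reduced to substance/time."""


class LayoutError(PathModelsError):
    """The overlap-removal pass did not converge."""


@dataclass(frozen=True)
class LayoutBox:
    """Axis-aligned box, anchored at its top-left corner."""

    x: float
    y: float
    width: float
    height: float

    def __post_init__(self) -> None:
        if self.width <= 0 or self.height <= 0:
            raise ValueError(f"box dimensions must be positive: {self}")

    @property
    def cx(self) -> float:
        return self.x + self.width / 2.0

    @property
    def cy(self) -> float:
        return self.y + self.height / 2.0

    @property
    def x2(self) -> float:
        return self.x + self.width

    @property
    def y2(self) -> float:
        return self.y + self.height

    @classmethod
    def from_center(cls, cx: float, cy: float, width: float, height: float) -> "LayoutBox":
        return cls(cx - width / 2.0, cy - height / 2.0, width, height)

    def moved_to(self, x: float, y: float) -> "LayoutBox":
        return LayoutBox(x, y, self.width, self.height)

    def overlaps(self, other: "LayoutBox", margin: float = 0.0) -> bool:
        return (
            self.x < other.x2 + margin
            and other.x < self.x2 + margin
            and self.y < other.y2 + margin
            and other.y < self.y2 + margin
        )
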