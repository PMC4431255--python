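"""Morphological cleanup sequences in the compact "HF + 4E + 4D" notation.

Segmented grape masks carry speckle noise (isolated false positives) and
small holes (specular highlights on berry skin).  Short sequences of
erosions (E), dilations (D) and hole filling (HF) remove both; because grape
clusters are large, equal numbers of erosions and dilations have a neutral
compensating effect on the cluster itself while wiping out structures
thinner than the erosion depth.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

__all__ = ["MorphParseError", "MorphSequence", "parse_sequence", "apply_sequence"]

#: 3×3 square structuring element (8-connected foreground).
SQUARE_3X3 = np.ones((3, 3), dtype=bool)

_TOKEN_RE = re.compile(r"^(\d*)(HF|E|D)$")


class MorphParseError(ValueError):
    """Raised for malformed sequence notation; carries the token position."""


@dataclass
class MorphSequence:
    """Ordered list of (op, count) steps; an empty list is the identity."""

    steps: list[tuple[str, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        for op, count in self.steps:
            if op not in ("E", "D", "HF"):
                raise ValueError(f"unknown morphological op {op!r}")
            if count < 1:
                raise ValueError("step counts must be positive")

    def expanded(self) -> list[str]:
        """Unit-step expansion, e.g. HF + 2E -> ['HF', 'E', 'E']."""
        out: list[str] = []
        for op, count in self.steps:
            out.extend([op] * count)
        return out

    def to_string(self) -> str:
        parts = []
        for op, count in self.steps:
            if op == "HF":
                parts.extend(["HF"] * count)
            else:
                parts.append(f"{count}{op}" if count > 1 else op)
        return " + ".join(parts)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.to_string()


def parse_sequence(text: str) -> MorphSequence:
    """Parse notation like ``"HF + 4E + 4D"`` into an ordered sequence.

    Tokens are ``[count]op`` joined by ``+`` with arbitrary whitespace; an
    empty string is the identity sequence.  ``"4E"`` means four unit
    erosions; order is preserved exactly as written.
    """
    text = text.strip()
    if not text:
        return MorphSequence([])
    steps: list[tuple[str, int]] = []
    for pos, raw in enumerate(text.split("+")):
        token = raw.strip()
        m = _TOKEN_RE.match(token)
        if not m:
            raise MorphParseError(
                f"unrecognized token {token!r} at position {pos} in {text!r}"
            )
        count_str, op = m.groups()
        count = int(count_str) if count_str else 1
        if count < 1:
            raise MorphParseError(
                f"zero count in token {token!r} at position {pos}"
            )
        steps.append((op, count))
    return MorphSequence(steps)


def _fill_holes(mask: np.ndarray) -> np.ndarray:
    # Hole = background component with no 4-connected path to the border,
    # the complement convention for 8-connected foreground.
    return ndimage.binary_fill_holes(mask)


def apply_sequence(mask: np.ndarray, seq: MorphSequence) -> np.ndarray:
    """Apply the steps left to right and return a new boolean mask.

    Erosion and dilation use the 3×3 square structuring element with pixels
    outside the image treated as background.
    """
    out = np.asarray(mask, dtype=bool)
    for op, count in seq.steps:
        if op == "E":
            out = ndimage.binary_erosion(
                out, structure=SQUARE_3X3, iterations=count, border_value=0
            )
        elif op == "D":
            out = ndimage.binary_dilation(
                out, structure=SQUARE_3X3, iterations=count, border_value=0
            )
        else:  # HF
            for _ in range(count):
                out = _fill_holes(out)
    return out
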