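"""Shared per-pixel tissue classes and per-cell staining tiers.

The pixel class set covers a DAB/hematoxylin immunohistochemistry scene:
chromogen-positive cytoplasm, counterstained nuclei, unstained background,
plus an explicit UNCLASSIFIED code for pixels no classifier would commit to.
Integer codes are stable and used verbatim in label images written to disk.
"""

from __future__ import annotations

from enum import IntEnum


class TissueClass(IntEnum):
    BACKGROUND = 0
    DKK3_POSITIVE = 1
    NUCLEI = 2
    UNCLASSIFIED = 3


#: Deterministic tie-break priority used by every pixel classifier:
#: on exactly equal scores the earlier class in this list wins.
CLASS_PRIORITY: tuple[TissueClass, ...] = (
    TissueClass.DKK3_POSITIVE,
    TissueClass.NUCLEI,
    TissueClass.BACKGROUND,
)


class Tier(IntEnum):
    """Per-cell DAB staining intensity tier; integer values are the H-score weights."""

    NEGATIVE = 0
    WEAK = 1
    MODERATE = 2
    STRONG = 3
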