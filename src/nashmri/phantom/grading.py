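"""Ordinal NASH-component grades computed from quantitative readouts.

Grade ranges quoted as ``5–33%`` are resolved as left-closed, right-open
bins ([5, 33) → grade 1), so every value maps to exactly one grade and the
mapping is monotone non-decreasing.
"""

from __future__ import annotations

__all__ = ["grade_steatosis", "grade_inflammation"]


def grade_steatosis(lv_pct: float) -> int:
    """Steatosis grade from lipid vacuolization percentage.

    0: <5 %, 1: [5, 33) %, 2: [33, 66) %, 3: ≥66 %.
    """
    if not 0.0 <= lv_pct <= 100.0:
        raise ValueError("lv_pct must be in [0, 100]")
    if lv_pct < 5.0:
        return 0
    if lv_pct < 33.0:
        return 1
    if lv_pct < 66.0:
        return 2
    return 3


def grade_inflammation(foci_per_field: float) -> int:
    """Inflammation grade from inflammatory foci per 20× field.

    0: no foci, 1: <2 foci, 2: 2–4 foci, 3: >4 foci.
    """
    if foci_per_field < 0:
        raise ValueError("foci count must be non-negative")
    if foci_per_field == 0:
        return 0
    if foci_per_field < 2:
        return 1
    if foci_per_field <= 4:
        return 2
    return 3
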