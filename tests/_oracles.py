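"""Independent brute-force oracles used by the taxonomy tests.

These evaluate the classification's defining feature columns directly and
match them against per-type signatures, independently of the package's
decision cascade.
"""

from __future__ import annotations

from decadd.taxonomy import AdditionType


def single_type_by_features(augend: int, addend: int) -> AdditionType:
    """Feature-table lookup for the single-addend types.

    Signature per type: (u == 0?, u + a versus 10).
    """
    u = augend % 10
    s = u + addend
    signature = (u == 0, "<" if s < 10 else ("=" if s == 10 else ">"))
    table = {
        (True, "<"): AdditionType.POST,  # round augend; u + a < 10 always
        (False, "<"): AdditionType.SUB,
        (False, "="): AdditionType.COMP,
        (False, ">"): AdditionType.SUPER,
    }
    return table[signature]


def _rel(x: int, target: int = 10) -> str:
    return "<" if x < target else ("=" if x == target else ">")


def dual_type_by_features(u: int, a1: int, a2: int) -> str:
    """Feature-table lookup for the dual-addend types; returns a label.

    Evaluates the four feature columns (u+a1, u+a2, a1+a2, u+a1+a2) and
    matches them against each type's feature row; type-6 subtypes are read
    off which of the three pairwise sums equal 10.
    """
    f1, f2, f3 = u + a1, u + a2, a1 + a2
    f4 = u + f3
    if u == 0:
        return {"<": "1", "=": "2", ">": "3"}[_rel(f3)]
    tens = (f1 == 10, f2 == 10, f3 == 10)
    if any(tens):
        c1, c2, pair = tens
        if c1 and pair and a1 != a2:
            return "6d"
        if c2 and pair and a1 != a2:
            return "6e"
        if c1:
            return "6a"
        if c2:
            return "6b"
        return "6c"
    if f4 < 10:
        return "4"
    if f4 == 10:
        return "5"
    if f4 < 20:
        return "7"
    if f4 == 20:
        return "8"
    return "9"


def dual_feature_row(u: int, a1: int, a2: int) -> tuple[str, str, str, str]:
    """The four feature-column relations (versus 10, total versus 10/20)."""
    f1, f2, f3 = u + a1, u + a2, a1 + a2
    f4 = u + f3
    return (_rel(f1), _rel(f2), _rel(f3), _rel(f4))
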