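"""Small shared helpers: reporting-grade percentages and tokenization."""

from __future__ import annotations

import re
from decimal import ROUND_HALF_UP, Decimal

_TOKEN_RE = re.compile(r"#?[A-Za-z0-9][A-Za-z0-9'\-]*|#")


def pct(numerator: float, denominator: float) -> float:
    """Percentage at one decimal place, round-half-up.

    All printed percentages in reports go through this single choke point so
    the rounding convention is uniform.  Returns ``nan`` for a zero
    denominator.
    """
    if denominator == 0:
        return float("nan")
    raw = Decimal(str(100.0 * numerator / denominator))
    return float(raw.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def tokenize(text: str) -> list[tuple[str, int, int]]:
    """Tokens with character offsets: ``(surface, start, end)``."""
    return [(m.group(0), m.start(), m.end()) for m in _TOKEN_RE.finditer(text)]


def token_tuple(text: str) -> tuple[str, ...]:
    """Lowercased token sequence of a phrase, for sequence matching."""
    return tuple(t.lower() for t, _, _ in tokenize(text))


def levenshtein(a: str, b: str, max_dist: int | None = None) -> int:
    """Edit distance; inputs here are short normalized address keys.

    With ``max_dist`` the computation runs in a diagonal band and returns
    ``max_dist + 1`` as soon as the true distance provably exceeds the bound.
    """
    if a == b:
        return 0
    if not a:
        return len(b)
    if not b:
        return len(a)
    if max_dist is None:
        max_dist = len(a) + len(b)
    if abs(len(a) - len(b)) > max_dist:
        return max_dist + 1
    big = max_dist + 1
    prev = [j if j <= max_dist else big for j in range(len(b) + 1)]
    for i, ca in enumerate(a, start=1):
        lo = max(1, i - max_dist)
        hi = min(len(b), i + max_dist)
        cur = [big] * (len(b) + 1)
        cur[0] = i if i <= max_dist else big
        best = cur[0] if lo > 1 else big
        for j in range(lo, hi + 1):
            cb = b[j - 1]
            cur[j] = min(prev[j] + 1, cur[j - 1] + 1, prev[j - 1] + (ca != cb))
            if cur[j] < best:
                best = cur[j]
        if best > max_dist:
            return big
        prev = cur
    return prev[-1] if prev[-1] <= max_dist else big


def edit_similarity(a: str, b: str, floor: float = 0.0) -> float:
    """Normalized edit similarity in [0, 1]: 1 - distance / max length.

    ``floor`` lets callers bound the computation: any similarity below it is
    reported as 0.0 without finishing the full dynamic program.
    """
    if not a and not b:
        return 1.0
    longest = max(len(a), len(b))
    max_dist = longest if floor <= 0.0 else int((1.0 - floor) * longest)
    dist = levenshtein(a, b, max_dist)
    if dist > max_dist:
        return 0.0
    return 1.0 - dist / longest
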