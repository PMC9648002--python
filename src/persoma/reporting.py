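"""Category accounting and percentage/reduction arithmetic for the
comparison reports, rendered the way the analysis figures print them."""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping


def _render(value: float, decimals: int) -> str:
    """Round-half-up rendering at a fixed number of decimals."""
    q = Decimal(1).scaleb(-decimals)
    return str(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ClassificationReport:
    counts: dict[str, int]
    total: int
    raw_percentages: dict[str, float]
    rendered_percentages: dict[str, str]

    def line(self, category: str) -> str:
        return (f"{self.counts[category]} "
                f"({self.rendered_percentages[category]}%) {category}")


def classification_report(counts: Mapping[str, int],
                          decimals: int = 2) -> ClassificationReport:
    """Counts and percentages over a partition.

    Raw percentages (100 x count / total) sum to exactly 100; rendered
    values use round-half-up at ``decimals`` places.
    """
    if any(c < 0 for c in counts.values()):
        raise ValueError("counts must be non-negative")
    total = sum(counts.values())
    if total <= 0:
        raise ValueError("total must be positive")
    raw = {k: 100.0 * v / total for k, v in counts.items()}
    rendered = {k: _render(v, decimals) for k, v in raw.items()}
    return ClassificationReport(counts=dict(counts), total=total,
                                raw_percentages=raw,
                                rendered_percentages=rendered)


def reduction_report(count_before: int, count_after: int) -> float:
    """Percent reduction 100 x (before - after) / before (render at one
    decimal with :func:`render_percent`)."""
    if count_before <= 0:
        raise ValueError("count_before must be positive")
    return 100.0 * (count_before - count_after) / count_before


def validation_rate(confirmed: int, tested: int) -> float:
    """Percent of tested sites confirmed (e.g., by Sanger sequencing)."""
    if tested <= 0:
        raise ValueError("tested must be positive")
    if not 0 <= confirmed <= tested:
        raise ValueError("confirmed must lie in [0, tested]")
    return 100.0 * confirmed / tested


def render_percent(value: float, decimals: int = 1) -> str:
    return _render(value, decimals)
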