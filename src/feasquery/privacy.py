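"""Count obfuscation: the only number that leaves a site is a rounded one.

A feasibility result is a single integer per site, but exact integers can
still be probed (issue a query, add one criterion, diff the counts) to
reconstruct individual patients.  Each site therefore rounds its exact
count to the nearest multiple of ten before reporting; a true zero is
reported as zero.  Ties (counts ending in 5) round up.  Counts 1–4 round
to 0 — a small-count disclosure trade-off accepted here, since the zero
rule applies only to true zero.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["ObfuscatedCount", "obfuscate"]


@dataclass(frozen=True)
class ObfuscatedCount:
    """A patient count rounded to a multiple of 10; safe to leave the site."""

    value: int

    def __post_init__(self) -> None:
        if self.value < 0 or self.value % 10 != 0:
            raise ValueError(f"obfuscated count must be a non-negative multiple of 10, got {self.value}")

    def __int__(self) -> int:
        return self.value


def obfuscate(n: int) -> ObfuscatedCount:
    """Round ``n`` to the nearest multiple of 10 (ties up); 0 stays 0.

    The result never deviates from ``n`` by more than 5 and the mapping is
    monotone, so aggregated totals remain meaningful.
    """
    if n < 0:
        raise ValueError(f"patient count cannot be negative: {n}")
    return ObfuscatedCount(((n + 5) // 10) * 10)
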