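"""Small reporting helpers shared by the CLI and the acceptance script."""

from __future__ import annotations


def rounded_percentage(count: int | float, total: int | float, ndigits: int = 0) -> float:
    """100 * count / total, rounded to ``ndigits`` decimal places.

    Uses half-away-from-zero rounding, the convention of hand-reported
    percentages (``round`` in Python banks ties to even, which is not what
    a reported "14%" means).
    """
    if total <= 0:
        raise ValueError("total must be positive")
    value = 100.0 * count / total
    scale = 10.0**ndigits
    import math

    scaled = value * scale
    rounded = math.floor(scaled + 0.5) if scaled >= 0 else math.ceil(scaled - 0.5)
    return rounded / scale


def composition_table(labels) -> dict:
    """Cluster label -> cell count, plus the total (conservation check)."""
    import numpy as np

    labels = np.asarray(labels)
    unique, counts = np.unique(labels, return_counts=True)
    table = {str(u): int(c) for u, c in zip(unique, counts)}
    table["_total"] = int(counts.sum())
    return table
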