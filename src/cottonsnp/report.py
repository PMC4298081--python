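"""Small report arithmetic shared by the run summary and its consumers."""

from __future__ import annotations


def percent(part: float, whole: float, ndigits: int = 1) -> float | None:
    """Percentage of ``part`` in ``whole`` rounded to ``ndigits`` (None if empty)."""
    if not whole:
        return None
    return round(100.0 * part / whole, ndigits)


def rate(successes: int, tested: int, ndigits: int = 1) -> float | None:
    """Assay validation rate as a percentage (e.g. scoreable KASP markers)."""
    return percent(successes, tested, ndigits)
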