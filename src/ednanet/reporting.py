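"""Small report-arithmetic helpers shared by outputs and summaries."""

from __future__ import annotations

__all__ = ["truncated_percent"]


def truncated_percent(part: float, whole: float) -> int:
    """Integer percentage of ``part`` in ``whole``, truncated toward zero.

    This is the convention used when quoting shares such as "the hub
    connects to 48 of 114 taxa (42%)".
    """
    if whole <= 0:
        raise ValueError("whole must be positive")
    return int(100.0 * part / whole)
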