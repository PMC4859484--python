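"""Significant-figure rounding and display formatting helpers.

Published epidemiological tables print proportions at two significant
figures; the estimators here keep full precision and delegate all display
rounding to this module so the two concerns never mix.
"""

from __future__ import annotations

import math

__all__ = ["round_sig", "fmt_sig", "fmt_pct"]


def round_sig(x: float, sig_figs: int = 2) -> float:
    """Round ``x`` to ``sig_figs`` significant figures (0 stays 0)."""
    if sig_figs < 1:
        raise ValueError("sig_figs must be >= 1")
    if x == 0 or not math.isfinite(x):
        return x
    ndigits = sig_figs - 1 - math.floor(math.log10(abs(x)))
    return round(x, ndigits)


def fmt_sig(x: float, sig_figs: int = 2) -> str:
    """Format ``x`` at ``sig_figs`` significant figures in plain decimal."""
    if x == 0:
        return "0"
    s = f"{x:.{sig_figs}g}"
    if "e" in s or "E" in s:  # avoid scientific notation for small proportions
        s = f"{round_sig(x, sig_figs):.{max(0, sig_figs - 1 - math.floor(math.log10(abs(x))))}f}"
    return s


def fmt_pct(fraction: float, sig_figs: int = 2) -> str:
    """Format a proportion in [0, 1] as a percentage at ``sig_figs`` figures."""
    return fmt_sig(fraction * 100.0, sig_figs)
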