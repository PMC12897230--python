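"""Worked-example tables for the diagnostic statistics.

These are the published aggregate counts of a paired evaluation in which the
same frozen three-class AMD classifier (DryAMD / WetAMD / NonAMD, 857 scans)
was run once on raw speckled OCT volumes ("noisy") and once on the
corresponding restored volumes ("denoised").  Only small integer tables are
stored: the per-class one-vs-rest confusion counts of each condition and the
paired 2x2 correctness table comparing the two conditions case by case.
Every summary statistic in the README's worked example is recomputed from
these integers at run time.
"""

from __future__ import annotations

from .diagnostics import McNemarInput, OneVsRestCounts

__all__ = ["example_ovr_counts", "example_paired_table", "EXAMPLE_CLASSES"]

EXAMPLE_CLASSES = ("DryAMD", "WetAMD", "NonAMD")

# class -> (tp, fn, fp, tn), N = 857 for every class
_OVR = {
    "noisy": {
        "DryAMD": (42, 12, 208, 595),
        "WetAMD": (13, 48, 30, 766),
        "NonAMD": (537, 205, 27, 88),
    },
    "denoised": {
        "DryAMD": (54, 0, 1, 802),
        "WetAMD": (60, 1, 0, 796),
        "NonAMD": (742, 0, 0, 115),
    },
}

# a = correct under both conditions, b = improved by denoising,
# c = degraded by denoising, d = wrong under both
_PAIRED = {"a": 592, "b": 264, "c": 0, "d": 1}


def example_ovr_counts(condition: str) -> OneVsRestCounts:
    """One-vs-rest confusion counts for ``condition`` in {"noisy", "denoised"}."""
    try:
        table = _OVR[condition]
    except KeyError:
        raise ValueError(f"condition must be 'noisy' or 'denoised', got {condition!r}") from None
    return OneVsRestCounts(
        classes=EXAMPLE_CLASSES,
        tp=tuple(table[c][0] for c in EXAMPLE_CLASSES),
        fn=tuple(table[c][1] for c in EXAMPLE_CLASSES),
        fp=tuple(table[c][2] for c in EXAMPLE_CLASSES),
        tn=tuple(table[c][3] for c in EXAMPLE_CLASSES),
    )


def example_paired_table() -> McNemarInput:
    """Paired noisy-vs-denoised correctness table (N = 857)."""
    return McNemarInput(**_PAIRED)
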