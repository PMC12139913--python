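"""Normalized exon-coverage profiles.

The profile superimposes all exons of a transcript group onto a single axis
from the first exon start to the last exon end. Coverage at a base is the
fraction of group transcripts whose exons contain it: bases exonic in every
transcript sit at 1.0, bases private to a subset sit below 1.0, and bases
intronic everywhere sit at 0. Because transcript models are interval sets,
the profile is piecewise constant; peaks and valleys are found as plateaus
(maximal runs of equal coverage) that are local maxima or minima.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .models import TranscriptModel


@dataclass
class CoverageProfile:
    """Coverage over a group span.

    ``origin`` is the 1-based genomic coordinate of offset 0; ``coverage`` is
    indexed by 0-based offsets over the closed span. ``peaks`` holds
    ``(representative_offset, height, start_offset, end_offset)`` per local
    maximum plateau (the representative is the plateau midpoint, left-biased
    for even lengths); ``valleys`` holds inclusive offset intervals of local
    minimum plateaus — the expanded intron spans between flanking exons.
    """

    origin: int
    coverage: np.ndarray
    n_transcripts: int
    peaks: list[tuple[int, float, int, int]]
    valleys: list[tuple[int, int]]

    def pos(self, offset: int) -> int:
        """Genomic coordinate of an offset."""
        return self.origin + offset

    def offset(self, pos: int) -> int:
        return pos - self.origin

    def in_valley(self, offset: int) -> bool:
        return any(s <= offset <= e for s, e in self.valleys)

    def valley_mean(self, valley: tuple[int, int]) -> float:
        s, e = valley
        return float(self.coverage[s : e + 1].mean())


def _plateaus(cov: np.ndarray) -> list[tuple[int, int, float]]:
    """Maximal runs of equal coverage as (start, end, value), inclusive."""
    change = np.flatnonzero(np.diff(cov)) + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change - 1, [len(cov) - 1]))
    return [(int(s), int(e), float(cov[s])) for s, e in zip(starts, ends)]


def build_profile(transcripts: list[TranscriptModel]) -> CoverageProfile:
    """Build the normalized exon-coverage profile of a transcript group."""
    if not transcripts:
        raise ValueError("cannot build a coverage profile from an empty group")
    lo = min(t.span[0] for t in transcripts)
    hi = max(t.span[1] for t in transcripts)
    n = len(transcripts)
    cov = np.zeros(hi - lo + 1, dtype=float)
    for t in transcripts:
        for e in t.exons:
            cov[e.start - lo : e.end - lo + 1] += 1.0
    cov /= n

    peaks: list[tuple[int, float, int, int]] = []
    valleys: list[tuple[int, int]] = []
    plats = _plateaus(cov)
    for i, (s, e, v) in enumerate(plats):
        left = plats[i - 1][2] if i > 0 else 0.0
        right = plats[i + 1][2] if i + 1 < len(plats) else 0.0
        if v > left and v > right:
            mid = s + (e - s) // 2
            peaks.append((mid, v, s, e))
        elif v < left and v < right:
            valleys.append((s, e))
    return CoverageProfile(lo, cov, n, peaks, valleys)
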