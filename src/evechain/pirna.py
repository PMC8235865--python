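"""Strand-bias tracks of piRNA-sized small-RNA alignments.

An EVE that acts as a piRNA source locus produces small RNAs predominantly
antisense to the element. Comparing the dominant piRNA orientation of two
EVE blocks against their genomic strands tests whether both behave like
parts of one original insertion — the orientation evidence consumed by
event merging.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .io import SmallRnaAlignment

__all__ = ["StrandRatioTrack", "strand_ratio_track", "orientation_verdict"]


@dataclass
class StrandRatioTrack:
    """Windowed forward-strand read fraction over one interval."""

    contig: str
    windows: pd.DataFrame  # columns: start, end, n_forward, n_total, ratio

    @property
    def overall_ratio(self) -> float | None:
        total = int(self.windows["n_total"].sum())
        if total == 0:
            return None
        return float(self.windows["n_forward"].sum()) / total


def strand_ratio_track(alignments: Sequence[SmallRnaAlignment],
                       interval: tuple[str, int, int],
                       window: int = 500,
                       min_len: int = 25,
                       max_len: int = 29) -> StrandRatioTrack:
    """Forward-strand ratio of 25–29-nt reads in tiling windows.

    ``interval`` is (contig, start, end), 1-based inclusive. A read counts
    in the window containing its 5'-most coordinate; reads outside the
    length range or the interval are ignored. Windows with no reads have
    ratio NaN.
    """
    contig, start, end = interval
    if end < start:
        raise ValueError("inverted interval")
    if window < 1:
        raise ValueError("window must be >= 1")
    starts = np.arange(start, end + 1, window)
    ends = np.minimum(starts + window - 1, end)
    n_forward = np.zeros(len(starts), dtype=np.int64)
    n_total = np.zeros(len(starts), dtype=np.int64)
    for a in alignments:
        if a.chrom != contig or not (min_len <= a.read_length <= max_len):
            continue
        if not (start <= a.pos <= end):
            continue
        w = (a.pos - start) // window
        n_total[w] += 1
        if a.strand == "+":
            n_forward[w] += 1
    with np.errstate(invalid="ignore"):
        ratio = np.where(n_total > 0, n_forward / np.maximum(n_total, 1), np.nan)
    df = pd.DataFrame({"start": starts, "end": ends,
                       "n_forward": n_forward, "n_total": n_total, "ratio": ratio})
    return StrandRatioTrack(contig=contig, windows=df)


def _dominance_label(track: StrandRatioTrack, dominance: float) -> str:
    ratio = track.overall_ratio
    if ratio is None:
        return "indeterminate"
    if ratio >= dominance:
        return "forward"
    if ratio <= 1 - dominance:
        return "reverse"
    return "indeterminate"


def orientation_verdict(track_a: StrandRatioTrack, track_b: StrandRatioTrack,
                        eve_strand_a: str, eve_strand_b: str,
                        dominance: float = 0.8) -> str:
    """Do two EVE blocks show the piRNA orientation expected of one insertion?

    piRNAs are expected antisense to the element: a plus-strand EVE block
    should be reverse-dominant and a minus-strand block forward-dominant.
    Returns "consistent" when both blocks show the expected anti-element
    bias, "inconsistent" when both are dominant but at least one points
    the wrong way, "indeterminate" when either block lacks a dominant
    orientation.
    """
    if track_a.windows.empty or track_b.windows.empty:
        raise ValueError("empty track")
    labels = (_dominance_label(track_a, dominance), _dominance_label(track_b, dominance))
    if "indeterminate" in labels:
        return "indeterminate"
    expected = {"+": "reverse", "-": "forward"}
    ok_a = labels[0] == expected[eve_strand_a]
    ok_b = labels[1] == expected[eve_strand_b]
    return "consistent" if (ok_a and ok_b) else "inconsistent"
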