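"""Per-position C-to-T conversion from amplicon reads.

Reads are anchored to the reference by exact matches to short flanks on
both sides of the protospacer; only indel-free reads (the intervening
segment has exactly protospacer length) enter the denominator.  Conversion
at each reference C is then the percentage of usable reads carrying a T at
that position.  Also provides the activity-window summary and the
canavanine-selection mutation-frequency statistic.
"""

from __future__ import annotations

import math
import warnings
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional

import pandas as pd

from .sequence_context import (
    GuideSite,
    NucleotideSequence,
    SequenceError,
    as_sequence,
    pam_relative_index,
    reverse_complement,
)

#: predominance_ratio value when the second-best position has zero conversion
RATIO_SENTINEL = math.inf


@dataclass(frozen=True)
class AnchoredReads:
    """Result of anchoring: extracted protospacer segments (5'->3' on the
    protospacer strand) plus a conservation-checked discard tally."""

    segments: tuple[str, ...]
    discarded: Mapping[str, int]
    total_reads: int

    @property
    def usable_reads(self) -> int:
        return len(self.segments)

    @property
    def n_discarded(self) -> int:
        return sum(self.discarded.values())


def _read_text(read) -> str:
    if hasattr(read, "seq"):  # Bio.SeqRecord
        return str(read.seq).upper()
    return str(read).upper()


def anchor_reads(
    reads: Iterable,
    reference: "NucleotideSequence | str",
    guide: GuideSite,
    flank_length: int = 10,
) -> AnchoredReads:
    """Anchor reads by exact flank matches around the protospacer.

    A read is usable iff it contains, in either orientation, both
    ``flank_length``-nt reference flanks of the protospacer with exactly
    the protospacer length between them.  Discard reasons: "short" (read
    shorter than flanks + protospacer), "indel" (both flanks found but the
    gap differs from the protospacer length), "no_anchor" (a flank is
    absent or mismatched).
    """
    ref = as_sequence(reference)
    start, end = guide.protospacer_interval
    if start - flank_length < 0 or end + flank_length > len(ref):
        raise SequenceError(
            "reference lacks sufficient flanking context around the protospacer"
        )
    if ref.bases[start:end] not in (
        guide.protospacer,
        reverse_complement(guide.protospacer).bases,
    ):
        raise SequenceError("reference does not contain the guide protospacer")
    left = ref.bases[start - flank_length : start]
    right = ref.bases[end : end + flank_length]
    proto_len = end - start
    min_len = proto_len + 2 * flank_length

    segments: list[str] = []
    discarded: Counter[str] = Counter()
    total = 0
    for read in reads:
        total += 1
        text = _read_text(read)
        if len(text) < min_len:
            discarded["short"] += 1
            continue
        segment = None
        saw_both_flanks = False
        for oriented in (text, reverse_complement(text).bases):
            i = oriented.find(left)
            while i != -1:
                j = oriented.find(right, i + flank_length)
                if j != -1:
                    saw_both_flanks = True
                    gap = j - (i + flank_length)
                    if gap == proto_len:
                        segment = oriented[i + flank_length : j]
                        break
                i = oriented.find(left, i + 1)
            if segment is not None:
                break
        if segment is None:
            discarded["indel" if saw_both_flanks else "no_anchor"] += 1
            continue
        if guide.strand == "-":
            segment = reverse_complement(segment).bases
        segments.append(segment)
    return AnchoredReads(
        segments=tuple(segments), discarded=dict(discarded), total_reads=total
    )


@dataclass(frozen=True)
class EditingTable:
    """Per-position C-to-T conversion percentages for one guide.

    ``per_position`` maps PAM-relative index -> (c_to_t_count,
    c_to_other_count, conversion_percent), restricted to reference Cs in
    the protospacer.
    """

    guide: GuideSite
    total_reads: int
    usable_reads: int
    per_position: Mapping[int, tuple[int, int, float]]

    def conversion_percent(self, position: int) -> float:
        return self.per_position[position][2]

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            {
                "position": pos,
                "c_to_t_count": ct,
                "c_to_other_count": co,
                "conversion_percent": pct,
            }
            for pos, (ct, co, pct) in sorted(self.per_position.items())
        ]
        return pd.DataFrame(
            rows,
            columns=[
                "position",
                "c_to_t_count",
                "c_to_other_count",
                "conversion_percent",
            ],
        )

    def to_tsv(self, handle) -> None:
        self.to_dataframe().to_csv(handle, sep="\t", index=False)

    def bar_summary(self, width: int = 50) -> str:
        """Plain-text bar chart of conversion by position."""
        lines = [f"usable reads: {self.usable_reads} / {self.total_reads}"]
        for pos, (_, _, pct) in sorted(self.per_position.items()):
            bar = "#" * round(pct / 100 * width)
            lines.append(f"C{pos:+d} {pct:6.2f}% {bar}")
        return "\n".join(lines)


def quantify_conversions(
    anchored: AnchoredReads, guide: GuideSite
) -> EditingTable:
    """C-to-T (and C-to-other) tallies at every reference C of the guide.

    conversion_percent = 100 x (usable reads with T at the position) /
    usable reads.  With zero usable reads the table is defined with all
    counts zero and no division performed.
    """
    proto = guide.protospacer
    length = len(proto)
    usable = anchored.usable_reads
    per_position: dict[int, tuple[int, int, float]] = {}
    for offset, base in enumerate(proto):
        if base != "C":
            continue
        position = pam_relative_index(offset, length)
        if usable == 0:
            per_position[position] = (0, 0, 0.0)
            continue
        c_to_t = 0
        c_to_other = 0
        for segment in anchored.segments:
            observed = segment[offset]
            if observed == "T":
                c_to_t += 1
            elif observed in ("A", "G"):
                c_to_other += 1
        per_position[position] = (c_to_t, c_to_other, 100.0 * c_to_t / usable)
    return EditingTable(
        guide=guide,
        total_reads=anchored.total_reads,
        usable_reads=usable,
        per_position=per_position,
    )


@dataclass(frozen=True)
class WindowSummary:
    threshold_percent: float
    window_bounds: Optional[tuple[int, int]]  # closed interval, None if empty
    predominant_position: Optional[int]
    predominance_ratio: Optional[float]  # RATIO_SENTINEL when second best is 0


def summarize_window(
    table: EditingTable, threshold_percent: float = 10.0
) -> WindowSummary:
    """Activity window (positions at/above threshold) and predominant site.

    Ties for the predominant position break toward the position closest to
    -18, then toward the more PAM-distal (more negative) one.  The
    predominance ratio is top conversion / second-best conversion over all
    assayed positions (infinite when the second best is zero).
    """
    if not table.per_position:
        raise SequenceError("editing table has no C positions")
    above = [
        pos
        for pos, (_, _, pct) in table.per_position.items()
        if pct >= threshold_percent
    ]
    if not above:
        return WindowSummary(threshold_percent, None, None, None)
    bounds = (min(above), max(above))
    ranked = sorted(
        table.per_position.items(),
        key=lambda item: (-item[1][2], abs(item[0] + 18), item[0]),
    )
    top_pos, (_, _, top_pct) = ranked[0]
    second_pct = ranked[1][1][2] if len(ranked) > 1 else 0.0
    ratio = RATIO_SENTINEL if second_pct == 0 else top_pct / second_pct
    return WindowSummary(threshold_percent, bounds, top_pos, ratio)


def canavanine_frequency(
    colonies_selective: int, colonies_nonselective: int
) -> float:
    """Mutation frequency from a canavanine selection assay: the ratio of
    the colony count on selective plates to the drug-free colony count."""
    if colonies_nonselective <= 0:
        raise ValueError("non-selective colony count must be positive")
    if colonies_selective > colonies_nonselective:
        warnings.warn(
            "selective colony count exceeds non-selective count",
            stacklevel=2,
        )
    return colonies_selective / colonies_nonselective
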