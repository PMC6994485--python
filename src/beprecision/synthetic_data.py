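"""Seed-deterministic generators with machine-readable ground truth.

Every generator emulates one of the toolkit's input types: amplicon reads
with controlled per-position C-to-T conversion probabilities (plus uniform
sequencing error and optional 1-nt indels at the target site), pathogenic
variant tables with flanking sequence, variant-call sets with a requested
substitution composition, and small random genomes.  All outputs carry
truth labels so that downstream estimates can be checked against the
generating parameters.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .be_catalog import (
    Catalog,
    builtin_catalog,
    enumerate_candidates,
    VariantRecord,
    VERDICT_BYSTANDER,
    VERDICT_NOT_TARGETABLE,
    VERDICT_PRECISE,
    _candidate_sort_key,
)
from .offtarget_tally import SPECTRUM_CLASSES, VariantCall
from .sequence_context import (
    GuideSite,
    NucleotideSequence,
    SequenceError,
    protospacer_offset,
    reverse_complement,
)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_BASE_INDEX = {ord(b): i for i, b in enumerate("ACGT")}


def random_genome(
    length: int, seed: int, gc_content: float = 0.5, name: str = "synthetic"
) -> NucleotideSequence:
    """Uniform (or GC-biased) random DNA sequence."""
    rng = np.random.default_rng(seed)
    p_gc = gc_content / 2
    p_at = (1 - gc_content) / 2
    codes = rng.choice(_BASES, size=length, p=[p_at, p_gc, p_gc, p_at])
    return NucleotideSequence(codes.tobytes().decode(), name=name)


# ---------------------------------------------------------------------------
# Amplicon read simulation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ReadSimulationSpec:
    """Parameters of one amplicon sequencing simulation.

    ``per_position_rates`` maps PAM-relative positions (which must be
    reference Cs of the guide's protospacer) to per-read conversion
    probabilities.  In "independent" mode each listed C converts
    independently; in "linked" mode a read is edited as a whole with
    ``linked_edit_probability`` and, if edited, converts each listed C
    with rate/linked_edit_probability (capped at 1), emulating processive
    co-editing within the window.
    """

    reference: NucleotideSequence
    guide: GuideSite
    per_position_rates: Mapping[int, float]
    sequencing_error_rate: float = 0.0
    indel_rate: float = 0.0
    n_reads: int = 1000
    seed: int = 0
    co_editing_mode: str = "independent"
    linked_edit_probability: float = 0.0

    def __post_init__(self) -> None:
        for prob in (
            *self.per_position_rates.values(),
            self.sequencing_error_rate,
            self.indel_rate,
            self.linked_edit_probability,
        ):
            if not 0.0 <= prob <= 1.0:
                raise SequenceError(f"probability {prob} outside [0, 1]")
        if self.co_editing_mode not in ("independent", "linked"):
            raise SequenceError(f"unknown co-editing mode {self.co_editing_mode!r}")
        proto = self.guide.protospacer
        for position in self.per_position_rates:
            off = protospacer_offset(position, len(proto))
            if proto[off] != "C":
                raise SequenceError(
                    f"conversion rate given at position {position}, which is "
                    f"{proto[off]!r} (not C) in the protospacer"
                )


def _plus_strand_index(guide: GuideSite, position: int) -> int:
    """Reference + strand coordinate of a PAM-relative protospacer position."""
    start, end = guide.protospacer_interval
    off = protospacer_offset(position, end - start)
    return start + off if guide.strand == "+" else end - 1 - off


def simulate_reads(
    spec: ReadSimulationSpec,
) -> tuple[list[SeqRecord], pd.DataFrame]:
    """Simulate amplicon reads covering the full reference.

    Returns FASTQ-ready records (constant maximal qualities) and a truth
    table with one row per read: conversion status at every listed
    position, sequencing-error count, and indel status.  Fully
    reproducible from ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    ref_bytes = np.frombuffer(spec.reference.bases.encode(), dtype=np.uint8)
    n, length = spec.n_reads, len(ref_bytes)
    reads = np.tile(ref_bytes, (n, 1))

    positions = sorted(spec.per_position_rates)
    # converted protospacer-strand C reads as T on + for a + guide, as A
    # (the complement of T) on + for a - guide
    edited_code = ord("T") if spec.guide.strand == "+" else ord("A")
    conversions = np.zeros((n, len(positions)), dtype=bool)
    if spec.co_editing_mode == "linked" and positions:
        q = spec.linked_edit_probability
        edited = rng.random(n) < q
        for k, pos in enumerate(positions):
            rate = spec.per_position_rates[pos]
            conditional = min(rate / q, 1.0) if q > 0 else 0.0
            conversions[:, k] = edited & (rng.random(n) < conditional)
    else:
        for k, pos in enumerate(positions):
            conversions[:, k] = rng.random(n) < spec.per_position_rates[pos]
    for k, pos in enumerate(positions):
        idx = _plus_strand_index(spec.guide, pos)
        reads[conversions[:, k], idx] = edited_code

    if spec.sequencing_error_rate > 0:
        error_mask = rng.random((n, length)) < spec.sequencing_error_rate
        shifts = rng.integers(1, 4, size=int(error_mask.sum()))
        rows, cols = np.nonzero(error_mask)
        current = reads[rows, cols]
        current_idx = np.array([_BASE_INDEX[c] for c in current])
        reads[rows, cols] = _BASES[(current_idx + shifts) % 4]
        n_errors = error_mask.sum(axis=1)
    else:
        n_errors = np.zeros(n, dtype=int)

    has_indel = (
        rng.random(n) < spec.indel_rate
        if spec.indel_rate > 0
        else np.zeros(n, dtype=bool)
    )
    start, end = spec.guide.protospacer_interval
    indel_positions = rng.integers(start, end, size=n)
    indel_is_deletion = rng.random(n) < 0.5
    indel_inserted = rng.choice(_BASES, size=n)

    records = []
    for i in range(n):
        text = reads[i].tobytes().decode()
        if has_indel[i]:
            j = int(indel_positions[i])
            if indel_is_deletion[i]:
                text = text[:j] + text[j + 1 :]
            else:
                text = text[:j] + chr(indel_inserted[i]) + text[j:]
        record = SeqRecord(
            Seq(text), id=f"read_{i:06d}", description=""
        )
        record.letter_annotations["phred_quality"] = [40] * len(text)
        records.append(record)

    truth = pd.DataFrame(
        {
            "read_id": [f"read_{i:06d}" for i in range(n)],
            "has_indel": has_indel,
            "n_errors": n_errors,
            **{
                f"converted_{pos}": conversions[:, k]
                for k, pos in enumerate(positions)
            },
        }
    )
    return records, truth


def write_fastq(records: Sequence[SeqRecord], path) -> None:
    SeqIO.write(records, str(path), "fastq")


def read_fastq(path) -> list[SeqRecord]:
    return list(SeqIO.parse(str(path), "fastq"))


# ---------------------------------------------------------------------------
# Pathogenic-variant table simulation
# ---------------------------------------------------------------------------

_INTENDED_PAM = "TGA"  # NGA; avoids the NG self-overlap of an NGG PAM

#: targetable context kinds and the positions they are built at
CONTEXT_KINDS = ("clean", "tcac", "ycc15")


def _draw_bases(rng: np.random.Generator, k: int, alphabet: str) -> str:
    codes = np.frombuffer(alphabet.encode(), dtype=np.uint8)
    return rng.choice(codes, size=k).tobytes().decode()


def _build_targetable(
    rng: np.random.Generator,
    flank_length: int,
    position: int,
    context: str,
) -> tuple[str, str]:
    """Flanks (5', 3') around a focal disease C placed at ``position``
    relative to a constructed PAM, with the requested bystander context
    and no competing guide placement.

    The entire window-reachable PAM zone downstream of the focal base is
    kept G-free except for the constructed PAM, so the focal C can only be
    read at the intended position.
    """
    k = -position  # distance of the focal C from the PAM start (11..20)
    # protospacer bases other than the focal C: no C (so "clean" rows have
    # no bystander anywhere), and no G downstream of the focal base (so no
    # competing PAM arises inside the zone)
    upstream_len = 20 - k  # protospacer bases 5' of the focal C
    upstream = _draw_bases(rng, upstream_len, "AGT")
    downstream = _draw_bases(rng, k - 1, "AT")
    proto = upstream + "C" + downstream
    offset = upstream_len  # focal C offset within the protospacer

    def set_at(s: str, pam_relative: int, base: str) -> str:
        i = protospacer_offset(pam_relative, 20)
        return s[:i] + base + s[i + 1 :]

    if context == "tcac":
        assert position == -15
        for rel, base in ((-16, "T"), (-14, "A"), (-13, "C")):
            proto = set_at(proto, rel, base)
    elif context == "ycc15":
        assert position == -15
        for rel, base in ((-17, "T"), (-16, "C")):
            proto = set_at(proto, rel, base)
    elif context != "clean":
        raise SequenceError(f"unknown context kind {context!r}")
    upstream, downstream = proto[:offset], proto[offset + 1 :]

    # tail: PAM, a C to block GAA/GAT readings of the PAM's own G, then a
    # G-free remainder of the zone and unconstrained sequence beyond it
    zone_tail = _draw_bases(rng, 21, "ACT")
    tail = _INTENDED_PAM + "C" + zone_tail
    prefix = _draw_bases(rng, flank_length - upstream_len, "ACGT")
    flank5 = prefix + upstream
    flank3 = downstream + tail
    if len(flank3) < flank_length:
        flank3 += _draw_bases(rng, flank_length - len(flank3), "ACGT")
    return flank5, flank3


def _build_nontargetable(
    rng: np.random.Generator, flank_length: int, zone: tuple[int, int]
) -> tuple[str, str]:
    """Flanks whose G-free downstream zone verifiably admits no PAM that
    would place the focal C inside any profiled editor window."""
    lo, hi = zone  # window union, e.g. (-20, -11)
    flank5 = _draw_bases(rng, flank_length, "ACGT")
    flank3 = list(_draw_bases(rng, flank_length, "ACGT"))
    # zone of flank3 offsets that could carry any base of a qualifying PAM:
    # PAM starts focal+(-hi)..focal+(-lo), motifs up to 4 nt
    for off in range(-hi - 1, min(-lo + 3, flank_length)):
        if flank3[off] == "G":
            flank3[off] = _draw_bases(rng, 1, "ACT")
    return flank5, "".join(flank3)


def simulate_variant_table(
    n: int,
    flank_length: int = 30,
    fraction_targetable: float = 0.7,
    seed: int = 0,
    catalog: Optional[Catalog] = None,
    max_retries: int = 20,
) -> tuple[list[VariantRecord], pd.DataFrame]:
    """Candidate pathogenic T>C / A>G variants with truth labels.

    Targetable records embed a constructed PAM placing the focal C at a
    known position with a controlled bystander context ("clean",
    no-bystander; "tcac", the TCAC motif at -15; "ycc15", the deliberately
    ambiguous YCC context at -15 for which no editor discriminates).
    Non-targetable records verifiably lack any qualifying PAM.  Half of
    the records are emitted in the complementary-strand (A>G)
    representation.  Truth labels carry the intended position, context and
    expected verdict.
    """
    if flank_length < 25:
        raise SequenceError("flank_length must be at least 25")
    catalog = catalog or builtin_catalog()
    rng = np.random.default_rng(seed)
    zone = catalog.window_union()
    ranking = catalog.scan_position_ranking
    positions = list(ranking)

    records: list[VariantRecord] = []
    truth_rows = []
    for i in range(n):
        targetable = rng.random() < fraction_targetable
        identifier = f"var_{i:04d}"
        if targetable:
            draw = rng.random()
            if draw < 0.7:
                context = "clean"
                position = positions[int(rng.integers(len(positions)))]
                expected = VERDICT_PRECISE
                ambiguous = False
            elif draw < 0.9:
                context, position = "tcac", -15
                expected = VERDICT_PRECISE
                ambiguous = False
            else:
                context, position = "ycc15", -15
                expected = VERDICT_BYSTANDER
                ambiguous = True
            flank5 = flank3 = None
            for _ in range(max_retries):
                f5, f3 = _build_targetable(rng, flank_length, position, context)
                candidates = enumerate_candidates(f5 + "C" + f3, len(f5), catalog)
                if candidates:
                    best = min(
                        candidates, key=lambda c: _candidate_sort_key(c, ranking)
                    )
                    if best.position == position:
                        flank5, flank3 = f5, f3
                        break
            if flank5 is None:  # keep the last draw; label it ambiguous
                flank5, flank3, ambiguous = f5, f3, True
        else:
            context, position, expected, ambiguous = "none", None, VERDICT_NOT_TARGETABLE, False
            flank5, flank3 = _build_nontargetable(rng, flank_length, zone)

        flipped = bool(rng.random() < 0.5)
        if flipped:
            record = VariantRecord(
                identifier=identifier,
                flank5=reverse_complement(flank3).bases,
                flank3=reverse_complement(flank5).bases,
                ref_base="A",
                alt_base="G",
            )
        else:
            record = VariantRecord(
                identifier=identifier,
                flank5=flank5,
                flank3=flank3,
                ref_base="T",
                alt_base="C",
            )
        records.append(record)
        truth_rows.append(
            {
                "identifier": identifier,
                "targetable": targetable,
                "context": context,
                "intended_position": position,
                "expected_verdict": expected,
                "ambiguous": ambiguous,
                "strand_flipped": flipped,
            }
        )
    return records, pd.DataFrame(truth_rows)


# ---------------------------------------------------------------------------
# Variant-call simulation
# ---------------------------------------------------------------------------

_CLASS_REPRESENTATIVES = {
    "C>A/G>T": (("C", "A"), ("G", "T")),
    "C>G/G>C": (("C", "G"), ("G", "C")),
    "C>T/G>A": (("C", "T"), ("G", "A")),
    "T>A/A>T": (("T", "A"), ("A", "T")),
    "T>C/A>G": (("T", "C"), ("A", "G")),
    "T>G/A>C": (("T", "G"), ("A", "C")),
}


def simulate_variant_calls(
    n_snv_by_class: Mapping[str, int],
    n_indel: int = 0,
    seed: int = 0,
    chrom: str = "chrI",
    contig_length: int = 1_000_000,
) -> list[VariantCall]:
    """Variant calls with exactly the requested composition, shuffled.

    SNV classes are the strand-collapsed labels of the spectrum tally;
    each SNV is emitted in one of its two strand representations at
    random.  Indels alternate 1-nt insertions and deletions.
    """
    unknown = set(n_snv_by_class) - set(SPECTRUM_CLASSES)
    if unknown:
        raise ValueError(f"unknown substitution classes {sorted(unknown)}")
    rng = np.random.default_rng(seed)
    calls = []
    for cls, count in n_snv_by_class.items():
        reps = _CLASS_REPRESENTATIVES[cls]
        for _ in range(int(count)):
            ref, alt = reps[int(rng.integers(2))]
            calls.append(
                VariantCall(chrom, int(rng.integers(1, contig_length)), ref, alt)
            )
    for j in range(int(n_indel)):
        anchor = "ACGT"[int(rng.integers(4))]
        extra = "ACGT"[int(rng.integers(4))]
        if j % 2 == 0:
            ref, alt = anchor, anchor + extra
        else:
            ref, alt = anchor + extra, anchor
        calls.append(VariantCall(chrom, int(rng.integers(1, contig_length)), ref, alt))
    order = rng.permutation(len(calls))
    return [calls[i] for i in order]


def write_vcf(
    calls: Sequence[VariantCall], path, contig_length: int = 1_000_000
) -> None:
    """Minimal valid VCFv4.2 for synthetic variant calls."""
    contigs = []
    for call in calls:
        if call.chrom not in contigs:
            contigs.append(call.chrom)
    with open(path, "w") as handle:
        handle.write("##fileformat=VCFv4.2\n")
        for contig in contigs:
            handle.write(f"##contig=<ID={contig},length={contig_length}>\n")
        handle.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for call in sorted(calls, key=lambda c: (c.chrom, c.pos)):
            handle.write(
                f"{call.chrom}\t{call.pos}\t.\t{call.ref}\t{call.alt}\t.\tPASS\t.\n"
            )
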