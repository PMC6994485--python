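"""Nucleotide sequences, IUPAC motif matching and protospacer/PAM discovery.

Coordinate conventions used throughout the package:

* all intervals are 0-based, half-open, on the + strand of the source
  sequence;
* positions inside a protospacer are reported PAM-relative as negative
  integers, with -1 denoting the base immediately 5'-adjacent to the first
  PAM base.  For the standard 20-nt protospacer this maps protospacer
  offset 19 to -1 and offset 2 to -18, so "C-18" is the third protospacer
  base.
"""

from __future__ import annotations

import sys
from dataclasses import dataclass
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

DEFAULT_PROTOSPACER_LENGTH = 20

VALID_BASES = frozenset("ACGTN")

# Only the degenerate codes actually used by the editor-selection rules are
# accepted; anything else is rejected loudly rather than silently matched.
IUPAC_CODES: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "N": frozenset("ACGT"),
    "D": frozenset("AGT"),  # not C
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
}

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class SequenceError(ValueError):
    """Raised for malformed sequences, patterns or coordinates."""


@dataclass(frozen=True)
class NucleotideSequence:
    """An upper-case DNA sequence over {A, C, G, T, N} with a label."""

    bases: str
    name: str = ""

    def __post_init__(self) -> None:
        normalized = self.bases.upper()
        if len(normalized) < 1:
            raise SequenceError("sequence must contain at least one base")
        illegal = set(normalized) - VALID_BASES
        if illegal:
            raise SequenceError(
                f"illegal characters in sequence {self.name!r}: {sorted(illegal)}"
            )
        object.__setattr__(self, "bases", normalized)

    def __len__(self) -> int:
        return len(self.bases)

    def __getitem__(self, index) -> str:
        return self.bases[index]

    def __str__(self) -> str:
        return self.bases


def as_sequence(seq: "NucleotideSequence | str", name: str = "") -> NucleotideSequence:
    if isinstance(seq, NucleotideSequence):
        return seq
    return NucleotideSequence(str(seq), name=name)


def reverse_complement(seq: "NucleotideSequence | str") -> NucleotideSequence:
    """Watson-Crick complement, reversed.  N maps to N."""
    s = as_sequence(seq)
    return NucleotideSequence(s.bases.translate(_COMPLEMENT)[::-1], name=s.name)


def complement_base(base: str) -> str:
    return base.translate(_COMPLEMENT)


def iupac_match(pattern: str, window: str) -> bool:
    """True iff ``window`` satisfies the IUPAC ``pattern`` position by position.

    Supported codes: literal A/C/G/T, N (any base), D (not C), R (A or G),
    Y (C or T).  An N in the *window* is treated conservatively: it matches
    pattern-N only, never a literal or degenerate code.
    """
    pattern = pattern.upper()
    window = window.upper()
    if len(pattern) != len(window):
        raise SequenceError(
            f"pattern {pattern!r} and window {window!r} differ in length"
        )
    for code, base in zip(pattern, window):
        allowed = IUPAC_CODES.get(code)
        if allowed is None:
            raise SequenceError(f"unsupported IUPAC code {code!r} in {pattern!r}")
        if base not in VALID_BASES:
            raise SequenceError(f"illegal base {base!r} in window {window!r}")
        if base == "N":
            if code != "N":
                return False
        elif base not in allowed:
            return False
    return True


@dataclass(frozen=True)
class PamSpec:
    """A Cas9 variant and the IUPAC PAM motifs it recognizes."""

    cas_variant_name: str
    motifs: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.motifs:
            raise SequenceError("PamSpec requires at least one motif")
        motifs = tuple(m.upper() for m in self.motifs)
        for motif in motifs:
            if not 2 <= len(motif) <= 4:
                raise SequenceError(f"PAM motif {motif!r} must be 2-4 nt long")
            bad = set(motif) - set(IUPAC_CODES)
            if bad:
                raise SequenceError(f"PAM motif {motif!r} has unsupported codes {bad}")
        object.__setattr__(self, "motifs", motifs)


@dataclass(frozen=True)
class GuideSite:
    """One protospacer + PAM occurrence on a strand of a source sequence.

    ``pam_start``/``pam_end`` and ``protospacer_interval`` are + strand
    coordinates regardless of ``strand``; ``protospacer`` is read 5'->3' on
    the protospacer strand.
    """

    source_name: str
    strand: str  # "+" or "-"
    pam_start: int
    pam_end: int
    cas_variant: str
    pam_motif_matched: str
    pam_sequence: str
    protospacer: str
    protospacer_interval: tuple[int, int]

    def protospacer_offset_of(self, plus_strand_index: int) -> int:
        """Map a + strand coordinate to a 0-based offset in the protospacer
        (5'->3' on the protospacer strand); raises if outside the interval."""
        start, end = self.protospacer_interval
        if not start <= plus_strand_index < end:
            raise SequenceError(
                f"position {plus_strand_index} outside protospacer {start}-{end}"
            )
        if self.strand == "+":
            return plus_strand_index - start
        return end - 1 - plus_strand_index


def pam_relative_index(
    offset_in_protospacer: int,
    protospacer_length: int = DEFAULT_PROTOSPACER_LENGTH,
) -> int:
    """PAM-relative position of a protospacer offset (offset 19 -> -1)."""
    if not 0 <= offset_in_protospacer < protospacer_length:
        raise SequenceError(
            f"offset {offset_in_protospacer} outside protospacer of length "
            f"{protospacer_length}"
        )
    return offset_in_protospacer - protospacer_length


def protospacer_offset(
    pam_relative: int, protospacer_length: int = DEFAULT_PROTOSPACER_LENGTH
) -> int:
    """Inverse of :func:`pam_relative_index`."""
    if not -protospacer_length <= pam_relative <= -1:
        raise SequenceError(f"PAM-relative position {pam_relative} out of range")
    return pam_relative + protospacer_length


def _scan_plus(
    bases: str,
    name: str,
    spec: PamSpec,
    protospacer_length: int,
) -> Iterable[tuple[int, str, str]]:
    """Yield (pam_start, motif, pam_sequence) for + orientation matches with
    a full-length protospacer 5' of the PAM."""
    n = len(bases)
    for motif in spec.motifs:
        m = len(motif)
        for pam_start in range(protospacer_length, n - m + 1):
            window = bases[pam_start : pam_start + m]
            if iupac_match(motif, window):
                yield pam_start, motif, window


def find_guide_sites(
    seq: "NucleotideSequence | str",
    pam_specs: Sequence[PamSpec],
    protospacer_length: int = DEFAULT_PROTOSPACER_LENGTH,
) -> list[GuideSite]:
    """Every protospacer+PAM occurrence of every motif on both strands.

    Each occurrence is reported once per (Cas variant, motif, position,
    strand); overlapping and nested motifs are reported independently.
    Output is sorted by + strand PAM coordinate, then strand, then variant.
    """
    s = as_sequence(seq)
    n = len(s)
    sites: list[GuideSite] = []
    rc = reverse_complement(s).bases
    for spec in pam_specs:
        for pam_start, motif, pam_seq in _scan_plus(
            s.bases, s.name, spec, protospacer_length
        ):
            proto_start = pam_start - protospacer_length
            sites.append(
                GuideSite(
                    source_name=s.name,
                    strand="+",
                    pam_start=pam_start,
                    pam_end=pam_start + len(motif),
                    cas_variant=spec.cas_variant_name,
                    pam_motif_matched=motif,
                    pam_sequence=pam_seq,
                    protospacer=s.bases[proto_start:pam_start],
                    protospacer_interval=(proto_start, pam_start),
                )
            )
        for rc_pam_start, motif, pam_seq in _scan_plus(
            rc, s.name, spec, protospacer_length
        ):
            m = len(motif)
            # map reverse-complement coordinates back to the + strand
            pam_start = n - rc_pam_start - m
            proto_plus_start = n - rc_pam_start
            sites.append(
                GuideSite(
                    source_name=s.name,
                    strand="-",
                    pam_start=pam_start,
                    pam_end=pam_start + m,
                    cas_variant=spec.cas_variant_name,
                    pam_motif_matched=motif,
                    pam_sequence=pam_seq,
                    protospacer=rc[rc_pam_start - protospacer_length : rc_pam_start],
                    protospacer_interval=(
                        proto_plus_start,
                        proto_plus_start + protospacer_length,
                    ),
                )
            )
    sites.sort(
        key=lambda g: (g.pam_start, g.strand, g.cas_variant, g.pam_motif_matched)
    )
    return sites


# ---------------------------------------------------------------------------
# FASTA and tabular output
# ---------------------------------------------------------------------------

def read_fasta(path) -> list[NucleotideSequence]:
    return [
        NucleotideSequence(str(rec.seq), name=rec.id)
        for rec in SeqIO.parse(str(path), "fasta")
    ]


def write_fasta(sequences: Iterable[NucleotideSequence], path) -> None:
    records = [
        SeqRecord(Seq(s.bases), id=s.name or f"seq{i}", description="")
        for i, s in enumerate(sequences)
    ]
    SeqIO.write(records, str(path), "fasta")


GUIDE_TSV_COLUMNS = (
    "sequence_name",
    "strand",
    "pam_start",
    "pam_end",
    "cas_variant",
    "pam_matched",
    "pam_sequence",
    "protospacer",
)


def guide_sites_to_tsv(sites: Iterable[GuideSite], handle=sys.stdout) -> None:
    handle.write("\t".join(GUIDE_TSV_COLUMNS) + "\n")
    for g in sites:
        handle.write(
            "\t".join(
                str(x)
                for x in (
                    g.source_name,
                    g.strand,
                    g.pam_start,
                    g.pam_end,
                    g.cas_variant,
                    g.pam_motif_matched,
                    g.pam_sequence,
                    g.protospacer,
                )
            )
            + "\n"
        )


def guide_sites_to_bed(sites: Iterable[GuideSite], handle=sys.stdout) -> None:
    """Protospacer intervals as BED6 (0-based, half-open)."""
    for g in sites:
        start, end = g.protospacer_interval
        name = f"{g.cas_variant}|{g.pam_motif_matched}"
        handle.write(
            f"{g.source_name}\t{start}\t{end}\t{name}\t0\t{g.strand}\n"
        )
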