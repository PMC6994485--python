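"""Indel/SNV counts and substitution spectra from variant-call records.

Consumes variant calls (VCF or in-memory records); calling itself is out
of scope.  The spectrum is collapsed onto the six strand-symmetric
substitution classes standard in mutation-spectrum analysis (a G>A call is
the same event as C>T read on the other strand); a 12-class uncollapsed
mode is available by flag.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

SNV_BASES = frozenset("ACGT")

#: strand-collapsed substitution classes, pyrimidine-first convention
SPECTRUM_CLASSES = (
    "C>A/G>T",
    "C>G/G>C",
    "C>T/G>A",
    "T>A/A>T",
    "T>C/A>G",
    "T>G/A>C",
)

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


@dataclass(frozen=True)
class VariantCall:
    """One called variant (one alternate allele)."""

    chrom: str
    pos: int
    ref: str
    alt: str


def substitution_class(ref: str, alt: str, collapse: bool = True) -> str:
    """Class label for a single-base substitution.

    Collapsed mode maps purine-reference calls onto their complementary-
    strand pyrimidine representation, e.g. G>A -> "C>T/G>A".
    """
    ref = ref.upper()
    alt = alt.upper()
    if ref not in SNV_BASES or alt not in SNV_BASES or ref == alt:
        raise ValueError(f"not a substitution: {ref!r}>{alt!r}")
    if not collapse:
        return f"{ref}>{alt}"
    if ref in ("G", "A"):
        ref, alt = _COMPLEMENT[ref], _COMPLEMENT[alt]
    label = f"{ref}>{alt}/{_COMPLEMENT[ref]}>{_COMPLEMENT[alt]}"
    assert label in SPECTRUM_CLASSES
    return label


@dataclass(frozen=True)
class VariantCallSummary:
    label: str
    n_indels: int
    n_snvs: int
    n_other: int  # MNVs / symbolic alleles, excluded from the spectrum
    n_skipped: int
    spectrum: Mapping[str, tuple[int, float]]  # class -> (count, frequency)

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "n_indels": self.n_indels,
            "n_snvs": self.n_snvs,
            "n_other": self.n_other,
            "n_skipped": self.n_skipped,
            "spectrum": {
                cls: {"count": count, "frequency": freq}
                for cls, (count, freq) in self.spectrum.items()
            },
        }

    def to_json(self, handle) -> None:
        json.dump(self.to_dict(), handle, indent=2)

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            {"class": cls, "count": count, "frequency": freq}
            for cls, (count, freq) in self.spectrum.items()
        ]
        return pd.DataFrame(rows, columns=["class", "count", "frequency"])


def split_multiallelic(records: Iterable[VariantCall]) -> Iterable[VariantCall]:
    """Split comma-separated alternate alleles into one record each."""
    for record in records:
        for alt in str(record.alt).split(","):
            yield VariantCall(record.chrom, record.pos, record.ref, alt.strip())


def tally_variants(
    records: Iterable[VariantCall],
    label: str = "",
    collapse: bool = True,
) -> VariantCallSummary:
    """Count indels and SNVs and build the substitution spectrum.

    A record is an SNV iff reference and alternate are both single bases;
    length-changing alleles are indels; equal-length multi-base (MNV) or
    symbolic alleles land in an "other" bucket outside the spectrum.
    Malformed allele strings are skipped with a tally, not an abort.
    """
    classes = (
        SPECTRUM_CLASSES
        if collapse
        else tuple(
            f"{r}>{a}" for r in "ACGT" for a in "ACGT" if r != a
        )
    )
    counts: Counter[str] = Counter()
    n_indels = n_snvs = n_other = n_skipped = 0
    for record in split_multiallelic(records):
        ref = str(record.ref).upper()
        alt = str(record.alt).upper()
        if not ref or not alt:
            n_skipped += 1
            continue
        if len(ref) == 1 and len(alt) == 1:
            if ref in SNV_BASES and alt in SNV_BASES and ref != alt:
                n_snvs += 1
                counts[substitution_class(ref, alt, collapse)] += 1
            else:
                n_skipped += 1
        elif set(ref) <= SNV_BASES and set(alt) <= SNV_BASES:
            if len(ref) == len(alt):
                n_other += 1
            else:
                n_indels += 1
        else:
            n_skipped += 1  # symbolic / breakend / malformed
    spectrum = {
        cls: (counts[cls], counts[cls] / n_snvs if n_snvs else 0.0)
        for cls in classes
    }
    return VariantCallSummary(
        label=label,
        n_indels=n_indels,
        n_snvs=n_snvs,
        n_other=n_other,
        n_skipped=n_skipped,
        spectrum=spectrum,
    )


def read_vcf(path) -> list[VariantCall]:
    """Read a VCF (v4.x, plain or gzipped) into per-alt variant calls."""
    from cyvcf2 import VCF

    calls = []
    vcf = VCF(str(path))
    try:
        for variant in vcf:
            for alt in variant.ALT:
                calls.append(
                    VariantCall(variant.CHROM, variant.POS, variant.REF, alt)
                )
    finally:
        vcf.close()
    return calls


def tally_vcf(path, label: Optional[str] = None, collapse: bool = True) -> VariantCallSummary:
    return tally_variants(
        read_vcf(path), label=label if label is not None else str(path), collapse=collapse
    )


def compare_summaries(
    summaries: Sequence[VariantCallSummary],
) -> pd.DataFrame:
    """Side-by-side counts/frequencies with pairwise count differences.

    Rows are metrics; one column per input label (input order preserved)
    plus a difference column per ordered label pair.  No significance
    testing is performed.
    """
    if len(summaries) < 2:
        raise ValueError("need at least two summaries to compare")
    labels = [s.label or f"summary{i}" for i, s in enumerate(summaries)]
    metrics: dict[str, list] = {}
    classes = list(summaries[0].spectrum)
    index = (
        ["n_indels", "n_snvs"]
        + [f"count[{c}]" for c in classes]
        + [f"frequency[{c}]" for c in classes]
    )
    for label, summary in zip(labels, summaries):
        metrics[label] = (
            [summary.n_indels, summary.n_snvs]
            + [summary.spectrum[c][0] for c in classes]
            + [summary.spectrum[c][1] for c in classes]
        )
    frame = pd.DataFrame(metrics, index=index)
    for i, a in enumerate(labels):
        for b in labels[i + 1 :]:
            frame[f"{a}-{b}"] = frame[a] - frame[b]
    return frame
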