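"""Cytosine base-editor knowledge base and selection logic.

Holds per-editor activity windows and position preferences, the decision
table mapping (distance of the target C from the PAM, bystander context)
to recommended editors, bystander risk reporting, and the pathogenic-variant
scanner that searches both strand representations of a T>C (or A>G) disease
allele for guide placements allowing precise correction.

The decision table is evaluated as a practitioner reads it: if the local
context around the target C matches one of the bystander motifs of the
matching distance bucket, those cells apply; the "no bystander" cell of the
bucket applies only otherwise, and then only for editors whose own activity
window is free of non-target Cs.  Bystander motifs are consulted only when
some non-target C actually lies within the range editors can reach (the
union of the cataloged activity windows): degenerate codes such as N admit
a bystander but do not require one, and a context whose only extra Cs sit
far outside every window belongs to the "no bystander" cell.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources
from typing import Iterable, Mapping, Optional, Sequence

import yaml

from .sequence_context import (
    GuideSite,
    NucleotideSequence,
    PamSpec,
    SequenceError,
    as_sequence,
    find_guide_sites,
    iupac_match,
    pam_relative_index,
    protospacer_offset,
)

DEFAULT_RANKING: tuple[int, ...] = (-18, -17, -19, -16, -15)

DISTANCE_BUCKETS = ("<-19", "-19", "-18", "-17", "-16", "-15", "-14", ">-14")

NO_BYSTANDER = "no-bystander"

VERDICT_PRECISE = "precisely-correctable"
VERDICT_BYSTANDER = "bystander-prone"
VERDICT_NOT_TARGETABLE = "not-targetable"


class CatalogError(ValueError):
    """Malformed catalog configuration or unresolvable editor name."""


class CapabilityError(ValueError):
    """Operation requires an editor window profile that is not available."""


@dataclass(frozen=True)
class BEProfile:
    """One base editor: identity, PAM compatibility, window, preferences.

    ``window`` is a closed PAM-relative interval (lo, hi) with lo <= hi,
    e.g. (-17, -14); ``preferred_positions`` is ordered most-preferred
    first.  Editors recommendable by name only carry ``window=None``.
    """

    name: str
    deaminase_family: str
    compatible_pams: tuple[str, ...]
    window: Optional[tuple[int, int]] = None
    preferred_positions: tuple[int, ...] = ()
    sequence_preference: Optional[str] = None
    provenance: str = "figure-informed-default"

    def __post_init__(self) -> None:
        if self.window is not None:
            lo, hi = self.window
            if not (-20 <= lo <= hi <= -1):
                raise CatalogError(f"{self.name}: window {self.window} out of range")
            for p in self.preferred_positions:
                if not lo <= p <= hi:
                    raise CatalogError(
                        f"{self.name}: preferred position {p} outside window"
                    )

    @property
    def has_window(self) -> bool:
        return self.window is not None

    def window_positions(self) -> range:
        if self.window is None:
            raise CapabilityError(f"{self.name} has no window profile")
        return range(self.window[0], self.window[1] + 1)


@dataclass(frozen=True)
class ContextRule:
    """One decision-table cell: distance bucket + bystander context."""

    distance_bucket: str
    bystander_pattern: str  # IUPAC pattern, or the NO_BYSTANDER sentinel
    target_offset_in_pattern: Optional[int]
    recommended_bes: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.distance_bucket not in DISTANCE_BUCKETS:
            raise CatalogError(f"unknown distance bucket {self.distance_bucket!r}")
        if not self.recommended_bes:
            raise CatalogError("rule with empty editor list")
        if self.bystander_pattern != NO_BYSTANDER:
            off = self.target_offset_in_pattern
            if off is None or not 0 <= off < len(self.bystander_pattern):
                raise CatalogError(
                    f"rule {self.bystander_pattern!r}: bad target offset {off}"
                )
            if self.bystander_pattern[off] != "C":
                raise CatalogError(
                    f"rule {self.bystander_pattern!r}: target position is not C"
                )

    @property
    def is_pattern(self) -> bool:
        return self.bystander_pattern != NO_BYSTANDER

    @property
    def specificity(self) -> int:
        """Count of non-N pattern positions (0 for no-bystander cells)."""
        if not self.is_pattern:
            return 0
        return sum(1 for c in self.bystander_pattern if c != "N")


@dataclass(frozen=True)
class Catalog:
    pam_specs: tuple[PamSpec, ...]
    profiles: Mapping[str, BEProfile]
    rules: tuple[ContextRule, ...]
    scan_position_ranking: tuple[int, ...] = DEFAULT_RANKING
    deaminase_lengths: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for rule in self.rules:
            for name in rule.recommended_bes:
                if name not in self.profiles:
                    raise CatalogError(
                        f"rule {rule.distance_bucket}/{rule.bystander_pattern} "
                        f"recommends unknown editor {name!r}"
                    )

    def profile(self, name: str) -> BEProfile:
        try:
            return self.profiles[name]
        except KeyError:
            raise CatalogError(f"unknown editor {name!r}") from None

    def windowed_profiles(self) -> list[BEProfile]:
        return [p for p in self.profiles.values() if p.has_window]

    def window_union(self) -> tuple[int, int]:
        windows = [p.window for p in self.windowed_profiles()]
        return min(w[0] for w in windows), max(w[1] for w in windows)


def _load_catalog_dict(config: dict) -> Catalog:
    pam_specs = tuple(
        PamSpec(entry["cas_variant"], tuple(entry["motifs"]))
        for entry in config["pam_specs"]
    )
    profiles: dict[str, BEProfile] = {}

    def add(entry: dict) -> None:
        window = tuple(entry["window"]) if entry.get("window") else None
        profiles[entry["name"]] = BEProfile(
            name=entry["name"],
            deaminase_family=entry["family"],
            compatible_pams=tuple(entry["pams"]),
            window=window,
            preferred_positions=tuple(entry.get("preferred", ())),
            sequence_preference=entry.get("sequence_preference"),
            provenance=entry.get("provenance", "figure-informed-default"),
        )

    for entry in config.get("editors", ()):
        add(entry)
    series = config.get("cda1_truncation_series")
    if series:
        for scaffold in series["scaffolds"]:
            for residue in series["residues"]:
                add(
                    {
                        "name": f"nCDA1Δ{residue}-{scaffold['suffix']}",
                        "family": "CDA1",
                        "pams": scaffold["pams"],
                        "window": series["window"],
                        "preferred": series["preferred"],
                        "provenance": series["provenance"],
                    }
                )
    rules = tuple(
        ContextRule(
            distance_bucket=str(entry["distance"]),
            bystander_pattern=str(entry["bystander"]),
            target_offset_in_pattern=entry.get("target_offset"),
            recommended_bes=tuple(entry["editors"]),
        )
        for entry in config["rules"]
    )
    return Catalog(
        pam_specs=pam_specs,
        profiles=profiles,
        rules=rules,
        scan_position_ranking=tuple(
            config.get("scan_position_ranking", DEFAULT_RANKING)
        ),
        deaminase_lengths=dict(config.get("deaminase_lengths", {})),
    )


def load_catalog(path) -> Catalog:
    """Load a catalog from a user-editable YAML config file."""
    with open(path) as handle:
        return _load_catalog_dict(yaml.safe_load(handle))


@lru_cache(maxsize=1)
def builtin_catalog() -> Catalog:
    """The built-in editor profiles and decision table."""
    text = resources.files(__package__).joinpath("data/catalog.yaml").read_text()
    return _load_catalog_dict(yaml.safe_load(text))


# ---------------------------------------------------------------------------
# Construct-name arithmetic
# ---------------------------------------------------------------------------

_TRUNCATION_RE = re.compile(r"(CDA1|A3A)(?:\([A-Z0-9]+\))?Δ(\d+)")


def truncation_removed_residues(
    construct_name: str, lengths: Optional[Mapping[str, int]] = None
) -> int:
    """Number of C-terminal residues removed by a truncation construct.

    ``A3AΔ182`` retains residues 1..182 of the 199-aa deaminase and
    therefore removes 17; ``CDA1Δ188`` removes 20 of 208.
    """
    if lengths is None:
        lengths = builtin_catalog().deaminase_lengths
    match = _TRUNCATION_RE.search(construct_name)
    if not match:
        raise CatalogError(f"no deaminase truncation in name {construct_name!r}")
    family, retained = match.group(1), int(match.group(2))
    full = lengths.get(family)
    if full is None:
        raise CatalogError(f"unknown deaminase family {family!r}")
    removed = full - retained
    if removed <= 0:
        raise CatalogError(
            f"{construct_name!r}: retained {retained} >= full length {full}"
        )
    return removed


# ---------------------------------------------------------------------------
# Context classification and recommendation
# ---------------------------------------------------------------------------

def distance_bucket(position: int) -> str:
    if not -20 <= position <= -1:
        raise SequenceError(f"PAM-relative position {position} out of range")
    if position < -19:
        return "<-19"
    if position > -14:
        return ">-14"
    return str(position)


@dataclass(frozen=True)
class ContextDescriptor:
    """Local context of a target C: distance bucket, protospacer sequence,
    and per-editor bystander C positions within each editor's own window."""

    target: int
    bucket: str
    protospacer: str
    bystanders_by_editor: Mapping[str, tuple[int, ...]]

    def no_bystander(self, editor: str) -> bool:
        return not self.bystanders_by_editor[editor]


def _target_offset(guide: GuideSite, target: int) -> int:
    length = len(guide.protospacer)
    off = protospacer_offset(target, length)
    base = guide.protospacer[off]
    if base != "C":
        raise SequenceError(
            f"protospacer base at position {target} is {base!r}, not C"
        )
    return off


def classify_context(guide: GuideSite, target: int, catalog: Catalog) -> ContextDescriptor:
    """Distance bucket plus per-editor bystander Cs for a target position.

    "No bystander" is an editor-specific property: it holds for an editor
    iff no C other than the target lies inside that editor's own window.
    """
    _target_offset(guide, target)
    length = len(guide.protospacer)
    bystanders: dict[str, tuple[int, ...]] = {}
    for profile in catalog.windowed_profiles():
        positions = []
        for p in profile.window_positions():
            if p == target or not -length <= p <= -1:
                continue
            if guide.protospacer[protospacer_offset(p, length)] == "C":
                positions.append(p)
        bystanders[profile.name] = tuple(positions)
    return ContextDescriptor(
        target=target,
        bucket=distance_bucket(target),
        protospacer=guide.protospacer,
        bystanders_by_editor=bystanders,
    )


@dataclass(frozen=True)
class Recommendation:
    matched_rules: tuple[ContextRule, ...]
    bes: tuple[str, ...]
    precise: bool
    warnings: tuple[str, ...] = ()


def _pattern_rule_fires(rule: ContextRule, guide: GuideSite, target_off: int) -> bool:
    pattern = rule.bystander_pattern
    start = target_off - rule.target_offset_in_pattern
    end = start + len(pattern)
    proto = guide.protospacer
    if start < 0 or end > len(proto):
        return False
    return iupac_match(pattern, proto[start:end])


def _has_window_bystander(
    guide: GuideSite, target: int, catalog: Catalog
) -> bool:
    """True iff any C other than the target lies within the union of the
    cataloged editor windows."""
    length = len(guide.protospacer)
    lo, hi = catalog.window_union()
    for p in range(max(lo, -length), hi + 1):
        if p == target:
            continue
        if guide.protospacer[protospacer_offset(p, length)] == "C":
            return True
    return False


def recommend(guide: GuideSite, target: int, catalog: Catalog) -> Recommendation:
    """Editor recommendation for a target C within a guide's protospacer.

    Matching cells are ordered by pattern specificity (count of non-N
    positions, descending) then table order; editor lists are concatenated
    with deduplication.  An empty match yields ``precise=False`` with a
    warning that no available editor discriminates the context.
    """
    target_off = _target_offset(guide, target)
    bucket = distance_bucket(target)
    context = classify_context(guide, target, catalog)

    pattern_hits = []
    if _has_window_bystander(guide, target, catalog):
        pattern_hits = [
            (idx, rule)
            for idx, rule in enumerate(catalog.rules)
            if rule.distance_bucket == bucket
            and rule.is_pattern
            and _pattern_rule_fires(rule, guide, target_off)
        ]
    matched: list[tuple[int, ContextRule, tuple[str, ...]]] = [
        (idx, rule, rule.recommended_bes) for idx, rule in pattern_hits
    ]
    if not pattern_hits:
        for idx, rule in enumerate(catalog.rules):
            if rule.distance_bucket != bucket or rule.is_pattern:
                continue
            eligible = tuple(
                name
                for name in rule.recommended_bes
                if not catalog.profile(name).has_window
                or context.no_bystander(name)
            )
            if eligible:
                matched.append((idx, rule, eligible))

    matched.sort(key=lambda item: (-item[1].specificity, item[0]))
    bes: list[str] = []
    for _, _, names in matched:
        for name in names:
            if name not in bes:
                bes.append(name)

    warnings: list[str] = []
    precise = bool(matched)
    if not precise:
        warnings.append(
            f"no discriminating editor for target {target} in context "
            f"{context.protospacer}"
        )
    for name in bes:
        profile = catalog.profile(name)
        pref = profile.sequence_preference
        if pref is not None:
            start = target_off - 1
            end = start + len(pref)
            local = guide.protospacer[max(start, 0) : end]
            if len(local) != len(pref) or not iupac_match(pref, local):
                warnings.append(f"{name}: reduced activity at non-{pref} sites")

    return Recommendation(
        matched_rules=tuple(rule for _, rule, _ in matched),
        bes=tuple(bes),
        precise=precise,
        warnings=tuple(warnings),
    )


def bystander_report(
    guide: GuideSite, target: int, be: BEProfile
) -> list[tuple[int, str]]:
    """Non-target Cs inside an editor's window, tiered by risk.

    Tier "high" for Cs at the editor's preferred positions, "low"
    otherwise.  Editors without a window profile cannot be assessed.
    """
    if not be.has_window:
        raise CapabilityError(f"{be.name} has no window profile")
    _target_offset(guide, target)
    length = len(guide.protospacer)
    report = []
    for p in be.window_positions():
        if p == target or not -length <= p <= -1:
            continue
        if guide.protospacer[protospacer_offset(p, length)] == "C":
            tier = "high" if p in be.preferred_positions else "low"
            report.append((p, tier))
    return report


# ---------------------------------------------------------------------------
# Pathogenic-variant scanning
# ---------------------------------------------------------------------------

@dataclass
class VariantRecord:
    """A candidate pathogenic substitution whose disease allele carries a C
    (on the given strand for T>C, on the complementary strand for A>G).

    ``flank5``/``flank3`` flank the focal base on the given strand; verdict
    fields are filled by :func:`scan_variants`.
    """

    identifier: str
    flank5: str
    flank3: str
    ref_base: str  # healthy allele on the given strand
    alt_base: str  # disease allele on the given strand; C or G
    verdict: Optional[str] = None
    best_guide: Optional[GuideSite] = None
    best_position: Optional[int] = None
    recommended_bes: tuple[str, ...] = ()
    bystander_flags: tuple[str, ...] = ()
    warnings: tuple[str, ...] = ()

    def disease_sequence(self) -> NucleotideSequence:
        return NucleotideSequence(
            self.flank5 + self.alt_base + self.flank3, name=self.identifier
        )

    @property
    def focal_index(self) -> int:
        return len(self.flank5)


@dataclass(frozen=True)
class ScanCandidate:
    guide: GuideSite
    position: int
    recommendation: Recommendation
    high_risk_bystanders: int
    bystanders: tuple[tuple[int, str], ...]


def _candidate_risk(
    guide: GuideSite, position: int, rec: Recommendation, catalog: Catalog
) -> tuple[int, tuple[tuple[int, str], ...]]:
    """Min count of high-tier bystanders over the profiled recommended
    editors (the practitioner picks the least risky one); falls back to all
    profiled editors covering the position when nothing profiled matched."""
    profiled = [
        catalog.profile(name)
        for name in rec.bes
        if catalog.profile(name).has_window
    ]
    if not profiled:
        if rec.precise:
            return 0, ()
        profiled = [
            p
            for p in catalog.windowed_profiles()
            if p.window[0] <= position <= p.window[1]
        ]
        if not profiled:
            return 0, ()
    best = None
    for profile in profiled:
        report = tuple(bystander_report(guide, position, profile))
        n_high = sum(1 for _, tier in report if tier == "high")
        key = (n_high, len(report))
        if best is None or key < best[0]:
            best = (key, report)
    return best[0][0], best[1]


def enumerate_candidates(
    sequence: "NucleotideSequence | str",
    focal_index: int,
    catalog: Catalog,
) -> list[ScanCandidate]:
    """All guide placements (both strands) putting the focal base, read as C
    on the protospacer strand, inside any profiled editor window."""
    seq = as_sequence(sequence)
    lo, hi = catalog.window_union()
    candidates = []
    for site in find_guide_sites(seq, catalog.pam_specs):
        start, end = site.protospacer_interval
        if not start <= focal_index < end:
            continue
        off = site.protospacer_offset_of(focal_index)
        if site.protospacer[off] != "C":
            continue
        position = pam_relative_index(off, len(site.protospacer))
        if not lo <= position <= hi:
            continue
        rec = recommend(site, position, catalog)
        risk, report = _candidate_risk(site, position, rec, catalog)
        candidates.append(
            ScanCandidate(
                guide=site,
                position=position,
                recommendation=rec,
                high_risk_bystanders=risk,
                bystanders=report,
            )
        )
    return candidates


def _candidate_sort_key(cand: ScanCandidate, ranking: Sequence[int]):
    try:
        rank = list(ranking).index(cand.position)
    except ValueError:
        rank = len(ranking)
    return (
        0 if cand.recommendation.precise else 1,
        rank,
        cand.high_risk_bystanders,
        abs(cand.position),
        0 if cand.guide.strand == "+" else 1,
        cand.guide.pam_start,
        cand.guide.cas_variant,
    )


def scan_variants(
    variants: Iterable[VariantRecord],
    catalog: Optional[Catalog] = None,
    ranking: Optional[Sequence[int]] = None,
    min_flank: int = 25,
) -> list[VariantRecord]:
    """Annotate each variant with its best correcting guide and a verdict.

    Both strand representations are evaluated (the focal C of an A>G
    disease allele lies on the complementary strand).  Candidates with a
    precise recommendation are preferred; within each group candidates are
    ranked by the position priority list, then by fewest high-risk
    bystanders; ties break toward the PAM-proximal position and the +
    strand.  (Without the precise-first step, relaxed NG PAMs reading the
    GG of an NGG site one base downstream would routinely pre-empt a
    precisely correctable placement with an imprecise higher-priority
    one.)  Verdicts: a precise
    recommendation with no high-risk bystanders is "precisely-correctable";
    any other placement is "bystander-prone"; no placement at all is
    "not-targetable".
    """
    catalog = catalog or builtin_catalog()
    ranking = tuple(ranking) if ranking is not None else catalog.scan_position_ranking
    out = []
    for record in variants:
        record.warnings = ()
        if len(record.flank5) < min_flank or len(record.flank3) < min_flank:
            record.verdict = None
            record.warnings = (
                f"flanks shorter than {min_flank} nt; record skipped",
            )
            out.append(record)
            continue
        if record.alt_base.upper() not in ("C", "G"):
            record.verdict = None
            record.warnings = (
                f"disease allele {record.alt_base!r} carries no C on either "
                "strand; record skipped",
            )
            out.append(record)
            continue
        candidates = enumerate_candidates(
            record.disease_sequence(), record.focal_index, catalog
        )
        if not candidates:
            record.verdict = VERDICT_NOT_TARGETABLE
            record.best_guide = None
            record.best_position = None
            record.recommended_bes = ()
            record.bystander_flags = ()
        else:
            best = min(candidates, key=lambda c: _candidate_sort_key(c, ranking))
            record.best_guide = best.guide
            record.best_position = best.position
            record.recommended_bes = best.recommendation.bes
            record.bystander_flags = tuple(
                f"{pos}:{tier}" for pos, tier in best.bystanders
            )
            record.warnings = best.recommendation.warnings
            if best.recommendation.precise and best.high_risk_bystanders == 0:
                record.verdict = VERDICT_PRECISE
            else:
                record.verdict = VERDICT_BYSTANDER
        out.append(record)
    return out


# ---------------------------------------------------------------------------
# Tabular I/O
# ---------------------------------------------------------------------------

VARIANT_TSV_COLUMNS = ("identifier", "flank5", "flank3", "ref_base", "alt_base")


def variants_from_tsv(path) -> list[VariantRecord]:
    import pandas as pd

    frame = pd.read_csv(path, sep="\t", dtype=str)
    missing = set(VARIANT_TSV_COLUMNS) - set(frame.columns)
    if missing:
        raise CatalogError(f"variant table lacks columns {sorted(missing)}")
    return [
        VariantRecord(
            identifier=row.identifier,
            flank5=row.flank5,
            flank3=row.flank3,
            ref_base=row.ref_base,
            alt_base=row.alt_base,
        )
        for row in frame.itertuples()
    ]


def variants_to_tsv(variants: Sequence[VariantRecord], handle) -> None:
    columns = VARIANT_TSV_COLUMNS + (
        "verdict",
        "best_position",
        "best_strand",
        "recommended_bes",
        "bystander_flags",
        "warnings",
    )
    handle.write("\t".join(columns) + "\n")
    for v in variants:
        handle.write(
            "\t".join(
                str(x)
                for x in (
                    v.identifier,
                    v.flank5,
                    v.flank3,
                    v.ref_base,
                    v.alt_base,
                    v.verdict or "",
                    "" if v.best_position is None else v.best_position,
                    v.best_guide.strand if v.best_guide else "",
                    ",".join(v.recommended_bes),
                    ",".join(v.bystander_flags),
                    ";".join(v.warnings),
                )
            )
            + "\n"
        )
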