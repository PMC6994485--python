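"""Editor catalog, decision-table recommendations and variant scanning."""

import io

import pytest

from beprecision import (
    CapabilityError,
    CatalogError,
    VariantRecord,
    VERDICT_BYSTANDER,
    VERDICT_NOT_TARGETABLE,
    VERDICT_PRECISE,
    bystander_report,
    classify_context,
    distance_bucket,
    recommend,
    reverse_complement,
    scan_variants,
    truncation_removed_residues,
    variants_from_tsv,
    variants_to_tsv,
)
from conftest import make_guide, protospacer_with


# ---------------------------------------------------------------------------
# catalog integrity
# ---------------------------------------------------------------------------

def test_builtin_catalog_resolves_every_rule_editor(catalog):
    for rule in catalog.rules:
        for name in rule.recommended_bes:
            assert catalog.profile(name) is not None


def test_builtin_catalog_contains_the_published_editor_set(catalog):
    for name in (
        "BE3",
        "nCDA1-BE3",
        "cCDA1-BE3",
        "nCDA1Δ198-BE3",
        "nCDA1Δ(194-188)-BE3",
        "nCDA1Δ190-BE3",
        "nCDA1Δ188-VQRBE3",
        "nCDA1Δ194-xBE3",
        "A3A-BE3",
        "A3A-NL-BE3",
        "A3AΔ190-BE3",
        "A3AΔ186-BE3",
        "A3AΔ182-BE3",
        "A3A(Y130F)Δ186-BE3",
        "eA3A-BE3",
    ):
        assert catalog.profile(name).has_window, name
    # recommendable by name only, no window profile
    assert not catalog.profile("YEE-BE3").has_window
    assert not catalog.profile("BE-PAPAPAP").has_window


def test_windows_and_preferences_are_consistent(catalog):
    for profile in catalog.windowed_profiles():
        lo, hi = profile.window
        assert -20 <= lo <= hi <= -1
        assert set(profile.preferred_positions) <= set(profile.window_positions())


def test_eA3A_carries_the_tcr_context_preference(catalog):
    assert catalog.profile("eA3A-BE3").sequence_preference == "TCR"


# ---------------------------------------------------------------------------
# construct-name arithmetic
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "name,removed",
    [
        ("nCDA1Δ195-BE3", 13),
        ("nCDA1Δ188-VQRBE3", 20),
        ("A3AΔ194-BE3", 5),
        ("A3AΔ190-BE3", 9),
        ("A3AΔ182-BE3", 17),
        ("A3A(Y130F)Δ186-BE3", 13),
    ],
)
def test_truncation_arithmetic(name, removed):
    assert truncation_removed_residues(name) == removed


def test_truncation_arithmetic_rejects_untruncated_names():
    with pytest.raises(CatalogError):
        truncation_removed_residues("BE3")


# ---------------------------------------------------------------------------
# context classification
# ---------------------------------------------------------------------------

def test_distance_buckets():
    assert distance_bucket(-20) == "<-19"
    assert distance_bucket(-19) == "-19"
    assert distance_bucket(-14) == "-14"
    assert distance_bucket(-13) == ">-14"
    assert distance_bucket(-1) == ">-14"


def test_single_c_context_has_no_bystanders_for_any_editor(catalog):
    guide = make_guide(protospacer_with({-18: "C"}))
    ctx = classify_context(guide, -18, catalog)
    assert ctx.bucket == "-18"
    assert all(not bys for bys in ctx.bystanders_by_editor.values())


def test_polyc_bystander_count_in_the_full_length_cda1_window(catalog):
    guide = make_guide("C" * 20)
    ctx = classify_context(guide, -18, catalog)
    # nCDA1-BE3 window spans -20..-14: six Cs besides the target
    assert len(ctx.bystanders_by_editor["nCDA1-BE3"]) == 6


def test_classify_context_requires_a_c_at_the_target(catalog):
    guide = make_guide(protospacer_with({-18: "C"}))
    with pytest.raises(Exception, match="A"):
        classify_context(guide, -17, catalog)


# ---------------------------------------------------------------------------
# recommend
# ---------------------------------------------------------------------------

def test_recommend_target_minus19_with_upstream_bystander(catalog):
    guide = make_guide(protospacer_with({-20: "C", -19: "C"}))
    rec = recommend(guide, -19, catalog)
    assert rec.precise and rec.bes == ("cCDA1-BE3",)


def test_recommend_tcc_context_at_minus16(catalog):
    guide = make_guide(protospacer_with({-17: "T", -16: "C", -15: "C"}))
    rec = recommend(guide, -16, catalog)
    assert rec.bes == ("cCDA1-BE3", "YEE-BE3", "BE-PAPAPAP")


def test_recommend_ycc_minus15_gap_has_no_discriminating_editor(catalog):
    for y in "TC":
        guide = make_guide(protospacer_with({-17: y, -16: "C", -15: "C"}))
        rec = recommend(guide, -15, catalog)
        assert not rec.precise and rec.bes == ()
        assert any("no discriminating editor" in w for w in rec.warnings)


def test_recommend_distal_target_without_bystander(catalog):
    guide = make_guide(protospacer_with({-20: "C"}))
    rec = recommend(guide, -20, catalog)
    assert rec.bes == ("nCDA1-BE3", "nCDA1Δ198-BE3", "A3A-NL-BE3")


def test_bystander_far_outside_every_window_counts_as_no_bystander(catalog):
    guide = make_guide(protospacer_with({-18: "C", -2: "C"}))
    rec = recommend(guide, -18, catalog)
    assert rec.precise
    assert rec.bes == ("nCDA1Δ198-BE3", "nCDA1-BE3", "cCDA1-BE3", "A3A-NL-BE3")


def test_recommend_is_deterministic(catalog):
    guide = make_guide(protospacer_with({-17: "C", -15: "C"}))
    first = recommend(guide, -15, catalog)
    assert all(recommend(guide, -15, catalog) == first for _ in range(3))


# ---------------------------------------------------------------------------
# bystander_report
# ---------------------------------------------------------------------------

def test_bystander_report_tiers(catalog):
    profile = catalog.profile("A3AΔ182-BE3")
    guide = make_guide(protospacer_with({-16: "C", -15: "C"}))
    assert bystander_report(guide, -15, profile) == [(-16, "high")]
    clean = make_guide(protospacer_with({-15: "C"}))
    assert bystander_report(clean, -15, profile) == []


def test_bystander_report_lists_every_window_c_for_polyc(catalog):
    profile = catalog.profile("nCDA1-BE3")
    guide = make_guide("C" * 20)
    report = bystander_report(guide, -18, profile)
    assert [pos for pos, _ in report] == [p for p in range(-20, -13) if p != -18]


def test_bystander_report_requires_window_profile(catalog):
    guide = make_guide(protospacer_with({-15: "C"}))
    with pytest.raises(CapabilityError):
        bystander_report(guide, -15, catalog.profile("YEE-BE3"))


# ---------------------------------------------------------------------------
# scan_variants
# ---------------------------------------------------------------------------

def _clean_minus18_variant():
    # focal disease C 18 nt 5' of an AG PAM, no other C near the windows
    proto = "TA" + "C" + "ATATTATTAATATTATA"
    flank5 = "TTATTAATATTAATTATATTAATTA" + proto[:2]
    flank3 = proto[3:] + "AGT" + "TATTATATTATTAATATTAATTATA"
    return VariantRecord("psen1_like", flank5, flank3, "T", "C")


def _tcac_minus15_variant():
    proto = "TATA" + "TCAC" + "ATTATATTTATA"  # focal C = first C of TCAC
    flank5 = "ATTAATTATATTAATTATATATTAT" + proto[:5]
    flank3 = proto[6:] + "AGG" + "TATTATATTATTAATATTAATTATA"
    return VariantRecord("tyr_like", flank5, flank3, "T", "C")


def test_scan_clean_minus18_site_is_precisely_correctable(catalog):
    record = _clean_minus18_variant()
    scan_variants([record], catalog)
    assert record.verdict == VERDICT_PRECISE
    assert record.best_position == -18


def test_scan_tcac_site_recommends_the_a3a_truncation_editors(catalog):
    record = _tcac_minus15_variant()
    scan_variants([record], catalog)
    assert record.verdict == VERDICT_PRECISE
    assert {"A3AΔ182-BE3", "A3A(Y130F)Δ186-BE3"} <= set(record.recommended_bes)


def test_scan_is_strand_consistent(catalog):
    for build in (_clean_minus18_variant, _tcac_minus15_variant):
        record = build()
        flipped = VariantRecord(
            record.identifier + "_rc",
            reverse_complement(record.flank3).bases,
            reverse_complement(record.flank5).bases,
            "A",
            "G",
        )
        scan_variants([record, flipped], catalog)
        assert flipped.verdict == record.verdict
        assert flipped.best_position == record.best_position
        assert flipped.recommended_bes == record.recommended_bes


def test_scan_without_any_qualifying_pam_is_not_targetable(catalog):
    # no G (hence no PAM with a G) anywhere downstream of the focal C
    record = VariantRecord(
        "no_pam", "ATTAATTATATTAATTATATATTAT", "TATTATATTATTAATATTAATTATA", "T", "C"
    )
    scan_variants([record], catalog)
    assert record.verdict == VERDICT_NOT_TARGETABLE
    assert record.best_guide is None


def test_scan_skips_short_flanks_with_a_warning_not_an_abort(catalog):
    short = VariantRecord("short", "ACGTACGT", "ACGTACGT", "T", "C")
    good = _clean_minus18_variant()
    scan_variants([short, good], catalog)
    assert short.verdict is None and short.warnings
    assert good.verdict == VERDICT_PRECISE


def test_variant_tsv_round_trip(tmp_path, catalog):
    records = [_clean_minus18_variant(), _tcac_minus15_variant()]
    scan_variants(records, catalog)
    out = io.StringIO()
    variants_to_tsv(records, out)
    path = tmp_path / "variants.tsv"
    path.write_text(out.getvalue())
    back = variants_from_tsv(path)
    assert [v.identifier for v in back] == ["psen1_like", "tyr_like"]
    assert back[0].flank5 == records[0].flank5
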