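import pytest

from isoanchor.errors import ParseError, ValidationError
from isoanchor.markers import (
    ABSENT_FROM_ANCHOR,
    SYSTEMATIC_ABSENCE,
    MarkerMatrix,
    MarkerProfile,
    MarkerSet,
    aggregate_copy_number,
    derive_anchored_set,
    derive_family_set,
    load_marker_hits,
    prevalence_screen,
    read_marker_set,
    write_marker_set,
)


def _set(n, set_id="base"):
    return MarkerSet(set_id, tuple(f"M{i}" for i in range(n)))


class TestMarkerSet:
    def test_duplicate_ids_rejected(self):
        with pytest.raises(ValidationError):
            MarkerSet("s", ("M1", "M1"))

    def test_marker_also_excluded_rejected(self):
        with pytest.raises(ValidationError):
            MarkerSet("s", ("M1",), excluded=(("M1", "reason"),))

    def test_all_ids_is_markers_plus_excluded(self):
        s = MarkerSet("s", ("M1",), excluded=(("M2", "r"),))
        assert s.all_ids == {"M1", "M2"}

    def test_tsv_roundtrip(self, tmp_path):
        s = MarkerSet("s", ("M1", "M3"), excluded=(("M2", ABSENT_FROM_ANCHOR),))
        write_marker_set(s, tmp_path / "s.tsv")
        back = read_marker_set(tmp_path / "s.tsv")
        assert back.markers == s.markers
        assert back.excluded == s.excluded


class TestMarkerProfile:
    def test_zero_copies_dropped(self):
        p = MarkerProfile("g", {"M1": 1, "M2": 0})
        assert p.present == {"M1"}
        assert p.count("M2") == 0

    def test_negative_copies_rejected(self):
        with pytest.raises(ValidationError):
            MarkerProfile("g", {"M1": -1})


class TestAnchoredSet:
    def test_anchor_absent_markers_excluded_with_reason(self):
        base = _set(5)
        anchor = MarkerProfile("anchor", {"M0": 1, "M1": 1, "M3": 2})
        derived = derive_anchored_set(base, anchor)
        assert derived.markers == ("M0", "M1", "M3")
        assert dict(derived.excluded) == {
            "M2": ABSENT_FROM_ANCHOR,
            "M4": ABSENT_FROM_ANCHOR,
        }
        assert derived.parent_set_id == "base"

    def test_idempotent(self):
        base = _set(5)
        anchor = MarkerProfile("anchor", {"M0": 1, "M1": 1})
        once = derive_anchored_set(base, anchor, set_id="a")
        twice = derive_anchored_set(once, anchor, set_id="a")
        assert twice.markers == once.markers

    def test_no_shared_marker_is_error(self):
        base = _set(3)
        anchor = MarkerProfile("anchor", {"X1": 1})
        with pytest.raises(ValidationError):
            MarkerMatrix.from_profiles([anchor], base)  # X1 outside universe
        with pytest.raises(ValidationError):
            derive_anchored_set(base, MarkerProfile("anchor", {}))


class TestPrevalence:
    def test_strict_threshold(self):
        # M0 in 1 of 10 genomes: prevalence exactly 0.10 is NOT flagged at 0.10
        profiles = [MarkerProfile(f"g{i}", {"M0": 1} if i == 0 else {"M1": 1}) for i in range(10)]
        matrix = MarkerMatrix.from_profiles(profiles, _set(2))
        report = prevalence_screen(matrix, ["M0", "M1"], threshold=0.10)
        assert report.flagged_markers == ()
        report = prevalence_screen(matrix, ["M0", "M1"], threshold=0.11)
        assert report.flagged_markers == ("M0",)

    def test_zero_threshold_flags_nothing(self):
        matrix = MarkerMatrix.from_profiles([MarkerProfile("g", {})], _set(1))
        report = prevalence_screen(matrix, ["M0"], threshold=0.0)
        assert report.flagged_markers == ()

    def test_completeness_weighting(self):
        # 2 of 4 genomes carry M0; at 50% mean completeness that is full prevalence
        profiles = [
            MarkerProfile(f"g{i}", {"M0": 1} if i < 2 else {"M1": 1}) for i in range(4)
        ]
        matrix = MarkerMatrix.from_profiles(profiles, _set(2))
        comp = {f"g{i}": 0.5 for i in range(4)}
        report = prevalence_screen(matrix, ["M0"], completeness=comp)
        assert report.records[0].prevalence == pytest.approx(1.0)

    def test_unknown_marker_rejected(self):
        matrix = MarkerMatrix.from_profiles([MarkerProfile("g", {"M0": 1})], _set(1))
        with pytest.raises(ValidationError):
            prevalence_screen(matrix, ["nope"])


class TestFamilySet:
    def test_screens_all_base_markers(self):
        base = _set(4)
        # M3 absent from every family genome -> systematic
        profiles = [MarkerProfile(f"g{i}", {"M0": 1, "M1": 1, "M2": 1}) for i in range(5)]
        matrix = MarkerMatrix.from_profiles(profiles, base)
        fam = derive_family_set(base, matrix)
        assert fam.markers == ("M0", "M1", "M2")
        assert dict(fam.excluded) == {"M3": SYSTEMATIC_ABSENCE}

    def test_empty_family_matrix_rejected(self):
        with pytest.raises(ValidationError):
            derive_family_set(_set(2), MarkerMatrix.from_profiles([], _set(2)))


class TestHitTable:
    def test_roundtrip_and_duplicate_summing(self, tmp_path):
        path = tmp_path / "hits.tsv"
        path.write_text(
            "genome_id\tmarker_id\tcopies\n"
            "g1\tM0\t1\n"
            "g1\tM0\t1\n"  # duplicate rows are summed
            "g2\tM1\t3\n"
        )
        matrix = load_marker_hits(path, _set(2))
        assert matrix["g1"].count("M0") == 2
        assert matrix["g2"].count("M1") == 3

    def test_parse_error_carries_line_number(self, tmp_path):
        path = tmp_path / "hits.tsv"
        path.write_text("genome_id\tmarker_id\tcopies\ng1\tM0\tnope\n")
        with pytest.raises(ParseError) as err:
            load_marker_hits(path, _set(1))
        assert err.value.line == 2

    def test_bad_header_rejected(self, tmp_path):
        path = tmp_path / "hits.tsv"
        path.write_text("a\tb\tc\ng1\tM0\t1\n")
        with pytest.raises(ParseError):
            load_marker_hits(path, _set(1))

    def test_negative_copies_rejected(self, tmp_path):
        path = tmp_path / "hits.tsv"
        path.write_text("genome_id\tmarker_id\tcopies\ng1\tM0\t-1\n")
        with pytest.raises(ValidationError):
            load_marker_hits(path, _set(1))


def test_aggregate_copy_number_means_with_absent_as_zero():
    matrix = MarkerMatrix.from_profiles(
        [MarkerProfile("g1", {"M0": 2}), MarkerProfile("g2", {"M0": 1, "M1": 1})],
        _set(2),
    )
    frame = aggregate_copy_number(matrix, {"g1": "T", "g2": "T"})
    assert frame.loc["T", "M0"] == pytest.approx(1.5)
    assert frame.loc["T", "M1"] == pytest.approx(0.5)
    with pytest.raises(ValidationError):
        aggregate_copy_number(matrix, {"g1": "T"})
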