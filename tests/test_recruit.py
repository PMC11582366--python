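import logging

import pandas as pd
import pytest

from isoanchor.errors import ValidationError
from isoanchor.recruit import (
    MappingSummary,
    abundance_table,
    aggregate_taxa,
    assign_depth_bin,
    depth_region_summary,
    detection,
    read_mapping_summaries,
    relative_abundance,
    write_mapping_summaries,
)


def _summary(sample="s1", genome="g1", mapped=1000, covered=500, length=1000,
             total=100000, depth=10.0, region="R"):
    return MappingSummary(sample, genome, mapped, covered, length, total, depth, region)


class TestDetection:
    def test_fraction(self):
        assert detection(250, 1000) == 0.25

    def test_covered_beyond_length_rejected(self):
        with pytest.raises(ValidationError):
            detection(1001, 1000)
        with pytest.raises(ValidationError):
            _summary(covered=1001)


class TestRelativeAbundance:
    def test_gated_below_threshold(self):
        s = _summary(covered=249, length=1000)  # detection 0.249
        assert relative_abundance(s) == 0.0

    def test_threshold_is_inclusive(self):
        s = _summary(mapped=500, covered=250, length=1000, total=100000)
        assert relative_abundance(s) == pytest.approx(0.5)

    def test_ungated_when_min_detection_zero(self):
        s = _summary(mapped=500, covered=0, length=1000)
        assert relative_abundance(s, min_detection=0.0) == pytest.approx(0.5)

    def test_coverage_mode(self):
        s = _summary(mapped=500, covered=500, length=1000)
        assert relative_abundance(s, mode="coverage") == pytest.approx(50.0)

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValidationError):
            relative_abundance(_summary(), mode="nope")


class TestAbundanceTable:
    def test_pivot_and_cap(self):
        summaries = [
            _summary(sample="s1", genome="g1", mapped=1000),
            _summary(sample="s1", genome="g2", mapped=2000),
            _summary(sample="s2", genome="g1", mapped=0, covered=0),
        ]
        table = abundance_table(summaries)
        assert table.abundance.loc["s1", "g1"] == pytest.approx(1.0)
        assert table.abundance.loc["s1", "g2"] == pytest.approx(2.0)
        assert table.abundance.loc["s2", "g1"] == 0.0
        assert (table.abundance.sum(axis=1) <= 100.0).all()


def test_aggregate_taxa_additive_consistency():
    summaries = [
        _summary(sample="s1", genome="g1", mapped=1000),
        _summary(sample="s1", genome="g2", mapped=2000),
        _summary(sample="s1", genome="g3", mapped=3000),
    ]
    table = abundance_table(summaries)
    taxonomy = {
        "g1": ("gen1", "fam1", "ord"),
        "g2": ("gen1", "fam1", "ord"),
        "g3": ("gen2", "fam2", "ord"),
    }
    tidy = aggregate_taxa(table, taxonomy)
    by = tidy.set_index(["level", "taxon"])["abundance"]
    assert by.loc[("genus", "gen1")] == pytest.approx(3.0)
    assert by.loc[("family", "fam1")] == pytest.approx(3.0)
    assert by.loc[("family", "fam2")] == pytest.approx(3.0)
    # order = sum of families = sum of genera
    assert by.loc[("order", "ord")] == pytest.approx(6.0)
    with pytest.raises(ValidationError):
        aggregate_taxa(table, {"g1": ("a", "b", "c")})


class TestDepthBins:
    def test_half_open_with_closed_last(self):
        bins = (0, 100, 200, 300)
        assert assign_depth_bin(0, bins) == "[0,100)"
        assert assign_depth_bin(99.9, bins) == "[0,100)"
        assert assign_depth_bin(100, bins) == "[100,200)"
        assert assign_depth_bin(300, bins) == "[200,300]"  # last bin closed
        assert assign_depth_bin(300.1, bins) is None

    def test_summary_excludes_missing_depth_with_warning(self, caplog):
        summaries = [
            _summary(sample="s1", genome="g1", depth=50.0),
            _summary(sample="s2", genome="g1", depth=None),
        ]
        table = abundance_table(summaries)
        tidy = aggregate_taxa(table, {"g1": ("gen", "fam", "ord")})
        meta = pd.DataFrame(
            {"sample_id": ["s1", "s2"], "depth_m": [50.0, None], "region": ["R", "R"]}
        )
        with caplog.at_level(logging.WARNING, logger="isoanchor.recruit"):
            out = depth_region_summary(tidy, meta)
        assert "s2" in caplog.text
        assert set(out["depth_bin"]) == {"[0,100)"}
        assert (out["n"] == 1).all()

    def test_bad_bins_rejected(self):
        with pytest.raises(ValidationError):
            depth_region_summary(
                pd.DataFrame(columns=["sample_id", "level", "taxon", "abundance"]),
                pd.DataFrame(columns=["sample_id", "depth_m"]),
                depth_bins=(100, 100),
            )


def test_mapping_summary_roundtrip(tmp_path):
    summaries = [_summary(), _summary(sample="s2", depth=None, region=None)]
    write_mapping_summaries(summaries, tmp_path / "m.tsv")
    back = read_mapping_summaries(tmp_path / "m.tsv")
    assert back == summaries


def test_mapping_summary_validation():
    with pytest.raises(ValidationError):
        _summary(mapped=11, total=10)
    with pytest.raises(ValidationError):
        _summary(length=0)
    with pytest.raises(ValidationError):
        _summary(mapped=-1)
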