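"""Domain types, invariants and TSV IO for libraries, designs, counts."""

import pytest

from dropout3d import (
    Category,
    Comparison,
    GuideLibrary,
    GuideRecord,
    SampleInfo,
    ScreenDesign,
    read_counts,
    read_guide_library,
    validate_design,
)
from dropout3d.screen import (
    CONTROL_GENE,
    Condition,
    CountsError,
    DesignError,
    LibraryError,
)

SP1 = "ACGTACGTACGTACGTAC"  # 18 nt
SP2 = "TGCATGCATGCATGCAT"  # 17 nt
SP3 = "GGGGCCCCAAAATTTTGC"


def write_lib(tmp_path, rows):
    path = tmp_path / "lib.tsv"
    header = "guide_id\tgene\tspacer\tcategory\n"
    path.write_text(header + "".join("\t".join(r) + "\n" for r in rows))
    return path


class TestGuideRecord:
    def test_valid_17_and_18mers(self):
        GuideRecord("g1", "MAPK1", SP1, Category.TARGETING)
        GuideRecord("g2", "MAPK1", SP2, Category.TARGETING)

    @pytest.mark.parametrize(
        "spacer", ["ACGT", "A" * 19, "ACGUACGUACGUACGUAC", "acgtNcgtacgtacgtac"]
    )
    def test_bad_spacer_rejected(self, spacer):
        with pytest.raises(LibraryError):
            GuideRecord("g1", "MAPK1", spacer, Category.TARGETING)

    def test_spacer_case_normalized(self):
        r = GuideRecord("g1", "MAPK1", SP1.lower(), Category.TARGETING)
        assert r.spacer == SP1

    def test_control_requires_sentinel(self):
        with pytest.raises(LibraryError, match="sentinel"):
            GuideRecord("g1", "MAPK1", SP1, Category.SAFE)
        GuideRecord("g1", CONTROL_GENE, SP1, Category.SAFE)

    def test_targeting_may_not_use_sentinel(self):
        with pytest.raises(LibraryError):
            GuideRecord("g1", CONTROL_GENE, SP1, Category.TARGETING)


class TestGuideLibrary:
    def test_read_two_row_tsv(self, tmp_path):
        lib = read_guide_library(
            write_lib(
                tmp_path,
                [
                    ("g1", "MAPK1", SP1, "targeting"),
                    ("g2", "MAPK1", SP2, "targeting"),
                ],
            )
        )
        assert len(lib) == 2
        assert lib.genes == ["MAPK1"]
        assert lib.guides_for("MAPK1") == ["g1", "g2"]

    def test_duplicate_spacer_reports_both_guides(self, tmp_path):
        path = write_lib(
            tmp_path,
            [("g1", "MAPK1", SP1, "targeting"), ("g2", "ROCK1", SP1, "targeting")],
        )
        with pytest.raises(LibraryError) as err:
            read_guide_library(path)
        assert "g1" in str(err.value) and "g2" in str(err.value)

    def test_duplicate_guide_id_rejected(self, tmp_path):
        path = write_lib(
            tmp_path,
            [("g1", "MAPK1", SP1, "targeting"), ("g1", "MAPK1", SP2, "targeting")],
        )
        with pytest.raises(LibraryError, match="duplicate guide_id"):
            read_guide_library(path)

    def test_bad_category_rejected(self, tmp_path):
        path = write_lib(tmp_path, [("g1", "MAPK1", SP1, "control")])
        with pytest.raises(LibraryError, match="category"):
            read_guide_library(path)

    def test_control_set_is_safe_union_nontargeting(self, toy_library):
        counts = toy_library.category_counts()
        assert len(toy_library.control_ids) == counts["safe"] + counts["non_targeting"]

    def test_roundtrip_preserves_order(self, tmp_path, toy_library):
        path = tmp_path / "lib.tsv"
        toy_library.write_tsv(path)
        again = read_guide_library(path)
        assert again.guide_ids == toy_library.guide_ids
        # byte-identical canonical rewrite
        path2 = tmp_path / "lib2.tsv"
        again.write_tsv(path2)
        assert path.read_bytes() == path2.read_bytes()


class TestDesign:
    def test_duplicate_key_rejected(self):
        s = SampleInfo("a", Condition.TWO_D, 0, 1)
        s2 = SampleInfo("b", Condition.TWO_D, 0, 1)
        with pytest.raises(DesignError, match="duplicate"):
            ScreenDesign([s, s2])

    def test_bad_day_rejected(self):
        with pytest.raises(DesignError):
            SampleInfo("a", Condition.TWO_D, 3, 1)

    def test_comparison_labels(self):
        assert Comparison(Condition.THREE_D, 14).label == "3D_D14_vs_D0"
        assert Comparison.from_label("2D_D7_vs_D0") == Comparison(Condition.TWO_D, 7)

    def test_full_design_has_four_computable_comparisons(self, toy_design):
        report = validate_design(toy_design)
        assert report.n_computable == 4
        assert report.replicate_counts[("2D", 0)] == 2

    def test_missing_3d_d14_leaves_three(self, toy_design):
        pruned = ScreenDesign(
            [s for s in toy_design.samples if not (s.condition is Condition.THREE_D and s.day == 14)]
        )
        report = validate_design(pruned)
        assert report.n_computable == 3
        assert any("3D_D14" in w for w in report.warnings)

    def test_empty_design(self):
        report = validate_design(ScreenDesign([]))
        assert report.n_computable == 0

    def test_sheet_roundtrip(self, tmp_path, toy_design):
        path = tmp_path / "samples.tsv"
        toy_design.write_tsv(path)
        again = ScreenDesign.read_tsv(path)
        assert again.sample_ids == toy_design.sample_ids


class TestCounts:
    def write_counts(self, tmp_path, lib, columns):
        path = tmp_path / "counts.tsv"
        lines = ["guide_id\t" + "\t".join(columns)]
        for i, g in enumerate(lib.guide_ids):
            lines.append(g + "\t" + "\t".join(str(10 + i) for _ in columns))
        path.write_text("\n".join(lines) + "\n")
        return path

    def test_read_aligns_to_library(self, tmp_path, toy_library, toy_design):
        path = self.write_counts(tmp_path, toy_library, ["2D_D0_R1", "2D_D7_R1"])
        cm = read_counts(path, toy_library, toy_design)
        assert cm.frame.shape == (len(toy_library), 2)
        assert cm.guide_ids == toy_library.guide_ids

    def test_unknown_guide_named_in_error(self, tmp_path, toy_library, toy_design):
        path = self.write_counts(tmp_path, toy_library, ["2D_D0_R1"])
        with open(path, "a") as fh:
            fh.write("ROGUE_GUIDE\t5\n")
        with pytest.raises(CountsError, match="ROGUE_GUIDE"):
            read_counts(path, toy_library, toy_design)

    def test_missing_guide_is_error_unless_zero_fill(self, tmp_path, toy_library, toy_design):
        path = self.write_counts(tmp_path, toy_library, ["2D_D0_R1"])
        lines = path.read_text().splitlines()
        path.write_text("\n".join(lines[:-1]) + "\n")  # drop last guide
        with pytest.raises(CountsError, match="missing"):
            read_counts(path, toy_library, toy_design)
        cm = read_counts(path, toy_library, toy_design, zero_fill_missing=True)
        assert cm.frame.loc[toy_library.guide_ids[-1], "2D_D0_R1"] == 0

    def test_float_cell_reported_with_location(self, tmp_path, toy_library, toy_design):
        path = self.write_counts(tmp_path, toy_library, ["2D_D0_R1"])
        text = path.read_text().replace("\t11\n", "\t3.5\n", 1)
        path.write_text(text)
        with pytest.raises(CountsError) as err:
            read_counts(path, toy_library, toy_design)
        msg = str(err.value)
        assert "3.5" in msg and "2D_D0_R1" in msg

    def test_negative_count_rejected(self, tmp_path, toy_library, toy_design):
        path = self.write_counts(tmp_path, toy_library, ["2D_D0_R1"])
        path.write_text(path.read_text().replace("\t10\n", "\t-1\n", 1))
        with pytest.raises(CountsError, match="negative"):
            read_counts(path, toy_library, toy_design)

    def test_sample_absent_from_design_rejected(self, tmp_path, toy_library, toy_design):
        path = self.write_counts(tmp_path, toy_library, ["NOT_A_SAMPLE"])
        with pytest.raises(CountsError, match="NOT_A_SAMPLE"):
            read_counts(path, toy_library, toy_design)

    def test_write_read_roundtrip_byte_identical(self, tmp_path, toy_counts, toy_library, toy_design):
        p1 = tmp_path / "c1.tsv"
        toy_counts.write_tsv(p1)
        again = read_counts(p1, toy_library, toy_design)
        p2 = tmp_path / "c2.tsv"
        again.write_tsv(p2)
        assert p1.read_bytes() == p2.read_bytes()
        assert (again.frame == toy_counts.frame).all().all()
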