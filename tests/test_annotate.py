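"""Classification cascade and family statistics."""

import math
import random

import numpy as np
import pytest

from mirberry.annotate import (
    MatureRef,
    ReferenceSets,
    classify_all,
    category_percentages,
    family_statistics,
    match_with_mismatches,
)
from mirberry.tagspace import UniqueTag


def _brute_force_best(tag, ref, max_mm, max_shift):
    """Independent exhaustive scan over every offset."""
    best = None
    min_overlap = max(1, min(len(tag), len(ref)) - max_shift)
    for shift in range(-max_shift, max_shift + 1):
        pairs = [
            (tag[i], ref[i + shift])
            for i in range(len(tag))
            if 0 <= i + shift < len(ref)
        ]
        if len(pairs) < min_overlap:
            continue
        mm = sum(a != b for a, b in pairs)
        if mm <= max_mm and (best is None or mm < best):
            best = mm
    return best


class TestMismatchMatching:
    def test_identical_sequences_match_perfectly(self):
        assert match_with_mismatches("ACGUACGUACGUACGUACGUA", "ACGUACGUACGUACGUACGUA") == 0

    def test_three_substitutions_exceed_cap(self):
        ref = "ACGUACGUACGUACGUACGUA"
        tag = "UCGUACGAACGUACGUACGUC"
        assert match_with_mismatches(tag, ref, max_mm=2) is None

    def test_shifted_match_found(self):
        ref = "ACGUACGUACGUACGUACGUA"
        assert match_with_mismatches(ref[2:] + "GG", ref, max_mm=2, max_shift=2) is not None

    def test_agrees_with_brute_force_over_offsets(self):
        rng = random.Random(11)
        for _ in range(300):
            ref = "".join(rng.choice("ACGU") for _ in range(21))
            tag = list(ref)
            for _ in range(rng.randint(0, 4)):
                tag[rng.randrange(21)] = rng.choice("ACGU")
            tag = "".join(tag)
            if rng.random() < 0.3:
                tag = tag[rng.randint(0, 2):]
            assert match_with_mismatches(tag, ref, 2, 2) == _brute_force_best(
                tag, ref, 2, 2
            )


def _mini_refs() -> ReferenceSets:
    refs = ReferenceSets()
    refs.cdna = {"g1": "TTTTGGGGCCCCAAAATTTTGGGGCCCCAAAA"}
    refs.matures = [MatureRef("mir-a", "FAMA", "GGGGCCCCAAAAUUUUGGGG")]
    refs.rfam = {"rRNA": {"rrna1": "CACACACACACACACACACACACACA"}}
    return refs


class TestCascade:
    def test_cdna_wins_over_mirbase(self):
        # the tag matches both a cDNA substring and the mature exactly:
        # the cascade order assigns it to cDNA
        refs = _mini_refs()
        tag = UniqueTag("GGGGCCCCAAAAUUUUGGGG", 2)
        assert tag.sequence.replace("U", "T") in refs.cdna["g1"]
        anns, report = classify_all([tag], refs)
        assert anns[0].category == "cDNA"
        assert report["cDNA"] == 1 and report["conserved-miRNA"] == 0

    def test_unmatched_tag_is_unclassified(self):
        anns, _ = classify_all([UniqueTag("AGAGAGAGAGAGAGAGAG", 1)], _mini_refs())
        assert anns[0].category == "unclassified"

    def test_reverse_complement_rfam_hit(self):
        refs = _mini_refs()
        anns, _ = classify_all([UniqueTag("UGUGUGUGUGUGUGUGUG", 1)], refs)
        assert anns[0].category == "rRNA"

    def test_empty_stage_skipped_with_fallthrough(self, caplog):
        refs = _mini_refs()
        refs.cdna = {}
        tag = UniqueTag("GGGGCCCCAAAAUUUUGGGG", 2)
        with caplog.at_level("WARNING"):
            anns, _ = classify_all([tag], refs)
        assert anns[0].category == "conserved-miRNA"
        assert any("cDNA" in rec.message for rec in caplog.records)

    def test_counts_partition_and_match_manifest(self, library, annotations):
        _, manifest = library
        anns, report = annotations
        assert sum(report.values()) == len(anns)
        expected = {}
        for entry in manifest.reads:
            if entry["expected_category"] != "clean":
                continue
            expected.setdefault(entry["expected_tag_class"], 0)
            expected[entry["expected_tag_class"]] += 1
        got_reads = {}
        for ann in anns:
            got_reads[ann.category] = got_reads.get(ann.category, 0) + ann.tag.count
        for category, count in expected.items():
            assert got_reads.get(category, 0) == count, category

    def test_conserved_annotations_have_family_and_low_mismatch(self, annotations):
        anns, _ = annotations
        for ann in anns:
            if ann.category == "conserved-miRNA":
                assert ann.family is not None
                assert ann.mismatches in (0, 1, 2)

    def test_percentages_to_three_decimals(self):
        report = {"cDNA": 1, "unclassified": 2}
        pct = category_percentages(report)
        assert pct == {"cDNA": 33.333, "unclassified": 66.667}


class TestFamilyStatistics:
    def _annotations(self, members_reads):
        anns = []
        i = 0
        for family, (members, reads) in members_reads.items():
            per = reads // members
            for m in range(members):
                count = per + (reads % members if m == 0 else 0)
                tag = UniqueTag("ACGU" * 5 + "AC", count)
                anns.append(
                    type("A", (), {
                        "category": "conserved-miRNA", "family": family, "tag": tag,
                    })()
                )
                i += 1
        return anns

    def test_proportional_families_correlate_perfectly(self):
        anns = self._annotations({"F1": (1, 1), "F2": (2, 2), "F3": (3, 3), "F4": (5, 5)})
        _, r, p = family_statistics(anns)
        assert r == pytest.approx(1.0)
        assert p < 0.01

    def test_anti_ordered_vectors_give_minus_one(self):
        anns = self._annotations({"F1": (1, 9), "F2": (2, 6), "F3": (3, 3)})
        _, r, _ = family_statistics(anns)
        assert r == pytest.approx(-1.0)

    def test_fewer_than_three_families_reports_null(self):
        anns = self._annotations({"F1": (1, 5), "F2": (2, 9)})
        summaries, r, p = family_statistics(anns)
        assert len(summaries) == 2 and r is None and p is None

    def test_matches_closed_form_product_moment(self):
        rng = np.random.default_rng(5)
        members = rng.integers(1, 40, size=29)
        reads = members * 12 + rng.integers(0, 15, size=29)
        anns = self._annotations(
            {f"F{i}": (int(m), int(t)) for i, (m, t) in enumerate(zip(members, reads))}
        )
        summaries, r, p = family_statistics(anns)
        x = np.array([s.members for s in summaries], dtype=float)
        y = np.array([s.reads for s in summaries], dtype=float)
        xc, yc = x - x.mean(), y - y.mean()
        r_closed = float((xc * yc).sum() / math.sqrt((xc**2).sum() * (yc**2).sum()))
        assert r == pytest.approx(r_closed, rel=1e-12)
        # p from the t transform with n - 2 degrees of freedom
        from scipy import stats as sps

        t = r_closed * math.sqrt(27 / (1 - r_closed**2))
        p_closed = 2 * sps.t.sf(abs(t), 27)
        assert p == pytest.approx(p_closed, rel=1e-6)
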