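"""Novel-miRNA rules, EST mapping, species screen and ORF scanning."""

import random

from mirberry.novelminer import (
    EstHit,
    NovelParams,
    candidate_tags,
    cross_species_filter,
    evaluate_rules,
    find_orfs,
    map_to_est,
    mine_novel,
)
from mirberry.tagspace import UniqueTag


class _Ann:
    def __init__(self, seq, count, category="unclassified"):
        self.tag = UniqueTag(seq, count)
        self.category = category


class TestCandidateTags:
    def test_read_cutoff_is_at_least_ten(self):
        anns = [
            _Ann("A" * 20 + "C", 9),
            _Ann("C" * 20 + "A", 10),
            _Ann("G" * 20 + "A", 50, category="cDNA"),
        ]
        selected = candidate_tags(anns)
        assert [t.count for t in selected] == [10]

    def test_empty_unclassified_set(self):
        assert candidate_tags([_Ann("ACGU" * 5, 99, "rRNA")]) == []


class TestMapToEst:
    def test_planted_coordinates_recovered(self, bundle):
        for design in bundle.hairpins:
            hits = map_to_est(design.mature, {design.est_id: design.est})
            assert EstHit(design.est_id, "+", design.mature_pos) in hits

    def test_absent_tag_maps_nowhere(self):
        assert map_to_est("ACGUACGUACGUACGUACGU", {"e": "T" * 100}) == []

    def test_double_occurrence_reported_twice(self):
        tag = "ACGTACGTACGTACGTAC"
        est = "CC" + tag + "GGGG" + tag + "CC"
        hits = [h for h in map_to_est(tag, {"e": est}) if h.strand == "+"]
        assert [h.position for h in hits] == [2, 2 + len(tag) + 4]

    def test_minus_strand_hit_uses_oriented_coordinates(self):
        tag = "AAGGTTCCAAGGTTCCAAGG"
        rc = tag.translate(str.maketrans("ACGT", "TGCA"))[::-1]
        est = "CCCC" + rc + "TTTT"
        (hit,) = map_to_est(tag, {"e": est})
        assert hit.strand == "-"
        oriented = est.translate(str.maketrans("ACGT", "TGCA"))[::-1]
        assert oriented[hit.position : hit.position + len(tag)] == tag


class TestEvaluateRules:
    def test_planted_designs_reproduce_their_flag_vectors(self, bundle):
        # every violator fails exactly its rule; every valid design passes all
        for design in bundle.hairpins:
            cand = evaluate_rules(
                UniqueTag(design.mature, 20),
                EstHit(design.est_id, "+", design.mature_pos),
                design.est,
            )
            assert cand.rules == design.expected_rules, design.name

    def test_mfe_threshold_is_inclusive(self, bundle):
        design = next(h for h in bundle.hairpins if h.rule_target == "all")
        cand = evaluate_rules(
            UniqueTag(design.mature, 20),
            EstHit(design.est_id, "+", design.mature_pos),
            design.est,
        )
        loose = NovelParams(max_mfe=cand.structure.mfe)
        cand2 = evaluate_rules(
            UniqueTag(design.mature, 20),
            EstHit(design.est_id, "+", design.mature_pos),
            design.est,
            loose,
        )
        assert cand2.rules["r3"] is True

    def test_gc_bounds_inclusive(self):
        params = NovelParams()
        assert params.gc_min <= 0.30 and params.gc_max >= 0.70

    def test_relaxing_min_reads_is_monotone(self, annotations, bundle):
        anns, _ = annotations
        strict = {
            c.mature.sequence
            for c in mine_novel(
                anns, bundle.refs.ests, bundle.refs.cross_species,
                NovelParams(min_reads=10),
            )[0]
            if c.accepted
        }
        relaxed = {
            c.mature.sequence
            for c in mine_novel(
                anns, bundle.refs.ests, bundle.refs.cross_species,
                NovelParams(min_reads=5),
            )[0]
            if c.accepted
        }
        assert strict <= relaxed


class TestCrossSpecies:
    def test_planted_tomato_sequence_is_not_unique(self, bundle):
        design = next(h for h in bundle.hairpins if h.in_cross_species)
        assert not cross_species_filter(design.mature, bundle.refs.cross_species)

    def test_absent_sequence_is_unique(self, bundle):
        assert cross_species_filter("ACGU" * 5 + "AG", bundle.refs.cross_species)

    def test_empty_sets_vacuously_unique_with_warning(self, caplog):
        with caplog.at_level("WARNING"):
            assert cross_species_filter("ACGU" * 5, {"sp": {}})
        assert any("vacuous" in rec.message for rec in caplog.records)


def _orf_oracle(rna, min_aa, max_aa):
    """Quadratic scan of every AUG..stop span."""
    rna = rna.upper().replace("T", "U")
    stops = {"UAA", "UAG", "UGA"}
    found = []
    for start in range(len(rna) - 2):
        if rna[start : start + 3] != "AUG":
            continue
        pos = start + 3
        while pos + 3 <= len(rna):
            if rna[pos : pos + 3] in stops:
                aa = (pos - start) // 3
                if aa >= min_aa and (max_aa is None or aa <= max_aa):
                    found.append((start % 3, start, pos + 3, aa))
                break
            pos += 3
    return found


class TestFindOrfs:
    def test_minimal_orf(self):
        orfs = find_orfs("AUGUAA", min_aa=1)
        assert len(orfs) == 1
        assert (orfs[0].start, orfs[0].end, orfs[0].peptide_length) == (0, 6, 1)

    def test_no_start_codon_no_orfs(self):
        assert find_orfs("CCCUUUCCCUUUCCC") == []

    def test_unterminated_orf_not_reported(self):
        assert find_orfs("AUGCCCCCC", min_aa=1) == []

    def test_matches_quadratic_oracle_on_random_sequences(self):
        rng = random.Random(17)
        for _ in range(60):
            seq = "".join(rng.choice("ACGU") for _ in range(rng.randint(9, 120)))
            got = [(o.frame, o.start, o.end, o.peptide_length) for o in find_orfs(seq, 1)]
            assert got == _orf_oracle(seq, 1, None)

    def test_mipep_band_applied(self, bundle, annotations):
        anns, _ = annotations
        _, orf_map = mine_novel(anns, bundle.refs.ests, bundle.refs.cross_species)
        assert orf_map  # accepted candidates exist
        for orfs in orf_map.values():
            for o in orfs:
                assert 4 <= o.peptide_length <= 75


class TestMineNovel:
    def test_all_valid_planted_hairpins_accepted(self, annotations, bundle):
        anns, _ = annotations
        candidates, _ = mine_novel(anns, bundle.refs.ests, bundle.refs.cross_species)
        by_mature = {c.mature.sequence: c for c in candidates}
        for design in bundle.hairpins:
            if design.rule_target == "all":
                assert by_mature[design.mature].accepted, design.name

    def test_single_rule_violators_rejected_with_that_rule(self, annotations, bundle):
        anns, _ = annotations
        candidates, _ = mine_novel(anns, bundle.refs.ests, bundle.refs.cross_species)
        by_mature = {c.mature.sequence: c for c in candidates}
        for design in bundle.hairpins:
            if not design.rule_target.startswith("r"):
                continue
            if design.rule_target in ("r1", "r2"):
                # length-filtered reads never reach the tag space
                assert design.mature not in by_mature
                continue
            cand = by_mature[design.mature]
            assert not cand.accepted
            failed = [r for r, ok in cand.rules.items() if not ok]
            assert failed == [design.rule_target.split("_")[0]], design.name

    def test_cross_species_hit_excluded(self, annotations, bundle):
        anns, _ = annotations
        candidates, _ = mine_novel(anns, bundle.refs.ests, bundle.refs.cross_species)
        design = next(h for h in bundle.hairpins if h.in_cross_species)
        cand = next(c for c in candidates if c.mature.sequence == design.mature)
        assert cand.rules_pass and not cand.cross_species_unique and not cand.accepted

    def test_low_count_design_never_becomes_candidate(self, annotations, bundle):
        anns, _ = annotations
        candidates, _ = mine_novel(anns, bundle.refs.ests, bundle.refs.cross_species)
        design = next(h for h in bundle.hairpins if h.rule_target == "low_count")
        assert design.mature not in {c.mature.sequence for c in candidates}
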