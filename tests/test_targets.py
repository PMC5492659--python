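"""Target-site scoring and the transcriptome scan vs brute-force rescoring."""

import random

import pytest

from mirberry.targets import (
    TargetParams,
    expectation_score,
    pair_type,
    predict_targets,
    regulatory_mode,
    seed_is_perfect,
)

_RC = str.maketrans("ACGU", "UGCA")


def _rc(seq):
    return seq.translate(_RC)[::-1]


def _mutate_site(site, mirna, pos_1based, kind):
    """Plant a wobble or mismatch opposite the given miRNA position."""
    idx = len(site) - pos_1based
    base = mirna[pos_1based - 1]
    if kind == "wobble":
        repl = {"G": "U", "U": "G"}[base]
    else:
        repl = {"A": "C", "C": "A", "G": "A", "U": "C"}[base]
    return site[:idx] + repl + site[idx + 1:]


MIRNA = "UGACCUAGGCUAAGCUCAAGC"  # 21 nt


class TestExpectationScore:
    def test_perfect_complement_scores_zero(self):
        assert expectation_score(MIRNA, _rc(MIRNA)) == 0.0

    def test_single_wobble_outside_seed(self):
        site = _mutate_site(_rc(MIRNA), MIRNA, 14, "wobble")
        assert expectation_score(MIRNA, site) == pytest.approx(0.5)

    def test_seed_penalties_doubled(self):
        site = _mutate_site(_rc(MIRNA), MIRNA, 5, "mismatch")
        assert expectation_score(MIRNA, site) == pytest.approx(2.0)

    def test_matches_positionwise_recount(self):
        rng = random.Random(13)
        for _ in range(200):
            mirna = "".join(rng.choice("ACGU") for _ in range(20))
            site = "".join(rng.choice("ACGU") for _ in range(20))
            total = 0.0
            for p in range(1, 21):
                kind = pair_type(mirna[p - 1], site[20 - p])
                pen = {"match": 0.0, "wobble": 0.5, "mismatch": 1.0}[kind]
                total += pen * (2 if 2 <= p <= 8 else 1)
            assert expectation_score(mirna, site) == pytest.approx(total)


class TestSeedRule:
    def test_full_complement_passes(self):
        assert seed_is_perfect(MIRNA, _rc(MIRNA))

    def test_mismatch_at_position_5_fails(self):
        assert not seed_is_perfect(MIRNA, _mutate_site(_rc(MIRNA), MIRNA, 5, "mismatch"))

    def test_position_1_is_outside_the_seed(self):
        assert seed_is_perfect(MIRNA, _mutate_site(_rc(MIRNA), MIRNA, 1, "mismatch"))

    def test_wobble_in_seed_fails_by_default(self):
        site = _mutate_site(_rc(MIRNA), MIRNA, 6, "wobble")
        assert not seed_is_perfect(MIRNA, site)
        assert seed_is_perfect(MIRNA, site, allow_wobble=True)


class TestRegulatoryMode:
    def test_perfect_duplex_means_cleavage(self):
        assert regulatory_mode(MIRNA, _rc(MIRNA)) == "cleavage"

    def test_mismatch_at_position_10_means_repression(self):
        site = _mutate_site(_rc(MIRNA), MIRNA, 10, "mismatch")
        assert regulatory_mode(MIRNA, site) == "translational-repression"

    def test_wobble_at_position_11_is_not_a_match(self):
        site = _mutate_site(_rc(MIRNA), MIRNA, 11, "wobble")
        assert regulatory_mode(MIRNA, site) == "translational-repression"


def _brute_force_hits(mirnas, transcripts, params):
    """Independent all-window rescoring with plain loops."""
    hits = []
    for mid in sorted(mirnas):
        mirna = mirnas[mid].replace("T", "U")
        m = min(params.scoring_length, len(mirna))
        for tid in sorted(transcripts):
            tx = transcripts[tid].upper().replace("T", "U")
            for i in range(len(tx) - m + 1):
                site = tx[i : i + m]
                ok_seed = all(
                    pair_type(mirna[p - 1], site[m - p]) == "match"
                    for p in range(2, 9)
                )
                if not ok_seed:
                    continue
                e = expectation_score(mirna, site)
                if e > params.max_expectation:
                    continue
                mode = (
                    "cleavage"
                    if all(
                        pair_type(mirna[p - 1], site[m - p]) == "match"
                        for p in range(9, 12)
                    )
                    else "translational-repression"
                )
                hits.append((mid, tid, i, i + m, e, mode))
    return sorted(hits, key=lambda h: (h[4], h[0], h[1], h[2]))


class TestPredictTargets:
    def test_exact_reverse_complement_is_a_perfect_cleavage_hit(self):
        mirna = MIRNA
        tx = "CCCAAA" + _rc(mirna[:20]).replace("U", "T") + "GGGTTT"
        hits = predict_targets({"m1": mirna}, {"t1": tx})
        assert len(hits) == 1
        h = hits[0]
        assert (h.start, h.end, h.expectation, h.mode) == (6, 26, 0.0, "cleavage")

    def test_seed_violation_blocks_even_good_scores(self):
        site = _mutate_site(_rc(MIRNA[:20]), MIRNA, 6, "wobble")
        tx = ("AAA" + site + "AAA").replace("U", "T")
        assert predict_targets({"m1": MIRNA}, {"t1": tx}) == []

    def test_empty_transcriptome_warns(self, caplog):
        with caplog.at_level("WARNING"):
            assert predict_targets({"m1": MIRNA}, {}) == []
        assert any("empty" in rec.message for rec in caplog.records)

    def test_raising_expectation_cap_only_adds_hits(self, bundle):
        mirnas = {m.identifier: m.sequence for m in bundle.refs.matures[:6]}
        strict = predict_targets(mirnas, bundle.refs.cdna, TargetParams(max_expectation=1.0))
        loose = predict_targets(mirnas, bundle.refs.cdna, TargetParams(max_expectation=3.0))
        assert set(map(tuple, ((h.mirna_id, h.transcript_id, h.start) for h in strict))) <= set(
            map(tuple, ((h.mirna_id, h.transcript_id, h.start) for h in loose))
        )

    def test_planted_sites_recovered_and_scan_equals_brute_force(self, bundle):
        mirnas = {m.identifier: m.sequence for m in bundle.refs.matures}
        params = TargetParams()
        hits = predict_targets(mirnas, bundle.refs.cdna, params)
        got = [
            (h.mirna_id, h.transcript_id, h.start, h.end, h.expectation, h.mode)
            for h in hits
        ]
        assert got == _brute_force_hits(mirnas, bundle.refs.cdna, params)
        planted = {
            (s.mirna_id, s.gene_id, s.start, s.end, s.expectation, s.mode)
            for s in bundle.target_sites
        }
        assert planted <= set(got)

    def test_upe_cap_filters_strongly_structured_sites(self):
        # the site pairs with its own reverse complement downstream, so
        # opening it forfeits the whole stem energy
        mirna = MIRNA
        site = _rc(mirna[:20])
        tx = (site + "AAAA" + mirna[:20]).replace("U", "T")
        open_hits = predict_targets({"m": mirna}, {"t": tx}, TargetParams())
        capped = predict_targets(
            {"m": mirna}, {"t": tx}, TargetParams(upe_enabled=True, upe_cap=0.1)
        )
        assert any(h.start == 0 for h in open_hits)
        assert all(h.start != 0 for h in capped)
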