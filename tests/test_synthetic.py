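"""Synthetic library generator: configs, determinism, manifests, designs."""

import filecmp

import numpy as np
import pytest

from mirberry.annotate import match_with_mismatches
from mirberry.fold import duplex_metrics, fold_mfe
from mirberry.synthetic_data import (
    CLASS_NAMES,
    ConfigError,
    GenerationError,
    LibraryConfig,
    TruthManifest,
    generate_library,
    make_fixture_references,
    make_hairpin,
)


class TestLibraryConfig:
    def test_defaults_validate(self):
        LibraryConfig().validate()

    def test_fractions_must_sum_to_one(self):
        cfg = LibraryConfig()
        cfg.fractions["conserved"] += 0.01
        with pytest.raises(ConfigError, match="sum to 1"):
            cfg.validate()

    def test_profile_lengths_bounded(self):
        cfg = LibraryConfig()
        cfg.length_profile = {40: 1.0}
        with pytest.raises(ConfigError, match="15-35"):
            cfg.validate()

    def test_missing_class_rejected(self):
        cfg = LibraryConfig()
        del cfg.fractions["polya"]
        with pytest.raises(ConfigError):
            cfg.validate()

    def test_empty_reference_with_nonzero_fraction(self, bundle, tmp_path):
        import copy

        broken = copy.deepcopy(bundle)
        broken.refs.rfam["rRNA"] = {}
        with pytest.raises(ConfigError, match="rrna"):
            generate_library(LibraryConfig(n_reads=10), broken, tmp_path / "x.fastq")


class TestGenerateLibrary:
    def test_zero_reads_gives_empty_outputs(self, bundle, tmp_path):
        manifest = generate_library(
            LibraryConfig(n_reads=0), bundle, tmp_path / "lib.fastq"
        )
        assert (tmp_path / "lib.fastq").read_text() == ""
        assert manifest.reads == []

    def test_same_seed_is_byte_identical(self, bundle, tmp_path):
        cfg = LibraryConfig(n_reads=1000, seed=7)
        generate_library(cfg, bundle, tmp_path / "a.fastq", tmp_path / "a.jsonl")
        generate_library(cfg, bundle, tmp_path / "b.fastq", tmp_path / "b.jsonl")
        assert filecmp.cmp(tmp_path / "a.fastq", tmp_path / "b.fastq", shallow=False)
        assert filecmp.cmp(tmp_path / "a.jsonl", tmp_path / "b.jsonl", shallow=False)

    def test_manifest_covers_every_read(self, library):
        fastq, manifest = library
        read_ids = [
            line[1:].strip()
            for i, line in enumerate(fastq.read_text().splitlines())
            if i % 4 == 0
        ]
        assert read_ids == [e["read_id"] for e in manifest.reads]

    def test_every_hairpin_records_rule_status(self, library):
        _, manifest = library
        assert manifest.hairpins
        for entry in manifest.hairpins:
            assert entry["expected_rules"]

    def test_class_counts_near_configured_fractions(self, library):
        _, manifest = library
        counts = manifest.class_counts()
        n = sum(counts.values())
        cfg = LibraryConfig()
        for cls in CLASS_NAMES:
            p = cfg.fractions[cls]
            se = (n * p * (1 - p)) ** 0.5
            assert abs(counts.get(cls, 0) - n * p) < 4.5 * se, cls

    def test_phred64_quality_characters(self, library):
        fastq, _ = library
        lines = fastq.read_text().splitlines()
        for qual in lines[3::4][:200]:
            assert all(ord(c) >= 64 for c in qual)

    def test_manifest_roundtrip(self, library, tmp_path):
        _, manifest = library
        manifest.save(tmp_path / "m.jsonl")
        loaded = TruthManifest.load(tmp_path / "m.jsonl")
        assert loaded.reads == manifest.reads
        assert loaded.hairpins == manifest.hairpins


class TestMakeHairpin:
    def test_perfect_complement_pairs_every_mature_base(self):
        rng = np.random.default_rng(0)
        res = make_hairpin("ACGUACGUACGUACGUACGUA", rng)
        structure = fold_mfe(res.precursor)
        d = duplex_metrics(structure, res.mature_offset, res.mature_offset + 21)
        assert d.paired_fraction == 1.0
        assert (d.max_bulge, d.max_adjacent_mismatches) == (0, 0)

    def test_requested_bulge_realized(self):
        rng = np.random.default_rng(1)
        res = make_hairpin("ACGUACGUACGUACGUACGUA", rng, bulge=(8 + 9, 5))
        structure = fold_mfe(res.precursor)
        d = duplex_metrics(structure, res.mature_offset, res.mature_offset + 21)
        assert d.max_bulge == 5  # violates the 4-nt bulge rule

    def test_requested_mismatch_run_realized(self):
        rng = np.random.default_rng(2)
        res = make_hairpin(
            "ACGUACGUACGUACGUACGUA", rng, mismatch_runs=[(8 + 9, 4)]
        )
        structure = fold_mfe(res.precursor)
        d = duplex_metrics(structure, res.mature_offset, res.mature_offset + 21)
        assert d.max_adjacent_mismatches == 4

    def test_unsupported_mature_length_raises(self):
        rng = np.random.default_rng(3)
        with pytest.raises(GenerationError, match="15-35"):
            make_hairpin("ACGU", rng)


class TestFixtureReferences:
    def test_deterministic_in_seed(self):
        a = make_fixture_references(5)
        b = make_fixture_references(5)
        assert a.refs.cdna == b.refs.cdna
        assert [m.sequence for m in a.refs.matures] == [
            m.sequence for m in b.refs.matures
        ]
        assert [h.est for h in a.hairpins] == [h.est for h in b.hairpins]

    def test_at_least_five_families_one_large(self, bundle):
        families = {}
        for m in bundle.refs.matures:
            families[m.family] = families.get(m.family, 0) + 1
        assert len(families) >= 5
        assert max(families.values()) >= 10

    def test_every_est_long_enough_for_a_hairpin(self, bundle):
        assert all(len(seq) >= 60 for seq in bundle.refs.ests.values())

    def test_go_table_covers_every_gene(self, bundle):
        covered = {gene for gene, _ in bundle.refs.go_table}
        assert covered == set(bundle.refs.cdna)

    def test_matures_distinct_under_the_matching_rule(self, bundle):
        seqs = [m.sequence for m in bundle.refs.matures]
        for i, a in enumerate(seqs):
            for b in seqs[i + 1:]:
                assert match_with_mismatches(a, b, max_mm=2, max_shift=2) is None

    def test_reference_sets_nonempty(self, bundle):
        refs = bundle.refs
        assert refs.cdna and refs.matures and refs.ests
        assert all(refs.rfam.values())
        assert all(refs.cross_species.values())
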