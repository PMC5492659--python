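"""Shared fixtures: one reference bundle and one mid-size synthetic
library are built once per session and reused across test modules."""

from __future__ import annotations

import pytest

from mirberry import annotate, preprocess, tagspace
from mirberry.synthetic_data import (
    LibraryConfig,
    generate_library,
    make_fixture_references,
)

FIXTURE_SEED = 3
LIBRARY_SEED = 7
LIBRARY_READS = 5_000


@pytest.fixture(scope="session")
def bundle():
    return make_fixture_references(FIXTURE_SEED)


@pytest.fixture(scope="session")
def library(bundle, tmp_path_factory):
    """(fastq path, truth manifest) for a 5000-read library."""
    root = tmp_path_factory.mktemp("library")
    fastq = root / "library.fastq"
    manifest = generate_library(
        LibraryConfig(n_reads=LIBRARY_READS, seed=LIBRARY_SEED), bundle, fastq,
        root / "truth.jsonl",
    )
    return fastq, manifest


@pytest.fixture(scope="session")
def cleaned(library):
    fastq, _ = library
    return preprocess.run_preprocess(fastq)


@pytest.fixture(scope="session")
def tags(cleaned):
    clean_reads, _ = cleaned
    return tagspace.collapse(seq for _, seq in clean_reads)


@pytest.fixture(scope="session")
def annotations(tags, bundle):
    return annotate.classify_all(tags, bundle.refs)
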