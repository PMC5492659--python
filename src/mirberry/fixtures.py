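"""Golden-run verification.

A small pinned-seed synthetic run (fixtures + 400-read library + full
pipeline) is summarized in ``data/golden_summary.json``.  ``verify_golden``
regenerates everything from the pinned seed in a temporary directory and
diffs the fresh summary against the shipped one, key by key.  Because all
fixtures are derived deterministically from the seed and every float in
the summary uses fixed formatting, the comparison is exact.
"""

from __future__ import annotations

import json
import tempfile
from importlib import resources
from pathlib import Path

from .io import save_references
from .pipeline import RunConfig, run_all
from .synthetic_data import LibraryConfig, generate_library, make_fixture_references

GOLDEN_SEED = 11
GOLDEN_N_READS = 400
_GOLDEN_RESOURCE = "data/golden_summary.json"


def golden_run(workdir: str | Path) -> dict:
    """Regenerate the pinned golden run and return its summary."""
    workdir = Path(workdir)
    bundle = make_fixture_references(GOLDEN_SEED)
    refs_dir = save_references(bundle.refs, workdir / "refs")
    fastq = workdir / "library.fastq"
    generate_library(
        LibraryConfig(n_reads=GOLDEN_N_READS, seed=GOLDEN_SEED), bundle, fastq
    )
    return run_all(
        RunConfig(
            fastq=str(fastq), refs_dir=str(refs_dir),
            outdir=str(workdir / "run"), force=True,
        )
    )


def _diff(expected, actual, prefix="") -> list[str]:
    diffs: list[str] = []
    if isinstance(expected, dict) and isinstance(actual, dict):
        for key in sorted(set(expected) | set(actual)):
            if key not in expected:
                diffs.append(f"{prefix}{key}: unexpected key")
            elif key not in actual:
                diffs.append(f"{prefix}{key}: missing key")
            else:
                diffs.extend(_diff(expected[key], actual[key], f"{prefix}{key}."))
    elif expected != actual:
        diffs.append(f"{prefix[:-1]}: expected {expected!r}, got {actual!r}")
    return diffs


def verify_golden() -> tuple[bool, list[str]]:
    """(pass, diff lines) for the golden run against the shipped summary."""
    expected = json.loads(
        resources.files("mirberry").joinpath(_GOLDEN_RESOURCE).read_text()
    )
    with tempfile.TemporaryDirectory() as tmp:
        actual = golden_run(tmp)
    diffs = _diff(expected, actual)
    return not diffs, diffs


def regenerate_golden(target: str | Path | None = None) -> Path:
    """Recompute the golden summary and write it (maintainer utility)."""
    if target is None:
        target = Path(__file__).parent / "data" / "golden_summary.json"
    with tempfile.TemporaryDirectory() as tmp:
        summary = golden_run(tmp)
    Path(target).write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
    return Path(target)
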