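"""Unique-tag collapsing and descriptive statistics.

Clean inserts (DNA alphabet) are converted to RNA (T -> U) and grouped by
exact sequence into unique tags; the tag count records how many reads
carried that sequence, so the counts always sum to the number of clean
reads.  On top of the tag space sit the descriptive summaries a small-RNA
survey reports: the read-length distribution (weighted by reads or by
unique tags), the tag-abundance spectrum (singletons, doubletons, ...),
and nucleotide composition overall, per position, and for the first base
stratified by tag length.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass
from typing import Iterable, Sequence

__all__ = [
    "UniqueTag",
    "collapse",
    "size_distribution",
    "abundance_spectrum",
    "nucleotide_composition",
    "CompositionTables",
]

_RNA_BASES = "ACGU"


@dataclass(frozen=True)
class UniqueTag:
    sequence: str  # RNA alphabet
    count: int

    def __post_init__(self) -> None:
        if self.count < 1:
            raise ValueError("tag count must be >= 1")


def collapse(clean_reads: Iterable[str]) -> list[UniqueTag]:
    """Group identical inserts into unique tags (RNA alphabet).

    Tags are returned sorted by descending count, then sequence, so the
    output order is deterministic.
    """
    counts: Counter[str] = Counter()
    for seq in clean_reads:
        counts[seq.upper().replace("T", "U")] += 1
    return [
        UniqueTag(seq, n)
        for seq, n in sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    ]


def size_distribution(
    tags: Sequence[UniqueTag], weighting: str = "reads"
) -> dict[int, float]:
    """Percentage of tags (or of reads) at each sequence length."""
    if weighting not in ("reads", "unique"):
        raise ValueError("weighting must be 'reads' or 'unique'")
    weights: defaultdict[int, float] = defaultdict(float)
    for tag in tags:
        weights[len(tag.sequence)] += tag.count if weighting == "reads" else 1
    total = sum(weights.values())
    if total == 0:
        return {}
    return {length: weights[length] / total * 100.0 for length in sorted(weights)}


# Default count classes: closed intervals on the tag count.
DEFAULT_COUNT_CLASSES: tuple[tuple[str, int, int | None], ...] = (
    ("1", 1, 1),
    ("2", 2, 2),
    ("3-10", 3, 10),
    ("11-100", 11, 100),
    ("101-1000", 101, 1000),
    ("1001-10000", 1001, 10000),
    (">10000", 10001, None),
)


def abundance_spectrum(
    tags: Sequence[UniqueTag],
    classes: Sequence[tuple[str, int, int | None]] = DEFAULT_COUNT_CLASSES,
) -> dict[str, tuple[int, float]]:
    """Number and percentage of unique tags per count class."""
    total = len(tags)
    out: dict[str, tuple[int, float]] = {}
    for label, lo, hi in classes:
        n = sum(1 for t in tags if t.count >= lo and (hi is None or t.count <= hi))
        out[label] = (n, n / total * 100.0 if total else 0.0)
    return out


@dataclass(frozen=True)
class CompositionTables:
    """Nucleotide composition summaries (percentages).

    ``positional[p][base]`` is normalised over the sequences of length
    > p only (0-based position), since shorter sequences have no base
    there; ``first_base_by_length[L][base]`` is over sequences of length L.
    """

    overall: dict[str, float]
    positional: list[dict[str, float]]
    first_base_by_length: dict[int, dict[str, float]]


def nucleotide_composition(sequences: Iterable[str]) -> CompositionTables:
    seqs = [s.upper().replace("T", "U") for s in sequences]
    for s in seqs:
        bad = set(s) - set(_RNA_BASES)
        if bad:
            raise ValueError(f"non-ACGU character(s) {sorted(bad)} in {s!r}")
    overall: Counter[str] = Counter()
    for s in seqs:
        overall.update(s)
    total = sum(overall.values())
    overall_pct = {
        b: (overall[b] / total * 100.0 if total else 0.0) for b in _RNA_BASES
    }
    max_len = max((len(s) for s in seqs), default=0)
    positional: list[dict[str, float]] = []
    for p in range(max_len):
        col = Counter(s[p] for s in seqs if len(s) > p)
        denom = sum(col.values())
        positional.append({b: col[b] / denom * 100.0 for b in _RNA_BASES})
    by_len: dict[int, dict[str, float]] = {}
    for length in sorted({len(s) for s in seqs}):
        col = Counter(s[0] for s in seqs if len(s) == length and s)
        denom = sum(col.values())
        if denom:
            by_len[length] = {b: col[b] / denom * 100.0 for b in _RNA_BASES}
    return CompositionTables(overall_pct, positional, by_len)
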