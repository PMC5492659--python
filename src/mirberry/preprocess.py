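"""Raw-read cleaning for small RNA libraries.

Input FASTQ is Phred+64 encoded (Q = ASCII code - 64).  Reads pass, in
order, through: per-base quality filtering (any base with Q below 10 fails
the read), 3' adapter location and trimming, 5' adapter-contaminant
removal, insert length bounds (18-30 nt), and a poly-A filter (insert at
least 80% adenine).  Every read lands in exactly one accounting category,
so the category counts partition the raw total.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields

from Bio.SeqIO.QualityIO import FastqGeneralIterator

ADAPTER_3P = "TCGTATGCCGTCTTCTGCTTG"
ADAPTER_5P = "GTTCAGAGTTCTACAGTCCGACGATC"


class FastqEncodingError(ValueError):
    """Quality characters below ASCII 64 (likely Phred+33 input)."""


class FastqParseError(ValueError):
    pass


@dataclass(frozen=True)
class RawRead:
    identifier: str
    sequence: str
    quality: str

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.quality):
            raise FastqParseError(
                f"{self.identifier}: sequence and quality lengths differ"
            )


@dataclass
class PreprocessParams:
    adapter3: str = ADAPTER_3P
    adapter5: str = ADAPTER_5P
    q_threshold: int = 10
    low_quality_mode: str = "any_base"  # or "mean"
    adapter_anchor: int = 8
    adapter_max_mismatches: int = 1
    min_len: int = 18
    max_len: int = 30
    polya_fraction: float = 0.8
    phred_offset: int = 64


# Table-style category labels, in filter order.
CATEGORY_LABELS = {
    "raw": "Total raw reads",
    "low_quality": "Low quality reads",
    "high_quality": "High quality reads",
    "adapter3_null": "3' adapter null",
    "insert_null": "Insert null",
    "contaminant5": "5' adapter contaminants",
    "too_short": "Smaller than 18 nt",
    "too_long": "Larger than 30 nt",
    "polya": "Poly A",
    "clean": "Clean reads",
}

REMOVAL_CATEGORIES = (
    "adapter3_null",
    "insert_null",
    "contaminant5",
    "too_short",
    "too_long",
    "polya",
)


@dataclass
class AccountingReport:
    """Read accounting with percentages of the raw total (3 decimals)."""

    raw: int = 0
    low_quality: int = 0
    adapter3_null: int = 0
    insert_null: int = 0
    contaminant5: int = 0
    too_short: int = 0
    too_long: int = 0
    polya: int = 0

    @property
    def high_quality(self) -> int:
        return self.raw - self.low_quality

    @property
    def clean(self) -> int:
        return self.high_quality - sum(getattr(self, c) for c in REMOVAL_CATEGORIES)

    def percentage(self, count: int) -> float:
        if self.raw == 0:
            return 0.0
        return round(count / self.raw * 100.0, 3)

    def counts(self) -> dict[str, int]:
        out = {"raw": self.raw, "low_quality": self.low_quality}
        out["high_quality"] = self.high_quality
        for c in REMOVAL_CATEGORIES:
            out[c] = getattr(self, c)
        out["clean"] = self.clean
        return out

    def as_rows(self) -> list[tuple[str, int, float]]:
        """(label, count, percent) rows in the canonical table order."""
        rows = []
        for key, count in self.counts().items():
            pct = self.percentage(count) if key != "raw" else None
            rows.append((CATEGORY_LABELS[key], count, pct))
        return rows

    @classmethod
    def from_counts(cls, **counts: int) -> "AccountingReport":
        valid = {f.name for f in fields(cls)}
        unknown = set(counts) - valid
        if unknown:
            raise ValueError(f"unknown categories: {sorted(unknown)}")
        return cls(**counts)


def phred64_quality(ch: str, offset: int = 64) -> int:
    """Quality score of one FASTQ character: Q = ASCII code - offset."""
    code = ord(ch)
    if code < offset:
        raise FastqEncodingError(
            f"quality character {ch!r} (ASCII {code}) below offset {offset}; "
            "input may be Phred+33 (use phred_offset=33)"
        )
    return code - offset


def is_low_quality(read: RawRead, q_threshold: int = 10, mode: str = "any_base",
                   offset: int = 64) -> bool:
    """True if the read fails the quality filter.

    ``any_base``: any single base with Q strictly below the threshold fails
    the read.  ``mean``: the mean Q over all bases must reach the threshold.
    """
    scores = [phred64_quality(c, offset) for c in read.quality]
    if not scores:
        return False
    if mode == "any_base":
        return min(scores) < q_threshold
    if mode == "mean":
        return sum(scores) / len(scores) < q_threshold
    raise ValueError(f"unknown low-quality mode {mode!r}")


def _anchored_match(window: str, anchor: str, max_mm: int) -> bool:
    if len(window) < len(anchor):
        return False
    mm = 0
    for a, b in zip(window, anchor):
        if a != b:
            mm += 1
            if mm > max_mm:
                return False
    return True


def trim_3prime_adapter(
    sequence: str,
    adapter3: str = ADAPTER_3P,
    anchor: int = 8,
    max_mm: int = 1,
) -> tuple[str | None, str]:
    """Locate the 3' adapter and return ``(insert, category)``.

    The leftmost position where the first ``anchor`` nt of the adapter
    occur with at most ``max_mm`` mismatches marks the insert end.  No
    occurrence -> ``("", "adapter3_null")`` with insert None; occurrence at
    position 0 -> insert None with category ``"insert_null"``.
    """
    if len(adapter3) < anchor:
        raise ValueError("adapter shorter than anchor length")
    head = adapter3[:anchor]
    for pos in range(0, len(sequence) - anchor + 1):
        if _anchored_match(sequence[pos : pos + anchor], head, max_mm):
            if pos == 0:
                return None, "insert_null"
            return sequence[:pos], "pass"
    return None, "adapter3_null"


def remove_5prime_contaminant(
    insert: str,
    adapter5: str = ADAPTER_5P,
    anchor: int = 8,
    max_mm: int = 1,
) -> str:
    """Flag inserts whose 5' end matches a suffix of the 5' adapter.

    Any adapter suffix of length >= ``anchor`` matching the insert start
    with at most ``max_mm`` mismatches marks the insert as a contaminant.
    Returns ``"contaminant5"`` or ``"pass"``.
    """
    for k in range(min(len(adapter5), len(insert)), anchor - 1, -1):
        if _anchored_match(insert[:k], adapter5[-k:], max_mm):
            return "contaminant5"
    return "pass"


def is_polya(insert: str, fraction: float = 0.8) -> bool:
    return bool(insert) and insert.upper().count("A") / len(insert) >= fraction


def categorize_read(read: RawRead, params: PreprocessParams) -> tuple[str, str | None]:
    """Run the full filter cascade on one read.

    Returns ``(category, insert)``; the insert is non-None only for clean
    reads.  Categories are checked in the fixed filter order, so a read
    failing several filters is counted once, at the first.
    """
    if is_low_quality(read, params.q_threshold, params.low_quality_mode,
                      params.phred_offset):
        return "low_quality", None
    insert, cat = trim_3prime_adapter(
        read.sequence, params.adapter3, params.adapter_anchor,
        params.adapter_max_mismatches,
    )
    if cat != "pass":
        return cat, None
    assert insert is not None
    if (
        remove_5prime_contaminant(
            insert, params.adapter5, params.adapter_anchor,
            params.adapter_max_mismatches,
        )
        == "contaminant5"
    ):
        return "contaminant5", None
    if len(insert) < params.min_len:
        return "too_short", None
    if len(insert) > params.max_len:
        return "too_long", None
    if is_polya(insert, params.polya_fraction):
        return "polya", None
    return "clean", insert


def parse_fastq(path, phred_offset: int = 64):
    """Yield RawRead records from a 4-line FASTQ file.

    Quality strings are kept verbatim (the offset is applied when scores
    are needed).  Malformed records raise FastqParseError with the
    approximate line number.
    """
    with open(path) as handle:
        n = 0
        try:
            for title, seq, qual in FastqGeneralIterator(handle):
                n += 1
                yield RawRead(title.split()[0], seq.upper(), qual)
        except ValueError as exc:
            raise FastqParseError(
                f"malformed FASTQ near line {4 * n + 1}: {exc}"
            ) from exc


def run_preprocess(
    fastq_path, params: PreprocessParams | None = None
) -> tuple[list[tuple[str, str]], AccountingReport]:
    """Clean a FASTQ file.

    Returns ``(clean_inserts, report)`` where ``clean_inserts`` is a list of
    ``(read id, insert sequence)``.
    """
    params = params or PreprocessParams()
    report = AccountingReport()
    clean: list[tuple[str, str]] = []
    for read in parse_fastq(fastq_path, params.phred_offset):
        report.raw += 1
        category, insert = categorize_read(read, params)
        if category == "clean":
            clean.append((read.identifier, insert))
        else:
            setattr(report, category, getattr(report, category) + 1)
    return clean, report
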