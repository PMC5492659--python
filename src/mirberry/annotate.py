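"""Unique-tag classification cascade and conserved-family statistics.

Tags are assigned to exactly one category, in a strict order: coding
sequence (exact substring of a cDNA on either strand), conserved miRNA
(ungapped match to a known mature miRNA with at most two mismatches,
allowing a small end shift), the Rfam-style ncRNA classes in the order
rRNA, tRNA, snRNA, snoRNA, other, and finally "unclassified".  The
substring-based matching is a deterministic, auditable stand-in for a
BLASTN search at permissive E-value; at small-RNA lengths the two agree in
practice and the substring rule is exactly reproducible.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from scipy import stats

from .tagspace import UniqueTag

logger = logging.getLogger(__name__)

RFAM_CLASS_ORDER = ("rRNA", "tRNA", "snRNA", "snoRNA", "other")

_DNA_RC = str.maketrans("ACGTN", "TGCAN")

CATEGORY_LABELS = {
    "total": "All unique tags",
    "cDNA": "Map to cDNA",
    "rRNA": "rRNA",
    "tRNA": "tRNA",
    "snoRNA": "snoRNA",
    "snRNA": "snRNA",
    "other": "Others in Rfam",
    "conserved-miRNA": "Match in miRBase",
    "unclassified": "Unclassified",
}


@dataclass(frozen=True)
class MatureRef:
    identifier: str
    family: str
    sequence: str  # RNA alphabet


@dataclass
class ReferenceSets:
    """All reference sequence sets consumed by the cascade."""

    cdna: dict[str, str] = field(default_factory=dict)  # DNA
    matures: list[MatureRef] = field(default_factory=list)
    precursors: dict[str, str] = field(default_factory=dict)  # RNA, optional
    rfam: dict[str, dict[str, str]] = field(default_factory=dict)  # class -> id -> DNA
    ests: dict[str, str] = field(default_factory=dict)  # DNA
    cross_species: dict[str, dict[str, str]] = field(default_factory=dict)
    go_table: list[tuple[str, str]] = field(default_factory=list)  # (gene, GO id)
    go_namespaces: dict[str, str] = field(default_factory=dict)  # GO id -> namespace


@dataclass(frozen=True)
class TagAnnotation:
    tag: UniqueTag
    category: str
    reference_id: str | None = None
    mismatches: int | None = None
    family: str | None = None


@dataclass(frozen=True)
class FamilySummary:
    family: str
    members: int  # unique tags
    reads: int


def match_with_mismatches(
    tag: str, reference: str, max_mm: int = 2, max_shift: int = 2
) -> int | None:
    """Best ungapped mismatch count between a tag and one reference.

    All relative offsets within ``max_shift`` are scanned; for each, the
    mismatch count over the overlap is taken, provided the overlap covers
    at least ``min(len) - max_shift`` positions.  Returns the minimum over
    offsets when it does not exceed ``max_mm``, else None.
    """
    a, b = tag.upper(), reference.upper()
    min_overlap = max(1, min(len(a), len(b)) - max_shift)
    best: int | None = None
    for shift in range(-max_shift, max_shift + 1):
        # shift = offset of tag start relative to reference start
        start_a = max(0, -shift)
        start_b = max(0, shift)
        overlap = min(len(a) - start_a, len(b) - start_b)
        if overlap < min_overlap:
            continue
        mm = 0
        limit = max_mm if best is None else min(max_mm, best - 1)
        for x, y in zip(a[start_a : start_a + overlap], b[start_b : start_b + overlap]):
            if x != y:
                mm += 1
                if mm > limit:
                    break
        else:
            if best is None or mm < best:
                best = mm
    return best


def _rc_dna(seq: str) -> str:
    return seq.translate(_DNA_RC)[::-1]


class _SubstringIndex:
    """Both-strand exact substring lookup over a named sequence set."""

    def __init__(self, refs: Mapping[str, str]):
        self._refs = {k: v.upper().replace("U", "T") for k, v in refs.items()}
        ids = sorted(self._refs)
        self._ids = ids
        self._fwd = "#".join(self._refs[i] for i in ids)
        self._rev = "#".join(_rc_dna(self._refs[i]) for i in ids)

    def __bool__(self) -> bool:
        return bool(self._refs)

    def find(self, tag_dna: str) -> str | None:
        """Id of the first reference containing the tag on either strand."""
        if tag_dna in self._fwd or tag_dna in self._rev:
            for rid in self._ids:
                ref = self._refs[rid]
                if tag_dna in ref or tag_dna in _rc_dna(ref):
                    return rid
        return None


@dataclass
class CascadeParams:
    mirna_max_mm: int = 2
    mirna_max_shift: int = 2


def _best_mature_hit(
    tag_rna: str, matures: Sequence[MatureRef], params: CascadeParams
) -> tuple[MatureRef, int] | None:
    best: tuple[int, str, MatureRef] | None = None
    for ref in matures:
        for candidate in (ref.sequence, ref.sequence.translate(
            str.maketrans("ACGU", "UGCA"))[::-1]):
            mm = match_with_mismatches(
                tag_rna, candidate, params.mirna_max_mm, params.mirna_max_shift
            )
            if mm is not None:
                key = (mm, ref.identifier)
                if best is None or key < (best[0], best[1]):
                    best = (mm, ref.identifier, ref)
    if best is None:
        return None
    return best[2], best[0]


def classify_all(
    tags: Sequence[UniqueTag],
    refs: ReferenceSets,
    params: CascadeParams | None = None,
) -> tuple[list[TagAnnotation], dict[str, int]]:
    """Run the full cascade over a tag collection.

    Returns the per-tag annotations and a category-count report whose
    values partition the tag total.  Empty reference stages are skipped
    with a logged warning (tags simply fall through to the next stage).
    """
    params = params or CascadeParams()
    cdna_index = _SubstringIndex(refs.cdna)
    if not cdna_index:
        logger.warning("cDNA reference set empty; coding-sequence stage skipped")
    if not refs.matures:
        logger.warning("mature miRNA reference set empty; conserved stage skipped")
    rfam_indexes: list[tuple[str, _SubstringIndex]] = []
    for cls in RFAM_CLASS_ORDER:
        entries = refs.rfam.get(cls, {})
        if entries:
            rfam_indexes.append((cls, _SubstringIndex(entries)))
        else:
            logger.warning("Rfam class %s empty; stage skipped", cls)

    annotations: list[TagAnnotation] = []
    report = {cat: 0 for cat in CATEGORY_LABELS if cat != "total"}
    for tag in tags:
        tag_dna = tag.sequence.replace("U", "T")
        ann: TagAnnotation | None = None
        rid = cdna_index.find(tag_dna) if cdna_index else None
        if rid is not None:
            ann = TagAnnotation(tag, "cDNA", rid)
        if ann is None and refs.matures:
            hit = _best_mature_hit(tag.sequence, refs.matures, params)
            if hit is not None:
                ref, mm = hit
                ann = TagAnnotation(tag, "conserved-miRNA", ref.identifier, mm, ref.family)
        if ann is None:
            for cls, index in rfam_indexes:
                rid = index.find(tag_dna)
                if rid is not None:
                    ann = TagAnnotation(tag, cls, rid)
                    break
        if ann is None:
            ann = TagAnnotation(tag, "unclassified")
        annotations.append(ann)
        report[ann.category] += 1
    return annotations, report


def category_percentages(report: Mapping[str, int]) -> dict[str, float]:
    """Per-category percentage of the unique-tag total, to 3 decimals."""
    total = sum(report.values())
    if total == 0:
        return {cat: 0.0 for cat in report}
    return {cat: round(n / total * 100.0, 3) for cat, n in report.items()}


def family_statistics(
    annotations: Sequence[TagAnnotation],
) -> tuple[list[FamilySummary], float | None, float | None]:
    """Conserved-family summaries plus the member-vs-reads Pearson r.

    The correlation (product-moment r, p from the t transform with n - 2
    degrees of freedom) requires at least 3 families; otherwise it is
    reported as None.
    """
    members: defaultdict[str, int] = defaultdict(int)
    reads: defaultdict[str, int] = defaultdict(int)
    for ann in annotations:
        if ann.category == "conserved-miRNA":
            assert ann.family is not None
            members[ann.family] += 1
            reads[ann.family] += ann.tag.count
    summaries = [
        FamilySummary(f, members[f], reads[f]) for f in sorted(members)
    ]
    if len(summaries) < 3:
        return summaries, None, None
    x = [s.members for s in summaries]
    y = [s.reads for s in summaries]
    r, p = stats.pearsonr(x, y)
    return summaries, float(r), float(p)
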