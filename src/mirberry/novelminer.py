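"""Rule-based novel miRNA discovery from unclassified tags.

Unclassified tags backed by at least 10 reads are mapped to EST sequences
by exact substring match; around each hit a precursor window is excised
and folded, and seven rules decide whether the tag is a credible novel
miRNA: mature length within 18-30 nt (rules 1-2), precursor MFE at most
-18 kcal/mol (rule 3), largest duplex bulge at most 4 nt (rule 4), no more
than 3 adjacent mismatches between miRNA and miRNA* (rule 5), mature and
star arising from the same EST (rule 6), and precursor GC content within
30-70%, bounds inclusive (rule 7).  Candidates whose mature also occurs in
the cDNA of other species are discarded as not blueberry-specific.  The
surviving pri-miRNA regions are scanned for short upstream ORFs, the
signature of candidate miRNA-encoded peptides (miPEPs).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .fold import (
    DuplexMetrics,
    FoldMetrics,
    HairpinStructure,
    NoDuplexError,
    fold_metrics,
    fold_mfe,
    duplex_metrics,
)
from .tagspace import UniqueTag

logger = logging.getLogger(__name__)

RULE_NAMES = {
    "r1": "mature length >= 18 nt",
    "r2": "mature length <= 30 nt",
    "r3": "precursor MFE <= -18 kcal/mol",
    "r4": "duplex bulge <= 4 nt",
    "r5": "adjacent mismatches <= 3",
    "r6": "miRNA and miRNA* on the same EST",
    "r7": "precursor GC content 30-70%",
}

_DNA_RC = str.maketrans("ACGTN", "TGCAN")

STOP_CODONS = {"UAA", "UAG", "UGA"}


@dataclass
class NovelParams:
    min_reads: int = 10
    min_len: int = 18
    max_len: int = 30
    max_mfe: float = -18.0
    max_bulge: int = 4
    max_adjacent_mm: int = 3
    gc_min: float = 0.30
    gc_max: float = 0.70
    flank: int = 150  # precursor window: mature +/- flank, clipped to the EST
    whole_est: bool = False
    min_paired_fraction: float = 0.5
    upstream_len: int = 500  # pri-miRNA region scanned for miPEP ORFs
    orf_min_aa: int = 4
    orf_max_aa: int = 75
    fold_engine: str = "bundled"


@dataclass(frozen=True)
class EstHit:
    est_id: str
    strand: str  # '+' or '-'
    position: int  # 0-based start of the mature on the oriented EST


@dataclass
class NovelCandidate:
    mature: UniqueTag
    est_id: str | None = None
    strand: str = "+"
    window_start: int = 0  # 0-based half-open, on the oriented EST
    window_end: int = 0
    mature_offset: int = 0  # mature start within the window
    structure: HairpinStructure | None = None
    star_sequence: str | None = None
    metrics: FoldMetrics | None = None
    duplex: DuplexMetrics | None = None
    rules: dict[str, bool] = field(default_factory=dict)
    cross_species_unique: bool = True
    fold_error: str | None = None

    @property
    def rules_pass(self) -> bool:
        return bool(self.rules) and all(self.rules.values())

    @property
    def accepted(self) -> bool:
        return self.rules_pass and self.cross_species_unique and self.fold_error is None


@dataclass(frozen=True)
class ORFRecord:
    frame: int  # 0, 1, 2 (forward frames only)
    start: int  # 0-based, includes the start codon
    end: int  # half-open, includes the stop codon
    peptide_length: int  # amino acids, stop excluded


def candidate_tags(
    annotations: Sequence, min_reads: int = 10
) -> list[UniqueTag]:
    """Unclassified tags with at least ``min_reads`` supporting reads.

    ``annotations`` are TagAnnotation records; the read-count cutoff is
    applied before EST mapping, mirroring the order of the discovery
    procedure.
    """
    out = [
        ann.tag
        for ann in annotations
        if ann.category == "unclassified" and ann.tag.count >= min_reads
    ]
    out.sort(key=lambda t: (-t.count, t.sequence))
    return out


def map_to_est(tag: str, ests: Mapping[str, str]) -> list[EstHit]:
    """All exact-substring occurrences of a tag in the EST set.

    Both strands are searched; a minus-strand hit is reported with its
    position on the reverse-complemented EST, which is the orientation the
    precursor is then excised in.
    """
    tag_dna = tag.upper().replace("U", "T")
    hits: list[EstHit] = []
    for est_id in sorted(ests):
        for strand in "+-":
            seq = ests[est_id].upper()
            if strand == "-":
                seq = seq.translate(_DNA_RC)[::-1]
            start = 0
            while True:
                pos = seq.find(tag_dna, start)
                if pos < 0:
                    break
                hits.append(EstHit(est_id, strand, pos))
                start = pos + 1
    return hits


def evaluate_rules(
    tag: UniqueTag,
    hit: EstHit,
    est_sequence: str,
    params: NovelParams | None = None,
) -> NovelCandidate:
    """Fold the precursor window around one EST hit and set all 7 rule flags.

    Rules 4 and 5 describe the miRNA/miRNA* duplex; when no duplex exists
    (the mature region is essentially unpaired, or pairs with itself), rule
    6 is the one that fails — the star arm is not on this EST window — and
    rules 4-5 hold vacuously.
    """
    params = params or NovelParams()
    est = est_sequence.upper()
    if hit.strand == "-":
        est = est.translate(_DNA_RC)[::-1]
    m_len = len(tag.sequence)
    if params.whole_est:
        lo, hi = 0, len(est)
    else:
        lo = max(0, hit.position - params.flank)
        hi = min(len(est), hit.position + m_len + params.flank)
    window_rna = est[lo:hi].replace("T", "U")
    cand = NovelCandidate(
        mature=tag,
        est_id=hit.est_id,
        strand=hit.strand,
        window_start=lo,
        window_end=hi,
        mature_offset=hit.position - lo,
    )
    rules = {
        "r1": m_len >= params.min_len,
        "r2": m_len <= params.max_len,
    }
    try:
        structure = fold_mfe(window_rna, engine=params.fold_engine)
    except Exception as exc:  # folding failure: rejected, not dropped
        cand.fold_error = str(exc)
        cand.rules = rules
        logger.warning("folding failed for tag %s: %s", tag.sequence, exc)
        return cand
    cand.structure = structure
    metrics = fold_metrics(structure)
    cand.metrics = metrics
    rules["r3"] = structure.mfe <= params.max_mfe
    rules["r7"] = params.gc_min <= metrics.gc <= params.gc_max
    try:
        duplex = duplex_metrics(
            structure, cand.mature_offset, cand.mature_offset + m_len
        )
        if duplex.paired_fraction < params.min_paired_fraction:
            raise NoDuplexError("mature region mostly unpaired")
    except NoDuplexError:
        rules["r4"] = True
        rules["r5"] = True
        rules["r6"] = False
    else:
        cand.duplex = duplex
        cand.star_sequence = window_rna[duplex.star_start : duplex.star_end]
        rules["r4"] = duplex.max_bulge <= params.max_bulge
        rules["r5"] = duplex.max_adjacent_mismatches <= params.max_adjacent_mm
        rules["r6"] = True  # star coordinates lie inside this EST window
    cand.rules = dict(sorted(rules.items()))
    return cand


def cross_species_filter(
    mature: str, species_sets: Mapping[str, Mapping[str, str]]
) -> bool:
    """True when the mature occurs in none of the other species' cDNA sets.

    Exact-substring search on both strands — the deterministic stand-in
    for a permissive cross-species BLASTN screen.
    """
    if not any(species_sets.values()):
        logger.warning("cross-species sets empty; uniqueness is vacuous")
        return True
    tag_dna = mature.upper().replace("U", "T")
    rc = tag_dna.translate(_DNA_RC)[::-1]
    for species in sorted(species_sets):
        for seq in species_sets[species].values():
            s = seq.upper()
            if tag_dna in s or rc in s:
                return False
    return True


def find_orfs(
    sequence: str, min_aa: int = 2, max_aa: int | None = None
) -> list[ORFRecord]:
    """All AUG-initiated, stop-terminated ORFs in the 3 forward frames.

    Each AUG is paired with the first in-frame stop downstream; the
    peptide length excludes the stop.  Reverse frames are not scanned (the
    pri-miRNA orientation is fixed by the mature hit strand).
    """
    rna = sequence.upper().replace("T", "U")
    orfs: list[ORFRecord] = []
    for start in range(0, len(rna) - 2):
        if rna[start : start + 3] != "AUG":
            continue
        for pos in range(start + 3, len(rna) - 2, 3):
            if rna[pos : pos + 3] in STOP_CODONS:
                aa = (pos - start) // 3
                if aa >= min_aa and (max_aa is None or aa <= max_aa):
                    orfs.append(ORFRecord(start % 3, start, pos + 3, aa))
                break
    orfs.sort(key=lambda o: (o.start, o.end))
    return orfs


def mipep_orfs(
    est_oriented: str,
    mature_position: int,
    params: NovelParams | None = None,
) -> list[ORFRecord]:
    """miPEP candidate ORFs in the pri-miRNA region upstream of the mature.

    Scans up to ``upstream_len`` nt 5' of the mature start and keeps ORFs
    encoding 4-75 aa peptides.
    """
    params = params or NovelParams()
    lo = max(0, mature_position - params.upstream_len)
    region = est_oriented[lo:mature_position]
    orfs = find_orfs(region, params.orf_min_aa, params.orf_max_aa)
    return [
        ORFRecord(o.frame, o.start + lo, o.end + lo, o.peptide_length) for o in orfs
    ]


def mine_novel(
    annotations: Sequence,
    ests: Mapping[str, str],
    species_sets: Mapping[str, Mapping[str, str]],
    params: NovelParams | None = None,
) -> tuple[list[NovelCandidate], dict[str, list[ORFRecord]]]:
    """Full discovery pass: cutoff, EST mapping, rules, species screen, ORFs.

    Every candidate tag with at least one EST hit yields one NovelCandidate
    (the best-scoring hit context: an accepted one if any, otherwise the
    hit passing the most rules).  Returns the candidates and, for accepted
    ones, their upstream miPEP ORFs keyed by mature sequence.
    """
    params = params or NovelParams()
    candidates: list[NovelCandidate] = []
    orf_map: dict[str, list[ORFRecord]] = {}
    for tag in candidate_tags(annotations, params.min_reads):
        hits = map_to_est(tag.sequence, ests)
        if not hits:
            continue
        unique = cross_species_filter(tag.sequence, species_sets)
        best: NovelCandidate | None = None
        for hit in hits:
            cand = evaluate_rules(tag, hit, ests[hit.est_id], params)
            cand.cross_species_unique = unique
            if best is None or sum(cand.rules.values()) > sum(best.rules.values()):
                best = cand
            if cand.rules_pass:
                best = cand
                break
        assert best is not None
        candidates.append(best)
        if best.accepted:
            est = ests[best.est_id].upper()
            if best.strand == "-":
                est = est.translate(_DNA_RC)[::-1]
            pos = best.window_start + best.mature_offset
            orf_map[tag.sequence] = mipep_orfs(est, pos, params)
    return candidates, orf_map
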