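"""Plant-style miRNA target prediction.

Every transcript window of the scoring length (20 nt, or the miRNA length
if shorter) is aligned ungapped and antiparallel against the miRNA and
scored with the classic penalty scheme of the miRU/psRNATarget lineage:
mismatch 1.0, G:U wobble 0.5, gap 2.0, all penalties doubled inside the
seed (miRNA positions 2-8 from the 5' end).  A reported hit must have a
perfect Watson-Crick seed (wobble not accepted there), an expectation
score within the cap (3 by default), and, when accessibility scoring is
enabled, a site-opening energy (UPE) within its cap (25 kcal/mol).
Whether miRNA positions 9-11 are all Watson-Crick paired decides the
regulatory-mode call: cleavage if so, translational repression otherwise.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping

from .fold import unpairing_energy

logger = logging.getLogger(__name__)

__all__ = [
    "TargetParams",
    "TargetHit",
    "pair_type",
    "expectation_score",
    "seed_is_perfect",
    "regulatory_mode",
    "score_site",
    "predict_targets",
]

_WC = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")}
_WOBBLE = {("G", "U"), ("U", "G")}

MISMATCH_PENALTY = 1.0
WOBBLE_PENALTY = 0.5
GAP_PENALTY = 2.0
SEED_START, SEED_END = 2, 8  # 1-based, inclusive, from the miRNA 5' end
MODE_START, MODE_END = 9, 11


@dataclass
class TargetParams:
    max_expectation: float = 3.0
    scoring_length: int = 20
    upe_enabled: bool = False
    upe_cap: float = 25.0
    upe_context: int = 17
    seed_allows_wobble: bool = False


def _to_rna(seq: str) -> str:
    return seq.upper().replace("T", "U")


def pair_type(mirna_base: str, target_base: str) -> str:
    """'match', 'wobble' or 'mismatch' for one antiparallel duplex position."""
    duo = (mirna_base, target_base)
    if duo in _WC:
        return "match"
    if duo in _WOBBLE:
        return "wobble"
    return "mismatch"


def _aligned_pairs(mirna: str, site: str) -> list[tuple[int, str]]:
    """(1-based miRNA position, pair type) for an antiparallel alignment.

    ``site`` is the target window 5'->3'; miRNA position p pairs the
    site base at index ``len(site) - p``.
    """
    m = len(site)
    if len(mirna) < m:
        raise ValueError("miRNA shorter than the aligned site window")
    return [
        (p, pair_type(mirna[p - 1], site[m - p])) for p in range(1, m + 1)
    ]


def expectation_score(mirna: str, site: str) -> float:
    """Penalty sum over the alignment; seed positions count double."""
    score = 0.0
    for p, kind in _aligned_pairs(_to_rna(mirna), _to_rna(site)):
        penalty = {"match": 0.0, "wobble": WOBBLE_PENALTY, "mismatch": MISMATCH_PENALTY}[kind]
        if SEED_START <= p <= SEED_END:
            penalty *= 2.0
        score += penalty
    return score


def seed_is_perfect(mirna: str, site: str, allow_wobble: bool = False) -> bool:
    """True when miRNA positions 2-8 are all paired (Watson-Crick only by
    default)."""
    ok = {"match", "wobble"} if allow_wobble else {"match"}
    return all(
        kind in ok
        for p, kind in _aligned_pairs(_to_rna(mirna), _to_rna(site))
        if SEED_START <= p <= SEED_END
    )


def regulatory_mode(mirna: str, site: str) -> str:
    """'cleavage' when positions 9-11 are all Watson-Crick matched, else
    'translational-repression' (wobble does not count as a match here)."""
    central = [
        kind
        for p, kind in _aligned_pairs(_to_rna(mirna), _to_rna(site))
        if MODE_START <= p <= MODE_END
    ]
    return "cleavage" if all(k == "match" for k in central) else "translational-repression"


@dataclass(frozen=True)
class TargetHit:
    mirna_id: str
    transcript_id: str
    start: int  # 0-based half-open on the transcript
    end: int
    expectation: float
    upe: float | None
    mode: str


def score_site(
    mirna: str, site: str, params: TargetParams | None = None
) -> tuple[float, bool, str]:
    """(expectation, seed ok, mode) for one miRNA/site window."""
    params = params or TargetParams()
    return (
        expectation_score(mirna, site),
        seed_is_perfect(mirna, site, params.seed_allows_wobble),
        regulatory_mode(mirna, site),
    )


def predict_targets(
    mirnas: Mapping[str, str],
    transcripts: Mapping[str, str],
    params: TargetParams | None = None,
) -> list[TargetHit]:
    """Scan every transcript window against every miRNA.

    Returns hits sorted by (expectation, miRNA id, transcript id, start).
    """
    params = params or TargetParams()
    if not transcripts:
        logger.warning("empty transcriptome; no target scan performed")
        return []
    hits: list[TargetHit] = []
    for mirna_id in sorted(mirnas):
        mirna = _to_rna(mirnas[mirna_id])
        m = min(params.scoring_length, len(mirna))
        for tx_id in sorted(transcripts):
            tx = _to_rna(transcripts[tx_id])
            for i in range(0, len(tx) - m + 1):
                site = tx[i : i + m]
                if not seed_is_perfect(mirna, site, params.seed_allows_wobble):
                    continue
                expectation = expectation_score(mirna, site)
                if expectation > params.max_expectation:
                    continue
                upe: float | None = None
                if params.upe_enabled:
                    upe = unpairing_energy(tx, i, i + m, params.upe_context)
                    if upe > params.upe_cap:
                        continue
                hits.append(
                    TargetHit(
                        mirna_id=mirna_id,
                        transcript_id=tx_id,
                        start=i,
                        end=i + m,
                        expectation=expectation,
                        upe=upe,
                        mode=regulatory_mode(mirna, site),
                    )
                )
    hits.sort(key=lambda h: (h.expectation, h.mirna_id, h.transcript_id, h.start))
    return hits
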