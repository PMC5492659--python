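"""Synthetic small-RNA libraries with machine-readable ground truth.

Generates everything the pipeline consumes — a Phred+64 FASTQ library, a
miniature reference collection (cDNA, mature miRNAs with family labels,
ncRNA classes, ESTs, cross-species cDNA, a gene->GO table) — together with
a truth manifest recording what every read was built to be and which rules
every planted hairpin was built to satisfy or violate.  All sampling flows
from one seeded NumPy generator, and each sampling step is simple enough
that re-executing it is the test oracle.

Default library composition mirrors a ripening-fruit small-RNA survey:
read lengths peak at 24 nt with secondary modes at 21 and 23 nt, planted
conserved-miRNA reads carry 0-2 mismatches (plus a 3-mismatch class that
must *not* be recovered), and the contaminant classes (poly-A, low
quality, adapter artifacts) exercise every cleaning filter.

Design of planted hairpins: the mature and an (imperfectly) reverse-
complementary star arm are joined by a short loop and embedded in a
synthetic EST.  Bulges are planted by deleting star-side partners,
mismatch runs by substituting star bases with non-pairing ones, and GC
content is steered through the sampling alphabet.  Every design is
verified by running the actual rule evaluator on the embedded EST and is
re-sampled (bounded retries) until exactly the intended rule flags are
realized.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .annotate import MatureRef, ReferenceSets
from .novelminer import NovelParams, evaluate_rules, EstHit
from .preprocess import (
    ADAPTER_3P,
    ADAPTER_5P,
    _anchored_match,
    remove_5prime_contaminant,
)
from .tagspace import UniqueTag

__all__ = [
    "LibraryConfig",
    "ConfigError",
    "GenerationError",
    "HairpinDesign",
    "PlantedSite",
    "FixtureBundle",
    "TruthManifest",
    "make_hairpin",
    "make_fixture_references",
    "generate_library",
]

_RNA_OF = str.maketrans("ACGT", "ACGU")
_DNA_OF = str.maketrans("ACGU", "ACGT")
_RC_RNA = str.maketrans("ACGU", "UGCA")
_RC_DNA = str.maketrans("ACGT", "TGCA")

# a base guaranteed to pair with neither X nor anything via wobble
_NONPAIR = {"A": "C", "C": "A", "G": "A", "U": "C"}

CLASS_NAMES = (
    "conserved",
    "novel",
    "rrna",
    "trna",
    "cdna",
    "polya",
    "lowqual",
    "adapter",
)

GOOD_Q_CHAR = "h"  # Q40 under Phred+64


class ConfigError(ValueError):
    pass


class GenerationError(RuntimeError):
    pass


DEFAULT_FRACTIONS = {
    "conserved": 0.35,
    "novel": 0.08,
    "rrna": 0.06,
    "trna": 0.04,
    "cdna": 0.30,
    "polya": 0.03,
    "lowqual": 0.07,
    "adapter": 0.07,
}

# Read-length profile: dominant 24 nt mode with secondary 21/23 nt modes.
DEFAULT_LENGTH_PROFILE = {
    18: 0.020, 19: 0.020, 20: 0.040, 21: 0.167, 22: 0.050, 23: 0.136,
    24: 0.516, 25: 0.020, 26: 0.010, 27: 0.008, 28: 0.006, 29: 0.004,
    30: 0.003,
}

DEFAULT_MISMATCH_RATES = {0: 0.70, 1: 0.15, 2: 0.10, 3: 0.05}


@dataclass
class LibraryConfig:
    n_reads: int = 10_000
    seed: int = 0
    fractions: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_FRACTIONS)
    )
    length_profile: dict[int, float] = field(
        default_factory=lambda: dict(DEFAULT_LENGTH_PROFILE)
    )
    mismatch_rates: dict[int, float] = field(
        default_factory=lambda: dict(DEFAULT_MISMATCH_RATES)
    )
    read_length: int = 44

    def validate(self) -> None:
        if self.n_reads < 0:
            raise ConfigError("n_reads must be non-negative")
        if set(self.fractions) != set(CLASS_NAMES):
            raise ConfigError(
                f"fractions must cover exactly the classes {CLASS_NAMES}"
            )
        if abs(sum(self.fractions.values()) - 1.0) > 1e-9:
            raise ConfigError("class fractions must sum to 1")
        if any(f < 0 for f in self.fractions.values()):
            raise ConfigError("class fractions must be non-negative")
        for length in self.length_profile:
            if not 15 <= length <= 35:
                raise ConfigError(f"profile length {length} outside 15-35 nt")
        if abs(sum(self.length_profile.values()) - 1.0) > 1e-9:
            raise ConfigError("length profile must sum to 1")
        if abs(sum(self.mismatch_rates.values()) - 1.0) > 1e-9:
            raise ConfigError("mismatch rates must sum to 1")

    @classmethod
    def from_dict(cls, data: Mapping) -> "LibraryConfig":
        cfg = cls(
            n_reads=int(data.get("n_reads", 10_000)),
            seed=int(data.get("seed", 0)),
            read_length=int(data.get("read_length", 44)),
        )
        if "fractions" in data:
            cfg.fractions = {k: float(v) for k, v in data["fractions"].items()}
        if "length_profile" in data:
            cfg.length_profile = {
                int(k): float(v) for k, v in data["length_profile"].items()
            }
        if "mismatch_rates" in data:
            cfg.mismatch_rates = {
                int(k): float(v) for k, v in data["mismatch_rates"].items()
            }
        cfg.validate()
        return cfg


# ---------------------------------------------------------------------------
# sequence sampling helpers


def _rand_seq(rng: np.random.Generator, length: int, gc: float = 0.5,
              alphabet: str = "ACGT") -> str:
    if alphabet == "ACGT" or alphabet == "ACGU":
        strong = "GC"
        weak = alphabet[0] + alphabet[3]  # A + T/U
        out = []
        for _ in range(length):
            pool = strong if rng.random() < gc else weak
            out.append(pool[rng.integers(0, 2)])
        return "".join(out)
    return "".join(alphabet[i] for i in rng.integers(0, len(alphabet), length))


def _contains_adapter_anchor(seq_dna: str, adapter: str = ADAPTER_3P,
                             anchor: int = 8, max_mm: int = 1) -> bool:
    head = adapter[:anchor]
    return any(
        _anchored_match(seq_dna[i : i + anchor], head, max_mm)
        for i in range(0, len(seq_dna) - anchor + 1)
    )


def _clean_insert_ok(seq_dna: str) -> bool:
    """Insert safe to plant as a clean read: not poly-A-like, no internal
    3'-adapter anchor, and a 5' end that cannot be mistaken for a
    5'-adapter remnant."""
    if seq_dna.count("A") / len(seq_dna) >= 0.75:
        return False
    if _contains_adapter_anchor(seq_dna):
        return False
    return remove_5prime_contaminant(seq_dna) == "pass"


def rna(seq: str) -> str:
    return seq.upper().translate(_RNA_OF)


def dna(seq: str) -> str:
    return seq.upper().translate(_DNA_OF)


# ---------------------------------------------------------------------------
# hairpin construction


@dataclass
class HairpinResult:
    precursor: str  # RNA
    mature_offset: int
    est: str  # DNA, precursor embedded mid-sequence
    mature_pos: int  # mature start on the EST (forward strand)


def make_hairpin(
    mature: str,
    rng: np.random.Generator,
    ext5: int = 8,
    ext3: int = 8,
    loop: str = "CAACUU",
    bulge: tuple[int, int] | None = None,
    mismatch_runs: Sequence[tuple[int, int]] = (),
    gc_target: float = 0.5,
    flank: int = 35,
    verify: bool = True,
    max_tries: int = 40,
) -> HairpinResult:
    """Build a precursor realizing the requested duplex imperfections.

    The 5' arm is the mature extended by ``ext5``/``ext3`` random nt; the
    3' arm starts as its reverse complement.  ``mismatch_runs`` is a list
    of ``(arm_index, run_length)`` substitutions of star bases with
    non-pairing ones (indices on the 5' arm); ``bulge=(arm_index, size)``
    deletes ``size`` star-side partners, leaving a one-sided bulge on the
    mature strand.  The result is embedded mid-sequence in a synthetic
    EST with low-interference A/C flanks.  When ``verify`` is set the
    construct is folded and re-sampled until the requested bulge size and
    largest mismatch run are realized exactly; unsatisfiable requests
    raise GenerationError naming the constraint.
    """
    mature = rna(mature)
    if not 15 <= len(mature) <= 35:
        raise GenerationError("mature length outside the supported 15-35 nt range")
    for attempt in range(max_tries):
        e5 = _rand_seq(rng, ext5, gc_target, "ACGU")
        e3 = _rand_seq(rng, ext3, gc_target, "ACGU")
        arm5 = e5 + mature + e3
        arm_len = len(arm5)
        arm3 = list(arm5.translate(_RC_RNA)[::-1])
        # arm3[arm_len - 1 - i] is the partner of arm5[i]
        for start, run in mismatch_runs:
            for i in range(start, min(start + run, arm_len)):
                arm3[arm_len - 1 - i] = _NONPAIR[arm5[i]]
        if bulge is not None:
            b_start, b_size = bulge
            drop = {
                arm_len - 1 - i
                for i in range(b_start, min(b_start + b_size, arm_len))
            }
            arm3 = [c for k, c in enumerate(arm3) if k not in drop]
        precursor = arm5 + loop + "".join(arm3)
        mature_offset = ext5
        # flanks drawn over {A, C}: they cannot pair with each other and
        # only weakly with the arms, so the designed stem dominates
        f5 = "".join("C" if rng.random() < gc_target else "A" for _ in range(flank))
        f3 = "".join("C" if rng.random() < gc_target else "A" for _ in range(flank))
        est = f5 + dna(precursor) + f3
        mature_pos = len(f5) + mature_offset
        result = HairpinResult(precursor, mature_offset, est, mature_pos)
        if not verify:
            return result
        realized = _realized_duplex(result, len(mature))
        if realized is None:
            continue
        want_bulge = bulge[1] if bulge else 0
        # only runs strictly inside the mature region show up in the
        # mature/star duplex metrics
        want_mm = max(
            (
                r
                for s, r in mismatch_runs
                if s > ext5 and s + r < ext5 + len(mature)
            ),
            default=0,
        )
        if realized == (want_bulge, want_mm):
            return result
    raise GenerationError(
        f"could not realize bulge={bulge} mismatch_runs={list(mismatch_runs)} "
        f"after {max_tries} attempts"
    )


def _realized_duplex(result: HairpinResult, mature_len: int) -> tuple[int, int] | None:
    from .fold import FoldError, duplex_metrics, fold_mfe

    structure = fold_mfe(result.precursor)
    try:
        metrics = duplex_metrics(
            structure, result.mature_offset, result.mature_offset + mature_len
        )
    except FoldError:
        return None
    return metrics.max_bulge, metrics.max_adjacent_mismatches


# ---------------------------------------------------------------------------
# planted hairpin designs


@dataclass
class HairpinDesign:
    name: str
    rule_target: str  # "all", "r1".."r7_low"/"r7_high", "cross_species", "low_count"
    mature: str  # RNA
    precursor: str  # RNA
    est_id: str
    est: str  # DNA
    mature_pos: int
    expected_rules: dict[str, bool]
    in_cross_species: bool = False
    planted_reads: int | None = None  # None: drawn from the novel read pool


@dataclass(frozen=True)
class PlantedSite:
    mirna_id: str
    gene_id: str
    start: int
    end: int
    expectation: float
    mode: str


@dataclass
class FixtureBundle:
    refs: ReferenceSets
    hairpins: list[HairpinDesign]
    target_sites: list[PlantedSite]
    enriched_term: str
    target_site_genes: list[str]


def _sample_mature(rng, length: int, gc: float = 0.5) -> str:
    while True:
        seq = _rand_seq(rng, length, gc, "ACGU")
        if seq.count("A") / length < 0.7 and _clean_insert_ok(dna(seq)):
            return seq


def _spaced_singles(rng, arm_len: int, avoid: tuple[int, int] | None = None
                    ) -> list[tuple[int, int]]:
    """Single-mismatch positions every 3-4 nt along the arm, keeping the
    duplex in the weak-stem regime typical of real precursors."""
    runs = []
    pos = int(rng.integers(2, 5))
    while pos < arm_len - 2:
        if avoid is None or not (avoid[0] - 1 <= pos <= avoid[1]):
            runs.append((pos, 1))
        pos += int(rng.integers(3, 5))
    return runs


def _verify_design(design: HairpinDesign, params: NovelParams) -> bool:
    tag = UniqueTag(design.mature, 20)
    cand = evaluate_rules(
        tag, EstHit(design.est_id, "+", design.mature_pos), design.est, params
    )
    return cand.rules == design.expected_rules


_STOPS_DNA = {"TAA", "TAG", "TGA"}


def _orf_segment(rng: np.random.Generator) -> str:
    """Upstream pri-miRNA stretch carrying one short ORF (5-30 aa)."""
    n_aa = int(rng.integers(5, 31))
    codons = ["ATG"]
    while len(codons) < n_aa:
        c = _rand_seq(rng, 3, 0.5)
        if c not in _STOPS_DNA:
            codons.append(c)
    codons.append("TAA")
    pad5 = "".join("C" if rng.random() < 0.5 else "A" for _ in range(10))
    pad3 = "".join("C" if rng.random() < 0.5 else "A" for _ in range(10))
    return pad5 + "".join(codons) + pad3


def _build_valid(name: str, rng, rule_target: str = "all",
                 planted_reads: int | None = None,
                 in_cross_species: bool = False) -> HairpinDesign:
    mature = _sample_mature(rng, int(rng.integers(20, 23)))
    res = make_hairpin(
        mature, rng,
        mismatch_runs=_spaced_singles(rng, 8 + len(mature) + 8),
        verify=False,
    )
    # pri-miRNAs tend to carry short upstream ORFs (miPEP candidates);
    # plant one so the ORF scan has something real to find
    upstream = _orf_segment(rng)
    return HairpinDesign(
        name=name, rule_target=rule_target, mature=mature,
        precursor=res.precursor, est_id=f"est_{name}", est=upstream + res.est,
        mature_pos=len(upstream) + res.mature_pos,
        expected_rules={f"r{i}": True for i in range(1, 8)},
        in_cross_species=in_cross_species, planted_reads=planted_reads,
    )


def _build_length_violator(name: str, rng, rule: str) -> HairpinDesign:
    length = 17 if rule == "r1" else 31
    mature = _sample_mature(rng, length)
    res = make_hairpin(
        mature, rng, mismatch_runs=_spaced_singles(rng, 8 + length + 8),
        verify=False,
    )
    expected = {f"r{i}": True for i in range(1, 8)}
    expected[rule] = False
    return HairpinDesign(
        name=name, rule_target=rule, mature=mature, precursor=res.precursor,
        est_id=f"est_{name}", est=res.est, mature_pos=res.mature_pos,
        expected_rules=expected,
    )


def _build_weak_mfe(name: str, rng) -> HairpinDesign:
    """Rule-3 violator: a real but feeble A/U duplex whose window MFE stays
    above -18 kcal/mol.  C-only loop and flanks cannot pair (no G present),
    so the stem energy is fully controlled."""
    while True:
        mature = "".join("A" if rng.random() < 0.5 else "U" for _ in range(18))
        frac_a = mature.count("A") / 18
        if 0.3 <= frac_a <= 0.7:
            break
    arm5 = mature
    arm3 = list(arm5.translate(_RC_RNA)[::-1])
    mm_runs = [(3, 2), (8, 2), (13, 2)]
    for start, run in mm_runs:
        for i in range(start, start + run):
            arm3[17 - i] = "C"
    precursor = arm5 + "CCCCCC" + "".join(arm3)
    est = "C" * 10 + dna(precursor) + "C" * 10
    expected = {f"r{i}": True for i in range(1, 8)}
    expected["r3"] = False
    return HairpinDesign(
        name=name, rule_target="r3", mature=mature, precursor=precursor,
        est_id=f"est_{name}", est=est, mature_pos=10,
        expected_rules=expected,
    )


def _build_duplex_violator(name: str, rng, rule: str) -> HairpinDesign:
    mature = _sample_mature(rng, 21)
    arm_len = 8 + 21 + 8
    center = 8 + 10
    if rule == "r4":
        res = make_hairpin(
            mature, rng, bulge=(center - 2, 5),
            mismatch_runs=_spaced_singles(rng, arm_len, avoid=(center - 4, center + 4)),
            verify=False,
        )
    else:  # r5: a 4-nt adjacent-mismatch run
        res = make_hairpin(
            mature, rng, mismatch_runs=[(center - 2, 4)], verify=False,
        )
    expected = {f"r{i}": True for i in range(1, 8)}
    expected[rule] = False
    return HairpinDesign(
        name=name, rule_target=rule, mature=mature, precursor=res.precursor,
        est_id=f"est_{name}", est=res.est, mature_pos=res.mature_pos,
        expected_rules=expected,
    )


def _build_no_star(name: str, rng) -> HairpinDesign:
    """Rule-6 violator: the EST carries a strong unrelated A/U hairpin and
    the mature sits downstream in an alphabet ({A, C}, no AA runs) that
    cannot form two adjacent pairs anywhere on the EST, so no star arm
    exists on it."""
    arm = "".join("A" if rng.random() < 0.5 else "U" for _ in range(25))
    decoy = arm + "CCCCCC" + arm.translate(_RC_RNA)[::-1]
    mature_chars: list[str] = []
    prev = "C"
    for _ in range(21):
        if prev == "A":
            base = "C"
        else:
            base = "A" if rng.random() < 0.45 else "C"
        mature_chars.append(base)
        prev = base
    mature = "".join(mature_chars)
    est = dna(decoy) + "C" * 25 + dna(mature) + "CCC"
    expected = {f"r{i}": True for i in range(1, 8)}
    expected["r6"] = False
    return HairpinDesign(
        name=name, rule_target="r6", mature=mature, precursor=decoy,
        est_id=f"est_{name}", est=est,
        mature_pos=len(decoy) + 25,
        expected_rules=expected,
    )


def _build_gc_violator(name: str, rng, high: bool) -> HairpinDesign:
    if high:
        mature = _sample_mature(rng, 21, gc=0.88)
        res = make_hairpin(mature, rng, gc_target=0.88, loop="AAAAAA",
                           flank=3, verify=False)
    else:
        while True:
            mature = "".join("A" if rng.random() < 0.5 else "U" for _ in range(21))
            if 0.3 <= mature.count("A") / 21 <= 0.65:
                break
        res = make_hairpin(mature, rng, gc_target=0.0, loop="CCCCCC",
                           flank=15, verify=False)
        # reintroduce a little GC through C-only flanks (done below)
        f5 = "C" * 5 + "A" * 10
        f3 = "A" * 10 + "C" * 5
        res = HairpinResult(
            res.precursor, res.mature_offset,
            f5 + dna(res.precursor) + f3, len(f5) + res.mature_offset,
        )
    expected = {f"r{i}": True for i in range(1, 8)}
    expected["r7"] = False
    return HairpinDesign(
        name=name, rule_target="r7_high" if high else "r7_low",
        mature=mature, precursor=res.precursor, est_id=f"est_{name}",
        est=res.est, mature_pos=res.mature_pos, expected_rules=expected,
    )


_BUILDERS = {
    "r1": lambda n, r: _build_length_violator(n, r, "r1"),
    "r2": lambda n, r: _build_length_violator(n, r, "r2"),
    "r3": lambda n, r: _build_weak_mfe(n, r),
    "r4": lambda n, r: _build_duplex_violator(n, r, "r4"),
    "r5": lambda n, r: _build_duplex_violator(n, r, "r5"),
    "r6": lambda n, r: _build_no_star(n, r),
    "r7_low": lambda n, r: _build_gc_violator(n, r, high=False),
    "r7_high": lambda n, r: _build_gc_violator(n, r, high=True),
}


def _design_hairpins(rng: np.random.Generator, params: NovelParams,
                     n_valid: int = 5, max_tries: int = 60) -> list[HairpinDesign]:
    designs: list[HairpinDesign] = []

    def verified(builder, name):
        for _ in range(max_tries):
            design = builder(name, rng)
            if _verify_design(design, params):
                return design
        raise GenerationError(f"could not realize design {name}")

    for i in range(n_valid):
        designs.append(verified(lambda n, r: _build_valid(n, r), f"valid{i + 1}"))
    for rule in ("r1", "r2", "r3", "r4", "r5", "r6", "r7_low", "r7_high"):
        designs.append(verified(_BUILDERS[rule], f"viol_{rule}"))
    designs.append(
        verified(
            lambda n, r: _build_valid(n, r, rule_target="cross_species",
                                      in_cross_species=True),
            "crosshit",
        )
    )
    designs.append(
        verified(
            lambda n, r: _build_valid(n, r, rule_target="low_count",
                                      planted_reads=5),
            "lowcount",
        )
    )
    return designs


# ---------------------------------------------------------------------------
# fixture references

_FAMILY_SIZES = {
    "MIR166": 10,
    "MIR156": 4,
    "MIR159": 3,
    "MIR396": 3,
    "MIR398": 2,
    "MIR171": 2,
}

_SPECIES = ("arabidopsis", "cranberry", "tomato", "grape", "kiwifruit")

# mismatch substitutions that are neither Watson-Crick nor wobble partners
_TARGET_MM = {"A": "C", "C": "A", "G": "A", "U": "C"}


def make_fixture_references(
    seed: int, params: NovelParams | None = None
) -> FixtureBundle:
    """Build the complete miniature reference collection.

    Deterministic in ``seed``.  Includes >= 5 miRNA families (one large),
    planted near-perfect target sites inside the cDNA set, and a GO table
    with one strongly enriched term among the target-site genes.
    """
    params = params or NovelParams()
    rng = np.random.default_rng(seed)
    refs = ReferenceSets()

    # mature miRNAs, family-labelled
    i = 0
    for family, size in _FAMILY_SIZES.items():
        for member in range(size):
            length = int(rng.integers(20, 23))
            seq = _sample_mature(rng, length)
            refs.matures.append(
                MatureRef(f"vac-{family.lower()}{chr(97 + member)}", family, seq)
            )
            i += 1

    # cDNA genes
    for g in range(30):
        length = int(rng.integers(300, 601))
        refs.cdna[f"gene{g + 1:04d}"] = _rand_seq(rng, length, 0.48)

    # ncRNA classes
    for cls, count, lo, hi in (
        ("rRNA", 5, 150, 400), ("tRNA", 5, 70, 90),
        ("snRNA", 3, 100, 200), ("snoRNA", 3, 70, 150),
        ("other", 3, 80, 200),
    ):
        refs.rfam[cls] = {
            f"{cls}_{k + 1}": _rand_seq(rng, int(rng.integers(lo, hi)), 0.5)
            for k in range(count)
        }

    # hairpin designs and their ESTs
    hairpins = _design_hairpins(rng, params)
    for h in hairpins:
        refs.ests[h.est_id] = h.est
    for e in range(3):
        refs.ests[f"est_plain{e + 1}"] = _rand_seq(rng, int(rng.integers(150, 301)), 0.45)

    # cross-species cDNA; one designed mature is planted into tomato
    for sp in _SPECIES:
        refs.cross_species[sp] = {
            f"{sp}_{k + 1}": _rand_seq(rng, int(rng.integers(200, 401)), 0.45)
            for k in range(5)
        }
    cross_hit = next(h for h in hairpins if h.in_cross_species)
    host_id = "tomato_1"
    host = refs.cross_species["tomato"][host_id]
    pos = int(rng.integers(20, len(host) - len(cross_hit.mature) - 20))
    refs.cross_species["tomato"][host_id] = (
        host[:pos] + dna(cross_hit.mature) + host[pos + len(cross_hit.mature):]
    )

    # planted target sites: near-perfect antiparallel complements with one
    # non-seed mismatch, inserted by segment replacement into cDNA genes
    sites: list[PlantedSite] = []
    gene_ids = sorted(refs.cdna)
    chosen = [refs.matures[k] for k in (0, 10, 14, 17, 20, 22)]
    site_cursor = 0
    for idx, ref in enumerate(chosen):
        m = min(20, len(ref.sequence))
        for s in range(2 + idx % 2):
            gene_id = gene_ids[site_cursor % len(gene_ids)]
            site_cursor += 2  # 15 sites over 30 genes: every gene used once
            mm_pos = 13 if s % 2 == 0 else 10  # 1-based miRNA position
            site = _make_site(ref.sequence[:m], mm_pos)
            gene = refs.cdna[gene_id]
            start = 40
            refs.cdna[gene_id] = gene[:start] + site + gene[start + m:]
            sites.append(
                PlantedSite(
                    mirna_id=ref.identifier, gene_id=gene_id, start=start,
                    end=start + m, expectation=1.0,
                    mode="cleavage" if mm_pos == 13 else "translational-repression",
                )
            )

    # gene -> GO table; one term is concentrated in the target-site genes
    bp_terms = [f"GO:{1000000 + t:07d}" for t in range(12)]
    mf_terms = [f"GO:{2000000 + t:07d}" for t in range(8)]
    for t in bp_terms:
        refs.go_namespaces[t] = "biological_process"
    for t in mf_terms:
        refs.go_namespaces[t] = "molecular_function"
    enriched_term = "GO:0999999"
    refs.go_namespaces[enriched_term] = "biological_process"
    all_terms = bp_terms + mf_terms
    site_genes = sorted({s.gene_id for s in sites})
    for gene_id in gene_ids:
        k = int(rng.integers(2, 5))
        picks = rng.choice(len(all_terms), size=k, replace=False)
        for p in sorted(picks):
            refs.go_table.append((gene_id, all_terms[p]))
    for gene_id in site_genes:
        refs.go_table.append((gene_id, enriched_term))
    refs.go_table.append((gene_ids[-1], enriched_term))  # one background gene
    refs.go_table.sort()

    return FixtureBundle(
        refs=refs, hairpins=hairpins, target_sites=sites,
        enriched_term=enriched_term, target_site_genes=site_genes,
    )


def _make_site(mirna_head: str, mm_pos: int) -> str:
    """DNA target site: reverse complement of the miRNA head with one
    planted mismatch at 1-based miRNA position ``mm_pos``."""
    m = len(mirna_head)
    site = list(dna(mirna_head.translate(_RC_RNA)[::-1]))
    # miRNA position p sits at site index m - p
    site[m - mm_pos] = dna(_TARGET_MM[mirna_head[mm_pos - 1]])
    return "".join(site)


# ---------------------------------------------------------------------------
# truth manifest


@dataclass
class TruthManifest:
    reads: list[dict] = field(default_factory=list)
    hairpins: list[dict] = field(default_factory=list)

    def class_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for entry in self.reads:
            counts[entry["klass"]] = counts.get(entry["klass"], 0) + 1
        return counts

    def expected_category_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for entry in self.reads:
            cat = entry["expected_category"]
            counts[cat] = counts.get(cat, 0) + 1
        return counts

    def save(self, path) -> None:
        with open(path, "w") as fh:
            for entry in self.reads:
                fh.write(json.dumps({"type": "read", **entry}, sort_keys=True) + "\n")
            for entry in self.hairpins:
                fh.write(json.dumps({"type": "hairpin", **entry}, sort_keys=True) + "\n")

    @classmethod
    def load(cls, path) -> "TruthManifest":
        manifest = cls()
        with open(path) as fh:
            for line in fh:
                entry = json.loads(line)
                kind = entry.pop("type")
                (manifest.reads if kind == "read" else manifest.hairpins).append(entry)
        return manifest


# ---------------------------------------------------------------------------
# library generation


def _draw_length(rng, profile_lengths, profile_probs) -> int:
    return int(profile_lengths[rng.choice(len(profile_lengths), p=profile_probs)])


def _mutate(rng, seq_dna: str, n_mm: int) -> str:
    out = list(seq_dna)
    positions = rng.choice(len(out), size=n_mm, replace=False)
    for p in sorted(int(x) for x in positions):
        alternatives = [b for b in "ACGT" if b != out[p]]
        out[p] = alternatives[int(rng.integers(0, 3))]
    return "".join(out)


def generate_library(
    config: LibraryConfig,
    bundle: FixtureBundle,
    fastq_path,
    manifest_path=None,
) -> TruthManifest:
    """Write a Phred+64 FASTQ library and return its truth manifest.

    One read per draw: the class is sampled from ``config.fractions``, the
    class-specific recipe builds the insert, the full 3' adapter is
    appended and the read padded/truncated to ``config.read_length``.
    Re-running with the same config and fixtures is byte-identical.
    """
    config.validate()
    refs = bundle.refs
    rng = np.random.default_rng(config.seed)
    class_probs = np.array([config.fractions[c] for c in CLASS_NAMES])
    for cls, ref_needed in (
        ("conserved", refs.matures),
        ("rrna", refs.rfam.get("rRNA")),
        ("trna", refs.rfam.get("tRNA")),
        ("cdna", refs.cdna),
        ("novel", bundle.hairpins),
    ):
        if config.fractions[cls] > 0 and not ref_needed:
            raise ConfigError(f"class {cls!r} requested but its reference set is empty")
    lengths = sorted(config.length_profile)
    length_probs = np.array([config.length_profile[l] for l in lengths])
    mm_levels = sorted(config.mismatch_rates)
    mm_probs = np.array([config.mismatch_rates[m] for m in mm_levels])
    novel_pool = [h for h in bundle.hairpins if h.planted_reads is None]
    fixed_count_designs = [h for h in bundle.hairpins if h.planted_reads is not None]
    fixed_queue: list[HairpinDesign] = []
    for h in fixed_count_designs:
        fixed_queue.extend([h] * h.planted_reads)

    manifest = TruthManifest()
    rl = config.read_length
    min_len, max_len = 18, 30  # the cleaning-stage insert bounds

    def expected_cat(insert_dna: str) -> str:
        if len(insert_dna) < min_len:
            return "too_short"
        if len(insert_dna) > max_len:
            return "too_long"
        if insert_dna.count("A") / len(insert_dna) >= 0.8:
            return "polya"
        return "clean"

    with open(fastq_path, "w") as fq:
        for i in range(config.n_reads):
            read_id = f"sr{i:08d}"
            cls = CLASS_NAMES[int(rng.choice(len(CLASS_NAMES), p=class_probs))]
            qual = GOOD_Q_CHAR * rl
            entry: dict = {"read_id": read_id, "klass": cls, "subtype": None,
                           "source_id": None, "mismatches": None}
            if cls == "conserved":
                ref = refs.matures[int(rng.integers(0, len(refs.matures)))]
                n_mm = int(mm_levels[rng.choice(len(mm_levels), p=mm_probs)])
                insert = dna(ref.sequence)
                if n_mm:
                    for _ in range(30):
                        mutated = _mutate(rng, insert, n_mm)
                        if _clean_insert_ok(mutated):
                            break
                    insert = mutated
                entry.update(source_id=ref.identifier, mismatches=n_mm)
                entry["expected_tag_class"] = (
                    "conserved-miRNA" if n_mm <= 2 else "unclassified"
                )
            elif cls == "novel":
                if fixed_queue:
                    design = fixed_queue.pop(0)
                else:
                    design = novel_pool[int(rng.integers(0, len(novel_pool)))]
                insert = dna(design.mature)
                entry.update(source_id=design.name)
                entry["expected_tag_class"] = "unclassified"
            elif cls in ("rrna", "trna", "cdna"):
                source = {
                    "rrna": refs.rfam["rRNA"],
                    "trna": refs.rfam["tRNA"],
                    "cdna": refs.cdna,
                }[cls]
                ids = sorted(source)
                for _ in range(30):
                    sid = ids[int(rng.integers(0, len(ids)))]
                    ref_seq = source[sid]
                    length = min(_draw_length(rng, lengths, length_probs), len(ref_seq))
                    start = int(rng.integers(0, len(ref_seq) - length + 1))
                    insert = ref_seq[start : start + length]
                    if _clean_insert_ok(insert):
                        break
                entry.update(source_id=sid)
                entry["expected_tag_class"] = {
                    "rrna": "rRNA", "trna": "tRNA", "cdna": "cDNA",
                }[cls]
            elif cls == "polya":
                length = _draw_length(rng, lengths, length_probs)
                n_other = int(rng.integers(0, max(1, length // 10)))
                insert_list = ["A"] * length
                if n_other:
                    pos = rng.choice(length, size=n_other, replace=False)
                    for p in sorted(int(x) for x in pos):
                        insert_list[p] = "CGT"[int(rng.integers(0, 3))]
                insert = "".join(insert_list)
                entry["expected_tag_class"] = None
            elif cls == "lowqual":
                length = _draw_length(rng, lengths, length_probs)
                insert = _rand_seq(rng, length, 0.5)
                n_bad = 1 + int(rng.integers(0, 3))
                qual_list = [GOOD_Q_CHAR] * rl
                bad_pos = rng.choice(rl, size=n_bad, replace=False)
                for p in sorted(int(x) for x in bad_pos):
                    qual_list[p] = chr(64 + int(rng.integers(0, 10)))
                qual = "".join(qual_list)
                entry["expected_tag_class"] = None
            else:  # adapter artifacts
                subtype = ("insert_null", "adapter3_null", "contaminant5")[
                    int(rng.integers(0, 3))
                ]
                entry["subtype"] = subtype
                entry["expected_tag_class"] = None
                if subtype == "insert_null":
                    seq = (ADAPTER_3P + _rand_seq(rng, rl, 0.5))[:rl]
                elif subtype == "adapter3_null":
                    while True:
                        seq = _rand_seq(rng, rl, 0.5)
                        if not _contains_adapter_anchor(seq):
                            break
                else:
                    while True:
                        core = _rand_seq(rng, 10 + int(rng.integers(0, 6)), 0.5)
                        contaminant = ADAPTER_5P[-12:] + core
                        if not _contains_adapter_anchor(contaminant):
                            break
                    seq = (contaminant + ADAPTER_3P + _rand_seq(rng, rl, 0.5))[:rl]
                entry["expected_category"] = subtype
                manifest.reads.append(entry)
                fq.write(f"@{read_id}\n{seq}\n+\n{qual}\n")
                continue
            if cls == "lowqual":
                entry["expected_category"] = "low_quality"
            elif cls == "polya":
                entry["expected_category"] = "polya"
            else:
                entry["expected_category"] = expected_cat(insert)
            entry["insert"] = insert
            seq = (insert + ADAPTER_3P + _rand_seq(rng, rl, 0.5))[:rl]
            manifest.reads.append(entry)
            fq.write(f"@{read_id}\n{seq}\n+\n{qual}\n")

    for h in bundle.hairpins:
        manifest.hairpins.append(
            {
                "name": h.name,
                "rule_target": h.rule_target,
                "mature": h.mature,
                "est_id": h.est_id,
                "mature_pos": h.mature_pos,
                "expected_rules": h.expected_rules,
                "in_cross_species": h.in_cross_species,
                "planted_reads": h.planted_reads,
            }
        )
    if manifest_path is not None:
        manifest.save(manifest_path)
    return manifest
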