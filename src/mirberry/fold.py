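"""RNA secondary-structure engine.

Minimum-free-energy folding of small RNAs under a bundled, deliberately
simple nearest-neighbor model: admissible pairs are Watson-Crick plus G:U
wobble, energy is earned only by stacked adjacent pairs, and every hairpin
loop pays a (linearly capped) closing penalty.  Interior loops, bulges and
multiloop junctions are free.  The model is small enough that an exhaustive
enumeration over all pseudoknot-free structures is feasible for short
sequences and serves as the oracle for the dynamic program; both read the
same parameter table (``data/energy_params.tsv``).

The module also derives the quantities the downstream miRNA rules consume:
GC fraction, adjusted MFE (AMFE, kcal/mol per 100 nt), the minimal folding
free energy index (MFEI = AMFE / GC%), and miRNA/miRNA* duplex metrics
(largest bulge, longest adjacent-mismatch run, star coordinates).

An external folding backend (ViennaRNA, when importable) can be plugged in
through ``fold_mfe(..., engine="vienna")``; all thresholds downstream apply
to whichever engine produced the structure.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from importlib import resources
from typing import Iterator, Sequence

import numpy as np

__all__ = [
    "EnergyModel",
    "FoldError",
    "NoDuplexError",
    "HairpinStructure",
    "DuplexMetrics",
    "FoldMetrics",
    "load_energy_model",
    "fold_mfe",
    "enumerate_structures",
    "structure_energy",
    "brute_force_mfe",
    "gc_fraction",
    "amfe",
    "mfei",
    "fold_metrics",
    "duplex_metrics",
    "unpairing_energy",
    "reverse_complement_rna",
]

_BASES = {"A": 0, "C": 1, "G": 2, "U": 3}
_RC_RNA = str.maketrans("ACGU", "UGCA")

# pair-class ids: 0 = not pairable, 1 = A:U, 2 = C:G, 3 = G:U
_PAIR_CLASS = np.zeros((4, 4), dtype=np.int8)
_PAIR_CLASS[0, 3] = _PAIR_CLASS[3, 0] = 1
_PAIR_CLASS[1, 2] = _PAIR_CLASS[2, 1] = 2
_PAIR_CLASS[2, 3] = _PAIR_CLASS[3, 2] = 3

_INF = 1e9
_TOL = 1e-6


class FoldError(ValueError):
    """Invalid input to the folding engine."""


class NoDuplexError(FoldError):
    """The mature region is entirely unpaired in the structure."""


@dataclass(frozen=True)
class EnergyModel:
    """Parameters of the bundled stacking model (kcal/mol)."""

    bond_au: float = 2.0
    bond_cg: float = 3.0
    bond_gu: float = 1.0
    stack_scale: float = 0.5
    hairpin_base: float = 3.0
    hairpin_slope: float = 0.1
    hairpin_cap: float = 5.0
    min_loop: int = 3
    allow_gu: bool = True

    @property
    def bond(self) -> np.ndarray:
        return np.array([0.0, self.bond_au, self.bond_cg, self.bond_gu])

    def stack(self, p: int, q: int) -> float:
        b = self.bond
        return -self.stack_scale * (b[p] + b[q])

    def hairpin_penalty(self, loop_len: int) -> float:
        return min(
            self.hairpin_base + self.hairpin_slope * (loop_len - self.min_loop),
            self.hairpin_cap,
        )


def load_energy_model(allow_gu: bool = True) -> EnergyModel:
    """Load the versioned parameter table shipped with the package."""
    text = (
        resources.files("mirberry").joinpath("data/energy_params.tsv").read_text()
    )
    params: dict[str, float] = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#") or line.startswith("param"):
            continue
        key, value = line.split("\t")
        params[key] = float(value)
    return EnergyModel(
        bond_au=params["bond_AU"],
        bond_cg=params["bond_CG"],
        bond_gu=params["bond_GU"],
        stack_scale=params["stack_scale"],
        hairpin_base=params["hairpin_base"],
        hairpin_slope=params["hairpin_slope"],
        hairpin_cap=params["hairpin_cap"],
        min_loop=int(params["min_loop"]),
        allow_gu=allow_gu,
    )


_DEFAULT_MODEL = load_energy_model()


def _encode(sequence: str) -> np.ndarray:
    seq = sequence.upper().replace("T", "U")
    try:
        return np.array([_BASES[c] for c in seq], dtype=np.int8)
    except KeyError as exc:
        raise FoldError(f"invalid RNA base {exc.args[0]!r} in sequence") from None


def reverse_complement_rna(sequence: str) -> str:
    return sequence.upper().replace("T", "U").translate(_RC_RNA)[::-1]


def _pair_class_matrix(
    enc: np.ndarray, model: EnergyModel, blocked: Sequence[int] | None
) -> np.ndarray:
    ptype = _PAIR_CLASS[enc[:, None], enc[None, :]].copy()
    if not model.allow_gu:
        ptype[ptype == 3] = 0
    if blocked:
        idx = np.fromiter(blocked, dtype=np.int64)
        ptype[idx, :] = 0
        ptype[:, idx] = 0
    return ptype


def _fill_py(ptype, bond, scale, hp_base, hp_slope, hp_cap, min_loop):
    n = ptype.shape[0]
    V = np.full((n, n), _INF)
    N = np.full((n, n), _INF)
    for span in range(2, n + 1):
        for i in range(0, n - span + 1):
            j = i + span - 1
            # V: best energy with (i, j) paired
            if ptype[i, j] != 0 and j - i - 1 >= min_loop:
                loop = j - i - 1
                best = min(hp_base + hp_slope * (loop - min_loop), hp_cap)
                if ptype[i + 1, j - 1] != 0 and V[i + 1, j - 1] < _INF:
                    st = -scale * (bond[ptype[i, j]] + bond[ptype[i + 1, j - 1]])
                    cand = V[i + 1, j - 1] + st
                    if cand < best:
                        best = cand
                if j - 1 > i + 1 and N[i + 1, j - 1] < _INF:
                    if N[i + 1, j - 1] < best:
                        best = N[i + 1, j - 1]
                V[i, j] = best
            # N: best energy of region [i, j] containing >= 1 pair
            best = N[i, j - 1] if j - 1 >= i else _INF
            for k in range(i, j):
                if V[k, j] >= _INF:
                    continue
                w = 0.0
                if k - 1 >= i + 1 and N[i, k - 1] < 0.0:
                    w = N[i, k - 1]
                cand = w + V[k, j]
                if cand < best:
                    best = cand
            N[i, j] = best
    return V, N


try:  # pragma: no cover - exercised implicitly when numba is present
    from numba import njit

    _fill_jit = njit(cache=False)(_fill_py)
except Exception:  # pragma: no cover
    _fill_jit = _fill_py


@dataclass(frozen=True)
class HairpinStructure:
    """A folded sequence: dot-bracket pairing plus its MFE in kcal/mol."""

    sequence: str
    pairing: str
    mfe: float

    def partners(self) -> list[int]:
        """Partner index per position, -1 when unpaired."""
        partner = [-1] * len(self.pairing)
        stack: list[int] = []
        for i, ch in enumerate(self.pairing):
            if ch == "(":
                stack.append(i)
            elif ch == ")":
                j = stack.pop()
                partner[i], partner[j] = j, i
        if stack:
            raise FoldError("unbalanced dot-bracket string")
        return partner


def _traceback(ptype, V, N, model: EnergyModel) -> list[tuple[int, int]]:
    bond = model.bond
    pairs: list[tuple[int, int]] = []
    n = ptype.shape[0]
    if n == 0 or N[0, n - 1] >= 0:
        return pairs
    tasks = [("N", 0, n - 1)]
    while tasks:
        kind, i, j = tasks.pop()
        if kind == "N":
            v = N[i, j]
            if j - 1 >= i and abs(N[i, j - 1] - v) < _TOL:
                tasks.append(("N", i, j - 1))
                continue
            found = False
            for k in range(i, j):
                if V[k, j] >= _INF:
                    continue
                w = 0.0
                use_inner = False
                if k - 1 >= i + 1 and N[i, k - 1] < 0.0:
                    w = N[i, k - 1]
                    use_inner = True
                if abs(w + V[k, j] - v) < _TOL:
                    tasks.append(("V", k, j))
                    if use_inner:
                        tasks.append(("N", i, k - 1))
                    found = True
                    break
            if not found:  # pragma: no cover - defensive
                raise FoldError("traceback failed (N)")
        else:  # V
            pairs.append((i, j))
            v = V[i, j]
            loop = j - i - 1
            if abs(model.hairpin_penalty(loop) - v) < _TOL:
                continue
            if ptype[i + 1, j - 1] != 0 and V[i + 1, j - 1] < _INF:
                st = -model.stack_scale * (
                    bond[ptype[i, j]] + bond[ptype[i + 1, j - 1]]
                )
                if abs(V[i + 1, j - 1] + st - v) < _TOL:
                    tasks.append(("V", i + 1, j - 1))
                    continue
            if j - 1 > i + 1 and abs(N[i + 1, j - 1] - v) < _TOL:
                tasks.append(("N", i + 1, j - 1))
                continue
            raise FoldError("traceback failed (V)")  # pragma: no cover
    return pairs


def _pairs_to_dotbracket(n: int, pairs: Sequence[tuple[int, int]]) -> str:
    db = ["."] * n
    for i, j in pairs:
        db[i], db[j] = "(", ")"
    return "".join(db)


def fold_mfe(
    sequence: str,
    engine: str = "bundled",
    model: EnergyModel | None = None,
    blocked: Sequence[int] | None = None,
) -> HairpinStructure:
    """Fold ``sequence`` and return one optimal structure.

    ``engine="bundled"`` runs the dynamic program over the bundled stacking
    model with deterministic tie-breaking (ties prefer unpaired bases, then
    the hairpin > stack > interior case order).  ``engine="vienna"`` defers
    to the ViennaRNA Turner-model bindings when installed.  ``blocked``
    positions (0-based) are forced unpaired; only the bundled engine
    supports them.
    """
    seq = sequence.upper().replace("T", "U")
    enc = _encode(seq)
    n = len(enc)
    if engine == "vienna":
        if blocked:
            raise FoldError("blocked positions require the bundled engine")
        try:
            import RNA  # type: ignore
        except ImportError as exc:  # pragma: no cover
            raise FoldError("ViennaRNA python bindings are not installed") from exc
        db, mfe_val = RNA.fold_compound(seq).mfe()
        return HairpinStructure(seq, db, float(mfe_val))
    if engine != "bundled":
        raise FoldError(f"unknown folding engine {engine!r}")
    model = model or _DEFAULT_MODEL
    if n == 0:
        return HairpinStructure(seq, "", 0.0)
    ptype = _pair_class_matrix(enc, model, blocked)
    V, N = _fill_jit(
        ptype,
        model.bond,
        model.stack_scale,
        model.hairpin_base,
        model.hairpin_slope,
        model.hairpin_cap,
        model.min_loop,
    )
    mfe_val = min(0.0, float(N[0, n - 1])) if n > 1 else 0.0
    pairs = _traceback(ptype, V, N, model) if mfe_val < 0 else []
    return HairpinStructure(seq, _pairs_to_dotbracket(n, pairs), round(mfe_val, 6))


# ---------------------------------------------------------------------------
# exhaustive oracle


def enumerate_structures(
    sequence: str, model: EnergyModel | None = None
) -> Iterator[tuple[tuple[int, int], ...]]:
    """Yield every pseudoknot-free structure (as a tuple of pairs).

    Intended for short sequences only; the count grows exponentially.
    """
    model = model or _DEFAULT_MODEL
    enc = _encode(sequence)
    ptype = _pair_class_matrix(enc, model, None)

    def rec(i: int, j: int) -> Iterator[tuple[tuple[int, int], ...]]:
        if i > j:
            yield ()
            return
        # position i unpaired
        for rest in rec(i + 1, j):
            yield rest
        # position i paired with l
        for l in range(i + model.min_loop + 1, j + 1):
            if ptype[i, l] == 0:
                continue
            for inner in rec(i + 1, l - 1):
                for outer in rec(l + 1, j):
                    yield ((i, l),) + inner + outer

    return rec(0, len(enc) - 1)


def structure_energy(
    sequence: str,
    pairs: Sequence[tuple[int, int]],
    model: EnergyModel | None = None,
) -> float:
    """Energy of an explicit structure under the bundled model.

    This is the ground-truth energy function shared by the dynamic program
    and the enumeration oracle: stacking terms for adjacent pairs plus a
    hairpin-loop closing penalty; everything else is free.
    """
    model = model or _DEFAULT_MODEL
    enc = _encode(sequence)
    n = len(enc)
    partner = [-1] * n
    for i, j in pairs:
        if not (0 <= i < j < n):
            raise FoldError(f"pair out of range: {(i, j)}")
        if _PAIR_CLASS[enc[i], enc[j]] == 0 or (
            not model.allow_gu and _PAIR_CLASS[enc[i], enc[j]] == 3
        ):
            raise FoldError(f"inadmissible pair at {(i, j)}")
        partner[i], partner[j] = j, i
    energy = 0.0
    pairset = {(min(i, j), max(i, j)) for i, j in pairs}
    bond = model.bond
    for i, j in pairset:
        if (i + 1, j - 1) in pairset:
            energy += -model.stack_scale * (
                bond[_PAIR_CLASS[enc[i], enc[j]]]
                + bond[_PAIR_CLASS[enc[i + 1], enc[j - 1]]]
            )
        if all(partner[k] == -1 for k in range(i + 1, j)):
            loop = j - i - 1
            if loop < model.min_loop:
                raise FoldError(f"hairpin loop shorter than {model.min_loop}")
            energy += model.hairpin_penalty(loop)
    return energy


def brute_force_mfe(sequence: str, model: EnergyModel | None = None) -> float:
    """MFE by explicit enumeration of every structure (oracle path)."""
    model = model or _DEFAULT_MODEL
    best = 0.0
    for pairs in enumerate_structures(sequence, model):
        e = structure_energy(sequence, pairs, model)
        if e < best:
            best = e
    return best


# ---------------------------------------------------------------------------
# derived metrics


def gc_fraction(sequence: str) -> float:
    if not sequence:
        raise FoldError("empty sequence")
    seq = sequence.upper()
    return (seq.count("G") + seq.count("C")) / len(seq)


@dataclass(frozen=True)
class FoldMetrics:
    """GC fraction, adjusted MFE and folding-energy index of a precursor."""

    gc: float
    amfe: float
    mfei: float


def amfe(mfe: float, length: int) -> float:
    """Adjusted MFE: |MFE| per 100 nt."""
    if length <= 0:
        raise FoldError("length must be positive")
    return abs(mfe) / length * 100.0


def mfei(mfe: float, length: int, gc: float) -> FoldMetrics:
    """Minimal folding free energy index: AMFE divided by GC percentage."""
    a = amfe(mfe, length)
    if a == 0.0:
        return FoldMetrics(gc=gc, amfe=0.0, mfei=0.0)
    if not 0.0 < gc < 1.0:
        raise FoldError("MFEI undefined for GC fraction outside (0, 1)")
    return FoldMetrics(gc=gc, amfe=a, mfei=a / (gc * 100.0))


def fold_metrics(structure: HairpinStructure) -> FoldMetrics:
    return mfei(structure.mfe, len(structure.sequence), gc_fraction(structure.sequence))


@dataclass(frozen=True)
class DuplexMetrics:
    """miRNA/miRNA* duplex imperfection summary.

    ``max_bulge`` is the longest one-sided unpaired run within the duplex
    (asymmetric excess of an interior loop counts as a bulge);
    ``max_adjacent_mismatches`` is the longest run of opposing unpaired
    positions (min of the two sides of each interior gap).  Terminal
    unpaired mature bases are outside the duplex and do not count; a
    ``paired_fraction`` below the caller's floor should instead be treated
    as "no duplex".
    """

    max_bulge: int
    max_adjacent_mismatches: int
    star_start: int
    star_end: int
    paired_fraction: float
    n_bulge_events: int


def duplex_metrics(
    structure: HairpinStructure, mature_start: int, mature_end: int
) -> DuplexMetrics:
    """Measure the duplex formed by the mature region of a folded precursor.

    Star coordinates follow the canonical Dicer geometry: the interval of
    positions paired to the mature region, extended 2 nt past its 3'
    (right) edge for the characteristic 2-nt overhang, clipped to the
    precursor.
    """
    n = len(structure.sequence)
    if not (0 <= mature_start < mature_end <= n):
        raise FoldError("mature region outside precursor")
    partner = structure.partners()
    paired = [
        (i, partner[i]) for i in range(mature_start, mature_end) if partner[i] >= 0
    ]
    if not paired:
        raise NoDuplexError("mature region entirely unpaired")
    partners = [q for _, q in paired]
    star_lo, star_hi = min(partners), max(partners) + 1
    star_hi = min(n, star_hi + 2)  # 2-nt 3' overhang
    if not (star_hi <= mature_start or star_lo >= mature_end):
        raise NoDuplexError("mature region pairs with itself; no distinct star arm")
    max_bulge = 0
    max_mm = 0
    n_bulges = 0
    for (p0, q0), (p1, q1) in itertools.pairwise(paired):
        gap_m = p1 - p0 - 1
        gap_s = abs(q1 - q0) - 1
        mm = min(gap_m, gap_s)
        bulge = abs(gap_m - gap_s)
        max_mm = max(max_mm, mm)
        if bulge > 0:
            n_bulges += 1
            max_bulge = max(max_bulge, bulge)
    return DuplexMetrics(
        max_bulge=max_bulge,
        max_adjacent_mismatches=max_mm,
        star_start=star_lo,
        star_end=star_hi,
        paired_fraction=len(paired) / (mature_end - mature_start),
        n_bulge_events=n_bulges,
    )


def unpairing_energy(
    sequence: str,
    site_start: int,
    site_end: int,
    context: int = 17,
    model: EnergyModel | None = None,
) -> float:
    """Energy (kcal/mol, >= 0) needed to open a target site.

    Folds the site plus ``context`` nt on each side, then refolds with the
    site positions forced unpaired; the difference is the pairing energy the
    site forfeits when opened (the accessibility proxy used for the UPE
    filter).
    """
    lo = max(0, site_start - context)
    hi = min(len(sequence), site_end + context)
    window = sequence[lo:hi]
    free = fold_mfe(window, model=model)
    blocked = list(range(site_start - lo, site_end - lo))
    opened = fold_mfe(window, model=model, blocked=blocked)
    return max(0.0, opened.mfe - free.mfe)
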