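"""RNA secondary structure: representation, loop decomposition, energies, folding.

The screen needs three structure capabilities: (1) represent a nested
secondary structure and split it into its energy-bearing loops, so that a
windowed "opening energy" can be read off around the start codon; (2) score
a structure with a nearest-neighbor free-energy model whose total is exactly
the sum over loops; (3) produce structures either with the built-in folding
engines or by parsing the output of an external predictor (Vienna
dot-bracket with an optional energy suffix), since large-scale screens
typically fold with an external tool and evaluate here.

Energy model
------------
A compact 37 °C nearest-neighbor parameterisation (Turner-style constants):
stacking energies for the six canonical pair types, size-dependent
hairpin/bulge/internal initiations for sizes up to 30 with logarithmic
extrapolation beyond, a Ninio asymmetry term for internal loops, an affine
multiloop model and a terminal A·U/G·U penalty.  Dangling ends, terminal
mismatches, coaxial stacking and the special small internal-loop tables are
deliberately omitted: the model stays exactly decomposable per loop, which
is what windowed energy extraction requires.  The exterior loop contributes
0 by convention.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

INF = float("inf")

RNA_ALPHABET = set("ACGU")

#: canonical pair types in table order
_PAIR_TYPES = ("CG", "GC", "GU", "UG", "AU", "UA")
_WC_PAIRS = {"CG", "GC", "AU", "UA"}
_WOBBLE = {"GU", "UG"}
_AU_GU_ENDS = {"AU", "UA", "GU", "UG"}

# Stacking free energies (kcal/mol, 37 C), Turner 2004 constants.
# Row: closing pair (s[i], s[j]); column: inner pair read 3'->5', i.e.
# (s[j-1], s[i+1]).  E.g. 5'-G C-3' over 3'-C G-5' = row GC, col GC = -3.40.
_STACK_ROWS = [
    # CG     GC     GU     UG     AU     UA
    [-2.40, -3.30, -2.10, -1.40, -2.10, -2.10],  # CG
    [-3.30, -3.40, -2.50, -1.50, -2.20, -2.40],  # GC
    [-2.10, -2.50, +1.30, -0.50, -1.40, -1.30],  # GU
    [-1.40, -1.50, -0.50, +0.30, -0.60, -1.00],  # UG
    [-2.10, -2.20, -1.40, -0.60, -1.10, -0.90],  # AU
    [-2.10, -2.40, -1.30, -1.00, -0.90, -1.30],  # UA
]
STACK_TABLE: dict[tuple[str, str], float] = {
    (p1, p2): _STACK_ROWS[r][c]
    for r, p1 in enumerate(_PAIR_TYPES)
    for c, p2 in enumerate(_PAIR_TYPES)
}

# Loop initiation free energies by size, 0..30 (kcal/mol, 37 C).
HAIRPIN_INIT = (
    INF, INF, INF, 5.40, 5.60, 5.70, 5.40, 6.00, 5.50, 6.40,
    6.50, 6.60, 6.70, 6.80, 6.90, 6.90, 7.00, 7.10, 7.10, 7.20,
    7.20, 7.30, 7.30, 7.40, 7.40, 7.50, 7.50, 7.50, 7.60, 7.60, 7.70,
)
BULGE_INIT = (
    INF, 3.80, 2.80, 3.20, 3.60, 4.00, 4.40, 4.60, 4.70, 4.80,
    4.90, 5.00, 5.10, 5.20, 5.30, 5.40, 5.40, 5.50, 5.50, 5.60,
    5.70, 5.70, 5.80, 5.80, 5.80, 5.90, 5.90, 6.00, 6.00, 6.00, 6.10,
)
INTERNAL_INIT = (
    INF, INF, 1.00, 1.00, 1.10, 2.00, 2.00, 2.10, 2.30, 2.40,
    2.50, 2.60, 2.70, 2.80, 2.90, 2.90, 3.00, 3.10, 3.10, 3.20,
    3.30, 3.30, 3.40, 3.40, 3.50, 3.50, 3.50, 3.60, 3.60, 3.70, 3.70,
)


class StructureError(ValueError):
    pass


class EnergyError(ValueError):
    pass


@dataclass
class EnergyParams:
    """Nearest-neighbor parameter set (37 °C, kcal/mol).

    ``loop_extrapolation_scale`` continues the initiation tables past size
    30 as ``init(30) + scale * ln(n/30)``.  ``strict`` makes an undefined
    stack (non-canonical pair) an error rather than a zero contribution.
    """

    stack: dict[tuple[str, str], float] = field(default_factory=lambda: dict(STACK_TABLE))
    hairpin_init: tuple[float, ...] = HAIRPIN_INIT
    bulge_init: tuple[float, ...] = BULGE_INIT
    internal_init: tuple[float, ...] = INTERNAL_INIT
    loop_extrapolation_scale: float = 1.079
    ninio_per_asymmetry: float = 0.60
    ninio_max: float = 3.00
    terminal_au: float = 0.50
    multiloop_offset: float = 3.40
    multiloop_per_branch: float = 0.40
    multiloop_per_unpaired: float = 0.00
    strict: bool = True

    def loop_init(self, table: tuple[float, ...], size: int) -> float:
        if size < len(table):
            return table[size]
        return table[-1] + self.loop_extrapolation_scale * math.log(size / (len(table) - 1))


def default_params() -> EnergyParams:
    """The packaged 37 °C parameter set."""
    return EnergyParams()


def is_canonical(a: str, b: str, allow_gu: bool = True) -> bool:
    p = a + b
    return p in _WC_PAIRS or (allow_gu and p in _WOBBLE)


# ---------------------------------------------------------------------------
# Structure representation
# ---------------------------------------------------------------------------

@dataclass
class SecondaryStructure:
    """A nested (pseudoknot-free) secondary structure over an RNA sequence."""

    sequence: str
    dotbracket: str
    pairs: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        self._partner = [-1] * len(self.sequence)
        for i, j in self.pairs:
            self._partner[i] = j
            self._partner[j] = i

    def __len__(self) -> int:
        return len(self.sequence)

    def partner(self, i: int) -> int:
        """Paired position of ``i``, or -1 if unpaired."""
        return self._partner[i]

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)


def pairs_to_dotbracket(n: int, pairs: Iterable[tuple[int, int]]) -> str:
    db = ["."] * n
    for i, j in pairs:
        db[i], db[j] = "(", ")"
    return "".join(db)


def structure_from_pairs(
    sequence: str, pairs: Iterable[tuple[int, int]]
) -> SecondaryStructure:
    pairs = tuple(sorted((min(i, j), max(i, j)) for i, j in pairs))
    return SecondaryStructure(sequence, pairs_to_dotbracket(len(sequence), pairs), pairs)


def parse_dotbracket(
    sequence: str,
    dotbracket: str,
    min_hairpin: int = 3,
    allow_gu: bool = True,
    require_canonical: bool = True,
) -> SecondaryStructure:
    """Parse a dot-bracket string into a validated structure.

    Errors identify the offending position (1-based in messages).  Pairs
    must be canonical Watson-Crick (or wobble if ``allow_gu``) unless
    ``require_canonical`` is off, and every hairpin must enclose at least
    ``min_hairpin`` unpaired bases.
    """
    sequence = sequence.upper().replace("T", "U")
    if len(sequence) != len(dotbracket):
        raise StructureError(
            f"sequence length {len(sequence)} != structure length {len(dotbracket)}"
        )
    bad = set(sequence) - RNA_ALPHABET
    if bad:
        raise StructureError(f"non-RNA symbols in sequence: {sorted(bad)}")
    stack: list[int] = []
    pairs: list[tuple[int, int]] = []
    for pos, ch in enumerate(dotbracket):
        if ch == "(":
            stack.append(pos)
        elif ch == ")":
            if not stack:
                raise StructureError(f"unbalanced ')' at position {pos + 1}")
            i = stack.pop()
            if pos - i - 1 < min_hairpin:
                raise StructureError(
                    f"pair ({i + 1},{pos + 1}) encloses {pos - i - 1} bases; "
                    f"min hairpin size is {min_hairpin}"
                )
            if require_canonical and not is_canonical(sequence[i], sequence[pos], allow_gu):
                raise StructureError(
                    f"non-canonical pair {sequence[i]}-{sequence[pos]} "
                    f"at ({i + 1},{pos + 1})"
                )
            pairs.append((i, pos))
        elif ch != ".":
            raise StructureError(f"invalid structure symbol {ch!r} at position {pos + 1}")
    if stack:
        raise StructureError(f"unbalanced '(' at position {stack[-1] + 1}")
    return SecondaryStructure(sequence, dotbracket, tuple(sorted(pairs)))


# ---------------------------------------------------------------------------
# Loop decomposition
# ---------------------------------------------------------------------------

@dataclass
class Loop:
    """One energy-bearing element of the decomposition.

    ``closing_pair`` is ``None`` only for the exterior loop.  A stack has
    exactly one branch pair and no unpaired positions; a hairpin has no
    branch pairs.  ``energy`` is filled by :func:`loop_energy` /
    :func:`annotate_energies`.
    """

    kind: str  # stack | hairpin | bulge | internal | multiloop | exterior
    closing_pair: Optional[tuple[int, int]]
    branch_pairs: list[tuple[int, int]]
    unpaired_positions: list[int]
    energy: Optional[float] = None

    @property
    def size(self) -> int:
        return len(self.unpaired_positions)

    def paired_endpoints(self) -> set[int]:
        pts = set()
        if self.closing_pair is not None:
            pts.update(self.closing_pair)
        for i, j in self.branch_pairs:
            pts.update((i, j))
        return pts


def _scan_loop(
    structure: SecondaryStructure, start: int, stop: int
) -> tuple[list[tuple[int, int]], list[int]]:
    """Branch pairs and unpaired positions in [start, stop], skipping subtrees."""
    branches: list[tuple[int, int]] = []
    unpaired: list[int] = []
    k = start
    while k <= stop:
        p = structure.partner(k)
        if p == -1:
            unpaired.append(k)
            k += 1
        else:
            branches.append((k, p))
            k = p + 1
    return branches, unpaired


def decompose_loops(structure: SecondaryStructure) -> list[Loop]:
    """Standard loop decomposition of a nested structure.

    Every pair closes exactly one loop and every unpaired position belongs
    to exactly one loop (possibly the exterior loop).  The exterior loop is
    reported first, then loops 5'->3' by closing-pair position.
    """
    loops: list[Loop] = []
    n = len(structure)
    branches, unpaired = _scan_loop(structure, 0, n - 1)
    loops.append(Loop("exterior", None, branches, unpaired))
    for (i, j) in structure.pairs:
        branches, unpaired = _scan_loop(structure, i + 1, j - 1)
        if not branches:
            kind = "hairpin"
        elif len(branches) == 1:
            k, l = branches[0]
            n1 = k - i - 1
            n2 = j - l - 1
            if n1 == 0 and n2 == 0:
                kind = "stack"
            elif n1 == 0 or n2 == 0:
                kind = "bulge"
            else:
                kind = "internal"
        else:
            kind = "multiloop"
        loops.append(Loop(kind, (i, j), branches, unpaired))
    return loops


# ---------------------------------------------------------------------------
# Loop energies
# ---------------------------------------------------------------------------

def _pair_type(seq: str, i: int, j: int) -> str:
    return seq[i] + seq[j]


def _au_penalty(seq: str, i: int, j: int, params: EnergyParams) -> float:
    return params.terminal_au if _pair_type(seq, i, j) in _AU_GU_ENDS else 0.0


def _stack_term(seq: str, i: int, j: int, k: int, l: int, params: EnergyParams) -> float:
    """Stacking of pair (i,j) on inner pair (k,l); table keyed on the inner
    pair read 3'->5'."""
    key = (_pair_type(seq, i, j), _pair_type(seq, l, k))
    try:
        return params.stack[key]
    except KeyError:
        if params.strict:
            raise EnergyError(
                f"no stacking entry for {key[0]} on {key[1]} "
                f"(pairs ({i + 1},{j + 1})/({k + 1},{l + 1}))"
            )
        return 0.0


def _hairpin_energy(seq: str, i: int, j: int, params: EnergyParams) -> float:
    return params.loop_init(params.hairpin_init, j - i - 1) + _au_penalty(seq, i, j, params)


def _two_way_energy(
    seq: str, i: int, j: int, k: int, l: int, params: EnergyParams
) -> float:
    """Energy of the stack/bulge/internal loop closed by (i,j) with inner (k,l)."""
    n1 = k - i - 1
    n2 = j - l - 1
    if n1 == 0 and n2 == 0:
        return _stack_term(seq, i, j, k, l, params)
    if n1 == 0 or n2 == 0:
        size = n1 + n2
        if size == 1:
            # single-nucleotide bulge: helix stacking is retained
            return params.loop_init(params.bulge_init, 1) + _stack_term(seq, i, j, k, l, params)
        return (
            params.loop_init(params.bulge_init, size)
            + _au_penalty(seq, i, j, params)
            + _au_penalty(seq, k, l, params)
        )
    size = n1 + n2
    asym = min(params.ninio_max, params.ninio_per_asymmetry * abs(n1 - n2))
    return (
        params.loop_init(params.internal_init, size)
        + asym
        + _au_penalty(seq, i, j, params)
        + _au_penalty(seq, k, l, params)
    )


def loop_energy(loop: Loop, sequence: str, params: EnergyParams | None = None) -> float:
    """Free energy of one loop (kcal/mol); exterior is 0 by convention."""
    params = params or default_params()
    seq = sequence.upper().replace("T", "U")
    if loop.kind == "exterior":
        return 0.0
    i, j = loop.closing_pair
    if loop.kind == "hairpin":
        return _hairpin_energy(seq, i, j, params)
    if loop.kind in ("stack", "bulge", "internal"):
        k, l = loop.branch_pairs[0]
        return _two_way_energy(seq, i, j, k, l, params)
    if loop.kind == "multiloop":
        e = (
            params.multiloop_offset
            + params.multiloop_per_branch * (1 + len(loop.branch_pairs))
            + params.multiloop_per_unpaired * len(loop.unpaired_positions)
            + _au_penalty(seq, i, j, params)
        )
        for k, l in loop.branch_pairs:
            e += _au_penalty(seq, k, l, params)
        return e
    raise EnergyError(f"unknown loop kind {loop.kind!r}")


def annotate_energies(
    loops: list[Loop], sequence: str, params: EnergyParams | None = None
) -> list[Loop]:
    """Fill ``energy`` on each loop in place; returns the same list."""
    params = params or default_params()
    for lp in loops:
        lp.energy = loop_energy(lp, sequence, params)
    return loops


def total_energy(structure: SecondaryStructure, params: EnergyParams | None = None) -> float:
    """Free energy of the whole structure: exactly the sum over its loops."""
    params = params or default_params()
    return sum(
        loop_energy(lp, structure.sequence, params) for lp in decompose_loops(structure)
    )


# ---------------------------------------------------------------------------
# Folding: Nussinov pair maximisation (oracle backend)
# ---------------------------------------------------------------------------

def fold_nussinov(
    sequence: str, min_hairpin: int = 3, allow_gu: bool = True
) -> SecondaryStructure:
    """Maximise the number of canonical nested pairs (Nussinov DP).

    The traceback is deterministic: at each subinterval, position ``i``
    is paired with the smallest partner that achieves the optimum, else
    left unpaired.  Intended as a simple, exactly-checkable backend for
    tests and demonstrations rather than a thermodynamic prediction.
    """
    seq = sequence.upper().replace("T", "U")
    n = len(seq)
    N = [[0] * n for _ in range(n)]
    for span in range(min_hairpin + 1, n):
        for i in range(n - span):
            j = i + span
            best = N[i + 1][j]
            for k in range(i + min_hairpin + 1, j + 1):
                if is_canonical(seq[i], seq[k], allow_gu):
                    inner = N[i + 1][k - 1] if k - 1 > i + 1 else 0
                    rest = N[k + 1][j] if k + 1 <= j else 0
                    best = max(best, 1 + inner + rest)
            N[i][j] = best
    pairs: list[tuple[int, int]] = []
    work = [(0, n - 1)]
    while work:
        i, j = work.pop()
        if j - i < min_hairpin + 1:
            continue
        target = N[i][j]
        if target == 0:
            continue
        chosen = None
        for k in range(i + min_hairpin + 1, j + 1):
            if is_canonical(seq[i], seq[k], allow_gu):
                inner = N[i + 1][k - 1] if k - 1 > i + 1 else 0
                rest = N[k + 1][j] if k + 1 <= j else 0
                if 1 + inner + rest == target:
                    chosen = k
                    break
        if chosen is None:
            work.append((i + 1, j))
        else:
            pairs.append((i, chosen))
            work.append((i + 1, chosen - 1))
            work.append((chosen + 1, j))
    return structure_from_pairs(seq, pairs)


# ---------------------------------------------------------------------------
# Folding: minimum free energy (Zuker-style DP)
# ---------------------------------------------------------------------------

_EPS = 1e-7


def fold_mfe(
    sequence: str,
    params: EnergyParams | None = None,
    max_internal_span: int = 30,
    min_hairpin: int = 3,
    allow_gu: bool = True,
) -> tuple[SecondaryStructure, float]:
    """Minimum-free-energy fold under the packaged nearest-neighbor model.

    Zuker-style dynamic program: ``V`` is the optimum given a closing pair,
    built from hairpin, two-way (stack/bulge/internal, total unpaired span
    capped at ``max_internal_span``) and affine multiloop cases; the
    exterior contributes 0.  The returned energy equals
    :func:`total_energy` of the returned structure by construction, and the
    traceback is deterministic (options are tried in a fixed order).
    """
    params = params or default_params()
    seq = sequence.upper().replace("T", "U")
    n = len(seq)
    if n == 0:
        return structure_from_pairs(seq, []), 0.0

    canon = [
        [is_canonical(seq[i], seq[j], allow_gu) for j in range(n)] for i in range(n)
    ]
    V = [[INF] * n for _ in range(n)]
    M = [[INF] * n for _ in range(n)]  # >=1 multiloop branch in [i, j]
    b = params.multiloop_per_branch
    c = params.multiloop_per_unpaired

    def two_way_candidates(i: int, j: int):
        for k in range(i + 1, min(i + 2 + max_internal_span, j)):
            n1 = k - i - 1
            lmin = max(k + min_hairpin + 1, j - 1 - (max_internal_span - n1))
            for l in range(j - 1, lmin - 1, -1):
                if V[k][l] < INF:
                    yield k, l

    for span in range(min_hairpin + 1, n):
        for i in range(n - span):
            j = i + span
            if canon[i][j]:
                best = _hairpin_energy(seq, i, j, params)
                for k, l in two_way_candidates(i, j):
                    e = _two_way_energy(seq, i, j, k, l, params) + V[k][l]
                    if e < best:
                        best = e
                if j - i >= 2 * (min_hairpin + 2):
                    close = (
                        params.multiloop_offset + b + _au_penalty(seq, i, j, params)
                    )
                    for k in range(i + 2, j - 1):
                        if M[i + 1][k - 1] < INF and M[k][j - 1] < INF:
                            e = close + M[i + 1][k - 1] + M[k][j - 1]
                            if e < best:
                                best = e
                V[i][j] = best
            # M: at least one branch somewhere in [i, j]
            best = INF
            if M[i][j - 1] < INF:
                best = M[i][j - 1] + c
            if M[i + 1][j] < INF:
                best = min(best, M[i + 1][j] + c)
            if V[i][j] < INF:
                best = min(best, V[i][j] + b + _au_penalty(seq, i, j, params))
            for k in range(i + 1, j + 1):
                if M[i][k - 1] < INF and M[k][j] < INF:
                    e = M[i][k - 1] + M[k][j]
                    if e < best:
                        best = e
            M[i][j] = best

    # exterior
    W = [0.0] * (n + 1)  # W[j+1] = best over prefix [0, j]
    for j in range(n):
        best = W[j]
        for i in range(j):
            if V[i][j] < INF:
                e = W[i] + V[i][j]
                if e < best:
                    best = e
        W[j + 1] = best

    pairs: list[tuple[int, int]] = []
    tasks: list[tuple[str, int, int, float]] = [("W", 0, n - 1, W[n])]
    while tasks:
        kind, i, j, target = tasks.pop()
        if kind == "W":
            # exterior: walk back from j, preferring "j unpaired" on ties,
            # else the smallest i whose pair (i, j) attains the optimum
            while j >= 0:
                if abs(W[j + 1] - W[j]) < _EPS:
                    j -= 1
                    continue
                for i2 in range(j):
                    if V[i2][j] < INF and abs(W[i2] + V[i2][j] - W[j + 1]) < _EPS:
                        tasks.append(("V", i2, j, V[i2][j]))
                        j = i2 - 1
                        break
                else:  # pragma: no cover - internal consistency guard
                    raise EnergyError(f"traceback failed in exterior at {j}")
        elif kind == "V":
            pairs.append((i, j))
            hp = _hairpin_energy(seq, i, j, params)
            if abs(hp - target) < _EPS:
                continue
            done = False
            for k, l in two_way_candidates(i, j):
                e = _two_way_energy(seq, i, j, k, l, params) + V[k][l]
                if abs(e - target) < _EPS:
                    tasks.append(("V", k, l, V[k][l]))
                    done = True
                    break
            if done:
                continue
            close = params.multiloop_offset + b + _au_penalty(seq, i, j, params)
            for k in range(i + 2, j - 1):
                if M[i + 1][k - 1] < INF and M[k][j - 1] < INF:
                    e = close + M[i + 1][k - 1] + M[k][j - 1]
                    if abs(e - target) < _EPS:
                        tasks.append(("M", i + 1, k - 1, M[i + 1][k - 1]))
                        tasks.append(("M", k, j - 1, M[k][j - 1]))
                        done = True
                        break
            if not done:  # pragma: no cover - internal consistency guard
                raise EnergyError(f"traceback failed at V({i},{j})")
        else:  # M
            while True:
                if j - 1 >= i and M[i][j - 1] < INF and abs(M[i][j - 1] + c - target) < _EPS:
                    j -= 1
                    target = M[i][j]
                    continue
                if i + 1 <= j and M[i + 1][j] < INF and abs(M[i + 1][j] + c - target) < _EPS:
                    i += 1
                    target = M[i][j]
                    continue
                if V[i][j] < INF and abs(
                    V[i][j] + b + _au_penalty(seq, i, j, params) - target
                ) < _EPS:
                    tasks.append(("V", i, j, V[i][j]))
                    break
                done = False
                for k in range(i + 1, j + 1):
                    if M[i][k - 1] < INF and M[k][j] < INF and abs(
                        M[i][k - 1] + M[k][j] - target
                    ) < _EPS:
                        tasks.append(("M", i, k - 1, M[i][k - 1]))
                        tasks.append(("M", k, j, M[k][j]))
                        done = True
                        break
                if not done:  # pragma: no cover
                    raise EnergyError(f"traceback failed at M({i},{j})")
                break

    structure = structure_from_pairs(seq, pairs)
    return structure, W[n]


# ---------------------------------------------------------------------------
# External-backend I/O (Vienna format)
# ---------------------------------------------------------------------------

_ENERGY_RE = re.compile(r"^([.()]+)\s*(?:\(\s*(-?\d+(?:\.\d+)?)\s*\))?\s*$")


def read_external_structure(
    path: str | Path,
    min_hairpin: int = 3,
    allow_gu: bool = True,
    require_canonical: bool = False,
) -> tuple[SecondaryStructure, Optional[float]]:
    """Read a Vienna-format file: sequence line, dot-bracket line, optional
    trailing ``(-123.4)`` energy.

    A leading FASTA-style ``>name`` line is accepted.  External predictors
    may emit non-canonical pairs, so canonical checking is off by default;
    the min-hairpin and balance invariants are still enforced.  Returns the
    structure and the reported energy (``None`` if absent, in which case the
    caller may recompute with :func:`total_energy`).
    """
    lines = [ln.strip() for ln in Path(path).read_text(encoding="utf-8").splitlines()]
    lines = [ln for ln in lines if ln]
    if lines and lines[0].startswith(">"):
        lines = lines[1:]
    if len(lines) < 2:
        raise StructureError(f"{path}: expected sequence and structure lines")
    sequence = lines[0].upper().replace("T", "U")
    m = _ENERGY_RE.match(lines[1])
    if not m:
        raise StructureError(f"{path}: malformed structure line {lines[1]!r}")
    dotbracket, energy_str = m.group(1), m.group(2)
    if len(dotbracket) != len(sequence):
        raise StructureError(
            f"{path}: structure length {len(dotbracket)} != sequence length {len(sequence)}"
        )
    structure = parse_dotbracket(
        sequence, dotbracket, min_hairpin=min_hairpin, allow_gu=allow_gu,
        require_canonical=require_canonical,
    )
    return structure, (float(energy_str) if energy_str is not None else None)


def write_structure(
    structure: SecondaryStructure,
    path: str | Path,
    energy: Optional[float] = None,
    name: Optional[str] = None,
) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        if name:
            fh.write(f">{name}\n")
        fh.write(structure.sequence + "\n")
        if energy is None:
            fh.write(structure.dotbracket + "\n")
        else:
            fh.write(f"{structure.dotbracket} ({energy:.2f})\n")


def loops_to_tsv(loops: list[Loop], path: str | Path) -> None:
    """Export a decomposition as TSV: kind, closing pair (1-based), size, energy."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("kind\tclosing_i\tclosing_j\tn_branches\tsize\tenergy\n")
        for lp in loops:
            ci = lp.closing_pair[0] + 1 if lp.closing_pair else ""
            cj = lp.closing_pair[1] + 1 if lp.closing_pair else ""
            e = "" if lp.energy is None else f"{lp.energy:.2f}"
            fh.write(
                f"{lp.kind}\t{ci}\t{cj}\t{len(lp.branch_pairs)}\t{lp.size}\t{e}\n"
            )
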