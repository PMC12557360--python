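"""Domain model: contracted Gaussian shells, shell pairs, point charges, batches.

All quantities are in atomic units (bohr, hartree).  A contracted shell is a
group of ``2l + 1`` real solid-harmonic Gaussians sharing a center, angular
momentum ``l`` and a fixed primitive expansion

    phi(r) = x_A^{ax} y_A^{ay} z_A^{az} * sum_k c_k exp(-zeta_k r_A^2)

Primitives are used exactly as given; no normalization is applied implicitly
(:func:`normalized_primitive_coefficients` is available when cross-checking
against engines that normalize).

The module also owns the combinatorial arithmetic of shells -- the numbers of
solid-harmonic, Cartesian and Hermite Gaussians per shell -- and the canonical
orderings of Cartesian components and Hermite triples used across the engine.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterator, Sequence

import numpy as np

__all__ = [
    "ANGSTROM_TO_BOHR",
    "L_MAX",
    "SHELL_LABELS",
    "Shell",
    "ShellPair",
    "ChargeSet",
    "Batch",
    "shell_dims",
    "herm_exact_count",
    "hermite_triples",
    "hermite_index",
    "hermite_addition_table",
    "cartesian_components",
    "make_shell_pairs",
    "random_shell",
    "read_xyz",
    "write_xyz",
    "read_gbs",
    "write_gbs",
    "read_charges",
    "normalized_primitive_coefficients",
]

#: Bohr radius in Angstrom (CODATA 2010); geometry files are Angstrom, the
#: engine works in bohr throughout.
ANGSTROM_TO_BOHR = 1.0 / 0.52917721092

#: Highest supported angular momentum of a single shell ("i" functions).
L_MAX = 6

SHELL_LABELS = "spdfghi"


class InputError(ValueError):
    """Invalid user-supplied value (geometry, basis, shell parameters)."""


# ---------------------------------------------------------------------------
# shell dimension arithmetic


@lru_cache(maxsize=None)
def shell_dims(l: int) -> tuple[int, int, int]:
    """Numbers of (solid-harmonic, Cartesian, Hermite) Gaussians for ``l``.

    A shell of angular momentum ``l`` spans ``2l + 1`` real solid harmonics
    and ``(l+1)(l+2)/2`` Cartesian monomials; the Hermite Gaussians needed to
    expand it are all derivative triples of total degree ``<= l``, of which
    there are ``(l+1)(l+2)(l+3)/6``.
    """
    l = _check_l(l)
    n_solid = 2 * l + 1
    n_cart = (l + 1) * (l + 2) // 2
    n_herm = (l + 1) * (l + 2) * (l + 3) // 6
    return n_solid, n_cart, n_herm


def herm_exact_count(l: int) -> int:
    """Number of Hermite triples of total degree exactly ``l``."""
    l = _check_l(l)
    return (l + 1) * (l + 2) // 2


def _check_l(l: int) -> int:
    if int(l) != l or l < 0:
        raise InputError(f"angular momentum must be a non-negative integer, got {l!r}")
    return int(l)


@lru_cache(maxsize=None)
def hermite_triples(L: int) -> tuple[tuple[int, int, int], ...]:
    """All Hermite triples with total degree ``<= L`` in graded order.

    Ordering is degree-major; within a degree, triples are sorted
    lexicographically descending on ``(tx, ty, tz)`` so that e.g. degree 1
    reads ``(1,0,0), (0,1,0), (0,0,1)``.  This ordering is fixed across the
    package: Hermite axes of every tensor use it.
    """
    L = _check_l(L)
    out: list[tuple[int, int, int]] = []
    for deg in range(L + 1):
        layer = [
            (tx, ty, deg - tx - ty)
            for tx in range(deg, -1, -1)
            for ty in range(deg - tx, -1, -1)
        ]
        out.extend(layer)
    return tuple(out)


@lru_cache(maxsize=None)
def hermite_index(L: int) -> dict[tuple[int, int, int], int]:
    """Triple -> position map for :func:`hermite_triples`\\ ``(L)``."""
    return {t: i for i, t in enumerate(hermite_triples(L))}


@lru_cache(maxsize=None)
def hermite_addition_table(L_bra: int, L_ket: int) -> np.ndarray:
    """Index-addition table ``T[i, j] = index(p + q)`` in the ``L_bra+L_ket`` list.

    ``i`` runs over Hermite triples of the bra range, ``j`` over the ket
    range; the sum triple is located in the combined graded list.
    """
    idx = hermite_index(L_bra + L_ket)
    bras = hermite_triples(L_bra)
    kets = hermite_triples(L_ket)
    table = np.empty((len(bras), len(kets)), dtype=np.intp)
    for i, p in enumerate(bras):
        for j, q in enumerate(kets):
            table[i, j] = idx[(p[0] + q[0], p[1] + q[1], p[2] + q[2])]
    return table


@lru_cache(maxsize=None)
def cartesian_components(l: int) -> tuple[tuple[int, int, int], ...]:
    """Cartesian quanta ``(ax, ay, az)`` of a shell, in alphabetical order.

    For d this reads xx, xy, xz, yy, yz, zz -- descending lexicographic on
    ``(ax, ay)``.
    """
    l = _check_l(l)
    return tuple(
        (ax, ay, l - ax - ay)
        for ax in range(l, -1, -1)
        for ay in range(l - ax, -1, -1)
    )


# ---------------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class Shell:
    """One contracted solid-harmonic Gaussian shell.

    Parameters
    ----------
    center
        Shell origin ``A`` in bohr.
    l
        Angular momentum, ``0 <= l <= L_MAX``.
    exponents
        Primitive exponents ``zeta_k > 0`` (bohr^-2), length ``K >= 1``.
    coefficients
        Contraction coefficients ``c_k`` applied to the unnormalized
        primitives, same length as ``exponents``.
    pure
        Solid-harmonic output flag; the public engine only produces pure
        (solid-harmonic) integrals, so this is always true.
    """

    center: np.ndarray
    l: int
    exponents: np.ndarray
    coefficients: np.ndarray
    pure: bool = True

    def __post_init__(self) -> None:
        center = np.asarray(self.center, dtype=float).reshape(3)
        exps = np.atleast_1d(np.asarray(self.exponents, dtype=float))
        coefs = np.atleast_1d(np.asarray(self.coefficients, dtype=float))
        object.__setattr__(self, "center", center)
        object.__setattr__(self, "exponents", exps)
        object.__setattr__(self, "coefficients", coefs)
        _check_l(self.l)
        if self.l > L_MAX:
            raise InputError(f"l={self.l} exceeds supported maximum {L_MAX}")
        if exps.size < 1 or exps.size != coefs.size:
            raise InputError("exponents/coefficients must be same nonzero length")
        if np.any(exps <= 0):
            raise InputError("primitive exponents must be positive")
        if not (np.all(np.isfinite(exps)) and np.all(np.isfinite(coefs))):
            raise InputError("shell parameters must be finite")

    @property
    def K(self) -> int:
        """Contraction degree."""
        return int(self.exponents.size)

    @property
    def nsolid(self) -> int:
        return 2 * self.l + 1

    @classmethod
    def dummy(cls, center: Sequence[float] = (0.0, 0.0, 0.0)) -> "Shell":
        """Zero-exponent unit s shell (a constant function).

        Pairing any shell with the dummy leaves its Gaussian product
        unchanged, which reduces an ``n``-center integral to the
        ``(n-1)``-center one exactly.  Used by the reduction oracles; it
        bypasses the positive-exponent invariant deliberately.
        """
        obj = object.__new__(cls)
        object.__setattr__(obj, "center", np.asarray(center, dtype=float).reshape(3))
        object.__setattr__(obj, "l", 0)
        object.__setattr__(obj, "exponents", np.array([0.0]))
        object.__setattr__(obj, "coefficients", np.array([1.0]))
        object.__setattr__(obj, "pure", True)
        return obj


@dataclass(frozen=True)
class ShellPair:
    """Precomputed per-primitive-pair data for a bra or ket shell product.

    For every primitive pair ``(k_a, k_b)`` the Gaussian product rule gives a
    single Hermite Gaussian center: total exponent ``zeta_p = zeta_a +
    zeta_b``, composite center ``P = (zeta_a A + zeta_b B) / zeta_p`` and the
    3-axis product prefactor ``exp(-zeta_a zeta_b |A-B|^2 / zeta_p)``.

    Attributes are flat arrays over the ``K_a * K_b`` primitive pairs, with
    the ``k_b`` index fastest.
    """

    shells: tuple[Shell, Shell]
    zeta_a: np.ndarray = field(repr=False)
    zeta_b: np.ndarray = field(repr=False)
    zeta_p: np.ndarray = field(repr=False)
    P: np.ndarray = field(repr=False)
    prefactor: np.ndarray = field(repr=False)
    coeff_product: np.ndarray = field(repr=False)

    @classmethod
    def from_shells(cls, a: Shell, b: Shell) -> "ShellPair":
        za, zb = np.meshgrid(a.exponents, b.exponents, indexing="ij")
        za, zb = za.ravel(), zb.ravel()
        zp = za + zb
        P = (za[:, None] * a.center + zb[:, None] * b.center) / zp[:, None]
        ab2 = float(np.dot(a.center - b.center, a.center - b.center))
        prefactor = np.exp(-za * zb * ab2 / zp)
        cc = np.multiply.outer(a.coefficients, b.coefficients).ravel()
        return cls(
            shells=(a, b),
            zeta_a=za,
            zeta_b=zb,
            zeta_p=zp,
            P=P,
            prefactor=prefactor,
            coeff_product=cc,
        )

    @property
    def K(self) -> int:
        return int(self.zeta_p.size)

    @property
    def L(self) -> int:
        """Total angular momentum ``l_a + l_b`` of the pair."""
        return self.shells[0].l + self.shells[1].l

    @property
    def nsolid_pair(self) -> int:
        return self.shells[0].nsolid * self.shells[1].nsolid


@dataclass(frozen=True)
class ChargeSet:
    """Point charges ``q_I`` at positions ``I`` (bohr).  May be empty."""

    charges: np.ndarray
    positions: np.ndarray

    def __post_init__(self) -> None:
        q = np.atleast_1d(np.asarray(self.charges, dtype=float))
        pos = np.asarray(self.positions, dtype=float).reshape(-1, 3)
        if q.size != pos.shape[0]:
            raise InputError("one position per charge required")
        if not (np.all(np.isfinite(q)) and np.all(np.isfinite(pos))):
            raise InputError("charges must be finite")
        object.__setattr__(self, "charges", q)
        object.__setattr__(self, "positions", pos)

    def __len__(self) -> int:
        return int(self.charges.size)

    @classmethod
    def empty(cls) -> "ChargeSet":
        return cls(np.zeros(0), np.zeros((0, 3)))


@dataclass
class Batch:
    """Homogeneous batch of shellsets processed lane-wise.

    All members share one integral class (same angular momenta and
    contraction degrees); ``lane_width`` is the analogue of the SIMD vector
    width and controls the granularity at which streaming consumers see
    results.
    """

    cls: str
    lanes: list
    lane_width: int = 8

    def __post_init__(self) -> None:
        if self.lane_width < 1:
            raise InputError("lane_width must be >= 1")
        sigs = {_shellset_signature(s) for s in self.lanes}
        if len(sigs) > 1:
            raise InputError(f"batch is not homogeneous: {sorted(sigs)}")

    def __len__(self) -> int:
        return len(self.lanes)

    def __iter__(self) -> Iterator:
        return iter(self.lanes)


def _shellset_signature(member) -> tuple:
    if isinstance(member, Shell):
        return (member.l, member.K)
    if isinstance(member, ShellPair):
        a, b = member.shells
        return (a.l, b.l, a.K, b.K)
    if isinstance(member, tuple):
        return tuple(_shellset_signature(m) for m in member)
    raise InputError(f"unsupported batch member {type(member).__name__}")


def class_tag(*ls: int) -> str:
    """Spectroscopic tag of an integral class, e.g. ``(dp|gf)`` -> 'dpgf'."""
    return "".join(SHELL_LABELS[l] for l in ls)


# ---------------------------------------------------------------------------
# operations


def make_shell_pairs(
    bra_shells: Sequence[Shell], ket_shells: Sequence[Shell]
) -> list[ShellPair]:
    """All bra x ket :class:`ShellPair` records (bra-major order)."""
    if len(bra_shells) == 0 or len(ket_shells) == 0:
        raise InputError("shell lists must be non-empty")
    return [ShellPair.from_shells(a, b) for a in bra_shells for b in ket_shells]


def random_shell(
    l: int,
    K: int,
    seed: int,
    exp_range: tuple[float, float] = (0.05, 50.0),
    center_scale: float = 0.0,
) -> Shell:
    """Random shell mimicking typical basis-set values.

    Exponents are log-uniform in ``exp_range`` (the default spans the valence
    range of common def2-type sets), contraction coefficients uniform in
    magnitude ``[0.2, 1.0]`` with random sign.  Deterministic in ``seed``.
    If ``center_scale`` is nonzero the center is uniform in the cube of that
    half-width, otherwise at the origin.
    """
    lo, hi = exp_range
    if not (0 < lo < hi):
        raise InputError(f"invalid exponent range {exp_range}")
    if K < 1:
        raise InputError("contraction degree must be >= 1")
    rng = np.random.default_rng(seed)
    exps = np.exp(rng.uniform(math.log(lo), math.log(hi), size=K))
    coefs = rng.uniform(0.2, 1.0, size=K) * rng.choice([-1.0, 1.0], size=K)
    center = (
        rng.uniform(-center_scale, center_scale, size=3)
        if center_scale
        else np.zeros(3)
    )
    return Shell(center=center, l=l, exponents=exps, coefficients=coefs)


def normalized_primitive_coefficients(shell: Shell) -> np.ndarray:
    """Coefficients rescaled so each primitive has unit L2 norm.

    Applies the standard Cartesian primitive normalization
    ``N = (2 zeta / pi)^{3/4} (4 zeta)^{l/2} / sqrt((2l-1)!!)`` for the
    ``z^l``-type component; useful when comparing against engines that store
    normalized primitives.
    """
    z = shell.exponents
    l = shell.l
    dfact = math.prod(range(2 * l - 1, 0, -2)) if l > 0 else 1
    norm = (2 * z / math.pi) ** 0.75 * (4 * z) ** (l / 2) / math.sqrt(dfact)
    return shell.coefficients * norm


# ---------------------------------------------------------------------------
# file formats


def read_xyz(text: str) -> tuple[list[str], np.ndarray]:
    """Parse standard XYZ text (Angstrom) -> (symbols, centers in bohr)."""
    lines = text.splitlines()
    if len(lines) < 2:
        raise InputError("XYZ input too short")
    try:
        natoms = int(lines[0].split()[0])
    except (IndexError, ValueError) as exc:
        raise InputError(f"line 1: bad atom count: {lines[0]!r}") from exc
    body = lines[2 : 2 + natoms]
    if len(body) < natoms:
        raise InputError(f"XYZ declares {natoms} atoms, found {len(body)}")
    symbols: list[str] = []
    coords = np.empty((natoms, 3))
    for i, line in enumerate(body):
        parts = line.split()
        if len(parts) < 4:
            raise InputError(f"line {i + 3}: expected 'El x y z', got {line!r}")
        symbols.append(parts[0])
        try:
            coords[i] = [float(p) for p in parts[1:4]]
        except ValueError as exc:
            raise InputError(f"line {i + 3}: bad coordinate in {line!r}") from exc
    return symbols, coords * ANGSTROM_TO_BOHR


def write_xyz(symbols: Sequence[str], centers_bohr: np.ndarray, comment: str = "") -> str:
    coords = np.asarray(centers_bohr) / ANGSTROM_TO_BOHR
    lines = [str(len(symbols)), comment]
    for sym, (x, y, z) in zip(symbols, coords):
        lines.append(f"{sym} {x:.12f} {y:.12f} {z:.12f}")
    return "\n".join(lines) + "\n"


_GBS_SHELL_RE = re.compile(r"^([A-Za-z]{1,2})\s+(\d+)\s+(\S+)\s*$")


def read_gbs(text: str, element: str) -> list[Shell]:
    """Parse Gaussian94 ``.gbs`` basis text for one element.

    SP shells are split into separate S and P shells.  Shells are centered
    at the origin; callers place them on atoms.
    """
    lines = text.splitlines()
    i = 0
    element = element.strip().lower()
    # locate the element block: "<El>  0"
    start = None
    while i < len(lines):
        parts = lines[i].split()
        if len(parts) == 2 and parts[0].lower() == element and parts[1] == "0":
            start = i + 1
            break
        i += 1
    if start is None:
        raise InputError(f"element {element!r} not found in basis text")
    shells: list[Shell] = []
    i = start
    while i < len(lines):
        line = lines[i].strip()
        if line.startswith("****"):
            break
        m = _GBS_SHELL_RE.match(line)
        if not m:
            raise InputError(f"line {i + 1}: expected shell header, got {line!r}")
        label, nprim = m.group(1).upper(), int(m.group(2))
        rows = []
        for j in range(nprim):
            try:
                rows.append([_gbs_float(v) for v in lines[i + 1 + j].split()])
            except (IndexError, ValueError) as exc:
                raise InputError(f"line {i + 2 + j}: bad primitive row") from exc
        i += 1 + nprim
        exps = np.array([r[0] for r in rows])
        if label == "SP":
            shells.append(Shell(np.zeros(3), 0, exps, np.array([r[1] for r in rows])))
            shells.append(Shell(np.zeros(3), 1, exps, np.array([r[2] for r in rows])))
            continue
        try:
            l = SHELL_LABELS.index(label.lower())
        except ValueError as exc:
            raise InputError(f"unsupported shell label {label!r}") from exc
        shells.append(Shell(np.zeros(3), l, exps, np.array([r[1] for r in rows])))
    return shells


def _gbs_float(s: str) -> float:
    return float(s.replace("D", "E").replace("d", "e"))


def write_gbs(element: str, shells: Sequence[Shell]) -> str:
    lines = [f"{element} 0"]
    for sh in shells:
        lines.append(f"{SHELL_LABELS[sh.l].upper()} {sh.K} 1.00")
        for z, c in zip(sh.exponents, sh.coefficients):
            lines.append(f"  {z: .12E} {c: .12E}")
    lines.append("****")
    return "\n".join(lines) + "\n"


def read_charges(text: str) -> ChargeSet:
    """Parse plain-text point charges, one ``q x y z`` (bohr) per line."""
    qs, pos = [], []
    for ln, line in enumerate(text.splitlines(), 1):
        line = line.split("#")[0].strip()
        if not line:
            continue
        parts = line.split()
        if len(parts) != 4:
            raise InputError(f"line {ln}: expected 'q x y z', got {line!r}")
        try:
            vals = [float(p) for p in parts]
        except ValueError as exc:
            raise InputError(f"line {ln}: bad number in {line!r}") from exc
        qs.append(vals[0])
        pos.append(vals[1:])
    if not qs:
        return ChargeSet.empty()
    return ChargeSet(np.array(qs), np.array(pos))
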