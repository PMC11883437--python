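"""Elemental formulas and isotopologue distribution math.

Everything downstream of the mass spectrometer rests on three primitives:

* :class:`ElementalFormula` — an element → atom-count map with safe
  element-wise arithmetic;
* :class:`ResidueTable` — peptide-bond residue compositions for the 20
  standard amino acids (free amino acid minus H2O), including each
  residue's nitrogen count ``nN(a)``;
* :func:`natural_distribution` — the probability that a molecule carries
  0, 1, 2, … extra neutrons at natural isotopic abundance, obtained by
  convolving per-element multinomial distributions.

The isotope constants are shipped as a fixed, versioned table
(``data/isotopes.tsv``) so that results do not depend on whichever
constants an environment happens to provide.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping

import numpy as np

PROTON_MASS = 1.007276466879

WATER = None  # set after ElementalFormula is defined
CARBAMIDOMETHYL = None  # +C2H3NO on cysteine (iodoacetamide alkylation)

_ELEMENT_RE = re.compile(r"([A-Z][a-z]?)(\d*)")


class UnknownResidueError(ValueError):
    """Raised when a peptide sequence contains a residue code not in the table."""


@dataclass(frozen=True)
class ElementalFormula:
    """Element symbol → non-negative atom count.

    Absent elements count as zero.  Addition and subtraction are
    element-wise; subtracting below zero raises ``ValueError`` because a
    molecule cannot contain a negative number of atoms.
    """

    counts: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self):
        clean = {}
        for el, n in dict(self.counts).items():
            n = int(n)
            if n < 0:
                raise ValueError(f"negative atom count for {el}: {n}")
            if n:
                clean[el] = n
        object.__setattr__(self, "counts", clean)

    @classmethod
    def parse(cls, text: str) -> "ElementalFormula":
        """Parse a Hill-style formula string such as ``"C5H12NOSi"``."""
        counts: dict[str, int] = {}
        pos = 0
        for m in _ELEMENT_RE.finditer(text):
            if m.start() != pos:
                raise ValueError(f"cannot parse formula {text!r} at {text[pos:]!r}")
            pos = m.end()
            el, num = m.group(1), m.group(2)
            counts[el] = counts.get(el, 0) + (int(num) if num else 1)
        if pos != len(text):
            raise ValueError(f"cannot parse formula {text!r} at {text[pos:]!r}")
        return cls(counts)

    def __getitem__(self, element: str) -> int:
        return self.counts.get(element, 0)

    def __add__(self, other: "ElementalFormula") -> "ElementalFormula":
        counts = dict(self.counts)
        for el, n in other.counts.items():
            counts[el] = counts.get(el, 0) + n
        return ElementalFormula(counts)

    def __sub__(self, other: "ElementalFormula") -> "ElementalFormula":
        counts = dict(self.counts)
        for el, n in other.counts.items():
            new = counts.get(el, 0) - n
            if new < 0:
                raise ValueError(
                    f"subtraction yields negative {el} count ({counts.get(el, 0)} - {n})"
                )
            counts[el] = new
        return ElementalFormula(counts)

    def __mul__(self, k: int) -> "ElementalFormula":
        return ElementalFormula({el: n * k for el, n in self.counts.items()})

    __rmul__ = __mul__

    def remove(self, element: str, k: int) -> "ElementalFormula":
        """Return a copy with ``k`` atoms of ``element`` removed."""
        return self - ElementalFormula({element: k})

    @property
    def n_atoms(self) -> int:
        return sum(self.counts.values())

    def to_string(self) -> str:
        order = ["C", "H", "N", "O", "S", "Si"]
        parts = []
        for el in order + sorted(set(self.counts) - set(order)):
            n = self.counts.get(el, 0)
            if n:
                parts.append(el + (str(n) if n > 1 else ""))
        return "".join(parts)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"ElementalFormula({self.to_string()})"


WATER = ElementalFormula({"H": 2, "O": 1})
CARBAMIDOMETHYL = ElementalFormula({"C": 2, "H": 3, "N": 1, "O": 1})


@dataclass(frozen=True)
class IsotopePolicy:
    """Per-element isotope masses and natural abundances.

    ``isotopes[element]`` is a list of ``(mass, abundance)`` pairs sorted by
    mass; neutron shifts are taken as the nominal mass difference from the
    lightest isotope.  ``label_element`` names the element supplied as
    tracer (nitrogen for a 15N pulse) and ``label_shift`` the neutron shift
    of its heavy isotope (1 for 15N).
    """

    isotopes: Mapping[str, tuple]
    label_element: str = "N"
    label_shift: int = 1

    def __post_init__(self):
        if self.label_element not in self.isotopes:
            raise ValueError(f"label element {self.label_element!r} not in policy")
        for el, pairs in self.isotopes.items():
            total = sum(p for _, p in pairs)
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"abundances for {el} sum to {total}, not 1")

    @classmethod
    def from_table(cls, rows: Iterable[tuple], **kw) -> "IsotopePolicy":
        table: dict[str, list] = {}
        for el, mass, ab in rows:
            table.setdefault(el, []).append((float(mass), float(ab)))
        return cls({el: tuple(sorted(v)) for el, v in table.items()}, **kw)

    def shift_distribution(self, element: str) -> np.ndarray:
        """Single-atom probability vector over neutron shifts 0, 1, 2, …"""
        pairs = self.isotopes[element]
        base = pairs[0][0]
        shifts = [int(round(m - base)) for m, _ in pairs]
        out = np.zeros(max(shifts) + 1)
        for s, (_, ab) in zip(shifts, pairs):
            out[s] += ab
        return out

    def monoisotopic_mass(self, formula: ElementalFormula) -> float:
        return sum(self.isotopes[el][0][0] * n for el, n in formula.counts.items())

    def natural_heavy_abundance(self, element: str, shift: int = 1) -> float:
        d = self.shift_distribution(element)
        return float(d[shift]) if shift < len(d) else 0.0


def _load_tsv(name: str) -> list[list[str]]:
    text = resources.files("fracsynth.data").joinpath(name).read_text()
    lines = [ln for ln in text.splitlines() if ln.strip()]
    return [ln.split("\t") for ln in lines[1:]]


def default_isotope_policy() -> IsotopePolicy:
    """The packaged isotope table (CODATA-style natural abundances)."""
    rows = [(el, float(m), float(a)) for el, m, a in _load_tsv("isotopes.tsv")]
    return IsotopePolicy.from_table(rows)


@dataclass(frozen=True)
class ResidueTable:
    """Peptide-bond residue compositions keyed by one-letter code."""

    residues: Mapping[str, ElementalFormula]

    def __post_init__(self):
        for code, f in self.residues.items():
            if f["N"] < 1:
                raise ValueError(f"residue {code} has no nitrogen")

    def formula(self, code: str) -> ElementalFormula:
        try:
            return self.residues[code]
        except KeyError:
            raise UnknownResidueError(f"unknown residue code {code!r}") from None

    def nitrogen(self, code: str) -> int:
        return self.formula(code)["N"]

    def __contains__(self, code: str) -> bool:
        return code in self.residues


def default_residue_table() -> ResidueTable:
    rows = _load_tsv("residues.tsv")
    residues = {}
    for code, _name, c, h, n, o, s in rows:
        residues[code] = ElementalFormula(
            {"C": int(c), "H": int(h), "N": int(n), "O": int(o), "S": int(s)}
        )
    return ResidueTable(residues)


# module-level defaults, loaded once
RESIDUES = default_residue_table()
ISOTOPES = default_isotope_policy()


def formula_of_peptide(
    sequence: str,
    residues: ResidueTable | None = None,
    fixed_mods: Mapping[str, ElementalFormula] | None = None,
) -> ElementalFormula:
    """Molecular formula of a peptide: Σ residue formulas + H2O termini.

    ``fixed_mods`` maps residue codes to adduct formulas added once per
    occurrence.  The default models carbamidomethylation of cysteine
    (iodoacetamide alkylation); variable modifications are not supported.
    """
    residues = residues or RESIDUES
    if fixed_mods is None:
        fixed_mods = {"C": CARBAMIDOMETHYL}
    if not sequence:
        raise ValueError("empty peptide sequence")
    total = WATER
    for ch in sequence:
        total = total + residues.formula(ch)
        if ch in fixed_mods:
            total = total + fixed_mods[ch]
    return total


def peptide_mz(sequence: str, charge: int, residues: ResidueTable | None = None,
               policy: IsotopePolicy | None = None) -> float:
    """Theoretical monoisotopic m/z of ``[M + zH]^z+``."""
    policy = policy or ISOTOPES
    mass = policy.monoisotopic_mass(formula_of_peptide(sequence, residues))
    return (mass + charge * PROTON_MASS) / charge


def _power_convolve(single: np.ndarray, n: int, n_peaks: int) -> np.ndarray:
    """``single`` convolved with itself ``n`` times, truncated to ``n_peaks``."""
    result = np.zeros(n_peaks)
    result[0] = 1.0
    base = single[:n_peaks]
    while n:
        if n & 1:
            result = np.convolve(result, base)[:n_peaks]
        n >>= 1
        if n:
            base = np.convolve(base, base)[:n_peaks]
    return result


def natural_distribution(
    formula: ElementalFormula,
    policy: IsotopePolicy | None = None,
    n_peaks: int = 8,
) -> np.ndarray:
    """P(molecule carries i extra neutrons), i = 0 … n_peaks-1.

    The per-element single-atom shift distributions are raised to the
    atom-count power by repeated convolution (binary exponentiation) and
    multiplied together, truncating at ``n_peaks`` throughout.  The tail
    beyond ``n_peaks`` is dropped, so the entries sum to ≤ 1.
    """
    if n_peaks < 1:
        raise ValueError("n_peaks must be >= 1")
    policy = policy or ISOTOPES
    out = np.zeros(n_peaks)
    out[0] = 1.0
    for el, n in formula.counts.items():
        if n == 0:
            continue
        single = policy.shift_distribution(el)
        out = np.convolve(out, _power_convolve(single, n, n_peaks))[:n_peaks]
    return out


@dataclass(frozen=True)
class LabelableCount:
    """Nitrogen bookkeeping for one peptide against the soluble pools."""

    n_total_n: int
    n_labelable: int
    breakdown: tuple  # (residue, position, nN, e_a, labelable)


def count_labelable_atoms(
    sequence: str,
    pool_enrichments: Mapping[str, float],
    residues: ResidueTable | None = None,
) -> LabelableCount:
    """Split a peptide's N atoms into labelable and non-labelable sets.

    An atom is labelable when the soluble pool of its residue's amino acid
    shows non-zero tracer enrichment ``e_a``.  Residues absent from the
    pool table (e.g. histidine and arginine below the GC–MS detection
    limit) contribute ``e_a = 0`` and are excluded.
    """
    residues = residues or RESIDUES
    breakdown = []
    n_total = 0
    n_lab = 0
    for pos, ch in enumerate(sequence):
        n_n = residues.nitrogen(ch)
        e_a = float(pool_enrichments.get(ch, 0.0))
        labelable = e_a > 0
        n_total += n_n
        if labelable:
            n_lab += n_n
        breakdown.append((ch, pos, n_n, e_a, labelable))
    return LabelableCount(n_total, n_lab, tuple(breakdown))
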