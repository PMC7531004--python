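"""Combinatorial library design and mass bookkeeping for gramicidin A analogues.

Gramicidin A is a linear 15-mer peptide antibiotic with alternating D/L
chirality, an N-terminal formyl cap and a C-terminal ethanolamide cap.  The
one-bead-one-compound (OBOC) library modelled here keeps nine scaffold
positions fixed (residues 1-3, 5, 7, 9, 11, 13 and 15, 1-based) and
randomises the six D-configured positions 4, 6, 8, 10, 12 and 14 over four
residues: D-Leu (L, 113 Da nominal), D-Val (V, 99), D-Thr (T, 101) and
D-N(gamma)-methylasparagine ("Asm"; machine code ``Z``, displayed as N',
128).  That gives 4**6 = 4096 distinct sequences, one per bead.

Masses are carried in three modes -- nominal (integer), average and
monoisotopic -- because fragment-ladder decoding is an integer-arithmetic
argument while molecular weights are quoted on the average scale (the capped
parent rounds to 1882 Da).  Residue masses come from standard amino-acid
compositions (:mod:`pyteomics.mass`); Asm is Asn plus one methylene.  D/L
chirality does not change mass and is carried as display metadata only.
"""

from __future__ import annotations

import itertools
import json
import math
from collections import Counter
from collections.abc import Iterable, Iterator, Mapping, Sequence
from dataclasses import dataclass, field
from enum import Enum
from functools import lru_cache
from pathlib import Path

import numpy as np
from pyteomics import mass as _pmass

__all__ = [
    "MassMode",
    "ResidueSpec",
    "PositionSlot",
    "LibraryScheme",
    "PeptideSequence",
    "CoverageSpec",
    "CoverageResult",
    "DegenerateMassGroup",
    "VariableComposition",
    "build_default_scheme",
    "enumerate_library",
    "peptide_mass",
    "variable_composition",
    "mass_degeneracy_audit",
    "coverage_analytic",
    "coverage_simulate",
    "write_fasta",
    "read_fasta",
    "PARENT_SEQUENCE",
]


class MassMode(str, Enum):
    """Mass scale: integer nominal units, chemical average, or monoisotopic."""

    NOMINAL = "nominal"
    AVERAGE = "average"
    MONOISOTOPIC = "monoisotopic"


def _mass_triplet(composition) -> dict[MassMode, float]:
    mono = _pmass.calculate_mass(composition=composition)
    avg = _pmass.calculate_mass(composition=composition, average=True)
    return {
        MassMode.NOMINAL: float(round(mono)),
        MassMode.AVERAGE: avg,
        MassMode.MONOISOTOPIC: mono,
    }


#: Mass of water (added once per peptide: the chain termini before capping).
WATER: Mapping[MassMode, float] = _mass_triplet(_pmass.Composition(formula="H2O"))

#: Proton mass for singly protonated ions ([M+H]+); 1 in nominal mode.
PROTON: Mapping[MassMode, float] = {
    MassMode.NOMINAL: 1.0,
    MassMode.AVERAGE: 1.00727646688,
    MassMode.MONOISOTOPIC: 1.00727646688,
}

# N-formylation replaces one amide H with CHO: net +CO.
_FORMYL_DELTA = _mass_triplet(_pmass.Composition(formula="CO"))
# C-terminal ethanolamide replaces the acid -OH with -NH-CH2CH2-OH: net +C2H5N.
_ETHANOLAMIDE_DELTA = _mass_triplet(_pmass.Composition(formula="C2H5N"))


@dataclass(frozen=True)
class ResidueSpec:
    """One amino-acid residue (chain unit, i.e. amino acid minus water).

    ``hbond_forming`` marks the library's hydrogen-bond-forming class:
    true for Thr (side-chain hydroxyl) and Asm (side-chain amide), false
    for the aliphatic/aromatic residues.
    """

    code: str
    display_name: str
    nominal_mass: int
    average_mass: float
    monoisotopic_mass: float
    hbond_forming: bool = False

    def mass(self, mode: MassMode) -> float:
        if mode is MassMode.NOMINAL:
            return float(self.nominal_mass)
        if mode is MassMode.AVERAGE:
            return self.average_mass
        return self.monoisotopic_mass


def _residue(code: str, display_name: str, composition, hbond: bool = False) -> ResidueSpec:
    t = _mass_triplet(composition)
    return ResidueSpec(
        code=code,
        display_name=display_name,
        nominal_mass=int(t[MassMode.NOMINAL]),
        average_mass=t[MassMode.AVERAGE],
        monoisotopic_mass=t[MassMode.MONOISOTOPIC],
        hbond_forming=hbond,
    )


def _standard_residues() -> dict[str, ResidueSpec]:
    table = {
        c: _residue(c, c, _pmass.std_aa_comp[c], hbond=(c == "T"))
        for c in "ACDEFGHIKLMNPQRSTVWY"
    }
    # Asm = Asn + CH2 (N-gamma-methylasparagine); displayed as N'.
    table["Z"] = _residue(
        "Z", "N'", _pmass.std_aa_comp["N"] + _pmass.Composition(formula="CH2"), hbond=True
    )
    return table


STANDARD_RESIDUES: Mapping[str, ResidueSpec] = _standard_residues()

#: Capped gramicidin A: fVGALAVVVWLWLWLW-ethanolamide, one-letter codes.
PARENT_SEQUENCE = "VGALAVVVWLWLWLW"


@dataclass(frozen=True)
class PositionSlot:
    """One of the 15 chain positions: fixed residue or randomised alphabet."""

    fixed: str | None = None
    alphabet: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if (self.fixed is None) == (not self.alphabet):
            raise ValueError("slot must be either fixed or carry a variable alphabet")

    @property
    def is_variable(self) -> bool:
        return self.fixed is None

    @staticmethod
    def fixed_slot(code: str) -> "PositionSlot":
        return PositionSlot(fixed=code)

    @staticmethod
    def variable_slot(alphabet: Sequence[str]) -> "PositionSlot":
        return PositionSlot(alphabet=tuple(alphabet))


@dataclass(frozen=True, eq=False)
class LibraryScheme:
    """The library blueprint: positions, residue masses and terminal caps.

    Compared and hashed by identity; the default scheme is a cached
    singleton, so sequences generated from it share one object.
    """

    name: str
    positions: tuple[PositionSlot, ...]
    residues: Mapping[str, ResidueSpec]
    n_term_cap_delta: Mapping[MassMode, float]
    c_term_cap_delta: Mapping[MassMode, float]
    parent: str | None = None

    @property
    def n_positions(self) -> int:
        return len(self.positions)

    @property
    def variable_positions(self) -> tuple[int, ...]:
        """0-based indices of the randomised positions, ascending."""
        return tuple(i for i, p in enumerate(self.positions) if p.is_variable)

    @property
    def alphabets(self) -> tuple[tuple[str, ...], ...]:
        return tuple(p.alphabet for p in self.positions if p.is_variable)

    @property
    def variable_alphabet(self) -> tuple[str, ...]:
        """Union of variable-position alphabets, in first-seen order."""
        seen: dict[str, None] = {}
        for alpha in self.alphabets:
            for c in alpha:
                seen.setdefault(c)
        return tuple(seen)

    @property
    def library_size(self) -> int:
        return math.prod(len(a) for a in self.alphabets) if self.alphabets else 1

    def residue(self, code: str) -> ResidueSpec:
        try:
            return self.residues[code]
        except KeyError:
            raise KeyError(f"unknown residue code {code!r} in scheme {self.name!r}") from None

    def validate(self, residues: str) -> None:
        if len(residues) != self.n_positions:
            raise ValueError(
                f"sequence length {len(residues)} != scheme length {self.n_positions}"
            )
        for i, (c, slot) in enumerate(zip(residues, self.positions), start=1):
            if slot.is_variable:
                if c not in slot.alphabet:
                    raise ValueError(
                        f"residue {c!r} at position {i} not in alphabet {slot.alphabet}"
                    )
            elif c != slot.fixed:
                raise ValueError(
                    f"fixed position {i} must carry {slot.fixed!r}, got {c!r}"
                )

    # ---- JSON serialization -------------------------------------------------

    def to_json(self) -> str:
        doc = {
            "name": self.name,
            "positions": [
                {"fixed": p.fixed} if not p.is_variable else {"alphabet": list(p.alphabet)}
                for p in self.positions
            ],
            "residues": {
                c: {
                    "display_name": r.display_name,
                    "nominal_mass": r.nominal_mass,
                    "average_mass": r.average_mass,
                    "monoisotopic_mass": r.monoisotopic_mass,
                    "hbond_forming": r.hbond_forming,
                }
                for c, r in sorted(self.residues.items())
            },
            "n_term_cap_delta": {m.value: v for m, v in self.n_term_cap_delta.items()},
            "c_term_cap_delta": {m.value: v for m, v in self.c_term_cap_delta.items()},
            "parent": self.parent,
        }
        return json.dumps(doc, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "LibraryScheme":
        doc = json.loads(text)
        positions = tuple(
            PositionSlot.fixed_slot(p["fixed"])
            if "fixed" in p
            else PositionSlot.variable_slot(p["alphabet"])
            for p in doc["positions"]
        )
        residues = {
            c: ResidueSpec(code=c, **r) for c, r in doc["residues"].items()
        }
        return cls(
            name=doc["name"],
            positions=positions,
            residues=residues,
            n_term_cap_delta={MassMode(k): v for k, v in doc["n_term_cap_delta"].items()},
            c_term_cap_delta={MassMode(k): v for k, v in doc["c_term_cap_delta"].items()},
            parent=doc.get("parent"),
        )


@dataclass(frozen=True)
class PeptideSequence:
    """A concrete capped 15-mer; equality and hashing use the residue string."""

    residues: str
    scheme: LibraryScheme = field(compare=False, repr=False)

    def __post_init__(self) -> None:
        self.scheme.validate(self.residues)

    def serialize(self) -> str:
        return self.residues

    @classmethod
    def parse(cls, text: str, scheme: LibraryScheme) -> "PeptideSequence":
        return cls(residues=text.strip().upper(), scheme=scheme)

    @property
    def is_parent(self) -> bool:
        return self.scheme.parent is not None and self.residues == self.scheme.parent

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.residues


@lru_cache(maxsize=None)
def build_default_scheme() -> LibraryScheme:
    """The gramicidin A OBOC scheme.

    Fixed scaffold: Val1, Gly2, Ala3, Ala5, Val7, Trp9, Trp11, Trp13, Trp15.
    Variable positions 4, 6, 8, 10, 12, 14 each draw from {L, V, T, Z};
    the parent carries L at 4/10/12/14 and V at 6/8.  Alphabet order is
    [L, V, T, Z]: the two aliphatic residues first, then the two
    hydrogen-bond formers.
    """
    fixed = {1: "V", 2: "G", 3: "A", 5: "A", 7: "V", 9: "W", 11: "W", 13: "W", 15: "W"}
    variable = {4, 6, 8, 10, 12, 14}
    alphabet = ("L", "V", "T", "Z")
    positions = tuple(
        PositionSlot.variable_slot(alphabet) if i in variable else PositionSlot.fixed_slot(fixed[i])
        for i in range(1, 16)
    )
    codes = set(fixed.values()) | set(alphabet)
    residues = {c: STANDARD_RESIDUES[c] for c in sorted(codes)}
    return LibraryScheme(
        name="gramicidinA-oboc-4096",
        positions=positions,
        residues=residues,
        n_term_cap_delta=dict(_FORMYL_DELTA),
        c_term_cap_delta=dict(_ETHANOLAMIDE_DELTA),
        parent=PARENT_SEQUENCE,
    )


def enumerate_library(scheme: LibraryScheme) -> Iterator[PeptideSequence]:
    """Yield every library member exactly once, in canonical order.

    Canonical order is a base-``|alphabet|`` odometer over the variable
    positions in ascending residue number, the last variable position
    cycling fastest, with each alphabet in its declared order.
    """
    template = [p.fixed or "" for p in scheme.positions]
    var_idx = scheme.variable_positions
    for combo in itertools.product(*scheme.alphabets):
        for i, c in zip(var_idx, combo):
            template[i] = c
        yield PeptideSequence(residues="".join(template), scheme=scheme)


def peptide_mass(seq: PeptideSequence, mode: MassMode = MassMode.AVERAGE) -> float:
    """Capped peptide mass: residue sum + water + formyl + ethanolamide deltas."""
    scheme = seq.scheme
    total = sum(scheme.residue(c).mass(mode) for c in seq.residues)
    return total + WATER[mode] + scheme.n_term_cap_delta[mode] + scheme.c_term_cap_delta[mode]


@dataclass(frozen=True)
class VariableComposition:
    """Residue counts over the variable positions of one sequence."""

    counts: Mapping[str, int]
    hbond_count: int

    def total(self) -> int:
        return sum(self.counts.values())

    def as_tuple(self) -> tuple[tuple[str, int], ...]:
        return tuple(sorted(self.counts.items()))


def variable_composition(seq: PeptideSequence) -> VariableComposition:
    """Count each alphabet residue at the variable positions.

    ``hbond_count`` is the number of hydrogen-bond-forming residues
    (T plus Asm) among them -- the quantity that defines subgroups
    B0/B1/B2 downstream.
    """
    scheme = seq.scheme
    counts = Counter({c: 0 for c in scheme.variable_alphabet})
    for i in scheme.variable_positions:
        counts[seq.residues[i]] += 1
    hbond = sum(n for c, n in counts.items() if scheme.residue(c).hbond_forming)
    return VariableComposition(counts=dict(counts), hbond_count=hbond)


@dataclass(frozen=True)
class DegenerateMassGroup:
    """Compositions whose capped parent masses coincide within tolerance."""

    mass: float
    compositions: tuple[tuple[tuple[str, int], ...], ...]


def _all_compositions(scheme: LibraryScheme) -> list[tuple[tuple[str, int], ...]]:
    alphabet = scheme.variable_alphabet
    k = len(scheme.variable_positions)
    comps = []
    for combo in itertools.combinations_with_replacement(alphabet, k):
        counts = Counter({c: 0 for c in alphabet})
        counts.update(combo)
        comps.append(tuple(sorted(counts.items())))
    return comps


def mass_degeneracy_audit(
    scheme: LibraryScheme,
    mode: MassMode = MassMode.NOMINAL,
    tolerance: float = 0.0,
) -> list[DegenerateMassGroup]:
    """Partition variable-position compositions by capped parent mass.

    Sequences sharing a composition share a parent mass, so the parent ion
    alone cannot tell them apart; compositions whose masses also coincide
    (within ``tolerance``) are mutually indistinguishable without the
    fragment ladder.  Returns every group of two or more compositions,
    ascending in mass, compositions sorted lexicographically.

    In the default scheme at nominal masses, {4L,1V,1T} and {4V,2Z} both
    sum to 652 over the variable positions.
    """
    if tolerance < 0:
        raise ValueError("tolerance must be >= 0")
    fixed_mass = sum(
        scheme.residue(p.fixed).mass(mode) for p in scheme.positions if not p.is_variable
    )
    base = fixed_mass + WATER[mode] + scheme.n_term_cap_delta[mode] + scheme.c_term_cap_delta[mode]
    comps = _all_compositions(scheme)
    masses = np.array(
        [base + sum(scheme.residue(c).mass(mode) * n for c, n in comp) for comp in comps]
    )
    order = np.argsort(masses, kind="stable")
    groups: list[DegenerateMassGroup] = []
    current: list[int] = []
    for idx in order:
        if current and masses[idx] - masses[current[-1]] > tolerance + 1e-9:
            if len(current) > 1:
                members = tuple(sorted(comps[i] for i in current))
                groups.append(DegenerateMassGroup(float(np.mean(masses[current])), members))
            current = []
        current.append(int(idx))
    if len(current) > 1:
        members = tuple(sorted(comps[i] for i in current))
        groups.append(DegenerateMassGroup(float(np.mean(masses[current])), members))
    return groups


def coverage_analytic(n_sequences: int, n_beads: int) -> float:
    """Expected fraction of sequences drawn at least once.

    Beads are i.i.d. uniform draws with replacement from the library
    (split-and-mix randomisation), so a given sequence is missed with
    probability (1 - 1/N)^B and the expected coverage is 1 - (1 - 1/N)^B.
    At N = 4096 and B = 13,584 this is 0.9637 -- the >= 96% design claim
    behind the threefold bead excess.
    """
    if n_sequences < 1:
        raise ValueError("library size must be >= 1")
    if n_beads < 0:
        raise ValueError("bead count must be >= 0")
    return 1.0 - (1.0 - 1.0 / n_sequences) ** n_beads


@dataclass(frozen=True)
class CoverageSpec:
    """Monte-Carlo coverage experiment: B uniform draws from N sequences."""

    library_size: int
    n_beads: int
    replicates: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        if self.library_size < 1:
            raise ValueError("library size must be >= 1")
        if self.n_beads < 0 or self.replicates < 1:
            raise ValueError("n_beads must be >= 0 and replicates >= 1")


@dataclass(frozen=True)
class CoverageResult:
    unique_fractions: tuple[float, ...]
    appearance_histogram: Mapping[int, int]

    @property
    def mean_unique_fraction(self) -> float:
        return float(np.mean(self.unique_fractions))

    @property
    def se_unique_fraction(self) -> float:
        arr = np.asarray(self.unique_fractions)
        if arr.size < 2:
            return float("nan")
        return float(arr.std(ddof=1) / math.sqrt(arr.size))


def coverage_simulate(spec: CoverageSpec) -> CoverageResult:
    """Simulate bead draws; reproducible given the seed.

    Per replicate, draws are multinomial over the N sequences; the unique
    fraction is the share of sequences with count >= 1.  The aggregated
    appearance histogram (count k -> number of sequence slots, pooled over
    replicates, including k = 0) approaches Binomial(B, 1/N) expectations.
    """
    rng = np.random.default_rng(spec.seed)
    p = np.full(spec.library_size, 1.0 / spec.library_size)
    fractions = []
    hist = Counter()
    for _ in range(spec.replicates):
        counts = rng.multinomial(spec.n_beads, p)
        fractions.append(float(np.mean(counts > 0)))
        binc = np.bincount(counts)
        for k, n in enumerate(binc):
            if n:
                hist[int(k)] += int(n)
    return CoverageResult(
        unique_fractions=tuple(fractions),
        appearance_histogram=dict(sorted(hist.items())),
    )


# ---- sequence file IO -------------------------------------------------------


def write_fasta(seqs: Iterable[PeptideSequence], path: str | Path, ids: Sequence[str] | None = None) -> None:
    """Write sequences as FASTA records (default ids ``bead_00001`` ...)."""
    from Bio.Seq import Seq
    from Bio.SeqIO import write as _write
    from Bio.SeqRecord import SeqRecord

    records = []
    for i, s in enumerate(seqs):
        rid = ids[i] if ids is not None else f"bead_{i + 1:05d}"
        records.append(SeqRecord(Seq(s.residues), id=rid, description=""))
    _write(records, str(path), "fasta")


def read_fasta(path: str | Path, scheme: LibraryScheme) -> list[tuple[str, PeptideSequence]]:
    from Bio.SeqIO import parse as _parse

    out = []
    for rec in _parse(str(path), "fasta"):
        out.append((rec.id, PeptideSequence.parse(str(rec.seq), scheme)))
    return out
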