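"""Five-stage triage of the bead-derived peptide solutions.

Each well holds the peptide released from one bead and carries three
readouts: H+/Na+ transport activity (normalised to the parent peptide),
P388 cell viability (%), and growth-inhibition flags for Streptococcus
pyogenes at three dilutions of the 15 uM stock (640-, 160- and 40-fold,
i.e. 23, 94 and 380 nM).  The triage is:

1. normalise transport to the parent control;
2. keep transport-positive wells (relative activity >= 1);
3. split by cytotoxicity: group A (viability <= 20%), group B
   (viability >= 30%), with the deliberate buffer (20, 30) kept as an
   explicit ``gap`` label rather than forced into either group;
4. code antibacterial potency by the highest effective dilution
   (+++ at 640-fold, ++ at 160-fold, + at 40-fold, - none);
5. deduplicate decoded sequences into compounds, subgroup group B by the
   number of hydrogen-bond-forming residues (B0/B1/B2), and apply the
   representative-selection rules.

A compound is group A if any of its wells is A, else group B if any is B:
"not found as group A" is a well-level exclusion.  Ambiguously decoded
wells never contribute to compounds; they are tallied in the run report.
"""

from __future__ import annotations

import warnings
from collections import defaultdict
from collections.abc import Iterable, Sequence
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from enum import Enum, IntEnum

from .library_design import LibraryScheme, PeptideSequence, variable_composition

__all__ = [
    "PotencyCode",
    "GroupLabel",
    "Subgroup",
    "WellRecord",
    "CompoundRecord",
    "SelectionReport",
    "InconsistentDilutionFlags",
    "normalize_transport",
    "assign_group",
    "antibacterial_code",
    "screening_concentration",
    "deduplicate",
    "assign_subgroup",
    "select_representatives",
    "classify_wells",
]


class PotencyCode(IntEnum):
    """Antibacterial potency, ordered: +++ > ++ > + > -."""

    NONE = 0
    SINGLE = 1
    DOUBLE = 2
    TRIPLE = 3

    @property
    def symbol(self) -> str:
        return {0: "-", 1: "+", 2: "++", 3: "+++"}[int(self)]

    @classmethod
    def from_symbol(cls, s: str) -> "PotencyCode":
        table = {"-": cls.NONE, "+": cls.SINGLE, "++": cls.DOUBLE, "+++": cls.TRIPLE}
        try:
            return table[s.strip()]
        except KeyError:
            raise ValueError(f"unknown potency symbol {s!r}") from None


class GroupLabel(str, Enum):
    A = "A"
    B = "B"
    GAP = "gap"
    TRANSPORT_NEGATIVE = "transport_negative"


class Subgroup(str, Enum):
    B0 = "B0"
    B1 = "B1"
    B2 = "B2"
    B3PLUS = "B3plus"
    NA = "n/a"


class InconsistentDilutionFlags(UserWarning):
    """Inhibition reported at a higher dilution but not a lower one."""


@dataclass
class WellRecord:
    """One bead-derived solution with its three assay readouts."""

    well_id: str
    transport_relative: float
    viability_pct: float | None
    abx_inhibition: tuple[bool, bool, bool]  # at 640-, 160-, 40-fold dilution
    sequence: str | None = None
    decode_status: str | None = None  # "unique" / "ambiguous" / "no_match"

    @property
    def potency(self) -> PotencyCode:
        return antibacterial_code(*self.abx_inhibition)


def normalize_transport(raw_response: float, parent_response: float) -> float:
    """Relative transport activity: raw fluorescence change / parent control."""
    if parent_response <= 0:
        raise ValueError(f"parent transport response must be > 0, got {parent_response}")
    return raw_response / parent_response


# Viability thresholds (%): more toxic -> A, less toxic -> B.
VIABILITY_A_MAX = 20.0
VIABILITY_B_MIN = 30.0


def assign_group(well: WellRecord) -> GroupLabel:
    """Stage-2/3 label; transport-negative wells bypass the viability split."""
    if well.transport_relative < 1.0:
        return GroupLabel.TRANSPORT_NEGATIVE
    if well.viability_pct is None:
        raise ValueError(f"well {well.well_id}: transport-positive but viability missing")
    if well.viability_pct <= VIABILITY_A_MAX:
        return GroupLabel.A
    if well.viability_pct >= VIABILITY_B_MIN:
        return GroupLabel.B
    return GroupLabel.GAP


def antibacterial_code(inhib_640: bool, inhib_160: bool, inhib_40: bool) -> PotencyCode:
    """Code by the highest effective dilution (640-fold is most dilute).

    Inhibition at a higher dilution (lower concentration) should imply
    inhibition at the lower dilutions; an inconsistent triple is repaired
    to the highest dilution showing inhibition, with a warning.
    """
    flags = (inhib_640, inhib_160, inhib_40)
    monotone = (not inhib_640 or inhib_160) and (not inhib_160 or inhib_40)
    if not monotone:
        warnings.warn(
            f"inconsistent dilution flags {flags}: coded by the highest "
            "dilution showing inhibition",
            InconsistentDilutionFlags,
            stacklevel=2,
        )
    if inhib_640:
        return PotencyCode.TRIPLE
    if inhib_160:
        return PotencyCode.DOUBLE
    if inhib_40:
        return PotencyCode.SINGLE
    return PotencyCode.NONE


def _round_sig(x: float, sig: int) -> float:
    if x == 0:
        return 0.0
    d = Decimal(repr(x))
    shift = sig - 1 - int(d.copy_abs().log10().to_integral_value(rounding="ROUND_FLOOR"))
    q = d.scaleb(shift).to_integral_value(rounding=ROUND_HALF_UP)
    return float(q.scaleb(-shift))


def screening_concentration(stock_uM: float, fold_dilution: float) -> float:
    """Assay concentration in nM, rounded to 2 significant figures.

    The 15 uM bead stock at 640-, 160- and 40-fold dilution gives the
    three antibacterial assay points 23, 94 and 380 nM.
    """
    if stock_uM <= 0:
        raise ValueError("stock concentration must be > 0")
    if fold_dilution < 1:
        raise ValueError("fold dilution must be >= 1")
    return _round_sig(stock_uM * 1000.0 / fold_dilution, 2)


@dataclass
class CompoundRecord:
    """A deduplicated unique sequence with its screen-level summary."""

    sequence: str
    appearance_frequency: int
    group: GroupLabel
    subgroup: Subgroup = Subgroup.NA
    best_potency: PotencyCode = PotencyCode.NONE
    is_parent: bool = False
    hbond_count: int = 0
    n_abx_active_wells: int = 0
    has_group_a_well: bool = False
    well_ids: tuple[str, ...] = ()


def deduplicate(
    wells: Iterable[WellRecord], scheme: LibraryScheme
) -> tuple[list[CompoundRecord], dict]:
    """Collapse uniquely decoded wells into one record per sequence.

    Group consensus: A if any well is A, else B if any is B, else the best
    remaining label.  ``appearance_frequency`` counts contributing wells.
    Wells without a unique decoding are excluded and tallied in the report.
    """
    by_seq: dict[str, list[WellRecord]] = defaultdict(list)
    n_total = n_ambiguous = n_no_match = n_undecoded = 0
    for w in wells:
        n_total += 1
        if w.decode_status == "unique" and w.sequence:
            by_seq[w.sequence].append(w)
        elif w.decode_status == "ambiguous":
            n_ambiguous += 1
        elif w.decode_status == "no_match":
            n_no_match += 1
        else:
            n_undecoded += 1

    records: list[CompoundRecord] = []
    for seq_str in sorted(by_seq):
        group_wells = by_seq[seq_str]
        labels = {assign_group(w) for w in group_wells}
        if GroupLabel.A in labels:
            group = GroupLabel.A
        elif GroupLabel.B in labels:
            group = GroupLabel.B
        elif GroupLabel.GAP in labels:
            group = GroupLabel.GAP
        else:
            group = GroupLabel.TRANSPORT_NEGATIVE
        pep = PeptideSequence.parse(seq_str, scheme)
        comp = variable_composition(pep)
        rec = CompoundRecord(
            sequence=seq_str,
            appearance_frequency=len(group_wells),
            group=group,
            best_potency=max((w.potency for w in group_wells), default=PotencyCode.NONE),
            is_parent=pep.is_parent,
            hbond_count=comp.hbond_count,
            n_abx_active_wells=sum(w.potency > PotencyCode.NONE for w in group_wells),
            has_group_a_well=GroupLabel.A in labels,
            well_ids=tuple(w.well_id for w in group_wells),
        )
        if rec.group is GroupLabel.B:
            rec.subgroup = assign_subgroup(rec)
        records.append(rec)

    report = {
        "n_wells": n_total,
        "n_unique_decoded": sum(len(v) for v in by_seq.values()),
        "n_ambiguous_excluded": n_ambiguous,
        "n_no_match_excluded": n_no_match,
        "n_undecoded_excluded": n_undecoded,
        "n_compounds": len(records),
    }
    return records, report


def assign_subgroup(rec: CompoundRecord) -> Subgroup:
    """B0/B1/B2 by hydrogen-bond-forming residue count; >= 3 flagged B3plus."""
    if rec.group is not GroupLabel.B:
        raise ValueError(f"subgroup defined only for group B, got {rec.group.value}")
    if rec.hbond_count >= 3:
        return Subgroup.B3PLUS
    return {0: Subgroup.B0, 1: Subgroup.B1, 2: Subgroup.B2}[rec.hbond_count]


@dataclass
class SelectionReport:
    """The three representative-selection rules, reported separately.

    (i)   group-A compounds strictly more potent than the parent;
    (ii)  B0/B1 compounds found antibacterially active in >= 3 wells and
          never seen in a group-A well;
    (iii) B2 compounds with appearance frequency >= 3.
    """

    a_over_parent: list[CompoundRecord] = field(default_factory=list)
    b0_b1_recurrent_active: list[CompoundRecord] = field(default_factory=list)
    b2_recurrent: list[CompoundRecord] = field(default_factory=list)

    @property
    def selected_sequences(self) -> list[str]:
        out = []
        for rec in self.a_over_parent + self.b0_b1_recurrent_active + self.b2_recurrent:
            if rec.sequence not in out:
                out.append(rec.sequence)
        return out


def select_representatives(
    records: Sequence[CompoundRecord], parent_potency: PotencyCode
) -> SelectionReport:
    report = SelectionReport()
    for rec in records:
        if rec.group is GroupLabel.A and not rec.is_parent and rec.best_potency > parent_potency:
            report.a_over_parent.append(rec)
        if (
            rec.group is GroupLabel.B
            and rec.subgroup in (Subgroup.B0, Subgroup.B1)
            and rec.n_abx_active_wells >= 3
            and not rec.has_group_a_well
        ):
            report.b0_b1_recurrent_active.append(rec)
        if rec.group is GroupLabel.B and rec.subgroup is Subgroup.B2 and rec.appearance_frequency >= 3:
            report.b2_recurrent.append(rec)
    return report


def wells_from_tables(plates, decoded=None) -> list[WellRecord]:
    """Build wells from a plate table, optionally joined with decoder output.

    ``plates`` columns: well_id, transport_raw, parent_transport_raw,
    viability_pct, abx640, abx160, abx40 (flags as 0/1 or booleans).
    ``decoded`` columns (per :mod:`~obocscreen.msms_decoding` CSV output):
    source_id, status, sequence, ... joined on well_id.
    """
    seq_by_well: dict[str, tuple[str | None, str | None]] = {}
    if decoded is not None:
        for row in decoded.itertuples(index=False):
            seq = getattr(row, "sequence", None)
            seq_by_well[str(row.source_id)] = (
                None if (seq is None or (isinstance(seq, float))) else str(seq),
                str(row.status),
            )
    wells = []
    for row in plates.itertuples(index=False):
        wid = str(row.well_id)
        seq, status = seq_by_well.get(wid, (None, None))
        viability = getattr(row, "viability_pct", None)
        wells.append(
            WellRecord(
                well_id=wid,
                transport_relative=normalize_transport(
                    float(row.transport_raw), float(row.parent_transport_raw)
                ),
                viability_pct=None if viability is None else float(viability),
                abx_inhibition=(bool(row.abx640), bool(row.abx160), bool(row.abx40)),
                sequence=seq,
                decode_status=status,
            )
        )
    return wells


def classify_wells(
    wells: Sequence[WellRecord],
    scheme: LibraryScheme,
    parent_potency: PotencyCode | None = None,
) -> tuple[list[CompoundRecord], SelectionReport, dict]:
    """Run stages 2-5 on normalised wells and return compounds + report.

    Only group A/B wells are sequenced and deduplicated (stage 5 follows
    the triage); gap and transport-negative wells are counted but carry no
    compounds.  ``parent_potency`` defaults to the parent compound's own
    best code when the parent was recovered, else ``++``.
    """
    stage_counts = {label.value: 0 for label in GroupLabel}
    screened: list[WellRecord] = []
    for w in wells:
        label = assign_group(w)
        stage_counts[label.value] += 1
        if label in (GroupLabel.A, GroupLabel.B):
            screened.append(w)
    records, dedup_report = deduplicate(screened, scheme)
    if parent_potency is None:
        parent_recs = [r for r in records if r.is_parent]
        parent_potency = parent_recs[0].best_potency if parent_recs else PotencyCode.DOUBLE
    selection = select_representatives(records, parent_potency)
    report = {
        "stage_counts": stage_counts,
        "n_transport_positive": stage_counts["A"] + stage_counts["B"] + stage_counts["gap"],
        "parent_potency": parent_potency.symbol,
        "subgroup_counts": {
            sg.value: sum(1 for r in records if r.subgroup is sg) for sg in Subgroup
        },
        "group_counts": {
            "A": sum(1 for r in records if r.group is GroupLabel.A),
            "B": sum(1 for r in records if r.group is GroupLabel.B),
        },
        **dedup_report,
    }
    return records, selection, report
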