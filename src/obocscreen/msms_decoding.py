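"""Constrained de novo sequencing of library peptides from b/y mass ladders.

Each of the 4096 library members yields a characteristic ladder of singly
protonated b ions (N-terminal fragments, carrying the formyl cap) and
y ions (C-terminal fragments, carrying the ethanolamide cap).  Because the
four randomised residues have pairwise-distinct masses, the full ladder
identifies the sequence even though the parent mass alone does not (parent
masses collide across compositions).  Decoding is therefore a constrained
search over the 4096-member library -- never over the full residue space:
candidates are pre-filtered by precursor mass when one is present, then
ranked by the number of ladder ions found in the observed peak list.

Ion conventions (singly charged, MALDI TOF/TOF regime):

    b_i = sum(residues 1..i)        + formyl_delta       + proton
    y_j = sum(residues 15-j+1..15)  + water + ethanolamide_delta + proton

so that b_i + y_(15-i) = [M+H]+ + proton exactly, in every mass mode.
In nominal mode all quantities are integers (b offset 28 + 1, y offset
18 + 43 + 1 = 62).  Only b/y series are generated; a ions, neutral losses
and multiply charged species are out of scope.
"""

from __future__ import annotations

import io
from collections.abc import Iterable, Sequence
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

import numpy as np
from pyteomics import mgf as _mgf

from .library_design import (
    PROTON,
    WATER,
    LibraryScheme,
    MassMode,
    PeptideSequence,
    enumerate_library,
    peptide_mass,
)

__all__ = [
    "FragmentLadder",
    "PeakList",
    "DecodingStatus",
    "DecodingCandidate",
    "DecodingResult",
    "Decoder",
    "theoretical_ladder",
    "match_peaks",
    "decode_spectrum",
    "read_peaklist",
    "read_peaklists",
    "write_peaklists",
    "default_tolerance",
    "PeakListFormatError",
]


@dataclass(frozen=True)
class FragmentLadder:
    """Theoretical singly-protonated b/y ladder of one library member."""

    sequence: str
    b_ions: tuple[float, ...]
    y_ions: tuple[float, ...]
    parent_mh: float
    mode: MassMode

    @property
    def ions(self) -> np.ndarray:
        return np.array(self.b_ions + self.y_ions)


def theoretical_ladder(seq: PeptideSequence, mode: MassMode = MassMode.MONOISOTOPIC) -> FragmentLadder:
    """b1..b(n-1) and y1..y(n-1) plus [M+H]+ for a capped library peptide."""
    scheme = seq.scheme
    masses = [scheme.residue(c).mass(mode) for c in seq.residues]
    ncap = scheme.n_term_cap_delta[mode]
    ccap = scheme.c_term_cap_delta[mode]
    proton = PROTON[mode]
    water = WATER[mode]
    b = tuple(sum(masses[:i]) + ncap + proton for i in range(1, len(masses)))
    y = tuple(sum(masses[-j:]) + water + ccap + proton for j in range(1, len(masses)))
    parent_mh = peptide_mass(seq, mode) + proton
    return FragmentLadder(sequence=seq.residues, b_ions=b, y_ions=y, parent_mh=parent_mh, mode=mode)


class PeakListFormatError(ValueError):
    """Raised when a peak-list file cannot be parsed; carries a line number."""


@dataclass(frozen=True)
class PeakList:
    """Observed spectrum: m/z values sorted ascending, exact duplicates
    merged by maximum intensity on ingest."""

    mz: np.ndarray
    intensity: np.ndarray
    precursor_mh: float | None = None
    source_id: str = ""

    def __post_init__(self) -> None:
        mz = np.asarray(self.mz, dtype=float)
        inten = np.asarray(self.intensity, dtype=float)
        if mz.shape != inten.shape:
            raise ValueError("m/z and intensity arrays must have equal length")
        if np.any(mz <= 0):
            raise ValueError("m/z values must be positive")
        order = np.argsort(mz, kind="stable")
        mz, inten = mz[order], inten[order]
        if mz.size:
            uniq, inv = np.unique(mz, return_inverse=True)
            if uniq.size != mz.size:
                merged = np.zeros_like(uniq)
                np.maximum.at(merged, inv, inten)
                mz, inten = uniq, merged
        object.__setattr__(self, "mz", mz)
        object.__setattr__(self, "intensity", inten)

    def __len__(self) -> int:
        return int(self.mz.size)

    @classmethod
    def from_pairs(
        cls,
        peaks: Iterable[tuple[float, float]],
        precursor_mh: float | None = None,
        source_id: str = "",
    ) -> "PeakList":
        arr = np.array(list(peaks), dtype=float).reshape(-1, 2)
        return cls(mz=arr[:, 0], intensity=arr[:, 1], precursor_mh=precursor_mh, source_id=source_id)


class DecodingStatus(str, Enum):
    UNIQUE = "unique"
    AMBIGUOUS = "ambiguous"
    NO_MATCH = "no_match"


@dataclass(frozen=True)
class DecodingCandidate:
    sequence: str
    matched_ion_count: int
    matched_fraction: float


@dataclass(frozen=True)
class DecodingResult:
    """Ranked candidates (count desc, canonical library order on ties).

    ``unique`` iff exactly one candidate attains the top score and clears
    the acceptance threshold; co-leaders are never silently broken --
    they are all listed and the status is ``ambiguous``.
    """

    candidates: tuple[DecodingCandidate, ...]
    status: DecodingStatus
    tolerance_used: float
    source_id: str = ""

    @property
    def sequence(self) -> str | None:
        """Top sequence when decoding is unique, else None."""
        if self.status is DecodingStatus.UNIQUE:
            return self.candidates[0].sequence
        return None


def default_tolerance(mode: MassMode) -> float:
    """0 Da in integer (nominal) mode, 0.3 Da otherwise (TOF/TOF scale)."""
    return 0.0 if mode is MassMode.NOMINAL else 0.3


def _nearest_distance(targets: np.ndarray, sorted_mz: np.ndarray) -> np.ndarray:
    """Distance from each target to its nearest observed peak."""
    pos = np.searchsorted(sorted_mz, targets)
    left = sorted_mz[np.clip(pos - 1, 0, sorted_mz.size - 1)]
    right = sorted_mz[np.clip(pos, 0, sorted_mz.size - 1)]
    return np.minimum(np.abs(targets - left), np.abs(right - targets))


def match_peaks(ladder: FragmentLadder, peaks: PeakList, tolerance: float) -> tuple[int, float]:
    """Count theoretical ions with an observed peak within tolerance.

    Each theoretical ion matches at most its single nearest peak; returns
    (matched_ion_count, matched_fraction) over the 2(n-1) ladder ions.
    A tolerance of exactly 0 means equality (to float round-off), the
    integer-mode convention.
    """
    if tolerance < 0:
        raise ValueError("tolerance must be >= 0")
    ions = ladder.ions
    if len(peaks) == 0:
        return 0, 0.0
    d = _nearest_distance(ions, peaks.mz)
    count = int(np.sum(d <= tolerance + 1e-9))
    return count, count / ions.size


class _LibraryIndex:
    """Pre-computed ladders for a whole scheme: (N, 2(n-1)) ion matrix."""

    def __init__(self, scheme: LibraryScheme, mode: MassMode):
        self.scheme = scheme
        self.mode = mode
        seqs = list(enumerate_library(scheme))
        self.sequences = [s.residues for s in seqs]
        n = scheme.n_positions
        mass_of = {c: scheme.residue(c).mass(mode) for c in scheme.residues}
        res = np.array([[mass_of[c] for c in s] for s in self.sequences])
        ncap = scheme.n_term_cap_delta[mode]
        ccap = scheme.c_term_cap_delta[mode]
        proton, water = PROTON[mode], WATER[mode]
        bcum = res.cumsum(axis=1)
        b = bcum[:, : n - 1] + ncap + proton
        y = res[:, ::-1].cumsum(axis=1)[:, : n - 1] + water + ccap + proton
        self.ions = np.concatenate([b, y], axis=1)
        self.parent_mh = bcum[:, -1] + water + ncap + ccap + proton


_INDEX_CACHE: dict[tuple[int, MassMode], _LibraryIndex] = {}


def _library_index(scheme: LibraryScheme, mode: MassMode) -> _LibraryIndex:
    key = (id(scheme), mode)
    idx = _INDEX_CACHE.get(key)
    if idx is None or idx.scheme is not scheme:
        idx = _LibraryIndex(scheme, mode)
        _INDEX_CACHE[key] = idx
    return idx


class Decoder:
    """Reusable decoder over one scheme; builds the ladder index once."""

    def __init__(
        self,
        scheme: LibraryScheme,
        mode: MassMode = MassMode.MONOISOTOPIC,
        tolerance: float | None = None,
        min_matched_fraction: float = 0.5,
        max_candidates: int = 10,
    ):
        if tolerance is None:
            tolerance = default_tolerance(mode)
        if tolerance < 0:
            raise ValueError("tolerance must be >= 0")
        if not 0 < min_matched_fraction <= 1:
            raise ValueError("min_matched_fraction must be in (0, 1]")
        self.scheme = scheme
        self.mode = mode
        self.tolerance = tolerance
        self.min_matched_fraction = min_matched_fraction
        self.max_candidates = max_candidates
        self._index = _library_index(scheme, mode)

    def decode(self, peaks: PeakList) -> DecodingResult:
        tol = self.tolerance
        if len(peaks) == 0:
            return DecodingResult((), DecodingStatus.NO_MATCH, tol, peaks.source_id)
        idx = self._index
        if peaks.precursor_mh is not None:
            sel = np.flatnonzero(np.abs(idx.parent_mh - peaks.precursor_mh) <= tol + 1e-9)
        else:
            sel = np.arange(len(idx.sequences))
        if sel.size == 0:
            return DecodingResult((), DecodingStatus.NO_MATCH, tol, peaks.source_id)
        ions = idx.ions[sel]
        d = _nearest_distance(ions.ravel(), peaks.mz).reshape(ions.shape)
        counts = (d <= tol + 1e-9).sum(axis=1)
        n_ions = ions.shape[1]
        order = np.lexsort((sel, -counts))
        top = int(counts[order[0]])
        top_fraction = top / n_ions
        n_leaders = int(np.sum(counts == top))
        cands = tuple(
            DecodingCandidate(
                sequence=idx.sequences[sel[i]],
                matched_ion_count=int(counts[i]),
                matched_fraction=float(counts[i] / n_ions),
            )
            for i in order[: self.max_candidates]
        )
        if top > 0 and top_fraction >= self.min_matched_fraction:
            status = DecodingStatus.UNIQUE if n_leaders == 1 else DecodingStatus.AMBIGUOUS
        elif top == 0 and peaks.precursor_mh is not None and sel.size > 1:
            # Parent-ion-only evidence consistent with several members:
            # the parent mass narrowed the library but nothing resolves it.
            status = DecodingStatus.AMBIGUOUS
        else:
            status = DecodingStatus.NO_MATCH
        return DecodingResult(cands, status, tol, peaks.source_id)


def decode_spectrum(
    peaks: PeakList,
    scheme: LibraryScheme,
    tolerance: float | None = None,
    min_matched_fraction: float = 0.5,
    mode: MassMode = MassMode.MONOISOTOPIC,
) -> DecodingResult:
    """One-shot wrapper around :class:`Decoder` (index cached per scheme)."""
    return Decoder(
        scheme, mode=mode, tolerance=tolerance, min_matched_fraction=min_matched_fraction
    ).decode(peaks)


# ---- peak-list IO -----------------------------------------------------------


def _scan_mgf_blocks(text: str) -> None:
    """Light structural check so format errors report a line number."""
    depth = 0
    for lineno, line in enumerate(text.splitlines(), start=1):
        s = line.strip().upper()
        if s == "BEGIN IONS":
            if depth:
                raise PeakListFormatError(f"line {lineno}: nested BEGIN IONS")
            depth = 1
        elif s == "END IONS":
            if not depth:
                raise PeakListFormatError(f"line {lineno}: END IONS without BEGIN IONS")
            depth = 0
    if depth:
        raise PeakListFormatError("unterminated BEGIN IONS block at end of file")


def read_peaklists(path: str | Path, format: str = "mgf") -> list[PeakList]:
    """Read one or more peak lists from an MGF or two-column TSV file."""
    path = Path(path)
    if format == "mgf":
        text = path.read_text()
        _scan_mgf_blocks(text)
        out = []
        with _mgf.MGF(io.StringIO(text)) as reader:
            for spec in reader:
                params = spec.get("params", {})
                pep = params.get("pepmass")
                precursor = float(pep[0]) if pep else None
                out.append(
                    PeakList(
                        mz=spec["m/z array"],
                        intensity=spec["intensity array"],
                        precursor_mh=precursor,
                        source_id=str(params.get("title", "")),
                    )
                )
        return out
    if format == "tsv":
        pairs = []
        for lineno, line in enumerate(path.read_text().splitlines(), start=1):
            s = line.strip()
            if not s or s.startswith("#"):
                continue
            parts = s.split()
            if len(parts) != 2:
                raise PeakListFormatError(f"line {lineno}: expected 'mz<TAB>intensity'")
            try:
                pairs.append((float(parts[0]), float(parts[1])))
            except ValueError:
                raise PeakListFormatError(f"line {lineno}: non-numeric value") from None
        return [PeakList.from_pairs(pairs, source_id=path.stem)]
    raise ValueError(f"unknown peak-list format {format!r}")


def read_peaklist(path: str | Path, format: str = "mgf") -> PeakList:
    """Read exactly one peak list; error if an MGF holds several blocks."""
    lists = read_peaklists(path, format=format)
    if len(lists) != 1:
        raise PeakListFormatError(f"{path} holds {len(lists)} peak lists, expected 1")
    return lists[0]


def write_peaklists(peaklists: Sequence[PeakList], path: str | Path, format: str = "mgf") -> None:
    """Write peak lists; MGF floats use fixed formatting (%.4f / %.1f)."""
    path = Path(path)
    if format == "mgf":
        spectra = []
        for pl in peaklists:
            params: dict = {"title": pl.source_id}
            if pl.precursor_mh is not None:
                params["pepmass"] = pl.precursor_mh
            spectra.append(
                {"m/z array": pl.mz, "intensity array": pl.intensity, "params": params}
            )
        with path.open("w") as fh:
            _mgf.write(spectra, fh, fragment_format="%.4f %.1f", write_charges=False)
        return
    if format == "tsv":
        if len(peaklists) != 1:
            raise ValueError("TSV format stores exactly one peak list per file")
        pl = peaklists[0]
        with path.open("w") as fh:
            for mz, inten in zip(pl.mz, pl.intensity):
                fh.write(f"{mz:.4f}\t{inten:.1f}\n")
        return
    raise ValueError(f"unknown peak-list format {format!r}")
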