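"""Synthetic OBOC screens with known ground truth.

Real screen data exist only as printed aggregates, so every pipeline
stage is exercised against generated screens whose truth is recoverable:
bead draws are i.i.d. uniform over the 4096-member library (split-and-mix
randomisation), each bead yields a singly-charged b/y fragment spectrum
with Bernoulli peak deletion and Gaussian m/z jitter, and the three assay
readouts are drawn from a rule-based latent activity model.

The latent model is a test harness, not a claim about biology.  Its
per-sequence truths are deterministic (hashed from the seed and the
sequence, so a compound behaves identically in every well it occupies)
and its rates are calibrated to the published screen aggregates: roughly
600 of 13,584 wells transport-positive, sequences with three or more
hydrogen-bond-forming residues never transport-positive, and
antibacterial activity probabilities of 0.76 / 0.97 / 0.17 / 0.03 for
group-A-like compounds and subgroups B0 / B1 / B2.  Gaps from real data:
no synthesis failures or truncations, no plate effects, no correlated
assay noise, and fragment intensities carry no chemistry.
"""

from __future__ import annotations

import hashlib
import json
from collections.abc import Mapping, Sequence
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .library_design import (
    LibraryScheme,
    MassMode,
    PeptideSequence,
    enumerate_library,
    variable_composition,
)
from .msms_decoding import PeakList, theoretical_ladder, write_peaklists
from .screening_classify import PotencyCode

__all__ = [
    "LatentActivityParams",
    "GeneratorConfig",
    "SequenceTruth",
    "WellTruth",
    "SimulatedScreen",
    "latent_truth",
    "sample_beads",
    "simulate_spectrum",
    "simulate_assays",
    "simulate_screen",
    "generate_screen",
]


@dataclass(frozen=True)
class LatentActivityParams:
    """Rule-based latent activity model over variable-position composition.

    Transport: sequences with <= 2 hydrogen-bond-forming residues (T/N')
    are transport-positive with a probability that falls with the T/N'
    count; three or more T/N' residues suppress transport outright
    (multiplicative decay per extra residue), encoding the observation
    that no such sequence survived the transport filter.  Positive
    probabilities are set so that roughly 600 of 13,584 wells exceed the
    parent's activity.

    Cytotoxicity: the kill probability grows with the aliphatic content,
    dominated by Leu (group A is Leu-enriched relative to group B).

    Antibacterial activity: Bernoulli per sequence with class
    probabilities matching the published percent-active values.
    """

    transport_base: float = 1.0
    transport_penalty_per_hbond3plus: float = 0.35
    transport_pos_prob_by_hbond: tuple[float, float, float] = (0.85, 0.28, 0.025)
    cytotox_L_weight: float = 0.05
    cytotox_V_weight: float = 0.01
    abx_active_prob: Mapping[str, float] = field(
        default_factory=lambda: {"A": 0.76, "B0": 0.97, "B1": 0.17, "B2": 0.03}
    )

    def __post_init__(self) -> None:
        probs = list(self.transport_pos_prob_by_hbond) + list(self.abx_active_prob.values())
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise ValueError("probabilities must lie in [0, 1]")


@dataclass(frozen=True)
class GeneratorConfig:
    """Screen-generation settings; config + seed fully determine the data.

    Defaults mirror the full experiment: 13,584 beads over 4096
    sequences, TOF/TOF-scale m/z jitter (sd 0.05 Da), 10% fragment-peak
    dropout, and a few percentage points of assay noise.  The parent
    transport control is 55.2 fluorescence-change %.
    """

    n_beads: int = 13584
    seed: int = 0
    peak_deletion_rate: float = 0.1
    mz_noise_sd: float = 0.05
    assay_noise_sd: float = 5.0
    parent_transport_raw: float = 55.2
    spectrum_mode: MassMode = MassMode.MONOISOTOPIC
    activity: LatentActivityParams = field(default_factory=LatentActivityParams)

    def __post_init__(self) -> None:
        if not 0.0 <= self.peak_deletion_rate <= 1.0:
            raise ValueError("peak_deletion_rate must lie in [0, 1]")
        if self.n_beads < 0 or self.mz_noise_sd < 0 or self.assay_noise_sd < 0:
            raise ValueError("n_beads and noise magnitudes must be non-negative")

    def noiseless(self) -> "GeneratorConfig":
        return replace(self, peak_deletion_rate=0.0, mz_noise_sd=0.0, assay_noise_sd=0.0)

    def to_json(self) -> str:
        doc = asdict(self)
        doc["spectrum_mode"] = self.spectrum_mode.value
        doc["activity"]["abx_active_prob"] = dict(self.activity.abx_active_prob)
        return json.dumps(doc, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "GeneratorConfig":
        doc = json.loads(text)
        act = doc.pop("activity", {})
        if "transport_pos_prob_by_hbond" in act:
            act["transport_pos_prob_by_hbond"] = tuple(act["transport_pos_prob_by_hbond"])
        doc["spectrum_mode"] = MassMode(doc.get("spectrum_mode", "monoisotopic"))
        return cls(activity=LatentActivityParams(**act), **doc)


def _useq(model_seed: int, channel: str, sequence: str) -> float:
    """Deterministic per-sequence uniform in [0, 1)."""
    digest = hashlib.blake2b(
        f"{model_seed}:{channel}:{sequence}".encode(), digest_size=8
    ).digest()
    return int.from_bytes(digest, "big") / 2.0**64


@dataclass(frozen=True)
class SequenceTruth:
    """Noise-free latent activity of one sequence (same in every well)."""

    sequence: str
    transport_relative: float
    viability_pct: float
    toxic: bool
    group: str  # 'A', 'B' or 'transport_negative'
    subgroup: str  # 'B0'/'B1'/'B2'/'B3plus' for group B, else 'n/a'
    potency: str  # '-', '+', '++', '+++'
    hbond_count: int

    @property
    def abx_flags(self) -> tuple[bool, bool, bool]:
        code = PotencyCode.from_symbol(self.potency)
        return (code >= 3, code >= 2, code >= 1)


def latent_truth(
    seq: PeptideSequence, params: LatentActivityParams, model_seed: int
) -> SequenceTruth:
    """Evaluate the latent model; deterministic in (sequence, model_seed).

    The parent peptide is pinned to its published screen behaviour:
    relative transport exactly 1 (it is its own normalisation control),
    cytotoxic, antibacterially active at the middle dilution (++).
    """
    comp = variable_composition(seq)
    h = comp.hbond_count
    counts = comp.counts
    s = seq.residues

    if seq.is_parent:
        return SequenceTruth(
            sequence=s, transport_relative=1.0, viability_pct=10.0, toxic=True,
            group="A", subgroup="n/a", potency="++", hbond_count=h,
        )

    u_mag = _useq(model_seed, "transport_mag", s)
    if h >= 3:
        positive = False
        rel = (
            params.transport_base
            * params.transport_penalty_per_hbond3plus ** (h - 2)
            * (0.6 + 0.4 * u_mag)
        )
    else:
        positive = _useq(model_seed, "transport_pos", s) < params.transport_pos_prob_by_hbond[h]
        if positive:
            rel = params.transport_base * (1.05 + 0.75 * u_mag)
        else:
            rel = params.transport_base * (0.30 + 0.60 * u_mag)

    p_tox = min(
        1.0, params.cytotox_L_weight * counts.get("L", 0) + params.cytotox_V_weight * counts.get("V", 0)
    )
    toxic = _useq(model_seed, "cytotox", s) < p_tox
    u_viab = _useq(model_seed, "viability", s)
    viability = 5.0 + 10.0 * u_viab if toxic else 60.0 + 30.0 * u_viab

    if toxic:
        abx_class = "A"
    elif h <= 2:
        abx_class = f"B{h}"
    else:
        abx_class = None
    p_abx = params.abx_active_prob.get(abx_class, 0.0) if abx_class else 0.0
    active = _useq(model_seed, "abx_active", s) < p_abx
    if active:
        u_pot = _useq(model_seed, "abx_potency", s)
        potency = "+++" if u_pot < 0.15 else ("++" if u_pot < 0.60 else "+")
    else:
        potency = "-"

    if not positive:
        group, subgroup = "transport_negative", "n/a"
    elif toxic:
        group, subgroup = "A", "n/a"
    else:
        group, subgroup = "B", (f"B{h}" if h <= 2 else "B3plus")
    return SequenceTruth(
        sequence=s, transport_relative=rel, viability_pct=viability, toxic=toxic,
        group=group, subgroup=subgroup, potency=potency, hbond_count=h,
    )


def sample_beads(
    scheme: LibraryScheme, config: GeneratorConfig
) -> list[tuple[str, PeptideSequence]]:
    """I.i.d. uniform draws with replacement; ids ``well_00001`` ..."""
    rng = np.random.default_rng(config.seed)
    members = list(enumerate_library(scheme))
    idx = rng.integers(0, len(members), size=config.n_beads)
    return [(f"well_{i + 1:05d}", members[j]) for i, j in enumerate(idx)]


def simulate_spectrum(
    seq: PeptideSequence,
    config: GeneratorConfig,
    rng: np.random.Generator,
    source_id: str = "",
) -> tuple[PeakList, dict]:
    """Noisy singly-charged MALDI-type spectrum of one library member.

    Emits the theoretical b/y ladder plus the precursor; each fragment
    peak is deleted independently with ``peak_deletion_rate`` (the
    precursor always survives) and every m/z is jittered with Gaussian
    noise of sd ``mz_noise_sd``.  Returns the peak list and a provenance
    record of which ladder ions were kept.
    """
    ladder = theoretical_ladder(seq, config.spectrum_mode)
    ions = ladder.ions
    keep = rng.random(ions.size) >= config.peak_deletion_rate
    mz = list(ions[keep]) + [ladder.parent_mh]
    intensity = [100.0] * int(keep.sum()) + [300.0]
    jitter = rng.normal(0.0, config.mz_noise_sd, size=len(mz)) if config.mz_noise_sd else np.zeros(len(mz))
    precursor = mz[-1] + jitter[-1]
    peaks = PeakList(
        mz=np.asarray(mz) + jitter,
        intensity=np.asarray(intensity),
        precursor_mh=precursor,
        source_id=source_id,
    )
    n_b = len(ladder.b_ions)
    provenance = {
        "kept_b": [int(i) + 1 for i in np.flatnonzero(keep[:n_b])],
        "kept_y": [int(i) + 1 for i in np.flatnonzero(keep[n_b:])],
        "n_kept": int(keep.sum()),
        "n_ions": int(ions.size),
    }
    return peaks, provenance


def simulate_assays(
    seq: PeptideSequence,
    params: LatentActivityParams,
    config: GeneratorConfig,
    rng: np.random.Generator,
    well_id: str = "",
) -> tuple[dict, SequenceTruth]:
    """One well's assay readouts: latent truth plus Gaussian assay noise.

    Transport is reported as raw fluorescence change (%), the product of
    the latent relative activity and the parent control, so the pipeline
    exercises its own normalisation.  Dilution flags derive from the
    latent potency without noise (they are already coarse).
    """
    truth = latent_truth(seq, params, model_seed=config.seed)
    noise = rng.normal(0.0, config.assay_noise_sd, size=2) if config.assay_noise_sd else np.zeros(2)
    transport_raw = truth.transport_relative * config.parent_transport_raw + noise[0]
    viability = float(np.clip(truth.viability_pct + noise[1], 0.0, 120.0))
    f640, f160, f40 = truth.abx_flags
    panel = {
        "well_id": well_id,
        "transport_raw": float(transport_raw),
        "parent_transport_raw": config.parent_transport_raw,
        "viability_pct": viability,
        "abx640": int(f640),
        "abx160": int(f160),
        "abx40": int(f40),
    }
    return panel, truth


@dataclass
class WellTruth:
    well_id: str
    truth: SequenceTruth


@dataclass
class SimulatedScreen:
    """In-memory synthetic screen: plate rows, spectra, per-well truth."""

    plate_rows: list[dict]
    spectra: list[PeakList]
    truth: list[WellTruth]
    config: GeneratorConfig

    def plates_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.plate_rows)


def simulate_screen(scheme: LibraryScheme, config: GeneratorConfig) -> SimulatedScreen:
    """Full screen: bead draws, one spectrum and one assay panel per well."""
    rng = np.random.default_rng(config.seed + 1)
    beads = sample_beads(scheme, config)
    rows, spectra, truths = [], [], []
    for well_id, seq in beads:
        peaks, _ = simulate_spectrum(seq, config, rng, source_id=well_id)
        panel, truth = simulate_assays(seq, config.activity, config, rng, well_id=well_id)
        rows.append(panel)
        spectra.append(peaks)
        truths.append(WellTruth(well_id=well_id, truth=truth))
    return SimulatedScreen(plate_rows=rows, spectra=spectra, truth=truths, config=config)


def generate_screen(
    scheme: LibraryScheme, config: GeneratorConfig, outdir: str | Path
) -> dict[str, Path]:
    """Write plates.csv, screen.mgf, truth.json and config.json.

    Output bytes are fully determined by config + seed (fixed float
    formatting throughout).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    screen = simulate_screen(scheme, config)
    paths = {
        "plates": outdir / "plates.csv",
        "spectra": outdir / "screen.mgf",
        "truth": outdir / "truth.json",
        "config": outdir / "config.json",
    }
    df = screen.plates_frame()
    df.to_csv(paths["plates"], index=False, float_format="%.4f")
    write_peaklists(screen.spectra, paths["spectra"], format="mgf")
    truth_doc = {
        "wells": [
            {
                "well_id": wt.well_id,
                "sequence": wt.truth.sequence,
                "transport_relative": round(wt.truth.transport_relative, 6),
                "viability_pct": round(wt.truth.viability_pct, 6),
                "group": wt.truth.group,
                "subgroup": wt.truth.subgroup,
                "potency": wt.truth.potency,
                "hbond_count": wt.truth.hbond_count,
            }
            for wt in screen.truth
        ]
    }
    paths["truth"].write_text(json.dumps(truth_doc, indent=1, sort_keys=True))
    paths["config"].write_text(config.to_json())
    return paths
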