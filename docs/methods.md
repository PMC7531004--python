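# Methods

`obocscreen` models the computational side of a one-bead-one-compound
(OBOC) screen of gramicidin A analogues: library design and mass
bookkeeping, MS/MS sequence decoding, three-assay hit triage, and
SAR/dose-response statistics, together with a synthetic screen generator
that supplies ground truth for every stage. This note records the models,
conventions and numerical choices, and what the synthetic tests do and do
not demonstrate.

## Library model and mass conventions

The library scheme fixes nine of the fifteen chain positions at the
parent residues (Val1, Gly2, Ala3, Ala5, Val7, Trp9/11/13/15) and
randomises the six D-configured positions 4, 6, 8, 10, 12 and 14 over
{D-Leu, D-Val, D-Thr, D-Asm}, where Asm is N(gamma)-methylasparagine.
Machine codes are single characters (`L V T Z`, with `Z` displayed as
N'), so a sequence serialises to a 15-character string and
`parse(serialize(s)) = s`. Chirality is display metadata only; it does
not affect mass. Canonical enumeration order is a base-4 odometer over
the variable positions in ascending residue number with alphabet order
`[L, V, T, Z]` (aliphatic residues first, then the hydrogen-bond
formers), giving 4^6 = 4096 members with the parent among them.

Masses are carried in three modes. Monoisotopic and average residue
masses come from the standard amino-acid compositions in
`pyteomics.mass`; Asm is the Asn residue plus one CH2 (monoisotopic
128.0586, nominal 128). Nominal masses are the rounded monoisotopic
values and all nominal arithmetic is integer. The two caps are mass
deltas relative to the free peptide: N-formylation is +CO (mono 27.9949)
and the C-terminal ethanolamide is +C2H5N (mono 43.0422, i.e. -OH
+NH-C2H4-OH). A capped peptide mass is the residue sum + water + both
cap deltas; the parent evaluates to 1882 Da (average, rounded), and the
four variable residues carry the pairwise-distinct integer units
113/99/101/128 on which the decoding argument rests.

The parent mass alone is *not* identifying: grouping the 84
variable-position compositions by capped nominal mass yields four
collision groups, e.g. {4L,1V,1T} vs {4V,2Z} (both 652 over the variable
sites). Unique identification needs the fragment ladder.

## Coverage statistics

Split-and-mix randomisation is modelled as i.i.d. uniform sampling with
replacement, so the expected fraction of sequences present on at least
one of B beads is 1 - (1 - 1/N)^B; at N = 4096, B = 13,584 (a threefold
bead excess) this is 0.9637. The Monte-Carlo counterpart draws
multinomial bead counts per replicate and also aggregates the
appearance-frequency histogram, which approaches Binomial(B, 1/N). The
simulator is seeded and its mean agrees with the analytic value within
Monte-Carlo error (4 standard errors at 200 replicates in the unit test,
3 in the acceptance check).

## Fragment ladders and decoding

Only singly protonated b and y ions are generated (MALDI TOF/TOF
regime); a ions, neutral losses, immonium ions and higher charge states
are out of scope. Conventions:

    b_i = sum(residues 1..i)       + formyl_delta               + proton
    y_j = sum(last j residues)     + water + ethanolamide_delta + proton

which makes the complementarity b_i + y_(n-i) = [M+H]+ + proton exact in
every mode (integer offsets 28+1 for b and 18+43+1 = 62 for y in nominal
mode).

Decoding is constrained de novo: candidates are drawn only from the 4096
enumerated sequences, never from the full residue space. When a
precursor is present, candidates are pre-filtered by parent [M+H]+
within tolerance; surviving ladders are scored by the number of the
2x14 theoretical ions with an observed peak within tolerance (each ion
matched to its nearest peak). Default tolerances: 0.3 Da in
monoisotopic/average mode (TOF/TOF scale), exact match in nominal mode;
both are configurable and reported in the result. A decode is `unique`
only when a single candidate attains the top score and its matched
fraction clears the acceptance threshold (default 0.5); ties are never
silently broken -- all co-leaders are listed and the status is
`ambiguous`. A spectrum that carries only parent-ion evidence consistent
with several members (e.g. a precursor in a mass-collision group) is
likewise `ambiguous`, while an empty or unmatchable spectrum is
`no_match`. With full noiseless ladders all 4096 members decode uniquely
and correctly (asserted exhaustively), and decoding accuracy degrades
monotonically as fragment peaks are deleted.

## Hit triage

Transport activity is normalised against the parent control well
(ratio of fluorescence changes; the control must be positive).
Transport-positive means relative activity >= 1. Positive wells split by
P388 viability: <= 20% is group A (more cytotoxic), >= 30% is group B
(less cytotoxic); the deliberate buffer (20, 30) is kept as an explicit
`gap` label rather than forced into either group. Antibacterial potency
is coded by the highest effective dilution of the 15 uM stock: +++ at
640-fold (23 nM), ++ at 160-fold (94 nM), + at 40-fold (380 nM), `-`
otherwise; concentrations are reported at two significant figures,
rounding half up. An inconsistent flag triple (inhibition at a higher
dilution but not a lower one) is repaired to the highest dilution showing
inhibition and logged as a warning, since the code is defined by the
highest effective dilution.

Deduplication collapses uniquely decoded A/B wells into compounds
(sequencing follows the triage, so only A/B wells contribute);
ambiguous or unmatched wells are excluded and tallied in the run report.
Group consensus is any-A-wins, then any-B: "not found as group A" is a
well-level exclusion. Group B compounds are subgrouped by the count of
hydrogen-bond-forming residues (T plus Asm): B0/B1/B2, with >= 3 flagged
`B3plus` (handled although the latent model makes such compounds
transport-negative). Representative selection reports three rule sets
separately, with no forced total: (i) group-A compounds whose best
potency code strictly exceeds the parent's (best-code comparison, the
per-compound reading of "more potent than the parent"); (ii) B0/B1
compounds antibacterially active in >= 3 wells and never seen in a
group-A well; (iii) B2 compounds with appearance frequency >= 3.

## Dose-response, MIC and fold changes

Potencies use the Hill model
`response = bottom + (top - bottom) / (1 + (EC50/c)^h)` with bottom/top
fixed at 0/100 by default (all responses are % scales) and a free-top
variant by flag. The fit is bounded nonlinear least squares on
log10-concentration. Initialisation is a deterministic grid (13 log-EC50
points spanning the data range plus one decade each side, slopes 0.5/1/
2/4); the best grid point seeds `scipy.optimize.least_squares` with the
slope bounded in [0.05, 10]. There are no random restarts, so a fit is a
pure function of the data. A constant response returns `converged=False`
with a diagnostic rather than a fabricated EC50. On noiseless curves the
fit is exact and the closed-form inverse
`c = EC50 ((p - bottom)/(top - p))^(1/h)` reproduces EC50 at p = 50 and
the HC10 identity (10% effect). Parameter recovery on noisy curves
(sigma = 2 % points, 8-point designs) achieves a median relative EC50
error of a few percent over 100 seeded curves.

One-point screen thresholds such as "EC55.2" are exposed through
`effect_concentration` but no specific printed threshold value is
asserted: the slope that such a threshold implies is not recoverable
from the screen summary alone.

MIC is read from a strictly decreasing twofold dilution series as the
lowest no-growth concentration above the highest growing one; growth
everywhere is censored `>max`, no growth anywhere `<=min`, and a
non-monotone pattern is resolved above the highest growing concentration
with a warning. Censored values propagate as explicit (value, flag)
pairs; a fold change with one censored operand is itself censored with a
direction flag, and one with two censored operands is refused. Fold
changes round half up to integers by default, with a two-significant-
figure rule for sub-unity ratios. Profile tables order groups
parent, A, B0, B1, B2 and sort within group by ascending cytotoxic IC50
with censored values last; heat-map colour bounds are attached as table
metadata, not applied to stored values.

## Synthetic screen generator

The generator emulates the experiment's structure so that every pipeline
stage has recoverable truth; it is a test harness, not a biological
claim. Defaults mirror the full screen: 13,584 beads drawn uniformly
with replacement from the 4096 sequences, one spectrum and one assay
panel per well, parent transport control 55.2 fluorescence-change %.

Spectra are the theoretical b/y ladder plus precursor with independent
Bernoulli deletion of fragment peaks (default rate 0.1; the precursor
always survives) and Gaussian m/z jitter (default sd 0.05 Da, well
inside the 0.3 Da matching tolerance). Which ions survived is recorded,
so matching bookkeeping can be checked exactly.

Assay readouts come from a rule-based latent model whose per-sequence
truths are hashed deterministically from the seed and the sequence --
a compound therefore behaves identically in every well it occupies, and
compound-level activity rates equal the configured Bernoulli rates.
Rules and calibration:

- Transport: sequences with >= 3 T/N' residues are never
  transport-positive (relative activity decays multiplicatively, factor
  0.35 per extra residue), encoding the absence of such sequences among
  screen hits. For 0/1/2 T/N' residues the positive probability is
  0.85/0.28/0.025, chosen so that ~4.4% of wells (roughly 600 of 13,584)
  are transport-positive while preserving the strong downward trend in
  hydrogen-bond content observed among hits. Positive sequences draw
  relative activity in [1.05, 1.80], negative ones in [0.30, 0.90],
  leaving a margin around the >= 1 threshold so small noise rarely flips
  a label.
- Cytotoxicity: kill probability 0.05 per Leu + 0.01 per Val at the
  variable positions (Leu-rich sequences are the more cytotoxic); toxic
  sequences have latent viability in [5, 15] %, non-toxic in [60, 90] %,
  straddling the 20/30 thresholds with a buffer.
- Antibacterial activity: Bernoulli per sequence with class
  probabilities 0.76 (A-like), 0.97 (B0), 0.17 (B1), 0.03 (B2) -- the
  published percent-active values used as calibration targets. Active
  sequences receive +++/++/+ with probabilities 0.15/0.45/0.40; dilution
  flags follow the code deterministically.
- The parent is pinned to its known screen behaviour: relative transport
  exactly 1 (it is its own normalisation control), cytotoxic, potency ++.

Observed readouts add Gaussian noise (default sd 5 % points) to the
continuous channels only; viability is clipped to [0, 120] %. On-disk
output (plates.csv, screen.mgf, truth.json, config.json) uses fixed
float formatting, so a config and seed determine every byte.

What the generator does **not** emulate: synthesis failures and
truncation products, per-bead loading variation, plate and batch
effects, correlated or non-Gaussian assay noise, chromatographic or
instrument-specific spectral artefacts, and any real sequence-activity
relationship beyond the composition rules above. Passing recovery tests
therefore demonstrates that the pipeline's logic is correct and
internally consistent -- not that it would reach any particular accuracy
on real screen data, whose per-well distributions are unknown.

## Problem sizes and determinism in the test suite

Exhaustive checks run over the full 4096-member library (enumeration,
degeneracy audit, noiseless decodability). End-to-end screen recovery
uses 2000-bead screens, large enough to populate all subgroups while the
whole suite stays fast; coverage simulations use 200 replicates;
dose-response recovery uses 100 seeded curves. Every stochastic
component takes an explicit seed (NumPy `default_rng` for sampling and
noise, a stable blake2b hash for per-sequence latent truths), and
property-based tests run derandomised.

## Known limitations

- Screen-level published counts (600 transport-positive wells, 74/519
  group sizes, 41/276 unique compounds, the 31/208/37 subgroup split)
  depend on per-well data that were never deposited; they serve here as
  calibration targets for the generator, not as reproducible outputs.
- Per-bead loading arithmetic (nmol -> ug -> uM) is not modelled; the
  printed values do not reconcile exactly and are not asserted.
- The decoder assumes clean singly-charged spectra; there is no
  centroiding, isotope handling or charge deconvolution.
- Average-mode matching shares the monoisotopic tolerance default even
  though average masses are not what a TOF/TOF reports; nominal or
  monoisotopic mode is recommended.
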