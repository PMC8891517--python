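# Methods

## The screening model

The package operationalises a directed-discovery screen for tetrapeptide
emulsifiers. The physical premise is that a peptide's value as an
emulsifier is proxied by its tendency to accumulate at an oil–water
interface in a coarse-grained simulation. The screen's unit of measurement
is **percent adsorbance**:

    %ADS = 100 × N_interface / N_total

computed over all peptide copies in one slab system. A peptide belongs to
`N_interface` when **any** of its beads lies within the adsorption cutoff
(0.8 nm, i.e. 8 Å) of either octane–water boundary plane. Three modelling
choices fix the statistic precisely:

- **Distance is measured along the slab normal only.** The boundaries are
  planes normal to the box's long axis, so bead-to-boundary distance is the
  1-D minimum-image distance along that axis. A 3-D distance would differ
  only for beads displaced laterally off a boundary plane's edge, which
  cannot happen for an infinite periodic plane.
- **Closed inequality.** A bead exactly at the cutoff counts as adsorbed
  ("within" the zone); a 1e-9 nm slack absorbs floating-point round-off in
  the wrap arithmetic.
- **Final-frame policy by default.** The screen scores the configuration at
  the completion of a fixed-length run. Because %ADS keeps rising on longer
  timescales, a trailing-window mean (`frame_policy=("window", k)`) is
  offered for analyses of time dependence, but the default matches the
  screening convention.

A peptide near both boundaries is counted once. %ADS is by construction in
[0, 100], non-decreasing in the cutoff, invariant under rigid translation
modulo the box and under relabelling of peptide ids; the test suite checks
all four properties plus agreement with a brute-force oracle that
enumerates periodic images explicitly.

## Interface location

The source simulations define the interface only implicitly. Here the two
boundary planes are located as the positions where the **water and octane
density profiles cross** (equal binned density, linear interpolation
between bin centres). Profiles use 0.2 nm bins by default; the profile
difference is smoothed with a 3-bin moving average and crossings closer
than two bin widths are merged before counting, because Poissonian
counting noise in the one or two bins straddling a sharp boundary can
otherwise split a single physical interface into several sign flips.
Anything other than exactly two crossings (single phase, fully mixed box)
raises a degenerate-interface error rather than guessing. On ideal
synthetic slabs the detected boundaries land within one bin width of the
construction planes.

The cutoff is not estimated from data; it is the screen's fixed 0.8 nm
parameter and must be smaller than half the aqueous slab width (type
invariant), since otherwise "bulk" ceases to exist.

## Slab construction

`build_initial_frame` produces the screening geometry: box 25 × 12.5 ×
12.5 nm (long axis x, configurable), aqueous slab centred on the long axis
with `water_fraction` = 0.5 of its length by default (the source geometry
fixes only that the aqueous phase is centred; the proportion is this
package's choice), 600 peptides and neutralising counter-ions uniform in
the slab, octane uniform outside it. Ion count = `n_peptides ×
|net_charge|` with species chosen by sign (Cl⁻ for cationic, Na⁺ for
anionic peptides); net charge sums side chains only, as the termini are
zwitterionic (net 0), and histidine is taken neutral at pH 7.

Peptides are represented **one bead per residue** in short straight chains
(0.35 nm spacing). %ADS needs only bead positions and bead→residue→peptide
assignment; Martini bead types, topologies and energetics stay with the
external engine. Solvent bead counts default to a nominal 2.0 beads/nm³ —
enough for clean density profiles while keeping construction fast; no
attempt is made to match real coarse-grained liquid densities, and the
builder performs no minimisation or dynamics. A capacity check rejects
requests that cannot fit a region at a 0.3 nm minimum spacing; placement
itself is uniform random and seed-deterministic (bit-reproducible).

GRO files are written with residue names W/OCT/ION plus three-letter amino
acid codes, one GRO residue per peptide, and atom names `R1..Rn` encoding
the residue position; the reader also accepts third-party (e.g. Martini)
naming through a residue-name→species mapping and a `residues_per_peptide`
grouping fallback. GRO stores 3 decimals in nm, so coordinates round-trip
to ±0.0005 nm (plus float32 read-back, tested at 5.2e-4).

## Sequence spaces and screening rules

Alphabets are ordered alphabetically by one-letter code so enumeration
output is reproducible. Three alphabets matter: the full 20, the 17-letter
set without F/W/Y, and the 13-letter set additionally without R/K/E/D.
Rule 2 of the screening set (L or I at a terminal position over the
13-letter alphabet) contains 2·2·13³ − 4·13² = 8,112 sequences by
inclusion–exclusion; rule 3 (all 17-letter tetrapeptides containing "RR")
contains 3·17² − 35 + 1 = 833; both are verified against brute-force
filters. Rule 1 extends each hit tripeptide by one residue at either
terminus, giving 2·17 = 34 tetrapeptides per hit (33 for a homo-tripeptide,
whose prepend/append coincide once). Hit tripeptides are an *input*: the
realized hit list of any particular campaign belongs to its data, so tests
and the acceptance script derive a deterministic synthetic 32-member list
from a synthetic tripeptide screen. Deduplication across rules keeps one
record per sequence with per-rule membership flags, so the control subset
remains recoverable from the merged screen.

The polarity table behind the p/n amphiphilicity pattern is the standard
hydropathy split (nonpolar A/V/L/I/M/P/G/C plus the aromatics; polar
S/T/N/Q/H/R/K/D/E), which reproduces p-n-n-n for HGII; it is an argument,
not a constant, for users who prefer a different split.

## Screen statistics

Per-amino-acid statistics are **presence-based**: each sequence containing
an amino acid contributes once to that amino acid's mean/spread regardless
of multiplicity (an occurrence-weighted variant is available behind a
flag). The spread is the sample (n−1) standard deviation by default, with
`ddof=0` available. Positional preference assigns sequences containing the
amino acid both terminally and internally to the terminal class. Threshold
counts are strict (`> threshold`). Rankings sort by %ADS with deterministic
lexicographic tie-breaks. Timescale comparison inner-joins two tables on
sequence and flags sequences that cross 50% only in the longer screen —
the quantity of interest when a short screen is used to discard candidates.

## Synthetic data: what it emulates, what it does not

`generate_slab_trajectory` places an exact number (`round(f·n)`) of
peptides with all beads inside the interfacial zone (alternating
boundaries, flat against the plane, jitter < cutoff) and the rest with all
beads ≥ 2× cutoff from both boundaries, so the constructed %ADS is exact —
it validates the *measurement*, not adsorption physics. An optional
`orientation_shift` pushes nonpolar residues of adsorbed peptides toward
the octane side to emulate interfacial ordering for the residue-ordering
analysis. Frames are independent redraws, not dynamics; no kinetics, no
aggregation, no timescale dependence.

`generate_ads_table` draws %ADS = clip(μ + Σ β(aa at each position) + ε,
0, 100) with Gaussian ε. Default effects are sized after the screen's
empirical pattern: R −25, D/E/K −15, L/I +8, and the remaining residues
small but distinct (within ±2, mirroring the small spread of their
screen-average contributions — an all-zero "neutral" block would leave the
effect ranking undefined and rank-recovery untestable). An `effect_sd` map
adds per-occurrence noise (e.g. for charged residues) to reproduce their
inflated %ADS spread. These defaults are configuration for generating
realistic test data, not fitted claims; passing the recovery tests shows
the estimator recovers a known additive structure, not that real screen
data are additive.

## Problem sizes and numerical choices

Tests and the acceptance script run at full combinatorial scale (17⁴ =
83,521 sequences for enumeration, brute-force rule filtering and effects
recovery — these are cheap) and at the screen's native system size for
slab fixtures (600 peptides, ~10⁴ beads, single frames), chosen because
construction and analysis are linear-time and exact recovery needs no
averaging. Spearman rank recovery uses the full 17-letter space (the
13-letter space excludes the charged residues that carry most of the
effect signal). Seeds: every stochastic routine takes an explicit seed;
sub-seeds are spawned via `numpy.random.SeedSequence`.

## Known limitations

- No MD: energetics, kinetics and the 4×-scaled coarse-grained time
  convention are out of scope; a single time tag labels each %ADS table.
- Interface detection assumes a slab whose aqueous region does not wrap
  through the periodic wall; translate first if it does.
- The RR-control predicate ("contains RR over the 17-letter alphabet")
  yields 833 sequences; published control sets may be constructed
  differently and should be taken from their deposited membership when
  exact reproduction matters.
- `load_ads_table` validates range, uniqueness and uniform length but does
  not attempt fuzzy column matching beyond the user-supplied column map.
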