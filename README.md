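# pepscreen

Virtual screening of short peptide emulsifiers from coarse-grained slab
simulations.

Oil-in-water emulsions are stabilised by molecules that adsorb at the
oil–water interface. Short peptides (tri- and tetrapeptides built from the
gene-encoded amino acids, excluding the aromatics F/W/Y) are attractive
food- and cosmetic-grade emulsifiers, but the tetrapeptide space alone
holds 17⁴ = 83,521 candidates — far too many to simulate or synthesise
exhaustively. `pepscreen` implements the screening machinery around such a
campaign for computational chemists running coarse-grained MD:

- **sequence_space** — enumerate restricted sequence spaces and assemble a
  tetrapeptide screening set from three rules: (1) single-residue N/C
  extensions of high-scoring "hit" tripeptides, (2) all 13-letter
  tetrapeptides (no F/W/Y and no charged R/K/E/D) with L or I at a
  terminus, and (3) a di-arginine (RR) negative-control set; plus residue
  charge/polarity classification, net charge and p/n amphiphilicity
  patterns.
- **system_builder** — construct the screening geometry: a periodic
  25 × 12.5 × 12.5 nm box with the aqueous slab centred on the long axis,
  octane filling the two outer slabs (two planar interfaces), 600 copies of
  the peptide and neutralising Na⁺/Cl⁻ ions; read/write GRO coordinate
  files and a tabular CSV frame format.
- **interface_analysis** — locate the two boundaries as the crossings of
  the water and octane density profiles and compute the screening
  statistic, percent adsorbance,

  ```
  %ADS = 100 × N_interface / N_total ,
  ```

  where a peptide counts as at the interface when any of its beads lies
  within 8 Å (0.8 nm) of either boundary plane (minimum-image distance
  along the slab normal, final frame by default). Per-species and
  per-residue density profiles and signed residue-ordering summaries
  support the same analysis.
- **screen_statistics** — screen-level analytics over %ADS tables:
  per-amino-acid presence means/spreads/prevalence, terminal-vs-interior
  positional preference, threshold counts, top/bottom rankings and paired
  timescale comparisons.
- **synthetic_data** — seed-deterministic generators: slab trajectories
  with an *exact* constructed adsorbed fraction, and %ADS tables drawn from
  an additive per-amino-acid effects model (charged residues depress
  adsorption, arginine most strongly; L/I raise it).

The MD itself (Martini force field, GROMACS) is out of scope: `pepscreen`
prepares systems for an external engine and analyses its trajectories, or
substitutes synthetic trajectories for testing.

## Worked example

```python
from pepscreen import *
from pepscreen.synthetic_data import (
    SlabFixtureConfig, EffectsModel, generate_slab_trajectory, generate_ads_table,
)

# a slab system in which 65% of 600 HGII peptides are placed interfacially
cfg = SlabFixtureConfig(
    system=SystemSpec(sequence="HGII", n_peptides=600, solvent_density=2.0),
    adsorbed_fraction=0.65, seed=42,
)
frames = generate_slab_trajectory(cfg, n_frames=1)
model = locate_interfaces(frames, bin_width=0.2)
res = percent_ads(frames, model)
print(f"boundaries: {model.boundary_low:.2f} / {model.boundary_high:.2f} nm")
print(f"%ADS = {res.percent_ads:.1f} ({res.n_peptides_interface:.0f}/{res.n_peptides_total})")
print(amphiphilicity_pattern("HGII"))
```

prints

```
boundaries: 6.26 / 18.80 nm
%ADS = 65.0 (390/600)
p-n-n-n
```

— the detected boundaries sit at the constructed slab edges (nominally
6.25 and 18.75 nm for a half-width aqueous slab), the constructed adsorbed
fraction is recovered exactly, and HGII reduces to the classic
polar-head/nonpolar-tail surfactant pattern. Screen-level statistics work
the same way on synthetic tables:

```python
seqs = enumerate_sequences(4, REDUCED_ALPHABET)          # 28,561 sequences
table = generate_ads_table(seqs[:5000], EffectsModel(noise_sd=5.0, seed=1))
print(aa_presence_stats(table).round(1).head(4))
```

```
    mean_ads  sd_ads  prevalence_pct  n_sequences
aa
L       62.1     6.3            20.7         1033
I       62.1     6.0            20.7         1033
A       56.7     6.9            58.1         2905
G       56.1     6.6            30.9         1544
```

i.e. the per-amino-acid presence means recover the generator's effect
ordering (L/I on top). A `pepscreen` console script exposes the same
operations (`pepscreen enumerate`, `screen-set`, `ads`, `profile`,
`stats`, `rank`, `compare`, `synth slab`, `synth table`); see
`pepscreen --help`.

Published screen tables (CSV or XLSX with sequence and %ADS columns) can be
loaded with `load_ads_table` and fed to the same analytics; the test suite
additionally checks such tables against their published summary statistics
when they are placed under `data/deposited/`.

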