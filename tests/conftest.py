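import numpy as np
import pytest

from pepscreen.system_builder import BoxSpec, Frame, SystemSpec


def make_frame(bead_rows, box=(25.0, 12.5, 12.5)):
    """Build a Frame from (x, y, z, species, peptide_id, residue_index) rows."""
    rows = list(bead_rows)
    pos = np.array([r[:3] for r in rows], dtype=float)
    species = np.array([r[3] for r in rows], dtype=object)
    pid = np.array([r[4] for r in rows], dtype=int)
    rix = np.array([r[5] for r in rows], dtype=int)
    return Frame(pos, species, pid, rix, BoxSpec(box))


def slab_background(box=(25.0, 12.5, 12.5), n=40, water_fraction=0.5):
    """Deterministic water/octane beads tracing an ideal slab profile."""
    lx = box[0]
    lo, hi = lx * (1 - water_fraction) / 2, lx * (1 + water_fraction) / 2
    rows = []
    for x in np.linspace(lo + 1e-3, hi - 1e-3, n):
        rows.append((x, 1.0, 1.0, "water", -1, -1))
    for x in np.linspace(0, lo - 1e-3, n // 2):
        rows.append((x, 1.0, 1.0, "octane", -1, -1))
    for x in np.linspace(hi + 1e-3, lx - 1e-3, n // 2):
        rows.append((x, 1.0, 1.0, "octane", -1, -1))
    return rows


@pytest.fixture
def small_spec():
    """A light slab system for fast construction tests."""
    return SystemSpec(
        sequence="PTAL",
        n_peptides=12,
        box=BoxSpec((25.0, 12.5, 12.5)),
        solvent_density=0.2,
    )


@pytest.fixture
def toy_slab_frame():
    """Ideal slab with two peptides: one adsorbed, one at the slab centre."""
    rows = slab_background()
    # peptide 0: bead on the low boundary
    rows += [(6.25, 2.0, 2.0, "peptide", 0, 0), (6.6, 2.0, 2.0, "peptide", 0, 1)]
    # peptide 1: both beads at the centre
    rows += [(12.5, 2.0, 2.0, "peptide", 1, 0), (12.85, 2.0, 2.0, "peptide", 1, 1)]
    return make_frame(rows)
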