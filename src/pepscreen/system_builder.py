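"""Initial slab-system construction and coordinate file I/O.

The screening geometry is a periodic box (default 25 x 12.5 x 12.5 nm) with
the aqueous phase centred on the long axis and octane filling the two outer
slabs, so that exactly two planar oil-water interfaces exist.  600 copies of
the screened peptide, in zwitterionic form, plus neutralising Na+ or Cl-
ions are dispersed in the aqueous slab.

Peptides are represented with one bead per residue: the adsorption statistic
only needs bead-to-residue assignment, never force-field bead types, so the
full coarse-grained topology stays with the external MD engine.  Frames are
serialised as GROMACS GRO files (via MDAnalysis) and as a plain tabular CSV
used for fixtures.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional

import numpy as np

from .sequence_space import CANONICAL_RESIDUES, net_charge, validate_sequence

__all__ = [
    "BoxSpec",
    "SystemSpec",
    "Frame",
    "CapacityError",
    "FrameParseError",
    "MappingError",
    "build_initial_frame",
    "write_gro",
    "read_gro",
    "write_frame_csv",
    "read_frame_csv",
    "read_trajectory",
    "DEFAULT_SPECIES_MAP",
]

SPECIES = ("water", "octane", "ion", "peptide")

AA_THREE = {
    "A": "ALA", "C": "CYS", "D": "ASP", "E": "GLU", "F": "PHE", "G": "GLY",
    "H": "HIS", "I": "ILE", "K": "LYS", "L": "LEU", "M": "MET", "N": "ASN",
    "P": "PRO", "Q": "GLN", "R": "ARG", "S": "SER", "T": "THR", "V": "VAL",
    "W": "TRP", "Y": "TYR",
}
THREE_AA = {v: k for k, v in AA_THREE.items()}

#: Residue-name -> species mapping used when reading GRO files.  Covers the
#: names this package writes plus common Martini conventions; third-party
#: naming is handled by passing a custom mapping.
DEFAULT_SPECIES_MAP: dict[str, str] = {
    "W": "water", "WN": "water", "SOL": "water",
    "OCT": "octane", "OCO": "octane",
    "ION": "ion", "NA": "ion", "CL": "ion", "NA+": "ion", "CL-": "ion",
    **{three: "peptide" for three in THREE_AA},
}


class CapacityError(ValueError):
    """Requested bead counts cannot fit the region at the minimum spacing."""


class FrameParseError(ValueError):
    """A coordinate file could not be parsed."""


class MappingError(KeyError):
    """A residue name has no species assignment in the mapping config."""


@dataclass(frozen=True)
class BoxSpec:
    """Periodic box dimensions in nm; the slab normal is the long axis."""

    lengths: tuple[float, float, float] = (25.0, 12.5, 12.5)
    long_axis: int = 0

    def __post_init__(self) -> None:
        if len(self.lengths) != 3 or any(l <= 0 for l in self.lengths):
            raise ValueError("box needs three positive lengths")
        if self.long_axis not in (0, 1, 2):
            raise ValueError("long_axis must be 0, 1 or 2")

    @property
    def long_length(self) -> float:
        return self.lengths[self.long_axis]


@dataclass
class SystemSpec:
    """One screening system: peptide copies in a water slab flanked by octane."""

    sequence: str = "PTAL"
    n_peptides: int = 600
    box: BoxSpec = field(default_factory=BoxSpec)
    water_fraction: float = 0.5
    n_water: Optional[int] = None
    n_octane: Optional[int] = None
    solvent_density: float = 2.0  # beads / nm^3 when counts are not given
    bond_length: float = 0.35  # nm between consecutive peptide beads
    min_spacing: float = 0.3  # nm, capacity check only

    def __post_init__(self) -> None:
        validate_sequence(self.sequence)
        if self.n_peptides < 0:
            raise ValueError("n_peptides must be >= 0")
        if not 0.0 < self.water_fraction < 1.0:
            raise ValueError("water_fraction must lie in (0, 1)")

    @property
    def slab_bounds(self) -> tuple[float, float]:
        """Nominal aqueous-slab bounds on the long axis (nm)."""
        L = self.box.long_length
        half = 0.5 * self.water_fraction * L
        return (0.5 * L - half, 0.5 * L + half)

    @property
    def ion_species(self) -> Optional[str]:
        q = net_charge(self.sequence)
        if q > 0:
            return "CL"
        if q < 0:
            return "NA"
        return None

    @property
    def n_ions(self) -> int:
        return self.n_peptides * abs(net_charge(self.sequence))

    def solvent_counts(self) -> tuple[int, int]:
        lx, ly, lz = self.box.lengths
        cross = ly * lz if self.box.long_axis == 0 else (
            lx * lz if self.box.long_axis == 1 else lx * ly
        )
        v_water = cross * self.box.long_length * self.water_fraction
        v_oct = cross * self.box.long_length * (1.0 - self.water_fraction)
        n_w = self.n_water if self.n_water is not None else int(round(v_water * self.solvent_density))
        n_o = self.n_octane if self.n_octane is not None else int(round(v_oct * self.solvent_density))
        return n_w, n_o


@dataclass
class Frame:
    """One snapshot of labelled bead positions in a periodic box.

    ``peptide_id`` and ``residue_index`` are -1 for non-peptide beads.
    """

    positions: np.ndarray  # (N, 3) nm
    species: np.ndarray  # (N,) str
    peptide_id: np.ndarray  # (N,) int
    residue_index: np.ndarray  # (N,) int
    box: BoxSpec
    periodic: bool = True

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.species = np.asarray(self.species, dtype=object)
        self.peptide_id = np.asarray(self.peptide_id, dtype=int)
        self.residue_index = np.asarray(self.residue_index, dtype=int)
        n = len(self.positions)
        if self.positions.shape != (n, 3) or not np.all(np.isfinite(self.positions)):
            raise ValueError("positions must be a finite (N, 3) array")
        if not (len(self.species) == len(self.peptide_id) == len(self.residue_index) == n):
            raise ValueError("per-bead arrays must share one length")
        bad = set(self.species) - set(SPECIES)
        if bad:
            raise ValueError(f"unknown species labels: {sorted(bad)}")
        is_pep = self.species == "peptide"
        if np.any((self.peptide_id >= 0) != is_pep):
            raise ValueError("peptide_id must be set exactly for peptide beads")
        if np.any((self.residue_index >= 0) != is_pep):
            raise ValueError("residue_index must be set exactly for peptide beads")

    def __len__(self) -> int:
        return len(self.positions)

    def select(self, species: str) -> np.ndarray:
        return np.flatnonzero(self.species == species)

    @property
    def n_peptides(self) -> int:
        ids = self.peptide_id[self.peptide_id >= 0]
        return len(np.unique(ids))

    def long_coords(self, wrapped: bool = True) -> np.ndarray:
        """Long-axis coordinates, optionally wrapped into [0, L)."""
        x = self.positions[:, self.box.long_axis]
        return np.mod(x, self.box.long_length) if wrapped else x


def _check_capacity(n: int, volume: float, spacing: float, what: str) -> None:
    capacity = int(volume / spacing**3)
    if n > capacity:
        raise CapacityError(
            f"{n} {what} beads cannot fit {volume:.1f} nm^3 at "
            f"{spacing} nm minimum spacing (capacity {capacity})"
        )


def build_initial_frame(spec: SystemSpec, seed: int) -> Frame:
    """Random initial configuration of the biphasic slab system.

    Water beads are uniform in the central slab, octane uniform in the two
    outer slabs, peptides (one bead per residue, a short chain along a random
    direction) and neutralising ions uniform in the aqueous region.
    Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(seed)
    ax = spec.box.long_axis
    other = [i for i in range(3) if i != ax]
    lx = spec.box.long_length
    lo, hi = spec.slab_bounds
    n_w, n_o = spec.solvent_counts()

    cross = spec.box.lengths[other[0]] * spec.box.lengths[other[1]]
    _check_capacity(n_w, cross * (hi - lo), spec.min_spacing, "water")
    _check_capacity(n_o, cross * (lx - hi + lo), spec.min_spacing, "octane")
    n_res = len(spec.sequence)
    _check_capacity(
        spec.n_peptides * n_res + spec.n_ions, cross * (hi - lo), spec.min_spacing, "solute"
    )

    def uniform_block(n: int, long_lo: float, long_hi: float) -> np.ndarray:
        pos = np.empty((n, 3))
        pos[:, ax] = rng.uniform(long_lo, long_hi, n)
        for i in other:
            pos[:, i] = rng.uniform(0.0, spec.box.lengths[i], n)
        return pos

    water = uniform_block(n_w, lo, hi)

    octane = np.empty((n_o, 3))
    u = rng.uniform(0.0, lx - (hi - lo), n_o)
    octane[:, ax] = np.where(u < lo, u, u + (hi - lo))
    for i in other:
        octane[:, i] = rng.uniform(0.0, spec.box.lengths[i], n_o)

    margin = (n_res - 1) * spec.bond_length
    if spec.n_peptides > 0 and hi - lo <= 2 * margin:
        raise CapacityError("aqueous slab narrower than an extended peptide chain")
    centers = uniform_block(spec.n_peptides, lo + margin, hi - margin)
    direc = rng.normal(size=(spec.n_peptides, 3))
    direc /= np.linalg.norm(direc, axis=1, keepdims=True)
    # straight one-bead-per-residue chains; transverse coords wrap periodically
    offsets = np.arange(n_res)[None, :, None] * spec.bond_length * direc[:, None, :]
    pep = (centers[:, None, :] + offsets).reshape(-1, 3)
    for i in other:
        pep[:, i] = np.mod(pep[:, i], spec.box.lengths[i])

    ions = uniform_block(spec.n_ions, lo, hi)

    positions = np.concatenate([pep, water, octane, ions])
    species = np.array(
        ["peptide"] * len(pep) + ["water"] * n_w + ["octane"] * n_o + ["ion"] * spec.n_ions,
        dtype=object,
    )
    pid = np.full(len(positions), -1, dtype=int)
    rix = np.full(len(positions), -1, dtype=int)
    pid[: len(pep)] = np.repeat(np.arange(spec.n_peptides), n_res)
    rix[: len(pep)] = np.tile(np.arange(n_res), spec.n_peptides)

    return Frame(positions, species, pid, rix, spec.box)


# --------------------------------------------------------------------------
# GRO serialisation (MDAnalysis-backed)

_ION_NAMES = {"NA": "NA", "CL": "CL"}


def _frame_resnames(frame: Frame, sequence: Optional[str]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-bead (resname, atomname, residue-group index) for GRO output."""
    n = len(frame)
    resnames = np.empty(n, dtype=object)
    names = np.empty(n, dtype=object)
    resindex = np.empty(n, dtype=int)

    is_pep = frame.species == "peptide"
    seq_letters = None
    if sequence is not None:
        seq_letters = validate_sequence(sequence)

    group = 0
    last_pid = None
    for i in range(n):
        sp = frame.species[i]
        if sp == "peptide":
            pid = frame.peptide_id[i]
            if pid != last_pid:
                group += 1
                last_pid = pid
            rix = frame.residue_index[i]
            letter = seq_letters[rix] if seq_letters and rix < len(seq_letters) else "G"
            resnames[i] = AA_THREE[letter]
            names[i] = f"R{rix + 1}"
        else:
            group += 1
            last_pid = None
            if sp == "water":
                resnames[i] = "W"
                names[i] = "W"
            elif sp == "octane":
                resnames[i] = "OCT"
                names[i] = "C1"
            else:
                resnames[i] = "ION"
                names[i] = "NA"
        resindex[i] = group - 1
    return resnames, names, resindex


def write_gro(frame: Frame, path: str | Path, sequence: Optional[str] = None) -> None:
    """Write a frame in GRO fixed-column format (coordinates in nm).

    Peptide beads are written one residue per bead with three-letter residue
    names (taken from ``sequence`` when given) and atom names ``R1..Rn``
    encoding the within-peptide residue position; all beads of one peptide
    share a residue id.  Coordinates survive a round-trip through
    :func:`read_gro` to the format's 0.001 nm precision.
    """
    import MDAnalysis as mda

    resnames, names, resindex = _frame_resnames(frame, sequence)
    n_res = resindex[-1] + 1 if len(frame) else 0
    u = mda.Universe.empty(
        n_atoms=len(frame),
        n_residues=max(n_res, 1),
        atom_resindex=resindex,
        residue_segindex=np.zeros(max(n_res, 1), dtype=int),
        trajectory=True,
    )
    u.add_TopologyAttr("names", names)
    u.add_TopologyAttr("resnames", [""] * max(n_res, 1))
    first_atom = np.searchsorted(resindex, np.arange(n_res))
    u.residues.resnames = resnames[first_atom] if len(frame) else ["W"]
    u.add_TopologyAttr("resids", (np.arange(max(n_res, 1)) % 99999) + 1)
    u.atoms.positions = frame.positions * 10.0  # nm -> Angstrom
    lx, ly, lz = frame.box.lengths
    u.dimensions = [lx * 10.0, ly * 10.0, lz * 10.0, 90.0, 90.0, 90.0]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u.atoms.write(str(path))


_ATOMNAME_RES = re.compile(r"^R(\d+)$")


def read_gro(
    path: str | Path,
    species_map: Optional[Mapping[str, str]] = None,
    residues_per_peptide: Optional[int] = None,
) -> Frame:
    """Read a GRO file into a labelled :class:`Frame`.

    ``species_map`` maps residue names to species (defaults cover this
    package's convention and common Martini names); unmapped names raise
    :class:`MappingError`.  Peptide chains are delimited by atom names
    ``R1..Rn`` where present, falling back to residue-id grouping with
    ``residues_per_peptide`` beads per chain.
    """
    import MDAnalysis as mda

    smap = dict(DEFAULT_SPECIES_MAP if species_map is None else species_map)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            u = mda.Universe(str(path))
    except (ValueError, IndexError, OSError) as exc:
        if isinstance(exc, FileNotFoundError):
            raise
        raise FrameParseError(f"cannot parse GRO file {path}: {exc}") from exc

    resnames = u.atoms.resnames
    unmapped = sorted(set(resnames) - set(smap))
    if unmapped:
        raise MappingError(f"residue names with no species mapping: {unmapped}")
    species = np.array([smap[r] for r in resnames], dtype=object)

    positions = u.atoms.positions / 10.0  # Angstrom -> nm
    if u.dimensions is None or not np.any(u.dimensions[:3]):
        raise FrameParseError(f"GRO file {path} carries no box vector")
    box = BoxSpec(tuple(float(d) / 10.0 for d in u.dimensions[:3]))

    pid = np.full(len(species), -1, dtype=int)
    rix = np.full(len(species), -1, dtype=int)
    pep_idx = np.flatnonzero(species == "peptide")
    if len(pep_idx):
        names = u.atoms.names[pep_idx]
        resids = u.atoms.resids[pep_idx]
        matches = [_ATOMNAME_RES.match(nm) for nm in names]
        if all(matches):
            current = -1
            for j, m in zip(pep_idx, matches):
                r = int(m.group(1)) - 1
                if r == 0:
                    current += 1
                pid[j] = current
                rix[j] = r
        else:
            # group consecutive beads sharing a residue id into residues,
            # then chunk residues into peptides of fixed length
            if residues_per_peptide is None or residues_per_peptide < 1:
                raise MappingError(
                    "peptide beads lack R<i> atom names; pass residues_per_peptide"
                )
            res_change = np.concatenate([[True], resids[1:] != resids[:-1]])
            res_ord = np.cumsum(res_change) - 1
            pid[pep_idx] = res_ord // residues_per_peptide
            rix[pep_idx] = res_ord % residues_per_peptide

    return Frame(positions, species, pid, rix, box)


# --------------------------------------------------------------------------
# Tabular frame format (CSV fixtures)


def write_frame_csv(frame: Frame, path: str | Path) -> None:
    """Write a frame as CSV with a header comment carrying the box spec."""
    import pandas as pd

    df = pd.DataFrame(
        {
            "x": frame.positions[:, 0],
            "y": frame.positions[:, 1],
            "z": frame.positions[:, 2],
            "species": frame.species,
            "peptide_id": frame.peptide_id,
            "residue_index": frame.residue_index,
        }
    )
    lx, ly, lz = frame.box.lengths
    with open(path, "w") as fh:
        fh.write(f"# box: {lx:.6f} {ly:.6f} {lz:.6f} long_axis: {frame.box.long_axis}\n")
        df.to_csv(fh, index=False, float_format="%.6f")


def read_frame_csv(path: str | Path) -> Frame:
    """Read a frame written by :func:`write_frame_csv`."""
    import pandas as pd

    with open(path) as fh:
        header = fh.readline()
        m = re.match(
            r"#\s*box:\s*([\d.eE+-]+)\s+([\d.eE+-]+)\s+([\d.eE+-]+)\s+long_axis:\s*(\d)",
            header,
        )
        if not m:
            raise FrameParseError(f"{path}: line 1 is not a '# box: ...' header")
        box = BoxSpec(
            (float(m.group(1)), float(m.group(2)), float(m.group(3))),
            long_axis=int(m.group(4)),
        )
        df = pd.read_csv(fh)
    required = {"x", "y", "z", "species", "peptide_id", "residue_index"}
    if not required <= set(df.columns):
        raise FrameParseError(f"{path}: missing columns {sorted(required - set(df.columns))}")
    return Frame(
        df[["x", "y", "z"]].to_numpy(float),
        df["species"].to_numpy(object),
        df["peptide_id"].to_numpy(int),
        df["residue_index"].to_numpy(int),
        box,
    )


def read_trajectory(
    topology: str | Path,
    trajectory: Optional[str | Path] = None,
    species_map: Optional[Mapping[str, str]] = None,
    residues_per_peptide: Optional[int] = None,
) -> list[Frame]:
    """Read a multi-frame trajectory (e.g. GRO + XTC) into labelled frames.

    Labels are resolved once from the topology with the same mapping rules as
    :func:`read_gro`; coordinates are taken per trajectory frame.
    """
    import MDAnalysis as mda

    template = read_gro(topology, species_map, residues_per_peptide)
    if trajectory is None:
        return [template]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe(str(topology), str(trajectory))
    frames = []
    for ts in u.trajectory:
        box = BoxSpec(tuple(float(d) / 10.0 for d in ts.dimensions[:3]))
        frames.append(
            Frame(
                u.atoms.positions / 10.0,
                template.species,
                template.peptide_id,
                template.residue_index,
                box,
            )
        )
    return frames
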