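"""Interface location, the %ADS adsorption statistic, and density profiles.

The screen's readout is percent adsorbance, %ADS: the percentage of
peptides in the box that have at least one bead within a fixed cutoff
(default 0.8 nm, i.e. 8 A) of either octane-water boundary at the end of a
simulation.  Boundaries are the two planes, normal to the box's long axis,
where the water and octane density profiles cross; distances to them are
measured along the long axis under the minimum-image convention.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Optional, Sequence, Union

import numpy as np

from .system_builder import Frame

__all__ = [
    "DensityProfile",
    "InterfaceModel",
    "AdsResult",
    "ResidueOrdering",
    "DegenerateInterfaceError",
    "density_profile",
    "locate_interfaces",
    "percent_ads",
    "residue_ordering",
]

#: Default adsorption cutoff, nm (8 A).
DEFAULT_CUTOFF = 0.8
#: Default histogram bin width for density profiles, nm.
DEFAULT_BIN_WIDTH = 0.2

Selection = Union[None, str, tuple, Callable[[Frame], np.ndarray]]


class DegenerateInterfaceError(ValueError):
    """The water/octane density profiles do not cross exactly twice."""


@dataclass
class DensityProfile:
    """Binned bead counts along the long axis, accumulated over frames."""

    bin_edges: np.ndarray  # (n_bins + 1,) nm
    counts: np.ndarray  # (n_bins,) total counts over all frames
    selection: object
    n_frames: int

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def mean_counts(self) -> np.ndarray:
        """Mean per-frame count per bin."""
        return self.counts / self.n_frames


@dataclass
class InterfaceModel:
    """Two planar boundaries on the long axis plus the adsorption cutoff."""

    boundary_low: float
    boundary_high: float
    cutoff: float = DEFAULT_CUTOFF

    def __post_init__(self) -> None:
        if not self.boundary_low < self.boundary_high:
            raise ValueError("boundary_low must lie below boundary_high")
        half_slab = 0.5 * (self.boundary_high - self.boundary_low)
        if not 0.0 < self.cutoff < half_slab:
            raise ValueError(
                f"cutoff {self.cutoff} nm must lie in (0, {half_slab}) nm "
                "(half the aqueous slab width)"
            )

    @property
    def boundaries(self) -> np.ndarray:
        return np.array([self.boundary_low, self.boundary_high])


@dataclass
class AdsResult:
    """%ADS for one system."""

    sequence: Optional[str]
    percent_ads: float
    n_peptides_total: int
    n_peptides_interface: float
    frame_policy: str


@dataclass
class ResidueOrdering:
    """Mean signed distance to the nearest boundary per residue position.

    Negative values sit on the water side, positive on the octane side;
    computed over adsorbed peptides only.
    """

    values: np.ndarray
    n_adsorbed: int

    @property
    def empty(self) -> bool:
        return self.n_adsorbed == 0


def _selection_mask(frame: Frame, selection: Selection) -> np.ndarray:
    if selection is None:
        return np.ones(len(frame), dtype=bool)
    if callable(selection):
        return np.asarray(selection(frame), dtype=bool)
    if isinstance(selection, str):
        return frame.species == selection
    if isinstance(selection, tuple) and len(selection) == 2 and selection[0] == "residue":
        return (frame.species == "peptide") & (frame.residue_index == int(selection[1]))
    raise ValueError(f"unintelligible selection {selection!r}")


def _check_boxes(frames: Sequence[Frame]) -> Frame:
    if not frames:
        raise ValueError("need at least one frame")
    first = frames[0]
    for f in frames[1:]:
        if f.box.lengths != first.box.lengths or f.box.long_axis != first.box.long_axis:
            raise ValueError("frames have inconsistent boxes")
    return first


def density_profile(
    frames: Sequence[Frame],
    selection: Selection = None,
    bin_width: float = DEFAULT_BIN_WIDTH,
) -> DensityProfile:
    """Histogram of selected beads along the long axis, summed over frames.

    Coordinates are wrapped into [0, L); every selected bead lands in
    exactly one bin, so total counts are conserved frame by frame.
    ``selection`` may be a species name, ``("residue", i)`` for peptide
    residue position ``i``, a boolean-mask callable, or ``None`` for all
    beads.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    first = _check_boxes(frames)
    L = first.box.long_length
    n_bins = max(1, int(np.ceil(L / bin_width)))
    edges = np.linspace(0.0, L, n_bins + 1)
    counts = np.zeros(n_bins)
    for f in frames:
        x = f.long_coords()[_selection_mask(f, selection)]
        counts += np.histogram(x, bins=edges)[0]
    return DensityProfile(edges, counts, selection, len(frames))


def locate_interfaces(
    frames: Sequence[Frame],
    bin_width: float = DEFAULT_BIN_WIDTH,
    cutoff: float = DEFAULT_CUTOFF,
    smooth_bins: int = 3,
) -> InterfaceModel:
    """Find the two octane-water boundary planes.

    Each boundary is the long-axis position where the linearly interpolated
    water and octane density profiles cross (equal density).  Profiles are
    smoothed with a short moving average (``smooth_bins``) and crossings
    closer than two bin widths are merged, so counting noise at a sharp
    boundary does not split one interface into several.  A slab system
    yields exactly two crossings; anything else (single phase, fully mixed)
    raises :class:`DegenerateInterfaceError`.
    """
    water = density_profile(frames, "water", bin_width)
    octane = density_profile(frames, "octane", bin_width)
    if water.counts.sum() == 0 or octane.counts.sum() == 0:
        raise DegenerateInterfaceError("need both water and octane beads")

    diff = water.mean_counts - octane.mean_counts
    if smooth_bins > 1 and len(diff) > smooth_bins:
        kernel = np.ones(smooth_bins) / smooth_bins
        diff = np.convolve(diff, kernel, mode="same")
    x = water.centers
    crossings: list[float] = []
    for i in range(len(diff) - 1):
        a, b = diff[i], diff[i + 1]
        if a == 0.0 and b == 0.0:
            continue
        if a == 0.0:
            crossings.append(x[i])
        elif a * b < 0.0:
            crossings.append(x[i] + (x[i + 1] - x[i]) * a / (a - b))
    if diff[-1] == 0.0:
        crossings.append(x[-1])

    # counting noise can flicker the sign within a boundary bin or two;
    # crossings that close together are one physical interface
    merged: list[list[float]] = []
    for c in sorted(crossings):
        if merged and c - merged[-1][-1] < 2.0 * bin_width:
            merged[-1].append(c)
        else:
            merged.append([c])
    boundaries = [float(np.mean(group)) for group in merged]

    if len(boundaries) != 2:
        raise DegenerateInterfaceError(
            f"expected 2 water/octane density crossings, found {len(boundaries)}"
        )
    return InterfaceModel(boundaries[0], boundaries[1], cutoff)


def _boundary_distances(frame: Frame, interfaces: InterfaceModel) -> np.ndarray:
    """Min-image long-axis distance of every bead to the nearest boundary."""
    L = frame.box.long_length
    x = frame.long_coords()
    d = np.abs(np.mod(x[:, None] - interfaces.boundaries[None, :] + 0.5 * L, L) - 0.5 * L)
    return d.min(axis=1)


def _adsorbed_ids(frame: Frame, interfaces: InterfaceModel) -> np.ndarray:
    """Ids of peptides with any bead within the cutoff of a boundary."""
    is_pep = frame.species == "peptide"
    if not np.any(is_pep):
        return np.array([], dtype=int)
    d = _boundary_distances(frame, interfaces)[is_pep]
    pid = frame.peptide_id[is_pep]
    # closed inequality: a bead exactly at the cutoff counts as adsorbed
    # (1e-9 nm absorbs float round-off in the distance arithmetic)
    return np.unique(pid[d <= interfaces.cutoff + 1e-9])


def percent_ads(
    frames: Sequence[Frame],
    interfaces: InterfaceModel,
    frame_policy: Union[str, tuple] = "final",
) -> AdsResult:
    """Percent adsorbance: peptides at an interface / peptides in system.

    A peptide is at the interface when the smallest minimum-image long-axis
    distance from any of its beads to either boundary plane is at most the
    cutoff; a peptide near both boundaries counts once.  ``frame_policy``
    is ``"final"`` (the last frame, the screening convention) or
    ``("window", k)`` for the mean over the trailing ``k`` frames.
    """
    _check_boxes(frames)
    if isinstance(frame_policy, tuple) and frame_policy[0] == "window":
        window = frames[-int(frame_policy[1]):]
        policy_tag = f"window:{len(window)}"
    elif frame_policy == "final":
        window = frames[-1:]
        policy_tag = "final"
    else:
        raise ValueError(f"unknown frame_policy {frame_policy!r}")

    totals, hits = [], []
    for f in window:
        n_total = f.n_peptides
        if n_total == 0:
            raise ValueError("percent_ads is undefined for a system with no peptides")
        totals.append(n_total)
        hits.append(len(_adsorbed_ids(f, interfaces)))
    n_total = totals[-1]
    n_iface = float(np.mean(hits))
    return AdsResult(
        sequence=None,
        percent_ads=100.0 * float(np.mean([h / t for h, t in zip(hits, totals)])),
        n_peptides_total=n_total,
        n_peptides_interface=n_iface,
        frame_policy=policy_tag,
    )


def residue_ordering(
    frames: Sequence[Frame],
    interfaces: InterfaceModel,
    frame_policy: Union[str, tuple] = "final",
) -> ResidueOrdering:
    """Mean signed boundary distance per residue position, adsorbed peptides.

    Sign convention: positive on the octane side of the nearest boundary,
    negative on the water side.  A high-ordering emulsifier shows positive
    values for its hydrophobic residues and negative for its hydrophilic
    ones.  With no adsorbed peptides the result is empty and a warning is
    issued.
    """
    _check_boxes(frames)
    if isinstance(frame_policy, tuple) and frame_policy[0] == "window":
        window = frames[-int(frame_policy[1]):]
    else:
        window = frames[-1:]

    sums: dict[int, float] = {}
    counts: dict[int, int] = {}
    n_adsorbed = 0
    for f in window:
        ads = _adsorbed_ids(f, interfaces)
        n_adsorbed += len(ads)
        if len(ads) == 0:
            continue
        is_pep = np.isin(f.peptide_id, ads)
        d = _boundary_distances(f, interfaces)[is_pep]
        x = f.long_coords()[is_pep]
        inside_water = (x > interfaces.boundary_low) & (x < interfaces.boundary_high)
        signed = np.where(inside_water, -d, d)
        for rix, s in zip(f.residue_index[is_pep], signed):
            sums[rix] = sums.get(rix, 0.0) + s
            counts[rix] = counts.get(rix, 0) + 1

    if n_adsorbed == 0:
        warnings.warn("no adsorbed peptides; residue ordering is empty")
        return ResidueOrdering(np.array([]), 0)
    n_res = max(sums) + 1
    values = np.array([sums.get(i, np.nan) / counts.get(i, 1) for i in range(n_res)])
    return ResidueOrdering(values, n_adsorbed)
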