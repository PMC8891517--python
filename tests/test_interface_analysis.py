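import numpy as np
import pytest

from pepscreen.interface_analysis import (
    DegenerateInterfaceError,
    InterfaceModel,
    density_profile,
    locate_interfaces,
    percent_ads,
    residue_ordering,
)
from pepscreen.synthetic_data import SlabFixtureConfig, generate_slab_trajectory
from pepscreen.system_builder import BoxSpec, Frame, SystemSpec

from conftest import make_frame, slab_background


def brute_force_percent_ads(frame, interfaces):
    """Independent oracle: explicit periodic-image enumeration per bead."""
    L = frame.box.long_length
    adsorbed = set()
    pids = sorted(set(frame.peptide_id[frame.peptide_id >= 0]))
    for pid in pids:
        beads = np.flatnonzero(frame.peptide_id == pid)
        for i in beads:
            x = frame.positions[i, frame.box.long_axis]
            for b in (interfaces.boundary_low, interfaces.boundary_high):
                for image in (-1, 0, 1):
                    if abs((x % L) + image * L - b) <= interfaces.cutoff:
                        adsorbed.add(pid)
    return 100.0 * len(adsorbed) / len(pids)


def shifted(frame, delta):
    pos = frame.positions.copy()
    ax = frame.box.long_axis
    pos[:, ax] = np.mod(pos[:, ax] + delta, frame.box.lengths[ax])
    return Frame(pos, frame.species, frame.peptide_id, frame.residue_index, frame.box)


@pytest.fixture(scope="module")
def slab_frames():
    cfg = SlabFixtureConfig(
        system=SystemSpec(sequence="PTAL", n_peptides=40, solvent_density=0.5),
        adsorbed_fraction=0.75,
        seed=42,
    )
    return generate_slab_trajectory(cfg, n_frames=1)


class TestDensityProfile:
    def test_mass_conservation(self, toy_slab_frame):
        prof = density_profile([toy_slab_frame], None, 0.2)
        assert prof.counts.sum() == len(toy_slab_frame)

    def test_additivity_over_frames(self, toy_slab_frame):
        one = density_profile([toy_slab_frame], "water", 0.2)
        two = density_profile([toy_slab_frame, toy_slab_frame], "water", 0.2)
        assert np.array_equal(two.counts, 2 * one.counts)
        assert np.allclose(two.mean_counts, one.mean_counts)

    def test_water_confined_to_slab(self, slab_frames):
        prof = density_profile(slab_frames, "water", 0.25)
        outside = (prof.centers < 6.0) | (prof.centers > 19.0)
        assert prof.counts[outside].sum() == 0

    def test_empty_selection_is_empty_profile(self, toy_slab_frame):
        prof = density_profile([toy_slab_frame], "ion", 0.2)
        assert prof.counts.sum() == 0

    def test_inconsistent_boxes_rejected(self, toy_slab_frame):
        other = make_frame([(1.0, 1.0, 1.0, "water", -1, -1)], box=(10.0, 5.0, 5.0))
        with pytest.raises(ValueError):
            density_profile([toy_slab_frame, other], None, 0.2)


class TestLocateInterfaces:
    def test_ideal_slab_boundaries_within_one_bin(self, slab_frames):
        model = locate_interfaces(slab_frames, bin_width=0.2)
        assert model.boundary_low == pytest.approx(6.25, abs=0.2)
        assert model.boundary_high == pytest.approx(18.75, abs=0.2)

    def test_single_phase_is_degenerate(self):
        frame = make_frame([(x, 1.0, 1.0, "water", -1, -1) for x in np.linspace(1, 24, 30)])
        with pytest.raises(DegenerateInterfaceError):
            locate_interfaces([frame])

    def test_translation_equivariance(self, slab_frames):
        base = locate_interfaces(slab_frames, bin_width=0.2)
        moved = locate_interfaces([shifted(f, 2.0) for f in slab_frames], bin_width=0.2)
        assert moved.boundary_low == pytest.approx(base.boundary_low + 2.0, abs=0.2)
        assert moved.boundary_high == pytest.approx(base.boundary_high + 2.0, abs=0.2)

    def test_model_invariants(self):
        with pytest.raises(ValueError):
            InterfaceModel(10.0, 5.0)
        with pytest.raises(ValueError):
            InterfaceModel(6.25, 18.75, cutoff=7.0)  # beyond half slab width


class TestPercentAds:
    def test_all_on_boundary_is_100(self):
        rows = slab_background()
        rows += [(6.25, 1.0, 1.0, "peptide", i, 0) for i in range(5)]
        model = InterfaceModel(6.25, 18.75)
        assert percent_ads([make_frame(rows)], model).percent_ads == 100.0

    def test_all_at_centre_is_0(self):
        rows = slab_background()
        rows += [(12.5, 1.0, 1.0, "peptide", i, 0) for i in range(5)]
        model = InterfaceModel(6.25, 18.75)
        assert percent_ads([make_frame(rows)], model).percent_ads == 0.0

    def test_counts_and_ratio_consistent(self, toy_slab_frame):
        model = InterfaceModel(6.25, 18.75)
        res = percent_ads([toy_slab_frame], model)
        assert res.percent_ads == 100.0 * res.n_peptides_interface / res.n_peptides_total
        assert res.percent_ads == 50.0

    def test_minimum_image_wrap(self):
        # bead at x=0.1 with a boundary at 24.9 is 0.2 nm away through the wall
        rows = slab_background() + [(0.1, 1.0, 1.0, "peptide", 0, 0)]
        model = InterfaceModel(10.0, 24.9, cutoff=0.8)
        assert percent_ads([make_frame(rows)], model).percent_ads == 100.0

    def test_bead_exactly_at_cutoff_counts(self):
        rows = slab_background() + [(7.05, 1.0, 1.0, "peptide", 0, 0)]
        model = InterfaceModel(6.25, 18.75, cutoff=0.8)
        assert percent_ads([make_frame(rows)], model).percent_ads == 100.0

    def test_monotone_in_cutoff(self, slab_frames):
        values = []
        for cutoff in (0.2, 0.8, 1.6, 3.0):
            model = InterfaceModel(6.25, 18.75, cutoff=cutoff)
            values.append(percent_ads(slab_frames, model).percent_ads)
        assert values == sorted(values)

    def test_translation_invariance(self, slab_frames):
        model = locate_interfaces(slab_frames, bin_width=0.2)
        base = percent_ads(slab_frames, model).percent_ads
        for delta in (1.7, 5.0, 13.2):
            moved_frames = [shifted(f, delta) for f in slab_frames]
            moved_model = InterfaceModel(
                model.boundary_low + delta, model.boundary_high + delta, model.cutoff
            )
            assert percent_ads(moved_frames, moved_model).percent_ads == base

    def test_peptide_id_permutation_invariance(self, slab_frames):
        frame = slab_frames[0]
        rng = np.random.default_rng(0)
        ids = np.arange(frame.n_peptides)
        perm = rng.permutation(ids)
        new_pid = frame.peptide_id.copy()
        mask = new_pid >= 0
        new_pid[mask] = perm[new_pid[mask]]
        permuted = Frame(
            frame.positions, frame.species, new_pid, frame.residue_index, frame.box
        )
        model = InterfaceModel(6.25, 18.75)
        assert (
            percent_ads([permuted], model).percent_ads
            == percent_ads([frame], model).percent_ads
        )

    def test_matches_brute_force_oracle_small_systems(self):
        rng = np.random.default_rng(123)
        model = InterfaceModel(6.25, 18.75, cutoff=0.8)
        for trial in range(20):
            rows = slab_background()
            n_pep = int(rng.integers(1, 11))
            for pid in range(n_pep):
                for rix in range(3):
                    rows.append(
                        (rng.uniform(0, 25), rng.uniform(0, 12.5), rng.uniform(0, 12.5),
                         "peptide", pid, rix)
                    )
            frame = make_frame(rows)
            assert percent_ads([frame], model).percent_ads == pytest.approx(
                brute_force_percent_ads(frame, model)
            )

    def test_no_peptides_rejected(self):
        frame = make_frame(slab_background())
        with pytest.raises(ValueError):
            percent_ads([frame], InterfaceModel(6.25, 18.75))

    def test_window_policy_averages_trailing_frames(self, toy_slab_frame):
        rows = slab_background()
        rows += [(6.25, 1.0, 1.0, "peptide", 0, 0), (6.6, 1.0, 1.0, "peptide", 0, 1)]
        rows += [(12.5, 1.0, 1.0, "peptide", 1, 0), (12.85, 1.0, 1.0, "peptide", 1, 1)]
        half = make_frame(rows)
        rows2 = slab_background()
        rows2 += [(6.25, 1.0, 1.0, "peptide", 0, 0), (6.6, 1.0, 1.0, "peptide", 0, 1)]
        rows2 += [(6.3, 1.0, 1.0, "peptide", 1, 0), (6.7, 1.0, 1.0, "peptide", 1, 1)]
        full = make_frame(rows2)
        model = InterfaceModel(6.25, 18.75)
        res = percent_ads([half, full], model, frame_policy=("window", 2))
        assert res.percent_ads == 75.0
        assert percent_ads([half, full], model).percent_ads == 100.0


class TestResidueOrdering:
    def test_constructed_signs_recovered(self):
        rows = slab_background()
        # residue 0 sits 0.3 nm into the octane side, residue 1 0.3 nm into water
        for pid, b, sign in [(0, 6.25, -1.0), (1, 18.75, +1.0)]:
            rows.append((b + sign * 0.3, 1.0, 1.0, "peptide", pid, 0))
            rows.append((b - sign * 0.3, 1.0, 1.0, "peptide", pid, 1))
        model = InterfaceModel(6.25, 18.75)
        ordering = residue_ordering([make_frame(rows)], model)
        assert ordering.n_adsorbed == 2
        assert ordering.values == pytest.approx([+0.3, -0.3])

    def test_symmetric_placement_matches_single_interface(self):
        model = InterfaceModel(6.25, 18.75)

        def build(boundaries):
            rows = slab_background()
            for pid, b in enumerate(boundaries):
                sign = -1.0 if b == 6.25 else +1.0
                rows.append((b + sign * 0.2, 1.0, 1.0, "peptide", pid, 0))
                rows.append((b - sign * 0.4, 1.0, 1.0, "peptide", pid, 1))
            return make_frame(rows)

        both = residue_ordering([build([6.25, 18.75])], model)
        low_only = residue_ordering([build([6.25])], model)
        assert both.values == pytest.approx(low_only.values)

    def test_no_adsorbed_peptides_warns_and_is_empty(self):
        rows = slab_background() + [(12.5, 1.0, 1.0, "peptide", 0, 0)]
        model = InterfaceModel(6.25, 18.75)
        with pytest.warns(UserWarning):
            ordering = residue_ordering([make_frame(rows)], model)
        assert ordering.empty

    def test_orientation_bias_sign_recovered_at_scale(self):
        # QQLL: polar head, nonpolar tail; the generator pushes nonpolar
        # residues toward octane for adsorbed peptides
        cfg = SlabFixtureConfig(
            system=SystemSpec(sequence="QQLL", n_peptides=600, solvent_density=0.5),
            adsorbed_fraction=1.0,
            orientation_shift=0.3,
            placement_jitter=0.05,
            seed=9,
        )
        frames = generate_slab_trajectory(cfg, 1)
        model = InterfaceModel(6.25, 18.75)
        ordering = residue_ordering(frames, model)
        assert ordering.n_adsorbed == 600
        assert ordering.values[0] < 0 < ordering.values[2]
        assert ordering.values[1] < 0 < ordering.values[3]
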