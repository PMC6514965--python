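"""Funnels, effective range, salt bridges and the energy decomposition."""

import numpy as np
import pytest

from capscan import (
    Atom, CapsomerModel, ElectrostaticParams, ForceRecord, LJParams,
    binding_energy, detect_funnel, effective_range, find_salt_bridges,
    frame_average_energy, make_frame_ensemble, salt_bridge_population,
)
from capscan.scan_analysis import ACIDIC_ATOMS, BASIC_ATOMS
from capscan.assembly_ops import rotation_about_axis


def records_from(axials, params=None, magnitudes=None):
    params = params if params is not None else list(range(1, len(axials) + 1))
    out = []
    for p, ax in zip(params, axials):
        mag = abs(ax) if magnitudes is None else magnitudes.pop(0)
        direction = np.array([1.0, 0, 0]) * (np.sign(ax) if ax else 1.0)
        rec = ForceRecord(float(p), mag * direction, axial_projection=float(ax))
        out.append(rec)
    return out


class TestFunnel:
    def test_documented_example(self):
        fun = detect_funnel(records_from([-1, 2, 5, 3, -2]), native_param=3)
        assert (fun.lo, fun.hi) == (2, 4)
        assert fun.extremum_param == 3
        assert fun.sign == "attractive"

    def test_all_negative_spans_full_run(self):
        fun = detect_funnel(records_from([-1, -4, -2, -3]), native_param=2)
        assert (fun.lo, fun.hi) == (1, 4)
        assert fun.sign == "repulsive"

    def test_all_zero_is_error(self):
        with pytest.raises(ValueError, match="funnel"):
            detect_funnel(records_from([0, 0, 0]), native_param=2)

    def test_tie_breaks_toward_native_then_smaller(self):
        fun = detect_funnel(records_from([5, 1, -1, 5, 1]), native_param=4)
        assert fun.extremum_param == 4
        fun = detect_funnel(records_from([5, 1, 5, 1, 5]), native_param=3)
        assert fun.extremum_param == 3
        fun = detect_funnel(records_from([5, 1, 1, 1, 5]), native_param=3)
        assert fun.extremum_param == 1  # equidistant -> smaller param

    def test_scale_invariance(self):
        base = [-1.0, 2.5, 4.0, 1.5, -0.5]
        f1 = detect_funnel(records_from(base), native_param=3)
        f2 = detect_funnel(records_from([7.3 * b for b in base]), native_param=3)
        assert (f1.lo, f1.hi, f1.extremum_param, f1.sign) == \
            (f2.lo, f2.hi, f2.extremum_param, f2.sign)

    def test_unsorted_records_rejected(self):
        recs = records_from([1, 2, 3], params=[3, 1, 2])
        with pytest.raises(ValueError, match="sorted"):
            detect_funnel(recs, native_param=2)


class TestEffectiveRange:
    def test_coherent_then_random(self):
        axials = [5, 4, 3, 2, 1, 0.001, -0.001]
        mags = [5, 4, 3, 2, 1, 1.0, 1.0]  # last two lose axial coherence
        recs = records_from(axials, params=[5, 10, 15, 25, 35, 36, 40],
                            magnitudes=mags)
        assert effective_range(recs, magnitude_floor=1e-3, coherence_floor=0.5) == 35

    def test_all_coherent_returns_last(self):
        recs = records_from([3, 2, 1])
        assert effective_range(recs, 1e-3, 0.5) == 3

    def test_none_qualify_warns_and_returns_start(self):
        recs = records_from([-1, -2])
        with pytest.warns(UserWarning):
            assert effective_range(recs, 1e-3, 0.5) == 1


def salty_pair(dist, basic_atom="NZ", basic_res="LYS", second=None):
    a = CapsomerModel.from_atoms(
        [Atom(1, "OE1", "GLU", "A", 1, np.zeros(3)),
         Atom(2, "CB", "GLU", "A", 1, np.array([1.0, 1, 0]))])
    atoms_b = [Atom(1, basic_atom, basic_res, "B", 9, np.array([dist, 0.0, 0]))]
    if second:
        atoms_b.append(Atom(2, second[0], basic_res, "B", 9,
                            np.array([second[1], 0.0, 0])))
    return a, CapsomerModel.from_atoms(atoms_b)


class TestSaltBridges:
    def test_within_cutoff(self):
        a, b = salty_pair(3.5)
        bridges = find_salt_bridges(a, b)
        assert len(bridges) == 1
        assert bridges[0].distance == pytest.approx(3.5)

    def test_beyond_cutoff(self):
        a, b = salty_pair(4.5)
        assert find_salt_bridges(a, b) == []

    def test_residue_pair_dedup_keeps_minimum(self):
        a, b = salty_pair(3.9, basic_atom="NH1", basic_res="ARG",
                          second=("NH2", 3.8))
        bridges = find_salt_bridges(a, b)
        assert len(bridges) == 1
        assert bridges[0].distance == pytest.approx(3.8)
        assert bridges[0].basic[-1] == "NH2"

    def test_both_directions_searched(self):
        # acidic on model B, basic on model A
        basic = CapsomerModel.from_atoms([Atom(1, "NZ", "LYS", "A", 1, np.zeros(3))])
        acidic = CapsomerModel.from_atoms(
            [Atom(1, "OD2", "ASP", "B", 2, np.array([3.0, 0, 0]))])
        assert len(find_salt_bridges(basic, acidic)) == 1

    def test_interface_only_prefilter_identical(self, mode_pairs):
        pair = mode_pairs[1]
        frames = make_frame_ensemble(pair, 5, jitter_sd=1.0,
                                     bridge_plant=[((7, 1), 0.6)], seed=3)
        for a, b in frames:
            fast = find_salt_bridges(a, b, interface_only=True)
            slow = find_salt_bridges(a, b, interface_only=False)
            assert [(x.acidic, x.basic, round(x.distance, 9)) for x in fast] == \
                [(x.acidic, x.basic, round(x.distance, 9)) for x in slow]

    def test_brute_force_equivalence_on_random_frames(self, rng):
        """cKDTree search must equal an O(N^2) all-pairs oracle."""
        names = list(ACIDIC_ATOMS | BASIC_ATOMS) + ["CA", "CB"]
        for _ in range(25):
            n = int(rng.integers(4, 20))
            def rand_model(chain):
                picks = rng.choice(names, size=n)
                resnames = ["GLU" if p in ACIDIC_ATOMS else
                            "LYS" if p in BASIC_ATOMS else "ALA" for p in picks]
                return CapsomerModel(rng.uniform(0, 15, (n, 3)), names=picks,
                                     residue_names=resnames, chain_ids=[chain] * n,
                                     residue_seqs=rng.integers(1, 6, n),
                                     charges=np.zeros(n))
            a, b = rand_model("A"), rand_model("B")
            got = {(x.acidic[:3], x.basic[:3]): round(x.distance, 9)
                   for x in find_salt_bridges(a, b)}
            expected = {}
            for acid_m, base_m in ((a, b), (b, a)):
                for i in range(n):
                    if str(acid_m.names[i]) not in ACIDIC_ATOMS:
                        continue
                    for j in range(n):
                        if str(base_m.names[j]) not in BASIC_ATOMS:
                            continue
                        d = float(np.linalg.norm(acid_m.positions[i]
                                                 - base_m.positions[j]))
                        if d <= 4.0:
                            key = ((str(acid_m.chain_ids[i]), int(acid_m.residue_seqs[i]),
                                    str(acid_m.residue_names[i])),
                                   (str(base_m.chain_ids[j]), int(base_m.residue_seqs[j]),
                                    str(base_m.residue_names[j])))
                            expected[key] = round(min(expected.get(key, np.inf), d), 9)
            assert got == expected


class TestPopulation:
    def test_planted_frequency(self, mode_pairs):
        frames = make_frame_ensemble(mode_pairs[1], 4, bridge_plant=[((7, 1), 0.75)],
                                     seed=11)
        stats = salt_bridge_population(frames)
        assert list(stats.per_pair_frequency.values()) == [0.75]

    def test_counts_and_mean(self, mode_pairs):
        frames = make_frame_ensemble(mode_pairs[1], 4,
                                     bridge_plant=[((7, 1), 0.5), ((8, 2), 1.0)],
                                     seed=5)
        stats = salt_bridge_population(frames)
        assert sorted(stats.per_frame_counts) == [1, 1, 2, 2]
        assert stats.mean_count == pytest.approx(1.5)

    def test_frame_order_invariance(self, mode_pairs):
        frames = make_frame_ensemble(mode_pairs[1], 8, jitter_sd=0.5,
                                     bridge_plant=[((7, 1), 0.5)], seed=2)
        s1 = salt_bridge_population(frames)
        s2 = salt_bridge_population(frames[::-1])
        assert s1.per_pair_frequency == s2.per_pair_frequency
        assert sorted(s1.per_frame_counts) == sorted(s2.per_frame_counts)
        assert s1.mean_count == pytest.approx(s2.mean_count)

    def test_inconsistent_topology_rejected(self, mode_pairs):
        frames = make_frame_ensemble(mode_pairs[1], 2, seed=0)
        truncated = CapsomerModel(frames[1][0].positions[:-1],
                                  charges=frames[1][0].charges[:-1])
        with pytest.raises(ValueError, match="topology"):
            salt_bridge_population([frames[0], (truncated, frames[1][1])])


def two_atoms(dist, q=(0.0, 0.0)):
    a = CapsomerModel(np.zeros((1, 3)), charges=np.array([q[0]]),
                      radii=np.array([1.7]))
    b = CapsomerModel(np.array([[dist, 0.0, 0.0]]), charges=np.array([q[1]]),
                      radii=np.array([1.7]))
    return a, b


class TestBindingEnergy:
    def test_lj_minimum_is_minus_epsilon(self):
        eps, sigma = 0.35, 3.2
        a, b = two_atoms(2 ** (1 / 6) * sigma)
        dec = binding_energy(a, b, lj_params=(LJParams.uniform(1, eps, sigma),
                                              LJParams.uniform(1, eps, sigma)),
                             sasa_params=(0.0, 0.0))
        assert dec.van_der_waals == pytest.approx(-eps, rel=1e-12)
        assert dec.coulombic == 0.0

    def test_cross_terms_vanish_at_200_angstrom(self, mode_pairs):
        pair = mode_pairs[1]
        far = pair.moving.translated(200.0 * pair.native_axis)
        dec = binding_energy(pair.fixed, far)
        assert abs(dec.coulombic) < 1e-3
        assert abs(dec.van_der_waals) < 1e-3

    def test_total_is_component_sum(self, mode_pairs):
        dec = binding_energy(mode_pairs[2].fixed, mode_pairs[2].moving)
        assert dec.total == pytest.approx(
            dec.polar_solvation + dec.nonpolar_solvation
            + dec.van_der_waals + dec.coulombic, abs=1e-6)

    def test_polar_opposes_coulomb_for_charged_pair(self):
        a, b = two_atoms(6.0, q=(+1.0, -1.0))
        dec = binding_energy(a, b, sasa_params=(0.0, 0.0))
        assert dec.coulombic < 0 < dec.polar_solvation
        assert abs(dec.polar_solvation) < abs(dec.coulombic)

    def test_rigid_motion_invariance(self, mode_pairs):
        pair = mode_pairs[1]
        dec0 = binding_energy(pair.fixed, pair.moving)
        R = rotation_about_axis([1, 1, 1], 53.0)
        t = np.array([5.0, -3.0, 8.0])
        fixed_r = pair.fixed.with_positions(pair.fixed.positions @ R.T + t)
        moving_r = pair.moving.with_positions(pair.moving.positions @ R.T + t)
        dec1 = binding_energy(fixed_r, moving_r)
        for term in ("polar_solvation", "van_der_waals", "coulombic"):
            assert getattr(dec1, term) == pytest.approx(getattr(dec0, term), abs=1e-6)
        # SASA is quadrature-based: looser tolerance
        assert dec1.nonpolar_solvation == pytest.approx(dec0.nonpolar_solvation,
                                                        abs=1e-2)

    def test_mismatched_lj_params_rejected(self, mode_pairs):
        pair = mode_pairs[1]
        with pytest.raises(ValueError, match="LJ"):
            binding_energy(pair.fixed, pair.moving,
                           lj_params=(LJParams.uniform(1), LJParams.uniform(1)))


class TestFrameAverage:
    def test_identical_frames_zero_sd(self, mode_pairs):
        frames = make_frame_ensemble(mode_pairs[1], 3, jitter_sd=0.0, seed=0)
        mean, sd = frame_average_energy(frames, sasa_points=100)
        for term in ("polar_solvation", "nonpolar_solvation", "van_der_waals",
                     "coulombic", "total"):
            assert getattr(sd, term) == pytest.approx(0.0, abs=1e-9)

    def test_mean_and_sd_match_numpy_oracle(self, mode_pairs):
        frames = make_frame_ensemble(mode_pairs[1], 4, jitter_sd=0.8, seed=9)
        per_frame = [binding_energy(a, b, sasa_points=100) for a, b in frames]
        mean, sd = frame_average_energy(frames, sasa_points=100)
        totals = [d.total for d in per_frame]
        assert mean.total == pytest.approx(np.mean(totals), abs=1e-9)
        assert sd.total == pytest.approx(np.std(totals, ddof=1), abs=1e-9)
        # two-value check: mean of sums equals sum of means
        assert mean.total == pytest.approx(
            mean.polar_solvation + mean.nonpolar_solvation + mean.van_der_waals
            + mean.coulombic, abs=1e-9)

    def test_single_frame_rejected(self, mode_pairs):
        frames = make_frame_ensemble(mode_pairs[1], 1, seed=0)
        with pytest.raises(ValueError, match="2 frames"):
            frame_average_energy(frames)
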