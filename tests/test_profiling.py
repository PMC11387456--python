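"""Group statistics: frequencies, differentials, correlations, RMSF, concordance."""

import itertools
import math

import numpy as np
import pytest

from siftkit.datasets import mutagenesis_path
from siftkit.interactions import SIFt
from siftkit.profiling import (
    ContactProfile,
    MutationEffect,
    MutationRecord,
    agonist_exclusion,
    contact_frequency,
    differential_contacts,
    frequent_positions,
    ligand_rmsf,
    mutagenesis_concordance,
    read_mutation_table,
    spearman_contact_activity,
)
from siftkit.structures import superpose_frames
from siftkit.synthetic_data import SyntheticSpec, simulate_complex, simulate_sift_panel, simulate_trajectory


def _sift(bits_row, panel=None, scheme=("contact",), cid="s"):
    bits = np.asarray(bits_row, dtype=bool).reshape(-1, len(scheme))
    panel = panel or [f"p{i:03d}" for i in range(bits.shape[0])]
    return SIFt(panel=list(panel), scheme=list(scheme), bits=bits, complex_id=cid)


class TestContactFrequency:
    def test_two_of_three(self):
        sifts = [_sift([1, 0]), _sift([1, 1]), _sift([0, 0])]
        profile = contact_frequency(sifts)
        assert profile.frequencies.tolist() == [2 / 3, 1 / 3]
        assert profile.n == 3

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            contact_frequency([])

    def test_mismatched_panels_rejected(self):
        with pytest.raises(ValueError):
            contact_frequency([_sift([1]), _sift([1, 0])])

    def test_bernoulli_panel_recovers_rate(self):
        spec = SyntheticSpec(seed=23, n_active=200, n_inactive=1,
                             planted_deltas={}, null_p=0.6)
        active, _, _ = simulate_sift_panel(spec, panel_size=8)
        profile = contact_frequency(active)
        tol = 3 * math.sqrt(0.6 * 0.4 / 200)
        assert np.all(np.abs(profile.frequencies - 0.6) <= tol)


class TestFrequentPositions:
    def test_strict_inequality_at_threshold(self):
        profile = ContactProfile(["a", "b"], [0.60, 0.61], n=100)
        assert frequent_positions([profile], threshold=0.60) == ["b"]

    def test_full_panel_when_always_contacted(self):
        profile = ContactProfile(["a", "b", "c"], [1.0, 1.0, 1.0], n=10)
        assert frequent_positions([profile]) == ["a", "b", "c"]

    def test_union_over_groups(self):
        g1 = ContactProfile(["a", "b", "c"], [0.2, 0.3, 0.9], n=10, group_label="g1")
        g2 = ContactProfile(["a", "b", "c"], [0.7, 0.65, 0.1], n=10, group_label="g2")
        assert frequent_positions([g1, g2]) == ["a", "b", "c"]

    def test_monotone_decreasing_in_threshold(self):
        rng = np.random.default_rng(5)
        profile = ContactProfile([f"r{i}" for i in range(20)], rng.random(20), n=50)
        sizes = [len(frequent_positions([profile], t)) for t in (0.2, 0.4, 0.6, 0.8)]
        assert sizes == sorted(sizes, reverse=True)


class TestDifferentialContacts:
    def test_full_separation_ranks_first(self):
        active = [_sift([1, 1]), _sift([1, 0])]
        inactive = [_sift([0, 1]), _sift([0, 0])]
        diff = differential_contacts(active, inactive)
        assert diff[0].residue == "p000"
        assert diff[0].delta == pytest.approx(1.0)

    def test_identical_groups_all_zero(self):
        group = [_sift([1, 0, 1]), _sift([0, 1, 1])]
        diff = differential_contacts(group, group)
        assert all(d.delta == 0.0 for d in diff)

    def test_swapping_groups_negates_delta(self):
        spec = SyntheticSpec(seed=29)
        active, inactive, _ = simulate_sift_panel(spec, panel_size=12)
        fwd = differential_contacts(active, inactive)
        rev = differential_contacts(inactive, active)
        fwd_by_res = {d.residue: d for d in fwd}
        for d in rev:
            assert d.delta == pytest.approx(-fwd_by_res[d.residue].delta)
        assert [d.residue for d in fwd] == [d.residue for d in rev]

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            differential_contacts([], [_sift([1])])

    def test_planted_residue_ranks_first(self):
        spec = SyntheticSpec(seed=29, planted_deltas={"p000": 0.4}, null_p=0.3)
        active, inactive, truth = simulate_sift_panel(spec, panel_size=31)
        diff = differential_contacts(active, inactive)
        assert diff[0].residue in truth["planted"]

    def test_top_k_truncates(self):
        spec = SyntheticSpec(seed=31)
        active, inactive, _ = simulate_sift_panel(spec, panel_size=10)
        assert len(differential_contacts(active, inactive, top_k=3)) == 3


class TestAgonistExclusion:
    def test_agonist_contacting_everything_empties_result(self):
        diff = differential_contacts([_sift([1, 1])], [_sift([0, 0])])
        agonist = _sift([1, 1])
        assert agonist_exclusion(diff, agonist) == []

    def test_agonist_contacting_nothing_keeps_all(self):
        diff = differential_contacts([_sift([1, 1])], [_sift([0, 0])])
        agonist = _sift([0, 0])
        assert agonist_exclusion(diff, agonist) == diff

    def test_partial_exclusion_preserves_ranking(self):
        active = [_sift([1, 1, 1]), _sift([1, 1, 0])]
        inactive = [_sift([0, 0, 0]), _sift([0, 1, 0])]
        diff = differential_contacts(active, inactive)
        agonist = _sift([1, 0, 0])     # contacts the top residue only
        kept = agonist_exclusion(diff, agonist)
        assert [d.residue for d in kept] == \
            [d.residue for d in diff if d.residue != "p000"]


class TestSpearman:
    def test_perfect_anticorrelation(self):
        freqs = {"c1": {"r": 0.9}, "c2": {"r": 0.5}, "c3": {"r": 0.1}}
        acts = {"c1": 10.0, "c2": 100.0, "c3": 1000.0}
        results = spearman_contact_activity(freqs, acts)
        assert results[0].rho == pytest.approx(-1.0)
        assert results[0].sign_set.value == "-1"

    def test_constant_frequency_is_undefined_not_zero(self):
        freqs = {c: {"r": 0.5} for c in ("c1", "c2", "c3")}
        acts = {"c1": 1.0, "c2": 2.0, "c3": 3.0}
        results = spearman_contact_activity(freqs, acts)
        assert math.isnan(results[0].rho)
        assert results[0].sign_set.value == "undefined"

    def test_all_permutations_match_closed_form(self):
        """Each of the 6 rank orders at n=3 gives rho in {1, 0.5, -0.5, -1},
        equal to 1 - 6*sum(d^2)/(n(n^2-1))."""
        acts = {"c1": 10.0, "c2": 100.0, "c3": 1000.0}   # ranks 1, 2, 3
        levels = [0.1, 0.5, 0.9]                          # ranks 1, 2, 3
        seen = set()
        for perm in itertools.permutations(range(3)):
            freqs = {f"c{i+1}": {"r": levels[perm[i]]} for i in range(3)}
            rho = spearman_contact_activity(freqs, acts)[0].rho
            d2 = sum((perm[i] - i) ** 2 for i in range(3))
            closed_form = 1 - 6 * d2 / (3 * (9 - 1))
            assert rho == pytest.approx(closed_form)
            seen.add(round(rho, 6))
        assert seen == {1.0, 0.5, -0.5, -1.0}

    def test_invariant_under_monotone_transform_of_activity(self):
        rng = np.random.default_rng(37)
        freqs = {f"c{i}": {"r1": rng.random(), "r2": rng.random()} for i in range(8)}
        acts = {f"c{i}": float(10 ** rng.uniform(0, 4)) for i in range(8)}
        log_acts = {c: math.log(v) for c, v in acts.items()}
        raw = spearman_contact_activity(freqs, acts)
        logged = spearman_contact_activity(freqs, log_acts)
        for a, b in zip(raw, logged):
            assert a.rho == pytest.approx(b.rho)

    def test_too_few_compounds_rejected(self):
        with pytest.raises(ValueError):
            spearman_contact_activity({"c1": {"r": 1.0}, "c2": {"r": 0.0}},
                                      {"c1": 1.0, "c2": 2.0})


class TestLigandRmsf:
    def test_identical_frames_zero(self):
        base, _ = simulate_complex("ionic", seed=31)
        spec = SyntheticSpec(seed=31, jitter_sigma_A=0.0)
        frames, _ = simulate_trajectory(base, spec, n_frames=10)
        result = ligand_rmsf(frames)
        assert result.ligand_mean_rmsf == pytest.approx(0.0, abs=1e-12)

    def test_gaussian_jitter_matches_closed_form(self):
        """Isotropic jitter sigma per coordinate gives per-atom RMSF of
        sigma*sqrt(3)."""
        sigma = 0.25
        base, _ = simulate_complex("ionic", seed=31)
        spec = SyntheticSpec(seed=31, jitter_sigma_A=sigma)
        frames, _ = simulate_trajectory(base, spec, n_frames=2000)
        aligned, _ = superpose_frames(frames)
        result = ligand_rmsf(aligned)
        expected = sigma * math.sqrt(3)
        assert np.all(np.abs(result.per_atom_rmsf - expected) <= 0.03 * expected)
        assert result.ligand_mean_rmsf == pytest.approx(
            float(np.mean(result.per_atom_rmsf)))

    def test_rigid_transform_of_all_frames_leaves_rmsf_unchanged(self):
        from siftkit.structures import _transform_complex
        from scipy.spatial.transform import Rotation
        base, _ = simulate_complex("ionic", seed=33)
        spec = SyntheticSpec(seed=33, jitter_sigma_A=0.1)
        frames, _ = simulate_trajectory(base, spec, n_frames=50)
        rng = np.random.default_rng(33)
        quat = rng.standard_normal(4)
        R = Rotation.from_quat(quat / np.linalg.norm(quat)).as_matrix()
        t = rng.uniform(-5, 5, 3)
        moved = [_transform_complex(cx, R, t) for cx in frames]
        a = ligand_rmsf(frames).per_atom_rmsf
        b = ligand_rmsf(moved).per_atom_rmsf
        np.testing.assert_allclose(a, b, atol=1e-9)

    def test_single_frame_rejected(self):
        base, _ = simulate_complex("ionic", seed=31)
        with pytest.raises(ValueError):
            ligand_rmsf([base])


class TestMutagenesisConcordance:
    def test_loss_mutation_is_concordant(self):
        flagged = ["D3x32"]
        mutations = [MutationRecord("3x32", "D3x32A", MutationEffect.LOSS)]
        report = mutagenesis_concordance(flagged, mutations)
        assert report.flagged_effectful == ["D3x32"]
        assert report.summary_counts()["flagged_effectful"] == 1

    def test_empty_table_gives_no_data(self):
        report = mutagenesis_concordance(["3x32", "6x52"], [])
        assert report.flagged_no_data == ["3x32", "6x52"]

    def test_planted_overlap_design(self):
        flagged = ["3x32", "5x43", "7x38"]
        mutations = [
            MutationRecord("3x32", "D3x32A", MutationEffect.LOSS),
            MutationRecord("5x43", "S5x43A", MutationEffect.MIXED),
            MutationRecord("6x52", "F6x52A", MutationEffect.DECREASE),
        ]
        report = mutagenesis_concordance(flagged, mutations)
        counts = report.summary_counts()
        assert counts == {"flagged_effectful": 1, "flagged_no_data": 1,
                          "effectful_unflagged": 1}
        assert report.per_residue["5x43"] == "mixed"

    def test_bundled_table_reads(self):
        mutations = read_mutation_table(mutagenesis_path())
        assert {m.residue for m in mutations} == \
            {"3x32", "3x33", "7x42", "7x38", "2x64", "6x52", "5x43"}


def test_profile_and_differential_plots_render(tmp_path):
    spec = SyntheticSpec(seed=3)
    active, inactive, _ = simulate_sift_panel(spec, panel_size=8)
    from siftkit.profiling import plot_contact_profiles, plot_differential
    profiles = [contact_frequency(active, group_label="active"),
                contact_frequency(inactive, group_label="inactive")]
    plot_contact_profiles(profiles, tmp_path / "profiles.svg")
    plot_differential(differential_contacts(active, inactive),
                      tmp_path / "diff.svg")
    assert (tmp_path / "profiles.svg").stat().st_size > 0
    assert (tmp_path / "diff.svg").stat().st_size > 0
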