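"""Ground-truthed generators: determinism, structure, and planted effects."""

import numpy as np
import pytest

from cortexdev import (
    CellCycleParams,
    SimConfig,
    gen_expression,
    gen_labeling_curve,
    gen_mitosis_tracks,
    gen_orientation_tracks,
    gen_toy_alignment,
    gen_zone_reference,
    predict_labeling,
)
from cortexdev.mitosis_timing import PHASE_NAMES, phase_durations
from cortexdev.synthetic_data import InvalidConfig


class TestSimConfig:
    def test_too_few_cells_rejected(self):
        with pytest.raises(InvalidConfig):
            SimConfig(n_cells=3)

    def test_negative_effect_rejected(self):
        with pytest.raises(InvalidConfig):
            SimConfig(type_effect=-1.0)

    def test_dropout_outside_unit_interval_rejected(self):
        with pytest.raises(InvalidConfig):
            SimConfig(dropout_rate=1.5)


class TestGenExpression:
    def test_seeded_rerun_identical(self):
        a, _, _ = gen_expression(SimConfig(seed=5))
        b, _, _ = gen_expression(SimConfig(seed=5))
        assert np.array_equal(a.values.to_numpy(), b.values.to_numpy())

    def test_different_seeds_differ(self):
        a, _, _ = gen_expression(SimConfig(seed=5))
        b, _, _ = gen_expression(SimConfig(seed=6))
        assert not np.array_equal(a.values.to_numpy(), b.values.to_numpy())

    def test_shapes_and_truth_consistency(self, default_sim):
        matrix, meta, truth = default_sim
        assert matrix.n_cells == 120 and matrix.n_genes == 300
        assert set(meta.table["species"]) == {"human", "chimpanzee"}
        u = truth.pseudotime
        # types are the pseudotime thirds
        expected = np.where(u < 1 / 3, "AP", np.where(u < 2 / 3, "BP", "N"))
        assert (truth.true_type.to_numpy() == expected).all()
        # neurons are postmitotic
        assert (truth.true_phase[truth.true_type == "N"] == "G1").all()
        # marker blocks are disjoint
        sets = [
            set(truth.signature_genes["NSPC"]),
            set(truth.signature_genes["neuron"]),
            set(truth.bp_genes),
            set(truth.g2m_genes),
            set(truth.species_shift_genes.index),
        ]
        assert sum(len(s) for s in sets) == len(set().union(*sets))

    def test_values_non_negative(self, default_matrix):
        assert (default_matrix.values.to_numpy() >= 0).all()

    def test_species_label_permutation_destroys_shift(self, default_sim):
        matrix, _, truth = default_sim
        ap = truth.true_type == "AP"
        x = matrix.values.loc[ap, truth.species_shift_genes.index]
        labels = truth.species[ap].to_numpy()
        real = np.abs(
            x[labels == "human"].mean() - x[labels == "chimpanzee"].mean()
        ).mean()
        rng = np.random.default_rng(1)
        perm = rng.permutation(labels)
        shuffled = np.abs(
            x[perm == "human"].mean() - x[perm == "chimpanzee"].mean()
        ).mean()
        effect = float(truth.species_shift_genes.iloc[0])
        assert real > effect / 2
        assert shuffled < effect / 2


class TestGenZoneReference:
    def test_profiles_cover_four_zones(self, default_sim):
        matrix, _, truth = default_sim
        ref = gen_zone_reference(truth, matrix)
        assert list(ref.profiles.columns) == ["VZ", "iSVZ", "oSVZ", "CP"]
        assert len(ref.profiles) == matrix.n_genes

    def test_too_few_cells_rejected(self):
        matrix, _, truth = gen_expression(SimConfig(seed=0))
        small = type(matrix)(matrix.values.iloc[:3], scale=matrix.scale)
        truth.pseudotime = truth.pseudotime.iloc[:3]
        with pytest.raises(Exception):
            gen_zone_reference(truth, small)


class TestGenMitosisTracks:
    GROUPS = [
        (
            "g",
            dict(prophase=5.5, prometaphase=8.8, metaphase=11.0, anaphase=2.2, telophase=5.5),
            dict(prophase=0.0, prometaphase=0.0, metaphase=0.0, anaphase=0.0, telophase=0.0),
            4,
        )
    ]

    def test_zero_sd_durations_equal_means(self):
        # means sit on the frame grid, so zero sd reproduces them exactly
        tracks = gen_mitosis_tracks(self.GROUPS, seed=0)
        for t in tracks:
            d = phase_durations(t)
            assert np.allclose(
                [getattr(d, p) for p in PHASE_NAMES], [5.5, 8.8, 11.0, 2.2, 5.5]
            )

    def test_seeded_rerun_identical(self):
        groups = [
            ("a", dict.fromkeys(PHASE_NAMES, 6.6), dict.fromkeys(PHASE_NAMES, 2.0), 60)
        ]
        t1 = gen_mitosis_tracks(groups, seed=3)
        t2 = gen_mitosis_tracks(groups, seed=3)
        assert all(
            np.array_equal(a.event_times, b.event_times) for a, b in zip(t1, t2)
        )

    def test_planted_group_shift_recovered(self):
        human = dict(prophase=5.5, prometaphase=8.8, metaphase=11.0, anaphase=2.2, telophase=5.5)
        chimp = dict(prophase=5.5, prometaphase=7.7, metaphase=7.1, anaphase=2.2, telophase=5.5)
        sds = dict.fromkeys(PHASE_NAMES, 2.0)
        tracks = gen_mitosis_tracks(
            [("human", human, sds, 60), ("chimp", chimp, sds, 60)], seed=11
        )
        pm = {
            g: np.array(
                [phase_durations(t).prometa_meta for t in tracks if t.group == g]
            )
            for g in ("human", "chimp")
        }
        diff = pm["human"].mean() - pm["chimp"].mean()
        sem = np.sqrt(pm["human"].var() / 60 + pm["chimp"].var() / 60)
        assert abs(diff - 5.0) < 3 * sem

    def test_tracks_validate_on_construction(self):
        tracks = gen_mitosis_tracks(self.GROUPS, seed=0)
        for t in tracks:
            frames = t.event_times / t.frame_interval
            assert np.abs(frames - np.round(frames)).max() < 1e-6

    def test_nonpositive_mean_rejected(self):
        bad = [("g", dict.fromkeys(PHASE_NAMES, 0.0), dict.fromkeys(PHASE_NAMES, 1.0), 2)]
        with pytest.raises(InvalidConfig):
            gen_mitosis_tracks(bad, seed=0)


class TestGenOrientationTracks:
    def test_zero_jitter_zero_drift_constant(self):
        tracks = gen_orientation_tracks(n=3, base_angle=45.0, jitter_sd=0.0, seed=0)
        for t in tracks:
            assert np.allclose(t.angles, 45.0)

    def test_samples_cover_cleavage_readout(self):
        for t in gen_orientation_tracks(n=2, seed=1):
            assert t.times.max() >= t.t_anaphase_onset + 2.2 - 1e-9

    def test_angles_bounded(self):
        for t in gen_orientation_tracks(n=5, base_angle=88.0, jitter_sd=10.0, seed=2):
            assert ((t.angles >= 0) & (t.angles <= 90)).all()

    def test_jitter_sd_recovered_empirically(self):
        tracks = gen_orientation_tracks(n=500, base_angle=45.0, jitter_sd=5.0, seed=3)
        sd = np.std(np.concatenate([t.angles for t in tracks]) - 45.0, ddof=1)
        assert 3.0 < sd < 7.0

    def test_out_of_range_base_angle_rejected(self):
        with pytest.raises(InvalidConfig):
            gen_orientation_tracks(n=1, base_angle=120.0)


class TestGenLabelingCurve:
    PARAMS = CellCycleParams(tc=46.5, ts=17.5, gf=0.9)

    def test_noiseless_matches_closed_form(self):
        c = gen_labeling_curve(self.PARAMS, [0.0, 6.0, 29.0, 48.0])
        assert np.isclose(c.labeling_index[0], 0.9 * 17.5 / 46.5)
        assert np.isclose(c.labeling_index[1], 0.454839, atol=5e-7)
        assert np.isclose(c.labeling_index[2], 0.9)  # t = Tc - Ts
        assert np.isclose(c.labeling_index[3], 0.9)

    def test_noiseless_non_decreasing_and_bounded(self):
        t = np.linspace(0, 60, 121)
        c = gen_labeling_curve(self.PARAMS, t)
        assert (np.diff(c.labeling_index) >= -1e-12).all()
        assert (c.labeling_index <= self.PARAMS.gf + 1e-12).all()

    def test_noise_clipped_to_unit_interval(self):
        c = gen_labeling_curve(self.PARAMS, [48.0] * 50, noise_sd=0.5, seed=0)
        assert ((c.labeling_index >= 0) & (c.labeling_index <= 1)).all()

    def test_replicates_recorded(self):
        c = gen_labeling_curve(self.PARAMS, [1.0, 2.0], replicates=3, seed=0)
        assert len(c.times_h) == 6
        assert sorted(set(c.replicate)) == [0, 1, 2]

    def test_negative_time_rejected(self):
        with pytest.raises(InvalidConfig):
            gen_labeling_curve(self.PARAMS, [-1.0])


class TestGenToyAlignment:
    def test_no_events_identical_gapless(self):
        aln, truth = gen_toy_alignment(30, seed=0)
        assert aln.seq_a == aln.seq_b
        assert "-" not in aln.seq_a
        assert truth["snp_positions"] == []

    def test_single_snp_one_mismatch_column(self):
        aln, truth = gen_toy_alignment(30, n_snps=1, seed=1)
        mismatches = [
            i
            for i, (a, b) in enumerate(zip(aln.seq_a, aln.seq_b))
            if a != b and a != "-" and b != "-"
        ]
        assert len(mismatches) == 1
        assert truth["snp_positions"] == mismatches  # gapless: column == ref pos

    def test_configured_indels_present(self):
        aln, truth = gen_toy_alignment(40, indels=[(10, 2, "b"), (25, 3, "a")], seed=2)
        assert aln.seq_b.count("-") == 2
        assert aln.seq_a.count("-") == 3
        assert truth["indels"] == [(10, 2, "b"), (25, 3, "a")]

    def test_seeded_rerun_identical(self):
        a1, _ = gen_toy_alignment(50, n_snps=4, indels=[(9, 2, "b")], seed=9)
        a2, _ = gen_toy_alignment(50, n_snps=4, indels=[(9, 2, "b")], seed=9)
        assert (a1.seq_a, a1.seq_b) == (a2.seq_a, a2.seq_b)

    def test_overlapping_indels_rejected(self):
        with pytest.raises(InvalidConfig, match="overlap"):
            gen_toy_alignment(40, indels=[(10, 3, "b"), (11, 2, "b")], seed=0)

    def test_out_of_bounds_indel_rejected(self):
        with pytest.raises(InvalidConfig):
            gen_toy_alignment(10, indels=[(8, 5, "b")], seed=0)
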