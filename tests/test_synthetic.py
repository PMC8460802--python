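"""Simulator behavior: synchrony model, counts, annotation, reads."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

import cyclemark as cm
from cyclemark.synthetic import (latent_expression, read_bed, read_facs,
                                 wrapped_normal_arc_mass, write_bed,
                                 write_facs)


class TestSynchrony:
    def test_fraction_rows_sum_to_one(self, default_design):
        fr, _ = cm.simulate_synchrony(cm.SynchronyModel(), default_design, seed=1)
        assert np.allclose(fr.sum(axis=1), 1.0, atol=1e-9)

    @settings(derandomize=True, max_examples=40, deadline=None)
    @given(sigma0=st.floats(0.0, 0.5), kappa=st.floats(0.0, 0.05),
           release=st.floats(0.0, 0.999))
    def test_fraction_rows_sum_to_one_any_parameters(self, sigma0, kappa, release):
        model = cm.SynchronyModel(sigma0=sigma0, kappa=kappa,
                                  release_position=release)
        design = cm.TimeCourseDesign(time_points_hours=(0, 6, 24))
        fr, _ = cm.simulate_synchrony(model, design, seed=0)
        assert np.allclose(fr.sum(axis=1), 1.0, atol=1e-9)

    def test_early_s_phase_entry(self, default_design):
        """Most cells enter the first S wave shortly after release."""
        fr, _ = cm.simulate_synchrony(cm.SynchronyModel(), default_design, seed=0)
        for rep in default_design.replicates:
            assert fr.loc[(rep, 3.0), "S"] >= 0.85

    def test_second_s_wave_weaker(self, default_design):
        """Synchrony decay: the second S-phase wave is lower than the first."""
        model = cm.SynchronyModel()
        first = max(wrapped_normal_arc_mass(*model.position_at(t), 0.40, 0.75)
                    for t in np.linspace(0, 7, 200))
        second = max(wrapped_normal_arc_mass(*model.position_at(t), 0.40, 0.75)
                     for t in np.linspace(14, 21, 200))
        assert first == pytest.approx(0.9, abs=0.05)
        assert second == pytest.approx(0.7, abs=0.07)
        assert second < first

    def test_infinite_dispersion_approaches_arc_lengths(self):
        model = cm.SynchronyModel()
        for phase, (a, b) in model.phase_intervals.items():
            mass = wrapped_normal_arc_mass(0.3, 50.0, a, b, n_images=300)
            assert mass == pytest.approx(b - a, abs=1e-6)

    def test_zero_dispersion_is_arc_indicator(self):
        model = cm.SynchronyModel(sigma0=0.0, kappa=0.0, replicate_jitter=0.0)
        design = cm.TimeCourseDesign(time_points_hours=(0, 3, 6))
        fr, pos = cm.simulate_synchrony(model, design, seed=0)
        for (rep, t), (mu, sd) in pos.items():
            assert sd == 0.0
            row = fr.loc[(rep, t)]
            assert sorted(row) == [0.0, 0.0, 1.0]
            phase = [p for p, (a, b) in model.phase_intervals.items()
                     if a <= mu < b][0]
            assert row[phase] == 1.0

    def test_negative_dispersion_rejected(self):
        with pytest.raises(ValueError):
            cm.SynchronyModel(sigma0=-0.1)
        with pytest.raises(ValueError):
            cm.SynchronyModel(kappa=-0.1)

    def test_phase_arcs_must_cover_circle(self):
        with pytest.raises(ValueError):
            cm.SynchronyModel(phase_intervals={"G1": (0.0, 0.4), "S": (0.5, 1.0)})


class TestExpression:
    def test_flat_gene_constant_latent(self, default_design):
        truth = cm.make_truth(n_genes=10, cyclic_frac=0.0, seed=0)
        _, pos = cm.simulate_synchrony(cm.SynchronyModel(), default_design, 0)
        lat = latent_expression(truth, pos, default_design)
        assert np.allclose(lat.std(axis=1), 0.0, atol=1e-12)

    def test_amplitude_damps_cycle_over_cycle(self, default_design):
        """Peak-to-trough range shrinks in the second cycle as synchrony decays."""
        truth = cm.make_truth(n_genes=40, cyclic_frac=1.0, seed=1)
        model = cm.SynchronyModel()
        dense = cm.TimeCourseDesign(
            time_points_hours=tuple(np.linspace(0, 28, 57)),
            replicates=("R1",))
        model_nj = cm.SynchronyModel(replicate_jitter=0.0)
        _, pos = cm.simulate_synchrony(model_nj, dense, 0)
        lat = latent_expression(truth, pos, dense)
        hours = np.array([dense.hours_of(s) for s in lat.columns])
        first = lat.loc[:, hours <= 14.0]
        second = lat.loc[:, hours > 14.0]
        r1 = first.max(axis=1) - first.min(axis=1)
        r2 = second.max(axis=1) - second.min(axis=1)
        assert (r2 < r1 + 1e-9).all()

    def test_nb_sample_mean_matches_target(self):
        """Monte-Carlo: NB draws at fixed mean m hit m within 3 SEs."""
        design = cm.TimeCourseDesign(time_points_hours=(0,),
                                     replicates=tuple(f"r{i}" for i in range(1000)))
        truth = cm.make_truth(n_genes=1, cyclic_frac=0.0, dispersion=0.1, seed=0)
        model = cm.SynchronyModel(replicate_jitter=0.0)
        _, pos = cm.simulate_synchrony(model, design, 0)
        counts, lat = cm.simulate_expression(truth, pos, design,
                                             library_sizes=1e6, seed=3)
        m = 2.0 ** lat.iloc[0, 0]
        phi = 0.1
        se = np.sqrt((m + phi * m * m) / 1000)
        assert abs(counts.iloc[0].mean() - m) < 3 * se

    def test_nonpositive_library_size_rejected(self, default_design):
        truth = cm.make_truth(n_genes=5, seed=0)
        _, pos = cm.simulate_synchrony(cm.SynchronyModel(), default_design, 0)
        with pytest.raises(ValueError):
            cm.simulate_expression(truth, pos, default_design,
                                   library_sizes=0.0, seed=0)


class TestAnnotation:
    def test_round_trip(self, tmp_path, small_dataset):
        path = tmp_path / "ann.gtf"
        cm.write_gtf(small_dataset.annotation, path)
        assert cm.read_gtf(path) == small_dataset.annotation

    def test_far_spaced_tss_pair(self):
        """PCNA-like layout: two transcript 5' ends 6,664 bp apart."""
        truth = cm.make_truth(n_genes=200, seed=3)
        ann, _ = cm.generate_annotation(truth, seed=3)
        cat = cm.select_tss(ann)
        far = truth.loc[truth["tss_spacing"] == 6664, "gene_id"]
        assert len(far) > 0
        assert (cat.loc[far, "tss_span"] == 6664).all()

    def test_single_tss_neighbor_distance_exact(self):
        truth = cm.make_truth(n_genes=300, seed=5)
        ann, _ = cm.generate_annotation(truth, seed=5)
        cat = cm.select_tss(ann)
        dist = cm.neighbor_distances(cat)
        t = truth.set_index("gene_id")
        # for neighbor pairs where both members have a single TSS the
        # realized representative-TSS distance equals the request
        nb = t[t["has_neighbor"]]
        for a, b in zip(nb.index[0::2], nb.index[1::2]):
            if t.loc[a, "n_tss"] == 1 and t.loc[b, "n_tss"] == 1:
                assert dist[a] == t.loc[a, "neighbor_distance"]

    def test_isolated_genes_far_from_others(self):
        truth = cm.make_truth(n_genes=200, seed=9)
        ann, _ = cm.generate_annotation(truth, seed=9)
        dist = cm.neighbor_distances(cm.select_tss(ann))
        iso = truth.loc[~truth["has_neighbor"], "gene_id"]
        assert (dist[iso] > 10_000).all()

    def test_too_small_genome_rejected(self):
        truth = cm.make_truth(n_genes=50, seed=0)
        with pytest.raises(ValueError):
            cm.generate_annotation(truth, genome_length=10_000, seed=0)

    def test_representative_tss_is_longest_transcript(self, small_dataset):
        cat = cm.select_tss(small_dataset.annotation)
        tx = small_dataset.annotation.transcripts
        for gid, row in cat.head(30).iterrows():
            sub = tx[tx["gene_id"] == gid]
            span = (sub["end"] - sub["start"]).max()
            chosen = sub[sub["transcript_id"] == row["transcript_id"]].iloc[0]
            assert chosen["end"] - chosen["start"] == span


@pytest.fixture(scope="module")
def flat_truth_reads():
    design = cm.TimeCourseDesign(time_points_hours=(0, 3, 6),
                                 replicates=("R1",))
    truth = cm.make_truth(n_genes=30, cyclic_frac=0.0, seed=2)
    model = cm.SynchronyModel()
    _, pos = cm.simulate_synchrony(model, design, 2)
    lat = latent_expression(truth, pos, design)
    ann, sizes = cm.generate_annotation(truth, seed=2)
    reads = cm.simulate_chip_reads(truth, lat, ann, sizes, design,
                                   antibodies=("polII",),
                                   reads_per_gene=200, seed=2)
    return design, truth, ann, sizes, reads


class TestChipReads:
    def test_uncoupled_counts_poisson_stable(self, flat_truth_reads):
        """Slope-0 genes: per-sample TSS read counts differ only by
        Poisson noise around a common mean.  Counted over the central
        bins of isolated genes so neighboring genes' windows don't
        contribute."""
        design, truth, ann, sizes, reads = flat_truth_reads
        cat = cm.select_tss(ann)
        iso = truth.loc[~truth["has_neighbor"], "gene_id"]
        per_sample = []
        for s in design.sample_ids:
            bins = cm.bin_tss_region(reads[("polII", s)], cat.loc[iso], sizes)
            per_sample.append(bins.iloc[:, 85:115].sum(axis=1))
        per_sample = pd.DataFrame(per_sample)
        lam = 200.0
        z = (per_sample - lam) / np.sqrt(lam)
        assert np.abs(z.to_numpy()).max() < 5.0

    def test_input_track_uniform(self, flat_truth_reads):
        """Input read positions pass a chi-square uniformity check."""
        design, truth, ann, sizes, reads = flat_truth_reads
        rng = np.random.default_rng(0)
        glen = sizes["chrSim"]
        inp = pd.concat([reads[("input", s)] for s in design.sample_ids])
        mids = ((inp["start"] + inp["end"]) // 2).to_numpy()
        nbins = 40
        obs, _ = np.histogram(mids, bins=nbins, range=(0, glen))
        assert sps.chisquare(obs).pvalue > 0.01

    def test_depth_doubling_doubles_counts(self):
        design = cm.TimeCourseDesign(time_points_hours=(0,), replicates=("R1",))
        truth = cm.make_truth(n_genes=40, cyclic_frac=0.0, seed=4)
        model = cm.SynchronyModel()
        _, pos = cm.simulate_synchrony(model, design, 4)
        lat = latent_expression(truth, pos, design)
        ann, sizes = cm.generate_annotation(truth, seed=4)
        n1 = sum(len(df) for (ab, s), df in cm.simulate_chip_reads(
            truth, lat, ann, sizes, design, antibodies=("polII",),
            reads_per_gene=100, seed=4).items() if ab == "polII")
        n2 = sum(len(df) for (ab, s), df in cm.simulate_chip_reads(
            truth, lat, ann, sizes, design, antibodies=("polII",),
            reads_per_gene=200, seed=4).items() if ab == "polII")
        assert n2 / n1 == pytest.approx(2.0, rel=0.05)

    def test_nonpositive_depth_rejected(self, flat_truth_reads):
        design, truth, ann, sizes, _ = flat_truth_reads
        with pytest.raises(ValueError):
            cm.simulate_chip_reads(truth, pd.DataFrame(), ann, sizes, design,
                                   reads_per_gene=0)


class TestFileRoundTrips:
    def test_bed_round_trip(self, tmp_path, small_dataset):
        key = next(iter(small_dataset.reads))
        df = small_dataset.reads[key].head(500)
        path = tmp_path / "reads.bed"
        write_bed(df, path)
        back = read_bed(path)
        pd.testing.assert_frame_equal(back, df.reset_index(drop=True))

    def test_malformed_bed_rejected(self, tmp_path):
        path = tmp_path / "bad.bed"
        path.write_text("chr1\t100\t50\tx\t0\t+\n")
        with pytest.raises(ValueError, match="line 1"):
            read_bed(path)

    def test_facs_round_trip(self, tmp_path, small_dataset):
        path = tmp_path / "facs.tsv"
        write_facs(small_dataset.fractions, path)
        back = read_facs(path)
        assert np.allclose(back.to_numpy(), small_dataset.fractions.to_numpy())
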