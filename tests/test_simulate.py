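"""Properties of the synthetic cohort generators."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from mutbench.genome import IntervalTrack
from mutbench.simulate import (
    CallerProfile,
    CohortConfig,
    random_error_sites,
    simulate_counts,
    simulate_depth_track,
    simulate_submission,
    simulate_truth,
    thin_and_mix,
)
from mutbench.variants import read_callset, write_callset
from tests.conftest import SMALL_CONFIG

TINY = CohortConfig(
    contig_lengths={"1": 200_000},
    contig_copy_number={"1": 4},
    mutation_rate_per_mb=150.0,
)


class TestTruth:
    def test_deterministic_given_seed(self):
        _, t1 = simulate_truth(TINY, seed=3)
        _, t2 = simulate_truth(TINY, seed=3)
        pd.testing.assert_frame_equal(t1, t2)

    def test_af_consistent_with_ploidy_and_clone(self, small_cohort):
        t = small_cohort["truth"]
        cfg = small_cohort["config"]
        expected = (
            cfg.purity * t["mutated_copies"] * t["clone_fraction"] / t["copy_number"]
        )
        assert np.allclose(t["af_tumour"], expected)

    def test_clonal_only_config_gives_discrete_afs(self):
        cfg = CohortConfig(
            contig_lengths={"1": 150_000}, contig_copy_number={"1": 4},
            ssm_class_weights={1: 1.0}, sim_class_weights={1: 1.0},
            mutation_rate_per_mb=200.0,
        )
        _, truth = simulate_truth(cfg, seed=4)
        allowed = {cfg.purity * m / 4 for m in (1, 2, 3, 4)}
        assert all(any(abs(af - a) < 1e-12 for a in allowed)
                   for af in truth["af_tumour"])

    def test_planted_count_matches_rate_across_seeds(self):
        cfg = CohortConfig(contig_lengths={"1": 100_000},
                           contig_copy_number={"1": 4},
                           mutation_rate_per_mb=300.0)
        counts = [len(simulate_truth(cfg, seed=s)[1]) for s in range(15)]
        expected = 30.0  # 300 per Mb on 0.1 Mb
        se = np.sqrt(expected / len(counts))
        # a small deficit is expected from collision rejection near repeats
        assert abs(np.mean(counts) - expected) < max(4 * se, 0.15 * expected)

    def test_truth_mutations_match_reference(self, small_cohort):
        sg, truth = small_cohort["sg"], small_cohort["truth"]
        for r in truth.sample(50, random_state=0).itertuples(index=False):
            assert sg.genome.fetch(r.chrom, r.pos, r.pos + len(r.ref)) == r.ref

    def test_annotated_repeats_occur_literally(self, small_cohort):
        sg = small_cohort["sg"]
        for chrom, s, e, label in list(sg.repeat_track)[:40]:
            seq = sg.genome.fetch(chrom, s, e)
            if label == "homopolymer":
                assert len(set(seq)) == 1
            elif label == "microsatellite":
                assert any(
                    seq == (seq[:p] * ((e - s) // p + 1))[: len(seq)]
                    for p in range(2, 7)
                )


class TestCounts:
    def _truth_df(self, sg, af, n=2000, af_normal=0.0):
        rng = np.random.default_rng(0)
        pos = np.sort(rng.choice(np.arange(200, sg.genome.length("1") - 200),
                                 size=n, replace=False))
        refs = [sg.genome.base("1", int(p)) for p in pos]
        return pd.DataFrame({
            "chrom": "1", "pos": pos, "ref": refs,
            "alt": ["T" if r != "T" else "A" for r in refs],
            "mut_class": "SSM", "planted_class": 1, "af_tumour": af,
            "af_normal": af_normal, "clone": "clonal", "copy_number": 4,
            "mutated_copies": 2, "clone_fraction": 1.0, "ambiguous": False,
            "depth_mult": 1.0, "in_tr": False,
        })

    @pytest.fixture(scope="class")
    @staticmethod
    def sg():
        return simulate_truth(TINY, seed=5)[0]

    def test_degenerate_binomial_af1(self, sg):
        truth = self._truth_df(sg, af=1.0, n=300)
        ev = simulate_counts(sg, truth, error_rate=0.0, seed=1,
                             with_mappability=False)
        assert (ev["t_alt"] == ev["depth_t"]).all()
        assert (ev["n_alt"] == 0).all()

    def test_contamination_halves_observed_af(self, sg):
        truth = self._truth_df(sg, af=0.5, n=4000)
        ev = simulate_counts(sg, truth, error_rate=0.0, contamination=0.5,
                             seed=2, with_mappability=False)
        obs = (ev["t_alt"] / ev["depth_t"]).mean()
        assert obs == pytest.approx(0.25, abs=0.01)

    def test_error_only_sites_emit_low_counts(self, sg):
        truth = self._truth_df(sg, af=0.3, n=50)
        extra = random_error_sites(sg, truth, n=1000, seed=3)
        ev = simulate_counts(sg, truth, extra_sites=extra, error_rate=1e-3,
                            seed=3, with_mappability=False)
        err = ev[ev["af_true"] == 0]
        assert len(err) == 1000
        rate = err["t_alt"].sum() / err["depth_t"].sum()
        assert rate == pytest.approx(1e-3, rel=0.5)


class TestSubmission:
    def test_full_sensitivity_no_fp_reproduces_truth(self, small_cohort):
        sg, truth = small_cohort["sg"], small_cohort["truth"]
        prof = CallerProfile("all", (1.0, 1.0, 1.0), fp_rate_per_mb=0.0, seed=1)
        cs = simulate_submission(sg, truth, prof)
        assert cs.keys() == {
            (r.chrom, int(r.pos), r.ref, r.alt) for r in truth.itertuples()
        }

    def test_zero_sensitivity_gives_empty_set(self, small_cohort):
        prof = CallerProfile("none", (0.0, 0.0, 0.0), fp_rate_per_mb=0.0, seed=1)
        cs = simulate_submission(small_cohort["sg"], small_cohort["truth"], prof)
        assert len(cs) == 0

    def test_blacklist_bias_concentrates_fps(self, small_cohort):
        """FP density inside blacklisted intervals ~ 10x background."""
        sg, truth = small_cohort["sg"], small_cohort["truth"]
        bl_span = sum(e - s for _, s, e, _l in sg.blacklist_track)
        genome_span = sg.genome.total_length
        n_in = n_out = 0
        for seed in range(8):
            prof = CallerProfile("b", (0, 0, 0), fp_rate_per_mb=40.0,
                                 fp_feature_bias={"blacklist": 10.0}, seed=seed)
            cs = simulate_submission(sg, truth, prof)
            chroms = np.array([c.chrom for c in cs], dtype=object)
            poss = np.array([c.pos for c in cs])
            inside = sg.blacklist_track.overlap_mask(chroms, poss)
            n_in += int(inside.sum())
            n_out += int((~inside).sum())
        dens_in = n_in / bl_span
        dens_out = n_out / (genome_span - bl_span)
        assert dens_in / dens_out == pytest.approx(10.0, rel=0.35)

    def test_invalid_profile_rejected(self):
        with pytest.raises(ValueError):
            CallerProfile("bad", (1.2, 0.5, 0.1))


class TestThinning:
    def test_identity(self, small_cohort):
        ev = small_cohort["evidence"]
        out = thin_and_mix(ev, fraction=1.0, contamination=0.0, seed=0)
        pd.testing.assert_frame_equal(out, ev)

    def test_depth_scales_and_af_unbiased(self, small_cohort):
        ev = small_cohort["evidence"]
        muts = ev[ev["af_true"] >= 0.2]
        outs = [thin_and_mix(muts, fraction=0.1, seed=s) for s in range(10)]
        mean_depth = np.mean([o["depth_t"].mean() for o in outs])
        assert mean_depth == pytest.approx(0.1 * muts["depth_t"].mean(), rel=0.05)
        af_full = (muts["t_alt"] / muts["depth_t"]).mean()
        af_thin = np.mean([
            (o["t_alt"] / np.maximum(o["depth_t"], 1)).mean() for o in outs
        ])
        assert af_thin == pytest.approx(af_full, abs=0.015)

    def test_contamination_halves_het_af(self, small_cohort):
        ev = small_cohort["evidence"]
        muts = ev[np.isclose(ev["af_true"], 0.49)]
        out = thin_and_mix(muts, fraction=1.0, contamination=0.5, seed=2)
        af = (out["t_alt"] / np.maximum(out["depth_t"], 1)).mean()
        assert af == pytest.approx(0.245, abs=0.03)

    def test_serial_thinning_commutes_in_expectation(self, small_cohort):
        ev = small_cohort["evidence"]
        once = pd.concat([
            thin_and_mix(ev, 0.3, seed=s) for s in range(5)
        ])
        twice = pd.concat([
            thin_and_mix(thin_and_mix(ev, 0.6, seed=s), 0.5, seed=s + 100)
            for s in range(5)
        ])
        assert once["t_alt"].mean() == pytest.approx(twice["t_alt"].mean(), rel=0.05)

    def test_invalid_fraction(self, small_cohort):
        with pytest.raises(ValueError):
            thin_and_mix(small_cohort["evidence"], fraction=0.0)


class TestFixtureRoundTrip:
    def test_cohort_files_reread_losslessly(self, tmp_path, small_cohort):
        sg, truth = small_cohort["sg"], small_cohort["truth"]
        sg.write(tmp_path)
        from mutbench.genome import Genome

        g2 = Genome.from_fasta(tmp_path / "genome.fa")
        assert g2.contigs == sg.genome.contigs
        assert g2["1"] == sg.genome["1"]
        t2 = IntervalTrack.from_bed(tmp_path / "repeats.bed")
        assert t2.intervals == sg.repeat_track.intervals

        from mutbench.variants import CallSet, MutationCall

        calls = CallSet("TRUTH", [
            MutationCall(r.chrom, int(r.pos), r.ref, r.alt)
            for r in truth.itertuples(index=False)
        ])
        write_callset(calls, tmp_path / "truth.vcf", genome=sg.genome)
        back = read_callset(tmp_path / "truth.vcf")
        assert back.keys() == calls.keys()


def test_depth_track_covers_genome(small_cohort):
    sg = small_cohort["sg"]
    track = simulate_depth_track(sg, mean_depth=30.0, window=1000, seed=1)
    span = (track["end"] - track["start"]).sum()
    assert span == sg.genome.total_length
    assert track["depth"].mean() == pytest.approx(30.0, rel=0.05)
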