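"""Binning, baseline, five-state classification and CNV recovery."""

import numpy as np
import pandas as pd
import pytest

from metharray import cnv
from metharray import data_model as dm
from metharray import synthetic as syn
from metharray.errors import ConfigError, IntegrityError, MethArrayError


def _manifest_single_chrom(n, chrom="1", step=1000):
    return dm.manifest_to_frame([
        dm.ProbeAnnotation(f"cg{i:04d}", chrom, 1 + i * step, "II") for i in range(n)
    ])


class TestProbeTotals:
    def test_sum_and_floor(self):
        ds = dm.IntensityDataset(
            meth=pd.DataFrame([[300.0], [0.0]], index=["a", "b"], columns=["s"]),
            unmeth=pd.DataFrame([[200.0], [0.0]], index=["a", "b"], columns=["s"]),
            detect_p=pd.DataFrame([[0.0], [0.0]], index=["a", "b"], columns=["s"]),
            group={"s": "other"},
        )
        t = cnv.probe_totals(ds)
        assert t.loc["a", "s"] == 500.0
        assert t.loc["b", "s"] == 1.0  # floored

    def test_channel_symmetry(self, small_cohort):
        raw, _ = small_cohort
        swapped = dm.IntensityDataset(
            meth=raw.unmeth, unmeth=raw.meth, detect_p=raw.detect_p, group=raw.group
        )
        assert np.allclose(cnv.probe_totals(raw), cnv.probe_totals(swapped))


class TestBuildBins:
    def test_even_division(self):
        bins = cnv.build_bins(_manifest_single_chrom(100), probes_per_bin=25)
        assert [b.n_probes for b in bins] == [25, 25, 25, 25]

    def test_remainder_merged_into_last(self):
        bins = cnv.build_bins(_manifest_single_chrom(103), probes_per_bin=25)
        assert [b.n_probes for b in bins] == [25, 25, 25, 28]

    def test_undersized_chromosome_flagged(self):
        bins = cnv.build_bins(_manifest_single_chrom(4), probes_per_bin=25)
        assert len(bins) == 1 and bins[0].undersized

    def test_default_genome_bin_count_and_containment(self, small_manifest):
        bins = cnv.build_bins(small_manifest, probes_per_bin=50)
        n_cpg = int(small_manifest["is_cpg_target"].sum())
        assert abs(len(bins) - n_cpg // 50) <= 23  # remainder merging per chromosome
        for b in bins:
            assert small_manifest.loc[list(b.probe_ids), "chrom"].nunique() == 1

    def test_bins_ordered_nonoverlapping(self, small_manifest):
        bins = cnv.build_bins(small_manifest, probes_per_bin=50)
        for prev, cur in zip(bins, bins[1:]):
            if prev.chrom == cur.chrom:
                assert prev.end < cur.start


class TestThresholds:
    @pytest.mark.parametrize("ratio,state", [
        (-1.0, "hom_del"), (-0.96, "hom_del"), (-0.5, "hemi_del"), (-0.24, "hemi_del"),
        (0.0, "neutral"), (0.12, "dup"), (0.5, "dup"), (0.72, "high_gain"), (1.0, "high_gain"),
    ])
    def test_published_cutoffs(self, ratio, state):
        assert cnv.CNVThresholds().classify(ratio) == state

    def test_total_function_on_random_ratios(self):
        thr = cnv.CNVThresholds()
        rng = np.random.default_rng(0)
        for r in rng.uniform(-3, 3, 200):
            assert thr.classify(float(r)) in cnv.STATES

    def test_misordered_thresholds_rejected(self):
        with pytest.raises(ConfigError):
            cnv.CNVThresholds(homozygous_del_max=0.0)


def _cohort_with(planted=(), seed=7, groups=None):
    config = syn.SimulationConfig(
        seed=seed, n_probes=8000,
        n_samples_per_group=groups or {"SE": 2, "control": 5},
        planted_cnvs=tuple(planted),
    )
    manifest = syn.generate_manifest(config)
    raw, truth = syn.generate_cohort(config, manifest)
    return manifest, raw, truth


class TestBaseline:
    def test_identical_controls_zero_mad(self):
        mf = _manifest_single_chrom(60)
        vals = np.tile(np.linspace(100, 1000, 60)[:, None], (1, 3))
        ds = dm.IntensityDataset(
            meth=pd.DataFrame(vals, index=mf.index, columns=["c1", "c2", "c3"]),
            unmeth=pd.DataFrame(vals, index=mf.index, columns=["c1", "c2", "c3"]),
            detect_p=pd.DataFrame(0.0, index=mf.index, columns=["c1", "c2", "c3"]),
            group={c: "control" for c in ["c1", "c2", "c3"]},
        )
        base = cnv.control_baseline(ds, cnv.build_bins(mf, probes_per_bin=20))
        assert np.allclose(base.mad, 0.0)

    def test_too_few_controls(self):
        mf = _manifest_single_chrom(60)
        vals = np.ones((60, 2)) * 100
        ds = dm.IntensityDataset(
            meth=pd.DataFrame(vals, index=mf.index, columns=["c1", "c2"]),
            unmeth=pd.DataFrame(vals, index=mf.index, columns=["c1", "c2"]),
            detect_p=pd.DataFrame(0.0, index=mf.index, columns=["c1", "c2"]),
            group={"c1": "control", "c2": "control"},
        )
        with pytest.raises(MethArrayError, match=">= 3"):
            cnv.control_baseline(ds, cnv.build_bins(mf, probes_per_bin=20))

    def test_invariant_to_control_order(self, small_cohort, small_manifest):
        raw, _ = small_cohort
        controls = raw.subset(samples=raw.samples_in_group("control"))
        reordered = controls.subset(samples=list(reversed(controls.samples)))
        bins = cnv.build_bins(small_manifest, probes_per_bin=50)
        b1 = cnv.control_baseline(controls, bins)
        b2 = cnv.control_baseline(reordered, bins)
        assert np.allclose(b1.median, b2.median)
        assert np.allclose(b1.mad, b2.mad)

    def test_held_out_copy2_sample_centers_on_zero(self):
        mf, raw, _ = _cohort_with(groups={"SE": 1, "control": 6}, seed=13)
        controls = raw.subset(samples=raw.samples_in_group("control"))
        held_out = raw.subset(samples=raw.samples_in_group("SE"))
        bins = cnv.build_bins(mf, probes_per_bin=50)
        base = cnv.control_baseline(controls, bins)
        prof = cnv.sample_profile(
            cnv.probe_totals(held_out).iloc[:, 0], base, sex="female", sample="held"
        )
        assert abs(float(np.mean(prof.log2_ratio))) < 0.05


class TestSampleProfile:
    def test_significance_gates_gain_loss(self):
        # construct a profile call directly from a synthetic baseline
        mf = _manifest_single_chrom(100)
        bins = cnv.build_bins(mf, probes_per_bin=50)
        base = cnv.Baseline(bins=tuple(bins), median=np.zeros(2), mad=np.zeros(2), n_controls=3)
        totals = pd.Series(2 ** np.r_[np.full(50, 10.5), np.full(50, 10.0)], index=mf.index)
        prof = cnv.sample_profile(totals, base, sex="female", mad_floor=0.5)
        # +0.25/-0.25 ratios after library scaling: dup-range but not significant
        assert set(prof.state) <= {"dup", "hemi_del", "neutral"}
        assert (prof.gain_loss == 0).all()

    def test_sex_unspecified_suppresses_chrX(self):
        config = syn.SimulationConfig(
            seed=21, n_probes=6000, n_samples_per_group={"SE": 1, "control": 4},
            planted_cnvs=(syn.PlantedCNV("SE", "X", 1, 1_500_000, 4),),
        )
        mf = syn.generate_manifest(config)
        raw, _ = syn.generate_cohort(config, mf)
        controls = raw.subset(samples=raw.samples_in_group("control"))
        bins = cnv.build_bins(mf, probes_per_bin=50)
        base = cnv.control_baseline(controls, bins)
        totals = cnv.probe_totals(raw.subset(samples=raw.samples_in_group("SE")))
        with pytest.warns(UserWarning, match="chrX"):
            prof = cnv.sample_profile(totals.iloc[:, 0], base, sex=None)
        on_x = np.array([b.chrom == "X" for b in prof.bins])
        assert (prof.gain_loss[on_x] == 0).all()

    def test_male_normal_x_not_called(self):
        # male sample (one X copy) against the female baseline: the +1 shift
        # must neutralize chrX across several seeds
        for seed in range(31, 36):
            config = syn.SimulationConfig(
                seed=seed, n_probes=6000, n_samples_per_group={"d0_PTC": 1, "control": 4},
                planted_cnvs=(),
            )
            mf = syn.generate_manifest(config)
            raw, _ = syn.generate_cohort(config, mf)
            controls = raw.subset(samples=raw.samples_in_group("control"))
            # halve chrX totals of the male sample: one X copy
            male = raw.subset(samples=raw.samples_in_group("d0_PTC"))
            on_x = (mf["chrom"] == "X").to_numpy()
            male.meth.iloc[on_x, 0] /= 2
            male.unmeth.iloc[on_x, 0] /= 2
            base = cnv.control_baseline(controls, cnv.build_bins(mf, probes_per_bin=50))
            prof = cnv.sample_profile(cnv.probe_totals(male).iloc[:, 0], base, sex="male")
            x_bins = np.array([b.chrom == "X" for b in prof.bins])
            assert (prof.gain_loss[x_bins] == 0).all()

    def test_planted_arm_gain_called_dup(self):
        planted = syn.PlantedCNV("SE", "2", 1, 1_200_000, 3)
        mf, raw, _ = _cohort_with([planted], seed=17)
        controls = raw.subset(samples=raw.samples_in_group("control"))
        tumors = raw.subset(samples=raw.samples_in_group("SE"))
        profiles = cnv.call_cnvs(tumors, controls, mf, sex="female")
        for p in profiles:
            arm = [i for i, b in enumerate(p.bins) if b.chrom == "2" and b.end <= 1_200_000]
            frac = np.mean(p.gain_loss[np.array(arm)] == 1)
            assert frac >= 0.95


class TestCohortSummary:
    def _profile(self, gain_loss, ratios=None):
        mf = _manifest_single_chrom(100)
        bins = tuple(cnv.build_bins(mf, probes_per_bin=50))
        gl = np.asarray(gain_loss)
        return cnv.CNVProfile(
            sample="s", bins=bins, log2_ratio=np.asarray(ratios if ratios is not None else gl, float),
            significant=gl != 0, state=np.array(["neutral"] * len(bins), dtype=object),
            gain_loss=gl,
        )

    def test_single_profile_identity(self):
        p = self._profile([1, -1], ratios=[0.6, -1.0])
        agg = cnv.cohort_summary([p])
        assert np.allclose(agg["mean_log2_ratio"], [0.6, -1.0])
        assert list(agg["majority_gain_loss"]) == [1, -1]

    def test_opposite_calls_cancel(self):
        agg = cnv.cohort_summary([self._profile([1, 0]), self._profile([-1, 0])])
        assert list(agg["majority_gain_loss"]) == [0, 0]

    def test_mixed_bins_rejected(self):
        p1 = self._profile([0, 0])
        mf = _manifest_single_chrom(60, chrom="2")
        bins2 = tuple(cnv.build_bins(mf, probes_per_bin=30))
        p2 = cnv.CNVProfile("t", bins2, np.zeros(2), np.zeros(2, bool),
                            np.array(["neutral", "neutral"], dtype=object), np.zeros(2, int))
        with pytest.raises(IntegrityError, match="mixed"):
            cnv.cohort_summary([p1, p2])

    def test_group_aggregate_shows_shared_gain(self, small_cohort, small_manifest, small_config):
        raw, _ = small_cohort
        controls = raw.subset(samples=raw.samples_in_group("control"))
        tumors = raw.subset(samples=raw.samples_in_group("SE"))
        profiles = cnv.call_cnvs(tumors, controls, small_manifest, sex="female")
        agg = cnv.cohort_summary(profiles)
        planted = small_config.planted_cnvs[0]
        in_seg = (agg["chrom"] == planted.chrom) & (agg["end"] <= planted.end)
        assert agg.loc[in_seg, "mean_log2_ratio"].mean() >= 0.5


def test_seg_export_roundtrip(tmp_path, small_cohort, small_manifest):
    raw, _ = small_cohort
    controls = raw.subset(samples=raw.samples_in_group("control"))
    tumors = raw.subset(samples=raw.samples_in_group("SE"))
    profiles = cnv.call_cnvs(tumors, controls, small_manifest, sex="female")
    seg = cnv.profiles_to_seg(profiles)
    path = tmp_path / "out.seg"
    dm.write_seg(seg, path)
    back = dm.read_seg(path)
    assert len(back) == len(seg)
    assert np.allclose(back["log2_ratio"], seg["log2_ratio"])
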