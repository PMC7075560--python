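"""Filtering, normalization, type-bias correction and beta/M transforms."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from metharray import data_model as dm
from metharray import preprocess as pp
from metharray.errors import MethArrayError


def _dataset(meth, unmeth, detect_p=None, samples=None, probes=None):
    meth = np.atleast_2d(np.asarray(meth, dtype=float))
    unmeth = np.atleast_2d(np.asarray(unmeth, dtype=float))
    probes = probes or [f"cg{i}" for i in range(meth.shape[0])]
    samples = samples or [f"s{j}" for j in range(meth.shape[1])]
    dp = np.zeros_like(meth) if detect_p is None else np.asarray(detect_p, dtype=float)
    return dm.IntensityDataset(
        meth=pd.DataFrame(meth, index=probes, columns=samples),
        unmeth=pd.DataFrame(unmeth, index=probes, columns=samples),
        detect_p=pd.DataFrame(dp, index=probes, columns=samples),
        group={s: "other" for s in samples},
    )


def _manifest(records):
    return dm.manifest_to_frame(records)


def _probe(pid, pos, **kw):
    defaults = dict(chrom="1", design_type="II")
    defaults.update(kw)
    return dm.ProbeAnnotation(probe_id=pid, pos=pos, **defaults)


class TestDetectionPvalues:
    def _setup(self, n_neg=99, probe_total=1000.0):
        # negative controls with totals 1..n_neg, one CpG probe per sample
        records = [_probe("cgA", 10)]
        records += [
            _probe(f"neg{i}", 100 + i, is_cpg_target=False, is_negative_control=True)
            for i in range(n_neg)
        ]
        mf = _manifest(records)
        meth = np.array([[probe_total / 2]] + [[(i + 1) / 2] for i in range(n_neg)])
        unmeth = meth.copy()
        return mf, _dataset(meth, unmeth, probes=list(mf.index))

    def test_above_all_controls_is_zero(self):
        mf, ds = self._setup(probe_total=10_000)
        assert pp.detection_pvalues(ds, mf).loc["cgA", "s0"] == 0.0

    def test_below_all_controls_is_one(self):
        mf, ds = self._setup(probe_total=0.1)
        assert pp.detection_pvalues(ds, mf).loc["cgA", "s0"] == 1.0

    def test_at_median_is_half(self):
        mf, ds = self._setup(n_neg=99, probe_total=50.0)  # the 50th of 99
        p = pp.detection_pvalues(ds, mf).loc["cgA", "s0"]
        assert abs(p - 0.5) <= 1 / 99 + 1e-12

    def test_too_few_negative_controls(self):
        mf, ds = self._setup(n_neg=5)
        with pytest.raises(MethArrayError, match="negative-control"):
            pp.detection_pvalues(ds, mf)


class TestFilterProbes:
    def test_detection_fraction_boundary(self):
        # detectable in 6 of 7 samples: 0.857 < 0.95 -> removed
        records = [_probe("cgA", 10), _probe("cgB", 500)]
        mf = _manifest(records)
        dp = np.array([[0.0] * 6 + [0.5], [0.0] * 7])
        ds = _dataset(np.ones((2, 7)), np.ones((2, 7)), dp, probes=list(mf.index))
        kept, report = pp.filter_probes(ds, mf)
        assert kept.probes == ["cgB"]
        assert report.removed["detection"] == 1

    def test_snp_probe_removed(self):
        records = [_probe("cgA", 10, snp_within_10bp_maf05=True), _probe("cgB", 500)]
        mf = _manifest(records)
        ds = _dataset(np.ones((2, 2)), np.ones((2, 2)), probes=list(mf.index))
        kept, report = pp.filter_probes(ds, mf)
        assert kept.probes == ["cgB"]
        assert report.removed["snp_within_10bp"] == 1

    def test_sequential_accounting_on_disjoint_planted_sets(self):
        # 100 failed, 50 SNP, 20 multi-target, all disjoint
        records, dp_rows = [], []
        pos = 10
        for i in range(300):
            pid = f"cg{i:04d}"
            snp = i < 50
            multi = 50 <= i < 70
            failed = 70 <= i < 170
            records.append(_probe(pid, pos, snp_within_10bp_maf05=snp, multi_target=multi))
            dp_rows.append([0.5] * 3 if failed else [0.0] * 3)
            pos += 1000
        mf = _manifest(records)
        ds = _dataset(np.ones((300, 3)), np.ones((300, 3)), np.array(dp_rows),
                      probes=list(mf.index))
        kept, report = pp.filter_probes(ds, mf)
        assert report.n_input == 300
        assert report.removed == {"non_cpg": 0, "detection": 100,
                                  "multi_target": 20, "snp_within_10bp": 50}
        assert report.n_retained == 130 == len(kept.probes)

    def test_filtering_idempotent(self, small_cohort, small_manifest):
        raw, _ = small_cohort
        once, _ = pp.filter_probes(raw, small_manifest)
        twice, report = pp.filter_probes(once, small_manifest)
        assert twice.probes == once.probes
        assert sum(report.removed.values()) == 0

    def test_all_removed_is_error(self):
        records = [_probe("cgA", 10, snp_within_10bp_maf05=True)]
        mf = _manifest(records)
        ds = _dataset([[1.0]], [[1.0]], probes=list(mf.index))
        with pytest.raises(MethArrayError, match="every probe"):
            pp.filter_probes(ds, mf)


class TestQuantileNormalize:
    def test_identical_distributions_fixed_point(self):
        rng = np.random.default_rng(0)
        col = rng.gamma(2.0, 100.0, size=40)
        ds = _dataset(np.column_stack([col, col]), np.column_stack([col, col]))
        out = pp.quantile_normalize(ds)
        assert np.allclose(out.meth.to_numpy(), ds.meth.to_numpy())

    def test_scaled_sample_maps_to_common_quantiles(self):
        rng = np.random.default_rng(1)
        a = rng.gamma(2.0, 100.0, size=60)
        ds = _dataset(np.column_stack([a, 2 * a]), np.column_stack([a, 2 * a]))
        out = pp.quantile_normalize(ds)
        m = out.meth.to_numpy()
        assert np.allclose(np.sort(m[:, 0]), np.sort(m[:, 1]))

    def test_sorted_columns_identical_random_matrix(self):
        rng = np.random.default_rng(2)
        x = rng.lognormal(8, 1, size=(50, 4))
        ds = _dataset(x, x + 1)
        out = pp.quantile_normalize(ds)
        for mat in (out.meth.to_numpy(), out.unmeth.to_numpy()):
            ref = np.sort(mat[:, 0])
            for j in range(1, 4):
                assert np.allclose(np.sort(mat[:, j]), ref)

    def test_single_sample_identity_with_warning(self):
        ds = _dataset([[1.0], [2.0]], [[3.0], [4.0]])
        with pytest.warns(UserWarning, match="single sample"):
            out = pp.quantile_normalize(ds)
        assert np.array_equal(out.meth.to_numpy(), ds.meth.to_numpy())


class TestBetaM:
    @pytest.mark.parametrize(
        "meth,unmeth,beta,m",
        [
            (100.0, 100.0, 0.5, 0.0),
            (800.0, 200.0, 0.8, 2.0),
            (1000.0, 0.0, 1.0, np.log2(999)),  # beta clamped to 0.999 for M
        ],
    )
    def test_identities(self, meth, unmeth, beta, m):
        b = pp.beta_from_channels([meth], [unmeth])[0]
        assert np.isclose(b, beta)
        assert np.isclose(pp.m_from_beta(b), m)

    def test_both_channels_zero_is_missing(self):
        ds = _dataset([[0.0, 5.0]], [[0.0, 5.0]])
        meth = pp.compute_beta_m(ds)
        assert np.isnan(meth.beta.iloc[0, 0])
        assert meth.beta.iloc[0, 1] == 0.5

    def test_m_finite_everywhere(self, small_meth):
        meth, _ = small_meth
        m = meth.m.to_numpy()
        assert np.isfinite(m[~np.isnan(m)]).all()
        assert np.nanmax(np.abs(m)) <= np.log2(999) + 1e-9

    @settings(max_examples=50, deadline=None)
    @given(st.floats(0.001, 0.999), st.floats(0.001, 0.999))
    def test_beta_m_monotone_bijection(self, b1, b2):
        m1, m2 = pp.m_from_beta(b1), pp.m_from_beta(b2)
        assert (b1 < b2) == (m1 < m2) or b1 == b2


class TestTypeBias:
    def _meth_ds(self, beta_i, beta_ii):
        n_i, n_ii = len(beta_i), len(beta_ii)
        records = [_probe(f"cgI{i}", 10 + i * 1000, design_type="I") for i in range(n_i)]
        records += [_probe(f"cgII{i}", 10**6 + i * 1000, design_type="II") for i in range(n_ii)]
        mf = _manifest(records)
        beta = np.concatenate([beta_i, beta_ii])[:, None]
        meth = dm.MethylationDataset(
            beta=pd.DataFrame(beta, index=mf.index, columns=["s0"]),
            m=pd.DataFrame(pp.m_from_beta(beta), index=mf.index, columns=["s0"]),
            group={"s0": "other"},
        )
        return mf, meth

    def test_equal_distributions_identity(self):
        vals = np.linspace(0.05, 0.95, 60)
        mf, meth = self._meth_ds(vals, vals)
        out = pp.correct_type_bias(meth, mf)
        ii = [p for p in out.probes if p.startswith("cgII")]
        assert np.allclose(out.beta.loc[ii, "s0"].to_numpy(), vals)

    def test_compressed_type_ii_expands(self):
        rng = np.random.default_rng(3)
        b_i = rng.uniform(0.0, 1.0, 200)
        b_ii = rng.uniform(0.1, 0.8, 200)
        mf, meth = self._meth_ds(b_i, b_ii)
        out = pp.correct_type_bias(meth, mf)
        ii = [p for p in out.probes if p.startswith("cgII")]
        corrected = out.beta.loc[ii, "s0"].to_numpy()
        assert corrected.min() < b_ii.min()
        assert corrected.max() > b_ii.max()
        assert (corrected >= 0).all() and (corrected <= 1).all()

    def test_monotone_within_type_ii(self):
        rng = np.random.default_rng(4)
        b_i = rng.uniform(0, 1, 120)
        b_ii = rng.uniform(0, 1, 120)
        mf, meth = self._meth_ds(b_i, b_ii)
        out = pp.correct_type_bias(meth, mf)
        ii = [p for p in out.probes if p.startswith("cgII")]
        corrected = out.beta.loc[ii, "s0"].to_numpy()
        order = np.argsort(b_ii)
        assert (np.diff(corrected[order]) >= -1e-12).all()

    def test_small_sample_skipped_with_warning(self):
        mf, meth = self._meth_ds(np.linspace(0.1, 0.9, 10), np.linspace(0.1, 0.9, 10))
        with pytest.warns(UserWarning, match="skipped"):
            out = pp.correct_type_bias(meth, mf)
        assert np.allclose(out.beta.to_numpy(), meth.beta.to_numpy())


def test_pipeline_metadata_records_stage_order(small_meth):
    meth, report = small_meth
    assert meth.metadata["pipeline"] == [
        "filter", "quantile_normalize", "beta", "type_bias:quantile-map", "m"
    ]
    assert report.n_retained == len(meth.probes)
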