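"""Synthetic-dataset generator: determinism, conservation, rendering contracts."""

import os
from dataclasses import replace

import numpy as np
import pytest
from scipy import stats

from botanicad import io, masscalc, mwco, synth
from botanicad.errors import ParameterError
from botanicad.synth import ConstituentSpec, GenerationConfig


def single_constituent(rt=5.0, mass_ug=2.0, sigma=0.1, uv=1.0, klass="polyphenol",
                       formula="C15H14O6", pos=False, neg=True):
    return ConstituentSpec(
        name="x", formula=formula, klass=klass, rt_min=rt,
        conc_ug_per_ml=mass_ug / 10.0 * 1000.0, peak_sigma_min=sigma,
        uv_response_weight=uv, ionizes_pos=pos, ionizes_neg=neg,
    )


class TestGenerateDataset:
    def test_construction_contract(self, default_dataset):
        ds = default_dataset
        assert len(ds.library) > 0
        assert ds.cad_trace.channel == "CAD" and ds.uv_trace.channel == "UV"
        assert {f.polarity for f in ds.ms_features} == {"pos", "neg"}
        assert set(ds.mwco_traces) == set(GenerationConfig().mwco_cutoffs_da)
        assert len(ds.gc_fid_peaks) == 20
        assert np.array_equal(ds.cad_trace.time_min, ds.uv_trace.time_min)

    def test_same_seed_reproduces_bit_for_bit(self):
        a = synth.generate_dataset(seed=11)
        b = synth.generate_dataset(seed=11)
        assert np.array_equal(a.cad_trace.signal, b.cad_trace.signal)
        assert np.array_equal(a.uv_trace.signal, b.uv_trace.signal)
        assert a.truth.equals(b.truth) and a.ms_truth.equals(b.ms_truth)
        assert [(f.mz, f.rt_min) for f in a.ms_features] == [
            (f.mz, f.rt_min) for f in b.ms_features
        ]

    def test_different_seeds_differ(self):
        a = synth.generate_dataset(seed=11)
        b = synth.generate_dataset(seed=12)
        assert not np.array_equal(a.cad_trace.signal, b.cad_trace.signal)

    def test_csv_export_byte_identical(self, tmp_path):
        dirs = []
        for sub in ("a", "b"):
            out = tmp_path / sub
            io.write_dataset(synth.generate_dataset(seed=3), out)
            dirs.append(out)
        files = sorted(os.listdir(dirs[0]))
        assert files == sorted(os.listdir(dirs[1]))
        for f in files:
            assert (dirs[0] / f).read_bytes() == (dirs[1] / f).read_bytes()

    def test_exported_files_carry_seed_comment(self, tmp_path):
        io.write_dataset(synth.generate_dataset(seed=42), tmp_path)
        meta = io.read_meta(tmp_path / "cad_trace.csv")
        assert meta["seed"] == "42"

    def test_mass_conservation(self, default_dataset):
        ds = default_dataset
        assert ds.truth.mass_ug.sum() == pytest.approx(ds.config.load_ug, rel=1e-9)

    def test_zero_tannin_fraction_removes_hump(self):
        cfg = replace(GenerationConfig(), tannin_fraction=0.0,
                      polyphenol_fraction=0.0, noise_sd_frac=0.0,
                      baseline_level=0.0)
        ds = synth.generate_dataset(cfg, seed=1)
        t, y = ds.cad_trace.time_min, ds.cad_trace.signal
        window = (t >= 15.0) & (t <= 45.0)
        assert np.trapezoid(y[window], t[window]) < 1e-6

    def test_truncated_class_counts(self):
        cfg = replace(GenerationConfig(), n_polar=4, n_polyphenol=6, n_nonpolar=1)
        ds = synth.generate_dataset(cfg, seed=1)
        counts = ds.truth[ds.truth.klass != "tannin"].klass.value_counts()
        assert counts["polar"] == 4 and counts["polyphenol"] == 6
        assert counts["nonpolar"] == 1

    def test_invalid_config_raises(self):
        with pytest.raises(ParameterError):
            GenerationConfig(noise_sd_frac=-0.1)
        with pytest.raises(ParameterError):
            GenerationConfig(time_start_min=10.0, time_end_min=5.0)
        with pytest.raises(ParameterError):
            GenerationConfig(polar_fraction=-0.2)


class TestRenderTrace:
    def test_single_constituent_area_equals_mass_times_rf(self):
        c = single_constituent(mass_ug=2.0)
        t = np.arange(0.0, 10.0, 0.005)
        tr = synth.render_trace([c], "CAD", t, rf_area_per_ug=0.85,
                                injection_vol_ul=10.0)
        area = np.trapezoid(tr.signal, tr.time_min)
        assert area == pytest.approx(2.0 * 0.85, rel=1e-3)

    def test_zero_uv_weight_absent_from_uv_channel(self):
        sugar = single_constituent(formula="C6H12O6", klass="polar", uv=0.0)
        t = np.arange(0.0, 10.0, 0.005)
        tr = synth.render_trace([sugar], "UV", t, 0.85, 10.0)
        assert np.all(tr.signal == 0.0)

    def test_coeluting_areas_are_additive(self):
        a = single_constituent(mass_ug=1.0)
        b = single_constituent(mass_ug=2.5)
        t = np.arange(0.0, 10.0, 0.005)
        together = synth.render_trace([a, b], "CAD", t, 1.0, 10.0)
        alone = synth.render_trace([a], "CAD", t, 1.0, 10.0)
        other = synth.render_trace([b], "CAD", t, 1.0, 10.0)
        assert np.allclose(together.signal, alone.signal + other.signal)

    def test_volatiles_do_not_register_on_lc_channels(self):
        v = ConstituentSpec(name="v", formula="C6H6O2", klass="volatile",
                            rt_min=5.0, conc_ug_per_ml=100.0, peak_sigma_min=0.05)
        t = np.arange(0.0, 10.0, 0.01)
        assert np.all(synth.render_trace([v], "CAD", t, 1.0, 10.0).signal == 0)

    def test_noise_requires_rng(self):
        c = single_constituent()
        with pytest.raises(ParameterError):
            synth.render_trace([c], "CAD", np.arange(0, 10, 0.01), 1.0, 10.0,
                               noise_sd=0.1)


class TestRenderMsFeatures:
    def test_polarity_flags_respected(self):
        neg_only = single_constituent(pos=False, neg=True)
        feats, truth = synth.render_ms_features([neg_only])
        assert {f.polarity for f in feats} == {"neg"}
        pos_only = single_constituent(pos=True, neg=False)
        feats, _ = synth.render_ms_features([pos_only])
        assert {f.polarity for f in feats} == {"pos"}

    def test_feature_mz_is_adduct_mass(self):
        c = single_constituent(formula="C15H14O6")
        feats, _ = synth.render_ms_features([c])
        assert feats[0].mz == pytest.approx(
            masscalc.ion_mz("C15H14O6", "[M-H]-"), abs=1e-9
        )

    def test_decoy_count_and_truth_labels(self):
        lib = [single_constituent(rt=3.0), single_constituent(rt=6.0)]
        feats, truth = synth.render_ms_features(
            lib, misalignment_decoys=1, rng=np.random.default_rng(0)
        )
        assert (~truth.contributor).sum() == 1
        assert len(feats) == len(truth) == 3  # two real features + one decoy

    def test_decoy_offset_is_three_times_alignment_tolerance(self):
        lib = [single_constituent(rt=3.0)]
        feats, truth = synth.render_ms_features(
            lib, misalignment_decoys=1, decoy_offset_min=0.3,
            rng=np.random.default_rng(1),
        )
        decoy = truth[~truth.contributor].iloc[0]
        assert decoy.rt_min == pytest.approx(3.3)

    def test_zero_jitter_gives_exact_apex_rt(self):
        c = single_constituent(rt=4.2)
        feats, _ = synth.render_ms_features([c], rt_jitter_sd=0.0)
        assert feats[0].rt_min == 4.2

    def test_adulterant_spike_adds_a_type_marker(self):
        feats, truth = synth.render_ms_features(
            [single_constituent()], adulterant_spike=True,
            rng=np.random.default_rng(0),
        )
        assert any(abs(f.mz - 575.1189) < 1e-6 for f in feats)


@pytest.fixture(scope="module")
def tannin_only():
    return replace(
        GenerationConfig(), polar_fraction=0.0, polyphenol_fraction=0.0,
        nonpolar_fraction=0.0, volatile_fraction=0.0, tannin_fraction=1.0,
        noise_sd_frac=0.0, baseline_level=0.0,
    )


class TestAttenuateByCutoff:
    def test_cutoff_above_everything_is_identity(self, tannin_only):
        ds = synth.generate_dataset(tannin_only, seed=1)
        tr = synth.attenuate_by_cutoff(ds.library, 1e12, tannin_only)
        assert np.allclose(tr.signal, ds.cad_trace.signal)

    def test_cutoff_below_tannins_removes_hump(self, tannin_only):
        ds = synth.generate_dataset(tannin_only, seed=1)
        tr = synth.attenuate_by_cutoff(ds.library, 100.0, tannin_only)
        assert np.all(tr.signal == 0.0)

    def test_losses_match_closed_form_lognormal_tail(self, tannin_only):
        """Measured MWCO losses track the latent distribution's survival
        function within the quadrature/stratification error."""
        ds = synth.generate_dataset(tannin_only, seed=1)
        series = mwco.loss_series(ds.cad_trace, ds.mwco_traces, (10.0, 50.0))
        dist = stats.lognorm(s=tannin_only.tannin_mw_sigma_ln,
                             scale=tannin_only.tannin_mw_median_da)
        for cutoff, loss in zip(series.cutoffs_da, series.loss_percent):
            assert loss == pytest.approx(100.0 * dist.sf(cutoff), abs=2.0)

    def test_loss_monotone_non_increasing_in_cutoff(self, default_dataset):
        series = mwco.loss_series(
            default_dataset.cad_trace, default_dataset.mwco_traces, (10.0, 50.0)
        )
        losses = list(series.loss_percent)
        assert all(a >= b - 0.5 for a, b in zip(losses, losses[1:]))

    def test_invalid_cutoff_raises(self, tannin_only):
        ds = synth.generate_dataset(tannin_only, seed=1)
        with pytest.raises(ParameterError):
            synth.attenuate_by_cutoff(ds.library, 0.0, tannin_only)
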