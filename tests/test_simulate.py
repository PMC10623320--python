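import re

import numpy as np
import pytest

from rootedit.core import IndelEvent, IndelSpectrum
from rootedit.simulate import (
    ConfigError,
    GenerationError,
    GroupSpec,
    InvalidSpectrumError,
    RepairSpectrumConfig,
    TraceMatrix,
    inject_seed_snp,
    load_size_weights,
    make_amplicon,
    pick_guide,
    sample_root_spectrum,
    simulate_study,
    synthesize_traces,
    template_base,
)


class TestSizeWeightFixture:
    def test_normalized_with_study_anchors(self):
        w = load_size_weights()
        assert abs(sum(w.values()) - 1.0) < 1e-9
        assert w[-1] == pytest.approx(0.226)
        assert w[1] == pytest.approx(0.191)
        assert min(w) == -30 and max(w) == 4
        dels = sum(v for s, v in w.items() if s < 0)
        ins = sum(v for s, v in w.items() if s > 0)
        assert dels / ins == pytest.approx(3.0, abs=1e-6)


class TestMakeAmplicon:
    def test_seeded_determinism(self):
        a = make_amplicon(300, 0.5, 7)
        b = make_amplicon(300, 0.5, 7)
        assert a.sequence == b.sequence
        assert (a.cds_start, a.cds_end) == (b.cds_start, b.cds_end)

    def test_gc_one_limit(self):
        amp = make_amplicon(300, 1.0, 7)
        forced = set(range(amp.cds_start, amp.cds_start + 3)) | set(
            range(amp.cds_end - 3, amp.cds_end)
        )
        outside = [b for i, b in enumerate(amp.sequence) if i not in forced]
        assert set(outside) <= {"G", "C"}

    def test_cds_in_frame_with_start_and_stop(self):
        amp = make_amplicon(300, 0.5, 7)
        assert amp.cds.startswith("ATG")
        assert amp.cds[-3:] in ("TAA", "TGA", "TAG")
        assert (amp.cds_end - amp.cds_start) % 3 == 0

    def test_pam_exists_in_cds_window(self):
        """Independent regex check: a GG dinucleotide (PAM core) occurs in
        the 5-65% CDS region or its reverse complement."""
        amp = make_amplicon(300, 0.5, 7)
        lo = amp.cds_start + int(0.05 * (amp.cds_end - amp.cds_start))
        hi = amp.cds_start + int(0.65 * (amp.cds_end - amp.cds_start))
        window = amp.sequence[max(0, lo - 25) : hi + 25]
        assert re.search("GG", window) or re.search("CC", window)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            make_amplicon(100, 0.5, 7)

    def test_no_pam_possible_fails(self):
        with pytest.raises(GenerationError):
            make_amplicon(150, 0.0, 7, max_tries=5)


class TestRepairSpectrumConfig:
    def test_weights_must_normalize(self):
        with pytest.raises(ConfigError):
            RepairSpectrumConfig(size_weights={-1: 0.5, 1: 0.4})

    def test_ranges_validated(self):
        with pytest.raises(ConfigError):
            RepairSpectrumConfig(dominant_count_range=(0, 4))
        with pytest.raises(ConfigError):
            RepairSpectrumConfig(dominant_count_range=(2, 5))
        with pytest.raises(ConfigError):
            RepairSpectrumConfig(wt_fraction_range=(-0.1, 0.5))


class TestSampleRootSpectrum:
    def test_degenerate_config_single_event_at_100(self, site):
        cfg = RepairSpectrumConfig(
            dominant_count_range=(1, 1), wt_fraction_range=(0.0, 0.0)
        )
        spec = sample_root_spectrum(cfg, site, 5)
        assert len(spec) == 1
        assert spec.events[0].percentage == pytest.approx(100.0)
        assert spec.wt_percentage == pytest.approx(0.0)

    def test_dominant_counts_within_range(self, site, default_config):
        for seed in range(400):
            spec = sample_root_spectrum(default_config, site, seed)
            dominant = [e for e in spec if e.percentage > 20.0]
            assert 1 <= len(dominant) <= 4
            assert len(dominant) == len(spec)  # all events dominant here
            total = spec.wt_percentage + sum(e.percentage for e in spec)
            assert total == pytest.approx(100.0, abs=1e-6)

    def test_template_bias_binomial(self, site, default_config):
        tb = template_base(site)
        hits = total = 0
        for seed in range(1500):
            for e in sample_root_spectrum(default_config, site, seed):
                if e.size == 1:
                    total += 1
                    hits += e.inserted_bases == tb
        frac = hits / total
        se = np.sqrt(0.75 * 0.25 / total)
        assert abs(frac - 0.75) < 3 * se

    def test_pooled_marginals_match_fixture(self, site, default_config):
        """>=10,000 events: 1-bp deletion and insertion shares and the
        deletion:insertion ratio reproduce the pooled study spectrum."""
        events = []
        seed = 0
        while len(events) < 10_000:
            events.extend(
                e.size for e in sample_root_spectrum(default_config, site, seed)
            )
            seed += 1
        ev = np.array(events)
        assert abs(100 * (ev == -1).mean() - 22.6) < 1.5
        assert abs(100 * (ev == 1).mean() - 19.1) < 1.5
        ratio = (ev < 0).sum() / (ev > 0).sum()
        assert abs(ratio - 3.0) < 0.3
        assert ev.min() >= -30 and ev.max() <= 4

    def test_suppressed_editing_yields_near_wt(self, site, default_config):
        cfg = default_config.replace(wt_fraction_range=(0.95, 1.0))
        indel = [
            100.0 - sample_root_spectrum(cfg, site, s).wt_percentage
            for s in range(50)
        ]
        assert np.mean(indel) < 5.0


class TestSynthesizeTraces:
    def test_pure_wt_noiseless_identity(self, amplicon, site):
        spec = IndelSpectrum(events=[], wt_percentage=100.0)
        control, edited = synthesize_traces(amplicon, site, spec, noise_sd=0.0)
        np.testing.assert_allclose(control.values, edited.values)

    def test_pure_deletion_is_shift(self, amplicon, site):
        spec = IndelSpectrum(
            events=[IndelEvent(size=-2, percentage=100.0)], wt_percentage=0.0
        )
        control, edited = synthesize_traces(amplicon, site, spec, noise_sd=0.0)
        cut = site.cut_pos
        n = len(amplicon)
        np.testing.assert_allclose(
            edited.values[cut : n - 2], control.values[cut + 2 :]
        )
        np.testing.assert_allclose(edited.values[:cut], control.values[:cut])

    def test_mixture_is_weighted_sum(self, amplicon, site):
        spec = IndelSpectrum(
            events=[IndelEvent(size=-1, percentage=40.0)], wt_percentage=60.0
        )
        control, edited = synthesize_traces(amplicon, site, spec, noise_sd=0.0)
        cut = site.cut_pos
        n = len(amplicon)
        expected = (
            0.6 * control.values[cut : n - 1] + 0.4 * control.values[cut + 1 :]
        )
        np.testing.assert_allclose(edited.values[cut : n - 1], expected, atol=1e-12)

    @pytest.mark.parametrize("noise_sd", [0.0, 0.02, 0.1])
    def test_rows_always_sum_to_one(self, amplicon, site, default_config, noise_sd):
        spec = sample_root_spectrum(default_config, site, 11)
        control, edited = synthesize_traces(
            amplicon, site, spec, noise_sd=noise_sd, seed=3
        )
        for tm in (control, edited):
            np.testing.assert_allclose(tm.values.sum(axis=1), 1.0, atol=1e-6)
            assert (tm.values >= 0).all()

    def test_oversized_event_rejected(self, amplicon, site):
        spec = IndelSpectrum(
            events=[IndelEvent(size=-40, percentage=50.0)], wt_percentage=50.0
        )
        with pytest.raises(InvalidSpectrumError):
            synthesize_traces(amplicon, site, spec, max_shift=30)
        # but realizable when the synthesis bound allows it
        synthesize_traces(amplicon, site, spec, max_shift=60)

    def test_trace_matrix_validation(self):
        with pytest.raises(ValueError):
            TraceMatrix(np.array([[0.5, 0.5, 0.5, 0.5]]))
        with pytest.raises(ValueError):
            TraceMatrix(np.array([[1.2, -0.2, 0.0, 0.0]]))


class TestMinusStrandGuides:
    def test_coordinates_template_and_recovery(self):
        """A minus-strand guide keeps protospacer/PAM in its own
        orientation, cut_pos in forward coordinates; the templated
        insertion, trace synthesis and decomposition stay consistent."""
        from rootedit.core import revcomp
        from rootedit.decompose import decompose
        from rootedit.predict import templated_insertion

        amp = make_amplicon(300, 0.45, 1)
        site = pick_guide(amp, prefer_strand="-")
        assert site.strand == "-"
        j = site.cut_pos - 6  # forward start of the CCN PAM
        assert site.protospacer == revcomp(amp.sequence[j + 3 : j + 23])
        assert site.pam == revcomp(amp.sequence[j : j + 3])
        # -4 template base agrees between the forward-strand generator and
        # the protospacer-strand predictor
        rc, cut_rc = revcomp(amp.sequence), len(amp.sequence) - site.cut_pos
        (pred,) = templated_insertion(rc, cut_rc).entries
        assert pred.inserted_base == site.protospacer[16]
        assert pred.inserted_base == revcomp(template_base(site))
        # noiseless round trip still exact
        spec = sample_root_spectrum(RepairSpectrumConfig(), site, 3)
        c, e = synthesize_traces(amp, site, spec, 0.0, 1)
        fit = decompose(c, e, site.cut_pos).spectrum.by_size()
        for s, p in spec.by_size().items():
            assert fit.get(s, 0.0) == pytest.approx(p, abs=2.0)


class TestSeedSnp:
    def test_single_substitution_at_pam_proximal_base(self, amplicon, site):
        snp = inject_seed_snp(amplicon, site, seed=4)
        diffs = [
            i for i, (a, b) in enumerate(zip(amplicon.sequence, snp.sequence))
            if a != b
        ]
        assert len(diffs) == 1
        expected = site.cut_pos + 2 if site.strand == "+" else site.cut_pos - 3
        assert diffs[0] == expected


class TestSimulateStudy:
    def test_record_count(self, default_config):
        groups = [GroupSpec("g1", "A", 15), GroupSpec("g1", "B", 15)]
        records = simulate_study(groups, default_config, seed=1)
        assert len(records) == 30

    def test_byte_identical_for_fixed_seed(self, default_config):
        groups = [GroupSpec("g1", "A", 5), GroupSpec("g2", "B", 5)]
        r1 = simulate_study(groups, default_config, seed=9)
        r2 = simulate_study(groups, default_config, seed=9)
        for a, b in zip(r1, r2):
            assert a.amplicon.sequence == b.amplicon.sequence
            assert a.true_spectrum == b.true_spectrum
            np.testing.assert_array_equal(a.edited.values, b.edited.values)

    def test_configured_means_are_recoverable(self, default_config):
        groups = [
            GroupSpec("g1", "hi", 25, mean_indel=75.0),
            GroupSpec("g1", "lo", 25, mean_indel=40.0),
        ]
        records = simulate_study(groups, default_config, seed=2)
        means = {}
        for construct in ("hi", "lo"):
            vals = [
                sum(e.percentage for e in r.true_spectrum)
                for r in records
                if r.construct == construct
            ]
            means[construct] = np.mean(vals)
        assert abs(means["hi"] - 75.0) < 5.0
        assert abs(means["lo"] - 40.0) < 5.0

    def test_invalid_group_size(self):
        with pytest.raises(ConfigError):
            GroupSpec("g1", "A", 0)
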