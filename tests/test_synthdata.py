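"""Synthetic cohort generator: geometry, effect injection, events, raw voltage."""

import re

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ieegcontrast.geometry import assign_anatomical_label
from ieegcontrast.synthdata import (CohortSpec, EffectSpec, generate_cohort,
                                    generate_geometry, generate_gpts, generate_raw)

SMALL = CohortSpec(n_subjects=3, electrodes_per_subject=(2, 3),
                   contacts_per_electrode=(6, 8), trials_per_condition=(20, 25), seed=7)


def electrode_groups(table, subject):
    groups = {}
    for c in table.subset(subject):
        groups.setdefault(re.match(r"(e\d+)c\d+", c.id).group(1), []).append(c)
    return groups


class TestGeometry:
    def test_deterministic_under_seed(self):
        t1, v1 = generate_geometry(SMALL)
        t2, v2 = generate_geometry(SMALL)
        pd.testing.assert_frame_equal(t1.to_frame(), t2.to_frame())
        assert np.array_equal(v1.voxels, v2.voxels)

    def test_contacts_equidistant_on_a_line(self):
        table, _ = generate_geometry(SMALL)
        for subject in table.subjects():
            for cs in electrode_groups(table, subject).values():
                xyz = np.array([c.xyz for c in cs])
                steps = np.linalg.norm(np.diff(xyz, axis=0), axis=1)
                assert np.allclose(steps, 3.5)
                # collinear: total span equals (n-1) * spacing
                span = np.linalg.norm(xyz[-1] - xyz[0])
                assert span == pytest.approx((len(cs) - 1) * 3.5)

    def test_counts_respect_spec_ranges(self):
        table, _ = generate_geometry(SMALL)
        assert table.subjects() == [f"SYN{i:02d}" for i in (1, 2, 3)]
        for subject in table.subjects():
            groups = electrode_groups(table, subject)
            assert 2 <= len(groups) <= 3
            for cs in groups.values():
                assert 6 <= len(cs) <= 8

    def test_electrodes_stay_within_one_hemisphere(self):
        table, _ = generate_geometry(SMALL)
        for subject in table.subjects():
            for cs in electrode_groups(table, subject).values():
                assert len({c.hemisphere for c in cs}) == 1

    def test_volume_labels_agree_with_contact_labels(self):
        table, volume = generate_geometry(SMALL)
        agree = total = 0
        for c in table:
            name = assign_anatomical_label(volume.voxel_index(c.xyz), volume)
            if name != "unknown":
                total += 1
                agree += name == c.label
        # contact labels use the nearest same-hemisphere centroid; the volume
        # rasterizes the global nearest-centroid rule, so they agree away from
        # boundaries/midline but not everywhere
        assert total > 0 and agree / total > 0.7

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError, match="spacing"):
            CohortSpec(contact_spacing_mm=0.0)
        with pytest.raises(ValueError, match="positive"):
            CohortSpec(noise_sd=-1.0)


class TestEffectSpec:
    def test_window_outside_post_stimulus_rejected(self):
        with pytest.raises(ValueError, match="window"):
            EffectSpec(effect_window_s=(0.5, 1.5))

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError, match="kind"):
            EffectSpec(effect_kind="phase")


class TestGenerateGpts:
    def test_deterministic_and_trial_counts_in_range(self):
        table, _ = generate_geometry(SMALL)
        g1, e1 = generate_gpts(table, SMALL)
        g2, e2 = generate_gpts(table, SMALL)
        pd.testing.assert_frame_equal(e1, e2)
        key = next(iter(g1))
        assert np.array_equal(g1[key].values, g2[key].values)
        counts = e1.groupby(["subject", "condition"]).size()
        assert counts.between(20, 25).all()

    def test_null_cohort_has_no_condition_contrast_in_mean(self):
        table, _ = generate_geometry(SMALL)
        gpts, _ = generate_gpts(table, SMALL)
        diffs = []
        for g in gpts.values():
            a, h = g.split_conditions()
            diffs.append(a.mean() - h.mean())
        assert abs(np.mean(diffs)) < 0.05

    def test_amplitude_effect_confined_to_targets_and_window(self):
        table, _ = generate_geometry(SMALL)
        targets = {(c.label, c.hemisphere) for c in table}
        target = sorted(targets)[0]
        effect = EffectSpec(target_structures={target}, effect_size=2.0,
                            effect_window_s=(0.3, 0.6))
        gpts, _ = generate_gpts(table, SMALL, effect)
        for g in gpts.values():
            a, h = g.split_conditions()
            win = (g.times >= 0.3) & (g.times <= 0.6)
            contrast = a[:, win].mean() - h[:, win].mean()
            pre = (g.times < 0.0)
            pre_contrast = a[:, pre].mean() - h[:, pre].mean()
            if (g.contact.label, g.contact.hemisphere) == target:
                assert contrast > 1.5
            else:
                assert abs(contrast) < 0.5
            assert abs(pre_contrast) < 0.5  # baseline untouched either way

    def test_unknown_target_structure_rejected(self):
        table, _ = generate_geometry(SMALL)
        effect = EffectSpec(target_structures={("not-a-structure", "LH")}, effect_size=1.0)
        with pytest.raises(ValueError, match="not present"):
            generate_gpts(table, SMALL, effect)

    def test_reaction_times_slower_for_angry(self):
        table, _, _, events, _ = generate_cohort(
            CohortSpec(n_subjects=6, electrodes_per_subject=(2, 2),
                       contacts_per_electrode=(6, 6), seed=11))
        rt_a = events.loc[events["condition"] == "angry", "rt_s"]
        rt_h = events.loc[events["condition"] == "happy", "rt_s"]
        p = stats.mannwhitneyu(rt_a, rt_h, alternative="two-sided").pvalue
        assert rt_a.mean() > rt_h.mean()
        assert p < 0.05


class TestGenerateCohort:
    def test_truth_records_the_planted_effect(self):
        spec = CohortSpec(n_subjects=2, electrodes_per_subject=(2, 2),
                          contacts_per_electrode=(6, 6), seed=3)
        table, _ = generate_geometry(spec)
        target = sorted({(c.label, c.hemisphere) for c in table})[0]
        effect = EffectSpec(target_structures={target}, effect_size=1.5)
        _, _, gpts, _, truth = generate_cohort(spec, effect)
        assert truth["target_structures"] == [list(target)]
        assert truth["effect_size"] == 1.5
        assert set(gpts) == {c.key for c in table}


class TestGenerateRaw:
    def test_shapes_onsets_and_line_noise(self):
        spec = CohortSpec(n_subjects=1, electrodes_per_subject=(1, 1),
                          contacts_per_electrode=(6, 6), seed=5)
        table, _ = generate_geometry(spec)
        x, onsets, events = generate_raw(table, spec, n_trials_per_condition=3, fs=1024.0)
        assert x.shape[0] == len(list(table.subset(table.subjects()[0])))
        assert len(onsets) == len(events) == 6
        assert np.all(np.diff(onsets) > 0)
        # the 50 Hz line component dominates its spectral neighborhood
        f, psd = np.abs(np.fft.rfftfreq(x.shape[1], 1 / 1024.0)), np.abs(np.fft.rfft(x[0])) ** 2
        at_line = psd[np.argmin(np.abs(f - 50.0))]
        nearby = psd[(f > 40) & (f < 46)].mean()
        assert at_line > 10 * nearby

    def test_burst_raises_gamma_power_on_angry_trials(self):
        spec = CohortSpec(n_subjects=1, electrodes_per_subject=(1, 1),
                          contacts_per_electrode=(6, 6), seed=5)
        table, _ = generate_geometry(spec)
        target = (table[0].label, table[0].hemisphere) if hasattr(table, "__getitem__") \
            else (next(iter(table)).label, next(iter(table)).hemisphere)
        effect = EffectSpec(target_structures={target}, effect_size=1.0,
                            effect_window_s=(0.3, 0.6))
        x, onsets, events = generate_raw(table, spec, effect,
                                         n_trials_per_condition=4, fs=1024.0,
                                         burst_snr=4.0, line_amplitude=0.0)
        contacts = list(table.subset(table.subjects()[0]))
        idx = [i for i, c in enumerate(contacts) if (c.label, c.hemisphere) == target]
        fs = 1024.0
        from scipy.signal import butter, sosfiltfilt
        sos = butter(4, [55.0, 115.0], btype="bandpass", fs=fs, output="sos")
        band = sosfiltfilt(sos, x[idx[0]])
        power = {}
        for cond in ("angry", "happy"):
            segs = []
            for onset in events.loc[events["condition"] == cond, "onset_s"]:
                i0, i1 = int((onset + 0.3) * fs), int((onset + 0.6) * fs)
                segs.append(np.mean(band[i0:i1] ** 2))
            power[cond] = np.mean(segs)
        assert power["angry"] > 2 * power["happy"]
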