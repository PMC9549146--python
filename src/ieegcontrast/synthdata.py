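"""Synthetic stereo-EEG cohorts with controlled condition effects.

The generator emulates the study conditions of a 13-subject depth-electrode
cohort: linear electrode trajectories with 3.5 mm contact spacing (8-18
contacts each) laid out around approximate structure centroids, ~45-65
artifact-free correct trials per condition, gamma-power traces on the
[-0.3, 1) s axis at 256 Hz, and reaction times that are slower for the angry
condition (0.97 s vs 0.85 s on average). Condition effects are injected as a
gamma-amplitude offset (in units of the noise SD) confined to chosen
structures and a chosen latency window, so every detection method can be
scored against a known ground truth. A raw-voltage generator (pink noise +
50 Hz line + condition-dependent 55-115 Hz bursts at 4096 Hz) exercises the
full spectral pipeline end to end.

The GPT noise model is temporally smoothed Gaussian noise (~50 ms moving
average), mimicking the autocorrelation of gamma-band power; it carries no
cross-trial or cross-channel structure, no artifacts and no oscillatory
background, so it tests the statistics, not the electrophysiology.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import uniform_filter1d
from scipy.signal import butter, sosfiltfilt
from scipy.spatial.distance import cdist

from .geometry import Contact, ContactTable, LabelVolume
from .groupcompare import load_centroids
from .spectral import GammaPowerTraces, gpt_time_axis

CONDITIONS = ("angry", "happy")


@dataclass
class EffectSpec:
    """Where, when and how strongly the two conditions differ."""

    target_structures: frozenset = frozenset()        # {(structure, hemisphere)}
    effect_size: float = 0.0                          # class mean difference, in noise SDs
    effect_window_s: tuple[float, float] = (0.3, 0.6)
    effect_kind: str = "amplitude"                    # or "latency"
    latency_shift_s: float = 0.0                      # only used by the latency kind

    def __post_init__(self) -> None:
        w0, w1 = self.effect_window_s
        if not (0.0 <= w0 < w1 <= 1.0):
            raise ValueError("effect window must lie within the post-stimulus range [0, 1] s")
        if self.effect_kind not in ("amplitude", "latency"):
            raise ValueError(f"unknown effect kind {self.effect_kind!r}")
        object.__setattr__(self, "target_structures", frozenset(self.target_structures))


@dataclass
class CohortSpec:
    """Cohort geometry and trial regime; defaults mirror the study cohort."""

    n_subjects: int = 13
    electrodes_per_subject: tuple[int, int] = (8, 14)
    contacts_per_electrode: tuple[int, int] = (8, 18)
    contact_spacing_mm: float = 3.5
    trials_per_condition: tuple[int, int] = (45, 65)
    noise_sd: float = 1.0
    rt_mean_s: dict = field(default_factory=lambda: {"angry": 0.97, "happy": 0.85})
    rt_sd_s: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        if self.contact_spacing_mm <= 0:
            raise ValueError("contact spacing must be positive")
        if self.noise_sd <= 0 or self.rt_sd_s <= 0:
            raise ValueError("noise and RT spreads must be positive")


def _implant_scheme(rng: np.random.Generator) -> list[str]:
    """Hemispheres an implant may target; cohort mix of LH-only/RH-only/bilateral."""
    return {"LH": ["LH"], "RH": ["RH"], "BI": ["LH", "RH"]}[
        str(rng.choice(["LH", "RH", "BI"], p=[0.55, 0.15, 0.30]))
    ]


def generate_geometry(spec: CohortSpec, centroids: pd.DataFrame | None = None,
                      voxel_size_mm: float = 2.0, unknown_beyond_mm: float = 25.0,
                      ) -> tuple[ContactTable, LabelVolume]:
    """Simulated electrode geometry plus a consistent rasterized label volume.

    Electrodes are straight lines of equidistant contacts (spec spacing)
    through a randomly chosen structure centroid with a random orientation;
    each contact is labeled by the nearest centroid in the electrode's
    hemisphere. The label volume rasterizes the same nearest-centroid rule on
    a regular grid (voxels farther than ``unknown_beyond_mm`` from every
    centroid are "unknown"), so volume-based and centroid-based labeling
    agree away from structure boundaries.
    """
    rng = np.random.default_rng(spec.seed)
    cent = (centroids if centroids is not None else load_centroids()).reset_index(drop=True)
    contacts: list[Contact] = []
    for si in range(spec.n_subjects):
        subject = f"SYN{si + 1:02d}"
        hemis = _implant_scheme(rng)
        n_elec = int(rng.integers(spec.electrodes_per_subject[0], spec.electrodes_per_subject[1] + 1))
        for ei in range(n_elec):
            hemi = hemis[ei % len(hemis)]
            pool = cent[cent["hemisphere"] == hemi]
            row = pool.iloc[int(rng.integers(len(pool)))]
            direction = rng.normal(size=3)
            direction /= np.linalg.norm(direction)
            n_c = int(rng.integers(spec.contacts_per_electrode[0], spec.contacts_per_electrode[1] + 1))
            offsets = (np.arange(n_c) - (n_c - 1) / 2.0) * spec.contact_spacing_mm
            xyz = np.array([row.x, row.y, row.z], float) + offsets[:, None] * direction
            # nearest same-hemisphere centroid labels each contact
            dists = cdist(xyz, pool[["x", "y", "z"]].to_numpy(float))
            labels = pool["structure"].to_numpy()[dists.argmin(axis=1)]
            for k in range(n_c):
                contacts.append(Contact(id=f"e{ei + 1}c{k + 1}", subject=subject,
                                        xyz=tuple(xyz[k]), label=str(labels[k]), hemisphere=hemi))

    table = ContactTable(contacts, template_name="synthetic")
    volume = _rasterize_centroids(cent, voxel_size_mm, unknown_beyond_mm)
    return table, volume


def _rasterize_centroids(cent: pd.DataFrame, voxel_size_mm: float, unknown_beyond_mm: float) -> LabelVolume:
    pts = cent[["x", "y", "z"]].to_numpy(float)
    lo = pts.min(axis=0) - 10.0
    hi = pts.max(axis=0) + 10.0
    shape = tuple(int(np.ceil((hi[i] - lo[i]) / voxel_size_mm)) + 1 for i in range(3))
    grids = np.meshgrid(*[lo[i] + voxel_size_mm * np.arange(shape[i]) for i in range(3)], indexing="ij")
    coords = np.stack([g.ravel() for g in grids], axis=1)
    dist = cdist(coords, pts)
    nearest = dist.argmin(axis=1)
    codes = nearest + 1
    codes[dist.min(axis=1) > unknown_beyond_mm] = 0
    # hemispheres share structure names; the code->name map keeps names only
    code_to_name = {i + 1: str(cent["structure"].iloc[i]) for i in range(len(cent))}
    return LabelVolume(voxels=codes.reshape(shape).astype(np.int32), code_to_name=code_to_name,
                       voxel_size_mm=(voxel_size_mm,) * 3, origin_mm=tuple(lo))


def _smooth_noise(rng: np.random.Generator, n_trials: int, n_time: int,
                  sd: float, kernel_samples: int = 13) -> np.ndarray:
    """Moving-average-smoothed Gaussian noise, rescaled back to SD ``sd``."""
    white = rng.standard_normal((n_trials, n_time))
    smooth = uniform_filter1d(white, size=kernel_samples, axis=1, mode="nearest")
    return smooth * (sd * np.sqrt(kernel_samples))


def _draw_rts(rng: np.random.Generator, conditions: np.ndarray, spec: CohortSpec) -> np.ndarray:
    rts = np.array([rng.normal(spec.rt_mean_s[c], spec.rt_sd_s) for c in conditions])
    return np.maximum(rts, 0.05)  # truncated positive


def generate_gpts(table: ContactTable, spec: CohortSpec, effect: EffectSpec | None = None,
                  seed: int | None = None) -> tuple[dict, pd.DataFrame]:
    """Per-contact gamma power traces plus a per-trial events table.

    Traces are on the baseline-corrected (dB-like) scale: zero-mean smoothed
    noise of SD ``spec.noise_sd``; contacts of the effect's target structures
    get ``effect_size x noise_sd`` added to the angry condition inside the
    effect window (amplitude kind) or a condition-shifted activation bump
    (latency kind). Returns ``({(subject, contact): GammaPowerTraces}, events)``.
    """
    effect = effect or EffectSpec()
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    times = gpt_time_axis()
    present = {(c.label, c.hemisphere) for c in table}
    missing = set(effect.target_structures) - present
    if missing:
        raise ValueError(f"effect targets not present in the contact table: {sorted(missing)}")
    w0, w1 = effect.effect_window_s
    window = (times >= w0) & (times <= w1)

    gpts: dict = {}
    events_rows = []
    for subject in table.subjects():
        n_a = int(rng.integers(spec.trials_per_condition[0], spec.trials_per_condition[1] + 1))
        n_h = int(rng.integers(spec.trials_per_condition[0], spec.trials_per_condition[1] + 1))
        conditions = np.array(["angry"] * n_a + ["happy"] * n_h)
        rng.shuffle(conditions)
        rts = _draw_rts(rng, conditions, spec)
        for t, (cond, rt) in enumerate(zip(conditions, rts)):
            events_rows.append({"subject": subject, "trial": t, "condition": cond,
                                "correct": True, "rt_s": float(rt), "artifact": False})
        angry = conditions == "angry"
        for contact in table.subset(subject):
            values = _smooth_noise(rng, len(conditions), len(times), spec.noise_sd)
            if (contact.label, contact.hemisphere) in effect.target_structures:
                if effect.effect_kind == "amplitude":
                    values[np.ix_(angry, window)] += effect.effect_size * spec.noise_sd
                else:
                    center = 0.5 * (w0 + w1)
                    bump = lambda c: np.exp(-0.5 * ((times - c) / 0.05) ** 2)
                    amp = effect.effect_size * spec.noise_sd
                    values[angry] += amp * bump(center + effect.latency_shift_s)
                    values[~angry] += amp * bump(center)
            gpts[contact.key] = GammaPowerTraces(values=values, times=times,
                                                 contact=contact, conditions=conditions)
    return gpts, pd.DataFrame(events_rows)


def generate_raw(table: ContactTable, spec: CohortSpec, effect: EffectSpec | None = None,
                 subject: str | None = None, fs: float = 4096.0,
                 n_trials_per_condition: int | None = None,
                 line_amplitude: float = 0.5, burst_snr: float = 2.0,
                 seed: int | None = None) -> tuple[np.ndarray, np.ndarray, pd.DataFrame]:
    """Continuous multichannel voltage for one subject, with stimulus onsets.

    Background is 1/f (pink) noise plus a 50 Hz line component; contacts of
    the effect's target structures additionally receive a 55-115 Hz
    band-limited burst inside the effect window on angry trials (amplitude
    ``burst_snr`` times the background SD). Returns
    ``(continuous [channels x samples], onsets_s, events)``.
    """
    effect = effect or EffectSpec()
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    subject = subject or table.subjects()[0]
    contacts = list(table.subset(subject))
    if not contacts:
        raise ValueError(f"subject {subject!r} has no contacts")

    n_per = n_trials_per_condition or int(np.mean(spec.trials_per_condition))
    conditions = np.array(["angry", "happy"] * n_per)
    rng.shuffle(conditions)
    n_trials = len(conditions)
    iti = 4.0
    onsets = 2.0 + iti * np.arange(n_trials)
    duration = onsets[-1] + 4.0
    n_samples = int(round(duration * fs))
    t = np.arange(n_samples) / fs

    # pink background: shape white noise by 1/sqrt(f) in the frequency domain
    freqs = np.fft.rfftfreq(n_samples, 1.0 / fs)
    shaping = np.where(freqs > 0, 1.0 / np.sqrt(np.maximum(freqs, freqs[1])), 0.0)
    x = np.empty((len(contacts), n_samples))
    for i in range(len(contacts)):
        spectrum = np.fft.rfft(rng.standard_normal(n_samples)) * shaping
        pink = np.fft.irfft(spectrum, n=n_samples)
        x[i] = pink / pink.std()
    if line_amplitude:
        x += line_amplitude * np.sin(2 * np.pi * 50.0 * t)

    sos = butter(4, [55.0, 115.0], btype="bandpass", fs=fs, output="sos")
    w0, w1 = effect.effect_window_s
    targeted = [i for i, c in enumerate(contacts)
                if (c.label, c.hemisphere) in effect.target_structures]
    for k, onset in enumerate(onsets):
        if conditions[k] != "angry" or not targeted:
            continue
        i0, i1 = int(round((onset + w0) * fs)), int(round((onset + w1) * fs))
        taper = np.hanning(i1 - i0)
        for i in targeted:
            burst = sosfiltfilt(sos, rng.standard_normal(i1 - i0 + 2048))[1024:-1024]
            burst = burst / burst.std() * burst_snr
            x[i, i0:i1] += burst * taper

    rts = _draw_rts(rng, conditions, spec)
    events = pd.DataFrame({"subject": subject, "trial": np.arange(n_trials),
                           "onset_s": onsets, "condition": conditions,
                           "correct": True, "rt_s": rts, "artifact": False})
    return x, onsets, events


def generate_cohort(spec: CohortSpec, effect: EffectSpec | None = None,
                    centroids: pd.DataFrame | None = None):
    """Geometry + label volume + GPTs + events + ground truth, in one call."""
    effect = effect or EffectSpec()
    table, volume = generate_geometry(spec, centroids=centroids)
    gpts, events = generate_gpts(table, spec, effect, seed=spec.seed + 1)
    truth = {
        "target_structures": sorted(list(s) for s in effect.target_structures),
        "effect_size": effect.effect_size,
        "effect_window_s": list(effect.effect_window_s),
        "effect_kind": effect.effect_kind,
        "seed": spec.seed,
    }
    return table, volume, gpts, events, truth
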