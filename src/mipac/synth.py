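"""Synthetic cohorts of theta-gamma coupled oscillatory time series.

The generator emulates the statistical structure the downstream analysis
assumes: per-subject quasi-rhythmic theta (~3-7 Hz) activity whose phase
modulates the amplitude of a gamma (~25-40 Hz) carrier, embedded in 1/f
background noise.  A cohort comprises three proficiency groups listening in
two languages (L1 native, L2 learned) under two conditions (natural speech
vs spectrally rotated control), recorded in two hemispheres.  Coupling
strength (modulation depth ``m``) is the ground truth: equal across groups
for L1, ordered with proficiency for L2, and near zero for the rotated
control.  Behavioral proficiency scores are generated with a linear link to
the subject's L2 coupling strength.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .containers import CONDITIONS, HEMISPHERES, LANGUAGES, TimeSeriesRecording

GRADES = (1, 2, 3)

#: Behavioral instruments and the noise SD (percentage points) of each.
#: Picture naming is the most sensitive instrument; the interview and the
#: self-reported daily-use measures carry more noise.
BEHAVIOR_NOISE_SD = {
    "picture_naming_pct": 10.0,
    "interview_pct": 15.0,
    "daily_use_pct": 20.0,
    "daily_listening_pct": 20.0,
}


def default_mod_depth() -> dict[tuple[int, str, str], float]:
    """Default ground-truth modulation depths per (grade, language, condition).

    L1 coupling is equal across groups; L2 coupling increases with grade;
    the rotated condition retains a weak residual coupling (m = 0.1) so the
    speech-specific contrast has a non-degenerate baseline.
    """
    depth: dict[tuple[int, str, str], float] = {}
    l2_natural = {1: 0.3, 2: 0.5, 3: 0.7}
    for g in GRADES:
        depth[(g, "L1", "natural")] = 0.7
        depth[(g, "L2", "natural")] = l2_natural[g]
        depth[(g, "L1", "rotated")] = 0.1
        depth[(g, "L2", "rotated")] = 0.1
    return depth


@dataclass
class SynthParams:
    """Ground-truth generative parameters for a synthetic cohort.

    Attributes
    ----------
    n_per_group
        Subjects per proficiency grade (beginner, intermediate, advanced).
    f_phase, f_amp
        Center frequencies (Hz) of the slow (theta) and fast (gamma)
        oscillations.  The gamma default (32 Hz) keeps both modulation
        sidebands (f_amp +/- f_phase = 27/37 Hz) strictly inside the
        25-40 Hz power band: with a carrier at 30 Hz the lower sideband
        sits exactly on the inclusive band edge and part of its
        jitter-broadened mass falls outside, which couples modulation
        depth to measured band power.
    freq_jitter_sd
        SD (Hz) of the cycle-wise instantaneous-frequency jitter that makes
        both rhythms quasi-periodic rather than sinusoidal.
    mod_depth
        Map (grade, language, condition) -> modulation depth m in [0, 1].
    preferred_phase
        Theta phase (radians) at which gamma amplitude is maximal.
    snr_db
        Oscillatory-signal-to-pink-noise ratio in dB; ``inf`` disables noise.
    trial_dur_s, n_trials
        Sentence-length trials: duration (s) and count per recording.
    fs
        Sampling rate (Hz).
    gamma_amp
        Amplitude of the gamma carrier relative to the unit theta carrier.
    subject_mod_sd
        Optional per-subject jitter (SD) on the cell modulation depth;
        0 keeps m identical within each design cell.
    behavior_intercept, behavior_slope
        Linear link from L2 modulation depth to behavioral percentage
        scores: score = intercept + slope * m + noise, clipped to [0, 100].
    seed
        Master seed; all randomness derives from it.
    """

    n_per_group: tuple[int, ...] = (13, 13, 12)
    f_phase: float = 5.0
    f_amp: float = 32.0
    freq_jitter_sd: float = 0.5
    mod_depth: dict[tuple[int, str, str], float] = field(default_factory=default_mod_depth)
    preferred_phase: float = 0.0
    snr_db: float = 0.0
    trial_dur_s: float = 10.0
    n_trials: int = 40
    fs: float = 500.0
    gamma_amp: float = 1.0
    subject_mod_sd: float = 0.0
    behavior_intercept: float = 35.0
    behavior_slope: float = 60.0
    behavior_noise_scale: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        if len(self.n_per_group) != len(GRADES):
            raise ValueError("n_per_group must give one count per grade")
        if any(n < 1 for n in self.n_per_group):
            raise ValueError("each group needs at least one subject")
        for key, m in self.mod_depth.items():
            if not 0.0 <= m <= 1.0:
                raise ValueError(f"mod_depth{key} = {m} outside [0, 1]")
        for g in GRADES:
            for lang in LANGUAGES:
                nat = self.mod_depth.get((g, lang, "natural"))
                rot = self.mod_depth.get((g, lang, "rotated"))
                if nat is None or rot is None:
                    raise ValueError(f"mod_depth missing cell for grade {g}, {lang}")
                if rot > nat:
                    raise ValueError(
                        f"rotated mod_depth must not exceed natural (grade {g}, {lang})"
                    )
        if self.fs <= 2.0 * (self.f_amp + 0.5):
            raise ValueError("fs too low for the gamma carrier (Nyquist)")
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")
        if self.trial_dur_s <= 0:
            raise ValueError("trial_dur_s must be positive")

    @property
    def n_subjects(self) -> int:
        return int(sum(self.n_per_group))


def pink_noise(n: int, rng: np.random.Generator) -> np.ndarray:
    """Unit-variance 1/f (pink) noise via spectral shaping of white noise."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n)
    shape = np.zeros_like(freqs)
    shape[1:] = 1.0 / np.sqrt(freqs[1:])
    x = np.fft.irfft(spec * shape, n)
    return x / x.std()


def _quasi_rhythmic_phase(
    n: int, fs: float, f0: float, jitter_sd: float, rng: np.random.Generator
) -> np.ndarray:
    """Phase of a rhythm whose frequency is redrawn each cycle.

    The instantaneous frequency is piecewise constant: each cycle's
    frequency is drawn from Normal(f0, jitter_sd), floored at 0.2*f0.
    """
    inst = np.empty(0)
    while inst.size < n:
        n_cycles = int(np.ceil((n - inst.size) / fs * f0 * 1.5)) + 8
        freqs = np.maximum(rng.normal(f0, jitter_sd, n_cycles), 0.2 * f0)
        durs = np.maximum(np.round(fs / freqs).astype(int), 1)
        inst = np.concatenate([inst, np.repeat(freqs, durs)])
    return 2.0 * np.pi * np.cumsum(inst[:n]) / fs


def generate_trial(
    params: SynthParams,
    cell: tuple[int, str, str],
    rng: np.random.Generator,
    mod_depth: float | None = None,
) -> np.ndarray:
    """Generate one trial for a design cell (grade, language, condition).

    Signal model: ``x(t) = cos(phi_th) + A * [1 - m + m*(1 + cos(phi_th -
    phi0))/2] * cos(phi_g) + pink noise``, with both phases integrated from
    cycle-wise jittered instantaneous frequencies and the envelope scaled
    to unit RMS so mean gamma power does not depend on m.  With ``m = 0``
    the gamma envelope is independent of theta phase; with ``m = 1`` it is
    fully modulated, peaking at theta phase ``phi0``.

    ``mod_depth`` overrides the cell's tabulated depth (used for
    per-subject jitter); the trial is bit-deterministic in ``rng`` state.
    """
    params.validate()
    if mod_depth is None:
        if cell not in params.mod_depth:
            raise KeyError(f"unknown design cell {cell}")
        mod_depth = params.mod_depth[cell]
    n = int(round(params.trial_dur_s * params.fs))
    phi_th = _quasi_rhythmic_phase(n, params.fs, params.f_phase, params.freq_jitter_sd, rng)
    phi_g = _quasi_rhythmic_phase(n, params.fs, params.f_amp, params.freq_jitter_sd, rng)
    envelope = 1.0 - mod_depth + mod_depth * (1.0 + np.cos(phi_th - params.preferred_phase)) / 2.0
    # Normalize to unit RMS so mean gamma-band power is independent of the
    # modulation depth (coupling strength must not leak into band power).
    envelope /= np.sqrt((1.0 - mod_depth / 2.0) ** 2 + mod_depth**2 / 8.0)
    signal = np.cos(phi_th) + params.gamma_amp * envelope * np.cos(phi_g)
    if np.isfinite(params.snr_db):
        noise_std = np.sqrt(np.mean(signal**2)) * 10.0 ** (-params.snr_db / 20.0)
        signal = signal + noise_std * pink_noise(n, rng)
    return signal


def _subject_ids(params: SynthParams) -> list[tuple[str, int]]:
    out = []
    k = 0
    for g, n in zip(GRADES, params.n_per_group):
        for _ in range(n):
            k += 1
            out.append((f"sub{k:02d}", g))
    return out


def generate_cohort(
    params: SynthParams,
) -> tuple[list[TimeSeriesRecording], pd.DataFrame]:
    """Generate the full cohort and its ground-truth table.

    Returns one recording per subject x language x condition x hemisphere
    (both hemispheres share the cell's modulation depth but have
    independent noise), and a long-format table of the depth ``m`` actually
    used for each recording.
    """
    params.validate()
    subjects = _subject_ids(params)
    root = np.random.SeedSequence(params.seed)
    n_rec = len(subjects) * len(LANGUAGES) * len(CONDITIONS) * len(HEMISPHERES)
    children = root.spawn(n_rec + len(subjects))
    recordings: list[TimeSeriesRecording] = []
    truth_rows: list[dict] = []
    idx = 0
    subj_rng = {sid: np.random.default_rng(children[n_rec + i]) for i, (sid, _) in enumerate(subjects)}
    for sid, grade in subjects:
        # Per-subject depth offsets, shared between conditions so the
        # rotated <= natural ordering is preserved.
        offsets = {
            lang: (subj_rng[sid].normal(0.0, params.subject_mod_sd) if params.subject_mod_sd > 0 else 0.0)
            for lang in LANGUAGES
        }
        for lang in LANGUAGES:
            for cond in CONDITIONS:
                m_cell = params.mod_depth[(grade, lang, cond)]
                m = float(np.clip(m_cell + offsets[lang] * (cond == "natural"), 0.0, 1.0))
                for hemi in HEMISPHERES:
                    rng = np.random.default_rng(children[idx])
                    idx += 1
                    trials = [
                        generate_trial(params, (grade, lang, cond), rng, mod_depth=m)
                        for _ in range(params.n_trials)
                    ]
                    recordings.append(
                        TimeSeriesRecording(
                            trials=trials,
                            fs=params.fs,
                            subject_id=sid,
                            grade=grade,
                            language=lang,
                            condition=cond,
                            hemisphere=hemi,
                        )
                    )
                    truth_rows.append(
                        {
                            "subject_id": sid,
                            "grade": grade,
                            "language": lang,
                            "condition": cond,
                            "hemisphere": hemi,
                            "mod_depth": m,
                        }
                    )
    return recordings, pd.DataFrame(truth_rows)


def generate_behavior(params: SynthParams, ground_truth: pd.DataFrame) -> pd.DataFrame:
    """Generate behavioral percentage scores linked to coupling strength.

    For each subject and language, each instrument's score is
    ``intercept + slope * m_natural + Normal(0, sd)`` clipped to [0, 100],
    where ``m_natural`` is the subject's natural-condition modulation depth
    for that language and ``sd`` is instrument-specific.
    """
    params.validate()
    m_nat = (
        ground_truth[ground_truth["condition"] == "natural"]
        .groupby(["subject_id", "language"], sort=False)["mod_depth"]
        .mean()
    )
    rng = np.random.default_rng(np.random.SeedSequence([params.seed, 2**20 + 7]))
    rows = []
    for (sid, lang), m in m_nat.items():
        row = {"subject_id": sid, "language": lang}
        for instrument, sd in BEHAVIOR_NOISE_SD.items():
            raw = params.behavior_intercept + params.behavior_slope * m + rng.normal(
                0.0, sd * params.behavior_noise_scale
            )
            row[instrument] = float(np.clip(raw, 0.0, 100.0))
        rows.append(row)
    return pd.DataFrame(rows)


def with_seed(params: SynthParams, seed: int) -> SynthParams:
    """Copy of ``params`` with a new master seed."""
    return replace(params, seed=seed)
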