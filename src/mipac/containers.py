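"""In-memory containers shared across the pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

LANGUAGES = ("L1", "L2")
CONDITIONS = ("natural", "rotated")
HEMISPHERES = ("left", "right")


@dataclass
class TimeSeriesRecording:
    """One subject x language x condition x hemisphere set of trial time series.

    Parameters
    ----------
    trials
        List of trial arrays, each of shape ``(n_samples,)`` for a single
        source or ``(n_samples, n_sources)`` for multi-source recordings.
    fs
        Sampling rate in Hz.
    subject_id, grade, language, condition, hemisphere
        Design metadata. ``grade`` is the proficiency group (1, 2 or 3);
        ``language`` is "L1"/"L2"; ``condition`` is "natural"/"rotated"
        (intelligible vs spectrally rotated speech); ``hemisphere`` is
        "left"/"right".
    """

    trials: list[np.ndarray]
    fs: float
    subject_id: str = "sub00"
    grade: int = 1
    language: str = "L1"
    condition: str = "natural"
    hemisphere: str = "left"

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if not self.trials:
            raise ValueError("recording needs at least one trial")
        self.trials = [np.asarray(t, dtype=float) for t in self.trials]
        ndims = {t.ndim for t in self.trials}
        if ndims - {1, 2}:
            raise ValueError("trials must be 1-D (samples) or 2-D (samples x sources)")
        if len(ndims) > 1:
            raise ValueError("all trials must have the same dimensionality")
        if self.language not in LANGUAGES:
            raise ValueError(f"language must be one of {LANGUAGES}")
        if self.condition not in CONDITIONS:
            raise ValueError(f"condition must be one of {CONDITIONS}")
        if self.hemisphere not in HEMISPHERES:
            raise ValueError(f"hemisphere must be one of {HEMISPHERES}")

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    @property
    def n_sources(self) -> int:
        t = self.trials[0]
        return 1 if t.ndim == 1 else t.shape[1]

    @property
    def meta(self) -> dict:
        return {
            "subject_id": self.subject_id,
            "grade": self.grade,
            "language": self.language,
            "condition": self.condition,
            "hemisphere": self.hemisphere,
        }


@dataclass
class GridMap:
    """A scalar field on the phase-frequency x amplitude-frequency grid."""

    phase_freqs: np.ndarray
    amp_freqs: np.ndarray
    values: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.phase_freqs = np.asarray(self.phase_freqs, dtype=float)
        self.amp_freqs = np.asarray(self.amp_freqs, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.phase_freqs.size, self.amp_freqs.size):
            raise ValueError(
                f"matrix shape {self.values.shape} does not match grids "
                f"({self.phase_freqs.size} x {self.amp_freqs.size})"
            )

    def same_grid(self, other: "GridMap") -> bool:
        return (
            self.phase_freqs.size == other.phase_freqs.size
            and self.amp_freqs.size == other.amp_freqs.size
            and np.allclose(self.phase_freqs, other.phase_freqs)
            and np.allclose(self.amp_freqs, other.amp_freqs)
        )


class Comodulogram(GridMap):
    """PAC (mutual information, bits) over the phase x amplitude grid."""

    @property
    def mi(self) -> np.ndarray:
        return self.values


class SsPacMap(GridMap):
    """Speech-specific PAC: natural-speech MI minus rotated-speech MI."""

    @property
    def sspac(self) -> np.ndarray:
        return self.values
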