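"""Mutual-information phase-amplitude coupling (PAC) estimation.

PAC between a slow band's phase and a fast band's amplitude envelope is
quantified as the mutual information (in bits) between the two sample
streams after each is quantized into 10 equipopulated (rank-based) bins.
The plugin ("direct") estimator is biased upward at finite n; the bias is
removed by quadratic extrapolation: the estimator is evaluated on the full
sample, on two disjoint random halves, and on four disjoint random
quarters, and the curve I(n) = I_inf + a/n + b/n^2 is solved for its
infinite-sample intercept I_inf.  Corrected values are not clipped at
zero, so condition differences (ssPAC) stay unbiased.

A comodulogram evaluates this estimator at every (phase-band, amp-band)
pair of a filter bank; the speech-specific ssPAC map is the elementwise
difference natural - rotated.
"""

from __future__ import annotations

import numpy as np

from .containers import Comodulogram, SsPacMap, TimeSeriesRecording
from .spectral import FilterBankSpec, analytic, bandpass

THETA_PHASE_BAND = (3.0, 7.5)
GAMMA_AMP_BAND = (22.0, 38.0)


def equipopulated_bins(values: np.ndarray, n_bins: int = 10) -> np.ndarray:
    """Rank-based quantization into (near-)equipopulated bins.

    The sample with rank r (stable sort, ties broken by original index)
    receives label ``floor(r * n_bins / n)``, so per-label counts differ
    from n/n_bins by at most one.
    """
    values = np.asarray(values)
    n = values.shape[0]
    if n < n_bins:
        raise ValueError(f"need at least {n_bins} samples, got {n}")
    order = np.argsort(values, kind="stable")
    labels = np.empty(n, dtype=np.int64)
    labels[order] = (np.arange(n, dtype=np.int64) * n_bins) // n
    return labels


def _mi_from_labels(phase_bins: np.ndarray, amp_bins: np.ndarray, n_bins: int) -> float:
    joint = np.bincount(phase_bins * n_bins + amp_bins, minlength=n_bins * n_bins).astype(float)
    n = joint.sum()
    pj = (joint / n).reshape(n_bins, n_bins)
    px = pj.sum(axis=1)
    py = pj.sum(axis=0)
    outer = px[:, None] * py[None, :]
    mask = pj > 0
    return float(np.sum(pj[mask] * np.log2(pj[mask] / outer[mask])))


def plugin_mi(phase_bins: np.ndarray, amp_bins: np.ndarray, n_bins: int | None = None) -> float:
    """Plugin (direct) MI estimate in bits from two label vectors.

    ``I = sum p(x,y) log2[p(x,y) / (p(x) p(y))]`` with 0 log 0 = 0;
    always in [0, log2(n_bins)] for equipopulated marginals.
    """
    phase_bins = np.asarray(phase_bins, dtype=np.int64)
    amp_bins = np.asarray(amp_bins, dtype=np.int64)
    if phase_bins.size == 0:
        raise ValueError("empty input")
    if phase_bins.shape != amp_bins.shape:
        raise ValueError("label vectors must have equal length")
    if n_bins is None:
        n_bins = int(max(phase_bins.max(), amp_bins.max())) + 1
    return _mi_from_labels(phase_bins, amp_bins, n_bins)


def quadratic_extrapolate(sizes: np.ndarray, values: np.ndarray) -> float:
    """Solve I(n) = I_inf + a/n + b/n^2 through three (size, value) points."""
    sizes = np.asarray(sizes, dtype=float)
    values = np.asarray(values, dtype=float)
    if sizes.shape != (3,) or values.shape != (3,):
        raise ValueError("exactly three (size, value) points required")
    u = 1.0 / sizes
    coeffs = np.linalg.solve(np.vander(u, 3), values)
    return float(coeffs[2])


def _partition(
    n: int, rng: np.random.Generator, n_blocks: int = 8
) -> tuple[list[np.ndarray], list[np.ndarray]]:
    """Disjoint random halves and quarters of range(n), block-structured.

    The index range is cut into ``n_blocks`` contiguous blocks which are
    randomly assigned (two per quarter, four per half).  Contiguous
    blocks preserve the serial dependence of band-limited signals, so a
    subset of size n/2 behaves like a record of half the length and the
    1/n bias law assumed by the quadratic extrapolation holds; for iid
    inputs the scheme is equivalent to a plain random split.
    """
    edges = np.linspace(0, n, n_blocks + 1).astype(int)
    blocks = [np.arange(edges[i], edges[i + 1]) for i in range(n_blocks)]
    order = rng.permutation(n_blocks)
    quarters = [
        np.sort(np.concatenate([blocks[order[2 * i]], blocks[order[2 * i + 1]]]))
        for i in range(4)
    ]
    halves = [
        np.sort(np.concatenate([quarters[0], quarters[1]])),
        np.sort(np.concatenate([quarters[2], quarters[3]])),
    ]
    return halves, quarters


def qe_corrected_mi(
    phase: np.ndarray,
    amp: np.ndarray,
    n_bins: int = 10,
    seed: int | np.random.Generator | None = 0,
) -> float:
    """Bias-corrected MI (bits) between raw phase and amplitude streams.

    Binning is recomputed within every subset so each subset estimator is
    self-consistent.  The result may be slightly negative under
    independence; it is deliberately not clipped.
    """
    phase = np.asarray(phase, dtype=float)
    amp = np.asarray(amp, dtype=float)
    if phase.shape != amp.shape or phase.ndim != 1:
        raise ValueError("phase and amp must be equal-length 1-D vectors")
    n = phase.shape[0]
    if n < 4 * n_bins:
        raise ValueError(f"need at least {4 * n_bins} samples, got {n}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    def sub_mi(idx: np.ndarray) -> float:
        return _mi_from_labels(
            equipopulated_bins(phase[idx], n_bins), equipopulated_bins(amp[idx], n_bins), n_bins
        )

    i1 = _mi_from_labels(equipopulated_bins(phase, n_bins), equipopulated_bins(amp, n_bins), n_bins)
    halves, quarters = _partition(n, rng)
    i2 = float(np.mean([sub_mi(idx) for idx in halves]))
    i4 = float(np.mean([sub_mi(idx) for idx in quarters]))
    n2 = float(np.mean([h.size for h in halves]))
    n4 = float(np.mean([q.size for q in quarters]))
    return quadratic_extrapolate(np.array([n, n2, n4]), np.array([i1, i2, i4]))


def _pooled_band_stream(
    trials: list[np.ndarray],
    center: float,
    spec: FilterBankSpec,
    edge_trim_s: float,
    kind: str,
) -> np.ndarray:
    """Filter, Hilbert and trim every trial at one center; pool samples.

    Equal-length trials are processed as one matrix (columns = trials);
    the pooled stream is ordered trial by trial either way.
    """
    lengths = {t.shape[0] for t in trials}
    if len(lengths) == 1:
        stacked = np.column_stack(trials)
        ph, am = analytic(bandpass(stacked, center, spec, kind), spec.fs, edge_trim_s)
        out = ph if kind == "phase" else am
        return out.T.reshape(-1)
    parts = []
    for trial in trials:
        ph, am = analytic(bandpass(trial, center, spec, kind), spec.fs, edge_trim_s)
        parts.append(ph if kind == "phase" else am)
    return np.concatenate(parts)


def comodulogram(
    recording: TimeSeriesRecording,
    spec: FilterBankSpec | None = None,
    n_bins: int = 10,
    edge_trim_s: float = 1.0,
    seed: int = 0,
) -> Comodulogram:
    """MI-PAC over all (phase band, amplitude band) pairs of a recording.

    Post-trim phase and amplitude samples are pooled across trials before
    binning; the random halves/quarters partition used by the quadratic
    extrapolation is drawn once per recording (per source) and shared by
    all grid cells, with rank binning recomputed inside every subset.
    Multi-source recordings are averaged over sources.
    """
    if recording.n_trials < 1:
        raise ValueError("recording has no trials")
    if spec is None:
        spec = FilterBankSpec(fs=recording.fs)
    mats = []
    for src in range(recording.n_sources):
        trials = (
            recording.trials
            if recording.trials[0].ndim == 1
            else [t[:, src] for t in recording.trials]
        )
        # every source shares the seed-determined partition
        mats.append(
            _single_source_comodulogram(
                trials, spec, n_bins, edge_trim_s, np.random.default_rng(seed)
            )
        )
    return Comodulogram(
        phase_freqs=spec.centers_phase,
        amp_freqs=spec.centers_amp,
        values=np.mean(mats, axis=0),
        meta=recording.meta,
    )


def _single_source_comodulogram(
    trials: list[np.ndarray],
    spec: FilterBankSpec,
    n_bins: int,
    edge_trim_s: float,
    rng: np.random.Generator,
) -> np.ndarray:
    n_total = sum(
        t.shape[0] - 2 * int(round(edge_trim_s * spec.fs)) for t in trials
    )
    if n_total < 4 * n_bins:
        raise ValueError("too few post-trim samples for bias-corrected MI")
    halves, quarters = _partition(n_total, rng)
    subsets = [np.arange(n_total)] + halves + quarters
    sizes = np.array(
        [
            n_total,
            float(np.mean([h.size for h in halves])),
            float(np.mean([q.size for q in quarters])),
        ]
    )

    def labels_per_subset(center: float, kind: str) -> list[np.ndarray]:
        stream = _pooled_band_stream(trials, center, spec, edge_trim_s, kind)
        return [equipopulated_bins(stream[idx], n_bins).astype(np.int16) for idx in subsets]

    try:
        phase_labels = [labels_per_subset(c, "phase") for c in spec.centers_phase]
        amp_labels = [labels_per_subset(c, "amp") for c in spec.centers_amp]
    except ValueError as err:
        raise ValueError(f"band decomposition failed: {err}") from err

    mi = np.empty((spec.centers_phase.size, spec.centers_amp.size))
    for i, pl in enumerate(phase_labels):
        for j, al in enumerate(amp_labels):
            try:
                i1 = _mi_from_labels(pl[0], al[0], n_bins)
                i2 = 0.5 * (
                    _mi_from_labels(pl[1], al[1], n_bins) + _mi_from_labels(pl[2], al[2], n_bins)
                )
                i4 = 0.25 * sum(_mi_from_labels(pl[k], al[k], n_bins) for k in range(3, 7))
                mi[i, j] = quadratic_extrapolate(sizes, np.array([i1, i2, i4]))
            except Exception as err:  # attach grid coordinates
                raise RuntimeError(
                    f"MI failed at phase {spec.centers_phase[i]} Hz, "
                    f"amp {spec.centers_amp[j]} Hz: {err}"
                ) from err
    return mi


def sspac(natural: Comodulogram, rotated: Comodulogram) -> SsPacMap:
    """Speech-specific PAC: natural-speech MI minus rotated-speech MI.

    Positive where cortical activity couples more strongly to natural than
    to spectrally rotated speech; negative otherwise.
    """
    if not natural.same_grid(rotated):
        raise ValueError("comodulogram grids do not match")
    for key in ("subject_id", "language", "hemisphere"):
        if natural.meta.get(key) != rotated.meta.get(key):
            raise ValueError(f"meta mismatch on {key!r}")
    if (natural.meta.get("condition"), rotated.meta.get("condition")) not in (
        ("natural", "rotated"),
        (None, None),
    ):
        raise ValueError("expected a natural and a rotated comodulogram, in that order")
    meta = {k: v for k, v in natural.meta.items() if k != "condition"}
    return SsPacMap(
        phase_freqs=natural.phase_freqs,
        amp_freqs=natural.amp_freqs,
        values=natural.values - rotated.values,
        meta=meta,
    )


def band_average(
    grid_map,
    phase_band: tuple[float, float] = THETA_PHASE_BAND,
    amp_band: tuple[float, float] = GAMMA_AMP_BAND,
) -> float:
    """Mean over grid cells whose centers fall inside both bands (inclusive)."""
    pmask = (grid_map.phase_freqs >= phase_band[0] - 1e-9) & (
        grid_map.phase_freqs <= phase_band[1] + 1e-9
    )
    amask = (grid_map.amp_freqs >= amp_band[0] - 1e-9) & (grid_map.amp_freqs <= amp_band[1] + 1e-9)
    if not pmask.any() or not amask.any():
        raise ValueError(f"bands {phase_band} x {amp_band} contain no grid cells")
    return float(grid_map.values[np.ix_(pmask, amask)].mean())
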