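"""Signal conditioning from per-block ROI series to per-condition group series.

The chain mirrors standard resting-state BOLD practice for ROI series:

1. nuisance regression against a shared reference series (e.g. the mean
   white-matter/ventricle signal),
2. a zero-phase high-pass filter removing drift below 0.009 Hz, applied per
   block so the filter never crosses recording boundaries,
3. pooled per-subject, per-region demeaning ("normalized around the mean"),
4. concatenation of all subjects' blocks of one condition into a single
   series, with the first and last 5 samples of every block smoothed by a
   Gaussian moving average of window 5 to suppress spurious dependence from
   the artificial junctions.

Under the default design this yields a 4,000 x 8 series per condition
(100 volumes x 2 blocks x 20 subjects).
"""
from __future__ import annotations

from collections import defaultdict

import numpy as np
from scipy import signal

from .core import Block, MultichannelSeries, RegionSet

__all__ = [
    "MultichannelSeries",
    "nuisance_regress",
    "highpass_filter",
    "normalize_subject",
    "smooth_block_edges",
    "concatenate_blocks",
    "preprocess_study",
]


def nuisance_regress(values: np.ndarray, nuisance: np.ndarray) -> np.ndarray:
    """Replace each region column by its OLS residual on [intercept, nuisance].

    Residuals are exactly orthogonal to the nuisance regressor and mean-zero.
    """
    values = np.atleast_2d(np.asarray(values, dtype=float))
    nuisance = np.asarray(nuisance, dtype=float).ravel()
    if len(nuisance) != values.shape[0]:
        raise ValueError(
            f"nuisance length {len(nuisance)} != series length {values.shape[0]}"
        )
    if np.std(nuisance) == 0.0:
        raise ValueError("nuisance regressor has zero variance (singular fit)")
    X = np.column_stack([np.ones_like(nuisance), nuisance])
    beta, *_ = np.linalg.lstsq(X, values, rcond=None)
    return values - X @ beta


def highpass_filter(
    values: np.ndarray,
    repetition_time: float,
    cutoff_hz: float = 0.009,
    order: int = 4,
) -> np.ndarray:
    """Zero-phase Butterworth high-pass along the sample axis of one block.

    Forward-backward filtering (``sosfiltfilt``) is used so that no phase
    shift is introduced: a phase-shifting filter would bias the lagged
    dependence estimates downstream.
    """
    values = np.atleast_2d(np.asarray(values, dtype=float))
    fs = 1.0 / repetition_time
    if cutoff_hz >= fs / 2.0:
        raise ValueError(
            f"cutoff {cutoff_hz} Hz >= Nyquist {fs / 2.0:.4g} Hz"
        )
    if cutoff_hz <= 0:
        raise ValueError("cutoff must be positive")
    sos = signal.butter(order, cutoff_hz, btype="highpass", fs=fs, output="sos")
    return signal.sosfiltfilt(sos, values, axis=0)


def normalize_subject(blocks: list[Block], scale_variance: bool = False) -> list[Block]:
    """Demean each region over the pooled samples of one subject.

    Demeaning is pooled across all of the subject's blocks (both conditions),
    not per block: per-block mean differences are part of the signal the
    analysis sees. With ``scale_variance`` the pooled standard deviation is
    divided out as well (off by default).
    """
    blocks = list(blocks)
    if not blocks:
        return []
    subjects = {b.subject for b in blocks}
    if len(subjects) != 1:
        raise ValueError(f"normalize_subject expects blocks of one subject, got {subjects}")
    pooled = np.vstack([b.values for b in blocks])
    mean = pooled.mean(axis=0)
    if scale_variance:
        std = pooled.std(axis=0)
        std[std == 0.0] = 1.0
    else:
        std = 1.0
    return [b.copy_with((b.values - mean) / std) for b in blocks]


def _gaussian_kernel(window: int, sigma: float) -> np.ndarray:
    return signal.windows.gaussian(window, std=sigma)


def smooth_block_edges(
    values: np.ndarray, n_edge: int = 5, window: int = 5, sigma: float = 1.0
) -> np.ndarray:
    """Gaussian moving average applied to the first/last ``n_edge`` samples only.

    The kernel is renormalized where it overhangs the series ends, so a
    constant block is preserved exactly. Interior samples are returned
    bit-identical.
    """
    values = np.atleast_2d(np.asarray(values, dtype=float))
    n = values.shape[0]
    if n <= 2 * n_edge:
        raise ValueError(f"block of {n} samples too short for {n_edge}-sample edge smoothing")
    k = _gaussian_kernel(window, sigma)
    num = signal.convolve2d(values, k[:, None], mode="same", boundary="fill")
    den = signal.convolve(np.ones(n), k, mode="same")
    smoothed = num / den[:, None]
    out = values.copy()
    out[:n_edge] = smoothed[:n_edge]
    out[-n_edge:] = smoothed[-n_edge:]
    return out


def concatenate_blocks(
    blocks: list[Block],
    repetition_time: float | None = None,
    n_edge: int = 5,
    window: int = 5,
    sigma: float = 1.0,
) -> MultichannelSeries:
    """Join all blocks of one condition into a single series.

    Blocks are ordered deterministically (subject ascending, then block index)
    and their start indices recorded as ``block_boundaries``. Only the first
    and last ``n_edge`` samples of each block are altered (edge smoothing).
    """
    blocks = sorted(blocks, key=lambda b: (b.subject, b.index))
    if not blocks:
        raise ValueError("no blocks to concatenate")
    conditions = {b.condition for b in blocks}
    if len(conditions) != 1:
        raise ValueError(f"blocks of several conditions passed: {conditions}")
    regions = blocks[0].regions
    lengths = {b.n_samples for b in blocks}
    for b in blocks:
        if b.regions.labels != regions.labels:
            raise ValueError("region-set mismatch across blocks")
    if len(lengths) != 1:
        raise ValueError(f"blocks have differing lengths: {sorted(lengths)}")
    parts, boundaries, subjects = [], [], []
    start = 0
    for b in blocks:
        parts.append(smooth_block_edges(b.values, n_edge=n_edge, window=window, sigma=sigma))
        boundaries.append(start)
        subjects.append(b.subject)
        start += b.n_samples
    return MultichannelSeries(
        values=np.vstack(parts),
        regions=regions,
        repetition_time=1.6 if repetition_time is None else repetition_time,
        block_boundaries=tuple(boundaries),
        condition=blocks[0].condition,
        subjects=tuple(subjects),
    )


def preprocess_study(
    blocks: list[Block],
    nuisance=None,
    repetition_time: float = 1.6,
    cutoff_hz: float = 0.009,
    demean: bool = True,
    scale_variance: bool = False,
    n_edge: int = 5,
) -> dict[str, MultichannelSeries]:
    """Run the full conditioning chain and return one series per condition.

    ``nuisance`` may be ``None`` (skip regression), a single series applied to
    every block, or a list with one series per block in the given order.
    """
    blocks = list(blocks)
    if nuisance is not None:
        if isinstance(nuisance, (list, tuple)):
            if len(nuisance) != len(blocks):
                raise ValueError("one nuisance series per block required")
            pairs = zip(blocks, nuisance)
        else:
            pairs = ((b, nuisance) for b in blocks)
        blocks = [b.copy_with(nuisance_regress(b.values, s)) for b, s in pairs]
    blocks = [
        b.copy_with(highpass_filter(b.values, repetition_time, cutoff_hz)) for b in blocks
    ]
    if demean:
        by_subject = defaultdict(list)
        for b in blocks:
            by_subject[b.subject].append(b)
        blocks = [
            nb
            for subj in sorted(by_subject)
            for nb in normalize_subject(by_subject[subj], scale_variance=scale_variance)
        ]
    by_condition = defaultdict(list)
    for b in blocks:
        by_condition[b.condition].append(b)
    return {
        cond: concatenate_blocks(bl, repetition_time=repetition_time, n_edge=n_edge)
        for cond, bl in by_condition.items()
    }
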