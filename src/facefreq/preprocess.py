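"""Epoched-EEG cleaning: re-reference, filter, baseline, rejection, interpolation.

The pipeline order is the conventional one and is what
:func:`preprocess_pipeline` applies: average re-reference -> zero-phase
0.1–30 Hz band-pass -> baseline correction over [-500, 0] ms -> automatic
artifact rejection (amplitude and spectral rules) -> bad-channel
interpolation.  Each step is also usable on its own.

Notes on the choices the description of the source recordings leaves
open: filtering is zero-phase (forward-backward) to preserve ERP
latencies; the amplitude threshold is applied after re-referencing; the
spectral-outlier rule compares each trial's power spectrum to the
across-trial mean and SD per frequency bin, within participant, and
bins with zero SD can never flag.  Ocular ICA is out of scope — a hook
accepts an externally computed unmixing matrix instead.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import signal

from .epochs import EpochSet
from .layout import SensorLayout

__all__ = [
    "rereference_average",
    "bandpass_and_baseline",
    "detect_artifact_trials",
    "interpolate_channels",
    "apply_unmixing_hook",
    "preprocess_pipeline",
    "rejection_log",
]


def rereference_average(epochs: EpochSet) -> EpochSet:
    """Subtract the instantaneous mean over good channels from every sample.

    Bad channels are excluded from the mean but still re-referenced.
    Idempotent; after the operation the sum over good channels is zero.
    """
    good = epochs.good_channel_indices()
    if good.size < 2:
        raise ValueError("average reference requires at least 2 good channels")
    out = epochs.copy()
    ref = out.data[:, good, :].mean(axis=1, keepdims=True)
    out.data = out.data - ref
    return out


def bandpass_and_baseline(
    epochs: EpochSet,
    lo: float = 0.1,
    hi: float = 30.0,
    baseline_ms: tuple[float, float] = (-500.0, 0.0),
    order: int = 4,
) -> EpochSet:
    """Zero-phase Butterworth band-pass, then per-trial baseline correction.

    The filter is applied forward-backward (``sosfiltfilt``) per channel;
    afterwards the mean over ``baseline_ms`` is subtracted per trial and
    channel.
    """
    nyq = epochs.sfreq / 2.0
    if hi >= nyq:
        raise ValueError(f"high cutoff {hi} Hz at or above Nyquist {nyq} Hz")
    if not 0 < lo < hi:
        raise ValueError("need 0 < lo < hi")
    sos = signal.butter(order, [lo, hi], btype="bandpass", fs=epochs.sfreq,
                        output="sos")
    out = epochs.copy()
    # maximal odd-reflection padding keeps the slow high-pass transient
    # from leaking into the short epoch
    out.data = signal.sosfiltfilt(sos, out.data, axis=-1,
                                  padlen=out.data.shape[-1] - 1)
    bmask = out.time_mask(baseline_ms)
    out.data -= out.data[:, :, bmask].mean(axis=-1, keepdims=True)
    return out


def detect_artifact_trials(
    epochs: EpochSet,
    amp_thresh: float = 150.0,
    spec_sd: float = 2.0,
    spec_frac: float = 0.10,
    band: tuple[float, float] = (1.0, 30.0),
) -> EpochSet:
    """Flag artifact trials by amplitude and spectral-outlier rules.

    A trial is rejected when any good-channel sample exceeds
    ``amp_thresh`` (uV, absolute), or when its power spectrum exceeds the
    across-trial mean + ``spec_sd`` standard deviations in more than
    ``spec_frac`` of the frequency bins inside ``band`` (Hz).  The
    per-trial spectrum is the channel-averaged periodogram; frequency
    bins whose across-trial SD is zero never flag.  Flagged trials stay
    in ``data`` but carry a reason code in ``rejected_trials``.
    """
    if band[1] > epochs.sfreq / 2.0:
        raise ValueError("spectral band exceeds Nyquist")
    out = epochs.copy()
    good = out.good_channel_indices()
    x = out.data[:, good, :]

    amp_bad = np.abs(x).max(axis=(1, 2)) > amp_thresh

    freqs, psd = signal.periodogram(x, fs=out.sfreq, axis=-1)
    psd = psd.mean(axis=1)  # channel-averaged: trials x freq bins
    fmask = (freqs >= band[0]) & (freqs <= band[1])
    psd = psd[:, fmask]
    mu = psd.mean(axis=0)
    sd = psd.std(axis=0, ddof=0)
    with np.errstate(invalid="ignore"):
        exceed = (psd > mu + spec_sd * sd) & (sd > 0)
    spec_bad = exceed.mean(axis=1) > spec_frac

    for i in np.flatnonzero(amp_bad | spec_bad):
        reasons = []
        if amp_bad[i]:
            reasons.append("amplitude")
        if spec_bad[i]:
            reasons.append("spectrum")
        out.rejected_trials[int(i)] = "+".join(reasons)
    return out


def interpolate_channels(
    epochs: EpochSet,
    layout: SensorLayout,
    bad: set[str] | None = None,
    max_bad_fraction: float = 0.10,
) -> EpochSet:
    """Replace bad channels by the inverse-distance mean of good neighbors.

    Mirrors the study's inclusion rule: if more than ``max_bad_fraction``
    of the channels are bad the recording is not usable and an error is
    raised.  Each bad channel needs at least one good neighbor in the
    layout adjacency.
    """
    out = epochs.copy()
    if bad is not None:
        out.bad_channels = set(bad)
    if not out.bad_channels:
        return out
    unknown = out.bad_channels - set(layout.names)
    if unknown:
        raise ValueError(f"bad channels not in layout: {unknown}")
    if len(out.bad_channels) > max_bad_fraction * layout.n_channels:
        raise ValueError(
            f"{len(out.bad_channels)} bad channels exceed the "
            f"{max_bad_fraction:.0%} cap for a usable recording")
    for name in sorted(out.bad_channels):
        i = layout.index(name)
        nb = [j for j in np.flatnonzero(layout.adjacency[i])
              if layout.names[j] not in out.bad_channels]
        if not nb:
            raise ValueError(f"bad channel {name} has no good neighbor")
        d = np.linalg.norm(layout.pos[nb] - layout.pos[i], axis=1)
        w = 1.0 / np.maximum(d, 1e-12)
        w /= w.sum()
        out.data[:, i, :] = np.einsum("k,tkx->tx", w, out.data[:, nb, :])
    out.bad_channels = set()
    return out


def apply_unmixing_hook(epochs: EpochSet, unmixing: np.ndarray,
                        drop_components: list[int]) -> EpochSet:
    """Remove externally identified components (e.g. ocular) from the data.

    ``unmixing`` (components x channels) comes from an external
    decomposition; the listed component indices are zeroed and the data
    projected back.
    """
    out = epochs.copy()
    mixing = np.linalg.pinv(unmixing)
    sources = np.einsum("kc,tcx->tkx", unmixing, out.data)
    sources[:, drop_components, :] = 0.0
    out.data = np.einsum("ck,tkx->tcx", mixing, sources)
    return out


def preprocess_pipeline(
    epochs: EpochSet,
    layout: SensorLayout,
    bad_channels: set[str] | None = None,
    amp_thresh: float = 150.0,
) -> EpochSet:
    """Full cleaning chain in the canonical order."""
    out = epochs.copy()
    if bad_channels:
        out.bad_channels = set(bad_channels)
    out = rereference_average(out)
    out = bandpass_and_baseline(out)
    out = detect_artifact_trials(out, amp_thresh=amp_thresh)
    out = interpolate_channels(out, layout)
    return out


def rejection_log(epochs_by_participant: dict[str, EpochSet]) -> pd.DataFrame:
    """Tidy per-trial rejection table (participant, trial, reason)."""
    rows = [
        {"participant": pid, "trial": tr, "reason": reason}
        for pid, ep in epochs_by_participant.items()
        for tr, reason in sorted(ep.rejected_trials.items())
    ]
    return pd.DataFrame(rows, columns=["participant", "trial", "reason"])
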