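"""Synthetic EEG cohorts with the structure the analyses assume.

The generator emulates the study design this package analyzes: two
groups of parents (18 pTD, 25 pASD), ~232 trials per participant split
evenly over the four hybrid-face conditions (AA, HH, AH, HA), 64
channels, and four condition-dependent ERP components:

* P1 — occipital positivity around 125 ms, condition-independent;
* N170 — temporo-parietal negativity around 180 ms, condition-independent;
* N250 — temporo-parietal negativity, 250–350 ms, condition-independent;
* LPP — sustained left-frontal / right-parietal positivity spanning
  430–730 ms, with a condition modulation that peaks for congruent-happy
  (HH) stimuli.

In the pASD group the LPP *condition contrast* (each condition's
deviation from the condition mean) is multiplied by an attenuation
factor in [0, 1], mirroring the reduced late modulation the analyses
look for.  Each pASD parent also receives a child-severity score built
to correlate negatively with that parent's realized LPP ROI contrast.

Component waveforms are Gaussian in time with fixed linear spatial
topographies; noise is Gaussian, white in time and spatially correlated
across channels with exponential distance decay, so adjacency-based
clustering is meaningful.  One global seed expands into independent
per-participant substreams, so any participant can be regenerated
without simulating the whole cohort.

The study does not report per-condition LPP amplitudes in microvolts;
the default amplitudes here are free parameters chosen to give a
plausible late-positive modulation (HH 3 uV vs ~1–1.5 uV elsewhere) on
top of band-limited single-trial noise of 5 uV per sample, which puts
the condition-mean noise floor at 58 trials (~0.7 uV) in the range of
typical residual ERP noise and makes the group-dispersion contrast
detectable at the study's sample sizes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .epochs import CONDITIONS, GROUPS, EpochSet
from .layout import SensorLayout, default_layout

__all__ = [
    "ComponentSim",
    "SimConfig",
    "Cohort",
    "simulate_epochs",
    "simulate_behavior",
    "simulate_cohort",
    "lpp_roi_contrast",
]


@dataclass
class ComponentSim:
    """One ERP component template: Gaussian in time, fixed topography.

    ``width_ms`` is the full width at half maximum of the temporal
    Gaussian.  ``amplitudes`` maps condition -> peak amplitude in uV
    (sign included).  The spatial topography is a sum of Gaussian blobs
    at ``centers`` (2-D layout coordinates) with spread ``spatial_sigma``,
    normalized to peak weight 1 so amplitudes are in uV at the best
    channel.
    """

    name: str
    latency_ms: float
    width_ms: float
    amplitudes: dict[str, float]
    centers: tuple[tuple[float, float], ...]
    spatial_sigma: float = 0.35

    def __post_init__(self) -> None:
        missing = set(CONDITIONS) - set(self.amplitudes)
        if missing:
            raise ValueError(f"component {self.name}: missing amplitudes {missing}")
        if not all(math.isfinite(a) for a in self.amplitudes.values()):
            raise ValueError(f"component {self.name}: amplitudes must be finite")
        if self.width_ms <= 0:
            raise ValueError(f"component {self.name}: width_ms must be positive")

    def temporal_profile(self, times_ms: np.ndarray) -> np.ndarray:
        sigma = self.width_ms / 2.3548200450309493  # FWHM -> SD
        return np.exp(-0.5 * ((times_ms - self.latency_ms) / sigma) ** 2)

    def topography(self, layout: SensorLayout) -> np.ndarray:
        w = np.zeros(layout.n_channels)
        for cx, cy in self.centers:
            d2 = ((layout.pos - (cx, cy)) ** 2).sum(axis=1)
            w += np.exp(-0.5 * d2 / self.spatial_sigma ** 2)
        peak = w.max()
        return w / peak if peak > 0 else w


def default_components() -> list[ComponentSim]:
    tp_centers = ((-0.65, -0.45), (0.65, -0.45))
    return [
        ComponentSim("P1", 125.0, 50.0, {c: 5.0 for c in CONDITIONS},
                     centers=((0.0, -0.8),), spatial_sigma=0.35),
        ComponentSim("N170", 180.0, 50.0, {c: -6.0 for c in CONDITIONS},
                     centers=tp_centers, spatial_sigma=0.30),
        ComponentSim("N250", 300.0, 100.0, {c: -3.0 for c in CONDITIONS},
                     centers=tp_centers, spatial_sigma=0.30),
        ComponentSim("LPP", 580.0, 300.0,
                     {"HH": 3.0, "AA": 1.0, "AH": 1.5, "HA": 1.5},
                     centers=((-0.45, 0.55), (0.5, -0.45)), spatial_sigma=0.40),
    ]


def _default_behavior() -> dict[str, float]:
    # P(respond "happy" | condition): congruent accuracies 0.74 / 0.59 and
    # incongruent rates that reproduce an emotional bias of ~0.084 and a
    # spatial-frequency bias of ~0.03 in expectation.
    return {"HH": 0.74, "AA": 0.41, "AH": 0.615, "HA": 0.553}


def _default_rt() -> dict[str, tuple[float, float]]:
    # Mean/SD in ms; congruent-happy responses are fastest.
    return {"HH": (607.0, 150.0), "AA": (644.0, 150.0),
            "AH": (650.0, 150.0), "HA": (645.0, 150.0)}


@dataclass
class SimConfig:
    """Parameters of the synthetic study.

    Key fields
    ----------
    n_per_group : dict group -> participant count (defaults 18 pTD, 25 pASD).
    n_trials_per_condition : trials per condition per participant (58,
        i.e. ~232 over the four conditions).
    sfreq : sampling rate in Hz.  The analyses are specified in ms, so
        results are rate-independent; 250 Hz keeps simulations desk-scale.
    epoch_window : epoch limits in seconds relative to stimulus onset.
    lpp_attenuation_pASD : multiplicative factor in [0, 1] on the LPP
        condition contrast in the pASD group (1 = no group difference).
    noise_sd : per-sample noise SD in uV.
    channel_noise_correlation : noise correlation between neighboring
        channels, in [0, 1); decays exponentially with layout distance.
    participant_amp_sd : SD (uV) of a per-participant additive shift of
        each component's overall amplitude (between-subject heterogeneity).
    contrast_scale_sd : SD of a per-participant multiplicative jitter on
        each component's condition contrast.
    severity_target_rho : if set, pASD severity scores are constructed so
        the population Spearman correlation with the realized LPP ROI
        contrast equals this value; otherwise the linear
        ``severity_intercept - severity_link * contrast + noise`` rule is
        used.
    """

    n_per_group: dict[str, int] = field(
        default_factory=lambda: {"pTD": 18, "pASD": 25})
    n_trials_per_condition: int = 58
    n_channels: int = 64
    sfreq: float = 250.0
    epoch_window: tuple[float, float] = (-0.5, 1.5)
    components: list[ComponentSim] = field(default_factory=default_components)
    lpp_attenuation_pASD: float = 0.3
    noise_sd: float = 5.0
    channel_noise_correlation: float = 0.6
    participant_amp_sd: float = 0.75
    contrast_scale_sd: float = 0.2
    behavior_params: dict[str, float] = field(default_factory=_default_behavior)
    rt_params: dict[str, tuple[float, float]] = field(default_factory=_default_rt)
    severity_intercept: float = 5.0
    severity_link: float = 0.0
    severity_noise_sd: float = 1.0
    severity_spread: float = 1.8
    severity_target_rho: float | None = -0.5
    lpp_roi: str = "right-parietal"
    lpp_window_ms: tuple[float, float] = (430.0, 730.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if set(self.n_per_group) - set(GROUPS):
            raise ValueError(f"groups must be among {GROUPS}")
        if self.n_trials_per_condition <= 0:
            raise ValueError("n_trials_per_condition must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not 0.0 <= self.lpp_attenuation_pASD <= 1.0:
            raise ValueError("lpp_attenuation_pASD must lie in [0, 1]")
        if not 0.0 <= self.channel_noise_correlation < 1.0:
            raise ValueError("channel_noise_correlation must lie in [0, 1)")
        for cond in CONDITIONS:
            p = self.behavior_params.get(cond)
            if p is None or not 0.0 < p < 1.0:
                raise ValueError(
                    f"behavior_params[{cond!r}] must lie strictly in (0, 1)")
        if self.epoch_window[0] >= self.epoch_window[1]:
            raise ValueError("epoch_window must be increasing")

    def times_ms(self) -> np.ndarray:
        t0, t1 = self.epoch_window
        n = int(round((t1 - t0) * self.sfreq))
        return (t0 + np.arange(n) / self.sfreq) * 1000.0

    def layout(self) -> SensorLayout:
        return default_layout(self.n_channels)

    def manifest(self) -> dict:
        d = asdict(self)
        d["components"] = [asdict(c) for c in self.components]
        return d


def _participant_rng(config: SimConfig, group: str, index: int,
                     stream: str) -> np.random.Generator:
    """Independent, reproducible substream per participant and purpose."""
    group_code = GROUPS.index(group)
    stream_code = {"epochs": 0, "behavior": 1, "severity": 2}[stream]
    return np.random.default_rng(
        np.random.SeedSequence(entropy=config.seed,
                               spawn_key=(group_code, index, stream_code)))


def _noise_chol(config: SimConfig, layout: SensorLayout) -> np.ndarray:
    c = config.channel_noise_correlation
    if c == 0.0:
        return np.eye(layout.n_channels)
    d = np.linalg.norm(layout.pos[:, None, :] - layout.pos[None, :, :], axis=-1)
    nb = d[layout.adjacency]
    d0 = np.median(nb) if nb.size else 1.0
    cov = c ** (d / d0)  # exponential decay: correlation c at neighbor distance
    return np.linalg.cholesky(cov + 1e-10 * np.eye(len(cov)))


def _condition_templates(
    config: SimConfig, layout: SensorLayout, group: str,
    amp_shift: np.ndarray, contrast_scale: np.ndarray,
) -> dict[str, np.ndarray]:
    """Per-condition channels x time templates for one participant."""
    times = config.times_ms()
    out = {c: np.zeros((layout.n_channels, times.size)) for c in CONDITIONS}
    for j, comp in enumerate(config.components):
        topo = comp.topography(layout)
        prof = comp.temporal_profile(times)
        amps = {c: comp.amplitudes[c] for c in CONDITIONS}
        mean_amp = float(np.mean(list(amps.values())))
        for c in CONDITIONS:
            contrast = amps[c] - mean_amp
            if group == "pASD" and comp.name == "LPP":
                contrast *= config.lpp_attenuation_pASD
            amp = (mean_amp + amp_shift[j]) + contrast_scale[j] * contrast
            out[c] += amp * topo[:, None] * prof[None, :]
    return out


def simulate_epochs(config: SimConfig, group: str, participant_index: int,
                    layout: SensorLayout | None = None) -> EpochSet:
    """Simulate one participant's epoched EEG.

    Each trial is the participant's condition template (Gaussian
    components with per-participant amplitude shifts and contrast
    scaling; the LPP contrast attenuated for pASD) plus spatially
    correlated Gaussian noise.  Deterministic given the config seed,
    group and participant index.
    """
    if group not in GROUPS:
        raise ValueError(f"group must be one of {GROUPS}, got {group!r}")
    if layout is None:
        layout = config.layout()
    rng = _participant_rng(config, group, participant_index, "epochs")

    n_comp = len(config.components)
    amp_shift = rng.normal(0.0, config.participant_amp_sd, size=n_comp)
    contrast_scale = np.maximum(
        rng.normal(1.0, config.contrast_scale_sd, size=n_comp), 0.0)
    templates = _condition_templates(config, layout, group,
                                     amp_shift, contrast_scale)

    n_tr = config.n_trials_per_condition * len(CONDITIONS)
    conds = np.array(CONDITIONS * config.n_trials_per_condition, dtype=object)
    rng.shuffle(conds)
    times = config.times_ms()
    chol = _noise_chol(config, layout)

    data = np.empty((n_tr, layout.n_channels, times.size))
    for i, c in enumerate(conds):
        noise = chol @ rng.normal(0.0, 1.0, size=(layout.n_channels, times.size))
        data[i] = templates[c] + config.noise_sd * noise

    pid = f"{group}{participant_index:02d}"
    return EpochSet(data=data, times=times, sfreq=config.sfreq,
                    ch_names=list(layout.names), condition=conds,
                    participant=pid, group=group)


def simulate_behavior(config: SimConfig, group: str,
                      participant_index: int) -> pd.DataFrame:
    """Simulate one participant's forced-choice responses and RTs.

    Responses are Bernoulli draws of "happy" with the configured
    per-condition probability; reaction times are log-normal with the
    configured mean/SD.  Trials are split into two blocks.
    """
    if group not in GROUPS:
        raise ValueError(f"group must be one of {GROUPS}, got {group!r}")
    rng = _participant_rng(config, group, participant_index, "behavior")
    conds = np.array(CONDITIONS * config.n_trials_per_condition, dtype=object)
    rng.shuffle(conds)
    n = conds.size
    p = np.array([config.behavior_params[c] for c in conds])
    happy = rng.random(n) < p
    mean = np.array([config.rt_params[c][0] for c in conds])
    sd = np.array([config.rt_params[c][1] for c in conds])
    sigma2 = np.log1p(sd ** 2 / mean ** 2)
    mu = np.log(mean) - sigma2 / 2.0
    rt = np.exp(mu + np.sqrt(sigma2) * rng.normal(size=n))
    pid = f"{group}{participant_index:02d}"
    half = n // 2
    return pd.DataFrame({
        "participant": pid,
        "group": group,
        "block": np.where(np.arange(n) < half, 1, 2),
        "trial": np.arange(1, n + 1),
        "condition": conds,
        "response": np.where(happy, "happy", "anger"),
        "rt_ms": rt,
    })


def lpp_roi_contrast(epochs: EpochSet, layout: SensorLayout,
                     window_ms: tuple[float, float] = (430.0, 730.0),
                     roi: str = "right-parietal") -> float:
    """Realized late-positive contrast: mean(HH) - mean(AA), uV.

    Averaged over clean trials, the ROI electrodes and the time window.
    """
    tmask = epochs.time_mask(window_ms)
    ch = [i for i in layout.roi_indices(roi)
          if layout.names[i] not in epochs.bad_channels]
    if not ch:
        raise ValueError("no good ROI channels")
    clean = epochs.clean_mask()
    vals = {}
    for cond in ("HH", "AA"):
        sel = clean & (epochs.condition == cond)
        if not sel.any():
            raise ValueError(f"no clean {cond} trials")
        vals[cond] = epochs.data[np.ix_(np.flatnonzero(sel), ch,
                                        np.flatnonzero(tmask))].mean()
    return float(vals["HH"] - vals["AA"])


@dataclass
class Cohort:
    """Full two-group synthetic study bundle."""

    epochs: dict[str, EpochSet]
    behavior: pd.DataFrame
    severity: pd.DataFrame
    layout: SensorLayout
    manifest: dict

    def participants(self, group: str | None = None) -> list[str]:
        if group is None:
            return list(self.epochs)
        return [p for p, e in self.epochs.items() if e.group == group]


def _severity_scores(config: SimConfig, contrasts: np.ndarray,
                     rng: np.random.Generator) -> np.ndarray:
    eps = rng.normal(size=contrasts.size)
    if config.severity_target_rho is not None:
        rho_s = config.severity_target_rho
        if not -1.0 < rho_s < 1.0:
            raise ValueError("severity_target_rho must lie in (-1, 1)")
        # Bivariate-normal Pearson correlation whose Spearman value is rho_s.
        rho_p = 2.0 * math.sin(math.pi * rho_s / 6.0)
        sd = contrasts.std(ddof=1)
        z = (contrasts - contrasts.mean()) / (sd if sd > 0 else 1.0)
        latent = rho_p * z + math.sqrt(1.0 - rho_p ** 2) * eps
        return config.severity_intercept + config.severity_spread * latent
    return (config.severity_intercept
            - config.severity_link * contrasts
            + config.severity_noise_sd * eps)


def simulate_cohort(config: SimConfig) -> Cohort:
    """Simulate the whole two-group study: EEG, behavior, severity.

    Each pASD parent's severity score is tied to that parent's realized
    LPP ROI contrast (negative correlation by default); the manifest
    records the seed and every generator parameter.
    """
    layout = config.layout()
    epochs: dict[str, EpochSet] = {}
    behavior = []
    contrasts: dict[str, float] = {}
    for group, n in config.n_per_group.items():
        for i in range(n):
            ep = simulate_epochs(config, group, i, layout=layout)
            epochs[ep.participant] = ep
            behavior.append(simulate_behavior(config, group, i))
            contrasts[ep.participant] = lpp_roi_contrast(
                ep, layout, config.lpp_window_ms, config.lpp_roi)

    pasd = [p for p in epochs if epochs[p].group == "pASD"]
    rng = np.random.default_rng(
        np.random.SeedSequence(entropy=config.seed, spawn_key=(99, 0, 2)))
    cvals = np.array([contrasts[p] for p in pasd])
    scores = _severity_scores(config, cvals, rng) if pasd else np.array([])
    severity = pd.DataFrame({
        "participant": pasd,
        "group": "pASD",
        "severity": scores,
        "lpp_contrast": cvals,
    })
    return Cohort(epochs=epochs, behavior=pd.concat(behavior, ignore_index=True)
                  if behavior else pd.DataFrame(),
                  severity=severity, layout=layout,
                  manifest=config.manifest())
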