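"""Spatial-frequency hybrid face stimuli and trial lists.

Hybrid faces combine the low-spatial-frequency (LSF) content of one face
image with the high-spatial-frequency (HSF) content of another rendering
of the same face.  Filtering is done in the Fourier domain with a
radially symmetric Butterworth gain specified in cycles per face width:
LSF content is whatever survives a low-pass at 6 cycles/face, HSF
content whatever survives a high-pass at 24 cycles/face.  At a display
size of 5.30 degrees of horizontal visual angle those cutoffs correspond
to roughly 1 and 4 cycles per degree.

The low-pass amplitude gain is ``|H(f)| = (1 + (f/fc)^(2 n))^(-1/2)``,
i.e. the squared gain is the classic Butterworth ``1/(1+(f/fc)^(2n))``
with half power (amplitude 1/sqrt(2)) exactly at the cutoff.  The
high-pass is defined as the spectral complement ``1 - |H_low|`` so that
low-pass plus high-pass at the same cutoff reconstructs the input
exactly.  The Butterworth order is a free parameter (default 2).

Since the photographic face database the design assumes cannot be
redistributed, :func:`synth_face` draws a deterministic, procedurally
generated face-like image (oval head, eyes, brows, mouth) whose brow
angle and mouth curvature encode the emotion and whose texture gives it
broadband spectral content.  It is a synthetic stand-in, adequate for
exercising the filtering and trial-list machinery.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ImageGrid",
    "radial_butterworth_filter",
    "make_hybrid",
    "synth_face",
    "cycles_per_degree",
    "build_trial_list",
    "LSF_CUTOFF",
    "HSF_CUTOFF",
]

LSF_CUTOFF = 6.0   # cycles/face below which content counts as LSF
HSF_CUTOFF = 24.0  # cycles/face above which content counts as HSF


@dataclass
class ImageGrid:
    """Grayscale image with face-size metadata.

    ``pixels`` are intensities (nominally in [0, 1]); ``face_width_px``
    is the horizontal extent of the face used to convert pixel
    frequencies to cycles per face; ``degrees_per_face`` is the
    displayed visual angle (horizontal, vertical).
    """

    pixels: np.ndarray
    face_width_px: int
    degrees_per_face: tuple[float, float] = (5.30, 6.80)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim == 3:  # desaturate color input: mean of channels
            self.pixels = self.pixels.mean(axis=2)
        if self.pixels.ndim != 2:
            raise ValueError("pixels must be a 2-D grayscale matrix")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("pixel intensities must be finite")
        if self.face_width_px <= 0:
            raise ValueError("face_width_px must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


def cycles_per_degree(cycles_per_face: float, degrees: float = 5.30) -> float:
    """Convert a cutoff in cycles/face to cycles/degree of visual angle."""
    if degrees <= 0:
        raise ValueError("degrees must be positive")
    return cycles_per_face / degrees


def _radial_frequency_cpf(shape: tuple[int, int], face_width_px: int) -> np.ndarray:
    """Radial frequency of every FFT bin, in cycles per face width.

    The horizontal face width sets the unit on both axes, so "cycles per
    face" always means cycles per face *width*.
    """
    fy = np.fft.fftfreq(shape[0])[:, None] * face_width_px
    fx = np.fft.fftfreq(shape[1])[None, :] * face_width_px
    return np.hypot(fy, fx)


def _lowpass_gain(f: np.ndarray, cutoff: float, order: int) -> np.ndarray:
    return 1.0 / np.sqrt(1.0 + (f / cutoff) ** (2 * order))


def radial_butterworth_filter(
    image: ImageGrid, cutoff: float, mode: str = "low", order: int = 2
) -> ImageGrid:
    """Filter an image with a radially symmetric Butterworth gain.

    Parameters
    ----------
    image : ImageGrid
        Input grayscale image.
    cutoff : float
        Cutoff in cycles per face width; must be positive and below the
        Nyquist frequency ``face_width_px / 2``.
    mode : {"low", "high"}
        Low-pass keeps frequencies below the cutoff (amplitude gain
        1/sqrt(2) at the cutoff).  High-pass is the complement
        ``1 - lowpass`` so the two reconstruct the input exactly.
    order : int
        Butterworth order (roll-off steepness), default 2.

    Notes
    -----
    The FFT treats the image as periodic; no padding is applied, so
    complementarity and linearity hold exactly.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    nyquist_cpf = image.face_width_px / 2.0
    if cutoff >= nyquist_cpf:
        raise ValueError(
            f"cutoff {cutoff} cycles/face is at or above Nyquist ({nyquist_cpf})"
        )
    if mode not in ("low", "high"):
        raise ValueError("mode must be 'low' or 'high'")
    if order < 1:
        raise ValueError("order must be >= 1")

    f = _radial_frequency_cpf(image.shape, image.face_width_px)
    gain = _lowpass_gain(f, cutoff, order)
    if mode == "high":
        gain = 1.0 - gain
    out = np.fft.ifft2(np.fft.fft2(image.pixels) * gain).real
    return ImageGrid(out, image.face_width_px, image.degrees_per_face)


def make_hybrid(
    lsf_source: ImageGrid,
    hsf_source: ImageGrid,
    lsf_cutoff: float = LSF_CUTOFF,
    hsf_cutoff: float = HSF_CUTOFF,
    order: int = 2,
    rescale: bool = False,
) -> ImageGrid:
    """Combine the LSF content of one image with the HSF content of another.

    ``hybrid = lowpass(lsf_source, 6 c/f) + highpass(hsf_source, 24 c/f)``.
    With ``rescale=True`` the output is linearly mapped back to [0, 1]
    for display; the default leaves the sum untouched so that algebraic
    identities (e.g. an all-zero HSF source leaving the LSF image alone)
    hold exactly.
    """
    if lsf_source.shape != hsf_source.shape:
        raise ValueError("source images must share dimensions")
    if lsf_source.face_width_px != hsf_source.face_width_px:
        raise ValueError("source images must share face_width_px")
    low = radial_butterworth_filter(lsf_source, lsf_cutoff, "low", order)
    high = radial_butterworth_filter(hsf_source, hsf_cutoff, "high", order)
    out = low.pixels + high.pixels
    if rescale:
        lo, hi = out.min(), out.max()
        if hi > lo:
            out = (out - lo) / (hi - lo)
    return ImageGrid(out, lsf_source.face_width_px, lsf_source.degrees_per_face)


# ---------------------------------------------------------------------
# Procedural face drawing (synthetic stand-in for face photographs)
# ---------------------------------------------------------------------

def synth_face(
    identity_seed: int, emotion: str, size: int = 256, face_width_px: int | None = None
) -> ImageGrid:
    """Draw a deterministic face-like image for a given identity and emotion.

    The face is an oval with eyes, pupils, brows and a mouth drawn as
    smooth intensity bumps on a textured background.  ``emotion``
    ("happy" or "anger") controls mouth curvature (up vs down) and brow
    angle (level vs knitted); ``identity_seed`` jitters feature geometry
    and the texture, so different seeds give different broadband images.
    """
    if emotion not in ("happy", "anger"):
        raise ValueError("emotion must be 'happy' or 'anger'")
    if face_width_px is None:
        face_width_px = int(size * 0.7)
    # geometry jitter and texture depend on identity only, so the two
    # emotions of one identity differ solely in brow tilt and mouth curve
    rng = np.random.default_rng(int(identity_seed))

    yy, xx = np.mgrid[0:size, 0:size].astype(float)
    cx = cy = size / 2
    u = (xx - cx) / (face_width_px / 2)          # +/-1 across the face width
    v = (yy - cy) / (face_width_px / 2 * 1.28)   # face is taller than wide

    jit = rng.normal(0, 0.02, size=8)
    img = np.full((size, size), 0.55)

    # head oval
    head = u ** 2 + v ** 2
    img += 0.35 * np.exp(-np.maximum(head - 1.0, 0.0) * 40) - 0.35
    img += 0.35 * (head < 1.0)

    def bump(ucen, vcen, su, sv, amp):
        return amp * np.exp(-(((u - ucen) / su) ** 2 + ((v - vcen) / sv) ** 2))

    eye_dx = 0.38 + jit[0]
    eye_y = -0.25 + jit[1]
    for s in (-1, 1):
        img += bump(s * eye_dx, eye_y, 0.16, 0.09, -0.35)        # eye whites' shadow
        img += bump(s * eye_dx + jit[2], eye_y, 0.05, 0.05, -0.3)  # pupil

    # brows: for anger the inner ends dip toward the nose
    brow_y = -0.43 + jit[3]
    brow_tilt = 0.16 if emotion == "anger" else 0.02
    for s in (-1, 1):
        along = np.clip((u - s * eye_dx) * s / 0.22, -1, 1)
        center_v = brow_y + brow_tilt * (-along)
        img += bump(s * eye_dx, 0, 0.2, 1e9, 0) + (
            -0.30 * np.exp(-(((u - s * eye_dx) / 0.20) ** 2
                            + ((v - center_v) / 0.045) ** 2))
        )

    # nose
    img += bump(0.0 + jit[4], 0.08, 0.06, 0.18, -0.12)

    # mouth: parabola opening up (happy) or down (anger)
    curve = -0.22 if emotion == "happy" else 0.18
    mouth_y = 0.48 + jit[5]
    mouth_v = mouth_y + curve * (u / 0.4) ** 2
    mouth = -0.4 * np.exp(-((u / 0.34) ** 2 + ((v - mouth_v) / 0.05) ** 2))
    img += mouth

    # broadband texture so both LSF and HSF bands carry energy
    img += rng.normal(0, 0.02, size=(size, size))
    img = np.clip(img, 0.0, 1.0)
    return ImageGrid(img, face_width_px)


def band_energy(image: ImageGrid, f_lo: float, f_hi: float) -> float:
    """Spectral energy (sum |FFT|^2, DC excluded) in [f_lo, f_hi) cycles/face."""
    f = _radial_frequency_cpf(image.shape, image.face_width_px)
    spec = np.abs(np.fft.fft2(image.pixels)) ** 2
    mask = (f >= f_lo) & (f < f_hi) & (f > 0)
    return float(spec[mask].sum())


# ---------------------------------------------------------------------
# Trial lists
# ---------------------------------------------------------------------

def build_trial_list(
    n_identities: int = 29, n_blocks: int = 2, seed: int = 0
) -> pd.DataFrame:
    """Build the forced-choice trial list.

    Each identity appears in all four hybrid conditions (AA, HH, AH,
    HA), giving ``4 * n_identities`` distinct stimuli (116 for the
    default 29 identities).  Every stimulus is shown once per block in
    random order, so two blocks yield 232 trials and each stimulus is
    seen twice over the session.  The response-hand mapping alternates
    between blocks (counterbalancing which hand signals "happy").
    """
    if n_identities < 1 or n_blocks < 1:
        raise ValueError("n_identities and n_blocks must be positive")
    rng = np.random.default_rng(seed)
    conditions = ["AA", "HH", "AH", "HA"]
    stimuli = [(ident, cond) for ident in range(n_identities) for cond in conditions]
    rows = []
    for block in range(1, n_blocks + 1):
        order = rng.permutation(len(stimuli))
        hand = "left-happy" if block % 2 == 1 else "right-happy"
        for t, s in enumerate(order, start=1):
            ident, cond = stimuli[s]
            rows.append(
                dict(block=block, trial=t, identity=ident, condition=cond,
                     happy_hand=hand)
            )
    return pd.DataFrame(rows)
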