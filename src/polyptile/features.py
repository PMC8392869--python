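"""Tile feature extraction: the 99 fuzzy-rule antecedents.

A tile is summarised by 99 numbers per colour representation:

* indices 1-6   -- mean and (population) standard deviation of each channel,
* indices 7-9   -- Canny edge density of each channel,
* indices 10-15 -- structural entropy ``Sstr`` and log spatial filling factor
                   ``lnq`` of each channel,
* indices 16-75 -- the same fifteen quantities on the four one-level wavelet
                   sub-bands LL, LH, HL, HH (15 each),
* indices 76-99 -- mean and standard deviation of the Sobel gradient
                   magnitude, direction, x component and y component of each
                   channel.

The entropy descriptors come from the generalized Renyi entropies of the
tile viewed as a 2D probability distribution: with ``p_i = I_i / sum_j I_j``
the order-``n`` entropy is ``S_n = ln(sum_i p_i^n) / (1 - n)`` (natural
logarithm; ``S_1`` is the Shannon limit).  Two shape descriptors follow:

* structural entropy     ``Sstr = S1 - S2 >= 0``
* log spatial filling    ``lnq  = S2 - S0 <= 0``

``Sstr`` measures how far the distribution is from uniform-over-its-support
(sensitive to localisation shape, e.g. a hemispherical polyp blob), while
``q = exp(S2 - S0)`` is the effective fraction of the support the
distribution fills.  Both are invariant to rescaling the intensities, which
makes them robust against illumination changes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import pywt
from scipy import ndimage
from skimage import feature as skfeature

from .imaging import Tile

__all__ = [
    "SOBEL_X", "SOBEL_Y", "ANTECEDENT_NAMES",
    "RenyiDescriptors", "WaveletSubbands", "AntecedentVector",
    "normalized_intensity", "renyi_entropy", "structural_descriptors",
    "channel_stats", "gradient_features", "edge_density", "dwt2",
    "extract_antecedents", "features_to_frame",
]

# Sobel derivative kernels; x increases to the right (columns), y downward
# (rows).  Applied by correlation so a positive x-slope gives positive gx.
SOBEL_X = np.array([[-1, 0, 1], [-2, 0, 2], [-1, 0, 1]], dtype=float)
SOBEL_Y = np.array([[-1, -2, -1], [0, 0, 0], [1, 2, 1]], dtype=float)


# --------------------------------------------------------------------------
# Renyi entropy descriptors
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class RenyiDescriptors:
    """The entropy triple and the two shape descriptors, all in nats."""

    S0: float
    S1: float
    S2: float
    Sstr: float
    logq: float
    valid: bool = True


def normalized_intensity(channel: np.ndarray) -> np.ndarray:
    """Flatten a nonnegative intensity field into a probability vector.

    Returns the empty vector for an all-zero field (degenerate tile).
    """
    arr = np.asarray(channel, dtype=float).ravel()
    if arr.size == 0:
        raise ValueError("empty intensity field")
    if arr.min() < 0:
        raise ValueError(
            "negative intensities: take magnitudes before normalising"
        )
    total = arr.sum()
    if total == 0:
        return np.zeros(0)
    return arr / total


def renyi_entropy(p: np.ndarray, n: float) -> float:
    """Order-``n`` generalized Renyi entropy of a probability vector, in nats.

    ``S_n = ln(sum p_i^n) / (1 - n)`` with the sum restricted to strictly
    positive ``p_i`` (this resolves the 0^0 ambiguity at ``n = 0``, where the
    entropy is the log of the support size).  ``n = 1`` returns the Shannon
    entropy ``-sum p_i ln p_i``.
    """
    if n < 0:
        raise ValueError("entropy order must be nonnegative")
    p = np.asarray(p, dtype=float)
    p = p[p > 0]
    if p.size == 0:
        raise ValueError("probability vector has no positive mass")
    if not np.isclose(p.sum(), 1.0, atol=1e-9):
        raise ValueError("probabilities must sum to 1")
    if n == 1:
        return float(-(p * np.log(p)).sum())
    return float(np.log((p ** n).sum()) / (1.0 - n))


def structural_descriptors(channel: np.ndarray) -> RenyiDescriptors:
    """Structural entropy and log filling factor of an intensity field.

    The field is normalised to a probability distribution first, so the
    descriptors are invariant under ``channel -> c * channel`` for any c > 0.
    An all-zero field yields zero descriptors flagged invalid rather than an
    error, so pipelines on dark tiles do not abort.
    """
    p = normalized_intensity(channel)
    if p.size == 0:
        return RenyiDescriptors(0.0, 0.0, 0.0, 0.0, 0.0, valid=False)
    pos = p[p > 0]
    if pos.max() == pos.min():
        # exactly uniform over its support: every order gives log(N), so
        # both descriptors are identically zero (no rounding residue)
        s = float(np.log(pos.size))
        return RenyiDescriptors(S0=s, S1=s, S2=s, Sstr=0.0, logq=0.0)
    s0 = renyi_entropy(p, 0)
    s1 = renyi_entropy(p, 1)
    s2 = renyi_entropy(p, 2)
    return RenyiDescriptors(S0=s0, S1=s1, S2=s2, Sstr=s1 - s2, logq=s2 - s0)


# --------------------------------------------------------------------------
# Channel statistics, gradients, edges
# --------------------------------------------------------------------------

def channel_stats(channel: np.ndarray) -> tuple:
    """Arithmetic mean and population standard deviation of a channel."""
    arr = np.asarray(channel, dtype=float)
    if arr.size == 0:
        raise ValueError("empty channel")
    return float(arr.mean()), float(arr.std())


def sobel_gradients(channel: np.ndarray) -> tuple:
    """Sobel x / y derivative images (correlation, reflect-padded borders)."""
    arr = np.asarray(channel, dtype=float)
    if arr.shape[0] < 3 or arr.shape[1] < 3:
        raise ValueError("channel must be at least 3 x 3 for Sobel gradients")
    gx = ndimage.correlate(arr, SOBEL_X, mode="reflect")
    gy = ndimage.correlate(arr, SOBEL_Y, mode="reflect")
    return gx, gy


def gradient_features(channel: np.ndarray) -> np.ndarray:
    """Eight gradient statistics of a channel.

    Order: magnitude mean, magnitude std, direction mean, direction std,
    x-component mean, x-component std, y-component mean, y-component std.
    Direction is ``atan2(gy, gx)`` in (-pi, pi], treated as a linear variable
    (atan2(0, 0) = 0 covers flat tiles).
    """
    gx, gy = sobel_gradients(channel)
    mag = np.hypot(gx, gy)
    direction = np.arctan2(gy, gx)
    direction[mag < 1e-12] = 0.0  # flat pixels have no direction
    return np.array([
        mag.mean(), mag.std(),
        direction.mean(), direction.std(),
        gx.mean(), gx.std(),
        gy.mean(), gy.std(),
    ])


def edge_density(channel: np.ndarray, low: float = 0.1, high: float = 0.2,
                 sigma: float = 1.0, method: str = "canny") -> float:
    """Fraction of tile pixels that lie on detected edges, in [0, 1].

    ``low`` and ``high`` are hysteresis thresholds expressed as fractions of
    the maximum smoothed Sobel gradient magnitude; ``sigma`` is the Gaussian
    smoothing scale of the Canny detector.  ``method='sobel'`` skips the
    non-maximum suppression / hysteresis machinery and simply thresholds the
    raw Sobel magnitude at ``high`` of its maximum.
    """
    if not (0 <= low < high <= 1):
        raise ValueError("need 0 <= low < high <= 1")
    arr = np.asarray(channel, dtype=float)
    if np.ptp(arr) == 0:
        return 0.0
    if method == "sobel":
        gx, gy = sobel_gradients(arr)
        mag = np.hypot(gx, gy)
        return float((mag >= high * mag.max()).sum()) / arr.size
    if method != "canny":
        raise ValueError(f"unknown edge method {method!r}")
    # scikit-image's canny takes absolute thresholds for float input, so
    # scale the fractions by the max magnitude of the smoothed gradient it
    # will see internally.
    smoothed = ndimage.gaussian_filter(arr, sigma, mode="reflect")
    mag = np.hypot(ndimage.sobel(smoothed, axis=1, mode="reflect"),
                   ndimage.sobel(smoothed, axis=0, mode="reflect"))
    mmax = mag.max()
    if mmax == 0:
        return 0.0
    edges = skfeature.canny(arr, sigma=sigma,
                            low_threshold=low * mmax,
                            high_threshold=high * mmax)
    return float(edges.sum()) / arr.size


# --------------------------------------------------------------------------
# Wavelet sub-bands
# --------------------------------------------------------------------------

@dataclass
class WaveletSubbands:
    """One decomposition level of a separable 2D discrete wavelet transform.

    LL is the two-way low-pass (smoothed) image; LH / HL mix low and high
    pass across the two axes and light up at horizontal / vertical intensity
    changes; HH responds where variation is rapid in both directions.  Each
    sub-band has ceil(T/2) x ceil(T/2) coefficients (periodized boundary).
    """

    LL: np.ndarray
    LH: np.ndarray
    HL: np.ndarray
    HH: np.ndarray
    wavelet_name: str = "haar"

    @property
    def filter_length(self) -> int:
        return pywt.Wavelet(self.wavelet_name).dec_len

    def inverse(self) -> np.ndarray:
        """Reconstruct the input tile (exact for orthonormal filters)."""
        return pywt.idwt2((self.LL, (self.LH, self.HL, self.HH)),
                          self.wavelet_name, mode="periodization")

    def as_dict(self) -> dict:
        return {"LL": self.LL, "LH": self.LH, "HL": self.HL, "HH": self.HH}


def dwt2(channel: np.ndarray, wavelet_name: str = "haar") -> WaveletSubbands:
    """One-level separable 2D DWT with dyadic downsampling.

    Periodization boundary mode keeps every sub-band at exactly half the
    (even) tile side and preserves the signal energy for orthonormal
    wavelets such as Haar.
    """
    arr = np.asarray(channel, dtype=float)
    try:
        wavelet = pywt.Wavelet(wavelet_name)
    except ValueError as exc:
        raise ValueError(f"unknown wavelet {wavelet_name!r}") from exc
    if min(arr.shape) < wavelet.dec_len:
        raise ValueError(
            f"tile side {min(arr.shape)} shorter than the "
            f"{wavelet.dec_len}-tap {wavelet_name} filter"
        )
    ll, (lh, hl, hh) = pywt.dwt2(arr, wavelet, mode="periodization")
    return WaveletSubbands(LL=ll, LH=lh, HL=hl, HH=hh,
                           wavelet_name=wavelet_name)


# --------------------------------------------------------------------------
# The 99-antecedent vector
# --------------------------------------------------------------------------

def _antecedent_names() -> list:
    chans = ["ch1", "ch2", "ch3"]
    names = []

    def block15(prefix):
        out = []
        for c in chans:
            out += [f"{prefix}mean_{c}", f"{prefix}std_{c}"]
        for c in chans:
            out.append(f"{prefix}edge_density_{c}")
        for c in chans:
            out += [f"{prefix}Sstr_{c}", f"{prefix}lnq_{c}"]
        return out

    names += block15("")
    for band in ("LL", "LH", "HL", "HH"):
        names += block15(f"{band}_")
    for quantity in ("grad_mag", "grad_dir", "grad_x", "grad_y"):
        for c in chans:
            names += [f"{quantity}_mean_{c}", f"{quantity}_std_{c}"]
    return names


#: Column names for the 99 antecedents, in canonical index order (1-based
#: index i corresponds to ANTECEDENT_NAMES[i-1]).
ANTECEDENT_NAMES = _antecedent_names()
assert len(ANTECEDENT_NAMES) == 99

#: 1-based indices of the Sstr / lnq antecedents (raw tile and all four
#: sub-bands): the entropy-only antecedent preset.
ENTROPY_INDICES = tuple(
    i for i, name in enumerate(ANTECEDENT_NAMES, start=1)
    if "Sstr" in name or "lnq" in name
)
assert ENTROPY_INDICES == tuple(
    list(range(10, 16)) + list(range(25, 31)) + list(range(40, 46))
    + list(range(55, 61)) + list(range(70, 76))
)

#: 1-based indices of the 24 gradient antecedents.
GRADIENT_INDICES = tuple(range(76, 100))


@dataclass
class FeatureConfig:
    """Knobs of the antecedent extractor."""

    wavelet: str = "haar"
    canny_sigma: float = 1.0
    canny_low: float = 0.1
    canny_high: float = 0.2
    edge_method: str = "canny"


@dataclass
class AntecedentVector:
    """The 99 antecedent values of one tile, in canonical order."""

    values: np.ndarray
    valid_mask: np.ndarray
    source_id: str = ""
    origin: tuple = (0, 0)
    label: str = "unlabeled"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
        if self.values.shape != (99,) or self.valid_mask.shape != (99,):
            raise ValueError("an antecedent vector has exactly 99 entries")

    def __len__(self) -> int:
        return 99

    def __getitem__(self, index1: int) -> float:
        """Value of the 1-based antecedent ``index1``."""
        if not 1 <= index1 <= 99:
            raise IndexError("antecedent indices run from 1 to 99")
        return float(self.values[index1 - 1])


def _fifteen(channels: Sequence[np.ndarray], cfg: FeatureConfig,
             magnitude: bool = False) -> tuple:
    """mean/std (6), edge density (3), Sstr/lnq (6) for three channels.

    ``magnitude=True`` rectifies signed wavelet detail coefficients before
    every statistic, since the probability normalisation behind the entropy
    descriptors needs nonnegative intensities and the physically meaningful
    quantity on a detail band is the size of the local variation.
    """
    values = np.empty(15)
    valid = np.ones(15, dtype=bool)
    chans = [np.abs(ch) if magnitude else np.asarray(ch, float)
             for ch in channels]
    for k, ch in enumerate(chans):
        values[2 * k], values[2 * k + 1] = channel_stats(ch)
    for k, ch in enumerate(chans):
        values[6 + k] = edge_density(
            ch, low=cfg.canny_low, high=cfg.canny_high,
            sigma=cfg.canny_sigma, method=cfg.edge_method)
    for k, ch in enumerate(chans):
        desc = structural_descriptors(ch)
        values[9 + 2 * k] = desc.Sstr
        values[9 + 2 * k + 1] = desc.logq
        valid[9 + 2 * k] = valid[9 + 2 * k + 1] = desc.valid
    return values, valid


def extract_antecedents(tile: Tile, config: Optional[FeatureConfig] = None
                        ) -> AntecedentVector:
    """Compute the full 99-entry antecedent vector of a tile.

    Indices 1-15 are evaluated on the raw channels, 16-75 repeat them on the
    LL / LH / HL / HH sub-bands (detail-band statistics use absolute
    coefficients), 76-99 are the Sobel gradient statistics of the raw
    channels.
    """
    cfg = config or FeatureConfig()
    px = np.asarray(tile.pixels, dtype=float)
    if px.ndim != 3 or px.shape[2] != 3:
        raise ValueError("tile must carry three colour channels")
    channels = [px[:, :, k] for k in range(3)]

    values = np.empty(99)
    valid = np.ones(99, dtype=bool)
    values[0:15], valid[0:15] = _fifteen(channels, cfg)

    subbands = [dwt2(ch, cfg.wavelet) for ch in channels]
    for b, band in enumerate(("LL", "LH", "HL", "HH")):
        lo = 15 + 15 * b
        band_channels = [sb.as_dict()[band] for sb in subbands]
        values[lo:lo + 15], valid[lo:lo + 15] = _fifteen(
            band_channels, cfg, magnitude=(band != "LL"))

    grads = np.array([gradient_features(ch) for ch in channels])  # 3 x 8
    # reorder to: per-quantity, per-channel (mean, std)
    for q in range(4):
        for c in range(3):
            values[75 + 6 * q + 2 * c] = grads[c, 2 * q]
            values[75 + 6 * q + 2 * c + 1] = grads[c, 2 * q + 1]

    return AntecedentVector(
        values=values, valid_mask=valid, source_id=tile.source_id,
        origin=tile.origin, label=tile.label.value,
    )


def features_to_frame(vectors: Sequence[AntecedentVector]) -> pd.DataFrame:
    """Feature matrix with provenance columns; one row per tile."""
    recs = []
    for v in vectors:
        row = {
            "source_id": v.source_id,
            "origin_row": v.origin[0],
            "origin_col": v.origin[1],
            "label": v.label,
        }
        row.update({name: v.values[i]
                    for i, name in enumerate(ANTECEDENT_NAMES)})
        recs.append(row)
    return pd.DataFrame(recs)
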