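"""Attention-based interpretation of a trained classifier.

Two linear read-outs turn the squeeze-and-excitation gate values into
physiologically readable summaries:

* the **weighted spatial map** — the attention-weighted sum of the absolute
  depthwise spatial kernels, max-normalized, read as a per-electrode
  importance map;
* the **weighted spectral profile** — the attention-weighted sum of the
  sinc kernels (each spatial filter contributing its parent band-pass
  kernel), max-normalized, whose Fourier magnitude shows the model's
  frequency emphasis.

Filters are also ranked by average attention and assigned to frequency
blocks (Low < 15 Hz, Mid 15–35 Hz, High > 35 Hz) by passband overlap; a
filter whose band spans a boundary belongs to every block it overlaps.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import SincEEGNet, SincFilterBank

logger = logging.getLogger(__name__)

__all__ = ["average_attention", "TopographicMap", "SpectralProfile",
           "weighted_spatial_map", "weighted_spectral_profile",
           "sort_filters", "FrequencyBlocks", "block_membership",
           "block_maps", "difference_map", "spatial_filter_matrix"]


def average_attention(attention: np.ndarray) -> np.ndarray:
    """Mean attention vector over trials (Algorithm: A_ave = (1/n) Σ A_i)."""
    attention = np.asarray(attention, dtype=np.float64)
    if attention.ndim != 2 or attention.shape[0] == 0:
        raise ValueError("attention must be (n_trials, n_filters) with "
                         "at least one trial")
    return attention.mean(axis=0)


@dataclass
class TopographicMap:
    """Per-channel weights aligned to channel labels; max-normalized."""

    weights: np.ndarray
    channel_labels: list[str] = field(default_factory=list)
    normalized: bool = True

    def to_frame(self) -> pd.DataFrame:
        labels = (self.channel_labels or
                  [str(i) for i in range(len(self.weights))])
        return pd.DataFrame({"channel": labels, "weight": self.weights})


@dataclass
class SpectralProfile:
    freqs_hz: np.ndarray
    magnitude: np.ndarray
    rate_hz: float
    degenerate: bool = False

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"freq_hz": self.freqs_hz,
                             "magnitude": self.magnitude})

    def centroid_hz(self) -> float:
        total = self.magnitude.sum()
        if total == 0:
            return float("nan")
        return float((self.freqs_hz * self.magnitude).sum() / total)


def spatial_filter_matrix(model: SincEEGNet) -> np.ndarray:
    """Depthwise spatial kernels as (n_maps × n_channels); map k has
    parent sinc filter k // multiplier."""
    F, M, C = model.spatial.data.shape
    return model.spatial.data.reshape(F * M, C).copy()


def parent_index(k: int | np.ndarray, multiplier: int) -> np.ndarray:
    return np.asarray(k) // multiplier


def weighted_spatial_map(filters: np.ndarray, a_ave: np.ndarray,
                         channel_labels: list[str] | None = None
                         ) -> TopographicMap:
    """F_WS = Σ_j a_ave[j]·|F_j|, divided by its maximum."""
    filters = np.asarray(filters, dtype=np.float64)
    a_ave = np.asarray(a_ave, dtype=np.float64)
    if filters.shape[0] != a_ave.shape[0]:
        raise ValueError(f"{filters.shape[0]} filters but "
                         f"{a_ave.shape[0]} attention values")
    fws = (a_ave[:, None] * np.abs(filters)).sum(axis=0)
    peak = fws.max()
    if peak == 0:
        raise ValueError("all-zero weighted map (degenerate filters)")
    return TopographicMap(weights=fws / peak,
                          channel_labels=list(channel_labels or []))


def weighted_spectral_profile(bank: SincFilterBank, a_ave: np.ndarray,
                              multiplier: int = 2,
                              n_fft: int = 1024) -> SpectralProfile:
    """Attention-weighted sum of sinc kernels, max-normalized, then FFT.

    Spatial filter j contributes its parent band-pass kernel
    (parent = j // multiplier); normalization precedes the transform.
    """
    kernels = bank.kernels().data
    a_ave = np.asarray(a_ave, dtype=np.float64)
    parents = parent_index(np.arange(len(a_ave)), multiplier)
    if parents.max() >= kernels.shape[0]:
        raise ValueError("attention vector longer than filter bank allows")
    ws = (a_ave[:, None] * kernels[parents]).sum(axis=0)
    peak = np.abs(ws).max()
    degenerate = peak == 0
    if not degenerate:
        ws = ws / ws.max() if ws.max() != 0 else ws / peak
    mag = np.abs(np.fft.rfft(ws, n_fft))
    freqs = np.fft.rfftfreq(n_fft, d=1.0 / bank.rate_hz)
    if degenerate:
        logger.warning("all-zero weighted sinc sum; spectrum is zero")
    return SpectralProfile(freqs_hz=freqs, magnitude=mag,
                           rate_hz=bank.rate_hz, degenerate=degenerate)


def sort_filters(a_ave: np.ndarray, bank: SincFilterBank,
                 multiplier: int = 2) -> pd.DataFrame:
    """Rank spatial filters by average attention (descending; ties broken
    by ascending index).  Each row carries the parent band-pass filter's
    (f1, f2) and center frequency (f1+f2)/2."""
    a_ave = np.asarray(a_ave, dtype=np.float64)
    order = np.lexsort((np.arange(len(a_ave)), -a_ave))
    f1, f2 = bank.cutoffs()
    parents = parent_index(order, multiplier)
    return pd.DataFrame({
        "rank": np.arange(1, len(a_ave) + 1),
        "filter_index": order,
        "parent_sinc": parents,
        "f1_hz": f1[parents],
        "f2_hz": f2[parents],
        "center_hz": (f1[parents] + f2[parents]) / 2.0,
        "attention": a_ave[order],
    })


@dataclass
class FrequencyBlocks:
    """Frequency blocks: Low < ``low_hz``, Mid in between, High > ``high_hz``."""

    low_hz: float = 15.0
    high_hz: float = 35.0

    def intervals(self) -> dict[str, tuple[float, float]]:
        return {"low": (0.0, self.low_hz),
                "mid": (self.low_hz, self.high_hz),
                "high": (self.high_hz, np.inf)}


def block_membership(bank: SincFilterBank, multiplier: int = 2,
                     blocks: FrequencyBlocks = FrequencyBlocks()
                     ) -> dict[str, np.ndarray]:
    """Spatial-filter indices whose parent passband overlaps each block.

    A filter spanning a boundary appears in every block it overlaps.
    """
    f1, f2 = bank.cutoffs()
    out: dict[str, np.ndarray] = {}
    n_maps = bank.n_filters * multiplier
    parents = parent_index(np.arange(n_maps), multiplier)
    for name, (lo, hi) in blocks.intervals().items():
        overlap = (f1[parents] < hi) & (f2[parents] > lo)
        out[name] = np.flatnonzero(overlap)
    return out


def block_maps(filters: np.ndarray, bank: SincFilterBank,
               a_ave: np.ndarray, multiplier: int = 2,
               blocks: FrequencyBlocks = FrequencyBlocks(),
               channel_labels: list[str] | None = None,
               membership: dict[str, np.ndarray] | None = None
               ) -> dict[str, TopographicMap]:
    """Per-block weighted spatial maps, each max-normalized.

    ``membership`` may be supplied explicitly (e.g., a hand-picked filter
    list); by default it is computed from passband overlap.
    """
    if membership is None:
        membership = block_membership(bank, multiplier, blocks)
    maps: dict[str, TopographicMap] = {}
    for name, idx in membership.items():
        if len(idx) == 0:
            logger.warning("frequency block %r has no member filters", name)
            maps[name] = TopographicMap(
                weights=np.zeros(filters.shape[1]),
                channel_labels=list(channel_labels or []),
                normalized=False)
            continue
        maps[name] = weighted_spatial_map(filters[idx], a_ave[idx],
                                          channel_labels)
    return maps


def difference_map(a: TopographicMap, b: TopographicMap) -> TopographicMap:
    """Element-wise a − b, computed before any renormalization."""
    if len(a.weights) != len(b.weights):
        raise ValueError("maps have different channel counts")
    return TopographicMap(weights=a.weights - b.weights,
                          channel_labels=list(a.channel_labels),
                          normalized=False)
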