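"""Triple-colocalization quantification for multi-channel fluorescence images.

Pipeline per channel: local 2-D median denoising, then Phansalkar local
adaptive thresholding (designed for low-contrast fluorescence). On the binary
masks and denoised intensities it computes the Manders split coefficients

    M1 = sum_i S1_i,coloc / sum_i S1_i        (S1_i,coloc = S1_i where both
    M2 = sum_j S2_j,coloc / sum_j S2_j         masked signals are positive)

and the contact fraction: the proportion of the ER ∧ mitochondria mask
intersection that also overlaps the third channel's mask, reported in
percent. Images are 2-D; z-stacks are handled slice-wise by the CLI with a
pooled summary.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy import ndimage


@dataclass(frozen=True)
class ColocParams:
    """Segmentation parameters.

    median_size: odd neighborhood (pixels) of the 2-D median filter.
    window_radius: half-width of the square window used for the local mean
        and standard deviation of the Phansalkar threshold.
    k_ph, r_ph, p_ph, q_ph: Phansalkar coefficients; defaults are the original
        publication's values for intensities normalized to [0, 1].
    """

    median_size: int = 3
    window_radius: int = 15
    k_ph: float = 0.25
    r_ph: float = 0.5
    p_ph: float = 2.0
    q_ph: float = 10.0

    def __post_init__(self) -> None:
        if self.median_size < 1 or self.median_size % 2 == 0:
            raise ValueError("median_size must be odd and >= 1")
        if self.window_radius < 1:
            raise ValueError("window_radius must be >= 1")


@dataclass
class ChannelStack:
    """Named, equally-shaped 2-D channels with intensities in [0, 1]."""

    channels: dict[str, np.ndarray]
    pixel_size_um: float | None = None

    def __post_init__(self) -> None:
        if len(self.channels) < 2:
            raise ValueError("a stack needs at least 2 channels")
        shapes = {ch.shape for ch in self.channels.values()}
        if len(shapes) != 1:
            raise ValueError("all channels must share one shape")
        for name, ch in self.channels.items():
            if ch.ndim != 2:
                raise ValueError(f"channel {name!r} is not 2-D")
            if not np.all(np.isfinite(ch)):
                raise ValueError(f"channel {name!r} has non-finite intensities")
            if ch.min() < 0 or ch.max() > 1:
                raise ValueError(f"channel {name!r} intensities outside [0, 1]")

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.channels.values())).shape

    @property
    def names(self) -> list[str]:
        return list(self.channels)

    def to_tiff(self, path: str | Path) -> None:
        """Write channels as a multi-page float32 TIFF in name order."""
        import tifffile

        data = np.stack([self.channels[n] for n in self.names]).astype(np.float32)
        tifffile.imwrite(
            path,
            data,
            photometric="minisblack",
            metadata={"channels": self.names},
        )


def read_stack(path: str | Path, channel_map: Mapping[str, int]) -> ChannelStack:
    """Read a multi-channel/multi-page TIFF and rescale each channel to [0, 1].

    ``channel_map`` names each plane index. Rescaling is per-channel min-max;
    a constant channel is left at zero.
    """
    import tifffile

    data = np.asarray(tifffile.imread(path), dtype=float)
    if data.ndim == 2:
        data = data[np.newaxis]
    if data.ndim != 3:
        raise ValueError(f"expected a 2-D or 3-D TIFF, got shape {data.shape}")
    channels: dict[str, np.ndarray] = {}
    for name, idx in channel_map.items():
        if not 0 <= idx < data.shape[0]:
            raise ValueError(
                f"channel map entry {name!r} -> {idx} outside {data.shape[0]} planes"
            )
        plane = data[idx]
        lo, hi = float(plane.min()), float(plane.max())
        channels[name] = (plane - lo) / (hi - lo) if hi > lo else np.zeros_like(plane)
    return ChannelStack(channels=channels)


def median_denoise(channel: np.ndarray, neighborhood: int) -> np.ndarray:
    """Local 2-D median filter with reflective edge handling."""
    if neighborhood < 1 or neighborhood % 2 == 0:
        raise ValueError("median neighborhood must be odd and >= 1")
    if neighborhood == 1:
        return np.asarray(channel, dtype=float).copy()
    return ndimage.median_filter(
        np.asarray(channel, dtype=float), size=neighborhood, mode="reflect"
    )


def _local_mean_std(img: np.ndarray, radius: int) -> tuple[np.ndarray, np.ndarray]:
    """Windowed mean and population std over (2r+1)^2 squares, reflect-padded."""
    size = 2 * radius + 1
    mean = ndimage.uniform_filter(img, size=size, mode="reflect")
    mean_sq = ndimage.uniform_filter(img * img, size=size, mode="reflect")
    var = np.maximum(mean_sq - mean * mean, 0.0)
    return mean, np.sqrt(var)


def phansalkar_surface(
    channel: np.ndarray, params: ColocParams = ColocParams()
) -> np.ndarray:
    """Per-pixel Phansalkar threshold t = m (1 + p exp(-q m) + k (s/r - 1)).

    m and s are the local windowed mean and (population) standard deviation;
    reflection at the borders duplicates the edge pixel.
    """
    img = np.asarray(channel, dtype=float)
    if img.ndim != 2:
        raise ValueError("expected a 2-D channel")
    if params.window_radius > min(img.shape) // 2:
        raise ValueError("window radius exceeds half the image extent")
    m, s = _local_mean_std(img, params.window_radius)
    return m * (
        1.0
        + params.p_ph * np.exp(-params.q_ph * m)
        + params.k_ph * (s / params.r_ph - 1.0)
    )


def phansalkar_threshold(
    channel: np.ndarray, params: ColocParams = ColocParams()
) -> np.ndarray:
    """Phansalkar local adaptive binarization.

    A pixel is foreground iff its intensity strictly exceeds the local
    threshold of :func:`phansalkar_surface` (so an all-zero image yields an
    empty mask).
    """
    img = np.asarray(channel, dtype=float)
    return img > phansalkar_surface(img, params)


def manders_split(
    s1: np.ndarray,
    s2: np.ndarray,
    mask1: np.ndarray,
    mask2: np.ndarray,
) -> tuple[float, float]:
    """Manders split coefficients on masked intensities.

    Intensities outside a channel's mask count as zero. M1 is the fraction of
    channel-1 signal (summed over pixels where masked channel 1 is positive)
    that lies where masked channel 2 is also positive; M2 symmetrically.
    Returns NaN for a coefficient whose denominator is zero (undefined, not
    an error).
    """
    if not (s1.shape == s2.shape == mask1.shape == mask2.shape):
        raise ValueError("all channels and masks must share one shape")
    m1v = np.where(mask1, s1, 0.0)
    m2v = np.where(mask2, s2, 0.0)
    pos1 = m1v > 0
    pos2 = m2v > 0
    both = pos1 & pos2
    d1 = float(m1v[pos1].sum())
    d2 = float(m2v[pos2].sum())
    m1 = float(m1v[both].sum() / d1) if d1 > 0 else math.nan
    m2 = float(m2v[both].sum() / d2) if d2 > 0 else math.nan
    return m1, m2


def contact_fraction(
    mask_a: np.ndarray, mask_b: np.ndarray, mask_c: np.ndarray
) -> float:
    """Percent of the A ∧ B contact area also covered by mask C.

    Returns NaN (undefined) when A and B do not touch at all.
    """
    if not (mask_a.shape == mask_b.shape == mask_c.shape):
        raise ValueError("masks must share one shape")
    contact = mask_a.astype(bool) & mask_b.astype(bool)
    n_contact = int(contact.sum())
    if n_contact == 0:
        return math.nan
    return 100.0 * float((contact & mask_c.astype(bool)).sum()) / n_contact


@dataclass
class ColocResult:
    """Manders coefficients per channel pair plus the triple contact fraction.

    ``manders[(A, B)]`` holds (M1, M2) for the ordered pair;
    ``triple_percent`` is the contact fraction of the configured (A, B, C)
    triple in percent, NaN when A and B share no pixels. The full parameter
    set is echoed for provenance.
    """

    manders: dict[tuple[str, str], tuple[float, float]]
    triple_percent: float
    triple_channels: tuple[str, str, str] | None
    mask_area: dict[str, int]
    params: ColocParams

    def to_dict(self) -> dict:
        def _clean(x: float) -> float | None:
            return None if (x != x) else x  # NaN -> null for JSON

        return {
            "manders": {
                f"{a}|{b}": {"M1": _clean(m1), "M2": _clean(m2)}
                for (a, b), (m1, m2) in self.manders.items()
            },
            "triple_percent": _clean(self.triple_percent),
            "triple_channels": list(self.triple_channels)
            if self.triple_channels
            else None,
            "mask_area": self.mask_area,
            "params": asdict(self.params),
        }


def coloc_pipeline(
    stack: ChannelStack,
    params: ColocParams = ColocParams(),
    triple: Sequence[str] | None = None,
) -> ColocResult:
    """Denoise, segment and quantify a channel stack.

    ``triple`` names (A, B, C) for the contact-fraction measurement; by
    default the stack's first three channels in order. With only two channels
    the triple measurement is skipped.
    """
    names = stack.names
    denoised = {
        n: median_denoise(stack.channels[n], params.median_size) for n in names
    }
    masks = {n: phansalkar_threshold(denoised[n], params) for n in names}

    manders: dict[tuple[str, str], tuple[float, float]] = {}
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            manders[(a, b)] = manders_split(
                denoised[a], denoised[b], masks[a], masks[b]
            )

    triple_names: tuple[str, str, str] | None = None
    triple_percent = math.nan
    if triple is None and len(names) >= 3:
        triple = names[:3]
    if triple is not None:
        a, b, c = triple
        for n in (a, b, c):
            if n not in masks:
                raise ValueError(f"triple channel {n!r} not in stack {names}")
        triple_names = (a, b, c)
        triple_percent = contact_fraction(masks[a], masks[b], masks[c])

    return ColocResult(
        manders=manders,
        triple_percent=triple_percent,
        triple_channels=triple_names,
        mask_area={n: int(masks[n].sum()) for n in names},
        params=params,
    )
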