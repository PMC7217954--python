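"""Synthetic ground-truth generators for every pipeline stage.

Three generators cover the three analysis stages:

* :func:`simulate_decay_experiment` — paired control / knockdown
  transcription-shutoff time courses with planted half-lives, planted
  stabilized / destabilized classes at an exact fold change, multiplicative
  lognormal noise, a global per-time-point scaling drift (transcription
  shutoff depresses total RNA, so raw units drift down even for stable
  species), and spiked-in stable reference transcripts.
* :func:`simulate_geneset_collection` — GMT-style gene-set collections in
  which a chosen number of sets are enriched for the planted changed
  transcripts at a chosen strength.
* :func:`simulate_coloc_stack` — three-channel blob-field images in which a
  controlled fraction of ER-mitochondria contact regions carries a
  third-channel (galectin) blob.

Every generator is a pure function of its arguments including the seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from stabiloc.coloc import ChannelStack
from stabiloc.stability import (
    DEFAULT_REFERENCES,
    DEFAULT_TIMEPOINTS_H,
    DESTABILIZED,
    STABILIZED,
    UNCHANGED,
    TimeCourseMatrix,
)


class ConfigurationError(ValueError):
    """Inconsistent simulation configuration."""


class GenerationError(RuntimeError):
    """The requested scene cannot be realized (e.g. objects do not fit)."""


def _default_scale_profile(timepoints: np.ndarray) -> np.ndarray:
    """Global RNA decline: linear from 1 at t=0 down to 0.6 at the last point."""
    return 1.0 - 0.4 * timepoints / timepoints[-1]


@dataclass(frozen=True)
class SimDecayConfig:
    """Study design for a paired-condition decay simulation.

    Half-lives are drawn log-uniformly inside ``half_life_range_h``. Planted
    stabilized transcripts have a control half-life exactly ``fold_change``
    times the knockdown one (and vice versa for destabilized); the draw is
    restricted so both sides stay inside ``half_life_range_h`` and remain
    recoverable under the downstream rapid-decay filter. ``noise_cv`` is the
    coefficient of variation of the multiplicative lognormal noise applied to
    every measurement.
    """

    n_transcripts: int = 500
    timepoints_h: tuple[float, ...] = DEFAULT_TIMEPOINTS_H
    half_life_range_h: tuple[float, float] = (3.0, 30.0)
    frac_stabilized: float = 0.1
    frac_destabilized: float = 0.05
    fold_change: float = 2.0
    noise_cv: float = 0.1
    global_scale_profile: tuple[float, ...] | None = None
    baseline_fpkm_range: tuple[float, float] = (5.0, 500.0)
    n_reference: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        tp = np.asarray(self.timepoints_h, dtype=float)
        if tp[0] != 0 or not np.all(np.diff(tp) > 0):
            raise ConfigurationError("timepoints must start at 0 and strictly increase")
        if not (0 <= self.frac_stabilized and 0 <= self.frac_destabilized):
            raise ConfigurationError("class fractions must be non-negative")
        if self.frac_stabilized + self.frac_destabilized > 1:
            raise ConfigurationError("class fractions must sum to at most 1")
        if self.fold_change < 1:
            raise ConfigurationError("fold_change must be >= 1")
        if self.noise_cv < 0:
            raise ConfigurationError("noise_cv must be >= 0")
        lo, hi = self.half_life_range_h
        if not (0 < lo < hi):
            raise ConfigurationError("half_life_range_h must be increasing and positive")
        if self.fold_change > 1 and lo * self.fold_change >= hi:
            raise ConfigurationError(
                "half_life_range_h too narrow to plant the requested fold_change"
            )
        if self.global_scale_profile is not None and len(
            self.global_scale_profile
        ) != len(self.timepoints_h):
            raise ConfigurationError("global_scale_profile length must match timepoints")

    @property
    def scale_profile(self) -> np.ndarray:
        tp = np.asarray(self.timepoints_h, dtype=float)
        if self.global_scale_profile is None:
            return _default_scale_profile(tp)
        return np.asarray(self.global_scale_profile, dtype=float)


@dataclass
class SimDecayTruth:
    """Ground truth of a decay simulation: one row per transcript.

    Columns: ``transcript_id``, ``t_half_control``, ``t_half_knockdown``
    (hours; +inf for references), ``true_class`` and ``is_reference``.
    """

    table: pd.DataFrame
    config: SimDecayConfig

    def to_json(self, path) -> None:
        out = self.table.copy()
        # JSON has no inf literal; references are flagged, store as null
        out = out.replace({np.inf: None})
        payload = {
            "config": {
                k: (list(v) if isinstance(v, tuple) else v)
                for k, v in vars(self.config).items()
            },
            "transcripts": out.to_dict(orient="records"),
        }
        import json

        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


def _reference_names(n: int) -> list[str]:
    names = list(DEFAULT_REFERENCES[:n])
    names += [f"REF{i}" for i in range(len(names) + 1, n + 1)]
    return names


def simulate_decay_experiment(
    config: SimDecayConfig,
) -> tuple[TimeCourseMatrix, TimeCourseMatrix, SimDecayTruth]:
    """Simulate paired control/knockdown chase time courses with known truth.

    Each non-reference transcript decays as
    ``baseline * exp(-ln2 * t / t_half)``; reference transcripts keep their
    baseline (noise only). All values are then multiplied by the time point's
    global scale factor and by lognormal noise with the configured CV.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    tp = np.asarray(cfg.timepoints_h, dtype=float)
    scale = cfg.scale_profile

    n = cfg.n_transcripts
    n_stab = int(round(cfg.frac_stabilized * n))
    n_destab = int(round(cfg.frac_destabilized * n))
    classes = np.array(
        [STABILIZED] * n_stab
        + [DESTABILIZED] * n_destab
        + [UNCHANGED] * (n - n_stab - n_destab)
    )
    rng.shuffle(classes)

    lo, hi = cfg.half_life_range_h
    f = cfg.fold_change

    def _loguniform(a: float, b: float, size: int) -> np.ndarray:
        return np.exp(rng.uniform(math.log(a), math.log(b), size=size))

    t_half_c = np.empty(n)
    t_half_k = np.empty(n)
    stab = classes == STABILIZED
    destab = classes == DESTABILIZED
    unch = ~(stab | destab)
    # keep both sides of planted pairs inside the recoverable range
    t_half_c[stab] = _loguniform(lo * f, hi, int(stab.sum()))
    t_half_k[stab] = t_half_c[stab] / f
    t_half_c[destab] = _loguniform(lo, hi / f, int(destab.sum()))
    t_half_k[destab] = t_half_c[destab] * f
    t_half_c[unch] = _loguniform(lo, hi, int(unch.sum()))
    t_half_k[unch] = t_half_c[unch]

    baselines = _loguniform(*cfg.baseline_fpkm_range, n + cfg.n_reference)
    ids = [f"TX{i:05d}" for i in range(1, n + 1)] + _reference_names(cfg.n_reference)

    def _noise(shape: tuple[int, ...], generator: np.random.Generator) -> np.ndarray:
        if cfg.noise_cv == 0:
            return np.ones(shape)
        sigma = math.sqrt(math.log(1.0 + cfg.noise_cv**2))
        return generator.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=shape)

    def _matrix(t_half: np.ndarray, label: str) -> TimeCourseMatrix:
        decay = np.exp(-math.log(2.0) * tp[np.newaxis, :] / t_half[:, np.newaxis])
        ref_rows = np.ones((cfg.n_reference, tp.size))
        clean = np.vstack([decay, ref_rows]) * baselines[:, np.newaxis]
        values = clean * _noise(clean.shape, rng) * scale[np.newaxis, :]
        df = pd.DataFrame(values, index=pd.Index(ids, name="transcript_id"), columns=tp)
        return TimeCourseMatrix(condition=label, values=df)

    control = _matrix(t_half_c, "control")
    knockdown = _matrix(t_half_k, "knockdown")

    truth = pd.DataFrame(
        {
            "transcript_id": ids,
            "t_half_control": np.concatenate([t_half_c, [np.inf] * cfg.n_reference]),
            "t_half_knockdown": np.concatenate([t_half_k, [np.inf] * cfg.n_reference]),
            "true_class": list(classes) + [UNCHANGED] * cfg.n_reference,
            "is_reference": [False] * n + [True] * cfg.n_reference,
        }
    )
    return control, knockdown, SimDecayTruth(table=truth, config=cfg)


def simulate_geneset_collection(
    truth: SimDecayTruth,
    n_sets: int = 50,
    set_size_range: tuple[int, int] = (10, 50),
    n_enriched: int = 5,
    enrichment_strength: float = 0.8,
    seed: int = 0,
) -> tuple[dict[str, list[str]], list[str]]:
    """Build a gene-set collection with planted enrichment.

    Enriched sets draw each member from the changed (stabilized or
    destabilized) transcripts with probability ``enrichment_strength`` and
    uniformly from the whole universe otherwise; null sets draw uniformly.
    Returns (collection mapping set name to member list, names of the planted
    enriched sets).
    """
    if n_enriched > n_sets:
        raise ConfigurationError("n_enriched cannot exceed n_sets")
    tt = truth.table
    universe = np.asarray(tt.loc[~tt["is_reference"], "transcript_id"])
    changed = np.asarray(
        tt.loc[
            ~tt["is_reference"] & tt["true_class"].isin([STABILIZED, DESTABILIZED]),
            "transcript_id",
        ]
    )
    lo, hi = set_size_range
    if hi > universe.size:
        raise ConfigurationError("set sizes cannot exceed the number of transcripts")
    if n_enriched > 0 and enrichment_strength > 0 and changed.size == 0:
        raise ConfigurationError("cannot plant enrichment without changed transcripts")

    rng = np.random.default_rng(seed)
    collection: dict[str, list[str]] = {}
    enriched_names: list[str] = []
    for i in range(n_sets):
        size = int(rng.integers(lo, hi + 1))
        is_enriched = i < n_enriched
        members: set[str] = set()
        if is_enriched and enrichment_strength > 0:
            n_from_changed = min(
                rng.binomial(size, enrichment_strength), changed.size
            )
            members.update(rng.choice(changed, size=n_from_changed, replace=False))
        remainder = np.setdiff1d(universe, np.asarray(sorted(members)))
        fill = size - len(members)
        members.update(rng.choice(remainder, size=fill, replace=False))
        name = f"SET{i + 1:03d}"
        collection[name] = sorted(members)
        if is_enriched:
            enriched_names.append(name)
    return collection, enriched_names


# ---------------------------------------------------------------------------
# colocalization scenes


@dataclass
class SimColocTruth:
    """Realized geometry of a synthetic colocalization scene.

    ``pairwise_fraction[(A, B)]`` is the fraction of the ideal (noiseless
    disk) mask of channel A overlapped by channel B. ``triple_fraction`` is
    |A ∧ B ∧ C| / |A ∧ B| on the ideal masks — realized after discrete
    placement, which is why it can differ from the requested target.
    """

    pairwise_fraction: dict[tuple[str, str], float]
    triple_fraction: float
    planted_fraction: float
    centers: dict[str, list[tuple[float, float]]]


def _disk_mask(shape: tuple[int, int], centers: Sequence[tuple[float, float]], radius: float) -> np.ndarray:
    mask = np.zeros(shape, dtype=bool)
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    for cy, cx in centers:
        mask |= (yy - cy) ** 2 + (xx - cx) ** 2 <= radius**2
    return mask


def _render(shape: tuple[int, int], centers: Sequence[tuple[float, float]], radius: float, amplitude: float = 0.85) -> np.ndarray:
    """Sum of Gaussian blobs (sigma = radius/2), truncated at 3 sigma."""
    img = np.zeros(shape, dtype=float)
    sigma = radius / 2.0
    cut = int(math.ceil(3 * sigma))
    for cy, cx in centers:
        y0, y1 = max(0, int(cy) - cut), min(shape[0], int(cy) + cut + 1)
        x0, x1 = max(0, int(cx) - cut), min(shape[1], int(cx) + cut + 1)
        yy, xx = np.mgrid[y0:y1, x0:x1]
        d2 = (yy - cy) ** 2 + (xx - cx) ** 2
        patch = amplitude * np.exp(-d2 / (2 * sigma**2))
        patch[d2 > (3 * sigma) ** 2] = 0.0
        img[y0:y1, x0:x1] += patch
    return img


def simulate_coloc_stack(
    shape: tuple[int, int] = (192, 192),
    n_objects: int = 12,
    object_radius: float = 5.0,
    target_triple_fraction: float = 0.5,
    noise_sd: float = 0.01,
    background: float = 0.05,
    seed: int = 0,
    contact_pairs: int | None = None,
    channel_names: tuple[str, str, str] = ("ER", "MITO", "GAL3"),
) -> tuple[ChannelStack, SimColocTruth]:
    """Simulate a three-channel blob field with controlled triple overlap.

    ``contact_pairs`` of the objects in the first two channels are placed as
    deliberate contact pairs (centers one radius apart, so their footprints
    intersect in a lens); the remaining objects in each channel are isolated.
    ``round(target_triple_fraction * contact_pairs)`` contacts receive a
    third-channel blob centered on the contact midpoint; the rest of the
    third channel's objects are placed away from any contact. Additive
    Gaussian noise and a uniform background are applied last; intensities are
    clipped to [0, 1]. The default noise_sd is small but non-zero: local
    adaptive thresholding assumes a camera-noise floor, and a perfectly flat
    background is a degenerate case real images never show.
    """
    if not 0 <= target_triple_fraction <= 1:
        raise ConfigurationError("target_triple_fraction must be in [0, 1]")
    if contact_pairs is None:
        contact_pairs = n_objects // 2
    if contact_pairs > n_objects:
        raise ConfigurationError("contact_pairs cannot exceed n_objects")
    if contact_pairs < 1:
        raise ConfigurationError("need at least one contact pair")

    rng = np.random.default_rng(seed)
    r = float(object_radius)
    margin = 3.0 * r
    min_sep = 5.0 * r
    n_triple = int(round(target_triple_fraction * contact_pairs))

    n_units = contact_pairs + 2 * (n_objects - contact_pairs) + (n_objects - n_triple)
    placed: list[tuple[float, float]] = []
    if shape[0] <= 2 * margin or shape[1] <= 2 * margin:
        raise GenerationError("image too small for the requested object radius")
    for _ in range(n_units):
        for _attempt in range(10000):
            cy = rng.uniform(margin, shape[0] - margin)
            cx = rng.uniform(margin, shape[1] - margin)
            if all((cy - py) ** 2 + (cx - px) ** 2 >= min_sep**2 for py, px in placed):
                placed.append((cy, cx))
                break
        else:
            raise GenerationError(
                f"could not place {n_units} objects of radius {r} in image {shape}"
            )

    it = iter(placed)
    contact_mid = [next(it) for _ in range(contact_pairs)]
    # contact pair: A and B centers one radius apart around the midpoint,
    # at a random orientation
    a_centers: list[tuple[float, float]] = []
    b_centers: list[tuple[float, float]] = []
    for cy, cx in contact_mid:
        theta = rng.uniform(0, 2 * math.pi)
        dy, dx = 0.5 * r * math.sin(theta), 0.5 * r * math.cos(theta)
        a_centers.append((cy + dy, cx + dx))
        b_centers.append((cy - dy, cx - dx))
    for _ in range(n_objects - contact_pairs):
        a_centers.append(next(it))
    for _ in range(n_objects - contact_pairs):
        b_centers.append(next(it))
    c_centers: list[tuple[float, float]] = list(contact_mid[:n_triple])
    for _ in range(n_objects - n_triple):
        c_centers.append(next(it))

    names = channel_names
    centers = {names[0]: a_centers, names[1]: b_centers, names[2]: c_centers}
    channels: dict[str, np.ndarray] = {}
    for name in names:
        img = _render(shape, centers[name], r) + background
        if noise_sd > 0:
            img = img + rng.normal(0.0, noise_sd, size=shape)
        channels[name] = np.clip(img, 0.0, 1.0)

    masks = {name: _disk_mask(shape, centers[name], r) for name in names}
    pairwise: dict[tuple[str, str], float] = {}
    for first in names:
        for second in names:
            if first == second:
                continue
            denom = masks[first].sum()
            pairwise[(first, second)] = (
                float((masks[first] & masks[second]).sum() / denom) if denom else 0.0
            )
    contact = masks[names[0]] & masks[names[1]]
    triple = float((contact & masks[names[2]]).sum() / contact.sum()) if contact.any() else 0.0

    stack = ChannelStack(channels=channels)
    truth = SimColocTruth(
        pairwise_fraction=pairwise,
        triple_fraction=triple,
        planted_fraction=n_triple / contact_pairs,
        centers={k: [(float(y), float(x)) for y, x in v] for k, v in centers.items()},
    )
    return stack, truth
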