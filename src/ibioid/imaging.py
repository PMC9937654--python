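"""Synaptosome confocal quantification and its synthetic image generator.

Workflow mirrored here: each channel of a multichannel image (TH marking
dopaminergic particles, Bassoon marking release sites, plus a target
channel, e.g. Neuroplastin) is binarized with an Otsu threshold; connected
components are size-gated in µm² (0.2–1 for TH, 0.15–2 for Bassoon and the
target); TH⁺ ROIs are classified by their Bassoon content (overlap with a
detected Bassoon ROI → Bassoon⁺; mean Bassoon intensity below 1× the
image-wide mean → Bassoon⁻; otherwise excluded); and the per-ROI target
intensities of the Bassoon⁺ and Bassoon⁻ classes are compared with an
unpaired two-tailed t-test and a two-sample KS test.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy import stats
from skimage import measure

TH_GATE_UM2 = (0.2, 1.0)
OTHER_GATE_UM2 = (0.15, 2.0)
NEG_FACTOR = 1.0


class DegenerateImageError(ValueError):
    """Constant image: no threshold separates two classes."""


class ThClass(str, Enum):
    BASSOON_POS = "BASSOON_POS"
    BASSOON_NEG = "BASSOON_NEG"
    EXCLUDED = "EXCLUDED"
    NA = "NA"


@dataclass
class MultiChannelImage:
    """Named 2-D intensity channels sharing one shape and pixel size."""

    channels: dict[str, np.ndarray]
    pixel_size_um: float

    def __post_init__(self) -> None:
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        shapes = {name: ch.shape for name, ch in self.channels.items()}
        if len(set(shapes.values())) != 1:
            raise ValueError(f"channel shapes differ: {shapes}")
        for name, ch in self.channels.items():
            if not np.all(np.isfinite(ch)) or np.any(ch < 0):
                raise ValueError(f"channel {name!r} has negative or non-finite pixels")

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.channels.values())).shape


@dataclass
class ParticleRecord:
    """One segmented ROI with geometry and per-channel mean intensities."""

    label: int
    channel: str
    area_um2: float
    centroid: tuple[float, float]
    mean_intensity: dict[str, float]
    coords: np.ndarray  # (n_px, 2) pixel coordinates
    th_class: ThClass = ThClass.NA


def otsu_threshold(channel: np.ndarray, n_bins: int = 256) -> float:
    """Histogram threshold maximizing between-class variance.

    Candidate thresholds are the bin edges of an ``n_bins`` histogram over
    [min, max]; the returned value is the lowest edge attaining the maximal
    between-class variance (ties broken toward the lowest qualifying bin).
    Pixels strictly above the threshold are foreground.
    """
    x = np.asarray(channel, dtype=float).ravel()
    if x.min() == x.max():
        raise DegenerateImageError("constant image has no Otsu threshold")
    hist, edges = np.histogram(x, bins=n_bins, range=(x.min(), x.max()))
    p = hist.astype(float) / hist.sum()
    centers = (edges[:-1] + edges[1:]) / 2.0

    w0 = np.cumsum(p)  # class 0 = bins 0..k
    w1 = 1.0 - w0
    mu_cum = np.cumsum(p * centers)
    mu_total = mu_cum[-1]
    valid = (w0 > 0) & (w1 > 0)
    between = np.zeros(n_bins)
    between[valid] = (mu_total * w0[valid] - mu_cum[valid]) ** 2 / (
        w0[valid] * w1[valid]
    )
    # lowest bin attaining the maximum; the relative tolerance absorbs
    # round-off so exact ties (cuts across empty bins) resolve consistently
    vmax = between.max()
    k = int(np.argmax(between >= vmax * (1.0 - 1e-12)))
    return float(edges[k + 1])


def detect_particles(
    channel: np.ndarray,
    threshold: float,
    pixel_size_um: float,
    area_range_um2: tuple[float, float],
    image: MultiChannelImage | None = None,
    channel_name: str = "",
    connectivity: int = 2,
) -> list[ParticleRecord]:
    """Size-gated connected components of the binary mask ``channel > t``.

    Components are 8-connected by default; areas are pixel counts ×
    pixel_size_um², and the [min, max] gate is inclusive at both ends. Mean
    intensities are computed for every channel of ``image`` (or just the
    segmented channel if no image is given).
    """
    lo, hi = area_range_um2
    if not lo < hi:
        raise ValueError("area gate must satisfy min < max")
    mask = np.asarray(channel) > threshold
    labels = measure.label(mask, connectivity=connectivity)
    px_area = pixel_size_um**2
    chans = image.channels if image is not None else {channel_name or "channel": channel}
    records: list[ParticleRecord] = []
    for region in measure.regionprops(labels):
        area = region.area * px_area
        if not (lo <= area <= hi):
            continue
        rr, cc = region.coords[:, 0], region.coords[:, 1]
        means = {name: float(ch[rr, cc].mean()) for name, ch in chans.items()}
        records.append(
            ParticleRecord(
                label=int(region.label),
                channel=channel_name,
                area_um2=float(area),
                centroid=tuple(float(c) for c in region.centroid),
                mean_intensity=means,
                coords=region.coords,
            )
        )
    return records


def classify_th_rois(
    th_rois: Sequence[ParticleRecord],
    bassoon_rois: Sequence[ParticleRecord],
    bassoon_channel: np.ndarray,
    neg_factor: float = NEG_FACTOR,
    rule: str = "overlap",
) -> list[ParticleRecord]:
    """Assign each TH ROI a Bassoon class; classes partition the TH ROIs.

    With the default ``rule='overlap'``: Bassoon⁺ if the TH ROI shares ≥1
    pixel with any detected Bassoon ROI; otherwise Bassoon⁻ if its mean
    Bassoon intensity is below ``neg_factor`` × the image-wide mean of the
    Bassoon channel; otherwise EXCLUDED. With ``rule='intensity'`` the
    positive class is instead defined symmetrically as mean Bassoon
    intensity ≥ ``neg_factor`` × image mean (no ROI is excluded).
    """
    if rule not in ("overlap", "intensity"):
        raise ValueError(f"unknown classification rule {rule!r}")
    shape = bassoon_channel.shape
    bassoon_mask = np.zeros(shape, dtype=bool)
    for roi in bassoon_rois:
        if roi.coords[:, 0].max() >= shape[0] or roi.coords[:, 1].max() >= shape[1]:
            raise ValueError("Bassoon ROI lies outside the Bassoon channel")
        bassoon_mask[roi.coords[:, 0], roi.coords[:, 1]] = True
    global_mean = float(bassoon_channel.mean())
    cutoff = neg_factor * global_mean

    out = []
    for roi in th_rois:
        rr, cc = roi.coords[:, 0], roi.coords[:, 1]
        if rr.max() >= shape[0] or cc.max() >= shape[1]:
            raise ValueError("TH ROI lies outside the Bassoon channel")
        mean_bsn = float(bassoon_channel[rr, cc].mean())
        if rule == "overlap":
            if bool(bassoon_mask[rr, cc].any()):
                cls = ThClass.BASSOON_POS
            elif mean_bsn < cutoff:
                cls = ThClass.BASSOON_NEG
            else:
                cls = ThClass.EXCLUDED
        else:
            cls = ThClass.BASSOON_POS if mean_bsn >= cutoff else ThClass.BASSOON_NEG
        roi.mean_intensity.setdefault("BASSOON", mean_bsn)
        roi.th_class = cls
        out.append(roi)
    return out


@dataclass
class IntensityComparison:
    t_statistic: float
    t_p: float
    ks_statistic: float
    ks_p: float
    n_pos: int
    n_neg: int
    t_skipped: bool
    hist_pos: tuple[np.ndarray, np.ndarray]
    hist_neg: tuple[np.ndarray, np.ndarray]


def compare_target_intensity(
    pos: Sequence[ParticleRecord],
    neg: Sequence[ParticleRecord],
    target_channel: str,
    n_bins: int = 20,
) -> IntensityComparison:
    """Unpaired two-tailed t-test and two-sample KS test on per-ROI mean
    target intensities of the Bassoon⁺ vs Bassoon⁻ classes."""
    if not pos or not neg:
        raise ValueError("both groups must be non-empty")
    x = np.array([r.mean_intensity[target_channel] for r in pos])
    y = np.array([r.mean_intensity[target_channel] for r in neg])
    t_skipped = len(x) < 2 or len(y) < 2
    if t_skipped:
        t, tp = np.nan, np.nan
    else:
        t, tp = stats.ttest_ind(x, y, equal_var=True)
    ks, ksp = stats.ks_2samp(x, y)
    lo = float(min(x.min(), y.min()))
    hi = float(max(x.max(), y.max()))
    if lo == hi:
        hi = lo + 1.0
    hp = np.histogram(x, bins=n_bins, range=(lo, hi))
    hn = np.histogram(y, bins=n_bins, range=(lo, hi))
    return IntensityComparison(
        t_statistic=float(t),
        t_p=float(tp),
        ks_statistic=float(ks),
        ks_p=float(ksp),
        n_pos=len(x),
        n_neg=len(y),
        t_skipped=t_skipped,
        hist_pos=hp,
        hist_neg=hn,
    )


# ---------------------------------------------------------------------------
# synthetic image generation
# ---------------------------------------------------------------------------


def _place_centers(
    n: int,
    shape: tuple[int, int],
    min_sep: float,
    margin: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Random centers with a minimum pairwise separation (dart throwing)."""
    h, w = shape
    if (h - 2 * margin) * (w - 2 * margin) < n * min_sep**2:
        raise ValueError(
            f"cannot pack {n} particles with separation {min_sep} into {shape}; "
            "use a larger frame or fewer particles"
        )
    centers: list[tuple[float, float]] = []
    attempts = 0
    max_attempts = 200 * n
    while len(centers) < n:
        attempts += 1
        if attempts > max_attempts:
            raise ValueError(
                f"failed to place {n} particles in {shape} after {max_attempts} "
                "attempts; use a larger frame"
            )
        r = rng.uniform(margin, h - margin)
        c = rng.uniform(margin, w - margin)
        if all((r - r0) ** 2 + (c - c0) ** 2 >= min_sep**2 for r0, c0 in centers):
            centers.append((r, c))
    return np.array(centers)


def _add_spot(
    img: np.ndarray, center: tuple[float, float], amplitude: float, sigma: float
) -> None:
    """Add a Gaussian spot in place, stamped on a local window."""
    r0, c0 = center
    half = int(np.ceil(4 * sigma))
    rlo, rhi = max(0, int(r0) - half), min(img.shape[0], int(r0) + half + 1)
    clo, chi = max(0, int(c0) - half), min(img.shape[1], int(c0) + half + 1)
    rr, cc = np.mgrid[rlo:rhi, clo:chi]
    img[rlo:rhi, clo:chi] += amplitude * np.exp(
        -((rr - r0) ** 2 + (cc - c0) ** 2) / (2 * sigma**2)
    )


def generate_synaptosome_image(
    n_particles: int = 150,
    frac_bassoon_pos: float = 0.5,
    effect_size: float = 0.0,
    noise_sd: float = 2.0,
    shape: tuple[int, int] = (256, 256),
    pixel_size_um: float = 0.138,
    seed: int = 0,
    spot_sigma_px: float = 2.0,
    amplitude: float = 120.0,
    target_base: float = 50.0,
    target_sd: float = 10.0,
    background: float = 8.0,
) -> tuple[MultiChannelImage, list[dict]]:
    """Simulate a 3-channel synaptosome field with ground truth.

    Gaussian TH spots are placed with a minimum separation; a
    ``frac_bassoon_pos`` fraction receives a co-located Bassoon spot. Each
    particle's TARGET spot amplitude is drawn N(target_base, target_sd),
    shifted up by ``effect_size`` for Bassoon⁺ particles. Gaussian read
    noise (sd ``noise_sd``) on a uniform background is added to every
    channel and clipped at zero. Deterministic per seed.

    Returns the image and one ground-truth dict per particle
    (center, bassoon_pos flag, target amplitude).
    """
    rng = np.random.default_rng(seed)
    min_sep = 6.0 * spot_sigma_px
    centers = _place_centers(n_particles, shape, min_sep, int(3 * spot_sigma_px), rng)
    n_pos = int(round(frac_bassoon_pos * n_particles))
    is_pos = np.zeros(n_particles, dtype=bool)
    is_pos[rng.permutation(n_particles)[:n_pos]] = True

    th = np.zeros(shape)
    bassoon = np.zeros(shape)
    target = np.zeros(shape)
    truth = []
    for i, (r, c) in enumerate(centers):
        _add_spot(th, (r, c), amplitude, spot_sigma_px)
        if is_pos[i]:
            _add_spot(bassoon, (r, c), amplitude, spot_sigma_px)
        t_amp = rng.normal(target_base + (effect_size if is_pos[i] else 0.0), target_sd)
        t_amp = max(t_amp, 1.0)
        _add_spot(target, (r, c), t_amp, spot_sigma_px)
        truth.append(
            {
                "center": (float(r), float(c)),
                "bassoon_pos": bool(is_pos[i]),
                "target_amplitude": float(t_amp),
            }
        )

    channels = {}
    for name, img in (("TH", th), ("BASSOON", bassoon), ("TARGET", target)):
        noisy = img + background
        if noise_sd > 0:
            noisy = noisy + rng.normal(0.0, noise_sd, shape)
        channels[name] = np.clip(noisy, 0.0, None)
    return MultiChannelImage(channels=channels, pixel_size_um=pixel_size_um), truth


def quantify_image(
    image: MultiChannelImage,
    target_channel: str = "TARGET",
    th_gate: tuple[float, float] = TH_GATE_UM2,
    other_gate: tuple[float, float] = OTHER_GATE_UM2,
    neg_factor: float = NEG_FACTOR,
    rule: str = "overlap",
) -> tuple[list[ParticleRecord], IntensityComparison]:
    """Full single-image pipeline: threshold, detect, classify, compare."""
    th = image.channels["TH"]
    bassoon = image.channels["BASSOON"]
    th_rois = detect_particles(
        th,
        otsu_threshold(th),
        image.pixel_size_um,
        th_gate,
        image=image,
        channel_name="TH",
    )
    bassoon_rois = detect_particles(
        bassoon,
        otsu_threshold(bassoon),
        image.pixel_size_um,
        other_gate,
        image=image,
        channel_name="BASSOON",
    )
    classified = classify_th_rois(th_rois, bassoon_rois, bassoon, neg_factor, rule)
    pos = [r for r in classified if r.th_class is ThClass.BASSOON_POS]
    neg = [r for r in classified if r.th_class is ThClass.BASSOON_NEG]
    comparison = compare_target_intensity(pos, neg, target_channel)
    return classified, comparison


def particle_table(records: Sequence[ParticleRecord]):
    """ROI list → tidy DataFrame for TSV export."""
    import pandas as pd

    rows = []
    for r in records:
        row = {
            "label": r.label,
            "channel": r.channel,
            "area_um2": r.area_um2,
            "centroid_row": r.centroid[0],
            "centroid_col": r.centroid[1],
            "th_class": r.th_class.value,
        }
        for name, v in r.mean_intensity.items():
            row[f"mean_{name}"] = v
        rows.append(row)
    return pd.DataFrame(rows)
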