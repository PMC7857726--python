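"""Border enrichment, colocalization and along-border profile metrics.

Enrichment is the ratio of mean fluorescence at a cell border to a reference
region (the whole cell pair, or a second non-junctional ROI). Colocalization
of two channels along a border is the plain Pearson correlation over the
pixels of a band ROI, with no intensity threshold. Along-border profiles
collapse the band to per-arc-position means and classify the two-channel
phase relationship (correlated co-occurrence across the junction vs
anti-phase lateral alternation).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datatypes import BorderRoi, RasterImage
from .preprocess import sample_border_band

__all__ = [
    "EnrichmentResult",
    "BorderProfile",
    "enrichment_cellpair",
    "enrichment_two_roi",
    "pearson_border",
    "border_profiles",
    "coip_ratio",
]


@dataclass
class EnrichmentResult:
    ratio: float
    definition: str  # cellpair | contact_vs_free | junction_vs_nonjunction
    border_mean: float
    reference_mean: float


@dataclass
class BorderProfile:
    arc_nm: np.ndarray
    ch1: np.ndarray
    ch2: np.ndarray
    pearson_r: float
    classification: str  # correlated | anti-phase | mixed


def enrichment_cellpair(image: RasterImage, border_mask: np.ndarray,
                        cellpair_mask: np.ndarray) -> EnrichmentResult:
    """Mean border intensity over mean cell-pair intensity.

    The border must lie within the cell pair; the reference mean is over the
    whole pair (border included), the segmented-ROI definition used for
    keratinocyte cell pairs.
    """
    border = np.asarray(border_mask, dtype=bool)
    pair = np.asarray(cellpair_mask, dtype=bool)
    if not border.any() or not pair.any():
        raise ValueError("masks must be non-empty")
    if (border & ~pair).any():
        raise ValueError("border mask must lie within the cell-pair mask")
    bmean = float(image.pixels[border].mean())
    pmean = float(image.pixels[pair].mean())
    if pmean == 0:
        raise ZeroDivisionError("cell-pair mean intensity is zero")
    return EnrichmentResult(ratio=bmean / pmean, definition="cellpair",
                            border_mean=bmean, reference_mean=pmean)


def enrichment_two_roi(image: RasterImage, roi_a: BorderRoi, roi_b: BorderRoi,
                       definition: str = "junction_vs_nonjunction") -> EnrichmentResult:
    """Ratio of mean intensities sampled under two band ROIs.

    Covers both two-ROI definitions: junction vs non-junction segments of a
    cell perimeter, and contacting vs non-contacting (free) surfaces.
    """
    a = sample_border_band(image, roi_a)
    b = sample_border_band(image, roi_b)
    if a.empty or b.empty:
        raise ValueError("an ROI band sampled no pixels")
    amean = float(a["value"].mean())
    bmean = float(b["value"].mean())
    if bmean == 0:
        raise ZeroDivisionError("reference ROI mean intensity is zero")
    return EnrichmentResult(ratio=amean / bmean, definition=definition,
                            border_mean=amean, reference_mean=bmean)


def pearson_border(ch1: RasterImage, ch2: RasterImage,
                   roi: BorderRoi) -> float:
    """Pearson correlation of two channels over a border band ROI.

    All pixels in the band contribute; no background threshold is applied.
    """
    if ch1.shape != ch2.shape:
        raise ValueError("channels must share a shape")
    band = sample_border_band(ch1, roi)
    if len(band) < 2:
        raise ValueError("need at least 2 samples in the ROI band")
    v1 = band["value"].to_numpy()
    v2 = ch2.pixels[band["row"].to_numpy(), band["col"].to_numpy()].astype(float)
    if v1.std() == 0 or v2.std() == 0:
        raise ValueError("Pearson undefined: a channel is constant over the ROI")
    return float(np.corrcoef(v1, v2)[0, 1])


def border_profiles(ch1: RasterImage, ch2: RasterImage, roi: BorderRoi,
                    correlated_r: float = 0.5,
                    antiphase_r: float = -0.2) -> BorderProfile:
    """Along-border per-position mean profiles and a phase classification.

    The band samples of each channel are averaged per arc position. The
    channels are called ``correlated`` when the band Pearson R is at least
    ``correlated_r``, ``anti-phase`` when R is at most ``antiphase_r``,
    otherwise ``mixed``. The thresholds are reporting conveniences and
    configurable.
    """
    band1 = sample_border_band(ch1, roi)
    prof1 = band1.groupby("arc_px")["value"].mean()
    v2 = ch2.pixels[band1["row"].to_numpy(), band1["col"].to_numpy()].astype(float)
    band2 = band1.assign(value=v2)
    prof2 = band2.groupby("arc_px")["value"].mean()
    r = pearson_border(ch1, ch2, roi)
    if r >= correlated_r:
        cls = "correlated"
    elif r <= antiphase_r:
        cls = "anti-phase"
    else:
        cls = "mixed"
    arc_nm = prof1.index.to_numpy() * ch1.pixel_size_nm
    return BorderProfile(arc_nm=arc_nm, ch1=prof1.to_numpy(),
                         ch2=prof2.to_numpy(), pearson_r=r,
                         classification=cls)


def dominant_period_nm(profile: BorderProfile) -> float:
    """Dominant alternation period of the ch1 profile via autocorrelation.

    Returns the arc distance of the first autocorrelation peak after the
    first zero crossing; useful for recovering the domain length of
    laterally separated channels (period = 2 domain lengths).
    """
    x = profile.ch1 - profile.ch1.mean()
    n = len(x)
    if n < 4:
        raise ValueError("profile too short")
    ac = np.correlate(x, x, mode="full")[n - 1:]
    ac /= ac[0]
    neg = np.nonzero(ac < 0)[0]
    if len(neg) == 0:
        raise ValueError("no zero crossing in autocorrelation")
    start = neg[0]
    peak = start + int(np.argmax(ac[start:]))
    step = profile.arc_nm[1] - profile.arc_nm[0]
    return float(peak * step)


def coip_ratio(partner_crsh: float, bait_crsh: float,
               partner_wt: float, bait_wt: float) -> float:
    """Bait-normalized co-immunoprecipitation band ratio, mutant over WT:
    (partner_crsh / bait_crsh) / (partner_wt / bait_wt)."""
    for name, v in (("bait_crsh", bait_crsh), ("bait_wt", bait_wt),
                    ("partner_wt", partner_wt)):
        if v <= 0:
            raise ZeroDivisionError(f"{name} must be positive")
    if partner_crsh < 0:
        raise ValueError("band intensities must be non-negative")
    return (partner_crsh / bait_crsh) / (partner_wt / bait_wt)
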