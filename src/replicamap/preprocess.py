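"""Preprocessing: lockmass alignment, binning, TIC normalization,
tissue segmentation and background correction.

The standard chain for DESI-MSI lipid imaging is::

    lockmass_align -> quantize (or pick_peaks) -> tic_normalize
                   -> segment_tissue -> background_correct

Lockmass alignment recalibrates each spectrum with a constant additive
m/z shift onto a prominent reference peak (default m/z 885.5498, the
PI 38:4 ion abundant in brain tissue). Quantization maps continuous
spectra onto a uniform bin axis — by default m/z 600–900 at 0.0125 width,
i.e. exactly 24,000 bins (half the nominal m/z resolution of a 20,000
resolving-power time-of-flight at this range). TIC normalization turns
intensities into relative abundances. Segmentation thresholds a
representative image accumulated from three region-informative channels,
and background correction z-scores every feature against the
background-pixel population so that off-tissue signal becomes
standard-normal by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .core import CommonRepresentation, MSIDataset, Spectrum, TissueMask
from .errors import (
    ChannelResolutionError,
    EmptyBackgroundError,
    EmptyFeatureError,
    ParameterError,
)

__all__ = [
    "BinAxis",
    "SegmentationChannels",
    "BackgroundStats",
    "LockmassReport",
    "lockmass_align",
    "quantize",
    "tic_normalize",
    "pick_peaks",
    "segment_tissue",
    "background_correct",
    "resolve_feature",
    "DEFAULT_LOCKMASS_MZ",
    "DEFAULT_SECTION_CHANNELS",
]

DEFAULT_LOCKMASS_MZ = 885.5498
#: representative channels used to build the tissue-segmentation image
DEFAULT_SECTION_CHANNELS = (794.55, 834.53, 886.60)
DEFAULT_RESOLVING_POWER = 20000.0


@dataclass(frozen=True)
class BinAxis:
    """Uniform half-open binning of the m/z axis.

    Bin ``k`` covers ``[mz_start + k*w, mz_start + (k+1)*w)``; a value
    exactly at ``mz_end`` is out of range. With the defaults (600–900 at
    width 0.0125) the axis has exactly 24,000 bins.
    """

    mz_start: float = 600.0
    mz_end: float = 900.0
    bin_width: float = 0.0125

    def __post_init__(self) -> None:
        if self.bin_width <= 0:
            raise ParameterError("bin_width must be positive")
        if self.mz_end <= self.mz_start:
            raise ParameterError("mz_end must exceed mz_start")

    @property
    def n_bins(self) -> int:
        return int(round((self.mz_end - self.mz_start) / self.bin_width))

    @property
    def centres(self) -> np.ndarray:
        return self.mz_start + (np.arange(self.n_bins) + 0.5) * self.bin_width

    def bin_of(self, mz: np.ndarray) -> np.ndarray:
        """Bin index per m/z value; -1 where out of range."""
        mz = np.asarray(mz, dtype=float)
        idx = np.floor((mz - self.mz_start) / self.bin_width).astype(np.int64)
        idx[(mz < self.mz_start) | (idx >= self.n_bins)] = -1
        return idx


@dataclass(frozen=True)
class SegmentationChannels:
    """Three m/z channels whose accumulated image separates tissue from background."""

    channels: tuple[float, float, float] = DEFAULT_SECTION_CHANNELS

    def __post_init__(self) -> None:
        if len(self.channels) != 3:
            raise ParameterError("exactly three segmentation channels are required")


@dataclass
class BackgroundStats:
    """Per-feature mean and s.d. of background-pixel intensities."""

    mean: np.ndarray
    sd: np.ndarray
    zero_sd: np.ndarray  # flag: features whose background s.d. was 0 (sd forced to 1)
    n_background: int = 0


@dataclass
class LockmassReport:
    n_aligned: int = 0
    n_unaligned: int = 0
    shifts: list = field(default_factory=list)


#: m/z samples farther apart than this belong to different (centroided) peaks
_PEAK_GAP_MZ = 0.05


def _apex_shift(spec: Spectrum, reference_mz: float, tolerance: float) -> float | None:
    """Additive shift putting the most intense in-window local maximum on the
    reference, or None when no qualifying peak exists."""
    lo = np.searchsorted(spec.mz, reference_mz - tolerance, side="left")
    hi = np.searchsorted(spec.mz, reference_mz + tolerance, side="right")
    if hi <= lo:
        return None
    window = spec.intensity[lo:hi]
    if not np.any(window > 0):
        return None
    # local maximum relative to adjacent samples of the same peak; samples
    # farther than the gap threshold are separate centroids, not shoulders
    order = np.argsort(window)[::-1]
    n = len(spec)
    for j in order:
        i = lo + j
        if window[j] <= 0:
            break
        left_ok = (
            i == 0
            or spec.mz[i] - spec.mz[i - 1] > _PEAK_GAP_MZ
            or spec.intensity[i - 1] <= spec.intensity[i]
        )
        right_ok = (
            i == n - 1
            or spec.mz[i + 1] - spec.mz[i] > _PEAK_GAP_MZ
            or spec.intensity[i + 1] <= spec.intensity[i]
        )
        if left_ok and right_ok:
            return reference_mz - spec.mz[i]
    return None


def lockmass_align(
    dataset: MSIDataset,
    reference_mz: float = DEFAULT_LOCKMASS_MZ,
    tolerance: float = 0.1,
) -> tuple[MSIDataset, LockmassReport]:
    """Recalibrate each spectrum by a constant additive m/z shift.

    The most intense local maximum within ``±tolerance`` of
    ``reference_mz`` is moved exactly onto the reference. Spectra with no
    qualifying peak (e.g. background pixels) are left unshifted and
    counted in the report.
    """
    if tolerance <= 0:
        raise ParameterError("tolerance must be positive")
    report = LockmassReport()
    spectra = []
    for spec in dataset.spectra:
        shift = _apex_shift(spec, reference_mz, tolerance)
        if shift is None:
            report.n_unaligned += 1
            spectra.append(spec)
        else:
            report.n_aligned += 1
            report.shifts.append(shift)
            spectra.append(spec.shifted(shift))
    out = MSIDataset(dataset.coords.copy(), spectra, dataset.pixel_size, dataset.meta)
    return out, report


def quantize(dataset: MSIDataset, axis: BinAxis | None = None) -> CommonRepresentation:
    """Bin every spectrum onto a shared uniform axis, summing intensities.

    Intensities whose m/z falls outside ``[mz_start, mz_end)`` are
    dropped; the in-range total intensity is conserved exactly (bins
    partition the range).
    """
    if axis is None:
        axis = BinAxis()
    n_bins = axis.n_bins
    if n_bins < 1:
        raise ParameterError("bin axis is empty")
    matrix = np.zeros((len(dataset), n_bins))
    for i, spec in enumerate(dataset.spectra):
        idx = axis.bin_of(spec.mz)
        keep = idx >= 0
        if keep.any():
            matrix[i] = np.bincount(
                idx[keep], weights=spec.intensity[keep], minlength=n_bins
            )
    return CommonRepresentation(
        matrix=matrix,
        feature_mz=axis.centres,
        coords=dataset.coords.copy(),
        mode="binned",
        pixel_size=dataset.pixel_size,
        meta=dataset.meta,
        provenance={
            "quantize": {
                "mz_start": axis.mz_start,
                "mz_end": axis.mz_end,
                "bin_width": axis.bin_width,
            }
        },
    )


def tic_normalize(representation: CommonRepresentation) -> CommonRepresentation:
    """Scale each pixel's intensities to sum to one.

    Zero-TIC pixels are never divided: they stay all-zero and are flagged
    in ``zero_tic``. Idempotent (up to floating-point rounding).
    """
    tic = representation.matrix.sum(axis=1)
    zero = tic <= 0
    scale = np.where(zero, 1.0, tic)
    out = representation.copy_with(
        representation.matrix / scale[:, None], tic_normalized=True
    )
    out.zero_tic = zero
    return out


def resolve_feature(
    representation: CommonRepresentation,
    mz: float,
    resolving_power: float = DEFAULT_RESOLVING_POWER,
) -> int:
    """Map a requested m/z to the nearest feature column.

    The match must lie within half an expected peak width
    (``mz / resolving_power / 2``) or, in binned mode, within one bin
    width — whichever is larger; otherwise a
    :class:`ChannelResolutionError` is raised.
    """
    axis = representation.feature_mz
    if axis.size == 0:
        raise ChannelResolutionError("empty feature axis")
    j = int(np.argmin(np.abs(axis - mz)))
    tol = mz / resolving_power / 2.0
    if representation.mode == "binned":
        width = float(axis[1] - axis[0]) if axis.size > 1 else tol
        tol = max(tol, width)
    if abs(axis[j] - mz) > tol:
        raise ChannelResolutionError(
            f"no feature within {tol:.4f} of m/z {mz} (nearest {axis[j]:.4f})"
        )
    return j


def segment_tissue(
    representation: CommonRepresentation,
    channels: SegmentationChannels | None = None,
    filter_size: int = 3,
    filter_target: str = "mask",
) -> TissueMask:
    """Threshold-based tissue segmentation.

    The representative image is the per-pixel sum of the three channel
    intensities; pixels strictly above the image mean are tissue. A
    median filter of ``filter_size × filter_size`` then removes
    salt-and-pepper noise. By default the boolean mask is filtered
    (majority vote of in-bounds neighbours, ties to background);
    ``filter_target="image"`` filters the representative image before
    thresholding instead.
    """
    if channels is None:
        channels = SegmentationChannels()
    if filter_size < 1:
        raise ParameterError("filter_size must be >= 1")
    cols = [resolve_feature(representation, mz) for mz in channels.channels]
    values = representation.matrix[:, cols].sum(axis=1)
    ny, nx = representation.grid_shape
    img = np.zeros((ny, nx))
    img[representation.coords[:, 1], representation.coords[:, 0]] = values

    if filter_target == "image" and filter_size > 1:
        img = ndimage.median_filter(img, size=filter_size, mode="nearest")
    mask = img > img.mean()
    if filter_target == "mask" and filter_size > 1:
        votes = ndimage.uniform_filter(
            mask.astype(float), size=filter_size, mode="constant", cval=0.0
        )
        valid = ndimage.uniform_filter(
            np.ones_like(img), size=filter_size, mode="constant", cval=0.0
        )
        # strict majority of in-bounds neighbours; exact ties -> background
        mask = votes > valid / 2 + 1e-12
    return TissueMask(mask)


def background_correct(
    representation: CommonRepresentation, mask: TissueMask
) -> tuple[CommonRepresentation, BackgroundStats]:
    """z-score every feature against the background-pixel population.

    After correction, background pixels have per-feature mean 0 and
    s.d. 1 for every feature whose background s.d. was positive;
    constant-background features are only mean-shifted (s.d. forced to 1)
    and flagged. Apply after TIC normalization.
    """
    is_tissue = mask.pixel_flags(representation.coords)
    bg = representation.matrix[~is_tissue]
    if bg.shape[0] < 2:
        raise EmptyBackgroundError(
            f"only {bg.shape[0]} background pixel(s); review the segmentation"
        )
    mean = bg.mean(axis=0)
    sd = bg.std(axis=0, ddof=0)
    zero_sd = sd == 0
    sd_safe = np.where(zero_sd, 1.0, sd)
    corrected = (representation.matrix - mean) / sd_safe
    stats = BackgroundStats(mean=mean, sd=sd_safe, zero_sd=zero_sd, n_background=bg.shape[0])
    out = representation.copy_with(corrected, background_corrected=True)
    return out, stats


def pick_peaks(
    datasets: list[MSIDataset],
    snr_threshold: float = 5.0,
    min_fraction: float = 0.5,
    axis: BinAxis | None = None,
    resolving_power: float = DEFAULT_RESOLVING_POWER,
    noise_window: int = 301,
) -> tuple[np.ndarray, list[CommonRepresentation]]:
    """Cohort-level peak picking on the mean spectrum.

    A surrogate for vendor peak identification: candidate features are
    local maxima of the cohort-mean binned spectrum exceeding
    ``snr_threshold`` × the local noise level (1.4826 × median absolute
    deviation in a sliding window), retained when present in at least
    ``min_fraction`` of the samples. "Present" means the sample's own
    mean spectrum exceeds half the SNR threshold against its own local
    noise at the apex. Each retained feature's per-pixel value is the
    summed intensity within ± half the expected peak width
    (``mz / resolving_power / 2``).

    Returns the picked apex m/z values and one peaks-mode representation
    per dataset.
    """
    if not datasets:
        raise ParameterError("at least one dataset is required")
    if axis is None:
        axis = BinAxis()
    binned = [quantize(d, axis) for d in datasets]
    sample_means = np.stack([b.matrix.mean(axis=0) for b in binned])
    cohort_mean = sample_means.mean(axis=0)

    baseline, noise = _local_noise(cohort_mean, noise_window)
    excess = cohort_mean - baseline
    is_local_max = np.zeros_like(cohort_mean, dtype=bool)
    interior = (cohort_mean[1:-1] >= cohort_mean[:-2]) & (
        cohort_mean[1:-1] >= cohort_mean[2:]
    )
    is_local_max[1:-1] = interior
    candidates = np.flatnonzero(is_local_max & (excess > snr_threshold * noise))

    centres = axis.centres
    sample_excess, sample_noise = [], []
    for m in sample_means:
        b, s = _local_noise(m, noise_window)
        sample_excess.append(m - b)
        sample_noise.append(s)
    sample_excess = np.stack(sample_excess)
    sample_noise = np.stack(sample_noise)
    kept = []
    for c in candidates:
        present = sample_excess[:, c] > (snr_threshold / 2.0) * sample_noise[:, c]
        if present.mean() >= min_fraction:
            kept.append(c)
    if not kept:
        raise EmptyFeatureError("no peaks passed the SNR / prevalence thresholds")
    kept = np.array(kept)
    apex_mz = centres[kept]

    reps = []
    half_widths = apex_mz / resolving_power / 2.0
    for d, b in zip(datasets, binned):
        cols = np.zeros((b.matrix.shape[0], len(kept)))
        for j, (mz, hw) in enumerate(zip(apex_mz, half_widths)):
            lo, hi = axis.bin_of(np.array([mz - hw, mz + hw]))
            lo = max(int(lo), 0)
            hi = int(hi) if hi >= 0 else axis.n_bins - 1
            cols[:, j] = b.matrix[:, lo : hi + 1].sum(axis=1)
        reps.append(
            CommonRepresentation(
                matrix=cols,
                feature_mz=apex_mz,
                coords=d.coords.copy(),
                mode="peaks",
                pixel_size=d.pixel_size,
                meta=d.meta,
                provenance={
                    "pick_peaks": {
                        "snr_threshold": snr_threshold,
                        "min_fraction": min_fraction,
                        "resolving_power": resolving_power,
                    }
                },
            )
        )
    return apex_mz, reps


def _local_noise(spectrum: np.ndarray, window: int) -> tuple[np.ndarray, np.ndarray]:
    """Sliding-window baseline (median) and noise (1.4826 × MAD) estimates."""
    med = ndimage.median_filter(spectrum, size=window, mode="nearest")
    mad = ndimage.median_filter(np.abs(spectrum - med), size=window, mode="nearest")
    noise = 1.4826 * mad
    floor = max(np.median(noise[noise > 0]) if np.any(noise > 0) else 0.0, 1e-12)
    return med, np.maximum(noise, floor)
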