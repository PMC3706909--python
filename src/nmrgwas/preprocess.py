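"""Spectral preprocessing: alignment, fixed-width binning, log transform,
per-bin outlier exclusion and region masking.

The pipeline order is fixed — align, bin, log10, 3-SD outlier removal,
water-region masking — and each cleaning step can only add missing values,
never restore them.  Bins are half-open intervals [left, right) of uniform
width; the bin label is the left edge rounded to 3 decimals, matching the
convention in which chemical-shift traits are reported (e.g. "1.370").
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "AlignmentError",
    "BinnedSpectraMatrix",
    "align_to_reference",
    "align_spectra",
    "bin_spectrum",
    "log_transform",
    "remove_outliers",
    "mask_regions",
    "preprocess_spectra",
]

LACTATE_WINDOW = (1.30, 1.42)
LACTATE_APEX = 1.37
WATER_REGION = (4.6, 5.0)


class AlignmentError(RuntimeError):
    """Raised when no reference signal is detectable in the alignment window."""


@dataclass
class BinnedSpectraMatrix:
    """Subjects x bins matrix of (possibly log10) intensities.

    ``values`` uses NaN for missing; ``bins`` has columns left, right,
    label.  ``excluded`` marks bins (e.g. the water region) that must not
    enter any downstream scan; excluded bins carry no values.
    """

    subjects: list[str]
    bins: pd.DataFrame
    values: np.ndarray
    excluded: np.ndarray = field(default=None)  # type: ignore[assignment]
    log_transformed: bool = False
    outliers_removed: bool = False
    water_masked: bool = False
    nonpositive_counts: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.excluded is None:
            self.excluded = np.zeros(len(self.bins), dtype=bool)
        self.excluded = np.asarray(self.excluded, dtype=bool)
        if self.values.shape != (len(self.subjects), len(self.bins)):
            raise ValueError("values shape inconsistent with subjects/bins")
        widths = self.bins["right"].to_numpy() - self.bins["left"].to_numpy()
        if len(widths) and not np.allclose(widths, widths[0], rtol=1e-6):
            raise ValueError("bins must have uniform width")
        lefts = self.bins["left"].to_numpy()
        if len(lefts) > 1 and not np.all(np.diff(lefts) > 0):
            raise ValueError("bins must be sorted and non-overlapping")

    @property
    def labels(self) -> np.ndarray:
        return self.bins["label"].to_numpy()

    @property
    def width(self) -> float:
        if not len(self.bins):
            return 0.0
        return float(self.bins["right"].iloc[0] - self.bins["left"].iloc[0])

    @property
    def n_bins(self) -> int:
        return len(self.bins)

    def active_mask(self) -> np.ndarray:
        """Bins eligible for analysis: not excluded, with at least one value."""
        return ~self.excluded & np.isfinite(self.values).any(axis=0)

    def column(self, label: float) -> np.ndarray:
        labels = self.labels
        idx = np.flatnonzero(np.isclose(labels, label, atol=1e-9))
        if idx.size == 0:
            raise KeyError(f"no bin labelled {label}")
        return self.values[:, idx[0]]

    def copy(self) -> "BinnedSpectraMatrix":
        return replace(self, values=self.values.copy(), excluded=self.excluded.copy(),
                       bins=self.bins.copy())


# --------------------------------------------------------------------------
# alignment
# --------------------------------------------------------------------------

def align_to_reference(
    grid: np.ndarray,
    spectrum: np.ndarray,
    window: tuple[float, float] = LACTATE_WINDOW,
    target: float = LACTATE_APEX,
    min_apex: float | None = None,
    subject: str | None = None,
) -> tuple[np.ndarray, float]:
    """Rigidly shift one spectrum so the window maximum sits at ``target``.

    The shift is an integer number of grid steps; vacated positions become
    NaN.  Returns ``(aligned, offset)`` where ``offset`` is the estimated
    displacement of the input (a spectrum displaced by +d yields offset -d).
    Raises :class:`AlignmentError` when the window maximum does not rise
    above a signal-presence threshold (by default five times the median
    absolute intensity of the whole spectrum, and strictly positive).
    """
    grid = np.asarray(grid, dtype=float)
    spectrum = np.asarray(spectrum, dtype=float)
    lo, hi = window
    if not (grid[0] <= lo and hi <= grid[-1]):
        raise ValueError("reference window must lie inside the ppm grid")
    sel = (grid >= lo) & (grid <= hi)
    wvals = spectrum[sel]
    finite = np.isfinite(wvals)
    if not finite.any():
        raise AlignmentError(f"no data in alignment window (subject {subject})")
    apex_local = int(np.nanargmax(wvals))
    apex_value = wvals[apex_local]
    if min_apex is None:
        med = float(np.nanmedian(np.abs(spectrum)))
        min_apex = 5.0 * med
    if not (apex_value > min_apex and apex_value > 0):
        raise AlignmentError(
            f"no reference signal above threshold in window {window}"
            + (f" for subject {subject}" if subject else "")
        )
    apex_idx = np.flatnonzero(sel)[0] + apex_local
    target_idx = int(np.argmin(np.abs(grid - target)))
    shift = target_idx - apex_idx  # grid steps to move the spectrum by
    aligned = np.full_like(spectrum, np.nan)
    if shift >= 0:
        aligned[shift:] = spectrum[: spectrum.size - shift] if shift else spectrum
    else:
        aligned[:shift] = spectrum[-shift:]
    step = float(grid[1] - grid[0])
    offset = shift * step  # correction applied: negative of the displacement
    return aligned, offset


def align_spectra(
    grid: np.ndarray,
    spectra: np.ndarray,
    window: tuple[float, float] = LACTATE_WINDOW,
    target: float = LACTATE_APEX,
    min_apex: float | None = None,
    subjects: list[str] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Align every row of a spectra matrix; returns (aligned, offsets)."""
    spectra = np.asarray(spectra, dtype=float)
    aligned = np.empty_like(spectra)
    offsets = np.empty(spectra.shape[0])
    for i in range(spectra.shape[0]):
        subj = subjects[i] if subjects is not None else str(i)
        aligned[i], offsets[i] = align_to_reference(
            grid, spectra[i], window=window, target=target,
            min_apex=min_apex, subject=subj,
        )
    return aligned, offsets


# --------------------------------------------------------------------------
# binning
# --------------------------------------------------------------------------

def bin_spectrum(
    grid: np.ndarray,
    spectra: np.ndarray,
    subjects: list[str] | None = None,
    ppm_range: tuple[float, float] = (0.0, 9.0),
    width: float = 0.001,
) -> BinnedSpectraMatrix:
    """Aggregate grid intensities into uniform half-open bins by the mean.

    The bin count is ceil(range / width) independent of the data; a bin
    containing no grid point (or only NaN) is missing for every subject.
    """
    if width <= 0:
        raise ValueError("bin width must be > 0")
    lo, hi = ppm_range
    if hi <= lo:
        raise ValueError("ppm range start must be below end")
    grid = np.asarray(grid, dtype=float)
    spectra = np.atleast_2d(np.asarray(spectra, dtype=float))
    n_bins = int(np.ceil((hi - lo) / width - 1e-9))
    lefts = lo + np.arange(n_bins) * width
    rights = lefts + width
    labels = np.round(lefts, 3)

    inside = (grid >= lo) & (grid < hi)
    idx = np.floor((grid[inside] - lo) / width + 1e-9).astype(int)
    idx = np.clip(idx, 0, n_bins - 1)
    vals = spectra[:, inside]
    finite = np.isfinite(vals)

    sums = np.zeros((spectra.shape[0], n_bins))
    counts = np.zeros((spectra.shape[0], n_bins))
    np.add.at(sums.T, idx, np.where(finite, vals, 0.0).T)
    np.add.at(counts.T, idx, finite.T.astype(float))
    with np.errstate(invalid="ignore"):
        values = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)

    points_per_bin = np.bincount(idx, minlength=n_bins)
    if n_bins and (points_per_bin == 0).mean() > 0.5:
        raise ValueError(
            "more than half of the bins contain no grid point: "
            "grid is too coarse for the requested bin width"
        )
    if subjects is None:
        subjects = [f"S{i:05d}" for i in range(spectra.shape[0])]
    bins = pd.DataFrame({"left": lefts, "right": rights, "label": labels})
    return BinnedSpectraMatrix(subjects=list(subjects), bins=bins, values=values)


# --------------------------------------------------------------------------
# cleaning
# --------------------------------------------------------------------------

def log_transform(binned: BinnedSpectraMatrix) -> BinnedSpectraMatrix:
    """log10-transform intensities; non-positive values become missing."""
    if binned.log_transformed:
        raise ValueError("matrix is already log-transformed")
    out = binned.copy()
    with np.errstate(invalid="ignore", divide="ignore"):
        nonpos = out.values <= 0
        vals = np.where(np.isfinite(out.values) & ~nonpos,
                        out.values, np.nan)
        out.values = np.log10(vals)
    out.nonpositive_counts = (nonpos & np.isfinite(binned.values)).sum(axis=0)
    out.log_transformed = True
    return out


def remove_outliers(binned: BinnedSpectraMatrix, k: float = 3.0) -> BinnedSpectraMatrix:
    """Set values more than ``k`` bin-SDs from the bin mean to missing.

    Mean and SD are computed once per bin from the pre-filter values.
    Bins with fewer than 2 non-missing values are left untouched (warning);
    a constant bin (SD 0) loses nothing.
    """
    if not binned.log_transformed:
        raise ValueError("outlier removal expects the log-transformed matrix")
    if k <= 0:
        raise ValueError("k must be > 0")
    out = binned.copy()
    vals = out.values
    finite = np.isfinite(vals)
    counts = finite.sum(axis=0)
    thin = counts < 2
    if thin.any():
        warnings.warn(f"{int(thin.sum())} bin(s) have <2 values; outlier rule skipped")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean = np.nanmean(np.where(finite, vals, np.nan), axis=0)
        sd = np.nanstd(np.where(finite, vals, np.nan), axis=0, ddof=0)
    cut = np.abs(vals - mean[None, :]) > k * sd[None, :]
    cut &= finite
    cut &= ~thin[None, :].repeat(vals.shape[0], axis=0)
    cut &= (sd > 0)[None, :]
    vals[cut] = np.nan
    out.values = vals
    out.outliers_removed = True
    return out


def mask_regions(
    binned: BinnedSpectraMatrix,
    regions: list[tuple[float, float]],
) -> BinnedSpectraMatrix:
    """Flag every bin intersecting any half-open region [lo, hi) as excluded.

    Excluded bins carry no values and never enter a downstream scan.
    """
    out = binned.copy()
    lefts = out.bins["left"].to_numpy()
    rights = out.bins["right"].to_numpy()
    for lo, hi in regions:
        if hi <= lo:
            raise ValueError(f"region ({lo}, {hi}) is empty")
        hit = (lefts < hi - 1e-12) & (rights > lo + 1e-12)
        out.excluded |= hit
    out.values[:, out.excluded] = np.nan
    out.water_masked = True
    return out


def preprocess_spectra(
    grid: np.ndarray,
    spectra: np.ndarray,
    subjects: list[str] | None = None,
    ppm_range: tuple[float, float] = (0.0, 9.0),
    width: float = 0.001,
    mask: list[tuple[float, float]] = (WATER_REGION,),
    sd_cut: float = 3.0,
    align: bool = True,
    align_window: tuple[float, float] = LACTATE_WINDOW,
) -> BinnedSpectraMatrix:
    """Full fixed-order preprocessing: align, bin, log10, de-outlier, mask."""
    if align:
        spectra, _ = align_spectra(grid, spectra, window=align_window,
                                   subjects=subjects)
    m = bin_spectrum(grid, spectra, subjects=subjects, ppm_range=ppm_range, width=width)
    m = log_transform(m)
    m = remove_outliers(m, k=sd_cut)
    m = mask_regions(m, list(mask))
    return m
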