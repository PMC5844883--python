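"""Single-cell gamma-H2AX scoring from two-channel fluorescence fields.

Nuclei are segmented in the DAPI channel by a marker-based watershed
(Gaussian smoothing, Otsu threshold, distance-transform maxima as markers),
mean gamma-H2AX intensity is measured per nucleus, cells are called
positive when their mean intensity exceeds the control mean plus one
control standard deviation (strict inequality), and foci are counted as
local maxima with a minimum separation and a minimum prominence above the
nucleus background.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage import feature, filters, measure, segmentation
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "NucleusSegmenter",
    "PositivityScorer",
    "PositivityThreshold",
    "FociDetector",
    "segment_nuclei",
    "measure_nuclei",
    "derive_threshold",
    "classify_positive",
    "detect_foci",
    "max_project",
]


def max_project(stack: np.ndarray) -> np.ndarray:
    """Per-pixel maximum across the planes of a z-stack."""
    stack = np.asarray(stack)
    if stack.ndim == 2:
        return stack.copy()
    if stack.ndim != 3 or stack.shape[0] < 1:
        raise ValueError("stack must be a non-empty 3-D array (planes, y, x)")
    return stack.max(axis=0)


def _as_gray(image: np.ndarray) -> np.ndarray:
    image = np.asarray(image)
    if image.ndim != 2:
        raise ValueError("expected a single-channel 2-D image")
    return image.astype(float)


class NucleusSegmenter(TransformerMixin, BaseEstimator):
    """Marker-based watershed segmentation of nuclei in a DAPI image.

    Pipeline: Gaussian smoothing -> global threshold (Otsu by default) ->
    Euclidean distance transform -> local-maxima markers with a minimum
    separation -> watershed on the inverted distance map -> small-region
    removal -> contiguous relabeling.

    Parameters
    ----------
    sigma : float
        Gaussian smoothing sigma in pixels.
    threshold : {"otsu"} or float
        Global foreground threshold method, or an absolute value.
    min_distance : int
        Minimum separation between watershed markers, in pixels; set near
        the expected nucleus radius.
    min_area : int
        Regions smaller than this many pixels are discarded.
    """

    def __init__(self, sigma: float = 2.0, threshold="otsu",
                 min_distance: int = 10, min_area: int = 40):
        self.sigma = sigma
        self.threshold = threshold
        self.min_distance = min_distance
        self.min_area = min_area

    def fit(self, X=None, y=None):
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        return self.segment(X)

    def segment(self, dapi: np.ndarray) -> np.ndarray:
        """Return an integer label map (0 = background)."""
        img = _as_gray(dapi)
        if img.max() == img.min():  # blank or constant field
            return np.zeros(img.shape, dtype=np.int32)
        smooth = filters.gaussian(img, sigma=self.sigma, preserve_range=True)
        if self.threshold == "otsu":
            thr = filters.threshold_otsu(smooth)
        else:
            thr = float(self.threshold)
        mask = smooth > thr
        if not mask.any():
            return np.zeros(img.shape, dtype=np.int32)
        distance = ndi.distance_transform_edt(mask)
        peaks = feature.peak_local_max(
            distance, min_distance=self.min_distance, labels=mask,
            exclude_border=False)
        markers = np.zeros(img.shape, dtype=np.int32)
        markers[tuple(peaks.T)] = np.arange(1, len(peaks) + 1)
        labels = segmentation.watershed(-distance, markers, mask=mask)
        return _drop_small(labels, self.min_area)


def _drop_small(labels: np.ndarray, min_area: int) -> np.ndarray:
    out = labels.copy()
    ids, counts = np.unique(out[out > 0], return_counts=True)
    for lab, cnt in zip(ids, counts):
        if cnt < min_area:
            out[out == lab] = 0
    # relabel contiguously, preserving region order
    remaining = np.unique(out[out > 0])
    lut = np.zeros(out.max() + 1 if out.size else 1, dtype=np.int32)
    lut[remaining] = np.arange(1, len(remaining) + 1)
    return lut[out]


def segment_nuclei(dapi: np.ndarray, sigma: float = 2.0, threshold="otsu",
                   min_distance: int = 10, min_area: int = 40) -> np.ndarray:
    """Functional wrapper over :class:`NucleusSegmenter`."""
    return NucleusSegmenter(sigma=sigma, threshold=threshold,
                            min_distance=min_distance,
                            min_area=min_area).segment(dapi)


def measure_nuclei(labels: np.ndarray, channel: np.ndarray) -> pd.DataFrame:
    """Per-nucleus area, centroid and mean channel intensity.

    Returns one row per label with columns ``label``, ``area``,
    ``centroid_y``, ``centroid_x``, ``mean_intensity``.
    """
    labels = np.asarray(labels)
    channel = _as_gray(channel)
    if labels.shape != channel.shape:
        raise ValueError("label map and channel must have the same shape")
    props = measure.regionprops(labels, intensity_image=channel)
    return pd.DataFrame([
        {"label": p.label, "area": int(p.area),
         "centroid_y": float(p.centroid[0]), "centroid_x": float(p.centroid[1]),
         "mean_intensity": float(p.intensity_mean)}
        for p in props
    ], columns=["label", "area", "centroid_y", "centroid_x", "mean_intensity"])


@dataclass(frozen=True)
class PositivityThreshold:
    """Control-derived positivity cutoff: control mean + 1 control SD."""

    control_mean: float
    control_sd: float
    n_control_cells: int

    @property
    def threshold(self) -> float:
        return self.control_mean + self.control_sd


class PositivityScorer(BaseEstimator):
    """Mean + 1 SD positivity classifier fitted on control (DMSO) cells.

    ``fit`` learns the control mean and sample standard deviation of
    per-nucleus mean intensities; ``predict`` flags cells strictly above
    ``mean + n_sd * sd``.

    Parameters
    ----------
    n_sd : float, default 1.0
        Number of control standard deviations above the control mean.
    """

    def __init__(self, n_sd: float = 1.0):
        self.n_sd = n_sd

    def fit(self, X, y=None):
        x = np.ravel(np.asarray(X, dtype=float))
        if x.size < 2:
            raise ValueError("need >= 2 control cells to derive a threshold")
        self.control_mean_ = float(x.mean())
        self.control_sd_ = float(x.std(ddof=1))
        self.threshold_ = self.control_mean_ + self.n_sd * self.control_sd_
        self.n_control_cells_ = int(x.size)
        return self

    def predict(self, X) -> np.ndarray:
        x = np.ravel(np.asarray(X, dtype=float))
        return x > self.threshold_  # strict: "higher than" the cutoff

    def percent_positive(self, X) -> float:
        x = np.ravel(np.asarray(X, dtype=float))
        if x.size == 0:
            raise ValueError("percent positive undefined for an empty population")
        return 100.0 * float(self.predict(x).mean())


def derive_threshold(control_intensities) -> PositivityThreshold:
    """Mean + 1 sample SD of control per-nucleus mean intensities."""
    s = PositivityScorer().fit(control_intensities)
    return PositivityThreshold(control_mean=s.control_mean_,
                               control_sd=s.control_sd_,
                               n_control_cells=s.n_control_cells_)


def classify_positive(records: pd.DataFrame,
                      threshold: PositivityThreshold) -> tuple[pd.DataFrame, float]:
    """Flag nuclei whose mean intensity strictly exceeds the threshold.

    Returns the records with a ``positive`` column plus the percent positive.
    """
    if records.empty:
        raise ValueError("percent positive undefined for an empty record table")
    out = records.copy()
    out["positive"] = out["mean_intensity"].to_numpy(float) > threshold.threshold
    return out, 100.0 * float(out["positive"].mean())


class FociDetector(BaseEstimator):
    """Per-nucleus focus counting by local-maxima detection.

    The channel is first smoothed with a small Gaussian (a matched filter
    for diffraction-limited spots, which suppresses single-pixel noise
    maxima); a focus is then a local maximum inside a nucleus mask, at
    least ``min_distance`` pixels from any brighter maximum, whose smoothed
    value exceeds the nucleus background (median smoothed intensity inside
    the mask) by at least ``prominence``.  The default prominence is 3x a
    robust (MAD-based) estimate of the raw-image noise SD.

    Counts are monotone non-increasing in prominence.
    """

    def __init__(self, min_distance: int = 3, prominence: float | None = None,
                 smooth_sigma: float = 1.0):
        self.min_distance = min_distance
        self.prominence = prominence
        self.smooth_sigma = smooth_sigma

    def detect(self, channel: np.ndarray,
               labels: np.ndarray) -> tuple[pd.DataFrame, pd.DataFrame]:
        """Return (foci table, per-nucleus counts).

        Foci table columns: ``label``, ``y``, ``x``, ``peak_intensity``
        (raw value at the peak), ``area`` (pixels above half-prominence
        around the peak, an area proxy).  Counts table: ``label``,
        ``foci_count``.
        """
        channel = _as_gray(channel)
        labels = np.asarray(labels)
        if labels.shape != channel.shape:
            raise ValueError("label map and channel must have the same shape")
        prom = self.prominence
        if prom is None:
            mad = np.median(np.abs(channel - np.median(channel)))
            prom = 3.0 * 1.4826 * mad
        smooth = (filters.gaussian(channel, sigma=self.smooth_sigma,
                                   preserve_range=True)
                  if self.smooth_sigma > 0 else channel)
        foci_rows = []
        label_ids = np.unique(labels[labels > 0])
        for lab in label_ids:
            mask = labels == lab
            background = float(np.median(smooth[mask]))
            peaks = feature.peak_local_max(
                np.where(mask, smooth, -np.inf),
                min_distance=self.min_distance,
                threshold_abs=background + prom if prom > 0 else None,
                exclude_border=False)
            for y, x in peaks:
                peak_val = float(smooth[y, x])
                if prom > 0 and not peak_val > background + prom:
                    continue
                half = background + (peak_val - background) / 2.0
                area = _peak_area(smooth, mask, (y, x), half)
                foci_rows.append({"label": int(lab), "y": int(y), "x": int(x),
                                  "peak_intensity": float(channel[y, x]),
                                  "area": area})
        foci = pd.DataFrame(foci_rows,
                            columns=["label", "y", "x", "peak_intensity", "area"])
        counts = pd.DataFrame({
            "label": label_ids.astype(int),
            "foci_count": [int((foci["label"] == lab).sum()) for lab in label_ids],
        })
        return foci, counts


def _peak_area(channel: np.ndarray, mask: np.ndarray, peak: tuple[int, int],
               level: float) -> int:
    """Size of the connected above-half-maximum region containing the peak."""
    above = (channel > level) & mask
    lab, _ = ndi.label(above)
    region = lab[peak]
    return int((lab == region).sum()) if region > 0 else 1


def detect_foci(channel: np.ndarray, labels: np.ndarray, min_distance: int = 3,
                prominence: float | None = None,
                smooth_sigma: float = 1.0) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Functional wrapper over :class:`FociDetector`."""
    return FociDetector(min_distance=min_distance, prominence=prominence,
                        smooth_sigma=smooth_sigma).detect(channel, labels)
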