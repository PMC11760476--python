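"""3PN classification: 46XX / 46XY / 69XXX / 69XXY decision tree.

Routing follows the Y chromosome: a sample showing homozygous chrY calls is
tested for 69XXY by comparing its chrX mean LRR to euploid-library bounds
(one X copy -> 46XY, two -> 69XXY); all other samples are tested for 69XXX
by the autosomal BAF mass in the 0.2-0.3 and 0.7-0.8 windows, where the
triploid heterozygote clusters at 1/3 and 2/3 shed mass that a diploid
(clusters at 0, 1/2, 1) does not. Both proportions strictly below the
euploid cut-offs mean 46XX; both at or above mean 69XXX; anything mixed or
between the LRR bounds is reported indeterminate rather than guessed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin

from .core import CALL_AB, CALL_NC, EuploidLibrary, SNPSample
from .heterozygosity import DegenerateInputError
from .thresholds import ThresholdsConfig


class CalibrationError(ValueError):
    """Raised when the euploid library's chrX LRR distributions overlap."""


class XLrrBounds(NamedTuple):
    one_copy_max: float  # max chrX mean LRR over 46XY library samples
    two_copy_min: float  # min chrX mean LRR over 46XX library samples


@dataclass
class TriploidyCall:
    """Decision-tree outcome with the intermediate statistics retained."""

    sample_id: str
    y_homozygous: bool
    n_y_called: int
    y_hom_fraction: Optional[float]
    chrx_mean_lrr: Optional[float]
    x_copies: Union[int, str, None]  # 1, 2, 'indeterminate', or None (unrouted)
    baf_prop_low: Optional[float]
    baf_prop_high: Optional[float]
    ploidy_class: str  # 46XX / 46XY / 69XXX / 69XXY / indeterminate


def y_homozygosity(sample: SNPSample, thresholds: ThresholdsConfig) -> Tuple[bool, dict]:
    """Y-presence gate: enough called chrY markers, mostly homozygous.

    True iff the number of called chrY markers is at least
    ``y_min_called`` and the homozygous fraction among them is at least
    ``y_hom_min_fraction``. Returns the flag plus diagnostics.
    """
    y = sample.manifest.is_y
    if not y.any():
        raise ValueError("manifest has no chrY markers; Y gate unavailable")
    calls = sample.calls[y]
    called = calls != CALL_NC
    n_called = int(called.sum())
    hom_frac = None
    flag = False
    if n_called >= thresholds.y_min_called:
        hom_frac = float((calls[called] != CALL_AB).mean())
        flag = hom_frac >= thresholds.y_hom_min_fraction
    elif n_called > 0:
        hom_frac = float((calls[called] != CALL_AB).mean())
    return flag, {"n_y_called": n_called, "y_hom_fraction": hom_frac}


def chrx_mean_lrr(sample: SNPSample) -> float:
    """Arithmetic mean of non-missing chrX LRR values."""
    lrr = sample.lrr[sample.manifest.is_x]
    lrr = lrr[np.isfinite(lrr)]
    if lrr.size == 0:
        raise DegenerateInputError(
            f"sample {sample.sample_id}: no chrX LRR values"
        )
    return float(lrr.mean())


def calibrate_x_lrr(library: EuploidLibrary) -> XLrrBounds:
    """Library calibration of the chrX LRR copy-number bounds.

    The one-copy bound is the maximum chrX mean LRR over the 46XY samples;
    the two-copy bound is the minimum over the 46XX samples. The two
    distributions must be distinct and not overlap, otherwise calibration
    fails.
    """
    xy = library.by_sex("46XY")
    xx = library.by_sex("46XX")
    if not xy or not xx:
        raise CalibrationError("library must contain both 46XY and 46XX samples")
    one_copy_max = max(chrx_mean_lrr(s) for s in xy)
    two_copy_min = min(chrx_mean_lrr(s) for s in xx)
    if not one_copy_max < two_copy_min:
        raise CalibrationError(
            f"euploid chrX LRR distributions overlap "
            f"(46XY max {one_copy_max:.6f} >= 46XX min {two_copy_min:.6f})"
        )
    return XLrrBounds(one_copy_max, two_copy_min)


def classify_x_copies(mean_lrr: float, bounds: XLrrBounds) -> Union[int, str]:
    """chrX copy count from mean LRR: <= one_copy_max -> 1, >= two_copy_min
    -> 2, strictly between -> ``'indeterminate'``."""
    if mean_lrr <= bounds.one_copy_max:
        return 1
    if mean_lrr >= bounds.two_copy_min:
        return 2
    return "indeterminate"


def baf_window_proportions(
    sample: SNPSample, thresholds: ThresholdsConfig
) -> Tuple[float, float]:
    """Fractions of non-missing autosomal BAF values inside the two windows
    (closed intervals; denominator = all non-missing autosomal BAF)."""
    baf = sample.baf[sample.manifest.is_autosomal]
    baf = baf[np.isfinite(baf)]
    if baf.size == 0:
        raise DegenerateInputError(
            f"sample {sample.sample_id}: no autosomal BAF values"
        )
    lo_a, lo_b = thresholds.baf_window_low
    hi_a, hi_b = thresholds.baf_window_high
    prop_low = float(((baf >= lo_a) & (baf <= lo_b)).mean())
    prop_high = float(((baf >= hi_a) & (baf <= hi_b)).mean())
    return prop_low, prop_high


def calibrate_baf_cutoffs(
    library: EuploidLibrary, thresholds: ThresholdsConfig
) -> Tuple[float, float]:
    """Library-specific alternative to the published BAF cut-offs: the
    maximum window proportions observed over the euploid library.

    This is a convenience for re-calibrating on a new platform; the shipped
    defaults (0.0589 / 0.0431) are the published operating points and are
    what the decision tree uses unless overridden.
    """
    props = [baf_window_proportions(s, thresholds) for s in library.samples]
    return (max(p for p, _ in props), max(q for _, q in props))


def classify_3pn(
    sample: SNPSample,
    thresholds: ThresholdsConfig,
    bounds: Optional[XLrrBounds] = None,
) -> TriploidyCall:
    """Run the full 3PN decision tree on one sample.

    ``bounds`` defaults to the explicit chrX LRR bounds in ``thresholds``;
    pass the output of :func:`calibrate_x_lrr` to use library calibration.
    Both branches' statistics are computed for diagnostics, but only the
    routed branch determines the class.
    """
    if bounds is None:
        if not thresholds.has_x_bounds:
            raise CalibrationError(
                "thresholds request calibration but no bounds were supplied"
            )
        bounds = XLrrBounds(
            float(thresholds.x_lrr_one_copy_max),
            float(thresholds.x_lrr_two_copy_min),
        )

    y_hom, y_diag = y_homozygosity(sample, thresholds)
    try:
        mean_lrr = chrx_mean_lrr(sample)
    except DegenerateInputError:
        mean_lrr = None
    try:
        prop_low, prop_high = baf_window_proportions(sample, thresholds)
    except DegenerateInputError:
        prop_low = prop_high = None

    x_copies: Union[int, str, None] = None
    if y_hom:
        if mean_lrr is None:
            label = "indeterminate"
        else:
            x_copies = classify_x_copies(mean_lrr, bounds)
            label = {1: "46XY", 2: "69XXY"}.get(x_copies, "indeterminate")
    else:
        if prop_low is None:
            label = "indeterminate"
        else:
            below_low = prop_low < thresholds.baf_cut_low
            below_high = prop_high < thresholds.baf_cut_high
            if below_low and below_high:
                label = "46XX"
            elif not below_low and not below_high:
                label = "69XXX"
            else:
                label = "indeterminate"

    return TriploidyCall(
        sample_id=sample.sample_id,
        y_homozygous=y_hom,
        n_y_called=y_diag["n_y_called"],
        y_hom_fraction=y_diag["y_hom_fraction"],
        chrx_mean_lrr=mean_lrr,
        x_copies=x_copies,
        baf_prop_low=prop_low,
        baf_prop_high=prop_high,
        ploidy_class=label,
    )


def calls_to_frame(calls: Sequence[TriploidyCall]) -> pd.DataFrame:
    return pd.DataFrame([vars(c) for c in calls])


class TriploidyDecisionTree(ClassifierMixin, BaseEstimator):
    """Sklearn-style estimator for the 3PN decision tree.

    ``fit`` calibrates the chrX LRR bounds from a euploid library
    (``X`` = samples, ``y`` = '46XX'/'46XY' labels); fitting without a
    library adopts the explicit bounds in ``thresholds`` (the published
    values by default). ``predict`` maps samples to
    46XX/46XY/69XXX/69XXY/indeterminate.
    """

    def __init__(self, thresholds: Optional[ThresholdsConfig] = None):
        self.thresholds = thresholds

    def fit(self, X: Optional[Sequence[SNPSample]] = None, y=None):
        thr = self.thresholds or ThresholdsConfig()
        if X is not None and len(X) > 0:
            if y is None:
                raise ValueError("library sex labels (y) required with samples")
            library = EuploidLibrary(list(X), list(y))
            self.x_bounds_ = calibrate_x_lrr(library)
        else:
            if not thr.has_x_bounds:
                raise CalibrationError(
                    "no library given and thresholds request calibration"
                )
            self.x_bounds_ = XLrrBounds(
                float(thr.x_lrr_one_copy_max), float(thr.x_lrr_two_copy_min)
            )
        self.thresholds_ = thr.with_x_bounds(*self.x_bounds_)
        self.classes_ = np.array(
            ["46XX", "46XY", "69XXX", "69XXY", "indeterminate"]
        )
        return self

    def decision_table(self, X: Sequence[SNPSample]) -> pd.DataFrame:
        from sklearn.utils.validation import check_is_fitted

        check_is_fitted(self, "x_bounds_")
        return calls_to_frame(
            [classify_3pn(s, self.thresholds_, self.x_bounds_) for s in X]
        )

    def predict(self, X: Sequence[SNPSample]) -> np.ndarray:
        return self.decision_table(X)["ploidy_class"].to_numpy()
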