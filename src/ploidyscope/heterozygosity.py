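"""Haploid/diploid classification of 0PN/1PN biopsies from the AB rate.

A haploid genome has no heterozygous loci, so its apparent AB rate sits at
the platform noise floor (~5% mis-calls, of which about half land on AB),
while a diploid biopsy on an informative-marker chip shows an AB rate well
above 18%. Classification is a two-threshold step function of the overall
heterozygosity rate; the gap between the thresholds is reported as
``indeterminate``, never silently coerced.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence, Union

import numpy as np
from scipy.cluster.hierarchy import leaves_list, linkage
from sklearn.base import BaseEstimator, ClassifierMixin

from .core import CALL_AB, CALL_NC, SNPSample
from .manifest import CHROMOSOMES, MarkerManifest
from .thresholds import ThresholdsConfig

HAPLOID = "haploid"
DIPLOID = "diploid"
INDETERMINATE = "indeterminate"


class DegenerateInputError(ValueError):
    """Raised when a computation has an empty denominator."""


@dataclass
class ABResult:
    """Per-sample heterozygosity summary and (optionally) its class."""

    sample_id: str
    n_called: int
    n_ab: int
    ab_rate: float
    call_rate: float
    qc_pass: Optional[bool] = None
    ploidy_class: Optional[str] = None


def compute_ab_rate(
    sample: SNPSample, marker_scope: Union[str, Iterable[str]] = "all"
) -> ABResult:
    """Heterozygosity rate of a sample over a chromosome scope.

    The default scope is every chromosome (the overall AB rate); pass
    ``'autosomes'`` or chromosome labels to restrict it. The denominator is
    the number of called (non-NC) markers in scope.
    """
    mask = sample.manifest.scope_mask(marker_scope)
    calls = sample.calls[mask]
    called = calls != CALL_NC
    n_called = int(called.sum())
    if n_called == 0:
        raise DegenerateInputError(
            f"sample {sample.sample_id}: no called markers in scope"
        )
    n_ab = int((calls == CALL_AB).sum())
    return ABResult(
        sample_id=sample.sample_id,
        n_called=n_called,
        n_ab=n_ab,
        ab_rate=n_ab / n_called,
        call_rate=n_called / int(mask.sum()),
    )


def classify_ab(ab_rate: float, thresholds: ThresholdsConfig) -> str:
    """Two-threshold step classification of an AB rate.

    <= ``ab_haploid_max`` is haploid, >= ``ab_diploid_min`` diploid, and the
    open interval between them indeterminate.
    """
    if not 0.0 <= ab_rate <= 1.0:
        raise ValueError(f"ab_rate must lie in [0, 1], got {ab_rate}")
    if ab_rate <= thresholds.ab_haploid_max:
        return HAPLOID
    if ab_rate >= thresholds.ab_diploid_min:
        return DIPLOID
    return INDETERMINATE


def qc_sample(
    sample: SNPSample,
    thresholds: ThresholdsConfig,
    truth_calls: Optional[np.ndarray] = None,
) -> dict:
    """Sample-level QC: call rate, and ADO/mis-call estimates when a truth
    (or replicate-consensus) call vector is available.

    The ADO estimate is the fraction of truly heterozygous, called markers
    read as homozygous; the mis-call estimate is the discordance on truly
    homozygous, called markers. Metrics without data are reported as None
    (not evaluated) and do not affect the pass flag; the flag is the AND of
    every evaluated metric against ``thresholds.qc_ranges``.
    """
    metrics: dict[str, Optional[float]] = {
        "call_rate": sample.call_rate,
        "ado_rate": None,
        "miscall_rate": None,
    }
    if truth_calls is not None:
        truth_calls = np.asarray(truth_calls, dtype=np.int8)
        if truth_calls.shape != sample.calls.shape:
            raise ValueError("truth_calls must align to the sample")
        called = (sample.calls != CALL_NC) & (truth_calls != CALL_NC)
        het = called & (truth_calls == CALL_AB)
        hom = called & (truth_calls != CALL_AB)
        if het.any():
            metrics["ado_rate"] = float(
                (sample.calls[het] != CALL_AB).mean()
            )
        if hom.any():
            metrics["miscall_rate"] = float(
                (sample.calls[hom] != truth_calls[hom]).mean()
            )
    qc_pass = True
    checks = {}
    for name, (lo, hi) in thresholds.qc_ranges.items():
        value = metrics.get(name)
        if value is None:
            checks[name] = None
        else:
            ok = lo <= value <= hi
            checks[name] = ok
            qc_pass &= ok
    return {"sample_id": sample.sample_id, "metrics": metrics,
            "checks": checks, "qc_pass": qc_pass}


def per_chromosome_ab_rates(sample: SNPSample) -> np.ndarray:
    """AB rate per chromosome (24-vector; 0 where no called markers)."""
    rates = np.zeros(len(CHROMOSOMES))
    for j, chrom in enumerate(CHROMOSOMES):
        calls = sample.calls[sample.manifest.chrom == chrom]
        called = calls != CALL_NC
        if called.any():
            rates[j] = (calls == CALL_AB).sum() / called.sum()
    return rates


@dataclass
class ClusterResult:
    linkage_matrix: np.ndarray
    sample_ids: list[str]
    leaf_order: list[str]
    features: np.ndarray

    def cut(self, n_clusters: int) -> np.ndarray:
        from scipy.cluster.hierarchy import fcluster

        return fcluster(self.linkage_matrix, n_clusters, criterion="maxclust")


def cluster_samples(
    samples: Sequence[SNPSample], linkage_method: str = "average"
) -> ClusterResult:
    """Unsupervised hierarchical clustering of samples on per-chromosome AB
    rates (Euclidean distance, average linkage by default).

    Haploid and diploid biopsies separate at the 2-cluster cut regardless of
    pronuclear scoring, which is the visual check behind the heatmap view of
    the cohort. Leaf order is deterministic given the input order (scipy's
    tie-breaking is by cluster index).
    """
    if len(samples) < 2:
        raise ValueError("clustering needs at least 2 samples")
    features = np.vstack([per_chromosome_ab_rates(s) for s in samples])
    Z = linkage(features, method=linkage_method, metric="euclidean")
    ids = [s.sample_id for s in samples]
    order = [ids[i] for i in leaves_list(Z)]
    return ClusterResult(Z, ids, order, features)


class HeterozygosityPloidyClassifier(ClassifierMixin, BaseEstimator):
    """Sklearn-style estimator wrapping the AB-rate step classifier.

    Parameters mirror the thresholds config: ``haploid_max`` (default 0.05)
    and ``diploid_min`` (default 0.18); ``scope`` selects the chromosomes
    entering the overall AB rate. ``X`` may be a sequence of
    :class:`SNPSample` or a 1-d/column array of precomputed AB rates.
    """

    def __init__(self, haploid_max: float = 0.05, diploid_min: float = 0.18,
                 scope: str = "all"):
        self.haploid_max = haploid_max
        self.diploid_min = diploid_min
        self.scope = scope

    def _thresholds(self) -> ThresholdsConfig:
        from .thresholds import ThresholdsConfig

        return ThresholdsConfig(
            ab_haploid_max=self.haploid_max, ab_diploid_min=self.diploid_min
        )

    def fit(self, X=None, y=None):
        """Validate parameters; the classifier has no free parameters to learn."""
        self.thresholds_ = self._thresholds()
        self.classes_ = np.array([DIPLOID, HAPLOID, INDETERMINATE])
        return self

    def ab_rates(self, X) -> np.ndarray:
        if len(X) and isinstance(X[0], SNPSample):
            return np.array(
                [compute_ab_rate(s, self.scope).ab_rate for s in X]
            )
        arr = np.asarray(X, dtype=float)
        return arr.ravel()

    def predict(self, X) -> np.ndarray:
        from sklearn.utils.validation import check_is_fitted

        check_is_fitted(self, "thresholds_")
        rates = self.ab_rates(X)
        return np.array([classify_ab(r, self.thresholds_) for r in rates])

    def results(self, samples: Sequence[SNPSample],
                thresholds: Optional[ThresholdsConfig] = None) -> list[ABResult]:
        """Full :class:`ABResult` per sample (rates, QC flag and class)."""
        from sklearn.utils.validation import check_is_fitted

        check_is_fitted(self, "thresholds_")
        thr = thresholds or self.thresholds_
        out = []
        for s in samples:
            res = compute_ab_rate(s, self.scope)
            res.ploidy_class = classify_ab(res.ab_rate, thr)
            res.qc_pass = qc_sample(s, thr)["qc_pass"]
            out.append(res)
        return out
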