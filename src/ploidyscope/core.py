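"""Core domain types: genotype calls, samples, ploidy states, noise model.

Genotype calls are stored as int8 codes (``CALL_AA``/``CALL_AB``/``CALL_BB``
and ``CALL_NC`` for no-calls); BAF and LRR are float64 vectors with NaN for
missing values. All three vectors are aligned to one :class:`MarkerManifest`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np

from .manifest import MarkerManifest

CALL_NC = np.int8(-1)
CALL_AA = np.int8(0)
CALL_AB = np.int8(1)
CALL_BB = np.int8(2)

CALL_TO_STR = {-1: "NC", 0: "AA", 1: "AB", 2: "BB"}
STR_TO_CALL = {v: np.int8(k) for k, v in CALL_TO_STR.items()}


def calls_from_strings(strings: Sequence[str]) -> np.ndarray:
    """Convert ``['AA', 'AB', ...]`` to the int8 call-code vector."""
    try:
        return np.array([STR_TO_CALL[s] for s in strings], dtype=np.int8)
    except KeyError as exc:
        raise ValueError(f"unknown genotype string: {exc.args[0]!r}") from None


@dataclass(frozen=True)
class PloidyState:
    """A whole-genome ploidy configuration.

    ``autosome_copies``, ``x_copies`` and ``y_copies`` give the copy number on
    each chromosome class; ``maternal_copies``/``paternal_copies`` record the
    parental contribution to the total set count (metadata only — the marker
    statistics never depend on parent of origin).
    """

    label: str
    maternal_copies: int
    paternal_copies: int
    autosome_copies: int
    x_copies: int
    y_copies: int

    @property
    def total_copies(self) -> int:
        return self.maternal_copies + self.paternal_copies


#: The five ploidy states the classifiers distinguish. Triploids are modelled
#: with a digynic 69XXX and a diandric 69XXY by convention; only the copy
#: numbers matter downstream.
PLOIDY_STATES: Mapping[str, PloidyState] = {
    "23X": PloidyState("23X", 1, 0, autosome_copies=1, x_copies=1, y_copies=0),
    "46XX": PloidyState("46XX", 1, 1, autosome_copies=2, x_copies=2, y_copies=0),
    "46XY": PloidyState("46XY", 1, 1, autosome_copies=2, x_copies=1, y_copies=1),
    "69XXX": PloidyState("69XXX", 2, 1, autosome_copies=3, x_copies=3, y_copies=0),
    "69XXY": PloidyState("69XXY", 1, 2, autosome_copies=3, x_copies=2, y_copies=1),
}


def get_state(label: str) -> PloidyState:
    try:
        return PLOIDY_STATES[label]
    except KeyError:
        raise ValueError(
            f"unknown ploidy state {label!r}; known: {sorted(PLOIDY_STATES)}"
        ) from None


@dataclass(frozen=True)
class NoiseModel:
    """Per-marker noise parameters of the simulated beadchip assay.

    ado_rate:
        Allele-dropout probability — a heterozygous call collapses to a random
        homozygote.
    miscall_rate:
        Probability a called genotype is replaced by one of the two wrong
        genotypes (default 0.05, the platform noise floor that motivates the
        5% haploid threshold).
    nocall_rate:
        Probability a called marker is emitted as NC.
    baf_sd:
        Gaussian spread of BAF around the allelic-dosage expectation,
        truncated to [0, 1].
    lrr_sd:
        Gaussian spread of per-marker LRR around its copy-number mean.
    chrx_lrr_mean_{1,2,3}copy:
        Mean chrX LRR for one/two/three X copies; one-copy mean must lie
        below the two-copy mean for library calibration to be possible.
    y_stray_call_rate:
        Rate at which chrY markers in Y-less samples emit a spurious call
        (uniform over AA/AB/BB) instead of NC.
    """

    ado_rate: float = 0.05
    miscall_rate: float = 0.05
    nocall_rate: float = 0.02
    baf_sd: float = 0.05
    lrr_sd: float = 0.25
    chrx_lrr_mean_1copy: float = -1.20
    chrx_lrr_mean_2copy: float = -0.90
    chrx_lrr_mean_3copy: float = -0.70
    y_stray_call_rate: float = 0.01

    def __post_init__(self):
        for name in ("ado_rate", "miscall_rate", "nocall_rate",
                     "y_stray_call_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        for name in ("baf_sd", "lrr_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not self.chrx_lrr_mean_1copy < self.chrx_lrr_mean_2copy:
            raise ValueError(
                "chrx_lrr_mean_1copy must be below chrx_lrr_mean_2copy "
                "(the calibration contract requires separation)"
            )

    def x_lrr_mean(self, x_copies: int) -> float:
        return {
            1: self.chrx_lrr_mean_1copy,
            2: self.chrx_lrr_mean_2copy,
            3: self.chrx_lrr_mean_3copy,
        }[x_copies]


@dataclass
class SNPSample:
    """One biopsy's per-marker genotype calls, BAF and LRR.

    All vectors are aligned to ``manifest`` (same length, same order). BAF and
    LRR are NaN wherever missing; by convention they are missing at NC
    markers.
    """

    sample_id: str
    manifest: MarkerManifest = field(repr=False)
    calls: np.ndarray = field(repr=False)
    baf: np.ndarray = field(repr=False)
    lrr: np.ndarray = field(repr=False)
    truth_label: Optional[str] = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        n = len(self.manifest)
        self.calls = np.asarray(self.calls, dtype=np.int8)
        self.baf = np.asarray(self.baf, dtype=float)
        self.lrr = np.asarray(self.lrr, dtype=float)
        for name in ("calls", "baf", "lrr"):
            v = getattr(self, name)
            if v.shape != (n,):
                raise ValueError(
                    f"{name} has shape {v.shape}, expected ({n},) to match manifest"
                )
        if not np.isin(self.calls, [-1, 0, 1, 2]).all():
            raise ValueError("calls contain codes outside {NC, AA, AB, BB}")
        finite = self.baf[np.isfinite(self.baf)]
        if finite.size and (finite.min() < 0 or finite.max() > 1):
            raise ValueError("BAF values must lie in [0, 1]")

    @property
    def is_called(self) -> np.ndarray:
        return self.calls != CALL_NC

    @property
    def call_rate(self) -> float:
        return float(self.is_called.mean()) if len(self.calls) else 0.0

    def calls_as_strings(self) -> list[str]:
        return [CALL_TO_STR[int(c)] for c in self.calls]

    def __len__(self) -> int:
        return len(self.calls)


def samples_equal(a: SNPSample, b: SNPSample, *, atol: float = 0.0) -> bool:
    """Field-wise equality of two samples (NaN-aware, optional float slack)."""
    if a.sample_id != b.sample_id or len(a) != len(b):
        return False
    if not np.array_equal(a.manifest.marker_ids, b.manifest.marker_ids):
        return False
    if not np.array_equal(a.calls, b.calls):
        return False
    for x, y in ((a.baf, b.baf), (a.lrr, b.lrr)):
        if not np.array_equal(np.isnan(x), np.isnan(y)):
            return False
        ok = np.isfinite(x)
        if not np.allclose(x[ok], y[ok], atol=atol, rtol=0.0):
            return False
    return True


@dataclass
class EuploidLibrary:
    """Reference collection of known 46XX/46XY samples used for calibration."""

    samples: list[SNPSample]
    sex_labels: list[str]

    def __post_init__(self):
        if len(self.samples) != len(self.sex_labels):
            raise ValueError("samples and sex_labels differ in length")
        bad = set(self.sex_labels) - {"46XX", "46XY"}
        if bad:
            raise ValueError(f"sex labels must be 46XX/46XY, got {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.samples)

    def by_sex(self, sex: str) -> list[SNPSample]:
        return [s for s, lab in zip(self.samples, self.sex_labels) if lab == sex]
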