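"""Synthetic SNP-beadchip data with the statistical structure the ploidy
classifiers assume.

The generative model is Hardy–Weinberg per marker: each of the state's
chromosome copies carries the B allele independently with the marker's
population B-allele frequency, so the B-allele dosage ``d`` at a marker with
``c`` copies is Binomial(c, p). The genotype call is AA/BB at the dosage
extremes and AB otherwise; the BAF expectation is ``d / c`` (0, 1/2, 1 for
diploids; 0, 1/3, 2/3, 1 for triploids; 0 or 1 for haploids) perturbed by
Gaussian noise truncated to [0, 1]. LRR is drawn around 0 everywhere except
chrX, whose mean encodes the X copy number. Assay noise is applied in the
fixed order allele dropout -> mis-call -> no-call; every noise stage draws a
full-length random vector so that raising one rate with a fixed seed only
enlarges that stage's affected set (the coupling behind the monotonicity
properties).

chrY markers of samples without a Y chromosome are no-calls apart from a
small stray-call rate whose genotype is uniform over AA/AB/BB — a realistic
false-signal floor for the Y-homozygosity gate.
"""

from __future__ import annotations

from typing import Callable, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .core import (
    CALL_AA,
    CALL_AB,
    CALL_BB,
    CALL_NC,
    EuploidLibrary,
    NoiseModel,
    PloidyState,
    SNPSample,
    get_state,
)
from .manifest import AUTOSOMES, MarkerManifest, concat_positions

#: cohort class name -> (truth ploidy group, aneuploidy label)
COHORT_CLASSES: Mapping[str, Tuple[str, str]] = {
    "diploid_euploid": ("diploid", "euploid"),
    "diploid_aneuploid": ("diploid", "aneuploid"),
    "diploid": ("diploid", "euploid"),
    "haploid": ("haploid", "unknown"),
    "triploid": ("triploid", "euploid"),
    "triploid_aneuploid": ("triploid", "aneuploid"),
}

_GROUP_STATES = {
    "diploid": ("46XX", "46XY"),
    "haploid": ("23X",),
    "triploid": ("69XXX", "69XXY"),
}


def _child_seeds(seed: int, n: int) -> np.ndarray:
    """Derive n reproducible child seeds (< 2**31) from one run seed."""
    return np.random.SeedSequence(seed).generate_state(n) & 0x7FFFFFFF


def make_manifest(
    n_autosomal: int,
    n_x: int,
    n_y: int,
    seed: int,
    pop_b_freq_sampler: Optional[Callable[[np.random.Generator, int], np.ndarray]] = None,
) -> MarkerManifest:
    """Build a random marker manifest spread over 22 autosomes + X + Y.

    Autosomal markers are spread as evenly as possible over chromosomes 1-22.
    ``pop_b_freq_sampler(rng, n)`` draws the population B-allele frequencies;
    the default is uniform on [0.2, 0.8], reflecting a beadchip designed
    around informative (high-MAF) markers.
    """
    for name, v in (("n_autosomal", n_autosomal), ("n_x", n_x), ("n_y", n_y)):
        if v < 1:
            raise ValueError(f"{name} must be >= 1, got {v}")
    rng = np.random.default_rng(seed)

    per = np.full(22, n_autosomal // 22, dtype=int)
    per[: n_autosomal % 22] += 1
    chroms = np.concatenate(
        [np.repeat(c, k) for c, k in zip(AUTOSOMES, per)]
        + [np.repeat("X", n_x), np.repeat("Y", n_y)]
    )
    pos = concat_positions(chroms, rng)
    if pop_b_freq_sampler is None:
        pbf = rng.uniform(0.2, 0.8, size=len(chroms))
    else:
        pbf = np.asarray(pop_b_freq_sampler(rng, len(chroms)), dtype=float)
    table = pd.DataFrame(
        {
            "marker_id": [f"m{c}_{p}" for c, p in zip(chroms, pos)],
            "chrom": chroms,
            "pos": pos,
            "pop_b_freq": pbf,
        }
    )
    # manifest rows ordered by chromosome then position
    order = {c: i for i, c in enumerate(list(AUTOSOMES) + ["X", "Y"])}
    table = table.sort_values(
        ["chrom", "pos"], key=lambda s: s.map(order) if s.name == "chrom" else s
    ).reset_index(drop=True)
    return MarkerManifest(table)


def simulate_sample(
    manifest: MarkerManifest,
    state: PloidyState | str,
    noise: NoiseModel,
    seed: int,
    sample_id: Optional[str] = None,
    metadata: Optional[dict] = None,
) -> SNPSample:
    """Simulate one biopsy under a ploidy state and a noise model.

    Deterministic given (manifest, state, noise, seed).
    """
    if isinstance(state, str):
        state = get_state(state)
    rng = np.random.default_rng(seed)
    n = len(manifest)
    pbf = manifest.pop_b_freq

    copies = np.full(n, state.autosome_copies, dtype=np.int64)
    copies[manifest.is_x] = state.x_copies
    copies[manifest.is_y] = state.y_copies

    # fixed draw order keeps seeds comparable across noise settings
    dosage = rng.binomial(copies, pbf)
    baf_noise = rng.normal(0.0, noise.baf_sd, size=n)
    lrr_noise = rng.normal(0.0, noise.lrr_sd, size=n)
    u_ado = rng.random(n)
    ado_side = rng.integers(0, 2, size=n)
    u_mc = rng.random(n)
    mc_pick = rng.integers(0, 2, size=n)
    u_nc = rng.random(n)
    u_stray = rng.random(n)
    stray_geno = rng.integers(0, 3, size=n).astype(np.int8)

    present = copies > 0
    calls = np.full(n, CALL_NC, dtype=np.int8)
    calls[present & (dosage == 0)] = CALL_AA
    calls[present & (dosage == copies)] = CALL_BB
    calls[present & (dosage > 0) & (dosage < copies)] = CALL_AB

    baf = np.full(n, np.nan)
    with np.errstate(invalid="ignore"):
        expected = np.where(present, dosage / np.maximum(copies, 1), np.nan)
    baf[present] = np.clip(expected[present] + baf_noise[present], 0.0, 1.0)

    lrr_mean = np.zeros(n)
    lrr_mean[manifest.is_x] = noise.x_lrr_mean(state.x_copies)
    lrr = lrr_mean + lrr_noise
    lrr[~present] = np.nan

    # allele dropout: heterozygote read as a random homozygote
    ado = (calls == CALL_AB) & (u_ado < noise.ado_rate)
    calls[ado] = np.where(ado_side[ado] == 0, CALL_AA, CALL_BB)

    # mis-call: called genotype replaced by one of the two wrong ones
    called = calls != CALL_NC
    mc = called & (u_mc < noise.miscall_rate)
    others = np.array([[1, 2], [0, 2], [0, 1]], dtype=np.int8)  # per genotype
    calls[mc] = others[calls[mc], mc_pick[mc]]

    # no-call
    nc = (calls != CALL_NC) & (u_nc < noise.nocall_rate)
    calls[nc] = CALL_NC

    # stray chrY calls for Y-less states
    absent_y = manifest.is_y & ~present
    stray = absent_y & (u_stray < noise.y_stray_call_rate)
    calls[stray] = stray_geno[stray]
    baf[stray] = np.clip(stray_geno[stray] / 2.0 + baf_noise[stray], 0.0, 1.0)
    lrr[stray] = lrr_noise[stray]

    missing = calls == CALL_NC
    baf[missing] = np.nan
    lrr[missing] = np.nan

    return SNPSample(
        sample_id=sample_id or f"sim_{state.label}_{seed}",
        manifest=manifest,
        calls=calls,
        baf=baf,
        lrr=lrr,
        truth_label=state.label,
        metadata=dict(metadata or {}),
    )


def simulate_library(
    manifest: MarkerManifest,
    n_xy: int,
    n_xx: int,
    noise: NoiseModel,
    seed: int,
) -> EuploidLibrary:
    """Simulate a euploid reference library of known 46XY and 46XX samples."""
    if n_xy < 1 or n_xx < 1:
        raise ValueError("library needs at least one sample of each sex")
    seeds = _child_seeds(seed, n_xy + n_xx)
    samples, labels = [], []
    for i in range(n_xy):
        samples.append(
            simulate_sample(manifest, "46XY", noise, int(seeds[i]),
                            sample_id=f"lib_XY_{i:03d}")
        )
        labels.append("46XY")
    for i in range(n_xx):
        samples.append(
            simulate_sample(manifest, "46XX", noise, int(seeds[n_xy + i]),
                            sample_id=f"lib_XX_{i:03d}")
        )
        labels.append("46XX")
    return EuploidLibrary(samples, labels)


def simulate_cohort(
    spec: Mapping[str, Mapping[str, int]],
    manifest: MarkerManifest,
    noise: NoiseModel,
    seed: int,
    maternal_age: Tuple[float, float] = (36.0, 4.2),
    paternal_age: Tuple[float, float] = (37.3, 5.5),
) -> Tuple[list[SNPSample], pd.DataFrame]:
    """Simulate a cohort from ``{pn_status: {class_name: count}}``.

    Class names are keys of :data:`COHORT_CLASSES`; aneuploidy labels are
    attached as metadata only (the marker data carries no aneuploidy signal).
    Maternal/paternal ages are drawn from normal distributions given as
    (mean, sd) in years. Returns the samples and a cohort metadata table.
    """
    slots = []
    for pn_status, classes in spec.items():
        for class_name, count in classes.items():
            if class_name not in COHORT_CLASSES:
                raise ValueError(
                    f"unknown cohort class {class_name!r}; "
                    f"known: {sorted(COHORT_CLASSES)}"
                )
            if count < 0:
                raise ValueError("cohort counts must be >= 0")
            slots.extend((pn_status, class_name) for _ in range(count))

    ss = np.random.SeedSequence(seed)
    meta_rng = np.random.default_rng(ss.spawn(1)[0])
    seeds = _child_seeds(seed + 1, max(len(slots), 1))

    samples: list[SNPSample] = []
    rows = []
    for i, (pn_status, class_name) in enumerate(slots):
        group, aneu = COHORT_CLASSES[class_name]
        states = _GROUP_STATES[group]
        state = states[int(meta_rng.integers(len(states)))]
        m_age = float(meta_rng.normal(*maternal_age))
        p_age = float(meta_rng.normal(*paternal_age))
        sid = f"{pn_status}_{class_name}_{i:04d}"
        meta = {
            "pn_status": pn_status,
            "aneuploidy_label": aneu,
            "maternal_age": m_age,
            "paternal_age": p_age,
        }
        samples.append(
            simulate_sample(manifest, state, noise, int(seeds[i]),
                            sample_id=sid, metadata=meta)
        )
        rows.append(
            {
                "sample_id": sid,
                "pn_status": pn_status,
                "truth_class": class_name,
                "truth_state": state,
                "aneuploidy_label": aneu,
                "maternal_age": round(m_age, 1),
                "paternal_age": round(p_age, 1),
                "fet_outcome": "",
            }
        )
    columns = [
        "sample_id", "pn_status", "truth_class", "truth_state",
        "aneuploidy_label", "maternal_age", "paternal_age", "fet_outcome",
    ]
    return samples, pd.DataFrame(rows, columns=columns)
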