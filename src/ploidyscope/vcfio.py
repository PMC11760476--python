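"""VCF interchange for SNP-array samples (gtc2vcf-style GT/BAF/LRR dialect).

Samples are written as VCF 4.2 with per-sample FORMAT fields ``GT``
(0/0, 0/1, 1/1, ./.), ``BAF`` and ``LRR`` (Float, ``.`` when missing). The
A allele maps to REF and the B allele to ALT; record IDs carry the manifest
marker ids. FORMAT floats are serialized with ~6 significant digits, so
round trips preserve BAF to 6 decimal places (and LRR to ~1e-5 at magnitude
1) rather than bit-exactly.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
import pysam

from .core import CALL_AA, CALL_AB, CALL_BB, CALL_NC, SNPSample
from .manifest import CHROMOSOMES, MarkerManifest

_GT = {int(CALL_AA): (0, 0), int(CALL_AB): (0, 1), int(CALL_BB): (1, 1),
       int(CALL_NC): (None, None)}


class VcfParseError(ValueError):
    """Raised for a malformed or non-conforming VCF."""


class AlignmentError(ValueError):
    """Raised when too many VCF records are absent from the manifest."""


def _build_header(manifest: MarkerManifest, sample_ids: Sequence[str]) -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    lengths = {}
    for chrom in CHROMOSOMES:
        mask = manifest.chrom == chrom
        lengths[chrom] = int(manifest.pos[mask].max()) + 1000 if mask.any() else 1000
    for chrom in CHROMOSOMES:
        header.contigs.add(chrom, length=lengths[chrom])
    header.formats.add("GT", 1, "String", "Genotype (A allele = REF, B allele = ALT)")
    header.formats.add("BAF", 1, "Float", "B-allele frequency")
    header.formats.add("LRR", 1, "Float", "Log R ratio")
    for sid in sample_ids:
        header.add_sample(sid)
    return header


def write_samples(samples: Sequence[SNPSample], vcf_path) -> None:
    """Write one or more manifest-aligned samples as a multi-sample VCF."""
    if not samples:
        raise ValueError("no samples to write")
    manifest = samples[0].manifest
    for s in samples[1:]:
        if not np.array_equal(s.manifest.marker_ids, manifest.marker_ids):
            raise ValueError("all samples must share one manifest")
    header = _build_header(manifest, [s.sample_id for s in samples])
    with pysam.VariantFile(str(vcf_path), "w", header=header) as out:
        chroms = manifest.chrom
        poss = manifest.pos
        ids = manifest.marker_ids
        for i in range(len(manifest)):
            rec = out.new_record(
                contig=str(chroms[i]), start=int(poss[i]) - 1,
                alleles=("A", "C"), id=str(ids[i]),
            )
            for s in samples:
                fmt = rec.samples[s.sample_id]
                fmt["GT"] = _GT[int(s.calls[i])]
                fmt["BAF"] = None if np.isnan(s.baf[i]) else float(s.baf[i])
                fmt["LRR"] = None if np.isnan(s.lrr[i]) else float(s.lrr[i])
            out.write(rec)


def write_sample(sample: SNPSample, vcf_path) -> None:
    """Write a single sample as VCF (see :func:`write_samples`)."""
    write_samples([sample], vcf_path)


def _gt_to_call(gt) -> np.int8:
    if gt is None or any(a is None for a in gt):
        return CALL_NC
    alts = sum(1 for a in gt if a == 1)
    if len(gt) != 2 or any(a not in (0, 1) for a in gt):
        raise VcfParseError(f"unsupported genotype {gt!r} (biallelic dialect)")
    return (CALL_AA, CALL_AB, CALL_BB)[alts]


def read_samples(
    vcf_path,
    manifest: MarkerManifest,
    max_unknown_frac: float = 0.0,
) -> list[SNPSample]:
    """Read all samples of a GT/BAF/LRR VCF, aligned to ``manifest``.

    Records whose ID is not in the manifest are rejected; if their fraction
    exceeds ``max_unknown_frac`` an :class:`AlignmentError` is raised.
    Manifest markers absent from the file are NC with missing BAF/LRR.
    """
    try:
        vf = pysam.VariantFile(str(vcf_path))
    except (OSError, ValueError) as exc:
        raise VcfParseError(f"cannot parse VCF {vcf_path}: {exc}") from exc
    with vf:
        for key in ("GT", "BAF", "LRR"):
            if key not in vf.header.formats:
                raise VcfParseError(
                    f"VCF {vcf_path} lacks the {key} FORMAT declaration"
                )
        sample_ids = list(vf.header.samples)
        if not sample_ids:
            raise VcfParseError(f"VCF {vcf_path} carries no samples")
        n = len(manifest)
        calls = {s: np.full(n, CALL_NC, dtype=np.int8) for s in sample_ids}
        baf = {s: np.full(n, np.nan) for s in sample_ids}
        lrr = {s: np.full(n, np.nan) for s in sample_ids}

        n_records = 0
        n_unknown = 0
        for rec in vf:
            n_records += 1
            if rec.id is None or rec.id not in manifest:
                n_unknown += 1
                continue
            i = manifest.index_of(rec.id)
            for s in sample_ids:
                fmt = rec.samples[s]
                calls[s][i] = _gt_to_call(fmt.get("GT"))
                b = fmt.get("BAF")
                if b is not None:
                    baf[s][i] = float(np.clip(b, 0.0, 1.0))
                l = fmt.get("LRR")
                if l is not None:
                    lrr[s][i] = float(l)
        if n_records and n_unknown / n_records > max_unknown_frac:
            raise AlignmentError(
                f"{n_unknown}/{n_records} VCF records absent from the manifest "
                f"(allowed fraction {max_unknown_frac})"
            )
    return [
        SNPSample(sample_id=s, manifest=manifest, calls=calls[s],
                  baf=baf[s], lrr=lrr[s])
        for s in sample_ids
    ]


def read_sample(
    vcf_path,
    manifest: MarkerManifest,
    sample_id: Optional[str] = None,
    max_unknown_frac: float = 0.0,
) -> SNPSample:
    """Read one sample (by name, or the only one) from a GT/BAF/LRR VCF."""
    samples = read_samples(vcf_path, manifest, max_unknown_frac)
    if sample_id is None:
        if len(samples) != 1:
            raise VcfParseError(
                f"VCF {vcf_path} holds {len(samples)} samples; pass sample_id"
            )
        return samples[0]
    for s in samples:
        if s.sample_id == sample_id:
            return s
    raise VcfParseError(f"sample {sample_id!r} not present in {vcf_path}")
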