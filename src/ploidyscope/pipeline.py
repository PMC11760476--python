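"""End-to-end orchestration: simulate -> QC -> calibrate -> classify ->
tabulate, with deterministic per-stage seeding and on-disk stage outputs.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path
from typing import Mapping, Optional

import numpy as np
import pandas as pd
import yaml

from .cohort import CohortRecord, tabulate_fet, tabulate_ploidy
from .core import NoiseModel
from .heterozygosity import HeterozygosityPloidyClassifier, qc_sample
from .simulate import make_manifest, simulate_cohort, simulate_library
from .thresholds import ThresholdsConfig, thresholds_from_dict
from .triploidy import TriploidyDecisionTree, calibrate_x_lrr
from .vcfio import write_samples

log = logging.getLogger("ploidyscope")


@dataclasses.dataclass
class RunConfig:
    """Everything a reproducible demo run needs.

    Every stochastic stage consumes a child seed derived deterministically
    from ``seed`` via a SeedSequence spawn, so identical configs give
    byte-identical outputs.
    """

    seed: int = 0
    n_autosomal: int = 4400
    n_x: int = 300
    n_y: int = 120
    library_n_xy: int = 37
    library_n_xx: int = 32
    noise: NoiseModel = dataclasses.field(default_factory=NoiseModel)
    thresholds: ThresholdsConfig = dataclasses.field(default_factory=ThresholdsConfig)
    cohort: Mapping[str, Mapping[str, int]] = dataclasses.field(
        default_factory=lambda: {
            "0PN": {"diploid_euploid": 8, "diploid_aneuploid": 6, "haploid": 2},
            "1PN": {"haploid": 4, "diploid_euploid": 4, "diploid_aneuploid": 4},
            "3PN": {"triploid": 6, "triploid_aneuploid": 4, "diploid": 2},
        }
    )
    calibrate_from_library: bool = False
    write_vcf: bool = True

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        kwargs = {}
        for key in ("seed", "n_autosomal", "n_x", "n_y", "library_n_xy",
                    "library_n_xx", "cohort", "calibrate_from_library",
                    "write_vcf"):
            if key in d:
                kwargs[key] = d[key]
        if "noise" in d:
            kwargs["noise"] = NoiseModel(**d["noise"])
        if "thresholds" in d:
            kwargs["thresholds"] = thresholds_from_dict(d["thresholds"])
        return cls(**kwargs)


def _stage_seeds(seed: int, n: int) -> list[int]:
    return [int(s) for s in np.random.SeedSequence(seed).generate_state(n) & 0x7FFFFFFF]


def run_pipeline(config: RunConfig, out_dir) -> Path:
    """Run the full demo pipeline into ``out_dir`` and return its path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    try:
        s_manifest, s_library, s_cohort = _stage_seeds(config.seed, 3)

        log.info("stage manifest: %d autosomal, %d X, %d Y markers",
                 config.n_autosomal, config.n_x, config.n_y)
        manifest = make_manifest(config.n_autosomal, config.n_x, config.n_y,
                                 seed=s_manifest)
        manifest.to_tsv(out / "manifest.tsv")

        log.info("stage simulate: library %d XY + %d XX, cohort %s",
                 config.library_n_xy, config.library_n_xx, dict(config.cohort))
        library = simulate_library(manifest, config.library_n_xy,
                                   config.library_n_xx, config.noise, s_library)
        samples, meta = simulate_cohort(config.cohort, manifest, config.noise,
                                        s_cohort)
        meta.to_csv(out / "cohort_metadata.tsv", sep="\t", index=False)
        if config.write_vcf and samples:
            write_samples(samples, out / "cohort.vcf")

        log.info("stage qc: %d samples", len(samples))
        qc_rows = []
        for s in samples:
            rep = qc_sample(s, config.thresholds)
            qc_rows.append({"sample_id": s.sample_id,
                            "call_rate": rep["metrics"]["call_rate"],
                            "qc_pass": rep["qc_pass"]})
        pd.DataFrame(qc_rows).to_csv(out / "qc.tsv", sep="\t", index=False)

        log.info("stage calibrate")
        bounds = calibrate_x_lrr(library)
        thresholds = config.thresholds
        if config.calibrate_from_library:
            thresholds = thresholds.with_x_bounds(*bounds)
        with open(out / "bounds.yaml", "w") as fh:
            yaml.safe_dump(
                {"x_lrr_one_copy_max": float(bounds.one_copy_max),
                 "x_lrr_two_copy_min": float(bounds.two_copy_min),
                 "used_for_classification": bool(config.calibrate_from_library)},
                fh)

        log.info("stage classify")
        by_id = {s.sample_id: s for s in samples}
        ab_clf = HeterozygosityPloidyClassifier(
            haploid_max=thresholds.ab_haploid_max,
            diploid_min=thresholds.ab_diploid_min,
        ).fit()
        tri_clf = TriploidyDecisionTree(thresholds=thresholds).fit()

        ab_ids = [r.sample_id for _, r in meta.iterrows()
                  if r.pn_status in ("0PN", "1PN")]
        tri_ids = [r.sample_id for _, r in meta.iterrows() if r.pn_status == "3PN"]

        ab_results = ab_clf.results([by_id[i] for i in ab_ids], thresholds)
        ab_df = pd.DataFrame([dataclasses.asdict(r) for r in ab_results])
        ab_df.to_csv(out / "ab_calls.tsv", sep="\t", index=False)

        tri_df = tri_clf.decision_table([by_id[i] for i in tri_ids])
        tri_df.to_csv(out / "tri_calls.tsv", sep="\t", index=False)

        log.info("stage tabulate")
        class_by_id = dict(zip(ab_df.get("sample_id", []),
                               ab_df.get("ploidy_class", [])))
        class_by_id.update(zip(tri_df.get("sample_id", []),
                               tri_df.get("ploidy_class", [])))
        records = [
            CohortRecord(
                sample_id=r.sample_id,
                pn_status=r.pn_status,
                ploidy_class=class_by_id[r.sample_id],
                aneuploidy_label=r.aneuploidy_label,
                maternal_age=r.maternal_age,
                paternal_age=r.paternal_age,
                fet_outcome=r.fet_outcome or None,
            )
            for _, r in meta.iterrows()
        ]
        tabulate_ploidy(records).to_csv(out / "ploidy_table.tsv", sep="\t",
                                        index=False)
        if any(r.fet_outcome for r in records):
            tabulate_fet(records).to_csv(out / "fet_table.tsv", sep="\t",
                                         index=False)
        log.info("done")
    finally:
        log.removeHandler(handler)
        handler.close()
    return out
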