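"""Marker manifest: the ordered SNP marker set shared by all samples.

A manifest fixes the marker order, chromosome assignment and population
B-allele frequency for every sample in a run; genotype/BAF/LRR vectors are
only meaningful relative to a manifest.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd

AUTOSOMES = tuple(str(c) for c in range(1, 23))
CHROMOSOMES = AUTOSOMES + ("X", "Y")

_MANIFEST_COLUMNS = ["marker_id", "chrom", "pos", "pop_b_freq"]


class ManifestError(ValueError):
    """Raised when a manifest violates its structural invariants."""


class MarkerManifest:
    """Ordered set of SNP markers with chromosome, position and population BAF.

    Parameters
    ----------
    table:
        DataFrame with columns ``marker_id``, ``chrom`` (``'1'``..``'22'``,
        ``'X'``, ``'Y'``), ``pos`` (1-based, strictly increasing within each
        chromosome) and ``pop_b_freq`` (population B-allele frequency in
        [0, 1]).
    """

    def __init__(self, table: pd.DataFrame):
        missing = [c for c in _MANIFEST_COLUMNS if c not in table.columns]
        if missing:
            raise ManifestError(f"manifest missing columns: {missing}")
        table = table[_MANIFEST_COLUMNS].reset_index(drop=True).copy()
        table["chrom"] = table["chrom"].astype(str)
        table["pos"] = table["pos"].astype(np.int64)
        table["pop_b_freq"] = table["pop_b_freq"].astype(float)

        bad_chrom = set(table["chrom"]) - set(CHROMOSOMES)
        if bad_chrom:
            raise ManifestError(f"unknown chromosome labels: {sorted(bad_chrom)}")
        if table["marker_id"].duplicated().any():
            dup = table.loc[table["marker_id"].duplicated(), "marker_id"].iloc[0]
            raise ManifestError(f"duplicate marker_id: {dup!r}")
        if (table["pos"] < 1).any():
            raise ManifestError("positions must be 1-based (>= 1)")
        if ((table["pop_b_freq"] < 0) | (table["pop_b_freq"] > 1)).any():
            raise ManifestError("pop_b_freq must lie in [0, 1]")
        for chrom, sub in table.groupby("chrom", sort=False):
            if not np.all(np.diff(sub["pos"].to_numpy()) > 0):
                raise ManifestError(
                    f"positions not strictly increasing on chromosome {chrom}"
                )

        self.table = table
        chrom = table["chrom"].to_numpy()
        self.is_autosomal = np.isin(chrom, AUTOSOMES)
        self.is_x = chrom == "X"
        self.is_y = chrom == "Y"
        self._index = {m: i for i, m in enumerate(table["marker_id"])}

    # -- basic container protocol -------------------------------------------------

    def __len__(self) -> int:
        return len(self.table)

    @property
    def n_markers(self) -> int:
        return len(self.table)

    @property
    def marker_ids(self) -> np.ndarray:
        return self.table["marker_id"].to_numpy()

    @property
    def chrom(self) -> np.ndarray:
        return self.table["chrom"].to_numpy()

    @property
    def pos(self) -> np.ndarray:
        return self.table["pos"].to_numpy()

    @property
    def pop_b_freq(self) -> np.ndarray:
        return self.table["pop_b_freq"].to_numpy()

    def index_of(self, marker_id: str) -> int:
        return self._index[marker_id]

    def __contains__(self, marker_id: str) -> bool:
        return marker_id in self._index

    def scope_mask(self, scope: str | Iterable[str] = "all") -> np.ndarray:
        """Boolean mask selecting markers in a chromosome scope.

        ``scope`` is ``'all'``, ``'autosomes'``, a single chromosome label, or
        an iterable of labels.
        """
        if isinstance(scope, str):
            if scope == "all":
                return np.ones(len(self), dtype=bool)
            if scope == "autosomes":
                return self.is_autosomal.copy()
            scope = [scope]
        labels = [str(s) for s in scope]
        unknown = set(labels) - set(CHROMOSOMES)
        if unknown:
            raise ManifestError(f"unknown scope chromosomes: {sorted(unknown)}")
        return np.isin(self.chrom, labels)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, MarkerManifest):
            return NotImplemented
        return self.table.equals(other.table)

    def __repr__(self) -> str:
        return (
            f"MarkerManifest({len(self)} markers: "
            f"{int(self.is_autosomal.sum())} autosomal, "
            f"{int(self.is_x.sum())} X, {int(self.is_y.sum())} Y)"
        )

    # -- TSV interchange ----------------------------------------------------------

    def to_tsv(self, path) -> None:
        # 17 significant digits keep pop_b_freq exact across round trips
        self.table.to_csv(path, sep="\t", index=False, float_format="%.17g")

    @classmethod
    def from_tsv(cls, path) -> "MarkerManifest":
        return cls(pd.read_csv(path, sep="\t", dtype={"chrom": str},
                               float_precision="round_trip"))


def concat_positions(chroms: Sequence[str], rng: np.random.Generator,
                     span: int = 250_000_000) -> np.ndarray:
    """Draw strictly increasing 1-based positions per chromosome."""
    chroms = np.asarray(chroms)
    pos = np.empty(len(chroms), dtype=np.int64)
    for chrom in np.unique(chroms):
        mask = chroms == chrom
        n = int(mask.sum())
        # sample without replacement to guarantee strict increase
        p = np.sort(rng.choice(span, size=n, replace=False)) + 1
        pos[mask] = p
    return pos
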