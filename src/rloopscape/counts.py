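"""Per-bin, per-library stranded count matrices and spike-in normalisation.

A pull-down experiment yields, per genotype and replicate, one unstranded
*input* library (total digested nucleic acid) and strand-resolved
*extracted* libraries (the hybrid pull-down fraction).  Counts are stored
as one integer matrix (bins x libraries) with a library table describing
(genotype, replicate, sample_type, strand) and per-library size factors.
An optional flagged subset of bins belongs to a spike-in contig with
constant true enrichment, used only for normalisation.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .trackio import GenomicTrack

LIBRARY_COLUMNS = ["library", "genotype", "replicate", "sample_type", "strand"]


@dataclass
class StrandedCountMatrix:
    bins: pd.DataFrame  # columns contig, start, end
    libraries: pd.DataFrame  # LIBRARY_COLUMNS; strand '.' for unstranded input
    counts: np.ndarray  # (n_bins, n_libraries) non-negative integers
    size_factors: np.ndarray | None = None
    spike_mask: np.ndarray | None = None  # True on spike-in bins
    mask: np.ndarray | None = None  # True on analysis-masked bins

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if not np.issubdtype(self.counts.dtype, np.integer):
            if not np.allclose(self.counts, np.round(self.counts)):
                raise ValueError("counts must be integral")
            self.counts = self.counts.astype(np.int64)
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        if self.counts.shape != (len(self.bins), len(self.libraries)):
            raise ValueError("counts shape does not match bins x libraries")
        if self.size_factors is None:
            self.size_factors = np.ones(len(self.libraries))
        self.size_factors = np.asarray(self.size_factors, dtype=float)
        if np.any(self.size_factors <= 0):
            raise ValueError("size factors must be positive")
        if self.spike_mask is None:
            self.spike_mask = np.zeros(len(self.bins), dtype=bool)
        if self.mask is None:
            self.mask = np.zeros(len(self.bins), dtype=bool)
        missing = [c for c in LIBRARY_COLUMNS if c not in self.libraries.columns]
        if missing:
            raise ValueError(f"library table lacks columns {missing}")
        for g, grp in self.libraries.groupby("genotype"):
            kinds = set(grp["sample_type"])
            if not {"input", "extracted"} <= kinds:
                raise ValueError(
                    f"genotype {g} needs at least one input and one extracted library"
                )

    @property
    def genotypes(self) -> list:
        return list(dict.fromkeys(self.libraries["genotype"]))

    def library_indices(self, genotype=None, sample_type=None, strand=None) -> np.ndarray:
        sel = np.ones(len(self.libraries), dtype=bool)
        if genotype is not None:
            sel &= (self.libraries["genotype"] == genotype).to_numpy()
        if sample_type is not None:
            sel &= (self.libraries["sample_type"] == sample_type).to_numpy()
        if strand is not None:
            sel &= (self.libraries["strand"] == strand).to_numpy()
        return np.flatnonzero(sel)

    def genome_bins(self) -> np.ndarray:
        """Indices of non-spike bins."""
        return np.flatnonzero(~self.spike_mask)

    # -- I/O ---------------------------------------------------------------

    def write(self, outdir) -> None:
        """One bedGraph per library plus libraries.tsv / bins metadata."""
        os.makedirs(outdir, exist_ok=True)
        lib = self.libraries.copy()
        lib["size_factor"] = self.size_factors
        lib.to_csv(os.path.join(outdir, "libraries.tsv"), sep="\t", index=False)
        meta = self.bins.copy()
        meta["spike"] = self.spike_mask.astype(int)
        meta["masked"] = self.mask.astype(int)
        meta.to_csv(os.path.join(outdir, "bins.tsv"), sep="\t", index=False)
        for j, name in enumerate(self.libraries["library"]):
            df = self.bins.copy()
            df["count"] = self.counts[:, j]
            df.to_csv(
                os.path.join(outdir, f"{name}.bedgraph"),
                sep="\t", header=False, index=False,
            )

    @classmethod
    def read(cls, outdir) -> "StrandedCountMatrix":
        lib = pd.read_csv(os.path.join(outdir, "libraries.tsv"), sep="\t")
        meta = pd.read_csv(os.path.join(outdir, "bins.tsv"), sep="\t")
        counts = np.column_stack(
            [
                pd.read_csv(
                    os.path.join(outdir, f"{name}.bedgraph"),
                    sep="\t", header=None,
                )[3].to_numpy()
                for name in lib["library"]
            ]
        )
        sf = lib.pop("size_factor").to_numpy() if "size_factor" in lib else None
        return cls(
            bins=meta[["contig", "start", "end"]],
            libraries=lib,
            counts=counts,
            size_factors=sf,
            spike_mask=meta["spike"].to_numpy(dtype=bool) if "spike" in meta else None,
            mask=meta["masked"].to_numpy(dtype=bool) if "masked" in meta else None,
        )

    def strand_track(self, library: str) -> GenomicTrack:
        j = int(np.flatnonzero((self.libraries["library"] == library).to_numpy())[0])
        keep = ~self.spike_mask
        sub = self.bins.loc[keep]
        return GenomicTrack(
            sub["contig"].iloc[0],
            sub["start"].to_numpy(),
            sub["end"].to_numpy(),
            self.counts[keep, j].astype(float),
        )


def size_factors_from_spike(counts: StrandedCountMatrix) -> np.ndarray:
    """Per-library size factors from spike-in bins.

    factor_l = (spike-bin sum of library l) / (geometric mean over libraries
    of those sums); multiplying to a genome-independent normalisation.
    """
    if counts.spike_mask is None or not counts.spike_mask.any():
        raise ValueError("no spike-in bins are flagged")
    sums = counts.counts[counts.spike_mask, :].sum(axis=0).astype(float)
    zero = np.flatnonzero(sums == 0)
    if zero.size:
        names = counts.libraries["library"].iloc[zero].tolist()
        raise ValueError(f"zero spike-in counts in libraries {names}")
    geo = np.exp(np.mean(np.log(sums)))
    return sums / geo
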