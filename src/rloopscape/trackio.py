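"""Binned genomic tracks and bedGraph I/O.

Tracks hold one value per fixed-width bin on a single contig, with NaN as
the explicit missing-value flag (masked bins are flagged, never dropped).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class GenomicTrack:
    contig: str
    starts: np.ndarray
    ends: np.ndarray
    values: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.starts = np.asarray(self.starts, dtype=np.int64)
        self.ends = np.asarray(self.ends, dtype=np.int64)
        self.values = np.asarray(self.values, dtype=float)
        if not (len(self.starts) == len(self.ends) == len(self.values)):
            raise ValueError("starts, ends, values must have equal length")
        if len(self.starts) > 1:
            if np.any(np.diff(self.starts) <= 0):
                raise ValueError("bins must be sorted and non-overlapping")
            widths = self.ends - self.starts
            if len(np.unique(widths)) != 1:
                raise ValueError("bins must have uniform width")

    @property
    def bin_width(self) -> int:
        return int(self.ends[0] - self.starts[0])

    @property
    def n_bins(self) -> int:
        return len(self.starts)

    def with_values(self, values, **metadata) -> "GenomicTrack":
        md = dict(self.metadata)
        md.update(metadata)
        return GenomicTrack(self.contig, self.starts, self.ends, values, md)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "contig": self.contig,
                "start": self.starts,
                "end": self.ends,
                "value": self.values,
            }
        )


def write_bedgraph(track: GenomicTrack, path, missing: str = "nan") -> None:
    df = track.to_frame()
    df["value"] = df["value"].map(lambda v: missing if np.isnan(v) else repr(float(v)))
    df.to_csv(path, sep="\t", header=False, index=False)


def read_bedgraph(path) -> GenomicTrack:
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        names=["contig", "start", "end", "value"],
        comment="#",
        na_values=["nan"],
    )
    contigs = df["contig"].unique()
    if len(contigs) != 1:
        raise ValueError(f"{path}: expected a single contig, found {list(contigs)}")
    return GenomicTrack(
        contigs[0],
        df["start"].to_numpy(),
        df["end"].to_numpy(),
        df["value"].to_numpy(dtype=float),
    )


def make_bins(contig: str, length: int, bin_width: int) -> tuple[np.ndarray, np.ndarray]:
    if length % bin_width != 0:
        raise ValueError(f"length {length} not divisible by bin width {bin_width}")
    starts = np.arange(0, length, bin_width, dtype=np.int64)
    return starts, starts + bin_width
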