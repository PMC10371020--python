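"""Genome annotation, replichore geometry, and orientation classification.

Coordinates are 0-based half-open internally everywhere; GFF3 (1-based
closed) is converted at the read/write boundary.  A feature's orientation
relative to DNA replication is *codirectional* when it is transcribed in
the direction of replication-fork travel on its replichore and *head_on*
otherwise.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd


class FeatureType(str, enum.Enum):
    CDS = "CDS"
    UTR5 = "UTR5"
    UTR3 = "UTR3"
    ncRNA = "ncRNA"
    rRNA = "rRNA"
    tRNA = "tRNA"


#: GFF3/SO feature-type spellings accepted on read, canonical name on write.
GFF3_TYPE_MAP = {
    "CDS": FeatureType.CDS,
    "five_prime_UTR": FeatureType.UTR5,
    "three_prime_UTR": FeatureType.UTR3,
    "ncRNA": FeatureType.ncRNA,
    "rRNA": FeatureType.rRNA,
    "tRNA": FeatureType.tRNA,
}
GFF3_TYPE_NAME = {
    FeatureType.CDS: "CDS",
    FeatureType.UTR5: "five_prime_UTR",
    FeatureType.UTR3: "three_prime_UTR",
    FeatureType.ncRNA: "ncRNA",
    FeatureType.rRNA: "rRNA",
    FeatureType.tRNA: "tRNA",
}


class Orientation(str, enum.Enum):
    head_on = "head_on"
    codirectional = "codirectional"
    unassigned = "unassigned"


@dataclass(frozen=True)
class GenomeFeature:
    """An annotated interval with strand and replication orientation."""

    id: str
    type: FeatureType
    contig: str
    start: int  # 0-based inclusive
    end: int  # 0-based exclusive
    strand: str  # '+' or '-'
    orientation: Orientation = Orientation.unassigned
    boundary_flag: bool = False  # spans oriC or ter; orientation from midpoint

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"feature {self.id}: require 0 <= start < end, got ({self.start}, {self.end})"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"feature {self.id}: unknown strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.start + self.end)


@dataclass(frozen=True)
class ReplichoreMap:
    """Origin/terminus geometry of a (circular) bacterial chromosome.

    Replication initiates bidirectionally at ``oriC_pos`` and the two forks
    meet at ``ter_pos``.  On the arc running from oriC towards ter in the
    direction of increasing coordinate ("clockwise"), forks travel in the
    ``+`` direction; on the other arc they travel in the ``-`` direction.
    """

    contig: str
    length: int
    oriC_pos: int
    ter_pos: int
    circular: bool = True

    def __post_init__(self) -> None:
        if self.oriC_pos == self.ter_pos:
            raise ValueError("oriC_pos and ter_pos must differ")
        for name in ("oriC_pos", "ter_pos"):
            v = getattr(self, name)
            if not 0 <= v < self.length:
                raise ValueError(f"{name}={v} outside [0, {self.length})")

    def fork_direction(self, pos) -> np.ndarray:
        """+1 where the replication fork travels rightward, -1 leftward."""
        pos = np.asarray(pos)
        if self.oriC_pos < self.ter_pos:
            clockwise = (pos >= self.oriC_pos) & (pos < self.ter_pos)
        else:
            clockwise = (pos >= self.oriC_pos) | (pos < self.ter_pos)
        return np.where(clockwise, 1, -1)

    def fork_distance(self, pos) -> np.ndarray:
        """Distance (bp) travelled by the fork from oriC to reach ``pos``."""
        pos = np.asarray(pos, dtype=float)
        d_cw = np.mod(pos - self.oriC_pos, self.length)
        d_ccw = np.mod(self.oriC_pos - pos, self.length)
        return np.where(self.fork_direction(pos) == 1, d_cw, d_ccw)


@dataclass
class MaskSet:
    """Intervals excluded from aggregation (e.g. duplicated rRNA copies).

    Bins overlapping a masked interval are flagged, never silently dropped.
    """

    intervals: list = field(default_factory=list)  # (contig, start, end)

    def __post_init__(self) -> None:
        for contig, start, end in self.intervals:
            if not 0 <= start < end:
                raise ValueError(f"invalid mask interval ({contig}, {start}, {end})")

    def mask_bins(self, contig: str, starts, ends) -> np.ndarray:
        """Boolean flag per bin: True where the bin overlaps any mask interval."""
        starts = np.asarray(starts)
        ends = np.asarray(ends)
        flag = np.zeros(len(starts), dtype=bool)
        for c, s, e in self.intervals:
            if c == contig:
                flag |= (starts < e) & (ends > s)
        return flag

    @classmethod
    def read_bed(cls, path) -> "MaskSet":
        ivals = []
        with open(path) as fh:
            for line in fh:
                if not line.strip() or line.startswith(("#", "track")):
                    continue
                c, s, e = line.split()[:3]
                ivals.append((c, int(s), int(e)))
        return cls(ivals)

    def write_bed(self, path) -> None:
        with open(path, "w") as fh:
            for c, s, e in self.intervals:
                fh.write(f"{c}\t{s}\t{e}\n")


def classify_orientation(feature: GenomeFeature, rep: ReplichoreMap) -> GenomeFeature:
    """Assign head-on/codirectional orientation relative to fork travel.

    Features spanning oriC or ter are classified by the arc containing their
    midpoint and flagged via ``boundary_flag``.
    """
    if feature.contig != rep.contig:
        raise ValueError(
            f"feature {feature.id} is on contig {feature.contig!r}, "
            f"replichore map is for contig {rep.contig!r}"
        )
    spans = (feature.start < rep.ter_pos < feature.end) or (
        feature.start < rep.oriC_pos < feature.end
    )
    fork = int(rep.fork_direction(feature.midpoint))
    gene_dir = 1 if feature.strand == "+" else -1
    orient = Orientation.codirectional if fork == gene_dir else Orientation.head_on
    return replace(feature, orientation=orient, boundary_flag=spans)


def classify_all(features, rep: ReplichoreMap) -> list:
    return [classify_orientation(f, rep) for f in features]


def first_n_bp(feature: GenomeFeature, n: int) -> GenomeFeature:
    """Strand-aware first ``n`` bp of a feature (clipped to its length)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    m = min(n, feature.length)
    if feature.strand == "+":
        start, end = feature.start, feature.start + m
    else:
        start, end = feature.end - m, feature.end
    return replace(feature, start=start, end=end)


# ---------------------------------------------------------------------------
# Annotation I/O
# ---------------------------------------------------------------------------


def read_annotation(path, fmt: str = "GFF3") -> list:
    """Read features from GFF3 or BED6, normalising to 0-based half-open.

    Unrecognised feature types are skipped with a warning; malformed rows or
    unknown strands raise with the offending line number.
    """
    fmt = fmt.upper()
    if fmt == "GFF3":
        return _read_gff3(path)
    if fmt == "BED":
        return _read_bed6(path)
    raise ValueError(f"unsupported annotation format {fmt!r}")


def _read_gff3(path) -> list:
    import gffutils
    from gffutils.exceptions import EmptyInputError

    # gffutils wants a file on disk for its sqlite import; db itself in memory
    try:
        db = _gff3_db(path)
    except EmptyInputError:
        return []
    features = []
    skipped = set()
    for rec in db.all_features():
        ftype = GFF3_TYPE_MAP.get(rec.featuretype)
        if ftype is None:
            skipped.add(rec.featuretype)
            continue
        if rec.strand not in ("+", "-"):
            raise ValueError(
                f"{path}: feature {rec.id} has unknown strand {rec.strand!r}"
            )
        fid = rec.attributes.get("ID", [rec.id])[0]
        features.append(
            GenomeFeature(
                id=fid,
                type=ftype,
                contig=rec.seqid,
                start=rec.start - 1,  # GFF3 is 1-based closed
                end=rec.end,
                strand=rec.strand,
            )
        )
    if skipped:
        warnings.warn(f"skipped unrecognised feature types: {sorted(skipped)}")
    return features


def _gff3_db(path):
    import gffutils

    return gffutils.create_db(
        str(path),
        ":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )


def _read_bed6(path) -> list:
    features = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track")):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 6:
                raise ValueError(f"{path}:{lineno}: expected >=6 BED columns")
            contig, start, end, name, _score, strand = parts[:6]
            if strand not in ("+", "-"):
                raise ValueError(f"{path}:{lineno}: unknown strand {strand!r}")
            try:
                ftype = FeatureType(name.split("|")[-1]) if "|" in name else FeatureType.CDS
            except ValueError:
                warnings.warn(f"{path}:{lineno}: unrecognised type in name {name!r}; skipped")
                continue
            fid = name.split("|")[0]
            features.append(
                GenomeFeature(fid, ftype, contig, int(start), int(end), strand)
            )
    return features


def write_annotation(features, path, fmt: str = "GFF3", source: str = "rloopscape") -> None:
    fmt = fmt.upper()
    if fmt == "GFF3":
        with open(path, "w") as fh:
            fh.write("##gff-version 3\n")
            for f in features:
                attrs = f"ID={f.id}"
                fh.write(
                    "\t".join(
                        [
                            f.contig,
                            source,
                            GFF3_TYPE_NAME[f.type],
                            str(f.start + 1),
                            str(f.end),
                            ".",
                            f.strand,
                            ".",
                            attrs,
                        ]
                    )
                    + "\n"
                )
    elif fmt == "BED":
        with open(path, "w") as fh:
            for f in features:
                fh.write(
                    f"{f.contig}\t{f.start}\t{f.end}\t{f.id}|{f.type.value}\t0\t{f.strand}\n"
                )
    else:
        raise ValueError(f"unsupported annotation format {fmt!r}")


def features_frame(features) -> pd.DataFrame:
    """Tabular view of a feature list (one row per feature)."""
    return pd.DataFrame(
        {
            "id": [f.id for f in features],
            "type": [f.type.value for f in features],
            "contig": [f.contig for f in features],
            "start": [f.start for f in features],
            "end": [f.end for f in features],
            "strand": [f.strand for f in features],
            "orientation": [f.orientation.value for f in features],
            "boundary_flag": [f.boundary_flag for f in features],
        }
    )
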