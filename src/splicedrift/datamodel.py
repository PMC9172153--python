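"""Domain types shared by every analysis stage.

All genomic coordinates held in memory are 0-based, half-open.  Conversions
from 1-based inclusive conventions (GTF, STAR splice-junction tables) happen
only inside the readers/writers in :mod:`splicedrift.io`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, Iterator, List, Mapping, Optional, Tuple

import numpy as np
import pandas as pd

STRANDS = ("+", "-")

#: Sentinel used for qPCR targets that never crossed the detection threshold.
NOT_DETECTED = None


@dataclass(frozen=True)
class ExonRecord:
    """One annotated exon; the unit of the differential-usage analysis."""

    gene_id: str
    exon_id: str
    chrom: str
    start: int  # 0-based inclusive
    end: int    # 0-based exclusive
    strand: str

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"exon {self.gene_id}/{self.exon_id}: require 0 <= start < end, "
                f"got [{self.start}, {self.end})"
            )
        if self.strand not in STRANDS:
            raise ValueError(
                f"exon {self.gene_id}/{self.exon_id}: strand must be '+' or '-', "
                f"got {self.strand!r}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class Junction:
    """A splice junction: the intron it removes plus its read support.

    ``strand`` may be ``'.'`` (unknown); such junctions match exons of either
    strand on the same chromosome.
    """

    chrom: str
    intron_start: int  # 0-based inclusive (first intronic base)
    intron_end: int    # 0-based exclusive (base after last intronic base)
    strand: str
    read_count: int

    def __post_init__(self) -> None:
        if self.intron_start >= self.intron_end:
            raise ValueError(
                f"junction {self.chrom}:{self.intron_start}-{self.intron_end}: "
                "intron_start must be < intron_end"
            )
        if self.read_count < 0:
            raise ValueError(
                f"junction {self.chrom}:{self.intron_start}-{self.intron_end}: "
                f"negative read count {self.read_count}"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"bad junction strand {self.strand!r}")

    @property
    def key(self) -> Tuple[str, int, int, str]:
        return (self.chrom, self.intron_start, self.intron_end, self.strand)


class JunctionSet:
    """Per-sample weighted splice junctions, unique per intron."""

    def __init__(self, sample_id: str, junctions: Iterable[Junction] = ()) -> None:
        self.sample_id = sample_id
        self._records: Dict[Tuple[str, int, int, str], Junction] = {}
        self._arrays: Dict[str, Tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]] = {}
        for j in junctions:
            self.add(j)

    def add(self, junction: Junction) -> None:
        if junction.key in self._records:
            raise ValueError(
                f"duplicate junction {junction.chrom}:{junction.intron_start}-"
                f"{junction.intron_end}({junction.strand}) in sample {self.sample_id}"
            )
        self._records[junction.key] = junction
        self._arrays.clear()

    def __len__(self) -> int:
        return len(self._records)

    def __iter__(self) -> Iterator[Junction]:
        return iter(sorted(self._records.values(), key=lambda j: j.key))

    def by_chrom(self, chrom: str) -> Tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """Arrays (starts, ends, counts, strand codes) for one chromosome.

        Strand codes: +1 for '+', -1 for '-', 0 for unknown.
        """
        if chrom not in self._arrays:
            recs = [j for j in self._records.values() if j.chrom == chrom]
            code = {"+": 1, "-": -1, ".": 0}
            self._arrays[chrom] = (
                np.array([j.intron_start for j in recs], dtype=np.int64),
                np.array([j.intron_end for j in recs], dtype=np.int64),
                np.array([j.read_count for j in recs], dtype=np.int64),
                np.array([code[j.strand] for j in recs], dtype=np.int8),
            )
        return self._arrays[chrom]

    @classmethod
    def merge(cls, sample_id: str, sets: Iterable["JunctionSet"]) -> "JunctionSet":
        """Sum read counts over several junction sets (additivity of evidence)."""
        acc: Dict[Tuple[str, int, int, str], int] = {}
        for js in sets:
            for j in js:
                acc[j.key] = acc.get(j.key, 0) + j.read_count
        merged = cls(sample_id)
        for (chrom, s, e, strand), n in acc.items():
            merged.add(Junction(chrom, s, e, strand, n))
        return merged


@dataclass(frozen=True)
class PasRecord:
    """A polyadenylation (cleavage) site, 0-based position, strand required."""

    gene_id: str
    chrom: str
    site: int
    strand: str

    def __post_init__(self) -> None:
        if self.site < 0:
            raise ValueError(f"PAS {self.gene_id}: negative site {self.site}")
        if self.strand not in STRANDS:
            raise ValueError(f"PAS {self.gene_id}: strand must be '+' or '-'")


class CoverageTrack:
    """Piecewise-constant read depth: sorted non-overlapping intervals per chromosome.

    ``mean_read_length`` is set when the track was built from read intervals;
    window counts are then reported in read equivalents (area / read length)
    instead of raw base-units of area.
    """

    def __init__(
        self,
        intervals: Mapping[str, Iterable[Tuple[int, int, float]]] | None = None,
        mean_read_length: Optional[float] = None,
    ) -> None:
        self._chroms: Dict[str, Tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        self.mean_read_length = mean_read_length
        if intervals:
            for chrom, ivs in intervals.items():
                self._set_chrom(chrom, list(ivs))

    def _set_chrom(self, chrom: str, ivs: List[Tuple[int, int, float]]) -> None:
        ivs = sorted(ivs)
        starts = np.array([iv[0] for iv in ivs], dtype=np.int64)
        ends = np.array([iv[1] for iv in ivs], dtype=np.int64)
        depths = np.array([iv[2] for iv in ivs], dtype=np.float64)
        if np.any(ends <= starts):
            raise ValueError(f"{chrom}: empty or inverted coverage interval")
        if np.any(depths < 0):
            raise ValueError(f"{chrom}: negative depth")
        if len(starts) > 1 and np.any(starts[1:] < ends[:-1]):
            raise ValueError(f"{chrom}: overlapping coverage intervals")
        self._chroms[chrom] = (starts, ends, depths)

    @property
    def chroms(self) -> List[str]:
        return sorted(self._chroms)

    def intervals(self, chrom: str) -> List[Tuple[int, int, float]]:
        if chrom not in self._chroms:
            return []
        starts, ends, depths = self._chroms[chrom]
        return [(int(s), int(e), float(d)) for s, e, d in zip(starts, ends, depths)]

    @classmethod
    def from_reads(
        cls, reads: Mapping[str, Iterable[Tuple[int, int]]]
    ) -> "CoverageTrack":
        """Sweep-line depth from a pile of read intervals (0-based half-open)."""
        track = cls()
        total_len = 0
        n_reads = 0
        for chrom, ivs in reads.items():
            events: Dict[int, float] = {}
            for s, e in ivs:
                if e <= s or s < 0:
                    raise ValueError(f"{chrom}: bad read interval [{s}, {e})")
                events[s] = events.get(s, 0) + 1
                events[e] = events.get(e, 0) - 1
                total_len += e - s
                n_reads += 1
            pos = sorted(events)
            out: List[Tuple[int, int, float]] = []
            depth = 0.0
            for p0, p1 in zip(pos, pos[1:]):
                depth += events[p0]
                if depth > 0:
                    out.append((p0, p1, depth))
            track._set_chrom(chrom, out)
        track.mean_read_length = total_len / n_reads if n_reads else None
        return track

    @classmethod
    def accumulate(
        cls, segments: Mapping[str, Iterable[Tuple[int, int, float]]]
    ) -> "CoverageTrack":
        """Sum possibly-overlapping depth segments into a canonical track."""
        track = cls()
        for chrom, segs in segments.items():
            events: Dict[int, float] = {}
            for s, e, d in segs:
                if e <= s:
                    raise ValueError(f"{chrom}: bad segment [{s}, {e})")
                events[s] = events.get(s, 0.0) + d
                events[e] = events.get(e, 0.0) - d
            pos = sorted(events)
            out: List[Tuple[int, int, float]] = []
            depth = 0.0
            for p0, p1 in zip(pos, pos[1:]):
                depth += events[p0]
                if depth > 1e-12:
                    out.append((p0, p1, depth))
            if out:
                track._set_chrom(chrom, out)
        return track

    def window_sum(self, chrom: str, start: int, end: int) -> float:
        """Integral of depth over [start, end); 0 outside covered intervals."""
        if end <= start or chrom not in self._chroms:
            return 0.0
        starts, ends, depths = self._chroms[chrom]
        lo = np.maximum(starts, start)
        hi = np.minimum(ends, end)
        overlap = np.clip(hi - lo, 0, None)
        return float(np.dot(overlap, depths))

    def total_mass(self) -> float:
        return sum(
            float(np.dot(e - s, d)) for s, e, d in self._chroms.values()
        )


class ExpressionTable:
    """Gene x sample expression matrix (TPM), all values non-negative."""

    def __init__(self, frame: pd.DataFrame) -> None:
        if (frame.values < 0).any():
            raise ValueError("expression values must be non-negative")
        self.frame = frame.astype(float)

    @property
    def genes(self) -> List[str]:
        return list(self.frame.index)

    @property
    def samples(self) -> List[str]:
        return list(self.frame.columns)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self.frame.index

    def value(self, gene_id: str, sample_id: str) -> float:
        return float(self.frame.at[gene_id, sample_id])

    def passes_cutoff(self, gene_id: str, samples: Iterable[str], cutoff: float) -> bool:
        """True when the gene exceeds the TPM cutoff in *every* listed sample."""
        vals = self.frame.loc[gene_id, list(samples)]
        return bool((vals > cutoff).all())


@dataclass
class SampleDesign:
    """Sample -> genotype map plus optional per-sample input paths."""

    samples: List[str]
    genotypes: Dict[str, str]
    junction_paths: Dict[str, str] = field(default_factory=dict)
    coverage_paths: Dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(set(self.samples)) != len(self.samples):
            raise ValueError("duplicate sample_id in design")
        for s in self.samples:
            g = self.genotypes.get(s)
            if g not in ("WT", "MUT"):
                raise ValueError(f"sample {s}: genotype must be WT or MUT, got {g!r}")

    def samples_for(self, genotype: str) -> List[str]:
        return [s for s in self.samples if self.genotypes[s] == genotype]

    def require_replicates(self, n: int = 2) -> None:
        for g in ("WT", "MUT"):
            k = len(self.samples_for(g))
            if k < n:
                raise ValueError(f"genotype {g} has {k} usable samples; need >= {n}")


@dataclass(frozen=True)
class QpcrMeasurement:
    """One (target, organ, mouse) qPCR pair: abnormal- and normal-isoform Ct.

    ``None`` marks a target that never crossed threshold within the run.
    """

    target: str
    organ: str
    genotype: str
    mouse_id: str
    ct_abnormal: Optional[float]
    ct_normal: Optional[float]

    def __post_init__(self) -> None:
        if self.genotype not in ("WT", "MUT"):
            raise ValueError(f"genotype must be WT or MUT, got {self.genotype!r}")
        for name, v in (("ct_abnormal", self.ct_abnormal), ("ct_normal", self.ct_normal)):
            if v is not None and v <= 0:
                raise ValueError(f"{name} must be positive when detected, got {v}")


@dataclass(frozen=True)
class DeltaCt:
    """A dCt(abnormal - normal) value with detection-limit semantics.

    ``is_lower_limit`` marks values censored because the abnormal isoform was
    undetected (true dCt >= value).  ``is_missing`` marks pairs where the
    normal isoform itself was undetected, so no dCt is defined.
    """

    value: float
    is_lower_limit: bool = False
    is_missing: bool = False

    def __post_init__(self) -> None:
        if self.is_missing and self.is_lower_limit:
            raise ValueError("a missing dCt cannot also be a lower limit")

    def token(self) -> str:
        """Render the value the way censored qPCR tables print it."""
        if self.is_missing:
            return "ND"
        if self.is_lower_limit:
            return f">{self.value:g}"
        return f"{self.value:g}"
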