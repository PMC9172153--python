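"""Readers and writers for the external formats.

Dialects handled here:

* exon annotation: GTF 2.2 (1-based inclusive on disk) and BED12
* splice junctions: BED12 junction rows (TopHat-style, two anchor blocks)
  and STAR ``SJ.out.tab``
* coverage: bedGraph, or a BED of read intervals piled into depth
* PAS catalog: BED6, one 1-bp interval per cleavage site
* tables: TSV with a header row (expression, design, qPCR Ct, dCt)

Everything is converted to 0-based half-open coordinates on the way in and
back to each dialect's native convention on the way out.
"""

from __future__ import annotations

import logging
import re
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import pandas as pd

from .datamodel import (
    CoverageTrack,
    DeltaCt,
    ExonRecord,
    ExpressionTable,
    Junction,
    JunctionSet,
    PasRecord,
    QpcrMeasurement,
    SampleDesign,
)

log = logging.getLogger(__name__)

_GTF_ATTR = re.compile(r'(\w+)\s+"([^"]*)"')


def _fields(line: str, sep: str = "\t") -> List[str]:
    return line.rstrip("\n").split(sep)


# ---------------------------------------------------------------------------
# exon annotation
# ---------------------------------------------------------------------------

def read_exon_annotation(path: str | Path, dialect: str = "gtf") -> List[ExonRecord]:
    """Read exon records from a GTF or BED12 file.

    GTF coordinates (1-based inclusive) are converted to 0-based half-open.
    Duplicate exons (same gene, coordinates and strand) are collapsed.
    """
    if dialect == "gtf":
        exons = _read_gtf_exons(path)
    elif dialect == "bed12":
        exons = _read_bed12_exons(path)
    else:
        raise ValueError(f"unknown annotation dialect {dialect!r}")
    if not exons:
        log.warning("annotation %s: no exons found", path)
    seen: Dict[Tuple[str, str, int, int, str], ExonRecord] = {}
    for ex in exons:
        key = (ex.gene_id, ex.chrom, ex.start, ex.end, ex.strand)
        seen.setdefault(key, ex)
    out = list(seen.values())
    ids = {(e.gene_id, e.exon_id) for e in out}
    if len(ids) != len(out):
        raise ValueError(f"annotation {path}: (gene_id, exon_id) pairs not unique")
    return out


def _read_gtf_exons(path: str | Path) -> List[ExonRecord]:
    exons: List[ExonRecord] = []
    per_gene: Dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            f = _fields(line)
            if len(f) < 9:
                raise ValueError(f"{path}:{lineno}: expected 9 GTF fields, got {len(f)}")
            if f[2] != "exon":
                continue
            try:
                start1, end1 = int(f[3]), int(f[4])
            except ValueError as err:
                raise ValueError(f"{path}:{lineno}: bad coordinates") from err
            attrs = dict(_GTF_ATTR.findall(f[8]))
            gene_id = attrs.get("gene_id")
            if gene_id is None:
                raise ValueError(f"{path}:{lineno}: exon without gene_id attribute")
            exon_id = attrs.get("exon_id")
            if exon_id is None:
                per_gene[gene_id] = per_gene.get(gene_id, 0) + 1
                exon_id = f"{gene_id}.e{per_gene[gene_id]}"
            if f[6] == ".":
                raise ValueError(f"{path}:{lineno}: exon strand '.' is not allowed")
            exons.append(
                ExonRecord(gene_id, exon_id, f[0], start1 - 1, end1, f[6])
            )
    return exons


def _read_bed12_exons(path: str | Path) -> List[ExonRecord]:
    exons: List[ExonRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("#", "track")):
                continue
            f = _fields(line)
            if len(f) < 12:
                raise ValueError(f"{path}:{lineno}: expected 12 BED12 fields, got {len(f)}")
            chrom, start, name, strand = f[0], int(f[1]), f[3], f[5]
            if strand == ".":
                raise ValueError(f"{path}:{lineno}: exon strand '.' is not allowed")
            n_blocks = int(f[9])
            sizes = [int(x) for x in f[10].rstrip(",").split(",")]
            offsets = [int(x) for x in f[11].rstrip(",").split(",")]
            if len(sizes) != n_blocks or len(offsets) != n_blocks:
                raise ValueError(f"{path}:{lineno}: block fields disagree with blockCount")
            for i, (sz, off) in enumerate(zip(sizes, offsets), 1):
                exons.append(
                    ExonRecord(name, f"{name}.{i}", chrom, start + off,
                               start + off + sz, strand)
                )
    return exons


def write_exon_annotation(
    exons: Sequence[ExonRecord], path: str | Path, dialect: str = "gtf",
    source: str = "splicedrift",
) -> None:
    if dialect == "gtf":
        with open(path, "w") as fh:
            for ex in sorted(exons, key=lambda e: (e.chrom, e.start, e.end)):
                attrs = f'gene_id "{ex.gene_id}"; exon_id "{ex.exon_id}";'
                fh.write(
                    f"{ex.chrom}\t{source}\texon\t{ex.start + 1}\t{ex.end}\t.\t"
                    f"{ex.strand}\t.\t{attrs}\n"
                )
    elif dialect == "bed12":
        by_gene: Dict[str, List[ExonRecord]] = {}
        for ex in exons:
            by_gene.setdefault(ex.gene_id, []).append(ex)
        with open(path, "w") as fh:
            for gene_id in sorted(by_gene):
                exs = sorted(by_gene[gene_id], key=lambda e: e.start)
                chrom, strand = exs[0].chrom, exs[0].strand
                if any(e.chrom != chrom or e.strand != strand for e in exs):
                    raise ValueError(f"gene {gene_id}: exons span chromosomes/strands")
                start, end = exs[0].start, max(e.end for e in exs)
                sizes = ",".join(str(e.length) for e in exs)
                offsets = ",".join(str(e.start - start) for e in exs)
                fh.write(
                    f"{chrom}\t{start}\t{end}\t{gene_id}\t0\t{strand}\t{start}\t"
                    f"{end}\t0\t{len(exs)}\t{sizes}\t{offsets}\n"
                )
    else:
        raise ValueError(f"unknown annotation dialect {dialect!r}")


# ---------------------------------------------------------------------------
# splice junctions
# ---------------------------------------------------------------------------

_SJ_STRAND = {"0": ".", "1": "+", "2": "-"}


def read_junctions(
    path: str | Path, dialect: str = "bed12_junctions", sample_id: Optional[str] = None
) -> JunctionSet:
    """Read one sample's junction evidence.

    ``bed12_junctions``: TopHat-style rows with two anchor blocks; the intron
    is (chromStart + blockSizes[0], chromEnd - blockSizes[1]) and the score
    column carries the supporting read count.

    ``sj_tab``: STAR ``SJ.out.tab``; the 1-based inclusive intron is converted
    to 0-based half-open and the unique-mapping read count is used.
    """
    sample = sample_id or Path(path).stem
    js = JunctionSet(sample)
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("#", "track")):
                continue
            f = _fields(line)
            if dialect == "bed12_junctions":
                if len(f) < 12:
                    raise ValueError(
                        f"{path}:{lineno}: expected 12 BED12 fields, got {len(f)}"
                    )
                if int(f[9]) != 2:
                    log.warning("%s:%d: blockCount != 2, junction skipped", path, lineno)
                    continue
                sizes = [int(x) for x in f[10].rstrip(",").split(",")]
                start, end = int(f[1]), int(f[2])
                count = int(f[4])
                if count < 0:
                    raise ValueError(f"{path}:{lineno}: negative junction count")
                js.add(Junction(f[0], start + sizes[0], end - sizes[1], f[5], count))
            elif dialect == "sj_tab":
                if len(f) < 7:
                    raise ValueError(
                        f"{path}:{lineno}: expected >= 7 SJ.out.tab fields, got {len(f)}"
                    )
                count = int(f[6])
                if count < 0:
                    raise ValueError(f"{path}:{lineno}: negative junction count")
                js.add(
                    Junction(f[0], int(f[1]) - 1, int(f[2]),
                             _SJ_STRAND.get(f[3], "."), count)
                )
            else:
                raise ValueError(f"unknown junction dialect {dialect!r}")
    return js


def write_junctions(
    js: JunctionSet, path: str | Path, dialect: str = "bed12_junctions",
    anchor: int = 8,
) -> None:
    strand_code = {".": "0", "+": "1", "-": "2"}
    with open(path, "w") as fh:
        for i, j in enumerate(js):
            if dialect == "bed12_junctions":
                a = min(anchor, j.intron_start)
                if a == 0:
                    raise ValueError("cannot anchor a junction whose intron starts at 0")
                start = j.intron_start - a
                end = j.intron_end + anchor
                fh.write(
                    f"{j.chrom}\t{start}\t{end}\tJUNC{i:06d}\t{j.read_count}\t"
                    f"{j.strand}\t{start}\t{end}\t0\t2\t{a},{anchor}\t"
                    f"0,{j.intron_end - start}\n"
                )
            elif dialect == "sj_tab":
                fh.write(
                    f"{j.chrom}\t{j.intron_start + 1}\t{j.intron_end}\t"
                    f"{strand_code[j.strand]}\t0\t0\t{j.read_count}\t0\t0\n"
                )
            else:
                raise ValueError(f"unknown junction dialect {dialect!r}")


# ---------------------------------------------------------------------------
# coverage
# ---------------------------------------------------------------------------

def read_coverage(path: str | Path, dialect: str = "bedgraph") -> CoverageTrack:
    if dialect == "bedgraph":
        ivs: Dict[str, List[Tuple[int, int, float]]] = {}
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                if not line.strip() or line.startswith(("#", "track")):
                    continue
                f = _fields(line)
                if len(f) < 4:
                    raise ValueError(f"{path}:{lineno}: expected 4 bedGraph fields")
                ivs.setdefault(f[0], []).append((int(f[1]), int(f[2]), float(f[3])))
        # CoverageTrack validates sortedness/overlap after an internal sort
        return CoverageTrack(ivs)
    if dialect == "read_bed":
        reads: Dict[str, List[Tuple[int, int]]] = {}
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                if not line.strip() or line.startswith(("#", "track")):
                    continue
                f = _fields(line)
                if len(f) < 3:
                    raise ValueError(f"{path}:{lineno}: expected >= 3 BED fields")
                reads.setdefault(f[0], []).append((int(f[1]), int(f[2])))
        return CoverageTrack.from_reads(reads)
    raise ValueError(f"unknown coverage dialect {dialect!r}")


def write_coverage(track: CoverageTrack, path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom in track.chroms:
            for s, e, d in track.intervals(chrom):
                fh.write(f"{chrom}\t{s}\t{e}\t{d:g}\n")


# ---------------------------------------------------------------------------
# PAS catalog (BED6, one 1-bp interval per site)
# ---------------------------------------------------------------------------

def read_pas_bed(path: str | Path) -> List[PasRecord]:
    out: List[PasRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("#", "track")):
                continue
            f = _fields(line)
            if len(f) < 6:
                raise ValueError(f"{path}:{lineno}: expected 6 BED fields")
            start, end = int(f[1]), int(f[2])
            if end != start + 1:
                raise ValueError(
                    f"{path}:{lineno}: PAS rows must be 1-bp intervals, got [{start},{end})"
                )
            if f[5] == ".":
                raise ValueError(f"{path}:{lineno}: PAS strand '.' is not allowed")
            out.append(PasRecord(f[3], f[0], start, f[5]))
    return out


def write_pas_bed(sites: Sequence[PasRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for p in sorted(sites, key=lambda p: (p.chrom, p.site, p.gene_id)):
            fh.write(f"{p.chrom}\t{p.site}\t{p.site + 1}\t{p.gene_id}\t0\t{p.strand}\n")


# ---------------------------------------------------------------------------
# tables
# ---------------------------------------------------------------------------

def _require_columns(frame: pd.DataFrame, cols: Iterable[str], path: str | Path) -> None:
    missing = [c for c in cols if c not in frame.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s): {', '.join(missing)}")


def read_expression_table(path: str | Path) -> ExpressionTable:
    frame = pd.read_csv(path, sep="\t")
    _require_columns(frame, ["gene_id"], path)
    frame = frame.set_index("gene_id")
    if frame.shape[1] == 0:
        raise ValueError(f"{path}: expression table has no sample columns")
    return ExpressionTable(frame)


def write_expression_table(table: ExpressionTable, path: str | Path) -> None:
    table.frame.to_csv(path, sep="\t", index_label="gene_id")


def read_design(path: str | Path) -> SampleDesign:
    frame = pd.read_csv(path, sep="\t", dtype=str)
    _require_columns(frame, ["sample_id", "genotype"], path)
    samples = list(frame["sample_id"])
    genotypes = dict(zip(frame["sample_id"], frame["genotype"]))
    jp = (
        dict(zip(frame["sample_id"], frame["junction_file"]))
        if "junction_file" in frame.columns else {}
    )
    cp = (
        dict(zip(frame["sample_id"], frame["coverage_file"]))
        if "coverage_file" in frame.columns else {}
    )
    return SampleDesign(samples, genotypes, jp, cp)


def write_design(design: SampleDesign, path: str | Path) -> None:
    cols = ["sample_id", "genotype"]
    rows = []
    for s in design.samples:
        row = {"sample_id": s, "genotype": design.genotypes[s]}
        if design.junction_paths:
            row["junction_file"] = design.junction_paths.get(s, "")
        if design.coverage_paths:
            row["coverage_file"] = design.coverage_paths.get(s, "")
        rows.append(row)
    frame = pd.DataFrame(rows)
    frame.to_csv(path, sep="\t", index=False)


def _parse_ct(token: str, where: str) -> Optional[float]:
    token = token.strip()
    if token.upper() == "ND":
        return None
    try:
        return float(token)
    except ValueError as err:
        raise ValueError(f"{where}: bad Ct value {token!r}") from err


def read_qpcr_table(path: str | Path) -> List[QpcrMeasurement]:
    """Raw Ct pairs: columns target, organ, genotype, mouse_id, ct_abnormal, ct_normal."""
    frame = pd.read_csv(path, sep="\t", dtype=str)
    _require_columns(
        frame, ["target", "organ", "genotype", "mouse_id", "ct_abnormal", "ct_normal"], path
    )
    out = []
    for i, row in frame.iterrows():
        where = f"{path}: row {i + 2}"
        out.append(
            QpcrMeasurement(
                row["target"], row["organ"], row["genotype"], row["mouse_id"],
                _parse_ct(row["ct_abnormal"], where),
                _parse_ct(row["ct_normal"], where),
            )
        )
    return out


def parse_delta_ct_token(token: str) -> DeltaCt:
    """Parse a published-style dCt cell: a number, ``">x"`` or ``"ND"``."""
    token = token.strip()
    if token.upper() == "ND":
        return DeltaCt(float("nan"), is_missing=True)
    if token.startswith(">"):
        return DeltaCt(float(token[1:]), is_lower_limit=True)
    return DeltaCt(float(token.replace("−", "-")))


def read_delta_ct_table(path: str | Path) -> pd.DataFrame:
    """Long-format pre-computed dCt table.

    Columns: organ, target, genotype, mouse_id, delta_ct (token).  Returns a
    frame with parsed ``value`` / ``is_lower_limit`` / ``is_missing`` columns.
    """
    frame = pd.read_csv(path, sep="\t", dtype=str)
    _require_columns(frame, ["organ", "target", "genotype", "mouse_id", "delta_ct"], path)
    parsed = [parse_delta_ct_token(t) for t in frame["delta_ct"]]
    frame = frame.copy()
    frame["value"] = [d.value for d in parsed]
    frame["is_lower_limit"] = [d.is_lower_limit for d in parsed]
    frame["is_missing"] = [d.is_missing for d in parsed]
    return frame


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def write_fasta(sequences: Dict[str, str], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name in sequences:
            fh.write(f">{name}\n")
            seq = sequences[name]
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def read_fasta(path: str | Path) -> Dict[str, str]:
    """Load a (small) FASTA into memory; use pyfaidx for large genomes."""
    seqs: Dict[str, str] = {}
    name = None
    chunks: List[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip()
            if line.startswith(">"):
                if name is not None:
                    seqs[name] = "".join(chunks)
                name = line[1:].split()[0]
                chunks = []
            elif line:
                chunks.append(line)
    if name is not None:
        seqs[name] = "".join(chunks)
    return seqs
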