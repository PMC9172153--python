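"""Transcription-termination accuracy downstream of polyadenylation sites.

For each catalogued PAS, read signal is integrated over a fixed-width window
immediately downstream of the cleavage site *in the direction of
transcription* (strand-mirrored for minus-strand genes), normalized by the
owning gene's expression, and compared between genotypes exactly as in the
exon-usage stage: signed contrast x plus Welch p.  Positive x means more
downstream signal in the mutant, i.e. transcriptional readthrough; negative
x means relatively effective PAS usage in the mutant.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Mapping, Sequence, Tuple

import math

import pandas as pd

from .datamodel import CoverageTrack, ExpressionTable, PasRecord, SampleDesign
from .exon_usage import DEFAULT_TPM_CUTOFF
from .stats import normalized_contrast, welch_t

log = logging.getLogger(__name__)

DEFAULT_PAS_WINDOW = 275


@dataclass
class ReadthroughEvent:
    pas: PasRecord
    rates: Dict[str, float]
    x: float
    p: float
    degenerate: bool = False


def downstream_window(
    pas: PasRecord, width: int = DEFAULT_PAS_WINDOW
) -> Tuple[int, int, bool]:
    """The [start, end) window downstream of the site, strand-mirrored.

    Returns (start, end, clipped): clipped is True when the window ran off
    the chromosome start and was truncated at 0.
    """
    if width <= 0:
        raise ValueError("window width must be positive")
    if pas.strand == "+":
        return pas.site, pas.site + width, False
    start = pas.site - width
    if start < 0:
        return 0, pas.site, True
    return start, pas.site, False


def window_count(track: CoverageTrack, chrom: str, start: int, end: int) -> float:
    """Signal in [start, end): depth-area, or read equivalents when the track
    was built from reads of known mean length."""
    area = track.window_sum(chrom, start, end)
    if track.mean_read_length:
        return area / track.mean_read_length
    return area


def readthrough_table(
    pas_catalog: Sequence[PasRecord],
    coverage: Mapping[str, CoverageTrack],
    expression: ExpressionTable,
    design: SampleDesign,
    width: int = DEFAULT_PAS_WINDOW,
    alpha: float = 0.05,
    tpm_cutoff: float = DEFAULT_TPM_CUTOFF,
) -> List[ReadthroughEvent]:
    """Per-PAS downstream rates, contrast and Welch p, sorted by p."""
    design.require_replicates(2)
    wt = design.samples_for("WT")
    mut = design.samples_for("MUT")
    for s in design.samples:
        if s not in coverage:
            raise ValueError(f"no coverage track for sample {s}")
        if s not in expression.samples:
            raise ValueError(f"sample {s} missing from expression table")

    events: List[ReadthroughEvent] = []
    n_orphan = n_cutoff = n_dropped = 0
    for pas in pas_catalog:
        if pas.gene_id not in expression:
            n_orphan += 1
            continue
        if not expression.passes_cutoff(pas.gene_id, design.samples, tpm_cutoff):
            n_cutoff += 1
            continue
        start, end, _clipped = downstream_window(pas, width)
        rates: Dict[str, float] = {}
        for s in design.samples:
            tpm = expression.value(pas.gene_id, s)
            rates[s] = window_count(coverage[s], pas.chrom, start, end) / tpm
        x = normalized_contrast([rates[s] for s in mut], [rates[s] for s in wt])
        if math.isnan(x):
            n_dropped += 1
            continue
        res = welch_t([rates[s] for s in mut], [rates[s] for s in wt])
        events.append(ReadthroughEvent(pas, rates, x, res.p, res.degenerate))
    if n_orphan:
        log.warning("readthrough_table: %d orphan PAS skipped (gene not in "
                    "expression table)", n_orphan)
    if n_cutoff:
        log.info("readthrough_table: %d PAS excluded by the TPM cutoff", n_cutoff)
    if n_dropped:
        log.info("readthrough_table: %d PAS dropped with zero signal in both "
                 "genotypes", n_dropped)
    events.sort(key=lambda e: (e.p, e.pas.gene_id, e.pas.site))
    return events


def readthrough_to_frame(
    events: Sequence[ReadthroughEvent], design: SampleDesign
) -> pd.DataFrame:
    rows = []
    for ev in events:
        row = {
            "gene_id": ev.pas.gene_id,
            "chrom": ev.pas.chrom,
            "site": ev.pas.site,
            "strand": ev.pas.strand,
            "x": ev.x,
            "p": ev.p,
        }
        for s in design.samples:
            row[f"rate.{s}"] = ev.rates[s]
        rows.append(row)
    return pd.DataFrame(rows)


def summarize_readthrough(
    events: Sequence[ReadthroughEvent], alpha: float = 0.05
) -> Dict[str, int]:
    sig = [e for e in events if e.p < alpha]
    return {
        "n_tested": len(events),
        "n_significant": len(sig),
        "n_readthrough": sum(1 for e in sig if e.x > 0),
        "n_effective_usage": sum(1 for e in sig if e.x < 0),
    }
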