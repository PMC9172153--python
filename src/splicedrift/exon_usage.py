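"""Differential exon usage from splice-junction evidence.

For every annotated exon and every sample we count

* skip evidence: reads of junctions whose intron spans the whole exon
  (intron_start < exon.start and intron_end > exon.end), and
* inclusion evidence: reads of junctions anchored exactly at either exon
  boundary (intron_end == exon.start or intron_start == exon.end).

Counts are normalized by the expression (TPM) of the owning gene in the same
sample, the genotype contrast x = (mut - wt) / (mut + wt) is computed for
both rate kinds, the larger-magnitude direction classifies the event
(exclusion vs inclusion) and a Welch t-test across per-sample rates gives
the p-value.  Exclusion events are plotted with positive x, inclusion events
with negative x (the inclusion-rate contrast is negated), so all-or-nothing
events land exactly on the +/-1 edges of the volcano.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .datamodel import ExonRecord, ExpressionTable, JunctionSet, SampleDesign
from .stats import normalized_contrast, welch_t

log = logging.getLogger(__name__)

DEFAULT_TPM_CUTOFF = 0.025

#: Sentinel returned by :func:`normalize_rates` for under-the-cutoff genes.
EXCLUDED = None


@dataclass
class UsageEvent:
    """One volcano dot: an exon with its per-sample rates, contrast and p."""

    exon: ExonRecord
    skip_rates: Dict[str, float]
    incl_rates: Dict[str, float]
    event_class: str  # "exclusion" | "inclusion"
    x: float
    p: float
    degenerate: bool = False


def count_skip(exon: ExonRecord, junctions: JunctionSet) -> int:
    """Total reads of junctions whose intron spans the whole exon."""
    starts, ends, counts, strands = junctions.by_chrom(exon.chrom)
    if starts.size == 0:
        return 0
    want = 1 if exon.strand == "+" else -1
    mask = (
        (starts < exon.start)
        & (ends > exon.end)
        & ((strands == 0) | (strands == want))
    )
    return int(counts[mask].sum())


def count_inclusion(exon: ExonRecord, junctions: JunctionSet) -> int:
    """Total reads of junctions anchored exactly at either exon boundary."""
    starts, ends, counts, strands = junctions.by_chrom(exon.chrom)
    if starts.size == 0:
        return 0
    want = 1 if exon.strand == "+" else -1
    mask = ((ends == exon.start) | (starts == exon.end)) & (
        (strands == 0) | (strands == want)
    )
    return int(counts[mask].sum())


def normalize_rates(
    count: int, expression: float, cutoff: float = DEFAULT_TPM_CUTOFF
) -> Optional[float]:
    """count / TPM, or ``EXCLUDED`` when the gene is below the TPM cutoff."""
    if count < 0:
        raise ValueError(f"negative count {count}")
    if expression < 0:
        raise ValueError(f"negative expression {expression}")
    if expression <= cutoff:
        return EXCLUDED
    return count / expression


def usage_table(
    annotation: Sequence[ExonRecord],
    junction_sets: Mapping[str, JunctionSet],
    expression: ExpressionTable,
    design: SampleDesign,
    alpha: float = 0.05,
    tpm_cutoff: float = DEFAULT_TPM_CUTOFF,
) -> List[UsageEvent]:
    """Per-exon skip/inclusion rates, contrast and Welch p, sorted by p.

    A gene must exceed the TPM cutoff in every sample for its exons to be
    testable; exons with no junction evidence in either direction are
    dropped (with a log entry of the count).
    """
    design.require_replicates(2)
    wt = design.samples_for("WT")
    mut = design.samples_for("MUT")
    for s in design.samples:
        if s not in junction_sets:
            raise ValueError(f"no junction set for sample {s}")
        if s not in expression.samples:
            raise ValueError(f"sample {s} missing from expression table")

    events: List[UsageEvent] = []
    n_dropped = n_below_cutoff = 0
    for exon in annotation:
        if exon.gene_id not in expression:
            n_below_cutoff += 1
            continue
        if not expression.passes_cutoff(exon.gene_id, design.samples, tpm_cutoff):
            n_below_cutoff += 1
            continue
        skip_rates: Dict[str, float] = {}
        incl_rates: Dict[str, float] = {}
        for s in design.samples:
            tpm = expression.value(exon.gene_id, s)
            skip_rates[s] = count_skip(exon, junction_sets[s]) / tpm
            incl_rates[s] = count_inclusion(exon, junction_sets[s]) / tpm
        x_skip = normalized_contrast(
            [skip_rates[s] for s in mut], [skip_rates[s] for s in wt]
        )
        x_incl = normalized_contrast(
            [incl_rates[s] for s in mut], [incl_rates[s] for s in wt]
        )
        if math.isnan(x_skip) and math.isnan(x_incl):
            n_dropped += 1
            continue
        # dominant direction: larger |contrast| wins, ties go to exclusion
        if math.isnan(x_incl) or (
            not math.isnan(x_skip) and abs(x_skip) >= abs(x_incl)
        ):
            event_class = "exclusion"
            rates = skip_rates
            x = x_skip
        else:
            event_class = "inclusion"
            rates = incl_rates
            x = -x_incl
        res = welch_t([rates[s] for s in mut], [rates[s] for s in wt])
        events.append(
            UsageEvent(exon, skip_rates, incl_rates, event_class, x, res.p,
                       res.degenerate)
        )
    if n_dropped:
        log.info("usage_table: %d exons dropped with no junction evidence", n_dropped)
    if n_below_cutoff:
        log.info("usage_table: %d exons excluded by the TPM cutoff", n_below_cutoff)
    events.sort(key=lambda e: (e.p, e.exon.gene_id, e.exon.exon_id))
    return events


def usage_to_frame(events: Sequence[UsageEvent], design: SampleDesign) -> pd.DataFrame:
    rows = []
    for ev in events:
        row = {
            "gene_id": ev.exon.gene_id,
            "exon_id": ev.exon.exon_id,
            "chrom": ev.exon.chrom,
            "start": ev.exon.start,
            "end": ev.exon.end,
            "strand": ev.exon.strand,
            "event_class": ev.event_class,
            "x": ev.x,
            "p": ev.p,
        }
        for s in design.samples:
            row[f"skip_rate.{s}"] = ev.skip_rates[s]
            row[f"incl_rate.{s}"] = ev.incl_rates[s]
        rows.append(row)
    return pd.DataFrame(rows)


def summarize_usage(events: Sequence[UsageEvent], alpha: float = 0.05) -> Dict[str, int]:
    """Significant-event counts split by direction, plus gene-body tally."""
    sig = [e for e in events if e.p < alpha]
    return {
        "n_tested": len(events),
        "n_significant": len(sig),
        "n_exclusion": sum(1 for e in sig if e.event_class == "exclusion"),
        "n_inclusion": sum(1 for e in sig if e.event_class == "inclusion"),
        "n_gene_bodies": len({e.exon.gene_id for e in sig}),
    }
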