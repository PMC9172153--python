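"""Compositional bias around differentially used exons.

For every significant usage event, three sequence windows are taken in
transcribed orientation: a fixed-width window upstream of the exon's 5'
boundary, the exon body itself, and a fixed-width window downstream of the
3' boundary (minus-strand exons are reverse-complemented and the flanks
swapped accordingly).  The normalized frequency of each of the 4^5 = 1024
possible 5-mers is computed per window, and each motif's frequencies are
rank-correlated (Spearman) against the events' signed usage contrast x.
Positive rho therefore associates a motif with exon exclusion in the
mutant, negative rho with inclusion.
"""

from __future__ import annotations

from itertools import product
from typing import Dict, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy import stats as sps

from .datamodel import ExonRecord
from .exon_usage import UsageEvent
from .stats import spearman_critical

DEFAULT_MOTIF_WINDOW = 250
DEFAULT_K = 5

WINDOW_CLASSES = ("upstream", "inside", "downstream")

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

#: base -> 2-bit code used for k-mer indexing; anything else is invalid
_CODE = np.full(256, -1, dtype=np.int64)
for _i, _b in enumerate("ACGT"):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i

GenomeLike = Union[Mapping[str, str], "object"]


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def motif_strings(k: int = DEFAULT_K) -> List[str]:
    """All 4^k motifs in the index order used by :func:`kmer_frequencies`."""
    return ["".join(p) for p in product("ACGT", repeat=k)]


def _chrom_seq(genome: GenomeLike, chrom: str) -> str:
    """Pull one chromosome as an upper-case string from a dict or a
    pyfaidx.Fasta-like object."""
    try:
        rec = genome[chrom]
    except KeyError as err:
        raise ValueError(f"chromosome {chrom} missing from genome") from err
    return str(rec if isinstance(rec, str) else rec[:]).upper()


def extract_windows(
    exon: ExonRecord, genome: GenomeLike, width: int = DEFAULT_MOTIF_WINDOW
) -> Tuple[str, str, str]:
    """(upstream, inside, downstream) sequences in transcribed orientation.

    Windows are clipped at chromosome bounds; for minus-strand exons all
    three sequences are reverse-complemented and the genomic left/right
    flanks swap roles.
    """
    seq = _chrom_seq(genome, exon.chrom)
    n = len(seq)
    if exon.end > n:
        raise ValueError(
            f"exon {exon.exon_id} extends beyond chromosome {exon.chrom} ({n} bp)"
        )
    left = seq[max(0, exon.start - width): exon.start]
    inside = seq[exon.start: exon.end]
    right = seq[exon.end: min(n, exon.end + width)]
    if exon.strand == "+":
        return left, inside, right
    return revcomp(right), revcomp(inside), revcomp(left)


def kmer_frequencies(seq: str, k: int = DEFAULT_K) -> np.ndarray:
    """Normalized overlapping k-mer frequencies as a 4^k vector.

    Windows containing non-ACGT letters are skipped and removed from the
    denominator; the vector sums to 1 whenever at least one window is valid,
    and is all-zero for sequences shorter than k.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    out = np.zeros(4 ** k, dtype=float)
    if len(seq) < k:
        return out
    codes = _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    windows = np.lib.stride_tricks.sliding_window_view(codes, k)
    valid = (windows >= 0).all(axis=1)
    if not valid.any():
        return out
    powers = 4 ** np.arange(k - 1, -1, -1, dtype=np.int64)
    idx = windows[valid] @ powers
    counts = np.bincount(idx, minlength=4 ** k)
    return counts / counts.sum()


def motif_usage_correlation(
    events: Sequence[UsageEvent],
    genome: GenomeLike,
    width: int = DEFAULT_MOTIF_WINDOW,
    k: int = DEFAULT_K,
    threshold: Optional[float] = None,
    alpha: float = 0.05,
    value_mode: str = "continuous",
) -> pd.DataFrame:
    """Spearman correlation of per-event motif frequency against usage x.

    ``value_mode="continuous"`` correlates against the signed contrast x;
    ``"binary"`` against +/-1 event-class labels.  ``threshold`` defaults to
    the one-tailed t-approximation critical |rho| at the event count (the
    published preset 0.0655 can be passed explicitly).

    Returns a frame with one row per (window_class, motif): columns motif,
    window_class, mean_frequency, rho, significant.
    """
    n = len(events)
    if n < 4:
        raise ValueError(f"need >= 4 events for motif correlation, got {n}")
    if value_mode == "continuous":
        xs = np.array([ev.x for ev in events], dtype=float)
    elif value_mode == "binary":
        xs = np.array(
            [1.0 if ev.event_class == "exclusion" else -1.0 for ev in events]
        )
    else:
        raise ValueError(f"unknown value_mode {value_mode!r}")
    if threshold is None:
        threshold = spearman_critical(n, alpha, "one")

    freq: Dict[str, np.ndarray] = {
        wc: np.empty((n, 4 ** k), dtype=float) for wc in WINDOW_CLASSES
    }
    for i, ev in enumerate(events):
        up, inside, down = extract_windows(ev.exon, genome, width)
        freq["upstream"][i] = kmer_frequencies(up, k)
        freq["inside"][i] = kmer_frequencies(inside, k)
        freq["downstream"][i] = kmer_frequencies(down, k)

    rank_x = sps.rankdata(xs)
    rank_x = rank_x - rank_x.mean()
    denom_x = np.sqrt(np.dot(rank_x, rank_x))
    motifs = motif_strings(k)
    rows = []
    for wc in WINDOW_CLASSES:
        mat = freq[wc]
        ranks = sps.rankdata(mat, axis=0)
        ranks = ranks - ranks.mean(axis=0)
        denom = np.sqrt((ranks ** 2).sum(axis=0)) * denom_x
        with np.errstate(invalid="ignore", divide="ignore"):
            rho = np.where(denom > 0, rank_x @ ranks / np.where(denom > 0, denom, 1.0),
                           np.nan)
        mean_freq = mat.mean(axis=0)
        for j, motif in enumerate(motifs):
            r = float(rho[j])
            rows.append({
                "motif": motif,
                "window_class": wc,
                "mean_frequency": float(mean_freq[j]),
                "rho": r,
                "significant": bool(not np.isnan(r) and abs(r) > threshold),
            })
    return pd.DataFrame(rows)
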