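"""Self-contained benchmark computations on simulated data.

These functions re-run the pipeline on freshly generated ground-truthed
inputs and measure calibration (type-I error on null data), planted-event
recovery (sensitivity, false-positive rate, contrast accuracy), the
qualitative motif-bias pattern, and the exact edge semantics of the
contrast statistic.  They back both the test suite and the reproduction
script.
"""

from __future__ import annotations

import math
from typing import Dict, Iterable, List, Sequence, Tuple

import numpy as np

from .datamodel import (
    ExonRecord,
    ExpressionTable,
    Junction,
    JunctionSet,
    SampleDesign,
)
from .exon_usage import usage_table
from .motif_bias import motif_usage_correlation
from .readthrough import readthrough_table
from .simulate import SimulationSpec, simulate
from .stats import spearman_critical

import pandas as pd

ALPHA = 0.05


def null_calibration(seeds: Sequence[int]) -> Dict[str, float]:
    """Fraction of null exon/PAS events with Welch p < alpha.

    Runs a no-planted-effects simulation (3 vs 3, default sizes) per seed
    and pools the rejection fraction over both event types.
    """
    n_exon = sig_exon = n_pas = sig_pas = 0
    for seed in seeds:
        spec = SimulationSpec(seed=seed, frac_exclusion=0.0, frac_inclusion=0.0,
                              frac_readthrough=0.0)
        res = simulate(spec)
        g, s = res.genome, res.samples
        ev = usage_table(g.exons, s.junctions, s.expression, s.design)
        rt = readthrough_table(g.pas, s.coverage, s.expression, s.design)
        n_exon += len(ev)
        sig_exon += sum(e.p < ALPHA for e in ev)
        n_pas += len(rt)
        sig_pas += sum(e.p < ALPHA for e in rt)
    return {
        "exon_rate": sig_exon / n_exon,
        "pas_rate": sig_pas / n_pas,
        "pooled_rate": (sig_exon + sig_pas) / (n_exon + n_pas),
        "n_exon": n_exon,
        "n_pas": n_pas,
        "n": n_exon + n_pas,
    }


def planted_recovery(seeds: Sequence[int]) -> Dict[str, float]:
    """Sensitivity / FPR / contrast accuracy on planted simulations.

    A planted event counts as recovered when it is significant at alpha,
    classified in the planted direction, and (for PAS) on the readthrough
    side.  Contrast accuracy is the mean |recovered x - planted x| over
    recovered events.
    """
    tp = {"exclusion": 0, "inclusion": 0, "readthrough": 0}
    total = {"exclusion": 0, "inclusion": 0, "readthrough": 0}
    fp_exon = null_exon = fp_pas = null_pas = 0
    errs: List[float] = []
    for seed in seeds:
        res = simulate(SimulationSpec(seed=seed))
        g, s = res.genome, res.samples
        ev = usage_table(g.exons, s.junctions, s.expression, s.design)
        rt = readthrough_table(g.pas, s.coverage, s.expression, s.design)
        det = {(e.exon.gene_id, e.exon.exon_id): e for e in ev}
        for r in g.exon_truth.itertuples():
            e = det.get((r.gene_id, r.exon_id))
            if r.planted_class == "none":
                null_exon += 1
                fp_exon += e is not None and e.p < ALPHA
            else:
                total[r.planted_class] += 1
                ok = (e is not None and e.p < ALPHA
                      and e.event_class == r.planted_class)
                tp[r.planted_class] += ok
                if ok:
                    errs.append(abs(e.x - r.true_x))
        detp = {(e.pas.gene_id, e.pas.site): e for e in rt}
        for r in g.pas_truth.itertuples():
            e = detp.get((r.gene_id, r.site))
            if r.planted:
                total["readthrough"] += 1
                ok = e is not None and e.p < ALPHA and e.x > 0
                tp["readthrough"] += ok
                if ok:
                    errs.append(abs(e.x - r.true_x))
            else:
                null_pas += 1
                fp_pas += e is not None and e.p < ALPHA
    out = {
        f"{cls}_sensitivity": tp[cls] / total[cls] for cls in tp
    }
    out.update({
        "exon_fpr": fp_exon / null_exon,
        "pas_fpr": fp_pas / null_pas,
        "n_null_exon": null_exon,
        "n_null_pas": null_pas,
        "n_planted": sum(total.values()),
        "contrast_mae": float(np.mean(errs)),
        "n_recovered": len(errs),
    })
    return out


def motif_pattern(seed: int = 1) -> Dict[str, float]:
    """rho of the planted G-rich / T-rich 5-mers in the downstream window,
    measured on the significant events of one planted simulation."""
    res = simulate(SimulationSpec(seed=seed))
    g, s = res.genome, res.samples
    ev = usage_table(g.exons, s.junctions, s.expression, s.design)
    sig = [e for e in ev if e.p < ALPHA]
    tab = motif_usage_correlation(sig, g.sequences)
    down = tab[tab.window_class == "downstream"].set_index("motif")
    thr = spearman_critical(len(sig), ALPHA, "one")
    return {
        "g_rho": float(down.loc["GGGGG", "rho"]),
        "t_rho": float(down.loc["TTTTT", "rho"]),
        "g_significant": bool(down.loc["GGGGG", "significant"]),
        "t_significant": bool(down.loc["TTTTT", "significant"]),
        "threshold": thr,
        "n_events": len(sig),
    }


def edge_semantics() -> Tuple[float, float]:
    """(x of a mutant-only skipped exon, x of a mutant-only included exon).

    Built from exact hand-constructed junction evidence; the values must be
    +1 and -1 exactly, the volcano's edge stacks.
    """
    samples = ["WT1", "WT2", "WT3", "MUT1", "MUT2", "MUT3"]
    design = SampleDesign(
        samples, {s: ("WT" if s.startswith("WT") else "MUT") for s in samples}
    )
    exons = [
        ExonRecord("gskip", "gskip.1", "chr1", 100, 200, "+"),
        ExonRecord("gskip", "gskip.2", "chr1", 400, 500, "+"),
        ExonRecord("gskip", "gskip.3", "chr1", 700, 800, "+"),
        ExonRecord("gincl", "gincl.1", "chr1", 5100, 5200, "+"),
        ExonRecord("gincl", "gincl.2", "chr1", 5400, 5500, "+"),
        ExonRecord("gincl", "gincl.3", "chr1", 5700, 5800, "+"),
    ]
    jsets = {}
    for s in samples:
        mut = s.startswith("MUT")
        juncs = [
            # gskip: inclusion path always, skip junction only in mutant
            Junction("chr1", 200, 400, "+", 20),
            Junction("chr1", 500, 700, "+", 20),
            # gincl: skip path always
            Junction("chr1", 5200, 5700, "+", 20),
        ]
        if mut:
            juncs.append(Junction("chr1", 200, 700, "+", 10))
            juncs.append(Junction("chr1", 5200, 5400, "+", 6))
            juncs.append(Junction("chr1", 5500, 5700, "+", 6))
        jsets[s] = JunctionSet(s, juncs)
    frame = pd.DataFrame({s: [2.0, 2.0] for s in samples},
                         index=["gskip", "gincl"])
    frame.index.name = "gene_id"
    events = usage_table(exons, jsets, ExpressionTable(frame), design)
    by_id = {e.exon.exon_id: e for e in events}
    right = by_id["gskip.2"]
    left = by_id["gincl.2"]
    assert right.event_class == "exclusion" and left.event_class == "inclusion"
    return right.x, left.x


def binomial_sigma(p: float, n: int) -> float:
    return math.sqrt(p * (1.0 - p) / n)
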