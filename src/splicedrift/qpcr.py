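"""Censored dCt(abnormal - normal) qPCR analysis.

Each measurement pairs the cycle threshold of an abnormal (mis-processed)
isoform, Ct_A, with that of the normal isoform of the same locus, Ct_N, in
the same cDNA.  dCt = Ct_A - Ct_N: smaller values mean relatively more
abnormal transcript.  When the abnormal isoform never crosses threshold,
Ct_A is set to the cycle ceiling of the run (default 40), making the dCt a
*lower limit* — the true value can only be larger.  When the normal isoform
itself is undetected the pair is uninformative and reported as missing
("ND").

Group means substitute censored values at their limits, which keeps the
reported mean a lower bound on any consistent completion of the data
(conservative in the direction of under-stating the abnormal/normal
difference).  ddCt = mean(WT dCt) - mean(mutant dCt): the number of extra
cycles, i.e. log2-fold relative enrichment of abnormal transcripts in the
mutant.

The packaged reference panel (``data/qpcr_panel_delta_ct.tsv``) is a
published five-target, six-organ, 3 vs 3 mouse dCt table for readthrough/
mis-splicing targets, used as a worked example and regression anchor.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import math

import pandas as pd

from .datamodel import DeltaCt, QpcrMeasurement
from .io import read_delta_ct_table
from .stats import WelchResult, welch_t

DEFAULT_CT_CEILING = 40.0


@dataclass
class GroupSummary:
    target: Optional[str]
    organ: Optional[str]
    genotype: str
    mean_delta_ct: float
    is_lower_limit: bool
    n_used: int
    n_nd: int


def delta_ct(m: QpcrMeasurement, ceiling: float = DEFAULT_CT_CEILING) -> DeltaCt:
    """dCt for one measurement, with detection-limit censoring at ``ceiling``."""
    for name, v in (("ct_abnormal", m.ct_abnormal), ("ct_normal", m.ct_normal)):
        if v is not None and v > ceiling:
            raise ValueError(
                f"{m.target}/{m.organ}/{m.mouse_id}: {name}={v} exceeds the "
                f"cycle ceiling {ceiling}"
            )
    if m.ct_normal is None:
        return DeltaCt(float("nan"), is_missing=True)
    if m.ct_abnormal is None:
        return DeltaCt(ceiling - m.ct_normal, is_lower_limit=True)
    return DeltaCt(m.ct_abnormal - m.ct_normal)


def group_summary(
    values: Sequence[DeltaCt],
    genotype: str = "",
    target: Optional[str] = None,
    organ: Optional[str] = None,
) -> GroupSummary:
    """Mean over non-missing dCt values, censored values entered at their limit."""
    usable = [v for v in values if not v.is_missing]
    n_nd = len(values) - len(usable)
    if not usable:
        raise ValueError("all dCt values are missing (ND)")
    mean = sum(v.value for v in usable) / len(usable)
    return GroupSummary(
        target, organ, genotype, mean,
        any(v.is_lower_limit for v in usable), len(usable), n_nd,
    )


def delta_delta_ct(wt: GroupSummary, mut: GroupSummary) -> Tuple[float, bool]:
    """ddCt = WT mean - mutant mean; flagged a lower limit when WT is one."""
    if wt.genotype != "WT" or mut.genotype != "MUT":
        raise ValueError("expected a WT summary and a MUT summary, in that order")
    if wt.target != mut.target or wt.organ != mut.organ:
        raise ValueError("ddCt requires matching target and organ (or pooled "
                         "summaries on both sides)")
    return wt.mean_delta_ct - mut.mean_delta_ct, wt.is_lower_limit


@dataclass
class QpcrReport:
    """Per-(organ, target) cells, per-organ Welch tests, pooled summaries."""

    cells: pd.DataFrame          # organ, target, genotype, mouse_id, token columns
    organ_tests: pd.DataFrame    # organ, n_wt, n_mut, t, p or NA reason
    wt_pooled: GroupSummary
    mut_pooled: GroupSummary
    delta_delta: float
    delta_delta_lower_limit: bool

    def write(self, path: str) -> None:
        with open(path, "w") as fh:
            self.cells.to_csv(fh, sep="\t", index=False)
            fh.write("\n")
            self.organ_tests.to_csv(fh, sep="\t", index=False)
            fh.write("\n")
            lim = ">" if self.delta_delta_lower_limit else ""
            fh.write(
                "pooled_mean_wt\tpooled_mean_mut\tdelta_delta_ct\n"
                f"{'>' if self.wt_pooled.is_lower_limit else ''}"
                f"{self.wt_pooled.mean_delta_ct:.2f}\t"
                f"{'>' if self.mut_pooled.is_lower_limit else ''}"
                f"{self.mut_pooled.mean_delta_ct:.2f}\t"
                f"{lim}{self.delta_delta:.2f}\n"
            )


def measurements_to_frame(
    measurements: Sequence[QpcrMeasurement], ceiling: float = DEFAULT_CT_CEILING
) -> pd.DataFrame:
    """Long dCt frame (organ, target, genotype, mouse_id, value, flags)."""
    rows = []
    for m in measurements:
        d = delta_ct(m, ceiling)
        rows.append({
            "organ": m.organ, "target": m.target, "genotype": m.genotype,
            "mouse_id": m.mouse_id, "delta_ct": d.token(), "value": d.value,
            "is_lower_limit": d.is_lower_limit, "is_missing": d.is_missing,
        })
    return pd.DataFrame(rows)


def _frame_group(frame: pd.DataFrame) -> List[DeltaCt]:
    return [
        DeltaCt(row["value"], bool(row["is_lower_limit"]), bool(row["is_missing"]))
        if not row["is_missing"] else DeltaCt(float("nan"), is_missing=True)
        for _, row in frame.iterrows()
    ]


def qpcr_report(delta_frame: pd.DataFrame, alpha: float = 0.05) -> QpcrReport:
    """Build the full censored-dCt report from a parsed long-format frame.

    The frame must carry organ, target, genotype, mouse_id, value,
    is_lower_limit, is_missing (the shape produced by
    :func:`splicedrift.io.read_delta_ct_table` or
    :func:`measurements_to_frame`).  Censored values enter tests and means at
    their limits; ND values are excluded.
    """
    required = {"organ", "target", "genotype", "mouse_id", "value",
                "is_lower_limit", "is_missing"}
    missing = required - set(delta_frame.columns)
    if missing:
        raise ValueError(f"dCt frame missing column(s): {', '.join(sorted(missing))}")

    cells = delta_frame[
        ["organ", "target", "genotype", "mouse_id"]
    ].copy()
    cells["delta_ct"] = [
        DeltaCt(v, bool(l), bool(md)).token() if not md else "ND"
        for v, l, md in zip(delta_frame["value"], delta_frame["is_lower_limit"],
                            delta_frame["is_missing"])
    ]

    usable = delta_frame[~delta_frame["is_missing"].astype(bool)]
    organ_rows = []
    for organ, sub in usable.groupby("organ", sort=False):
        wt_vals = sub.loc[sub["genotype"] == "WT", "value"].to_numpy(float)
        mut_vals = sub.loc[sub["genotype"] == "MUT", "value"].to_numpy(float)
        if len(wt_vals) < 2 or len(mut_vals) < 2:
            organ_rows.append({"organ": organ, "n_wt": len(wt_vals),
                               "n_mut": len(mut_vals), "t": float("nan"),
                               "p": float("nan"),
                               "note": "NA: <2 usable values in a genotype"})
            continue
        res: WelchResult = welch_t(wt_vals, mut_vals)
        organ_rows.append({"organ": organ, "n_wt": len(wt_vals),
                           "n_mut": len(mut_vals), "t": res.t, "p": res.p,
                           "note": "censored values at their limits"})
    organ_tests = pd.DataFrame(organ_rows)

    def pooled(genotype: str) -> GroupSummary:
        sub = delta_frame[delta_frame["genotype"] == genotype]
        return group_summary(_frame_group(sub), genotype)

    wt_pooled = pooled("WT")
    mut_pooled = pooled("MUT")
    ddct = wt_pooled.mean_delta_ct - mut_pooled.mean_delta_ct
    return QpcrReport(cells, organ_tests, wt_pooled, mut_pooled, ddct,
                      wt_pooled.is_lower_limit)


def load_reference_panel() -> pd.DataFrame:
    """The packaged published dCt panel (five targets, six organs, 3 vs 3)."""
    with importlib.resources.as_file(
        importlib.resources.files("splicedrift").joinpath(
            "data/qpcr_panel_delta_ct.tsv"
        )
    ) as p:
        return read_delta_ct_table(p)
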