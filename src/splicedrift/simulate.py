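"""Ground-truthed synthetic inputs for every pipeline stage.

The generator emulates the study design the analysis assumes: a small
genome of multi-exon genes on both strands, three wild-type versus three
mutant samples, log-normally distributed gene expression shared between
genotypes, junction read counts proportional to expression and to per-exon
inclusion usage, and 3'-end coverage with a genotype-dependent readthrough
fraction downstream of each gene's polyadenylation site.

The splicing model is a transcript ensemble: each internal exon ``e`` has an
inclusion usage ``u_e`` in [0, 1] (terminal exons have u = 1), and the
expected read count of the junction joining exons ``a`` and ``b`` is

    depth_scale * TPM * u_a * u_b * prod_{c between a and b} (1 - u_c)

so junction flux is conserved at every exon boundary.  Planting an effect
changes only the affected exon's ``u`` between genotypes, which makes the
planted contrast exact in expectation and leaves every other exon null:

* exclusion event with target contrast x: skip fraction s = 1 - u moves
  from baseline*(1 - x) in WT to baseline*(1 + x) in the mutant;
* inclusion event (a cryptic exon): u itself moves from incl_base*(1 - x)
  to incl_base*(1 + x), so the exon is rarely included in WT and far more
  often in the mutant.

Counts are rounded gamma-multiplied means (multiplicative noise with a
configured coefficient of variation), not full read simulations: the
pipeline consumes junction counts and coverage areas, and these are their
sufficient statistics.  G-rich (or T-rich) 5-mer runs are written into the
transcribed-downstream windows of exons planted for exclusion (inclusion),
which is the compositional signal the motif stage looks for.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .datamodel import (
    CoverageTrack,
    ExonRecord,
    ExpressionTable,
    Junction,
    JunctionSet,
    PasRecord,
    QpcrMeasurement,
    SampleDesign,
)
from . import io as sio


@dataclass
class SimulationSpec:
    """All knobs of the generator; the defaults are the study conditions."""

    n_genes: int = 125
    exons_per_gene: Tuple[int, int] = (3, 6)
    exon_length: Tuple[int, int] = (80, 300)
    intron_length: Tuple[int, int] = (200, 600)
    # gaps must exceed twice the PAS window so that the post-PAS segments of
    # adjacent genes on opposite strands can never overlap
    intergenic: Tuple[int, int] = (600, 1200)
    n_samples_per_genotype: int = 3
    baseline_skip_rate: float = 0.05
    inclusion_base: float = 0.1      # WT-side usage anchor of cryptic exons
    frac_exclusion: float = 0.1      # of eligible internal exons
    frac_inclusion: float = 0.1
    exclusion_contrast: float = 0.8
    inclusion_contrast: float = 0.8
    frac_readthrough: float = 0.1    # of all PAS (planted on gene-end sites)
    readthrough_contrast: float = 0.8
    baseline_readthrough: float = 0.05
    extra_pas_per_gene: float = 1.4  # mean extra (internal) PAS per gene
    noise_cv: float = 0.1
    expression_mu: float = math.log(15.0)   # log-TPM location
    expression_sigma: float = 1.0
    depth_scale: float = 60.0        # junction reads per TPM at full usage
    coverage_scale: float = 5.0      # gene-body depth per TPM
    pas_window: int = 275
    motif_window: int = 250
    motif_runs_per_window: int = 8   # planted 5-mer runs per 250-bp window
    seed: int = 0

    def validate(self) -> None:
        for name in ("frac_exclusion", "frac_inclusion", "frac_readthrough",
                     "baseline_skip_rate", "baseline_readthrough",
                     "inclusion_base"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in ("exclusion_contrast", "inclusion_contrast",
                     "readthrough_contrast"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise ValueError(f"{name} must be in (0, 1], got {v}")
        for name in ("exons_per_gene", "exon_length", "intron_length",
                     "intergenic"):
            lo, hi = getattr(self, name)
            if lo > hi or lo < 1:
                raise ValueError(f"{name}: bad range ({lo}, {hi})")
        if self.exons_per_gene[0] < 3:
            raise ValueError("genes need at least 3 exons (one internal)")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")
        if self.n_genes < 0:
            raise ValueError("n_genes must be >= 0")
        if self.intron_length[0] <= 0:
            raise ValueError("introns must have positive length")
        if self.intergenic[0] <= 2 * self.pas_window:
            raise ValueError(
                "intergenic gaps must exceed twice the PAS window, otherwise "
                "post-PAS segments of neighbouring genes can overlap"
            )


@dataclass
class GeneModel:
    gene_id: str
    chrom: str
    strand: str
    exons: List[ExonRecord]

    @property
    def start(self) -> int:
        return self.exons[0].start

    @property
    def end(self) -> int:
        return self.exons[-1].end


@dataclass
class SimulatedGenome:
    spec: SimulationSpec
    sequences: Dict[str, str]
    genes: List[GeneModel]
    exons: List[ExonRecord]
    pas: List[PasRecord]
    exon_truth: pd.DataFrame   # gene_id, exon_id, planted_class, true_x
    pas_truth: pd.DataFrame    # gene_id, site, planted, true_x
    # per (gene_id, exon_id): (u_wt, u_mut) inclusion usage of internal exons
    usage: Dict[Tuple[str, str], Tuple[float, float]] = field(default_factory=dict)
    # per gene_id: (rt_wt, rt_mut) readthrough fraction at the gene-end PAS
    readthrough: Dict[str, Tuple[float, float]] = field(default_factory=dict)


@dataclass
class SimulatedSamples:
    design: SampleDesign
    expression: ExpressionTable
    junctions: Dict[str, JunctionSet]
    coverage: Dict[str, CoverageTrack]


@dataclass
class SimulationResult:
    genome: SimulatedGenome
    samples: SimulatedSamples


def _split_rates(base: float, x: float) -> Tuple[float, float]:
    """(wt, mut) rates with mean ``base`` and exact contrast ``x``."""
    return base * (1.0 - x), base * (1.0 + x)


def simulate_genome(spec: SimulationSpec, rng: Optional[np.random.Generator] = None
                    ) -> SimulatedGenome:
    """Random genome + annotation + PAS catalog + planted-truth tables."""
    spec.validate()
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    chrom = "chr1"
    bases = np.array(list("ACGT"))

    genes: List[GeneModel] = []
    cursor = int(rng.integers(*_incl(spec.intergenic)))
    for gi in range(spec.n_genes):
        gene_id = f"g{gi:04d}"
        strand = "+" if gi % 2 == 0 else "-"
        k = int(rng.integers(spec.exons_per_gene[0], spec.exons_per_gene[1] + 1))
        exon_lens = rng.integers(*_incl(spec.exon_length), size=k)
        intron_lens = rng.integers(*_incl(spec.intron_length), size=k - 1)
        exons: List[ExonRecord] = []
        pos = cursor
        for j in range(k):
            exons.append(
                ExonRecord(gene_id, f"{gene_id}.e{j + 1}", chrom, pos,
                           pos + int(exon_lens[j]), strand)
            )
            pos += int(exon_lens[j])
            if j < k - 1:
                pos += int(intron_lens[j])
        genes.append(GeneModel(gene_id, chrom, strand, exons))
        cursor = pos + int(rng.integers(*_incl(spec.intergenic)))

    genome_len = cursor + 10
    seq = rng.choice(bases, size=genome_len)

    # --- plant splicing effects -------------------------------------------
    # inclusion hosts need a middle exon whose neighbours are both internal
    incl_hosts = [g for g in genes if len(g.exons) >= 5]
    n_internal = sum(len(g.exons) - 2 for g in genes)
    n_incl = round(spec.frac_inclusion * n_internal)
    n_excl = round(spec.frac_exclusion * n_internal)
    if n_incl > len(incl_hosts):
        raise ValueError(
            f"cannot place {n_incl} inclusion events: only {len(incl_hosts)} "
            "genes have >= 5 exons"
        )
    incl_genes = list(rng.choice(len(incl_hosts), size=n_incl, replace=False)) \
        if n_incl else []
    planted: Dict[Tuple[str, str], Tuple[str, float]] = {}
    usage: Dict[Tuple[str, str], Tuple[float, float]] = {}
    taken_genes = set()
    for gidx in incl_genes:
        g = incl_hosts[int(gidx)]
        k = len(g.exons)
        j = int(rng.integers(2, k - 2))  # both neighbours internal
        exon = g.exons[j]
        u_wt, u_mut = _split_rates(spec.inclusion_base, spec.inclusion_contrast)
        usage[(g.gene_id, exon.exon_id)] = (u_wt, u_mut)
        planted[(g.gene_id, exon.exon_id)] = ("inclusion", -spec.inclusion_contrast)
        taken_genes.add(g.gene_id)
    excl_hosts = [g for g in genes if g.gene_id not in taken_genes]
    if n_excl > len(excl_hosts):
        raise ValueError(f"cannot place {n_excl} exclusion events in "
                         f"{len(excl_hosts)} free genes")
    excl_genes = list(rng.choice(len(excl_hosts), size=n_excl, replace=False)) \
        if n_excl else []
    for gidx in excl_genes:
        g = excl_hosts[int(gidx)]
        k = len(g.exons)
        j = int(rng.integers(1, k - 1))
        exon = g.exons[j]
        s_wt, s_mut = _split_rates(spec.baseline_skip_rate, spec.exclusion_contrast)
        usage[(g.gene_id, exon.exon_id)] = (1.0 - s_wt, 1.0 - s_mut)
        planted[(g.gene_id, exon.exon_id)] = ("exclusion", spec.exclusion_contrast)

    # default usage for unplanted internal exons
    for g in genes:
        for exon in g.exons[1:-1]:
            usage.setdefault(
                (g.gene_id, exon.exon_id),
                (1.0 - spec.baseline_skip_rate, 1.0 - spec.baseline_skip_rate),
            )

    # --- motif planting ----------------------------------------------------
    w = spec.motif_window
    n_slots = w // 5
    for (gene_id, exon_id), (cls, _x) in planted.items():
        g = next(gg for gg in genes if gg.gene_id == gene_id)
        exon = next(e for e in g.exons if e.exon_id == exon_id)
        run = "GGGGG" if cls == "exclusion" else "TTTTT"
        if g.strand == "+":
            win_start, genomic_run = exon.end, run
        else:
            win_start = exon.start - w
            genomic_run = run.translate(str.maketrans("ACGT", "TGCA"))[::-1]
        slots = rng.choice(n_slots, size=min(spec.motif_runs_per_window, n_slots),
                           replace=False)
        for slot in slots:
            p = win_start + int(slot) * 5
            if 0 <= p and p + 5 <= genome_len:
                seq[p:p + 5] = list(genomic_run)

    # --- PAS catalog -------------------------------------------------------
    pas: List[PasRecord] = []
    pas_truth_rows = []
    readthrough: Dict[str, Tuple[float, float]] = {}
    n_rt_target = None  # decided after the catalog size is known
    for g in genes:
        site = g.end if g.strand == "+" else g.start
        pas.append(PasRecord(g.gene_id, chrom, site, g.strand))
        gene_len = g.end - g.start
        n_extra = int(rng.poisson(spec.extra_pas_per_gene))
        max_off = gene_len - 50
        if max_off > 285:
            offsets = sorted({int(o) for o in rng.integers(280, max_off,
                                                           size=n_extra)})
            for off in offsets:
                s = g.end - off if g.strand == "+" else g.start + off
                pas.append(PasRecord(g.gene_id, chrom, s, g.strand))
    n_rt_target = round(spec.frac_readthrough * len(pas))
    if n_rt_target > spec.n_genes:
        raise ValueError("frac_readthrough too high: more planted readthrough "
                         "events than gene-end PAS")
    rt_genes = set()
    if n_rt_target:
        picks = rng.choice(spec.n_genes, size=n_rt_target, replace=False)
        rt_genes = {genes[int(i)].gene_id for i in picks}
    for g in genes:
        if g.gene_id in rt_genes:
            readthrough[g.gene_id] = _split_rates(spec.baseline_readthrough,
                                                  spec.readthrough_contrast)
        else:
            readthrough[g.gene_id] = (spec.baseline_readthrough,
                                      spec.baseline_readthrough)
    gene_end_site = {g.gene_id: (g.end if g.strand == "+" else g.start)
                     for g in genes}
    for p in pas:
        is_primary = p.site == gene_end_site[p.gene_id]
        p_planted = is_primary and p.gene_id in rt_genes
        pas_truth_rows.append({
            "gene_id": p.gene_id, "chrom": p.chrom, "site": p.site,
            "strand": p.strand, "planted": p_planted,
            "true_x": spec.readthrough_contrast if p_planted else 0.0,
        })

    exons = [e for g in genes for e in g.exons]
    exon_truth_rows = []
    for g in genes:
        for e in g.exons:
            cls, x = planted.get((g.gene_id, e.exon_id), ("none", 0.0))
            exon_truth_rows.append({
                "gene_id": g.gene_id, "exon_id": e.exon_id, "chrom": e.chrom,
                "start": e.start, "end": e.end, "strand": e.strand,
                "planted_class": cls, "true_x": x,
            })

    return SimulatedGenome(
        spec=spec,
        sequences={chrom: "".join(seq)},
        genes=genes,
        exons=exons,
        pas=pas,
        exon_truth=pd.DataFrame(exon_truth_rows),
        pas_truth=pd.DataFrame(pas_truth_rows),
        usage=usage,
        readthrough=readthrough,
    )


def _incl(rng_pair: Tuple[int, int]) -> Tuple[int, int]:
    lo, hi = rng_pair
    return lo, hi + 1


def simulate_samples(
    spec: SimulationSpec, genome: SimulatedGenome,
    rng: Optional[np.random.Generator] = None,
) -> SimulatedSamples:
    """Per-sample junctions, coverage, expression and the design table."""
    if rng is None:
        rng = np.random.default_rng(spec.seed + 1)
    n = spec.n_samples_per_genotype
    samples = [f"WT{i + 1}" for i in range(n)] + [f"MUT{i + 1}" for i in range(n)]
    genotypes = {s: ("WT" if s.startswith("WT") else "MUT") for s in samples}
    design = SampleDesign(samples, genotypes)
    cv = spec.noise_cv

    def noise(size=None):
        if cv == 0:
            return 1.0 if size is None else np.ones(size)
        shape = 1.0 / cv ** 2
        return rng.gamma(shape, cv ** 2, size=size)

    # expression: base shared between genotypes, per-sample multiplicative noise
    base_tpm = rng.lognormal(spec.expression_mu, spec.expression_sigma,
                             size=len(genome.genes))
    expr = {}
    for gi, g in enumerate(genome.genes):
        expr[g.gene_id] = {s: float(base_tpm[gi] * noise()) for s in samples}
    if expr:
        expr_frame = pd.DataFrame(expr).T[samples]
    else:
        expr_frame = pd.DataFrame(columns=samples, dtype=float)
    expr_frame.index.name = "gene_id"
    expression = ExpressionTable(expr_frame)

    junction_sets: Dict[str, JunctionSet] = {s: JunctionSet(s) for s in samples}
    cov_segments: Dict[str, List[Tuple[int, int, float]]] = {s: [] for s in samples}
    gidx = {0: 0, 1: 1}  # wt, mut index into usage tuples

    for g in genome.genes:
        k = len(g.exons)
        u = {}
        for j, e in enumerate(g.exons):
            if j == 0 or j == k - 1:
                u[j] = (1.0, 1.0)
            else:
                u[j] = genome.usage[(g.gene_id, e.exon_id)]
        rt = genome.readthrough[g.gene_id]
        site = g.end if g.strand == "+" else g.start
        for s in samples:
            geno = 0 if genotypes[s] == "WT" else 1
            tpm = expression.value(g.gene_id, s)
            # junction counts over all exon pairs (transcript-ensemble model)
            for a in range(k - 1):
                for b in range(a + 1, k):
                    mean = spec.depth_scale * tpm * u[a][geno] * u[b][geno]
                    for c in range(a + 1, b):
                        mean *= 1.0 - u[c][geno]
                    if mean <= 0:
                        continue
                    count = int(round(mean * float(noise())))
                    if count > 0:
                        junction_sets[s].add(
                            Junction(g.chrom, g.exons[a].end, g.exons[b].start,
                                     g.strand, count)
                        )
            # coverage: uniform gene body plus the post-PAS readthrough segment
            body_depth = spec.coverage_scale * tpm * float(noise())
            cov_segments[s].append((g.start, g.end, body_depth))
            rt_depth = spec.coverage_scale * tpm * rt[geno] * float(noise())
            if rt_depth > 0:
                if g.strand == "+":
                    cov_segments[s].append((site, site + spec.pas_window, rt_depth))
                else:
                    cov_segments[s].append((max(0, site - spec.pas_window), site,
                                            rt_depth))

    chrom = genome.genes[0].chrom if genome.genes else "chr1"
    coverage = {
        s: CoverageTrack.accumulate({chrom: segs}) if segs else CoverageTrack()
        for s, segs in cov_segments.items()
    }
    return SimulatedSamples(design, expression, junction_sets, coverage)


def simulate(spec: SimulationSpec) -> SimulationResult:
    """One-call simulation: genome outputs plus per-sample evidence."""
    rng = np.random.default_rng(spec.seed)
    genome = simulate_genome(spec, rng)
    samples = simulate_samples(spec, genome, rng)
    return SimulationResult(genome, samples)


def write_simulation(result: SimulationResult, outdir: str | Path) -> None:
    """Emit every input file the CLI stages consume, plus the truth tables."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    g = result.genome
    s = result.samples
    sio.write_fasta(g.sequences, out / "genome.fa")
    sio.write_exon_annotation(g.exons, out / "annotation.gtf", "gtf")
    sio.write_pas_bed(g.pas, out / "pas.bed")
    sio.write_expression_table(s.expression, out / "expression.tsv")
    g.exon_truth.to_csv(out / "truth_exons.tsv", sep="\t", index=False)
    g.pas_truth.to_csv(out / "truth_pas.tsv", sep="\t", index=False)
    jp, cp = {}, {}
    for sample in s.design.samples:
        jp[sample] = f"{sample}.junctions.bed"
        cp[sample] = f"{sample}.bedgraph"
        sio.write_junctions(s.junctions[sample], out / jp[sample])
        sio.write_coverage(s.coverage[sample], out / cp[sample])
    design = SampleDesign(s.design.samples, s.design.genotypes, jp, cp)
    sio.write_design(design, out / "design.tsv")


def simulate_qpcr_panel(
    targets: Sequence[str] = ("Pick1",),
    organs: Sequence[str] = ("liver", "testis", "brain"),
    n_mice: int = 3,
    wt_delta_mean: float = 9.0,
    delta_delta: float = 5.0,
    sd: float = 1.0,
    ct_normal_mean: float = 26.0,
    ct_normal_sd: float = 1.0,
    ceiling: float = 40.0,
    seed: int = 0,
) -> List[QpcrMeasurement]:
    """Synthetic censored qPCR panel with a planted genotype shift.

    WT dCt is centred on ``wt_delta_mean`` and mutant dCt on
    ``wt_delta_mean - delta_delta``; the abnormal-isoform Ct is censored at
    ``ceiling`` exactly as in a real run, so high WT dCt values come out as
    lower limits.
    """
    rng = np.random.default_rng(seed)
    out: List[QpcrMeasurement] = []
    for organ in organs:
        for target in targets:
            for geno, mean in (("WT", wt_delta_mean),
                               ("MUT", wt_delta_mean - delta_delta)):
                for i in range(n_mice):
                    ct_n = float(rng.normal(ct_normal_mean, ct_normal_sd))
                    d = float(rng.normal(mean, sd))
                    ct_a: Optional[float] = ct_n + d
                    if ct_a > ceiling:
                        ct_a = None
                    out.append(
                        QpcrMeasurement(target, organ, geno, f"{geno}{i + 1}",
                                        ct_a, ct_n)
                    )
    return out
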