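"""Synthetic cohort generator with planted, recoverable structure.

Everything downstream of this module — probe-level differential-expression
p-values, rat-to-human homology, gene annotation, and case-control CNV
cohorts — can be generated here with known ground truth, so the whole
analysis chain (ranking -> annotation -> burden regression -> permutation
correction) is testable without any external download.

The causal structure is deliberately simple and inverted relative to a
retrospective study: per-subject CNVs are drawn first, and case/control
status is then drawn from a logistic model whose linear predictor is
``alpha + planted_log_or * (distinct planted-set genes hit)``.  The planted
log odds ratio is therefore the literal estimand of the downstream burden
regression, which makes exact parameter-recovery tests possible.  Optional
size confounding (case CNV intervals physically stretched after phenotype
assignment) induces the "background enrichment" that permutation correction
exists to remove.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .cnv import CNVRecord, DELETION, DUPLICATION, write_cnv_file
from .ranking import ProbeStat

__all__ = [
    "SimConfig",
    "GeneRecord",
    "gen_gene_annotation",
    "gen_homology_table",
    "gen_probe_stats",
    "gen_cnv_cohort",
    "simulate_all",
    "write_gene_bed",
    "write_homology_tsv",
    "write_probe_tsv",
    "write_subject_tsv",
]


@dataclass(frozen=True)
class GeneRecord:
    """A gene's identifier and genomic interval (0-based half-open)."""

    gene_id: str
    chrom: str
    start: int
    end: int

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class SimConfig:
    """Parameters of the synthetic study.

    Defaults mirror the scale of the real compiled case-control CNV
    resource (11 917 cases, 16 416 controls across three studies) and a
    gene universe of roughly human density (~6.8 genes/Mb).  Tests and the
    acceptance script use proportionally scaled-down copies; the scaling
    keeps gene density, CNV size distribution and probe rate fixed.
    """

    n_genes: int = 18000
    n_chroms: int = 22
    genome_length_per_chrom: int = 120_000_000
    n_cases: int = 11917
    n_controls: int = 16416
    cnvs_per_subject_mean: float = 1.0
    # lognormal length: median exp(12.3) ~ 220 kb, comfortably above the
    # 100 kb reliability filter
    cnv_length_log_mean: float = 12.3
    cnv_length_log_sd: float = 0.55
    probes_per_kb: float = 0.25
    deletion_fraction: float = 0.5
    planted_set_fraction: float = 0.05
    planted_log_or: float = 0.0
    size_confounding_factor: float = 1.0
    n_chip_types: int = 3
    n_studies: int = 3
    signal_fraction: float = 0.05
    signal_effect: float = 3.0
    probes_per_gene_max: int = 3
    frac_nontargeting: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for name in ("deletion_fraction", "planted_set_fraction",
                     "signal_fraction", "frac_nontargeting"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v} must lie in [0, 1]")
        for name in ("n_genes", "n_chroms", "genome_length_per_chrom",
                     "n_cases", "n_controls", "n_chip_types", "n_studies",
                     "probes_per_gene_max"):
            v = getattr(self, name)
            if v < 1:
                raise ValueError(f"{name}={v} must be >= 1")
        if self.cnvs_per_subject_mean < 0:
            raise ValueError("cnvs_per_subject_mean must be >= 0")
        if self.size_confounding_factor < 1.0:
            raise ValueError("size_confounding_factor must be >= 1")
        if not np.isfinite(self.planted_log_or):
            raise ValueError("planted_log_or must be finite")
        # median CNV length under the lognormal; if it sits below the
        # standard 100 kb reliability filter the filtered cohort starves
        if np.exp(self.cnv_length_log_mean) < 100_000:
            warnings.warn(
                "median simulated CNV length is below 100 kb; the standard "
                "size filter will remove most CNVs", UserWarning,
                stacklevel=2)

    @property
    def n_subjects(self) -> int:
        return self.n_cases + self.n_controls

    @property
    def case_fraction(self) -> float:
        return self.n_cases / self.n_subjects

    def replace(self, **kwargs) -> "SimConfig":
        return dataclasses.replace(self, **kwargs)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _rng(seed) -> np.random.Generator:
    return np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# gene annotation

def gen_gene_annotation(config: SimConfig) -> list[GeneRecord]:
    """Place ``n_genes`` non-overlapping genes across the genome.

    Genes are distributed as evenly as possible over chromosomes, placed in
    order within each chromosome, with lognormal lengths (median ~24 kb,
    matching typical human gene spans) and random intergenic gaps.  Output
    is sorted by (chromosome index, start) and intervals never overlap.
    """
    rng = _rng(config.seed)
    per_chrom = np.full(config.n_chroms, config.n_genes // config.n_chroms)
    per_chrom[: config.n_genes % config.n_chroms] += 1
    records: list[GeneRecord] = []
    gid = 0
    for ci in range(config.n_chroms):
        n = int(per_chrom[ci])
        if n == 0:
            continue
        chrom = f"chr{ci + 1}"
        L = config.genome_length_per_chrom
        lengths = np.minimum(
            rng.lognormal(mean=10.1, sigma=0.9, size=n).astype(np.int64) + 200,
            max(L // max(n, 1) - 1, 1),
        )
        total_len = int(lengths.sum())
        free = L - total_len
        if free < n:
            raise ValueError(
                f"genome too small to place {n} genes of total length "
                f"{total_len} on a chromosome of {L} bp")
        # n+1 gaps summing to the free space
        cuts = np.sort(rng.choice(free, size=n, replace=False))
        gaps = np.diff(np.concatenate([[0], cuts]))
        pos = 0
        for k in range(n):
            pos += int(gaps[k])
            start = pos
            end = start + int(lengths[k])
            records.append(GeneRecord(f"G{gid:06d}", chrom, start, end))
            pos = end
            gid += 1
    return records


def write_gene_bed(genes: list[GeneRecord], path) -> None:
    """Write gene intervals as BED (0-based half-open)."""
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f"{g.chrom}\t{g.start}\t{g.end}\t{g.gene_id}\n")


def read_gene_bed(path) -> list[GeneRecord]:
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            chrom, start, end, name = line.split()[:4]
            out.append(GeneRecord(name, chrom, int(start), int(end)))
    return out


# ---------------------------------------------------------------------------
# homology

def gen_homology_table(
    genes: list[GeneRecord],
    frac_unmapped: float = 0.05,
    frac_multimapped: float = 0.05,
    seed: int = 0,
) -> pd.DataFrame:
    """Build a HomoloGene-style source->human mapping table.

    Each human gene ``G...`` in the annotation is paired with a synthetic
    source (rat) gene ``S...`` sharing a homology group id.  A fraction of
    source genes is left out of the table entirely (unmapped) and a
    fraction is additionally mapped to a second, off-universe human
    identifier (multimapped), so downstream uniqueness filtering has work
    to do.  Columns: ``group_id, source_gene_id, human_gene_id``.
    """
    if frac_unmapped + frac_multimapped > 1:
        raise ValueError("frac_unmapped + frac_multimapped must be <= 1")
    rng = _rng(seed)
    n = len(genes)
    u = rng.uniform(size=n)
    rows = []
    for i, g in enumerate(genes):
        src = _source_id(g.gene_id)
        group = f"HG{i:06d}"
        if u[i] < frac_unmapped:
            continue  # source gene absent from the table
        rows.append((group, src, g.gene_id))
        if u[i] >= 1.0 - frac_multimapped:
            # second human homolog outside the annotation universe
            rows.append((group, src, f"GX{i:06d}"))
    return pd.DataFrame(rows, columns=["group_id", "source_gene_id",
                                       "human_gene_id"])


def _source_id(gene_id: str) -> str:
    return "S" + gene_id[1:]


def write_homology_tsv(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# probe-level differential-expression p-values

def gen_probe_stats(
    genes: list[GeneRecord],
    config: SimConfig,
    seed: int | None = None,
    signal_genes: set[str] | None = None,
) -> tuple[list[ProbeStat], set[str]]:
    """Emit per-probe p-value pairs (one per normalization channel).

    Each source gene carries 1..probes_per_gene_max probes.  Null-gene
    probes draw two independent Uniform(0,1) p-values.  Signal-gene probes
    share one latent normal effect shifted by ``signal_effect``; each
    channel observes it with independent noise, and the p-value is the
    upper-tail normal probability — giving two small, positively correlated
    p-values per probe, the situation produced by testing the same
    contrast under two normalizations.  A further ``frac_nontargeting``
    of probes is annotated with no unique gene target.

    Returns (probes, signal_gene_ids) where the ids are *human* gene ids —
    the generator's ground truth for recovery tests.  ``signal_genes`` may
    be passed to pin the truth set (e.g. to couple it to a planted CNV
    effect); otherwise it is drawn at rate ``signal_fraction``.
    """
    from scipy.stats import norm

    rng = _rng(config.seed if seed is None else seed)
    if signal_genes is None:
        n_sig = int(round(config.signal_fraction * len(genes)))
        idx = rng.choice(len(genes), size=n_sig, replace=False)
        signal_genes = {genes[i].gene_id for i in idx}
    probes: list[ProbeStat] = []
    pid = 0
    for g in genes:
        k = int(rng.integers(1, config.probes_per_gene_max + 1))
        is_signal = g.gene_id in signal_genes
        for _ in range(k):
            if is_signal:
                latent = config.signal_effect + rng.normal()
                t1 = latent + 0.5 * rng.normal()
                t2 = latent + 0.5 * rng.normal()
                p1 = float(norm.sf(t1))
                p2 = float(norm.sf(t2))
            else:
                p1, p2 = float(rng.uniform()), float(rng.uniform())
            p1 = min(max(p1, 1e-300), 1.0)
            p2 = min(max(p2, 1e-300), 1.0)
            probes.append(ProbeStat(f"P{pid:07d}", _source_id(g.gene_id),
                                    p1, p2))
            pid += 1
    # non-targeting probes: p-values uniform, no unique gene
    n_nt = int(round(config.frac_nontargeting * len(probes)))
    for _ in range(n_nt):
        probes.append(ProbeStat(f"P{pid:07d}", None,
                                float(rng.uniform()), float(rng.uniform())))
        pid += 1
    return probes, signal_genes


def write_probe_tsv(probes: list[ProbeStat], path) -> None:
    with open(path, "w") as fh:
        fh.write("probe_id\tsource_gene_id\tp_mas5\tp_rma\n")
        for p in probes:
            src = p.source_gene_id if p.source_gene_id is not None else "NA"
            fh.write(f"{p.probe_id}\t{src}\t{p.p_mas5:.17g}\t{p.p_rma:.17g}\n")


# ---------------------------------------------------------------------------
# CNV cohort

def _solve_intercept(hits: np.ndarray, log_or: float, target: float) -> float:
    """Intercept such that mean sigmoid(alpha + log_or*hits) == target."""
    from scipy.optimize import brentq

    def f(alpha):
        return float(np.mean(1.0 / (1.0 + np.exp(-(alpha + log_or * hits))))
                     - target)

    return brentq(f, -50.0, 50.0, xtol=1e-10)


def _count_set_hits(cnv_rows, genes_by_chrom, planted: set[str],
                    n_subjects: int) -> np.ndarray:
    """Distinct planted genes hit per subject, via sorted-interval search."""
    hit_sets: list[set[str]] = [set() for _ in range(n_subjects)]
    for si, chrom, start0, end0 in cnv_rows:  # 0-based half-open
        starts, ends, ids = genes_by_chrom[chrom]
        lo = int(np.searchsorted(ends, start0, side="right"))
        hi = int(np.searchsorted(starts, end0, side="left"))
        for j in range(lo, hi):
            if ids[j] in planted:
                hit_sets[si].add(ids[j])
    return np.array([len(s) for s in hit_sets], dtype=float)


def gen_cnv_cohort(
    genes: list[GeneRecord],
    gene_set_truth: set[str],
    config: SimConfig,
    seed: int | None = None,
) -> tuple[pd.DataFrame, list[CNVRecord]]:
    """Generate a case-control CNV cohort with a planted gene-set effect.

    Returns ``(subjects, cnvs)``: a subject table with columns
    ``subject_id, phenotype, chip, study`` and a list of CNV records in
    1-based inclusive coordinates, serializable to the PLINK-style .cnv
    dialect.
    """
    if config.planted_log_or != 0.0 and not gene_set_truth:
        raise ValueError("planted_log_or != 0 requires a non-empty "
                         "planted gene set")
    rng = _rng(config.seed if seed is None else seed)
    n = config.n_subjects

    # raw CNVs per subject: (subject_idx, chrom, start0, end0 half-open)
    counts = rng.poisson(config.cnvs_per_subject_mean, size=n)
    total = int(counts.sum())
    chrom_idx = rng.integers(0, config.n_chroms, size=total)
    lengths = np.maximum(
        rng.lognormal(config.cnv_length_log_mean, config.cnv_length_log_sd,
                      size=total).astype(np.int64), 1)
    lengths = np.minimum(lengths, config.genome_length_per_chrom)
    starts = (rng.uniform(size=total)
              * (config.genome_length_per_chrom - lengths)).astype(np.int64)
    is_del = rng.uniform(size=total) < config.deletion_fraction
    subj_of = np.repeat(np.arange(n), counts)

    genes_by_chrom: dict[str, tuple[np.ndarray, np.ndarray, list[str]]] = {}
    for g in genes:
        genes_by_chrom.setdefault(g.chrom, ([], [], []))  # type: ignore
    tmp: dict[str, list] = {c: [[], [], []] for c in
                            {g.chrom for g in genes}}
    for g in genes:
        tmp[g.chrom][0].append(g.start)
        tmp[g.chrom][1].append(g.end)
        tmp[g.chrom][2].append(g.gene_id)
    genes_by_chrom = {c: (np.array(v[0]), np.array(v[1]), v[2])
                      for c, v in tmp.items()}
    for c in [f"chr{i + 1}" for i in range(config.n_chroms)]:
        genes_by_chrom.setdefault(
            c, (np.array([], dtype=int), np.array([], dtype=int), []))

    rows = [(int(subj_of[k]), f"chr{int(chrom_idx[k]) + 1}",
             int(starts[k]), int(starts[k] + lengths[k]))
            for k in range(total)]
    hits = _count_set_hits(rows, genes_by_chrom, gene_set_truth, n)

    alpha = _solve_intercept(hits, config.planted_log_or,
                             config.case_fraction)
    prob = 1.0 / (1.0 + np.exp(-(alpha + config.planted_log_or * hits)))
    phenotype = (rng.uniform(size=n) < prob).astype(int)

    # size confounding: stretch case CNV intervals after phenotype draw
    f = config.size_confounding_factor
    if f > 1.0:
        for k in range(total):
            if phenotype[subj_of[k]] == 1:
                si, chrom, s0, e0 = rows[k]
                new_len = min(int((e0 - s0) * f),
                              config.genome_length_per_chrom - s0)
                rows[k] = (si, chrom, s0, s0 + new_len)

    chip = rng.integers(0, config.n_chip_types, size=n)
    study = rng.integers(0, config.n_studies, size=n)
    subjects = pd.DataFrame({
        "subject_id": [f"SUBJ{i:06d}" for i in range(n)],
        "phenotype": phenotype,
        "chip": [f"chip{c}" for c in chip],
        "study": [f"study{s}" for s in study],
    })

    cnvs: list[CNVRecord] = []
    for k, (si, chrom, s0, e0) in enumerate(rows):
        length = e0 - s0
        n_probes = max(1, int(round(config.probes_per_kb * length / 1000.0)))
        cnvs.append(CNVRecord(
            subject_id=f"SUBJ{si:06d}", chrom=chrom,
            start=s0 + 1, end=e0,  # 1-based inclusive
            cnv_type=DELETION if is_del[k] else DUPLICATION,
            n_probes=n_probes))
    return subjects, cnvs


def write_subject_tsv(subjects: pd.DataFrame, path) -> None:
    subjects.to_csv(path, sep="\t", index=False)


def read_subject_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t",
                       dtype={"subject_id": str, "phenotype": int,
                              "chip": str, "study": str})


# ---------------------------------------------------------------------------
# end-to-end file-set generation

def simulate_all(config: SimConfig, outdir,
                 conditions: tuple[str, ...] = ("consolidation", "retrieval",
                                                "extinction"),
                 causal_condition: str = "extinction",
                 frac_unmapped: float = 0.05,
                 frac_multimapped: float = 0.05) -> dict:
    """Generate the full synthetic file set under ``outdir``.

    One probe table is written per condition; only ``causal_condition``'s
    signal genes are planted as the CNV-burden effect.  Returns a manifest
    of paths plus the ground truth.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = _rng(config.seed)
    genes = gen_gene_annotation(config)
    homology = gen_homology_table(genes, frac_unmapped, frac_multimapped,
                                  seed=int(rng.integers(2**31)))
    probe_paths = {}
    signal_truth = {}
    for cond in conditions:
        probes, sig = gen_probe_stats(genes, config,
                                      seed=int(rng.integers(2**31)))
        signal_truth[cond] = sorted(sig)
        p = outdir / f"probes_{cond}.tsv"
        write_probe_tsv(probes, p)
        probe_paths[cond] = str(p)
    planted = set(signal_truth[causal_condition]) if causal_condition else set()
    subjects, cnvs = gen_cnv_cohort(genes, planted, config,
                                    seed=int(rng.integers(2**31)))
    write_gene_bed(genes, outdir / "genes.bed")
    write_homology_tsv(homology, outdir / "homology.tsv")
    write_subject_tsv(subjects, outdir / "subjects.tsv")
    write_cnv_file(cnvs, outdir / "cohort.cnv",
                   fid_map=None)
    truth = {
        "planted_set": sorted(planted),
        "planted_log_or": config.planted_log_or,
        "signal_genes": signal_truth,
        "causal_condition": causal_condition,
    }
    with open(outdir / "truth.json", "w") as fh:
        json.dump(truth, fh, indent=1)
    return {
        "genes_bed": str(outdir / "genes.bed"),
        "homology_tsv": str(outdir / "homology.tsv"),
        "subjects_tsv": str(outdir / "subjects.tsv"),
        "cnv_file": str(outdir / "cohort.cnv"),
        "probe_tsvs": probe_paths,
        "truth_json": str(outdir / "truth.json"),
    }
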