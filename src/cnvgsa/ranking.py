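"""Probe-level p-values -> ranked human gene list -> top-fraction gene sets.

The ranking chain mirrors the standard microarray collapse for a
two-normalization design: per probe, the MAS5.0-derived and RMA-derived
differential-expression p-values are combined with Fisher's method
(chi-square with 4 d.f.); where several probes target one gene, the
Fisher-combined values are collapsed to a single gene-level p-value with
the Simes procedure; source (rat) genes are mapped to human homologs
through a HomoloGene-style table, dropping any gene without a unique
human homolog; genes are ranked by p-value and the top fraction taken as
the gene set.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import chi2

logger = logging.getLogger(__name__)

__all__ = [
    "ProbeStat",
    "GeneScore",
    "GeneSet",
    "filter_probes",
    "fisher_combine",
    "simes_combine",
    "collapse_to_genes",
    "select_top_fraction",
    "read_probe_tsv",
    "read_homology_tsv",
]

#: floor applied to p-values before log transforms; guards underflowed inputs
P_FLOOR = 1e-300


@dataclass(frozen=True)
class ProbeStat:
    """One probe set's dual-normalization p-value pair and its target gene.

    ``source_gene_id`` is None when the probe does not target a unique gene
    (such probes are removed by :func:`filter_probes`).
    """

    probe_id: str
    source_gene_id: str | None
    p_mas5: float
    p_rma: float


@dataclass(frozen=True)
class GeneScore:
    human_gene_id: str
    combined_p: float
    rank: int  # 1 = most significant


@dataclass(frozen=True)
class GeneSet:
    """The top ``fraction`` of a ranking, labeled by condition."""

    label: str
    fraction: float
    members: frozenset[str] = field(default_factory=frozenset)

    def __len__(self) -> int:
        return len(self.members)


def filter_probes(probes: list[ProbeStat]) -> list[ProbeStat]:
    """Remove probes that do not target a unique gene."""
    kept = [p for p in probes if p.source_gene_id is not None]
    removed = len(probes) - len(kept)
    if removed:
        logger.info("filter_probes: removed %d of %d probes without a "
                    "unique gene target", removed, len(probes))
    if probes and not kept:
        warnings.warn("all probes removed by unique-target filter; "
                      "downstream ranking will be empty", UserWarning,
                      stacklevel=2)
    return kept


def _clamp_p(p: float, name: str) -> float:
    if not (0.0 < p <= 1.0):
        if p <= 0.0:
            logger.warning("%s=%g clamped to floor %g", name, p, P_FLOOR)
            return P_FLOOR
        raise ValueError(f"{name}={p} outside (0, 1]")
    return max(p, P_FLOOR)


def fisher_combine(p1: float, p2: float) -> float:
    """Fisher's method for two p-values.

    X = -2(ln p1 + ln p2) is chi-square with 4 degrees of freedom under
    the joint null; returns its survival probability at X.
    """
    p1 = _clamp_p(p1, "p1")
    p2 = _clamp_p(p2, "p2")
    x = -2.0 * (np.log(p1) + np.log(p2))
    return float(chi2.sf(x, df=4))


def simes_combine(pvals) -> float:
    """Simes combination: min over i of m*p(i)/i on the order statistics.

    Valid as a gene-level p-value under independence or positive dependence
    of the probe-level p-values; equals the single value when m == 1.
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        raise ValueError("simes_combine requires a non-empty list")
    if np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    p = np.sort(p)
    m = p.size
    return float(min(np.min(m * p / np.arange(1, m + 1)), 1.0))


def _unique_maps(homology: pd.DataFrame, bidirectional: bool = True
                 ) -> pd.DataFrame:
    """Rows of the homology table surviving uniqueness filtering.

    Always drops source genes mapping to more than one human gene; with
    ``bidirectional`` (default) also drops human genes receiving more than
    one source gene, preventing a human gene from being double-counted.
    """
    t = homology[["source_gene_id", "human_gene_id"]].drop_duplicates()
    src_counts = t.groupby("source_gene_id")["human_gene_id"].transform("size")
    t = t[src_counts == 1]
    if bidirectional:
        hum_counts = t.groupby("human_gene_id")["source_gene_id"].transform(
            "size")
        t = t[hum_counts == 1]
    return t


def collapse_to_genes(
    probes: list[ProbeStat],
    homology: pd.DataFrame,
    bidirectional_unique: bool = True,
) -> list[GeneScore]:
    """Collapse filtered probes to a ranked human gene list.

    Per source gene the probes' Fisher-combined p-values are collapsed
    with Simes; source genes are then mapped to human identifiers,
    excluding any gene without a unique human homolog (and, by default,
    human genes receiving more than one source gene).  Ties in the final
    ranking are broken by lexicographic human gene id, so the ranking is
    deterministic.
    """
    probes = [p for p in probes if p.source_gene_id is not None]
    if not probes:
        warnings.warn("no probes to collapse; empty ranking", UserWarning,
                      stacklevel=2)
        return []
    per_gene: dict[str, list[float]] = {}
    for p in probes:
        per_gene.setdefault(p.source_gene_id, []).append(
            fisher_combine(p.p_mas5, p.p_rma))
    mapping = _unique_maps(homology, bidirectional_unique)
    src2hum = dict(zip(mapping["source_gene_id"], mapping["human_gene_id"]))
    n_unmapped = sum(1 for s in per_gene if s not in src2hum)
    if n_unmapped:
        logger.info("collapse_to_genes: %d of %d source genes dropped "
                    "(no unique human homolog)", n_unmapped, len(per_gene))
    scored = [(src2hum[src], simes_combine(ps))
              for src, ps in per_gene.items() if src in src2hum]
    if not scored:
        warnings.warn("homology intersection empty; empty ranking",
                      UserWarning, stacklevel=2)
        return []
    scored.sort(key=lambda t: (t[1], t[0]))
    return [GeneScore(h, p, i + 1) for i, (h, p) in enumerate(scored)]


def select_top_fraction(scores: list[GeneScore], fraction: float,
                        label: str = "") -> GeneSet:
    """Top ``floor(fraction * N)`` genes of a ranking as a GeneSet.

    The ranking's lexicographic tie-break makes the cutoff deterministic.
    """
    if not (0.0 < fraction <= 1.0):
        raise ValueError(f"fraction={fraction} outside (0, 1]")
    k = int(np.floor(fraction * len(scores)))
    if k == 0:
        raise ValueError(
            f"fraction={fraction} of {len(scores)} genes selects 0 genes")
    ordered = sorted(scores, key=lambda s: s.rank)
    return GeneSet(label=label, fraction=fraction,
                   members=frozenset(s.human_gene_id for s in ordered[:k]))


# ---------------------------------------------------------------------------
# IO

def read_probe_tsv(path) -> list[ProbeStat]:
    df = pd.read_csv(path, sep="\t", dtype={"probe_id": str,
                                            "source_gene_id": str})
    out = []
    for row in df.itertuples(index=False):
        src = row.source_gene_id
        if pd.isna(src) or src == "NA":
            src = None
        out.append(ProbeStat(row.probe_id, src, float(row.p_mas5),
                             float(row.p_rma)))
    return out


def read_homology_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype=str)


def write_ranking_tsv(scores: list[GeneScore], path, header: str = "") -> None:
    with open(path, "w") as fh:
        if header:
            fh.write(header)
        fh.write("human_gene_id\tcombined_p\trank\n")
        for s in sorted(scores, key=lambda s: s.rank):
            fh.write(f"{s.human_gene_id}\t{s.combined_p:.17g}\t{s.rank}\n")


def read_ranking_tsv(path) -> list[GeneScore]:
    df = pd.read_csv(path, sep="\t", comment="#")
    return [GeneScore(r.human_gene_id, float(r.combined_p), int(r.rank))
            for r in df.itertuples(index=False)]


def write_gene_set(gene_set: GeneSet, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# label={gene_set.label} fraction={gene_set.fraction}\n")
        for g in sorted(gene_set.members):
            fh.write(g + "\n")


def read_gene_set(path) -> GeneSet:
    label, fraction = "", 1.0
    members = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line.startswith("#"):
                for tok in line[1:].split():
                    if tok.startswith("label="):
                        label = tok[6:]
                    elif tok.startswith("fraction="):
                        fraction = float(tok[9:])
                continue
            if line:
                members.append(line)
    return GeneSet(label=label, fraction=fraction, members=frozenset(members))
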