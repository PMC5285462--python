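"""Randomized-gene-set null and empirical p-values.

Asymptotic p-values from the burden regression are contaminated by
"background enrichment": any gene set whatsoever shows case enrichment
when cases simply carry larger or more gene-rich CNVs than the model's
covariates capture.  The remedy is to permute the ranked gene list and
take same-sized top-fraction sets as a null family: the fraction of
random sets scoring as or more significant than the observed set is an
empirical p-value with the background built into the null.

Each permutation shuffles the whole gene list once and takes nested
top-fraction sets from it (the 1% set is a subset of the 2% set, and so
on), so one shuffle serves every fraction.  Permuted fits reuse the
observed covariate structure — only the exposure column changes — which
makes 2000 permutations a vectorized column swap rather than a pipeline
re-run.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .burden import BurdenModel, build_burden_table, DEFAULT_COVARIATES
from .ranking import GeneScore, select_top_fraction

logger = logging.getLogger(__name__)

__all__ = [
    "DEFAULT_FRACTIONS",
    "PermutationProfile",
    "permute_gene_sets",
    "empirical_pvalue",
    "threshold_profile",
    "subject_gene_hits",
    "plot_profiles",
]

DEFAULT_FRACTIONS = (0.01, 0.02, 0.05, 0.10, 0.15, 0.20, 0.25)
DEFAULT_N_PERM = 2000


@dataclass(frozen=True)
class PermutationProfile:
    """One point of the signed threshold profile (one set, one fraction)."""

    set_label: str
    fraction: float
    observed_p: float
    observed_z: float
    empirical_p: float
    signed_log_stat: float
    n_permutations: int
    flag: str = ""


def permute_gene_sets(universe, fractions, n_perm: int, seed: int):
    """Yield ``n_perm`` dicts mapping fraction -> frozenset of gene ids.

    One uniform shuffle of the full universe per permutation; each
    fraction's set is the shuffle's top ``floor(f*N)`` genes, so sets are
    nested within a permutation.  Reproducible under ``seed``.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    ids = np.asarray(sorted(universe))
    n = ids.size
    sizes = {f: int(np.floor(f * n)) for f in fractions}
    rng = np.random.default_rng(seed)
    for _ in range(n_perm):
        perm = rng.permutation(n)
        yield {f: frozenset(ids[perm[:k]]) for f, k in sizes.items()}


def empirical_pvalue(observed_p: float, null_ps, mode: str = "plain"
                     ) -> float:
    """Fraction of null statistics as or more significant than observed.

    ``plain`` (default): ``#{null <= observed} / N`` — ties count as "as
    significant".  ``add_one``: ``(k+1)/(N+1)``, which never returns an
    exact zero; its use is logged.
    """
    null = np.asarray(null_ps, dtype=float)
    if null.size == 0:
        raise ValueError("null_ps must be non-empty")
    k = int(np.sum(null <= observed_p))
    if mode == "plain":
        return k / null.size
    if mode == "add_one":
        logger.info("empirical_pvalue: add-one mode, (%d+1)/(%d+1)",
                    k, null.size)
        return (k + 1) / (null.size + 1)
    raise ValueError(f"unknown mode {mode!r}")


def subject_gene_hits(subjects: pd.DataFrame, annotated_cnvs, universe
                      ) -> tuple[dict[str, np.ndarray], int]:
    """Per-gene arrays of subject indices with at least one CNV hitting
    the gene (restricted to ``universe``).

    This subject-by-gene hit structure is computed once; every permuted
    set's hit counts come from summing these indicator columns, never
    from re-annotating CNVs.
    """
    sid_index = {s: i for i, s in enumerate(subjects["subject_id"])}
    universe = set(universe)
    per_gene: dict[str, set[int]] = {}
    for a in annotated_cnvs:
        i = sid_index.get(a.cnv.subject_id)
        if i is None:
            continue
        for g in a.genes_hit:
            if g in universe:
                per_gene.setdefault(g, set()).add(i)
    return ({g: np.fromiter(s, dtype=np.intp) for g, s in per_gene.items()},
            len(subjects))


def _hits_vector(gene_set, per_gene: dict[str, np.ndarray], n: int
                 ) -> np.ndarray:
    hits = np.zeros(n)
    for g in gene_set:
        idx = per_gene.get(g)
        if idx is not None:
            hits[idx] += 1.0
    return hits


def _signed_log(empirical_p: float, z: float, n_perm: int) -> float:
    floor = 1.0 / n_perm
    if empirical_p < floor:
        logger.info("empirical p %.3g floored at 1/%d for the signed "
                    "statistic", empirical_p, n_perm)
        empirical_p = floor
    return float(-np.log10(empirical_p) * np.sign(z))


def threshold_profile(
    rankings,
    annotated_cnvs,
    subjects: pd.DataFrame,
    fractions=DEFAULT_FRACTIONS,
    n_perm: int = DEFAULT_N_PERM,
    seed: int = 0,
    stratum: str = "all",
    covariates=DEFAULT_COVARIATES,
    direction_mode: str = "p",
    empirical_mode: str = "plain",
) -> list[PermutationProfile]:
    """Observed vs permuted enrichment over a grid of top fractions.

    Parameters
    ----------
    rankings : list[GeneScore] or dict[str, list[GeneScore]]
        One ranked gene list, or several labeled ones.  Rankings sharing a
        gene universe share one permutation null per fraction.
    direction_mode : {"p", "signed"}
        "p" (default) calls a permuted set as-or-more significant when its
        two-tailed p is <= the observed p, regardless of direction;
        "signed" additionally requires the permuted z to be at least as
        extreme *in the observed direction*.

    Returns one :class:`PermutationProfile` per (ranking, fraction), with
    the signed statistic ``-log10(empirical_p) * sgn(z)``; the empirical p
    is floored at 1/n_perm inside the log to keep the statistic finite.
    """
    if isinstance(rankings, dict):
        labeled = rankings
    else:
        labeled = {"": rankings}
    base = build_burden_table(subjects, annotated_cnvs, frozenset(),
                              stratum=stratum)
    model = BurdenModel(base, covariates=covariates, stratum=stratum)

    # group rankings by identical universe so nulls are shared
    by_universe: dict[frozenset, list[str]] = {}
    universes: dict[str, frozenset] = {}
    for label, ranking in labeled.items():
        u = frozenset(s.human_gene_id for s in ranking)
        universes[label] = u
        by_universe.setdefault(u, []).append(label)

    # annotate once into the subject x gene hit structure per universe
    full_universe = frozenset().union(*by_universe) if by_universe \
        else frozenset()
    per_gene, n_subj = subject_gene_hits(subjects, annotated_cnvs,
                                         full_universe)

    # null fits per (universe, fraction): arrays of (p, z)
    null_stats: dict[tuple[frozenset, float], tuple[np.ndarray, np.ndarray]] \
        = {}
    rng = np.random.default_rng(seed)
    for u in by_universe:
        sub_seed = int(rng.integers(2**31))
        ps: dict[float, list[float]] = {f: [] for f in fractions}
        zs: dict[float, list[float]] = {f: [] for f in fractions}
        n_drop = 0
        for perm_sets in permute_gene_sets(u, fractions, n_perm, sub_seed):
            for f, gene_set in perm_sets.items():
                r = model.fit_with_hits(
                    _hits_vector(gene_set, per_gene, n_subj))
                if r.estimable:
                    ps[f].append(r.p)
                    zs[f].append(r.z)
                else:
                    n_drop += 1
        if n_drop:
            logger.info("dropped %d non-estimable permuted fits", n_drop)
        for f in fractions:
            null_stats[(u, f)] = (np.asarray(ps[f]), np.asarray(zs[f]))

    profiles: list[PermutationProfile] = []
    for label, ranking in labeled.items():
        u = universes[label]
        for f in fractions:
            gene_set = select_top_fraction(ranking, f, label=label)
            obs = model.fit_with_hits(
                _hits_vector(gene_set.members, per_gene, n_subj))
            null_p, null_z = null_stats[(u, f)]
            flag = ""
            n_valid = null_p.size
            if n_valid < n_perm * 0.99:
                flag = (f"only {n_valid}/{n_perm} permutations estimable")
            if not obs.estimable or n_valid == 0:
                profiles.append(PermutationProfile(
                    label, f, float("nan"), float("nan"), float("nan"),
                    float("nan"), n_valid,
                    flag=flag or obs.flag or "observed fit non-estimable"))
                continue
            if direction_mode == "signed":
                sgn = np.sign(obs.z) if obs.z != 0 else 1.0
                as_extreme = (null_p <= obs.p) & (np.sign(null_z) == sgn)
                emp = (np.sum(as_extreme) / n_valid
                       if empirical_mode == "plain"
                       else (np.sum(as_extreme) + 1) / (n_valid + 1))
            else:
                emp = empirical_pvalue(obs.p, null_p, mode=empirical_mode)
            profiles.append(PermutationProfile(
                label, f, obs.p, obs.z, emp,
                _signed_log(emp, obs.z, n_valid), n_valid, flag=flag))
    return profiles


def profiles_to_frame(profiles: list[PermutationProfile]) -> pd.DataFrame:
    return pd.DataFrame([{
        "set_label": p.set_label, "fraction": p.fraction,
        "observed_p": p.observed_p, "observed_z": p.observed_z,
        "empirical_p": p.empirical_p, "signed_log_stat": p.signed_log_stat,
        "n_permutations": p.n_permutations, "flag": p.flag,
    } for p in profiles])


def plot_profiles(profiles: list[PermutationProfile], path=None):
    """Signed threshold profile: -log10(empirical p) x sgn(z) against the
    top-fraction grid, one line per gene set, with the 0.05 threshold as
    dotted lines."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = profiles_to_frame(profiles)
    fig, ax = plt.subplots(figsize=(6, 4))
    for label, sub in df.groupby("set_label"):
        sub = sub.sort_values("fraction")
        ax.plot(sub["fraction"] * 100, sub["signed_log_stat"],
                marker="o", label=label or "gene set")
    thr = -np.log10(0.05)
    ax.axhline(thr, ls=":", c="k", lw=1)
    ax.axhline(-thr, ls=":", c="k", lw=1)
    ax.axhline(0, c="0.7", lw=0.5)
    ax.set_xlabel("top fraction of ranked genes (%)")
    ax.set_ylabel(r"$-\log_{10}(P_{emp}) \times \mathrm{sgn}(Z)$")
    ax.legend(fontsize=8)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
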