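"""Gene-set CNV burden regression.

The unit of analysis is the subject.  For a given gene set and CNV stratum
each subject contributes: the count of distinct gene-set genes overlapped
by their filtered CNVs (``set_hits``, the exposure), total CNV size in kb,
total distinct annotated genes hit, chip type and study (the covariates),
and case-control status (the outcome).  ``BurdenModel.fit`` estimates the
log odds ratio per gene-set gene hit by maximum-likelihood logistic
regression with a two-tailed Wald test; Bonferroni correction handles the
primary multiple-testing family, and per-gene refits attribute a set's
signal to its individual members.

Subjects with no CNVs are retained with zero burden: they carry baseline
information, and excluding them would condition on CNV carriage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.tools.sm_exceptions import PerfectSeparationError

from .cnv import AnnotatedCNV, stratify_by_type

logger = logging.getLogger(__name__)

__all__ = [
    "build_burden_table",
    "BurdenModel",
    "BurdenResults",
    "EnrichmentResult",
    "fit_enrichment",
    "bonferroni",
    "per_gene_enrichment",
]

DEFAULT_COVARIATES = ("total_cnv_kb", "total_genes_hit", "chip", "study")


def build_burden_table(
    subjects: pd.DataFrame,
    annotated_cnvs: list[AnnotatedCNV],
    gene_set,
    stratum: str = "all",
    strict: bool = True,
    genes_per_cnv_mode: str = "total",
) -> pd.DataFrame:
    """One row per subject with phenotype, covariates and gene-set hits.

    ``set_hits`` counts *distinct* gene-set genes across a subject's CNVs
    (a gene hit by two CNVs of one subject counts once); ``total_genes_hit``
    counts distinct genes from the full annotation.  CNV-free subjects get
    zeros.  With ``genes_per_cnv_mode="mean"`` an additional
    ``mean_genes_per_cnv`` column carries the per-subject mean of genes per
    CNV as an alternative reading of the genes-per-CNV covariate.
    """
    members = set(getattr(gene_set, "members", gene_set))
    annotated = stratify_by_type(annotated_cnvs, stratum)
    known = set(subjects["subject_id"])
    kb: dict[str, float] = {}
    all_hit: dict[str, set] = {}
    set_hit: dict[str, set] = {}
    n_cnvs: dict[str, int] = {}
    for a in annotated:
        sid = a.cnv.subject_id
        if sid not in known:
            msg = f"CNV subject {sid!r} absent from subject table"
            if strict:
                raise KeyError(msg)
            logger.warning("%s; skipping", msg)
            continue
        kb[sid] = kb.get(sid, 0.0) + a.cnv.length / 1000.0
        all_hit.setdefault(sid, set()).update(a.genes_hit)
        set_hit.setdefault(sid, set()).update(a.genes_hit & members)
        n_cnvs[sid] = n_cnvs.get(sid, 0) + 1

    df = subjects.copy()
    df["set_hits"] = [len(set_hit.get(s, ())) for s in df["subject_id"]]
    df["total_cnv_kb"] = [kb.get(s, 0.0) for s in df["subject_id"]]
    df["total_genes_hit"] = [len(all_hit.get(s, ()))
                             for s in df["subject_id"]]
    if genes_per_cnv_mode == "mean":
        df["mean_genes_per_cnv"] = [
            len(all_hit.get(s, ())) / n_cnvs[s] if n_cnvs.get(s) else 0.0
            for s in df["subject_id"]]
    return df


@dataclass(frozen=True)
class EnrichmentResult:
    """Enrichment of one gene set in one CNV collection."""

    set_label: str
    stratum: str
    beta: float
    se: float
    z: float
    p: float
    p_corrected: float
    n_case: int
    n_control: int
    estimable: bool = True
    flag: str = ""

    def corrected(self, m: int) -> "EnrichmentResult":
        return replace(self, p_corrected=bonferroni(self.p, m))


class BurdenModel:
    """Covariate-adjusted logistic regression of case status on gene-set
    burden.

    Parameters
    ----------
    burden : DataFrame
        Output of :func:`build_burden_table` (or any frame with a binary
        ``phenotype`` column, a ``set_hits`` exposure and the requested
        covariate columns).
    covariates : sequence of str
        Columns entering the model alongside ``set_hits``.  Non-numeric
        columns are dummy-coded (first level as reference); single-level
        categoricals are dropped with a log message.
    """

    def __init__(self, burden: pd.DataFrame,
                 covariates=DEFAULT_COVARIATES,
                 set_label: str = "", stratum: str = "all"):
        self.burden = burden
        self.set_label = set_label
        self.stratum = stratum
        self.covariates = tuple(covariates)
        self.endog = burden["phenotype"].to_numpy(dtype=float)
        cols = [np.ones(len(burden)), burden["set_hits"].to_numpy(float)]
        names = ["const", "set_hits"]
        for cov in self.covariates:
            col = burden[cov]
            if pd.api.types.is_numeric_dtype(col):
                cols.append(col.to_numpy(float))
                names.append(cov)
            else:
                levels = sorted(col.unique())
                if len(levels) < 2:
                    logger.info("dropping single-level covariate %r", cov)
                    continue
                for lev in levels[1:]:
                    cols.append((col == lev).to_numpy(float))
                    names.append(f"{cov}[{lev}]")
        self.exog = np.column_stack(cols)
        self.exog_names = names
        self._hits_col = 1

    @classmethod
    def from_components(cls, subjects, annotated_cnvs, gene_set,
                        stratum: str = "all", covariates=DEFAULT_COVARIATES,
                        strict: bool = True) -> "BurdenModel":
        table = build_burden_table(subjects, annotated_cnvs, gene_set,
                                   stratum=stratum, strict=strict)
        label = getattr(gene_set, "label", "")
        return cls(table, covariates=covariates, set_label=label,
                   stratum=stratum)

    @property
    def n_case(self) -> int:
        return int(self.endog.sum())

    @property
    def n_control(self) -> int:
        return int(len(self.endog) - self.endog.sum())

    def fit(self, test: str = "wald", maxiter: int = 100) -> "BurdenResults":
        """Maximum-likelihood fit; Wald (default) or likelihood-ratio test
        on the ``set_hits`` coefficient, two-tailed either way."""
        return self._fit_exog(self.exog, test=test, maxiter=maxiter)

    def fit_with_hits(self, hits: np.ndarray, test: str = "wald"
                      ) -> "BurdenResults":
        """Refit with the exposure column replaced (permutation workhorse:
        the covariate structure is fixed, only ``set_hits`` changes)."""
        exog = self.exog.copy()
        exog[:, self._hits_col] = hits
        return self._fit_exog(exog, test=test)

    def _fit_exog(self, exog, test="wald", maxiter=100) -> "BurdenResults":
        hits = exog[:, self._hits_col]
        if np.ptp(hits) == 0.0:
            return BurdenResults(self, None, flag="constant set_hits: "
                                 "exposure non-estimable")
        if self.n_case == 0 or self.n_control == 0:
            return BurdenResults(self, None,
                                 flag="need at least one case and control")
        try:
            with np.errstate(all="ignore"):
                res = sm.Logit(self.endog, exog).fit(
                    disp=0, method="newton", maxiter=maxiter, warn_convergence=False)
        except (PerfectSeparationError, np.linalg.LinAlgError) as exc:
            return BurdenResults(self, None, flag=f"fit failed: {exc}")
        se = res.bse[self._hits_col]
        if not np.isfinite(se) or se > 1e3:
            return BurdenResults(self, res,
                                 flag="quasi-separation: unstable estimate")
        flag = "" if res.mle_retvals.get("converged", True) \
            else "did not converge"
        r = BurdenResults(self, res, flag=flag)
        if test == "lr":
            r._apply_lr_test(exog)
        return r

    def _fit_reduced(self, exog, maxiter=100):
        keep = [i for i in range(exog.shape[1]) if i != self._hits_col]
        with np.errstate(all="ignore"):
            return sm.Logit(self.endog, exog[:, keep]).fit(
                disp=0, method="newton", maxiter=maxiter, warn_convergence=False)


class BurdenResults:
    """Estimates, uncertainty and diagnostics for one burden fit.

    ``beta``/``se``/``z``/``p`` describe the ``set_hits`` coefficient;
    ``params`` holds the full coefficient vector.  ``p_corrected`` defaults
    to the uncorrected value until :meth:`corrected` is applied with the
    family size.
    """

    def __init__(self, model: BurdenModel, sm_results, flag: str = ""):
        self.model = model
        self._sm = sm_results
        self.flag = flag
        self.estimable = sm_results is not None
        j = model._hits_col
        if self.estimable:
            from scipy.stats import norm
            self.params = np.asarray(sm_results.params)
            self.bse = np.asarray(sm_results.bse)
            self.beta = float(self.params[j])
            self.se = float(self.bse[j])
            self.z = self.beta / self.se
            self.p = float(2.0 * norm.sf(abs(self.z)))
        else:
            self.params = self.bse = None
            self.beta = self.se = self.z = self.p = float("nan")
        self.p_corrected = self.p
        self.test = "wald"

    def _apply_lr_test(self, exog) -> None:
        from scipy.stats import chi2
        reduced = self.model._fit_reduced(exog)
        stat = 2.0 * (self._sm.llf - reduced.llf)
        self.p = float(chi2.sf(max(stat, 0.0), df=1))
        self.p_corrected = self.p
        self.test = "lr"

    def corrected(self, m: int) -> "BurdenResults":
        self.p_corrected = bonferroni(self.p, m)
        return self

    def as_result(self, m: int = 1) -> EnrichmentResult:
        return EnrichmentResult(
            set_label=self.model.set_label, stratum=self.model.stratum,
            beta=self.beta, se=self.se, z=self.z, p=self.p,
            p_corrected=bonferroni(self.p, m) if self.estimable
            else float("nan"),
            n_case=self.model.n_case, n_control=self.model.n_control,
            estimable=self.estimable, flag=self.flag)

    def summary(self) -> str:
        lines = [
            "Gene-set CNV burden logistic regression",
            f"  gene set : {self.model.set_label or '<unnamed>'}"
            f"  stratum: {self.model.stratum}",
            f"  subjects : {len(self.model.endog)} "
            f"({self.model.n_case} cases / {self.model.n_control} controls)",
        ]
        if not self.estimable:
            lines.append(f"  NON-ESTIMABLE: {self.flag}")
            return "\n".join(lines)
        lines.append(f"  test     : {self.test} (two-tailed)")
        if self.flag:
            lines.append(f"  flag     : {self.flag}")
        lines.append(f"  {'term':<18}{'coef':>10}{'se':>10}{'z':>8}"
                     f"{'p':>12}")
        from scipy.stats import norm
        for name, b, s in zip(self.model.exog_names, self.params, self.bse):
            z = b / s if s > 0 else float("nan")
            p = 2.0 * norm.sf(abs(z))
            lines.append(f"  {name:<18}{b:>10.4f}{s:>10.4f}{z:>8.2f}"
                         f"{p:>12.3g}")
        lines.append(f"  set_hits p (two-tailed) = {self.p:.4g}; "
                     f"corrected = {self.p_corrected:.4g}")
        return "\n".join(lines)


def fit_enrichment(table: pd.DataFrame,
                   covariates=DEFAULT_COVARIATES,
                   set_label: str = "", stratum: str = "all",
                   test: str = "wald") -> EnrichmentResult:
    """Fit the burden regression on a prepared table and return the
    enrichment of the gene set (uncorrected; apply :func:`bonferroni` or
    ``EnrichmentResult.corrected`` for the family)."""
    model = BurdenModel(table, covariates=covariates, set_label=set_label,
                        stratum=stratum)
    return model.fit(test=test).as_result()


def bonferroni(p: float, m: int) -> float:
    """Bonferroni correction: min(1, m*p)."""
    if m < 1:
        raise ValueError("m must be >= 1")
    return float(min(1.0, m * p))


def per_gene_enrichment(subjects: pd.DataFrame,
                        annotated_cnvs: list[AnnotatedCNV],
                        gene_set,
                        stratum: str = "all",
                        covariates=DEFAULT_COVARIATES,
                        strict: bool = True) -> pd.DataFrame:
    """Refit the burden model per gene-set member, with that single gene's
    hit count as the exposure.

    This is an exploratory attribution of the set-level signal to
    individual genes; p-values are deliberately uncorrected.  Genes hit by
    no subject are reported as non-estimable.
    """
    members = sorted(getattr(gene_set, "members", gene_set))
    base = build_burden_table(subjects, annotated_cnvs, frozenset(),
                              stratum=stratum, strict=strict)
    model = BurdenModel(base, covariates=covariates,
                        set_label=getattr(gene_set, "label", ""),
                        stratum=stratum)
    annotated = stratify_by_type(annotated_cnvs, stratum)
    hit_subjects: dict[str, set] = {g: set() for g in members}
    for a in annotated:
        for g in a.genes_hit:
            if g in hit_subjects:
                hit_subjects[g].add(a.cnv.subject_id)
    sid_index = {s: i for i, s in enumerate(base["subject_id"])}
    rows = []
    for g in members:
        hits = np.zeros(len(base))
        for s in hit_subjects[g]:
            if s in sid_index:
                hits[sid_index[s]] = 1.0
        r = model.fit_with_hits(hits)
        rows.append({
            "gene": g, "n_carriers": int(hits.sum()),
            "beta": r.beta, "se": r.se, "z": r.z, "p": r.p,
            "estimable": r.estimable, "flag": r.flag,
        })
    return pd.DataFrame(rows)
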