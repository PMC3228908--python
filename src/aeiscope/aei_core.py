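"""AEI ratios, gDNA-based bias correction, significance calls and summaries.

The allelic expression imbalance (AEI) ratio of a heterozygous sample is the
allele-specific transcript count of the gene's designated numerator mSNP
allele divided by the denominator-allele count; the log2 transform makes
positive and negative imbalances symmetric.  Because PCR amplifies the two
alleles with gene-specific efficiency (up to ~1.5-fold), each gene's ratios
are corrected by the inverse of its mean genomic-DNA ratio — gDNA from a
heterozygote carries the alleles 1:1 by construction, so its mean corrected
ratio must be exactly 1.

Tables are pandas DataFrames with columns
``sample_id, gene, template, count_M, count_m, total_reads, ratio,
log2_ratio, corrected`` (plus ``call``/``threshold_used`` after significance
calling).  ``template`` is "gDNA" or "cDNA".
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "SIGNIFICANCE_THRESHOLD_LOG2",
    "BiasCorrector",
    "compute_aei",
    "fit_correction_factors",
    "apply_correction",
    "call_significance",
    "summarize_genes",
    "study_rollup",
    "replicate_concordance",
    "linear_from_log2",
    "log2_from_linear",
]

#: default per-sample significance threshold, log2 units (the 95% envelope of
#: normalized gDNA ratios: linear 0.82 .. 1.22)
SIGNIFICANCE_THRESHOLD_LOG2 = 0.29


def linear_from_log2(x):
    """Linear AEI ratio corresponding to a log2 ratio."""
    return np.power(2.0, x)


def log2_from_linear(r):
    """Log2 AEI ratio corresponding to a linear ratio."""
    return np.log2(r)


def _numerator_map(references) -> dict[str, str]:
    """gene -> numerator allele ('M' or 'm') from any reference representation."""
    if isinstance(references, dict):
        return {g: str(a) for g, a in references.items()}
    if isinstance(references, pd.DataFrame):
        return dict(zip(references["gene"], references["numerator_allele"]))
    return {r.gene: r.numerator_allele for r in references}


def compute_aei(counts: pd.DataFrame, references) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Linear and log2 AEI ratios from allele counts.

    ``references`` supplies each gene's numerator allele (reference table
    DataFrame, list of AmpliconReference, or a gene->allele dict).  Records
    where either allele count is zero cannot form a ratio and are returned in
    the second frame with an exclusion reason instead of being pseudocounted.
    """
    num = _numerator_map(references)
    missing = sorted(set(counts["gene"]) - set(num))
    if missing:
        raise ValueError(f"genes absent from reference table: {missing}")
    df = counts.copy()
    zero = (df["count_M"] == 0) | (df["count_m"] == 0)
    excluded = df[zero].copy()
    if len(excluded):
        excluded["reason"] = np.where(
            (excluded["count_M"] == 0) & (excluded["count_m"] == 0),
            "no_reads",
            "zero_count_one_allele",
        )
    df = df[~zero].copy()
    num_allele = df["gene"].map(num)
    numc = np.where(num_allele == "M", df["count_M"], df["count_m"])
    denc = np.where(num_allele == "M", df["count_m"], df["count_M"])
    df["total_reads"] = df["count_M"] + df["count_m"]
    df["ratio"] = numc / denc
    df["log2_ratio"] = np.log2(df["ratio"])
    df["corrected"] = False
    return df.reset_index(drop=True), excluded.reset_index(drop=True)


class BiasCorrector(BaseEstimator, TransformerMixin):
    """Per-gene PCR amplification-bias correction learned from gDNA ratios.

    fit() computes one factor per gene as the inverse of the mean uncorrected
    gDNA linear ratio ("arithmetic", the default, or "geometric" — the
    log2-symmetric alternative).  transform() multiplies every record's ratio
    by its gene's factor and recomputes the log2; it applies to both gDNA and
    cDNA records and refuses records already corrected.  After transform, the
    per-gene mean of corrected gDNA linear ratios is 1 to machine precision
    (arithmetic mode).

    Fitted attribute ``factors_``: DataFrame (gene, factor, n_gdna_samples).
    """

    def __init__(self, mean: str = "arithmetic", min_gdna_warn: int = 3,
                 on_missing_gene: str = "drop"):
        self.mean = mean
        self.min_gdna_warn = min_gdna_warn
        self.on_missing_gene = on_missing_gene

    def fit(self, X: pd.DataFrame, y=None):
        if self.mean not in ("arithmetic", "geometric"):
            raise ValueError("mean must be 'arithmetic' or 'geometric'")
        g = X[(X["template"] == "gDNA") & (~X["corrected"])]
        if g.empty:
            raise ValueError("no uncorrected gDNA records to fit on")
        if self.mean == "arithmetic":
            means = g.groupby("gene")["ratio"].mean()
        else:
            means = g.groupby("gene")["ratio"].agg(lambda r: float(np.exp(np.mean(np.log(r)))))
        counts = g.groupby("gene")["ratio"].size()
        few = counts[counts < self.min_gdna_warn]
        if len(few):
            warnings.warn(
                f"{len(few)} gene(s) have fewer than {self.min_gdna_warn} gDNA "
                f"samples for correction: {sorted(few.index)[:5]}..."
            )
        self.factors_ = pd.DataFrame(
            {
                "gene": means.index,
                "factor": (1.0 / means).values,
                "n_gdna_samples": counts.reindex(means.index).values,
            }
        ).reset_index(drop=True)
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        if not hasattr(self, "factors_"):
            raise AttributeError("fit must be called first")
        if X["corrected"].any():
            raise ValueError("records already corrected; refusing double application")
        fmap = dict(zip(self.factors_["gene"], self.factors_["factor"]))
        known = X["gene"].isin(fmap)
        if not known.all():
            dropped = sorted(X.loc[~known, "gene"].unique())
            if self.on_missing_gene == "error":
                raise ValueError(f"no correction factor for genes: {dropped}")
            warnings.warn(f"dropping genes without gDNA correction factor: {dropped}")
        out = X[known].copy()
        out["ratio"] = out["ratio"] * out["gene"].map(fmap)
        out["log2_ratio"] = np.log2(out["ratio"])
        out["corrected"] = True
        return out.reset_index(drop=True)


def fit_correction_factors(aei: pd.DataFrame, mean: str = "arithmetic") -> pd.DataFrame:
    """Per-gene correction factors (gene, factor, n_gdna_samples)."""
    return BiasCorrector(mean=mean).fit(aei).factors_


def apply_correction(aei: pd.DataFrame, factors: pd.DataFrame) -> pd.DataFrame:
    """Apply precomputed per-gene factors to uncorrected records."""
    bc = BiasCorrector()
    bc.factors_ = factors
    return bc.transform(aei)


def call_significance(
    aei: pd.DataFrame,
    threshold: float = SIGNIFICANCE_THRESHOLD_LOG2,
    error_curve=None,
    require_corrected: bool = True,
) -> pd.DataFrame:
    """Per-sample significance of log2 AEI ratios.

    A record is called positive when log2_ratio > +threshold and negative
    when < -threshold; the boundaries themselves are non-significant (strict
    inequalities).  With an ``error_curve`` the threshold becomes the
    read-depth-specific error bound E(total_reads) instead of the constant.
    """
    if require_corrected and not aei["corrected"].all():
        raise ValueError(
            "records must be bias-corrected before significance calling "
            "(pass require_corrected=False to override)"
        )
    out = aei.copy()
    if error_curve is not None:
        thr = np.asarray(error_curve.lookup(out["total_reads"].to_numpy()), dtype=float)
        thr = np.atleast_1d(thr)
    else:
        thr = np.full(len(out), float(threshold))
    out["threshold_used"] = thr
    out["call"] = np.select(
        [out["log2_ratio"].to_numpy() < -thr, out["log2_ratio"].to_numpy() > thr],
        ["negative", "positive"],
        default="non-significant",
    )
    return out


def summarize_genes(called: pd.DataFrame, template: str = "cDNA") -> pd.DataFrame:
    """Per-gene AEI pattern: call fractions and log2 extremes.

    Operates on significance-called records of one template (default cDNA).
    Fractions sum to 1 per gene.
    """
    df = called[called["template"] == template]
    if df.empty:
        raise ValueError(f"no {template} records to summarize")
    rows = []
    for gene, g in df.groupby("gene"):
        n = len(g)
        vc = g["call"].value_counts()
        rows.append(
            {
                "gene": gene,
                "n_het_samples": n,
                "frac_negative": vc.get("negative", 0) / n,
                "frac_nonsig": vc.get("non-significant", 0) / n,
                "frac_positive": vc.get("positive", 0) / n,
                "min_log2": float(g["log2_ratio"].min()),
                "max_log2": float(g["log2_ratio"].max()),
            }
        )
    return pd.DataFrame(rows)


def study_rollup(summary: pd.DataFrame) -> dict:
    """Study-level rollups over the per-gene summaries.

    Reports the fraction of genes with any significant sample, with >= 20% of
    samples significant, and with none, plus the mean significant fraction and
    a 10-bin histogram of per-gene significant fractions.
    """
    sig_frac = (summary["frac_negative"] + summary["frac_positive"]).to_numpy()
    hist, edges = np.histogram(sig_frac, bins=np.linspace(0, 1, 11))
    return {
        "n_genes": int(len(summary)),
        "frac_genes_any_significant": float(np.mean(sig_frac > 0)),
        "frac_genes_ge20pct_significant": float(np.mean(sig_frac >= 0.20)),
        "frac_genes_no_aei": float(np.mean(sig_frac == 0)),
        "mean_significant_fraction": float(sig_frac.mean()),
        "median_significant_fraction": float(np.median(sig_frac)),
        "significant_fraction_histogram": {
            "bin_edges": edges.tolist(),
            "counts": hist.tolist(),
        },
    }


def replicate_concordance(
    aei_a: pd.DataFrame, aei_b: pd.DataFrame, template: str = "cDNA"
) -> pd.DataFrame:
    """Per-gene OLS agreement between two independent assays.

    Records are matched by (sample_id, gene); genes with fewer than 3 matched
    pairs are reported as not assessable, and zero variance in either assay
    leaves r2 undefined (NaN).
    """
    a = aei_a[aei_a["template"] == template][["sample_id", "gene", "log2_ratio"]]
    b = aei_b[aei_b["template"] == template][["sample_id", "gene", "log2_ratio"]]
    merged = a.merge(b, on=["sample_id", "gene"], suffixes=("_a", "_b"))
    rows = []
    for gene, g in merged.groupby("gene"):
        n = len(g)
        row = {"gene": gene, "n_pairs": n, "slope": np.nan, "intercept": np.nan,
               "r2": np.nan, "assessable": False}
        if n >= 3:
            x = g["log2_ratio_a"].to_numpy()
            y = g["log2_ratio_b"].to_numpy()
            if np.ptp(x) > 0 and np.ptp(y) > 0:
                res = stats.linregress(x, y)
                row.update(
                    slope=float(res.slope),
                    intercept=float(res.intercept),
                    r2=float(res.rvalue**2),
                    assessable=True,
                )
        rows.append(row)
    return pd.DataFrame(rows)
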