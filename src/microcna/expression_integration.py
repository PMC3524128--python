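"""Copy-number / expression integration.

Per gene, samples are dichotomized at the gene's cohort median expression
(strictly above / strictly below; exact-median ties are excluded). Against
that, three views of CNA-expression association:

* per-gene concordance rates by aberration class (a concordant sample pairs
  an amplification-type status with above-median expression or a
  deletion-type status with below-median expression);
* pooled 2x2 tables over all (gene, sample) pairs, tested with a two-sided
  Fisher exact test;
* per-gene one-way ANOVA of expression between aberrant and non-aberrant
  samples.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import ExpressionMatrix

logger = logging.getLogger(__name__)

AMP_CLASSES = {"gross-gain", "micro-amp"}
DEL_CLASSES = {"gross-loss", "micro-del"}
CONCORDANCE_CLASSES = ("gross-gain", "gross-loss", "micro-amp", "micro-del")


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts with rows = expression above/below median, columns = class present/absent."""

    a: int  # above median, class present
    b: int  # above median, class absent
    c: int  # below median, class present
    d: int  # below median, class absent

    def __post_init__(self):
        for v in (self.a, self.b, self.c, self.d):
            if v < 0 or int(v) != v:
                raise ValueError("contingency cells must be nonnegative integers")


@dataclass
class ConcordanceSummary:
    """Per aberration class: genes carrying it, and how many are 100% / >=50% concordant."""

    table: pd.DataFrame  # index = class; columns n_genes_with_class, n_100pct, n_ge50pct, + rates


def dichotomize_expression(expr: ExpressionMatrix, min_present: int = 3) -> pd.DataFrame:
    """Gene x sample ternary matrix: +1 above gene median, −1 below, 0 at, NaN missing.

    The median is taken over each gene's non-missing samples (midpoint
    convention for even counts). Genes with fewer than ``min_present``
    present values are dropped with a log message.
    """
    vals = expr.values.where(expr.present_mask)
    n_present = vals.notna().sum(axis=1)
    thin = n_present < min_present
    if thin.any():
        logger.info("dropping %d genes with < %d present expression values", int(thin.sum()), min_present)
        vals = vals.loc[~thin]
    med = vals.median(axis=1)
    out = pd.DataFrame(np.nan, index=vals.index, columns=vals.columns)
    diff = vals.sub(med, axis=0)
    out[diff > 0] = 1.0
    out[diff < 0] = -1.0
    out[diff == 0] = 0.0
    return out


def gene_concordance(statuses: pd.DataFrame, dicho: pd.DataFrame) -> ConcordanceSummary:
    """Within-gene concordance rates for each aberration class.

    For each gene and class, the class-bearing samples are those whose status
    equals the class; a sample is concordant when its dichotomized expression
    matches the class direction (+1 for gains/amps, −1 for losses/dels);
    "at"/missing expression makes the sample non-concordant but it still
    counts in the gene's denominator. Genes with no class-bearing sample are
    excluded from that class's denominator.
    """
    genes = statuses.index.intersection(dicho.index)
    samples = statuses.columns.intersection(dicho.columns)
    st = statuses.loc[genes, samples]
    dx = dicho.loc[genes, samples]
    rows = []
    for cls in CONCORDANCE_CLASSES:
        direction = 1.0 if cls in AMP_CLASSES else -1.0
        bearing = st == cls
        n_bearing = bearing.sum(axis=1)
        concordant = (bearing & (dx == direction)).sum(axis=1)
        has = n_bearing > 0
        frac = concordant[has] / n_bearing[has]
        n_genes = int(has.sum())
        n_100 = int((frac == 1.0).sum())
        n_50 = int((frac >= 0.5).sum())
        rows.append(
            {
                "class": cls,
                "n_genes_with_class": n_genes,
                "n_100pct": n_100,
                "n_ge50pct": n_50,
                "rate_100pct": n_100 / n_genes if n_genes else np.nan,
                "rate_ge50pct": n_50 / n_genes if n_genes else np.nan,
            }
        )
    return ConcordanceSummary(table=pd.DataFrame(rows).set_index("class"))


def pooled_contingency(
    statuses: pd.DataFrame, dicho: pd.DataFrame, class_filter: str = "any-micro"
) -> ContingencyTable2x2:
    """Pooled 2x2 over all (gene, sample) pairs with non-tied expression.

    ``class_filter`` is one of micro-amp, micro-del, any-micro (or any single
    status value): column 1 counts pairs whose status matches the filter,
    column 2 the rest; rows split on above vs. below gene-median expression.
    """
    genes = statuses.index.intersection(dicho.index)
    samples = statuses.columns.intersection(dicho.columns)
    st = statuses.loc[genes, samples].to_numpy(dtype=object)
    dx = dicho.loc[genes, samples].to_numpy(dtype=float)
    if class_filter == "any-micro":
        present = (st == "micro-amp") | (st == "micro-del")
    else:
        present = st == class_filter
    above = dx == 1.0
    below = dx == -1.0
    return ContingencyTable2x2(
        a=int((above & present).sum()),
        b=int((above & ~present).sum()),
        c=int((below & present).sum()),
        d=int((below & ~present).sum()),
    )


def fisher_exact_2x2(table: ContingencyTable2x2, rel_tol: float = 1e-7) -> float:
    """Two-sided Fisher exact p-value, minimum-likelihood convention.

    With margins fixed, sums the hypergeometric point probabilities of every
    table whose probability is at most that of the observed one (within
    ``rel_tol`` relative tolerance, so floating-point ties count). Any zero
    margin gives p = 1 by convention.
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    n = a + b + c + d
    r1, c1 = a + b, a + c
    if r1 == 0 or r1 == n or c1 == 0 or c1 == n:
        return 1.0
    lo = max(0, c1 - (n - r1))
    hi = min(r1, c1)
    support = np.arange(lo, hi + 1)
    pmf = stats.hypergeom.pmf(support, n, c1, r1)
    p_obs = pmf[a - lo]
    p = float(pmf[pmf <= p_obs * (1.0 + rel_tol)].sum())
    return min(p, 1.0)


def anova_by_status(
    values: Sequence[float], labels: Sequence[str], aberrant_label: str = "aberrant"
) -> tuple[float, float]:
    """One-way fixed-effects ANOVA of expression between two status groups.

    Returns ``(F, p)`` with p from F(1, n−2); a group with fewer than two
    samples yields ``(nan, nan)`` with a warning.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    g1 = values[labels == aberrant_label]
    g2 = values[labels != aberrant_label]
    if len(g1) < 2 or len(g2) < 2:
        warnings.warn("ANOVA needs >= 2 samples per group; returning NA", stacklevel=2)
        return float("nan"), float("nan")
    if np.allclose(values, values[0]):
        return 0.0, 1.0
    f, p = stats.f_oneway(g1, g2)
    return float(f), float(p)


def per_gene_anova(
    statuses: pd.DataFrame, expr: ExpressionMatrix, classes: Optional[set] = None
) -> pd.DataFrame:
    """ANOVA per gene: aberrant (status in ``classes``) vs. everyone else.

    Default classes are the two micro kinds. Genes where either group has
    fewer than two expressed samples are reported with NaN.
    """
    classes = classes or {"micro-amp", "micro-del"}
    genes = statuses.index.intersection(expr.values.index)
    samples = statuses.columns.intersection(expr.values.columns)
    rows = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for gene in genes:
            vals = expr.values.loc[gene, samples].where(expr.present_mask.loc[gene, samples])
            ok = vals.notna()
            lab = statuses.loc[gene, samples].isin(classes).map({True: "aberrant", False: "other"})
            n_ab = int((lab[ok] == "aberrant").sum())
            f, p = anova_by_status(vals[ok].to_numpy(), lab[ok].to_numpy())
            rows.append({"gene": gene, "n_aberrant": n_ab, "n_other": int(ok.sum()) - n_ab, "F": f, "p": p})
    return pd.DataFrame(rows).set_index("gene")
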