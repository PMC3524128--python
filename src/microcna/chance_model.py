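"""Expected-by-chance null for per-gene micro-aberration counts.

The null treats each probe's log2 ratio as an independent draw from the
pooled empirical distribution (no spatial autocorrelation — a deliberate
simplification). A chance micro-aberration is a maximal run of consecutive
threshold exceedances whose length falls in the callable micro range, and a
scan-statistic expectation with gene-size correction (the number of places a
run of length r fits among a gene's probes) gives the expected count per
gene across the cohort. Observed counts are then tested against the
expectation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

EPS = 1e-12


@dataclass
class NullExpectation:
    gene_symbol: str
    n_probes: int
    p_exceed: float
    expected_count: float
    observed_count: int
    p_value: float


def exceedance_probability(values: Iterable[float], threshold: float = 0.30) -> float:
    """Empirical fraction of |log2| values strictly above the threshold."""
    arr = np.asarray(list(values) if not isinstance(values, np.ndarray) else values, dtype=float)
    arr = arr[~np.isnan(arr)]
    if arr.size == 0:
        raise ValueError("empty log-ratio multiset")
    return float((np.abs(arr) > threshold).mean())


def expected_micro_count(
    n_probes_gene: int,
    p_exceed: float,
    min_probes: int = 5,
    max_probes: int = 64,
    n_samples: int = 96,
) -> float:
    """Expected maximal exceedance runs of length in [min_probes, max_probes).

    For a Bernoulli(p) string of length n, the expected number of maximal
    runs of length exactly r is (n − r − 1)·p^r·(1−p)^2 + 2·p^r·(1−p) for
    r < n (the two boundary placements need only one non-exceedance flank)
    and p^n for r = n. Summed over the callable micro lengths and multiplied
    by the number of samples. p = 0 or 1 are handled as limits.
    """
    n = int(n_probes_gene)
    p = float(p_exceed)
    if not 0.0 <= p <= 1.0:
        raise ValueError("p_exceed must be a probability")
    if p == 0.0:
        return 0.0
    total = 0.0
    q = 1.0 - p
    for r in range(min_probes, min(max_probes - 1, n) + 1):
        if r > n:
            break
        if r == n:
            total += p**n
        else:
            total += p**r * q * ((n - r - 1) * q + 2.0)
    return float(n_samples) * total


def simulate_run_count(
    n_probes: int,
    p_exceed: float,
    min_probes: int = 5,
    max_probes: int = 64,
    n_replicates: int = 10_000,
    rng: Optional[np.random.Generator] = None,
) -> np.ndarray:
    """Monte-Carlo counts of callable maximal runs in Bernoulli probe strings.

    Returns one count per replicate string; the mean estimates the per-sample
    expectation that :func:`expected_micro_count` computes analytically.
    """
    rng = rng or np.random.default_rng()
    x = rng.random((n_replicates, n_probes)) < p_exceed
    padded = np.zeros((n_replicates, n_probes + 2), dtype=np.int8)
    padded[:, 1:-1] = x
    d = np.diff(padded, axis=1)
    # per row, starts and ends alternate in order, so the flattened sequences align
    rows, start_pos = np.nonzero(d == 1)
    _, end_pos = np.nonzero(d == -1)
    lengths = end_pos - start_pos
    callable_runs = (lengths >= min_probes) & (lengths < max_probes)
    return np.bincount(rows[callable_runs], minlength=n_replicates).astype(np.int64)


def observed_vs_expected_test(observed: int, expected: float, mode: str = "exact") -> float:
    """P-value for an observed count against its chance expectation.

    ``exact`` (default): Poisson upper tail P(X >= observed | lambda =
    max(expected, eps)). ``chisq``: one-cell chi-square (observed −
    expected)^2 / max(expected, eps) on 1 df — degenerate for near-zero
    expectations but provided for display parity with the classical test.
    """
    if observed < 0 or expected < 0:
        raise ValueError("observed and expected must be nonnegative")
    lam = max(float(expected), EPS)
    if mode == "exact":
        return float(stats.poisson.sf(observed - 1, lam))
    if mode == "chisq":
        stat = (observed - lam) ** 2 / lam
        return float(stats.chi2.sf(stat, df=1))
    raise ValueError(f"unknown mode {mode!r}")


def format_p(p: float, floor: float = 0.001) -> str:
    """Display convention: values below the floor print as '<.001'."""
    if np.isnan(p):
        return "NA"
    if p < floor:
        return "<.001"
    return f"{p:.3g}"


def chance_table(
    matrix,
    micros,
    threshold: float = 0.30,
    min_probes: int = 5,
    max_probes: int = 64,
    mode: str = "exact",
) -> pd.DataFrame:
    """Per-gene observed vs. expected-by-chance micro counts with p-values.

    ``p_exceed`` comes from the pooled empirical log-ratio distribution of
    the whole matrix; the gene-size correction enters through each gene's
    probe count. Rows are sorted by observed count, descending.
    """
    p = exceedance_probability(matrix.values.to_numpy().ravel(), threshold)
    n_samples = len(matrix.samples)
    probes_per_gene = matrix.probes.table.groupby("gene_symbol", sort=False).size()
    obs_all: dict[str, int] = {}
    obs_amp: dict[str, int] = {}
    obs_del: dict[str, int] = {}
    for m in micros:
        g = m.segment.gene_symbol
        obs_all[g] = obs_all.get(g, 0) + 1
        if m.kind == "micro-amp":
            obs_amp[g] = obs_amp.get(g, 0) + 1
        else:
            obs_del[g] = obs_del.get(g, 0) + 1
    rows = []
    for gene, n_probes in probes_per_gene.items():
        expected = expected_micro_count(int(n_probes), p, min_probes, max_probes, n_samples)
        observed = obs_all.get(gene, 0)
        rows.append(
            {
                "gene": gene,
                "n_probes": int(n_probes),
                "observed_all": observed,
                "observed_amp": obs_amp.get(gene, 0),
                "observed_del": obs_del.get(gene, 0),
                "p_exceed": p,
                "expected": expected,
                "p_value": observed_vs_expected_test(observed, expected, mode),
            }
        )
    df = pd.DataFrame(rows).sort_values(["observed_all", "gene"], ascending=[False, True])
    df["p_display"] = df["p_value"].map(format_p)
    return df.set_index("gene")
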