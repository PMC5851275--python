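"""Enrichment statistics: chi-square tests, BH adjustment, resampling Z.

The chi-square path is the plain Pearson statistic without continuity
correction (scipy), with Benjamini-Hochberg adjustment across a set of
tests.  The resampling test draws ``n_resample`` samples of families
without replacement from a background pool, counts positives in each, and
standardises the observed count against the replicate distribution
(population standard deviation); both the two-sided and the one-sided
normal tail are reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .families import Thresholds


@dataclass
class EnrichmentResult:
    name: str
    table: np.ndarray
    chi2: float
    dof: int
    p_value: float
    adjusted_p: float | None
    observed_prop: np.ndarray
    expected_prop: np.ndarray


def chi_square_test(table, name: str = "") -> EnrichmentResult:
    """Pearson chi-square (no continuity correction) on one contingency table."""
    arr = np.asarray(table, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 2 or arr.shape[1] < 2:
        raise ValueError("contingency table must be at least 2x2")
    row_sums = arr.sum(axis=1)
    col_sums = arr.sum(axis=0)
    for i, s in enumerate(row_sums):
        if s == 0:
            raise ValueError(f"degenerate contingency table: row {i} sums to 0")
    for j, s in enumerate(col_sums):
        if s == 0:
            raise ValueError(f"degenerate contingency table: column {j} sums to 0")
    chi2, p, dof, expected = sps.chi2_contingency(arr, correction=False)
    total = arr.sum()
    return EnrichmentResult(
        name=name, table=arr, chi2=float(chi2), dof=int(dof),
        p_value=float(p), adjusted_p=None,
        observed_prop=arr / total, expected_prop=expected / total,
    )


def bh_adjust(p_values: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, idempotent)."""
    if len(p_values) == 0:
        return []
    return list(multipletests(p_values, method="fdr_bh")[1])


def chi_square_enrichment(
    tables: Mapping[str, object],
    adjust: bool = True,
) -> list[EnrichmentResult]:
    """Run a family of chi-square tests with optional BH adjustment."""
    results = [chi_square_test(tbl, name) for name, tbl in tables.items()]
    if adjust:
        adjusted = bh_adjust([r.p_value for r in results])
        for r, ap in zip(results, adjusted):
            r.adjusted_p = float(ap)
    return results


@dataclass
class ResamplingResult:
    observed: int
    replicate_counts: list[int]
    mean: float
    sd: float
    z_score: float
    p_two_sided: float
    p_one_sided: float
    seed: int


def resampling_zscore(
    observed: int,
    pool: Sequence[bool],
    sample_size: int,
    t: Thresholds | None = None,
    seed: int = 0,
    exhaustive: bool = False,
) -> ResamplingResult:
    """Standardise an observed positive count against resampled baselines.

    Each of ``n_resample`` replicates samples ``sample_size`` pool entries
    without replacement and counts positives.  Z uses the population SD of
    the replicate counts; a zero SD (degenerate pool) is an error.  Fully
    deterministic for a fixed seed.

    With ``exhaustive=True`` the replicates are *all* subsets of the pool
    of the given size (feasible for small pools only), which makes the
    baseline distribution exact.
    """
    t = t or Thresholds()
    flags = np.asarray(pool, dtype=bool)
    if sample_size > flags.size:
        raise ValueError("sample_size exceeds the pool size")
    rng = np.random.default_rng(seed)
    if exhaustive:
        from itertools import combinations

        counts = np.array([
            sum(flags[list(idx)])
            for idx in combinations(range(flags.size), sample_size)
        ])
    else:
        counts = np.array([
            int(flags[rng.choice(flags.size, size=sample_size,
                                 replace=False)].sum())
            for _ in range(t.n_resample)
        ])
    mean = float(counts.mean())
    sd = float(counts.std(ddof=0))
    if sd == 0:
        raise ValueError("degenerate pool: replicate counts have zero variance")
    z = (observed - mean) / sd
    p_one = float(sps.norm.sf(abs(z)))
    return ResamplingResult(
        observed=observed, replicate_counts=counts.tolist(),
        mean=mean, sd=sd, z_score=float(z),
        p_two_sided=2 * p_one, p_one_sided=p_one, seed=seed,
    )


def degree_summary(
    degrees: Mapping[str, int],
    groups: Mapping[str, str],
    essential: Mapping[str, bool] | None = None,
) -> pd.DataFrame:
    """Per-group median and quartiles of PPI degree, plus essential fraction.

    Quartiles use the linear-interpolation convention (numpy default).
    Genes without a group assignment are ignored.
    """
    if not degrees:
        raise ValueError("empty degree table")
    rows = []
    by_group: dict[str, list[str]] = {}
    for gene, grp in groups.items():
        if gene in degrees:
            by_group.setdefault(grp, []).append(gene)
    for grp in sorted(by_group):
        genes = by_group[grp]
        vals = np.array([degrees[g] for g in genes], dtype=float)
        row = {
            "group": grp,
            "n": len(genes),
            "median": float(np.percentile(vals, 50)),
            "q1": float(np.percentile(vals, 25)),
            "q3": float(np.percentile(vals, 75)),
        }
        if essential is not None:
            flagged = [g for g in genes if g in essential]
            row["essential_fraction"] = (
                sum(essential[g] for g in flagged) / len(flagged)
                if flagged else float("nan")
            )
        rows.append(row)
    return pd.DataFrame(rows).set_index("group")
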