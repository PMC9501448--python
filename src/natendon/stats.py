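"""Regional comparison statistics and report tables.

The three tendon regions of the same subjects form a repeated-measures
design: a Friedman test screens for any regional difference, and when it
fires at alpha = 0.05 the three region pairs are compared with paired
Wilcoxon signed-rank tests whose p-values are Bonferroni-corrected by the
factor 3.  The signed-rank p defaults to the normal approximation without
continuity correction (what the original SPSS analysis printed); exact and
unpaired variants are available behind flags.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "FriedmanResult",
    "RegionalComparison",
    "friedman_test",
    "pairwise_wilcoxon_bonferroni",
    "regional_comparison",
    "build_report",
]

PAIRS = ("INS-MID", "INS-MTJ", "MID-MTJ")
_REGIONS = ("INS", "MID", "MTJ")


@dataclass(frozen=True)
class FriedmanResult:
    p_value: float
    statistic: float
    avg_ranks: tuple
    method: str


def _check_table(values) -> np.ndarray:
    v = np.asarray(values, dtype=float)
    if v.ndim != 2 or v.shape[1] != 3:
        raise ValueError(f"expected an n x 3 table, got shape {v.shape}")
    if v.shape[0] < 2:
        raise ValueError("need at least 2 subjects")
    if np.any(~np.isfinite(v)):
        raise ValueError("table contains missing cells")
    return v


def _friedman_stat(v: np.ndarray) -> tuple[float, np.ndarray]:
    """Tie-corrected Friedman chi-square and average ranks (mid-ranks)."""
    n, k = v.shape
    ranks = np.apply_along_axis(sps.rankdata, 1, v)
    avg = ranks.mean(axis=0)
    chi2 = 12.0 * n / (k * (k + 1)) * float(((avg - (k + 1) / 2.0) ** 2).sum())
    ties = 0.0
    for row in v:
        _, counts = np.unique(row, return_counts=True)
        ties += float((counts**3 - counts).sum())
    correction = 1.0 - ties / (n * k * (k**2 - 1))
    if correction <= 0:
        return 0.0, avg
    return chi2 / correction, avg


def friedman_test(values, method: str = "chi2") -> FriedmanResult:
    """Friedman test on an n x 3 repeated-measures table.

    ``method='chi2'`` uses the chi-square approximation with 2 degrees of
    freedom (ties mid-ranked, tie-corrected); ``'exact'`` enumerates all
    within-row orderings (n <= 8) and returns the permutation p-value of the
    same statistic.
    """
    v = _check_table(values)
    stat, avg = _friedman_stat(v)
    if method == "chi2":
        p = float(sps.chi2.sf(stat, df=v.shape[1] - 1))
        return FriedmanResult(min(p, 1.0), stat, tuple(avg), "chi2")
    if method != "exact":
        raise ValueError(f"unknown method {method!r}")
    n, k = v.shape
    if k**n > 10**7 or n > 8:
        raise ValueError("exact enumeration limited to n <= 8 subjects")
    perms = list(itertools.permutations(range(k)))
    count = total = 0
    for assignment in itertools.product(perms, repeat=n):
        permuted = np.array([v[i, list(p)] for i, p in enumerate(assignment)])
        s, _ = _friedman_stat(permuted)
        count += s >= stat - 1e-9
        total += 1
    return FriedmanResult(count / total, stat, tuple(avg), "exact")


def pairwise_wilcoxon_bonferroni(
    values, method: str = "approx", paired: bool = True
) -> dict[str, float]:
    """Bonferroni-corrected p-values for the three region pairs.

    Paired signed-rank per pair; ``method='approx'`` is the two-sided normal
    approximation without continuity correction, ``'exact'`` the exact null
    distribution.  ``paired=False`` falls back to the rank-sum
    (Mann-Whitney) test for independent groups.  Corrected p =
    ``min(3 * p, 1)``; a pair with all-zero differences yields p = 1.
    """
    v = _check_table(values)
    cols = {"INS": v[:, 0], "MID": v[:, 1], "MTJ": v[:, 2]}
    out = {}
    for pair in PAIRS:
        a_name, b_name = pair.split("-")
        a, b = cols[a_name], cols[b_name]
        if paired and np.all(a == b):
            p = 1.0
        elif paired:
            p = float(
                sps.wilcoxon(
                    a, b, zero_method="wilcox", correction=False, method=method
                ).pvalue
            )
        else:
            p = float(sps.mannwhitneyu(a, b, alternative="two-sided").pvalue)
        out[pair] = min(3.0 * p, 1.0)
    return out


@dataclass
class RegionalComparison:
    """Friedman screen plus (when significant) corrected pairwise tests."""

    parameter: str
    friedman_p: float
    pairwise_p: dict | None
    significant: dict = field(default_factory=dict)
    alpha: float = 0.05


def regional_comparison(values, parameter: str = "", alpha: float = 0.05, **kw) -> RegionalComparison:
    """Run the two-stage regional test; pairwise p only when the screen fires."""
    fr = friedman_test(values, **{k: v for k, v in kw.items() if k == "method"})
    pairwise = None
    flags = {}
    if fr.p_value < alpha:
        pairwise = pairwise_wilcoxon_bonferroni(values)
        flags = {pair: p <= alpha for pair, p in pairwise.items()}
    return RegionalComparison(parameter, fr.p_value, pairwise, flags, alpha)


def _collect(quants, attr: str, region: str, stat: str) -> np.ndarray:
    return np.array(
        [getattr(getattr(q, attr)[region], stat) for q in quants], dtype=float
    )


def build_report(
    subject_quants: Sequence,
    relaxometry_fits: Mapping[str, Sequence] | None = None,
) -> dict[str, pd.DataFrame]:
    """Assemble the three report tables of a cohort.

    * ``table1`` — per-ROI relaxation fit summary (mean over subjects):
      columns ``roi, t1_ms, r2_t1, t2s_ms, t2l_ms, ps_pct, r2_t2`` plus
      between-subject SD columns.  ``relaxometry_fits`` maps ROI name to a
      list of ``(t1_fit, t2_fit)`` FitResult pairs.
    * ``table2`` — per-region aTSC / SNR / proton-T2* means with
      between-subject SD (NaN for a single subject) and the mean within-ROI
      SD in %.
    * ``table3`` — Friedman and Bonferroni-corrected pairwise p-values per
      parameter (means and within-ROI SDs), requiring >= 2 subjects.
    """
    quants = list(subject_quants)
    if not quants:
        raise ValueError("need at least one subject")
    for q in quants:
        missing = [r for r in _REGIONS + ("Total",) if r not in q.atsc]
        if missing:
            raise ValueError(f"subject quantification missing regions: {missing}")

    tables: dict[str, pd.DataFrame] = {}

    if relaxometry_fits:
        rows = []
        for roi_name, fit_pairs in relaxometry_fits.items():
            t1s = np.array([fp[0].t1_ms for fp in fit_pairs], dtype=float)
            r2_t1 = np.array([fp[0].r_squared for fp in fit_pairs], dtype=float)
            t2s = np.array([fp[1].t2s_ms for fp in fit_pairs], dtype=float)
            t2l = np.array([fp[1].t2l_ms for fp in fit_pairs], dtype=float)
            ps = np.array([fp[1].ps for fp in fit_pairs], dtype=float)
            r2_t2 = np.array([fp[1].r_squared for fp in fit_pairs], dtype=float)
            sd = lambda x: float(x.std(ddof=1)) if x.size > 1 else np.nan
            rows.append(
                {
                    "roi": roi_name,
                    "t1_ms": float(t1s.mean()),
                    "r2_t1": float(r2_t1.mean()),
                    "t2s_ms": float(t2s.mean()),
                    "t2l_ms": float(t2l.mean()),
                    "ps_pct": float(100.0 * ps.mean()),
                    "r2_t2": float(r2_t2.mean()),
                    "t1_ms_sd": sd(t1s),
                    "t2s_ms_sd": sd(t2s),
                    "t2l_ms_sd": sd(t2l),
                    "ps_pct_sd": sd(100.0 * ps),
                }
            )
        tables["table1"] = pd.DataFrame(rows)

    param_attrs = [("aTSC [mM]", "atsc"), ("23Na SNR", "snr"), ("1H T2* [ms]", "h1_t2star")]
    rows = []
    for label, attr in param_attrs:
        if not getattr(quants[0], attr):
            continue
        for region in _REGIONS + ("Total",):
            means = _collect(quants, attr, region, "mean")
            within = _collect(quants, attr, region, "rel_sd_pct")
            rows.append(
                {
                    "parameter": label,
                    "roi": region,
                    "mean": float(means.mean()),
                    "between_subject_sd": float(means.std(ddof=1)) if len(quants) > 1 else np.nan,
                    "within_roi_sd_pct": float(within.mean()),
                    "n_subjects": len(quants),
                }
            )
    tables["table2"] = pd.DataFrame(rows)

    if len(quants) > 1:
        rows = []
        for label, attr in param_attrs:
            if not getattr(quants[0], attr):
                continue
            for stat, stat_label in (("mean", "mean"), ("rel_sd_pct", "SD")):
                table = np.column_stack(
                    [_collect(quants, attr, region, stat) for region in _REGIONS]
                )
                cmp_res = regional_comparison(table, parameter=f"{stat_label} {label}")
                row = {
                    "parameter": f"{stat_label} {label}",
                    "friedman_p": round(cmp_res.friedman_p, 3),
                }
                for pair in PAIRS:
                    row[pair] = (
                        round(cmp_res.pairwise_p[pair], 3) if cmp_res.pairwise_p else np.nan
                    )
                rows.append(row)
        tables["table3"] = pd.DataFrame(rows)
    return tables
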