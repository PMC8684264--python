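"""Paired-core heterogeneity tests, subtype-level ANOVA/Tukey comparisons, immune densities.

Intra-tumoral heterogeneity between the two cores of one specimen is tested on
the 16-class EPH×Ki67 label vectors of their cancer cells, treated literally
as numeric vectors of class indices (the group-major ordering is fixed, so the
index is an ordinal score — a deliberate, documented simplification).  A pair
is called significantly different only when BOTH a Wilcoxon rank-sum test and
a label-permutation test of the absolute mean-difference give p < alpha
(default 0.01); the conjunction is conservative.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .io import pos_col


@dataclass
class PairedCoreResult:
    """Result of one paired-core comparison."""

    case_id: str
    core_a: str
    core_b: str
    n_a: int
    n_b: int
    wilcoxon_p: float
    permutation_p: float
    n_permutations: int
    seed: int | None
    alpha: float = 0.01

    @property
    def significant(self) -> bool:
        return max(self.wilcoxon_p, self.permutation_p) < self.alpha

    def summary(self) -> str:
        flag = "DIFFERENT" if self.significant else "not different"
        return (
            f"case {self.case_id}: cores {self.core_a} (n={self.n_a}) vs "
            f"{self.core_b} (n={self.n_b}); Wilcoxon p={self.wilcoxon_p:.4g}, "
            f"permutation p={self.permutation_p:.4g} "
            f"(n_perm={self.n_permutations}); {flag} at alpha={self.alpha}"
        )


def _wilcoxon_ranksum(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sample Wilcoxon rank-sum p-value.

    Exact enumeration for small tie-free samples; otherwise the normal
    approximation with tie correction (class vectors are heavily tied).
    """
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        return 1.0
    no_ties = len(np.unique(pooled)) == len(pooled)
    method = "exact" if (len(pooled) < 50 and no_ties) else "asymptotic"
    return float(sps.mannwhitneyu(a, b, alternative="two-sided", method=method).pvalue)


def permutation_mean_test(
    a: np.ndarray,
    b: np.ndarray,
    n_perm: int = 10_000,
    rng: np.random.Generator | None = None,
) -> float:
    """Label-permutation p-value for T = |mean(a) - mean(b)|.

    Implemented by resampling the per-value counts allocated to group a from a
    multivariate hypergeometric distribution over the pooled value counts —
    exactly the distribution induced by shuffling group labels, at O(distinct
    values) per permutation.  Add-one estimator:
    p = (1 + #{T_perm >= T_obs}) / (1 + n_perm).
    """
    rng = rng if rng is not None else np.random.default_rng()
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both vectors must be non-empty")
    t_obs = abs(a.mean() - b.mean())
    values, counts = np.unique(np.concatenate([a, b]), return_counts=True)
    if len(values) == 1:
        return 1.0
    total = float((values * counts).sum())
    n_a, n_b = a.size, b.size
    take = rng.multivariate_hypergeometric(counts, n_a, size=n_perm)
    sum_a = take @ values
    t_perm = np.abs(sum_a / n_a - (total - sum_a) / n_b)
    return float((1 + np.count_nonzero(t_perm >= t_obs - 1e-12)) / (1 + n_perm))


def permutation_mean_test_bruteforce(
    a: np.ndarray, b: np.ndarray, n_perm: int, rng: np.random.Generator
) -> float:
    """Reference implementation: literal label shuffles (used as test oracle)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    pooled = np.concatenate([a, b])
    t_obs = abs(a.mean() - b.mean())
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(pooled)
        t = abs(perm[: a.size].mean() - perm[a.size :].mean())
        if t >= t_obs - 1e-12:
            count += 1
    return (1 + count) / (1 + n_perm)


def chi2_contingency_test(a: np.ndarray, b: np.ndarray) -> float:
    """Chi-squared contingency alternative treating classes as nominal
    (provided for sensitivity analysis; not the default decision rule)."""
    values = np.unique(np.concatenate([a, b]))
    table = np.array(
        [[np.count_nonzero(a == v) for v in values], [np.count_nonzero(b == v) for v in values]]
    )
    table = table[:, table.sum(axis=0) > 0]
    if table.shape[1] < 2:
        return 1.0
    return float(sps.chi2_contingency(table).pvalue)


def compare_paired_cores(
    classes_a,
    classes_b,
    alpha: float = 0.01,
    n_perm: int = 10_000,
    seed: int | None = None,
    case_id: str = "",
    core_a: str = "a",
    core_b: str = "b",
) -> PairedCoreResult:
    """Test whether two cores of one specimen differ in 16-class composition.

    Both the Wilcoxon rank-sum test (on class indices, tie-corrected) and the
    permutation test must reach p < alpha for the pair to be called different.
    """
    a = np.asarray(classes_a, dtype=float)
    b = np.asarray(classes_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("paired-core vectors must be non-empty")
    rng = np.random.default_rng(seed)
    return PairedCoreResult(
        case_id=case_id,
        core_a=core_a,
        core_b=core_b,
        n_a=a.size,
        n_b=b.size,
        wilcoxon_p=_wilcoxon_ranksum(a, b),
        permutation_p=permutation_mean_test(a, b, n_perm=n_perm, rng=rng),
        n_permutations=n_perm,
        seed=seed,
        alpha=alpha,
    )


@dataclass
class PairedScreenResult:
    """Per-case paired-core tests plus per-subtype significance tallies."""

    results: list = field(default_factory=list)
    alpha: float = 0.01

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "case_id": r.case_id,
                    "core_a": r.core_a,
                    "core_b": r.core_b,
                    "n_a": r.n_a,
                    "n_b": r.n_b,
                    "wilcoxon_p": r.wilcoxon_p,
                    "permutation_p": r.permutation_p,
                    "significant": r.significant,
                }
                for r in self.results
            ]
        )

    def subtype_tally(self, meta: pd.DataFrame) -> pd.DataFrame:
        """Significant/total cases per subtype.  A case whose two cores carry
        discordant subtypes is tallied under both subtypes."""
        sub_of = dict(zip(meta["core_id"].astype(str), meta["subtype"]))
        rows: dict[str, list[int]] = {}
        for r in self.results:
            subs = {sub_of[str(r.core_a)], sub_of[str(r.core_b)]}
            for s in subs:
                rows.setdefault(s, [0, 0])
                rows[s][0] += int(r.significant)
                rows[s][1] += 1
        return pd.DataFrame(
            [
                {
                    "subtype": s,
                    "n_significant": v[0],
                    "n_cases": v[1],
                    "fraction_significant": v[0] / v[1],
                }
                for s, v in sorted(rows.items())
            ]
        )

    def summary(self) -> str:
        n_sig = sum(r.significant for r in self.results)
        lines = [
            f"Paired-core heterogeneity screen: {len(self.results)} cases, "
            f"{n_sig} significant at alpha={self.alpha} (both tests)"
        ]
        lines += ["  " + r.summary() for r in self.results]
        return "\n".join(lines)


def run_paired_core_screen(
    cancer_cells: pd.DataFrame,
    meta: pd.DataFrame,
    alpha: float = 0.01,
    n_perm: int = 10_000,
    seed: int | None = None,
) -> PairedScreenResult:
    """One paired-core test per case with exactly two cores carrying cancer cells."""
    rng = np.random.default_rng(seed)
    core_case = meta[["core_id", "case_id"]].astype(str)
    classes_by_core = {
        str(cid): sub["eph_ki67_class"].to_numpy(dtype=int)
        for cid, sub in cancer_cells.groupby("core_id")
    }
    result = PairedScreenResult(alpha=alpha)
    for case_id, sub in core_case.groupby("case_id", sort=True):
        cores = sorted(sub["core_id"].tolist())
        if len(cores) != 2:
            continue
        ca, cb = cores
        if ca not in classes_by_core or cb not in classes_by_core:
            continue
        a, b = classes_by_core[ca], classes_by_core[cb]
        pair_seed = int(rng.integers(0, 2**31 - 1))
        result.results.append(
            compare_paired_cores(
                a, b, alpha=alpha, n_perm=n_perm, seed=pair_seed,
                case_id=case_id, core_a=ca, core_b=cb,
            )
        )
    return result


@dataclass
class AnovaResult:
    """One-way ANOVA with Tukey HSD pairwise comparisons."""

    f_statistic: float
    p_value: float
    tukey: pd.DataFrame
    group_sizes: dict

    def summary(self) -> str:
        head = f"one-way ANOVA: F = {self.f_statistic:.4g}, p = {self.p_value:.4g}"
        return head + "\n" + self.tukey.to_string(index=False)


def compare_groups_anova(values_by_group: dict, alpha: float = 0.01) -> AnovaResult:
    """One-way ANOVA across named groups plus Tukey honest-significant-difference
    pairwise table (used for EPH fractions across subtypes and for E_H across
    central classes)."""
    groups = {k: np.asarray(v, dtype=float) for k, v in values_by_group.items()}
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    f, p = sps.f_oneway(*groups.values())
    labels = np.concatenate([[k] * len(v) for k, v in groups.items()])
    data = np.concatenate(list(groups.values()))
    tk = pairwise_tukeyhsd(data, labels, alpha=alpha)
    tukey = pd.DataFrame(tk.summary().data[1:], columns=tk.summary().data[0])
    return AnovaResult(
        f_statistic=float(f),
        p_value=float(p),
        tukey=tukey,
        group_sizes={k: len(v) for k, v in groups.items()},
    )


def immune_density(all_cells: pd.DataFrame) -> pd.DataFrame:
    """Per-core CD8 and CD20 densities: positive cells as a percentage of all
    QC-passing segmented cells in the core."""
    if "qc_pass" in all_cells.columns:
        all_cells = all_cells[all_cells["qc_pass"]]
    rows = []
    for core_id, sub in all_cells.groupby("core_id", sort=True):
        n = len(sub)
        rows.append(
            {
                "core_id": core_id,
                "n_cells": n,
                "cd8_density_pct": 100.0 * float(sub[pos_col("cd8")].mean()) if n else float("nan"),
                "cd20_density_pct": 100.0 * float(sub[pos_col("cd20")].mean()) if n else float("nan"),
            }
        )
    return pd.DataFrame(rows)
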