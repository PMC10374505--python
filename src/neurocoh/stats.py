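"""Permutation-based group comparison of graph measures with FDR control.

Each of the 13 global measures in each of the 5 frequency bands is compared
between the two groups with a two-sided label-permutation test on the
difference of group means (1000 permutations by default, "+1" smoothed so
p is never 0), and the 65 raw p-values are corrected jointly by the
Benjamini-Hochberg step-up procedure. The clinical covariate table is
compared variable-by-variable with Welch t-tests (continuous) or chi-square
tests (binary), the conventional bedside analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sp_stats
from statsmodels.stats.multitest import multipletests

from .synth import CLINICAL_BINARY

__all__ = ["permutation_test", "fdr_bh", "compare_measures",
           "compare_clinical", "GroupComparisonResults", "measures_to_frame"]


def permutation_test(
    a: np.ndarray,
    b: np.ndarray,
    n_perm: int = 1000,
    seed: int = 0,
    statistic: str = "mean_diff",
) -> float:
    """Two-sided permutation p-value for a difference between two samples.

    The test statistic is the difference of group means (or Welch's t with
    ``statistic="t"``); group labels are permuted jointly ``n_perm`` times
    and the p-value is ``(1 + #{|T_perm| >= |T_obs|}) / (n_perm + 1)``.
    Deterministic given ``seed``. Two identical constant samples give p = 1.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least 2 observations per group")
    if not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise ValueError("non-finite values in input")
    pooled = np.concatenate([a, b])
    n_a = a.size

    def stat(x: np.ndarray, y: np.ndarray, axis: int = -1) -> np.ndarray:
        if statistic == "mean_diff":
            return x.mean(axis=axis) - y.mean(axis=axis)
        if statistic == "t":
            va = x.var(axis=axis, ddof=1) / x.shape[axis]
            vb = y.var(axis=axis, ddof=1) / y.shape[axis]
            denom = np.sqrt(va + vb)
            with np.errstate(invalid="ignore", divide="ignore"):
                t = (x.mean(axis=axis) - y.mean(axis=axis)) / denom
            return np.where(denom == 0, 0.0, t)
        raise ValueError(f"unknown statistic {statistic!r}")

    obs = abs(float(stat(a, b)))
    rng = np.random.default_rng(seed)
    idx = np.tile(np.arange(pooled.size), (n_perm, 1))
    idx = rng.permuted(idx, axis=1)
    perm = pooled[idx]
    t_perm = np.abs(stat(perm[:, :n_a], perm[:, n_a:]))
    count = int((t_perm >= obs - 1e-12).sum())
    return (1 + count) / (n_perm + 1)


def fdr_bh(p_values: np.ndarray, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up correction.

    Returns (adjusted p-values, reject flags at level ``q``). Adjusted
    p-values are monotone in the raw p-values; a hypothesis is rejected iff
    its adjusted p is <= q.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value array")
    if np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    reject, p_adj, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return p_adj, reject


@dataclass
class GroupComparisonResults:
    """Results container for the measure-by-band group comparison."""

    table: pd.DataFrame
    group_a: str
    group_b: str
    alpha: float
    n_perm: int
    seed: int

    @property
    def significant(self) -> pd.DataFrame:
        return self.table[self.table["significant"]]

    def summary(self) -> str:
        lines = [
            f"Group comparison: {self.group_a} vs {self.group_b} "
            f"({self.n_perm} permutations, BH-FDR alpha={self.alpha}, "
            f"seed={self.seed})",
            f"{len(self.table)} tests, {int(self.table['significant'].sum())} "
            "significant after FDR",
            "",
        ]
        with pd.option_context("display.width", 120, "display.max_rows", 200):
            tab = self.table.copy()
            for col in ("mean_a", "mean_b", "difference", "p_perm", "p_fdr"):
                tab[col] = tab[col].map(lambda v: f"{v:.4f}")
            lines.append(tab.to_string(index=False))
        return "\n".join(lines)


def measures_to_frame(measures: list) -> pd.DataFrame:
    """Long-format DataFrame (subject_id, group_label, band, measure, value)
    from a list of :class:`~neurocoh.graph.GraphMeasures`."""
    from .graph import MEASURE_NAMES

    rows = []
    for m in measures:
        d = m.to_dict()
        for name in MEASURE_NAMES:
            rows.append({
                "subject_id": d["subject_id"], "group_label": d["group_label"],
                "band": d["band"], "measure": name, "value": d[name],
            })
    return pd.DataFrame(rows)


def compare_measures(
    measures: pd.DataFrame,
    alpha: float = 0.05,
    n_perm: int = 1000,
    seed: int = 0,
    statistic: str = "mean_diff",
) -> GroupComparisonResults:
    """Permutation + FDR comparison of every measure in every band.

    ``measures`` is the long-format frame from :func:`measures_to_frame`
    (columns subject_id, group_label, band, measure, value) with exactly two
    groups. All measure x band cells must be present and finite; FDR is
    applied jointly across the full family of tests. Fully reproducible
    given ``seed``.
    """
    from .graph import MEASURE_NAMES

    required = {"subject_id", "group_label", "band", "measure", "value"}
    if not required.issubset(measures.columns):
        raise ValueError(f"measures frame must have columns {sorted(required)}")
    groups = sorted(measures["group_label"].unique())
    if len(groups) != 2:
        raise ValueError(f"need exactly 2 groups, got {groups}")
    g_a, g_b = groups
    bands = list(dict.fromkeys(measures["band"]))
    rng = np.random.default_rng(seed)
    rows = []
    for band in bands:
        for name in MEASURE_NAMES:
            cell = measures[(measures["band"] == band) & (measures["measure"] == name)]
            a = cell.loc[cell["group_label"] == g_a, "value"].to_numpy()
            b = cell.loc[cell["group_label"] == g_b, "value"].to_numpy()
            if a.size < 2 or b.size < 2 or not (
                np.isfinite(a).all() and np.isfinite(b).all()
            ):
                raise ValueError(
                    f"missing or non-finite cell: measure={name!r}, band={band!r}"
                )
            p = permutation_test(
                a, b, n_perm=n_perm, seed=int(rng.integers(2**31)),
                statistic=statistic,
            )
            rows.append({
                "measure": name, "band": band,
                "mean_a": a.mean(), "mean_b": b.mean(),
                "difference": a.mean() - b.mean(), "p_perm": p,
            })
    table = pd.DataFrame(rows)
    p_adj, reject = fdr_bh(table["p_perm"].to_numpy(), q=alpha)
    table["p_fdr"] = p_adj
    table["significant"] = reject
    return GroupComparisonResults(
        table=table, group_a=g_a, group_b=g_b, alpha=alpha,
        n_perm=n_perm, seed=seed,
    )


def compare_clinical(clinical: pd.DataFrame) -> pd.DataFrame:
    """Variable-wise two-group comparison of the clinical covariate table.

    Continuous variables get a Welch t-test; binary variables a chi-square
    test on the 2x2 contingency table. Returns a frame with group means,
    the test used, its statistic and p-value. A zero-variance continuous
    variable raises.
    """
    if "group_label" not in clinical.columns:
        raise ValueError("clinical table must have a group_label column")
    groups = sorted(clinical["group_label"].unique())
    if len(groups) != 2:
        raise ValueError(f"need exactly 2 groups, got {groups}")
    g_a, g_b = groups
    counts = clinical["group_label"].value_counts()
    if counts.min() < 2:
        raise ValueError("need at least 2 subjects per group")
    rows = []
    for col in clinical.columns:
        if col in ("group_label", "subject_id"):
            continue
        a = clinical.loc[clinical["group_label"] == g_a, col].to_numpy(dtype=float)
        b = clinical.loc[clinical["group_label"] == g_b, col].to_numpy(dtype=float)
        if col in CLINICAL_BINARY or set(np.unique(np.concatenate([a, b]))) <= {0.0, 1.0}:
            contingency = np.array([
                [(a == 1).sum(), (a == 0).sum()],
                [(b == 1).sum(), (b == 0).sum()],
            ])
            test = "chi-square"
            if (contingency.sum(axis=0) == 0).any():
                # variable constant in the pooled sample: no difference testable
                stat_val, p = 0.0, 1.0
            else:
                res = sp_stats.chi2_contingency(contingency, correction=True)
                stat_val, p = float(res[0]), float(res[1])
        else:
            if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
                raise ValueError(f"zero-variance continuous variable {col!r}")
            t, p = sp_stats.ttest_ind(a, b, equal_var=False)
            stat_val, test = float(t), "welch-t"
        rows.append({
            "variable": col, "test": test,
            "mean_a": float(a.mean()), "mean_b": float(b.mean()),
            "statistic": stat_val, "p_value": float(p),
        })
    return pd.DataFrame(rows)
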