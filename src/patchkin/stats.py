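"""Group comparison ladder for per-patch summary statistics.

Mirrors common electrophysiology practice: Shapiro-Wilk normality gate,
then either one-way ANOVA with Bonferroni post-hoc (parametric route)
or Kruskal-Wallis with Dunn's multiple-comparison test (nonparametric
route); voltage-resolved curves are compared per potential with
Mann-Whitney tests under a family-wise correction across voltages.

The omnibus and pairwise primitives are delegated to scipy/statsmodels;
this module owns the routing, the Dunn rank test, the adjustment
policy, and the reporting shapes.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as _stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ComparisonResult",
    "VoltageComparison",
    "normality_gate",
    "compare_groups",
    "dunn_test",
    "per_voltage_compare",
    "ALPHA",
]

ALPHA = 0.05

GroupData = "dict[str, np.ndarray]"


@dataclass(frozen=True)
class ComparisonResult:
    """Omnibus plus adjusted pairwise p-values for >= 2 groups."""

    test_name: str
    omnibus_p: float
    pairwise: tuple[tuple[str, str, float], ...]
    route: str  # "parametric" | "nonparametric"
    degenerate: bool = False


@dataclass(frozen=True)
class VoltageComparison:
    voltage: float
    raw_p: float
    adjusted_p: float
    n_a: int
    n_b: int


def _as_groups(groups) -> dict[str, np.ndarray]:
    if isinstance(groups, pd.DataFrame):
        return {
            str(g): sub["value"].to_numpy(dtype=float)
            for g, sub in groups.groupby("group", sort=False)
        }
    return {str(k): np.asarray(v, dtype=float) for k, v in groups.items()}


def normality_gate(groups, alpha: float = ALPHA) -> str:
    """Choose the test route: Shapiro-Wilk on every group.

    Returns "nonparametric" if any group rejects normality at ``alpha``
    or is too small (n < 3) or degenerate (constant) to test, else
    "parametric".
    """
    gd = _as_groups(groups)
    if len(gd) < 2:
        raise ValueError("need >= 2 groups")
    for label, x in gd.items():
        if len(x) < 3:
            warnings.warn(
                f"group {label!r} has n={len(x)} < 3; "
                "falling back to the nonparametric route",
                stacklevel=2,
            )
            return "nonparametric"
        if np.ptp(x) == 0:
            warnings.warn(
                f"group {label!r} is constant; Shapiro-Wilk undefined, "
                "using the nonparametric route",
                stacklevel=2,
            )
            return "nonparametric"
        if _stats.shapiro(x).pvalue < alpha:
            return "nonparametric"
    return "parametric"


def dunn_test(
    gd: dict[str, np.ndarray], adjust: str = "bonferroni"
) -> list[tuple[str, str, float]]:
    """Dunn's rank-based post-hoc for Kruskal-Wallis, with tie correction.

    z_ij = (Rbar_i - Rbar_j) / sqrt((N(N+1)/12 - T)(1/n_i + 1/n_j)),
    T = sum(t^3 - t) / (12 (N - 1)) over tie groups; two-sided normal
    p-values adjusted across all pairs.
    """
    labels = list(gd)
    pooled = np.concatenate([gd[l] for l in labels])
    n_total = len(pooled)
    ranks = _stats.rankdata(pooled)
    mean_ranks, sizes = {}, {}
    i = 0
    for l in labels:
        n = len(gd[l])
        mean_ranks[l] = ranks[i : i + n].mean()
        sizes[l] = n
        i += n
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts)) / (12.0 * (n_total - 1))
    var_base = n_total * (n_total + 1) / 12.0 - tie_term
    pairs = list(itertools.combinations(labels, 2))
    raw = []
    for a, b in pairs:
        se = np.sqrt(var_base * (1.0 / sizes[a] + 1.0 / sizes[b]))
        if se == 0:
            raw.append(1.0)
            continue
        z = (mean_ranks[a] - mean_ranks[b]) / se
        raw.append(2.0 * _stats.norm.sf(abs(z)))
    adj = multipletests(raw, method=adjust)[1] if raw else []
    return [(a, b, float(p)) for (a, b), p in zip(pairs, adj)]


def compare_groups(
    groups,
    route: str,
    parametric_posthoc: str = "bonferroni",
    nonparametric_adjust: str = "bonferroni",
) -> ComparisonResult:
    """Omnibus + pairwise comparison along the chosen route.

    Parametric: one-way ANOVA, pairwise Welch-free t tests under
    Bonferroni (Tukey HSD available via ``parametric_posthoc="tukey"``).
    Nonparametric: Kruskal-Wallis omnibus, Dunn pairwise.
    Constant data in every group is reported as degenerate (p = 1).
    """
    gd = _as_groups(groups)
    if len(gd) < 2:
        raise ValueError("need >= 2 groups")
    arrays = list(gd.values())
    pooled = np.concatenate(arrays)
    if np.ptp(pooled) == 0:
        return ComparisonResult(
            test_name="degenerate (constant data)",
            omnibus_p=1.0,
            pairwise=(),
            route=route,
            degenerate=True,
        )
    labels = list(gd)
    pairs = list(itertools.combinations(labels, 2))
    if route == "parametric":
        omnibus = _stats.f_oneway(*arrays).pvalue
        if parametric_posthoc == "tukey":
            res = _stats.tukey_hsd(*arrays)
            pairwise = [
                (labels[i], labels[j], float(res.pvalue[i, j]))
                for i, j in itertools.combinations(range(len(labels)), 2)
            ]
            name = "one-way ANOVA + Tukey HSD"
        else:
            raw = [
                _stats.ttest_ind(gd[a], gd[b]).pvalue for a, b in pairs
            ]
            adj = multipletests(raw, method="bonferroni")[1]
            pairwise = [
                (a, b, float(p)) for (a, b), p in zip(pairs, adj)
            ]
            name = "one-way ANOVA + Bonferroni t"
    elif route == "nonparametric":
        try:
            omnibus = _stats.kruskal(*arrays).pvalue
        except ValueError:  # all values identical within the pooled sample
            omnibus = 1.0
        pairwise = dunn_test(gd, adjust=nonparametric_adjust)
        name = "Kruskal-Wallis + Dunn"
    else:
        raise ValueError(f"unknown route {route!r}")
    return ComparisonResult(
        test_name=name,
        omnibus_p=float(omnibus),
        pairwise=tuple(pairwise),
        route=route,
    )


def per_voltage_compare(
    curves: pd.DataFrame,
    pair: tuple[str, str],
    adjust: str = "holm",
    min_n: int = 3,
) -> list[VoltageComparison]:
    """Two-sided Mann-Whitney per shared voltage, corrected across voltages.

    ``curves`` has columns (group, voltage, value); the family-wise
    adjustment across voltages defaults to Holm (Sidak available).
    Voltages where either group has fewer than ``min_n`` patches are
    skipped with a warning.
    """
    a, b = pair
    da = curves[curves["group"] == a]
    db = curves[curves["group"] == b]
    shared = sorted(set(da["voltage"]) & set(db["voltage"]))
    if not shared:
        raise ValueError(f"groups {a!r} and {b!r} share no voltages")
    kept, raw = [], []
    for v in shared:
        xa = da.loc[da["voltage"] == v, "value"].to_numpy(dtype=float)
        xb = db.loc[db["voltage"] == v, "value"].to_numpy(dtype=float)
        if len(xa) < min_n or len(xb) < min_n:
            warnings.warn(
                f"skipping {v} mV: n < {min_n} in one group", stacklevel=2
            )
            continue
        if np.ptp(np.concatenate([xa, xb])) == 0:
            p = 1.0  # identical constant data: no evidence either way
        else:
            p = float(_stats.mannwhitneyu(xa, xb, alternative="two-sided").pvalue)
        kept.append((v, len(xa), len(xb)))
        raw.append(p)
    if not raw:
        raise ValueError("no voltages with enough patches to compare")
    method = {"holm": "holm", "sidak": "sidak"}[adjust]
    adj = multipletests(raw, method=method)[1]
    return [
        VoltageComparison(
            voltage=float(v), raw_p=float(r), adjusted_p=float(p),
            n_a=na, n_b=nb,
        )
        for (v, na, nb), r, p in zip(kept, raw, adj)
    ]
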