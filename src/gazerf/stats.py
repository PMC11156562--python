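"""Statistical machinery: permutation tests, FDR control, hierarchical bootstrap.

Population-level tests weight monkeys equally: the test statistic (real or
permuted) is averaged first over neurons within each monkey, then over
monkeys.  For self-consistency statistics the unit of permutation is the
fixation pair (pair partners are reassigned); for other statistics it is
the values (labels are shuffled).  Permutation p-values use the add-one
convention, p = (1 + #{permuted >= observed}) / (1 + n_permutations), so
they are valid (never exactly zero) under exchangeable nulls.

Multiple comparisons are controlled per analysis with the two-stage
Benjamini-Krieger-Yekutieli step-up procedure at FDR q (default 0.01).
Spread of population center estimates comes from a hierarchical bootstrap:
resample monkeys with replacement, then neurons within each sampled
monkey.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy import stats as sps

__all__ = [
    "PermutationSpec",
    "permutation_test",
    "bky_fdr",
    "hierarchical_bootstrap_ci",
    "rank_tests",
    "exclude_sparse_monkeys",
]


@dataclass
class PermutationSpec:
    """Declarative description of a permutation test.

    statistic: 'pearson' (pairs unit), 'mean_diff' (values unit with
    binary labels), or a callable taking the per-neuron payload arrays.
    unit: what gets permuted -- 'pairs' reassigns pair partners (the
    second member is shuffled across pairs), 'values' shuffles labels.
    tail: 'greater', 'less' or 'two'.
    """

    statistic: str | Callable = "pearson"
    unit: str = "pairs"
    n_permutations: int = 10_000
    tail: str = "greater"

    def __post_init__(self) -> None:
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")
        if self.unit not in ("pairs", "values"):
            raise ValueError(f"unknown permutation unit: {self.unit!r}")
        if self.tail not in ("greater", "less", "two"):
            raise ValueError(f"unknown tail: {self.tail!r}")


def _corr_rows(A: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pearson r between each row of A (m, n) and b (n,)."""
    Ac = A - A.mean(axis=1, keepdims=True)
    bc = b - b.mean()
    denom = np.sqrt((Ac**2).sum(axis=1) * (bc**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(denom > 0, Ac @ bc / denom, np.nan)


def permutation_test(
    spec: PermutationSpec,
    neurons: Sequence[tuple],
    monkeys: Sequence[str],
    rng: np.random.Generator | int | None = None,
) -> dict:
    """Monkey-weighted permutation test over per-neuron data.

    neurons: one payload per neuron -- for unit 'pairs' a tuple (a, b) of
    paired response arrays (a earlier member); for unit 'values' a tuple
    (values, labels).  monkeys: monkey id per neuron.  The population
    statistic is the mean of per-neuron statistics per monkey, then the
    unweighted mean over monkeys, computed identically for observed and
    permuted data.

    Returns {'p', 'observed', 'null'} with the add-one p-value for the
    requested tail.  Errors if the statistic is undefined (NaN) on more
    than 10% of permutations.
    """
    if isinstance(rng, (int, np.integer)) or rng is None:
        rng = np.random.default_rng(rng)
    monkeys = np.asarray(monkeys)
    if len(monkeys) != len(neurons):
        raise ValueError("monkeys must label each neuron")
    n_perm = spec.n_permutations
    stats_obs = np.empty(len(neurons))
    stats_perm = np.empty((n_perm, len(neurons)))
    for i, payload in enumerate(neurons):
        a, b = (np.asarray(v, float) for v in payload)
        if spec.unit == "pairs":
            if spec.statistic == "pearson":
                stats_obs[i] = _corr_rows(b[None, :], a)[0]
                B = np.stack([rng.permutation(b) for _ in range(n_perm)])
                stats_perm[:, i] = _corr_rows(B, a)
            else:
                fn = spec.statistic
                stats_obs[i] = fn(a, b)
                for k in range(n_perm):
                    stats_perm[k, i] = fn(a, rng.permutation(b))
        else:  # values: a = values, b = labels
            if spec.statistic == "mean_diff":
                lab = b.astype(bool)
                stats_obs[i] = a[lab].mean() - a[~lab].mean()
                n1 = int(lab.sum())
                P = np.stack([rng.permutation(len(a)) for _ in range(n_perm)])
                vals = a[P]
                stats_perm[:, i] = vals[:, :n1].mean(axis=1) - vals[:, n1:].mean(axis=1)
            elif spec.statistic == "pearson":
                stats_obs[i] = _corr_rows(b[None, :], a)[0]
                B = np.stack([rng.permutation(b) for _ in range(n_perm)])
                stats_perm[:, i] = _corr_rows(B, a)
            else:
                fn = spec.statistic
                stats_obs[i] = fn(a, b)
                for k in range(n_perm):
                    stats_perm[k, i] = fn(a, rng.permutation(b))
    observed = _monkey_mean(stats_obs[None, :], monkeys)[0]
    null = _monkey_mean(stats_perm, monkeys)
    bad = ~np.isfinite(null)
    if bad.mean() > 0.10:
        raise ValueError("statistic undefined on more than 10% of permutations")
    null = null[~bad]
    n_eff = len(null)
    if spec.tail == "greater":
        p = (1 + int(np.sum(null >= observed))) / (1 + n_eff)
    elif spec.tail == "less":
        p = (1 + int(np.sum(null <= observed))) / (1 + n_eff)
    else:
        p = (1 + int(np.sum(np.abs(null) >= abs(observed)))) / (1 + n_eff)
    return {"p": float(p), "observed": float(observed), "null": null}


def _monkey_mean(stats: np.ndarray, monkeys: np.ndarray) -> np.ndarray:
    """Mean over neurons per monkey, then unweighted mean over monkeys.

    stats: (n_reps, n_neurons) -> (n_reps,).
    """
    out = []
    for m in np.unique(monkeys):
        out.append(np.nanmean(stats[:, monkeys == m], axis=1))
    return np.mean(np.stack(out), axis=0)


# ---------------------------------------------------------------------------
# FDR control
# ---------------------------------------------------------------------------

def _bh_reject(p: np.ndarray, q: float) -> np.ndarray:
    """Benjamini-Hochberg step-up rejection flags at level q."""
    m = len(p)
    order = np.argsort(p, kind="stable")
    ranked = p[order]
    thresh = q * (np.arange(1, m + 1) / m)
    below = np.flatnonzero(ranked <= thresh)
    flags = np.zeros(m, bool)
    if len(below):
        flags[order[: below[-1] + 1]] = True
    return flags


def bky_fdr(pvalues: np.ndarray, q: float = 0.01) -> np.ndarray:
    """Two-stage Benjamini-Krieger-Yekutieli FDR control (step-up).

    Stage 1 runs Benjamini-Hochberg at q' = q / (1 + q) to estimate the
    number of true nulls m0 = m - r1; stage 2 reruns BH at q' * m / m0.
    Returns boolean rejection flags per hypothesis.
    """
    p = np.asarray(pvalues, float)
    if p.ndim != 1 or len(p) == 0:
        raise ValueError("pvalues must be a nonempty 1-D array")
    if np.any(~np.isfinite(p)) or np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    q1 = q / (1.0 + q)
    stage1 = _bh_reject(p, q1)
    r1 = int(stage1.sum())
    if r1 == 0:
        return np.zeros(m, bool)
    if r1 == m:
        return np.ones(m, bool)
    m0 = m - r1
    return _bh_reject(p, q1 * m / m0)


# ---------------------------------------------------------------------------
# Hierarchical bootstrap
# ---------------------------------------------------------------------------

def hierarchical_bootstrap_ci(
    groups: Sequence[np.ndarray],
    n_boot: int = 1000,
    level: float = 0.95,
    center: str = "mean",
    rng: np.random.Generator | int | None = None,
) -> dict:
    """Center and uncertainty of a monkey-weighted population estimate.

    groups: per-monkey arrays of per-neuron values.  The center is the
    mean (or median) over neurons per monkey, then over monkeys.  Each
    bootstrap replicate resamples monkeys with replacement, then neurons
    within each sampled monkey.  Returns {'center', 'ci', 'sem', 'boot'}.
    """
    if isinstance(rng, (int, np.integer)) or rng is None:
        rng = np.random.default_rng(rng)
    groups = [np.asarray(g, float) for g in groups]
    if len(groups) == 0 or any(len(g) == 0 for g in groups):
        raise ValueError("each monkey must contribute at least one value")
    agg = np.mean if center == "mean" else np.median
    point = float(agg([agg(g) for g in groups]))
    nm = len(groups)
    sizes = {len(g) for g in groups}
    if len(sizes) == 1:
        k = sizes.pop()
        V = np.stack(groups)  # (nm, k)
        mid = rng.integers(0, nm, size=(n_boot, nm))
        nid = rng.integers(0, k, size=(n_boot, nm, k))
        sampled = V[mid[..., None], nid]
        boots = agg(agg(sampled, axis=2), axis=1)
    else:
        boots = np.empty(n_boot)
        for t in range(n_boot):
            mids = rng.integers(0, nm, nm)
            per = [agg(rng.choice(groups[m], len(groups[m]), replace=True)) for m in mids]
            boots[t] = agg(per)
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(boots, [alpha, 1.0 - alpha])
    return {
        "center": point,
        "ci": (float(lo), float(hi)),
        "sem": float(np.std(boots)),
        "boot": boots,
    }


# ---------------------------------------------------------------------------
# Rank tests and inclusion rules
# ---------------------------------------------------------------------------

def rank_tests(
    x: np.ndarray,
    y: np.ndarray,
    paired: bool = False,
    tail: str = "two-sided",
) -> dict:
    """Mann-Whitney U (unpaired) or Wilcoxon signed-rank (paired) p-value.

    Exact null distributions for small samples without ties, normal
    approximation otherwise (scipy's 'auto' policy).  All-tied paired
    differences give an invalid result instead of an error.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if paired:
        if len(x) != len(y) or len(x) < 2:
            raise ValueError("paired test needs >= 2 pairs")
        d = x - y
        if np.all(d == 0):
            return {"p": float("nan"), "statistic": float("nan"), "valid": False}
        res = sps.wilcoxon(x, y, alternative=tail, method="auto")
    else:
        if len(x) < 2 or len(y) < 2:
            raise ValueError("unpaired test needs >= 2 observations per group")
        res = sps.mannwhitneyu(x, y, alternative=tail, method="auto")
    return {"p": float(res.pvalue), "statistic": float(res.statistic), "valid": True}


def exclude_sparse_monkeys(counts: dict[str, dict[str, int]], frac: float = 0.05) -> dict:
    """Per-region inclusion flags for monkeys contributing few neurons.

    counts: region -> monkey -> neuron count.  A monkey is excluded from
    a region when its count is below ``frac`` times the median count
    across monkeys in that region.
    """
    flags: dict[str, dict[str, bool]] = {}
    for region, per_monkey in counts.items():
        med = float(np.median(list(per_monkey.values())))
        flags[region] = {m: c >= frac * med for m, c in per_monkey.items()}
    return flags
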