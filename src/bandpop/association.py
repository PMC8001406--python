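"""Association statistics: Mantel tests, trait correlation/regression,
group comparisons and stepwise marker-trait regression.

The stepwise multiple regression (SMRA) treats each polymorphic band
column as a candidate predictor of a genotype-mean trait and applies the
SPSS-style probability-of-F rules: at each step the candidate with the
smallest partial-F p-value enters if p <= p_enter, then any included
predictor with p >= p_remove leaves, until nothing changes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from skbio import DistanceMatrix

from .io import BandMatrix, TraitTable

__all__ = [
    "MantelResult",
    "mantel",
    "trait_correlations",
    "kruskal_wallis",
    "anova_tukey",
    "compact_letters",
    "StepwiseReport",
    "smra",
    "fold_range",
]


# ---------------------------------------------------------------------------
# Mantel test
# ---------------------------------------------------------------------------


@dataclass
class MantelResult:
    r: float
    p_value: float
    n_permutations: int
    tail: str
    n_items: int


def mantel(
    d1: DistanceMatrix,
    d2: DistanceMatrix,
    n_perm: int = 999,
    seed: int | np.random.Generator = 0,
    tail: str = "upper",
) -> MantelResult:
    """Mantel correlation between two distance matrices over the same
    items.

    r is the Pearson correlation over the N(N-1)/2 off-diagonal pairs;
    the null distribution permutes rows and columns of ``d2``
    simultaneously.  ``tail`` is ``"upper"`` (positive association) or
    ``"two-sided"``.  The observed configuration is counted in p.
    """
    if set(d1.ids) != set(d2.ids):
        raise ValueError("distance matrices have different labels")
    if tail not in ("upper", "two-sided"):
        raise ValueError(f"unknown tail {tail!r}")
    n = d1.shape[0]
    if n < 4:
        raise ValueError("Mantel test needs >= 4 items")
    order = [list(d2.ids).index(i) for i in d1.ids]
    m1 = d1.data
    m2 = d2.data[np.ix_(order, order)]
    iu = np.triu_indices(n, 1)
    v1 = m1[iu]
    r_obs = float(np.corrcoef(v1, m2[iu])[0, 1])

    rng = np.random.default_rng(seed)
    hits = 1
    for _ in range(n_perm):
        perm = rng.permutation(n)
        r_p = float(np.corrcoef(v1, m2[np.ix_(perm, perm)][iu])[0, 1])
        if tail == "upper":
            hits += r_p >= r_obs - 1e-12
        else:
            hits += abs(r_p) >= abs(r_obs) - 1e-12
    return MantelResult(r=r_obs, p_value=hits / (n_perm + 1),
                        n_permutations=n_perm, tail=tail, n_items=n)


# ---------------------------------------------------------------------------
# Trait correlations and group tests
# ---------------------------------------------------------------------------


def trait_correlations(tt: TraitTable, ci: float = 0.95) -> pd.DataFrame:
    """Pairwise Pearson r, r^2 with confidence interval, and the simple
    OLS fit (slope/intercept) per trait pair, on genotype means."""
    means = tt.genotype_means()
    if means.shape[0] < 3:
        raise ValueError("need >= 3 genotypes")
    constant = means.columns[means.std(axis=0, ddof=1) == 0]
    if len(constant):
        raise ValueError(f"trait {constant[0]!r} is constant")
    rows = []
    traits = list(means.columns)
    for i, ta in enumerate(traits):
        for tb in traits[i + 1:]:
            x, y = means[ta].to_numpy(), means[tb].to_numpy()
            res = stats.pearsonr(x, y)
            lo, hi = res.confidence_interval(confidence_level=ci)
            fit = stats.linregress(x, y)
            rows.append({
                "trait_x": ta, "trait_y": tb,
                "r": res.statistic, "r2": res.statistic ** 2,
                "p": res.pvalue, "r_ci_low": lo, "r_ci_high": hi,
                "slope": fit.slope, "intercept": fit.intercept,
            })
    return pd.DataFrame(rows)


def kruskal_wallis(values_by_group: dict[str, np.ndarray]) -> tuple[float, float]:
    """Kruskal-Wallis H (tie-corrected) and its chi-square p-value.

    All-identical data yields (H, p) = (0, 1).
    """
    groups = [np.asarray(v, dtype=float) for v in values_by_group.values()]
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    if sum(len(g) for g in groups) < 2:
        raise ValueError("need >= 2 observations")
    flat = np.concatenate(groups)
    if np.all(flat == flat[0]):
        return 0.0, 1.0
    h, p = stats.kruskal(*groups)
    return float(h), float(p)


def compact_letters(labels: list[str], significant: set[frozenset]) -> dict[str, str]:
    """Insert-and-absorb compact letter display.

    ``significant`` holds the pairs (as 2-element frozensets) declared
    significantly different.  Groups sharing a letter are not
    significantly different.
    """
    letter_sets: list[set[str]] = [set(labels)]
    for pair in significant:
        a, b = sorted(pair)
        for s in list(letter_sets):
            if a in s and b in s:
                letter_sets.remove(s)
                for drop in (a, b):
                    new = s - {drop}
                    # absorb: keep only maximal sets
                    if new and not any(new <= other for other in letter_sets):
                        letter_sets.append(new)
    letter_sets.sort(key=lambda s: sorted(labels).index(min(s, key=labels.index))
                     if s else 0)
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    out: dict[str, list[str]] = {l: [] for l in labels}
    for letter, s in zip(alphabet, letter_sets):
        for l in labels:
            if l in s:
                out[l].append(letter)
    return {l: "".join(v) for l, v in out.items()}


def anova_tukey(
    values_by_group: dict[str, np.ndarray], alpha: float = 0.05
) -> tuple[pd.DataFrame, pd.DataFrame, dict[str, str]]:
    """One-way ANOVA, Tukey HSD pairwise comparisons and a compact letter
    display (groups sharing a letter are not significantly different)."""
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    labels = list(values_by_group)
    groups = [np.asarray(values_by_group[l], dtype=float) for l in labels]
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    if any(len(g) < 2 for g in groups):
        raise ValueError("each group needs >= 2 replicates")
    if all(np.var(g) == 0 for g in groups):
        raise ValueError("zero within-group variance everywhere")

    f, p = stats.f_oneway(*groups)
    n = sum(len(g) for g in groups)
    anova = pd.DataFrame([
        {"source": "between", "df": len(groups) - 1, "F": f, "p": p},
        {"source": "within", "df": n - len(groups), "F": np.nan, "p": np.nan},
    ])

    flat = np.concatenate(groups)
    lab = np.concatenate([[l] * len(g) for l, g in zip(labels, groups)])
    tk = pairwise_tukeyhsd(flat, lab, alpha=alpha)
    pairs = pd.DataFrame(tk.summary().data[1:], columns=tk.summary().data[0])
    significant = {
        frozenset((row["group1"], row["group2"]))
        for _, row in pairs.iterrows() if bool(row["reject"])
    }
    letters = compact_letters(labels, significant)
    return anova, pairs, letters


# ---------------------------------------------------------------------------
# Stepwise marker-trait regression
# ---------------------------------------------------------------------------


@dataclass
class StepwiseReport:
    """Ordered selection steps of a stepwise marker-trait regression."""

    trait: str
    steps: pd.DataFrame = field(default_factory=pd.DataFrame)
    p_enter: float = 0.045
    p_remove: float = 0.099

    @property
    def selected(self) -> list[str]:
        if self.steps.empty:
            return []
        included: list[str] = []
        for _, row in self.steps.iterrows():
            if row["action"] == "enter":
                included.append(row["allele"])
            else:
                included.remove(row["allele"])
        return included

    @property
    def final_r2(self) -> float:
        return float(self.steps["R2"].iloc[-1]) if len(self.steps) else 0.0


def _ols_stats(y: np.ndarray, X: np.ndarray):
    """(coef, t, p, r2, sse) for y ~ [1, X]."""
    n = len(y)
    design = np.column_stack([np.ones(n), X])
    k = design.shape[1]
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ coef
    sse = float(resid @ resid)
    sst = float(((y - y.mean()) ** 2).sum())
    df = n - k
    if df <= 0 or sse <= 0:
        return coef, np.full(k, np.inf), np.zeros(k), 1.0, sse
    mse = sse / df
    xtx_inv = np.linalg.pinv(design.T @ design)
    se = np.sqrt(np.clip(np.diag(xtx_inv) * mse, 1e-300, None))
    t = coef / se
    p = 2.0 * stats.t.sf(np.abs(t), df)
    r2 = 1.0 - sse / sst if sst > 0 else 0.0
    return coef, t, p, r2, sse


def smra(
    tt: TraitTable,
    bm: BandMatrix,
    trait: str,
    p_enter: float = 0.045,
    p_remove: float = 0.099,
    primer_classes: dict[str, str] | None = None,
    max_steps: int = 100,
) -> StepwiseReport:
    """Forward-entry / backward-removal stepwise regression of a trait on
    individual band (allele) scores.

    Entry: the candidate with the smallest partial-F p-value joins if
    p <= p_enter.  Removal: any included allele with p >= p_remove
    leaves.  ``p_enter < p_remove`` is enforced to prevent cycling.
    Reported per step: multiple R, R^2, R^2 change and F change at the
    step, plus the standardized beta, t and p of each entered allele in
    the FINAL model (the at-entry t/p are also kept as ``t_at_step`` /
    ``p_at_step``).
    """
    if trait not in tt.traits:
        raise ValueError(f"trait {trait!r} not in the trait table")
    if p_enter >= p_remove:
        raise ValueError("p_enter must be < p_remove (prevents cycling)")

    classes = primer_classes or bm.primer_classes or {}
    means = tt.genotype_means()[trait]
    genos = [g for g in bm.genotype_ids if g in means.index]
    if len(genos) < 5:
        raise ValueError("too few genotypes with trait data")
    sub = bm.subset(genos)
    y = means.loc[genos].to_numpy(dtype=float)

    X = np.where(np.isnan(sub.scores), 0.0, sub.scores)
    variable = X.std(axis=0) > 0
    cand_idx = np.flatnonzero(variable)
    if cand_idx.size == 0:
        raise ValueError("no alleles with nonzero variance")
    band_ids = sub.band_ids

    included: list[int] = []
    rows = []
    r2_prev = 0.0
    n = len(y)

    for _ in range(max_steps):
        changed = False
        # forward step: best candidate by partial-F p-value
        best = None
        for j in cand_idx:
            if j in included:
                continue
            cols = included + [int(j)]
            _, t, p, r2, _ = _ols_stats(y, X[:, cols])
            p_j = p[-1]
            if best is None or p_j < best[1] - 1e-15:
                best = (int(j), float(p_j), float(r2))
        if best is not None and best[1] <= p_enter:
            j, p_j, r2 = best
            df2 = n - (len(included) + 2)
            f_change = ((r2 - r2_prev) / 1) / ((1 - r2) / df2) if r2 < 1 else np.inf
            included.append(j)
            cols = included
            _, t, p, r2_now, _ = _ols_stats(y, X[:, cols])
            rows.append({
                "action": "enter", "allele": band_ids[j],
                "marker_class": classes.get(sub.primer_of_band[band_ids[j]], "All"),
                "R": np.sqrt(r2_now), "R2": r2_now,
                "R2_change": r2_now - r2_prev, "F_change": f_change,
                "t_at_step": t[-1], "p_at_step": p[-1],
            })
            r2_prev = r2_now
            changed = True

        # backward step: drop anything whose p has drifted above p_remove
        while len(included) > 0:
            _, t, p, r2, _ = _ols_stats(y, X[:, included])
            worst = int(np.argmax(p[1:]))
            if p[1 + worst] < p_remove:
                break
            j = included.pop(worst)
            _, _, _, r2_after, _ = _ols_stats(y, X[:, included]) if included else (
                None, None, None, 0.0, None)
            rows.append({
                "action": "remove", "allele": band_ids[j],
                "marker_class": classes.get(sub.primer_of_band[band_ids[j]], "All"),
                "R": np.sqrt(r2_after), "R2": r2_after,
                "R2_change": r2_after - r2_prev, "F_change": np.nan,
                "t_at_step": np.nan, "p_at_step": np.nan,
            })
            r2_prev = r2_after
            changed = True
        if not changed:
            break

    steps = pd.DataFrame(rows)
    # final-model statistics for the alleles still included
    if included:
        coef, t, p, r2, _ = _ols_stats(y, X[:, included])
        sd_y = y.std(ddof=1)
        beta_std = {
            band_ids[j]: coef[1 + a] * X[:, j].std(ddof=1) / sd_y
            for a, j in enumerate(included)
        }
        t_fin = {band_ids[j]: t[1 + a] for a, j in enumerate(included)}
        p_fin = {band_ids[j]: p[1 + a] for a, j in enumerate(included)}
        if len(steps):
            steps["beta_final"] = steps["allele"].map(beta_std)
            steps["t_final"] = steps["allele"].map(t_fin)
            steps["p_final"] = steps["allele"].map(p_fin)
    return StepwiseReport(trait=trait, steps=steps,
                          p_enter=p_enter, p_remove=p_remove)


def fold_range(values: np.ndarray) -> tuple[float, float, float]:
    """(min, max, fold = max/min) of genotype-level values; min must be > 0."""
    v = np.asarray(values, dtype=float)
    lo, hi = float(v.min()), float(v.max())
    if lo <= 0:
        raise ValueError("fold range undefined: minimum is <= 0")
    return lo, hi, hi / lo
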