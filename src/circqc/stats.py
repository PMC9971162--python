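"""Per-pair enrichment contrasts between not-depleted and depleted
circRNAs.

Binary factors are tested with the two-tailed Fisher exact test (odds
ratio from the 2×2 cross product, Haldane +0.5 only for reporting a
finite OR when a cell is empty — the p-value is always the uncorrected
exact test).  Quantitative factors use the one-sided Wilcoxon rank-sum
test with the rank-biserial-style effect size r = |Z|/√N and a seeded
percentile-bootstrap 95% CI.  P-values are Benjamini–Hochberg adjusted
*within each factor's family across sample pairs*.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

NOT_DEPLETED = "not-depleted"
DEPLETED = "depleted"


@dataclass
class FactorTestResult:
    pair_id: str
    factor: str
    test: str                      # "FET" | "WRST"
    direction: str                 # "two-sided" | "greater" | "less"
    table: tuple = ()              # 2×2 counts (FET) or (n_not_depleted, n_depleted)
    odds_ratio: float = np.nan
    effect_size_r: float = np.nan
    ci95_low: float = np.nan
    ci95_high: float = np.nan
    p: float = np.nan
    fdr: float = np.nan
    note: str = ""
    extra: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = {k: getattr(self, k) for k in
             ("pair_id", "factor", "test", "direction", "odds_ratio",
              "effect_size_r", "ci95_low", "ci95_high", "p", "fdr", "note")}
        d["table"] = ";".join(map(str, np.ravel(self.table)))
        d.update(self.extra)
        return d


def _classes(depletion_class: pd.Series) -> pd.Series:
    cls = depletion_class[depletion_class.isin([NOT_DEPLETED, DEPLETED])]
    if not (cls == NOT_DEPLETED).any():
        raise ValueError("no candidates in class 'not-depleted'")
    if not (cls == DEPLETED).any():
        raise ValueError("no candidates in class 'depleted'")
    return cls


# ---------------------------------------------------------------------------
# Fisher exact test
# ---------------------------------------------------------------------------

def fet_from_table(table: np.ndarray) -> tuple[float, float, str]:
    """(odds_ratio, two-tailed p, note) for a 2×2 table [[a,b],[c,d]].

    OR is the sample cross-product (a·d)/(b·c); with an empty cell the
    Haldane +0.5 correction is applied to the OR (flagged) while the
    p-value remains the uncorrected exact test.
    """
    t = np.asarray(table, dtype=float)
    a, b = t[0]
    c, d = t[1]
    note = ""
    if min(a, b, c, d) == 0:
        note = "haldane"
        orr = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
    else:
        orr = (a * d) / (b * c)
    _, p = sps.fisher_exact(np.asarray(table), alternative="two-sided")
    return float(orr), float(p), note


def fet_enrichment(depletion_class: pd.Series, factor: pd.Series,
                   pair_id: str = "", factor_name: str = "") -> FactorTestResult:
    """Two-tailed FET of a binary factor against depletion class.

    Table rows are factor+/factor−, columns not-depleted/depleted, so
    OR > 1 means the factor is enriched among not-depleted circRNAs.
    Candidates with a missing factor value are dropped pairwise.
    """
    cls = _classes(depletion_class)
    f = factor.reindex(cls.index)
    keep = f.notna()
    cls, f = cls[keep], f[keep].astype(bool)
    nd = cls == NOT_DEPLETED
    a = int((f & nd).sum())
    b = int((f & ~nd).sum())
    c = int((~f & nd).sum())
    d = int((~f & ~nd).sum())
    orr, p, note = fet_from_table([[a, b], [c, d]])
    se = np.sqrt(sum(1.0 / max(x, 0.5) for x in (a, b, c, d)))
    lo, hi = np.exp(np.log(orr) - 1.96 * se), np.exp(np.log(orr) + 1.96 * se)
    return FactorTestResult(pair_id, factor_name or factor.name or "factor", "FET",
                            "two-sided", ((a, b), (c, d)), odds_ratio=orr,
                            ci95_low=float(lo), ci95_high=float(hi), p=p, note=note)


# ---------------------------------------------------------------------------
# Wilcoxon rank-sum test
# ---------------------------------------------------------------------------

def _rank_sum_z(x: np.ndarray, y: np.ndarray, alternative: str) -> tuple[float, float]:
    """(U of x, Z) with tie correction and 0.5 continuity correction."""
    n1, n2 = len(x), len(y)
    ranks = sps.rankdata(np.concatenate([x, y]))
    r1 = ranks[:n1].sum()
    u1 = r1 - n1 * (n1 + 1) / 2
    mu = n1 * n2 / 2
    n = n1 + n2
    _, tie_counts = np.unique(np.concatenate([x, y]), return_counts=True)
    tie_term = ((tie_counts ** 3 - tie_counts).sum()) / (n * (n - 1)) if n > 1 else 0.0
    sigma2 = n1 * n2 / 12 * (n + 1 - tie_term)
    if sigma2 <= 0:
        return u1, 0.0
    sigma = np.sqrt(sigma2)
    if alternative == "greater":
        z = (u1 - mu - 0.5) / sigma
    elif alternative == "less":
        z = (u1 - mu + 0.5) / sigma
    else:
        z = (u1 - mu - 0.5 * np.sign(u1 - mu)) / sigma
    return u1, float(z)


def rank_sum_p(x, y, alternative: str = "greater", exact_max_n: int = 25) -> float:
    """One- or two-sided Wilcoxon rank-sum p; exact enumeration when both
    groups are small and tie-free, tie-corrected normal approximation
    with continuity correction otherwise."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    both_small = len(x) <= exact_max_n and len(y) <= exact_max_n
    no_ties = len(np.unique(np.concatenate([x, y]))) == len(x) + len(y)
    method = "exact" if (both_small and no_ties) else "asymptotic"
    if method == "exact":
        return float(sps.mannwhitneyu(x, y, alternative=alternative, method="exact").pvalue)
    _, z = _rank_sum_z(x, y, alternative)
    if alternative == "two-sided":
        return float(2 * sps.norm.sf(abs(z)))
    return float(sps.norm.sf(z))


def wilcoxon_effect_size(x, y) -> float:
    """r = |Z|/√N, the effect size reported by rstatix::wilcox_effsize."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    _, z = _rank_sum_z(x, y, "two-sided")
    return float(abs(z) / np.sqrt(len(x) + len(y)))


def wrst_enrichment(depletion_class: pd.Series, factor: pd.Series,
                    direction: str = "greater", pair_id: str = "",
                    factor_name: str = "", n_boot: int = 1000,
                    seed: int = 0, exact_max_n: int = 25) -> FactorTestResult:
    """One-sided WRST of a quantitative factor, not-depleted vs depleted.

    ``direction='greater'`` tests whether not-depleted circRNAs have the
    larger values.  Effect size r = |Z|/√N with a seeded percentile
    bootstrap 95% CI.  All-tied data yield p = 0.5 (one-sided), r = 0
    and a warning.
    """
    cls = _classes(depletion_class)
    f = factor.reindex(cls.index)
    keep = f.notna()
    cls, f = cls[keep], f[keep].astype(float)
    x = f[cls == NOT_DEPLETED].to_numpy()
    y = f[cls == DEPLETED].to_numpy()
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both depletion classes must be nonempty after dropping missing values")
    name = factor_name or factor.name or "factor"
    if np.unique(np.concatenate([x, y])).size == 1:
        warnings.warn(f"{name}: all values tied across both groups", stacklevel=2)
        p = 0.5 if direction in ("greater", "less") else 1.0
        return FactorTestResult(pair_id, name, "WRST", direction, (len(x), len(y)),
                                effect_size_r=0.0, p=p, note="all-tied")
    p = rank_sum_p(x, y, direction, exact_max_n)
    r = wilcoxon_effect_size(x, y)
    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    for i in range(n_boot):
        bx = rng.choice(x, len(x), replace=True)
        by = rng.choice(y, len(y), replace=True)
        boots[i] = wilcoxon_effect_size(bx, by)
    lo, hi = np.percentile(boots, [2.5, 97.5])
    return FactorTestResult(pair_id, name, "WRST", direction, (len(x), len(y)),
                            effect_size_r=r, ci95_low=float(lo), ci95_high=float(hi), p=p)


# ---------------------------------------------------------------------------
# multiple testing, summaries
# ---------------------------------------------------------------------------

def bh_adjust_array(p: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted values for one family."""
    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def bh_adjust(results: pd.DataFrame, family: str = "factor") -> pd.DataFrame:
    """Add an ``fdr`` column, adjusting within each factor's family of
    tests across sample pairs (set ``family=None`` for one global
    family)."""
    out = results.copy()
    if family is None:
        out["fdr"] = bh_adjust_array(out["p"].to_numpy())
    else:
        out["fdr"] = (out.groupby(family, group_keys=False)["p"]
                      .transform(lambda s: bh_adjust_array(s.to_numpy())))
    return out


def trend_table(depletion_class: pd.Series, factor: pd.Series,
                bins: int | list | None = None, pair_id: str = "",
                factor_name: str = "") -> pd.DataFrame:
    """Percentage of not-depleted circRNAs per factor level (or bin),
    with Spearman (and Pearson) correlation between level and
    percentage."""
    cls = _classes(depletion_class)
    f = factor.reindex(cls.index)
    keep = f.notna()
    cls, f = cls[keep], f[keep]
    if bins is not None:
        f = pd.cut(f.astype(float), bins)
        level_order = f.cat.categories
        level_value = [iv.mid for iv in level_order]
    else:
        level_order = sorted(f.unique())
        level_value = [float(v) for v in level_order]
    rows = []
    for lev, val in zip(level_order, level_value):
        sub = cls[f == lev]
        if not len(sub):
            continue
        rows.append({"pair_id": pair_id, "factor": factor_name or factor.name,
                     "level": str(lev), "level_value": val, "n_candidates": len(sub),
                     "pct_not_depleted": 100.0 * (sub == NOT_DEPLETED).mean()})
    table = pd.DataFrame(rows)
    if len(table) >= 2:
        rho, _ = sps.spearmanr(table["level_value"], table["pct_not_depleted"])
        pear, _ = sps.pearsonr(table["level_value"], table["pct_not_depleted"])
    else:
        rho = pear = np.nan
    table["spearman"] = rho
    table["pearson"] = pear
    return table


def significance_summary(results: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Per factor: number of sample pairs passing FDR < alpha with a
    consistent direction, and the 'important' flag (passes in *all*
    pairs).  Direction consistency means OR on the same side of 1 (FET)
    or the same tested direction (WRST) in every significant pair."""
    rows = []
    for factor, grp in results.groupby("factor"):
        sig = grp[grp["fdr"] < alpha]
        if len(sig) and sig["test"].iloc[0] == "FET":
            sides = np.sign(np.log(sig["odds_ratio"].astype(float)))
            consistent = len(set(sides[sides != 0])) <= 1
        else:
            consistent = sig["direction"].nunique() <= 1
        n_pass = len(sig) if consistent else 0
        rows.append({"factor": factor, "n_pairs": grp["pair_id"].nunique(),
                     "n_pass": n_pass,
                     "important": bool(n_pass == grp["pair_id"].nunique() and n_pass > 0
                                       and alpha > 0)})
    return pd.DataFrame(rows).sort_values("factor").reset_index(drop=True)


def labelset_enrichment(depletion_class: pd.Series, label: set[str] | pd.Series,
                        pair_id: str = "", label_name: str = "label",
                        ) -> FactorTestResult | None:
    """FET of external label membership (validated / database-specific /
    multi-replicate sets) against depletion class, with per-class
    membership percentages.  Degenerate label vectors (all or none
    labeled) skip the test with a warning."""
    cls = _classes(depletion_class)
    if isinstance(label, (set, frozenset)):
        member = pd.Series(cls.index.isin(label), index=cls.index)
    else:
        member = label.reindex(cls.index).fillna(False).astype(bool)
    if member.all() or not member.any():
        warnings.warn(f"{label_name}: degenerate membership (all or none); test skipped",
                      stacklevel=2)
        return None
    res = fet_enrichment(cls, member, pair_id, label_name)
    nd = cls == NOT_DEPLETED
    res.extra["pct_labeled_not_depleted"] = 100.0 * member[nd].mean()
    res.extra["pct_labeled_depleted"] = 100.0 * member[~nd].mean()
    return res


def factor_count_stratification(n_supporting: pd.Series, label: set[str] | pd.Series,
                                max_count: int = 7) -> pd.DataFrame:
    """For each supporting-factor count k: percentage of candidates with
    exactly k (and with ≥ k) factors that belong to the label set."""
    if isinstance(label, (set, frozenset)):
        member = pd.Series(n_supporting.index.isin(label), index=n_supporting.index)
    else:
        member = label.reindex(n_supporting.index).fillna(False).astype(bool)
    rows = []
    for k in range(max_count + 1):
        eq = n_supporting == k
        ge = n_supporting >= k
        rows.append({
            "n_supporting_factors": k,
            "n_eq": int(eq.sum()),
            "pct_labeled_eq": 100.0 * member[eq].mean() if eq.any() else np.nan,
            "n_ge": int(ge.sum()),
            "pct_labeled_ge": 100.0 * member[ge].mean() if ge.any() else np.nan,
        })
    return pd.DataFrame(rows)
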