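"""Binomial GLM of depletion class on the eight reliability factors,
with an RCVE importance decomposition.

The response y is 1 for a not-depleted circRNA and 0 for a depleted
one.  The full model ``y ~ f1 + … + f8`` is fit by maximum likelihood;
for each factor a reduced model without that factor is refit **on the
identical candidate subset**, and the factor's relative contribution to
variability explained is

    RCVE = (r²_all − r²_reduced) / r²_all,

using McFadden's pseudo-r² (1 − ll/ll₀) by default, which keeps RCVE in
[0, 1] for nested likelihood-based fits.  Factors are ranked per sample
pair by descending RCVE (ties mid-ranked) and averaged across pairs.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import rankdata

logger = logging.getLogger(__name__)

DEFAULT_FACTORS = ["bsj_read_count", "multi_tool", "full_length", "n_samples",
                   "both_annotated", "same_isoform", "both_AS",
                   "n_functional_features"]

PSEUDO_R2_KINDS = ("mcfadden", "coxsnell", "nagelkerke", "tjur")


def _loglike(y: np.ndarray, p: np.ndarray) -> float:
    eps = 1e-12
    p = np.clip(p, eps, 1 - eps)
    return float(np.sum(y * np.log(p) + (1 - y) * np.log1p(-p)))


def pseudo_r_squared(y: np.ndarray, p: np.ndarray, kind: str = "mcfadden") -> float:
    """Pseudo-r² of a fitted binary model from its predicted probabilities."""
    y = np.asarray(y, dtype=float)
    n = len(y)
    pbar = y.mean()
    ll = _loglike(y, p)
    ll0 = _loglike(y, np.full(n, pbar))
    if kind == "mcfadden":
        return 1.0 - ll / ll0 if ll0 != 0 else 0.0
    if kind == "coxsnell":
        return 1.0 - np.exp(2.0 * (ll0 - ll) / n)
    if kind == "nagelkerke":
        cs = 1.0 - np.exp(2.0 * (ll0 - ll) / n)
        return cs / (1.0 - np.exp(2.0 * ll0 / n))
    if kind == "tjur":
        return float(p[y == 1].mean() - p[y == 0].mean())
    raise ValueError(f"unknown pseudo-r² kind {kind!r}; choose from {PSEUDO_R2_KINDS}")


def _fit_logistic(y: np.ndarray, X: pd.DataFrame, maxiter: int,
                  ridge_on_separation: float) -> tuple[pd.Series, np.ndarray, dict]:
    """ML logistic fit with intercept; tiny-ridge refit on separation.

    Returns (params, fitted probabilities, diagnostics).
    """
    Xc = sm.add_constant(X, has_constant="add")
    diag = {"separation": False, "converged": True}
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        try:
            res = sm.GLM(y, Xc, family=sm.families.Binomial()).fit(maxiter=maxiter)
            params = res.params
            fitted = np.asarray(res.fittedvalues)
            diag["converged"] = bool(res.converged)
            diag["bse"] = res.bse
            diag["pvalues"] = res.pvalues
            sep = any("PerfectSeparation" in type(w.message).__name__ or
                      "separation" in str(w.message).lower() for w in caught)
            if sep or not np.all(np.isfinite(params)) or np.abs(params).max() > 1e3:
                raise ValueError("separation suspected")
        except Exception:
            diag["separation"] = True
            res = sm.GLM(y, Xc, family=sm.families.Binomial()).fit_regularized(
                alpha=ridge_on_separation, L1_wt=0.0, maxiter=maxiter)
            params = pd.Series(np.asarray(res.params), index=Xc.columns)
            eta = Xc.to_numpy() @ params.to_numpy()
            fitted = 1.0 / (1.0 + np.exp(-eta))
            diag["bse"] = pd.Series(np.nan, index=Xc.columns)
            diag["pvalues"] = pd.Series(np.nan, index=Xc.columns)
    if not diag["converged"]:
        raise RuntimeError("logistic fit did not converge; inspect the factor matrix")
    return params, fitted, diag


class CircReliabilityModel:
    """Logistic model of circRNA depletion class on reliability factors.

    Built from a merged quantification + factor table; ``fit`` returns a
    :class:`CircReliabilityResults` carrying coefficient estimates,
    pseudo-r², per-factor RCVE and ranks.
    """

    def __init__(self, endog: pd.Series, exog: pd.DataFrame, pair_id: str = ""):
        if endog.nunique() < 2:
            raise ValueError("response needs both classes present")
        keep = exog.notna().all(axis=1) & endog.notna()
        dropped = int((~keep).sum())
        if dropped:
            logger.info("dropping %d candidates with missing factor values (listwise)",
                        dropped)
        exog = exog.loc[keep].astype(float)
        constant = [c for c in exog.columns if exog[c].nunique() <= 1]
        if constant:
            warnings.warn(f"dropping constant factor column(s): {constant}", stacklevel=2)
            exog = exog.drop(columns=constant)
        self.endog = endog.loc[keep].astype(int)
        self.exog = exog
        self.pair_id = pair_id

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, factors: list[str] | None = None,
                       response: str = "depletion_class",
                       pair_id: str = "") -> "CircReliabilityModel":
        """Build from a table with a depletion-class (or 0/1) response
        column and one column per factor (default: the eight standard
        factors).  Excluded candidates are dropped."""
        factors = factors or [f for f in DEFAULT_FACTORS if f in df.columns]
        missing = [f for f in factors if f not in df.columns]
        if missing:
            raise ValueError(f"factor columns missing from table: {missing}")
        resp = df[response]
        if resp.dtype == object:
            keep = resp.isin(["not-depleted", "depleted"])
            df = df.loc[keep]
            y = (df[response] == "not-depleted").astype(int)
        else:
            y = resp.astype(int)
        return cls(y, df[factors], pair_id=pair_id)

    def fit(self, pseudo_r2: str = "mcfadden", maxiter: int = 100,
            ridge_on_separation: float = 1e-4,
            rcve_tolerance: float = 1e-8) -> "CircReliabilityResults":
        y = self.endog.to_numpy()
        params, fitted, diag = _fit_logistic(y, self.exog, maxiter, ridge_on_separation)
        r2_all = pseudo_r_squared(y, fitted, pseudo_r2)
        ll_all = _loglike(y, fitted)
        rows = []
        if r2_all == 0:
            warnings.warn("full-model pseudo-r² is 0; RCVE undefined", stacklevel=2)
        for factor in self.exog.columns:
            Xr = self.exog.drop(columns=[factor])
            _, fr, dr = _fit_logistic(y, Xr, maxiter, ridge_on_separation)
            r2_red = pseudo_r_squared(y, fr, pseudo_r2)
            ll_red = _loglike(y, fr)
            if ll_red > ll_all + 1e-6:
                warnings.warn(f"reduced model for {factor} out-scored the full model; "
                              "check convergence", stacklevel=2)
            if r2_all != 0:
                rcve = (r2_all - r2_red) / r2_all
                clipped = False
                if rcve < 0:
                    if rcve < -max(rcve_tolerance, 1e-3):
                        warnings.warn(f"RCVE for {factor} is {rcve:.3g} < 0", stacklevel=2)
                    rcve, clipped = 0.0, True
            else:
                rcve, clipped = np.nan, False
            rows.append({"factor": factor, "ll_reduced": ll_red,
                         "r2_reduced": r2_red, "rcve": rcve, "clipped": clipped,
                         "separation": dr["separation"]})
        table = pd.DataFrame(rows).set_index("factor")
        if table["rcve"].notna().all():
            # round before ranking so numerically-equal factors tie (mid-rank)
            table["rank"] = rankdata(-np.round(table["rcve"].to_numpy(), 8),
                                     method="average")
        else:
            table["rank"] = np.nan
        return CircReliabilityResults(self, params, diag, pseudo_r2, r2_all, ll_all, table)


@dataclass
class CircReliabilityResults:
    """Fit results: coefficients, pseudo-r², per-factor RCVE and ranks."""

    model: CircReliabilityModel
    params: pd.Series
    diagnostics: dict
    pseudo_r2_kind: str
    r2_all: float
    ll_all: float
    rcve_table: pd.DataFrame = field(repr=False)

    @property
    def pair_id(self) -> str:
        return self.model.pair_id

    @property
    def bse(self) -> pd.Series:
        return self.diagnostics["bse"]

    @property
    def pvalues(self) -> pd.Series:
        return self.diagnostics["pvalues"]

    @property
    def rcve(self) -> pd.Series:
        return self.rcve_table["rcve"]

    @property
    def ranks(self) -> pd.Series:
        return self.rcve_table["rank"]

    def summary(self) -> str:
        lines = [
            f"CircReliabilityModel results{f' — pair {self.pair_id}' if self.pair_id else ''}",
            f"n = {len(self.model.endog)}, not-depleted = {int(self.model.endog.sum())}",
            f"pseudo-r² ({self.pseudo_r2_kind}) = {self.r2_all:.4f}"
            + ("  [ridge refit: separation]" if self.diagnostics["separation"] else ""),
            "",
            f"{'factor':<24}{'coef':>10}{'se':>10}{'rcve':>10}{'rank':>6}",
        ]
        for factor in self.model.exog.columns:
            coef = self.params.get(factor, np.nan)
            se = self.bse.get(factor, np.nan)
            row = self.rcve_table.loc[factor]
            lines.append(f"{factor:<24}{coef:>10.4f}{se:>10.4f}"
                         f"{row['rcve']:>10.4f}{row['rank']:>6.1f}")
        return "\n".join(lines)

    def to_frame(self) -> pd.DataFrame:
        out = self.rcve_table.copy()
        out.insert(0, "pair_id", self.pair_id)
        out["coef"] = self.params.reindex(out.index)
        out["r2_all"] = self.r2_all
        return out.reset_index()


def rank_across_pairs(results: list[CircReliabilityResults] | list[pd.DataFrame],
                      ) -> tuple[pd.DataFrame, pd.Series]:
    """Combine per-pair RCVE ranks into a pairs × factors table and the
    per-factor average rank (ascending = more important)."""
    if not results:
        raise ValueError("need at least one fitted result")
    rank_rows = {}
    for i, res in enumerate(results):
        if isinstance(res, CircReliabilityResults):
            rank_rows[res.pair_id or f"pair{i + 1}"] = res.ranks
        else:
            rank_rows[res["pair_id"].iloc[0]] = res.set_index("factor")["rank"]
    ranks = pd.DataFrame(rank_rows).T
    ranks.index.name = "pair_id"
    avg = ranks.mean(axis=0).sort_values()
    avg.name = "average_rank"
    return ranks, avg
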