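"""Forward selection of environmental predictors and standardized
coefficients.

Predictors are z-scored internally; at each step the candidate giving
the largest R-squared gain is admitted if its partial F-test clears the
entry level alpha (default 0.05).  The final joint OLS on z-scored
response and predictors yields partial standardized coefficients, which
carry the direction of each relationship.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SelectionResult",
    "forward_select",
    "standardized_coefficients",
    "spearman_matrix",
]

log = logging.getLogger(__name__)


@dataclass
class SelectionResult:
    response: str
    selected: list[str]
    cumulative_r2: list[float]
    entry_p: list[float]
    coefficients: pd.Series  # partial standardized coefficients, final model

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "variable": self.selected,
                "cumulative_r2": self.cumulative_r2,
                "entry_p": self.entry_p,
                "b": [self.coefficients[v] for v in self.selected],
            }
        )


def _r2(y: np.ndarray, x: np.ndarray) -> float:
    beta, *_ = np.linalg.lstsq(x, y, rcond=None)
    resid = y - x @ beta
    tss = float(np.sum((y - y.mean()) ** 2))
    return 1.0 - float(np.sum(resid**2)) / tss if tss > 0 else 0.0


def forward_select(
    y: np.ndarray,
    candidates: pd.DataFrame,
    alpha: float = 0.05,
    response: str = "y",
    adjusted_r2_stop: bool = False,
) -> SelectionResult:
    """Forward variable selection with a partial-F entry test.

    At each step the candidate with the largest R-squared gain enters if
    its partial F-test p-value is below ``alpha`` (ties broken by gain,
    then by variable name).  With ``adjusted_r2_stop`` the adjusted
    R-squared of the all-candidates model additionally caps the search (a
    stricter double-stopping rule, off by default).  Candidates perfectly
    collinear with the selected set are skipped with a warning.
    """
    y = np.asarray(y, dtype=float)
    n = y.size
    if n <= candidates.shape[1] + 2:
        raise ValueError("need n > number of candidates + 2")
    z = (candidates - candidates.mean()) / candidates.std(ddof=1)
    z = z.astype(float)

    r2_cap = np.inf
    if adjusted_r2_stop:
        x_all = np.column_stack([np.ones(n), z.to_numpy()])
        r2_all = _r2(y, x_all)
        k = candidates.shape[1]
        r2_cap = 1 - (1 - r2_all) * (n - 1) / (n - k - 1)

    selected: list[str] = []
    cum_r2: list[float] = []
    entry_p: list[float] = []
    current_r2 = 0.0
    remaining = sorted(z.columns)
    while remaining:
        best = None
        for name in remaining:
            cols = selected + [name]
            x = np.column_stack([np.ones(n)] + [z[c].to_numpy() for c in cols])
            if np.linalg.matrix_rank(x) < x.shape[1]:
                warnings.warn(f"candidate {name!r} collinear with selected set; skipped")
                continue
            r2_new = _r2(y, x)
            key = (r2_new, name)  # max gain, lexicographic tie-break via sort order
            if best is None or r2_new > best[0] + 1e-12:
                best = (r2_new, name)
        if best is None:
            break
        r2_new, name = best
        df_resid = n - (len(selected) + 2)
        gain = max(0.0, r2_new - current_r2)
        if gain <= 1e-12:
            p = 1.0
        elif 1 - r2_new <= 1e-12:
            p = 0.0
        else:
            f = gain / ((1 - r2_new) / df_resid)
            p = float(stats.f.sf(f, 1, df_resid))
        if p >= alpha or r2_new > r2_cap + 1e-12:
            break
        selected.append(name)
        cum_r2.append(r2_new)
        entry_p.append(p)
        current_r2 = r2_new
        remaining.remove(name)

    coef = standardized_coefficients(y, candidates[selected]) if selected else pd.Series(dtype=float)
    return SelectionResult(response, selected, cum_r2, entry_p, coef)


def standardized_coefficients(y: np.ndarray, predictors: pd.DataFrame) -> pd.Series:
    """Partial standardized regression coefficients (z-scored OLS)."""
    y = np.asarray(y, dtype=float)
    zy = (y - y.mean()) / y.std(ddof=1)
    zx = ((predictors - predictors.mean()) / predictors.std(ddof=1)).to_numpy(float)
    x = np.column_stack([np.ones(len(zy)), zx])
    if np.linalg.matrix_rank(x) < x.shape[1]:
        corr = predictors.corr().abs()
        np.fill_diagonal(corr.values, 0)
        pair = corr.stack().idxmax()
        raise np.linalg.LinAlgError(f"rank-deficient predictors, e.g. {pair}")
    beta, *_ = np.linalg.lstsq(x, zy, rcond=None)
    return pd.Series(beta[1:], index=predictors.columns, name="b")


def spearman_matrix(variables: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise Spearman rho and p with pairwise-complete observations."""
    cols = list(variables.columns)
    k = len(cols)
    rho = pd.DataFrame(np.eye(k), index=cols, columns=cols)
    pval = pd.DataFrame(np.zeros((k, k)), index=cols, columns=cols)
    for i in range(k):
        for j in range(i + 1, k):
            sub = variables[[cols[i], cols[j]]].dropna()
            if len(sub) < 3 or sub[cols[i]].nunique() < 2 or sub[cols[j]].nunique() < 2:
                r, p = np.nan, np.nan
            else:
                r, p = stats.spearmanr(sub[cols[i]], sub[cols[j]])
            rho.iloc[i, j] = rho.iloc[j, i] = r
            pval.iloc[i, j] = pval.iloc[j, i] = p
    return rho, pval
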