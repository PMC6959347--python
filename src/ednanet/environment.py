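"""Associating modules and taxa with environmental covariates.

Module-level summaries (richness of detected taxa per time point, or
the mean ensemble index) and individual taxon index series are
correlated against each environmental variable using Pearson and/or
Spearman.  With few time points the p-values are weak evidence; they
are reported, never used to filter.  The connectivity-versus-environment
relationship asks whether a module's better-connected taxa track its
designated variable more closely.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import pearsonr, spearmanr

from ednanet.index import IndexTable

__all__ = [
    "module_richness",
    "module_env_correlation",
    "taxon_env_correlation",
    "connectivity_env_relationship",
]


def _corr(x: np.ndarray, y: np.ndarray, method: str) -> tuple[float, float]:
    """(r, p) or (nan, nan) when either series is constant."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.allclose(x, x[0]) or np.allclose(y, y[0]):
        return float("nan"), float("nan")
    if method == "pearson":
        res = pearsonr(x, y)
    elif method == "spearman":
        res = spearmanr(x, y)
    else:
        raise ValueError(f"unknown method {method!r}")
    return float(res.statistic), float(res.pvalue)


def module_richness(table: IndexTable, modules: pd.Series) -> dict[str, pd.DataFrame]:
    """Per-module richness and mean index over time points.

    Richness at ``t`` counts module taxa with index > 0; both summaries
    are defined at every time point for every labeled module.
    """
    values = table.values
    labels = modules.reindex(values.index)
    out_rich, out_mean = {}, {}
    for label in sorted(labels.dropna().unique()):
        members = values.loc[labels == label]
        out_rich[label] = (members.to_numpy() > 0).sum(axis=0)
        out_mean[label] = members.to_numpy().mean(axis=0)
    richness = pd.DataFrame(out_rich, index=values.columns).T
    mean_index = pd.DataFrame(out_mean, index=values.columns).T
    return {"richness": richness, "mean_index": mean_index}


def module_env_correlation(profiles: dict[str, pd.DataFrame],
                           env: pd.DataFrame,
                           methods: tuple[str, ...] = ("pearson", "spearman"),
                           ) -> pd.DataFrame:
    """Correlate each module summary series against each variable.

    Requires >= 3 shared time points.  Returns long-format rows
    (module, summary, variable, method, r, p); undefined associations
    (constant series) carry NaN.
    """
    for summary, prof in profiles.items():
        shared = [c for c in prof.columns if c in set(env.index)]
        if len(shared) < 3:
            raise ValueError(
                f"need >= 3 shared time points, got {len(shared)} for {summary}")
    rows = []
    for summary, prof in profiles.items():
        shared = [c for c in prof.columns if c in set(env.index)]
        e = env.loc[shared]
        for module in prof.index:
            series = prof.loc[module, shared].to_numpy(dtype=float)
            for var in env.columns:
                for method in methods:
                    r, p = _corr(series, e[var].to_numpy(), method)
                    rows.append({"module": module, "summary": summary,
                                 "variable": var, "method": method,
                                 "r": r, "p": p})
    return pd.DataFrame(rows)


def taxon_env_correlation(table: IndexTable, env: pd.DataFrame,
                          method: str = "spearman") -> pd.DataFrame:
    """Per-taxon correlation of the index series with each variable.

    Constant taxa are flagged undefined (NaN r/p) rather than dropped.
    """
    values = table.values
    shared = [c for c in values.columns if c in set(env.index)]
    if len(shared) < 3:
        raise ValueError("need >= 3 shared time points")
    e = env.loc[shared]
    rows = []
    for taxon in values.index:
        series = values.loc[taxon, shared].to_numpy(dtype=float)
        for var in env.columns:
            r, p = _corr(series, e[var].to_numpy(), method)
            rows.append({"taxon": taxon, "variable": var, "method": method,
                         "r": r, "p": p, "undefined": not np.isfinite(r)})
    return pd.DataFrame(rows)


def connectivity_env_relationship(connectivity: pd.Series,
                                  taxon_env: pd.DataFrame,
                                  modules: pd.Series,
                                  module: str,
                                  variable: str) -> tuple[float, float]:
    """Spearman r between intramodular k and the per-taxon env correlation.

    Evaluated within one module for its designated variable; a positive
    value means better-connected taxa correlate more strongly with the
    variable.
    """
    members = modules.index[modules == module]
    if len(members) < 4:
        raise ValueError(f"module {module!r} has fewer than 4 taxa")
    sub = taxon_env[(taxon_env["variable"] == variable)
                    & (taxon_env["taxon"].isin(set(members)))]
    sub = sub.dropna(subset=["r"]).set_index("taxon")
    k = connectivity.reindex(sub.index).to_numpy(dtype=float)
    r_env = sub["r"].to_numpy(dtype=float)
    return _corr(k, r_env, "spearman")
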