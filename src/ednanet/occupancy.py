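"""Site-occupancy filtering of OTUs from PCR-replicate detections.

Each field water sample is assayed by ``K`` PCR replicates; an OTU is
"detected" in a replicate when it has at least one read.  Treating the
replicates as independent draws from a common binomial distribution, a
two-parameter mixture separates true presence (occupancy probability
``psi``) from imperfect per-replicate detection (``p``):

    L(psi, p) = prod_samples [ psi * C(K, k) p^k (1-p)^(K-k)
                               + (1 - psi) * 1{k = 0} ]

OTUs whose fitted ``psi`` falls below a threshold (default 0.8) are
eliminated as likely false-positive discoveries.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.stats import binom

__all__ = [
    "OccupancyEstimate",
    "detection_history",
    "fit_occupancy",
    "filter_otus",
    "occupancy_report",
]


@dataclass(frozen=True)
class OccupancyEstimate:
    otu_id: str
    psi_hat: float
    p_hat: float
    log_likelihood: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.psi_hat <= 1.0 and 0.0 <= self.p_hat <= 1.0):
            raise ValueError("psi_hat and p_hat must lie in [0, 1]")


def detection_history(counts: pd.DataFrame, metadata: pd.DataFrame) -> pd.DataFrame:
    """Collapse replicate columns into per-(OTU, field sample) detections.

    Parameters
    ----------
    counts
        OTUs x samples integer table.
    metadata
        Indexed by sample id with columns ``sample_type``, ``timepoint``,
        ``replicate``.  Only ``field`` samples enter the history; a field
        sample is the set of replicate columns sharing a time point.

    Returns
    -------
    Long table with columns ``otu_id``, ``sample``, ``k`` (replicates
    with >= 1 read) and ``K`` (replicates assayed).  Replicates with
    zero total reads still count toward ``K``.
    """
    field = metadata[metadata["sample_type"] == "field"]
    field = field[field.index.isin(counts.columns)]
    if field.empty:
        raise ValueError("no field samples found in metadata/counts")
    records = []
    for timepoint, group in field.groupby("timepoint", sort=True):
        cols = list(group.index)
        block = counts[cols].to_numpy() > 0
        k = block.sum(axis=1)
        for otu, ki in zip(counts.index, k):
            records.append((otu, int(timepoint), int(ki), len(cols)))
    return pd.DataFrame(records, columns=["otu_id", "sample", "k", "K"])


def _log_likelihood(psi: np.ndarray, p: np.ndarray,
                    k: np.ndarray, K: np.ndarray) -> np.ndarray:
    """Vectorized mixture log-likelihood on a (psi, p) grid.

    ``psi`` and ``p`` broadcast against each other; ``k``/``K`` are the
    per-sample detection history.
    """
    psi = np.asarray(psi, dtype=float)[..., None]
    p = np.asarray(p, dtype=float)[..., None]
    pmf = binom.pmf(k, K, np.clip(p, 0.0, 1.0))
    lik = psi * pmf + (1.0 - psi) * (k == 0)
    return np.log(np.maximum(lik, 1e-300)).sum(axis=-1)


def fit_occupancy(history: pd.DataFrame, otu_id: str | None = None,
                  grid_step: float = 0.01) -> OccupancyEstimate:
    """Maximum-likelihood (psi, p) for one OTU's detection history.

    A coarse grid search (``grid_step``) locates the basin; a bounded
    Nelder-Mead refinement polishes the optimum.  Grid ties break toward
    the smaller ``psi``.  Degenerate histories resolve at the
    boundaries: all-detected gives (1, 1), never-detected gives (0, 0)
    with ``p`` unidentifiable by convention.
    """
    if otu_id is None:
        ids = history["otu_id"].unique()
        if len(ids) != 1:
            raise ValueError("history holds several OTUs; pass otu_id")
        otu_id = ids[0]
        sub = history
    else:
        sub = history[history["otu_id"] == otu_id]
    if sub.empty:
        raise ValueError(f"no detection history for {otu_id!r}")
    k = sub["k"].to_numpy(dtype=int)
    K = sub["K"].to_numpy(dtype=int)
    if np.any((k < 0) | (k > K)) or np.any(K < 1):
        raise ValueError("invalid detection history: need 0 <= k <= K, K >= 1")

    if not k.any():
        return OccupancyEstimate(otu_id, 0.0, 0.0,
                                 float(_log_likelihood(0.0, 0.0, k, K)))

    axis = np.arange(0.0, 1.0 + grid_step / 2, grid_step)
    ll = _log_likelihood(axis[:, None], axis[None, :], k, K)
    # argmax scans psi-major in ascending order -> first max = smallest psi
    best = np.unravel_index(np.argmax(ll), ll.shape)
    psi0, p0 = axis[best[0]], axis[best[1]]

    res = minimize(
        lambda x: -float(_log_likelihood(x[0], x[1], k, K)),
        x0=[psi0, p0], method="Nelder-Mead",
        bounds=[(0.0, 1.0), (0.0, 1.0)],
        options={"xatol": 1e-6, "fatol": 1e-10},
    )
    psi_hat, p_hat = (float(np.clip(v, 0.0, 1.0)) for v in res.x)
    refined_ll = float(_log_likelihood(psi_hat, p_hat, k, K))
    grid_ll = float(ll[best])
    if refined_ll < grid_ll:  # refinement must never lose to the grid
        psi_hat, p_hat, refined_ll = float(psi0), float(p0), grid_ll
    return OccupancyEstimate(otu_id, psi_hat, p_hat, refined_ll)


def fit_all(history: pd.DataFrame, grid_step: float = 0.01
            ) -> dict[str, OccupancyEstimate]:
    """Fit every OTU appearing in the detection history."""
    return {
        otu: fit_occupancy(sub, otu_id=otu, grid_step=grid_step)
        for otu, sub in history.groupby("otu_id", sort=False)
    }


def filter_otus(estimates: dict[str, OccupancyEstimate],
                threshold: float = 0.8) -> tuple[set[str], pd.DataFrame]:
    """Retain OTUs with ``psi_hat >= threshold`` (boundary kept).

    Returns the retained id set and a per-OTU audit table.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError(f"threshold must be in [0, 1], got {threshold}")
    rows = [
        {"otu_id": est.otu_id, "psi_hat": est.psi_hat, "p_hat": est.p_hat,
         "log_likelihood": est.log_likelihood,
         "retained": est.psi_hat >= threshold}
        for est in estimates.values()
    ]
    audit = pd.DataFrame(rows).set_index("otu_id")
    retained = set(audit.index[audit["retained"]])
    return retained, audit


def occupancy_report(counts: pd.DataFrame, metadata: pd.DataFrame,
                     threshold: float = 0.8) -> tuple[set[str], pd.DataFrame]:
    """Convenience: history -> fits -> filter for one count table."""
    history = detection_history(counts, metadata)
    estimates = fit_all(history)
    return filter_otus(estimates, threshold=threshold)
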