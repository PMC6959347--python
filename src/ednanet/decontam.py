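"""Control-based decontamination and replicate quality control.

Two steps, applied to within-sample read proportions:

1.  Subtract each OTU's most-likely proportional contamination — its
    largest (or, optionally, mean) proportion across negative/blank
    controls — from every sample, flooring at zero and renormalizing.
2.  Drop field samples whose PCR replicates are overly dissimilar
    (maximum pairwise Bray-Curtis above a threshold, default 0.49),
    then collapse surviving replicates to one column per time point by
    averaging proportions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

__all__ = [
    "ContaminationProfile",
    "proportionalize",
    "estimate_contamination",
    "subtract_contamination",
    "bray_curtis",
    "replicate_dissimilarity",
    "drop_dissimilar_samples",
    "collapse_replicates",
]


@dataclass
class ContaminationProfile:
    """Per-OTU contamination proportion and its provenance."""

    proportions: pd.Series          # OTU -> c_i in [0, 1]
    control_ids: list[str] = field(default_factory=list)
    estimator: str = "max"


def proportionalize(counts: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
    """Column-wise read proportions; all-zero columns pass through flagged.

    Returns the proportion table and the list of all-zero column ids.
    """
    values = counts.to_numpy(dtype=float)
    if (values < 0).any():
        raise ValueError("counts must be nonnegative")
    totals = values.sum(axis=0)
    empty = totals == 0
    safe = np.where(empty, 1.0, totals)
    props = pd.DataFrame(values / safe, index=counts.index, columns=counts.columns)
    return props, list(counts.columns[empty])


def estimate_contamination(props: pd.DataFrame, control_ids: list[str],
                           estimator: str = "max") -> ContaminationProfile:
    """Most-likely per-OTU contamination from control columns.

    ``estimator`` is ``"max"`` (conservative, default) or ``"mean"``.
    With no controls every c_i is zero.
    """
    if estimator not in ("max", "mean"):
        raise ValueError(f"estimator must be 'max' or 'mean', got {estimator!r}")
    controls = [c for c in control_ids if c in props.columns]
    if not controls:
        c = pd.Series(0.0, index=props.index)
    elif estimator == "max":
        c = props[controls].max(axis=1)
    else:
        c = props[controls].mean(axis=1)
    return ContaminationProfile(c, control_ids=controls, estimator=estimator)


def subtract_contamination(props: pd.DataFrame,
                           profile: ContaminationProfile) -> pd.DataFrame:
    """``p'_ij = max(0, p_ij - c_i)``, then renormalize each column.

    Columns that become (or were) all-zero stay all-zero.
    """
    if not props.index.equals(profile.proportions.index):
        profile_c = profile.proportions.reindex(props.index, fill_value=0.0)
    else:
        profile_c = profile.proportions
    adjusted = (props.to_numpy() - profile_c.to_numpy()[:, None]).clip(min=0.0)
    totals = adjusted.sum(axis=0)
    safe = np.where(totals == 0, 1.0, totals)
    return pd.DataFrame(adjusted / safe, index=props.index, columns=props.columns)


def bray_curtis(x: np.ndarray, y: np.ndarray) -> float:
    """``BC(x, y) = sum|x_i - y_i| / sum(x_i + y_i)``; 0 for two empties."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    denom = float((x + y).sum())
    if denom == 0.0:
        return 0.0
    return float(np.abs(x - y).sum() / denom)


def replicate_dissimilarity(props: pd.DataFrame,
                            replicate_groups: dict) -> pd.Series:
    """Max pairwise Bray-Curtis among each field sample's replicates.

    ``replicate_groups`` maps a field-sample key (e.g. time point) to
    its replicate column ids.  Groups with a single replicate pass
    trivially with value 0.
    """
    out = {}
    for sample, cols in replicate_groups.items():
        cols = [c for c in cols if c in props.columns]
        if len(cols) < 1:
            raise ValueError(f"replicate group {sample!r} has no columns")
        if len(cols) == 1:
            out[sample] = 0.0
            continue
        block = props[cols].to_numpy()
        out[sample] = max(
            bray_curtis(block[:, i], block[:, j])
            for i, j in combinations(range(len(cols)), 2)
        )
    return pd.Series(out, name="max_bray_curtis")


def drop_dissimilar_samples(dissimilarity: pd.Series,
                            threshold: float = 0.49
                            ) -> tuple[list, pd.DataFrame]:
    """Retain field samples with max pairwise BC <= threshold.

    Strictly-greater values drop (the boundary is retained).  Returns
    the retained sample keys and a QC report.  Raises if everything
    would be dropped.
    """
    dropped = dissimilarity > threshold
    report = pd.DataFrame({
        "max_bray_curtis": dissimilarity,
        "dropped": dropped,
    })
    retained = [s for s in dissimilarity.index if not dropped.loc[s]]
    if not retained:
        raise ValueError(
            "all samples exceeded the replicate-dissimilarity threshold "
            f"{threshold}; diagnostics:\n{report.to_string()}")
    return retained, report


def collapse_replicates(props: pd.DataFrame,
                        replicate_groups: dict,
                        retained: list | None = None) -> pd.DataFrame:
    """One proportion column per field sample: mean of replicates, renormalized."""
    keys = list(replicate_groups) if retained is None else list(retained)
    data = {}
    for sample in keys:
        cols = [c for c in replicate_groups[sample] if c in props.columns]
        mean = props[cols].to_numpy().mean(axis=1)
        total = mean.sum()
        data[sample] = mean / total if total > 0 else mean
    return pd.DataFrame(data, index=props.index)
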