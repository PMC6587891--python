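"""Edge and region biomarker ranking from group differences in connectivity.

The significant alteration of connectivity (SAC) of an edge is the absolute
difference of its group-mean weights, min-max normalized over edges so the
most altered edge scores exactly 1. Region weights accumulate the SAC
scores of the top-ranked edges incident to each region, again min-max
normalized. Subnetworks restricted to a set of regions summarize where the
alteration concentrates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "sac_scores",
    "region_weights",
    "subnet_extract",
    "SubnetSummary",
]


def _mean_matrix(networks) -> np.ndarray:
    mats = [np.asarray(getattr(c, "values", c), dtype=float) for c in networks]
    return np.mean(mats, axis=0)


def _labels_of(networks, n) -> list:
    for c in networks:
        labels = getattr(c, "region_labels", None)
        if labels is not None:
            return list(labels)
    return [f"R{i + 1}" for i in range(n)]


def sac_scores(patient_networks, control_networks, stat: str = "meandiff") -> pd.DataFrame:
    """Edge-level alteration table: columns region_A, region_B, weight_score.

    Raw score per edge = |mean_patient − mean_control| (``stat="meandiff"``,
    the default) or the absolute Welch t statistic (``stat="t"``, for
    sensitivity analysis); min-max normalized to [0, 1]; rows sorted by
    descending score, ties by (i, j). When every edge is equally
    (un)altered the normalization is degenerate and all scores are 0 with a
    warning.
    """
    if stat not in ("meandiff", "t"):
        raise ValueError(f"unknown SAC statistic {stat!r}")
    if len(patient_networks) < 2 or len(control_networks) < 2:
        raise ValueError("need at least 2 subjects per group for SAC")
    mp = _mean_matrix(patient_networks)
    mc = _mean_matrix(control_networks)
    if mp.shape != mc.shape:
        raise ValueError("group networks have mismatched shapes")
    n = mp.shape[0]
    labels = _labels_of(list(patient_networks) + list(control_networks), n)
    iu, ju = np.triu_indices(n, k=1)
    if stat == "t":
        from scipy import stats as sps

        vp = np.stack([np.asarray(getattr(c, "values", c))[iu, ju]
                       for c in patient_networks])
        vc = np.stack([np.asarray(getattr(c, "values", c))[iu, ju]
                       for c in control_networks])
        with np.errstate(divide="ignore", invalid="ignore"):
            raw = np.abs(sps.ttest_ind(vp, vc, axis=0, equal_var=False).statistic)
        raw = np.nan_to_num(raw, nan=0.0, posinf=0.0)
    else:
        raw = np.abs(mp - mc)[iu, ju]
    lo, hi = raw.min(), raw.max()
    if hi - lo == 0:
        warnings.warn("all edge alterations equal; SAC scores degenerate to 0",
                      stacklevel=2)
        score = np.zeros_like(raw)
    else:
        score = (raw - lo) / (hi - lo)
    df = pd.DataFrame(
        {
            "region_A": [labels[i] for i in iu],
            "region_B": [labels[j] for j in ju],
            "weight_score": score,
            "_i": iu,
            "_j": ju,
        }
    )
    df = df.sort_values(["weight_score", "_i", "_j"],
                        ascending=[False, True, True], kind="stable")
    return df.drop(columns=["_i", "_j"]).reset_index(drop=True)


def region_weights(sac: pd.DataFrame, top_n: int = 30) -> pd.DataFrame:
    """Accumulate top-n SAC scores per incident region, min-max normalized.

    Only regions appearing in the top-n rows are listed; sorted descending.
    """
    if top_n > len(sac):
        raise ValueError(f"top_n={top_n} exceeds the {len(sac)} available SAC rows")
    top = sac.head(top_n)
    acc: dict = {}
    for _, row in top.iterrows():
        for region in (row["region_A"], row["region_B"]):
            acc[region] = acc.get(region, 0.0) + float(row["weight_score"])
    regions = sorted(acc)
    raw = np.array([acc[r] for r in regions])
    lo, hi = raw.min(), raw.max()
    norm = np.zeros_like(raw) if hi - lo == 0 else (raw - lo) / (hi - lo)
    if hi - lo == 0 and hi > 0:
        norm = np.ones_like(raw)  # all regions equally altered, all maximal
    df = pd.DataFrame({"region": regions, "weight_score": norm, "_raw": raw})
    df = df.sort_values(["weight_score", "region"], ascending=[False, True],
                        kind="stable")
    return df.drop(columns="_raw").reset_index(drop=True)


@dataclass
class SubnetSummary:
    regions: list
    patient_mean: np.ndarray
    control_mean: np.ndarray
    difference: np.ndarray  # patient − control
    patient_strength: float  # mean over subnet edges
    control_strength: float


def subnet_extract(patient_networks, control_networks, regions) -> SubnetSummary:
    """Group-mean subnetworks restricted to ``regions`` (names or indices)."""
    mp = _mean_matrix(patient_networks)
    mc = _mean_matrix(control_networks)
    n = mp.shape[0]
    labels = _labels_of(list(patient_networks) + list(control_networks), n)
    idx = []
    names = []
    for r in regions:
        if isinstance(r, (int, np.integer)):
            if not 0 <= r < n:
                raise ValueError(f"region index {r} out of range")
            idx.append(int(r))
            names.append(labels[int(r)])
        else:
            if r not in labels:
                raise ValueError(f"unknown region name {r!r}")
            idx.append(labels.index(r))
            names.append(r)
    idx = np.array(idx)
    sp = mp[np.ix_(idx, idx)]
    sc = mc[np.ix_(idx, idx)]
    iu, ju = np.triu_indices(len(idx), k=1)
    return SubnetSummary(
        regions=names,
        patient_mean=sp,
        control_mean=sc,
        difference=sp - sc,
        patient_strength=float(sp[iu, ju].mean()),
        control_strength=float(sc[iu, ju].mean()),
    )
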