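"""Variable filtering, k-nearest-neighbor imputation, min-max normalization.

The preprocessing chain mirrors standard practice for small clinical tables:
variables missing for more than 70% of participants are dropped (strict
inequality: a variable missing for exactly 70% is retained), remaining gaps
are filled by a kNN scheme, and variables are linearly mapped to [0,1].

The kNN distance between two participants is Gower-like: Euclidean distance
over min-max-scaled, mutually observed continuous variables plus simple
matching (0/1 mismatch) on mutually observed binary variables, divided by
the number of mutually observed variables.  Imputed values are the median
(continuous) or mode (binary, ties -> 1) of the k nearest donors that
observe the target variable; equidistant donors are ordered by participant
index.  A participant sharing no observed variable with any donor falls
back to the column median/mode (logged).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import CohortTable

log = logging.getLogger(__name__)


def filter_by_missingness(
    table: CohortTable, threshold: float = 0.70
) -> tuple[CohortTable, list[str]]:
    """Drop variables whose missing fraction strictly exceeds ``threshold``.

    Returns the filtered table (variable order preserved) and the list of
    removed variable names for the provenance report.
    """
    if not (0.0 < threshold < 1.0):
        raise ValueError("threshold must lie in (0,1)")
    if table.n_participants == 0 or not table.variables:
        raise ValueError("empty table")
    frac = table.missing_fraction()
    removed = [v for v in table.variables if frac[v] > threshold]
    kept = [v for v in table.variables if frac[v] <= threshold]
    return table.subset_variables(kept), removed


@dataclass
class ImputationReport:
    n_imputed: int
    fallback_participants: list


def knn_impute(
    table: CohortTable, k: int = 5, return_report: bool = False
) -> CohortTable | tuple[CohortTable, ImputationReport]:
    """Fill every masked cell from the k nearest participants.

    Observed cells are never altered.  Requires ``k < n_participants`` and
    at least one observed variable per participant.
    """
    n = table.n_participants
    if not (1 <= k < n):
        raise ValueError("require 1 <= k < n_participants")
    mask = table.mask.to_numpy(bool)
    if mask.all(axis=1).any():
        raise ValueError("every participant needs at least one observed variable")
    if not mask.any():
        return (table.copy(), ImputationReport(0, [])) if return_report else table.copy()

    values = table.values.to_numpy(float).copy()
    variables = table.variables
    is_binary = np.array([v in set(table.binary_variables) for v in variables])

    # min-max scale continuous columns over their observed entries for the
    # distance computation only
    scaled = values.copy()
    for j, name in enumerate(variables):
        if is_binary[j]:
            continue
        obs = values[~mask[:, j], j]
        if obs.size == 0:
            continue
        lo, hi = obs.min(), obs.max()
        scaled[:, j] = 0.0 if hi == lo else (values[:, j] - lo) / (hi - lo)

    observed = ~mask
    # pairwise Gower-like distances
    dist = np.full((n, n), np.inf)
    for i in range(n):
        mutual = observed[i] & observed  # n × p
        counts = mutual.sum(axis=1)
        diff = scaled[i] - scaled
        cont_sq = np.where(mutual & ~is_binary, diff**2, 0.0).sum(axis=1)
        bin_mismatch = np.where(
            mutual & is_binary, values[i] != values, False
        ).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            d = (np.sqrt(cont_sq) + bin_mismatch) / counts
        d[counts == 0] = np.inf
        dist[i] = d
        dist[i, i] = np.inf

    out = values.copy()
    fallback = []
    n_imputed = 0
    for i in range(n):
        miss_js = np.flatnonzero(mask[i])
        if miss_js.size == 0:
            continue
        # stable order: distance, then participant index
        order = np.lexsort((np.arange(n), dist[i]))
        for j in miss_js:
            donors = [h for h in order if observed[h, j] and np.isfinite(dist[i, h])]
            if not donors:
                col = values[observed[:, j], j]
                if col.size == 0:
                    raise ValueError(
                        f"variable {variables[j]!r} has no observed values"
                    )
                out[i, j] = _aggregate(col, bool(is_binary[j]))
                fallback.append((table.participants[i], variables[j]))
                log.warning(
                    "participant %s has no usable neighbor for %s; "
                    "column fallback used", table.participants[i], variables[j]
                )
            else:
                donor_vals = values[donors[:k], j]
                out[i, j] = _aggregate(donor_vals, bool(is_binary[j]))
            n_imputed += 1

    result = CohortTable(
        pd.DataFrame(out, index=table.values.index, columns=table.values.columns),
        table.meta.copy(),
    )
    if return_report:
        return result, ImputationReport(n_imputed, fallback)
    return result


def _aggregate(vals: np.ndarray, binary: bool) -> float:
    if binary:
        ones = (vals == 1.0).sum()
        zeros = (vals == 0.0).sum()
        return 1.0 if ones >= zeros else 0.0  # documented tie -> 1
    return float(np.median(vals))


def minmax_normalize(
    table: CohortTable,
) -> tuple[CohortTable, dict[str, tuple[float, float]]]:
    """Map every variable linearly to [0,1]: y = (x - min) / (max - min).

    Runs after imputation (no missing cells allowed).  A constant variable
    maps to all zeros with a warning.  The per-variable (min, max) pairs are
    returned so new observations can be projected onto the same scale.
    """
    if not table.is_complete():
        raise ValueError("normalize after imputation: table still has missing cells")
    values = table.values.to_numpy(float).copy()
    ranges: dict[str, tuple[float, float]] = {}
    for j, name in enumerate(table.variables):
        lo, hi = float(values[:, j].min()), float(values[:, j].max())
        ranges[name] = (lo, hi)
        if hi == lo:
            warnings.warn(
                f"variable {name!r} is constant; normalized to all zeros",
                stacklevel=2,
            )
            values[:, j] = 0.0
        else:
            values[:, j] = (values[:, j] - lo) / (hi - lo)
    out = CohortTable(
        pd.DataFrame(values, index=table.values.index, columns=table.values.columns),
        table.meta.copy(),
    )
    return out, ranges


def preprocess_cohort(
    table: CohortTable, threshold: float = 0.70, k: int = 5
) -> tuple[CohortTable, dict]:
    """filter -> impute -> normalize; returns the table plus a provenance log."""
    filtered, removed = filter_by_missingness(table, threshold)
    imputed, report = knn_impute(filtered, k=k, return_report=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        normalized, ranges = minmax_normalize(imputed)
    provenance = {
        "removed_variables": removed,
        "n_imputed_cells": report.n_imputed,
        "fallback_cells": report.fallback_participants,
        "ranges": ranges,
    }
    return normalized, provenance
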