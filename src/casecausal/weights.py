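"""Inverse-probability weights derived from control data.

The case-control identification strategies reweight cases *and* controls by
inverse exposure propensities that are estimated from controls only:

* time-fixed weight ``W = A_0/p + (1-A_0)/(1-p)`` with
  ``p = Pr(A_0=1 | L_0, selected as control)``;
* time-varying per-protocol weights
  ``W_k = prod_{j<=k} [A_j/p_j + (1-A_j)/(1-p_j)]`` with
  ``p_j = Pr(A_j=1 | L_0..L_j, A_0..A_{j-1}, Y_j=0, selected at window j)``
  (the propensity to switch exposure level), after which every subject is
  censored from the first window at which they deviate from a
  constant-exposure protocol.

Propensities are fitted saturated (stratum-wise empirical frequencies) on
discrete covariates; strata at 0 or 1 are positivity violations and error
out only when a weight actually touches them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import PositivityViolationError


@dataclass
class PropensityMap:
    """Stratum -> (estimated Pr(A=1 | stratum), stratum count/mass)."""

    conditioning: tuple
    strata: dict = field(default_factory=dict)  # key tuple -> (p, n)
    flagged: set = field(default_factory=set)  # strata with p in {0, 1}

    def p(self, key: tuple) -> float:
        if key not in self.strata:
            raise PositivityViolationError(
                f"no control data for stratum {key!r} (conditioning "
                f"{self.conditioning!r})"
            )
        if key in self.flagged:
            raise PositivityViolationError(
                f"propensity is degenerate ({self.strata[key][0]}) in stratum "
                f"{key!r}"
            )
        return self.strata[key][0]

    def to_record(self) -> dict:
        return {
            "conditioning": list(self.conditioning),
            "strata": [
                {"key": list(k), "n": n, "p": p}
                for k, (p, n) in sorted(self.strata.items(), key=repr)
            ],
        }


def fit_propensity(
    control_records: pd.DataFrame,
    conditioning: list[str],
    exposure_col: str,
    weight_col: str | None = None,
    method: str = "saturated",
) -> PropensityMap:
    """Saturated (nonparametric) exposure propensity among controls.

    ``control_records`` holds one row per control (or, for distribution-level
    use, one row per enumeration atom with its probability in
    ``weight_col``).  Conditioning on an empty list yields a single stratum
    with the overall control exposure prevalence.
    """
    if method != "saturated":
        raise ValueError(f"unknown propensity method {method!r}")
    if len(control_records) == 0:
        raise ValueError("control_records is empty")
    df = control_records
    w = (
        df[weight_col].to_numpy(dtype=float)
        if weight_col is not None
        else np.ones(len(df))
    )
    a = df[exposure_col].to_numpy(dtype=float)
    pm = PropensityMap(conditioning=tuple(conditioning))
    if conditioning:
        keys = list(map(tuple, df[list(conditioning)].to_numpy()))
    else:
        keys = [()] * len(df)
    agg: dict = {}
    for key, wi, ai in zip(keys, w, a):
        tot, exp_ = agg.setdefault(key, [0.0, 0.0])
        agg[key][0] = tot + wi
        agg[key][1] = exp_ + wi * ai
    for key, (tot, exp_) in agg.items():
        if tot <= 0.0:
            continue
        key = tuple(int(v) if float(v).is_integer() else v for v in key)
        p = exp_ / tot
        pm.strata[key] = (p, tot)
        if p <= 0.0 or p >= 1.0:
            pm.flagged.add(key)
    return pm


def time_fixed_weight(a0: int, p: float) -> float:
    """Eq.-style time-fixed IP weight: W = a0/p + (1-a0)/(1-p)."""
    if not (0.0 < p < 1.0):
        raise PositivityViolationError(f"propensity {p} not strictly in (0, 1)")
    return a0 / p + (1 - a0) / (1 - p)


def cohort_time_fixed_weights(
    cohort: pd.DataFrame, pmap: PropensityMap, key_cols: list[str] = ("L_0",)
) -> np.ndarray:
    """Vectorised W over a cohort table, using baseline exposure A_0."""
    keys = [tuple(int(v) for v in row) for row in cohort[list(key_cols)].to_numpy()]
    a0 = cohort["A_0"].to_numpy(dtype=float)
    out = np.empty(len(cohort))
    for i, (key, a) in enumerate(zip(keys, a0)):
        out[i] = time_fixed_weight(int(a), pmap.p(key))
    return out


def censor_at_deviation(cohort: pd.DataFrame) -> pd.DataFrame:
    """Attach ``censor_time``: the first window k >= 1 with A_k != A_0 among
    at-risk windows, or +inf when exposure stays constant while at risk.

    All downstream per-protocol computation ignores windows >= censor_time.
    """
    from .dgp import cohort_K

    K = cohort_K(cohort)
    out = cohort.copy()
    a = np.column_stack(
        [cohort[f"A_{k}"].to_numpy(dtype=float) for k in range(K)]
    )
    censor = np.full(len(cohort), np.inf)
    for k in range(1, K):
        dev = (~np.isnan(a[:, k])) & (a[:, k] != a[:, 0]) & np.isinf(censor)
        censor[dev] = k
    out["censor_time"] = censor
    return out


def _pp_key(l_vals, a_vals, j: int) -> tuple:
    """History key for the window-j switch propensity:
    (L_0..L_j, A_0..A_{j-1})."""
    return tuple(int(v) for v in l_vals[: j + 1]) + tuple(
        int(v) for v in a_vals[:j]
    )


def time_varying_weights(
    trajectory, propensity_maps, K: int | None = None
) -> np.ndarray:
    """Per-window weights W_0..W_{K-1} for one subject.

    ``trajectory`` is a cohort-table row (mapping with L_k, A_k, T);
    ``propensity_maps`` is one PropensityMap per window, each conditioned on
    the full history (L_0..L_j, A_0..A_{j-1}).  W_k is defined for at-risk
    windows before any protocol deviation (NaN elsewhere) and telescopes:
    W_k = W_{k-1} * (window-k factor).
    """
    if K is None:
        K = len(propensity_maps)
    l_vals = [trajectory[f"L_{k}"] for k in range(K)]
    a_vals = [trajectory[f"A_{k}"] for k in range(K)]
    t = trajectory["T"]
    out = np.full(K, np.nan)
    w = 1.0
    for j in range(K):
        if not (np.isinf(t) or j <= t):  # past the event: no longer at risk
            break
        aj = a_vals[j]
        if np.isnan(aj):
            break
        if j >= 1 and aj != a_vals[0]:  # censored from the deviation window
            break
        pj = propensity_maps[j].p(_pp_key(l_vals, a_vals, j))
        if not (0.0 < pj < 1.0):
            raise PositivityViolationError(
                f"window-{j} propensity {pj} not strictly in (0, 1)"
            )
        w *= aj / pj + (1 - aj) / (1 - pj)
        out[j] = w
    return out
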