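"""Identification-strategy estimators and their exact distribution-level
counterparts.

Every unmatched strategy compares cases with controls through an exposure
odds (ratio), possibly after inverse-probability weighting:

* case-base: ratio of W-weighted baseline-exposure odds, cases vs controls,
  with the time-fixed weight W derived from control data — identifies the
  marginal ITT risk ratio;
* survivor: ratio of exposure odds given L_0, cases vs surviving controls,
  unweighted — identifies the conditional ITT odds ratio given L_0;
* risk-set (ITT): W-weighted case exposure odds over control exposure odds
  weighted by W times the number of times selected — identifies the marginal
  ITT hazard ratio when counterfactual hazards are constant over windows;
* risk-set (PP): after censoring at protocol deviation, case odds weighted
  by the time-varying W_k of the event window over control odds weighted by
  the weighted selection count sum_k W_k S_k — identifies the marginal
  sustained-regime ("always vs never exposed") hazard ratio.

The matched strategies reduce to the ratio of discordant-pair counts
(A_0, A') = (1,0) over (0,1).

``evaluate_identifying_functional`` computes the same functionals exactly at
the distribution level: expectations replace sample sums, exact eligible-set
masses replace realized draws, and expected selection counts replace
n_selected.  This is the oracle the identification suite compares against
the enumerated estimands.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dgp import DGPSpec, cohort_K, enumerate_trajectories, validate_spec
from .errors import UndefinedEstimandError, ZeroCellError
from .sampling import ControlSelection, MatchedSample, qualify_cases
from .weights import (
    PropensityMap,
    censor_at_deviation,
    cohort_time_fixed_weights,
    fit_propensity,
    time_varying_weights,
)


@dataclass
class EstimateResult:
    """A point estimate with its diagnostics."""

    scheme: str
    mode: str
    estimand_kind: str
    estimate: float | dict | None
    diagnostics: dict = field(default_factory=dict)
    provenance: str = "sample-level"
    reason: str | None = None

    def to_record(self) -> dict:
        return {
            "scheme": self.scheme, "mode": self.mode,
            "estimand_kind": self.estimand_kind, "estimate": self.estimate,
            "provenance": self.provenance, "reason": self.reason,
            "diagnostics": {
                k: (v if not isinstance(v, np.generic) else v.item())
                for k, v in self.diagnostics.items()
            },
        }


def weighted_exposure_odds(exposures, weights, cell: str = "") -> float:
    """Sum w over exposed divided by sum w over unexposed."""
    a = np.asarray(exposures, dtype=float)
    w = np.asarray(weights, dtype=float)
    num = float(np.sum(w * (a == 1)))
    den = float(np.sum(w * (a == 0)))
    if num <= 0.0:
        raise ZeroCellError(f"zero weighted exposed cell {cell!r}")
    if den <= 0.0:
        raise ZeroCellError(f"zero weighted unexposed cell {cell!r}")
    return num / den


# ---------------------------------------------------------------------------
# sample-level estimators
# ---------------------------------------------------------------------------


def _case_mask(cohort: pd.DataFrame, mode: str) -> np.ndarray:
    ids = set(qualify_cases(cohort, mode)["subject_id"])
    return cohort["subject_id"].isin(ids).to_numpy()


def estimate_case_base_rr(
    cohort: pd.DataFrame,
    selection: ControlSelection,
    propensity_map: PropensityMap | None = None,
) -> EstimateResult:
    """Case-base strategy for the marginal ITT risk ratio."""
    ctrl = selection.S.astype(bool)
    if propensity_map is None:
        propensity_map = fit_propensity(
            cohort.loc[ctrl], ["L_0"], exposure_col="A_0"
        )
    W = cohort_time_fixed_weights(cohort, propensity_map)
    cases = _case_mask(cohort, "ITT")
    a0 = cohort["A_0"].to_numpy(dtype=float)
    case_odds = weighted_exposure_odds(a0[cases], W[cases], "cases")
    ctrl_odds = weighted_exposure_odds(a0[ctrl], W[ctrl], "controls")
    return EstimateResult(
        scheme="case-base", mode="ITT", estimand_kind="marginal-RR",
        estimate=case_odds / ctrl_odds,
        diagnostics={
            "n_cases": int(cases.sum()), "n_controls": int(ctrl.sum()),
            "case_odds": case_odds, "control_odds": ctrl_odds,
            "weighted_cells": {
                "case_exposed": float(np.sum(W[cases & (a0 == 1)])),
                "case_unexposed": float(np.sum(W[cases & (a0 == 0)])),
                "control_exposed": float(np.sum(W[ctrl & (a0 == 1)])),
                "control_unexposed": float(np.sum(W[ctrl & (a0 == 0)])),
            },
        },
    )


def estimate_survivor_or(
    cohort: pd.DataFrame,
    selection: ControlSelection,
    stratified: bool = True,
) -> EstimateResult:
    """Survivor strategy: exposure odds ratio cases vs surviving controls,
    per L_0 stratum (or crude/marginal when stratified=False — the
    rare-event approximation to the marginal risk ratio)."""
    ctrl = selection.S.astype(bool)
    cases = _case_mask(cohort, "ITT")
    a0 = cohort["A_0"].to_numpy(dtype=float)
    l0 = cohort["L_0"].to_numpy(dtype=float).astype(int)
    if not stratified:
        est = weighted_exposure_odds(
            a0[cases], np.ones(cases.sum()), "cases"
        ) / weighted_exposure_odds(a0[ctrl], np.ones(ctrl.sum()), "controls")
        return EstimateResult(
            "survivor", "ITT", "marginal-OR-approx", est,
            diagnostics={"n_cases": int(cases.sum()),
                         "n_controls": int(ctrl.sum())},
        )
    out: dict = {}
    flagged = []
    for l in sorted(set(l0)):
        m = l0 == l
        try:
            out[l] = weighted_exposure_odds(
                a0[cases & m], np.ones((cases & m).sum()), f"cases L0={l}"
            ) / weighted_exposure_odds(
                a0[ctrl & m], np.ones((ctrl & m).sum()), f"controls L0={l}"
            )
        except ZeroCellError as exc:
            out[l] = None
            flagged.append((l, str(exc)))
    return EstimateResult(
        "survivor", "ITT", "conditional-OR-given-L0", out,
        diagnostics={"n_cases": int(cases.sum()),
                     "n_controls": int(ctrl.sum()), "flagged": flagged},
    )


def estimate_risk_set_hr_itt(
    cohort: pd.DataFrame,
    selection: ControlSelection,
    propensity_map: PropensityMap | None = None,
    propensity_source: str = "window0",
) -> EstimateResult:
    """Risk-set strategy for the marginal ITT hazard ratio.

    Weights follow the time-fixed form with selection at window 0 as the
    conditioning event (``propensity_source="window0"``, the literal
    reading); ``"pooled"`` fits on all ever-selected controls, each weighted
    by its selection count (a documented deviation).
    """
    n_sel = selection.n_selected
    ever = n_sel > 0
    if propensity_map is None:
        if propensity_source == "window0":
            sub = selection.S_k[:, 0].astype(bool)
            if not sub.any():
                raise ZeroCellError("no controls selected at window 0")
            propensity_map = fit_propensity(
                cohort.loc[sub], ["L_0"], exposure_col="A_0"
            )
        elif propensity_source == "pooled":
            sub = cohort.loc[ever].copy()
            sub["_w"] = n_sel[ever]
            propensity_map = fit_propensity(
                sub, ["L_0"], exposure_col="A_0", weight_col="_w"
            )
        else:
            raise ValueError(f"unknown propensity_source {propensity_source!r}")
    W = cohort_time_fixed_weights(cohort, propensity_map)
    cases = _case_mask(cohort, "ITT")
    a0 = cohort["A_0"].to_numpy(dtype=float)
    case_odds = weighted_exposure_odds(a0[cases], W[cases], "cases")
    ctrl_odds = weighted_exposure_odds(
        a0[ever], W[ever] * n_sel[ever], "controls"
    )
    return EstimateResult(
        "risk-set", "ITT", "marginal-HR-ITT", case_odds / ctrl_odds,
        diagnostics={
            "n_cases": int(cases.sum()),
            "n_controls_ever": int(ever.sum()),
            "total_selections": int(n_sel.sum()),
            "propensity_source": propensity_source,
        },
    )


def estimate_risk_set_hr_pp(
    cohort: pd.DataFrame,
    selection: ControlSelection,
    propensity_maps: list | None = None,
) -> EstimateResult:
    """Risk-set strategy for the per-protocol (always-vs-never) hazard ratio.

    Time-varying weights W_k are derived from controls selected in window k
    (propensity to switch given full history among the event-free), every
    subject is censored from its first protocol deviation, cases take the
    weight of their event window, and controls the weighted selection count
    sum_k W_k S_k over uncensored windows.
    """
    K = cohort_K(cohort)
    if propensity_maps is None:
        propensity_maps = []
        for j in range(K):
            sub = selection.S_k[:, j].astype(bool)
            if not sub.any():
                raise ZeroCellError(f"no controls selected at window {j}")
            df = cohort.loc[sub]
            cols = [f"L_{i}" for i in range(j + 1)] + [f"A_{i}" for i in range(j)]
            propensity_maps.append(
                fit_propensity(df, cols, exposure_col=f"A_{j}")
            )
    cc = censor_at_deviation(cohort)
    censor = cc["censor_time"].to_numpy(dtype=float)
    t = cohort["T"].to_numpy(dtype=float)
    a0 = cohort["A_0"].to_numpy(dtype=float)

    # per-subject weight paths, cached on the discrete history
    cache: dict = {}
    Wmat = np.full((len(cohort), K), np.nan)
    records = cohort.to_dict("records")
    for i, row in enumerate(records):
        key = tuple(
            (None if isinstance(v := row[f"L_{k}"], float) and np.isnan(v) else v)
            for k in range(K)
        ) + tuple(
            (None if isinstance(v := row[f"A_{k}"], float) and np.isnan(v) else v)
            for k in range(K)
        ) + (row["T"],)
        if key not in cache:
            cache[key] = time_varying_weights(row, propensity_maps, K)
        Wmat[i] = cache[key]

    pp_cases = np.isfinite(t) & (censor > t)
    case_w = np.array(
        [Wmat[i, int(t[i])] if pp_cases[i] else np.nan for i in range(len(cohort))]
    )
    ctrl_w = np.nansum(np.where(selection.S_k > 0, Wmat, 0.0), axis=1)
    ever = ctrl_w > 0
    case_odds = weighted_exposure_odds(
        a0[pp_cases], case_w[pp_cases], "PP cases"
    )
    ctrl_odds = weighted_exposure_odds(a0[ever], ctrl_w[ever], "PP controls")
    return EstimateResult(
        "risk-set", "PP", "marginal-HR-PP", case_odds / ctrl_odds,
        diagnostics={
            "n_cases": int(pp_cases.sum()),
            "n_controls_contributing": int(ever.sum()),
            "n_censored": int(np.isfinite(censor).sum()),
        },
    )


def estimate_matched_ratio(matched: MatchedSample) -> EstimateResult:
    """Discordant-pair ratio: #(A_0, A') = (1,0) over #(0,1).

    Concordant pairs are counted in diagnostics but unused.  With no (0,1)
    pairs (or no discordant pairs at all) the estimate is undefined and the
    reason is carried on the result.
    """
    counts = {(1, 0): 0, (0, 1): 0, (1, 1): 0, (0, 0): 0}
    for s in matched:
        counts[(s.case_exposure, s.control_exposure)] += 1
    diag = {
        "pairs_10": counts[(1, 0)], "pairs_01": counts[(0, 1)],
        "pairs_11": counts[(1, 1)], "pairs_00": counts[(0, 0)],
        "dropped_cases": len(getattr(matched, "dropped", [])),
    }
    scheme = getattr(matched, "scheme", "matched")
    mode = getattr(matched, "mode", "ITT")
    if counts[(1, 0)] + counts[(0, 1)] == 0:
        return EstimateResult(scheme, mode, "matched-ratio", None,
                              diagnostics=diag, reason="no discordant pairs")
    if counts[(0, 1)] == 0:
        return EstimateResult(scheme, mode, "matched-ratio", None,
                              diagnostics=diag, reason="zero (0,1) pairs")
    return EstimateResult(
        scheme, mode, "matched-ratio", counts[(1, 0)] / counts[(0, 1)],
        diagnostics=diag,
    )


# ---------------------------------------------------------------------------
# distribution-level functionals (exact oracle)
# ---------------------------------------------------------------------------


def _fsum(pairs) -> float:
    return math.fsum(pairs)


def _atom_censor(atom) -> float:
    """First window with a protocol deviation (inf when adherent)."""
    for j in range(1, len(atom.a)):
        if atom.a[j] != atom.a[0]:
            return float(j)
    return math.inf


def _exact_l0_propensity(atoms, restrict=None) -> dict:
    """Pr(A_0 = 1 | L_0 = l) among ``restrict`` (default: everyone)."""
    keep = restrict if restrict is not None else (lambda a: True)
    num: dict = {}
    den: dict = {}
    for a in atoms:
        if keep(a):
            den[a.l[0]] = den.get(a.l[0], 0.0) + a.p
            if a.a[0] == 1:
                num[a.l[0]] = num.get(a.l[0], 0.0) + a.p
    return {l: num.get(l, 0.0) / m for l, m in den.items() if m > 0.0}


def _exact_switch_propensities(atoms, K: int) -> list:
    """p_j(L_0..L_j, A_0..A_{j-1}) = Pr(A_j = 1 | history, Y_j = 0)."""
    maps: list = []
    for j in range(K):
        num: dict = {}
        den: dict = {}
        for a in atoms:
            if a.t is not None and a.t < j:
                continue  # not at risk at j
            key = a.l[: j + 1] + a.a[:j]
            den[key] = den.get(key, 0.0) + a.p
            if a.a[j] == 1:
                num[key] = num.get(key, 0.0) + a.p
        maps.append({k: num.get(k, 0.0) / m for k, m in den.items() if m > 0.0})
    return maps


def _tf_weight(atom, p_l0: dict) -> float:
    p = p_l0[atom.l[0]]
    if not (0.0 < p < 1.0):
        raise UndefinedEstimandError(
            f"exact propensity degenerate ({p}) at L_0={atom.l[0]}"
        )
    return atom.a[0] / p + (1 - atom.a[0]) / (1 - p)


def _tv_weights(atom, pmaps) -> list:
    """W_j along an atom's adherent at-risk windows (list padded with None)."""
    out = [None] * len(pmaps)
    w = 1.0
    censor = _atom_censor(atom)
    for j in range(len(atom.a)):
        if j >= censor:
            break
        p = pmaps[j].get(atom.l[: j + 1] + atom.a[:j])
        if p is None or not (0.0 < p < 1.0):
            raise UndefinedEstimandError(
                f"exact switch propensity degenerate at window {j}"
            )
        w *= atom.a[j] / p + (1 - atom.a[j]) / (1 - p)
        out[j] = w
    return out


def _odds_from_cells(c1: float, c0: float, what: str) -> float:
    if c1 <= 0.0 or c0 <= 0.0:
        raise ZeroCellError(f"zero mass cell in {what} ({c1}, {c0})")
    return c1 / c0


def _per_window_fractions(atoms, K: int, mode: str, m_per_case: int) -> dict:
    """Expected per-window sampling fraction of the fixed-m-per-case design:
    m * Pr(case event in window k) / Pr(risk set at k)."""
    out = {}
    for k in range(K):
        at_risk = _fsum(a.p for a in atoms if a.t is None or a.t >= k)
        if mode == "PP":
            ev = _fsum(
                a.p for a in atoms if a.t == k and _atom_censor(a) > k
            )
        else:
            ev = _fsum(a.p for a in atoms if a.t == k)
        out[k] = m_per_case * ev / at_risk if at_risk > 0.0 else 0.0
    return out


def evaluate_identifying_functional(
    spec: DGPSpec,
    scheme: str,
    mode: str = "ITT",
    matched: bool = False,
    control_source: str | None = None,
    sampling_model: str = "constant",
    m_per_case: int = 1,
    weight_mode: str = "time-varying",
    stratified: bool = True,
) -> EstimateResult:
    """Exact (distribution-level) value of a sampling scheme's identifying
    functional, evaluated on the enumerated observed-data law.

    ``control_source="survivor"`` feeds survivor-only controls into the
    case-base functional (an assumption-violation probe).
    ``sampling_model`` sets the per-window risk-set sampling fractions:
    ``"constant"`` is the identification results' literal design assumption (the fraction
    cancels in the odds ratio); ``"per-case"`` uses the expected fractions of
    the fixed-m-per-case design.  ``weight_mode="time-fixed"`` runs the PP
    functional with baseline-only weights (a time-varying-confounding probe).
    """
    if not spec.validated:
        spec = validate_spec(spec)
    atoms = enumerate_trajectories(spec)
    K = spec.K

    if matched:
        return _matched_functional(atoms, K, scheme, mode)

    if scheme == "case-base":
        ctrl = (
            (lambda a: a.t is None)
            if control_source == "survivor"
            else (lambda a: True)
        )
        p_l0 = _exact_l0_propensity(atoms, restrict=ctrl)
        num = _odds_from_cells(
            _fsum(a.p * _tf_weight(a, p_l0) for a in atoms if a.event and a.a[0] == 1),
            _fsum(a.p * _tf_weight(a, p_l0) for a in atoms if a.event and a.a[0] == 0),
            "case-base cases",
        )
        den = _odds_from_cells(
            _fsum(a.p * _tf_weight(a, p_l0) for a in atoms if ctrl(a) and a.a[0] == 1),
            _fsum(a.p * _tf_weight(a, p_l0) for a in atoms if ctrl(a) and a.a[0] == 0),
            "case-base controls",
        )
        return EstimateResult(
            "case-base", "ITT", "marginal-RR", num / den,
            provenance="distribution-level",
            diagnostics={"control_source": control_source or "case-base"},
        )

    if scheme == "survivor":
        if not stratified:
            num = _odds_from_cells(
                _fsum(a.p for a in atoms if a.event and a.a[0] == 1),
                _fsum(a.p for a in atoms if a.event and a.a[0] == 0),
                "survivor cases",
            )
            den = _odds_from_cells(
                _fsum(a.p for a in atoms if a.t is None and a.a[0] == 1),
                _fsum(a.p for a in atoms if a.t is None and a.a[0] == 0),
                "survivor controls",
            )
            return EstimateResult(
                "survivor", "ITT", "marginal-OR-approx", num / den,
                provenance="distribution-level",
            )
        out: dict = {}
        for l in spec.covariate_space:
            num = _odds_from_cells(
                _fsum(a.p for a in atoms if a.event and a.a[0] == 1 and a.l[0] == l),
                _fsum(a.p for a in atoms if a.event and a.a[0] == 0 and a.l[0] == l),
                f"survivor cases L0={l}",
            )
            den = _odds_from_cells(
                _fsum(a.p for a in atoms if a.t is None and a.a[0] == 1 and a.l[0] == l),
                _fsum(a.p for a in atoms if a.t is None and a.a[0] == 0 and a.l[0] == l),
                f"survivor controls L0={l}",
            )
            out[l] = num / den
        return EstimateResult(
            "survivor", "ITT", "conditional-OR-given-L0", out,
            provenance="distribution-level",
        )

    if scheme == "risk-set" and mode == "ITT":
        p_l0 = _exact_l0_propensity(
            atoms, restrict=lambda a: True  # S_0: everyone is at risk at t_0
        )
        if sampling_model == "constant":
            frac = {k: 1.0 for k in range(K)}
        elif sampling_model == "per-case":
            frac = _per_window_fractions(atoms, K, "ITT", m_per_case)
        else:
            raise ValueError(f"unknown sampling_model {sampling_model!r}")

        def exp_count(a):  # E[sum_k S_k | trajectory]
            return _fsum(frac[k] for k in range(a.n_at_risk_windows(K)))

        num = _odds_from_cells(
            _fsum(a.p * _tf_weight(a, p_l0) for a in atoms if a.event and a.a[0] == 1),
            _fsum(a.p * _tf_weight(a, p_l0) for a in atoms if a.event and a.a[0] == 0),
            "risk-set ITT cases",
        )
        den = _odds_from_cells(
            _fsum(a.p * _tf_weight(a, p_l0) * exp_count(a) for a in atoms if a.a[0] == 1),
            _fsum(a.p * _tf_weight(a, p_l0) * exp_count(a) for a in atoms if a.a[0] == 0),
            "risk-set ITT controls",
        )
        return EstimateResult(
            "risk-set", "ITT", "marginal-HR-ITT", num / den,
            provenance="distribution-level",
            diagnostics={"sampling_model": sampling_model,
                         "fractions": frac},
        )

    if scheme == "risk-set" and mode == "PP":
        pmaps = _exact_switch_propensities(atoms, K)
        if sampling_model == "constant":
            frac = {k: 1.0 for k in range(K)}
        elif sampling_model == "per-case":
            frac = _per_window_fractions(atoms, K, "PP", m_per_case)
        else:
            raise ValueError(f"unknown sampling_model {sampling_model!r}")
        p_l0 = _exact_l0_propensity(atoms) if weight_mode == "time-fixed" else None

        num_cells = [0.0, 0.0]
        den_cells = [0.0, 0.0]
        for a in atoms:
            censor = _atom_censor(a)
            if weight_mode == "time-varying":
                W = _tv_weights(a, pmaps)
            else:  # baseline-only weights: ignore time-varying confounding
                w0 = _tf_weight(a, p_l0)
                W = [
                    (w0 if j < censor and (a.t is None or j <= a.t) else None)
                    for j in range(K)
                ]
            if a.event and censor > a.t:
                num_cells[a.a[0]] += a.p * W[a.t]
            # control contributions over uncensored at-risk windows
            nk = a.n_at_risk_windows(K)
            contrib = _fsum(
                W[j] * frac[j] for j in range(nk) if j < censor and W[j] is not None
            )
            den_cells[a.a[0]] += a.p * contrib
        num = _odds_from_cells(num_cells[1], num_cells[0], "risk-set PP cases")
        den = _odds_from_cells(den_cells[1], den_cells[0], "risk-set PP controls")
        return EstimateResult(
            "risk-set", "PP", "marginal-HR-PP", num / den,
            provenance="distribution-level",
            diagnostics={"sampling_model": sampling_model,
                         "weight_mode": weight_mode},
        )

    raise ValueError(f"unknown scheme/mode {scheme!r}/{mode!r}")


def _matched_functional(atoms, K: int, scheme: str, mode: str) -> EstimateResult:
    """Exact discordant-pair probabilities: integrate over the case law and
    the matched pool's exposure composition."""
    pairs = {(1, 0): 0.0, (0, 1): 0.0, (1, 1): 0.0, (0, 0): 0.0}

    if scheme in ("case-base", "survivor"):
        restrict = (lambda a: True) if scheme == "case-base" else (lambda a: a.t is None)
        p_pool = _exact_l0_propensity(atoms, restrict=restrict)
        for a in atoms:
            if not a.event:
                continue
            pa = p_pool.get(a.l[0])
            if pa is None:
                continue
            x = a.a[0]
            pairs[(x, 1)] += a.p * pa
            pairs[(x, 0)] += a.p * (1.0 - pa)
    elif scheme == "risk-set" and mode == "ITT":
        # pool at (k, l0): subjects event-free at t_k with matching L_0
        p_pool = {
            k: _exact_l0_propensity(
                atoms, restrict=lambda a, k=k: a.t is None or a.t >= k
            )
            for k in range(K)
        }
        for a in atoms:
            if not a.event:
                continue
            pa = p_pool[a.t].get(a.l[0])
            if pa is None:
                continue
            x = a.a[0]
            pairs[(x, 1)] += a.p * pa
            pairs[(x, 0)] += a.p * (1.0 - pa)
    elif scheme == "risk-set" and mode == "PP":
        # pool at (k, L_0..L_k): adherent, event-free at t_k, matching history
        pool_mass: dict = {}
        for a in atoms:
            censor = _atom_censor(a)
            nk = a.n_at_risk_windows(K)
            for k in range(nk):
                if k >= censor:
                    break
                key = (k, a.l[: k + 1])
                cell = pool_mass.setdefault(key, [0.0, 0.0])
                cell[a.a[0]] += a.p
        for a in atoms:
            censor = _atom_censor(a)
            if not (a.event and censor > a.t):
                continue
            cell = pool_mass.get((a.t, a.l[: a.t + 1]))
            if cell is None or (cell[0] + cell[1]) <= 0.0:
                continue
            pa = cell[1] / (cell[0] + cell[1])
            x = a.a[0]
            pairs[(x, 1)] += a.p * pa
            pairs[(x, 0)] += a.p * (1.0 - pa)
    else:
        raise ValueError(f"unknown matched scheme/mode {scheme!r}/{mode!r}")

    diag = {f"pair_{x}{y}": v for (x, y), v in pairs.items()}
    if pairs[(0, 1)] <= 0.0:
        return EstimateResult(
            scheme, mode, "matched-ratio", None, diagnostics=diag,
            provenance="distribution-level", reason="zero (0,1) pair mass",
        )
    return EstimateResult(
        scheme, mode, "matched-ratio", pairs[(1, 0)] / pairs[(0, 1)],
        diagnostics=diag, provenance="distribution-level",
    )
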