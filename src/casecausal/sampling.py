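"""Case qualification and control-sampling schemes.

Three classical schemes for drawing controls in a case-control study nested
in a fixed cohort:

* **case-base** (case-cohort): controls drawn uniformly from the whole
  baseline cohort, ignoring covariates, exposure and survival;
* **survivor** (cumulative-incidence): controls drawn uniformly from the
  subjects who reach the administrative end event-free (Y_K = 0);
* **risk-set** (incidence-density): for each incident case with event in
  window k, controls drawn uniformly from the subjects event-free at t_k;
  a subject may be selected as a control more than once, and a case may
  serve as a control in a window before its own event.

A subject qualifies as a case iff it sustains the event by t_K and, for
per-protocol analyses, adhered to a constant-exposure protocol until the
incident event.  When a protocol deviation falls in the event window itself,
the tie is resolved by ``deviation_policy``: the default ``"qualify"`` counts
the subject as a case (the event is not attributed to the contemporaneous
deviation), while ``"censor"`` treats the deviation as preceding the event —
the convention the weighting analysis uses, since censoring removes the
whole deviation window.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dgp import cohort_K
from .errors import SamplingInfeasibleError
from .weights import censor_at_deviation

logger = logging.getLogger(__name__)


@dataclass
class ControlSelection:
    """Outcome of a control-sampling run."""

    scheme: str  # case-base | survivor | risk-set
    mode: str  # ITT | PP
    S: np.ndarray | None = None  # per-subject indicator (single-draw schemes)
    S_k: np.ndarray | None = None  # (n, K) per-window indicators (risk-set)
    n_selected: np.ndarray | None = None  # per-subject sum_k S_k
    sampling_fractions: dict = field(default_factory=dict)
    links: pd.DataFrame | None = None  # case_id, window, control_id
    seed: int | None = None
    design: str | None = None

    def selection_frame(self, cohort: pd.DataFrame) -> pd.DataFrame:
        """Selection output as a flat table (CSV-ready)."""
        rows = []
        ids = cohort["subject_id"].to_numpy()
        if self.S is not None:
            for i, sid in enumerate(ids):
                rows.append(
                    {"subject_id": sid, "scheme": self.scheme, "mode": self.mode,
                     "window": -1, "selected": int(self.S[i])}
                )
        if self.S_k is not None:
            for k in range(self.S_k.shape[1]):
                for i, sid in enumerate(ids):
                    rows.append(
                        {"subject_id": sid, "scheme": self.scheme,
                         "mode": self.mode, "window": k,
                         "selected": int(self.S_k[i, k])}
                    )
        return pd.DataFrame(rows)


@dataclass
class MatchedSet:
    """A case and its single matched control exposure A'."""

    case_id: int
    case_window: int | None
    case_exposure: int
    control_exposure: int
    control_id: int
    match_key: tuple


@dataclass
class MatchedSample:
    """Matched sets plus bookkeeping of cases dropped for empty pools."""

    sets: list
    dropped: list  # (case_id, match_key)
    scheme: str = ""
    mode: str = ""

    def __iter__(self):
        return iter(self.sets)

    def __len__(self):
        return len(self.sets)

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {"case_id": s.case_id, "case_window": s.case_window,
                 "case_exposure": s.case_exposure,
                 "control_exposure": s.control_exposure,
                 "control_id": s.control_id, "match_key": str(s.match_key)}
                for s in self.sets
            ]
        )


# ---------------------------------------------------------------------------
# qualification and eligibility
# ---------------------------------------------------------------------------


def _with_censor(cohort: pd.DataFrame) -> pd.DataFrame:
    if "censor_time" not in cohort.columns:
        return censor_at_deviation(cohort)
    return cohort


def qualify_cases(
    cohort: pd.DataFrame, mode: str, deviation_policy: str = "qualify"
) -> pd.DataFrame:
    """Subjects qualifying as cases, with their event windows.

    ITT: everyone with the event by t_K (Y_K = 1).  PP: additionally the
    exposure must be constant over the at-risk windows before the incident
    event; ``deviation_policy`` resolves deviations in the event window
    itself (see module docstring).
    """
    K = cohort_K(cohort)
    t = cohort["T"].to_numpy(dtype=float)
    has_event = np.isfinite(t) & (t < K)
    if mode == "ITT":
        mask = has_event
    elif mode == "PP":
        cc = _with_censor(cohort)
        censor = cc["censor_time"].to_numpy(dtype=float)
        if deviation_policy == "qualify":
            mask = has_event & (censor >= t)
        elif deviation_policy == "censor":
            mask = has_event & (censor > t)
        else:
            raise ValueError(f"unknown deviation_policy {deviation_policy!r}")
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return pd.DataFrame(
        {
            "subject_id": cohort.loc[mask, "subject_id"].to_numpy(),
            "event_window": t[mask].astype(int),
        }
    )


def eligible_controls(
    cohort: pd.DataFrame, k: int, scheme: str, mode: str = "ITT"
) -> list:
    """Subject ids eligible for selection as a control.

    * risk-set, ITT: event-free at t_k (cases included before their own
      event — a subject may be selected as a control more than once);
    * risk-set, PP: additionally uncensored through window k (no protocol
      deviation at or before t_k), since censored windows contribute nothing
      to the weighted analysis;
    * case-base: the whole baseline cohort, k ignored;
    * survivor: event-free at t_K, k ignored.
    """
    K = cohort_K(cohort)
    t = cohort["T"].to_numpy(dtype=float)
    if scheme == "case-base":
        mask = np.ones(len(cohort), dtype=bool)
    elif scheme == "survivor":
        mask = ~np.isfinite(t)
    elif scheme == "risk-set":
        if not (0 <= k <= K - 1):
            raise ValueError(f"window {k} outside 0..{K - 1}")
        mask = t >= k
        if mode == "PP":
            cc = _with_censor(cohort)
            mask = mask & (cc["censor_time"].to_numpy(dtype=float) > k)
    else:
        raise ValueError(f"unknown scheme {scheme!r}")
    return sorted(cohort.loc[mask, "subject_id"].tolist())


# ---------------------------------------------------------------------------
# unmatched sampling
# ---------------------------------------------------------------------------


def sample_case_base_controls(
    cohort: pd.DataFrame, n_controls: int, seed: int
) -> ControlSelection:
    """Uniform draw without replacement from the whole baseline cohort."""
    n = len(cohort)
    if n_controls > n:
        raise ValueError(f"n_controls={n_controls} exceeds cohort size {n}")
    rng = np.random.default_rng(seed)
    S = np.zeros(n, dtype=np.int64)
    S[rng.choice(n, size=n_controls, replace=False)] = 1
    return ControlSelection(
        scheme="case-base", mode="ITT", S=S, n_selected=S.copy(),
        sampling_fractions={"overall": n_controls / n}, seed=seed,
    )


def sample_survivor_controls(
    cohort: pd.DataFrame, n_controls: int, seed: int
) -> ControlSelection:
    """Uniform draw without replacement among survivors (Y_K = 0)."""
    t = cohort["T"].to_numpy(dtype=float)
    pool = np.flatnonzero(~np.isfinite(t))
    if len(pool) < n_controls:
        raise SamplingInfeasibleError(
            f"only {len(pool)} survivors for {n_controls} controls"
        )
    rng = np.random.default_rng(seed)
    S = np.zeros(len(cohort), dtype=np.int64)
    S[rng.choice(pool, size=n_controls, replace=False)] = 1
    return ControlSelection(
        scheme="survivor", mode="ITT", S=S, n_selected=S.copy(),
        sampling_fractions={"overall": n_controls / len(pool)}, seed=seed,
    )



def sample_risk_set_controls(
    cohort: pd.DataFrame,
    m_per_case: int,
    mode: str,
    seed: int,
    design: str = "per-case",
    fraction: float | None = None,
    exclude_index_case: bool = True,
) -> ControlSelection:
    """Risk-set control selection.

    design="per-case": for each qualifying case with event in window k, draw
    ``m_per_case`` subjects uniformly without replacement from the window-k
    risk set (event-free at t_k); the index case is excluded from its own
    draw by default but remains in the eligible set for other cases.

    design="bernoulli": every risk-set member is selected independently with
    probability ``fraction`` in every window — the constant-sampling-
    probability design the identification results assume literally.

    Selection is drawn from the plain risk set (Y_k = 0) in both modes; in PP
    analyses, censoring is applied downstream, and selected subject-windows
    past a protocol deviation contribute only to propensity estimation, never
    to the weighted odds.  S_k stays binary; per-(case, control) links are
    kept separately.
    """
    K = cohort_K(cohort)
    n = len(cohort)
    t = cohort["T"].to_numpy(dtype=float)
    ids = cohort["subject_id"].to_numpy()
    pos = {sid: i for i, sid in enumerate(ids)}
    rng = np.random.default_rng(seed)
    policy = "censor" if mode == "PP" else "qualify"
    cases = qualify_cases(cohort, mode, deviation_policy=policy)

    S_k = np.zeros((n, K), dtype=np.int64)
    link_rows = []
    fractions: dict = {}
    risk_sets = {k: np.flatnonzero(t >= k) for k in range(K)}

    if design == "per-case":
        for k, grp in cases.groupby("event_window"):
            pool = risk_sets[int(k)]
            n_cases = len(grp)
            for cid in grp["subject_id"]:
                i = pos[cid]
                effective = len(pool) - (1 if exclude_index_case else 0)
                if effective < m_per_case:
                    raise SamplingInfeasibleError(
                        f"window {int(k)}: eligible set of size "
                        f"{effective} < m_per_case={m_per_case}"
                    )
                drawn = None
                if effective > 4 * m_per_case:
                    # rejection sampling: avoids copying the pool per case
                    for _ in range(64):
                        cand = pool[
                            rng.integers(0, len(pool), size=2 * m_per_case + 8)
                        ]
                        if exclude_index_case:
                            cand = cand[cand != i]
                        uniq = pd.unique(cand)
                        if len(uniq) >= m_per_case:
                            drawn = uniq[:m_per_case]
                            break
                if drawn is None:
                    this_pool = (
                        pool[pool != i] if exclude_index_case else pool
                    )
                    drawn = rng.choice(this_pool, m_per_case, replace=False)
                S_k[drawn, int(k)] = 1
                for d in drawn:
                    link_rows.append(
                        {"case_id": cid, "window": int(k),
                         "control_id": ids[d]}
                    )
            fractions[int(k)] = m_per_case * n_cases / max(len(pool), 1)
    elif design == "bernoulli":
        if fraction is None or not (0.0 < fraction <= 1.0):
            raise ValueError("bernoulli design requires fraction in (0, 1]")
        for k in range(K):
            pool = risk_sets[k]
            sel = pool[rng.random(len(pool)) < fraction]
            S_k[sel, k] = 1
            fractions[k] = fraction
    else:
        raise ValueError(f"unknown design {design!r}")

    return ControlSelection(
        scheme="risk-set", mode=mode, S_k=S_k, n_selected=S_k.sum(axis=1),
        sampling_fractions=fractions,
        links=pd.DataFrame(link_rows, columns=["case_id", "window", "control_id"]),
        seed=seed, design=design,
    )


# ---------------------------------------------------------------------------
# exact pair matching
# ---------------------------------------------------------------------------


def _match_pools(cohort: pd.DataFrame, scheme: str, mode: str, K: int) -> dict:
    """Pool membership per match key.

    case-base: all subjects keyed by L_0; survivor: survivors keyed by L_0;
    risk-set ITT: (k, L_0) over risk sets; risk-set PP: (k, L_0..L_k) over
    adherent, uncensored risk sets.
    """
    t = cohort["T"].to_numpy(dtype=float)
    l0 = cohort["L_0"].to_numpy(dtype=float).astype(int)
    pools: dict = {}
    if scheme in ("case-base", "survivor"):
        mask = (
            np.ones(len(cohort), dtype=bool)
            if scheme == "case-base"
            else ~np.isfinite(t)
        )
        for i in np.flatnonzero(mask):
            pools.setdefault((l0[i],), []).append(i)
    elif scheme == "risk-set":
        cc = _with_censor(cohort) if mode == "PP" else cohort
        censor = (
            cc["censor_time"].to_numpy(dtype=float) if mode == "PP" else None
        )
        lmat = np.column_stack(
            [cohort[f"L_{k}"].to_numpy(dtype=float) for k in range(K)]
        )
        for k in range(K):
            at_risk = t >= k
            if mode == "PP":
                at_risk = at_risk & (censor > k)
            for i in np.flatnonzero(at_risk):
                if mode == "PP":
                    key = (k,) + tuple(int(v) for v in lmat[i, : k + 1])
                else:
                    key = (k, l0[i])
                pools.setdefault(key, []).append(i)
    else:
        raise ValueError(f"unknown scheme {scheme!r}")
    return {key: np.asarray(v) for key, v in pools.items()}


def sample_matched_controls(
    cohort: pd.DataFrame,
    scheme: str,
    mode: str = "ITT",
    seed: int = 0,
    exclude_self: bool = True,
) -> MatchedSample:
    """Assign one matched control exposure A' to every qualifying case.

    The control source subject is drawn uniformly from the scheme's pool
    sharing the case's match key (L_0, or the full covariate history up to
    the event window for risk-set PP).  By default the case is excluded from
    its own pool, except when it is the pool's only member (degenerate pool:
    the case's own A_0 is returned).  Cases with an empty pool are dropped
    and logged with their match key.
    """
    if len(cohort) == 0:
        raise ValueError("cohort is empty")
    K = cohort_K(cohort)
    rng = np.random.default_rng(seed)
    policy = "censor" if mode == "PP" else "qualify"
    cases = qualify_cases(cohort, mode, deviation_policy=policy)
    pools = _match_pools(cohort, scheme, mode, K)
    ids = cohort["subject_id"].to_numpy()
    pos = {sid: i for i, sid in enumerate(ids)}
    a0 = cohort["A_0"].to_numpy(dtype=float)
    l0 = cohort["L_0"].to_numpy(dtype=float).astype(int)
    lmat = np.column_stack(
        [cohort[f"L_{k}"].to_numpy(dtype=float) for k in range(K)]
    )

    sets: list[MatchedSet] = []
    dropped: list = []
    for cid, k in zip(cases["subject_id"], cases["event_window"]):
        i = pos[cid]
        if scheme in ("case-base", "survivor"):
            key = (l0[i],)
            window = None
        elif mode == "PP":
            key = (int(k),) + tuple(int(v) for v in lmat[i, : int(k) + 1])
            window = int(k)
        else:
            key = (int(k), l0[i])
            window = int(k)
        pool = pools.get(key)
        if pool is not None and exclude_self:
            others = pool[pool != i]
            pool = others if len(others) > 0 else (pool if i in pool else others)
        if pool is None or len(pool) == 0:
            dropped.append((cid, key))
            logger.warning(
                "matched case %s dropped: empty %s pool for key %s",
                cid, scheme, key,
            )
            continue
        j = pool[rng.integers(0, len(pool))]
        sets.append(
            MatchedSet(
                case_id=int(cid), case_window=window,
                case_exposure=int(a0[i]), control_exposure=int(a0[j]),
                control_id=int(ids[j]), match_key=key,
            )
        )
    return MatchedSample(sets=sets, dropped=dropped, scheme=scheme, mode=mode)
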