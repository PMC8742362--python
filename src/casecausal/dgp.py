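"""Discrete-time structural cohort models with counterfactual ground truth.

A fixed cohort is followed from a common time zero over ``K`` half-open
windows ``[t_k, t_{k+1})``, ``k = 0..K-1``, ending at the administrative study
end ``t_K``.  While at risk (event-free at ``t_k``) a subject carries a
discrete covariate ``L_k`` and a binary exposure ``A_k``; ``Y_k = I(T < t_k)``
indicates whether the incident event has occurred by ``t_k`` (so ``Y_0 = 0``
and "event in window k" means ``Y_k = 0, Y_{k+1} = 1``).  An optional binary
unmeasured confounder ``U`` may enter the exposure and hazard laws to engineer
exchangeability violations.

The model is fully discrete, so the joint distribution of complete
trajectories can be enumerated exactly; interventional (counterfactual)
distributions are obtained by enumerating the same tree with the exposure law
replaced by a regime.  Two regime families are supported: intervening on the
baseline exposure only (``A_0 := a``, later exposures following their natural
law) and the sustained regimes "always exposed" / "never exposed"
(``A_k := a`` for all k).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Iterable, Mapping, NamedTuple

import numpy as np
import pandas as pd

from .errors import (
    EnumerationTooLargeError,
    InvalidGridError,
    InvalidProbabilityError,
    NormalizationError,
    UndefinedStratumError,
)

_PROB_TOL = 1e-12

# ---------------------------------------------------------------------------
# Regimes
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Regime:
    """An exposure intervention.

    kind="baseline": set A_0 := a, leave later exposures to their natural law.
    kind="sustained": set A_k := a for every window ("always"/"never" exposed).
    """

    kind: str
    a: int

    def forced(self, k: int) -> int | None:
        """Exposure value forced at window k, or None if natural."""
        if self.kind == "sustained":
            return self.a
        if self.kind == "baseline":
            return self.a if k == 0 else None
        raise ValueError(f"unknown regime kind {self.kind!r}")


def parse_regime(regime) -> Regime:
    """Accept Regime objects or the shorthands 'always', 'never',
    'baseline-0', 'baseline-1'."""
    if isinstance(regime, Regime):
        return regime
    table = {
        "always": Regime("sustained", 1),
        "never": Regime("sustained", 0),
        "baseline-1": Regime("baseline", 1),
        "baseline-0": Regime("baseline", 0),
    }
    try:
        return table[regime]
    except KeyError:
        raise ValueError(f"unknown regime {regime!r}") from None


# ---------------------------------------------------------------------------
# Spec
# ---------------------------------------------------------------------------

# Law signatures (u is None when the model has no unmeasured confounder):
#   init_l(u) -> {code: prob}                       distribution of L_0
#   covariate_law(k, u, l_hist, a_hist) -> {code: prob}
#       distribution of L_k (k >= 1) given L_0..L_{k-1}, A_0..A_{k-1}
#   exposure_law(k, u, l_hist, a_hist) -> Pr(A_k = 1)
#       given L_0..L_k (l_hist has length k+1) and A_0..A_{k-1}
#   hazard_law(k, u, l_hist, a_hist) -> Pr(Y_{k+1} = 1 | Y_k = 0)
#       given L_0..L_k and A_0..A_k (a_hist has length k+1)


@dataclass
class DGPSpec:
    """Structural specification of a discrete-time cohort model."""

    K: int
    covariate_space: tuple
    init_l: Callable
    exposure_law: Callable
    hazard_law: Callable
    covariate_law: Callable | None = None  # None => L is time-fixed (L_k = L_0)
    p_u: float | None = None
    include_U: bool = False
    freeze_exposure: bool = False
    constant_hazard_enforced: bool = False
    homogeneity_scale: str = "none"  # risk-ratio | odds-ratio | hazard-ratio | none
    name: str = ""
    # canonical tabulated laws, filled in by validate_spec
    tables: dict | None = field(default=None, repr=False, compare=False)

    @property
    def validated(self) -> bool:
        return self.tables is not None


class Atom(NamedTuple):
    """One complete trajectory (including U) with its probability.

    ``l`` and ``a`` cover exactly the at-risk windows: 0..t if the event
    occurs in window t, 0..K-1 for survivors (t is None).
    """

    u: int | None
    l: tuple
    a: tuple
    t: int | None
    p: float

    @property
    def event(self) -> bool:
        return self.t is not None

    def n_at_risk_windows(self, K: int) -> int:
        return self.t + 1 if self.t is not None else K


def _check_prob(p, what: str) -> float:
    p = float(p)
    if not (0.0 <= p <= 1.0) or math.isnan(p):
        raise InvalidProbabilityError(f"{what} returned {p}, outside [0, 1]")
    return p


def _check_dist(dist: Mapping, space: tuple, what: str) -> dict:
    out = {}
    total = 0.0
    for code, p in dist.items():
        if code not in space:
            raise NormalizationError(f"{what}: code {code!r} not in covariate space")
        out[code] = _check_prob(p, what)
        total += out[code]
    if abs(total - 1.0) > _PROB_TOL:
        raise NormalizationError(f"{what}: probabilities sum to {total}, not 1")
    return out


def _u_support(spec: DGPSpec) -> list[int | None]:
    if spec.include_U:
        if spec.p_u is None:
            raise InvalidProbabilityError("include_U set but p_u is None")
        return [0, 1]
    return [None]


def _u_prob(spec: DGPSpec, u) -> float:
    if u is None:
        return 1.0
    return spec.p_u if u == 1 else 1.0 - spec.p_u


def atom_bound(spec: DGPSpec) -> int:
    """Crude upper bound on the number of enumeration atoms."""
    nl = len(spec.covariate_space)
    nu = 2 if spec.include_U else 1
    l_paths = nl**spec.K if spec.covariate_law is not None else nl
    return nu * l_paths * (2**spec.K) * (spec.K + 1)


def validate_spec(spec: DGPSpec, cap: int = 10_000_000) -> DGPSpec:
    """Validate all invariants and attach a canonical, hashable tabulation of
    every law over the reachable history space.

    Raises InvalidGridError, InvalidProbabilityError or NormalizationError.
    """
    if spec.K < 1:
        raise InvalidGridError(f"K must be >= 1, got {spec.K}")
    if spec.include_U:
        _check_prob(spec.p_u, "p_u")
    space = tuple(spec.covariate_space)
    if len(space) < 1:
        raise NormalizationError("covariate space is empty")

    tables: dict = {"init_l": {}, "exposure": {}, "covariate": {}, "hazard": {}}

    def rec(u, k, lhist, ahist, reachable):
        # exposure at window k
        pa = _check_prob(
            spec.exposure_law(k, u, lhist, ahist), f"exposure_law(k={k})"
        )
        if spec.freeze_exposure and k >= 1 and pa not in (0.0, 1.0):
            raise InvalidProbabilityError(
                "freeze_exposure set but exposure_law is not deterministic "
                f"at k={k}"
            )
        if spec.freeze_exposure and k >= 1 and pa != float(ahist[0]):
            raise InvalidProbabilityError(
                f"freeze_exposure set but exposure_law(k={k}) != A_0"
            )
        tables["exposure"][(k, u, lhist, ahist)] = pa
        for a_k, pr_a in ((1, pa), (0, 1.0 - pa)):
            if pr_a <= 0.0 and not spec.freeze_exposure:
                # still tabulate hazards for unreachable arm? skip: unreachable
                pass
            anew = ahist + (a_k,)
            ph = _check_prob(
                spec.hazard_law(k, u, lhist, anew), f"hazard_law(k={k})"
            )
            tables["hazard"][(k, u, lhist, anew)] = ph
            if k + 1 < spec.K:
                if spec.covariate_law is None:
                    rec(u, k + 1, lhist + (lhist[0],), anew, reachable)
                else:
                    dist = _check_dist(
                        spec.covariate_law(k + 1, u, lhist, anew),
                        space,
                        f"covariate_law(k={k + 1})",
                    )
                    tables["covariate"][(k + 1, u, lhist, anew)] = tuple(
                        sorted(dist.items())
                    )
                    for l_next in dist:
                        rec(u, k + 1, lhist + (l_next,), anew, reachable)

    bound = atom_bound(spec)
    if bound > cap:
        raise EnumerationTooLargeError(bound, cap)

    for u in _u_support(spec):
        dist0 = _check_dist(spec.init_l(u), space, "init_l")
        tables["init_l"][u] = tuple(sorted(dist0.items()))
        for l0 in dist0:
            rec(u, 0, (l0,), (), True)

    out = replace(spec)
    out.covariate_space = space
    out.tables = tables
    return out


def canonical_form(spec: DGPSpec) -> tuple:
    """Hashable canonical representation of a validated spec's laws."""
    if spec.tables is None:
        spec = validate_spec(spec)
    t = spec.tables
    return (
        spec.K,
        spec.covariate_space,
        spec.p_u,
        tuple(sorted(t["init_l"].items(), key=repr)),
        tuple(sorted(t["exposure"].items(), key=repr)),
        tuple(sorted(t["covariate"].items(), key=repr)),
        tuple(sorted(t["hazard"].items(), key=repr)),
    )


# ---------------------------------------------------------------------------
# Exact enumeration
# ---------------------------------------------------------------------------


def enumerate_trajectories(
    spec: DGPSpec, regime: Regime | str | None = None, cap: int = 10_000_000
) -> list[Atom]:
    """Enumerate every complete trajectory (including U) with its probability.

    With ``regime`` given, the exposure law is replaced by the intervention
    (covariate and hazard laws are evaluated at the intervened exposure
    history), yielding the interventional trajectory distribution.

    Probabilities sum to 1 within 1e-12.
    """
    if not spec.validated:
        spec = validate_spec(spec, cap=cap)
    bound = atom_bound(spec)
    if bound > cap:
        raise EnumerationTooLargeError(bound, cap)
    reg = parse_regime(regime) if regime is not None else None
    space = spec.covariate_space
    atoms: list[Atom] = []

    def rec(u, k, lhist, ahist, p):
        if p == 0.0:
            return
        forced = reg.forced(k) if reg is not None else None
        if forced is None:
            pa = spec.exposure_law(k, u, lhist, ahist)
            arms = ((1, pa), (0, 1.0 - pa))
        else:
            arms = ((forced, 1.0),)
        for a_k, pr_a in arms:
            if pr_a == 0.0:
                continue
            anew = ahist + (a_k,)
            ph = spec.hazard_law(k, u, lhist, anew)
            if ph > 0.0:
                atoms.append(Atom(u, lhist, anew, k, p * pr_a * ph))
            p_surv = p * pr_a * (1.0 - ph)
            if p_surv == 0.0:
                continue
            if k + 1 == spec.K:
                atoms.append(Atom(u, lhist, anew, None, p_surv))
            elif spec.covariate_law is None:
                rec(u, k + 1, lhist + (lhist[0],), anew, p_surv)
            else:
                dist = spec.covariate_law(k + 1, u, lhist, anew)
                for l_next, pl in dist.items():
                    if pl > 0.0:
                        rec(u, k + 1, lhist + (l_next,), anew, p_surv * pl)

    for u in _u_support(spec):
        pu = _u_prob(spec, u)
        if pu == 0.0:
            continue
        for l0, pl0 in spec.init_l(u).items():
            if pl0 > 0.0:
                rec(u, 0, (l0,), (), pu * pl0)

    total = math.fsum(a.p for a in atoms)
    if abs(total - 1.0) > _PROB_TOL:  # pragma: no cover - guarded by validate
        raise NormalizationError(f"enumerated probabilities sum to {total}")
    return atoms


def _stratum_mask(atoms: Iterable[Atom], conditioning) -> Callable[[Atom], bool]:
    """Build an atom filter for 'marginal', ('L0', l) or ('history', prefix)."""
    if conditioning in (None, "marginal"):
        return lambda atom: True
    kind, value = conditioning
    if kind == "L0":
        return lambda atom: atom.l[0] == value
    if kind == "history":
        prefix = tuple(value)

        def match(atom: Atom) -> bool:
            return atom.l[: len(prefix)] == prefix

        return match
    raise ValueError(f"unknown conditioning {conditioning!r}")


def interventional_distribution(
    spec: DGPSpec, regime, conditioning="marginal"
) -> dict:
    """Per-index event probabilities and per-window discrete-time hazards
    under an exposure regime, computed by exact enumeration of the intervened
    model.

    Returns ``{"risk": {k: Pr(Y_k(.) = 1)} for k = 1..K,
               "hazard": {k: Pr(Y_{k+1}(.) = 1 | Y_k(.) = 0)} for k = 0..K-1}``.
    Hazards at windows with an empty risk set are None.
    """
    if not spec.validated:
        spec = validate_spec(spec)
    atoms = enumerate_trajectories(spec, regime=regime)
    keep = _stratum_mask(atoms, conditioning)
    sel = [a for a in atoms if keep(a)]
    mass = math.fsum(a.p for a in sel)
    if mass <= 0.0:
        raise UndefinedStratumError(
            f"conditioning stratum {conditioning!r} has zero probability"
        )
    # For 'history' conditioning the prefix restricts the covariate path; the
    # stratum is only well-defined for windows the prefix covers.
    risk = {}
    hazard = {}
    for k in range(spec.K):
        at_risk = math.fsum(a.p for a in sel if a.t is None or a.t >= k)
        events = math.fsum(a.p for a in sel if a.t == k)
        hazard[k] = (events / at_risk) if at_risk > 0.0 else None
        cum = math.fsum(a.p for a in sel if a.t is not None and a.t <= k)
        risk[k + 1] = cum / mass
    return {"risk": risk, "hazard": hazard, "mass": mass}


# ---------------------------------------------------------------------------
# Simulation
# ---------------------------------------------------------------------------


def _categorical_draw(dist: dict, codes: tuple, u: np.ndarray) -> np.ndarray:
    """Inverse-CDF draw from a single discrete distribution for all rows."""
    probs = np.array([dist.get(c, 0.0) for c in codes])
    cum = np.cumsum(probs)
    idx = np.searchsorted(cum, u, side="right")
    idx = np.minimum(idx, len(codes) - 1)
    return np.asarray(codes)[idx]


def _grouped_apply(keys: list[tuple], fn) -> np.ndarray:
    """Evaluate ``fn(key)`` once per distinct key and broadcast (laws are
    deterministic functions of the discrete history, so this is exact)."""
    cache: dict = {}
    out = np.empty(len(keys), dtype=object)
    for i, key in enumerate(keys):
        if key not in cache:
            cache[key] = fn(key)
        out[i] = cache[key]
    return out


REGIME_COLUMNS = {
    "baseline-0": "b0",
    "baseline-1": "b1",
    "always": "s1",
    "never": "s0",
}


def _simulate_path(spec, n, U, uL, uA, uY, regime: Regime | None):
    """Run one exposure regime (or the observed law when regime is None)
    through the shared exogenous uniforms.  Returns (L, A, T) with T = event
    window or K for survivors."""
    K = spec.K
    codes = spec.covariate_space
    L = np.full((n, K), -1, dtype=np.int64)
    A = np.full((n, K), -1, dtype=np.int64)
    T = np.full(n, K, dtype=np.int64)  # K encodes "event-free at t_K"
    u_vals = U if U is not None else np.full(n, -1, dtype=np.int64)

    # L_0
    if spec.include_U:
        for uv in (0, 1):
            m = u_vals == uv
            if m.any():
                L[m, 0] = _categorical_draw(spec.init_l(uv), codes, uL[m, 0])
    else:
        L[:, 0] = _categorical_draw(spec.init_l(None), codes, uL[:, 0])

    alive = np.ones(n, dtype=bool)
    for k in range(K):
        idx = np.flatnonzero(alive)
        if idx.size == 0:
            break
        lh = [tuple(int(v) for v in L[i, : k + 1]) for i in idx]
        ah = [tuple(int(v) for v in A[i, :k]) for i in idx]
        uu = [int(u_vals[i]) if U is not None else None for i in idx]
        forced = regime.forced(k) if regime is not None else None
        if forced is None:
            keys = list(zip(uu, lh, ah))
            pa = _grouped_apply(
                keys, lambda key: float(spec.exposure_law(k, key[0], key[1], key[2]))
            ).astype(float)
            A[idx, k] = (uA[idx, k] < pa).astype(np.int64)
        else:
            A[idx, k] = forced
        ah2 = [h + (int(A[i, k]),) for h, i in zip(ah, idx)]
        keys = list(zip(uu, lh, ah2))
        ph = _grouped_apply(
            keys, lambda key: float(spec.hazard_law(k, key[0], key[1], key[2]))
        ).astype(float)
        event = uY[idx, k] < ph
        T[idx[event]] = k
        alive[idx[event]] = False
        if k + 1 < K:
            surv = idx[~event]
            if surv.size == 0:
                continue
            if spec.covariate_law is None:
                L[surv, k + 1] = L[surv, 0]
            else:
                lh_s = [tuple(int(v) for v in L[i, : k + 1]) for i in surv]
                ah_s = [tuple(int(v) for v in A[i, : k + 1]) for i in surv]
                uu_s = [int(u_vals[i]) if U is not None else None for i in surv]
                keys = list(zip(uu_s, lh_s, ah_s))
                dists = _grouped_apply(
                    keys,
                    lambda key: tuple(
                        sorted(spec.covariate_law(k + 1, key[0], key[1], key[2]).items())
                    ),
                )
                # group rows sharing a distribution for vectorized inverse-CDF
                by_dist: dict = {}
                for row, d in zip(surv, dists):
                    by_dist.setdefault(d, []).append(row)
                for d, rows in by_dist.items():
                    rows = np.asarray(rows)
                    L[rows, k + 1] = _categorical_draw(dict(d), codes, uL[rows, k + 1])
    return L, A, T


def sample_cohort(
    spec: DGPSpec,
    n: int,
    seed: int,
    attach_counterfactuals: bool = False,
) -> pd.DataFrame:
    """Simulate a cohort of ``n`` subjects.

    Returns one row per subject with columns ``subject_id``, ``T`` (event
    window, ``inf`` when event-free at t_K), ``L_0..L_{K-1}``,
    ``A_0..A_{K-1}`` (NaN after the event, per the at-risk convention) and
    ``Y_1..Y_K``.  With ``attach_counterfactuals`` the four regime outcome
    sequences are added (columns ``Y{k}_b0/b1/s0/s1``), generated from the
    same exogenous uniform draws as the observed path — one draw per
    structural equation per window — so consistency holds row-wise whenever
    the observed exposure path matches a regime.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    if not spec.validated:
        spec = validate_spec(spec)
    K = spec.K
    rng = np.random.default_rng(seed)
    uU = rng.random(n)
    uL = rng.random((n, K))
    uA = rng.random((n, K))
    uY = rng.random((n, K))
    U = (uU < spec.p_u).astype(np.int64) if spec.include_U else None

    L, A, T = _simulate_path(spec, n, U, uL, uA, uY, None)

    data: dict = {"subject_id": np.arange(n)}
    Tout = T.astype(float)
    Tout[T == K] = np.inf
    data["T"] = Tout
    for k in range(K):
        col = L[:, k].astype(float)
        col[T < k] = np.nan
        data[f"L_{k}"] = col
    for k in range(K):
        col = A[:, k].astype(float)
        col[T < k] = np.nan
        data[f"A_{k}"] = col
    for k in range(1, K + 1):
        data[f"Y_{k}"] = (T < k).astype(np.int64)

    if attach_counterfactuals:
        for name, tag in REGIME_COLUMNS.items():
            _, _, Tr = _simulate_path(spec, n, U, uL, uA, uY, parse_regime(name))
            for k in range(1, K + 1):
                data[f"Y{k}_{tag}"] = (Tr < k).astype(np.int64)
    return pd.DataFrame(data)


# ---------------------------------------------------------------------------
# Spec serialization (stratum -> probability tables)
# ---------------------------------------------------------------------------


def spec_to_dict(spec: DGPSpec) -> dict:
    """Serializable form of a validated spec: each law as a table keyed by
    the (window, U, covariate-history, exposure-history) stratum."""
    if not spec.validated:
        spec = validate_spec(spec)
    t = spec.tables

    def key_rec(key):
        k, u, l, a = key
        return {"k": k, "u": u, "l": list(l), "a": list(a)}

    return {
        "K": spec.K,
        "covariate_space": list(spec.covariate_space),
        "p_u": spec.p_u,
        "include_U": spec.include_U,
        "freeze_exposure": spec.freeze_exposure,
        "constant_hazard_enforced": spec.constant_hazard_enforced,
        "homogeneity_scale": spec.homogeneity_scale,
        "name": spec.name,
        "init_l": [
            {"u": u, "dist": {str(c): p for c, p in dist}}
            for u, dist in sorted(t["init_l"].items(), key=repr)
        ],
        "exposure": [
            {**key_rec(key), "p": p}
            for key, p in sorted(t["exposure"].items(), key=repr)
        ],
        "covariate": [
            {**key_rec(key), "dist": {str(c): p for c, p in dist}}
            for key, dist in sorted(t["covariate"].items(), key=repr)
        ],
        "hazard": [
            {**key_rec(key), "p": p}
            for key, p in sorted(t["hazard"].items(), key=repr)
        ],
    }


def spec_from_dict(d: dict) -> DGPSpec:
    """Rebuild a spec whose laws are table lookups; validated on return."""
    space = tuple(d["covariate_space"])
    code = {str(c): c for c in space}

    init = {
        rec["u"]: {code[c]: p for c, p in rec["dist"].items()}
        for rec in d["init_l"]
    }
    exposure = {
        (r["k"], r["u"], tuple(r["l"]), tuple(r["a"])): r["p"]
        for r in d["exposure"]
    }
    hazard = {
        (r["k"], r["u"], tuple(r["l"]), tuple(r["a"])): r["p"]
        for r in d["hazard"]
    }
    covariate = {
        (r["k"], r["u"], tuple(r["l"]), tuple(r["a"])): {
            code[c]: p for c, p in r["dist"].items()
        }
        for r in d["covariate"]
    }
    spec = DGPSpec(
        K=d["K"],
        covariate_space=space,
        init_l=lambda u: init[u],
        exposure_law=lambda k, u, l, a: exposure[(k, u, tuple(l), tuple(a))],
        hazard_law=lambda k, u, l, a: hazard[(k, u, tuple(l), tuple(a))],
        covariate_law=(
            (lambda k, u, l, a: covariate[(k, u, tuple(l), tuple(a))])
            if covariate
            else None
        ),
        p_u=d["p_u"],
        include_U=d["include_U"],
        freeze_exposure=d["freeze_exposure"],
        constant_hazard_enforced=d["constant_hazard_enforced"],
        homogeneity_scale=d["homogeneity_scale"],
        name=d.get("name", ""),
    )
    return validate_spec(spec)


def write_spec(spec: DGPSpec, path) -> None:
    """Write a spec as YAML (JSON-compatible structure)."""
    import yaml

    with open(path, "w") as fh:
        yaml.safe_dump(spec_to_dict(spec), fh, sort_keys=False)


def read_spec(path) -> DGPSpec:
    import yaml

    with open(path) as fh:
        return spec_from_dict(yaml.safe_load(fh))


# ---------------------------------------------------------------------------
# Cohort table I/O
# ---------------------------------------------------------------------------


def write_cohort(cohort: pd.DataFrame, path) -> None:
    """Write a cohort table as CSV with 'inf' as the event-free sentinel and
    empty cells for post-event (missing) values."""
    cohort.to_csv(path, index=False)


def read_cohort(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    df["T"] = df["T"].astype(float)
    return df


def cohort_K(cohort: pd.DataFrame) -> int:
    """Number of exposure windows in a cohort table."""
    ks = [int(c.split("_")[1]) for c in cohort.columns if c.startswith("A_")]
    if not ks:
        raise ValueError("cohort table has no A_k columns")
    return max(ks) + 1
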