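"""Independent oracles for cross-checking the package.

Everything here is deliberately written in a different style from the
package internals: the enumerator multiplies law factors along explicitly
materialised full paths (no shared tree walk), and the g-formula oracle is a
direct recursive summation over (U, covariate-path) histories.
"""

from __future__ import annotations

import itertools
import math


def _u_states(spec):
    return [(0, 1.0 - spec.p_u), (1, spec.p_u)] if spec.include_U else [(None, 1.0)]


def brute_force_atoms(spec) -> dict:
    """Map (u, l_prefix, a_prefix, t) -> probability by materialising every
    full (l-path, a-path, event-time) combination and multiplying factors."""
    K = spec.K
    codes = tuple(spec.covariate_space)
    out: dict = {}
    for u, pu in _u_states(spec):
        if pu == 0.0:
            continue
        l_paths = (
            itertools.product(codes, repeat=K)
            if spec.covariate_law is not None
            else [(c,) * K for c in codes]
        )
        for l_path in l_paths:
            for a_path in itertools.product((0, 1), repeat=K):
                for t in list(range(K)) + [None]:
                    nk = (t + 1) if t is not None else K
                    # one canonical representative per (prefix, t): suffix
                    # values past the at-risk windows are meaningless
                    if any(a_path[j] != 0 for j in range(nk, K)):
                        continue
                    if spec.covariate_law is not None and any(
                        l_path[j] != codes[0] for j in range(nk, K)
                    ):
                        continue
                    p = pu * spec.init_l(u).get(l_path[0], 0.0)
                    for k in range(nk):
                        lh, ah = l_path[: k + 1], a_path[:k]
                        if k >= 1:
                            if spec.covariate_law is None:
                                if l_path[k] != l_path[0]:
                                    p = 0.0
                                    break
                            else:
                                p *= spec.covariate_law(k, u, l_path[:k], ah).get(
                                    l_path[k], 0.0
                                )
                        pa = spec.exposure_law(k, u, lh, ah)
                        p *= pa if a_path[k] == 1 else 1.0 - pa
                        ph = spec.hazard_law(k, u, lh, a_path[: k + 1])
                        p *= ph if t == k else 1.0 - ph
                        if p == 0.0:
                            break
                    if p > 0.0:
                        key = (u, l_path[:nk], a_path[:nk], t)
                        out[key] = out.get(key, 0.0) + p
    return out


def _forced_exposure(regime_kind, regime_a, k, natural):
    if regime_kind == "sustained":
        return [(regime_a, 1.0)]
    if regime_kind == "baseline" and k == 0:
        return [(regime_a, 1.0)]
    return [(1, natural), (0, 1.0 - natural)]


def gformula_survival(spec, regime_kind: str, regime_a: int, condition_l0=None):
    """Counterfactual survival curve [Pr(Y_0=0), ..., Pr(Y_K=0)] under a
    regime, by direct recursive summation over (U, covariate-path) histories.

    With ``condition_l0`` the curve is conditional on L_0 = l (U reweighted
    by Bayes where applicable)."""
    K = spec.K
    curves = [1.0]
    for horizon in range(1, K + 1):
        total = 0.0
        norm = 0.0
        for u, pu in _u_states(spec):
            init = spec.init_l(u)
            for l0, pl0 in init.items():
                if condition_l0 is not None and l0 != condition_l0:
                    continue
                w = pu * pl0
                norm += w
                total += w * _survive_through(
                    spec, regime_kind, regime_a, u, (l0,), (), 0, horizon
                )
        curves.append(total / norm)
    return curves


def _survive_through(spec, regime_kind, regime_a, u, lhist, ahist, k, horizon):
    """Pr(event-free through windows k..horizon-1 | history)."""
    if k == horizon:
        return 1.0
    natural = spec.exposure_law(k, u, lhist, ahist)
    total = 0.0
    for a_k, pa in _forced_exposure(regime_kind, regime_a, k, natural):
        if pa == 0.0:
            continue
        h = spec.hazard_law(k, u, lhist, ahist + (a_k,))
        stay = pa * (1.0 - h)
        if stay == 0.0:
            continue
        if k + 1 == horizon:
            total += stay
        elif spec.covariate_law is None:
            total += stay * _survive_through(
                spec, regime_kind, regime_a, u, lhist + (lhist[0],),
                ahist + (a_k,), k + 1, horizon,
            )
        else:
            dist = spec.covariate_law(k + 1, u, lhist, ahist + (a_k,))
            for l_next, pl in dist.items():
                if pl > 0.0:
                    total += stay * pl * _survive_through(
                        spec, regime_kind, regime_a, u, lhist + (l_next,),
                        ahist + (a_k,), k + 1, horizon,
                    )
    return total


def gformula_risk(spec, regime_kind, regime_a, condition_l0=None) -> float:
    """Counterfactual cumulative risk Pr(Y_K(.) = 1) (optionally given L_0)."""
    return 1.0 - gformula_survival(spec, regime_kind, regime_a, condition_l0)[-1]


def gformula_hazards(spec, regime_kind, regime_a) -> list:
    """Counterfactual per-window discrete hazards from the survival curve."""
    s = gformula_survival(spec, regime_kind, regime_a)
    return [
        (s[k] - s[k + 1]) / s[k] if s[k] > 0.0 else None
        for k in range(spec.K)
    ]


def direct_weight_product(a_hist, p_list) -> float:
    """Independently coded W_k product for the telescoping check."""
    w = 1.0
    for a, p in zip(a_hist, p_list):
        w *= (a / p) + ((1 - a) / (1 - p))
    return w


def exact_pair_inclusion(n_pool: int, n_draw: int) -> float:
    """Inclusion probability of one subject under uniform sampling without
    replacement: C(n-1, c-1)/C(n, c) = c/n, written combinatorially."""
    return math.comb(n_pool - 1, n_draw - 1) / math.comb(n_pool, n_draw)
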