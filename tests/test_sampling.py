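"""Control-sampling schemes: worked-example walk-throughs, scheme soundness,
uniformity of inclusion, and reproducibility."""

import numpy as np
import pytest

from casecausal import (
    eligible_controls,
    qualify_cases,
    sample_case_base_controls,
    sample_matched_controls,
    sample_risk_set_controls,
    sample_survivor_controls,
)
from casecausal.errors import SamplingInfeasibleError

from oracles import exact_pair_inclusion


class TestWorkedExample:
    """The nine-subject, twelve-window follow-up illustration."""

    def test_pp_case_qualification(self, fig1):
        assert sorted(qualify_cases(fig1, "PP")["subject_id"]) == [2, 3, 8]

    def test_itt_case_qualification_includes_switcher(self, fig1):
        ids = sorted(qualify_cases(fig1, "ITT")["subject_id"])
        assert 1 in ids and ids == [1, 2, 3, 6, 8]

    def test_itt_eligibility_at_first_switchers_event_window(self, fig1):
        assert eligible_controls(fig1, 5, "risk-set", "ITT") == [
            1, 4, 5, 6, 7, 8, 9,
        ]

    def test_pp_eligibility_at_last_event_window(self, fig1):
        assert eligible_controls(fig1, 7, "risk-set", "PP") == [4, 5, 7, 9]

    def test_pp_eligibility_at_first_pp_case_window_is_everyone(self, fig1):
        assert eligible_controls(fig1, 3, "risk-set", "PP") == list(range(1, 10))

    def test_window_zero_risk_set_is_everyone(self, fig1):
        assert eligible_controls(fig1, 0, "risk-set", "ITT") == list(range(1, 10))

    def test_five_incident_events(self, fig1):
        assert int(fig1["Y_12"].sum()) == 5

    def test_survivor_controls_only_from_event_free_rows(self, fig1):
        sel = sample_survivor_controls(fig1, 2, seed=4)
        chosen = set(fig1.loc[sel.S.astype(bool), "subject_id"])
        assert chosen <= {4, 5, 7, 9}

    def test_event_free_cohort_has_no_cases(self, fig1):
        survivors = fig1[~np.isfinite(fig1["T"])].reset_index(drop=True)
        assert len(qualify_cases(survivors, "ITT")) == 0
        assert len(qualify_cases(survivors, "PP")) == 0

    def test_risk_set_controls_drawn_only_from_eligible(self, fig1):
        sel = sample_risk_set_controls(fig1, 2, "ITT", seed=1)
        elig5 = set(eligible_controls(fig1, 5, "risk-set", "ITT"))
        row1_links = sel.links[
            (sel.links["case_id"] == 1) & (sel.links["window"] == 5)
        ]
        assert set(row1_links["control_id"]) <= elig5 - {1}

    def test_case_can_serve_as_control_before_its_own_event(self, fig1):
        # row 8 (event in window 7) is risk-set eligible at window 5
        assert 8 in eligible_controls(fig1, 5, "risk-set", "ITT")
        hits = 0
        for seed in range(40):
            sel = sample_risk_set_controls(fig1, 3, "ITT", seed=seed)
            links = sel.links
            hits += int(
                (
                    (links["control_id"] == 8)
                    & (links["window"] < 7)
                ).any()
            )
        assert hits > 0


class TestSchemeSoundness:
    def test_survivor_scheme_never_selects_a_case(self, small_cohort):
        sel = sample_survivor_controls(small_cohort, 50, seed=3)
        assert np.isinf(small_cohort.loc[sel.S.astype(bool), "T"]).all()

    def test_risk_set_selection_zero_outside_risk_set(self, small_cohort):
        sel = sample_risk_set_controls(small_cohort, 2, "ITT", seed=3)
        t = small_cohort["T"].to_numpy()
        for k in range(sel.S_k.shape[1]):
            assert not sel.S_k[(t < k), k].any()

    def test_case_base_full_draw_selects_everyone(self, fig1):
        sel = sample_case_base_controls(fig1, len(fig1), seed=0)
        assert sel.S.all()

    def test_case_base_overdraw_rejected(self, fig1):
        with pytest.raises(ValueError):
            sample_case_base_controls(fig1, len(fig1) + 1, seed=0)

    def test_survivor_infeasible_when_everyone_has_event(self, fig1):
        all_events = fig1[np.isfinite(fig1["T"])].reset_index(drop=True)
        with pytest.raises(SamplingInfeasibleError):
            sample_survivor_controls(all_events, 1, seed=0)

    def test_risk_set_infeasible_when_pool_too_small(self, fig1):
        with pytest.raises(SamplingInfeasibleError):
            sample_risk_set_controls(fig1, 20, "ITT", seed=0)

    def test_reproducibility_under_fixed_seed(self, small_cohort):
        for sampler in (
            lambda s: sample_case_base_controls(small_cohort, 30, s),
            lambda s: sample_survivor_controls(small_cohort, 30, s),
        ):
            assert (sampler(11).S == sampler(11).S).all()
        a = sample_risk_set_controls(small_cohort, 2, "ITT", seed=11)
        b = sample_risk_set_controls(small_cohort, 2, "ITT", seed=11)
        assert (a.S_k == b.S_k).all()
        ma = sample_matched_controls(small_cohort, "case-base", seed=11)
        mb = sample_matched_controls(small_cohort, "case-base", seed=11)
        assert ma.frame().equals(mb.frame())


class TestInclusionUniformity:
    """On a tiny cohort, empirical inclusion frequencies over many seeds must
    match the exact combinatorial inclusion probability inside the eligible
    pool and be zero outside it."""

    @pytest.mark.parametrize("scheme,n_draw", [("case-base", 3),
                                               ("survivor", 2)])
    def test_single_draw_schemes(self, fig1, scheme, n_draw):
        reps = 2000
        counts = np.zeros(len(fig1))
        for seed in range(reps):
            if scheme == "case-base":
                sel = sample_case_base_controls(fig1, n_draw, seed)
                pool = np.ones(len(fig1), dtype=bool)
            else:
                sel = sample_survivor_controls(fig1, n_draw, seed)
                pool = ~np.isfinite(fig1["T"]).to_numpy()
            counts += sel.S
        p = exact_pair_inclusion(int(pool.sum()), n_draw)
        se = np.sqrt(p * (1 - p) / reps)
        assert (counts[~pool] == 0).all()
        assert np.all(np.abs(counts[pool] / reps - p) < 4 * se)

    def test_risk_set_uniform_within_window_pool(self, fig1):
        reps = 2000
        k = 7  # row 8's event window; pool excludes the index case
        counts = np.zeros(len(fig1))
        for seed in range(reps):
            sel = sample_risk_set_controls(fig1, 2, "ITT", seed=seed)
            counts += sel.S_k[:, k]
        t = fig1["T"].to_numpy()
        pool = (t >= k) & (fig1["subject_id"] != 8).to_numpy()
        p = exact_pair_inclusion(int(pool.sum()), 2)
        se = np.sqrt(p * (1 - p) / reps)
        assert (counts[~pool] == 0).all()
        assert np.all(np.abs(counts[pool] / reps - p) < 4 * se)


class TestMatching:
    def test_match_key_always_agrees_with_control_source(self, small_cohort):
        ms = sample_matched_controls(small_cohort, "risk-set", "ITT", seed=5)
        pos = {
            sid: i for i, sid in enumerate(small_cohort["subject_id"])
        }
        l0 = small_cohort["L_0"].to_numpy()
        for s in ms:
            assert l0[pos[s.control_id]] == s.match_key[-1]
            assert s.control_id != s.case_id

    def test_control_exposure_distribution_matches_pool_prevalence(self, fig1):
        """Pr(A'=1 | case L_0) equals the exposure prevalence of the matched
        pool, checked empirically against the exact pool composition."""
        reps = 3000
        draws: dict = {}
        for seed in range(reps):
            for s in sample_matched_controls(fig1, "case-base", seed=seed):
                draws.setdefault(s.case_id, []).append(s.control_exposure)
        l0 = dict(zip(fig1["subject_id"], fig1["L_0"].astype(int)))
        a0 = dict(zip(fig1["subject_id"], fig1["A_0"].astype(int)))
        for cid, vals in draws.items():
            pool = [j for j in l0 if l0[j] == l0[cid] and j != cid]
            prev = np.mean([a0[j] for j in pool])
            se = np.sqrt(max(prev * (1 - prev), 1e-9) / len(vals))
            assert abs(np.mean(vals) - prev) < 4 * se + 1e-12

    def test_degenerate_single_subject_pool_matches_self(self):
        import pandas as pd

        cohort = pd.DataFrame(
            {"subject_id": [0], "T": [0.0], "L_0": [1.0], "L_1": [np.nan],
             "A_0": [1.0], "A_1": [np.nan], "Y_1": [1], "Y_2": [1]}
        )
        ms = sample_matched_controls(cohort, "case-base", seed=0)
        assert len(ms) == 1
        assert ms.sets[0].control_id == 0
        assert ms.sets[0].control_exposure == 1

    def test_empty_pool_drops_case_with_log(self, fig1, caplog):
        # survivor matching: a case whose L_0 stratum has no survivors
        import pandas as pd

        rows = fig1[fig1["subject_id"].isin([2, 5])].reset_index(drop=True)
        # case row 2 has L_0=0; the only survivor (row 5) has L_0=1
        ms = sample_matched_controls(rows, "survivor", seed=0)
        assert len(ms) == 0 and len(ms.dropped) == 1
        assert ms.dropped[0][0] == 2
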