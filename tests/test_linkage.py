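"""The matching cascade: blocking, stage criteria, one-to-one resolution."""
import random
from datetime import date

import pytest

from cohortlink import (
    CandidatePair,
    SimulationParams,
    default_linkage_config,
    generate_twin_cohorts,
)
from cohortlink.linkage import (
    art_stage,
    block_by_dob,
    cd4_stage,
    corroboration_score,
    flag_manual_candidates,
    resolve_manual,
    run_linkage,
)

from _oracle import oracle_linkage
from helpers import D, art, clinic, config, preg_record, pregnancy


def _by_id(records):
    return {r.record_id: r for r in records}


def _pair(c, p):
    return CandidatePair(c.record_id, p.record_id, c.dob)


# --------------------------------------------------------------------------
# blocking


class TestBlocking:
    def test_disjoint_dobs_give_no_pairs(self):
        assert block_by_dob([clinic(dob="1970-01-02")],
                            [preg_record(dob="1970-01-03")]) == []

    def test_shared_dob_gives_full_cross_product(self):
        cs = [clinic(record_id=f"C{i}") for i in range(2)]
        ps = [preg_record(record_id=f"P{i}") for i in range(3)]
        pairs = block_by_dob(cs, ps)
        assert len(pairs) == 6
        assert {(q.clinic_id, q.pregnancy_id) for q in pairs} == {
            (f"C{i}", f"P{j}") for i in range(2) for j in range(3)}

    def test_simulated_pair_count_equals_double_loop(self):
        params = SimulationParams(n_clinic=500, n_pregnancy=400, seed=7)
        cs, ps, _ = generate_twin_cohorts(params)
        pairs = block_by_dob(cs, ps)
        brute = sum(1 for c in cs for p in ps if c.dob == p.dob)
        assert len(pairs) == brute

    def test_every_pair_shares_dob(self):
        params = SimulationParams(n_clinic=100, n_pregnancy=80, seed=5)
        cs, ps, _ = generate_twin_cohorts(params)
        cby, pby = _by_id(cs), _by_id(ps)
        for q in block_by_dob(cs, ps):
            assert cby[q.clinic_id].dob == pby[q.pregnancy_id].dob == q.dob


# --------------------------------------------------------------------------
# CD4 stages


class TestCD4Stage:
    def _setup(self, clinic_count, preg_count, **kw):
        d = D("2004-05-10")
        c = clinic(cd4_series=[(d, clinic_count)], **kw.get("clinic_kw", {}))
        p = preg_record(pregnancies=[pregnancy(
            delivery_date="2004-09-23", outcome="live-birth",
            first_cd4=(d, preg_count), **kw.get("preg_kw", {}))])
        return c, p

    def test_counts_within_tolerance_on_same_date_match(self):
        c, p = self._setup(352, 350)
        decisions = cd4_stage([_pair(c, p)], _by_id([c]), _by_id([p]), config(), 0)
        assert len(decisions) == 1
        assert decisions[0].criterion == "cd4±10"
        assert decisions[0].stage == "CD4-exact"
        assert not decisions[0].manual_flag

    def test_discrepant_counts_without_site_or_diagnosis_do_not_match(self):
        c, p = self._setup(350, 380)
        assert cd4_stage([_pair(c, p)], _by_id([c]), _by_id([p]), config(), 0) == []

    def test_large_count_difference_at_equivalent_site_flags_manual(self):
        d = D("2004-05-10")
        c = clinic(cd4_series=[(d, 350)], sites=[("H01", D("2003-01-01"))])
        p = preg_record(pregnancies=[pregnancy(
            delivery_date="2004-09-23", outcome="live-birth",
            first_cd4=(d, 500), site="M01")])
        cfg = config(site_equivalence={"M01": ("H01",)})
        decisions = cd4_stage([_pair(c, p)], _by_id([c]), _by_id([p]), cfg, 0)
        assert len(decisions) == 1
        assert decisions[0].criterion == "site"
        assert decisions[0].manual_flag  # |350-500| = 150 > 100

    def test_identical_diagnosis_date_rescues_discrepant_counts(self):
        c, p = self._setup(350, 380)
        c.hiv_diagnosis_date = p.hiv_diagnosis_date = D("2001-02-03")
        decisions = cd4_stage([_pair(c, p)], _by_id([c]), _by_id([p]), config(), 0)
        assert [d.criterion for d in decisions] == ["diagnosis-date"]
        assert not decisions[0].manual_flag  # 30 <= 100

    def test_window_stage_accepts_dates_within_30_days(self):
        c = clinic(cd4_series=[(D("2004-05-10"), 352)])
        p = preg_record(pregnancies=[pregnancy(
            delivery_date="2004-09-23", outcome="live-birth",
            first_cd4=(D("2004-06-05"), 350))])
        assert cd4_stage([_pair(c, p)], _by_id([c]), _by_id([p]), config(), 0) == []
        decisions = cd4_stage([_pair(c, p)], _by_id([c]), _by_id([p]), config(), 30)
        assert [d.stage for d in decisions] == ["CD4-window"]


# --------------------------------------------------------------------------
# ART stages


class TestARTStage:
    def _run(self, c, p, cfg=None, window=0):
        return art_stage([_pair(c, p)], _by_id([c]), _by_id([p]),
                         cfg or config(), window)

    def test_drug_and_both_dates_matching_is_first_criterion(self):
        ep = art("ZDVm", "2004-03-01", "2004-10-12")
        c = clinic(art_episodes=[ep])
        p = preg_record(pregnancies=[pregnancy(
            delivery_date="2004-10-01", outcome="live-birth",
            antenatal_art=[art("ZDVm", "2004-03-01", "2004-10-12")])])
        decisions = self._run(c, p)
        assert [d.criterion for d in decisions] == ["drug+start+stop"]

    def test_missing_drug_with_matching_dates_is_third_criterion(self):
        c = clinic(art_episodes=[art("ZDVm", "2004-03-01", "2004-10-12")])
        p = preg_record(pregnancies=[pregnancy(
            delivery_date="2004-10-01", outcome="live-birth",
            antenatal_art=[art(None, "2004-03-01", "2004-10-12")])])
        assert [d.criterion for d in self._run(c, p)] == ["start+stop"]

    def test_single_date_without_site_or_diagnosis_fails(self):
        c = clinic(art_episodes=[art("ZDVm", "2004-03-01", "2004-10-12")])
        p = preg_record(pregnancies=[pregnancy(
            delivery_date="2004-10-01", outcome="live-birth",
            antenatal_art=[art("3TC", "2004-03-01", "2004-11-30")])])
        assert self._run(c, p) == []

    def test_window_stage_tolerates_seven_day_shift(self):
        c = clinic(art_episodes=[art("ZDVm", "2004-03-01", "2004-10-12")])
        p = preg_record(pregnancies=[pregnancy(
            delivery_date="2004-10-01", outcome="live-birth",
            antenatal_art=[art("ZDVm", "2004-03-06", "2004-10-08")])])
        assert self._run(c, p, window=0) == []
        decisions = self._run(c, p, window=7)
        assert [d.criterion for d in decisions] == ["drug+start+stop"]
        assert decisions[0].stage == "ART-window"


# --------------------------------------------------------------------------
# manual stage


class TestManualStage:
    def test_matching_soundex_is_flagged(self):
        c = clinic(soundex="T520")
        p = preg_record(soundex="T520")
        flags = flag_manual_candidates([_pair(c, p)], _by_id([c]), _by_id([p]),
                                       config())
        assert [f.criterion for f in flags] == ["soundex"]
        assert flags[0].manual_flag

    def test_zdv_monotherapy_started_mid_pregnancy_is_an_art_profile(self):
        # delivery 2005-09-23 => conception 2005-01-01; 20 weeks in = late May
        c = clinic(art_episodes=[art("ZDVm", "2005-05-21")])
        p = preg_record(pregnancies=[pregnancy(delivery_date="2005-09-23",
                                               outcome="live-birth")])
        flags = flag_manual_candidates([_pair(c, p)], _by_id([c]), _by_id([p]),
                                       config())
        assert [f.criterion for f in flags] == ["art-profile"]

    def test_first_trimester_start_is_not_an_art_profile(self):
        c = clinic(art_episodes=[art("ZDVm", "2005-02-15")])  # week ~6
        p = preg_record(pregnancies=[pregnancy(delivery_date="2005-09-23",
                                               outcome="live-birth")])
        assert flag_manual_candidates([_pair(c, p)], _by_id([c]), _by_id([p]),
                                      config()) == []

    def test_pregnant_reason_code_is_an_art_profile(self):
        c = clinic(art_episodes=[art("AZT+3TC+NVP", "2007-01-10",
                                     reason="pregnant")])
        p = preg_record()
        flags = flag_manual_candidates([_pair(c, p)], _by_id([c]), _by_id([p]),
                                       config())
        assert [f.criterion for f in flags] == ["art-profile"]

    def test_nothing_satisfied_is_not_flagged(self):
        assert flag_manual_candidates([_pair(clinic(), preg_record())],
                                      _by_id([clinic()]),
                                      _by_id([preg_record()]), config()) == []

    def _corroborated_pair(self, cid="C1", vl_value=4800):
        d = D("2003-04-01")
        c = clinic(record_id=cid, country_of_birth="Nigeria",
                   ethnicity="black-African",
                   hiv_diagnosis_date=D("2001-05-01"),
                   vl_series=[(d, vl_value)], soundex="T520")
        p = preg_record(country_of_birth="Nigeria", ethnicity="black-African",
                        hiv_diagnosis_date=D("2001-05-01"),
                        pregnancies=[pregnancy(delivery_date="2003-09-23",
                                               outcome="live-birth",
                                               first_vl=(d, 4800))])
        return c, p

    def test_strong_corroboration_confirms_flagged_pair(self):
        c, p = self._corroborated_pair()
        flags = flag_manual_candidates([_pair(c, p)], _by_id([c]), _by_id([p]),
                                       config())
        confirmed = resolve_manual(flags, _by_id([c]), _by_id([p]), config())
        assert [d.pair.clinic_id for d in confirmed] == ["C1"]

    def test_site_agreement_alone_does_not_confirm(self):
        c = clinic(sites=[("H01", D("2002-01-01"))])
        p = preg_record(pregnancies=[pregnancy(delivery_date="2003-09-23",
                                               outcome="live-birth",
                                               site="M01")])
        cfg = config(site_equivalence={"M01": ("H01",)})
        flags = flag_manual_candidates([_pair(c, p)], _by_id([c]), _by_id([p]), cfg)
        assert [f.criterion for f in flags] == ["site"]
        assert resolve_manual(flags, _by_id([c]), _by_id([p]), cfg) == []

    def test_strongest_of_two_flagged_candidates_wins(self):
        c1, p = self._corroborated_pair("C1")          # score 4+
        c2 = clinic(record_id="C2", country_of_birth="Nigeria",
                    hiv_diagnosis_date=D("2001-05-01"))  # score 2
        cby, pby = _by_id([c1, c2]), _by_id([p])
        score1, _, _ = corroboration_score(c1, p, config())
        score2, _, _ = corroboration_score(c2, p, config())
        assert score1 > score2 >= config().corroboration_threshold
        flags = flag_manual_candidates([_pair(c1, p), _pair(c2, p)], cby, pby,
                                       config())
        confirmed = resolve_manual(flags, cby, pby, config())
        assert [d.pair.clinic_id for d in confirmed] == ["C1"]


# --------------------------------------------------------------------------
# the full cascade


STAGE_ORDER = ["CD4-exact", "CD4-window", "ART-exact", "ART-window", "manual"]


def _satisfiable(stage, c, p, cfg):
    """Would this single pair be confirmed at the given stage in isolation?"""
    pairs = [_pair(c, p)]
    cby, pby = _by_id([c]), _by_id([p])
    if stage == "CD4-exact":
        ds = cd4_stage(pairs, cby, pby, cfg, 0)
    elif stage == "CD4-window":
        ds = cd4_stage(pairs, cby, pby, cfg, cfg.cd4_date_window_days)
    elif stage == "ART-exact":
        ds = art_stage(pairs, cby, pby, cfg, 0)
    elif stage == "ART-window":
        ds = art_stage(pairs, cby, pby, cfg, cfg.art_date_window_days)
    else:
        return bool(resolve_manual(flag_manual_candidates(pairs, cby, pby, cfg),
                                   cby, pby, cfg))
    for d in ds:
        if d.manual_flag:
            score, nondemo, _ = corroboration_score(c, p, cfg)
            if score < cfg.corroboration_threshold or nondemo < 1:
                continue
        return True
    return False


class TestRunLinkage:
    def test_empty_pregnancy_cohort_yields_nothing(self):
        confirmed, events = run_linkage([clinic()], [], config())
        assert confirmed == [] and events == []

    @pytest.mark.parametrize("seed", range(6))
    def test_small_instances_equal_brute_force_oracle(self, seed):
        params = SimulationParams(n_clinic=20, n_pregnancy=16,
                                  overlap_fraction=0.5, p_dob_typo=0.1,
                                  seed=seed)
        cs, ps, _ = generate_twin_cohorts(params)
        cfg = default_linkage_config(params)
        confirmed, _ = run_linkage(cs, ps, cfg)
        got = {d.pair.key: (d.stage, d.criterion) for d in confirmed}
        assert got == oracle_linkage(cs, ps, cfg)

    @pytest.mark.parametrize("seed", range(8))
    def test_cascade_invariants_on_random_instances(self, seed):
        params = SimulationParams(n_clinic=40, n_pregnancy=30, seed=seed)
        cs, ps, _ = generate_twin_cohorts(params)
        cfg = default_linkage_config(params)
        cby, pby = _by_id(cs), _by_id(ps)
        confirmed, events = run_linkage(cs, ps, cfg)

        # one-to-one
        assert len({d.pair.clinic_id for d in confirmed}) == len(confirmed)
        assert len({d.pair.pregnancy_id for d in confirmed}) == len(confirmed)
        # blocking soundness
        for d in confirmed:
            assert cby[d.pair.clinic_id].dob == pby[d.pair.pregnancy_id].dob
        # stage precedence: a confirmed pair never satisfies an earlier stage
        for d in confirmed:
            for earlier in STAGE_ORDER[:STAGE_ORDER.index(d.stage)]:
                assert not _satisfiable(earlier, cby[d.pair.clinic_id],
                                        pby[d.pair.pregnancy_id], cfg), \
                    f"{d.pair.key} at {d.stage} already satisfiable at {earlier}"
        # every confirmed match has a matched audit event
        matched_events = {(e.clinic_id, e.pregnancy_id)
                          for e in events if e.action == "matched"}
        assert {d.pair.key for d in confirmed} == matched_events

    @pytest.mark.parametrize("seed", range(4))
    def test_input_order_does_not_change_confirmed_set(self, seed):
        params = SimulationParams(n_clinic=40, n_pregnancy=30, seed=seed)
        cs, ps, _ = generate_twin_cohorts(params)
        cfg = default_linkage_config(params)
        baseline = {d.pair.key for d in run_linkage(cs, ps, cfg)[0]}
        rnd = random.Random(seed)
        cs2, ps2 = cs[:], ps[:]
        rnd.shuffle(cs2)
        rnd.shuffle(ps2)
        assert {d.pair.key for d in run_linkage(cs2, ps2, cfg)[0]} == baseline

    @pytest.mark.parametrize("seed", range(4))
    def test_wider_windows_never_lose_matches(self, seed):
        params = SimulationParams(n_clinic=40, n_pregnancy=30, seed=seed)
        cs, ps, _ = generate_twin_cohorts(params)
        narrow = default_linkage_config(params)
        wide = default_linkage_config(params)
        wide.cd4_date_window_days = 60
        wide.art_date_window_days = 21
        assert (len(run_linkage(cs, ps, wide)[0])
                >= len(run_linkage(cs, ps, narrow)[0]))
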