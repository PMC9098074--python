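"""Deployment, linkage, bootstrap quantiles and period comparisons."""

from collections import defaultdict
from datetime import date, timedelta

import numpy as np
import pytest

from refwait.cohort import ConsultClaim, ReferralNote
from refwait.features import COUNT, build_vocabulary
from refwait.grid import FittedClassifier, PipelineConfig
from refwait.waits import (
    NON_SUBSTANTIAL,
    SUBSTANTIAL_DECREASE,
    SUBSTANTIAL_INCREASE,
    QuantileEstimate,
    WaitObservation,
    compare_periods,
    deploy,
    link_wait_times,
    summarize_by_specialty,
    summarize_waits,
)

CFG = PipelineConfig(0, False, COUNT, "l2", 1.0, None)


def keyword_classifier(specialty, keyword):
    vocab = build_vocabulary([[keyword, "filler"]] * 5, min_count=1)
    w = np.zeros(len(vocab))
    w[vocab.index[keyword]] = 10.0
    return FittedClassifier(CFG, vocab, w, -5.0, specialty)


@pytest.fixture()
def toy_notes():
    return [
        ReferralNote("p1", "n1", date(2015, 11, 1), "angina angina filler stuff here now"),
        ReferralNote("p2", "n2", date(2015, 3, 1), "rash rash filler stuff here now"),
        ReferralNote("p3", "n3", date(2015, 5, 1), "filler filler filler stuff here now"),
    ]


class TestDeploy:
    def test_threshold_zero_marks_everything(self, toy_notes):
        clfs = {"cardiology": keyword_classifier("cardiology", "angina")}
        assert len(deploy(clfs, toy_notes, threshold=0.0)) == len(toy_notes)

    def test_threshold_above_one_marks_nothing(self, toy_notes):
        clfs = {"cardiology": keyword_classifier("cardiology", "angina")}
        assert deploy(clfs, toy_notes, threshold=1.01) == set()

    def test_notes_matched_by_keyword(self, toy_notes):
        clfs = {
            "cardiology": keyword_classifier("cardiology", "angina"),
            "dermatology": keyword_classifier("dermatology", "rash"),
        }
        assert deploy(clfs, toy_notes, 0.5) == {("n1", "cardiology"), ("n2", "dermatology")}

    def test_positive_sets_nested_in_threshold(self, clean_labeled):
        from refwait.grid import train_final

        clf = {"cardiology": train_final(clean_labeled, "cardiology", CFG)}
        notes = [ln.note for ln in clean_labeled]
        lo = deploy(clf, notes, 0.5)
        hi = deploy(clf, notes, 0.6)
        assert hi <= lo


class TestLinkWaitTimes:
    def test_leap_year_wait_is_152_days(self, toy_notes):
        # independent calendar oracle for the same interval
        assert (date(2016, 4, 1) - date(2015, 11, 1)).days == 152
        claims = [ConsultClaim("p1", "cardiology", date(2016, 4, 1))]
        obs = link_wait_times([("n1", "cardiology")], toy_notes, claims, 2015)
        assert len(obs) == 1 and obs[0].wait == 152

    def test_claim_before_referral_ignored(self, toy_notes):
        claims = [ConsultClaim("p1", "cardiology", date(2015, 10, 1))]
        assert link_wait_times([("n1", "cardiology")], toy_notes, claims, 2015) == []

    def test_claim_two_years_out_ignored(self, toy_notes):
        claims = [ConsultClaim("p1", "cardiology", date(2017, 1, 5))]
        assert link_wait_times([("n1", "cardiology")], toy_notes, claims, 2015) == []

    def test_first_claim_on_or_after_first_note_wins(self):
        notes = [ReferralNote("p1", "n1", date(2015, 2, 1), "x"),
                 ReferralNote("p1", "n2", date(2015, 6, 1), "x")]
        claims = [ConsultClaim("p1", "derm", date(2015, 7, 1)),
                  ConsultClaim("p1", "derm", date(2015, 3, 1))]
        obs = link_wait_times([("n1", "derm"), ("n2", "derm")], notes, claims, 2015)
        assert len(obs) == 1
        assert obs[0].referral_date == date(2015, 2, 1)
        assert obs[0].consult_date == date(2015, 3, 1)

    def test_same_day_consult_counts_as_zero_wait(self, toy_notes):
        claims = [ConsultClaim("p1", "cardiology", date(2015, 11, 1))]
        obs = link_wait_times([("n1", "cardiology")], toy_notes, claims, 2015)
        assert obs[0].wait == 0

    def test_date_tie_broken_by_note_id(self):
        notes = [ReferralNote("p1", "nb", date(2015, 2, 1), "x"),
                 ReferralNote("p1", "na", date(2015, 2, 1), "x")]
        claims = [ConsultClaim("p1", "derm", date(2015, 3, 1))]
        obs = link_wait_times([("nb", "derm"), ("na", "derm")], notes, claims, 2015)
        assert len(obs) == 1  # one observation per (patient, specialty)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_per_patient_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        notes, claims, positives = [], [], []
        for p in range(60):
            pid = f"p{p}"
            for j in range(rng.integers(0, 3)):
                d = date(2015, 1, 1) + timedelta(days=int(rng.integers(0, 365)))
                nid = f"n{p}_{j}"
                notes.append(ReferralNote(pid, nid, d, "x"))
                if rng.random() < 0.8:
                    positives.append((nid, "derm"))
            for _ in range(rng.integers(0, 3)):
                d = date(2015, 1, 1) + timedelta(days=int(rng.integers(0, 600)))
                claims.append(ConsultClaim(pid, "derm", d))

        got = {(o.patient_id, o.referral_date, o.consult_date)
               for o in link_wait_times(positives, notes, claims, 2015)}

        # brute force: scan every patient independently
        pos_ids = {nid for nid, _ in positives}
        expected = set()
        by_pid = defaultdict(list)
        for n in notes:
            if n.note_id in pos_ids and n.date.year == 2015:
                by_pid[n.patient_id].append(n)
        for pid, pnotes in by_pid.items():
            first = min(pnotes, key=lambda n: (n.date, n.note_id))
            cands = [c.date for c in claims
                     if c.patient_id == pid and c.date >= first.date
                     and c.date.year in (2015, 2016)]
            if cands:
                expected.add((pid, first.date, min(cands)))
        assert got == expected


def obs(waits, spec="derm"):
    base = date(2015, 1, 1)
    return [WaitObservation(f"p{i}", spec, base, base + timedelta(days=int(w)))
            for i, w in enumerate(waits)]


class TestSummarizeWaits:
    def test_odd_length_median(self):
        est = summarize_waits(obs([10, 20, 30]), B=100, seed=0)
        assert est.quantiles[0.5].point == 20

    def test_single_observation_degenerate(self):
        est = summarize_waits(obs([42]), B=50, seed=0)
        for q in est.quantiles.values():
            assert q.point == q.ci_low == q.ci_high == 42

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            summarize_waits([])

    def test_quantiles_monotone_and_ci_brackets_point(self):
        rng = np.random.default_rng(7)
        est = summarize_waits(obs(rng.integers(0, 200, 300)), B=500, seed=1)
        qs = [est.quantiles[q].point for q in (0.5, 0.75, 0.9)]
        assert qs == sorted(qs)
        for q in est.quantiles.values():
            assert q.ci_low <= q.point <= q.ci_high

    def test_deterministic_given_seed(self):
        waits = list(np.random.default_rng(3).integers(0, 100, 50))
        a = summarize_waits(obs(waits), B=200, seed=9)
        b = summarize_waits(obs(waits), B=200, seed=9)
        assert a.quantiles == b.quantiles

    def test_bootstrap_ci_covers_lognormal_median(self):
        # 2000 draws with true median 40: the 95% CI should cover 40 in
        # nearly all of 20 replicates
        covered = 0
        for rep in range(20):
            rng = np.random.default_rng(1000 + rep)
            waits = np.round(np.exp(np.log(40) + 0.5 * rng.standard_normal(2000)))
            est = summarize_waits(obs(waits), B=500, seed=rep)
            q = est.quantiles[0.5]
            covered += q.ci_low <= 40 <= q.ci_high
        assert covered >= 18

    def test_grouping_by_specialty(self):
        mixed = obs([10, 20, 30], "a") + obs([100, 200, 300], "b")
        out = summarize_by_specialty(mixed, B=50, seed=0)
        assert set(out) == {"a", "b"}
        assert out["a"].quantiles[0.5].point == 20
        assert out["b"].quantiles[0.5].point == 200


class TestComparePeriods:
    EST = QuantileEstimate(0.5, point=60.0, ci_low=50.0, ci_high=70.0)

    @pytest.mark.parametrize(
        ("prior", "verdict"),
        [
            (40.0, SUBSTANTIAL_INCREASE),
            (80.0, SUBSTANTIAL_DECREASE),
            (60.0, NON_SUBSTANTIAL),
            (50.0, NON_SUBSTANTIAL),  # on the bound: inside the closed CI
            (70.0, NON_SUBSTANTIAL),
        ],
    )
    def test_verdicts(self, prior, verdict):
        assert compare_periods(self.EST, prior) == verdict
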