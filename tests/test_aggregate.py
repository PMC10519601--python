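"""User-record construction, the posting partition, and sample selection."""

import math

import numpy as np
import pytest

from bdforum.aggregate import (
    UserRecord,
    build_user_records,
    partition_rq1,
    read_records_tsv,
    regression_frame,
    select_rq2,
    select_rq3,
    write_records_tsv,
)
from bdforum.corpus import UserAttributes
from bdforum.lexicon import CATEGORIES, score_text
from bdforum.synth import SynthConfig, generate
from bdforum.taxonomy import classify, fixture_taxonomy
from tests.conftest import BASE_TS, make_post


def scores(lexicon, text):
    return score_text(text, lexicon)


def triple(lexicon, post, context):
    return (post, context, score_text(post.body, lexicon))


LONG = " ".join(["stone"] * 30)  # 30 neutral tokens, passes the 25-word filter
SHORT = "too short"


def record(author="u", gender=1, age=30.0, n_mh_all=0, n_nonmh_all=8,
           n_mh_posts=0, n_nonmh_posts=8, mean_mh=None, mean_nonmh="zeros",
           active_days=10, activity=1.0):
    if mean_nonmh == "zeros":
        mean_nonmh = dict.fromkeys(CATEGORIES, 0.0)
    return UserRecord(
        author=author, gender=gender, age=age, active_days=active_days,
        activity=activity, n_mh_all=n_mh_all, n_nonmh_all=n_nonmh_all,
        n_mh_posts=n_mh_posts, n_nonmh_posts=n_nonmh_posts,
        mean_mh=mean_mh, mean_nonmh=mean_nonmh,
    )


class TestBuildUserRecords:
    def test_activity_formula(self, lexicon):
        # 20 posts spanning exactly 10 UTC days -> active_days 10, activity 2.0
        posts = [
            make_post(pid=f"p{i}", ts=BASE_TS + i * (10 * 86400) // 19, body=SHORT)
            for i in range(20)
        ]
        triples = [triple(lexicon, p, "nonMH") for p in posts]
        (rec,) = build_user_records({"u1"}, triples, {})
        assert rec.active_days == 10
        assert rec.activity == pytest.approx(2.0)
        assert rec.posted_in_mh == 0

    def test_single_post_user_floors_active_days(self, lexicon):
        triples = [triple(lexicon, make_post(body=SHORT), "nonMH")]
        (rec,) = build_user_records({"u1"}, triples, {})
        assert rec.active_days == 1 and rec.activity == pytest.approx(1.0)

    def test_context_means_use_only_filtered_posts(self, lexicon):
        body_scored = "love " + " ".join(["stone"] * 24)  # wc 25, posemo 4%
        posts = [
            triple(lexicon, make_post(pid="a", body=body_scored), "nonMH"),
            triple(lexicon, make_post(pid="b", body="love love love"), "nonMH"),  # wc 3, dropped
        ]
        (rec,) = build_user_records({"u1"}, posts, {})
        assert rec.n_nonmh_all == 2 and rec.n_nonmh_posts == 1
        assert rec.mean_nonmh["posemo"] == pytest.approx(4.0)
        assert rec.mean_mh is None

    def test_cohort_author_with_no_posts_is_error(self, lexicon):
        with pytest.raises(ValueError, match="no posts"):
            build_user_records({"ghost"}, [], {})

    def test_attributes_joined(self, lexicon):
        triples = [triple(lexicon, make_post(body=SHORT), "nonMH")]
        attrs = {"u1": UserAttributes("u1", 27.5, 0)}
        (rec,) = build_user_records({"u1"}, triples, attrs)
        assert rec.age == 27.5 and rec.gender == 0

    def test_planted_mean_recovered_at_three_se(self, lexicon):
        # one user, 30 non-MH posts x ~100 tokens, anxiety emission 0.01
        rates = {"posemo": 0.0, "anxiety": 0.01, "anger": 0.0, "sadness": 0.0, "i": 0.0}
        config = SynthConfig(
            n_users=1, seed=31, p_mh_poster=0.0, posts_per_user_per_context=30.0,
            tokens_per_post=100.0,
            emission_rates={k: dict(rates) for k in
                            (("MH", "mh_poster"), ("MH", "non_mh_poster"),
                             ("nonMH", "mh_poster"), ("nonMH", "non_mh_poster"))},
        )
        posts, _, _ = generate(config)
        tax = fixture_taxonomy()
        triples = [(p, classify(p.subreddit, tax), score_text(p.body, lexicon)) for p in posts]
        (rec,) = build_user_records({posts[0].author}, triples, {})
        n_tokens = rec.n_nonmh_posts * 100
        se = 100.0 * math.sqrt(0.01 * 0.99 / n_tokens)
        assert abs(rec.mean_nonmh["anxiety"] - 1.00) <= 3 * se


class TestPartition:
    def test_one_user_per_class(self):
        records = [
            record("a", n_mh_all=2, n_nonmh_all=3),
            record("b", n_mh_all=2, n_nonmh_all=0),
            record("c", n_mh_all=0, n_nonmh_all=3),
        ]
        part = partition_rq1(records)
        assert part.proportions == pytest.approx(
            {"both": 1 / 3, "only_mh": 1 / 3, "only_nonmh": 1 / 3}
        )
        assert sum(part.proportions.values()) == pytest.approx(1.0)

    def test_four_four_is_active_contributor(self):
        part = partition_rq1([record(n_mh_all=4, n_nonmh_all=4)])
        assert part.n_both_active == 1

    def test_three_mh_posts_is_not_active(self):
        part = partition_rq1([record(n_mh_all=3, n_nonmh_all=9)])
        assert part.n_both == 1 and part.n_both_active == 0

    def test_all_both_class(self):
        part = partition_rq1([record(n_mh_all=1, n_nonmh_all=1) for _ in range(5)])
        assert part.proportions["only_mh"] == 0.0

    def test_under_eight_strata(self):
        part = partition_rq1([
            record("a", n_mh_all=3, n_nonmh_all=2),   # both, <8 total
            record("b", n_mh_all=9, n_nonmh_all=0),   # only MH, >=8
            record("c", n_mh_all=0, n_nonmh_all=7),   # only non-MH, <8
        ])
        assert part.n_both_under8 == 1
        assert part.n_only_mh_8plus == 1
        assert part.n_only_nonmh_under8 == 1

    def test_reordering_invariance(self):
        records = [record(str(i), n_mh_all=i % 3, n_nonmh_all=(i + 1) % 4) for i in range(12)]
        assert partition_rq1(records) == partition_rq1(list(reversed(records)))


class TestSelection:
    def test_rq2_boundary(self):
        assert select_rq2([record(n_mh_posts=4, n_nonmh_posts=4, n_mh_all=4)])
        assert not select_rq2([record(n_mh_posts=3, n_nonmh_posts=9, n_mh_all=3)])
        assert select_rq2([]) == []

    def test_rq3_outcome_zero_boundary(self):
        sample = select_rq3([
            record("treated", n_mh_all=5, n_mh_posts=4, n_nonmh_posts=4),
            record("control", n_mh_all=0, n_mh_posts=0, n_nonmh_posts=8),
        ])
        outcome = {r.author: r.posted_in_mh for r in sample}
        assert outcome == {"treated": 1, "control": 0}

    def test_rq3_drops_missing_gender(self):
        with pytest.raises(ValueError, match="single outcome class"):
            select_rq3([
                record("a", n_mh_all=5, n_mh_posts=4, n_nonmh_posts=4, gender=None),
                record("b", n_mh_all=0, n_nonmh_posts=8),
            ])

    def test_rq3_one_mh_post_not_eligible(self):
        sample = select_rq3([
            record("x", n_mh_all=1, n_mh_posts=1, n_nonmh_posts=9),
            record("t", n_mh_all=4, n_mh_posts=4, n_nonmh_posts=4),
            record("c", n_mh_all=0, n_nonmh_posts=8),
        ])
        assert {r.author for r in sample} == {"t", "c"}

    def test_outcome_group_consistency(self):
        sample = select_rq3([
            record("t", n_mh_all=6, n_mh_posts=5, n_nonmh_posts=6),
            record("c", n_mh_all=0, n_nonmh_posts=11),
        ])
        for r in sample:
            if r.posted_in_mh == 0:
                assert r.n_mh_all == 0
            else:
                assert r.n_mh_posts >= 4 and r.n_nonmh_posts >= 4

    def test_regression_frame_uses_only_nonmh_means(self):
        sentinel = dict.fromkeys(CATEGORIES, 999.0)
        sample = [
            record("t", n_mh_all=5, n_mh_posts=4, n_nonmh_posts=4, mean_mh=sentinel),
            record("c", n_mh_all=0, n_nonmh_posts=8),
        ]
        X, y = regression_frame(sample)
        assert not (X[list(CATEGORIES)] == 999.0).any().any()
        assert list(y) == [1.0, 0.0]


def test_records_tsv_round_trip(tmp_path):
    records = [
        record("a", n_mh_all=5, n_mh_posts=4, n_nonmh_posts=4,
               mean_mh=dict.fromkeys(CATEGORIES, 1.25)),
        record("b", gender=None, age=None),
    ]
    path = tmp_path / "records.tsv"
    write_records_tsv(records, path)
    back = read_records_tsv(path)
    assert [r.author for r in back] == ["a", "b"]
    assert back[0].mean_mh["anxiety"] == pytest.approx(1.25)
    assert back[1].gender is None and back[1].age is None
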