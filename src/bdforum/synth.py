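"""Synthetic forum corpora with planted statistical structure.

The generator emulates the construction of a self-reported-diagnosis corpus:
each synthetic user carries a latent group (``mh_poster`` — posts in MH
communities — or ``non_mh_poster``), a gender and age, at least one
bipolar-diagnosis statement post, and a stream of posts whose tokens are
i.i.d. draws from a categorical emission model. Each token is one of five
category signature words (with the per-(context, group) emission probability
configured for that category) or a neutral filler, so the expected
dictionary score of a cell is exactly ``100 × emission probability`` and
every downstream estimate has a closed-form binomial oracle.

Default emission rates are set so the synthetic corpus reproduces the
qualitative structure reported for real cohorts: in MH-community posts,
less positive emotion but more anxiety, sadness, and first-person singular;
between groups, MH posters slightly higher anxiety/sadness in their non-MH
posts. Contamination (exclusion phrases, psychotic-disorder statements) is
planted separately so cohort filtering can be tested against ground truth.

All randomness flows from one ``numpy`` Generator seeded once; draws are
consumed user by user in a fixed documented order (group, gender, age,
post counts, timestamps, subreddits, tokens), so a seed pins the corpus
byte for byte.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Iterable

import numpy as np

from bdforum.corpus import Post, UserAttributes

MH = "MH"
NON_MH = "nonMH"
MH_POSTER = "mh_poster"
NON_MH_POSTER = "non_mh_poster"

#: Signature word per category; each matches exactly one category of the
#: bundled default lexicon.
SIGNATURE_WORDS = {
    "posemo": "love",
    "anxiety": "worried",
    "anger": "hate",
    "sadness": "sad",
    "i": "me",
}
CATEGORY_ORDER = tuple(SIGNATURE_WORDS)

FILLER_WORDS = ("table", "chair", "window", "river", "stone", "cloud", "road", "garden")

MH_SUBREDDITS = ("bipolar", "bipolarreddit", "bipolar2", "bipolarsos", "mentalhealth")
NON_MH_SUBREDDITS = ("askreddit", "gaming", "movies", "science", "funny", "books")

DIAGNOSIS_TEMPLATES = (
    "I was diagnosed with bipolar disorder a while back and wanted to share.",
    "My psychiatrist diagnosed me with bipolar 2 last spring.",
    "I have been diagnosed with bipolar 1 and finally feel ready to talk.",
)
EXCLUSION_TEMPLATES = (
    "To be clear, I'm not officially diagnosed, it just resonates.",
    "I am self-diagnosed, never saw a professional about it.",
)
PSYCHOTIC_TEMPLATES = (
    "Years before that I was diagnosed with schizophrenia by another doctor.",
    "I was also diagnosed with schizoaffective disorder at the clinic.",
)

_FIRST_POST_WINDOW = (1451606400, 1527811200)  # 2016-01-01 .. 2018-06-01 UTC


def _default_emission_rates() -> dict[tuple[str, str], dict[str, float]]:
    # MH-context rates follow the printed per-100-token score levels for MH
    # posts; non-MH rates follow the non-MH levels, with the non-poster group
    # slightly lower on anxiety/sadness/posemo (the between-group structure).
    mh_context = {"posemo": 0.0348, "anxiety": 0.0067, "anger": 0.0075, "sadness": 0.0081, "i": 0.0882}
    nonmh_posters = {"posemo": 0.0364, "anxiety": 0.0037, "anger": 0.0078, "sadness": 0.0045, "i": 0.0639}
    nonmh_others = {"posemo": 0.0358, "anxiety": 0.0030, "anger": 0.0078, "sadness": 0.0038, "i": 0.0639}
    return {
        (MH, MH_POSTER): dict(mh_context),
        (MH, NON_MH_POSTER): dict(mh_context),
        (NON_MH, MH_POSTER): dict(nonmh_posters),
        (NON_MH, NON_MH_POSTER): dict(nonmh_others),
    }


@dataclass
class SynthConfig:
    """Study conditions for one synthetic corpus."""

    n_users: int = 500
    seed: int = 0
    p_mh_poster: float = 0.76
    # share of MH posters with no non-MH posts at all; with p_mh_poster=0.76
    # this puts ~6.8% of users in the only-MH class and ~24% in never-MH
    p_only_mh: float = 0.09
    p_feminine: float = 0.55
    age_mean: float = 32.0
    age_sd: float = 9.0
    posts_per_user_per_context: float = 10.0
    tokens_per_post: float = 80.0
    emission_rates: dict[tuple[str, str], dict[str, float]] = field(
        default_factory=_default_emission_rates
    )
    p_excluded_phrase: float = 0.0
    p_psychotic_comorbid: float = 0.0
    p_missing_attribute: float = 0.0
    allow_short_posts: bool = False

    def __post_init__(self) -> None:
        for name in ("p_mh_poster", "p_only_mh", "p_feminine", "p_excluded_phrase",
                     "p_psychotic_comorbid", "p_missing_attribute"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {p}")
        for key, rates in self.emission_rates.items():
            if any(not 0.0 <= r <= 1.0 for r in rates.values()):
                raise ValueError(f"emission rates for {key} outside [0, 1]")
            if sum(rates.values()) > 1.0:
                raise ValueError(f"emission probabilities for {key} sum above 1")
        if not self.allow_short_posts and self.tokens_per_post < 26:
            raise ValueError("tokens_per_post must be >= 26 unless allow_short_posts")


@dataclass
class UserTruth:
    group: str
    gender: int
    age: float
    posted_in_mh: bool
    has_exclusion_phrase: bool = False
    has_psychotic_statement: bool = False


@dataclass
class PlantedTruth:
    """Ground truth of one generated corpus, for test harnesses."""

    users: dict[str, UserTruth]
    emission_rates: dict[tuple[str, str], dict[str, float]]

    @property
    def expected_scores(self) -> dict[tuple[str, str], dict[str, float]]:
        """Per-cell expected dictionary scores: 100 × emission probability."""
        return {
            key: {cat: 100.0 * p for cat, p in rates.items()}
            for key, rates in self.emission_rates.items()
        }

    def clean_authors(self) -> set[str]:
        return {
            a
            for a, u in self.users.items()
            if not (u.has_exclusion_phrase or u.has_psychotic_statement)
        }

    def to_jsonable(self) -> dict:
        return {
            "users": {a: asdict(u) for a, u in self.users.items()},
            "emission_rates": {
                f"{ctx}/{grp}": rates for (ctx, grp), rates in self.emission_rates.items()
            },
        }


def _post_tokens(rng: np.random.Generator, wc: int, rates: dict[str, float]) -> str:
    probs = np.array([rates[c] for c in CATEGORY_ORDER] + [1.0 - sum(rates.values())])
    idx = rng.choice(len(probs), size=wc, p=probs)
    words = [
        SIGNATURE_WORDS[CATEGORY_ORDER[i]] if i < len(CATEGORY_ORDER)
        else FILLER_WORDS[pos % len(FILLER_WORDS)]
        for pos, i in enumerate(idx)
    ]
    return " ".join(words)


def generate(config: SynthConfig) -> tuple[list[Post], list[UserAttributes], PlantedTruth]:
    """Generate a corpus, an attribute table, and its planted truth.

    Every user posts at least one diagnosis statement (in a non-MH
    community, so the statement itself never flips the MH-posting label);
    ``mh_poster`` users additionally post in MH-flagged communities.
    Contamination is not applied here — see :func:`plant_contamination`.
    """
    rng = np.random.default_rng(config.seed)
    posts: list[Post] = []
    attributes: list[UserAttributes] = []
    users: dict[str, UserTruth] = {}
    post_counter = 0

    mean_posts = config.posts_per_user_per_context
    for u in range(config.n_users):
        author = f"u{u:05d}"
        group = MH_POSTER if rng.random() < config.p_mh_poster else NON_MH_POSTER
        gender = 0 if rng.random() < config.p_feminine else 1
        age = float(np.round(max(16.0, rng.normal(config.age_mean, config.age_sd)), 1))

        if group == MH_POSTER:
            n_mh = int(1 + rng.poisson(max(mean_posts - 1.0, 0.0)))
            only_mh = rng.random() < config.p_only_mh
            n_nonmh = 0 if only_mh else int(1 + rng.poisson(max(mean_posts - 1.0, 0.0)))
        else:
            n_mh = 0
            n_nonmh = int(1 + rng.poisson(max(mean_posts - 1.0, 0.0)))
        n_posts = n_mh + n_nonmh + 1  # +1 diagnosis statement post

        # the posting window is drawn independently of post volume, so
        # activity controls carry no structural group signal
        start = int(rng.integers(*_FIRST_POST_WINDOW))
        duration = float(rng.uniform(30.0, 700.0)) * 86400.0
        offsets = np.sort(rng.uniform(0.0, duration, size=n_posts))
        times = (start + offsets).astype(int)

        # contexts in a fixed order: diagnosis post first, then MH, then non-MH
        contexts = [None] + [MH] * n_mh + [NON_MH] * n_nonmh
        template = DIAGNOSIS_TEMPLATES[int(rng.integers(len(DIAGNOSIS_TEMPLATES)))]

        for k, ctx in enumerate(contexts):
            post_counter += 1
            pid = f"p{post_counter:07d}"
            if ctx is None:
                # the diagnosis statement goes where the user posts: an
                # MH community for MH posters, a non-MH one otherwise
                pool = MH_SUBREDDITS if group == MH_POSTER else NON_MH_SUBREDDITS
                sub = pool[int(rng.integers(len(pool)))]
                body = template
            else:
                pool = MH_SUBREDDITS if ctx == MH else NON_MH_SUBREDDITS
                sub = pool[int(rng.integers(len(pool)))]
                if config.allow_short_posts:
                    wc = int(1 + rng.poisson(max(config.tokens_per_post - 1.0, 0.0)))
                else:
                    wc = int(26 + rng.poisson(config.tokens_per_post - 26.0))
                body = _post_tokens(rng, wc, config.emission_rates[(ctx, group)])
            posts.append(
                Post(id=pid, author=author, subreddit=sub, created_utc=int(times[k]), body=body)
            )

        age_out: float | None = age
        gender_out: int | None = gender
        if config.p_missing_attribute > 0:
            if rng.random() < config.p_missing_attribute:
                age_out = None
            if rng.random() < config.p_missing_attribute:
                gender_out = None
        attributes.append(UserAttributes(author=author, age=age_out, gender=gender_out))
        users[author] = UserTruth(
            group=group, gender=gender, age=age, posted_in_mh=(n_mh > 0)
        )

    truth = PlantedTruth(users=users, emission_rates=dict(config.emission_rates))
    return posts, attributes, truth


def plant_contamination(
    posts: list[Post],
    truth: PlantedTruth,
    config: SynthConfig,
    rng: np.random.Generator,
) -> list[Post]:
    """Append exclusion-phrase / psychotic-statement posts to random users.

    Per user, independently: with ``p_excluded_phrase`` an exclusion-phrase
    post and with ``p_psychotic_comorbid`` a psychotic-disorder statement
    post are appended (non-MH community, after the user's last post). The
    planted truth records which users were contaminated. With both
    probabilities zero the corpus is returned unchanged.
    """
    if config.p_excluded_phrase == 0 and config.p_psychotic_comorbid == 0:
        return posts
    last_time = {p.author: p.created_utc for p in posts}  # posts are in time order per user
    counter = len(posts)
    out = list(posts)
    for author in sorted(truth.users):
        u = truth.users[author]
        extras = []
        if rng.random() < config.p_excluded_phrase:
            u.has_exclusion_phrase = True
            extras.append(EXCLUSION_TEMPLATES[int(rng.integers(len(EXCLUSION_TEMPLATES)))])
        if rng.random() < config.p_psychotic_comorbid:
            u.has_psychotic_statement = True
            extras.append(PSYCHOTIC_TEMPLATES[int(rng.integers(len(PSYCHOTIC_TEMPLATES)))])
        for body in extras:
            counter += 1
            out.append(
                Post(
                    id=f"p{counter:07d}",
                    author=author,
                    subreddit=NON_MH_SUBREDDITS[int(rng.integers(len(NON_MH_SUBREDDITS)))],
                    created_utc=int(last_time[author]) + 3600,
                    body=body,
                )
            )
    return out


def simulate_logistic_sample(
    n: int,
    beta: dict[str, float],
    seed: int,
) -> tuple["pandas.DataFrame", np.ndarray]:
    """Draw a regression sample with known coefficients (recovery oracle).

    Predictors are drawn to match the scale of the real analysis sample
    (dictionary scores in percent, raw active-day counts); the outcome is
    Bernoulli with log-odds ``intercept + Σ beta_j x_j``. Coefficients
    absent from ``beta`` are zero.
    """
    import pandas as pd

    rng = np.random.default_rng(seed)
    X = pd.DataFrame(
        {
            "age": np.clip(rng.normal(32.0, 9.0, n), 16.0, None),
            "gender": (rng.random(n) < 0.45).astype(float),
            "active_days": rng.gamma(2.0, 300.0, n),
            "activity": rng.gamma(2.0, 1.0, n),
            "posemo": np.clip(rng.normal(3.6, 0.9, n), 0.0, None),
            "anxiety": np.clip(rng.normal(0.40, 0.25, n), 0.0, None),
            "anger": np.clip(rng.normal(0.78, 0.45, n), 0.0, None),
            "sadness": np.clip(rng.normal(0.45, 0.25, n), 0.0, None),
            "i": np.clip(rng.normal(6.4, 2.0, n), 0.0, None),
        }
    )
    eta = np.full(n, float(beta.get("intercept", 0.0)))
    for name, b in beta.items():
        if name == "intercept":
            continue
        eta += b * X[name].to_numpy()
    p = 1.0 / (1.0 + np.exp(-eta))
    y = (rng.random(n) < p).astype(float)
    return X, y
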