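"""End-to-end orchestration: synth → mine → classify → score → aggregate → analyse.

:func:`run` executes the whole pipeline under one :class:`RunConfig` and
writes a self-describing report bundle: the posting partition, the paired
within-user comparison table, the regression coefficient table and model-fit
summary, plus a manifest with a config hash and per-file content hashes. A
rerun with the same config and seed reproduces the bundle byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from bdforum import aggregate as agg
from bdforum import cohort as coh
from bdforum import corpus as cps
from bdforum import lexicon as lex
from bdforum import stats as st
from bdforum import synth
from bdforum import taxonomy as tax
from bdforum.lexicon import CATEGORIES

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Paths, thresholds, and the synthetic stage's conditions."""

    out_dir: str = "results/run"
    seed: int = 0
    corpus: str | None = None  # None → synthesise
    taxonomy: str | None = None  # None → bundled fixture taxonomy
    lexicon: str | None = None  # None → bundled default lexicon
    attributes: str | None = None
    patterns: str | None = None  # None → bundled default pattern set
    min_wc: int = lex.MIN_WORDS
    rq2_min: int = agg.RQ2_MIN_POSTS
    rq3_min: int = agg.RQ3_MIN_POSTS
    bonferroni_m: int = st.BONFERRONI_M
    synth: synth.SynthConfig = field(default_factory=synth.SynthConfig)

    def config_hash(self) -> str:
        payload = dataclasses.asdict(self)
        payload.pop("out_dir")  # where the bundle lands is not part of the analysis
        payload["synth"]["emission_rates"] = {
            f"{k[0]}/{k[1]}": v for k, v in payload["synth"]["emission_rates"].items()
        }
        blob = json.dumps(payload, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as handle:
        for chunk in iter(lambda: handle.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_rq2_tsv(table, path: Path) -> None:
    cols = [
        "variable", "n", "mean_mh", "sd_mh", "mean_nonmh", "sd_nonmh",
        "t", "df", "p", "p_bonf", "d_z", "d_av", "interpretation",
    ]
    with open(path, "w", encoding="utf-8") as handle:
        handle.write("\t".join(cols) + "\n")
        for row in table:
            handle.write(
                f"{row.variable}\t{row.n}\t{row.mean_mh:.6g}\t{row.sd_mh:.6g}\t"
                f"{row.mean_nonmh:.6g}\t{row.sd_nonmh:.6g}\t{row.t:.6g}\t{row.df}\t"
                f"{row.p:.6g}\t{row.p_bonf:.6g}\t{row.d_z:.6g}\t{row.d_av:.6g}\t"
                f"{row.interpretation}\n"
            )


def _write_coefficients_tsv(estimates, path: Path) -> None:
    with open(path, "w", encoding="utf-8") as handle:
        handle.write("name\tbeta\tse\tz\tp\tci_lo\tci_hi\todds_ratio\tor_lo\tor_hi\n")
        for e in estimates:
            lo, hi = e.ci
            olo, ohi = e.or_ci
            handle.write(
                f"{e.name}\t{e.beta:.6g}\t{e.se:.6g}\t{e.z:.6g}\t{e.p:.6g}\t"
                f"{lo:.6g}\t{hi:.6g}\t{e.odds_ratio:.6g}\t{olo:.6g}\t{ohi:.6g}\n"
            )


def _fit_summary(fit: st.ModelFit) -> dict:
    hl, cs, nk = fit.pseudo_r2
    return {
        "ll": fit.ll,
        "ll_null": fit.ll_null,
        "k": fit.k,
        "n": fit.n,
        "aic": fit.aic,
        "bic": fit.bic,
        "df_resid": fit.df_resid,
        "pseudo_r2": {"hosmer_lemeshow": hl, "cox_snell": cs, "nagelkerke": nk},
    }


CONTROLS = ["age", "gender", "active_days", "activity"]


def run(config: RunConfig) -> dict:
    """Run the full pipeline; returns the report dict also written to disk."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    outputs: list[Path] = []

    def track(path: Path) -> Path:
        outputs.append(path)
        return path

    # --- corpus -----------------------------------------------------------
    if config.corpus is None:
        sc = dataclasses.replace(config.synth, seed=config.seed)
        posts, attr_list, truth = synth.generate(sc)
        rng = np.random.default_rng(config.seed + 1)
        posts = synth.plant_contamination(posts, truth, sc, rng)
        cps.write_posts(posts, track(out / "corpus.jsonl"))
        cps.write_attributes(attr_list, track(out / "attributes.tsv"))
        with open(track(out / "planted_truth.json"), "w", encoding="utf-8") as handle:
            json.dump(truth.to_jsonable(), handle, indent=2, sort_keys=True)
            handle.write("\n")
        attributes = {a.author: a for a in attr_list}
    else:
        posts = list(cps.read_posts(config.corpus))
        attributes = cps.read_attributes(config.attributes) if config.attributes else {}
    logger.info("corpus: %d posts, %d authors", len(posts), len({p.author for p in posts}))

    # --- cohort mining ----------------------------------------------------
    patterns = coh.load_patterns(config.patterns) if config.patterns else coh.default_patterns()
    cohort, decisions, summary = coh.build_cohort(posts, patterns)
    coh.write_decisions_tsv(decisions, track(out / "cohort_decisions.tsv"))
    logger.info(
        "cohort: %d/%d users included (%.1f%% single-post users)",
        len(cohort), summary.n_users, 100 * summary.frac_single_post_users,
    )

    # --- classify + score -------------------------------------------------
    taxonomy = tax.load_taxonomy(config.taxonomy) if config.taxonomy else tax.fixture_taxonomy()
    lexicon = lex.load_lexicon(config.lexicon) if config.lexicon else lex.default_lexicon()
    classified_scored = [
        (p, tax.classify(p.subreddit, taxonomy), lex.score_text(p.body, lexicon))
        for p in posts
    ]
    tax.write_classification_tsv(
        ((p.id, p.subreddit, ctx) for p, ctx, _ in classified_scored),
        track(out / "post_contexts.tsv"),
    )
    lex.write_scores_tsv(
        ((p.id, s) for p, _, s in classified_scored), track(out / "post_scores.tsv")
    )
    n_mh = sum(1 for _, ctx, _ in classified_scored if ctx == tax.MH)
    logger.info("classified: %d MH posts, %d non-MH posts", n_mh, len(posts) - n_mh)

    # --- aggregate --------------------------------------------------------
    records = agg.build_user_records(cohort, classified_scored, attributes, min_wc=config.min_wc)
    agg.write_records_tsv(records, track(out / "user_records.tsv"))
    partition = agg.partition_rq1(records)
    agg.write_partition(
        partition, track(out / "rq1_partition.json"), track(out / "rq1_partition.tsv")
    )
    logger.info(
        "partition: both %.1f%%, only-MH %.1f%%, only-non-MH %.1f%%",
        *(100 * partition.proportions[k] for k in ("both", "only_mh", "only_nonmh")),
    )

    # --- paired within-user comparison -----------------------------------
    rq2_sample = agg.select_rq2(records, min_posts=config.rq2_min)
    rq2 = st.rq2_table(rq2_sample)
    _write_rq2_tsv(rq2, track(out / "rq2_table.tsv"))
    logger.info("paired comparison: n = %d users", len(rq2_sample))

    # --- regression -------------------------------------------------------
    rq3_sample = agg.select_rq3(records, rq2_min=config.rq2_min, rq3_min=config.rq3_min)
    X, y = agg.regression_frame(rq3_sample)
    controls_est, controls_fit = st.fit_logistic(X[CONTROLS], y)
    full_est, full_fit = st.fit_logistic(X, y)
    lrt = st.likelihood_ratio(controls_fit, full_fit)
    _write_coefficients_tsv(full_est, track(out / "rq3_coefficients.tsv"))
    rel_prob = st.relative_probability(full_est, st.mean_profile(X))
    bal_rng = np.random.default_rng(config.seed + 2)
    Xb, yb, bal_est, bal_fit = st.gender_balanced_rerun(X, y, bal_rng)
    _write_coefficients_tsv(bal_est, track(out / "rq3_coefficients_gender_balanced.tsv"))
    modelfit = {
        "n": int(full_fit.n),
        "outcome_prevalence": float(np.mean(y)),
        "controls": _fit_summary(controls_fit),
        "full": _fit_summary(full_fit),
        "lrt": {"x2": lrt.x2, "df": lrt.df, "p": lrt.p},
        "relative_probability_gender_pct": rel_prob,
        "gender_balanced": {"n": int(bal_fit.n), **_fit_summary(bal_fit)},
    }
    with open(track(out / "rq3_modelfit.json"), "w", encoding="utf-8") as handle:
        json.dump(modelfit, handle, indent=2, sort_keys=True)
        handle.write("\n")
    logger.info(
        "regression: n = %d, LRT X2(%d) = %.2f, p = %.3g",
        full_fit.n, lrt.df, lrt.x2, lrt.p,
    )

    # --- manifest ---------------------------------------------------------
    manifest = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "version": __import__("bdforum").__version__,
        "files": {p.name: _sha256(p) for p in sorted(outputs)},
        "counts": {
            "posts": len(posts),
            "users": summary.n_users,
            "cohort": len(cohort),
            "rq2_sample": len(rq2_sample),
            "rq3_sample": len(rq3_sample),
        },
    }
    with open(out / "manifest.json", "w", encoding="utf-8") as handle:
        json.dump(manifest, handle, indent=2, sort_keys=True)
        handle.write("\n")

    return {
        "partition": partition,
        "rq2": rq2,
        "rq3_estimates": full_est,
        "rq3_controls_fit": controls_fit,
        "rq3_full_fit": full_fit,
        "lrt": lrt,
        "relative_probability_gender_pct": rel_prob,
        "gender_balanced_estimates": bal_est,
        "manifest": manifest,
    }
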