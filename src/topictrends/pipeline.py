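"""End-to-end pipeline: corpus in, reporting tables out.

``run_pipeline`` wires the stages together — read/deduplicate/filter,
tokenize/clean/count, topic-number selection, final fit, trend statistics,
term-group scoring, and (when full texts are supplied) the concordance
check — writing every table plus a reproducibility manifest to the output
directory.  A single global seed drives all stages; stage seeds are derived
deterministically as ``seed + stage ordinal``.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

from . import __version__
from .concordance import concordance_check
from .corpus_io import ExportDialect, deduplicate, filter_records, read_export
from .lda import LdaConfig, fit_lda_config
from .model_selection import select_k
from .preprocess import build_dtm, remove_custom_terms, remove_stopwords, tokenize
from .synthetic import read_fulltexts
from .term_analysis import load_term_groups, score_table, score_term_groups, top_terms
from .trends import annual_series, assign_topics, topic_summary, trend_table

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline"]

_STAGES = ("corpus", "preprocess", "select_k", "fit", "trends", "terms", "concordance")


@dataclass
class RunConfig:
    """Everything a run needs; round-trips through JSON."""

    input_paths: list[str]
    output_dir: str
    # screening
    require_abstract: bool = True
    year_range: tuple[int, int] | None = (2000, 2020)
    doc_types: list[str] | None = None  # None = {article, review}
    languages: list[str] | None = None  # None = {english}
    # preprocessing
    custom_patterns: list[str] = field(default_factory=list)
    min_term_freq: int = 1
    # model selection + fitting
    k_grid: list[int] = field(default_factory=lambda: [5, 9, 10, 20, 30])
    threshold: float = 0.999
    rule: str = "any_document"
    alpha: float | None = None
    eta: float = 0.1
    sweeps: int = 1000
    burn_in: int = 500
    estimator: str = "mean"
    seed: int = 1
    # reporting
    trend_alpha: float = 0.05
    top_n_terms: int = 100
    term_groups_path: str | None = None
    # concordance
    fulltext_dir: str | None = None
    concordance_m: int = 20

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        data = json.loads(Path(path).read_text())
        if data.get("year_range") is not None:
            data["year_range"] = tuple(data["year_range"])
        return cls(**data)

    def lda_config(self) -> LdaConfig:
        return LdaConfig(
            alpha=self.alpha, eta=self.eta, sweeps=self.sweeps,
            burn_in=self.burn_in, estimator=self.estimator,
        )


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis; returns the run manifest (also written to
    ``<output_dir>/manifest.json``).  Any stage failure aborts with the
    stage name recorded in the partial manifest."""
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "config": dataclasses.asdict(config),
        "seed": config.seed,
        "stages": {},
        "artifacts": [],
    }

    def _save_manifest():
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))

    stage = "corpus"
    try:
        t0 = time.perf_counter()
        records = []
        for p in config.input_paths:
            records.extend(read_export(p, ExportDialect()))
        records = deduplicate(records)
        records, report = filter_records(
            records,
            require_abstract=config.require_abstract,
            year_range=config.year_range,
            doc_types=set(config.doc_types) if config.doc_types else frozenset({"article", "review"}),
            languages=set(config.languages) if config.languages else frozenset({"english"}),
        )
        manifest["stages"][stage] = {
            "seconds": time.perf_counter() - t0,
            "n_input": report.n_input,
            "removed": report.removed,
            "n_retained": report.n_retained,
        }

        stage = "preprocess"
        t0 = time.perf_counter()
        tokens = tokenize(records)
        tokens = remove_stopwords(tokens)
        tokens = remove_custom_terms(tokens, config.custom_patterns)
        dtm = build_dtm(tokens, min_term_freq=config.min_term_freq)
        dtm.to_mtx(outdir / "dtm.mtx")
        manifest["stages"][stage] = {
            "seconds": time.perf_counter() - t0,
            "n_docs": dtm.n_docs,
            "n_terms": dtm.n_terms,
            "n_tokens": dtm.total_count,
        }
        manifest["artifacts"].append("dtm.mtx")

        stage = "select_k"
        t0 = time.perf_counter()
        selection = select_k(
            dtm, config.k_grid, threshold=config.threshold, rule=config.rule,
            config=config.lda_config(), base_seed=config.seed + _STAGES.index(stage),
        )
        selection.to_csv(outdir / "k_selection.csv")
        manifest["stages"][stage] = {
            "seconds": time.perf_counter() - t0,
            "chosen_k": selection.chosen_k,
        }
        manifest["chosen_k"] = selection.chosen_k
        manifest["artifacts"].append("k_selection.csv")

        stage = "fit"
        t0 = time.perf_counter()
        model = fit_lda_config(
            dtm, selection.chosen_k, config.lda_config(),
            seed=config.seed + _STAGES.index(stage),
        )
        model.save(outdir / "model")
        manifest["stages"][stage] = {"seconds": time.perf_counter() - t0}
        manifest["artifacts"].append("model/")

        stage = "trends"
        t0 = time.perf_counter()
        assignment = assign_topics(model)
        assignment.to_csv(outdir / "assignments.csv", index=False)
        summary = topic_summary(assignment, records, model)
        summary.to_csv(outdir / "topic_summary.csv", index=False)
        annual = annual_series(assignment, records, year_range=config.year_range)
        annual.to_csv(outdir / "annual_series.csv", index=False)
        fits = trend_table(annual, alpha=config.trend_alpha)
        fits.to_csv(outdir / "trend_fits.csv", index=False)
        manifest["stages"][stage] = {"seconds": time.perf_counter() - t0}
        manifest["artifacts"] += ["assignments.csv", "topic_summary.csv", "annual_series.csv", "trend_fits.csv"]

        stage = "terms"
        t0 = time.perf_counter()
        top = {
            k: top_terms(model, k, n=min(config.top_n_terms, len(model.terms)))
            for k in range(model.k)
        }
        (outdir / "top_terms.json").write_text(
            json.dumps({str(k): v for k, v in top.items()}, indent=2)
        )
        groups = load_term_groups(config.term_groups_path) if config.term_groups_path else None
        scores = score_term_groups(model, groups, top_n=config.top_n_terms)
        score_table(scores).to_csv(outdir / "term_group_scores.csv")
        manifest["stages"][stage] = {"seconds": time.perf_counter() - t0}
        manifest["artifacts"] += ["top_terms.json", "term_group_scores.csv"]

        if config.fulltext_dir is not None:
            stage = "concordance"
            t0 = time.perf_counter()
            fulltexts = read_fulltexts(config.fulltext_dir)
            result = concordance_check(
                model, fulltexts, m=config.concordance_m,
                custom_patterns=tuple(config.custom_patterns),
                min_term_freq=config.min_term_freq,
                lda_config=config.lda_config(),
                seed=config.seed + _STAGES.index(stage),
            )
            result.table.to_csv(outdir / "concordance_docs.csv", index=False)
            (outdir / "concordance.json").write_text(
                json.dumps(
                    {
                        "n_requested": result.n_requested,
                        "n_available": result.n_available,
                        "n_agree": result.n_agree,
                        "pct_agree": result.pct_agree,
                        "pct_agree_rounded": result.pct_agree_rounded,
                        "topic_mapping": {str(a): b for a, b in result.topic_mapping.items()},
                    },
                    indent=2,
                )
            )
            manifest["stages"][stage] = {
                "seconds": time.perf_counter() - t0,
                "pct_agree": result.pct_agree,
            }
            manifest["artifacts"] += ["concordance_docs.csv", "concordance.json"]
    except Exception as exc:
        manifest["failed_stage"] = stage
        manifest["error"] = repr(exc)
        _save_manifest()
        raise

    _save_manifest()
    return manifest
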