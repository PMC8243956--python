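"""End-to-end orchestration from one declarative config, with a run manifest.

Stages: data (generate a synthetic preset, or load counts/ratings/judgments
CSVs) -> composite corpus pooling -> semantic pooling -> training runs +
evaluation -> report.  Every stage's randomness descends from the single
master seed, and the manifest embeds the full config snapshot so a completed
run can be re-executed exactly.
"""

from __future__ import annotations


import hashlib
import json
import logging
from datetime import datetime, timezone
from pathlib import Path

import pandas as pd
import yaml

from . import __version__, _seeds
from .corpus import (
    VerbLexicon,
    build_composite_corpus,
    read_corpus_counts,
    write_composite_corpus,
)
from .errors import SchemaError, ValidationError
from .evaluation import (
    ExperimentConfig,
    ExperimentResult,
    critical_r,
    read_judgments,
    run_experiment,
)
from .learner import LearnerConfig
from .semantics import pool_semantic_profiles, read_semantic_ratings, write_profiles
from .synth import generate_dataset, preset_config

log = logging.getLogger("dircause")

DEFAULT_CONFIG = {
    "seed": 0,
    "out": "results",
    "plot": False,
    "scale": {"min": 1.0, "max": 9.0},
    "data": {"preset": "strong"},
    "corpus": {"n_per_language": 300_000},
    "experiment": {
        "n_runs": 48,
        "n_epochs": 50,
        "n_per_epoch": 10_000,
        "scheme": "split_half",
        "kfold_k": 4,
        "permute_semantics": False,
        "permutation_per_run": True,
        "resample_per_epoch": True,
        "learning_rate": 0.01,
        "use_bias": False,
        "loss": "xent",
    },
}

#: reserved seed slots for the pooling stage and preset generation
_POOL_SLOT = (999, 998)
_SYNTH_SLOT = (999, 997)


def load_config(source) -> dict:
    """Load and normalize a pipeline config from a YAML path or a dict."""
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            raw = yaml.safe_load(fh) or {}
    elif isinstance(source, dict):
        raw = source
    else:
        raise SchemaError("config must be a mapping or a path to a YAML file")
    if "config" in raw:  # a manifest: re-execute its embedded snapshot
        raw = raw["config"]
    cfg = {k: (dict(v) if isinstance(v, dict) else v) for k, v in DEFAULT_CONFIG.items()}
    for key, value in raw.items():
        if key not in cfg:
            raise SchemaError(f"unknown config key {key!r}")
        if isinstance(cfg[key], dict):
            if not isinstance(value, dict):
                raise SchemaError(f"config section {key!r} must be a mapping")
            unknown = set(value) - set(cfg[key]) - {"counts", "ratings", "judgments", "overrides"}
            if key == "data":
                unknown -= {"preset"}
            if unknown:
                raise SchemaError(f"unknown key(s) {sorted(unknown)} in section {key!r}")
            cfg[key].update(value)
        else:
            cfg[key] = value
    return cfg


def experiment_config(cfg: dict) -> ExperimentConfig:
    e = cfg["experiment"]
    return ExperimentConfig(
        n_runs=int(e["n_runs"]),
        n_epochs=int(e["n_epochs"]),
        n_per_epoch=int(e["n_per_epoch"]),
        scheme=str(e["scheme"]),
        kfold_k=int(e["kfold_k"]),
        permute_semantics=bool(e["permute_semantics"]),
        permutation_per_run=bool(e["permutation_per_run"]),
        resample_per_epoch=bool(e["resample_per_epoch"]),
        learner=LearnerConfig(
            learning_rate=float(e["learning_rate"]),
            use_bias=bool(e["use_bias"]),
            loss=str(e["loss"]),
        ),
        seed=int(cfg["seed"]),
    )


def _file_digest(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def _load_inputs(cfg: dict):
    """Return (lexicon, corpora, ratings, judgments, input_digests)."""
    data = cfg["data"]
    scale = cfg["scale"]
    digests = {}
    if "preset" in data and data.get("preset"):
        overrides = dict(data.get("overrides") or {})
        gen = preset_config(
            str(data["preset"]),
            seed=_seeds.run_epoch_seed(int(cfg["seed"]), *_SYNTH_SLOT),
            scale_min=float(scale["min"]),
            scale_max=float(scale["max"]),
            **overrides,
        )
        ds = generate_dataset(gen)
        log.info("data: generated preset %r (%d verbs)", data["preset"], gen.n_verbs)
        return ds.lexicon, ds.corpora, ds.ratings, ds.judgments, digests
    for key in ("counts", "ratings", "judgments"):
        if key not in data:
            raise SchemaError("data section needs either 'preset' or counts/ratings/judgments paths")
    counts_paths = list(data["counts"])
    if not counts_paths:
        raise ValidationError("data.counts lists no files")
    lexicon = VerbLexicon(
        tuple(pd.read_csv(counts_paths[0])["verb"].drop_duplicates().astype(str))
    )
    corpora = []
    for p in counts_paths:
        corpora.append(read_corpus_counts(p, lexicon))
        digests[str(p)] = _file_digest(p)
    ratings = read_semantic_ratings(data["ratings"], float(scale["min"]), float(scale["max"]))
    digests[str(data["ratings"])] = _file_digest(data["ratings"])
    judgments = read_judgments(data["judgments"])
    digests[str(data["judgments"])] = _file_digest(data["judgments"])
    log.info("data: loaded %d corpora, %d verbs", len(corpora), len(lexicon))
    return lexicon, corpora, ratings, judgments, digests


def build_report(result: ExperimentResult, cfg: dict, lexicon: VerbLexicon) -> dict:
    """Summary surface: config echo, critical values, final-epoch gate table."""
    econf = result.config
    n_verbs = len(lexicon)
    if econf.scheme == "split_half":
        n_train = n_verbs // 2
    else:
        n_train = n_verbs - n_verbs // econf.kfold_k
    df_by_set = {"seen": n_train - 2, "unseen": (n_verbs - n_train) - 2}
    crit = {
        "full_lexicon": {
            "df": n_verbs - 2,
            "p05_one_tailed": critical_r(n_verbs - 2, 0.05, "one"),
            "p01_one_tailed": critical_r(n_verbs - 2, 0.01, "one"),
        }
    }
    for vs, dfree in df_by_set.items():
        crit[vs] = {
            "df": dfree,
            "p05_one_tailed": critical_r(dfree, 0.05, "one"),
            "p01_one_tailed": critical_r(dfree, 0.01, "one"),
        }
    final = {}
    for row in result.final_epoch_summary().itertuples(index=False):
        cell = final.setdefault(row.measure, {})
        cell[row.verb_set] = {
            "mean_r": None if pd.isna(row.mean_r) else float(row.mean_r),
            "sd_r": None if pd.isna(row.sd_r) else float(row.sd_r),
            "n_runs": int(row.n_runs),
            "significant_p05": bool(
                not pd.isna(row.mean_r)
                and row.mean_r > crit[row.verb_set]["p05_one_tailed"]
            ),
            "significant_p01": bool(
                not pd.isna(row.mean_r)
                and row.mean_r > crit[row.verb_set]["p01_one_tailed"]
            ),
        }
    last_epoch = int(result.run_averaged["epoch"].max())
    run_avg_final = {
        m: {
            vs: (None if pd.isna(r) else float(r))
            for vs, r in result.run_averaged[
                (result.run_averaged.epoch == last_epoch)
                & (result.run_averaged.measure == m)
            ][["verb_set", "r"]].itertuples(index=False)
        }
        for m in result.run_averaged["measure"].unique()
    }
    return {
        "package_version": __version__,
        "config": cfg,
        "n_verbs": n_verbs,
        "critical_r": crit,
        "final_epoch": {"epoch": last_epoch, "correlations": final},
        "run_averaged_final": run_avg_final,
    }


def run_pipeline(config_source, out_dir=None) -> dict:
    """Execute all stages; write outputs and a manifest; return the manifest."""
    cfg = load_config(config_source)
    out = Path(out_dir if out_dir is not None else cfg["out"])
    out.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])

    lexicon, corpora, ratings, judgments, digests = _load_inputs(cfg)

    log.info("corpus: pooling %d languages", len(corpora))
    composite = build_composite_corpus(
        corpora,
        int(cfg["corpus"]["n_per_language"]),
        _seeds.run_epoch_seed(seed, *_POOL_SLOT),
    )
    write_composite_corpus(composite, lexicon, out / "composite.csv")
    (out / "composite_provenance.json").write_text(
        json.dumps(
            {
                "languages": {lang: n for lang, n in composite.provenance},
                "seed": _seeds.run_epoch_seed(seed, *_POOL_SLOT),
            },
            indent=2,
        )
    )

    scale = cfg["scale"]
    profiles = pool_semantic_profiles(ratings, float(scale["min"]), float(scale["max"]), lexicon)
    write_profiles(profiles, lexicon, out / "profiles.csv")

    econf = experiment_config(cfg)
    log.info(
        "experiment: %d runs x %d epochs x %d exemplars (%s%s)",
        econf.n_runs,
        econf.n_epochs,
        econf.n_per_epoch,
        econf.scheme,
        ", permuted semantics" if econf.permute_semantics else "",
    )
    result = run_experiment(econf, composite, profiles, judgments, lexicon)

    result.correlations.to_csv(out / "correlations.csv", index=False)
    result.run_averaged.to_csv(out / "run_averaged_correlations.csv", index=False)
    result.predictions_frame(lexicon).to_csv(out / "predictions.csv", index=False)
    report = build_report(result, cfg, lexicon)
    (out / "report.json").write_text(json.dumps(report, indent=2))
    if cfg.get("plot"):
        from .plotting import plot_correlation_series

        plot_correlation_series(result.correlations, out / "correlations.png")

    manifest = {
        "package_version": __version__,
        "created_utc": datetime.now(timezone.utc).isoformat(),
        "seed": seed,
        "config": cfg,
        "input_digests": digests,
        "outputs": sorted(p.name for p in out.iterdir() if p.name != "manifest.json"),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    log.info("pipeline complete: %s", out)
    return manifest
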