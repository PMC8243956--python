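"""Model-human evaluation: judgment tables, correlations, folds, experiments.

The result surface mirrors the study design: 48 independent model runs, each
trained for 50 epochs of 10,000 exemplars on a random half (or k-fold
complement) of the lexicon, interrogated after every epoch on every verb, and
correlated (Pearson) with across-participant mean acceptability judgments —
separately for three measures (difference score a_less - a_more, raw less, raw
more) and two verb sets (seen during training vs held out).

Per-run correlations are the headline (their across-run SD is the dispersion
shown as error bars); a run-averaged variant — one correlation per epoch on
activations first averaged over runs — is computed alongside.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import scipy.stats

from . import _seeds
from .corpus import CompositeCorpus, VerbLexicon, sample_exemplars, shuffle_stream
from .errors import (
    CoverageError,
    SchemaError,
    UndefinedCorrelationError,
    ValidationError,
)
from .learner import LearnerConfig, init_learner, interrogate_all, train_epoch
from .semantics import ProfileMap, permute_profiles

MEASURES = ("diff", "less", "more")
VERB_SETS = ("seen", "unseen")

_JUDGMENT_COLUMNS = ("participant", "verb", "form", "rating")
_FORMS = ("less", "more")


def read_judgments(path) -> pd.DataFrame:
    """Read a per-participant judgments CSV (participant, verb, form, rating).

    Ratings are integers on the 5-point acceptability scale; each
    (participant, verb, form) key may appear at most once.
    """
    df = pd.read_csv(path)
    missing = [c for c in _JUDGMENT_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"judgments file missing column(s) {missing}")
    return validate_judgments(df)


def validate_judgments(df: pd.DataFrame) -> pd.DataFrame:
    bad = set(df["form"]) - set(_FORMS)
    if bad:
        raise SchemaError(f"unknown form name(s) {sorted(bad)}")
    r = df["rating"].to_numpy()
    if not np.issubdtype(r.dtype, np.integer) or (r < 1).any() or (r > 5).any():
        raise ValidationError("ratings must be integers in 1..5")
    if df.duplicated(subset=["participant", "verb", "form"]).any():
        raise ValidationError("duplicate (participant, verb, form) rating")
    return df[list(_JUDGMENT_COLUMNS)].copy()


def write_judgments(df: pd.DataFrame, path) -> None:
    df[list(_JUDGMENT_COLUMNS)].to_csv(path, index=False)


@dataclass(frozen=True)
class VerbFormMeans:
    """Across-participant mean rating per verb and form, in lexicon order."""

    less: np.ndarray
    more: np.ndarray

    @property
    def diff(self) -> np.ndarray:
        """Relative preference for the less- over the more-transparent form."""
        return self.less - self.more

    def measure(self, name: str) -> np.ndarray:
        if name == "diff":
            return self.diff
        if name == "less":
            return self.less
        if name == "more":
            return self.more
        raise ValidationError(f"unknown measure {name!r}")


def mean_judgments(table: pd.DataFrame, lexicon: VerbLexicon) -> VerbFormMeans:
    means = table.groupby(["verb", "form"], sort=False)["rating"].mean()
    out = {f: np.full(len(lexicon), np.nan) for f in _FORMS}
    for (verb, form), m in means.items():
        out[str(form)][lexicon.index(str(verb))] = m
    for f in _FORMS:
        if np.isnan(out[f]).any():
            raise CoverageError(f"missing mean rating for some verb in form {f!r}")
    return VerbFormMeans(less=out["less"], more=out["more"])


def pearson_r(x: Sequence[float], y: Sequence[float]) -> float:
    """Sample Pearson correlation; undefined on constant input (never coerced to 0)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("x and y must be 1-d and of equal length")
    if len(x) < 3:
        raise ValidationError("need at least 3 points")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedCorrelationError("correlation undefined for a constant vector")
    return float(scipy.stats.pearsonr(x, y).statistic)


def critical_r(df: int, alpha: float, tails: str = "one") -> float:
    """Smallest |r| significant at ``alpha`` with ``df`` degrees of freedom.

    r_crit = t_crit / sqrt(t_crit^2 + df), with t_crit the upper-alpha (or
    alpha/2 for two-tailed) Student-t quantile.
    """
    if df < 1:
        raise ValidationError("df must be >= 1")
    if not 0 < alpha < 1:
        raise ValidationError("alpha must lie in (0, 1)")
    if tails not in ("one", "two"):
        raise ValidationError("tails must be 'one' or 'two'")
    a = alpha if tails == "one" else alpha / 2
    t = scipy.stats.t.ppf(1 - a, df)
    return float(t / np.sqrt(t * t + df))


@dataclass(frozen=True)
class FoldPlan:
    """Per-run partition of the lexicon into training and held-out verbs."""

    scheme: str
    folds: tuple[tuple[np.ndarray, np.ndarray], ...]  # (train_ids, heldout_ids) per run

    def __len__(self) -> int:
        return len(self.folds)


def make_fold_plan(
    n_verbs: int, scheme: str, n_runs: int, seed: int, k: int = 4
) -> FoldPlan:
    """Fresh random partition per run: split-half, or one random held-out fold of k."""
    if n_runs < 1:
        raise ValidationError("n_runs must be >= 1")
    rng = np.random.default_rng(seed)
    folds = []
    if scheme == "split_half":
        if n_verbs % 2 != 0:
            raise ValidationError("split_half needs an even lexicon size")
        half = n_verbs // 2
        for _ in range(n_runs):
            perm = rng.permutation(n_verbs)
            folds.append((np.sort(perm[:half]), np.sort(perm[half:])))
    elif scheme == "kfold":
        if n_verbs % k != 0:
            raise ValidationError(f"k={k} does not divide lexicon size {n_verbs}")
        size = n_verbs // k
        for _ in range(n_runs):
            perm = rng.permutation(n_verbs)
            held_fold = int(rng.integers(k))
            held = perm[held_fold * size : (held_fold + 1) * size]
            train = np.setdiff1d(perm, held)
            folds.append((np.sort(train), np.sort(held)))
    else:
        raise ValidationError(f"unknown scheme {scheme!r}")
    return FoldPlan(scheme=scheme, folds=tuple(folds))


@dataclass(frozen=True)
class ExperimentConfig:
    n_runs: int = 48
    n_epochs: int = 50
    n_per_epoch: int = 10_000
    scheme: str = "split_half"
    kfold_k: int = 4
    permute_semantics: bool = False
    permutation_per_run: bool = True
    resample_per_epoch: bool = True
    learner: LearnerConfig = field(default_factory=LearnerConfig)
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_runs, self.n_epochs, self.n_per_epoch) < 1:
            raise ValidationError("n_runs, n_epochs and n_per_epoch must be >= 1")


@dataclass
class ExperimentResult:
    config: ExperimentConfig
    predictions: np.ndarray  # (n_runs, n_epochs, n_verbs, 3) activations
    seen: np.ndarray  # (n_runs, n_verbs) bool
    correlations: pd.DataFrame  # epoch, measure, verb_set, mean_r, sd_r, n_runs
    run_averaged: pd.DataFrame  # epoch, measure, verb_set, r

    def predictions_frame(self, lexicon: Optional[VerbLexicon] = None) -> pd.DataFrame:
        R, E, V, _ = self.predictions.shape
        run, epoch, verb = np.meshgrid(
            np.arange(R), np.arange(1, E + 1), np.arange(V), indexing="ij"
        )
        flat = self.predictions.reshape(-1, 3)
        df = pd.DataFrame(
            {
                "run": run.ravel(),
                "epoch": epoch.ravel(),
                "verb": verb.ravel(),
                "a_less": flat[:, 0],
                "a_more": flat[:, 1],
                "a_other": flat[:, 2],
            }
        )
        df["diff"] = df["a_less"] - df["a_more"]
        df["seen"] = self.seen[df["run"], df["verb"]]
        if lexicon is not None:
            df["verb"] = [lexicon.labels[v] for v in df["verb"]]
        return df

    def final_epoch_summary(self) -> pd.DataFrame:
        last = self.correlations["epoch"].max()
        return self.correlations[self.correlations["epoch"] == last].reset_index(drop=True)


def _single_run(
    config: ExperimentConfig,
    composite: CompositeCorpus,
    profiles: ProfileMap,
    run: int,
    train_ids: np.ndarray,
) -> np.ndarray:
    """Train one run and return its (n_epochs, n_verbs, 3) interrogation record."""
    prof = profiles
    if config.permute_semantics:
        pseed = _seeds.permutation_seed(config.seed, run if config.permutation_per_run else 0)
        prof = permute_profiles(profiles, pseed)
    state = init_learner(config.learner, len(profiles))
    record = np.empty((config.n_epochs, len(profiles), 3))
    base_stream = None
    for epoch in range(1, config.n_epochs + 1):
        eseed = _seeds.run_epoch_seed(config.seed, run, epoch)
        if config.resample_per_epoch or base_stream is None:
            stream = sample_exemplars(
                composite, config.n_per_epoch, restrict_to=train_ids, seed=eseed
            )
            base_stream = stream
        else:
            stream = shuffle_stream(base_stream, eseed)
        train_epoch(state, stream, prof, config.learner.learning_rate)
        record[epoch - 1] = interrogate_all(state, prof)
    return record


def _rowwise_r(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Pearson r of each row of X against y; NaN where either side is constant."""
    Xc = X - X.mean(axis=-1, keepdims=True)
    yc = y - y.mean()
    num = Xc @ yc
    den = np.sqrt((Xc**2).sum(axis=-1) * (yc**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(den > 0, num / np.where(den > 0, den, 1.0), np.nan)
    return r


def run_predictions(
    config: ExperimentConfig, composite: CompositeCorpus, profiles: ProfileMap
) -> tuple[np.ndarray, np.ndarray, FoldPlan]:
    """All runs' per-epoch interrogations plus the seen-verb mask per run."""
    n_verbs = len(profiles)
    plan = make_fold_plan(
        n_verbs, config.scheme, config.n_runs, _seeds.fold_seed(config.seed), config.kfold_k
    )
    preds = np.empty((config.n_runs, config.n_epochs, n_verbs, 3))
    seen = np.zeros((config.n_runs, n_verbs), dtype=bool)
    for run, (train_ids, _held) in enumerate(plan.folds):
        seen[run, train_ids] = True
        preds[run] = _single_run(config, composite, profiles, run, train_ids)
    return preds, seen, plan


def correlate_predictions(
    preds: np.ndarray, seen: np.ndarray, human: VerbFormMeans
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-run-then-aggregate and run-averaged correlation series.

    Undefined correlations (a constant vector on either side) are recorded as
    missing and excluded from the mean/SD; ``n_runs`` counts defined values.
    """
    R, E, V, _ = preds.shape
    model = {
        "diff": preds[..., 0] - preds[..., 1],
        "less": preds[..., 0],
        "more": preds[..., 1],
    }
    rows = []
    avg_rows = []
    for measure in MEASURES:
        M = model[measure]
        y = human.measure(measure)
        for verb_set in VERB_SETS:
            in_set = seen if verb_set == "seen" else ~seen
            per_run = np.full((R, E), np.nan)
            for i in range(R):
                idx = np.flatnonzero(in_set[i])
                if idx.size >= 3:
                    per_run[i] = _rowwise_r(M[i][:, idx], y[idx])
            with np.errstate(invalid="ignore"):
                mean_r = np.nanmean(per_run, axis=0)
                n_def = np.sum(~np.isnan(per_run), axis=0)
                sd_r = np.full(E, np.nan)
                ok = n_def > 1
                sd_r[ok] = np.nanstd(per_run[:, ok], axis=0, ddof=1)
            for e in range(E):
                rows.append(
                    (e + 1, measure, verb_set, mean_r[e], sd_r[e], int(n_def[e]))
                )
            # run-averaged variant: average activations over the runs in which
            # each verb falls in this set, then one correlation per epoch
            counts = in_set.sum(axis=0).astype(float)  # (V,)
            valid = counts > 0
            if valid.sum() >= 3:
                summed = np.einsum("rev,rv->ev", M, in_set.astype(float))
                avg = summed[:, valid] / counts[valid]
                r_avg = _rowwise_r(avg, y[valid])
            else:
                r_avg = np.full(E, np.nan)
            for e in range(E):
                avg_rows.append((e + 1, measure, verb_set, r_avg[e]))
    series = pd.DataFrame(
        rows, columns=["epoch", "measure", "verb_set", "mean_r", "sd_r", "n_runs"]
    )
    run_avg = pd.DataFrame(avg_rows, columns=["epoch", "measure", "verb_set", "r"])
    return series, run_avg


def run_experiment(
    config: ExperimentConfig,
    composite: CompositeCorpus,
    profiles: ProfileMap,
    judgments: pd.DataFrame,
    lexicon: VerbLexicon,
) -> ExperimentResult:
    """Full protocol: folds, (optional) permutation, training, interrogation,
    and model-human correlation aggregation."""
    if len(profiles) != len(lexicon) or composite.counts.shape[0] != len(lexicon):
        raise ValidationError("composite, profiles and lexicon sizes disagree")
    human = mean_judgments(judgments, lexicon)
    preds, seen, _plan = run_predictions(config, composite, profiles)
    series, run_avg = correlate_predictions(preds, seen, human)
    return ExperimentResult(
        config=config,
        predictions=preds,
        seen=seen,
        correlations=series,
        run_averaged=run_avg,
    )


def heldout_df(n_heldout: int) -> int:
    """Degrees of freedom for a correlation over n verbs (n - 2)."""
    return n_heldout - 2


__all__ = [
    "MEASURES",
    "VERB_SETS",
    "ExperimentConfig",
    "ExperimentResult",
    "FoldPlan",
    "VerbFormMeans",
    "correlate_predictions",
    "critical_r",
    "heldout_df",
    "make_fold_plan",
    "mean_judgments",
    "pearson_r",
    "read_judgments",
    "run_experiment",
    "run_predictions",
    "validate_judgments",
    "write_judgments",
]
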