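"""Synthetic study data with the structure the analysis assumes.

A single latent per verb — directness of causation, theta in [0, 1] — drives
everything: the four semantic features are monotone functions of theta plus
rater noise (direct causation merges the causing and caused events and
requires a causer, while suppressing causee autonomy and directive causation);
each synthetic language's corpus prefers the less-transparent causative for
more-direct verbs through a logistic link with slope ``effect_strength``; and
participants' 5-point acceptability judgments follow the same latent with
participant noise and Likert discretization.

The generator targets this assumed structure, not the empirical distributions
of any real corpus: it is the ground truth against which parameter recovery by
the full pipeline is measured.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .corpus import CorpusCounts, VerbLexicon, write_corpus_counts
from .errors import ValidationError
from .semantics import FEATURES, ProfileMap, pool_semantic_profiles, write_profiles
from .evaluation import validate_judgments, write_judgments


@dataclass(frozen=True)
class GeneratorConfig:
    """Study-scale defaults: 60 verbs, 5 languages x 20 raters, 48 participants."""

    n_verbs: int = 60
    n_languages: int = 5
    n_raters_per_language: int = 20
    n_participants: int = 48
    corpus_total_per_language: int = 300_000
    effect_strength: float = 6.0  # logistic slope of the latent on form choice
    rater_noise_sd: float = 0.10  # SD as a fraction of the instrument range
    participant_noise_sd: float = 0.10  # SD on the unit acceptability scale
    other_rate: float = 0.5  # baseline probability of a noncausative token
    lenience: float = 0.0  # 0..1: pull of MORE-form judgments toward ceiling
    language_offset_sd: float = 0.25  # per-language intercept spread (logit scale)
    scale_min: float = 1.0
    scale_max: float = 9.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(
            self.n_verbs,
            self.n_languages,
            self.n_raters_per_language,
            self.n_participants,
            self.corpus_total_per_language,
        ) < 1:
            raise ValidationError("all sizes must be >= 1")
        if self.effect_strength < 0:
            raise ValidationError("effect_strength must be >= 0")
        if not 0 <= self.other_rate <= 1:
            raise ValidationError("other_rate must lie in [0, 1]")
        if not 0 <= self.lenience <= 1:
            raise ValidationError("lenience must lie in [0, 1]")
        if not self.scale_max > self.scale_min:
            raise ValidationError("scale_max must exceed scale_min")


#: Named study conditions.  "strong" is the default signal regime; "null"
#: severs the latent from form choice and judgments (effect_strength 0);
#: "balinese-like" adds across-the-board tolerance for the more-transparent
#: form on the judgment side only.
PRESETS = {
    "strong": {},
    "null": {"effect_strength": 0.0},
    "balinese-like": {"lenience": 1.0},
}


def preset_config(name: str, seed: int = 0, **overrides) -> GeneratorConfig:
    if name not in PRESETS:
        raise ValidationError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}")
    return GeneratorConfig(seed=seed, **{**PRESETS[name], **overrides})


def _rng(config: GeneratorConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng((config.seed, stream))


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def generate_lexicon(config: GeneratorConfig) -> tuple[VerbLexicon, np.ndarray]:
    """Verb labels plus latent directness values spanning [0, 1] with jitter."""
    if config.n_verbs < 2:
        raise ValidationError("need at least 2 verbs")
    rng = _rng(config, 1)
    theta = np.linspace(0.0, 1.0, config.n_verbs)
    jitter = rng.uniform(-0.4, 0.4, config.n_verbs) / (config.n_verbs - 1)
    theta = np.clip(theta + jitter, 0.0, 1.0)
    return VerbLexicon.default(config.n_verbs), theta


# Monotone maps from latent directness to each feature's noiseless mean, on
# [0, 1]: direct causation merges events and requires a causer; indirect
# causation leaves the causee autonomous and invites directive causation.
FEATURE_MAPS = {
    "event_merge": lambda t: t,
    "autonomy": lambda t: 1.0 - t,
    "directive": lambda t: (1.0 - t) ** 2,
    "requires": lambda t: t**2,
}


def generate_semantic_ratings(theta: np.ndarray, config: GeneratorConfig) -> pd.DataFrame:
    """Per-rater feature ratings: scaled monotone map of theta plus rater noise.

    Noise is Gaussian with SD ``rater_noise_sd`` expressed as a fraction of the
    instrument range, applied before scaling and truncated to the bounds.
    """
    rng = _rng(config, 2)
    lexicon = VerbLexicon.default(len(theta))
    span = config.scale_max - config.scale_min
    rows = []
    for lang in range(config.n_languages):
        for rater in range(config.n_raters_per_language):
            rater_id = f"L{lang + 1}_r{rater + 1:02d}"
            for feature in FEATURES:
                m = FEATURE_MAPS[feature](theta)
                noisy = np.clip(m + rng.normal(0.0, config.rater_noise_sd, len(theta)), 0, 1)
                ratings = config.scale_min + span * noisy
                for v in range(len(theta)):
                    rows.append((rater_id, f"L{lang + 1}", lexicon.labels[v], feature, ratings[v]))
    return pd.DataFrame(rows, columns=["rater", "language", "verb", "feature", "rating"])


def generate_corpus_counts(theta: np.ndarray, config: GeneratorConfig) -> list[CorpusCounts]:
    """One verb-by-construction count table per synthetic language.

    Per-verb token totals follow a seeded long-tailed (lognormal) distribution;
    within a verb, a token is noncausative (OTHER) with probability
    ``other_rate`` and otherwise LESS-transparent with probability
    sigmoid(effect_strength * (theta - 0.5) + language offset).
    """
    rng = _rng(config, 3)
    n_verbs = len(theta)
    if config.corpus_total_per_language < n_verbs:
        raise ValidationError("corpus_total_per_language must be >= n_verbs")
    offsets = rng.normal(0.0, config.language_offset_sd, config.n_languages)
    corpora = []
    for lang in range(config.n_languages):
        weights = rng.lognormal(0.0, 1.0, n_verbs)
        totals = rng.multinomial(config.corpus_total_per_language, weights / weights.sum())
        p_less = _sigmoid(config.effect_strength * (theta - 0.5) + offsets[lang])
        counts = np.zeros((n_verbs, 3), dtype=np.int64)
        for v in range(n_verbs):
            p = np.array(
                [
                    (1 - config.other_rate) * p_less[v],
                    (1 - config.other_rate) * (1 - p_less[v]),
                    config.other_rate,
                ]
            )
            counts[v] = rng.multinomial(totals[v], p)
        corpora.append(CorpusCounts(language=f"L{lang + 1}", counts=counts))
    return corpora


def latent_acceptability(theta: np.ndarray, config: GeneratorConfig) -> tuple[np.ndarray, np.ndarray]:
    """Noiseless unit-scale acceptability of the two forms per verb.

    ``lenience`` interpolates the MORE-form curve toward a flat ceiling (0.97),
    emulating across-the-board tolerance for the periphrastic causative: at 1
    the MORE judgments carry no latent signal at all, while the LESS form and
    the difference score retain theirs.
    """
    accept_less = _sigmoid(config.effect_strength * (theta - 0.5))
    base_more = _sigmoid(-config.effect_strength * (theta - 0.5))
    accept_more = (1 - config.lenience) * base_more + config.lenience * 0.97
    return accept_less, accept_more


def generate_judgments(theta: np.ndarray, config: GeneratorConfig) -> pd.DataFrame:
    """48-participant 5-point Likert table for both causative forms per verb."""
    rng = _rng(config, 4)
    lexicon = VerbLexicon.default(len(theta))
    accept_less, accept_more = latent_acceptability(theta, config)
    rows = []
    for p in range(config.n_participants):
        pid = f"p{p + 1:02d}"
        for form, accept in (("less", accept_less), ("more", accept_more)):
            noisy = accept + rng.normal(0.0, config.participant_noise_sd, len(theta))
            ratings = np.clip(np.rint(1 + 4 * noisy), 1, 5).astype(int)
            for v in range(len(theta)):
                rows.append((pid, lexicon.labels[v], form, ratings[v]))
    df = pd.DataFrame(rows, columns=["participant", "verb", "form", "rating"])
    return validate_judgments(df)


@dataclass(frozen=True)
class SyntheticDataset:
    config: GeneratorConfig
    lexicon: VerbLexicon
    theta: np.ndarray
    corpora: list[CorpusCounts]
    ratings: pd.DataFrame
    judgments: pd.DataFrame

    def pooled_profiles(self) -> ProfileMap:
        return pool_semantic_profiles(
            self.ratings, self.config.scale_min, self.config.scale_max, self.lexicon
        )


def generate_dataset(config: GeneratorConfig) -> SyntheticDataset:
    lexicon, theta = generate_lexicon(config)
    return SyntheticDataset(
        config=config,
        lexicon=lexicon,
        theta=theta,
        corpora=generate_corpus_counts(theta, config),
        ratings=generate_semantic_ratings(theta, config),
        judgments=generate_judgments(theta, config),
    )


def write_fixture_set(dataset: SyntheticDataset, out_dir) -> dict[str, str]:
    """Write counts (one CSV per language), ratings, pooled profiles, judgments."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    for corpus in dataset.corpora:
        p = out / f"counts_{corpus.language}.csv"
        write_corpus_counts(corpus, dataset.lexicon, p)
        paths[f"counts_{corpus.language}"] = str(p)
    ratings_path = out / "ratings.csv"
    dataset.ratings.to_csv(ratings_path, index=False)
    paths["ratings"] = str(ratings_path)
    profiles_path = out / "profiles.csv"
    write_profiles(dataset.pooled_profiles(), dataset.lexicon, profiles_path)
    paths["profiles"] = str(profiles_path)
    judgments_path = out / "judgments.csv"
    write_judgments(dataset.judgments, judgments_path)
    paths["judgments"] = str(judgments_path)
    theta_path = out / "latent_theta.csv"
    pd.DataFrame({"verb": dataset.lexicon.labels, "theta": dataset.theta}).to_csv(
        theta_path, index=False
    )
    paths["latent_theta"] = str(theta_path)
    return paths
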