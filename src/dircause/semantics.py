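"""Semantic feature profiles: rating input, cross-language pooling, permutation.

Each verb carries four continuous semantic features drawn from the typology of
causation — Event-Merge (do the causing and caused events merge in space and
time?), Autonomy (does the causee retain autonomy?), Directive (is causation by
directive rather than physical means?), and Requires (does the event require an
external causer?).  Raters judge each verb on an instrument scale; ratings are
pooled by taking the mean over all raters of all languages and min-max rescaled
to [0, 1].

The random-semantics control permutes whole four-feature profiles across verb
identities: the internal structure of the feature set is untouched, but the
link between a verb's semantics and its corpus distribution is destroyed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd

from .corpus import VerbLexicon
from .errors import CoverageError, SchemaError, ValidationError

#: Fixed feature order; also the order of the four semantic input units.
FEATURES = ("event_merge", "autonomy", "directive", "requires")
N_FEATURES = len(FEATURES)

_RATING_COLUMNS = ("rater", "language", "verb", "feature", "rating")


class SemanticProfile(NamedTuple):
    event_merge: float
    autonomy: float
    directive: float
    requires: float


@dataclass(frozen=True)
class ProfileMap:
    """One pooled [0, 1] profile per verb; rows follow lexicon order."""

    values: np.ndarray  # (n_verbs, 4) float64
    provenance: str = "pooled"

    def __post_init__(self) -> None:
        v = np.asarray(self.values)
        if v.ndim != 2 or v.shape[1] != N_FEATURES:
            raise ValidationError("profile values must have shape (n_verbs, 4)")
        if not np.isfinite(v).all() or (v < 0).any() or (v > 1).any():
            raise ValidationError("profile values must lie in [0, 1]")

    def __len__(self) -> int:
        return int(self.values.shape[0])

    def profile(self, verb_id: int) -> SemanticProfile:
        return SemanticProfile(*map(float, self.values[verb_id]))


def read_semantic_ratings(path, scale_min: float, scale_max: float) -> pd.DataFrame:
    """Read and validate a per-rater ratings CSV (rater, language, verb, feature, rating)."""
    if not scale_max > scale_min:
        raise ValidationError("scale_max must exceed scale_min")
    df = pd.read_csv(path)
    missing = [c for c in _RATING_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"ratings file missing column(s) {missing}")
    bad = set(df["feature"]) - set(FEATURES)
    if bad:
        raise SchemaError(f"unknown feature name(s) {sorted(bad)}")
    if df.duplicated(subset=["rater", "verb", "feature"]).any():
        raise ValidationError("duplicate (rater, verb, feature) rating")
    r = df["rating"].to_numpy(dtype=float)
    if not np.isfinite(r).all() or (r < scale_min).any() or (r > scale_max).any():
        raise ValidationError(f"ratings must lie within [{scale_min}, {scale_max}]")
    return df[list(_RATING_COLUMNS)].copy()


def pool_semantic_profiles(
    table: pd.DataFrame, scale_min: float, scale_max: float, lexicon: VerbLexicon
) -> ProfileMap:
    """Mean over all raters (all languages pooled), then rescale to [0, 1].

    The rescaling (mean - scale_min) / (scale_max - scale_min) is affine, so
    the verb ranking per feature is unchanged by the instrument bounds.
    """
    if not scale_max > scale_min:
        raise ValidationError("scale_max must exceed scale_min")
    means = table.groupby(["verb", "feature"], sort=False)["rating"].mean()
    values = np.full((len(lexicon), N_FEATURES), np.nan)
    for (verb, feature), m in means.items():
        values[lexicon.index(str(verb)), FEATURES.index(str(feature))] = m
    if np.isnan(values).any():
        n_missing = int(np.isnan(values).sum())
        raise CoverageError(f"{n_missing} (verb, feature) cell(s) have no ratings")
    scaled = (values - scale_min) / (scale_max - scale_min)
    return ProfileMap(values=scaled, provenance="pooled")


def permute_profiles(profiles: ProfileMap, seed: int) -> ProfileMap:
    """Reassign whole 4-feature profiles to uniformly random verbs.

    One permutation is drawn and then fixed, so within a model run every verb
    keeps a consistent (if arbitrary) semantic profile.  The multiset of
    profiles — hence every per-feature moment and the 4x4 feature correlation
    matrix over verbs — is exactly preserved.
    """
    if len(profiles) < 2:
        raise ValidationError("permutation needs at least two verbs")
    perm = np.random.default_rng(seed).permutation(len(profiles))
    return ProfileMap(values=profiles.values[perm], provenance=f"permuted(seed={seed})")


def write_profiles(profiles: ProfileMap, lexicon: VerbLexicon, path) -> None:
    df = pd.DataFrame(profiles.values, columns=list(FEATURES))
    df.insert(0, "verb", list(lexicon.labels))
    df.to_csv(path, index=False)


def read_profiles(path, lexicon: VerbLexicon) -> ProfileMap:
    df = pd.read_csv(path)
    missing = [c for c in ("verb", *FEATURES) if c not in df.columns]
    if missing:
        raise SchemaError(f"profiles file missing column(s) {missing}")
    values = np.full((len(lexicon), N_FEATURES), np.nan)
    for row in df.itertuples(index=False):
        values[lexicon.index(str(row.verb))] = [getattr(row, f) for f in FEATURES]
    if np.isnan(values).any():
        raise CoverageError("profiles file does not cover the full lexicon")
    return ProfileMap(values=values, provenance="pooled")
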