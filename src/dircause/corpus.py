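"""Verb-by-construction corpus tables, composite pooling, and exemplar streams.

The unit of input is a pre-coded (verb, construction) count.  Each verb can
occur in a *less-transparent* causative (the compact transitive causative), a
*more-transparent* causative (the periphrastic MAKE-type causative), or any
*other* (noncausative) form.  Per-language count tables are pooled into one
composite training distribution by multinomial sampling, and training streams
are drawn from the composite, again multinomially, with replacement.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Iterator, NamedTuple, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import SchemaError, ValidationError


class Construction(enum.IntEnum):
    """Output category of one corpus utterance."""

    LESS_TRANSPARENT = 0
    MORE_TRANSPARENT = 1
    OTHER = 2

    @property
    def causative(self) -> int:
        """1 for either causative form, 0 for noncausative (OTHER)."""
        return 0 if self is Construction.OTHER else 1

    @property
    def short_name(self) -> str:
        return _SHORT_NAMES[self]


_SHORT_NAMES = {
    Construction.LESS_TRANSPARENT: "less",
    Construction.MORE_TRANSPARENT: "more",
    Construction.OTHER: "other",
}
CONSTRUCTION_BY_NAME = {v: k for k, v in _SHORT_NAMES.items()}
N_CONSTRUCTIONS = 3


@dataclass(frozen=True)
class VerbLexicon:
    """Ordered verb inventory; ids are the 0-based positions of ``labels``."""

    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.labels) == 0:
            raise ValidationError("lexicon must contain at least one verb")
        if len(set(self.labels)) != len(self.labels):
            raise ValidationError("verb labels must be unique")

    def __len__(self) -> int:
        return len(self.labels)

    def index(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise ValidationError(f"verb {label!r} not in lexicon") from None

    @classmethod
    def default(cls, n_verbs: int = 60) -> "VerbLexicon":
        return cls(tuple(f"v{i:02d}" for i in range(n_verbs)))


class TrainingExemplar(NamedTuple):
    verb_id: int
    label: Construction
    causative: int


@dataclass(frozen=True)
class CorpusCounts:
    """One language's verb-by-construction frequency table.

    ``counts`` has shape (n_verbs, 3), column order LESS / MORE / OTHER.
    """

    language: str
    counts: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.counts)
        if c.ndim != 2 or c.shape[1] != N_CONSTRUCTIONS:
            raise ValidationError("counts must have shape (n_verbs, 3)")
        if (c < 0).any():
            raise ValidationError("counts must be nonnegative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass(frozen=True)
class CompositeCorpus:
    """Pooled multi-language exemplar counts plus sampling provenance."""

    counts: np.ndarray  # (n_verbs, 3) int64
    provenance: tuple[tuple[str, int], ...]

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass(frozen=True)
class ExemplarStream:
    """An ordered stream of training exemplars, stored as parallel arrays."""

    verb_ids: np.ndarray  # int32
    labels: np.ndarray  # int8, values in Construction

    @property
    def causative(self) -> np.ndarray:
        return (self.labels != int(Construction.OTHER)).astype(np.int8)

    def __len__(self) -> int:
        return int(self.verb_ids.shape[0])

    def __iter__(self) -> Iterator[TrainingExemplar]:
        caus = self.causative
        for v, l, c in zip(self.verb_ids, self.labels, caus):
            yield TrainingExemplar(int(v), Construction(int(l)), int(c))


_COUNT_COLUMNS = ("language", "verb", "construction", "count")


def read_corpus_counts(path, lexicon: VerbLexicon) -> CorpusCounts:
    """Read one language's counts CSV (language, verb, construction, count).

    Missing (verb, construction) cells are taken as zero; unknown verbs or
    construction names, negative counts, duplicate cells, and multi-language
    files are rejected.
    """
    df = pd.read_csv(path)
    missing = [c for c in _COUNT_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"counts file missing column(s) {missing}")
    languages = df["language"].unique()
    if len(languages) != 1:
        raise SchemaError(f"expected exactly one language per file, found {list(languages)}")
    bad = set(df["construction"]) - set(CONSTRUCTION_BY_NAME)
    if bad:
        raise SchemaError(f"unknown construction name(s) {sorted(bad)}")
    if df.duplicated(subset=["verb", "construction"]).any():
        raise ValidationError("duplicate (verb, construction) rows")
    counts = np.zeros((len(lexicon), N_CONSTRUCTIONS), dtype=np.int64)
    for verb, cons, count in df[["verb", "construction", "count"]].itertuples(index=False):
        if not float(count).is_integer() or count < 0:
            raise ValidationError(f"count for ({verb}, {cons}) must be a nonnegative integer")
        counts[lexicon.index(str(verb)), int(CONSTRUCTION_BY_NAME[cons])] = int(count)
    if counts.sum() <= 0:
        raise ValidationError("corpus table has zero total count")
    return CorpusCounts(language=str(languages[0]), counts=counts)


def write_corpus_counts(corpus: CorpusCounts, lexicon: VerbLexicon, path) -> None:
    rows = [
        (corpus.language, lexicon.labels[v], lab.short_name, int(corpus.counts[v, lab]))
        for v in range(len(lexicon))
        for lab in Construction
    ]
    pd.DataFrame(rows, columns=_COUNT_COLUMNS).to_csv(path, index=False)


def build_composite_corpus(
    corpora: Sequence[CorpusCounts], n_per_language: int, seed: int
) -> CompositeCorpus:
    """Pool languages by drawing ``n_per_language`` exemplars from each.

    Draws are multinomial over each language's cell proportions (with
    replacement), so any ``n_per_language`` is valid regardless of corpus size.
    """
    if not corpora:
        raise ValidationError("need at least one corpus")
    if n_per_language < 1:
        raise ValidationError("n_per_language must be >= 1")
    shapes = {c.counts.shape for c in corpora}
    if len(shapes) != 1:
        raise ValidationError("all corpora must cover the same lexicon")
    rng = np.random.default_rng(seed)
    pooled = np.zeros_like(corpora[0].counts)
    provenance = []
    for c in corpora:
        if c.total <= 0:
            raise ValidationError(f"corpus {c.language!r} is empty")
        p = c.counts.ravel() / c.total
        pooled += rng.multinomial(n_per_language, p).reshape(pooled.shape)
        provenance.append((c.language, n_per_language))
    return CompositeCorpus(counts=pooled, provenance=tuple(provenance))


def write_composite_corpus(composite: CompositeCorpus, lexicon: VerbLexicon, path) -> None:
    rows = [
        (lexicon.labels[v], lab.short_name, int(composite.counts[v, lab]))
        for v in range(len(lexicon))
        for lab in Construction
    ]
    pd.DataFrame(rows, columns=["verb", "construction", "count"]).to_csv(path, index=False)


def read_composite_corpus(
    path, lexicon: VerbLexicon, provenance: tuple[tuple[str, int], ...] = ()
) -> CompositeCorpus:
    df = pd.read_csv(path)
    missing = [c for c in ("verb", "construction", "count") if c not in df.columns]
    if missing:
        raise SchemaError(f"composite file missing column(s) {missing}")
    counts = np.zeros((len(lexicon), N_CONSTRUCTIONS), dtype=np.int64)
    for verb, cons, count in df[["verb", "construction", "count"]].itertuples(index=False):
        if count < 0:
            raise ValidationError("composite counts must be nonnegative")
        counts[lexicon.index(str(verb)), int(CONSTRUCTION_BY_NAME[cons])] = int(count)
    return CompositeCorpus(counts=counts, provenance=tuple(provenance))


def sample_exemplars(
    composite: CompositeCorpus,
    n: int,
    restrict_to: Optional[Sequence[int]] = None,
    seed: int = 0,
) -> ExemplarStream:
    """Draw ``n`` exemplars multinomially from the composite, in random order.

    With ``restrict_to`` given, cells of all other verbs are excluded, so a
    held-out verb can never enter a training stream.
    """
    if n < 1:
        raise ValidationError("n must be >= 1")
    counts = composite.counts
    n_verbs = counts.shape[0]
    if restrict_to is not None:
        mask = np.zeros(n_verbs, dtype=bool)
        mask[np.asarray(list(restrict_to), dtype=np.int64)] = True
        counts = np.where(mask[:, None], counts, 0)
    total = counts.sum()
    if total <= 0:
        raise ValidationError("no exemplars available after restriction")
    rng = np.random.default_rng(seed)
    cell_counts = rng.multinomial(n, counts.ravel() / total)
    cell_verbs = np.repeat(np.arange(n_verbs, dtype=np.int32), N_CONSTRUCTIONS)
    cell_labels = np.tile(np.arange(N_CONSTRUCTIONS, dtype=np.int8), n_verbs)
    verb_ids = np.repeat(cell_verbs, cell_counts)
    labels = np.repeat(cell_labels, cell_counts)
    order = rng.permutation(n)
    return ExemplarStream(verb_ids=verb_ids[order], labels=labels[order])


def shuffle_stream(stream: ExemplarStream, seed: int) -> ExemplarStream:
    """Re-randomize presentation order of a fixed exemplar set."""
    order = np.random.default_rng(seed).permutation(len(stream))
    return ExemplarStream(verb_ids=stream.verb_ids[order], labels=stream.labels[order])
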