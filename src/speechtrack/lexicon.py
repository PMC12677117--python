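"""Pronunciation lexicon and cohort-model lexical statistics.

The lexicon maps orthographic words to phoneme sequences and corpus
frequencies (occurrences per million). It backs the incremental
cohort model: as a word unfolds phoneme by phoneme, the *cohort* is
the set of lexicon entries whose pronunciation starts with the
phonemes heard so far. Frequency-weighted cohort reduction defines
phoneme surprisal; the frequency distribution over the active cohort
defines cohort entropy.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "Lexicon",
    "make_lexicon",
    "build_cohorts",
    "word_frequency",
    "word_surprisal",
    "phoneme_surprisal",
    "cohort_entropy",
    "BigramProvider",
    "linguistic_event_streams",
    "OOV_FLOOR_PER_MILLION",
]

#: frequency (per million) assumed for out-of-vocabulary words
OOV_FLOOR_PER_MILLION = 0.5


@dataclass(frozen=True)
class LexiconEntry:
    word: str
    phonemes: tuple[str, ...]
    frequency: float  # occurrences per million, > 0


@dataclass
class Lexicon:
    """A pronunciation lexicon with per-million word frequencies."""

    entries: list[LexiconEntry]
    _by_word: dict[str, LexiconEntry] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        words = [e.word for e in self.entries]
        if len(set(words)) != len(words):
            raise ValueError("lexicon words must be unique")
        for e in self.entries:
            if len(e.phonemes) == 0:
                raise ValueError(f"empty phoneme sequence for {e.word!r}")
            if not e.frequency > 0:
                raise ValueError(f"non-positive frequency for {e.word!r}")
        self._by_word = {e.word: e for e in self.entries}

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, word: str) -> bool:
        return word in self._by_word

    def __getitem__(self, word: str) -> LexiconEntry:
        return self._by_word[word]

    @property
    def words(self) -> list[str]:
        return [e.word for e in self.entries]

    @property
    def total_frequency(self) -> float:
        return float(sum(e.frequency for e in self.entries))

    def to_tsv(self, path: str | Path) -> None:
        """Write ``word<TAB>phonemes<TAB>freq_per_million`` rows."""
        with open(path, "w", encoding="utf-8") as fh:
            for e in self.entries:
                fh.write(f"{e.word}\t{' '.join(e.phonemes)}\t{e.frequency:.10g}\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "Lexicon":
        entries = []
        with open(path, encoding="utf-8") as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if len(parts) != 3:
                    raise ValueError(f"{path}:{lineno}: expected 3 tab-separated fields")
                word, phon, freq = parts
                entries.append(
                    LexiconEntry(word, tuple(phon.split()), float(freq))
                )
        return cls(entries)


def make_lexicon(
    n_words: int,
    inventory: tuple[str, ...] = ("p", "t", "k", "b", "d", "g", "a", "e", "i", "o", "u", "s", "n", "m", "l", "r"),
    zipf_exponent: float = 1.0,
    word_length_range: tuple[int, int] = (2, 6),
    seed: int = 0,
) -> Lexicon:
    """Generate a random lexicon with Zipf-distributed frequencies.

    Word frequencies follow ``freq(rank) ∝ rank**-zipf_exponent`` and are
    scaled to per-million units (relative frequencies sum to one across
    the lexicon). Word lengths are sampled uniformly from
    ``word_length_range`` over a small phoneme inventory, so prefix
    sharing — which the cohort model needs — arises naturally.
    """
    if n_words < 2:
        raise ValueError("n_words must be >= 2")
    inventory = tuple(inventory)
    if not inventory:
        raise ValueError("phoneme inventory must be non-empty")
    lo, hi = word_length_range
    if lo < 1 or hi < lo:
        raise ValueError("invalid word_length_range")
    n_forms = sum(len(inventory) ** k for k in range(lo, hi + 1))
    if n_forms < n_words:
        raise ValueError(
            f"cannot draw {n_words} distinct words of length {lo}..{hi} "
            f"from a {len(inventory)}-symbol inventory ({n_forms} forms exist)"
        )
    rng = np.random.default_rng(seed)
    seen: set[tuple[str, ...]] = set()
    forms: list[tuple[str, ...]] = []
    while len(forms) < n_words:
        k = int(rng.integers(lo, hi + 1))
        form = tuple(str(s) for s in rng.choice(inventory, size=k))
        if form not in seen:
            seen.add(form)
            forms.append(form)
    ranks = np.arange(1, n_words + 1, dtype=float)
    rel = ranks**-zipf_exponent
    rel /= rel.sum()
    entries = [
        LexiconEntry("".join(form), form, float(1e6 * p))
        for form, p in zip(forms, rel)
    ]
    return Lexicon(entries)


def word_frequency(word: str, lexicon: Lexicon, oov_floor: float = OOV_FLOOR_PER_MILLION) -> float:
    """Log10 word frequency per million (SUBTLEX convention).

    Out-of-vocabulary words fall back to ``log10(oov_floor)`` with a
    warning.
    """
    if word in lexicon:
        return float(np.log10(lexicon[word].frequency))
    warnings.warn(f"word {word!r} not in lexicon; using floor frequency", stacklevel=2)
    return float(np.log10(oov_floor))


def word_surprisal(probabilities: np.ndarray | list[float]) -> np.ndarray:
    """Word surprisal in bits, ``-log2 p(w_i | context)``.

    ``probabilities`` are per-token conditional probabilities in (0, 1].
    Which tokens are *excluded* from the neural analysis (the first two
    words of each target sentence) is handled downstream by the event
    assembly, not here.
    """
    p = np.asarray(probabilities, dtype=float)
    if np.any(p <= 0) or np.any(p > 1):
        raise ValueError("probabilities must lie in (0, 1]")
    return -np.log2(p)


@dataclass(frozen=True)
class Cohort:
    """Words compatible with a phoneme prefix, with summed frequency."""

    prefix: tuple[str, ...]
    members: tuple[str, ...]
    summed_frequency: float


def build_cohorts(word: str, lexicon: Lexicon) -> list[Cohort]:
    """Cohort sequence for a word: cohort_0 is the whole vocabulary,
    cohort_i the entries matching the first *i* phonemes.

    Homophones count as distinct members; their frequencies both enter
    the summed frequency.
    """
    if word not in lexicon:
        raise KeyError(f"word {word!r} has no pronunciation in the lexicon")
    phonemes = lexicon[word].phonemes
    cohorts = []
    for i in range(len(phonemes) + 1):
        prefix = phonemes[:i]
        members = tuple(
            e.word for e in lexicon.entries if e.phonemes[: i] == prefix
        )
        summed = sum(lexicon[m].frequency for m in members)
        cohorts.append(Cohort(prefix, members, float(summed)))
    return cohorts


def phoneme_surprisal(word: str, lexicon: Lexicon) -> np.ndarray:
    """Per-phoneme surprisal in bits from cohort frequency ratios.

    ``s_i = -log2( freq(cohort_i) / freq(cohort_{i-1}) )`` — the
    information carried by phoneme *i* about word identity. Values
    telescope: their sum equals ``-log2(freq(cohort_last)/freq(cohort_0))``.
    The word-initial phoneme is computed here but flagged for exclusion
    by the event assembly.
    """
    cohorts = build_cohorts(word, lexicon)
    freqs = np.array([c.summed_frequency for c in cohorts])
    if np.any(freqs <= 0):
        raise ValueError("zero cohort frequency (word not reachable in lexicon)")
    return -np.log2(freqs[1:] / freqs[:-1])


def cohort_entropy(word: str, lexicon: Lexicon) -> np.ndarray:
    """Per-phoneme cohort entropy in bits.

    ``H_i`` is the Shannon entropy of the relative-frequency
    distribution over ``cohort_{i-1}`` — the uncertainty about word
    identity just before phoneme *i* is heard.
    """
    cohorts = build_cohorts(word, lexicon)
    out = np.empty(len(cohorts) - 1)
    for i in range(1, len(cohorts)):
        prev = cohorts[i - 1]
        p = np.array([lexicon[m].frequency for m in prev.members])
        p = p / p.sum()
        out[i - 1] = float(-(p * np.log2(p)).sum())
    return out


def linguistic_event_streams(
    tokens: list[str],
    word_intervals: list,
    phoneme_intervals: list[list],
    lexicon: Lexicon,
    probabilities: np.ndarray | list[float] | None = None,
    provider: "BigramProvider | None" = None,
    stream: str = "target",
    exclude_first_words: int | None = None,
    truncate_before_s: float | None = None,
):
    """Valued event streams for the four linguistic predictors.

    Returns a dict of :class:`~speechtrack.acoustic.EventStream` for
    ``word_frequency``, ``word_surprisal``, ``phoneme_surprisal`` and
    ``cohort_entropy``, honoring the exclusion rules:

    - word-level events for the first ``exclude_first_words`` words of
      a target sentence carry no value (default 2 for the target
      stream, 0 for the distractor: isolated sentences give the first
      words no usable context);
    - word-initial phonemes are excluded from the phoneme-level
      streams so that word and phoneme levels stay separable;
    - distractor events before ``truncate_before_s`` (the target-onset
      head start) are dropped entirely.

    ``probabilities`` are per-token conditional word probabilities; a
    :class:`BigramProvider` may be passed instead.
    """
    from .acoustic import EventStream

    if exclude_first_words is None:
        exclude_first_words = 2 if stream == "target" else 0
    if probabilities is None:
        if provider is None:
            raise ValueError("need per-token probabilities or a provider")
        probabilities = provider.sentence_probabilities(tokens)
    surprisals = word_surprisal(probabilities)
    if len(tokens) != len(word_intervals) or len(tokens) != len(phoneme_intervals):
        raise ValueError("tokens, word_intervals and phoneme_intervals must align")

    wf_t, wf_v, ws_t, ws_v = [], [], [], []
    ps_t, ps_v, ce_t, ce_v = [], [], [], []
    for i, (tok, iv, phons) in enumerate(zip(tokens, word_intervals, phoneme_intervals)):
        onset = iv.onset
        dropped = truncate_before_s is not None and onset < truncate_before_s
        excluded = i < exclude_first_words
        if not dropped and not excluded:
            wf_t.append(onset)
            wf_v.append(word_frequency(tok, lexicon))
            ws_t.append(onset)
            ws_v.append(float(surprisals[i]))
        ps = phoneme_surprisal(tok, lexicon)
        ce = cohort_entropy(tok, lexicon)
        for j, ph_iv in enumerate(phons):
            if j == 0:  # word-initial phoneme excluded
                continue
            if truncate_before_s is not None and ph_iv.onset < truncate_before_s:
                continue
            ps_t.append(ph_iv.onset)
            ps_v.append(float(ps[j]))
            ce_t.append(ph_iv.onset)
            ce_v.append(float(ce[j]))

    def _es(times, values, label):
        order = np.argsort(times)
        return EventStream(np.asarray(times)[order], np.asarray(values)[order], label, stream)

    return {
        "word_frequency": _es(wf_t, wf_v, "word_frequency"),
        "word_surprisal": _es(ws_t, ws_v, "word_surprisal"),
        "phoneme_surprisal": _es(ps_t, ps_v, "phoneme_surprisal"),
        "cohort_entropy": _es(ce_t, ce_v, "cohort_entropy"),
    }


class BigramProvider:
    """Add-k bigram language model over a token corpus.

    A small fallback word-probability provider: conditional
    probabilities ``p(w_i | w_{i-1})`` with add-k smoothing over the
    training vocabulary. Any provider mapping sentences to per-token
    conditional probabilities can replace it (the study-grade provider
    is a neural language model, consumed here through the same
    interface).
    """

    BOS = "<s>"

    def __init__(self, sentences: list[list[str]], k: float = 0.5):
        if k <= 0:
            raise ValueError("smoothing constant k must be > 0")
        self.k = float(k)
        self.vocab: set[str] = set()
        self.bigram: dict[tuple[str, str], int] = {}
        self.context: dict[str, int] = {}
        for sent in sentences:
            prev = self.BOS
            for tok in sent:
                self.vocab.add(tok)
                self.bigram[(prev, tok)] = self.bigram.get((prev, tok), 0) + 1
                self.context[prev] = self.context.get(prev, 0) + 1
                prev = tok
        self._v = len(self.vocab) + 1  # +1 for unseen-token mass

    def probability(self, token: str, previous: str | None) -> float:
        prev = self.BOS if previous is None else previous
        num = self.bigram.get((prev, token), 0) + self.k
        den = self.context.get(prev, 0) + self.k * self._v
        return num / den

    def sentence_probabilities(self, tokens: list[str]) -> np.ndarray:
        prev: str | None = None
        out = []
        for tok in tokens:
            out.append(self.probability(tok, prev))
            prev = tok
        return np.asarray(out)
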