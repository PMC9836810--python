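"""Data model and corpus plumbing for symptom–prescription generation.

Two kinds of record feed the model:

* SP pairs — a symptom token sequence and the herb list of the prescription
  that treated it (optionally annotated with the prescription's efficacy
  phrase, which the auxiliary guidance branch consumes);
* PE pairs — a prescription and its efficacy phrase, used to train the
  prescription→efficacy branch on its own.

Canonical file format is JSONL with explicit token arrays; a TSV dialect
(tab-separated fields, space-joined tokens) is accepted.  Tokens are
opaque strings supplied pre-split; a helper splits raw text into
characters for corpora where the unit is the Chinese character.
"""

from __future__ import annotations

import json
import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

logger = logging.getLogger(__name__)

PAD, BOS, EOS, UNK = "<pad>", "<bos>", "<eos>", "<unk>"
SPECIALS = (PAD, BOS, EOS, UNK)

#: corpus length caps: at most 21 symptom tokens and 23 herbs per record
MAX_SYMPTOMS = 21
MAX_HERBS = 23
#: corpus frequency above which a herb counts as "conventional"
CHL_MIN_COUNT = 480


@dataclass
class DataPair:
    """One (symptoms, prescription[, efficacy]) record."""

    symptoms: list[str]
    prescription: list[str]
    efficacy: list[str] | None = None
    source_id: str = ""

    def __post_init__(self):
        if len(self.symptoms) < 1:
            raise ValueError("symptoms must be nonempty")
        if len(self.prescription) < 1:
            raise ValueError("prescription must be nonempty")
        if len(set(self.prescription)) != len(self.prescription):
            seen: set[str] = set()
            deduped = [h for h in self.prescription
                       if not (h in seen or seen.add(h))]
            logger.warning("duplicate herbs collapsed in record %r: %s -> %s",
                           self.source_id, self.prescription, deduped)
            self.prescription = deduped

    @property
    def n_symptoms(self) -> int:
        return len(self.symptoms)

    @property
    def n_herbs(self) -> int:
        return len(self.prescription)


@dataclass
class ConventionalHerbLibrary:
    """High-frequency herbs, ordered by descending corpus count (ties by token)."""

    herbs: list[str]
    counts: dict[str, int] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.herbs)

    def __iter__(self):
        return iter(self.herbs)


class SubVocab:
    """Token↔index bijection with specials at the lowest indices."""

    def __init__(self, tokens):
        self.itos: list[str] = list(SPECIALS) + sorted(set(tokens) - set(SPECIALS))
        self.stoi: dict[str, int] = {t: i for i, t in enumerate(self.itos)}

    @classmethod
    def from_itos(cls, itos: list[str]) -> "SubVocab":
        sub = cls.__new__(cls)
        sub.itos = list(itos)
        sub.stoi = {t: i for i, t in enumerate(sub.itos)}
        return sub

    def __len__(self) -> int:
        return len(self.itos)

    def index(self, token: str) -> int:
        return self.stoi.get(token, self.stoi[UNK])

    def token(self, idx: int) -> str:
        return self.itos[idx]

    def encode(self, tokens) -> list[int]:
        return [self.index(t) for t in tokens]


@dataclass
class TokenVocab:
    """The three sub-vocabularies (symptom, herb, efficacy tokens).

    The herb index space is shared by the generator head and the copy
    mechanism, so candidate herbs are always in-vocabulary by construction.
    """

    symptom: SubVocab
    herb: SubVocab
    efficacy: SubVocab

    def content_hash(self) -> str:
        import hashlib
        h = hashlib.sha256()
        for sub in (self.symptom, self.herb, self.efficacy):
            h.update("\x1f".join(sub.itos).encode())
            h.update(b"\x1e")
        return h.hexdigest()[:16]


# ---------------------------------------------------------------------------
# file I/O

def _pair_from_record(rec: dict, schema: str, lineno: int, source: str) -> DataPair:
    try:
        if schema == "sp":
            return DataPair(symptoms=list(rec["symptoms"]),
                            prescription=list(rec["prescription"]),
                            efficacy=list(rec["efficacy"]) if rec.get("efficacy") else None,
                            source_id=rec.get("source_id", f"{source}:{lineno}"))
        elif schema == "pe":
            # PE records ride in the same container: prescription + efficacy,
            # with a placeholder symptom slot unused downstream.
            return DataPair(symptoms=list(rec.get("symptoms", ["-"])) or ["-"],
                            prescription=list(rec["prescription"]),
                            efficacy=list(rec["efficacy"]),
                            source_id=rec.get("source_id", f"{source}:{lineno}"))
        raise ValueError(f"unknown schema {schema!r}")
    except (KeyError, TypeError) as e:
        raise ValueError(f"{source}: malformed record at line {lineno}: {e}") from e


def load_pairs(path: str | Path, schema: str = "sp") -> list[DataPair]:
    """Load SP or PE pairs from JSONL (or the TSV dialect, by extension).

    Raises ``ValueError`` naming the offending line for malformed records.
    An empty file yields an empty list.
    """
    path = Path(path)
    pairs: list[DataPair] = []
    is_tsv = path.suffix.lower() in {".tsv", ".txt"}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if is_tsv:
                fields = line.split("\t")
                want = 2
                if len(fields) < want:
                    raise ValueError(f"{path}: malformed record at line {lineno}: "
                                     f"expected >= {want} tab-separated fields")
                if schema == "sp":
                    rec = {"symptoms": fields[0].split(),
                           "prescription": fields[1].split()}
                    if len(fields) > 2 and fields[2].strip():
                        rec["efficacy"] = fields[2].split()
                else:
                    rec = {"prescription": fields[0].split(),
                           "efficacy": fields[1].split()}
            else:
                try:
                    rec = json.loads(line)
                except json.JSONDecodeError as e:
                    raise ValueError(f"{path}: malformed record at line {lineno}: {e}") from e
            pairs.append(_pair_from_record(rec, schema, lineno, str(path)))
    return pairs


def save_pairs(pairs: list[DataPair], path: str | Path, schema: str = "sp") -> None:
    """Write pairs as JSONL; ``load_pairs`` round-trips the result."""
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        for p in pairs:
            if schema == "sp":
                rec = {"symptoms": p.symptoms, "prescription": p.prescription}
                if p.efficacy:
                    rec["efficacy"] = p.efficacy
            else:
                rec = {"prescription": p.prescription, "efficacy": p.efficacy}
            if p.source_id:
                rec["source_id"] = p.source_id
            fh.write(json.dumps(rec, ensure_ascii=False) + "\n")


def char_split(text: str) -> list[str]:
    """Split raw text into character tokens (whitespace dropped)."""
    return [c for c in text if not c.isspace()]


# ---------------------------------------------------------------------------
# filtering / statistics

def filter_pairs(pairs: list[DataPair], max_symptoms: int = MAX_SYMPTOMS,
                 max_herbs: int = MAX_HERBS) -> list[DataPair]:
    """Keep pairs with at most ``max_symptoms`` symptom tokens and
    ``max_herbs`` herbs (inclusive caps), preserving order."""
    if max_symptoms < 1 or max_herbs < 1:
        raise ValueError("length caps must be >= 1")
    kept = [p for p in pairs
            if p.n_symptoms <= max_symptoms and p.n_herbs <= max_herbs]
    logger.info("filter_pairs: kept %d / dropped %d", len(kept), len(pairs) - len(kept))
    return kept


def herb_counts(pairs: list[DataPair]) -> Counter:
    c: Counter = Counter()
    for p in pairs:
        c.update(p.prescription)
    return c


def build_chl(pairs: list[DataPair], min_count: int = CHL_MIN_COUNT) -> ConventionalHerbLibrary:
    """Conventional herb library: herbs with corpus count strictly above
    ``min_count``, ordered by descending count then token string."""
    if not pairs:
        raise ValueError("build_chl requires a nonempty corpus")
    counts = herb_counts(pairs)
    herbs = sorted((h for h, c in counts.items() if c > min_count),
                   key=lambda h: (-counts[h], h))
    if not herbs:
        raise ValueError(
            f"no herb occurs more than {min_count} times; lower min_count "
            f"(max observed count is {max(counts.values())})")
    return ConventionalHerbLibrary(herbs=herbs, counts={h: counts[h] for h in herbs})


def build_vocab(pairs_sp: list[DataPair], pairs_pe: list[DataPair] | None = None) -> TokenVocab:
    """Vocabularies over every token seen, deterministic given input."""
    pairs_pe = pairs_pe or []
    if not pairs_sp and not pairs_pe:
        raise ValueError("build_vocab requires at least one pair")
    sym, herb, eff = set(), set(), set()
    for p in pairs_sp:
        sym.update(p.symptoms)
        herb.update(p.prescription)
        if p.efficacy:
            eff.update(p.efficacy)
    for p in pairs_pe:
        herb.update(p.prescription)
        if p.efficacy:
            eff.update(p.efficacy)
    return TokenVocab(symptom=SubVocab(sym), herb=SubVocab(herb), efficacy=SubVocab(eff))


def train_test_split(pairs: list[DataPair], test_fraction: float = 0.1,
                     seed: int = 0) -> tuple[list[DataPair], list[DataPair]]:
    """Seeded random split, 9:1 by default."""
    rng = np.random.default_rng(seed)
    idx = rng.permutation(len(pairs))
    n_test = int(round(len(pairs) * test_fraction))
    test = {int(i) for i in idx[:n_test]}
    return ([p for i, p in enumerate(pairs) if i not in test],
            [p for i, p in enumerate(pairs) if i in test])
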