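"""Synthetic symptom–prescription corpora with latent syndrome structure.

Real prescribing corpora pair a free-text symptom presentation with a
multi-herb formula; the statistical regularity the generator exploits is
that presentations cluster into syndromes, each syndrome calling for a
fixed set of core herbs plus a looser pool of assistants, and each
syndrome's formulas sharing an efficacy phrase.  The generator emulates
exactly that structure with abstract tokens ("S001", "H017", "E02a"):

* a *world* of syndromes, each owning a weighted symptom pool, a core
  herb set (disjoint across syndromes), an assistant herb pool and an
  efficacy phrase;
* SP pairs sampled by picking a syndrome, drawing symptoms from its pool
  (with a configurable rate of off-syndrome noise tokens) and emitting
  core herbs plus a random draw of assistants;
* PE pairs pairing a formula drawn the same way with the syndrome's
  efficacy phrase.

Token frequencies inside a pool are Zipf-skewed by default, mimicking the
heavy-tailed token statistics of real corpora; everything is driven by a
single seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .corpus import MAX_HERBS, MAX_SYMPTOMS, DataPair

__all__ = ["SynthConfig", "SyndromeSpec", "make_world", "generate_corpus"]


@dataclass
class SynthConfig:
    n_syndromes: int = 4
    symptom_vocab_size: int = 60
    herb_vocab_size: int = 60
    core_herbs_per_syndrome: int = 4
    assistant_herbs_per_syndrome: int = 6
    symptoms_per_pair: tuple[int, int] = (4, 10)
    assistants_per_pair: tuple[int, int] = (1, 3)
    n_pairs_sp: int = 200
    n_pairs_pe: int = 80
    noise_rate: float = 0.1
    pool_overlap: float = 0.0
    zipf_exponent: float = 1.0  # 0 => uniform within-pool sampling
    efficacy_phrase_len: int = 3
    symptom_pool_size: Optional[int] = None  # default: vocab split evenly
    seed: int = 0

    def __post_init__(self):
        if not (0.0 <= self.noise_rate <= 1.0 and 0.0 <= self.pool_overlap <= 1.0):
            raise ValueError("rates must lie in [0, 1]")
        lo, hi = self.symptoms_per_pair
        if not (1 <= lo <= hi <= MAX_SYMPTOMS):
            raise ValueError(f"symptoms_per_pair must lie within [1, {MAX_SYMPTOMS}]")
        cap = self.core_herbs_per_syndrome + self.assistants_per_pair[1]
        if cap > MAX_HERBS:
            raise ValueError(f"core + assistant herbs per pair ({cap}) exceeds {MAX_HERBS}")


@dataclass
class SyndromeSpec:
    id: int
    symptom_pool: list[str]
    symptom_weights: np.ndarray = field(repr=False)
    core_herbs: list[str] = field(default_factory=list)
    assistant_pool: list[str] = field(default_factory=list)
    efficacy_phrase: list[str] = field(default_factory=list)

    def __post_init__(self):
        if set(self.core_herbs) & set(self.assistant_pool):
            raise ValueError("core and assistant herb sets must be disjoint")
        if len(self.efficacy_phrase) < 1:
            raise ValueError("efficacy phrase must be nonempty")


def _zipf_weights(n: int, a: float) -> np.ndarray:
    if a == 0.0:
        return np.full(n, 1.0 / n)
    w = 1.0 / np.arange(1, n + 1, dtype=float) ** a
    return w / w.sum()


def make_world(config: SynthConfig) -> list[SyndromeSpec]:
    """Draw the latent syndrome structure; deterministic given the seed."""
    rng = np.random.default_rng(config.seed)
    ns = config.n_syndromes
    pool_size = config.symptom_pool_size or config.symptom_vocab_size // ns
    own = int(round(pool_size * (1.0 - config.pool_overlap)))
    need_sym = ns * own
    need_herb = ns * config.core_herbs_per_syndrome
    if need_sym > config.symptom_vocab_size:
        raise ValueError(f"symptom vocab {config.symptom_vocab_size} too small for "
                         f"{ns} syndromes x {own} exclusive pool tokens")
    if need_herb > config.herb_vocab_size:
        raise ValueError(f"herb vocab {config.herb_vocab_size} too small for "
                         f"{ns} syndromes x {config.core_herbs_per_syndrome} core herbs")

    symptoms = [f"S{i:03d}" for i in range(config.symptom_vocab_size)]
    herbs = [f"H{i:03d}" for i in range(config.herb_vocab_size)]
    sym_perm = [symptoms[i] for i in rng.permutation(len(symptoms))]
    herb_perm = [herbs[i] for i in rng.permutation(len(herbs))]

    world = []
    for z in range(ns):
        pool = sym_perm[z * own:(z + 1) * own]
        # shared (overlap) tokens drawn from outside the exclusive blocks
        n_shared = pool_size - own
        if n_shared > 0:
            leftovers = sym_perm[ns * own:]
            if len(leftovers) < n_shared:
                raise ValueError("symptom vocab too small for the requested overlap")
            pool = pool + [str(t) for t in rng.choice(leftovers, size=n_shared, replace=False)]
        core = herb_perm[z * config.core_herbs_per_syndrome:
                         (z + 1) * config.core_herbs_per_syndrome]
        rest = [h for h in herb_perm[ns * config.core_herbs_per_syndrome:]]
        if len(rest) < config.assistant_herbs_per_syndrome:
            raise ValueError("herb vocab too small for assistant pools")
        assistants = [str(h) for h in rng.choice(rest, size=config.assistant_herbs_per_syndrome,
                                               replace=False)]
        phrase = [f"E{z:02d}{chr(ord('a') + j)}" for j in range(config.efficacy_phrase_len)]
        world.append(SyndromeSpec(
            id=z, symptom_pool=pool,
            symptom_weights=_zipf_weights(len(pool), config.zipf_exponent),
            core_herbs=core, assistant_pool=assistants, efficacy_phrase=phrase))
    return world


def _draw_prescription(spec: SyndromeSpec, config: SynthConfig,
                       rng: np.random.Generator) -> list[str]:
    lo, hi = config.assistants_per_pair
    n_assist = int(rng.integers(lo, hi + 1))
    n_assist = min(n_assist, len(spec.assistant_pool))
    assistants = [str(h) for h in rng.choice(spec.assistant_pool, size=n_assist, replace=False)]
    seen: set[str] = set()
    rx = [h for h in spec.core_herbs + assistants if not (h in seen or seen.add(h))]
    return rx[:MAX_HERBS]


def _draw_symptoms(spec: SyndromeSpec, world: list[SyndromeSpec],
                   config: SynthConfig, rng: np.random.Generator) -> list[str]:
    lo, hi = config.symptoms_per_pair
    n = int(rng.integers(lo, hi + 1))
    n = min(n, len(spec.symptom_pool))
    toks = [str(t) for t in rng.choice(spec.symptom_pool, size=n, replace=False,
                                      p=spec.symptom_weights)]
    if config.noise_rate > 0.0 and len(world) > 1:
        others = [t for w in world if w.id != spec.id for t in w.symptom_pool
                  if t not in spec.symptom_pool]
        for i in range(len(toks)):
            if others and rng.random() < config.noise_rate:
                toks[i] = str(rng.choice(others))
    return toks


def generate_corpus(world: list[SyndromeSpec], config: SynthConfig
                    ) -> tuple[list[DataPair], list[DataPair]]:
    """Sample the SP and PE corpora from a world.

    SP pairs carry the syndrome's efficacy phrase as auxiliary supervision
    and record the latent syndrome id in ``source_id`` ("z<k>:<i>") so that
    retrieval and ablation experiments can be scored against the truth.
    Every emitted pair satisfies the corpus length caps by construction.
    """
    rng = np.random.default_rng(config.seed + 1)
    sp, pe = [], []
    for i in range(config.n_pairs_sp):
        spec = world[int(rng.integers(len(world)))]
        sp.append(DataPair(symptoms=_draw_symptoms(spec, world, config, rng),
                           prescription=_draw_prescription(spec, config, rng),
                           efficacy=list(spec.efficacy_phrase),
                           source_id=f"z{spec.id}:{i}"))
    for i in range(config.n_pairs_pe):
        spec = world[int(rng.integers(len(world)))]
        pe.append(DataPair(symptoms=["-"],
                           prescription=_draw_prescription(spec, config, rng),
                           efficacy=list(spec.efficacy_phrase),
                           source_id=f"z{spec.id}:pe{i}"))
    return sp, pe
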