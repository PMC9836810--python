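"""Task-qualified knowledge-base matching (TKMM).

The knowledge base holds one record per training pair: the symptom token
sequence, its prescription, and the frozen content representation of the
symptoms.  A query representation Cs is scored against every record with
a blended dissimilarity

    Sim = lambda1 * (1 - cos(Cs, KB_Cs)) + lambda2 * Nor(ED),

where ED is Euclidean distance normalised per query over the scanned
records (divide by the max by default; min–max is a config option), so
Sim is in [0, ~1] and *smaller means more similar*.  The prescriptions of
the k best records are unioned (first-occurrence order) into the herbal
candidate pool that feeds the copy mechanism.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["KBRecord", "KnowledgeBase", "HerbCandidatePool",
           "blended_similarity", "build_kb", "select_candidates"]


@dataclass
class KBRecord:
    symptoms: list[str]
    prescription: list[str]
    representation: np.ndarray
    source_id: str = ""


@dataclass
class KnowledgeBase:
    records: list[KBRecord]
    reps: np.ndarray = field(repr=False)  # (D, d) row-stacked representations

    def __len__(self) -> int:
        return len(self.records)


@dataclass
class HerbCandidatePool:
    """Duplicate-free union of the k retrieved prescriptions' herbs."""

    herbs: list[str]
    source_record_ids: list[int]
    scores: list[float]  # ascending

    def __len__(self) -> int:
        return len(self.herbs)

    def __iter__(self):
        return iter(self.herbs)


def build_kb(pairs, represent) -> KnowledgeBase:
    """One record per pair, order preserved; ``represent`` maps a symptom
    token list to its content-representation vector and must stay fixed for
    the whole build."""
    records = []
    for i, p in enumerate(pairs):
        try:
            rep = np.asarray(represent(p.symptoms), dtype=np.float64)
        except Exception as e:
            raise RuntimeError(f"encoder failed on KB record {i} "
                               f"({p.source_id!r}): {e}") from e
        records.append(KBRecord(symptoms=list(p.symptoms),
                                prescription=list(p.prescription),
                                representation=rep,
                                source_id=p.source_id or str(i)))
    if not records:
        raise ValueError("cannot build an empty knowledge base")
    return KnowledgeBase(records=records, reps=np.stack([r.representation for r in records]))


def _sim_components(cs: np.ndarray, reps: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    qn = np.linalg.norm(cs)
    rn = np.linalg.norm(reps, axis=1)
    if qn == 0.0 or np.any(rn == 0.0):
        raise ValueError("zero vector in similarity computation")
    cos = reps @ cs / (rn * qn)
    ed = np.linalg.norm(reps - cs, axis=1)
    return cos, ed


def _normalise_ed(ed: np.ndarray, mode: str) -> np.ndarray:
    if mode == "max":
        m = ed.max()
        return ed / m if m > 0 else ed
    lo, hi = ed.min(), ed.max()
    return (ed - lo) / (hi - lo) if hi > lo else np.zeros_like(ed)


def blended_similarity(cs: np.ndarray, reps: np.ndarray, lambda1: float = 0.4,
                       lambda2: float = 0.6, ed_norm: str = "max") -> np.ndarray:
    """Sim of a query against each row of ``reps``; the ED normalisation is
    taken over exactly this scan, so scores are comparable within a query."""
    if abs(lambda1 + lambda2 - 1.0) > 1e-9:
        raise ValueError(f"lambda1 + lambda2 must equal 1, got {lambda1 + lambda2}")
    cs = np.asarray(cs, dtype=np.float64)
    reps = np.atleast_2d(np.asarray(reps, dtype=np.float64))
    cos, ed = _sim_components(cs, reps)
    return lambda1 * (1.0 - cos) + lambda2 * _normalise_ed(ed, ed_norm)


def select_candidates(kb: KnowledgeBase, cs: np.ndarray, k: int = 20,
                      lambda1: float = 0.4, ed_norm: str = "max",
                      exclude_source_id: str | None = None) -> HerbCandidatePool:
    """Rank all records by Sim (ascending, ties by KB index) and pool the
    herbs of the first k prescriptions.

    ``exclude_source_id`` drops the query's own record during training so a
    training pair cannot retrieve its own label.
    """
    mask = np.ones(len(kb), dtype=bool)
    if exclude_source_id is not None:
        for i, r in enumerate(kb.records):
            if r.source_id == exclude_source_id:
                mask[i] = False
    idx_all = np.flatnonzero(mask)
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > idx_all.size:
        raise ValueError(f"k={k} exceeds the {idx_all.size} available KB records")
    sims = blended_similarity(cs, kb.reps[idx_all], lambda1, 1.0 - lambda1, ed_norm)
    order = np.argsort(sims, kind="stable")[:k]
    chosen = [int(idx_all[j]) for j in order]
    herbs, seen = [], set()
    for i in chosen:
        for h in kb.records[i].prescription:
            if h not in seen:
                seen.add(h)
                herbs.append(h)
    return HerbCandidatePool(herbs=herbs, source_record_ids=chosen,
                             scores=[float(sims[j]) for j in order])
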