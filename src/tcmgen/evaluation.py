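"""Set-based prescription metrics, score aggregation, relevance export.

A generated prescription H and a label prescription P are compared as
sets of herb tokens:

    precision = |H ∩ P| / |H|,  recall = |H ∩ P| / |P|,
    F1 = 2 |H ∩ P| / (|H| + |P|),

macro-averaged over pairs (micro aggregation available).  Score
aggregation reproduces the arithmetic of panel evaluations in which each
judge scores herbal effectiveness (HE) and herbal compatibility (HC) on
0–5 and Total = HE + HC.  ``relevance_matrix`` turns a generation trace
into the symptom×herb attention matrix used for heat-map style
inspection of which symptoms drove which herbs.

Two packaged fixtures (``tcmgen/data``) hold published reference inputs:
a four-judge score grid for six models, and two worked case studies with
the label and per-model herb lists.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources

import numpy as np

__all__ = ["PairMetrics", "pair_metrics", "corpus_metrics", "aggregate_scores",
           "relevance_matrix", "load_score_table", "load_case_studies"]


@dataclass
class PairMetrics:
    precision: float
    recall: float
    f1: float
    intersection_size: int
    pred_size: int
    label_size: int
    empty_prediction: bool = False


def pair_metrics(pred: list[str], label: list[str],
                 matching: str = "exact") -> PairMetrics:
    """Set overlap metrics for one pair; ``matching="casefold"`` lowercases
    tokens before intersecting.  An empty prediction yields precision 0
    (flagged) so the metric is total."""
    if matching == "casefold":
        pred = [t.casefold() for t in pred]
        label = [t.casefold() for t in label]
    elif matching != "exact":
        raise ValueError("matching must be 'exact' or 'casefold'")
    hs, ps = set(pred), set(label)
    if not ps:
        raise ValueError("label prescription must be nonempty")
    inter = len(hs & ps)
    if not hs:
        return PairMetrics(0.0, 0.0, 0.0, 0, 0, len(ps), empty_prediction=True)
    precision = inter / len(hs)
    recall = inter / len(ps)
    f1 = 2.0 * inter / (len(hs) + len(ps))
    return PairMetrics(precision, recall, f1, inter, len(hs), len(ps))


def corpus_metrics(pairs, matching: str = "exact",
                   average: str = "macro") -> dict:
    """Aggregate metrics over (pred, label) pairs.

    ``macro`` (default) averages per-pair metrics; ``micro`` pools the
    intersection/size counts first.
    """
    pairs = list(pairs)
    if not pairs:
        raise ValueError("corpus_metrics requires at least one pair")
    per = [pair_metrics(h, p, matching) for h, p in pairs]
    if average == "macro":
        return {"precision": float(np.mean([m.precision for m in per])),
                "recall": float(np.mean([m.recall for m in per])),
                "f1": float(np.mean([m.f1 for m in per])),
                "n": len(per)}
    if average == "micro":
        inter = sum(m.intersection_size for m in per)
        np_, nl = sum(m.pred_size for m in per), sum(m.label_size for m in per)
        prec = inter / np_ if np_ else 0.0
        rec = inter / nl
        f1 = 2.0 * inter / (np_ + nl) if np_ + nl else 0.0
        return {"precision": prec, "recall": rec, "f1": f1, "n": len(per)}
    raise ValueError("average must be 'macro' or 'micro'")


def aggregate_scores(table: dict) -> dict:
    """Panel-score arithmetic.

    ``table`` maps model name -> list of per-judge {"HE": x, "HC": y}
    cells.  Returns per-model means of HE, HC and Total (= HE + HC), plus
    pairwise relative improvements of mean Total in percent:
    improvement(A, B) = (mean_A - mean_B) / mean_B * 100.
    """
    means = {}
    for model, cells in table.items():
        for i, c in enumerate(cells):
            if "HE" not in c or "HC" not in c:
                raise ValueError(f"missing HE/HC cell for {model!r}, judge {i + 1}")
        he = float(np.mean([c["HE"] for c in cells]))
        hc = float(np.mean([c["HC"] for c in cells]))
        means[model] = {"HE": he, "HC": hc, "Total": he + hc}
    improvements = {}
    for a in means:
        for b in means:
            if a != b and means[b]["Total"] > 0:
                improvements[(a, b)] = ((means[a]["Total"] - means[b]["Total"])
                                        / means[b]["Total"] * 100.0)
    return {"means": means, "improvements": improvements}


def relevance_matrix(trace: list[dict], source: str = "coverage") -> np.ndarray:
    """Symptom×herb relevance from a generation trace: one row per emitted
    herb holding the attention distribution over symptom positions at that
    step (``source``: "coverage" for the coverage attention, "content" for
    the encoder content attention).  Rows sum to 1."""
    key = {"coverage": "coverage_attention", "content": "content_attention"}[source]
    rows = [step[key] for step in trace]
    if not rows:
        return np.zeros((0, 0))
    return np.asarray(rows, dtype=float)


def _load_json(name: str) -> dict:
    with resources.files("tcmgen.data").joinpath(name).open(encoding="utf-8") as fh:
        return json.load(fh)


def load_score_table() -> dict:
    """Packaged four-judge HE/HC score grid (six models)."""
    return _load_json("score_table.json")


def load_case_studies() -> dict:
    """Packaged worked case studies: label and per-model herb lists."""
    return _load_json("case_studies.json")
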