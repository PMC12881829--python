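"""Zero-shot prediction over candidate names and entropy-based OOD detection.

Each cell is scored by cosine similarity against every candidate name
embedding; the argmax is the predicted label. The unseen-type detector
computes the Shannon entropy (nats) of the softmax restricted to the SEEN
candidates and renormalized: a cell spreading its probability mass across
seen types is unlikely to be one of them. Cells whose entropy strictly
exceeds the threshold — by default the median (second quartile) of the
test set's entropies — are flagged and reassigned to the best unseen
candidate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import softmax as _softmax

from .io_formats import normalize_name

__all__ = ["PredictionResult", "predict", "seen_entropy", "ood_threshold",
           "apply_ood", "predict_with_ood"]


@dataclass
class PredictionResult:
    cell_id: str
    similarities: np.ndarray
    probabilities: np.ndarray
    seen_entropy: float
    predicted_name: str
    ood_flag: bool = False
    final_name: str | None = None

    def __post_init__(self):
        if self.final_name is None:
            self.final_name = self.predicted_name

    @property
    def top_similarity(self) -> float:
        return float(np.max(self.similarities))


def seen_entropy(probabilities: np.ndarray, seen_mask: np.ndarray) -> float:
    """Entropy (nats) of the seen-candidate-restricted, renormalized
    distribution; 0 * ln 0 counts as 0."""
    p = np.asarray(probabilities, dtype=np.float64)
    mask = np.asarray(seen_mask, dtype=bool)
    seen_mass = p[mask].sum()
    if seen_mass <= 0:
        raise ValueError("no probability mass on seen candidates")
    q = p[mask] / seen_mass
    nz = q[q > 0]
    return float(-(nz * np.log(nz)).sum())


def predict(cells: np.ndarray, model, cell_ids: list[str],
            candidates: list[str],
            seen_set: set[str] | list[str],
            temperature: float | None = None) -> list[PredictionResult]:
    """Score every cell against every candidate name.

    ``cells`` is a preprocessed (normalized-log) cells x genes array over
    the model's vocabulary. Candidate names must be unique; ``seen_set``
    must be a subset of them. Name embeddings are computed once and shared
    across cells. Ties in similarity resolve to the earliest candidate.

    Probabilities are the softmax of similarity / temperature; by default
    the temperature the model was trained with, so the inference
    distribution matches the contrastive objective's scale.
    """
    if temperature is None:
        temperature = getattr(getattr(model, "config", None),
                              "temperature", 1.0)
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    candidates = [normalize_name(c) for c in candidates]
    if not candidates:
        raise ValueError("no candidate names")
    if len(set(candidates)) != len(candidates):
        raise ValueError("candidate names must be unique")
    seen_set = {normalize_name(s) for s in seen_set}
    unknown = seen_set - set(candidates)
    if unknown:
        raise ValueError(f"seen names not in candidates: {sorted(unknown)}")
    seen_mask = np.array([c in seen_set for c in candidates])
    if not seen_mask.any():
        raise ValueError("at least one candidate must be seen")

    name_emb = model.embed_names(candidates)
    cell_emb = model.embed_cells(np.atleast_2d(cells))
    name_n = name_emb / np.linalg.norm(name_emb, axis=1, keepdims=True)
    cell_n = cell_emb / np.linalg.norm(cell_emb, axis=1, keepdims=True)
    sims = cell_n @ name_n.T  # (n_cells, n_candidates)
    probs = _softmax(sims / temperature, axis=1)

    results = []
    for i, cid in enumerate(cell_ids):
        best = int(np.argmax(sims[i]))  # argmax takes first on ties
        results.append(PredictionResult(
            cell_id=str(cid),
            similarities=sims[i],
            probabilities=probs[i],
            seen_entropy=seen_entropy(probs[i], seen_mask),
            predicted_name=candidates[best],
        ))
    return results


def ood_threshold(entropies) -> float:
    """Second quartile (median, linear-interpolation convention) of the
    per-cell seen-entropy values."""
    entropies = np.asarray(list(entropies), dtype=np.float64)
    if entropies.size == 0:
        raise ValueError("no entropies given")
    return float(np.quantile(entropies, 0.5))


def apply_ood(results: list[PredictionResult], threshold: float,
              candidates: list[str],
              seen_set: set[str] | list[str]) -> list[PredictionResult]:
    """Flag cells with seen_entropy strictly above the threshold and assign
    them the most similar UNSEEN candidate; others keep the global argmax."""
    if np.isnan(threshold):
        raise ValueError("threshold must not be NaN")
    candidates = [normalize_name(c) for c in candidates]
    seen_set = {normalize_name(s) for s in seen_set}
    unseen_idx = [j for j, c in enumerate(candidates) if c not in seen_set]
    for r in results:
        r.ood_flag = bool(r.seen_entropy > threshold)
        if r.ood_flag:
            if not unseen_idx:
                raise ValueError(
                    "cell flagged as unseen but no unseen candidates exist")
            best = max(unseen_idx, key=lambda j: (r.similarities[j], -j))
            r.final_name = candidates[best]
        else:
            r.final_name = r.predicted_name
    return results


def predict_with_ood(cells: np.ndarray, model, cell_ids: list[str],
                     candidates: list[str],
                     seen_set) -> tuple[list[PredictionResult], float]:
    """Predict, derive the median-entropy threshold from these cells, and
    apply OOD reassignment. Returns (results, threshold)."""
    results = predict(cells, model, cell_ids, candidates, seen_set)
    threshold = ood_threshold([r.seen_entropy for r in results])
    apply_ood(results, threshold, candidates, seen_set)
    return results, threshold
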