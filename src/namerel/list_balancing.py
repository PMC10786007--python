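"""Stimulus-list balancing by randomized cosine-similarity matching.

Two naming lists are balanced on word frequency (Zipf), age of acquisition,
and name agreement (H-index; lower = higher agreement) by z-scoring the
three norms into per-item feature vectors, sampling many random perfect
matchings of the items, keeping the matching with the highest mean pairwise
cosine similarity, and splitting each pair across the two lists.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "FEATURES",
    "Matching",
    "read_norms",
    "zscore_features",
    "cosine_similarity",
    "balance_lists",
    "summarize_lists",
]

FEATURES = ["zipf_frequency", "aoa", "h_index"]


@dataclass(frozen=True)
class Matching:
    """A perfect matching of the items and its mean pairwise cosine similarity."""

    pairs: tuple[tuple[str, str], ...]
    mean_cosine: float

    def __post_init__(self) -> None:
        words = [w for pair in self.pairs for w in pair]
        if len(set(words)) != len(words):
            raise ValueError("matching pairs must be disjoint")
        if not -1.0 <= self.mean_cosine <= 1.0 + 1e-12:
            raise ValueError("mean cosine outside [-1, 1]")


def read_norms(path: str | Path) -> pd.DataFrame:
    """Read a stimulus-norms CSV (columns: word, zipf_frequency, aoa, h_index)."""
    norms = pd.read_csv(path, dtype={"word": str})
    missing = [c for c in ["word", *FEATURES] if c not in norms.columns]
    if missing:
        raise ValueError(f"norms file missing column(s): {missing}")
    if norms["word"].duplicated().any():
        dups = norms.loc[norms["word"].duplicated(), "word"].tolist()
        raise ValueError(f"duplicate words in norms: {dups[:5]}")
    if norms[FEATURES].isna().any().any():
        raise ValueError("norms contain missing feature values")
    return norms


def zscore_features(norms: pd.DataFrame, ddof: int = 1) -> np.ndarray:
    """Z-score the three norm columns into per-item feature vectors.

    Uses the sample SD (ddof=1) by default; each column of the result has
    mean 0 and SD 1.
    """
    if len(norms) < 2:
        raise ValueError("need at least 2 items to z-score")
    X = norms[FEATURES].to_numpy(dtype=float)
    sd = X.std(axis=0, ddof=ddof)
    for j, feat in enumerate(FEATURES):
        if sd[j] == 0:
            raise ValueError(f"feature {feat!r} has zero variance")
    return (X - X.mean(axis=0)) / sd


def cosine_similarity(u: np.ndarray, v: np.ndarray) -> float:
    """Cosine of the angle between two feature vectors."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape:
        raise ValueError("vectors must have the same length")
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        raise ValueError("cosine similarity undefined for zero vector")
    return float(u @ v / (nu * nv))


def _cosine_matrix(X: np.ndarray) -> np.ndarray:
    norms = np.linalg.norm(X, axis=1, keepdims=True)
    if (norms == 0).any():
        raise ValueError("zero feature vector encountered")
    Xn = X / norms
    return Xn @ Xn.T


def balance_lists(
    norms: pd.DataFrame,
    n_samples: int = 1_000_000,
    seed: int = 0,
    ddof: int = 1,
    batch_size: int = 2_000,
) -> tuple[list[str], list[str], Matching]:
    """Split the items into two lists balanced on the three norms.

    Random perfect matchings are generated by shuffling the item order and
    pairing adjacent elements; the matching with the highest mean cosine
    similarity over ``n_samples`` draws is kept, and each pair is split
    between the lists by a fair coin. Deterministic under ``seed``.
    """
    n = len(norms)
    if n < 4 or n % 2:
        raise ValueError(f"need an even item count >= 4, got {n}")
    if n_samples < 1:
        raise ValueError("n_samples must be positive")
    X = zscore_features(norms, ddof=ddof)
    C = _cosine_matrix(X)
    words = norms["word"].tolist()
    rng = np.random.default_rng(seed)

    best_score = -np.inf
    best_perm: np.ndarray | None = None
    remaining = n_samples
    while remaining > 0:
        b = min(batch_size, remaining)
        remaining -= b
        perms = np.argsort(rng.random((b, n)), axis=1)
        left = perms[:, 0::2]
        right = perms[:, 1::2]
        scores = C[left, right].mean(axis=1)
        k = int(np.argmax(scores))
        if scores[k] > best_score:
            best_score = float(scores[k])
            best_perm = perms[k]

    assert best_perm is not None
    pairs = []
    list_a, list_b = [], []
    coins = rng.random(n // 2)
    for j in range(n // 2):
        i1, i2 = int(best_perm[2 * j]), int(best_perm[2 * j + 1])
        w1, w2 = words[i1], words[i2]
        pairs.append((w1, w2))
        if coins[j] < 0.5:
            list_a.append(w1)
            list_b.append(w2)
        else:
            list_a.append(w2)
            list_b.append(w1)
    matching = Matching(pairs=tuple(pairs), mean_cosine=best_score)
    return list_a, list_b, matching


def summarize_lists(
    list_a: list[str], list_b: list[str], norms: pd.DataFrame
) -> pd.DataFrame:
    """Per-list mean and SD of each raw norm (frequency, AoA, H-index).

    The two lists must partition the norms' words.
    """
    set_a, set_b = set(list_a), set(list_b)
    if set_a & set_b:
        raise ValueError(f"lists overlap: {sorted(set_a & set_b)[:5]}")
    if set_a | set_b != set(norms["word"]):
        raise ValueError("lists do not partition the norms")
    rows = []
    for name, members in (("list_1", list_a), ("list_2", list_b)):
        sub = norms[norms["word"].isin(members)]
        row = {"list": name, "n": len(sub)}
        for feat in FEATURES:
            row[f"{feat}_mean"] = float(sub[feat].mean())
            row[f"{feat}_sd"] = float(sub[feat].std(ddof=1))
        rows.append(row)
    return pd.DataFrame(rows)
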