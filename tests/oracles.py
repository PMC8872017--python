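"""Independent brute-force oracles used to check the package's fast paths.

These deliberately avoid the package's own implementations: the cell
interpreter is written directly against numpy, the AUROC is an explicit
pairwise count, and the onset/window scans are naive enumerations.
"""

from __future__ import annotations

import numpy as np

_ACT = {
    "tanh": np.tanh,
    "relu": lambda v: np.maximum(v, 0.0),
    "identity": lambda v: v,
    "sigmoid": lambda v: 1.0 / (1.0 + np.exp(-v)),
}


def reference_cell_forward(
    activations: tuple[str, ...],
    parents: tuple[int, ...],
    weights: dict[str, np.ndarray],
    head_w: np.ndarray,
    head_b: np.ndarray,
    x: np.ndarray,
) -> np.ndarray:
    """Plain-numpy interpreter of the cell DAG; returns logits."""
    n = len(activations)
    batch, steps, _ = x.shape
    hidden = weights["recur"].shape[0]
    children = {j: [] for j in range(1, n + 1)}
    for i, p in enumerate(parents):
        children[p].append(i + 2)
    terminals = [k for k in range(1, n + 1) if not children[k]]
    h_prev = np.zeros((batch, hidden))
    for t in range(steps):
        out = {}
        out[1] = _ACT[activations[0]](x[:, t, :] @ weights["input"] + h_prev @ weights["recur"])
        for k in range(2, n + 1):
            p = parents[k - 2]
            out[k] = _ACT[activations[k - 1]](out[p] @ weights[f"edge:{p}-{k}"])
        h_prev = sum(out[k] for k in terminals) / len(terminals)
    return h_prev @ head_w + head_b


def pairwise_auroc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Exhaustive positive/negative pair count; ties score one half."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    wins = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                wins += 1.0
            elif p == q:
                wins += 0.5
    return wins / (len(pos) * len(neg))


def brute_force_onset(flags: list[bool], has_infection: bool, min_run: int = 5) -> int | None:
    """Earliest start of >= min_run consecutive True flags."""
    if not has_infection:
        return None
    for s in range(len(flags) - min_run + 1):
        if all(flags[s : s + min_run]):
            return s
    return None


def brute_force_windows(length: int, onset: int | None, horizon: int) -> list[int]:
    """Start hours of emitted 5 h windows under the exact-hour target rule."""
    starts = []
    for s in range(length):
        target = s + 5 + horizon
        if target > length:
            continue
        if onset is not None and target > onset:
            continue
        starts.append(s)
    return starts
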