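"""Train/test index plans: bootstrap, subsampling, (repeated) K-fold CV.

Bootstrap (``BS``) draws n indices with replacement; the test set is the
out-of-bag complement, which asymptotically leaves 36.8 % of the sample
out.  Subsampling (``SS``) draws round(0.632 n) distinct indices without
replacement so the train/test proportions match the bootstrap
expectation.  Cross-validation splits a random permutation into K folds
whose sizes differ by at most one; ``CVKrep`` repeats the whole K-fold
scheme B times.  Splits are simple random (no outcome stratification).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np

from ._util import as_generator, round_half_even

log = logging.getLogger(__name__)

STRATEGIES = ("BS", "SS", "CVK", "CVKrep")

#: asymptotic expected fraction of distinct observations in a bootstrap draw
SUBSAMPLE_FRACTION = 0.632


@dataclass
class ResamplingPlan:
    strategy: str
    n: int
    B: int
    K: int | None
    splits: list[tuple[np.ndarray, np.ndarray]]
    repetition: np.ndarray = field(default=None)  # CVKrep: rep id per split

    def __len__(self):
        return len(self.splits)

    def __iter__(self):
        return iter(self.splits)

    def to_json(self) -> str:
        """Serialize with 1-based observation indices for audit."""
        return json.dumps({
            "strategy": self.strategy, "n": self.n, "B": self.B,
            "K": self.K,
            "repetition": None if self.repetition is None
            else self.repetition.tolist(),
            "splits": [
                {"train": (tr + 1).tolist(), "test": (te + 1).tolist()}
                for tr, te in self.splits
            ],
        })

    @classmethod
    def from_json(cls, text: str) -> "ResamplingPlan":
        d = json.loads(text)
        splits = [
            (np.asarray(s["train"]) - 1, np.asarray(s["test"]) - 1)
            for s in d["splits"]
        ]
        rep = None if d["repetition"] is None else np.asarray(d["repetition"])
        return cls(d["strategy"], d["n"], d["B"], d["K"], splits, rep)


def _bootstrap_split(n: int, rng) -> tuple[np.ndarray, np.ndarray]:
    for attempt in range(100):
        train = rng.integers(0, n, size=n)
        test = np.setdiff1d(np.arange(n), train)
        if len(test) > 0:
            if attempt:
                log.info("redrew %d degenerate bootstrap draw(s)", attempt)
            return train, test
    raise RuntimeError("could not draw a bootstrap sample with a non-empty "
                       "out-of-bag set")


def _cv_folds(n: int, K: int, rng) -> list[np.ndarray]:
    perm = rng.permutation(n)
    return np.array_split(perm, K)  # remainder goes to the first folds


def draw_resamples(n: int, strategy: str, B: int = 1, K: int | None = None,
                   seed=None) -> ResamplingPlan:
    """Draw a resampling plan.

    ``CVK`` ignores B (one pass over K folds); ``CVKrep`` produces B
    repetitions of K folds, tagged with their repetition index so CV
    estimates can be averaged per repetition first.
    """
    if strategy not in STRATEGIES:
        raise ValueError(f"unknown strategy {strategy!r}")
    if B < 1:
        raise ValueError("B must be >= 1")
    rng = as_generator(seed)
    splits: list[tuple[np.ndarray, np.ndarray]] = []
    repetition = None
    if strategy in ("CVK", "CVKrep"):
        if K is None or not 2 <= K <= n:
            raise ValueError("CV requires 2 <= K <= n")
        n_rep = 1 if strategy == "CVK" else B
        reps = []
        for r in range(n_rep):
            folds = _cv_folds(n, K, rng)
            for fold in folds:
                train = np.setdiff1d(np.arange(n), fold)
                splits.append((train, np.sort(fold)))
                reps.append(r)
        repetition = np.asarray(reps)
        B = n_rep
    elif strategy == "BS":
        for _ in range(B):
            splits.append(_bootstrap_split(n, rng))
    else:  # SS
        size = round_half_even(SUBSAMPLE_FRACTION * n)
        size = min(max(size, 1), n - 1)
        for _ in range(B):
            train = rng.choice(n, size=size, replace=False)
            test = np.setdiff1d(np.arange(n), train)
            splits.append((train, test))
    return ResamplingPlan(strategy, n, B, K, splits, repetition)
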