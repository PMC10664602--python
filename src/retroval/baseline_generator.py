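"""Token-level Markov-chain SMILES generator.

A desk-scale stand-in implementing the generator contract the evaluation
framework needs — fit on a corpus, focus (fine-tune analog) toward a small
set of compounds, sample raw SMILES, and assign per-molecule negative log
likelihoods (in nats). It makes no chemistry guarantees: sampled strings
may be invalid, which is exactly what the validity metric measures.
"""

from __future__ import annotations

import json
import math
import re
from collections import Counter, defaultdict
from typing import Sequence

import numpy as np

BEGIN = "^"
END = "$"

_TOKEN_RE = re.compile(
    r"(\[[^\]]+\]|Br|Cl|%\d{2}|.)"
)

DEFAULT_ORDER = 3
DEFAULT_SMOOTHING = 0.01


class TokenizeError(ValueError):
    """Raised for strings that cannot be split into SMILES tokens."""


def tokenize(smiles: str) -> list[str]:
    """Deterministic SMILES tokenization.

    Two-letter halogens, bracket atoms and two-digit ring closures are
    single tokens; concatenating the tokens reproduces the input exactly.
    """
    if not smiles:
        raise TokenizeError("empty string")
    if smiles.count("[") != smiles.count("]"):
        raise TokenizeError(f"dangling bracket in {smiles!r}")
    tokens = _TOKEN_RE.findall(smiles)
    if "".join(tokens) != smiles or any("[" in t and not t.endswith("]") for t in tokens):
        raise TokenizeError(f"cannot tokenize {smiles!r}")
    return tokens


class MarkovSmilesModel:
    """Order-``k`` Markov chain over SMILES tokens with additive smoothing.

    Transition counts are collected at fit time over contexts of the last
    ``order`` tokens (padded with a begin sentinel); smoothing pseudo-counts
    are applied at query time. :meth:`focus` layers a second count table on
    top, mixed per context with weight ``lam`` — contexts never seen in the
    focus corpus fall back to the prior distribution.
    """

    def __init__(self, order: int = DEFAULT_ORDER, smoothing: float = DEFAULT_SMOOTHING):
        if order < 1:
            raise ValueError("order must be >= 1")
        if smoothing < 0:
            raise ValueError("smoothing must be >= 0")
        self.order = order
        self.smoothing = float(smoothing)
        self.counts: dict[tuple, Counter] = defaultdict(Counter)
        self.focus_counts: dict[tuple, Counter] | None = None
        self.lam: float = 0.0
        self.vocab: list[str] = []
        self._fitted = False

    # -- fitting ---------------------------------------------------------

    def _transitions(self, smiles: str):
        toks = tokenize(smiles) + [END]
        ctx = [BEGIN] * self.order
        for tok in toks:
            yield tuple(ctx), tok
            ctx = ctx[1:] + [tok]

    def fit(self, corpus: Sequence[str]) -> "MarkovSmilesModel":
        if len(corpus) == 0:
            raise ValueError("empty corpus")
        vocab = {END}
        for smi in corpus:
            for ctx, tok in self._transitions(smi):
                self.counts[ctx][tok] += 1
            vocab.update(tokenize(smi))
        self.vocab = sorted(vocab)
        self._fitted = True
        return self

    def focus(self, focus_corpus: Sequence[str], lam: float) -> "MarkovSmilesModel":
        """Return a copy mixed toward the focus corpus with weight ``lam``."""
        if not self._fitted:
            raise ValueError("fit before focus")
        if len(focus_corpus) == 0:
            raise ValueError("empty focus corpus")
        if not 0.0 <= lam <= 1.0:
            raise ValueError("lam must be in [0, 1]")
        out = MarkovSmilesModel(self.order, self.smoothing)
        out.counts = self.counts
        out._fitted = True
        out.lam = float(lam)
        out.focus_counts = defaultdict(Counter)
        vocab = set(self.vocab)
        for smi in focus_corpus:
            for ctx, tok in out._transitions(smi):
                out.focus_counts[ctx][tok] += 1
            vocab.update(tokenize(smi))
        out.vocab = sorted(vocab)
        return out

    # -- probabilities ---------------------------------------------------

    def _dist_from(self, counts: Counter) -> np.ndarray:
        v = len(self.vocab)
        arr = np.array(
            [counts.get(t, 0) for t in self.vocab], dtype=np.float64
        )
        total = arr.sum()
        denom = total + self.smoothing * v
        if denom == 0:
            raise ValueError(
                "context has no counts and smoothing is 0: "
                "distribution undefined"
            )
        return (arr + self.smoothing) / denom

    def context_distribution(self, ctx: tuple) -> np.ndarray:
        """Probability over ``self.vocab`` for the next token after ``ctx``."""
        if not self._fitted:
            raise ValueError("model is not fitted")
        prior = self._dist_from(self.counts.get(ctx, Counter()))
        if self.focus_counts is None or self.lam == 0.0:
            return prior
        fc = self.focus_counts.get(ctx)
        if fc is None or sum(fc.values()) == 0:
            return prior  # unseen in focus: fall back to prior
        return (1.0 - self.lam) * prior + self.lam * self._dist_from(fc)

    # -- inference -------------------------------------------------------

    def nll(self, smiles: str) -> float:
        """Negative log likelihood of the string in nats (incl. end token).

        Tokens outside the model vocabulary, or zero-probability
        transitions under zero smoothing, yield ``inf``.
        """
        if not self._fitted:
            raise ValueError("model is not fitted")
        total = 0.0
        index = {t: i for i, t in enumerate(self.vocab)}
        for ctx, tok in self._transitions(smiles):
            i = index.get(tok)
            if i is None:
                return math.inf
            try:
                p = self.context_distribution(ctx)[i]
            except ValueError:  # unseen context under zero smoothing
                return math.inf
            if p == 0.0:
                return math.inf
            total -= math.log(p)
        return total

    def sample(
        self, n: int, max_len: int = 100, seed: int = 0
    ) -> list[str]:
        """Draw ``n`` raw SMILES strings (possibly invalid), reproducibly."""
        if not self._fitted:
            raise ValueError("model is not fitted")
        if n < 1:
            raise ValueError("n must be >= 1")
        rng = np.random.default_rng(seed)
        v = len(self.vocab)
        cache: dict[tuple, np.ndarray] = {}
        out = []
        for _ in range(n):
            ctx = tuple([BEGIN] * self.order)
            toks: list[str] = []
            for _ in range(max_len):
                p = cache.get(ctx)
                if p is None:
                    p = self.context_distribution(ctx)
                    cache[ctx] = p
                tok = self.vocab[rng.choice(v, p=p)]
                if tok == END:
                    break
                toks.append(tok)
                ctx = ctx[1:] + (tok,)
            out.append("".join(toks))
        return out

    # -- persistence -----------------------------------------------------

    _SEP = "\x1f"

    def save(self, path) -> None:
        def enc(table):
            return {
                self._SEP.join(ctx): dict(cnt) for ctx, cnt in table.items()
            }

        blob = {
            "order": self.order,
            "smoothing": self.smoothing,
            "vocab": self.vocab,
            "lam": self.lam,
            "counts": enc(self.counts),
            "focus_counts": enc(self.focus_counts)
            if self.focus_counts is not None
            else None,
        }
        with open(path, "w") as fh:
            json.dump(blob, fh)

    @classmethod
    def load(cls, path) -> "MarkovSmilesModel":
        with open(path) as fh:
            blob = json.load(fh)
        model = cls(blob["order"], blob["smoothing"])

        def dec(table):
            out = defaultdict(Counter)
            for key, cnt in table.items():
                out[tuple(key.split(cls._SEP))] = Counter(cnt)
            return out

        model.counts = dec(blob["counts"])
        model.vocab = blob["vocab"]
        model.lam = blob["lam"]
        if blob["focus_counts"] is not None:
            model.focus_counts = dec(blob["focus_counts"])
        model._fitted = True
        return model


def region_nll_summary(models: dict, labelled_dataset):
    """Mean/median NLL per (model, region) for cross-model comparison.

    ``models`` maps a display name (e.g. "prior", "focused") to a fitted
    model. Non-finite NLLs (out-of-vocabulary compounds under zero
    smoothing) are excluded from the summary statistics and counted in
    ``n_infinite``. Empty regions are absent.
    """
    import pandas as pd

    rows = []
    for name, model in models.items():
        for region in ("alpha", "beta", "gamma"):
            smiles = labelled_dataset.region_smiles(region)
            if not smiles:
                continue
            nlls = np.array([model.nll(s) for s in smiles])
            finite = nlls[np.isfinite(nlls)]
            rows.append(
                {
                    "model": name,
                    "region": region,
                    "n": int(len(nlls)),
                    "n_infinite": int(np.sum(~np.isfinite(nlls))),
                    "mean_nll": float(np.mean(finite)) if len(finite) else np.nan,
                    "median_nll": float(np.median(finite)) if len(finite) else np.nan,
                }
            )
    return pd.DataFrame(
        rows,
        columns=["model", "region", "n", "n_infinite", "mean_nll", "median_nll"],
    )
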