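"""Simple recurrent (Elman) network for next-POS prediction.

The second sequential context model: a three-level network whose sigmoid
hidden layer carries a weighted summary of the full preceding tag sequence.
At step i the input is the one-hot code of tag w_{i-1} (an all-zero vector at
the first word), and the softmax output estimates P(w_i | w_1..w_{i-1}).
The hidden state is reset at sentence boundaries.

Training is plain stochastic gradient descent with full backpropagation
through time over each sentence, with early stopping on development-set
perplexity.  The reference architecture is V-500-V; the package default is a
much smaller hidden layer (H=32), which is ample for the synthetic tag
corpora used here.  Everything is deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .grammar import POSCorpus

__all__ = ["SRNConfig", "SRNModel", "train_srn"]


@dataclass(frozen=True)
class SRNConfig:
    hidden: int = 32
    epochs: int = 50
    learning_rate: float = 0.3
    batch_size: int = 1  # sentences per gradient step
    dev_fraction: float = 0.1
    patience: int = 3
    init_scale: float = 0.1  # 0.0 gives an exactly-uniform untrained model
    seed: int = 0


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def _sigmoid(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-z))


@dataclass
class SRNModel:
    """Trained Elman network; weights fully determine the surprisal series."""

    vocabulary: tuple[str, ...]
    W_xh: np.ndarray  # (V, H)
    W_hh: np.ndarray  # (H, H)
    b_h: np.ndarray  # (H,)
    W_ho: np.ndarray  # (H, V)
    b_o: np.ndarray  # (V,)
    config: SRNConfig
    training_log: list[dict] = field(default_factory=list)

    @property
    def V(self) -> int:
        return len(self.vocabulary)

    @property
    def H(self) -> int:
        return self.W_hh.shape[0]

    def _index(self, sent: tuple[str, ...]) -> np.ndarray:
        idx = np.empty(len(sent), dtype=np.intp)
        lookup = {t: i for i, t in enumerate(self.vocabulary)}
        for j, t in enumerate(sent):
            if t not in lookup:
                raise ValueError(f"tag {t!r} not in SRN vocabulary")
            idx[j] = lookup[t]
        return idx

    def _forward(self, targets: np.ndarray):
        """Hidden states and output distributions for one sentence."""
        n = len(targets)
        hs = np.zeros((n + 1, self.H))
        ys = np.empty((n, self.V))
        for i in range(n):
            x_contrib = 0.0 if i == 0 else self.W_xh[targets[i - 1]]
            hs[i + 1] = _sigmoid(x_contrib + hs[i] @ self.W_hh + self.b_h)
            ys[i] = _softmax(hs[i + 1] @ self.W_ho + self.b_o)
        return hs, ys

    def sequence_probs(self, sent: tuple[str, ...]) -> np.ndarray:
        targets = self._index(tuple(sent))
        _, ys = self._forward(targets)
        return ys[np.arange(len(targets)), targets]

    def sequence_surprisals(self, sent: tuple[str, ...]) -> np.ndarray:
        return -np.log2(self.sequence_probs(tuple(sent)))

    def output_distributions(self, sent: tuple[str, ...]) -> np.ndarray:
        """Softmax distribution at every step; rows sum to one."""
        _, ys = self._forward(self._index(tuple(sent)))
        return ys

    # -- persistence -------------------------------------------------------

    def save(self, path) -> None:
        np.savez(
            path,
            vocabulary=np.array(self.vocabulary),
            W_xh=self.W_xh,
            W_hh=self.W_hh,
            b_h=self.b_h,
            W_ho=self.W_ho,
            b_o=self.b_o,
        )

    @classmethod
    def load(cls, path) -> "SRNModel":
        z = np.load(path, allow_pickle=False)
        return cls(
            vocabulary=tuple(str(v) for v in z["vocabulary"]),
            W_xh=z["W_xh"],
            W_hh=z["W_hh"],
            b_h=z["b_h"],
            W_ho=z["W_ho"],
            b_o=z["b_o"],
            config=SRNConfig(),
        )

    # -- training ----------------------------------------------------------

    def _bptt(self, targets: np.ndarray):
        """Cross-entropy gradients for one sentence (full BPTT)."""
        hs, ys = self._forward(targets)
        n = len(targets)
        d_out = ys.copy()
        d_out[np.arange(n), targets] -= 1.0  # dL/dz_out, L = sum CE

        gW_ho = hs[1:].T @ d_out
        gb_o = d_out.sum(axis=0)
        gW_xh = np.zeros_like(self.W_xh)
        gW_hh = np.zeros_like(self.W_hh)
        gb_h = np.zeros_like(self.b_h)

        dh_next = np.zeros(self.H)
        for i in range(n - 1, -1, -1):
            dh = d_out[i] @ self.W_ho.T + dh_next
            dz = dh * hs[i + 1] * (1.0 - hs[i + 1])
            gb_h += dz
            gW_hh += np.outer(hs[i], dz)
            if i > 0:
                gW_xh[targets[i - 1]] += dz
            dh_next = dz @ self.W_hh.T
        with np.errstate(divide="ignore"):
            loss = -np.log(ys[np.arange(n), targets]).sum()
        return loss, (gW_xh, gW_hh, gb_h, gW_ho, gb_o)

    def _perplexity(self, sentences) -> float:
        total_bits = 0.0
        total_words = 0
        for sent in sentences:
            targets = self._index(sent)
            _, ys = self._forward(targets)
            p = ys[np.arange(len(targets)), targets]
            total_bits += float(-np.log2(p + 1e-300).sum())
            total_words += len(targets)
        return 2.0 ** (total_bits / total_words)


def train_srn(corpus: POSCorpus, config: SRNConfig | None = None) -> SRNModel:
    """Train an SRN with early stopping on development perplexity.

    The corpus is split deterministically (by the config seed) into training
    and development sentences.  Training stops when dev perplexity has not
    improved for ``patience`` consecutive epochs; the best-scoring weights
    are returned.  Identical (corpus, config) gives identical weights.
    """
    config = config or SRNConfig()
    vocab = tuple(sorted(corpus.tagset))
    V, H = len(vocab), config.hidden
    rng = np.random.default_rng(config.seed)

    model = SRNModel(
        vocabulary=vocab,
        W_xh=rng.normal(0.0, 1.0, (V, H)) * config.init_scale,
        W_hh=rng.normal(0.0, 1.0, (H, H)) * config.init_scale,
        b_h=np.zeros(H),
        W_ho=rng.normal(0.0, 1.0, (H, V)) * config.init_scale,
        b_o=np.zeros(V),
        config=config,
    )

    sentences = [tuple(s) for s in corpus.sentences]
    order = rng.permutation(len(sentences))
    n_dev = max(1, int(round(config.dev_fraction * len(sentences))))
    if len(sentences) == 1:
        dev_idx, train_idx = order[:1], order[:1]
    else:
        dev_idx, train_idx = order[:n_dev], order[n_dev:]
    dev = [sentences[i] for i in dev_idx]
    train = [sentences[i] for i in train_idx]
    idx_cache = {i: model._index(sentences[i]) for i in range(len(sentences))}

    best_ppl = model._perplexity(dev)
    best_weights = _snapshot(model)
    model.training_log.append({"epoch": 0, "dev_perplexity": best_ppl})
    stale = 0

    lr = config.learning_rate
    for epoch in range(1, config.epochs + 1):
        perm = rng.permutation(len(train))
        grads_acc = None
        n_in_batch = 0
        for k, j in enumerate(perm):
            loss, grads = model._bptt(idx_cache[train_idx[j]])
            if not (np.isfinite(loss) and np.isfinite(model.W_hh).all()):
                raise FloatingPointError(
                    f"non-finite training loss at epoch {epoch} "
                    f"(learning rate {lr}); reduce the learning rate"
                )
            if grads_acc is None:
                grads_acc = list(grads)
            else:
                for a, g in zip(grads_acc, grads):
                    a += g
            n_in_batch += 1
            if n_in_batch == config.batch_size or k == len(perm) - 1:
                scale = lr / n_in_batch
                model.W_xh -= scale * grads_acc[0]
                model.W_hh -= scale * grads_acc[1]
                model.b_h -= scale * grads_acc[2]
                model.W_ho -= scale * grads_acc[3]
                model.b_o -= scale * grads_acc[4]
                grads_acc = None
                n_in_batch = 0
        ppl = model._perplexity(dev)
        model.training_log.append({"epoch": epoch, "dev_perplexity": ppl})
        if ppl < best_ppl - 1e-12:
            best_ppl = ppl
            best_weights = _snapshot(model)
            stale = 0
        else:
            stale += 1
            if stale >= config.patience:
                break
    _restore(model, best_weights)
    return model


def _snapshot(model: SRNModel):
    return (
        model.W_xh.copy(),
        model.W_hh.copy(),
        model.b_h.copy(),
        model.W_ho.copy(),
        model.b_o.copy(),
    )


def _restore(model: SRNModel, weights) -> None:
    model.W_xh, model.W_hh, model.b_h, model.W_ho, model.b_o = (
        w.copy() for w in weights
    )
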