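"""The tagger network and its training objectives.

Architecture: learned word embeddings feed a (bi)directional LSTM encoder;
the final hidden states (concatenated across directions) form the document
representation h, and one independent binary logistic classifier per disease
code produces p_d = sigmoid(e_d . h + b_d).  The rows e_d of the final-layer
weight matrix are the *disease-code embeddings* on which the hierarchical
regularization acts.

Three losses:

* joint binary cross-entropy over all codes (the multitask baseline);
* a cluster penalty on the code embeddings — squared L2 attraction between
  codes in the same meta-disease, a hinged margin repulsion between codes in
  different meta-diseases — so that related codes share classifier structure;
* a meta-disease prediction loss — each meta-disease probability is the
  noisy-OR of its member code probabilities, q_g = 1 - prod_d (1 - p_d), and
  is trained with BCE against the OR of the member labels.

With both auxiliary weights at zero the model is exactly the plain BLSTM
baseline; with ``bidirectional=False`` as well, the plain LSTM baseline.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict, field, replace
from typing import Sequence

import numpy as np

from ._autodiff import Adam, Tensor, concat, gather_rows, parameter
from .corpus import Note, Vocabulary
from .ontology import CodeOntology

EPS = 1e-7  # probability clamp in cross-entropy terms


@dataclass
class TaggerConfig:
    """Hyperparameters of the tagger and its training run."""

    vocab_size: int | None = None
    embedding_dim: int = 100
    hidden_dim: int = 256          # per direction
    bidirectional: bool = True     # False reproduces the unidirectional baseline
    dropout: float = 0.2
    lambda_cluster: float = 0.0    # cluster-penalty weight (>0: DeepTag)
    beta_meta: float = 0.0         # meta-loss weight (>0: DeepTag-M)
    cluster_margin: float = 1.0
    learning_rate: float = 1e-3
    batch_size: int = 32
    max_epochs: int = 20
    patience: int = 3
    max_len: int = 512             # token-sequence truncation (from the tail)
    threshold: float = 0.5         # binarization; p == 0.5 predicts positive
    seed: int = 0

    def __post_init__(self) -> None:
        if self.lambda_cluster < 0 or self.beta_meta < 0:
            raise ValueError("loss weights must be non-negative")
        if self.cluster_margin <= 0:
            raise ValueError("cluster margin must be positive")


class TaggerModel:
    """Parameter container plus encode/predict for one configuration."""

    def __init__(
        self,
        config: TaggerConfig,
        vocabulary: Vocabulary,
        ontology: CodeOntology,
    ) -> None:
        if config.vocab_size is None:
            config = replace(config, vocab_size=len(vocabulary))
        self.config = config
        self.vocabulary = vocabulary
        self.ontology = ontology
        self.n_codes = ontology.n_diseases
        rng = np.random.default_rng(config.seed)
        E, H = config.embedding_dim, config.hidden_dim
        self.embedding = parameter(rng, (config.vocab_size, E), scale=0.1)
        self.cells = {"fwd": _lstm_params(rng, E, H)}
        if config.bidirectional:
            self.cells["bwd"] = _lstm_params(rng, E, H)
        rep = H * (2 if config.bidirectional else 1)
        self.label_embeddings = parameter(rng, (self.n_codes, rep))
        self.label_bias = Tensor(np.zeros(self.n_codes), requires_grad=True)
        self._rng = rng  # dropout noise; advanced only in training mode

    # -- parameter plumbing ---------------------------------------------

    @property
    def rep_dim(self) -> int:
        return self.config.hidden_dim * (2 if self.config.bidirectional else 1)

    def parameters(self) -> list[Tensor]:
        params = [self.embedding]
        for cell in self.cells.values():
            params.extend(cell.values())
        params += [self.label_embeddings, self.label_bias]
        return params

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {"embedding": self.embedding.data, "label_E": self.label_embeddings.data,
                 "label_b": self.label_bias.data}
        for name, cell in self.cells.items():
            for k, v in cell.items():
                state[f"{name}.{k}"] = v.data
        return state

    def load_state(self, state: dict[str, np.ndarray]) -> None:
        self.embedding.data = state["embedding"].copy()
        self.label_embeddings.data = state["label_E"].copy()
        self.label_bias.data = state["label_b"].copy()
        for name, cell in self.cells.items():
            for k in cell:
                cell[k].data = state[f"{name}.{k}"].copy()

    # -- forward --------------------------------------------------------

    def encode_batch(
        self, ids: np.ndarray, lengths: np.ndarray, training: bool = False
    ) -> Tensor:
        """Document representations for a padded id matrix (B, T).

        The representation is the final LSTM state at each sequence's true
        length; bidirectional mode concatenates the final states of a forward
        pass and a pass over the reversed sequence.  Dropout (inverted, on
        the representation) applies only in training mode.
        """
        if ids.ndim != 2 or ids.shape[0] != len(lengths):
            raise ValueError("ids must be (batch, time) matching lengths")
        if np.any(lengths < 1):
            raise ValueError("cannot encode an empty token sequence")
        if ids.max(initial=0) >= self.config.vocab_size:
            raise ValueError("token id out of vocabulary range")
        parts = [self._run_direction(ids, lengths, "fwd")]
        if self.config.bidirectional:
            rev = _reverse_valid(ids, lengths)
            parts.append(self._run_direction(rev, lengths, "bwd"))
        h = concat(parts, axis=-1) if len(parts) > 1 else parts[0]
        if training and self.config.dropout > 0:
            keep = 1.0 - self.config.dropout
            mask = self._rng.random(h.shape) < keep
            h = h * (mask / keep)
        return h

    def _run_direction(self, ids: np.ndarray, lengths: np.ndarray, name: str) -> Tensor:
        cell = self.cells[name]
        return _lstm_final_state(
            self.embedding, cell["Wx"], cell["Wh"], cell["b"], ids, lengths
        )

    def logits(self, h: Tensor) -> Tensor:
        return h @ _transpose(self.label_embeddings) + self.label_bias

    def predict_proba(
        self, notes: Sequence[Note], batch_size: int | None = None
    ) -> np.ndarray:
        """Per-code probabilities, (n_notes, n_codes), in eval mode."""
        bs = batch_size or self.config.batch_size
        out = np.empty((len(notes), self.n_codes))
        for start in range(0, len(notes), bs):
            chunk = notes[start : start + bs]
            ids, lengths = make_batch(chunk, self.vocabulary, self.config.max_len)
            h = self.encode_batch(ids, lengths, training=False)
            out[start : start + len(chunk)] = self.logits(h).sigmoid().data
        return out

    def predict_labels(self, notes: Sequence[Note]) -> np.ndarray:
        """Binary predictions at the configured threshold (ties positive)."""
        return (self.predict_proba(notes) >= self.config.threshold).astype(np.int8)

    # -- persistence ----------------------------------------------------

    def save(self, path) -> None:
        meta = {
            "config": asdict(self.config),
            "vocab_tokens": self.vocabulary._id_to_token[2:],
            "ontology": {
                "subtype_to_disease": self.ontology.subtype_to_disease,
                "disease_to_meta": {str(k): v for k, v in self.ontology.disease_to_meta.items()},
                "disease_names": self.ontology.disease_names,
                "meta_names": self.ontology.meta_names,
                "other_index": self.ontology.other_index,
                "strict_cardinality": self.ontology.strict_cardinality,
            },
        }
        np.savez(path, __meta__=json.dumps(meta), **self.state_dict())

    @classmethod
    def load(cls, path) -> "TaggerModel":
        with np.load(path, allow_pickle=False) as archive:
            meta = json.loads(str(archive["__meta__"]))
            state = {k: archive[k] for k in archive.files if k != "__meta__"}
        onto = meta["ontology"]
        ontology = CodeOntology(
            subtype_to_disease=onto["subtype_to_disease"],
            disease_to_meta={int(k): v for k, v in onto["disease_to_meta"].items()},
            disease_names=onto["disease_names"],
            meta_names=onto["meta_names"],
            other_index=onto["other_index"],
            strict_cardinality=onto["strict_cardinality"],
        )
        vocab = Vocabulary(meta["vocab_tokens"])
        model = cls(TaggerConfig(**meta["config"]), vocab, ontology)
        model.load_state(state)
        return model


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def _lstm_final_state(
    emb: Tensor, Wx: Tensor, Wh: Tensor, b: Tensor,
    ids: np.ndarray, lengths: np.ndarray,
) -> Tensor:
    """Run an LSTM over a padded id matrix; return the final masked state.

    Implemented as a single fused autodiff node: the forward loop caches the
    per-step activations and the backward closure replays them in reverse
    (standard backpropagation through time), which avoids building hundreds
    of tape nodes per document.  State updates are masked so each sequence's
    state freezes at its own length; gate order is input/forget/cell/output.
    """
    B, T = ids.shape
    H = Wh.data.shape[0]
    WxD, WhD, bD, embD = Wx.data, Wh.data, b.data, emb.data
    h = np.zeros((B, H))
    c = np.zeros((B, H))
    cache = []
    masks = (np.arange(T)[None, :] < lengths[:, None]).astype(float)
    for t in range(T):
        x = embD[ids[:, t]]
        gates = x @ WxD + h @ WhD + bD
        i = _sigmoid(gates[:, :H])
        f = _sigmoid(gates[:, H : 2 * H])
        g = np.tanh(gates[:, 2 * H : 3 * H])
        o = _sigmoid(gates[:, 3 * H :])
        c_new = f * c + i * g
        tanh_c = np.tanh(c_new)
        m = masks[:, t][:, None]
        cache.append((x, i, f, g, o, c, h, tanh_c, m))
        h = o * tanh_c * m + h * (1.0 - m)
        c = c_new * m + c * (1.0 - m)
    out = Tensor(h, parents=(emb, Wx, Wh, b))

    def backward(grad_h: np.ndarray) -> None:
        dWx = np.zeros_like(WxD)
        dWh = np.zeros_like(WhD)
        db = np.zeros_like(bD)
        demb = np.zeros_like(embD)
        dh = grad_h.copy()
        dc = np.zeros((B, H))
        for t in reversed(range(T)):
            x, i, f, g, o, c_prev, h_prev, tanh_c, m = cache[t]
            dh_new = dh * m
            dc_new = dh_new * o * (1.0 - tanh_c**2) + dc * m
            do = dh_new * tanh_c
            df = dc_new * c_prev
            di = dc_new * g
            dg = dc_new * i
            dgates = np.concatenate(
                [di * i * (1 - i), df * f * (1 - f), dg * (1 - g * g), do * o * (1 - o)],
                axis=1,
            )
            dWx += x.T @ dgates
            dWh += h_prev.T @ dgates
            db += dgates.sum(axis=0)
            np.add.at(demb, ids[:, t], dgates @ WxD.T)
            dh = dgates @ WhD.T + dh * (1.0 - m)
            dc = dc_new * f + dc * (1.0 - m)
        emb._accumulate(demb)
        Wx._accumulate(dWx)
        Wh._accumulate(dWh)
        b._accumulate(db)

    out._backward = backward
    return out


def _lstm_params(rng: np.random.Generator, input_dim: int, hidden_dim: int):
    b = np.zeros(4 * hidden_dim)
    b[hidden_dim : 2 * hidden_dim] = 1.0  # forget-gate bias: remember by default
    return {
        "Wx": parameter(rng, (input_dim, 4 * hidden_dim)),
        "Wh": parameter(rng, (hidden_dim, 4 * hidden_dim)),
        "b": Tensor(b, requires_grad=True),
    }


def _transpose(t: Tensor) -> Tensor:
    out = Tensor(t.data.T, parents=(t,))
    out._backward = lambda g: t._accumulate(g.T)
    return out


def _reverse_valid(ids: np.ndarray, lengths: np.ndarray) -> np.ndarray:
    """Reverse each row's first ``length`` entries; padding stays in place."""
    rev = ids.copy()
    for i, L in enumerate(lengths):
        rev[i, :L] = ids[i, :L][::-1]
    return rev


def make_batch(
    notes: Sequence[Note], vocabulary: Vocabulary, max_len: int
) -> tuple[np.ndarray, np.ndarray]:
    """Encode and right-pad a batch of notes; truncation drops the tail."""
    seqs = [vocabulary.encode(n.tokens[:max_len]) for n in notes]
    lengths = np.array([len(s) for s in seqs])
    if np.any(lengths == 0):
        raise ValueError("batch contains a note with no tokens")
    T = int(lengths.max())
    ids = np.full((len(seqs), T), vocabulary.pad_id, dtype=np.int64)
    for i, s in enumerate(seqs):
        ids[i, : len(s)] = s
    return ids, lengths


# -- losses ------------------------------------------------------------------


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def bce_loss(probs, labels) -> Tensor:
    """Mean binary cross-entropy over documents and codes, clamped at 1e-7."""
    labels = np.asarray(labels, dtype=float)
    if not np.isin(labels, (0.0, 1.0)).all():
        raise ValueError("labels must be binary")
    p = _as_tensor(probs).clip(EPS, 1.0 - EPS)
    return -(labels * p.log() + (1.0 - labels) * (1.0 - p).log()).mean()


def cluster_penalty(label_embeddings, ontology: CodeOntology, margin: float = 1.0) -> Tensor:
    """Hierarchical regularizer on the disease-code embedding rows.

    Mean squared distance over same-meta pairs (attraction) plus mean hinged
    squared margin violation max(0, m - ||e_i - e_j||)^2 over cross-meta
    pairs (repulsion): same-meta codes end up closer to each other than to
    codes of other meta-diseases.  Singleton metas contribute no attraction
    term.
    """
    groups = ontology.meta_groups()
    if len(groups) < 2:
        raise ValueError("cluster penalty needs at least 2 meta groups")
    E = _as_tensor(label_embeddings)
    group_of = np.empty(E.shape[0], dtype=int)
    for g, members in enumerate(groups):
        group_of[members] = g
    ii, jj = np.triu_indices(E.shape[0], k=1)
    same = group_of[ii] == group_of[jj]
    diff = gather_rows(E, ii) - gather_rows(E, jj)
    d2 = diff.square().sum(axis=1)
    if same.any():
        intra = d2[np.flatnonzero(same)].mean()
    else:
        intra = Tensor(0.0)
    d_inter = (d2[np.flatnonzero(~same)] + 1e-12).sqrt()
    inter = (margin - d_inter).relu().square().mean()
    return intra + inter


def meta_loss(probs, labels, ontology: CodeOntology) -> Tensor:
    """Noisy-OR meta-disease prediction loss.

    q_g = 1 - prod_{d in g} (1 - p_d); the meta label is the OR of member
    labels; returns the mean BCE over documents and meta groups.
    """
    p = _as_tensor(probs)
    labels = np.asarray(labels, dtype=float)
    terms = []
    meta_labels = []
    for members in ontology.meta_groups():
        if not members:
            raise ValueError("empty meta group")
        cols = np.asarray(members)
        comp = 1.0 - p[:, cols].clip(EPS, 1.0 - EPS)
        log_comp = comp.log().sum(axis=1)
        q = 1.0 - _exp(log_comp)
        terms.append(q.reshape(-1, 1))
        meta_labels.append(labels[:, cols].max(axis=1))
    q_all = concat(terms, axis=1)
    y_meta = np.stack(meta_labels, axis=1)
    return bce_loss(q_all, y_meta)


def _exp(t: Tensor) -> Tensor:
    e = np.exp(t.data)
    out = Tensor(e, parents=(t,))
    out._backward = lambda g: t._accumulate(g * e)
    return out


def total_loss(
    probs,
    labels,
    model: TaggerModel,
) -> Tensor:
    """L = BCE + lambda_cluster * cluster penalty + beta_meta * meta loss."""
    cfg = model.config
    loss = bce_loss(probs, labels)
    if cfg.lambda_cluster > 0:
        loss = loss + cfg.lambda_cluster * cluster_penalty(
            model.label_embeddings, model.ontology, cfg.cluster_margin
        )
    if cfg.beta_meta > 0:
        loss = loss + cfg.beta_meta * meta_loss(probs, labels, model.ontology)
    return loss


# -- training ----------------------------------------------------------------


@dataclass
class TrainLog:
    epoch_losses: list[float] = field(default_factory=list)
    val_weighted_f1: list[float] = field(default_factory=list)
    best_epoch: int = -1


def train(
    model: TaggerModel,
    train_notes: Sequence[Note],
    val_notes: Sequence[Note],
    verbose: bool = False,
) -> TrainLog:
    """Minibatch Adam on the total loss with early stopping.

    Early stopping monitors weighted F1 on the validation split; the returned
    model carries the best-validation checkpoint.  Fully deterministic given
    the config seed.  Aborts with a diagnostic on divergence (non-finite
    loss).
    """
    from .evaluation import evaluate  # local import: evaluation depends on model types

    cfg = model.config
    if not train_notes or not val_notes:
        raise ValueError("train and validation splits must be nonempty")
    rng = np.random.default_rng(cfg.seed + 1)
    opt = Adam(model.parameters(), lr=cfg.learning_rate)
    log = TrainLog()
    best_f1, best_state, patience_left = -1.0, None, cfg.patience
    for epoch in range(cfg.max_epochs):
        order = rng.permutation(len(train_notes))
        epoch_loss, n_batches = 0.0, 0
        for start in range(0, len(order), cfg.batch_size):
            batch = [train_notes[i] for i in order[start : start + cfg.batch_size]]
            ids, lengths = make_batch(batch, model.vocabulary, cfg.max_len)
            labels = np.stack([n.labels for n in batch]).astype(float)
            h = model.encode_batch(ids, lengths, training=True)
            probs = model.logits(h).sigmoid()
            loss = total_loss(probs, labels, model)
            if not np.isfinite(loss.data):
                raise RuntimeError(
                    f"training diverged: non-finite loss at epoch {epoch}, "
                    f"batch {n_batches} (lr={cfg.learning_rate})"
                )
            opt.zero_grad()
            loss.backward()
            opt.step()
            epoch_loss += float(loss.data)
            n_batches += 1
        log.epoch_losses.append(epoch_loss / n_batches)
        report = evaluate(model.predict_proba(val_notes),
                          np.stack([n.labels for n in val_notes]),
                          threshold=cfg.threshold)
        val_f1 = report.aggregates["weighted_f1"]
        log.val_weighted_f1.append(val_f1)
        if verbose:
            print(f"epoch {epoch}: loss={log.epoch_losses[-1]:.4f} val_wF1={val_f1:.4f}")
        if val_f1 > best_f1:
            best_f1, best_state = val_f1, model.state_dict()
            log.best_epoch = epoch
            patience_left = cfg.patience
        else:
            patience_left -= 1
            if patience_left <= 0:
                break
    if best_state is not None:
        model.load_state(best_state)
    return log
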