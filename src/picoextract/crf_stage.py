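"""Linear-chain CRF training and decoding.

The model assigns a label sequence Y to the sentence sequence X of an
abstract through

    P(Y | X) = exp( sum_t sum_k lambda_k f_k(y_{t-1}, y_t, x, t) ) / Z(X)

with binary observation features (the token bag of each sentence crossed
with its label) and label-bigram transition features.  Weights are estimated
by penalized maximum likelihood — the log-likelihood gradient comes from
forward–backward marginals and the Gaussian prior contributes -w^2/(2*sigma^2)
— and optimized with L-BFGS.  Decoding is Viterbi.

Two corpus-specific conventions live here rather than in a generic CRF:

* multi-label sentences are expanded into consecutive duplicate positions at
  training time, one per gold label (the standard training-file layout);
* at test time every sentence can be repeated ``reps`` times in sequence and
  the labels decoded for the copies are pooled into a per-sentence candidate
  set.  Transition context differs across copies (the first copy still sees
  the previous sentence, the last sees the next), which is what lets
  identical inputs receive different labels.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy import optimize, sparse
from scipy.special import logsumexp

from .corpus_io import AbstractRecord, LABELS, LabeledCorpus
from .features import FeatureVector


@dataclass
class CRFConfig:
    """Training-time knobs; defaults are the configuration that performed
    best in the model-setting experiments (prior variance 10, full training
    proportion, 3 test repetitions)."""

    gaussian_prior_variance: float = 10.0
    training_proportion: float = 1.0
    test_repetitions: int = 3
    max_iterations: int = 200
    tolerance: float = 1e-4
    random_seed: int = 0

    def validate(self) -> None:
        if self.gaussian_prior_variance <= 0:
            raise ValueError("gaussian_prior_variance must be positive")
        if not 0 < self.training_proportion <= 1:
            raise ValueError("training_proportion must be in (0, 1]")
        if self.test_repetitions < 1:
            raise ValueError("test_repetitions must be >= 1")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")


class LinearChainCRF:
    """Weights, alphabets and inference for a linear-chain CRF."""

    def __init__(self, labels: Sequence[str], feature_index: dict[str, int]):
        self.labels = list(labels)
        self.feature_index = feature_index
        n_feat, n_lab = len(feature_index), len(self.labels)
        self.state_weights = np.zeros((n_feat, n_lab))
        self.trans_weights = np.zeros((n_lab, n_lab))

    # -- encoding -----------------------------------------------------------

    def encode_tokens(self, token_bags: Sequence[Sequence[str]]) -> list[np.ndarray]:
        """Map token bags to known-feature index arrays (unknowns dropped)."""
        out = []
        for bag in token_bags:
            idx = {self.feature_index[t] for t in bag if t in self.feature_index}
            out.append(np.fromiter(sorted(idx), dtype=np.int64, count=len(idx)))
        return out

    def _emissions(self, encoded: Sequence[np.ndarray]) -> np.ndarray:
        em = np.zeros((len(encoded), len(self.labels)))
        for t, idx in enumerate(encoded):
            if idx.size:
                em[t] = self.state_weights[idx].sum(axis=0)
        return em

    # -- inference ----------------------------------------------------------

    def viterbi(self, encoded: Sequence[np.ndarray]) -> list[str]:
        em = self._emissions(encoded)
        T, L = em.shape
        if T == 0:
            return []
        delta = em[0].copy()
        back = np.zeros((T, L), dtype=np.int64)
        for t in range(1, T):
            scores = delta[:, None] + self.trans_weights  # prev x cur
            back[t] = scores.argmax(axis=0)
            delta = scores.max(axis=0) + em[t]
        path = [int(delta.argmax())]
        for t in range(T - 1, 0, -1):
            path.append(int(back[t, path[-1]]))
        path.reverse()
        return [self.labels[i] for i in path]

    def _forward_backward(self, em: np.ndarray):
        """Log alpha/beta and log partition for one sequence."""
        T, L = em.shape
        alpha = np.zeros((T, L))
        alpha[0] = em[0]
        for t in range(1, T):
            alpha[t] = em[t] + logsumexp(alpha[t - 1][:, None] + self.trans_weights, axis=0)
        beta = np.zeros((T, L))
        for t in range(T - 2, -1, -1):
            beta[t] = logsumexp(self.trans_weights + em[t + 1] + beta[t + 1], axis=1)
        log_z = logsumexp(alpha[-1])
        return alpha, beta, log_z

    # -- training -----------------------------------------------------------

    def fit(
        self,
        sequences: Sequence[Sequence[np.ndarray]],
        label_sequences: Sequence[Sequence[str]],
        variance: float = 10.0,
        max_iterations: int = 200,
        tolerance: float = 1e-4,
    ) -> dict:
        n_feat, n_lab = self.state_weights.shape
        label_idx = {lab: i for i, lab in enumerate(self.labels)}

        # Flatten positions; one global sparse design matrix for state feats.
        bounds = [0]
        rows, cols = [], []
        y_flat: list[int] = []
        for seq, labs in zip(sequences, label_sequences):
            for t, idx in enumerate(seq):
                pos = bounds[-1] + t
                rows.extend([pos] * idx.size)
                cols.extend(idx.tolist())
            y_flat.extend(label_idx[l] for l in labs)
            bounds.append(bounds[-1] + len(seq))
        n_pos = bounds[-1]
        X = sparse.csr_matrix(
            (np.ones(len(rows)), (rows, cols)), shape=(n_pos, n_feat)
        )
        y = np.asarray(y_flat, dtype=np.int64)
        y_onehot = np.zeros((n_pos, n_lab))
        y_onehot[np.arange(n_pos), y] = 1.0
        # Empirical transition counts are constant across iterations.
        emp_trans = np.zeros((n_lab, n_lab))
        for s, labs in enumerate(label_sequences):
            idxs = [label_idx[l] for l in labs]
            for a, b in zip(idxs[:-1], idxs[1:]):
                emp_trans[a, b] += 1.0

        n_state = n_feat * n_lab

        # Group sequences by length so forward-backward runs batched: one
        # recursion step per (length group, t) instead of per sequence.
        by_length: dict[int, list[int]] = {}
        for s, seq in enumerate(sequences):
            by_length.setdefault(len(seq), []).append(s)
        groups = []
        for T, members in sorted(by_length.items()):
            pos = np.concatenate(
                [np.arange(bounds[s], bounds[s + 1]) for s in members]
            )
            groups.append((T, np.asarray(members), pos))

        def _lse(m: np.ndarray, axis: int) -> np.ndarray:
            mx = m.max(axis=axis, keepdims=True)
            return (mx + np.log(np.exp(m - mx).sum(axis=axis, keepdims=True))).squeeze(axis)

        def objective(w: np.ndarray):
            self.state_weights = w[:n_state].reshape(n_feat, n_lab)
            self.trans_weights = w[n_state:].reshape(n_lab, n_lab)
            W = self.trans_weights
            em_all = np.asarray(X @ self.state_weights)
            gold_em = em_all[np.arange(n_pos), y].sum()
            gold_trans = float((emp_trans * W).sum())
            ll = gold_em + gold_trans
            marg = np.zeros_like(em_all)
            exp_trans = np.zeros((n_lab, n_lab))
            for T, members, pos in groups:
                em = em_all[pos].reshape(len(members), T, n_lab)
                alpha = np.zeros_like(em)
                alpha[:, 0] = em[:, 0]
                for t in range(1, T):
                    alpha[:, t] = em[:, t] + _lse(
                        alpha[:, t - 1][:, :, None] + W[None], axis=1
                    )
                beta = np.zeros_like(em)
                for t in range(T - 2, -1, -1):
                    beta[:, t] = _lse(
                        W[None] + (em[:, t + 1] + beta[:, t + 1])[:, None, :], axis=2
                    )
                log_z = _lse(alpha[:, -1], axis=1)  # (G,)
                ll -= float(log_z.sum())
                marg[pos] = np.exp(
                    alpha + beta - log_z[:, None, None]
                ).reshape(-1, n_lab)
                if T > 1:
                    pair = (
                        alpha[:, :-1, :, None]
                        + W[None, None]
                        + (em[:, 1:] + beta[:, 1:])[:, :, None, :]
                        - log_z[:, None, None, None]
                    )
                    exp_trans += np.exp(pair).sum(axis=(0, 1))
            grad_state = np.asarray((X.T @ (y_onehot - marg)))
            grad_trans = emp_trans - exp_trans
            ll -= float(w @ w) / (2.0 * variance)
            grad = np.concatenate([grad_state.ravel(), grad_trans.ravel()])
            grad -= w / variance
            return -ll, -grad

        w0 = np.zeros(n_state + n_lab * n_lab)
        result = optimize.minimize(
            objective,
            w0,
            jac=True,
            method="L-BFGS-B",
            options={"maxiter": max_iterations, "ftol": tolerance * 1e-3,
                     "gtol": tolerance},
        )
        self.state_weights = result.x[:n_state].reshape(n_feat, n_lab)
        self.trans_weights = result.x[n_state:].reshape(n_lab, n_lab)
        return {"converged": bool(result.success), "n_iter": int(result.nit),
                "neg_log_likelihood": float(result.fun)}


@dataclass
class TrainedModel:
    """Fitted CRF plus the configuration that produced it."""

    crf: LinearChainCRF
    config: CRFConfig
    fit_info: dict

    @property
    def label_set(self) -> list[str]:
        return list(self.crf.labels)


def _training_sequences(
    corpus: LabeledCorpus,
    vectors: Mapping[tuple[str, int], FeatureVector],
):
    """Token-bag and label sequences; multi-label sentences are expanded into
    consecutive duplicate positions, one per gold label."""
    token_seqs, label_seqs = [], []
    for abstract in corpus.abstracts:
        bags, labs = [], []
        for sent in abstract.sentences:
            vec = vectors[(abstract.abstract_id, sent.index)]
            if not sent.gold_labels:
                raise ValueError(
                    f"training sentence {sent.index} of {abstract.abstract_id!r} "
                    "has no gold label"
                )
            for label in sent.gold_labels:
                bags.append(vec.crf_tokens())
                labs.append(label)
        token_seqs.append(bags)
        label_seqs.append(labs)
    return token_seqs, label_seqs


def train(
    corpus: LabeledCorpus,
    vectors: Mapping[tuple[str, int], FeatureVector],
    config: CRFConfig | None = None,
) -> TrainedModel:
    """Fit the CRF on a labeled corpus (standard training layout)."""
    config = config or CRFConfig()
    config.validate()
    if not corpus.abstracts:
        raise ValueError("cannot train on an empty corpus")
    observed = {lab for s in corpus.sentences() for lab in s.gold_labels}
    if len(observed) < 2:
        raise ValueError(
            f"training corpus is degenerate: only labels {sorted(observed)}"
        )
    if config.training_proportion < 1.0:
        rng = np.random.default_rng(config.random_seed)
        n_keep = max(1, int(round(config.training_proportion * len(corpus))))
        keep = set(rng.choice(len(corpus), size=n_keep, replace=False).tolist())
        corpus = LabeledCorpus(
            abstracts=[a for i, a in enumerate(corpus.abstracts) if i in keep],
            provenance=corpus.provenance,
        )
    token_seqs, label_seqs = _training_sequences(corpus, vectors)
    alphabet: dict[str, int] = {}
    for bags in token_seqs:
        for bag in bags:
            for tok in bag:
                if tok not in alphabet:
                    alphabet[tok] = len(alphabet)
    crf = LinearChainCRF(LABELS, alphabet)
    encoded = [crf.encode_tokens(bags) for bags in token_seqs]
    info = crf.fit(
        encoded,
        label_seqs,
        variance=config.gaussian_prior_variance,
        max_iterations=config.max_iterations,
        tolerance=config.tolerance,
    )
    return TrainedModel(crf=crf, config=config, fit_info=info)


def predict_with_repetition(
    model: TrainedModel,
    abstract: AbstractRecord,
    vectors: Mapping[tuple[str, int], FeatureVector],
    reps: int | None = None,
) -> list[set[str]]:
    """Candidate label sets per sentence of one abstract.

    Each sentence is duplicated ``reps`` times consecutively before Viterbi
    decoding and the labels of its copies are pooled.  The plain (reps=1)
    decode is always included among the candidates, so repetition can only
    add alternatives; with reps=1 this is exactly plain decoding.
    """
    reps = model.config.test_repetitions if reps is None else reps
    if reps < 1:
        raise ValueError("reps must be >= 1")
    bags = [
        vectors[(abstract.abstract_id, s.index)].crf_tokens()
        for s in abstract.sentences
    ]
    if not bags:
        return []
    encoded = model.crf.encode_tokens(bags)
    plain = model.crf.viterbi(encoded)
    candidates = [{lab} for lab in plain]
    if reps > 1:
        repeated = [e for e in encoded for _ in range(reps)]
        decoded = model.crf.viterbi(repeated)
        for i in range(len(bags)):
            candidates[i].update(decoded[i * reps : (i + 1) * reps])
    return candidates


# ---------------------------------------------------------------------------
# Persistence: npz weights + JSON sidecar (versioned)
# ---------------------------------------------------------------------------

_FORMAT_VERSION = 1


def save_model(model: TrainedModel, path: str | Path) -> Path:
    path = Path(path)
    np.savez(
        path,
        state_weights=model.crf.state_weights,
        trans_weights=model.crf.trans_weights,
    )
    path = path if path.suffix == ".npz" else path.with_suffix(path.suffix + ".npz")
    sidecar = {
        "format_version": _FORMAT_VERSION,
        "labels": model.crf.labels,
        "feature_index": model.crf.feature_index,
        "config": asdict(model.config),
        "fit_info": model.fit_info,
    }
    path.with_suffix(".json").write_text(
        json.dumps(sidecar, indent=2), encoding="utf-8"
    )
    return path


def load_model(path: str | Path) -> TrainedModel:
    path = Path(path)
    if path.suffix != ".npz":
        path = path.with_suffix(path.suffix + ".npz")
    sidecar = json.loads(path.with_suffix(".json").read_text(encoding="utf-8"))
    if sidecar.get("format_version") != _FORMAT_VERSION:
        raise ValueError(f"unsupported model format {sidecar.get('format_version')}")
    crf = LinearChainCRF(sidecar["labels"], sidecar["feature_index"])
    arrays = np.load(path)
    crf.state_weights = arrays["state_weights"]
    crf.trans_weights = arrays["trans_weights"]
    return TrainedModel(
        crf=crf, config=CRFConfig(**sidecar["config"]), fit_info=sidecar["fit_info"]
    )
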