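"""Convolutional chromatin-accessibility model, SAD scores, mutagenesis.

A small multi-task convolutional sequence classifier in the Basset mold:
convolution layers (ReLU, max-pooling) act as learned motif detectors,
the flattened feature map feeds fully connected layers, and one sigmoid
output per peak set / timepoint predicts P(peak). Training is plain SGD
with momentum; the checkpoint with the best validation accuracy is kept.

Variant scoring is model-agnostic: any object exposing
``predict_proba(sequences) -> (n, tasks)`` works, so a PWM-logistic oracle
can stand in for the network in exact tests.

* SAD (SNP accessibility difference): per-task P(peak|alt) - P(peak|ref)
  for the two allele-carrying windows centered on the variant; positive
  values mean more predicted accessibility on the alternative allele.
* Saturated mutagenesis: the predicted accessibility change for every
  possible substitution at every window position; per position, the loss
  score is the largest possible decrease and the gain score the largest
  possible increase.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

import numpy as np

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}


def one_hot(seqs) -> np.ndarray:
    """(n, 4, L) one-hot; N (or any non-ACGT) becomes an all-zero column."""
    if isinstance(seqs, str):
        seqs = [seqs]
    n, L = len(seqs), len(seqs[0])
    out = np.zeros((n, 4, L), dtype=np.float64)
    for i, s in enumerate(seqs):
        if len(s) != L:
            raise ValueError("all sequences must share one width")
        for j, b in enumerate(s.upper()):
            k = _BASE_INDEX.get(b)
            if k is not None:
                out[i, k, j] = 1.0
    return out


@dataclass
class PeakSequenceDataset:
    """Fixed-width one-hot sequences with per-task binary labels and splits."""

    X: np.ndarray                 # (n, 4, width)
    Y: np.ndarray                 # (n, tasks) in {0,1}
    train_idx: np.ndarray
    val_idx: np.ndarray
    test_idx: np.ndarray
    width: int
    task_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        splits = [set(self.train_idx), set(self.val_idx), set(self.test_idx)]
        for a in range(3):
            for b in range(a + 1, 3):
                if splits[a] & splits[b]:
                    raise ValueError("train/val/test splits must be disjoint")
        if not set(np.unique(self.Y)) <= {0.0, 1.0}:
            raise ValueError("labels must be binary")


def dataset_from_sequences(seqs, labels, seed: int = 0,
                           task_names=None) -> PeakSequenceDataset:
    """Wrap raw sequences + labels with a deterministic 80/10/10 split."""
    X = one_hot(list(seqs))
    Y = np.atleast_2d(np.asarray(labels, dtype=float))
    if Y.shape[0] != X.shape[0]:
        Y = Y.T
    rng = np.random.default_rng(seed)
    order = rng.permutation(X.shape[0])
    n = X.shape[0]
    n_tr, n_va = int(0.8 * n), int(0.1 * n)
    return PeakSequenceDataset(
        X, Y, order[:n_tr], order[n_tr:n_tr + n_va], order[n_tr + n_va:],
        X.shape[2], list(task_names or [f"task{i}" for i in range(Y.shape[1])]))


def build_dataset(peak_beds: dict, genome_fasta, width: int = 200,
                  seed: int = 0) -> PeakSequenceDataset:
    """Labeled windows from per-task peak BEDs over a genome FASTA.

    Each peak's midpoint is extended to ``width``; a window is labeled 1
    for every task with a peak overlapping the window midpoint. Negatives
    are sampled uniformly from non-peak regions, 1:1 per task. Windows
    falling outside chromosome bounds are dropped with a warning.
    """
    import warnings

    from Bio import SeqIO

    genome = {rec.id: str(rec.seq).upper()
              for rec in SeqIO.parse(str(genome_fasta), "fasta")}
    tasks = list(peak_beds)
    peaks_by_task = {}
    for t in tasks:
        bed = peak_beds[t]
        if not hasattr(bed, "itertuples"):
            import pandas as pd
            bed = pd.read_csv(bed, sep="\t", header=None,
                              names=["chrom", "start", "end"],
                              usecols=[0, 1, 2])
        rows = list(bed.itertuples(index=False))
        if not rows:
            raise ValueError(f"zero peaks for task {t!r}")
        peaks_by_task[t] = [(r.chrom, int(r.start), int(r.end)) for r in rows]

    rng = np.random.default_rng(seed)
    seqs, labels = [], []
    covered = {c: np.zeros(len(s), dtype=bool) for c, s in genome.items()}
    for t in tasks:
        for c, s, e in peaks_by_task[t]:
            covered[c][s:e] = True

    def window_at(chrom: str, mid: int):
        s = mid - width // 2
        e = s + width
        if s < 0 or e > len(genome[chrom]):
            return None
        return genome[chrom][s:e], s, e

    n_dropped = 0
    for t in tasks:
        for chrom, s, e in peaks_by_task[t]:
            got = window_at(chrom, (s + e) // 2)
            if got is None:
                n_dropped += 1
                continue
            seq, ws, we = got
            mid = (ws + we) // 2
            lab = [any(ps <= mid < pe for pc, ps, pe in peaks_by_task[u]
                       if pc == chrom) for u in tasks]
            seqs.append(seq)
            labels.append([float(x) for x in lab])
        # 1:1 negatives per task from non-peak territory
        need = len(peaks_by_task[t])
        tries = 0
        while need > 0 and tries < 100 * len(peaks_by_task[t]):
            tries += 1
            chrom = list(genome)[int(rng.integers(len(genome)))]
            if len(genome[chrom]) <= width:
                continue
            mid = int(rng.integers(width // 2, len(genome[chrom]) - width // 2))
            ws, we = mid - width // 2, mid - width // 2 + width
            if covered[chrom][ws:we].any():
                continue
            seqs.append(genome[chrom][ws:we])
            labels.append([0.0] * len(tasks))
            need -= 1
    if n_dropped:
        warnings.warn(f"dropped {n_dropped} peak(s) outside genome bounds")
    return dataset_from_sequences(seqs, labels, seed=seed, task_names=tasks)


@dataclass
class ModelConfig:
    """Architecture and optimizer knobs for the accessibility classifier.

    The production-scale preset mirrors the published configuration (two
    conv layers of 512 and 128 filters, sizes 9 and 5, 0.1 conv dropout,
    width-1 pooling, two 128-unit hidden layers with 0.5 dropout, weight
    normalization, learning rate 0.01, momentum 0.97); the default here is
    a reduced desk-scale model with the same shape.
    """

    conv_filters: tuple[int, ...] = (32, 16)
    filter_sizes: tuple[int, ...] = (9, 5)
    conv_dropout: float = 0.1
    pool_widths: tuple[int, ...] = (1, 1)
    fc_units: tuple[int, ...] = (32,)
    fc_dropout: float = 0.25
    weight_norm: bool = False   # unstable with momentum 0.97 at desk scale
    learning_rate: float = 0.01
    momentum: float = 0.97
    max_epochs: int = 25
    batch_size: int = 64
    seed: int = 0

    def __post_init__(self) -> None:
        if not (len(self.conv_filters) == len(self.filter_sizes)
                == len(self.pool_widths)):
            raise ValueError("conv spec lists must share one length")
        for d in (self.conv_dropout, self.fc_dropout):
            if not 0 <= d < 1:
                raise ValueError("dropout must lie in [0, 1)")


def full_scale_preset(**overrides) -> ModelConfig:
    """The published full-scale architecture (slow on one CPU)."""
    cfg = dict(conv_filters=(512, 128), filter_sizes=(9, 5),
               conv_dropout=0.1, pool_widths=(1, 1), fc_units=(128, 128),
               fc_dropout=0.5, weight_norm=True, learning_rate=0.01,
               momentum=0.97)
    cfg.update(overrides)
    return ModelConfig(**cfg)


def _im2col(x: np.ndarray, k: int) -> np.ndarray:
    # x: (n, C, L) -> (n, L-k+1, C*k)
    v = np.lib.stride_tricks.sliding_window_view(x, k, axis=2)
    return v.transpose(0, 2, 1, 3).reshape(x.shape[0], x.shape[2] - k + 1, -1)


def _wn_forward(V: np.ndarray, g: np.ndarray) -> np.ndarray:
    norm = np.linalg.norm(V, axis=1, keepdims=True)
    return g[:, None] * V / norm


def _wn_backward(V, g, dW):
    norm = np.linalg.norm(V, axis=1, keepdims=True)
    vhat = V / norm
    dg = (dW * vhat).sum(axis=1)
    dV = (g[:, None] / norm) * (dW - (dW * vhat).sum(axis=1, keepdims=True) * vhat)
    return dV, dg


class AccessibilityModel:
    """Multi-task convolutional peak classifier (numpy, CPU).

    Conv layers use valid convolution + ReLU + non-overlapping max-pooling;
    the final conv output is flattened into the fully connected stack and a
    sigmoid head, one unit per task. With ``weight_norm`` each weight
    matrix is reparameterized as W = g * V / ||V|| per output row.
    """

    def __init__(self, config: ModelConfig, n_tasks: int, width: int):
        self.config = config
        self.n_tasks = n_tasks
        self.width = width
        rng = np.random.default_rng(config.seed)
        self.params: dict[str, np.ndarray] = {}
        c_in, L = 4, width
        for i, (f, k, p) in enumerate(zip(config.conv_filters,
                                          config.filter_sizes,
                                          config.pool_widths)):
            fan_in = c_in * k
            self.params[f"Vc{i}"] = rng.normal(0, np.sqrt(2 / fan_in), (f, fan_in))
            self.params[f"gc{i}"] = np.linalg.norm(self.params[f"Vc{i}"], axis=1)
            self.params[f"bc{i}"] = np.zeros(f)
            c_in, L = f, (L - k + 1) // p
            if L < 1:
                raise ValueError("window too short for the conv stack")
        d = c_in * L  # flattened conv output
        for j, u in enumerate(config.fc_units):
            self.params[f"Vf{j}"] = rng.normal(0, np.sqrt(2 / d), (u, d))
            self.params[f"gf{j}"] = np.linalg.norm(self.params[f"Vf{j}"], axis=1)
            self.params[f"bf{j}"] = np.zeros(u)
            d = u
        self.params["Vo"] = rng.normal(0, np.sqrt(1 / d), (n_tasks, d))
        self.params["go"] = np.linalg.norm(self.params["Vo"], axis=1)
        self.params["bo"] = np.zeros(n_tasks)
        self.history: list[dict] = []

    # --- forward -----------------------------------------------------------

    def _weight(self, tag: str) -> np.ndarray:
        V, g = self.params[f"V{tag}"], self.params[f"g{tag}"]
        return _wn_forward(V, g) if self.config.weight_norm else V

    def _forward(self, X: np.ndarray, train: bool = False,
                 rng: np.random.Generator | None = None):
        cfg = self.config
        cache = {"X": X, "drop": {}}
        a = X
        for i, (k, p) in enumerate(zip(cfg.filter_sizes, cfg.pool_widths)):
            col = _im2col(a, k)                       # (n, L', C*k)
            W = self._weight(f"c{i}")
            z = col @ W.T + self.params[f"bc{i}"]     # (n, L', F)
            r = np.maximum(z, 0.0)
            if train and cfg.conv_dropout > 0:
                mask = (rng.random(r.shape) >= cfg.conv_dropout) / (1 - cfg.conv_dropout)
                cache["drop"][f"c{i}"] = mask
                r = r * mask
            if p > 1:
                Lp = r.shape[1] // p
                rp = r[:, :Lp * p].reshape(r.shape[0], Lp, p, -1)
                arg = rp.argmax(axis=2)
                r_out = np.take_along_axis(rp, arg[:, :, None, :], axis=2)[:, :, 0, :]
                cache[f"poolarg{i}"] = (arg, r.shape)
                r = r_out
            cache[f"col{i}"], cache[f"z{i}"], cache[f"a{i}"] = col, z, r
            a = r.transpose(0, 2, 1)                  # (n, F, L'')
        # flatten conv output into the FC stack
        cache["gshape"] = a.shape
        h = a.reshape(a.shape[0], -1)
        cache["h-1"] = h
        for j in range(len(cfg.fc_units)):
            W = self._weight(f"f{j}")
            z = h @ W.T + self.params[f"bf{j}"]
            h2 = np.maximum(z, 0.0)
            if train and cfg.fc_dropout > 0:
                mask = (rng.random(h2.shape) >= cfg.fc_dropout) / (1 - cfg.fc_dropout)
                cache["drop"][f"f{j}"] = mask
                h2 = h2 * mask
            cache[f"zf{j}"], cache[f"h{j}"] = z, h2
            h = h2
        logits = h @ self._weight("o").T + self.params["bo"]
        prob = 1.0 / (1.0 + np.exp(-logits))
        cache["logits"], cache["prob"] = logits, prob
        return prob, cache

    def predict_proba(self, seqs) -> np.ndarray:
        """P(peak) per task; accepts sequences or a (n,4,L) one-hot array."""
        X = seqs if isinstance(seqs, np.ndarray) else one_hot(seqs)
        prob, _ = self._forward(X, train=False)
        return prob

    def predict_logits(self, seqs) -> np.ndarray:
        """Pre-sigmoid activations; lets variant scoring subtract
        probabilities without float saturation at 0/1."""
        X = seqs if isinstance(seqs, np.ndarray) else one_hot(seqs)
        _, cache = self._forward(X, train=False)
        return cache["logits"]

    # --- backward / training ----------------------------------------------

    def _backward(self, cache, Y: np.ndarray) -> dict[str, np.ndarray]:
        cfg = self.config
        n = Y.shape[0]
        grads: dict[str, np.ndarray] = {}

        def store(tag, dW, db):
            if cfg.weight_norm:
                dV, dg = _wn_backward(self.params[f"V{tag}"],
                                      self.params[f"g{tag}"], dW)
                grads[f"V{tag}"], grads[f"g{tag}"] = dV, dg
            else:
                grads[f"V{tag}"] = dW
            grads[f"b{tag}"] = db

        dlogits = (cache["prob"] - Y) / (n * Y.shape[1])
        h_last = cache[f"h{len(cfg.fc_units) - 1}"] if cfg.fc_units else cache["h-1"]
        store("o", dlogits.T @ h_last, dlogits.sum(axis=0))
        dh = dlogits @ self._weight("o")
        for j in range(len(cfg.fc_units) - 1, -1, -1):
            if f"f{j}" in cache["drop"]:
                dh = dh * cache["drop"][f"f{j}"]
            dz = dh * (cache[f"zf{j}"] > 0)
            h_prev = cache[f"h{j - 1}"]
            store(f"f{j}", dz.T @ h_prev, dz.sum(axis=0))
            dh = dz @ self._weight(f"f{j}")
        # unflatten into the last conv layer's output shape
        da = dh.reshape(cache["gshape"]).transpose(0, 2, 1)   # (n, L'', F)
        for i in range(len(cfg.conv_filters) - 1, -1, -1):
            p = cfg.pool_widths[i]
            if p > 1:
                arg, full_shape = cache[f"poolarg{i}"]
                Lp = arg.shape[1]
                dr = np.zeros((da.shape[0], Lp, p, da.shape[2]))
                np.put_along_axis(dr, arg[:, :, None, :], da[:, :, None, :], axis=2)
                dr_full = np.zeros(full_shape)
                dr_full[:, :Lp * p] = dr.reshape(da.shape[0], Lp * p, -1)
                da = dr_full
            if f"c{i}" in cache["drop"]:
                da = da * cache["drop"][f"c{i}"]
            dz = da * (cache[f"z{i}"] > 0)            # (n, L', F)
            col = cache[f"col{i}"]
            dW = np.einsum("nlf,nlc->fc", dz, col)
            store(f"c{i}", dW, dz.sum(axis=(0, 1)))
            if i > 0:
                dcol = dz @ self._weight(f"c{i}")     # (n, L', C*k)
                k = cfg.filter_sizes[i]
                C = self.config.conv_filters[i - 1]
                prev_len = cache[f"a{i - 1}"].shape[1]
                da_prev = np.zeros((dz.shape[0], prev_len, C))
                dcol = dcol.reshape(dz.shape[0], dz.shape[1], C, k)
                for off in range(k):
                    da_prev[:, off:off + dz.shape[1]] += dcol[:, :, :, off]
                da = da_prev
        return grads

    def fit(self, dataset: PeakSequenceDataset, verbose: bool = False):
        """SGD with momentum; keeps the best-validation-accuracy weights."""
        cfg = self.config
        rng = np.random.default_rng(cfg.seed + 1)
        vel = {k: np.zeros_like(v) for k, v in self.params.items()}
        Xtr, Ytr = dataset.X[dataset.train_idx], dataset.Y[dataset.train_idx]
        Xva, Yva = dataset.X[dataset.val_idx], dataset.Y[dataset.val_idx]
        for t in range(Ytr.shape[1]):
            if len(np.unique(Ytr[:, t])) < 2:
                raise ValueError(f"task {t} has a single class in training split")
        best_acc, best_params = -1.0, None
        for epoch in range(cfg.max_epochs):
            order = rng.permutation(len(Xtr))
            losses = []
            for s in range(0, len(order), cfg.batch_size):
                idx = order[s:s + cfg.batch_size]
                prob, cache = self._forward(Xtr[idx], train=True, rng=rng)
                eps = 1e-12
                loss = -np.mean(Ytr[idx] * np.log(prob + eps)
                                + (1 - Ytr[idx]) * np.log(1 - prob + eps))
                if not np.isfinite(loss):
                    raise FloatingPointError(
                        f"non-finite training loss at epoch {epoch}")
                losses.append(loss)
                grads = self._backward(cache, Ytr[idx])
                for k, gr in grads.items():
                    vel[k] = cfg.momentum * vel[k] - cfg.learning_rate * gr
                    self.params[k] = self.params[k] + vel[k]
            val_prob = self.predict_proba(Xva)
            val_acc = float(((val_prob >= 0.5) == (Yva >= 0.5)).mean())
            self.history.append({"epoch": epoch,
                                 "train_loss": float(np.mean(losses)),
                                 "val_accuracy": val_acc})
            if verbose:
                print(f"epoch {epoch}: loss {np.mean(losses):.4f} "
                      f"val_acc {val_acc:.4f}")
            if val_acc > best_acc:
                best_acc = val_acc
                best_params = {k: v.copy() for k, v in self.params.items()}
        if best_params is not None:
            self.params = best_params
        return self

    def weights_hash(self) -> str:
        h = hashlib.sha256()
        for k in sorted(self.params):
            h.update(k.encode())
            h.update(np.ascontiguousarray(self.params[k]).tobytes())
        return h.hexdigest()

    # --- persistence -------------------------------------------------------

    def save(self, prefix) -> None:
        np.savez(str(prefix) + ".npz", **self.params)
        sidecar = {"config": self.config.__dict__, "n_tasks": self.n_tasks,
                   "width": self.width, "history": self.history}
        with open(str(prefix) + ".json", "w") as fh:
            json.dump(sidecar, fh, indent=1, default=list)

    @classmethod
    def load(cls, prefix) -> "AccessibilityModel":
        with open(str(prefix) + ".json") as fh:
            side = json.load(fh)
        raw = side["config"]
        for k in ("conv_filters", "filter_sizes", "pool_widths", "fc_units"):
            raw[k] = tuple(raw[k])
        model = cls(ModelConfig(**raw), side["n_tasks"], side["width"])
        with np.load(str(prefix) + ".npz") as npz:
            model.params = {k: npz[k] for k in npz.files}
        model.history = side["history"]
        return model


def train(dataset: PeakSequenceDataset, config: ModelConfig,
          verbose: bool = False) -> AccessibilityModel:
    """Convenience wrapper: build the model for the dataset shape and fit."""
    model = AccessibilityModel(config, dataset.Y.shape[1], dataset.width)
    return model.fit(dataset, verbose=verbose)


# ---------------------------------------------------------------------------
# variant scoring (model-agnostic: anything with predict_proba works)
# ---------------------------------------------------------------------------

@dataclass
class SadScore:
    """Per-task accessibility difference alt - ref and its summary."""

    per_task: np.ndarray
    summary: float               # max-magnitude task value (sign kept)


def sigmoid_difference(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """sigmoid(a) - sigmoid(b) without catastrophic saturation.

    Near-certain predictions round both probabilities to exactly 1.0 (or
    0.0) in float64, hiding small allele effects; rewriting the difference
    in terms of exp(-|x|) keeps its sign and magnitude."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    # sigmoid(a)-sigmoid(b) == (e^-b - e^-a) / ((1+e^-a)(1+e^-b))
    #                       == (e^a - e^b)   / ((1+e^a)(1+e^b))
    with np.errstate(over="ignore"):
        upper = (np.exp(-b) - np.exp(-a)) / ((1 + np.exp(-a)) * (1 + np.exp(-b)))
        lower = (np.exp(a) - np.exp(b)) / ((1 + np.exp(a)) * (1 + np.exp(b)))
    both_pos = np.minimum(a, b) >= 0
    both_neg = np.maximum(a, b) <= 0
    plain = 1 / (1 + np.exp(-a)) - 1 / (1 + np.exp(-b))
    return np.where(both_pos, upper, np.where(both_neg, lower, plain))


def _prob_difference(model, win_a: str, win_b: str) -> np.ndarray:
    """Per-task P(peak|win_a) - P(peak|win_b), logit-stable if possible."""
    if hasattr(model, "predict_logits"):
        lg = model.predict_logits([win_a, win_b])
        return sigmoid_difference(lg[0], lg[1])
    prob = model.predict_proba([win_a, win_b])
    return prob[0] - prob[1]


def sad(model, ref_window: str, alt_window: str) -> SadScore:
    """SNP accessibility difference between allele-carrying windows."""
    if len(ref_window) != len(alt_window):
        raise ValueError("ref and alt windows must share one width")
    diff = _prob_difference(model, alt_window, ref_window)
    return SadScore(diff, float(diff[np.abs(diff).argmax()]))


@dataclass
class MutagenesisMatrix:
    """4 x width predicted accessibility changes plus loss/gain profiles."""

    matrix: np.ndarray           # (4, width); reference-base cells are 0
    loss: np.ndarray             # per position, largest decrease (<= 0)
    gain: np.ndarray             # per position, largest increase (>= 0)
    task: int


def saturated_mutagenesis(model, window: str, task: int | None = None,
                          ) -> MutagenesisMatrix:
    """Predicted accessibility change for every substitution in the window.

    ``task`` selects the output column; by default the task with the
    highest reference-window probability (the most accessible condition).
    """
    width = len(window)
    if getattr(model, "width", width) != width:
        raise ValueError(f"window width {width} != model input width "
                         f"{model.width}")
    ref_prob = model.predict_proba([window])[0]
    if task is None:
        task = int(np.argmax(ref_prob))
    mutants, where = [], []
    for j, refb in enumerate(window.upper()):
        for b in "ACGT":
            if b == refb:
                continue
            mutants.append(window[:j] + b + window[j + 1:])
            where.append((_BASE_INDEX[b], j))
    mat = np.zeros((4, width))
    if hasattr(model, "predict_logits"):
        ref_logit = model.predict_logits([window])[0, task]
        logits = model.predict_logits(mutants)[:, task]
        deltas = sigmoid_difference(logits, np.full_like(logits, ref_logit))
    else:
        deltas = model.predict_proba(mutants)[:, task] - ref_prob[task]
    for (bi, j), d in zip(where, deltas):
        mat[bi, j] = d
    loss = np.minimum(mat.min(axis=0), 0.0)
    gain = np.maximum(mat.max(axis=0), 0.0)
    return MutagenesisMatrix(mat, loss, gain, task)


def empirical_percentile(sad_summary: float, background_sads,
                         ) -> tuple[float, float]:
    """Percentile of |SAD| among background |SAD|s and its add-one p-value."""
    bg = np.abs(np.asarray(list(background_sads), dtype=float))
    if bg.size == 0:
        raise ValueError("background must be non-empty")
    obs = abs(float(sad_summary))
    percentile = float((bg < obs).mean() * 100.0)
    p = float((1 + int((bg >= obs).sum())) / (bg.size + 1))
    return percentile, p
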