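"""Biological interpretability: motifs from convolution kernels and from
TF-conditioned integrated-gradients attributions.

Two routes from a trained model back to sequence motifs:

* **Kernel motifs** — each first-layer convolution filter is turned into a
  PWM either by a per-column softmax of its weights, or (default for MEME
  export, in the DeepBind tradition) by scanning sequences and counting the
  bases of subsequences whose activation clears a fraction of the global
  maximum.
* **Attribution motifs** — integrated gradients of one output logit with
  respect to the one-hot input, conditioned on the corresponding TF
  embedding, are distilled into a PWM by pooling the highest-attribution
  windows across positive sequences.

Both paths emit :class:`~transbind.pwm.PositionWeightMatrix` objects, so
either can be serialized to MEME minimal format for downstream database
comparison (e.g. TOMTOM against JASPAR).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn import Tensor
from .pwm import ALPHABET, PositionWeightMatrix
from .pipeline import one_hot

__all__ = [
    "AttributionMap",
    "kernel_to_pwm_weights",
    "kernel_to_pwm_activations",
    "integrated_gradients",
    "attribution_to_pwm",
    "kernels_to_meme",
]


@dataclass
class AttributionMap:
    """Signed per-position, per-base attributions plus the completeness gap
    |sum(attributions) - (F(x) - F(baseline))|."""

    matrix: np.ndarray  # (L, 4)
    convergence_gap: float
    output_delta: float  # F(x) - F(baseline)

    @property
    def observed_base_scores(self) -> np.ndarray:
        """Per-position attribution of the base actually present (assumes
        the map was computed on a one-hot input)."""
        return self.matrix.sum(axis=1)


def kernel_to_pwm_weights(kernel: np.ndarray,
                          name: str = "kernel") -> PositionWeightMatrix:
    """Per-column softmax (temperature 1) of a 4 x k (or k x 4) kernel."""
    kernel = np.asarray(kernel, dtype=float)
    if kernel.ndim != 2 or 4 not in kernel.shape:
        raise ValueError("kernel must be 4 x k or k x 4")
    if kernel.shape[0] == 4 and kernel.shape[1] != 4:
        kernel = kernel.T  # -> (k, 4)
    shifted = kernel - kernel.max(axis=1, keepdims=True)
    e = np.exp(shifted)
    probs = e / e.sum(axis=1, keepdims=True)
    return PositionWeightMatrix(name, probs)


def _kernel_activations(kernel_kx4: np.ndarray, onehot: np.ndarray) -> np.ndarray:
    """(N, L-k+1) activations of one kernel over one-hot sequences."""
    k = kernel_kx4.shape[0]
    windows = np.lib.stride_tricks.sliding_window_view(onehot, k, axis=1)
    # windows: (N, L-k+1, 4, k); kernel: (k, 4)
    return np.einsum("nwbk,kb->nw", windows, kernel_kx4)


def kernel_to_pwm_activations(
    kernel: np.ndarray,
    sequences: list[str] | np.ndarray,
    frac_of_max: float = 0.5,
    name: str = "kernel",
) -> PositionWeightMatrix:
    """Count-based motif: scan sequences with the kernel and build a PFM
    from every k-long subsequence activating at >= frac_of_max of the
    global maximum activation."""
    kernel = np.asarray(kernel, dtype=float)
    if kernel.shape[0] == 4 and kernel.shape[1] != 4:
        kernel = kernel.T
    k = kernel.shape[0]
    if isinstance(sequences, np.ndarray):
        oh = np.asarray(sequences, dtype=float)
        seq_idx = oh.argmax(axis=2)
    else:
        oh = np.stack([one_hot(s) for s in sequences]).astype(float)
        seq_idx = oh.argmax(axis=2)
    if oh.shape[1] < k:
        raise ValueError("sequences shorter than the kernel")
    acts = _kernel_activations(kernel, oh)
    threshold = frac_of_max * acts.max()
    hits = np.argwhere(acts >= threshold)
    if hits.size == 0:
        raise ValueError("no subsequence reaches the activation threshold")
    counts = np.zeros((k, 4))
    for n, pos in hits:
        sub = seq_idx[n, pos : pos + k]
        counts[np.arange(k), sub] += 1
    return PositionWeightMatrix.from_counts(name, counts)


def kernels_to_meme(model, sequences, frac_of_max: float = 0.5,
                    background: np.ndarray | None = None) -> str:
    """All first-layer kernels of a model -> MEME text via the activation
    route; kernels with no qualifying sites fall back to weight-softmax."""
    from .pwm import write_meme

    weights = model.core.encoder.conv.weight.data  # (F, k, 4)
    pwms = []
    for f in range(weights.shape[0]):
        try:
            pwm = kernel_to_pwm_activations(weights[f], sequences,
                                            frac_of_max, name=f"kernel_{f}")
        except ValueError:
            pwm = kernel_to_pwm_weights(weights[f], name=f"kernel_{f}")
        pwms.append(pwm)
    return write_meme(pwms, background)


def integrated_gradients(
    forward,
    x: np.ndarray,
    baseline: np.ndarray | None = None,
    steps: int = 128,
) -> AttributionMap:
    """Integrated gradients of a scalar model output w.r.t. the input.

    `forward(tensor)` must map an (L, 4) input Tensor (with gradients) to a
    scalar Tensor — e.g. one logit of the multilabel model, conditioning on
    that label's TF embedding, or the pairwise model's logit for a chosen
    TF. Attribution = (x - baseline) * mean over the straight-line path of
    the gradient, evaluated at midpoint Riemann nodes; the completeness gap
    is reported, never hidden.
    """
    if steps < 1:
        raise ValueError("steps must be >= 1")
    x = np.asarray(x, dtype=float)
    base = np.zeros_like(x) if baseline is None else np.asarray(baseline, float)
    if base.shape != x.shape:
        raise ValueError("baseline shape must match input")
    diff = x - base
    grad_sum = np.zeros_like(x)
    for i in range(steps):
        alpha = (i + 0.5) / steps
        point = Tensor(base + alpha * diff, requires_grad=True)
        out = forward(point)
        out.backward()
        grad_sum += point.grad
    attributions = diff * grad_sum / steps
    fx = forward(Tensor(x)).item()
    fb = forward(Tensor(base)).item()
    delta = fx - fb
    gap = abs(attributions.sum() - delta)
    return AttributionMap(attributions, float(gap), float(delta))


def integrated_gradients_batch(
    forward_batch,
    X: np.ndarray,
    baseline: np.ndarray | None = None,
    steps: int = 128,
) -> list[AttributionMap]:
    """Integrated gradients for many inputs sharing one scalar output head.

    `forward_batch(tensor)` maps a (B, L, 4) Tensor to a (B,) Tensor of
    per-sample outputs. Because samples are independent, the gradient of
    the summed output w.r.t. the batch input is the stack of per-sample
    gradients, so each path step costs one forward/backward for the whole
    batch.
    """
    if steps < 1:
        raise ValueError("steps must be >= 1")
    X = np.asarray(X, dtype=float)
    base = np.zeros_like(X) if baseline is None else np.asarray(baseline, float)
    if base.shape != X.shape:
        raise ValueError("baseline shape must match input batch")
    diff = X - base
    grad_sum = np.zeros_like(X)
    for i in range(steps):
        alpha = (i + 0.5) / steps
        point = Tensor(base + alpha * diff, requires_grad=True)
        out = forward_batch(point).sum()
        out.backward()
        grad_sum += point.grad
    attributions = diff * grad_sum / steps
    fx = forward_batch(Tensor(X)).data
    fb = forward_batch(Tensor(base)).data
    maps = []
    for b in range(len(X)):
        delta = float(fx[b] - fb[b])
        gap = abs(attributions[b].sum() - delta)
        maps.append(AttributionMap(attributions[b], float(gap), delta))
    return maps


def multilabel_logit_fn(model, label_index: int):
    """Closure exposing logit `label_index` of the multilabel model as a
    scalar function of a single (L, 4) input."""

    def forward(x: Tensor) -> Tensor:
        logits = model(x.reshape(1, *x.shape))
        return logits[0, label_index]

    return forward


def pairwise_logit_fn(model, embedding: np.ndarray):
    """Closure exposing the pairwise model's logit for one TF embedding."""
    emb = np.asarray(embedding, dtype=float)[None, :]

    def forward(x: Tensor) -> Tensor:
        return model(x.reshape(1, *x.shape), emb)[0]

    return forward


_RC = str.maketrans("ACGT", "TGCA")


def _orient_subseqs(subseqs: list[str], iters: int = 4) -> list[str]:
    """Strand disambiguation for motif building: binding evidence sits on
    either strand, so each window is flipped to whichever orientation the
    current consensus model likes better (a few deterministic EM rounds,
    forward preferred on ties). The consensus is seeded from the first
    window alone, which breaks the symmetry of an exact strand mixture."""
    w = len(subseqs[0])

    def counts_of(seqs):
        c = np.full((w, 4), 0.5)  # pseudocount
        for s in seqs:
            for i, ch in enumerate(s):
                c[i, ALPHABET.index(ch)] += 1
        return c

    model = counts_of(subseqs[:1])
    cur = list(subseqs)
    for _ in range(iters):
        logp = np.log(model / model.sum(axis=1, keepdims=True))

        def loglik(s):
            return sum(logp[i, ALPHABET.index(c)] for i, c in enumerate(s))

        new = []
        for orig in subseqs:
            rc = orig.translate(_RC)[::-1]
            new.append(rc if loglik(rc) > loglik(orig) else orig)
        if new == cur:
            break
        cur = new
        model = counts_of(cur)
    return cur


def attribution_to_pwm(
    maps: list[AttributionMap],
    sequences: list[str],
    window_width: int = 8,
    top_frac: float = 0.25,
    name: str = "attribution_motif",
    orient: bool = True,
) -> PositionWeightMatrix:
    """Distill attribution maps into a PWM from high-attribution windows.

    For each sequence, positive attributions of the observed base are summed
    in every sliding window of `window_width`; each sequence contributes its
    best window, and windows scoring in the top `top_frac` quantile across
    sequences are stacked (aligned by window start) into a position
    frequency matrix.
    """
    if not maps:
        raise ValueError("need at least one attribution map")
    if window_width < 1:
        raise ValueError("window_width must be >= 1")
    if not 0.0 < top_frac <= 1.0:
        raise ValueError("top_frac must lie in (0, 1]")
    if len(maps) != len(sequences):
        raise ValueError("one sequence per attribution map required")
    best = []
    for amap, seq in zip(maps, sequences):
        pos_scores = np.clip(amap.observed_base_scores, 0.0, None)
        if len(pos_scores) < window_width:
            raise ValueError("sequence shorter than window_width")
        window_sums = np.convolve(pos_scores, np.ones(window_width),
                                  mode="valid")
        j = int(window_sums.argmax())
        best.append((float(window_sums[j]), seq[j : j + window_width]))
    scores = np.array([s for s, _ in best])
    cutoff = np.quantile(scores, 1.0 - top_frac)
    chosen = [sub.upper() for s, sub in best if s >= cutoff]
    if not chosen:
        raise ValueError("no windows selected")
    if orient and len(chosen) > 1:
        chosen = _orient_subseqs(chosen)
    counts = np.zeros((window_width, 4))
    for sub in chosen:
        for i, c in enumerate(sub.upper()):
            counts[i, ALPHABET.index(c)] += 1
    return PositionWeightMatrix.from_counts(name, counts)
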