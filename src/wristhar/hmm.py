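"""Discrete-observation hidden Markov model with scaled recursions.

The sequence model used to smooth the window classifier's label stream:
hidden states are the true activities, observations are discrete symbols
(by default the classifier's predicted labels, so M = N = 4). Provides

* scaled forward/backward recursions (:func:`forward`, :func:`backward`)
  with the per-step normalization of Rabiner's classic tutorial, so
  likelihoods of long sequences never underflow;
* state posteriors gamma and pairwise posteriors xi (:func:`posteriors`);
* maximum-probability path decoding in log space (:func:`viterbi`);
* unsupervised parameter estimation by Baum-Welch EM
  (:func:`baum_welch`) and the supervised counting estimators used by the
  default pipeline (:func:`estimate_supervised`,
  :func:`emission_from_confusion`).

An observation sequence that is impossible under the model is a value,
not an error: the result carries ``log_likelihood = -inf`` and an
``impossible`` flag so callers can fall back gracefully.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = [
    "HmmParams",
    "ForwardBackwardResult",
    "forward",
    "backward",
    "posteriors",
    "viterbi",
    "baum_welch",
    "estimate_supervised",
    "emission_from_confusion",
    "random_params",
]

FORMAT_VERSION = 1
_STOCH_TOL = 1e-9


@dataclass
class HmmParams:
    """Initial distribution pi, transitions A and emissions B.

    ``A[i, j] = P(next = j | current = i)`` and
    ``B[i, o] = P(observe o | state i)``; pi and every row of A and B must
    be probability vectors.
    """

    pi: np.ndarray
    A: np.ndarray
    B: np.ndarray

    def __post_init__(self) -> None:
        self.pi = np.asarray(self.pi, dtype=float)
        self.A = np.asarray(self.A, dtype=float)
        self.B = np.asarray(self.B, dtype=float)
        n = self.pi.shape[0]
        if self.pi.ndim != 1 or n < 1:
            raise ValueError("pi must be a nonempty 1-D probability vector")
        if self.A.shape != (n, n):
            raise ValueError(f"A must be {n}x{n}, got {self.A.shape}")
        if self.B.ndim != 2 or self.B.shape[0] != n or self.B.shape[1] < 1:
            raise ValueError(f"B must have {n} rows, got shape {self.B.shape}")
        for name, arr in (("pi", self.pi), ("A", self.A), ("B", self.B)):
            if np.any(arr < -_STOCH_TOL) or np.any(arr > 1 + _STOCH_TOL):
                raise ValueError(f"{name} entries must lie in [0, 1]")
        if abs(self.pi.sum() - 1.0) > _STOCH_TOL:
            raise ValueError("pi must sum to 1")
        for name, arr in (("A", self.A), ("B", self.B)):
            if np.any(np.abs(arr.sum(axis=1) - 1.0) > _STOCH_TOL):
                raise ValueError(f"every row of {name} must sum to 1")

    @property
    def n_states(self) -> int:
        return self.pi.shape[0]

    @property
    def n_symbols(self) -> int:
        return self.B.shape[1]

    def to_dict(self) -> dict:
        return {
            "format_version": FORMAT_VERSION,
            "pi": self.pi.tolist(),
            "A": self.A.tolist(),
            "B": self.B.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "HmmParams":
        if d.get("format_version") != FORMAT_VERSION:
            raise ValueError(
                f"unsupported HMM format version {d.get('format_version')!r}"
            )
        return cls(np.asarray(d["pi"]), np.asarray(d["A"]), np.asarray(d["B"]))

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict()))

    @classmethod
    def load(cls, path: str | Path) -> "HmmParams":
        return cls.from_dict(json.loads(Path(path).read_text()))


@dataclass
class ForwardBackwardResult:
    """Scaled forward/backward quantities for one observation sequence.

    ``alpha[t, i]`` is the filtered state posterior
    ``P(q_t = i | o_1..o_t)`` (i.e. the classic alpha divided by the
    running product of per-step scales); ``scales[t]`` is that step's
    normalizer, so ``log_likelihood = sum(log(scales))``. ``beta`` is
    scaled compatibly so that ``gamma = alpha * beta`` is already
    row-normalized. ``gamma``/``xi`` are filled by :func:`posteriors` and
    ``None`` after a bare forward/backward pass.
    """

    log_likelihood: float
    alpha: np.ndarray
    scales: np.ndarray
    beta: np.ndarray | None = None
    gamma: np.ndarray | None = None
    xi: np.ndarray | None = None
    impossible: bool = False


def _check_obs(params: HmmParams, obs) -> np.ndarray:
    o = np.asarray(obs, dtype=int)
    if o.ndim != 1 or o.shape[0] < 1:
        raise ValueError("observation sequence must be a nonempty 1-D array")
    if np.any(o < 0) or np.any(o >= params.n_symbols):
        raise ValueError(
            f"observation symbols must lie in [0, {params.n_symbols})"
        )
    return o


def forward(params: HmmParams, obs) -> ForwardBackwardResult:
    """Scaled forward pass: filtered posteriors and log P(O | lambda).

    alpha_1(i) = pi_i b_i(o_1) and
    alpha_{t+1}(i) = [sum_j alpha_t(j) a_{ji}] b_i(o_{t+1}), normalized at
    every step; the log-likelihood is the sum of log scale factors. A
    zero-probability sequence yields ``-inf`` with ``impossible=True``.
    """
    o = _check_obs(params, obs)
    t_len, n = o.shape[0], params.n_states
    alpha = np.zeros((t_len, n))
    scales = np.zeros(t_len)
    impossible = False
    a_raw = params.pi * params.B[:, o[0]]
    for t in range(t_len):
        if t > 0:
            a_raw = (alpha[t - 1] @ params.A) * params.B[:, o[t]]
        c = a_raw.sum()
        scales[t] = c
        if c == 0.0:
            impossible = True
            alpha[t:] = 1.0 / n  # arbitrary but normalized continuation
            scales[t:] = 0.0
            break
        alpha[t] = a_raw / c
    with np.errstate(divide="ignore"):
        ll = float(np.sum(np.log(scales))) if not impossible else -np.inf
    return ForwardBackwardResult(ll, alpha, scales, impossible=impossible)


def backward(params: HmmParams, obs) -> np.ndarray:
    """Scaled backward pass, using the forward pass's scale factors.

    beta_T(i) = 1 and
    beta_t(i) = sum_j a_{ij} b_j(o_{t+1}) beta_{t+1}(j), each step divided
    by the forward scale c_{t+1} so that alpha_t * beta_t sums to 1.
    """
    fwd = forward(params, obs)
    return _backward_scaled(params, _check_obs(params, obs), fwd)


def _backward_scaled(
    params: HmmParams, o: np.ndarray, fwd: ForwardBackwardResult
) -> np.ndarray:
    t_len, n = o.shape[0], params.n_states
    beta = np.ones((t_len, n))
    if fwd.impossible:
        return beta
    for t in range(t_len - 2, -1, -1):
        beta[t] = params.A @ (params.B[:, o[t + 1]] * beta[t + 1]) / fwd.scales[t + 1]
    return beta


def posteriors(params: HmmParams, obs) -> ForwardBackwardResult:
    """Forward-backward smoothing: gamma and xi posteriors.

    gamma_t(i) is proportional to alpha_t(i) beta_t(i) and
    xi_t(i, j) to alpha_t(i) a_{ij} b_j(o_{t+1}) beta_{t+1}(j); both are
    normalized per time step.
    """
    o = _check_obs(params, obs)
    fwd = forward(params, o)
    beta = _backward_scaled(params, o, fwd)
    gamma = fwd.alpha * beta
    gamma /= gamma.sum(axis=1, keepdims=True)
    t_len = o.shape[0]
    xi = np.zeros((max(t_len - 1, 0), params.n_states, params.n_states))
    if not fwd.impossible:
        for t in range(t_len - 1):
            m = (
                fwd.alpha[t][:, None]
                * params.A
                * (params.B[:, o[t + 1]] * beta[t + 1])[None, :]
            ) / fwd.scales[t + 1]
            xi[t] = m / m.sum()
    return ForwardBackwardResult(
        fwd.log_likelihood, fwd.alpha, fwd.scales, beta, gamma, xi, fwd.impossible
    )


def viterbi(params: HmmParams, obs) -> tuple[np.ndarray, float]:
    """Most probable state path and its log probability.

    Dynamic programming in log space; ties at every maximization are broken
    toward the lower state index. An all-zero-probability situation returns
    a path of zeros with log probability ``-inf``.
    """
    o = _check_obs(params, obs)
    t_len, n = o.shape[0], params.n_states
    with np.errstate(divide="ignore"):
        log_pi = np.log(params.pi)
        log_a = np.log(params.A)
        log_b = np.log(params.B)
    delta = log_pi + log_b[:, o[0]]
    psi = np.zeros((t_len, n), dtype=int)
    for t in range(1, t_len):
        cand = delta[:, None] + log_a  # cand[i, j]: from i into j
        psi[t] = np.argmax(cand, axis=0)  # first max -> lowest index
        delta = cand[psi[t], np.arange(n)] + log_b[:, o[t]]
    path = np.zeros(t_len, dtype=int)
    path[-1] = int(np.argmax(delta))
    logp = float(delta[path[-1]])
    if not np.isfinite(logp):
        return np.zeros(t_len, dtype=int), -np.inf
    for t in range(t_len - 2, -1, -1):
        path[t] = psi[t + 1][path[t + 1]]
    return path, logp


def random_params(
    n_states: int, n_symbols: int, rng: np.random.Generator
) -> HmmParams:
    """Random strictly positive row-stochastic parameters (EM starting point)."""
    def rows(shape):
        m = rng.uniform(0.1, 1.0, size=shape)
        return m / m.sum(axis=-1, keepdims=True)

    return HmmParams(rows(n_states), rows((n_states, n_states)),
                     rows((n_states, n_symbols)))


def baum_welch(
    sequences: list,
    n_states: int,
    n_symbols: int,
    init: HmmParams | int | None = None,
    max_iter: int = 100,
    tol: float = 1e-6,
    n_restarts: int = 1,
) -> tuple[HmmParams, list[float]]:
    """Baum-Welch EM over one or more observation sequences.

    E-step: gamma/xi posteriors per sequence. M-step: pi from the summed
    initial-step gammas, A from summed xi over summed gamma occupancy, B
    from symbol-conditional gamma mass. Iterates until the total
    log-likelihood improves by less than ``tol`` or ``max_iter`` is hit;
    the returned per-iteration log-likelihoods are non-decreasing (up to
    numerical slack). A state with no occupancy has its rows reset to
    uniform with a warning.

    ``init`` may be explicit parameters, an integer seed for a random
    start, or ``None`` (seed 0). Because EM only finds local likelihood
    maxima, ``n_restarts > 1`` runs that many seeded random starts (seeds
    derived from ``init``) and keeps the fit with the best final
    log-likelihood; ignored when ``init`` is explicit parameters.
    """
    if not sequences:
        raise ValueError("need at least one observation sequence")
    seqs = [np.asarray(s, dtype=int) for s in sequences]
    if isinstance(init, HmmParams):
        return _baum_welch_once(seqs, n_states, n_symbols, init, max_iter, tol)
    base_seed = 0 if init is None else int(init)
    best: tuple[HmmParams, list[float]] | None = None
    for r in range(max(n_restarts, 1)):
        start = random_params(
            n_states, n_symbols, np.random.default_rng([base_seed, r])
        )
        fit = _baum_welch_once(seqs, n_states, n_symbols, start, max_iter, tol)
        if best is None or fit[1][-1] > best[1][-1]:
            best = fit
    return best


def _baum_welch_once(
    seqs: list[np.ndarray],
    n_states: int,
    n_symbols: int,
    params: HmmParams,
    max_iter: int,
    tol: float,
) -> tuple[HmmParams, list[float]]:
    ll_history: list[float] = []
    for _ in range(max_iter):
        pi_acc = np.zeros(n_states)
        xi_acc = np.zeros((n_states, n_states))
        gamma_trans_acc = np.zeros(n_states)  # occupancy excluding last step
        b_acc = np.zeros((n_states, n_symbols))
        gamma_acc = np.zeros(n_states)
        total_ll = 0.0
        for o in seqs:
            res = posteriors(params, o)
            total_ll += res.log_likelihood
            pi_acc += res.gamma[0]
            if res.xi.shape[0]:
                xi_acc += res.xi.sum(axis=0)
                gamma_trans_acc += res.gamma[:-1].sum(axis=0)
            np.add.at(b_acc.T, o, res.gamma)
            gamma_acc += res.gamma.sum(axis=0)
        ll_history.append(total_ll)

        pi = pi_acc / pi_acc.sum()
        A = np.empty((n_states, n_states))
        B = np.empty((n_states, n_symbols))
        starved = []
        for i in range(n_states):
            if gamma_trans_acc[i] > 0:
                A[i] = xi_acc[i] / gamma_trans_acc[i]
            else:
                A[i] = 1.0 / n_states
                starved.append(i)
            if gamma_acc[i] > 0:
                B[i] = b_acc[i] / gamma_acc[i]
            else:
                B[i] = 1.0 / n_symbols
                if i not in starved:
                    starved.append(i)
        if starved:
            warnings.warn(
                f"states {starved} received no posterior occupancy; their rows "
                f"were reset to uniform",
                RuntimeWarning,
                stacklevel=2,
            )
        # guard against round-off drifting rows away from stochasticity
        A /= A.sum(axis=1, keepdims=True)
        B /= B.sum(axis=1, keepdims=True)
        params = HmmParams(pi, A, B)
        if len(ll_history) >= 2 and abs(ll_history[-1] - ll_history[-2]) < tol:
            break
    return params, ll_history


def estimate_supervised(
    label_sequences: list, n_states: int, pseudocount: float = 1.0
) -> tuple[np.ndarray, np.ndarray]:
    """Supervised (pi, A) from labelled state sequences by smoothed counting.

    pi from first-symbol counts, A from bigram counts, each plus
    ``pseudocount`` before row normalization.
    """
    if not label_sequences:
        raise ValueError("need at least one label sequence")
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    first = np.zeros(n_states) + pseudocount
    bigram = np.zeros((n_states, n_states)) + pseudocount
    for seq in label_sequences:
        s = np.asarray(seq, dtype=int)
        if s.size == 0:
            continue
        if np.any(s < 0) or np.any(s >= n_states):
            raise ValueError(f"labels must lie in [0, {n_states})")
        first[s[0]] += 1
        np.add.at(bigram, (s[:-1], s[1:]), 1)
    if first.sum() == 0 or np.any(bigram.sum(axis=1) == 0):
        raise ValueError(
            "a state has no observed transitions and pseudocount is 0; "
            "increase pseudocount"
        )
    return first / first.sum(), bigram / bigram.sum(axis=1, keepdims=True)


def emission_from_confusion(
    true_labels, predicted_labels, n_states: int, pseudocount: float = 1.0
) -> np.ndarray:
    """Emission matrix B from a labelled confusion count.

    ``B[i, o] = (count(true=i, pred=o) + pseudocount) /
    (count(true=i) + n_states * pseudocount)`` — how the window classifier
    errs, which is exactly what the smoothing HMM needs to know.
    """
    t = np.asarray(true_labels, dtype=int)
    p = np.asarray(predicted_labels, dtype=int)
    if t.shape != p.shape or t.ndim != 1:
        raise ValueError("true and predicted labels must be equal-length vectors")
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    for name, v in (("true", t), ("predicted", p)):
        if np.any(v < 0) or np.any(v >= n_states):
            raise ValueError(f"{name} labels must lie in [0, {n_states})")
    counts = np.zeros((n_states, n_states))
    np.add.at(counts, (t, p), 1)
    row_tot = counts.sum(axis=1)
    if pseudocount == 0 and np.any(row_tot == 0):
        # No data and no smoothing leaves these rows undefined; fall back
        # to uniform so the matrix stays row-stochastic and usable.
        missing = np.flatnonzero(row_tot == 0).tolist()
        warnings.warn(
            f"classes {missing} are absent from the true labels and "
            f"pseudocount is 0; their emission rows were set to uniform",
            RuntimeWarning,
            stacklevel=2,
        )
        counts[missing] = 1.0 / n_states
        row_tot = counts.sum(axis=1)
    return (counts + pseudocount) / (row_tot + n_states * pseudocount)[:, None]
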