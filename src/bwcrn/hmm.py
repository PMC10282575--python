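"""Classical hidden-Markov-model machinery.

This module implements the discrete Baum-Welch (BW) pipeline — forward and
backward recursions, E-step, M-step (single- and multi-sequence), and the
iterated fit — together with a brute-force likelihood by explicit path
enumeration that serves as an independent oracle in the test suite, and a
synthetic sequence sampler.

An HMM over a hidden-state set H and a visible alphabet V is parameterized by
an initial distribution ``pi`` on H, a row-stochastic transition matrix
``theta`` (H x H) and a row-stochastic emission matrix ``psi`` (H x V).  The
likelihood of an observed word v_1..v_L is

    P(v | theta, psi) = sum over hidden paths h_1..h_L of
        pi[h_1] psi[h_1, v_1] prod_{l>=2} theta[h_{l-1}, h_l] psi[h_l, v_l].

Forward/backward are run with per-position scaling by default so that
sequences of length in the hundreds do not underflow; every E-step quantity
is scale-invariant, so scaling never changes results.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Sequence as SequenceType

import numpy as np

__all__ = [
    "HMMParams",
    "ObservedSequence",
    "Trellis",
    "FitResult",
    "ThetaRegionReport",
    "OutOfDomainError",
    "sample_sequence",
    "brute_force_likelihood",
    "forward",
    "backward",
    "e_step",
    "m_step",
    "m_step_multi",
    "log_likelihood",
    "bw_fit",
    "check_theta_region",
]

_STOCH_TOL = 1e-9


class OutOfDomainError(ValueError):
    """A Baum-Welch denominator is zero: the parameters left the region Theta."""


def _check_stochastic(name: str, arr: np.ndarray) -> None:
    if np.any(arr < 0):
        raise ValueError(f"{name} has negative entries")
    sums = arr.sum(axis=-1)
    if not np.allclose(sums, 1.0, rtol=0.0, atol=_STOCH_TOL):
        raise ValueError(f"rows of {name} must sum to 1 (got {sums})")


@dataclass
class HMMParams:
    """Initial distribution, transition matrix and emission matrix.

    The same type carries both "current" parameters and the primed updates
    produced by an M-step or read off a reaction-network equilibrium.
    """

    pi: np.ndarray
    theta: np.ndarray
    psi: np.ndarray

    def __post_init__(self) -> None:
        self.pi = np.asarray(self.pi, dtype=float)
        self.theta = np.asarray(self.theta, dtype=float)
        self.psi = np.asarray(self.psi, dtype=float)
        n = self.n_hidden
        if n < 1 or self.n_symbols < 1:
            raise ValueError("need at least one hidden state and one symbol")
        if self.theta.shape != (n, n):
            raise ValueError("theta must be square |H| x |H|")
        if self.psi.shape[0] != n:
            raise ValueError("psi must have one row per hidden state")
        _check_stochastic("pi", self.pi[None, :])
        _check_stochastic("theta", self.theta)
        _check_stochastic("psi", self.psi)

    @property
    def n_hidden(self) -> int:
        return len(self.pi)

    @property
    def n_symbols(self) -> int:
        return self.psi.shape[1]

    def copy(self) -> "HMMParams":
        return HMMParams(self.pi.copy(), self.theta.copy(), self.psi.copy())

    def strictly_positive(self) -> bool:
        """True iff (theta, psi) lies in the open region Theta_0."""
        return bool(np.all(self.theta > 0) and np.all(self.psi > 0))

    def max_abs_diff(self, other: "HMMParams") -> float:
        return max(
            float(np.max(np.abs(self.pi - other.pi))),
            float(np.max(np.abs(self.theta - other.theta))),
            float(np.max(np.abs(self.psi - other.psi))),
        )

    @classmethod
    def uniform(cls, n_hidden: int, n_symbols: int) -> "HMMParams":
        return cls(
            np.full(n_hidden, 1.0 / n_hidden),
            np.full((n_hidden, n_hidden), 1.0 / n_hidden),
            np.full((n_hidden, n_symbols), 1.0 / n_symbols),
        )

    @classmethod
    def random(cls, n_hidden: int, n_symbols: int, rng) -> "HMMParams":
        """Row-wise flat-Dirichlet draw (the 'random initialization' of the
        experiments)."""
        rng = np.random.default_rng(rng)
        return cls(
            rng.dirichlet(np.ones(n_hidden)),
            rng.dirichlet(np.ones(n_hidden), size=n_hidden),
            rng.dirichlet(np.ones(n_symbols), size=n_hidden),
        )


@dataclass
class ObservedSequence:
    """A finite word over the visible alphabet, stored as indices into V."""

    symbols: np.ndarray
    alphabet: list[str]

    def __post_init__(self) -> None:
        self.symbols = np.asarray(self.symbols, dtype=int)
        self.alphabet = list(self.alphabet)
        if self.symbols.ndim != 1:
            raise ValueError("symbols must be a flat index array")
        if len(self.symbols) and (
            self.symbols.min() < 0 or self.symbols.max() >= len(self.alphabet)
        ):
            raise ValueError("symbol index outside the declared alphabet")

    def __len__(self) -> int:
        return len(self.symbols)

    @property
    def L(self) -> int:
        return len(self.symbols)

    def tokens(self) -> list[str]:
        return [self.alphabet[i] for i in self.symbols]

    def counts(self) -> np.ndarray:
        return np.bincount(self.symbols, minlength=len(self.alphabet))

    @classmethod
    def from_tokens(
        cls, tokens: SequenceType[str], alphabet: SequenceType[str] | None = None
    ) -> "ObservedSequence":
        """Build from symbol tokens.  Symbols are indexed by order of
        appearance in the declared alphabet; with no declared alphabet, by
        order of first appearance in the data."""
        tokens = list(tokens)
        if alphabet is None:
            alphabet = list(dict.fromkeys(tokens))
        alphabet = list(alphabet)
        index = {s: i for i, s in enumerate(alphabet)}
        try:
            idx = [index[t] for t in tokens]
        except KeyError as exc:
            raise ValueError(f"token {exc.args[0]!r} not in alphabet {alphabet}") from exc
        return cls(np.array(idx, dtype=int), alphabet)


def _as_sequences(seqs) -> list[ObservedSequence]:
    if isinstance(seqs, ObservedSequence):
        return [seqs]
    return list(seqs)


@dataclass
class Trellis:
    """Forward/backward tables and posterior expectations for one sequence.

    ``alpha``/``beta`` may be scaled row-by-row; ``gamma`` (L x |H|) and
    ``xi`` ((L-1) x |H| x |H|) are always normalized posteriors.
    """

    alpha: np.ndarray
    beta: np.ndarray
    gamma: np.ndarray
    xi: np.ndarray
    scale: np.ndarray | None = None


@dataclass
class FitResult:
    params: HMMParams
    loglik_history: list[float]
    n_iter: int
    converged: bool
    in_theta_region: bool
    params_history: list[HMMParams] = field(default_factory=list)


@dataclass
class ThetaRegionReport:
    in_theta: bool
    state_sums: np.ndarray
    offending_states: list[int]
    all_symbols_observed: bool
    lemma_precondition: bool


def sample_sequence(
    params: HMMParams, L: int, seed
) -> tuple[ObservedSequence, np.ndarray]:
    """Sample an observed word of length L and its hidden path from the HMM.

    Returns ``(sequence, hidden_path)``; identical seeds give identical
    output.  Symbols are labelled ``v1..v|V|``.
    """
    if L < 1:
        raise ValueError("L must be >= 1")
    rng = np.random.default_rng(seed)
    n_h, n_v = params.n_hidden, params.n_symbols
    hidden = np.empty(L, dtype=int)
    visible = np.empty(L, dtype=int)
    hidden[0] = rng.choice(n_h, p=params.pi)
    visible[0] = rng.choice(n_v, p=params.psi[hidden[0]])
    for ell in range(1, L):
        hidden[ell] = rng.choice(n_h, p=params.theta[hidden[ell - 1]])
        visible[ell] = rng.choice(n_v, p=params.psi[hidden[ell]])
    alphabet = [f"v{i + 1}" for i in range(n_v)]
    return ObservedSequence(visible, alphabet), hidden


def brute_force_likelihood(params: HMMParams, seq: ObservedSequence) -> float:
    """Likelihood by explicit enumeration of all |H|^L hidden paths.

    Exponential-time oracle; refuses instances with more than 10^6 paths.
    """
    n_h, L = params.n_hidden, seq.L
    if n_h**L > 10**6:
        raise ValueError(
            f"|H|^L = {n_h}^{L} exceeds the enumeration guard (10^6); "
            "use forward() instead"
        )
    v = seq.symbols
    total = 0.0
    for path in itertools.product(range(n_h), repeat=L):
        p = params.pi[path[0]] * params.psi[path[0], v[0]]
        for ell in range(1, L):
            p *= params.theta[path[ell - 1], path[ell]] * params.psi[path[ell], v[ell]]
        total += p
    return total


def forward(
    params: HMMParams, seq: ObservedSequence, scaled: bool = True
) -> tuple[np.ndarray, np.ndarray | None]:
    """Forward recursion alpha[l, h].

    Unscaled: alpha[0] = pi * psi[:, v_1]; alpha[l+1] = (alpha[l] @ theta)
    * psi[:, v_{l+1}].  Scaled: each row is divided by its sum c_l (rows with
    sum zero are left as zeros, c_l = 0) and the factors are returned; the raw
    table is ``alpha * cumprod(scale)`` and the log-likelihood is
    ``sum(log(scale))``.
    """
    v = seq.symbols
    L, n_h = seq.L, params.n_hidden
    alpha = np.zeros((L, n_h))
    scale = np.zeros(L) if scaled else None
    row = params.pi * params.psi[:, v[0]]
    for ell in range(L):
        if ell > 0:
            row = (alpha[ell - 1] @ params.theta) * params.psi[:, v[ell]]
        if scaled:
            c = row.sum()
            scale[ell] = c
            alpha[ell] = row / c if c > 0 else row
        else:
            alpha[ell] = row
    return alpha, scale


def backward(
    params: HMMParams, seq: ObservedSequence, scaled: bool = True
) -> np.ndarray:
    """Backward recursion beta[l, h]; beta[L-1] = 1.

    With ``scaled``, each row below L is normalized by its sum, which is
    enough for every (scale-invariant) E-step use.
    """
    v = seq.symbols
    L, n_h = seq.L, params.n_hidden
    beta = np.zeros((L, n_h))
    beta[L - 1] = 1.0
    for ell in range(L - 2, -1, -1):
        row = params.theta @ (params.psi[:, v[ell + 1]] * beta[ell + 1])
        if scaled:
            c = row.sum()
            beta[ell] = row / c if c > 0 else row
        else:
            beta[ell] = row
    return beta


def e_step(
    params: HMMParams,
    seq: ObservedSequence,
    alpha: np.ndarray,
    beta: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Posterior state probabilities gamma and transition probabilities xi.

    gamma[l, h] ∝ alpha[l, h] beta[l, h];
    xi[l, g, h] ∝ alpha[l, g] theta[g, h] psi[h, v_{l+1}] beta[l+1, h];
    each gamma row and each xi slice is normalized to 1, so any positive
    row-wise rescaling of alpha or beta cancels.
    """
    v = seq.symbols
    L = seq.L
    ab = alpha * beta
    denoms = ab.sum(axis=1)
    bad = np.nonzero(denoms <= 0)[0]
    if bad.size:
        raise OutOfDomainError(
            f"zero E-step denominator at position {int(bad[0]) + 1} "
            "(sum_f alpha*beta = 0): parameters outside Theta for this sequence"
        )
    gamma = ab / denoms[:, None]
    xi = np.empty((L - 1, params.n_hidden, params.n_hidden))
    for ell in range(L - 1):
        slab = (
            alpha[ell][:, None]
            * params.theta
            * (params.psi[:, v[ell + 1]] * beta[ell + 1])[None, :]
        )
        s = slab.sum()
        if s <= 0:
            raise OutOfDomainError(
                f"zero xi normalization at position {ell + 1}"
            )
        xi[ell] = slab / s
    return gamma, xi


def m_step(
    gamma: np.ndarray, xi: np.ndarray, seq: ObservedSequence
) -> tuple[np.ndarray, np.ndarray]:
    """Re-estimate (theta', psi') from expected counts.

    theta'[g, h] = sum_l xi[l, g, h] / sum_l sum_f xi[l, g, f];
    psi'[h, w]   = sum_{l : v_l = w} gamma[l, h] / sum_l gamma[l, h].
    Rows sum to 1 by construction.  Raises :class:`OutOfDomainError` when a
    denominator vanishes, naming the row.
    """
    n_h = gamma.shape[1]
    n_v = len(seq.alphabet)
    xi_row = xi.sum(axis=0)  # |H| x |H|
    theta_den = xi_row.sum(axis=1)
    bad = np.nonzero(theta_den <= 0)[0]
    if bad.size:
        raise OutOfDomainError(
            f"theta' row {int(bad[0]) + 1} has zero expected transition mass"
        )
    theta_p = xi_row / theta_den[:, None]
    occ = np.zeros((n_h, n_v))
    for w in range(n_v):
        mask = seq.symbols == w
        if mask.any():
            occ[:, w] = gamma[mask].sum(axis=0)
    psi_den = gamma.sum(axis=0)
    bad = np.nonzero(psi_den <= 0)[0]
    if bad.size:
        raise OutOfDomainError(
            f"psi' row {int(bad[0]) + 1} has zero expected occupancy"
        )
    psi_p = occ / psi_den[:, None]
    return theta_p, psi_p


def m_step_multi(
    gammas: SequenceType[np.ndarray],
    xis: SequenceType[np.ndarray],
    seqs: SequenceType[ObservedSequence],
    update_pi: bool = False,
    pi_old: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray | None]:
    """Pooled M-step over R sequences; optionally re-estimates pi.

    pi'[g] = (1/R) sum_i gamma_i[0, g]; theta' and psi' pool the expected
    counts over sequences.  With R = 1 and ``update_pi`` off this reduces to
    :func:`m_step`.
    """
    seqs = list(seqs)
    if not seqs:
        raise ValueError("need at least one sequence")
    n_h = gammas[0].shape[1]
    n_v = len(seqs[0].alphabet)
    xi_row = np.zeros((n_h, n_h))
    occ = np.zeros((n_h, n_v))
    psi_den = np.zeros(n_h)
    for gamma, xi, seq in zip(gammas, xis, seqs):
        xi_row += xi.sum(axis=0)
        for w in range(n_v):
            mask = seq.symbols == w
            if mask.any():
                occ[:, w] += gamma[mask].sum(axis=0)
        psi_den += gamma.sum(axis=0)
    theta_den = xi_row.sum(axis=1)
    bad = np.nonzero(theta_den <= 0)[0]
    if bad.size:
        raise OutOfDomainError(
            f"theta' row {int(bad[0]) + 1} has zero expected transition mass"
        )
    bad = np.nonzero(psi_den <= 0)[0]
    if bad.size:
        raise OutOfDomainError(
            f"psi' row {int(bad[0]) + 1} has zero expected occupancy"
        )
    theta_p = xi_row / theta_den[:, None]
    psi_p = occ / psi_den[:, None]
    pi_p = None
    if update_pi:
        pi_p = np.mean([g[0] for g in gammas], axis=0)
    elif pi_old is not None:
        pi_p = np.asarray(pi_old, float).copy()
    return theta_p, psi_p, pi_p


def log_likelihood(params: HMMParams, seqs) -> float:
    """Log-likelihood via the scaled forward recursion, summed over
    sequences.  Returns ``-inf`` (not an exception) for likelihood zero."""
    total = 0.0
    for seq in _as_sequences(seqs):
        _, scale = forward(params, seq, scaled=True)
        if np.any(scale <= 0):
            return float("-inf")
        total += float(np.sum(np.log(scale)))
    return total


def bw_fit(
    params0: HMMParams,
    seqs,
    tol: float = 1e-10,
    max_iter: int = 10_000,
    update_pi: bool = False,
    record_history: bool = False,
) -> FitResult:
    """Iterate full Baum-Welch updates until the max-abs parameter change
    drops below ``tol`` or ``max_iter`` is reached.

    Raises :class:`OutOfDomainError` (annotated with the iteration index)
    when an update divides by zero; start from strictly positive parameters
    to stay inside Theta (the EM iteration preserves positivity whenever the
    observed sequences cover the alphabet).
    """
    seq_list = _as_sequences(seqs)
    if any(s.L < 2 for s in seq_list):
        raise ValueError("single-sequence Baum-Welch needs L >= 2")
    params = params0.copy()
    history: list[float] = []
    params_history: list[HMMParams] = [params.copy()] if record_history else []
    converged = False
    n = 0
    for n in range(1, max_iter + 1):
        history.append(log_likelihood(params, seq_list))
        try:
            gammas, xis = [], []
            for seq in seq_list:
                alpha, _ = forward(params, seq, scaled=True)
                beta = backward(params, seq, scaled=True)
                gamma, xi = e_step(params, seq, alpha, beta)
                gammas.append(gamma)
                xis.append(xi)
            theta_p, psi_p, pi_p = m_step_multi(
                gammas, xis, seq_list, update_pi=update_pi, pi_old=params.pi
            )
        except OutOfDomainError as exc:
            raise OutOfDomainError(f"iteration {n}: {exc}") from exc
        new = HMMParams(pi_p if pi_p is not None else params.pi, theta_p, psi_p)
        delta = new.max_abs_diff(params)
        params = new
        if record_history:
            params_history.append(params.copy())
        if delta < tol:
            converged = True
            break
    history.append(log_likelihood(params, seq_list))
    in_theta = all(
        check_theta_region(params, seq).in_theta for seq in seq_list
    )
    return FitResult(params, history, n, converged, in_theta, params_history)


def check_theta_region(params: HMMParams, seq: ObservedSequence) -> ThetaRegionReport:
    """Diagnose membership of the no-division-by-zero region Theta.

    Theta requires sum_l alpha[l, h] beta[l, h] > 0 for every hidden state h.
    Also reports the positivity-preservation precondition: every alphabet
    symbol observed and (pi > 0 with L >= 2, or the symbols covered by
    v_2..v_L with L >= 3).
    """
    alpha, _ = forward(params, seq, scaled=True)
    beta = backward(params, seq, scaled=True)
    sums = (alpha * beta).sum(axis=0)
    offending = [int(h) for h in np.nonzero(sums <= 0)[0]]
    observed = set(seq.symbols.tolist())
    all_obs = observed == set(range(len(seq.alphabet)))
    tail_obs = set(seq.symbols[1:].tolist()) == set(range(len(seq.alphabet)))
    lemma = (all_obs and np.all(params.pi > 0) and seq.L >= 2) or (
        tail_obs and seq.L >= 3
    )
    return ThetaRegionReport(
        in_theta=not offending,
        state_sums=sums,
        offending_states=offending,
        all_symbols_observed=all_obs,
        lemma_precondition=bool(lemma),
    )
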