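"""Reference experiments: symmetric fixed point, a length-5 boundary case,
and the dishonest-casino HMM.

The three experiments exercise the discrete Baum-Welch algorithm against the
fully autonomous reaction-network dynamics (BW3) on the data sets used
throughout the package:

* ``run_symmetric_fixed_point`` — a binary sequence with fixed symbol counts,
  trained from uniform parameters.  Both routes land on the same symmetric
  fixed point: uniform transitions, emission rows equal to the empirical
  symbol frequencies.
* ``run_length5_example`` — the alternating word v2 v1 v2 v1 v2.  Both
  routes converge to *boundary* equilibria, and to different ones: the
  discrete algorithm reaches theta = [[0,1],[1,0]], psi = [[0,1],[1,0]],
  while the continuous dynamics freezes with an interior entry in the first
  theta row.  The frozen interior value depends on the initialization (the
  subnetwork rates vanish along the trajectory), so only the structure of
  the limit is init-independent.
* ``run_casino_experiment`` — a two-state (Honest/Dishonest) HMM over a
  three-sided die.  Parameters (including the initial distribution) are
  learned from 150 training rolls starting from a random initialization,
  and the hidden states of 150 test rolls are decoded from the posterior.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from . import hmm
from .hmm import HMMParams, ObservedSequence
from .schemes import SchemeConfig, SchemeResult, fixed_point_residual, run_bw3

__all__ = [
    "ExperimentSpec",
    "ExperimentReport",
    "CASINO_GENERATOR",
    "posterior_decode",
    "run_symmetric_fixed_point",
    "run_length5_example",
    "run_casino_experiment",
    "compare_runs",
    "LENGTH5_SEQUENCE",
    "default_length5_init",
]

#: Generator HMM of the dishonest-casino example: state 1 = Honest (fair
#: three-sided die), state 2 = Dishonest (loaded toward the third face).
CASINO_GENERATOR = HMMParams(
    pi=np.array([1.0, 0.0]),
    theta=np.array([[0.95, 0.05], [0.25, 0.75]]),
    psi=np.array([[0.34, 0.33, 0.33], [0.01, 0.01, 0.98]]),
)

LENGTH5_SEQUENCE = ("v2", "v1", "v2", "v1", "v2")


def default_length5_init() -> HMMParams:
    """Positive initialization for the length-5 boundary experiment.

    The published account of this example uses a specific initialization
    that is not reproduced here; this fixed positive starting point yields
    the same qualitative outcome (two different boundary equilibria, the
    interior theta entry in the continuous limit)."""
    return HMMParams(
        [0.5, 0.5], [[0.5, 0.5], [0.6, 0.4]], [[0.3, 0.7], [0.6, 0.4]]
    )


@dataclass
class ExperimentSpec:
    """Declarative description of one training/decoding experiment."""

    generator: HMMParams | None = None
    sequence_source: str = "sampled"  # printed | sampled | file
    seed: int | None = None
    length: int | None = None
    initialization: str = "uniform"  # uniform | random | explicit
    init_seed: int | None = None
    init_params: HMMParams | None = None
    train_split: int | None = None
    mode: str = "bw3"

    def __post_init__(self):
        if self.train_split is not None and self.length is not None:
            if not (0 < self.train_split < self.length):
                raise ValueError("train/test split outside the sequence")


@dataclass
class ExperimentReport:
    name: str
    sequence_tokens: list[list[str]]
    fitted: dict[str, HMMParams] = field(default_factory=dict)
    logliks: dict[str, float] = field(default_factory=dict)
    decoded: dict[str, np.ndarray] = field(default_factory=dict)
    agreement: dict[str, float] = field(default_factory=dict)
    residuals: dict[str, float] = field(default_factory=dict)
    boundary: dict[str, bool] = field(default_factory=dict)
    notes: list[str] = field(default_factory=list)
    extras: dict = field(default_factory=dict)


def posterior_decode(params: HMMParams, seq: ObservedSequence) -> np.ndarray:
    """Per-position argmax of the posterior state probabilities gamma;
    ties resolve to the lowest state index."""
    alpha, _ = hmm.forward(params, seq, scaled=True)
    beta = hmm.backward(params, seq, scaled=True)
    gamma, _ = hmm.e_step(params, seq, alpha, beta)
    return np.argmax(gamma, axis=1)


def _matched_agreement(track: np.ndarray, reference: np.ndarray, n_states: int) -> float:
    """Best agreement over relabelings of the hidden states."""
    from itertools import permutations

    best = 0.0
    for perm in permutations(range(n_states)):
        relabeled = np.array(perm)[track]
        best = max(best, float(np.mean(relabeled == reference)))
    return best


def _seq_from_counts(counts: Sequence[int], seed: int = 0) -> ObservedSequence:
    tokens = []
    for k, c in enumerate(counts):
        tokens += [f"v{k + 1}"] * int(c)
    rng = np.random.default_rng(seed)
    rng.shuffle(tokens)
    return ObservedSequence.from_tokens(tokens, [f"v{k + 1}" for k in range(len(counts))])


def run_symmetric_fixed_point(
    counts: Sequence[int] = (49, 51),
    L: int | None = None,
    seed: int = 0,
    config: SchemeConfig | None = None,
) -> ExperimentReport:
    """Train from uniform parameters on a binary sequence with the given
    symbol counts; discrete Baum-Welch and BW3 reach the same symmetric
    fixed point (uniform theta, emission rows = empirical frequencies)."""
    counts = [int(c) for c in counts]
    L = L or sum(counts)
    if sum(counts) != L:
        raise ValueError("counts must sum to the sequence length")
    seq = _seq_from_counts(counts, seed=seed)
    p0 = HMMParams.uniform(2, len(counts))
    fit = hmm.bw_fit(p0, seq)
    config = config or SchemeConfig(t_max=2000.0)
    r3 = run_bw3(p0, seq, config)
    report = ExperimentReport("symmetric_fixed_point", [seq.tokens()])
    report.fitted = {"bw": fit.params, "bw3": r3.report.params}
    report.logliks = {
        "bw": hmm.log_likelihood(fit.params, seq),
        "bw3": hmm.log_likelihood(r3.report.params, seq),
    }
    report.residuals = {
        "bw": fixed_point_residual(fit.params, seq),
        "bw3": r3.report.bw_residual,
    }
    report.boundary = {"bw": not fit.params.strictly_positive(),
                       "bw3": r3.report.boundary}
    report.extras = {
        "empirical_frequencies": (np.asarray(counts) / L).tolist(),
        "bw3_trajectory": r3.trajectory,
        "bw_loglik_history": fit.loglik_history,
    }
    return report


def run_length5_example(
    init_params: HMMParams | None = None,
    config: SchemeConfig | None = None,
) -> ExperimentReport:
    """Discrete vs continuous training on the word v2 v1 v2 v1 v2.

    The hub is placed at the second hidden state so that the boundary limit
    appears in the same orientation in which it is conventionally written
    (pinned second theta row); at a boundary equilibrium the hub choice
    decides which row pins, unlike in the positive case where results are
    hub-independent.
    """
    p0 = init_params or default_length5_init()
    seq = ObservedSequence.from_tokens(LENGTH5_SEQUENCE, ["v1", "v2"])
    fit = hmm.bw_fit(p0, seq, max_iter=50_000)
    config = config or SchemeConfig(t_max=50_000.0, h_star=1)
    r3 = run_bw3(p0, seq, config)
    # the discrete algorithm restarted at the continuous limit
    fit_restart = hmm.bw_fit(r3.report.params, seq, max_iter=50_000)
    report = ExperimentReport("length5_boundary", [seq.tokens()])
    report.fitted = {
        "bw": fit.params,
        "bw3": r3.report.params,
        "bw_from_bw3_limit": fit_restart.params,
    }
    report.logliks = {
        "bw": hmm.log_likelihood(fit.params, seq),
        "bw3": hmm.log_likelihood(r3.report.params, seq),
        "bw_from_bw3_limit": hmm.log_likelihood(fit_restart.params, seq),
    }
    report.residuals = {
        "bw": fixed_point_residual(fit.params, seq),
        "bw3": r3.report.bw_residual,
    }
    report.boundary = {"bw": True, "bw3": True}
    report.notes.append(
        "both limits are boundary equilibria; the interior entry of the "
        "continuous limit depends on the initialization"
    )
    report.extras = {
        "theta_difference": float(
            np.max(np.abs(fit.params.theta - r3.report.params.theta))
        ),
        "psi_difference": float(
            np.max(np.abs(fit.params.psi - r3.report.params.psi))
        ),
        "bw3_trajectory": r3.trajectory,
        "bw_loglik_history": fit.loglik_history,
    }
    return report


def run_casino_experiment(
    seed: int = 0,
    init_seed: int | None = None,
    n_rolls: int = 300,
    train_len: int = 150,
    sequence_file=None,
    init_file=None,
    config: SchemeConfig | None = None,
) -> ExperimentReport:
    """Dishonest-casino training/decoding comparison.

    Samples ``n_rolls`` die rolls from the casino generator HMM (or loads a
    deposited roll sequence when ``sequence_file`` is given), trains both the
    discrete algorithm and BW3 — initial distribution included — on the
    first ``train_len`` rolls from a random (flat Dirichlet) initialization,
    then posterior-decodes the remaining rolls with the generator and with
    each trained model.  Agreement is measured against the generator-HMM
    decoding and against the true sampled hidden path.
    """
    from .io import read_params, read_sequences

    gen = CASINO_GENERATOR
    report = ExperimentReport("dishonest_casino", [])
    hidden = None
    if sequence_file is not None:
        seqs = read_sequences(sequence_file, alphabet=["v1", "v2", "v3"])
        full = seqs[0]
        report.notes.append(f"rolls loaded from {sequence_file}")
    else:
        full, hidden = hmm.sample_sequence(gen, n_rolls, seed)
        report.notes.append(
            "no deposited roll sequence supplied; using a locally sampled "
            "stand-in, printed-value comparisons are not applicable"
        )
    if init_file is not None:
        p0 = read_params(init_file)
        report.notes.append(f"initialization loaded from {init_file}")
    else:
        p0 = HMMParams.random(
            gen.n_hidden, gen.n_symbols,
            np.random.default_rng(init_seed if init_seed is not None else seed + 1000),
        )
        report.notes.append(
            "no deposited initialization supplied; using a seeded random "
            "(flat Dirichlet) stand-in"
        )
    train = ObservedSequence(full.symbols[:train_len], full.alphabet)
    test = ObservedSequence(full.symbols[train_len:], full.alphabet)
    report.sequence_tokens = [full.tokens()]

    fit = hmm.bw_fit(p0, train, update_pi=True)
    config = config or SchemeConfig(t_max=5000.0, learn_pi=True)
    if not config.learn_pi:
        raise ValueError("the casino experiment learns pi; set learn_pi")
    r3 = run_bw3(p0, train, config)

    report.fitted = {"generator": gen, "init": p0, "bw": fit.params,
                     "bw3": r3.report.params}
    report.logliks = {
        "init": hmm.log_likelihood(p0, train),
        "bw": hmm.log_likelihood(fit.params, train),
        "bw3": hmm.log_likelihood(r3.report.params, train),
    }
    decoded = {
        name: posterior_decode(p, test)
        for name, p in (("generator", gen), ("bw", fit.params), ("bw3", r3.report.params))
    }
    report.decoded = decoded
    # hidden-state labels are only identified up to permutation after
    # unsupervised training; report raw and best-permutation agreement
    report.agreement = {}
    for name in ("bw", "bw3"):
        report.agreement[f"{name}_vs_generator"] = float(
            np.mean(decoded[name] == decoded["generator"])
        )
        report.agreement[f"{name}_vs_generator_matched"] = _matched_agreement(
            decoded[name], decoded["generator"], gen.n_hidden
        )
    if hidden is not None:
        true_states = hidden[train_len:]
        for name in ("generator", "bw", "bw3"):
            report.agreement[f"{name}_vs_truth"] = float(
                np.mean(decoded[name] == true_states)
            )
            report.agreement[f"{name}_vs_truth_matched"] = _matched_agreement(
                decoded[name], true_states, gen.n_hidden
            )
        report.extras["true_hidden_test"] = true_states
    report.residuals = {
        "bw": fixed_point_residual(fit.params, train, update_pi=True),
        "bw3": r3.report.bw_residual,
    }
    report.boundary = {"bw": not fit.params.strictly_positive(),
                       "bw3": r3.report.boundary}
    report.extras["bw3_trajectory"] = r3.trajectory
    report.extras["bw_loglik_history"] = fit.loglik_history
    return report


def compare_runs(reports: Sequence[ExperimentReport]) -> pd.DataFrame:
    """Pairwise comparison table of the fitted parameter sets.

    All reports must describe the same observed data.  Rows compare each
    pair of (report, method) entries: max-abs parameter distances,
    log-likelihood gap, fixed-point residuals and boundary flags.
    """
    reports = list(reports)
    if len(reports) < 1:
        raise ValueError("need at least one report")
    ref = reports[0].sequence_tokens
    for r in reports[1:]:
        if r.sequence_tokens != ref:
            raise ValueError("reports describe different observed data")
    entries = []
    for r in reports:
        for method, params in r.fitted.items():
            entries.append((f"{r.name}:{method}", r, method, params))
    if len(entries) < 2:
        raise ValueError("need at least two fitted parameter sets to compare")
    rows = []
    for a in range(len(entries)):
        for b in range(a + 1, len(entries)):
            name_a, rep_a, meth_a, pa = entries[a]
            name_b, rep_b, meth_b, pb = entries[b]
            rows.append(
                {
                    "a": name_a,
                    "b": name_b,
                    "theta_dist": float(np.max(np.abs(pa.theta - pb.theta))),
                    "psi_dist": float(np.max(np.abs(pa.psi - pb.psi))),
                    "pi_dist": float(np.max(np.abs(pa.pi - pb.pi))),
                    "loglik_gap": abs(
                        rep_a.logliks.get(meth_a, np.nan)
                        - rep_b.logliks.get(meth_b, np.nan)
                    ),
                    "residual_a": rep_a.residuals.get(meth_a, np.nan),
                    "residual_b": rep_b.residuals.get(meth_b, np.nan),
                    "boundary_a": rep_a.boundary.get(meth_a, False),
                    "boundary_b": rep_b.boundary.get(meth_b, False),
                }
            )
    return pd.DataFrame(rows)
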