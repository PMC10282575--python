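"""Construction of the Baum-Welch reaction network.

Every quantity of the Baum-Welch algorithm — forward variables alpha[l,h],
backward variables beta[l,h], posteriors gamma[l,h] and xi[l,g,h], the
parameters theta/psi/pi and their primed updates — is a separate chemical
species.  Each reaction converts exactly one molecule of one species into one
molecule of another species of the same family, modulated by catalysts that
appear unchanged on both sides (the futile-cycle motif).  A distinguished
hidden state ``h*`` and visible state ``v*`` act as hubs that break symmetry:
all flow within a family is routed through the hub species, and the rate
constants are 1, so that at equilibrium the concentration ratios reproduce
the Baum-Welch ratios (balance equations).

The observed sequence enters only through indicator catalysts ``E[l,w]``
(1 when symbol w is observed at position l, else 0), so one network serves
every sequence of a given length.

Mass-action semantics: a reaction with reactant r and catalysts c_1..c_k
fires at rate ``k * x_r * x_{c_1} ... x_{c_k}``, removing from r and adding
to the product.  Concentration sums over each family row (alpha position
row, theta' row, ...) are conserved.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from lxml import etree

from .hmm import ObservedSequence

__all__ = [
    "SpeciesIndex",
    "Reaction",
    "CRN",
    "ObservationEncoding",
    "ConservedClass",
    "enumerate_species",
    "build_network",
    "encode_observations",
    "mass_action_rhs",
    "conserved_classes",
    "CompiledRHS",
    "identify_parameters",
    "transformation_graph",
    "connectivity_diagnostics",
    "export_text",
    "import_text",
    "export_sbml",
]


class SpeciesIndex:
    """Bijective map between structured species names and contiguous ids.

    Index arguments are 0-based; printed names are 1-based (``alpha[3,1]`` is
    the forward species for position 3, hidden state 1).  For more than one
    sequence the per-sequence species carry a leading sequence tag,
    ``alpha[2;3,1]``.
    """

    def __init__(
        self,
        n_hidden: int,
        n_symbols: int,
        lengths: Sequence[int],
        learn_pi: bool = False,
    ):
        if n_hidden < 2:
            raise ValueError("need at least two hidden states (|H| >= 2)")
        if n_symbols < 1:
            raise ValueError("need at least one visible symbol")
        lengths = [int(L) for L in lengths]
        if not lengths or any(L < 2 for L in lengths):
            raise ValueError("every sequence length must be >= 2")
        self.n_hidden = n_hidden
        self.n_symbols = n_symbols
        self.lengths = lengths
        self.learn_pi = learn_pi
        self._names: list[str] = []
        self._build()
        self._ids = {name: i for i, name in enumerate(self._names)}

    # -- layout ---------------------------------------------------------
    def _build(self) -> None:
        H, V = self.n_hidden, self.n_symbols
        add = self._names.append
        for g in range(H):
            for h in range(H):
                add(f"theta[{g + 1},{h + 1}]")
        for g in range(H):
            for h in range(H):
                add(f"theta'[{g + 1},{h + 1}]")
        for h in range(H):
            for w in range(V):
                add(f"psi[{h + 1},{w + 1}]")
        for h in range(H):
            for w in range(V):
                add(f"psi'[{h + 1},{w + 1}]")
        for h in range(H):
            add(f"pi[{h + 1}]")
        if self.learn_pi:
            for h in range(H):
                add(f"pi'[{h + 1}]")
        self._seq_offsets = []
        for i, L in enumerate(self.lengths):
            self._seq_offsets.append(len(self._names))
            tag = "" if len(self.lengths) == 1 else f"{i + 1};"
            for ell in range(L):
                for h in range(H):
                    add(f"alpha[{tag}{ell + 1},{h + 1}]")
            for ell in range(L):
                for h in range(H):
                    add(f"beta[{tag}{ell + 1},{h + 1}]")
            for ell in range(L):
                for h in range(H):
                    add(f"gamma[{tag}{ell + 1},{h + 1}]")
            for ell in range(L - 1):
                for g in range(H):
                    for h in range(H):
                        add(f"xi[{tag}{ell + 1},{g + 1},{h + 1}]")
            for ell in range(L):
                for w in range(V):
                    add(f"E[{tag}{ell + 1},{w + 1}]")

    # -- id helpers -----------------------------------------------------
    def __len__(self) -> int:
        return len(self._names)

    @property
    def names(self) -> list[str]:
        return list(self._names)

    def id_of(self, name: str) -> int:
        return self._ids[name]

    def name_of(self, sid: int) -> str:
        return self._names[sid]

    def theta_id(self, g: int, h: int) -> int:
        return g * self.n_hidden + h

    def theta_p_id(self, g: int, h: int) -> int:
        return self.n_hidden**2 + g * self.n_hidden + h

    def psi_id(self, h: int, w: int) -> int:
        return 2 * self.n_hidden**2 + h * self.n_symbols + w

    def psi_p_id(self, h: int, w: int) -> int:
        return 2 * self.n_hidden**2 + self.n_hidden * self.n_symbols + h * self.n_symbols + w

    def pi_id(self, h: int) -> int:
        return 2 * self.n_hidden**2 + 2 * self.n_hidden * self.n_symbols + h

    def pi_p_id(self, h: int) -> int:
        if not self.learn_pi:
            raise KeyError("pi' species exist only when learn_pi is set")
        return self.pi_id(self.n_hidden - 1) + 1 + h

    def _seq_base(self, i: int) -> int:
        return self._seq_offsets[i]

    def alpha_id(self, ell: int, h: int, i: int = 0) -> int:
        return self._seq_base(i) + ell * self.n_hidden + h

    def beta_id(self, ell: int, h: int, i: int = 0) -> int:
        L = self.lengths[i]
        return self._seq_base(i) + L * self.n_hidden + ell * self.n_hidden + h

    def gamma_id(self, ell: int, h: int, i: int = 0) -> int:
        L = self.lengths[i]
        return self._seq_base(i) + 2 * L * self.n_hidden + ell * self.n_hidden + h

    def xi_id(self, ell: int, g: int, h: int, i: int = 0) -> int:
        L, H = self.lengths[i], self.n_hidden
        return (
            self._seq_base(i)
            + 3 * L * H
            + ell * H * H
            + g * H
            + h
        )

    def e_id(self, ell: int, w: int, i: int = 0) -> int:
        L, H = self.lengths[i], self.n_hidden
        return (
            self._seq_base(i)
            + 3 * L * H
            + (L - 1) * H * H
            + ell * self.n_symbols
            + w
        )

    def e_ids(self) -> list[int]:
        out = []
        for i, L in enumerate(self.lengths):
            for ell in range(L):
                for w in range(self.n_symbols):
                    out.append(self.e_id(ell, w, i))
        return out

    def param_ids(self, primed: bool = True) -> list[int]:
        """Ids of the parameter species read out as the result (theta',
        psi', and pi' when learning pi)."""
        H, V = self.n_hidden, self.n_symbols
        if primed:
            ids = [self.theta_p_id(g, h) for g in range(H) for h in range(H)]
            ids += [self.psi_p_id(h, w) for h in range(H) for w in range(V)]
            if self.learn_pi:
                ids += [self.pi_p_id(h) for h in range(H)]
        else:
            ids = [self.theta_id(g, h) for g in range(H) for h in range(H)]
            ids += [self.psi_id(h, w) for h in range(H) for w in range(V)]
            if self.learn_pi:
                ids += [self.pi_id(h) for h in range(H)]
        return ids


def enumerate_species(
    n_hidden: int,
    n_symbols: int,
    L: int | Sequence[int],
    n_sequences: int = 1,
    learn_pi: bool = False,
) -> SpeciesIndex:
    """Complete species index for the network dimensions.

    ``L`` may be a single length (replicated over ``n_sequences``) or a list
    of per-sequence lengths.  Trellis and E species are duplicated per
    sequence; theta/psi/pi species are shared.
    """
    lengths = [L] * n_sequences if isinstance(L, int) else list(L)
    return SpeciesIndex(n_hidden, n_symbols, lengths, learn_pi=learn_pi)


@dataclass(frozen=True)
class Reaction:
    """One mono-molecular conversion ``reactant -> product`` plus catalysts.

    Catalysts appear on both sides; the mass-action rate is
    ``rate * x[reactant] * prod(x[c] for c in catalysts)``.
    """

    reactant: int
    product: int
    catalysts: tuple[int, ...]
    rate: float = 1.0
    subnet: str = ""

    def __post_init__(self):
        if self.reactant == self.product:
            raise ValueError("reactant and product must differ (no-op reaction)")
        if self.rate <= 0:
            raise ValueError("rate constant must be positive")


@dataclass
class ConservedClass:
    name: str
    ids: list[int]


@dataclass
class CRN:
    species: SpeciesIndex
    reactions: list[Reaction]
    h_star: int
    v_star: int
    learn_pi: bool = False
    identified: bool = False  # theta == theta' (BW3 wiring)

    def __post_init__(self):
        self._by_subnet: dict[str, list[Reaction]] | None = None

    @property
    def n_species(self) -> int:
        return len(self.species)

    def reactions_by_subnet(self) -> dict[str, list[Reaction]]:
        if self._by_subnet is None:
            out: dict[str, list[Reaction]] = {}
            for r in self.reactions:
                out.setdefault(r.subnet, []).append(r)
            self._by_subnet = out
        return self._by_subnet

    def execution_order(self) -> list[str]:
        """Subnetwork labels in the sequential (BW1) execution order:
        forward, backward (reversed), gamma, xi, then the M-step parts."""
        idx = self.species
        order: list[str] = []
        for i, L in enumerate(idx.lengths):
            tag = _seq_tag(idx, i)
            order += [f"R{ell + 1}alpha{tag}" for ell in range(L)]
            order += [f"R{ell + 1}beta{tag}" for ell in range(L - 2, -1, -1)]
            order += [f"R{ell + 1}gamma{tag}" for ell in range(L)]
            order += [f"R{ell + 1}xi{tag}" for ell in range(L - 1)]
        order.append("Rtheta")
        order.append("Rpsi")
        if self.learn_pi:
            order.append("Rpi")
        return order

    def inference_subnets(self) -> list[str]:
        return [s for s in self.execution_order() if s not in ("Rtheta", "Rpsi", "Rpi")]

    def learning_subnets(self) -> list[str]:
        return [s for s in ("Rtheta", "Rpsi", "Rpi") if s == "Rpi" and self.learn_pi or s != "Rpi"]


def _seq_tag(idx: SpeciesIndex, i: int) -> str:
    return "" if len(idx.lengths) == 1 else f"@{i + 1}"


def build_network(
    n_hidden: int,
    n_symbols: int,
    lengths: int | Sequence[int],
    h_star: int = 0,
    v_star: int = 0,
    learn_pi: bool = False,
) -> CRN:
    """Emit the full Baum-Welch reaction network.

    Subnetworks (labels): ``R1alpha`` and ``R{l}alpha`` (forward),
    ``R{l}beta`` (backward), ``R{l}gamma`` and ``R{l}xi`` (E-step),
    ``Rtheta``/``Rpsi`` (M-step) and, with ``learn_pi``, ``Rpi``.  No-op
    conversions (the hub onto itself) are omitted — they would have zero net
    effect.  All rate constants are 1.
    """
    lengths = [lengths] if isinstance(lengths, int) else list(lengths)
    idx = SpeciesIndex(n_hidden, n_symbols, lengths, learn_pi=learn_pi)
    H, V = n_hidden, n_symbols
    if not (0 <= h_star < H):
        raise ValueError("h_star outside the hidden-state set")
    if not (0 <= v_star < V):
        raise ValueError("v_star outside the visible alphabet")
    hs, vs = h_star, v_star
    rxns: list[Reaction] = []

    for i, L in enumerate(lengths):
        tag = _seq_tag(idx, i)

        # forward: R1alpha (initialization row), R{l+1}alpha (recursion rows)
        lab = f"R1alpha{tag}"
        for h in range(H):
            if h == hs:
                continue
            for w in range(V):
                rxns.append(Reaction(
                    idx.alpha_id(0, h, i), idx.alpha_id(0, hs, i),
                    (idx.pi_id(hs), idx.psi_id(hs, w), idx.e_id(0, w, i)),
                    subnet=lab))
                rxns.append(Reaction(
                    idx.alpha_id(0, hs, i), idx.alpha_id(0, h, i),
                    (idx.pi_id(h), idx.psi_id(h, w), idx.e_id(0, w, i)),
                    subnet=lab))
        for ell in range(L - 1):  # transforms position ell+2 (1-based ell+2)
            lab = f"R{ell + 2}alpha{tag}"
            for h in range(H):
                if h == hs:
                    continue
                for g in range(H):
                    for w in range(V):
                        rxns.append(Reaction(
                            idx.alpha_id(ell + 1, h, i), idx.alpha_id(ell + 1, hs, i),
                            (idx.alpha_id(ell, g, i), idx.theta_id(g, hs),
                             idx.psi_id(hs, w), idx.e_id(ell + 1, w, i)),
                            subnet=lab))
                        rxns.append(Reaction(
                            idx.alpha_id(ell + 1, hs, i), idx.alpha_id(ell + 1, h, i),
                            (idx.alpha_id(ell, g, i), idx.theta_id(g, h),
                             idx.psi_id(h, w), idx.e_id(ell + 1, w, i)),
                            subnet=lab))

        # backward: R{l}beta transforms position l, catalysed at l+1
        for ell in range(L - 1):
            lab = f"R{ell + 1}beta{tag}"
            for h in range(H):
                if h == hs:
                    continue
                for g in range(H):
                    for w in range(V):
                        rxns.append(Reaction(
                            idx.beta_id(ell, h, i), idx.beta_id(ell, hs, i),
                            (idx.beta_id(ell + 1, g, i), idx.theta_id(hs, g),
                             idx.psi_id(g, w), idx.e_id(ell + 1, w, i)),
                            subnet=lab))
                        rxns.append(Reaction(
                            idx.beta_id(ell, hs, i), idx.beta_id(ell, h, i),
                            (idx.beta_id(ell + 1, g, i), idx.theta_id(h, g),
                             idx.psi_id(g, w), idx.e_id(ell + 1, w, i)),
                            subnet=lab))

        # E-step occupancy: R{l}gamma for every position
        for ell in range(L):
            lab = f"R{ell + 1}gamma{tag}"
            for h in range(H):
                if h == hs:
                    continue
                rxns.append(Reaction(
                    idx.gamma_id(ell, h, i), idx.gamma_id(ell, hs, i),
                    (idx.alpha_id(ell, hs, i), idx.beta_id(ell, hs, i)),
                    subnet=lab))
                rxns.append(Reaction(
                    idx.gamma_id(ell, hs, i), idx.gamma_id(ell, h, i),
                    (idx.alpha_id(ell, h, i), idx.beta_id(ell, h, i)),
                    subnet=lab))

        # E-step transitions: R{l}xi, hub (h*, h*)
        for ell in range(L - 1):
            lab = f"R{ell + 1}xi{tag}"
            hub = idx.xi_id(ell, hs, hs, i)
            for g in range(H):
                for h in range(H):
                    if g == hs and h == hs:
                        continue
                    for w in range(V):
                        rxns.append(Reaction(
                            idx.xi_id(ell, g, h, i), hub,
                            (idx.alpha_id(ell, hs, i), idx.theta_id(hs, hs),
                             idx.beta_id(ell + 1, hs, i), idx.psi_id(hs, w),
                             idx.e_id(ell + 1, w, i)),
                            subnet=lab))
                        rxns.append(Reaction(
                            hub, idx.xi_id(ell, g, h, i),
                            (idx.alpha_id(ell, g, i), idx.theta_id(g, h),
                             idx.beta_id(ell + 1, h, i), idx.psi_id(h, w),
                             idx.e_id(ell + 1, w, i)),
                            subnet=lab))

        # M-step, transition rows: theta' catalysed by xi species
        for ell in range(L - 1):
            for g in range(H):
                for h in range(H):
                    if h == hs:
                        continue
                    rxns.append(Reaction(
                        idx.theta_p_id(g, h), idx.theta_p_id(g, hs),
                        (idx.xi_id(ell, g, hs, i),), subnet="Rtheta"))
                    rxns.append(Reaction(
                        idx.theta_p_id(g, hs), idx.theta_p_id(g, h),
                        (idx.xi_id(ell, g, h, i),), subnet="Rtheta"))

        # M-step, emission rows: psi' routed through the v* hub
        for ell in range(L):
            for h in range(H):
                for w in range(V):
                    if w == vs:
                        continue
                    rxns.append(Reaction(
                        idx.psi_p_id(h, w), idx.psi_p_id(h, vs),
                        (idx.gamma_id(ell, h, i), idx.e_id(ell, vs, i)),
                        subnet="Rpsi"))
                    rxns.append(Reaction(
                        idx.psi_p_id(h, vs), idx.psi_p_id(h, w),
                        (idx.gamma_id(ell, h, i), idx.e_id(ell, w, i)),
                        subnet="Rpsi"))

        # initial-distribution update (multi-sequence M-step)
        if learn_pi:
            for g in range(H):
                if g == hs:
                    continue
                rxns.append(Reaction(
                    idx.pi_p_id(g), idx.pi_p_id(hs),
                    (idx.gamma_id(0, hs, i),), subnet="Rpi"))
                rxns.append(Reaction(
                    idx.pi_p_id(hs), idx.pi_p_id(g),
                    (idx.gamma_id(0, g, i),), subnet="Rpi"))

    return CRN(idx, rxns, h_star, v_star, learn_pi=learn_pi)


@dataclass
class ObservationEncoding:
    """Indicator concentrations for the E species of one or more sequences."""

    species: SpeciesIndex
    values: np.ndarray  # full species-length vector, nonzero only on E ids

    def apply(self, conc: np.ndarray) -> np.ndarray:
        out = conc.copy()
        for sid in self.species.e_ids():
            out[sid] = self.values[sid]
        return out


def encode_observations(
    seqs: ObservedSequence | Sequence[ObservedSequence],
    species: SpeciesIndex,
) -> ObservationEncoding:
    """Set E[l, w] = 1 exactly when symbol w is observed at position l."""
    seq_list = [seqs] if isinstance(seqs, ObservedSequence) else list(seqs)
    if len(seq_list) != len(species.lengths):
        raise ValueError("sequence count does not match the species index")
    values = np.zeros(len(species))
    for i, seq in enumerate(seq_list):
        if seq.L != species.lengths[i]:
            raise ValueError(f"sequence {i + 1} length {seq.L} != {species.lengths[i]}")
        if seq.symbols.max() >= species.n_symbols:
            raise ValueError("sequence symbol outside the network alphabet")
        for ell, w in enumerate(seq.symbols):
            values[species.e_id(ell, int(w), i)] = 1.0
    return ObservationEncoding(species, values)


# ---------------------------------------------------------------------------
# mass-action semantics


class CompiledRHS:
    """Vectorized mass-action right-hand side (and Jacobian) for a CRN.

    ``fixed`` marks species whose concentrations are constant (E species,
    frozen catalysts); reactions involving a fixed-at-zero catalyst are
    pruned, and derivatives of fixed species are forced to zero.
    """

    def __init__(
        self,
        crn: CRN,
        fixed: dict[int, float] | None = None,
        reactions: Iterable[Reaction] | None = None,
    ):
        self.crn = crn
        self.n = crn.n_species
        self.fixed = dict(fixed or {})
        rxns = list(reactions if reactions is not None else crn.reactions)
        if self.fixed:
            zero = {s for s, v in self.fixed.items() if v == 0.0}
            rxns = [r for r in rxns if not (set(r.catalysts) & zero)]
        self.active = rxns
        m = len(rxns)
        kmax = max((len(r.catalysts) for r in rxns), default=0)
        self._react = np.array([r.reactant for r in rxns], dtype=int)
        self._prod = np.array([r.product for r in rxns], dtype=int)
        self._k = np.array([r.rate for r in rxns])
        # sentinel column index self.n maps to a constant 1.0
        self._cats = np.full((m, kmax), self.n, dtype=int)
        for j, r in enumerate(rxns):
            self._cats[j, : len(r.catalysts)] = r.catalysts
        self._fixed_ids = np.array(sorted(self.fixed), dtype=int)
        self._fixed_vals = np.array([self.fixed[s] for s in sorted(self.fixed)])

    def _extended(self, x: np.ndarray) -> np.ndarray:
        xx = np.empty(self.n + 1)
        xx[:-1] = x
        if self._fixed_ids.size:
            xx[self._fixed_ids] = self._fixed_vals
        xx[-1] = 1.0
        return xx

    def rates(self, x: np.ndarray) -> np.ndarray:
        xx = self._extended(x)
        return self._k * xx[self._react] * np.prod(xx[self._cats], axis=1)

    def __call__(self, t: float, x: np.ndarray) -> np.ndarray:
        r = self.rates(x)
        d = np.zeros(self.n + 1)
        np.subtract.at(d, self._react, r)
        np.add.at(d, self._prod, r)
        d = d[:-1]
        if self._fixed_ids.size:
            d[self._fixed_ids] = 0.0
        return d

    def jac(self, t: float, x: np.ndarray) -> np.ndarray:
        xx = self._extended(x)
        m, kmax = self._cats.shape
        cols = np.column_stack([self._react[:, None], self._cats]) if kmax else self._react[:, None]
        F = xx[cols]  # m x (kmax+1) factor values
        nf = F.shape[1]
        # product of all factors except column j, via prefix/suffix products
        pre = np.ones((m, nf + 1))
        suf = np.ones((m, nf + 1))
        for j in range(nf):
            pre[:, j + 1] = pre[:, j] * F[:, j]
            suf[:, nf - 1 - j] = suf[:, nf - j] * F[:, nf - 1 - j]
        J = np.zeros((self.n + 1, self.n + 1))
        for j in range(nf):
            partial = self._k * pre[:, j] * suf[:, j + 1]
            np.subtract.at(J, (self._react, cols[:, j]), partial)
            np.add.at(J, (self._prod, cols[:, j]), partial)
        J = J[:-1, :-1]
        if self._fixed_ids.size:
            J[self._fixed_ids, :] = 0.0
            J[:, self._fixed_ids] = 0.0
        return J


def mass_action_rhs(crn: CRN, concentrations: np.ndarray) -> np.ndarray:
    """Derivative vector of the full network at the given state."""
    conc = np.asarray(concentrations, dtype=float)
    if conc.shape != (crn.n_species,):
        raise ValueError(
            f"concentration vector has shape {conc.shape}, expected ({crn.n_species},)"
        )
    return CompiledRHS(crn)(0.0, conc)


# ---------------------------------------------------------------------------
# conserved classes and connectivity diagnostics


def conserved_classes(crn: CRN) -> list[ConservedClass]:
    """Partition of the non-catalyst species into invariant-total classes:
    alpha/beta/gamma position rows, xi position slices, theta'/psi' rows and
    (when learning) the pi' simplex."""
    idx = crn.species
    H, V = idx.n_hidden, idx.n_symbols
    out: list[ConservedClass] = []
    for i, L in enumerate(idx.lengths):
        tag = _seq_tag(idx, i)
        for ell in range(L):
            out.append(ConservedClass(
                f"alpha[{ell + 1}]{tag}", [idx.alpha_id(ell, h, i) for h in range(H)]))
        for ell in range(L):
            out.append(ConservedClass(
                f"beta[{ell + 1}]{tag}", [idx.beta_id(ell, h, i) for h in range(H)]))
        for ell in range(L):
            out.append(ConservedClass(
                f"gamma[{ell + 1}]{tag}", [idx.gamma_id(ell, h, i) for h in range(H)]))
        for ell in range(L - 1):
            out.append(ConservedClass(
                f"xi[{ell + 1}]{tag}",
                [idx.xi_id(ell, g, h, i) for g in range(H) for h in range(H)]))
    for g in range(H):
        out.append(ConservedClass(
            f"theta'[{g + 1}]", [idx.theta_p_id(g, h) for h in range(H)]))
    for h in range(H):
        out.append(ConservedClass(
            f"psi'[{h + 1}]", [idx.psi_p_id(h, w) for w in range(V)]))
    if crn.learn_pi:
        out.append(ConservedClass("pi'", [idx.pi_p_id(h) for h in range(H)]))
    return out


def class_of_subnet(crn: CRN, label: str) -> list[ConservedClass]:
    """Conserved classes whose species are transformed by the subnetwork."""
    members: set[int] = set()
    for r in crn.reactions_by_subnet().get(label, []):
        members.add(r.reactant)
        members.add(r.product)
    return [c for c in conserved_classes(crn) if members & set(c.ids)]


def validate_conservation(crn: CRN) -> None:
    """Check every reaction transforms within one conserved class."""
    cls_of = {}
    for c in conserved_classes(crn):
        for sid in c.ids:
            cls_of[sid] = c.name
    for r in crn.reactions:
        a, b = cls_of.get(r.reactant), cls_of.get(r.product)
        if a is None or a != b:
            raise ValueError(
                f"reaction {crn.species.name_of(r.reactant)} -> "
                f"{crn.species.name_of(r.product)} crosses conserved classes"
            )


def transformation_graph(crn: CRN, label: str, conc: np.ndarray):
    """Directed graph of a subnetwork's conversions, weighted by the summed
    mass-action catalyst products at the given concentrations."""
    import networkx as nx

    G = nx.DiGraph()
    for r in crn.reactions_by_subnet().get(label, []):
        G.add_node(r.reactant)
        G.add_node(r.product)
        w = r.rate * float(np.prod(conc[list(r.catalysts)]))
        if G.has_edge(r.reactant, r.product):
            G[r.reactant][r.product]["weight"] += w
        else:
            G.add_edge(r.reactant, r.product, weight=w)
    return G


def connectivity_diagnostics(crn: CRN, label: str, conc: np.ndarray) -> dict:
    """Strong-connectivity report for one subnetwork at a parameter state.

    With every catalyst product positive the hub-and-spokes graph is strongly
    connected; zero parameters break it into components (mass drains from
    source components) or create dead-end nodes (mass accumulates).
    """
    import networkx as nx

    G = transformation_graph(crn, label, conc)
    pos = nx.DiGraph(
        (u, v, d) for u, v, d in G.edges(data=True) if d["weight"] > 0
    )
    pos.add_nodes_from(G.nodes)
    comps = [sorted(c) for c in nx.strongly_connected_components(pos)]
    dead_ends = [n for n in pos.nodes if pos.out_degree(n) == 0]
    return {
        "strongly_connected": len(comps) == 1,
        "n_components": len(comps),
        "components": comps,
        "dead_end_nodes": sorted(dead_ends),
    }


def identify_parameters(crn: CRN) -> CRN:
    """Rewire catalysts so that unprimed parameter species are replaced by
    their primed counterparts (theta := theta', psi := psi', and pi := pi'
    when learning pi) — the fully autonomous feedback wiring."""
    idx = crn.species
    H, V = idx.n_hidden, idx.n_symbols
    remap: dict[int, int] = {}
    for g in range(H):
        for h in range(H):
            remap[idx.theta_id(g, h)] = idx.theta_p_id(g, h)
    for h in range(H):
        for w in range(V):
            remap[idx.psi_id(h, w)] = idx.psi_p_id(h, w)
    if crn.learn_pi:
        for h in range(H):
            remap[idx.pi_id(h)] = idx.pi_p_id(h)
    new_rxns = [
        Reaction(
            r.reactant,
            r.product,
            tuple(remap.get(c, c) for c in r.catalysts),
            r.rate,
            r.subnet,
        )
        for r in crn.reactions
    ]
    return CRN(idx, new_rxns, crn.h_star, crn.v_star, crn.learn_pi, identified=True)


# ---------------------------------------------------------------------------
# export / import

_HEADER_RE = re.compile(
    r"#\s*bwcrn\s+H=(\d+)\s+V=(\d+)\s+L=([\d,]+)\s+h\*=(\d+)\s+v\*=(\d+)"
    r"\s+learn_pi=(\w+)\s+identified=(\w+)"
)


def export_text(crn: CRN) -> str:
    """Human-readable reaction listing; round-trips through
    :func:`import_text`.  The transformed species is written first, catalysts
    are repeated on both sides."""
    idx = crn.species
    lines = [
        "# bwcrn H={} V={} L={} h*={} v*={} learn_pi={} identified={}".format(
            idx.n_hidden,
            idx.n_symbols,
            ",".join(str(L) for L in idx.lengths),
            crn.h_star + 1,
            crn.v_star + 1,
            crn.learn_pi,
            crn.identified,
        )
    ]
    for r in crn.reactions:
        cats = " + ".join(idx.name_of(c) for c in r.catalysts)
        lhs = idx.name_of(r.reactant) + (" + " + cats if cats else "")
        rhs = idx.name_of(r.product) + (" + " + cats if cats else "")
        lines.append(f"{lhs} -> {rhs} ; k={r.rate:g} ; subnet={r.subnet}")
    return "\n".join(lines) + "\n"


def import_text(text: str) -> CRN:
    """Parse the plain-text reaction format back into a CRN."""
    lines = [ln.strip() for ln in text.splitlines() if ln.strip()]
    if not lines:
        raise ValueError("empty network document")
    m = _HEADER_RE.match(lines[0])
    if not m:
        raise ValueError("missing or malformed bwcrn header line")
    H, V = int(m.group(1)), int(m.group(2))
    lengths = [int(x) for x in m.group(3).split(",")]
    h_star, v_star = int(m.group(4)) - 1, int(m.group(5)) - 1
    learn_pi = m.group(6) == "True"
    identified = m.group(7) == "True"
    idx = SpeciesIndex(H, V, lengths, learn_pi=learn_pi)
    rxns = []
    for ln in lines[1:]:
        if ln.startswith("#"):
            continue
        try:
            body, kpart, spart = (p.strip() for p in ln.split(";"))
            lhs, rhs = (s.strip() for s in body.split("->"))
            lhs_names = [s.strip() for s in lhs.split("+")]
            rhs_names = [s.strip() for s in rhs.split("+")]
            rate = float(kpart.split("=", 1)[1])
            subnet = spart.split("=", 1)[1].strip()
            rxns.append(
                Reaction(
                    idx.id_of(lhs_names[0]),
                    idx.id_of(rhs_names[0]),
                    tuple(idx.id_of(n) for n in lhs_names[1:]),
                    rate,
                    subnet,
                )
            )
        except (ValueError, KeyError) as exc:
            raise ValueError(f"malformed reaction line: {ln!r}") from exc
    return CRN(idx, rxns, h_star, v_star, learn_pi, identified=identified)


_SBML_NS = "http://www.sbml.org/sbml/level3/version1/core"
_MATHML_NS = "http://www.w3.org/1998/Math/MathML"


def _sanitize(name: str) -> str:
    return (
        name.replace("'", "p")
        .replace("[", "_")
        .replace("]", "")
        .replace(",", "_")
        .replace(";", "s")
        .replace("@", "_s")
    )


def export_sbml(crn: CRN, initial: np.ndarray | None = None) -> bytes:
    """Serialize the network as an SBML level-3 document (write-only).

    Species initial concentrations come from ``initial`` (zeros when absent);
    each reaction gets a mass-action kinetic law k * reactant * catalysts,
    with catalysts as modifiers.
    """
    idx = crn.species
    if initial is None:
        initial = np.zeros(len(idx))
    root = etree.Element(f"{{{_SBML_NS}}}sbml", nsmap={None: _SBML_NS})
    root.set("level", "3")
    root.set("version", "1")
    model = etree.SubElement(root, f"{{{_SBML_NS}}}model")
    model.set("id", "baum_welch_network")
    comps = etree.SubElement(model, f"{{{_SBML_NS}}}listOfCompartments")
    comp = etree.SubElement(comps, f"{{{_SBML_NS}}}compartment")
    comp.set("id", "cell")
    comp.set("constant", "true")
    comp.set("size", "1")
    species_el = etree.SubElement(model, f"{{{_SBML_NS}}}listOfSpecies")
    for sid in range(len(idx)):
        sp = etree.SubElement(species_el, f"{{{_SBML_NS}}}species")
        sp.set("id", _sanitize(idx.name_of(sid)))
        sp.set("name", idx.name_of(sid))
        sp.set("compartment", "cell")
        sp.set("initialConcentration", repr(float(initial[sid])))
        sp.set("hasOnlySubstanceUnits", "false")
        sp.set("boundaryCondition", "false")
        sp.set("constant", "false")
    rxns_el = etree.SubElement(model, f"{{{_SBML_NS}}}listOfReactions")
    for j, r in enumerate(crn.reactions):
        rx = etree.SubElement(rxns_el, f"{{{_SBML_NS}}}reaction")
        rx.set("id", f"r{j}")
        rx.set("name", r.subnet)
        rx.set("reversible", "false")
        lref = etree.SubElement(rx, f"{{{_SBML_NS}}}listOfReactants")
        ref = etree.SubElement(lref, f"{{{_SBML_NS}}}speciesReference")
        ref.set("species", _sanitize(idx.name_of(r.reactant)))
        ref.set("stoichiometry", "1")
        ref.set("constant", "true")
        lprod = etree.SubElement(rx, f"{{{_SBML_NS}}}listOfProducts")
        ref = etree.SubElement(lprod, f"{{{_SBML_NS}}}speciesReference")
        ref.set("species", _sanitize(idx.name_of(r.product)))
        ref.set("stoichiometry", "1")
        ref.set("constant", "true")
        if r.catalysts:
            lmod = etree.SubElement(rx, f"{{{_SBML_NS}}}listOfModifiers")
            for c in r.catalysts:
                mref = etree.SubElement(lmod, f"{{{_SBML_NS}}}modifierSpeciesReference")
                mref.set("species", _sanitize(idx.name_of(c)))
        kl = etree.SubElement(rx, f"{{{_SBML_NS}}}kineticLaw")
        math = etree.SubElement(kl, f"{{{_MATHML_NS}}}math", nsmap={None: _MATHML_NS})
        apply_el = etree.SubElement(math, f"{{{_MATHML_NS}}}apply")
        etree.SubElement(apply_el, f"{{{_MATHML_NS}}}times")
        cn = etree.SubElement(apply_el, f"{{{_MATHML_NS}}}cn")
        cn.text = repr(float(r.rate))
        for s in (r.reactant, *r.catalysts):
            ci = etree.SubElement(apply_el, f"{{{_MATHML_NS}}}ci")
            ci.text = _sanitize(idx.name_of(s))
    return etree.tostring(
        root, pretty_print=True, xml_declaration=True, encoding="UTF-8"
    )
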