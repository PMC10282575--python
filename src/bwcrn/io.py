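"""Readers and writers for on-disk formats.

Canonical formats: HMM parameters as a JSON document
``{"alphabet": [...], "hidden": [...], "pi": [...], "theta": [[...]],
"psi": [[...]]}`` (TSV matrices with header rows also accepted); observed
sequences as whitespace/newline-separated symbol tokens, or FASTA-like
records for single-character alphabets; trajectories as tidy and wide CSV.

Every artifact written here carries a metadata block (package version, seed,
configuration hash) so that identical configurations yield identical files.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .hmm import HMMParams, ObservedSequence
from .schemes import SchemeConfig, Trajectory

__all__ = [
    "read_params",
    "write_params",
    "read_tsv_matrix",
    "read_sequences",
    "write_sequences",
    "write_trajectory_tidy",
    "write_trajectory_wide",
    "read_scheme_config",
    "config_hash",
    "artifact_meta",
]


def config_hash(obj) -> str:
    """Stable short hash of a JSON-serializable configuration."""
    blob = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def artifact_meta(seed=None, config=None) -> dict:
    from . import __version__

    meta = {"generator": "bwcrn", "version": __version__}
    if seed is not None:
        meta["seed"] = int(seed)
    if config is not None:
        meta["config_hash"] = config_hash(config)
    return meta


# ---------------------------------------------------------------------------
# parameters


def write_params(
    path, params: HMMParams, alphabet: Sequence[str] | None = None,
    hidden: Sequence[str] | None = None, seed=None, config=None,
) -> None:
    doc = {
        "_meta": artifact_meta(seed=seed, config=config),
        "alphabet": list(alphabet or [f"v{i + 1}" for i in range(params.n_symbols)]),
        "hidden": list(hidden or [f"H{i + 1}" for i in range(params.n_hidden)]),
        "pi": params.pi.tolist(),
        "theta": params.theta.tolist(),
        "psi": params.psi.tolist(),
    }
    Path(path).write_text(json.dumps(doc, indent=2) + "\n")


def read_params(path) -> HMMParams:
    """Read HMM parameters from canonical JSON (see :func:`write_params`)."""
    try:
        doc = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise ValueError(f"{path}: not valid JSON ({exc})") from exc
    missing = {"pi", "theta", "psi"} - doc.keys()
    if missing:
        raise ValueError(f"{path}: missing fields {sorted(missing)}")
    return HMMParams(np.array(doc["pi"]), np.array(doc["theta"]), np.array(doc["psi"]))


def read_params_alphabet(path) -> list[str] | None:
    doc = json.loads(Path(path).read_text())
    return doc.get("alphabet")


def read_tsv_matrix(path) -> tuple[list[str], list[str], np.ndarray]:
    """TSV matrix with a header row of column labels and a leading row-label
    column; returns (row_labels, col_labels, values)."""
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    return list(df.index.astype(str)), list(df.columns.astype(str)), df.to_numpy(float)


# ---------------------------------------------------------------------------
# sequences


def read_sequences(path, alphabet: Sequence[str] | None = None) -> list[ObservedSequence]:
    """Read observed sequences.

    Plain format: whitespace/newline-separated tokens, one sequence per
    non-comment block separated by blank lines (a single block is one
    sequence).  FASTA-like: records beginning with '>' whose residues are
    single-character symbols, each of which must be in the declared alphabet.
    """
    text = Path(path).read_text()
    lines = text.splitlines()
    if any(ln.startswith(">") for ln in lines):
        records: list[list[str]] = []
        for ln in lines:
            if ln.startswith(">"):
                records.append([])
            elif ln.strip() and records:
                records[-1].extend(list(ln.strip()))
        if alphabet is not None and any(len(s) != 1 for s in alphabet):
            raise ValueError(
                "FASTA-like input requires a single-character alphabet"
            )
        return [ObservedSequence.from_tokens(r, alphabet) for r in records if r]
    blocks: list[list[str]] = [[]]
    for ln in lines:
        if ln.startswith("#"):
            continue
        if not ln.strip():
            if blocks[-1]:
                blocks.append([])
            continue
        blocks[-1].extend(ln.split())
    blocks = [b for b in blocks if b]
    if not blocks:
        raise ValueError(f"{path}: no sequence tokens found")
    if alphabet is None:
        seen: dict[str, None] = {}
        for b in blocks:
            for tok in b:
                seen.setdefault(tok)
        alphabet = list(seen)
    return [ObservedSequence.from_tokens(b, alphabet) for b in blocks]


def write_sequences(
    path, seqs: Sequence[ObservedSequence], hidden_paths=None, seed=None, config=None,
) -> None:
    meta = artifact_meta(seed=seed, config=config)
    lines = ["# " + json.dumps(meta)]
    for seq in seqs:
        lines.append(" ".join(seq.tokens()))
        lines.append("")
    Path(path).write_text("\n".join(lines))
    if hidden_paths is not None:
        hp = Path(str(path) + ".hidden")
        out = ["# " + json.dumps(meta)]
        for track in hidden_paths:
            out.append(" ".join(f"H{int(h) + 1}" for h in track))
            out.append("")
        hp.write_text("\n".join(out))


# ---------------------------------------------------------------------------
# trajectories


def _traj_frames(traj: Trajectory) -> pd.DataFrame:
    H = traj.theta.shape[1]
    V = traj.psi.shape[2]
    cols = {"t": traj.t}
    for g in range(H):
        for h in range(H):
            cols[f"theta[{g + 1},{h + 1}]"] = traj.theta[:, g, h]
    for h in range(H):
        for w in range(V):
            cols[f"psi[{h + 1},{w + 1}]"] = traj.psi[:, h, w]
    for h in range(H):
        cols[f"pi[{h + 1}]"] = traj.pi[:, h]
    cols["loglik"] = traj.loglik
    return pd.DataFrame(cols)


def write_trajectory_wide(path, traj: Trajectory, seed=None, config=None) -> None:
    """Wide CSV: one row per time point, one column per parameter species
    plus the log-likelihood."""
    df = _traj_frames(traj)
    with open(path, "w") as fh:
        fh.write("# " + json.dumps(artifact_meta(seed=seed, config=config)) + "\n")
        df.to_csv(fh, index=False)


def write_trajectory_tidy(path, traj: Trajectory, seed=None, config=None) -> None:
    """Tidy CSV: (time, species, concentration) triples."""
    wide = _traj_frames(traj)
    tidy = wide.melt(id_vars="t", var_name="species", value_name="concentration")
    with open(path, "w") as fh:
        fh.write("# " + json.dumps(artifact_meta(seed=seed, config=config)) + "\n")
        tidy.to_csv(fh, index=False)


# ---------------------------------------------------------------------------
# configuration


def read_scheme_config(path) -> SchemeConfig:
    """Scheme configuration from YAML or JSON mirroring SchemeConfig fields."""
    text = Path(path).read_text()
    doc = yaml.safe_load(text)
    if not isinstance(doc, dict):
        raise ValueError(f"{path}: expected a mapping of SchemeConfig fields")
    known = set(SchemeConfig.__dataclass_fields__)
    unknown = set(doc) - known
    if unknown:
        raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
    return SchemeConfig(**doc)
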