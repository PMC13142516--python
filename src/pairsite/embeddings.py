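"""Embedding backends: synthetic hash embedder, file loader, PLM adapter contract.

The synthetic backend is a pure function of (sequence, d, seed): each
residue's vector is drawn from a cryptographic hash of its local k-mer
context, so identical contexts give identical rows (up to an optional
smooth positional component).  Short linear motifs are therefore linearly
separable in embedding space — the property the planted-motif fixtures and
the learnability tests rely on.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Literal

import numpy as np

from .model import EmbeddingMatrix

__all__ = ["EmbedderSpec", "embed_sequence", "save_embedding", "load_embedding",
           "AMINO_ACIDS", "register_plm_adapter"]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_ALPHABET = set(AMINO_ACIDS + "X")

# A PLM adapter maps (sequence) -> L x d array; registered at run time by
# users who have a language-model stack installed (expected checkpoint:
# esm2_t33_650M_UR50D, d=1280).  Weights are never vendored here.
_PLM_ADAPTERS: dict[str, Callable[[str], np.ndarray]] = {}


def register_plm_adapter(name: str, fn: Callable[[str], np.ndarray]) -> None:
    _PLM_ADAPTERS[name] = fn


@dataclass(frozen=True)
class EmbedderSpec:
    backend: Literal["synthetic", "file", "plm_adapter"] = "synthetic"
    embed_dim: int = 32
    seed: int = 0
    context_k: int = 3          # local k-mer context width (odd)
    positional_scale: float = 0.05  # 0 disables the positional component
    context_window: int = 1022
    path: str | None = None     # file backend: directory of .npz matrices
    adapter: str | None = None  # plm_adapter backend: registered adapter name


def _kmer_vector(kmer: str, d: int, seed: int) -> np.ndarray:
    digest = hashlib.sha256(f"{seed}|{d}|{kmer}".encode()).digest()
    rng = np.random.default_rng(int.from_bytes(digest[:8], "little"))
    v = rng.standard_normal(d)
    return v / np.linalg.norm(v)


def embed_sequence(sequence: str, spec: EmbedderSpec) -> EmbeddingMatrix:
    """Produce the L x d embedding of one sequence under the given backend."""
    sequence = sequence.strip().upper().rstrip("*")
    if len(sequence) < 1:
        raise ValueError("empty sequence")
    bad = set(sequence) - _ALPHABET
    if bad:
        raise ValueError(f"illegal residue characters: {sorted(bad)}")

    if spec.backend == "synthetic":
        return _embed_synthetic(sequence, spec)
    if spec.backend == "file":
        if spec.path is None:
            raise ValueError("file backend requires a path")
        return load_embedding(Path(spec.path) / _sequence_filename(sequence))
    if spec.backend == "plm_adapter":
        if len(sequence) > spec.context_window:
            raise ValueError(
                f"sequence length {len(sequence)} exceeds the adapter context window "
                f"{spec.context_window}; use the chunked inference path"
            )
        if spec.adapter not in _PLM_ADAPTERS:
            raise ValueError(f"no PLM adapter registered under {spec.adapter!r}")
        values = np.asarray(_PLM_ADAPTERS[spec.adapter](sequence))
        return EmbeddingMatrix(sequence_id=sequence[:16], values=values, source="plm")
    raise ValueError(f"unknown backend {spec.backend!r}")


def _embed_synthetic(sequence: str, spec: EmbedderSpec) -> EmbeddingMatrix:
    k = spec.context_k
    if k < 1 or k % 2 == 0:
        raise ValueError("context_k must be odd and >= 1")
    half = k // 2
    # replicate padding: edge residues keep a homogeneous context, so a
    # homopolymer embeds to identical rows (positional component aside)
    padded = sequence[0] * half + sequence + sequence[-1] * half
    L, d = len(sequence), spec.embed_dim
    values = np.empty((L, d))
    cache: dict[str, np.ndarray] = {}
    for i in range(L):
        kmer = padded[i : i + k]
        if kmer not in cache:
            cache[kmer] = _kmer_vector(kmer, d, spec.seed)
        values[i] = cache[kmer]
    if spec.positional_scale > 0.0:
        pos = np.arange(L)[:, None]
        freq = np.exp(-np.arange(d)[None, :] / d)
        values = values + spec.positional_scale * np.sin(pos * freq)
    return EmbeddingMatrix(sequence_id=sequence[:16], values=values, source="synthetic")


def _sequence_filename(sequence: str) -> str:
    """Content-addressed file name so the file backend needs no id registry."""
    return hashlib.sha1(sequence.encode()).hexdigest()[:16] + ".npz"


def save_embedding_for_sequence(matrix: EmbeddingMatrix, sequence: str, directory: str | Path) -> Path:
    path = Path(directory) / _sequence_filename(sequence.strip().upper().rstrip("*"))
    save_embedding(matrix, path)
    return path


def save_embedding(matrix: EmbeddingMatrix, path: str | Path) -> None:
    """One matrix per file: binary array plus a JSON header (id, L, d)."""
    header = json.dumps(
        {"id": matrix.sequence_id, "L": matrix.length, "d": matrix.embed_dim,
         "source": matrix.source}
    )
    np.savez(path, values=matrix.values, header=np.array(header))


def load_embedding(path: str | Path) -> EmbeddingMatrix:
    with np.load(path, allow_pickle=False) as data:
        header = json.loads(str(data["header"]))
        values = data["values"]
    if values.shape != (header["L"], header["d"]):
        raise ValueError(f"embedding file {path}: header/array shape mismatch")
    return EmbeddingMatrix(
        sequence_id=header["id"], values=values, source=header.get("source", "file")
    )
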