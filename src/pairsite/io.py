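"""File formats: FASTA, pair lists, probability/label tracks, checkpoints.

All emitted coordinates are 1-based; internal arrays are 0-based.
"""

from __future__ import annotations

import csv
import json
from pathlib import Path

import numpy as np
from Bio import SeqIO

from .model import ModelConfig, ModelParams, PARAM_NAMES, ResidueProbabilityTrack

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_pairs_tsv",
    "write_track_tsv",
    "write_label_track_tsv",
    "write_interface_bed",
    "save_checkpoint",
    "load_checkpoint",
]


def read_fasta(path: str | Path) -> dict[str, str]:
    """Multi-record FASTA reader; wrapped lines joined, trailing '*' stripped."""
    records: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        records[rec.id] = str(rec.seq).upper().rstrip("*")
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    return records


def write_fasta(sequences: dict[str, str], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for sid, seq in sequences.items():
            fh.write(f">{sid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_pairs_tsv(path: str | Path) -> list[tuple[str, str]]:
    """Query/partner pair list: two tab-separated columns, '#' comments."""
    pairs = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ValueError(f"{path}:{lineno}: expected two tab-separated columns")
            pairs.append((fields[0], fields[1]))
    return pairs


def write_track_tsv(
    tracks: list[ResidueProbabilityTrack],
    sequences: dict[str, str],
    path: str | Path,
    cutoff: float = 0.5,
) -> None:
    """sequence_id, partner_id, position (1-based), residue, probability, call."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(
            ["sequence_id", "partner_id", "position", "residue", "probability", "binary_call"]
        )
        for track in tracks:
            seq = sequences.get(track.sequence_id, "X" * track.length)
            for i, p in enumerate(track.probabilities):
                writer.writerow(
                    [track.sequence_id, track.partner_id, i + 1, seq[i],
                     f"{p:.6f}", int(p >= cutoff)]
                )


def write_label_track_tsv(track, sequence: str, path: str | Path) -> None:
    """parent_id, position (1-based), residue, label, covered."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(["parent_id", "position", "residue", "label", "covered"])
        for i in range(track.parent_length):
            writer.writerow(
                [track.parent_id, i + 1, sequence[i] if i < len(sequence) else "X",
                 int(track.labels[i]), int(track.coverage_mask[i])]
            )


def write_interface_bed(track, path: str | Path) -> None:
    """BED-like half-open intervals of consecutive interface residues."""
    labels = np.asarray(track.labels)
    with open(path, "w") as fh:
        start = None
        for i in range(labels.size + 1):
            on = i < labels.size and labels[i]
            if on and start is None:
                start = i
            elif not on and start is not None:
                fh.write(f"{track.parent_id}\t{start}\t{i}\n")
                start = None


def save_checkpoint(
    params: ModelParams,
    config: ModelConfig,
    path: str | Path,
    model_tag: str = "custom",
    extra: dict | None = None,
) -> None:
    """Parameter container (.npz) plus a JSON sidecar with the full config."""
    path = Path(path)
    np.savez(path, **params.as_dict())
    sidecar = {
        "model_tag": model_tag,
        "trained": params.trained_flag,
        "config": {
            "embed_dim": config.embed_dim,
            "num_heads": config.num_heads,
            "mlp_hidden": config.mlp_hidden,
            "dropout_rate": config.dropout_rate,
            "attention_scale_mode": config.attention_scale_mode,
            "use_residual": config.use_residual,
            "output_bias_init": config.output_bias_init,
        },
    }
    if extra:
        sidecar.update(extra)
    with open(path.with_suffix(".json"), "w") as fh:
        json.dump(sidecar, fh, indent=2)


def load_checkpoint(path: str | Path) -> tuple[ModelParams, ModelConfig, dict]:
    path = Path(path)
    if path.suffix != ".npz":
        path = path.with_suffix(".npz")
    with open(path.with_suffix(".json")) as fh:
        sidecar = json.load(fh)
    config = ModelConfig(**sidecar["config"])
    with np.load(path) as data:
        params = ModelParams(
            **{name: data[name].copy() for name in PARAM_NAMES},
            trained_flag=bool(sidecar.get("trained", False)),
        )
    params.validate(config)
    return params, config, sidecar
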