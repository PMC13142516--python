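"""Interface labeling from complex structures via solvent-accessibility change.

A residue of the focal chain is an interface residue when its relative
solvent accessibility (RSA) rises by more than 4 percentage points upon
separating the complex into isolated chains — occlusion by the partner is
the operational definition of contact.  SASA is estimated with the
Shrake–Rupley sphere-point method (960 deterministic Fibonacci points,
probe 1.4 Å); RSA normalises each residue's SASA by a residue-type maximum
(Tien et al. theoretical values).  Labels computed on the structure-resolved
sequence are transferred to full-length parent sequences by global alignment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.spatial import cKDTree

__all__ = [
    "ChainStructure",
    "InterfaceLabelTrack",
    "compute_sasa",
    "residue_rsa",
    "delta_rsa_labels",
    "map_to_parent",
    "load_chains",
    "ELEMENT_RADII",
    "MAX_ASA_TIEN",
    "DEFAULT_PROBE_RADIUS",
    "DEFAULT_N_POINTS",
    "DELTA_RSA_THRESHOLD",
]

DEFAULT_PROBE_RADIUS = 1.4  # water probe, Å
DEFAULT_N_POINTS = 960
DELTA_RSA_THRESHOLD = 4.0   # percentage points

# van der Waals radii (Å) by element; protein heavy atoms plus a generic fallback
ELEMENT_RADII = {
    "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "P": 1.80,
    "SE": 1.90, "H": 1.20, "X": 1.70,
}

# Tien et al. (2013) theoretical maximum accessible surface areas, Å²
MAX_ASA_TIEN = {
    "ALA": 129.0, "ARG": 274.0, "ASN": 195.0, "ASP": 193.0, "CYS": 167.0,
    "GLN": 225.0, "GLU": 223.0, "GLY": 104.0, "HIS": 224.0, "ILE": 197.0,
    "LEU": 201.0, "LYS": 236.0, "MET": 224.0, "PHE": 240.0, "PRO": 159.0,
    "SER": 155.0, "THR": 172.0, "TRP": 285.0, "TYR": 263.0, "VAL": 174.0,
    "UNK": 200.0,
}

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}


@dataclass
class ChainStructure:
    """One chain: ordered residues plus a flat atom table."""

    chain_id: str
    residue_names: list[str]          # 3-letter codes, structure order
    residue_numbers: list[int]        # author numbering, for reporting
    atom_elements: list[str]
    atom_residue_index: np.ndarray    # 0-based index into residue lists
    atom_coords: np.ndarray           # (n_atoms, 3) in Å
    atom_radii: np.ndarray | None = None  # per-atom vdW radius; None -> by element

    def __post_init__(self) -> None:
        self.atom_coords = np.asarray(self.atom_coords, dtype=np.float64).reshape(-1, 3)
        self.atom_residue_index = np.asarray(self.atom_residue_index, dtype=np.int64)
        if not np.all(np.isfinite(self.atom_coords)):
            raise ValueError("non-finite atom coordinates")
        if self.atom_residue_index.size and (
            self.atom_residue_index.min() < 0
            or self.atom_residue_index.max() >= len(self.residue_names)
        ):
            raise ValueError("atom references a non-existent residue")
        if self.atom_radii is None:
            self.atom_radii = np.array(
                [ELEMENT_RADII.get(e.upper(), ELEMENT_RADII["X"]) for e in self.atom_elements]
            )
        else:
            self.atom_radii = np.asarray(self.atom_radii, dtype=np.float64)

    @property
    def n_residues(self) -> int:
        return len(self.residue_names)

    @property
    def sequence(self) -> str:
        return "".join(THREE_TO_ONE.get(r, "X") for r in self.residue_names)


@dataclass
class InterfaceLabelTrack:
    """Binary interface annotation on a full-length parent sequence."""

    parent_id: str
    parent_length: int
    labels: np.ndarray
    coverage_mask: np.ndarray
    n_dropped_labels: int = 0

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int8).ravel()
        self.coverage_mask = np.asarray(self.coverage_mask, dtype=np.int8).ravel()
        if self.labels.size != self.parent_length or self.coverage_mask.size != self.parent_length:
            raise ValueError("track lengths must equal parent_length")
        if np.any(self.labels > self.coverage_mask):
            raise ValueError("label present at a position not covered by the structure")


def _fibonacci_sphere(n: int) -> np.ndarray:
    """n nearly uniform unit vectors; deterministic (golden-spiral lattice)."""
    i = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * i / n)
    theta = np.pi * (1.0 + np.sqrt(5.0)) * i
    return np.column_stack(
        (np.cos(theta) * np.sin(phi), np.sin(theta) * np.sin(phi), np.cos(phi))
    )


def compute_sasa(
    chains: list[ChainStructure],
    probe_radius: float = DEFAULT_PROBE_RADIUS,
    n_points: int = DEFAULT_N_POINTS,
) -> dict[str, np.ndarray]:
    """Shrake–Rupley per-residue SASA (Å²), occlusion pooled over all chains.

    Each atom is inflated by the probe radius; surface points falling inside
    any other inflated atom are buried.  Residue SASA sums its atoms.
    """
    coords = np.vstack([c.atom_coords for c in chains])
    radii = np.concatenate([c.atom_radii for c in chains])
    if coords.shape[0] < 1:
        raise ValueError("structure contains no atoms")
    expanded = radii + probe_radius
    sphere = _fibonacci_sphere(n_points)
    tree = cKDTree(coords)
    max_reach = 2.0 * expanded.max()

    atom_sasa = np.empty(coords.shape[0])
    for i in range(coords.shape[0]):
        pts = coords[i] + expanded[i] * sphere
        neighbors = [j for j in tree.query_ball_point(coords[i], max_reach) if j != i]
        accessible = np.ones(n_points, dtype=bool)
        for j in neighbors:
            d2 = np.sum((pts - coords[j]) ** 2, axis=1)
            accessible &= d2 > expanded[j] ** 2
        atom_sasa[i] = 4.0 * np.pi * expanded[i] ** 2 * accessible.mean()

    out: dict[str, np.ndarray] = {}
    offset = 0
    for c in chains:
        n = c.atom_coords.shape[0]
        per_res = np.zeros(c.n_residues)
        np.add.at(per_res, c.atom_residue_index, atom_sasa[offset : offset + n])
        out[c.chain_id] = per_res
        offset += n
    return out


def residue_rsa(
    sasa: np.ndarray,
    residue_names: list[str],
    max_asa_table: dict[str, float] | None = None,
    cap_at_100: bool = False,
) -> np.ndarray:
    """RSA (%) = 100 * SASA / maxASA(residue type); unknown types fall back
    to the generic value with a warning."""
    table = max_asa_table if max_asa_table is not None else MAX_ASA_TIEN
    rsa = np.empty(len(residue_names))
    for i, name in enumerate(residue_names):
        if name not in table:
            warnings.warn(f"residue type {name!r} not in maxASA table; using generic value")
        rsa[i] = 100.0 * sasa[i] / table.get(name, table.get("UNK", 200.0))
    if cap_at_100:
        rsa = np.minimum(rsa, 100.0)
    return rsa


def delta_rsa_labels(
    chains: list[ChainStructure],
    focal_chain: str,
    threshold: float = DELTA_RSA_THRESHOLD,
    probe_radius: float = DEFAULT_PROBE_RADIUS,
    n_points: int = DEFAULT_N_POINTS,
    max_asa_table: dict[str, float] | None = None,
) -> np.ndarray:
    """Binary interface labels on the focal chain.

    label(i) = 1 iff RSA_isolated(i) - RSA_in_complex(i) > threshold, with
    RSA_isolated computed on the focal chain alone.  The inequality is
    strict: a change of exactly `threshold` is not an interface.
    """
    by_id = {c.chain_id: c for c in chains}
    if focal_chain not in by_id:
        raise KeyError(f"focal chain {focal_chain!r} not in complex")
    focal = by_id[focal_chain]
    sasa_complex = compute_sasa(chains, probe_radius, n_points)[focal_chain]
    sasa_isolated = compute_sasa([focal], probe_radius, n_points)[focal_chain]
    rsa_complex = residue_rsa(sasa_complex, focal.residue_names, max_asa_table)
    rsa_isolated = residue_rsa(sasa_isolated, focal.residue_names, max_asa_table)
    return (rsa_isolated - rsa_complex > threshold).astype(np.int8)


def map_to_parent(
    structure_labels: np.ndarray,
    structure_sequence: str,
    parent_sequence: str,
    parent_id: str = "",
    min_identity_pct: float = 90.0,
) -> InterfaceLabelTrack:
    """Transfer structure-derived labels to a full-length parent sequence.

    Global pairwise alignment; each structural residue aligned to a parent
    residue transfers its label there.  Structural labels aligned to gaps
    are dropped (counted in n_dropped_labels).  If alignment identity over
    the structural residues falls below `min_identity_pct`, the mapping is
    rejected — mirrors the >=90% curation filter.
    """
    from Bio import Align

    labels = np.asarray(structure_labels).ravel()
    if labels.size != len(structure_sequence):
        raise ValueError("labels and structure sequence length differ")

    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 2.0
    aligner.mismatch_score = -1.0
    aligner.open_gap_score = -5.0
    aligner.extend_gap_score = -0.5
    alignment = aligner.align(parent_sequence, structure_sequence)[0]

    L = len(parent_sequence)
    out = np.zeros(L, dtype=np.int8)
    mask = np.zeros(L, dtype=np.int8)
    matches = 0
    mapped = np.full(len(structure_sequence), -1)
    for (p0, p1), (s0, s1) in zip(*alignment.aligned):
        for off in range(p1 - p0):
            mapped[s0 + off] = p0 + off
            if parent_sequence[p0 + off] == structure_sequence[s0 + off]:
                matches += 1
    identity = 100.0 * matches / len(structure_sequence)
    if identity < min_identity_pct:
        raise ValueError(
            f"structure/parent alignment identity {identity:.1f}% below "
            f"{min_identity_pct}% floor; mapping rejected"
        )
    dropped = 0
    for s_idx, p_idx in enumerate(mapped):
        if p_idx < 0:
            if labels[s_idx]:
                dropped += 1
            continue
        mask[p_idx] = 1
        if labels[s_idx]:
            out[p_idx] = 1
    if dropped:
        warnings.warn(f"{dropped} labeled structural residue(s) aligned to gaps; dropped")
    return InterfaceLabelTrack(
        parent_id=parent_id,
        parent_length=L,
        labels=out,
        coverage_mask=mask,
        n_dropped_labels=dropped,
    )


def load_chains(path: str | Path) -> list[ChainStructure]:
    """Read a PDB or mmCIF file into ChainStructure objects.

    Hydrogens, waters and hetero records are excluded; alternate locations
    resolve to the highest-occupancy conformer.
    """
    import biotite.structure as struc
    import biotite.structure.io as strucio

    arr = strucio.load_structure(str(path), altloc="occupancy")
    arr = arr[~arr.hetero]
    arr = arr[arr.element != "H"]
    chains: list[ChainStructure] = []
    for chain_id in np.unique(arr.chain_id):
        sub = arr[arr.chain_id == chain_id]
        res_starts = struc.get_residue_starts(sub)
        names, numbers = [], []
        res_index = np.empty(sub.array_length(), dtype=np.int64)
        for ri, start in enumerate(res_starts):
            end = res_starts[ri + 1] if ri + 1 < len(res_starts) else sub.array_length()
            names.append(str(sub.res_name[start]))
            numbers.append(int(sub.res_id[start]))
            res_index[start:end] = ri
        chains.append(
            ChainStructure(
                chain_id=str(chain_id),
                residue_names=names,
                residue_numbers=numbers,
                atom_elements=[str(e) for e in sub.element],
                atom_residue_index=res_index,
                atom_coords=sub.coord.astype(np.float64),
            )
        )
    return chains
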