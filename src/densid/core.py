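"""Core domain containers shared across the toolkit.

The objects here are deliberately lightweight: plain dataclasses over numpy
arrays, with validation helpers where an invariant is cheap to check.  All
coordinates are in Angstrom; residue numbering is 1-based in files and
0-based in memory.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

# Fixed alphabetical one-letter amino-acid order; matches the HMMER3 amino
# alphabet so emission columns map 1:1 onto profile files.
AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {a: i for i, a in enumerate(AA_ALPHABET)}

NT_ALPHABET = "ACGU"

AA_THREE = {
    "A": "ALA", "C": "CYS", "D": "ASP", "E": "GLU", "F": "PHE",
    "G": "GLY", "H": "HIS", "I": "ILE", "K": "LYS", "L": "LEU",
    "M": "MET", "N": "ASN", "P": "PRO", "Q": "GLN", "R": "ARG",
    "S": "SER", "T": "THR", "V": "VAL", "W": "TRP", "Y": "TYR",
}
AA_ONE = {v: k for k, v in AA_THREE.items()}
# Single-letter residue names used for RNA nucleotides in coordinate files.
NT_THREE = {n: n for n in NT_ALPHABET}

PROTEIN_ANCHOR = "CA"
NUCLEOTIDE_ANCHOR = "P"

PROTEIN_BACKBONE = ("CA", "C", "N", "O")
NUCLEOTIDE_BACKBONE = ("P", "OP1", "OP2", "O5'")

# Swiss-Prot-like amino-acid composition (release-averaged frequencies),
# selectable as an alternative to the uniform background.
SWISSPROT_FREQS = np.array([
    0.0826, 0.0139, 0.0546, 0.0672, 0.0387, 0.0707, 0.0228, 0.0591,
    0.0580, 0.0965, 0.0241, 0.0406, 0.0475, 0.0393, 0.0553, 0.0665,
    0.0535, 0.0686, 0.0110, 0.0292,
])
SWISSPROT_FREQS = SWISSPROT_FREQS / SWISSPROT_FREQS.sum()


def uniform_background() -> np.ndarray:
    """Uniform distribution over the 20 amino acids."""
    return np.full(20, 1.0 / 20.0)


def get_background(name: str | np.ndarray | None) -> np.ndarray:
    """Resolve a background spec (None/'uniform'/'swissprot'/array) to a 20-vector."""
    if name is None or (isinstance(name, str) and name == "uniform"):
        return uniform_background()
    if isinstance(name, str):
        if name == "swissprot":
            return SWISSPROT_FREQS.copy()
        raise ValueError(f"unknown background {name!r}")
    bg = np.asarray(name, dtype=float)
    if bg.shape != (20,) or not np.isclose(bg.sum(), 1.0):
        raise ValueError("background must be a 20-vector summing to 1")
    return bg


@dataclass
class Residue:
    """One polymer residue: identity, atom coordinates, optional score.

    ``identity`` is a one-letter code from the 20 amino acids or the 4
    nucleotides, or ``"X"`` for unknown.  ``kind`` disambiguates e.g.
    alanine vs adenine.  ``score`` carries the [0, 1] per-residue confidence
    that round-trips through the B-factor column of coordinate files.
    """

    identity: str
    atoms: dict[str, np.ndarray] = field(default_factory=dict)
    kind: str = "protein"  # "protein" | "nucleotide"
    seq_pos: int | None = None  # 1-based position in the assigned target
    score: float | None = None

    @property
    def anchor_name(self) -> str:
        return PROTEIN_ANCHOR if self.kind == "protein" else NUCLEOTIDE_ANCHOR

    @property
    def anchor(self) -> np.ndarray | None:
        return self.atoms.get(self.anchor_name)

    def copy(self) -> "Residue":
        return Residue(
            identity=self.identity,
            atoms={k: v.copy() for k, v in self.atoms.items()},
            kind=self.kind,
            seq_pos=self.seq_pos,
            score=self.score,
        )


@dataclass
class Chain:
    chain_id: str
    residues: list[Residue] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.residues)

    def copy(self) -> "Chain":
        return Chain(self.chain_id, [r.copy() for r in self.residues])


@dataclass
class AtomicModel:
    """Ordered chains of residues, in one shared coordinate frame."""

    chains: list[Chain] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.chains)

    def __getitem__(self, chain_id: str) -> Chain:
        for ch in self.chains:
            if ch.chain_id == chain_id:
                return ch
        raise KeyError(chain_id)

    @property
    def n_residues(self) -> int:
        return sum(len(ch) for ch in self.chains)

    def residues(self):
        for ch in self.chains:
            yield from ch.residues

    def copy(self) -> "AtomicModel":
        return AtomicModel([ch.copy() for ch in self.chains])


@dataclass
class ResidueProfile:
    """Per-residue amino-acid probability matrix plus confidences for one chain.

    ``probs`` is L x 20 in the fixed alphabetical order; each row sums to 1.
    ``conf`` holds the per-residue confidence c(i) in [0, 1] that drives the
    profile-HMM transition probabilities.
    """

    chain_id: str
    probs: np.ndarray
    conf: np.ndarray

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        self.conf = np.asarray(self.conf, dtype=float)
        self.validate()

    def __len__(self) -> int:
        return self.probs.shape[0]

    def validate(self) -> None:
        if self.probs.ndim != 2 or self.probs.shape[1] != 20:
            raise ValueError("probs must be an L x 20 matrix")
        if self.conf.shape != (self.probs.shape[0],):
            raise ValueError("conf length must equal the number of rows of probs")
        if np.any(self.probs < 0):
            raise ValueError("probabilities must be non-negative")
        sums = self.probs.sum(axis=1)
        if np.any(np.abs(sums - 1.0) > 1e-6):
            bad = int(np.argmax(np.abs(sums - 1.0)))
            raise ValueError(f"row {bad} of probs sums to {sums[bad]:.6g}, not 1")
        if np.any((self.conf < 0) | (self.conf > 1)):
            bad = int(np.argmax((self.conf < 0) | (self.conf > 1)))
            raise ValueError(f"confidence at index {bad} outside [0, 1]")


@dataclass
class SequenceEntry:
    id: str
    sequence: str
    description: str = ""


@dataclass
class SequenceDatabase:
    """Ordered protein sequence collection (e.g. a proteome) with unique ids."""

    entries: list[SequenceEntry] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for e in self.entries:
            if e.id in seen:
                raise ValueError(f"duplicate sequence id {e.id!r}")
            seen.add(e.id)
            if not e.sequence:
                raise ValueError(f"empty sequence for id {e.id!r}")

    def __len__(self) -> int:
        return len(self.entries)

    def __getitem__(self, key: int | str) -> SequenceEntry:
        if isinstance(key, int):
            return self.entries[key]
        for e in self.entries:
            if e.id == key:
                return e
        raise KeyError(key)


@dataclass
class DensityMap:
    """3-D density grid with per-axis voxel size and an origin, both in A.

    ``grid[i, j, k]`` sits at ``origin + (i * vx, j * vy, k * vz)``.
    """

    grid: np.ndarray
    voxel_size: np.ndarray
    origin: np.ndarray

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=np.float32)
        self.voxel_size = np.asarray(self.voxel_size, dtype=float).reshape(3)
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        if self.grid.ndim != 3 or min(self.grid.shape) < 2:
            raise ValueError("grid must be 3-D with at least 2 voxels per axis")
        if np.any(self.voxel_size <= 0):
            raise ValueError("voxel sizes must be positive")

    def world_to_grid(self, xyz: np.ndarray) -> np.ndarray:
        """Fractional grid coordinates of world positions (A)."""
        return (np.asarray(xyz, dtype=float) - self.origin) / self.voxel_size
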