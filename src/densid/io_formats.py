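"""Readers and writers for the standard formats the toolkit touches.

Coordinate models go through gemmi (PDB and mmCIF), density maps through
gemmi's MRC2014 support, and sequences through plain FASTA.  The tabular
profile format is the toolkit's own interchange for per-residue amino-acid
probability matrices: tab-separated text with one row per residue —
chain_id, residue_index (1-based), confidence, then 20 probabilities in
fixed alphabetical order (A, C, D, ..., Y).

The per-residue confidence score lives in the B-factor column of coordinate
files: it is written as-is (a value in [0, 1]) and surfaced again on read
when every B-factor in the file lies in that range.
"""

from __future__ import annotations

import os

import gemmi
import numpy as np

from .core import (
    AA_ONE,
    AA_THREE,
    NT_ALPHABET,
    AtomicModel,
    Chain,
    DensityMap,
    Residue,
    ResidueProfile,
    SequenceDatabase,
    SequenceEntry,
)

_AA_LETTERS = set("ACDEFGHIKLMNPQRSTVWYX")


# ---------------------------------------------------------------------------
# Atomic models (PDB / mmCIF)
# ---------------------------------------------------------------------------

def _residue_from_gemmi(gres: gemmi.Residue) -> Residue:
    name = gres.name.strip().upper()
    if name in AA_ONE:
        identity, kind = AA_ONE[name], "protein"
    elif name in NT_ALPHABET and len(name) == 1:
        identity, kind = name, "nucleotide"
    elif name in {"DA", "DC", "DG", "DT", "DU"}:
        identity = "U" if name == "DT" else name[1]
        kind = "nucleotide"
    else:
        identity, kind = "X", "protein"
    atoms: dict[str, np.ndarray] = {}
    bvals: dict[str, float] = {}
    for at in gres:
        atoms[at.name] = np.array([at.pos.x, at.pos.y, at.pos.z])
        bvals[at.name] = at.b_iso
    res = Residue(identity=identity, atoms=atoms, kind=kind)
    if bvals:
        # score candidate from the anchor atom's B-factor; validated by caller
        anchor = res.anchor_name
        res.score = float(bvals.get(anchor, next(iter(bvals.values()))))
    return res


def read_model(path: str | os.PathLike, format: str = "auto") -> AtomicModel:
    """Read a PDB or mmCIF file into an :class:`AtomicModel`.

    B-factors are surfaced as per-residue scores when every value in the
    file lies in [0, 1]; otherwise scores are left unset.
    """
    path = os.fspath(path)
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    try:
        if format == "auto":
            st = gemmi.read_structure(path)
        else:
            fmt = gemmi.CoorFormat.Pdb if format == "pdb" else gemmi.CoorFormat.Mmcif
            st = gemmi.read_structure(path, format=fmt)
    except (RuntimeError, ValueError) as exc:
        raise ValueError(f"cannot parse {path} as a coordinate file: {exc}") from exc
    if len(st) == 0:
        raise ValueError(f"{path}: no models in file")
    st.setup_entities()
    gmodel = st[0]
    model = AtomicModel()
    all_scores: list[float] = []
    for gch in gmodel:
        chain = Chain(chain_id=gch.name)
        for gres in gch:
            if gres.is_water():
                continue
            res = _residue_from_gemmi(gres)
            if res.score is not None:
                all_scores.append(res.score)
            chain.residues.append(res)
        if chain.residues:
            model.chains.append(chain)
    if model.n_residues == 0:
        raise ValueError(f"{path}: empty model")
    # B-factors only carry scores when the whole file uses the [0, 1] range.
    scores_valid = all_scores and all(0.0 <= s <= 1.0 for s in all_scores)
    for res in model.residues():
        res.score = round(res.score, 6) if (scores_valid and res.score is not None) else None
    return model


def write_model(model: AtomicModel, path: str | os.PathLike, format: str | None = None) -> None:
    """Write a model to PDB or mmCIF, storing per-residue scores as B-factors.

    Unset scores are written as 0.00.  The format is taken from the file
    extension when not given explicitly.
    """
    path = os.fspath(path)
    if format is None:
        format = "mmcif" if path.endswith((".cif", ".mmcif")) else "pdb"
    if model.n_residues == 0:
        raise ValueError("refusing to write an empty model")
    st = gemmi.Structure()
    st.name = "densid"
    gmodel = gemmi.Model("1")
    for chain in model.chains:
        gch = gemmi.Chain(chain.chain_id)
        for i, res in enumerate(chain.residues):
            if not res.atoms:
                raise ValueError(
                    f"residue {i} of chain {chain.chain_id} has no atoms"
                )
            gres = gemmi.Residue()
            gres.het_flag = "A"  # polymer residue even in 1-residue chains
            if res.kind == "protein":
                gres.name = AA_THREE.get(res.identity, "UNK")
            else:
                gres.name = res.identity if res.identity in NT_ALPHABET else "N"
            gres.seqid = gemmi.SeqId(i + 1, " ")
            b = 0.0 if res.score is None else float(res.score)
            for name, xyz in res.atoms.items():
                at = gemmi.Atom()
                at.name = name
                at.pos = gemmi.Position(*map(float, xyz))
                at.b_iso = round(b, 2)
                at.occ = 1.0
                at.element = gemmi.Element(name.strip("0123456789'*")[:1] or "C")
                gres.add_atom(at)
            gch.add_residue(gres)
        gmodel.add_chain(gch)
    st.add_model(gmodel)
    st.setup_entities()
    if format == "pdb":
        st.write_pdb(path)
    elif format == "mmcif":
        st.make_mmcif_document().write_file(path)
    else:
        raise ValueError(f"unknown model format {format!r}")


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | os.PathLike) -> SequenceDatabase:
    """Read a FASTA file; sequences are uppercased, ids must be unique."""
    entries: list[SequenceEntry] = []
    cur_id: str | None = None
    cur_desc = ""
    cur_seq: list[str] = []
    seen: set[str] = set()

    def flush() -> None:
        if cur_id is None:
            return
        if cur_id in seen:
            raise ValueError(f"duplicate FASTA id {cur_id!r}")
        seen.add(cur_id)
        entries.append(SequenceEntry(cur_id, "".join(cur_seq).upper(), cur_desc))

    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith(">"):
                flush()
                header = line[1:].strip()
                parts = header.split(None, 1)
                cur_id = parts[0] if parts else ""
                cur_desc = parts[1] if len(parts) > 1 else ""
                cur_seq = []
            elif line.strip():
                cur_seq.append(line.strip())
    flush()
    return SequenceDatabase(entries)


def write_fasta(db: SequenceDatabase, path: str | os.PathLike, width: int = 60) -> None:
    with open(path, "w") as fh:
        for e in db.entries:
            header = f">{e.id}" + (f" {e.description}" if e.description else "")
            fh.write(header + "\n")
            for i in range(0, len(e.sequence), width):
                fh.write(e.sequence[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Density maps (MRC2014 via gemmi)
# ---------------------------------------------------------------------------

_ORIGIN_WORDS = (50, 51, 52)


def read_map(path: str | os.PathLike) -> DensityMap:
    """Read an MRC2014 map; voxel size from cell/grid, origin from the header."""
    try:
        ccp4 = gemmi.read_ccp4_map(os.fspath(path))
    except (RuntimeError, ValueError) as exc:
        raise ValueError(f"cannot read {path} as MRC: {exc}") from exc
    grid = np.array(ccp4.grid, copy=True)
    voxel = np.array(ccp4.grid.spacing)
    origin = np.array([ccp4.header_float(w) for w in _ORIGIN_WORDS])
    return DensityMap(grid=grid, voxel_size=voxel, origin=origin)


def write_map(dmap: DensityMap, path: str | os.PathLike) -> None:
    ccp4 = gemmi.Ccp4Map()
    ccp4.grid = gemmi.FloatGrid(np.ascontiguousarray(dmap.grid, dtype=np.float32))
    nx, ny, nz = dmap.grid.shape
    vx, vy, vz = dmap.voxel_size
    ccp4.grid.unit_cell = gemmi.UnitCell(nx * vx, ny * vy, nz * vz, 90, 90, 90)
    ccp4.grid.spacegroup = gemmi.SpaceGroup("P1")
    ccp4.update_ccp4_header()
    for w, v in zip(_ORIGIN_WORDS, dmap.origin):
        ccp4.set_header_float(w, float(v))
    ccp4.write_ccp4_map(os.fspath(path))


# ---------------------------------------------------------------------------
# Tabular residue-probability profiles
# ---------------------------------------------------------------------------

def read_profile_table(path: str | os.PathLike) -> list[ResidueProfile]:
    """Read the tab-separated profile table into per-chain profiles.

    Rows are grouped by chain_id in file order.  Probability rows within
    1e-3 of summing to 1 are renormalized exactly; larger deviations are an
    error.
    """
    order: list[str] = []
    probs: dict[str, list[np.ndarray]] = {}
    confs: dict[str, list[float]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 23:
                raise ValueError(
                    f"{path}:{lineno}: expected 23 tab-separated fields, got {len(fields)}"
                )
            chain_id = fields[0]
            conf = float(fields[2])
            if not 0.0 <= conf <= 1.0:
                raise ValueError(f"{path}:{lineno}: confidence {conf} outside [0, 1]")
            row = np.array([float(x) for x in fields[3:]])
            s = row.sum()
            if abs(s - 1.0) > 1e-3:
                raise ValueError(
                    f"{path}:{lineno}: probability row sums to {s:.6g}, not 1"
                )
            row = row / s
            if chain_id not in probs:
                order.append(chain_id)
                probs[chain_id] = []
                confs[chain_id] = []
            probs[chain_id].append(row)
            confs[chain_id].append(conf)
    return [
        ResidueProfile(chain_id=cid, probs=np.array(probs[cid]), conf=np.array(confs[cid]))
        for cid in order
    ]


def write_profile_table(profiles: list[ResidueProfile], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for rp in profiles:
            for i in range(len(rp)):
                cells = [rp.chain_id, str(i + 1), f"{rp.conf[i]:.6f}"]
                cells += [f"{p:.8g}" for p in rp.probs[i]]
                fh.write("\t".join(cells) + "\n")
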