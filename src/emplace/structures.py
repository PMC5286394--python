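"""Atomic structures, rigid-body segmentation, coarse-graining, crosslink tables.

Structures are held Cα-friendly but keep every atom read from the file, with
author residue numbering preserved verbatim (crosslink tables cite author
numbering).  Rigid bodies are named residue-range selections; the coarse-grained
bead model converts each 10-residue stretch of a chain (or body) to one bead
whose radius encloses the mean per-residue volume.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import numpy as np
import pandas as pd

#: mean amino-acid volume, Å^3 per residue (0.135 nm^3)
RESIDUE_VOLUME_A3 = 135.0

#: average residue mass in Da, used as the per-Cα weight in density simulation
RESIDUE_MASS_DA = 110.0


class SchemaError(ValueError):
    """A delimited table is missing required columns."""


class ParseError(ValueError):
    """A structure or map file could not be parsed."""


@dataclass
class AtomicModel:
    """A molecular model as parallel per-atom arrays.

    chain : array of str, per-atom chain id
    resnum : int array, author residue numbers (unique within a chain)
    resname, atomname : arrays of str
    xyz : (n, 3) float array, Å
    subunit_of_chain : chain id -> subunit (protein) name
    copy_of_chain : chain id -> copy index (1 or 2 for duplicated subunits)
    """

    chain: np.ndarray
    resnum: np.ndarray
    resname: np.ndarray
    atomname: np.ndarray
    xyz: np.ndarray
    subunit_of_chain: dict[str, str] = field(default_factory=dict)
    copy_of_chain: dict[str, int] = field(default_factory=dict)

    def __post_init__(self):
        self.chain = np.asarray(self.chain, dtype=object)
        self.resnum = np.asarray(self.resnum, dtype=int)
        self.resname = np.asarray(self.resname, dtype=object)
        self.atomname = np.asarray(self.atomname, dtype=object)
        self.xyz = np.asarray(self.xyz, dtype=float)
        n = len(self.chain)
        if not (len(self.resnum) == len(self.resname) == len(self.atomname) == n
                and self.xyz.shape == (n, 3)):
            raise ValueError("per-atom arrays have inconsistent lengths")
        if n and not np.all(np.isfinite(self.xyz)):
            raise ValueError("non-finite atom coordinates")
        for c in self.chains():
            if c not in self.subunit_of_chain:
                self.subunit_of_chain[c] = c
            if c not in self.copy_of_chain:
                self.copy_of_chain[c] = 1

    @property
    def n_atoms(self) -> int:
        return len(self.chain)

    def chains(self) -> list[str]:
        seen: dict[str, None] = {}
        for c in self.chain:
            seen.setdefault(c, None)
        return list(seen)

    def ca_mask(self) -> np.ndarray:
        return np.asarray([a == "CA" for a in self.atomname], dtype=bool)

    def ca_model(self) -> "AtomicModel":
        """Cα-only view (copy) of the model."""
        return self.subset(self.ca_mask())

    def subset(self, mask: np.ndarray) -> "AtomicModel":
        return AtomicModel(
            chain=self.chain[mask],
            resnum=self.resnum[mask],
            resname=self.resname[mask],
            atomname=self.atomname[mask],
            xyz=self.xyz[mask],
            subunit_of_chain=dict(self.subunit_of_chain),
            copy_of_chain=dict(self.copy_of_chain),
        )

    def select(self, chain: str | None = None, resnums=None,
               atomname: str | None = None) -> np.ndarray:
        """Boolean mask of atoms matching the given criteria."""
        m = np.ones(self.n_atoms, dtype=bool)
        if chain is not None:
            m &= self.chain == chain
        if resnums is not None:
            rset = set(int(r) for r in np.atleast_1d(resnums))
            m &= np.asarray([int(r) in rset for r in self.resnum])
        if atomname is not None:
            m &= self.atomname == atomname
        return m

    def transformed(self, pose) -> "AtomicModel":
        out = dataclasses.replace(self)
        out.xyz = pose.apply(self.xyz)
        return out


@dataclass(frozen=True)
class RigidBody:
    """A named rigid domain: residue ranges of one or more chains.

    members: tuple of (chain id, first residue, last residue), inclusive.
    linker_neighbors: tuple of (other body name, number of linker residues
    between this body and the neighbor along the shared chain).
    """

    name: str
    members: tuple[tuple[str, int, int], ...]
    linker_neighbors: tuple[tuple[str, int], ...] = ()

    def atom_mask(self, model: AtomicModel) -> np.ndarray:
        m = np.zeros(model.n_atoms, dtype=bool)
        for chain, lo, hi in self.members:
            m |= (model.chain == chain) & (model.resnum >= lo) & (model.resnum <= hi)
        return m

    def contains(self, chain: str, resnum: int) -> bool:
        return any(c == chain and lo <= resnum <= hi for c, lo, hi in self.members)


@dataclass
class BeadModel:
    """Coarse-grained representation: one bead per ≤`stretch`-residue run.

    centers : (m, 3) Å; radii : (m,) Å; parent : per-bead body (or chain) name;
    spans : per-bead (chain, first resnum, last resnum, n residues).
    """

    centers: np.ndarray
    radii: np.ndarray
    parent: list[str]
    spans: list[tuple[str, int, int, int]]

    def __post_init__(self):
        self.centers = np.asarray(self.centers, dtype=float).reshape(-1, 3)
        self.radii = np.asarray(self.radii, dtype=float).reshape(-1)

    @property
    def n_beads(self) -> int:
        return len(self.radii)

    @property
    def weights(self) -> np.ndarray:
        """Per-bead mass in Da (residue count × mean residue mass)."""
        return np.asarray([s[3] for s in self.spans], dtype=float) * RESIDUE_MASS_DA


@dataclass(frozen=True)
class Crosslink:
    """One identified residue–residue crosslink."""

    protein1: str
    residue1: int
    protein2: str
    residue2: int
    linker: str = "DSS"
    ld_score: float = 30.0

    def __post_init__(self):
        if self.residue1 <= 0 or self.residue2 <= 0:
            raise ValueError("residue numbers must be positive")
        if not np.isfinite(self.ld_score):
            raise ValueError("ld score must be finite")

    @property
    def is_interlink(self) -> bool:
        return self.protein1 != self.protein2

    @property
    def is_dimeric(self) -> bool:
        """Same residue linked to itself — only possible across two copies."""
        return self.protein1 == self.protein2 and self.residue1 == self.residue2

    def unordered_key(self):
        a = (self.protein1, self.residue1)
        b = (self.protein2, self.residue2)
        return (min(a, b), max(a, b), self.linker)


# ---------------------------------------------------------------------------
# structure I/O


def read_structure(path, fmt: str | None = None,
                   subunit_of_chain: dict[str, str] | None = None,
                   copy_of_chain: dict[str, int] | None = None) -> AtomicModel:
    """Read a PDB or mmCIF file into an :class:`AtomicModel`.

    Multi-model files use the first model.  Author residue numbering is kept.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        if fmt == "pdb":
            st = gemmi.read_pdb(str(path))
        elif fmt in ("mmcif", "cif"):
            st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Mmcif)
        else:
            st = gemmi.read_structure(str(path))
    except (RuntimeError, ValueError) as exc:
        raise ParseError(f"cannot parse structure file {path}: {exc}") from exc
    if len(st) == 0:
        raise ValueError(f"structure file {path} contains no model")
    model = st[0]
    chains, resnums, resnames, atomnames, xyz = [], [], [], [], []
    for ch in model:
        for res in ch:
            for atom in res:
                chains.append(ch.name)
                resnums.append(res.seqid.num)
                resnames.append(res.name)
                atomnames.append(atom.name)
                xyz.append([atom.pos.x, atom.pos.y, atom.pos.z])
    if not chains:
        raise ValueError(f"structure file {path} contains no atoms")
    return AtomicModel(
        chain=np.asarray(chains, dtype=object),
        resnum=np.asarray(resnums),
        resname=np.asarray(resnames, dtype=object),
        atomname=np.asarray(atomnames, dtype=object),
        xyz=np.asarray(xyz),
        subunit_of_chain=dict(subunit_of_chain or {}),
        copy_of_chain=dict(copy_of_chain or {}),
    )


def write_structure(model: AtomicModel, path) -> None:
    """Write a model as PDB (by extension .pdb) or mmCIF (.cif)."""
    st = gemmi.Structure()
    st.name = "emplace"
    gm = gemmi.Model("1")
    for cname in model.chains():
        ch = gemmi.Chain(cname)
        mask = model.chain == cname
        idx = np.flatnonzero(mask)
        current = None
        res = None
        for i in idx:
            rn = int(model.resnum[i])
            if rn != current:
                if res is not None:
                    ch.add_residue(res)
                res = gemmi.Residue()
                res.name = str(model.resname[i])
                res.seqid = gemmi.SeqId(rn, " ")
                current = rn
            atom = gemmi.Atom()
            atom.name = str(model.atomname[i])
            atom.element = gemmi.Element("C")
            x, y, z = model.xyz[i]
            atom.pos = gemmi.Position(float(x), float(y), float(z))
            res.add_atom(atom)
        if res is not None:
            ch.add_residue(res)
        gm.add_chain(ch)
    st.add_model(gm)
    st.setup_entities()
    path = Path(path)
    if path.suffix.lower() in (".cif", ".mmcif"):
        st.make_mmcif_document().write_file(str(path))
    else:
        st.write_pdb(str(path))


# ---------------------------------------------------------------------------
# crosslink tables

_COLUMN_ALIASES = {
    "protein1": "protein1",
    "abspos1": "residue1",
    "residue1": "residue1",
    "protein2": "protein2",
    "abspos2": "residue2",
    "residue2": "residue2",
    "linker": "linker",
    "ldscore": "ld_score",
    "ld-score": "ld_score",
    "ld_score": "ld_score",
}

_REQUIRED = ("protein1", "residue1", "protein2", "residue2", "linker", "ld_score")


def read_crosslink_table(path, min_ld: float = 30.0) -> list[Crosslink]:
    """Read an xQuest-style delimited crosslink table and filter by confidence.

    Keeps links with ld_score >= min_ld (the high-confidence threshold is
    inclusive); duplicate unordered residue pairs with the same linker collapse
    to one record keeping the maximum score.
    """
    df = pd.read_csv(path, sep=None, engine="python")
    colmap = {}
    for col in df.columns:
        key = str(col).strip().lower().replace(" ", "")
        key = _COLUMN_ALIASES.get(key, _COLUMN_ALIASES.get(key.replace("-", "_")))
        if key:
            colmap[col] = key
    df = df.rename(columns=colmap)
    missing = [c for c in _REQUIRED if c not in df.columns]
    if missing:
        raise SchemaError(f"crosslink table missing required columns: {missing}")
    best: dict[tuple, Crosslink] = {}
    for row in df.itertuples(index=False):
        link = Crosslink(
            protein1=str(row.protein1), residue1=int(row.residue1),
            protein2=str(row.protein2), residue2=int(row.residue2),
            linker=str(row.linker), ld_score=float(row.ld_score),
        )
        if link.ld_score < min_ld:
            continue
        key = link.unordered_key()
        if key not in best or link.ld_score > best[key].ld_score:
            best[key] = link
    return list(best.values())


def write_crosslink_table(links, path, sep: str = "\t") -> None:
    df = pd.DataFrame(
        [(l.protein1, l.residue1, l.protein2, l.residue2, l.linker, l.ld_score)
         for l in links],
        columns=["Protein1", "AbsPos1", "Protein2", "AbsPos2", "linker", "ld-score"],
    )
    df.to_csv(path, sep=sep, index=False)


# ---------------------------------------------------------------------------
# segmentation and coarse-graining


def segment_rigid_bodies(model: AtomicModel, body_defs) -> list[RigidBody]:
    """Build rigid bodies from residue-range definitions.

    body_defs: mapping name -> list of (chain, first, last) ranges, or a list of
    {"name": ..., "members": [(chain, first, last), ...]} dicts.  Ranges of
    distinct bodies within one chain must be disjoint.  Linker neighbor counts
    are the sequence gaps between consecutive bodies of one chain.
    """
    if isinstance(body_defs, dict):
        defs = [(name, [tuple(r) for r in ranges]) for name, ranges in body_defs.items()]
    else:
        defs = [(d["name"], [tuple(r) for r in d["members"]]) for d in body_defs]

    per_chain: dict[str, list[tuple[int, int, str]]] = {}
    for name, ranges in defs:
        for chain, lo, hi in ranges:
            lo, hi = int(lo), int(hi)
            if hi < lo:
                raise ValueError(f"body {name}: inverted range {lo}-{hi}")
            for plo, phi, pname in per_chain.get(chain, []):
                if lo <= phi and plo <= hi:
                    raise ValueError(
                        f"bodies {pname} and {name} overlap on chain {chain}: "
                        f"{plo}-{phi} vs {lo}-{hi}")
            per_chain.setdefault(chain, []).append((lo, hi, name))

    # linker gaps between consecutive bodies along each chain
    neighbors: dict[str, list[tuple[str, int]]] = {name: [] for name, _ in defs}
    for chain, ranges in per_chain.items():
        ranges.sort()
        for (lo1, hi1, n1), (lo2, hi2, n2) in zip(ranges, ranges[1:]):
            if n1 == n2:
                continue
            gap = lo2 - hi1 - 1
            neighbors[n1].append((n2, gap))
            neighbors[n2].append((n1, gap))

    return [RigidBody(name=name, members=tuple((c, int(lo), int(hi)) for c, lo, hi in ranges),
                      linker_neighbors=tuple(neighbors[name]))
            for name, ranges in defs]


def coarse_grain(model: AtomicModel, stretch: int = 10,
                 bodies: list[RigidBody] | None = None) -> BeadModel:
    """Convert each `stretch`-residue run of Cα atoms to one bead.

    Bead center = centroid of the member Cα atoms; bead radius = radius of the
    sphere whose volume is span × 135 Å³ (mean amino-acid volume).  When
    `bodies` is given, stretches never cross body boundaries and beads are
    parented to their body; otherwise beads are parented to their chain.
    A trailing stretch shorter than `stretch` is allowed.
    """
    if stretch < 1:
        raise ValueError("stretch must be >= 1")
    ca = model.ca_model()
    if ca.n_atoms == 0:
        raise ValueError("model has no CA atoms to coarse-grain")

    groups: list[tuple[str, str, np.ndarray]] = []  # (parent, chain, atom idx)
    if bodies is None:
        for chain in ca.chains():
            idx = np.flatnonzero(ca.chain == chain)
            idx = idx[np.argsort(ca.resnum[idx], kind="stable")]
            groups.append((chain, chain, idx))
    else:
        for body in bodies:
            for chain, lo, hi in body.members:
                sel = (ca.chain == chain) & (ca.resnum >= lo) & (ca.resnum <= hi)
                idx = np.flatnonzero(sel)
                if len(idx) == 0:
                    continue
                idx = idx[np.argsort(ca.resnum[idx], kind="stable")]
                groups.append((body.name, chain, idx))

    centers, radii, parent, spans = [], [], [], []
    for pname, chain, idx in groups:
        if len(idx) == 0:
            raise ValueError(f"chain {chain} has no CA atoms")
        for start in range(0, len(idx), stretch):
            chunk = idx[start:start + stretch]
            span = len(chunk)
            centers.append(ca.xyz[chunk].mean(axis=0))
            radii.append((3.0 * span * RESIDUE_VOLUME_A3 / (4.0 * np.pi)) ** (1.0 / 3.0))
            parent.append(pname)
            spans.append((chain, int(ca.resnum[chunk[0]]), int(ca.resnum[chunk[-1]]), span))
    return BeadModel(centers=np.asarray(centers), radii=np.asarray(radii),
                     parent=parent, spans=spans)
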