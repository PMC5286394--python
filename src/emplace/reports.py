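"""End-stage comparisons: superposition RMSD, crosslink network summaries,
and the mirrored-map (handedness) significance report."""

from __future__ import annotations

import json

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from emplace.fitting import FitOptions, handedness_test
from emplace.geom import Pose, quat_from_rotation
from emplace.structures import AtomicModel, Crosslink


def superpose_rmsd(model_a: AtomicModel, model_b: AtomicModel,
                   atomname: str = "CA") -> dict:
    """Least-squares rigid superposition of paired atoms; RMSD in Å.

    Atoms pair by (chain, residue number, atom name) over the selection.  The
    optimal rotation is proper (no reflection).  Returns rmsd, n_atoms, and
    the transform mapping A onto B.
    """
    def _index(model):
        out = {}
        for i in range(model.n_atoms):
            if atomname is not None and model.atomname[i] != atomname:
                continue
            out[(model.chain[i], int(model.resnum[i]), model.atomname[i])] = i
        return out

    ia = _index(model_a)
    ib = _index(model_b)
    keys = [k for k in ia if k in ib]
    if len(keys) < 3:
        raise ValueError(f"only {len(keys)} paired atoms; need at least 3")
    pa = model_a.xyz[[ia[k] for k in keys]]
    pb = model_b.xyz[[ib[k] for k in keys]]
    ca = pa.mean(axis=0)
    cb = pb.mean(axis=0)
    # Kabsch via scipy; align_vectors returns the proper rotation mapping
    # (pa - ca) onto (pb - cb) in the least-squares sense
    rot, _ = Rotation.align_vectors(pb - cb, pa - ca)
    moved = rot.apply(pa - ca) + cb
    rmsd = float(np.sqrt(((moved - pb) ** 2).sum(axis=1).mean()))
    transform = Pose(quaternion=quat_from_rotation(rot),
                     translation=tuple(cb - rot.apply(ca)))
    return {"rmsd": rmsd, "n_atoms": len(keys), "transform": transform}


def crosslink_network_summary(crosslinks: list[Crosslink]) -> dict:
    """Counts by category plus a per-protein-pair link-count matrix.

    Inter/intra partition the unique links by protein identity; dimeric links
    (same residue to itself, necessarily across copies) are additionally
    counted in n_dimeric.
    """
    n_inter = sum(1 for l in crosslinks if l.is_interlink)
    n_intra = sum(1 for l in crosslinks if not l.is_interlink)
    n_dimeric = sum(1 for l in crosslinks if l.is_dimeric)
    proteins = sorted({p for l in crosslinks for p in (l.protein1, l.protein2)})
    matrix = pd.DataFrame(0, index=proteins, columns=proteins, dtype=int)
    for l in crosslinks:
        a, b = sorted((l.protein1, l.protein2))
        matrix.loc[a, b] += 1
        if a != b:
            matrix.loc[b, a] += 1
    return {"n_inter": n_inter, "n_intra": n_intra, "n_dimeric": n_dimeric,
            "matrix": matrix}


def handedness_report(body, dmap, seed: int = 0,
                      options: FitOptions | None = None) -> dict:
    """Mirrored-map fit-significance comparison, serializable to JSON.

    Emits the best-fit P-value and NCC per hand, the score histogram data
    (all library NCCs), and the verdict.
    """
    result = handedness_test(body, dmap, seed=seed, options=options)
    return {
        "pvalue_native": result["pvalue_native"],
        "pvalue_mirrored": result["pvalue_mirrored"],
        "ncc_native": result["ncc_native"],
        "ncc_mirrored": result["ncc_mirrored"],
        "log10_pvalue_ratio": result["log10_pvalue_ratio"],
        "preferred_hand": result["preferred_hand"],
        "scores_native": [f.ncc for f in result["library_native"].fits],
        "scores_mirrored": [f.ncc for f in result["library_mirrored"].fits],
    }


def handedness_report_json(report: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(report, fh, indent=1)


def handedness_report_from_json(path) -> dict:
    with open(path) as fh:
        return json.load(fh)
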