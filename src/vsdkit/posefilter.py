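"""Rescoring filter for receptor/ligand docking poses, ensemble clustering
and per-residue fluctuation analysis.

The filter re-scores rigid-body docking solutions of a gating-modifier
toxin bound to a membrane-embedded voltage-sensor domain with six criteria:

1. buried contact area > 250 A^2 (Shrake-Rupley SASA difference / 2);
2. at least three "good" contacts (H-bonds, ionic bridges, aromatic
   stacking), judged on heavy-atom geometry;
3. hydrophobic/hydrophilic complementarity of the contact surface > 0.4,
   a sign-agreement score over molecular-hydrophobicity-potential samples;
4. an ionic anchor: one of the toxin residues K24/K28/R29 bridges to a
   receptor Asp/Glu carboxylate;
5. toxin residue I27 within 4 A of the receptor (its amide signal vanishes
   on complex formation);
6. the W11/F12/W16 hydrophobic cluster points toward the membrane
   (micelle) side of the frame.

Geometric cutoffs are standard literature values (the criteria thresholds
themselves are the published ones) and all live in :class:`FilterConfig`.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile
from scipy.spatial.distance import cdist
from scipy.spatial.transform import Rotation

__all__ = [
    "MembraneFrame",
    "Pose",
    "FilterConfig",
    "FilterReport",
    "load_structure",
    "save_structure",
    "load_pose",
    "contact_area",
    "good_contacts",
    "hydrophobic_complementarity",
    "ionic_anchor_check",
    "proximity_check",
    "orientation_check",
    "filter_poses",
    "gromos_cluster",
    "rmsf",
]


# ---------------------------------------------------------------- structures

def load_structure(path) -> struc.AtomArray:
    """Read the first model of a PDB file into an AtomArray."""
    pdb = PDBFile.read(str(path))
    arr = pdb.get_structure(model=1)
    return arr


def save_structure(path, atoms: struc.AtomArray) -> None:
    pdb = PDBFile()
    pdb.set_structure(atoms)
    pdb.write(str(path))


def _heavy(atoms: struc.AtomArray) -> struc.AtomArray:
    return atoms[atoms.element != "H"]


@dataclass(frozen=True)
class MembraneFrame:
    """Membrane (micelle) reference frame for orientation checks.

    Planar mode: ``normal`` is the outward (extracellular) unit normal and
    ``offset`` the boundary-plane offset along it (A).  Sphere mode stands
    in for a micelle: ``sphere_center``/``sphere_radius`` (24 A by default
    when used).
    """

    normal: tuple = (0.0, 0.0, 1.0)
    offset: float = 0.0
    sphere_center: tuple | None = None
    sphere_radius: float = 24.0

    def __post_init__(self):
        n = np.asarray(self.normal, dtype=float)
        if not np.isclose(np.linalg.norm(n), 1.0, atol=1e-6):
            raise ValueError("membrane normal must be unit length")

    def inward_direction(self, from_point: np.ndarray) -> np.ndarray:
        """Unit vector pointing into the membrane/micelle from a point."""
        if self.sphere_center is not None:
            v = np.asarray(self.sphere_center, dtype=float) - from_point
            norm = np.linalg.norm(v)
            if norm == 0:
                raise ValueError("point coincides with the micelle center")
            return v / norm
        return -np.asarray(self.normal, dtype=float)

    def to_json(self) -> str:
        d = {"normal": list(self.normal), "offset": self.offset}
        if self.sphere_center is not None:
            d["sphere_center"] = list(self.sphere_center)
            d["sphere_radius"] = self.sphere_radius
        return json.dumps(d)

    @classmethod
    def from_json(cls, text: str) -> "MembraneFrame":
        d = json.loads(text)
        return cls(
            normal=tuple(d.get("normal", (0, 0, 1))),
            offset=float(d.get("offset", 0.0)),
            sphere_center=tuple(d["sphere_center"]) if "sphere_center" in d else None,
            sphere_radius=float(d.get("sphere_radius", 24.0)),
        )


@dataclass
class Pose:
    """A receptor/ligand pose in a shared membrane coordinate frame."""

    receptor: struc.AtomArray
    ligand: struc.AtomArray
    frame: MembraneFrame = field(default_factory=MembraneFrame)
    name: str = "pose"

    def __post_init__(self):
        for part, label in ((self.receptor, "receptor"), (self.ligand, "ligand")):
            if part.array_length() == 0:
                raise ValueError(f"{label} is empty")
            if not np.all(np.isfinite(part.coord)):
                raise ValueError(f"{label} has non-finite coordinates")


def load_pose(receptor_path, ligand_path, frame_path=None, name=None) -> Pose:
    frame = MembraneFrame()
    if frame_path is not None and Path(frame_path).exists():
        frame = MembraneFrame.from_json(Path(frame_path).read_text())
    return Pose(
        receptor=_heavy(load_structure(receptor_path)),
        ligand=_heavy(load_structure(ligand_path)),
        frame=frame,
        name=name or Path(ligand_path).stem,
    )


# ------------------------------------------------------------- configuration

@dataclass(frozen=True)
class FilterConfig:
    """Thresholds of the six criteria plus the geometric contact cutoffs."""

    min_contact_area: float = 250.0       # A^2
    min_good_contacts: int = 3
    min_complementarity: float = 0.4
    anchor_residues: tuple = (24, 28, 29)  # toxin Lys/Lys/Arg
    proximity_residue: int = 27            # toxin Ile
    proximity_cutoff: float = 4.0          # A, strict
    cluster_residues: tuple = (11, 12, 16) # toxin Trp/Phe/Trp
    max_orientation_angle: float = 60.0    # degrees
    hbond_max_dist: float = 3.5
    hbond_min_angle: float = 120.0
    ionic_max_dist: float = 4.0
    stack_max_centroid: float = 5.5
    sasa_points: int = 960
    probe_radius: float = 1.4
    mhp_pair_cutoff: float = 5.0
    mhp_decay: float = 2.0


# --------------------------------------------------------------- criterion 1

def contact_area(pose: Pose, config: FilterConfig = FilterConfig()) -> float:
    """Buried contact area (A^2): (SASA_R + SASA_L - SASA_RL) / 2.

    Shrake-Rupley with a 1.4 A probe and 960 sphere points per atom on
    single-atom van der Waals radii.  Atoms whose radius is unknown are
    skipped with a warning (computed on available atoms).
    """

    def total_sasa(arr):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            vals = struc.sasa(
                arr,
                probe_radius=config.probe_radius,
                point_number=config.sasa_points,
                vdw_radii="Single",
            )
        if np.any(np.isnan(vals)):
            warnings.warn("atoms without vdW radius skipped in SASA")
        return float(np.nansum(vals))

    a = total_sasa(pose.receptor)
    b = total_sasa(pose.ligand)
    ab = total_sasa(pose.receptor + pose.ligand)
    return max((a + b - ab) / 2.0, 0.0)


# --------------------------------------------------------------- criterion 2

#: Heavy-atom ring definitions for stacking and orientation geometry.
RING_ATOMS = {
    "PHE": ("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "TYR": ("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "TRP": ("CG", "CD1", "NE1", "CD2", "CE2", "CE3", "CZ2", "CZ3", "CH2"),
    "HIS": ("CG", "ND1", "CD2", "CE1", "NE2"),
}

#: Side-chain H-bond donors: residue -> ((donor atom, antecedent), ...).
SIDECHAIN_DONORS = {
    "SER": (("OG", "CB"),),
    "THR": (("OG1", "CB"),),
    "TYR": (("OH", "CZ"),),
    "LYS": (("NZ", "CE"),),
    "ARG": (("NE", "CD"), ("NH1", "CZ"), ("NH2", "CZ")),
    "TRP": (("NE1", "CD1"),),
    "HIS": (("ND1", "CG"), ("NE2", "CE1")),
    "ASN": (("ND2", "CG"),),
    "GLN": (("NE2", "CD"),),
}

#: Side-chain H-bond acceptors.
SIDECHAIN_ACCEPTORS = {
    "ASP": ("OD1", "OD2"),
    "GLU": ("OE1", "OE2"),
    "ASN": ("OD1",),
    "GLN": ("OE1",),
    "SER": ("OG",),
    "THR": ("OG1",),
    "TYR": ("OH",),
    "HIS": ("ND1", "NE2"),
}

CATION_ATOMS = {"LYS": ("NZ",), "ARG": ("NH1", "NH2", "NE")}
ANION_ATOMS = {"ASP": ("OD1", "OD2"), "GLU": ("OE1", "OE2")}


def _atom_records(arr: struc.AtomArray):
    """(index, res_name, res_id, atom_name, coord) iterator."""
    for i in range(arr.array_length()):
        yield i, arr.res_name[i], arr.res_id[i], arr.atom_name[i], arr.coord[i]


def _donors(arr):
    out = []
    for i, rname, rid, aname, xyz in _atom_records(arr):
        if aname == "N" and rname != "PRO":
            out.append((i, rid, rname, aname, "CA"))
        for d, ante in SIDECHAIN_DONORS.get(rname, ()):
            if aname == d:
                out.append((i, rid, rname, aname, ante))
    return out


def _acceptors(arr):
    out = []
    for i, rname, rid, aname, xyz in _atom_records(arr):
        if aname == "O":
            out.append((i, rid, rname, aname))
        if aname in SIDECHAIN_ACCEPTORS.get(rname, ()):
            out.append((i, rid, rname, aname))
    return out


def _find_atom(arr, res_id, atom_name):
    mask = (arr.res_id == res_id) & (arr.atom_name == atom_name)
    idx = np.nonzero(mask)[0]
    return int(idx[0]) if len(idx) else None


def _angle_deg(a, b, c):
    """Angle at vertex b, degrees."""
    v1 = a - b
    v2 = c - b
    cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))


def _ring_geometry(arr, res_id, res_name):
    names = RING_ATOMS.get(res_name)
    if names is None:
        return None
    mask = (arr.res_id == res_id) & np.isin(arr.atom_name, names)
    coords = arr.coord[mask]
    if len(coords) < 3:
        return None
    centroid = coords.mean(axis=0)
    _, _, vh = np.linalg.svd(coords - centroid)
    return centroid, vh[2]


def _ionic_pairs(pose: Pose, config: FilterConfig):
    pairs = []
    for cat_arr, an_arr, direction in (
        (pose.ligand, pose.receptor, "ligand->receptor"),
        (pose.receptor, pose.ligand, "receptor->ligand"),
    ):
        cats = [
            (i, rid, rname, aname)
            for i, rname, rid, aname, _ in _atom_records(cat_arr)
            if aname in CATION_ATOMS.get(rname, ())
        ]
        ans = [
            (i, rid, rname, aname)
            for i, rname, rid, aname, _ in _atom_records(an_arr)
            if aname in ANION_ATOMS.get(rname, ())
        ]
        for ci, crid, crn, can in cats:
            for ai, arid, arn, aan in ans:
                d = np.linalg.norm(cat_arr.coord[ci] - an_arr.coord[ai])
                if d <= config.ionic_max_dist:
                    pairs.append(
                        {
                            "type": "ionic",
                            "direction": direction,
                            "cation": (crn, int(crid), can),
                            "anion": (arn, int(arid), aan),
                            "distance": float(d),
                        }
                    )
    return pairs


def good_contacts(pose: Pose, config: FilterConfig = FilterConfig()) -> dict:
    """Count typed inter-partner contacts: ionic bridges, H-bonds, stacking.

    Heavy-atom geometry: H-bond = donor-acceptor N/O pair <= 3.5 A with the
    antecedent-donor-acceptor angle >= 120 deg (a missing antecedent atom
    passes the angle check — reduced models are accepted); ionic = Lys/Arg
    nitrogen to Asp/Glu carboxylate oxygen <= 4.0 A; stacking = ring
    centroids <= 5.5 A with inter-plane angle <= 30 deg (parallel) or
    between 60 and 120 deg (T-shaped).  A donor/acceptor pair already
    counted as ionic is not double-counted as an H-bond; each contact is
    reported once per (residue pair, type).
    """
    contacts = list(_ionic_pairs(pose, config))
    ionic_atoms = set()
    for c in contacts:
        ionic_atoms.add((c["cation"][1], c["cation"][2], c["anion"][1], c["anion"][2]))
        ionic_atoms.add((c["anion"][1], c["anion"][2], c["cation"][1], c["cation"][2]))

    # hydrogen bonds, both directions
    for don_arr, acc_arr, direction in (
        (pose.ligand, pose.receptor, "ligand->receptor"),
        (pose.receptor, pose.ligand, "receptor->ligand"),
    ):
        for di, drid, drn, dan, ante in _donors(don_arr):
            for ai, arid, arn, aan in _acceptors(acc_arr):
                if (drid, dan, arid, aan) in ionic_atoms:
                    continue
                d = np.linalg.norm(don_arr.coord[di] - acc_arr.coord[ai])
                if d > config.hbond_max_dist:
                    continue
                ante_idx = _find_atom(don_arr, drid, ante)
                if ante_idx is not None:
                    ang = _angle_deg(
                        don_arr.coord[ante_idx], don_arr.coord[di], acc_arr.coord[ai]
                    )
                    if ang < config.hbond_min_angle:
                        continue
                contacts.append(
                    {
                        "type": "hbond",
                        "direction": direction,
                        "donor": (drn, int(drid), dan),
                        "acceptor": (arn, int(arid), aan),
                        "distance": float(d),
                    }
                )

    # aromatic stacking
    lig_rings = [
        (rid, rn, _ring_geometry(pose.ligand, rid, rn))
        for rid, rn in {
            (int(r), n) for r, n in zip(pose.ligand.res_id, pose.ligand.res_name)
        }
        if rn in RING_ATOMS
    ]
    rec_rings = [
        (rid, rn, _ring_geometry(pose.receptor, rid, rn))
        for rid, rn in {
            (int(r), n) for r, n in zip(pose.receptor.res_id, pose.receptor.res_name)
        }
        if rn in RING_ATOMS
    ]
    for lrid, lrn, lgeo in lig_rings:
        if lgeo is None:
            continue
        for rrid, rrn, rgeo in rec_rings:
            if rgeo is None:
                continue
            d = np.linalg.norm(lgeo[0] - rgeo[0])
            if d > config.stack_max_centroid:
                continue
            cosang = abs(float(np.dot(lgeo[1], rgeo[1])))
            plane_angle = np.degrees(np.arccos(np.clip(cosang, 0.0, 1.0)))
            if plane_angle <= 30.0:
                kind = "parallel"
            elif 60.0 <= plane_angle <= 120.0:
                kind = "t-shaped"
            else:
                continue
            contacts.append(
                {
                    "type": "stacking",
                    "kind": kind,
                    "ligand_residue": (lrn, lrid),
                    "receptor_residue": (rrn, rrid),
                    "distance": float(d),
                    "plane_angle": float(plane_angle),
                }
            )

    # de-duplicate per (residue pair, type)
    seen = set()
    unique = []
    for c in contacts:
        if c["type"] == "stacking":
            key = ("stacking", c["ligand_residue"][1], c["receptor_residue"][1])
        elif c["type"] == "ionic":
            key = ("ionic", c["cation"][1], c["anion"][1], c["direction"])
        else:
            key = ("hbond", c["donor"][1], c["acceptor"][1], c["direction"])
        if key in seen:
            continue
        seen.add(key)
        unique.append(c)
    return {"count": len(unique), "contacts": unique}


# --------------------------------------------------------------- criterion 3

def _atom_hydrophobicity(arr: struc.AtomArray) -> np.ndarray:
    """Crude per-atom hydrophobicity constants (Ghose-Crippen-flavored).

    Carbons are hydrophobic, N/O hydrophilic, charged groups strongly so.
    The absolute scale is irrelevant: only the sign pattern enters the
    complementarity score.
    """
    vals = np.zeros(arr.array_length())
    for i, rname, rid, aname, _ in _atom_records(arr):
        el = arr.element[i]
        if aname in CATION_ATOMS.get(rname, ()) or aname in ANION_ATOMS.get(rname, ()):
            vals[i] = -1.0
        elif el == "O":
            vals[i] = -0.4
        elif el == "N":
            vals[i] = -0.6
        elif el == "S":
            vals[i] = 0.1
        elif el == "C":
            vals[i] = -0.1 if aname == "C" else (0.1 if aname == "CA" else 0.35)
    return vals


def hydrophobic_complementarity(
    pose: Pose, config: FilterConfig = FilterConfig()
) -> float | None:
    """Sign-agreement MHP score over the contact surface, in [-1, 1].

    Sample points are midpoints of inter-partner heavy-atom pairs within
    ``mhp_pair_cutoff``; at each point the molecular hydrophobicity
    potential of each partner is the exp(-d/2 A)-decayed sum of its atomic
    constants.  The score is the mean product of the two MHP signs:
    +1 for a perfectly matched (hydrophobic-on-hydrophobic,
    polar-on-polar) interface, -1 for a fully mismatched one.  Returns
    ``None`` (criterion fails) when the partners make no contact.  This is
    a deliberately simple stand-in for full MHP surface maps; see the
    methods note.
    """
    rc = pose.receptor.coord
    lc = pose.ligand.coord
    d = cdist(rc, lc)
    ii, jj = np.nonzero(d <= config.mhp_pair_cutoff)
    if len(ii) == 0:
        return None
    points = 0.5 * (rc[ii] + lc[jj])
    fr = _atom_hydrophobicity(pose.receptor)
    fl = _atom_hydrophobicity(pose.ligand)
    dr = cdist(points, rc)
    dl = cdist(points, lc)
    mhp_r = (np.exp(-dr / config.mhp_decay) * fr[None, :]).sum(axis=1)
    mhp_l = (np.exp(-dl / config.mhp_decay) * fl[None, :]).sum(axis=1)
    return float(np.mean(np.sign(mhp_r) * np.sign(mhp_l)))


# --------------------------------------------------------- criteria 4 and 5

def ionic_anchor_check(pose: Pose, config: FilterConfig = FilterConfig()) -> dict:
    """Does one of the anchor toxin residues form an ionic bridge?

    The anchor residues (default K24/K28/R29) must be present in the
    ligand, otherwise the input is rejected as misnumbered.
    """
    present = set(int(r) for r in pose.ligand.res_id)
    missing = [r for r in config.anchor_residues if r not in present]
    if missing:
        raise ValueError(f"anchor residues {missing} absent from the ligand")
    partners = [
        c
        for c in _ionic_pairs(pose, config)
        if c["direction"] == "ligand->receptor"
        and c["cation"][1] in config.anchor_residues
    ]
    return {"pass": len(partners) > 0, "partners": partners}


def proximity_check(pose: Pose, config: FilterConfig = FilterConfig()) -> dict:
    """Minimum heavy-atom distance from the reporter toxin residue (I27)."""
    mask = pose.ligand.res_id == config.proximity_residue
    if not np.any(mask):
        raise ValueError(
            f"residue {config.proximity_residue} absent from the ligand"
        )
    d = cdist(pose.ligand.coord[mask], pose.receptor.coord).min()
    return {"pass": bool(d < config.proximity_cutoff), "min_distance": float(d)}


# --------------------------------------------------------------- criterion 6

def orientation_check(pose: Pose, config: FilterConfig = FilterConfig()) -> dict:
    """Angle between the toxin's hydrophobic-cluster direction and the
    inward membrane normal; passes at or below ``max_orientation_angle``.

    The cluster direction runs from the ligand centroid to the mean ring
    centroid of the cluster residues (W11/F12/W16 by default; residues
    without a known ring fall back to their side-chain centroid).
    """
    lig_centroid = pose.ligand.coord.mean(axis=0)
    ring_centroids = []
    for rid in config.cluster_residues:
        mask = pose.ligand.res_id == rid
        if not np.any(mask):
            raise ValueError(f"cluster residue {rid} absent from the ligand")
        rname = pose.ligand.res_name[mask][0]
        geo = _ring_geometry(pose.ligand, rid, rname)
        if geo is not None:
            ring_centroids.append(geo[0])
        else:
            side = mask & ~np.isin(pose.ligand.atom_name, ("N", "CA", "C", "O"))
            coords = pose.ligand.coord[side if np.any(side) else mask]
            ring_centroids.append(coords.mean(axis=0))
    v = np.mean(ring_centroids, axis=0) - lig_centroid
    norm = np.linalg.norm(v)
    if norm == 0:
        raise ValueError("degenerate cluster geometry")
    inward = pose.frame.inward_direction(lig_centroid)
    angle = float(np.degrees(np.arccos(np.clip(np.dot(v / norm, inward), -1, 1))))
    return {"pass": angle <= config.max_orientation_angle, "angle": angle}


# ------------------------------------------------------------------- filter

@dataclass
class FilterReport:
    """Per-pose criterion values and pass/fail flags."""

    name: str
    contact_area: float
    n_good_contacts: int
    complementarity: float | None
    ionic_anchor: bool
    i27_min_dist: float
    orientation_angle: float
    criteria: dict
    zdock_score: float | None = None

    @property
    def passed(self) -> bool:
        return all(self.criteria.values())

    def as_dict(self) -> dict:
        d = {
            "name": self.name,
            "contact_area": self.contact_area,
            "n_good_contacts": self.n_good_contacts,
            "complementarity": self.complementarity,
            "ionic_anchor": self.ionic_anchor,
            "i27_min_dist": self.i27_min_dist,
            "orientation_angle": self.orientation_angle,
            "pass": self.passed,
        }
        if self.zdock_score is not None:
            d["zdock_score"] = self.zdock_score
        d.update({f"pass_{k}": v for k, v in self.criteria.items()})
        return d


def evaluate_pose(pose: Pose, config: FilterConfig = FilterConfig()) -> FilterReport:
    area = contact_area(pose, config)
    gc = good_contacts(pose, config)
    comp = hydrophobic_complementarity(pose, config)
    anchor = ionic_anchor_check(pose, config)
    prox = proximity_check(pose, config)
    orient = orientation_check(pose, config)
    criteria = {
        "contact_area": area > config.min_contact_area,
        "good_contacts": gc["count"] >= config.min_good_contacts,
        "complementarity": comp is not None and comp > config.min_complementarity,
        "ionic_anchor": anchor["pass"],
        "i27_proximity": prox["pass"],
        "orientation": orient["pass"],
    }
    return FilterReport(
        name=pose.name,
        contact_area=area,
        n_good_contacts=gc["count"],
        complementarity=comp,
        ionic_anchor=anchor["pass"],
        i27_min_dist=prox["min_distance"],
        orientation_angle=orient["angle"],
        criteria=criteria,
    )


def filter_poses(
    poses, config: FilterConfig = FilterConfig()
) -> tuple[list[FilterReport], list[Pose]]:
    """Evaluate all six criteria per pose; survivors must pass all.

    Returns (reports, surviving poses); per-criterion pass counts are
    available by aggregating the reports.
    """
    poses = list(poses)
    if not poses:
        raise ValueError("need at least one pose")
    reports = [evaluate_pose(p, config) for p in poses]
    survivors = [p for p, rep in zip(poses, reports) if rep.passed]
    return reports, survivors


def reports_to_frame(reports) -> pd.DataFrame:
    return pd.DataFrame([r.as_dict() for r in reports])


# -------------------------------------------------- ensembles: cluster, RMSF

def _ensemble_coords(ensemble, selection: str | None = "CA"):
    """Stack an ensemble into (n_frames, n_atoms, 3) coordinates.

    ``ensemble`` is a list of AtomArrays with consistent atom sets, an
    AtomArrayStack, or a raw coordinate array.  ``selection`` picks an atom
    name subset (None = all atoms).
    """
    if isinstance(ensemble, np.ndarray):
        if ensemble.ndim != 3:
            raise ValueError("coordinate ensemble must be (n_frames, n_atoms, 3)")
        return ensemble.astype(float), None
    if isinstance(ensemble, struc.AtomArrayStack):
        frames = [ensemble[i] for i in range(ensemble.stack_depth())]
    else:
        frames = list(ensemble)
    masks = []
    for f in frames:
        mask = np.ones(f.array_length(), bool) if selection is None else (
            f.atom_name == selection
        )
        masks.append(mask)
    counts = {int(m.sum()) for m in masks}
    if len(counts) != 1 or counts == {0}:
        raise ValueError("inconsistent atom sets across the ensemble")
    coords = np.stack([f.coord[m] for f, m in zip(frames, masks)])
    res_ids = frames[0].res_id[masks[0]]
    return coords.astype(float), res_ids


def _pairwise_rmsd(coords: np.ndarray) -> np.ndarray:
    """All-pair RMSD (A) after optimal (Kabsch) superposition."""
    n, m, _ = coords.shape
    centered = coords - coords.mean(axis=1, keepdims=True)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            _, rssd = Rotation.align_vectors(centered[i], centered[j])
            out[i, j] = out[j, i] = rssd / np.sqrt(m)
    return out


def gromos_cluster(
    ensemble,
    cutoff_nm: float = 0.25,
    selection: str | None = "CA",
) -> list[dict]:
    """Gromos (Daura) conformational clustering.

    Iteratively: count, for every remaining conformer, its neighbors within
    the RMSD cutoff (after pairwise Kabsch superposition); the conformer
    with the most neighbors becomes a cluster center (lowest index on
    ties), it and its neighbors are removed, and the procedure repeats.
    Every conformer ends up in exactly one cluster.  Coordinates are in A;
    the cutoff argument is in nm to match the usual convention.
    """
    coords, _ = _ensemble_coords(ensemble, selection)
    n = coords.shape[0]
    rmsd = _pairwise_rmsd(coords)
    cutoff = cutoff_nm * 10.0
    remaining = list(range(n))
    clusters = []
    while remaining:
        idx = np.array(remaining)
        sub = rmsd[np.ix_(idx, idx)]
        neighbor_counts = (sub <= cutoff).sum(axis=1)  # includes self
        center_pos = int(np.argmax(neighbor_counts))   # argmax -> lowest index tie-break
        members = idx[sub[center_pos] <= cutoff]
        clusters.append({"center": int(idx[center_pos]),
                         "members": [int(m) for m in members]})
        remaining = [i for i in remaining if i not in set(members.tolist())]
    return clusters


def rmsf(ensemble, selection: str | None = "CA", max_iter: int = 10) -> pd.DataFrame:
    """Per-residue root-mean-square fluctuation (nm) about the ensemble mean.

    Frames are iteratively superposed (Kabsch) onto the running mean
    structure until the mean stabilizes; per-atom RMSF is then averaged per
    residue.  Rigid-body motion is removed by the superposition, so
    rigidly transformed copies give ~0.
    """
    coords, res_ids = _ensemble_coords(ensemble, selection)
    n, m, _ = coords.shape
    if n < 2:
        raise ValueError("need at least 2 frames")
    work = coords - coords.mean(axis=1, keepdims=True)
    ref = work[0]
    for _ in range(max_iter):
        aligned = np.empty_like(work)
        for i in range(n):
            rot, _ = Rotation.align_vectors(ref, work[i])
            aligned[i] = rot.apply(work[i])
        new_ref = aligned.mean(axis=0)
        new_ref -= new_ref.mean(axis=0)
        if np.allclose(new_ref, ref, atol=1e-10):
            work = aligned
            break
        ref = new_ref
        work = aligned
    mean = work.mean(axis=0)
    per_atom = np.sqrt(((work - mean) ** 2).sum(axis=2).mean(axis=0)) / 10.0
    if res_ids is None:
        return pd.DataFrame({"atom_index": np.arange(m), "rmsf_nm": per_atom})
    df = pd.DataFrame({"residue_id": res_ids, "rmsf_nm": per_atom})
    return df.groupby("residue_id", as_index=False).rmsf_nm.mean()
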