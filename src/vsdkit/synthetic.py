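"""Seeded synthetic inputs with planted ground truth for every pipeline stage.

The study this pipeline reproduces deposited no raw data, so each analysis
stage ships with a generator that emulates its input format and plants a
known truth: a labeling scheme, an interface residue set with CSP
magnitudes, dissociation constants, a distance distribution with modulation
depth and background, or a receptor/ligand pose built to pass or fail each
filter criterion by construction.  Every generator is a pure function of
its parameters and seed; the planted truth serializes losslessly to JSON
alongside the generated dataset.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import biotite.structure as struc

from . import binding as _binding
from . import deer as _deer
from .labeling import AMINO_ACIDS, LabelingScheme, predict_spectra
from .posefilter import MembraneFrame, Pose

__all__ = [
    "GroundTruth",
    "gen_sequence",
    "gen_peaklists",
    "gen_titration",
    "gen_deer",
    "gen_toy_complex",
    "gen_pose_suite",
    "InfeasibleToggleError",
    "CRITERIA",
    "AA_SHIFT_STATS",
]


@dataclass
class GroundTruth:
    """Planted parameters of one generated dataset, JSON-serializable."""

    kind: str
    seed: int
    params: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "GroundTruth":
        return cls(**json.loads(text))

    def write(self, path) -> None:
        Path(path).write_text(self.to_json())


# ------------------------------------------------------------- sequences

def gen_sequence(
    length: int,
    weights=None,
    seed: int = 0,
    exclude: tuple = (),
) -> tuple[str, GroundTruth]:
    """Seeded random residue string.

    ``weights`` maps one-letter codes to composition weights (uniform by
    default); ``exclude`` removes amino-acid types entirely — the
    cell-free-expression emulation excludes cysteine (``exclude=("C",)``)
    and handles histidine through the stock (His unlabeled), not here.
    """
    if length < 2:
        raise ValueError("length must be >= 2")
    alphabet = [aa for aa in AMINO_ACIDS if aa not in exclude]
    if weights is None:
        w = np.ones(len(alphabet))
    else:
        w = np.array([float(weights.get(aa, 0.0)) for aa in alphabet])
    if w.sum() <= 0:
        raise ValueError("composition weights sum to zero")
    rng = np.random.default_rng(seed)
    seq = "".join(rng.choice(alphabet, size=length, p=w / w.sum()))
    truth = GroundTruth(
        kind="sequence", seed=seed,
        params={"length": length, "exclude": list(exclude)},
    )
    return seq, truth


# ------------------------------------------------------------- peak lists

#: Typical backbone amide shift statistics per amino-acid type:
#: (mean 1H ppm, sd 1H, mean 15N ppm, sd 15N).  A small internal fixture of
#: random-coil-like values; no live database is queried.
AA_SHIFT_STATS = {
    "A": (8.20, 0.45, 123.2, 3.5), "C": (8.43, 0.45, 118.8, 3.5),
    "D": (8.34, 0.45, 120.6, 3.5), "E": (8.42, 0.45, 120.6, 3.5),
    "F": (8.30, 0.50, 120.3, 4.0), "G": (8.33, 0.45, 109.5, 2.5),
    "H": (8.42, 0.50, 119.6, 4.0), "I": (8.00, 0.50, 121.5, 4.0),
    "K": (8.29, 0.45, 121.5, 3.5), "L": (8.16, 0.45, 121.8, 3.5),
    "M": (8.28, 0.45, 120.5, 3.5), "N": (8.40, 0.45, 118.9, 3.5),
    "P": (np.nan, 0.0, np.nan, 0.0), "Q": (8.32, 0.45, 119.8, 3.5),
    "R": (8.27, 0.45, 121.3, 3.5), "S": (8.31, 0.45, 116.3, 3.0),
    "T": (8.24, 0.45, 113.6, 3.0), "V": (8.03, 0.50, 121.1, 4.0),
    "W": (8.25, 0.55, 121.7, 4.0), "Y": (8.12, 0.50, 120.3, 4.0),
}


def gen_peaklists(
    sequence: str,
    scheme: LabelingScheme | None = None,
    sample: int = 0,
    planted: dict | None = None,
    broadening_factor: float = 0.3,
    noise_sd: float = 0.0,
    missing_rate: float = 0.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Apo/bound peak-list pair with a planted binding interface.

    ``planted`` maps residue ids (1-based) to ``(ddH_ppm, ddN_ppm,
    broadened)``; broadened residues additionally lose intensity by
    ``broadening_factor``.  Base shifts are drawn once per residue from
    :data:`AA_SHIFT_STATS`; measurement noise of ``noise_sd`` (ppm on 1H;
    5x on 15N) is added independently to each list, so with ``noise_sd=0``
    and nothing planted the two lists are identical.  When a ``scheme`` is
    given, peaks exist only for residues NH-visible in the chosen sample
    (planting an invisible residue is recorded as a warning in the truth).
    With ``missing_rate=1`` both lists are empty.
    """
    planted = dict(planted or {})
    rng = np.random.default_rng(seed)
    if scheme is None:
        visible = [i + 1 for i, aa in enumerate(sequence) if aa != "P"]
    else:
        spectra = predict_spectra(scheme, sequence)[sample]
        visible = spectra.residue_id.tolist()
    warnings = [
        f"planted residue {rid} is not NH-visible under the scheme"
        for rid in planted
        if rid not in visible
    ]
    rows = []
    for rid in visible:
        aa = sequence[rid - 1]
        mh, sh, mn, sn = AA_SHIFT_STATS[aa]
        rows.append(
            {
                "residue_id": rid,
                "aa": aa,
                "dH_ppm": rng.normal(mh, sh),
                "dN_ppm": rng.normal(mn, sn),
                "intensity": float(rng.lognormal(0.0, 0.2)),
            }
        )
    base = pd.DataFrame(rows, columns=["residue_id", "aa", "dH_ppm", "dN_ppm", "intensity"])

    def with_noise(df):
        out = df.copy()
        if noise_sd > 0:
            out["dH_ppm"] += rng.normal(0, noise_sd, len(out))
            out["dN_ppm"] += rng.normal(0, 5 * noise_sd, len(out))
        return out

    apo = with_noise(base)
    bound = base.copy()
    for rid, (ddh, ddn, broad) in planted.items():
        m = bound.residue_id == rid
        bound.loc[m, "dH_ppm"] += ddh
        bound.loc[m, "dN_ppm"] += ddn
        if broad:
            bound.loc[m, "intensity"] *= broadening_factor
    bound = with_noise(bound)
    if missing_rate > 0:
        apo = apo[rng.random(len(apo)) >= missing_rate]
        bound = bound[rng.random(len(bound)) >= missing_rate]
    truth = GroundTruth(
        kind="peaklists",
        seed=seed,
        params={
            "planted": {str(k): list(v) for k, v in planted.items()},
            "broadening_factor": broadening_factor,
            "noise_sd": noise_sd,
            "missing_rate": missing_rate,
            "sample": sample,
        },
        warnings=warnings,
    )
    return apo.reset_index(drop=True), bound.reset_index(drop=True), truth


# ------------------------------------------------------------- titrations

def gen_titration(
    system: _binding.BindingSystem,
    vsd0: float,
    detergent0: float,
    hm3_totals,
    dd_max: dict | None = None,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Receptor-detected titration table from the equilibrium model.

    ``dd_max`` maps reporter names to limiting shift changes (ppm); the
    default emulates one cytoplasmic-site and one extracellular-site
    reporter.  Observables come from :func:`vsdkit.binding.solve_species`
    plus seeded Gaussian noise of ``noise_sd`` ppm.
    """
    if dd_max is None:
        dd_max = {"F28": 0.10, "N57": 0.12}
    rng = np.random.default_rng(seed)
    rows = []
    for rep, a in dd_max.items():
        for L0 in np.asarray(hm3_totals, dtype=float):
            pt = _binding.TitrationPoint(vsd0, float(L0), detergent0)
            if vsd0 > 0:
                sol = _binding.solve_species(pt, system)
                dd = _binding.predict_observable(
                    sol, "receptor-detected", a, vsd0=vsd0
                )
            else:
                dd = 0.0
            rows.append(
                {
                    "VSD0_M": vsd0,
                    "Hm3_0_M": float(L0),
                    "Detergent0_M": detergent0,
                    "reporter": rep,
                    "dd_obs_ppm": dd + (rng.normal(0, noise_sd) if noise_sd else 0.0),
                }
            )
    truth = GroundTruth(
        kind="titration",
        seed=seed,
        params={
            "K_M": system.K_M, "K_V": system.K_V, "n_site": system.n_site,
            "statistical_factor": system.statistical_factor,
            "dd_max": dd_max, "noise_sd": noise_sd,
        },
    )
    return pd.DataFrame(rows), truth


def gen_micelle_titration(
    system: _binding.BindingSystem,
    ligand_total: float,
    detergent_totals,
    dd_max: float = 0.2,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Micelle-only (no receptor) detergent titration of the ligand."""
    rng = np.random.default_rng(seed)
    rows = []
    for det in np.asarray(detergent_totals, dtype=float):
        pt = _binding.TitrationPoint(0.0, ligand_total, float(det))
        sol = _binding.solve_species(pt, system)
        p_mic = sol.hm3_mic / ligand_total if ligand_total > 0 else 0.0
        rows.append(
            {
                "VSD0_M": 0.0,
                "Hm3_0_M": ligand_total,
                "Detergent0_M": float(det),
                "reporter": "ligand",
                "dd_obs_ppm": p_mic * dd_max
                + (rng.normal(0, noise_sd) if noise_sd else 0.0),
            }
        )
    truth = GroundTruth(
        kind="micelle_titration",
        seed=seed,
        params={"K_M": system.K_M, "n_site": system.n_site,
                "dd_max": dd_max, "noise_sd": noise_sd},
    )
    return pd.DataFrame(rows), truth


# ------------------------------------------------------------------- DEER

def gen_deer(
    means,
    sds,
    weights=None,
    lam: float = 0.03,
    background: _deer.BackgroundModel | None = None,
    t_ns=None,
    noise_sd: float = 0.0,
    seed: int = 0,
    r_nm=None,
) -> tuple[_deer.DeerTrace, GroundTruth]:
    """DEER trace from a Gaussian-mixture distance distribution."""
    if background is None:
        background = _deer.BackgroundModel()
    r = _deer.default_r_grid() if r_nm is None else np.asarray(r_nm, float)
    dist = _deer.DistanceDistribution.from_gaussians(r, means, sds, weights)
    trace = _deer.simulate_trace(
        dist, lam, background, t_ns=t_ns, noise_sd=noise_sd, seed=seed
    )
    truth = GroundTruth(
        kind="deer",
        seed=seed,
        params={
            "means_nm": list(np.atleast_1d(means).astype(float)),
            "sds_nm": list(np.atleast_1d(sds).astype(float)),
            "weights": None if weights is None else list(np.atleast_1d(weights).astype(float)),
            "lambda": lam,
            "background_k": background.k,
            "background_dimension": background.dimension,
            "noise_sd": noise_sd,
        },
    )
    return trace, truth


# ------------------------------------------------------------ toy complex

CRITERIA = (
    "contact_area",
    "good_contacts",
    "complementarity",
    "ionic_anchor",
    "i27_proximity",
    "orientation",
)


class InfeasibleToggleError(ValueError):
    """The requested pass/fail combination cannot be built geometrically."""


def _helix_backbone(atoms, chain, res_ids, res_names, axis_xy, z_start, direction,
                    rise=1.5, twist_deg=100.0, radius=2.3):
    """Ideal helix CA trace with approximate N, C, O positions."""
    ax, ay = axis_xy
    for k, (rid, rname) in enumerate(zip(res_ids, res_names)):
        phi = np.radians(twist_deg * k)
        z = z_start + direction * rise * k
        ca = np.array([ax + radius * np.cos(phi), ay + radius * np.sin(phi), z])
        out = np.array([np.cos(phi), np.sin(phi), 0.0])
        n = ca + np.array([-0.8 * np.sin(phi), 0.8 * np.cos(phi), -0.9 * direction])
        c = ca + np.array([0.8 * np.sin(phi), -0.8 * np.cos(phi), 0.9 * direction])
        o = c + out * 1.2
        for name, el, xyz in (("N", "N", n), ("CA", "C", ca), ("C", "C", c), ("O", "O", o)):
            atoms.append((chain, rid, rname, name, el, xyz))
        yield rid, rname, ca, out


def _toy_receptor(rng) -> tuple[list, dict]:
    """Four-helix bundle with a hydrophobic extracellular canopy and an
    acidic (Glu/Asp/Glu) trio on top of the second helix.

    Returns the atom record list, the acidic carboxylate-oxygen target
    positions keyed by residue id, and a canopy reference atom position
    (the highest leucine carbon, used to plant the I27 proximity contact).
    """
    atoms: list = []
    acid_targets = {}
    canopy_ref = None
    helices = [
        ((-6.0, -6.0), range(39, 59), +1, -26.5),
        ((6.0, -6.0), range(59, 79), -1, 2.5),
        ((6.0, 6.0), range(79, 99), +1, -26.0),
        ((-6.0, 6.0), range(99, 119), -1, 2.0),
    ]
    # carboxylate tips on the outer face of helix 2, mutually >= 4.5 A apart
    # and > 5 A away from the ligand's bulk contact footprint, so one engaged
    # anchor yields exactly one ionic bridge and the acidic oxygens do not
    # leak into the hydrophobic-complementarity samples of the bulk interface
    acid_specs = {59: ("GLU", (12.0, -7.0)), 60: ("ASP", (12.0, -11.5)),
                  61: ("GLU", (7.5, -13.0))}
    for axis_xy, ids, direction, z0 in helices:
        ids = list(ids)
        names = []
        for rid in ids:
            if rid in acid_specs:
                names.append(acid_specs[rid][0])
            else:
                # top canopy residues are leucines, the TM body alanine
                z = z0 + direction * 1.5 * (ids.index(rid))
                names.append("LEU" if z > -1.5 else "ALA")
        for rid, rname, ca, out in _helix_backbone(
            atoms, "R", ids, names, axis_xy, z0, direction
        ):
            if rname == "ALA":
                atoms.append(("R", rid, rname, "CB", "C", ca + out * 1.5))
            elif rname == "LEU":
                up = np.array([0.0, 0.0, 1.0])
                cb = ca + out * 1.0 + up * 1.1
                cg = cb + out * 0.6 + up * 1.3
                atoms.append(("R", rid, rname, "CB", "C", cb))
                atoms.append(("R", rid, rname, "CG", "C", cg))
                cd2 = cg - out * 0.3 + up * 1.4
                atoms.append(("R", rid, rname, "CD1", "C", cg + out * 1.2 + up * 0.8))
                atoms.append(("R", rid, rname, "CD2", "C", cd2))
                if canopy_ref is None or cd2[2] > canopy_ref[2]:
                    canopy_ref = cd2
            elif rname in ("GLU", "ASP"):
                ox, oy = acid_specs[rid][1]
                tip = np.array([ox, oy, 6.0])
                cb = ca + (tip - ca) * 0.3
                cg = ca + (tip - ca) * 0.6
                cd = ca + (tip - ca) * 0.85
                o1 = tip + np.array([0.6, 0.0, 0.0])
                o2 = tip + np.array([-0.6, 0.0, 0.3])
                suffix = "E" if rname == "GLU" else "D"
                atoms.append(("R", rid, rname, "CB", "C", cb))
                atoms.append(("R", rid, rname, "CG", "C", cg))
                if rname == "GLU":
                    atoms.append(("R", rid, rname, "CD", "C", cd))
                atoms.append(("R", rid, rname, f"O{suffix}1", "O", o1))
                atoms.append(("R", rid, rname, f"O{suffix}2", "O", o2))
                acid_targets[rid] = o1
    return atoms, acid_targets, canopy_ref


def _ring(center, radius, n, z_offset=0.0):
    ang = np.linspace(0, 2 * np.pi, n, endpoint=False)
    return [
        center + np.array([radius * np.cos(a), radius * np.sin(a), z_offset])
        for a in ang
    ]


def _toy_ligand(toggles: dict, acid_targets: dict, canopy_ref, rng) -> list:
    """Beta-hairpin-like toxin stand-in built atom by atom so that every
    toggled criterion passes or fails by construction."""
    atoms: list = []
    lifted = not toggles["contact_area"]
    lift = 6.0 if lifted else 0.0
    z_bot, z_top = 9.2 + lift, 13.7 + lift

    engaged_anchors: tuple
    if toggles["ionic_anchor"]:
        engaged_anchors = (24, 28, 29) if toggles["good_contacts"] else (24,)
    else:
        engaged_anchors = ()
    ser_bridges = toggles["good_contacts"] and not toggles["ionic_anchor"]

    anchor_map = {24: 59, 28: 60, 29: 61}  # toxin residue -> receptor acid

    # ---- bottom (contact) layer: ids 17-26, 28-35 on a lateral grid
    bottom_ids = [i for i in range(17, 36) if i not in (27,)]
    xs = np.linspace(-6.8, 6.8, 5)
    ys = np.linspace(-5.1, 5.1, 4)
    grid = [(x, y) for y in ys for x in xs]
    bridge_ids = (20, 21, 22)
    polar_face = not toggles["complementarity"]
    for rid, (gx, gy) in zip(bottom_ids, grid):
        jitter = rng.normal(0.0, 0.05, 3)
        ca = np.array([gx, gy, z_bot + 1.5]) + jitter
        atoms.append(("L", rid, None, "N", "N", ca + np.array([-0.7, 0.4, 0.9])))
        atoms.append(("L", rid, None, "C", "C", ca + np.array([0.7, -0.4, 0.9])))
        atoms.append(("L", rid, None, "O", "O", ca + np.array([1.2, -0.9, 1.4])))
        if rid in anchor_map:
            rname = "LYS" if rid in (24, 28) else "ARG"
            atoms.append(("L", rid, rname, "CA", "C", ca))
            target = acid_targets[anchor_map[rid]]
            if rid in engaged_anchors:
                tip = target + np.array([0.0, 0.0, 3.0])
            else:
                tip = ca + np.array([0.0, 0.0, 3.0])
            if rname == "LYS":
                chain = [("CB", 0.25), ("CG", 0.5), ("CD", 0.75)]
                for name, f in chain:
                    atoms.append(("L", rid, rname, name, "C", ca + (tip - ca) * f))
                atoms.append(("L", rid, rname, "CE", "C", tip + np.array([0, 0, 1.5])))
                atoms.append(("L", rid, rname, "NZ", "N", tip))
            else:
                for name, f in (("CB", 0.2), ("CG", 0.4), ("CD", 0.6)):
                    atoms.append(("L", rid, rname, name, "C", ca + (tip - ca) * f))
                atoms.append(("L", rid, rname, "NE", "N", tip + np.array([0, 0, 2.6])))
                atoms.append(("L", rid, rname, "CZ", "C", tip + np.array([0, 0, 1.3])))
                atoms.append(("L", rid, rname, "NH1", "N", tip))
                atoms.append(("L", rid, rname, "NH2", "N", tip + np.array([1.1, 0, 1.6])))
        elif ser_bridges and rid in bridge_ids:
            target = acid_targets[59 + bridge_ids.index(rid)]
            og = target + np.array([0.0, 0.0, 2.9])
            atoms.append(("L", rid, "SER", "CA", "C", ca))
            atoms.append(("L", rid, "SER", "CB", "C", og + np.array([0, 0, 1.5])))
            atoms.append(("L", rid, "SER", "OG", "O", og))
        elif polar_face:
            atoms.append(("L", rid, "ASN", "CA", "C", ca))
            atoms.append(("L", rid, "ASN", "OD1", "O", ca + np.array([-0.7, 0, -2.3])))
            atoms.append(("L", rid, "ASN", "ND2", "N", ca + np.array([0.7, 0, -2.3])))
        else:
            atoms.append(("L", rid, "ALA", "CA", "C", ca))
            atoms.append(("L", rid, "ALA", "CB", "C", ca + np.array([-0.7, 0, -2.3])))
            atoms.append(("L", rid, "ALA", "CG", "C", ca + np.array([0.7, 0, -2.3])))

    # ---- upper layer: ids 5-16 plus 27
    upper_ids = list(range(5, 17)) + [27]
    xs_u = np.linspace(-6.0, 6.0, 4)
    ys_u = np.linspace(-4.5, 4.5, 4)
    grid_u = [(x, y) for y in ys_u for x in xs_u]
    cluster_names = {11: "TRP", 12: "PHE", 16: "TRP"}
    for rid, (gx, gy) in zip(upper_ids, grid_u):
        jitter = rng.normal(0.0, 0.05, 3)
        ca = np.array([gx, gy, z_top]) + jitter
        rname = cluster_names.get(rid, "ILE" if rid == 27 else "ALA")
        atoms.append(("L", rid, rname, "N", "N", ca + np.array([-0.7, 0.4, 0.6])))
        atoms.append(("L", rid, rname, "CA", "C", ca))
        atoms.append(("L", rid, rname, "C", "C", ca + np.array([0.7, -0.4, 0.6])))
        atoms.append(("L", rid, rname, "O", "O", ca + np.array([1.2, -0.9, 1.0])))
        if rid == 27:
            # reporter side chain reaches the receptor canopy when engaged
            if toggles["i27_proximity"]:
                tip = canopy_ref + np.array([0.0, 0.0, 3.2])
            else:
                tip = ca + np.array([0.0, 0.0, 1.8])
            atoms.append(("L", rid, "ILE", "CB", "C", ca + (tip - ca) * 0.33))
            atoms.append(("L", rid, "ILE", "CG1", "C", ca + (tip - ca) * 0.66))
            atoms.append(("L", rid, "ILE", "CG2", "C",
                          ca + (tip - ca) * 0.33 + np.array([1.2, 0, 0])))
            atoms.append(("L", rid, "ILE", "CD1", "C", tip))
        elif rid not in cluster_names:
            atoms.append(("L", rid, "ALA", "CB", "C", ca + np.array([0, 0, 1.5])))

    # ---- hydrophobic cluster rings (W11/F12/W16)
    lig_z_mid = 0.5 * (z_bot + z_top) + 0.6
    ring_z = lig_z_mid - 4.8 if toggles["orientation"] else lig_z_mid + 4.8
    ring_specs = {
        11: (np.array([-1.8, 0.0, ring_z]),
             ("CG", "CD1", "NE1", "CD2", "CE2", "CE3", "CZ2", "CZ3", "CH2"), 1.7),
        12: (np.array([1.8, 1.2, ring_z]),
             ("CG", "CD1", "CD2", "CE1", "CE2", "CZ"), 1.4),
        16: (np.array([1.2, -1.8, ring_z]),
             ("CG", "CD1", "NE1", "CD2", "CE2", "CE3", "CZ2", "CZ3", "CH2"), 1.7),
    }
    for rid, (center, names, radius) in ring_specs.items():
        for name, xyz in zip(names, _ring(center, radius, len(names))):
            el = "N" if name.startswith("N") else "C"
            atoms.append(("L", rid, cluster_names[rid], name, el, xyz))

    # fill residue names left as None (filler backbone rows)
    fixed = []
    name_by_rid = {}
    for chain, rid, rname, aname, el, xyz in atoms:
        if rname is not None:
            name_by_rid.setdefault(rid, rname)
    for chain, rid, rname, aname, el, xyz in atoms:
        fixed.append((chain, rid, rname or name_by_rid.get(rid, "ALA"), aname, el, xyz))
    return fixed


def _records_to_array(records) -> struc.AtomArray:
    arr = struc.AtomArray(len(records))
    for i, (chain, rid, rname, aname, el, xyz) in enumerate(records):
        arr.chain_id[i] = chain
        arr.res_id[i] = rid
        arr.res_name[i] = rname
        arr.atom_name[i] = aname
        arr.element[i] = el
        arr.coord[i] = np.asarray(xyz, dtype=float)
    arr.hetero[:] = False
    return arr


def _check_feasible(toggles: dict) -> None:
    contact_bearing = (
        toggles["good_contacts"] or toggles["ionic_anchor"]
        or toggles["i27_proximity"]
    )
    if toggles["complementarity"] and not toggles["contact_area"] and not contact_bearing:
        raise InfeasibleToggleError(
            "complementarity can only pass where the partners touch: with "
            "contact_area failing and no contact-bearing criterion passing "
            "there is no interface to score"
        )


def gen_toy_complex(
    toggles: dict | None = None, seed: int = 0
) -> tuple[Pose, GroundTruth]:
    """Receptor/ligand pose built so each criterion passes or fails on demand.

    The receptor is an ideal four-helix bundle (1.5 A rise, 100 deg/turn)
    in a planar membrane frame (outward normal +z, boundary z = 0) with a
    leucine canopy and a Glu/Asp/Glu trio on its extracellular face; the
    ligand is a two-layer hairpin stand-in carrying the named toxin
    residues K24/K28/R29 (ionic anchors), I27 (proximity reporter) and
    W11/F12/W16 (membrane-facing aromatic cluster).  ``toggles`` maps each
    criterion name in :data:`CRITERIA` to the desired pass flag (default:
    all pass).  Combinations that would require scoring a non-existent
    interface raise :class:`InfeasibleToggleError`.  Geometry favors
    testability over realism: side chains are placed directly at their
    target positions, without rotamer sampling.
    """
    full = {c: True for c in CRITERIA}
    if toggles:
        unknown = set(toggles) - set(CRITERIA)
        if unknown:
            raise ValueError(f"unknown criteria {sorted(unknown)}")
        full.update(toggles)
    _check_feasible(full)
    rng = np.random.default_rng(seed)
    rec_records, acid_targets, canopy_ref = _toy_receptor(rng)
    lig_records = _toy_ligand(full, acid_targets, canopy_ref, rng)
    pose = Pose(
        receptor=_records_to_array(rec_records),
        ligand=_records_to_array(lig_records),
        frame=MembraneFrame(normal=(0.0, 0.0, 1.0), offset=0.0),
        name="toy-" + "".join("P" if full[c] else "F" for c in CRITERIA),
    )
    truth = GroundTruth(kind="toy_complex", seed=seed,
                        params={"toggles": {c: bool(full[c]) for c in CRITERIA}})
    return pose, truth


def gen_pose_suite(seed: int = 0) -> tuple[list[Pose], list[GroundTruth]]:
    """Twelve poses: ten violating exactly one criterion each (the six
    criteria, with the first four repeated) and two fully compliant."""
    specs = [{c: False} for c in CRITERIA]
    specs += [{c: False} for c in CRITERIA[:4]]
    specs += [None, None]
    poses, truths = [], []
    for i, spec in enumerate(specs):
        pose, truth = gen_toy_complex(spec, seed=seed + i)
        poses.append(pose)
        truths.append(truth)
    return poses, truths
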