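"""The five physicochemical descriptors of the 2D-QSAR model.

* ``b_rotN``       — count of rotatable single bonds (non-ring single bonds
                     between non-terminal heavy atoms; amides count).
* ``RPC-``         — relative negative partial charge: most negative atomic
                     charge divided by the sum of all negative charges.
* ``opr_leadlike`` — 1 iff the molecule violates fewer than two of Oprea's
                     lead-like criteria, else 0.
* ``SlogP_VSA2``   — summed approximate van der Waals surface area of atoms
                     whose Crippen atomic logP contribution lies in (-0.2, 0].
* ``ASA``          — water-accessible surface area (Shrake-Rupley, 1.4 A probe).

Descriptor values from different engines (charge models, radii, surface
quadrature) are not interchangeable numerically; the published orderings
between compounds, not absolute values, are what this engine reproduces.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import Crippen, Descriptors, Lipinski, rdMolDescriptors

from .chemio import ActivityTable, AlignedConformer, generate_conformer

__all__ = [
    "DESCRIPTOR_NAMES",
    "OPREA_CRITERIA",
    "count_rotatable_bonds",
    "relative_negative_partial_charge",
    "oprea_leadlike",
    "slogp_vsa2",
    "accessible_surface_area",
    "compute_descriptors",
    "compute_descriptor_matrix",
]

DESCRIPTOR_NAMES = ("b_rotN", "RPC-", "opr_leadlike", "SlogP_VSA2", "ASA")

#: Oprea lead-like criteria evaluated as (name, predicate-on-mol).
#: A violation is a criterion that evaluates False.
OPREA_CRITERIA = {
    "mw<=450": lambda m: Descriptors.MolWt(m) <= 450.0,
    "-3.5<=logP<=4.5": lambda m: -3.5 <= Crippen.MolLogP(m) <= 4.5,
    "rings<=4": lambda m: rdMolDescriptors.CalcNumRings(m) <= 4,
    "rotatable<=10": lambda m: count_rotatable_bonds(m) <= 10,
    "donors<=5": lambda m: Lipinski.NumHDonors(m) <= 5,
    "acceptors<=8": lambda m: Lipinski.NumHAcceptors(m) <= 8,
}


def _as_mol(mol) -> Chem.Mol:
    if isinstance(mol, Chem.Mol):
        return mol
    m = Chem.MolFromSmiles(mol)
    if m is None:
        raise ValueError(f"unparsable structure {mol!r}")
    return m


def count_rotatable_bonds(mol) -> int:
    """Non-ring single bonds whose two end atoms each bind >= 2 heavy atoms."""
    m = _as_mol(mol)
    n = 0
    for bond in m.GetBonds():
        if bond.GetBondType() != Chem.BondType.SINGLE or bond.IsInRing():
            continue
        a, b = bond.GetBeginAtom(), bond.GetEndAtom()
        if a.GetAtomicNum() == 1 or b.GetAtomicNum() == 1:
            continue
        deg_a = sum(1 for x in a.GetNeighbors() if x.GetAtomicNum() > 1)
        deg_b = sum(1 for x in b.GetNeighbors() if x.GetAtomicNum() > 1)
        if deg_a >= 2 and deg_b >= 2:
            n += 1
    return n


def relative_negative_partial_charge(conf: AlignedConformer) -> float:
    """q_min^- / sum(q^-): fraction of negative charge on the most negative atom."""
    q = np.asarray(conf.charges, dtype=float)
    neg = q[q < 0]
    if neg.size == 0:
        return 0.0
    return float(neg.min() / neg.sum())


def oprea_leadlike(mol) -> int:
    """1 iff fewer than two violations of the configured lead-like criteria."""
    m = _as_mol(mol)
    violations = sum(0 if ok(m) else 1 for ok in OPREA_CRITERIA.values())
    return 1 if violations < 2 else 0


def oprea_violations(mol) -> dict[str, bool]:
    """Per-criterion pass/fail map (True = satisfied)."""
    m = _as_mol(mol)
    return {name: bool(ok(m)) for name, ok in OPREA_CRITERIA.items()}


def slogp_vsa2(mol) -> float:
    """Summed per-atom VSA over atoms with Crippen logP contribution in (-0.2, 0]."""
    m = _as_mol(mol)
    contribs = rdMolDescriptors._CalcCrippenContribs(m)
    vsa = list(rdMolDescriptors._CalcLabuteASAContribs(m)[0])
    total = 0.0
    for (logp, _), v in zip(contribs, vsa):
        if -0.2 < logp <= 0.0:
            total += v
    return float(total)


def _sphere_points(n: int) -> np.ndarray:
    """Deterministic quasi-uniform unit-sphere point set (Fibonacci spiral)."""
    i = np.arange(n, dtype=float) + 0.5
    phi = np.arccos(1.0 - 2.0 * i / n)
    theta = np.pi * (1.0 + 5.0 ** 0.5) * i
    return np.column_stack(
        (np.cos(theta) * np.sin(phi), np.sin(theta) * np.sin(phi), np.cos(phi))
    )


def accessible_surface_area(
    conf: AlignedConformer, probe: float = 1.4, n_points: int = 960
) -> float:
    """Shrake-Rupley solvent-accessible surface area in A^2.

    Each atom's solvent sphere (vdW radius + probe) is sampled with a fixed
    deterministic point set; points buried inside any other atom's solvent
    sphere are discarded.  Exactly coincident duplicate atoms are counted
    once.  Quadrature error is ~1% at the default 960 points.
    """
    xyz = conf.xyz
    rs = conf.radii + probe
    if len(xyz) > 1:
        # drop exact duplicates (same centre and radius) to keep the
        # complete-overlap limit well defined
        keep = []
        for i in range(len(xyz)):
            dup = any(
                np.linalg.norm(xyz[i] - xyz[j]) < 1e-6 and abs(rs[i] - rs[j]) < 1e-9
                for j in keep
            )
            if not dup:
                keep.append(i)
        xyz, rs = xyz[keep], rs[keep]
    pts = _sphere_points(n_points)
    total = 0.0
    n = len(xyz)
    if n == 0:
        return 0.0
    d2 = ((xyz[:, None, :] - xyz[None, :, :]) ** 2).sum(-1)
    for i in range(n):
        # neighbours whose solvent sphere can occlude atom i's surface
        nbr = np.where((d2[i] < (rs[i] + rs) ** 2) & (np.arange(n) != i))[0]
        surf = xyz[i] + rs[i] * pts
        if nbr.size:
            dd = ((surf[:, None, :] - xyz[nbr][None, :, :]) ** 2).sum(-1)
            exposed = (dd >= (rs[nbr] ** 2)[None, :]).all(axis=1)
            frac = exposed.mean()
        else:
            frac = 1.0
        total += 4.0 * np.pi * rs[i] ** 2 * frac
    return float(total)


@dataclass(frozen=True)
class DescriptorResult:
    values: dict[str, float]
    conformer: AlignedConformer


def compute_descriptors(structure: str, seed: int = 0) -> DescriptorResult:
    """All five descriptors for one molecule (conformer generated internally)."""
    conf = generate_conformer(structure, seed=seed)
    mol = conf.mol if conf.mol is not None else _as_mol(structure)
    values = {
        "b_rotN": float(count_rotatable_bonds(mol)),
        "RPC-": relative_negative_partial_charge(conf),
        "opr_leadlike": float(oprea_leadlike(mol)),
        "SlogP_VSA2": slogp_vsa2(mol),
        "ASA": accessible_surface_area(conf),
    }
    return DescriptorResult(values, conf)


def compute_descriptor_matrix(table: ActivityTable, seed: int = 0) -> pd.DataFrame:
    """n x 5 descriptor table (rows = compound ids), deterministic per seed."""
    rows, errors = {}, []
    for c in table:
        try:
            rows[c.id] = compute_descriptors(c.structure, seed=seed).values
        except Exception as exc:  # surface which compound failed
            errors.append(f"{c.id}: {exc}")
    if errors:
        raise RuntimeError("descriptor computation failed for: " + "; ".join(errors))
    df = pd.DataFrame.from_dict(rows, orient="index", columns=list(DESCRIPTOR_NAMES))
    df.index.name = "id"
    return df


def validate_descriptor_matrix(df: pd.DataFrame) -> None:
    """Raise if any descriptor-range invariant is violated."""
    if df.empty:
        return
    if not np.isfinite(df.to_numpy(dtype=float)).all():
        raise ValueError("non-finite descriptor values")
    b = df["b_rotN"]
    if ((b < 0) | (b != b.round())).any():
        raise ValueError("b_rotN must be a non-negative integer")
    if ((df["RPC-"] < 0) | (df["RPC-"] > 1)).any():
        raise ValueError("RPC- out of [0, 1]")
    if (~df["opr_leadlike"].isin([0.0, 1.0])).any():
        raise ValueError("opr_leadlike must be 0/1")
    if (df["SlogP_VSA2"] < 0).any():
        raise ValueError("SlogP_VSA2 must be >= 0")
    if (df["ASA"] <= 0).any():
        raise ValueError("ASA must be positive")
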