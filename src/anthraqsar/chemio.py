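"""Structure and activity-table I/O, conformer generation and rigid alignment.

The compound series modelled here are anthranilamide-type FXR partial
agonists whose potency is reported as EC50 in micromolar units.  Activities
are converted to pEC50 = -log10(EC50 in molar) = 6 - log10(EC50 in uM).

Conformers are generated with distance-geometry embedding followed by MMFF
minimisation; the lowest-energy conformer out of ``n_embeddings`` trials is
kept.  Partial charges default to the Gasteiger empirical model and van der
Waals radii to the Bondi set — both are explicit, switchable choices since
they feed the charge-based descriptor and the 3D fields downstream.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Sequence

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import AllChem, rdFMCS

__all__ = [
    "Compound",
    "ActivityTable",
    "AlignedConformer",
    "BONDI_RADII",
    "pec50_from_ec50",
    "ec50_from_pec50",
    "load_activity_table",
    "load_fxr_table",
    "load_designed_table",
    "generate_conformer",
    "align_to_template",
    "common_scaffold_mapping",
    "conformers_to_sdf",
]

#: Bondi van der Waals radii (Angstrom); 1.20 A for hydrogen.
BONDI_RADII: dict[str, float] = {
    "H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "F": 1.47,
    "P": 1.80, "S": 1.80, "Cl": 1.75, "Br": 1.85, "I": 1.98,
}
_DEFAULT_RADIUS = 1.70


def pec50_from_ec50(ec50_uM: float) -> float:
    """Convert a micromolar EC50 to pEC50 (=-log10 of the molar EC50)."""
    if not ec50_uM > 0:
        raise ValueError(f"EC50 must be positive, got {ec50_uM!r}")
    return 6.0 - math.log10(ec50_uM)


def ec50_from_pec50(pec50: float) -> float:
    """Inverse of :func:`pec50_from_ec50` (returns micromolar EC50)."""
    return 10.0 ** (6.0 - pec50)


@dataclass(frozen=True)
class Compound:
    """One molecule of the series: id, structure and activity."""

    id: str
    structure: str
    ec50_uM: float | None = None
    pec50: float | None = None
    split: str = "train"
    pred_mlr: float | None = None
    pred_comfa: float | None = None

    def __post_init__(self):
        if self.split not in ("train", "test"):
            raise ValueError(f"{self.id}: split must be train/test, got {self.split!r}")
        if self.ec50_uM is None and self.pec50 is None:
            raise ValueError(f"{self.id}: need ec50_uM or pec50")
        if self.ec50_uM is not None:
            derived = pec50_from_ec50(self.ec50_uM)
            if self.pec50 is None:
                object.__setattr__(self, "pec50", derived)
            elif abs(self.pec50 - derived) > 1e-3:
                raise ValueError(
                    f"{self.id}: pec50 {self.pec50} inconsistent with "
                    f"EC50 {self.ec50_uM} uM (expected {derived:.3f})"
                )

    @property
    def mol(self) -> Chem.Mol:
        m = Chem.MolFromSmiles(self.structure)
        if m is None:
            raise ValueError(f"{self.id}: unparsable structure {self.structure!r}")
        return m


@dataclass(frozen=True)
class ActivityTable:
    """An ordered compound collection with a train/test split."""

    compounds: tuple[Compound, ...]

    def __post_init__(self):
        ids = [c.id for c in self.compounds]
        dupes = {i for i in ids if ids.count(i) > 1}
        if dupes:
            raise ValueError(f"duplicate compound id(s): {sorted(dupes)}")

    def __len__(self) -> int:
        return len(self.compounds)

    def __iter__(self):
        return iter(self.compounds)

    def __getitem__(self, cid: str) -> Compound:
        for c in self.compounds:
            if c.id == cid:
                return c
        raise KeyError(cid)

    @property
    def train(self) -> tuple[Compound, ...]:
        return tuple(c for c in self.compounds if c.split == "train")

    @property
    def test(self) -> tuple[Compound, ...]:
        return tuple(c for c in self.compounds if c.split == "test")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": [c.id for c in self.compounds],
                "structure": [c.structure for c in self.compounds],
                "ec50_uM": [c.ec50_uM for c in self.compounds],
                "pec50": [c.pec50 for c in self.compounds],
                "split": [c.split for c in self.compounds],
                "pred_mlr": [c.pred_mlr for c in self.compounds],
                "pred_comfa": [c.pred_comfa for c in self.compounds],
            }
        ).set_index("id")

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path)


def _table_from_frame(df: pd.DataFrame) -> ActivityTable:
    required = {"id", "structure"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"missing required column(s): {sorted(missing)}")
    if "ec50_uM" not in df.columns and "pec50" not in df.columns:
        raise ValueError("need at least one of ec50_uM / pec50 columns")
    compounds = []
    for _, row in df.iterrows():
        cid = str(row["id"])
        smi = str(row["structure"])
        if Chem.MolFromSmiles(smi) is None:
            raise ValueError(f"row {cid!r}: unparsable structure {smi!r}")
        ec50 = row.get("ec50_uM")
        ec50 = None if ec50 is None or pd.isna(ec50) else float(ec50)
        if ec50 is not None and ec50 <= 0:
            raise ValueError(f"row {cid!r}: non-positive EC50 {ec50}")
        pec50 = row.get("pec50")
        pec50 = None if pec50 is None or pd.isna(pec50) else float(pec50)
        split = row.get("split")
        split = "train" if split is None or pd.isna(split) else str(split)
        pm = row.get("pred_mlr")
        pc = row.get("pred_comfa")
        compounds.append(
            Compound(
                id=cid, structure=smi, ec50_uM=ec50, pec50=pec50, split=split,
                pred_mlr=None if pm is None or pd.isna(pm) else float(pm),
                pred_comfa=None if pc is None or pd.isna(pc) else float(pc),
            )
        )
    return ActivityTable(tuple(compounds))


def load_activity_table(path=None, dialect: str = "csv") -> ActivityTable:
    """Load an activity table from CSV, or the packaged 41-compound fixture.

    ``dialect='packaged-fixture'`` ignores ``path`` and returns the shipped
    dataset (31 train / 10 test compounds with experimental pEC50 and the
    published 2D- and 3D-model predicted columns).
    """
    if dialect == "packaged-fixture":
        return load_fxr_table()
    if dialect != "csv":
        raise ValueError(f"unknown dialect {dialect!r}")
    return _table_from_frame(pd.read_csv(path))


def _read_packaged(name: str) -> pd.DataFrame:
    with resources.files("anthraqsar.data").joinpath(name).open() as fh:
        return pd.read_csv(fh)


def load_fxr_table() -> ActivityTable:
    """The packaged 41-compound anthranilamide FXR dataset (31 train / 10 test)."""
    table = _table_from_frame(_read_packaged("aad_fxr_table3.csv"))
    assert len(table.train) == 31 and len(table.test) == 10
    return table


def load_designed_table() -> pd.DataFrame:
    """The nine designed compounds (N1-N9) plus the template T30.

    Columns: structure (SMILES) and the published model predictions
    (pred_mlr, pred_comfa) for reference.
    """
    return _read_packaged("aad_fxr_designed.csv").set_index("id")


# ---------------------------------------------------------------------------
# Conformers

@dataclass(frozen=True)
class AlignedConformer:
    """A 3D point-atom molecule: elements, coordinates (A), charges, radii."""

    elements: tuple[str, ...]
    xyz: np.ndarray            # (n, 3) Angstrom
    charges: np.ndarray        # (n,) elementary charges
    radii: np.ndarray          # (n,) Angstrom vdW
    mol: Chem.Mol | None = field(default=None, compare=False, repr=False)

    def __post_init__(self):
        xyz = np.asarray(self.xyz, dtype=float)
        q = np.asarray(self.charges, dtype=float)
        r = np.asarray(self.radii, dtype=float)
        if xyz.shape != (len(self.elements), 3):
            raise ValueError("xyz must be (n_atoms, 3)")
        if not np.isfinite(xyz).all():
            raise ValueError("non-finite coordinates")
        if (r <= 0).any():
            raise ValueError("vdW radii must be positive")
        object.__setattr__(self, "xyz", xyz)
        object.__setattr__(self, "charges", q)
        object.__setattr__(self, "radii", r)

    def __len__(self) -> int:
        return len(self.elements)

    @property
    def heavy_mask(self) -> np.ndarray:
        return np.array([e != "H" for e in self.elements])

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "AlignedConformer":
        return replace(self, xyz=self.xyz @ rotation.T + translation)


def generate_conformer(
    structure: str,
    seed: int = 0,
    n_embeddings: int = 10,
    charge_model: str = "gasteiger",
) -> AlignedConformer:
    """Embed, MMFF-minimise and charge a molecule from a SMILES string.

    ``n_embeddings`` independent distance-geometry embeddings are each
    minimised with MMFF94 (energy convergence well below 0.01 kcal/mol) and
    the lowest-energy result kept; deterministic for fixed (structure, seed).
    """
    mol = Chem.MolFromSmiles(structure)
    if mol is None:
        raise ValueError(f"unparsable structure {structure!r}")
    mol = Chem.AddHs(mol)
    params = AllChem.ETKDGv3()
    params.randomSeed = int(seed) % (2**31 - 1)
    ids = AllChem.EmbedMultipleConfs(mol, numConfs=n_embeddings, params=params)
    if len(ids) == 0:
        # retry with random coordinates before giving up
        params.useRandomCoords = True
        ids = AllChem.EmbedMultipleConfs(mol, numConfs=n_embeddings, params=params)
        if len(ids) == 0:
            raise RuntimeError(f"3D embedding failed for {structure!r}")
    props = AllChem.MMFFGetMoleculeProperties(mol)
    best_id, best_e = None, np.inf
    for cid in ids:
        if props is not None:
            ff = AllChem.MMFFGetMoleculeForceField(mol, props, confId=cid)
            ff.Minimize(energyTol=1e-6, forceTol=1e-4)
            e = ff.CalcEnergy()
        else:  # MMFF lacks parameters for some elements (e.g. iodine-rich)
            AllChem.UFFOptimizeMolecule(mol, confId=cid)
            e = AllChem.UFFGetMoleculeForceField(mol, confId=cid).CalcEnergy()
        if e < best_e:
            best_id, best_e = cid, e
    conf = mol.GetConformer(best_id)
    xyz = np.array(conf.GetPositions(), dtype=float)

    if charge_model == "gasteiger":
        Chem.rdPartialCharges.ComputeGasteigerCharges(mol)
        q = np.array([a.GetDoubleProp("_GasteigerCharge") for a in mol.GetAtoms()])
        q = np.nan_to_num(q)
    elif charge_model == "formal":
        q = np.array([float(a.GetFormalCharge()) for a in mol.GetAtoms()])
    else:
        raise ValueError(f"unknown charge model {charge_model!r}")

    elements = tuple(a.GetSymbol() for a in mol.GetAtoms())
    radii = np.array([BONDI_RADII.get(e, _DEFAULT_RADIUS) for e in elements])
    keep = Chem.Mol(mol)
    for cid in list(ids):
        if cid != best_id:
            keep.RemoveConformer(cid)
    return AlignedConformer(elements, xyz, q, radii, mol=keep)


def _kabsch(P: np.ndarray, Q: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Optimal rotation+translation mapping P onto Q (least squares)."""
    pc, qc = P.mean(axis=0), Q.mean(axis=0)
    H = (P - pc).T @ (Q - qc)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = qc - R @ pc
    return R, t


def align_to_template(
    conformer: AlignedConformer,
    template: AlignedConformer,
    mapping: Sequence[tuple[int, int]],
) -> tuple[AlignedConformer, float]:
    """Rigidly superpose ``conformer`` onto ``template`` over mapped atoms.

    ``mapping`` is a list of (conformer_index, template_index) pairs, at
    least three and not collinear.  Returns the transformed conformer and
    the minimised RMSD over the mapped atoms.
    """
    mapping = list(mapping)
    if len(mapping) < 3:
        raise ValueError("alignment needs >= 3 mapped atom pairs")
    P = conformer.xyz[[i for i, _ in mapping]]
    Q = template.xyz[[j for _, j in mapping]]
    # collinearity check on the mapped conformer atoms
    if np.linalg.matrix_rank(P - P.mean(axis=0), tol=1e-8) < 2:
        raise ValueError("mapped atoms are collinear; alignment is degenerate")
    R, t = _kabsch(P, Q)
    moved = conformer.transformed(R, t)
    d = moved.xyz[[i for i, _ in mapping]] - Q
    rmsd = float(np.sqrt((d ** 2).sum() / len(mapping)))
    return moved, rmsd


def common_scaffold_mapping(
    mol: Compound | str, template: Compound | str, timeout: int = 10
) -> list[tuple[int, int]]:
    """Atom-index pairs of the maximum common connected substructure.

    Pairs are (mol_index, template_index) over heavy atoms, with a
    deterministic tie-break (lowest canonical match).  Raises if the shared
    substructure has fewer than three atoms.
    """
    m1 = Chem.MolFromSmiles(mol.structure if isinstance(mol, Compound) else mol)
    m2 = Chem.MolFromSmiles(template.structure if isinstance(template, Compound) else template)
    if m1 is None or m2 is None:
        raise ValueError("unparsable structure")
    res = rdFMCS.FindMCS(
        [m1, m2],
        timeout=timeout,
        atomCompare=rdFMCS.AtomCompare.CompareElements,
        bondCompare=rdFMCS.BondCompare.CompareOrder,
        ringMatchesRingOnly=True,
        completeRingsOnly=False,
    )
    if res.numAtoms < 3:
        raise ValueError("common substructure smaller than 3 atoms")
    patt = Chem.MolFromSmarts(res.smartsString)
    hit1 = min(m1.GetSubstructMatches(patt, uniquify=True) or [m1.GetSubstructMatch(patt)])
    hit2 = min(m2.GetSubstructMatches(patt, uniquify=True) or [m2.GetSubstructMatch(patt)])
    if not hit1 or not hit2:
        raise ValueError("substructure match failed")
    return list(zip(hit1, hit2))


def map_heavy_atoms_to_conformer(conf: AlignedConformer, smiles_index: int) -> int:
    """Map a heavy-atom index of the parent SMILES to the conformer (H-added) order.

    RDKit's AddHs appends hydrogens after the original heavy atoms, so the
    identity map applies; kept as a named helper to make that contract explicit.
    """
    return smiles_index


def conformers_to_sdf(confs: dict[str, AlignedConformer], path) -> None:
    """Write conformers (with 3D coordinates) to a multi-molecule SDF."""
    writer = Chem.SDWriter(str(path))
    try:
        for cid, conf in confs.items():
            if conf.mol is None:
                raise ValueError(f"{cid}: conformer carries no RDKit mol")
            mol = Chem.Mol(conf.mol)
            c = mol.GetConformer()
            for i, (x, y, z) in enumerate(conf.xyz):
                c.SetAtomPosition(i, (float(x), float(y), float(z)))
            mol.SetProp("_Name", str(cid))
            writer.write(mol)
    finally:
        writer.close()
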