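"""Multi-model PDB reading/writing via gemmi, with a flat in-memory model.

A :class:`Model` is a thin wrapper over a pandas DataFrame with one row per
atom (serial, name, element, res_name, res_seq, chain, x, y, z); a
:class:`StructureEnsemble` is an ordered list of models sharing atom
identities, as in an NMR ensemble deposited with MODEL/ENDMDL records.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import gemmi
import numpy as np
import pandas as pd

ATOM_COLUMNS = ["serial", "name", "element", "res_name", "res_seq", "chain", "x", "y", "z"]


@dataclass
class Model:
    """One coordinate set (one MODEL record of a PDB file)."""

    atoms: pd.DataFrame

    def __post_init__(self) -> None:
        missing = set(ATOM_COLUMNS) - set(self.atoms.columns)
        if missing:
            raise ValueError(f"model missing atom columns: {sorted(missing)}")
        xyz = self.atoms[["x", "y", "z"]].to_numpy(dtype=float)
        if not np.isfinite(xyz).all():
            raise ValueError("coordinates must be finite")

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def xyz(self) -> np.ndarray:
        return self.atoms[["x", "y", "z"]].to_numpy(dtype=float)

    def with_xyz(self, xyz: np.ndarray) -> "Model":
        df = self.atoms.copy()
        df[["x", "y", "z"]] = np.asarray(xyz, dtype=float)
        return Model(df)

    def select(
        self,
        res_seq: Iterable[int] | None = None,
        atom_names: Iterable[str] | None = None,
        elements: Iterable[str] | None = None,
    ) -> pd.DataFrame:
        df = self.atoms
        if res_seq is not None:
            df = df[df["res_seq"].isin(list(res_seq))]
        if atom_names is not None:
            df = df[df["name"].isin(list(atom_names))]
        if elements is not None:
            df = df[df["element"].isin(list(elements))]
        return df

    @classmethod
    def from_records(cls, records: Sequence[dict]) -> "Model":
        return cls(pd.DataFrame(records, columns=ATOM_COLUMNS))


@dataclass
class StructureEnsemble:
    """An ordered set of models sharing atom identities."""

    models: list[Model]
    label: str = ""

    def __len__(self) -> int:
        return len(self.models)

    def __getitem__(self, i: int) -> Model:
        return self.models[i]


def _model_from_gemmi(gm: gemmi.Model) -> Model:
    records = []
    serial = 0
    for chain in gm:
        for res in chain:
            for atom in res:
                serial += 1
                records.append(
                    {
                        "serial": serial,
                        "name": atom.name,
                        "element": atom.element.name,
                        "res_name": res.name,
                        "res_seq": res.seqid.num,
                        "chain": chain.name,
                        "x": atom.pos.x,
                        "y": atom.pos.y,
                        "z": atom.pos.z,
                    }
                )
    return Model.from_records(records)


def read_structure(path: str | Path, label: str | None = None) -> StructureEnsemble:
    """Read a (multi-model) PDB or mmCIF file into an ensemble."""
    st = gemmi.read_structure(str(path))
    models = [_model_from_gemmi(gm) for gm in st]
    return StructureEnsemble(models=models, label=label or st.name or Path(path).stem)


def read_pdb_string(text: str, label: str = "") -> StructureEnsemble:
    st = gemmi.read_pdb_string(text)
    return StructureEnsemble(models=[_model_from_gemmi(gm) for gm in st], label=label)


def _gemmi_from_ensemble(ens: StructureEnsemble) -> gemmi.Structure:
    st = gemmi.Structure()
    st.name = ens.label or "ensemble"
    for i, model in enumerate(ens.models, start=1):
        gm = gemmi.Model(i)
        for chain_name in model.atoms["chain"].unique():
            ch = gemmi.Chain(str(chain_name))
            cdf = model.atoms[model.atoms["chain"] == chain_name]
            for (res_seq, res_name), rdf in cdf.groupby(["res_seq", "res_name"], sort=True):
                res = gemmi.Residue()
                res.name = str(res_name)
                res.seqid = gemmi.SeqId(int(res_seq), " ")
                for r in rdf.itertuples():
                    a = gemmi.Atom()
                    a.name = str(r.name)
                    a.element = gemmi.Element(str(r.element))
                    a.pos = gemmi.Position(float(r.x), float(r.y), float(r.z))
                    res.add_atom(a)
                ch.add_residue(res)
            gm.add_chain(ch)
        st.add_model(gm)
    st.setup_entities()
    return st


def ensemble_to_pdb(ens: StructureEnsemble) -> str:
    """Serialize an ensemble as PDB text (MODEL/ENDMDL for multi-model)."""
    return _gemmi_from_ensemble(ens).make_pdb_string()


def write_structure(ens: StructureEnsemble, path: str | Path) -> None:
    Path(path).write_text(ensemble_to_pdb(ens))
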