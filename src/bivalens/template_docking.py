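"""Template-based rigid docking: place a ligand onto each dimer monomer.

The binding-mode template is a receptor-monomer:ligand complex.  Docking a
frame monomer means superposing the template's receptor-fit atoms onto the
monomer's matching atoms (Kabsch) and carrying the template's ligand along
with the same rigid transform — docking by alignment.  Receptor coordinates
are never modified; the fit RMSD is reported per dock for quality control.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import DockQualityWarning, PairingError
from .structure_io import Selection, Structure, concat_structures
from .superposition import kabsch_fit

#: Fit RMSDs above this (Å) raise a :class:`DockQualityWarning` (not fatal).
DEFAULT_FIT_RMSD_CEILING = 3.0


@dataclass
class BindingTemplate:
    """A receptor-monomer + ligand complex with declared selections.

    ``receptor_fit_selection`` names the atoms used for superposition,
    ``ligand_selection`` the atoms carried by the resulting transform and
    ``ligand_cterm_selection`` the ligand's membrane-proximal
    (carboxy-terminal) domain used for clash scoring.
    """

    complex: Structure
    receptor_fit_selection: Selection
    ligand_selection: Selection
    ligand_cterm_selection: Selection

    def __post_init__(self):
        fit = set(self.receptor_fit_selection.resolve(self.complex).tolist())
        lig = set(self.ligand_selection.resolve(self.complex).tolist())
        cterm = set(self.ligand_cterm_selection.resolve(self.complex).tolist())
        if fit & lig:
            raise ValueError(
                "receptor fit selection and ligand selection must be disjoint")
        if not cterm <= lig:
            raise ValueError(
                "ligand C-terminal selection must be a subset of the ligand")

    def ligand_structure(self) -> Structure:
        return self.complex.subset(self.ligand_selection.resolve(self.complex))

    def ligand_cterm_mask(self) -> np.ndarray:
        """Boolean mask of C-terminal-domain atoms within the ligand block."""
        lig = self.ligand_selection.resolve(self.complex)
        cterm = set(self.ligand_cterm_selection.resolve(self.complex).tolist())
        return np.array([i in cterm for i in lig.tolist()], dtype=bool)


@dataclass
class DockedComplex:
    """A dimer frame with one ligand docked per monomer.

    The ligand blocks have the template ligand's topology; ``cterm_mask``
    marks the C-terminal-domain atoms inside each block (chain relabelling
    does not disturb it).
    """

    dimer: Structure
    ligand_1: Structure
    ligand_2: Structure
    fit_rmsd_1: float
    fit_rmsd_2: float
    cterm_mask: np.ndarray = field(default_factory=lambda: np.empty(0, bool))

    def to_structure(self) -> Structure:
        """Merged receptor + both ligands, e.g. for PDB export."""
        return concat_structures([self.dimer, self.ligand_1, self.ligand_2],
                                 model_id=self.dimer.model_id)


def _paired_indices(frame: Structure, monomer_selection: Selection,
                    template: BindingTemplate) -> tuple[np.ndarray, np.ndarray]:
    idx_frame = monomer_selection.resolve(frame)
    idx_tmpl = template.receptor_fit_selection.resolve(template.complex)
    if idx_frame.size != idx_tmpl.size:
        raise PairingError(
            f"monomer selection ({idx_frame.size} atoms) and template fit "
            f"selection ({idx_tmpl.size} atoms) differ in length")
    res_frame = [frame.residue_identity()[i] for i in idx_frame]
    res_tmpl = [template.complex.residue_identity()[i] for i in idx_tmpl]
    if res_frame != res_tmpl:
        raise PairingError(
            "monomer and template fit atoms are not identity-matched "
            "(residue number / insertion code / atom name)")
    return idx_frame, idx_tmpl


def dock_one(frame: Structure, monomer_selection: Selection,
             template: BindingTemplate,
             fit_rmsd_ceiling: float = DEFAULT_FIT_RMSD_CEILING,
             ) -> tuple[Structure, float]:
    """Dock the template ligand onto one monomer of ``frame``.

    Returns the transformed ligand (a copy; the frame is untouched) and the
    receptor-fit RMSD in Å.  A fit RMSD above ``fit_rmsd_ceiling`` emits a
    :class:`DockQualityWarning`.
    """
    idx_frame, idx_tmpl = _paired_indices(frame, monomer_selection, template)
    transform, fit_rmsd = kabsch_fit(template.complex.coord[idx_tmpl],
                                     frame.coord[idx_frame])
    if fit_rmsd > fit_rmsd_ceiling:
        warnings.warn(
            f"fit RMSD {fit_rmsd:.2f} Å exceeds ceiling "
            f"{fit_rmsd_ceiling:.2f} Å (distorted monomer?)",
            DockQualityWarning)
    ligand = template.ligand_structure()
    ligand = ligand.with_coord(transform.apply(ligand.coord))
    ligand.model_id = frame.model_id
    return ligand, fit_rmsd


def _free_chain_ids(frame: Structure, count: int) -> list[str]:
    used = set(frame.chain_id.tolist())
    pool = [c for c in "XYZLMNOPQRSTUVWABCDEFGHIJK0123456789" if c not in used]
    return pool[:count]


def dock_dimer(frame: Structure, monomer_1: Selection, monomer_2: Selection,
               template: BindingTemplate,
               fit_rmsd_ceiling: float = DEFAULT_FIT_RMSD_CEILING,
               ) -> DockedComplex:
    """Dock the template ligand independently onto both monomers.

    The two monomer selections must be disjoint.  Docked ligand chains are
    relabelled to identifiers unused by the receptor so the merged complex
    is a valid PDB.
    """
    i1 = set(monomer_1.resolve(frame).tolist())
    i2 = set(monomer_2.resolve(frame).tolist())
    if i1 & i2:
        raise PairingError("the two monomer selections overlap")
    lig1, rmsd1 = dock_one(frame, monomer_1, template, fit_rmsd_ceiling)
    lig2, rmsd2 = dock_one(frame, monomer_2, template, fit_rmsd_ceiling)
    new_chains = _free_chain_ids(frame, 2)
    return DockedComplex(
        dimer=frame,
        ligand_1=lig1.with_chain_id(new_chains[0]),
        ligand_2=lig2.with_chain_id(new_chains[1]),
        fit_rmsd_1=rmsd1,
        fit_rmsd_2=rmsd2,
        cterm_mask=template.ligand_cterm_mask(),
    )
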