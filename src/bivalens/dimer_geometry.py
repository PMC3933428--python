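"""Dimer openness descriptors and reoriented-conformation builds.

Quantifies how "open" a receptor homodimer is (binding-site separation,
interface gap, opening and twist angles) and constructs alternative starting
conformations: rotating one subunit about the dimer-interface axis while
requiring that the original interface residues stay in contact, and grafting
a monomer onto another dimer's subunit arrangement (the open-homologue
orientation build).

Conventions: each monomer's long axis is the first principal component of
its selected atom cloud, with the sign fixed to point from the
interface-anchor centroid toward the binding-site centroid; the interface
axis is the line through the two interface-anchor centroids; all
constructions are exactly rigid per subunit.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation

from .errors import EmptySelectionError, RejectedBuildError
from .structure_io import Selection, Structure, concat_structures
from .superposition import kabsch_fit

DEFAULT_CONTACT_CUTOFF = 5.0  # Å, heavy-atom "still part of the interface"


@dataclass
class DimerDescriptor:
    """Geometric openness measures of one dimer conformation.

    All distances in Å, angles in degrees within [0°, 180°].
    """

    binding_site_separation: float
    interface_gap: float
    opening_angle: float
    twist_angle: float


@dataclass
class ReorientationSpec:
    """How to rotate one subunit and which contacts must survive.

    ``rotation_axis_definition="interface_axis"`` rotates about the line
    through the two interface-anchor centroids; ``"custom"`` uses
    ``custom_axis_point``/``custom_axis_direction``.  After the rotation,
    every residue in ``preserve_interface_selection`` must keep at least one
    heavy-atom contact within ``contact_cutoff`` Å of the partner monomer,
    else the build is rejected.
    """

    angle: float
    preserve_interface_selection: Selection
    rotation_axis_definition: Literal["interface_axis", "custom"] = "interface_axis"
    contact_cutoff: float = DEFAULT_CONTACT_CUTOFF
    interface_anchor_1: Selection | None = None
    interface_anchor_2: Selection | None = None
    custom_axis_point: np.ndarray | None = None
    custom_axis_direction: np.ndarray | None = None


def _heavy_centroid(structure: Structure, selection: Selection) -> np.ndarray:
    idx = selection.resolve(structure)
    heavy = idx[structure.heavy_mask[idx]]
    if heavy.size == 0:
        raise EmptySelectionError("selection contains no heavy atoms")
    return structure.coord[heavy].mean(axis=0)


def _principal_axis(coords: np.ndarray) -> np.ndarray:
    centered = coords - coords.mean(axis=0)
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    return vt[0]


def _monomer_axis(structure: Structure, monomer: Selection,
                  tail: np.ndarray, head: np.ndarray) -> np.ndarray:
    """First principal axis of the monomer cloud, oriented tail -> head."""
    idx = monomer.resolve(structure)
    names = structure.atom_name[idx]
    ca = idx[names == "CA"]
    cloud = structure.coord[ca if ca.size >= 3 else idx]
    axis = _principal_axis(cloud)
    if np.dot(axis, head - tail) < 0:
        axis = -axis
    return axis / np.linalg.norm(axis)


def _angle_deg(u: np.ndarray, v: np.ndarray) -> float:
    c = float(np.clip(np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v)),
                      -1.0, 1.0))
    return float(np.degrees(np.arccos(c)))


def describe_dimer(frame: Structure,
                   monomer_1: Selection, monomer_2: Selection,
                   binding_site_1: Selection, binding_site_2: Selection,
                   interface_anchor_1: Selection,
                   interface_anchor_2: Selection) -> DimerDescriptor:
    """Compute openness descriptors for a two-subunit dimer frame.

    Centroids are over heavy atoms of each selection; monomer axes are
    principal components of each subunit's Cα cloud (all atoms if no Cα),
    oriented from the interface-anchor centroid toward the binding-site
    centroid.  Twist is the angle between the two axes' projections onto
    the plane perpendicular to the monomer-centroid connection line.
    """
    bs1 = _heavy_centroid(frame, binding_site_1)
    bs2 = _heavy_centroid(frame, binding_site_2)
    if1 = _heavy_centroid(frame, interface_anchor_1)
    if2 = _heavy_centroid(frame, interface_anchor_2)
    u1 = _monomer_axis(frame, monomer_1, if1, bs1)
    u2 = _monomer_axis(frame, monomer_2, if2, bs2)
    c1 = _heavy_centroid(frame, monomer_1)
    c2 = _heavy_centroid(frame, monomer_2)
    sep_axis = c2 - c1
    norm = np.linalg.norm(sep_axis)
    if norm < 1e-9:
        twist = 0.0
    else:
        sep_axis = sep_axis / norm
        p1 = u1 - np.dot(u1, sep_axis) * sep_axis
        p2 = u2 - np.dot(u2, sep_axis) * sep_axis
        if np.linalg.norm(p1) < 1e-9 or np.linalg.norm(p2) < 1e-9:
            twist = 0.0
        else:
            twist = _angle_deg(p1, p2)
    return DimerDescriptor(
        binding_site_separation=float(np.linalg.norm(bs1 - bs2)),
        interface_gap=float(np.linalg.norm(if1 - if2)),
        opening_angle=_angle_deg(u1, u2),
        twist_angle=twist,
    )


def _axis_from_spec(frame: Structure,
                    spec: ReorientationSpec) -> tuple[np.ndarray, np.ndarray]:
    if spec.rotation_axis_definition == "custom":
        if spec.custom_axis_point is None or spec.custom_axis_direction is None:
            raise ValueError("custom axis requires point and direction")
        point = np.asarray(spec.custom_axis_point, dtype=np.float64)
        direction = np.asarray(spec.custom_axis_direction, dtype=np.float64)
    else:
        if spec.interface_anchor_1 is None or spec.interface_anchor_2 is None:
            raise ValueError(
                "interface_axis definition requires both anchor selections")
        a1 = _heavy_centroid(frame, spec.interface_anchor_1)
        a2 = _heavy_centroid(frame, spec.interface_anchor_2)
        point = 0.5 * (a1 + a2)
        direction = a2 - a1
    norm = np.linalg.norm(direction)
    if norm < 1e-9:
        raise ValueError("rotation axis direction is degenerate")
    return point, direction / norm


def _check_interface_contacts(structure: Structure, moving_mask: np.ndarray,
                              preserve: Selection, cutoff: float) -> list:
    """Residues in ``preserve`` lacking a cross-subunit heavy-atom contact."""
    heavy = structure.heavy_mask
    mover = np.flatnonzero(moving_mask & heavy)
    static = np.flatnonzero(~moving_mask & heavy)
    tree_m = cKDTree(structure.coord[mover])
    tree_s = cKDTree(structure.coord[static])
    idx = preserve.resolve(structure)
    idx = idx[heavy[idx]]
    lost = []
    residues: dict[tuple, list[int]] = {}
    for i in idx.tolist():
        key = (str(structure.chain_id[i]), int(structure.res_id[i]),
               str(structure.icode[i]))
        residues.setdefault(key, []).append(i)
    for key, atom_idx in sorted(residues.items()):
        coords = structure.coord[atom_idx]
        partner = tree_s if moving_mask[atom_idx[0]] else tree_m
        dists, _ = partner.query(coords, k=1)
        if float(np.min(dists)) > cutoff:
            lost.append(key)
    return lost


def reorient_dimer(frame: Structure, monomer_to_move: Selection,
                   spec: ReorientationSpec) -> Structure:
    """Rigidly rotate one subunit about the interface (or custom) axis.

    The moved subunit is an exact rigid copy of the original (internal
    geometry untouched).  After the rotation every residue of
    ``spec.preserve_interface_selection`` must retain a heavy-atom contact
    within ``spec.contact_cutoff`` Å of the partner subunit, otherwise a
    :class:`RejectedBuildError` names the lost contacts.
    """
    idx_move = monomer_to_move.resolve(frame)
    moving_mask = np.zeros(len(frame), dtype=bool)
    moving_mask[idx_move] = True
    chains_moved = set(frame.chain_id[idx_move].tolist())
    for ch in chains_moved:
        if not np.all(moving_mask[frame.chain_id == ch]):
            raise ValueError(
                f"moving selection must cover entire chains; chain {ch!r} "
                "is only partially selected")
    out = frame.copy()
    if abs(spec.angle) > 1e-15:
        point, direction = _axis_from_spec(frame, spec)
        rot = Rotation.from_rotvec(np.radians(spec.angle) * direction)
        out.coord[idx_move] = (
            rot.apply(frame.coord[idx_move] - point) + point)
    lost = _check_interface_contacts(out, moving_mask,
                                     spec.preserve_interface_selection,
                                     spec.contact_cutoff)
    if lost:
        names = ", ".join(f"{c}/{r}{(ic or '')}" for c, r, ic in lost)
        raise RejectedBuildError(
            f"reorientation by {spec.angle:g}° breaks the interface: "
            f"residues without a {spec.contact_cutoff:g} Å contact: {names}",
            lost_contacts=lost)
    return out


def graft_onto_dimer_template(monomer: Structure, dimer_template: Structure,
                              template_monomer_1: Selection,
                              template_monomer_2: Selection,
                              fit_atom_names: frozenset[str] | None = None,
                              ) -> Structure:
    """Place two rigid copies of ``monomer`` onto a dimer template.

    For each template subunit, the monomer's atoms are paired to the subunit
    by (residue number, insertion code, atom name) identity — restricted to
    ``fit_atom_names`` when given — superposed by Kabsch, and a transformed
    copy of the full monomer is emitted with the subunit's chain id.  The
    result has the template's subunit arrangement with the monomer's
    internal geometry (the open-homologue orientation build).
    """
    mono_ident = monomer.residue_identity()
    placed = []
    for tmpl_sel in (template_monomer_1, template_monomer_2):
        idx_t = tmpl_sel.resolve(dimer_template)
        tmpl_ident = [dimer_template.residue_identity()[i] for i in idx_t]
        lookup = {ident: j for j, ident in enumerate(mono_ident)}
        pairs_m, pairs_t = [], []
        for i, ident in zip(idx_t.tolist(), tmpl_ident):
            if fit_atom_names is not None and ident[2] not in fit_atom_names:
                continue
            j = lookup.get(ident)
            if j is not None:
                pairs_m.append(j)
                pairs_t.append(i)
        if len(pairs_m) < 3:
            raise EmptySelectionError(
                "fewer than 3 identity-matched fit atoms between monomer "
                "and template subunit")
        transform, _ = kabsch_fit(monomer.coord[pairs_m],
                                  dimer_template.coord[pairs_t])
        copy = monomer.with_coord(transform.apply(monomer.coord))
        copy = copy.with_chain_id(str(dimer_template.chain_id[idx_t[0]]))
        placed.append(copy)
    return concat_structures(placed, model_id=dimer_template.model_id)
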