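"""Synthetic dimer/ligand systems with known ground-truth valency.

The generator emulates the geometry that decides receptor-dimer valency:
an elongated two-subunit dimer joined at a membrane-proximal interface,
with a controllable opening angle and twist, plus an elongated tandem
two-domain ligand docked per subunit.  At small opening angles the docked
ligands' membrane-proximal (carboxy-terminal) domains collide — the
compact, monovalent geometry; at large angles they are well separated —
the open, bivalent-competent geometry.

Toy bodies are quasi-spherical atom clusters on deterministic lattices
(rings, helices and Fibonacci shells), not protein-like chains: every
downstream operation is purely geometric.  The closed-form separation of
the two carboxy-terminal domain centroids,

    s(alpha) = interface_offset + 2 * d_axial * sin(alpha / 2),

is exact for the jitter-free construction, so ground-truth bivalency flags
follow from comparing ``s`` with the hard contact bound
``2 * domain_radius + 2 * (r_vdw + r_probe)`` with margins far outside the
classifier's zero tolerance.  Randomness comes exclusively from
:func:`numpy.random.default_rng` (PCG64) seeded by the caller, so every
output is reproducible from its seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .structure_io import Ensemble, Selection, Structure, concat_structures
from .template_docking import BindingTemplate

CARBON_VDW = 1.70           # Å, matches the default radius table
DEFAULT_PROBE = 1.4         # Å

# Two well-separated opening-angle regimes (degrees) used when a bivalent
# fraction is programmed.  Compact: deep C-terminal-domain interpenetration.
# Open: separation far beyond the contact bound.
COMPACT_MEAN, COMPACT_SD, COMPACT_RANGE = 2.5, 1.0, (0.0, 5.0)
OPEN_MEAN, OPEN_SD, OPEN_RANGE = 50.0, 5.0, (35.0, 65.0)


@dataclass
class ToySystemSpec:
    """Dimensions of the toy receptor monomer and tandem ligand (Å)."""

    monomer_atom_count: int = 24
    monomer_length: float = 20.0
    ligand_domain_atom_count: int = 12
    ligand_domain_separation: float = 19.0
    interface_offset: float = 2.0
    seed: int = 0

    def __post_init__(self):
        if self.monomer_atom_count < 21:
            raise ValueError("monomer needs at least 21 atoms "
                             "(two 6-rings plus a ≥9-atom body)")
        if self.ligand_domain_atom_count < 4 \
                or self.ligand_domain_atom_count % 2 != 0:
            raise ValueError("each ligand domain needs an even count of "
                             "at least 4 atoms (centrosymmetric shell)")
        if self.monomer_length <= 0 or self.ligand_domain_separation <= 0:
            raise ValueError("degenerate spec: lengths must be positive")


@dataclass
class EnsembleSpec:
    """Sampling conditions for a synthetic conformational ensemble."""

    n_frames: int = 100
    opening_angle_mean: float = COMPACT_MEAN   # degrees
    opening_angle_sd: float = COMPACT_SD
    twist_mean: float = 0.0
    twist_sd: float = 0.0
    atom_jitter_sd: float = 0.05               # Å
    bivalent_fraction_target: float | None = None
    seed: int = 0

    def __post_init__(self):
        if self.n_frames < 1:
            raise ValueError("need at least one frame")
        if self.bivalent_fraction_target is not None and not (
                0.0 <= self.bivalent_fraction_target <= 1.0):
            raise ValueError("bivalent_fraction_target must lie in [0, 1]")


@dataclass
class ToySelections:
    """Named selections for the toy template complex and dimer frames."""

    receptor_fit: Selection
    ligand: Selection
    ligand_cterm: Selection
    monomer_1: Selection
    monomer_2: Selection
    binding_site_1: Selection
    binding_site_2: Selection
    interface_anchor_1: Selection
    interface_anchor_2: Selection


@dataclass
class ToySystem:
    """A generated monomer/ligand/template bundle plus its exact geometry."""

    spec: ToySystemSpec
    monomer: Structure
    ligand: Structure
    template: BindingTemplate
    selections: ToySelections
    cterm_axial_distance: float   # base -> C-term-domain centroid, Å
    domain_radius: float          # ligand domain shell radius, Å

    def cterm_separation(self, opening_angle_deg: float) -> float:
        """Closed-form distance between docked C-term-domain centroids."""
        return cterm_separation(opening_angle_deg, self.spec.interface_offset,
                                self.cterm_axial_distance)

    def contact_bound(self, probe_radius: float = DEFAULT_PROBE) -> float:
        """Centroid separation beyond which buried surface is exactly 0."""
        return 2.0 * self.domain_radius + 2.0 * (CARBON_VDW + probe_radius)


def cterm_separation(opening_angle_deg: float, interface_offset: float,
                     cterm_axial_distance: float) -> float:
    half = np.radians(opening_angle_deg) / 2.0
    return float(interface_offset
                 + 2.0 * cterm_axial_distance * np.sin(half))


# ---------------------------------------------------------------------------
# Deterministic body lattices
# ---------------------------------------------------------------------------

def _ring(n: int, radius: float, z: float, phase: float = 0.0) -> np.ndarray:
    phi = 2.0 * np.pi * np.arange(n) / n + phase
    return np.column_stack([radius * np.cos(phi), radius * np.sin(phi),
                            np.full(n, z)])


def _stacked_rings(n: int, radius: float, z_lo: float,
                   z_hi: float) -> np.ndarray:
    """Body atoms as ≥3-membered rings: exactly axisymmetric covariance.

    Keeping every ring rotation-symmetric about z makes the cloud's first
    principal axis exactly the z axis, which the opening-angle descriptor
    contract relies on.
    """
    n_rings = max(1, n // 4)
    sizes = np.full(n_rings, n // n_rings)
    sizes[:n % n_rings] += 1
    if np.any(sizes < 3):
        raise ValueError("body too small for symmetric rings")
    zs = np.linspace(z_lo, z_hi, n_rings)
    return np.concatenate([
        _ring(int(size), radius, z, phase=j * 0.7)
        for j, (size, z) in enumerate(zip(sizes, zs))
    ])


def _fibonacci_shell(n: int, radius: float, center: np.ndarray) -> np.ndarray:
    """Quasi-uniform, exactly centrosymmetric shell (n even).

    Half the points come from the golden-section spiral on the upper
    hemisphere and the other half are their antipodes, so the shell's
    centroid is exactly ``center`` — the closed-form ground-truth geometry
    relies on this.
    """
    if n % 2 != 0:
        raise ValueError("shell atom count must be even")
    m = n // 2
    k = np.arange(m, dtype=np.float64)
    z = 1.0 - (2.0 * k + 1.0) / (2.0 * m)      # upper hemisphere
    phi = k * np.pi * (3.0 - np.sqrt(5.0))
    rho = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    upper = np.column_stack([rho * np.cos(phi), rho * np.sin(phi), z])
    pts = np.concatenate([upper, -upper])
    return center + radius * pts


def _body(coord: np.ndarray, chain: str, first_res: int = 1) -> Structure:
    n = coord.shape[0]
    return Structure(
        serial=np.arange(1, n + 1),
        atom_name=np.full(n, "CA"),
        res_name=np.full(n, "GLY"),
        chain_id=np.full(n, chain),
        res_id=np.arange(first_res, first_res + n),
        icode=np.full(n, ""),
        element=np.full(n, "C"),
        coord=coord,
    )


# ---------------------------------------------------------------------------
# System construction
# ---------------------------------------------------------------------------

def make_toy_system(spec: ToySystemSpec | None = None) -> ToySystem:
    """Build the toy monomer, tandem ligand and binding-mode template.

    The monomer (chain R in the template) is an elongated cluster along +z:
    an interface-anchor ring at the base, a helical body, and a binding-site
    ring at the tip.  The ligand (chain L) is two Fibonacci shells on the
    monomer axis: a distal binding domain just beyond the tip, mated to the
    binding site, and a proximal carboxy-terminal domain further out.
    Construction is fully deterministic.
    """
    spec = spec or ToySystemSpec()
    L = spec.monomer_length
    n = spec.monomer_atom_count
    n_ring = 6
    mono_coord = np.concatenate([
        _ring(n_ring, 2.5, 0.05 * L),                           # interface anchors
        _stacked_rings(n - 2 * n_ring, 3.5, 0.25 * L, 0.75 * L),  # body
        _ring(n_ring, 2.5, 0.95 * L),                           # binding site
    ])
    monomer = _body(mono_coord, chain="R")

    n_d = spec.ligand_domain_atom_count
    dom_radius = 3.0
    bind_center = np.array([0.0, 0.0, L + 6.0])
    cterm_center = np.array([0.0, 0.0,
                             L + 6.0 + spec.ligand_domain_separation])
    lig_coord = np.concatenate([
        _fibonacci_shell(n_d, dom_radius, bind_center),
        _fibonacci_shell(n_d, dom_radius, cterm_center),
    ])
    ligand = _body(lig_coord, chain="L")

    template_complex = concat_structures([monomer, ligand])
    sel = ToySelections(
        receptor_fit=Selection.make(chains=["R"]),
        ligand=Selection.make(chains=["L"]),
        ligand_cterm=Selection.make(chains=["L"],
                                    residues=[(n_d + 1, 2 * n_d)]),
        monomer_1=Selection.make(chains=["A"]),
        monomer_2=Selection.make(chains=["B"]),
        binding_site_1=Selection.make(chains=["A"], residues=[(n - 5, n)]),
        binding_site_2=Selection.make(chains=["B"], residues=[(n - 5, n)]),
        interface_anchor_1=Selection.make(chains=["A"], residues=[(1, n_ring)]),
        interface_anchor_2=Selection.make(chains=["B"], residues=[(1, n_ring)]),
    )
    template = BindingTemplate(
        complex=template_complex,
        receptor_fit_selection=sel.receptor_fit,
        ligand_selection=sel.ligand,
        ligand_cterm_selection=sel.ligand_cterm,
    )
    return ToySystem(
        spec=spec, monomer=monomer, ligand=ligand, template=template,
        selections=sel,
        cterm_axial_distance=float(cterm_center[2]),
        domain_radius=dom_radius,
    )


def _rot_y(angle_rad: float) -> np.ndarray:
    c, s = np.cos(angle_rad), np.sin(angle_rad)
    return np.array([[c, 0.0, s], [0.0, 1.0, 0.0], [-s, 0.0, c]])


def _rot_z(angle_rad: float) -> np.ndarray:
    c, s = np.cos(angle_rad), np.sin(angle_rad)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def make_dimer_frame(monomer: Structure, opening_angle: float,
                     twist: float = 0.0, jitter_sd: float = 0.0,
                     seed: int = 0, interface_offset: float = 2.0,
                     model_id: int = 1) -> Structure:
    """Place two copies of the monomer about a C2 (z) axis.

    Subunit 1 (chain A) is the monomer spun by ``twist`` about its own long
    axis, tilted outward by half the opening angle about y, and shifted by
    half the interface offset along +x; subunit 2 (chain B) is its exact
    C2 image (180° about z).  Optional i.i.d. Gaussian jitter (``jitter_sd``
    Å per coordinate, seeded) is added to every atom.
    """
    if not (0.0 <= opening_angle <= 120.0):
        raise ValueError("opening angle must lie in [0°, 120°]")
    half = np.radians(opening_angle) / 2.0
    base = monomer.coord @ _rot_z(np.radians(twist)).T @ _rot_y(half).T
    base = base + np.array([interface_offset / 2.0, 0.0, 0.0])
    sub2 = base @ _rot_z(np.pi).T
    coord = np.concatenate([base, sub2])
    if jitter_sd > 0.0:
        rng = np.random.default_rng(seed)
        coord = coord + rng.normal(0.0, jitter_sd, size=coord.shape)
    n = len(monomer)
    frame = concat_structures([
        _body(coord[:n], chain="A"),
        _body(coord[n:], chain="B"),
    ], model_id=model_id)
    return frame


# ---------------------------------------------------------------------------
# Ensemble generation
# ---------------------------------------------------------------------------

def _draw_angles(rng: np.random.Generator, n: int, mean: float, sd: float,
                 lo: float, hi: float) -> np.ndarray:
    if sd <= 0.0:
        return np.full(n, np.clip(mean, lo, hi))
    return np.clip(rng.normal(mean, sd, size=n), lo, hi)


def generate_ensemble(system: ToySystem, spec: EnsembleSpec,
                      trajectory_id: str = "traj",
                      probe_radius: float = DEFAULT_PROBE,
                      ) -> tuple[Ensemble, pd.DataFrame]:
    """Generate a synthetic trajectory plus per-frame ground truth.

    With ``bivalent_fraction_target`` set, ``round(target * n_frames)``
    frames are drawn from the open regime and the rest from the compact
    regime, in seed-shuffled order, so the realised bivalent fraction is
    exact by construction.  Without a target, opening angles follow the
    spec's (mean, sd) continuum and the truth flag comes from the
    closed-form separation against the contact bound.

    Returns the ensemble and a data frame with columns ``frame``,
    ``time_ns``, ``opening_angle_deg``, ``twist_deg``,
    ``cterm_separation_A``, ``margin_A`` (separation minus contact bound;
    positive ⇒ bivalent) and ``bivalent_true``.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_frames
    bound = system.contact_bound(probe_radius)

    if spec.bivalent_fraction_target is not None:
        n_open = int(round(spec.bivalent_fraction_target * n))
        flags = np.zeros(n, dtype=bool)
        flags[:n_open] = True
        flags = flags[rng.permutation(n)]
        angles = np.empty(n)
        angles[flags] = _draw_angles(rng, int(flags.sum()),
                                     OPEN_MEAN, OPEN_SD, *OPEN_RANGE)
        angles[~flags] = _draw_angles(rng, int((~flags).sum()),
                                      COMPACT_MEAN, COMPACT_SD, *COMPACT_RANGE)
    else:
        angles = _draw_angles(rng, n, spec.opening_angle_mean,
                              spec.opening_angle_sd, 0.0, 120.0)
        flags = None

    twists = _draw_angles(rng, n, spec.twist_mean, spec.twist_sd,
                          -180.0, 180.0)
    separations = np.array([system.cterm_separation(a) for a in angles])
    if flags is None:
        flags = separations > bound

    frame_seeds = rng.integers(0, 2**31 - 1, size=n)
    frames = [
        make_dimer_frame(system.monomer, angles[k], twists[k],
                         jitter_sd=spec.atom_jitter_sd,
                         seed=int(frame_seeds[k]),
                         interface_offset=system.spec.interface_offset,
                         model_id=k + 1)
        for k in range(n)
    ]
    times = np.arange(n, dtype=np.float64)
    ensemble = Ensemble(frames=frames, trajectory_id=trajectory_id,
                        frame_times=times)
    truth = pd.DataFrame({
        "frame": np.arange(n),
        "time_ns": times,
        "opening_angle_deg": angles,
        "twist_deg": twists,
        "cterm_separation_A": separations,
        "margin_A": separations - bound,
        "bivalent_true": flags,
    })
    return ensemble, truth
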