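"""Calpha structure-based (Go-type) model: topology, energy, forces.

The potential encodes the native structure: harmonic bonds and angles
between adjacent beads, a 1+3 cosine dihedral for local (secondary)
structure, an attractive 10-12 pair term between native contacts with its
minimum exactly at the native pair distance, and a purely repulsive r^-12
excluded-volume term between all remaining pairs. All minima sit at the
native geometry, so the native conformation is a stationary point of the
potential with zero energy (up to the truncated repulsive tail).

Units: energies in the basic scale epsilon (nominally 1 kJ/mol), lengths
in nm, temperatures in reduced units epsilon/k_B.
"""
from __future__ import annotations

import dataclasses
import io

import numpy as np
from numba import njit

from .contacts import ANGSTROM_TO_NM, ContactMap
from .errors import ContactSizeMismatch, ShapeMismatch
from .geometry import bond_angle, dihedral_angle
from .structure_io import ProteinStructure

__all__ = ["SBMParameters", "SBMTopology", "build_topology",
           "potential_energy", "forces", "export_topology", "read_topology"]


@dataclasses.dataclass
class SBMParameters:
    """Force constants of the Calpha model (configurable; conventional
    ratios: backbone terms far stiffer than the contact scale)."""
    epsilon: float = 1.0            # basic energy unit
    k_bond: float = 20000.0         # eps/nm^2
    k_angle: float = 40.0           # eps/rad^2
    k_dihedral: float = 1.0         # eps
    contact_strength: float = 1.0   # eps per native contact
    nc_epsilon: float = 1.0         # eps, excluded volume
    nc_sigma: float = 0.4           # nm, excluded-volume diameter
    nonbonded_cutoff: float = 3.0   # nm
    exclusion_depth: int = 3        # bonds

    def __post_init__(self):
        for f in dataclasses.fields(self):
            if getattr(self, f.name) <= 0:
                raise ValueError(f"{f.name} must be positive")


@dataclasses.dataclass
class SBMTopology:
    label: str
    native_coords: np.ndarray       # (N, 3) nm
    bonds: np.ndarray               # (N-1, 2) int
    r0: np.ndarray                  # (N-1,) nm
    angles: np.ndarray              # (N-2, 3) int
    theta0: np.ndarray              # rad
    dihedrals: np.ndarray           # (N-3, 4) int
    phi0: np.ndarray                # rad
    contact_pairs: np.ndarray       # (M, 2) int
    contact_d: np.ndarray           # (M,) nm
    contact_eps: np.ndarray         # (M,)
    nonbonded_pairs: np.ndarray     # (K, 2) int, non-excluded non-contact
    params: SBMParameters

    @property
    def n_beads(self) -> int:
        return len(self.native_coords)

    @property
    def exclusions(self) -> set[tuple[int, int]]:
        """Pairs removed from the generic repulsion (0-based)."""
        n = self.n_beads
        excl = {(i, j) for i in range(n)
                for j in range(i + 1, min(n, i + self.params.exclusion_depth + 1))}
        excl |= {(int(i), int(j)) for i, j in self.contact_pairs}
        return excl


def build_topology(s: ProteinStructure, cm: ContactMap,
                   params: SBMParameters | None = None,
                   label: str | None = None) -> SBMTopology:
    """Derive all equilibrium values from the native Calpha coordinates."""
    params = params or SBMParameters()
    if cm.n_residues != s.n_residues:
        raise ContactSizeMismatch(
            f"map covers {cm.n_residues} residues, structure {s.n_residues}")
    x = s.ca_coords() * ANGSTROM_TO_NM
    return topology_from_coords(x, cm, params, label or s.label)


def topology_from_coords(x: np.ndarray, cm: ContactMap,
                         params: SBMParameters,
                         label: str = "") -> SBMTopology:
    n = len(x)
    bonds = np.array([[i, i + 1] for i in range(n - 1)],
                     dtype=np.int64).reshape(-1, 2)
    r0 = np.linalg.norm(x[1:] - x[:-1], axis=1)
    angles = np.array([[i, i + 1, i + 2] for i in range(n - 2)],
                      dtype=np.int64).reshape(-1, 3)
    theta0 = np.array([np.deg2rad(bond_angle(x[i], x[i + 1], x[i + 2]))
                       for i in range(n - 2)])
    dihedrals = np.array([[i, i + 1, i + 2, i + 3] for i in range(n - 3)],
                         dtype=np.int64).reshape(-1, 4)
    phi0 = np.array([np.deg2rad(dihedral_angle(x[i], x[i + 1], x[i + 2],
                                               x[i + 3]))
                     for i in range(n - 3)])
    cs = cm.sorted_contacts()
    contact_pairs = np.array([[c.i - 1, c.j - 1] for c in cs],
                             dtype=np.int64).reshape(-1, 2)
    contact_d = np.array([c.d_ij for c in cs])
    contact_eps = np.full(len(cs), params.contact_strength)
    cset = {(c.i - 1, c.j - 1) for c in cs}
    nb = [(i, j) for i in range(n)
          for j in range(i + params.exclusion_depth + 1, n)
          if (i, j) not in cset]
    nonbonded = np.array(nb, dtype=np.int64).reshape(-1, 2)
    return SBMTopology(label, np.ascontiguousarray(x, dtype=np.float64),
                       bonds, r0, angles, theta0, dihedrals, phi0,
                       contact_pairs, contact_d, contact_eps, nonbonded,
                       params)


# ---------------------------------------------------------------------------
# energy/force kernel (shared with the dynamics integrator)

@njit(cache=True)
def energy_forces_kernel(x, bonds, r0, k_bond, angles, theta0, k_angle,
                         dihedrals, phi0, k_dih, cpairs, cd, ceps,
                         nbpairs, nc_eps, nc_sigma, nb_cutoff):
    n = x.shape[0]
    f = np.zeros((n, 3))
    e_bond = 0.0
    for b in range(bonds.shape[0]):
        i, j = bonds[b, 0], bonds[b, 1]
        dx0 = x[j, 0] - x[i, 0]
        dx1 = x[j, 1] - x[i, 1]
        dx2 = x[j, 2] - x[i, 2]
        r = np.sqrt(dx0 * dx0 + dx1 * dx1 + dx2 * dx2)
        dr = r - r0[b]
        e_bond += 0.5 * k_bond * dr * dr
        fac = -k_bond * dr / r
        f[j, 0] += fac * dx0
        f[j, 1] += fac * dx1
        f[j, 2] += fac * dx2
        f[i, 0] -= fac * dx0
        f[i, 1] -= fac * dx1
        f[i, 2] -= fac * dx2

    e_angle = 0.0
    for a in range(angles.shape[0]):
        i, j, k = angles[a, 0], angles[a, 1], angles[a, 2]
        u0 = x[i, 0] - x[j, 0]
        u1 = x[i, 1] - x[j, 1]
        u2 = x[i, 2] - x[j, 2]
        v0 = x[k, 0] - x[j, 0]
        v1 = x[k, 1] - x[j, 1]
        v2 = x[k, 2] - x[j, 2]
        nu = np.sqrt(u0 * u0 + u1 * u1 + u2 * u2)
        nv = np.sqrt(v0 * v0 + v1 * v1 + v2 * v2)
        cost = (u0 * v0 + u1 * v1 + u2 * v2) / (nu * nv)
        if cost > 1.0:
            cost = 1.0
        elif cost < -1.0:
            cost = -1.0
        theta = np.arccos(cost)
        sint = np.sqrt(1.0 - cost * cost)
        if sint < 1e-8:
            sint = 1e-8
        dth = theta - theta0[a]
        e_angle += 0.5 * k_angle * dth * dth
        coeff = -k_angle * dth
        di0 = (cost * u0 / nu - v0 / nv) / (nu * sint)
        di1 = (cost * u1 / nu - v1 / nv) / (nu * sint)
        di2 = (cost * u2 / nu - v2 / nv) / (nu * sint)
        dk0 = (cost * v0 / nv - u0 / nu) / (nv * sint)
        dk1 = (cost * v1 / nv - u1 / nu) / (nv * sint)
        dk2 = (cost * v2 / nv - u2 / nu) / (nv * sint)
        f[i, 0] += coeff * di0
        f[i, 1] += coeff * di1
        f[i, 2] += coeff * di2
        f[k, 0] += coeff * dk0
        f[k, 1] += coeff * dk1
        f[k, 2] += coeff * dk2
        f[j, 0] -= coeff * (di0 + dk0)
        f[j, 1] -= coeff * (di1 + dk1)
        f[j, 2] -= coeff * (di2 + dk2)

    e_dih = 0.0
    for t in range(dihedrals.shape[0]):
        i, j, k, l = (dihedrals[t, 0], dihedrals[t, 1], dihedrals[t, 2],
                      dihedrals[t, 3])
        b10 = x[j, 0] - x[i, 0]
        b11 = x[j, 1] - x[i, 1]
        b12 = x[j, 2] - x[i, 2]
        b20 = x[k, 0] - x[j, 0]
        b21 = x[k, 1] - x[j, 1]
        b22 = x[k, 2] - x[j, 2]
        b30 = x[l, 0] - x[k, 0]
        b31 = x[l, 1] - x[k, 1]
        b32 = x[l, 2] - x[k, 2]
        n10 = b11 * b22 - b12 * b21
        n11 = b12 * b20 - b10 * b22
        n12 = b10 * b21 - b11 * b20
        n20 = b21 * b32 - b22 * b31
        n21 = b22 * b30 - b20 * b32
        n22 = b20 * b31 - b21 * b30
        b2n = np.sqrt(b20 * b20 + b21 * b21 + b22 * b22)
        n1sq = n10 * n10 + n11 * n11 + n12 * n12
        n2sq = n20 * n20 + n21 * n21 + n22 * n22
        if n1sq < 1e-16 or n2sq < 1e-16:
            continue
        m0 = n11 * b22 - n12 * b21
        m1 = n12 * b20 - n10 * b22
        m2 = n10 * b21 - n11 * b20
        yv = (m0 * n20 + m1 * n21 + m2 * n22) / b2n
        xv = n10 * n20 + n11 * n21 + n12 * n22
        phi = np.arctan2(yv, xv)
        dphi = phi - phi0[t]
        e_dih += k_dih * ((1.0 - np.cos(dphi))
                          + 0.5 * (1.0 - np.cos(3.0 * dphi)))
        dV = k_dih * (np.sin(dphi) + 1.5 * np.sin(3.0 * dphi))
        c11 = (b10 * b20 + b11 * b21 + b12 * b22) / (b2n * b2n)
        c33 = (b30 * b20 + b31 * b21 + b32 * b22) / (b2n * b2n)
        gi = b2n / n1sq
        gl = -b2n / n2sq
        for d in range(3):
            if d == 0:
                dpi = gi * n10
                dpl = gl * n20
            elif d == 1:
                dpi = gi * n11
                dpl = gl * n21
            else:
                dpi = gi * n12
                dpl = gl * n22
            dpj = (-1.0 - c11) * dpi + c33 * dpl
            dpk = c11 * dpi + (-1.0 - c33) * dpl
            f[i, d] -= dV * dpi
            f[j, d] -= dV * dpj
            f[k, d] -= dV * dpk
            f[l, d] -= dV * dpl

    e_contact = 0.0
    for c in range(cpairs.shape[0]):
        i, j = cpairs[c, 0], cpairs[c, 1]
        dx0 = x[j, 0] - x[i, 0]
        dx1 = x[j, 1] - x[i, 1]
        dx2 = x[j, 2] - x[i, 2]
        r2 = dx0 * dx0 + dx1 * dx1 + dx2 * dx2
        r = np.sqrt(r2)
        s2 = cd[c] * cd[c] / r2
        s10 = s2 * s2 * s2 * s2 * s2
        s12 = s10 * s2
        e_contact += ceps[c] * (5.0 * s12 - 6.0 * s10)
        fac = 60.0 * ceps[c] * (s12 - s10) / r2
        f[j, 0] += fac * dx0
        f[j, 1] += fac * dx1
        f[j, 2] += fac * dx2
        f[i, 0] -= fac * dx0
        f[i, 1] -= fac * dx1
        f[i, 2] -= fac * dx2

    e_nc = 0.0
    cut2 = nb_cutoff * nb_cutoff
    sig2 = nc_sigma * nc_sigma
    for p in range(nbpairs.shape[0]):
        i, j = nbpairs[p, 0], nbpairs[p, 1]
        dx0 = x[j, 0] - x[i, 0]
        dx1 = x[j, 1] - x[i, 1]
        dx2 = x[j, 2] - x[i, 2]
        r2 = dx0 * dx0 + dx1 * dx1 + dx2 * dx2
        if r2 > cut2:
            continue
        sr2 = sig2 / r2
        sr6 = sr2 * sr2 * sr2
        sr12 = sr6 * sr6
        e_nc += nc_eps * sr12
        fac = 12.0 * nc_eps * sr12 / r2
        f[j, 0] += fac * dx0
        f[j, 1] += fac * dx1
        f[j, 2] += fac * dx2
        f[i, 0] -= fac * dx0
        f[i, 1] -= fac * dx1
        f[i, 2] -= fac * dx2

    return e_bond, e_angle, e_dih, e_contact, e_nc, f


def _kernel_args(t: SBMTopology):
    p = t.params
    return (t.bonds, t.r0, p.k_bond, t.angles, t.theta0, p.k_angle,
            t.dihedrals, t.phi0, p.k_dihedral, t.contact_pairs, t.contact_d,
            t.contact_eps, t.nonbonded_pairs, p.nc_epsilon, p.nc_sigma,
            p.nonbonded_cutoff)


def potential_energy(t: SBMTopology, coords: np.ndarray):
    """Total potential energy and its components at ``coords`` (nm)."""
    coords = np.ascontiguousarray(coords, dtype=np.float64)
    if coords.shape != (t.n_beads, 3):
        raise ShapeMismatch(f"expected {(t.n_beads, 3)}, got {coords.shape}")
    eb, ea, ed, ec, en, _ = energy_forces_kernel(coords, *_kernel_args(t))
    components = {"bond": eb, "angle": ea, "dihedral": ed,
                  "contact": ec, "noncontact": en}
    return eb + ea + ed + ec + en, components


def forces(t: SBMTopology, coords: np.ndarray) -> np.ndarray:
    """-grad E at ``coords`` (nm), shape (N, 3)."""
    coords = np.ascontiguousarray(coords, dtype=np.float64)
    if coords.shape != (t.n_beads, 3):
        raise ShapeMismatch(f"expected {(t.n_beads, 3)}, got {coords.shape}")
    return energy_forces_kernel(coords, *_kernel_args(t))[5]


# ---------------------------------------------------------------------------
# GROMACS-dialect export / import

def export_topology(t: SBMTopology) -> tuple[str, str]:
    """Emit a (.top, .gro) text pair in the GROMACS dialect.

    Native 10-12 contacts go into ``[ pairs ]`` as C10/C12 coefficients
    (E = C12/r^12 - C10/r^10); the .gro carries native coordinates at
    9-decimal precision so energies round-trip through
    :func:`read_topology` to high accuracy.
    """
    p = t.params
    top = io.StringIO()
    top.write("; Calpha structure-based model\n")
    top.write("[ defaults ]\n; nbfunc comb-rule gen-pairs\n  1 1 no\n\n")
    top.write("[ atomtypes ]\n; name mass charge ptype c10 c12\n")
    c12 = p.nc_epsilon * p.nc_sigma ** 12
    top.write(f"  CA 1.000 0.000 A 0.0 {c12:.12e}\n\n")
    top.write("[ moleculetype ]\n; name exclusions\n  Macromolecule "
              f"{p.exclusion_depth}\n\n")
    top.write("[ atoms ]\n; nr type resnr residue atom cgnr charge mass\n")
    for i in range(t.n_beads):
        top.write(f"  {i + 1} CA {i + 1} GLY CA {i + 1} 0.000 1.000\n")
    top.write("\n[ bonds ]\n; ai aj func r0(nm) kb\n")
    for b in range(len(t.bonds)):
        i, j = t.bonds[b]
        top.write(f"  {i + 1} {j + 1} 1 {t.r0[b]:.9e} {p.k_bond:.9e}\n")
    top.write("\n[ angles ]\n; ai aj ak func th0(deg) ka\n")
    for a in range(len(t.angles)):
        i, j, k = t.angles[a]
        top.write(f"  {i + 1} {j + 1} {k + 1} 1 "
                  f"{np.rad2deg(t.theta0[a]):.9e} {p.k_angle:.9e}\n")
    top.write("\n[ dihedrals ]\n; ai aj ak al func phi0(deg) kd mult\n")
    for d in range(len(t.dihedrals)):
        i, j, k, l = t.dihedrals[d]
        phi = np.rad2deg(t.phi0[d])
        top.write(f"  {i + 1} {j + 1} {k + 1} {l + 1} 1 "
                  f"{phi + 180.0:.9e} {p.k_dihedral:.9e} 1\n")
        top.write(f"  {i + 1} {j + 1} {k + 1} {l + 1} 1 "
                  f"{3.0 * phi + 180.0:.9e} {0.5 * p.k_dihedral:.9e} 3\n")
    top.write("\n[ pairs ]\n; ai aj func c10 c12\n")
    for c in range(len(t.contact_pairs)):
        i, j = t.contact_pairs[c]
        d = t.contact_d[c]
        eps = t.contact_eps[c]
        top.write(f"  {i + 1} {j + 1} 1 {6.0 * eps * d ** 10:.12e} "
                  f"{5.0 * eps * d ** 12:.12e}\n")
    top.write("\n[ exclusions ]\n; ai aj\n")
    for c in range(len(t.contact_pairs)):
        i, j = t.contact_pairs[c]
        top.write(f"  {i + 1} {j + 1}\n")
    top.write("\n[ system ]\n; name\nMacromolecule\n\n"
              "[ molecules ]\n; name #molec\nMacromolecule 1\n")

    gro = io.StringIO()
    gro.write(f"{t.label or 'SBM'}\n{t.n_beads:5d}\n")
    for i, xyz in enumerate(t.native_coords):
        gro.write(f"{i + 1:5d}{'GLY':>5s}{'CA':>5s}{i + 1:5d}"
                  f"{xyz[0]:15.9f}{xyz[1]:15.9f}{xyz[2]:15.9f}\n")
    gro.write(f"{20.0:10.5f}{20.0:10.5f}{20.0:10.5f}\n")
    return top.getvalue(), gro.getvalue()


def read_topology(top_text: str, gro_text: str,
                  params: SBMParameters | None = None) -> SBMTopology:
    """Reconstruct an :class:`SBMTopology` from an exported pair."""
    lines = gro_text.splitlines()
    label = lines[0].strip()
    n = int(lines[1])
    coords = np.array([[float(v) for v in ln[20:].split()[:3]]
                       for ln in lines[2:2 + n]])

    section = None
    bonds, r0 = [], []
    angles, theta0 = [], []
    dih: dict[tuple, list] = {}
    cpairs, cd, ceps = [], [], []
    k_bond = k_angle = k_dih = None
    nc_c12 = None
    excl_depth = 3
    for raw in top_text.splitlines():
        line = raw.split(";")[0].strip()
        if not line:
            continue
        if line.startswith("["):
            section = line.strip("[] ").lower()
            continue
        parts = line.split()
        if section == "atomtypes":
            nc_c12 = float(parts[5])
        elif section == "moleculetype":
            excl_depth = int(parts[1])
        elif section == "bonds":
            bonds.append((int(parts[0]) - 1, int(parts[1]) - 1))
            r0.append(float(parts[3]))
            k_bond = float(parts[4])
        elif section == "angles":
            angles.append(tuple(int(v) - 1 for v in parts[:3]))
            theta0.append(np.deg2rad(float(parts[4])))
            k_angle = float(parts[5])
        elif section == "dihedrals":
            key = tuple(int(v) - 1 for v in parts[:4])
            mult = int(parts[7])
            phis = float(parts[5])
            if mult == 1:
                dih[key] = np.deg2rad(phis - 180.0)
                k_dih = float(parts[6])
        elif section == "pairs":
            i, j = int(parts[0]) - 1, int(parts[1]) - 1
            c10, c12 = float(parts[3]), float(parts[4])
            d = np.sqrt(6.0 * c12 / (5.0 * c10))
            eps = c10 / (6.0 * d ** 10)
            cpairs.append((i, j))
            cd.append(d)
            ceps.append(eps)

    base = params or SBMParameters()
    nc_sigma = (nc_c12 / base.nc_epsilon) ** (1.0 / 12.0) if nc_c12 else base.nc_sigma
    p = SBMParameters(epsilon=base.epsilon,
                      k_bond=k_bond or base.k_bond,
                      k_angle=k_angle or base.k_angle,
                      k_dihedral=k_dih or base.k_dihedral,
                      contact_strength=base.contact_strength,
                      nc_epsilon=base.nc_epsilon, nc_sigma=nc_sigma,
                      nonbonded_cutoff=base.nonbonded_cutoff,
                      exclusion_depth=excl_depth)
    cset = set(cpairs)
    nb = [(i, j) for i in range(n) for j in range(i + excl_depth + 1, n)
          if (i, j) not in cset]
    dih_keys = sorted(dih)
    return SBMTopology(
        label, coords,
        np.array(bonds, dtype=np.int64).reshape(-1, 2), np.array(r0),
        np.array(angles, dtype=np.int64).reshape(-1, 3), np.array(theta0),
        np.array(dih_keys, dtype=np.int64).reshape(-1, 4),
        np.array([dih[k] for k in dih_keys]),
        np.array(cpairs, dtype=np.int64).reshape(-1, 2), np.array(cd),
        np.array(ceps), np.array(nb, dtype=np.int64).reshape(-1, 2), p)
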