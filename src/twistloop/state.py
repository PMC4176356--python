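"""Internal dynamical state: positions + per-segment frame angles.

The public :class:`~twistloop.chain.BeadChain` stores derived per-junction
material twists.  Dynamics and gradients instead work on a redundant-free
representation: per-segment frame angles ``theta`` measured against
reference directors that are parallel-transported in time (quasi-static
frame).  The junction twist is

    phi_i = theta_{i+1} - theta_i + ref_i(positions),

where ``ref_i`` is the twist of the reference directors across junction i.
Linking number Lk = Tw + Wr is conserved by construction up to integrator
error, because any writhe picked up by the centre line appears in the
reference twists with the opposite sign (holonomy of the tangent path).

The positional gradient of the junction twist at fixed ``theta`` is the
standard discrete-rod expression through the curvature binormal

    kb_i = 2 (e_i x e_{i+1}) / (|e_i||e_{i+1}| + e_i . e_{i+1}),
    d phi_i / d e_i = kb_i / (2 |e_i|),   d phi_i / d e_{i+1} = kb_i / (2 |e_{i+1}|),

which the test suite checks against central finite differences of
:meth:`FrameState.energy_at`.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _geometry as geom
from .chain import (
    BeadChain,
    ForceField,
    PolymerSystem,
    WCA_CUT,
    as_system,
)

__all__ = ["FrameState"]


def _pair_energy_force(r, eps_wca, sigma, aff_eps, aff_rcut, is_affinity):
    """(energy, dV/dr) for one non-bonded pair distance."""
    if is_affinity and aff_eps > 0.0:
        if r >= aff_rcut:
            return 0.0, 0.0
        sr6 = (sigma / r) ** 6
        e = 4.0 * aff_eps * (sr6 * sr6 - sr6)
        dv = -24.0 * aff_eps * (2.0 * sr6 * sr6 - sr6) / r
        return e, dv
    if r >= WCA_CUT * sigma:
        return 0.0, 0.0
    sr6 = (sigma / r) ** 6
    e = 4.0 * eps_wca * (sr6 * sr6 - sr6) + eps_wca
    dv = -24.0 * eps_wca * (2.0 * sr6 * sr6 - sr6) / r
    return e, dv


@dataclass
class FrameState:
    """Flattened multi-ring state with time-parallel reference directors."""

    positions: np.ndarray       # (M, 3)
    theta: np.ndarray           # (M,) per-segment frame angles
    directors: np.ndarray       # (M, 3) reference directors, unit, normal to tangents
    tangents: np.ndarray        # (M, 3) tangents the directors refer to
    ring_start: np.ndarray      # (R+1,) int
    extra_bonds: np.ndarray     # (B, 2) int
    affinity_pairs: np.ndarray  # (P, 2) int
    template: PolymerSystem     # metadata carrier (diameters, labels, ...)

    # ------------------------------------------------------------------
    @classmethod
    def from_system(cls, obj: BeadChain | PolymerSystem) -> "FrameState":
        system = as_system(obj)
        pos, theta, dirs, tans = [], [], [], []
        for ch in system.chains:
            a = geom.bishop_frames(ch.positions)
            th = geom.theta_from_junction_twists(ch.positions, ch.twist_angles, a)
            pos.append(ch.positions)
            theta.append(th)
            dirs.append(a)
            tans.append(geom.ring_tangents(ch.positions))
        return cls(
            positions=np.concatenate(pos),
            theta=np.concatenate(theta),
            directors=np.concatenate(dirs),
            tangents=np.concatenate(tans),
            ring_start=system.offsets.astype(np.int64),
            extra_bonds=np.array(system.extra_bonds, dtype=np.int64).reshape(-1, 2),
            affinity_pairs=np.array(system.affinity_pairs, dtype=np.int64).reshape(-1, 2),
            template=system,
        )

    @property
    def n_rings(self) -> int:
        return len(self.ring_start) - 1

    def _ring_slices(self):
        for r in range(self.n_rings):
            yield self.ring_start[r], self.ring_start[r + 1]

    # ------------------------------------------------------------------
    def _transported_directors(self, positions: np.ndarray):
        """Directors carried by time-parallel transport onto the tangents of
        ``positions``; returns (directors, tangents)."""
        dirs = np.empty_like(self.directors)
        tans = np.empty_like(self.tangents)
        for lo, hi in self._ring_slices():
            t_new = geom.ring_tangents(positions[lo:hi])
            for k in range(hi - lo):
                d = geom.parallel_transport(self.directors[lo + k], self.tangents[lo + k], t_new[k])
                d = d - np.dot(d, t_new[k]) * t_new[k]
                dirs[lo + k] = d / np.linalg.norm(d)
                tans[lo + k] = t_new[k]
        return dirs, tans

    def junction_twists(self, positions: np.ndarray | None = None,
                        theta: np.ndarray | None = None) -> np.ndarray:
        """Material junction twists phi for the given (default: stored) DOF."""
        positions = self.positions if positions is None else positions
        theta = self.theta if theta is None else theta
        dirs, _ = self._transported_directors(positions)
        out = np.empty(len(theta))
        for lo, hi in self._ring_slices():
            out[lo:hi] = geom.junction_twists_from_theta(
                positions[lo:hi], theta[lo:hi], dirs[lo:hi]
            )
        return out

    def advance_frames(self, new_positions: np.ndarray) -> None:
        """Quasi-static update: transport reference directors onto the
        tangents of ``new_positions`` and adopt them as the new reference."""
        dirs, tans = self._transported_directors(new_positions)
        self.directors, self.tangents = dirs, tans
        self.positions = np.array(new_positions)

    # ------------------------------------------------------------------
    def energy_at(self, ff: ForceField, positions: np.ndarray | None = None,
                  theta: np.ndarray | None = None, edge: float | None = None) -> float:
        """Total energy as a function of the independent DOF (x, theta).

        This is the function whose negative gradient :meth:`forces` returns;
        reference directors are transported (not re-seeded) so the twist
        co-moves with the geometry.
        """
        positions = self.positions if positions is None else positions
        theta = self.theta if theta is None else theta
        phi = self.junction_twists(positions, theta)

        e = 0.0
        for r, (lo, hi) in enumerate(self._ring_slices()):
            p = positions[lo:hi]
            edges = geom.ring_edges(p)
            blen = np.linalg.norm(edges, axis=1)
            e += 0.5 * ff.k_bond * np.sum((blen - ff.rest_length) ** 2)
            t = edges / blen[:, None]
            e += ff.k_bend * np.sum(1.0 - np.sum(t * np.roll(t, -1, axis=0), axis=1))
            phi0 = ff.phi0_array(hi - lo)
            e += 0.5 * ff.k_dihedral * np.sum(1.0 - np.cos(phi[lo:hi] - phi0))
        e += self._pair_energy(ff, positions, edge)
        return float(e)

    def _minimum_image(self, dx, edge):
        if edge is None:
            return dx
        return dx - edge * np.round(dx / edge)

    def _wca_pairs(self) -> np.ndarray:
        from .chain import _nonbonded_pairs

        wca, _ = _nonbonded_pairs(self.template)
        return wca

    def _pair_energy(self, ff, positions, edge) -> float:
        e = 0.0
        for a, b in self.extra_bonds:
            d = np.linalg.norm(self._minimum_image(positions[b] - positions[a], edge))
            e += 0.5 * ff.k_bond * (d - ff.rest_length) ** 2
        aff = {tuple(sorted(p)) for p in self.affinity_pairs.tolist()}
        for i, j in self._wca_pairs():
            r = np.linalg.norm(self._minimum_image(positions[j] - positions[i], edge))
            e += _pair_energy_force(r, ff.eps_excluded, ff.sigma_lj, 0.0, ff.r_cut, False)[0]
        for i, j in self.affinity_pairs:
            r = np.linalg.norm(self._minimum_image(positions[j] - positions[i], edge))
            e += _pair_energy_force(r, ff.eps_excluded, ff.sigma_lj, ff.epsilon, ff.r_cut, True)[0]
        return e

    # ------------------------------------------------------------------
    def forces(self, ff: ForceField, edge: float | None = None):
        """Analytic ``(-dE/dx, -dE/dtheta)`` at the stored state."""
        m = len(self.positions)
        grad = np.zeros((m, 3))
        tq = np.zeros(m)
        pos = self.positions
        phi = self.junction_twists()

        for r, (lo, hi) in enumerate(self._ring_slices()):
            n = hi - lo
            p = pos[lo:hi]
            edges = geom.ring_edges(p)
            blen = np.linalg.norm(edges, axis=1)
            t = edges / blen[:, None]
            phi0 = ff.phi0_array(n)
            g = 0.5 * ff.k_dihedral * np.sin(phi[lo:hi] - phi0)  # dV/dphi per junction

            for i in range(n):
                inext = (i + 1) % n
                # bond i: e_i = x_{i+1} - x_i
                fb = ff.k_bond * (blen[i] - ff.rest_length) * t[i]
                grad[lo + i] += -fb
                grad[lo + inext] += fb
                # junction i between segments i and i+1 (bead i+1)
                j2 = (i + 2) % n
                c = float(np.dot(t[i], t[inext]))
                dce1 = (t[inext] - c * t[i]) / blen[i]
                dce2 = (t[i] - c * t[inext]) / blen[inext]
                # bending E = k_bend (1 - c)
                grad[lo + i] += ff.k_bend * dce1
                grad[lo + inext] += ff.k_bend * (dce2 - dce1)
                grad[lo + j2] += -ff.k_bend * dce2
                # torsion positional gradient via curvature binormal
                denom = blen[i] * blen[inext] + float(np.dot(edges[i], edges[inext]))
                kb = 2.0 * np.cross(edges[i], edges[inext]) / denom
                dphi_de1 = kb / (2.0 * blen[i])
                dphi_de2 = kb / (2.0 * blen[inext])
                grad[lo + i] += g[i] * (-dphi_de1)
                grad[lo + inext] += g[i] * (dphi_de1 - dphi_de2)
                grad[lo + j2] += g[i] * dphi_de2
            # frame-angle torques: -dE/dtheta_i = g_i - g_{i-1}
            tq[lo:hi] = g - np.roll(g, 1)

        # pair terms
        for a, b in self.extra_bonds:
            dx = self._minimum_image(pos[b] - pos[a], edge)
            d = np.linalg.norm(dx)
            f = ff.k_bond * (d - ff.rest_length) * dx / d
            grad[a] += -f
            grad[b] += f
        for i, j in self._wca_pairs():
            dx = self._minimum_image(pos[j] - pos[i], edge)
            rij = np.linalg.norm(dx)
            _, dv = _pair_energy_force(rij, ff.eps_excluded, ff.sigma_lj, 0.0, ff.r_cut, False)
            grad[i] += -dv * dx / rij
            grad[j] += dv * dx / rij
        for i, j in self.affinity_pairs:
            dx = self._minimum_image(pos[j] - pos[i], edge)
            rij = np.linalg.norm(dx)
            _, dv = _pair_energy_force(rij, ff.eps_excluded, ff.sigma_lj, ff.epsilon, ff.r_cut, True)
            grad[i] += -dv * dx / rij
            grad[j] += dv * dx / rij

        return -grad, tq

    # ------------------------------------------------------------------
    def to_system(self) -> PolymerSystem:
        """Snapshot back to public chains with derived junction twists."""
        phi = self.junction_twists()
        chains = []
        for r, (lo, hi) in enumerate(self._ring_slices()):
            tmpl = self.template.chains[r]
            chains.append(
                BeadChain(
                    positions=self.positions[lo:hi].copy(),
                    twist_angles=phi[lo:hi].copy(),
                    bead_diameter_nm=tmpl.bead_diameter_nm,
                    bp_per_bead=tmpl.bp_per_bead,
                    special_sites=dict(tmpl.special_sites),
                )
            )
        return PolymerSystem(
            chains=chains,
            extra_bonds=[tuple(b) for b in self.extra_bonds.tolist()],
            affinity_pairs=[tuple(p) for p in self.affinity_pairs.tolist()],
        )
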