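"""Finite-volume assembly and steady-state solution.

The discretized system couples, per control volume, the four tracked
species (CO2, H2CO3, HCO3-, O2) through conservative diffusive/membrane
conductances and local reaction terms, plus a well-mixed substomatal gas
node for land plants.  Steady states are found by pseudo-transient
continuation (implicit Euler steps with an adaptively growing pseudo-time
step, one Newton iteration per step) finished by undamped Newton polishing;
the DIC chemistry spans rate constants from 6e-2 to 1e7 1/s, so a fully
implicit treatment with an analytic sparse Jacobian is used throughout.
Positivity is enforced by step-length control, never by clipping.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sparse
import scipy.sparse.linalg as spla

from .geometry import GeometryModel, build_geometry
from .kinetics import BICA_AREA_FLUX_TO_INTERNAL, O2Stoichiometry
from .mesh import Mesh, discretize
from .parameters import (
    MOL_PER_INTERNAL_AMOUNT,
    micromolar_gas_to_ppm,
    proton_concentration,
)
from .scenarios import ScenarioConfig, external_boundary_values

SPECIES = ("CO2", "H2CO3", "HCO3", "O2")
NSP = 4
_SP = {s: k for k, s in enumerate(SPECIES)}


class SolverError(RuntimeError):
    def __init__(self, message: str, history: list | None = None):
        super().__init__(message)
        self.history = history or []


# ----------------------------------------------------------------------


class SteadyStateProblem:
    """Assembled nonlinear steady-state system for one scenario."""

    def __init__(self, mesh: Mesh, scenario: ScenarioConfig,
                 o2_stoichiometry: str | O2Stoichiometry = "default"):
        self.mesh = mesh
        self.scenario = scenario
        self.geometry = mesh.geometry
        self.params = mesh.geometry.params
        if isinstance(o2_stoichiometry, str):
            o2_stoichiometry = O2Stoichiometry.preset(o2_stoichiometry)
        self.o2_stoich = o2_stoichiometry
        self._assemble()

    # -- index helpers --------------------------------------------------

    def idx(self, aq_node: int, species: str) -> int:
        return self._aq_pos[aq_node] * NSP + _SP[species]

    # -- assembly -------------------------------------------------------

    def _assemble(self) -> None:
        mesh, geom, p = self.mesh, self.geometry, self.params
        comps = geom.compartments

        aq_nodes = [n for n in range(mesh.n_nodes)
                    if comps[mesh.comp_idx[n]].phase == "aqueous"]
        gas_nodes = [n for n in range(mesh.n_nodes)
                     if comps[mesh.comp_idx[n]].phase == "gas"]
        self.aq_nodes = np.asarray(aq_nodes)
        self._aq_pos = {n: k for k, n in enumerate(aq_nodes)}
        self.n_aq = len(aq_nodes)
        self.has_gas = bool(gas_nodes)
        if len(gas_nodes) > 1:
            raise ValueError("at most one gas compartment is supported")
        self.gas_node = gas_nodes[0] if gas_nodes else None
        self.n = self.n_aq * NSP + (2 if self.has_gas else 0)
        self.i_gas_co2 = self.n_aq * NSP if self.has_gas else None
        self.i_gas_o2 = self.n_aq * NSP + 1 if self.has_gas else None

        # per-unknown "volume" for pseudo-time scaling
        vols = np.repeat(mesh.volume[self.aq_nodes], NSP).astype(float)
        if self.has_gas:
            vols = np.concatenate([vols, [mesh.volume[self.gas_node]] * 2])
        self.vol_per_unknown = vols

        diffusivity = {"CO2": p.D_CO2, "H2CO3": p.D_H2CO3,
                       "HCO3": p.D_HCO3, "O2": p.D_O2}
        rows: list[int] = []
        cols: list[int] = []
        vals: list[float] = []
        b = np.zeros(self.n)

        def add(r, c, v):
            rows.append(r)
            cols.append(c)
            vals.append(v)

        def conduct(i, j, sp, g):
            pi, pj = self.idx(i, sp), self.idx(j, sp)
            add(pi, pj, g)
            add(pi, pi, -g)
            add(pj, pi, g)
            add(pj, pj, -g)

        four_pi = 4.0 * np.pi

        def node_diffusivity(node: int, sp: str) -> float:
            c = comps[mesh.comp_idx[node]]
            return diffusivity[sp] / c.viscosity

        def half_cell_resistance(node: int, sp: str, r_m: float,
                                 area: float) -> float:
            """Spherical diffusive resistance from a node centre to a
            bounding surface at radius r_m (zero for well-mixed nodes)."""
            c = comps[mesh.comp_idx[node]]
            if c.well_mixed:
                return 0.0
            frac = area / (four_pi * r_m * r_m)  # partial-coverage fraction
            rc = mesh.r_c[node]
            lo, hi = (rc, r_m) if rc < r_m else (r_m, rc)
            return (1.0 / lo - 1.0 / hi) / (four_pi * node_diffusivity(node, sp) * frac)

        # interior diffusion within aqueous compartments: exact spherical
        # shell resistance between adjacent node centres
        for (i, j, area, dist, ci) in mesh.faces:
            c = comps[ci]
            if c.phase != "aqueous":
                continue
            g_geom = four_pi / (1.0 / mesh.r_c[i] - 1.0 / mesh.r_c[j])
            for sp in SPECIES:
                conduct(i, j, sp, diffusivity[sp] / c.viscosity * g_geom)

        ext = external_boundary_values(self.scenario)
        self._ext = ext
        self.transporters: list[tuple[int, int, float, float]] = []
        self._outer_series: list[tuple[int, str, float, float]] = []  # (aq idx, sp, G, ext value)

        for itf in geom.interfaces:
            if itf.kind == "membrane":
                ni = mesh.outermost_node(itf.inner)
                nj = mesh.innermost_node(itf.outer)
                r_m = mesh.r_hi[ni]
                for sp, perm in itf.species_permeability.items():
                    if perm > 0:
                        # membrane conductance in series with the two
                        # half-cell diffusive resistances
                        r_tot = (1.0 / (perm * itf.area)
                                 + half_cell_resistance(ni, sp, r_m, itf.area)
                                 + half_cell_resistance(nj, sp, r_m, itf.area))
                        conduct(ni, nj, sp, 1.0 / r_tot)
                for t in itf.transporters:
                    self._add_transporter(t, itf.area)
            elif itf.kind == "distributed":
                nt = mesh.nodes_of(itf.inner)
                if len(nt) != 1:
                    raise ValueError("distributed interface needs a well-mixed inner node")
                targets = mesh.nodes_of(itf.outer)
                w = mesh.volume[targets] / mesh.volume[targets].sum()
                for sp, perm in itf.species_permeability.items():
                    if perm <= 0:
                        continue
                    for tnode, wk in zip(targets, w):
                        conduct(int(nt[0]), int(tnode), sp, perm * itf.area * wk)
            elif itf.kind == "series_gas":
                na = mesh.outermost_node(itf.inner)
                henry = {"CO2": p.H_CO2, "O2": p.H_O2}
                for sp, g in itf.conductance.items():
                    if g <= 0:
                        continue
                    g = 1.0 / (1.0 / g + half_cell_resistance(
                        na, sp, mesh.r_hi[na], itf.area))
                    pa = self.idx(na, sp)
                    h = henry[sp]
                    if itf.outer == "substomatal_gas":
                        pg = self.i_gas_co2 if sp == "CO2" else self.i_gas_o2
                        add(pa, pg, g / h)
                        add(pa, pa, -g)
                        add(pg, pg, -g / h)
                        add(pg, pa, g)
                    else:  # external gas Dirichlet (hornwort)
                        cext = ext[f"{sp}_gas"]
                        b[pa] += g * cext / h
                        add(pa, pa, -g)
                        self._outer_series.append((pa, sp, g, cext / h))
            elif itf.kind == "series_bulk":
                na = mesh.outermost_node(itf.inner)
                for sp, g in itf.conductance.items():
                    if g <= 0:
                        continue
                    g = 1.0 / (1.0 / g + half_cell_resistance(
                        na, sp, mesh.r_hi[na], itf.area))
                    pa = self.idx(na, sp)
                    b[pa] += g * ext[sp]
                    add(pa, pa, -g)
                    self._outer_series.append((pa, sp, g, ext[sp]))
            elif itf.kind == "stomata":
                for sp, g in itf.conductance.items():
                    pg = self.i_gas_co2 if sp == "CO2" else self.i_gas_o2
                    cext = ext[f"{sp}_gas"]
                    b[pg] += g * cext
                    add(pg, pg, -g)

        # spontaneous DIC chemistry is linear once H+ is pinned by pH: fold in
        for a in aq_nodes:
            c = comps[mesh.comp_idx[a]]
            V = mesh.volume[a]
            h = proton_concentration(c.pH)
            ic, ih2, ih3 = (self.idx(a, s) for s in ("CO2", "H2CO3", "HCO3"))
            kf, kr = p.kf_hyd, p.kr_dehyd
            kfd, krp = p.kf_deprot, p.kr_prot * h
            add(ic, ic, -kf * V)
            add(ic, ih2, kr * V)
            add(ih2, ic, kf * V)
            add(ih2, ih2, -(kr + kfd) * V)
            add(ih2, ih3, krp * V)
            add(ih3, ih2, kfd * V)
            add(ih3, ih3, -krp * V)

        self.L = sparse.csr_matrix(
            (vals, (rows, cols)), shape=(self.n, self.n))
        self.Labs = sparse.csr_matrix(
            (np.abs(vals), (rows, cols)), shape=(self.n, self.n))
        self.b = b

        # -- nonlinear bookkeeping -------------------------------------
        # carbonic anhydrase sets
        ca_node, ca_conc, ca_h, ca_lumen = [], [], [], []
        for a in aq_nodes:
            c = comps[mesh.comp_idx[a]]
            for conc, ph_used in c.ca_entries:
                ca_node.append(a)
                ca_conc.append(conc)
                ca_h.append(proton_concentration(ph_used))
                ca_lumen.append(c.name == "pyrenoid")
        self.ca_ic = np.array([self.idx(a, "CO2") for a in ca_node], dtype=int)
        self.ca_ih = np.array([self.idx(a, "HCO3") for a in ca_node], dtype=int)
        self.ca_V = np.array([mesh.volume[a] for a in ca_node])
        self.ca_conc = np.asarray(ca_conc, dtype=float)
        self.ca_h = np.asarray(ca_h, dtype=float)
        self.ca_lumen = np.asarray(ca_lumen, dtype=bool)

        # rubisco nodes
        rub, dens = [], []
        for a in aq_nodes:
            c = comps[mesh.comp_idx[a]]
            if c.rubisco_density > 0:
                rub.append(a)
                dens.append(c.rubisco_density)
        self.rub_nodes = np.asarray(rub, dtype=int)
        self.rub_ic = np.array([self.idx(a, "CO2") for a in rub], dtype=int)
        self.rub_io = np.array([self.idx(a, "O2") for a in rub], dtype=int)
        self.rub_V = np.array([mesh.volume[a] for a in rub])
        self.rub_vmax_c = np.asarray(dens, dtype=float)
        self.rub_vmax_o = self.rub_vmax_c * (p.Rub_Vmax_o / p.Rub_Vmax_c)
        self.rub_total_capacity = float((self.rub_vmax_c * self.rub_V).sum())

        # coupling targets (well-mixed sources over compartment volumes)
        cyt = mesh.nodes_of("cytosol")
        self.cyt_co2_rows = np.array([self.idx(int(a), "CO2") for a in cyt])
        self.cyt_o2_rows = np.array([self.idx(int(a), "O2") for a in cyt])
        self.cyt_w = mesh.volume[cyt] / mesh.volume[cyt].sum()
        stro = mesh.nodes_of("stroma")
        self.str_o2_rows = np.array([self.idx(int(a), "O2") for a in stro])
        self.str_w = mesh.volume[stro] / mesh.volume[stro].sum()

    def _add_transporter(self, t, area: float) -> None:
        if t.vmax <= 0:
            return
        if self._is_inside(t.source, t.dest):
            # source compartment lies outside the destination: pump inward
            src = self.mesh.innermost_node(t.source)
            dst = self.mesh.outermost_node(t.dest)
        else:
            src = self.mesh.outermost_node(t.source)
            dst = self.mesh.innermost_node(t.dest)
        vmax_int = t.vmax * area * BICA_AREA_FLUX_TO_INTERNAL
        self.transporters.append(
            (self.idx(src, t.species), self.idx(dst, t.species), vmax_int, t.km))

    def _is_inside(self, source: str, dest: str) -> bool:
        # True when the source compartment lies outside the destination
        order = [c.name for c in self.geometry.compartments if not c.well_mixed]
        return order.index(source) > order.index(dest)

    # -- residual / jacobian -------------------------------------------

    def residual(self, x: np.ndarray, want_jac: bool = False):
        """F(x) (uM um^3/s per row), row scale S, totals, optional Jacobian."""
        p = self.params
        F = self.L @ x + self.b
        S = self.Labs @ np.abs(x) + np.abs(self.b)

        jr: list[np.ndarray] = []
        jc: list[np.ndarray] = []
        jv: list[np.ndarray] = []

        def addj(r, c, v):
            jr.append(np.asarray(r, dtype=int).ravel())
            jc.append(np.asarray(c, dtype=int).ravel())
            jv.append(np.asarray(v, dtype=float).ravel())

        # carbonic anhydrase
        j_lumen = 0.0
        if len(self.ca_ic):
            co2 = x[self.ca_ic]
            hco3 = x[self.ca_ih]
            k = self.ca_conc * p.CA_kcat
            kmr = p.CA_Km_CO2 / p.CA_Km_HCO3
            num = k * (co2 - hco3 * self.ca_h / p.CA_Keq)
            den = p.CA_Km_CO2 + hco3 * kmr + co2
            rate = num / den
            amt = rate * self.ca_V
            np.add.at(F, self.ca_ic, -amt)
            np.add.at(F, self.ca_ih, amt)
            np.add.at(S, self.ca_ic, np.abs(amt))
            np.add.at(S, self.ca_ih, np.abs(amt))
            j_lumen = float(-(amt[self.ca_lumen]).sum())  # net HCO3- -> CO2
            if want_jac:
                d_co2 = (k * den - num) / den**2 * self.ca_V
                d_hco3 = (-k * self.ca_h / p.CA_Keq * den - num * kmr) / den**2 * self.ca_V
                addj(self.ca_ic, self.ca_ic, -d_co2)
                addj(self.ca_ic, self.ca_ih, -d_hco3)
                addj(self.ca_ih, self.ca_ic, d_co2)
                addj(self.ca_ih, self.ca_ih, d_hco3)

        # rubisco
        vc_tot = vo_tot = 0.0
        if len(self.rub_ic):
            co2 = x[self.rub_ic]
            o2 = x[self.rub_io]
            kc, ko = p.km_co2, p.km_o2
            dc = co2 + kc * (1.0 + o2 / ko)
            do = o2 + ko * (1.0 + co2 / kc)
            vc = self.rub_vmax_c * co2 / dc
            vo = self.rub_vmax_o * o2 / do
            amt_c = vc * self.rub_V
            amt_o = vo * self.rub_V
            vc_tot = float(amt_c.sum())
            vo_tot = float(amt_o.sum())
            np.add.at(F, self.rub_ic, -amt_c)
            np.add.at(F, self.rub_io, -amt_o)
            np.add.at(S, self.rub_ic, amt_c)
            np.add.at(S, self.rub_io, amt_o)

            dvc_dc = self.rub_vmax_c * (dc - co2) / dc**2 * self.rub_V
            dvc_do = -self.rub_vmax_c * co2 * (kc / ko) / dc**2 * self.rub_V
            dvo_do = self.rub_vmax_o * (do - o2) / do**2 * self.rub_V
            dvo_dc = -self.rub_vmax_o * o2 * (ko / kc) / do**2 * self.rub_V
            if want_jac:
                addj(self.rub_ic, self.rub_ic, -dvc_dc)
                addj(self.rub_ic, self.rub_io, -dvc_do)
                addj(self.rub_io, self.rub_io, -dvo_do)
                addj(self.rub_io, self.rub_ic, -dvo_dc)

            # global couplings: photorespired CO2 to cytosol, O2 evolution
            # to stroma, photorespiratory O2 consumption in cytosol
            st = self.o2_stoich
            src_co2 = 0.5 * vo_tot
            src_o2_str = st.evolved_per_carbox * vc_tot + st.evolved_per_oxy * vo_tot
            src_o2_cyt = -st.photoresp_o2_per_oxy * vo_tot
            np.add.at(F, self.cyt_co2_rows, src_co2 * self.cyt_w)
            np.add.at(F, self.str_o2_rows, src_o2_str * self.str_w)
            np.add.at(F, self.cyt_o2_rows, src_o2_cyt * self.cyt_w)
            np.add.at(S, self.cyt_co2_rows, abs(src_co2) * self.cyt_w)
            np.add.at(S, self.str_o2_rows, abs(src_o2_str) * self.str_w)
            np.add.at(S, self.cyt_o2_rows, abs(src_o2_cyt) * self.cyt_w)
            if want_jac:
                dvc = (dvc_dc, dvc_do)
                dvo = (dvo_dc, dvo_do)
                cols_cd = (self.rub_ic, self.rub_io)
                for w_rows, w, coeffs in (
                    (self.cyt_co2_rows, self.cyt_w, (0.5 * dvo[0], 0.5 * dvo[1])),
                    (self.str_o2_rows, self.str_w,
                     (st.evolved_per_carbox * dvc[0] + st.evolved_per_oxy * dvo[0],
                      st.evolved_per_carbox * dvc[1] + st.evolved_per_oxy * dvo[1])),
                    (self.cyt_o2_rows, self.cyt_w,
                     (-st.photoresp_o2_per_oxy * dvo[0], -st.photoresp_o2_per_oxy * dvo[1])),
                ):
                    for cols, dtot in zip(cols_cd, coeffs):
                        rr, cc = np.meshgrid(w_rows, cols, indexing="ij")
                        addj(rr, cc, np.outer(w, dtot))

        # active transport
        j_bica = 0.0
        for (isrc, idst, vmax, km) in self.transporters:
            s0 = x[isrc]
            f = vmax * s0 / (km + s0)
            j_bica += f
            F[idst] += f
            F[isrc] -= f
            S[idst] += abs(f)
            S[isrc] += abs(f)
            if want_jac:
                df = vmax * km / (km + s0) ** 2
                addj([idst], [isrc], [df])
                addj([isrc], [isrc], [-df])

        totals = {"Vc_total": vc_tot, "Vo_total": vo_tot, "J_lumenCA": j_lumen,
                  "J_BicA": j_bica}
        if not want_jac:
            return F, S, totals, None
        if jr:
            Jnl = sparse.csr_matrix(
                (np.concatenate(jv), (np.concatenate(jr), np.concatenate(jc))),
                shape=(self.n, self.n))
            J = self.L + Jnl
        else:
            J = self.L.copy()
        return F, S, totals, J

    # -- initial condition ---------------------------------------------

    def initial_state(self, co2_scale: float = 1.0) -> np.ndarray:
        """Chemical-equilibrium start: every aqueous node equilibrated with
        the external CO2 and O2 at its own compartment pH."""
        p = self.params
        ext = self._ext
        if self.scenario.organism == "alga":
            co2_aq = ext["CO2"]
            o2_aq = ext["O2"]
        else:
            co2_aq = ext["CO2_gas"] / p.H_CO2
            o2_aq = ext["O2_gas"] / p.H_O2
        co2_aq = max(co2_aq * co2_scale, 1e-9)
        x = np.empty(self.n)
        comps = self.geometry.compartments
        for a in self.aq_nodes:
            c = comps[self.mesh.comp_idx[a]]
            h = proton_concentration(c.pH)
            h2co3 = co2_aq * p.kf_hyd / p.kr_dehyd
            hco3 = h2co3 * p.kf_deprot / (p.kr_prot * h)
            x[self.idx(a, "CO2")] = co2_aq
            x[self.idx(a, "H2CO3")] = h2co3
            x[self.idx(a, "HCO3")] = hco3
            x[self.idx(a, "O2")] = o2_aq
        if self.has_gas:
            x[self.i_gas_co2] = ext["CO2_gas"]
            x[self.i_gas_o2] = ext["O2_gas"]
        return x

    # -- diagnostics ----------------------------------------------------

    def boundary_dic_influx(self, x: np.ndarray) -> float:
        """Net DIC influx across the outermost model boundary (uM um^3/s)."""
        if self.has_gas:
            for itf in self.geometry.interfaces:
                if itf.kind == "stomata":
                    g = itf.conductance["CO2"]
                    return g * (self._ext["CO2_gas"] - x[self.i_gas_co2])
        total = 0.0
        for (pa, spn, g, cext) in self._outer_series:
            if spn in ("CO2", "H2CO3", "HCO3"):
                total += g * (cext - x[pa])
        return total


# ----------------------------------------------------------------------


@dataclass
class SteadyStateSolution:
    problem: SteadyStateProblem
    x: np.ndarray
    residual_norm: float
    iterations: int
    history: list = field(default_factory=list)

    @property
    def scenario(self) -> ScenarioConfig:
        return self.problem.scenario

    def _totals(self) -> dict:
        _, _, totals, _ = self.problem.residual(self.x)
        return totals

    @property
    def Vc_total(self) -> float:
        """Total carboxylation, mol/s."""
        return self._totals()["Vc_total"] * MOL_PER_INTERNAL_AMOUNT

    @property
    def Vo_total(self) -> float:
        """Total oxygenation, mol/s."""
        return self._totals()["Vo_total"] * MOL_PER_INTERNAL_AMOUNT

    @property
    def J_lumenCA(self) -> float:
        """Net lumenal-CA dehydration flux (HCO3- -> CO2), mol/s."""
        return self._totals()["J_lumenCA"] * MOL_PER_INTERNAL_AMOUNT

    @property
    def J_BicA(self) -> float:
        """Total active bicarbonate pumping flux, mol/s."""
        return self._totals()["J_BicA"] * MOL_PER_INTERNAL_AMOUNT

    @property
    def net_fixation(self) -> float:
        """Vc - Vo/2, mol/s."""
        t = self._totals()
        return (t["Vc_total"] - 0.5 * t["Vo_total"]) * MOL_PER_INTERNAL_AMOUNT

    def rubisco_saturation(self) -> float:
        """Achieved carboxylation as a fraction of total rubisco capacity."""
        t = self._totals()
        return t["Vc_total"] / self.problem.rub_total_capacity

    def boundary_dic_influx(self) -> float:
        """mol/s across the outermost boundary."""
        return self.problem.boundary_dic_influx(self.x) * MOL_PER_INTERNAL_AMOUNT

    def concentration(self, compartment: str, species: str,
                      how: str = "mean") -> float:
        """Volume-weighted summary of a species in a compartment (uM)."""
        m = self.problem.mesh
        nodes = m.nodes_of(compartment)
        vals = np.array([self.x[self.problem.idx(int(a), species)] for a in nodes])
        vols = m.volume[nodes]
        if how == "mean":
            return float((vals * vols).sum() / vols.sum())
        if how == "max":
            return float(vals.max())
        if how == "min":
            return float(vals.min())
        raise ValueError(how)

    def substomatal_co2_ppm(self) -> float:
        pr = self.problem
        if not pr.has_gas:
            raise ValueError("scenario has no substomatal gas compartment")
        return micromolar_gas_to_ppm(self.x[pr.i_gas_co2])

    def to_frame(self) -> pd.DataFrame:
        """Node-wise concentrations as a tidy table."""
        pr = self.problem
        m = pr.mesh
        rows = []
        for a in pr.aq_nodes:
            for spn in SPECIES:
                rows.append({
                    "node": int(a), "radius_um": float(m.r_c[a]),
                    "compartment": m.compartment_name(int(a)),
                    "species": spn, "phase": "aqueous",
                    "concentration_uM": float(self.x[pr.idx(int(a), spn)]),
                    "volume_um3": float(m.volume[a]),
                })
        if pr.has_gas:
            for spn, i in (("CO2", pr.i_gas_co2), ("O2", pr.i_gas_o2)):
                rows.append({
                    "node": int(pr.gas_node), "radius_um": float(m.r_c[pr.gas_node]),
                    "compartment": "substomatal_gas", "species": spn,
                    "phase": "gas", "concentration_uM": float(self.x[i]),
                    "volume_um3": float(m.volume[pr.gas_node]),
                })
        return pd.DataFrame(rows)

    def summary(self) -> dict:
        t = self._totals()
        out = {
            "label": self.scenario.label,
            "Vc_total_mol_s": t["Vc_total"] * MOL_PER_INTERNAL_AMOUNT,
            "Vo_total_mol_s": t["Vo_total"] * MOL_PER_INTERNAL_AMOUNT,
            "J_lumenCA_mol_s": t["J_lumenCA"] * MOL_PER_INTERNAL_AMOUNT,
            "net_fixation_mol_s": (t["Vc_total"] - 0.5 * t["Vo_total"])
            * MOL_PER_INTERNAL_AMOUNT,
            "rubisco_saturation": t["Vc_total"] / self.problem.rub_total_capacity,
            "boundary_dic_influx_mol_s": self.boundary_dic_influx(),
            "residual_norm": self.residual_norm,
            "iterations": self.iterations,
        }
        if self.problem.has_gas:
            out["substomatal_co2_ppm"] = self.substomatal_co2_ppm()
        return out


# ----------------------------------------------------------------------


def assemble(mesh: Mesh, scenario: ScenarioConfig,
             o2_stoichiometry: str | O2Stoichiometry = "default") -> SteadyStateProblem:
    return SteadyStateProblem(mesh, scenario, o2_stoichiometry)


def solve_steady_state(problem: SteadyStateProblem,
                       tol: float = 1e-10,
                       max_iter: int = 600,
                       x0: np.ndarray | None = None) -> SteadyStateSolution:
    """Pseudo-transient continuation to the steady state.

    ``tol`` is relative: convergence requires max_i |F_i| <= tol * S_max,
    where S_max is the largest per-row sum of absolute flux/rate terms (a
    turnover scale).  A Newton polishing phase then pushes the residual to
    the smallest value it can reach.
    """
    x = problem.initial_state() if x0 is None else np.array(x0, dtype=float)
    V = problem.vol_per_unknown
    history: list[float] = []

    F, S, _, J = problem.residual(x, want_jac=True)
    smax = max(float(S.max()), 1e-300)
    fnorm = float(np.abs(F).max())
    history.append(fnorm)

    dt = 1e-6
    dt_max = 1e14
    best_x, best_f = x.copy(), fnorm
    it = 0
    while it < max_iter:
        if fnorm <= tol * smax:
            break
        it += 1
        A = sparse.diags(V / dt) - J
        try:
            delta = spla.spsolve(sparse.csc_matrix(A), F)
        except Exception:
            dt *= 0.25
            continue
        if not np.all(np.isfinite(delta)):
            dt *= 0.25
            continue
        # positivity-preserving step control (no clipping)
        neg = delta < 0
        alpha = 1.0
        if np.any(neg):
            lim = x[neg] / (-delta[neg] + 1e-300)
            alpha = min(1.0, 0.95 * float(lim.min()))
        if alpha <= 1e-12:
            dt *= 0.25
            continue
        x_new = x + alpha * delta
        F_new, S_new, _, J_new = problem.residual(x_new, want_jac=True)
        f_new = float(np.abs(F_new).max())
        if not np.isfinite(f_new) or f_new > 10.0 * fnorm:
            dt *= 0.25
            continue
        # accept; grow the pseudo-time step (switched evolution relaxation)
        growth = fnorm / max(f_new, 1e-300)
        dt = min(dt * min(max(growth, 1.1), 10.0), dt_max)
        x, F, J = x_new, F_new, J_new
        smax = max(float(S_new.max()), 1e-300)
        fnorm = f_new
        history.append(fnorm)
        if fnorm < best_f:
            best_x, best_f = x.copy(), fnorm

    if fnorm > tol * smax:
        raise SolverError(
            f"steady-state solve did not converge: |F|={fnorm:.3e}, "
            f"scale={smax:.3e}, tol={tol}", history)

    # Newton polish (pure Newton with positivity limiting)
    for _ in range(8):
        F, S, _, J = problem.residual(x, want_jac=True)
        f0 = float(np.abs(F).max())
        if f0 <= 1e-14 * smax:
            break
        try:
            delta = spla.spsolve(sparse.csc_matrix(-J), F)
        except Exception:
            break
        if not np.all(np.isfinite(delta)):
            break
        neg = delta < 0
        alpha = 1.0
        if np.any(neg):
            lim = x[neg] / (-delta[neg] + 1e-300)
            alpha = min(1.0, 0.95 * float(lim.min()))
        x_try = x + alpha * delta
        F_try, _, _, _ = problem.residual(x_try)
        if float(np.abs(F_try).max()) < f0:
            x = x_try
            fnorm = float(np.abs(F_try).max())
        else:
            break
        history.append(fnorm)

    return SteadyStateSolution(problem, x, residual_norm=fnorm / smax,
                               iterations=it, history=history)


def solve_scenario(scenario: ScenarioConfig, dr: float = 0.05,
                   tol: float = 1e-10,
                   o2_stoichiometry: str | O2Stoichiometry = "default",
                   x0: np.ndarray | None = None) -> SteadyStateSolution:
    """Convenience pipeline: geometry -> mesh -> assembly -> solve."""
    geom = build_geometry(scenario)
    mesh = discretize(geom, dr=dr)
    problem = assemble(mesh, scenario, o2_stoichiometry)
    return solve_steady_state(problem, tol=tol, x0=x0)


# ----------------------------------------------------------------------


def mass_balance_report(solution: SteadyStateSolution) -> pd.DataFrame:
    """Per-compartment, per-species budget: transport in - out + reactions.

    At steady state every row closes to the solver residual.  ``transport``
    is inferred as the negative of the local reaction/source total, and
    ``residual`` is the actual imbalance from the converged state.
    """
    pr = solution.problem
    F, _, _, _ = pr.residual(solution.x)
    Lx = pr.L @ solution.x + pr.b
    reaction = F - Lx  # nonlinear part: reactions, pumps, coupled sources
    rows = []
    comps = pr.geometry.compartments
    for c in comps:
        if c.phase != "aqueous":
            continue
        nodes = pr.mesh.nodes_of(c.name)
        for spn in SPECIES:
            ids = [pr.idx(int(a), spn) for a in nodes]
            rows.append({
                "compartment": c.name,
                "species": spn,
                "net_transport_mol_s": float(Lx[ids].sum()) * MOL_PER_INTERNAL_AMOUNT,
                "net_reaction_mol_s": float(reaction[ids].sum()) * MOL_PER_INTERNAL_AMOUNT,
                "residual_mol_s": float(F[ids].sum()) * MOL_PER_INTERNAL_AMOUNT,
            })
    return pd.DataFrame(rows)
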