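"""Compilation of a :class:`ReactionNetwork` into a fast ODE right-hand side.

The compiler flattens the network into index arrays once; binding a concrete
parameter vector is cheap, so the calibration and screening loops can rebuild
rate constants thousands of times without re-deriving structure.

Every species' derivative is the stoichiometry-weighted sum of reaction
fluxes.  Fluxes are cytosol-referenced; the stoichiometric matrix carries the
compartment volume ratios, rows of clamped species are zeroed, and the free
cytosolic Ca row is scaled by the buffering fraction ``f_buf``.
"""

from __future__ import annotations

import numpy as np

from .network import ReactionNetwork, RateConstant


class CompiledModel:
    """Structure-compiled ODE system; call :meth:`bind` to fix parameters."""

    def __init__(self, network: ReactionNetwork):
        self.network = network
        self.n_species = len(network.species)
        self.species_index = dict(network.index)
        n_rxn = len(network.reactions)

        comp_vol = {}
        v_cyt = network.params["V_cyt"]
        for c in network.compartments.values():
            comp_vol[c.name] = c.volume_L if c.volume_L is not None else v_cyt

        # volume factor per species: d[conc_in_comp] = flux * V_cyt / V_comp
        self.vol_factor = np.array(
            [v_cyt / comp_vol[s.compartment] for s in network.species])

        self.clamped = np.array([s.clamped for s in network.species])

        # stoichiometric matrix with volume factors folded in
        N = np.zeros((self.n_species, n_rxn))
        for j, rxn in enumerate(network.reactions):
            for sname, st in rxn.reactants.items():
                N[self.species_index[sname], j] -= st
            for sname, st in rxn.products.items():
                N[self.species_index[sname], j] += st
        N *= self.vol_factor[:, None]
        N[self.clamped, :] = 0.0
        self.N = N

        # raw stoichiometry without volume factors/clamping (conservation
        # checks are done on this one)
        self.N_raw = np.zeros((self.n_species, n_rxn))
        for j, rxn in enumerate(network.reactions):
            for sname, st in rxn.reactants.items():
                self.N_raw[self.species_index[sname], j] -= st
            for sname, st in rxn.products.items():
                self.N_raw[self.species_index[sname], j] += st

        # --- mass-action reactions: up to two distinct reactant species ----
        ma_idx, ma_i1, ma_e1, ma_i2, ma_e2, ma_k = [], [], [], [], [], []
        # --- Michaelis-Menten ----------------------------------------------
        mm_idx, mm_enz, mm_sub, mm_kcat, mm_km = [], [], [], [], []
        # --- hill fluxes -----------------------------------------------------
        hf = []

        dummy = self.n_species  # index of a constant-1 slot
        for j, rxn in enumerate(network.reactions):
            rl = rxn.rate_law
            if rl.kind == "mass_action":
                pairs = sorted(rxn.reactants.items())
                if len(pairs) > 2:
                    raise ValueError(
                        f"{rxn.name}: more than two distinct reactants")
                i1, e1 = ((self.species_index[pairs[0][0]], pairs[0][1])
                          if len(pairs) > 0 else (dummy, 1))
                i2, e2 = ((self.species_index[pairs[1][0]], pairs[1][1])
                          if len(pairs) > 1 else (dummy, 1))
                ma_idx.append(j)
                ma_i1.append(i1); ma_e1.append(e1)
                ma_i2.append(i2); ma_e2.append(e2)
                ma_k.append(rl.kf)
            elif rl.kind == "michaelis_menten":
                mm_idx.append(j)
                mm_enz.append(self.species_index[rl.enzyme])
                # substrate: the consumed reactant if any; non-consuming
                # reactions (clamped substrate pools) are patched below
                sub = next(iter(rxn.reactants)) if rxn.reactants else rl.enzyme
                mm_sub.append(self.species_index[sub])
                mm_kcat.append(rl.kcat)
                mm_km.append(rl.Km)
            else:  # hill_flux
                hf.append((j, rl))

        # NOTE: for non-consuming MM reactions (clamped substrate pools) the
        # substrate must be given explicitly; patch them here by reaction
        # name -> substrate.
        non_consuming = {"ip3_production": "PIP2", "cgmp_synthesis": "GTP"}
        for k, j in enumerate(mm_idx):
            name = network.reactions[j].name
            if name in non_consuming:
                mm_sub[k] = self.species_index[non_consuming[name]]

        self._ma = (np.array(ma_idx, dtype=int),
                    np.array(ma_i1, dtype=int), np.array(ma_e1, dtype=float),
                    np.array(ma_i2, dtype=int), np.array(ma_e2, dtype=float),
                    ma_k)
        self._mm = (np.array(mm_idx, dtype=int),
                    np.array(mm_enz, dtype=int), np.array(mm_sub, dtype=int),
                    mm_kcat, mm_km)
        self._hf = hf
        self.n_reactions = n_rxn
        self._ca_row = self.species_index["Ca_cyt"]

    # ------------------------------------------------------------------
    def bind(self, params) -> "BoundModel":
        """Fix a parameter set; returns a callable ODE system."""
        return BoundModel(self, params)

    def conservation_vector(self, component: str) -> np.ndarray:
        """Membership vector w such that w . y is conserved (w @ N_raw = 0)."""
        if component == "ArgCit":
            key = "ArgCit"
        else:
            key = component
        w = np.array([s.components.get(key, 0) for s in self.network.species],
                     dtype=float)
        return w


class BoundModel:
    def __init__(self, compiled: CompiledModel, params):
        self.compiled = compiled
        self.params = params
        c = compiled

        ma_idx, i1, e1, i2, e2, ma_k = c._ma
        self._ma_idx = ma_idx
        self._i1, self._e1, self._i2, self._e2 = i1, e1, i2, e2
        self._ma_kvals = np.array([rc.value(params) for rc in ma_k])
        # exponent-1 fast path
        self._e1_is1 = bool(np.all(e1 == 1))
        self._e2_is1 = bool(np.all(e2 == 1))

        mm_idx, enz, sub, kcat, km = c._mm
        self._mm_idx = mm_idx
        self._mm_enz, self._mm_sub = enz, sub
        self._mm_kcat = np.array([rc.value(params) for rc in kcat])
        self._mm_km = np.array([rc.value(params) for rc in km])

        self._hf = []
        for j, rl in c._hf:
            entry = {
                "j": j,
                "Imax": rl.Imax.value(params),
                "K": rl.K.value(params),
                "n": rl.n,
                "act": c.species_index[rl.activator],
                "inhibited": rl.inhibited,
                "driving": (tuple(c.species_index[s] for s in rl.driving)
                            if rl.driving else None),
                "modifier": ((c.species_index[rl.modifier[0]],
                              rl.modifier[1]) if rl.modifier else None),
            }
            self._hf.append(entry)

        self._row_scale = np.ones(c.n_species)
        self._row_scale[c._ca_row] = params["f_buf"]
        self._N = c.N
        self._nsp = c.n_species
        self._v = np.zeros(c.n_reactions)

    def fluxes(self, y: np.ndarray) -> np.ndarray:
        """Cytosol-referenced reaction fluxes (nM/min) at state ``y``."""
        Cx = np.empty(self._nsp + 1)
        np.maximum(y, 0.0, out=Cx[:-1])
        Cx[-1] = 1.0

        v = self._v
        v[:] = 0.0

        if self._e1_is1:
            a = Cx[self._i1]
        else:
            a = Cx[self._i1] ** self._e1
        if self._e2_is1:
            b = Cx[self._i2]
        else:
            b = Cx[self._i2] ** self._e2
        v[self._ma_idx] = self._ma_kvals * a * b

        s = Cx[self._mm_sub]
        v[self._mm_idx] = self._mm_kcat * Cx[self._mm_enz] * s \
            / (self._mm_km + s)

        for h in self._hf:
            x = Cx[h["act"]] ** h["n"]
            Kn = h["K"] ** h["n"]
            occ = Kn / (Kn + x) if h["inhibited"] else x / (Kn + x)
            flux = h["Imax"] * occ
            if h["driving"] is not None:
                i, k = h["driving"]
                flux *= (Cx[i] - Cx[k])
            if h["modifier"] is not None:
                m, ref = h["modifier"]
                flux *= Cx[m] / ref
            v[h["j"]] = flux
        return v

    def __call__(self, t: float, y: np.ndarray) -> np.ndarray:
        dydt = self._N @ self.fluxes(y)
        dydt *= self._row_scale
        return dydt

    def jac(self, t: float, y: np.ndarray) -> np.ndarray:
        """Analytic Jacobian d(dydt)/dy (speeds up the stiff solver)."""
        c = self.compiled
        n_sp, n_rxn = self._nsp, c.n_reactions
        Cx = np.empty(n_sp + 1)
        np.maximum(y, 0.0, out=Cx[:-1])
        Cx[-1] = 1.0

        # d(flux_r)/d(species_j), assembled sparsely then densified
        D = np.zeros((n_rxn, n_sp + 1))

        i1, e1, i2, e2 = self._i1, self._e1, self._i2, self._e2
        C1, C2 = Cx[i1], Cx[i2]
        with np.errstate(divide="ignore", invalid="ignore"):
            p1 = np.where(e1 == 1, 1.0, e1 * C1 ** (e1 - 1))
            p2 = np.where(e2 == 1, 1.0, e2 * C2 ** (e2 - 1))
        d1 = self._ma_kvals * p1 * (C2 ** e2)
        d2 = self._ma_kvals * (C1 ** e1) * p2
        np.add.at(D, (self._ma_idx, i1), d1)
        np.add.at(D, (self._ma_idx, i2), d2)

        E, S = Cx[self._mm_enz], Cx[self._mm_sub]
        denom = self._mm_km + S
        np.add.at(D, (self._mm_idx, self._mm_enz),
                  self._mm_kcat * S / denom)
        np.add.at(D, (self._mm_idx, self._mm_sub),
                  self._mm_kcat * E * self._mm_km / denom ** 2)

        for h in self._hf:
            j = h["j"]
            a = Cx[h["act"]]
            n = h["n"]
            Kn = h["K"] ** n
            an = a ** n
            occ = Kn / (Kn + an) if h["inhibited"] else an / (Kn + an)
            if a > 0 or n == 1:
                apow = 1.0 if n == 1 else a ** (n - 1)
                docc = n * Kn * apow / (Kn + an) ** 2
                if h["inhibited"]:
                    docc = -docc
            else:
                docc = 0.0
            drive = 1.0
            if h["driving"] is not None:
                di, dk = h["driving"]
                drive = Cx[di] - Cx[dk]
            mod = 1.0
            if h["modifier"] is not None:
                mi, ref = h["modifier"]
                mod = Cx[mi] / ref
            base = h["Imax"] * mod
            D[j, h["act"]] += base * docc * drive
            if h["driving"] is not None:
                D[j, di] += base * occ
                D[j, dk] -= base * occ
            if h["modifier"] is not None:
                D[j, mi] += h["Imax"] * occ * drive / ref

        # clipped states: rates do not respond below zero
        D[:, :-1][:, y < 0] = 0.0
        J = (self._N * self._row_scale[:, None]) @ D[:, :-1]
        return J


def build_odes(network: ReactionNetwork, params=None) -> BoundModel:
    """Compile ``network`` and bind ``params`` (defaults to the network's).

    The returned object maps ``(t, state) -> d(state)/dt``.
    """
    compiled = CompiledModel(network)
    return compiled.bind(params if params is not None else network.params)
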