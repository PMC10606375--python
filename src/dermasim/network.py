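"""Compartment flux-network plumbing shared by the vehicle, barrier and cell.

A :class:`FluxNetwork` is a list of nodes (each with a dilution volume) and
directed links.  Link ``l`` from node ``a`` to node ``b`` with conductance
``PA = P*SA`` and partition coefficient ``kp`` carries flux

    F_l = PA * (C_a - C_b / kp)            [kg/s]

which is added to ``b`` and removed from ``a``.  The network RHS is linear in
the amounts; nonlinear sources (particle dissolution) are layered on top by
the caller.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp

from .core import DomainError


class FluxNetwork:
    def __init__(self, volumes: np.ndarray, labels: list[str] | None = None):
        self.volumes = np.asarray(volumes, dtype=float)
        if np.any(~np.isfinite(self.volumes)) or np.any(self.volumes <= 0):
            raise DomainError("all node volumes must be positive and finite")
        self.labels = labels or [f"node{i}" for i in range(len(self.volumes))]
        self._ia: list[int] = []
        self._ib: list[int] = []
        self._pa: list[float] = []
        self._kp: list[float] = []
        self._frozen = False

    @property
    def n_nodes(self) -> int:
        return len(self.volumes)

    @property
    def n_links(self) -> int:
        return len(self._ia)

    def add_link(self, ia: int, ib: int, permeability: float, area: float,
                 kp: float = 1.0) -> None:
        if self._frozen:
            raise RuntimeError("network already frozen")
        n = self.n_nodes
        if not (0 <= ia < n and 0 <= ib < n) or ia == ib:
            raise DomainError(f"bad link endpoints ({ia}, {ib})")
        if permeability <= 0 or area <= 0 or kp <= 0:
            raise DomainError("link permeability, area and kp must be positive")
        self._ia.append(ia)
        self._ib.append(ib)
        self._pa.append(permeability * area)
        self._kp.append(kp)

    def freeze(self) -> None:
        """Build the frozen array form and the linear rate matrix."""
        self.ia = np.asarray(self._ia, dtype=np.intp)
        self.ib = np.asarray(self._ib, dtype=np.intp)
        self.pa = np.asarray(self._pa, dtype=float)
        self.kp = np.asarray(self._kp, dtype=float)
        n, m = self.n_nodes, self.n_links
        # incidence: column l has -1 at ia, +1 at ib
        rows = np.concatenate([self.ia, self.ib])
        cols = np.concatenate([np.arange(m), np.arange(m)])
        data = np.concatenate([-np.ones(m), np.ones(m)])
        self.incidence = sp.csr_matrix((data, (rows, cols)), shape=(n, m))
        # F = G @ y  with y amounts:  G[l, ia] = pa/V_a ; G[l, ib] = -pa/(V_b*kp)
        grows = np.concatenate([np.arange(m), np.arange(m)])
        gcols = np.concatenate([self.ia, self.ib])
        gdata = np.concatenate([self.pa / self.volumes[self.ia],
                                -self.pa / (self.volumes[self.ib] * self.kp)])
        G = sp.csr_matrix((gdata, (grows, gcols)), shape=(m, n))
        self.rate_matrix = (self.incidence @ G).tocsr()
        self._frozen = True

    # -- dynamics -----------------------------------------------------------

    def link_fluxes(self, conc: np.ndarray) -> np.ndarray:
        return self.pa * (conc[self.ia] - conc[self.ib] / self.kp)

    def rhs_linear(self, amounts: np.ndarray) -> np.ndarray:
        return self.rate_matrix @ amounts

    def jac_sparsity(self) -> sp.csr_matrix:
        pat = self.rate_matrix.copy()
        pat.data = np.ones_like(pat.data)
        return (pat + sp.eye(self.n_nodes, format="csr")).tocsr()

    # -- steady state -------------------------------------------------------

    def steady_concentrations(self, fixed: dict[int, float]) -> np.ndarray:
        """Concentrations solving zero net flux at every non-fixed node.

        ``fixed`` maps node index -> held concentration (Dirichlet).  Raises
        on a structurally singular (disconnected) system.
        """
        if not self._frozen:
            self.freeze()
        n = self.n_nodes
        # conductance on concentrations: node balance rows
        rows, cols, data = [], [], []
        for a, b, pa, kp in zip(self.ia, self.ib, self.pa, self.kp):
            # flux a->b = pa*(C_a - C_b/kp)
            rows += [a, a, b, b]
            cols += [a, b, a, b]
            data += [-pa, pa / kp, pa, -pa / kp]
        A = sp.csr_matrix((data, (rows, cols)), shape=(n, n)).tolil()
        rhs = np.zeros(n)
        free = np.array([i not in fixed for i in range(n)])
        c = np.zeros(n)
        for i, v in fixed.items():
            c[i] = v
        Af = A[free][:, free].tocsc()
        rhs_f = -(A[free][:, ~free] @ c[~free])
        try:
            sol = sp.linalg.spsolve(Af, rhs_f)
        except Exception as exc:  # pragma: no cover - structural failure path
            raise DomainError(f"singular flux network: {exc}") from exc
        if np.any(~np.isfinite(sol)):
            raise DomainError("singular (disconnected) flux network")
        c[free] = sol
        return c

    def node_net_flux(self, conc: np.ndarray) -> np.ndarray:
        return self.incidence @ self.link_fluxes(conc)
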